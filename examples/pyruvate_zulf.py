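"""Zero-field spectrum of [2-13C]pyruvic acid and residual-field effects.

The methyl A3X group gives two J-lines, at J_CH and 2J_CH (total proton spin
1/2 and 3/2 manifolds).  A small residual field along the magnetometer axis
splits the 2J line into its Zeeman components while the J line -- whose only
detectable transition has m = 0 on both sides -- stays single.
"""

from zulfsim import Protocol, fft_spectrum, find_peaks, peak_ratio_report, zulf_experiment
from zulfsim.fixtures import paper_fixtures, pyruvate_system

fx = paper_fixtures()["pyruvate"]

traj = zulf_experiment(pyruvate_system(), fx.protocol)
spec = fft_spectrum(traj, apodization_rate=0.5, zero_fill=4)
peaks = find_peaks(spec, 0.05, 2.0)
print("zero residual field:")
for p in peaks:
    print(f"  line at {p.position_hz:6.3f} Hz  amplitude {p.amplitude:.3e}")
report = peak_ratio_report(peaks)
print(f"  position ratio: {report.loc[0, 'position_ratio']:.4f}  (2J/J = 2)")

proto = Protocol(shuttle_time_s=0.0, guiding_field_t=0.0, dwell_time_s=4e-3,
                 n_points=4000, residual_field_t=(0.0, 0.0, 5e-8))
traj = zulf_experiment(pyruvate_system(), proto)
spec = fft_spectrum(traj, apodization_rate=0.5, zero_fill=4)
peaks = find_peaks(spec, 0.03, 2.0)
print("\n50 nT residual field along z:")
for p in peaks:
    print(f"  line at {p.position_hz:6.3f} Hz  amplitude {p.amplitude:.3e}")
n_j = sum(1 for p in peaks if 5 < p.position_hz < 8.5)
n_2j = sum(1 for p in peaks if 10.5 < p.position_hz < 14.5)
print(f"  -> J line stays single ({n_j} component), "
      f"2J line splits ({n_2j} components)")
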