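"""Collapse of the AXB zero-field multiplet with increasing exchange rate.

The AXB system (X = 13C, A/B = 1H; J_AX = 120 Hz, J_AB = 3 Hz) dissociates
its labile B proton.  Slow exchange leaves the multiplet structure split by
J_AB around 120 Hz; once the exchange rate far exceeds J_AB the B spin
averages out and all intensity collapses into the single AX line.
"""

from zulfsim import ExchangeParams, fft_spectrum, find_peaks, zulf_experiment
from zulfsim.fixtures import axb_pair, paper_fixtures

pair = axb_pair()
protocol = paper_fixtures()["AXB"].protocol

for kd in (0.5, 5.0, 50.0, 500.0):
    params = ExchangeParams(kd_s=kd, wa_s=kd)  # equimolar AXB / AX
    traj = zulf_experiment(pair, protocol, params)
    spec = fft_spectrum(traj, apodization_rate=0.5, zero_fill=4)
    peaks = find_peaks(spec, 0.10, 100.0)  # look at the 120 Hz region
    desc = ", ".join(f"{p.position_hz:.2f} Hz" for p in peaks)
    print(f"k = {kd:6.1f} 1/s: {len(peaks)} line(s) near J_AX: {desc}")
print("-> multiplet components merge into one line at J_AX once k >> J_AB")
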