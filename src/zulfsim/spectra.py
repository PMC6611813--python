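"""Fourier transformation, peak picking and line metrics.

Real detected signals (ZULF magnetometer traces) transform to the one-sided
nonnegative-frequency spectrum; complex FIDs (high-field quadrature
detection) transform to the full two-sided axis.  Peak metrics default to the
magnitude spectrum -- the ZULF phase is protocol dependent -- with a
real-part mode for high-field spectra after the trivial zero-order phasing
implied by the pulse-acquire convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "Spectrum",
    "Peak",
    "fft_spectrum",
    "find_peaks",
    "peak_ratio_report",
    "write_spectrum",
    "read_spectrum",
    "write_peaks",
]


@dataclass
class Spectrum:
    """Frequency-domain signal with its processing metadata."""

    frequency_hz: np.ndarray
    amplitude: np.ndarray  # complex
    resolution_hz: float  # 1/(N*dt) before zero-filling
    metadata: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.amplitude)

    @property
    def two_sided(self) -> bool:
        return bool(self.metadata.get("two_sided", False))


@dataclass(frozen=True)
class Peak:
    """One spectral line: position, height, width, area."""

    position_hz: float
    amplitude: float
    fwhh_hz: float
    integral: float


def fft_spectrum(
    traj,
    apodization_rate=None,
    zero_fill: int = 1,
    first_point_half: bool = True,
    remove_dc: bool | None = None,
) -> Spectrum:
    """Discrete Fourier transform of a trajectory.

    ``apodization_rate`` (1/s) multiplies the signal by ``exp(-rate*t)``
    before the transform, adding ``rate/pi`` Hz to every Lorentzian FWHH; the
    default matches the acquisition length (``1/T_acq``).  ``zero_fill``
    extends the record to ``zero_fill * n_points`` samples (interpolating the
    spectrum without changing line positions).  The customary halving of the
    first point suppresses the constant baseline offset of one-sided records
    and can be disabled for energy-conservation checks.

    ``remove_dc`` subtracts the time-domain mean before transforming: ZULF
    magnetometer traces carry the large static magnetization of the sample as
    a non-evolving offset whose zero-frequency peak would otherwise tower over
    the J-lines.  Default (``None``): on for real signals, off for complex
    FIDs (where a genuine line may sit at zero offset).
    """
    signal = np.asarray(traj.signal)
    dt = traj.dwell_time_s
    n = signal.size
    if n == 0:
        raise ValueError("empty trajectory")
    if zero_fill < 1 or int(zero_fill) != zero_fill:
        raise ValueError("zero_fill must be a positive integer")
    if remove_dc is None:
        remove_dc = not np.iscomplexobj(signal)
    if remove_dc:
        signal = signal - signal.mean()
    t_acq = n * dt
    rate = 1.0 / t_acq if apodization_rate is None else float(apodization_rate)
    y = signal * np.exp(-rate * traj.times)
    if first_point_half:
        y = y.copy()
        y[0] *= 0.5
    n_fft = int(n * zero_fill)
    if np.iscomplexobj(signal):
        amp = np.fft.fftshift(np.fft.fft(y, n_fft))
        freq = np.fft.fftshift(np.fft.fftfreq(n_fft, dt))
        two_sided = True
    else:
        amp = np.fft.rfft(y, n_fft)
        freq = np.fft.rfftfreq(n_fft, dt)
        two_sided = False
    meta = {
        "remove_dc": bool(remove_dc),
        "apodization_rate_s": rate,
        "zero_fill": int(zero_fill),
        "dwell_time_s": dt,
        "n_points": n,
        "two_sided": two_sided,
        "first_point_half": first_point_half,
    }
    meta.update(getattr(traj, "metadata", {}) or {})
    return Spectrum(frequency_hz=freq, amplitude=amp, resolution_hz=1.0 / t_acq,
                    metadata=meta)


def _representation(spec: Spectrum, mode: str) -> np.ndarray:
    if mode == "magnitude":
        return spec.magnitude
    if mode == "real":
        return spec.amplitude.real
    raise ValueError("mode must be 'magnitude' or 'real'")


def _parabolic_refine(y: np.ndarray, i: int):
    if 0 < i < y.size - 1:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if denom != 0.0:
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            if abs(delta) <= 1.0:
                height = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
                return delta, height
    return 0.0, y[i]


def _half_height_crossing(freq, y, i, half, step):
    j = i
    while 0 <= j + step < y.size and y[j + step] < y[j]:
        j += step
        if y[j] <= half:
            f0, f1 = freq[j - step], freq[j]
            y0, y1 = y[j - step], y[j]
            if y1 == y0:
                return freq[j]
            return f0 + (half - y0) * (f1 - f0) / (y1 - y0)
    return None


def _support(y, i):
    lo = i
    while lo > 0 and y[lo - 1] < y[lo]:
        lo -= 1
    hi = i
    while hi < y.size - 1 and y[hi + 1] < y[hi]:
        hi += 1
    return lo, hi


def find_peaks(
    spec: Spectrum,
    min_rel_amplitude: float = 0.05,
    exclude_below_hz: float = 2.0,
    mode: str = "magnitude",
) -> list[Peak]:
    """Locate spectral lines above a relative threshold.

    Local maxima of the chosen representation above
    ``min_rel_amplitude * max`` are kept, excluding ``|f| < exclude_below_hz``
    (the zero-frequency peak from the sample's static magnetization).
    Positions are refined by three-point parabolic interpolation, FWHH by
    linear interpolation at half height, integrals by the trapezoid rule over
    each peak's monotonic support.  An empty list (no peaks) is not an error.
    """
    y = _representation(spec, mode)
    freq = spec.frequency_hz
    included = np.abs(freq) >= exclude_below_hz
    if not included.any():
        return []
    ymax = y[included].max()
    if ymax <= 0:
        return []
    threshold = min_rel_amplitude * ymax
    y_masked = np.where(included, y, -np.inf)
    idx, _ = scipy.signal.find_peaks(y_masked, height=threshold)
    peaks = []
    df = freq[1] - freq[0] if freq.size > 1 else spec.resolution_hz
    for i in idx:
        delta, height = _parabolic_refine(y, i)
        position = freq[i] + delta * df
        half = 0.5 * height
        left = _half_height_crossing(freq, y, i, half, -1)
        right = _half_height_crossing(freq, y, i, half, +1)
        fwhh = (right - left) if (left is not None and right is not None) else np.nan
        lo, hi = _support(y, i)
        integral = float(np.trapezoid(y[lo:hi + 1], freq[lo:hi + 1]))
        peaks.append(Peak(position_hz=float(position), amplitude=float(height),
                          fwhh_hz=float(fwhh), integral=integral))
    peaks.sort(key=lambda p: p.position_hz)
    return peaks


def peak_ratio_report(peaks) -> pd.DataFrame:
    """Pairwise position and amplitude ratios, sorted by position.

    For each pair (i, j) with position_i < position_j the ratios
    ``position_j/position_i`` and ``amplitude_j/amplitude_i`` are tabulated;
    this is the direct check for multiplet patterns such as the 2J/J line
    pair of an A3X system or the 1:4:6:4:1 quintet.
    """
    peaks = sorted(peaks, key=lambda p: p.position_hz)
    if len(peaks) < 2:
        raise ValueError("need at least two peaks for a ratio report")
    rows = []
    for a in range(len(peaks)):
        for b in range(a + 1, len(peaks)):
            pa, pb = peaks[a], peaks[b]
            rows.append({
                "position_a_hz": pa.position_hz,
                "position_b_hz": pb.position_hz,
                "position_ratio": pb.position_hz / pa.position_hz
                if pa.position_hz != 0 else np.inf,
                "amplitude_a": pa.amplitude,
                "amplitude_b": pb.amplitude,
                "amplitude_ratio": pb.amplitude / pa.amplitude
                if pa.amplitude != 0 else np.inf,
            })
    return pd.DataFrame(rows)


def write_spectrum(path, spec: Spectrum, header: dict | None = None,
                   mode: str = "magnitude") -> None:
    """Two-column delimited text: frequency_Hz, amplitude; '#' header lines."""
    y = _representation(spec, mode)
    lines = []
    meta = dict(spec.metadata)
    if header:
        meta.update(header)
    for key in sorted(meta):
        lines.append(f"# {key}: {meta[key]}")
    lines.append("# columns: frequency_hz amplitude")
    for f, a in zip(spec.frequency_hz, y):
        lines.append(f"{f:.10g}\t{a:.10g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spectrum(path) -> Spectrum:
    """Read a spectrum written by :func:`write_spectrum`."""
    meta = {}
    freqs, amps = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            f, a = line.split()
            freqs.append(float(f))
            amps.append(float(a))
    freq = np.array(freqs)
    res = float(meta.get("resolution_hz", freq[1] - freq[0] if freq.size > 1 else 0.0))
    return Spectrum(frequency_hz=freq, amplitude=np.array(amps, dtype=complex),
                    resolution_hz=res, metadata=meta)


def write_peaks(path, peaks, header: dict | None = None) -> None:
    """Delimited peak table: position_hz, amplitude, fwhh_hz, integral."""
    lines = []
    for key in sorted(header or {}):
        lines.append(f"# {key}: {header[key]}")
    lines.append("# columns: position_hz amplitude fwhh_hz integral")
    for p in peaks:
        lines.append(f"{p.position_hz:.10g}\t{p.amplitude:.10g}\t"
                     f"{p.fwhh_hz:.10g}\t{p.integral:.10g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
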