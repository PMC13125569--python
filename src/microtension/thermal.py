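"""DSC endotherm analysis: onset temperature, peak temperature and FWHM.

Collagen thermal denaturation appears as an endothermic peak in a heat-flow
scan (here 20–100 °C at a nominal 5 °C/min). The transition is characterised
by a linear baseline fitted over two flanking temperature windows, the peak
temperature of the baseline-subtracted signal, the full width at half
maximum by linear interpolation, and an ISO-style onset: the intersection of
the baseline with the tangent at the point of maximum slope on the leading
edge. Higher onset temperatures indicate a more crosslinked, thermally
stabilised collagen network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = ["Endotherm", "EndothermMetrics", "endotherm_metrics"]


@dataclass(frozen=True)
class Endotherm:
    """One heat-flow scan. ``endo_down=True`` marks instruments that plot
    endothermic events as negative heat flow; curves are sign-normalised so
    the transition is a positive peak before analysis."""

    temperature_C: np.ndarray
    heat_flow: np.ndarray
    scan_rate_C_min: float = 5.0
    endo_down: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_C, dtype=float)
        h = np.asarray(self.heat_flow, dtype=float)
        if t.shape != h.shape or t.size < 10:
            raise InputError("temperature and heat flow must be equal-length, ≥10 samples")
        if not np.all(np.diff(t) > 0):
            raise InputError("temperature must be strictly increasing")
        if self.scan_rate_C_min <= 0:
            raise InputError("scan rate must be > 0")
        object.__setattr__(self, "temperature_C", t)
        object.__setattr__(self, "heat_flow", h)


@dataclass(frozen=True)
class EndothermMetrics:
    T_onset_C: float
    T_peak_C: float
    FWHM_C: float
    peak_height: float
    baseline_coeffs: tuple  # (slope, intercept)


def _crossing(t: np.ndarray, s: np.ndarray, level: float,
              rising: bool) -> float:
    """First (rising) or last (falling) linear-interpolated crossing of level."""
    above = s >= level
    if rising:
        idx = np.nonzero(~above[:-1] & above[1:])[0]
        if idx.size == 0:
            raise InputError("no rising half-maximum crossing found")
        i = int(idx[0])
    else:
        idx = np.nonzero(above[:-1] & ~above[1:])[0]
        if idx.size == 0:
            raise InputError("no falling half-maximum crossing found")
        i = int(idx[-1])
    frac = (level - s[i]) / (s[i + 1] - s[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def endotherm_metrics(curve: Endotherm,
                      baseline_windows: tuple) -> EndothermMetrics:
    """Extract T_onset, T_peak and FWHM from one endotherm.

    ``baseline_windows`` is a pair of (T_lo, T_hi) intervals flanking the
    transition, each covering ≥5 samples; a straight baseline is fitted over
    their union and subtracted. The peak must exceed 3× the baseline-fit
    residual SD, and the windows must not contain the peak.
    """
    t = curve.temperature_C
    hf = curve.heat_flow if not curve.endo_down else -curve.heat_flow
    (lo1, hi1), (lo2, hi2) = baseline_windows
    sel = ((t >= lo1) & (t <= hi1)) | ((t >= lo2) & (t <= hi2))
    for (lo, hi) in ((lo1, hi1), (lo2, hi2)):
        if int(((t >= lo) & (t <= hi)).sum()) < 5:
            raise InputError(f"baseline window ({lo}, {hi}) covers <5 samples")
    slope, intercept = np.polyfit(t[sel], hf[sel], 1)
    baseline = slope * t + intercept
    raw_signal = hf - baseline
    resid_sd = float(np.std(hf[sel] - baseline[sel]))

    # light Savitzky–Golay smoothing so slope/peak extraction tolerates
    # instrument noise; cubic windows preserve Gaussian-like peaks
    if t.size >= 50:
        from scipy.signal import savgol_filter

        win = min(2 * (t.size // 80) + 1, 81)
        win = max(win, 5)
        signal = savgol_filter(raw_signal, win, 3)
    else:
        signal = raw_signal

    i_peak = int(np.argmax(signal))
    peak_height = float(signal[i_peak])
    if peak_height <= 3.0 * resid_sd or (resid_sd == 0 and peak_height <= 0):
        raise InputError("no transition: peak below 3× baseline residual SD")
    # refine the peak position by a quadratic fit over the top of the peak
    cap = signal >= 0.8 * peak_height
    lo_i = i_peak
    while lo_i > 0 and cap[lo_i - 1]:
        lo_i -= 1
    hi_i = i_peak
    while hi_i < t.size - 1 and cap[hi_i + 1]:
        hi_i += 1
    if hi_i - lo_i >= 4:
        coeffs = np.polyfit(t[lo_i:hi_i + 1], signal[lo_i:hi_i + 1], 2)
        if coeffs[0] < 0:
            vertex = -coeffs[1] / (2.0 * coeffs[0])
            if t[lo_i] <= vertex <= t[hi_i]:
                T_peak = float(vertex)
            else:
                T_peak = float(t[i_peak])
        else:
            T_peak = float(t[i_peak])
    else:
        T_peak = float(t[i_peak])
    for (lo, hi) in ((lo1, hi1), (lo2, hi2)):
        if lo <= T_peak <= hi:
            raise InputError(f"baseline window ({lo}, {hi}) overlaps the peak")

    half = peak_height / 2.0
    t_left = _crossing(t, signal, half, rising=True)
    t_right = _crossing(t, signal, half, rising=False)
    fwhm = t_right - t_left

    # onset: tangent at the maximum-slope point of the leading edge, from
    # baseline exit (signal > 3×resid SD, falling back to 5% of peak on
    # noiseless curves) up to the peak
    exit_level = max(3.0 * resid_sd, 0.05 * peak_height)
    lead = np.nonzero(signal[: i_peak + 1] >= exit_level)[0]
    if lead.size == 0:
        raise InputError("leading edge never exits the baseline")
    i0 = int(lead[0])
    seg = slice(max(i0, 1), i_peak + 1)
    dsig = np.gradient(signal, t)
    i_tan = int(np.argmax(dsig[seg])) + seg.start
    m = float(dsig[i_tan])
    if m <= 0:
        raise InputError("non-positive leading-edge slope; no onset tangent")
    # tangent through (t[i_tan], signal[i_tan]) meets signal = 0 (the baseline)
    T_onset = float(t[i_tan] - signal[i_tan] / m)

    return EndothermMetrics(
        T_onset_C=T_onset,
        T_peak_C=T_peak,
        FWHM_C=float(fwhm),
        peak_height=peak_height,
        baseline_coeffs=(float(slope), float(intercept)),
    )
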