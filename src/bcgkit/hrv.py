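"""Time- and frequency-domain heart-rate-variability indicators.

Computed identically for ECG R-R and BCG J-J interval series so the two
sources can be compared like-for-like.  Conventions: SDNN uses the
population denominator n; MSSD (the RMS of successive differences) uses
n-1 successive differences; pNN50 is reported both as a proportion and as
a raw count; spectral powers come from a Welch periodogram of the
cubic-resampled tachogram with LF = 0.04-0.15 Hz, HF = 0.15-0.4 Hz and
TP = 0.0033-0.4 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

__all__ = ["IntervalSeries", "HRVSummary", "time_domain", "frequency_domain", "hrv_summary"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
TP_BAND = (0.0033, 0.4)


@dataclass
class IntervalSeries:
    """Successive beat-to-beat intervals with their event times."""

    intervals_s: np.ndarray
    beat_times_s: np.ndarray
    source: str = "bcg_jj"  # or "ecg_rr"

    def __post_init__(self) -> None:
        self.intervals_s = np.asarray(self.intervals_s, dtype=float)
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.size != self.intervals_s.size + 1:
            raise ValueError("need len(beat_times) == len(intervals) + 1")
        if self.intervals_s.size and (
            np.any(self.intervals_s < 0.3) or np.any(self.intervals_s >= 3.0)
        ):
            bad = self.intervals_s[(self.intervals_s < 0.3) | (self.intervals_s >= 3.0)][0]
            raise ValueError(f"interval {bad:.3f} s outside the plausible [0.3, 3) s range")

    @classmethod
    def from_beat_indices(cls, indices, fs: float, source: str = "bcg_jj",
                          drop_implausible: bool = True) -> "IntervalSeries":
        """Build a series from beat sample indices.

        With ``drop_implausible`` (default), intervals outside [0.3, 3) s —
        detection gaps across masked artifact spans, or spurious doubles —
        are removed, as is standard when cleaning a tachogram of ectopy;
        the surviving intervals keep their true end times.
        """
        times = np.asarray(indices, dtype=float) / fs
        iv = np.diff(times)
        if drop_implausible and iv.size:
            keep = (iv >= 0.3) & (iv < 3.0)
            if not keep.all():
                iv = iv[keep]
                ends = times[1:][keep]
                starts = times[:-1][keep]
                first = starts[0] if iv.size else times[0]
                return cls(intervals_s=iv,
                           beat_times_s=np.concatenate([[first], ends]),
                           source=source)
        return cls(intervals_s=iv, beat_times_s=times, source=source)

    def __len__(self) -> int:
        return int(self.intervals_s.size)


@dataclass
class HRVSummary:
    mean_s: float = float("nan")
    sdnn_s: float = float("nan")
    pnn50: float = float("nan")        # proportion in [0, 1]
    nn50_count: int = 0
    mssd_s: float = float("nan")
    cv: float = float("nan")
    lf: float = float("nan")           # band powers, s^2
    hf: float = float("nan")
    tp: float = float("nan")
    n_beats: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_s": self.mean_s, "sdnn_s": self.sdnn_s, "pnn50": self.pnn50,
            "nn50_count": self.nn50_count, "mssd_s": self.mssd_s, "cv": self.cv,
            "lf": self.lf, "hf": self.hf, "tp": self.tp, "n_beats": self.n_beats,
        }


def time_domain(series: IntervalSeries) -> HRVSummary:
    """Mean, SDNN, pNN50, MSSD and CV of an interval series."""
    x = series.intervals_s
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 intervals for time-domain HRV")
    mean = float(np.mean(x))
    sdnn = float(np.sqrt(np.mean((x - mean) ** 2)))  # population denominator n
    d = np.diff(x)
    mssd = float(np.sqrt(np.sum(d**2) / d.size))
    nn50 = int(np.count_nonzero(np.abs(d) > 0.050))
    return HRVSummary(
        mean_s=mean,
        sdnn_s=sdnn,
        pnn50=nn50 / d.size,
        nn50_count=nn50,
        mssd_s=mssd,
        cv=sdnn / mean,
        n_beats=n + 1,
    )


def frequency_domain(series: IntervalSeries, resample_hz: float = 4.0) -> HRVSummary:
    """LF, HF and TP band powers from the Welch spectrum of the tachogram.

    The irregular interval series is cubic-interpolated onto a uniform
    ``resample_hz`` grid, mean-detrended, and analysed with a Welch
    periodogram (256-sample Hann segments, 50 % overlap).
    """
    x = series.intervals_s
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 intervals for spectral HRV")
    if n < 64:
        warnings.warn(f"only {n} intervals; spectral HRV is unreliable below ~256",
                      stacklevel=2)
    t_beat = series.beat_times_s[1:]  # interval i ends at beat i+1
    grid = np.arange(t_beat[0], t_beat[-1], 1.0 / resample_hz)
    tach = CubicSpline(t_beat, x)(grid)
    tach = tach - tach.mean()
    nperseg = min(256, tach.size)
    f, p = welch(tach, fs=resample_hz, window="hann", nperseg=nperseg,
                 noverlap=nperseg // 2, detrend=False)
    out = HRVSummary(n_beats=n + 1)
    out.lf = _band_power(f, p, LF_BAND)
    out.hf = _band_power(f, p, HF_BAND)
    out.tp = _band_power(f, p, TP_BAND)
    return out


def _band_power(f: np.ndarray, p: np.ndarray, band) -> float:
    m = (f >= band[0]) & (f <= band[1])
    if not m.any():
        return 0.0
    return float(np.trapezoid(p[m], f[m]))


def hrv_summary(series: IntervalSeries, resample_hz: float = 4.0) -> HRVSummary:
    """Combined time- and (when feasible) frequency-domain summary."""
    out = time_domain(series)
    if len(series) >= 8:
        bands = frequency_domain(series, resample_hz)
        out.lf, out.hf, out.tp = bands.lf, bands.hf, bands.tp
    return out
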