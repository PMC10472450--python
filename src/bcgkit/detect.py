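"""IJK-complex detection: fuse STFT candidates with IMF peaks.

The coarse band-energy candidates (robust but temporally blurred) are
snapped onto the over-complete IMF peak list by a regional search:

* exactly one IMF peak within +/-40 ms of the candidate -> take it;
* both flanking peaks within the region -> take the nearer (rare);
* neither within the region -> the candidate has been dragged toward a
  dominant H or L wave; follow the historical drift direction (median of
  the last 9 signed offsets), unless the trend-consistent peak is more
  than twice as far as the other, in which case take the nearer.

I and K are then the first sufficiently deep local minima flanking J in
the IMF with a zero crossing in between; positions are refined to the
filtered raw signal, rhythm outliers interpolated, and pad regions
trimmed.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .emd import NoCardiacMode, detect_imf_peaks, eemd, select_cardiac_imf
from .preprocess import artifact_sample_mask, bandpass_bcg, segment
from .records import BeatAnnotations, PeakList, SignalRecord
from .stft import adaptive_window_length, detect_candidate_beats, stft_band_energy

__all__ = [
    "FusionState",
    "locate_j_waves",
    "locate_i_k_waves",
    "refine_to_raw",
    "interpolate_outliers",
    "detect_ijk",
    "DetectionReport",
]


@dataclass
class FusionState:
    """Carries the J-offset history (and branch counters) across segments."""

    region: int                      # regional search half-window, samples
    maxlen: int = 9
    history: deque = None
    counts: dict = field(default_factory=lambda: {
        "case1": 0, "case2": 0, "case3": 0, "override": 0, "one_sided": 0,
    })
    all_offsets: list = field(default_factory=list)  # full trace, diagnostics

    def __post_init__(self) -> None:
        if self.history is None:
            self.history = deque(maxlen=self.maxlen)
        else:
            self.history = deque(self.history, maxlen=self.maxlen)

    def push(self, offset: int) -> None:
        self.history.append(int(offset))
        self.all_offsets.append(int(offset))

    def trend_left(self, rule: str = "median") -> bool | None:
        """True if the drift trend points left, None with no history."""
        if not self.history:
            return None
        if rule == "count":
            h = np.asarray(self.history)
            n_left = int(np.sum(h < 0))
            n_right = int(np.sum(h > 0))
            if n_left == n_right:
                return None
            return n_left > n_right
        return float(np.median(self.history)) < 0


def locate_j_waves(locs_stft: PeakList, locs_imf: PeakList, fs: float,
                   config: RunConfig | None = None,
                   state: FusionState | None = None):
    """Choose one IMF peak per STFT candidate as the J-wave position.

    Returns ``(j_indices, state)``; the state accumulates the signed
    offsets (chosen J minus STFT candidate) that drive the trend rule, and
    branch counters for diagnostics.  Duplicate choices for adjacent
    candidates collapse to one beat, and a chosen J closer than the
    minimum beat gap to its predecessor is dropped.
    """
    cfg = config if config is not None else RunConfig()
    region = int(round(cfg.region_ms * fs / 1000.0))
    if state is None:
        state = FusionState(region=region, maxlen=cfg.history)
    imf_idx = locs_imf.indices
    if imf_idx.size == 0:
        return np.array([], dtype=np.int64), state
    chosen: list[int] = []
    min_gap = int(round(cfg.min_beat_gap * fs))
    for s in locs_stft.indices:
        left_pool = imf_idx[imf_idx < s]
        right_pool = imf_idx[imf_idx > s]
        if imf_idx[imf_idx == s].size:
            j = int(s)  # an IMF peak exactly on the candidate: distance 0
            state.counts["case1"] += 1
        elif left_pool.size == 0 and right_pool.size == 0:
            continue
        elif left_pool.size == 0 or right_pool.size == 0:
            pool = right_pool if left_pool.size == 0 else left_pool
            j = int(pool[0] if left_pool.size == 0 else pool[-1])
            state.counts["one_sided"] += 1
        else:
            left = int(left_pool[-1])
            right = int(right_pool[0])
            dl = s - left
            dr = right - s
            in_l = dl <= region
            in_r = dr <= region
            if in_l and in_r:
                state.counts["case3"] += 1
                j = left if dl <= dr else right  # equidistant tie -> left
            elif in_l or in_r:
                state.counts["case1"] += 1
                j = left if in_l else right
            else:
                state.counts["case2"] += 1
                trend_left = state.trend_left(cfg.trend_rule)
                if trend_left is None:
                    j = left if dl <= dr else right
                else:
                    j = left if trend_left else right
                    d_trend, d_other = (dl, dr) if trend_left else (dr, dl)
                    if d_trend > 2 * d_other:
                        state.counts["override"] += 1
                        j = right if trend_left else left
        state.push(j - int(s))
        if chosen and j == chosen[-1]:
            continue  # adjacent candidates agreed on one beat
        if chosen and j - chosen[-1] < min_gap:
            continue  # below the physiological floor: keep the earlier beat
        chosen.append(j)
    return np.asarray(chosen, dtype=np.int64), state


def locate_i_k_waves(j_indices: np.ndarray, cardiac_imf: np.ndarray, fs: float,
                     threshold: float, max_scan_s: float = 0.3,
                     min_gap_s: float = 0.3) -> BeatAnnotations:
    """Find I and K as the first qualified minima flanking each J.

    A candidate minimum qualifies if it lies below minus half the peak
    threshold and at least one zero crossing separates it from J.  Beats
    where I or K cannot be found within ``max_scan_s`` keep their J (for
    rate estimation) but carry ``valid=False``.
    """
    x = np.asarray(cardiac_imf, dtype=float)
    limit = int(round(max_scan_s * fs))
    depth = -0.5 * abs(threshold)
    beats = []
    valid = []
    for j in np.asarray(j_indices, dtype=np.int64):
        j = _snap_to_local_max(x, int(j), 1)
        i_idx = _scan_for_wave(x, j, -1, limit, depth)
        k_idx = _scan_for_wave(x, j, +1, limit, depth)
        beats.append((i_idx, j, k_idx))
        valid.append(i_idx is not None and k_idx is not None)
    return BeatAnnotations(beats=beats, valid=valid, fs=fs, min_gap_s=min_gap_s)


def _snap_to_local_max(x: np.ndarray, j: int, radius: int) -> int:
    lo = max(j - radius, 0)
    hi = min(j + radius + 1, x.size)
    return lo + int(np.argmax(x[lo:hi]))


def _scan_for_wave(x: np.ndarray, j: int, direction: int, limit: int,
                   depth: float) -> int | None:
    """First local minimum beyond a zero crossing, deeper than ``depth``."""
    n = x.size
    idx = j + direction
    steps = 0
    while 0 < idx < n - 1 and steps < limit:
        if x[idx] <= x[idx - 1] and x[idx] <= x[idx + 1]:
            lo, hi = (idx, j + 1) if direction < 0 else (j, idx + 1)
            span = x[lo:hi]
            has_zc = bool(np.any(np.diff(np.signbit(span)) != 0) or np.any(span == 0))
            if x[idx] <= depth and has_zc:
                return int(idx)
        idx += direction
        steps += 1
    return None


def refine_to_raw(ann: BeatAnnotations, raw_bcg: np.ndarray, fs: float,
                  refine_ms: float = 12.0) -> BeatAnnotations:
    """Snap I/J/K to the matching extremum of the filtered raw signal.

    Each wave moves to the local maximum (J) or minimum (I, K) of
    ``raw_bcg`` within +/-``refine_ms``.  If the refined triple violates
    i < j < k, the offending I/K is dropped and the beat marked invalid.
    """
    if ann.n_beats == 0:
        return ann
    x = np.asarray(raw_bcg, dtype=float)
    w = max(int(round(refine_ms * fs / 1000.0)), 1)
    beats = []
    valid = []
    for b, (i_idx, j_idx, k_idx) in enumerate(ann.beat_tuples()):
        j_new = _window_extremum(x, j_idx, w, np.argmax)
        i_new = None if i_idx is None else _window_extremum(x, i_idx, w, np.argmin)
        k_new = None if k_idx is None else _window_extremum(x, k_idx, w, np.argmin)
        ok = bool(ann.valid[b])
        if i_new is not None and i_new >= j_new:
            i_new, ok = None, False
        if k_new is not None and k_new <= j_new:
            k_new, ok = None, False
        beats.append((i_new, j_new, k_new))
        valid.append(ok)
    # refinement windows are tiny relative to the beat gap, so J order holds
    return BeatAnnotations(beats=beats, valid=valid, fs=ann.fs, min_gap_s=ann.min_gap_s)


def _window_extremum(x: np.ndarray, idx: int, w: int, picker) -> int:
    lo = max(idx - w, 0)
    hi = min(idx + w + 1, x.size)
    return lo + int(picker(x[lo:hi]))


def interpolate_outliers(ann: BeatAnnotations, fs: float,
                         bounds=(0.6, 1.67), window: int = 11) -> BeatAnnotations:
    """Replace rhythm outliers by interpolated beats.

    A J-J interval outside ``bounds`` x the running median (``window``
    beats) marks its terminal J as an outlier; that J is re-placed by
    linear interpolation between its neighbours and the beat flagged
    ``valid=False`` (its I/K are dropped).  A replacement that cannot
    respect the minimum beat gap removes the beat instead.
    """
    if int(np.sum(ann.valid)) < 3:
        if ann.n_beats:
            warnings.warn("fewer than 3 valid beats; outlier pass skipped", stacklevel=2)
        return ann
    import pandas as pd

    j = ann.j_indices.astype(float).copy()
    intervals = np.diff(j) / fs
    med = (
        pd.Series(intervals)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    outlier_beat = np.zeros(ann.n_beats, dtype=bool)
    for t, (iv, m) in enumerate(zip(intervals, med)):
        if iv < bounds[0] * m or iv > bounds[1] * m:
            outlier_beat[t + 1] = True
    if not outlier_beat.any():
        return ann
    tuples = ann.beat_tuples()
    beats = []
    valid = []
    min_gap = ann.min_gap_s * fs
    prev_j = None
    for b in range(ann.n_beats):
        i_idx, j_idx, k_idx = tuples[b]
        ok = bool(ann.valid[b])
        if outlier_beat[b] and 0 < b < ann.n_beats - 1:
            j_idx = int(round((ann.j_indices[b - 1] + ann.j_indices[b + 1]) / 2.0))
            i_idx = k_idx = None
            ok = False
        if prev_j is not None and j_idx - prev_j < min_gap:
            continue  # interpolation could not restore a plausible rhythm
        beats.append((i_idx, j_idx, k_idx))
        valid.append(ok)
        prev_j = j_idx
    return BeatAnnotations(beats=beats, valid=valid, fs=ann.fs, min_gap_s=ann.min_gap_s)


@dataclass
class DetectionReport:
    """Per-segment diagnostics of one detection run."""

    segments: list = field(default_factory=list)  # dicts: wt, n_candidates, ...
    counts: dict = field(default_factory=dict)    # cumulative fusion branch counts
    offsets: list = field(default_factory=list)   # signed chosen-J minus S(t)-peak trace
    n_beats: int = 0

    def to_dict(self) -> dict:
        return {"segments": self.segments, "counts": self.counts,
                "offsets": self.offsets, "n_beats": self.n_beats}


def detect_ijk(record: SignalRecord, config: RunConfig | None = None,
               return_report: bool = False):
    """End-to-end IJK-complex detection on a record's ``bcg`` channel.

    Pipeline: bandpass -> 10 s segmentation with 2 s pads -> per segment
    {adaptive window length -> S(t) -> coarse candidates -> EEMD ->
    cardiac IMF -> low-threshold IMF peaks -> J fusion -> I/K search} ->
    pad trimming and artifact masking -> raw-signal refinement -> rhythm
    outlier interpolation.  Deterministic for a fixed ``rng_seed``.

    A segment that fails any stage contributes no beats but does not abort
    the record.
    """
    cfg = config if config is not None else RunConfig()
    cfg.validate_against_fs(record.fs)
    fs = record.fs
    filtered = bandpass_bcg(record, cfg.bcg_band)
    bcg = filtered.channel("bcg")
    mask = artifact_sample_mask(bcg, fs)
    segs = segment(filtered, cfg.segment_s, cfg.pad_s, channel="bcg")
    seeds = np.random.SeedSequence(cfg.rng_seed).generate_state(len(segs)) % (2**31)
    state = FusionState(region=int(round(cfg.region_ms * fs / 1000.0)), maxlen=cfg.history)
    report = DetectionReport()
    beats_all: list[tuple] = []
    valid_all: list[bool] = []
    for si, seg in enumerate(segs):
        diag = {"segment": si, "artifact": seg.artifact, "wt_s": None,
                "n_candidates": 0, "n_imf_peaks": 0, "n_beats": 0, "flags": []}
        report.segments.append(diag)
        x = seg.samples
        if np.ptp(x) == 0:
            diag["flags"].append("flat")
            continue
        wt = adaptive_window_length(x, fs, cfg)
        diag["wt_s"] = wt
        curve = stft_band_energy(x, fs, wt, cfg.jband)
        cands = detect_candidate_beats(curve, fs, cfg.min_beat_gap)
        diag["n_candidates"] = len(cands)
        if len(cands) == 0:
            diag["flags"].append("no_candidates")
            continue
        imfset = eemd(x, nstd=cfg.nstd, ne=cfg.ne, seed=int(seeds[si]),
                      sd_stop=cfg.sd_stop, max_sift=cfg.max_sift)
        try:
            ci = select_cardiac_imf(imfset, fs, band=cfg.imf_band, jband=cfg.jband)
        except NoCardiacMode:
            diag["flags"].append("no_cardiac_mode")
            continue
        imf = imfset.imfs[ci]
        diag["cardiac_imf"] = ci
        peaks = detect_imf_peaks(imf, fs)
        diag["n_imf_peaks"] = len(peaks)
        if len(peaks) == 0:
            diag["flags"].append("no_imf_peaks")
            continue
        js, state = locate_j_waves(cands, peaks, fs, cfg, state)
        if js.size == 0:
            diag["flags"].append("empty_fusion")
            continue
        ann_seg = locate_i_k_waves(js, imf, fs, peaks.threshold_used,
                                   min_gap_s=cfg.min_beat_gap)
        offset = seg.offset
        core_lo, core_hi = seg.core_span
        kept = 0
        for b, (i_idx, j_idx, k_idx) in enumerate(ann_seg.beat_tuples()):
            j_rec = j_idx + offset
            if not core_lo <= j_rec < core_hi:
                continue  # pad region: trimmed, owned by the neighbouring core
            if mask[j_rec]:
                continue  # motion-artifact span
            beats_all.append(
                (None if i_idx is None else i_idx + offset,
                 j_rec,
                 None if k_idx is None else k_idx + offset)
            )
            valid_all.append(bool(ann_seg.valid[b]))
            kept += 1
        diag["n_beats"] = kept
    # cross-segment cleanup: enforce order and the beat-gap floor
    beats_all, valid_all = _dedupe_across_segments(beats_all, valid_all,
                                                   int(round(cfg.min_beat_gap * fs)))
    ann = BeatAnnotations(beats=beats_all, valid=valid_all, fs=fs,
                          min_gap_s=cfg.min_beat_gap)
    ann = refine_to_raw(ann, bcg, fs, cfg.refine_ms)
    ann = interpolate_outliers(ann, fs)
    report.counts = dict(state.counts)
    report.offsets = list(state.all_offsets)
    report.n_beats = ann.n_beats
    if return_report:
        return ann, report
    return ann


def _dedupe_across_segments(beats: list, valid: list, min_gap: int):
    out_b: list[tuple] = []
    out_v: list[bool] = []
    for beat, ok in zip(beats, valid):
        if out_b and beat[1] - out_b[-1][1] < min_gap:
            continue
        out_b.append(beat)
        out_v.append(ok)
    return out_b, out_v
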