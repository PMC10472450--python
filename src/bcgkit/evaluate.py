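"""Method-agreement machinery: error metrics, Bland-Altman statistics,
beat matching and the ECG-gated reference detector.

The detector under test is compared against an ECG-referenced oracle: the
BCG is epoch-averaged on ECG R gates, the template J/I/K offsets are read
off the average, and per-beat reference waves are local extrema near the
template offsets.  Agreement between paired value sequences is summarised
by MAE, MAE%, RMSE, Bland-Altman bias with 1.96-SD limits, and a paired
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import BeatAnnotations, PeakList, SignalRecord

__all__ = [
    "AgreementReport",
    "BeatMatching",
    "pair_beats",
    "agreement",
    "ecg_referenced_ijk",
    "compare_morphology",
    "paired_heart_rates",
    "summarize_subjects",
]


@dataclass
class AgreementReport:
    """Paired-sequence agreement: errors, Bland-Altman and paired t."""

    mae: float
    mae_pct: float          # 100 * MAE / mean(reference)
    rmse: float
    bias: float             # mean(test - reference)
    loa: tuple              # bias -/+ 1.96 * SD(differences)
    n_pairs: int
    t_stat: float
    p_value: float
    coverage_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "mae": self.mae, "mae_pct": self.mae_pct, "rmse": self.rmse,
            "bias": self.bias, "loa": list(self.loa), "n_pairs": self.n_pairs,
            "t_stat": self.t_stat, "p_value": self.p_value,
            "coverage_pct": self.coverage_pct,
        }


def agreement(seq_ref, seq_test) -> AgreementReport:
    """MAE, MAE%, RMSE, Bland-Altman bias/limits and paired t-test."""
    ref = np.asarray(seq_ref, dtype=float)
    test = np.asarray(seq_test, dtype=float)
    if ref.size != test.size:
        raise ValueError(f"length mismatch: {ref.size} vs {test.size}")
    if ref.size < 2:
        raise ValueError("need at least 2 pairs")
    d = test - ref
    mae = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d**2)))
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.allclose(d, d[0]):
        t_stat = 0.0 if d[0] == 0 else float("inf") * np.sign(d[0])
        p_value = 1.0 if d[0] == 0 else 0.0
    else:
        t_res = stats.ttest_rel(test, ref)
        t_stat, p_value = float(t_res.statistic), float(t_res.pvalue)
    ref_mean = float(np.mean(ref))
    return AgreementReport(
        mae=mae,
        mae_pct=100.0 * mae / ref_mean if ref_mean != 0 else float("nan"),
        rmse=rmse,
        bias=bias,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
        n_pairs=int(ref.size),
        t_stat=t_stat,
        p_value=p_value,
    )


@dataclass
class BeatMatching:
    """One-to-one R-to-J matching with coverage bookkeeping."""

    pairs: list                 # (reference position, detected beat position)
    coverage_pct: float         # 100 * matched / n_reference
    n_reference: int
    n_detected: int
    n_false: int                # detected beats matched to no reference


def pair_beats(reference: PeakList, detected: BeatAnnotations, fs: float,
               r_to_j_bound_s: float = 0.4) -> BeatMatching:
    """Match each reference R peak to the nearest unused J in (R, R+bound].

    Unmatched references count against coverage; detected beats matched to
    no reference are reported as false detections.
    """
    r_idx = reference.indices
    j_idx = detected.j_indices
    bound = r_to_j_bound_s * fs
    used = np.zeros(j_idx.size, dtype=bool)
    pairs = []
    for rp, r in enumerate(r_idx):
        window = np.flatnonzero((j_idx > r) & (j_idx <= r + bound) & ~used)
        if window.size == 0:
            continue
        jp = window[np.argmin(j_idx[window] - r)]
        used[jp] = True
        pairs.append((rp, int(jp)))
    n_ref = int(r_idx.size)
    coverage = 100.0 * len(pairs) / n_ref if n_ref else 0.0
    return BeatMatching(
        pairs=pairs,
        coverage_pct=coverage,
        n_reference=n_ref,
        n_detected=int(j_idx.size),
        n_false=int(j_idx.size) - len(pairs),
    )


def paired_heart_rates(reference: PeakList, detected: BeatAnnotations, fs: float,
                       r_to_j_bound_s: float = 0.4,
                       valid_only: bool = True):
    """Beat-to-beat heart-rate pairs (reference bpm, detected bpm).

    For every pair of consecutive reference beats that were both matched,
    the reference rate is 60/RR and the detected rate 60/JJ between the
    matched J positions.  Returns ``(hr_ref, hr_test, matching)``.
    """
    ann = detected
    if valid_only and ann.n_beats and not ann.valid.all():
        keep = np.flatnonzero(ann.valid)
        tuples = ann.beat_tuples()
        ann = BeatAnnotations(
            beats=[tuples[b] for b in keep],
            valid=[True] * keep.size,
            fs=ann.fs,
            min_gap_s=ann.min_gap_s,
        ) if keep.size else ann
    matching = pair_beats(reference, ann, fs, r_to_j_bound_s)
    r_idx = reference.indices
    j_idx = ann.j_indices
    hr_ref, hr_test = [], []
    by_ref = dict(matching.pairs)
    for rp in range(r_idx.size - 1):
        if rp in by_ref and (rp + 1) in by_ref:
            rr = (r_idx[rp + 1] - r_idx[rp]) / fs
            jj = (j_idx[by_ref[rp + 1]] - j_idx[by_ref[rp]]) / fs
            hr_ref.append(60.0 / rr)
            hr_test.append(60.0 / jj)
    return np.asarray(hr_ref), np.asarray(hr_test), matching


def ecg_referenced_ijk(record: SignalRecord, r_peaks: PeakList,
                       epoch_s: float = 0.6, search_ms: float = 25.0) -> BeatAnnotations:
    """ECG-gated ensemble-average reference detector.

    Epochs [R, R+epoch_s) of the filtered BCG are ensemble averaged; the
    template J is the global maximum of the average and template I/K its
    flanking minima.  Per beat, each wave is the local extremum of the
    epoch within +/-``search_ms`` of the template offset.
    """
    x = record.channel("bcg")
    fs = record.fs
    n = x.size
    epoch_n = int(round(epoch_s * fs))
    gates = [int(r) for r in r_peaks.indices if r >= 0 and r + epoch_n <= n]
    if len(gates) < 10:
        raise ValueError(f"need >= 10 complete epochs, have {len(gates)}")
    epochs = np.stack([x[r:r + epoch_n] for r in gates])
    template = epochs.mean(axis=0)
    off_j = int(np.argmax(template))
    off_i = _nearest_min(template, off_j, -1)
    off_k = _nearest_min(template, off_j, +1)
    w = max(int(round(search_ms * fs / 1000.0)), 1)
    beats = []
    valid = []
    for r, epoch in zip(gates, epochs):
        j_loc = _epoch_extremum(epoch, off_j, w, np.argmax)
        i_loc = None if off_i is None else _epoch_extremum(epoch, off_i, w, np.argmin)
        k_loc = None if off_k is None else _epoch_extremum(epoch, off_k, w, np.argmin)
        ok = i_loc is not None and k_loc is not None
        if i_loc is not None and i_loc >= j_loc:
            i_loc, ok = None, False
        if k_loc is not None and k_loc <= j_loc:
            k_loc, ok = None, False
        beats.append(
            (None if i_loc is None else r + i_loc,
             r + j_loc,
             None if k_loc is None else r + k_loc)
        )
        valid.append(ok)
    return BeatAnnotations(beats=beats, valid=valid, fs=fs)


def _nearest_min(x: np.ndarray, start: int, direction: int) -> int | None:
    idx = start + direction
    while 0 < idx < x.size - 1:
        if x[idx] <= x[idx - 1] and x[idx] <= x[idx + 1]:
            return int(idx)
        idx += direction
    return None


def _epoch_extremum(epoch: np.ndarray, offset: int, w: int, picker) -> int:
    lo = max(offset - w, 0)
    hi = min(offset + w + 1, epoch.size)
    return lo + int(picker(epoch[lo:hi]))


def compare_morphology(ref: BeatAnnotations, test: BeatAnnotations,
                       record: SignalRecord, pair_bound_s: float = 0.1) -> dict:
    """I-J amplitude and I-K interval agreement between two annotation sets.

    Beats are paired one-to-one by J proximity (<= ``pair_bound_s``);
    beats lacking I or K on either side are excluded entirely.  Returns
    ``{"ij_amplitude": AgreementReport, "ik_interval_ms": AgreementReport}``
    computed on the record's (filtered) ``bcg`` channel.
    """
    x = record.channel("bcg")
    fs = record.fs
    pairs = _pair_by_j(ref, test, fs, pair_bound_s)
    amp_ref, amp_test, ik_ref, ik_test = [], [], [], []
    rt, tt = ref.beat_tuples(), test.beat_tuples()
    for rp, tp in pairs:
        ri, rj, rk = rt[rp]
        ti, tj, tk = tt[tp]
        if None in (ri, rk, ti, tk):
            continue
        amp_ref.append(x[rj] - x[ri])
        amp_test.append(x[tj] - x[ti])
        ik_ref.append((rk - ri) / fs * 1000.0)
        ik_test.append((tk - ti) / fs * 1000.0)
    if len(amp_ref) < 2:
        raise ValueError("no pairable beats with complete I/J/K")
    return {
        "ij_amplitude": agreement(amp_ref, amp_test),
        "ik_interval_ms": agreement(ik_ref, ik_test),
    }


def _pair_by_j(ref: BeatAnnotations, test: BeatAnnotations, fs: float,
               bound_s: float) -> list:
    bound = bound_s * fs
    jr = ref.j_indices
    jt = test.j_indices
    used = np.zeros(jt.size, dtype=bool)
    pairs = []
    for rp, j in enumerate(jr):
        d = np.abs(jt - j).astype(float)
        d[used] = np.inf
        if d.size == 0 or d.min() > bound:
            continue
        tp = int(np.argmin(d))
        used[tp] = True
        pairs.append((rp, tp))
    return pairs


def summarize_subjects(rows: pd.DataFrame, decimals: int = 2) -> pd.Series:
    """Arithmetic column means of a per-subject metric table, rounded."""
    if len(rows) == 0:
        raise ValueError("empty table")
    numeric = rows.select_dtypes(include=[np.number])
    if numeric.shape[1] == 0:
        raise ValueError("no numeric columns to summarise")
    return numeric.mean(axis=0).round(decimals)
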