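"""Published per-subject benchmark tables for desk-scale cross-checks.

A 12-subject supine validation study of this detection scheme (ten
healthy adults and two coronary-heart-disease patients, 10 min recordings
at 250 Hz, ECG-referenced) reported per-subject heart-rate agreement and
IJK morphology errors.  The raw recordings are not deposited, but the
printed per-subject summary values are reproduced here so the package's
summary arithmetic (column means, MAE% ratios) can be validated against
the published mean rows.

Columns follow the published layout; an asterisked subject id marks the
two CHD patients (ids 11 and 12 here).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_hr_benchmark", "load_morphology_benchmark"]

# Per-subject beat-to-beat heart-rate agreement (BCG J-J vs ECG R-R):
# subject mean heart rate with SD, MAE and RMSE in bpm, MAE% and coverage.
_HR_ROWS = [
    # subject, hr_mean, hr_sd, mae_bpm, mae_pct, rmse_bpm, coverage_pct
    (1, 72.94, 4.72, 0.59, 0.81, 1.85, 95.88),
    (2, 81.18, 4.79, 1.49, 1.84, 3.00, 97.44),
    (3, 59.73, 2.71, 0.65, 1.09, 1.53, 95.56),
    (4, 59.16, 2.23, 0.33, 0.56, 0.88, 95.44),
    (5, 62.49, 4.18, 1.83, 2.93, 3.12, 89.89),
    (6, 63.39, 4.01, 1.12, 1.77, 2.56, 95.85),
    (7, 68.81, 2.59, 0.66, 0.96, 1.42, 89.09),
    (8, 63.80, 2.88, 0.84, 1.32, 1.53, 95.66),
    (9, 74.60, 6.91, 1.10, 1.47, 3.44, 92.97),
    (10, 65.30, 4.34, 1.60, 2.45, 2.71, 91.40),
    (11, 85.55, 2.06, 1.17, 1.37, 1.70, 91.79),
    (12, 59.97, 2.06, 0.47, 0.78, 0.75, 93.34),
]

# Per-subject morphology agreement: I-K interval (ms) and I-J amplitude (V)
# against the ECG-gated ensemble-average reference.
_MORPH_ROWS = [
    # subject, ik_mean_ms, ik_sd_ms, ik_mae_ms, ik_mae_pct,
    #          ij_mean_v, ij_sd_v, ij_mae_v, ij_mae_pct
    (1, 171.63, 4.45, 1.41, 0.82, 2.96, 0.68, 0.05, 1.75),
    (2, 192.00, 9.81, 6.27, 3.27, 3.74, 0.77, 0.04, 1.07),
    (3, 139.08, 8.15, 2.57, 1.85, 5.43, 0.46, 0.01, 0.19),
    (4, 150.48, 4.11, 0.81, 0.54, 4.08, 0.72, 0.05, 1.26),
    (5, 152.24, 3.58, 0.23, 0.15, 4.56, 0.49, 0.01, 0.27),
    (6, 170.03, 4.70, 0.90, 0.53, 4.87, 1.44, 0.20, 4.11),
    (7, 191.30, 2.13, 0.59, 0.31, 3.19, 0.39, 0.06, 1.92),
    (8, 183.72, 2.83, 0.59, 0.32, 3.98, 0.65, 0.03, 0.85),
    (9, 159.92, 3.48, 0.32, 0.20, 4.50, 0.54, 0.01, 0.27),
    (10, 163.78, 5.61, 1.73, 1.06, 4.23, 1.00, 0.06, 1.39),
    (11, 175.31, 5.79, 2.15, 1.22, 3.17, 0.77, 0.12, 3.79),
    (12, 166.24, 3.36, 0.20, 0.12, 4.75, 1.06, 0.01, 0.21),
]

# Published "mean" rows, for cross-checking summarize_subjects.
HR_MEAN_ROW = {"hr_mean": 68.08, "hr_sd": 3.62, "mae_bpm": 0.99,
               "mae_pct": 1.45, "rmse_bpm": 2.04, "coverage_pct": 93.69}
MORPH_MEAN_ROW = {"ik_mean_ms": 167.98, "ik_sd_ms": 4.83, "ik_mae_ms": 1.48,
                  "ik_mae_pct": 0.87, "ij_mean_v": 4.12, "ij_sd_v": 0.75,
                  "ij_mae_v": 0.05, "ij_mae_pct": 1.42}


def load_hr_benchmark() -> pd.DataFrame:
    """Per-subject heart-rate agreement table (12 subjects)."""
    return pd.DataFrame(
        _HR_ROWS,
        columns=["subject", "hr_mean", "hr_sd", "mae_bpm", "mae_pct",
                 "rmse_bpm", "coverage_pct"],
    ).set_index("subject")


def load_morphology_benchmark() -> pd.DataFrame:
    """Per-subject I-K interval / I-J amplitude agreement table."""
    return pd.DataFrame(
        _MORPH_ROWS,
        columns=["subject", "ik_mean_ms", "ik_sd_ms", "ik_mae_ms", "ik_mae_pct",
                 "ij_mean_v", "ij_sd_v", "ij_mae_v", "ij_mae_pct"],
    ).set_index("subject")
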