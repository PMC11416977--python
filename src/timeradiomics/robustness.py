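"""Intra-observer feature-robustness filtering via intraclass correlation.

Reproducibility of each radiomic feature across two raters' ROI
delineations is scored with ICC(2,1) — two-way random effects, absolute
agreement, single measurement — the standard choice for re-segmentation
studies.  Features with ICC strictly above the threshold (default 0.80)
are retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["icc", "filter_robust"]


def icc(table: np.ndarray) -> float:
    """ICC(2,1) of an n-subjects x k-raters rating table.

    Computed from the two-way ANOVA decomposition:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with MS_R the between-subject, MS_C the between-rater and MS_E the
    residual mean square.  A table with zero total variance returns 1
    (identical constant ratings agree perfectly).
    """
    x = np.asarray(table, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"rating table must be 2-D, got shape {x.shape}")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("rating table contains non-finite entries")

    grand = x.mean()
    if np.allclose(x, grand):
        return 1.0
    row_mean = x.mean(axis=1)
    col_mean = x.mean(axis=0)
    ss_rows = k * ((row_mean - grand) ** 2).sum()
    ss_cols = n * ((col_mean - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        return 1.0
    return float((ms_r - ms_e) / denom)


def filter_robust(
    features_r1: pd.DataFrame,
    features_r2: pd.DataFrame,
    threshold: float = 0.80,
) -> tuple[list[str], pd.Series]:
    """Retain features whose two-rater ICC strictly exceeds ``threshold``.

    Both frames must share identical feature columns (cases x features,
    same case order).  Returns (retained feature ids in column order,
    per-feature ICC report).
    """
    cols1, cols2 = list(features_r1.columns), list(features_r2.columns)
    if cols1 != cols2:
        only1 = sorted(set(cols1) - set(cols2))
        only2 = sorted(set(cols2) - set(cols1))
        raise ValueError(
            "feature id mismatch between raters; "
            f"only in first: {only1[:5]}...; only in second: {only2[:5]}..."
            if only1 or only2
            else "feature columns are ordered differently between raters"
        )
    if len(features_r1) != len(features_r2):
        raise ValueError("rater tables have different numbers of cases")
    iccs = pd.Series(
        {
            col: icc(np.column_stack([features_r1[col].to_numpy(),
                                      features_r2[col].to_numpy()]))
            for col in cols1
        }
    )
    retained = [c for c in cols1 if iccs[c] > threshold]
    return retained, iccs
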