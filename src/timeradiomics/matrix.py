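"""Labelled analysis matrices: label encoding, normalization, deduplication.

Binary labels come from median dichotomization of infiltration
percentages (low = 0, high = 1; values equal to the median go low), from
the iRECIST response grouping (CR/PR favorable = 1, SD/PD poor = 0), or
from 12-month progression status.  Z-score normalization and Pearson
deduplication statistics are fitted on training rows only, so no test
information leaks into the model-building path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "median_dichotomize",
    "encode_response",
    "encode_pfs12",
    "ZScoreScaler",
    "zscore_fit_apply",
    "pcc_dedup",
    "LabelledMatrix",
    "build_labelled_matrix",
]

LABEL_KINDS = ("cd3", "cd8", "trm", "response", "pfs12")


def median_dichotomize(values) -> np.ndarray:
    """Split at the median: value > median -> 1, value <= median -> 0."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("median dichotomization needs at least 2 cases")
    med = np.median(x)
    if np.all(x == x[0]):
        raise ValueError("all values identical: no median split exists")
    return (x > med).astype(np.int64)


def encode_response(category: str) -> int:
    """iRECIST response to binary outcome: CR/PR -> 1, SD/PD -> 0."""
    mapping = {"CR": 1, "PR": 1, "SD": 0, "PD": 0}
    try:
        return mapping[category]
    except KeyError:
        raise ValueError(
            f"unknown response category {category!r}; expected one of CR/PR/SD/PD"
        ) from None


def encode_pfs12(pfs_months: float, event: int) -> int | None:
    """Progression status at 12 months.

    Progression event at <= 12 months -> 1; follow-up (event or censoring)
    beyond 12 months -> 0; censored before 12 months -> None (status
    indeterminate, case excluded).
    """
    if pfs_months < 0:
        raise ValueError(f"negative PFS time {pfs_months}")
    if event and pfs_months <= 12.0:
        return 1
    if pfs_months > 12.0:
        return 0
    return None


@dataclass
class ZScoreScaler:
    """Per-feature Z-score transform with training-only statistics.

    Uses the population (1/n) standard deviation.  Constant training
    columns are dropped with a warning list in ``dropped``.
    """

    mean_: pd.Series | None = None
    sd_: pd.Series | None = None
    dropped: list[str] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return self.mean_ is not None

    def fit(self, train: pd.DataFrame) -> "ZScoreScaler":
        mean = train.mean(axis=0)
        sd = train.std(axis=0, ddof=0)
        self.dropped = list(train.columns[sd == 0])
        keep = sd > 0
        self.mean_ = mean[keep]
        self.sd_ = sd[keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("scaler is not fitted")
        return (X[self.mean_.index] - self.mean_) / self.sd_


def zscore_fit_apply(matrix: pd.DataFrame, train_rows) -> tuple[pd.DataFrame, ZScoreScaler]:
    """Fit Z-score parameters on ``train_rows`` and transform all rows.

    Training columns of the result have mean 0 and population SD 1; test
    rows are transformed with the training parameters.
    """
    scaler = ZScoreScaler().fit(matrix.loc[train_rows])
    return scaler.transform(matrix), scaler


def pcc_dedup(matrix: pd.DataFrame, threshold: float = 0.99) -> list[str]:
    """Drop the later member of any feature pair with |Pearson r| > threshold.

    A greedy scan in column (manifest) order keeps the earlier feature of
    an offending pair; the result is deterministic given the column order
    and invariant to row order.  Correlations should be computed on
    training rows only — pass the training slice.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    X = matrix.to_numpy(dtype=np.float64)
    cols = list(matrix.columns)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Xc = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        corr = np.abs(Xc.T @ Xc / len(X))
    # constant columns have undefined correlation; treat as uncorrelated
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    keep: list[int] = []
    for idx in range(len(cols)):
        if all(corr[idx, k] <= threshold for k in keep):
            keep.append(idx)
    return [cols[k] for k in keep]


@dataclass
class LabelledMatrix:
    """Cases x features values with a binary per-case label."""

    X: pd.DataFrame
    y: pd.Series
    label_kind: str
    excluded: pd.Series | None = None  # case_id -> exclusion reason

    def __post_init__(self) -> None:
        if self.label_kind not in LABEL_KINDS:
            raise ValueError(f"label_kind must be one of {LABEL_KINDS}")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature rows and labels are misaligned")


def build_labelled_matrix(
    features: pd.DataFrame, clinical: pd.DataFrame, label_kind: str
) -> LabelledMatrix:
    """Join a feature table with a clinical table into a labelled matrix.

    ``clinical`` is indexed by case_id with columns cd3_pct/cd8_pct/trm_pct
    (surgical cohort) or response/pfs_months/event (immunotherapy cohort).
    For pfs12, cases censored before 12 months are excluded with a reason.
    """
    clin = clinical.loc[features.index]
    excluded = None
    if label_kind in ("cd3", "cd8", "trm"):
        y = pd.Series(
            median_dichotomize(clin[f"{label_kind}_pct"]), index=features.index
        )
    elif label_kind == "response":
        y = clin["response"].map(encode_response)
    elif label_kind == "pfs12":
        status = {
            cid: encode_pfs12(row["pfs_months"], int(row["event"]))
            for cid, row in clin.iterrows()
        }
        excluded_ids = [cid for cid, s in status.items() if s is None]
        excluded = pd.Series(
            {cid: "censored before 12 months" for cid in excluded_ids}
        )
        kept = [cid for cid, s in status.items() if s is not None]
        features = features.loc[kept]
        y = pd.Series({cid: status[cid] for cid in kept})
    else:
        raise ValueError(f"unknown label kind {label_kind!r}")
    return LabelledMatrix(X=features, y=y.astype(np.int64), label_kind=label_kind,
                          excluded=excluded)
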