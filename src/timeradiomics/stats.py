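"""ROC/AUC machinery, DeLong comparison, contingency tables, survival.

AUC is the Mann-Whitney concordance with half credit for ties; its
variance and the paired comparison of two correlated AUCs use DeLong's
placement-value method.  Kaplan-Meier estimation, the log-rank test and
the Breslow (generalized Wilcoxon, at-risk-weighted) test are delegated
to lifelines.  The Cox proportional-hazards fit is a Newton-Raphson
maximization of the Breslow partial likelihood implemented here, so that
small-sample behaviour and tie handling are fully specified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RocResult",
    "SurvivalFit",
    "CoxFit",
    "roc_auc",
    "delong_test",
    "optimal_cutoff",
    "dcr_table",
    "km_fit",
    "compare_survival",
    "cox_fit",
    "cox_risk_auc",
]


# --------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    """AUC with DeLong variance, 95% CI and a threshold sweep."""

    auc: float
    variance: float
    ci: tuple[float, float]
    thresholds: np.ndarray = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)
    specificity: np.ndarray = field(repr=False)


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (per positive), V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # placement of each positive among negatives and vice versa, ties half
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / len(pos) for n in neg])
    return v10, v01, float(v10.mean())


def roc_auc(scores, labels) -> RocResult:
    """AUC of a continuous score against a binary label.

    The DeLong variance gives the 95% CI as AUC +/- 1.96 sqrt(var),
    clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    classes = set(np.unique(y))
    if not classes == {0, 1}:
        raise ValueError(f"labels must contain both classes 0 and 1, got {sorted(classes)}")
    v10, v01, auc = _placements(s, y)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.96 * np.sqrt(var)
    ci = (max(auc - half, 0.0), min(auc + half, 1.0))

    # threshold sweep: midpoints between consecutive unique scores plus
    # sentinels; predicted positive when score > threshold
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thr = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    sens = np.array([np.mean(s[y == 1] > t) for t in thr])
    spec = np.array([np.mean(s[y == 0] <= t) for t in thr])
    return RocResult(auc=auc, variance=float(var), ci=ci,
                     thresholds=thr, sensitivity=sens, specificity=spec)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong's paired comparison of two correlated AUCs.

    Both scores must be evaluated on the same cases and labels.  Returns
    (z statistic, two-sided p).  A degenerate (zero) variance of the AUC
    difference yields p = 1 with a warning.
    """
    sa = np.asarray(scores_a, dtype=np.float64)
    sb = np.asarray(scores_b, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("paired design requires equal-length score and label vectors")
    v10a, v01a, auc_a = _placements(sa, y)
    v10b, v01b, auc_b = _placements(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        if auc_a != auc_b:
            warnings.warn("degenerate DeLong variance; returning p = 1")
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def optimal_cutoff(roc: RocResult) -> float:
    """Threshold maximizing sensitivity + specificity (the Youden point).

    Ties resolve to the lowest threshold.  A flat sweep (no discrimination)
    also returns the lowest threshold, with a warning.
    """
    j = roc.sensitivity + roc.specificity
    if len(j) == 0:
        raise ValueError("empty threshold sweep")
    if np.allclose(j, j[0]):
        warnings.warn("flat ROC sweep: no informative cutoff; returning lowest threshold")
        return float(roc.thresholds[0])
    return float(roc.thresholds[int(np.argmax(j))])


# --------------------------------------------------------------------------
# Disease control rate


def dcr_table(groups, control_flags) -> dict:
    """2x2 disease-control table with per-group DCR% and a group test.

    ``groups`` are binary group indicators (0 = low, 1 = high); the DCR of
    a group is 100 x controlled / group size, rounded to one decimal.
    Pearson chi-square without continuity correction is used unless any
    expected cell count is below 5, in which case Fisher's exact test is
    reported.
    """
    g = np.asarray(groups, dtype=np.int64)
    c = np.asarray(control_flags, dtype=np.int64)
    table = np.array(
        [
            [np.sum((g == 0) & (c == 1)), np.sum((g == 0) & (c == 0))],
            [np.sum((g == 1) & (c == 1)), np.sum((g == 1) & (c == 0))],
        ]
    )
    n_low, n_high = table.sum(axis=1)
    if n_low == 0 or n_high == 0:
        raise ValueError("both groups must be nonempty")
    dcr_low = round(100.0 * table[0, 0] / n_low, 1)
    dcr_high = round(100.0 * table[1, 0] / n_high, 1)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        _, p = sps.fisher_exact(table)
        test = "fisher"
    else:
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        test = "chi2"
    if np.all(table[0] / n_low == table[1] / n_high):
        p = 1.0
    return {
        "table": table,
        "dcr_low_pct": dcr_low,
        "dcr_high_pct": dcr_high,
        "test": test,
        "p": float(p),
    }


# --------------------------------------------------------------------------
# Survival


@dataclass(frozen=True)
class SurvivalFit:
    """Kaplan-Meier estimate with Greenwood SEs and restricted mean."""

    times: np.ndarray = field(repr=False)
    survival: np.ndarray = field(repr=False)
    se: np.ndarray = field(repr=False)
    restricted_mean: float = 0.0
    restricted_mean_se: float = 0.0
    horizon: float = 0.0


def km_fit(times, events, horizon: float | None = None) -> SurvivalFit:
    """Product-limit survival estimate.

    The restricted mean survival time (the area under the KM curve up to
    ``horizon``, default the largest observed time) is reported with its
    standard error.
    """
    from lifelines import KaplanMeierFitter

    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=np.int64)
    if np.any(t < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    if horizon is None:
        horizon = float(t.max())
    surv = kmf.survival_function_["KM_estimate"]
    grid = surv.index.to_numpy(dtype=float)  # starts at 0 with S = 1
    s_vals = surv.to_numpy(dtype=float)
    event_table = kmf.event_table
    at_risk = event_table["at_risk"].to_numpy(dtype=float)
    observed = event_table["observed"].to_numpy(dtype=float)

    # Greenwood SE of S(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            at_risk * (at_risk - observed) > 0,
            observed / (at_risk * (at_risk - observed)),
            0.0,
        )
    se = s_vals * np.sqrt(np.cumsum(terms))

    # restricted mean = area under the KM step function over [0, horizon];
    # variance by the standard KM-mean formula: sum over event times of
    # A_i^2 d_i / (n_i (n_i - d_i)) with A_i the remaining area past t_i
    edges = np.append(np.clip(grid, None, horizon), horizon)
    widths = np.diff(edges)
    rmst = float(np.sum(s_vals * np.clip(widths, 0.0, None)))
    var = 0.0
    for i in range(len(grid)):
        if observed[i] > 0 and grid[i] < horizon and at_risk[i] > observed[i]:
            inner = np.append(np.clip(grid[i:], None, horizon), horizon)
            area = float(np.sum(s_vals[i:] * np.clip(np.diff(inner), 0.0, None)))
            var += area**2 * observed[i] / (at_risk[i] * (at_risk[i] - observed[i]))
    return SurvivalFit(
        times=grid,
        survival=s_vals,
        se=se,
        restricted_mean=rmst,
        restricted_mean_se=float(np.sqrt(var)),
        horizon=float(horizon),
    )


def compare_survival(times, events, groups) -> tuple[float, float]:
    """Two-group survival comparison: (log-rank p, Breslow p).

    Log-rank is the unweighted Mantel-Haenszel test; Breslow is the
    generalized Wilcoxon test weighting each event time by the number at
    risk, hence sensitive to early differences.
    """
    from lifelines.statistics import logrank_test

    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=np.int64)
    g = np.asarray(groups, dtype=np.int64)
    if len(np.unique(g)) != 2:
        raise ValueError("exactly two groups are required")
    if e[g == 0].sum() == 0 and e[g == 1].sum() == 0:
        raise ValueError("no events in either group")
    lr = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
    br = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1],
                      weightings="wilcoxon")
    return float(lr.p_value), float(br.p_value)


# --------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxFit:
    """Cox model fit: coefficients, hazard ratios, Wald inference, risk score."""

    names: tuple[str, ...]
    coef: np.ndarray
    hr: np.ndarray
    se: np.ndarray
    p: np.ndarray
    risk_score: np.ndarray = field(repr=False)
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "HR": self.hr, "se": self.se, "p": self.p},
            index=list(self.names),
        )


def _cox_loglik(beta, X, times, events):
    """Breslow partial log-likelihood, gradient and Hessian."""
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-times)  # decreasing time: cumulative risk sets
    Xo, to, eo, wo = X[order], times[order], events[order], w[order]
    cum_w = np.cumsum(wo)
    cum_xw = np.cumsum(Xo * wo[:, None], axis=0)
    cum_xxw = np.cumsum(Xo[:, :, None] * Xo[:, None, :] * wo[:, None, None], axis=0)
    # Breslow: ties share the full risk set at their common time; map each
    # event to the last index with time >= its time
    ll, grad, hess = 0.0, np.zeros(X.shape[1]), np.zeros((X.shape[1], X.shape[1]))
    idx_of_time = {}
    for i in range(len(to)):
        idx_of_time[to[i]] = i  # last occurrence wins (largest risk set)
    for i in range(len(to)):
        if not eo[i]:
            continue
        j = idx_of_time[to[i]]
        sw = cum_w[j]
        sx = cum_xw[j] / sw
        ll += (Xo[i] @ beta) - np.log(sw)
        grad += Xo[i] - sx
        hess -= cum_xxw[j] / sw - np.outer(sx, sx)
    return ll, grad, hess


def cox_fit(covariates, times, events, names=None, max_iter: int = 50,
            tol: float = 1e-8) -> CoxFit:
    """Newton-Raphson Cox fit with Breslow tie handling.

    Iterates to gradient norm < ``tol``; a monotone likelihood (perfect
    separation) caps the iterations with a divergence warning.  Raises on
    constant or linearly dependent covariates.
    """
    if isinstance(covariates, pd.DataFrame):
        names = tuple(covariates.columns)
        X = covariates.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(covariates, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        names = tuple(names) if names is not None else tuple(
            f"x{i}" for i in range(X.shape[1])
        )
    t = np.asarray(times, dtype=np.float64)
    e = np.asarray(events, dtype=np.int64)
    if np.any(X.std(axis=0) == 0):
        const = [names[i] for i in range(X.shape[1]) if X[:, i].std() == 0]
        raise ValueError(f"constant covariates: {const}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinear columns)")
    if e.sum() < X.shape[1] + 1:
        raise ValueError("too few events for the number of covariates")

    # center for numerical stability; the fit is invariant to centering
    Xc = X - X.mean(axis=0)
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik(beta, Xc, t, e)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta - step
        if np.linalg.norm(new_beta) > 50:  # monotone likelihood guard
            beta = new_beta
            break
        beta = new_beta
    if not converged:
        warnings.warn("Cox Newton-Raphson did not converge (possible separation)")
    _, _, hess = _cox_loglik(beta, Xc, t, e)
    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return CoxFit(
        names=names,
        coef=beta,
        hr=np.exp(beta),
        se=se,
        p=p,
        risk_score=Xc @ beta,
        converged=converged,
    )


def cox_risk_auc(fit: CoxFit, binary_outcome) -> RocResult:
    """AUC of the Cox linear predictor against a binary outcome.

    The risk score is invariant to covariate centering, so the AUC is too.
    """
    return roc_auc(fit.risk_score, binary_outcome)
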