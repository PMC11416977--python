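"""End-to-end orchestration of the two-cohort radiomic study.

``run_study`` executes: simulate surgical (TIME) and immunotherapy (ICI)
cohorts -> extract features -> intra-observer robustness filter ->
labelled matrices (cd3 / cd8 / trm / response / pfs12) -> model
exploration per label -> integrated cross-cohort infiltration prediction
-> survival analysis per predicted grouping plus a multivariable Cox
model.  The run is a pure function of its configuration; the report
carries per-stage SHA-256 provenance hashes of every intermediate table.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import ExtractionConfig, extract_cases
from .imaging import RoiMask
from .matrix import build_labelled_matrix, encode_pfs12, encode_response
from .model_search import SearchGrid, build_integrated_model, grid_search
from .phantom import (
    CohortSpec,
    PhantomSpec,
    generate_ici_cohort,
    generate_time_cohort,
    ici_cohort_table,
    time_cohort_table,
)
from .robustness import filter_robust
from .stats import compare_survival, cox_fit, cox_risk_auc, dcr_table, km_fit

__all__ = ["RunConfig", "run_study", "report_json", "run_study_to_json"]

MARKERS = ("cd3", "cd8", "trm")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one study run.

    Thresholds default to the study conventions: ICC > 0.80 robustness,
    |PCC| > 0.99 deduplication, 70/30 stratified split, 1..10 retained
    features, 12-month progression horizon.
    """

    seed: int = 0
    n_time: int = 60
    n_ici: int = 50
    effect_size: float = 1.5
    survival_link: float = math.log(0.218)
    censoring_rate: float = 0.02
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    grid: SearchGrid = field(default_factory=lambda: SearchGrid(
        selectors=("ANOVA", "KW"),
        classifiers=("LR", "NB", "LDA"),
        n_features=tuple(range(1, 6)),
    ))
    icc_threshold: float = 0.80
    pcc_threshold: float = 0.99
    split_fraction: float = 0.70
    pfs_horizon_months: float = 12.0
    n_rater_cases: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.icc_threshold < 1.0):
            raise ValueError("icc_threshold must be in (0, 1)")
        if not (0.0 < self.pcc_threshold <= 1.0):
            raise ValueError("pcc_threshold must be in (0, 1]")
        if not (0.5 <= self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in [0.5, 1)")


def _jitter_mask(mask: RoiMask, rng: np.random.Generator) -> RoiMask:
    """Emulate a second rater's ROI delineation by a boundary jitter.

    A small random fraction of the outer shell is added and of the inner
    boundary removed, mimicking slice-wise redrawing differences.
    """
    m = mask.voxels
    shell_out = ndimage.binary_dilation(m) & ~m
    shell_in = m & ~ndimage.binary_erosion(m)
    out = m.copy()
    out[shell_out & (rng.random(m.shape) < 0.15)] = True
    removed = shell_in & (rng.random(m.shape) < 0.15)
    if (out & ~removed).sum() > 0:
        out &= ~removed
    return RoiMask(out, mask.spacing)


def _sha(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(float_format="%.10g").encode()).hexdigest()


def run_study(config: RunConfig) -> dict:
    """Run the whole study; returns a nested, JSON-serializable report."""
    provenance: dict[str, str] = {}
    report: dict = {"config_seed": config.seed, "provenance": provenance}

    # --- stage 1: simulate -------------------------------------------------
    time_spec = CohortSpec(
        n_cases=config.n_time,
        effect_size=config.effect_size,
        survival_link=config.survival_link,
        censoring_rate=config.censoring_rate,
        seed=config.seed,
    )
    ici_spec = CohortSpec(
        n_cases=config.n_ici,
        effect_size=config.effect_size,
        survival_link=config.survival_link,
        censoring_rate=config.censoring_rate,
        seed=config.seed + 1,
    )
    time_cases = generate_time_cohort(time_spec, config.phantom)
    ici_cases = generate_ici_cohort(ici_spec, config.phantom)
    time_clin = time_cohort_table(time_cases).set_index("case_id")
    ici_clin = ici_cohort_table(ici_cases).set_index("case_id")
    provenance["time_clinical"] = _sha(time_clin)
    provenance["ici_clinical"] = _sha(ici_clin)

    # --- stage 2: extract --------------------------------------------------
    time_feats = extract_cases(time_cases, config.extraction)
    ici_feats = extract_cases(ici_cases, config.extraction)
    provenance["time_features"] = _sha(time_feats)
    provenance["ici_features"] = _sha(ici_feats)

    # --- stage 3: robustness filter ---------------------------------------
    n_rater = min(config.n_rater_cases, len(time_cases))
    rater_rng = np.random.default_rng(config.seed + 1000)
    rater_cases = [
        type(c)(
            case_id=c.case_id,
            volume=c.volume,
            mask=_jitter_mask(c.mask, rater_rng),
            cd3_pct=c.cd3_pct,
            cd8_pct=c.cd8_pct,
            trm_pct=c.trm_pct,
            latent_z=c.latent_z,
        )
        for c in time_cases[:n_rater]
    ]
    rater_feats = extract_cases(rater_cases, config.extraction)
    retained, iccs = filter_robust(
        time_feats.iloc[:n_rater], rater_feats, config.icc_threshold
    )
    report["robustness"] = {
        "n_features_total": int(time_feats.shape[1]),
        "n_features_retained": len(retained),
        "icc_threshold": config.icc_threshold,
    }
    time_feats = time_feats[retained]
    ici_feats = ici_feats[retained]

    # --- stage 4: TIME infiltration models --------------------------------
    time_results = {}
    report["time_models"] = {}
    for marker in MARKERS:
        lm = build_labelled_matrix(time_feats, time_clin, marker)
        best, leaderboard, _ = grid_search(
            lm, config.grid, config.seed, config.split_fraction, config.pcc_threshold
        )
        time_results[marker] = (lm, best)
        report["time_models"][marker] = {
            "selector": best.config.selector,
            "classifier": best.config.classifier,
            "n_features": best.config.n_features,
            "feature_ids": list(best.feature_ids),
            "train_auc": round(best.train_auc, 6),
            "test_auc": round(best.test_auc, 6),
            "n_configs": int(len(leaderboard)),
        }

    # --- stage 5: immunotherapy outcome models -----------------------------
    outcome_results = {}
    report["ici_models"] = {}
    for label in ("response", "pfs12"):
        lm = build_labelled_matrix(ici_feats, ici_clin, label)
        best, leaderboard, _ = grid_search(
            lm, config.grid, config.seed, config.split_fraction, config.pcc_threshold
        )
        outcome_results[label] = (lm, best)
        report["ici_models"][label] = {
            "selector": best.config.selector,
            "classifier": best.config.classifier,
            "n_features": best.config.n_features,
            "train_auc": round(best.train_auc, 6),
            "test_auc": round(best.test_auc, 6),
            "n_excluded": 0 if lm.excluded is None else int(len(lm.excluded)),
        }

    # --- stage 6: integrated TIME-immunotherapy models ---------------------
    response_y = ici_clin["response"].map(encode_response)
    integrated = {}
    report["integrated_models"] = {}
    for marker in MARKERS:
        lm, best = time_results[marker]
        integ = build_integrated_model(
            lm, best, outcome_results["response"][1], ici_feats,
            ici_response=response_y, seed=config.seed,
        )
        integrated[marker] = integ
        both = len(set(integ.groups)) == 2
        report["integrated_models"][marker] = {
            "response_auc": round(integ.response_roc.auc, 6),
            "response_auc_ci": [round(v, 6) for v in integ.response_roc.ci],
            "n_low": int((integ.groups == 0).sum()),
            "n_high": int((integ.groups == 1).sum()),
            "both_groups_nonempty": bool(both),
        }

    # --- stage 7: survival by predicted infiltration -----------------------
    times = ici_clin["pfs_months"].to_numpy()
    events = ici_clin["event"].to_numpy()
    control = response_y.to_numpy()  # disease control = favorable response
    report["survival"] = {}
    for marker in MARKERS:
        g = integrated[marker].groups.loc[ici_clin.index].to_numpy()
        entry: dict = {}
        if len(set(g)) == 2:
            dcr = dcr_table(g, control)
            lr_p, br_p = compare_survival(times, events, g)
            km_low = km_fit(times[g == 0], events[g == 0], horizon=float(times.max()))
            km_high = km_fit(times[g == 1], events[g == 1], horizon=float(times.max()))
            entry = {
                "dcr_low_pct": dcr["dcr_low_pct"],
                "dcr_high_pct": dcr["dcr_high_pct"],
                "dcr_p": round(dcr["p"], 6),
                "logrank_p": round(lr_p, 6),
                "breslow_p": round(br_p, 6),
                "mean_pfs_low": round(km_low.restricted_mean, 4),
                "mean_pfs_low_se": round(km_low.restricted_mean_se, 4),
                "mean_pfs_high": round(km_high.restricted_mean, 4),
                "mean_pfs_high_se": round(km_high.restricted_mean_se, 4),
                "significant": bool(lr_p < 0.05),
            }
        else:
            entry = {"degenerate_grouping": True, "significant": False}
        report["survival"][marker] = entry

    # --- stage 8: multivariable Cox on predicted infiltration --------------
    cov = pd.DataFrame(
        {m: integrated[m].groups.loc[ici_clin.index] for m in MARKERS}
    )
    cox_entry: dict = {}
    usable = [m for m in MARKERS if cov[m].nunique() == 2]
    cov = cov[usable]
    if len(usable) >= 1 and np.linalg.matrix_rank(
        cov.to_numpy() - cov.to_numpy().mean(axis=0)
    ) == len(usable):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cox_fit(cov, times, events)
        pfs12_label = pd.Series(
            {cid: encode_pfs12(ici_clin.loc[cid, "pfs_months"],
                               int(ici_clin.loc[cid, "event"]))
             for cid in ici_clin.index}
        ).dropna()
        cox_entry = {
            m: {"HR": round(float(fit.hr[i]), 6), "p": round(float(fit.p[i]), 6)}
            for i, m in enumerate(usable)
        }
        if set(pfs12_label) == {0, 1}:
            mask_idx = [list(ici_clin.index).index(c) for c in pfs12_label.index]
            sub_fit = type(fit)(
                names=fit.names, coef=fit.coef, hr=fit.hr, se=fit.se, p=fit.p,
                risk_score=fit.risk_score[mask_idx], converged=fit.converged,
            )
            roc = cox_risk_auc(sub_fit, pfs12_label.to_numpy())
            cox_entry["risk_score_auc"] = round(roc.auc, 6)
        cox_entry["significant"] = bool(np.any(fit.p[: len(usable)] < 0.05))
    else:
        cox_entry = {"degenerate_covariates": True, "significant": False}
    report["cox"] = cox_entry

    return report


def report_json(report: dict) -> str:
    """Serialize a study report deterministically (sorted keys)."""
    return json.dumps(report, sort_keys=True, indent=2)


def run_study_to_json(config: RunConfig, out_path=None) -> str:
    text = report_json(run_study(config))
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
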