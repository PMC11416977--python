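"""Synthetic CT phantom and cohort generation.

The generators emulate the statistical structure that the downstream
radiomic analysis assumes: an ellipsoidal tumor ROI carrying a stationary
Gaussian random-field texture on a noisy lung background, a surgical
("TIME") cohort in which latent T-cell infiltration fractions modulate the
tumor texture, and an immunotherapy ("ICI") cohort in which the same latent
infiltration drives the iRECIST response category and an exponential
proportional-hazards progression-free-survival (PFS) time.

All generators are pure functions of their seeds: one global seed fans out
to per-case substreams, so adding a case never perturbs earlier cases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .imaging import ImageVolume, RoiMask

__all__ = [
    "PhantomSpec",
    "InfiltrationMarginals",
    "CohortSpec",
    "TimeCase",
    "IciCase",
    "generate_phantom",
    "generate_time_cohort",
    "generate_ici_cohort",
    "time_cohort_table",
    "ici_cohort_table",
    "RESPONSE_CATEGORIES",
]

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of one synthetic tumor phantom.

    Parameters
    ----------
    grid_shape : voxels per axis (z, y, x); each >= 8.
    voxel_spacing : mm per axis.
    roi_axes : ellipsoid semi-axes in mm, ordered (z, y, x).
    texture_correlation_length : mm; Gaussian smoothing scale of the
        intra-tumor texture field.
    texture_contrast : HU; standard deviation of the texture field.
    roi_mean : HU; mean intensity inside the tumor (soft-tissue range).
    background_mean, background_std : HU; i.i.d. Gaussian lung background.
    seed : RNG seed; identical seeds give bit-identical phantoms.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_axes: tuple[float, float, float] = (8.0, 10.0, 12.0)
    texture_correlation_length: float = 3.0
    texture_contrast: float = 40.0
    roi_mean: float = 40.0
    background_mean: float = -800.0
    background_std: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 8 per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if self.texture_contrast < 0:
            raise ValueError("texture_contrast must be >= 0")
        for ax in range(3):
            semi_vox = self.roi_axes[ax] / self.voxel_spacing[ax]
            if semi_vox > (self.grid_shape[ax] - 1) / 2.0 - 0.5:
                raise ValueError(
                    f"ROI semi-axis {self.roi_axes[ax]} mm does not fit inside the "
                    f"{self.grid_shape[ax]}-voxel grid on axis {ax} at spacing "
                    f"{self.voxel_spacing[ax]} mm; enlarge the grid or shrink the ROI"
                )


@dataclass(frozen=True)
class InfiltrationMarginals:
    """Beta parameters for nested infiltration fractions (flow-cytometry %).

    CD3 is drawn first as a Beta fraction of leukocytes; CD8 as a Beta
    fraction of CD3; tissue-resident memory (TRM) as a Beta fraction of CD8.
    Nesting enforces TRM <= CD8 <= CD3 per case by construction.
    """

    cd3: tuple[float, float] = (4.0, 6.0)
    cd8_of_cd3: tuple[float, float] = (3.0, 3.0)
    trm_of_cd8: tuple[float, float] = (2.0, 3.0)

    def moments(self) -> dict[str, tuple[float, float]]:
        """Analytic (mean, sd) of each marginal fraction in [0, 1].

        The CD8 and TRM marginals are products of independent Betas, whose
        raw moments factorize.
        """

        def beta_m1_m2(a: float, b: float) -> tuple[float, float]:
            m1 = a / (a + b)
            m2 = a * (a + 1) / ((a + b) * (a + b + 1))
            return m1, m2

        out: dict[str, tuple[float, float]] = {}
        m1, m2 = 1.0, 1.0
        for name, (a, b) in (
            ("cd3", self.cd3),
            ("cd8", self.cd8_of_cd3),
            ("trm", self.trm_of_cd8),
        ):
            f1, f2 = beta_m1_m2(a, b)
            m1 *= f1
            m2 *= f2
            sd = math.sqrt(max(m2 - m1 * m1, 0.0))
            out[name] = (m1, sd)
        return out


@dataclass(frozen=True)
class CohortSpec:
    """Statistical coupling parameters for a simulated patient cohort.

    ``effect_size`` couples the standardized latent infiltration to the
    tumor texture (mean shift in units of the texture SD per latent-z unit;
    0 = images carry no label information).  ``response_link`` are logistic
    intercept/slope from latent CD8 z to P(favorable response = CR or PR).
    ``survival_link`` is the log hazard ratio per latent CD8 z unit for the
    exponential PFS model; the default corresponds to the strong protective
    CD8 effect (HR ~= 0.218) the pipeline is designed to detect.
    """

    n_cases: int = 135
    effect_size: float = 1.5
    infiltration_marginals: InfiltrationMarginals = field(default_factory=InfiltrationMarginals)
    response_link: tuple[float, float] = (1.1, 1.0)
    survival_link: float = math.log(0.218)
    baseline_median_pfs: float = 10.3
    censoring_rate: float = 0.02
    censoring_horizon: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 4:
            raise ValueError(f"n_cases must be >= 4, got {self.n_cases}")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError(f"censoring_rate must be in [0, 1), got {self.censoring_rate}")
        if not np.isfinite(self.survival_link):
            raise ValueError("survival_link must be finite")
        moms = self.infiltration_marginals.moments()
        if any(sd == 0 for _, sd in moms.values()):
            warnings.warn("degenerate infiltration marginals: zero variance; "
                          "labels will be emitted but carry no signal")


@dataclass(frozen=True)
class TimeCase:
    """One surgical-cohort case: phantom image + infiltration percentages."""

    case_id: str
    volume: ImageVolume
    mask: RoiMask
    cd3_pct: float
    cd8_pct: float
    trm_pct: float
    latent_z: dict[str, float] = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class IciCase:
    """One immunotherapy-cohort case: phantom image + clinical outcome."""

    case_id: str
    volume: ImageVolume
    mask: RoiMask
    response: str
    pfs_months: float
    event: int
    latent_z: dict[str, float] = field(default_factory=dict, repr=False)


@lru_cache(maxsize=64)
def _smoothing_norm(sigma_vox: tuple[float, float, float], shape: tuple[int, int, int]) -> float:
    """l2 norm of the Gaussian smoothing kernel (impulse response)."""
    imp = np.zeros(shape)
    imp[tuple(n // 2 for n in shape)] = 1.0
    ker = ndimage.gaussian_filter(imp, sigma_vox, mode="constant")
    return float(np.sqrt(np.sum(ker**2)))


def _texture_field(
    rng: np.random.Generator, spec: PhantomSpec, contrast: float
) -> np.ndarray:
    """Stationary Gaussian random field with unit-variance normalization.

    White noise smoothed with a Gaussian kernel whose width equals the
    texture correlation length, rescaled analytically so the marginal voxel
    SD equals ``contrast`` HU.
    """
    if contrast == 0:
        return np.zeros(spec.grid_shape)
    noise = rng.standard_normal(spec.grid_shape)
    sigma_vox = tuple(
        spec.texture_correlation_length / s for s in spec.voxel_spacing
    )
    smooth = ndimage.gaussian_filter(noise, sigma_vox, mode="wrap")
    norm = _smoothing_norm(sigma_vox, spec.grid_shape)
    return smooth * (contrast / norm)


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in spec.grid_shape]
    grids = np.ogrid[tuple(slice(0, n) for n in spec.grid_shape)]
    q = sum(
        ((g - c) * s / a) ** 2
        for g, c, s, a in zip(grids, center, spec.voxel_spacing, spec.roi_axes)
    )
    return q <= 1.0


def generate_phantom(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    roi_mean_shift: float = 0.0,
    contrast_scale: float = 1.0,
) -> tuple[ImageVolume, RoiMask]:
    """Generate one phantom volume and its ellipsoidal tumor mask.

    ``roi_mean_shift`` (HU) and ``contrast_scale`` are hooks used by the
    cohort generators to couple latent infiltration to texture; direct
    callers normally leave them at their neutral values.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec)
    vox = spec.background_mean + spec.background_std * rng.standard_normal(spec.grid_shape)
    texture = _texture_field(rng, spec, spec.texture_contrast * contrast_scale)
    vox[mask] = spec.roi_mean + roi_mean_shift + texture[mask]
    return (
        ImageVolume(vox, spec.voxel_spacing),
        RoiMask(mask, spec.voxel_spacing),
    )


def _draw_infiltration(
    rng: np.random.Generator, marg: InfiltrationMarginals
) -> tuple[float, float, float]:
    cd3 = rng.beta(*marg.cd3)
    cd8 = cd3 * rng.beta(*marg.cd8_of_cd3)
    trm = cd8 * rng.beta(*marg.trm_of_cd8)
    return cd3, cd8, trm


def _standardize(frac: float, name: str, marg: InfiltrationMarginals) -> float:
    mean, sd = marg.moments()[name]
    if sd == 0:
        return 0.0
    return (frac - mean) / sd


def _case_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _coupled_phantom(
    phantom: PhantomSpec,
    cohort: CohortSpec,
    z_cd3: float,
    z_cd8: float,
    rng: np.random.Generator,
) -> tuple[ImageVolume, RoiMask]:
    # latent CD8 shifts the tumor mean (in texture-SD units); latent CD3
    # mildly modulates the texture amplitude, giving each marker an imaging
    # correlate while keeping effect_size=0 an exact null.
    shift = cohort.effect_size * phantom.texture_contrast * z_cd8
    scale = math.exp(0.1 * cohort.effect_size * z_cd3)
    return generate_phantom(phantom, rng=rng, roi_mean_shift=shift, contrast_scale=scale)


def generate_time_cohort(
    cohort: CohortSpec, phantom: PhantomSpec
) -> list[TimeCase]:
    """Simulate the surgical cohort: phantoms + infiltration percentages.

    Per case the nested Beta marginals give CD3/CD8/TRM percentages with
    TRM <= CD8 <= CD3, and the phantom texture parameters are shifted by
    ``effect_size`` times the standardized latent infiltration.
    """
    marg = cohort.infiltration_marginals
    cases = []
    for i in range(cohort.n_cases):
        rng = _case_rng(cohort.seed, i)
        cd3, cd8, trm = _draw_infiltration(rng, marg)
        z = {name: _standardize(v, name, marg) for name, v in
             (("cd3", cd3), ("cd8", cd8), ("trm", trm))}
        vol, mask = _coupled_phantom(phantom, cohort, z["cd3"], z["cd8"], rng)
        cases.append(
            TimeCase(
                case_id=f"time_{i:04d}",
                volume=vol,
                mask=mask,
                cd3_pct=100.0 * cd3,
                cd8_pct=100.0 * cd8,
                trm_pct=100.0 * trm,
                latent_z=z,
            )
        )
    return cases


def _draw_response(rng: np.random.Generator, cohort: CohortSpec, z_cd8: float) -> str:
    b0, b1 = cohort.response_link
    p_fav = 1.0 / (1.0 + math.exp(-(b0 + b1 * z_cd8)))
    # conditional CR/PR and SD/PD splits follow the observed response mix
    # of an anti-PD-1-treated NSCLC cohort (CR 8, PR 76, SD 18, PD 10).
    if rng.random() < p_fav:
        return "CR" if rng.random() < 8.0 / 84.0 else "PR"
    return "SD" if rng.random() < 18.0 / 28.0 else "PD"


def _draw_pfs(
    rng: np.random.Generator, cohort: CohortSpec, z_cd8: float
) -> tuple[float, int]:
    lam0 = math.log(2.0) / cohort.baseline_median_pfs
    lam = lam0 * math.exp(cohort.survival_link * z_cd8)
    t = rng.exponential(1.0 / lam)
    if cohort.censoring_rate == 0:
        return t, 1
    # independent exponential censoring calibrated so the expected censored
    # fraction at z=0 equals censoring_rate, truncated at the administrative
    # follow-up horizon.
    mu = cohort.censoring_rate / (1.0 - cohort.censoring_rate) * lam0
    c = min(rng.exponential(1.0 / mu), cohort.censoring_horizon)
    if t <= c:
        return t, 1
    return c, 0


def generate_ici_cohort(
    cohort: CohortSpec, phantom: PhantomSpec
) -> list[IciCase]:
    """Simulate the immunotherapy cohort: phantoms + response + PFS.

    Response is drawn from a logistic link on latent CD8 infiltration; PFS
    from an exponential proportional-hazards model with log-HR equal to
    ``survival_link`` per latent CD8 z unit, with independent censoring.
    """
    marg = cohort.infiltration_marginals
    cases = []
    for i in range(cohort.n_cases):
        rng = _case_rng(cohort.seed, i)
        cd3, cd8, trm = _draw_infiltration(rng, marg)
        z = {name: _standardize(v, name, marg) for name, v in
             (("cd3", cd3), ("cd8", cd8), ("trm", trm))}
        vol, mask = _coupled_phantom(phantom, cohort, z["cd3"], z["cd8"], rng)
        response = _draw_response(rng, cohort, z["cd8"])
        pfs, event = _draw_pfs(rng, cohort, z["cd8"])
        cases.append(
            IciCase(
                case_id=f"ici_{i:04d}",
                volume=vol,
                mask=mask,
                response=response,
                pfs_months=pfs,
                event=event,
                latent_z=z,
            )
        )
    return cases


def time_cohort_table(cases: list[TimeCase]):
    """Clinical table (case_id, cd3_pct, cd8_pct, trm_pct) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "cd3_pct": [c.cd3_pct for c in cases],
            "cd8_pct": [c.cd8_pct for c in cases],
            "trm_pct": [c.trm_pct for c in cases],
        }
    )


def ici_cohort_table(cases: list[IciCase]):
    """Clinical table (case_id, response, pfs_months, event) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "response": [c.response for c in cases],
            "pfs_months": [c.pfs_months for c in cases],
            "event": [c.event for c in cases],
        }
    )
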