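"""Phantom brain slices and synthetic cohorts for end-to-end testing.

No raw imaging is distributed with the analysis, so this module generates
slices that carry the same statistical structure the pipeline is built to
detect: an elliptical "brain" on a zero background, a smooth background
intensity field, bright roughly-convex lesions (white-matter-hyperintensity
surrogates) whose count and size differ by group, and pixel noise.  Each
lesion is a truncated Gaussian bump and therefore contributes one local
maximum, which keeps the persistence ground truth countable: one extra
dim-1 (hole) death per lesion above the background.

Clinical covariates are sampled to match the reported group contrasts of
the study population: the case (NPSLE-like) group is somewhat younger, has
a higher prevalence of cerebrovascular disease, higher CH50, and longer
disease duration.

All randomness flows from a single seed through
:class:`numpy.random.SeedSequence` spawning; no global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import peel_features, persistence, preprocess

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_covariates",
    "generate_cohort",
    "scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one phantom slice.

    Per-group fields are (control, case) pairs; ``group`` selects the entry
    at generation time.  Units: pixels for lengths; amplitudes are in units
    of the background-field SD (the smooth "anatomy" field is scaled to SD
    ``bg_amplitude`` = 1 in the mask, so it dominates the in-mask variance
    the way tissue contrast dominates a real slice).

    A lesion of radius r is a compactly supported Gaussian bump truncated
    (continuously) at 2r, with peak height
    ``lesion_boost * r / radius_median[0]``: larger lesions are brighter,
    the way bigger hyperintensities suffer less partial-volume dilution.
    Each bump contributes one local maximum, i.e. one extra hole death.

    Pixel noise is spatially correlated (white noise blurred with
    ``noise_sigma``) so it produces a modest, stable number of texture
    maxima rather than thousands of single-pixel ones.
    """

    shape: tuple[int, int] = (256, 256)
    brain_axes: tuple[float, float] | None = None  # semi-axes (rows, cols)
    bg_sigma: float = 8.0  # blur radius of the smooth background field
    bg_amplitude: float = 1.0
    lam: tuple[float, float] = (6.0, 12.0)  # Poisson lesion rate per group
    radius_median: tuple[float, float] = (2.5, 3.75)  # log-normal median, px
    radius_log_sd: float = 0.2
    lesion_boost: float = 2.0  # peak height at the reference (control) radius
    lesion_trunc: float = 1.5  # support radius, in units of r
    noise_sd: float = 0.1
    noise_sigma: float = 2.5  # correlation length of the pixel noise
    lesion_count: int | None = None  # fixed count override (testing)

    def axes(self) -> tuple[float, float]:
        if self.brain_axes is not None:
            return self.brain_axes
        h, w = self.shape
        return 0.42 * h, 0.36 * w


@dataclass(frozen=True)
class CohortSpec:
    """Covariate-generation parameters, (control, case) per-group pairs.

    Medians/IQRs follow the reported demographics: age is normal (case
    median 39.5, IQR 28.5-47.3; control median 44.5, IQR 30.8-54.3),
    cerebrovascular-disease prevalence 30% vs 10%, CH50 log-normal (case
    median 30.6, IQR 24.3-37.7; control 24.4, IQR 19.8-31.9), disease
    duration exponential (medians 3.5 vs ~0 years), prednisolone dose
    log-normal (medians 15 vs 9 mg/day).
    """

    n: tuple[int, int] = (30, 30)
    age_median: tuple[float, float] = (44.5, 39.5)
    age_sd: tuple[float, float] = (17.4, 13.9)  # from IQR / 1.349
    cvd_prevalence: tuple[float, float] = (0.10, 0.30)
    ch50_log_median: tuple[float, float] = (math.log(24.4), math.log(30.6))
    ch50_log_sd: tuple[float, float] = (0.353, 0.325)
    duration_median: tuple[float, float] = (0.5, 3.5)  # years
    pred_log_median: tuple[float, float] = (math.log(9.0), math.log(15.0))
    pred_log_sd: tuple[float, float] = (0.8, 0.6)


def _ellipse_mask(shape, axes) -> np.ndarray:
    h, w = shape
    a, b = axes
    yy, xx = np.ogrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def generate_phantom(
    spec: PhantomSpec, group: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One phantom slice and its brain mask, reproducible per seed.

    In-mask intensity = smooth background + lesion bumps + pixel noise;
    out-of-mask pixels are 0.  Lesion centers are uniform over the mask
    eroded by the lesion radius, so every bump lies inside the brain.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    h, w = spec.shape
    mask = _ellipse_mask(spec.shape, spec.axes())
    img = np.zeros((h, w))

    if spec.bg_amplitude > 0:
        bg = ndimage.gaussian_filter(rng.standard_normal((h, w)), spec.bg_sigma)
        s = bg[mask].std()
        if s > 0:
            img[mask] += spec.bg_amplitude * bg[mask] / s

    g = int(group)
    lam = spec.lam[g]
    if spec.lesion_count is not None:
        n_lesions = spec.lesion_count
    else:
        n_lesions = rng.poisson(lam) if lam > 0 else 0
    if n_lesions:
        edt = ndimage.distance_transform_edt(mask)
        yy, xx = np.mgrid[:h, :w]
        base = math.exp(-spec.lesion_trunc**2 / 2)
        for _ in range(n_lesions):
            r = rng.lognormal(math.log(spec.radius_median[g]), spec.radius_log_sd)
            if 2 * r >= min(spec.axes()):
                raise ValueError("lesion larger than brain ellipse")
            inside = edt > r
            if not inside.any():
                raise ValueError("lesion larger than brain ellipse")
            flat = np.flatnonzero(inside)
            c = flat[rng.integers(len(flat))]
            cy, cx = divmod(c, w)
            d2 = (yy - cy) ** 2.0 + (xx - cx) ** 2.0
            peak = spec.lesion_boost * r / spec.radius_median[0]
            bump = peak * np.maximum(
                np.exp(-d2 / (2 * r * r)) - base, 0.0
            ) / (1.0 - base)
            img += bump

    if spec.noise_sd > 0:
        noise = ndimage.gaussian_filter(
            rng.standard_normal((h, w)), spec.noise_sigma
        )
        s = noise[mask].std()
        if s > 0:
            img[mask] += spec.noise_sd * noise[mask] / s

    img[~mask] = 0.0
    return img, mask


def generate_covariates(
    cspec: CohortSpec, group: int, rng: np.random.Generator
) -> dict[str, float]:
    g = int(group)
    return {
        "age": float(rng.normal(cspec.age_median[g], cspec.age_sd[g])),
        "cvd": float(rng.random() < cspec.cvd_prevalence[g]),
        "ch50": float(
            rng.lognormal(cspec.ch50_log_median[g], cspec.ch50_log_sd[g])
        ),
        "duration": float(
            rng.exponential(cspec.duration_median[g] / math.log(2))
        ),
        "pred_dose": float(
            rng.lognormal(cspec.pred_log_median[g], cspec.pred_log_sd[g])
        ),
    }


def extract_features(
    image: np.ndarray, mask: np.ndarray, alpha: float = 0.95
) -> dict[str, float]:
    """Standardize one slice and return its 14 diagram features."""
    field = preprocess.standardize(image, mask)
    dgm0, dgm1 = persistence.compute_diagrams(field)
    row: dict[str, float] = {}
    row.update(peel_features.diagram_features(dgm0, alpha).to_dict("dim0_"))
    row.update(peel_features.diagram_features(dgm1, alpha).to_dict("dim1_"))
    return row


def generate_cohort(
    pspec: PhantomSpec,
    cspec: CohortSpec,
    seed: int,
    alpha: float = 0.95,
    return_images: bool = False,
):
    """Simulate a full cohort and run feature extraction on every subject.

    Returns a cohort DataFrame (one row per subject: group, covariates, 14
    feature columns), plus the (image, mask) pairs when ``return_images``.
    """
    ss = np.random.SeedSequence(seed)
    n0, n1 = cspec.n
    child = ss.spawn(n0 + n1)
    rows = []
    images = []
    k = 0
    for group, n in ((0, n0), (1, n1)):
        for _ in range(n):
            rng = np.random.default_rng(child[k])
            img, mask = generate_phantom(pspec, group, rng)
            row = {"subject_id": f"S{k:03d}", "group": group}
            row.update(generate_covariates(cspec, group, rng))
            row.update(extract_features(img, mask, alpha))
            rows.append(row)
            if return_images:
                images.append((img, mask))
            k += 1
    table = pd.DataFrame(rows)
    if return_images:
        return table, images
    return table


def scenario(
    name: str, shape: tuple[int, int] = (256, 256), n: int = 30
) -> tuple[PhantomSpec, CohortSpec]:
    """Named presets: "paperlike" (default group contrast), "null" (no
    group difference anywhere), "strong" (amplified lesion contrast)."""
    pspec = PhantomSpec(shape=shape)
    cspec = CohortSpec(n=(n, n))
    if name == "paperlike":
        return pspec, cspec
    if name == "null":
        lam = pspec.lam[0]
        rad = pspec.radius_median[0]
        pnull = replace(pspec, lam=(lam, lam), radius_median=(rad, rad))
        cnull = CohortSpec(
            n=(n, n),
            age_median=(44.5, 44.5),
            age_sd=(17.4, 17.4),
            cvd_prevalence=(0.10, 0.10),
            ch50_log_median=(math.log(24.4),) * 2,
            ch50_log_sd=(0.353, 0.353),
            duration_median=(0.5, 0.5),
            pred_log_median=(math.log(9.0),) * 2,
            pred_log_sd=(0.8, 0.8),
        )
        return pnull, cnull
    if name == "strong":
        pstrong = replace(
            pspec,
            lam=(pspec.lam[0], 3 * pspec.lam[0]),
            radius_median=(pspec.radius_median[0], 2 * pspec.radius_median[0]),
        )
        return pstrong, cspec
    raise ValueError(f"unknown scenario {name!r}")


SCENARIOS = ("null", "paperlike", "strong")
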