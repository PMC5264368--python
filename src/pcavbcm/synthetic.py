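"""Synthetic aphasia cohorts with known ground truth.

No imaging data are distributable with the published cohort, so this module
generates cohorts with exactly the statistical structure the analysis
assumes, at desk scale:

* ``k`` independent standard-normal latent abilities per patient;
* a behavioural battery whose measures load on the latents through a
  block-structured loading matrix (mimicking the published omnibus solution:
  a large phonological block, semantic and executive blocks, and a
  speech-quanta block), plus unique noise, affinely mapped to percent scores;
* a lattice "brain" (an ellipsoid template of unit intensity) in which each
  latent is assigned a disjoint ellipsoidal target region whose intensity is
  reduced in proportion to how impaired the patient is on that latent;
* a global severity scalar per patient, partially coupled to the latents,
  which erodes an outer "severity belt" of the template — the analogue of the
  middle-cerebral-artery outer territory whose integrity tracks overall
  lesion volume.  This plants the lesion-volume confound that the
  volume-covariate analysis is designed to remove;
* binary lesion masks obtained by thresholding damaged (pre-smoothing)
  intensity at a fraction of the template, and smoothed intensity volumes.

Everything is deterministic given ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vbcm import BrainVolume, lesion_volume, smooth

DEFAULT_SHAPE = (48, 56, 48)
DEFAULT_VOXEL_MM = 2.0


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel index space."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def rho2(self, shape) -> np.ndarray:
        """Squared relative radial coordinate (0 at centre, 1 on the surface)."""
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        return sum(
            ((g - c) / r) ** 2 for g, c, r in zip(grids, self.center, self.radii)
        )

    def mask(self, shape) -> np.ndarray:
        return self.rho2(shape) <= 1.0


def _default_loading_pattern(n_measures: int = 21, k: int = 4) -> np.ndarray:
    """Block loading pattern echoing the published omnibus structure:
    blocks of 11 / 3 / 3 / 4 measures with primary loadings around .75 and
    small fixed cross-loadings."""
    if (n_measures, k) != (21, 4):
        raise ValueError("the default pattern is defined for 21 measures x 4 factors")
    lam = np.zeros((21, 4))
    blocks = {0: range(0, 11), 1: range(11, 14), 2: range(14, 17), 3: range(17, 21)}
    for f, rows in blocks.items():
        for i in rows:
            lam[i, f] = 0.75
    # mild cross-loadings, fixed (not random) so the pattern is a constant
    lam[6, 2] = 0.35   # a phonological test with an executive component
    lam[9, 1] = 0.30   # naming loads on semantics too
    lam[10, 1] = 0.30
    lam[13, 2] = 0.25
    lam[17, 1] = 0.30  # lexical-variety measure shares semantic variance
    lam[19, 0] = 0.20
    return lam


def _default_regions() -> list[Ellipsoid]:
    # four disjoint left-hemisphere targets inside the template ellipsoid
    return [
        Ellipsoid((13.0, 16.0, 24.0), (4.5, 5.5, 4.5)),
        Ellipsoid((13.0, 36.0, 22.0), (4.5, 5.5, 4.5)),
        Ellipsoid((15.0, 26.0, 34.0), (4.5, 5.5, 4.5)),
        Ellipsoid((15.0, 26.0, 12.0), (4.5, 5.5, 4.5)),
    ]


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults are the package's study conditions."""

    n_patients: int = 31
    n_factors: int = 4
    loading_pattern: np.ndarray = field(default_factory=_default_loading_pattern)
    noise_sd: float | np.ndarray = 0.45
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_size: float = DEFAULT_VOXEL_MM
    brain: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((23.5, 27.5, 23.5), (19.0, 24.0, 20.0))
    )
    regions: list[Ellipsoid] = field(default_factory=_default_regions)
    core: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((10.0, 26.0, 24.0), (3.0, 4.0, 3.0))
    )
    belt_inner: float = 0.72  # belt = brain shell between these relative radii,
    belt_outer: float = 0.95  # restricted to the left hemisphere
    belt_profile_min: float = 0.3  # damage depth at the belt's inner edge
    effect_size: float | np.ndarray = 0.65  # intensity drop per latent sd of deficit
    belt_effect: float = 1.0  # intensity drop at the belt rim for severity 1
    core_effect: float = 0.8  # intensity drop in the common infarct core
    severity_coupling: float = 0.85  # corr of severity driver with mean deficit
    severity_min: float = 0.55  # severity range: every patient erodes at least
    severity_max: float = 1.0  # the belt rim; the worst erode the whole belt
    image_noise_sd: float = 0.06
    mask_criterion: float = 0.5  # lesion = damaged intensity below this x template
    fwhm_mm: float = 8.0
    score_center: float = 55.0
    score_scale: float = 16.0

    def validate(self) -> None:
        lam = np.asarray(self.loading_pattern, float)
        if lam.shape[1] != self.n_factors:
            raise ValueError("loading pattern columns != n_factors")
        if (np.abs(lam).max(axis=0) < 0.5).any():
            raise ValueError("every factor needs at least one loading >= .5")
        if len(self.regions) != self.n_factors:
            raise ValueError("need one target region per factor")
        masks = [r.mask(self.shape) for r in self.regions] + [self.core.mask(self.shape)]
        labels = [f"region {i}" for i in range(len(self.regions))] + ["core"]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if (masks[i] & masks[j]).any():
                    raise ValueError(f"{labels[i]} and {labels[j]} overlap")
        belt = self.belt_mask()
        for lab, m in zip(labels, masks):
            if (belt & m).any():
                raise ValueError(f"{lab} intersects the severity belt")
        if np.any(np.asarray(self.effect_size) < 0) or self.belt_effect < 0:
            raise ValueError("effect sizes must be non-negative")

    # --- geometry -------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        # centre the lattice on the world origin, MNI-like
        for ax in range(3):
            aff[ax, 3] = -self.voxel_size * (self.shape[ax] - 1) / 2.0
        return aff

    def template(self) -> np.ndarray:
        return self.brain.mask(self.shape).astype(float)

    def region_masks(self) -> list[np.ndarray]:
        return [r.mask(self.shape) for r in self.regions]

    def belt_mask(self) -> np.ndarray:
        rho = np.sqrt(self.brain.rho2(self.shape))
        shell = (rho >= self.belt_inner) & (rho <= self.belt_outer)
        left = np.zeros(self.shape, bool)
        left[: int(self.brain.center[0] - 2), :, :] = True  # left hemisphere only
        belt = shell & left
        for r in [*self.regions, self.core]:
            belt &= ~r.mask(self.shape)
        return belt

    def belt_profile(self) -> np.ndarray:
        """Radial damage-depth profile over the belt.

        Depth grows from ``belt_profile_min`` at the inner edge to 1 at the
        outer rim following an inverse-square law in the radial coordinate.
        With this profile the number of belt voxels whose damage exceeds the
        lesion criterion grows approximately linearly with the patient's
        severity, so total lesion volume is close to a linear proxy for
        severity — which is what lets a linear volume covariate absorb the
        belt confound, and is also how the cohort avoids an implausible
        all-or-nothing belt lesion."""
        rho = np.sqrt(self.brain.rho2(self.shape))
        q = np.clip(
            (rho - self.belt_inner) / (self.belt_outer - self.belt_inner), 0.0, 1.0
        )
        pmin = self.belt_profile_min
        prof = pmin / (1.0 - (1.0 - pmin) * q)
        return prof * self.belt_mask()


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    spec: SyntheticSpec
    latents: np.ndarray  # n x k
    behaviour: pd.DataFrame  # n x m percent scores
    volumes: list[BrainVolume]
    masks: list[np.ndarray]
    severity: np.ndarray
    clip_fraction: float

    @property
    def lesion_volumes(self) -> np.ndarray:
        return np.asarray([lesion_volume(m) for m in self.masks])


def gen_latents(n: int, k: int, seed: int | np.random.Generator) -> np.ndarray:
    """Independent standard-normal latent abilities, reproducible by seed."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((n, k))


def gen_behavior(
    latents: np.ndarray,
    loading_pattern: np.ndarray,
    noise_sd: float | np.ndarray,
    seed: int | np.random.Generator,
    score_center: float = 55.0,
    score_scale: float = 16.0,
) -> tuple[pd.DataFrame, float]:
    """Percent-score battery from latents: ``raw = latents @ Lambda.T + eps``,
    affinely mapped to [0, 100] with clipping.

    Returns the score table and the fraction of cells clipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = np.asarray(loading_pattern, float)
    z = np.asarray(latents, float)
    raw = z @ lam.T + rng.standard_normal((z.shape[0], lam.shape[0])) * noise_sd
    scores = score_center + score_scale * raw
    clipped = float(((scores < 0) | (scores > 100)).mean())
    scores = np.clip(scores, 0.0, 100.0)
    cols = [f"m{j:02d}" for j in range(lam.shape[0])]
    return pd.DataFrame(scores, columns=cols), clipped


def gen_severity(
    latents: np.ndarray, spec: SyntheticSpec, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-patient global damage scalar, partially coupled to the latents.

    A standard-normal driver, ``w * (mean deficit) + sqrt(1-w^2) * noise``, is
    squashed through the normal CDF onto ``[severity_min, severity_max]``.
    The bounded range means every patient erodes at least the outer rim of
    the severity belt (every stroke patient has some lesion) and no patient's
    belt damage saturates the intensity scale.  Together with the
    inverse-square belt depth profile this keeps both the belt-voxel
    intensities and the lesioned belt-voxel count linear in severity, so the
    lesion-volume covariate can actually absorb the severity confound the way
    the volume-corrected analysis intends.
    """
    from scipy.stats import norm

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.asarray(latents, float)
    n, k = z.shape
    w = spec.severity_coupling
    driver = w * (-z.mean(axis=1) * np.sqrt(k)) + np.sqrt(1 - w**2) * rng.standard_normal(n)
    return spec.severity_min + (spec.severity_max - spec.severity_min) * norm.cdf(driver)


def gen_lesions(
    latents: np.ndarray,
    severity: np.ndarray,
    spec: SyntheticSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[list[BrainVolume], list[np.ndarray]]:
    """Damaged intensity volumes (smoothed) and binary lesion masks.

    Damage in target region ``f`` is ``effect * max(0, -latent_f)``; damage in
    the severity belt is ``belt_effect * severity``.  The mask thresholds the
    pre-smoothing intensity at ``mask_criterion`` of the template.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.asarray(latents, float)
    template = spec.template()
    brain = template > 0
    # radially tapered damage profiles: deeper at the region core, so the
    # lesioned extent grows continuously with the deficit / severity
    region_profiles = [
        (1.0 - 0.5 * np.clip(r.rho2(spec.shape), 0.0, 1.0)) * r.mask(spec.shape)
        for r in spec.regions
    ]
    belt_profile = spec.belt_profile()
    core_mask = spec.core.mask(spec.shape)
    effects = np.broadcast_to(np.asarray(spec.effect_size, float), (spec.n_factors,))
    affine = spec.affine()
    volumes, masks = [], []
    for i in range(z.shape[0]):
        damage = np.zeros(spec.shape)
        for f, prof in enumerate(region_profiles):
            damage += prof * (effects[f] * max(0.0, -z[i, f]))
        damage += belt_profile * (spec.belt_effect * severity[i])
        damage += core_mask * spec.core_effect  # common infarct core, all patients
        intact = np.clip(template - damage, 0.0, None)
        mask = brain & (intact < spec.mask_criterion * template)
        noisy = intact + rng.standard_normal(spec.shape) * spec.image_noise_sd * brain
        smoothed = smooth(noisy, spec.fwhm_mm, spec.voxel_size)
        volumes.append(BrainVolume(smoothed, affine))
        masks.append(mask)
    return volumes, masks


def default_paper_like_spec() -> SyntheticSpec:
    """The default study conditions: 31 patients, 4 factors, 21 measures,
    a 48 x 56 x 48 lattice of 2 mm voxels with four planted regions."""
    spec = SyntheticSpec()
    spec.validate()
    return spec


def generate_cohort(spec: SyntheticSpec | None = None, seed: int = 0) -> SyntheticCohort:
    """Full deterministic cohort: latents, behaviour, severity, images, masks."""
    spec = spec or default_paper_like_spec()
    spec.validate()
    rng = np.random.default_rng(seed)
    latents = gen_latents(spec.n_patients, spec.n_factors, rng)
    behaviour, clipped = gen_behavior(
        latents, spec.loading_pattern, spec.noise_sd, rng,
        spec.score_center, spec.score_scale,
    )
    behaviour.index = [f"P{i:02d}" for i in range(spec.n_patients)]
    severity = gen_severity(latents, spec, rng)
    volumes, masks = gen_lesions(latents, severity, spec, rng)
    return SyntheticCohort(
        spec=spec,
        latents=latents,
        behaviour=behaviour,
        volumes=volumes,
        masks=masks,
        severity=severity,
        clip_fraction=clipped,
    )
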