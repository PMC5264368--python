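"""Desk-scale validation experiments for the imaging stage.

The published imaging results cannot be recomputed without the original
scans, so the permutation machinery is validated by simulation instead:

* a per-voxel loop oracle for the vectorised GLM;
* the empirical type-I error of cluster-level FWE inference on pure-noise
  cohorts;
* recovery of the planted regions (Dice overlap of each factor's top
  FWE-significant cluster with its ground-truth region) on default synthetic
  cohorts;
* the lesion-volume confound demonstration: the severity belt reads out as a
  spurious factor correlate until lesion volume enters the design.

All experiments are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .factors import fit_pca
from .synthetic import SyntheticSpec, default_paper_like_spec, generate_cohort
from .vbcm import (
    VoxelGLM,
    default_analysis_mask,
    label_clusters,
    permute_fwe,
    smooth,
    threshold,
)


def glm_loop_oracle_max_diff(seed: int = 0, shape=(8, 8, 8), n: int = 14) -> float:
    """Max |t| difference between the vectorised GLM and an explicit
    per-voxel loop with sequential scalar accumulation.  Zero means the two
    are bit-identical."""
    rng = np.random.default_rng(seed)
    p = 3
    X = np.c_[np.ones(n), rng.standard_normal((n, p - 1))]
    Y = rng.standard_normal((n, int(np.prod(shape))))
    glm = VoxelGLM(interest=["x1"]).fit(
        pd.DataFrame(X, columns=["x0", "x1", "x2"]), Y
    )
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    worst = 0.0
    for v in range(Y.shape[1]):
        beta = [sum(pinv[j, i] * Y[i, v] for i in range(n)) for j in range(p)]
        resid = [Y[i, v] - sum(X[i, j] * beta[j] for j in range(p)) for i in range(n)]
        s2 = sum(e * e for e in resid) / (n - p)
        t = beta[1] / np.sqrt(s2 * XtX_inv[1, 1])
        worst = max(worst, abs(glm.t_["x1"][v] - t))
    return worst


def type_i_error(
    n_datasets: int = 200,
    n_perm: int = 200,
    n: int = 31,
    shape: tuple[int, int, int] = (14, 14, 14),
    fwhm_mm: float = 6.0,
    alpha: float = 0.05,
    p_voxel: float = 0.005,
    seed: int = 0,
) -> float:
    """Fraction of pure-noise cohorts with any FWE-significant cluster.

    Volumes are smoothed white noise, independent of the behavioural score,
    so any significant cluster is a false positive; the fraction estimates
    the family-wise error rate of the permutation correction.
    """
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, bool)
    hits = 0
    for _ in range(n_datasets):
        vols = [smooth(rng.standard_normal(shape), fwhm_mm, 2.0) for _ in range(n)]
        design = pd.DataFrame(
            {
                "intercept": np.ones(n),
                "score": rng.standard_normal(n),
                "nuisance": rng.standard_normal(n),
            }
        )
        table = permute_fwe(
            vols, design, "score", mask, p_voxel=p_voxel, n_perm=n_perm, seed=rng
        )
        if len(table) and (table["p_fwe"] < alpha).any():
            hits += 1
    return hits / n_datasets


def _assign_factors_to_regions(scores: np.ndarray, latents: np.ndarray):
    """Pair fitted factors with ground-truth latents by maximal |correlation|."""
    k = scores.shape[1]
    C = np.corrcoef(scores.T, latents.T)[:k, k:]
    return np.abs(C).argmax(axis=1)


def region_recovery(
    n_seeds: int = 20,
    n_perm: int = 200,
    alpha: float = 0.05,
    p_voxel: float = 0.005,
    spec: SyntheticSpec | None = None,
    seed0: int = 0,
    dice_threshold: float = 0.5,
) -> dict:
    """Planted-region recovery with the lesion-volume covariate in the model.

    A seed succeeds when the omnibus decomposition retains the planted factor
    count, the factor-to-region assignment is one-to-one, and every factor's
    top FWE-significant cluster has Dice overlap above threshold with its
    planted region.
    """
    spec = spec or default_paper_like_spec()
    regions = spec.region_masks()
    brain = spec.template() > 0
    successes, per_seed = 0, []
    for s in range(n_seeds):
        seed = seed0 + s
        cohort = generate_cohort(spec, seed)
        model = fit_pca(cohort.behaviour)
        if model.n_components_ != spec.n_factors:
            per_seed.append({"seed": seed, "ok": False, "reason": "retention"})
            continue
        assign = _assign_factors_to_regions(model.scores_, cohort.latents)
        if sorted(assign) != list(range(spec.n_factors)):
            per_seed.append({"seed": seed, "ok": False, "reason": "assignment"})
            continue
        amask = default_analysis_mask(cohort.masks, brain)
        n = spec.n_patients
        design = pd.DataFrame({"intercept": np.ones(n)})
        for j in range(spec.n_factors):
            design[f"F{j + 1}"] = model.scores_[:, j]
        vol = cohort.lesion_volumes.astype(float)
        design["lesion_volume"] = vol - vol.mean()
        dice = []
        rng = np.random.default_rng(seed)
        for j in range(spec.n_factors):
            fac = f"F{j + 1}"
            table = permute_fwe(
                cohort.volumes, design, fac, amask,
                p_voxel=p_voxel, n_perm=n_perm, seed=rng,
            )
            sig = table[table["p_fwe"] < alpha]
            if not len(sig):
                dice.append(0.0)
                continue
            glm = VoxelGLM(interest=[fac]).fit(
                design, np.asarray([v.data[amask] for v in cohort.volumes])
            )
            tmap = glm.t_map(fac, amask)
            supra = threshold(tmap, glm.df_, p_voxel) & amask
            _, labels = label_clusters(supra, 26)
            top = sig.sort_values(["p_fwe", "extent"], ascending=[True, False]).iloc[0]
            cluster = labels == top["label"]
            region = regions[assign[j]]
            dice.append(
                2.0 * (cluster & region).sum() / (cluster.sum() + region.sum())
            )
        ok = all(d > dice_threshold for d in dice)
        successes += ok
        per_seed.append({"seed": seed, "ok": ok, "dice": [round(d, 3) for d in dice]})
    return {"rate": successes / n_seeds, "per_seed": per_seed}


def confound_demonstration(
    n_seeds: int = 6,
    n_perm: int = 200,
    alpha: float = 0.05,
    p_voxel: float = 0.005,
    spec: SyntheticSpec | None = None,
    seed0: int = 0,
) -> dict:
    """Severity-belt false positives with and without the volume covariate.

    A cluster counts as a belt false positive when it is FWE-significant and
    more than half its voxels lie in the severity belt (which carries no
    factor-specific signal, only global severity).  Returns the fraction of
    seeds showing at least one belt false positive under each model.
    """
    spec = spec or default_paper_like_spec()
    belt = spec.belt_mask()
    brain = spec.template() > 0
    hits = {"without_volume": 0, "with_volume": 0}
    for s in range(n_seeds):
        seed = seed0 + s
        cohort = generate_cohort(spec, seed)
        model = fit_pca(cohort.behaviour)
        k = model.n_components_
        amask = default_analysis_mask(cohort.masks, brain)
        n = spec.n_patients
        vol = cohort.lesion_volumes.astype(float)
        for variant in hits:
            design = pd.DataFrame({"intercept": np.ones(n)})
            for j in range(k):
                design[f"F{j + 1}"] = model.scores_[:, j]
            if variant == "with_volume":
                design["lesion_volume"] = vol - vol.mean()
            rng = np.random.default_rng(seed)
            found = False
            for j in range(k):
                fac = f"F{j + 1}"
                table = permute_fwe(
                    cohort.volumes, design, fac, amask,
                    p_voxel=p_voxel, n_perm=n_perm, seed=rng,
                )
                sig = table[table["p_fwe"] < alpha]
                if not len(sig):
                    continue
                glm = VoxelGLM(interest=[fac]).fit(
                    design, np.asarray([v.data[amask] for v in cohort.volumes])
                )
                supra = threshold(glm.t_map(fac, amask), glm.df_, p_voxel) & amask
                _, labels = label_clusters(supra, 26)
                for _, row in sig.iterrows():
                    cluster = labels == row["label"]
                    if (cluster & belt).sum() / cluster.sum() > 0.5:
                        found = True
            hits[variant] += found
    return {
        "without_volume_rate": hits["without_volume"] / n_seeds,
        "with_volume_rate": hits["with_volume"] / n_seeds,
        "n_seeds": n_seeds,
    }
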