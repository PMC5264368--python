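"""Voxel-based correlational methodology (VBCM).

Mass-univariate lesion-symptom mapping on continuous tissue intensity: at
every voxel inside an analysis mask, ordinary least squares regresses smoothed
image intensity on a design matrix containing the behavioural regressors of
interest (factor scores) plus nuisance covariates (intercept, optionally
mean-centred lesion volume), and a t statistic is formed for each interest
regressor.  Unlike classical lesion-symptom mapping this needs no binary
lesion/spared classification — both behaviour and tissue signal are treated as
continuous.

Voxel-level inference thresholds the t map (one-tailed by default: higher
intensity with better scores); cluster-level family-wise error is controlled
by a Freedman-Lane max-cluster-extent permutation scheme: the data are
residualised on the nuisance regressors, residual rows are permuted, the model
is refit and the largest suprathreshold cluster extent is recorded per
permutation.  The corrected p value of an observed cluster of extent ``e`` is
``(1 + #{max extents >= e}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class BrainVolume:
    """A 3-D intensity lattice with its voxel->world affine."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img_or_path) -> "BrainVolume":
        img = (
            img_or_path
            if isinstance(img_or_path, nib.spatialimages.SpatialImage)
            else nib.load(str(img_or_path))
        )
        return cls(np.asarray(img.get_fdata(), float), np.asarray(img.affine, float))


def smooth(data: np.ndarray, fwhm_mm: float, voxel_size) -> np.ndarray:
    """Separable Gaussian smoothing with a FWHM given in millimetres.

    ``fwhm_mm = 0`` is the identity.  Reflecting boundaries keep total
    intensity conserved up to floating point.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(data, float).copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    sigma = fwhm_mm / (voxel_size * _FWHM_TO_SIGMA)
    return ndimage.gaussian_filter(np.asarray(data, float), sigma=sigma, mode="reflect")


def lesion_volume(mask: np.ndarray) -> int:
    """Number of lesioned voxels in a binary mask."""
    return int(np.asarray(mask, bool).sum())


def overlap_map(masks) -> np.ndarray:
    """Voxelwise count of patients lesioned at each location."""
    masks = [np.asarray(m, bool) for m in masks]
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for i, m in enumerate(masks):
        if m.shape != shape:
            raise ValueError(f"mask {i} geometry {m.shape} != {shape}")
    return np.sum(masks, axis=0).astype(int)


# ---------------------------------------------------------------------------
# GLM

def _stack(volumes, mask: np.ndarray) -> np.ndarray:
    """n aligned volumes -> (n, v) matrix of in-mask intensities."""
    mask = np.asarray(mask, bool)
    rows = []
    for vol in volumes:
        arr = vol.data if isinstance(vol, BrainVolume) else np.asarray(vol, float)
        if arr.shape != mask.shape:
            raise ValueError(f"volume shape {arr.shape} != mask shape {mask.shape}")
        rows.append(arr[mask])
    return np.asarray(rows, float)


class VoxelGLM(BaseEstimator):
    """Mass-univariate OLS of voxel intensity on a behavioural design.

    ``fit(X, Y)`` takes the n x p design matrix ``X`` (DataFrame columns name
    the regressors) and the n x v in-mask intensity matrix ``Y``.  Per voxel,
    ``beta = pinv(X) y`` and for each requested regressor ``j``,
    ``t_j = beta_j / se(beta_j)`` with ``df = n - p``.

    Attributes
    ----------
    coef_ : (p, v) OLS coefficients.
    t_ : dict regressor name -> length-v t statistics.
    df_ : residual degrees of freedom.
    sigma2_ : length-v residual variance estimates.
    """

    def __init__(self, interest: list[str] | None = None):
        self.interest = interest

    def fit(self, X, Y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, float)
            names = [f"x{j}" for j in range(X.shape[1])]
        Y = np.asarray(Y, float)
        n, p = X.shape
        if Y.shape[0] != n:
            raise ValueError("design rows do not match number of volumes")
        if n <= p:
            raise ValueError(f"need n > p regressors (n={n}, p={p})")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # report which columns are linearly dependent on the others
            dependent = []
            for j in range(p):
                others = np.delete(X, j, axis=1)
                if np.linalg.matrix_rank(others) == rank:
                    dependent.append(names[j])
            raise ValueError(f"rank-deficient design; collinear columns: {dependent}")
        self.regressor_names_ = names
        XtX_inv = np.linalg.inv(X.T @ X)
        pinv = XtX_inv @ X.T
        # unoptimised einsum keeps a fixed sequential accumulation order, so
        # the vectorised fit is bit-for-bit the same as a per-voxel loop
        beta = np.einsum("ji,iv->jv", pinv, Y)
        resid = Y - np.einsum("ij,jv->iv", X, beta)
        self.df_ = n - p
        self.sigma2_ = np.einsum("iv,iv->v", resid, resid) / self.df_
        self.coef_ = beta
        which = self.interest if self.interest is not None else names
        constant = np.ptp(Y, axis=0) == 0  # no between-patient signal at all
        self.t_ = {}
        for name in which:
            j = names.index(name)
            se = np.sqrt(self.sigma2_ * XtX_inv[j, j])
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, beta[j] / se, 0.0)
            t[constant] = 0.0
            self.t_[name] = t
        return self

    def t_map(self, name: str, mask: np.ndarray) -> np.ndarray:
        """Unflatten one regressor's t vector into the 3-D analysis mask."""
        check_is_fitted(self, "t_")
        out = np.zeros(np.asarray(mask, bool).shape, float)
        out[np.asarray(mask, bool)] = self.t_[name]
        return out


@dataclass
class StatMap:
    """Per-regressor t maps over a common analysis mask."""

    t: dict[str, np.ndarray]  # 3-D lattices
    df: int
    mask: np.ndarray
    affine: np.ndarray


def fit_glm(volumes, design: pd.DataFrame, analysis_mask: np.ndarray,
            interest: list[str] | None = None) -> StatMap:
    """Fit the voxelwise GLM over an analysis mask and return 3-D t maps."""
    mask = np.asarray(analysis_mask, bool)
    Y = _stack(volumes, mask)
    glm = VoxelGLM(interest=interest).fit(design, Y)
    affine = (
        volumes[0].affine if isinstance(volumes[0], BrainVolume) else np.eye(4)
    )
    tmaps = {name: glm.t_map(name, mask) for name in glm.t_}
    return StatMap(t=tmaps, df=glm.df_, mask=mask, affine=np.asarray(affine, float))


# ---------------------------------------------------------------------------
# thresholding and clusters

def t_critical(p_voxel: float, df: int, tail: str = "one") -> float:
    if tail == "one":
        return float(stats.t.isf(p_voxel, df))
    if tail == "two":
        return float(stats.t.isf(p_voxel / 2.0, df))
    raise ValueError("tail must be 'one' or 'two'")


def threshold(tmap: np.ndarray, df: int, p_voxel: float, tail: str = "one") -> np.ndarray:
    """Suprathreshold mask at voxelwise p < p_voxel (strict inequality)."""
    crit = t_critical(p_voxel, df, tail)
    t = np.asarray(tmap, float)
    return (np.abs(t) > crit) if tail == "two" else (t > crit)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_clusters(
    mask: np.ndarray,
    connectivity: int = 26,
    tmap: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> pd.DataFrame:
    """Connected components of a suprathreshold mask.

    Returns ``(table, labels)``: a table with one row per cluster — label,
    extent (voxels), the peak voxel (the in-cluster maximum of ``|t|`` when a
    t map is supplied, else the first voxel) in world (mm) coordinates, and
    the peak t value, ordered by descending extent — plus the integer label
    image itself.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = np.asarray(mask, bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    rows = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if tmap is not None:
            tvals = np.asarray(tmap, float)[tuple(idx.T)]
            peak_i = int(np.abs(tvals).argmax())
            peak_t = float(tvals[peak_i])
        else:
            peak_i, peak_t = 0, np.nan
        peak_vox = idx[peak_i]
        if affine is not None:
            peak_mm = (np.asarray(affine) @ np.r_[peak_vox, 1.0])[:3]
        else:
            peak_mm = peak_vox.astype(float)
        rows.append(
            {
                "label": lab,
                "extent": int(len(idx)),
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "peak_t": peak_t,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["label", "extent", "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t"],
    )
    if len(table):
        table = table.sort_values("extent", ascending=False, ignore_index=True)
    return table, labels


# ---------------------------------------------------------------------------
# permutation FWE

def _max_extent(mask3d: np.ndarray, structure) -> int:
    labels, n = ndimage.label(mask3d, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def permute_fwe(
    volumes,
    design: pd.DataFrame,
    interest_regressor: str,
    analysis_mask: np.ndarray,
    p_voxel: float = 0.005,
    connectivity: int = 26,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    tail: str = "one",
) -> pd.DataFrame:
    """Cluster table with Freedman-Lane max-extent FWE-corrected p values.

    The corrected p of an observed cluster honours the permutation floor
    ``1 / (1 + n_perm)`` and is monotone non-increasing in cluster extent.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if interest_regressor not in list(design.columns):
        raise ValueError(f"{interest_regressor!r} not a design column")
    mask = np.asarray(analysis_mask, bool)
    Y = _stack(volumes, mask)
    affine = volumes[0].affine if isinstance(volumes[0], BrainVolume) else None
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    structure = _STRUCTURES[connectivity]

    glm = VoxelGLM(interest=[interest_regressor]).fit(design, Y)
    df = glm.df_
    tmap = glm.t_map(interest_regressor, mask)
    supra = threshold(tmap, df, p_voxel, tail) & mask
    table, labels = label_clusters(supra, connectivity, tmap=tmap, affine=affine)

    # Freedman-Lane: residualise on the nuisance-only model, permute rows of
    # the residuals, add the nuisance fit back, refit the full model.
    X = design.to_numpy(float)
    j = list(design.columns).index(interest_regressor)
    Z = np.delete(X, j, axis=1)
    Zpinv = np.linalg.pinv(Z)
    fit_nuis = Z @ (Zpinv @ Y)
    resid = Y - fit_nuis
    n = Y.shape[0]
    crit = t_critical(p_voxel, df, tail)

    XtX_inv = np.linalg.inv(X.T @ X)
    pinvX = XtX_inv @ X.T
    cjj = XtX_inv[j, j]
    max_extents = np.empty(n_perm, int)
    blank = np.zeros(mask.shape, bool)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yb = fit_nuis + resid[perm]
        beta = pinvX @ Yb
        rb = Yb - X @ beta
        sigma2 = (rb**2).sum(axis=0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = np.where(sigma2 > 0, beta[j] / np.sqrt(sigma2 * cjj), 0.0)
        supra_b = np.abs(tb) > crit if tail == "two" else tb > crit
        blank[mask] = supra_b
        max_extents[b] = _max_extent(blank, structure)
        blank[mask] = False

    corrected = [
        (1.0 + int((max_extents >= e).sum())) / (1.0 + n_perm)
        for e in table["extent"]
    ]
    table = table.copy()
    table["p_fwe"] = corrected
    return table


@dataclass
class VBCMConfig:
    """Settings for a full VBCM run."""

    p_voxel: float = 0.005
    fwe_alpha: float = 0.05
    connectivity: int = 26
    n_perm: int = 1000
    seed: int = 0
    tail: str = "one"
    fwhm_mm: float = 8.0
    min_lesioned: int = 1  # analysis mask: voxels lesioned in >= this many patients
    center_volume_covariate: bool = True
    extra: dict = field(default_factory=dict)


def default_analysis_mask(masks, brain_mask: np.ndarray, min_lesioned: int = 1) -> np.ndarray:
    """Voxels lesioned in at least ``min_lesioned`` patients, within brain."""
    counts = overlap_map(masks)
    return (counts >= min_lesioned) & np.asarray(brain_mask, bool)


def vbcm_analysis(
    volumes,
    factor_scores: pd.DataFrame,
    lesion_volumes,
    analysis_mask: np.ndarray,
    config: VBCMConfig | None = None,
    include_volume_covariate: bool | None = None,
) -> dict:
    """Simultaneous VBCM of all factor scores, with and without the
    lesion-volume covariate, plus a volume-vs-intensity map.

    Returns a dict with keys ``"with_volume"`` and ``"without_volume"``, each
    mapping factor name -> (StatMap t lattice embedded dict, cluster table),
    and ``"volume_map"``: the t map of the (centred) lesion-volume regressor
    alone.  ``include_volume_covariate`` restricts the run to one variant.
    """
    config = config or VBCMConfig()
    factor_scores = pd.DataFrame(factor_scores)
    n = len(factor_scores)
    lesion_volumes = np.asarray(lesion_volumes, float)
    if lesion_volumes.shape[0] != n:
        raise ValueError("lesion_volumes length does not match factor scores")
    vol = lesion_volumes - lesion_volumes.mean() if config.center_volume_covariate else lesion_volumes

    variants = (
        {True: None, False: None}
        if include_volume_covariate is None
        else {include_volume_covariate: None}
    )
    rng = np.random.default_rng(config.seed)
    results: dict = {}
    for with_vol in variants:
        design = pd.DataFrame({"intercept": np.ones(n)}, index=factor_scores.index)
        for c in factor_scores.columns:
            design[c] = factor_scores[c].to_numpy(float)
        if with_vol:
            design["lesion_volume"] = vol
        per_factor = {}
        if len(factor_scores.columns) > 0:
            statmap = fit_glm(volumes, design, analysis_mask,
                              interest=list(factor_scores.columns))
            for c in factor_scores.columns:
                table = permute_fwe(
                    volumes,
                    design,
                    c,
                    analysis_mask,
                    p_voxel=config.p_voxel,
                    connectivity=config.connectivity,
                    n_perm=config.n_perm,
                    seed=rng,
                    tail=config.tail,
                )
                per_factor[c] = {"t": statmap.t[c], "df": statmap.df, "clusters": table}
        results["with_volume" if with_vol else "without_volume"] = per_factor

    # severity map: intensity regressed on lesion volume alone
    vol_design = pd.DataFrame({"intercept": np.ones(n), "lesion_volume": vol})
    vol_map = fit_glm(volumes, vol_design, analysis_mask, interest=["lesion_volume"])
    results["volume_map"] = {"t": vol_map.t["lesion_volume"], "df": vol_map.df}
    return results


def write_cluster_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), affine), str(path))
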