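"""Voxelwise GLM, smoothing, clustering and permutation inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcavbcm.vbcm import (
    BrainVolume,
    VoxelGLM,
    fit_glm,
    label_clusters,
    lesion_volume,
    overlap_map,
    permute_fwe,
    smooth,
    t_critical,
    threshold,
)


class TestSmooth:
    def test_constant_volume_unchanged(self):
        vol = np.full((10, 10, 10), 3.5)
        np.testing.assert_allclose(smooth(vol, 8.0, 2.0), vol, atol=1e-10)

    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        np.testing.assert_array_equal(smooth(vol, 0.0, 2.0), vol)

    def test_mass_conserved_under_reflect_boundary(self, rng):
        vol = rng.uniform(size=(12, 12, 12))
        out = smooth(vol, 8.0, 2.0)
        assert out.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_impulse_response_fwhm(self):
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        out = smooth(vol, 8.0, 2.0)  # 2 mm voxels -> sigma = 1.699 voxels
        profile = out[:, 20, 20]
        half = profile.max() / 2
        above = np.flatnonzero(profile >= half)
        # linear interpolation at the half-maximum crossings, in mm
        lo, hi = above[0], above[-1]
        f = lambda i, j: i + (half - profile[i]) / (profile[j] - profile[i])
        width_vox = f(hi, hi + 1) - f(lo, lo - 1)
        assert width_vox * 2.0 == pytest.approx(8.0, abs=0.1)

    def test_linear_and_shift_equivariant_interior(self, rng):
        a = rng.normal(size=(16, 16, 16))
        b = rng.normal(size=(16, 16, 16))
        lin = smooth(a + 2 * b, 6.0, 2.0)
        np.testing.assert_allclose(
            lin, smooth(a, 6.0, 2.0) + 2 * smooth(b, 6.0, 2.0), atol=1e-12
        )
        # interior = further from the rolled axis' boundary than the kernel radius
        shifted = np.roll(a, 1, axis=0)
        np.testing.assert_allclose(
            smooth(shifted, 6.0, 2.0)[7:-7], np.roll(smooth(a, 6.0, 2.0), 1, axis=0)[7:-7],
            atol=1e-9,
        )


class TestMaskUtilities:
    def test_lesion_volume_counts(self):
        assert lesion_volume(np.zeros((5, 5, 5), bool)) == 0
        block = np.zeros((12, 12, 12), bool)
        block[:10, :10, :10] = True
        assert lesion_volume(block) == 1000

    def test_overlap_map_sums_and_bounds(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = True
        out = overlap_map([m, m])
        assert out.max() == 2 and out.sum() == 2
        other = np.zeros((4, 4, 4), bool)
        other[1, 1, 1] = True
        assert overlap_map([m, other]).max() == 1

    def test_overlap_geometry_mismatch(self):
        with pytest.raises(ValueError, match="geometry"):
            overlap_map([np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool)])


class TestVoxelGLM:
    def test_constant_intensities_give_zero_t(self):
        n = 10
        Y = np.ones((n, 27))
        X = pd.DataFrame({"intercept": np.ones(n), "s": np.arange(n, dtype=float)})
        glm = VoxelGLM(interest=["s"]).fit(X, Y)
        np.testing.assert_array_equal(glm.t_["s"], np.zeros(27))

    def test_matches_closed_form_simple_regression(self):
        # tiny printed problem: n=5, one regressor + intercept
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.9, 3.4, 3.1, 4.6])
        X = pd.DataFrame({"intercept": np.ones(5), "x": x})
        glm = VoxelGLM(interest=["x"]).fit(X, y[:, None])
        r = stats.linregress(x, y)
        slope_t = r.slope / r.stderr
        assert glm.t_["x"][0] == pytest.approx(slope_t, rel=1e-10)
        assert glm.df_ == 3

    def test_orthogonal_regressor_leaves_coefficients(self, rng):
        """Frisch-Waugh: adding an orthogonal regressor leaves the first
        coefficient untouched; the t only changes through df and residuals."""
        n, v = 20, 50
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        x1 -= x1.mean()
        x2 -= x2.mean()
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # exactly orthogonal to x1 and 1
        Y = rng.standard_normal((n, v))
        small = VoxelGLM(interest=["x1"]).fit(
            pd.DataFrame({"i": np.ones(n), "x1": x1}), Y
        )
        big = VoxelGLM(interest=["x1"]).fit(
            pd.DataFrame({"i": np.ones(n), "x1": x1, "x2": x2}), Y
        )
        i1 = small.regressor_names_.index("x1")
        np.testing.assert_allclose(small.coef_[1], big.coef_[1], atol=1e-10)
        assert big.df_ == small.df_ - 1

    def test_rank_deficient_design_names_columns(self):
        n = 8
        x = np.arange(n, dtype=float)
        X = pd.DataFrame({"intercept": np.ones(n), "a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            VoxelGLM().fit(X, np.ones((n, 3)))

    def test_vectorised_fit_bit_identical_to_voxel_loop(self, rng):
        n, p = 14, 3
        X = np.c_[np.ones(n), rng.standard_normal((n, p - 1))]
        Y = rng.standard_normal((n, 8**3))
        glm = VoxelGLM(interest=["x1"]).fit(
            pd.DataFrame(X, columns=["x0", "x1", "x2"]), Y
        )
        XtX_inv = np.linalg.inv(X.T @ X)
        pinv = XtX_inv @ X.T
        t_loop = np.empty(Y.shape[1])
        for vx in range(Y.shape[1]):
            beta = np.array(
                [sum(pinv[j, i] * Y[i, vx] for i in range(n)) for j in range(p)]
            )
            resid = np.array(
                [Y[i, vx] - sum(X[i, j] * beta[j] for j in range(p)) for i in range(n)]
            )
            s2 = sum(e * e for e in resid) / (n - p)
            t_loop[vx] = beta[1] / np.sqrt(s2 * XtX_inv[1, 1])
        np.testing.assert_array_equal(glm.t_["x1"], t_loop)


class TestThreshold:
    def test_p_one_keeps_everything(self):
        t = np.zeros((3, 3, 3))
        assert threshold(t, df=10, p_voxel=1.0).all()

    def test_zero_map_empty_at_standard_threshold(self):
        assert not threshold(np.zeros((3, 3, 3)), df=27, p_voxel=0.005).any()

    def test_strict_inequality_at_critical_value(self):
        crit = t_critical(0.005, 27)
        assert crit == pytest.approx(stats.t.isf(0.005, 27))
        tmap = np.full((2, 2, 2), crit)
        assert not threshold(tmap, 27, 0.005).any()
        assert threshold(tmap + 1e-9, 27, 0.005).all()

    def test_two_tailed_uses_magnitude(self):
        tmap = np.array([[[-5.0, 5.0]]])
        one = threshold(tmap, 20, 0.005, tail="one")
        two = threshold(tmap, 20, 0.005, tail="two")
        assert one.tolist() == [[[False, True]]]
        assert two.all()


def flood_fill_labels(mask, connectivity):
    """Independent BFS flood-fill component labelling."""
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
        and {6: abs(i) + abs(j) + abs(k) == 1,
             18: abs(i) + abs(j) + abs(k) <= 2,
             26: True}[connectivity]
    ]
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for idx in np.argwhere(mask):
        if labels[tuple(idx)]:
            continue
        nxt += 1
        queue = [tuple(idx)]
        labels[tuple(idx)] = nxt
        while queue:
            c = queue.pop()
            for off in offsets:
                nb = tuple(np.add(c, off))
                if all(0 <= nb[d] < mask.shape[d] for d in range(3)):
                    if mask[nb] and not labels[nb]:
                        labels[nb] = nxt
                        queue.append(nb)
    return labels


class TestClusters:
    def test_corner_touching_blocks_by_connectivity(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[0:2, 0:2, 0:2] = True
        mask[2:4, 2:4, 2:4] = True  # touches only at a corner
        t26, _ = label_clusters(mask, connectivity=26)
        t6, _ = label_clusters(mask, connectivity=6)
        assert len(t26) == 1 and len(t6) == 2

    def test_single_voxel_cluster(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 2, 3] = True
        table, _ = label_clusters(mask, tmap=np.ones(mask.shape), affine=np.eye(4))
        assert len(table) == 1
        assert table.loc[0, "extent"] == 1
        assert tuple(table.loc[0, ["peak_x_mm", "peak_y_mm", "peak_z_mm"]]) == (1, 2, 3)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        mask = rng.random((20, 20, 20)) < 0.25
        table, labels = label_clusters(mask, connectivity)
        oracle = flood_fill_labels(mask, connectivity)
        # same partition: label images agree up to relabelling
        assert labels.astype(bool).sum() == oracle.astype(bool).sum()
        pairs = {(a, b) for a, b in zip(labels[mask], oracle[mask])}
        assert len(pairs) == len({a for a, _ in pairs}) == len({b for _, b in pairs})
        assert sorted(table["extent"]) == sorted(
            np.bincount(oracle.ravel())[1:][np.bincount(oracle.ravel())[1:] > 0]
        )

    def test_peak_uses_world_coordinates(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 3, 4] = True
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-4, -4, -4]
        table, _ = label_clusters(mask, tmap=np.ones(mask.shape), affine=affine)
        assert tuple(table.loc[0, ["peak_x_mm", "peak_y_mm", "peak_z_mm"]]) == (0, 2, 4)


def _noise_volumes(rng, n, shape=(10, 10, 10)):
    return [smooth(rng.standard_normal(shape), 4.0, 2.0) for _ in range(n)]


class TestPermutationFWE:
    def test_planted_effect_hits_p_floor(self, rng):
        n, shape = 20, (10, 10, 10)
        score = rng.standard_normal(n)
        vols = []
        for i in range(n):
            v = smooth(rng.standard_normal(shape), 4.0, 2.0) * 0.05
            v[2:6, 2:6, 2:6] += score[i]  # overwhelming effect
            vols.append(v)
        design = pd.DataFrame({"intercept": np.ones(n), "score": score})
        table = permute_fwe(
            vols, design, "score", np.ones(shape, bool), n_perm=100, seed=1
        )
        assert table.loc[0, "p_fwe"] == pytest.approx(1 / 101)

    def test_corrected_p_monotone_in_extent(self, rng):
        n = 16
        vols = _noise_volumes(rng, n)
        design = pd.DataFrame(
            {"intercept": np.ones(n), "score": rng.standard_normal(n)}
        )
        table = permute_fwe(
            vols, design, "score", np.ones((10, 10, 10), bool),
            p_voxel=0.2, n_perm=100, seed=3,
        )
        if len(table) > 1:
            ordered = table.sort_values("extent", ascending=False)
            assert ordered["p_fwe"].is_monotonic_increasing

    def test_seed_reproducible(self, rng):
        n = 12
        vols = _noise_volumes(rng, n)
        design = pd.DataFrame(
            {"intercept": np.ones(n), "score": np.arange(n, dtype=float)}
        )
        kw = dict(p_voxel=0.05, n_perm=100, seed=42)
        a = permute_fwe(vols, design, "score", np.ones((10, 10, 10), bool), **kw)
        b = permute_fwe(vols, design, "score", np.ones((10, 10, 10), bool), **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_regressor_and_small_nperm_fail(self, rng):
        vols = _noise_volumes(rng, 8)
        design = pd.DataFrame({"intercept": np.ones(8), "s": np.arange(8.0)})
        with pytest.raises(ValueError, match="not a design column"):
            permute_fwe(vols, design, "zz", np.ones((10, 10, 10), bool))
        with pytest.raises(ValueError, match="n_perm"):
            permute_fwe(vols, design, "s", np.ones((10, 10, 10), bool), n_perm=10)


class TestFitGlmVolumes:
    def test_brainvolume_roundtrip_and_affine(self, tmp_path, rng):
        data = rng.normal(size=(6, 7, 8))
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        vol = BrainVolume(data, affine)
        assert vol.voxel_size == pytest.approx([2, 2, 2])
        path = tmp_path / "v.nii"
        import nibabel as nib

        nib.save(vol.to_nifti(), str(path))
        again = BrainVolume.from_nifti(path)
        np.testing.assert_allclose(again.data, data, atol=1e-6)

    def test_fit_glm_statmap_shape(self, rng):
        n, shape = 12, (6, 6, 6)
        vols = [BrainVolume(rng.normal(size=shape), np.eye(4)) for _ in range(n)]
        design = pd.DataFrame(
            {"intercept": np.ones(n), "s": rng.standard_normal(n)}
        )
        mask = np.zeros(shape, bool)
        mask[1:5, 1:5, 1:5] = True
        sm = fit_glm(vols, design, mask, interest=["s"])
        assert sm.t["s"].shape == shape
        assert (sm.t["s"][~mask] == 0).all()
        assert sm.df == n - 2
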