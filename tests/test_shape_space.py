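"""Tangent PCA, dimensionality selection, mean shapes, and TPS warps."""

import numpy as np
import pytest
from dataclasses import replace

import molarmorph as mm
from molarmorph.errors import DegenerateConfigurationError
from molarmorph.shape_space import (
    DistanceCorrelationProfile,
    distance_correlation_profile,
    group_mean_shapes,
    mean_shape_pca,
    select_dimensionality,
    tps_warp,
)


class TestShapePca:
    def test_rank_and_variance_conservation(self, medium_fit):
        _, fit = medium_fit
        space = mm.shape_pca(fit)
        assert space.n_nonzero == 47
        Xc = fit.tangent_coords - fit.tangent_coords.mean(axis=0)
        total_var = np.sum(Xc**2) / (len(Xc) - 1)
        assert space.eigenvalues.sum() == pytest.approx(total_var, rel=1e-10)
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)
        assert space.percent_variance.sum() == pytest.approx(100.0, abs=0.01)
        assert np.abs(space.scores.mean(axis=0)).max() < 1e-9

    def test_reconstruction_from_all_components(self, small_fit):
        space = mm.shape_pca(small_fit)
        recon = space.scores @ space.eigenvectors + space.mean
        assert np.abs(recon - small_fit.tangent_coords).max() < 1e-9

    def test_single_direction_variation_aligns_pc1(self, template):
        rng = np.random.default_rng(8)
        base = template.coords.ravel()
        direction = rng.standard_normal(54)
        direction /= np.linalg.norm(direction)
        X = base + np.outer(rng.normal(0, 2.0, 40), direction)
        space = mm.shape_pca(X)
        assert abs(space.eigenvectors[0] @ direction) > 0.99
        assert space.eigenvalues[0] / space.eigenvalues.sum() > 0.999

    def test_all_pc_distances_equal_tangent_distances(self, small_fit):
        from scipy.spatial.distance import pdist

        space = mm.shape_pca(small_fit)
        assert np.allclose(
            pdist(space.scores), pdist(small_fit.tangent_coords), rtol=1e-9
        )

    def test_too_few_specimens_rejected(self):
        with pytest.raises(ValueError):
            mm.shape_pca(np.zeros((2, 12)))


class TestDistanceCorrelation:
    def test_full_dimension_correlation_is_one(self, small_fit):
        space = mm.shape_pca(small_fit)
        prof = distance_correlation_profile(small_fit, space)
        assert prof.r_values[-1] == pytest.approx(1.0, abs=1e-5)
        assert np.all(prof.r_values >= -1.0) and np.all(prof.r_values <= 1.0 + 1e-12)

    def test_profile_matches_brute_force_recomputation(self, small_fit):
        """Independent oracle: per-m full recomputation of both distance
        vectors and the correlation."""
        space = mm.shape_pca(small_fit)
        prof = distance_correlation_profile(small_fit, space)
        n = small_fit.n_specimens
        ref = []
        for i in range(n):
            for j in range(i + 1, n):
                ref.append(
                    mm.procrustes_distance(small_fit.aligned[i], small_fit.aligned[j])
                )
        ref = np.array(ref)
        for m in (1, 5, space.n_components):
            eu = []
            for i in range(n):
                for j in range(i + 1, n):
                    eu.append(np.linalg.norm(space.scores[i, :m] - space.scores[j, :m]))
            r = np.corrcoef(np.array(eu), ref)[0, 1]
            assert prof.r(m) == pytest.approx(r, abs=1e-12)

    def test_selection_threshold_first(self):
        r = np.concatenate([np.linspace(0.3, 0.97, 19), [0.985], np.linspace(0.986, 1.0, 27)])
        prof = DistanceCorrelationProfile(r)
        m_star, plateau = select_dimensionality(prof)
        assert m_star == 20
        assert plateau >= 1

    def test_selection_trivial_cases(self):
        prof = DistanceCorrelationProfile(np.array([0.99, 0.995, 1.0]))
        assert select_dimensionality(prof)[0] == 1
        assert select_dimensionality(prof, threshold=1.0)[0] == 3
        with pytest.raises(ValueError):
            select_dimensionality(DistanceCorrelationProfile(np.array([0.5, 0.9])), 0.95)


class TestGroupMeans:
    def test_single_and_duplicate_specimen_groups(self, small_fit):
        labels = np.array(
            ["a"] + ["b"] * (small_fit.n_specimens - 1)
        )
        means = group_mean_shapes(small_fit, labels)
        assert np.allclose(means["a"], small_fit.aligned[0])
        dup = np.stack([small_fit.aligned[0], small_fit.aligned[0]])
        from molarmorph.procrustes import ProcrustesFit

        f2 = ProcrustesFit(dup, small_fit.consensus, np.ones(2), np.empty((2, 0)), 1, True)
        m2 = group_mean_shapes(f2, np.array(["x", "x"]))
        assert np.allclose(m2["x"], small_fit.aligned[0])

    def test_empty_group_rejected(self, small_fit):
        labels = np.array(["a"] * small_fit.n_specimens)
        with pytest.raises(ValueError):
            group_mean_shapes(small_fit, labels, groups=["a", "ghost"])

    def test_mean_shape_pca_rank(self, medium_fit):
        ds, fit = medium_fit
        means = group_mean_shapes(fit, ds.labels("group"))
        space = mean_shape_pca(means)
        assert space.n_nonzero <= 3

    def test_collinear_means_have_one_component(self, template):
        base = template.coords.ravel()
        v = np.ones(54) / np.sqrt(54)
        means = {f"g{i}": (base + i * v).reshape(18, 3) for i in range(4)}
        space = mean_shape_pca(means)
        assert space.n_nonzero == 1
        with pytest.raises(ValueError):
            mean_shape_pca({"a": means["g0"], "b": means["g1"]})


class TestTpsWarp:
    def test_identity_warp(self, template):
        w = tps_warp(template.coords, template.coords)
        assert w.bending_energy == pytest.approx(0.0, abs=1e-12)
        assert np.abs(w.weights).max() < 1e-10
        grid = w.grid["xy"]
        assert np.allclose(grid["warped"], grid["points"], atol=1e-8)

    def test_affine_target_recovered_without_bending(self, template):
        A = np.array([[1.2, 0.1, 0.0], [0.0, 0.9, 0.1], [0.05, 0.0, 1.1]])
        b = np.array([2.0, -1.0, 0.5])
        w = tps_warp(template.coords, template.coords @ A.T + b)
        assert np.abs(w.weights).max() < 1e-9
        assert w.bending_energy == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(w.affine[:, 0], b, atol=1e-8)
        assert np.allclose(w.affine[:, 1:], A, atol=1e-8)

    def test_landmark_interpolation_exact_on_random_pairs(self, template):
        rng = np.random.default_rng(31)
        for _ in range(5):
            target = template.coords + rng.normal(0, 0.8, template.coords.shape)
            w = tps_warp(template.coords, target)
            assert np.abs(w.transform(template.coords) - target).max() < 1e-8
            assert w.bending_energy >= 0

    def test_off_landmark_points_match_linear_system_oracle(self, template):
        """Independent oracle: assemble and solve the interpolation system
        with scipy and evaluate the warp by hand."""
        from scipy.linalg import solve as sp_solve

        rng = np.random.default_rng(32)
        target = template.coords + rng.normal(0, 0.5, template.coords.shape)
        w = tps_warp(template.coords, target)
        P = template.coords
        k = len(P)
        K = np.linalg.norm(P[:, None] - P[None, :], axis=2)
        Pm = np.column_stack([np.ones(k), P])
        L = np.block([[K, Pm], [Pm.T, np.zeros((4, 4))]])
        sol = sp_solve(L, np.vstack([target, np.zeros((4, 3))]))
        query = rng.normal(0, 5, (10, 3)) + P.mean(axis=0)
        U = np.linalg.norm(query[:, None] - P[None], axis=2)
        expected = U @ sol[:k] + np.column_stack([np.ones(10), query]) @ sol[k:]
        assert np.allclose(w.transform(query), expected, atol=1e-8)

    def test_coplanar_reference_rejected(self):
        flat = np.column_stack([np.random.default_rng(1).normal(size=(10, 2)), np.zeros(10)])
        with pytest.raises(DegenerateConfigurationError):
            tps_warp(flat, flat + 0.1)


def test_group_offset_recovery_in_simulation():
    """Designed mean-shape offsets are recovered by GPA + group means.

    Allometry is disabled and group mean sizes equalized so the designed
    offset is the only systematic mean-shape difference."""
    spec = mm.default_study_spec(seed=77)
    spec = replace(
        spec,
        cell_sizes={(g, s): 100 for g in ("control", "mild", "moderate", "severe")
                    for s in ("F", "M")},
        allometry_vector=None,
        group_size_means={g: 18.0 for g in ("control", "mild", "moderate", "severe")},
    )
    ds = mm.generate_study(spec, seed=77)
    fit = mm.gpa(ds)
    means = group_mean_shapes(fit, ds.labels("group"))
    designed = {"mild": 0.035, "moderate": 0.045, "severe": 0.055}
    for g, d0 in designed.items():
        d = mm.procrustes_distance(means["control"], means[g])
        assert abs(d - d0) / d0 < 0.10
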