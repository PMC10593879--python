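"""Planted-truth generators: determinism, marginals, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import polycortex as px
from polycortex.synthetic import SpecError, default_gradients


class TestCohort:
    def test_same_seed_identical(self):
        spec = px.CohortSpec(n_subjects=40)
        a = px.simulate_cohort(spec, seed=3)
        b = px.simulate_cohort(spec, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_marginals(self):
        df = px.simulate_cohort(px.CohortSpec(n_subjects=390,
                                              age_range=(3, 21)), seed=0)
        assert df["age"].between(3, 21).all()
        assert set(df["sex"]) <= {"F", "M"}
        assert df.filter(regex=r"^pc\d+$").shape[1] == 10
        assert 0.35 < (df["sex"] == "F").mean() < 0.60

    def test_score_age_uncorrelated(self):
        df = px.simulate_cohort(px.CohortSpec(n_subjects=10_000), seed=7)
        assert abs(np.corrcoef(df["score"], df["age"])[0, 1]) < 0.03

    def test_invalid_specs_rejected(self):
        with pytest.raises(SpecError):
            px.CohortSpec(n_subjects=0)
        with pytest.raises(SpecError):
            px.CohortSpec(age_range=(21, 3))
        with pytest.raises(SpecError):
            px.CohortSpec(sex_ratio=1.5)


class TestThickness:
    def test_noiseless_limit_is_score_times_effect(self, mesh2, cohort50):
        eff = px.EffectSpec(effect_map=np.full(mesh2.n_vertices, 0.7),
                            noise_sd=1e-9, noise_fwhm=0.0)
        stack = px.simulate_thickness(mesh2, cohort50, eff, seed=1)
        expected = np.outer(cohort50["score"], np.full(mesh2.n_vertices, 0.7))
        cx = ~mesh2.medial_wall
        assert np.allclose(stack[:, cx], expected[:, cx], atol=1e-6)

    def test_medial_wall_nan_every_subject(self, mesh2, cohort50):
        eff = px.EffectSpec(effect_map=np.zeros(mesh2.n_vertices))
        stack = px.simulate_thickness(mesh2, cohort50, eff, seed=1)
        assert np.isnan(stack[:, mesh2.medial_wall]).all()
        assert np.isfinite(stack[:, ~mesh2.medial_wall]).all()

    def test_mesh_effect_mismatch(self, mesh2, cohort50):
        eff = px.EffectSpec(effect_map=np.zeros(mesh2.n_vertices + 1))
        with pytest.raises(SpecError):
            px.simulate_thickness(mesh2, cohort50, eff, seed=1)

    def test_fwhm_roundtrip(self, mesh3):
        """Planted noise FWHM is recovered by the smoothness estimator."""
        target = 20.0  # mm, ~2.7 mean edge lengths on this mesh
        subjects = px.simulate_cohort(px.CohortSpec(n_subjects=80), seed=2)
        eff = px.EffectSpec(effect_map=np.zeros(mesh3.n_vertices),
                            noise_sd=1.0, noise_fwhm=target)
        stack = px.simulate_thickness(mesh3, subjects, eff, seed=3)
        sm = px.estimate_fwhm(stack, mesh3)
        assert abs(sm.fwhm - target) / target < 0.15

    def test_beta_recovery(self, mesh2):
        """Fitting the GLM on simulated data recovers the planted slopes."""
        rng = np.random.default_rng(8)
        subjects = px.simulate_cohort(px.CohortSpec(n_subjects=400), seed=8)
        noise_sd = 0.2
        beta_true = px.smooth(rng.standard_normal(mesh2.n_vertices), mesh2,
                              3 * mesh2.mean_edge_length)
        beta_true *= 0.5 * noise_sd / beta_true.std()  # vertexwise SNR ~ 0.5
        eff = px.EffectSpec(effect_map=beta_true, noise_sd=noise_sd,
                            noise_fwhm=2 * mesh2.mean_edge_length)
        stack = px.simulate_thickness(mesh2, subjects, eff, seed=9)
        res = px.fit_model(stack, subjects,
                           px.DesignSpec(standardize=False))
        cx = ~mesh2.medial_wall
        r = np.corrcoef(res.beta[cx], beta_true[cx])[0, 1]
        assert r > 0.9
        bias = np.mean(res.beta[cx] - beta_true[cx])
        assert abs(bias) < 0.02 * noise_sd


class TestExpression:
    def test_noiseless_recovery_both_routes(self):
        spec = px.ExpressionSpec(n_genes=120, specimen_noise_sd=0.0)
        sx = px.simulate_expression(spec, seed=4)
        for comp in px.COMPARTMENTS:
            score = px.score_compartment(sx.panel, sx.markers[comp])
            score = score.reindex(spec.areas).to_numpy()
            r = np.corrcoef(score, sx.gradients[comp])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-10)
        for ct in px.CELL_TYPES:
            score = px.score_celltype(sx.panel, sx.weights, ct)
            score = score.reindex(spec.areas).to_numpy()
            r = np.corrcoef(score, sx.gradients[ct])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-10)

    def test_six_component_scores_per_area(self):
        sx = px.simulate_expression(px.ExpressionSpec(n_genes=120), seed=5)
        scores = px.score_all_components(sx.panel, sx.weights, sx.markers)
        assert scores.shape == (11, 6)
        assert set(scores.columns) == set(px.COMPONENTS)

    def test_seed_contract(self):
        spec = px.ExpressionSpec(n_genes=80)
        a = px.simulate_expression(spec, seed=1)
        b = px.simulate_expression(spec, seed=2)
        assert not np.allclose(a.panel["value"], b.panel["value"])
        for comp in px.COMPONENTS:
            assert np.array_equal(a.gradients[comp], b.gradients[comp])

    def test_gradient_length_mismatch(self):
        grads = default_gradients()
        grads["astrocyte"] = grads["astrocyte"][:-1]
        with pytest.raises(SpecError):
            px.ExpressionSpec(component_gradients=grads)


class TestDisorderMaps:
    def test_exact_negative_mixing(self, mesh3, atlases3, rng):
        labels = atlases3["parcels"][0]
        ref_v = px.smooth(rng.standard_normal(mesh3.n_vertices), mesh3,
                          3 * mesh3.mean_edge_length)
        ref_v[mesh3.medial_wall] = np.nan
        _, ref = px.parcellate(ref_v, labels)
        maps = px.simulate_disorder_maps(mesh3, labels, ref, {"x": -1.0},
                                         seed=1)
        m = np.isfinite(ref) & np.isfinite(maps["x"])
        r = np.corrcoef(ref[m], maps["x"][m])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_planted_correlation_exact_and_zero_mean(self, mesh3, atlases3,
                                                     rng):
        labels = atlases3["parcels"][0]
        ref_v = px.smooth(rng.standard_normal(mesh3.n_vertices), mesh3,
                          3 * mesh3.mean_edge_length)
        ref_v[mesh3.medial_wall] = np.nan
        _, ref = px.parcellate(ref_v, labels)
        targets = {f"d{i}": 0.0 for i in range(200)}
        maps = px.simulate_disorder_maps(mesh3, labels, ref, targets, seed=2)
        rs = []
        m = np.isfinite(ref)
        for v in maps.values():
            rs.append(np.corrcoef(ref[m], v[m])[0, 1])
        assert abs(np.mean(rs)) < 0.05
        # sample correlation is matched exactly by Gram-Schmidt mixing
        assert np.max(np.abs(rs)) < 1e-9

    def test_six_disorders_six_maps(self, mesh3, atlases3, rng):
        labels = atlases3["parcels"][0]
        _, ref = px.parcellate(
            np.where(mesh3.medial_wall, np.nan,
                     rng.standard_normal(mesh3.n_vertices)), labels)
        targets = dict.fromkeys(px.DISORDERS, -0.3)
        maps = px.simulate_disorder_maps(mesh3, labels, ref, targets, seed=3)
        assert len(maps) == 6

    def test_constant_reference_rejected(self, mesh3, atlases3):
        labels = atlases3["parcels"][0]
        ids = np.unique(labels[labels > 0])
        with pytest.raises(SpecError):
            px.simulate_disorder_maps(mesh3, labels, np.ones(len(ids)),
                                      {"x": 0.5}, seed=1)


class TestAtlases:
    def test_patch_counts_and_contiguity(self, mesh3, atlases3):
        import scipy.sparse.csgraph as csg
        for key, n in (("types", 6), ("networks", 7), ("parcels", 64),
                       ("fine", 200)):
            labels, names = atlases3[key]
            ids = np.unique(labels[labels > 0])
            assert len(ids) == n
            assert len(names) == n
        # networks span both hemispheres as a few separated patches each
        labels = atlases3["networks"][0]
        for pid in np.unique(labels[labels > 0]):
            for hemi in ("L", "R"):
                idx = np.where((labels == pid)
                               & (mesh3.hemisphere == hemi))[0]
                assert len(idx) > 0
                sub = mesh3.adjacency[idx][:, idx]
                n_comp, _ = csg.connected_components(sub, directed=False)
                assert 1 <= n_comp <= 4  # 3 seeds, medial cap may split one
        # split parcels live in exactly one hemisphere, contiguous
        labels = atlases3["parcels"][0]
        for pid in np.unique(labels[labels > 0]):
            idx = np.where(labels == pid)[0]
            assert len(set(mesh3.hemisphere[idx])) == 1
            sub = mesh3.adjacency[idx][:, idx]
            n_comp, _ = csg.connected_components(sub, directed=False)
            assert n_comp <= 2  # medial cap may split a cell

    def test_deterministic_given_seed(self, mesh2):
        a = px.make_atlases(mesh2, seed=5)
        b = px.make_atlases(mesh2, seed=5)
        for key in a:
            assert np.array_equal(a[key][0], b[key][0])
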