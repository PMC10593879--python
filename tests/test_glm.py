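"""Design construction and vertexwise OLS: oracles and identities."""

import numpy as np
import pytest

import polycortex as px
from polycortex.glm import DesignError


def _toy_stack(rng, n, V):
    return rng.standard_normal((n, V))


class TestBuildDesign:
    def test_column_audit_two_scanners(self, cohort50):
        """intercept+score+age+age2+2 interactions+sex+10 PCs+scanner+bv."""
        X, names, _ = px.build_design(cohort50, px.DesignSpec())
        assert len(names) == 19
        assert names[:6] == ["intercept", "score", "age", "age2",
                             "score_x_age", "score_x_age2"]
        assert names[-1] == "brain_volume"
        assert X.shape == (50, 19)

    def test_centered_age_sums_to_zero(self, cohort50):
        X, names, center = px.build_design(cohort50, px.DesignSpec())
        assert center == pytest.approx(cohort50["age"].mean())
        assert abs(X[:, names.index("age")].sum()) < 1e-10

    def test_single_level_factor_contributes_no_columns(self, cohort50):
        df = cohort50.copy()
        df["scanner"] = "only"
        X, names, _ = px.build_design(df, px.DesignSpec())
        assert not any(n.startswith("scanner") for n in names)
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_rank_deficient_design_rejected(self, cohort50):
        df = cohort50.copy()
        df["pc1"] = df["pc2"]  # duplicate column
        with pytest.raises(DesignError):
            px.build_design(df, px.DesignSpec())

    def test_missing_values_rejected(self, cohort50):
        df = cohort50.copy()
        df.loc[0, "age"] = np.nan
        with pytest.raises(DesignError):
            px.build_design(df, px.DesignSpec())


class TestFitVertexwise:
    def test_matches_normal_equations_oracle(self, rng):
        """QR path agrees with an independent inv(X'X)X'y solve per vertex."""
        n, V = 8, 6
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        names = ["intercept", "score", "cov"]
        Y = _toy_stack(rng, n, V)
        res = px.fit_vertexwise(Y, X, names, contrast="score")
        XtXi = np.linalg.inv(X.T @ X)
        for v in range(V):
            b = XtXi @ X.T @ Y[:, v]
            e = Y[:, v] - X @ b
            s2 = e @ e / (n - 3)
            se = np.sqrt(s2 * XtXi[1, 1])
            assert res.beta[v] == pytest.approx(b[1], rel=1e-8)
            assert res.se[v] == pytest.approx(se, rel=1e-8)
            assert res.tstat[v] == pytest.approx(b[1] / se, rel=1e-8)
        assert res.df == n - 3

    def test_row_order_invariance(self, mesh2, cohort50, rng):
        eff = px.EffectSpec(effect_map=np.zeros(mesh2.n_vertices),
                            noise_sd=0.5)
        Y = px.simulate_thickness(mesh2, cohort50, eff, seed=4)
        res1 = px.fit_model(Y, cohort50)
        perm = rng.permutation(len(cohort50))
        res2 = px.fit_model(Y[perm], cohort50.iloc[perm].reset_index(drop=True))
        assert np.allclose(res1.tstat, res2.tstat, equal_nan=True, atol=1e-10)

    def test_perfect_fit_returns_nan_sentinel(self, cohort50):
        X, names, _ = px.build_design(cohort50, px.DesignSpec())
        Y = np.outer(X[:, names.index("score")], np.ones(4))
        res = px.fit_vertexwise(Y, X, names, contrast="score")
        assert np.allclose(res.beta, 1.0)
        assert np.isnan(res.tstat).all()  # finite-field guard

    def test_all_nan_vertex_gives_nan_outputs(self, cohort50, rng):
        X, names, _ = px.build_design(cohort50, px.DesignSpec())
        Y = _toy_stack(rng, 50, 5)
        Y[:, 2] = np.nan
        res = px.fit_vertexwise(Y, X, names)
        assert np.isnan(res.beta[2]) and np.isnan(res.tstat[2])
        assert np.isfinite(res.beta[[0, 1, 3, 4]]).all()

    def test_too_few_subjects_rejected(self, cohort50, rng):
        X, names, _ = px.build_design(cohort50, px.DesignSpec())
        with pytest.raises(DesignError):
            px.fit_vertexwise(_toy_stack(rng, 10, 3), X[:10], names)

    def test_t_squared_equals_nested_F(self, cohort50, rng):
        """Single-df contrast: t^2 equals the nested-model F statistic."""
        X, names, _ = px.build_design(cohort50, px.DesignSpec())
        Y = _toy_stack(rng, 50, 3)
        res = px.fit_vertexwise(Y, X, names, contrast="score")
        j = names.index("score")
        X0 = np.delete(X, j, axis=1)
        for v in range(3):
            rss1 = np.sum((Y[:, v] - X @ np.linalg.lstsq(X, Y[:, v],
                                                         rcond=None)[0]) ** 2)
            rss0 = np.sum((Y[:, v] - X0 @ np.linalg.lstsq(X0, Y[:, v],
                                                          rcond=None)[0]) ** 2)
            F = (rss0 - rss1) / (rss1 / res.df)
            assert res.tstat[v] ** 2 == pytest.approx(F, rel=1e-6)

    def test_brain_volume_shift_changes_only_intercept(self, mesh2, cohort50):
        eff = px.EffectSpec(effect_map=np.zeros(mesh2.n_vertices),
                            noise_sd=0.5)
        Y = px.simulate_thickness(mesh2, cohort50, eff, seed=6)
        spec = px.DesignSpec(standardize=False)
        res1 = px.fit_model(Y, cohort50, spec)
        shifted = cohort50.copy()
        shifted["brain_volume"] = shifted["brain_volume"] + 1e5
        res2 = px.fit_model(Y, shifted, spec)
        for nm in res1.names:
            a, b = res1.coefficient(nm), res2.coefficient(nm)
            if nm == "intercept":
                assert not np.allclose(a, b, equal_nan=True)
            else:
                assert np.allclose(a, b, equal_nan=True, atol=1e-8)


class TestAgeGroups:
    def test_partition_and_group_centering(self, mesh2):
        subjects = px.simulate_cohort(px.CohortSpec(n_subjects=300), seed=10)
        eff = px.EffectSpec(effect_map=np.zeros(mesh2.n_vertices),
                            noise_sd=0.5)
        Y = px.simulate_thickness(mesh2, subjects, eff, seed=11)
        groups = px.fit_age_groups(Y, subjects)
        ns = [res.n for res in groups.values()]
        assert sum(ns) == 300  # disjoint bounds cover the range
        for (lo, hi), res in groups.items():
            sel = np.floor(subjects["age"]).between(lo, hi)
            assert res.age_center == pytest.approx(
                subjects.loc[sel, "age"].mean())

    def test_constant_planted_effect_agrees_across_groups(self, mesh2):
        subjects = px.simulate_cohort(px.CohortSpec(n_subjects=390), seed=12)
        noise_sd = 0.2
        rng = np.random.default_rng(13)
        beta = px.smooth(rng.standard_normal(mesh2.n_vertices), mesh2,
                         3 * mesh2.mean_edge_length)
        beta *= 0.5 * noise_sd / beta.std()
        eff = px.EffectSpec(effect_map=beta, noise_sd=noise_sd)
        Y = px.simulate_thickness(mesh2, subjects, eff, seed=14)
        groups = list(px.fit_age_groups(Y, subjects).values())
        cx = ~mesh2.medial_wall
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(groups[i].beta[cx], groups[j].beta[cx])[0, 1]
                assert r > 0.8

    def test_empty_group_rejected(self, mesh2, cohort50):
        eff = px.EffectSpec(effect_map=np.zeros(mesh2.n_vertices))
        Y = px.simulate_thickness(mesh2, cohort50, eff, seed=1)
        with pytest.raises(DesignError):
            px.fit_age_groups(Y, cohort50, bounds=[(80.0, 90.0)])


class TestAgeCenterSweep:
    def test_without_interactions_sweep_is_constant(self, mesh2, cohort50):
        eff = px.EffectSpec(effect_map=np.zeros(mesh2.n_vertices),
                            noise_sd=0.5)
        Y = px.simulate_thickness(mesh2, cohort50, eff, seed=15)
        spec = px.DesignSpec(include_interactions=False)
        sweep = px.age_center_sweep(Y, cohort50, spec, centers=[3.0, 12.0, 21.0])
        maps = [r.beta for r in sweep.values()]
        assert np.allclose(maps[0], maps[1], equal_nan=True, atol=1e-10)
        assert np.allclose(maps[0], maps[2], equal_nan=True, atol=1e-10)

    def test_reparameterization_identity(self, mesh2, cohort50):
        """Sweep betas equal b1 + b4*(c-c0) + b5*(c-c0)^2 of a single fit."""
        eff = px.EffectSpec(effect_map=np.full(mesh2.n_vertices, 0.1),
                            noise_sd=0.5)
        Y = px.simulate_thickness(mesh2, cohort50, eff, seed=16)
        base = px.fit_model(Y, cohort50, px.DesignSpec())
        c0 = base.age_center
        sweep = px.age_center_sweep(Y, cohort50, px.DesignSpec(),
                                    centers=np.arange(3.0, 22.0))
        assert len(sweep) == 19
        b1 = base.coefficient("score")
        b4 = base.coefficient("score_x_age")
        b5 = base.coefficient("score_x_age2")
        for c, res in sweep.items():
            d = c - c0
            pred = b1 + b4 * d + b5 * d ** 2
            assert np.allclose(res.beta, pred, equal_nan=True, atol=1e-6)


def test_age_polynomial_aic_prefers_planted_degree(mesh2):
    subjects = px.simulate_cohort(px.CohortSpec(n_subjects=300), seed=20)
    age_c = subjects["age"] - subjects["age"].mean()
    eff = px.EffectSpec(effect_map=np.zeros(mesh2.n_vertices), noise_sd=0.3)
    Y = px.simulate_thickness(mesh2, subjects, eff, seed=21)
    Y += 0.05 * (age_c.to_numpy() ** 2)[:, None]  # quadratic age profile
    table = px.age_polynomial_aic(Y, subjects)
    assert list(table["degree"]) == [0, 1, 2]
    assert table["mean_aic"].idxmin() == 2
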