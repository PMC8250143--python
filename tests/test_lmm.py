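"""REML machinery: design construction, profiled criterion, fitting, BLUPs."""

import numpy as np
import pandas as pd
import pytest

from gsblup import (
    FixedSpec,
    RandomTermSpec,
    RelationshipMatrix,
    UserCovLMM,
    blups,
    fit_lmm,
    heritability,
    kron_kernel,
    summarize,
)
from gsblup.lmm import build_design, fitted_values, reml_criterion
from gsblup.simdata import simulate_phenotypes

from _oracles import blup_dense, reml_loglik_dense
from conftest import labelled_psd


def incidence(levels_of_rows, levels):
    pos = {g: j for j, g in enumerate(levels)}
    Z = np.zeros((len(levels_of_rows), len(levels)))
    Z[np.arange(len(levels_of_rows)), [pos[g] for g in levels_of_rows]] = 1.0
    return Z


class TestBuildDesign:
    def test_replicated_incidence(self):
        K = RelationshipMatrix(np.eye(3), ["a", "b", "c"])
        data = pd.DataFrame({"GID": ["a", "b", "c", "a", "b", "c"], "y": range(6)})
        d = build_design(data, FixedSpec(), [RandomTermSpec("g", "GID", K)])
        assert d.Z[0].shape == (6, 3)
        assert (d.Z[0].sum(axis=0) == 2).all()
        assert (d.Z[0].sum(axis=1) == 1).all()

    def test_two_term_intercept_only(self, two_term_dataset):
        data, terms, _ = two_term_dataset
        d = build_design(data, FixedSpec(), terms)
        assert d.q == 2 and d.p == 1

    def test_three_term_with_location_factor(self, rng):
        K1 = labelled_psd(4, rng, prefix="P", unit_diag=True)
        K2 = labelled_psd(4, rng, prefix="M", unit_diag=True)
        K3 = kron_kernel(K1, K2)
        rows = []
        for loc in ("L1", "L2"):
            for a in K1.labels:
                for b in K2.labels:
                    rows.append({"Loc": loc, "P": a, "M": b, "H": f"{a}:{b}", "y": 0.0})
        data = pd.DataFrame(rows)
        d = build_design(
            data,
            FixedSpec(terms=[("Loc", "categorical")]),
            [
                RandomTermSpec("gca1", "P", K1),
                RandomTermSpec("gca2", "M", K2),
                RandomTermSpec("sca", "H", K3),
            ],
        )
        assert d.q == 3
        assert d.p == 2  # intercept + one dummy for 2 locations

    def test_missing_level_reported(self):
        K = RelationshipMatrix(np.eye(2), ["a", "b"])
        data = pd.DataFrame({"GID": ["a", "zz"], "y": [0.0, 1.0]})
        with pytest.raises(KeyError, match="zz"):
            build_design(data, FixedSpec(), [RandomTermSpec("g", "GID", K)])

    def test_rank_deficient_fixed_design_names_alias(self):
        K = RelationshipMatrix(np.eye(3), ["a", "b", "c"])
        data = pd.DataFrame(
            {"GID": ["a", "b", "c"], "x1": [1.0, 2.0, 3.0], "x2": [2.0, 4.0, 6.0],
             "y": [0.0, 1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="x2"):
            build_design(
                data,
                FixedSpec(terms=[("x1", "numeric"), ("x2", "numeric")]),
                [RandomTermSpec("g", "GID", K)],
            )


class TestRemlCriterion:
    def _toy(self, rng, n=12, r=5, seed=7):
        K = labelled_psd(r, rng)
        lv = [f"g{i + 1}" for i in range(r)]
        rows = [lv[i % r] for i in range(n)]
        Z = incidence(rows, lv)
        data, _, _ = simulate_phenotypes([(Z, K, 0.7)], 0.3, seed=seed, term_names=["GID"])
        d = build_design(data, FixedSpec(), [RandomTermSpec("g", "GID", K)])
        return d, data["y"].to_numpy(), K, Z

    def test_lambda_zero_reduces_to_ols(self, rng):
        d, y, _, _ = self._toy(rng)
        _, beta, s2 = reml_criterion(np.array([-50.0]), d, y)
        X = d.X
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = np.sum((y - X @ beta_ols) ** 2)
        assert np.allclose(beta, beta_ols)
        assert s2 == pytest.approx(rss / (d.n - d.p))

    def test_matches_dense_restricted_likelihood(self, rng):
        """Profiled transformed-scale criterion equals the dense original-scale
        restricted likelihood over a 50-point lambda grid."""
        d, y, K, Z = self._toy(rng)
        for loglam in np.linspace(-4, 4, 50):
            ll, _, s2 = reml_criterion(np.array([loglam]), d, y)
            ll_oracle = reml_loglik_dense(
                y, d.X, [Z], [K.values], [np.exp(loglam) * s2], s2
            )
            assert ll == pytest.approx(ll_oracle, abs=1e-8)

    def test_invariant_to_fixed_reparameterization(self, rng):
        r = 4
        K = labelled_psd(r, rng)
        lv = K.labels
        rows = [lv[i % r] for i in range(16)]
        Z = incidence(rows, lv)
        x = rng.standard_normal(16)
        data = pd.DataFrame({"GID": rows, "x": x})
        data["y"] = x + Z @ rng.standard_normal(r) + 0.1 * rng.standard_normal(16)
        fixed = FixedSpec(terms=[("x", "numeric")])
        d1 = build_design(data, fixed, [RandomTermSpec("g", "GID", K)])
        data2 = data.copy()
        data2["x"] = 3.0 * data["x"] + 1.7  # invertible column transform of [1, x]
        d2 = build_design(data2, fixed, [RandomTermSpec("g", "GID", K)])
        y = data["y"].to_numpy()
        # the criterion shifts by the constant -log|det(A)| under X -> X A,
        # so the profile shape, argmax and variance estimates are invariant
        diffs = []
        for loglam in (-1.0, 0.0, 2.0):
            ll1, _, s2_1 = reml_criterion(np.array([loglam]), d1, y)
            ll2, _, s2_2 = reml_criterion(np.array([loglam]), d2, y)
            diffs.append(ll1 - ll2)
            assert s2_1 == pytest.approx(s2_2, abs=1e-10)
        assert max(diffs) - min(diffs) < 1e-8


class TestFitLMM:
    def test_balanced_oneway_matches_anova_closed_form(self):
        a, r = 20, 5
        rng = np.random.default_rng(42)
        groups = np.repeat(np.arange(a), r)
        u = rng.normal(0, 1.0, a)
        y = 2.0 + u[groups] + rng.normal(0, 0.5, a * r)
        data = pd.DataFrame({"GID": [f"g{i}" for i in groups], "y": y})
        K = RelationshipMatrix(np.eye(a), [f"g{i}" for i in range(a)])
        m = fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K)])
        gm = y.reshape(a, r).mean(axis=1)
        ms_w = np.sum((y.reshape(a, r) - gm[:, None]) ** 2) / (a * (r - 1))
        ms_b = r * np.sum((gm - y.mean()) ** 2) / (a - 1)
        assert m.sigma2["residual"] == pytest.approx(ms_w, abs=1e-6)
        assert m.sigma2["g"] == pytest.approx(max((ms_b - ms_w) / r, 0.0), abs=1e-6)

    def test_zero_noise_degenerates_to_ols(self):
        n = 24
        x = np.linspace(0, 1, n)
        data = pd.DataFrame(
            {"GID": [f"g{i}" for i in range(n)], "x": x, "y": 1.0 + 2.0 * x}
        )
        K = RelationshipMatrix(np.eye(n), [f"g{i}" for i in range(n)])
        m = fit_lmm(
            data, "y", fixed=FixedSpec(terms=[("x", "numeric")]),
            random=[RandomTermSpec("g", "GID", K)],
        )
        assert m.beta.to_numpy() == pytest.approx([1.0, 2.0], abs=1e-6)
        assert m.sigma2["residual"] < 1e-10
        assert m.sigma2["g"] < 1e-10

    @pytest.mark.parametrize("n_grid", [60])
    def test_optimum_beats_dense_grid(self, n_grid):
        """Optimizer's criterion value dominates a dense lambda grid (small n)."""
        rng = np.random.default_rng(1)
        for inst in range(5):
            r, n = 5, 14
            K = labelled_psd(r, np.random.default_rng(100 + inst))
            lv = K.labels
            rows = [lv[i % r] for i in range(n)]
            Z = incidence(rows, lv)
            data, _, _ = simulate_phenotypes(
                [(Z, K, 0.6)], 0.4, seed=200 + inst, term_names=["GID"]
            )
            m = fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K)])
            d = m.design
            y = data["y"].to_numpy()
            grid = np.linspace(-10, 10, n_grid)
            grid_max = max(reml_criterion(np.array([g]), d, y)[0] for g in grid)
            assert m.reml_loglik >= grid_max - 1e-6

    def test_factorization_equivalence(self, grouped_dataset):
        data, K, _ = grouped_dataset
        fits = {
            meth: fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K, meth)])
            for meth in ("cholesky", "eigen")
        }
        assert fits["cholesky"].reml_loglik == pytest.approx(
            fits["eigen"].reml_loglik, abs=1e-6
        )
        du = (fits["cholesky"].u["g"] - fits["eigen"].u["g"]).abs().max()
        assert du <= 1e-6

    def test_scale_equivariance(self, grouped_dataset):
        data, K, _ = grouped_dataset
        m1 = fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K)])
        data2 = data.copy()
        c = 3.0
        data2["y"] = c * data2["y"]
        m2 = fit_lmm(data2, "y", random=[RandomTermSpec("g", "GID", K)])
        for k in m1.sigma2:
            assert m2.sigma2[k] == pytest.approx(c**2 * m1.sigma2[k], rel=1e-4)
        assert m2.lambdas["g"] == pytest.approx(m1.lambdas["g"], rel=1e-3)

    def test_permutation_invariance(self, grouped_dataset):
        data, K, _ = grouped_dataset
        m1 = fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K)])
        perm = np.random.default_rng(9).permutation(len(data))
        m2 = fit_lmm(
            data.iloc[perm].reset_index(drop=True), "y",
            random=[RandomTermSpec("g", "GID", K)],
        )
        assert m1.reml_loglik == pytest.approx(m2.reml_loglik, abs=1e-7)
        assert np.allclose(m1.u["g"].to_numpy(), m2.u["g"].to_numpy(), atol=1e-7)

    def test_missing_responses_dropped_with_warning(self, grouped_dataset):
        data, K, _ = grouped_dataset
        data = data.copy()
        data.loc[:4, "y"] = np.nan
        with pytest.warns(UserWarning, match="dropped 5"):
            m = fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K)])
        assert m.n_dropped == 5


class TestBlups:
    def test_matches_dense_original_scale_formula(self, grouped_dataset):
        data, K, _ = grouped_dataset
        m = fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K)])
        d = m.design
        y = data["y"].to_numpy()
        u_oracle = blup_dense(
            y, d.X, m.beta.to_numpy(), d.Z, [k.values for k in d.K_sub],
            [m.sigma2["g"]], m.sigma2["residual"],
        )[0]
        assert np.abs(m.u["g"].to_numpy() - u_oracle).max() < 1e-8

    def test_two_term_dense_identity(self, two_term_dataset):
        data, terms, _ = two_term_dataset
        m = fit_lmm(data, "y", random=terms)
        d = m.design
        y = data["y"].to_numpy()
        s2 = [m.sigma2[t.name] for t in terms]
        u_oracle = blup_dense(
            y, d.X, m.beta.to_numpy(), d.Z, [k.values for k in d.K_sub],
            s2, m.sigma2["residual"],
        )
        for j, t in enumerate(terms):
            assert np.abs(m.u[t.name].to_numpy() - u_oracle[j]).max() < 1e-8

    def test_fitted_plus_residual_reconstructs_response(self, grouped_dataset):
        data, K, _ = grouped_dataset
        m = fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K)])
        yhat = fitted_values(m)
        resid = data["y"].to_numpy() - yhat
        assert np.allclose(yhat + resid, data["y"].to_numpy())
        # shrinkage: fitted values track y but are not an interpolation
        assert 0 < np.std(resid) < np.std(data["y"].to_numpy())

    def test_blups_accessor_returns_labelled_copies(self, grouped_dataset):
        data, K, _ = grouped_dataset
        m = fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K)])
        b = blups(m)
        assert set(b) == {"g"}
        assert list(b["g"].index) == list(m.u["g"].index)
        b["g"].iloc[0] = 999.0
        assert m.u["g"].iloc[0] != 999.0


class TestSummary:
    @pytest.mark.parametrize(
        "s1,s2,se,expected", [(3.0, 1.0, 1.0, 0.8), (2.0, 1.0, 0.0, 1.0)]
    )
    def test_heritability_formula(self, s1, s2, se, expected, grouped_dataset):
        data, K, _ = grouped_dataset
        m = fit_lmm(data, "y", random=[RandomTermSpec("g", "GID", K)])
        m.sigma2 = {"a": s1, "b": s2, "residual": se}
        assert heritability(m, ["a", "b"]) == pytest.approx(expected)

    def test_report_lists_all_components(self, two_term_dataset):
        data, terms, _ = two_term_dataset
        m = fit_lmm(data, "y", random=terms)
        rep = summarize(m)
        for key in ("markers", "pedigree", "residual", "(Intercept)"):
            assert key in rep


class TestEstimatorInterface:
    def test_fit_sets_trailing_underscore_attributes(self, grouped_dataset):
        data, K, _ = grouped_dataset
        est = UserCovLMM(response="y", random_terms=[RandomTermSpec("g", "GID", K)])
        est.fit(data)
        for attr in ("beta_", "sigma2_", "reml_loglik_", "u_", "converged_"):
            assert hasattr(est, attr)

    def test_get_set_params_roundtrip(self, grouped_dataset):
        data, K, _ = grouped_dataset
        est = UserCovLMM(response="y", random_terms=[RandomTermSpec("g", "GID", K)])
        params = est.get_params()
        est2 = UserCovLMM(**params)
        est2.set_params(restricted=True)
        est2.fit(data)
        assert est2.converged_

    def test_predict_in_sample_matches_fitted_values(self, grouped_dataset):
        data, K, _ = grouped_dataset
        est = UserCovLMM(response="y", random_terms=[RandomTermSpec("g", "GID", K)])
        est.fit(data)
        assert np.allclose(est.predict(), fitted_values(est.result_))

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            UserCovLMM().predict()
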