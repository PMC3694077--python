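import numpy as np
import pandas as pd
import pytest

from rfiwgas.pheno import (
    RfiModelSpec,
    build_a_inverse,
    build_design,
    compute_adfi,
    compute_adg,
    compute_rfi,
    derive_phenotypes,
    factor_incidence,
    inbreeding_coefficients,
    solve_mme,
    tabular_a,
)
from conftest import random_pedigree


class TestAdg:
    def test_two_point_slope(self):
        assert compute_adg([0, 14], [40, 54]) == pytest.approx(1.0)

    def test_exact_linear_any_intercept(self):
        days = np.arange(0, 99, 14)
        assert compute_adg(days, 37.2 + 0.9 * days) == pytest.approx(0.9)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(1)
        days = np.arange(0, 99, 14, dtype=float)
        w = 40 + 0.85 * days + rng.normal(0, 1, days.size)
        X = np.column_stack([np.ones_like(days), days])
        beta = np.linalg.solve(X.T @ X, X.T @ w)
        assert compute_adg(days, w) == pytest.approx(beta[1], abs=1e-10)

    def test_order_invariance_and_errors(self):
        days = np.array([0.0, 14, 28, 42])
        w = np.array([40.0, 52, 66, 77])
        perm = [2, 0, 3, 1]
        assert compute_adg(days[perm], w[perm]) == pytest.approx(compute_adg(days, w))
        with pytest.raises(ValueError):
            compute_adg([5, 5], [40, 41])


class TestAdfi:
    def test_constant_intake(self):
        assert compute_adfi(np.arange(10), np.full(10, 2.5)) == pytest.approx(2.5)

    def test_exact_quadratic_closed_form_mean(self):
        c0, c1, c2 = 1.5, 0.02, -1e-4
        days = np.arange(0, 91)
        y = c0 + c1 * days + c2 * days**2
        # analytic mean of the quadratic over the integer days 0..90
        grid = np.arange(0, 91)
        expected = (c0 + c1 * grid + c2 * grid**2).mean()
        assert compute_adfi(days, y) == pytest.approx(expected, abs=1e-10)

    def test_missing_days_stay_close_to_complete_fit(self):
        rng = np.random.default_rng(2)
        days = np.arange(0, 91)
        y = 2.0 + 0.01 * days - 5e-5 * days**2 + rng.normal(0, 0.2, days.size)
        keep = rng.random(days.size) > 0.3
        full = compute_adfi(days, y)
        sub = compute_adfi(days[keep], y[keep])
        assert abs(full - sub) < 0.15

    def test_too_few_days_error(self):
        with pytest.raises(ValueError):
            compute_adfi([0, 1], [2.0, 2.1])


class TestAInverse:
    def test_two_unrelated_founders(self):
        ped = random_pedigree(2, 2, np.random.default_rng(0))
        np.testing.assert_allclose(build_a_inverse(ped).toarray(), np.eye(2))

    def test_trio_textbook_values(self):
        ped = random_pedigree(3, 2, np.random.default_rng(0))
        Ainv = build_a_inverse(ped).toarray()
        expected = np.array([[1.5, 0.5, -1.0], [0.5, 1.5, -1.0], [-1.0, -1.0, 2.0]])
        np.testing.assert_allclose(Ainv, expected)

    def test_inverts_tabular_a_on_random_pedigree(self):
        rng = np.random.default_rng(12)
        ped = random_pedigree(50, 8, rng)
        A = tabular_a(ped)
        Ainv = build_a_inverse(ped).toarray()
        np.testing.assert_allclose(A @ Ainv, np.eye(50), atol=1e-8)

    def test_inbreeding_full_sib_mating(self):
        # offspring of full sibs has F = 0.25
        rows = [
            dict(animal_id="s", sire_id="0", dam_id="0", sex="M"),
            dict(animal_id="d", sire_id="0", dam_id="0", sex="F"),
            dict(animal_id="b", sire_id="s", dam_id="d", sex="M"),
            dict(animal_id="c", sire_id="s", dam_id="d", sex="F"),
            dict(animal_id="x", sire_id="b", dam_id="c", sex="M"),
        ]
        ped = pd.DataFrame(rows)
        F = inbreeding_coefficients(ped)
        assert F[-1] == pytest.approx(0.25)

    def test_cycle_detection(self):
        ped = pd.DataFrame([
            dict(animal_id="a", sire_id="b", dam_id="0", sex="M"),
            dict(animal_id="b", sire_id="a", dam_id="0", sex="M"),
        ])
        with pytest.raises(ValueError):
            build_a_inverse(ped)


def _random_mixed_problem(rng, n=60, q=8):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    Z, _ = factor_incidence(rng.integers(0, q, size=n))
    u = rng.normal(0, 1.0, q)
    y = X @ [2.0, 0.5, -0.3] + Z @ u + rng.normal(0, 1.0, n)
    return y, X, Z


class TestSolveMme:
    def test_infinite_ratio_reduces_to_ols(self):
        rng = np.random.default_rng(4)
        y, X, Z = _random_mixed_problem(rng)
        sol = solve_mme(y, X, [(Z, None)], [1e12])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(sol.fixed, ols, atol=1e-6)
        assert np.max(np.abs(sol.random[0])) < 1e-6

    def test_matches_dense_gls_oracle(self):
        rng = np.random.default_rng(8)
        y, X, Z = _random_mixed_problem(rng)
        lam = 2.5
        V = Z @ Z.T / lam + np.eye(len(y))
        Vinv = np.linalg.inv(V)
        b_gls = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        sol = solve_mme(y, X, [(Z, None)], [lam])
        np.testing.assert_allclose(sol.fixed, b_gls, atol=1e-8)
        u_gls = (Z.T @ Vinv @ (y - X @ b_gls)) / lam
        np.testing.assert_allclose(sol.random[0], u_gls, atol=1e-8)

    def test_duplicate_observation_residuals_split_symmetrically(self):
        rng = np.random.default_rng(6)
        y, X, Z = _random_mixed_problem(rng)
        y2 = np.concatenate([y, y[:1]])
        X2 = np.vstack([X, X[:1]])
        Z2 = np.vstack([Z, Z[:1]])
        sol = solve_mme(y2, X2, [(Z2, None)], [2.0])
        assert sol.residuals[0] == pytest.approx(sol.residuals[-1], abs=1e-10)

    def test_non_conformable_error(self):
        with pytest.raises(ValueError):
            solve_mme(np.ones(5), np.ones((4, 1)))

    def test_reordering_invariance(self):
        rng = np.random.default_rng(10)
        y, X, Z = _random_mixed_problem(rng)
        perm = rng.permutation(len(y))
        sol1 = solve_mme(y, X, [(Z, None)], [3.0])
        sol2 = solve_mme(y[perm], X[perm], [(Z[perm], None)], [3.0])
        np.testing.assert_allclose(sol1.fixed, sol2.fixed, atol=1e-8)
        np.testing.assert_allclose(sol1.random[0], sol2.random[0], atol=1e-8)


class TestComputeRfi:
    def test_zero_ratio_matches_ols_and_orthogonality(self, small_dataset):
        from rfiwgas import pheno

        tab = pheno.derive_phenotypes(
            small_dataset.weights, small_dataset.intakes,
            small_dataset.traits, small_dataset.pedigree,
        )
        # pure fixed-effect model, cell intercepts subtracted too
        spec = RfiModelSpec(variance_ratios={}, subtract_line=True)
        out = compute_rfi(tab, small_dataset.pedigree, spec)
        ok = out["RFI"].notna()
        sub = out.loc[ok]
        # per-cell mean ~ 0 and per-cell orthogonality to each covariate
        for cell, grp in sub.groupby("gen_line"):
            assert abs(grp["RFI"].mean()) < 1e-8
            for cov in ["onwt_dev", "age_dev", "offwt_dev", "metamidwt", "adga", "offbfa"]:
                x = grp[cov] - grp[cov].mean()
                if x.std() == 0:
                    continue
                r = np.corrcoef(grp["RFI"], x)[0, 1]
                assert abs(r) < 1e-6

        # recovered cell slopes equal a direct OLS oracle
        X, names = build_design(
            sub, factors=["gen_line", "group", "sex"],
            interactions=[(c, "gen_line") for c in ["onwt_dev", "age_dev", "offwt_dev",
                                                    "metamidwt", "adga", "offbfa"]],
        )
        beta = np.linalg.lstsq(X, sub["ADFI"].to_numpy(), rcond=None)[0]
        fitted_oracle = X @ beta
        np.testing.assert_allclose(
            sub["RFI"].to_numpy(), sub["ADFI"].to_numpy() - fitted_oracle, atol=1e-8
        )

    def test_divergent_lines_rank_low_below_high(self, small_phenotypes, small_dataset):
        last_gen = small_dataset.config.n_generations - 1
        g = small_phenotypes[small_phenotypes["generation"] == last_gen]
        low = g.loc[g["line"] == "LOW", "RFI"].mean()
        high = g.loc[g["line"] == "HIGH", "RFI"].mean()
        assert low < high

    def test_small_cell_error_names_cell(self, small_dataset):
        from rfiwgas import pheno

        tab = pheno.derive_phenotypes(
            small_dataset.weights, small_dataset.intakes,
            small_dataset.traits, small_dataset.pedigree,
        )
        tiny = tab.groupby("gen_line").head(3)  # 3 animals per cell < 6 covariates
        with pytest.raises(ValueError, match="cell"):
            compute_rfi(tiny, small_dataset.pedigree, RfiModelSpec(variance_ratios={}))


def test_em_reml_recovers_ratio_order_of_magnitude():
    from rfiwgas.pheno import em_reml_ratios

    rng = np.random.default_rng(30)
    n, q = 600, 40
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    Z, _ = factor_incidence(rng.integers(0, q, n))
    true_lam = 2.0  # sigma2_e / sigma2_u = 1 / 0.5
    y = X @ [1.0, 0.5] + Z @ rng.normal(0, np.sqrt(0.5), q) + rng.normal(0, 1.0, n)
    (lam,) = em_reml_ratios(y, X, [(Z, None)], [5.0])
    assert 0.5 < lam < 8.0  # right order of magnitude around 2


def test_derive_phenotypes_recovers_noiseless_slope(small_dataset):
    # rebuild one animal's weights without noise: ADG must equal the slope
    days = np.arange(0, 99, 14)
    w = pd.DataFrame({"animal_id": "z", "day": days, "weight_kg": 40 + 0.93 * days})
    assert compute_adg(w["day"], w["weight_kg"]) == pytest.approx(0.93)
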