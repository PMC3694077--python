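import numpy as np
import pandas as pd
import pytest

from rfiwgas.bayesb import (
    BayesBConfig,
    expected_window_share,
    fit_bayesb,
    gelman_rubin,
    genomic_heritability,
    make_windows,
    summarize_windows,
)
from rfiwgas.geno_io import MarkerMap, encode_centered


def _map_frame(chroms, positions):
    return MarkerMap(pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(chroms))],
        "chrom": [str(c) for c in chroms],
        "pos_bp": positions,
        "allele_a": "A",
        "allele_b": "B",
    }))


def _sim_xy(n, k, h2, n_qtl, seed, qtl_scale=None):
    rng = np.random.default_rng(seed)
    codes = rng.binomial(2, rng.uniform(0.1, 0.5, k), size=(n, k)).astype(np.int8)
    Z = encode_centered(codes)
    qtl = rng.choice(k, n_qtl, replace=False)
    beta = rng.normal(size=n_qtl)
    if qtl_scale is not None:
        beta = beta * qtl_scale
    g = Z[:, qtl] @ beta
    g = (g - g.mean()) / g.std() * np.sqrt(h2)
    y = g + rng.normal(0, np.sqrt(1 - h2), n)
    return y, Z, qtl, g


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            BayesBConfig(pi=0.0)
        with pytest.raises(ValueError):
            BayesBConfig(burn_in=100, n_iter=100)
        with pytest.raises(ValueError):
            BayesBConfig(thin=0)

    def test_saved_state_count(self):
        y, Z, _, _ = _sim_xy(50, 20, 0.5, 2, 0)
        cfg = BayesBConfig(n_iter=1050, burn_in=100, thin=25, seed=1)
        s = fit_bayesb(y, np.ones((50, 1)), Z, cfg)
        assert s.n_states == (1050 - 100) // 25


class TestSamplerLimits:
    def test_pi_one_gives_zero_genetic_variance_and_ols_fixed(self):
        rng = np.random.default_rng(2)
        n = 120
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.5, -0.7] + rng.normal(0, 1, n)
        _, Z, _, _ = _sim_xy(n, 30, 0.5, 2, 3)
        cfg = BayesBConfig(pi=1.0, n_iter=4000, burn_in=500, thin=5, seed=4)
        s = fit_bayesb(y, X, Z, cfg)
        assert np.all(s.effects == 0.0)
        h2 = genomic_heritability(s)
        assert h2["mean"] == 0.0
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(s.fixed.mean(axis=0), ols, atol=0.05)

    def test_single_marker_conjugate_posterior_oracle(self):
        # delta pinned to 1 (pi ~ 0), variances pinned by huge prior df:
        # the posterior of the single effect is the closed-form ridge normal
        rng = np.random.default_rng(5)
        n = 200
        z = rng.normal(size=(n, 1))
        sigma2_a, sigma2_e = 0.8, 1.0
        a_true = 0.6
        y = z[:, 0] * a_true + rng.normal(0, np.sqrt(sigma2_e), n)
        y = y - y.mean()
        cfg = BayesBConfig(
            pi=1e-12, n_iter=10_500, burn_in=500, thin=1,
            nu_effect=1e7, nu_resid=1e7,
            scale_effect=sigma2_a, scale_resid=sigma2_e, seed=6,
        )
        s = fit_bayesb(y, np.zeros((n, 0)), z, cfg)
        zz = float(z[:, 0] @ z[:, 0])
        v = 1.0 / (zz / sigma2_e + 1.0 / sigma2_a)
        post_mean = v * float(z[:, 0] @ y) / sigma2_e
        draws = s.effects[:, 0]
        mc_se = draws.std(ddof=1) / np.sqrt(len(draws) / 10)  # crude ESS deflation
        assert abs(draws.mean() - post_mean) < 3 * max(mc_se, 1e-4)
        assert abs(draws.std() - np.sqrt(v)) < 0.1 * np.sqrt(v)

    def test_zero_variance_phenotype_error(self):
        _, Z, _, _ = _sim_xy(30, 10, 0.5, 1, 7)
        with pytest.raises(ValueError):
            fit_bayesb(np.ones(30), np.ones((30, 1)), Z, BayesBConfig(n_iter=10, burn_in=1))

    def test_constant_column_gets_zero_effect(self):
        y, Z, _, _ = _sim_xy(60, 10, 0.5, 2, 8)
        Z = Z.copy()
        Z[:, 3] = 0.0
        s = fit_bayesb(y, np.ones((60, 1)), Z, BayesBConfig(n_iter=500, burn_in=100, thin=2, seed=9))
        assert np.all(s.effects[:, 3] == 0.0)


class TestSamplerRecovery:
    def test_breeding_value_recovery(self):
        y, Z, qtl, g = _sim_xy(300, 500, 0.5, 20, 10)
        cfg = BayesBConfig(pi=0.98, n_iter=3000, burn_in=500, thin=10,
                           expected_h2=0.5, seed=11)
        s = fit_bayesb(y, np.ones((300, 1)), Z, cfg)
        ghat = s.genetic_values().mean(axis=1)
        assert np.corrcoef(ghat, g)[0, 1] > 0.5

    def test_reproducible_and_cross_seed_consistent(self):
        y, Z, _, _ = _sim_xy(150, 200, 0.5, 5, 12)
        cfg = dict(pi=0.98, n_iter=3000, burn_in=500, thin=5, expected_h2=0.5)
        s1 = fit_bayesb(y, np.ones((150, 1)), Z, BayesBConfig(**cfg, seed=13))
        s1b = fit_bayesb(y, np.ones((150, 1)), Z, BayesBConfig(**cfg, seed=13))
        np.testing.assert_array_equal(s1.effects, s1b.effects)
        s2 = fit_bayesb(y, np.ones((150, 1)), Z, BayesBConfig(**cfg, seed=14))
        v1 = s1.genetic_values().var(axis=0)
        v2 = s2.genetic_values().var(axis=0)
        assert gelman_rubin([v1, v2]) < 1.1

    def test_inclusion_count_tracks_prior_under_null(self):
        rng = np.random.default_rng(15)
        k, n = 400, 200
        codes = rng.binomial(2, 0.3, size=(n, k)).astype(np.int8)
        Z = encode_centered(codes)
        y = rng.normal(size=n)
        pi = 0.95
        s = fit_bayesb(y, np.ones((n, 1)), Z,
                       BayesBConfig(pi=pi, n_iter=3000, burn_in=500, thin=5, seed=16))
        mean_inc = s.included_per_state().mean()
        expect = k * (1 - pi)
        assert abs(mean_inc - expect) < 4 * np.sqrt(k * pi * (1 - pi))


class TestWindows:
    def test_megabase_boundary(self):
        mm = _map_frame([1, 1], [999_999, 1_000_001])
        w = make_windows(mm)
        assert w.n_windows == 2

    def test_single_window(self):
        mm = _map_frame([1, 1, 1], [10, 500_000, 999_999])
        assert make_windows(mm).n_windows == 1

    def test_random_assignment_matches_floor_oracle(self):
        rng = np.random.default_rng(17)
        pos = np.sort(rng.integers(1, 50_000_000, 200))
        mm = _map_frame([1] * 200, pos)
        w = make_windows(mm)
        oracle_bins = (pos - 1) // 1_000_000
        for j in range(200):
            chrom, b, idx = w.windows[w.labels[j]]
            assert b == oracle_bins[j]
            assert j in idx

    def test_unmapped_markers_excluded(self):
        mm = _map_frame([1, "U", 2], [100, 200, 300])
        w = make_windows(mm)
        assert w.labels[1] == -1
        assert w.n_windows == 2

    def test_expected_share_report_values(self):
        assert round(expected_window_share(2815), 2) == 0.04
        assert expected_window_share(1) == 100.0
        assert expected_window_share(200) == 0.5
        with pytest.raises(ValueError):
            expected_window_share(0)


class TestWindowSummaries:
    def test_planted_qtl_window_ranks_first(self):
        rng = np.random.default_rng(18)
        n, k = 300, 400
        codes = rng.binomial(2, rng.uniform(0.2, 0.5, k), size=(n, k)).astype(np.int8)
        Z = encode_centered(codes)
        g = Z[:, 200] * 1.0  # one large QTL
        g = g / g.std() * np.sqrt(0.45)
        y = g + rng.normal(0, np.sqrt(0.55), n)
        pos = np.arange(k) * 250_000 + 1  # 4 SNPs per Mb window
        mm = _map_frame([1] * k, pos)
        cfg = BayesBConfig(pi=0.99, n_iter=4000, burn_in=500, thin=10, expected_h2=0.45, seed=19)
        s = fit_bayesb(y, np.ones((n, 1)), Z, cfg)
        wins = summarize_windows(s, make_windows(mm), mm)
        top = wins.sort_values("pct_genetic_variance", ascending=False).iloc[0]
        assert 200 in [int(x[1:]) for x in top["snp_ids"].split(";")]
        assert top["ppa"] > 0.9
        assert top["candidate"]

    def test_window_without_included_snps_is_zero(self):
        y, Z, _, _ = _sim_xy(80, 12, 0.5, 1, 20)
        mm = _map_frame([1] * 12, np.arange(12) * 2_000_000 + 1)
        s = fit_bayesb(y, np.ones((80, 1)), Z,
                       BayesBConfig(pi=1.0, n_iter=300, burn_in=100, thin=2, seed=21))
        wins = summarize_windows(s, make_windows(mm), mm)
        assert (wins["pct_genetic_variance"] == 0).all()
        assert (wins["ppa"] == 0).all()

    def test_candidate_calls_invariant_to_snp_order_within_window(self):
        y, Z, _, _ = _sim_xy(150, 40, 0.5, 4, 22)
        pos = np.arange(40) * 100_000 + 1
        mm = _map_frame([1] * 40, pos)
        cfg = BayesBConfig(pi=0.9, n_iter=1500, burn_in=300, thin=5, seed=23)
        s = fit_bayesb(y, np.ones((150, 1)), Z, cfg)
        w = make_windows(mm)
        wins1 = summarize_windows(s, w, mm)
        # permute SNPs within each window consistently in Z, labels, samples
        perm = np.arange(40)
        for _, _, idx in w.windows:
            perm[idx] = idx[::-1]
        s2 = type(s)(effects=s.effects[:, perm], fixed=s.fixed, sigma2_e=s.sigma2_e,
                     Z=s.Z[:, perm], config=s.config)
        w2 = make_windows(_map_frame([1] * 40, pos[np.argsort(perm, kind="stable")]))
        wins2 = summarize_windows(s2, w, mm)
        np.testing.assert_allclose(
            wins1["pct_genetic_variance"], wins2["pct_genetic_variance"], atol=1e-12
        )
        assert wins1["candidate"].equals(wins2["candidate"])


class TestHeritability:
    def test_recovery_within_tolerance(self):
        y, Z, _, _ = _sim_xy(400, 600, 0.5, 20, 24)
        cfg = BayesBConfig(pi=0.97, n_iter=3000, burn_in=500, thin=10, expected_h2=0.4, seed=25)
        s = fit_bayesb(y, np.ones((400, 1)), Z, cfg)
        h2 = genomic_heritability(s)
        assert abs(h2["mean"] - 0.5) < 0.12
        assert h2["lower95"] <= h2["mean"] <= h2["upper95"]

    def test_duplicated_data_shifts_little(self):
        # at a data-dominated n/k ratio the posterior is insensitive to
        # duplicating every observation
        y, Z, _, _ = _sim_xy(400, 100, 0.5, 10, 26)
        cfg = dict(pi=0.95, n_iter=3000, burn_in=500, thin=10, expected_h2=0.5)
        s1 = fit_bayesb(y, np.ones((400, 1)), Z, BayesBConfig(**cfg, seed=27))
        y2 = np.concatenate([y, y])
        Z2 = np.vstack([Z, Z])
        s2 = fit_bayesb(y2, np.ones((800, 1)), Z2, BayesBConfig(**cfg, seed=28))
        h1 = genomic_heritability(s1)["mean"]
        h2v = genomic_heritability(s2)["mean"]
        assert abs(h1 - h2v) < 0.06
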