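"""Gibbs sampler machinery: truncated-normal draws, determinism, constraint
masks, chain bookkeeping, Gaussian-submodel oracles and error handling."""

import numpy as np
import pandas as pd
import pytest

import thresholdsire as ts
from thresholdsire.model import chain_plan, restrict_to_sires, sample_truncated_normal
from thresholdsire.simulate import SimConfig, simulate_pedigree, simulate_records, sire_map


class TestTruncatedNormal:
    def test_left_tail_moment_matches_closed_form(self):
        # standard normal truncated to (-inf, 0): mean = -sqrt(2/pi)
        rng = np.random.default_rng(0)
        n = 100_000
        x = sample_truncated_normal(
            np.zeros(n), 1.0, np.full(n, -np.inf), np.zeros(n), rng
        )
        expect = -np.sqrt(2 / np.pi)
        se = np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert x.mean() == pytest.approx(expect, abs=3 * se)

    def test_support_respected(self):
        rng = np.random.default_rng(1)
        x = sample_truncated_normal(
            np.zeros(1000), 1.0, np.zeros(1000), np.full(1000, np.inf), rng
        )
        assert np.all(x > 0)
        y = sample_truncated_normal(
            np.full(500, 2.0), 0.5, np.full(500, 1.0), np.full(500, 3.0), rng
        )
        assert np.all((y >= 1.0) & (y <= 3.0))

    def test_deterministic_given_seed(self):
        a = sample_truncated_normal(
            np.zeros(100), 1.0, -np.inf, 0.0, np.random.default_rng(7)
        )
        b = sample_truncated_normal(
            np.zeros(100), 1.0, -np.inf, 0.0, np.random.default_rng(7)
        )
        np.testing.assert_array_equal(a, b)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            sample_truncated_normal(
                np.zeros(3), 1.0, np.ones(3), np.zeros(3), np.random.default_rng(0)
            )


class TestChainPlan:
    def test_study_default_gives_5000(self):
        assert chain_plan(300_000, 50_000, 50) == 5000

    def test_small_config(self):
        assert chain_plan(1000, 100, 10) == 90

    def test_invalid(self):
        with pytest.raises(ValueError):
            chain_plan(100, 0, 0)


class TestCovarianceSet:
    def test_full_R_mask(self):
        cov = ts.CovarianceSet.default_start()
        R = cov.full_R()
        assert R[0, 1] == 0.0 and R[0, 2] == 0.0
        assert R[1, 0] == 0.0 and R[2, 0] == 0.0

    def test_non_pd_rejected(self):
        cov = ts.CovarianceSet.default_start()
        cov.H = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            cov.validate()


class TestFitMechanics:
    def test_reproducible_given_seed(self, small_sim):
        model = ts.ThresholdSireModel(small_sim["stacked"], small_sim["ped"], trait="TS")
        r1 = model.fit(n_iter=120, burn_in=40, thin=2, seed=3)
        r2 = model.fit(n_iter=120, burn_in=40, thin=2, seed=3)
        pd.testing.assert_frame_equal(r1.draws, r2.draws)

    def test_different_seeds_differ(self, small_sim):
        model = ts.ThresholdSireModel(small_sim["stacked"], small_sim["ped"], trait="TS")
        r1 = model.fit(n_iter=60, burn_in=20, thin=2, seed=3)
        r2 = model.fit(n_iter=60, burn_in=20, thin=2, seed=4)
        assert not r1.draws.equals(r2.draws)

    def test_constraint_mask_and_support_every_stored_draw(self, short_fit):
        d = short_fit.draws
        # liability residual positive; thresholds strictly above the pinned
        # cut at 1; production covariances give PD 2x2 blocks
        assert (d["res_teat_teat"] > 0).all()
        assert (d["cut3"] > 1.0).all()
        det = d["res_my_my"] * d["res_scs_scs"] - d["res_my_scs"] ** 2
        assert (det > 0).all()
        for eff in ("herd", "pe", "sire"):
            r = d[f"{eff}_teat_my"] / np.sqrt(d[f"{eff}_teat_teat"] * d[f"{eff}_my_my"])
            assert (np.abs(r) <= 1).all()

    def test_zero_length_chain_returns_start(self, small_sim):
        model = ts.ThresholdSireModel(small_sim["stacked"], small_sim["ped"], trait="TS")
        start = ts.CovarianceSet.default_start()
        res = model.fit(n_iter=0, burn_in=0, thin=1, seed=0, start=start)
        assert res.n_stored == 0
        np.testing.assert_allclose(res.final_cov.H, start.H)

    def test_row_order_invariant_sufficient_statistics(self, small_sim):
        stacked = small_sim["stacked"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(stacked.df))
        shuffled = ts.StackedData(
            df=stacked.df.iloc[perm].reset_index(drop=True),
            herd_levels=stacked.herd_levels,
            cow_levels=stacked.cow_levels,
            sire_levels=stacked.sire_levels,
        )
        m1 = ts.ThresholdSireModel(stacked, small_sim["ped"], trait="TS")
        m2 = ts.ThresholdSireModel(shuffled, small_sim["ped"], trait="TS")
        np.testing.assert_allclose(m1.X0tX0, m2.X0tX0, atol=1e-9)
        np.testing.assert_allclose(m1.Ainv_ss, m2.Ainv_ss, atol=1e-9)
        np.testing.assert_allclose(m1.ps_weights_t, m2.ps_weights_t, atol=1e-12)

    def test_binary_scheme_fixes_residual_at_one(self, small_sim):
        cfg = SimConfig(n_herds=6, n_cows=120, n_sires=25, n_base_dams=100,
                        seed=1, trait="TSa")
        ped = simulate_pedigree(cfg)
        tb, pb, _ = simulate_records(cfg, ped)
        st = ts.stack_datasets(tb, pb, sire_map(ped))
        model = ts.ThresholdSireModel(st, ped, trait="TSa")
        res = model.fit(n_iter=100, burn_in=20, thin=2, seed=0)
        assert (res.draws["res_teat_teat"] == 1.0).all()
        assert "cut3" not in res.draws.columns

    def test_empty_category_advises_collapse(self, small_sim):
        stacked = small_sim["stacked"]
        df = stacked.df.copy()
        df.loc[(df["block"] == "teat") & (df["score"] == 4), "score"] = 3
        broken = ts.StackedData(df, stacked.herd_levels, stacked.cow_levels,
                                stacked.sire_levels)
        with pytest.raises(ValueError, match="collapse"):
            ts.ThresholdSireModel(broken, small_sim["ped"], trait="TS")

    def test_unknown_trait_rejected(self, small_sim):
        with pytest.raises(ValueError):
            ts.ThresholdSireModel(small_sim["stacked"], small_sim["ped"], trait="TSx")

    def test_sires_only_relationship_option(self, small_sim):
        m_full = ts.ThresholdSireModel(small_sim["stacked"], small_sim["ped"], trait="TS")
        m_sub = ts.ThresholdSireModel(
            small_sim["stacked"], small_sim["ped"], trait="TS", sires_only=True
        )
        # sires relate only through their own ancestors, so both routes agree
        np.testing.assert_allclose(m_full.A_ss, m_sub.A_ss, atol=1e-10)

    def test_restrict_to_sires_keeps_ancestors_only(self, small_sim):
        ped = small_sim["ped"]
        sires = small_sim["stacked"].sire_levels
        sub = restrict_to_sires(ped, sires)
        assert set(sires) <= set(sub.ids)
        assert not any(str(i).startswith("C") for i in sub.ids)


class TestGaussianSubmodelOracle:
    """With the teat block absent the model is a bi-variate Gaussian mixed
    model; at fixed (true) covariance components the posterior mean of a
    fixed effect has the GLS closed form."""

    def _bivariate_data(self, seed=0, n_cows=60, n_td=4):
        cfg = SimConfig(n_herds=5, n_cows=n_cows, n_sires=15, n_base_dams=50,
                        seed=seed, testday_mean=n_td, testday_sd=0.0)
        ped = simulate_pedigree(cfg)
        tb, pb, truth = simulate_records(cfg, ped)
        st = ts.stack_datasets(tb, pb.iloc[0:0], sire_map(ped))
        # production-only stack: drop teat rows, keep the production rows
        st_p = ts.stack_datasets(tb, pb, sire_map(ped))
        df = st_p.df[st_p.df["block"] == "prod"].reset_index(drop=True)
        prod_only = ts.StackedData(df, st_p.herd_levels, st_p.cow_levels,
                                   st_p.sire_levels)
        return prod_only, ped, truth

    def test_fixed_effect_posterior_mean_matches_gls(self):
        prod_only, ped, truth = self._bivariate_data()
        cov = truth["covariances"]
        model = ts.ThresholdSireModel(prod_only, ped, trait="TSa")
        res = model.fit(n_iter=4000, burn_in=1000, thin=2, seed=1,
                        fix_covariances=cov)

        # GLS oracle: dense V over the stacked bivariate observations
        df = prod_only.df[prod_only.df["block"] == "prod"]
        n = len(df)
        y = np.concatenate([df["my"].to_numpy(), df["scs"].to_numpy()])
        herd = df["herd_i"].to_numpy()
        cow = df["cow_i"].to_numpy()
        sire_levels = {s: i for i, s in enumerate(prod_only.sire_levels)}
        sire = np.array([sire_levels[s] for s in df["sire"]])
        ps = df["ps"].to_numpy()
        A = ped.relationship_matrix()
        pos = ped.index_of(prod_only.sire_levels)
        A_ss = A[np.ix_(pos, pos)]

        def block(Zidx, K, rel=None):
            same = rel if rel is not None else (Zidx[:, None] == Zidx[None, :]).astype(float)
            V = np.zeros((2 * n, 2 * n))
            for a in range(2):
                for b in range(2):
                    V[a * n:(a + 1) * n, b * n:(b + 1) * n] = same * K[a + 1, b + 1]
            return V

        V = block(herd, cov.H) + block(cow, cov.P)
        V += block(sire, cov.S, rel=A_ss[np.ix_(sire, sire)])
        for a in range(2):
            for b in range(2):
                V[a * n:(a + 1) * n, b * n:(b + 1) * n] += np.eye(n) * cov.Rprod[a, b]
        classes = np.unique(ps)
        X = np.zeros((2 * n, 2 * len(classes)))
        for k, c in enumerate(classes):
            X[:n, 2 * k] = ps == c
            X[n:, 2 * k + 1] = ps == c
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        C = np.linalg.inv(XtVi @ X)
        beta = C @ (XtVi @ y)

        # with a flat prior and known covariances the posterior of the fixed
        # effects is exactly N(beta_GLS, C); compare every class mean within
        # Monte-Carlo error of the (autocorrelated) chain
        for k, c in enumerate(classes):
            for off, lab in ((0, "my"), (1, "scs")):
                d = res.draws[f"b_{lab}:ps{c + 1}"].to_numpy()
                se = np.sqrt(C[2 * k + off, 2 * k + off])
                mc_tol = 6 * se / np.sqrt(len(d) / 10)  # conservative ESS
                assert d.mean() == pytest.approx(beta[2 * k + off], abs=max(mc_tol, 0.05)), (
                    f"class {c + 1} {lab}"
                )

    def test_reml_oracle_variance_recovery_univariate(self):
        # MY-only submodel vs REML (statsmodels MixedLM, cow random intercept)
        import statsmodels.formula.api as smf

        prod_only, ped, truth = self._bivariate_data(seed=3, n_cows=120, n_td=6)
        model = ts.ThresholdSireModel(prod_only, ped, trait="TSa")
        res = model.fit(n_iter=3000, burn_in=800, thin=2, seed=2)
        df = prod_only.df[prod_only.df["block"] == "prod"].copy()
        df["ps"] = df["ps"].astype("category")
        reml = smf.mixedlm("my ~ C(ps)", df, groups=df["cow_i"]).fit(reml=True)
        pe_reml = float(reml.cov_re.iloc[0, 0])
        # the Gibbs model splits cow-level variance over cow + herd + sire
        pe_gibbs = (
            res.component_draws("pe", "my")
            + res.component_draws("herd", "my")
            + res.component_draws("sire", "my")
        )
        lo, hi = ts.hpd_interval(pe_gibbs, 0.99)
        assert lo <= pe_reml * 1.3 and hi >= pe_reml * 0.7
        # residual variances agree more tightly
        res_gibbs = res.component_draws("res", "my").mean()
        assert res_gibbs == pytest.approx(reml.scale, rel=0.2)


def test_four_class_heritability_recovery_long_chain():
    """One 20,000-iteration chain on 4-class synthetic data at the published
    truth: the teat heritability (truth 0.238) must fall in its 95% HPD.
    The free-threshold update mixes slowly, hence the longer single chain
    rather than many short replicates."""
    cfg = SimConfig(n_herds=24, n_cows=400, n_sires=60, n_base_dams=300,
                    seed=0, score_month_max=4, trait="TS")
    ped = simulate_pedigree(cfg)
    teat, prod, truth = simulate_records(cfg, ped)
    stacked = ts.stack_datasets(teat, prod, sire_map(ped))
    model = ts.ThresholdSireModel(stacked, ped, trait="TS")
    res = model.fit(n_iter=20_000, burn_in=5_000, thin=10, seed=11)
    h2 = ts.heritability(
        res.component_draws("sire", "teat"),
        res.component_draws("pe", "teat"),
        res.component_draws("herd", "teat"),
        res.component_draws("res", "teat"),
    )
    lo, hi = ts.hpd_interval(h2, 0.95)
    cv = truth["covariances"]
    h2_true = float(ts.heritability(cv.S[0, 0], cv.P[0, 0], cv.H[0, 0], cv.r11))
    assert lo <= h2_true <= hi


def test_results_summary_layout(short_fit):
    summ = short_fit.summary()
    assert {"parameter", "trait", "mean", "hpd_low", "hpd_high", "geweke_z"} <= set(summ.columns)
    traits = summ[summ["parameter"] == "heritability"]["trait"].tolist()
    assert traits == ["teat", "my", "scs"]
    assert (summ["hpd_low"] <= summ["mean"]).all()
    assert (summ["mean"] <= summ["hpd_high"]).all()


def test_lsm_probability_levels(short_fit):
    lsm = short_fit.lsm_probability("qtr", above=1)
    assert set(lsm["level"]) == {"FL", "FR", "RL", "RR"}
    assert ((lsm["mean"] > 0) & (lsm["mean"] < 1)).all()
    lsm2 = short_fit.lsm_probability("hyg", above=2)
    # P(score>2) <= P(score>1) on average
    assert lsm2["mean"].mean() < lsm["mean"].mean()
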