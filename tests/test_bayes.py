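"""Conjugate NIG updating, Savage-Dickey Bayes factors, window detection,
MVNIG regression, and the Monte-Carlo effect-size comparison."""

import numpy as np
import pytest
from scipy import stats

from intersep.bayes import (
    EvidenceTrace,
    NIGPrior,
    bf10_vs_zero,
    ceiling_filter,
    detect_windows,
    evidence_trace,
    monte_carlo_effect_comparison,
    mvnig_regression,
    nig_update,
)


def numerical_bf10(prior: NIGPrior, y: np.ndarray) -> float:
    """Independent oracle: marginal-likelihood ratio by grid integration
    over (mu, sigma^2).  m1 integrates the NIG prior; m0 fixes mu = 0 and
    puts the prior's conditional distribution of sigma^2 given mu = 0 on
    the variance (IG(alpha + 1/2, beta) - the nesting under which the
    Savage-Dickey density ratio is the Bayes factor)."""
    y = np.asarray(y, float)
    n, s1, s2sum = len(y), y.sum(), (y**2).sum()
    sig2 = np.exp(np.linspace(np.log(1e-3), np.log(1e3), 4000))
    log_ig = stats.invgamma.logpdf(sig2, prior.alpha, scale=prior.beta)
    log_ig0 = stats.invgamma.logpdf(sig2, prior.alpha + 0.5, scale=prior.beta)
    mus = np.linspace(-5, 5, 2001)

    def loglik(mu, s2):
        # sum_i log N(y_i | mu, s2) via sufficient statistics
        return -0.5 * n * np.log(2 * np.pi * s2) - (
            s2sum - 2 * mu * s1 + n * mu**2
        ) / (2 * s2)

    # m0: integrate over sigma^2 only
    m0 = np.trapezoid(np.exp(loglik(0.0, sig2) + log_ig0), sig2)
    # m1: joint grid over (mu, sigma^2), Gaussian prior on mu given sigma^2
    lp = loglik(mus[:, None], sig2[None, :]) + stats.norm.logpdf(
        mus[:, None], prior.mu0, np.sqrt(sig2 / prior.v)[None, :]
    )
    inner = np.trapezoid(np.exp(lp), mus, axis=0)
    m1 = np.trapezoid(inner * np.exp(log_ig), sig2)
    return m1 / m0


class TestNIGUpdate:
    def test_no_observations_returns_prior(self):
        prior = NIGPrior()
        post = nig_update(prior, [])
        assert (post.mu_n, post.v_n, post.alpha_n, post.beta_n) == (0.0, 30.0, 15.0, 15.0)

    def test_sequential_equals_batch(self, rng):
        """Conjugacy: one-at-a-time updating in any order equals the batch
        formula to near machine precision."""
        prior = NIGPrior()
        y = rng.normal(0.4, 0.2, 25)
        batch = nig_update(prior, y)
        # sequential: fold each observation in via sufficient statistics
        state = prior
        for yi in rng.permutation(y):
            post = nig_update(
                NIGPrior(state.mu0, state.v, state.alpha, state.beta)
                if isinstance(state, NIGPrior)
                else NIGPrior(state.mu_n, state.v_n, state.alpha_n, state.beta_n),
                [yi],
            )
            state = post
        assert state.mu_n == pytest.approx(batch.mu_n, abs=1e-12)
        assert state.v_n == pytest.approx(batch.v_n, abs=1e-12)
        assert state.alpha_n == pytest.approx(batch.alpha_n, abs=1e-12)
        assert state.beta_n == pytest.approx(batch.beta_n, abs=1e-12)

    def test_posterior_mean_matches_grid_posterior(self, rng):
        """mu_n agrees with a brute-force grid posterior mean."""
        prior = NIGPrior()
        y = rng.normal(0.5, 0.1, 10)
        post = nig_update(prior, y)
        mus = np.linspace(-2, 2, 3000)
        sig2 = np.exp(np.linspace(np.log(1e-3), np.log(1e2), 1500))
        log_post = (
            stats.norm.logpdf(y[:, None, None], mus[None, :, None], np.sqrt(sig2)[None, None, :]).sum(axis=0)
            + stats.norm.logpdf(mus[:, None], prior.mu0, np.sqrt(sig2 / prior.v)[None, :])
            + stats.invgamma.logpdf(sig2, prior.alpha, scale=prior.beta)[None, :]
        )
        w = np.exp(log_post - log_post.max())
        grid_mean = (mus[:, None] * w).sum() / w.sum()
        assert post.mu_n == pytest.approx(grid_mean, abs=1e-3)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="index 2"):
            nig_update(NIGPrior(), [0.1, 0.2, np.nan])


class TestSavageDickey:
    def test_prior_equals_posterior_gives_bf_one(self):
        prior = NIGPrior()
        post = nig_update(prior, [])
        assert bf10_vs_zero(prior, post) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_numerical_oracle(self, seed):
        """Savage-Dickey BF10 matches the marginal-likelihood ratio from
        numerical integration within 1% on small-n cases."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        mu = rng.uniform(-0.8, 0.8)
        sd = rng.uniform(0.2, 1.5)
        y = rng.normal(mu, sd, n)
        prior = NIGPrior()
        bf = bf10_vs_zero(prior, nig_update(prior, y))
        assert bf == pytest.approx(numerical_bf10(prior, y), rel=0.01)

    def test_strong_positive_data_exceeds_threshold(self, rng):
        y = rng.normal(1.5, 0.5, 36)
        prior = NIGPrior()
        assert bf10_vs_zero(prior, nig_update(prior, y)) > 3.0

    def test_null_centered_data_supports_null(self, rng):
        y = rng.normal(0.0, 0.01, 36)
        prior = NIGPrior()
        assert bf10_vs_zero(prior, nig_update(prior, y)) < 1.0

    def test_monotone_in_sample_mean(self, rng):
        """BF10 increases with |mean| at fixed n and spread."""
        prior = NIGPrior()
        noise = rng.normal(0, 1.0, 200)
        bfs = []
        for m in np.linspace(0.0, 2.0, 9):
            y = m + noise - noise.mean()  # exact mean m, fixed spread
            bfs.append(bf10_vs_zero(prior, nig_update(prior, y)))
        assert np.all(np.diff(bfs) > 0)


class TestEvidenceTraceAndWindows:
    def _trace(self, bf, mu, dt=0.02):
        n = len(bf)
        ones = np.ones(n)
        return EvidenceTrace(
            times_s=np.arange(n) * dt, mu_n=np.asarray(mu, float), v_n=ones,
            alpha_n=ones, beta_n=ones, bf10=np.asarray(bf, float), n_obs=ones,
            mean_contrast=np.asarray(mu, float),
        )

    def test_all_subthreshold_yields_no_windows(self):
        tr = self._trace(np.full(50, 2.9), np.ones(50))
        assert detect_windows(tr) == []

    def test_duration_rule(self):
        """4-sample (0.08 s) runs are dropped; 7-sample (0.14 s) runs kept."""
        bf = np.ones(40)
        bf[5:9] = 5.0  # 4 samples = 0.08 s
        bf[20:27] = 5.0  # 7 samples = 0.14 s
        tr = self._trace(bf, np.ones(40))
        wins = detect_windows(tr)
        assert len(wins) == 1
        assert wins[0]["start_s"] == pytest.approx(0.40)
        assert wins[0]["end_s"] == pytest.approx(0.54)

    def test_runs_split_by_subthreshold_gap(self):
        bf = np.ones(60)
        bf[10:20] = 4.0
        bf[21:31] = 4.0  # one sub-threshold sample between
        tr = self._trace(bf, np.ones(60))
        assert len(detect_windows(tr)) == 2

    def test_runs_split_by_sign_change(self):
        bf = np.full(30, 5.0)
        mu = np.ones(30)
        mu[15:] = -1.0
        wins = detect_windows(self._trace(bf, mu))
        assert [w["sign"] for w in wins] == ["similarity", "dissimilarity"]

    def test_idempotent_and_padding_invariant(self):
        bf = np.ones(50)
        bf[10:20] = 4.0
        tr = self._trace(bf, np.ones(50))
        w1 = detect_windows(tr)
        w2 = detect_windows(tr)
        assert w1 == w2
        padded = self._trace(np.concatenate([np.ones(7), bf]), np.ones(57))
        w3 = detect_windows(padded)
        assert len(w3) == 1 and w3[0]["end_s"] - w3[0]["start_s"] == pytest.approx(
            w1[0]["end_s"] - w1[0]["start_s"]
        )

    def test_trace_matches_scalar_update(self, rng):
        """The vectorized per-timepoint trace equals scalar nig_update."""
        Y = rng.normal(0.1, 0.3, (20, 5))
        Y[3, 2] = np.nan
        tr = evidence_trace(Y, np.arange(5) * 0.02)
        for t in range(5):
            col = Y[:, t]
            post = nig_update(NIGPrior(), col[np.isfinite(col)])
            assert tr.mu_n[t] == pytest.approx(post.mu_n, abs=1e-12)
            assert tr.beta_n[t] == pytest.approx(post.beta_n, abs=1e-12)
            assert tr.bf10[t] == pytest.approx(
                bf10_vs_zero(NIGPrior(), post), rel=1e-10
            )


class TestMVNIGRegression:
    def test_flat_prior_limit_recovers_least_squares(self, rng):
        X = np.linalg.qr(rng.standard_normal((50, 3)))[0]  # orthonormal columns
        y = rng.standard_normal(50)
        res = mvnig_regression(y, X, lambda_scale=1e-12, standardize=False)
        ols = np.linalg.lstsq(np.column_stack([X, np.ones(50)]), y, rcond=None)[0]
        np.testing.assert_allclose(res.betas, ols, atol=1e-8)

    def test_planted_effect_recovered(self, rng):
        n = 600
        x = rng.standard_normal(n)
        y = 0.3 * x + rng.standard_normal(n) * np.sqrt(1 - 0.09)
        res = mvnig_regression(y, x[:, None], ["effect"])
        assert abs(res.betas[0] - 0.3) < 0.1
        assert res.bf10[0] > 3.0

    def test_null_rarely_flagged(self):
        flagged = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            y = r.standard_normal(600)
            X = np.column_stack([r.standard_normal(600), r.integers(1, 5, 600)])
            res = mvnig_regression(y, X, ["effect", "repetition"])
            flagged += res.bf10[0] >= 3.0
        assert flagged <= 5  # <= 10% of runs

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(ValueError, match="collinear"):
            mvnig_regression(rng.standard_normal(30), X, ["a", "b"])

    def test_constant_predictor_rejected(self, rng):
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        with pytest.raises(ValueError, match="constant"):
            mvnig_regression(rng.standard_normal(30), X, ["const", "x"])

    def test_requires_more_trials_than_predictors(self, rng):
        with pytest.raises(ValueError, match="n > p"):
            mvnig_regression(rng.standard_normal(3), rng.standard_normal((3, 5)))


def test_ceiling_filter_excludes_high_accuracy_participants():
    import pandas as pd

    t = pd.DataFrame(
        {
            "participant": np.repeat([0, 1, 2], 20),
            "ac_correct": np.concatenate([np.ones(20), np.r_[np.ones(19), 0], np.r_[np.ones(10), np.zeros(10)]]),
        }
    )
    kept, excluded = ceiling_filter(t, "ac_correct", 0.9)
    assert excluded == [0, 1]  # 100% and 95% accuracy are above the 90% cap
    assert set(kept["participant"]) == {2}


class TestMonteCarloComparison:
    def test_identical_conditions_give_p_near_one(self):
        df = monte_carlo_effect_comparison(
            {"a": 0.5, "b": 0.5}, {"a": 0.1, "b": 0.1}, seed=0
        )
        assert df.loc[0, "p_two_tailed"] == pytest.approx(1.0, abs=0.05)

    def test_distant_conditions_give_small_p(self):
        df = monte_carlo_effect_comparison(
            {"a": 1.0, "b": 0.0}, {"a": 0.1, "b": 0.1}, seed=0
        )
        assert df.loc[0, "p_two_tailed"] < 0.001
        assert bool(df.loc[0, "significant_0.05"])

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            monte_carlo_effect_comparison({"a": 1.0, "b": 0.0}, {"a": 0.0, "b": 0.1})
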