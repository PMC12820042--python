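"""Conjugate Bayesian evidence accumulation and trial-level regression.

The per-timepoint similarity contrast is tested against zero with a
Normal-Inverse-Gamma (NIG) model: the prior (mu0 = 0, v = 30, alpha = 15,
beta = 15) treats the mean as worth 30 pseudo-observations around zero
with a residual scale near 1, a deliberately skeptical choice that
controls false discoveries across the many timepoints.  The conjugate
update is order-invariant, so "consecutive" updating over observations
equals the batch formula.  Evidence for a nonzero mean is the
Savage-Dickey density ratio: the marginal distribution of the mean is a
scaled Student t (df = 2 alpha, scale = sqrt(beta / (alpha v))) under both
prior and posterior, and BF10 is their density ratio at zero.  Only
supra-threshold (BF10 >= 3) runs of consistent sign longer than 0.1 s
count as detected (dis)similarity windows.

Trial-level regression uses the multivariate analogue (MVNIG, precision
lambda = 30 I) with standardized variables and per-coefficient
Savage-Dickey Bayes factors.  A Monte-Carlo routine compares effect sizes
across conditions by sampling their estimate/SE distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NIGPrior:
    mu0: float = 0.0
    v: float = 30.0
    alpha: float = 15.0
    beta: float = 15.0

    def __post_init__(self):
        if self.v <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("v, alpha, beta must all be positive")


@dataclass
class NIGPosterior:
    mu_n: float
    v_n: float
    alpha_n: float
    beta_n: float


def nig_update(prior: NIGPrior, observations) -> NIGPosterior:
    """Standard conjugate NIG update with the data as i.i.d. normal
    observations.  n = 0 returns the prior unchanged."""
    y = np.asarray(observations, float).ravel()
    if y.size and not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        raise ValueError(f"non-finite observation at index {bad}")
    n = y.size
    if n == 0:
        return NIGPosterior(prior.mu0, prior.v, prior.alpha, prior.beta)
    ybar = y.mean()
    v_n = prior.v + n
    mu_n = (prior.v * prior.mu0 + n * ybar) / v_n
    alpha_n = prior.alpha + n / 2.0
    beta_n = (
        prior.beta
        + 0.5 * np.sum((y - ybar) ** 2)
        + (n * prior.v / (2.0 * v_n)) * (ybar - prior.mu0) ** 2
    )
    return NIGPosterior(mu_n, v_n, alpha_n, beta_n)


def _mu_marginal_logpdf(x, mu, v, alpha, beta):
    """Marginal density of the mean: scaled t(2 alpha, mu, sqrt(beta/(alpha v)))."""
    scale = np.sqrt(beta / (alpha * v))
    return stats.t.logpdf(x, df=2.0 * alpha, loc=mu, scale=scale)


def bf10_vs_zero(prior: NIGPrior, posterior: NIGPosterior) -> float:
    """Savage-Dickey Bayes factor for mean != 0: prior over posterior
    marginal density at zero.  Equals 1 when posterior == prior."""
    if posterior.beta_n <= 0 or posterior.v_n <= 0:
        raise ValueError("degenerate posterior scale")
    lp0 = _mu_marginal_logpdf(0.0, prior.mu0, prior.v, prior.alpha, prior.beta)
    lp1 = _mu_marginal_logpdf(
        0.0, posterior.mu_n, posterior.v_n, posterior.alpha_n, posterior.beta_n
    )
    return float(np.exp(lp0 - lp1))


@dataclass
class EvidenceTrace:
    """Per-timepoint posterior parameters, BF10, and detected windows."""

    times_s: np.ndarray
    mu_n: np.ndarray
    v_n: np.ndarray
    alpha_n: np.ndarray
    beta_n: np.ndarray
    bf10: np.ndarray
    n_obs: np.ndarray
    mean_contrast: np.ndarray
    windows: list[dict] = field(default_factory=list)


def evidence_trace(
    observations: np.ndarray, times_s: np.ndarray, prior: NIGPrior | None = None
) -> EvidenceTrace:
    """NIG update at every timepoint of ``observations``
    (n_observations x n_timepoints, NaN = missing) and Savage-Dickey BF10
    against zero, vectorized over timepoints."""
    prior = prior or NIGPrior()
    Y = np.asarray(observations, float)
    finite = np.isfinite(Y)
    n = finite.sum(axis=0).astype(float)
    Ysafe = np.where(finite, Y, 0.0)
    s1 = Ysafe.sum(axis=0)
    s2 = (Ysafe**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ybar = np.where(n > 0, s1 / np.maximum(n, 1), 0.0)
    v_n = prior.v + n
    mu_n = (prior.v * prior.mu0 + n * ybar) / v_n
    alpha_n = prior.alpha + n / 2.0
    sse = np.maximum(s2 - n * ybar**2, 0.0)
    beta_n = prior.beta + 0.5 * sse + (n * prior.v / (2.0 * v_n)) * (ybar - prior.mu0) ** 2
    lp0 = _mu_marginal_logpdf(0.0, prior.mu0, prior.v, prior.alpha, prior.beta)
    lp1 = _mu_marginal_logpdf(0.0, mu_n, v_n, alpha_n, beta_n)
    bf10 = np.exp(lp0 - lp1)
    return EvidenceTrace(
        times_s=np.asarray(times_s),
        mu_n=mu_n,
        v_n=v_n,
        alpha_n=alpha_n,
        beta_n=beta_n,
        bf10=bf10,
        n_obs=n,
        mean_contrast=ybar,
    )


def detect_windows(
    trace: EvidenceTrace, threshold: float = 3.0, min_duration_s: float = 0.1
) -> list[dict]:
    """Maximal runs with BF10 >= threshold and consistent contrast sign;
    runs of duration <= min_duration_s are dropped.  Each window carries
    its extent, sign label and mean contrast."""
    bf = np.asarray(trace.bf10)
    t = np.asarray(trace.times_s)
    if len(t) > 1:
        dt = float(t[1] - t[0])
    else:
        dt = min_duration_s  # single point can never exceed the duration rule
    sign = np.sign(trace.mu_n)
    supra = (bf >= threshold) & (sign != 0) & np.isfinite(bf)
    windows: list[dict] = []
    i = 0
    n = len(bf)
    while i < n:
        if not supra[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and supra[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        duration = (j - i + 1) * dt
        if duration > min_duration_s:
            windows.append(
                {
                    "start_s": float(t[i]),
                    "end_s": float(t[j] + dt),
                    "sign": "similarity" if sign[i] > 0 else "dissimilarity",
                    "mean_contrast": float(np.mean(trace.mean_contrast[i : j + 1])),
                    "min_bf10": float(np.min(bf[i : j + 1])),
                    "n_timepoints": int(j - i + 1),
                }
            )
        i = j + 1
    trace.windows = windows
    return windows


@dataclass
class MVNIGRegressionResult:
    predictor_names: list[str]
    betas: np.ndarray  # posterior mean coefficients (standardized if asked)
    bf10: np.ndarray  # per-coefficient Savage-Dickey BF
    m_n: np.ndarray
    lambda_n: np.ndarray
    alpha_n: float
    beta_n: float
    n_trials: int
    standardized: bool

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "standardized": self.standardized,
            "coefficients": {
                name: {"beta": float(b), "bf10": float(bf)}
                for name, b, bf in zip(self.predictor_names, self.betas, self.bf10)
            },
            "alpha_n": float(self.alpha_n),
            "beta_n": float(self.beta_n),
        }


def mvnig_regression(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    predictor_names: list[str] | None = None,
    lambda_scale: float = 30.0,
    alpha: float = 15.0,
    beta: float = 15.0,
    standardize: bool = True,
) -> MVNIGRegressionResult:
    """Bayesian linear regression with an MVNIG prior (m0 = 0,
    Lambda0 = lambda_scale * I).

    Posterior: Lambda_n = X'X + lambda I, m_n = Lambda_n^-1 X'y,
    alpha_n = alpha + n/2, beta_n = beta + (y'y - m_n' Lambda_n m_n)/2.
    Per-coefficient BF10 is the Savage-Dickey ratio of the marginal t
    densities at zero.  With ``standardize`` the outcome and every column
    are z-scored first (binary outcomes included - the Gaussian conjugate
    model is applied to accuracy as-is); otherwise an intercept column is
    appended and reported.
    """
    if isinstance(X, pd.DataFrame):
        predictor_names = predictor_names or list(X.columns)
        X = X.to_numpy(float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"y has {len(y)} rows, X has {n}")
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    predictor_names = predictor_names or [f"x{j}" for j in range(p)]

    sds = X.std(axis=0, ddof=0)
    degenerate = [predictor_names[j] for j in np.flatnonzero(sds == 0)]
    if standardize and degenerate:
        raise ValueError(f"constant predictor column(s): {degenerate}")
    if standardize:
        X = (X - X.mean(axis=0)) / sds
        ysd = y.std(ddof=0)
        if ysd == 0:
            raise ValueError("outcome is constant; cannot standardize")
        y = (y - y.mean()) / ysd
    else:
        X = np.column_stack([X, np.ones(n)])
        predictor_names = list(predictor_names) + ["intercept"]
        p += 1

    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    if rank < p:
        # name the offending columns via the QR diagonal
        r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [predictor_names[j] for j in np.flatnonzero(r_diag < 1e-8 * r_diag.max())]
        raise ValueError(f"rank-deficient design matrix; collinear columns: {bad}")

    lam_n = xtx + lambda_scale * np.eye(p)
    m_n = np.linalg.solve(lam_n, X.T @ y)
    alpha_n = alpha + n / 2.0
    beta_n = beta + 0.5 * (y @ y - m_n @ lam_n @ m_n)
    lam_inv = np.linalg.inv(lam_n)

    prior_scale = np.sqrt(beta / (alpha * lambda_scale))
    post_scales = np.sqrt(beta_n / alpha_n * np.diag(lam_inv))
    lp0 = stats.t.logpdf(0.0, df=2.0 * alpha, loc=0.0, scale=prior_scale)
    lp1 = stats.t.logpdf(0.0, df=2.0 * alpha_n, loc=m_n, scale=post_scales)
    bf10 = np.exp(lp0 - lp1)

    return MVNIGRegressionResult(
        predictor_names=predictor_names,
        betas=m_n,
        bf10=bf10,
        m_n=m_n,
        lambda_n=lam_n,
        alpha_n=alpha_n,
        beta_n=float(beta_n),
        n_trials=n,
        standardized=standardize,
    )


def ceiling_filter(
    trial_table: pd.DataFrame, outcome: str, max_accuracy: float = 0.9
) -> tuple[pd.DataFrame, list]:
    """Drop participants without enough incorrect trials on ``outcome``
    (accuracy above ``max_accuracy``), the unbalanced-data guard used
    before the outcome regressions.  Returns (filtered table, excluded
    participant ids)."""
    acc = trial_table.groupby("participant")[outcome].mean()
    excluded = sorted(acc.index[acc > max_accuracy].tolist())
    kept = trial_table[~trial_table["participant"].isin(excluded)].reset_index(drop=True)
    return kept, excluded


def monte_carlo_effect_comparison(
    estimates: dict[str, float],
    ses: dict[str, float],
    n_iter: int = 10000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Pairwise two-tailed Monte-Carlo comparison of per-condition effect
    sizes: sample each condition's estimate from N(estimate, se^2) for
    ``n_iter`` iterations, and for each pair take twice the smaller tail
    fraction of the difference distribution as the p-value (0.05
    criterion flagged)."""
    names = list(estimates)
    for c in names:
        if ses[c] <= 0:
            raise ValueError(f"standard error for {c!r} must be positive")
    rng = np.random.default_rng(seed)
    draws = {c: rng.normal(estimates[c], ses[c], n_iter) for c in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = draws[a] - draws[b]
            frac_pos = float(np.mean(diff > 0))
            p = 2.0 * min(frac_pos, 1.0 - frac_pos)
            rows.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "mean_difference": float(diff.mean()),
                    "p_two_tailed": p,
                    "significant_0.05": p < 0.05,
                }
            )
    return pd.DataFrame(rows)
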