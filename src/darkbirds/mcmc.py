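"""Metropolis-Hastings machinery and the two Bayesian models.

A single component-wise Gaussian random-walk Metropolis engine drives
both Bayesian analyses:

* the white-noise linear alternative to the fossil-count regression,
  where the observed counts are normal around a mean that is a linear
  function of the standardized predictors (baseline ``mu0`` uniform on
  [0, 200], noise sd ``sigma`` with a Gamma(shape 1, rate 0.01) prior,
  effect sizes with a hierarchical normal prior whose sd carries an
  Exponential(1) hyperprior), and
* the logistic species-description curve used for the global lower
  bound, where cumulative described-species counts are normal around a
  three-parameter logistic of calendar year with flat priors, positivity
  constraints, and the midpoint confined to the observed time window.

Iteration counts are configuration-scaled: the defaults favour
desk-scale runs of a few minutes, while the heavy settings used for
archival-quality chains remain available through :class:`McmcConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from darkbirds.data_prep import INTERACTION, PredictorMatrix
from darkbirds.extrapolation import AREA, EFFORT, UndiscoveredDraws, probability_round


@dataclass
class McmcConfig:
    iterations: int = 200_000
    thinning: int = 100
    burn_in: float = 0.1  # fraction of iterations discarded

    def n_samples(self) -> int:
        return int(np.floor(self.iterations * (1.0 - self.burn_in) / self.thinning))


@dataclass
class McmcChain:
    names: list[str]
    samples: np.ndarray  # (n_samples, p) post burn-in, thinned
    acceptance: pd.Series  # per-component acceptance rate
    seed: int | None
    config: McmcConfig = field(default_factory=McmcConfig)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.names)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        x = self[name]
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))

    def split_half_z(self) -> pd.Series:
        """Geweke-style z-score comparing first- and second-half means."""
        h = self.samples.shape[0] // 2
        a, b = self.samples[:h], self.samples[h:]
        se = np.sqrt(a.var(axis=0, ddof=1) / len(a) + b.var(axis=0, ddof=1) / len(b))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (a.mean(axis=0) - b.mean(axis=0)) / se
        return pd.Series(z, index=self.names)


def run_mh(
    log_posterior,
    init: np.ndarray,
    proposal_scales: np.ndarray,
    config: McmcConfig | None = None,
    seed: int | None = None,
    names: list[str] | None = None,
) -> McmcChain:
    """Component-wise Gaussian random-walk Metropolis sampling.

    Each iteration sweeps over the parameters, proposing a Gaussian step
    on one component at a time and accepting by the Metropolis rule.
    The returned chain holds the thinned post-burn-in samples, exactly
    ``floor(iterations * (1 - burn_in) / thinning)`` of them.
    """
    config = config or McmcConfig()
    rng = np.random.default_rng(seed)
    x = np.asarray(init, dtype=float).copy()
    scales = np.asarray(proposal_scales, dtype=float)
    p = len(x)
    if np.any(scales == 0):
        warnings.warn("zero proposal scale: the corresponding component is degenerate and will not move")
    lp = float(log_posterior(x))
    if not np.isfinite(lp):
        raise ValueError("log posterior is not finite at the initial point; choose a new start")
    burn = int(np.floor(config.iterations * config.burn_in))
    n_keep = config.n_samples()
    samples = np.empty((n_keep, p))
    accepts = np.zeros(p)
    kept = 0
    # pre-draw randomness in blocks for speed
    for it in range(config.iterations):
        steps = rng.standard_normal(p) * scales
        logu = np.log(rng.random(p))
        for j in range(p):
            old = x[j]
            x[j] = old + steps[j]
            lp_new = float(log_posterior(x))
            if lp_new - lp >= logu[j]:
                lp = lp_new
                accepts[j] += 1
            else:
                x[j] = old
        post = it - burn
        if post >= 0 and (post + 1) % config.thinning == 0 and kept < n_keep:
            samples[kept] = x
            kept += 1
    samples = samples[:kept]
    acc = pd.Series(accepts / config.iterations, index=names or [f"p{j}" for j in range(p)])
    return McmcChain(
        names=list(acc.index), samples=samples, acceptance=acc, seed=seed, config=config
    )


# ---------------------------------------------------------------------------
# White-noise linear model of fossil counts


def fit_whitenoise_linear(
    design: PredictorMatrix | pd.DataFrame,
    fossil_counts,
    config: McmcConfig | None = None,
    seed: int | None = None,
    mu0_limits: tuple[float, float] = (0.0, 200.0),
    sigma_gamma: tuple[float, float] = (1.0, 0.01),  # shape, rate
    tau_rate: float = 1.0,
) -> McmcChain:
    """Sample the white-noise linear model's posterior.

    The counts are modelled as N(mu0 + sum_i e_i P_i, sigma) on the
    natural count scale, with the interaction carrying its own effect.
    Chain columns are ``mu0``, ``sigma``, ``tau`` (hierarchical effect
    sd) and ``e_<predictor>``.
    """
    X = (design.values if isinstance(design, PredictorMatrix) else design).to_numpy(float)
    cols = list((design.values if isinstance(design, PredictorMatrix) else design).columns)
    y = np.asarray(fossil_counts, dtype=float)
    if len(y) != len(X):
        raise ValueError("design and response lengths differ")
    n, k = X.shape
    lo, hi = mu0_limits
    shape, rate = sigma_gamma

    def log_posterior(theta: np.ndarray) -> float:
        mu0, sigma, tau = theta[0], theta[1], theta[2]
        if not (lo <= mu0 <= hi) or sigma <= 0 or tau <= 0:
            return -np.inf
        e = theta[3:]
        mu = mu0 + X @ e
        r = y - mu
        loglik = -n * np.log(sigma) - 0.5 * float(r @ r) / (sigma * sigma)
        logprior = (shape - 1.0) * np.log(sigma) - rate * sigma  # gamma on sigma
        logprior += -tau_rate * tau  # exponential hyperprior on tau
        logprior += -k * np.log(tau) - 0.5 * float(e @ e) / (tau * tau)
        return loglik + logprior

    # start near the least-squares solution so desk-scale chains converge fast
    Xc = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid_sd = float(np.std(y - Xc @ beta, ddof=1))
    init = np.concatenate([[np.clip(beta[0], lo + 1e-6, hi - 1e-6), max(resid_sd, 1e-3), max(np.abs(beta[1:]).mean(), 0.5)], beta[1:]])
    se = resid_sd / np.sqrt(n)
    scales = np.concatenate([[3 * se, 0.3 * max(resid_sd, 1e-3), 0.3], np.full(k, 3 * se)])
    names = ["mu0", "sigma", "tau"] + [f"e_{c}" for c in cols]
    return run_mh(log_posterior, init, scales, config=config or McmcConfig(), seed=seed, names=names)


def whitenoise_extrapolate(
    chain: McmcChain,
    archipelagos: pd.DataFrame,
    design: PredictorMatrix,
    rng: np.random.Generator,
) -> dict[str, UndiscoveredDraws]:
    """Effort-benchmarked extrapolation on the natural count scale.

    The same benchmarking logic as the log-scale model, but the white
    noise model is linear in the counts themselves, so the effort
    increment is additive: undiscovered = max(increment, 0), probability
    rounded. The reference archipelago again gets exactly zero.
    """
    ref_rows = archipelagos.loc[archipelagos["is_reference"]]
    if len(ref_rows) != 1:
        raise ValueError("exactly one reference archipelago is required")
    reference = ref_rows.iloc[0]
    e_eff = chain[f"e_{EFFORT}"]
    e_int = chain[f"e_{INTERACTION}"] if f"e_{INTERACTION}" in chain.names else 0.0
    z_ref = float(design.to_model_space(EFFORT, reference[EFFORT]))
    out = {}
    for _, rec in archipelagos.iterrows():
        z_eff = float(design.to_model_space(EFFORT, rec[EFFORT]))
        z_area = float(design.to_model_space(AREA, rec[AREA]))
        inc = (e_eff + e_int * z_area) * (z_ref - z_eff)
        clamped = int(np.sum(inc < 0))
        undiscovered = np.maximum(inc, 0.0)
        out[str(rec["archipelago_id"])] = UndiscoveredDraws(
            archipelago_id=str(rec["archipelago_id"]),
            draws=probability_round(undiscovered, rng),
            clamp_events=clamped,
        )
    return out


# ---------------------------------------------------------------------------
# Logistic species-description curve (global lower bound)


def logistic_mean(years: np.ndarray, maximum: float, midpoint: float, rate: float) -> np.ndarray:
    return maximum / (1.0 + np.exp(-rate * (years - midpoint)))


def fit_description_logistic(
    series: pd.DataFrame,
    config: McmcConfig | None = None,
    seed: int | None = None,
    n_described: int | None = None,
    midpoint_window: tuple[float, float] | None = None,
) -> tuple[McmcChain, np.ndarray, np.ndarray]:
    """Fit the logistic description curve and derive the lower bound.

    ``series`` has columns ``year`` and ``n_described`` (cumulative).
    Priors are flat apart from positivity of the asymptote, growth rate
    and noise sd, and a hard window on the midpoint (the observed year
    range by default). Returns the chain plus the posterior draws of the
    describable total (the asymptote) and of the number of species still
    undescribed (asymptote minus the described count).
    """
    years = series["year"].to_numpy(float)
    counts = series["n_described"].to_numpy(float)
    if len(np.unique(years)) < 5:
        raise ValueError("need at least 5 distinct years to fit the description curve")
    w_lo, w_hi = midpoint_window or (float(years.min()), float(years.max()))
    n = len(years)

    def log_posterior(theta: np.ndarray) -> float:
        maximum, midpoint, growth, sigma = theta
        if maximum <= 0 or growth <= 0 or sigma <= 0 or not (w_lo <= midpoint <= w_hi):
            return -np.inf
        r = counts - logistic_mean(years, maximum, midpoint, growth)
        return -n * np.log(sigma) - 0.5 * float(r @ r) / (sigma * sigma)

    top = float(counts.max())
    half = float(years[min(int(np.searchsorted(counts, 0.5 * top)), n - 1)])
    init = np.array([1.2 * top, np.clip(half, w_lo, w_hi), 0.05, max(0.05 * top, 1.0)])
    scales = np.array([0.02 * top, 2.0, 0.004, 0.1 * init[3]])
    chain = run_mh(
        log_posterior,
        init,
        scales,
        config=config or McmcConfig(),
        seed=seed,
        names=["maximum", "midpoint", "growth_rate", "sigma"],
    )
    described = float(counts[-1]) if n_described is None else float(n_described)
    describable = chain["maximum"]
    undescribed = describable - described
    return chain, describable, undescribed
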