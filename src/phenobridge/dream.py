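"""DREAM (DiffeRential Evolution Adaptive Metropolis) calibration of the DVR model.

Per genotype, the posterior of (alpha, beta, G) given observed days to
heading is sampled with multiple interacting chains.  Each chain proposes
a jump built from the difference of randomly chosen pairs of other
chains, scaled by 2.38/sqrt(2*delta*d') (with occasional unit jumps that
allow mode switching), with per-dimension crossover masking whose
probabilities adapt during burn-in.  This self-tunes the proposal scale
and orientation, which matters here because alpha, beta and G are
strongly correlated a posteriori and the posterior can be multimodal.

Priors are independent normals truncated to box bounds:
alpha ~ N(3, 1) on [0, 20], beta ~ N(4, 1) on [0, 25],
G ~ N(35, 2) on [30, 120] days.

The likelihood treats observed DTH as the model prediction plus iid
Gaussian error (sd ``sigma_obs``, default 2 days).  A simulation that
never reaches heading within the horizon contributes a large finite
penalty residual so chains stay mobile.  An alternative likelihood that
concentrates the error variance out (-n/2 * log SSE) is selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phenology import (
    DEFAULT_MAX_DAYS,
    CardinalConstants,
    DVRParams,
    dth_batch,
)

__all__ = [
    "ParamPrior",
    "PriorSpec",
    "DreamConfig",
    "PosteriorResult",
    "log_prior",
    "log_likelihood",
    "dream_step",
    "run_dream",
    "summarize_posterior",
    "gelman_rubin",
    "CrossoverState",
]

PARAM_NAMES = ("alpha", "beta", "g_days")


@dataclass(frozen=True)
class ParamPrior:
    mu: float
    sigma: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("prior bounds must satisfy lower < upper")
        if self.sigma <= 0:
            raise ValueError("prior sigma must be positive")


@dataclass(frozen=True)
class PriorSpec:
    """Truncated-normal priors for the three DVR parameters."""

    alpha: ParamPrior = ParamPrior(3.0, 1.0, 0.0, 20.0)
    beta: ParamPrior = ParamPrior(4.0, 1.0, 0.0, 25.0)
    g_days: ParamPrior = ParamPrior(35.0, 2.0, 30.0, 120.0)

    @property
    def mus(self) -> np.ndarray:
        return np.array([p.mu for p in self._all])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([p.sigma for p in self._all])

    @property
    def lowers(self) -> np.ndarray:
        return np.array([p.lower for p in self._all])

    @property
    def uppers(self) -> np.ndarray:
        return np.array([p.upper for p in self._all])

    @property
    def _all(self):
        return (self.alpha, self.beta, self.g_days)

    def truncated_means(self) -> np.ndarray:
        """Analytic means of the truncated-normal marginals."""
        out = []
        for p in self._all:
            a = (p.lower - p.mu) / p.sigma
            b = (p.upper - p.mu) / p.sigma
            out.append(stats.truncnorm.mean(a, b, loc=p.mu, scale=p.sigma))
        return np.array(out)


@dataclass(frozen=True)
class DreamConfig:
    """Sampler settings.

    ``n_iterations`` counts generations per chain; ``n_burn_in`` and
    ``n_keep`` count pooled draws (chains x generations).  Crossover
    probabilities adapt and outlier chains are corrected only during
    burn-in, so retained draws form a valid MCMC sample.
    """

    n_chains: int = 10
    n_iterations: int = 50_000
    n_burn_in: int = 10_000
    n_keep: int = 10_000
    delta_choices: tuple[int, ...] = (1, 2, 3)
    n_crossover_levels: int = 3
    jump_prob: float = 0.2
    jitter_b: float = 0.05
    noise_bstar: float = 1e-6
    sigma_obs: float = 2.0
    likelihood: str = "gaussian"  # or "sse"
    max_days: int = DEFAULT_MAX_DAYS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains <= 2 * len(PARAM_NAMES):
            raise ValueError("n_chains must exceed twice the number of parameters")
        if self.n_burn_in + self.n_keep > self.n_chains * self.n_iterations:
            raise ValueError("n_burn_in + n_keep exceeds the pooled draw count")
        if self.n_chains < 2 * max(self.delta_choices) + 1:
            raise ValueError("too few chains for the requested number of pairs")
        if self.likelihood not in ("gaussian", "sse"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")


@dataclass
class PosteriorResult:
    samples: np.ndarray          # n_keep x 3
    mean: np.ndarray
    median: np.ndarray
    mode: np.ndarray
    rhat: np.ndarray
    acceptance_rate: float
    chains: np.ndarray           # n_iterations x n_chains x 3 (full history)

    def params_mean(self) -> DVRParams:
        return DVRParams(*self.mean)


@dataclass
class CrossoverState:
    """Adaptive crossover bookkeeping (selection probs, usage, jump distance)."""

    cr_values: np.ndarray
    probs: np.ndarray
    counts: np.ndarray
    dist: np.ndarray

    @classmethod
    def create(cls, n_levels: int) -> "CrossoverState":
        cr = np.arange(1, n_levels + 1) / n_levels
        return cls(cr_values=cr, probs=np.full(n_levels, 1.0 / n_levels),
                   counts=np.zeros(n_levels), dist=np.zeros(n_levels))

    def update_probs(self) -> None:
        used = self.counts > 0
        if used.sum() == 0 or self.dist.sum() <= 0:
            return
        w = np.where(used, self.dist / np.maximum(self.counts, 1), 0.0)
        if w.sum() > 0:
            # keep every level selectable
            self.probs = 0.9 * w / w.sum() + 0.1 / len(w)


# ---------------------------------------------------------------------------
# Target density


def log_prior(theta: np.ndarray, prior: PriorSpec) -> float:
    """Sum of truncated-normal log densities (truncation constant dropped)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < prior.lowers) or np.any(theta > prior.uppers):
        return -np.inf
    z = (theta - prior.mus) / prior.sigmas
    return float(np.sum(-0.5 * z * z - np.log(prior.sigmas)
                        - 0.5 * math.log(2 * math.pi)))


class HeadingLikelihood:
    """Precompiled likelihood of observed DTH for one genotype.

    Caches the alpha/beta-independent log response bases of every
    environment so each evaluation costs one exp per response plus the
    phase bookkeeping.
    """

    def __init__(self, observed_dth, envs, cardinals: CardinalConstants | None = None,
                 sigma_obs: float = 2.0, kind: str = "gaussian",
                 max_days: int = DEFAULT_MAX_DAYS,
                 censored_penalty_offset: float = 30.0):
        if len(observed_dth) == 0:
            raise ValueError("at least one heading observation is required")
        if len(observed_dth) != len(envs):
            raise ValueError("one environment per observation is required")
        c = cardinals or CardinalConstants()
        self.observed = np.asarray(observed_dth, dtype=float)
        self.sigma = float(sigma_obs)
        self.kind = kind
        self.max_days = max_days
        self.offset = censored_penalty_offset
        logs = [env.response_logs(c, max_days) for env in envs]
        self.log_f = np.vstack([lf for lf, _ in logs])
        self.log_g = np.vstack([lg for _, lg in logs])

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        alpha, beta, g = theta
        dth = dth_batch(self.log_f, self.log_g, alpha, beta, g).astype(float)
        res = dth - self.observed
        censored = dth < 0
        if censored.any():
            # censored: finite, strongly unfavorable
            res[censored] = self.max_days - self.observed[censored] + self.offset
        return res

    def __call__(self, theta: np.ndarray) -> float:
        res = self.residuals(theta)
        n = res.shape[0]
        sse = float(res @ res)
        if self.kind == "sse":
            return -0.5 * n * math.log(max(sse, 1e-12))
        return (-0.5 * n * math.log(2 * math.pi * self.sigma ** 2)
                - sse / (2 * self.sigma ** 2))


def log_likelihood(params: DVRParams, observed_dth, envs,
                   cardinals: CardinalConstants | None = None,
                   sigma_obs: float = 2.0, kind: str = "gaussian",
                   max_days: int = DEFAULT_MAX_DAYS) -> float:
    """Gaussian iid log likelihood of observed DTH under the DVR model."""
    lik = HeadingLikelihood(observed_dth, envs, cardinals, sigma_obs, kind, max_days)
    return lik(params.as_array())


# ---------------------------------------------------------------------------
# Sampler


def _reflect(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    z = np.where(z < lo, 2 * lo - z, z)
    z = np.where(z > hi, 2 * hi - z, z)
    return np.clip(z, lo, hi)


def dream_step(states: np.ndarray, log_posts: np.ndarray, log_post_fn,
               config: DreamConfig, cr_state: CrossoverState,
               rng: np.random.Generator, prior: PriorSpec,
               adapt: bool = False):
    """One DREAM generation over all chains.

    Returns ``(states, log_posts, accepted)`` with in-place style updates
    applied to copies of the inputs.
    """
    n, d = states.shape
    lo, hi = prior.lowers, prior.uppers
    new_states = states.copy()
    new_logps = log_posts.copy()
    accepted = np.zeros(n, dtype=bool)
    pop_std = np.maximum(states.std(axis=0), 1e-12)

    for i in range(n):
        delta = int(rng.choice(config.delta_choices))
        if n < 2 * delta + 1:
            raise ValueError("not enough chains for the sampled pair count")
        others = np.delete(np.arange(n), i)
        picks = rng.choice(others, size=2 * delta, replace=False)
        r1, r2 = picks[:delta], picks[delta:]
        diff = states[r1].sum(axis=0) - states[r2].sum(axis=0)

        m = int(rng.choice(len(cr_state.cr_values), p=cr_state.probs))
        cr = cr_state.cr_values[m]
        mask = rng.random(d) < cr
        if not mask.any():
            mask[rng.integers(d)] = True
        dprime = int(mask.sum())

        if rng.random() < config.jump_prob:
            gamma = 1.0
        else:
            gamma = 2.38 / math.sqrt(2.0 * delta * dprime)
        e = rng.uniform(-config.jitter_b, config.jitter_b, size=d)
        eps = rng.normal(0.0, config.noise_bstar, size=d) if config.noise_bstar > 0 \
            else np.zeros(d)
        dx = np.where(mask, (1.0 + e) * gamma * diff + eps, 0.0)
        z = _reflect(states[i] + dx, lo, hi)

        logp_z = log_post_fn(z)
        if math.log(rng.random()) < logp_z - log_posts[i]:
            new_states[i] = z
            new_logps[i] = logp_z
            accepted[i] = True
        if adapt:
            cr_state.counts[m] += 1
            jump = (new_states[i] - states[i]) / pop_std
            cr_state.dist[m] += float(jump @ jump)
    return new_states, new_logps, accepted


def _correct_outliers(states, logps, history_logps) -> int:
    """IQR rule on mean log posterior of the stored burn-in history.

    Outlier chains are moved to the best chain's state; returns the
    number of corrections.
    """
    means = history_logps.mean(axis=0)
    q1, q3 = np.percentile(means, [25, 75])
    thresh = q1 - 2.0 * (q3 - q1)
    best = int(np.argmax(logps))
    n_fix = 0
    for i in np.nonzero(means < thresh)[0]:
        if i != best:
            states[i] = states[best]
            logps[i] = logps[best]
            n_fix += 1
    return n_fix


def run_dream(log_post_fn, prior: PriorSpec, config: DreamConfig) -> PosteriorResult:
    """Run DREAM on an arbitrary log-posterior over the prior box.

    ``log_post_fn(theta) -> float`` must already include the prior term;
    use :func:`fit_genotype` for the standard DVR target.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_chains, len(PARAM_NAMES)
    a = (prior.lowers - prior.mus) / prior.sigmas
    b = (prior.uppers - prior.mus) / prior.sigmas
    states = stats.truncnorm.rvs(a, b, loc=prior.mus, scale=prior.sigmas,
                                 size=(n, d), random_state=rng)
    logps = np.array([log_post_fn(s) for s in states])

    burn_gens = config.n_burn_in // n
    cr_state = CrossoverState.create(config.n_crossover_levels)
    history = np.empty((config.n_iterations, n, d))
    logp_hist = np.empty((config.n_iterations, n))
    n_accepted = 0
    n_proposed = 0
    check_every = max(burn_gens // 10, 1)

    for gen in range(config.n_iterations):
        in_burn = gen < burn_gens
        states, logps, acc = dream_step(states, logps, log_post_fn, config,
                                        cr_state, rng, prior, adapt=in_burn)
        if not in_burn:
            n_accepted += int(acc.sum())
            n_proposed += n
        history[gen] = states
        logp_hist[gen] = logps
        if in_burn and gen > 0 and gen % check_every == 0:
            cr_state.update_probs()
            half = logp_hist[gen // 2:gen + 1]
            _correct_outliers(states, logps, half)

    pooled = history.reshape(config.n_iterations * n, d)
    post = pooled[config.n_burn_in:]
    idx = np.linspace(0, post.shape[0] - 1, config.n_keep).round().astype(int)
    samples = post[idx]

    rhat = gelman_rubin(history[burn_gens:])
    mean, median, mode = summarize_posterior(samples)
    return PosteriorResult(
        samples=samples, mean=mean, median=median, mode=mode, rhat=rhat,
        acceptance_rate=n_accepted / max(n_proposed, 1), chains=history,
    )


def fit_genotype(observed_dth, envs, prior: PriorSpec | None = None,
                 config: DreamConfig | None = None,
                 cardinals: CardinalConstants | None = None) -> PosteriorResult:
    """Calibrate (alpha, beta, G) for one genotype from its DTH records."""
    prior = prior or PriorSpec()
    config = config or DreamConfig()
    lik = HeadingLikelihood(observed_dth, envs, cardinals,
                            sigma_obs=config.sigma_obs, kind=config.likelihood,
                            max_days=config.max_days)

    def log_post(theta):
        lp = log_prior(theta, prior)
        if not np.isfinite(lp):
            return -np.inf
        return lp + lik(theta)

    return run_dream(log_post, prior, config)


# ---------------------------------------------------------------------------
# Summaries and diagnostics


def _fd_mode(x: np.ndarray) -> float:
    """Midpoint of the highest Freedman-Diaconis histogram bin."""
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0 or x.max() == x.min():
        return float(np.median(x))
    width = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    nbins = max(int(np.ceil((x.max() - x.min()) / width)), 1)
    counts, edges = np.histogram(x, bins=nbins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def summarize_posterior(samples: np.ndarray):
    """Per-parameter posterior mean, median and histogram mode."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty posterior sample")
    if samples.ndim == 1:
        samples = samples[:, None]
    mean = samples.mean(axis=0)
    median = np.median(samples, axis=0)
    mode = np.array([_fd_mode(samples[:, j]) for j in range(samples.shape[1])])
    return mean, median, mode


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor per parameter.

    ``chains`` has shape (n_gen, n_chains, n_params); the statistic uses
    between- and within-chain variances of the provided window.
    """
    n, m, d = chains.shape
    if n < 2:
        return np.full(d, np.nan)
    means = chains.mean(axis=0)                       # m x d
    w = chains.var(axis=0, ddof=1).mean(axis=0)       # within
    b = n * means.var(axis=0, ddof=1)                 # between
    var_hat = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / w)
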