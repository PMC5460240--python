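"""Hierarchical Bayesian mixed-effects estimation of PK-model parameters.

The model separates the individual level from the population level:
individual parameter vectors are conditionally independent draws from
population distributions (lognormal for positive parameters, normal
otherwise) whose location and spread are themselves estimated.  Sparse
plasma concentration data enter through a multiplicative lognormal residual
model.  Sampling is Metropolis-within-Gibbs:

1. random-walk updates of each individual's (transformed) parameter vector,
   one forward simulation per proposal;
2. a conjugate normal update of each population mean given the individual
   values (random-walk when the prior is not normal on the working scale);
3. random-walk updates of each population standard deviation (half-normal
   hyperprior) and of the residual sigma, both on the log scale and both
   using cached residual sums, so they cost no simulations.

Proposal scales adapt only during a declared adaptation window, preserving
detailed balance afterwards.  Everything is reproducible from one seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .pbpk.types import ConcentrationProfile, ValidationError

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


class DiagnosticsError(RuntimeError):
    """The sampler produced chains that cannot be used as posterior draws."""


# -- distributions ---------------------------------------------------------


@dataclass(frozen=True)
class Distribution:
    """A (possibly truncated) prior/population distribution.

    ``lognormal`` parameters are on the log scale (location = mean of log,
    scale = sd of log).  ``uniform`` requires finite bounds and ignores
    location/scale.  Truncation renormalizes the density over
    [lower_bound, upper_bound].
    """

    family: str  # normal | lognormal | uniform
    location: float = 0.0
    scale: float = 1.0
    lower_bound: float = -math.inf
    upper_bound: float = math.inf

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal", "uniform"):
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.family == "uniform":
            if not (math.isfinite(self.lower_bound) and math.isfinite(self.upper_bound)):
                raise ValidationError("uniform distribution requires finite bounds")
        elif self.scale <= 0:
            raise ValidationError("scale must be positive")
        if self.lower_bound >= self.upper_bound:
            raise ValidationError("lower bound must be below upper bound")
        if self.family == "lognormal" and self.lower_bound < 0:
            object.__setattr__(self, "lower_bound", 0.0)

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(self.location, self.scale)
        if self.family == "lognormal":
            return stats.lognorm(s=self.scale, scale=math.exp(self.location))
        return stats.uniform(self.lower_bound, self.upper_bound - self.lower_bound)

    @property
    def _lognorm_trunc(self) -> float:
        """log of the probability mass inside the truncation bounds."""
        fr = self._frozen()
        mass = fr.cdf(self.upper_bound) - fr.cdf(self.lower_bound)
        if mass <= 0:
            raise ValidationError("truncation bounds leave no probability mass")
        return math.log(mass)

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        out = np.where(
            (x >= self.lower_bound) & (x <= self.upper_bound),
            self._frozen().logpdf(x),
            -np.inf,
        )
        if math.isfinite(self.lower_bound) or math.isfinite(self.upper_bound):
            out = out - self._lognorm_trunc
        return out

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        fr = self._frozen()
        lo, hi = fr.cdf(self.lower_bound), fr.cdf(self.upper_bound)
        u = rng.uniform(lo, hi, size=size)
        return fr.ppf(u)

    def mean(self) -> float:
        return float(self._frozen().mean())

    def sd(self) -> float:
        return float(self._frozen().std())


@dataclass(frozen=True)
class PriorSpec:
    """Named prior distributions with physiological / drug-specific role tags."""

    entries: dict[str, Distribution]
    roles: dict[str, str] = field(default_factory=dict)
    source_label: Optional[str] = None

    def __post_init__(self) -> None:
        for name, role in self.roles.items():
            if name not in self.entries:
                raise ValidationError(f"role tag for unknown parameter {name!r}")
            if role not in ("physiological", "drug_specific"):
                raise ValidationError(f"unknown role {role!r} for {name!r}")

    def require(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.entries]
        if missing:
            raise ValidationError(f"priors missing for parameters {missing}")


# -- model and data --------------------------------------------------------


@dataclass
class IndividualData:
    """Observed concentration profiles of one individual, keyed by compound."""

    individual_id: str
    observations: dict[str, ConcentrationProfile]

    def n_observations(self) -> int:
        return sum(len(p) for p in self.observations.values())


@dataclass
class HierarchicalModel:
    """Structural model plus estimation setup for one learning step.

    ``predict_fns[i]`` maps a natural-scale parameter vector (ordered as
    ``param_names``) to predicted concentrations per compound, aligned with
    individual *i*'s observation grid.
    """

    param_names: tuple[str, ...]
    priors: PriorSpec
    predict_fns: list[Callable[[np.ndarray], dict[str, np.ndarray]]]
    data: list[IndividualData]
    omega_hyperprior_scale: float = 0.5
    sigma_prior_scale: float = 0.5
    fixed_omega: Optional[dict[str, float]] = None
    fixed_sigma: Optional[float] = None

    def __post_init__(self) -> None:
        self.priors.require(self.param_names)
        if len(self.predict_fns) != len(self.data):
            raise ValidationError("one prediction function per individual required")
        for name in self.param_names:
            fam = self.priors.entries[name].family
            if fam not in ("normal", "lognormal", "uniform"):
                raise ValidationError(f"unsupported prior family {fam!r} for {name!r}")


@dataclass
class McmcResult:
    """Chains and diagnostics of one sampler run."""

    chains: np.ndarray  # iterations × columns
    columns: tuple[str, ...]
    acceptance: dict[str, float]
    rhat: dict[str, float]
    burn_in: int
    log_posterior: np.ndarray
    seed: int
    param_names: tuple[str, ...]
    log_scale: dict[str, bool]  # population parameters carried on log scale?

    def column(self, name: str) -> np.ndarray:
        return self.chains[:, self.columns.index(name)]

    def posterior(self) -> np.ndarray:
        return self.chains[self.burn_in :]


# -- likelihood ------------------------------------------------------------


def log_likelihood(
    predicted: dict[str, np.ndarray],
    observed: dict[str, ConcentrationProfile],
    sigma: float,
) -> float:
    """Multiplicative lognormal observation density, summed over compounds
    and time points: log(obs) ~ Normal(log(pred), sigma²)."""
    ssr, n_obs, const = _residual_summary(predicted, observed)
    return _loglik_from_summary(ssr, n_obs, const, sigma)


def _residual_summary(
    predicted: dict[str, np.ndarray], observed: dict[str, ConcentrationProfile]
) -> tuple[float, int, float]:
    ssr = 0.0
    n_obs = 0
    const = 0.0
    for compound, profile in observed.items():
        obs = profile.concentrations
        if np.any(obs <= 0):
            raise ValidationError(
                f"multiplicative error model needs positive observations "
                f"({profile.individual_id}, {compound})"
            )
        pred = np.asarray(predicted[compound], float)
        if pred.shape != obs.shape:
            raise ValidationError(
                f"prediction grid mismatch for {profile.individual_id}/{compound}"
            )
        log_res = np.log(np.maximum(pred, 1e-300)) - np.log(obs)
        ssr += float(np.dot(log_res, log_res))
        n_obs += obs.size
        const += float(-np.sum(np.log(obs)))
    return ssr, n_obs, const


def _loglik_from_summary(ssr: float, n_obs: int, const: float, sigma: float) -> float:
    if n_obs == 0:
        return 0.0
    return -0.5 * ssr / sigma**2 - n_obs * math.log(sigma) + const - 0.5 * n_obs * _LOG_2PI


# -- convergence diagnostics ----------------------------------------------


def gelman_rubin(chains: np.ndarray, n_segments: int = 4) -> np.ndarray:
    """Potential-scale-reduction statistic per parameter.

    ``chains`` is either (n_chains, n_iterations, n_params) for true
    multi-chain input, or (n_iterations, n_params) for the single-long-chain
    strategy, in which case the chain is cut into ``n_segments`` disjoint
    segments that play the role of chains.  Constant chains yield NaN.
    """
    arr = np.asarray(chains, float)
    if arr.ndim == 2:
        n = (arr.shape[0] // n_segments) * n_segments
        if n == 0:
            raise ValidationError("chain too short for the requested segmentation")
        arr = arr[:n].reshape(n_segments, n // n_segments, arr.shape[1])
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValidationError("need ≥2 chains or segments")
    m, n, _ = arr.shape
    seg_means = arr.mean(axis=1)
    seg_vars = arr.var(axis=1, ddof=1)
    w = seg_vars.mean(axis=0)
    b = n * seg_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (n - 1) / n * w + b / n
        rhat = np.sqrt(var_plus / w)
    if np.any(~np.isfinite(rhat)):
        logger.warning("R-hat undefined (constant chain) for %d parameter(s)",
                       int(np.sum(~np.isfinite(rhat))))
    return rhat


def find_burn_in(
    chains: np.ndarray,
    threshold: float = 1.1,
    n_segments: int = 4,
    n_candidates: int = 20,
) -> tuple[int, np.ndarray]:
    """First candidate burn-in for which all finite R̂ of the remainder fall
    below ``threshold``; returns (burn_in, rhat_at_that_point).  Falls back
    to half the chain if no candidate converges."""
    n_iter = chains.shape[0]
    candidates = np.unique(
        (np.linspace(0.0, 0.5, n_candidates) * n_iter).astype(int)
    )
    best_rhat = None
    for c in candidates:
        if n_iter - c < 2 * n_segments:
            break
        rhat = gelman_rubin(chains[c:], n_segments=n_segments)
        best_rhat = rhat
        finite = rhat[np.isfinite(rhat)]
        if finite.size == 0 or np.all(finite < threshold):
            return int(c), rhat
    return int(n_iter // 2), best_rhat


# -- posterior subsample ---------------------------------------------------


def posterior_subsample(result: McmcResult, n: int = 500, seed: int = 0) -> np.ndarray:
    """``n`` approximately independent post-burn-in draws.

    The post-burn-in chain is cut into ``n`` blocks of length
    ``stride = floor(remaining / n)`` and one iteration is drawn uniformly
    from each block (without replacement by construction); the rows are then
    returned in random order.
    """
    post = result.posterior()
    remaining = post.shape[0]
    if remaining < n:
        raise ValidationError(
            f"need ≥{n} post-burn-in iterations, have {remaining}"
        )
    stride = remaining // n
    rng = np.random.default_rng(seed)
    idx = np.arange(n) * stride + rng.integers(0, stride, size=n)
    return post[rng.permutation(idx)]


# -- the sampler -----------------------------------------------------------


def _halfnormal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return 0.5 * _LOG_2PI * -1 + math.log(2.0) - math.log(scale) - 0.5 * (x / scale) ** 2


@dataclass
class _ParamSetup:
    name: str
    log_scale: bool  # hierarchy on log of the natural parameter
    prior_loc: float  # prior for the population mean, on working scale
    prior_scale: float
    prior_uniform: Optional[tuple[float, float]]  # working-scale bounds, if uniform
    lower: float
    upper: float


def _setup_params(model: HierarchicalModel) -> list[_ParamSetup]:
    out = []
    for name in model.param_names:
        d = model.priors.entries[name]
        if d.family == "lognormal":
            lo = math.log(d.lower_bound) if d.lower_bound > 0 else -math.inf
            hi = math.log(d.upper_bound) if math.isfinite(d.upper_bound) else math.inf
            out.append(_ParamSetup(name, True, d.location, d.scale, None, lo, hi))
        elif d.family == "normal":
            out.append(
                _ParamSetup(name, False, d.location, d.scale, None, d.lower_bound, d.upper_bound)
            )
        else:  # uniform prior on the population mean, natural scale
            out.append(
                _ParamSetup(
                    name,
                    False,
                    0.5 * (d.lower_bound + d.upper_bound),
                    (d.upper_bound - d.lower_bound) / math.sqrt(12.0),
                    (d.lower_bound, d.upper_bound),
                    d.lower_bound,
                    d.upper_bound,
                )
            )
    return out


def run_mcmc(
    model: HierarchicalModel,
    n_iter: int = 20_000,
    seed: int = 0,
    adapt_fraction: float = 0.25,
    rhat_threshold: float = 1.1,
    n_segments: int = 4,
    initial_sigma: float = 0.2,
    initial_omega: float = 0.3,
) -> McmcResult:
    """Metropolis-within-Gibbs sampling of the hierarchical posterior.

    Reproducible bit-for-bit under a fixed seed.  Proposal step sizes adapt
    toward 20–40% acceptance during the first ``adapt_fraction`` of the
    chain only.  Burn-in is determined afterwards by scanning segment-wise
    R̂ against ``rhat_threshold``.
    """
    if n_iter < 8 * n_segments:
        raise ValidationError("n_iter too small for diagnostics")
    n_ind = len(model.data)
    if n_ind == 0:
        raise ValidationError("need at least one individual")
    if not any(d.n_observations() >= 2 for d in model.data):
        logger.warning("no individual has ≥2 observations; sampling the prior")
    setups = _setup_params(model)
    p = len(setups)
    rng = np.random.default_rng(seed)

    mu = np.array([s.prior_loc for s in setups])
    omega = np.full(p, initial_omega)
    fixed_omega_mask = np.zeros(p, dtype=bool)
    if model.fixed_omega:
        for j, s in enumerate(setups):
            if s.name in model.fixed_omega:
                omega[j] = model.fixed_omega[s.name]
                fixed_omega_mask[j] = True
    sigma = model.fixed_sigma if model.fixed_sigma is not None else initial_sigma

    eta = np.tile(mu, (n_ind, 1))  # individual vectors, working scale

    def natural(vec: np.ndarray) -> np.ndarray:
        out = vec.copy()
        for j, s in enumerate(setups):
            if s.log_scale:
                out[j] = math.exp(vec[j])
        return out

    # cached per-individual residual summaries at the current state
    cache = []
    for i in range(n_ind):
        pred = model.predict_fns[i](natural(eta[i]))
        cache.append(_residual_summary(pred, model.data[i].observations))

    def pop_logpdf(vec: np.ndarray) -> float:
        out = 0.0
        for j, s in enumerate(setups):
            if not (s.lower <= vec[j] <= s.upper):
                return -math.inf
            out += -0.5 * ((vec[j] - mu[j]) / omega[j]) ** 2 - math.log(omega[j])
        return out

    def mu_logprior() -> float:
        out = 0.0
        for j, s in enumerate(setups):
            if s.prior_uniform is not None:
                lo, hi = s.prior_uniform
                if not (lo <= mu[j] <= hi):
                    return -math.inf
                out += -math.log(hi - lo)
            else:
                out += -0.5 * ((mu[j] - s.prior_loc) / s.prior_scale) ** 2 - math.log(
                    s.prior_scale
                )
        return out

    ind_step = np.full((n_ind, p), 0.15)
    mu_step = np.array([0.3 * s.prior_scale for s in setups])
    omega_step = 0.3
    sigma_step = 0.3
    adapt_until = int(adapt_fraction * n_iter)
    adapt_block = 25

    ind_cols = [f"{model.data[i].individual_id}__{s.name}" for i in range(n_ind) for s in setups]
    columns = (
        [f"mu__{s.name}" for s in setups]
        + [f"omega__{s.name}" for s in setups]
        + ["sigma"]
        + ind_cols
    )
    chains = np.empty((n_iter, len(columns)))
    log_post = np.empty(n_iter)

    acc_ind = np.zeros(n_ind)
    acc_ind_block = np.zeros(n_ind)
    acc_mu = acc_omega = acc_sigma = 0.0
    n_mu_rw = 0

    any_uniform = any(s.prior_uniform is not None for s in setups)

    for it in range(n_iter):
        # (i) individual-level updates: exact conditional draw when an
        # individual has no observations (their full conditional is the
        # population law), random-walk Metropolis otherwise
        for i in range(n_ind):
            if model.data[i].n_observations() == 0:
                draw = mu + omega * rng.standard_normal(p)
                if all(s.lower <= draw[j] <= s.upper for j, s in enumerate(setups)):
                    eta[i] = draw
                    acc_ind[i] += 1
                    acc_ind_block[i] += 1
                continue
            prop = eta[i] + ind_step[i] * rng.standard_normal(p)
            lp_new = pop_logpdf(prop)
            if math.isfinite(lp_new):
                try:
                    pred = model.predict_fns[i](natural(prop))
                    summ = _residual_summary(pred, model.data[i].observations)
                    ll_new = _loglik_from_summary(*summ, sigma)
                except Exception:
                    ll_new = -math.inf
                    summ = None
                ll_old = _loglik_from_summary(*cache[i], sigma)
                if math.log(rng.uniform()) < (ll_new + lp_new) - (
                    ll_old + pop_logpdf(eta[i])
                ):
                    eta[i] = prop
                    cache[i] = summ
                    acc_ind[i] += 1
                    acc_ind_block[i] += 1
            else:
                rng.uniform()  # keep the random stream aligned

        # (ii) population means: conjugate normal update (random walk when
        # the prior is uniform)
        if not any_uniform:
            for j, s in enumerate(setups):
                prec = 1.0 / s.prior_scale**2 + n_ind / omega[j] ** 2
                mean = (
                    s.prior_loc / s.prior_scale**2 + eta[:, j].sum() / omega[j] ** 2
                ) / prec
                mu[j] = mean + rng.standard_normal() / math.sqrt(prec)
        else:
            n_mu_rw += 1
            prop_mu = mu + mu_step * rng.standard_normal(p)
            lp_old = mu_logprior() + sum(pop_logpdf(eta[i]) for i in range(n_ind))
            mu_save = mu.copy()
            mu = prop_mu
            lp_new = mu_logprior() + sum(pop_logpdf(eta[i]) for i in range(n_ind))
            if math.log(rng.uniform()) < lp_new - lp_old:
                acc_mu += 1
            else:
                mu = mu_save

        # (iii) population spreads: log-scale random walk, half-normal prior
        for j in range(p):
            if fixed_omega_mask[j]:
                rng.standard_normal()
                rng.uniform()
                continue
            prop = omega[j] * math.exp(omega_step * rng.standard_normal())
            dev = eta[:, j] - mu[j]
            ssd = float(np.dot(dev, dev))

            def omega_lp(w: float) -> float:
                return (
                    -0.5 * ssd / w**2
                    - n_ind * math.log(w)
                    + _halfnormal_logpdf(w, model.omega_hyperprior_scale)
                    + math.log(w)  # Jacobian of the log-scale walk
                )

            if math.log(rng.uniform()) < omega_lp(prop) - omega_lp(omega[j]):
                omega[j] = prop
                acc_omega += 1

        # (iv) residual sigma: log-scale random walk on cached summaries
        if model.fixed_sigma is None:
            prop = sigma * math.exp(sigma_step * rng.standard_normal())

            def sigma_lp(sg: float) -> float:
                return (
                    sum(_loglik_from_summary(*c, sg) for c in cache)
                    + _halfnormal_logpdf(sg, model.sigma_prior_scale)
                    + math.log(sg)
                )

            if math.log(rng.uniform()) < sigma_lp(prop) - sigma_lp(sigma):
                sigma = prop
                acc_sigma += 1
        else:
            rng.standard_normal()
            rng.uniform()

        # proposal adaptation, burn-in only
        if it < adapt_until and (it + 1) % adapt_block == 0:
            rates = acc_ind_block / adapt_block
            ind_step *= np.exp(0.5 * (rates - 0.3))[:, None]
            np.clip(ind_step, 1e-4, 5.0, out=ind_step)
            acc_ind_block[:] = 0.0

        chains[it, :p] = mu
        chains[it, p : 2 * p] = omega
        chains[it, 2 * p] = sigma
        chains[it, 2 * p + 1 :] = eta.ravel()
        log_post[it] = (
            sum(_loglik_from_summary(*cache[i], sigma) for i in range(n_ind))
            + sum(pop_logpdf(eta[i]) for i in range(n_ind))
            + mu_logprior()
            + sum(
                _halfnormal_logpdf(omega[j], model.omega_hyperprior_scale)
                for j in range(p)
                if not fixed_omega_mask[j]
            )
            + (
                _halfnormal_logpdf(sigma, model.sigma_prior_scale)
                if model.fixed_sigma is None
                else 0.0
            )
        )

    post_adapt = max(n_iter - adapt_until, 1)
    acceptance = {
        f"individual__{model.data[i].individual_id}": float(acc_ind[i] / n_iter)
        for i in range(n_ind)
    }
    acceptance["omega"] = float(acc_omega / (n_iter * max(1, int((~fixed_omega_mask).sum()))))
    if model.fixed_sigma is None:
        acceptance["sigma"] = float(acc_sigma / n_iter)
    if n_mu_rw:
        acceptance["mu"] = float(acc_mu / n_mu_rw)
    has_data = [i for i in range(n_ind) if model.data[i].n_observations() > 0]
    post_adapt_acc = [
        acc_ind[i] for i in has_data
    ]
    if has_data and min(post_adapt_acc) == 0:
        raise DiagnosticsError(
            "an individual block accepted no proposals after the adaptation "
            "window; review the proposal step sizes"
        )

    burn_in, rhat_arr = find_burn_in(
        chains, threshold=rhat_threshold, n_segments=n_segments
    )
    rhat_full = gelman_rubin(chains[burn_in:], n_segments=n_segments)
    rhat = {c: float(r) for c, r in zip(columns, rhat_full)}
    return McmcResult(
        chains=chains,
        columns=tuple(columns),
        acceptance=acceptance,
        rhat=rhat,
        burn_in=burn_in,
        log_posterior=log_post,
        seed=seed,
        param_names=model.param_names,
        log_scale={s.name: s.log_scale for s in setups},
    )
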