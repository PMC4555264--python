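"""Hierarchical Bayesian estimation of the population methylmercury half-life.

Model
-----
For subject ``i`` with blood concentration ``y_i``, intake ``d_i`` and
weight ``w_i``::

    log y_i = log f(d_i) + eps_i,        eps_i ~ Normal(0, sigma^2)
    f(d_i)  = d_i * t_half_i * Abs * frac_b * w_i / (ln2 * V_b)

with individual half-lives drawn from a truncated-normal population
distribution ``t_half_i ~ TN(mu, tau^2, 0, inf)``.  Informative priors keep
the kinetic nuisance parameters inside their biological range::

    mu     ~ TN(72, 10.8^2, 0, inf)      tau    ~ Unif(10, 40)
    Abs    ~ Unif(0.9, 1)                frac_b ~ Unif(0, 0.1)
    V_b    ~ Unif(2.99, 4.34)            sigma  ~ Unif(0, 100)

``sigma`` is the standard deviation of the residual on the natural-log
concentration scale and is treated as dimensionless.

Sampler
-------
A Metropolis-within-Gibbs scheme updates, in fixed order per iteration:
the vector of individual half-lives (vectorized Gaussian random walk,
proposals <= 0 rejected), ``mu`` (truncated-normal conjugate-form
independence proposal with a Metropolis correction for the
``Phi(mu/tau)^(-n)`` normalizing terms, which break exact conjugacy),
``tau``, the three kinetic nuisances and ``log sigma`` (scalar random
walks, out-of-support proposals rejected).  Random-walk scales adapt
toward 20-45% acceptance during burn-in and are frozen afterwards, so the
retained draws target the exact posterior.  Each chain owns an
independent RNG stream spawned deterministically from the user seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from .tk_model import LN2, TKParams, invert_half_life

__all__ = [
    "Priors",
    "PopulationParams",
    "ChainState",
    "MCMCConfig",
    "ChainSet",
    "FitResult",
    "sample_truncated_normal",
    "truncnorm_mean",
    "log_likelihood",
    "log_prior",
    "run_mcmc",
    "fit_population",
    "prepare_cohort",
    "SCALAR_PARAMS",
]

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)

#: Scalar parameters in the reporting order of the posterior table.
SCALAR_PARAMS = ("mu", "tau", "Abs", "V_b", "frac_b", "sigma")


@dataclass(frozen=True)
class Priors:
    """Prior hyperparameters; defaults are the informative biological ranges."""

    mu_centre: float = 72.0
    mu_sd: float = 10.8
    tau_bounds: tuple[float, float] = (10.0, 40.0)
    abs_bounds: tuple[float, float] = (0.9, 1.0)
    fracb_bounds: tuple[float, float] = (0.0, 0.1)
    vb_bounds: tuple[float, float] = (2.99, 4.34)
    sigma_bounds: tuple[float, float] = (0.0, 100.0)


@dataclass
class PopulationParams:
    """Population mean/SD of the half-life (days) and residual log-scale SD."""

    mu: float
    tau: float
    sigma: float


@dataclass
class ChainState:
    """Full parameter state of one chain."""

    t_half: np.ndarray
    pop: PopulationParams
    tk: TKParams

    def scalars(self) -> dict[str, float]:
        return {
            "mu": self.pop.mu,
            "tau": self.pop.tau,
            "Abs": self.tk.abs_fraction,
            "V_b": self.tk.blood_volume,
            "frac_b": self.tk.frac_blood,
            "sigma": self.pop.sigma,
        }


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler schedule.

    The desk-scale default (4 chains x 30,000 iterations, 10,000 burn-in,
    thin 5) yields 16,000 retained draws; heavier production schedules are
    expressed through the same fields.
    """

    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 5
    n_chains: int = 4
    seed: int = 0
    adapt: bool = True
    floor_zero_intake: bool = False

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class ChainSet:
    """Retained MCMC draws with their schedule metadata.

    ``draws[name]`` has shape (n_chains, n_draws); ``t_half`` has shape
    (n_chains, n_draws, n_subjects).
    """

    draws: dict[str, np.ndarray]
    t_half: np.ndarray
    subject_ids: list[str]
    config: MCMCConfig
    acceptance: dict[str, list[float]] = field(default_factory=dict)
    n_excluded_zero_intake: int = 0

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """All post-burn-in thinned draws of ``name`` pooled across chains."""
        return self.draws[name].reshape(-1)

    def pooled_t_half(self) -> np.ndarray:
        """Pooled individual half-life draws, shape (n_chains*n_draws, n)."""
        return self.t_half.reshape(-1, self.t_half.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table ``chain, iteration, parameter, value``."""
        frames = []
        for name, arr in self.draws.items():
            n_chains, n_draws = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(n_chains), n_draws),
                        "iteration": np.tile(np.arange(n_draws), n_chains),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class FitResult:
    chains: ChainSet
    summary: pd.DataFrame


# ---------------------------------------------------------------------------
# truncated-normal sampling

def sample_truncated_normal(centre, sd, lower, upper, rng, size=None):
    """Draw from Normal(centre, sd^2) restricted to (lower, upper).

    Uses inverse-CDF sampling when the interval overlaps the central
    +/-5 SD region and a translated-exponential rejection sampler (Robert
    1995) when it lies entirely in a tail, so draws remain exact even many
    SDs from the centre.
    """
    if not sd > 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    if not lower < upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")
    a = (lower - centre) / sd
    b = (upper - centre) / sd
    scalar = size is None
    n = 1 if scalar else int(size)
    if a >= 5.0:
        z = _tail_rejection(a, b, rng, n)
    elif b <= -5.0:
        z = -_tail_rejection(-b, -a, rng, n)
    else:
        pa, pb = ndtr(a), ndtr(b)
        u = pa + (pb - pa) * rng.random(n)
        z = ndtri(u)
        z = np.clip(z, a, b)  # guard FP round-off at the edges
    x = centre + sd * z
    return float(x[0]) if scalar else x


def _tail_rejection(a: float, b: float, rng, n: int) -> np.ndarray:
    """Exact right-tail sampler for standard-normal z in [a, b], a >= 0."""
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 16)
        z = a + rng.exponential(1.0 / alpha, size=m)
        accept = (z <= b) & (np.log(rng.random(m)) <= -0.5 * (z - alpha) ** 2)
        z = z[accept]
        take = min(z.size, n - filled)
        out[filled : filled + take] = z[:take]
        filled += take
    return out


def truncnorm_mean(centre: float, sd: float, lower: float = 0.0) -> float:
    """Closed-form mean of TN(centre, sd^2, lower, inf)."""
    a = (lower - centre) / sd
    lam = math.exp(-0.5 * a * a - 0.5 * _LOG_2PI) / ndtr(-a)
    return centre + sd * lam


# ---------------------------------------------------------------------------
# cohort preparation

def prepare_cohort(cohort: pd.DataFrame, floor_zero_intake: bool = False):
    """Validate a cohort table and extract (y, d, w, ids, n_excluded).

    Zero-intake subjects make ``log f(d)`` undefined; they are excluded
    with a logged count unless ``floor_zero_intake``, in which case their
    intake is floored at half the smallest positive intake.
    """
    required = {"subject_id", "weight_kg", "blood_mehg_ug_per_L", "intake_ug_per_kg_day"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")
    y = cohort["blood_mehg_ug_per_L"].to_numpy(float)
    d = cohort["intake_ug_per_kg_day"].to_numpy(float)
    w = cohort["weight_kg"].to_numpy(float)
    ids = cohort["subject_id"].astype(str).tolist()
    if np.any(y <= 0):
        raise ValueError("all blood concentrations must be > 0 to take logs")
    if np.any(w <= 0):
        raise ValueError("all body weights must be > 0")
    n_excluded = 0
    zero = d <= 0
    if zero.any():
        if floor_zero_intake:
            positive = d[d > 0]
            if positive.size == 0:
                raise ValueError("no subject has positive intake")
            d = np.where(zero, 0.5 * positive.min(), d)
            logger.warning("floored %d zero-intake subjects", int(zero.sum()))
        else:
            n_excluded = int(zero.sum())
            logger.warning("excluded %d zero-intake subjects", n_excluded)
            keep = ~zero
            y, d, w = y[keep], d[keep], w[keep]
            ids = [i for i, k in zip(ids, keep) if k]
    return y, d, w, ids, n_excluded


# ---------------------------------------------------------------------------
# model densities (reference forms; the sampler uses cached increments)

def log_likelihood(cohort: pd.DataFrame | Sequence, state: ChainState) -> float:
    """Sum over subjects of the Normal(0, sigma^2) log-density of the
    log-scale residual ``log y_i - log f(d_i)``."""
    y, d, w = _ydw(cohort)
    if np.any(y <= 0):
        raise ValueError("log_likelihood requires y > 0")
    if np.any(d <= 0):
        raise ValueError("log_likelihood requires d > 0 (filter upstream)")
    t = np.asarray(state.t_half, float)
    if t.shape[0] != y.shape[0]:
        raise ValueError("state.t_half length must match cohort size")
    tk = state.tk
    sigma = state.pop.sigma
    logf = (
        np.log(d)
        + np.log(t)
        + np.log(w)
        + math.log(tk.abs_fraction * tk.frac_blood / (LN2 * tk.blood_volume))
    )
    r = np.log(y) - logf
    n = y.shape[0]
    return float(-0.5 * n * (_LOG_2PI + 2.0 * math.log(sigma)) - np.sum(r * r) / (2.0 * sigma**2))


def _ydw(cohort):
    if isinstance(cohort, pd.DataFrame):
        return (
            cohort["blood_mehg_ug_per_L"].to_numpy(float),
            cohort["intake_ug_per_kg_day"].to_numpy(float),
            cohort["weight_kg"].to_numpy(float),
        )
    y = np.asarray([s.blood_mehg for s in cohort], float)
    d = np.asarray([s.intake for s in cohort], float)
    w = np.asarray([s.weight for s in cohort], float)
    return y, d, w


def _log_uniform(x: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if not (lo < x < hi):
        return -math.inf
    return -math.log(hi - lo)


def log_prior(state: ChainState, priors: Priors = Priors()) -> float:
    """Joint log-prior including all truncated-normal normalizing constants.

    Returns -inf outside any prior support rather than raising.
    """
    mu, tau, sigma = state.pop.mu, state.pop.tau, state.pop.sigma
    tk = state.tk
    total = 0.0
    total += _log_uniform(tau, priors.tau_bounds)
    total += _log_uniform(tk.abs_fraction, priors.abs_bounds)
    total += _log_uniform(tk.frac_blood, priors.fracb_bounds)
    total += _log_uniform(tk.blood_volume, priors.vb_bounds)
    total += _log_uniform(sigma, priors.sigma_bounds)
    if not math.isfinite(total):
        return -math.inf
    if mu <= 0:
        return -math.inf
    # mu ~ TN(mu_centre, mu_sd^2, 0, inf), normalizer Phi(mu_centre/mu_sd)
    zmu = (mu - priors.mu_centre) / priors.mu_sd
    total += (
        -0.5 * _LOG_2PI
        - math.log(priors.mu_sd)
        - 0.5 * zmu * zmu
        - float(log_ndtr(priors.mu_centre / priors.mu_sd))
    )
    t = np.asarray(state.t_half, float)
    if t.size:
        if np.any(t <= 0):
            return -math.inf
        zt = (t - mu) / tau
        total += float(
            t.size * (-0.5 * _LOG_2PI - math.log(tau) - log_ndtr(mu / tau))
            - 0.5 * np.sum(zt * zt)
        )
    return total


# ---------------------------------------------------------------------------
# the sampler

_BLOCKS = ("t_half", "mu", "tau", "Abs", "frac_b", "V_b", "sigma", "mu_shift", "tau_scale")

_INIT_STEPS = {
    "t_half": 25.0,
    "tau": 4.0,
    "Abs": 0.03,
    "frac_b": 0.03,
    "V_b": 0.4,
    "sigma": 0.4,
    "mu_shift": 8.0,
    "tau_scale": 0.4,
}


def _init_state(rng, y, d, w, priors: Priors, fixed: Mapping[str, float]) -> ChainState:
    def pick(name, draw):
        return float(fixed[name]) if name in fixed else draw()

    mu = pick("mu", lambda: sample_truncated_normal(priors.mu_centre, priors.mu_sd, 0, np.inf, rng))
    tau = pick("tau", lambda: rng.uniform(*priors.tau_bounds))
    abs_f = pick("Abs", lambda: rng.uniform(*priors.abs_bounds))
    frac_b = pick("frac_b", lambda: rng.uniform(max(priors.fracb_bounds[0], 1e-6), priors.fracb_bounds[1]))
    v_b = pick("V_b", lambda: rng.uniform(*priors.vb_bounds))
    sigma = pick("sigma", lambda: rng.uniform(max(priors.sigma_bounds[0], 1e-3), priors.sigma_bounds[1]))
    tk = TKParams(abs_fraction=abs_f, frac_blood=frac_b, blood_volume=v_b)
    if y.size:
        t = np.clip(invert_half_life(y, d, w, tk), 1.0, 1000.0).astype(float)
    else:
        t = np.empty(0)
    return ChainState(t_half=t, pop=PopulationParams(mu=mu, tau=tau, sigma=sigma), tk=tk)


def _run_chain(y, d, w, config: MCMCConfig, priors: Priors, rng, init: ChainState | None, fixed):
    n = y.size
    state = init if init is not None else _init_state(rng, y, d, w, priors, fixed)
    t = np.asarray(state.t_half, float).copy()
    mu, tau, sigma = state.pop.mu, state.pop.tau, state.pop.sigma
    abs_f, frac_b, v_b = state.tk.abs_fraction, state.tk.frac_blood, state.tk.blood_volume

    z = np.log(y) - np.log(d) - np.log(w) if n else np.empty(0)
    C = math.log(abs_f * frac_b / (LN2 * v_b))
    logt = np.log(t) if n else np.empty(0)
    r = z - logt - C
    S1 = float(r.sum())
    S2 = float(r @ r)

    mu_c, mu_sd = priors.mu_centre, priors.mu_sd
    tau_lo, tau_hi = priors.tau_bounds
    abs_lo, abs_hi = priors.abs_bounds
    fb_lo, fb_hi = priors.fracb_bounds
    vb_lo, vb_hi = priors.vb_bounds
    sig_lo, sig_hi = priors.sigma_bounds

    steps = dict(_INIT_STEPS)
    proposed = {k: 0 for k in _BLOCKS}
    accepted = {k: 0.0 for k in _BLOCKS}
    win_prop = {k: 0 for k in _BLOCKS}
    win_acc = {k: 0.0 for k in _BLOCKS}

    n_draws = (config.n_iter - config.burn_in + config.thin - 1) // config.thin
    out_scalar = {p: np.empty(n_draws) for p in SCALAR_PARAMS}
    out_t = np.empty((n_draws, n))
    idraw = 0

    sample_t = n > 0
    do = {b: b not in fixed for b in _BLOCKS}

    for it in range(config.n_iter):
        inv2s2 = 1.0 / (2.0 * sigma * sigma)
        if sample_t:
            # --- individual half-lives: vectorized random walk on t
            tp = t + steps["t_half"] * rng.standard_normal(n)
            valid = tp > 0.0
            tp_safe = np.where(valid, tp, 1.0)
            logtp = np.log(tp_safe)
            rp = z - logtp - C
            inv2tau2 = 1.0 / (2.0 * tau * tau)
            dlog = (r * r - rp * rp) * inv2s2 + ((t - mu) ** 2 - (tp_safe - mu) ** 2) * inv2tau2
            acc = valid & (np.log(rng.random(n)) < dlog)
            if acc.any():
                t = np.where(acc, tp_safe, t)
                logt = np.where(acc, logtp, logt)
                r = np.where(acc, rp, r)
                S1 = float(r.sum())
                S2 = float(r @ r)
            frac = float(acc.mean())
            proposed["t_half"] += 1
            accepted["t_half"] += frac
            win_prop["t_half"] += 1
            win_acc["t_half"] += frac

        if do["mu"]:
            # --- mu: TN conjugate-form independence proposal + Metropolis
            # correction for the Phi(mu/tau)^(-n) normalizing terms
            if n:
                prec = 1.0 / (mu_sd * mu_sd) + n / (tau * tau)
                v = 1.0 / prec
                m = v * (mu_c / (mu_sd * mu_sd) + float(t.sum()) / (tau * tau))
            else:
                v, m = mu_sd * mu_sd, mu_c
            mup = sample_truncated_normal(m, math.sqrt(v), 0.0, np.inf, rng)
            if n:
                la = -n * (float(log_ndtr(mup / tau)) - float(log_ndtr(mu / tau)))
                ok = la >= 0.0 or math.log(rng.random()) < la
            else:
                ok = True
            proposed["mu"] += 1
            if ok:
                mu = mup
                accepted["mu"] += 1

        if do["tau"]:
            taup = tau + steps["tau"] * rng.standard_normal()
            proposed["tau"] += 1
            win_prop["tau"] += 1
            if tau_lo < taup < tau_hi:
                if n:
                    st = float(((t - mu) ** 2).sum())
                    la = (
                        n * (math.log(tau) - math.log(taup))
                        + st * (1.0 / (2.0 * tau * tau) - 1.0 / (2.0 * taup * taup))
                        - n * (float(log_ndtr(mu / taup)) - float(log_ndtr(mu / tau)))
                    )
                else:
                    la = 0.0
                if la >= 0.0 or math.log(rng.random()) < la:
                    tau = taup
                    accepted["tau"] += 1
                    win_acc["tau"] += 1

        # --- kinetic nuisances act on the likelihood only through
        # C = log(Abs * frac_b / (ln2 * V_b)); O(1) via cached S1, S2
        for name, cur, lo, hi, sign in (
            ("Abs", abs_f, abs_lo, abs_hi, 1.0),
            ("frac_b", frac_b, fb_lo, fb_hi, 1.0),
            ("V_b", v_b, vb_lo, vb_hi, -1.0),
        ):
            if not do[name]:
                continue
            prop = cur + steps[name] * rng.standard_normal()
            proposed[name] += 1
            win_prop[name] += 1
            if lo < prop < hi:
                delta = sign * (math.log(prop) - math.log(cur))
                new_S2 = S2 - 2.0 * delta * S1 + n * delta * delta
                la = (S2 - new_S2) * inv2s2
                if la >= 0.0 or math.log(rng.random()) < la:
                    if name == "Abs":
                        abs_f = prop
                    elif name == "frac_b":
                        frac_b = prop
                    else:
                        v_b = prop
                    C += delta
                    if n:
                        r -= delta
                    S1 -= n * delta
                    S2 = new_S2
                    accepted[name] += 1
                    win_acc[name] += 1

        if do["sigma"]:
            # --- log-scale random walk; Jacobian sigma'/sigma for the
            # uniform prior on sigma itself
            sigp = sigma * math.exp(steps["sigma"] * rng.standard_normal())
            proposed["sigma"] += 1
            win_prop["sigma"] += 1
            if sig_lo < sigp < sig_hi:
                la = (
                    -n * (math.log(sigp) - math.log(sigma))
                    - S2 * (1.0 / (2.0 * sigp * sigp) - inv2s2)
                    + (math.log(sigp) - math.log(sigma))
                )
                if la >= 0.0 or math.log(rng.random()) < la:
                    sigma = sigp
                    accepted["sigma"] += 1
                    win_acc["sigma"] += 1

        # --- interweaving group moves: the centered blocks above move mu
        # and tau only through slow drift of the latent half-life vector,
        # so a joint translation of (mu, t) and a joint scaling of
        # (tau, t - mu) walk the directions they cannot (Liu-Sabatti-style
        # group moves; the scale move carries a log-walk Jacobian exp(e)).
        if sample_t and do["mu"]:
            e = steps["mu_shift"] * rng.standard_normal()
            mup = mu + e
            proposed["mu_shift"] += 1
            win_prop["mu_shift"] += 1
            if mup > 0.0 and t.min() + e > 0.0:
                tp = t + e
                logtp = np.log(tp)
                rp = z - logtp - C
                new_S2 = float(rp @ rp)
                la = (
                    (S2 - new_S2) * inv2s2
                    - ((mup - mu_c) ** 2 - (mu - mu_c) ** 2) / (2.0 * mu_sd * mu_sd)
                    - n * (float(log_ndtr(mup / tau)) - float(log_ndtr(mu / tau)))
                )
                if la >= 0.0 or math.log(rng.random()) < la:
                    mu = mup
                    t, logt, r = tp, logtp, rp
                    S1 = float(r.sum())
                    S2 = new_S2
                    accepted["mu_shift"] += 1
                    win_acc["mu_shift"] += 1

        if sample_t and do["tau"]:
            e = steps["tau_scale"] * rng.standard_normal()
            c = math.exp(e)
            taup = c * tau
            proposed["tau_scale"] += 1
            win_prop["tau_scale"] += 1
            if tau_lo < taup < tau_hi:
                tp = mu + c * (t - mu)
                if tp.min() > 0.0:
                    logtp = np.log(tp)
                    rp = z - logtp - C
                    new_S2 = float(rp @ rp)
                    la = (
                        e
                        + (S2 - new_S2) * inv2s2
                        - n * (float(log_ndtr(mu / taup)) - float(log_ndtr(mu / tau)))
                    )
                    if la >= 0.0 or math.log(rng.random()) < la:
                        tau = taup
                        t, logt, r = tp, logtp, rp
                        S1 = float(r.sum())
                        S2 = new_S2
                        accepted["tau_scale"] += 1
                        win_acc["tau_scale"] += 1

        if config.adapt and it < config.burn_in and (it + 1) % 50 == 0:
            for b, sc in steps.items():
                if win_prop[b]:
                    rate = win_acc[b] / win_prop[b]
                    # log-scale walks stay exp-safe; others just bounded
                    hi = 5.0 if b in ("sigma", "tau_scale") else 1e4
                    steps[b] = min(max(sc * math.exp(0.8 * (rate - 0.3)), 1e-8), hi)
                win_prop[b] = 0
                win_acc[b] = 0.0

        if it == config.burn_in - 1:
            dead = [
                b
                for b in _BLOCKS
                if proposed[b] > 0 and accepted[b] == 0 and (b != "t_half" or sample_t)
            ]
            if dead:
                rates = {b: accepted[b] / max(proposed[b], 1) for b in _BLOCKS if proposed[b]}
                raise RuntimeError(
                    f"no accepted proposals during burn-in for blocks {dead}; "
                    f"acceptance rates: {rates}"
                )

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out_scalar["mu"][idraw] = mu
            out_scalar["tau"][idraw] = tau
            out_scalar["Abs"][idraw] = abs_f
            out_scalar["V_b"][idraw] = v_b
            out_scalar["frac_b"][idraw] = frac_b
            out_scalar["sigma"][idraw] = sigma
            if n:
                out_t[idraw] = t
            idraw += 1

    rates = {b: (accepted[b] / proposed[b] if proposed[b] else math.nan) for b in _BLOCKS}
    return out_scalar, out_t, rates


def run_mcmc(
    cohort: pd.DataFrame,
    config: MCMCConfig = MCMCConfig(),
    inits: Sequence[ChainState] | None = None,
    priors: Priors = Priors(),
    fixed: Mapping[str, float] | None = None,
) -> ChainSet:
    """Run the Metropolis-within-Gibbs sampler.

    Parameters
    ----------
    cohort : DataFrame
        Columns ``subject_id, weight_kg, blood_mehg_ug_per_L,
        intake_ug_per_kg_day`` (an empty cohort samples the prior).
    config : MCMCConfig
        Schedule; ``config.seed`` deterministically spawns one independent
        RNG stream per chain, so identical seed+config+input reproduce the
        ChainSet bit for bit.
    inits : sequence of ChainState, optional
        Per-chain initial states; defaults to independent prior draws with
        half-lives initialized at the closed-form inversion, clipped to
        (1, 1000) days.
    fixed : mapping, optional
        Scalar parameters (by reporting name, e.g. ``"sigma"``) to hold
        fixed at given values instead of sampling.
    """
    fixed = dict(fixed or {})
    if cohort is None or len(cohort) == 0:
        y = d = w = np.empty(0)
        ids: list[str] = []
        n_excluded = 0
    else:
        y, d, w, ids, n_excluded = prepare_cohort(cohort, config.floor_zero_intake)
    if inits is not None and len(inits) != config.n_chains:
        raise ValueError("need one initial state per chain")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    per_chain = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(streams[c])
        init = inits[c] if inits is not None else None
        per_chain.append(_run_chain(y, d, w, config, priors, rng, init, fixed))

    draws = {
        p: np.stack([pc[0][p] for pc in per_chain], axis=0) for p in SCALAR_PARAMS
    }
    t_half = np.stack([pc[1] for pc in per_chain], axis=0)
    acceptance = {b: [pc[2][b] for pc in per_chain] for b in _BLOCKS}
    logger.info(
        "MCMC done: n=%d subjects, %d chains x %d draws; mean acceptance %s",
        y.size,
        config.n_chains,
        draws["mu"].shape[1],
        {
            b: round(float(np.nanmean(v)), 3)
            for b, v in acceptance.items()
            if not np.all(np.isnan(v))
        },
    )
    return ChainSet(
        draws=draws,
        t_half=t_half,
        subject_ids=ids,
        config=config,
        acceptance=acceptance,
        n_excluded_zero_intake=n_excluded,
    )


def fit_population(
    cohort: pd.DataFrame,
    config: MCMCConfig = MCMCConfig(),
    stratify_by_sex: bool = False,
    priors: Priors = Priors(),
) -> dict[str, FitResult]:
    """Fit the population model, optionally with independent per-sex fits.

    Returns a mapping stratum -> FitResult; the stratified layout carries
    the blocks ``total``, ``male``, ``female`` (empty strata are skipped
    with a warning).  Each stratum is a fully independent fit: no
    parameters are shared across strata.
    """
    from .diagnostics import summarize

    strata: dict[str, pd.DataFrame] = {"total": cohort}
    if stratify_by_sex:
        for sex in ("male", "female"):
            sub = cohort[cohort["sex"] == sex]
            if len(sub) == 0:
                logger.warning("stratum %r is empty; skipped", sex)
                continue
            strata[sex] = sub.reset_index(drop=True)

    results: dict[str, FitResult] = {}
    for i, (name, sub) in enumerate(strata.items()):
        cfg = replace(config, seed=config.seed + i)
        chains = run_mcmc(sub, cfg, priors=priors)
        results[name] = FitResult(chains=chains, summary=summarize(chains))
    return results
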