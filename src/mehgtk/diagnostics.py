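"""Convergence diagnostics and posterior summaries.

All diagnostics are pure functions of the draw sequences.  The posterior
summary mirrors the conventional reporting layout: one row per parameter
with mean, SD and the 2.5 / 50 / 97.5% quantiles, one block per stratum.
Quantiles use linear interpolation of the empirical CDF (the "type 7"
convention), so outputs are reproducible bit for bit.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "autocorrelation",
    "effective_sample_size",
    "gelman_rubin",
    "summarize",
    "plot_trace",
    "plot_autocorrelation",
    "plot_posterior_density",
]

DEFAULT_QUANTILES = (2.5, 50.0, 97.5)


def _check_varying(chain: np.ndarray) -> np.ndarray:
    chain = np.asarray(chain, float)
    if chain.ndim != 1:
        raise ValueError("chain must be one-dimensional")
    if np.ptp(chain) == 0.0:
        raise ValueError("constant chain: autocorrelation undefined (zero variance)")
    return chain


def autocorrelation(chain, max_lag: int) -> np.ndarray:
    """Empirical autocorrelation at lags 0..max_lag (lag 0 is exactly 1)."""
    chain = _check_varying(chain)
    if len(chain) <= max_lag:
        raise ValueError("chain length must exceed max_lag")
    rho = _sm_acf(chain, nlags=max_lag, fft=True)
    rho[0] = 1.0
    return rho


def effective_sample_size(chain, max_lag: int | None = None) -> float:
    """Effective number of independent draws in an autocorrelated chain.

    Uses the initial-positive-sequence estimator: the autocorrelation sum
    is truncated at the first lag whose consecutive-lag pair sum turns
    negative.  The result is capped at the chain length (an antithetic
    chain may transiently exceed it).
    """
    chain = _check_varying(chain)
    n = len(chain)
    if n < 10:
        raise ValueError("chain too short for ESS estimation (need >= 10)")
    if max_lag is None:
        max_lag = min(n - 1, 1000)
    rho = autocorrelation(chain, max_lag)
    s = 0.0
    for k in range(1, max_lag, 2):
        pair = rho[k] + (rho[k + 1] if k + 1 <= max_lag else 0.0)
        if pair < 0.0:
            break
        s += pair
    ess = n / (1.0 + 2.0 * s)
    return float(min(max(ess, 1e-12), n))


def gelman_rubin(chains: Sequence[np.ndarray]) -> float:
    """Split potential-scale-reduction factor R-hat.

    Each chain is split in half; R-hat compares the pooled between- and
    within-half variances and approaches 1 for well-mixed chains.
    """
    arrs = [np.asarray(c, float) for c in chains]
    if len(arrs) < 2:
        raise ValueError("need at least two chains")
    lengths = {a.shape[0] for a in arrs}
    if len(lengths) != 1:
        raise ValueError("chains must have equal lengths")
    n = lengths.pop()
    if n < 10:
        raise ValueError("chains too short (need length >= 10)")
    half = n // 2
    splits = np.array([h for a in arrs for h in (a[:half], a[half : 2 * half])])
    m, n2 = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w == 0.0:
        raise ValueError("zero within-chain variance")
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def summarize(
    chains,
    quantiles: Sequence[float] = DEFAULT_QUANTILES,
) -> pd.DataFrame:
    """Posterior summary table (mean, SD, quantiles) of pooled draws.

    ``chains`` is either a ChainSet or a mapping parameter -> draw array
    (arrays are pooled over all leading axes).  Output rows follow the
    parameter order given; columns are Mean, SD and the requested
    percentile labels.
    """
    if hasattr(chains, "draws"):
        pools: Mapping[str, np.ndarray] = {k: v.reshape(-1) for k, v in chains.draws.items()}
    else:
        pools = {k: np.asarray(v, float).reshape(-1) for k, v in chains.items()}
    if not pools or any(v.size == 0 for v in pools.values()):
        raise ValueError("empty draws: nothing to summarize")
    q = np.asarray(quantiles, float)
    rows = {}
    for name, x in pools.items():
        qs = np.percentile(x, q)  # linear-interpolation (type 7) quantiles
        rows[name] = [x.mean(), x.std(ddof=1) if x.size > 1 else 0.0, *qs]
    cols = ["Mean", "SD", *[f"{p:g}%" for p in q]]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).rename_axis("parameter")


# ---------------------------------------------------------------------------
# plots (best-effort; contract is only that they run on valid ChainSets)

def _axes_grid(n, ncols=2):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 2.5 * nrows), squeeze=False)
    return fig, axes.ravel()


def plot_trace(chainset, path=None):
    """Per-parameter trace plot, one line per chain."""
    names = list(chainset.draws)
    fig, axes = _axes_grid(len(names))
    for ax, name in zip(axes, names):
        for c in range(chainset.n_chains):
            ax.plot(chainset.draws[name][c], lw=0.4)
        ax.set_title(name)
        ax.set_xlabel("retained draw")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_autocorrelation(chainset, max_lag: int = 40, path=None):
    """Autocorrelation of each parameter (first chain)."""
    names = list(chainset.draws)
    fig, axes = _axes_grid(len(names))
    for ax, name in zip(axes, names):
        rho = autocorrelation(chainset.draws[name][0], max_lag)
        ax.bar(np.arange(len(rho)), rho, width=0.8)
        ax.set_title(name)
        ax.set_xlabel("lag")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_posterior_density(chainset, path=None):
    """Pooled posterior density per parameter (histogram)."""
    names = list(chainset.draws)
    fig, axes = _axes_grid(len(names))
    for ax, name in zip(axes, names):
        ax.hist(chainset.pooled(name), bins=60, density=True)
        ax.set_title(name)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
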