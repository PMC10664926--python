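"""Rare-event posterior for total mortality M and the credible bound M*.

When carcasses are rare, the observed count x understates mortality: each
of M fatalities is detected independently with overall probability g, so
x | M ~ Binomial(M, g).  Fatality estimation in this regime asks how large
M could plausibly be.  With an objective prior on M — the marginal of
M | λ ~ Poisson(λ) under the Jeffreys rate prior π(λ) ∝ λ^{-1/2}, i.e.

    π(m) = Γ(m + ½) / m!,

the posterior is p(m | x) ∝ C(m, x) g^x (1−g)^{m−x} π(m) for m ≥ x, and
M* is the smallest m whose cumulative posterior reaches the credibility
level 1 − α.  Uncertainty in g enters by replacing the binomial with its
beta-binomial mixture over g ~ Beta(α_g, β_g).

All mass functions are computed in log space (no factorial overflow for m
up to 10⁷), with the truncation point grown adaptively until the
neglected tail is below 1e-8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

__all__ = [
    "PosteriorM",
    "objective_prior",
    "log_objective_prior",
    "posterior_m",
    "posterior_m_beta",
    "m_star",
    "mstar_table",
]

TAIL_TOL = 1e-8


def log_objective_prior(m) -> np.ndarray:
    """log π(m) with π(m) = Γ(m+½)/m! (unnormalised; decreasing in m)."""
    m = np.asarray(m, dtype=float)
    return gammaln(m + 0.5) - gammaln(m + 1.0)


def objective_prior(m_max: int) -> np.ndarray:
    """Unnormalised prior weights π(0..m_max); π(0) = Γ(½) = √π."""
    if m_max < 0:
        raise ValueError("m_max must be >= 0")
    return np.exp(log_objective_prior(np.arange(m_max + 1)))


@dataclass
class PosteriorM:
    """Truncated posterior mass function over total mortality M."""

    x: int
    g_spec: Union[float, tuple[float, float]]
    pmf: np.ndarray
    m_max: int

    @property
    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def mean(self) -> float:
        return float(np.arange(self.m_max + 1) @ self.pmf)


def _log_unnorm_fixed(m: np.ndarray, x: int, g: float) -> np.ndarray:
    out = np.full(m.shape, -np.inf)
    ok = m >= x
    mm = m[ok]
    out[ok] = (
        gammaln(mm + 1.0) - gammaln(x + 1.0) - gammaln(mm - x + 1.0)
        + x * math.log(g) + (mm - x) * math.log1p(-g)
        + log_objective_prior(mm)
    )
    return out


def _log_unnorm_beta(m: np.ndarray, x: int, a: float, b: float) -> np.ndarray:
    out = np.full(m.shape, -np.inf)
    ok = m >= x
    mm = m[ok]
    out[ok] = (
        gammaln(mm + 1.0) - gammaln(x + 1.0) - gammaln(mm - x + 1.0)
        + betaln(a + x, b + mm - x) - betaln(a, b)
        + log_objective_prior(mm)
    )
    return out


def _adaptive_pmf(log_unnorm, m_start: int, m_cap: int = 1 << 22) -> np.ndarray:
    """Normalised pmf over 0..m_max, doubling m_max until the relative
    tail (estimated geometrically from the terminal decay rate) is tiny."""
    m_max = m_start
    while True:
        m = np.arange(m_max + 1)
        lw = log_unnorm(m)
        w = np.exp(lw - np.max(lw))
        total = w.sum()
        # geometric tail bound from the last ratio
        ratio = w[-1] / w[-2] if w[-2] > 0 else 0.0
        tail = w[-1] * ratio / (1.0 - ratio) if 0.0 < ratio < 1.0 else w[-1] * m_max
        if w[-1] == 0.0 or tail / total < TAIL_TOL:
            return w / total
        if m_max >= m_cap:
            raise RuntimeError(
                f"posterior tail not converged by m_max={m_max}; "
                "posterior may be too heavy-tailed (check g specification)"
            )
        m_max *= 2


def posterior_m(x: int, g: float) -> PosteriorM:
    """Posterior over M for observed count x and fixed detection g."""
    if x < 0 or int(x) != x:
        raise ValueError("x must be a nonnegative integer")
    if not 0.0 < g <= 1.0:
        raise ValueError("g must be in (0, 1]; the posterior is improper at g = 0")
    x = int(x)
    if g == 1.0:
        pmf = np.zeros(x + 1)
        pmf[x] = 1.0
        return PosteriorM(x=x, g_spec=g, pmf=pmf, m_max=x)
    m_start = x + math.ceil(10.0 / g) + 50
    pmf = _adaptive_pmf(lambda m: _log_unnorm_fixed(m, x, g), m_start)
    return PosteriorM(x=x, g_spec=g, pmf=pmf, m_max=len(pmf) - 1)


def posterior_m_beta(x: int, g_alpha: float, g_beta: float) -> PosteriorM:
    """Posterior over M with g ~ Beta(g_alpha, g_beta) uncertainty.

    Reduces to :func:`posterior_m` at the Beta mean as the Beta variance
    shrinks.  The marginal posterior tail thickens as ~ m^{-(g_alpha+½)},
    so g_alpha must exceed ½ for a proper posterior.
    """
    if x < 0 or int(x) != x:
        raise ValueError("x must be a nonnegative integer")
    if g_alpha <= 0 or g_beta <= 0:
        raise ValueError("Beta parameters must be positive")
    if g_alpha <= 0.5:
        raise ValueError("g_alpha must exceed 0.5 for a proper posterior on M")
    x = int(x)
    g_mean = g_alpha / (g_alpha + g_beta)
    m_start = x + math.ceil(10.0 / g_mean) + 50
    pmf = _adaptive_pmf(lambda m: _log_unnorm_beta(m, x, g_alpha, g_beta), m_start)
    return PosteriorM(x=x, g_spec=(g_alpha, g_beta), pmf=pmf, m_max=len(pmf) - 1)


def m_star(posterior: PosteriorM, alpha: float = 0.5) -> int:
    """Credible upper bound: smallest m with P(M ≤ m | x) ≥ 1 − α."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    cdf = posterior.cdf
    # small epsilon guards the >= comparison against accumulated rounding
    idx = int(np.searchsorted(cdf, 1.0 - alpha - 1e-12))
    return max(idx, posterior.x)


def mstar_table(
    g_values=(0.10, 0.20, 0.30, 0.40, 0.50),
    x_values=(0, 1, 2, 3, 4),
    alpha: float = 0.5,
) -> pd.DataFrame:
    """M* grid over detection probabilities and observed counts."""
    rows = []
    for g in g_values:
        row = {"g": g}
        for x in x_values:
            row[f"x={x}"] = m_star(posterior_m(x, g), alpha)
        rows.append(row)
    return pd.DataFrame(rows)
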