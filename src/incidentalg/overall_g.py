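"""Assembly of the overall probability of incidental detection, g.

For one site-season class the overall probability that a carcass arriving
during the period is both available and incidentally detected factorises
approximately as

    g ≈ p · r · a,

where p is the per-opportunity detection probability estimated from decoy
trials, r the mean probability of persisting between detection
opportunities, and a the density-weighted area adjustment.  A carcass
missed once is harder to find again; the detection decay factor k scales
detection on successive opportunities (p, pk, pk², ...).  The default
k = 0.67 is the only published estimate, with a 30-day search interval and
a single guaranteed opportunity per interval.

Season classes combine by weighted average (uniform 0.25 weights when
temporal collision risk is treated as uniform); multi-year averages follow
the same rule with effort weights.  Uncertainty is propagated by
transparent parametric Monte Carlo: a Jeffreys Beta posterior on p, the
asymptotic normal of the persistence fit on r, and a held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .persistence import (
    PersistenceModel,
    mean_persistence_from_params,
    mean_persistence_probability,
)

__all__ = [
    "DEFAULT_K",
    "DEFAULT_INTERVAL_DAYS",
    "SeasonClassG",
    "CombinedG",
    "class_g",
    "effective_detection",
    "persistence_r_draws",
    "g_uncertainty",
    "combine_classes",
    "multi_year_g",
]

DEFAULT_K = 0.67
DEFAULT_INTERVAL_DAYS = 30.0


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")


def class_g(p: float, r: float, a: float) -> float:
    """g ≈ p·r·a for one class."""
    for name, v in (("p", p), ("r", r), ("a", a)):
        _check_unit(name, v)
    return p * r * a


def effective_detection(
    p: float,
    k: float,
    persistence_model: PersistenceModel,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    n_searches: int = 1,
) -> float:
    """Probability of ever detecting a carcass over J search opportunities.

    A carcass arrives uniformly in the first interval and may be found on
    searches at I, 2I, ..., JI with detection p·k^{j-1} on the j-th
    opportunity, provided it persisted that long and was missed before:

        p_eff = Σ_j E_T[S(jI − T)] · p·k^{j−1} · Π_{i<j}(1 − p·k^{i−1}).

    With J = 1 this is exactly p·r — the product form of g.  The result
    already includes persistence, so g = p_eff · a.
    """
    _check_unit("p", p)
    _check_unit("k", k)
    if n_searches < 1:
        raise ValueError("n_searches must be >= 1")
    total = 0.0
    miss = 1.0
    for j in range(1, n_searches + 1):
        # E_T[S(jI - T)] = (1/I) ∫_{(j-1)I}^{jI} S(u) du
        e_j = _interval_mean_survival(persistence_model, interval_days, j)
        detect_j = p * k ** (j - 1)
        total += e_j * detect_j * miss
        miss *= 1.0 - detect_j
    return total


def _interval_mean_survival(model: PersistenceModel, interval: float, j: int) -> float:
    from scipy import integrate

    if j == 1:
        return mean_persistence_probability(model, interval)
    value, _ = integrate.quad(lambda u: float(model.sf(u)),
                              (j - 1) * interval, j * interval,
                              epsabs=1e-10, limit=200)
    return value / interval


@dataclass
class SeasonClassG:
    """Per-(site, season) overall detection probability with uncertainty."""

    site_id: str
    season: str
    p: float
    k: float
    r: float
    a: float
    n_searches: int
    g: float
    g_ci90: tuple[float, float]
    beta_fit: Optional[tuple[float, float]]
    n_found: int = 0
    n_available: int = 0
    not_applicable: bool = False
    draws: Optional[np.ndarray] = field(default=None, repr=False)


@dataclass
class CombinedG:
    classes: list[SeasonClassG]
    weights: tuple[float, ...]
    g_bar: float
    ci90: tuple[float, float]
    beta_fit: Optional[tuple[float, float]] = None
    draws: Optional[np.ndarray] = field(default=None, repr=False)


def _beta_moment_match(draws: np.ndarray) -> Optional[tuple[float, float]]:
    m = float(np.mean(draws))
    v = float(np.var(draws))
    if v <= 0 or not 0 < m < 1:
        return None
    c = m * (1.0 - m) / v - 1.0
    if c <= 0:
        return None
    return (m * c, (1.0 - m) * c)


def persistence_r_draws(
    persistence_model: PersistenceModel,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    n_draws: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Monte Carlo draws of r from the persistence fit's asymptotic normal.

    Classes that share one persistence fit share its estimation error, so
    the same draw vector should be passed to each of their g computations;
    drawing independently per class would spuriously average the shared
    error away in the combined interval.
    """
    rng = np.random.default_rng(seed)
    if persistence_model.fitter is None:
        r_point = mean_persistence_probability(persistence_model, interval_days)
        return np.full(n_draws, r_point)
    param_draws = persistence_model.parameter_draws(n_draws, rng)
    r = np.array([
        mean_persistence_from_params(persistence_model.family, pd_, interval_days)
        for pd_ in param_draws
    ])
    return np.clip(r, 0.0, 1.0)


def g_uncertainty(
    n_found: int,
    n_available: int,
    persistence_model: PersistenceModel,
    a: float,
    k: float = DEFAULT_K,
    interval_days: float = DEFAULT_INTERVAL_DAYS,
    n_searches: int = 1,
    n_draws: int = 2000,
    seed: int = 0,
    site_id: str = "",
    season: str = "",
    r_draws: Optional[np.ndarray] = None,
) -> SeasonClassG:
    """Monte Carlo g for one class: Jeffreys Beta on p, asymptotic normal
    on the persistence parameters, area adjustment fixed.

    ``r_draws`` supplies precomputed persistence draws (see
    :func:`persistence_r_draws`); pass the same vector to every class that
    shares a persistence fit so the combined interval keeps the common
    estimation error.  A season with no trials possible (n_available = 0)
    or no searched area (a = 0) has g = 0 with a not-applicable interval,
    mirroring winter shutdowns.
    """
    _check_unit("a", a)
    _check_unit("k", k)
    if n_found > n_available:
        raise ValueError("n_found exceeds n_available")
    r_point = mean_persistence_probability(persistence_model, interval_days)
    if n_available == 0 or a == 0.0:
        return SeasonClassG(
            site_id=site_id, season=season, p=0.0, k=k, r=r_point, a=a,
            n_searches=n_searches, g=0.0, g_ci90=(0.0, 0.0), beta_fit=None,
            n_found=n_found, n_available=n_available, not_applicable=True,
            draws=np.zeros(n_draws),
        )
    rng = np.random.default_rng(seed)
    p_hat = n_found / n_available
    p_draws = rng.beta(n_found + 0.5, n_available - n_found + 0.5, size=n_draws)
    if r_draws is None:
        r_draws = persistence_r_draws(persistence_model, interval_days,
                                      n_draws, seed=seed + 1)
    elif len(r_draws) != n_draws:
        raise ValueError("r_draws length must equal n_draws")

    if n_searches == 1:
        g_draws = p_draws * r_draws * a
        g_point = class_g(p_hat, r_point, a)
    else:
        # scale the single-opportunity p·r draws by the multi-search uplift
        uplift = (effective_detection(p_hat, k, persistence_model,
                                      interval_days, n_searches)
                  / max(p_hat * r_point, 1e-300))
        g_draws = p_draws * r_draws * a * uplift
        g_point = effective_detection(p_hat, k, persistence_model,
                                      interval_days, n_searches) * a
    lo, hi = np.quantile(g_draws, [0.05, 0.95])
    return SeasonClassG(
        site_id=site_id, season=season, p=p_hat, k=k, r=r_point, a=a,
        n_searches=n_searches, g=g_point, g_ci90=(float(lo), float(hi)),
        beta_fit=_beta_moment_match(g_draws), n_found=n_found,
        n_available=n_available, draws=g_draws,
    )


def combine_classes(
    classes: Sequence[SeasonClassG],
    weights: Optional[Sequence[float]] = None,
) -> CombinedG:
    """Weighted combination of class g's: g_bar = Σ wᵢ gᵢ.

    The combined uncertainty mixes the per-class Monte Carlo draws with
    the same weights (draw streams are aligned by index, so the same seeds
    reproduce the same combined interval).
    """
    if not classes:
        raise ValueError("no classes supplied")
    if weights is None:
        weights = [1.0 / len(classes)] * len(classes)
    if len(weights) != len(classes):
        raise ValueError("weights length must match classes")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    if abs(sum(weights) - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    g_bar = float(sum(w * c.g for w, c in zip(weights, classes)))
    draws = None
    ci = (g_bar, g_bar)
    if all(c.draws is not None for c in classes):
        lengths = {len(c.draws) for c in classes}
        if len(lengths) != 1:
            raise ValueError("per-class draw counts differ; use a common n_draws")
        draws = np.zeros(lengths.pop())
        for w, c in zip(weights, classes):
            draws += w * c.draws
        lo, hi = np.quantile(draws, [0.05, 0.95])
        ci = (float(lo), float(hi))
    return CombinedG(classes=list(classes), weights=tuple(weights), g_bar=g_bar,
                     ci90=ci, beta_fit=_beta_moment_match(draws) if draws is not None else None,
                     draws=draws)


def multi_year_g(
    yearly_g: Sequence[float],
    yearly_weights: Optional[Sequence[float]] = None,
) -> float:
    """Average g over a multi-year period with effort weights.

    Uniform weights by default; years without monitoring contribute their
    (possibly zero) g at full weight.
    """
    if not len(yearly_g):
        raise ValueError("no yearly g values supplied")
    for gy in yearly_g:
        _check_unit("g", gy)
    if yearly_weights is None:
        yearly_weights = [1.0 / len(yearly_g)] * len(yearly_g)
    if len(yearly_weights) != len(yearly_g):
        raise ValueError("weights length must match yearly_g")
    if abs(sum(yearly_weights) - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    return float(sum(w * gy for w, gy in zip(yearly_weights, yearly_g)))
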