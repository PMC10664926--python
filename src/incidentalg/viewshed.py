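"""Viewshed complexity and the density-weighted area adjustment.

The area adjustment ``a`` is the expected fraction of carcasses that fall
where detection is possible.  It combines three pieces:

* a map of viewshed complexity classes (low / moderate / high /
  unviewable) on a regular grid covering the 100-m search disc around a
  turbine,
* a radial carcass fall-distance density f(r) on [0, 100] m, calibrated so
  its quartiles match the published density-quartile boundaries
  (33 / 45 / 61 m), and
* the fraction of turbines actually visited.

The density-weighted proportion (DWP) of a grid weights each viewable cell
by the carcass density at its centre, f(r)/(2πr) per unit area, so blocked
area far from the turbine — where few carcasses fall — costs less than
blocked area near the base.  DWP can therefore exceed the unweighted
viewable proportion.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GRID_CLASSES",
    "classify_viewshed",
    "FallDistanceModel",
    "calibrate_fall_distance",
    "ViewshedGrid",
    "AreaAdjustment",
    "density_weighted_proportion",
    "site_area_adjustment",
]

#: integer codes used in grid files
GRID_CLASSES = ("low", "moderate", "high", "unviewable")
UNVIEWABLE = GRID_CLASSES.index("unviewable")

VEG_HEIGHT_CLASSES = ("lt15", "16_30", "31_45", "gt46", "rocky")

# ground-cover lookup: rows = bare-ground bands (high to none), columns =
# vegetation height classes lt15 / 16_30 / 31_45 / gt46 / rocky
_CLASSIFICATION = {
    "gt90": ("low", "low", "low", "low", "moderate"),
    "26_90": ("low", "moderate", "moderate", "moderate", "moderate"),
    "1_25": ("low", "moderate", "high", "high", "high"),
    "0": ("low", "moderate", "high", "high", "high"),
}


def classify_viewshed(percent_bare_ground: float, veg_height_class: str) -> str:
    """Viewshed complexity class from ground-cover descriptors.

    Bare-ground bands are >90 / 26–90 / 1–25 / 0 percent (the middle band
    boundaries are treated as continuous: anything in (25, 90] falls in the
    middle band).
    """
    if not 0.0 <= percent_bare_ground <= 100.0:
        raise ValueError("percent_bare_ground outside [0, 100]")
    if veg_height_class not in VEG_HEIGHT_CLASSES:
        raise ValueError(
            f"veg_height_class={veg_height_class!r} not one of {VEG_HEIGHT_CLASSES}"
        )
    if percent_bare_ground > 90.0:
        row = "gt90"
    elif percent_bare_ground > 25.0:
        row = "26_90"
    elif percent_bare_ground > 0.0:
        row = "1_25"
    else:
        row = "0"
    return _CLASSIFICATION[row][VEG_HEIGHT_CLASSES.index(veg_height_class)]


@dataclass
class FallDistanceModel:
    """Radial carcass fall-distance distribution truncated at ``r_max``.

    A two-parameter positive family (gamma by default) truncated to
    [0, r_max]; F(r) = F0(r) / F0(r_max) where F0 is the untruncated CDF.
    """

    family: str
    shape: float
    scale: float
    r_max: float = 100.0
    achieved_quartiles: Optional[tuple[float, float, float]] = None
    fit_sse: Optional[float] = None

    def _dist(self):
        if self.family == "gamma_truncated":
            return stats.gamma(self.shape, scale=self.scale)
        if self.family == "weibull_truncated":
            return stats.weibull_min(self.shape, scale=self.scale)
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def _trunc_mass(self) -> float:
        return self._dist().cdf(self.r_max)

    def pdf(self, r):
        r = np.asarray(r, dtype=float)
        out = self._dist().pdf(r) / self._trunc_mass
        return np.where((r >= 0) & (r <= self.r_max), out, 0.0)

    def cdf(self, r):
        r = np.asarray(r, dtype=float)
        out = self._dist().cdf(np.clip(r, 0.0, self.r_max)) / self._trunc_mass
        return np.clip(out, 0.0, 1.0)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        return self._dist().ppf(q * self._trunc_mass)

    def quartiles(self) -> tuple[float, float, float]:
        q = self.ppf(np.array([0.25, 0.5, 0.75]))
        return tuple(float(v) for v in q)

    def mode(self) -> float:
        if self.family == "gamma_truncated":
            return max(0.0, (self.shape - 1.0) * self.scale)
        if self.family == "weibull_truncated":
            if self.shape <= 1.0:
                return 0.0
            return self.scale * ((self.shape - 1.0) / self.shape) ** (1.0 / self.shape)
        raise ValueError(self.family)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample fall distances by inverse-CDF of the truncated family."""
        return np.asarray(self.ppf(rng.uniform(size=n)), dtype=float)


def calibrate_fall_distance(
    quartiles_m: Sequence[float] = (33.0, 45.0, 61.0),
    r_max: float = 100.0,
    family: str = "gamma_truncated",
) -> FallDistanceModel:
    """Fit a truncated two-parameter family to target fall-distance quartiles.

    Minimises the squared error (in metres) between model and target
    quartiles.  The defaults anchor the model to the published density
    quartile boundaries, giving a unimodal density rising to a mode near
    40 m and decaying out to 100 m.
    """
    q1, q2, q3 = (float(q) for q in quartiles_m)
    if not 0.0 < q1 < q2 < q3 < r_max:
        raise ValueError("quartiles must satisfy 0 < q1 < q2 < q3 < r_max")
    targets = np.array([q1, q2, q3])

    def objective(log_params):
        shape, scale = np.exp(log_params)
        model = FallDistanceModel(family, shape, scale, r_max)
        with np.errstate(all="ignore"):
            achieved = np.asarray(model.ppf([0.25, 0.5, 0.75]), dtype=float)
        if not np.all(np.isfinite(achieved)):
            return 1e12
        return float(np.sum((achieved - targets) ** 2))

    x0 = np.log([2.5, q2 / 2.0])
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    if not res.success:
        raise RuntimeError(f"fall-distance calibration failed: {res.message}")
    shape, scale = np.exp(res.x)
    model = FallDistanceModel(family, float(shape), float(scale), r_max)
    model.achieved_quartiles = model.quartiles()
    model.fit_sse = float(res.fun)
    return model


@dataclass
class ViewshedGrid:
    """Regular grid of viewshed classes on the turbine-centred search disc.

    ``cells`` holds integer codes indexing :data:`GRID_CLASSES`; the grid
    origin is the turbine base at the array centre and cell membership is
    by cell-centre distance.
    """

    turbine_id: str
    cell_size_m: float
    cells: np.ndarray
    radius_m: float = 100.0

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D array")
        half_extent = max(self.cells.shape) * self.cell_size_m / 2.0
        if half_extent + self.cell_size_m / 2.0 < self.radius_m:
            raise ValueError("grid does not cover the full search disc")

    def cell_distances(self) -> np.ndarray:
        ny, nx = self.cells.shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.cell_size_m
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.cell_size_m
        return np.hypot(y[:, None], x[None, :])

    def in_disc(self) -> np.ndarray:
        return self.cell_distances() <= self.radius_m

    @property
    def viewable_proportion(self) -> float:
        disc = self.in_disc()
        return float(np.mean(self.cells[disc] != UNVIEWABLE))

    @classmethod
    def full(cls, turbine_id: str, class_name: str = "low",
             cell_size_m: float = 1.0, radius_m: float = 100.0) -> "ViewshedGrid":
        n = int(np.ceil(2 * radius_m / cell_size_m)) + 1
        code = GRID_CLASSES.index(class_name)
        return cls(turbine_id, cell_size_m, np.full((n, n), code, dtype=np.int8),
                   radius_m)

    def to_csv(self, path) -> None:
        header = (f"# turbine_id={self.turbine_id} cell_size_m={self.cell_size_m} "
                  f"radius_m={self.radius_m}\n")
        buf = io.StringIO()
        np.savetxt(buf, self.cells, fmt="%d", delimiter=",")
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "ViewshedGrid":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("grid CSV must start with a '# key=value' header line")
            meta = dict(tok.split("=") for tok in header[1:].split())
            cells = np.loadtxt(fh, dtype=int, delimiter=",")
        return cls(
            turbine_id=meta["turbine_id"],
            cell_size_m=float(meta["cell_size_m"]),
            cells=cells,
            radius_m=float(meta.get("radius_m", 100.0)),
        )


@dataclass(frozen=True)
class AreaAdjustment:
    """Site-season area adjustment a = mean DWP × fraction of turbines searched."""

    dwp: float
    turbines_searched_fraction: float
    a: float
    viewable_proportion: Optional[float] = None
    n_searched: int = 0
    n_total: int = 0


def _cell_weights(grid: ViewshedGrid, model: FallDistanceModel) -> np.ndarray:
    """Carcass mass attributed to each in-disc cell (cell-centre rule).

    Weight is f(r)/(2πr) × cell area at the cell-centre distance r.  The
    centre cell (r → 0) instead gets the total carcass mass of an
    equal-area disc, avoiding the 1/r singularity.
    """
    r = grid.cell_distances()
    area = grid.cell_size_m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = model.pdf(r) / (2.0 * np.pi * r) * area
    # equal-area-disc rule for any cell containing the turbine base
    rho = grid.cell_size_m / np.sqrt(np.pi)
    centre = r < grid.cell_size_m / 2.0
    w[centre] = float(model.cdf(rho)) / max(int(centre.sum()), 1)
    w[~grid.in_disc()] = 0.0
    return w


def density_weighted_proportion(
    grid: ViewshedGrid, model: FallDistanceModel
) -> tuple[float, float]:
    """(viewable_proportion, dwp) for one turbine grid.

    dwp is the carcass-density-weighted fraction of the disc that is
    viewable; viewable_proportion is the unweighted cell-area fraction.
    """
    if model.r_max != grid.radius_m:
        raise ValueError("fall-distance model must be truncated at the grid radius")
    w = _cell_weights(grid, model)
    total = float(w.sum())
    viewable = float(w[grid.cells != UNVIEWABLE].sum())
    return grid.viewable_proportion, viewable / total


def site_area_adjustment(
    per_turbine_dwp: Sequence[float],
    n_searched: int,
    n_total: int,
    viewable_proportions: Optional[Sequence[float]] = None,
) -> AreaAdjustment:
    """Combine per-turbine DWP with the fraction of turbines searched.

    Unsearched turbines are assumed similar to searched ones; only their
    count enters, via n_searched / n_total.  A season with no searched
    turbines (e.g. a winter access shutdown) yields a = 0.
    """
    if n_searched > n_total:
        raise ValueError("n_searched exceeds n_total")
    if n_searched == 0:
        warnings.warn(
            "no turbines searched; area adjustment is 0 for this season",
            stacklevel=2,
        )
        return AreaAdjustment(dwp=float("nan"), turbines_searched_fraction=0.0,
                              a=0.0, n_searched=0, n_total=n_total)
    if len(per_turbine_dwp) != n_searched:
        raise ValueError("need one dwp per searched turbine")
    dwp = float(np.mean(per_turbine_dwp))
    frac = n_searched / n_total
    vp = float(np.mean(viewable_proportions)) if viewable_proportions is not None else None
    return AreaAdjustment(dwp=dwp, turbines_searched_fraction=frac, a=dwp * frac,
                          viewable_proportion=vp, n_searched=n_searched,
                          n_total=n_total)
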