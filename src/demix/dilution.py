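"""Basis-material endpoint calibration from aqueous dilution series.

An aqueous basis solution diluted with water attenuates linearly in
concentration: ``mu(c) = (c / c_stock) * mu_stock + (1 - c / c_stock) *
mu_water``. Measuring a handful of dilutions and fitting ordinary least
squares per energy therefore pins down the stock ("endpoint") attenuation with
better statistical accuracy than a single measurement at full concentration.

The fit is two independent OLS regressions of mu against concentration, one
per energy; the endpoint is the fitted line evaluated at the stock
concentration. Parameter uncertainty is reported as relative standard error in
percent, |SE / estimate| * 100.

Because every series is water-based, the zero-concentration intercepts of all
series should coincide with the attenuation of pure water; the
:func:`water_intersection_check` diagnostic quantifies how well they do (and
where the series lines mutually intersect in the (mu_low, mu_high) plane)
without ever failing — disagreement is a data-quality signal, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import AttenuationVector
from .errors import DegenerateDesignError, InsufficientDataError, InvalidInputError

__all__ = [
    "ConcentrationSeries",
    "RegressionResult",
    "WaterIntersectionReport",
    "fit_series",
    "water_intersection_check",
]


@dataclass(frozen=True)
class ConcentrationSeries:
    """Dilution series for one material: (concentration, attenuation) points."""

    material_name: str
    points: tuple[tuple[float, AttenuationVector], ...]
    stock_concentration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) < 3:
            raise InsufficientDataError(
                f"need >= 3 points, got {len(self.points)} for {self.material_name!r}"
            )
        concs = [c for c, _ in self.points]
        if any(not c > 0 for c in concs):
            raise InvalidInputError("concentrations must be strictly positive")
        if self.stock_concentration < max(concs):
            raise InvalidInputError(
                "stock_concentration must be >= the largest series concentration"
            )

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    def mu(self, energy: int) -> np.ndarray:
        """Attenuations at energy channel 0 (low) or 1 (high)."""
        return np.array([p.as_array()[energy] for _, p in self.points])


@dataclass(frozen=True)
class RegressionResult:
    """Per-energy OLS fit of one dilution series and its endpoint."""

    material_name: str
    stock_concentration: float
    slope: tuple[float, float]              # 1/cm per mg/ml, (low, high)
    intercept: tuple[float, float]          # 1/cm
    slope_stderr: tuple[float, float]
    intercept_stderr: tuple[float, float]
    endpoint: AttenuationVector             # fitted line at stock concentration
    relative_slope_error_pct: tuple[float, float]
    relative_intercept_error_pct: tuple[float, float]
    residual_norm: tuple[float, float]

    def line_point(self, concentration: float) -> np.ndarray:
        """Fitted (mu_low, mu_high) at a given concentration."""
        return np.array(
            [self.intercept[e] + self.slope[e] * concentration for e in (0, 1)]
        )


def _rel_err_pct(se: float, estimate: float) -> float:
    if estimate == 0.0:
        return float("inf") if se > 0 else 0.0
    return abs(se / estimate) * 100.0


def fit_series(series: ConcentrationSeries) -> RegressionResult:
    """Fit mu against concentration by OLS, independently per energy.

    Returns slopes/intercepts with standard errors and the endpoint evaluated
    at the stock concentration. A series whose points lie exactly on a line is
    recovered to round-off with zero standard errors.
    """
    c = series.concentrations
    if np.ptp(c) == 0.0:
        raise DegenerateDesignError(
            f"all concentrations identical ({c[0]} mg/ml); slope is undetermined"
        )
    slopes, intercepts, s_se, i_se, resid = [], [], [], [], []
    for energy in (0, 1):
        mu = series.mu(energy)
        fit = stats.linregress(c, mu)
        slopes.append(float(fit.slope))
        intercepts.append(float(fit.intercept))
        s_se.append(float(fit.stderr) if np.isfinite(fit.stderr) else 0.0)
        i_se.append(float(fit.intercept_stderr) if np.isfinite(fit.intercept_stderr) else 0.0)
        resid.append(float(np.linalg.norm(mu - (fit.slope * c + fit.intercept))))
    endpoint = AttenuationVector(
        intercepts[0] + slopes[0] * series.stock_concentration,
        intercepts[1] + slopes[1] * series.stock_concentration,
    )
    return RegressionResult(
        material_name=series.material_name,
        stock_concentration=series.stock_concentration,
        slope=(slopes[0], slopes[1]),
        intercept=(intercepts[0], intercepts[1]),
        slope_stderr=(s_se[0], s_se[1]),
        intercept_stderr=(i_se[0], i_se[1]),
        endpoint=endpoint,
        relative_slope_error_pct=(_rel_err_pct(s_se[0], slopes[0]),
                                  _rel_err_pct(s_se[1], slopes[1])),
        relative_intercept_error_pct=(_rel_err_pct(i_se[0], intercepts[0]),
                                      _rel_err_pct(i_se[1], intercepts[1])),
        residual_norm=(resid[0], resid[1]),
    )


@dataclass(frozen=True)
class WaterIntersectionReport:
    """Diagnostic distances of dilution regressions to the pure-water point."""

    #: per material: |intercept - mu_water| at (low, high), in 1/cm
    intercept_offsets: dict[str, tuple[float, float]]
    #: per material pair: intersection of the two series lines in the
    #: (mu_low, mu_high) plane, or None for parallel lines
    pairwise_intersections: dict[tuple[str, str], Optional[tuple[float, float]]]
    #: largest Euclidean distance between any two intersection points (0 if < 2)
    max_pairwise_scatter: float


def water_intersection_check(
    regressions: Sequence[RegressionResult],
    water_point: AttenuationVector,
) -> WaterIntersectionReport:
    """Check that zero-concentration extrapolations meet at pure water.

    All series are water dilutions, so in theory every fitted line passes
    through the water point at concentration zero. Reports per-material,
    per-energy |intercept - mu_water| plus the scatter of pairwise line
    intersections in the (mu_low, mu_high) plane. Purely diagnostic: never
    raises on disagreement.
    """
    if len(regressions) < 2:
        raise InsufficientDataError("need >= 2 regressions to compare")
    w = water_point.as_array()
    offsets = {
        r.material_name: (abs(r.intercept[0] - w[0]), abs(r.intercept[1] - w[1]))
        for r in regressions
    }
    intersections: dict[tuple[str, str], Optional[tuple[float, float]]] = {}
    points = []
    for ra, rb in combinations(regressions, 2):
        key = (ra.material_name, rb.material_name)
        # line m: (mu_low, mu_high)(c) = intercept_m + slope_m * c; solve
        # ra(c_a) == rb(c_b) for (c_a, c_b)
        mat = np.array([[ra.slope[0], -rb.slope[0]], [ra.slope[1], -rb.slope[1]]])
        rhs = np.array([rb.intercept[0] - ra.intercept[0],
                        rb.intercept[1] - ra.intercept[1]])
        if abs(np.linalg.det(mat)) < 1e-300:
            intersections[key] = None
            continue
        ca, _cb = np.linalg.solve(mat, rhs)
        point = ra.line_point(float(ca))
        intersections[key] = (float(point[0]), float(point[1]))
        points.append(point)
    scatter = 0.0
    for pa, pb in combinations(points, 2):
        scatter = max(scatter, float(np.linalg.norm(pa - pb)))
    return WaterIntersectionReport(offsets, intersections, scatter)
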