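"""Global calibration of basis-material attenuation correction factors.

The attenuation of clot constituents (fibrin/platelets, RBC, WBC) cannot be
measured in isolation; it is seeded from tabulated chemical assumptions and
then corrected against specimens whose three-material composition is known
from histology and which contain no contrast agent — only the formalin they
were fixed in interferes.

For each such specimen j the CT point is first adjusted for the (unknown)
formalin fraction f4_j,

    mu'_j = (mu_CT_j - f4_j * mu_formalin) / (1 - f4_j),

and then compared with what the corrected basis predicts for the histology
composition: each entry of the 2x3 attenuation matrix gets a multiplicative
correction factor c_m (m = 1..6, one per material x energy), and the group
cost is

    L(c, f4) = sum_j || (mu'_j, 1) - M(c) @ f_j^Histo ||^2

with M(c) the corrected attenuation rows plus a row of ones (volume
conservation). L is neither linear nor convex in (c, f4) jointly, so a global
optimizer over a bounded box is required. Following the field convention the
WBC factors are frozen at 1 (WBC is close to generic soft tissue and
contributes little), leaving 4 free factors + one formalin fraction per
specimen.

Implementation: for fixed f4 the cost is an ordinary bounded linear least
squares in c (solved exactly), so the search is projected onto the formalin
fractions alone — a simplicial-homology global search over the f4 box with the
inner c solve, followed by a derivative-free local polish. This keeps the
global stage low-dimensional, is deterministic for a fixed configuration, and
reaches machine-precision cost on noiseless data.

Groups calibrated separately are aggregated by inverse-cost weighted means:
groups that fit their specimens better count more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from .core import AttenuationVector, BasisMaterial, BasisSet
from .correction import HistologyFractions
from .errors import DomainError, InvalidInputError, OptimizationError, ShapeError

__all__ = [
    "CalibrationSpecimen",
    "OptimizerConfig",
    "GroupCalibration",
    "CalibrationSummary",
    "adjust_for_fourth_material",
    "group_cost",
    "optimize_group",
    "aggregate_groups",
    "apply_correction_factors",
]


@dataclass(frozen=True)
class CalibrationSpecimen:
    """A contrast-agent-free specimen used for basis calibration."""

    specimen_id: str
    mu_ct: AttenuationVector
    histology: HistologyFractions


@dataclass(frozen=True)
class OptimizerConfig:
    """Bounds and budget for the global-then-local factor search.

    ``c_bounds`` is the box for every free correction factor (wide enough to
    cover both near-unity density corrections and the large factors that arise
    when a material was seeded from a badly wrong chemical assumption).
    ``sampling_points``/``iterations`` drive the simplicial global stage over
    the formalin fractions. All stages are deterministic for a fixed config;
    ``seed`` is reserved for optional stochastic extensions.
    """

    c_bounds: tuple[float, float] = (0.25, 5.0)
    f4_bounds: tuple[float, float] = (0.0, 0.999)
    sampling_points: int = 128
    iterations: int = 2
    seed: int = 0
    polish: bool = True
    polish_maxiter: int = 6000


@dataclass(frozen=True)
class GroupCalibration:
    """Calibration result for one specimen group."""

    group_id: str
    #: six factors ordered (low: m1, m2, m3, high: m1, m2, m3) in basis order
    correction_factors: np.ndarray
    formalin_fractions: np.ndarray           # per specimen, group order
    cost_value: float                        # L at the optimum, (1/cm)^2 units
    fixed_factor_mask: np.ndarray            # bool, True where frozen
    specimen_ids: tuple[str, ...] = ()

    @property
    def cost_per_mille(self) -> float:
        """Cost scaled by 1000 for report-style display."""
        return 1000.0 * self.cost_value


@dataclass(frozen=True)
class CalibrationSummary:
    """Inverse-cost weighted aggregation of group calibrations."""

    material_names: tuple[str, str, str]
    weighted_factors: np.ndarray             # six, same ordering as groups
    weights: np.ndarray                      # positive, sum to 1, group order
    final_attenuation: dict[str, AttenuationVector]


def adjust_for_fourth_material(
    mu_ct: AttenuationVector, f4: float, mu4: AttenuationVector
) -> AttenuationVector:
    """Remove a known-attenuation fourth material from a measured point.

    Per energy: ``(mu_CT - f4 * mu_4) / (1 - f4)`` — the exact inverse of
    mixing a three-material point with a fraction f4 of the fourth material.
    Identity at f4 = 0.
    """
    if not 0.0 <= f4 < 1.0:
        raise DomainError(f"f4 must lie in [0, 1), got {f4!r}")
    adjusted = _adjust_array(mu_ct.as_array(), f4, mu4.as_array())
    return AttenuationVector.from_array(adjusted)


def _adjust_array(mu_ct: np.ndarray, f4: float, mu4: np.ndarray) -> np.ndarray:
    """Array form of the fourth-material adjustment.

    Used inside the cost evaluation, where trial formalin fractions may
    overshoot and push the adjusted point negative — legal for a candidate
    that the optimizer will reject, so no domain check on the output.
    """
    if not 0.0 <= f4 < 1.0:
        raise DomainError(f"f4 must lie in [0, 1), got {f4!r}")
    return (mu_ct - f4 * mu4) / (1.0 - f4)


def _corrected_matrix(c: np.ndarray, basis: BasisSet) -> np.ndarray:
    """3x3 matrix with correction-scaled attenuation rows and a row of ones."""
    mu = basis.mu_matrix()
    return np.vstack([c[:3] * mu[0], c[3:] * mu[1], np.ones(3)])


def group_cost(
    c: Sequence[float],
    f4_vec: Sequence[float],
    specimens: Sequence[CalibrationSpecimen],
    basis: BasisSet,
    mu_formalin: AttenuationVector,
) -> float:
    """Sum of squared residuals of all specimens for given factors and formalin fractions."""
    c = np.asarray(c, dtype=float)
    f4_vec = np.asarray(f4_vec, dtype=float)
    if c.shape != (6,):
        raise ShapeError(f"expected 6 correction factors, got shape {c.shape}")
    if len(specimens) == 0:
        raise InvalidInputError("specimens must be nonempty")
    if f4_vec.shape != (len(specimens),):
        raise ShapeError(
            f"expected {len(specimens)} formalin fractions, got shape {f4_vec.shape}"
        )
    matrix = _corrected_matrix(c, basis)
    mu_f = mu_formalin.as_array()
    total = 0.0
    for specimen, f4 in zip(specimens, f4_vec):
        mu_p = _adjust_array(specimen.mu_ct.as_array(), float(f4), mu_f)
        target = np.array([mu_p[0], mu_p[1], 1.0])
        residual = target - matrix @ specimen.histology.as_array(basis.names)
        total += float(residual @ residual)
    return total


def _fixed_to_mask(
    fixed_factors: Optional[Mapping[str, float]], basis: BasisSet
) -> tuple[np.ndarray, np.ndarray]:
    """Translate {material name: value} into a length-6 (mask, values) pair."""
    mask = np.zeros(6, dtype=bool)
    values = np.ones(6)
    if fixed_factors:
        for name, value in fixed_factors.items():
            idx = basis.names.index(name)
            for m in (idx, idx + 3):
                mask[m] = True
                values[m] = float(value)
    return mask, values


def _solve_factors(
    f4_vec: np.ndarray,
    specimens: Sequence[CalibrationSpecimen],
    basis: BasisSet,
    mu_formalin: AttenuationVector,
    mask: np.ndarray,
    fixed_values: np.ndarray,
    c_bounds: tuple[float, float],
) -> np.ndarray:
    """Exact bounded least-squares solve for the free factors at fixed f4.

    The cost is linear in c once f4 is fixed: each specimen contributes one
    equation per energy, sum_i c_{row,i} * mu_i * f_ij = mu'_j. The
    volume-conservation row has zero residual whenever histology sums to 1 and
    carries no c dependence, so it is omitted from the solve.
    """
    mu = basis.mu_matrix()
    n = len(specimens)
    G = np.zeros((2 * n, 6))
    rhs = np.zeros(2 * n)
    mu_f = mu_formalin.as_array()
    for j, (specimen, f4) in enumerate(zip(specimens, f4_vec)):
        f = specimen.histology.as_array(basis.names)
        mu_p = _adjust_array(specimen.mu_ct.as_array(), float(f4), mu_f)
        G[2 * j, 0:3] = mu[0] * f
        G[2 * j + 1, 3:6] = mu[1] * f
        rhs[2 * j] = mu_p[0]
        rhs[2 * j + 1] = mu_p[1]
    free = ~mask
    c = fixed_values.copy()
    if free.any():
        reduced_rhs = rhs - G[:, mask] @ fixed_values[mask]
        result = optimize.lsq_linear(
            G[:, free], reduced_rhs, bounds=c_bounds, method="bvls"
        )
        c[free] = result.x
    return c


def optimize_group(
    specimens: Sequence[CalibrationSpecimen],
    basis: BasisSet,
    mu_formalin: AttenuationVector,
    fixed_factors: Optional[Mapping[str, float]] = None,
    config: OptimizerConfig = OptimizerConfig(),
    *,
    group_id: str = "group",
) -> GroupCalibration:
    """Calibrate one group of specimens by global-then-local search.

    ``fixed_factors`` freezes a material's factor at both energies (e.g.
    ``{"WBC": 1.0}``). The global stage searches the per-specimen formalin
    fractions with the free factors profiled out by an exact inner solve; the
    local stage polishes the incumbent. Deterministic for a fixed config.
    """
    if len(specimens) < 2:
        raise InvalidInputError(f"need >= 2 specimens per group, got {len(specimens)}")
    mask, fixed_values = _fixed_to_mask(fixed_factors, basis)
    free = ~mask
    n_free = int(free.sum())
    n = len(specimens)
    mu = basis.mu_matrix()
    mu_f = mu_formalin.as_array()
    histo = np.array([s.histology.as_array(basis.names) for s in specimens])
    mu_ct = np.array([s.mu_ct.as_array() for s in specimens])

    def reduced_cost(f4_vec: np.ndarray) -> float:
        f4_vec = np.clip(np.asarray(f4_vec, dtype=float), *config.f4_bounds)
        c = _solve_factors(
            f4_vec, specimens, basis, mu_formalin, mask, fixed_values, config.c_bounds
        )
        return group_cost(c, f4_vec, specimens, basis, mu_formalin)

    def residuals(x: np.ndarray) -> np.ndarray:
        """Per-specimen, per-energy residuals over (free factors, f4)."""
        c = fixed_values.copy()
        c[free] = x[:n_free]
        f4_vec = np.clip(x[n_free:], *config.f4_bounds)
        matrix = np.vstack([c[:3] * mu[0], c[3:] * mu[1]])
        out = np.empty(2 * n)
        for j in range(n):
            mu_p = _adjust_array(mu_ct[j], float(f4_vec[j]), mu_f)
            out[2 * j : 2 * j + 2] = mu_p - matrix @ histo[j]
        return out

    # global stage over the formalin fractions with the factors profiled out
    starts: list[np.ndarray] = []
    try:
        result = optimize.shgo(
            reduced_cost,
            [config.f4_bounds] * n,
            n=config.sampling_points,
            iters=config.iterations,
            sampling_method="sobol",
        )
        if result.x is not None:
            starts.append(np.asarray(result.x, dtype=float))
        for x in list(getattr(result, "xl", []) or [])[:3]:
            starts.append(np.asarray(x, dtype=float))
    except Exception:  # global stage is best-effort; the polish rescues coarse starts
        pass
    starts.append(np.full(n, 0.5 * (config.f4_bounds[0] + config.f4_bounds[1])))
    starts.append(np.full(n, config.f4_bounds[0]))

    # local stage: joint bounded least squares (trust-region reflective), which
    # converges to machine precision on zero-residual optima where simplex or
    # quasi-Newton descent stalls in the very flat valley of this cost
    lower = np.concatenate([np.full(n_free, config.c_bounds[0]), np.full(n, config.f4_bounds[0])])
    upper = np.concatenate([np.full(n_free, config.c_bounds[1]), np.full(n, config.f4_bounds[1])])
    best_x: Optional[np.ndarray] = None
    best_cost = np.inf
    seen: set[bytes] = set()
    for f4_start in starts[:6]:
        key = np.round(f4_start, 6).tobytes()
        if key in seen:
            continue
        seen.add(key)
        c_start = _solve_factors(
            f4_start, specimens, basis, mu_formalin, mask, fixed_values, config.c_bounds
        )
        x0 = np.clip(np.concatenate([c_start[free], f4_start]), lower, upper)
        if config.polish:
            local = optimize.least_squares(
                residuals,
                x0,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=config.polish_maxiter,
            )
            x, cost = local.x, float(2.0 * local.cost)
        else:
            x, cost = x0, float(np.sum(residuals(x0) ** 2))
        if cost < best_cost:
            best_x, best_cost = x, cost
    if best_x is None or not np.isfinite(best_cost):
        raise OptimizationError(
            f"group {group_id!r}: no usable optimum found", incumbent=best_x
        )
    c_opt = fixed_values.copy()
    c_opt[free] = best_x[:n_free]
    best_f4 = np.clip(best_x[n_free:], *config.f4_bounds)
    best_cost = group_cost(c_opt, best_f4, specimens, basis, mu_formalin)
    best_x = best_f4
    return GroupCalibration(
        group_id=group_id,
        correction_factors=c_opt,
        formalin_fractions=best_x,
        cost_value=best_cost,
        fixed_factor_mask=mask,
        specimen_ids=tuple(s.specimen_id for s in specimens),
    )


def aggregate_groups(
    groups: Sequence[GroupCalibration],
    basis: BasisSet,
    *,
    cost_floor: float = 1e-300,
) -> CalibrationSummary:
    """Inverse-cost weighted mean of group factors and the final attenuation table.

    Weights are proportional to 1/cost (normalized to sum 1, so the cost's
    absolute scale cancels); a vanishing cost is capped at ``cost_floor``,
    making that group weight-dominant instead of dividing by zero. Final
    attenuation is the initial attenuation scaled entrywise by the weighted
    factors. Weighted means always lie in the convex hull of the group values.
    """
    if len(groups) == 0:
        raise InvalidInputError("need at least one group")
    if any(g.cost_value < 0 for g in groups):
        raise InvalidInputError("cost values must be >= 0")
    costs = np.array([max(g.cost_value, cost_floor) for g in groups])
    weights = (1.0 / costs) / np.sum(1.0 / costs)
    factors = np.vstack([g.correction_factors for g in groups])
    weighted = weights @ factors
    mu = basis.mu_matrix()
    final = {
        name: AttenuationVector(weighted[i] * mu[0, i], weighted[i + 3] * mu[1, i])
        for i, name in enumerate(basis.names)
    }
    names = basis.names
    return CalibrationSummary(
        material_names=(names[0], names[1], names[2]),
        weighted_factors=weighted,
        weights=weights,
        final_attenuation=final,
    )


def apply_correction_factors(basis: BasisSet, factors: Sequence[float]) -> BasisSet:
    """Scale a 3-material basis by six factors (low: m1..m3, high: m1..m3)."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (6,):
        raise ShapeError(f"expected 6 factors, got shape {factors.shape}")
    materials = []
    for i, m in enumerate(basis.materials):
        materials.append(
            BasisMaterial(
                name=m.name,
                attenuation=AttenuationVector(
                    factors[i] * m.attenuation.mu_low,
                    factors[i + 3] * m.attenuation.mu_high,
                ),
                stock_concentration=m.stock_concentration,
                provenance=(m.provenance + "; correction factors applied").strip("; "),
            )
        )
    return BasisSet(tuple(materials), basis.energy_pair)
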