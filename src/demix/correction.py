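"""Histology-anchored recovery of materials invisible to histology.

Histology quantifies three clot constituents (RBC, WBC, fibrin/platelets) but
is blind to the contrast agent (iomeprol) diffused into the clot and to the
formalin it was fixed in. Dual-energy CT sees everything. This module fuses
the two modalities: the histology composition maps to a point

    mu_Histo = sum_j f_j^Histo * mu_j

in the (mu_low, mu_high) plane; each invisible ("extra") material k pulls that
point along its characteristic optimization path mu_k - mu_Histo. Scaling the
histology fractions by ``c_a = 1 - sum_k f~_k`` and adding the extras, the
shifted point is

    mu(f~) = mu_Histo - sum_k f~_k * (mu_Histo - mu_k)

and the extra fractions are found by minimizing the squared distance of this
point to the measured CT point,

    L(f~) = || (mu_Histo - mu_CT) - sum_k f~_k * (mu_Histo - mu_k) ||^2

subject to f~_k >= 0 and sum_k f~_k <= 1 - eps. With one extra the problem is
overdetermined (two equations, one unknown) and a nonzero matching error
remains; with two extras whose paths are linearly independent any interior
point is reached exactly and the cost vanishes — which is why reported
matching errors come from specimens optimized by a single path.

The problem is a box/sum-constrained linear least squares in one or two
variables; it is solved exactly by enumerating the active constraint sets (the
continuous analogue of non-negative least squares), so no iterative optimizer
is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .core import AttenuationVector, BasisMaterial, BasisSet, SpecimenMeasurement
from .errors import (
    CompositionError,
    ConfigurationError,
    DegenerateGeometryWarning,
    DomainError,
    ShapeError,
)
from .three_material import FractionVector

__all__ = [
    "HistologyFractions",
    "CorrectionResult",
    "histology_point",
    "corrected_point",
    "fit_extra_fractions",
    "renormalize_composition",
    "matching_error",
    "fraction_to_concentration",
    "relative_error_pct",
]

#: Safety margin keeping sum(f~) strictly below 1 so that c_s = 1/c_a stays finite.
SUM_EPS = 1e-6

_HISTO_SUM_TOL = 5e-3


@dataclass(frozen=True)
class HistologyFractions:
    """Three-component composition from the reference modality.

    Area fractions reported by histology are treated as volume fractions; each
    lies in [0, 1] and the three sum to 1 within tolerance (renormalized
    exactly on construction).
    """

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        fr = {str(k): float(v) for k, v in self.fractions.items()}
        if len(fr) != 3:
            raise ShapeError(f"histology needs exactly 3 materials, got {list(fr)}")
        if any(v < 0 or v > 1 for v in fr.values()):
            raise CompositionError(f"histology fractions must lie in [0, 1]: {fr}")
        total = sum(fr.values())
        if abs(total - 1.0) > _HISTO_SUM_TOL:
            raise CompositionError(
                f"histology fractions must sum to 1 within {_HISTO_SUM_TOL:g}; "
                f"sum is {total:.6g}"
            )
        object.__setattr__(self, "fractions", {k: v / total for k, v in fr.items()})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.fractions)

    def as_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        names = tuple(order) if order is not None else self.names
        return np.array([self.fractions[n] for n in names], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.fractions[name]


@dataclass(frozen=True)
class CorrectionResult:
    """Full output of one extra-material correction."""

    specimen_id: str
    extra_fractions: dict[str, float]          # f~_k per extra material
    c_a: float                                 # 1 - sum(f~)
    c_s: float                                 # 1 / c_a
    full_composition: FractionVector           # 3 + n materials, sums to 1
    histology_point: AttenuationVector
    optimized_point: AttenuationVector
    path_vectors: dict[str, np.ndarray]        # f~_k * (mu_k - mu_Histo), 1/cm
    matching_error_pct: tuple[float, float]    # per energy, percent
    cost_value: float


def histology_point(histo: HistologyFractions, basis: BasisSet) -> AttenuationVector:
    """Map a histology composition to its attenuation point.

    The linear mixing model restricted to the histology materials; by
    convexity the point lies inside the triangle those materials span.
    """
    try:
        mus = np.column_stack([basis.get(n).attenuation.as_array() for n in histo.names])
    except KeyError as exc:
        raise ConfigurationError(str(exc)) from exc
    return AttenuationVector.from_array(mus @ histo.as_array())


def _check_extras(extra_fractions: np.ndarray) -> None:
    if np.any(extra_fractions < 0):
        raise DomainError(f"extra fractions must be >= 0: {extra_fractions.tolist()}")
    if extra_fractions.sum() >= 1.0:
        raise DomainError(
            f"extra fractions must sum to < 1, got {extra_fractions.sum():.6g}"
        )


def corrected_point(
    histo_point: AttenuationVector,
    extra_fractions: Sequence[float] | Mapping[str, float],
    extra_materials: Sequence[BasisMaterial],
) -> AttenuationVector:
    """Shift the histology point along the extras' optimization paths.

    Returns ``mu_Histo + sum_k f~_k * (mu_k - mu_Histo)`` — affine in each
    f~_k, equal to the histology point at f~ = 0 and to mu_k at f~_k -> 1.
    """
    if isinstance(extra_fractions, Mapping):
        f = np.array([float(extra_fractions[m.name]) for m in extra_materials])
    else:
        f = np.asarray(extra_fractions, dtype=float)
    if f.size != len(extra_materials):
        raise ShapeError(
            f"got {f.size} fractions for {len(extra_materials)} extra materials"
        )
    _check_extras(f)
    point = histo_point.as_array()
    for frac, material in zip(f, extra_materials):
        point = point + frac * (material.attenuation.as_array() - histo_point.as_array())
    return AttenuationVector.from_array(point)


def _constrained_lsq(A: np.ndarray, b: np.ndarray, s_max: float) -> np.ndarray:
    """Exact minimizer of ||b - A f||^2 over f >= 0, sum(f) <= s_max.

    Enumerates active sets (each variable at 0 or free, sum constraint active
    or not) and solves the equality-constrained least squares for each; with
    the small number of extras (1-2) this is exhaustive and exact.
    """
    k = A.shape[1]
    best_f, best_cost = np.zeros(k), float(np.dot(b, b))
    indices = list(range(k))
    for n_free in range(1, k + 1):
        for free in combinations(indices, n_free):
            Af = A[:, list(free)]
            for sum_active in (False, True):
                if sum_active:
                    # KKT system for min ||b - Af x||^2 s.t. 1'x = s_max
                    G = Af.T @ Af
                    kkt = np.zeros((n_free + 1, n_free + 1))
                    kkt[:n_free, :n_free] = 2.0 * G
                    kkt[:n_free, n_free] = 1.0
                    kkt[n_free, :n_free] = 1.0
                    rhs = np.concatenate([2.0 * Af.T @ b, [s_max]])
                    try:
                        sol = np.linalg.solve(kkt, rhs)
                    except np.linalg.LinAlgError:
                        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
                    x = sol[:n_free]
                else:
                    x, *_ = np.linalg.lstsq(Af, b, rcond=None)
                if np.any(x < -1e-12) or x.sum() > s_max + 1e-12:
                    continue
                x = np.clip(x, 0.0, None)
                f = np.zeros(k)
                f[list(free)] = x
                cost = float(np.sum((b - A @ f) ** 2))
                if cost < best_cost - 1e-18 or (
                    abs(cost - best_cost) <= 1e-18 and f.sum() < best_f.sum()
                ):
                    best_f, best_cost = f, cost
    return best_f


def fit_extra_fractions(
    measurement: SpecimenMeasurement,
    histo: HistologyFractions,
    basis: BasisSet,
    extra_materials: Sequence[BasisMaterial],
    *,
    eps: float = SUM_EPS,
) -> CorrectionResult:
    """Recover the fractions of 1-2 extra materials for one specimen.

    Minimizes the matching cost between the shifted histology point and the
    measured CT point over the constrained box f~_k >= 0, sum f~_k <= 1 - eps,
    then renormalizes to the full 4- or 5-material composition.

    If the two extras' path vectors are collinear the fit degenerates to a
    single direction; a :class:`DegenerateGeometryWarning` is emitted and the
    better single-extra fit is returned.
    """
    if not 1 <= len(extra_materials) <= 2:
        raise ShapeError(f"supported: 1 or 2 extra materials, got {len(extra_materials)}")
    mu_h = histology_point(histo, basis)
    A = np.column_stack(
        [mu_h.as_array() - m.attenuation.as_array() for m in extra_materials]
    )
    if np.any(np.linalg.norm(A, axis=0) < 1e-12):
        raise DomainError(
            "an extra material's attenuation coincides with the histology point; "
            "its optimization path is degenerate"
        )
    b = mu_h.as_array() - measurement.mu_ct.as_array()
    if A.shape[1] == 2 and np.linalg.matrix_rank(A, tol=1e-10) < 2:
        warnings.warn(
            "collinear optimization paths for "
            f"{[m.name for m in extra_materials]}; reducing to a single extra",
            DegenerateGeometryWarning,
            stacklevel=2,
        )
        candidates = []
        for idx in (0, 1):
            f1 = _constrained_lsq(A[:, [idx]], b, 1.0 - eps)
            f = np.zeros(2)
            f[idx] = f1[0]
            candidates.append((float(np.sum((b - A @ f) ** 2)), f))
        _, f_opt = min(candidates, key=lambda t: t[0])
    else:
        f_opt = _constrained_lsq(A, b, 1.0 - eps)

    extras = {m.name: float(v) for m, v in zip(extra_materials, f_opt)}
    optimized = corrected_point(mu_h, f_opt, extra_materials)
    cost = float(np.sum((b - A @ f_opt) ** 2))
    full = renormalize_composition(histo, extras)
    return CorrectionResult(
        specimen_id=measurement.specimen_id,
        extra_fractions=extras,
        c_a=1.0 - float(f_opt.sum()),
        c_s=1.0 / (1.0 - float(f_opt.sum())),
        full_composition=full,
        histology_point=mu_h,
        optimized_point=optimized,
        path_vectors={
            m.name: float(v) * (m.attenuation.as_array() - mu_h.as_array())
            for m, v in zip(extra_materials, f_opt)
        },
        matching_error_pct=matching_error(optimized, measurement.mu_ct),
        cost_value=cost,
    )


def renormalize_composition(
    histo: HistologyFractions,
    extra_fractions: Mapping[str, float],
) -> FractionVector:
    """Scale histology fractions by ``c_a = 1 - sum(f~)`` and append the extras.

    The result is the full composition over 3 + n materials and sums to 1.
    """
    f = np.array([float(v) for v in extra_fractions.values()])
    _check_extras(f)
    c_a = 1.0 - float(f.sum())
    full = {name: c_a * value for name, value in histo.fractions.items()}
    for name, value in extra_fractions.items():
        if name in full:
            raise ConfigurationError(f"extra material {name!r} duplicates a histology material")
        full[name] = float(value)
    return FractionVector(full, sum_constrained=True, sum_tol=1e-9)


def matching_error(
    optimized_point: AttenuationVector,
    measured_point: AttenuationVector,
) -> tuple[float, float]:
    """Per-energy relative deviation of the optimized from the measured point, in %."""
    opt, meas = optimized_point.as_array(), measured_point.as_array()
    if np.any(meas <= 0):
        raise DomainError(f"measured attenuations must be > 0: {meas.tolist()}")
    err = 100.0 * np.abs(opt - meas) / meas
    return (float(err[0]), float(err[1]))


def fraction_to_concentration(fraction: float, material: BasisMaterial) -> float:
    """Volume fraction of an aqueous stock -> concentration in mg/ml."""
    if material.stock_concentration is None:
        raise ConfigurationError(
            f"material {material.name!r} has no stock concentration configured"
        )
    return fraction * material.stock_concentration


def relative_error_pct(true_value: float, estimated_value: float) -> float:
    """Unsigned relative error in percent, 100 * |est - true| / true."""
    if true_value == 0:
        raise DomainError("relative error undefined for true value 0")
    return 100.0 * abs(estimated_value - true_value) / abs(true_value)
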