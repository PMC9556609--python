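"""Closed-form three-material decomposition under volume conservation.

With two monoenergetic attenuation values per specimen, two materials is the
limit for a plain two-equation solve. Adding the volume-conservation row
``f1 + f2 + f3 = 1`` yields a 3x3 linear system

    [ mu_{1,low}  mu_{2,low}  mu_{3,low}  ] [f1]   [mu_CT,low ]
    [ mu_{1,high} mu_{2,high} mu_{3,high} ] [f2] = [mu_CT,high]
    [     1           1           1       ] [f3]   [    1     ]

whose solution is the unique volume-fraction decomposition over three basis
materials. Geometrically the basis materials span a triangle in the
(mu_low, mu_high) plane; measurements inside the triangle give fractions in
[0, 1], measurements outside give a solution with a negative component, which
is returned as computed with an out-of-gamut flag rather than clamped — the
un-clamped geometry is what the extra-material correction reasons about.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .core import BasisSet, SpecimenMeasurement, DEFAULT_FRACTION_SUM_TOL
from .errors import CompositionError, ConditioningError, ShapeError

__all__ = ["FractionVector", "build_system_matrix", "solve_three_material"]

#: Default ceiling on the system-matrix condition number. High enough to admit
#: genuinely similar materials (which may differ only in the third decimal at
#: the high energy), low enough to reject linearly dependent bases.
DEFAULT_CONDITION_CEILING = 1e8

_GAMUT_TOL = 1e-9


@dataclass
class FractionVector:
    """Volume fractions keyed by material name.

    ``sum_constrained`` marks compositions bound by volume conservation; such
    vectors must sum to 1 within tolerance. Individual fractions may lie
    outside [0, 1] (flagged via ``out_of_gamut``) when a measurement falls
    outside the basis material gamut. ``residual`` carries the linear-solve
    residual norm when the vector came from a decomposition.
    """

    fractions: dict[str, float]
    sum_constrained: bool = True
    out_of_gamut: bool = False
    residual: Optional[float] = None
    sum_tol: float = field(default=DEFAULT_FRACTION_SUM_TOL, repr=False)

    def __post_init__(self) -> None:
        self.fractions = {str(k): float(v) for k, v in self.fractions.items()}
        if self.sum_constrained:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > self.sum_tol:
                raise CompositionError(
                    f"constrained fractions must sum to 1 within {self.sum_tol:g}; "
                    f"sum is {total:.9g}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.fractions)

    def as_array(self, order: Optional[tuple[str, ...]] = None) -> np.ndarray:
        names = order if order is not None else self.names
        return np.array([self.fractions[n] for n in names], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.fractions[name]

    def items(self):
        return self.fractions.items()


def build_system_matrix(basis: BasisSet) -> np.ndarray:
    """3x3 system matrix: attenuation rows at each energy plus a row of ones."""
    if len(basis) != 3:
        raise ShapeError(f"three-material solve needs exactly 3 materials, got {len(basis)}")
    return np.vstack([basis.mu_matrix(), np.ones(3)])


def solve_three_material(
    measurement: SpecimenMeasurement,
    basis: BasisSet,
    *,
    condition_ceiling: float = DEFAULT_CONDITION_CEILING,
) -> FractionVector:
    """Solve the volume-conserving 3x3 system for one measurement.

    Returns the exact linear-algebra solution; fractions sum to 1 to round-off.
    A solution component outside [0, 1] means the measurement lies outside the
    triangle spanned by the basis materials in the (mu_low, mu_high) plane; it
    is reported as computed with ``out_of_gamut=True``.

    Raises :class:`ConditioningError` when the basis materials are (near-)
    linearly dependent — the system then has no stable unique solution.
    """
    matrix = build_system_matrix(basis)
    cond = float(np.linalg.cond(matrix))
    if not np.isfinite(cond) or cond > condition_ceiling:
        raise ConditioningError(
            f"system matrix condition number {cond:.3e} exceeds ceiling "
            f"{condition_ceiling:.1e}; basis materials are linearly dependent "
            "or too similar to separate"
        )
    rhs = np.array([measurement.mu_ct.mu_low, measurement.mu_ct.mu_high, 1.0])
    f = np.linalg.solve(matrix, rhs)
    residual = float(np.linalg.norm(matrix @ f - rhs))
    out_of_gamut = bool(np.any(f < -_GAMUT_TOL) or np.any(f > 1 + _GAMUT_TOL))
    return FractionVector(
        dict(zip(basis.names, f)),
        sum_constrained=True,
        out_of_gamut=out_of_gamut,
        residual=residual,
        sum_tol=1e-9,
    )
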