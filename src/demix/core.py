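"""Domain types and forward physics for two-energy attenuation mixing.

Everything downstream of image reconstruction works on ROI-mean linear
attenuation coefficients mu (1/cm) sampled at a pair of virtual monoenergetic
energies (by default 50 and 200 keV). Two pieces of physics live here:

* the linear mixing model — the attenuation of a mixture is the
  volume-fraction-weighted sum of its constituents' attenuations at each
  energy, ``mu_E = sum_i f_i * mu_{i,E}``;
* the Hounsfield-unit normalization ``mu = HU * mu_water / 1000 + mu_water``,
  which maps the clinical HU scale back to physical attenuation.

HU values appear only at the I/O boundary and are converted eagerly; all
internal math is in 1/cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

from .errors import CompositionError, DomainError, InvalidInputError, ShapeError

__all__ = [
    "EnergyPair",
    "AttenuationVector",
    "BasisMaterial",
    "BasisSet",
    "SpecimenMeasurement",
    "hu_to_mu",
    "mu_to_hu",
    "mix_attenuation",
    "DEFAULT_FRACTION_SUM_TOL",
]

#: Default tolerance on |sum(f) - 1| for compositions given at full precision.
DEFAULT_FRACTION_SUM_TOL = 1e-6

#: Looser tolerance for compositions transcribed from 3-decimal report tables;
#: readers renormalize when the sum is within this band of 1.
TABLE_FRACTION_SUM_TOL = 5e-3


@dataclass(frozen=True)
class EnergyPair:
    """The two virtual monoenergetic energies, in keV.

    Nothing in the math depends on the literal values; they label the two
    attenuation channels. Default (50, 200).
    """

    e_low: float = 50.0
    e_high: float = 200.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.e_low) and math.isfinite(self.e_high)):
            raise InvalidInputError("energies must be finite")
        if not 0.0 < self.e_low < self.e_high:
            raise InvalidInputError(
                f"require 0 < e_low < e_high, got ({self.e_low}, {self.e_high})"
            )


@dataclass(frozen=True)
class AttenuationVector:
    """Linear attenuation at the two working energies, in 1/cm."""

    mu_low: float
    mu_high: float

    def __post_init__(self) -> None:
        for value in (self.mu_low, self.mu_high):
            if not math.isfinite(value):
                raise InvalidInputError(f"attenuation must be finite, got {value!r}")
            if value < 0.0:
                raise InvalidInputError(f"attenuation must be >= 0, got {value!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.mu_low, self.mu_high], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "AttenuationVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (2,):
            raise ShapeError(f"expected a length-2 vector, got shape {arr.shape}")
        return cls(float(arr[0]), float(arr[1]))


@dataclass(frozen=True)
class BasisMaterial:
    """A named basis material with its two-energy attenuation.

    ``stock_concentration`` (mg/ml) is set for aqueous bases prepared by
    dilution of a stock solution; it converts volume fractions of the stock
    into concentrations. ``provenance`` is a free-text note on where the
    attenuation values came from (e.g. "regression endpoint",
    "config constant").
    """

    name: str
    attenuation: AttenuationVector
    stock_concentration: Optional[float] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("material name must be non-empty")
        if self.stock_concentration is not None and not self.stock_concentration > 0:
            raise InvalidInputError(
                f"stock_concentration must be > 0, got {self.stock_concentration!r}"
            )


@dataclass(frozen=True)
class BasisSet:
    """An ordered collection of distinct basis materials at one energy pair."""

    materials: tuple[BasisMaterial, ...]
    energy_pair: EnergyPair = field(default_factory=EnergyPair)

    def __post_init__(self) -> None:
        object.__setattr__(self, "materials", tuple(self.materials))
        if len(self.materials) < 2:
            raise InvalidInputError("a basis set needs at least 2 materials")
        names = [m.name for m in self.materials]
        if len(set(names)) != len(names):
            raise InvalidInputError(f"duplicate material names in basis: {names}")

    def __len__(self) -> int:
        return len(self.materials)

    def __iter__(self) -> Iterator[BasisMaterial]:
        return iter(self.materials)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.materials)

    def get(self, name: str) -> BasisMaterial:
        for m in self.materials:
            if m.name == name:
                return m
        raise KeyError(f"material {name!r} not in basis {self.names}")

    def mu_matrix(self) -> np.ndarray:
        """2 x n matrix; row 0 is mu at e_low, row 1 at e_high, basis order."""
        return np.array([[m.attenuation.mu_low for m in self.materials],
                         [m.attenuation.mu_high for m in self.materials]])

    def subset(self, names: Sequence[str]) -> "BasisSet":
        return BasisSet(tuple(self.get(n) for n in names), self.energy_pair)


@dataclass(frozen=True)
class SpecimenMeasurement:
    """One specimen's ROI-mean two-energy attenuation point.

    ``source_units`` records whether the value originated as HU (converted at
    read time with a water reference) or was supplied directly in 1/cm; the
    stored ``mu_ct`` is always in 1/cm.
    """

    specimen_id: str
    mu_ct: AttenuationVector
    source_units: Literal["mu_per_cm", "hounsfield"] = "mu_per_cm"


def hu_to_mu(hu_value: float, mu_water: float, *, allow_negative: bool = False) -> float:
    """Convert a Hounsfield value at one energy to linear attenuation (1/cm).

    ``mu = HU * mu_water / 1000 + mu_water``, with water mapping to itself and
    HU = -1000 (air) mapping to zero. Values below -1000 give negative mu and
    raise unless ``allow_negative`` is set.
    """
    if not (math.isfinite(hu_value) and math.isfinite(mu_water)):
        raise InvalidInputError("hu_value and mu_water must be finite")
    if not mu_water > 0:
        raise DomainError(f"mu_water must be > 0, got {mu_water!r}")
    mu = hu_value * mu_water / 1000.0 + mu_water
    if mu < 0 and not allow_negative:
        raise DomainError(
            f"HU={hu_value} gives negative attenuation {mu:.6g} 1/cm; "
            "pass allow_negative=True to keep it"
        )
    return mu


def mu_to_hu(mu: float, mu_water: float) -> float:
    """Algebraic inverse of :func:`hu_to_mu`: ``HU = 1000 * (mu - mu_water) / mu_water``."""
    if not (math.isfinite(mu) and math.isfinite(mu_water)):
        raise InvalidInputError("mu and mu_water must be finite")
    if mu_water == 0:
        raise DomainError("mu_water must be nonzero")
    return 1000.0 * (mu - mu_water) / mu_water


def mix_attenuation(
    fractions: Sequence[float],
    basis: BasisSet,
    *,
    sum_tol: float = DEFAULT_FRACTION_SUM_TOL,
) -> AttenuationVector:
    """Forward mixing model: volume-fraction-weighted sum of basis attenuations.

    ``fractions`` must align with ``basis`` order, lie in [0, 1], and sum to 1
    within ``sum_tol``.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or f.size != len(basis):
        raise ShapeError(
            f"got {f.size} fractions for a {len(basis)}-material basis"
        )
    if not np.all(np.isfinite(f)):
        raise InvalidInputError("fractions must be finite")
    if np.any(f < -sum_tol) or np.any(f > 1 + sum_tol):
        raise CompositionError(f"fractions must lie in [0, 1], got {f.tolist()}")
    total = float(f.sum())
    if abs(total - 1.0) > sum_tol:
        raise CompositionError(
            f"fractions must sum to 1 within {sum_tol:g}; sum is {total:.9g}"
        )
    mu = basis.mu_matrix() @ f
    return AttenuationVector.from_array(mu)
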