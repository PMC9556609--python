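"""Synthetic phantom generation: forward-simulated specimens with ground truth.

Two scenarios are emulated so that every stage of the pipeline is testable
without any acquisition:

* **aqueous** — laboratory test mixtures pipetted from aqueous stock solutions
  (eosin, iomeprol, NaCl) and distilled water into small tubes; volumes map to
  volume fractions, fractions map to attenuation through the linear mixing
  model, and optional additive Gaussian noise stands in for measurement noise.
* **clot** — clot-like specimens whose RBC/WBC/fibrin-platelets composition is
  "seen by histology" while hidden formalin and iomeprol fractions shift the
  measured CT point along their characteristic paths. Optionally the true
  basis attenuations are perturbed by known correction factors so the
  calibration module has something to recover.

Noise is applied to measurements only — ground truth and histology stay
exact. A single integer seed drives all draws and cohorts are
order-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .basis_calibration import apply_correction_factors
from .core import (
    AttenuationVector,
    BasisMaterial,
    BasisSet,
    SpecimenMeasurement,
    mix_attenuation,
)
from .correction import HistologyFractions
from .dilution import ConcentrationSeries
from .errors import DomainError, InvalidInputError
from .three_material import FractionVector
from . import materials

__all__ = [
    "PhantomSpec",
    "ClotSamplerConfig",
    "GroundTruthBundle",
    "volumes_to_fractions",
    "make_aqueous_cohort",
    "make_clot_cohort",
    "make_dilution_series",
    "iomeprol_recovery_experiment",
]

#: Default per-energy additive measurement noise, 1/cm. Illustrative: chosen
#: so that sub-mg/ml contrast-agent fractions sit near the detection limit.
DEFAULT_NOISE_SIGMA = 0.002


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe book for an aqueous cohort.

    ``recipes`` maps specimen ids to pipetted volumes (ml) per basis material;
    materials omitted from a recipe contribute zero volume.
    """

    recipes: dict[str, dict[str, float]]
    basis: BasisSet
    noise_sigma: float | tuple[float, float] = DEFAULT_NOISE_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        sigma = np.atleast_1d(np.asarray(self.noise_sigma, dtype=float))
        if np.any(sigma < 0):
            raise InvalidInputError(f"noise_sigma must be >= 0, got {self.noise_sigma!r}")
        for sid, volumes in self.recipes.items():
            vols = np.array(list(volumes.values()), dtype=float)
            if np.any(vols < 0) or vols.sum() <= 0:
                raise InvalidInputError(
                    f"specimen {sid!r}: volumes must be >= 0 with positive total"
                )
            unknown = set(volumes) - set(self.basis.names)
            if unknown:
                raise InvalidInputError(f"specimen {sid!r}: unknown materials {unknown}")


@dataclass(frozen=True)
class ClotSamplerConfig:
    """Simplex sampler for clot histology triples.

    Two Dirichlet cluster modes reflect that clot constituents appear
    regionally clustered: a fibrin-dominant and an RBC-dominant mode. Alpha
    triples are in role order (fibrin, WBC, RBC); roles are matched to basis
    material names ("fibrin...", "WBC", "RBC") and fall back to basis order
    when the names are unrecognized. The WBC fraction is capped (default 0.15)
    by rejection.
    """

    mode_weights: tuple[float, float] = (0.5, 0.5)
    fibrin_mode_alpha: tuple[float, float, float] = (6.0, 0.4, 1.2)
    rbc_mode_alpha: tuple[float, float, float] = (1.2, 0.4, 6.0)
    wbc_cap: float = 0.15


@dataclass
class GroundTruthBundle:
    """A synthetic cohort with everything the pipeline may be asked to recover."""

    specimen_ids: list[str]
    basis: BasisSet
    true_fractions: pd.DataFrame                 # full composition per specimen
    noiseless: list[SpecimenMeasurement]
    noisy: list[SpecimenMeasurement]
    histology: Optional[list[HistologyFractions]] = None
    true_extra_fractions: Optional[pd.DataFrame] = None
    true_correction_factors: Optional[np.ndarray] = None
    seed: int = 0


def volumes_to_fractions(volumes: Mapping[str, float]) -> FractionVector:
    """Pipetted volumes (ml) -> volume fractions (each volume over the total)."""
    names = list(volumes)
    vols = np.array([float(volumes[n]) for n in names])
    if np.any(vols < 0):
        raise DomainError(f"volumes must be >= 0: {dict(volumes)}")
    total = vols.sum()
    if total <= 0:
        raise DomainError("total volume must be positive")
    return FractionVector(dict(zip(names, vols / total)), sum_constrained=True, sum_tol=1e-9)


def _noisy(mu: np.ndarray, sigma, rng: np.random.Generator) -> AttenuationVector:
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (2,))
    draw = mu + rng.normal(0.0, 1.0, size=2) * sigma
    return AttenuationVector.from_array(np.clip(draw, 0.0, None))


def make_aqueous_cohort(spec: PhantomSpec) -> GroundTruthBundle:
    """Forward-simulate an aqueous cohort from pipetting recipes."""
    rng = np.random.default_rng(spec.seed)
    names = spec.basis.names
    ids, rows, clean, noisy = [], [], [], []
    for sid, volumes in spec.recipes.items():
        full = {n: volumes.get(n, 0.0) for n in names}
        fractions = volumes_to_fractions(full)
        f = fractions.as_array(names)
        mu = mix_attenuation(f, spec.basis, sum_tol=1e-9).as_array()
        ids.append(sid)
        rows.append(f)
        clean.append(
            SpecimenMeasurement(sid, AttenuationVector.from_array(mu))
        )
        noisy.append(SpecimenMeasurement(sid, _noisy(mu, spec.noise_sigma, rng)))
    return GroundTruthBundle(
        specimen_ids=ids,
        basis=spec.basis,
        true_fractions=pd.DataFrame(rows, index=ids, columns=list(names)),
        noiseless=clean,
        noisy=noisy,
        seed=spec.seed,
    )


def _role_order(names: Sequence[str]) -> list[str]:
    """Order basis names as (fibrin, WBC, RBC) roles, or keep basis order."""
    roles: dict[str, str] = {}
    for n in names:
        low = n.lower()
        if "fibrin" in low:
            roles.setdefault("fibrin", n)
        elif "wbc" in low or "white" in low:
            roles.setdefault("wbc", n)
        elif "rbc" in low or "red" in low:
            roles.setdefault("rbc", n)
    if len(roles) == 3:
        return [roles["fibrin"], roles["wbc"], roles["rbc"]]
    return list(names)


def _sample_histology(
    rng: np.random.Generator, config: ClotSamplerConfig, names: Sequence[str]
) -> HistologyFractions:
    ordered = _role_order(names)
    weights = np.asarray(config.mode_weights, dtype=float)
    weights = weights / weights.sum()
    for _ in range(10_000):
        mode = rng.choice(2, p=weights)
        alpha = config.fibrin_mode_alpha if mode == 0 else config.rbc_mode_alpha
        draw = rng.dirichlet(alpha)   # role order: (fibrin, wbc, rbc)
        if draw[1] <= config.wbc_cap:
            return HistologyFractions(dict(zip(ordered, draw)))
    raise DomainError("histology sampler rejected 10000 draws; check wbc_cap")


def make_clot_cohort(
    n_specimens: int,
    *,
    basis: Optional[BasisSet] = None,
    extras: Optional[Sequence[BasisMaterial]] = None,
    sampler: ClotSamplerConfig = ClotSamplerConfig(),
    formalin_range: tuple[float, float] = (0.05, 0.35),
    iomeprol_range: tuple[float, float] = (0.0, 0.065),
    true_correction_factors: Optional[Sequence[float]] = None,
    noise_sigma: float | tuple[float, float] = 0.0,
    seed: int = 0,
) -> GroundTruthBundle:
    """Forward-simulate clot-like specimens with hidden extras.

    ``basis`` is the assumed histology basis (fibrin/WBC/RBC order follows the
    sampler); ``extras`` default to (formalin, iomeprol). Extra fractions are
    drawn uniformly from their ranges. If ``true_correction_factors`` are
    given, the *measurements* are generated from the factor-scaled basis while
    the returned bundle keeps the assumed basis — exactly the situation the
    calibration module must untangle.
    """
    if basis is None:
        basis = materials.clot_basis()
    if extras is None:
        extras = (materials.formalin(), materials.iomeprol())
    for lo, hi in (formalin_range, iomeprol_range):
        if not (0.0 <= lo <= hi < 1.0):
            raise DomainError("extra-fraction ranges must satisfy 0 <= lo <= hi < 1")
    if formalin_range[1] + iomeprol_range[1] >= 1.0:
        raise DomainError("extra-fraction range maxima must sum to < 1")
    rng = np.random.default_rng(seed)
    factors = (
        np.ones(6)
        if true_correction_factors is None
        else np.asarray(true_correction_factors, dtype=float)
    )
    true_basis = apply_correction_factors(basis, factors)
    extra_names = [m.name for m in extras]
    ids, histo_list, extra_rows, full_rows, clean, noisy = [], [], [], [], [], []
    for j in range(n_specimens):
        sid = f"clot{j + 1}"
        histo = _sample_histology(rng, sampler, basis.names)
        f_extras = np.array(
            [rng.uniform(*formalin_range), rng.uniform(*iomeprol_range)]
        )[: len(extras)]
        c_a = 1.0 - f_extras.sum()
        mu_h = np.column_stack(
            [true_basis.get(n).attenuation.as_array() for n in histo.names]
        ) @ histo.as_array()
        mu = mu_h.copy()
        for frac, material in zip(f_extras, extras):
            mu = mu + frac * (material.attenuation.as_array() - mu_h)
        ids.append(sid)
        histo_list.append(histo)
        extra_rows.append(f_extras)
        full_rows.append(
            np.concatenate([c_a * histo.as_array(basis.names), f_extras])
        )
        clean.append(SpecimenMeasurement(sid, AttenuationVector.from_array(mu)))
        noisy.append(SpecimenMeasurement(sid, _noisy(mu, noise_sigma, rng)))
    return GroundTruthBundle(
        specimen_ids=ids,
        basis=basis,
        true_fractions=pd.DataFrame(
            full_rows, index=ids, columns=list(basis.names) + extra_names
        ),
        noiseless=clean,
        noisy=noisy,
        histology=histo_list,
        true_extra_fractions=pd.DataFrame(extra_rows, index=ids, columns=extra_names),
        true_correction_factors=factors,
        seed=seed,
    )


def make_dilution_series(
    material: BasisMaterial,
    concentrations: Sequence[float],
    *,
    water_attenuation: AttenuationVector = materials.WATER_ATTENUATION,
    noise_sigma: float | tuple[float, float] = 0.0,
    seed: int = 0,
) -> ConcentrationSeries:
    """Simulate a water-dilution series of one aqueous stock.

    Points follow ``mu(c) = (c/c_stock) * mu_stock + (1 - c/c_stock) * mu_water``
    with optional additive Gaussian noise per energy.
    """
    if material.stock_concentration is None:
        raise InvalidInputError(f"{material.name!r} needs a stock concentration")
    rng = np.random.default_rng(seed)
    c_stock = material.stock_concentration
    mu_stock = material.attenuation.as_array()
    w = water_attenuation.as_array()
    points = []
    for c in concentrations:
        mu = (c / c_stock) * mu_stock + (1.0 - c / c_stock) * w
        points.append((float(c), _noisy(mu, noise_sigma, rng)))
    return ConcentrationSeries(material.name, tuple(points), c_stock)


def iomeprol_recovery_experiment(
    concentrations_mg_per_ml: Sequence[float],
    *,
    n_replicates: int = 300,
    noise_sigma: float | tuple[float, float] = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
) -> pd.DataFrame:
    """Measure how contrast-agent recovery accuracy depends on concentration.

    Emulates the single-path aqueous model test: specimens mix eosin, water
    and NaCl in fixed proportions plus an iomeprol fraction set by the target
    concentration; the reference modality "sees" only the iomeprol-free triple
    and the fit recovers the iomeprol fraction from the noisy measurement.
    With one path and two energies the problem is overdetermined, so additive
    measurement noise translates into a roughly constant absolute
    concentration error — and a relative error that grows as the
    concentration falls, which is what sets the detection limit.

    Returns one row per concentration with the mean absolute (mg/ml) and mean
    relative (%) recovery errors over the replicates.
    """
    # late import: correction depends on three_material, not on phantoms
    from .correction import fit_extra_fractions

    basis = materials.aqueous_basis()
    iom = basis.get("iomeprol")
    base = {"eosin": 0.10, "water": 0.55, "sodium_chloride": 0.35}
    histo = HistologyFractions(base)
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concentrations_mg_per_ml:
        f_iom = conc / iom.stock_concentration
        fractions = np.array(
            [base["eosin"], f_iom, base["water"], base["sodium_chloride"]]
        )
        fractions[[0, 2, 3]] *= 1.0 - f_iom
        mu = mix_attenuation(fractions, basis, sum_tol=1e-9).as_array()
        abs_errors = []
        for rep in range(n_replicates):
            m = SpecimenMeasurement(f"c{conc}_{rep}", _noisy(mu, noise_sigma, rng))
            r = fit_extra_fractions(m, histo, basis, [iom])
            conc_est = r.extra_fractions["iomeprol"] * iom.stock_concentration
            abs_errors.append(abs(conc_est - conc))
        abs_errors = np.asarray(abs_errors)
        rows.append(
            {
                "concentration_mg_per_ml": conc,
                "mean_abs_error_mg_per_ml": abs_errors.mean(),
                "mean_rel_error_pct": 100.0 * (abs_errors / conc).mean(),
            }
        )
    return pd.DataFrame(rows)
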