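"""Shipped example basis-material definitions.

These constants are illustrative defaults for the synthetic phantoms, the
worked examples and the CLI; they are stated in 1/cm at (50, 200) keV. The
aqueous endpoints follow typical dilution-series regression values for the
stock solutions named; water, formalin and the clot constituents are
config-style constants a user would normally replace with values calibrated
for their own scanner. None of them is measured ground truth.
"""

from __future__ import annotations

from .core import AttenuationVector, BasisMaterial, BasisSet, EnergyPair

__all__ = [
    "WATER_ATTENUATION",
    "water",
    "iomeprol",
    "eosin",
    "sodium_chloride",
    "formalin",
    "fibrin_platelets",
    "rbc",
    "wbc",
    "aqueous_basis",
    "clot_basis",
    "initial_clot_basis",
]

ENERGIES = EnergyPair(50.0, 200.0)

#: Pure water at (50, 200) keV, 1/cm — NIST-style tabulated values.
WATER_ATTENUATION = AttenuationVector(0.2269, 0.1370)


def water() -> BasisMaterial:
    return BasisMaterial("water", WATER_ATTENUATION, provenance="config constant")


def iomeprol(stock_concentration: float = 20.0) -> BasisMaterial:
    """Iomeprol in aqueous solution at the given stock concentration (mg/ml)."""
    return BasisMaterial(
        "iomeprol",
        AttenuationVector(0.433, 0.152),
        stock_concentration=stock_concentration,
        provenance="regression endpoint (example)",
    )


def eosin(stock_concentration: float = 40.0) -> BasisMaterial:
    """Eosin Y disodium salt in aqueous solution (mg/ml stock)."""
    return BasisMaterial(
        "eosin",
        AttenuationVector(0.290, 0.141),
        stock_concentration=stock_concentration,
        provenance="regression endpoint (example)",
    )


def sodium_chloride(stock_concentration: float = 200.0) -> BasisMaterial:
    """Sodium chloride in aqueous solution (mg/ml stock)."""
    return BasisMaterial(
        "sodium_chloride",
        AttenuationVector(0.306, 0.151),
        stock_concentration=stock_concentration,
        provenance="regression endpoint (example)",
    )


def formalin() -> BasisMaterial:
    """Neutral buffered ~3.6% formalin solution; close to, but distinct from, water."""
    return BasisMaterial(
        "formalin", AttenuationVector(0.2293, 0.1383), provenance="config constant"
    )


def fibrin_platelets() -> BasisMaterial:
    return BasisMaterial(
        "fibrin_platelets",
        AttenuationVector(0.2693, 0.1636),
        provenance="calibrated example value",
    )


def rbc() -> BasisMaterial:
    return BasisMaterial(
        "RBC", AttenuationVector(0.2769, 0.1703), provenance="calibrated example value"
    )


def wbc() -> BasisMaterial:
    """WBC approximated as generic soft tissue."""
    return BasisMaterial(
        "WBC", AttenuationVector(0.2230, 0.1361), provenance="config constant"
    )


def aqueous_basis() -> BasisSet:
    """Eosin / iomeprol / water / NaCl — the laboratory test-mixture basis."""
    return BasisSet(
        (eosin(), iomeprol(), water(), sodium_chloride()), ENERGIES
    )


def clot_basis() -> BasisSet:
    """Fibrin-platelets / RBC / WBC with calibrated example attenuations."""
    return BasisSet((fibrin_platelets(), rbc(), wbc()), ENERGIES)


def initial_clot_basis() -> BasisSet:
    """Pre-calibration clot basis seeded from chemical-composition assumptions.

    The RBC entry mimics a hemoglobin/MCHC-derived seed that underestimates
    whole-cell attenuation by a large factor; fibrin is a protein-density
    estimate. Illustrative only — the calibration module exists to correct
    these.
    """
    return BasisSet(
        (
            BasisMaterial(
                "fibrin_platelets",
                AttenuationVector(0.2892, 0.1847),
                provenance="chemical assumption (example)",
            ),
            BasisMaterial(
                "RBC",
                AttenuationVector(0.0731, 0.0450),
                provenance="chemical assumption (example)",
            ),
            wbc(),
        ),
        ENERGIES,
    )
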