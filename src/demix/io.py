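"""Readers and writers for the package's delimited-table and config formats.

Tables are comma-separated UTF-8 with a mandatory header row and decimal
points. Every quantitative table carries an explicit ``units`` column so HU
and 1/cm can never be silently confused; HU measurements are converted at
read time with a user-supplied water reference and never stored. CSV reports
round for human readers; the JSON writers keep full precision, so the
read -> write -> read loop is lossless on the JSON path.

Material definition files are YAML documents::

    energy_pair: {e_low: 50.0, e_high: 200.0}
    materials:
      - name: iomeprol
        mu_low: 0.433
        mu_high: 0.152
        units: "1/cm"
        stock_concentration_mg_per_ml: 20.0
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .basis_calibration import CalibrationSummary, GroupCalibration
from .core import (
    AttenuationVector,
    BasisMaterial,
    BasisSet,
    EnergyPair,
    SpecimenMeasurement,
    hu_to_mu,
)
from .correction import CorrectionResult, HistologyFractions
from .errors import ConfigurationError, ParseError
from .three_material import FractionVector

__all__ = [
    "read_material_entries",
    "read_materials",
    "write_materials",
    "read_measurements",
    "write_measurements",
    "read_histology",
    "write_histology",
    "write_fractions",
    "write_correction_report",
    "write_calibration_report",
    "write_report",
]

_MU_UNITS = {"1/cm", "mu_per_cm"}
_HU_UNITS = {"hu", "hounsfield"}


# ---------------------------------------------------------------- materials

def read_material_entries(path: str | Path) -> list[BasisMaterial]:
    """Read the material entries of a YAML definition file (any count >= 1)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "materials" not in data:
        raise ParseError(f"{path}: expected a mapping with a 'materials' list")
    entries = []
    for i, raw in enumerate(data["materials"]):
        units = raw.get("units")
        if units not in _MU_UNITS:
            raise ParseError(
                f"{path}: material #{i + 1} ({raw.get('name')!r}) must declare "
                f"units '1/cm', got {units!r}"
            )
        entries.append(
            BasisMaterial(
                name=raw["name"],
                attenuation=AttenuationVector(float(raw["mu_low"]), float(raw["mu_high"])),
                stock_concentration=(
                    float(raw["stock_concentration_mg_per_ml"])
                    if raw.get("stock_concentration_mg_per_ml") is not None
                    else None
                ),
                provenance=raw.get("provenance", ""),
            )
        )
    return entries


def read_materials(path: str | Path) -> BasisSet:
    """Read a YAML basis-material definition file into a :class:`BasisSet`."""
    data = yaml.safe_load(Path(path).read_text())
    energy = EnergyPair(**(data or {}).get("energy_pair", {}))
    return BasisSet(tuple(read_material_entries(path)), energy)


def write_materials(basis: BasisSet, path: str | Path) -> None:
    data = {
        "energy_pair": {"e_low": basis.energy_pair.e_low, "e_high": basis.energy_pair.e_high},
        "materials": [
            {
                "name": m.name,
                "mu_low": m.attenuation.mu_low,
                "mu_high": m.attenuation.mu_high,
                "units": "1/cm",
                "stock_concentration_mg_per_ml": m.stock_concentration,
                "provenance": m.provenance,
            }
            for m in basis
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ------------------------------------------------------------- measurements

def read_measurements(
    path: str | Path,
    *,
    water_reference: Optional[AttenuationVector] = None,
) -> list[SpecimenMeasurement]:
    """Read a measurement table (specimen_id, value_low, value_high, units).

    Rows in HU are converted with ``water_reference`` (required for them);
    rows already in 1/cm pass through. Row order is preserved.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    required = {"specimen_id", "value_low", "value_high", "units"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row_number, row in enumerate(table.itertuples(index=False), start=2):
        units = str(row.units).strip().lower()
        try:
            lo, hi = float(row.value_low), float(row.value_high)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {row_number}: non-numeric value") from exc
        if units in _MU_UNITS:
            mu = AttenuationVector(lo, hi)
            source = "mu_per_cm"
        elif units in _HU_UNITS:
            if water_reference is None:
                raise ConfigurationError(
                    f"{path}: row {row_number} is in HU but no water reference was supplied"
                )
            mu = AttenuationVector(
                hu_to_mu(lo, water_reference.mu_low),
                hu_to_mu(hi, water_reference.mu_high),
            )
            source = "hounsfield"
        else:
            raise ParseError(
                f"{path}: row {row_number}: unknown units {row.units!r} "
                "(expected '1/cm' or 'HU')"
            )
        out.append(SpecimenMeasurement(str(row.specimen_id), mu, source))
    return out


def write_measurements(
    measurements: Sequence[SpecimenMeasurement], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "specimen_id": [m.specimen_id for m in measurements],
            "value_low": [m.mu_ct.mu_low for m in measurements],
            "value_high": [m.mu_ct.mu_high for m in measurements],
            "units": "1/cm",
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- histology

def read_histology(path: str | Path) -> dict[str, HistologyFractions]:
    """Read a histology table: specimen_id, three material columns, units.

    ``units`` declares 'percent' (0-100) or 'fraction' (0-1) per row. Values
    are normalized to fractions; rows whose sum deviates from 1 beyond the
    tolerance baked into :class:`HistologyFractions` are rejected with the
    offending row named.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    if "specimen_id" not in table.columns or "units" not in table.columns:
        raise ParseError(f"{path}: need 'specimen_id' and 'units' columns")
    value_cols = [c for c in table.columns if c not in ("specimen_id", "units")]
    if len(value_cols) != 3:
        raise ParseError(
            f"{path}: expected exactly 3 material columns, got {value_cols}"
        )
    out: dict[str, HistologyFractions] = {}
    for row_number, row in enumerate(table.itertuples(index=False), start=2):
        units = str(row.units).strip().lower()
        scale = {"percent": 0.01, "fraction": 1.0}.get(units)
        if scale is None:
            raise ParseError(
                f"{path}: row {row_number}: units must be 'percent' or 'fraction', "
                f"got {row.units!r}"
            )
        values = {c: scale * float(getattr(row, c)) for c in value_cols}
        try:
            out[str(row.specimen_id)] = HistologyFractions(values)
        except Exception as exc:
            raise ParseError(f"{path}: row {row_number}: {exc}") from exc
    return out


def write_histology(
    histology: dict[str, HistologyFractions], path: str | Path
) -> None:
    rows = []
    for sid, h in histology.items():
        row = {"specimen_id": sid, **h.fractions, "units": "fraction"}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------------ reports

def write_fractions(
    fractions: dict[str, FractionVector], path: str | Path, *, decimals: int = 6
) -> None:
    """Write per-specimen fraction vectors as a CSV (one row per specimen)."""
    rows = []
    for sid, fv in fractions.items():
        rows.append({"specimen_id": sid, **{k: round(v, decimals) for k, v in fv.items()},
                     "out_of_gamut": fv.out_of_gamut})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_correction_report(
    results: Sequence[CorrectionResult],
    csv_path: str | Path,
    json_path: Optional[str | Path] = None,
    *,
    stocks: Optional[dict[str, float]] = None,
    fraction_decimals: int = 3,
    concentration_decimals: int = 3,
) -> None:
    """Write correction results as a rounded CSV plus a full-precision JSON.

    ``stocks`` maps extra-material names to stock concentrations (mg/ml) so
    the CSV can carry a concentration column next to each fraction. The CSV is
    header-only for an empty result list.
    """
    rows = []
    for r in results:
        row: dict[str, object] = {"specimen_id": r.specimen_id}
        for name, value in r.full_composition.items():
            row[f"fraction_{name}"] = round(value, fraction_decimals)
        for name, value in r.extra_fractions.items():
            if stocks and name in stocks:
                row[f"concentration_{name}_mg_per_ml"] = round(
                    value * stocks[name], concentration_decimals
                )
        row["matching_error_low_pct"] = round(r.matching_error_pct[0], 4)
        row["matching_error_high_pct"] = round(r.matching_error_pct[1], 4)
        rows.append(row)
    columns = list(rows[0]) if rows else ["specimen_id"]
    pd.DataFrame(rows, columns=columns).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = [
            {
                "specimen_id": r.specimen_id,
                "extra_fractions": r.extra_fractions,
                "c_a": r.c_a,
                "c_s": r.c_s,
                "full_composition": dict(r.full_composition.items()),
                "histology_point": list(r.histology_point.as_array()),
                "optimized_point": list(r.optimized_point.as_array()),
                "path_vectors": {k: list(v) for k, v in r.path_vectors.items()},
                "matching_error_pct": list(r.matching_error_pct),
                "cost_value": r.cost_value,
            }
            for r in results
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2))


def write_calibration_report(
    summary: CalibrationSummary,
    groups: Sequence[GroupCalibration],
    csv_path: str | Path,
    json_path: Optional[str | Path] = None,
) -> None:
    """Write a factor-table CSV (one row per group plus the weighted mean)."""
    names = summary.material_names
    columns = [f"c_{n}_low" for n in names] + [f"c_{n}_high" for n in names]
    rows = []
    for g in groups:
        rows.append(
            {"group": g.group_id,
             **dict(zip(columns, np.round(g.correction_factors, 4))),
             "cost_per_mille": round(g.cost_per_mille, 4)}
        )
    rows.append(
        {"group": "weighted_mean",
         **dict(zip(columns, np.round(summary.weighted_factors, 4))),
         "cost_per_mille": float("nan")}
    )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "material_names": list(names),
            "weighted_factors": list(summary.weighted_factors),
            "weights": list(summary.weights),
            "final_attenuation": {
                k: list(v.as_array()) for k, v in summary.final_attenuation.items()
            },
            "groups": [
                {
                    "group_id": g.group_id,
                    "correction_factors": list(g.correction_factors),
                    "formalin_fractions": list(g.formalin_fractions),
                    "cost_value": g.cost_value,
                    "specimen_ids": list(g.specimen_ids),
                }
                for g in groups
            ],
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))


def write_report(results, path: str | Path, style: str = "csv", **kwargs) -> None:
    """Dispatching writer: correction results or fraction tables to CSV/JSON."""
    results = list(results) if not isinstance(results, dict) else results
    if isinstance(results, dict):
        write_fractions(results, path, **kwargs)
    elif all(isinstance(r, CorrectionResult) for r in results):
        json_path = kwargs.pop("json_path", None)
        write_correction_report(results, path, json_path, **kwargs)
    else:
        raise ConfigurationError(f"no writer for results of type {type(results)!r}")
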