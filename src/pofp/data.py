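"""Reading, validating and cleaning photophysics tables.

Records mirror aggregate-science database exports: a SMILES string plus any
subset of solid-state and nanoaggregate emission peak wavelengths (nm),
fluorescence quantum yield, lifetime (ns), an aggregate-feature class label
(AIE/ACQ/TADF/AIDF/RTP) and an excited-state mechanism label
(ICT_TICT/ESIPT/NA/CL). Wavelengths are converted to transition energies by
the spectroscopist's rule of thumb E = 1240 / lambda (eV, lambda in nm).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from pofp.features import (
    Rejection,
    SUPPORTED_ELEMENTS,
    FingerprintError,
    molecule_elements,
    parse_smiles,
)

FEATURE_CLASSES = ("AIE", "ACQ", "TADF", "AIDF", "RTP")
MECHANISMS = ("ICT_TICT", "ESIPT", "NA", "CL")

#: CSV schema (header required; extra columns are ignored).
CSV_COLUMNS = (
    "smiles", "lambda_solid_nm", "lambda_agg_nm", "qy", "lifetime_ns",
    "feature_class", "mechanism",
)

#: The exact-as-printed conversion constant of E ~ 1240 / lambda.
EV_NM = 1240.0


def wavelength_to_energy(lambda_nm: float) -> float:
    """Convert an emission wavelength (nm) to a transition energy (eV)."""
    if not lambda_nm > 0:
        raise ValueError(f"wavelength must be positive, got {lambda_nm}")
    return EV_NM / lambda_nm


def energy_to_wavelength(energy_ev: float) -> float:
    """Inverse of :func:`wavelength_to_energy` (the map is an involution)."""
    if not energy_ev > 0:
        raise ValueError(f"energy must be positive, got {energy_ev}")
    return EV_NM / energy_ev


@dataclass(frozen=True)
class PhotophysRecord:
    """One database entry: a structure plus measured photophysics."""

    smiles: str
    lambda_solid: Optional[float] = None
    lambda_agg: Optional[float] = None
    quantum_yield: Optional[float] = None
    lifetime: Optional[float] = None
    feature_class: Optional[str] = None
    mechanism: Optional[str] = None

    def __post_init__(self):
        for lam in (self.lambda_solid, self.lambda_agg):
            if lam is not None and not (0 < lam < 10000):
                raise ValueError(f"wavelength {lam} nm outside (0, 10000)")
        if self.quantum_yield is not None and not (0 <= self.quantum_yield <= 1):
            raise ValueError(f"quantum yield {self.quantum_yield} outside [0, 1]")
        if self.lifetime is not None and not self.lifetime > 0:
            raise ValueError(f"lifetime {self.lifetime} ns must be positive")
        if self.feature_class is not None and self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.mechanism is not None and self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if all(
            getattr(self, f.name) is None
            for f in dataclasses.fields(self)
            if f.name != "smiles"
        ):
            raise ValueError("record must carry at least one property or label")


@dataclass
class Dataset:
    """An ordered collection of records with a provenance tag."""

    records: list[PhotophysRecord]
    provenance: str

    def __post_init__(self):
        if not self.provenance:
            raise ValueError("provenance tag must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "smiles": r.smiles,
                "lambda_solid_nm": r.lambda_solid,
                "lambda_agg_nm": r.lambda_agg,
                "qy": r.quantum_yield,
                "lifetime_ns": r.lifetime,
                "feature_class": r.feature_class,
                "mechanism": r.mechanism,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    value = float(value)
    return None if math.isnan(value) else value


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    value = str(value).strip()
    return value or None


def _record_from_row(row: pd.Series) -> PhotophysRecord:
    smiles = _opt_str(row.get("smiles"))
    if smiles is None:
        raise ValueError("missing smiles")
    return PhotophysRecord(
        smiles=smiles,
        lambda_solid=_opt_float(row.get("lambda_solid_nm")),
        lambda_agg=_opt_float(row.get("lambda_agg_nm")),
        quantum_yield=_opt_float(row.get("qy")),
        lifetime=_opt_float(row.get("lifetime_ns")),
        feature_class=_opt_str(row.get("feature_class")),
        mechanism=_opt_str(row.get("mechanism")),
    )


def read_records(path: str | Path) -> tuple[Dataset, list[Rejection]]:
    """Read a CSV (or JSON-lines ``.jsonl``) table into a Dataset.

    Malformed rows are reported, not fatal; a missing ``smiles`` column is a
    fatal configuration error.
    """
    path = Path(path)
    if path.suffix == ".jsonl":
        frame = pd.read_json(path, lines=True) if path.stat().st_size else pd.DataFrame()
    else:
        # keep_default_na=False: the mechanism label "NA" is data, not a
        # missing value; only genuinely empty cells parse to absent.
        frame = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if len(frame.columns) and "smiles" not in frame.columns:
        raise KeyError(f"{path}: input table has no 'smiles' column")
    records: list[PhotophysRecord] = []
    rejections: list[Rejection] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        try:
            records.append(_record_from_row(row))
        except (ValueError, TypeError) as exc:
            rejections.append(Rejection(i, _opt_str(row.get("smiles")) or "", str(exc)))
    return Dataset(records=records, provenance=f"file:{path.name}"), rejections


def write_records(ds: Dataset, path: str | Path) -> None:
    """Write a Dataset to CSV or JSON-lines; round-trips with read_records."""
    path = Path(path)
    frame = ds.to_frame()
    if path.suffix == ".jsonl":
        frame.to_json(path, orient="records", lines=True)
    else:
        frame.to_csv(path, index=False)


def clean_records(ds: Dataset, dedup: bool = False) -> tuple[Dataset, list[Rejection]]:
    """Drop records with invalid SMILES or non-representable elements.

    Retained records contain only elements the fingerprint can represent
    (the organic/main-group set plus Au, Bi, Ir, Ru, Eu of feature 38);
    everything else is rejected with reason ``invalid_smiles`` or
    ``disallowed_element``. Cleaning never throws on data content and never
    mutates retained records, so it is idempotent.

    Duplicate SMILES are retained by default (databases legitimately hold
    polymorph entries); ``dedup=True`` keeps only the first occurrence and
    rejects the rest with reason ``duplicate_smiles``.
    """
    kept: list[PhotophysRecord] = []
    rejections: list[Rejection] = []
    seen: set[str] = set()
    for i, rec in enumerate(ds.records):
        if dedup and rec.smiles in seen:
            rejections.append(Rejection(i, rec.smiles, "duplicate_smiles"))
            continue
        try:
            mol = parse_smiles(rec.smiles)
        except FingerprintError:
            rejections.append(Rejection(i, rec.smiles, "invalid_smiles"))
            continue
        if molecule_elements(mol) - SUPPORTED_ELEMENTS:
            rejections.append(Rejection(i, rec.smiles, "disallowed_element"))
            continue
        kept.append(rec)
        seen.add(rec.smiles)
    tag = ds.provenance if ds.provenance.endswith("|cleaned") else ds.provenance + "|cleaned"
    return Dataset(records=kept, provenance=tag), rejections
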