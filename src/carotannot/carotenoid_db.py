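"""Curated carotenoid reference table: lookup by neutral mass, filter by taxon.

The packaged table replaces a live spectral-database query so the pipeline
runs fully offline. Masses are derived from standard molecular formulas
(nominal scale for unit-resolution work, monoisotopic for high resolution)
and cross-checked against the formula at load time. Producer taxa encode
literature plausibility (e.g. capsanthin is a plant pigment; caloxanthin is
known from Erythrobacter and several cyanobacteria) and drive a demotion —
never a rejection — downstream. Fine-structure ranges are curator-supplied
brackets of published %III/II determinations and are fully overridable via
a user table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .spectra_model import TAXA

_ELEMENT_NOMINAL = {"C": 12, "H": 1, "O": 16, "N": 14}
_ELEMENT_MONO = {"C": 12.0, "H": 1.0078250319, "O": 15.9949146221, "N": 14.0030740052}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str, scale: str = "nominal") -> float:
    """Mass of a molecular formula on the nominal or monoisotopic scale."""
    table = _ELEMENT_NOMINAL if scale == "nominal" else _ELEMENT_MONO
    mass = 0.0
    consumed = 0
    for m in _FORMULA_RE.finditer(formula):
        el, count = m.group(1), m.group(2)
        if el not in table:
            raise ValueError(f"unsupported element {el!r} in formula {formula!r}")
        mass += table[el] * (int(count) if count else 1)
        consumed += len(m.group(0))
    if consumed != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return float(mass)


@dataclass(frozen=True)
class CarotenoidRecord:
    name: str
    formula: str
    nominal_mass: float
    monoisotopic_mass: float
    n_hydroxyl: int
    n_methoxy: int
    n_keto: int
    n_epoxide: int
    compound_class: frozenset[str]
    producers: frozenset[str]
    diagnostic_fragments: tuple[tuple[float, str], ...] = ()
    fine_structure_range: tuple[float, float] | None = None
    ref_lambda_max: tuple[float, ...] | None = None
    #: literature-reported water-loss intensity behaviour for isomer pairs
    isomer_water_loss: str | None = None  # "high" | "low" | None
    #: instrument-observed neutral mass when the exact structure is ambiguous
    observed_mass: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.nominal_mass <= 0 or self.monoisotopic_mass <= 0:
            raise ValueError(f"{self.name}: masses must be positive")
        if min(self.n_hydroxyl, self.n_methoxy, self.n_keto, self.n_epoxide) < 0:
            raise ValueError(f"{self.name}: group counts must be >= 0")
        if not self.producers:
            raise ValueError(f"{self.name}: producers must be non-empty")
        bad = self.producers - (TAXA - {"unknown"})
        if bad:
            raise ValueError(f"{self.name}: unknown producer taxa {sorted(bad)}")
        for scale, mass in (("nominal", self.nominal_mass),
                            ("monoisotopic", self.monoisotopic_mass)):
            expected = formula_mass(self.formula, scale)
            if abs(mass - expected) > 1.0:
                raise ValueError(
                    f"record {self.name!r}: {scale} mass {mass} inconsistent with "
                    f"formula {self.formula} (expected {expected:.3f}, > 1 Da off)"
                )

    def mass(self, scale: str = "nominal") -> float:
        return self.nominal_mass if scale == "nominal" else self.monoisotopic_mass


def _split(cell, sep: str = ";") -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return []
    return [t.strip() for t in str(cell).split(sep) if t.strip()]


def _parse_diagnostics(cell) -> tuple[tuple[float, str], ...]:
    out = []
    for token in _split(cell, "|"):
        mz_s, _, note = token.partition(":")
        out.append((float(mz_s), note.strip()))
    return tuple(out)


def load_reference(path: str | Path | None = None) -> list[CarotenoidRecord]:
    """Load the packaged reference table, or a user CSV with the same header."""
    if path is None:
        source = resources.files("carotannot").joinpath("data/carotenoids.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    records: list[CarotenoidRecord] = []
    for _, row in df.iterrows():
        fs_lo, fs_hi = row.get("fine_structure_low"), row.get("fine_structure_high")
        fs_range = None
        if pd.notna(fs_lo) and pd.notna(fs_hi):
            fs_range = (float(fs_lo), float(fs_hi))
        lam = tuple(float(x) for x in _split(row.get("ref_lambda_max")))
        iso = row.get("isomer_water_loss")
        obs = row.get("observed_mass")
        records.append(CarotenoidRecord(
            name=str(row["name"]).strip(),
            formula=str(row["formula"]).strip(),
            nominal_mass=float(row["nominal_mass"]),
            monoisotopic_mass=float(row["monoisotopic_mass"]),
            n_hydroxyl=int(row["n_hydroxyl"]),
            n_methoxy=int(row["n_methoxy"]),
            n_keto=int(row["n_keto"]),
            n_epoxide=int(row["n_epoxide"]),
            compound_class=frozenset(_split(row["compound_class"])),
            producers=frozenset(_split(row["producers"])),
            diagnostic_fragments=_parse_diagnostics(row.get("diagnostic_fragments")),
            fine_structure_range=fs_range,
            ref_lambda_max=lam or None,
            isomer_water_loss=str(iso).strip() if pd.notna(iso) and str(iso).strip() else None,
            observed_mass=float(obs) if pd.notna(obs) else None,
            notes=str(row.get("notes", "")) if pd.notna(row.get("notes", "")) else "",
        ))
    names = [r.name.lower() for r in records]
    if len(names) != len(set(names)):
        raise ValueError("reference table contains duplicate record names")
    return records


def candidates_by_mass(neutral_mass: float, tol: float,
                       records: list[CarotenoidRecord],
                       scale: str = "nominal") -> list[CarotenoidRecord]:
    """Records whose mass lies within ``tol`` of a neutral-mass hypothesis.

    Ordered by absolute mass error, ties by name; an empty result is a valid
    outcome (the signal stays unexplained downstream).
    """
    if not tol > 0:
        raise ValueError("tolerance must be positive")
    hits = [r for r in records if abs(r.mass(scale) - neutral_mass) <= tol]
    hits.sort(key=lambda r: (abs(r.mass(scale) - neutral_mass), r.name))
    return hits


def producer_compatible(record: CarotenoidRecord, taxon: str) -> bool:
    """True iff the taxon is a known producer; ``unknown`` never filters."""
    if taxon not in TAXA:
        raise ValueError(f"taxon must be one of {sorted(TAXA)}, got {taxon!r}")
    return taxon == "unknown" or taxon in record.producers


def find_record(records: list[CarotenoidRecord], name: str) -> CarotenoidRecord:
    """Resolve a printed compound string to exactly one record.

    Matching is case-insensitive and ignores a trailing parenthetical
    synonym (e.g. "Caloxanthin (=Hydroxy-zeaxanthin)").
    """
    key = re.sub(r"\s*\(.*\)\s*$", "", name).strip().lower()
    hits = [r for r in records if r.name.lower() == key]
    if len(hits) != 1:
        raise KeyError(f"compound name {name!r} resolves to {len(hits)} records")
    return hits[0]
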