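"""Accurate-mass compound identification.

Chemical formulas are parsed to element counts, monoisotopic masses are
summed from an embedded table of most-abundant-isotope masses (CODATA/IUPAC
values, 6+ decimals), adduct m/z values follow
``(multiplicity * M + mass_shift) / |charge|`` with the proton convention
(+1.007276 Da for [M+H]+), and batch queries match observed m/z against a
compound-database snapshot within a ppm or Da tolerance.

The mass-accuracy delta is computed relative to the *reference* (adduct)
m/z: delta_ppm = |observed - reference| / reference * 1e6.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import math
import pandas as pd

__all__ = [
    "Formula",
    "AdductSpec",
    "CompoundRecord",
    "MatchResult",
    "ATOMIC_MASSES",
    "PROTON_MASS",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_delta",
    "match_database",
    "read_compound_db",
]

#: monoisotopic (most-abundant isotope) masses, Da
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00782503207, "D": 2.01410177785, "B": 11.0093054,
    "C": 12.0, "N": 14.0030740048, "O": 15.9949146196,
    "F": 18.99840322, "Na": 22.9897692809, "Mg": 23.985041700,
    "Si": 27.9769265325, "P": 30.97376163, "S": 31.97207100,
    "Cl": 34.96885268, "K": 38.96370668, "Ca": 39.96259098,
    "Fe": 55.9349375, "Cu": 62.9295975, "Zn": 63.9291422,
    "Se": 79.9165213, "Br": 78.9183371, "I": 126.904473,
}

#: proton mass, Da — the [M+H]+ shift (not the hydrogen-atom mass)
PROTON_MASS = 1.007276


Formula = dict[str, int]


@dataclass(frozen=True)
class AdductSpec:
    name: str
    charge: int
    mass_shift: float
    multiplicity: int = 1

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError(f"adduct {self.name}: charge must be nonzero")
        if self.multiplicity < 1:
            raise ValueError(f"adduct {self.name}: multiplicity must be >= 1")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


#: shipped adduct registry; "M" formalizes neutral-mass queries (charge 1,
#: zero shift) so the same machinery covers neutral mode
ADDUCTS: dict[str, AdductSpec] = {
    "M": AdductSpec("M", 1, 0.0),
    "M+H": AdductSpec("M+H", 1, PROTON_MASS),
    "M+Na": AdductSpec("M+Na", 1, 22.989218),
    "M+K": AdductSpec("M+K", 1, 38.963158),
    "M+NH4": AdductSpec("M+NH4", 1, 18.033823),
    "2M+H": AdductSpec("2M+H", 1, PROTON_MASS, multiplicity=2),
    "M-H": AdductSpec("M-H", -1, -PROTON_MASS),
    "M+Cl": AdductSpec("M+Cl", -1, 34.969402),
}


@dataclass
class CompoundRecord:
    db_name: str
    db_id: str
    name: str
    formula: str | None
    monoisotopic_mass: float
    xref_id: str | None = None

    def __post_init__(self):
        if self.formula:
            calc = monoisotopic_mass(parse_formula(self.formula))
            if calc > 0 and abs(calc - self.monoisotopic_mass) / calc > 1e-6:
                raise ValueError(
                    f"{self.db_id}: recorded mass {self.monoisotopic_mass} "
                    f"disagrees with formula mass {calc:.6f} beyond 1 ppm")


@dataclass
class MatchResult:
    query_mz: float
    adduct: str
    db_name: str
    db_id: str
    name: str
    formula: str | None
    adduct_mz: float
    delta: float          # in the requested tolerance's unit
    delta_unit: str       # 'ppm' or 'da'


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation-like formula into element counts.

    Underscore subscript markers (``C_17_H_19_NO_3_``) are tolerated;
    implicit count is 1; repeated elements accumulate.
    """
    cleaned = text.replace("_", "").strip()
    if not cleaned:
        return {}
    counts: Formula = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(cleaned):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {cleaned[pos:]!r}")
        pos = m.end()
        el = m.group(1)
        if el not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
    if pos != len(cleaned):
        raise ValueError(f"cannot parse formula {text!r} at {cleaned[pos:]!r}")
    return counts


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of count x most-abundant-isotope mass; empty formula is 0."""
    return sum(ATOMIC_MASSES[el] * n for el, n in formula.items())


def adduct_mz(M: float, adduct: AdductSpec | str) -> float:
    """m/z of an adduct of neutral mass M:
    (multiplicity * M + mass_shift) / |charge|."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if M <= 0:
        raise ValueError("neutral mass must be positive")
    return (adduct.multiplicity * M + adduct.mass_shift) / abs(adduct.charge)


def ppm_delta(observed: float, reference: float) -> float:
    """|observed - reference| / reference * 1e6 (reference = adduct m/z)."""
    if reference <= 0:
        raise ValueError("reference m/z must be positive")
    return abs(observed - reference) / reference * 1e6


def match_database(queries, db: list[CompoundRecord],
                   adducts=("M+H",), tol: float = 3.0, tol_unit: str = "ppm",
                   mode: str = "positive") -> list[MatchResult]:
    """Batch accurate-mass query against a compound-database snapshot.

    Per query x compatible adduct, every record whose adduct m/z falls
    within the tolerance is returned, sorted by delta ascending (ties by
    db_id). ``mode`` restricts adducts by polarity ('neutral' admits only
    the bare-M adduct). A query with no hit simply yields nothing.
    """
    if not db:
        raise ValueError("empty compound database")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if tol_unit not in ("ppm", "da"):
        raise ValueError("tol_unit must be 'ppm' or 'da'")
    specs = []
    for a in adducts:
        spec = ADDUCTS[a] if isinstance(a, str) else a
        if mode == "neutral":
            if spec.name != "M":
                continue
        elif spec.polarity != mode or spec.name == "M":
            continue
        specs.append(spec)
    if mode == "neutral" and not specs:
        specs = [ADDUCTS["M"]]
    out: list[MatchResult] = []
    for q in queries:
        hits = []
        for spec in specs:
            for rec in db:
                ref = adduct_mz(rec.monoisotopic_mass, spec)
                d_ppm = ppm_delta(q, ref)
                d_da = abs(q - ref)
                delta = d_ppm if tol_unit == "ppm" else d_da
                if delta <= tol:
                    hits.append(MatchResult(q, spec.name, rec.db_name,
                                            rec.db_id, rec.name, rec.formula,
                                            ref, delta, tol_unit))
        hits.sort(key=lambda h: (h.delta, h.db_id))
        out.extend(hits)
    return out


def read_compound_db(path, sep: str = "\t") -> list[CompoundRecord]:
    """Read a DB snapshot TSV: db_name, db_id, xref_id, name, formula,
    monoisotopic_mass. A missing monoisotopic_mass is computed from the
    formula."""
    df = pd.read_csv(path, sep=sep, dtype={"db_id": str, "xref_id": str})
    records = []
    for _, row in df.iterrows():
        formula = row.get("formula")
        formula = None if pd.isna(formula) else str(formula)
        mass = row.get("monoisotopic_mass")
        if pd.isna(mass):
            if formula is None:
                raise ValueError(f"{row['db_id']}: neither mass nor formula")
            mass = monoisotopic_mass(parse_formula(formula))
        xref = row.get("xref_id")
        records.append(CompoundRecord(
            db_name=str(row["db_name"]), db_id=str(row["db_id"]),
            name=str(row["name"]), formula=formula,
            monoisotopic_mass=float(mass),
            xref_id=None if pd.isna(xref) else str(xref)))
    return records
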