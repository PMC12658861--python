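"""Bundled demonstration dataset: 12 common narcotics measured by targeted
LC-MS/MS.

Each record carries the compound's chemical formula, the published [M+H]+
reference m/z (4 decimals), the measured (estimated) MS1 m/z, retention
time, the concentration determined for the 500 ppb test sample, and
database availability flags. These are measurement inputs for worked
examples and tests of the identification and calibration modules.
"""

from __future__ import annotations

from dataclasses import dataclass

from .identify import PROTON_MASS, CompoundRecord

__all__ = ["Narcotic", "NARCOTICS", "hmdb_like_db", "massbank_like_db"]


@dataclass(frozen=True)
class Narcotic:
    name: str
    formula: str
    estimated_mz: float       # measured MS1 m/z, positive mode [M+H]+
    adduct_mz: float          # published [M+H]+ reference m/z (4 dp)
    rt_s: float               # retention time of the 500 ppb test sample
    conc_500: float           # determined concentration in the 500 ppb sample, ppb
    hmdb_id: str | None
    in_massbank: bool


NARCOTICS: list[Narcotic] = [
    Narcotic("heroin", "C21H23NO5", 370.1642, 370.1649, 685.3724, 507.4039, None, True),
    Narcotic("morphine", "C17H19NO3", 286.1430, 286.1438, 146.2696, 499.5544, "HMDB0014440", True),
    Narcotic("cocaine", "C17H21NO4", 304.1538, 304.1543, 701.1360, 501.2351, "HMDB0015043", True),
    Narcotic("thebaine", "C19H21NO3", 312.1586, 312.1594, 678.8176, 450.4228, "HMDB0029378", True),
    Narcotic("delta9-THC", "C21H30O2", 315.2318, 315.2319, 1513.3190, 467.1095, "HMDB0014613", True),
    Narcotic("amphetamine", "C9H13N", 136.1118, 136.1121, 419.1944, 773.8217, "HMDB0014328", True),
    Narcotic("MA", "C10H15N", 150.1273, 150.1277, 496.8365, 595.2049, "HMDB0015517", True),
    Narcotic("MDMA", "C11H15NO2", 194.1172, 194.1176, 538.9991, 520.7164, "HMDB0254382", True),
    Narcotic("MDA", "C10H13NO2", 180.1017, 180.1019, 505.6407, 492.0814, "HMDB0041931", True),
    Narcotic("ketamine", "C13H16ClNO", 238.0992, 238.0993, 599.9313, 547.7417, "HMDB0015352", True),
    Narcotic("FM2", "C16H12FN3O3", 314.0930, 314.0935, 1044.2740, 512.0763, "HMDB0015510", True),
    Narcotic("nimetazepam", "C16H13N3O3", 296.1025, 296.1030, 1040.5220, 537.2955, None, False),
]


def _record(db_name: str, db_id: str, n: Narcotic) -> CompoundRecord:
    # recorded mass consistent with the published reference adduct m/z
    # (curated database masses, like HMDB's, differ from formula-derived
    # monoisotopic masses in the 4th decimal)
    return CompoundRecord(db_name=db_name, db_id=db_id, name=n.name,
                          formula=n.formula,
                          monoisotopic_mass=n.adduct_mz - PROTON_MASS)


def hmdb_like_db() -> list[CompoundRecord]:
    """Synthetic HMDB-style snapshot: the narcotics that HMDB carries."""
    return [_record("HMDB", n.hmdb_id, n) for n in NARCOTICS if n.hmdb_id]


def massbank_like_db() -> list[CompoundRecord]:
    """Synthetic MassBank-style snapshot (all but nimetazepam)."""
    return [_record("MassBank", f"MB{i:06d}", n)
            for i, n in enumerate(NARCOTICS) if n.in_massbank]
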