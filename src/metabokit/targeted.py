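"""Targeted peak detection, abundance quantification, S/N and fragment
relative abundances for LC-MS/MS runs.

A target names an analyte by its MS1 m/z (optionally RT and a list of true
MS2 fragment m/z values). Detection scans MS1 centroids within a ppm window
for the most intense match; MS2 fragments are located in product-ion scans
whose precursor and RT agree with the MS1 hit. Abundance is the sum of the
extracted ion chromatogram inside an RT window, and S/N is the mean divided
by the sample standard deviation of the intensities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msio import Run, extract_xic

__all__ = [
    "TargetDefinition",
    "FragmentMatch",
    "TargetedResult",
    "detect_ms1",
    "match_ms2",
    "integrate_abundance",
    "signal_to_noise",
    "relative_abundance",
    "analyze_targets",
    "read_targets",
]

#: demonstration defaults: 1000 ppm m/z window, +/-5 s RT window
DEFAULT_MZ_TOL_PPM = 1000.0
DEFAULT_RT_TOL_S = 5.0


@dataclass
class TargetDefinition:
    name: str
    ms1_mz: float
    rt: float | None = None
    fragment_mz: list[float] = field(default_factory=list)
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM
    rt_tol: float = DEFAULT_RT_TOL_S
    # fragment window: ("ppm", value) or ("da", value); Da default because
    # fragment targets are often given as nominal (integer) masses
    fragment_tol: tuple[str, float] = ("da", 0.5)

    def __post_init__(self):
        if self.ms1_mz <= 0:
            raise ValueError(f"{self.name}: ms1_mz must be positive")
        if self.mz_tol_ppm <= 0 or self.rt_tol <= 0:
            raise ValueError(f"{self.name}: tolerances must be positive")


@dataclass
class FragmentMatch:
    true_mz: float
    estimated_mz: float | None  # None = not detected (reported as NA)
    abundance: float | None
    relative_abundance: float | None = None


@dataclass
class TargetedResult:
    name: str
    estimated_mz: float | None
    rt: float | None
    abundance: float | None
    sn: float | None
    fragments: list[FragmentMatch] = field(default_factory=list)

    @property
    def detected(self) -> bool:
        return self.estimated_mz is not None


def detect_ms1(run: Run, target: TargetDefinition):
    """Locate the target's MS1 peak: the maximum-intensity centroid within
    the ppm window (and the RT window, when the target supplies an RT).

    Returns ``(estimated_mz, rt)`` of the best match or ``(None, None)``
    when nothing falls inside the window. The estimated m/z is the observed
    centroid value, not the query.
    """
    half = target.ms1_mz * target.mz_tol_ppm * 1e-6
    best = None  # (intensity, -mz) max; lower mz wins exact ties
    best_hit = (None, None)
    for spec in run.ms1():
        if target.rt is not None and abs(spec.rt - target.rt) > target.rt_tol:
            continue
        j0 = np.searchsorted(spec.mz, target.ms1_mz - half, side="left")
        j1 = np.searchsorted(spec.mz, target.ms1_mz + half, side="right")
        if j1 <= j0:
            continue
        j = j0 + int(np.argmax(spec.intensity[j0:j1]))
        key = (spec.intensity[j], -spec.mz[j])
        if best is None or key > best:
            best = key
            best_hit = (float(spec.mz[j]), float(spec.rt))
    return best_hit


def _frag_half_width(mz: float, tol: tuple[str, float]) -> float:
    mode, value = tol
    if mode == "ppm":
        return mz * value * 1e-6
    if mode == "da":
        return value
    raise ValueError(f"unknown tolerance mode {mode!r} (use 'ppm' or 'da')")


def match_ms2(run: Run, target: TargetDefinition, rt: float) -> list[FragmentMatch]:
    """Match the target's true fragment m/z values in MS2 scans near ``rt``.

    Eligible scans have a precursor within the MS1 ppm window and RT within
    ``rt_tol`` of ``rt``. Per fragment the highest-intensity centroid inside
    the fragment window wins (lower m/z on exact ties); an undetected
    fragment is reported with ``None`` (NA) fields — absence is data.
    """
    half_prec = target.ms1_mz * target.mz_tol_ppm * 1e-6
    scans = [
        s for s in run.ms2()
        if abs(s.precursor_mz - target.ms1_mz) <= half_prec
        and abs(s.rt - rt) <= target.rt_tol
    ]
    out = []
    for fmz in target.fragment_mz:
        half = _frag_half_width(fmz, target.fragment_tol)
        best = None
        hit = FragmentMatch(true_mz=fmz, estimated_mz=None, abundance=None)
        for s in scans:
            j0 = np.searchsorted(s.mz, fmz - half, side="left")
            j1 = np.searchsorted(s.mz, fmz + half, side="right")
            if j1 <= j0:
                continue
            j = j0 + int(np.argmax(s.intensity[j0:j1]))
            key = (s.intensity[j], -s.mz[j])
            if best is None or key > best:
                best = key
                hit = FragmentMatch(true_mz=fmz, estimated_mz=float(s.mz[j]),
                                    abundance=float(s.intensity[j]))
        out.append(hit)
    return out


def integrate_abundance(run: Run, mz: float, rt: float, mz_tol_ppm: float,
                        rt_window: float) -> float:
    """Accumulated XIC intensity over ``[rt - rt_window, rt + rt_window]``."""
    if mz_tol_ppm <= 0 or rt_window <= 0:
        raise ValueError("windows must be positive")
    trace = extract_xic(run, mz, mz_tol_ppm, (rt - rt_window, rt + rt_window))
    if not trace:
        warnings.warn(f"empty RT window around {rt:.2f} s; abundance 0")
        return 0.0
    return float(sum(v for _, v in trace))


def signal_to_noise(values) -> float:
    """Mean divided by sample standard deviation (n-1 denominator).

    Zero variance yields ``math.inf`` with a warning; fewer than two values
    is an error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("signal_to_noise needs at least two values")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero variance: S/N undefined, returning inf")
        return math.inf
    return float(arr.mean()) / sd


def relative_abundance(intensities) -> list[float | None]:
    """Scale intensities to percent of the base (most intense) peak.

    ``None`` entries (undetected fragments) propagate; all-None input stays
    all-None.
    """
    present = [v for v in intensities if v is not None]
    if not present:
        return [None] * len(intensities)
    base = max(present)
    if base == 0:
        return [None if v is None else 0.0 for v in intensities]
    return [None if v is None else 100.0 * v / base for v in intensities]


def analyze_targets(run: Run, targets: list[TargetDefinition],
                    rt_window: float | None = None):
    """Run the full targeted workflow for a batch of targets.

    Returns ``(results, ms1_table, ms2_table)`` where the tables are tidy
    DataFrames (one MS1 row per target; one MS2 row per fragment) with the
    literal string ``"NA"`` conventions left to the writer — missing values
    are NaN here. A target that is not found yields an all-NA row; one miss
    never aborts the batch.
    """
    results: list[TargetedResult] = []
    for t in targets:
        est_mz, rt = detect_ms1(run, t)
        if est_mz is None:
            results.append(TargetedResult(t.name, None, None, None, None,
                                          [FragmentMatch(f, None, None)
                                           for f in t.fragment_mz]))
            continue
        rt_w = rt_window if rt_window is not None else t.rt_tol
        abundance = integrate_abundance(run, est_mz, rt, t.mz_tol_ppm, rt_w)
        trace = extract_xic(run, est_mz, t.mz_tol_ppm, (rt - rt_w, rt + rt_w))
        vals = [v for _, v in trace]
        sn = signal_to_noise(vals) if len(vals) >= 2 else None
        frags = match_ms2(run, t, rt)
        rel = relative_abundance([f.abundance for f in frags])
        for f, r in zip(frags, rel):
            f.relative_abundance = r
        results.append(TargetedResult(t.name, est_mz, rt, abundance, sn, frags))

    ms1_rows = [
        {"name": r.name, "estimated_mz": r.estimated_mz, "rt_s": r.rt,
         "abundance": r.abundance, "sn": r.sn}
        for r in results
    ]
    ms2_rows = [
        {"name": r.name, "true_mz": f.true_mz, "estimated_mz": f.estimated_mz,
         "abundance": f.abundance, "relative_abundance": f.relative_abundance}
        for r in results for f in r.fragments
    ]
    ms1_cols = ["name", "estimated_mz", "rt_s", "abundance", "sn"]
    ms2_cols = ["name", "true_mz", "estimated_mz", "abundance", "relative_abundance"]
    return (results,
            pd.DataFrame(ms1_rows, columns=ms1_cols),
            pd.DataFrame(ms2_rows, columns=ms2_cols))


def read_targets(path, sep: str = "\t") -> list[TargetDefinition]:
    """Read a target table: columns ``name``, ``ms1_mz``, optional ``rt``,
    optional ``fragment_mz`` (semicolon-separated list)."""
    df = pd.read_csv(path, sep=sep)
    targets = []
    for _, row in df.iterrows():
        frags = []
        if "fragment_mz" in df.columns and pd.notna(row.get("fragment_mz")):
            frags = [float(x) for x in str(row["fragment_mz"]).split(";") if x.strip()]
        rt = float(row["rt"]) if "rt" in df.columns and pd.notna(row.get("rt")) else None
        kwargs = {}
        if "mz_tol_ppm" in df.columns and pd.notna(row.get("mz_tol_ppm")):
            kwargs["mz_tol_ppm"] = float(row["mz_tol_ppm"])
        if "rt_tol" in df.columns and pd.notna(row.get("rt_tol")):
            kwargs["rt_tol"] = float(row["rt_tol"])
        targets.append(TargetDefinition(str(row["name"]), float(row["ms1_mz"]),
                                        rt=rt, fragment_mz=frags, **kwargs))
    return targets
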