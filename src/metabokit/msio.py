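"""Mass-spectrometry run I/O and synthetic run generation.

Runs are held in memory as ordered lists of centroided spectra. mzML is the
on-disk interchange format, read and written by a self-contained
PSI-vocabulary implementation so that a run survives a write/read round
trip bit-for-bit within float tolerance.

Retention time is seconds everywhere inside the package; minutes are accepted
only at explicit I/O boundaries (``rt_minutes`` flags on the readers).
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

__all__ = [
    "Spectrum",
    "Run",
    "FormatError",
    "read_mzml",
    "write_mzml",
    "synthesize_run",
    "extract_xic",
]


class FormatError(ValueError):
    """Raised for malformed or unsupported (e.g. profile-mode) spectra."""


@dataclass
class Spectrum:
    """A single centroided scan.

    Parameters
    ----------
    ms_level : int
        1 for survey scans, 2 for product-ion scans.
    rt : float
        Retention time in seconds.
    mz : ndarray
        Centroid m/z values, strictly increasing.
    intensity : ndarray
        Non-negative intensities, same length as ``mz``.
    precursor_mz : float or None
        Required for MS2 scans; None for MS1.
    """

    ms_level: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ms_level not in (1, 2):
            raise FormatError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise FormatError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise FormatError("centroid m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise FormatError("intensities must be non-negative")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise FormatError("MS2 spectrum requires a precursor m/z")


@dataclass
class Run:
    """An LC-MS(/MS) acquisition: spectra ordered by retention time."""

    spectra: list[Spectrum] = field(default_factory=list)
    run_id: str = "run"

    def __post_init__(self):
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise FormatError("spectra must be ordered by non-decreasing rt")

    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def __len__(self) -> int:
        return len(self.spectra)


def _decode_array(bda) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, 32/64-bit float, optional zlib."""
    dtype = "<d"
    compressed = False
    for cv in bda.findall(f"{{{_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000521":
            dtype = "<f"
        elif acc == "MS:1000523":
            dtype = "<d"
        elif acc == "MS:1000574":
            compressed = True
    node = bda.find(f"{{{_NS}}}binary")
    raw = base64.b64decode((node.text or "").strip()) if node is not None else b""
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    A self-contained lxml parser (binary arrays: base64, 32/64-bit float,
    optional zlib). Profile-mode spectra are rejected with a
    :class:`FormatError` naming the scan index rather than silently
    centroided. RT is converted to seconds (mzML may store minutes; the
    unit accession decides).
    """
    try:
        tree = etree.parse(str(path))
    except OSError:
        raise
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: not well-formed mzML ({exc})") from exc
    root = tree.getroot()
    spectra: list[Spectrum] = []
    for i, sp in enumerate(root.iter(f"{{{_NS}}}spectrum")):
        accs = {cv.get("accession"): cv.get("value", "")
                for cv in sp.findall(f"{{{_NS}}}cvParam")}
        if "MS:1000128" in accs:
            raise FormatError(f"profile-mode spectrum at scan index {i}; centroid first")
        if "MS:1000511" not in accs:
            raise FormatError(f"spectrum at scan index {i} lacks an ms level")
        level = int(accs["MS:1000511"])
        rt = None
        for cv in sp.iter(f"{{{_NS}}}cvParam"):
            if cv.get("accession") == "MS:1000016":
                rt = float(cv.get("value"))
                if cv.get("unitName", "second").startswith("minute"):
                    rt *= 60.0
        if rt is None:
            raise FormatError(f"spectrum at scan index {i} lacks a scan start time")
        prec = None
        if level == 2:
            for cv in sp.iter(f"{{{_NS}}}cvParam"):
                if cv.get("accession") == "MS:1000744":
                    prec = float(cv.get("value"))
            if prec is None:
                raise FormatError(f"MS2 spectrum at scan index {i} lacks a precursor m/z")
        mz_arr = inten_arr = None
        for bda in sp.iter(f"{{{_NS}}}binaryDataArray"):
            kinds = {cv.get("accession") for cv in bda.findall(f"{{{_NS}}}cvParam")}
            if "MS:1000514" in kinds:
                mz_arr = _decode_array(bda)
            elif "MS:1000515" in kinds:
                inten_arr = _decode_array(bda)
        if mz_arr is None or inten_arr is None:
            raise FormatError(f"spectrum at scan index {i} lacks m/z or intensity array")
        try:
            spectra.append(Spectrum(ms_level=level, rt=rt, mz=mz_arr,
                                    intensity=inten_arr, precursor_mz=prec))
        except FormatError as exc:
            raise FormatError(f"scan index {i}: {exc}") from exc
    spectra.sort(key=lambda s: s.rt)
    return Run(spectra=spectra, run_id=str(path))


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession, name, value="", unit=None):
    attrib = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
    if unit is not None:
        attrib.update(
            {"unitCvRef": "UO", "unitAccession": unit[0], "unitName": unit[1]}
        )
    etree.SubElement(parent, f"{{{_NS}}}cvParam", attrib)


def write_mzml(run: Run, path) -> str:
    """Serialize a :class:`Run` to a minimal standards-conforming mzML file.

    Arrays are written as uncompressed little-endian 64-bit floats so the
    read/write round trip is exact to float64 precision.
    """
    if not isinstance(run, Run):
        raise TypeError("run must be a Run")
    rts = [s.rt for s in run.spectra]
    if any(b < a for a, b in zip(rts, rts[1:])):
        raise FormatError("run violates rt ordering; refusing to write")

    root = etree.Element(f"{{{_NS}}}mzML", nsmap={None: _NS}, version="1.1.0")
    cvlist = etree.SubElement(root, f"{{{_NS}}}cvList", count="2")
    etree.SubElement(cvlist, f"{{{_NS}}}cv", id="MS", fullName="PSI-MS", URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    etree.SubElement(cvlist, f"{{{_NS}}}cv", id="UO", fullName="Unit Ontology", URI="http://ontologies.berkeleybop.org/uo.obo")
    fdl = etree.SubElement(root, f"{{{_NS}}}fileDescription")
    fc = etree.SubElement(fdl, f"{{{_NS}}}fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    sw_list = etree.SubElement(root, f"{{{_NS}}}softwareList", count="1")
    etree.SubElement(sw_list, f"{{{_NS}}}software", id="metabokit", version="0.1.0")
    ic_list = etree.SubElement(root, f"{{{_NS}}}instrumentConfigurationList", count="1")
    etree.SubElement(ic_list, f"{{{_NS}}}instrumentConfiguration", id="IC1")
    dp_list = etree.SubElement(root, f"{{{_NS}}}dataProcessingList", count="1")
    dp = etree.SubElement(dp_list, f"{{{_NS}}}dataProcessing", id="DP1")
    pm = etree.SubElement(dp, f"{{{_NS}}}processingMethod", order="1", softwareRef="metabokit")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    mrun = etree.SubElement(
        root, f"{{{_NS}}}run", id=run.run_id or "run",
        defaultInstrumentConfigurationRef="IC1",
    )
    slist = etree.SubElement(
        mrun, f"{{{_NS}}}spectrumList", count=str(len(run.spectra)),
        defaultDataProcessingRef="DP1",
    )
    for i, spec in enumerate(run.spectra):
        sp = etree.SubElement(
            slist, f"{{{_NS}}}spectrum", index=str(i),
            id=f"scan={i + 1}", defaultArrayLength=str(len(spec.mz)),
        )
        _cv(sp, "MS:1000511", "ms level", spec.ms_level)
        _cv(sp, "MS:1000127", "centroid spectrum")
        _cv(sp, "MS:1000579" if spec.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if spec.ms_level == 1 else "MSn spectrum")
        sl = etree.SubElement(sp, f"{{{_NS}}}scanList", count="1")
        _cv(sl, "MS:1000795", "no combination")
        scan = etree.SubElement(sl, f"{{{_NS}}}scan")
        _cv(scan, "MS:1000016", "scan start time", repr(float(spec.rt)),
            unit=("UO:0000010", "second"))
        if spec.ms_level == 2:
            pl = etree.SubElement(sp, f"{{{_NS}}}precursorList", count="1")
            prec = etree.SubElement(pl, f"{{{_NS}}}precursor")
            sil = etree.SubElement(prec, f"{{{_NS}}}selectedIonList", count="1")
            ion = etree.SubElement(sil, f"{{{_NS}}}selectedIon")
            _cv(ion, "MS:1000744", "selected ion m/z", repr(float(spec.precursor_mz)),
                unit=("MS:1000040", "m/z"))
        bal = etree.SubElement(sp, f"{{{_NS}}}binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (spec.mz, "MS:1000514", "m/z array", ("MS:1000040", "m/z")),
            (spec.intensity, "MS:1000515", "intensity array",
             ("MS:1000131", "number of detector counts")),
        ):
            enc = _encode_array(arr)
            bda = etree.SubElement(
                bal, f"{{{_NS}}}binaryDataArray", encodedLength=str(len(enc)),
            )
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name, unit=unit)
            b = etree.SubElement(bda, f"{{{_NS}}}binary")
            b.text = enc

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    return str(path)


# width of the synthetic chromatographic peak, seconds (sigma of the Gaussian)
PEAK_SIGMA_S = 3.0


def synthesize_run(
    targets,
    noise_sd: float = 0.0,
    rt_grid=None,
    seed: int = 0,
    peak_sigma: float = PEAK_SIGMA_S,
    mz_grid_noise: int = 20,
    run_id: str = "synthetic",
) -> Run:
    """Generate a deterministic synthetic targeted LC-MS/MS run.

    Each target is ``(mz, rt_apex, height, fragments)`` where ``fragments``
    is a dict ``{fragment_mz: intensity}`` (may be empty). MS1 spectra follow
    the rt grid with Gaussian chromatographic profiles of width
    ``peak_sigma`` seconds; one MS2 spectrum per target with fragments is
    emitted at the grid point nearest its apex. ``noise_sd`` adds a Gaussian
    baseline (clipped at zero) on ``mz_grid_noise`` decoy centroids.
    """
    if rt_grid is None:
        rt_grid = np.arange(0.0, 120.0, 1.0)
    rt_grid = np.asarray(rt_grid, dtype=float)
    if rt_grid.size == 0:
        raise ValueError("rt grid must be non-empty")
    for mz, rt_apex, height, _frags in targets:
        if height <= 0:
            raise ValueError(f"target at m/z {mz} has non-positive height {height}")

    rng = np.random.default_rng(seed)
    noise_mz = np.sort(rng.uniform(50.0, 1000.0, size=mz_grid_noise)) if noise_sd > 0 else None

    spectra: list[Spectrum] = []
    ms2_at: dict[int, list] = {}
    for mz, rt_apex, height, frags in targets:
        if frags:
            idx = int(np.argmin(np.abs(rt_grid - rt_apex)))
            ms2_at.setdefault(idx, []).append((mz, frags))

    for i, rt in enumerate(rt_grid):
        mzs, ints = [], []
        for mz, rt_apex, height, _frags in targets:
            mzs.append(mz)
            ints.append(height * float(np.exp(-0.5 * ((rt - rt_apex) / peak_sigma) ** 2)))
        if noise_sd > 0:
            mzs.extend(noise_mz)
            ints.extend(np.clip(rng.normal(0.0, noise_sd, size=noise_mz.size), 0.0, None))
        order = np.argsort(mzs)
        mz_arr = np.asarray(mzs, dtype=float)[order]
        int_arr = np.asarray(ints, dtype=float)[order]
        # merge exactly coincident centroids to keep mz strictly increasing
        if mz_arr.size > 1 and np.any(np.diff(mz_arr) <= 0):
            uniq, inv = np.unique(mz_arr, return_inverse=True)
            merged = np.zeros_like(uniq)
            np.add.at(merged, inv, int_arr)
            mz_arr, int_arr = uniq, merged
        spectra.append(Spectrum(ms_level=1, rt=float(rt), mz=mz_arr, intensity=int_arr))
        for prec_mz, frags in ms2_at.get(i, []):
            fmz = np.asarray(sorted(frags), dtype=float)
            fint = np.asarray([frags[m] for m in sorted(frags)], dtype=float)
            spectra.append(
                Spectrum(ms_level=2, rt=float(rt), mz=fmz, intensity=fint,
                         precursor_mz=float(prec_mz))
            )
    return Run(spectra=spectra, run_id=run_id)


def extract_xic(run: Run, mz: float, tol_ppm: float, rt_range=None):
    """Extracted ion chromatogram: per MS1 scan, the summed intensity of
    centroids within ``tol_ppm`` (relative to the query m/z) of ``mz``.

    Returns a list of ``(rt, intensity)`` pairs, one per MS1 spectrum inside
    ``rt_range`` (a ``(lo, hi)`` interval in seconds, or None for all).
    Matching centroids within one scan are summed, not maxed.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if rt_range is not None:
        lo, hi = rt_range
        if lo > hi:
            raise ValueError(f"inverted rt_range ({lo} > {hi})")
    half = mz * tol_ppm * 1e-6
    out = []
    for spec in run.ms1():
        if rt_range is not None and not (lo <= spec.rt <= hi):
            continue
        j0 = np.searchsorted(spec.mz, mz - half, side="left")
        j1 = np.searchsorted(spec.mz, mz + half, side="right")
        out.append((spec.rt, float(spec.intensity[j0:j1].sum())))
    return out
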