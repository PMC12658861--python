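"""Abundance-matrix normalization and transformation.

Implements the scaling steps commonly applied before multivariate analysis
of metabolite abundances: Pareto scaling (mean-center, divide by the square
root of the standard deviation — damps large fold changes without erasing
data structure), the rank-based inverse normal transform (Blom variant, the
GWAS convention), internal-standard normalization, and log transforms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .feature_table import FeatureTable

__all__ = [
    "mask_zeros",
    "pareto_scale",
    "rint",
    "rint_table",
    "normalize_internal_standard",
    "log_transform",
]


def mask_zeros(table: FeatureTable) -> FeatureTable:
    """Treat zero abundances as non-detects: replace 0 with NA.

    Zero cells in an abundance matrix are censoring artifacts, not measured
    intensities; carrying them into scaling or association models inflates
    per-feature variance. Apply after QC rate filtering, before modelling.
    """
    return table.with_values(table.values.replace(0.0, np.nan))


def pareto_scale(table: FeatureTable) -> FeatureTable:
    """Per-feature Pareto scaling: (x - mean) / sqrt(sd), sample sd.

    A zero-variance feature is centered but left unscaled (with a warning);
    NA cells are preserved. The scaled feature's sd equals sqrt(original sd).
    """
    out = table.values.copy().astype(float)
    for fid in out.index:
        row = out.loc[fid]
        if row.notna().sum() < 2:
            raise ValueError(f"feature {fid!r} has fewer than 2 non-NA values")
        sd = row.std(ddof=1)
        centered = row - row.mean()
        if sd == 0:
            warnings.warn(f"feature {fid!r} has zero variance; centered only")
            out.loc[fid] = centered
        else:
            out.loc[fid] = centered / np.sqrt(sd)
    return table.with_values(out)


def rint(values, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform of a 1-D array.

    Blom variant: Phi^-1((rank - c) / (n - 2c + 1)) with c = 3/8, average
    ranks for ties, NA preserved. All-equal input maps to all zeros (every
    rank ties at the midpoint) with a warning.
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("rint needs at least two non-NA values")
    obs = arr[mask]
    if np.all(obs == obs[0]):
        warnings.warn("all values equal: RINT returns zeros")
        out = np.full_like(arr, np.nan)
        out[mask] = 0.0
        return out
    ranks = _sps.rankdata(obs, method="average")
    q = _sps.norm.ppf((ranks - c) / (n - 2 * c + 1))
    out = np.full_like(arr, np.nan)
    out[mask] = q
    return out


def rint_table(table: FeatureTable, c: float = 3.0 / 8.0) -> FeatureTable:
    """Apply :func:`rint` to every feature (row) of a table."""
    out = table.values.copy().astype(float)
    for fid in out.index:
        out.loc[fid] = rint(out.loc[fid].to_numpy(), c=c)
    return table.with_values(out)


def normalize_internal_standard(table: FeatureTable, is_feature: str) -> FeatureTable:
    """Divide every feature, per sample, by the internal standard's abundance."""
    if is_feature not in table.values.index:
        raise KeyError(f"internal standard {is_feature!r} not in table")
    is_row = table.values.loc[is_feature]
    bad = [s for s in table.sample_ids
           if pd.isna(is_row[s]) or is_row[s] == 0]
    if bad:
        raise ValueError(f"internal standard zero or NA in samples: {bad}")
    return table.with_values(table.values.div(is_row, axis=1))


def log_transform(table: FeatureTable, base: float = 2.0,
                  offset: float = 0.0) -> FeatureTable:
    """Elementwise log_base(x + offset); NA preserved.

    Cells with x + offset <= 0 make the transform undefined; they are
    reported explicitly in the error.
    """
    vals = table.values.astype(float)
    shifted = vals + offset
    bad = shifted <= 0
    if bad.any().any():
        cells = [(f, s) for f in vals.index for s in vals.columns
                 if pd.notna(shifted.loc[f, s]) and shifted.loc[f, s] <= 0]
        if cells:
            raise ValueError(f"log undefined (x + offset <= 0) at cells: {cells[:10]}")
    return table.with_values(np.log(shifted) / np.log(base))
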