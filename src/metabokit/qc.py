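"""Peak (feature) and sample quality control.

Feature filtering combines the classic missing-rate / zero-rate screens with
a signal-to-noise criterion (mean over sample sd of each feature across
samples) that catches peaks with erratic intensity even when their
missingness is acceptable. Sample filtering clusters samples on a
correlation distance (1 - r; Pearson, Spearman or Kendall tau-b) with
average linkage and removes samples left in singleton clusters when the
dendrogram is cut at a user height.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

from .feature_table import FeatureTable

__all__ = [
    "QcReport",
    "peak_metrics",
    "filter_peaks",
    "sample_distance",
    "filter_samples",
]

_METHODS = ("pearson", "spearman", "kendall")


@dataclass
class QcReport:
    feature_metrics: pd.DataFrame = None   # missing_rate, zero_rate, sn per feature
    retained: list[str] = field(default_factory=list)
    removed: pd.DataFrame = None           # id + reason
    thresholds: dict = field(default_factory=dict)


def peak_metrics(table: FeatureTable) -> pd.DataFrame:
    """Per-feature missing rate, zero rate (among non-NA cells) and S/N.

    S/N is mean/sd (sample sd) over non-NA values; an all-NA feature gets
    NaN everywhere except missing_rate; zero variance gives inf.
    """
    if table.shape[1] < 2:
        raise ValueError("peak metrics need at least two samples")
    rows = []
    for fid in table.values.index:
        x = table.values.loc[fid].to_numpy(dtype=float)
        n = x.size
        miss = np.isnan(x)
        obs = x[~miss]
        missing_rate = miss.sum() / n
        if obs.size == 0:
            rows.append((fid, 1.0, np.nan, np.nan))
            continue
        zero_rate = (obs == 0).sum() / obs.size
        if obs.size < 2:
            sn = np.nan
        else:
            sd = obs.std(ddof=1)
            sn = math.inf if sd == 0 else obs.mean() / sd
        rows.append((fid, missing_rate, zero_rate, sn))
    return pd.DataFrame(rows, columns=["feature_id", "missing_rate",
                                       "zero_rate", "sn"]).set_index("feature_id")


def filter_peaks(table: FeatureTable, max_missing: float = 0.2,
                 max_zero: float = 0.2, min_sn: float = 0.0):
    """Keep features passing all three screens; return (table, QcReport).

    A feature is retained iff missing_rate <= max_missing AND zero_rate <=
    max_zero AND sn >= min_sn (NaN sn fails a positive threshold). Removing
    everything yields an empty table with a warning, not an error.
    """
    for name, v in (("max_missing", max_missing), ("max_zero", max_zero)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    metrics = peak_metrics(table)
    removed = []
    keep = []
    for fid, m in metrics.iterrows():
        reasons = []
        if m.missing_rate > max_missing:
            reasons.append(f"missing_rate {m.missing_rate:.3f} > {max_missing}")
        if not np.isnan(m.zero_rate) and m.zero_rate > max_zero:
            reasons.append(f"zero_rate {m.zero_rate:.3f} > {max_zero}")
        sn_ok = (m.sn >= min_sn) if not np.isnan(m.sn) else (min_sn <= 0)
        if not sn_ok:
            reasons.append(f"sn {m.sn:.3f} < {min_sn}" if not np.isnan(m.sn)
                           else f"sn undefined < {min_sn}")
        if reasons:
            removed.append((fid, "; ".join(reasons)))
        else:
            keep.append(fid)
    if not keep:
        warnings.warn("all features removed by peak filtering")
    report = QcReport(
        feature_metrics=metrics,
        retained=keep,
        removed=pd.DataFrame(removed, columns=["feature_id", "reason"]),
        thresholds={"max_missing": max_missing, "max_zero": max_zero,
                    "min_sn": min_sn},
    )
    return table.subset_features(keep), report


def sample_distance(table: FeatureTable, method: str = "pearson") -> pd.DataFrame:
    """Sample-by-sample distance matrix: 1 - correlation, pairwise-complete.

    ``method`` is pearson, spearman or kendall (tau-b, tie-corrected).
    The result is symmetric with a zero diagonal.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    if table.shape[1] < 3:
        raise ValueError("sample distances need at least three samples")
    corr = table.values.corr(method=method)  # pairwise-complete by pandas
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    return (dist + dist.T) / 2.0


def filter_samples(table: FeatureTable, method: str = "pearson",
                   cut: float = 0.5):
    """Remove outlier samples: average-linkage clustering of the correlation
    distance; samples in singleton clusters after cutting at height ``cut``
    are dropped. Returns (table, QcReport).
    """
    if cut <= 0:
        raise ValueError("cut must be positive")
    dist = sample_distance(table, method)
    condensed = squareform(np.clip(dist.values, 0.0, None), checks=False)
    link = _hier.linkage(condensed, method="average")
    labels = _hier.fcluster(link, t=cut, criterion="distance")
    counts = pd.Series(labels).value_counts()
    samples = list(dist.index)
    keep = [s for s, lab in zip(samples, labels) if counts[lab] > 1]
    removed = [(s, f"singleton cluster at height {cut}")
               for s, lab in zip(samples, labels) if counts[lab] == 1]
    if not keep:
        warnings.warn("all samples removed by sample filtering")
    report = QcReport(
        retained=keep,
        removed=pd.DataFrame(removed, columns=["sample_id", "reason"]),
        thresholds={"method": method, "cut": cut},
    )
    return table.subset_samples(keep), report
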