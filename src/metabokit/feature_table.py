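"""The feature-abundance matrix shared by preprocessing, QC and statistics.

``FeatureTable`` wraps a features x samples :class:`pandas.DataFrame` plus a
per-sample metadata frame (group label and numeric covariates). NA cells are
legal and every transform in the package preserves their positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]


@dataclass
class FeatureTable:
    values: pd.DataFrame                      # features x samples
    sample_meta: pd.DataFrame | None = None   # indexed by sample id

    def __post_init__(self):
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.sample_meta is not None:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples missing from metadata: {sorted(missing)}")
            self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, new_values: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(new_values, self.sample_meta)

    def subset_features(self, ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(ids)], self.sample_meta)

    def subset_samples(self, ids) -> "FeatureTable":
        ids = list(ids)
        meta = self.sample_meta.loc[ids] if self.sample_meta is not None else None
        return FeatureTable(self.values[ids], meta)

    # ---- I/O: TSV with features in rows, first column feature id ----

    @classmethod
    def read_tsv(cls, path, meta_path=None, sep: str = "\t") -> "FeatureTable":
        values = pd.read_csv(path, sep=sep, index_col=0)
        meta = pd.read_csv(meta_path, sep=sep, index_col=0) if meta_path else None
        return cls(values, meta)

    def write_tsv(self, path, sep: str = "\t") -> None:
        self.values.to_csv(path, sep=sep, na_rep="NA")

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.values.equals(other.values)
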