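"""Core expression-study container.

An :class:`ExpressionStudy` bundles one dataset's feature-by-sample matrix
with its per-sample annotations (disease group, dataset id, compartment).
All pipeline stages consume and return this container, so cross-dataset
operations can rely on a shared feature namespace and labelled groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical progression order of the disease groups.
STAGE_ORDER = ("HC", "CP", "PDAC", "MPDAC")


@dataclass
class ExpressionStudy:
    """One dataset: a features x samples matrix plus sample annotations.

    Parameters
    ----------
    values
        DataFrame with feature ids as the index and sample ids as columns.
    annotations
        DataFrame indexed by sample id with at least a ``group`` column;
        ``dataset_id`` and ``compartment`` columns are carried if present.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    dataset_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if "group" not in self.annotations.columns:
            raise ValueError("annotations must have a 'group' column")
        missing = [s for s in self.values.columns if s not in self.annotations.index]
        if missing:
            raise ValueError(f"samples without annotation: {missing[:5]}")
        self.values.index.name = "feature"
        # align annotation rows to matrix column order
        self.annotations = self.annotations.loc[self.values.columns]
        if self.annotations["group"].isna().any():
            raise ValueError("every sample needs a group label")
        if not self.dataset_id and "dataset_id" in self.annotations.columns:
            ids = self.annotations["dataset_id"].unique()
            if len(ids) == 1:
                self.dataset_id = str(ids[0])

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series:
        return self.annotations["group"]

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.annotations["group"] == group
        return list(self.annotations.index[mask])

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "ExpressionStudy":
        sample_ids = list(sample_ids)
        return ExpressionStudy(
            values=self.values[sample_ids].copy(),
            annotations=self.annotations.loc[sample_ids].copy(),
            dataset_id=self.dataset_id,
        )

    def group_means(self, groups=None) -> pd.DataFrame:
        """Per-feature mean expression of each group (features x groups)."""
        if groups is None:
            groups = [g for g in STAGE_ORDER if g in set(self.groups)]
        out = {}
        for g in groups:
            cols = self.samples_in_group(g)
            if not cols:
                raise ValueError(f"group {g!r} absent from study")
            out[g] = self.values[cols].mean(axis=1)
        return pd.DataFrame(out)
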