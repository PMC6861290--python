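"""Core in-memory containers for amplicon community analysis.

Everything downstream operates on four light wrappers around pandas
DataFrames: a feature-by-sample count table, a seven-rank taxonomy table,
per-SV attributes (length, negative-control flag), and sample metadata
(variety, cropping strategy, derived treatment group, sample type).
Distance matrices get their own symmetric container with a metric label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The seven taxonomic ranks, coarsest to finest.
RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")

#: Treatment groups of the mixed-cropping design, in plot order.
GROUPS = ("mono_A", "mixed_A", "mixed_W", "mono_W")


@dataclass
class CountTable:
    """Nonnegative integer feature x sample count matrix.

    Parameters
    ----------
    data
        DataFrame with features as the index and samples as columns.
    axis_rank
        What one row represents: ``"SV"``, ``"genus"``, ``"family"`` ...
    """

    data: pd.DataFrame
    axis_rank: str = "SV"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids in count table")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        values = self.data.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("negative counts in count table")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def feature_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def select_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[:, list(sample_ids)].copy(), self.axis_rank)

    def copy(self) -> "CountTable":
        return CountTable(self.data.copy(), self.axis_rank)


@dataclass
class TaxonomyTable:
    """Per-feature rank assignments; entries may be missing (NaN) before
    fill-down."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValueError(f"taxonomy table missing rank columns: {missing}")
        self.data = self.data.loc[:, list(RANKS)]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def copy(self) -> "TaxonomyTable":
        return TaxonomyTable(self.data.copy())


@dataclass
class SVAttributes:
    """Per-SV sequence length (bp) and negative-control flag."""

    data: pd.DataFrame  # columns: length, is_control

    def __post_init__(self) -> None:
        for col in ("length", "is_control"):
            if col not in self.data.columns:
                raise ValueError(f"SV attributes missing column {col!r}")
        if (self.data["length"] < 1).any():
            raise ValueError("SV lengths must be >= 1 bp")


def derive_group(variety: str, cropping: str) -> str:
    """Treatment group label from variety ('A'/'W') and cropping
    ('mono'/'mixed')."""
    if variety not in ("A", "W"):
        raise ValueError(f"unknown variety {variety!r}")
    if cropping not in ("mono", "mixed"):
        raise ValueError(f"unknown cropping {cropping!r}")
    return f"{cropping}_{variety}"


@dataclass
class SampleMetadata:
    """Per-sample design variables: variety, cropping, derived treatment
    group, sample type (root or soil)."""

    data: pd.DataFrame  # columns: variety, cropping, group, sample_type

    def __post_init__(self) -> None:
        for col in ("variety", "cropping", "group", "sample_type"):
            if col not in self.data.columns:
                raise ValueError(f"metadata missing column {col!r}")
        root = self.data[self.data["sample_type"] == "root"]
        for sid, row in root.iterrows():
            expected = derive_group(row["variety"], row["cropping"])
            if row["group"] != expected:
                raise ValueError(
                    f"sample {sid}: group {row['group']!r} inconsistent with "
                    f"variety/cropping (expected {expected!r})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def samples_in_group(self, group: str, sample_type: str = "root") -> list[str]:
        mask = (self.data["group"] == group) & (self.data["sample_type"] == sample_type)
        return list(self.data.index[mask])

    def root_groups(self) -> dict[str, list[str]]:
        """Mapping group -> root sample ids, in design order."""
        present = [g for g in GROUPS if g in set(self.data["group"])]
        extra = [g for g in dict.fromkeys(self.data["group"]) if g not in present and g != "soil"]
        out = {}
        for g in present + extra:
            ids = self.samples_in_group(g)
            if ids:
                out[g] = ids
        return out


class DistanceMatrix:
    """Symmetric, hollow, nonnegative sample x sample distance matrix.

    Thin container so results carry their metric label through the
    pipeline; scikit-bio interop is provided for the permutation tests'
    cross-checks.
    """

    def __init__(self, values, ids, metric: str = ""):
        values = np.asarray(values, dtype=float)
        ids = list(ids)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(ids) != values.shape[0]:
            raise ValueError("id count does not match matrix size")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-10):
            raise ValueError("distance matrix must be hollow (zero diagonal)")
        if (values < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        np.clip(values, 0.0, None, out=values)
        self.values = values
        self.ids = ids
        self.metric = metric

    @property
    def shape(self):
        return self.values.shape

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) distances as a flat vector."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def filter(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        sub = self.values[np.ix_(idx, idx)]
        return DistanceMatrix(sub, ids, self.metric)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)
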