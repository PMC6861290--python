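"""Feature-table preprocessing: quality filters, taxonomy fill-down,
agglomeration, rarefaction, relative-abundance profiles, cross-kingdom merge.

These are the standard steps between a denoised SV table and the community
analyses: remove off-target-length and control-derived SVs and those with
fewer than 100 reads in total, propagate the deepest taxonomic assignment
down to species level so agglomeration never drops unidentified features,
sum counts to a chosen rank, rarefy samples to a common depth without
replacement, and concatenate the two kingdoms' genus tables for the
cross-kingdom co-occurrence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import RANKS, CountTable, SampleMetadata, SVAttributes, TaxonomyTable


@dataclass
class FilterReport:
    """How many features each filter rule removed, in application order."""

    n_input: int
    removed_by_length: int = 0
    removed_by_control: int = 0
    removed_by_min_reads: int = 0
    n_retained: int = 0
    rules: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_input": [self.n_input],
                "removed_by_length": [self.removed_by_length],
                "removed_by_control": [self.removed_by_control],
                "removed_by_min_reads": [self.removed_by_min_reads],
                "n_retained": [self.n_retained],
                "rules": ["; ".join(self.rules)],
            }
        )


def filter_features(
    table: CountTable,
    attrs: SVAttributes | None = None,
    length_window: tuple[int, int] | None = None,
    drop_control: bool = False,
    min_total_reads: int = 0,
    control_first: bool = True,
) -> tuple[CountTable, FilterReport]:
    """Apply the SV quality filters; features surviving all requested rules
    are retained in their original order.

    ``length_window`` is inclusive on both ends; ``min_total_reads`` keeps
    features whose total across samples is at least the threshold (a
    "fewer than N reads" rule removes totals strictly below N). The order
    of control removal versus the read filter is configurable and recorded
    in the report.
    """
    report = FilterReport(n_input=len(table.feature_ids))
    keep = pd.Series(True, index=table.data.index)

    needs_attrs = length_window is not None or drop_control
    if needs_attrs:
        if attrs is None:
            raise ValueError("length/control filters requested but no SV attributes given")
        missing = [f for f in table.feature_ids if f not in attrs.data.index]
        if missing:
            raise ValueError(f"SV attributes missing for features: {missing[:5]}")

    def apply_length():
        if length_window is None:
            return
        lo, hi = length_window
        lengths = attrs.data.loc[table.data.index, "length"]
        bad = (lengths < lo) | (lengths > hi)
        report.removed_by_length = int((bad & keep).sum())
        keep[bad] = False
        report.rules.append(f"length in [{lo}, {hi}]")

    def apply_control():
        if not drop_control:
            return
        flags = attrs.data.loc[table.data.index, "is_control"].astype(bool)
        report.removed_by_control = int((flags & keep).sum())
        keep[flags] = False
        report.rules.append("drop negative-control SVs")

    def apply_min_reads():
        if min_total_reads <= 0:
            return
        totals = table.feature_totals()
        bad = totals < min_total_reads
        report.removed_by_min_reads = int((bad & keep).sum())
        keep[bad] = False
        report.rules.append(f"total reads >= {min_total_reads}")

    apply_length()
    if control_first:
        apply_control()
        apply_min_reads()
    else:
        apply_min_reads()
        apply_control()

    out = CountTable(table.data.loc[keep].copy(), table.axis_rank)
    report.n_retained = len(out.feature_ids)
    return out, report


def fill_taxonomy(tax: TaxonomyTable) -> TaxonomyTable:
    """Propagate the deepest assigned rank downward.

    A feature assigned only to family "Prevotellaceae" gets genus and
    species "Family_Prevotellaceae"; filled entries carry the rank prefix
    so they remain distinguishable from true assignments. Idempotent:
    already-filled markers are left untouched.
    """
    df = tax.data.astype(object).copy()

    def is_missing(value) -> bool:
        return pd.isna(value) or str(value).strip() == ""

    for fid, row in df.iterrows():
        deepest = None
        for rank in RANKS:
            value = row[rank]
            if not is_missing(value):
                deepest = (rank, str(value))
        if deepest is None:
            raise ValueError(f"feature {fid!r} has no taxonomic assignment at any rank")
        filling = False
        marker = None
        for rank in RANKS:
            if is_missing(row[rank]):
                if not filling:
                    filling = True
                df.loc[fid, rank] = marker
            else:
                # Remember the last real assignment; markers propagate it.
                value = str(row[rank])
                if "_" in value and value.split("_", 1)[0] in RANKS:
                    marker = value  # already a fill-down marker
                else:
                    marker = f"{rank}_{value}"
                filling = False
        # Holes above the deepest assignment are filled from the rank above.
    # Second pass: any remaining missing (only possible if kingdom missing)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"feature {bad!r} could not be fully annotated")
    return TaxonomyTable(df)


def agglomerate(table: CountTable, tax: TaxonomyTable, rank: str) -> CountTable:
    """Sum counts of features sharing a name at ``rank``.

    Assumes taxonomy fill-down has run, so no feature is dropped for a
    missing rank. Per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = [f for f in table.feature_ids if f not in tax.data.index]
    if missing:
        raise ValueError(f"taxonomy missing for features: {missing[:5]}")
    names = tax.data.loc[table.data.index, rank]
    if names.isna().any():
        bad = list(names.index[names.isna()])[:5]
        raise ValueError(f"missing {rank} assignment (run fill_taxonomy first): {bad}")
    grouped = table.data.groupby(names, sort=False).sum()
    grouped.index.name = None
    return CountTable(grouped, axis_rank=rank.lower())


@dataclass
class RarefactionReport:
    depth: int
    dropped_samples: list[str]
    dropped_features: list[str]


def rarefy(
    table: CountTable,
    depth: int,
    seed: int | np.random.SeedSequence = 0,
    drop_empty_features: bool = False,
) -> tuple[CountTable, RarefactionReport]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (recorded in
    the report). Features that become all-zero are retained by default so
    feature axes stay comparable across iterations; set
    ``drop_empty_features`` to remove them.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    keep_samples = list(totals.index[totals >= depth])
    dropped = [s for s in table.sample_ids if s not in keep_samples]
    if not keep_samples:
        raise ValueError(f"rarefaction depth {depth} exceeds every sample's total")

    rng = np.random.default_rng(seed)
    out = np.empty((len(table.feature_ids), len(keep_samples)), dtype=np.int64)
    for j, sid in enumerate(keep_samples):
        col = table.data[sid].to_numpy()
        total = int(col.sum())
        if total == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.feature_ids, columns=keep_samples)
    dropped_features: list[str] = []
    if drop_empty_features:
        empty = df.sum(axis=1) == 0
        dropped_features = list(df.index[empty])
        df = df.loc[~empty]
    return (
        CountTable(df, table.axis_rank),
        RarefactionReport(depth=depth, dropped_samples=dropped, dropped_features=dropped_features),
    )


def merge_kingdoms(
    bacteria: CountTable, fungi: CountTable
) -> tuple[CountTable, dict[str, str]]:
    """Concatenate two kingdoms' tables row-wise with kingdom-prefixed
    feature ids; returns the merged table and a feature -> kingdom map."""
    if bacteria.axis_rank != fungi.axis_rank:
        raise ValueError(
            f"tables at different ranks: {bacteria.axis_rank!r} vs {fungi.axis_rank!r}"
        )
    set_b, set_f = set(bacteria.sample_ids), set(fungi.sample_ids)
    if set_b != set_f:
        only_b = sorted(set_b - set_f)
        only_f = sorted(set_f - set_b)
        raise ValueError(
            f"sample sets differ; only in bacteria: {only_b}, only in fungi: {only_f}"
        )
    samples = sorted(set_b)
    b = bacteria.data.loc[:, samples]
    f = fungi.data.loc[:, samples]
    b = b.rename(index={i: f"Bacteria|{i}" for i in b.index})
    f = f.rename(index={i: f"Fungi|{i}" for i in f.index})
    merged = pd.concat([b, f], axis=0)
    kingdom_map = {i: "bacteria" for i in b.index} | {i: "fungi" for i in f.index}
    return CountTable(merged, bacteria.axis_rank), kingdom_map


def split_kingdoms(
    merged: CountTable, kingdom_map: dict[str, str]
) -> tuple[CountTable, CountTable]:
    """Inverse of :func:`merge_kingdoms` (original ids restored)."""
    parts = {}
    for kingdom in ("bacteria", "fungi"):
        ids = [f for f in merged.feature_ids if kingdom_map[f] == kingdom]
        df = merged.data.loc[ids]
        df = df.rename(index={i: i.split("|", 1)[1] for i in ids})
        parts[kingdom] = CountTable(df, merged.axis_rank)
    return parts["bacteria"], parts["fungi"]


def taxon_profiles(
    table: CountTable,
    tax: TaxonomyTable,
    meta: SampleMetadata,
    rank: str,
    top_n: int | None = None,
    min_combined_relabund: float | None = None,
) -> pd.DataFrame:
    """Group-mean relative abundances at a rank, ranked by overall mean.

    Each sample is first converted to relative abundances (summing to 1),
    aggregated to ``rank``, then averaged within treatment groups. Taxa are
    sorted by descending overall mean; optionally truncated to the top
    ``top_n`` and/or filtered to taxa whose combined (summed across groups)
    relative abundance exceeds ``min_combined_relabund``.
    """
    unknown = [s for s in table.sample_ids if s not in meta.data.index]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown[:5]}")
    at_rank = agglomerate(table, tax, rank)
    rel = at_rank.data / at_rank.data.sum(axis=0)
    groups = meta.data.loc[at_rank.sample_ids, "group"]
    profile = rel.T.groupby(groups).mean().T  # taxa x groups
    order = profile.mean(axis=1).sort_values(ascending=False).index
    profile = profile.loc[order]
    if min_combined_relabund is not None:
        profile = profile[profile.sum(axis=1) > min_combined_relabund]
    if top_n is not None:
        profile = profile.iloc[:top_n]
    return profile
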