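"""Synthetic paired bacterial/fungal community generator.

Emulates a mixed-cropping glasshouse experiment with two crop varieties
(A = Ambassador-like, W = Winfreda-like) grown as mono- or mixed-crops,
yielding four root treatment groups. The generative model is a standard
compositional surrogate:

1. Per-genus baseline log-abundance ``mu0 ~ Normal(m, s^2)`` and per-variety
   offsets ``delta_A, delta_W ~ Normal(0, sigma_v^2)``.
2. Group centroids in latent (log) space: a mono-crop of variety V sits at
   ``mu0 + delta_V``; under mixed-cropping a kingdom-specific mixing
   coefficient ``lambda`` blends in the other variety's centroid,
   ``(1 - lambda) * (mu0 + delta_V) + lambda * (mu0 + delta_other)``.
   Making ``lambda`` asymmetric between kingdoms reproduces the observed
   pattern where one variety's bacteria shift under mixed-cropping while
   its fungi stay put, and vice versa.
3. Per sample, the latent vector is the group centroid plus correlated
   Gaussian noise. The noise correlation matrix embeds "planted" blocks of
   co-occurring genera (possibly spanning kingdoms, active only in chosen
   groups); bacterial and fungal latents are drawn jointly and split so
   cross-kingdom structure survives.
4. Per kingdom, counts are ``Multinomial(softmax(latent), depth)`` with the
   sequencing depth drawn uniformly from a per-kingdom range.

The same scenario and seed give bit-identical tables. A separate expansion
step splits genus counts across sequence variants (SVs) and attaches
lengths and negative-control flags, producing fixtures for the SV-level
quality filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GROUPS, RANKS, CountTable, SampleMetadata, SVAttributes, TaxonomyTable

__all__ = [
    "PlantedBlock",
    "SVExpansion",
    "SyntheticScenario",
    "PlantedTruth",
    "simulate_experiment",
    "expand_to_sv_level",
]


class ScenarioError(ValueError):
    """Raised when a scenario violates its invariants."""


@dataclass(frozen=True)
class PlantedBlock:
    """A set of genera given latent pairwise correlation ``r`` in the noise,
    active only in the listed treatment groups."""

    members: tuple[str, ...]
    r: float
    groups: tuple[str, ...]


@dataclass(frozen=True)
class SVExpansion:
    """How genus counts are split into sequence variants.

    ``mean_svs_per_genus`` is the mean of ``1 + Poisson(mean - 1)``;
    lengths are drawn around ``length_mode`` (clipped to
    [length_min, length_max]) except for a fraction of outliers beyond the
    window; ``n_contaminants`` extra SVs are flagged as negative-control
    derived; ``rare_sv_fraction`` of SVs are thinned below 100 total reads.
    """

    mean_svs_per_genus: float = 3.0
    length_mode: int = 253
    length_sd: float = 3.0
    length_min: int = 240
    length_max: int = 260
    length_outlier_fraction: float = 0.005
    outlier_length_range: tuple[int, int] = (261, 434)
    n_contaminants: int = 2
    rare_sv_fraction: float = 0.05


# Depth ranges reflect typical per-sample read totals for 16S vs ITS runs
# (tens of thousands vs thousands of reads).
_DEFAULT_DEPTHS = {"bacteria": (14020, 95216), "fungi": (2653, 13954)}

# Default kingdom-asymmetric mixing: variety A's bacteria shift strongly
# toward W while W's barely move; the fungal pattern is mirrored.
_DEFAULT_LAMBDA = {
    "bacteria": {"A": 0.6, "W": 0.05},
    "fungi": {"A": 0.05, "W": 0.6},
}


def _default_group_sizes() -> dict[str, int]:
    # 8 mono pots x 2 plants, 11 mixed pots x 1 plant per variety.
    return {"mono_A": 16, "mixed_A": 11, "mixed_W": 11, "mono_W": 16}


@dataclass
class SyntheticScenario:
    """Full parameterization of the generative model."""

    n_samples_per_group: dict[str, int] = field(default_factory=_default_group_sizes)
    n_genera: dict[str, int] = field(default_factory=lambda: {"bacteria": 120, "fungi": 30})
    base_log_abundance: tuple[float, float] = (0.0, 1.0)  # mean m, spread s
    variety_effect_sd: float = 0.6
    noise_sd: float = 1.0
    mixing_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_LAMBDA.items()}
    )
    planted_blocks: list[PlantedBlock] = field(default_factory=list)
    depth_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_DEPTHS)
    )
    missing_taxonomy_fraction: float = 0.2
    n_soil_samples: int = 0
    sv_expansion: SVExpansion = field(default_factory=SVExpansion)
    pd_repair_tolerance: float = 0.1
    seed: int = 0

    def feature_ids(self, kingdom: str) -> list[str]:
        prefix = {"bacteria": "b", "fungi": "f"}[kingdom]
        return [f"{prefix}Genus{i + 1:03d}" for i in range(self.n_genera[kingdom])]

    def all_feature_ids(self) -> list[str]:
        return self.feature_ids("bacteria") + self.feature_ids("fungi")

    def validate(self) -> None:
        for kingdom, lam in self.mixing_coefficients.items():
            for variety, value in lam.items():
                if not 0.0 <= value <= 1.0:
                    raise ScenarioError(
                        f"mixing coefficient lambda[{kingdom}][{variety}] = {value} "
                        "outside [0, 1]"
                    )
        known = set(self.all_feature_ids())
        for block in self.planted_blocks:
            unknown = [m for m in block.members if m not in known]
            if unknown:
                raise ScenarioError(f"planted block references unknown features: {unknown}")
            if not -1.0 < block.r < 1.0:
                raise ScenarioError(f"planted correlation {block.r} outside (-1, 1)")
            if len(block.members) < 2:
                raise ScenarioError("planted block needs at least 2 members")
            bad_groups = [g for g in block.groups if g not in GROUPS]
            if bad_groups:
                raise ScenarioError(f"planted block names unknown groups: {bad_groups}")
        for kingdom, (lo, hi) in self.depth_range.items():
            if lo < 1 or hi < lo:
                raise ScenarioError(f"invalid depth range for {kingdom}: ({lo}, {hi})")
        for group, n in self.n_samples_per_group.items():
            if n < 3:
                raise ScenarioError(f"group {group} has {n} samples; need >= 3")
        if self.sv_expansion.mean_svs_per_genus < 1:
            raise ScenarioError("mean SVs per genus must be >= 1")


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: planted pairs, latent group centroids,
    and any positive-definiteness repairs applied to the noise correlation."""

    correlated_pairs: list[tuple[str, str, int, frozenset]]
    group_centroids: dict[str, dict[str, np.ndarray]]  # group -> kingdom -> latent
    pd_repairs: list[str] = field(default_factory=list)

    def pairs_in_group(self, group: str) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _sign, groups in self.correlated_pairs if group in groups}


def _nearest_correlation(matrix: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped nearest correlation matrix (unit diagonal)."""
    eigval, eigvec = np.linalg.eigh(matrix)
    if eigval.min() >= min_eig:
        return matrix
    eigval = np.clip(eigval, min_eig, None)
    repaired = (eigvec * eigval) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def _group_correlation(
    scenario: SyntheticScenario, group: str, feature_index: dict[str, int]
) -> tuple[np.ndarray, bool]:
    g = len(feature_index)
    corr = np.eye(g)
    active = [b for b in scenario.planted_blocks if group in b.groups]
    for block in active:
        idx = [feature_index[m] for m in block.members]
        for i in idx:
            for j in idx:
                if i != j:
                    corr[i, j] = block.r
    repaired = _nearest_correlation(corr)
    changed = not np.array_equal(repaired, corr)
    if changed:
        drift = np.abs(repaired - corr).max()
        if drift > scenario.pd_repair_tolerance:
            names = ", ".join("{" + ",".join(b.members) + "}" for b in active)
            raise ScenarioError(
                f"noise correlation for group {group!r} is not positive definite "
                f"within repair tolerance (max entry change {drift:.3f}); "
                f"offending planted blocks: {names}"
            )
    return repaired, changed


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def _planted_pairs(scenario: SyntheticScenario) -> list[tuple[str, str, int, frozenset]]:
    pairs: dict[tuple[str, str], tuple[int, set]] = {}
    for block in scenario.planted_blocks:
        sign = 1 if block.r > 0 else -1
        members = sorted(block.members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                key = (a, b)
                if key in pairs:
                    old_sign, groups = pairs[key]
                    if old_sign != sign:
                        raise ScenarioError(
                            f"pair ({a}, {b}) planted with conflicting signs"
                        )
                    groups.update(block.groups)
                else:
                    pairs[key] = (sign, set(block.groups))
    return [(a, b, sign, frozenset(groups)) for (a, b), (sign, groups) in sorted(pairs.items())]


def _make_taxonomy(scenario: SyntheticScenario, rng: np.random.Generator) -> TaxonomyTable:
    """Plausible 7-rank lineages; a configurable fraction of genera lack
    genus/species names so the fill-down step has realistic work to do."""
    rows = {}
    lineage_pools = {"bacteria": 8, "fungi": 4}
    kingdom_names = {"bacteria": "Bacteria", "fungi": "Fungi"}
    for kingdom in ("bacteria", "fungi"):
        n_pool = lineage_pools[kingdom]
        prefix = kingdom_names[kingdom]
        for i, fid in enumerate(scenario.feature_ids(kingdom)):
            lineage = i % n_pool
            row = {
                "Kingdom": prefix,
                "Phylum": f"{prefix}Phylum{lineage + 1}",
                "Class": f"{prefix}Class{lineage + 1}",
                "Order": f"{prefix}Order{lineage + 1}",
                "Family": f"{prefix}Family{(i % (2 * n_pool)) + 1}",
                "Genus": fid,
                "Species": f"{fid}_sp",
            }
            u = rng.random()
            if u < scenario.missing_taxonomy_fraction / 2:
                row["Genus"] = np.nan
                row["Species"] = np.nan
            elif u < scenario.missing_taxonomy_fraction:
                row["Species"] = np.nan
            rows[fid] = row
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def simulate_experiment(
    scenario: SyntheticScenario,
) -> tuple[CountTable, CountTable, TaxonomyTable, SampleMetadata, PlantedTruth]:
    """Draw one full synthetic experiment.

    Returns genus-level bacterial and fungal count tables, a combined
    taxonomy table over both kingdoms, sample metadata, and the planted
    ground truth for recovery tests.
    """
    scenario.validate()
    root_ss, soil_ss = np.random.SeedSequence(scenario.seed).spawn(2)
    rng = np.random.default_rng(root_ss)

    g_b = scenario.n_genera["bacteria"]
    features = scenario.all_feature_ids()
    feature_index = {f: i for i, f in enumerate(features)}
    g_total = len(features)
    kingdom_slice = {"bacteria": slice(0, g_b), "fungi": slice(g_b, g_total)}

    m, s = scenario.base_log_abundance
    mu0 = rng.normal(m, s, g_total)
    delta = {"A": rng.normal(0.0, scenario.variety_effect_sd, g_total),
             "W": rng.normal(0.0, scenario.variety_effect_sd, g_total)}

    # Latent group centroids, blended per kingdom under mixed-cropping.
    centroids: dict[str, np.ndarray] = {}
    for group in GROUPS:
        cropping, variety = group.split("_")
        other = "W" if variety == "A" else "A"
        centroid = np.empty(g_total)
        for kingdom, sl in kingdom_slice.items():
            own = mu0[sl] + delta[variety][sl]
            if cropping == "mono":
                centroid[sl] = own
            else:
                lam = scenario.mixing_coefficients[kingdom][variety]
                centroid[sl] = (1.0 - lam) * own + lam * (mu0[sl] + delta[other][sl])
        centroids[group] = centroid

    repairs: list[str] = []
    cholesky: dict[str, np.ndarray] = {}
    for group in GROUPS:
        corr, changed = _group_correlation(scenario, group, feature_index)
        if changed:
            repairs.append(f"nearest-PD repair applied to noise correlation of {group}")
        cholesky[group] = np.linalg.cholesky(corr)

    counts = {k: {} for k in ("bacteria", "fungi")}
    meta_rows = {}
    for group in GROUPS:
        n = scenario.n_samples_per_group.get(group, 0)
        cropping, variety = group.split("_")
        chol = cholesky[group]
        for i in range(n):
            sid = f"{group}_{i + 1:02d}"
            latent = centroids[group] + scenario.noise_sd * (chol @ rng.standard_normal(g_total))
            for kingdom, sl in kingdom_slice.items():
                lo, hi = scenario.depth_range[kingdom]
                depth = int(rng.integers(lo, hi + 1))
                counts[kingdom][sid] = rng.multinomial(depth, _softmax(latent[sl]))
            meta_rows[sid] = {
                "variety": variety,
                "cropping": cropping,
                "group": group,
                "sample_type": "root",
            }

    # Soil samples come from the unshifted baseline and use a separate
    # random stream, so adding/removing them never perturbs root counts.
    if scenario.n_soil_samples:
        soil_rng = np.random.default_rng(soil_ss)
        for i in range(scenario.n_soil_samples):
            sid = f"soil_{i + 1:02d}"
            latent = mu0 + scenario.noise_sd * soil_rng.standard_normal(g_total)
            for kingdom, sl in kingdom_slice.items():
                lo, hi = scenario.depth_range[kingdom]
                depth = int(soil_rng.integers(lo, hi + 1))
                counts[kingdom][sid] = soil_rng.multinomial(depth, _softmax(latent[sl]))
            meta_rows[sid] = {
                "variety": "-",
                "cropping": "-",
                "group": "soil",
                "sample_type": "soil",
            }

    tables = {}
    for kingdom in ("bacteria", "fungi"):
        df = pd.DataFrame(counts[kingdom], index=scenario.feature_ids(kingdom))
        tables[kingdom] = CountTable(df.astype(np.int64), axis_rank="genus")

    taxonomy = _make_taxonomy(scenario, rng)
    metadata = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))
    truth = PlantedTruth(
        correlated_pairs=_planted_pairs(scenario),
        group_centroids={
            g: {k: centroids[g][sl].copy() for k, sl in kingdom_slice.items()}
            for g in GROUPS
        },
        pd_repairs=repairs,
    )
    return tables["bacteria"], tables["fungi"], taxonomy, metadata, truth


def expand_to_sv_level(
    genus_table: CountTable,
    scenario: SyntheticScenario,
    taxonomy: TaxonomyTable | None = None,
    seed: int | None = None,
) -> tuple[CountTable, SVAttributes, TaxonomyTable]:
    """Split genus-level counts into SV-level rows with lengths and flags.

    Each genus's counts are divided across ``1 + Poisson(mean - 1)`` SVs by a
    Dirichlet weight vector shared across samples; lengths cluster at the
    configured mode with a small outlier fraction outside the filter window;
    contaminant SVs (negative-control derived) are appended; and a
    configured fraction of SVs is thinned below 100 total reads.
    """
    scenario.validate()
    cfg = scenario.sv_expansion
    if seed is None:
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 17]))
    else:
        rng = np.random.default_rng(seed)

    sv_rows = []
    sv_ids = []
    parent_genus = []
    n_samples = len(genus_table.sample_ids)
    counter = 0
    for fid in genus_table.feature_ids:
        n_svs = 1 + int(rng.poisson(cfg.mean_svs_per_genus - 1.0))
        weights = rng.dirichlet(np.ones(n_svs)) if n_svs > 1 else np.ones(1)
        row = genus_table.data.loc[fid].to_numpy()
        split = np.zeros((n_svs, n_samples), dtype=np.int64)
        for j, total in enumerate(row):
            if total > 0:
                split[:, j] = rng.multinomial(int(total), weights)
        for k in range(n_svs):
            counter += 1
            sv_ids.append(f"SV{counter:05d}")
            parent_genus.append(fid)
            sv_rows.append(split[k])

    sv_counts = np.asarray(sv_rows, dtype=np.int64)
    n_svs_total = len(sv_ids)

    # Thin a fraction of SVs below the 100-read threshold (without
    # replacement across samples so column structure stays plausible).
    n_rare = int(round(cfg.rare_sv_fraction * n_svs_total))
    if n_rare:
        rare_idx = rng.choice(n_svs_total, size=n_rare, replace=False)
        for idx in rare_idx:
            total = int(sv_counts[idx].sum())
            if total >= 100:
                target = int(rng.integers(1, 100))
                sv_counts[idx] = rng.multivariate_hypergeometric(sv_counts[idx], target)

    lengths = np.clip(
        np.rint(rng.normal(cfg.length_mode, cfg.length_sd, n_svs_total)),
        cfg.length_min,
        cfg.length_max,
    ).astype(int)
    n_outliers = int(round(cfg.length_outlier_fraction * n_svs_total))
    if n_outliers:
        out_idx = rng.choice(n_svs_total, size=n_outliers, replace=False)
        lo, hi = cfg.outlier_length_range
        lengths[out_idx] = rng.integers(lo, hi + 1, size=n_outliers)
    is_control = np.zeros(n_svs_total, dtype=bool)

    # Contaminant SVs: low, diffuse counts flagged as control-derived.
    for c in range(cfg.n_contaminants):
        counter += 1
        sv_ids.append(f"SV{counter:05d}")
        parent_genus.append(None)
        contam = rng.poisson(30.0, n_samples)
        sv_counts = np.vstack([sv_counts, contam[None, :]])
        lengths = np.append(lengths, int(np.clip(
            round(rng.normal(cfg.length_mode, cfg.length_sd)), cfg.length_min, cfg.length_max
        )))
        is_control = np.append(is_control, True)

    sv_table = CountTable(
        pd.DataFrame(sv_counts, index=sv_ids, columns=genus_table.sample_ids),
        axis_rank="SV",
    )
    attrs = SVAttributes(
        pd.DataFrame({"length": lengths, "is_control": is_control}, index=sv_ids)
    )

    tax_rows = {}
    for sid, parent in zip(sv_ids, parent_genus):
        if parent is not None and taxonomy is not None and parent in taxonomy.data.index:
            tax_rows[sid] = taxonomy.data.loc[parent].to_dict()
        elif parent is not None:
            tax_rows[sid] = {r: np.nan for r in RANKS} | {"Kingdom": "Unknown", "Genus": parent}
        else:
            tax_rows[sid] = {r: np.nan for r in RANKS} | {"Kingdom": "Contaminant"}
    sv_tax = TaxonomyTable(pd.DataFrame.from_dict(tax_rows, orient="index", columns=list(RANKS)))
    return sv_table, attrs, sv_tax
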