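"""Cross-kingdom Spearman co-occurrence analysis.

For each treatment group, a Spearman correlation matrix is computed over
all pairs of genera in the merged bacteria+fungi table (root samples of
that group only). Pairs are then counted in nested tiers — significant
(p < 0.05), moderate-or-stronger (|rho| > 0.5), strong (|rho| > 0.75) and
strong positive (rho > 0.75), with percentages relative to the significant
count — and the strong pairs form a co-occurrence network whose nodes are
genera labelled by kingdom.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .containers import CountTable

__all__ = [
    "CooccurrenceResult",
    "NetworkSummary",
    "spearman_cooccurrence",
    "tiered_interaction_counts",
    "build_network",
    "network_summary_stats",
    "summary_table",
]


@dataclass
class CooccurrenceResult:
    """Paired symmetric rho and p matrices over the group's features.

    Zero-variance features (rank correlation undefined) are excluded before
    pair enumeration; the exclusion count is recorded.
    """

    feature_ids: list[str]
    rho: np.ndarray
    p: np.ndarray
    n_samples: int
    group: str
    kingdom_map: dict[str, str]
    n_excluded_zero_variance: int = 0
    p_method: str = "t-approximation"

    def n_pairs(self) -> int:
        f = len(self.feature_ids)
        return f * (f - 1) // 2

    def iter_pairs(self):
        """Yield (i, j, feature_i, feature_j, rho, p) over unordered pairs."""
        ids = self.feature_ids
        for i, j in itertools.combinations(range(len(ids)), 2):
            yield i, j, ids[i], ids[j], self.rho[i, j], self.p[i, j]

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        for _i, _j, a, b, rho, p in self.iter_pairs():
            rows.append(
                {
                    "feature_a": a,
                    "feature_b": b,
                    "rho": rho,
                    "p": p,
                    "sign": int(np.sign(rho)),
                    "kingdom_a": self.kingdom_map.get(a, ""),
                    "kingdom_b": self.kingdom_map.get(b, ""),
                }
            )
        return pd.DataFrame(rows)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (tiny n only)."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    count = 0
    total = math.factorial(n)
    for perm in itertools.permutations(ry):
        if abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12:
            count += 1
    return count / total


def spearman_cooccurrence(
    table: CountTable,
    kingdom_map: dict[str, str],
    group_samples: list[str],
    group: str = "",
    exact_p: bool = False,
) -> CooccurrenceResult:
    """Spearman correlation matrix over feature pairs within one group.

    Rho uses average ranks for ties; p-values are two-sided via the
    t-approximation with df = n - 2. For n <= 9 an exact permutation p is
    available behind ``exact_p`` (n! enumeration per pair).
    """
    if len(group_samples) < 4:
        raise ValueError(f"group {group!r} has fewer than 4 samples")
    if not table.feature_ids:
        raise ValueError("empty count table")
    sub = table.select_samples(group_samples)
    values = sub.values.astype(float)
    n = values.shape[1]

    variances = values.var(axis=1)
    keep = variances > 0
    n_excluded = int((~keep).sum())
    values = values[keep]
    ids = [f for f, k in zip(sub.feature_ids, keep) if k]
    if len(ids) < 2:
        raise ValueError("fewer than 2 features with nonzero variance")

    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    rho = np.corrcoef(ranks)
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)

    if exact_p:
        if n > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        p = np.ones_like(rho)
        for i, j in itertools.combinations(range(len(ids)), 2):
            p[i, j] = p[j, i] = _spearman_exact_p(values[i], values[j])
        method = "exact-permutation"
    else:
        # t-approximation, df = n - 2, two-sided.
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho ** 2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        np.fill_diagonal(p, 1.0)
        method = "t-approximation"

    return CooccurrenceResult(
        feature_ids=ids,
        rho=rho,
        p=p,
        n_samples=n,
        group=group,
        kingdom_map=dict(kingdom_map),
        n_excluded_zero_variance=n_excluded,
        p_method=method,
    )


@dataclass
class NetworkSummary:
    """Tiered interaction counts for one treatment group (one table row).

    The tiers are nested subsets of the significant pairs, so
    ``n_strong_positive <= n_strong <= n_moderate_or_stronger <=
    n_significant`` always holds. Percentages are fractions of the
    significant count, rounded to the nearest integer (None when nothing
    is significant).
    """

    group: str
    n_significant: int
    n_moderate_or_stronger: int
    n_strong: int
    n_strong_positive: int
    pct_moderate_or_stronger: int | None
    pct_strong: int | None
    pct_strong_positive: int | None
    alpha: float = 0.05
    moderate_threshold: float = 0.5
    strong_threshold: float = 0.75

    def row(self) -> dict[str, str]:
        def cell(count, pct):
            return f"{count} ({pct}%)" if pct is not None else f"{count}"

        return {
            "Treatment": self.group,
            "Significant": str(self.n_significant),
            f"|rho|>{self.moderate_threshold}": cell(
                self.n_moderate_or_stronger, self.pct_moderate_or_stronger
            ),
            f"|rho|>{self.strong_threshold}": cell(self.n_strong, self.pct_strong),
            f"rho>{self.strong_threshold}": cell(
                self.n_strong_positive, self.pct_strong_positive
            ),
        }


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (optional; raw p is the default
    filter)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def _pct(count: int, denom: int) -> int | None:
    if denom == 0:
        return None
    # Round-half-up so e.g. 4.5% renders as 5%.
    return int(math.floor(100.0 * count / denom + 0.5))


def tiered_counts_from_arrays(
    rho_flat: np.ndarray,
    p_flat: np.ndarray,
    group: str = "",
    alpha: float = 0.05,
    moderate_threshold: float = 0.5,
    strong_threshold: float = 0.75,
) -> NetworkSummary:
    """Tier counting on flat vectors of per-pair rho and p (the formatter
    behind the per-group summary table)."""
    if not 0 < moderate_threshold < strong_threshold < 1:
        raise ValueError("need 0 < moderate < strong < 1")
    sig = p_flat < alpha
    n_sig = int(sig.sum())
    moderate = sig & (np.abs(rho_flat) > moderate_threshold)
    strong = sig & (np.abs(rho_flat) > strong_threshold)
    strong_pos = sig & (rho_flat > strong_threshold)
    return NetworkSummary(
        group=group,
        n_significant=n_sig,
        n_moderate_or_stronger=int(moderate.sum()),
        n_strong=int(strong.sum()),
        n_strong_positive=int(strong_pos.sum()),
        pct_moderate_or_stronger=_pct(int(moderate.sum()), n_sig),
        pct_strong=_pct(int(strong.sum()), n_sig),
        pct_strong_positive=_pct(int(strong_pos.sum()), n_sig),
        alpha=alpha,
        moderate_threshold=moderate_threshold,
        strong_threshold=strong_threshold,
    )


def summary_from_counts(
    group: str,
    n_significant: int,
    n_moderate_or_stronger: int,
    n_strong: int,
    n_strong_positive: int,
    alpha: float = 0.05,
    moderate_threshold: float = 0.5,
    strong_threshold: float = 0.75,
) -> NetworkSummary:
    """Build a summary row (with computed percentages) directly from tier
    counts, e.g. when re-formatting published interaction tables."""
    if not n_strong_positive <= n_strong <= n_moderate_or_stronger <= n_significant:
        raise ValueError("tier counts must be nested")
    return NetworkSummary(
        group=group,
        n_significant=n_significant,
        n_moderate_or_stronger=n_moderate_or_stronger,
        n_strong=n_strong,
        n_strong_positive=n_strong_positive,
        pct_moderate_or_stronger=_pct(n_moderate_or_stronger, n_significant),
        pct_strong=_pct(n_strong, n_significant),
        pct_strong_positive=_pct(n_strong_positive, n_significant),
        alpha=alpha,
        moderate_threshold=moderate_threshold,
        strong_threshold=strong_threshold,
    )


def tiered_interaction_counts(
    result: CooccurrenceResult,
    alpha: float = 0.05,
    moderate_threshold: float = 0.5,
    strong_threshold: float = 0.75,
    adjust_benjamini_hochberg: bool = False,
) -> NetworkSummary:
    """Count pairs in the nested significance/strength tiers.

    The significance filter uses raw p-values by default; set
    ``adjust_benjamini_hochberg`` to apply the BH false-discovery-rate
    correction across all pairs first.
    """
    iu = np.triu_indices(len(result.feature_ids), k=1)
    p_flat = result.p[iu]
    if adjust_benjamini_hochberg:
        p_flat = benjamini_hochberg(p_flat)
    return tiered_counts_from_arrays(
        result.rho[iu],
        p_flat,
        group=result.group,
        alpha=alpha,
        moderate_threshold=moderate_threshold,
        strong_threshold=strong_threshold,
    )


def summary_table(summaries: list[NetworkSummary]) -> pd.DataFrame:
    """One row per treatment group, counts with bracketed percentages."""
    return pd.DataFrame([s.row() for s in summaries])


def build_network(
    result: CooccurrenceResult,
    alpha: float = 0.05,
    rho_threshold: float = 0.75,
) -> nx.Graph:
    """Graph of significant strong interactions.

    Edges are unordered pairs with ``p < alpha`` and ``|rho| > threshold``,
    carrying rho, p and sign; nodes are the incident features, labelled by
    kingdom.
    """
    if not 0 < rho_threshold < 1:
        raise ValueError("rho threshold must be in (0, 1)")
    g = nx.Graph(group=result.group, rho_threshold=rho_threshold, alpha=alpha)
    for _i, _j, a, b, rho, p in result.iter_pairs():
        if p < alpha and abs(rho) > rho_threshold:
            for node in (a, b):
                if node not in g:
                    g.add_node(node, kingdom=result.kingdom_map.get(node, ""))
            g.add_edge(a, b, rho=float(rho), p=float(p), sign=int(np.sign(rho)))
    return g


def network_summary_stats(net: nx.Graph) -> dict:
    """Edge/node counts, positive-edge proportion, within- vs cross-kingdom
    edge counts, and degree summary."""
    n_edges = net.number_of_edges()
    n_nodes = net.number_of_nodes()
    if n_edges == 0:
        return {
            "n_edges": 0,
            "n_nodes": n_nodes,
            "prop_positive": None,
            "n_bacteria_bacteria": 0,
            "n_fungi_fungi": 0,
            "n_cross_kingdom": 0,
            "max_degree": 0,
            "mean_degree": 0.0,
        }
    n_pos = sum(1 for _a, _b, d in net.edges(data=True) if d["sign"] > 0)
    kinds = {"bacteria|bacteria": 0, "fungi|fungi": 0, "cross": 0}
    for a, b in net.edges():
        ka, kb = net.nodes[a].get("kingdom", ""), net.nodes[b].get("kingdom", "")
        if ka == kb == "bacteria":
            kinds["bacteria|bacteria"] += 1
        elif ka == kb == "fungi":
            kinds["fungi|fungi"] += 1
        else:
            kinds["cross"] += 1
    degrees = [d for _n, d in net.degree()]
    return {
        "n_edges": n_edges,
        "n_nodes": n_nodes,
        "prop_positive": n_pos / n_edges,
        "n_bacteria_bacteria": kinds["bacteria|bacteria"],
        "n_fungi_fungi": kinds["fungi|fungi"],
        "n_cross_kingdom": kinds["cross"],
        "max_degree": max(degrees),
        "mean_degree": float(np.mean(degrees)),
    }
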