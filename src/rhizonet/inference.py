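"""Ordination and permutation inference implemented from first principles.

One-way PERMANOVA partitions squared inter-sample distances among groups
and assesses the pseudo-F by permuting group labels; the Mantel test
correlates the upper triangles of two distance matrices with a
simultaneous row/column permutation null; NMDS minimises Kruskal stress-1
with monotone (pool-adjacent-violators) regression over dissimilarity
ranks, taking the best of several restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .containers import DistanceMatrix

__all__ = ["PermanovaResult", "MantelResult", "Ordination", "permanova", "mantel", "nmds"]


@dataclass
class PermanovaResult:
    pseudo_F: float
    R_squared: float
    p_value: float
    df_between: int
    df_within: int
    SS_between: float
    SS_within: float
    SS_total: float
    n_permutations: int
    exhaustive: bool = False

    def summary(self) -> str:
        return (
            f"PERMANOVA: F_{self.df_between},{self.df_within} = {self.pseudo_F:.3f}, "
            f"R^2 = {self.R_squared:.3f}, p = {self.p_value:.4g} "
            f"({'exhaustive' if self.exhaustive else f'{self.n_permutations} permutations'})"
        )


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    correlation_method: str
    exhaustive: bool = False

    def summary(self) -> str:
        return f"Mantel: r = {self.r:.3f}, p = {self.p_value:.4g} ({self.correlation_method})"


@dataclass
class Ordination:
    coordinates: np.ndarray  # samples x k, centered
    stress: float
    sample_ids: list
    n_restarts: int
    converged: bool
    seed: int


def _ss_within(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    ss = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def _multiset_permutations(items: list):
    """Distinct permutations of a multiset (lexicographic)."""
    items = sorted(items)

    def rec(remaining):
        if not remaining:
            yield []
            return
        seen = set()
        for i, x in enumerate(remaining):
            if x in seen:
                continue
            seen.add(x)
            for rest in rec(remaining[:i] + remaining[i + 1:]):
                yield [x] + rest

    yield from rec(items)


def n_distinct_assignments(labels) -> int:
    """Number of distinct orderings of the label multiset."""
    labels = list(labels)
    total = math.factorial(len(labels))
    for g in set(labels):
        total //= math.factorial(labels.count(g))
    return total


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive_if_feasible: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson 2001).

    ``SS_total = (1/n) sum_{i<j} d_ij^2``; ``SS_within`` sums the analogous
    within-group terms; ``pseudo-F = [SS_between/(a-1)] / [SS_within/(n-a)]``.
    The p-value permutes group labels with the +1 correction, or enumerates
    all distinct label assignments when feasible and requested.
    """
    labels = np.asarray(list(groups))
    n = len(dm)
    if len(labels) != n:
        raise ValueError("group labels do not match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    a = len(uniq)
    d2 = dm.values ** 2
    ss_total = d2.sum() / (2.0 * n)
    if ss_total <= 0:
        raise ValueError("degenerate distance matrix: all distances are zero")
    ss_within = _ss_within(d2, labels, uniq)
    ss_between = ss_total - ss_within
    df_between, df_within = a - 1, n - a

    def pseudo_f(ssw: float) -> float:
        # ssw = 0 (perfect separation) legitimately gives an infinite F.
        if ssw <= 0:
            return np.inf
        return ((ss_total - ssw) / df_between) / (ssw / df_within)

    f_obs = pseudo_f(ss_within)

    n_assignments = n_distinct_assignments(labels)
    if exhaustive_if_feasible and n_assignments <= n_permutations:
        count_ge = 0
        for perm_labels in _multiset_permutations(list(labels)):
            f_perm = pseudo_f(_ss_within(d2, np.asarray(perm_labels), uniq))
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / n_assignments
        n_perm_used, exhaustive = n_assignments, True
    else:
        rng = np.random.default_rng(seed)
        count_ge = 0
        for _ in range(n_permutations):
            f_perm = pseudo_f(_ss_within(d2, rng.permutation(labels), uniq))
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = (count_ge + 1) / (n_permutations + 1)
        n_perm_used, exhaustive = n_permutations, False

    return PermanovaResult(
        pseudo_F=f_obs,
        R_squared=ss_between / ss_total,
        p_value=p,
        df_between=df_between,
        df_within=df_within,
        SS_between=ss_between,
        SS_within=ss_within,
        SS_total=ss_total,
        n_permutations=n_perm_used,
        exhaustive=exhaustive,
    )


def _vec_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance distance vector in Mantel test")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    correlation_method: str = "pearson",
    exhaustive_if_feasible: bool = False,
) -> MantelResult:
    """Mantel test of association between two distance matrices.

    ``r`` correlates the upper-triangle vectors; the null permutes the rows
    and columns of the second matrix simultaneously. One-sided p for
    positive association with the +1 correction (or exact enumeration of
    all n! relabelings when requested and feasible).
    """
    if dm1.ids != dm2.ids:
        if set(dm1.ids) == set(dm2.ids):
            dm2 = dm2.filter(dm1.ids)
        else:
            raise ValueError(
                f"sample sets differ: {sorted(set(dm1.ids) ^ set(dm2.ids))}"
            )
    n = len(dm1)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 samples")
    iu = np.triu_indices(n, k=1)
    v1 = dm1.values[iu]
    r_obs = _vec_corr(v1, dm2.values[iu], correlation_method)

    if exhaustive_if_feasible and math.factorial(n) <= n_permutations:
        import itertools

        count_ge = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            perm = np.asarray(perm)
            v2p = dm2.values[np.ix_(perm, perm)][iu]
            if _vec_corr(v1, v2p, correlation_method) >= r_obs - 1e-12:
                count_ge += 1
            total += 1
        return MantelResult(r_obs, count_ge / total, total, correlation_method, True)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        v2p = dm2.values[np.ix_(perm, perm)][iu]
        if _vec_corr(v1, v2p, correlation_method) >= r_obs - 1e-12:
            count_ge += 1
    p = (count_ge + 1) / (n_permutations + 1)
    return MantelResult(r_obs, p, n_permutations, correlation_method, False)


def _classical_mds(dm_values: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling used as one NMDS initialization."""
    n = dm_values.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm_values ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:k]
    vals = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(vals)


def _stress_and_disparities(d_config: np.ndarray, order: np.ndarray) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and PAV disparities for one configuration."""
    dhat = np.empty_like(d_config)
    dhat[order] = isotonic_regression(d_config[order]).x
    denom = (d_config ** 2).sum()
    if denom <= 0:
        return np.inf, dhat
    stress = np.sqrt(((d_config - dhat) ** 2).sum() / denom)
    return stress, dhat


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> Ordination:
    """Nonmetric multidimensional scaling minimising Kruskal stress-1.

    Iterates monotone regression (pool-adjacent-violators over the rank
    order of the input dissimilarities) with Guttman-transform updates;
    runs one classical-MDS initialization plus ``n_restarts`` random
    starts and returns the best, with coordinates centered at the origin.
    """
    n = len(dm)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError("need more samples than ordination dimensions")
    d = dm.condensed()
    order = np.argsort(d, kind="stable")
    iu = np.triu_indices(n, k=1)
    rng = np.random.default_rng(seed)

    inits = [_classical_mds(dm.values, k)]
    inits += [rng.standard_normal((n, k)) for _ in range(n_restarts)]

    best = None
    any_converged = False
    for x in inits:
        x = x - x.mean(axis=0)
        stress_prev = np.inf
        converged = False
        for _ in range(max_iter):
            d_config = pdist(x)
            stress, dhat = _stress_and_disparities(d_config, order)
            if abs(stress_prev - stress) < tol:
                converged = True
                break
            stress_prev = stress
            # Guttman transform with unit weights.
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d_config > 0, dhat / d_config, 0.0)
            b = np.zeros((n, n))
            b[iu] = -ratio
            b += b.T
            np.fill_diagonal(b, -b.sum(axis=1))
            x = (b @ x) / n
            x = x - x.mean(axis=0)
        d_config = pdist(x)
        stress, _ = _stress_and_disparities(d_config, order)
        if best is None or stress < best[0]:
            best = (stress, x.copy())
        any_converged = any_converged or converged

    stress, coords = best
    return Ordination(
        coordinates=coords - coords.mean(axis=0),
        stress=float(stress),
        sample_ids=list(dm.ids),
        n_restarts=n_restarts,
        converged=any_converged,
        seed=seed,
    )
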