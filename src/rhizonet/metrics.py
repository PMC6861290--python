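"""Diversity and community-distance computations.

Alpha diversity is iterative rarefied richness: each sample is repeatedly
subsampled (without replacement) to the depth of the shallowest sample and
the nonzero features counted, averaging over trials. Beta diversity covers
Bray-Curtis, binary and quantitative Jaccard, and Jensen-Shannon
divergence (natural log, so bounded by ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import CountTable, DistanceMatrix
from .feature_table import rarefy

METRICS = ("bray_curtis", "jaccard_binary", "jaccard_quant", "jsd")


@dataclass
class RichnessEstimate:
    """Per-sample mean and SD of rarefied richness across trials."""

    per_sample: pd.DataFrame  # columns: mean_richness, sd_richness
    depth: int
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        df = self.per_sample.copy()
        df["depth"] = self.depth
        df["n_trials"] = self.n_trials
        return df


def iterative_richness(
    table: CountTable,
    n_trials: int = 100,
    seed: int = 0,
    depth: int | None = None,
) -> RichnessEstimate:
    """Mean rarefied richness over ``n_trials`` independent rarefactions.

    The depth defaults to the minimum sample total so no sample is dropped.
    Each trial uses a child seed derived from the master seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])[:5]
        raise ValueError(f"samples with zero total reads: {bad}")
    if depth is None:
        depth = int(totals.min())
    ss = np.random.SeedSequence(seed)
    richness = np.zeros((n_trials, len(table.sample_ids)))
    for t, child in enumerate(ss.spawn(n_trials)):
        rarefied, _rep = rarefy(table, depth, seed=child)
        richness[t] = (rarefied.values > 0).sum(axis=0)
    per_sample = pd.DataFrame(
        {
            "mean_richness": richness.mean(axis=0),
            "sd_richness": richness.std(axis=0, ddof=0),
        },
        index=table.sample_ids,
    )
    return RichnessEstimate(per_sample=per_sample, depth=depth, n_trials=n_trials)


def expected_rarefied_richness(counts: np.ndarray, depth: int) -> float:
    """Closed-form expected richness of a without-replacement subsample.

    For a sample with feature counts ``n_f`` totalling ``N``, the chance a
    feature survives rarefaction to depth ``d`` is hypergeometric:
    ``1 - C(N - n_f, d) / C(N, d)``; the expectation is the sum over
    features. Used as the analytic oracle for the iterative estimator.
    """
    from scipy.special import gammaln

    counts = np.asarray(counts)
    counts = counts[counts > 0]
    total = counts.sum()
    if depth > total:
        raise ValueError("depth exceeds sample total")

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    probs = np.where(
        total - counts < depth,
        1.0,
        1.0 - np.exp(log_comb(total - counts, depth) - log_comb(total, depth)),
    )
    return float(probs.sum())


def _jsd_condensed(proportions: np.ndarray) -> np.ndarray:
    """Pairwise Jensen-Shannon divergence (natural log) over sample rows."""
    n = proportions.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(proportions > 0, proportions * np.log(proportions), 0.0).sum(axis=1)
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            mix = 0.5 * (proportions[i] + proportions[j])
            with np.errstate(divide="ignore", invalid="ignore"):
                mlogm = np.where(mix > 0, mix * np.log(mix), 0.0).sum()
            out[k] = 0.5 * plogp[i] + 0.5 * plogp[j] - mlogm
            k += 1
    return np.clip(out, 0.0, np.log(2.0))


def distance_matrix(table: CountTable, metric: str) -> DistanceMatrix:
    """Pairwise sample distances under the chosen metric.

    Bray-Curtis operates on the counts as given (rarefy first if depth bias
    matters); Jensen-Shannon normalizes each sample to proportions
    internally. Quantitative Jaccard is the monotone transform
    ``2*BC / (1 + BC)`` of Bray-Curtis.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    x = table.values.T.astype(float)  # samples x features
    totals = x.sum(axis=1)
    if metric == "jsd" and (totals == 0).any():
        raise ValueError("Jensen-Shannon divergence requires nonzero sample totals")

    if metric == "bray_curtis":
        condensed = pdist(x, metric="braycurtis")
    elif metric == "jaccard_binary":
        condensed = pdist(x > 0, metric="jaccard")
    elif metric == "jaccard_quant":
        bc = pdist(x, metric="braycurtis")
        condensed = 2.0 * bc / (1.0 + bc)
    else:  # jsd
        condensed = _jsd_condensed(x / totals[:, None])
    condensed = np.nan_to_num(condensed, nan=0.0)
    return DistanceMatrix(squareform(condensed), table.sample_ids, metric)
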