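"""Washout behavior of induced features: persistence, deltas, trajectories.

After stimulation and washout, an induced peak either keeps its signal
("persists"), decays back to baseline, or climbs further.  Persistence is a
significance call against the *unstimulated* baseline — a feature persists
when its washout-vs-unstim log2 fold change is still >= 0 with FDR < 0.01 —
because "remaining above baseline" is only meaningful in that contrast.
Population-level shifts are summarized by the mean log2 fold change between
pre- and post-washout condition means with a paired Wilcoxon signed-rank
test, and qualitative patterns are recovered by k-means on Z-scored
condition-mean log2 CPM trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .normalize import CpmMatrix

__all__ = [
    "call_persistence",
    "persistence_fraction",
    "wilcoxon_signed_rank",
    "washout_delta_stats",
    "WashoutDeltaStats",
    "TrajectoryClusters",
    "cluster_trajectories",
]


def call_persistence(
    induced_ids,
    washout_results: dict[str, pd.DataFrame],
    l2fc_min: float = 0.0,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Persistence calls per induced feature per post-washout treatment.

    ``washout_results`` maps a washout-treatment label (media / rux /
    anti_ifng) to the differential table of the washout-vs-unstimulated
    contrast.  A feature persists when l2fc >= ``l2fc_min`` (inclusive) and
    fdr < ``fdr_max`` (strict).
    """
    induced_ids = list(induced_ids)
    rows = []
    for treatment, results in washout_results.items():
        missing = [f for f in induced_ids if f not in results.index]
        if missing:
            raise KeyError(
                f"induced features missing from {treatment!r} results: {missing[:5]}"
            )
        sub = results.loc[induced_ids]
        for fid, r in sub.iterrows():
            rows.append(
                {
                    "feature_id": fid,
                    "washout_treatment": treatment,
                    "l2fc_washout_vs_unstim": r["l2fc"],
                    "fdr_washout_vs_unstim": r["fdr"],
                    "persistent": bool(r["l2fc"] >= l2fc_min and r["fdr"] < fdr_max),
                }
            )
    return pd.DataFrame(rows)


def persistence_fraction(calls: pd.DataFrame, treatment: str) -> float:
    """Fraction of induced features called persistent under one treatment."""
    sub = calls[calls["washout_treatment"] == treatment]
    if len(sub) == 0:
        raise ValueError(f"no persistence calls for treatment {treatment!r}")
    return float(sub["persistent"].mean())


def wilcoxon_signed_rank(deltas, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped (Wilcoxon's rule).  For up to
    ``exact_max_n`` remaining pairs the null distribution of the positive
    rank sum is enumerated exactly by dynamic programming over sign flips
    (midranks for tied magnitudes); beyond that the normal approximation
    with tie and continuity corrections is used.  Returns ``(W_plus, p)``.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 2:
        raise ValueError("Wilcoxon test undefined with fewer than 2 nonzero pairs")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # integer-scale midranks (multiples of 0.5) and convolve sign flips:
        # the generating polynomial of W+ is prod_i (1 + x^{2 r_i}) / 2^n
        scaled = np.rint(2 * ranks).astype(int)
        dist = np.zeros(scaled.sum() + 1)
        dist[0] = 1.0
        for r in scaled:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = 0.5 * (dist + shifted)
        w_scaled = int(round(2 * w_plus))
        cdf = float(dist[: w_scaled + 1].sum())
        sf = float(dist[w_scaled:].sum())
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        _, p = stats.wilcoxon(
            d, alternative="two-sided", correction=True, method="approx"
        )
        p = float(p)
    return w_plus, p


@dataclass
class WashoutDeltaStats:
    """Population summary of the pre-to-post washout shift."""

    mean_l2fc: float
    pvalue: float
    n_pairs: int


def washout_delta_stats(
    matrix: CpmMatrix,
    feature_ids,
    pre_condition: str,
    post_condition: str,
) -> WashoutDeltaStats:
    """Mean per-feature log2(post/pre) on condition means, with Wilcoxon p.

    ``matrix`` must already be pseudocounted so logs are finite.  Expects at
    least two features whose delta is nonzero; the p-value is undefined
    otherwise and a ``ValueError`` is raised.
    """
    ids = list(feature_ids)
    pre = matrix.condition_mean(pre_condition).loc[ids]
    post = matrix.condition_mean(post_condition).loc[ids]
    delta = np.log2(post.to_numpy()) - np.log2(pre.to_numpy())
    mean = float(delta.mean())
    _, p = wilcoxon_signed_rank(delta)
    return WashoutDeltaStats(mean, p, n_pairs=int((delta != 0).sum()))


@dataclass
class TrajectoryClusters:
    """k-means partition of Z-scored condition-mean trajectories."""

    k: int
    assignments: pd.Series  # feature_id -> cluster label 0..k-1
    centroids: pd.DataFrame  # k x conditions
    excluded: list[str]  # zero-variance features left unclustered
    seed: int


def cluster_trajectories(
    matrix: CpmMatrix,
    feature_ids,
    conditions: list[str],
    k: int = 3,
    seed: int = 0,
    order_condition: str | None = None,
) -> TrajectoryClusters:
    """Cluster features on Z-scored log2 condition-mean CPM profiles.

    Each feature's profile is its log2 mean CPM across the given conditions,
    standardized to mean 0 / sd 1 across the profile.  Features with zero
    variance across conditions cannot be Z-scored and are excluded (reported
    in ``excluded``).  Clusters are relabeled deterministically by descending
    centroid value at ``order_condition`` (default: the last condition, the
    washout endpoint), so label 0 is always the most-persistent pattern.
    """
    ids = list(feature_ids)
    profiles = pd.DataFrame(
        {c: np.log2(matrix.condition_mean(c).loc[ids]) for c in conditions}
    )
    sd = profiles.std(axis=1, ddof=0)
    flat = sd == 0
    excluded = list(profiles.index[flat])
    usable = profiles[~flat]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(usable):
        raise ValueError(f"k={k} exceeds {len(usable)} clusterable features")
    z = usable.sub(usable.mean(axis=1), axis=0).div(sd[~flat], axis=0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(z.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=conditions)
    anchor = order_condition if order_condition is not None else conditions[-1]
    order = np.argsort(-centroids[anchor].to_numpy(), kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = pd.Series(
        [relabel[int(l)] for l in raw_labels], index=usable.index, name="cluster"
    )
    centroids = centroids.iloc[order].reset_index(drop=True)
    return TrajectoryClusters(k, labels, centroids, excluded, seed)
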