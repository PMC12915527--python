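"""Enhancer-to-gene assignment by TSS proximity, and durability coupling.

Peaks are linked to protein-coding genes whose TSS lies within +/-20 kb of
the peak midpoint; promoter-proximal pairs (within +/-1 kb of the TSS) are
excluded, since those reflect promoter rather than enhancer signal.  A peak
may link to several genes and a gene to several peaks.  The potentiation/
durability relation pairs each link's gene-level mean potentiation with the
peak's post-washout log2 fold change and summarizes it with a Spearman rank
correlation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FeatureSet, TssRecord

__all__ = ["link_peaks_to_genes", "potentiation_vs_durability"]


def link_peaks_to_genes(
    peaks: FeatureSet,
    tss: Sequence[TssRecord],
    window: int = 20_000,
    promoter_window: int = 1_000,
    protein_coding_only: bool = True,
) -> pd.DataFrame:
    """All (peak, gene) pairs with promoter-distal TSS proximity.

    A pair is retained when the absolute midpoint-to-TSS distance is <=
    ``window`` (inclusive) and > ``promoter_window`` on the same chromosome.
    Distance is signed by gene strand: positive means the peak lies
    downstream of the TSS.  Columns: feature_id, gene_id, distance,
    promoter_proximal (always False for retained links).
    """
    records = [t for t in tss if t.protein_coding or not protein_coding_only]
    by_chrom: dict[str, list[TssRecord]] = {}
    for t in records:
        by_chrom.setdefault(t.chrom, []).append(t)
    positions = {
        chrom: (np.array([t.tss for t in ts]), ts) for chrom, ts in by_chrom.items()
    }
    rows = []
    for peak in peaks:
        if peak.chrom not in positions:
            continue
        pos, ts = positions[peak.chrom]
        mid = peak.midpoint
        close = np.abs(pos - mid) <= window
        for idx in np.nonzero(close)[0]:
            gene = ts[idx]
            offset = mid - gene.tss
            distance = offset if gene.strand == "+" else -offset
            if abs(offset) <= promoter_window:
                continue
            rows.append(
                {
                    "feature_id": peak.feature_id,
                    "gene_id": gene.gene_id,
                    "distance": distance,
                    "promoter_proximal": False,
                }
            )
    return pd.DataFrame(
        rows, columns=["feature_id", "gene_id", "distance", "promoter_proximal"]
    )


def potentiation_vs_durability(
    links: pd.DataFrame,
    mean_potentiation: pd.Series,
    enhancer_washout_l2fc: pd.Series,
    gene_subset: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Pair gene potentiation with linked-enhancer washout fold change.

    ``gene_subset`` restricts the analysis (typically to LPS-induced genes).
    Each link contributes one pair, so a gene with several enhancers appears
    once per enhancer.  Returns (pairs table, Spearman rho, two-sided p);
    fewer than 3 pairs is an error since the correlation is undefined.
    """
    sub = links
    if gene_subset is not None:
        keep = set(gene_subset)
        sub = links[links["gene_id"].isin(keep)]
    sub = sub[
        sub["gene_id"].isin(mean_potentiation.index)
        & sub["feature_id"].isin(enhancer_washout_l2fc.index)
    ]
    pairs = pd.DataFrame(
        {
            "feature_id": sub["feature_id"].to_numpy(),
            "gene_id": sub["gene_id"].to_numpy(),
            "mean_potentiation": mean_potentiation.loc[sub["gene_id"]].to_numpy(),
            "enhancer_washout_l2fc": enhancer_washout_l2fc.loc[
                sub["feature_id"]
            ].to_numpy(),
        }
    )
    if len(pairs) < 3:
        raise ValueError("fewer than 3 (gene, enhancer) pairs; correlation undefined")
    rho, p = stats.spearmanr(
        pairs["mean_potentiation"], pairs["enhancer_washout_l2fc"]
    )
    return pairs, float(rho), float(p)
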