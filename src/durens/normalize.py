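"""CPM normalization, pseudocounting, and the acute-abundance peak filter.

Normalization is deliberately minimal — counts-per-million per sample, with a
pseudocount *floor* applied afterwards — because the downstream memory calls
are threshold rules on condition-mean CPM, not model fits.  Two pseudocount
policies are supported:

``percentile_1_per_condition``
    The floor for each condition group is the 1st percentile of all CPM values
    observed across that group's samples (peak assays).
``fixed_1``
    A flat floor of 1 CPM (gene expression).

The acute-abundance filter drops weak peaks before differential testing: a
peak is kept when its mean CPM in at least one acute-stimulation condition
reaches that condition's median (configurable percentile) of per-peak means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SampleDesign

__all__ = ["CpmMatrix", "cpm", "apply_pseudocount", "acute_abundance_filter"]

PSEUDOCOUNT_POLICIES = ("percentile_1_per_condition", "fixed_1")


@dataclass
class CpmMatrix:
    """Counts-per-million, features x samples, with pseudocount provenance."""

    frame: pd.DataFrame
    design: SampleDesign
    pseudocount_policy: str | None = None
    floors: dict[str, float] = field(default_factory=dict)

    def condition_mean(self, condition: str) -> pd.Series:
        """Mean CPM per feature over the replicates of one condition."""
        return self.frame[self.design.samples_for(condition)].mean(axis=1)


def cpm(counts: CountMatrix) -> CpmMatrix:
    """Scale each sample to counts per million.  No pseudocount yet.

    Raises ``ValueError`` naming the sample if a library size is zero.
    """
    libsizes = counts.library_sizes()
    empty = libsizes.index[libsizes == 0].tolist()
    if empty:
        raise ValueError(f"zero library size for sample(s): {empty}")
    frame = counts.counts / libsizes * 1e6
    return CpmMatrix(frame, counts.design)


def apply_pseudocount(
    matrix: CpmMatrix,
    policy: str = "percentile_1_per_condition",
    percentile: float = 1.0,
) -> CpmMatrix:
    """Floor CPM values under the chosen pseudocount policy.

    The floor is applied as an elementwise ``max`` — values already above it
    are untouched, so the operation is monotone and idempotent.  Under the
    percentile policy the floor is computed per condition group over all CPM
    values of that group's samples (all features, not only expressed ones).
    """
    if policy not in PSEUDOCOUNT_POLICIES:
        raise ValueError(f"unknown pseudocount policy {policy!r}")
    out = matrix.frame.copy()
    floors: dict[str, float] = {}
    if policy == "fixed_1":
        out = out.clip(lower=1.0)
        floors["*"] = 1.0
    else:
        for condition in matrix.design.conditions:
            samples = [s for s in matrix.design.samples_for(condition) if s in out.columns]
            if not samples:
                continue
            values = out[samples].to_numpy().ravel()
            if values.size == 0:
                raise ValueError(f"empty condition group {condition!r}")
            p = float(np.percentile(values, percentile))
            out[samples] = out[samples].clip(lower=p)
            floors[condition] = p
    return CpmMatrix(out, matrix.design, pseudocount_policy=policy, floors=floors)


def acute_abundance_filter(
    matrix: CpmMatrix,
    acute_conditions: Iterable[str],
    percentile: float = 0.5,
) -> pd.Index:
    """Keep features in the top (1 - percentile) of abundance in any acute condition.

    For each acute condition, the per-feature mean CPM over its replicates is
    compared against the ``percentile`` quantile of those means; a feature
    passes if it ties or exceeds the threshold in at least one condition
    (inclusive >=, so with percentile 0.5 exactly half-or-more survive each
    condition and ties are kept).  Order of the returned index matches the
    input feature order.
    """
    acute = list(acute_conditions)
    if not acute:
        raise ValueError("acute_conditions must be non-empty")
    keep = pd.Series(False, index=matrix.frame.index)
    for condition in acute:
        means = matrix.condition_mean(condition)
        threshold = float(np.quantile(means.to_numpy(), percentile))
        keep |= means >= threshold
    return matrix.frame.index[keep]
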