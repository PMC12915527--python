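"""Gene-level memory calls: induction, persistence bands, potentiation, tolerance.

These are pure threshold rules on condition-mean CPM (pseudocount floor 1),
separate from the count-based differential test used for peaks:

* an *induced* gene reaches at least ``fold_min`` (default 5x) CPM at 8 h of
  stimulation relative to unstimulated cells;
* *persistence* is the washout CPM as a percent of the 8-h CPM, banded into
  >=90%, 20-90% and <20%;
* a *potentiated* gene is LPS-inducible (>= ``lps_fold_min`` over the naive
  0-h level) and at least ``delta_fold_min``-fold higher in cytokine-pretreated
  than naive cells at two contiguous timepoints of the restimulation course;
* a *tolerized* gene shows a >= ``reduction_fold_min``-fold reduction after
  pretreatment at two contiguous timepoints while remaining LPS-inducible
  under JAK blockade (the ruxolitinib arm);
* the *basal set-point* splits potentiated genes by their pre-restimulation
  (0 h) log2 ratio against the naive arm, threshold 0.5 (strict >);
* *mean potentiation* is the average over post-0 h timepoints of the
  difference in log2 fold change (vs naive 0 h) between the two arms.

"Contiguous" means adjacent on the sampled timepoint grid (the grids are
irregular, e.g. {0, 1, 3, 6, 12} h, so clock-time adjacency is not usable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import CpmMatrix

__all__ = [
    "GeneTimecourse",
    "build_timecourse",
    "call_induced_genes",
    "persistence_percent",
    "persistence_band",
    "BANDS",
    "lps_induction",
    "call_potentiated",
    "call_tolerized",
    "split_basal",
    "mean_potentiation",
]

BANDS = (">=90", "20-90", "<20")


@dataclass
class GeneTimecourse:
    """Condition-mean CPM (pseudocounted) per arm over a shared timepoint grid.

    ``arms`` maps an arm label (e.g. ``"PBS"``, ``"IFNG"``, ``"PBS_RUX"``) to
    a genes x timepoints DataFrame whose columns are the grid in ascending
    order.  All arms share gene index and grid.
    """

    timepoints: tuple[float, ...]
    arms: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        if list(tps) != sorted(tps):
            raise ValueError("timepoints must be ascending")
        ref_index = None
        for name, frame in self.arms.items():
            if tuple(float(c) for c in frame.columns) != tps:
                raise ValueError(f"arm {name!r} does not match the timepoint grid")
            if ref_index is None:
                ref_index = frame.index
            elif not frame.index.equals(ref_index):
                raise ValueError(f"arm {name!r} has a different gene index")
        self.timepoints = tps

    @property
    def genes(self) -> pd.Index:
        return next(iter(self.arms.values())).index


def build_timecourse(
    matrix: CpmMatrix, arms: Mapping[str, Mapping[float, str]]
) -> GeneTimecourse:
    """Assemble a timecourse from a CPM matrix and arm -> {timepoint: condition} maps."""
    grids = {name: tuple(sorted(float(t) for t in m)) for name, m in arms.items()}
    grid = next(iter(grids.values()))
    if any(g != grid for g in grids.values()):
        raise ValueError(f"timepoint grids differ between arms: {grids}")
    frames = {}
    for name, mapping in arms.items():
        cols = {float(t): matrix.condition_mean(c) for t, c in mapping.items()}
        frames[name] = pd.DataFrame(cols)[list(grid)]
    return GeneTimecourse(grid, frames)


def call_induced_genes(
    cpm_unstim: pd.Series, cpm_stim: pd.Series, fold_min: float = 5.0
) -> pd.Index:
    """Genes whose stimulated CPM is at least ``fold_min`` times baseline (inclusive)."""
    if not cpm_unstim.index.equals(cpm_stim.index):
        cpm_stim = cpm_stim.reindex(cpm_unstim.index)
        if cpm_stim.isna().any():
            raise ValueError("stimulated CPM missing for some genes")
    ratio = cpm_stim / cpm_unstim
    return cpm_unstim.index[ratio >= fold_min]


def persistence_percent(cpm_washout: pd.Series, cpm_8h: pd.Series) -> pd.Series:
    """Washout expression as a percent of the 8-h level (plain ratio x 100)."""
    if (cpm_8h <= 0).any():
        raise ValueError("8-h CPM must be positive (pseudocount floor >= 1)")
    return 100.0 * cpm_washout / cpm_8h


def persistence_band(percent: pd.Series | float):
    """Band a persistence percent: >=90, 20-90 (inclusive of 20), <20.

    The bands partition [0, inf): percent >= 90 -> ">=90"; 20 <= percent < 90
    -> "20-90"; percent < 20 -> "<20".
    """
    scalar = np.isscalar(percent)
    p = pd.Series([percent]) if scalar else percent
    if (p < 0).any():
        raise ValueError("persistence percent must be non-negative")
    out = pd.Series(
        np.select([p >= 90, p >= 20], [">=90", "20-90"], default="<20"),
        index=p.index,
    )
    return out.iloc[0] if scalar else out


def lps_induction(
    tc: GeneTimecourse, arms: Sequence[str], naive_arm: str
) -> pd.Series:
    """Max fold over the course relative to the naive arm's 0-h level."""
    naive0 = tc.arms[naive_arm].iloc[:, 0]
    best = None
    for arm in arms:
        fold = tc.arms[arm].div(naive0, axis=0).max(axis=1)
        best = fold if best is None else np.maximum(best, fold)
    return best


def _contiguous_run(mask: np.ndarray, run: int) -> np.ndarray:
    """Row-wise: does any window of ``run`` consecutive True values exist?"""
    if run <= 1:
        return mask.any(axis=1)
    hit = np.zeros(mask.shape[0], dtype=bool)
    for start in range(mask.shape[1] - run + 1):
        hit |= mask[:, start : start + run].all(axis=1)
    return hit


def call_potentiated(
    tc: GeneTimecourse,
    pbs_arm: str = "PBS",
    ifng_arm: str = "IFNG",
    lps_fold_min: float = 5.0,
    delta_fold_min: float = 2.0,
    contiguous: int = 2,
    induction_arms: Sequence[str] | None = None,
) -> pd.Series:
    """Boolean potentiation call per gene.

    A gene is potentiated iff (a) it is LPS-inducible — the naive (PBS) arm's
    CPM reaches ``lps_fold_min`` times its own 0-h level somewhere on the
    course — and (b) the pretreated/naive CPM ratio is >= ``delta_fold_min``
    at ``contiguous`` adjacent grid timepoints.  Pretreatment-driven elevation
    alone never satisfies the induction gate: the gene must respond to LPS in
    untrained cells.
    """
    if induction_arms is None:
        induction_arms = (pbs_arm,)
    induced = lps_induction(tc, induction_arms, pbs_arm) >= lps_fold_min
    ratio = tc.arms[ifng_arm].to_numpy() / tc.arms[pbs_arm].to_numpy()
    boosted = _contiguous_run(ratio >= delta_fold_min, contiguous)
    return pd.Series(induced.to_numpy() & boosted, index=tc.genes, name="potentiated")


def call_tolerized(
    tc: GeneTimecourse,
    pbs_arm: str = "PBS",
    ifng_arm: str = "IFNG",
    rux_arm: str = "PBS_RUX",
    reduction_fold_min: float = 2.0,
    contiguous: int = 2,
    rux_induction_min: float = 4.0,
) -> pd.Series:
    """Boolean tolerance call per gene.

    Tolerized iff (a) the naive/pretreated CPM ratio is >=
    ``reduction_fold_min`` at ``contiguous`` adjacent timepoints and (b) the
    gene is still LPS-inducible under JAK blockade: its ruxolitinib-arm CPM
    reaches ``rux_induction_min`` times that arm's 0-h level.
    """
    if rux_arm not in tc.arms:
        raise KeyError(f"ruxolitinib arm {rux_arm!r} absent from timecourse")
    ratio = tc.arms[pbs_arm].to_numpy() / tc.arms[ifng_arm].to_numpy()
    reduced = _contiguous_run(ratio >= reduction_fold_min, contiguous)
    rux = tc.arms[rux_arm]
    rux_fold = rux.div(rux.iloc[:, 0], axis=0).max(axis=1)
    return pd.Series(
        reduced & (rux_fold >= rux_induction_min).to_numpy(),
        index=tc.genes,
        name="tolerized",
    )


def split_basal(
    tc: GeneTimecourse,
    pbs_arm: str = "PBS",
    ifng_arm: str = "IFNG",
    threshold_l2fc: float = 0.5,
) -> pd.Series:
    """Basal set-point split at the pre-restimulation (0 h) timepoint.

    ``basal_elevated`` iff log2(pretreated 0 h / naive 0 h) is strictly above
    ``threshold_l2fc``; a value of exactly 0.5 falls in the equal-basal class.
    """
    l2fc0 = np.log2(tc.arms[ifng_arm].iloc[:, 0] / tc.arms[pbs_arm].iloc[:, 0])
    # tiny slack keeps a ratio of exactly 2^threshold on the equal-basal side
    return pd.Series(
        l2fc0 > threshold_l2fc + 1e-9, index=tc.genes, name="basal_elevated"
    )


def mean_potentiation(
    tc: GeneTimecourse,
    pbs_arm: str = "PBS",
    ifng_arm: str = "IFNG",
    include_t0: bool = False,
) -> pd.Series:
    """Average over timepoints of the arm difference in L2FC vs naive 0 h.

    Both arms' fold changes share the naive 0-h denominator, so the per-
    timepoint difference reduces to log2(pretreated / naive) at that
    timepoint.  The 0-h point is excluded by default because both arms are
    referenced to it.
    """
    cols = list(range(len(tc.timepoints))) if include_t0 else list(
        range(1, len(tc.timepoints))
    )
    if not cols:
        raise ValueError("no timepoints to average over")
    delta = np.log2(
        tc.arms[ifng_arm].iloc[:, cols].to_numpy()
        / tc.arms[pbs_arm].iloc[:, cols].to_numpy()
    )
    return pd.Series(delta.mean(axis=1), index=tc.genes, name="mean_potentiation")
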