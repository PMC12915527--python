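"""Synthetic stimulus-washout datasets with planted, labelled memory classes.

The generator emulates the statistical structure of the real experiments so
the whole pipeline is testable without any download:

* **Peak assay** (enhancer marks / accessibility): negative-binomial counts
  over peaks for conditions {unstimulated, IFNg 8 h, LPS 8 h, LPS+rux 8 h}
  and day-4 washout arms {media, ruxolitinib, anti-IFNg}, 2 replicates each.
  Planted classes: stimulus-specific induced (half IFNg-, half LPS-specific),
  shared induced, and IFNg-induced peaks that persist / decay / further
  increase after washout.  Signaling blockade after washout (rux, anti-IFNg)
  erases the persistence effect, returning planted-persistent peaks to
  baseline.
* **Gene assay** (expression): one count matrix covering both gene designs —
  the IFNg-8 h / washout design (media and rux arms) and the LPS
  restimulation time course {0, 1, 3, 6, 12 h} with pretreatment arms
  {PBS, IFNg} crossed with washout conditioning {media, rux}.  Planted
  classes: IFNg-induced genes with full / partial / no persistence,
  potentiated genes (with equal or elevated basal set-point) whose
  pretreatment boost appears at two or more consecutive timepoints,
  and tolerized genes that stay LPS-inducible under JAK blockade.
  (For genes, the ``stim_specific_induced`` class label denotes an
  IFNg-induced gene with intermediate, mid-band persistence.)
* **Enhancer-gene coupling**: each potentiated gene is paired with one
  persistent peak placed 3-15 kb from its TSS; the peak's post-washout
  effect and the gene's potentiation delta share a per-gene strength factor,
  planting a positive rank correlation.  All other peaks are intergenic
  (> 20 kb from every TSS).

Counts are drawn NB(mean, phi) with variance mu + phi * mu^2 via the
gamma-Poisson mixture; all class effects act on the latent log2-CPM mean, so
counts stay marginally negative binomial.  Same config (including seed) =>
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    FeatureSet,
    GenomicInterval,
    SampleDesign,
    TssRecord,
    write_bed,
    write_counts,
    write_design,
    write_tss,
)

__all__ = [
    "EffectSizes",
    "GeneratorConfig",
    "TruthLabels",
    "SimulatedDataset",
    "generate_dataset",
    "worked_example_fixture",
    "PEAK_CLASSES",
    "GENE_CLASSES",
]

PEAK_CLASSES = (
    "stim_specific_induced",
    "shared_induced",
    "persistent",
    "decaying",
    "increasing",
)
GENE_CLASSES = (
    "stim_specific_induced",
    "persistent",
    "decaying",
    "increasing",
    "potentiated_equal_basal",
    "potentiated_elevated_basal",
    "tolerized",
)

PEAK_CONDITIONS = (
    "UNSTIM",
    "IFNG_8H",
    "LPS_8H",
    "LPS_RUX_8H",
    "WASH_MEDIA",
    "WASH_RUX",
    "WASH_AIFNG",
)
_PEAK_WASHOUT = {
    "UNSTIM": "none",
    "IFNG_8H": "none",
    "LPS_8H": "none",
    "LPS_RUX_8H": "none",
    "WASH_MEDIA": "media",
    "WASH_RUX": "rux",
    "WASH_AIFNG": "anti_ifng",
}
_PEAK_TIME = {
    "UNSTIM": 0.0,
    "IFNG_8H": 8.0,
    "LPS_8H": 8.0,
    "LPS_RUX_8H": 8.0,
    "WASH_MEDIA": 96.0,
    "WASH_RUX": 96.0,
    "WASH_AIFNG": 96.0,
}

GENE_WASH_CONDITIONS = ("UNSTIM", "IFNG_8H", "WASH_MEDIA", "WASH_RUX")
RESTIM_ARMS = ("PBS", "IFNG", "PBS_RUX", "IFNG_RUX")


@dataclass(frozen=True)
class EffectSizes:
    """Planted log2 effects, chosen to mirror strong, unambiguous responders."""

    induction: float = 4.0  # 8-h stimulation over baseline (peaks and genes)
    post_washout_increase: float = 1.0  # extra gain of the "increasing" class
    persistent_washout_drop: float = 1.0  # persistent peaks dip below the 8-h peak
    partial_persistence: float = -1.0  # mid-band genes: washout = 8 h minus 1
    potentiation_delta: float = 1.5  # pretreated-arm boost at late timepoints
    tolerance_delta: float = 1.5  # pretreated-arm reduction at mid timepoints
    basal_shift: float = 2.0  # elevated-basal potentiated genes, all timepoints
    lps_profile_peak: float = 3.5  # max LPS induction (log2) on the time course


def _default_fractions() -> dict[str, float]:
    # minority fractions: induced features are a small share of the feature
    # universe, so CPM compositionality distorts planted fold changes little
    return {
        "stim_specific_induced": 0.04,
        "shared_induced": 0.02,
        "persistent": 0.02,
        "decaying": 0.02,
        "increasing": 0.01,
        "potentiated_equal_basal": 0.010,
        "potentiated_elevated_basal": 0.015,
        "tolerized": 0.010,
    }


@dataclass
class GeneratorConfig:
    n_peaks: int = 10_000
    n_genes: int = 10_000
    replicates: int = 2
    nb_dispersion: float = 0.2  # peak assays (tag counts in peaks)
    nb_dispersion_genes: float = 0.05  # RNA-seq; expressed genes are less dispersed
    baseline_log2cpm_range: tuple[float, float] = (2.0, 7.0)
    # LPS-response genes start near-silent (cytokines/chemokines), which also
    # keeps their induced mass a small share of the library
    lps_baseline_log2cpm_range: tuple[float, float] = (1.0, 3.0)
    class_fractions: dict[str, float] = field(default_factory=_default_fractions)
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    nominal_libsize: float = 2e6  # peak assays
    nominal_libsize_genes: float = 2e7  # RNA-seq depth
    lps_grid: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0, 12.0)
    noncoding_fraction: float = 0.02  # drawn from null genes only
    seed: int = 0

    def __post_init__(self) -> None:
        for space, classes in (("peak", PEAK_CLASSES), ("gene", GENE_CLASSES)):
            total = sum(self.class_fractions.get(c, 0.0) for c in classes)
            if total > 1.0 + 1e-9:
                raise ValueError(f"{space} class fractions sum to {total} > 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class TruthLabels:
    """Planted class per feature/gene plus enhancer-gene couplings."""

    peak_class: pd.Series
    gene_class: pd.Series
    couplings: pd.DataFrame  # columns: gene_id, feature_id, strength


@dataclass
class SimulatedDataset:
    peaks: FeatureSet
    peak_counts: CountMatrix
    tss: list[TssRecord]
    gene_counts: CountMatrix
    truth: TruthLabels
    config: GeneratorConfig

    @property
    def peak_design(self) -> SampleDesign:
        return self.peak_counts.design

    @property
    def gene_design(self) -> SampleDesign:
        return self.gene_counts.design

    def write(self, outdir: str | Path) -> None:
        """Write analysis-facing files and truth labels (kept separate)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed(self.peaks, outdir / "peaks.bed")
        write_counts(self.peak_counts, outdir / "peak_counts.tsv")
        write_design(self.peak_design, outdir / "peak_design.tsv")
        write_counts(self.gene_counts, outdir / "gene_counts.tsv")
        write_design(self.gene_design, outdir / "gene_design.tsv")
        write_tss(self.tss, outdir / "tss.tsv")
        self.truth.peak_class.rename("planted_class").to_frame().to_csv(
            outdir / "truth_peaks.tsv", sep="\t", index_label="feature_id"
        )
        self.truth.gene_class.rename("planted_class").to_frame().to_csv(
            outdir / "truth_genes.tsv", sep="\t", index_label="gene_id"
        )
        self.truth.couplings.to_csv(outdir / "truth_couplings.tsv", sep="\t", index=False)


def _assign_classes(
    rng: np.random.Generator, n: int, fractions: dict[str, float], classes: tuple[str, ...]
) -> np.ndarray:
    labels = np.array(["null"] * n, dtype=object)
    counts = {c: int(round(fractions.get(c, 0.0) * n)) for c in classes}
    if sum(counts.values()) > n:
        raise ValueError("class fractions infeasible for this feature count")
    order = rng.permutation(n)
    pos = 0
    for c in classes:
        labels[order[pos : pos + counts[c]]] = c
        pos += counts[c]
    return labels


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mu)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mu * phi)
    return rng.poisson(lam)


def _lps_shape(grid: tuple[float, ...], peak_l2: float) -> np.ndarray:
    """Rising-then-plateau LPS induction profile on the grid (log2 units)."""
    base = {0.0: 0.0, 1.0: 2.0, 3.0: 3.0, 6.0: peak_l2, 12.0: 3.0}
    return np.array([base.get(t, peak_l2) for t in grid])


def generate_dataset(config: GeneratorConfig) -> SimulatedDataset:
    """Draw a full labelled dataset under the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    eff = config.effect_sizes
    lo, hi = config.baseline_log2cpm_range

    # ---- peaks: classes, baselines, latent effects per condition -----------
    peak_ids = [f"pk{i:06d}" for i in range(config.n_peaks)]
    peak_class = _assign_classes(rng, config.n_peaks, config.class_fractions, PEAK_CLASSES)
    # stimulus-specific peaks split evenly between IFNg- and LPS-specific
    stim_idx = np.nonzero(peak_class == "stim_specific_induced")[0]
    ifng_specific = np.zeros(config.n_peaks, dtype=bool)
    ifng_specific[stim_idx[: len(stim_idx) // 2]] = True
    lps_specific = np.zeros(config.n_peaks, dtype=bool)
    lps_specific[stim_idx[len(stim_idx) // 2 :]] = True

    base_p = rng.uniform(lo, hi, config.n_peaks)
    is_ifng_induced = ifng_specific | np.isin(
        peak_class, ["shared_induced", "persistent", "decaying", "increasing"]
    )
    peak_eff = {c: np.zeros(config.n_peaks) for c in PEAK_CONDITIONS}
    peak_eff["IFNG_8H"][is_ifng_induced] = eff.induction
    peak_eff["LPS_8H"][lps_specific | (peak_class == "shared_induced")] = eff.induction
    peak_eff["LPS_RUX_8H"][lps_specific] = eff.induction  # JAK-independent
    persists_media = ifng_specific | np.isin(peak_class, ["shared_induced", "persistent"])
    peak_eff["WASH_MEDIA"][persists_media] = eff.induction - eff.persistent_washout_drop
    peak_eff["WASH_MEDIA"][peak_class == "increasing"] = (
        eff.induction + eff.post_washout_increase
    )
    # blockade arms erase persistence: WASH_RUX / WASH_AIFNG stay at baseline

    # ---- genes: classes, baselines, both designs ---------------------------
    gene_ids = [f"g{i:06d}" for i in range(config.n_genes)]
    gene_class = _assign_classes(rng, config.n_genes, config.class_fractions, GENE_CLASSES)
    base_g = rng.uniform(lo, hi, config.n_genes)
    lps_lo, lps_hi = config.lps_baseline_log2cpm_range
    lps_classes = np.isin(
        gene_class,
        ["potentiated_equal_basal", "potentiated_elevated_basal", "tolerized"],
    )
    base_g[lps_classes] = rng.uniform(lps_lo, lps_hi, int(lps_classes.sum()))

    ifng_induced_gene = np.isin(
        gene_class, ["stim_specific_induced", "persistent", "decaying", "increasing"]
    )
    gene_wash_eff = {c: np.zeros(config.n_genes) for c in GENE_WASH_CONDITIONS}
    gene_wash_eff["IFNG_8H"][ifng_induced_gene] = eff.induction
    gene_wash_eff["WASH_MEDIA"][gene_class == "persistent"] = eff.induction
    gene_wash_eff["WASH_MEDIA"][gene_class == "increasing"] = (
        eff.induction + eff.post_washout_increase
    )
    gene_wash_eff["WASH_MEDIA"][gene_class == "stim_specific_induced"] = (
        eff.induction + eff.partial_persistence
    )
    # decaying genes and both blockade-insensitive classes return to baseline

    grid = config.lps_grid
    shape = _lps_shape(grid, eff.lps_profile_peak)
    lps_inducible = np.isin(
        gene_class,
        ["potentiated_equal_basal", "potentiated_elevated_basal", "tolerized"],
    )
    potentiated = np.isin(
        gene_class, ["potentiated_equal_basal", "potentiated_elevated_basal"]
    )
    tolerized = gene_class == "tolerized"
    # per-gene strength factor (>= 1 so deltas never undershoot the nominal
    # effect size), shared with the coupled enhancer
    strength = rng.uniform(1.0, 1.4, config.n_genes)

    # timepoint masks: boost at the late half, reduction at the middle
    late = np.array([i >= max(2, len(grid) - 3) for i in range(len(grid))])
    mid = np.array([0 < i < len(grid) - 1 for i in range(len(grid))])

    restim_eff: dict[str, np.ndarray] = {}
    for arm in RESTIM_ARMS:
        for j, t in enumerate(grid):
            e = np.zeros(config.n_genes)
            e[lps_inducible] = shape[j]
            if arm == "IFNG":
                if late[j]:
                    e[potentiated] += eff.potentiation_delta * strength[potentiated]
                e[gene_class == "potentiated_elevated_basal"] += eff.basal_shift
                if mid[j]:
                    e[tolerized] -= eff.tolerance_delta * strength[tolerized]
            # rux-conditioned arms: potentiation and tolerance are erased,
            # LPS induction itself is JAK-independent for these genes
            restim_eff[f"{arm}_LPS_{t:g}H"] = e

    # ---- genome layout and couplings --------------------------------------
    chroms = [f"chr{i+1}" for i in range(5)]
    tss_records: list[TssRecord] = []
    null_genes = np.nonzero(gene_class == "null")[0]
    n_noncoding = int(round(config.noncoding_fraction * config.n_genes))
    noncoding = set(null_genes[:n_noncoding].tolist())
    gene_pos = np.zeros(config.n_genes, dtype=int)
    gene_chrom = []
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        pos = 50_000 + (i // len(chroms)) * 100_000
        gene_chrom.append(chrom)
        gene_pos[i] = pos
        tss_records.append(
            TssRecord(gene_ids[i], chrom, pos, "+" if i % 2 == 0 else "-", i not in noncoding)
        )

    pot_idx = np.nonzero(potentiated)[0]
    persist_idx = np.nonzero(peak_class == "persistent")[0]
    n_couple = min(len(pot_idx), len(persist_idx))
    coupling_rows = []
    coupled_peak_gene: dict[int, int] = {}
    offsets = rng.uniform(3_000, 15_000, n_couple)
    signs = rng.choice([-1, 1], n_couple)
    for k in range(n_couple):
        coupled_peak_gene[int(persist_idx[k])] = int(pot_idx[k])
        coupling_rows.append(
            {
                "gene_id": gene_ids[pot_idx[k]],
                "feature_id": peak_ids[persist_idx[k]],
                "strength": strength[pot_idx[k]],
            }
        )
    couplings = pd.DataFrame(coupling_rows, columns=["gene_id", "feature_id", "strength"])

    # coupled persistent peaks: washout effect scales with the gene's planted
    # mean potentiation (late-timepoint delta plus any basal shift), mapped
    # linearly onto [0.4, 1] x induction so every coupled peak still persists
    if n_couple:
        n_nonzero = max(len(grid) - 1, 1)
        planted_pot = (late[1:].sum() / n_nonzero) * eff.potentiation_delta * strength[
            pot_idx
        ] + np.where(
            gene_class[pot_idx] == "potentiated_elevated_basal", eff.basal_shift, 0.0
        )
        lo_p, hi_p = planted_pot.min(), planted_pot.max()
        span = (planted_pot - lo_p) / (hi_p - lo_p) if hi_p > lo_p else np.full_like(planted_pot, 0.5)
        for k in range(n_couple):
            peak_eff["WASH_MEDIA"][persist_idx[k]] = eff.induction * (0.4 + 0.6 * span[k])

    intervals = []
    intergenic_offsets = rng.uniform(25_000, 75_000, config.n_peaks)
    for i in range(config.n_peaks):
        if i in coupled_peak_gene:
            g = coupled_peak_gene[i]
            mid_pos = int(gene_pos[g] + signs[list(coupled_peak_gene).index(i)] * offsets[
                list(coupled_peak_gene).index(i)
            ])
            chrom = gene_chrom[g]
        else:
            chrom = chroms[i % len(chroms)]
            slot = i // len(chroms)
            mid_pos = int(50_000 + slot * 100_000 + intergenic_offsets[i])
        intervals.append(GenomicInterval(chrom, mid_pos - 250, mid_pos + 250, peak_ids[i]))
    peaks = FeatureSet(intervals)

    # ---- designs and counts ------------------------------------------------
    def _draw_matrix(
        ids: list[str],
        base: np.ndarray,
        effects: dict[str, np.ndarray],
        washout_of,
        time_of,
        phi: float,
        nominal_libsize: float,
    ) -> CountMatrix:
        rows = []
        columns: dict[str, np.ndarray] = {}
        for cond in effects:
            for rep in range(1, config.replicates + 1):
                sid = f"{cond}_r{rep}"
                libsize = nominal_libsize * np.exp(
                    rng.uniform(np.log(0.5), np.log(2.0))
                )
                mu = libsize * np.power(2.0, base + effects[cond]) / 1e6
                columns[sid] = _nb_counts(rng, mu, phi)
                rows.append(
                    {
                        "sample_id": sid,
                        "assay": "synthetic",
                        "condition": cond,
                        "washout_treatment": washout_of(cond),
                        "timepoint_h": time_of(cond),
                        "replicate": rep,
                    }
                )
        design = SampleDesign(pd.DataFrame(rows))
        counts = pd.DataFrame(columns, index=pd.Index(ids, name="feature_id"))
        return CountMatrix(counts, design)

    peak_counts = _draw_matrix(
        peak_ids,
        base_p,
        peak_eff,
        _PEAK_WASHOUT.__getitem__,
        _PEAK_TIME.__getitem__,
        config.nb_dispersion,
        config.nominal_libsize,
    )

    gene_effects = dict(gene_wash_eff)
    gene_effects.update(restim_eff)

    def _gene_washout(cond: str) -> str:
        if cond in _PEAK_WASHOUT:
            return _PEAK_WASHOUT[cond]
        return "rux" if "_RUX_" in cond or cond.startswith(("PBS_RUX", "IFNG_RUX")) else "media"

    def _gene_time(cond: str) -> float:
        if cond in _PEAK_TIME:
            return _PEAK_TIME[cond]
        return float(cond.rsplit("_", 1)[1].rstrip("H"))

    gene_counts = _draw_matrix(
        gene_ids,
        base_g,
        gene_effects,
        _gene_washout,
        _gene_time,
        config.nb_dispersion_genes,
        config.nominal_libsize_genes,
    )

    truth = TruthLabels(
        peak_class=pd.Series(peak_class, index=peak_ids, name="planted_class"),
        gene_class=pd.Series(gene_class, index=gene_ids, name="planted_class"),
        couplings=couplings,
    )
    return SimulatedDataset(peaks, peak_counts, tss_records, gene_counts, truth, config)


# ---------------------------------------------------------------------------
# Hand-written smoke fixture


def worked_example_fixture() -> SimulatedDataset:
    """A tiny hand-written dataset whose every downstream call is hand-checkable.

    Counts are integers chosen so that each sample column sums to a round
    total (2000 for peaks, 1000 for genes, via filler features), making every
    CPM value and fold ratio exact by inspection.  Expected behavior:

    * ``pk_persist`` and ``pk_incr`` are induced and persist under media but
      not under ruxolitinib; ``pk_decay`` is induced but does not persist.
    * ``g_ind`` is >= 5-fold induced with a >=90% media persistence band and a
      <20% rux band; ``g_mid`` lands in the 20-90% band.
    * ``g_pot`` is potentiated with an equal basal set-point, ``g_pot_hi``
      potentiated with an elevated basal set-point, ``g_tol`` tolerized.
    * ``pk_persist`` links to ``g_pot`` (+10 kb), ``pk_incr`` to ``g_pot_hi``
      (+10750), ``pk_decay`` to ``g_tol`` (-10250); other peaks are unlinked.
    """
    peak_rows = {
        #              U1   U2   I1   I2   M1   M2   R1   R2
        "pk_persist": [5, 5, 320, 320, 320, 320, 6, 6],
        "pk_decay": [5, 5, 320, 320, 6, 6, 5, 5],
        "pk_incr": [5, 5, 320, 320, 640, 640, 6, 6],
        "pk_null": [100, 100, 100, 100, 100, 100, 100, 100],
    }
    peak_samples = ["U1", "U2", "I1", "I2", "M1", "M2", "R1", "R2"]
    peak_df = pd.DataFrame(peak_rows, index=peak_samples).T
    peak_df.loc["pk_fill"] = 2000 - peak_df.sum(axis=0)
    peak_design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": peak_samples,
                "assay": ["cuttag"] * 8,
                "condition": ["UNSTIM"] * 2 + ["IFNG_8H"] * 2 + ["WASH_MEDIA"] * 2 + ["WASH_RUX"] * 2,
                "washout_treatment": ["none"] * 4 + ["media"] * 2 + ["rux"] * 2,
                "timepoint_h": [0, 0, 8, 8, 96, 96, 96, 96],
                "replicate": [1, 2] * 4,
            }
        )
    )
    peak_counts = CountMatrix(peak_df, peak_design)

    peaks = FeatureSet(
        [
            GenomicInterval("chr1", 109_750, 110_250, "pk_persist"),  # +10 kb of g_pot
            GenomicInterval("chr2", 89_500, 90_000, "pk_decay"),  # -10250 of g_tol
            GenomicInterval("chr1", 310_500, 311_000, "pk_incr"),  # +10750 of g_pot_hi
            GenomicInterval("chr3", 150_000, 150_500, "pk_null"),
            GenomicInterval("chr4", 1_000, 1_500, "pk_fill"),
        ]
    )
    tss = [
        TssRecord("g_pot", "chr1", 100_000, "+", True),
        TssRecord("g_pot_hi", "chr1", 300_000, "+", True),
        TssRecord("g_tol", "chr2", 100_000, "+", True),
        TssRecord("g_ind", "chr1", 500_000, "+", True),
        TssRecord("g_mid", "chr2", 300_000, "-", True),
        TssRecord("g_null", "chr3", 100_000, "+", True),
        TssRecord("g_fill", "chr3", 300_000, "-", True),
    ]

    # gene matrix spans the washout design (2 reps) and the LPS restimulation
    # course (arms PBS / IFNG / PBS_RUX over 0, 1, 3, 6 h; 1 rep)
    wash_samples = ["GU1", "GU2", "GI1", "GI2", "GM1", "GM2", "GR1", "GR2"]
    grid = (0.0, 1.0, 3.0, 6.0)
    restim_conditions = [f"{arm}_LPS_{t:g}H" for arm in ("PBS", "IFNG", "PBS_RUX") for t in grid]
    gene_rows = {
        #          GU GU GI  GI  GM  GM GR GR | PBS 0,1,3,6 | IFNG 0,1,3,6 | RUX 0,1,3,6
        "g_ind": [2, 2, 20, 20, 19, 19, 1, 1, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5],
        "g_mid": [2, 2, 20, 20, 10, 10, 1, 1, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5, 5],
        "g_pot": [5, 5, 5, 5, 5, 5, 5, 5, 2, 4, 10, 12, 2, 4, 20, 24, 2, 4, 10, 12],
        "g_pot_hi": [5, 5, 5, 5, 5, 5, 5, 5, 2, 4, 10, 12, 6, 12, 30, 36, 2, 4, 10, 12],
        "g_tol": [5, 5, 5, 5, 5, 5, 5, 5, 3, 12, 24, 12, 3, 6, 6, 15, 3, 12, 15, 12],
        "g_null": [10] * 20,
    }
    gene_samples = wash_samples + restim_conditions
    gene_df = pd.DataFrame(gene_rows, index=gene_samples).T
    gene_df.loc["g_fill"] = 1000 - gene_df.sum(axis=0)
    gene_design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": gene_samples,
                "assay": ["rnaseq"] * len(gene_samples),
                "condition": (
                    ["UNSTIM"] * 2 + ["IFNG_8H"] * 2 + ["WASH_MEDIA"] * 2 + ["WASH_RUX"] * 2
                    + restim_conditions
                ),
                "washout_treatment": (
                    ["none"] * 4 + ["media"] * 2 + ["rux"] * 2
                    + ["media"] * 8 + ["rux"] * 4
                ),
                "timepoint_h": [0, 0, 8, 8, 96, 96, 96, 96] + [t for _ in range(3) for t in grid],
                "replicate": [1, 2] * 4 + [1] * 12,
            }
        )
    )
    gene_counts = CountMatrix(gene_df, gene_design)

    truth = TruthLabels(
        peak_class=pd.Series(
            {
                "pk_persist": "persistent",
                "pk_decay": "decaying",
                "pk_incr": "increasing",
                "pk_null": "null",
                "pk_fill": "null",
            },
            name="planted_class",
        ),
        gene_class=pd.Series(
            {
                "g_ind": "persistent",
                "g_mid": "stim_specific_induced",
                "g_pot": "potentiated_equal_basal",
                "g_pot_hi": "potentiated_elevated_basal",
                "g_tol": "tolerized",
                "g_null": "null",
                "g_fill": "null",
            },
            name="planted_class",
        ),
        couplings=pd.DataFrame(
            {
                "gene_id": ["g_pot", "g_pot_hi", "g_tol"],
                "feature_id": ["pk_persist", "pk_incr", "pk_decay"],
                "strength": [1.0, 1.0, 1.0],
            }
        ),
    )
    config = GeneratorConfig(n_peaks=5, n_genes=7, class_fractions={}, seed=0)
    return SimulatedDataset(peaks, peak_counts, tss, gene_counts, truth, config)
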