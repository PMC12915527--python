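"""End-to-end orchestration of the peak, gene and linkage analyses.

Each stage is a plain function taking a resolved config dict plus either
in-memory objects or the file paths named in the config.  Every run writes
its per-feature tables, a JSON summary whose every number is recomputable
from those tables, and a resolved copy of the config, so results are
reproducible from the output directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, durability, linkage, memory_genes, normalize
from .config import ConfigError
from .io_formats import (
    CountMatrix,
    FeatureSet,
    MemoryCallSet,
    read_bed,
    read_counts,
    read_design,
    read_tss,
    write_report,
)

__all__ = ["run_peaks", "run_genes", "run_link"]

log = logging.getLogger("durens")


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _dump_config(cfg: dict, outdir: Path) -> None:
    _write_json(cfg, outdir / "config.resolved.json")


def _load_peak_inputs(cfg: dict) -> tuple[FeatureSet, CountMatrix]:
    paths = cfg["paths"]
    for key in ("peaks_bed", "peak_counts", "peak_design"):
        if not paths.get(key):
            raise ConfigError(f"paths.{key} is required for the peak analysis")
    design = read_design(paths["peak_design"])
    return read_bed(paths["peaks_bed"]), read_counts(paths["peak_counts"], design)


def run_peaks(
    cfg: dict,
    outdir: str | Path,
    peaks: FeatureSet | None = None,
    counts: CountMatrix | None = None,
) -> dict:
    """Peak pipeline: filter -> differential -> induced -> persistence -> clusters.

    Returns the summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if peaks is None or counts is None:
        peaks, counts = _load_peak_inputs(cfg)
    design = counts.design
    unstim = cfg["conditions"]["unstim"]
    stims = list(cfg["conditions"]["stims"])
    washout = dict(cfg["conditions"]["washout"])
    present = set(design.conditions)
    missing = [c for c in [unstim, *stims, *washout.values()] if c not in present]
    if missing:
        raise ConfigError(f"design lacks conditions required by config: {missing}")

    summary: dict = {"n_peaks": len(counts.counts)}
    cpm_raw = normalize.cpm(counts)
    cpm_pc = normalize.apply_pseudocount(
        cpm_raw,
        policy=cfg["pseudocount"]["policy"],
        percentile=cfg["pseudocount"]["percentile"],
    )
    kept = normalize.acute_abundance_filter(
        cpm_raw,
        acute_conditions=cfg["filter"]["acute_conditions"],
        percentile=cfg["filter"]["percentile"],
    )
    summary["n_after_abundance_filter"] = int(len(kept))
    log.info("abundance filter kept %d / %d peaks", len(kept), len(counts.counts))
    filtered = counts.subset_features(kept)

    floors = cpm_pc.floors

    def _floor(condition: str) -> float:
        return floors.get(condition, floors.get("*", 1.0))

    induced_sets: dict[str, pd.Index] = {}
    for stim in stims:
        disp = differential.estimate_dispersion(
            filtered,
            design.samples_for(unstim),
            design.samples_for(stim),
            shrinkage_weight=cfg["differential"]["shrinkage_weight"],
        )
        res = differential.nb_exact_test(
            filtered,
            design.samples_for(unstim),
            design.samples_for(stim),
            disp,
            cpm_floor_ref=_floor(unstim),
            cpm_floor_trt=_floor(stim),
        )
        res.to_csv(outdir / f"differential_{stim}_vs_{unstim}.tsv", sep="\t")
        induced = differential.call_induced(
            res, cfg["differential"]["l2fc_min"], cfg["differential"]["fdr_max"]
        )
        induced_sets[stim] = induced
        pd.Series(induced).to_csv(
            outdir / f"induced_{stim}.txt", index=False, header=False
        )
        summary[f"n_induced_{stim}"] = int(len(induced))
        log.info("%s vs %s: %d induced peaks", stim, unstim, len(induced))

    stim_condition = cfg["durability"]["stim_condition"]
    induced = induced_sets.get(stim_condition, pd.Index([]))
    washout_results: dict[str, pd.DataFrame] = {}
    for treatment, condition in washout.items():
        disp = differential.estimate_dispersion(
            filtered,
            design.samples_for(unstim),
            design.samples_for(condition),
            shrinkage_weight=cfg["differential"]["shrinkage_weight"],
        )
        res = differential.nb_exact_test(
            filtered,
            design.samples_for(unstim),
            design.samples_for(condition),
            disp,
            cpm_floor_ref=_floor(unstim),
            cpm_floor_trt=_floor(condition),
        )
        res.to_csv(outdir / f"differential_{condition}_vs_{unstim}.tsv", sep="\t")
        washout_results[treatment] = res

    summary["persistence_fraction"] = {}
    if len(induced) > 0:
        calls = durability.call_persistence(
            induced,
            washout_results,
            l2fc_min=cfg["durability"]["persistence"]["l2fc_min"],
            fdr_max=cfg["durability"]["persistence"]["fdr_max"],
        )
        calls.to_csv(outdir / "persistence_calls.tsv", sep="\t", index=False)
        for treatment in washout:
            frac = durability.persistence_fraction(calls, treatment)
            summary["persistence_fraction"][treatment] = frac
            log.info("persistence fraction (%s): %.3f", treatment, frac)

        conditions = [unstim, stim_condition, *washout.values()]
        k = cfg["durability"]["k"]
        if len(induced) >= k:
            clusters = durability.cluster_trajectories(
                cpm_pc,
                induced,
                conditions,
                k=k,
                seed=cfg["durability"]["seed"],
                order_condition=washout.get("media", conditions[-1]),
            )
            clusters.assignments.to_csv(outdir / "clusters.tsv", sep="\t")
            clusters.centroids.to_csv(outdir / "cluster_centroids.tsv", sep="\t")
            summary["cluster_sizes"] = (
                clusters.assignments.value_counts().sort_index().tolist()
            )
            summary["n_unclustered_zero_variance"] = len(clusters.excluded)
    else:
        pd.DataFrame(
            columns=[
                "feature_id",
                "washout_treatment",
                "l2fc_washout_vs_unstim",
                "fdr_washout_vs_unstim",
                "persistent",
            ]
        ).to_csv(outdir / "persistence_calls.tsv", sep="\t", index=False)

    _write_json(summary, outdir / "summary.json")
    _dump_config(cfg, outdir)
    return summary


def run_genes(
    cfg: dict,
    outdir: str | Path,
    counts: CountMatrix | None = None,
    protein_coding: set[str] | None = None,
) -> dict:
    """Gene pipeline: induction -> persistence bands -> potentiation/tolerance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if counts is None:
        paths = cfg["paths"]
        for key in ("gene_counts", "gene_design"):
            if not paths.get(key):
                raise ConfigError(f"paths.{key} is required for the gene analysis")
        design = read_design(paths["gene_design"])
        counts = read_counts(paths["gene_counts"], design)
        if protein_coding is None and paths.get("tss"):
            tss = read_tss(paths["tss"])
            protein_coding = {t.gene_id for t in tss if t.protein_coding}
    design = counts.design

    if protein_coding is not None:
        keep = [g for g in counts.counts.index if g in protein_coding]
        counts = counts.subset_features(keep)
    summary: dict = {"n_genes": len(counts.counts)}

    cpm_pc = normalize.apply_pseudocount(normalize.cpm(counts), policy="fixed_1")
    mc = cfg["memory"]
    cond = cfg["conditions"]

    calls = pd.DataFrame(index=counts.counts.index.copy())
    calls.index.name = "gene_id"

    present = set(design.conditions)
    has_wash_design = cond["gene_unstim"] in present and cond["gene_stim"] in present
    if has_wash_design:
        cpm_unstim = cpm_pc.condition_mean(cond["gene_unstim"])
        cpm_stim = cpm_pc.condition_mean(cond["gene_stim"])
        induced = memory_genes.call_induced_genes(cpm_unstim, cpm_stim, mc["fold_min"])
        calls["induced_8h"] = calls.index.isin(induced)
        summary["n_induced_genes"] = int(len(induced))
        for treatment, condition in cond["gene_washout"].items():
            if condition not in present:
                continue
            percent = memory_genes.persistence_percent(
                cpm_pc.condition_mean(condition), cpm_stim
            )
            band = memory_genes.persistence_band(percent)
            calls[f"persistence_percent_{treatment}"] = percent
            calls[f"persistence_band_{treatment}"] = band
            counts_by_band = (
                band[calls["induced_8h"]].value_counts().reindex(memory_genes.BANDS).fillna(0)
            )
            summary[f"band_counts_{treatment}"] = {
                b: int(n) for b, n in counts_by_band.items()
            }

    arms_needed = list(cond["restim_arms"])
    grid = [float(t) for t in cond["restim_grid"]]
    template = cond["restim_template"]
    arm_maps = {
        arm: {t: template.format(arm=arm, t=t) for t in grid} for arm in arms_needed
    }
    have_restim = all(
        c in present for m in arm_maps.values() for c in m.values()
    )
    if have_restim:
        tc = memory_genes.build_timecourse(cpm_pc, arm_maps)
        lps_induced = memory_genes.lps_induction(
            tc, (mc["pbs_arm"], mc["ifng_arm"]), mc["pbs_arm"]
        ) >= mc["lps_fold_min"]
        potentiated = memory_genes.call_potentiated(
            tc,
            pbs_arm=mc["pbs_arm"],
            ifng_arm=mc["ifng_arm"],
            lps_fold_min=mc["lps_fold_min"],
            delta_fold_min=mc["delta_fold_min"],
            contiguous=mc["contiguous"],
        )
        tolerized = memory_genes.call_tolerized(
            tc,
            pbs_arm=mc["pbs_arm"],
            ifng_arm=mc["ifng_arm"],
            rux_arm=mc["rux_arm"],
            reduction_fold_min=mc["reduction_fold_min"],
            contiguous=mc["contiguous"],
            rux_induction_min=mc["rux_induction_min"],
        )
        basal = memory_genes.split_basal(
            tc, mc["pbs_arm"], mc["ifng_arm"], mc["basal_l2fc"]
        )
        mean_pot = memory_genes.mean_potentiation(tc, mc["pbs_arm"], mc["ifng_arm"])
        calls["lps_induced"] = lps_induced.reindex(calls.index)
        calls["potentiated"] = potentiated.reindex(calls.index)
        calls["tolerized"] = tolerized.reindex(calls.index)
        calls["basal_elevated"] = basal.reindex(calls.index)
        calls["mean_potentiation"] = mean_pot.reindex(calls.index)
        summary["n_lps_induced"] = int(calls["lps_induced"].sum())
        summary["n_potentiated"] = int(calls["potentiated"].sum())
        summary["n_tolerized"] = int(calls["tolerized"].sum())
        summary["n_potentiated_basal_elevated"] = int(
            (calls["potentiated"] & calls["basal_elevated"]).sum()
        )
        summary["n_potentiated_basal_equal"] = int(
            (calls["potentiated"] & ~calls["basal_elevated"]).sum()
        )

    report = MemoryCallSet(calls, params={"thresholds": mc, "seed": cfg["seed"]})
    write_report(report, outdir / "gene_calls.tsv")
    _write_json(summary, outdir / "summary.json")
    _dump_config(cfg, outdir)
    return summary


def run_link(
    cfg: dict,
    outdir: str | Path,
    peaks: FeatureSet | None = None,
    tss=None,
    gene_calls: pd.DataFrame | None = None,
    washout_l2fc: pd.Series | None = None,
    induced_peaks=None,
    peaks_outdir: str | Path | None = None,
    genes_outdir: str | Path | None = None,
) -> dict:
    """Linkage stage: TSS-window links plus potentiation/durability correlation.

    Inputs may be in-memory, or recovered from previous ``run_peaks`` /
    ``run_genes`` output directories.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cond = cfg["conditions"]
    if peaks is None:
        peaks = read_bed(cfg["paths"]["peaks_bed"])
    if tss is None:
        tss = read_tss(cfg["paths"]["tss"])
    if gene_calls is None:
        genes_outdir = Path(genes_outdir)
        gene_calls = pd.read_csv(genes_outdir / "gene_calls.tsv", sep="\t", index_col=0)
    if washout_l2fc is None or induced_peaks is None:
        peaks_outdir = Path(peaks_outdir)
        media = cond["washout"]["media"]
        diff = pd.read_csv(
            peaks_outdir / f"differential_{media}_vs_{cond['unstim']}.tsv",
            sep="\t",
            index_col=0,
        )
        washout_l2fc = diff["l2fc"]
        stim = cfg["durability"]["stim_condition"]
        induced_path = peaks_outdir / f"induced_{stim}.txt"
        induced_peaks = pd.read_csv(induced_path, header=None)[0].astype(str).tolist()

    induced_fs = peaks.subset(induced_peaks) if induced_peaks is not None else peaks
    links = linkage.link_peaks_to_genes(
        induced_fs,
        tss,
        window=cfg["linkage"]["window"],
        promoter_window=cfg["linkage"]["promoter_window"],
    )
    links.to_csv(outdir / "links.tsv", sep="\t", index=False)
    summary: dict = {"n_links": int(len(links))}
    lps_induced = (
        gene_calls.index[gene_calls["lps_induced"].fillna(False).astype(bool)]
        if "lps_induced" in gene_calls
        else gene_calls.index
    )
    try:
        pairs, rho, p = linkage.potentiation_vs_durability(
            links,
            gene_calls["mean_potentiation"].dropna(),
            washout_l2fc,
            gene_subset=lps_induced,
        )
        pairs.to_csv(outdir / "potentiation_pairs.tsv", sep="\t", index=False)
        summary["spearman_rho"] = rho
        summary["spearman_p"] = p
        summary["n_pairs"] = int(len(pairs))
    except ValueError as exc:
        summary["spearman_rho"] = None
        summary["note"] = str(exc)
    _write_json(summary, outdir / "summary.json")
    _dump_config(cfg, outdir)
    return summary
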