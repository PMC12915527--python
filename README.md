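# durens

**Durability of stimulus-induced enhancers and gene-expression memory in
macrophages.**

Terminally differentiated macrophages remember a cytokine exposure: an 8-hour
IFNγ pulse leaves behind *de novo* enhancer marks (H3K4me1), open chromatin
and elevated interferon-stimulated gene expression that can persist for days
after the cytokine is washed out — unless IFNγ→JAK/STAT signaling is blocked
(ruxolitinib, anti-IFNγ antibody), in which case the landscape reverts to
baseline. The memory also reprograms the LPS response: some LPS-inducible
genes become *potentiated* (stronger induction after IFNγ pretreatment),
others *tolerized* (weaker induction).

`durens` is the analysis layer for this kind of stimulus → washout →
restimulation experiment. It starts from plain count tables (reads in peaks
from CUT&Tag/ATAC, gene-level RNA-seq counts) and a sample-design table, and
provides, as a tested reusable pipeline:

* **normalize** — CPM normalization, pseudocount floors (per-condition 1st
  percentile for peak assays, CPM 1 for genes), and the acute-stimulation
  abundance filter (keep peaks in the top half of abundance in at least one
  acute condition).
* **differential** — a conditional negative-binomial exact test
  (Robinson–Smyth style) per feature between two condition groups, with
  method-of-moments dispersion estimation shrunk toward a common value,
  BH-FDR, and the induced-feature gate **L2FC > 2, FDR < 0.01**.
* **durability** — persistence calls after washout (**L2FC ≥ 0, FDR < 0.01**
  against the unstimulated baseline), persistence fractions per post-washout
  treatment, paired Wilcoxon signed-rank statistics for population shifts,
  and k-means clustering of Z-scored condition-mean trajectories (k = 3 by
  default: persist / decay / further increase).
* **memory_genes** — gene-level rules: ≥5-fold induction, washout
  persistence bands (≥90%, 20–90%, <20% of the 8-h CPM), potentiated and
  tolerized LPS-response calls with the two-contiguous-timepoint criterion,
  the basal set-point split at L2FC 0.5, and the per-gene mean potentiation
  score.
* **linkage** — enhancer–gene assignment within ±20 kb of a protein-coding
  TSS (±1 kb promoter-proximal peaks excluded) and the Spearman correlation
  between gene potentiation and linked-enhancer durability.
* **synthetic_data** — a negative-binomial simulator that plants all of the
  above classes with known labels, so the entire pipeline is testable
  without any external download.
* **pipeline / cli** — `durens simulate | peaks | genes | link` with YAML
  config, seeds, and deterministic outputs.

## Worked example

Simulate a labelled dataset and run all three stages:

```bash
printf 'n_peaks: 2000\nn_genes: 2000\n' > sim.yaml
durens simulate --config sim.yaml --out sim --seed 1

cat > run.yaml <<EOF
paths:
  peaks_bed: sim/peaks.bed
  peak_counts: sim/peak_counts.tsv
  peak_design: sim/peak_design.tsv
  gene_counts: sim/gene_counts.tsv
  gene_design: sim/gene_design.tsv
  tss: sim/tss.tsv
EOF

durens peaks --config run.yaml --out peaks_run
durens genes --config run.yaml --out genes_run
durens link  --config run.yaml --out link_run --peaks-out peaks_run --genes-out genes_run
```

`peaks_run/summary.json` from this exact run:

```json
{
  "n_peaks": 2000,
  "n_after_abundance_filter": 1213,
  "n_induced_IFNG_8H": 144,
  "n_induced_LPS_8H": 75,
  "n_induced_LPS_RUX_8H": 38,
  "persistence_fraction": {"media": 0.4375, "rux": 0.0, "anti_ifng": 0.0},
  "cluster_sizes": [59, 49, 36],
  "n_unclustered_zero_variance": 0
}
```

Reading it: of 2000 simulated peaks, 1213 pass the acute-abundance filter;
144 are called IFNγ-induced at the L2FC > 2 / FDR < 0.01 gate. After washout,
44% of the induced peaks are still significantly above baseline when cells
stay in plain media, and none are when JAK signaling is blocked — the planted
blockade effect. The three k-means clusters are the persist / decay /
further-increase trajectory patterns.

`genes_run/summary.json` (same run) reports 159 genes ≥5-fold induced, their
washout bands (46 / 78 / 35 genes at ≥90% / 20–90% / <20% retention in media
versus 0 / 8 / 151 under ruxolitinib), 47 potentiated genes (15 with an equal
and 32 with an elevated basal set-point) and 20 tolerized genes.
`link_run/summary.json` gives the potentiation–durability coupling across 31
enhancer–gene pairs: Spearman ρ = 0.70, p = 1.4e-05.

Per-feature tables (differential results, persistence calls, cluster
assignments, gene calls, links) are written next to each summary as TSV, and
a resolved copy of the config is stored in every output directory.

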