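# crelink

Inference of cis-regulatory-element → gene regulatory relationships from
**paired single-cell chromatin-accessibility (CA) and gene-expression (GE)
profiles** — the setting where both modalities are measured in the *same*
cell, so the co-variation between the accessibility of an individual peak
and the expression of a nearby gene can be read directly across cells.

The package is aimed at computational biologists analysing joint
scATAC+scRNA data (or realistic simulations of it) who want per-cell
regulatory links, the cell identities those links define, and TF-level
accessibility summaries.

## What it computes

Given a peaks × cells fragment-count matrix, a genes × cells expression
count matrix, peak intervals, gene TSS annotation and TF motifs
(JASPAR-style PFMs), `crelink` infers peak → gene links by three
strategies:

1. **Accessibility co-variation** — for each gene, the weighted Spearman
   correlation ρ between a promoter peak (TSS ± 2 kb) and each distal peak
   within 1 Mb; a link is assigned when ρ > 0.25 for at least one NMF
   signature, using that signature's per-cell exposures *h<sub>k</sub>* as
   weights (so correlations are not diluted by subpopulation structure).
2. **Paired co-variation** — the same screen with the gene's normalized
   expression as the response.
3. **Per-cell partition test** — regulons (a TF plus its co-expressed
   targets) are scored per cell by the area under the recovery curve of
   their genes in the top 5 % of the cell's expression ranking; each TF is
   called active/inactive from the bimodal AUC distribution; a peak is
   *active* in a cell when it carries a motif of an active TF (≥ 95 % of
   the motif's best attainable log-odds score) plus a fragment; a link is
   assigned when a Wilcoxon rank-sum test of the gene's expression across
   the active/inactive cell partition gives p < 0.05.

Strategy 3 yields a **binary links × cells matrix** of per-cell on/off
states.  Non-negative matrix factorization *V ≈ WH* over ranks K ∈ [2, 6]
(rank selected by the Frobenius-error elbow, the mean Amari distance
across restarts, and the cophenetic correlation of the consensus matrix)
decomposes it into signatures that separate cell identities.  The package
also computes chromVAR-style per-TF accessibility deviation z-scores with
accessibility-matched background peak sets, validates links against
chromatin-interaction (BEDPE) anchors, and ships a seed-reproducible
synthetic paired-omics generator with planted ground truth.

Normalization follows pooled-size-factor deconvolution (ring-ordered cell
pools, least-squares solution, rescaled to mean 1); features are filtered
to those detected in ≥ 10 % of cells (peaks need > 1 fragment to count as
detected).

## Worked example

```python
from crelink import SynthConfig, evaluate_links, generate, run_paired_pipeline

dataset = generate(SynthConfig())          # 300 cells, 3 types, 100 planted links
result = run_paired_pipeline(
    dataset.pair, dataset.pwms, sequences=dataset.sequences,
    seed=1, strategies=(3,), link_nmf=True,
)
ev = evaluate_links(result.links_by_strategy[3], result.pair.peaks, dataset.truth)
print(f"precision: {ev.precision:.3f}  recall: {ev.recall:.3f}  F1: {ev.f1:.3f}")
print(f"selected NMF rank: {result.link_nmf_rank}")
```

prints

```
precision: 0.990  recall: 1.000  F1: 0.995
selected NMF rank: 3
```

i.e. 101 links were inferred of which 100 are the planted ones, every
planted link was recovered at p < 0.05, and rank selection on the binary
link matrix finds the three planted subpopulations (their exposure argmax
clusters the cells with adjusted Rand index 1.0).  The scripts under
`examples/` walk through each capability — link inference and evaluation,
comparing the three strategies and validating against interaction
anchors, NMF signatures of the link matrix, and TF deviation scores —
each printing the numbers it computes and a note on what they mean.

A thin command line mirrors the library (`crelink simulate`, `filter`,
`normalize`, `tfactivity`, `nmf`, `deviations`, `validate`, and `run` for
a YAML-configured end-to-end pipeline with a reproducibility manifest).

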