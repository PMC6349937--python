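"""End-to-end orchestration of the link-inference stages.

Two entry points:

* :func:`run_paired_pipeline` — the in-memory engine: filter, normalize,
  build regulons, call TF activity, scan motifs, label active regions,
  infer links by the requested strategies and factorize the per-cell link
  matrix.  Used directly from Python and by the evaluation utilities.
* :func:`run_pipeline` — the configuration-file driver behind the command
  line: reads a YAML config (with either a ``simulate`` block or input
  file paths), executes the requested stages, writes every intermediate
  in its interchange format and records a reproducibility manifest.

One master seed fans out to deterministic per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chromdev import (
    DeviationResult,
    annotate_motif_peaks,
    compute_deviations,
    sample_background_peaks,
)
from .chiavalid import strategy_overlap, validation_proportion
from .iofmt import (
    GeneRecord,
    GenomicInterval,
    InteractionRecord,
    PWMRecord,
    read_bed,
    read_bedpe,
    read_count_matrix,
    read_gene_annotation,
    read_jaspar_pfm,
    write_count_matrix,
    write_links,
)
from .linkinfer import (
    LinkMatrix,
    RegulatoryLink,
    count_tested_pairs,
    strategy1_links,
    strategy2_links,
    strategy3_links,
)
from .matrixcore import OmicsPair, filter_features, normalize, pooled_size_factors
from .nmfsig import NMFResult, nmf_factorize, select_rank
from .synthgen import SynthConfig, SyntheticDataset, generate
from .tfmotif import (
    MotifHitIndex,
    TFActivity,
    build_motif_hit_index,
    build_regulons,
    call_tf_activity,
    label_active_regions,
)

logger = logging.getLogger(__name__)

# fixed offsets fanning the master seed out to stages
_SEED_ACTIVITY = 101
_SEED_NMF_EXPOSURE = 202
_SEED_NMF_LINKS = 303
_SEED_BACKGROUND = 404


@dataclass
class PipelineResult:
    """All intermediates of one pipeline run."""

    pair: OmicsPair  # filtered counts
    peak_subset: np.ndarray  # indices into the pre-filter peak list
    ca_norm: pd.DataFrame
    ge_norm: pd.DataFrame
    regulons: list
    tf_activity: TFActivity | None
    hit_index: MotifHitIndex | None
    active_mask: np.ndarray | None
    links_by_strategy: dict[int, list[RegulatoryLink]]
    link_matrix: LinkMatrix | None
    link_nmf: NMFResult | None = None
    link_nmf_rank: int | None = None
    link_nmf_metrics: pd.DataFrame | None = None
    deviations: DeviationResult | None = None

    @property
    def all_links(self) -> list[RegulatoryLink]:
        return [l for links in self.links_by_strategy.values() for l in links]


def run_paired_pipeline(
    pair: OmicsPair,
    pwms: Sequence[PWMRecord],
    sequences: Sequence[str] | None = None,
    hit_index: MotifHitIndex | None = None,
    seed: int = 0,
    strategies: Sequence[int] = (1, 2, 3),
    min_cell_fraction: float = 0.10,
    ca_min_fragments: int = 2,
    rho_threshold: float = 0.25,
    alpha: float = 0.05,
    window: float = 1_000_000,
    promoter_window: int = 2_000,
    min_group: int = 3,
    corr_min: float = 0.3,
    min_regulon_size: int = 10,
    top_frac: float = 0.05,
    match_fraction: float = 0.95,
    exposure_rank: int = 3,
    exposure_restarts: int = 3,
    exposure_max_iter: int = 300,
    link_nmf: bool = True,
    link_k_range: tuple[int, int] = (2, 6),
    link_nmf_restarts: int = 20,
    run_deviations: bool = False,
) -> PipelineResult:
    """Run filtering, normalization, TF activity, linking and NMF.

    ``sequences`` (per pre-filter peak) or a precomputed ``hit_index``
    (indexed by pre-filter peak position) supplies the motif evidence for
    strategy 3; with neither, only strategies 1-2 can run.
    """
    full_peak_names = list(pair.ca.index)
    filtered = filter_features(pair, min_cell_fraction, ca_min_fragments)
    name_pos = {n: i for i, n in enumerate(full_peak_names)}
    peak_subset = np.array([name_pos[n] for n in filtered.ca.index])

    sf_ca = pooled_size_factors(filtered.ca)
    sf_ge = pooled_size_factors(filtered.ge)
    ca_norm = normalize(filtered.ca, sf_ca)
    ge_norm = normalize(filtered.ge, sf_ge)

    tf_names = [p.tf_name for p in pwms]
    regulons = build_regulons(
        ge_norm, tf_names, corr_min=corr_min, min_size=min_regulon_size
    )

    activity: TFActivity | None = None
    mask: np.ndarray | None = None
    sub_index: MotifHitIndex | None = None
    if 3 in strategies:
        if hit_index is None:
            if sequences is None:
                raise ValueError("strategy 3 needs peak sequences or a motif hit index")
            sub_sequences = [sequences[i] for i in peak_subset]
            sub_index = build_motif_hit_index(sub_sequences, pwms, match_fraction)
        else:
            sub_index = MotifHitIndex()
            for new_idx, old_idx in enumerate(peak_subset):
                for tf, frac in hit_index.hits.get(old_idx, {}).items():
                    sub_index.add(new_idx, tf, frac)
        if not regulons:
            raise ValueError("no regulons could be built; strategy 3 cannot run")
        activity = call_tf_activity(ge_norm, regulons, top_frac, seed=seed + _SEED_ACTIVITY)
        mask = label_active_regions(filtered.peaks, sub_index, activity, filtered.ca)

    links_by_strategy: dict[int, list[RegulatoryLink]] = {}
    if 1 in strategies:
        ca_nmf = nmf_factorize(
            ca_norm, exposure_rank, exposure_restarts, exposure_max_iter,
            seed=seed + _SEED_NMF_EXPOSURE,
        )
        links_by_strategy[1] = strategy1_links(
            ca_norm, filtered.peaks, filtered.genes, ca_nmf.H,
            rho_threshold, window, promoter_window,
        )
    if 2 in strategies:
        ge_nmf = nmf_factorize(
            ge_norm, exposure_rank, exposure_restarts, exposure_max_iter,
            seed=seed + _SEED_NMF_EXPOSURE + 1,
        )
        links_by_strategy[2] = strategy2_links(
            ca_norm, ge_norm, filtered.peaks, filtered.genes, ge_nmf.H,
            rho_threshold, window, promoter_window,
        )
    link_matrix: LinkMatrix | None = None
    if 3 in strategies:
        assert mask is not None
        links3, link_matrix = strategy3_links(
            ge_norm, mask, filtered.peaks, filtered.genes, window, alpha, min_group
        )
        links_by_strategy[3] = links3

    result = PipelineResult(
        pair=filtered,
        peak_subset=peak_subset,
        ca_norm=ca_norm,
        ge_norm=ge_norm,
        regulons=regulons,
        tf_activity=activity,
        hit_index=sub_index,
        active_mask=mask,
        links_by_strategy=links_by_strategy,
        link_matrix=link_matrix,
    )

    if link_nmf and link_matrix is not None and link_matrix.matrix.shape[0] >= link_k_range[0] + 1:
        best_k, metrics, factorizations = select_rank(
            link_matrix.matrix.astype(float),
            k_range=link_k_range,
            n_restarts=link_nmf_restarts,
            seed=seed + _SEED_NMF_LINKS,
        )
        result.link_nmf_rank = best_k
        result.link_nmf_metrics = metrics
        result.link_nmf = factorizations[best_k]

    if run_deviations and sub_index is not None:
        annotation = annotate_motif_peaks(sub_index, len(filtered.peaks), tf_names)
        backgrounds = sample_background_peaks(
            filtered.ca.to_numpy().mean(axis=1), seed=seed + _SEED_BACKGROUND
        )
        result.deviations = compute_deviations(filtered.ca, annotation, backgrounds)
    return result


def permuted_mask_link_rate(
    ge_norm: pd.DataFrame,
    active_mask: np.ndarray,
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    n_rounds: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    window: float = 1_000_000,
    min_group: int = 3,
) -> tuple[float, int]:
    """Type-I-error check: link rate after permuting each mask row.

    Each round independently shuffles every peak's active-cell set across
    cells, destroying the mask/expression alignment while preserving each
    row's on-count; the returned rate is total links over total tested
    pairs, which should sit near ``alpha`` under the null.
    """
    rng = np.random.default_rng(seed)
    total_links = 0
    total_tested = 0
    gene_ids = [g.gene_id for g in genes if g.gene_id in ge_norm.index]
    for _ in range(n_rounds):
        permuted = np.empty_like(active_mask)
        for i in range(active_mask.shape[0]):
            permuted[i] = active_mask[i, rng.permutation(active_mask.shape[1])]
        links, _ = strategy3_links(
            ge_norm, permuted, peaks, genes, window, alpha, min_group
        )
        total_links += len(links)
        total_tested += count_tested_pairs(
            permuted, peaks, genes, gene_ids, window, min_group
        )
    if total_tested == 0:
        raise ValueError("no testable pairs under the permuted mask")
    return total_links / total_tested, total_tested


def interactions_from_truth(truth, promoter_window: int = 1000) -> list[InteractionRecord]:
    """Synthetic chromatin interactions joining every planted link's peak
    to its target promoter (for validation arithmetic on generated data)."""
    genes_tss = {l.gene_id: None for l in truth.links}
    records = []
    for link in truth.links:
        peak = truth.peaks[link.peak_index]
        # the planted target TSS is recoverable from the promoter peak center
        prom = truth.peaks[truth.promoter_peaks[link.gene_id]]
        tss = int(prom.midpoint)
        records.append(
            InteractionRecord(
                GenomicInterval(peak.chrom, peak.start, peak.end),
                GenomicInterval(peak.chrom, max(0, tss - promoter_window), tss + promoter_window),
            )
        )
    return records


# ---------------------------------------------------------------------------
# configuration-file driver


def _load_inputs(cfg: dict[str, Any]) -> tuple[OmicsPair, list[PWMRecord], list[str] | None]:
    inputs = cfg["inputs"]
    peaks = read_bed(inputs["peaks_bed"])
    dialect = inputs.get("annotation_dialect", "gtf")
    genes = read_gene_annotation(inputs["gene_annotation"], dialect)
    ca = read_count_matrix(
        inputs["ca_matrix"], inputs.get("ca_rows"), inputs.get("ca_cols")
    )
    ge = read_count_matrix(
        inputs["ge_matrix"], inputs.get("ge_rows"), inputs.get("ge_cols")
    )
    pair = OmicsPair(ca=ca, ge=ge, peaks=peaks, genes=genes)
    pwms = read_jaspar_pfm(inputs["pfm"]) if "pfm" in inputs else []
    sequences = None
    if "peak_sequences" in inputs:
        sequences = [
            l.strip() for l in Path(inputs["peak_sequences"]).read_text().splitlines() if l.strip()
        ]
    return pair, pwms, sequences


def _write_dataset(dataset: SyntheticDataset, out: Path) -> None:
    write_count_matrix(dataset.pair.ca, out / "ca_counts.mtx")
    write_count_matrix(dataset.pair.ge, out / "ge_counts.mtx")
    with open(out / "peaks.bed", "w") as fh:
        for p in dataset.pair.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t.\t0\t{p.strand}\n")
    with open(out / "genes.tss.tsv", "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tstart\tend\n")
        for g in dataset.pair.genes:
            iv = g.interval
            fh.write(f"{g.gene_id}\t{iv.chrom}\t{g.tss}\t{iv.strand}\t{iv.start}\t{iv.end}\n")
    with open(out / "motifs.pfm", "w") as fh:
        for pwm in dataset.pwms:
            fh.write(f">{pwm.tf_name}\n")
            counts = np.round(pwm.matrix * 1000).astype(int)
            for row in counts.T:
                fh.write("\t".join(map(str, row)) + "\n")
    (out / "peak_sequences.txt").write_text("\n".join(dataset.sequences) + "\n")
    truth = dataset.truth
    with open(out / "truth_links.tsv", "w") as fh:
        fh.write("peak_index\tgene_id\ttf_name\tcell_type\teffect\n")
        for l in truth.links:
            fh.write(f"{l.peak_index}\t{l.gene_id}\t{l.tf_name}\t{l.cell_type}\t{l.effect}\n")
    pd.Series(truth.cell_types, index=dataset.pair.cells, name="cell_type").to_csv(
        out / "truth_cell_types.tsv", sep="\t"
    )


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the stages named in a YAML configuration file.

    The config either carries a ``simulate`` block (generator settings) or
    an ``inputs`` block with file paths.  Outputs, logs and a manifest
    (package/library versions, master seed, a hash of the full parameter
    set and per-stage matrix shapes) are written to the output directory.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text()) or {}
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'simulate' or 'inputs' block")
    out = Path(out_dir or cfg.get("out", "crelink_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages")
    params = cfg.get("params", {})

    manifest: dict[str, Any] = {
        "package": "crelink",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "parameter_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }

    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs.setdefault("seed", seed)
        dataset = generate(SynthConfig(**sim_kwargs))
        _write_dataset(dataset, out)
        pair, pwms, sequences = dataset.pair, dataset.pwms, dataset.sequences
        manifest["stages"]["simulate"] = {
            "n_peaks": pair.ca.shape[0],
            "n_genes": pair.ge.shape[0],
            "n_cells": pair.n_cells,
            "n_planted_links": len(dataset.truth.links),
        }
        if stages is not None and stages == ["simulate"]:
            _finish_manifest(out, manifest)
            return out
    elif "inputs" in cfg:
        pair, pwms, sequences = _load_inputs(cfg)
        manifest["stages"]["load"] = {
            "n_peaks": pair.ca.shape[0],
            "n_genes": pair.ge.shape[0],
            "n_cells": pair.n_cells,
        }
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")

    strategies = tuple(params.get("strategies", (1, 2, 3)))
    result = run_paired_pipeline(
        pair,
        pwms,
        sequences=sequences,
        seed=seed,
        strategies=strategies,
        **{
            k: params[k]
            for k in (
                "min_cell_fraction", "ca_min_fragments", "rho_threshold", "alpha",
                "window", "promoter_window", "min_group", "corr_min",
                "min_regulon_size", "top_frac", "match_fraction", "exposure_rank",
            )
            if k in params
        },
        run_deviations=bool(params.get("deviations", True)),
    )

    manifest["stages"]["filter"] = {
        "n_peaks": result.pair.ca.shape[0],
        "n_genes": result.pair.ge.shape[0],
    }
    if result.tf_activity is not None:
        result.tf_activity.auc.to_csv(out / "tf_auc.tsv", sep="\t")
        result.tf_activity.active.to_csv(out / "tf_active.tsv", sep="\t")
        manifest["stages"]["tfactivity"] = {"n_regulons": len(result.regulons)}
    for s, links in result.links_by_strategy.items():
        write_links(links, result.pair.peaks, out / f"links_strategy{s}.tsv")
        manifest["stages"][f"link_strategy{s}"] = {"n_links": len(links)}
    if result.link_matrix is not None and len(result.link_matrix.links):
        result.link_matrix.to_frame().to_csv(out / "link_matrix.tsv", sep="\t")
    if result.link_nmf is not None:
        result.link_nmf_metrics.to_csv(out / "nmf_rank_metrics.tsv", sep="\t")
        np.savetxt(out / "nmf_W.tsv", result.link_nmf.W, delimiter="\t")
        np.savetxt(out / "nmf_H.tsv", result.link_nmf.H, delimiter="\t")
        manifest["stages"]["nmf"] = {"selected_rank": result.link_nmf_rank}
    if result.deviations is not None:
        result.deviations.deviations.to_csv(out / "deviation_z.tsv", sep="\t")
        result.deviations.variability.to_csv(out / "variability.tsv", sep="\t")
        manifest["stages"]["deviations"] = {
            "n_motifs": result.deviations.deviations.shape[0]
        }
    if "bedpe" in cfg.get("inputs", {}):
        interactions = read_bedpe(cfg["inputs"]["bedpe"])
        props = validation_proportion(
            result.all_links, result.pair.peaks, result.pair.genes, interactions
        )
        pd.DataFrame(props).T.to_csv(out / "validation.tsv", sep="\t")
        manifest["stages"]["validate"] = {
            str(s): v["proportion"] for s, v in props.items()
        }
    if len(result.links_by_strategy) > 1:
        overlap = strategy_overlap(result.links_by_strategy)
        (out / "strategy_overlap.json").write_text(json.dumps(overlap, indent=2))

    _finish_manifest(out, manifest)
    return out


def _finish_manifest(out: Path, manifest: dict[str, Any]) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
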