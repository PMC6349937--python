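"""Seed-reproducible synthetic paired accessibility/expression data.

The generator emulates the statistical structure the link-inference
pipeline consumes: several cell subpopulations, TF activity programs per
subpopulation, motif-bearing peaks whose accessibility is raised where
their TF is active, and planted peak -> gene regulatory links that raise
target-gene expression in the same cells.  Accessibility counts are
Poisson (sparse), expression counts are negative binomial (over-dispersed)
with Bernoulli dropout.

Genome layout.  Every planted link lives in its own 2.4 Mb block on
chromosome ``chrL``: the target gene's TSS at the block center, a
co-modulated promoter peak over the TSS, and one motif-bearing distal
peak at an exponentially distributed distance (proximal-biased, as real
links are).  TF genes sit on ``chrT``; decoy genes and decoy peaks sit on
two further, mutually distant chromosomes.  The separation means the
1 Mb test window of any distal peak contains exactly its own target
gene, so precision/recall against the planted truth measure the
statistical power of the inference rather than layout confounding; the
methods note discusses what this does and does not represent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .iofmt import GeneRecord, GenomicInterval, PWMRecord
from .linkinfer import RegulatoryLink
from .matrixcore import OmicsPair

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

BLOCK_WIDTH = 2_400_000
MIN_LINK_DISTANCE = 20_000
MAX_LINK_DISTANCE = 900_000
LINK_DISTANCE_SCALE = 150_000


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the package's reference
    conditions for end-to-end evaluation."""

    n_cells: int = 300
    n_cell_types: int = 3
    n_genes: int = 500
    n_peaks: int = 2000
    n_tfs: int = 10
    n_links: int = 100
    link_effect_size: float = 1.0  # log2 fold change on active target expression
    ca_mean_fragments: float = 2.0  # baseline Poisson mean per peak and cell
    ca_activity_multiplier: float = 3.0  # accessibility gain where the TF is active
    ge_mean_counts: float = 10.0  # baseline NB mean per gene and cell
    ge_dispersion: float = 0.1  # NB dispersion (var = mu + mu^2 * disp)
    dropout_rate: float = 0.1  # Bernoulli zeroing of expression entries
    tf_expression_log2fc: float = 2.0  # TF gene elevation in its active types
    motif_length: int = 10
    peak_length: int = 200
    seed: int = 17

    def __post_init__(self) -> None:
        for name in (
            "n_cells", "n_cell_types", "n_genes", "n_peaks", "n_tfs", "n_links",
            "motif_length", "peak_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if 2 * self.n_links > self.n_peaks:
            raise ValueError(
                f"cannot place {self.n_links} links (2 peaks each) in {self.n_peaks} peaks"
            )
        if self.n_links + self.n_tfs > self.n_genes:
            raise ValueError("n_genes must cover target and TF genes")
        if self.n_cell_types > self.n_cells:
            raise ValueError("more cell types than cells")


@dataclass(frozen=True)
class PlantedLink:
    peak_index: int  # distal, motif-bearing peak
    gene_id: str
    tf_name: str
    cell_type: int
    effect: float


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for recovery evaluation."""

    cell_types: np.ndarray  # per-cell type label
    active_tfs_by_type: dict[int, list[str]]
    links: list[PlantedLink]
    motif_placements: dict[int, tuple[str, int, str]]  # peak -> (tf, offset, strand)
    promoter_peaks: dict[str, int]  # gene_id -> promoter peak index
    peaks: list[GenomicInterval] = field(repr=False, default_factory=list)
    config: SynthConfig | None = None

    def tf_active_in_cell(self, tf_name: str) -> np.ndarray:
        """Planted per-cell activity of one TF (boolean over cells)."""
        active_types = {
            t for t, tfs in self.active_tfs_by_type.items() if tf_name in tfs
        }
        return np.isin(self.cell_types, list(active_types))


@dataclass
class SyntheticDataset:
    pair: OmicsPair
    pwms: list[PWMRecord]
    sequences: list[str]
    truth: SyntheticTruth


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _consensus_pwm(tf_name: str, consensus: str, hit_count: int = 85, miss_count: int = 5) -> PWMRecord:
    counts = np.full((len(consensus), 4), float(miss_count))
    for i, base in enumerate(consensus):
        counts[i, "ACGT".index(base)] = hit_count
    smoothed = counts + 1.0
    return PWMRecord(tf_name, smoothed / smoothed.sum(axis=1, keepdims=True), 1.0)


def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate(config: SynthConfig | None = None) -> SyntheticDataset:
    """Generate one paired dataset with planted structure.

    All randomness flows from ``config.seed``; a fixed config yields
    byte-identical matrices across runs.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- cells and programs -------------------------------------------------
    cell_types = rng.permutation(np.arange(cfg.n_cells) % cfg.n_cell_types)
    cells = [f"cell{i:04d}" for i in range(cfg.n_cells)]
    tf_names = [f"TF{i:02d}" for i in range(cfg.n_tfs)]
    tf_type = {tf: i % cfg.n_cell_types for i, tf in enumerate(tf_names)}
    active_tfs_by_type = {
        t: [tf for tf in tf_names if tf_type[tf] == t] for t in range(cfg.n_cell_types)
    }
    type_masks = {
        t: cell_types == t for t in range(cfg.n_cell_types)
    }

    # --- motifs -------------------------------------------------------------
    pwms = [
        _consensus_pwm(tf, _random_sequence(rng, cfg.motif_length)) for tf in tf_names
    ]
    consensus = {p.tf_name: p.consensus for p in pwms}

    # --- genome layout ------------------------------------------------------
    peaks: list[GenomicInterval] = []
    genes: list[GeneRecord] = []
    sequences: list[str] = []
    links: list[PlantedLink] = []
    motif_placements: dict[int, tuple[str, int, str]] = {}
    promoter_peaks: dict[str, int] = {}

    n_targets = cfg.n_links
    n_null_genes = cfg.n_genes - n_targets - cfg.n_tfs
    n_null_peaks = cfg.n_peaks - 2 * cfg.n_links

    # planted link blocks on chrL
    for i in range(cfg.n_links):
        tf = tf_names[i % cfg.n_tfs]
        ctype = tf_type[tf]
        gene_id = f"G{i:04d}"
        tss = i * BLOCK_WIDTH + BLOCK_WIDTH // 2
        genes.append(GeneRecord(gene_id, GenomicInterval("chrL", tss, tss + 1000, "+")))

        prom_start = tss - cfg.peak_length // 2
        promoter_idx = len(peaks)
        peaks.append(GenomicInterval("chrL", prom_start, prom_start + cfg.peak_length))
        sequences.append(_random_sequence(rng, cfg.peak_length))
        promoter_peaks[gene_id] = promoter_idx

        distance = float(
            np.clip(
                rng.exponential(LINK_DISTANCE_SCALE), MIN_LINK_DISTANCE, MAX_LINK_DISTANCE
            )
        )
        sign = 1 if rng.random() < 0.5 else -1
        distal_start = int(tss + sign * distance)
        distal_idx = len(peaks)
        peaks.append(GenomicInterval("chrL", distal_start, distal_start + cfg.peak_length))
        seq = list(_random_sequence(rng, cfg.peak_length))
        offset = int(rng.integers(0, cfg.peak_length - cfg.motif_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        motif = consensus[tf] if strand == "+" else _reverse_complement(consensus[tf])
        seq[offset : offset + cfg.motif_length] = motif
        sequences.append("".join(seq))
        motif_placements[distal_idx] = (tf, offset, strand)
        links.append(PlantedLink(distal_idx, gene_id, tf, ctype, cfg.link_effect_size))

    # TF genes on their own chromosome
    for j, tf in enumerate(tf_names):
        tss = j * 10_000
        genes.append(GeneRecord(tf, GenomicInterval("chrT", tss, tss + 1000, "+")))

    # decoy genes (uniform expression) far from every peak
    for j in range(n_null_genes):
        tss = j * 10_000
        genes.append(
            GeneRecord(f"N{j:04d}", GenomicInterval("chrG", tss, tss + 1000, "+"))
        )

    # decoy peaks (uniform accessibility, no planted motif)
    for j in range(n_null_peaks):
        start = j * 2_000
        peaks.append(GenomicInterval("chrP", start, start + cfg.peak_length))
        sequences.append(_random_sequence(rng, cfg.peak_length))

    # --- accessibility counts ----------------------------------------------
    ca_lam = np.full((cfg.n_peaks, cfg.n_cells), cfg.ca_mean_fragments, dtype=float)
    for link in links:
        boost = type_masks[link.cell_type]
        prom = promoter_peaks[link.gene_id]
        ca_lam[link.peak_index, boost] = cfg.ca_mean_fragments * cfg.ca_activity_multiplier
        ca_lam[prom, boost] = cfg.ca_mean_fragments * cfg.ca_activity_multiplier
    ca_counts = rng.poisson(ca_lam)

    # --- expression counts --------------------------------------------------
    ge_mean = np.full((cfg.n_genes, cfg.n_cells), cfg.ge_mean_counts, dtype=float)
    gene_pos = {g.gene_id: i for i, g in enumerate(genes)}
    for link in links:
        ge_mean[gene_pos[link.gene_id], type_masks[link.cell_type]] *= 2.0**link.effect
    for tf in tf_names:
        ge_mean[gene_pos[tf], type_masks[tf_type[tf]]] *= 2.0**cfg.tf_expression_log2fc
    ge_counts = _negative_binomial(rng, ge_mean, cfg.ge_dispersion)
    if cfg.dropout_rate > 0:
        keep = rng.random(ge_counts.shape) >= cfg.dropout_rate
        ge_counts = ge_counts * keep

    pair = OmicsPair(
        ca=pd.DataFrame(ca_counts, index=[f"peak{i:04d}" for i in range(cfg.n_peaks)], columns=cells),
        ge=pd.DataFrame(ge_counts, index=[g.gene_id for g in genes], columns=cells),
        peaks=peaks,
        genes=genes,
    )
    truth = SyntheticTruth(
        cell_types=cell_types,
        active_tfs_by_type=active_tfs_by_type,
        links=links,
        motif_placements=motif_placements,
        promoter_peaks=promoter_peaks,
        peaks=peaks,
        config=cfg,
    )
    return SyntheticDataset(pair=pair, pwms=pwms, sequences=sequences, truth=truth)


@dataclass(frozen=True)
class LinkEvaluation:
    precision: float
    recall: float
    f1: float
    n_true: int
    n_inferred: int
    n_matched: int
    precision_defined: bool


def _coord_key(peak: GenomicInterval, gene_id: str) -> tuple:
    return (peak.chrom, peak.start, peak.end, gene_id)


def evaluate_links(
    inferred: Sequence[RegulatoryLink],
    peaks: Sequence[GenomicInterval],
    truth: SyntheticTruth,
) -> LinkEvaluation:
    """Exact-pair precision/recall/F1 of inferred links against the truth.

    Links are matched on (peak coordinates, gene id), so the peak list the
    inferred indices refer to may be a filtered subset of the generated
    one.  Empty truth is an error; an empty inference has undefined
    precision, reported as 0 with ``precision_defined=False``.
    """
    if not truth.links:
        raise ValueError("empty truth")
    true_keys = {
        _coord_key(truth.peaks[l.peak_index], l.gene_id) for l in truth.links
    }
    inferred_keys = {_coord_key(peaks[l.peak_index], l.gene_id) for l in inferred}
    matched = len(true_keys & inferred_keys)
    recall = matched / len(true_keys)
    if inferred_keys:
        precision = matched / len(inferred_keys)
        defined = True
    else:
        precision, defined = 0.0, False
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return LinkEvaluation(
        precision=precision,
        recall=recall,
        f1=f1,
        n_true=len(true_keys),
        n_inferred=len(inferred_keys),
        n_matched=matched,
        precision_defined=defined,
    )
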