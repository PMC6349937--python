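"""Filtering, normalization and genomic-context summaries of paired matrices.

The central container is :class:`OmicsPair`: a peaks x cells accessibility
count matrix and a genes x cells expression count matrix over one shared,
ordered set of cells.  Normalization follows the pooled-deconvolution
size-factor estimator: cells are arranged on a ring ordered by library
size, sliding pools of several sizes each contribute one linear equation
relating the pool members' factors to the pool's count ratio against an
average pseudo-cell, and the system is solved by least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iofmt import GeneRecord, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_POOL_SIZES = (21, 26, 31, 36, 41)

MARK_NAMES = frozenset({"H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3"})


class EmptyMatrixError(ValueError):
    """All features were removed by filtering."""


@dataclass
class OmicsPair:
    """Paired accessibility (peaks x cells) and expression (genes x cells)
    count matrices with their feature annotations."""

    ca: pd.DataFrame
    ge: pd.DataFrame
    peaks: list[GenomicInterval]
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        if list(self.ca.columns) != list(self.ge.columns):
            raise ValueError("CA and GE matrices must share the same cell ordering")
        if self.ca.shape[0] != len(self.peaks):
            raise ValueError("peak list length does not match CA row count")
        if self.ge.shape[0] != len(self.genes):
            raise ValueError("gene list length does not match GE row count")

    @property
    def cells(self) -> list[str]:
        return list(self.ca.columns)

    @property
    def n_cells(self) -> int:
        return self.ca.shape[1]


def filter_features(
    pair: OmicsPair,
    min_cell_fraction: float = 0.10,
    ca_min_fragments: int = 2,
    inclusive: bool = True,
) -> OmicsPair:
    """Drop rarely detected features from both matrices; cells are untouched.

    A peak counts as detected in a cell when it holds at least
    ``ca_min_fragments`` fragments (default 2, i.e. strictly more than one);
    a gene when it has any count.  Features detected in at least
    (``inclusive``, the default) or strictly more than ``min_cell_fraction``
    of cells are retained.
    """
    n = pair.n_cells
    ca_detected = (pair.ca.to_numpy() >= ca_min_fragments).mean(axis=1)
    ge_detected = (pair.ge.to_numpy() >= 1).mean(axis=1)
    if inclusive:
        keep_peaks = ca_detected >= min_cell_fraction
        keep_genes = ge_detected >= min_cell_fraction
    else:
        keep_peaks = ca_detected > min_cell_fraction
        keep_genes = ge_detected > min_cell_fraction
    if not keep_peaks.any() or not keep_genes.any():
        raise EmptyMatrixError("empty matrix after filtering")
    logger.info(
        "filter_features: kept %d/%d peaks, %d/%d genes (n_cells=%d)",
        int(keep_peaks.sum()), len(keep_peaks), int(keep_genes.sum()), len(keep_genes), n,
    )
    return OmicsPair(
        ca=pair.ca.loc[keep_peaks],
        ge=pair.ge.loc[keep_genes],
        peaks=[p for p, k in zip(pair.peaks, keep_peaks) if k],
        genes=[g for g, k in zip(pair.genes, keep_genes) if k],
    )


def _library_size_factors(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0).astype(float)
    return lib / lib.mean()


def pooled_size_factors(
    counts: pd.DataFrame | np.ndarray,
    pool_sizes: Sequence[int] = DEFAULT_POOL_SIZES,
) -> np.ndarray:
    """Per-cell size factors by deconvolution from cell pools.

    Cells are placed on a ring ordered by library size (alternating ends so
    neighbouring pool windows are balanced).  For every pool size and every
    ring offset, the pooled count vector is compared to the average
    pseudo-cell; the median per-feature ratio gives one equation
    ``sum of member factors = pooled ratio``.  The stacked system is solved
    by least squares together with low-weight per-cell library-size
    equations that pin the scale, and the solution is rescaled to mean 1.

    Falls back to plain library-size factors (with a warning) when there
    are fewer cells than the smallest pool.
    """
    X = np.asarray(counts, dtype=float)
    n_features, n_cells = X.shape
    if (X.sum(axis=0) == 0).any():
        raise ValueError("pooled_size_factors: all-zero cell")
    pool_sizes = sorted(set(int(s) for s in pool_sizes))
    if n_cells < min(pool_sizes):
        logger.warning(
            "pooled_size_factors: %d cells < smallest pool %d; using library-size factors",
            n_cells, min(pool_sizes),
        )
        return _library_size_factors(X)

    lib = X.sum(axis=0)
    order = np.argsort(lib)
    # interleave from both ends of the sorted order onto the ring
    ring = np.empty(n_cells, dtype=int)
    ring[0::2] = order[: (n_cells + 1) // 2]
    ring[1::2] = order[(n_cells + 1) // 2:][::-1]

    ref = X.mean(axis=1)  # average pseudo-cell
    use = ref > 0
    ref_use = ref[use]

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for size in pool_sizes:
        if size > n_cells:
            continue
        for offset in range(n_cells):
            members = ring[(offset + np.arange(size)) % n_cells]
            pooled = X[:, members].sum(axis=1)
            ratio = np.median(pooled[use] / ref_use)
            row = np.zeros(n_cells)
            row[members] = 1.0
            rows.append(row)
            rhs.append(ratio)
    # low-weight per-cell anchors: keeps the system full rank and the scale fixed
    anchor_w = 0.01 * len(rows) / n_cells
    lib_factors = _library_size_factors(X)
    for c in range(n_cells):
        row = np.zeros(n_cells)
        row[c] = anchor_w
        rows.append(row)
        rhs.append(anchor_w * lib_factors[c])

    A = np.vstack(rows)
    b = np.asarray(rhs)
    theta, *_ = np.linalg.lstsq(A, b, rcond=None)
    if (theta <= 0).any():
        positive = theta[theta > 0]
        floor = positive.min() * 0.01 if positive.size else 1e-8
        logger.warning(
            "pooled_size_factors: %d non-positive factors clipped to %.3g",
            int((theta <= 0).sum()), floor,
        )
        theta = np.where(theta <= 0, floor, theta)
    return theta / theta.mean()


def normalize(
    counts: pd.DataFrame | np.ndarray,
    size_factors: np.ndarray,
    log1p: bool = False,
) -> pd.DataFrame | np.ndarray:
    """Divide each cell's counts by its size factor; optionally log1p."""
    size_factors = np.asarray(size_factors, dtype=float)
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    if isinstance(counts, pd.DataFrame):
        if len(size_factors) != counts.shape[1]:
            raise ValueError("size-factor length must equal the number of cells")
        out = counts / size_factors
    else:
        counts = np.asarray(counts, dtype=float)
        if len(size_factors) != counts.shape[1]:
            raise ValueError("size-factor length must equal the number of cells")
        out = counts / size_factors[None, :]
    return np.log1p(out) if log1p else out


def cpm(counts: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Counts per million per cell: entry x 1e6 / cell total."""
    values = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        if isinstance(counts, pd.DataFrame):
            names = ", ".join(str(counts.columns[i]) for i in zero[:5])
        else:
            names = ", ".join(map(str, zero[:5]))
        raise ValueError(f"cpm: zero-total cell(s): {names}")
    out = values * 1e6 / totals
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def assign_peak_target_genes(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    window: int = 5000,
) -> dict[int, set[str]]:
    """Putative target genes per peak: genes whose TSS lies within ``window``
    bases of the peak, i.e. in ``[peak.start - window, peak.end + window)``."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append((g.tss, g.gene_id))
    for entries in by_chrom.values():
        entries.sort()
    result: dict[int, set[str]] = {}
    for i, peak in enumerate(peaks):
        entries = by_chrom.get(peak.chrom, [])
        if not entries:
            result[i] = set()
            continue
        tss_arr = np.array([t for t, _ in entries])
        lo = np.searchsorted(tss_arr, peak.start - window, side="left")
        hi = np.searchsorted(tss_arr, peak.end + window, side="left")
        result[i] = {entries[j][1] for j in range(lo, hi)}
    return result


def classify_genes_by_marks(gene_marks: Mapping[str, set[str]]) -> dict[str, str]:
    """Assign each gene an activity class from its overlapping histone marks.

    active   = (H3K4me3 or H3K4me1) and H3K27ac and not H3K27me3
    bivalent = (H3K4me3 or H3K4me1) and H3K27me3
    inactive = H3K27me3 alone (no H3K4me3/H3K4me1/H3K27ac)
    anything else is unclassified; bivalent takes precedence over inactive.
    """
    out: dict[str, str] = {}
    for gene, marks in gene_marks.items():
        unknown = set(marks) - MARK_NAMES
        if unknown:
            raise ValueError(f"unknown mark name(s) {sorted(unknown)} for gene {gene}")
        k4 = "H3K4me3" in marks or "H3K4me1" in marks
        k27ac = "H3K27ac" in marks
        k27me3 = "H3K27me3" in marks
        if k4 and k27me3:
            out[gene] = "bivalent"
        elif k4 and k27ac and not k27me3:
            out[gene] = "active"
        elif k27me3 and not k4 and not k27ac:
            out[gene] = "inactive"
        else:
            out[gene] = "unclassified"
    return out


def context_density(
    ca_cpm: pd.DataFrame | np.ndarray,
    region_set: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
) -> np.ndarray:
    """Per-cell mean CPM over the peaks overlapping a region set.

    Returns an empty array (with a warning) when no peak overlaps.
    """
    selected = [
        i for i, p in enumerate(peaks) if any(p.overlaps(r) for r in region_set)
    ]
    values = ca_cpm.to_numpy() if isinstance(ca_cpm, pd.DataFrame) else np.asarray(ca_cpm, float)
    if not selected:
        logger.warning("context_density: no peak overlaps the region set")
        return np.empty(0)
    return values[selected].mean(axis=0)
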