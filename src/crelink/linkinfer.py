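"""Inference of peak -> gene regulatory links from paired single-cell data.

Three strategies are implemented:

* **Strategy 1** (accessibility only): a distal peak is linked to a gene
  when the weighted Spearman correlation between the distal peak's signal
  and a promoter peak's signal exceeds a threshold (default 0.25) for at
  least one NMF signature, using that signature's per-cell exposures as
  weights.
* **Strategy 2** (paired): same screen, but the response is the gene's
  normalized expression rather than promoter accessibility.
* **Strategy 3** (per-cell): cells are partitioned by whether a nearby
  region is *active* in them (motif of an active TF present, see
  :mod:`crelink.tfmotif`); a Wilcoxon rank-sum test on the gene's
  expression between the two partitions assigns a link at p < alpha.
  Strategy 3 yields a binary links x cells matrix recording the per-cell
  on/off state of every link.

The signature-weighted correlation guards against correlations being
diluted by between-subpopulation structure: each signature's exposures
up-weight one subpopulation at a time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iofmt import GeneRecord, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_RHO_THRESHOLD = 0.25
DEFAULT_WINDOW = 1_000_000
DEFAULT_PROMOTER_WINDOW = 2_000
DEFAULT_ALPHA = 0.05
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class RegulatoryLink:
    """One inferred (peak, gene) regulatory relationship."""

    peak_index: int
    gene_id: str
    strategy: int
    statistic: float  # rho for strategies 1-2, Wilcoxon p for strategy 3
    signature_index: int | None = None
    n_cells_on: int = 0

    @property
    def statistic_name(self) -> str:
        return "rho" if self.strategy in (1, 2) else "wilcoxon_p"

    @property
    def key(self) -> tuple[int, str]:
        return (self.peak_index, self.gene_id)


@dataclass
class LinkMatrix:
    """Binary links x cells matrix; entry 1 means the link is 'on' in that
    cell (its region is active there)."""

    matrix: np.ndarray
    links: list[RegulatoryLink]
    cells: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("link matrix must be 2-D")
        if self.matrix.shape != (len(self.links), len(self.cells)):
            raise ValueError("link matrix shape must be (n_links, n_cells)")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("link matrix entries must be binary")

    def to_frame(self) -> pd.DataFrame:
        index = [f"{l.peak_index}|{l.gene_id}" for l in self.links]
        return pd.DataFrame(self.matrix, index=index, columns=self.cells)


def weighted_spearman(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Spearman correlation: weighted Pearson of the midrank vectors.

    Returns NaN (with a warning) when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, w must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("weighted_spearman: constant input, correlation undefined")
        return float("nan")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    wsum = w.sum()
    mx = (w * rx).sum() / wsum
    my = (w * ry).sum() / wsum
    cov = (w * (rx - mx) * (ry - my)).sum()
    vx = (w * (rx - mx) ** 2).sum()
    vy = (w * (ry - my) ** 2).sum()
    if vx == 0 or vy == 0:
        logger.warning("weighted_spearman: zero weighted variance")
        return float("nan")
    return float(cov / math.sqrt(vx * vy))


def _exact_rank_sum_p(a_ranks_sum: float, n1: int, n2: int) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n1+n2, n1) rank
    assignments (tie-free case only)."""
    n = n1 + n2
    sums = np.fromiter(
        (sum(c) for c in combinations(range(1, n + 1), n1)), dtype=float
    )
    lo = np.mean(sums <= a_ranks_sum + 1e-9)
    hi = np.mean(sums >= a_ranks_sum - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    min_group: int = 3,
    method: str = "auto",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration of rank assignments when the combined sample is
    tie-free and has at most 12 observations (``method`` forces either
    path: "exact" requires a tie-free sample); otherwise the normal
    approximation with midranks, tie-corrected variance and a continuity
    correction, sharpened in the tie-free case by an Edgeworth term for
    the (negative) excess kurtosis of the rank-sum distribution.  Only the
    two-sided alternative is exposed for now.
    """
    if alternative != "two-sided":
        raise NotImplementedError("only the two-sided alternative is implemented")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < min_group or n2 < min_group:
        raise ValueError(f"each group needs >= {min_group} observations")
    pooled = np.concatenate([a, b])
    n = n1 + n2
    ranks = stats.rankdata(pooled, method="average")
    w = ranks[:n1].sum()
    tie_free = len(np.unique(pooled)) == n
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" and not tie_free:
        raise ValueError("exact enumeration requires a tie-free sample")
    use_exact = (
        method == "exact"
        or (method == "auto" and tie_free and n <= EXACT_WILCOXON_MAX_N)
    )
    if use_exact:
        return _exact_rank_sum_p(w, n1, n2)
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 1.0
    z = max(0.0, abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    tail = stats.norm.sf(z)
    if tie_free:
        # fourth-cumulant Edgeworth refinement; exact excess kurtosis of W
        g2 = -6.0 * (n1**2 + n2**2 + n1 * n2 + n) / (5.0 * n1 * n2 * (n + 1))
        tail += g2 / 24.0 * (z**3 - 3.0 * z) * stats.norm.pdf(z)
    return float(min(1.0, max(0.0, 2.0 * tail)))


def _peaks_by_chrom(peaks: Sequence[GenomicInterval]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        out.setdefault(p.chrom, []).append(i)
    return out


def _classify_gene_peaks(
    gene: GeneRecord,
    peaks: Sequence[GenomicInterval],
    chrom_index: dict[str, list[int]],
    window: float,
    promoter_window: int,
) -> tuple[list[int], list[int]]:
    """Split a gene's nearby peaks into promoter and distal sets.

    Promoter peaks overlap [tss - pw, tss + pw + 1); distal peaks have any
    base within ``window`` of the TSS and are not promoter peaks.
    """
    tss = gene.tss
    promoter: list[int] = []
    distal: list[int] = []
    for i in chrom_index.get(gene.interval.chrom, []):
        p = peaks[i]
        if p.start < tss + promoter_window + 1 and p.end > tss - promoter_window:
            promoter.append(i)
        elif p.start < tss + window and p.end > tss - window:
            distal.append(i)
    return promoter, distal


def _max_signature_rho(
    x: np.ndarray, y: np.ndarray, H: np.ndarray
) -> tuple[float, int]:
    best, best_sig = -np.inf, -1
    for s in range(H.shape[0]):
        rho = weighted_spearman(x, y, H[s])
        if not math.isnan(rho) and rho > best:
            best, best_sig = rho, s
    return best, best_sig


def strategy1_links(
    ca_norm: pd.DataFrame | np.ndarray,
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    H_exposures: np.ndarray,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    window: float = DEFAULT_WINDOW,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> list[RegulatoryLink]:
    """Accessibility-only links: distal peak vs promoter-peak correlation.

    For every (promoter peak, distal peak) pair of a gene, the weighted
    Spearman correlation is computed once per NMF signature with that
    signature's exposure row as weights; the distal peak is linked when the
    maximum over signatures and promoter peaks exceeds ``rho_threshold``.
    """
    X = ca_norm.to_numpy() if isinstance(ca_norm, pd.DataFrame) else np.asarray(ca_norm, float)
    H = np.asarray(H_exposures, dtype=float)
    n_cells = X.shape[1]
    chrom_index = _peaks_by_chrom(peaks)
    links: list[RegulatoryLink] = []
    skipped = 0
    for gene in genes:
        promoter, distal = _classify_gene_peaks(gene, peaks, chrom_index, window, promoter_window)
        if not promoter:
            skipped += 1
            continue
        for d in distal:
            best, best_sig = -np.inf, -1
            for p in promoter:
                rho, sig = _max_signature_rho(X[p], X[d], H)
                if rho > best:
                    best, best_sig = rho, sig
            if best > rho_threshold:
                links.append(
                    RegulatoryLink(d, gene.gene_id, 1, best, best_sig, n_cells_on=n_cells)
                )
    if skipped:
        logger.info("strategy1: %d genes without a promoter peak skipped", skipped)
    return links


def strategy2_links(
    ca_norm: pd.DataFrame | np.ndarray,
    ge_norm: pd.DataFrame,
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    H_exposures: np.ndarray,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    window: float = DEFAULT_WINDOW,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
) -> list[RegulatoryLink]:
    """Paired links: distal-peak accessibility vs gene expression correlation.

    Same screen as strategy 1 with the gene's normalized expression as the
    response; the exposure weights come from NMF of the expression matrix.
    """
    X = ca_norm.to_numpy() if isinstance(ca_norm, pd.DataFrame) else np.asarray(ca_norm, float)
    H = np.asarray(H_exposures, dtype=float)
    n_cells = X.shape[1]
    chrom_index = _peaks_by_chrom(peaks)
    links: list[RegulatoryLink] = []
    skipped = 0
    for gene in genes:
        if gene.gene_id not in ge_norm.index:
            skipped += 1
            continue
        expr = ge_norm.loc[gene.gene_id].to_numpy(dtype=float)
        _, distal = _classify_gene_peaks(gene, peaks, chrom_index, window, promoter_window)
        for d in distal:
            rho, sig = _max_signature_rho(expr, X[d], H)
            if rho > rho_threshold:
                links.append(
                    RegulatoryLink(d, gene.gene_id, 2, rho, sig, n_cells_on=n_cells)
                )
    if skipped:
        logger.info("strategy2: %d genes absent from the expression matrix skipped", skipped)
    return links


def strategy3_links(
    ge_norm: pd.DataFrame,
    active_region_mask: np.ndarray,
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    window: float = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
    min_group: int = 3,
) -> tuple[list[RegulatoryLink], LinkMatrix]:
    """Per-cell links: Wilcoxon test across the active/inactive partition.

    For every peak within ``window`` of a gene's TSS, cells are split by the
    peak's active-region mask; the gene's normalized expression is compared
    between the two groups with a Wilcoxon rank-sum test, and a link is
    assigned when p < ``alpha``.  The returned LinkMatrix row of each link
    is the peak's mask row (on in a cell iff the region is active there).
    """
    mask = np.asarray(active_region_mask)
    if mask.shape[0] != len(peaks):
        raise ValueError("mask row count must equal the number of peaks")
    cells = list(ge_norm.columns)
    if mask.shape[1] != len(cells):
        raise ValueError("mask column count must equal the number of cells")
    chrom_index = _peaks_by_chrom(peaks)
    links: list[RegulatoryLink] = []
    rows: list[np.ndarray] = []
    untested = 0
    for gene in genes:
        if gene.gene_id not in ge_norm.index:
            continue
        expr = ge_norm.loc[gene.gene_id].to_numpy(dtype=float)
        tss = gene.tss
        for i in chrom_index.get(gene.interval.chrom, []):
            p = peaks[i]
            if not (p.start < tss + window and p.end > tss - window):
                continue
            on = mask[i].astype(bool)
            n_on = int(on.sum())
            n_off = len(on) - n_on
            if n_on < min_group or n_off < min_group:
                untested += 1
                continue
            pval = wilcoxon_rank_sum(expr[on], expr[~on], min_group=min_group)
            if pval < alpha:
                links.append(
                    RegulatoryLink(i, gene.gene_id, 3, pval, None, n_cells_on=n_on)
                )
                rows.append(mask[i].astype(np.int8))
    if untested:
        logger.info("strategy3: %d (peak, gene) pairs untested (degenerate partition)", untested)
    matrix = np.vstack(rows) if rows else np.zeros((0, len(cells)), dtype=np.int8)
    return links, LinkMatrix(matrix, links, cells)


def count_tested_pairs(
    active_region_mask: np.ndarray,
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    gene_ids: Iterable[str],
    window: float = DEFAULT_WINDOW,
    min_group: int = 3,
) -> int:
    """Number of (peak, gene) pairs strategy 3 would actually test."""
    mask = np.asarray(active_region_mask)
    gene_ids = set(gene_ids)
    chrom_index = _peaks_by_chrom(peaks)
    n = 0
    for gene in genes:
        if gene.gene_id not in gene_ids:
            continue
        for i in chrom_index.get(gene.interval.chrom, []):
            p = peaks[i]
            if not (p.start < gene.tss + window and p.end > gene.tss - window):
                continue
            n_on = int(mask[i].sum())
            if min_group <= n_on <= mask.shape[1] - min_group:
                n += 1
    return n


def pairwise_correlation_screen(
    ca_norm: pd.DataFrame | np.ndarray,
    ge_norm: pd.DataFrame,
    pairs: Sequence[tuple[int, str]],
    fdr: float = 0.10,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Pearson screen over candidate (peak, gene) pairs with BH control.

    Returns counts of significant positive / negative correlations at the
    requested FDR plus the full per-pair table.
    """
    X = ca_norm.to_numpy() if isinstance(ca_norm, pd.DataFrame) else np.asarray(ca_norm, float)
    rows = []
    for peak_idx, gene_id in pairs:
        if gene_id not in ge_norm.index:
            continue
        x = X[peak_idx]
        y = ge_norm.loc[gene_id].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"peak_index": peak_idx, "gene_id": gene_id, "r": r, "p": p})
    table = pd.DataFrame(rows, columns=["peak_index", "gene_id", "r", "p"])
    if len(table):
        table["q"] = stats.false_discovery_control(table["p"].to_numpy(), method="bh")
        table["significant"] = table["q"] < fdr
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    sig = table[table["significant"]] if len(table) else table
    counts = {
        "positive": int((sig["r"] > 0).sum()) if len(table) else 0,
        "negative": int((sig["r"] < 0).sum()) if len(table) else 0,
        "tested": int(len(table)),
    }
    return counts, table


def link_distance_distribution(
    links: Sequence[RegulatoryLink],
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    bin_width: int = 10_000,
    max_distance: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Histogram of |peak midpoint - TSS| distances over fixed-width bins."""
    if not links:
        raise ValueError("no links to bin")
    tss_by_id = {g.gene_id: g.tss for g in genes}
    distances = [
        abs(peaks[l.peak_index].midpoint - tss_by_id[l.gene_id]) for l in links
    ]
    edges = np.arange(0, max_distance + bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    if counts.sum() == 0:
        raise ValueError("all link distances fall beyond the histogram range")
    return counts
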