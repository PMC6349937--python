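"""Per-TF chromatin-accessibility deviation z-scores.

For each motif (TF) the counts over its annotated peaks in each cell are
compared to the counts expected if every cell sampled peaks in proportion
to the pooled peak totals at that cell's sequencing depth:

    expected(m, c) = cell_total(c) * sum_over_cells(motif peak counts) / grand_total
    raw(m, c)      = (observed - expected) / expected

Raw deviations confound motif signal with technical covariates, so each
motif's raw deviation is z-scored against raw deviations of B background
peak sets matched on mean accessibility (and GC content when available).
A motif's *variability* is the standard deviation of its z-score row
across cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tfmotif import MotifHitIndex

logger = logging.getLogger(__name__)

DEFAULT_N_BACKGROUND = 50
DEFAULT_N_BINS = 25


@dataclass
class DeviationResult:
    """Bias-corrected deviation z-scores and per-motif variability."""

    deviations: pd.DataFrame  # motifs x cells z-scores
    variability: pd.Series  # per-motif sd of the z row
    raw: pd.DataFrame  # motifs x cells raw (observed-expected)/expected
    dropped_motifs: list[str]


def annotate_motif_peaks(
    motif_hit_index: MotifHitIndex, n_peaks: int, tf_names: list[str] | None = None
) -> pd.DataFrame:
    """Binary motifs x peaks annotation matrix from a motif hit index."""
    if tf_names is None:
        tf_names = sorted({tf for hits in motif_hit_index.hits.values() for tf in hits})
    M = np.zeros((len(tf_names), n_peaks), dtype=np.int8)
    pos = {tf: i for i, tf in enumerate(tf_names)}
    for p_idx, hits in motif_hit_index.hits.items():
        if p_idx >= n_peaks:
            raise ValueError(f"hit peak index {p_idx} out of range for {n_peaks} peaks")
        for tf in hits:
            if tf in pos:
                M[pos[tf], p_idx] = 1
    return pd.DataFrame(M, index=tf_names, columns=range(n_peaks))


def sample_background_peaks(
    peak_mean_accessibility: np.ndarray,
    gc_content: np.ndarray | None = None,
    B: int = DEFAULT_N_BACKGROUND,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
) -> np.ndarray:
    """B background peaks per peak, matched on mean accessibility bins.

    Peaks are quantile-binned on mean accessibility; when GC content is
    supplied the binning is two-dimensional (sqrt(n_bins) quantile bins
    per covariate).  Each background peak is drawn uniformly from the
    source peak's bin, with replacement, reproducibly from ``seed``.
    Returns an (n_peaks, B) integer array.
    """
    acc = np.asarray(peak_mean_accessibility, dtype=float)
    n_peaks = len(acc)
    if n_peaks < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} peaks, got {n_peaks}")
    rng = np.random.default_rng(seed)

    def _bin(values: np.ndarray, k: int) -> np.ndarray:
        # quantile bins; ties collapse bins, which only widens the match
        qs = np.quantile(values, np.linspace(0, 1, k + 1)[1:-1])
        return np.searchsorted(qs, values, side="right")

    if gc_content is not None:
        k = max(2, int(round(np.sqrt(n_bins))))
        bins = _bin(acc, k) * (k + 1) + _bin(np.asarray(gc_content, float), k)
    else:
        bins = _bin(acc, n_bins)

    members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins == b) for b in np.unique(bins)
    }
    out = np.empty((n_peaks, B), dtype=np.int64)
    for p in range(n_peaks):
        pool = members[bins[p]]
        if len(pool) == 1:
            logger.warning("sample_background_peaks: singleton bin, peak %d maps to itself", p)
            out[p] = p
        else:
            out[p] = rng.choice(pool, size=B, replace=True)
    return out


def _raw_deviations(
    counts: np.ndarray, annotation: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Raw fractional deviations for each annotation row; returns the
    deviations and a validity mask (rows with positive expectation)."""
    cell_totals = counts.sum(axis=0, keepdims=True)  # (1, cells)
    grand = counts.sum()
    peak_fractions = counts.sum(axis=1) / grand  # per-peak share of all counts
    observed = annotation @ counts  # (motifs, cells)
    expected = (annotation @ peak_fractions)[:, None] * cell_totals
    valid = expected[:, 0] > 0
    raw = np.zeros_like(observed, dtype=float)
    raw[valid] = (observed[valid] - expected[valid]) / expected[valid]
    return raw, valid


def compute_deviations(
    ca_counts: pd.DataFrame | np.ndarray,
    motif_annotation: pd.DataFrame,
    background_sets: np.ndarray,
) -> DeviationResult:
    """Background-normalized accessibility deviation z-scores per motif.

    ``background_sets`` is the (n_peaks, B) array from
    :func:`sample_background_peaks`; background annotation b of a motif
    replaces each annotated peak with its b-th matched background peak.
    Motifs whose expected counts are zero are dropped with a warning.
    """
    counts = ca_counts.to_numpy(dtype=float) if isinstance(ca_counts, pd.DataFrame) else np.asarray(ca_counts, float)
    annot = motif_annotation.to_numpy(dtype=float)
    motif_names = list(motif_annotation.index)
    n_peaks = counts.shape[0]
    if annot.shape[1] != n_peaks:
        raise ValueError("annotation columns must match peak count")
    if background_sets.shape[0] != n_peaks:
        raise ValueError("background sets must cover every peak")

    raw, valid = _raw_deviations(counts, annot)
    B = background_sets.shape[1]
    bg_raws = np.empty((B, annot.shape[0], counts.shape[1]))
    for b in range(B):
        # permute the annotation columns through the b-th background draw
        bg_annot = np.zeros_like(annot)
        for m in range(annot.shape[0]):
            src = np.flatnonzero(annot[m])
            np.add.at(bg_annot[m], background_sets[src, b], 1.0)
        bg_raw, _ = _raw_deviations(counts, bg_annot)
        bg_raws[b] = bg_raw
    bg_mean = bg_raws.mean(axis=0)
    bg_sd = bg_raws.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (raw - bg_mean) / bg_sd
    z[~np.isfinite(z)] = 0.0

    dropped = [motif_names[m] for m in np.flatnonzero(~valid)]
    if dropped:
        logger.warning("compute_deviations: dropping motifs with zero expectation: %s", dropped)
    keep = np.flatnonzero(valid)
    kept_names = [motif_names[m] for m in keep]
    cells = (
        list(ca_counts.columns) if isinstance(ca_counts, pd.DataFrame) else list(range(counts.shape[1]))
    )
    deviations = pd.DataFrame(z[keep], index=kept_names, columns=cells)
    raw_df = pd.DataFrame(raw[keep], index=kept_names, columns=cells)
    return DeviationResult(
        deviations=deviations,
        variability=compute_variability(deviations),
        raw=raw_df,
        dropped_motifs=dropped,
    )


def compute_variability(deviations: pd.DataFrame) -> pd.Series:
    """Per-motif variability: sample standard deviation of the z row."""
    if deviations.shape[1] < 2:
        raise ValueError("variability needs at least 2 cells")
    return deviations.std(axis=1, ddof=1)
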