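"""TF regulon activity and motif-based active-region labeling.

This module supplies the two upstream steps of the per-cell linking
strategy (strategy 3 in :mod:`crelink.linkinfer`):

1. **Regulon activity.**  A regulon is a TF plus the target genes it is
   co-expressed with.  Per cell, a regulon's enrichment is the area under
   the recovery curve (AUC) of its genes within the top fraction of that
   cell's expression ranking; each TF is then called active or inactive
   per cell from the bimodal distribution of its AUC scores.
2. **Active regions.**  Position weight matrices of the TFs are scanned
   over peak sequences on both strands; a peak is *active* in a cell when
   it carries a qualifying motif (score at or above 95% of the motif's
   best attainable score) of a TF that is active in that cell, and, by
   default, at least one accessibility fragment in that cell.

The regulon builder here is a deliberately simple co-expression screen
(rank correlation with the TF, optionally pruned by motif context); the
module also accepts externally built regulons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .iofmt import GeneRecord, GenomicInterval, PWMRecord

logger = logging.getLogger(__name__)

DEFAULT_MATCH_FRACTION = 0.95
DEFAULT_TOP_FRAC = 0.05
DEFAULT_MIN_REGULON_SIZE = 10
DEFAULT_CORR_MIN = 0.3
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class Regulon:
    """A TF and its target-gene set (the TF's own gene included)."""

    tf_name: str
    target_gene_ids: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.target_gene_ids:
            raise ValueError("regulon must contain at least one gene")

    def __len__(self) -> int:
        return len(self.target_gene_ids)


@dataclass(frozen=True)
class MotifHit:
    offset: int
    strand: str
    score_fraction: float


@dataclass
class MotifHitIndex:
    """Mapping peak index -> {tf_name: best qualifying score fraction}."""

    hits: dict[int, dict[str, float]] = field(default_factory=dict)

    def add(self, peak_index: int, tf_name: str, score_fraction: float) -> None:
        best = self.hits.setdefault(peak_index, {})
        if score_fraction > best.get(tf_name, -np.inf):
            best[tf_name] = score_fraction

    def tfs_for_peak(self, peak_index: int) -> set[str]:
        return set(self.hits.get(peak_index, ()))

    def peaks_for_tf(self, tf_name: str) -> list[int]:
        return [p for p, tfs in self.hits.items() if tf_name in tfs]

    def __len__(self) -> int:
        return sum(len(v) for v in self.hits.values())


@dataclass
class TFActivity:
    """Per-cell regulon AUC scores and binary activity calls."""

    auc: pd.DataFrame  # TFs x cells, values in [0, 1]
    active: pd.DataFrame  # TFs x cells, binary
    thresholds: dict[str, float]

    def __post_init__(self) -> None:
        if self.auc.shape != self.active.shape:
            raise ValueError("auc and active must have identical shape")
        expected = self.auc.to_numpy() >= np.array(
            [self.thresholds[tf] for tf in self.auc.index]
        ).reshape(-1, 1)
        if not (self.active.to_numpy().astype(bool) == expected).all():
            raise ValueError("active calls inconsistent with thresholds")

    def is_active(self, tf_name: str) -> np.ndarray:
        return self.active.loc[tf_name].to_numpy().astype(bool)


# ---------------------------------------------------------------------------
# regulons and activity


def build_regulons(
    ge_norm: pd.DataFrame,
    tf_names: Sequence[str],
    motif_hit_index: MotifHitIndex | None = None,
    peaks: Sequence[GenomicInterval] | None = None,
    genes: Sequence[GeneRecord] | None = None,
    corr_min: float = DEFAULT_CORR_MIN,
    min_size: int = DEFAULT_MIN_REGULON_SIZE,
    tss_window: int = 10_000,
) -> list[Regulon]:
    """Build co-expression regulons: one per TF whose gene is in the matrix.

    Candidate targets are the genes whose Spearman correlation with the
    TF's expression across cells is at least ``corr_min``.  When motif
    context (hit index + peaks + genes) is supplied, candidates are pruned
    to genes with a qualifying motif of that TF in a peak whose
    ``tss_window`` neighbourhood contains the gene's TSS.  Regulons smaller
    than ``min_size`` are dropped.
    """
    expr = ge_norm.to_numpy(dtype=float)
    # rank once per gene; Spearman = Pearson on ranks
    ranks = np.apply_along_axis(stats.rankdata, 1, expr)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    gene_ids = list(ge_norm.index)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    motif_context = motif_hit_index is not None and peaks is not None and genes is not None
    if motif_context:
        tss_by_id = {g.gene_id: (g.interval.chrom, g.tss) for g in genes}

    regulons: list[Regulon] = []
    for tf in tf_names:
        if tf not in gene_pos:
            logger.warning("build_regulons: TF gene %s absent from expression matrix", tf)
            continue
        t = gene_pos[tf]
        if norms[t] == 0:
            logger.warning("build_regulons: TF gene %s has constant expression", tf)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = centered @ centered[t] / (norms * norms[t])
        targets = {gene_ids[i] for i in np.flatnonzero(rho >= corr_min - 1e-12)}
        targets.add(tf)
        if motif_context:
            allowed = set()
            for p_idx in motif_hit_index.peaks_for_tf(tf):
                peak = peaks[p_idx]
                for gid in targets:
                    chrom, tss = tss_by_id.get(gid, (None, None))
                    if chrom == peak.chrom and peak.start - tss_window <= tss < peak.end + tss_window:
                        allowed.add(gid)
            allowed.add(tf)
            targets &= allowed
        if len(targets) < min_size:
            logger.info("build_regulons: regulon %s too small (%d < %d), dropped", tf, len(targets), min_size)
            continue
        provenance = "coexpression" + ("+motif" if motif_context else "")
        regulons.append(Regulon(tf, frozenset(targets), provenance))
    return regulons


def recovery_auc(
    cell_expression: pd.Series,
    regulon: Regulon,
    top_frac: float = DEFAULT_TOP_FRAC,
) -> float:
    """Normalized area under the recovery curve of a regulon's genes.

    Genes are ranked by expression, descending, ties broken by the stable
    input gene order.  The recovery curve is the cumulative count of
    regulon genes over the top ``ceil(top_frac * n)`` ranks; the area under
    it is normalized by the maximal achievable area (all regulon genes
    packed at the very top), so perfect packing scores 1 and total absence
    from the top fraction scores 0.
    """
    if len(regulon) == 0:
        raise ValueError("empty regulon")
    values = cell_expression.to_numpy(dtype=float)
    n = len(values)
    m = math.ceil(top_frac * n)
    if m < 1:
        raise ValueError("top fraction selects no genes")
    order = np.argsort(-values, kind="stable")[:m]
    in_regulon = np.fromiter(
        (cell_expression.index[i] in regulon.target_gene_ids for i in order),
        dtype=float,
        count=m,
    )
    cum = np.cumsum(in_regulon)
    max_cum = np.minimum(np.arange(1, m + 1), len(regulon))
    return float(cum.sum() / max_cum.sum())


def regulon_auc_matrix(
    ge_norm: pd.DataFrame,
    regulons: Sequence[Regulon],
    top_frac: float = DEFAULT_TOP_FRAC,
) -> pd.DataFrame:
    """AUC of every regulon in every cell (TFs x cells)."""
    n = ge_norm.shape[0]
    m = math.ceil(top_frac * n)
    values = ge_norm.to_numpy(dtype=float)
    # per-cell descending stable order over genes
    order = np.argsort(-values, axis=0, kind="stable")[:m]
    gene_ids = np.asarray(ge_norm.index)
    top_genes = gene_ids[order]  # (m, n_cells)
    rows = {}
    for reg in regulons:
        member = np.isin(top_genes, list(reg.target_gene_ids))
        cum = np.cumsum(member, axis=0)
        max_cum = np.minimum(np.arange(1, m + 1), len(reg)).sum()
        rows[reg.tf_name] = cum.sum(axis=0) / max_cum
    return pd.DataFrame(rows, index=ge_norm.columns).T


def binarize_activity(
    auc_row: np.ndarray | pd.Series,
    seed: int = 0,
    n_restarts: int = 10,
    separation: float = 0.5,
) -> tuple[float, np.ndarray]:
    """Threshold one TF's AUC scores into active/inactive cells.

    A two-component Gaussian mixture is fitted (EM, ``n_restarts``
    initialisations); the threshold is the smallest point between the
    component means where the posterior flips to the high-mean component.
    When the components are indistinct (|mu1 - mu2| < ``separation`` x
    (sigma1 + sigma2)) the fallback threshold mean + 2 sd is used; a
    constant row yields all-inactive.
    """
    x = np.asarray(auc_row, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 cells to binarize")
    if np.ptp(x) == 0:
        logger.warning("binarize_activity: constant AUC row, all cells inactive")
        return float(np.inf), np.zeros(len(x), dtype=np.int8)
    gmm = GaussianMixture(
        n_components=2,
        n_init=n_restarts,
        random_state=seed,
        covariance_type="full",
        reg_covar=1e-8,
    ).fit(x.reshape(-1, 1))
    mu = gmm.means_.ravel()
    sd = np.sqrt(gmm.covariances_.ravel())
    lo, hi = (0, 1) if mu[0] <= mu[1] else (1, 0)
    if abs(mu[hi] - mu[lo]) < separation * (sd[lo] + sd[hi]):
        threshold = float(x.mean() + 2.0 * x.std())
        if not (x >= threshold).any():
            logger.info("binarize_activity: fallback threshold above all cells, all inactive")
    else:
        grid = np.linspace(mu[lo], mu[hi], 1001)
        post = gmm.predict_proba(grid.reshape(-1, 1))[:, hi]
        above = np.flatnonzero(post >= 0.5)
        threshold = float(grid[above[0]]) if above.size else float(mu[hi])
    return threshold, (x >= threshold).astype(np.int8)


def call_tf_activity(
    ge_norm: pd.DataFrame,
    regulons: Sequence[Regulon],
    top_frac: float = DEFAULT_TOP_FRAC,
    seed: int = 0,
) -> TFActivity:
    """Regulon AUC scores plus per-TF binary activity calls."""
    auc = regulon_auc_matrix(ge_norm, regulons, top_frac=top_frac)
    thresholds: dict[str, float] = {}
    active = np.zeros(auc.shape, dtype=np.int8)
    for i, tf in enumerate(auc.index):
        thr, calls = binarize_activity(auc.iloc[i].to_numpy(), seed=seed)
        thresholds[tf] = thr
        active[i] = calls
    return TFActivity(auc, pd.DataFrame(active, index=auc.index, columns=auc.columns), thresholds)


# ---------------------------------------------------------------------------
# motif scanning


def _encode_sequence(sequence: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _log_odds(pwm: PWMRecord, background: Sequence[float]) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if (pwm.matrix == 0).any():
        raise ValueError("PWM contains zero probabilities; use a positive pseudocount")
    return np.log2(pwm.matrix / bg)


def pwm_max_score(pwm: PWMRecord, background: Sequence[float] = (0.25,) * 4) -> float:
    """Best attainable log-odds score: the sum of per-position maxima."""
    return float(_log_odds(pwm, background).max(axis=1).sum())


def pwm_min_score(pwm: PWMRecord, background: Sequence[float] = (0.25,) * 4) -> float:
    """Worst attainable log-odds score: the sum of per-position minima."""
    return float(_log_odds(pwm, background).min(axis=1).sum())


def _window_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Score every window of the encoded sequence; NaN where a window
    contains an ambiguous base."""
    L = logodds.shape[0]
    if len(codes) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows < 4).all(axis=1)
    safe = np.where(windows < 4, windows, 0)
    scores = logodds[np.arange(L)[None, :], safe].sum(axis=1)
    scores[~valid] = np.nan
    return scores


def scan_peak(
    sequence: str,
    pwm: PWMRecord,
    match_fraction: float = DEFAULT_MATCH_FRACTION,
    background: Sequence[float] = (0.25,) * 4,
    literal_fraction: bool = False,
) -> list[MotifHit]:
    """Scan one sequence with one PWM on both strands.

    A window is a hit when its score fraction reaches ``match_fraction``.
    By default the fraction is shift-normalized,
    ``(score - min) / (max - min)``, which keeps the "fraction of the best
    possible score" well defined when log-odds scores can be negative;
    ``literal_fraction=True`` uses the raw ratio ``score / max`` instead.
    Windows containing N are skipped; sequences shorter than the motif
    yield no hits.
    """
    codes = _encode_sequence(sequence)
    logodds = _log_odds(pwm, background)
    max_s = logodds.max(axis=1).sum()
    min_s = logodds.min(axis=1).sum()
    # reverse strand: score the reverse-complement motif on the forward sequence
    rc_logodds = logodds[::-1, ::-1]
    hits: list[MotifHit] = []
    for strand, lo in (("+", logodds), ("-", rc_logodds)):
        scores = _window_scores(codes, lo)
        for offset in np.flatnonzero(~np.isnan(scores)):
            score = scores[offset]
            if literal_fraction:
                frac = score / max_s if max_s > 0 else -np.inf
            else:
                frac = (score - min_s) / (max_s - min_s) if max_s > min_s else 0.0
            if frac >= match_fraction:
                hits.append(MotifHit(int(offset), strand, float(frac)))
    return hits


def build_motif_hit_index(
    sequences: Sequence[str],
    pwms: Sequence[PWMRecord],
    match_fraction: float = DEFAULT_MATCH_FRACTION,
    background: Sequence[float] = (0.25,) * 4,
    literal_fraction: bool = False,
) -> MotifHitIndex:
    """Scan every peak sequence with every PWM; record best hit per (peak, TF)."""
    index = MotifHitIndex()
    for p_idx, seq in enumerate(sequences):
        for pwm in pwms:
            for hit in scan_peak(
                seq, pwm, match_fraction, background, literal_fraction
            ):
                index.add(p_idx, pwm.tf_name, hit.score_fraction)
    return index


def hit_index_from_table(table: pd.DataFrame) -> MotifHitIndex:
    """Build a hit index from a table with columns peak_index, tf_name
    (and optionally score_fraction), for use when no genome is available."""
    index = MotifHitIndex()
    frac = table["score_fraction"] if "score_fraction" in table.columns else None
    for i, row in enumerate(table.itertuples(index=False)):
        index.add(int(row.peak_index), str(row.tf_name), float(frac.iloc[i]) if frac is not None else 1.0)
    return index


def label_active_regions(
    peaks: Sequence[GenomicInterval],
    motif_hit_index: MotifHitIndex,
    tf_activity: TFActivity,
    ca_counts: pd.DataFrame | np.ndarray,
    require_fragment: bool = True,
) -> np.ndarray:
    """Binary peaks x cells mask of active accessible regions.

    A peak is active in a cell iff some TF has a qualifying motif hit in
    the peak and is active in that cell — and, when ``require_fragment``
    (the default), the peak holds at least one fragment in that cell.
    """
    counts = ca_counts.to_numpy() if isinstance(ca_counts, pd.DataFrame) else np.asarray(ca_counts)
    n_peaks, n_cells = counts.shape
    if n_peaks != len(peaks):
        raise ValueError("ca_counts rows must match the peak list")
    if len(motif_hit_index) == 0:
        logger.warning("label_active_regions: empty motif hit index, all-zero mask")
        return np.zeros((n_peaks, n_cells), dtype=np.int8)
    active_by_tf = {
        tf: tf_activity.is_active(tf) for tf in tf_activity.auc.index
    }
    mask = np.zeros((n_peaks, n_cells), dtype=np.int8)
    for p_idx, tf_hits in motif_hit_index.hits.items():
        row = np.zeros(n_cells, dtype=bool)
        for tf in tf_hits:
            if tf in active_by_tf:
                row |= active_by_tf[tf]
        mask[p_idx] = row
    if require_fragment:
        mask &= (counts >= 1).astype(np.int8)
    return mask
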