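"""Validation of inferred links against chromatin-interaction anchors.

A link is *supported* when some interaction places one anchor over the
link's peak and the other over the gene's promoter (TSS plus/minus a
promoter window), in either anchor assignment.  The per-strategy
proportion of supported links is the headline comparison between the
inference strategies; the three-way overlap of the strategies' link sets
is reported alongside.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np

from .iofmt import GeneRecord, GenomicInterval, InteractionRecord
from .linkinfer import RegulatoryLink

DEFAULT_PROMOTER_WINDOW = 2000


def _overlaps_slop(a: GenomicInterval, b: GenomicInterval, slop: int) -> bool:
    return a.chrom == b.chrom and a.start < b.end + slop and b.start - slop < a.end


def link_supported(
    link: RegulatoryLink,
    peaks: Sequence[GenomicInterval],
    genes_by_id: Mapping[str, GeneRecord],
    interactions: Sequence[InteractionRecord],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    anchor_slop: int = 0,
) -> bool:
    """True iff some interaction joins the link's peak to its gene's promoter."""
    peak = peaks[link.peak_index]
    gene = genes_by_id[link.gene_id]
    tss_lo = max(0, gene.tss - promoter_window)
    promoter = GenomicInterval(gene.interval.chrom, tss_lo, gene.tss + promoter_window + 1)
    for rec in interactions:
        if (
            _overlaps_slop(peak, rec.anchor1, anchor_slop)
            and _overlaps_slop(promoter, rec.anchor2, anchor_slop)
        ) or (
            _overlaps_slop(peak, rec.anchor2, anchor_slop)
            and _overlaps_slop(promoter, rec.anchor1, anchor_slop)
        ):
            return True
    return False


def validation_proportion(
    links: Sequence[RegulatoryLink],
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    interactions: Sequence[InteractionRecord],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    anchor_slop: int = 0,
) -> dict[int, dict[str, float]]:
    """Fraction of supported links per strategy.

    Returns ``{strategy: {"supported": k, "total": n, "proportion": k/n}}``;
    an empty link set is an error, an empty interaction set yields 0.
    """
    if not links:
        raise ValueError("no links to validate")
    genes_by_id = {g.gene_id: g for g in genes}
    counts: Counter[int] = Counter()
    supported: Counter[int] = Counter()
    for link in links:
        counts[link.strategy] += 1
        if interactions and link_supported(
            link, peaks, genes_by_id, interactions, promoter_window, anchor_slop
        ):
            supported[link.strategy] += 1
    return {
        s: {
            "supported": supported[s],
            "total": counts[s],
            "proportion": supported[s] / counts[s],
        }
        for s in sorted(counts)
    }


def strategy_overlap(
    links_by_strategy: Mapping[int, Sequence[RegulatoryLink]],
) -> dict[str, int]:
    """Counts of every region of the three-set Venn diagram of link keys.

    Region names are e.g. ``"1"`` (strategy 1 only), ``"1&3"``,
    ``"1&2&3"``.  Strategies missing from the mapping contribute empty
    sets.
    """
    sets = {
        s: {l.key for l in links_by_strategy.get(s, ())} for s in (1, 2, 3)
    }
    universe = sets[1] | sets[2] | sets[3]
    regions: Counter[str] = Counter()
    for key in universe:
        member = [str(s) for s in (1, 2, 3) if key in sets[s]]
        regions["&".join(member)] += 1
    return {
        name: regions.get(name, 0)
        for name in ("1", "2", "3", "1&2", "1&3", "2&3", "1&2&3")
    }
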