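"""Readers and writers for the standard genomic formats the pipeline touches.

Every coordinate in this package is BED-style: 0-based, half-open
``[start, end)``.  GTF input (1-based, inclusive) is converted on read,
exactly once.  Strand ``"."`` is treated as ``"+"`` wherever a transcription
start site has to be derived.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}
_BASES = ("A", "C", "G", "T")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its strand-aware transcription start site.

    ``tss`` is the first transcribed base: ``interval.start`` on the plus
    (or unknown) strand, ``interval.end - 1`` on the minus strand.
    """

    gene_id: str
    interval: GenomicInterval
    tss: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.tss == -1:
            tss = (
                self.interval.start
                if self.interval.strand in ("+", ".")
                else self.interval.end - 1
            )
            object.__setattr__(self, "tss", tss)
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError(
                f"tss {self.tss} outside interval "
                f"[{self.interval.start},{self.interval.end})"
            )


@dataclass(frozen=True)
class PWMRecord:
    """A position probability matrix over A/C/G/T with its pseudocount.

    ``matrix`` has shape (length, 4), each row summing to one after the
    pseudocount has been added to every cell of the raw count matrix.
    """

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if m.shape[0] < 4:
            raise ValueError(f"PWM length must be >= 4, got {m.shape[0]}")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class InteractionRecord:
    """A chromatin-interaction anchor pair, anchors in canonical order."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    score: float | None = None

    def __post_init__(self) -> None:
        a, b = self.anchor1, self.anchor2
        if (a.chrom, a.start, a.end) > (b.chrom, b.start, b.end):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)


def _split_line(line: str) -> list[str]:
    return line.rstrip("\n").rstrip("\r").split("\t")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>=3 columns) into a list of intervals.

    Coordinates are kept verbatim (BED is already 0-based half-open).
    Column 6, when present, supplies the strand.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line)
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not intervals:
        logger.warning("BED file %s contained no intervals", path)
    return intervals


def _dedup_longest(records: list[GeneRecord]) -> list[GeneRecord]:
    by_id: dict[str, GeneRecord] = {}
    for rec in records:
        prev = by_id.get(rec.gene_id)
        if prev is None:
            by_id[rec.gene_id] = rec
        else:
            logger.warning("duplicated gene_id %s: keeping longest interval", rec.gene_id)
            if len(rec.interval) > len(prev.interval):
                by_id[rec.gene_id] = rec
    return list(by_id.values())


def _read_gtf(path: Path) -> list[GeneRecord]:
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path),
            tmp.name,
            force=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        records: list[GeneRecord] = []
        featuretypes = set(db.featuretypes())
        ftype = "gene" if "gene" in featuretypes else None
        feats = db.features_of_type(ftype) if ftype else db.all_features()
        for feat in feats:
            if "gene_id" not in feat.attributes:
                raise ParseError(f"{path}: feature without gene_id attribute at line {feat.start}")
            gene_id = feat.attributes["gene_id"][0]
            strand = feat.strand if feat.strand in VALID_STRANDS else "."
            # GTF is 1-based inclusive; convert once to 0-based half-open.
            interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
            records.append(GeneRecord(gene_id, interval))
    return _dedup_longest(records)


def _read_tss_table(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: tss_table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        strand = row.strand if row.strand in VALID_STRANDS else "."
        tss = int(row.tss)
        if "start" in df.columns and "end" in df.columns:
            interval = GenomicInterval(row.chrom, int(row.start), int(row.end), strand)
        else:
            # degenerate single-base gene body around the TSS
            interval = GenomicInterval(row.chrom, tss, tss + 1, strand)
        records.append(GeneRecord(row.gene_id, interval, tss))
    return _dedup_longest(records)


def read_gene_annotation(path: str | Path, dialect: str = "gtf") -> list[GeneRecord]:
    """Read gene models from a GTF file or a simplified TSS table.

    The TSS table dialect is a TSV with columns gene_id, chrom, tss, strand
    (optionally start/end for the gene body).
    """
    path = Path(path)
    if dialect == "gtf":
        return _read_gtf(path)
    if dialect == "tss_table":
        return _read_tss_table(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def read_count_matrix(
    path: str | Path,
    row_names_path: str | Path | None = None,
    col_names_path: str | Path | None = None,
) -> pd.DataFrame:
    """Read a features x cells count matrix.

    Either a dense tab-delimited table with a header row and row names in
    the first column, or a matrix-market triplet file accompanied by two
    one-name-per-line sidecar files (rows, then columns).
    """
    path = Path(path)
    if row_names_path is not None or col_names_path is not None:
        if row_names_path is None or col_names_path is None:
            raise ValueError("matrix-market input needs both name sidecar files")
        mat = scipy.io.mmread(str(path))
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = [l.strip() for l in Path(row_names_path).read_text().splitlines() if l.strip()]
        cols = [l.strip() for l in Path(col_names_path).read_text().splitlines() if l.strip()]
        if len(rows) != mat.shape[0]:
            raise ParseError(
                f"{row_names_path}: {len(rows)} row names for matrix with {mat.shape[0]} rows"
            )
        if len(cols) != mat.shape[1]:
            raise ParseError(
                f"{col_names_path}: {len(cols)} column names for matrix with {mat.shape[1]} columns"
            )
        df = pd.DataFrame(np.asarray(mat), index=rows, columns=cols)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate row names")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate column names")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ParseError(f"{path}: non-numeric entries")
    if (values < 0).any():
        raise ParseError(f"{path}: negative entries in count matrix")
    if not np.allclose(values, np.round(values)):
        raise ParseError(f"{path}: non-integer entries in count matrix")
    return df.astype(np.int64)


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled matrix as matrix-market plus .rows/.cols sidecars."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(df.to_numpy()))
    path.with_suffix(path.suffix + ".rows").write_text("\n".join(map(str, df.index)) + "\n")
    path.with_suffix(path.suffix + ".cols").write_text("\n".join(map(str, df.columns)) + "\n")


def read_jaspar_pfm(path: str | Path, pseudocount: float = 1.0) -> list[PWMRecord]:
    """Read JASPAR-style position frequency matrices.

    Each record is a ``>name`` header followed by four equal-length rows of
    counts in A, C, G, T order; rows may carry the ``A [ ... ]`` letter/
    bracket decoration.  Counts are converted to probabilities after the
    pseudocount has been added to every cell.
    """
    path = Path(path)
    records: list[PWMRecord] = []
    name: str | None = None
    rows: list[list[float]] = []

    def _flush(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if len(rows) != 4:
            raise ParseError(f"{path}:{lineno}: motif {name!r} needs 4 rows (A,C,G,T), got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ParseError(f"{path}:{lineno}: motif {name!r} has rows of unequal length")
        counts = np.array(rows, dtype=float).T  # (length, 4)
        smoothed = counts + pseudocount
        denom = smoothed.sum(axis=1, keepdims=True)
        if (denom == 0).any():
            raise ParseError(f"{path}:{lineno}: motif {name!r} has an all-zero position")
        records.append(PWMRecord(name, smoothed / denom, pseudocount))
        name, rows = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                name = line[1:].split()[0]
                continue
            cleaned = line
            if cleaned[0] in "ACGTacgt" and (len(cleaned) == 1 or not cleaned[1].isdigit()):
                cleaned = cleaned[1:]
            cleaned = cleaned.replace("[", " ").replace("]", " ")
            try:
                rows.append([float(tok) for tok in cleaned.split()])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric count") from exc
        _flush(lineno + 1)
    return records


def read_bedpe(path: str | Path) -> list[InteractionRecord]:
    """Read a BEDPE interaction file (>=6 columns); anchors are normalized
    to canonical (chrom, start) order.  Interchromosomal pairs are kept."""
    path = Path(path)
    records: list[InteractionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_line(line)
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 columns")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            score: float | None = None
            if len(fields) >= 8:
                try:
                    score = float(fields[7])
                except ValueError:
                    score = None
            records.append(InteractionRecord(a, b, score))
    return records


LINK_COLUMNS = [
    "peak_chrom",
    "peak_start",
    "peak_end",
    "gene_id",
    "strategy",
    "statistic",
    "p_or_rho",
    "n_cells_on",
]


def links_to_frame(links: Sequence, peaks: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Tabulate RegulatoryLink objects against their peak coordinates."""
    rows = []
    for link in links:
        peak = peaks[link.peak_index]
        rows.append(
            {
                "peak_chrom": peak.chrom,
                "peak_start": peak.start,
                "peak_end": peak.end,
                "gene_id": link.gene_id,
                "strategy": link.strategy,
                "statistic": link.statistic_name,
                "p_or_rho": link.statistic,
                "n_cells_on": link.n_cells_on,
            }
        )
    df = pd.DataFrame(rows, columns=LINK_COLUMNS)
    return df.sort_values(["gene_id", "peak_chrom", "peak_start"], kind="stable").reset_index(
        drop=True
    )


def write_links(links: Sequence, peaks: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write links as a TSV with a stable (gene_id, chrom, start) ordering."""
    links_to_frame(links, peaks).to_csv(path, sep="\t", index=False)


def read_links_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
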