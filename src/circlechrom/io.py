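"""Readers and writers for the external representations used by the pipeline.

All coordinates are 0-based half-open, including everything emitted as
BED/bedGraph.  Tabular inputs are plain TSVs with a fixed header:

* mod-call table:   ``read_id  ref  pos  strand  prob``
* alignment table:  ``read_id  read_start  read_end  chrom  ref_start  ref_end  strand``

Modification probabilities are serialized to 4 decimal places, which is the
precision regime of the probability cutoff (0.53) with headroom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pyfaidx

MODCALL_COLUMNS = ("read_id", "ref", "pos", "strand", "prob")
ALIGNMENT_COLUMNS = (
    "read_id",
    "read_start",
    "read_end",
    "chrom",
    "ref_start",
    "ref_end",
    "strand",
)

STRANDS = ("+", "-")


class TableFormatError(ValueError):
    """A tabular input violated its schema; carries the 1-based line number."""

    def __init__(self, path, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        loc = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{loc}: {message}")


@dataclass(frozen=True)
class GenomeSequence:
    """A named reference sequence over {A, C, G, T, N}."""

    name: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def base_at(self, pos: int) -> str:
        if not 0 <= pos < self.length:
            raise IndexError(f"position {pos} outside [0, {self.length}) on {self.name}")
        return self.seq[pos]

    def subseq(self, start: int, end: int) -> str:
        if not (0 <= start < end <= self.length):
            raise IndexError(
                f"interval [{start}, {end}) outside [0, {self.length}) on {self.name}"
            )
        return self.seq[start:end]


@dataclass(frozen=True)
class SegmentAlignment:
    """One mapped block of a long read: read interval <-> reference interval."""

    read_id: str
    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str

    def __post_init__(self):
        if self.read_start >= self.read_end:
            raise ValueError(f"read interval empty: [{self.read_start}, {self.read_end})")
        if self.ref_start >= self.ref_end:
            raise ValueError(f"reference interval empty: [{self.ref_start}, {self.ref_end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def read_len(self) -> int:
        return self.read_end - self.read_start

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class GeneAnnotation:
    """A gene anchored by its transcription start (TSS) and end (TES).

    For a + strand gene tss < tes; for a - strand gene tss > tes — the TSS is
    always the transcription start, whatever the genomic orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    expression: float | None = None

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")
        if self.expression is not None and self.expression < 0:
            raise ValueError(f"gene {self.gene_id}: negative expression")


# ---------------------------------------------------------------------------
# generic validated TSV reading


def _read_tsv(path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # wrong field count etc.
        raise TableFormatError(path, None, f"malformed table: {exc}") from exc
    if tuple(df.columns) != tuple(columns):
        raise TableFormatError(
            path, 1, f"header must be {list(columns)}, got {list(df.columns)}"
        )
    return df


def _numeric(df: pd.DataFrame, col: str, path, kind=np.int64):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 1-based
        raise TableFormatError(path, line, f"column {col!r}: cannot parse {df[col][bad].iloc[0]!r}")
    return vals.to_numpy(dtype=kind)


def _check_strand(df: pd.DataFrame, path):
    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise TableFormatError(path, line, f"strand must be + or -, got {df['strand'][bad].iloc[0]!r}")


def read_modcall_table(path) -> pd.DataFrame:
    """Read a per-read m6A mod-call table.

    Returns a DataFrame with columns read_id, ref, pos (int), strand, prob
    (float in [0, 1]).  Malformed rows raise :class:`TableFormatError` naming
    the offending line.
    """
    raw = _read_tsv(path, MODCALL_COLUMNS)
    _check_strand(raw, path)
    pos = _numeric(raw, "pos", path, np.int64)
    prob = _numeric(raw, "prob", path, np.float64)
    out_of_range = (prob < 0) | (prob > 1)
    if out_of_range.any():
        line = int(np.flatnonzero(out_of_range)[0]) + 2
        raise TableFormatError(path, line, f"prob {prob[out_of_range][0]} outside [0, 1]")
    return pd.DataFrame(
        {
            "read_id": raw["read_id"].to_numpy(),
            "ref": raw["ref"].to_numpy(),
            "pos": pos,
            "strand": raw["strand"].to_numpy(),
            "prob": prob,
        }
    )


def write_modcall_table(calls: pd.DataFrame, path) -> None:
    df = calls.loc[:, list(MODCALL_COLUMNS)].copy()
    df["prob"] = df["prob"].map(lambda p: f"{p:.4f}")
    df.to_csv(path, sep="\t", index=False)


def read_alignment_table(path) -> pd.DataFrame:
    """Read a split-alignment table (one row per mapped segment)."""
    raw = _read_tsv(path, ALIGNMENT_COLUMNS)
    _check_strand(raw, path)
    out = {"read_id": raw["read_id"].to_numpy(), "chrom": raw["chrom"].to_numpy(),
           "strand": raw["strand"].to_numpy()}
    for col in ("read_start", "read_end", "ref_start", "ref_end"):
        out[col] = _numeric(raw, col, path, np.int64)
    df = pd.DataFrame(out)[list(ALIGNMENT_COLUMNS)]
    empty = (df["read_start"] >= df["read_end"]) | (df["ref_start"] >= df["ref_end"])
    if empty.any():
        line = int(np.flatnonzero(empty.to_numpy())[0]) + 2
        raise TableFormatError(path, line, "empty read or reference interval")
    return df


def write_alignment_table(segments: pd.DataFrame, path) -> None:
    segments.loc[:, list(ALIGNMENT_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_genome_fasta(path) -> dict[str, GenomeSequence]:
    """Load a FASTA file into named in-memory sequences (uppercased)."""
    fa = pyfaidx.Fasta(str(path), sequence_always_upper=True, rebuild=True)
    try:
        return {name: GenomeSequence(name, str(fa[name][:])) for name in fa.keys()}
    finally:
        fa.close()


def write_fasta(seqs: Mapping[str, str] | Iterable[GenomeSequence], path, width: int = 80) -> None:
    if isinstance(seqs, Mapping):
        items = seqs.items()
    else:
        items = ((s.name, s.seq) for s in seqs)
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene annotations


def read_gene_bed(path, dialect: str = "bed") -> list[GeneAnnotation]:
    """Read gene annotations from BED6 (default) or GFF (``dialect='gff'``).

    BED is 0-based half-open as-is; GFF coordinates are converted from
    1-based closed to 0-based half-open.  TSS/TES are assigned by strand.
    """
    path = Path(path)
    if dialect not in ("bed", "gff"):
        raise ValueError(f"dialect must be 'bed' or 'gff', got {dialect!r}")
    genes: list[GeneAnnotation] = []
    if dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 6:
            raise TableFormatError(path, 1, f"BED6 required (strand column), got {df.shape[1]} columns")
        for i, row in enumerate(df.itertuples(index=False), start=1):
            chrom, start, end, name, _score, strand = row[:6]
            if strand not in STRANDS:
                raise TableFormatError(path, i, f"strand must be + or -, got {strand!r}")
            start, end = int(start), int(end)
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(GeneAnnotation(name, chrom, strand, tss, tes))
    else:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 9:
            raise TableFormatError(path, 1, f"GFF requires 9 columns, got {df.shape[1]}")
        for i, row in enumerate(df.itertuples(index=False), start=1):
            chrom, _src, _feat, start1, end1, _score, strand, _frame, attrs = row[:9]
            if strand not in STRANDS:
                raise TableFormatError(path, i, f"strand must be + or -, got {strand!r}")
            start, end = int(start1) - 1, int(end1)  # 1-based closed -> 0-based half-open
            gene_id = _gff_gene_id(attrs, default=f"gene_{i}")
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(GeneAnnotation(gene_id, chrom, strand, tss, tes))
    return genes


def _gff_gene_id(attrs: str, default: str) -> str:
    for part in str(attrs).replace(";", " ").split():
        for key in ("ID=", "gene_id="):
            if part.startswith(key):
                return part[len(key):].strip('"')
    return default


def write_gene_bed(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = (g.tss, g.tes) if g.strand == "+" else (g.tes, g.tss)
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


def attach_expression(genes: Sequence[GeneAnnotation], path) -> list[GeneAnnotation]:
    """Attach per-gene expression values from a 2-column TSV (gene_id, value)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: float})
    if df.shape[1] != 2:
        raise TableFormatError(path, 1, "expression table needs exactly 2 columns")
    values = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    for g in genes:
        if g.gene_id in values:
            g.expression = float(values[g.gene_id])
    return list(genes)


def write_expression_table(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for g in genes:
            if g.expression is not None:
                fh.write(f"{g.gene_id}\t{g.expression:.4f}\n")


# ---------------------------------------------------------------------------
# track / record output


def write_bedgraph(tracks, path) -> None:
    """Write one or several BinnedTracks as 4-column bedGraph.

    Bins with undefined ratio (zero covered adenosines) are omitted.  Tracks
    must arrive sorted and a reference may not reappear after another one has
    started (interleaving is an error).
    """
    if not isinstance(tracks, (list, tuple)):
        tracks = [tracks]
    seen: set[str] = set()
    prev_ref = None
    with open(path, "w") as fh:
        for track in tracks:
            if track.ref != prev_ref:
                if track.ref in seen:
                    raise ValueError(f"reference {track.ref!r} interleaved in bedGraph output")
                seen.add(track.ref)
                prev_ref = track.ref
            starts = np.asarray(track.starts)
            if np.any(np.diff(starts) <= 0):
                raise ValueError("track bins not sorted by start")
            ratio = track.ratio
            for s, r in zip(starts, ratio):
                if np.isnan(r):
                    continue
                fh.write(f"{track.ref}\t{s}\t{s + track.width}\t{r:.6g}\n")


def write_ecdna_bed(records, path) -> None:
    """Write clustered circle records as BED: name=ecdna_<k>, score=support."""
    with open(path, "w") as fh:
        for k, rec in enumerate(records):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\tecdna_{k}\t{rec.support}\n")


def write_ecdna_json(records, path) -> None:
    payload = [
        {
            "name": f"ecdna_{k}",
            "chrom": rec.chrom,
            "start": int(rec.start),
            "end": int(rec.end),
            "support": int(rec.support),
            "read_ids": sorted(rec.read_ids),
        }
        for k, rec in enumerate(records)
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
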