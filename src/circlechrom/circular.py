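"""Rotated, N-padded reference sequences for detected circles.

Aligning junction-spanning reads against the linear genome loses the
modified-base signal around the head-to-tail junction, so each detected
circle gets its own reference: the genomic interval rotated so the junction
sits mid-sequence, with N pads on both ends to keep long reads mappable.

Coordinates on such a reference lift back to the genome through the inverse
rotation; pad positions have no genomic image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import EcDNARecord
from .io import GenomeSequence

DEFAULT_PAD = 10_000


@dataclass(frozen=True)
class CircularReference:
    """A circle's private reference: N^pad + rotate(core, rotation) + N^pad.

    ``rotation`` moves the first ``rotation`` bases of the genomic interval to
    the end of the core, so the head-to-tail junction (genomic end joining
    genomic start) sits at core offset ``size - rotation``.
    """

    name: str
    origin_chrom: str
    origin_start: int
    origin_end: int
    rotation: int
    pad: int
    seq: str

    def __post_init__(self):
        size = self.origin_end - self.origin_start
        if size <= 0:
            raise ValueError("empty origin interval")
        if not 0 <= self.rotation < size:
            raise ValueError(f"rotation {self.rotation} outside [0, {size})")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")
        if len(self.seq) != size + 2 * self.pad:
            raise ValueError("sequence length inconsistent with size and pad")

    @property
    def size(self) -> int:
        return self.origin_end - self.origin_start

    @property
    def junction_pos(self) -> int:
        """Position (in reference coordinates) of the first base past the
        junction, i.e. the genomic start base."""
        return self.pad + (self.size - self.rotation)

    @property
    def core_start(self) -> int:
        return self.pad

    @property
    def core_end(self) -> int:
        return self.pad + self.size


def build_reference(
    genome: GenomeSequence | dict[str, GenomeSequence],
    rec: EcDNARecord,
    rotation: int | None = None,
    pad: int = DEFAULT_PAD,
    name: str | None = None,
) -> CircularReference:
    """Assemble the rotated, padded reference for one circle record.

    By default the rotation is size // 2, centering the junction so that
    window-based scoring has full context on both sides.
    """
    if isinstance(genome, dict):
        if rec.chrom not in genome:
            raise KeyError(f"chromosome {rec.chrom!r} not in genome")
        genome = genome[rec.chrom]
    size = rec.end - rec.start
    if rotation is None:
        rotation = size // 2
    if not (0 <= rec.start < rec.end <= genome.length):
        raise IndexError(
            f"record [{rec.start}, {rec.end}) outside chromosome of length {genome.length}"
        )
    if not 0 <= rotation < size:
        raise ValueError(f"rotation {rotation} outside [0, {size})")
    core = genome.subseq(rec.start, rec.end)
    rotated = core[rotation:] + core[:rotation]
    seq = "N" * pad + rotated + "N" * pad
    if name is None:
        name = f"{rec.chrom}_{rec.start}_{rec.end}_circle"
    return CircularReference(name, rec.chrom, rec.start, rec.end, rotation, pad, seq)


def liftover_to_genome(ref: CircularReference, pos: int) -> tuple[str, int] | None:
    """Map a circular-reference position to (chrom, genome position).

    Pad positions return None; out-of-range positions raise.
    """
    if not 0 <= pos < len(ref.seq):
        raise IndexError(f"position {pos} outside [0, {len(ref.seq)})")
    core = pos - ref.pad
    if core < 0 or core >= ref.size:
        return None
    return ref.origin_chrom, ref.origin_start + (core + ref.rotation) % ref.size


def liftover_from_genome(ref: CircularReference, chrom: str, genome_pos: int) -> int | None:
    """Inverse of :func:`liftover_to_genome` for positions inside the circle's
    genomic interval; None if the position is outside it."""
    if chrom != ref.origin_chrom:
        return None
    off = genome_pos - ref.origin_start
    if off < 0 or off >= ref.size:
        return None
    return ref.pad + (off - ref.rotation) % ref.size


def junction_distance(ref: CircularReference, pos: int) -> int:
    """Signed circular distance (bp) from the head-to-tail junction point.

    Positive values run downstream of the junction (into the genomic start of
    the circle); the range is (-size/2, size/2].  Pad positions are an error.
    """
    if not 0 <= pos < len(ref.seq):
        raise IndexError(f"position {pos} outside [0, {len(ref.seq)})")
    core = pos - ref.pad
    if core < 0 or core >= ref.size:
        raise ValueError(f"position {pos} falls in an N pad; no junction distance")
    d = (core - (ref.size - ref.rotation)) % ref.size
    if d > ref.size // 2:
        d -= ref.size
    return d


def calls_to_circular(
    calls: pd.DataFrame, ref: CircularReference, read_ids=None
) -> pd.DataFrame:
    """Re-express genome-coordinate mod calls in a circle's own coordinates.

    Keeps only calls on the circle's chromosome that fall inside its genomic
    interval (optionally restricted to its supporting reads); ``ref``/``pos``
    columns are rewritten to the circular reference.
    """
    sub = calls[calls["ref"] == ref.origin_chrom]
    if read_ids is not None:
        sub = sub[sub["read_id"].isin(set(read_ids))]
    off = sub["pos"].to_numpy() - ref.origin_start
    inside = (off >= 0) & (off < ref.size)
    sub = sub.loc[inside].copy()
    new_pos = ref.pad + (sub["pos"].to_numpy() - ref.origin_start - ref.rotation) % ref.size
    sub["ref"] = ref.name
    sub["pos"] = new_pos.astype(np.int64)
    return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sidecar (de)serialization so liftover survives a round-trip through FASTA


def write_sidecar(refs: list[CircularReference], path) -> None:
    payload = [
        {
            "name": r.name,
            "origin_chrom": r.origin_chrom,
            "origin_start": r.origin_start,
            "origin_end": r.origin_end,
            "rotation": r.rotation,
            "pad": r.pad,
        }
        for r in refs
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_sidecar(path, sequences: dict[str, GenomeSequence]) -> list[CircularReference]:
    with open(path) as fh:
        payload = json.load(fh)
    refs = []
    for d in payload:
        seq = sequences[d["name"]].seq
        refs.append(
            CircularReference(
                d["name"], d["origin_chrom"], d["origin_start"], d["origin_end"],
                d["rotation"], d["pad"], seq,
            )
        )
    return refs
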