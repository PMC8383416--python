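"""Synthetic data with known truth for every stage of the pipeline.

The generator emulates a methyltransferase-footprinting long-read experiment
on a genome carrying simple excision circles: reads are 5-50 kb (the real
experiment's 10-100 kb scaled to a desk-size 100 kb genome), a small fixed
fraction (0.9%) of reads derive from circles and align head-to-tail when
they cross the junction, and every adenosine on a read's template strand
receives an m6A probability drawn from a noise distribution (mean 0.49)
under nucleosomes or a signal distribution (mean 0.85) in open chromatin.
Open/closed truth is an alternating 147/50 bp nucleosome/linker tiling with
optional nucleosome-depleted regions (NDRs) at TSSs.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import GenomeSequence, GeneAnnotation, ALIGNMENT_COLUMNS, MODCALL_COLUMNS

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Knobs of the generator; defaults are the study conditions."""

    seed: int = 7
    chrom_name: str = "sim1"
    genome_len: int = 100_000
    n_genes: int = 8
    gene_len_range: tuple[int, int] = (2_000, 5_000)
    nucleosome_len: int = 147
    linker_len: int = 50
    ndr_at_tss: bool = True
    ndr_width: int = 300
    uniform_open: bool = False
    n_ecdna: int = 5
    ecdna_size_range: tuple[int, int] = (2_000, 10_000)
    ecdna_read_frac: float = 0.009
    read_len_range: tuple[int, int] = (5_000, 50_000)
    noise_mean: float = 0.49
    noise_sd: float = 0.05
    signal_mean: float = 0.85
    signal_sd: float = 0.08
    strand_asymmetry: float = 0.0
    coverage: float = 30.0
    breakpoint_jitter: int = 0
    junction_open_width: int = 0
    beta_probs: bool = False

    def __post_init__(self):
        if self.genome_len <= 0 or self.nucleosome_len <= 0 or self.linker_len < 0:
            raise ValueError("lengths must be positive")
        if not 0 <= self.ecdna_read_frac <= 1:
            raise ValueError("ecdna_read_frac must lie in [0, 1]")
        if not self.signal_mean > self.noise_mean:
            raise ValueError("signal_mean must exceed noise_mean")
        for lo, hi in (self.gene_len_range, self.ecdna_size_range, self.read_len_range):
            if not 0 < lo <= hi:
                raise ValueError("ranges must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class TruthCircle:
    """A true excision circle: the interval the simulator circularized."""

    name: str
    chrom: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Everything the generator knows that the pipeline must recover."""

    mask: dict[str, np.ndarray]            # True = open chromatin
    dyads: dict[str, np.ndarray]           # nucleosome dyad positions (no NDR overlap)
    circles: list[TruthCircle] = field(default_factory=list)
    read_truth: pd.DataFrame | None = None


@dataclass
class SimData:
    config: SimConfig
    genome: dict[str, GenomeSequence]
    genes: list[GeneAnnotation]
    truth: TruthSet
    alignments: pd.DataFrame
    calls: pd.DataFrame
    control_calls: pd.DataFrame | None = None


# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Uniform-random genome, non-overlapping alternating-strand genes and a
    nucleosome/linker chromatin truth mask (with NDRs at TSSs if enabled)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome_len
    seq = "".join(_BASES[rng.integers(0, 4, size=L)])
    genome = {config.chrom_name: GenomeSequence(config.chrom_name, seq)}

    # genes: one per equal slot, margins keep +-500 bp flanks inside the slot
    margin = 600
    genes: list[GeneAnnotation] = []
    if config.n_genes > 0:
        slot = L // config.n_genes
        if slot - 2 * margin < config.gene_len_range[0]:
            raise ValueError("genes cannot be placed: genome too small for n_genes")
        for g in range(config.n_genes):
            glen = int(rng.integers(
                config.gene_len_range[0],
                min(config.gene_len_range[1], slot - 2 * margin) + 1,
            ))
            lo = g * slot + margin
            hi = (g + 1) * slot - margin - glen
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if g % 2 == 0 else "-"
            tss, tes = (start, start + glen) if strand == "+" else (start + glen, start)
            expression = float(np.round(10.0 * rng.lognormal(0.0, 1.0), 4))
            genes.append(GeneAnnotation(f"gene_{g}", config.chrom_name, strand, tss, tes, expression))

    mask = np.zeros(L, dtype=bool)
    dyads: list[int] = []
    if config.uniform_open:
        mask[:] = True
    else:
        unit = config.linker_len + config.nucleosome_len
        pos = 0
        nuc_intervals = []
        while pos + unit <= L:
            mask[pos : pos + config.linker_len] = True
            nuc_intervals.append((pos + config.linker_len, pos + unit))
            pos += unit
        mask[pos:L] = True  # trailing partial unit left open
        ndr_intervals = []
        if config.ndr_at_tss:
            half = config.ndr_width // 2
            for g in genes:
                a, b = max(0, g.tss - half), min(L, g.tss + half)
                mask[a:b] = True
                ndr_intervals.append((a, b))
        for a, b in nuc_intervals:
            if all(b <= x or a >= y for x, y in ndr_intervals):
                dyads.append(a + config.nucleosome_len // 2)

    truth = TruthSet(
        mask={config.chrom_name: mask},
        dyads={config.chrom_name: np.array(dyads, dtype=np.int64)},
    )
    return genome, genes, truth


def simulate_ecdna_events(
    config: SimConfig,
    genome: dict[str, GenomeSequence],
    rng: np.random.Generator | None = None,
) -> list[TruthCircle]:
    """Place non-overlapping single-locus excision circles uniformly."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.genome_len
    lo, hi = config.ecdna_size_range
    if hi > L:
        raise ValueError("ecdna_size_range exceeds genome length")
    circles: list[TruthCircle] = []
    taken: list[tuple[int, int]] = []
    attempts = 0
    while len(circles) < config.n_ecdna:
        attempts += 1
        if attempts > 1000 * max(config.n_ecdna, 1):
            raise ValueError("cannot place non-overlapping circles; relax sizes or count")
        size = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, L - size + 1))
        end = start + size
        if any(start < y and end > x for x, y in taken):
            continue
        taken.append((start, end))
        circles.append(TruthCircle(f"circle_{len(circles)}", config.chrom_name, start, end))
    return circles


def _probs_for_positions(config, rng, open_mask, minus_strand: bool) -> np.ndarray:
    mean_sig = config.signal_mean - (config.strand_asymmetry if minus_strand else 0.0)
    means = np.where(open_mask, mean_sig, config.noise_mean)
    sds = np.where(open_mask, config.signal_sd, config.noise_sd)
    if config.beta_probs:
        v = sds**2
        common = means * (1 - means) / np.maximum(v, 1e-6) - 1
        common = np.maximum(common, 0.5)
        draws = rng.beta(means * common, (1 - means) * common)
    else:
        draws = rng.normal(means, sds)
    return np.clip(draws, 0.0, 1.0)


def simulate_reads(
    config: SimConfig,
    genome: dict[str, GenomeSequence],
    truth: TruthSet,
    rng: np.random.Generator | None = None,
    all_noise: bool = False,
    n_reads: int | None = None,
):
    """Draw reads, emit their split alignments and per-base m6A calls.

    A fixed count round(ecdna_read_frac * n_reads) of reads derives from
    circles (the observed read composition, not a per-read coin flip); a
    circle read crossing the junction emits two same-strand, outward-oriented
    segments.  Calls are emitted at every adenosine of the read's template
    strand, in genome coordinates, with probabilities from the signal or
    noise distribution according to the truth mask (``all_noise`` forces the
    noise distribution everywhere — the unmethylated control sample).
    Returns (alignments, calls, read_truth) and stores read_truth in
    ``truth``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom = config.chrom_name
    gseq = genome[chrom]
    L = gseq.length
    seq_arr = np.frombuffer(gseq.seq.encode(), dtype="S1")
    is_a = seq_arr == b"A"
    is_t = seq_arr == b"T"
    mask = truth.mask[chrom]

    mean_len = float(np.mean(config.read_len_range))
    if n_reads is None:
        n_reads = max(1, int(round(config.coverage * L / mean_len)))
    circles = truth.circles
    n_ec = int(round(config.ecdna_read_frac * n_reads)) if circles else 0
    ec_idx = set(rng.choice(n_reads, size=n_ec, replace=False).tolist()) if n_ec else set()

    aln_rows = []
    call_frames = []
    truth_rows = []
    j = config.breakpoint_jitter

    for i in range(n_reads):
        read_id = f"read_{i:05d}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        length = int(rng.integers(config.read_len_range[0], config.read_len_range[1] + 1))
        if i in ec_idx:
            c = circles[int(rng.integers(0, len(circles)))]
            length = min(length, c.size)
            entry = int(rng.integers(c.start, c.end))
            if strand == "+":
                arm1 = min(length, c.end - entry)
                rem = length - arm1
                covered = [(entry, entry + arm1)]
                if rem > 0:
                    covered.append((c.start, c.start + rem))
            else:
                arm1 = min(length, entry - c.start)
                rem = length - arm1
                covered = [(entry - arm1, entry)]
                if rem > 0:
                    covered.append((c.end - rem, c.end))
            spans = rem > 0
            if spans:
                (a_lo, a_hi), (b_lo, b_hi) = covered
                # jitter the reported junction-side breakpoints only
                if strand == "+":
                    a_hi_r = min(L, max(a_lo + 1, a_hi + int(rng.integers(-j, j + 1)))) if j else a_hi
                    b_lo_r = max(0, min(b_hi - 1, b_lo + int(rng.integers(-j, j + 1)))) if j else b_lo
                    segs = [(a_lo, a_hi_r), (b_lo_r, b_hi)]
                else:
                    a_lo_r = max(0, min(a_hi - 1, a_lo + int(rng.integers(-j, j + 1)))) if j else a_lo
                    b_hi_r = min(L, max(b_lo + 1, b_hi + int(rng.integers(-j, j + 1)))) if j else b_hi
                    segs = [(a_lo_r, a_hi), (b_lo, b_hi_r)]
                rpos = 0
                for lo_, hi_ in segs:
                    aln_rows.append((read_id, rpos, rpos + (hi_ - lo_), chrom, lo_, hi_, strand))
                    rpos += hi_ - lo_
            else:
                lo_, hi_ = covered[0]
                aln_rows.append((read_id, 0, hi_ - lo_, chrom, lo_, hi_, strand))
            source = c.name
            start_repr = entry
            min_arm = min(arm1, rem) if spans else 0
        else:
            length = min(length, L)
            start = int(rng.integers(0, L - length + 1))
            covered = [(start, start + length)]
            aln_rows.append((read_id, 0, length, chrom, start, start + length, strand))
            source, start_repr, spans, min_arm = "linear", start, False, 0

        pos_parts = []
        for lo_, hi_ in covered:
            base_mask = is_a[lo_:hi_] if strand == "+" else is_t[lo_:hi_]
            pos_parts.append(np.flatnonzero(base_mask) + lo_)
        pos = np.concatenate(pos_parts) if pos_parts else np.array([], dtype=np.int64)
        if pos.size:
            if all_noise:
                open_here = np.zeros(pos.size, dtype=bool)
            else:
                open_here = mask[pos].copy()
                if i in ec_idx and config.junction_open_width > 0:
                    half = config.junction_open_width // 2
                    dist = np.minimum(pos - c.start, c.end - pos)
                    open_here |= dist < half
            probs = _probs_for_positions(config, rng, open_here, strand == "-")
            call_frames.append(
                pd.DataFrame(
                    {
                        "read_id": read_id,
                        "ref": chrom,
                        "pos": pos.astype(np.int64),
                        "strand": strand,
                        "prob": np.round(probs, 4),
                    }
                )
            )
        truth_rows.append((read_id, source, chrom, strand, length, start_repr, spans, min_arm))

    alignments = pd.DataFrame(aln_rows, columns=list(ALIGNMENT_COLUMNS))
    calls = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else pd.DataFrame(columns=list(MODCALL_COLUMNS))
    )
    read_truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "source", "chrom", "strand", "length", "start", "spans_junction", "min_arm"],
    )
    if not all_noise:
        truth.read_truth = read_truth
    return alignments, calls, read_truth


def simulate_dataset(config: SimConfig, with_control: bool = False) -> SimData:
    """Run the whole generator under one seed: genome, circles, reads, calls.

    ``with_control`` additionally simulates an unmethylated control sample
    (all-noise probabilities, 20% of the read count).
    """
    rng = np.random.default_rng(config.seed)
    genome, genes, truth = simulate_genome(config, rng)
    truth.circles = simulate_ecdna_events(config, genome, rng)
    alignments, calls, _ = simulate_reads(config, genome, truth, rng)
    control = None
    if with_control:
        mean_len = float(np.mean(config.read_len_range))
        n_ctrl = max(1, int(round(0.2 * config.coverage * config.genome_len / mean_len)))
        _, control, _ = simulate_reads(config, genome, truth, rng, all_noise=True, n_reads=n_ctrl)
    return SimData(config, genome, genes, truth, alignments, calls, control)


def detectable_circles(truth: TruthSet, min_seg_len: int = 1000, size_range=(50, 100_000)):
    """Truth circles represented by at least one junction-spanning read whose
    both arms exceed ``min_seg_len`` — the molecules a split-read detector
    could possibly see."""
    if truth.read_truth is None:
        raise ValueError("simulate_reads has not been run on this truth set")
    rt = truth.read_truth
    ok = rt[(rt["spans_junction"]) & (rt["min_arm"] > min_seg_len)]
    by_name = {c.name: c for c in truth.circles}
    lo, hi = size_range
    return [
        by_name[name]
        for name in sorted(set(ok["source"]))
        if lo <= by_name[name].size <= hi
    ]
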