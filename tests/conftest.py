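import numpy as np
import pytest

from circlechrom.simulate import SimConfig, simulate_dataset
from circlechrom import threshold as cthresh


@pytest.fixture(scope="session")
def default_sim():
    """The default study-condition simulation (seed 7, 100 kb, 5 circles, 30x)."""
    return simulate_dataset(SimConfig(), with_control=True)


@pytest.fixture(scope="session")
def default_fit(default_sim):
    return cthresh.fit_probability_mixture(default_sim.calls["prob"].to_numpy())


@pytest.fixture(scope="session")
def binarized_calls(default_sim):
    return cthresh.binarize_calls(default_sim.calls, 0.53)


@pytest.fixture(scope="session")
def sim_files(tmp_path_factory, default_sim):
    """The default simulation written out in the pipeline's input formats."""
    from circlechrom import io as cio

    out = tmp_path_factory.mktemp("simdata")
    d = default_sim
    cio.write_fasta(d.genome.values(), out / "genome.fasta")
    cio.write_gene_bed(d.genes, out / "genes.bed")
    cio.write_expression_table(d.genes, out / "expression.tsv")
    cio.write_alignment_table(d.alignments, out / "alignments.tsv")
    cio.write_modcall_table(d.calls, out / "modcalls.tsv")
    cio.write_modcall_table(d.control_calls, out / "control.tsv")
    return out


@pytest.fixture(scope="session")
def uniform_sim():
    """Uniformly open chromatin: the null for metagene flatness."""
    return simulate_dataset(SimConfig(uniform_open=True))


# ---------------------------------------------------------------------------
# independent junction-geometry oracle: simulate reading around a circle


def oracle_is_junction_pair(a, b, min_seg_len=1000):
    """Exhaustive circular-traversal oracle for a read-ordered segment pair.

    Reconstructs the only circle the pair could imply (min start, max end),
    walks the read base by base around it from the first segment's entry
    point, and accepts iff the walk reproduces both segments and crosses the
    head-to-tail junction exactly once.  Independent of classify_pair's
    coordinate inequalities.
    """
    if a.read_id != b.read_id:
        raise ValueError("different reads")
    if a.read_len <= min_seg_len or b.read_len <= min_seg_len:
        return None
    if a.chrom != b.chrom or a.strand != b.strand:
        return None
    # alignment blocks: read length equals reference length per segment
    if a.read_len != a.ref_len or b.read_len != b.ref_len:
        return None
    cs = min(a.ref_start, b.ref_start)
    ce = max(a.ref_end, b.ref_end)
    size = ce - cs
    L = a.read_len + b.read_len
    if L > size:
        return None
    if a.strand == "+":
        walk = [cs + (a.ref_start - cs + t) % size for t in range(L)]
        seg_a = list(range(a.ref_start, a.ref_end))
        seg_b = list(range(b.ref_start, b.ref_end))
    else:
        walk = [cs + (a.ref_end - 1 - cs - t) % size for t in range(L)]
        seg_a = list(range(a.ref_end - 1, a.ref_start - 1, -1))
        seg_b = list(range(b.ref_end - 1, b.ref_start - 1, -1))
    if walk[: a.read_len] != seg_a or walk[a.read_len :] != seg_b:
        return None
    # junction crossings: discontinuities in the walk direction
    step = 1 if a.strand == "+" else -1
    wraps = sum(1 for u, v in zip(walk, walk[1:]) if v - u != step)
    if wraps != 1:
        return None
    return (a.chrom, a.strand, cs, ce)
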