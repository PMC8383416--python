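"""Accessibility tracks, metagene profiles and single-molecule window calls.

The bulk accessibility score of a bin is the pooled methylation ratio:
m6A bases in all covered reads under the bin divided by adenosine bases in
all covered reads under the bin (50-bp bins sliding every 5 bp by default).
Regional averages everywhere are count-weighted pooled ratios, never means
of bin ratios.

Single-molecule accessibility aggregates the raw per-base probabilities of
one read over a window through the fitted mixture: the window's open
posterior is the normalized product of the signal-component densities
against the noise-component densities under a configurable prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import CircularReference, junction_distance
from .threshold import MixtureFit

DEFAULT_BIN = 50
DEFAULT_STEP = 5
DEFAULT_FLANK = 500

OPEN, CLOSED, NO_CALL = 1, 0, -1
STATE_NAMES = {OPEN: "open", CLOSED: "closed", NO_CALL: "no_call"}


@dataclass
class BinnedTrack:
    """Sliding-window methylation-ratio track with its raw counts."""

    ref: str
    width: int
    step: int
    starts: np.ndarray
    meth_A: np.ndarray
    total_A: np.ndarray
    strand_mode: str = "both"

    def __post_init__(self):
        if np.any(self.meth_A > self.total_A) or np.any(self.meth_A < 0):
            raise ValueError("bin counts must satisfy 0 <= meth_A <= total_A")

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total_A > 0, self.meth_A / np.maximum(self.total_A, 1), np.nan)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.width / 2


@dataclass
class MetageneProfile:
    """Mean accessibility around an anchor (TSS, TES or circle junction)."""

    anchor: str
    offsets: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    n_genes: int
    stratum: str = "all"
    # raw pooled counts per offset (all genes, all sources, unnormalized)
    pooled_meth: np.ndarray | None = None
    pooled_total: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "value": self.values, "stderr": self.stderr,
             "n": self.n_genes}
        )


@dataclass
class MoleculeWindowCalls:
    """Per-window open/closed states of a single molecule (read)."""

    read_id: str
    ref: str
    window: int
    starts: np.ndarray
    states: np.ndarray  # int8: 1 open, 0 closed, -1 no_call
    posteriors: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": self.read_id,
                "ref": self.ref,
                "start": self.starts,
                "end": self.starts + self.window,
                "state": [STATE_NAMES[s] for s in self.states],
                "posterior": self.posteriors,
            }
        )


# ---------------------------------------------------------------------------
# counting machinery


def _select_strand(calls: pd.DataFrame, strand_mode: str) -> pd.DataFrame:
    if strand_mode == "both":
        return calls
    if strand_mode in ("plus", "minus"):
        return calls[calls["strand"] == ("+" if strand_mode == "plus" else "-")]
    raise ValueError(f"strand_mode must be both/plus/minus, got {strand_mode!r}")


def position_counts(
    calls: pd.DataFrame, ref: str, length: int, strand_mode: str = "both"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position pooled (methylated, total) adenosine counts over one ref.

    ``calls`` must be binarized (carry a boolean ``methylated`` column).
    """
    sub = _select_strand(calls[calls["ref"] == ref], strand_mode)
    pos = sub["pos"].to_numpy()
    if pos.size and (pos.min() < 0 or pos.max() >= length):
        raise IndexError("call position outside reference length")
    total = np.bincount(pos, minlength=length).astype(np.int64)
    meth = np.bincount(pos[sub["methylated"].to_numpy()], minlength=length).astype(np.int64)
    return meth, total


def _window_sums(per_pos: np.ndarray, starts: np.ndarray, width: int) -> np.ndarray:
    csum = np.concatenate([[0], np.cumsum(per_pos)])
    lo = np.clip(starts, 0, per_pos.size)
    hi = np.clip(starts + width, 0, per_pos.size)
    return csum[hi] - csum[lo]


def methylation_ratio_track(
    calls: pd.DataFrame,
    ref: str,
    ref_length: int,
    bin: int = DEFAULT_BIN,
    step: int = DEFAULT_STEP,
    strand_mode: str = "both",
) -> BinnedTrack:
    """Pooled methylation-ratio track over ``ref`` (complete bins only)."""
    if not bin >= step > 0:
        raise ValueError("need bin >= step > 0")
    if ref_length < bin:
        raise ValueError(f"reference length {ref_length} shorter than bin {bin}")
    meth, total = position_counts(calls, ref, ref_length, strand_mode)
    starts = np.arange(0, ref_length - bin + 1, step, dtype=np.int64)
    return BinnedTrack(
        ref=ref,
        width=bin,
        step=step,
        starts=starts,
        meth_A=_window_sums(meth, starts, bin),
        total_A=_window_sums(total, starts, bin),
        strand_mode=strand_mode,
    )


# ---------------------------------------------------------------------------
# metagene profiles


def _depth_factor(calls: pd.DataFrame) -> float:
    """Mean per-site read depth of a call set: calls per distinct adenosine site."""
    if len(calls) == 0:
        return 1.0
    n_sites = len(calls.drop_duplicates(["ref", "pos", "strand"]))
    return len(calls) / n_sites


def metagene_profile(
    calls,
    genes,
    anchor: str = "TSS",
    flank: int = DEFAULT_FLANK,
    bin: int = DEFAULT_BIN,
    step: int = DEFAULT_STEP,
    depth_norm: bool = True,
    stratum: str = "all",
) -> MetageneProfile:
    """Mean pooled methylation ratio around gene anchors on a 5-bp grid.

    ``calls`` may be one binarized call set or a sequence of sets from
    different sources (e.g. circle-derived and linear); with ``depth_norm``
    each source's counts are divided by its mean per-site depth before
    pooling.  Minus-strand genes are flipped so positive offsets always run
    transcription-downstream.  Per-offset values are means over genes with a
    defined ratio there.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    if flank % step != 0:
        raise ValueError("flank must be a multiple of step")
    sources = [calls] if isinstance(calls, pd.DataFrame) else list(calls)
    factors = [(_depth_factor(s) if depth_norm else 1.0) for s in sources]

    offsets = np.arange(-flank, flank + 1, step, dtype=np.int64)
    half = bin // 2
    # per-source per-chrom cumulative counts
    per_chrom: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    chroms = sorted({c for s in sources for c in s["ref"].unique()})
    for chrom in chroms:
        arrs = []
        for s in sources:
            sub = s[s["ref"] == chrom]
            length = int(sub["pos"].max()) + 1 if len(sub) else 1
            meth, total = position_counts(s, chrom, length)
            arrs.append((meth, total))
        per_chrom[chrom] = arrs

    gene_ratios = []
    pooled_meth = np.zeros(offsets.size, dtype=np.int64)
    pooled_total = np.zeros(offsets.size, dtype=np.int64)
    for g in genes:
        if g.chrom not in per_chrom:
            continue
        p0 = g.tss if anchor == "TSS" else g.tes
        sign = 1 if g.strand == "+" else -1
        centers = p0 + sign * offsets
        starts = centers - half
        meth_o = np.zeros(offsets.size)
        tot_o = np.zeros(offsets.size)
        for (meth, total), f in zip(per_chrom[g.chrom], factors):
            raw_m = _window_sums(meth, starts, bin)
            raw_t = _window_sums(total, starts, bin)
            pooled_meth += raw_m
            pooled_total += raw_t
            meth_o += raw_m / f
            tot_o += raw_t / f
        with np.errstate(invalid="ignore"):
            ratio = np.where(tot_o > 0, meth_o / np.maximum(tot_o, 1e-300), np.nan)
        if np.any(tot_o > 0):
            gene_ratios.append(ratio)
    if not gene_ratios:
        raise ValueError("no usable genes: no gene has covered flanks on these references")

    mat = np.vstack(gene_ratios)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(mat, axis=0)
        n_def = np.sum(~np.isnan(mat), axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    stderr = np.where(n_def > 1, sd / np.sqrt(np.maximum(n_def, 1)), np.nan)
    return MetageneProfile(
        anchor, offsets, values, stderr, mat.shape[0], stratum, pooled_meth, pooled_total
    )


def junction_profile(
    circle_calls: list[tuple[CircularReference, pd.DataFrame]],
    flank: int = DEFAULT_FLANK,
    bin: int = DEFAULT_BIN,
    step: int = DEFAULT_STEP,
) -> MetageneProfile:
    """Mean methylation ratio by signed distance to the head-to-tail junction.

    ``circle_calls`` pairs each circular reference with binarized calls in
    its own coordinates; counts are pooled across circles on a 5-bp grid.
    """
    if flank % step != 0:
        raise ValueError("flank must be a multiple of step")
    half = bin // 2
    span = flank + bin  # margin so edge windows are complete
    meth_d = np.zeros(2 * span + 1, dtype=np.int64)
    tot_d = np.zeros(2 * span + 1, dtype=np.int64)
    for ref, calls in circle_calls:
        sub = calls[calls["ref"] == ref.name]
        for pos, methylated in zip(sub["pos"].to_numpy(), sub["methylated"].to_numpy()):
            d = junction_distance(ref, int(pos))
            if -span <= d <= span:
                tot_d[d + span] += 1
                if methylated:
                    meth_d[d + span] += 1
    if tot_d.sum() == 0:
        raise ValueError("no junction-spanning coverage on the supplied circles")
    offsets = np.arange(-flank, flank + 1, step, dtype=np.int64)
    starts = offsets - half + span
    meth_o = _window_sums(meth_d, starts, bin).astype(float)
    tot_o = _window_sums(tot_d, starts, bin).astype(float)
    with np.errstate(invalid="ignore"):
        values = np.where(tot_o > 0, meth_o / np.maximum(tot_o, 1), np.nan)
    stderr = np.full(offsets.size, np.nan)
    return MetageneProfile(
        "junction", offsets, values, stderr, len(circle_calls),
        pooled_meth=meth_o.astype(np.int64), pooled_total=tot_o.astype(np.int64),
    )


def expression_strata(genes) -> dict[str, str]:
    """Assign high/medium/low expression strata by descending expression rank.

    Top 25% of ranks are high, 25-75% medium, bottom 25% low, with boundaries
    at ceil(n * 0.25); genes tied at a boundary all take the better stratum.
    Genes without an expression value are excluded with a warning.
    """
    with_expr = [g for g in genes if g.expression is not None]
    missing = [g.gene_id for g in genes if g.expression is None]
    if missing:
        warnings.warn(f"excluding {len(missing)} genes without expression: {missing[:5]}")
    n = len(with_expr)
    if n < 4:
        raise ValueError(f"need at least 4 genes with expression, got {n}")
    values = np.sort([g.expression for g in with_expr])[::-1]
    b = int(np.ceil(n * 0.25))
    high_min = values[b - 1]          # smallest value still in the top block
    medium_min = values[n - b - 1]    # smallest value still in the medium block
    out = {}
    for g in with_expr:
        if g.expression >= high_min:
            out[g.gene_id] = "high"
        elif g.expression >= medium_min:
            out[g.gene_id] = "medium"
        else:
            out[g.gene_id] = "low"
    return out


# ---------------------------------------------------------------------------
# single-molecule calls


def single_molecule_windows(
    calls: pd.DataFrame,
    fit: MixtureFit,
    window: int = 200,
    min_A: int = 2,
    prior_open: float = 0.5,
    ref_length: int | None = None,
) -> MoleculeWindowCalls:
    """Bayesian open/closed call per window for one read.

    Window posterior of being open = prior * prod f_signal(p_i) normalized
    against (1 - prior) * prod f_noise(p_i), with f_* the fitted mixture's
    component densities at the raw per-base probabilities.  A window with
    fewer than ``min_A`` covered adenosines is a no-call.  Open requires
    posterior strictly above 0.5 (an exact tie is called closed).
    """
    if fit is None:
        raise ValueError("a mixture fit is required for single-molecule calls")
    if window < 50:
        raise ValueError("window must be >= 50 bp")
    if min_A < 2:
        raise ValueError("min_A must be >= 2")
    if not 0 < prior_open < 1:
        raise ValueError("prior_open must be in (0, 1)")
    reads = calls["read_id"].unique()
    refs = calls["ref"].unique()
    if len(reads) != 1 or len(refs) != 1:
        raise ValueError("calls must come from exactly one read on one reference")
    read_id, ref = str(reads[0]), str(refs[0])
    pos = calls["pos"].to_numpy()
    probs = calls["prob"].to_numpy()
    if ref_length is None:
        ref_length = int(pos.max()) + 1
    starts = np.arange(0, ref_length, window, dtype=np.int64)
    states = np.full(starts.size, NO_CALL, dtype=np.int8)
    posteriors = np.full(starts.size, np.nan)
    idx = pos // window
    log_prior = np.log(prior_open) - np.log1p(-prior_open)
    for w in np.unique(idx):
        p = probs[idx == w]
        if p.size < min_A:
            continue
        lo = np.sum(fit.component_logpdf(p, 1))
        lc = np.sum(fit.component_logpdf(p, 0))
        logit = log_prior + lo - lc
        post = 1.0 / (1.0 + np.exp(-logit))
        posteriors[w] = post
        states[w] = OPEN if post > 0.5 else CLOSED
    return MoleculeWindowCalls(read_id, ref, window, starts, states, posteriors)


def molecule_calls_for_ref(
    calls: pd.DataFrame,
    fit: MixtureFit,
    ref: str,
    ref_length: int,
    window: int = 200,
    min_A: int = 2,
    prior_open: float = 0.5,
    min_windows: int = 1,
) -> list[MoleculeWindowCalls]:
    """Single-molecule window calls for every read covering ``ref``."""
    sub = calls[calls["ref"] == ref]
    out = []
    for read_id, grp in sub.groupby("read_id", sort=True):
        mwc = single_molecule_windows(grp, fit, window, min_A, prior_open, ref_length)
        if np.sum(mwc.states != NO_CALL) >= min_windows:
            out.append(mwc)
    return out


def mean_accessibility(
    calls: pd.DataFrame,
    ref: str | None = None,
    start: int | None = None,
    end: int | None = None,
    strand_mode: str = "both",
) -> float:
    """Pooled methylation ratio over a region (count-weighted, not a mean of
    bin ratios).  Raises if the region covers no adenosines."""
    sub = _select_strand(calls, strand_mode)
    if ref is not None:
        sub = sub[sub["ref"] == ref]
    if start is not None:
        sub = sub[sub["pos"] >= start]
    if end is not None:
        sub = sub[sub["pos"] < end]
    total = len(sub)
    if total == 0:
        raise ValueError("region covers no adenosines: pooled ratio undefined")
    return float(sub["methylated"].sum() / total)


def profile_peak_offset(profile: MetageneProfile, frac: float = 0.5) -> int:
    """Location of a profile's maximum, robust to flat-topped peaks.

    An open region wider than the bin produces a plateau whose literal argmax
    position is noise; the peak is located as the midpoint of the contiguous
    run of offsets above ``min + frac * (max - min)`` that contains the
    argmax.
    """
    v = profile.values
    defined = ~np.isnan(v)
    if not defined.any():
        raise ValueError("profile has no defined values")
    lo, hi = np.nanmin(v), np.nanmax(v)
    thresh = lo + frac * (hi - lo)
    above = defined & (v >= thresh)
    k = int(np.nanargmax(v))
    i = j = k
    while i > 0 and above[i - 1]:
        i -= 1
    while j + 1 < v.size and above[j + 1]:
        j += 1
    return int(round(float(np.mean(profile.offsets[i : j + 1]))))


# ---------------------------------------------------------------------------
# nucleosome footprint calling


def call_nucleosome_dyads(
    track: BinnedTrack,
    threshold: float | None = None,
    min_run_bins: int = 15,
) -> np.ndarray:
    """Estimate nucleosome dyad positions from a methylation-ratio track.

    A protected footprint appears as a contiguous run of low-ratio bins; the
    expected track is flat across the footprint interior, so the dyad is
    estimated as the midpoint of each below-threshold run rather than its
    (noise-dominated) argmin.  The default threshold is the midpoint between
    the 10th and 90th percentiles of defined bin ratios.
    """
    ratio = track.ratio
    defined = ~np.isnan(ratio)
    if not defined.any():
        return np.array([], dtype=np.int64)
    if threshold is None:
        lo, hi = np.percentile(ratio[defined], [10, 90])
        threshold = (lo + hi) / 2
    below = defined & (ratio < threshold)
    dyads = []
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if j - i + 1 >= min_run_bins:
                centers = track.centers[i : j + 1]
                dyads.append(int(round(float(np.mean(centers)))))
            i = j + 1
        else:
            i += 1
    return np.array(dyads, dtype=np.int64)
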