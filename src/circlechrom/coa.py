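"""Single-molecule co-accessibility (COA) between window pairs.

For each window pair (i, j) on one reference, every molecule k spanning both
windows contributes a term 1 - |A_i - A_j| / (A_i + A_j); COA(i, j) is the
mean over the >= N spanning molecules.  With binary accessibility states the
term is an agreement indicator once the undefined 0/0 case (both windows
closed) is taken as perfect agreement — the only convention under which
COA(i, i) = 1 also holds for closed windows.  A continuous mode using the
open posteriors as A is available as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import MoleculeWindowCalls, NO_CALL, OPEN

DEFAULT_WINDOW = 200  # bp, about the resolution of accessible regions
DEFAULT_MIN_READS = 5


@dataclass
class COAMatrix:
    """Symmetric per-window co-accessibility matrix for one reference."""

    ref: str
    w: int
    window_starts: np.ndarray
    values: np.ndarray       # NaN where n_spanning < N
    n_spanning: np.ndarray
    N: int

    def to_long_frame(self) -> pd.DataFrame:
        ii, jj = np.nonzero(~np.isnan(self.values))
        keep = ii <= jj
        ii, jj = ii[keep], jj[keep]
        return pd.DataFrame(
            {
                "ref": self.ref,
                "start_i": self.window_starts[ii],
                "start_j": self.window_starts[jj],
                "coa": self.values[ii, jj],
                "n": self.n_spanning[ii, jj],
            }
        )


def _stack_molecules(molecules: list[MoleculeWindowCalls]):
    ref = molecules[0].ref
    w = molecules[0].window
    starts = molecules[0].starts
    A = np.full((len(molecules), starts.size), np.nan)
    P = np.full((len(molecules), starts.size), np.nan)
    for k, m in enumerate(molecules):
        if m.ref != ref or m.window != w or m.starts.size != starts.size or np.any(m.starts != starts):
            raise ValueError("molecule window grids do not match (ref, w, phase)")
        defined = m.states != NO_CALL
        A[k, defined] = (m.states[defined] == OPEN).astype(float)
        P[k, defined] = m.posteriors[defined]
    return ref, w, starts, A, P


def coaccessibility_matrix(
    molecules: list[MoleculeWindowCalls],
    N: int = DEFAULT_MIN_READS,
    mode: str = "binary",
) -> COAMatrix:
    """COA over all window pairs of one reference.

    ``mode='binary'`` uses the open/closed states (A in {0, 1});
    ``mode='continuous'`` uses the open posteriors.  Entries with fewer than
    ``N`` spanning molecules are undefined (NaN).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if mode not in ("binary", "continuous"):
        raise ValueError(f"mode must be 'binary' or 'continuous', got {mode!r}")
    if not molecules:
        raise ValueError("no molecules supplied")
    ref, w, starts, A, P = _stack_molecules(molecules)
    X = A if mode == "binary" else P
    D = ~np.isnan(X)
    n_span = (D.astype(np.int64).T @ D.astype(np.int64))

    Xz = np.where(D, X, 0.0)
    if mode == "binary":
        # term reduces to state agreement (with 0/0 := 1)
        agree = Xz.T @ Xz + (D - Xz).T @ (D - Xz)
        term_sum = agree
    else:
        term_sum = np.zeros((starts.size, starts.size))
        for k in range(X.shape[0]):
            a = Xz[k]
            d = D[k]
            s = a[:, None] + a[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                t = 1.0 - np.abs(a[:, None] - a[None, :]) / np.where(s > 0, s, np.inf)
            t = np.where(s > 0, t, 1.0)  # 0/0: both fully closed -> agreement
            mask = d[:, None] & d[None, :]
            term_sum += np.where(mask, t, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(n_span >= N, term_sum / np.maximum(n_span, 1), np.nan)
    return COAMatrix(ref, w, starts, values, n_span, N)


@dataclass
class COADistanceSummary:
    """Mean COA as a function of window separation."""

    separations: np.ndarray       # in window units
    mean_coa: np.ndarray
    n_pairs: np.ndarray
    background: float
    max_correlated_separation: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"separation": self.separations, "mean_coa": self.mean_coa, "n_pairs": self.n_pairs}
        )


def coa_summary_by_distance(matrix: COAMatrix, background_frac: float = 0.75) -> COADistanceSummary:
    """Collapse a COA matrix to mean COA per window separation.

    The background level is the mean COA over the largest available
    separations (those >= ``background_frac`` of the maximum defined
    separation); the summary also reports the largest separation whose mean
    COA exceeds that background.
    """
    vals = matrix.values
    n = vals.shape[0]
    ii, jj = np.nonzero(~np.isnan(vals))
    off = ii != jj
    if off.sum() < 2:
        raise ValueError("need at least 2 defined off-diagonal entries")
    d = np.abs(ii - jj)
    seps = np.arange(0, n)
    mean_coa = np.full(n, np.nan)
    n_pairs = np.zeros(n, dtype=np.int64)
    for s in np.unique(d):
        mask = d == s
        mean_coa[s] = float(np.mean(vals[ii[mask], jj[mask]]))
        n_pairs[s] = int(mask.sum()) // (2 if s > 0 else 1)
    defined_seps = np.flatnonzero(~np.isnan(mean_coa))
    d_max = defined_seps.max()
    far = defined_seps[defined_seps >= background_frac * d_max]
    far = far[far > 0] if np.any(far > 0) else far
    background = float(np.mean(mean_coa[far]))
    above = [int(s) for s in defined_seps if s > 0 and mean_coa[s] > background]
    max_corr = max(above) if above else 0
    keep = ~np.isnan(mean_coa)
    return COADistanceSummary(seps[keep], mean_coa[keep], n_pairs[keep], background, max_corr)
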