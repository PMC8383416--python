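"""Deriving the true-m6A probability cutoff from a two-component mixture.

Nanopore modified-base callers assign most adenosines a nonzero m6A
probability, so raw calls on a methyltransferase-treated sample show two
populations: a narrow noise peak (unmethylated bases the caller is unsure
about, mean around 0.49) and a signal peak near 1 from genuinely methylated,
accessible bases.  A two-component Gaussian mixture is fitted to the raw
probabilities and the cutoff separating the populations is the posterior
crossover between the components.  The published constant 0.53 remains
available as a fixed bypass.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import logsumexp

DEFAULT_FIXED_CUTOFF = 0.53
MIN_FIT_VALUES = 100
_SD_FLOOR = 1e-3


@dataclass
class MixtureFit:
    """A fitted 2-component Gaussian mixture over m6A probabilities.

    Component 0 is the noise (lower-mean) component, component 1 the signal.
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    cutoff: float | None
    loglik: float
    n_iter: int
    converged: bool
    diagnostic: str | None = None
    loglik_trace: list[float] | None = None

    def component_logpdf(self, x, component: int):
        return stats.norm.logpdf(x, self.means[component], self.sds[component])

    def posterior_signal(self, x):
        """P(signal component | value) under the fit."""
        x = np.asarray(x, dtype=float)
        l0 = np.log(self.weights[0]) + self.component_logpdf(x, 0)
        l1 = np.log(self.weights[1]) + self.component_logpdf(x, 1)
        return np.exp(l1 - np.logaddexp(l0, l1))

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d.pop("loglik_trace")
        text = json.dumps(d, indent=2, sort_keys=True) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "MixtureFit":
        with open(path) as fh:
            d = json.load(fh)
        d["weights"] = tuple(d["weights"])
        d["means"] = tuple(d["means"])
        d["sds"] = tuple(d["sds"])
        return cls(**d)


def fit_probability_mixture(
    probs,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> MixtureFit:
    """Fit a 2-component Gaussian mixture to raw m6A probabilities by EM.

    Initialisation is deterministic (means at the 25th/75th percentiles,
    equal weights, sds at half the inter-quartile spread); ``seed`` is
    accepted for interface stability but the fit involves no sampling.
    Convergence: log-likelihood improvement below ``tol`` or ``max_iter``.
    A fit whose means come closer than 0.02 or whose smaller weight drops
    below 0.01 is flagged degenerate (not converged, no cutoff).
    """
    x = np.asarray(probs, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < MIN_FIT_VALUES:
        raise ValueError(f"need at least {MIN_FIT_VALUES} values, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("probabilities must lie in [0, 1]")

    q25, q75 = np.percentile(x, [25, 75])
    if q75 - q25 < 1e-12:
        return MixtureFit(
            weights=(0.5, 0.5), means=(float(q25), float(q75)),
            sds=(_SD_FLOOR, _SD_FLOOR), cutoff=None, loglik=float("nan"),
            n_iter=0, converged=False,
            diagnostic="degenerate input: inter-quartile spread is zero",
        )
    means = np.array([q25, q75], dtype=float)
    sds = np.full(2, max((q75 - q25) / 2.0, _SD_FLOOR))
    weights = np.array([0.5, 0.5])

    prev_ll = -np.inf
    trace: list[float] = []
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E step
        log_comp = np.stack(
            [np.log(weights[k]) + stats.norm.logpdf(x, means[k], sds[k]) for k in range(2)]
        )
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(np.sum(log_norm))
        if ll + 1e-9 < prev_ll:
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {n_iter}: {prev_ll} -> {ll}"
            )
        trace.append(ll)
        resp = np.exp(log_comp - log_norm)
        # M step
        nk = resp.sum(axis=1)
        weights = nk / x.size
        means = resp @ x / nk
        sds = np.sqrt(np.array([resp[k] @ (x - means[k]) ** 2 / nk[k] for k in range(2)]))
        sds = np.maximum(sds, _SD_FLOOR)
        if ll - prev_ll < tol:
            converged = True
            break
        prev_ll = ll

    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    fit = MixtureFit(
        weights=(float(weights[0]), float(weights[1])),
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        cutoff=None,
        loglik=trace[-1],
        n_iter=n_iter,
        converged=converged,
        loglik_trace=trace,
    )
    if abs(fit.means[1] - fit.means[0]) < 0.02 or min(fit.weights) < 0.01:
        fit.converged = False
        fit.diagnostic = (
            f"degenerate fit: means {fit.means}, weights {fit.weights} "
            "(components collapsed); no cutoff emitted"
        )
        return fit
    if fit.converged:
        try:
            fit.cutoff = crossover_cutoff(fit)
        except ValueError as exc:
            fit.diagnostic = f"no crossover cutoff: {exc}"
    return fit


def crossover_cutoff(fit: MixtureFit, xtol: float = 1e-6) -> float:
    """Smallest point between the component means where the signal component's
    weighted density overtakes the noise component's (posterior crossover)."""
    if not fit.converged:
        raise ValueError("cannot derive a cutoff from a non-converged fit")
    (w0, w1), (m0, m1), (s0, s1) = fit.weights, fit.means, fit.sds

    def g(x):
        return (np.log(w1) + stats.norm.logpdf(x, m1, s1)) - (
            np.log(w0) + stats.norm.logpdf(x, m0, s0)
        )

    # scan a fine grid for the first sign change inside (m0, m1)
    grid = np.linspace(m0, m1, 4001)
    vals = g(grid)
    if vals[0] >= 0:
        raise ValueError("signal density already dominates at the noise mean")
    idx = np.flatnonzero((vals[:-1] < 0) & (vals[1:] >= 0))
    if idx.size == 0:
        raise ValueError(
            "no crossover between the component means (pathological sds/weights)"
        )
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    root = float(brentq(g, lo, hi, xtol=xtol))
    return root


def crossover_closed_form(fit: MixtureFit) -> float:
    """Closed-form crossover: solve the quadratic from log-density equality.

    Independent of the numeric solver; used as its oracle.
    """
    (w0, w1), (m0, m1), (s0, s1) = fit.weights, fit.means, fit.sds
    a = 1.0 / (2 * s0**2) - 1.0 / (2 * s1**2)
    b = m1 / s1**2 - m0 / s0**2
    c = (
        m0**2 / (2 * s0**2)
        - m1**2 / (2 * s1**2)
        + np.log(w1 / s1)
        - np.log(w0 / s0)
    )
    if abs(a) < 1e-15:  # equal sds: linear equation
        roots = np.array([-c / b])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            raise ValueError("no real crossover")
        roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > m0) & (roots < m1)]
    if inside.size == 0:
        raise ValueError("no crossover between the component means")
    return float(inside.min())


def evaluate_cutoff(treated_probs, control_probs, cutoff: float, fit: MixtureFit) -> dict:
    """Sensitivity/specificity of a cutoff against an unmethylated control.

    Specificity: fraction of control values below the cutoff.  Sensitivity:
    among treated values the fit assigns to the signal component (posterior
    > 0.5), the fraction at or above the cutoff.
    """
    treated = np.asarray(treated_probs, dtype=float)
    control = np.asarray(control_probs, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("treated and control collections must be nonempty")
    specificity = float(np.mean(control < cutoff))
    signal_mask = fit.posterior_signal(treated) > 0.5
    n_signal = int(signal_mask.sum())
    if n_signal == 0:
        sensitivity = float("nan")
    else:
        sensitivity = float(np.mean(treated[signal_mask] >= cutoff))
    return {"sensitivity": sensitivity, "specificity": specificity, "n_signal": n_signal}


def binarize_calls(calls, cutoff: float = DEFAULT_FIXED_CUTOFF):
    """Add a boolean ``methylated`` column: prob strictly over the cutoff.

    The boundary is exclusive (a call exactly at the cutoff is unmethylated),
    so methylated counts are non-increasing in the cutoff.
    """
    if not 0 < cutoff < 1:
        raise ValueError(f"cutoff must be in (0, 1), got {cutoff}")
    out = calls.copy()
    out["methylated"] = out["prob"].to_numpy() > cutoff
    return out
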