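"""Mixture fitting, crossover cutoff and binarization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circlechrom.threshold import (
    MixtureFit,
    binarize_calls,
    crossover_closed_form,
    crossover_cutoff,
    evaluate_cutoff,
    fit_probability_mixture,
)


def draw_mixture(n, rng, w=0.5, m=(0.45, 0.85), s=(0.05, 0.08)):
    comp = rng.random(n) < w
    x = np.where(comp, rng.normal(m[0], s[0], n), rng.normal(m[1], s[1], n))
    return np.clip(x, 0, 1)


class TestFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        x = draw_mixture(100_000, rng)
        fit = fit_probability_mixture(x)
        assert fit.converged
        assert abs(fit.means[0] - 0.45) < 0.01
        assert abs(fit.means[1] - 0.85) < 0.01
        assert abs(fit.weights[0] - 0.5) < 0.02
        assert abs(fit.weights[1] - 0.5) < 0.02

    def test_identical_values_degenerate(self):
        fit = fit_probability_mixture(np.full(500, 0.5))
        assert not fit.converged
        assert fit.cutoff is None
        assert "degenerate" in fit.diagnostic

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_probability_mixture(np.linspace(0, 1, 50))

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_probability_mixture(np.linspace(-0.1, 1, 200))

    def test_loglik_never_decreases(self):
        rng = np.random.default_rng(3)
        fit = fit_probability_mixture(draw_mixture(5000, rng))
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_matches_sklearn_reference(self):
        """Independent EM implementation agrees with scikit-learn's."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = draw_mixture(20_000, rng)
        fit = fit_probability_mixture(x)
        gm = GaussianMixture(2, covariance_type="diag", tol=1e-6, max_iter=500,
                             n_init=3, random_state=0).fit(x[:, None])
        ref_means = np.sort(gm.means_.ravel())
        assert np.allclose(sorted(fit.means), ref_means, atol=0.005)


class TestCrossover:
    def test_symmetric_case_is_midpoint(self):
        fit = MixtureFit((0.5, 0.5), (0.4, 0.8), (0.05, 0.05), None, 0.0, 1, True)
        assert crossover_cutoff(fit) == pytest.approx(0.6, abs=1e-6)
        assert crossover_closed_form(fit) == pytest.approx(0.6, abs=1e-12)

    def test_fitted_cutoff_matches_closed_form(self):
        rng = np.random.default_rng(21)
        fit = fit_probability_mixture(draw_mixture(50_000, rng))
        assert fit.cutoff == pytest.approx(crossover_closed_form(fit), abs=1e-3)

    def test_agreement_on_random_parameter_sets(self):
        rng = np.random.default_rng(99)
        n_checked = 0
        while n_checked < 100:
            m0 = rng.uniform(0.2, 0.5)
            m1 = m0 + rng.uniform(0.1, 0.4)
            s0, s1 = rng.uniform(0.02, 0.12, 2)
            w0 = rng.uniform(0.1, 0.9)
            fit = MixtureFit((w0, 1 - w0), (m0, m1), (s0, s1), None, 0.0, 1, True)
            try:
                analytic = crossover_closed_form(fit)
            except ValueError:
                continue
            try:
                numeric = crossover_cutoff(fit)
            except ValueError:
                continue
            assert numeric == pytest.approx(analytic, abs=1e-3)
            n_checked += 1

    def test_non_converged_fit_rejected(self):
        fit = MixtureFit((0.5, 0.5), (0.4, 0.8), (0.05, 0.05), None, 0.0, 1, False)
        with pytest.raises(ValueError):
            crossover_cutoff(fit)

    def test_no_crossover_raises_diagnostic(self):
        # signal already dominates at the noise mean: no crossover in between
        fit = MixtureFit((0.01, 0.99), (0.4, 0.5), (0.5, 0.1), None, 0.0, 1, True)
        with pytest.raises(ValueError):
            crossover_cutoff(fit)


class TestEvaluateCutoff:
    def _fit(self):
        return MixtureFit((0.5, 0.5), (0.45, 0.85), (0.05, 0.08), None, 0.0, 1, True)

    def test_control_below_cutoff_gives_full_specificity(self):
        fit = self._fit()
        out = evaluate_cutoff([0.8, 0.9], np.full(100, 0.3), 0.6, fit)
        assert out["specificity"] == 1.0

    def test_zero_cutoff_gives_zero_specificity(self):
        fit = self._fit()
        out = evaluate_cutoff([0.8], np.full(50, 0.3), 0.0, fit)
        assert out["specificity"] == 0.0

    def test_matches_gaussian_tail_integrals(self):
        """Sensitivity/specificity agree with the normal-CDF oracle."""
        rng = np.random.default_rng(42)
        fit0 = self._fit()
        boundary = crossover_closed_form(fit0)  # posterior > 0.5 <=> x > boundary
        cutoff = 0.7
        treated = draw_mixture(400_000, rng)
        control = np.clip(rng.normal(0.45, 0.05, 200_000), 0, 1)
        out = evaluate_cutoff(treated, control, cutoff, fit0)
        spec_expected = stats.norm.cdf(cutoff, 0.45, 0.05)

        def mix_sf(x):
            return 0.5 * stats.norm.sf(x, 0.45, 0.05) + 0.5 * stats.norm.sf(x, 0.85, 0.08)

        sens_expected = mix_sf(cutoff) / mix_sf(boundary)
        assert out["specificity"] == pytest.approx(spec_expected, abs=0.005)
        assert out["sensitivity"] == pytest.approx(sens_expected, abs=0.005)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_cutoff([], [0.1], 0.5, self._fit())


class TestBinarize:
    def _calls(self, probs):
        return pd.DataFrame(
            {
                "read_id": "r1",
                "ref": "chr1",
                "pos": np.arange(len(probs)),
                "strand": "+",
                "prob": probs,
            }
        )

    def test_boundary_is_strictly_over(self):
        out = binarize_calls(self._calls([0.53]), 0.53)
        assert not out["methylated"].iloc[0]

    def test_just_over_is_methylated(self):
        out = binarize_calls(self._calls([0.531]), 0.53)
        assert bool(out["methylated"].iloc[0])

    def test_counts_monotone_in_cutoff(self):
        rng = np.random.default_rng(8)
        calls = self._calls(rng.random(2000))
        counts = [
            int(binarize_calls(calls, c)["methylated"].sum()) for c in (0.4, 0.53, 0.8)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            binarize_calls(self._calls([0.5]), 1.0)
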