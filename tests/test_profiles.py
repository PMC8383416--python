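"""Tracks, metagene profiles, strata, single-molecule calls, dyad calling."""

import numpy as np
import pandas as pd
import pytest

from circlechrom.io import GeneAnnotation
from circlechrom.profiles import (
    CLOSED,
    NO_CALL,
    OPEN,
    call_nucleosome_dyads,
    expression_strata,
    mean_accessibility,
    metagene_profile,
    methylation_ratio_track,
    molecule_calls_for_ref,
    position_counts,
    profile_peak_offset,
    single_molecule_windows,
)
from circlechrom.simulate import SimConfig, simulate_dataset
from circlechrom.threshold import MixtureFit, binarize_calls


def make_calls(rows):
    """rows: (read_id, ref, pos, strand, prob, methylated)"""
    return pd.DataFrame(
        rows, columns=["read_id", "ref", "pos", "strand", "prob", "methylated"]
    )


@pytest.fixture(scope="module")
def toy_fit():
    return MixtureFit((0.6, 0.4), (0.49, 0.85), (0.05, 0.08), 0.6, 0.0, 1, True)


class TestTrack:
    def test_two_read_pooled_ratio_is_half(self):
        rows = []
        for i in range(5):
            rows.append(("r1", "c", i, "+", 0.9, i < 2))   # 2 of 5 methylated
            rows.append(("r2", "c", 10 + i, "+", 0.9, i < 3))  # 3 of 5
        track = methylation_ratio_track(make_calls(rows), "c", 50, bin=50, step=5)
        assert track.ratio[0] == pytest.approx(0.5)
        assert track.total_A[0] == 10 and track.meth_A[0] == 5

    def test_all_methylated_gives_unit_ratio(self):
        rows = [("r1", "c", p, "+", 0.99, True) for p in range(0, 100, 3)]
        track = methylation_ratio_track(make_calls(rows), "c", 100)
        covered = track.total_A > 0
        assert np.all(track.ratio[covered] == 1.0)

    def test_counts_match_bruteforce_recount(self, binarized_calls, default_sim):
        track = methylation_ratio_track(binarized_calls, "sim1", 100_000)
        sub = binarized_calls[binarized_calls["ref"] == "sim1"]
        pos = sub["pos"].to_numpy()
        meth = sub["methylated"].to_numpy()
        rng = np.random.default_rng(0)
        for k in rng.choice(track.starts.size, 40, replace=False):
            s = track.starts[k]
            inside = (pos >= s) & (pos < s + 50)
            assert track.total_A[k] == int(inside.sum())
            assert track.meth_A[k] == int((inside & meth).sum())

    def test_strand_counts_decompose(self, binarized_calls):
        both = methylation_ratio_track(binarized_calls, "sim1", 100_000, strand_mode="both")
        plus = methylation_ratio_track(binarized_calls, "sim1", 100_000, strand_mode="plus")
        minus = methylation_ratio_track(binarized_calls, "sim1", 100_000, strand_mode="minus")
        assert np.array_equal(both.total_A, plus.total_A + minus.total_A)
        assert np.array_equal(both.meth_A, plus.meth_A + minus.meth_A)


class TestMetagene:
    def _symmetric_calls(self, center, half=600, period=10):
        """Calls with a pattern symmetric about ``center``: methylated iff the
        distance to center, in periods, is even."""
        rows = []
        for d in range(-half, half + 1):
            p = center + d
            rows.append(("r1", "c", p, "+", 0.9, (abs(d) // period) % 2 == 0))
        return make_calls(rows)

    def test_minus_gene_profile_mirrors_plus_gene(self):
        center = 2000
        calls = self._symmetric_calls(center)
        plus = metagene_profile(calls, [GeneAnnotation("gp", "c", "+", center, center + 100)])
        minus = metagene_profile(calls, [GeneAnnotation("gm", "c", "-", center, center - 100)])
        np.testing.assert_allclose(plus.values, minus.values[::-1], atol=1e-12)

    def test_duplicated_reads_leave_profile_unchanged(self, binarized_calls, default_sim):
        genes = default_sim.genes
        base = metagene_profile(binarized_calls, genes)
        doubled = binarized_calls.copy()
        doubled["read_id"] = doubled["read_id"] + "_dup"
        prof2 = metagene_profile(pd.concat([binarized_calls, doubled]), genes)
        np.testing.assert_allclose(base.values, prof2.values, atol=1e-12)

    def test_no_usable_genes_rejected(self, binarized_calls):
        genes = [GeneAnnotation("g", "chrZ", "+", 1000, 2000)]
        with pytest.raises(ValueError):
            metagene_profile(binarized_calls, genes)

    def test_ndr_at_tss_puts_peak_at_zero(self, binarized_calls, default_sim):
        prof = metagene_profile(binarized_calls, default_sim.genes, "TSS")
        assert abs(profile_peak_offset(prof)) <= 25


class TestExpressionStrata:
    def _genes(self, exprs):
        out = []
        for i, e in enumerate(exprs):
            out.append(GeneAnnotation(f"g{i}", "c", "+", 100 * i, 100 * i + 50, e))
        return out

    def test_four_genes_quartile_rule(self):
        strata = expression_strata(self._genes([10, 7, 3, 1]))
        assert strata == {"g0": "high", "g1": "medium", "g2": "medium", "g3": "low"}

    def test_ties_share_better_stratum(self):
        strata = expression_strata(self._genes([5, 5, 5, 5]))
        assert set(strata.values()) == {"high"}

    def test_fewer_than_four_rejected(self):
        with pytest.raises(ValueError):
            expression_strata(self._genes([3, 2, 1]))

    def test_missing_expression_excluded_with_warning(self):
        genes = self._genes([10, 7, 3, 1]) + [GeneAnnotation("gx", "c", "+", 900, 950)]
        with pytest.warns(UserWarning):
            strata = expression_strata(genes)
        assert "gx" not in strata

    def test_eight_genes_counts(self):
        strata = expression_strata(self._genes([8, 7, 6, 5, 4, 3, 2, 1]))
        counts = pd.Series(list(strata.values())).value_counts().to_dict()
        assert counts == {"high": 2, "medium": 4, "low": 2}


class TestSingleMoleculeWindows:
    def _calls(self, probs, start=0, spacing=10):
        rows = [
            ("r1", "c", start + i * spacing, "+", p, p > 0.6) for i, p in enumerate(probs)
        ]
        return make_calls(rows)

    def test_probs_at_signal_mean_call_open(self, toy_fit):
        calls = self._calls([0.85] * 10)
        out = single_molecule_windows(calls, toy_fit, window=200, ref_length=200)
        assert out.states[0] == OPEN
        assert out.posteriors[0] > 0.99

    def test_too_few_adenosines_is_no_call(self, toy_fit):
        calls = self._calls([0.85])
        out = single_molecule_windows(calls, toy_fit, window=200, min_A=2, ref_length=200)
        assert out.states[0] == NO_CALL
        assert np.isnan(out.posteriors[0])

    def test_exact_tie_called_closed(self, toy_fit):
        # equal component densities at every position, prior 0.5 -> posterior 0.5
        fit = MixtureFit((0.5, 0.5), (0.4, 0.8), (0.1, 0.1), None, 0.0, 1, True)
        calls = self._calls([0.6] * 5)  # midpoint: equal densities
        out = single_molecule_windows(calls, fit, window=200, ref_length=200)
        assert out.posteriors[0] == pytest.approx(0.5, abs=1e-12)
        assert out.states[0] == CLOSED

    def test_posterior_monotone_in_any_probability(self, toy_fit):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.3, 0.9, 8)
        calls = self._calls(base)
        p0 = single_molecule_windows(calls, toy_fit, window=200, ref_length=200).posteriors[0]
        for i in range(len(base)):
            raised = base.copy()
            raised[i] = min(1.0, raised[i] + 0.05)
            p1 = single_molecule_windows(
                self._calls(raised), toy_fit, window=200, ref_length=200
            ).posteriors[0]
            assert p1 >= p0 - 1e-12

    def test_missing_fit_rejected(self):
        with pytest.raises(ValueError):
            single_molecule_windows(self._calls([0.8, 0.9]), None)

    def test_mixed_reads_rejected(self, toy_fit):
        calls = pd.concat([self._calls([0.8] * 3), self._calls([0.8] * 3).assign(read_id="r2")])
        with pytest.raises(ValueError):
            single_molecule_windows(calls, toy_fit)


class TestMeanAccessibility:
    def test_fully_methylated_region(self):
        calls = make_calls([("r", "c", p, "+", 0.9, True) for p in range(16)])
        assert mean_accessibility(calls, "c", 0, 16) == 1.0

    def test_four_of_sixteen(self):
        calls = make_calls([("r", "c", p, "+", 0.9, p < 4) for p in range(16)])
        assert mean_accessibility(calls, "c", 0, 16) == 0.25

    def test_pooled_differs_from_bin_mean(self):
        # bin A: 1/10 methylated; bin B: 1/1 methylated
        rows = [("r", "c", p, "+", 0.9, p == 0) for p in range(10)]
        rows += [("r", "c", 50, "+", 0.9, True)]
        calls = make_calls(rows)
        pooled = mean_accessibility(calls, "c", 0, 100)
        assert pooled == pytest.approx(2 / 11)
        bin_mean = np.mean([1 / 10, 1 / 1])
        assert pooled != pytest.approx(bin_mean)

    def test_empty_region_rejected(self):
        calls = make_calls([("r", "c", 5, "+", 0.9, True)])
        with pytest.raises(ValueError):
            mean_accessibility(calls, "c", 100, 200)


class TestDyadCalling:
    def test_recovers_simulated_nucleosome_positions(self, binarized_calls, default_sim):
        track = methylation_ratio_track(binarized_calls, "sim1", 100_000)
        called = call_nucleosome_dyads(track)
        truth = default_sim.truth.dyads["sim1"]
        hits = sum(1 for d in truth if np.any(np.abs(called - d) <= 25))
        assert hits / truth.size >= 0.9
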