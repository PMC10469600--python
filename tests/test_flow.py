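"""Control-based gating, quadrant classification and co-expression aggregation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dualreporter import flow as fl
from dualreporter import synth


def sample_from(ypet, mturq, **meta):
    return fl.FlowSample(ypet=np.asarray(ypet, float),
                         mturq=np.asarray(mturq, float), **meta)


def summary_from_fractions(fractions, n, gene_ypet=None, gene_mturq=None,
                           orientation=None):
    counts = tuple(int(round(f * n)) for f in fractions)
    counts = counts[:3] + (n - sum(counts[:3]),)
    gates = fl.GateSet(ypet_threshold=1.0, mturq_threshold=1.0, quantile=0.999)
    return fl.QuadrantSummary(counts=counts, n=n, qc_pass=n >= 24000, gates=gates,
                              gene_ypet=gene_ypet, gene_mturq=gene_mturq,
                              orientation=orientation)


class TestFitGates:
    def test_control_false_positive_rate_matches_quantile(self, control_sample, gates):
        n = control_sample.n
        expected = 1 - gates.quantile
        se = np.sqrt(expected * (1 - expected) / n)
        for channel in (control_sample.ypet, control_sample.mturq):
            thr = gates.ypet_threshold if channel is control_sample.ypet else gates.mturq_threshold
            fp = np.mean(channel > thr)
            assert abs(fp - expected) <= 3 * se

    def test_threshold_equals_sort_based_quantile_oracle(self, control_sample, gates):
        # independent oracle: smallest order statistic covering >= q of events
        import math
        for values, thr in ((control_sample.ypet, gates.ypet_threshold),
                            (control_sample.mturq, gates.mturq_threshold)):
            ordered = np.sort(values)
            k = math.ceil(0.999 * values.size) - 1
            assert thr == ordered[k]

    @pytest.mark.parametrize("q", [1.5, 0.0, 1.0, -0.2])
    def test_quantile_outside_unit_interval_raises(self, control_sample, q):
        with pytest.raises(fl.FlowError):
            fl.fit_gates(control_sample, quantile=q)

    def test_too_few_control_events_raises(self):
        tiny = synth.make_control(n=1000, seed=1)
        small = sample_from(tiny.ypet[:500], tiny.mturq[:500])
        with pytest.raises(fl.FlowError):
            fl.fit_gates(small)


class TestClassifyQuadrants:
    def test_all_events_below_both_gates_are_double_negative(self, gates):
        s = sample_from([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        summary = fl.classify_quadrants(s, gates)
        assert summary.fractions == (1.0, 0.0, 0.0, 0.0)

    def test_known_mixture_fractions_recovered_within_binomial_error(self, gates):
        frac = (0.2, 0.3, 0.4, 0.1)
        n = 24_000
        sample = synth.make_flow(synth.FlowMixtureSpec(fractions=frac, n=n, seed=31))
        summary = fl.classify_quadrants(sample, gates)
        for observed, p in zip(summary.fractions, frac):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * se

    def test_under_24000_events_fails_qc_but_still_summarized(self, gates):
        sample = synth.make_flow(synth.FlowMixtureSpec(n=10_000, seed=32))
        summary = fl.classify_quadrants(sample, gates)
        assert not summary.qc_pass
        assert summary.n == 10_000

    def test_event_exactly_on_threshold_is_negative(self):
        gates = fl.GateSet(ypet_threshold=100.0, mturq_threshold=200.0, quantile=0.999)
        s = sample_from([100.0, 100.0001], [200.0, 200.0001])
        summary = fl.classify_quadrants(s, gates)
        assert summary.counts == (1, 0, 0, 1)

    @given(st.lists(st.tuples(st.floats(0, 1e4), st.floats(0, 1e4)),
                    min_size=1, max_size=200))
    def test_counts_sum_to_n_and_label_swap_swaps_single_positives(self, events):
        ypet = [e[0] for e in events]
        mturq = [e[1] for e in events]
        gates = fl.GateSet(ypet_threshold=5000.0, mturq_threshold=5000.0, quantile=0.999)
        a = fl.classify_quadrants(sample_from(ypet, mturq), gates)
        b = fl.classify_quadrants(sample_from(mturq, ypet), gates)
        assert sum(a.counts) == len(events)
        assert a.counts[0] == b.counts[0] and a.counts[3] == b.counts[3]
        assert a.counts[1] == b.counts[2] and a.counts[2] == b.counts[1]

    @given(st.floats(min_value=0, max_value=9000))
    def test_raising_a_gate_never_increases_the_positive_count(self, delta):
        rng = np.random.default_rng(33)
        s = sample_from(rng.uniform(0, 10_000, 500), rng.uniform(0, 10_000, 500))
        low = fl.GateSet(ypet_threshold=500.0, mturq_threshold=500.0, quantile=0.999)
        high = fl.GateSet(ypet_threshold=500.0 + delta, mturq_threshold=500.0,
                          quantile=0.999)
        a, b = fl.classify_quadrants(s, low), fl.classify_quadrants(s, high)
        assert b.counts[2] + b.counts[3] <= a.counts[2] + a.counts[3]


class TestPercentExpressing:
    def test_double_negative_sample_is_zero_percent(self):
        assert fl.percent_expressing(summary_from_fractions((1, 0, 0, 0), 1000)) == 0.0

    def test_ypet_only_plus_both_is_100_percent(self):
        s = summary_from_fractions((0, 0, 0.5, 0.5), 1000)
        assert fl.percent_expressing(s) == 100.0

    def test_mixture_recovery_through_gating(self, gates):
        sample = synth.make_flow(synth.FlowMixtureSpec(
            fractions=(0.2, 0.3, 0.4, 0.1), n=24_000, seed=34))
        summary = fl.classify_quadrants(sample, gates)
        se = 100 * np.sqrt(0.5 * 0.5 / 24_000)
        assert fl.percent_expressing(summary) == pytest.approx(50.0, abs=3 * se)

    def test_only_ypet_channel_supported(self):
        with pytest.raises(fl.FlowError):
            fl.percent_expressing(summary_from_fractions((1, 0, 0, 0), 100), channel="mTurq")

    def test_per_gene_aggregation_averages_ypet_carrying_strains(self):
        summaries = [
            summary_from_fractions((0.5, 0, 0.5, 0), 1000, "hag", "tapA", 1),
            summary_from_fractions((0.3, 0, 0.7, 0), 1000, "hag", "sspB", 1),
            summary_from_fractions((0, 0, 1.0, 0), 1000, "tapA", "hag", 2),
        ]
        table = fl.percent_expressing_by_gene(summaries).set_index("gene")
        assert table.loc["hag", "percent_expressing"] == pytest.approx(60.0)
        assert table.loc["hag", "n_strains"] == 2
        assert table.loc["tapA", "percent_expressing"] == pytest.approx(100.0)


class TestCoexpressionMatrix:
    def test_entry_is_maximum_over_the_two_orientations(self):
        summaries = [
            summary_from_fractions((0.82, 0, 0, 0.18), 10_000, "hag", "tapA", 1),
            summary_from_fractions((0.78, 0, 0, 0.22), 10_000, "tapA", "hag", 2),
        ]
        result = fl.build_coexpression_matrix(summaries)
        assert result.matrix.loc["hag", "tapA"] == pytest.approx(22.0)
        assert result.matrix.loc["tapA", "hag"] == pytest.approx(22.0)
        prov = result.provenance.iloc[0]
        assert prov["max_orientation"] == 2
        assert prov["orientation_1"] == pytest.approx(18.0)

    def test_identical_orientations_give_that_common_value(self):
        summaries = [
            summary_from_fractions((0.9, 0, 0, 0.1), 1000, "a", "b", 1),
            summary_from_fractions((0.9, 0, 0, 0.1), 1000, "b", "a", 2),
        ]
        result = fl.build_coexpression_matrix(summaries)
        assert result.matrix.loc["a", "b"] == pytest.approx(10.0)

    def test_unmeasured_pair_is_missing_not_zero(self):
        summaries = [summary_from_fractions((0.9, 0, 0, 0.1), 1000, "a", "b", 1)]
        result = fl.build_coexpression_matrix(summaries, genes=["a", "b", "c"])
        assert np.isnan(result.matrix.loc["a", "c"])
        assert ("a", "c") in result.missing_pairs

    def test_matrix_is_symmetric_in_unit_range_with_nan_diagonal(self, gates):
        rng = np.random.default_rng(35)
        genes = ["g1", "g2", "g3"]
        summaries = []
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                for orientation, (gy, gm) in enumerate([(a, b), (b, a)], start=1):
                    p11 = rng.uniform(0, 0.5)
                    frac = (1 - p11 - 0.2, 0.1, 0.1, p11)
                    s = synth.make_flow(synth.FlowMixtureSpec(
                        fractions=frac, n=5000, seed=int(rng.integers(2**31))),
                        gene_ypet=gy, gene_mturq=gm, orientation=orientation)
                    summaries.append(fl.classify_quadrants(s, gates))
        result = fl.build_coexpression_matrix(summaries)
        m = result.matrix.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True)
        off = m[~np.eye(len(genes), dtype=bool)]
        assert np.all((off >= 0) & (off <= 100))
        assert np.isnan(np.diag(m)).all()


class TestClassifyRelationship:
    @pytest.mark.parametrize("p_a,p_b,p_both,expected", [
        (0.5, 0.5, 0.5, "overlapping"),      # full coverage of both
        (0.5, 0.5, 0.0, "distinct"),         # no overlap at all
        (0.5, 0.5, 0.05, "anticorrelated"),  # r = 0.2 under independence
        (0.0, 0.5, 0.0, "distinct"),         # one gene never expressed
        (0.5, 0.5, 0.25, "partial"),         # exactly the independence expectation
    ])
    def test_relationship_labels(self, p_a, p_b, p_both, expected):
        assert fl.classify_relationship(p_a, p_b, p_both) == expected

    def test_invalid_fraction_raises(self):
        with pytest.raises(fl.FlowError):
            fl.classify_relationship(1.2, 0.5, 0.1)


class TestEndToEndRecovery:
    def test_mixture_parameters_recovered_in_at_least_28_of_30_specs(self, gates):
        rng = np.random.default_rng(40)
        ok = 0
        n = 24_000
        for i in range(30):
            raw = rng.dirichlet([2, 2, 2, 2])
            frac = tuple(raw / raw.sum())
            sample = synth.make_flow(synth.FlowMixtureSpec(
                fractions=frac, n=n, seed=100 + i))
            s = fl.classify_quadrants(sample, gates)
            p_a_true = frac[2] + frac[3]          # YPet-expressing
            p_b_true = frac[1] + frac[3]          # mTurq-expressing
            p11_true = frac[3]
            p_a = (s.counts[2] + s.counts[3]) / n
            p_b = (s.counts[1] + s.counts[3]) / n
            p11 = s.counts[3] / n
            within = all(
                abs(est - true) <= 3 * np.sqrt(max(true * (1 - true), 1e-12) / n) + 2 / n
                for est, true in ((p_a, p_a_true), (p_b, p_b_true), (p11, p11_true)))
            ok += within
        assert ok >= 28
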