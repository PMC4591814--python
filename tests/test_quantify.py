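"""Band-intensity statistics: worked examples, algebraic identities,
oracle equivalence and replicate aggregation."""

import numpy as np
import pytest

import tlsquant as tq
from tlsquant.errors import AggregationError, EfficiencyUndefinedError


def lane(bands, k=None):
    if k is None:
        k = max(bands)
    return tq.Lane.from_band_dict(bands, k)


class TestCumulative:
    def test_worked_examples(self):
        ln = lane({0: 50, 1: 25, 2: 25})
        assert tq.cumulative_at_least(ln, 1) == 50
        assert tq.cumulative_at_least(ln, 0) == 100

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ln = tq.Lane("x", "e", "s", 1.0, 1, rng.uniform(size=10))
            cum = [tq.cumulative_at_least(ln, n) for n in range(10)]
            assert all(a >= b - 1e-12 for a, b in zip(cum, cum[1:]))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            tq.cumulative_at_least(lane({0: 1, 1: 1}), 5)


class TestPerPositionStatistics:
    def test_termination_examples(self):
        ln = lane({0: 50, 1: 25, 2: 25})
        assert tq.termination_probability(ln, 0) == 0.5
        assert tq.termination_probability(ln, 2) == 1.0

    def test_insertion_examples(self):
        ln = lane({0: 25, 1: 25, 2: 50})
        assert tq.insertion_probability(ln, 1) == 0.75
        assert tq.insertion_probability(ln, 2) == pytest.approx(50 / 75)

    def test_extension_example(self):
        assert tq.extension_probability(lane({0: 50, 1: 25, 2: 25}), 1) == 0.5

    def test_bypass_examples(self):
        ln = lane({0: 25, 1: 25, 2: 50})
        assert tq.bypass_probability(ln, 1) == 0.5
        assert tq.bypass_probability(lane({2: 100}, k=2), 1) == 1.0

    def test_undefined_is_none_not_zero(self):
        ln = lane({0: 100, 1: 0, 2: 0})
        assert tq.insertion_probability(ln, 2) is None
        assert tq.termination_probability(ln, 2) is None

    def test_identities_on_random_lanes(self):
        """termination + extension = 1, bypass = insertion x extension and
        extension(N) = insertion(N+1), to 1e-12, wherever defined."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            k = rng.integers(2, 12)
            vals = rng.uniform(size=k + 1) * (rng.uniform(size=k + 1) < 0.8)
            if vals.sum() == 0:
                vals[0] = 1.0
            ln = tq.Lane("x", "e", "s", 1.0, 1, vals)
            for n in range(1, k):
                ins, ext = tq.insertion_probability(ln, n), tq.extension_probability(ln, n)
                term, byp = tq.termination_probability(ln, n), tq.bypass_probability(ln, n)
                if term is not None and ext is not None:
                    assert abs(term + ext - 1) < 1e-12
                if byp is not None and ins is not None and ext is not None:
                    assert abs(byp - ins * ext) < 1e-12
                nxt = tq.insertion_probability(ln, n + 1)
                if ext is not None and nxt is not None:
                    assert abs(ext - nxt) < 1e-12

    def test_scale_invariance(self):
        ln = lane({0: 10, 1: 5, 2: 3, 3: 7})
        scaled = tq.Lane("x", "e", "s", 1.0, 1, ln.intensities * 137.5)
        for n in range(1, 3):
            for fn in (tq.insertion_probability, tq.extension_probability,
                       tq.bypass_probability, tq.termination_probability):
                assert fn(ln, n) == pytest.approx(fn(scaled, n), abs=1e-12)

    def test_oracle_equivalence(self, sub14tg, make_analytic_lane):
        """On the analytic single-engagement distribution the insertion
        statistic recovers the generating continuation vector exactly."""
        rng = np.random.default_rng(3)
        s = rng.uniform(0.05, 0.95, sub14tg.k)
        dist = tq.expected_length_distribution(s, 0, n_engagements=1)
        ln = make_analytic_lane(dist, sub14tg)
        for i in range(1, sub14tg.k + 1):
            assert tq.insertion_probability(ln, i) == pytest.approx(s[i - 1], abs=1e-12)

    def test_multihit_inflates_insertion_beyond_n1(self, sub14tg, make_analytic_lane):
        """Re-engagement gives dissociated molecules extra chances, so on a
        Poisson-engagement distribution insertion at N >= 2 exceeds the
        single-engagement value (N1 instead reflects the engaged fraction)."""
        s = np.full(sub14tg.k, 0.5)
        multi = make_analytic_lane(tq.expected_length_distribution(s, 1.0), sub14tg)
        for i in range(2, sub14tg.k + 1):
            assert tq.insertion_probability(multi, i) >= s[i - 1] - 1e-12
        assert tq.insertion_probability(multi, 1) < s[0]


class TestPercentExtension:
    def test_examples(self):
        assert tq.percent_extension(lane({0: 40, 1: 60})) == 60.0
        assert tq.percent_extension(lane({0: 100, 1: 0})) == 0.0

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            tq.percent_extension(tq.Lane("x", "e", "s", 1.0, 1, np.zeros(3)))

    def test_no_misinsertion_no_extension(self, substrates):
        """With misinsertion off and only the wrong dNTP offered, nothing
        leaves the primer band."""
        sub = substrates["16/G"]
        prof = tq.ExtensionProfile("t", np.full(sub.k, 0.9), np.zeros(sub.k))
        cond = tq.ReactionConditions(
            seed=2, dntps={"dTTP"}, times=(10.0,), replicates=1,
            molecules=5000, engagement_rate=0.5, noise_sigma_mult=0.0,
        )
        lanes = tq.simulate_lanes(prof, sub, cond)
        assert tq.percent_extension(lanes[0]) == 0.0


class TestBypassEfficiency:
    def test_identity(self):
        assert tq.bypass_efficiency(0.37, 0.37) == pytest.approx(100.0)

    def test_undefined_on_zero_undamaged(self):
        with pytest.raises(EfficiencyUndefinedError):
            tq.bypass_efficiency(0.1, 0.0)


class TestAggregate:
    def _lanes(self, bypass_targets, enzyme="E", substrate="S"):
        """Three-band lanes (k=2) whose bypass at N1 hits given targets."""
        out = []
        for i, b in enumerate(bypass_targets):
            # cum0=1, cum1=0.5, cum2=b  => bypass(1)=b
            ints = np.array([0.5, 0.5 - b, b])
            out.append(tq.Lane(f"l{i}", enzyme, substrate, 2.0, i + 1, ints))
        return out

    def test_mean_and_sd(self):
        summ = tq.aggregate(self._lanes([0.12, 0.13, 0.11]), 1)
        assert summ.bypass_mean == pytest.approx(0.12)
        assert summ.bypass_sd == pytest.approx(0.01)
        assert summ.n_lanes == 3

    def test_single_lane_sd_zero(self):
        summ = tq.aggregate(self._lanes([0.2]), 1)
        assert summ.bypass_sd == 0.0 and summ.n_lanes == 1

    def test_noiseless_replicates_have_zero_sd(self, sub14tg, wt_profiles):
        # analytic lanes stand in for infinite molecule counts
        s = tq.effective_continuation(wt_profiles["damaged"], sub14tg)
        dist = tq.expected_length_distribution(s, 0, n_engagements=1)
        lanes = [
            tq.Lane(f"l{i}", "WT-like", "14/Tg", t, r, dist * 1e4)
            for i, (t, r) in enumerate([(2, 1), (4, 1), (6, 1), (2, 2), (4, 2), (6, 2)])
        ]
        summ = tq.aggregate(lanes, sub14tg.lesion_n)
        assert summ.bypass_sd == pytest.approx(0.0, abs=1e-15)
        n = sub14tg.lesion_n
        assert summ.bypass_mean == pytest.approx(s[n - 1] * s[n], abs=1e-12)

    def test_mixed_enzymes_rejected(self):
        lanes = self._lanes([0.1]) + self._lanes([0.2], enzyme="F")
        with pytest.raises(AggregationError):
            tq.aggregate(lanes, 1)

    def test_undefined_lanes_excluded(self):
        lanes = self._lanes([0.1, 0.2])
        dead = tq.Lane("dead", "E", "S", 2.0, 9, np.array([1.0, 0.0, 0.0]))
        summ = tq.aggregate(lanes + [dead], 1)
        assert summ.n_lanes == 2 and summ.n_excluded == 1

    def test_by_experiment_pooling(self):
        lanes = []
        for rep, vals in ((1, [0.10, 0.12]), (2, [0.20, 0.22])):
            for i, b in enumerate(vals):
                ints = np.array([0.5, 0.5 - b, b])
                lanes.append(tq.Lane(f"r{rep}i{i}", "E", "S", 2.0 * (i + 1), rep, ints))
        summ = tq.aggregate(lanes, 1, pooling="by_experiment")
        assert summ.bypass_mean == pytest.approx(0.16)
        assert summ.bypass_sd == pytest.approx(np.std([0.11, 0.21], ddof=1))


class TestEfficiencyFromSummaries:
    def _summary(self, mean, sd, substrate="S-dam"):
        return tq.BypassSummary(
            enzyme="E", substrate_name=substrate, lesion_n=1, n_lanes=6,
            insertion_mean=mean, insertion_sd=sd,
            extension_mean=mean, extension_sd=sd,
            bypass_mean=mean, bypass_sd=sd,
        )

    def test_table_style_ratio(self):
        out = tq.efficiency_from_summaries(
            self._summary(0.122, 0.002), self._summary(0.678, 0.009, "S-und")
        )
        assert tq.format_percent(out.efficiency_pct) == "18.0"

    def test_propagated_sd_closed_form(self):
        d = self._summary(0.4, 0.04)
        u = self._summary(0.4, 0.04, "S-und")
        out = tq.efficiency_from_summaries(d, u)
        assert out.efficiency_pct == pytest.approx(100.0)
        assert out.efficiency_sd_pct == pytest.approx(100 * np.sqrt(2) * 0.1)

    def test_same_substrate_rejected(self):
        with pytest.raises(ValueError):
            tq.efficiency_from_summaries(self._summary(0.1, 0), self._summary(0.2, 0))


class TestPositionStats:
    def test_reason_codes_for_zero_denominators(self):
        ln = lane({0: 100, 1: 0, 2: 0})
        st = tq.position_stats(ln)
        assert ("insertion", 2, "zero denominator") in st.undefined
        assert np.isnan(st.insertion[2])
        assert st.termination[0] == 1.0

    def test_format_percent_half_up(self):
        assert tq.format_percent(17.9941) == "18.0"
        assert tq.format_percent(3.35) == "3.4"
        assert tq.format_percent(10.0897) == "10.1"
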