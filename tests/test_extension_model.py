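"""Generative extension model: analytic oracle and Monte-Carlo simulator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tlsquant as tq
from tlsquant.errors import ConfigurationError

s_vectors = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=8
)


def _profile(e_correct, e_mis=None, **kw):
    e_correct = np.asarray(e_correct, dtype=float)
    if e_mis is None:
        e_mis = np.zeros_like(e_correct)
    return tq.ExtensionProfile("test", e_correct, e_mis, **kw)


class TestEffectiveContinuation:
    def test_all_dntps_identity(self, sub14tg):
        prof = _profile(np.linspace(0.1, 0.9, sub14tg.k))
        s = tq.effective_continuation(prof, sub14tg)
        assert np.array_equal(s, prof.e_correct)

    def test_single_dntp_uses_misinsertion(self, substrates):
        sub = substrates["16/G"]  # N1 template base G, correct dNTP dCTP
        prof = _profile(np.full(sub.k, 0.9), np.full(sub.k, 0.01))
        s = tq.effective_continuation(prof, sub, {"dTTP"})
        assert s[0] == 0.01
        # dTTP is correct wherever the template base is A
        for entry in tq.position_map(sub):
            expected = 0.9 if entry.template_base == "A" else 0.01
            assert s[entry.n - 1] == expected

    def test_absorbing_nick(self, substrates):
        sub = substrates["nicked-16/T"]
        prof = _profile(np.full(sub.k, 0.9), displacement_factor=0.0)
        s = tq.effective_continuation(prof, sub)
        assert np.all(s[sub.nick_n - 1:] == 0.0)

    def test_length_mismatch(self, sub14tg):
        with pytest.raises(ConfigurationError):
            tq.effective_continuation(_profile([0.5, 0.5]), sub14tg)


class TestExpectedLengthDistribution:
    def test_no_engagement_is_point_mass(self):
        dist = tq.expected_length_distribution([0.3, 0.7], 0.0)
        assert np.array_equal(dist, [1.0, 0.0, 0.0])

    def test_single_engagement_enumeration(self):
        dist = tq.expected_length_distribution([0.5, 0.5], 0, n_engagements=1)
        assert np.allclose(dist, [0.5, 0.25, 0.25], atol=1e-15)

    def test_two_engagements_enumeration(self):
        # second chance from N0: P(N0) = 0.5^2, the rest reaches N1
        dist = tq.expected_length_distribution([0.5], 0, n_engagements=2)
        assert np.allclose(dist, [0.25, 0.75], atol=1e-15)

    @given(s_vectors, st.floats(min_value=0.0, max_value=10.0))
    def test_probability_vector(self, s, lam_t):
        dist = tq.expected_length_distribution(s, lam_t)
        assert np.all(dist >= 0)
        assert abs(dist.sum() - 1.0) < 1e-12
        assert dist.size == len(s) + 1

    def test_eventual_complete_extension(self):
        dist = tq.expected_length_distribution(np.full(5, 0.3), 50.0)
        assert dist[-1] > 0.999

    def test_lesion_permeability_monotone(self, sub14tg):
        """Raising continuation at the lesion strictly increases the mass
        beyond it."""
        masses = []
        for s_lesion in (0.2, 0.6):
            s = np.full(sub14tg.k, 0.9)
            s[sub14tg.lesion_n - 1] = s_lesion
            dist = tq.expected_length_distribution(s, 1.0)
            masses.append(dist[sub14tg.lesion_n + 1 :].sum())
        assert masses[1] > masses[0]

    def test_rejects_invalid_s(self):
        with pytest.raises(ConfigurationError):
            tq.expected_length_distribution([1.2], 1.0)


class TestSimulateLanes:
    def test_monte_carlo_matches_oracle(self, sub14tg, wt_profiles):
        """Noise-free single-engagement frequencies agree with the analytic
        distribution within binomial sampling error."""
        n = 100_000
        cond = tq.ReactionConditions(
            seed=7, times=(1.0,), replicates=1, molecules=n,
            noise_sigma_mult=0.0, single_hit=True,
        )
        lane = tq.simulate_lanes(wt_profiles["damaged"], sub14tg, cond)[0]
        s = tq.effective_continuation(wt_profiles["damaged"], sub14tg)
        expected = tq.expected_length_distribution(s, 0, n_engagements=1)
        empirical = lane.intensities / lane.total
        bound = 3 * np.sqrt(expected * (1 - expected) / n) + 1e-9
        assert np.all(np.abs(empirical - expected) <= bound)

    def test_total_variation_poisson_regime(self, substrates):
        """Stochastic/analytic agreement on fixture substrates with random
        continuation vectors: TV distance below 0.01 at 1e5 molecules."""
        rng = np.random.default_rng(42)
        for name in ("14/Tg", "16/T"):
            sub = substrates[name]
            prof = _profile(rng.uniform(size=sub.k))
            cond = tq.ReactionConditions(
                seed=3, times=(1.0,), replicates=1, molecules=100_000,
                engagement_rate=0.5, noise_sigma_mult=0.0,
            )
            lane = tq.simulate_lanes(prof, sub, cond)[0]
            s = tq.effective_continuation(prof, sub)
            expected = tq.expected_length_distribution(s, 0.5)
            tv = 0.5 * np.abs(lane.intensities / lane.total - expected).sum()
            assert tv < 0.01

    def test_perfect_processivity_reaches_full_length(self, sub14tg):
        prof = _profile(np.ones(sub14tg.k))
        cond = tq.ReactionConditions(
            seed=1, times=(1.0,), replicates=1, molecules=1000,
            noise_sigma_mult=0.0, single_hit=True,
        )
        lane = tq.simulate_lanes(prof, sub14tg, cond)[0]
        assert lane.intensities[-1] == 1000 and lane.intensities[:-1].sum() == 0

    def test_seed_determinism(self, sub14tg, wt_profiles):
        cond = tq.ReactionConditions(seed=99, times=(2.0, 4.0), replicates=2,
                                     molecules=2000)
        a = tq.simulate_lanes(wt_profiles["damaged"], sub14tg, cond)
        b = tq.simulate_lanes(wt_profiles["damaged"], sub14tg, cond)
        assert len(a) == len(b) == 4
        for la, lb in zip(a, b):
            assert la.lane_id == lb.lane_id
            assert np.array_equal(la.intensities, lb.intensities)

    def test_lane_metadata(self, sub14tg, wt_profiles):
        cond = tq.ReactionConditions(seed=5, times=(2.0, 4.0, 6.0), replicates=2,
                                     molecules=100)
        lanes = tq.simulate_lanes(wt_profiles["damaged"], sub14tg, cond)
        assert len(lanes) == 6
        assert {ln.time_min for ln in lanes} == {2.0, 4.0, 6.0}
        assert all(ln.substrate_name == "14/Tg" for ln in lanes)


class TestExampleProfiles:
    def test_single_hit_efficiency_matches_design(self, sub14tg):
        """The WT-like profile's single-hit bypass efficiency sits within
        2 percentage points of 18%, the mutant-like one near 3.8%."""
        profs = tq.example_profiles(sub14tg.k, sub14tg.lesion_n)
        n = sub14tg.lesion_n

        def eff(arms):
            d, u = arms["damaged"].e_correct, arms["undamaged"].e_correct
            return 100 * (d[n - 1] * d[n]) / (u[n - 1] * u[n])

        assert abs(eff(profs["WT-like"]) - 18.0) < 2.0
        assert abs(eff(profs["mutant-like"]) - 3.8) < 2.0
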