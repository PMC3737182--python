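"""Rates, expected class frequencies and event enumeration of the ancestral
process."""

import numpy as np
import pytest

from sweepis.ancestral_process import (
    HaplotypeFrequencyModel,
    RateContext,
    enumerate_events,
    event_type_probabilities,
    expected_class_frequency,
    hazard_coefficients,
    proposal_total_rate_hbar,
    recombination_transition_prob,
    total_rate_gamma,
    waiting_hazard_per_gen,
)
from sweepis.haplotype_coding import (
    CodedHaplotype,
    RecombinationMap,
    SampleConfiguration,
)


@pytest.fixture()
def freq_model(small_trajectory, uniform_map_25):
    return HaplotypeFrequencyModel(small_trajectory, uniform_map_25, 17)


def _ctx(cfg, v, traj, fm, mu=0.0, cc=0.0, two_n0=200.0):
    betas = np.array([fm.beta(h) for h in cfg.types])
    return RateContext(cfg, v, int(traj.counts[v]), two_n0, mu, cc, betas,
                       x_v=float(traj.freqs[v]))


class TestClassFrequencies:
    def test_founder_certain_at_founding(self, freq_model):
        T = freq_model.age
        assert freq_model.class_prob(17, 7, T - 1) == pytest.approx(1.0)
        assert freq_model.class_prob(3, 2, T - 1) == 0.0

    def test_partition_sums_to_one(self, freq_model):
        for t in (0, freq_model.age // 2):
            total = sum(
                freq_model.class_prob(r1, r2, t)
                for r1 in range(18) for r2 in range(8)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_no_recombination_keeps_founder(self, small_trajectory):
        rmap = RecombinationMap(np.arange(1, 26) * 1000,
                                np.zeros(25))
        fm = HaplotypeFrequencyModel(small_trajectory, rmap, 17)
        assert fm.class_prob(17, 7, 0) == pytest.approx(1.0)

    def test_survival_monotone_in_extent(self, freq_model):
        sv = [freq_model.survival("left", k, 0) for k in range(18)]
        assert all(a >= b for a, b in zip(sv, sv[1:]))

    def test_beyond_trajectory_errors(self, freq_model):
        with pytest.raises(ValueError):
            expected_class_frequency(CodedHaplotype(1, 1), freq_model.age + 1,
                                     freq_model)

    def test_forward_simulation_oracle_two_locus(self, small_trajectory):
        """P_[linked](0) matches the fraction of non-escaped lineages in
        forward simulation of the escape process along the trajectory."""
        r = 2e-3
        rmap = RecombinationMap(np.array([1, 10_000_000]),
                                np.array([0.0, 100 * r]))
        fm = HaplotypeFrequencyModel(small_trajectory, rmap, 0)
        expected = fm.survival("right", 1, 0)
        rng = np.random.default_rng(11)
        x = small_trajectory.freqs
        T = small_trajectory.age
        n = 40_000
        # per-generation escape hazard r (1 - X_u) from founding to present
        survive = np.ones(n, dtype=bool)
        for u in range(T - 1, 0, -1):
            survive &= rng.random(n) >= r * (1.0 - x[u])
        frac = survive.mean()
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(frac - expected) <= 3 * se + 1e-3


class TestRates:
    def test_gamma_no_coalescence_single_lineage(self, small_trajectory,
                                                 freq_model):
        cfg = SampleConfiguration([CodedHaplotype(17, 7)], [1])
        ctx = _ctx(cfg, 5, small_trajectory, freq_model, mu=1e-4, cc=1e-3)
        gamma = total_rate_gamma(ctx)
        assert gamma == pytest.approx(0.5 * (ctx.theta + ctx.rho))

    def test_gamma_arithmetic_pair(self, small_trajectory, freq_model):
        # n = 2, lambda = 1, X = 0.5, theta = rho = 0 -> gamma = 2
        cfg = SampleConfiguration([CodedHaplotype(17, 7)], [2])
        ctx = RateContext(cfg, 0, 100, 200.0, 0.0, 0.0,
                          np.array([1.0]), x_v=0.5)
        assert total_rate_gamma(ctx) == pytest.approx(2.0)

    def test_gamma_g6pd_form(self, small_trajectory, g6pd_map, g6pd_config):
        """With theta = 0 the total rate is the coalescence term plus the
        recombination term only."""
        fm = HaplotypeFrequencyModel(small_trajectory, g6pd_map, 17)
        ctx = _ctx(g6pd_config, 3, small_trajectory, fm, mu=0.0, cc=fm.total_len)
        n = g6pd_config.n_lineages
        coal = n * (n - 1) / 2 * ctx.two_n0 / ctx.copies
        rec = 0.5 * ctx.rho * float(np.dot(g6pd_config.mult, ctx.betas))
        assert total_rate_gamma(ctx) == pytest.approx(coal + rec)

    def test_gamma_zero_frequency_with_pair_errors(self, small_trajectory,
                                                   freq_model):
        cfg = SampleConfiguration([CodedHaplotype(17, 7)], [2])
        ctx = RateContext(cfg, 0, 0, 200.0, 0.0, 0.0, np.array([1.0]))
        with pytest.raises(ValueError):
            total_rate_gamma(ctx)

    def test_event_type_probabilities_sum_to_one(self, small_trajectory,
                                                 freq_model):
        cfg = SampleConfiguration(
            [CodedHaplotype(17, 7), CodedHaplotype(3, 2)], [2, 1])
        ctx = _ctx(cfg, 4, small_trajectory, freq_model, mu=2e-4, cc=3e-3)
        assert sum(event_type_probabilities(ctx)) == pytest.approx(1.0)


class TestTransitionProbabilities:
    def test_no_self_transition(self, freq_model):
        h = CodedHaplotype(5, 3)
        assert recombination_transition_prob(h, h, 2, freq_model) == 0.0

    def test_extension_distribution_normalised(self, freq_model):
        h = CodedHaplotype(5, 3)
        total = sum(
            recombination_transition_prob(
                h, CodedHaplotype(b, 3), 2, freq_model)
            for b in range(6, 18)
        )
        # selected-donor weighting: deficit equals donors of shorter extent
        probs = freq_model.side_class_probs("left", 2)
        assert total == pytest.approx(probs[6:].sum() / 1.0, abs=1e-12)

    def test_shrinking_moves_forbidden(self, freq_model):
        assert recombination_transition_prob(
            CodedHaplotype(5, 3), CodedHaplotype(2, 3), 2, freq_model) == 0.0

    def test_two_locus_reduction_matches_hand_rate(self, small_trajectory):
        """With one marker the extension probability equals the hand-coded
        two-locus rate: donor frequency of the intact class."""
        r = 1e-3
        rmap = RecombinationMap(np.array([1, 1_000_000]),
                                np.array([0.0, 100 * r]))
        fm = HaplotypeFrequencyModel(small_trajectory, rmap, 0)
        v = 3
        p = recombination_transition_prob(
            CodedHaplotype(0, 0), CodedHaplotype(0, 1), v, fm)
        hand = np.exp(-r * fm.clock(v))  # P_[intact](v)
        assert p == pytest.approx(hand, abs=1e-12)


class TestEnumeration:
    def test_proposal_probabilities_sum_to_one(self, small_trajectory,
                                               freq_model):
        cfg = SampleConfiguration(
            [CodedHaplotype(17, 7), CodedHaplotype(9, 4, (12,)),
             CodedHaplotype(3, 2)], [3, 1, 2])
        ctx = _ctx(cfg, 6, small_trajectory, freq_model, mu=1e-4,
                   cc=freq_model.total_len)
        events = enumerate_events(cfg, 6, freq_model, ctx)
        w = np.array([e.w_prop for e in events])
        assert np.all(w > 0)
        assert (w / w.sum()).sum() == pytest.approx(1.0)

    def test_hbar_equals_sum_of_enumerated_terms(self, small_trajectory,
                                                 freq_model):
        cfg = SampleConfiguration(
            [CodedHaplotype(17, 7), CodedHaplotype(9, 4), CodedHaplotype(3, 2)],
            [2, 2, 1])
        ctx = _ctx(cfg, 4, small_trajectory, freq_model, mu=5e-5,
                   cc=freq_model.total_len)
        events = enumerate_events(cfg, 4, freq_model, ctx)
        manual = sum(e.w_prop for e in events)
        assert proposal_total_rate_hbar(cfg, 4, freq_model, ctx) == \
            pytest.approx(ctx.two_n0 * manual)

    def test_singletons_without_mutations_dead_end(self, small_trajectory,
                                                   freq_model):
        # theta = 0, full-extent singleton: no admissible event
        cfg = SampleConfiguration([CodedHaplotype(17, 7)], [1])
        ctx = _ctx(cfg, 4, small_trajectory, freq_model, mu=0.0, cc=1e-2)
        assert enumerate_events(cfg, 4, freq_model, ctx) == []

    def test_single_type_coalescence_weight(self, small_trajectory,
                                            freq_model):
        n = 5
        cfg = SampleConfiguration([CodedHaplotype(17, 7)], [n])
        ctx = _ctx(cfg, 4, small_trajectory, freq_model)
        events = enumerate_events(cfg, 4, freq_model, ctx)
        assert len(events) == 1
        assert events[0].kind == "coalescence"
        assert events[0].w_prop == pytest.approx(n * (n - 1) / ctx.copies)

    def test_forced_merge_under_infinite_sites(self, small_trajectory,
                                               freq_model):
        """A singleton whose shifted code already exists must merge, not
        shift."""
        h = CodedHaplotype(9, 4, (12,))
        shifted = CodedHaplotype(9, 4)
        cfg = SampleConfiguration([h, shifted], [1, 2])
        ctx = _ctx(cfg, 4, small_trajectory, freq_model, mu=1e-4)
        kinds = {e.kind for e in enumerate_events(cfg, 4, freq_model, ctx)}
        assert "mutation_merge" in kinds
        assert "mutation_shift" not in kinds

    def test_reachable_class_count(self):
        """The coded recombination classes form a grid of
        (m_L + 1) x (m_R + 1) states."""
        m_left, m_right = 4, 3
        states = {
            (r1, r2) for r1 in range(m_left + 1) for r2 in range(m_right + 1)
        }
        assert len(states) == (m_left + 1) * (m_right + 1)
        # every state is producible by coordinate changes from the founder
        from sweepis.haplotype_coding import coordinate_change, \
            founder_haplotype
        founder = founder_haplotype(m_left, m_right)
        reached = set()
        for r1 in range(m_left + 1):
            h = coordinate_change(founder, "left", r1, mutant_col=m_left)
            for r2 in range(m_right + 1):
                h2 = coordinate_change(h, "right", r2, mutant_col=m_left)
                reached.add((h2.r1, h2.r2))
        assert reached == states


class TestWaitingHazard:
    def test_matches_components(self, small_trajectory, freq_model):
        cfg = SampleConfiguration(
            [CodedHaplotype(17, 7), CodedHaplotype(3, 2)], [2, 1])
        mu, cc = 1e-4, freq_model.total_len
        coeffs = hazard_coefficients(cfg, freq_model, mu, cc)
        v = 5
        iv = small_trajectory.counts[v]
        h = waiting_hazard_per_gen(coeffs, iv, small_trajectory.freqs[v])
        betas = [freq_model.beta(t) for t in cfg.types]
        expected = (3 * 2 / 2 / iv
                    + sum(m * (mu + cc) * b
                          for m, b in zip(cfg.mult, betas)))
        assert h == pytest.approx(expected)
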