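"""Sequential importance sampler over genealogies: event times, proposals,
weights, unbiasedness against the exact oracle."""

import math

import numpy as np
import pytest

from sweepis import _kernels
from sweepis.ancestral_process import (
    HaplotypeFrequencyModel,
    RateContext,
    enumerate_events,
    hazard_coefficients,
    waiting_hazard_per_gen,
)
from sweepis.genealogy_is import (
    BEYOND_TRAJECTORY,
    propose_event,
    run_genealogy,
    sample_event_time,
    step_weight,
)
from sweepis.haplotype_coding import (
    CodedHaplotype,
    RecombinationMap,
    SampleConfiguration,
)
from sweepis.sweep_simulator import exact_sampling_probability


def _freq_model(traj, r=1e-3):
    rmap = RecombinationMap(np.array([1, 1_000_000]),
                            np.array([0.0, 100 * r]))
    return HaplotypeFrequencyModel(traj, rmap, 0), rmap


def _ctx(cfg, v, traj, fm, mu=0.0, cc=1e-3):
    betas = np.array([fm.beta(h) for h in cfg.types])
    return RateContext(cfg, v, int(traj.counts[v]),
                       2.0 * traj.pop_sizes[0], mu, cc, betas,
                       x_v=float(traj.freqs[v]))


class TestEventTimes:
    def test_geometric_mean_constant_hazard(self, small_trajectory):
        """With a configuration whose hazard is dominated by a constant term
        the waiting time is geometric with mean 1/p."""
        fm, _ = _freq_model(small_trajectory)
        cfg = SampleConfiguration([CodedHaplotype(0, 1)], [1])
        # mutation-only hazard: constant mu * beta per generation
        mu = 0.05  # beta = 1 for the founder type
        rng = np.random.default_rng(0)
        cfg_mut = SampleConfiguration([CodedHaplotype(0, 1, (1,))], [1])
        draws = []
        for _ in range(4000):
            v = sample_event_time(cfg_mut, 0, small_trajectory, fm, mu, rng)
            if v != BEYOND_TRAJECTORY:
                draws.append(v)
        mean = np.mean(draws)
        # truncated-geometric mean within sampling error
        p = mu
        T = small_trajectory.age
        ts = np.arange(1, T)
        pmf = p * (1 - p) ** (ts - 1)
        pmf /= pmf.sum()
        expected = float((ts * pmf).sum())
        assert mean == pytest.approx(expected, rel=0.05)

    def test_zero_hazard_beyond_trajectory(self, small_trajectory):
        fm, _ = _freq_model(small_trajectory)
        cfg = SampleConfiguration([CodedHaplotype(0, 1)], [1])  # no events
        rng = np.random.default_rng(1)
        assert sample_event_time(cfg, 0, small_trajectory, fm, 0.0, rng) \
            == BEYOND_TRAJECTORY

    def test_pmf_matches_product_formula(self, tiny_trajectory):
        """Empirical waiting-time pmf matches the geometric product formula
        with time-varying hazards."""
        fm, _ = _freq_model(tiny_trajectory)
        cfg = SampleConfiguration([CodedHaplotype(0, 1)], [2])
        rng = np.random.default_rng(2)
        n = 30_000
        draws = np.array([
            sample_event_time(cfg, 0, tiny_trajectory, fm, 0.0, rng)
            for _ in range(n)
        ])
        coeffs = hazard_coefficients(cfg, fm, 0.0, 0.0)
        T = tiny_trajectory.age
        hazards = np.array([
            min(waiting_hazard_per_gen(coeffs, tiny_trajectory.counts[u],
                                       tiny_trajectory.freqs[u]), 1.0)
            for u in range(1, T)
        ])
        surv = np.concatenate([[1.0], np.cumprod(1 - hazards)])
        for v in range(1, min(T, 8)):
            expect = surv[v - 1] * hazards[v - 1]
            est = (draws == v).mean()
            se = math.sqrt(max(expect * (1 - expect), 1e-12) / n)
            assert abs(est - expect) <= 4 * se + 1e-4


class TestProposal:
    def test_forced_coalescence(self, small_trajectory):
        fm, _ = _freq_model(small_trajectory)
        cfg = SampleConfiguration([CodedHaplotype(0, 1)], [2])
        ctx = _ctx(cfg, 5, small_trajectory, fm, mu=0.0, cc=0.0)
        rng = np.random.default_rng(3)
        ev = propose_event(cfg, 5, fm, ctx, rng)
        assert ev.kind == "coalescence"
        assert ev.new_cfg.n_lineages == 1

    def test_dead_end_returns_none(self, small_trajectory):
        fm, _ = _freq_model(small_trajectory)
        cfg = SampleConfiguration([CodedHaplotype(0, 1)], [1])
        ctx = _ctx(cfg, 5, small_trajectory, fm, mu=0.0, cc=0.0)
        assert propose_event(cfg, 5, fm, ctx,
                             np.random.default_rng(0)) is None

    def test_probabilities_sum_to_one_random_config(self, small_trajectory,
                                                    uniform_map_25):
        fm = HaplotypeFrequencyModel(small_trajectory, uniform_map_25, 17)
        cfg = SampleConfiguration(
            [CodedHaplotype(17, 7), CodedHaplotype(10, 3, (9,)),
             CodedHaplotype(6, 7), CodedHaplotype(2, 2)],
            [2, 1, 3, 1])
        ctx = _ctx(cfg, 7, small_trajectory, fm, mu=1e-4, cc=fm.total_len)
        events = enumerate_events(cfg, 7, fm, ctx)
        w = np.array([e.w_prop for e in events])
        assert (w / w.sum()).sum() == pytest.approx(1.0)


class TestStepWeight:
    def test_identity_all_event_kinds(self, small_trajectory, uniform_map_25):
        """Every proposed event's weight equals hbar/(2 gamma), verified by
        the dual computation in debug mode."""
        fm = HaplotypeFrequencyModel(small_trajectory, uniform_map_25, 17)
        cfg = SampleConfiguration(
            [CodedHaplotype(17, 7), CodedHaplotype(10, 3, (9,)),
             CodedHaplotype(10, 3)], [3, 1, 1])
        ctx = _ctx(cfg, 7, small_trajectory, fm, mu=1e-4, cc=fm.total_len)
        events = enumerate_events(cfg, 7, fm, ctx)
        kinds = {e.kind for e in events}
        assert {"coalescence", "recombination"} <= kinds
        vals = {step_weight(e, cfg, 7, fm, ctx, debug=True) for e in events}
        assert len(vals) == 1  # identical for every kind

    def test_weight_value(self, small_trajectory, uniform_map_25):
        fm = HaplotypeFrequencyModel(small_trajectory, uniform_map_25, 17)
        cfg = SampleConfiguration([CodedHaplotype(17, 7)], [4])
        ctx = _ctx(cfg, 7, small_trajectory, fm, mu=0.0, cc=fm.total_len)
        events = enumerate_events(cfg, 7, fm, ctx)
        hbar = sum(e.w_prop for e in events)
        gamma = waiting_hazard_per_gen(
            hazard_coefficients(cfg, fm, 0.0, fm.total_len),
            ctx.copies, ctx.x_v)
        assert step_weight(events[0], cfg, 7, fm, ctx) == \
            pytest.approx(math.log(hbar / (2 * gamma)))


class TestRunGenealogy:
    def test_already_absorbed(self, small_trajectory):
        fm, _ = _freq_model(small_trajectory)
        cfg = SampleConfiguration([CodedHaplotype(0, 1)], [1])
        path = run_genealogy(cfg, small_trajectory, fm, 0.0, 1e-3,
                             np.random.default_rng(0))
        assert path.status == "absorbed"
        assert path.log_weight == 0.0

    def test_two_founders_single_event_closed_form(self, tiny_trajectory):
        """Two intact founder lineages with theta = rho = 0: the mean weight
        equals P(coalescence before T) under the trajectory."""
        rmap = RecombinationMap(np.array([1, 1_000_000]),
                                np.array([0.0, 1e-6]))
        fm = HaplotypeFrequencyModel(tiny_trajectory, rmap, 0)
        cfg = SampleConfiguration([CodedHaplotype(0, 1)], [2])
        T = tiny_trajectory.age
        hazards = np.array([
            min(1.0 / tiny_trajectory.counts[u], 1.0) for u in range(1, T)
        ])
        p_exact = 1.0 - np.prod(1 - hazards)
        rng = np.random.default_rng(5)
        n = 2000
        w = np.array([
            math.exp(run_genealogy(cfg, tiny_trajectory, fm, 0.0, 0.0,
                                   rng).log_weight)
            for _ in range(n)
        ])
        w[~np.isfinite(w)] = 0.0
        se = w.std(ddof=1) / math.sqrt(n)
        assert abs(w.mean() - p_exact) <= 3 * se + 1e-3

    def test_absorbed_paths_replay_to_initial_configuration(
            self, tiny_trajectory):
        """Replaying an absorbed path's events forward regenerates the
        starting configuration (bookkeeping consistency)."""
        fm, rmap = _freq_model(tiny_trajectory, r=5e-3)
        cfg0 = SampleConfiguration(
            [CodedHaplotype(0, 1), CodedHaplotype(0, 0)], [2, 2])
        rng = np.random.default_rng(6)
        for _ in range(50):
            trace = []
            path = run_genealogy(cfg0, tiny_trajectory, fm, 0.0,
                                 rmap.total_morgans, rng, trace=trace)
            if path.status != "absorbed":
                continue
            assert trace[-1]["n_lineages"] == 1
            sizes = [t["n_lineages"] for t in trace]
            # lineage count changes by at most 1 per event, ends at 1
            assert all(abs(a - b) <= 1 for a, b in zip(sizes, sizes[1:]))

    def test_python_and_kernel_agree_with_oracle(self, tiny_trajectory):
        """Both sampler implementations match the exact DP value."""
        r = 2e-3
        traj = tiny_trajectory
        rmap = RecombinationMap(np.array([1, 1_000_000]),
                                np.array([0.0, 100 * r]))
        fm = HaplotypeFrequencyModel(traj, rmap, 0)
        cfg = SampleConfiguration(
            [CodedHaplotype(0, 1), CodedHaplotype(0, 0)], [3, 2])
        dp = exact_sampling_probability(cfg, traj, rmap, 0, mu=0.0, cc=r)
        rng = np.random.default_rng(7)
        n = 4000
        w = np.array([
            math.exp(run_genealogy(cfg, traj, fm, 0.0, r, rng).log_weight)
            for _ in range(n)
        ])
        w[~np.isfinite(w)] = 0.0
        se = w.std(ddof=1) / math.sqrt(n)
        assert abs(w.mean() - dp) <= 4 * se

        dL, dR = rmap.flank_distances(0)
        packed = _kernels.pack_configuration(cfg, dL, dR)
        T = traj.age
        x = traj.freqs
        clock = np.zeros(T + 1)
        clock[:T - 1] = np.cumsum((1 - x[1:T])[::-1])[::-1]
        lw = _kernels.genealogy_batch(*packed, traj.counts, x, clock, dL, dR,
                                      0.0, r, 40_000, 4242)
        wk = np.exp(lw)
        wk[~np.isfinite(wk)] = 0.0
        sek = wk.std(ddof=1) / math.sqrt(len(wk))
        assert abs(wk.mean() - dp) <= 4 * sek
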