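"""Sequential importance sampling over genealogical histories.

Conditional on one allele-frequency trajectory, the coded sample
configuration is driven backward in time: waiting times are geometric with
the per-generation total hazard of the ancestral process, the event is drawn
from the proposal built from the terms of hbar, and every step contributes
the importance weight hbar/(2 gamma) — identical for all four event kinds,
which the sampler cross-checks against the direct target/proposal ratio in
debug mode.  A path is absorbed when a single lineage carrying the intact
founder haplotype remains; paths that run beyond the trajectory (or hit a
dead end) are rejected with weight zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ancestral_process import (
    Event,
    HaplotypeFrequencyModel,
    RateContext,
    enumerate_events,
    hazard_coefficients,
    waiting_hazard_per_gen,
)
from .haplotype_coding import SampleConfiguration

__all__ = ["GenealogyPath", "sample_event_time", "propose_event", "step_weight",
           "run_genealogy"]

BEYOND_TRAJECTORY = -1


@dataclass
class GenealogyPath:
    """An event sequence with its accumulated log importance weight."""

    events: list = field(default_factory=list)
    status: str = "running"          # running | absorbed | rejected
    log_weight: float = 0.0
    n_steps: int = 0

    def reject(self):
        self.status = "rejected"
        self.log_weight = -np.inf
        return self


def sample_event_time(cfg, t: int, traj, freq_model, mu: float, rng,
                      cc: float = 0.0, mut_betas=None) -> int:
    """Draw the next event generation v > t by per-generation Bernoulli trials
    with the total hazard A/I_u + B_mu + B_r (1 - X_u); returns
    BEYOND_TRAJECTORY when no event fires before the trajectory ends.

    The geometric scan is done by inverse-CDF on the cumulative log-survival
    (distributionally identical to generation-by-generation trials).
    """
    T = traj.age
    if t >= T - 1:
        return BEYOND_TRAJECTORY
    a, b_const, b_x = hazard_coefficients(cfg, freq_model, mu, cc, mut_betas)
    counts = traj.counts[t + 1:T].astype(float)
    x = traj.freqs[t + 1:T]
    donor = x if freq_model.selected_donor else (1.0 - x)
    hazards = np.clip(a / counts + b_const + b_x * donor, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        log_surv = np.cumsum(np.log1p(-hazards))
    target = math.log(max(rng.random(), 1e-300))
    idx = int(np.searchsorted(-log_surv, -target, side="right"))
    if idx >= len(hazards):
        return BEYOND_TRAJECTORY
    return t + 1 + idx


def propose_event(cfg, v: int, freq_model, ctx: RateContext, rng) -> Event | None:
    """Pick one admissible event at v with probability proportional to its
    term in hbar; None signals a dead end (hbar = 0)."""
    events = enumerate_events(cfg, v, freq_model, ctx)
    if not events:
        return None
    weights = np.array([e.w_prop for e in events])
    total = weights.sum()
    if total <= 0.0:
        return None
    idx = rng.choice(len(events), p=weights / total)
    return events[idx]


def step_weight(event: Event, cfg, v: int, freq_model, ctx: RateContext,
                debug: bool = False) -> float:
    """Log importance-weight increment log(hbar/(2 gamma)) for one step.

    With the proportional proposal the target/proposal ratio collapses to
    hbar/(2 gamma) for every event kind; in debug mode both routes are
    computed and must agree to 1e-9.
    """
    events = enumerate_events(cfg, v, freq_model, ctx)
    hbar_g = sum(e.w_prop for e in events)
    coeffs = hazard_coefficients(cfg, freq_model, ctx.mu, ctx.cc,
                                 ctx.mut_betas)
    gamma_g = waiting_hazard_per_gen(coeffs, ctx.copies, ctx.x_v,
                                     freq_model.selected_donor)
    w = hbar_g / (2.0 * gamma_g)
    if debug:
        # direct ratio: target = w_prop/(2 gamma_g), proposal = w_prop/hbar_g
        direct = (event.w_prop / (2.0 * gamma_g)) / (event.w_prop / hbar_g)
        if not math.isclose(direct, w, rel_tol=1e-9, abs_tol=1e-12):
            raise AssertionError(
                f"step-weight bookkeeping mismatch: {direct} vs {w}"
            )
    return math.log(w)


def run_genealogy(
    cfg0: SampleConfiguration,
    traj,
    freq_model: HaplotypeFrequencyModel,
    mu: float,
    cc: float,
    rng,
    debug: bool = False,
    trace: list | None = None,
) -> GenealogyPath:
    """Drive ``cfg0`` backward along ``traj`` until absorption or rejection.

    Absorption requires a single lineage equal to the intact founder code;
    a lone non-founder lineage keeps taking mutation/recombination moves (the
    founder of the sweep carries the full ancestral haplotype by
    construction).  The terminal factor q((T, e_1)) is 1 at the founder.
    """
    two_n0 = 2.0 * traj.pop_sizes[0]
    founder = freq_model.founder
    counts = traj.counts
    freqs = traj.freqs

    def ctx_builder(cfg, v, mut_betas):
        betas = np.array([freq_model.beta(h) for h in cfg.types])
        return RateContext(cfg, v, int(counts[v]), two_n0, mu, cc, betas,
                           x_v=float(freqs[v]), mut_betas=mut_betas)

    path = GenealogyPath()
    cfg = cfg0
    mut_betas = np.array([freq_model.beta(h) for h in cfg.types])
    t = 0
    while not cfg.is_absorbed(founder):
        v = sample_event_time(cfg, t, traj, freq_model, mu, rng, cc=cc,
                              mut_betas=mut_betas)
        if v == BEYOND_TRAJECTORY:
            return path.reject()
        ctx = ctx_builder(cfg, v, mut_betas)
        event = propose_event(cfg, v, freq_model, ctx, rng)
        if event is None:
            return path.reject()
        path.log_weight += step_weight(event, cfg, v, freq_model, ctx, debug=debug)
        path.events.append((v, event.kind, event.source))
        path.n_steps += 1
        if trace is not None:
            trace.append({
                "v": v, "kind": event.kind,
                "n_lineages": event.new_cfg.n_lineages,
                "log_weight": path.log_weight,
            })
        cfg = event.new_cfg
        if event.new_mut_betas is not None:
            mut_betas = np.asarray(event.new_mut_betas)
        t = v
    path.status = "absorbed"
    return path
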