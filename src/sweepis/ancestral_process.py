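"""Transition model of the simplified multilocus ancestral process.

Conditional on a frequency trajectory of the selected allele, the coded
sample configuration evolves backward in time by coalescence (restricted to
the selected class, whose size is I_t chromosomes), mutation (removal of the
most recent mutation coordinate of a singleton type) and recombination
(restoration of a trimmed flank by a donor chromosome of the selected
class).

Expected class frequencies
--------------------------
Ancestral material beyond genetic distance d from the selected site escapes
to the background at per-generation rate d * (1 - X_u), so it survives down
to generation t with probability exp(-d * C(t)), C(t) =
sum_{u=t+1}^{T-1}(1 - X_u), independently per flank.  Differencing adjacent
"at-least" survivals yields the expected exact-extent class frequencies
P_[h](t) among carriers; they partition to one.

Default transition model
------------------------
* Coalescence: total rate C(n,2)/(lambda_v X_v), allocated n(n_k - 1) to
  same-type mergers within type k; the cross-type deficit is inconsistent
  with the data and absorbs probability.
* Mutation: the clock of a lineage runs at mu times its *observable*
  fraction — the coded fraction at observation, carried unchanged through
  flank extensions (material acquired backward is truncated away before
  observation and cannot carry observable mutations) and averaged at
  merges.  Shift/merge allocation follows the infinitely-many-sites
  sampling recursion.
* Recombination: a lineage with break at interval a extends one flank to
  b > a at per-generation rate r_int(a) * P_side(b, v) * X_v — the break
  interval's map length times the frequency of selected-class donors of the
  restored extent (background donors are double migrations and dropped);
  donors of shorter extent cannot restore the flank and count as deficit.
  Extents never shrink backward.
* Waiting hazard: the classical total rate gamma(v, n) =
  C(n,2)/(lambda_v X_v) + sum theta_i/2 + sum rho_i/2 (per 2 N_0
  generations; divided by 2 N_0 for the per-generation geometric scan), so
  every lineage pays the rho beta_i / 2 survival charge.

An alternative escape-reversal convention (extensions at rate
r_int(a)(1 - X_v) with conditional extent law and an explicit
interior-escape death hazard in the waiting rate) is available through the
``selected_donor`` / ``paper_hazard`` flags; see docs/methods.md for the
comparison.

Units: per generation internally (mutation rate ``mu`` per haplotype, map
distances in Morgans); the coalescent-scaled total rate per 2 N_0
generations is exposed as :func:`total_rate_gamma`.  The step importance
weight hbar/(2 gamma) is unit-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .haplotype_coding import (
    CodedHaplotype,
    RecombinationMap,
    SampleConfiguration,
    coordinate_change,
    founder_haplotype,
    remove_type,
    shift_first_mutation,
)

__all__ = [
    "HaplotypeFrequencyModel",
    "RateContext",
    "Event",
    "expected_class_frequency",
    "recombination_transition_prob",
    "total_rate_gamma",
    "proposal_total_rate_hbar",
    "event_type_probabilities",
    "enumerate_events",
    "hazard_coefficients",
    "waiting_hazard_per_gen",
]


class HaplotypeFrequencyModel:
    """Deterministic expected frequencies of ancestral-segment classes along
    one trajectory, cached for reuse across genealogy replicates.

    ``selected_donor`` selects the weighting of backward flank extensions:
    True (default) weights the restoring recombination by the frequency of
    selected-class donor chromosomes carrying the restored extent,
    P_[dest](v) * X_v, the simplification in which donors from the
    background class are dropped; False weights it by the background escape
    hazard (1 - X_v) with the restored extent drawn conditionally, and adds
    the interior-escape death hazard (see docs/methods.md).
    """

    def __init__(self, traj, rmap: RecombinationMap, mutant_col: int,
                 selected_donor: bool = True, paper_hazard: bool = True):
        self.selected_donor = bool(selected_donor)
        self.paper_hazard = bool(paper_hazard)
        self.mutant_col = int(mutant_col)
        self.d_left, self.d_right = rmap.flank_distances(mutant_col)
        self.m_left = len(self.d_left) - 1
        self.m_right = len(self.d_right) - 1
        self.total_len = float(self.d_left[-1] + self.d_right[-1])
        x = traj.freqs
        T = traj.age
        # escape clock C(t) = sum_{u=t+1}^{T-1} (1 - X_u); C(T-1) = 0
        c = np.zeros(T + 1)
        if T >= 2:
            c[:T - 1] = np.cumsum((1.0 - x[1:T])[::-1])[::-1]
        self._clock = c
        self.age = T

    def clock(self, t: int) -> float:
        return float(self._clock[t])

    def survival(self, side: str, k: int, t: int) -> float:
        """P(retained extent >= k SNPs on ``side`` at generation t)."""
        d = self.d_left if side == "left" else self.d_right
        return float(np.exp(-d[k] * self._clock[t]))

    def side_class_probs(self, side: str, t: int) -> np.ndarray:
        """Exact-extent probabilities over 0..m_side for one flank."""
        d = self.d_left if side == "left" else self.d_right
        surv = np.exp(-d * self._clock[t])
        probs = np.empty_like(surv)
        probs[:-1] = surv[:-1] - surv[1:]
        probs[-1] = surv[-1]
        return probs

    def conditional_extent_probs(self, side: str, a: int, t: int) -> np.ndarray:
        """P(extent = b | extent > a) for b = a+1 .. m_side at generation t.

        Computed from hazard differences so it stays normalised even when
        the unconditional survivals underflow.
        """
        d = self.d_left if side == "left" else self.d_right
        m = len(d) - 1
        cv = self._clock[t]
        out = np.empty(m - a)
        for b in range(a + 1, m + 1):
            head = math.exp(-(d[b] - d[a + 1]) * cv)
            if b < m:
                out[b - a - 1] = head * -math.expm1(-(d[b + 1] - d[b]) * cv)
            else:
                out[b - a - 1] = head
        return out

    def class_prob(self, r1: int, r2: int, t: int) -> float:
        """Expected frequency of the exact class (r1, r2) among selected
        chromosomes at generation t (flanks independent)."""
        return float(
            self.side_class_probs("left", t)[r1]
            * self.side_class_probs("right", t)[r2]
        )

    def beta(self, h: CodedHaplotype) -> float:
        """Ancestral fraction of a coded type under this map."""
        if self.total_len <= 0:
            raise ValueError("map has zero genetic length")
        return float(self.d_left[h.r1] + self.d_right[h.r2]) / self.total_len

    def flank_hazard_scale(self, h: CodedHaplotype) -> float:
        """Per-lineage recombination hazard coefficient.

        Selected-donor mode: the break-interval lengths r_int(a) of the two
        flanks (hazard scales with X_u).  Background mode: Morgans from the
        selected site through each flank's break interval (hazard scales
        with 1 - X_u; interior escapes are deaths).
        """
        dl, dr = self.d_left, self.d_right
        if self.selected_donor:
            left = dl[h.r1 + 1] - dl[h.r1] if h.r1 < self.m_left else 0.0
            right = dr[h.r2 + 1] - dr[h.r2] if h.r2 < self.m_right else 0.0
        else:
            left = dl[min(h.r1 + 1, self.m_left)]
            right = dr[min(h.r2 + 1, self.m_right)]
        return float(left + right)

    @property
    def founder(self) -> CodedHaplotype:
        return founder_haplotype(self.m_left, self.m_right)


def expected_class_frequency(h: CodedHaplotype, t: int, freq_model) -> float:
    """P_[h](t): expected within-class frequency of exact extent (R1, R2)."""
    if t > freq_model.age:
        raise ValueError("generation beyond the end of the trajectory")
    return freq_model.class_prob(h.r1, h.r2, t)


def recombination_transition_prob(
    h_from: CodedHaplotype, h_to: CodedHaplotype, v: int, freq_model
) -> float:
    """p_{h_to, h_from}: conditional probability that the escape reversal on a
    lineage of type ``h_from`` at generation v restores type ``h_to``.

    Non-zero only when ``h_to`` extends exactly one flank of ``h_from`` (the
    mutation coordinates carried along unchanged); the restored extent
    follows the conditional survival law of the donor classes.  Sums to one
    over reachable destinations of the extended flank.
    """
    for side, cur, other_same in (
        ("left", h_from.r1, h_to.r2 == h_from.r2),
        ("right", h_from.r2, h_to.r1 == h_from.r1),
    ):
        new = h_to.r1 if side == "left" else h_to.r2
        if other_same and new > cur:
            expected = coordinate_change(
                h_from, side, new, mutant_col=freq_model.mutant_col
            )
            if expected != h_to:
                return 0.0
            if freq_model.selected_donor:
                return float(freq_model.side_class_probs(side, v)[new])
            probs = freq_model.conditional_extent_probs(side, cur, v)
            return float(probs[new - cur - 1])
    return 0.0


@dataclass
class RateContext:
    """Per-generation rate inputs at time v for a configuration."""

    cfg: SampleConfiguration
    v: int
    copies: int          # I_v, chromosomes in the selected class
    two_n0: float        # 2 N_0 (after any X-linkage rescaling)
    mu: float            # per-haplotype per-generation mutation rate
    cc: float            # per-haplotype map length, Morgans (recomb. fraction)
    betas: np.ndarray    # ancestral fraction per distinct type
    x_v: float = 0.0     # frequency X_v of the selected allele
    mut_betas: np.ndarray | None = None  # observable-segment fraction per type

    @property
    def effective_mut_betas(self) -> np.ndarray:
        """Mutation-clock fractions: the observable (sampled) segment of each
        type, falling back to the coded fraction when not tracked."""
        return self.betas if self.mut_betas is None else self.mut_betas

    @property
    def theta(self) -> float:
        return 2.0 * self.two_n0 * self.mu

    @property
    def rho(self) -> float:
        return 2.0 * self.two_n0 * self.cc


def total_rate_gamma(ctx: RateContext) -> float:
    """Classical total event rate gamma(v, n) per 2 N_0 generations:
    C(n,2)/(lambda_v X_v) + sum_i theta_i/2 + sum_i rho_i/2."""
    n = ctx.cfg.n_lineages
    if ctx.copies <= 0 and n >= 2:
        raise ValueError("coalescence forced before loss: trajectory too short")
    beta_tot = float(np.dot(ctx.cfg.mult, ctx.betas))
    coal = n * (n - 1) / 2.0 * ctx.two_n0 / ctx.copies if n >= 2 else 0.0
    return coal + 0.5 * (ctx.theta + ctx.rho) * beta_tot


def event_type_probabilities(ctx: RateContext):
    """Shares of gamma for (mutation, recombination, coalescence); sum to 1."""
    gamma = total_rate_gamma(ctx)
    beta_tot = float(np.dot(ctx.cfg.mult, ctx.betas))
    n = ctx.cfg.n_lineages
    p_mut = 0.5 * ctx.theta * beta_tot / gamma
    p_rec = 0.5 * ctx.rho * beta_tot / gamma
    p_coal = (n * (n - 1) / 2.0 * ctx.two_n0 / ctx.copies) / gamma if n >= 2 else 0.0
    return p_mut, p_rec, p_coal


def hazard_coefficients(cfg: SampleConfiguration, freq_model, mu: float,
                        cc: float = 0.0, mut_betas=None):
    """Decomposition of the sampler's per-generation hazard between events:

    hazard(u) = A / I_u + B_const + B_x * w(X_u)

    with A = C(n,2).  The mutation hazard uses the observable-segment
    fraction of each type when supplied (material acquired by backward
    extension is truncated away before observation and carries no
    observable mutations).  Under the classical rate (``paper_hazard``) the
    recombination hazard is cc * beta_i per lineage, frequency-independent
    (B_x = 0); otherwise it is the flank hazard of
    :meth:`HaplotypeFrequencyModel.flank_hazard_scale` weighted by X_u or
    (1 - X_u) according to the donor convention.
    """
    n = cfg.n_lineages
    a = n * (n - 1) / 2.0
    b_const = 0.0
    b_x = 0.0
    for i, (h, m) in enumerate(zip(cfg.types, cfg.mult)):
        beta = freq_model.beta(h)
        mb = beta if mut_betas is None else mut_betas[i]
        b_const += m * mu * mb
        if freq_model.paper_hazard:
            b_const += m * cc * beta
        else:
            b_x += m * freq_model.flank_hazard_scale(h)
    return a, b_const, b_x


def waiting_hazard_per_gen(coeffs, i_u: float, x_u: float,
                           selected_donor: bool = True) -> float:
    """The sampler's total per-generation rate gamma_g at one generation."""
    a, b_const, b_x = coeffs
    coal = a / i_u if a > 0 else 0.0
    donor = x_u if selected_donor else (1.0 - x_u)
    return coal + b_const + b_x * donor


@dataclass
class Event:
    """One admissible backward move with its proposal weight.

    ``w_prop`` is the per-generation proposal term (a summand of the
    per-generation hbar); the target-chain probability of the move given an
    event at v is ``w_prop / (2 gamma_g)`` with gamma_g the waiting hazard.
    """

    kind: str                    # coalescence | mutation_shift | mutation_merge | recombination
    source: int                  # index of the acted-on type
    new_cfg: SampleConfiguration
    w_prop: float
    detail: tuple = ()
    new_mut_betas: tuple | None = None   # aligned with new_cfg.types


def enumerate_events(
    cfg: SampleConfiguration, v: int, freq_model, ctx: RateContext
) -> list[Event]:
    """Every admissible one-step backward move from ``cfg`` at generation v,
    with proposal weights proportional to twice the target rates:

    - coalescence within type k (n_k >= 2):      n (n_k - 1) / I_v
    - mutation shift of singleton k:             2 mu mb_k
    - mutation merge of singleton k into j:      2 mu mb_j (n_j + 1)
    - flank extension of a lineage of type i
      from break a to extent b > a:              2 n_i r_int(a) w(X_v) P(b, v)

    where mb is the observable-segment fraction of a type (its coded beta at
    observation, carried unchanged through extensions and averaged at
    merges) and w(X_v)·P(b, v) is the donor weighting of the frequency
    model.  A mutation on a singleton whose shifted code already exists must
    merge (infinitely-many-sites: the coordinate is a singleton in the
    sample).  Each event carries the updated observable fractions aligned
    with its new configuration.
    """
    events: list[Event] = []
    n = cfg.n_lineages
    mult = cfg.mult
    mbs = ctx.effective_mut_betas

    def aligned_mb(new_cfg, mb_map):
        return tuple(float(mb_map[h2]) for h2 in new_cfg.types)

    base_map = {h2: float(mbs[i2]) for i2, h2 in enumerate(cfg.types)}

    for k, h in enumerate(cfg.types):
        if mult[k] >= 2:
            new_cfg = cfg.replace_counts({h: -1})
            events.append(Event(
                "coalescence", k, new_cfg, n * (mult[k] - 1) / ctx.copies,
                new_mut_betas=aligned_mb(new_cfg, base_map),
            ))

    for k, h in enumerate(cfg.types):
        if mult[k] != 1 or h.n_mut == 0 or ctx.mu <= 0.0:
            continue
        shifted = shift_first_mutation(h)
        j = cfg.index_of(shifted)
        if j is None:
            new_cfg = cfg.replace_counts({h: -1, shifted: +1})
            mb_map = dict(base_map)
            mb_map.pop(h)
            mb_map[shifted] = float(mbs[k])
            events.append(Event(
                "mutation_shift", k, new_cfg, 2.0 * ctx.mu * mbs[k],
                new_mut_betas=aligned_mb(new_cfg, mb_map),
            ))
        else:
            new_cfg = remove_type(cfg, k).replace_counts({shifted: +1})
            mb_map = dict(base_map)
            mb_map.pop(h)
            mb_map[shifted] = float(
                (mult[j] * mbs[j] + mbs[k]) / (mult[j] + 1))
            events.append(Event(
                "mutation_merge", k, new_cfg,
                2.0 * ctx.mu * mbs[j] * (mult[j] + 1), (j,),
                new_mut_betas=aligned_mb(new_cfg, mb_map),
            ))

    if freq_model.selected_donor:
        donor_weight = ctx.x_v
    else:
        donor_weight = 1.0 - ctx.x_v
    if donor_weight > 0.0:
        for i, h in enumerate(cfg.types):
            for side, cur, d in (
                ("left", h.r1, freq_model.d_left),
                ("right", h.r2, freq_model.d_right),
            ):
                m_side = len(d) - 1
                if cur >= m_side:
                    continue
                r_int = float(d[cur + 1] - d[cur])
                if r_int <= 0.0:
                    continue
                if freq_model.selected_donor:
                    # restored extent ~ donor-class frequencies; donors of
                    # shorter extent cannot restore and count as deficit
                    probs = freq_model.side_class_probs(side, v)[cur + 1:]
                else:
                    probs = freq_model.conditional_extent_probs(side, cur, v)
                for b in range(cur + 1, m_side + 1):
                    p_b = probs[b - cur - 1]
                    if p_b <= 0.0:
                        continue
                    dest = coordinate_change(h, side, b,
                                             mutant_col=freq_model.mutant_col)
                    w = 2.0 * mult[i] * r_int * donor_weight * p_b
                    new_cfg = cfg.replace_counts({h: -1, dest: +1})
                    mb_map = dict(base_map)
                    # the moving lineage keeps its observable material
                    j = cfg.index_of(dest)
                    n_j = 0 if j is None else int(mult[j])
                    mb_dest = float(mbs[i]) if n_j == 0 else float(
                        (n_j * mbs[j] + mbs[i]) / (n_j + 1))
                    if mult[i] == 1:
                        mb_map.pop(h)
                    mb_map[dest] = mb_dest
                    events.append(Event(
                        "recombination", i, new_cfg, w, (side, b),
                        new_mut_betas=aligned_mb(new_cfg, mb_map),
                    ))
    return events


def proposal_total_rate_hbar(
    cfg: SampleConfiguration, v: int, freq_model, ctx: RateContext
) -> float:
    """hbar((T, n)_v) in events per 2 N_0 generations."""
    return ctx.two_n0 * sum(e.w_prop for e in enumerate_events(cfg, v, freq_model, ctx))
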