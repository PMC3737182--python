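"""Synthetic sweep data with known truth, and the exact sampling-probability
oracle used as the correctness anchor of the importance sampler.

The generator runs a forward Wright-Fisher trajectory conditioned (by
rejection) to carry the mutant from one copy to a target present-day
frequency, builds the intra-allelic coalescent tree of the sampled selected
chromosomes inside that trajectory, truncates ancestral flanks by
recombination escape along each branch, sprinkles new mutations on retained
segments, and emits the annotated haplotype matrix together with the truth.

The oracle solves the backward ancestral process exactly by dynamic
programming over (configuration, generation), using the *same* per-generation
hazards and target transition probabilities as the importance sampler, so the
sampler's mean weight must converge to the oracle value on any instance small
enough to enumerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestral_process import HaplotypeFrequencyModel, RateContext, enumerate_events
from .haplotype_coding import (
    CodedHaplotype,
    RecombinationMap,
    SampleConfiguration,
    SelectedHaplotypeMatrix,
    encode_sample,
    founder_haplotype,
)
from .wf_trajectory import Demography, SelectionModel, Trajectory, forward_log_prob

__all__ = ["SimulatedDataset", "simulate_dataset", "two_locus_oracle",
           "exact_sampling_probability"]


@dataclass
class SimulatedDataset:
    """A simulated sweep sample with full truth attached."""

    matrix: SelectedHaplotypeMatrix          # selected haplotypes only
    background: np.ndarray                   # background haplotype rows
    rmap: RecombinationMap
    trajectory: Trajectory
    s: float
    theta: float
    rho: float
    N: float
    x0: float
    n_sample: int

    @property
    def n_selected(self) -> int:
        return self.matrix.n_haplotypes


def _forward_conditioned_trajectory(
    sel: SelectionModel, demog: Demography, x0: float, rng,
    max_tries: int = 100_000, t_cap: int | None = None,
) -> Trajectory:
    """Forward path from a single copy, observed at a random generation at
    which the mutant frequency lies at x0.

    Sampling follows the flux measure of the inference model (forward path
    probability times the mutational influx): a path is simulated to
    absorption, every generation whose frequency falls within a narrow band
    of x0 is an eligible observation time, paths are accepted with
    probability proportional to their number of eligible generations, and
    one of them is drawn uniformly.  Observing at first passage instead
    would bias the data toward unusually fast sweeps, which matters for
    weak selection.
    """
    if t_cap is None:
        t_cap = int(8 * demog.N0 * demog.scale)
    two_n = int(round(2 * demog.size(0)))
    target = int(round(two_n * x0))
    # band wide enough that the path cannot step across it in one
    # generation (deterministic motion ~ s2 x (1-x) per generation)
    step = abs(sel.s2) * x0 * (1.0 - x0)
    band = max(1, int(round(two_n * max(0.002, 1.5 * step))))
    visit_cap = 1024
    from ._kernels import forward_path_kernel

    for _ in range(max_tries):
        path = forward_path_kernel(two_n, sel.s1, sel.s2, t_cap,
                                   int(rng.integers(2**31 - 1)))
        visits = np.flatnonzero(np.abs(path[1:] - target) <= band) + 1
        if len(visits) == 0:
            continue
        # weight paths by their sojourn in the observation band
        if rng.random() > min(len(visits), visit_cap) / visit_cap:
            continue
        t_obs = int(visits[rng.integers(len(visits))])
        counts = np.concatenate([path[:t_obs + 1][::-1], [0]]).astype(np.int64)
        sizes = demog.sizes_to(len(counts) - 1)
        traj = Trajectory(counts, sizes, logp_backward=np.nan)
        traj.logp_forward = forward_log_prob(traj, sel, demog)
        return traj
    raise RuntimeError("trajectory retry budget exhausted; is x0 reachable?")


def _coalescent_tree(n_leaves: int, counts: np.ndarray, rng):
    """Discrete-generation coalescent of the selected class: per-generation
    pair hazard 1/I_t.  Returns (parent, node_time); the root is the founder
    lineage at T-1."""
    T = len(counts) - 1
    parent = {}
    node_time = {i: 0 for i in range(n_leaves)}
    active = list(range(n_leaves))
    next_id = n_leaves
    t = 0
    while len(active) > 1:
        t += 1
        if t > T - 1:
            t = T - 1
        k = len(active)
        hazard = min(k * (k - 1) / 2.0 / counts[t], 1.0) if counts[t] > 0 else 1.0
        if t == T - 1 or rng.random() < hazard:
            i, j = rng.choice(k, size=2, replace=False)
            a, b = active[i], active[j]
            active = [x for x in active if x not in (a, b)] + [next_id]
            parent[a] = parent[b] = next_id
            node_time[next_id] = t
            next_id += 1
    root = active[0]
    node_time[root] = T - 1
    return parent, node_time, root


def simulate_dataset(
    s: float,
    N: float = 10_000.0,
    theta: float = 500.0,
    rho: float = 500.0,
    x0: float = 0.60,
    n_sample: int = 20,
    m_snps: int = 121,
    mutant_col: int | None = None,
    rng=None,
    x_linked: bool = False,
) -> SimulatedDataset:
    """Generate one sweep dataset under the stated study conditions.

    Defaults mirror the simulation study this package reproduces: scaled
    rates theta = rho = 500, N = 10,000, present-day mutant frequency 0.60,
    additive selection.  ``m_snps`` markers are placed uniformly in genetic
    distance across the mapped region whose total length is rho/(4N) Morgans;
    the default grid is dense enough that the infinitely-many-sites
    deposition of sweep-era mutations is not column-limited at theta = 500.
    """
    rng = np.random.default_rng(rng)
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must be in (0, 1)")
    demog = Demography(N0=N, x_linked=x_linked)
    sel = SelectionModel.additive(s)
    ne = N * demog.scale
    mu = theta / (4.0 * ne)
    cc = rho / (4.0 * ne)        # Morgans across the analysed region
    if mutant_col is None:
        mutant_col = m_snps // 2
    # markers uniform in genetic distance; 1 cM/Mb physical scale for bp
    positions = np.round(np.linspace(0, cc * 100 * 1e6, m_snps)).astype(np.int64)
    positions = np.maximum.accumulate(positions + np.arange(m_snps))  # strict
    rmap = RecombinationMap(positions, np.linspace(0.0, cc * 100, m_snps))

    traj = _forward_conditioned_trajectory(sel, demog, x0, rng)
    counts = traj.counts
    T = traj.age
    x = traj.freqs
    # cumulative (1 - X_u) between generation pairs, for branch escape hazards
    cum_bg = np.concatenate([[0.0], np.cumsum(1.0 - x[1:T])])  # index by t

    n_selected = int(round(n_sample * x0))
    if not 1 <= n_selected <= n_sample:
        raise ValueError("no selected chromosomes at this x0 / n_sample")
    parent, node_time, root = _coalescent_tree(n_selected, counts, rng)

    d_left, d_right = rmap.flank_distances(mutant_col)
    m_left, m_right = mutant_col, m_snps - mutant_col - 1

    def branch_extent(parent_ext: int, w: float, d: np.ndarray) -> int:
        """Truncate one flank over a branch with escape weight w = sum(1-X)."""
        ext = parent_ext
        for k in range(parent_ext):
            r_int = d[k + 1] - d[k]
            if rng.random() < -np.expm1(-r_int * w):
                ext = k
                break
        return ext

    # walk the tree root -> leaves accumulating extents and mutations
    children: dict[int, list[int]] = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)
    ext_l = {root: m_left}
    ext_r = {root: m_right}
    muts: dict[int, tuple] = {root: ()}
    mutated_cols: set[int] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in children.get(node, []):
            w = cum_bg[node_time[node]] - cum_bg[node_time[ch]]
            gens = node_time[node] - node_time[ch]
            el = branch_extent(ext_l[node], w, d_left)
            er = branch_extent(ext_r[node], w, d_right)
            kept = tuple(
                p for p in muts[node]
                if mutant_col - el <= p <= mutant_col + er
            )
            beta = (d_left[el] + d_right[er]) / (d_left[-1] + d_right[-1])
            n_new = rng.poisson(mu * beta * gens) if mu > 0 else 0
            # mutations fall on typed columns inside the retained segment
            new_sites = []
            if n_new > 0:
                candidates = [
                    j for j in range(mutant_col - el, mutant_col + er + 1)
                    if j != mutant_col and j not in mutated_cols
                    and j not in kept
                ]
                rng.shuffle(candidates)
                new_sites = candidates[:n_new]
                mutated_cols.update(new_sites)
            ext_l[ch], ext_r[ch] = el, er
            muts[ch] = tuple(new_sites) + kept  # most recent first
            stack.append(ch)

    # background allele frequencies and the ancestral haplotype itself
    bg_freq = rng.beta(1.0, 1.0, size=m_snps)
    anc = (rng.random(m_snps) < bg_freq).astype(np.int8)
    anc[mutant_col] = 1
    bg_freq[mutant_col] = 0.0  # background chromosomes never carry the mutant

    sel_rows, mask_rows = [], []
    for leaf in range(n_selected):
        el, er = ext_l[leaf], ext_r[leaf]
        row = (rng.random(m_snps) < bg_freq).astype(np.int8)
        mask = np.zeros(m_snps, dtype=bool)
        lo, hi = mutant_col - el, mutant_col + er
        mask[lo:hi + 1] = True
        row[lo:hi + 1] = anc[lo:hi + 1]
        for p in muts[leaf]:
            row[p] = 1 - anc[p]
        row[mutant_col] = 1
        sel_rows.append(row)
        mask_rows.append(mask)

    background = (
        rng.random((n_sample - n_selected, m_snps)) < bg_freq
    ).astype(np.int8)

    matrix = SelectedHaplotypeMatrix(
        np.array(sel_rows), mutant_col, np.array(mask_rows), positions,
        ancestral_alleles=anc,
    )
    return SimulatedDataset(
        matrix=matrix, background=background, rmap=rmap, trajectory=traj,
        s=s, theta=theta, rho=rho, N=N, x0=x0, n_sample=n_sample,
    )


# ---------------------------------------------------------------------------
# exact dynamic-programming oracle


def _state_key(cfg: SampleConfiguration, mbs) -> frozenset:
    """Hashable key over (type, multiplicity, observable fraction)."""
    return frozenset(
        (h.r1, h.r2, h.muts, int(n), round(float(b), 10))
        for h, n, b in zip(cfg.types, cfg.mult, mbs)
    )


def _closure(cfg0: SampleConfiguration, mb0, freq_model, mu: float,
             cc: float, max_states: int):
    """All (configuration, observable fractions) states reachable from the
    start under the backward moves.

    Enumerated at v = 0, where the escape clock is largest so every
    extension destination has positive probability (and at v = T-1 for the
    degenerate clock-zero case).
    """
    seen = {}
    order = []
    stack = [(cfg0, tuple(float(b) for b in mb0))]
    while stack:
        cfg, mbs = stack.pop()
        key = _state_key(cfg, mbs)
        if key in seen:
            continue
        seen[key] = len(order)
        order.append((cfg, mbs))
        if len(order) > max_states:
            raise RuntimeError(
                "oracle state space too large; use the importance sampler"
            )
        betas = np.array([freq_model.beta(h) for h in cfg.types])
        for v in (0, max(freq_model.age - 1, 0)):
            # interior frequency so both donor weightings enumerate fully
            ctx = RateContext(cfg, v, 1, 1.0, mu, cc, betas, x_v=0.5,
                              mut_betas=np.asarray(mbs))
            for e in enumerate_events(cfg, v, freq_model, ctx):
                stack.append((e.new_cfg, e.new_mut_betas))
    return seen, order


def exact_sampling_probability(
    cfg0: SampleConfiguration,
    traj: Trajectory,
    rmap: RecombinationMap,
    mutant_col: int,
    mu: float = 0.0,
    cc: float = 0.0,
    max_states: int = 20_000,
    selected_donor: bool = True,
    paper_hazard: bool = True,
) -> float:
    """Exact probability q((T, n)_0) of the observed configuration under the
    simplified multilocus ancestral process, by backward DP over generations.

    Matches the importance sampler's measure exactly: per-generation hazard
    min(gamma/(2 N_0), 1), target move probability w_prop/(2 gamma_per_gen),
    absorption at the intact founder singleton.  The state carries the
    observable-segment fractions that drive the mutation clock.
    """
    freq_model = HaplotypeFrequencyModel(traj, rmap, mutant_col,
                                         selected_donor=selected_donor,
                                         paper_hazard=paper_hazard)
    founder = founder_haplotype(freq_model.m_left, freq_model.m_right)
    two_n0 = 2.0 * traj.pop_sizes[0]
    counts = traj.counts
    T = traj.age

    mb0 = [freq_model.beta(h) for h in cfg0.types]
    seen, states = _closure(cfg0, mb0, freq_model, mu, cc, max_states)
    n_states = len(states)
    absorbed = np.array([c.is_absorbed(founder) for c, _ in states])

    from .ancestral_process import hazard_coefficients

    betas_per = [
        np.array([freq_model.beta(h) for h in c.types]) for c, _ in states
    ]
    coeffs = [hazard_coefficients(c, freq_model, mu, cc, mbs)
              for c, mbs in states]
    a_coef = np.array([c[0] for c in coeffs])
    b_const = np.array([c[1] for c in coeffs])
    b_x = np.array([c[2] for c in coeffs])
    freqs = traj.freqs

    def moves_at(idx: int, v: int):
        cfg, mbs = states[idx]
        ctx = RateContext(cfg, v, int(counts[v]), two_n0, mu, cc,
                          betas_per[idx], x_v=float(freqs[v]),
                          mut_betas=np.asarray(mbs))
        return [(seen[_state_key(e.new_cfg, e.new_mut_betas)], e.w_prop)
                for e in enumerate_events(cfg, v, freq_model, ctx)]

    value = absorbed.astype(float)  # V(state, T-1)
    for t in range(T - 2, -1, -1):
        v = t + 1
        iv = counts[v]
        donor = freqs[v] if freq_model.selected_donor else (1.0 - freqs[v])
        gamma_g = a_coef / iv + b_const + b_x * donor
        hazard = np.minimum(gamma_g, 1.0)
        new_value = value.copy()
        for idx in range(n_states):
            if absorbed[idx]:
                continue
            if gamma_g[idx] <= 0.0:
                new_value[idx] = value[idx]
                continue
            contrib = 0.0
            for dest, w in moves_at(idx, v):
                if w > 0.0:
                    contrib += w * value[dest]
            new_value[idx] = (
                (1.0 - hazard[idx]) * value[idx]
                + hazard[idx] * contrib / (2.0 * gamma_g[idx])
            )
        value = new_value
    return float(value[seen[_state_key(cfg0, mb0)]])


def two_locus_oracle(
    q1: int, q2: int, traj: Trajectory, r: float, mu: float = 0.0,
    marker_side: str = "right", max_n: int = 12,
    selected_donor: bool = True, paper_hazard: bool = True,
) -> float:
    """Exact probability of observing ``q1`` selected chromosomes that retain
    the ancestral marker allele and ``q2`` that lost it, for a single marker
    at recombination fraction ``r`` from the selected site."""
    if q1 + q2 > max_n:
        raise ValueError("state space guard: use the importance sampler")
    if q1 + q2 < 1:
        raise ValueError("need at least one selected chromosome")
    positions = np.array([1_000, 1_000_000])
    gen = np.array([0.0, 100.0 * r])  # cM; fractions linear in map distance
    if marker_side == "right":
        rmap = RecombinationMap(positions, gen)
        mutant_col = 0
        retained, lost = CodedHaplotype(0, 1), CodedHaplotype(0, 0)
    else:
        rmap = RecombinationMap(positions, gen)
        mutant_col = 1
        retained, lost = CodedHaplotype(1, 0), CodedHaplotype(0, 0)
    types, mult = [], []
    if q1:
        types.append(retained)
        mult.append(q1)
    if q2:
        types.append(lost)
        mult.append(q2)
    cfg0 = SampleConfiguration(types, mult)
    return exact_sampling_probability(
        cfg0, traj, rmap, mutant_col, mu=mu, cc=r,
        selected_donor=selected_donor, paper_hazard=paper_hazard,
    )
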