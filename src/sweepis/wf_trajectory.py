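"""Wright-Fisher allele-frequency trajectories of the selected mutant.

The frequency path of the selected allele is sampled *backward* in time from
its present-day count down to loss (the generation the mutation arose), under
genotypic selection and a deterministic, possibly time-varying population
size.  The backward proposal inverts the deterministic selection map each
generation and draws the earlier count binomially; the forward Wright-Fisher
probability of the same path and the resulting importance weight are computed
exactly, so weighted averages over backward paths are unbiased for
expectations under the forward process conditioned on a single founding copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import binom

__all__ = [
    "Demography",
    "SelectionModel",
    "Trajectory",
    "backward_step",
    "sample_trajectory",
    "forward_log_prob",
    "trajectory_weight",
]


@dataclass(frozen=True)
class Demography:
    """Diploid effective population size N_t (t = 0 now, increasing into the past).

    Piecewise-constant sizes are given as ``(generation_start, N)`` breakpoints;
    ``growth_rate`` g instead gives exponential growth toward the present,
    N_t = N0 * exp(-g t).  ``x_linked`` rescales every size by 3/4, the
    effective size of an X-linked locus relative to the autosomes.
    """

    N0: float
    breakpoints: tuple = ()
    growth_rate: float = 0.0
    x_linked: bool = False

    def __post_init__(self):
        if self.N0 < 1:
            raise ValueError("N0 must be at least 1")
        object.__setattr__(
            self, "breakpoints",
            tuple(sorted((int(t), float(n)) for t, n in self.breakpoints)),
        )

    @property
    def scale(self) -> float:
        return 0.75 if self.x_linked else 1.0

    def size(self, t) -> np.ndarray:
        """N_t (after the X-linkage rescaling), vectorised over generations."""
        t = np.asarray(t, dtype=float)
        if self.growth_rate != 0.0:
            n = self.N0 * np.exp(-self.growth_rate * t)
        else:
            n = np.full_like(t, float(self.N0))
            for start, size in self.breakpoints:
                n = np.where(t >= start, size, n)
        return np.maximum(n * self.scale, 1.0)

    def sizes_to(self, t_max: int) -> np.ndarray:
        return self.size(np.arange(t_max + 1))

    def lam(self, t) -> np.ndarray:
        """λ_t = N_t / N_0 (both after rescaling)."""
        return self.size(t) / (self.N0 * self.scale)


@dataclass(frozen=True)
class SelectionModel:
    """Genotypic selection at the mutant site.

    Relative fitnesses are 1, 1 + s2, 1 + s1 for genotypes aa, Aa, AA.  The
    additive scheme (1, 1 + s/2, 1 + s) sets s1 = s, s2 = s/2.
    """

    s1: float
    s2: float

    def __post_init__(self):
        if 1.0 + self.s1 <= 0 or 1.0 + self.s2 <= 0:
            raise ValueError("fitnesses must be positive")

    @classmethod
    def additive(cls, s: float) -> "SelectionModel":
        return cls(s1=s, s2=s / 2.0)

    @property
    def s(self) -> float:
        return self.s1

    def forward_map(self, x):
        """Deterministic post-selection frequency x' given pre-selection x."""
        x = np.asarray(x, dtype=float)
        num = x * (1.0 + self.s1 * x + self.s2 * (1.0 - x))
        den = 1.0 + self.s1 * x * x + 2.0 * self.s2 * x * (1.0 - x)
        return num / den

    def inverse_map(self, y: float, tol: float = 1e-12) -> float:
        """The unique root y' in [0, 1] of forward_map(y') = y (bisection;
        the map is monotone on the unit interval for any valid model)."""
        if y <= 0.0:
            return 0.0
        if y >= 1.0:
            return 1.0
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if float(self.forward_map(mid)) < y:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


@dataclass
class Trajectory:
    """A backward-sampled frequency path with its probabilities.

    ``counts[t]`` is the copy number I_t of the selected allele among the
    2 N_t chromosomes at generation t, for t = 0 … T with I_T = 0 and
    I_{T-1} = 1 (single founding copy).  T is the allele age.
    """

    counts: np.ndarray
    pop_sizes: np.ndarray
    logp_backward: float
    logp_forward: float = np.nan

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.pop_sizes = np.asarray(self.pop_sizes, dtype=float)

    @property
    def age(self) -> int:
        return len(self.counts) - 1

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / (2.0 * self.pop_sizes)


def _binom_logpmf(k, n, p):
    if p <= 0.0:
        return 0.0 if k == 0 else -np.inf
    if p >= 1.0:
        return 0.0 if k == n else -np.inf
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * math.log(p) + (n - k) * math.log1p(-p)
    )


def backward_step(i_prev: int, t: int, sel: SelectionModel, demog: Demography, rng):
    """One backward generation: draw I_t ~ Binomial(2 N_t, Y') where Y' is the
    pre-selection frequency consistent with I_{t-1}.

    Returns ``(i_t, log_prob)``.
    """
    n_prev = demog.size(t - 1)
    n_t = demog.size(t)
    two_nt = int(round(2 * n_t))
    if not 0 < i_prev <= int(round(2 * n_prev)):
        raise ValueError("count at t-1 outside (0, 2N_{t-1}]")
    y = i_prev / (2.0 * n_prev)
    y_prime = sel.inverse_map(y)
    i_t = int(rng.binomial(two_nt, y_prime))
    return i_t, float(_binom_logpmf(i_t, two_nt, y_prime))


def sample_trajectory(
    i0: int, sel: SelectionModel, demog: Demography, rng, t_max: int | None = None
) -> Trajectory | None:
    """Sample one backward path from I_0 = ``i0`` to loss.

    Returns ``None`` when the path fails to lose the allele within ``t_max``
    generations (default 4 * 2 N_0); callers count and redraw or discard.
    """
    if t_max is None:
        t_max = int(8 * demog.N0 * demog.scale)
    if not 1 <= i0 <= int(round(2 * demog.size(0))):
        raise ValueError("i0 outside [1, 2N_0]")
    counts = [i0]
    logp_b = 0.0
    t = 0
    while counts[-1] > 0:
        t += 1
        if t > t_max:
            return None
        i_t, lp = backward_step(counts[-1], t, sel, demog, rng)
        counts.append(i_t)
        logp_b += lp
    counts = np.array(counts, dtype=np.int64)
    sizes = demog.sizes_to(len(counts) - 1)
    traj = Trajectory(counts, sizes, logp_backward=logp_b)
    traj.logp_forward = forward_log_prob(traj, sel, demog)
    return traj


def forward_log_prob(traj: Trajectory, sel: SelectionModel, demog: Demography) -> float:
    """Forward Wright-Fisher log-probability of a path founded by one copy.

    The founding term is 1 when I_{T-1} = 1 and 0 otherwise; every later
    generation contributes Binomial(I_{t-1}; 2 N_{t-1}, X'_t) with X'_t the
    deterministic post-selection frequency of X_t.
    """
    counts = traj.counts
    T = traj.age
    if counts[T] != 0:
        raise ValueError("trajectory must end at loss (I_T = 0)")
    if counts[T - 1] != 1:
        return -np.inf
    sizes = traj.pop_sizes
    logp = 0.0
    for t in range(T - 1, 0, -1):
        x_t = counts[t] / (2.0 * sizes[t])
        x_prime = float(sel.forward_map(x_t))
        two_n = int(round(2 * sizes[t - 1]))
        logp += _binom_logpmf(int(counts[t - 1]), two_n, x_prime)
    return float(logp)


def trajectory_weight(traj: Trajectory) -> float:
    """Log importance weight: log P_F - log P_B + log(2 N_T).

    The chromosome count at the first generation after loss enters because
    the influx of new mutations is proportional to it; under constant N it is
    a common constant across trajectories.
    """
    if not np.isfinite(traj.logp_forward):
        return -np.inf
    n_loss = traj.pop_sizes[traj.age]
    return float(traj.logp_forward - traj.logp_backward + math.log(2.0 * n_loss))
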