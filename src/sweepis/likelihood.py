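"""Monte-Carlo likelihood of the selection coefficient and the allele-age
posterior.

For each s on a grid, M backward frequency trajectories are drawn and K
genealogy paths per trajectory; the likelihood is the double average of
trajectory weight times mean genealogy weight.  The noisy log-likelihood
curve is smoothed by a tricube-weighted local-polynomial regression, the MLE
is the argmax of the smoothed curve, and the confidence interval is the
profile-likelihood set at the chi-square(1) 95% cutoff (1.92 log-units).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from . import _kernels
from .ancestral_process import HaplotypeFrequencyModel
from .genealogy_is import run_genealogy
from .haplotype_coding import RecombinationMap, SampleConfiguration
from .wf_trajectory import Demography, SelectionModel, sample_trajectory, \
    trajectory_weight

__all__ = [
    "ModelInputs", "LikelihoodCurve", "AgePosterior",
    "estimate_loglik", "likelihood_curve", "mle_ci", "age_posterior",
    "local_polynomial_smooth",
]

PROFILE_CUTOFF_95 = 1.92  # chi-square(1)/2 at 95%


@dataclass
class ModelInputs:
    """Everything the Monte-Carlo likelihood needs besides s."""

    cfg0: SampleConfiguration
    rmap: RecombinationMap
    mutant_col: int
    demog: Demography
    theta: float
    x0: float
    t_max: int | None = None
    selected_donor: bool = True
    paper_hazard: bool = True

    @property
    def ne(self) -> float:
        return float(self.demog.size(0))

    @property
    def two_n0(self) -> int:
        return int(round(2.0 * self.ne))

    @property
    def mu(self) -> float:
        """Per-haplotype per-generation mutation rate implied by theta."""
        return self.theta / (4.0 * self.ne)

    @property
    def cc(self) -> float:
        """Whole-haplotype map length in Morgans."""
        return self.rmap.total_morgans

    @property
    def i0(self) -> int:
        return max(1, int(round(self.two_n0 * self.x0)))

    @property
    def t_cap(self) -> int:
        return self.t_max if self.t_max is not None else 4 * self.two_n0

    @property
    def constant_size(self) -> bool:
        return not self.demog.breakpoints and self.demog.growth_rate == 0.0


@dataclass
class MonteCarloRun:
    """Raw per-trajectory results for one value of s."""

    totals: np.ndarray          # log(traj weight * mean genealogy weight)
    ages: np.ndarray
    n_traj_rejected: int = 0
    n_paths_rejected: int = 0
    n_paths: int = 0


def _clock_from_counts(counts: np.ndarray, two_n: float) -> np.ndarray:
    """Escape clock C(t) = sum_{u=t+1}^{T-1} (1 - X_u)."""
    T = len(counts) - 1
    x = counts / two_n
    c = np.zeros(T + 1)
    if T >= 2:
        c[:T - 1] = np.cumsum((1.0 - x[1:T])[::-1])[::-1]
    return c


def _mc_run(s: float, inputs: ModelInputs, M: int, K: int, seed: int,
            use_kernel: bool = True) -> MonteCarloRun:
    sel = SelectionModel.additive(s)
    ss = np.random.SeedSequence([int(seed) % (2**31 - 1), 17])
    child_seeds = ss.generate_state(2 * M) % (2**31 - 1)
    totals = np.full(M, -np.inf)
    ages = np.zeros(M, dtype=np.int64)
    run = MonteCarloRun(totals, ages)
    run.n_paths = M * K

    d_left, d_right = inputs.rmap.flank_distances(inputs.mutant_col)
    packed = _kernels.pack_configuration(inputs.cfg0, d_left, d_right)
    two_n = inputs.two_n0

    use_kernel = use_kernel and inputs.constant_size
    rng = np.random.default_rng(ss)

    for m in range(M):
        if use_kernel:
            counts, lpb, lpf, ok = _kernels.sample_trajectory_kernel(
                inputs.i0, two_n, sel.s1, sel.s2, inputs.t_cap,
                int(child_seeds[2 * m]),
            )
            if not ok:
                run.n_traj_rejected += 1
                continue
            ages[m] = len(counts) - 1
            if not np.isfinite(lpf):
                continue
            logw_traj = lpf - lpb + math.log(float(two_n))
            clock = _clock_from_counts(counts, two_n)
            xfreq = counts / float(two_n)
            logw = _kernels.genealogy_batch(
                *packed, counts, xfreq, clock, d_left, d_right,
                inputs.mu, inputs.cc, K, int(child_seeds[2 * m + 1]),
                inputs.selected_donor, inputs.paper_hazard,
            )
        else:
            traj = sample_trajectory(inputs.i0, sel, inputs.demog, rng,
                                     t_max=inputs.t_cap)
            if traj is None:
                run.n_traj_rejected += 1
                continue
            ages[m] = traj.age
            logw_traj = trajectory_weight(traj)
            if not np.isfinite(logw_traj):
                continue
            fm = HaplotypeFrequencyModel(traj, inputs.rmap, inputs.mutant_col,
                                         selected_donor=inputs.selected_donor,
                                         paper_hazard=inputs.paper_hazard)
            logw = np.array([
                run_genealogy(inputs.cfg0, traj, fm, inputs.mu, inputs.cc,
                              rng).log_weight
                for _ in range(K)
            ])
        finite = np.isfinite(logw)
        run.n_paths_rejected += int(K - finite.sum())
        if finite.any():
            lg = logsumexp(logw[finite]) - math.log(K)
            totals[m] = logw_traj + lg
    return run


def _inverse_map_table(sel: SelectionModel, two_n: int) -> np.ndarray:
    """Pre-selection frequency y' with forward_map(y') = i/2N, for every
    copy number i (vectorised bisection)."""
    y = np.arange(two_n + 1) / two_n
    lo = np.zeros_like(y)
    hi = np.ones_like(y)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = np.asarray(sel.forward_map(mid)) < y
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    out = 0.5 * (lo + hi)
    out[0] = 0.0
    out[-1] = 1.0
    return out


def _path_log_binom(counts_from, counts_to, two_n: int, p: np.ndarray,
                    logc: np.ndarray) -> float:
    """sum_t log Binomial(counts_to[t]; 2N, p[t]) with cached log-binomial
    coefficients."""
    p = np.clip(p, 1e-15, 1 - 1e-15)
    return float(np.sum(
        logc[counts_to] + counts_to * np.log(p)
        + (two_n - counts_to) * np.log1p(-p)
    ))


def pooled_likelihood_curve_raw(s_grid, inputs: ModelInputs, M: int, K: int,
                                seed: int):
    """Raw log-likelihood over the grid from one shared trajectory pool.

    Each grid value anchors M backward trajectories; every trajectory is
    reweighted to every s by multiple importance sampling with the balance
    heuristic (the proposal is the equal mixture of the anchors' backward
    laws), and its mean genealogy weight — which depends on the trajectory
    only — is computed once and reused across the grid.  The whole curve
    therefore shares a single Monte-Carlo noise realisation, which removes
    most point-to-point jitter before smoothing.

    Returns ``(loglik, se, MonteCarloRun-like stats)``; constant population
    size only.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    G = len(s_grid)
    two_n = inputs.two_n0
    ss = np.random.SeedSequence([int(seed) % (2**31 - 1), 23])
    child = ss.generate_state(2 * G * M) % (2**31 - 1)
    d_left, d_right = inputs.rmap.flank_distances(inputs.mutant_col)
    packed = _kernels.pack_configuration(inputs.cfg0, d_left, d_right)

    logc = gammaln(two_n + 1) - gammaln(np.arange(two_n + 1) + 1) \
        - gammaln(two_n - np.arange(two_n + 1) + 1)
    inv_tabs = [_inverse_map_table(SelectionModel.additive(s), two_n)
                for s in s_grid]
    fwd_tabs = [np.asarray(SelectionModel.additive(s).forward_map(
        np.arange(two_n + 1) / two_n)) for s in s_grid]

    pool = []          # (counts, mean genealogy log-weight)
    n_rejected = 0
    idx = 0
    for a in range(G):
        sel = SelectionModel.additive(s_grid[a])
        for m in range(M):
            counts, lpb, lpf, ok = _kernels.sample_trajectory_kernel(
                inputs.i0, two_n, sel.s1, sel.s2, inputs.t_cap,
                int(child[idx]))
            idx += 2
            if not ok or not np.isfinite(lpf):
                n_rejected += 1
                continue
            clock = _clock_from_counts(counts, two_n)
            xfreq = counts / float(two_n)
            logw = _kernels.genealogy_batch(
                *packed, counts, xfreq, clock, d_left, d_right,
                inputs.mu, inputs.cc, K, int(child[idx - 1]),
                inputs.selected_donor, inputs.paper_hazard,
            )
            finite = np.isfinite(logw)
            if not finite.any():
                n_rejected += 1
                continue
            lg = logsumexp(logw[finite]) - math.log(K)
            pool.append((np.asarray(counts), lg))

    n_total = G * M
    loglik = np.full(G, -np.inf)
    se = np.full(G, np.nan)
    if not pool:
        return loglik, se, n_rejected

    # mixture backward log-probability of each pooled path
    log_mix = np.empty(len(pool))
    logpf = np.empty((G, len(pool)))
    for j, (counts, _) in enumerate(pool):
        frm = counts[:-1]
        to = counts[1:]
        lpb_a = np.array([
            _path_log_binom(frm, to, two_n, inv_tabs[a][frm], logc)
            for a in range(G)
        ])
        log_mix[j] = logsumexp(lpb_a) - math.log(G)
        body_from = counts[:-2]      # I_{t-1} for t = T-1 .. 1
        body_to = counts[1:-1]
        for a in range(G):
            logpf[a, j] = _path_log_binom(
                body_to, body_from, two_n, fwd_tabs[a][body_to], logc)

    lgs = np.array([lg for _, lg in pool])
    base = math.log(2.0 * inputs.ne)
    for a in range(G):
        lw = logpf[a] + base - log_mix + lgs
        mx = lw.max()
        w = np.exp(lw - mx)
        mean_w = w.sum() / n_total
        loglik[a] = mx + math.log(mean_w)
        if len(w) > 1:
            # delta-method SE including the zero-weight rejected samples
            var = (np.sum((w - mean_w) ** 2)
                   + (n_total - len(w)) * mean_w**2) / (n_total - 1)
            se[a] = math.sqrt(var / n_total) / mean_w
    return loglik, se, n_rejected


def estimate_loglik(s: float, inputs: ModelInputs, M: int, K: int,
                    seed: int, use_kernel: bool = True):
    """Monte-Carlo log-likelihood at one s with its standard error.

    Returns ``(loglik, se)``; -inf (with a warning) when every sampled path
    was rejected at this sampling effort.
    """
    if M < 1 or K < 1:
        raise ValueError("M and K must be at least 1")
    run = _mc_run(s, inputs, M, K, seed, use_kernel=use_kernel)
    totals = run.totals
    if not np.isfinite(totals).any():
        warnings.warn(f"all paths rejected at s={s}; -inf log-likelihood")
        return -np.inf, np.nan
    mx = totals.max()
    w = np.exp(totals - mx)
    loglik = mx + math.log(w.mean())
    if M > 1:
        se = w.std(ddof=1) / (w.mean() * math.sqrt(M))
    else:
        se = np.nan
    return float(loglik), float(se)


def local_polynomial_smooth(x, y, x_eval=None, bandwidth: float | None = None,
                            degree: int = 1, weights=None):
    """Local-polynomial regression with tricube kernel weights.

    ``bandwidth`` is an absolute half-width in the units of ``x`` (default:
    30% of the span).  Points with non-finite ``y`` are ignored.  At each
    evaluation point a degree-``degree`` polynomial is fitted by weighted
    least squares and its value at the point returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    xs, ys = x[keep], y[keep]
    if len(xs) < degree + 1:
        raise ValueError("not enough finite points to smooth")
    if bandwidth is None:
        bandwidth = 0.3 * (xs.max() - xs.min())
    if x_eval is None:
        x_eval = x
    x_eval = np.asarray(x_eval, dtype=float)
    base_w = np.ones_like(xs) if weights is None else np.asarray(weights)[keep]
    out = np.empty_like(x_eval)
    for i, x0 in enumerate(x_eval):
        u = np.abs(xs - x0) / bandwidth
        w = np.where(u < 1.0, (1.0 - u**3)**3, 0.0) * base_w
        if (w > 0).sum() < degree + 1:
            # widen to the nearest degree+1 points
            idx = np.argsort(np.abs(xs - x0))[:degree + 1]
            w = np.zeros_like(xs)
            w[idx] = 1.0
        coef = np.polynomial.polynomial.polyfit(xs - x0, ys, degree, w=np.sqrt(w))
        out[i] = coef[0]
    return out


@dataclass
class LikelihoodCurve:
    """Grid log-likelihood estimates with the smoothed curve and the MLE."""

    s_grid: np.ndarray
    loglik: np.ndarray
    se: np.ndarray
    smoothed: np.ndarray
    s_hat: float
    ci_low: float
    ci_high: float
    M: int
    K: int
    seed: int
    bandwidth_frac: float
    s_dense: np.ndarray = field(default=None, repr=False)
    smoothed_dense: np.ndarray = field(default=None, repr=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "s": self.s_grid,
            "loglik": self.loglik,
            "se": self.se,
            "smoothed": self.smoothed,
        })


def likelihood_curve(
    s_grid,
    inputs: ModelInputs,
    M: int = 1000,
    K: int = 100,
    seed: int = 0,
    bandwidth_frac: float = 0.3,
    common_random_numbers: bool = True,
    use_kernel: bool = True,
    n_dense: int = 400,
) -> LikelihoodCurve:
    """Estimate, smooth and maximise the log-likelihood over a grid of s.

    With common random numbers (default, constant population size) a single
    trajectory pool anchored at the grid values is shared across every s by
    multiple importance sampling, so the Monte-Carlo noise is common to the
    whole curve; otherwise each grid point is estimated independently.
    Smoothing is performed on log10(s) with a tricube local-linear fit whose
    bandwidth is ``bandwidth_frac`` of the grid span.
    """
    s_grid = np.asarray(sorted(s_grid), dtype=float)
    if len(s_grid) < 5:
        raise ValueError("grid needs at least 5 points")
    pooled = common_random_numbers and use_kernel and inputs.constant_size
    if pooled:
        raw, se, _ = pooled_likelihood_curve_raw(s_grid, inputs, M, K, seed)
    else:
        raw = np.empty_like(s_grid)
        se = np.empty_like(s_grid)
        for i, s in enumerate(s_grid):
            pt_seed = seed if common_random_numbers else seed + 7919 * (i + 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw[i], se[i] = estimate_loglik(s, inputs, M, K, pt_seed,
                                                use_kernel=use_kernel)
    lx = np.log10(s_grid)
    bandwidth = bandwidth_frac * (lx.max() - lx.min())
    smoothed = local_polynomial_smooth(lx, raw, bandwidth=bandwidth)
    lx_dense = np.linspace(lx.min(), lx.max(), n_dense)
    sm_dense = local_polynomial_smooth(lx, raw, x_eval=lx_dense,
                                       bandwidth=bandwidth)
    s_hat = float(10 ** lx_dense[np.argmax(sm_dense)])
    curve = LikelihoodCurve(
        s_grid=s_grid, loglik=raw, se=se, smoothed=smoothed,
        s_hat=s_hat, ci_low=np.nan, ci_high=np.nan,
        M=M, K=K, seed=seed, bandwidth_frac=bandwidth_frac,
        s_dense=10 ** lx_dense, smoothed_dense=sm_dense,
    )
    curve.ci_low, curve.ci_high = mle_ci(curve)[1:]
    return curve


def mle_ci(curve: LikelihoodCurve, level: float = 0.95):
    """Profile-likelihood interval {s : l(s_hat) - l(s) <= cutoff}.

    The 95% cutoff is 1.92 log-units (half the chi-square(1) quantile);
    endpoints are linearly interpolated on the dense smoothed curve and
    clamped to the grid with a warning when the curve does not drop below
    the cutoff inside the grid.
    """
    if level != 0.95:
        from scipy.stats import chi2

        cutoff = 0.5 * chi2.ppf(level, df=1)
    else:
        cutoff = PROFILE_CUTOFF_95
    s = curve.s_dense
    ll = curve.smoothed_dense
    imax = int(np.argmax(ll))
    drop = ll[imax] - ll

    def _cross(indices, edge):
        """First crossing of the cutoff walking away from the peak."""
        for i in indices:
            if drop[i] > cutoff:
                prev = i + 1 if i < imax else i - 1
                if drop[i] == drop[prev]:
                    return float(s[i]), False
                f = (cutoff - drop[prev]) / (drop[i] - drop[prev])
                return float(s[prev] + f * (s[i] - s[prev])), False
        return float(edge), True

    lo, clamped_lo = _cross(range(imax - 1, -1, -1), s[0])
    hi, clamped_hi = _cross(range(imax + 1, len(s)), s[-1])
    if clamped_lo or clamped_hi:
        warnings.warn("profile CI endpoint clamped to the grid edge")
    return float(curve.s_hat), float(lo), float(hi)


@dataclass
class AgePosterior:
    """Weighted allele-age samples at the fitted s."""

    ages: np.ndarray
    weights: np.ndarray
    s_hat: float

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.ages))

    @property
    def mode(self) -> float:
        return float(self.ages[np.argmax(self.weights)])

    def quantile(self, q):
        order = np.argsort(self.ages)
        cw = np.cumsum(self.weights[order])
        return np.interp(np.atleast_1d(q), cw, self.ages[order])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age": self.ages, "weight": self.weights})


def age_posterior(s_hat: float, inputs: ModelInputs, M: int = 1000,
                  K: int = 100, seed: int = 0,
                  use_kernel: bool = True) -> AgePosterior:
    """Posterior of the allele age T from the trajectory/genealogy weights at
    s = s_hat: each sampled trajectory's age enters with weight proportional
    to its trajectory weight times its mean genealogy weight."""
    run = _mc_run(s_hat, inputs, M, K, seed, use_kernel=use_kernel)
    finite = np.isfinite(run.totals)
    if not finite.any():
        raise RuntimeError("zero total weight: no accepted paths at s_hat")
    totals = run.totals[finite]
    ages = run.ages[finite]
    w = np.exp(totals - totals.max())
    w /= w.sum()
    return AgePosterior(ages=ages, weights=w, s_hat=float(s_hat))
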