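"""Model/Results interface for sweep inference.

``SelectiveSweepModel`` bundles the coded sample configuration, genetic map
and population model; ``fit`` runs the importance-sampling likelihood over a
grid of selection coefficients and returns a ``SweepFitResults`` carrying the
MLE, its profile-likelihood interval, the smoothed curve and diagnostics,
with ``summary()``, ``age_posterior()`` and plotting attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotype_coding import (
    RecombinationMap,
    SampleConfiguration,
    SelectedHaplotypeMatrix,
    encode_sample,
)
from .likelihood import (
    AgePosterior,
    LikelihoodCurve,
    ModelInputs,
    age_posterior,
    likelihood_curve,
)
from .wf_trajectory import Demography

__all__ = ["SelectiveSweepModel", "SweepFitResults"]


class SelectiveSweepModel:
    """Likelihood model for the intensity of an ongoing selective sweep.

    Parameters
    ----------
    matrix : SelectedHaplotypeMatrix
        Phased selected haplotypes with their ancestral-segment annotation.
    rmap : RecombinationMap
        Genetic map covering the same SNPs.
    x0 : float
        Present-day population frequency of the selected allele.
    theta : float
        Scaled mutation rate 4 N_e mu of the whole haplotype (0 when no new
        mutations are observed on the ancestral segments).
    demography : Demography, optional
        Defaults to a constant size of 10,000 diploids; pass
        ``Demography(N0, x_linked=True)`` for X-linked loci.
    """

    def __init__(self, matrix: SelectedHaplotypeMatrix | None, rmap,
                 *, x0: float, theta: float = 0.0,
                 demography: Demography | None = None,
                 configuration: SampleConfiguration | None = None,
                 mutant_col: int | None = None,
                 t_max: int | None = None):
        if matrix is None and configuration is None:
            raise ValueError("need a haplotype matrix or a coded configuration")
        self.matrix = matrix
        self.rmap = rmap
        if matrix is not None:
            self.configuration = encode_sample(matrix)
            self.mutant_col = matrix.mutant_col
        else:
            self.configuration = configuration
            if mutant_col is None:
                raise ValueError("mutant_col required with a bare configuration")
            self.mutant_col = mutant_col
        self.demography = demography or Demography(N0=10_000.0)
        self.x0 = float(x0)
        self.theta = float(theta)
        self.inputs = ModelInputs(
            cfg0=self.configuration, rmap=rmap, mutant_col=self.mutant_col,
            demog=self.demography, theta=self.theta, x0=self.x0, t_max=t_max,
        )

    @classmethod
    def from_configuration(cls, configuration, rmap, mutant_col, **kwargs):
        """Build directly from a coded configuration (e.g. a published table)."""
        return cls(None, rmap, configuration=configuration,
                   mutant_col=mutant_col, **kwargs)

    def default_grid(self, s_min: float, s_max: float, n: int = 25):
        return np.geomspace(s_min, s_max, n)

    def fit(self, s_grid=None, *, s_min: float = 0.005, s_max: float = 0.15,
            grid_size: int = 25, M: int = 1000, K: int = 100, seed: int = 0,
            bandwidth_frac: float = 0.3, common_random_numbers: bool = True,
            use_kernel: bool = True) -> "SweepFitResults":
        """Estimate the likelihood curve and the MLE of s.

        M trajectories and K genealogies per trajectory are sampled at each
        of the grid points (log-spaced by default between ``s_min`` and
        ``s_max``).
        """
        if s_grid is None:
            s_grid = self.default_grid(s_min, s_max, grid_size)
        curve = likelihood_curve(
            s_grid, self.inputs, M=M, K=K, seed=seed,
            bandwidth_frac=bandwidth_frac,
            common_random_numbers=common_random_numbers,
            use_kernel=use_kernel,
        )
        return SweepFitResults(model=self, curve=curve, seed=seed)


@dataclass
class SweepFitResults:
    """Fitted sweep model: point estimate, interval and diagnostics."""

    model: SelectiveSweepModel
    curve: LikelihoodCurve
    seed: int
    _age: AgePosterior | None = field(default=None, repr=False)

    @property
    def s_hat(self) -> float:
        return self.curve.s_hat

    @property
    def conf_int(self):
        return (self.curve.ci_low, self.curve.ci_high)

    def age_posterior(self, M: int | None = None, K: int | None = None,
                      seed: int | None = None) -> AgePosterior:
        """Allele-age posterior from repeated trajectory samples at s_hat."""
        self._age = age_posterior(
            self.s_hat, self.model.inputs,
            M=M or self.curve.M, K=K or self.curve.K,
            seed=self.seed if seed is None else seed,
        )
        return self._age

    def summary(self) -> str:
        c = self.curve
        n = self.model.configuration.n_lineages
        d = self.model.configuration.n_types
        lines = [
            "Selective sweep inference (importance-sampling likelihood)",
            "=" * 60,
            f"selected haplotypes:        n = {n} in {d} distinct types",
            f"scaled mutation rate theta: {self.model.theta:g}",
            f"map length:                 {self.model.inputs.cc * 100:.4f} cM",
            f"present-day frequency x0:   {self.model.x0:.4f}",
            f"effective size N_e:         {self.model.inputs.ne:,.0f}",
            f"grid: {len(c.s_grid)} points in [{c.s_grid[0]:g}, {c.s_grid[-1]:g}]"
            f"  M = {c.M}, K = {c.K}, seed = {c.seed}",
            "-" * 60,
            f"s_hat (MLE):                {c.s_hat:.4f}",
            f"95% profile interval:       ({c.ci_low:.4f}, {c.ci_high:.4f})",
        ]
        if self._age is not None:
            q = self._age.quantile([0.025, 0.5, 0.975])
            lines += [
                f"allele age posterior mean:  {self._age.mean:,.0f} generations",
                f"          2.5/50/97.5%:     {q[0]:,.0f} / {q[1]:,.0f} / {q[2]:,.0f}",
            ]
        return "\n".join(lines)

    def plot_likelihood(self, ax=None):
        """Raw estimates with Monte-Carlo error bars and the smoothed curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.errorbar(c.s_grid, c.loglik, yerr=c.se, fmt="o", ms=4,
                    alpha=0.6, label="raw MC estimate")
        ax.plot(c.s_dense, c.smoothed_dense, "-", label="smoothed")
        ax.axvline(c.s_hat, ls="--", color="k", lw=0.8)
        ax.axvspan(c.ci_low, c.ci_high, alpha=0.1, color="k")
        ax.set_xscale("log")
        ax.set_xlabel("selection coefficient s")
        ax.set_ylabel("log-likelihood")
        ax.legend()
        return ax
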