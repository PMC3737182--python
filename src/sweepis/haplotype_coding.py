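"""Haplotype coding for the simplified multilocus sweep model.

A sample of phased haplotypes carrying a positively selected mutant is reduced
to a small summary per chromosome: the contiguous block of sites still
descended from the *ancestral haplotype* (the chromosome on which the selected
mutation arose) is recorded by two *recombination coordinates* — the number of
SNPs retained on each side of the selected site — plus the positions of any
new mutations that arose on the retained block during the sweep (*mutation
coordinates*).  Identical codes are grouped with multiplicities into a sample
configuration, the state of the backward-in-time ancestral process.

Coordinates are 0-based internally; file I/O is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RecombinationMap",
    "CodedHaplotype",
    "SelectedHaplotypeMatrix",
    "SampleConfiguration",
    "encode_sample",
    "shift_first_mutation",
    "coordinate_change",
    "remove_type",
    "ancestral_fraction",
]


@dataclass(frozen=True)
class RecombinationMap:
    """Genetic map over the analysed SNPs.

    Parameters
    ----------
    positions : array of int
        Physical coordinates (bp), strictly increasing, one per SNP.
    genetic_pos : array of float
        Cumulative map position in centimorgans, non-decreasing, one per SNP.

    Recombination fractions between sites are taken linear in map distance
    (Morgans), which is the first-order (no-interference, no-double-crossover)
    approximation appropriate for the sub-centimorgan scales of sweep data.
    """

    positions: np.ndarray
    genetic_pos: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        gen = np.asarray(self.genetic_pos, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "genetic_pos", gen)
        if pos.ndim != 1 or gen.shape != pos.shape:
            raise ValueError("positions and genetic_pos must be 1-D and equal length")
        if len(pos) < 2:
            raise ValueError("a map needs at least two SNPs")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("physical positions must be strictly increasing")
        if np.any(np.diff(gen) < 0):
            raise ValueError("genetic map positions must be non-decreasing")

    @classmethod
    def uniform(cls, positions, rate_cm_per_mb: float) -> "RecombinationMap":
        """Constant-rate map: ``rate_cm_per_mb`` over the given bp positions."""
        pos = np.asarray(positions, dtype=np.int64)
        gen = (pos - pos[0]) * rate_cm_per_mb * 1e-6
        return cls(pos, gen)

    @property
    def total_morgans(self) -> float:
        """Map length of the whole analysed region in Morgans."""
        return float(self.genetic_pos[-1] - self.genetic_pos[0]) / 100.0

    def fraction_between(self, j1: int, j2: int) -> float:
        """Recombination fraction between SNP ``j1`` and SNP ``j2``.

        Zero between identical loci, additive over adjacent intervals to
        first order (Morgans difference).
        """
        return abs(float(self.genetic_pos[j2] - self.genetic_pos[j1])) / 100.0

    def flank_distances(self, mutant_col: int):
        """Cumulative Morgans from the selected site out to each flanking SNP.

        Returns ``(d_left, d_right)`` with ``d_left[k]`` the distance from the
        mutant to the SNP ``k`` places to its left (``d_left[0] = 0``), and
        similarly to the right.
        """
        g = self.genetic_pos / 100.0
        c = mutant_col
        d_left = g[c] - g[c::-1]  # length m_L + 1
        d_right = g[c:] - g[c]    # length m_R + 1
        return np.asarray(d_left, dtype=float), np.asarray(d_right, dtype=float)


@dataclass(frozen=True, order=True)
class CodedHaplotype:
    """One selected haplotype reduced to its ancestral-segment summary.

    ``r1``/``r2`` count the SNPs retained from the ancestral haplotype to the
    left/right of the selected site; ``muts`` holds absolute SNP column
    indices (0-based) inside that block carrying a non-ancestral allele,
    most recent first.
    """

    r1: int
    r2: int
    muts: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "muts", tuple(int(p) for p in self.muts))
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("recombination coordinates must be non-negative")
        if len(set(self.muts)) != len(self.muts):
            raise ValueError("mutation coordinates must be distinct")

    @property
    def n_mut(self) -> int:
        return len(self.muts)

    def in_segment(self, col: int, mutant_col: int) -> bool:
        return mutant_col - self.r1 <= col <= mutant_col + self.r2

    def __str__(self):  # match the field's "(R1, R2, M1, ...)" notation
        parts = [str(self.r1), str(self.r2)] + [str(p) for p in self.muts]
        return "(" + ", ".join(parts) + ")"


@dataclass
class SelectedHaplotypeMatrix:
    """Binary allele matrix of the selected haplotypes with ancestry annotation.

    Rows are chromosomes carrying the selected allele, columns are SNPs.
    ``ancestral_mask[i, j]`` is True where the allele of row ``i`` at SNP
    ``j`` descends from the ancestral haplotype.  The mask of each row must be
    a single contiguous block containing the selected site: double
    cross-overs back into the ancestral state are excluded by the model, so
    non-contiguous masks are rejected rather than truncated.

    ``ancestral_alleles`` optionally gives the allelic state of the ancestral
    haplotype per column; when absent it is taken as the per-column majority
    among masked entries (ties resolved toward allele 1, the convention used
    for the selected site itself).
    """

    alleles: np.ndarray
    mutant_col: int
    ancestral_mask: np.ndarray
    positions: np.ndarray
    ancestral_alleles: np.ndarray | None = None

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.ancestral_mask = np.asarray(self.ancestral_mask, dtype=bool)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n, m = self.alleles.shape
        if self.ancestral_mask.shape != (n, m):
            raise ValueError("ancestral_mask shape must match alleles")
        if self.positions.shape != (m,):
            raise ValueError("positions must have one entry per SNP column")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("SNP positions must be strictly increasing")
        if not 0 <= self.mutant_col < m:
            raise ValueError("mutant_col out of range")
        if not np.all(self.ancestral_mask[:, self.mutant_col]):
            raise ValueError(
                "every selected haplotype must be ancestral at the selected site"
            )
        for i in range(n):
            idx = np.flatnonzero(self.ancestral_mask[i])
            if len(idx) != idx[-1] - idx[0] + 1:
                raise ValueError(
                    f"row {i}: ancestral mask is not a single contiguous block "
                    "(double cross-overs are outside the model)"
                )

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def m_left(self) -> int:
        """SNP count left of the selected site."""
        return self.mutant_col

    @property
    def m_right(self) -> int:
        return self.n_snps - self.mutant_col - 1

    def resolved_ancestral_alleles(self) -> np.ndarray:
        if self.ancestral_alleles is not None:
            return np.asarray(self.ancestral_alleles, dtype=np.int8)
        anc = np.zeros(self.n_snps, dtype=np.int8)
        for j in range(self.n_snps):
            masked = self.alleles[self.ancestral_mask[:, j], j]
            if masked.size == 0 or 2 * masked.sum() >= masked.size:
                anc[j] = 1
            else:
                anc[j] = 0
        return anc


@dataclass
class SampleConfiguration:
    """Distinct coded haplotypes with multiplicities: the state (T, n)."""

    types: list
    mult: np.ndarray

    def __post_init__(self):
        self.mult = np.asarray(self.mult, dtype=np.int64).reshape(-1)
        if len(self.types) != len(self.mult):
            raise ValueError("types and multiplicities differ in length")
        if np.any(self.mult < 1):
            raise ValueError("zero-multiplicity types must be dropped")
        if len(set(self.types)) != len(self.types):
            raise ValueError("types must be pairwise distinct")

    @property
    def n_types(self) -> int:
        return len(self.types)

    @property
    def n_lineages(self) -> int:
        return int(self.mult.sum())

    def index_of(self, h: CodedHaplotype):
        try:
            return self.types.index(h)
        except ValueError:
            return None

    def as_key(self):
        """Canonical hashable form (order-independent)."""
        return frozenset(
            (h.r1, h.r2, h.muts, int(n)) for h, n in zip(self.types, self.mult)
        )

    def is_absorbed(self, founder: CodedHaplotype) -> bool:
        return self.n_types == 1 and self.mult[0] == 1 and self.types[0] == founder

    def replace_counts(self, changes: dict) -> "SampleConfiguration":
        """Return a new configuration with multiplicities adjusted.

        ``changes`` maps CodedHaplotype -> increment (possibly for new types);
        types whose multiplicity reaches zero are dropped; new types are
        appended in encounter order.
        """
        types = list(self.types)
        mult = list(self.mult)
        for h, delta in changes.items():
            i = types.index(h) if h in types else None
            if i is None:
                if delta <= 0:
                    raise ValueError("cannot decrement an absent type")
                types.append(h)
                mult.append(delta)
            else:
                mult[i] += delta
        keep = [i for i, n in enumerate(mult) if n > 0]
        if any(n < 0 for n in mult):
            raise ValueError("multiplicity went negative")
        return SampleConfiguration([types[i] for i in keep], [mult[i] for i in keep])

    def __str__(self):
        return "{" + ", ".join(
            f"{h}:{n}" for h, n in zip(self.types, self.mult)
        ) + "}"


def founder_haplotype(m_left: int, m_right: int) -> CodedHaplotype:
    """The intact ancestral haplotype: full extent, no mutations."""
    return CodedHaplotype(m_left, m_right, ())


def _mutation_order(muts_per_row: list, n_rows: int) -> dict:
    """Order mutation coordinates most-recent (innermost of the nesting) first.

    Under infinitely-many-sites the carriers of a more recent mutation are a
    subset of the carriers of any older mutation on the same lineage path, so
    smaller carrier sets come first; ties break by SNP position.
    """
    carriers: dict[int, int] = {}
    for muts in muts_per_row:
        for p in muts:
            carriers[p] = carriers.get(p, 0) + 1
    return {p: (carriers[p], p) for p in carriers}


def encode_sample(matrix: SelectedHaplotypeMatrix) -> SampleConfiguration:
    """Code each selected haplotype and group identical codes.

    Each row becomes ``(R1, R2, M...)`` where R1/R2 count the contiguous
    ancestral SNPs left/right of the selected site and M lists the columns in
    that block whose allele differs from the ancestral haplotype.  Group order
    follows first occurrence.
    """
    c = matrix.mutant_col
    anc = matrix.resolved_ancestral_alleles()
    raw_muts = []
    extents = []
    for i in range(matrix.n_haplotypes):
        idx = np.flatnonzero(matrix.ancestral_mask[i])
        lo, hi = idx[0], idx[-1]
        r1, r2 = c - lo, hi - c
        mut_cols = [
            j for j in range(lo, hi + 1)
            if j != c and matrix.alleles[i, j] != anc[j]
        ]
        extents.append((r1, r2))
        raw_muts.append(mut_cols)

    order = _mutation_order(raw_muts, matrix.n_haplotypes)
    types: list[CodedHaplotype] = []
    mult: list[int] = []
    for (r1, r2), mut_cols in zip(extents, raw_muts):
        muts = tuple(sorted(mut_cols, key=lambda p: order[p]))
        h = CodedHaplotype(r1, r2, muts)
        if h in types:
            mult[types.index(h)] += 1
        else:
            types.append(h)
            mult.append(1)
    return SampleConfiguration(types, mult)


def shift_first_mutation(h: CodedHaplotype) -> CodedHaplotype:
    """Operator S: drop the most recent mutation coordinate."""
    if not h.muts:
        raise ValueError("haplotype has no mutation coordinate to shift")
    return replace(h, muts=h.muts[1:])


def coordinate_change(
    h: CodedHaplotype, side: str, new_r: int, *, mutant_col: int
) -> CodedHaplotype:
    """Operator C: set one recombination coordinate, dropping mutations that
    fall outside the new ancestral region."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if new_r < 0:
        raise ValueError("coordinate must be non-negative")
    r1, r2 = (new_r, h.r2) if side == "left" else (h.r1, new_r)
    kept = tuple(
        p for p in h.muts if mutant_col - r1 <= p <= mutant_col + r2
    )
    return CodedHaplotype(r1, r2, kept)


def remove_type(cfg: SampleConfiguration, k: int) -> SampleConfiguration:
    """Operator R_k: delete type ``k`` and its multiplicity."""
    if not 0 <= k < cfg.n_types:
        raise IndexError("type index out of range")
    types = [h for i, h in enumerate(cfg.types) if i != k]
    mult = [int(n) for i, n in enumerate(cfg.mult) if i != k]
    return SampleConfiguration(types, mult)


def ancestral_fraction(
    h: CodedHaplotype, rmap: RecombinationMap, *, mutant_col: int
) -> float:
    """Ancestral fraction β: genetic length of the retained segment over the
    genetic length of the whole analysed haplotype."""
    g = rmap.genetic_pos
    total = float(g[-1] - g[0])
    if total <= 0:
        raise ValueError("map has zero genetic length")
    lo = mutant_col - h.r1
    hi = mutant_col + h.r2
    if lo < 0 or hi >= len(g):
        raise ValueError("coded extent falls outside the map")
    return float(g[hi] - g[lo]) / total


def decode_configuration(
    cfg: SampleConfiguration, m: int, mutant_col: int
) -> SelectedHaplotypeMatrix:
    """Rebuild a minimal allele matrix realising a coded configuration.

    Uses the all-ones ancestral haplotype and zeros elsewhere; mutated sites
    flip to 0 inside the block.  Round-tripping through
    :func:`encode_sample` recovers ``cfg``.
    """
    rows, masks = [], []
    for h, n in zip(cfg.types, cfg.mult):
        allele = np.zeros(m, dtype=np.int8)
        mask = np.zeros(m, dtype=bool)
        lo, hi = mutant_col - h.r1, mutant_col + h.r2
        mask[lo:hi + 1] = True
        allele[lo:hi + 1] = 1
        for p in h.muts:
            allele[p] = 0
        for _ in range(int(n)):
            rows.append(allele.copy())
            masks.append(mask.copy())
    positions = np.arange(1, m + 1) * 1000
    return SelectedHaplotypeMatrix(
        np.array(rows), mutant_col, np.array(masks), positions,
        ancestral_alleles=np.ones(m, dtype=np.int8),
    )
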