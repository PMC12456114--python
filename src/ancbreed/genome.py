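"""Haplotype-resolved genomes and simulated meiosis.

A generation of diploid individuals is carried as three aligned ``N x 2 x L``
arrays: the genotype panel ``G`` (0 reference / 1 alternate allele), the local
ancestry panel ``A`` (1 = target population, 0 = introgressed) and the founder
panel ``F`` giving, for every locus of every haplotype, the founder haplotype
it descends from.  All three are propagated jointly through meiosis, so
identity-by-descent, local ancestry and genotypes stay mutually consistent by
construction.

Meiosis is a crossover process without interference on a genetic map measured
in Morgans: a gamete inherits alternating segments of the two parental
haplotype copies, with segment lengths drawn i.i.d. Exponential(1) Morgans, so
the crossover count per gamete is Poisson with mean the map length ``D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeMap",
    "Panel",
    "Gamete",
    "simulate_gamete",
    "simulate_gamete_indices",
    "make_offspring",
    "founder_labels",
]


@dataclass(frozen=True)
class GenomeMap:
    """A single chromosome described purely by its genetic map.

    Parameters
    ----------
    L : int
        Number of SNPs observed along the chromosome.
    D : float
        Genetic length in Morgans.
    positions : ndarray of shape (L,), optional
        Map position of each SNP in (0, D], strictly increasing.  Defaults to
        even spacing ``R_l = l * D / L`` for ``l = 1..L``.
    """

    L: int
    D: float
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("L must be non-negative")
        if self.D <= 0:
            raise ValueError("genetic length D must be positive (Morgans)")
        if self.positions is None:
            pos = np.arange(1, self.L + 1, dtype=float) * (self.D / self.L) if self.L else np.empty(0)
            object.__setattr__(self, "positions", pos)
        else:
            pos = np.asarray(self.positions, dtype=float)
            if pos.shape != (self.L,):
                raise ValueError(f"positions must have shape ({self.L},)")
            if self.L and (np.any(np.diff(pos) <= 0) or pos[0] <= 0 or pos[-1] > self.D):
                raise ValueError("positions must be strictly increasing within (0, D]")
            object.__setattr__(self, "positions", pos)


def founder_labels(n: int) -> np.ndarray:
    """Unique founder-haplotype labels for ``n`` diploid founders.

    Individual ``i`` (1-based) receives labels ``2i - 1`` and ``2i`` on its
    first and second haplotype copy, so every founder haplotype carries a
    distinct label in ``{1 .. 2n}`` and no founder is self-identical.
    """
    lab = np.empty((n, 2), dtype=np.int32)
    lab[:, 0] = 2 * np.arange(1, n + 1) - 1
    lab[:, 1] = 2 * np.arange(1, n + 1)
    return lab


@dataclass
class Panel:
    """One generation of diploid individuals with aligned tracks.

    Attributes
    ----------
    t : int
        Generation index (0 = founders of the breeding program).
    G, A : ndarray of shape (N, 2, L), uint8
        Binary genotype and local-ancestry tracks.
    F : ndarray of shape (N, 2, L), int32
        Founder-haplotype labels.
    """

    t: int
    G: np.ndarray
    A: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.ascontiguousarray(self.G, dtype=np.uint8)
        self.A = np.ascontiguousarray(self.A, dtype=np.uint8)
        self.F = np.ascontiguousarray(self.F, dtype=np.int32)
        if not (self.G.shape == self.A.shape == self.F.shape):
            raise ValueError("G, A, F must share identical (N, 2, L) shapes")
        if self.G.ndim != 3 or self.G.shape[1] != 2:
            raise ValueError("panel arrays must have shape (N, 2, L)")
        if self.N < 1:
            raise ValueError("a panel holds at least one individual")
        if self.t < 0:
            raise ValueError("generation index must be non-negative")
        if np.any(self.G > 1) or np.any(self.A > 1):
            raise ValueError("G and A must be binary")

    @property
    def N(self) -> int:
        return self.G.shape[0]

    @property
    def L(self) -> int:
        return self.G.shape[2]

    def reset_founders(self) -> "Panel":
        """Return a copy declared as generation 0 with fresh founder labels."""
        F = np.repeat(founder_labels(self.N)[:, :, None], self.L, axis=2)
        return Panel(t=0, G=self.G.copy(), A=self.A.copy(), F=F)

    def subset(self, indices: np.ndarray) -> "Panel":
        idx = np.asarray(indices)
        return Panel(t=self.t, G=self.G[idx], A=self.A[idx], F=self.F[idx])

    def target_fraction(self) -> np.ndarray:
        """Per-individual genome-wide target-ancestry dose, shape (N,)."""
        return self.A.mean(axis=(1, 2))

    def haplotype_target_fraction(self) -> np.ndarray:
        """Per-haplotype target-ancestry fraction, shape (2N,)."""
        return self.A.mean(axis=2).ravel()


@dataclass
class Gamete:
    """A single recombined gamete.

    ``a`` records, per SNP, which parental copy (1 or 2) was inherited; the
    ``g``, ``anc`` and ``f`` tracks are the corresponding slices of the
    parent's G, A and F rows, all taken with the same inheritance vector.
    """

    a: np.ndarray
    g: np.ndarray
    anc: np.ndarray
    f: np.ndarray


def simulate_gamete_indices(genome_map: GenomeMap, rng) -> np.ndarray:
    """Draw the inheritance vector ``a`` of one gamete.

    The crossover process starts at map position 0 on a copy drawn by
    ``rng.integers(1, 3)`` and lays down segments of length
    ``rng.exponential()`` Morgans, switching copy at every breakpoint, until a
    segment end passes the last SNP.  The rng is consumed in exactly that
    order (one ``integers`` call, then one ``exponential`` call per segment),
    which makes the process scriptable in tests.
    """
    L = genome_map.L
    a = np.empty(L, dtype=np.int8)
    if L == 0:
        return a
    pos = genome_map.positions
    last = pos[-1]
    h = int(rng.integers(1, 3))
    p = 0.0
    while True:
        e = p + float(rng.exponential())
        lo = np.searchsorted(pos, p, side="left")
        hi = np.searchsorted(pos, e, side="left")
        a[lo:hi] = h
        h = 3 - h
        p = e
        if p > last:
            break
    return a


def simulate_gamete(genome_map: GenomeMap, rng) -> np.ndarray:
    """Alias of :func:`simulate_gamete_indices` (returns the vector ``a``)."""
    return simulate_gamete_indices(genome_map, rng)


def _gamete_tracks(panel: Panel, parent: int, genome_map: GenomeMap, rng) -> Gamete:
    a = simulate_gamete_indices(genome_map, rng)
    sel = a - 1  # 0-based copy index per SNP
    cols = np.arange(panel.L)
    return Gamete(
        a=a,
        g=panel.G[parent, sel, cols],
        anc=panel.A[parent, sel, cols],
        f=panel.F[parent, sel, cols],
    )


def make_offspring(
    panel: Panel,
    parent_i: int,
    parent_j: int,
    genome_map: GenomeMap,
    rng,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Produce one child's ``(G, A, F)`` rows, each of shape (2, L).

    Haplotype 1 of the child is a gamete of ``parent_i`` and haplotype 2 a
    gamete of ``parent_j``; the same inheritance vector drives all three
    tracks of a gamete, so ancestry and founder labels remain consistent with
    the genotypes.  Self-mating is rejected.
    """
    if parent_i == parent_j:
        raise ValueError("self-mating is not allowed (parent_i == parent_j)")
    gi = _gamete_tracks(panel, parent_i, genome_map, rng)
    gj = _gamete_tracks(panel, parent_j, genome_map, rng)
    g = np.stack([gi.g, gj.g])
    a = np.stack([gi.anc, gj.anc])
    f = np.stack([gi.f, gj.f])
    return g, a, f


def breed_generation(
    panel: Panel,
    pairs: np.ndarray,
    genome_map: GenomeMap,
    rng,
) -> Panel:
    """Breed one child per row of ``pairs`` (shape (n, 2) of parent indices)."""
    n = len(pairs)
    G = np.empty((n, 2, panel.L), dtype=np.uint8)
    A = np.empty_like(G)
    F = np.empty((n, 2, panel.L), dtype=np.int32)
    for k, (i, j) in enumerate(pairs):
        G[k], A[k], F[k] = make_offspring(panel, int(i), int(j), genome_map, rng)
    return Panel(t=panel.t + 1, G=G, A=A, F=F)


def random_mating_pairs(n_parents: int, n_children: int, rng) -> np.ndarray:
    """Wright-Fisher pair draws: two distinct uniform parents per child."""
    if n_parents < 2:
        raise ValueError("random mating needs at least two parents")
    p1 = rng.integers(0, n_parents, size=n_children)
    p2 = rng.integers(0, n_parents - 1, size=n_children)
    p2 = np.where(p2 >= p1, p2 + 1, p2)  # skip self
    return np.column_stack([p1, p2])
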