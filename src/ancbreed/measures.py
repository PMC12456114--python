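"""Selection measures over pairs of individuals and realized scores.

Seven measures are defined per locus and averaged along the genome.  For a
candidate pair (i, j) the *expected* measure averages the four equiprobable
haplotype transmissions (a, b) of a potential offspring:

=====  ==============================================================  =========
id     per-locus kernel                                                direction
=====  ==============================================================  =========
K      1/4 * sum_ab I(F_ia = F_jb)                                     minimize
H      1/4 * sum_ab I(G_ia != G_jb)                                    maximize
Q      1/8 * sum_ab (A_ia + A_jb)                                      maximize
PH     1/4 * sum_ab I(A_ia + A_jb = 2) * I(G_ia != G_jb)               maximize
PK     1 - 1/4 * sum_ab I(A_ia + A_jb = 2) * I(F_ia != F_jb)           minimize
WPH    1/8 * sum_ab [(1-d)(A_ia + A_jb) + 2d I(A=2) I(G_ia != G_jb)]   maximize
WPK    1/8 * sum_ab [(1-d)(2-A_ia-A_jb) + 2d (1 - I(A=2) I(F != F))]   minimize
=====  ==============================================================  =========

PH and PK are the "population" forms: loci whose copies are not both of
target ancestry are masked out, counting as heterozygosity 0 and kinship 1,
so only diversity of target-population material is rewarded.  The weighted
forms trade the masked diversity term (weight ``delta``) against the plain
ancestry dose (weight ``1 - delta``); WPH at delta = 0 reduces to Q and at
delta = 1 to PH, and likewise WPK spans 1 - Q to PK.

Realized population scores use the same per-locus quantities evaluated on an
individual's own two copies, averaged over loci and individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .genome import Panel

__all__ = [
    "MEASURE_IDS",
    "MAXIMIZED",
    "MINIMIZED",
    "MeasureSpec",
    "PairwiseMatrix",
    "ScoreReport",
    "per_locus_pair_measure",
    "expected_pair_matrix",
    "realized_scores",
    "realized_wph_locus",
]

MAXIMIZED = frozenset({"H", "Q", "PH", "WPH"})
MINIMIZED = frozenset({"K", "PK", "WPK"})
MEASURE_IDS = tuple(sorted(MAXIMIZED | MINIMIZED))


@dataclass(frozen=True)
class MeasureSpec:
    """A selection measure: one of K/H/Q/PH/PK/WPH/WPK plus its weight.

    ``delta`` only affects the weighted measures (WPH, WPK); the default 0.5
    weights masked diversity and ancestry dose equally.
    """

    id: str
    delta: float = 0.5

    def __post_init__(self) -> None:
        if self.id not in MAXIMIZED and self.id not in MINIMIZED:
            raise ValueError(f"unknown measure id {self.id!r}; expected one of {MEASURE_IDS}")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")

    @property
    def direction(self) -> str:
        """'maximize' or 'minimize'."""
        return "maximize" if self.id in MAXIMIZED else "minimize"


@dataclass
class PairwiseMatrix:
    """Symmetric N x N matrix of an expected measure over potential offspring."""

    values: np.ndarray
    measure: MeasureSpec

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("pairwise matrix must be square")
        self.values = v


@dataclass
class ScoreReport:
    """Realized population scores for one generation (all in [0, 1])."""

    t: int
    S_Q: float
    S_H: float
    S_K: float
    S_PH: float
    S_PK: float
    replicate: int | None = None

    def as_dict(self) -> dict:
        d = {
            "generation": self.t,
            "S_Q": self.S_Q,
            "S_H": self.S_H,
            "S_K": self.S_K,
            "S_PH": self.S_PH,
            "S_PK": self.S_PK,
        }
        if self.replicate is not None:
            d = {"replicate": self.replicate, **d}
        return d


def per_locus_pair_measure(measure, hapdata_i, hapdata_j) -> float:
    """Reference (scalar) evaluation of one kernel at a single locus.

    ``hapdata_i`` and ``hapdata_j`` are ``(g, a, f)`` triples holding the two
    allele states, ancestry indicators and founder labels of one individual at
    the locus.  The four (a, b) haplotype pairings are enumerated explicitly;
    this is the slow, transparent form the vectorized matrix builder is tested
    against.
    """
    if isinstance(measure, str):
        measure = MeasureSpec(measure)
    gi, ai, fi = (np.asarray(x) for x in hapdata_i)
    gj, aj, fj = (np.asarray(x) for x in hapdata_j)
    d = measure.delta
    total = 0.0
    for a, b in product((0, 1), (0, 1)):
        het = float(gi[a] != gj[b])
        dose = float(ai[a] + aj[b])
        both = float(ai[a] + aj[b] == 2)
        ibd = float(fi[a] == fj[b])
        if measure.id == "K":
            total += ibd / 4.0
        elif measure.id == "H":
            total += het / 4.0
        elif measure.id == "Q":
            total += dose / 8.0
        elif measure.id == "PH":
            total += both * het / 4.0
        elif measure.id == "PK":
            total += both * (1.0 - ibd) / 4.0
        elif measure.id == "WPH":
            total += ((1.0 - d) * dose + 2.0 * d * both * het) / 8.0
        elif measure.id == "WPK":
            total += ((1.0 - d) * (2.0 - dose) + 2.0 * d * (1.0 - both * (1.0 - ibd))) / 8.0
    if measure.id == "PK":
        total = 1.0 - total
    return total


def realized_wph_locus(g1: int, g2: int, a1: int, a2: int, delta: float = 0.5) -> float:
    """Weighted population heterozygosity of one realized locus.

    ``(1-delta) * (a1+a2)/2 + delta * I(a1+a2=2) * I(g1!=g2)``: at the default
    delta = 0.5 this takes value 0 with no target-ancestry allele, 0.25 with a
    single one, 0.5 for two identical target alleles and 1 for a heterozygous
    target variant (relative weights 0:1:2:4).
    """
    dose = (a1 + a2) / 2.0
    het = float(a1 + a2 == 2) * float(g1 != g2)
    return (1.0 - delta) * dose + delta * het


# -- vectorized pairwise matrices -------------------------------------------

_CHUNK_ELEMS = 30_000_000  # bound on the broadcast (rows * N * L) work arrays


def _ibd_sums(F: np.ndarray, A: np.ndarray | None) -> np.ndarray:
    """Sum over (a, b, l) of I(F_ial = F_jbl), optionally masked by A_ial*A_jbl.

    Founder-label equality cannot be phrased as a matrix product, so it is
    evaluated by broadcasting in row chunks to bound peak memory.
    """
    N, _, L = F.shape
    out = np.zeros((N, N))
    rows = max(1, _CHUNK_ELEMS // max(1, N * L))
    for a in (0, 1):
        Fa = F[:, a, :]
        for b in (0, 1):
            Fb = F[:, b, :]
            for lo in range(0, N, rows):
                hi = min(lo + rows, N)
                eq = Fa[lo:hi, None, :] == Fb[None, :, :]
                if A is not None:
                    eq &= (A[lo:hi, a, None, :] & A[None, :, b, :]).astype(bool)
                out[lo:hi] += eq.sum(axis=2)
    return out


def _het_sums(G: np.ndarray, A: np.ndarray | None) -> np.ndarray:
    """Sum over (a, b, l) of I(G_ial != G_jbl), optionally ancestry-masked."""
    N, _, L = G.shape
    out = np.zeros((N, N))
    for a in (0, 1):
        for b in (0, 1):
            Ga = G[:, a, :].astype(float)
            Gb = G[:, b, :].astype(float)
            if A is not None:
                Aa = A[:, a, :].astype(float)
                Ab = A[:, b, :].astype(float)
                out += (Aa * Ga) @ (Ab * (1.0 - Gb)).T
                out += (Aa * (1.0 - Ga)) @ (Ab * Gb).T
            else:
                out += Ga @ (1.0 - Gb).T
                out += (1.0 - Ga) @ Gb.T
    return out


def _dose_sums(A: np.ndarray) -> np.ndarray:
    """Sum over (a, b, l) of (A_ial + A_jbl)."""
    per_ind = A.sum(axis=(1, 2)).astype(float)  # both copies, all loci
    return 2.0 * (per_ind[:, None] + per_ind[None, :])


def _both_target_sums(A: np.ndarray) -> np.ndarray:
    """Sum over (a, b, l) of A_ial * A_jbl (the diploidy mask count)."""
    N = A.shape[0]
    out = np.zeros((N, N))
    for a in (0, 1):
        for b in (0, 1):
            out += A[:, a, :].astype(float) @ A[:, b, :].T.astype(float)
    return out


def expected_pair_matrix(measure, panel: Panel) -> PairwiseMatrix:
    """Expected measure between every pair of individuals in the panel.

    Entry (i, j) is the per-locus kernel averaged over all L loci; the
    diagonal is the self-pairing value (used by ranking averages, never by
    actual matings).  Only the accumulators the requested measure needs are
    computed, so the cheap measures (H, Q, WPH) avoid the founder-label
    comparisons entirely.
    """
    if isinstance(measure, str):
        measure = MeasureSpec(measure)
    G, A, F = panel.G, panel.A, panel.F
    L = panel.L
    d = measure.delta
    mid = measure.id

    if mid == "K":
        vals = _ibd_sums(F, None) / (4.0 * L)
    elif mid == "H":
        vals = _het_sums(G, None) / (4.0 * L)
    elif mid == "Q":
        vals = _dose_sums(A) / (8.0 * L)
    elif mid == "PH":
        vals = _het_sums(G, A) / (4.0 * L)
    elif mid == "PK":
        vals = 1.0 - (_both_target_sums(A) - _ibd_sums(F, A)) / (4.0 * L)
    elif mid == "WPH":
        vals = ((1.0 - d) * _dose_sums(A) + 2.0 * d * _het_sums(G, A)) / (8.0 * L)
    else:  # WPK
        masked_nonibd = _both_target_sums(A) - _ibd_sums(F, A)
        vals = ((1.0 - d) * (8.0 * L - _dose_sums(A)) / 2.0
                + d * (4.0 * L - masked_nonibd)) / (4.0 * L)
    return PairwiseMatrix(values=vals, measure=measure)


def realized_scores(panel: Panel, replicate: int | None = None) -> ScoreReport:
    """Population scores of the realized individuals of one generation."""
    G, A, F = panel.G, panel.A, panel.F
    het = G[:, 0, :] != G[:, 1, :]
    ibd = F[:, 0, :] == F[:, 1, :]
    both = (A[:, 0, :] & A[:, 1, :]).astype(bool)
    dose = (A[:, 0, :].astype(float) + A[:, 1, :]) / 2.0
    return ScoreReport(
        t=panel.t,
        S_Q=float(dose.mean()),
        S_H=float(het.mean()),
        S_K=float(ibd.mean()),
        S_PH=float((both & het).mean()),
        S_PK=float((~(both & ~ibd)).mean()),
        replicate=replicate,
    )
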