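"""The captive breeding program: ranking, pairing, and the generation loop.

The default rule is ranked selection: a breeding score ``B_i`` — the mean of
the pairwise expected measure over the individuals still in the candidate
pool — is recomputed as the least promising individual is repeatedly removed
onto a stack, so the final stack orders the generation worst to best.  Pairs
are then taken best-downwards, each drawing a Poisson number of offspring
(mean 4.2 by default, from studbook demography) until the fixed capacity N is
reached.  A compliance rate below one replaces each recommended partner, with
probability 1-c, by a random unpaired lower-ranked individual.

A simpler threshold rule retains the better half of individuals by their
realized score and mates them at random; and the RANDOM strategy mates the
whole generation uniformly.  Both serve as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap, Panel, make_offspring, random_mating_pairs, breed_generation
from .measures import (
    MeasureSpec,
    PairwiseMatrix,
    ScoreReport,
    expected_pair_matrix,
    realized_scores,
)

__all__ = [
    "BreedingConfig",
    "rank_individuals",
    "pair_and_breed",
    "threshold_breed",
    "individual_scores",
    "run_program",
]

STRATEGIES = ("RANDOM", "K", "H", "Q", "PH", "PK", "WPH", "WPK")


@dataclass(frozen=True)
class BreedingConfig:
    """Breeding-program parameters.

    ``measure`` is one of K/H/Q/PH/PK/WPH/WPK or RANDOM; ``offspring_mean``
    is the Poisson mean number of surviving offspring per pair;
    ``compliance`` is the probability that a pairing recommendation is
    followed.
    """

    measure: str = "PK"
    delta: float = 0.5
    rule: str = "ranked"
    capacity: int = 150
    offspring_mean: float = 4.2
    compliance: float = 1.0
    threshold_quantile: float = 0.5
    n_generations: int = 20

    def __post_init__(self) -> None:
        if self.measure not in STRATEGIES:
            raise ValueError(f"measure must be one of {STRATEGIES}")
        if self.rule not in ("ranked", "threshold"):
            raise ValueError("rule must be 'ranked' or 'threshold'")
        if self.capacity < 2:
            raise ValueError("capacity must be at least 2")
        if self.offspring_mean <= 0:
            raise ValueError("offspring_mean must be positive")
        if not 0 < self.compliance <= 1:
            raise ValueError("compliance must lie in (0, 1]")
        if not 0 <= self.threshold_quantile < 1:
            raise ValueError("threshold_quantile must lie in [0, 1)")

    def measure_spec(self) -> MeasureSpec | None:
        if self.measure == "RANDOM":
            return None
        return MeasureSpec(self.measure, self.delta)


def rank_individuals(matrix, direction: str | None = None) -> np.ndarray:
    """Order individuals worst to best by iterated mean pairwise score.

    At every iteration the breeding score of each remaining individual is the
    mean of its pairwise entries over the other remaining individuals (the
    self term is excluded); the least promising one — lowest score when the
    measure is maximized, highest when minimized — is moved onto the stack.
    Ties break toward the lower index.  Returns the stack: index 0 is the
    worst individual, the last entry the best.
    """
    if isinstance(matrix, PairwiseMatrix):
        M = matrix.values
        if direction is None:
            direction = matrix.measure.direction
    else:
        M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("ranking needs a square pairwise matrix")
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    N = M.shape[0]
    if N < 2:
        raise ValueError("ranking needs at least two individuals")

    remaining = np.ones(N, dtype=bool)
    stack = np.empty(N, dtype=np.int64)
    sign = 1.0 if direction == "maximize" else -1.0
    for it in range(N - 1):
        n_rem = N - it
        # fresh sums each iteration keep exact ties exact (no drift from
        # incremental updates), so the index tie-break is deterministic
        B = (M[:, remaining].sum(axis=1) - np.diag(M)) / (n_rem - 1)
        B = np.where(remaining, sign * B, np.inf)  # promising = large
        worst = int(np.argmin(B))  # first occurrence = lowest index on ties
        stack[it] = worst
        remaining[worst] = False
    stack[N - 1] = int(np.flatnonzero(remaining)[0])
    return stack


def _draw_pair(unpaired: list, compliance: float, rng) -> tuple[int, int]:
    """Pop the best individual and its (possibly non-compliant) partner.

    ``unpaired`` is ordered worst to best.  The recommended partner is the
    next best; with probability 1-c a random unpaired lower-ranked individual
    substitutes and the recommendation returns to the pool.
    """
    p1 = unpaired.pop()
    comply = rng.random() < compliance
    if not comply and len(unpaired) >= 2:
        k = int(rng.integers(len(unpaired) - 1))  # exclude the recommended
        p2 = unpaired.pop(k)
    else:
        p2 = unpaired.pop()
    return p1, p2


def pair_and_breed(
    stack: np.ndarray,
    panel: Panel,
    config: BreedingConfig,
    genome_map: GenomeMap,
    rng,
) -> Panel:
    """Consume the ranking stack best-downwards and breed to capacity.

    Each pair draws Poisson(offspring_mean) children; the generation closes
    when capacity is reached (the last brood is truncated).  If every pair
    has bred and capacity is still short, pairing restarts from the best
    pair with fresh Poisson draws, so the population size stays exactly N.
    """
    N = config.capacity
    L = panel.L
    G = np.empty((N, 2, L), dtype=np.uint8)
    A = np.empty_like(G)
    F = np.empty((N, 2, L), dtype=np.int32)
    n_done = 0
    unpaired: list = []
    while n_done < N:
        if len(unpaired) < 2:
            unpaired = list(int(i) for i in stack)  # (re)start from the top
        p1, p2 = _draw_pair(unpaired, config.compliance, rng)
        brood = int(rng.poisson(config.offspring_mean))
        for _ in range(min(brood, N - n_done)):
            G[n_done], A[n_done], F[n_done] = make_offspring(
                panel, p1, p2, genome_map, rng
            )
            n_done += 1
    return Panel(t=panel.t + 1, G=G, A=A, F=F)


def individual_scores(panel: Panel, measure) -> np.ndarray:
    """Realized per-individual score of the requested measure, shape (N,)."""
    if isinstance(measure, str):
        measure = MeasureSpec(measure)
    G, A, F = panel.G, panel.A, panel.F
    het = (G[:, 0, :] != G[:, 1, :]).mean(axis=1)
    ibd = (F[:, 0, :] == F[:, 1, :]).mean(axis=1)
    both = (A[:, 0, :] & A[:, 1, :]).astype(bool)
    dose = ((A[:, 0, :].astype(float) + A[:, 1, :]) / 2.0).mean(axis=1)
    ph = (both & (G[:, 0, :] != G[:, 1, :])).mean(axis=1)
    pk = 1.0 - (both & (F[:, 0, :] != F[:, 1, :])).mean(axis=1)
    d = measure.delta
    table = {
        "K": ibd,
        "H": het,
        "Q": dose,
        "PH": ph,
        "PK": pk,
        "WPH": (1 - d) * dose + d * ph,
        "WPK": (1 - d) * (1 - dose) + d * pk,
    }
    return table[measure.id]


def threshold_breed(
    scores: np.ndarray,
    panel: Panel,
    config: BreedingConfig,
    genome_map: GenomeMap,
    rng,
) -> Panel:
    """Retain individuals above the score quantile; random-mate to capacity.

    The better ``ceil((1 - q) * N)`` individuals by the measure's direction
    are kept (ties resolved toward the lower index) and bred by
    Wright-Fisher pair draws without self-mating.
    """
    spec = config.measure_spec()
    if spec is None:
        raise ValueError("threshold rule needs a concrete measure, not RANDOM")
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    quota = int(np.ceil((1.0 - config.threshold_quantile) * n))
    quota = max(2, quota)
    key = -scores if spec.direction == "maximize" else scores
    order = np.argsort(key, kind="stable")  # best first, ties by index
    keep = np.sort(order[:quota])
    if len(keep) < 2:
        raise ValueError("threshold selection left fewer than two individuals")
    selected = panel.subset(keep)
    pairs = random_mating_pairs(selected.N, config.capacity, rng)
    return breed_generation(selected, pairs, genome_map, rng)


def _advance(panel, config, genome_map, rng) -> Panel:
    spec = config.measure_spec()
    if spec is None:  # RANDOM strategy: uniform Wright-Fisher mating
        pairs = random_mating_pairs(panel.N, config.capacity, rng)
        return breed_generation(panel, pairs, genome_map, rng)
    if config.rule == "threshold":
        sc = individual_scores(panel, spec)
        return threshold_breed(sc, panel, config, genome_map, rng)
    matrix = expected_pair_matrix(spec, panel)
    stack = rank_individuals(matrix)
    return pair_and_breed(stack, panel, config, genome_map, rng)


def run_program(
    panel: Panel,
    genome_map: GenomeMap,
    config: BreedingConfig,
    rng,
    replicate: int | None = None,
) -> tuple[list[ScoreReport], Panel]:
    """Run the breeding loop and return the score trajectory + final panel.

    The trajectory includes the founder generation, so it holds
    ``n_generations + 1`` reports.
    """
    trajectory = [realized_scores(panel, replicate)]
    for _ in range(config.n_generations):
        panel = _advance(panel, config, genome_map, rng)
        trajectory.append(realized_scores(panel, replicate))
    return trajectory, panel
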