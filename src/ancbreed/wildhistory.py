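"""Simulated population history: diverged sources, introgression, captivity.

Two source populations — the conservation *target* and the *introgressing*
population — diverge from a common ancestor under the Balding-Nichols model:
each locus has an ancestral frequency ``f ~ U(0.05, 0.95)`` and population
frequencies ``f_A, f_I ~ Beta(f(1-F)/F, (1-f)(1-F)/F)`` with drift parameter
``F`` per population, so E[f_A] = f and Var[f_A] = F f(1-f).  With both drift
parameters 0.2 the two populations are separated by F_ST = 0.4 by
construction.

The wild history then runs ``T_init`` Wright-Fisher generations during which
each parent of each offspring is drawn from the (static) introgressing source
with probability ``alpha_t`` and from the evolving wild population otherwise;
the default schedule is a two-generation pulse alpha = (0.2, 0.2, 0, ..., 0)
over ten generations.  Captivity is founded by a uniform *bottleneck* (the
sampled animals are indexed as program founders and given fresh founder
labels), one round of uniform random breeding, *selection* of the least
introgressed fraction, and a final Wright-Fisher round up to the program
capacity N.  Introgression therefore lies ``T_init + 2`` generations before
the program starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeMap, Panel, _gamete_tracks, founder_labels, random_mating_pairs

__all__ = [
    "WildHistoryConfig",
    "sample_population_frequencies",
    "build_source_panels",
    "simulate_wild_history",
    "form_captive_population",
    "make_captive_panel",
]


def _default_alpha() -> tuple:
    return (0.2, 0.2) + (0.0,) * 8


@dataclass(frozen=True)
class WildHistoryConfig:
    """Parameters of the pre-program population history.

    ``alpha`` is the per-generation, per-parent introgression probability;
    its length is the number of wild generations ``T_init``.  If
    ``initial_introgression`` is set, the two pulse entries are re-calibrated
    so that the captive population starts at that introgressed fraction
    (within ±0.02); otherwise the raw schedule is used as given.
    """

    freq_low: float = 0.05
    freq_high: float = 0.95
    F_A: float = 0.2
    F_I: float = 0.2
    N_A: int = 500
    N_I: int = 500
    alpha: tuple = field(default_factory=_default_alpha)
    p_bottleneck: float = 0.25
    p_captive: float = 0.25
    N: int = 150
    initial_introgression: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError("introgression rates alpha must lie in [0, 1]")
        object.__setattr__(self, "alpha", tuple(float(x) for x in a))
        for name in ("p_bottleneck", "p_captive"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("F_A", "F_I"):
            F = getattr(self, name)
            if not 0 <= F < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 <= self.freq_low < self.freq_high <= 1:
            raise ValueError("require 0 <= freq_low < freq_high <= 1")

    @property
    def T_init(self) -> int:
        return len(self.alpha)

    @property
    def introgression_age(self) -> int:
        """Generations between the start of the pulse and program start."""
        return self.T_init + 2


def sample_population_frequencies(config: WildHistoryConfig, L: int, rng):
    """Per-locus frequencies (f_ancestral, f_target, f_introgressing).

    The ancestral frequency is uniform on (freq_low, freq_high); the two
    population frequencies are independent Balding-Nichols Beta draws around
    it.  A drift parameter of exactly 0 collapses to the point mass at f.
    """
    f = rng.uniform(config.freq_low, config.freq_high, size=L)

    def bn(F: float) -> np.ndarray:
        if F == 0.0:
            return f.copy()
        return rng.beta(f * (1 - F) / F, (1 - f) * (1 - F) / F)

    return f, bn(config.F_A), bn(config.F_I)


def _haplotype_panel(freqs: np.ndarray, n: int, ancestry: int, rng) -> Panel:
    """A panel of ``n`` diploids with i.i.d. Bernoulli(freq) haplotypes."""
    L = len(freqs)
    G = (rng.random((n, 2, L)) < freqs).astype(np.uint8)
    A = np.full((n, 2, L), ancestry, dtype=np.uint8)
    F = np.zeros((n, 2, L), dtype=np.int32)
    return Panel(t=0, G=G, A=A, F=F)


def build_source_panels(config: WildHistoryConfig, genome_map: GenomeMap, rng):
    """Draw the target (A=1) and introgressing (A=0) source populations."""
    _, fA, fI = sample_population_frequencies(config, genome_map.L, rng)
    target = _haplotype_panel(fA, config.N_A, 1, rng)
    introg = _haplotype_panel(fI, config.N_I, 0, rng)
    return target, introg


def _mixed_child(wild: Panel, introg: Panel, alpha: float, genome_map: GenomeMap, rng):
    """Rows of one child whose parents are wild or introgressing-source."""
    sources = rng.random(2) < alpha
    idx = [
        int(rng.integers(introg.N if s else wild.N)) for s in sources
    ]
    if sources[0] == sources[1] and idx[0] == idx[1]:  # forbid selfing
        pool = introg.N if sources[0] else wild.N
        idx[1] = (idx[1] + 1 + int(rng.integers(pool - 1))) % pool
    gams = [
        _gamete_tracks(introg if s else wild, i, genome_map, rng)
        for s, i in zip(sources, idx)
    ]
    g = np.stack([gams[0].g, gams[1].g])
    a = np.stack([gams[0].anc, gams[1].anc])
    f = np.stack([gams[0].f, gams[1].f])
    return g, a, f


def simulate_wild_history(
    config: WildHistoryConfig, genome_map: GenomeMap, rng, sources=None
) -> Panel:
    """Run the wild generations with the introgression schedule ``alpha``.

    The introgressing source panel is held fixed (migrants always come from
    the unchanged source population); the wild population evolves by
    Wright-Fisher mating at constant size ``N_A``.
    """
    if sources is None:
        wild, introg = build_source_panels(config, genome_map, rng)
    else:
        wild, introg = sources
    L = genome_map.L
    for t, alpha in enumerate(config.alpha, start=1):
        G = np.empty((config.N_A, 2, L), dtype=np.uint8)
        A = np.empty_like(G)
        F = np.zeros((config.N_A, 2, L), dtype=np.int32)
        for k in range(config.N_A):
            G[k], A[k], F[k] = _mixed_child(wild, introg, alpha, genome_map, rng)
        wild = Panel(t=t, G=G, A=A, F=F)
    return wild


def _random_breed(panel: Panel, n_children: int, genome_map: GenomeMap, rng) -> Panel:
    from .genome import breed_generation

    pairs = random_mating_pairs(panel.N, n_children, rng)
    return breed_generation(panel, pairs, genome_map, rng)


def form_captive_population(
    wild_panel: Panel, config: WildHistoryConfig, genome_map: GenomeMap, rng
) -> Panel:
    """Bottleneck, founder labelling, selection, and captive breeding.

    1. A uniform fraction ``p_bottleneck`` of wild individuals is sampled;
       these are the program founders and receive fresh unique founder
       labels.  They breed one round of uniform random mating (constant
       size).
    2. The least-introgressed fraction ``p_captive`` of their offspring is
       retained and bred by Wright-Fisher mating up to capacity ``N``.

    The returned panel is generation 0 of the breeding program.
    """
    n_found = max(2, round(config.p_bottleneck * wild_panel.N))
    keep = rng.choice(wild_panel.N, size=n_found, replace=False)
    founders = wild_panel.subset(np.sort(keep)).reset_founders()

    brood = _random_breed(founders, n_found, genome_map, rng)

    n_sel = max(2, round(config.p_captive * brood.N))
    order = np.argsort(-brood.target_fraction(), kind="stable")
    selected = brood.subset(np.sort(order[:n_sel]))
    if selected.N < 2:
        raise ValueError("captive selection left fewer than two individuals")

    captive = _random_breed(selected, config.N, genome_map, rng)
    captive.t = 0
    return captive


def make_captive_panel(
    config: WildHistoryConfig, genome_map: GenomeMap, rng
) -> tuple[Panel, dict]:
    """Full pipeline from source populations to the captive founder panel.

    When ``config.initial_introgression`` is set, the two-generation pulse is
    re-calibrated: a pulse of strength ``alpha = 1 - sqrt(1 - q_raw)`` per
    generation yields raw introgression ``q_raw`` before selection, and
    ``q_raw`` is adjusted multiplicatively until the post-selection captive
    mean matches the requested level within ±0.02 (at most 8 attempts).
    Returns the captive panel and a diagnostics dict.
    """
    target = config.initial_introgression
    if target is None:
        wild = simulate_wild_history(config, genome_map, rng)
        captive = form_captive_population(wild, config, genome_map, rng)
        achieved = float(1.0 - captive.target_fraction().mean())
        return captive, {
            "achieved_introgression": achieved,
            "alpha": config.alpha,
            "introgression_age": config.introgression_age,
        }

    if not 0 < target < 1:
        raise ValueError("initial_introgression must lie in (0, 1)")
    T = config.T_init
    if T < 2:
        raise ValueError("calibrated pulse needs at least two wild generations")
    q_raw = float(target)
    captive, achieved, alpha_used = None, None, None
    for _ in range(8):
        q_raw = min(max(q_raw, 1e-4), 0.95)
        a = 1.0 - np.sqrt(1.0 - q_raw)
        alpha_used = (a, a) + (0.0,) * (T - 2)
        cfg = replace(config, alpha=alpha_used, initial_introgression=None)
        wild = simulate_wild_history(cfg, genome_map, rng)
        captive = form_captive_population(wild, cfg, genome_map, rng)
        achieved = float(1.0 - captive.target_fraction().mean())
        if abs(achieved - target) <= 0.02:
            break
        q_raw *= target / max(achieved, 1e-6)
    return captive, {
        "achieved_introgression": achieved,
        "alpha": alpha_used,
        "introgression_age": config.introgression_age,
    }
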