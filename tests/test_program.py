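"""Ranking, pairing, compliance, threshold rule, and the program loop."""

import numpy as np
import pytest

from ancbreed.genome import GenomeMap, Panel, founder_labels
from ancbreed.measures import realized_scores
from ancbreed.program import (
    BreedingConfig,
    individual_scores,
    pair_and_breed,
    rank_individuals,
    run_program,
    threshold_breed,
)


class HybridRNG:
    """Real generator with optionally scripted poisson/uniform draws."""

    def __init__(self, seed=0, poissons=None, uniforms=None):
        self._g = np.random.default_rng(seed)
        self._pois = list(poissons) if poissons is not None else None
        self._unif = list(uniforms) if uniforms is not None else None

    def integers(self, *a, **k):
        return self._g.integers(*a, **k)

    def exponential(self, *a, **k):
        return self._g.exponential(*a, **k)

    def choice(self, *a, **k):
        return self._g.choice(*a, **k)

    def random(self, *a, **k):
        if self._unif:
            return self._unif.pop(0)
        return self._g.random(*a, **k)

    def poisson(self, *a, **k):
        if self._pois:
            return self._pois.pop(0)
        return self._g.poisson(*a, **k)


def labelled_panel(n, L=10):
    """Panel whose founder labels identify each parent haplotype."""
    F = np.repeat(founder_labels(n)[:, :, None], L, axis=2)
    rng = np.random.default_rng(7)
    return Panel(
        t=0,
        G=rng.integers(0, 2, (n, 2, L)),
        A=np.ones((n, 2, L), dtype=np.uint8),
        F=F,
    )


def parent_set(child_F, n_parents):
    """Recover which founders contributed to a child from its labels."""
    labs = founder_labels(n_parents)
    return {i for i in range(n_parents) if np.isin(child_F, labs[i]).any()}


class TestRanking:
    def test_two_individuals_trivial(self):
        stack = rank_individuals(np.array([[0.5, 0.1], [0.1, 0.5]]), "minimize")
        assert sorted(stack.tolist()) == [0, 1]

    def test_pair_of_high_heterozygosity_mates_kept_last(self):
        # individuals 0 and 1 complement each other (H=0.9); 2 and 3 are
        # eliminated first under the iterative mean-update
        H = np.full((4, 4), 0.1)
        np.fill_diagonal(H, 0.0)
        H[0, 1] = H[1, 0] = 0.9
        stack = rank_individuals(H, "maximize")
        assert set(stack[:2].tolist()) == {2, 3}
        assert set(stack[2:].tolist()) == {0, 1}

    def test_total_tie_breaks_by_ascending_index(self):
        M = np.full((5, 5), 0.3)
        assert rank_individuals(M, "maximize").tolist() == [0, 1, 2, 3, 4]
        assert rank_individuals(M, "minimize").tolist() == [0, 1, 2, 3, 4]

    def test_minimize_direction_flips_order(self):
        K = np.full((3, 3), 0.2)
        K[0, 1] = K[1, 0] = 0.9  # 0 and 1 are close kin: eliminate them first
        stack = rank_individuals(K, "minimize")
        assert stack[-1] == 2

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            rank_individuals(np.zeros((3, 2)), "maximize")


class TestPairAndBreed:
    GM = GenomeMap(10, 1.0)

    def test_capacity_exact_and_top_pair_parents(self):
        panel = labelled_panel(4)
        cfg = BreedingConfig(capacity=6, compliance=1.0)
        rng = HybridRNG(seed=1, poissons=[100], uniforms=[0.0])
        child = pair_and_breed(np.array([0, 1, 2, 3]), panel, cfg, self.GM, rng)
        assert child.N == 6
        # every child is parented by the best pair (3, 2)
        for k in range(child.N):
            assert parent_set(child.F[k], 4) <= {2, 3}

    def test_zero_brood_moves_to_next_pair(self):
        panel = labelled_panel(4)
        cfg = BreedingConfig(capacity=5, compliance=1.0)
        rng = HybridRNG(seed=2, poissons=[0, 100], uniforms=[0.0, 0.0])
        child = pair_and_breed(np.array([0, 1, 2, 3]), panel, cfg, self.GM, rng)
        for k in range(child.N):
            assert parent_set(child.F[k], 4) <= {0, 1}

    def test_population_size_is_exact_even_with_small_broods(self):
        panel = labelled_panel(5)
        cfg = BreedingConfig(capacity=12, offspring_mean=1.0)
        child = pair_and_breed(np.arange(5), panel, cfg, self.GM, np.random.default_rng(3))
        assert child.N == 12

    def test_non_compliance_substitutes_lower_ranked_partner(self):
        panel = labelled_panel(4)
        cfg = BreedingConfig(capacity=6, compliance=0.5)
        # coin 0.9 >= c fails: partner of 3 is drawn from {0, 1}, not 2
        rng = HybridRNG(seed=4, poissons=[100], uniforms=[0.9])
        child = pair_and_breed(np.array([0, 1, 2, 3]), panel, cfg, self.GM, rng)
        parents = set().union(*(parent_set(child.F[k], 4) for k in range(child.N)))
        assert 3 in parents
        assert 2 not in parents

    def test_compliant_coin_reproduces_full_compliance(self):
        panel = labelled_panel(4)
        stack = np.array([0, 1, 2, 3])
        kw = dict(poissons=[100], uniforms=[0.3])
        a = pair_and_breed(stack, panel, BreedingConfig(capacity=6, compliance=1.0), self.GM, HybridRNG(seed=5, **kw))
        b = pair_and_breed(stack, panel, BreedingConfig(capacity=6, compliance=0.6), self.GM, HybridRNG(seed=5, **kw))
        assert np.array_equal(a.G, b.G) and np.array_equal(a.F, b.F)


class TestThresholdRule:
    GM = GenomeMap(10, 1.0)

    def test_distinct_scores_retain_better_half(self):
        panel = labelled_panel(6)
        scores = np.array([0.5, 0.1, 0.4, 0.2, 0.6, 0.3])
        cfg = BreedingConfig(measure="K", rule="threshold", capacity=8)
        child = threshold_breed(scores, panel, cfg, self.GM, np.random.default_rng(0))
        assert child.N == 8
        # K is minimized: the three lowest scores (indices 1, 3, 5) breed
        parents = set().union(*(parent_set(child.F[k], 6) for k in range(child.N)))
        assert parents <= {1, 3, 5}

    def test_quantile_zero_is_pure_random_mating(self):
        panel = labelled_panel(4)
        cfg = BreedingConfig(measure="H", rule="threshold", capacity=30, threshold_quantile=0.0)
        child = threshold_breed(np.arange(4.0), panel, cfg, self.GM, np.random.default_rng(1))
        parents = set().union(*(parent_set(child.F[k], 4) for k in range(child.N)))
        assert parents == {0, 1, 2, 3}

    def test_tied_scores_resolved_by_ascending_index(self):
        panel = labelled_panel(5)
        cfg = BreedingConfig(measure="H", rule="threshold", capacity=10)
        child = threshold_breed(np.zeros(5), panel, cfg, self.GM, np.random.default_rng(2))
        # quota = ceil(0.5 * 5) = 3: ties keep indices 0, 1, 2
        parents = set().union(*(parent_set(child.F[k], 5) for k in range(child.N)))
        assert parents <= {0, 1, 2}

    def test_individual_scores_weighted_identity(self):
        panel = labelled_panel(4)
        s_q = individual_scores(panel, "Q")
        s_ph = individual_scores(panel, "PH")
        s_wph = individual_scores(panel, "WPH")
        assert np.allclose(s_wph, 0.5 * s_q + 0.5 * s_ph)


class TestRunProgram:
    GM = GenomeMap(40, 2.0)

    def _panel(self, n=16, L=40, seed=11):
        rng = np.random.default_rng(seed)
        F = np.repeat(founder_labels(n)[:, :, None], L, axis=2)
        return Panel(
            t=0,
            G=rng.integers(0, 2, (n, 2, L)),
            A=(rng.random((n, 2, L)) < 0.7).astype(np.uint8),
            F=F,
        )

    def test_zero_generations_scores_founders_only(self):
        panel = self._panel()
        traj, final = run_program(
            panel, self.GM, BreedingConfig(capacity=16, n_generations=0), np.random.default_rng(0)
        )
        assert len(traj) == 1 and final is panel

    def test_population_size_constant(self):
        panel = self._panel()
        cfg = BreedingConfig(measure="WPH", capacity=16, n_generations=3)
        _, final = run_program(panel, self.GM, cfg, np.random.default_rng(1))
        assert final.N == 16

    def test_random_mating_heterozygosity_drifts_down(self):
        # without introgression, E[S_H] decays under genetic drift
        first, last = [], []
        for rep in range(20):
            panel = self._panel(n=12, seed=100 + rep)
            panel.A[:] = 1
            cfg = BreedingConfig(measure="RANDOM", capacity=12, n_generations=6)
            traj, _ = run_program(panel, self.GM, cfg, np.random.default_rng(rep))
            first.append(traj[0].S_H)
            last.append(traj[-1].S_H)
        assert np.mean(last) < np.mean(first)

    def test_ancestry_mean_is_martingale_under_random_mating(self):
        # mean S_Q is conserved in expectation without selection
        deltas = []
        for rep in range(25):
            panel = self._panel(n=14, seed=200 + rep)
            cfg = BreedingConfig(measure="RANDOM", capacity=14, n_generations=4)
            traj, _ = run_program(panel, self.GM, cfg, np.random.default_rng(rep))
            deltas.append(traj[-1].S_Q - traj[0].S_Q)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3.5 * se

    def test_ancestry_selection_beats_random_mating(self):
        # PK selection raises final target ancestry relative to random mating
        sel, rand = [], []
        for rep in range(10):
            panel = self._panel(n=20, seed=300 + rep)
            for measure, out in (("PK", sel), ("RANDOM", rand)):
                cfg = BreedingConfig(measure=measure, capacity=20, n_generations=5)
                traj, _ = run_program(panel, self.GM, cfg, np.random.default_rng(rep))
                out.append(traj[-1].S_Q)
        assert np.mean(sel) > np.mean(rand)
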