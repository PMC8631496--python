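"""Agent placement, cluster growth, state classification, replicates."""

import numpy as np
import pytest
from scipy import stats as sps

from pncell import (
    CellState,
    PlacementError,
    Stimulus,
    classify_states,
    grow_clusters,
    place_agents,
    replicate_runs,
    run_once,
    summarize_replicates,
    target_count,
)
from pncell.abm3d import RunSummary, select_nucleation
from pncell.sca_model import ConfigurationError

N_SMALL = 400
SEEDS_SMALL = 3


def small_world(seed=0):
    world = place_agents(N_SMALL, 1000.0, seed)
    select_nucleation(world, np.random.default_rng((seed, 1)), SEEDS_SMALL)
    return world


def brute_force_growth(positions, seeds, target):
    """Greedy globally-nearest-neighbour growth by explicit pair scans."""
    marked = set(int(s) for s in seeds)
    order = []
    while len(marked) < target:
        best = (np.inf, None)
        for i in range(len(positions)):
            if i in marked:
                continue
            d = min(float(np.linalg.norm(positions[i] - positions[j]))
                    for j in marked)
            if d < best[0] - 1e-12:
                best = (d, i)
        marked.add(best[1])
        order.append((best[1], best[0]))
    return marked, order


class TestPlacement:
    def test_fixed_seed_reproduces_positions(self):
        a = place_agents(N_SMALL, seed=42)
        b = place_agents(N_SMALL, seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert a.content_hash() == b.content_hash()

    def test_different_seeds_differ(self):
        a = place_agents(N_SMALL, seed=1)
        b = place_agents(N_SMALL, seed=2)
        assert not np.array_equal(a.positions, b.positions)

    def test_minimum_pairwise_distance_exhaustive(self):
        world = place_agents(N_SMALL, seed=3)
        d = np.linalg.norm(
            world.positions[:, None, :] - world.positions[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0

    def test_positions_inside_domain(self):
        world = place_agents(N_SMALL, seed=4)
        assert world.positions.min() >= 0.0
        assert world.positions.max() <= 1000.0

    def test_unsatisfiable_density_rejected(self):
        with pytest.raises(PlacementError):
            place_agents(10000, domain_um=50.0, seed=0)


class TestClusterGrowth:
    def test_target_equal_to_seeds_means_no_growth(self):
        world = small_world()
        grow_clusters(world, Stimulus.IL1B, SEEDS_SMALL)
        assert int(world.il1b.sum()) == SEEDS_SMALL
        assert set(np.flatnonzero(world.il1b)) == set(world.nucleation[Stimulus.IL1B])
        assert len(world.growth_distances[Stimulus.IL1B]) == 0

    def test_single_addition_is_global_nearest_neighbour(self):
        world = small_world()
        seeds = world.nucleation[Stimulus.IL1B]
        grow_clusters(world, Stimulus.IL1B, SEEDS_SMALL + 1)
        added = set(np.flatnonzero(world.il1b)) - set(seeds)
        assert len(added) == 1
        # exhaustive scan for the closest outsider
        dists = {}
        for i in range(world.n_agents):
            if i in set(seeds):
                continue
            dists[i] = min(np.linalg.norm(world.positions[i] - world.positions[s])
                           for s in seeds)
        assert added.pop() == min(dists, key=dists.get)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_growth_reproduces_brute_force_oracle(self, seed):
        world = small_world(seed)
        target = 40
        grow_clusters(world, Stimulus.IL1B, target)
        marked, order = brute_force_growth(
            world.positions, world.nucleation[Stimulus.IL1B], target)
        assert set(np.flatnonzero(world.il1b)) == marked
        assert world.growth_distances[Stimulus.IL1B] == pytest.approx(
            [d for _, d in order])

    def test_exact_target_count_from_percentage(self):
        world = small_world()
        pct = 16.0
        grow_clusters(world, Stimulus.IL1B, target_count(pct, world.n_agents))
        assert int(world.il1b.sum()) == round(0.16 * N_SMALL)

    def test_identical_seed_sets_fully_overlap(self):
        world = small_world()
        world.nucleation[Stimulus.TNFA] = world.nucleation[Stimulus.IL1B].copy()
        grow_clusters(world, Stimulus.IL1B, 60)
        grow_clusters(world, Stimulus.TNFA, 60)
        summary = classify_states(world)
        assert summary.counts[CellState.IL1B_TNFA_POS] == 60

    def test_distant_seed_groups_stay_disjoint(self):
        # two agents-only world: each cytokine nucleates on its own corner
        positions = np.array([[10.0, 10, 10], [990.0, 990, 990]])
        from pncell.abm3d import ABMWorld
        world = ABMWorld(positions=positions, domain_um=1000.0, seed=0)
        world.nucleation[Stimulus.IL1B] = np.array([0])
        world.nucleation[Stimulus.TNFA] = np.array([1])
        grow_clusters(world, Stimulus.IL1B, 1)
        grow_clusters(world, Stimulus.TNFA, 1)
        assert classify_states(world).counts[CellState.IL1B_TNFA_POS] == 0

    def test_target_beyond_population_rejected(self):
        world = small_world()
        with pytest.raises(ConfigurationError):
            grow_clusters(world, Stimulus.IL1B, N_SMALL + 1)

    def test_target_below_seed_count_rejected(self):
        world = small_world()
        with pytest.raises(ConfigurationError):
            grow_clusters(world, Stimulus.IL1B, SEEDS_SMALL - 1)

    def test_growth_distance_sequence_is_recorded_per_step(self):
        world = small_world()
        grow_clusters(world, Stimulus.IL1B, 30)
        assert len(world.growth_distances[Stimulus.IL1B]) == 30 - SEEDS_SMALL


class TestClassification:
    def test_classes_partition_all_agents(self):
        pct = {Stimulus.IL1B: 16.0, Stimulus.TNFA: 24.0}
        _, summary = run_once(pct, n_agents=N_SMALL,
                              seeds_per_cytokine=SEEDS_SMALL, seed=5)
        assert sum(summary.counts.values()) == N_SMALL

    def test_single_plus_double_equals_cytokine_target(self):
        pct = {Stimulus.IL1B: 16.0, Stimulus.TNFA: 24.0}
        _, summary = run_once(pct, n_agents=N_SMALL,
                              seeds_per_cytokine=SEEDS_SMALL, seed=6)
        assert summary.total_positive(Stimulus.IL1B) == round(0.16 * N_SMALL)
        assert summary.total_positive(Stimulus.TNFA) == round(0.24 * N_SMALL)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            RunSummary(n_agents=10, counts={s: 1 for s in CellState}, seed=0)


class TestReplicates:
    def test_totals_deterministic_across_runs_but_overlap_varies(self):
        pct = {Stimulus.IL1B: 16.0, Stimulus.TNFA: 24.0}
        summary = replicate_runs(pct, n_runs=4, base_seed=0, n_agents=N_SMALL,
                                 seeds_per_cytokine=SEEDS_SMALL)
        il1b_totals = {r.total_positive(Stimulus.IL1B) for r in summary.runs}
        tnfa_totals = {r.total_positive(Stimulus.TNFA) for r in summary.runs}
        assert il1b_totals == {round(0.16 * N_SMALL)}
        assert tnfa_totals == {round(0.24 * N_SMALL)}
        doubles = [r.counts[CellState.IL1B_TNFA_POS] for r in summary.runs]
        assert len(set(doubles)) > 1

    def test_ci_matches_textbook_t_interval(self):
        pct = {Stimulus.IL1B: 16.0, Stimulus.TNFA: 24.0}
        summary = replicate_runs(pct, n_runs=5, base_seed=3, n_agents=N_SMALL,
                                 seeds_per_cytokine=SEEDS_SMALL)
        vals = np.array([r.counts[CellState.IL1B_TNFA_POS] for r in summary.runs],
                        dtype=float)
        half = sps.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
        lo, hi = summary.ci95[CellState.IL1B_TNFA_POS]
        assert lo == pytest.approx(vals.mean() - half)
        assert hi == pytest.approx(vals.mean() + half)

    def test_equal_seeds_give_zero_width_interval(self):
        pct = {Stimulus.IL1B: 16.0, Stimulus.TNFA: 24.0}
        _, a = run_once(pct, n_agents=N_SMALL, seeds_per_cytokine=SEEDS_SMALL,
                        seed=9)
        _, b = run_once(pct, n_agents=N_SMALL, seeds_per_cytokine=SEEDS_SMALL,
                        seed=9)
        summary = summarize_replicates([a, b])
        for state in CellState:
            lo, hi = summary.ci95[state]
            assert lo == hi == summary.mean[state]

    def test_single_run_summary_has_degenerate_interval(self):
        pct = {Stimulus.IL1B: 16.0, Stimulus.TNFA: 24.0}
        _, one = run_once(pct, n_agents=N_SMALL, seeds_per_cytokine=SEEDS_SMALL,
                          seed=2)
        summary = summarize_replicates([one])
        assert summary.n_runs == 1
        for state in CellState:
            assert summary.ci95[state] == (summary.mean[state],
                                           summary.mean[state])

    def test_world_hash_identical_for_identical_config(self):
        pct = {Stimulus.IL1B: 16.0, Stimulus.TNFA: 24.0}
        w1, _ = run_once(pct, n_agents=N_SMALL, seeds_per_cytokine=SEEDS_SMALL,
                         seed=4)
        w2, _ = run_once(pct, n_agents=N_SMALL, seeds_per_cytokine=SEEDS_SMALL,
                         seed=4)
        assert w1.content_hash() == w2.content_hash()
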