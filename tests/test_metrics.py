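import math

import numpy as np
import pytest

from sproutsim import (LatticeConfig, build_sprout, count_overtakes,
                       fisher_exact, generate_fixture_trajectory,
                       identify_tip, migrated_distance, score_sp_patterns,
                       time_at_tip_by_initial_rank, tip_contribution,
                       adhesion_strength_summary)
from sproutsim.lattice import EMPTY, SproutMesh


def fixture(com_x, **kwargs):
    com_x = np.asarray(com_x, dtype=float)
    T, n = com_x.shape
    spec = {"timesteps": np.arange(T), "genotype": kwargs.pop(
        "genotype", np.zeros(n, dtype=int)), "com_x": com_x}
    spec.update(kwargs)
    return generate_fixture_trajectory(spec)


class TestIdentifyTip:
    def _mesh(self, front_owners):
        cfg = LatticeConfig()
        mesh = build_sprout(cfg)
        mesh.owner[50, :] = front_owners  # one row beyond the initial front
        return mesh

    def test_sole_occupant(self):
        mesh = self._mesh([3] * 10)
        assert identify_tip(mesh, np.zeros(10)) == 3

    def test_majority_beats_vegfr2(self):
        mesh = self._mesh([2] * 6 + [5] * 4)
        vp = np.zeros(10)
        vp[5] = 99.0
        assert identify_tip(mesh, vp) == 2

    def test_tie_broken_by_vegfr2(self):
        mesh = self._mesh([2] * 5 + [5] * 5)
        vp = np.zeros(10)
        vp[5] = 1.0
        assert identify_tip(mesh, vp) == 5

    def test_double_tie_lowest_id(self):
        mesh = self._mesh([7] * 5 + [4] * 5)
        assert identify_tip(mesh, np.zeros(10)) == 4

    def test_window_walks_back_to_occupied_row(self):
        """The window is the frontmost occupied row wherever it lies."""
        cfg = LatticeConfig()
        owner = np.full((cfg.axial_length, cfg.circumference), EMPTY,
                        dtype=np.int32)
        owner[0:3, :] = 1
        owner[3, 0:2] = 6
        mesh = SproutMesh(cfg, owner, np.zeros(10, dtype=np.int8))
        assert identify_tip(mesh, np.zeros(10)) == 6


class TestTipContribution:
    def test_all_one_genotype(self):
        res = tip_contribution([1] * 12)
        assert res.fraction(1) == 1.0
        assert res.fraction(0) == 0.0

    def test_counts_sum_to_runs(self):
        res = tip_contribution([0, 1, 1, 0, 1])
        assert sum(res.counts.values()) == res.n_runs == 5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            tip_contribution([])


class TestCountOvertakes:
    def test_static(self):
        traj = fixture(np.tile([0.0, 1.0, 2.0], (50, 1)))
        assert count_overtakes(traj) == 0

    def test_single_persistent_swap(self):
        com = np.tile([0.0, 1.0, 2.0, 3.0], (60, 1))
        com[30:, 2], com[30:, 3] = 3.0, 2.0  # cells 2 and 3 swap for good
        assert count_overtakes(fixture(com)) == 1

    def test_swap_reverted_within_debounce(self):
        com = np.tile([0.0, 1.0], (60, 1))
        com[30:35, 0], com[30:35, 1] = 1.0, 0.0  # 5-step excursion
        assert count_overtakes(fixture(com), debounce=10) == 0

    def test_back_and_forth_counts_twice(self):
        com = np.tile([0.0, 1.0], (90, 1))
        com[30:60, 0], com[30:60, 1] = 1.0, 0.0
        assert count_overtakes(fixture(com), debounce=10) == 2

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            count_overtakes(fixture([[0.0, 1.0]]))


class TestMigratedDistance:
    def test_stationary(self):
        traj = fixture(np.tile([5.0], (20, 1)))
        assert migrated_distance(traj, 0) == 0.0

    def test_folded_path(self):
        com = np.array([[0.0], [2.0], [1.0]])
        assert migrated_distance(fixture(com), 0) == pytest.approx(3.0)

    def test_circumferential_motion_ignored(self):
        com = np.tile([1.0], (30, 1))
        com_y = np.arange(30).reshape(-1, 1) % 10.0
        traj = fixture(com, com_y=com_y)
        assert migrated_distance(traj, 0) == 0.0


class TestTimeAtTip:
    def test_single_tip_holds_window(self):
        T = 40
        traj = fixture(np.tile([0.0, 1.0, 2.0], (T, 1)),
                       tip=np.full(T, 2))
        occ = time_at_tip_by_initial_rank(traj)
        assert occ[2] == (T, True)       # frontmost initial rank
        assert occ[0] == (0, False)
        assert sum(v[0] for v in occ.values()) == T

    def test_occupancies_partition_window(self):
        T = 30
        tip = np.array([0, 1, 2] * 10)
        traj = fixture(np.tile([0.0, 1.0, 2.0], (T, 1)), tip=tip)
        occ = time_at_tip_by_initial_rank(traj)
        assert sum(v[0] for v in occ.values()) == T
        assert all(v[1] for v in occ.values())


class TestAdhesionSummary:
    def test_all_strong(self):
        T, n = 10, 4
        traj = fixture(np.tile(np.arange(n, dtype=float), (T, 1)),
                       strong=np.ones((T, n)),
                       genotype=np.array([0, 0, 1, 1]))
        out = adhesion_strength_summary(traj)
        assert out["per_genotype"] == {0: 1.0, 1: 1.0}
        assert out["mean_strong_per_timestep"] == n

    def test_fractions_are_means(self):
        T, n = 4, 2
        strong = np.array([[1, 0], [1, 0], [0, 0], [1, 1]])
        traj = fixture(np.tile([0.0, 1.0], (T, 1)), strong=strong,
                       genotype=np.array([1, 0]))
        out = adhesion_strength_summary(traj)
        assert out["per_genotype"][1] == pytest.approx(0.75)
        assert out["per_genotype"][0] == pytest.approx(0.25)


def sp_fixture(active_rows, adj_mask_value=0, deployed=None):
    """Trajectory with prescribed per-timestep signal-active patterns."""
    active = np.asarray(active_rows, dtype=float)
    T, n = active.shape
    if deployed is None:
        deployed = np.full((T, n), 10.0)  # actin threshold met everywhere
    adj = np.full((T, n), adj_mask_value, dtype=np.int64)
    return fixture(np.tile(np.arange(n, dtype=float), (T, 1)),
                   signal_active=active, deployed=deployed, adj_mask=adj)


class TestScoreSPPatterns:
    def test_hand_computed_runs(self):
        """3 non-adjacent actives held 100 steps, broken 20, held 50:
        avg pattern 75, max 100, avg stabilizing 20."""
        n = 10
        on = np.zeros(n)
        on[[0, 4, 8]] = 1
        rows = [on] * 100 + [np.zeros(n)] * 20 + [on] * 50
        stats = score_sp_patterns(sp_fixture(rows))
        assert stats.avg_pattern_time == pytest.approx(75.0)
        assert stats.max_pattern_time == pytest.approx(100.0)
        assert stats.avg_stabilizing_time == pytest.approx(20.0)
        assert stats.n_patterns == 2

    def test_all_active_never_stable(self):
        rows = [np.ones(10)] * 80
        stats = score_sp_patterns(sp_fixture(rows))
        assert stats.n_patterns == 0
        assert stats.avg_pattern_time == 0.0
        assert stats.avg_stabilizing_time == pytest.approx(80.0)

    def test_adjacent_actives_not_stable(self):
        n = 10
        on = np.zeros(n)
        on[[0, 1, 5]] = 1  # cells 0 and 1 adjacent
        adj = np.zeros((40, n), dtype=np.int64)
        adj[:, 0] = 1 << 1
        adj[:, 1] = 1 << 0
        traj = fixture(np.tile(np.arange(n, dtype=float), (40, 1)),
                       signal_active=np.tile(on, (40, 1)),
                       deployed=np.full((40, n), 10.0), adj_mask=adj)
        stats = score_sp_patterns(traj)
        assert stats.n_patterns == 0

    def test_stunted_cells_count_as_active(self):
        """Signal-active cells below the actin threshold are stunted but
        still count toward the 3-active pattern."""
        n = 10
        on = np.zeros(n)
        on[[0, 4, 8]] = 1
        deployed = np.zeros((60, n))  # nobody meets the actin threshold
        stats = score_sp_patterns(sp_fixture([on] * 60, deployed=deployed))
        assert stats.n_patterns == 1
        assert stats.max_pattern_time == 60

    def test_pure_function(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, size=(200, 10)).astype(float)
        traj = sp_fixture(rows)
        a = score_sp_patterns(traj)
        b = score_sp_patterns(traj)
        assert (a.avg_pattern_time, a.max_pattern_time,
                a.avg_stabilizing_time, a.n_patterns) == \
               (b.avg_pattern_time, b.max_pattern_time,
                b.avg_stabilizing_time, b.n_patterns)

    @pytest.mark.parametrize("seed", range(20))
    def test_brute_force_rescoring(self, seed):
        """Equivalence with an independent rescoring of the same state
        sequence (run-length bookkeeping written from scratch)."""
        rng = np.random.default_rng(seed)
        T, n = 300, 10
        active = (rng.random((T, n)) < 0.3).astype(float)
        deployed = rng.integers(0, 8, size=(T, n)).astype(float)
        adj = rng.integers(0, 2 ** n, size=(T, n))
        # symmetrise the adjacency masks
        for t in range(T):
            for i in range(n):
                for j in range(n):
                    if (adj[t, i] >> j) & 1:
                        adj[t, j] |= 1 << i
        traj = fixture(np.tile(np.arange(n, dtype=float), (T, 1)),
                       signal_active=active, deployed=deployed,
                       adj_mask=adj)
        stats = score_sp_patterns(traj, theta_a=3.0, n_ideal=3)
        exp = _rescore(active, deployed, adj, theta_a=3.0, n_ideal=3)
        assert stats.n_patterns == exp["n_patterns"]
        assert stats.avg_pattern_time == pytest.approx(exp["avg"])
        assert stats.max_pattern_time == pytest.approx(exp["max"])
        assert stats.avg_stabilizing_time == pytest.approx(exp["stab"])

    def test_bad_n_ideal(self):
        with pytest.raises(ValueError):
            score_sp_patterns(sp_fixture([np.zeros(10)] * 5), n_ideal=0)


def _rescore(active, deployed, adj, theta_a, n_ideal):
    """Independent S&P rescoring: literal per-timestep state machine."""
    T, n = active.shape
    stable = []
    for t in range(T):
        ids = [i for i in range(n) if active[t, i]]
        # both sprout-active and stunted-active cells count
        good = len(ids) == n_ideal and not any(
            (int(adj[t, i]) >> j) & 1 for i in ids for j in ids if j != i)
        stable.append(good)
    patterns, gaps = [], []
    run = gap = 0
    for good in stable:
        if good:
            if run == 0 and gap > 0:
                gaps.append(gap)
                gap = 0
            run += 1
        else:
            if run:
                patterns.append(run)
                run = 0
            gap += 1
    if run:
        patterns.append(run)
    if gap and not patterns and not gaps:
        gaps.append(gap)
    return {"n_patterns": len(patterns),
            "avg": float(np.mean(patterns)) if patterns else 0.0,
            "max": float(max(patterns)) if patterns else 0.0,
            "stab": float(np.mean(gaps)) if gaps else 0.0}


class TestFisherExact:
    def test_no_association(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_separation(self):
        expected = 2.0 / math.comb(20, 10)
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(
            expected, abs=1e-12)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])

    @pytest.mark.parametrize("seed", range(30))
    def test_enumeration_oracle(self, seed):
        """Two-sided p equals the sum of hypergeometric probabilities not
        exceeding the observed table's, by full enumeration."""
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(v) for v in rng.integers(0, 16, size=4))
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(_fisher_enumerate(a, b, c, d), abs=1e-12)


def _fisher_enumerate(a, b, c, d):
    row1, row2 = a + b, c + d
    col1 = a + c
    ntot = row1 + row2

    def table_prob(x):
        return (math.comb(row1, x) * math.comb(row2, col1 - x)
                / math.comb(ntot, col1))

    observed = table_prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = table_prob(x)
        if p <= observed * (1 + 1e-12):
            total += p
    return total
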