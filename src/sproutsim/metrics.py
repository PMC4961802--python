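"""Quantification of simulated sprouts.

Implements the in-silico analogues of the wet-lab scoring procedures: tip
identification by front-window occupancy (with the VEGFR2 tie-break),
tip-contribution fractions over replicate runs, debounced cell-cell overtake
counting, accumulated axial migration, time-at-tip by initial position,
adhesive-strength summaries, the salt-and-pepper pattern scorer and Fisher's
exact test on tip counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._kernel import front_window_tip
from .lattice import SproutMesh
from .trajectory import Trajectory

__all__ = ["SPStats", "TipCompetitionResult", "identify_tip",
           "tip_contribution", "count_overtakes", "migrated_distance",
           "time_at_tip_by_initial_rank", "adhesion_strength_summary",
           "score_sp_patterns", "fisher_exact"]


@dataclass
class SPStats:
    """Salt-and-pepper pattern persistence summary (timesteps)."""

    avg_pattern_time: float
    max_pattern_time: float
    avg_stabilizing_time: float
    n_patterns: int
    active_count_hist: np.ndarray = field(default=None, repr=False)


@dataclass
class TipCompetitionResult:
    """Tip counts per genotype over a replicate set."""

    counts: dict
    n_runs: int

    def fraction(self, genotype) -> float:
        return self.counts.get(genotype, 0) / self.n_runs


def identify_tip(mesh: SproutMesh, vp: np.ndarray) -> int:
    """Tip cell of a mesh snapshot by the front-grid-site rule.

    The window is the full circumference at the maximal occupied axial row
    (cell bodies only; filopodia are excluded, matching the wet-lab
    convention of scoring cell-body position rather than protrusions).  The
    cell occupying most window sites wins; an exact tie goes to the higher
    active VEGFR2; a remaining tie to the lower cell id.
    """
    tip = int(front_window_tip(mesh.owner, np.asarray(vp, dtype=float),
                               mesh.n_cells))
    if tip < 0:
        raise ValueError("mesh has no occupied sites")
    return tip


def tip_contribution(tip_genotypes, n_genotypes: int = 2
                     ) -> TipCompetitionResult:
    """Fraction of runs whose endpoint tip cell has each genotype."""
    tips = list(tip_genotypes)
    if not tips:
        raise ValueError("tip_contribution needs at least one run")
    counts = {}
    for g in tips:
        counts[int(g)] = counts.get(int(g), 0) + 1
    return TipCompetitionResult(counts=counts, n_runs=len(tips))


def count_overtakes(traj: Trajectory, debounce: int = 30) -> int:
    """Number of persistent COM_x rank inversions between cell pairs.

    An overtake is counted when the sign of COM_x(i) - COM_x(j) flips and
    the new order holds for at least ``debounce`` consecutive recorded
    steps (15 min — transient boundary jitter between abreast cells does
    not count); a swap reverted within the window is ignored.  Ties inherit
    the preceding order.
    """
    if traj.n_steps < 2:
        raise ValueError("need at least two timesteps")
    com = traj.com_x
    n = traj.n_cells
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(com[:, i] - com[:, j]).astype(np.int8)
            # forward-fill exact ties with the previous order
            zeros = s == 0
            if zeros.any():
                idx = np.where(zeros, 0, np.arange(s.shape[0]))
                np.maximum.accumulate(idx, out=idx)
                s = s[idx]
            # run-length encode the order signal; an overtake is a run of
            # the opposite order lasting at least the debounce window
            change = np.nonzero(np.diff(s))[0] + 1
            starts = np.concatenate(([0], change))
            lengths = np.diff(np.concatenate((starts, [s.shape[0]])))
            established = s[0]
            for start, length in zip(starts, lengths):
                val = s[start]
                if val == 0:
                    continue
                if established == 0:
                    established = val  # first resolved order: no overtake
                elif val != established and length >= debounce:
                    total += 1
                    established = val
    return total


def migrated_distance(traj: Trajectory, cell_id: int) -> float:
    """Total axial distance covered: sum over timesteps of
    |COM_x(t+1) - COM_x(t)| (circumferential motion does not count)."""
    if traj.n_steps < 2:
        raise ValueError("need at least two timesteps")
    return float(np.abs(np.diff(traj.com_x[:, cell_id])).sum())


def time_at_tip_by_initial_rank(traj: Trajectory) -> dict:
    """Tip-occupancy time keyed by each cell's initial COM_x rank.

    Rank 0 is the rearmost cell at the first recorded timestep.  Values are
    (timesteps at tip, ever-reached-tip flag); occupancies sum to the window
    length.
    """
    order = np.argsort(traj.com_x[0], kind="stable")  # rank -> cell id
    out = {}
    for rank, cell in enumerate(order):
        occ = int((traj.tip == cell).sum())
        out[rank] = (occ, occ > 0)
    return out


def adhesion_strength_summary(traj: Trajectory) -> dict:
    """Per-genotype fraction of strongly adhesive cell-timesteps, plus the
    mean number of STRONG cells per timestep."""
    out = {"per_genotype": {}, "mean_strong_per_timestep":
           float(traj.strong.sum(axis=1).mean())}
    for g in np.unique(traj.genotype):
        mask = traj.genotype == g
        out["per_genotype"][int(g)] = float(traj.strong[:, mask].mean())
    return out


def score_sp_patterns(traj: Trajectory, theta_a: float = 3.0,
                      n_ideal: int = 3) -> SPStats:
    """Score salt-and-pepper patterns over the analysis window.

    Per timestep every cell is tested for three properties: its Dll4 and
    active-VEGFR2 levels (the recorded ``signal_active`` flag) and its actin
    pool.  Signal-active cells with deployed actin >= theta_a are "sprout
    active"; signal-active cells below the actin threshold are "stunted
    active"; both count as active.  A timestep holds a stable S&P pattern
    iff the number of active cells equals ``n_ideal`` and no two active
    cells are 4-adjacent.  Contiguous stable runs yield the pattern times
    (average and maximum); the gaps between successive patterns yield the
    stabilizing times (the counter does not run during stable patterns and
    is reset when a new pattern forms).  A window with no pattern at all
    reports the full window as its stabilizing time.
    """
    if n_ideal <= 0:
        raise ValueError("n_ideal must be positive")
    T, n = traj.n_steps, traj.n_cells
    active = np.asarray(traj.signal_active, dtype=bool)
    stable = np.zeros(T, dtype=bool)
    hist = np.zeros(n + 1, dtype=np.int64)
    for t in range(T):
        act = np.nonzero(active[t])[0]
        hist[act.size] += 1
        if act.size != n_ideal:
            continue
        adjacent = False
        for a in range(act.size):
            for b in range(a + 1, act.size):
                if (int(traj.adj_mask[t, act[a]]) >> act[b]) & 1:
                    adjacent = True
                    break
            if adjacent:
                break
        stable[t] = not adjacent
    pattern_times = []
    stabilizing_times = []
    run = 0
    gap = 0
    for t in range(T):
        if stable[t]:
            if run == 0 and gap > 0:  # a new pattern forms
                stabilizing_times.append(gap)
                gap = 0
            run += 1
        else:
            if run > 0:  # pattern lost
                pattern_times.append(run)
                run = 0
            gap += 1
    if run > 0:
        pattern_times.append(run)
    if gap > 0 and not pattern_times and not stabilizing_times:
        stabilizing_times.append(gap)
    return SPStats(
        avg_pattern_time=float(np.mean(pattern_times)) if pattern_times
        else 0.0,
        max_pattern_time=float(max(pattern_times)) if pattern_times else 0.0,
        avg_stabilizing_time=float(np.mean(stabilizing_times))
        if stabilizing_times else 0.0,
        n_patterns=len(pattern_times),
        active_count_hist=hist)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test p-value on a 2x2 contingency table of
    tip counts (sums hypergeometric probabilities <= the observed table's)."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("fisher_exact requires non-zero margins")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
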