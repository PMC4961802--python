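"""Scenario orchestration: effector mechanisms, replicate sets with seeds,
k-value calibration sweeps and the named in-silico experiments."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel, metrics
from .cytoskeleton import FilopodiaParams
from .lattice import (KD, WT, ConfigurationError, LatticeConfig, SproutMesh,
                      assign_genotypes, build_sprout)
from .rearrangement import AdhesionParams, PottsParams
from .signalling import SignallingParams
from .trajectory import Trajectory

__all__ = [
    "MOSAIC_KD", "PHARMACOLOGICAL", "EffectorConfig", "ScenarioConfig",
    "CalibrationSpec", "RunSummary", "run_scenario", "run_replicates",
    "calibrate_single_effector", "calibrate_combo", "named_experiments",
    "generate_fixture_trajectory", "TIMESTEP_SECONDS", "ENDPOINT_24H",
    "ENDPOINT_125H", "TIP_FRACTION_1TO1", "TIP_FRACTION_9TO1",
]

MOSAIC_KD = "MOSAIC_KD"
PHARMACOLOGICAL = "PHARMACOLOGICAL"

MECHANISMS = ("FIL", "COR", "ADH", "FIL/COR", "FIL/ADH", "COR/ADH", "ALL")

#: 30 s of wall-clock angiogenesis per simulation timestep.
TIMESTEP_SECONDS = 30
ENDPOINT_24H = 24 * 3600 // TIMESTEP_SECONDS       # = 2,880 timesteps
ENDPOINT_125H = 125 * 3600 // TIMESTEP_SECONDS     # = 15,000 timesteps

#: In-vitro spheroid competition constants the k values are calibrated
#: against: knockdown tip-cell fractions in 1:1 and 9:1 mosaics.
TIP_FRACTION_1TO1 = 0.224
TIP_FRACTION_9TO1 = 0.668


@dataclass(frozen=True)
class EffectorConfig:
    """Which ATP effectors a mechanism perturbs, and how strongly.

    ``mechanism`` is one of FIL, COR, ADH, FIL/COR, FIL/ADH, COR/ADH, ALL
    (or None for wild type).  k values of effectors outside the mechanism
    are forced to 1.  MOSAIC_KD applies the k values only to KD-genotype
    cells; PHARMACOLOGICAL applies them to every cell.
    """

    mechanism: str | None = None
    k_fil: float = 1.0
    k_cor: float = 1.0
    k_adh: float = 1.0
    mode: str = MOSAIC_KD

    def __post_init__(self):
        if self.mechanism is not None and self.mechanism not in MECHANISMS:
            raise ConfigurationError(
                f"unknown mechanism {self.mechanism!r}; "
                f"legal: {MECHANISMS}")
        if self.mode not in (MOSAIC_KD, PHARMACOLOGICAL):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for name in ("fil", "cor", "adh"):
            if name.upper() not in self.effectors:
                object.__setattr__(self, f"k_{name}", 1.0)

    @property
    def effectors(self) -> frozenset:
        if self.mechanism is None:
            return frozenset()
        if self.mechanism == "ALL":
            return frozenset({"FIL", "COR", "ADH"})
        return frozenset(self.mechanism.split("/"))

    def per_cell_k(self, genotype: np.ndarray):
        """(k_fil, k_cor, k_adh) arrays per cell for this application mode."""
        n = genotype.shape[0]
        if self.mode == PHARMACOLOGICAL:
            mask = np.ones(n, dtype=bool)
        else:
            mask = np.asarray(genotype) == KD
        out = []
        for k in (self.k_fil, self.k_cor, self.k_adh):
            arr = np.ones(n)
            arr[mask] = k
            out.append(arr)
        return tuple(out)


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything one seeded simulation run needs."""

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    signalling: SignallingParams = field(default_factory=SignallingParams)
    filopodia: FilopodiaParams = field(default_factory=FilopodiaParams)
    adhesion: AdhesionParams = field(default_factory=AdhesionParams)
    potts: PottsParams = field(default_factory=PottsParams)
    effector: EffectorConfig = field(default_factory=EffectorConfig)
    ratio: tuple = (1, 1)          #: (kd, wt); mosaic genotype ratio
    total_timesteps: int = ENDPOINT_125H
    n_replicates: int = 50

    def __post_init__(self):
        if self.total_timesteps <= self.potts.stabilization:
            raise ConfigurationError(
                "total_timesteps must exceed the stabilization period")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")

    def to_json(self) -> str:
        def enc(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: getattr(obj, k)
                        for k in obj.__dataclass_fields__}
            return str(obj)
        return json.dumps(self, default=enc, indent=2)


@dataclass
class RunSummary:
    """Endpoint metrics of one seeded run."""

    seed: int
    tip_cell: int
    tip_genotype: int
    overtakes: int
    migrated: np.ndarray
    sp: metrics.SPStats
    adhesion: dict
    filopodia_count_mean: np.ndarray
    filopodia_length_mean: np.ndarray
    time_at_tip: dict


def run_scenario(config: ScenarioConfig, seed: int, *,
                 keep_trajectory: bool = True, snapshot_every: int = 0,
                 record_from: int | None = None
                 ) -> tuple[Trajectory | None, RunSummary]:
    """One seeded simulation: build, place genotypes, stabilize signalling
    for the movement-free period, run full dynamics to the endpoint, and
    score the post-stabilization window.  Same (config, seed) gives
    bit-identical output."""
    mesh = assign_genotypes(build_sprout(config.lattice), config.ratio, seed)
    if record_from is None:
        record_from = min(config.potts.stabilization,
                          config.total_timesteps - 1)
    kfil, kcor, kadh = config.effector.per_cell_k(mesh.genotype)
    sig, fil = config.signalling, config.filopodia
    adh, potts = config.adhesion, config.potts
    rec, tip_rec, adj_rec, snaps = _kernel.simulate(
        mesh.owner, kfil, kcor, kadh,
        sig.v_max, sig.k_sat, sig.v0, sig.g, sig.m, sig.delta_d, sig.d_half, sig.d_max,
        sig.sigma, sig.tau, sig.w, sig.theta_d, sig.theta_v, sig.dapt,
        sig.su_fold, sig.noise_sd, sig.beta_filo, sig.l_sat, sig.rho_d,
        sig.rho_r,
        fil.a_max, fil.c, fil.l_max, fil.p_ret, fil.retract_thresh,
        adh.eta, potts.lambda_mig, potts.temperature, potts.lambda_area,
        potts.j0, adh.alpha_strong, adh.alpha_weak, potts.j_cm,
        potts.gamma_per,
        config.lattice.circumference // config.lattice.cells_per_cross_section,
        potts.lambda_width, potts.n_attempts, potts.side_bias, potts.mu_mig,
        potts.strong_motility, potts.nhat_scale,
        float(np.floor((1 - potts.area_band) * config.lattice.target_area)),
        float(np.ceil((1 + potts.area_band) * config.lattice.target_area)),
        float(config.lattice.target_area),
        config.total_timesteps, potts.stabilization, seed,
        record_from, snapshot_every)
    traj = Trajectory.from_kernel(rec, tip_rec, adj_rec, mesh.genotype,
                                  record_from)
    tip = int(traj.tip[-1])
    summary = RunSummary(
        seed=seed,
        tip_cell=tip,
        tip_genotype=int(mesh.genotype[tip]),
        overtakes=metrics.count_overtakes(traj),
        migrated=np.abs(np.diff(traj.com_x, axis=0)).sum(axis=0),
        sp=metrics.score_sp_patterns(traj),
        adhesion=metrics.adhesion_strength_summary(traj),
        filopodia_count_mean=traj.filo_count.mean(axis=0),
        filopodia_length_mean=traj.filo_mean_length().mean(axis=0),
        time_at_tip=metrics.time_at_tip_by_initial_rank(traj))
    if snapshot_every > 0:
        summary.snapshots = snaps  # ad hoc attachment for consistency tests
    return (traj if keep_trajectory else None), summary


@dataclass
class ReplicateResult:
    """Aggregate over a seeded replicate set."""

    config: ScenarioConfig
    summaries: list
    tip: metrics.TipCompetitionResult
    fisher_p_vs_expected: float

    @property
    def kd_tip_fraction(self) -> float:
        return self.tip.fraction(KD)

    def mean(self, attr: str) -> float:
        return float(np.mean([getattr(s, attr) for s in self.summaries]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            rows.append({
                "seed": s.seed, "tip_cell": s.tip_cell,
                "tip_genotype": s.tip_genotype, "overtakes": s.overtakes,
                "avg_pattern_time": s.sp.avg_pattern_time,
                "max_pattern_time": s.sp.max_pattern_time,
                "avg_stabilizing_time": s.sp.avg_stabilizing_time,
                "n_patterns": s.sp.n_patterns,
            })
        return pd.DataFrame(rows)


def run_replicates(config: ScenarioConfig, n: int | None = None,
                   base_seed: int = 0) -> ReplicateResult:
    """Run seeds base_seed .. base_seed+n-1 and aggregate.

    The Fisher test compares observed KD/WT tip counts against the counts
    expected from the mosaic ratio (e.g. 50:50 or 90:10).
    """
    if n is None:
        n = config.n_replicates
    if n < 1:
        raise ConfigurationError("need at least one replicate")
    summaries = []
    for i in range(n):
        _, s = run_scenario(config, base_seed + i, keep_trajectory=False)
        summaries.append(s)
    tip = metrics.tip_contribution([s.tip_genotype for s in summaries])
    kd_tips = tip.counts.get(KD, 0)
    kd, wt = config.ratio
    exp_kd = round(n * kd / (kd + wt))
    table = np.array([[kd_tips, n - kd_tips], [exp_kd, n - exp_kd]])
    if (table.sum(axis=0) == 0).any():
        p = 1.0  # degenerate margin: no evidence of association
    else:
        p = metrics.fisher_exact(table)
    return ReplicateResult(config=config, summaries=summaries, tip=tip,
                           fisher_p_vs_expected=p)


@dataclass(frozen=True)
class CalibrationSpec:
    """Grid sweep specification for matching the in-vitro competition data."""

    mechanism: str = "FIL"
    grid: tuple = tuple(np.round(np.linspace(0.0, 1.0, 11), 3))
    target_1to1: float = TIP_FRACTION_1TO1
    target_9to1: float = TIP_FRACTION_9TO1
    n_replicates: int = 50
    n_refine: int = 150
    total_timesteps: int = ENDPOINT_24H
    base_seed: int = 0

    def __post_init__(self):
        if not self.grid:
            raise ConfigurationError("calibration grid is empty")
        if not all(0.0 <= k <= 2.0 for k in self.grid):
            raise ConfigurationError("grid values must lie in [0, 2]")
        if not (0 < self.target_1to1 < 1 and 0 < self.target_9to1 < 1):
            raise ConfigurationError("targets must lie in (0, 1)")


@dataclass
class CalibrationResult:
    k_star: float
    sweep: pd.DataFrame       # columns: k, ratio, kd_fraction, ci_lo, ci_hi
    fraction_1to1: float
    fraction_9to1: float
    within_ci: bool


def _binomial_ci(frac: float, n: int) -> tuple[float, float]:
    half = 1.96 * np.sqrt(max(frac * (1 - frac), 1e-12) / n)
    return max(0.0, frac - half), min(1.0, frac + half)


def _mechanism_config(mechanism: str, ks: dict, ratio, total_timesteps,
                      mode=MOSAIC_KD, base: ScenarioConfig | None = None
                      ) -> ScenarioConfig:
    base = base or ScenarioConfig()
    eff = EffectorConfig(mechanism=mechanism, mode=mode, **ks)
    return replace(base, effector=eff, ratio=ratio,
                   total_timesteps=total_timesteps)


def calibrate_single_effector(spec: CalibrationSpec,
                              base: ScenarioConfig | None = None
                              ) -> CalibrationResult:
    """Sweep a single effector's k over the grid against both mosaic ratios
    and select the k minimising the summed squared deviation of the
    simulated knockdown tip fractions from the in-vitro constants
    (0.224 at 1:1, 0.668 at 9:1)."""
    if spec.mechanism not in ("FIL", "COR", "ADH"):
        raise ConfigurationError("single-effector calibration needs a "
                                 "single mechanism")
    key = f"k_{spec.mechanism.lower()}"
    rows = []
    losses = []
    for k in spec.grid:
        fracs = {}
        for ratio, target in (((1, 1), spec.target_1to1),
                              ((9, 1), spec.target_9to1)):
            cfg = _mechanism_config(spec.mechanism, {key: float(k)}, ratio,
                                    spec.total_timesteps, base=base)
            res = run_replicates(cfg, spec.n_replicates, spec.base_seed)
            frac = res.kd_tip_fraction
            lo, hi = _binomial_ci(frac, spec.n_replicates)
            rows.append({"k": float(k), "ratio": f"{ratio[0]}:{ratio[1]}",
                         "kd_fraction": frac, "ci_lo": lo, "ci_hi": hi})
            fracs[ratio] = frac
        losses.append((fracs[(1, 1)] - spec.target_1to1) ** 2
                      + (fracs[(9, 1)] - spec.target_9to1) ** 2)
    k_star = float(spec.grid[int(np.argmin(losses))])
    # refinement pass at the selected point
    final = {}
    for ratio in ((1, 1), (9, 1)):
        cfg = _mechanism_config(spec.mechanism, {key: k_star}, ratio,
                                spec.total_timesteps, base=base)
        res = run_replicates(cfg, spec.n_refine, spec.base_seed)
        final[ratio] = res.kd_tip_fraction
    ok = True
    for ratio, target in (((1, 1), spec.target_1to1),
                          ((9, 1), spec.target_9to1)):
        lo, hi = _binomial_ci(final[ratio], spec.n_refine)
        ok = ok and (lo <= target <= hi)
    return CalibrationResult(k_star=k_star, sweep=pd.DataFrame(rows),
                             fraction_1to1=final[(1, 1)],
                             fraction_9to1=final[(9, 1)], within_ci=ok)


def calibrate_combo(mechanism: str, s_grid, spec: CalibrationSpec | None
                    = None, base: ScenarioConfig | None = None
                    ) -> tuple[dict, CalibrationResult]:
    """Calibrate a combinatorial mechanism through one shared sweep
    parameter s: every contributing effector is perturbed by the same
    fractional extent, k_X = 1 - s; non-contributing k values stay 1."""
    spec = spec or CalibrationSpec(mechanism=mechanism)
    eff = EffectorConfig(mechanism=mechanism).effectors
    if len(eff) < 2:
        raise ConfigurationError("combo calibration needs >= 2 effectors")
    rows = []
    losses = []
    for s in s_grid:
        ks = {f"k_{e.lower()}": 1.0 - float(s) for e in eff}
        fracs = {}
        for ratio, target in (((1, 1), spec.target_1to1),
                              ((9, 1), spec.target_9to1)):
            cfg = _mechanism_config(mechanism, ks, ratio,
                                    spec.total_timesteps, base=base)
            res = run_replicates(cfg, spec.n_replicates, spec.base_seed)
            frac = res.kd_tip_fraction
            lo, hi = _binomial_ci(frac, spec.n_replicates)
            rows.append({"k": 1.0 - float(s),
                         "ratio": f"{ratio[0]}:{ratio[1]}",
                         "kd_fraction": frac, "ci_lo": lo, "ci_hi": hi})
            fracs[ratio] = frac
        losses.append((fracs[(1, 1)] - spec.target_1to1) ** 2
                      + (fracs[(9, 1)] - spec.target_9to1) ** 2)
    s_star = float(np.asarray(s_grid)[int(np.argmin(losses))])
    ks_star = {f"k_{e.lower()}": 1.0 - s_star for e in eff}
    final = {}
    for ratio in ((1, 1), (9, 1)):
        cfg = _mechanism_config(mechanism, ks_star, ratio,
                                spec.total_timesteps, base=base)
        res = run_replicates(cfg, spec.n_refine, spec.base_seed)
        final[ratio] = res.kd_tip_fraction
    ok = True
    for ratio, target in (((1, 1), spec.target_1to1),
                          ((9, 1), spec.target_9to1)):
        lo, hi = _binomial_ci(final[ratio], spec.n_refine)
        ok = ok and (lo <= target <= hi)
    full = {"k_fil": 1.0, "k_cor": 1.0, "k_adh": 1.0}
    full.update(ks_star)
    return full, CalibrationResult(k_star=1.0 - s_star,
                                   sweep=pd.DataFrame(rows),
                                   fraction_1to1=final[(1, 1)],
                                   fraction_9to1=final[(9, 1)],
                                   within_ci=ok)


def named_experiments(k_fil: float = 0.1, k_adh: float = 0.7) -> dict:
    """Registry of ready-made scenario configurations for the in-silico
    experiments: mosaic competition controls, DAPT, elevated-VEGF
    disorganization, pharmacological PFKFB3 inhibition (non-mosaic) and the
    combined VEGFR2-blockade rescue.  ``k_fil``/``k_adh`` are the calibrated
    effector constants to use for the knockdown/inhibition scenarios.
    """
    base = ScenarioConfig()
    sig = base.signalling
    reg = {
        "competition_1to1": replace(
            base, ratio=(1, 1),
            effector=EffectorConfig("FIL", k_fil=k_fil), n_replicates=150),
        "competition_9to1": replace(
            base, ratio=(9, 1),
            effector=EffectorConfig("FIL", k_fil=k_fil), n_replicates=150),
        "control_1to1": replace(base, ratio=(1, 1), n_replicates=150),
        "control_9to1": replace(base, ratio=(9, 1), n_replicates=150),
        "dapt_mosaic": replace(
            base, ratio=(1, 1), signalling=replace(sig, dapt=True),
            effector=EffectorConfig("FIL", k_fil=k_fil)),
        "combo_rescue_10x": replace(
            base, signalling=replace(sig, m=10.0, su_fold=6.0),
            effector=EffectorConfig("FIL/ADH", k_fil=k_fil, k_adh=k_adh,
                                    mode=PHARMACOLOGICAL)),
    }
    for mult, tag in ((1.44, "1.44x"), (2.0, "2x"), (10.0, "10x")):
        reg[f"vegf_{tag}"] = replace(base,
                                     signalling=replace(sig, m=mult))
        reg[f"vegf_{tag}_pi_fil"] = replace(
            base, signalling=replace(sig, m=mult),
            effector=EffectorConfig("FIL", k_fil=k_fil,
                                    mode=PHARMACOLOGICAL))
        reg[f"vegf_{tag}_pi_fil_adh"] = replace(
            base, signalling=replace(sig, m=mult),
            effector=EffectorConfig("FIL/ADH", k_fil=k_fil, k_adh=k_adh,
                                    mode=PHARMACOLOGICAL))
        reg[f"vegf_{tag}_pi_fil_cor"] = replace(
            base, signalling=replace(sig, m=mult),
            effector=EffectorConfig("FIL/COR", k_fil=k_fil, k_cor=k_adh,
                                    mode=PHARMACOLOGICAL))
    for f in (1, 2, 3, 4, 5, 6):
        reg[f"su5416_10x_f{f}"] = replace(
            base, signalling=replace(sig, m=10.0, su_fold=float(f)))
    return reg


def generate_fixture_trajectory(spec: dict) -> Trajectory:
    """Build a schema-complete Trajectory from a handwritten specification
    (metric unit-testing without the simulator).

    ``spec`` maps field names to per-timestep per-cell lists; required:
    ``timesteps`` (T,), ``genotype`` (n,) and ``com_x`` (T, n).  Omitted
    per-cell fields default to zeros, ``tip`` to -1 and ``adj_mask`` to 0.
    """
    try:
        timesteps = np.asarray(spec["timesteps"])
        genotype = np.asarray(spec["genotype"], dtype=np.int8)
        com_x = np.asarray(spec["com_x"], dtype=float)
    except KeyError as e:
        raise ValueError(f"fixture spec is missing required field {e}")
    T, n = com_x.shape
    fields = {}
    for name in ("com_y", "vp", "dll", "notch", "vhat", "nhat", "strong",
                 "signal_active", "deployed", "filo_count",
                 "filo_len_total"):
        arr = np.asarray(spec.get(name, np.zeros((T, n))), dtype=float)
        if arr.shape != (T, n):
            raise ValueError(f"fixture field {name} has shape {arr.shape}, "
                             f"expected {(T, n)}")
        fields[name] = arr
    tip = np.asarray(spec.get("tip", np.full(T, -1)), dtype=np.int64)
    adj = np.asarray(spec.get("adj_mask", np.zeros((T, n))), dtype=np.int64)
    return Trajectory(timesteps=timesteps, genotype=genotype, com_x=com_x,
                      tip=tip, adj_mask=adj, **fields)
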