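"""Discrete-time VEGF -> VEGFR2 -> Dll4 -> Notch lateral inhibition.

Model sketch
------------
Each cell carries a VEGFR2 capacity R_c in [0, V_max] shared equally among
its M_tot memAgents.  A memAgent at axial position x binds the local VEGF
with saturating signalling-competent occupancy
s(x) = min(1, m*(V0 + g*x) / (K_sat * f)), where f >= 1 models VEGFR2
kinase inhibition (an exact f-fold activation division in the unsaturated
regime), so its activation is V'_m = (R_c / M_tot) * s(x).  Filopodium
sites are VEGFR2-enriched by a factor beta — the positive feedback by
which filopodia amplify lateral inhibition.  Summed activation Vp_c
(clamped at R_c) drives delayed, sigmoidal, saturating Dll4 production;
neighbour Dll4, weighted by shared-boundary fraction (per-junction
transfer saturating at l_sat sites), activates Notch, which
down-regulates the VEGFR2 capacity through a saturating Hill law after
the same expression delay tau.  "Effective" levels Vhat/Nhat are trailing
moving averages over W timesteps and feed the slower adhesion and
cortical-protrusion machinery.

High VEGF is pathological because saturation destroys the differential:
as occupancy approaches 1 everywhere, even Notch-inhibited cells re-enter
the Dll4-producing regime, mutual inhibition turns global, and the
salt-and-pepper pattern gives way to disorganized, near-homogeneous
activity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernel
from ._kernel import (saturation_profile, seed_rng, step_signalling_kernel,
                      vegf_profile)
from .lattice import SproutMesh

__all__ = [
    "SignallingParams", "SignallingState", "vegf_at", "update_signalling",
    "classify_signal_active", "apply_su5416",
]


@dataclass(frozen=True)
class SignallingParams:
    """Gains, delays and thresholds of the lateral-inhibition loop.

    Defaults are fixed by the patterning calibration criterion: a 10-cell
    sprout at normal VEGF must settle into a stable pattern of exactly three
    non-adjacent active cells within the 1,000-timestep stabilization
    window.
    """

    v_max: float = 100.0     #: maximal VEGFR2 capacity per cell (a.u.)
    k_sat: float = 1.0       #: VEGF saturation constant (conc. units)
    v0: float = 0.25         #: VEGF gradient intercept at the sprout rear
    g: float = 0.01          #: VEGF gradient slope per axial site
    m: float = 1.0           #: VEGF multiplier (1, 1.44, 2, 10)
    delta_d: float = 1.0     #: Dll4 production gain on active VEGFR2
    d_half: float = 25.0     #: active VEGFR2 at half-maximal Dll4 production
    d_max: float = 120.0     #: Dll4 cap (the high-VEGF saturation point)
    sigma: float = 6.0       #: Notch -> VEGFR2 capacity inhibition gain
    tau: int = 5             #: expression delay, timesteps (2.5 min)
    w: int = 60              #: effective-level smoothing window, timesteps
    theta_d: float = 20.0    #: Dll4 activation threshold
    theta_v: float = 20.0    #: active-VEGFR2 activation threshold
    dapt: bool = False       #: remove Notch signalling between all cells
    su_fold: float = 1.0     #: VEGFR2-signalling reduction factor f >= 1
    noise_sd: float = 0.03   #: multiplicative per-step noise on Vp
    beta_filo: float = 10.0  #: VEGFR2 enrichment of filopodium sites
    l_sat: float = 5.0       #: junction saturation length for Notch weights
    rho_d: float = 0.1       #: Dll4 relaxation rate toward delayed target
    rho_r: float = 0.1       #: VEGFR2-capacity relaxation rate

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("VEGF multiplier m must be > 0")
        if self.su_fold < 1:
            raise ValueError("su_fold must be >= 1")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if min(self.delta_d, self.sigma) < 0:
            raise ValueError("gains must be >= 0")
        if min(self.theta_d, self.theta_v) <= 0:
            raise ValueError("thresholds must be > 0")


class SignallingState:
    """Per-cell signalling levels plus the delay and smoothing buffers."""

    def __init__(self, n_cells: int, params: SignallingParams):
        self.n_cells = n_cells
        self.t = 0
        self.r_cap = np.full(n_cells, params.v_max)
        self.vp = np.zeros(n_cells)
        self.dll = np.zeros(n_cells)
        self.notch = np.zeros(n_cells)
        self.vhat = np.zeros(n_cells)
        self.nhat = np.zeros(n_cells)
        self.dbuf = np.zeros((n_cells, params.tau))
        self.rbuf = np.full((n_cells, params.tau), params.v_max)
        self.vwin = np.zeros((n_cells, params.w))
        self.nwin = np.zeros((n_cells, params.w))
        self.nhat_max = 0.0  #: sprout-wide maximum of Nhat this step


def vegf_at(x, params: SignallingParams):
    """VEGF concentration at axial position x: m*(V0 + g*x), clipped at 0."""
    v = params.m * (params.v0 + params.g * np.asarray(x, dtype=float))
    return np.maximum(v, 0.0)


def update_signalling(mesh: SproutMesh, state: SignallingState,
                      params: SignallingParams, *,
                      noise: bool = False, seed: int | None = None
                      ) -> SignallingState:
    """Advance the signalling state one timestep on the current mesh.

    Mutates and returns ``state``.  Noise is off by default so the update is
    a deterministic map (the fused simulator enables it); pass a seed to
    reseed the kernel RNG first.
    """
    if seed is not None:
        seed_rng(seed)
    svals = saturation_profile(mesh.config.axial_length, params.v0, params.g,
                               params.m, params.k_sat, params.su_fold)
    ssum_body, n_body = _kernel.body_activation(mesh.owner, svals,
                                                mesh.n_cells)
    ssum_filo, n_filo = _kernel.filopodia_activation(
        mesh.filo_len, mesh.filo_base, svals, params.beta_filo)
    _, _, lmat, *_ = _kernel.scan_mesh(mesh.owner, mesh.n_cells)
    state.nhat_max = step_signalling_kernel(
        state.t, ssum_body, n_body, ssum_filo, n_filo, lmat,
        state.r_cap, state.vp, state.dll, state.notch, state.dbuf,
        state.rbuf, state.vwin, state.nwin, state.vhat, state.nhat,
        state.nhat_max,
        params.v_max, params.delta_d, params.d_half, params.d_max, params.sigma,
        params.tau, params.w, params.l_sat, params.rho_d, params.rho_r,
        1.0, params.dapt, params.noise_sd, noise)
    state.t += 1
    return state


def classify_signal_active(dll, vp, theta_d: float, theta_v: float):
    """Signal-active iff Dll4 >= theta_D and active VEGFR2 >= theta_V
    (boundary inclusive); independent of the actin pool."""
    return np.logical_and(np.asarray(dll) >= theta_d,
                          np.asarray(vp) >= theta_v)


def apply_su5416(params: SignallingParams, fold: float) -> SignallingParams:
    """Reduce VEGFR2 signalling activity ``fold``-times (kinase inhibition);
    per-site activation is divided by the factor."""
    if fold < 1:
        raise ValueError("su5416 fold reduction must be >= 1")
    return replace(params, su_fold=float(fold))
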