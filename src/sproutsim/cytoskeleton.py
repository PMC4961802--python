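"""Actin pool bookkeeping and stochastic filopodia dynamics.

Each cell owns a fixed pool of A_max actin units; a deployed unit occupies
one filopodium site.  Filopodia are 1-site-wide axial chains in a layer
above the body lattice, anchored at the cell's frontmost body site of each
column it owns — the 2-D surrogate of filopodia probing up the VEGF
gradient.  They carry receptors (amplifying signalling; see
:mod:`sproutsim.signalling`) but never count as cell-body occupancy for the
tip rule.  The ATP effector E^FIL scales the extension probability through
k_FIL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import scan_mesh, seed_rng, step_filopodia_kernel, \
    saturation_profile
from .lattice import SproutMesh
from .signalling import SignallingParams, SignallingState

__all__ = ["ActinPool", "FilopodiaParams", "filopodia_extension_probability",
           "step_filopodia", "filopodia_stats"]


@dataclass
class ActinPool:
    """Conserved per-cell actin budget: deployed + free = A_max always."""

    a_max: int = 60
    deployed: int = 0

    @property
    def free(self) -> int:
        return self.a_max - self.deployed


@dataclass(frozen=True)
class FilopodiaParams:
    c: float = 0.1              #: VEGFR2 -> actin activation strength
    l_max: int = 12             #: maximal filopodium length, sites
    p_ret: float = 0.05         #: per-step spontaneous tip retraction prob.
    retract_thresh: float = 0.15  #: normalised activation below which a tip
    #: retracts deterministically (R_c * s / (V_max f) < threshold)
    a_max: int = 60             #: actin units per cell
    k_fil: float = 1.0          #: ATP modifier of E^FIL (1 = wild type)

    def __post_init__(self):
        if not (0.0 <= self.p_ret <= 1.0):
            raise ValueError("p_ret must be a probability")
        if self.l_max < 1:
            raise ValueError("l_max must be >= 1")


def filopodia_extension_probability(vprime: float, m_tot: int, free_actin: int,
                                    params: FilopodiaParams,
                                    v_max: float = 100.0,
                                    k_fil: float | None = None) -> float:
    """Extension probability of one eligible memAgent.

    p = min(1, k_FIL * C * V'_m / (V_max / M_tot)): the memAgent's active
    VEGFR2 relative to its per-memAgent receptor capacity, scaled by the
    activation strength C and the ATP modifier k_FIL.  Forced to 0 with no
    free actin.
    """
    if free_actin < 1:
        return 0.0
    if k_fil is None:
        k_fil = params.k_fil
    if m_tot < 1:
        m_tot = 1
    p = k_fil * params.c * vprime / (v_max / m_tot)
    return float(min(1.0, max(0.0, p)))


def step_filopodia(mesh: SproutMesh, state: SignallingState,
                   params: FilopodiaParams, sig: SignallingParams,
                   *, seed: int | None = None,
                   k_fil: np.ndarray | None = None) -> SproutMesh:
    """One stochastic extension/retraction sweep (mutates ``mesh``).

    Eligible sites are the per-column chain tips (or fresh anchors); each
    extends with :func:`filopodia_extension_probability`, consuming one actin
    unit; tips retract spontaneously with p_ret or deterministically at low
    local activation; retraction returns actin to the pool; chains whose
    anchor moved retract entirely.  Lengths never exceed l_max.
    """
    if seed is not None:
        seed_rng(seed)
    n = mesh.n_cells
    if k_fil is None:
        k_fil = np.full(n, params.k_fil)
    svals = saturation_profile(mesh.config.axial_length, sig.v0, sig.g,
                               sig.m, sig.k_sat, sig.su_fold)
    _, n_body, _, frontmost, *_ = scan_mesh(mesh.owner, n)
    m_tot = (n_body + mesh.filo_len.sum(axis=1)).astype(np.int64)
    deployed = mesh.filo_len.sum(axis=1).astype(np.int64)
    step_filopodia_kernel(mesh.owner, mesh.filo_len, mesh.filo_base,
                          deployed, frontmost, state.r_cap, m_tot, svals,
                          np.asarray(k_fil, dtype=np.float64),
                          params.c, sig.v_max, 1.0, params.a_max,
                          params.l_max, params.p_ret, params.retract_thresh)
    return mesh


def filopodia_stats(mesh: SproutMesh, cell_id: int) -> tuple[int, float]:
    """(number of chains, mean chain length in sites) for one cell;
    (0, 0.0) when the cell has no filopodia."""
    lens = mesh.filo_len[cell_id]
    chains = lens[lens > 0]
    if chains.size == 0:
        return 0, 0.0
    return int(chains.size), float(chains.mean())
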