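"""Cellular-Potts junctional dynamics: differential adhesion, cortical
protrusion gating and Metropolis acceptance of boundary moves.

A boundary move copies a site's owner into a 4-neighbour site.  A cell's
protrusive activity is k_COR * (1 - Nhat/Nhat_scale), further reduced for
strongly adhesive cells (stable VE-cadherin junctions suppress protrusive
actin).  Frontward expansions are cortical protrusions (E^COR): attempted
at lambda * activity and carrying chemotactic work mu * activity along
the VEGF gradient; sideways/rearward expansions are passive junction
fluctuations attempted at the constant rate side_bias.  Adhesion enters the
contact energy through the binary E^ADH classification: strongly adhesive
pairs form low-energy interfaces that are hard to break.  Notch-inhibited
and strongly adhesive cells therefore rarely advance, which is what
drives differential motility and tip competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernel import (attempt_moves_kernel, column_counts, connectivity_ok,
                      delta_hamiltonian, scan_mesh, seed_rng)
from .lattice import SproutMesh
from .signalling import SignallingState

__all__ = ["STRONG", "WEAK", "AdhesionParams", "PottsParams",
           "classify_adhesion", "cortical_protrusion_probability",
           "hamiltonian_delta", "step_rearrangement"]

STRONG = "STRONG"
WEAK = "WEAK"


@dataclass(frozen=True)
class AdhesionParams:
    """Binary adhesive-strength classification (E^ADH).

    High effective VEGFR2 activity means more VE-cadherin endocytosis and
    hence weak adhesion; eta is the calibrated threshold on Vhat.  k_ADH
    multiplies Vhat before thresholding (equivalent to dividing eta), so
    k_ADH < 1 — reduced ATP, slower VE-cadherin turnover — shifts cells
    toward strong adhesion.
    """

    eta: float = 55.0
    k_adh: float = 1.0
    alpha_strong: float = 2.0   #: contact-energy bonus, strongly adhesive
    alpha_weak: float = 0.5     #: contact-energy bonus, weakly adhesive

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if not self.alpha_strong > self.alpha_weak >= 0:
            raise ValueError("need alpha_strong > alpha_weak >= 0")
        if self.k_adh < 0:
            raise ValueError("k_adh must be >= 0")


@dataclass(frozen=True)
class PottsParams:
    lambda_mig: float = 0.6    #: migratory capacity (protrusion attempt rate)
    k_cor: float = 1.0         #: ATP modifier of E^COR (1 = wild type)
    temperature: float = 1.5   #: Metropolis temperature
    lambda_area: float = 0.4   #: soft area-constraint stiffness
    j0: float = 4.5            #: baseline cell-cell contact energy
    j_cm: float = 2.0          #: cell-medium contact energy
    gamma_per: float = 0.2     #: cortex tension per unit perimeter
    lambda_width: float = 1.0  #: penalty on circumferential spread beyond
    #: the resting cross-section width (cells resist annularising)
    n_attempts: int = 150      #: boundary-move attempts per timestep
    side_bias: float = 0.3     #: attempt probability of passive (sideways/
    #: rearward) junction fluctuations; frontward expansion is the actively
    #: gated cortical protrusion
    mu_mig: float = 0.5        #: chemotactic work per site of frontward
    #: expansion (generated by the protrusion machinery, so scaled by the
    #: cell's protrusive activity)
    strong_motility: float = 0.3  #: protrusive-activity factor of strongly
    #: adhesive cells (stable junctions suppress protrusive actin)
    nhat_scale: float = 50.0   #: effective-Notch level of a fully
    #: inhibited cell; normalises the protrusion suppression
    area_band: float = 0.2     #: hard volume guard: moves may not push a
    #: territory beyond +-this fraction of the target area
    stabilization: int = 1000  #: timesteps with movement disabled

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_attempts < 1:
            raise ValueError("n_attempts must be >= 1")


def classify_adhesion(vhat: float, params: AdhesionParams,
                      k_adh: float | None = None) -> str:
    """WEAK iff k_ADH * Vhat >= eta (boundary inclusive), else STRONG."""
    k = params.k_adh if k_adh is None else k_adh
    return WEAK if k * vhat >= params.eta else STRONG


def cortical_protrusion_probability(nhat: float, nhat_max: float,
                                    params: PottsParams,
                                    k_cor: float | None = None) -> float:
    """p = min(1, k_COR * lambda * (1 - Nhat/Nhat_max)): effective active
    Notch, normalised to [0, 1] by the sprout's current maximum, suppresses
    junctional cortex protrusions."""
    k = params.k_cor if k_cor is None else k_cor
    frac = 0.0 if nhat_max <= 0 else min(1.0, nhat / nhat_max)
    return float(min(1.0, max(0.0, k * params.lambda_mig * (1.0 - frac))))


def hamiltonian_delta(mesh: SproutMesh, site_a: tuple[int, int],
                      site_b: tuple[int, int], adhesion: AdhesionParams,
                      potts: PottsParams,
                      strong: np.ndarray) -> tuple[float, bool]:
    """Energy change of copying owner(a) into the 4-adjacent site b.

    Returns (dH, ok); ok is False — with dH = 0 — when the move would
    disconnect or annihilate the losing cell's territory (rejected before
    evaluation, flagged rather than raised).
    """
    ax_, ay_ = site_a
    bx, by = site_b
    circ = mesh.config.circumference
    dx, dy = bx - ax_, (by - ay_) % circ
    if not ((abs(dx) == 1 and dy == 0) or (dx == 0 and dy in (1, circ - 1))):
        raise ValueError("sites must be 4-adjacent (wrap-aware)")
    new_owner = int(mesh.owner[ax_, ay_])
    old_owner = int(mesh.owner[bx, by])
    if old_owner == new_owner:
        return 0.0, True
    if old_owner >= 0 and not connectivity_ok(mesh.owner, bx, by):
        return 0.0, False
    area = mesh.areas()
    colcount, ncols = column_counts(mesh.owner, mesh.n_cells)
    width0 = mesh.config.circumference // mesh.config.cells_per_cross_section
    dh = delta_hamiltonian(
        mesh.owner, bx, by, new_owner,
        np.asarray(strong, dtype=np.uint8), area,
        float(mesh.config.target_area), potts.lambda_area, potts.j0,
        adhesion.alpha_strong, adhesion.alpha_weak, potts.j_cm,
        potts.gamma_per, colcount, ncols, width0, potts.lambda_width)
    return float(dh), True


def step_rearrangement(mesh: SproutMesh, state: SignallingState,
                       adhesion: AdhesionParams, potts: PottsParams,
                       *, seed: int | None = None,
                       k_cor: np.ndarray | None = None,
                       k_adh: np.ndarray | None = None) -> SproutMesh:
    """One timestep of Metropolis boundary dynamics (mutates ``mesh``)."""
    if seed is not None:
        seed_rng(seed)
    n = mesh.n_cells
    if k_cor is None:
        k_cor = np.full(n, potts.k_cor)
    if k_adh is None:
        k_adh = np.full(n, adhesion.k_adh)
    strong = (np.asarray(k_adh) * state.vhat < adhesion.eta).astype(np.uint8)
    area, _, _, _, front_row, _ = scan_mesh(mesh.owner, n)
    colcount, ncols = column_counts(mesh.owner, n)
    width0 = mesh.config.circumference // mesh.config.cells_per_cross_section
    attempt_moves_kernel(
        mesh.owner, strong, area, np.asarray(k_cor, dtype=np.float64),
        state.nhat, state.nhat_max, front_row,
        float(mesh.config.target_area), potts.lambda_mig,
        potts.temperature, potts.lambda_area, potts.j0,
        adhesion.alpha_strong, adhesion.alpha_weak, potts.j_cm,
        potts.gamma_per, colcount, ncols, width0, potts.lambda_width,
        potts.n_attempts, potts.side_bias, potts.mu_mig,
        potts.strong_motility, potts.nhat_scale,
        float(np.floor((1 - potts.area_band) * mesh.config.target_area)),
        float(np.ceil((1 + potts.area_band) * mesh.config.target_area)),
    )
    return mesh
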