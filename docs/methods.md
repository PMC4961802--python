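# Model and methods

This note documents the model implemented in `sproutsim`: its assumptions,
the parameters that matter, the numerical choices, and what the simulated
conditions do and do not show about real sprouts.

## Geometry

The sprout surface is modelled as a 2-D lattice on the unrolled vessel
wall: axis `x` runs along the sprout (increasing toward the front), axis
`y` around the circumference (10 sites, periodic). Each site is a unit
square owned by one endothelial cell or by the medium. The initial sprout
tiles 5 axial bands of 2 cells each (50 sites per cell, 10 axial × 5
circumferential); alternate bands are offset by half a territory width
(brick-like), so every cell contacts both cells of the neighbouring
cross-sections, as on a real cylindrical sprout where territories are not
aligned. This staggering is what makes the ideal salt-and-pepper pattern of
the 10-cell sprout contain exactly three active cells: actives must occupy
alternate bands, one cell per band. With aligned seams the contact graph
degenerates to a ladder that admits a five-active checkerboard.

The original membrane-agent formulation represents each cell as hundreds of
spring-connected membrane agents in 3-D. Here, memAgents are the territory
sites with at least one non-owner 4-neighbour plus all filopodium sites,
and the Hookean cortex is replaced by a perimeter-tension energy in the
rearrangement Hamiltonian. This preserves the observables the scoring
methods consume (front-window occupancy, centres of mass, junction
adjacency, filopodia counts) at a small fraction of the cost.

Rationale for two further geometric choices:

- **Centres of mass** are computed over boundary (cell-body) memAgents
  only, with a circular mean circumferentially. On this coarse lattice a
  single 12-site filopodium would otherwise displace the COM by whole site
  units — on the dense 3-D membrane mesh filopodia carry a negligible share
  of agents. Position metrics therefore track cell bodies, the same
  convention the tip rule uses.
- **Cells cannot annularise**: a quadratic penalty on circumferential
  spread beyond the resting cross-section width (5 columns) represents
  cortical polarity. Without it the boundary-minimising dynamics dissolve
  the two-cells-per-cross-section structure into full-ring bands within a
  few thousand timesteps.

## Signalling

Discrete time, one timestep = 30 s (so 2,880 steps = 24 h and 15,000 steps
= 125 h, the two analysis endpoints).

- VEGF is a linear axial gradient `V(x) = m·(V0 + g·x)` with multiplier `m`
  (1 normal; 1.44, 2, 10 for the pathological conditions). A memAgent at
  row `x` has fractional receptor occupancy `s(x) = min(1, V(x)/K_sat)`.
- Each cell's VEGFR2 capacity `R_c ∈ [0, V_max]` is shared equally over its
  `M_tot` memAgents; per-site activation is `V'_m = (R_c/M_tot)·s(x)`,
  where the kinase-inhibition factor `f ≥ 1` enters through the occupancy
  `s(x) = min(1, V(x)/(K_sat·f))`: in the unsaturated regime this divides
  activation exactly by `f`, while at saturating VEGF the ligand excess
  partially compensates (receptor-excess pharmacology) — which is what
  lets a sixfold signalling reduction re-expose the gradient at
  tumour-level VEGF. Filopodium sites are VEGFR2-enriched (factor
  `beta_filo = 10`) — the positive feedback by which filopodia amplify
  signalling, and the channel through which the E^FIL effector reaches
  activity, adhesion and competition. The summed `Vp_c` is clamped at
  `R_c`.
- Dll4 production is sigmoidal and saturating,
  `D* = D_max·(δ·Vp)²/((δ·Vp)² + d_half²)`, applied after a τ-step
  expression delay with first-order relaxation (rate `rho_d`). The switch
  shape (half-point `d_half = 25`, Hill coefficient 2) is what locks
  winners and losers apart; the cap `D_max` is what makes high VEGF
  pathological (below).
- Notch activation is the shared-boundary-fraction-weighted sum of
  neighbour Dll4; per-junction transfer saturates at `l_sat = 5` shared
  sites so the long intra-band seam does not drown out the short seams
  with the neighbouring cross-sections. Both competitions matter: one
  winner per band (partner seam), and alternation between bands (diagonal
  seams). DAPT is modelled as `Np_c = 0` for every cell.
- Receptor capacity is down-regulated by a saturating (Hill) law
  `R* = V_max/(1 + (σ·Np/V_max)²)`, again delayed and relaxed. A linear
  clamped law (`V_max − σ·Np` clipped at 0) was tried first and cannot
  satisfy the patterning criterion: whenever the collective transient
  drives all cells to the hard zero, the cell-to-cell differentials that
  lateral inhibition amplifies are annihilated and the sprout rings
  synchronously instead of patterning. The Hill form never reaches zero,
  so deep inhibition preserves ratios.
- "Effective" levels `V̂, N̂` are trailing moving averages over `w = 60`
  steps; they feed the slower adhesion and protrusion machinery.
  A cell is **signal-active** iff `D ≥ θ_D` and `Vp ≥ θ_V` (both 20,
  boundary-inclusive).

Parameter defaults were fixed by the patterning calibration criterion: a
10-cell wild-type sprout at normal VEGF must settle into a stable pattern
of exactly three non-adjacent active cells within the 1,000-step
movement-free stabilization window. The delay `τ = 5` steps with
relaxation rate 0.1 sits below the oscillation threshold of the
delayed-inhibition loop (τ ≈ 8 at these gains, where patterning gives way
to synchronized oscillation); per-step multiplicative noise of 3% on `Vp`
breaks the within-band symmetry.

### Why high VEGF disorganizes the sprout

At `m = 1` the inhibited cells' activation (`R_low·s̄ ≈ few`) sits far
below the Dll4 switch point, so patterns lock. Raising `m` raises `s̄`
toward 1 everywhere: inhibited cells re-enter the Dll4-producing regime,
mutual inhibition becomes global, and the pattern destabilizes — pattern
times shrink, stabilizing times grow, rearrangement degrades. Sixfold
VEGFR2-signalling reduction (the kinase-inhibitor condition) divides all
activation by 6 and restores the separation even at `m = 10`; reducing
filopodia (`k_FIL < 1` in every cell, the pharmacological-inhibition
condition) removes the amplification part of the activation and partially
restores it at intermediate VEGF.

## Cytoskeleton

Each cell has a conserved pool of `A_max = 60` actin units; a deployed unit
occupies one filopodium site. Filopodia are 1-site-wide axial chains in a
layer above the body lattice, anchored at the cell's frontmost body site of
each column it owns (the 2-D surrogate of filopodia probing up the
gradient; they never count as body occupancy for the tip rule). A tip
extends with probability `min(1, k_FIL·C·V'_m/(V_max/M_tot))` (`C = 0.1`),
retracts spontaneously with `p_ret = 0.05` per step, deterministically when
local normalised activation falls below 0.15, and entirely when its anchor
moves. Retraction returns actin to the pool; chains never exceed 12 sites.
The deterministic retraction threshold keeps filopodia a property of
*active* cells, which is what couples the E^FIL effector to competition:
fewer filopodia → lower `Vp` → losing the activation race → strong
adhesion and no protrusions → displaced from the front.

## Rearrangement

Modified Cellular-Potts boundary dynamics, `n_attempts = 150` random
boundary proposals per timestep after the stabilization window:

- Hamiltonian: heterotypic cell–cell contact energy
  `J0 − (α_i + α_j)` with `α` set by the binary adhesion class
  (strong pairs form low-energy, hard-to-break interfaces; `J0 = 4.5`,
  `α_strong = 2`, `α_weak = 0.5`), cell–medium contact `J_cm = 2`,
  quadratic soft area constraint (stiffness 0.4) around the 50-site
  target plus a hard volume guard — no move may push a territory beyond
  ±20% of the target — cortex tension `γ·perimeter`, and the
  circumferential-width penalty above.
- **E^ADH**: weak iff `k_ADH·V̂ ≥ η` (η = 55, between the effective
  activity of a filopodia-bearing active cell and a body-only or
  inhibited cell). `k_ADH` multiplies `V̂` rather than dividing `η`
  (equivalent up to reparameterization); `k_ADH < 1` models reduced ATP →
  slower VE-cadherin turnover → stronger adhesion.
- **E^COR**: a cell's protrusive activity is
  `k_COR·(1 − N̂/N̂_scale)·(0.3 if strongly adhesive)`, with `N̂` clamped
  to the fixed scale `N̂_scale = 50` (the effective Notch of a fully
  inhibited cell at calibration — a fixed scale rather than the running
  maximum, which an early transient would inflate).  The strong-cell
  factor is the adhesion→motility link: stable VE-cadherin junctions
  suppress protrusive actin.  Frontward expansions are cortical
  protrusions attempted with probability `λ·activity` (`λ = 0.6`);
  sideways/rearward expansions are passive junction fluctuations
  attempted at the constant rate 0.3, ungated so the area-transfer chains
  that intercalation requires never jam behind inhibited cells.
- Frontward expansions additionally gain the chemotactic work
  `μ·activity` per site (`μ = 0.5`; rearward ones pay it) — the
  front-rear polarity of a migrating EC, generated by the same protrusion
  machinery.  Accepted with Metropolis probability `min(1, exp(−ΔH/T))`,
  `T = 1.5`.
- Moves that would split or annihilate the losing territory are rejected
  outright (exact check: a fast local-ring criterion, falling back to BFS
  over the territory).

## Quantification

- **Tip cell**: the cell occupying most of the 10 circumference sites of
  the frontmost occupied row (cell bodies only); exact ties go to the
  higher active VEGFR2, remaining ties to the lower cell id. An empty
  window recedes to the previous occupied row by construction.
- **Overtakes**: debounced persistent COM_x rank inversions per cell pair —
  an inversion counts once it persists 30 consecutive timesteps (15 min);
  ties inherit the preceding order.
- **Migration**: summed `|ΔCOM_x|` between consecutive timesteps.
- **S&P scoring**: per timestep, signal-active cells with deployed actin
  ≥ 3 units are "sprout active", signal-active cells below it "stunted
  active"; both count as active. A timestep is a stable pattern iff
  exactly 3 cells are active and no two actives are 4-adjacent.
  Contiguous stable runs give the average/maximal pattern times; gaps
  between successive patterns give the stabilizing time (the counter does
  not run during patterns and resets when a new pattern forms; a window
  with no pattern reports its full length).
- **Adhesive strength**: per-genotype fraction of strongly adhesive
  cell-timesteps.
- **Statistics**: Fisher's exact test (two-sided) on tip counts; ≥50
  seeded replicates per condition, each replicate differing only in the
  seed that places the genotypes and drives the stochastic dynamics.

## Calibration of the effector constants

Following the published procedure, single-effector constants are swept
over a grid and scored against the two in-vitro spheroid competition
constants (knockdown tip fraction 22.4% in 1:1 and 66.8% in 9:1 mosaics);
the selected `k` minimises the summed squared deviation, with acceptance
judged by the 95% binomial confidence interval at n = 150 replicates.
Combinatorial mechanisms sweep a single shared extent `s` with
`k_X = 1 − s` for every contributing effector. In this implementation the
filopodia effector is the strongest competition lever and its calibration
selects a strong knockdown (k_FIL at or near 0); the knockdown tip
fractions it achieves sit within the 95% CI of both in-vitro constants.

## Problem sizes and determinism

Everything is seeded: one integer seed determines genotype placement and
the whole stochastic trajectory, and identical (config, seed) pairs give
bit-identical output. Default analysis uses the 125-h endpoint (15,000
timesteps; one run takes well under a second). The test suite and the
acceptance script use 50–150 replicates per condition and 4,000–8,000-step
windows for the direction-only phenotype comparisons, where the pattern
statistics have long settled.

## Limitations

- The lattice surrogate has no lumen, no explicit springs, no cell
  division, and a fixed 10-cell complement; sprout elongation is bounded
  by the domain.
- The VEGF field is static (no consumption or diffusion); filopodia sense
  but do not deform it.
- The functional forms of the three effectors are reconstructions from
  their published symbol lists, with all gains exposed in configuration;
  parameter defaults are fixed by the patterning criterion rather than
  taken from the original (unpublished) constants. Conclusions should be
  read as qualitative/structural, not as quantitative predictions for real
  endothelium.
- The in-silico knockdown equivalence between the 24-h and 125-h endpoints
  is weaker here than in the original 3-D model: rearrangement in the
  lattice model expresses genotype differences more slowly, so competition
  experiments use the 125-h endpoint throughout.
- The overtake count is dominated by boundary jitter between abreast
  same-band cells (with a hysteresis gap of one site or more there are
  almost no deep positional exchanges in any condition).  Because the
  homogeneous high-VEGF state leaves all five cross-section pairs
  jittering while the patterned normal state pins most of them apart,
  the count *rises* mildly with VEGF here, opposite to the reduction in
  directed rearrangement that the pattern-time and stabilizing-time
  metrics capture correctly.
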