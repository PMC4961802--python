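"""Numba-compiled core of the sprout simulator.

Everything here operates on plain numpy arrays so the same subroutines can be
driven one step at a time from the Python module surface (``signalling``,
``cytoskeleton``, ``rearrangement``) or fused into the full simulation loop
(:func:`simulate`) used by ``experiments.run_scenario``.

Array conventions
-----------------
owner        (AX, CIRC) int32   cell id owning each lattice site, EMPTY = -1.
                                x (axis 0) is axial, increasing toward the
                                sprout front; y (axis 1) is circumferential
                                with wrap-around.
filo_len     (n, CIRC)  int32   length of the filopodium chain cell ``c``
                                anchors in column ``y`` (0 = none).
filo_base    (n, CIRC)  int32   axial index of the anchoring body site; the
                                chain occupies x = base+1 .. base+len in a
                                layer above the body lattice.

The per-timestep random draws happen in a fixed order (filopodia by cell then
column, signalling noise by cell, Potts proposals sequentially), so a seeded
run is bit-reproducible.
"""

import numpy as np
from numba import njit

EMPTY = -1

# indices of the per-step per-cell record block (see simulate())
REC_FIELDS = (
    "com_x", "com_y", "vp", "dll", "notch", "vhat", "nhat",
    "strong", "signal_active", "deployed", "filo_count", "filo_len_total",
)


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's global RNG (separate stream from numpy's Python-level RNG)."""
    np.random.seed(seed)


@njit(cache=True)
def vegf_profile(ax_len, v0, gslope, mvegf):
    """VEGF concentration per axial row: m * (v0 + g*x), clipped at 0."""
    out = np.empty(ax_len, dtype=np.float64)
    for x in range(ax_len):
        v = mvegf * (v0 + gslope * x)
        out[x] = v if v > 0.0 else 0.0
    return out


@njit(cache=True)
def saturation_profile(ax_len, v0, gslope, mvegf, k_sat, su_fold=1.0):
    """Per-row fractional signalling-competent VEGFR2 occupancy
    min(1, V(x) / (K_sat * f)).

    The kinase-inhibition factor f rescales the receptor sensitivity: in
    the unsaturated regime this divides per-site activation exactly by f,
    while at saturating VEGF the excess ligand partially compensates —
    receptor-excess pharmacology, which is what lets a sixfold signalling
    reduction re-expose the VEGF gradient at tumour-level VEGF.
    """
    out = vegf_profile(ax_len, v0, gslope, mvegf)
    for x in range(ax_len):
        s = out[x] / (k_sat * su_fold)
        out[x] = 1.0 if s > 1.0 else s
    return out


@njit(cache=True)
def scan_mesh(owner, n_cells):
    """One pass over the lattice gathering per-cell geometry.

    Returns (area, n_boundary, lmat, frontmost, front_row, perimeter) where
    ``frontmost[c, y]`` is the maximal axial index of a body site of cell c in
    column y (-1 if the cell owns no site there), ``lmat`` the symmetric
    matrix of shared heterotypic boundary lengths (4-adjacency, wrap-aware)
    and ``front_row`` the maximal occupied axial row of the whole sprout.
    """
    ax_len, circ = owner.shape
    area = np.zeros(n_cells, dtype=np.int64)
    n_boundary = np.zeros(n_cells, dtype=np.int64)
    perimeter = np.zeros(n_cells, dtype=np.int64)
    lmat = np.zeros((n_cells, n_cells), dtype=np.int64)
    frontmost = np.full((n_cells, circ), -1, dtype=np.int64)
    front_row = -1
    for x in range(ax_len):
        for y in range(circ):
            c = owner[x, y]
            if c < 0:
                continue
            area[c] += 1
            if x > front_row:
                front_row = x
            if x > frontmost[c, y]:
                frontmost[c, y] = x
            boundary = False
            # +x / -x neighbours (domain ends are walls, not boundary)
            for dx in (-1, 1):
                xx = x + dx
                if 0 <= xx < ax_len:
                    o = owner[xx, y]
                    if o != c:
                        boundary = True
                        perimeter[c] += 1
                        if o >= 0 and dx == 1:
                            lmat[c, o] += 1
                            lmat[o, c] += 1
                else:
                    pass  # wall: interior for boundary purposes
            for dy in (-1, 1):
                yy = (y + dy) % circ
                o = owner[x, yy]
                if o != c:
                    boundary = True
                    perimeter[c] += 1
                    if o >= 0 and dy == 1:
                        lmat[c, o] += 1
                        lmat[o, c] += 1
            if boundary:
                n_boundary[c] += 1
    return area, n_boundary, lmat, frontmost, front_row, perimeter


@njit(cache=True)
def full_scan(owner, svals, x_hi, n_cells):
    """Fused geometry/activation pass used by the simulation loop.

    One sweep over rows [0, x_hi) gathering, per cell: area, boundary
    memAgent count, boundary activation sum, shared-boundary matrix,
    per-column frontmost body row, perimeter, and body-COM accumulators
    (x-sum, circular y sin/cos sums, memAgent count).  ``x_hi`` bounds the
    occupied region (the sprout front can advance at most one row per
    timestep, so the caller passes last front_row + 2).
    """
    ax_len, circ = owner.shape
    if x_hi > ax_len:
        x_hi = ax_len
    area = np.zeros(n_cells, dtype=np.int64)
    n_boundary = np.zeros(n_cells, dtype=np.int64)
    ssum = np.zeros(n_cells, dtype=np.float64)
    perimeter = np.zeros(n_cells, dtype=np.int64)
    lmat = np.zeros((n_cells, n_cells), dtype=np.int64)
    frontmost = np.full((n_cells, circ), -1, dtype=np.int64)
    sx = np.zeros(n_cells, dtype=np.float64)
    sy_sin = np.zeros(n_cells, dtype=np.float64)
    sy_cos = np.zeros(n_cells, dtype=np.float64)
    cnt = np.zeros(n_cells, dtype=np.int64)
    front_row = -1
    two_pi = 2.0 * np.pi
    siny = np.empty(circ)
    cosy = np.empty(circ)
    for y in range(circ):
        siny[y] = np.sin(two_pi * y / circ)
        cosy[y] = np.cos(two_pi * y / circ)
    for x in range(x_hi):
        for y in range(circ):
            c = owner[x, y]
            if c < 0:
                continue
            area[c] += 1
            if x > front_row:
                front_row = x
            if x > frontmost[c, y]:
                frontmost[c, y] = x
            boundary = False
            for dx in (-1, 1):
                xx = x + dx
                if 0 <= xx < ax_len:
                    o = owner[xx, y]
                    if o != c:
                        boundary = True
                        perimeter[c] += 1
                        if o >= 0 and dx == 1:
                            lmat[c, o] += 1
                            lmat[o, c] += 1
            for dy in (-1, 1):
                yy = (y + dy) % circ
                o = owner[x, yy]
                if o != c:
                    boundary = True
                    perimeter[c] += 1
                    if o >= 0 and dy == 1:
                        lmat[c, o] += 1
                        lmat[o, c] += 1
            if boundary:
                n_boundary[c] += 1
                ssum[c] += svals[x]
                sx[c] += x
                sy_sin[c] += siny[y]
                sy_cos[c] += cosy[y]
                cnt[c] += 1
    return (area, n_boundary, ssum, lmat, frontmost, front_row, perimeter,
            sx, sy_sin, sy_cos, cnt)


@njit(cache=True)
def memagent_com(owner, filo_len, filo_base, n_cells):
    """Centre of mass per cell over cell-body memAgents (boundary sites);
    plain mean along x, circular mean along y.

    Filopodium sites are excluded: on this coarse lattice a single thin
    chain would otherwise displace the COM by whole site units, whereas on
    the dense membrane mesh it approximates, filopodia carry a negligible
    share of the membrane agents.  Position metrics therefore track cell
    bodies, the same convention the tip rule uses.
    """
    ax_len, circ = owner.shape
    sx = np.zeros(n_cells, dtype=np.float64)
    sy_sin = np.zeros(n_cells, dtype=np.float64)
    sy_cos = np.zeros(n_cells, dtype=np.float64)
    cnt = np.zeros(n_cells, dtype=np.int64)
    two_pi = 2.0 * np.pi
    for x in range(ax_len):
        for y in range(circ):
            c = owner[x, y]
            if c < 0:
                continue
            boundary = False
            if x > 0 and owner[x - 1, y] != c:
                boundary = True
            elif x < ax_len - 1 and owner[x + 1, y] != c:
                boundary = True
            elif owner[x, (y + 1) % circ] != c:
                boundary = True
            elif owner[x, (y - 1) % circ] != c:
                boundary = True
            if boundary:
                ang = two_pi * y / circ
                sx[c] += x
                sy_sin[c] += np.sin(ang)
                sy_cos[c] += np.cos(ang)
                cnt[c] += 1
    com_x = np.full(n_cells, np.nan)
    com_y = np.full(n_cells, np.nan)
    for c in range(n_cells):
        if cnt[c] > 0:
            com_x[c] = sx[c] / cnt[c]
            ang = np.arctan2(sy_sin[c] / cnt[c], sy_cos[c] / cnt[c])
            if ang < 0.0:
                ang += two_pi
            com_y[c] = ang * circ / two_pi
    return com_x, com_y


@njit(cache=True)
def body_activation(owner, svals, n_cells):
    """Sum of per-row receptor saturation over each cell's boundary body
    sites, and the boundary site counts (body memAgents)."""
    ax_len, circ = owner.shape
    ssum = np.zeros(n_cells, dtype=np.float64)
    cnt = np.zeros(n_cells, dtype=np.int64)
    for x in range(ax_len):
        for y in range(circ):
            c = owner[x, y]
            if c < 0:
                continue
            boundary = False
            if x > 0 and owner[x - 1, y] != c:
                boundary = True
            elif x < ax_len - 1 and owner[x + 1, y] != c:
                boundary = True
            elif owner[x, (y + 1) % circ] != c:
                boundary = True
            elif owner[x, (y - 1) % circ] != c:
                boundary = True
            if boundary:
                ssum[c] += svals[x]
                cnt[c] += 1
    return ssum, cnt


@njit(cache=True)
def step_filopodia_kernel(owner, filo_len, filo_base, deployed, frontmost,
                          r_cap, m_tot, svals, kfil,
                          c_strength, v_max, su_fold, a_max, l_max,
                          p_ret, retract_thresh):
    """One stochastic filopodia update.

    Chains are 1-site-wide axial protrusions in a layer above the body
    lattice, anchored at the cell's frontmost body site of each owned
    column.  An anchor that moved retracts the whole chain (actin returned).
    Tips retract spontaneously with probability ``p_ret`` and
    deterministically when the local normalised activation
    R_c * s(x) / (V_max * f) falls below ``retract_thresh``.  Extension of a
    tip (or a fresh chain) succeeds with probability
    min(1, k_FIL * C * V'_m / (V_max / M_tot)) = min(1, k_FIL*C*R_c*s/V_max/f)
    and consumes one actin unit from the cell's pool of ``a_max`` units.
    """
    n_cells, circ = filo_len.shape
    ax_len = owner.shape[0]
    for c in range(n_cells):
        for y in range(circ):
            L = filo_len[c, y]
            anchor = frontmost[c, y]
            if L > 0 and anchor != filo_base[c, y]:
                deployed[c] -= L
                filo_len[c, y] = 0
                L = 0
            filo_base[c, y] = anchor
            if anchor < 0:
                continue
            # retraction of the current tip
            if L > 0:
                tip_x = anchor + L
                q_tip = r_cap[c] * svals[tip_x] / (v_max * su_fold)
                if q_tip < retract_thresh:
                    filo_len[c, y] -= 1
                    deployed[c] -= 1
                    L -= 1
                elif np.random.random() < p_ret:
                    filo_len[c, y] -= 1
                    deployed[c] -= 1
                    L -= 1
            # extension
            if L < l_max and deployed[c] < a_max:
                target = anchor + L + 1
                if target < ax_len:
                    mt = m_tot[c] if m_tot[c] > 0 else 1
                    vprime = (r_cap[c] / mt) * svals[target] / su_fold
                    p_ext = kfil[c] * c_strength * vprime / (v_max / mt)
                    if p_ext > 1.0:
                        p_ext = 1.0
                    if np.random.random() < p_ext:
                        filo_len[c, y] += 1
                        deployed[c] += 1


@njit(cache=True)
def filopodia_activation(filo_len, filo_base, svals, beta_filo):
    """Receptor-weighted activation sum and site count of all filopodium
    sites per cell (filopodia are VEGFR2-enriched by factor beta)."""
    n_cells, circ = filo_len.shape
    ssum = np.zeros(n_cells, dtype=np.float64)
    cnt = np.zeros(n_cells, dtype=np.int64)
    for c in range(n_cells):
        for y in range(circ):
            L = filo_len[c, y]
            for i in range(1, L + 1):
                ssum[c] += beta_filo * svals[filo_base[c, y] + i]
                cnt[c] += 1
    return ssum, cnt


@njit(cache=True)
def step_signalling_kernel(t, ssum_body, n_body, ssum_filo, n_filo, lmat,
                           r_cap, vp, dll, notch, dbuf, rbuf,
                           vwin, nwin, vhat, nhat, nhat_max,
                           v_max, delta_d, d_half, d_max, sigma, tau, wwin,
                           l_sat, rho_d, rho_r, su_fold, dapt, noise_sd,
                           use_noise):
    """One discrete-time update of the VEGF->VEGFR2->Dll4->Notch loop.

    Per-memAgent activation V'_m = (R_c / M_tot) * min(1, V/K_sat) / f is
    summed over boundary and (receptor-enriched) filopodium sites, clamped to
    R_c; Dll4 production and VEGFR2 down-regulation act through tau-step
    delay buffers with first-order relaxation; Notch activation sums
    neighbour Dll4 with junction weights saturating at l_sat shared sites.
    Effective levels Vhat/Nhat are trailing moving averages over wwin steps.
    Returns the updated running maximum of Nhat (used to normalise the
    cortical-protrusion response).
    """
    n_cells = r_cap.shape[0]
    slot = t % tau
    wslot = t % wwin
    # --- active VEGFR2 ---
    for c in range(n_cells):
        m_tot = n_body[c] + n_filo[c]
        if m_tot < 1:
            m_tot = 1
        raw = (r_cap[c] / m_tot) * (ssum_body[c] + ssum_filo[c]) / su_fold
        if use_noise:
            raw *= 1.0 + noise_sd * np.random.normal()
        if raw < 0.0:
            raw = 0.0
        if raw > r_cap[c]:
            raw = r_cap[c]
        vp[c] = raw
    # --- Dll4 (delayed, sigmoidal, capped, relaxed) ---
    # production switches on around Vp = d_half (Hill coefficient 2) and
    # saturates at d_max: active cells present near-maximal Dll4, inhibited
    # cells almost none -- the switch that locks the pattern in
    for c in range(n_cells):
        target = dbuf[c, slot]  # stored tau steps ago
        u = delta_d * vp[c]
        prod = d_max * u * u / (u * u + d_half * d_half)
        dbuf[c, slot] = prod
        dll[c] += rho_d * (target - dll[c])
        if dll[c] < 0.0:
            dll[c] = 0.0
    # --- Notch activation from neighbours ---
    for c in range(n_cells):
        if dapt:
            notch[c] = 0.0
            continue
        # neighbour Dll4 weighted by shared-boundary fraction.  Per-junction
        # signal transfer saturates at l_sat shared sites, so the long
        # intra-band seam does not drown out the short seams with the
        # neighbouring cross-sections (both competitions matter: one winner
        # per band, and alternation between bands).
        acc = 0.0
        denom = 0.0
        for j in range(n_cells):
            if j == c or lmat[c, j] == 0:
                continue
            w = lmat[c, j] if lmat[c, j] < l_sat else l_sat
            acc += w * dll[j]
            denom += w
        if denom < l_sat:
            denom = l_sat
        notch[c] = acc / denom
    # --- VEGFR2 capacity down-regulation (delayed, saturating, relaxed) ---
    # Hill-type suppression: half-maximal when sigma*Np = V_max.  Never
    # exactly zero, so the cell-to-cell differentials that lateral
    # inhibition amplifies survive deep inhibition.
    for c in range(n_cells):
        target = rbuf[c, slot]
        u = sigma * notch[c] / v_max
        new = v_max / (1.0 + u * u)
        rbuf[c, slot] = new
        r_cap[c] += rho_r * (target - r_cap[c])
        if r_cap[c] < 0.0:
            r_cap[c] = 0.0
        if r_cap[c] > v_max:
            r_cap[c] = v_max
    # --- effective (windowed) levels ---
    # the protrusion response is normalised by the sprout's current maximal
    # effective Notch (not a cumulative maximum: an early synchronized
    # transient would otherwise make every later cell look uninhibited)
    nhat_max = 0.0
    for c in range(n_cells):
        vhat[c] += (vp[c] - vwin[c, wslot]) / wwin
        nhat[c] += (notch[c] - nwin[c, wslot]) / wwin
        vwin[c, wslot] = vp[c]
        nwin[c, wslot] = notch[c]
        if nhat[c] > nhat_max:
            nhat_max = nhat[c]
    return nhat_max


@njit(cache=True)
def connectivity_ok(owner, x, y):
    """True if removing site (x, y) keeps its owner's territory 4-connected
    (circumferential wrap).  Exact check: BFS over the remaining territory."""
    ax_len, circ = owner.shape
    c = owner[x, y]
    # Fast path: if the owner's sites in the 8-ring around (x, y) form one
    # contiguous cyclic run, they stay 4-connected without (x, y) (ring-
    # consecutive sites are mutually 4-adjacent), so removal is safe.
    ring = np.zeros(8, dtype=np.uint8)
    n_ring = 0
    for k in range(8):
        if k == 0:
            nx, ny = x - 1, y
        elif k == 1:
            nx, ny = x - 1, (y + 1) % circ
        elif k == 2:
            nx, ny = x, (y + 1) % circ
        elif k == 3:
            nx, ny = x + 1, (y + 1) % circ
        elif k == 4:
            nx, ny = x + 1, y
        elif k == 5:
            nx, ny = x + 1, (y - 1) % circ
        elif k == 6:
            nx, ny = x, (y - 1) % circ
        else:
            nx, ny = x - 1, (y - 1) % circ
        if 0 <= nx < ax_len and owner[nx, ny] == c:
            ring[k] = 1
            n_ring += 1
    if n_ring > 0:
        runs = 0
        for k in range(8):
            if ring[k] == 1 and ring[(k + 1) % 8] == 0:
                runs += 1
        if runs == 1:
            return True
    # Slow path: exact BFS over the remaining territory.
    # find a seed site != (x,y)
    seed_x = -1
    seed_y = -1
    total = 0
    for xx in range(ax_len):
        for yy in range(circ):
            if owner[xx, yy] == c and not (xx == x and yy == y):
                total += 1
                if seed_x < 0:
                    seed_x = xx
                    seed_y = yy
    if total == 0:
        return False  # last site: removing it destroys the cell
    visited = np.zeros((ax_len, circ), dtype=np.uint8)
    stack_x = np.empty(total, dtype=np.int64)
    stack_y = np.empty(total, dtype=np.int64)
    stack_x[0] = seed_x
    stack_y[0] = seed_y
    visited[seed_x, seed_y] = 1
    n_stack = 1
    n_seen = 1
    while n_stack > 0:
        n_stack -= 1
        cx = stack_x[n_stack]
        cy = stack_y[n_stack]
        for k in range(4):
            if k == 0:
                nx, ny = cx - 1, cy
            elif k == 1:
                nx, ny = cx + 1, cy
            elif k == 2:
                nx, ny = cx, (cy + 1) % circ
            else:
                nx, ny = cx, (cy - 1) % circ
            if nx < 0 or nx >= ax_len:
                continue
            if nx == x and ny == y:
                continue
            if owner[nx, ny] == c and visited[nx, ny] == 0:
                visited[nx, ny] = 1
                stack_x[n_stack] = nx
                stack_y[n_stack] = ny
                n_stack += 1
                n_seen += 1
    return n_seen == total


@njit(cache=True)
def contact_energy(o1, o2, strong, j0, alpha_strong, alpha_weak, j_cm):
    """Per-unit-boundary contact energy between two site owners.

    Same owner (or wall, encoded -2): 0.  Cell-medium: j_cm.  Cell-cell:
    j0 - (alpha_1 + alpha_2) with alpha picked by the adhesion class, so
    strongly adhesive pairs form low-energy (hard to break) interfaces.
    """
    if o1 == o2:
        return 0.0
    if o1 == -2 or o2 == -2:
        return 0.0
    if o1 == EMPTY or o2 == EMPTY:
        return j_cm
    a1 = alpha_strong if strong[o1] else alpha_weak
    a2 = alpha_strong if strong[o2] else alpha_weak
    return j0 - (a1 + a2)


@njit(cache=True)
def width_penalty(ncols, width0, lambda_width):
    """Cortical-polarity cost of a cell spreading beyond its resting
    circumferential width (prevents cells from annularising around the
    vessel, which would dissolve the cross-section structure)."""
    excess = ncols - width0
    if excess <= 0:
        return 0.0
    return lambda_width * excess * excess


@njit(cache=True)
def delta_hamiltonian(owner, bx, by, new_owner, strong, area, target_area,
                      lambda_area, j0, alpha_strong, alpha_weak, j_cm,
                      gamma_per, colcount, ncols, width0, lambda_width):
    """Energy change of copying ``new_owner`` into site (bx, by).

    Local evaluation of Delta(contact) + Delta(area penalty) +
    Delta(cortex-tension * perimeter) + Delta(circumferential-width
    penalty); exact for this Hamiltonian because all terms are sums of
    local contributions.  ``colcount[c, y]`` counts cell c's sites in
    column y and ``ncols[c]`` its occupied-column total.
    """
    ax_len, circ = owner.shape
    old_owner = owner[bx, by]
    d_contact = 0.0
    k_new = 0   # neighbours sharing new_owner
    k_old = 0   # neighbours sharing old_owner
    k_wall = 0  # domain-end edges carry no energy and no perimeter
    for k in range(4):
        if k == 0:
            nx, ny = bx - 1, by
        elif k == 1:
            nx, ny = bx + 1, by
        elif k == 2:
            nx, ny = bx, (by + 1) % circ
        else:
            nx, ny = bx, (by - 1) % circ
        if nx < 0 or nx >= ax_len:
            o = -2  # wall
            k_wall += 1
        else:
            o = owner[nx, ny]
        d_contact += (contact_energy(new_owner, o, strong, j0, alpha_strong,
                                     alpha_weak, j_cm)
                      - contact_energy(old_owner, o, strong, j0, alpha_strong,
                                       alpha_weak, j_cm))
        if o == new_owner:
            k_new += 1
        if o == old_owner:
            k_old += 1
    n_edges = 4 - k_wall
    d_area = 0.0
    d_perim = 0.0
    if new_owner >= 0:
        a = area[new_owner]
        d_area += lambda_area * ((a + 1.0 - target_area) ** 2
                                 - (a - target_area) ** 2)
        d_perim += (n_edges - k_new) - k_new
    if old_owner >= 0:
        a = area[old_owner]
        d_area += lambda_area * ((a - 1.0 - target_area) ** 2
                                 - (a - target_area) ** 2)
        d_perim += k_old - (n_edges - k_old)
    d_width = 0.0
    if new_owner >= 0 and colcount[new_owner, by] == 0:
        d_width += (width_penalty(ncols[new_owner] + 1, width0, lambda_width)
                    - width_penalty(ncols[new_owner], width0, lambda_width))
    if old_owner >= 0 and colcount[old_owner, by] == 1:
        d_width += (width_penalty(ncols[old_owner] - 1, width0, lambda_width)
                    - width_penalty(ncols[old_owner], width0, lambda_width))
    return d_contact + d_area + gamma_per * d_perim + d_width


@njit(cache=True)
def metropolis_accept(dh, temperature):
    """Accept a proposal with probability min(1, exp(-dH/T))."""
    if dh <= 0.0:
        return True
    return np.random.random() < np.exp(-dh / temperature)


@njit(cache=True)
def attempt_moves_kernel(owner, strong, area, kcor, nhat, nhat_max,
                         front_row, target_area,
                         lambda_mig, temperature, lambda_area,
                         j0, alpha_strong, alpha_weak, j_cm, gamma_per,
                         colcount, ncols, width0, lambda_width,
                         n_attempts, side_bias, mu_mig, strong_motility,
                         nhat_scale, area_floor, area_ceil):
    """One timestep of Metropolis boundary dynamics.

    Each attempt proposes copying the owner of a random site into a random
    4-neighbour.  Frontward expansions are cortical protrusions — the
    active junction-advancing machinery — and fire only if a Bernoulli draw
    with probability min(1, k_COR * lambda * (1 - Nhat/Nhat_max)) succeeds;
    sideways and rearward expansions are passive junction fluctuations,
    attempted with the constant probability ``side_bias`` so that inhibited
    cells can still yield ground and areas re-equilibrate.  Frontward
    expansions additionally gain the chemotactic work ``mu_mig`` (rearward
    ones pay it).  Proposals that would split or annihilate the losing
    cell's territory are rejected outright.  Surviving proposals are
    accepted with probability min(1, exp(-dH/T)).  Returns (n_accepted,
    new front_row).
    """
    ax_len, circ = owner.shape
    x_hi = front_row + 2
    if x_hi > ax_len:
        x_hi = ax_len
    accepted = 0
    # protrusion suppression is normalised by a fixed effective-Notch
    # scale (the level of a fully inhibited cell at calibration), not the
    # sprout's fluctuating maximum
    norm = nhat_scale if nhat_scale > 1e-12 else 1e-12
    for _ in range(n_attempts):
        bx = np.int64(np.random.random() * x_hi)
        by = np.int64(np.random.random() * circ)
        k = np.int64(np.random.random() * 4)
        if k == 0:
            axs, ays = bx - 1, by
        elif k == 1:
            axs, ays = bx + 1, by
        elif k == 2:
            axs, ays = bx, (by + 1) % circ
        else:
            axs, ays = bx, (by - 1) % circ
        if axs < 0 or axs >= ax_len:
            continue
        src = owner[axs, ays]
        dst = owner[bx, by]
        if src == dst:
            continue
        mu_eff = 0.0
        if src >= 0:  # expansion of cell `src`
            frac = nhat[src] / norm
            if frac > 1.0:
                frac = 1.0
            protrusive = kcor[src] * (1.0 - frac)
            if strong[src]:
                # stable VE-cadherin junctions suppress protrusive actin:
                # strongly adhesive cells are less motile
                protrusive *= strong_motility
            mu_eff = mu_mig * protrusive
            if bx > axs:
                # frontward: cortical protrusion, Notch-gated via E^COR,
                # generating the chemotactic work along the gradient
                p_gate = lambda_mig * protrusive
            else:
                # sideways/rearward: passive junction fluctuation, ungated
                # so the area-transfer chains that intercalation requires
                # never jam behind inhibited cells
                p_gate = side_bias
            if p_gate > 1.0:
                p_gate = 1.0
            if np.random.random() >= p_gate:
                continue
        if dst >= 0:
            if area[dst] <= area_floor:  # hard volume guard (-20%)
                continue
            if not connectivity_ok(owner, bx, by):
                continue
        if src >= 0 and area[src] >= area_ceil:  # hard volume guard (+20%)
            continue
        dh = delta_hamiltonian(owner, bx, by, src, strong, area, target_area,
                               lambda_area, j0, alpha_strong, alpha_weak,
                               j_cm, gamma_per, colcount, ncols, width0,
                               lambda_width)
        if src >= 0:
            # chemotactic work along the VEGF gradient: expanding a cell
            # one site frontward is favourable, rearward costly; the force
            # is generated by the protrusion machinery, so it scales with
            # the cell's protrusive activity
            dh -= mu_eff * (bx - axs)
        if not metropolis_accept(dh, temperature):
            continue
        owner[bx, by] = src
        if src >= 0:
            area[src] += 1
            if colcount[src, by] == 0:
                ncols[src] += 1
            colcount[src, by] += 1
            if bx > front_row:
                front_row = bx
                x_hi = front_row + 2
                if x_hi > ax_len:
                    x_hi = ax_len
        if dst >= 0:
            area[dst] -= 1
            colcount[dst, by] -= 1
            if colcount[dst, by] == 0:
                ncols[dst] -= 1
        accepted += 1
    # front row may have receded
    while front_row > 0:
        occupied = False
        for y in range(circ):
            if owner[front_row, y] >= 0:
                occupied = True
                break
        if occupied:
            break
        front_row -= 1
    return accepted, front_row


@njit(cache=True)
def column_counts(owner, n_cells):
    """Per-cell site counts per circumferential column, and the number of
    occupied columns per cell."""
    ax_len, circ = owner.shape
    colcount = np.zeros((n_cells, circ), dtype=np.int64)
    for x in range(ax_len):
        for y in range(circ):
            c = owner[x, y]
            if c >= 0:
                colcount[c, y] += 1
    ncols = np.zeros(n_cells, dtype=np.int64)
    for c in range(n_cells):
        for y in range(circ):
            if colcount[c, y] > 0:
                ncols[c] += 1
    return colcount, ncols


@njit(cache=True)
def front_window_tip(owner, vp, n_cells):
    """Tip cell by the 10-front-grid-site rule.

    The window is the full circumference at the maximal occupied axial row
    (body memAgents only; filopodia live in a separate layer and are never
    counted).  Most window sites wins; exact tie -> higher active VEGFR2;
    remaining tie -> lower cell id.
    """
    ax_len, circ = owner.shape
    row = ax_len - 1
    while row >= 0:
        occupied = False
        for y in range(circ):
            if owner[row, y] >= 0:
                occupied = True
                break
        if occupied:
            break
        row -= 1
    if row < 0:
        return -1
    counts = np.zeros(n_cells, dtype=np.int64)
    for y in range(circ):
        c = owner[row, y]
        if c >= 0:
            counts[c] += 1
    best = -1
    for c in range(n_cells):
        if counts[c] == 0:
            continue
        if best < 0:
            best = c
        elif counts[c] > counts[best]:
            best = c
        elif counts[c] == counts[best] and vp[c] > vp[best]:
            best = c
    return best


@njit(cache=True)
def simulate(owner, kfil, kcor, kadh,
             # signalling
             v_max, k_sat, v0, gslope, mvegf, delta_d, d_half, d_max, sigma,
             tau, wwin, theta_d, theta_v, dapt, su_fold, noise_sd,
             beta_filo, l_sat, rho_d, rho_r,
             # cytoskeleton
             a_max, c_strength, l_max_f, p_ret, retract_thresh,
             # adhesion / potts
             eta, lambda_mig, temperature, lambda_area,
             j0, alpha_strong, alpha_weak, j_cm, gamma_per,
             width0, lambda_width, n_attempts, side_bias, mu_mig,
             strong_motility, nhat_scale, area_floor, area_ceil,
             target_area,
             # schedule
             n_steps, stabilization, seed, record_from,
             snapshot_every):
    """Fused simulation loop.

    Movement is disabled for the first ``stabilization`` timesteps (the S&P
    pattern forms first); signalling and filopodia run from t=0.  Records are
    collected for t >= record_from.  If snapshot_every > 0, body-ownership
    snapshots are stored every that many recorded steps (for consistency
    checks against the Python-level operations).
    """
    np.random.seed(seed)
    ax_len, circ = owner.shape
    n_cells = int(owner.max()) + 1
    svals = saturation_profile(ax_len, v0, gslope, mvegf, k_sat, su_fold)
    su_fold = 1.0  # the reduction now lives in the occupancy profile

    filo_len = np.zeros((n_cells, circ), dtype=np.int32)
    filo_base = np.full((n_cells, circ), -1, dtype=np.int32)
    deployed = np.zeros(n_cells, dtype=np.int64)

    r_cap = np.full(n_cells, v_max, dtype=np.float64)
    vp = np.zeros(n_cells, dtype=np.float64)
    dll = np.zeros(n_cells, dtype=np.float64)
    notch = np.zeros(n_cells, dtype=np.float64)
    vhat = np.zeros(n_cells, dtype=np.float64)
    nhat = np.zeros(n_cells, dtype=np.float64)
    dbuf = np.zeros((n_cells, tau), dtype=np.float64)
    rbuf = np.full((n_cells, tau), v_max, dtype=np.float64)
    vwin = np.zeros((n_cells, wwin), dtype=np.float64)
    nwin = np.zeros((n_cells, wwin), dtype=np.float64)
    nhat_max = 0.0

    n_rec = n_steps - record_from
    rec = np.zeros((n_rec, n_cells, 12), dtype=np.float32)
    tip_rec = np.full(n_rec, -1, dtype=np.int16)
    adj_rec = np.zeros((n_rec, n_cells), dtype=np.int32)
    n_snap = 0
    if snapshot_every > 0:
        n_snap = (n_rec + snapshot_every - 1) // snapshot_every
    snaps = np.zeros((n_snap, ax_len, circ), dtype=np.int32)

    (area, n_body, ssum_body, lmat, frontmost, front_row, _per,
     sx, sy_sin, sy_cos, com_cnt) = full_scan(owner, svals, ax_len, n_cells)
    colcount, ncols = column_counts(owner, n_cells)
    m_tot = n_body.copy()
    two_pi = 2.0 * np.pi

    for t in range(n_steps):
        # --- filopodia (geometry from the post-move scan of step t-1) ---
        step_filopodia_kernel(owner, filo_len, filo_base, deployed, frontmost,
                              r_cap, m_tot, svals, kfil,
                              c_strength, v_max, su_fold, a_max, l_max_f,
                              p_ret, retract_thresh)
        # --- signalling ---
        ssum_filo, nf = filopodia_activation(filo_len, filo_base, svals,
                                             beta_filo)
        for c in range(n_cells):
            m_tot[c] = n_body[c] + nf[c]
        nhat_max = step_signalling_kernel(
            t, ssum_body, n_body, ssum_filo, nf, lmat,
            r_cap, vp, dll, notch, dbuf, rbuf,
            vwin, nwin, vhat, nhat, nhat_max,
            v_max, delta_d, d_half, d_max, sigma, tau, wwin,
            l_sat, rho_d, rho_r, su_fold, dapt, noise_sd, True)
        strong = np.zeros(n_cells, dtype=np.uint8)
        for c in range(n_cells):
            if kadh[c] * vhat[c] < eta:
                strong[c] = 1
        # --- rearrangement ---
        if t >= stabilization:
            _acc, front_row = attempt_moves_kernel(
                owner, strong, area, kcor, nhat, nhat_max, front_row,
                target_area, lambda_mig, temperature, lambda_area,
                j0, alpha_strong, alpha_weak, j_cm, gamma_per,
                colcount, ncols, width0, lambda_width, n_attempts,
                side_bias, mu_mig, strong_motility, nhat_scale,
                area_floor, area_ceil)
        # geometry for next step / records (single fused pass)
        (area, n_body, ssum_body, lmat, frontmost, front_row, _per,
         sx, sy_sin, sy_cos, com_cnt) = full_scan(owner, svals,
                                                  front_row + 2, n_cells)
        # --- record ---
        if t >= record_from:
            i = t - record_from
            for c in range(n_cells):
                if com_cnt[c] > 0:
                    rec[i, c, 0] = sx[c] / com_cnt[c]
                    ang = np.arctan2(sy_sin[c] / com_cnt[c],
                                     sy_cos[c] / com_cnt[c])
                    if ang < 0.0:
                        ang += two_pi
                    rec[i, c, 1] = ang * circ / two_pi
                else:
                    rec[i, c, 0] = np.nan
                    rec[i, c, 1] = np.nan
                rec[i, c, 2] = vp[c]
                rec[i, c, 3] = dll[c]
                rec[i, c, 4] = notch[c]
                rec[i, c, 5] = vhat[c]
                rec[i, c, 6] = nhat[c]
                rec[i, c, 7] = strong[c]
                sa = 1.0 if (dll[c] >= theta_d and vp[c] >= theta_v) else 0.0
                rec[i, c, 8] = sa
                rec[i, c, 9] = deployed[c]
                nch = 0
                tot = 0
                for y in range(circ):
                    if filo_len[c, y] > 0:
                        nch += 1
                        tot += filo_len[c, y]
                rec[i, c, 10] = nch
                rec[i, c, 11] = tot
                mask = 0
                for j in range(n_cells):
                    if j != c and lmat[c, j] > 0:
                        mask |= 1 << j
                adj_rec[i, c] = mask
            tip_rec[i] = front_window_tip(owner, vp, n_cells)
            if snapshot_every > 0 and i % snapshot_every == 0:
                snaps[i // snapshot_every] = owner
    return rec, tip_rec, adj_rec, snaps
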