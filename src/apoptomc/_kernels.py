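"""Numba kernels for the lattice Monte Carlo engine.

All kernels operate in place on the flat arrays owned by
:class:`apoptomc.lattice.LatticeState`.  Sites are flat indices; ``nbr`` is
the precomputed (n_sites, 6) face-neighbor table with -1 marking off-lattice
directions (reflecting walls).  Randomness comes from numba's process-local
``np.random`` state, seeded once per cell run via :func:`seed_rng`, which
makes a whole single-cell run a deterministic function of (configuration,
seed).

Register layout (``regs``): see ``LatticeState`` — index 0 holds the live
molecule count, 10 the free-slot stack depth.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# register indices (mirrors LatticeState)
R_NLIVE, R_RELEASED, R_POOL, R_VIA_C8, R_VIA_C9 = 0, 1, 2, 3, 4
R_RELEASE_STEP, R_APO_STEP, R_HALFMAX_STEP, R_C8GEN, R_STEP = 5, 6, 7, 8, 9
R_NFREE = 10

# rule kinds (mirrors kinetics)
K_BIND, K_UNBIND, K_CATALYZE, K_CONVERT, K_EXCHANGE = 0, 1, 2, 3, 4


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _site_allowed(t, comp, released, in_block, is_shell):
    """May a molecule of compartment ``comp`` sit at flat site ``t``?"""
    if comp == 0:
        return released == 1 or in_block[t] == 0
    if comp == 1:
        return in_block[t] == 1
    return is_shell[t] == 1


@njit(cache=True, inline="always")
def _remove_molecule(i, occ, msite, species, comp, act, act_idx, counts,
                     free_stack, regs):
    occ[msite[i]] = -1
    k = act_idx[i]
    last = act[regs[R_NLIVE] - 1]
    act[k] = last
    act_idx[last] = k
    act_idx[i] = -1
    regs[R_NLIVE] -= 1
    counts[species[i]] -= 1
    species[i] = -1
    free_stack[regs[R_NFREE]] = i
    regs[R_NFREE] += 1


@njit(cache=True, inline="always")
def _add_molecule(t, sp, cp, occ, msite, species, comp, act, act_idx,
                  counts, free_stack, regs):
    regs[R_NFREE] -= 1
    i = free_stack[regs[R_NFREE]]
    species[i] = sp
    comp[i] = cp
    msite[i] = t
    occ[t] = i
    act[regs[R_NLIVE]] = i
    act_idx[i] = regs[R_NLIVE]
    regs[R_NLIVE] += 1
    counts[sp] += 1
    return i


@njit(cache=True)
def diffuse_one(occ, msite, species, comp, nbr, in_block, is_shell, regs, i,
                pdiff_cyt, pdiff_mem, immobile):
    """One diffusion attempt for live molecule ``i``; True if it moved."""
    if immobile[species[i]] == 1:
        return False
    p = pdiff_mem if comp[i] == 2 else pdiff_cyt
    if np.random.random() >= p:
        return False
    t = nbr[msite[i], np.random.randint(6)]
    if t < 0 or occ[t] != -1:
        return False
    if not _site_allowed(t, comp[i], regs[R_RELEASED], in_block, is_shell):
        return False
    occ[msite[i]] = -1
    occ[t] = i
    msite[i] = t
    return True


@njit(cache=True)
def react_one(occ, msite, species, comp, act, act_idx, counts,
              nbr, in_block, is_shell, regs, i,
              pair_rule, bi_prob, bi_kind, bi_prod_a, bi_prod_b, bi_cxside,
              uni_start, uni_count, uni_kind, uni_prob, uni_prod_site,
              uni_prod_nbr, uni_nbr_comp, uni_prov, uni_needs_shell,
              free_stack, scratch):
    """One reaction attempt for live molecule ``i``.

    Collects every applicable rule (unimolecular + one per adjacent reaction
    partner), picks one uniformly, and fires it with its acceptance
    probability.  Returns the provenance code of a caspase-3 producing event
    (0 otherwise).  ``scratch`` is a preallocated int64 work array (>= 30).
    """
    sp = species[i]
    here = msite[i]

    cand_rule = scratch[0:12]
    cand_dir = scratch[12:24]
    nc = 0

    for u in range(uni_count[sp]):
        r = uni_start[sp] + u
        if uni_needs_shell[r] == 1:
            if comp[i] != 0 or is_shell[here] == 0:
                continue
        cand_rule[nc] = r
        cand_dir[nc] = -1
        nc += 1

    for d in range(6):
        t = nbr[here, d]
        if t < 0:
            continue
        j = occ[t]
        if j == -1:
            continue
        r = pair_rule[sp, species[j]]
        if r == -1:
            continue
        # the mitochondrial membrane separates interior from cytosol
        if (comp[i] == 1) != (comp[j] == 1):
            continue
        cand_rule[nc] = r
        cand_dir[nc] = d
        nc += 1

    if nc == 0:
        return 0
    pick = np.random.randint(nc)
    r = cand_rule[pick]
    d = cand_dir[pick]

    if d == -1:
        # unimolecular
        if np.random.random() >= uni_prob[r]:
            return 0
        kind = uni_kind[r]
        if kind == K_CONVERT:
            comp[i] = 2
            return 0
        # unbind / catalyze: partner product to a random free allowed neighbor
        pn = uni_prod_nbr[r]
        pn_comp = comp[i] if uni_nbr_comp[r] == 9 else 0
        free_t = scratch[24:30]
        nf = 0
        for dd in range(6):
            t = nbr[here, dd]
            if t < 0 or occ[t] != -1:
                continue
            if not _site_allowed(t, pn_comp, regs[R_RELEASED], in_block, is_shell):
                continue
            free_t[nf] = t
            nf += 1
        if nf == 0:
            return 0
        t = free_t[np.random.randint(nf)]
        counts[sp] -= 1
        species[i] = uni_prod_site[r]
        counts[species[i]] += 1
        _add_molecule(t, pn, pn_comp, occ, msite, species, comp, act,
                      act_idx, counts, free_stack, regs)
        prov = uni_prov[r]
        if kind == K_CATALYZE and prov == 1:
            regs[R_VIA_C8] += 1
        elif kind == K_CATALYZE and prov == 2:
            regs[R_VIA_C9] += 1
        return prov

    # bimolecular
    if np.random.random() >= bi_prob[r]:
        return 0
    j = occ[nbr[here, d]]
    if bi_kind[r] == K_BIND:
        # the complex keeps the membrane-resident reactant's site so that
        # membrane species never leave the mitochondrial shell
        keep = i
        rem = j
        if comp[j] == 2 and comp[i] != 2:
            keep = j
            rem = i
        new_comp = 2 if (comp[i] == 2 or comp[j] == 2) else 0
        prod = bi_prod_a[r]
        _remove_molecule(rem, occ, msite, species, comp, act, act_idx,
                         counts, free_stack, regs)
        counts[species[keep]] -= 1
        species[keep] = prod
        counts[prod] += 1
        comp[keep] = new_comp
    else:  # K_EXCHANGE: dimer forms at the complex site, activator is freed
        cx = i if bi_cxside[r] == 0 else j
        mono = j if bi_cxside[r] == 0 else i
        counts[species[cx]] -= 1
        counts[species[mono]] -= 1
        species[cx] = bi_prod_a[r]       # active dimer, complex compartment
        species[mono] = bi_prod_b[r]     # freed activator, cytosolic
        counts[species[cx]] += 1
        counts[species[mono]] += 1
        comp[mono] = 0
    return 0


# --------------------------------------------------------------------------
# adaptor field (DISC)
# --------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _active_neighbors(mem_occ, ad_active, x, y, skip_x, skip_y):
    """Active adaptors on the four in-plane neighbors of (x, y), excluding
    the (skip_x, skip_y) site (pass -1, -1 to count all)."""
    nx, ny = mem_occ.shape
    n = 0
    for k in range(4):
        tx = x + (1 if k == 0 else (-1 if k == 1 else 0))
        ty = y + (1 if k == 2 else (-1 if k == 3 else 0))
        if tx < 0 or tx >= nx or ty < 0 or ty >= ny:
            continue
        if tx == skip_x and ty == skip_y:
            continue
        j = mem_occ[tx, ty]
        if j != -1 and ad_active[j] == 1:
            n += 1
    return n


@njit(cache=True)
def adaptor_metropolis_move(mem_occ, ad_x, ad_y, ad_active, j, e_dd):
    """One Metropolis diffusion attempt for adaptor ``j``.

    The move energy counts the active-active nearest-neighbor pairs gained or
    lost (each pair contributes ``e_dd`` in units of k_B T); acceptance is
    min[1, exp(-dE)].  Inactive adaptors move freely (dE = 0).  Returns True
    if the adaptor moved.
    """
    nx, ny = mem_occ.shape
    d = np.random.randint(4)
    tx = ad_x[j] + (1 if d == 0 else (-1 if d == 1 else 0))
    ty = ad_y[j] + (1 if d == 2 else (-1 if d == 3 else 0))
    if tx < 0 or tx >= nx or ty < 0 or ty >= ny:
        return False
    if mem_occ[tx, ty] != -1:
        return False
    if ad_active[j] == 1:
        n_old = _active_neighbors(mem_occ, ad_active, ad_x[j], ad_y[j], -1, -1)
        n_new = _active_neighbors(mem_occ, ad_active, tx, ty, ad_x[j], ad_y[j])
        d_e = e_dd * (n_new - n_old)
        if d_e > 0.0 and np.random.random() >= np.exp(-d_e):
            return False
    mem_occ[ad_x[j], ad_y[j]] = -1
    mem_occ[tx, ty] = j
    ad_x[j] = tx
    ad_y[j] = ty
    return True


@njit(cache=True)
def adaptor_react(mem_occ, ad_x, ad_y, ad_active, j,
                  p_on_ad, p_off_ad, p_c8, min_nbrs, c8_species,
                  occ, msite, species, comp, act, act_idx, counts,
                  free_stack, regs, ny, nz, in_block, is_shell):
    """One reaction attempt for adaptor ``j``: caspase-8 generation (while
    active and cluster-eligible), then activity switching.

    Generation converts one procaspase 8 from the well-mixed pool into an
    active caspase 8 placed at the adaptor's membrane-adjacent lattice site
    (its z = 0 column); the attempt is rejected if that site is occupied.
    """
    if ad_active[j] == 1:
        if regs[R_POOL] > 0:
            n_act = _active_neighbors(mem_occ, ad_active, ad_x[j], ad_y[j], -1, -1)
            if n_act >= min_nbrs and np.random.random() < p_c8:
                t = (ad_x[j] * ny + ad_y[j]) * nz
                if occ[t] == -1 and _site_allowed(t, 0, regs[R_RELEASED],
                                                 in_block, is_shell):
                    _add_molecule(t, c8_species, 0, occ, msite, species,
                                  comp, act, act_idx, counts, free_stack, regs)
                    regs[R_POOL] -= 1
                    regs[R_C8GEN] += 1
        if np.random.random() < p_off_ad:
            ad_active[j] = 0
    else:
        if np.random.random() < p_on_ad:
            ad_active[j] = 1


@njit(cache=True)
def adaptor_pair_count(mem_occ, ad_x, ad_y, ad_active):
    """Number of active-active nearest-neighbor pairs on the membrane."""
    n = 0
    nx, ny = mem_occ.shape
    for j in range(len(ad_x)):
        if ad_active[j] == 0:
            continue
        x, y = ad_x[j], ad_y[j]
        if x + 1 < nx:
            k = mem_occ[x + 1, y]
            if k != -1 and ad_active[k] == 1:
                n += 1
        if y + 1 < ny:
            k = mem_occ[x, y + 1]
            if k != -1 and ad_active[k] == 1:
                n += 1
    return n


# --------------------------------------------------------------------------
# the Monte Carlo loop
# --------------------------------------------------------------------------

@njit(cache=True)
def mc_step(occ, msite, species, comp, act, act_idx, counts,
            nbr, in_block, is_shell, regs,
            pair_rule, bi_prob, bi_kind, bi_prod_a, bi_prod_b, bi_cxside,
            uni_start, uni_count, uni_kind, uni_prob, uni_prod_site,
            uni_prod_nbr, uni_nbr_comp, uni_prov, uni_needs_shell,
            free_stack, scratch, pdiff_cyt, pdiff_mem, immobile,
            mem_occ, ad_x, ad_y, ad_active,
            p_on_ad, p_off_ad, e_dd, p_c8, min_nbrs, c8_species,
            ny, nz, release_threshold, bax2_species, apo_a, apo_b):
    """One MC step: 2N random samples, then the release and event checks.

    N is frozen at step start (molecules plus adaptors); each sample picks an
    entity uniformly among those currently present and attempts, with equal
    probability, a diffusion move or a reaction/switch move.

    The molecule branch is a manual inline of :func:`diffuse_one` /
    :func:`react_one` (identical semantics and RNG consumption; function
    calls this hot would dominate the runtime) — keep them in sync.
    """
    n_ad = len(ad_x)
    budget = 2 * (regs[R_NLIVE] + n_ad)
    regs[R_STEP] += 1
    for _ in range(budget):
        tot = regs[R_NLIVE] + n_ad
        # one draw picks both the entity and the move type (diffusion vs
        # reaction/switch, a fair coin)
        draw = np.random.randint(2 * tot)
        k = draw >> 1
        move_diff = (draw & 1) == 0
        if k < regs[R_NLIVE]:
            i = act[k]
            # --- molecule branch, inlined from diffuse_one / react_one ----
            if move_diff:
                if immobile[species[i]] == 1:
                    continue
                p = pdiff_mem if comp[i] == 2 else pdiff_cyt
                if np.random.random() >= p:
                    continue
                t = nbr[msite[i], np.random.randint(6)]
                if t < 0 or occ[t] != -1:
                    continue
                if not _site_allowed(t, comp[i], regs[R_RELEASED],
                                     in_block, is_shell):
                    continue
                occ[msite[i]] = -1
                occ[t] = i
                msite[i] = t
            else:
                sp = species[i]
                here = msite[i]
                nc = 0
                for u in range(uni_count[sp]):
                    r = uni_start[sp] + u
                    if uni_needs_shell[r] == 1:
                        if comp[i] != 0 or is_shell[here] == 0:
                            continue
                    scratch[nc] = r
                    scratch[12 + nc] = -1
                    nc += 1
                for d in range(6):
                    t = nbr[here, d]
                    if t < 0:
                        continue
                    j = occ[t]
                    if j == -1:
                        continue
                    r = pair_rule[sp, species[j]]
                    if r == -1:
                        continue
                    if (comp[i] == 1) != (comp[j] == 1):
                        continue
                    scratch[nc] = r
                    scratch[12 + nc] = d
                    nc += 1
                if nc == 0:
                    continue
                pick = np.random.randint(nc)
                r = scratch[pick]
                d = scratch[12 + pick]
                if d == -1:
                    if np.random.random() >= uni_prob[r]:
                        continue
                    kind = uni_kind[r]
                    if kind == K_CONVERT:
                        comp[i] = 2
                        continue
                    pn = uni_prod_nbr[r]
                    pn_comp = comp[i] if uni_nbr_comp[r] == 9 else 0
                    nf = 0
                    for dd in range(6):
                        t = nbr[here, dd]
                        if t < 0 or occ[t] != -1:
                            continue
                        if not _site_allowed(t, pn_comp, regs[R_RELEASED],
                                             in_block, is_shell):
                            continue
                        scratch[24 + nf] = t
                        nf += 1
                    if nf == 0:
                        continue
                    t = scratch[24 + np.random.randint(nf)]
                    counts[sp] -= 1
                    species[i] = uni_prod_site[r]
                    counts[species[i]] += 1
                    _add_molecule(t, pn, pn_comp, occ, msite, species, comp,
                                  act, act_idx, counts, free_stack, regs)
                    if kind == K_CATALYZE:
                        prov = uni_prov[r]
                        if prov == 1:
                            regs[R_VIA_C8] += 1
                        elif prov == 2:
                            regs[R_VIA_C9] += 1
                else:
                    if np.random.random() >= bi_prob[r]:
                        continue
                    j = occ[nbr[here, d]]
                    if bi_kind[r] == K_BIND:
                        keep = i
                        rem = j
                        if comp[j] == 2 and comp[i] != 2:
                            keep = j
                            rem = i
                        new_comp = 2 if (comp[i] == 2 or comp[j] == 2) else 0
                        prod = bi_prod_a[r]
                        _remove_molecule(rem, occ, msite, species, comp, act,
                                         act_idx, counts, free_stack, regs)
                        counts[species[keep]] -= 1
                        species[keep] = prod
                        counts[prod] += 1
                        comp[keep] = new_comp
                    else:
                        cx = i if bi_cxside[r] == 0 else j
                        mono = j if bi_cxside[r] == 0 else i
                        counts[species[cx]] -= 1
                        counts[species[mono]] -= 1
                        species[cx] = bi_prod_a[r]
                        species[mono] = bi_prod_b[r]
                        counts[species[cx]] += 1
                        counts[species[mono]] += 1
                        comp[mono] = 0
        else:
            j = k - regs[R_NLIVE]
            if move_diff:
                adaptor_metropolis_move(mem_occ, ad_x, ad_y, ad_active, j, e_dd)
            else:
                adaptor_react(mem_occ, ad_x, ad_y, ad_active, j,
                              p_on_ad, p_off_ad, p_c8, min_nbrs, c8_species,
                              occ, msite, species, comp, act, act_idx,
                              counts, free_stack, regs, ny, nz,
                              in_block, is_shell)
    # all-or-none mitochondrial release (checked once per step, fires once)
    if regs[R_RELEASED] == 0 and counts[bax2_species] >= release_threshold:
        for m in range(regs[R_NLIVE]):
            i = act[m]
            if comp[i] == 1:
                comp[i] = 0
        regs[R_RELEASED] = 1
        regs[R_RELEASE_STEP] = regs[R_STEP]
    if regs[R_APO_STEP] < 0 and counts[apo_a] + counts[apo_b] > 0:
        regs[R_APO_STEP] = regs[R_STEP]


@njit(cache=True)
def run_cell(seed, max_steps, record_every,
             occ, msite, species, comp, act, act_idx, counts,
             nbr, in_block, is_shell, regs,
             pair_rule, bi_prob, bi_kind, bi_prod_a, bi_prod_b, bi_cxside,
             uni_start, uni_count, uni_kind, uni_prob, uni_prod_site,
             uni_prod_nbr, uni_nbr_comp, uni_prov, uni_needs_shell,
             free_stack, scratch, pdiff_cyt, pdiff_mem, immobile,
             mem_occ, ad_x, ad_y, ad_active,
             p_on_ad, p_off_ad, e_dd, p_c8, min_nbrs, c8_species,
             ny, nz, release_threshold, bax2_species, apo_a, apo_b,
             half_max_count, c3_species, stop_on_apoptosome,
             rec_step, rec_counts, rec_extra):
    """Run one cell until half-maximal free caspase 3 or ``max_steps``.

    Samples the species-count vector every ``record_every`` steps (plus the
    initial and final states) into ``rec_step`` / ``rec_counts`` /
    ``rec_extra``; returns ``(n_rows, reason)`` with reason 0 = max_steps,
    1 = half_max, 2 = first apoptosome (when ``stop_on_apoptosome``).
    """
    np.random.seed(seed)
    row = 0

    def _record(row_i, step_i):
        rec_step[row_i] = step_i
        for s in range(counts.shape[0]):
            rec_counts[row_i, s] = counts[s]
        # extras: active adaptors, c8 generated, provenance counters
        n_on = 0
        for a in range(len(ad_active)):
            if ad_active[a] == 1:
                n_on += 1
        rec_extra[row_i, 0] = n_on
        rec_extra[row_i, 1] = regs[R_C8GEN]
        rec_extra[row_i, 2] = regs[R_VIA_C8]
        rec_extra[row_i, 3] = regs[R_VIA_C9]

    _record(row, 0)
    row += 1
    reason = 0
    for step in range(1, max_steps + 1):
        mc_step(occ, msite, species, comp, act, act_idx, counts,
                nbr, in_block, is_shell, regs,
                pair_rule, bi_prob, bi_kind, bi_prod_a, bi_prod_b, bi_cxside,
                uni_start, uni_count, uni_kind, uni_prob, uni_prod_site,
                uni_prod_nbr, uni_nbr_comp, uni_prov, uni_needs_shell,
                free_stack, scratch, pdiff_cyt, pdiff_mem, immobile,
                mem_occ, ad_x, ad_y, ad_active,
                p_on_ad, p_off_ad, e_dd, p_c8, min_nbrs, c8_species,
                ny, nz, release_threshold, bax2_species, apo_a, apo_b)
        if counts[c3_species] >= half_max_count:
            regs[R_HALFMAX_STEP] = step
            reason = 1
            _record(row, step)
            row += 1
            break
        if stop_on_apoptosome == 1 and regs[R_APO_STEP] >= 0:
            reason = 2
            _record(row, step)
            row += 1
            break
        if step % record_every == 0:
            _record(row, step)
            row += 1
    else:
        if rec_step[row - 1] != max_steps:
            _record(row, max_steps)
            row += 1
    return row, reason


@njit(cache=True)
def msd_walk(seed, n_walkers, n_steps, nx, ny, nz, pdiff):
    """Mean-squared displacement (lattice units^2) of independent walkers.

    Each walker performs one diffusion attempt per MC step on an empty
    lattice with reflecting walls, starting at the center.  Returns the MSD
    after ``n_steps`` steps, for the dilute-limit diffusion law.
    """
    np.random.seed(seed)
    total = 0.0
    x0, y0, z0 = nx // 2, ny // 2, nz // 2
    dx = np.array([1, -1, 0, 0, 0, 0], dtype=np.int64)
    dy = np.array([0, 0, 1, -1, 0, 0], dtype=np.int64)
    dz = np.array([0, 0, 0, 0, 1, -1], dtype=np.int64)
    for _ in range(n_walkers):
        x, y, z = x0, y0, z0
        for _ in range(n_steps):
            if np.random.random() >= pdiff:
                continue
            d = np.random.randint(6)
            tx = x + dx[d]
            ty = y + dy[d]
            tz = z + dz[d]
            if tx < 0 or tx >= nx or ty < 0 or ty >= ny or tz < 0 or tz >= nz:
                continue
            x, y, z = tx, ty, tz
        total += float((x - x0) ** 2 + (y - y0) ** 2 + (z - z0) ** 2)
    return total / n_walkers
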