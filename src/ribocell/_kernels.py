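"""Numba kernels implementing the per-step Monte Carlo events.

State layout (shared with :mod:`ribocell.world`):

* ``pool``   -- int64 (R, 10): per-room molecule counts.  For an unoccupied
  room these are free molecules; for a protocell-occupied room they are the
  interior pool.  Species order: Npp, Np, Nt(A), Nt(C), Nt(G), Nt(U), Gp, G,
  FA, PL.
* ``occ``    -- bool (R,): protocell present.
* ``mem_fa`` / ``mem_pl`` -- int64 (R,): membrane composition.
* strand store -- structure-of-arrays over slots (see ``world.StrandStore``):
  ``alive``, ``room``, ``length``, ``seq`` (uint8, 5'->3', A=0 C=1 G=2 U=3),
  duplex state ``dstart``/``dlen``/``dseq``/``dbond``, species ``flags``.

A duplex is a template strand plus a contiguous block of aligned substrate
residues: ``dseq[pos]`` is the base paired at template position ``pos`` for
``pos`` in ``[dstart, dstart+dlen)``; ``dbond[j] == 1`` means the nascent
bond between aligned positions ``j`` and ``j+1`` has been ligated.

All randomness inside kernels flows from numba's global RNG, seeded once per
run through :func:`seed_kernel_rng`; runs are reproducible given the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .parameters import PARAM_INDEX

# --- species indices in the pool array ---------------------------------------
NPP, NP_, NTA, NTC, NTG, NTU, GP, G, FA, PL = range(10)
NSP = 10

# --- function codes carried by species definitions ---------------------------
FUNC_NONE, FUNC_GR, FUNC_NR, FUNC_NPR, FUNC_TR = 0, 1, 2, 3, 4

# --- parameter-vector indices (generated from the canonical order) -----------
_g = globals()
for _name, _idx in PARAM_INDEX.items():
    _g["I_" + _name] = int(_idx)
del _g, _name, _idx


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _binom(n, p):
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return np.int64(n)
    return np.random.binomial(np.int64(n), p)


# --- alias tables for the fixed split probabilities 1/4, 1/3, 1/2 -----------
# Uniform splitting of n entities over k slots draws Binomial(n, 1/k) chains;
# these are the hottest RNG calls of the simulation, so each (n, p) pair up
# to _NMAX gets a Vose alias table giving O(1) exact draws.

_NMAX_ALIAS = 768


import functools


@functools.lru_cache(maxsize=16)
def _build_alias_family(p: float, nmax: int):
    tot = (nmax + 1) * (nmax + 2) // 2
    probs = np.zeros(tot, np.float64)
    alias = np.zeros(tot, np.int32)
    logr = np.log(p) - np.log1p(-p)
    for n in range(nmax + 1):
        off = n * (n + 1) // 2
        # log-space recurrence: stable for extreme p and large n
        k = np.arange(n, dtype=np.float64)
        logpmf = np.concatenate((
            [0.0], np.cumsum(np.log((n - k) / (k + 1.0)) + logr)))
        logpmf += n * np.log1p(-p)
        pmf = np.exp(logpmf - logpmf.max())
        pmf /= pmf.sum()
        q = pmf * (n + 1)
        small = [k for k in range(n + 1) if q[k] < 1.0]
        large = [k for k in range(n + 1) if q[k] >= 1.0]
        pr = np.ones(n + 1)
        al = np.arange(n + 1, dtype=np.int32)
        while small and large:
            s = small.pop()
            g = large.pop()
            pr[s] = q[s]
            al[s] = g
            q[g] = q[g] - (1.0 - q[s])
            (small if q[g] < 1.0 else large).append(g)
        probs[off:off + n + 1] = pr
        alias[off:off + n + 1] = al
    return probs, alias


_AL4_P, _AL4_A = _build_alias_family(0.25, _NMAX_ALIAS)
_AL3_P, _AL3_A = _build_alias_family(1.0 / 3.0, _NMAX_ALIAS)
_AL2_P, _AL2_A = _build_alias_family(0.5, _NMAX_ALIAS)


@njit(cache=False, inline="always")
def _alias_draw(probs, alias, n):
    off = n * (n + 1) // 2
    j = np.random.randint(0, n + 1)
    if np.random.random() < probs[off + j]:
        return np.int64(j)
    return np.int64(alias[off + j])


@njit(cache=False, inline="always")
def _binom_quarter(n):
    if 0 < n <= _NMAX_ALIAS:
        return _alias_draw(_AL4_P, _AL4_A, n)
    return _binom(n, 0.25)


@njit(cache=False, inline="always")
def _binom_third(n):
    if 0 < n <= _NMAX_ALIAS:
        return _alias_draw(_AL3_P, _AL3_A, n)
    return _binom(n, 1.0 / 3.0)


@njit(cache=False, inline="always")
def _binom_half(n):
    if 0 < n <= _NMAX_ALIAS:
        return _alias_draw(_AL2_P, _AL2_A, n)
    return _binom(n, 0.5)


@njit(cache=False, inline="always")
def _split4(n):
    """Multinomial(n; 1/4, 1/4, 1/4, 1/4) via conditional binomials."""
    k0 = _binom_quarter(n)
    m = n - k0
    k1 = _binom_third(m)
    m -= k1
    k2 = _binom_half(m)
    return k0, k1, k2, m - k2


# =============================================================================
# closed-form per-event probabilities
# =============================================================================

@njit(cache=True)
def rna_move_prob(m, p_mv):
    # Zimm-model scaling of polymer diffusivity with mass
    return min(1.0, p_mv / np.sqrt(m))


@njit(cache=True)
def bond_break_prob(double_stranded, outside, p_bb, f_do):
    p = p_bb * f_do if outside else p_bb
    p = min(1.0, p)
    if double_stranded:
        p = p * np.sqrt(p)  # p ** 1.5, both parallel bonds at once
    return min(1.0, p)


@njit(cache=True)
def separation_prob(n_pairs, p_sp):
    return min(1.0, p_sp ** np.sqrt(n_pairs))


@njit(cache=True)
def membrane_formation_prob(a_tails, p_mf, l_am):
    if a_tails < l_am:
        return 0.0
    x = a_tails - l_am + 1.0
    return 1.0 - (1.0 - p_mf) ** x


@njit(cache=True)
def amphiphile_leave_prob(base, ions, b_tails, f_pl, rpm):
    vol = (0.5 * b_tails) ** 1.5
    y = 1.0 + ions / vol
    z = 1.0 + f_pl * rpm
    return min(1.0, base / (y * z))


@njit(cache=True)
def division_prob(b_tails, p_cd, l_am):
    p = p_cd * (1.0 - 2.0 * l_am / b_tails)
    return max(0.0, p)


@njit(cache=True)
def _perm_factors(par, fa, pl, ions, t_count):
    """(s, u, v, v_weak, v_tr) for one membrane."""
    b = fa + 2 * pl
    rpm = 2.0 * pl / b
    s = b / par[I_L_AM]
    vol = (0.5 * b) ** 1.5
    u = 1.0 + par[I_F_DE] * ions / vol
    v = 1.0 + par[I_F_PP] * rpm
    vw = 1.0 + par[I_F_PPW] * rpm
    vt = 1.0 + par[I_F_PP] * rpm / (1.0 + t_count * par[I_F_TR])
    return s, u, v, vw, vt


@njit(cache=True)
def permeation_prob(par, species, inward, fa, pl, ions, t_count):
    """Membrane permeation probability for Nt / Np / Npp / Gp.

    ``species`` is a pool index (NTA..NTU treated alike, NP_, NPP, GP).
    Inward crossing is throttled by cell volume (s), Donnan's equilibrium (u)
    and phospholipid content (v); outward crossing only by the latter.
    The TR transport effect modifies the Np divisor in both directions.
    """
    s, u, v, vw, vt = _perm_factors(par, fa, pl, ions, t_count)
    if species == NP_:
        base, div = par[I_P_NPP], vt
    elif species == NPP:
        base, div = par[I_P_NPPP], vw
    elif species == GP:
        base, div = par[I_P_GPP], vw
        u = 1.0  # glycerol is uncharged: no Donnan term either way
    else:  # a nucleotide
        base, div = par[I_P_NP], v
    if inward:
        return min(1.0, base * s / (u * div))
    return min(1.0, base / div)


# =============================================================================
# phase 1: free-molecule movement, membrane joining and permeation
# =============================================================================

@njit(cache=False)
def phase_move(par, pool, occ, mem_fa, mem_pl, nbr, i_arr, t_arr,
               mv_probs, mv_alias):
    R = pool.shape[0]
    p_mv = par[I_P_MV]
    inbuf = np.zeros((R, NSP), np.int64)
    add_fa = np.zeros(R, np.int64)
    add_pl = np.zeros(R, np.int64)
    # per-protocell crossing probabilities (rows: Nt, Np, Npp, Gp)
    pin = np.zeros((R, 4), np.float64)
    pout = np.zeros((R, 4), np.float64)
    for r in range(R):
        if not occ[r]:
            continue
        b = mem_fa[r] + 2 * mem_pl[r]
        if b <= 0:
            continue
        s, u, v, vw, vt = _perm_factors(par, mem_fa[r], mem_pl[r], i_arr[r], t_arr[r])
        pin[r, 0] = min(1.0, par[I_P_NP] * s / (u * v))
        pin[r, 1] = min(1.0, par[I_P_NPP] * s / (u * vt))
        pin[r, 2] = min(1.0, par[I_P_NPPP] * s / (u * vw))
        pin[r, 3] = min(1.0, par[I_P_GPP] * s / vw)
        pout[r, 0] = min(1.0, par[I_P_NP] / v)
        pout[r, 1] = min(1.0, par[I_P_NPP] / vt)
        pout[r, 2] = min(1.0, par[I_P_NPPP] / vw)
        pout[r, 3] = min(1.0, par[I_P_GPP] / vw)
    for r in range(R):
        if occ[r]:
            # interior molecules: a crossing attempt is movement (P_MV),
            # direction, then the membrane test.  Joins are direction-free;
            # permeation is thinned before the (rare) direction split.
            for sp in range(NSP):
                n = pool[r, sp]
                if n == 0 or sp == G:
                    continue  # glycerophosphate reacts only via synthesis
                if sp == FA:
                    j = _binom(n, p_mv * par[I_P_FJM])
                    add_fa[r] += j
                    pool[r, sp] -= j
                    continue
                if sp == PL:
                    j = _binom(n, p_mv * par[I_P_PJM])
                    add_pl[r] += j
                    pool[r, sp] -= j
                    continue
                if sp == NP_:
                    p_x = pout[r, 1]
                elif sp == NPP:
                    p_x = pout[r, 2]
                elif sp == GP:
                    p_x = pout[r, 3]
                else:
                    p_x = pout[r, 0]
                exiters = _binom(n, p_mv * p_x)
                e0, e1, e2, e3 = _split4(exiters)
                lost = np.int64(0)
                for d in range(4):
                    if d == 0:
                        k = e0
                    elif d == 1:
                        k = e1
                    elif d == 2:
                        k = e2
                    else:
                        k = e3
                    if k == 0:
                        continue
                    q = nbr[r, d]
                    if not occ[q]:  # occupied neighbor: nowhere to land
                        inbuf[q, sp] += k
                        lost += k
                pool[r, sp] -= lost
            continue
        for sp in range(NSP):
            n = pool[r, sp]
            if n == 0:
                continue
            if n <= _NMAX_ALIAS:
                movers = _alias_draw(mv_probs, mv_alias, n)
            else:
                movers = _binom(n, p_mv)
            lost = np.int64(0)
            m0, m1, m2, m3 = _split4(movers)
            for d in range(4):
                if d == 0:
                    k = m0
                elif d == 1:
                    k = m1
                elif d == 2:
                    k = m2
                else:
                    k = m3
                if k == 0:
                    continue
                q = nbr[r, d]
                if not occ[q]:
                    inbuf[q, sp] += k
                    lost += k
                else:
                    # attempt to cross into protocell q
                    if sp == FA:
                        j = _binom(k, par[I_P_FJM])
                        add_fa[q] += j
                    elif sp == PL:
                        j = _binom(k, par[I_P_PJM])
                        add_pl[q] += j
                    elif sp == G:
                        j = 0  # glycerophosphate reacts only from inside
                    elif sp == NP_:
                        j = _binom(k, pin[q, 1])
                        inbuf[q, sp] += j
                    elif sp == NPP:
                        j = _binom(k, pin[q, 2])
                        inbuf[q, sp] += j
                    elif sp == GP:
                        j = _binom(k, pin[q, 3])
                        inbuf[q, sp] += j
                    else:  # a nucleotide
                        j = _binom(k, pin[q, 0])
                        inbuf[q, sp] += j
                    lost += j
            pool[r, sp] -= lost
    for r in range(R):
        mem_fa[r] += add_fa[r]
        mem_pl[r] += add_pl[r]
        for sp in range(NSP):
            pool[r, sp] += inbuf[r, sp]


# =============================================================================
# phase 2: small-molecule reactions
# =============================================================================

@njit(cache=False)
def phase_react(par, pool, occ, act_mask):
    """Formation/decay of Npp/Np/Nt and Gp/G, with presence-gated catalysis.

    ``act_mask`` has bit ``1 << func`` set when a free strand bearing that
    catalytic function sits in the compartment.  All conversion counts are
    drawn from start-of-phase counts (competing risks for Np, which may both
    form a nucleotide and decay), so no molecule reacts twice in one step.
    """
    R = pool.shape[0]
    for r in range(R):
        a = act_mask[r]
        fdo = 1.0 if occ[r] else par[I_F_DO]
        # Npp -> Np
        p_npf = par[I_P_NPFR] if a & (1 << FUNC_NPR) else par[I_P_NPF]
        form_np = _binom(pool[r, NPP], p_npf)
        # Np -> Nt vs Np -> Npp (mutually exclusive fates)
        p_nf = par[I_P_NFR] if a & (1 << FUNC_NR) else par[I_P_NF]
        n_np = pool[r, NP_]
        form_nt = _binom(n_np, p_nf)
        if p_nf < 1.0:
            dec_np = _binom(n_np - form_nt, min(1.0, par[I_P_NPD] / (1.0 - p_nf)))
        else:
            dec_np = 0
        # Nt -> Np (decay, faster outside protocells)
        p_nd = min(1.0, par[I_P_ND] * fdo)
        dec_nt = np.int64(0)
        for bb in range(4):
            d = _binom(pool[r, NTA + bb], p_nd)
            pool[r, NTA + bb] -= d
            dec_nt += d
        # Gp -> G and G -> Gp
        p_gf = par[I_P_GFR] if a & (1 << FUNC_GR) else par[I_P_GF]
        form_g = _binom(pool[r, GP], p_gf)
        dec_g = _binom(pool[r, G], par[I_P_GD])
        # apply
        pool[r, NPP] += dec_np - form_np
        pool[r, NP_] += form_np + dec_nt - form_nt - dec_np
        b0, b1, b2, b3 = _split4(form_nt)
        pool[r, NTA] += b0
        pool[r, NTC] += b1
        pool[r, NTG] += b2
        pool[r, NTU] += b3
        pool[r, GP] += dec_g - form_g
        pool[r, G] += form_g - dec_g


# =============================================================================
# strand-store helpers
# =============================================================================

@njit(cache=True)
def compute_flags(seq_row, L, domains, dom_len):
    """Bitmask of species whose characteristic domain is a substring."""
    f = 0
    for k in range(domains.shape[0]):
        if dom_len <= L:
            hit = False
            for start in range(L - dom_len + 1):
                ok = True
                for j in range(dom_len):
                    if seq_row[start + j] != domains[k, j]:
                        ok = False
                        break
                if ok:
                    hit = True
                    break
            if hit:
                f |= 1 << k
    return f


@njit(cache=True, inline="always")
def _alloc_slot(meta, free_stack):
    ft = meta[0]
    slot = free_stack[ft - 1]
    meta[0] = ft - 1
    if slot + 1 > meta[1]:
        meta[1] = slot + 1
    return slot


@njit(cache=True, inline="always")
def _free_slot(meta, free_stack, s, alive):
    alive[s] = False
    free_stack[meta[0]] = s
    meta[0] += 1


@njit(cache=True)
def _build_lists(top, alive, room, head, nxt):
    head[:] = -1
    for s in range(top):
        if alive[s]:
            r = room[s]
            nxt[s] = head[r]
            head[r] = s


@njit(cache=True)
def scan_strands(top, alive, room, length, dlen, flags, func_codes,
                 i_arr, t_arr, act_mask):
    """Per-room impermeable-ion totals, TR counts and active-function bits.

    Ions count every residue of every strand complex (template plus aligned
    substrates).  Catalytic/transport activity requires a free single strand
    (a duplexed template is inert).
    """
    i_arr[:] = 0
    t_arr[:] = 0
    act_mask[:] = 0
    nsp = func_codes.shape[0]
    for s in range(top):
        if not alive[s]:
            continue
        r = room[s]
        i_arr[r] += length[s] + dlen[s]
        if dlen[s] == 0 and flags[s] != 0:
            f = flags[s]
            for k in range(nsp):
                if f & (1 << k):
                    fc = func_codes[k]
                    if fc != FUNC_NONE:
                        act_mask[r] |= 1 << fc
                        if fc == FUNC_TR:
                            t_arr[r] += 1


# =============================================================================
# phase 3: RNA events
# =============================================================================

@njit(cache=True)
def _shuffled_alive(top, alive):
    n = 0
    for s in range(top):
        if alive[s]:
            n += 1
    idx = np.empty(n, np.int64)
    j = 0
    for s in range(top):
        if alive[s]:
            idx[j] = s
            j += 1
    for k in range(n - 1, 0, -1):  # Fisher-Yates
        m = np.random.randint(0, k + 1)
        tmp = idx[k]
        idx[k] = idx[m]
        idx[m] = tmp
    return idx


@njit(cache=True)
def _random_ligation(par, pool, top, alive, room, length, seq,
                     dstart, dlen, dseq, dbond, flags,
                     meta, free_stack, domains, dom_len, head, nxt):
    """Random end-to-end joining of free nucleotides and bare strands.

    Every unordered pair drawn from the compartment's monomers and bare
    single strands is a pairing opportunity firing with P_RL; a molecule
    ligates at most once per step.
    """
    R = pool.shape[0]
    p_rl = par[I_P_RL]
    if p_rl <= 0.0:
        return
    lmax = seq.shape[1]
    for r in range(R):
        n_mono = (pool[r, NTA] + pool[r, NTC] + pool[r, NTG] + pool[r, NTU])
        n_bare = 0
        s = head[r]
        while s >= 0:
            if alive[s] and dlen[s] == 0:
                n_bare += 1
            s = nxt[s]
        k_ent = n_mono + n_bare
        if k_ent < 2:
            continue
        n_pairs = k_ent * (k_ent - 1) // 2
        n_fire = _binom(n_pairs, p_rl)
        if n_fire == 0:
            continue
        # materialize the entity list: monomers as -(base+1), strands by slot
        ents = np.empty(k_ent, np.int64)
        pos = 0
        for bb in range(4):
            for _ in range(pool[r, NTA + bb]):
                ents[pos] = -(bb + 1)
                pos += 1
        s = head[r]
        while s >= 0:
            if alive[s] and dlen[s] == 0:
                ents[pos] = s
                pos += 1
            s = nxt[s]
        used = np.zeros(k_ent, np.uint8)
        for _ in range(n_fire):
            i = np.random.randint(0, k_ent)
            j = np.random.randint(0, k_ent - 1)
            if j >= i:
                j += 1
            if used[i] or used[j]:
                continue
            # random concatenation order
            if np.random.random() < 0.5:
                i, j = j, i
            a, b = ents[i], ents[j]
            la = 1 if a < 0 else length[a]
            lb = 1 if b < 0 else length[b]
            if la + lb > lmax:
                continue
            used[i] = 1
            used[j] = 1
            if a < 0 and b < 0:
                slot = _alloc_slot(meta, free_stack)
                alive[slot] = True
                room[slot] = r
                length[slot] = 2
                seq[slot, 0] = np.uint8(-a - 1)
                seq[slot, 1] = np.uint8(-b - 1)
                dstart[slot] = -1
                dlen[slot] = 0
                pool[r, NTA + (-a - 1)] -= 1
                pool[r, NTA + (-b - 1)] -= 1
                flags[slot] = compute_flags(seq[slot], 2, domains, dom_len)
            elif a < 0:  # monomer + strand: prepend
                for m in range(lb - 1, -1, -1):
                    seq[b, m + 1] = seq[b, m]
                seq[b, 0] = np.uint8(-a - 1)
                length[b] = lb + 1
                pool[r, NTA + (-a - 1)] -= 1
                flags[b] = compute_flags(seq[b], lb + 1, domains, dom_len)
            elif b < 0:  # strand + monomer: append
                seq[a, la] = np.uint8(-b - 1)
                length[a] = la + 1
                pool[r, NTA + (-b - 1)] -= 1
                flags[a] = compute_flags(seq[a], la + 1, domains, dom_len)
            else:  # strand + strand
                for m in range(lb):
                    seq[a, la + m] = seq[b, m]
                length[a] = la + lb
                _free_slot(meta, free_stack, b, alive)
                flags[a] = compute_flags(seq[a], la + lb, domains, dom_len)


@njit(cache=True)
def _attract_one(par, pool, s, alive, room, length, seq,
                 dstart, dlen, dseq, dbond, meta, free_stack, head, nxt,
                 olig_buf):
    """One substrate-attraction attempt for template ``s`` (P_AT already fired).

    Picks the extension site (either end of the aligned block; a uniform
    anchor position on a bare template), then draws a substrate: with P_FP a
    mispairing monomer (uniform over the in-stock non-complementary bases),
    otherwise the complementary monomer or a fully complementary bare
    oligomer from the same compartment, in proportion to their counts.
    Returns 1 if a substrate was aligned.
    """
    r = room[s]
    L = length[s]
    dl = dlen[s]
    ds = dstart[s]
    bare = dl == 0
    left_ext = False
    if bare:
        pos = np.random.randint(0, L)
    else:
        can_left = ds > 0
        can_right = ds + dl < L
        if can_left and can_right:
            left_ext = np.random.random() < 0.5
        elif can_left:
            left_ext = True
        pos = ds - 1 if left_ext else ds + dl
    tb = seq[s, pos]
    cb = 3 - tb
    if np.random.random() < par[I_P_FP]:
        # false pairing: a random non-complementary base, if any in stock
        tot = np.int64(0)
        for bb in range(4):
            if bb != cb:
                tot += pool[r, NTA + bb]
        if tot == 0:
            return 0
        u = np.random.randint(0, tot)
        pick = -1
        acc = np.int64(0)
        for bb in range(4):
            if bb != cb:
                acc += pool[r, NTA + bb]
                if u < acc:
                    pick = bb
                    break
        pool[r, NTA + pick] -= 1
        _place_monomer(s, pos, np.uint8(pick), bare, left_ext,
                       dstart, dlen, dseq, dbond)
        return 1
    # correct pairing: monomers of the complementary base compete with
    # fully complementary bare oligomers from the same compartment
    w_m = pool[r, NTA + cb]
    n_olig = 0
    cand = head[r]
    buf_cap = olig_buf.shape[0]
    while cand >= 0:
        if cand != s and alive[cand] and dlen[cand] == 0:
            if _olig_fits(cand, s, pos, bare, left_ext, length, seq):
                if n_olig < buf_cap:
                    olig_buf[n_olig] = cand
                n_olig += 1
        cand = nxt[cand]
    if n_olig > buf_cap:
        n_olig = buf_cap
    total = w_m + n_olig
    if total == 0:
        return 0
    u = np.random.randint(0, total)
    if u < w_m:
        pool[r, NTA + cb] -= 1
        _place_monomer(s, pos, np.uint8(cb), bare, left_ext,
                       dstart, dlen, dseq, dbond)
        return 1
    _place_oligomer(olig_buf[u - w_m], s, pos, bare, left_ext,
                    length, seq, dstart, dlen, dseq, dbond,
                    meta, free_stack, alive)
    return 1


@njit(cache=True, inline="always")
def _olig_fits(o, s, pos, bare, left_ext, length, seq):
    """Does bare strand ``o`` complement the template span at the site?

    The span runs rightward from ``pos`` for right extension (and for bare
    templates, anchored at the chosen position), leftward ending at ``pos``
    for left extension.  Antiparallel pairing: ``o`` (5'->3') must equal the
    reverse complement of the template span.
    """
    lo = length[o]
    L = length[s]
    if lo < 2:
        return False
    if left_ext:
        a = pos - lo + 1
        if a < 0:
            return False
    else:
        a = pos
        if a + lo > L:
            return False
    for m in range(lo):
        if seq[o, lo - 1 - m] != 3 - seq[s, a + m]:
            return False
    return True


@njit(cache=True, inline="always")
def _place_monomer(s, pos, base, bare, left_ext, dstart, dlen, dseq, dbond):
    dseq[s, pos] = base
    if bare:
        dstart[s] = pos
        dlen[s] = 1
    elif left_ext:
        dstart[s] = pos
        dlen[s] += 1
        dbond[s, pos] = 0  # junction to the old block start, not yet ligated
    else:
        dlen[s] += 1
        dbond[s, pos - 1] = 0


@njit(cache=True, inline="always")
def _place_oligomer(o, s, pos, bare, left_ext, length, seq,
                    dstart, dlen, dseq, dbond, meta, free_stack, alive):
    lo = length[o]
    a = pos - lo + 1 if left_ext else pos
    for m in range(lo):
        dseq[s, a + m] = seq[o, lo - 1 - m]
    for m in range(lo - 1):
        dbond[s, a + m] = 1  # the oligomer's own internal bonds
    if bare:
        dstart[s] = a
        dlen[s] = lo
    elif left_ext:
        dbond[s, pos] = 0
        dstart[s] = a
        dlen[s] += lo
    else:
        dbond[s, pos - 1] = 0
        dlen[s] += lo
    _free_slot(meta, free_stack, o, alive)


@njit(cache=True)
def _release_duplex(pool, s, room, length, seq, dstart, dlen, dseq, dbond,
                    alive, meta, free_stack, flags, domains, dom_len):
    """Release all aligned material of ``s`` as free strands / nucleotides.

    Maximal ligated runs become new strands (sequence read antiparallel,
    5'->3'); single unligated residues return to the nucleotide pool.
    """
    r = room[s]
    a = dstart[s]
    end = a + dlen[s]
    seg_start = a
    for j in range(a, end):
        seg_ends = j == end - 1 or dbond[s, j] == 0
        if seg_ends:
            slen = j - seg_start + 1
            if slen == 1:
                pool[r, NTA + dseq[s, seg_start]] += 1
            else:
                slot = _alloc_slot(meta, free_stack)
                alive[slot] = True
                room[slot] = r
                length[slot] = slen
                for m in range(slen):
                    seq[slot, m] = dseq[s, j - m]
                dstart[slot] = -1
                dlen[slot] = 0
                flags[slot] = compute_flags(seq[slot], slen, domains, dom_len)
            seg_start = j + 1
    dlen[s] = 0
    dstart[s] = -1


@njit(cache=True)
def _release_run(pool, s, a, b, room, length, seq, dstart, dlen, dseq, dbond,
                 alive, meta, free_stack, flags, domains, dom_len):
    """Release the aligned run [a, b) from template ``s`` (an end run)."""
    r = room[s]
    rl = b - a
    if rl == 1:
        pool[r, NTA + dseq[s, a]] += 1
    else:
        slot = _alloc_slot(meta, free_stack)
        alive[slot] = True
        room[slot] = r
        length[slot] = rl
        for m in range(rl):
            seq[slot, m] = dseq[s, b - 1 - m]
        dstart[slot] = -1
        dlen[slot] = 0
        flags[slot] = compute_flags(seq[slot], rl, domains, dom_len)
    for j in range(a, b - 1):
        dbond[s, j] = 0
    if a == dstart[s]:
        dstart[s] = b
    dlen[s] -= rl
    if dlen[s] == 0:
        dstart[s] = -1


@njit(cache=True)
def _separate_ends(par, pool, s, room, length, seq, dstart, dlen, dseq, dbond,
                   alive, meta, free_stack, flags, domains, dom_len):
    """Separation events for template ``s``.

    Two kinds of aligned material can leave: a substrate that has not been
    ligated into the growing copy (a lone monomer at a block edge, falling
    with P_SP), and the full complementary chain (the block spans and fully
    ligates the template; it leaves with ``P_SP ** sqrt(L)``).  Ligated
    partial runs are anchored by their base pairs and stay until the copy
    completes — template-directed synthesis ratchets toward full-length,
    faithful products.
    """
    p_sp = par[I_P_SP]
    ds = dstart[s]
    dl = dlen[s]
    if dl <= 0:
        return
    end = ds + dl
    L = length[s]
    if dl == L:
        ligated = True
        for j in range(ds, end - 1):
            if dbond[s, j] == 0:
                ligated = False
                break
        if ligated:
            if np.random.random() < p_sp ** np.sqrt(L):
                _release_run(pool, s, ds, end, room, length, seq, dstart,
                             dlen, dseq, dbond, alive, meta, free_stack,
                             flags, domains, dom_len)
            return
    # unligated lone monomers at the block edges are loose substrates
    left_lone = dl == 1 or dbond[s, ds] == 0
    if left_lone and np.random.random() < p_sp:
        _release_run(pool, s, ds, ds + 1, room, length, seq, dstart, dlen,
                     dseq, dbond, alive, meta, free_stack, flags,
                     domains, dom_len)
        if dlen[s] <= 1:
            return
        end = dstart[s] + dlen[s]
    if dlen[s] >= 2 and dbond[s, end - 2] == 0:
        if np.random.random() < p_sp:
            _release_run(pool, s, end - 1, end, room, length, seq, dstart,
                         dlen, dseq, dbond, alive, meta, free_stack, flags,
                         domains, dom_len)


@njit(cache=True)
def _break_strand(par, pool, s, occ, alive, room, length, seq,
                  dstart, dlen, dseq, dbond, flags, meta, free_stack,
                  domains, dom_len):
    """Backbone bond breaking for one strand (template plus aligned block).

    Bonds facing a ligated nascent bond are a double-stranded site: both
    bonds sever together at the rarer double rate; all other template bonds
    break at the single rate (scaled by F_DO outside protocells).
    """
    r = room[s]
    L = length[s]
    if L < 2:
        return
    outside = not occ[r]
    p1 = bond_break_prob(False, outside, par[I_P_BB], par[I_F_DO])
    p2 = bond_break_prob(True, outside, par[I_P_BB], par[I_F_DO])
    ds = dstart[s]
    dl = dlen[s]
    n_double = 0
    if dl > 1:
        for j in range(ds, ds + dl - 1):
            if dbond[s, j] == 1:
                n_double += 1
    n_single = (L - 1) - n_double
    k1 = _binom(n_single, p1)
    k2 = _binom(n_double, p2)
    if k1 + k2 == 0:
        return
    # sequential sampling of which bonds break
    cut = np.zeros(L - 1, np.uint8)
    rem1, rem_n1 = k1, n_single
    rem2, rem_n2 = k2, n_double
    for j in range(L - 1):
        isdouble = dl > 1 and ds <= j < ds + dl - 1 and dbond[s, j] == 1
        if isdouble:
            if rem2 > 0 and np.random.random() < rem2 / rem_n2:
                cut[j] = 1
                rem2 -= 1
            rem_n2 -= 1
        else:
            if rem1 > 0 and np.random.random() < rem1 / rem_n1:
                cut[j] = 1
                rem1 -= 1
            rem_n1 -= 1
    # copy originals, then rebuild fragments
    tmp_seq = np.empty(L, np.uint8)
    tmp_dseq = np.empty(L, np.uint8)
    tmp_db = np.empty(L, np.uint8)
    aligned = np.zeros(L, np.uint8)
    for m in range(L):
        tmp_seq[m] = seq[s, m]
        tmp_dseq[m] = dseq[s, m]
        tmp_db[m] = dbond[s, m]
    if dl > 0:
        for m in range(ds, ds + dl):
            aligned[m] = 1
    _free_slot(meta, free_stack, s, alive)
    frag_a = 0
    for j in range(L):
        if j == L - 1 or cut[j] == 1:
            frag_b = j  # fragment spans [frag_a, frag_b]
            flen = frag_b - frag_a + 1
            # aligned sub-block of the fragment
            fa_ = -1
            fl_ = 0
            for m in range(frag_a, frag_b + 1):
                if aligned[m]:
                    if fa_ < 0:
                        fa_ = m
                    fl_ += 1
            if flen == 1 and fl_ == 0:
                pool[r, NTA + tmp_seq[frag_a]] += 1
            else:
                slot = _alloc_slot(meta, free_stack)
                alive[slot] = True
                room[slot] = r
                length[slot] = flen
                for m in range(flen):
                    seq[slot, m] = tmp_seq[frag_a + m]
                    dseq[slot, m] = tmp_dseq[frag_a + m]
                    dbond[slot, m] = 0
                if fl_ > 0:
                    dstart[slot] = fa_ - frag_a
                    dlen[slot] = fl_
                    for m in range(fl_ - 1):
                        dbond[slot, fa_ - frag_a + m] = tmp_db[fa_ + m]
                else:
                    dstart[slot] = -1
                    dlen[slot] = 0
                flags[slot] = compute_flags(seq[slot], flen, domains, dom_len)
            frag_a = j + 1


@njit(cache=True)
def _uniform():
    return np.random.random()


@njit(cache=True)
def _end_decay_one(par, pool, occ, s, alive, room, length, seq,
                   dstart, dlen, dseq, dbond, flags, meta, free_stack,
                   domains, dom_len):
    """Chain-end residue decay for one strand; frees it if nothing is left."""
    r = room[s]
    p_nde = min(1.0, par[I_P_NDE] * (1.0 if occ[r] else par[I_F_DO]))
    if p_nde <= 0.0:
        return
    L = length[s]
    dl = dlen[s]
    ds = dstart[s]
    left_single = dl == 0 or ds > 0
    if left_single and L > 0 and np.random.random() < p_nde:
        pool[r, NP_] += 1
        L -= 1
        for m in range(L):
            seq[s, m] = seq[s, m + 1]
        if dl > 0:
            for m in range(L):
                dseq[s, m] = dseq[s, m + 1]
                dbond[s, m] = dbond[s, m + 1]
            ds -= 1
            dstart[s] = ds
        length[s] = L
        flags[s] = compute_flags(seq[s], L, domains, dom_len)
    right_single = dl == 0 or ds + dl < L
    if right_single and L > 0 and np.random.random() < p_nde:
        pool[r, NP_] += 1
        L -= 1
        length[s] = L
        flags[s] = compute_flags(seq[s], L, domains, dom_len)
    if L == 0:
        _free_slot(meta, free_stack, s, alive)


@njit(cache=True)
def phase_rna(par, pool, occ, nbr, alive, room, length, seq,
              dstart, dlen, dseq, dbond, flags, meta, free_stack,
              domains, dom_len, head, nxt):
    """All RNA events of one step, in fixed sub-phase order.

    Random ligation, substrate attraction (randomized strand order; one
    attempt per template), template-directed ligation, duplex separation,
    backbone breaking, chain-end decay, and movement of free strands.
    """
    top = meta[1]
    _build_lists(top, alive, room, head, nxt)
    _random_ligation(par, pool, top, alive, room, length, seq,
                     dstart, dlen, dseq, dbond, flags,
                     meta, free_stack, domains, dom_len, head, nxt)
    # --- attraction (resource competition: randomized order) ---
    # chains below L_TMIN cannot hold a substrate long enough to template:
    # a one-or-two-pair hybrid has no helical stability (the same physics
    # behind the P_SP ** sqrt(n) separation law), so they never nucleate.
    p_at = par[I_P_AT]
    l_tmin = par[I_L_TMIN]
    olig_buf = np.empty(4096, np.int64)
    order = _shuffled_alive(meta[1], alive)
    for ii in range(order.shape[0]):
        s = order[ii]
        if not alive[s] or dlen[s] >= length[s] or length[s] < l_tmin:
            continue
        if np.random.random() < p_at:
            _attract_one(par, pool, s, alive, room, length, seq,
                         dstart, dlen, dseq, dbond, meta, free_stack,
                         head, nxt, olig_buf)
    # --- per-strand pass: template ligation, separation, breaking,
    # end decay, movement (events are rare and strand-local, so one fused
    # sweep in slot order is statistically equivalent to separate sweeps) ---
    p_tl = par[I_P_TL]
    p_sp = par[I_P_SP]
    p_mv = par[I_P_MV]
    top = meta[1]
    for s in range(top):
        if not alive[s]:
            continue
        dl = dlen[s]
        if dl >= 2:
            for j in range(dstart[s], dstart[s] + dl - 1):
                if dbond[s, j] == 0 and np.random.random() < p_tl:
                    dbond[s, j] = 1
        if dl > 0:
            _separate_ends(par, pool, s, room, length, seq, dstart, dlen,
                           dseq, dbond, alive, meta, free_stack,
                           flags, domains, dom_len)
        _break_strand(par, pool, s, occ, alive, room, length, seq,
                      dstart, dlen, dseq, dbond, flags, meta, free_stack,
                      domains, dom_len)
        if not alive[s]:
            continue
        _end_decay_one(par, pool, occ, s, alive, room, length, seq,
                       dstart, dlen, dseq, dbond, flags, meta, free_stack,
                       domains, dom_len)
        if not alive[s]:
            continue
        r = room[s]
        if length[s] == 1 and dlen[s] == 0:
            # a bare length-1 remnant is a free nucleotide, not a strand
            pool[r, NTA + seq[s, 0]] += 1
            _free_slot(meta, free_stack, s, alive)
            continue
        if occ[r]:
            continue
        if np.random.random() < rna_move_prob(length[s] + dlen[s], p_mv):
            q = nbr[r, np.random.randint(0, 4)]
            if not occ[q]:
                room[s] = q


# =============================================================================
# phase 4: membrane events
# =============================================================================

@njit(cache=False)
def phase_membrane(par, pool, occ, mem_fa, mem_pl, nbr, i_arr):
    """Phospholipid synthesis/decay, amphiphile efflux, membrane formation."""
    R = pool.shape[0]
    for r in range(R):
        if occ[r]:
            # phospholipid synthesis: interior G + 2 membrane FA -> membrane PL
            pl0 = mem_pl[r]
            k = _binom(pool[r, G], par[I_P_PF])
            cap = mem_fa[r] // 2
            if k > cap:
                k = cap
            pool[r, G] -= k
            mem_fa[r] -= 2 * k
            mem_pl[r] += k
            # membrane phospholipid decay (pre-synthesis count)
            kd = _binom(pl0, par[I_P_PDM])
            mem_pl[r] -= kd
            mem_fa[r] += 2 * kd
            pool[r, G] += kd
            # interior free phospholipid decay
            kf = _binom(pool[r, PL], par[I_P_PD])
            pool[r, PL] -= kf
            pool[r, FA] += 2 * kf
            pool[r, G] += kf
            # amphiphiles leaving the membrane
            b = mem_fa[r] + 2 * mem_pl[r]
            if b > 0:
                rpm = 2.0 * mem_pl[r] / b
                lf = amphiphile_leave_prob(par[I_P_FLM], i_arr[r], b,
                                           par[I_F_PL], rpm)
                lp = amphiphile_leave_prob(par[I_P_PLM], i_arr[r], b,
                                           par[I_F_PL], rpm)
                kfa = _binom(mem_fa[r], lf)
                kpl = _binom(mem_pl[r], lp)
                mem_fa[r] -= kfa
                mem_pl[r] -= kpl
                fa_in = _binom_half(kfa)
                pl_in = _binom_half(kpl)
                pool[r, FA] += fa_in
                pool[r, PL] += pl_in
                fa_out = kfa - fa_in
                pl_out = kpl - pl_in
                if fa_out + pl_out > 0:
                    # released to the exterior: a random unoccupied neighbor
                    n_t = 0
                    for d in range(4):
                        if not occ[nbr[r, d]]:
                            n_t += 1
                    if n_t == 0:
                        pool[r, FA] += fa_out  # fully enclosed: stays inside
                        pool[r, PL] += pl_out
                    else:
                        remf, remp = fa_out, pl_out
                        left = n_t
                        for d in range(4):
                            q = nbr[r, d]
                            if occ[q]:
                                continue
                            if left > 1:
                                cf = _binom(remf, 1.0 / left)
                                cp = _binom(remp, 1.0 / left)
                            else:
                                cf, cp = remf, remp
                            pool[q, FA] += cf
                            pool[q, PL] += cp
                            remf -= cf
                            remp -= cp
                            left -= 1
            if mem_fa[r] + mem_pl[r] == 0:
                occ[r] = False  # membrane fully dispersed: contents go free
        else:
            # free phospholipid decay
            kf = _binom(pool[r, PL], par[I_P_PD])
            pool[r, PL] -= kf
            pool[r, FA] += 2 * kf
            pool[r, G] += kf
            # membrane formation
            a = pool[r, FA] + 2 * pool[r, PL]
            if a >= par[I_L_AM]:
                if np.random.random() < membrane_formation_prob(
                        a, par[I_P_MF], par[I_L_AM]):
                    mem_fa[r] = pool[r, FA]
                    mem_pl[r] = pool[r, PL]
                    pool[r, FA] = 0
                    pool[r, PL] = 0
                    occ[r] = True


# =============================================================================
# phase 5: protocell events
# =============================================================================

@njit(cache=True)
def _push_room_contents(pool, occ, nbr, q, exclude, head, nxt, room):
    """Displace the free contents of room ``q`` to its unoccupied neighbors.

    ``exclude`` is a room never used as a push target (the initiator's side).
    Returns False when no target exists (the caller decides what to do)."""
    n_t = 0
    for d in range(4):
        t = nbr[q, d]
        if t != exclude and not occ[t]:
            n_t += 1
    if n_t == 0:
        return False
    # split each species multinomially among the targets
    left = n_t
    for d in range(4):
        t = nbr[q, d]
        if t == exclude or occ[t]:
            continue
        for sp in range(NSP):
            n = pool[q, sp]
            if n == 0:
                continue
            k = _binom(n, 1.0 / left) if left > 1 else n
            pool[q, sp] -= k
            pool[t, sp] += k
        left -= 1
    # free strands: uniform target each
    targets = np.empty(n_t, np.int64)
    m = 0
    for d in range(4):
        t = nbr[q, d]
        if t != exclude and not occ[t]:
            targets[m] = t
            m += 1
    s = head[q]
    while s >= 0:
        t = targets[np.random.randint(0, n_t)]
        snext = nxt[s]
        room[s] = t
        nxt[s] = head[t]
        head[t] = s
        s = snext
    head[q] = -1
    return True


@njit(cache=False)
def phase_protocell(par, pool, occ, mem_fa, mem_pl, nbr,
                    alive, room, meta, head, nxt):
    """Protocell movement, fusion, division and breakage."""
    R = pool.shape[0]
    top = meta[1]
    _build_lists(top, alive, room, head, nxt)
    occ_list = np.empty(R, np.int64)
    n_occ = 0
    for r in range(R):
        if occ[r]:
            occ_list[n_occ] = r
            n_occ += 1
    for k in range(n_occ - 1, 0, -1):
        m = np.random.randint(0, k + 1)
        tmp = occ_list[k]
        occ_list[k] = occ_list[m]
        occ_list[m] = tmp
    moved_in = np.zeros(R, np.uint8)
    interior = np.empty(NSP, np.int64)
    # --- movement ---
    p_mc = par[I_P_MC]
    for ii in range(n_occ):
        r = occ_list[ii]
        if not occ[r] or moved_in[r]:
            continue
        if np.random.random() >= p_mc:
            continue
        q = nbr[r, np.random.randint(0, 4)]
        if occ[q]:
            continue
        # lift the protocell out of r (interior kept aside)
        for sp in range(NSP):
            interior[sp] = pool[r, sp]
            pool[r, sp] = 0
        cell_strands = head[r]
        head[r] = -1
        occ[r] = False
        # displace q's free contents; the vacated r is the fallback target
        if not _push_room_contents(pool, occ, nbr, q, r, head, nxt, room):
            for sp in range(NSP):
                pool[r, sp] += pool[q, sp]
                pool[q, sp] = 0
            s = head[q]
            while s >= 0:
                snext = nxt[s]
                room[s] = r
                nxt[s] = head[r]
                head[r] = s
                s = snext
            head[q] = -1
        # set the protocell down in q
        mem_fa[q] = mem_fa[r]
        mem_pl[q] = mem_pl[r]
        mem_fa[r] = 0
        mem_pl[r] = 0
        for sp in range(NSP):
            pool[q, sp] += interior[sp]
        s = cell_strands
        while s >= 0:
            snext = nxt[s]
            room[s] = q
            nxt[s] = head[q]
            head[q] = s
            s = snext
        occ[q] = True
        moved_in[q] = 1
    # --- fusion (each adjacent pair tested once, randomized order) ---
    p_cf = par[I_P_CF]
    if p_cf > 0.0:
        pairs = np.empty((2 * R, 2), np.int64)
        n_pairs = 0
        for r in range(R):
            if not occ[r]:
                continue
            for d in range(2):  # down, right: each pair enumerated once
                q = nbr[r, 2 * d + 1]
                if occ[q] and q != r:
                    pairs[n_pairs, 0] = r
                    pairs[n_pairs, 1] = q
                    n_pairs += 1
        for k in range(n_pairs - 1, 0, -1):
            m = np.random.randint(0, k + 1)
            t0, t1 = pairs[k, 0], pairs[k, 1]
            pairs[k, 0], pairs[k, 1] = pairs[m, 0], pairs[m, 1]
            pairs[m, 0], pairs[m, 1] = t0, t1
        for ii in range(n_pairs):
            r, q = pairs[ii, 0], pairs[ii, 1]
            if not (occ[r] and occ[q]):
                continue
            if np.random.random() >= p_cf:
                continue
            mem_fa[r] += mem_fa[q]
            mem_pl[r] += mem_pl[q]
            mem_fa[q] = 0
            mem_pl[q] = 0
            for sp in range(NSP):
                pool[r, sp] += pool[q, sp]
                pool[q, sp] = 0
            s = head[q]
            while s >= 0:
                snext = nxt[s]
                room[s] = r
                nxt[s] = head[r]
                head[r] = s
                s = snext
            head[q] = -1
            occ[q] = False
    # --- division (fresh room list; cells born or moved this step sit out) ---
    n_div = 0
    for r in range(R):
        if occ[r] and not moved_in[r]:
            occ_list[n_div] = r
            n_div += 1
    for k in range(n_div - 1, 0, -1):
        m = np.random.randint(0, k + 1)
        tmp = occ_list[k]
        occ_list[k] = occ_list[m]
        occ_list[m] = tmp
    for ii in range(n_div):
        r = occ_list[ii]
        if not occ[r]:
            continue
        b = mem_fa[r] + 2 * mem_pl[r]
        if b <= 0:
            continue
        p = division_prob(b, par[I_P_CD], par[I_L_AM])
        if p <= 0.0 or np.random.random() >= p:
            continue
        n_free = 0
        for d in range(4):
            if not occ[nbr[r, d]]:
                n_free += 1
        if n_free == 0:
            continue  # fully surrounded: division suppressed
        pick = np.random.randint(0, n_free)
        q = -1
        for d in range(4):
            t = nbr[r, d]
            if not occ[t]:
                if pick == 0:
                    q = t
                    break
                pick -= 1
        # displace the target room's free contents; if it is walled in,
        # they are engulfed into the offspring's interior instead
        _push_room_contents(pool, occ, nbr, q, r, head, nxt, room)
        # random assortment: every amphiphile and interior entity, p = 1/2
        cf = _binom_half(mem_fa[r])
        cp = _binom_half(mem_pl[r])
        mem_fa[q] = cf
        mem_pl[q] = cp
        mem_fa[r] -= cf
        mem_pl[r] -= cp
        for sp in range(NSP):
            k = _binom_half(pool[r, sp])
            pool[r, sp] -= k
            pool[q, sp] += k
        s = head[r]
        head_r = np.int64(-1)
        while s >= 0:
            snext = nxt[s]
            if np.random.random() < 0.5:
                room[s] = q
                nxt[s] = head[q]
                head[q] = s
            else:
                nxt[s] = head_r
                head_r = s
            s = snext
        head[r] = head_r
        occ[q] = True
        moved_in[q] = 1
        if mem_fa[q] + mem_pl[q] == 0:
            occ[q] = False
        if mem_fa[r] + mem_pl[r] == 0:
            occ[r] = False
    # --- breakage ---
    p_cb = par[I_P_CB]
    for ii in range(n_div):
        r = occ_list[ii]
        if not occ[r]:
            continue
        if np.random.random() < p_cb:
            pool[r, FA] += mem_fa[r]
            pool[r, PL] += mem_pl[r]
            mem_fa[r] = 0
            mem_pl[r] = 0
            occ[r] = False
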