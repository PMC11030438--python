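"""Compiled Wright-Fisher core.

The population is stored sparsely: each haplotype is a length-prefixed row of
site-slot indices sorted by genomic position, and per-slot tables hold the
position, selection coefficient, class, origin generation and bookkeeping
state of every segregating mutation.  Fixed mutations are flagged dead,
skipped (and thereby dropped) during the next generation's gamete copies, and
their slots recycled — observable behaviour is identical to removing them
immediately, since a fixed site multiplies every individual's fitness by the
same factor.

Status codes returned by the kernel:
0 ok; 1 haplotype capacity exceeded; 2 record capacity exceeded;
3 site capacity exceeded; 4 all fitnesses zero; 5 non-finite (infinite)
fitness; 6 sweep failed to resolve within the generation cap.
"""

import numpy as np
from numba import njit

# mutation-class codes
NEUTRAL, BENEFICIAL, DELETERIOUS, SWEEP = 0, 1, 2, 3

# fate codes
SEGREGATING, FIXED, LOST = 0, 1, 2

# DFE kind codes (mirrors models.FitnessEffectDistribution.kind)
K_NEUTRAL, K_FIXED, K_GAMMA, K_LOGNORMAL = 0, 1, 2, 3

STATUS_OK = 0
STATUS_HAP_CAPACITY = 1
STATUS_RECORD_CAPACITY = 2
STATUS_SITE_CAPACITY = 3
STATUS_ZERO_FITNESS = 4
STATUS_INFINITE_FITNESS = 5
STATUS_SWEEP_CAP = 6


@njit(cache=True)
def _draw_s(kind, p1, p2, sign):
    """Draw one selection coefficient; (p1, p2) = (s, -), (mean, shape) or (mu, sigma)."""
    if kind == K_NEUTRAL:
        return 0.0
    if kind == K_FIXED:
        return p1
    if kind == K_GAMMA:
        scale = abs(p1) / p2
        d = np.random.gamma(p2) * scale
        return d if p1 > 0 else -d
    # lognormal
    return sign * np.exp(p1 + p2 * np.random.standard_normal())


@njit(cache=True, inline="always")
def _log_factor(f):
    return np.log(f) if f > 0.0 else -np.inf


@njit(cache=True, inline="always")
def _poisson_small(lam, p0):
    """Inverse-CDF Poisson draw with precomputed p0 = exp(-lam).

    One uniform and (usually) one comparison for the small rates that
    dominate per-gamete draws; large rates fall back to the library sampler.
    """
    if lam <= 0.0:
        return 0
    if lam > 30.0:
        return np.random.poisson(lam)
    u = np.random.random()
    k = 0
    p = p0
    c = p
    while u > c:
        k += 1
        p *= lam / k
        c += p
        if k > 200:
            break
    return k


@njit(cache=True)
def _sorted_insert(row, length, slot, pos, spos):
    """Insert ``slot`` into position-sorted haplotype ``row`` of given length."""
    lo, hi = 0, length
    while lo < hi:
        mid = (lo + hi) // 2
        if spos[row[mid]] < pos:
            lo = mid + 1
        else:
            hi = mid
    for j in range(length, lo, -1):
        row[j] = row[j - 1]
    row[lo] = slot


@njit(cache=True)
def _run_wf_kernel(seed,
                   N_anc, N_post, burn_gens, rec_gens,
                   L, mu, r, h,
                   f_n, f_b,
                   dfe_kind, dfe_p1, dfe_p2, dfe_sign,
                   sweep_enabled, sweep_s, sweep_pos0, sweep_condition,
                   sample_n_req, HCAP, SC, RC, sweep_gen_cap, max_attempts):
    np.random.seed(seed)

    Nmax = max(N_anc, N_post)
    hap = np.zeros((2, 2 * Nmax, HCAP), dtype=np.int32)
    hlen = np.zeros((2, 2 * Nmax), dtype=np.int32)
    cur = 0

    spos = np.zeros(SC, dtype=np.int64)
    ss = np.zeros(SC, dtype=np.float64)
    # per-site log fitness factors, precomputed at birth: log(1+h*s) and
    # log(1+s); -inf encodes a factor clamped to 0 (lethal genotype)
    slhet = np.zeros(SC, dtype=np.float64)
    slhom = np.zeros(SC, dtype=np.float64)
    sclass = np.zeros(SC, dtype=np.int8)
    srec = np.full(SC, -1, dtype=np.int64)
    scnt = np.zeros(SC, dtype=np.int32)
    sstate = np.zeros(SC, dtype=np.int8)  # 0 free, 1 alive, 2 dead (fixed, pending cleanup)
    free = np.empty(SC, dtype=np.int32)
    for i in range(SC):
        free[i] = SC - 1 - i
    nfree = SC
    high = 0
    occ = np.zeros(L, dtype=np.uint8)

    rpos = np.zeros(RC, dtype=np.int64)
    rclass = np.zeros(RC, dtype=np.int8)
    rs = np.zeros(RC, dtype=np.float64)
    rorigin = np.zeros(RC, dtype=np.int64)
    rfate = np.zeros(RC, dtype=np.int8)
    rfix = np.full(RC, -1, dtype=np.int64)
    nrec = 0

    arisen = np.zeros(4, dtype=np.int64)
    nfixed = np.zeros(4, dtype=np.int64)
    nlost = np.zeros(4, dtype=np.int64)

    pending = np.empty(SC, dtype=np.int32)
    npending = 0
    n_sel_alive = 0

    # sweep snapshot buffers (allocated small when no sweep)
    snb = 2 * Nmax if sweep_enabled else 1
    snc = SC if sweep_enabled else 1
    snL = L if sweep_enabled else 1
    sn_hap = np.zeros((snb, HCAP if sweep_enabled else 1), dtype=np.int32)
    sn_hlen = np.zeros(snb, dtype=np.int32)
    sn_spos = np.zeros(snc, dtype=np.int64)
    sn_ss = np.zeros(snc, dtype=np.float64)
    sn_slhet = np.zeros(snc, dtype=np.float64)
    sn_slhom = np.zeros(snc, dtype=np.float64)
    sn_sclass = np.zeros(snc, dtype=np.int8)
    sn_srec = np.full(snc, -1, dtype=np.int64)
    sn_sstate = np.zeros(snc, dtype=np.int8)
    sn_free = np.zeros(snc, dtype=np.int32)
    sn_occ = np.zeros(snL, dtype=np.uint8)
    sn_arisen = np.zeros(4, dtype=np.int64)
    sn_nfixed = np.zeros(4, dtype=np.int64)
    sn_nlost = np.zeros(4, dtype=np.int64)
    sn_nfree = 0
    sn_high = 0
    sn_nrec = 0
    sn_nsel = 0
    have_snapshot = False

    w = np.zeros(Nmax, dtype=np.float64)
    cumw = np.zeros(Nmax, dtype=np.float64)
    bps = np.zeros(64, dtype=np.int64)

    mu_L = mu * L
    r_span = r * (L - 1)
    p0_mu = np.exp(-mu_L) if mu_L <= 30.0 else 0.0
    p0_r = np.exp(-r_span) if r_span <= 30.0 else 0.0
    total_gens = burn_gens + rec_gens

    status = STATUS_OK
    t = 0
    N_cur = N_anc
    sweep_site = -1
    sweep_done = False
    attempts = 0

    while True:
        if sweep_enabled == 1:
            if sweep_done:
                break
            if t >= burn_gens and sweep_site == -1:
                if not have_snapshot:
                    # snapshot the post-burn-in population for restart-on-loss
                    for i in range(2 * N_cur):
                        sn_hlen[i] = hlen[cur, i]
                        for j in range(hlen[cur, i]):
                            sn_hap[i, j] = hap[cur, i, j]
                    for j in range(SC):
                        sn_spos[j] = spos[j]
                        sn_ss[j] = ss[j]
                        sn_slhet[j] = slhet[j]
                        sn_slhom[j] = slhom[j]
                        sn_sclass[j] = sclass[j]
                        sn_srec[j] = srec[j]
                        sn_sstate[j] = sstate[j]
                        sn_free[j] = free[j]
                    for j in range(L):
                        sn_occ[j] = occ[j]
                    for j in range(4):
                        sn_arisen[j] = arisen[j]
                        sn_nfixed[j] = nfixed[j]
                        sn_nlost[j] = nlost[j]
                    sn_nfree = nfree
                    sn_high = high
                    sn_nrec = nrec
                    sn_nsel = n_sel_alive
                    have_snapshot = True
                # introduce the sweeping beneficial in one random haplotype
                pos = sweep_pos0
                while occ[pos] == 1:
                    pos = (pos + 1) % L
                if nfree == 0:
                    status = STATUS_SITE_CAPACITY
                    break
                nfree -= 1
                slot = free[nfree]
                if slot + 1 > high:
                    high = slot + 1
                spos[slot] = pos
                ss[slot] = sweep_s
                slhet[slot] = _log_factor(1.0 + h * sweep_s)
                slhom[slot] = _log_factor(1.0 + sweep_s)
                sclass[slot] = SWEEP
                sstate[slot] = 1
                scnt[slot] = 0  # tallied during the coming generation's copies
                occ[pos] = 1
                if nrec >= RC:
                    status = STATUS_RECORD_CAPACITY
                    break
                rpos[nrec] = pos
                rclass[nrec] = SWEEP
                rs[nrec] = sweep_s
                rorigin[nrec] = t
                rfate[nrec] = SEGREGATING
                rfix[nrec] = -1
                srec[slot] = nrec
                nrec += 1
                arisen[SWEEP] += 1
                n_sel_alive += 1
                carrier = np.int64(np.random.random() * 2 * N_cur)
                if carrier >= 2 * N_cur:
                    carrier = 2 * N_cur - 1
                if hlen[cur, carrier] >= HCAP:
                    status = STATUS_HAP_CAPACITY
                    break
                _sorted_insert(hap[cur, carrier], hlen[cur, carrier], slot, pos, spos)
                hlen[cur, carrier] += 1
                sweep_site = slot
            if sweep_site >= 0 and t - burn_gens > sweep_gen_cap:
                status = STATUS_SWEEP_CAP
                break
        elif t >= total_gens:
            break

        N_next = N_post if (t + 1) > burn_gens else N_anc
        nxt = 1 - cur

        # ---- fitness of current parents -------------------------------
        use_fitness = n_sel_alive > 0
        if use_fitness:
            bad = False
            for i in range(N_cur):
                a = 2 * i
                b = 2 * i + 1
                la = hlen[cur, a]
                lb = hlen[cur, b]
                ia = 0
                ib = 0
                logw = 0.0
                while True:
                    while ia < la and sstate[hap[cur, a, ia]] == 2:
                        ia += 1
                    while ib < lb and sstate[hap[cur, b, ib]] == 2:
                        ib += 1
                    if ia >= la and ib >= lb:
                        break
                    if ib >= lb or (ia < la and spos[hap[cur, a, ia]] <= spos[hap[cur, b, ib]]):
                        sa = hap[cur, a, ia]
                        if ib < lb and spos[hap[cur, b, ib]] == spos[sa]:
                            logw += slhom[sa]  # homozygous
                            ia += 1
                            ib += 1
                        else:
                            logw += slhet[sa]
                            ia += 1
                    else:
                        logw += slhet[hap[cur, b, ib]]
                        ib += 1
                wi = np.exp(logw)  # exp(-inf) = 0 for lethal genotypes
                if not np.isfinite(wi):
                    bad = True
                w[i] = wi
            if bad:
                status = STATUS_INFINITE_FITNESS
                break
            tot = 0.0
            for i in range(N_cur):
                tot += w[i]
                cumw[i] = tot
            if tot <= 0.0:
                status = STATUS_ZERO_FITNESS
                break

        # ---- produce 2*N_next gametes ---------------------------------
        # (live-site counts were zeroed during the previous fate scan;
        # slots born this generation start at 1)
        post_burn = (t + 1) > burn_gens
        have_dead = npending > 0  # substitutions from last generation still in lists
        abort = False
        for child in range(2 * N_next):
            # pick a parent proportional to fitness (two independent picks per
            # offspring; gametes 2k and 2k+1 belong to offspring k); the
            # fractional part of the uniform pick doubles as the phase coin
            if use_fitness:
                u = np.random.random() * cumw[N_cur - 1]
                lo = 0
                hi_ = N_cur - 1
                while lo < hi_:
                    mid = (lo + hi_) // 2
                    if cumw[mid] <= u:
                        lo = mid + 1
                    else:
                        hi_ = mid
                parent = lo
                coin = np.random.random() < 0.5
            else:
                u = np.random.random() * N_cur
                parent = np.int64(u)
                if parent >= N_cur:
                    parent = N_cur - 1
                coin = (u - parent) < 0.5

            a = 2 * parent
            b = 2 * parent + 1
            crow = hap[nxt, child]
            clen = 0

            k = _poisson_small(r_span, p0_r)
            if k == 0:
                src = a if coin else b
                ls = hlen[cur, src]
                if ls > HCAP:
                    abort = True
                    break
                if have_dead:
                    for j in range(ls):
                        slot = hap[cur, src, j]
                        if sstate[slot] == 2:
                            continue
                        crow[clen] = slot
                        clen += 1
                        scnt[slot] += 1
                else:
                    for j in range(ls):
                        slot = hap[cur, src, j]
                        crow[j] = slot
                        scnt[slot] += 1
                    clen = ls
            else:
                if k > 64:
                    k = 64  # Poisson(r*(L-1)) beyond 64 crossovers is unreachable at simulated rates
                for j in range(k):
                    bps[j] = 1 + np.int64(np.random.random() * (L - 1))
                # insertion sort (k is small)
                for j in range(1, k):
                    v = bps[j]
                    m = j - 1
                    while m >= 0 and bps[m] > v:
                        bps[m + 1] = bps[m]
                        m -= 1
                    bps[m + 1] = v
                side = 0 if coin else 1
                la = hlen[cur, a]
                lb = hlen[cur, b]
                ia = 0
                ib = 0
                ibp = 0
                while True:
                    while ia < la and sstate[hap[cur, a, ia]] == 2:
                        ia += 1
                    while ib < lb and sstate[hap[cur, b, ib]] == 2:
                        ib += 1
                    if ia >= la and ib >= lb:
                        break
                    if ib >= lb:
                        slot = hap[cur, a, ia]
                        take_from = 0
                        pos = spos[slot]
                        both = False
                    elif ia >= la:
                        slot = hap[cur, b, ib]
                        take_from = 1
                        pos = spos[slot]
                        both = False
                    else:
                        pa = spos[hap[cur, a, ia]]
                        pb = spos[hap[cur, b, ib]]
                        if pa == pb:
                            slot = hap[cur, a, ia]
                            pos = pa
                            take_from = 0
                            both = True
                        elif pa < pb:
                            slot = hap[cur, a, ia]
                            pos = pa
                            take_from = 0
                            both = False
                        else:
                            slot = hap[cur, b, ib]
                            pos = pb
                            take_from = 1
                            both = False
                    while ibp < k and bps[ibp] <= pos:
                        ibp += 1
                    active = (side + ibp) % 2
                    if both:
                        # homozygous in parent: transmitted regardless of phase
                        if clen >= HCAP:
                            abort = True
                            break
                        crow[clen] = slot
                        clen += 1
                        scnt[slot] += 1
                        ia += 1
                        ib += 1
                    else:
                        if take_from == active:
                            if clen >= HCAP:
                                abort = True
                                break
                            crow[clen] = slot
                            clen += 1
                            scnt[slot] += 1
                        if take_from == 0:
                            ia += 1
                        else:
                            ib += 1
                if abort:
                    break

            # new mutations
            m = _poisson_small(mu_L, p0_mu)
            for _ in range(m):
                pos = np.int64(np.random.random() * L)
                if pos >= L:
                    pos = L - 1
                while occ[pos] == 1:
                    pos = np.int64(np.random.random() * L)
                    if pos >= L:
                        pos = L - 1
                u = np.random.random()
                if u < f_n:
                    mcls = NEUTRAL
                elif u < f_n + f_b:
                    mcls = BENEFICIAL
                else:
                    mcls = DELETERIOUS
                sv = _draw_s(dfe_kind[mcls], dfe_p1[mcls], dfe_p2[mcls], dfe_sign[mcls])
                if nfree == 0:
                    abort = True
                    status = STATUS_SITE_CAPACITY
                    break
                nfree -= 1
                slot = free[nfree]
                if slot + 1 > high:
                    high = slot + 1
                spos[slot] = pos
                ss[slot] = sv
                if sv == 0.0:
                    slhet[slot] = 0.0
                    slhom[slot] = 0.0
                else:
                    slhet[slot] = _log_factor(1.0 + h * sv)
                    slhom[slot] = _log_factor(1.0 + sv)
                sclass[slot] = mcls
                sstate[slot] = 1
                scnt[slot] = 1
                occ[pos] = 1
                if sv != 0.0:
                    n_sel_alive += 1
                if post_burn:
                    if nrec >= RC:
                        abort = True
                        status = STATUS_RECORD_CAPACITY
                        break
                    rpos[nrec] = pos
                    rclass[nrec] = mcls
                    rs[nrec] = sv
                    rorigin[nrec] = t + 1
                    rfate[nrec] = SEGREGATING
                    rfix[nrec] = -1
                    srec[slot] = nrec
                    nrec += 1
                    arisen[mcls] += 1
                else:
                    srec[slot] = -1
                if clen >= HCAP:
                    abort = True
                    break
                _sorted_insert(crow, clen, slot, pos, spos)
                clen += 1
            if abort:
                break
            hlen[nxt, child] = clen

        if abort:
            if status == STATUS_OK:
                status = STATUS_HAP_CAPACITY
            break

        # ---- recycle slots of mutations that fixed last generation ----
        for i in range(npending):
            slot = pending[i]
            sstate[slot] = 0
            occ[spos[slot]] = 0
            nfree += 1
            free[nfree - 1] = slot
        npending = 0

        # ---- sweep bookkeeping (restart on loss) ----------------------
        if sweep_site >= 0 and scnt[sweep_site] == 0 and sweep_condition == 1:
            attempts += 1
            if attempts >= max_attempts:
                status = STATUS_SWEEP_CAP
                break
            # restore the snapshot (taken at t = burn_gens, population N_anc);
            # randomness continues from the current stream
            for i in range(snb):
                hlen[0, i] = sn_hlen[i]
                for j in range(sn_hlen[i]):
                    hap[0, i, j] = sn_hap[i, j]
            cur = 0
            for j in range(SC):
                spos[j] = sn_spos[j]
                ss[j] = sn_ss[j]
                slhet[j] = sn_slhet[j]
                slhom[j] = sn_slhom[j]
                sclass[j] = sn_sclass[j]
                srec[j] = sn_srec[j]
                sstate[j] = sn_sstate[j]
                free[j] = sn_free[j]
                scnt[j] = 0  # stale tallies from the failed attempt
            for j in range(L):
                occ[j] = sn_occ[j]
            for j in range(4):
                arisen[j] = sn_arisen[j]
                nfixed[j] = sn_nfixed[j]
                nlost[j] = sn_nlost[j]
            nfree = sn_nfree
            high = sn_high
            nrec = sn_nrec
            n_sel_alive = sn_nsel
            npending = 0
            sweep_site = -1
            t = burn_gens
            N_cur = N_anc
            continue

        # ---- fate scan -------------------------------------------------
        two_n = 2 * N_next
        for slot in range(high):
            if sstate[slot] != 1:
                continue
            c = scnt[slot]
            scnt[slot] = 0  # reset for the next generation's tally
            if c == 0:
                sstate[slot] = 0
                occ[spos[slot]] = 0
                nfree += 1
                free[nfree - 1] = slot
                if ss[slot] != 0.0:
                    n_sel_alive -= 1
                rr = srec[slot]
                if rr >= 0:
                    rfate[rr] = LOST
                    nlost[sclass[slot]] += 1
                if slot == sweep_site:
                    sweep_site = -1
                    sweep_done = True  # unconditional sweep lost: stop
            elif c == two_n:
                sstate[slot] = 2
                pending[npending] = slot
                npending += 1
                if ss[slot] != 0.0:
                    n_sel_alive -= 1
                rr = srec[slot]
                if rr >= 0:
                    rfate[rr] = FIXED
                    rfix[rr] = t + 1
                    nfixed[sclass[slot]] += 1
                if slot == sweep_site:
                    sweep_done = True

        cur = nxt
        N_cur = N_next
        t += 1

    # ---- final sample ---------------------------------------------------
    if status == STATUS_OK:
        sample_n = min(sample_n_req, N_cur)
        # partial Fisher-Yates over individual indices
        order = np.arange(N_cur)
        for i in range(sample_n):
            j = i + np.int64(np.random.random() * (N_cur - i))
            if j >= N_cur:
                j = N_cur - 1
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        colmap = np.full(high, -1, dtype=np.int64)
        nseg = 0
        for slot in range(high):
            if sstate[slot] == 1:
                colmap[slot] = nseg
                nseg += 1
        sm_pos = np.zeros(nseg, dtype=np.int64)
        sm_class = np.zeros(nseg, dtype=np.int8)
        sm_s = np.zeros(nseg, dtype=np.float64)
        for slot in range(high):
            cidx = colmap[slot]
            if cidx >= 0:
                sm_pos[cidx] = spos[slot]
                sm_class[cidx] = sclass[slot]
                sm_s[cidx] = ss[slot]
        matrix = np.zeros((2 * sample_n, nseg), dtype=np.uint8)
        for i in range(sample_n):
            ind = order[i]
            for hrow in range(2):
                src = 2 * ind + hrow
                for j in range(hlen[cur, src]):
                    slot = hap[cur, src, j]
                    cidx = colmap[slot]
                    if cidx >= 0:
                        matrix[2 * i + hrow, cidx] = 1
    else:
        sample_n = 0
        sm_pos = np.zeros(0, dtype=np.int64)
        sm_class = np.zeros(0, dtype=np.int8)
        sm_s = np.zeros(0, dtype=np.float64)
        matrix = np.zeros((0, 0), dtype=np.uint8)

    return (status, t, attempts, nrec,
            rpos[:nrec].copy(), rclass[:nrec].copy(), rs[:nrec].copy(),
            rorigin[:nrec].copy(), rfate[:nrec].copy(), rfix[:nrec].copy(),
            arisen, nfixed, nlost,
            sample_n, sm_pos, sm_class, sm_s, matrix)
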