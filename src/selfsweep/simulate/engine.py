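"""Numba kernels: forward Wright-Fisher life cycle and genealogy trace.

The forward pass simulates a diploid population of N individuals with mixed
mating (selfing probability sigma), viability selection 1 : 1+hs : 1+s at
the selected locus, and free crossover placement along a linear arrangement
of K linked neutral positions.  Nothing but the selected allele is carried
as state: for every gamete we record its parent and a compact bit field
(bit 0 = strand carrying the selected locus, bit i = crossover in interval
i), which is the complete inheritance history of the window.

The backward pass traces the sampled haplotypes through those records,
per neutral position, yielding each position's sample genealogy inside the
window (merge times and compositions).  Below the window the population is
at neutral equilibrium, so the genealogy is completed with the standard
selfing-scaled coalescent expectations: pairwise E[T2] = 2Ne with
Ne = N/(1+F) (after an instantaneous identity-by-descent merge with
probability F for lineage pairs landing in the same founding individual),
and expected branch length subtending i of m lineages 4Ne/i with the
subtended subset uniform.  Diversity and SFS summaries are therefore exact
conditional expectations given the realized window genealogy — no neutral
mutations need to be simulated, and no burn-in is required.

Scenario codes: 0 = de novo, 1 = standing (the allele is held at p0 by
count-conditioned neutral reproduction for the standing phase, then becomes
selected), 2 = recurrent mutation, 3 = neutral control (no selected allele,
fixed number of generations).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# forward status codes
OK = 0
CAP_EXCEEDED = 1
RESTARTS_EXHAUSTED = 2

DE_NOVO = 0
STANDING = 1
RECURRENT = 2
NEUTRAL = 3


@njit(cache=True)
def _popcount(x):
    c = 0
    while x:
        c += x & 1
        x >>= 1
    return c


@njit(cache=True)
def _bernoulli_indices(n, p, out):
    """Skip-sampling of independent Bernoulli(p) successes over range(n).

    Writes success indices into ``out``; returns the count.
    """
    if p <= 0.0:
        return 0
    cnt = 0
    if p >= 1.0:
        for j in range(n):
            out[cnt] = j
            cnt += 1
        return cnt
    log1m = math.log(1.0 - p)
    j = -1
    while True:
        u = np.random.random()
        j += 1 + int(math.log(u) / log1m)
        if j >= n:
            break
        out[cnt] = j
        cnt += 1
        if cnt >= out.shape[0]:
            break
    return cnt


@njit(cache=True)
def _one_attempt(par, rec, allele, allele_next, scratch,
                 N, sigma, s, h, scen, p0_count, mu_b, rho, t_cap, fixed_t):
    """Run one forward attempt.  Returns (status, T, onset).

    status 0: fixation reached (or fixed_t generations done for NEUTRAL);
    status 1: allele lost (caller restarts); status 2: t_cap exceeded.

    For STANDING, ``fixed_t`` is the held standing phase: the founders carry
    the derived allele on ``p0_count`` haplotypes and neutral reproduction is
    conditioned to keep that count fixed — the model's own standing-phase
    assumption — for ``fixed_t`` generations before selection switches on.
    For NEUTRAL, ``fixed_t`` is the total number of forward generations.
    """
    two_n = 2 * N
    # founders
    for j in range(two_n):
        allele[j] = 0
    if scen == DE_NOVO:
        allele[0] = 1
    elif scen == STANDING:
        for j in range(p0_count):
            allele[j] = 1
    sel_on = scen == DE_NOVO or scen == RECURRENT
    onset = fixed_t if scen == STANDING else 0
    n_sites = rho.shape[0]

    t = 0
    while True:
        t += 1
        if t > t_cap:
            return CAP_EXCEEDED, t - 1, onset
        if scen == STANDING:
            sel_on = t > fixed_t
        row = t - 1

        # viability selection via rejection sampling: accept a uniform
        # candidate parent with probability w(genotype)/(1+s)
        acc_het = (1.0 + h * s) / (1.0 + s)
        acc_anc = 1.0 / (1.0 + s)

        count = 0
        pool = np.int64(0)
        pool_bits = 0
        for i in range(N):
            # each uniform is split into a candidate index (26 high bits)
            # and an acceptance / selfing coin (remainder)
            if sel_on:
                while True:
                    u = np.random.random()
                    x = u * 67108864.0  # 2^26
                    i1 = int(x)
                    cand = int(i1 * 1.4901161193847656e-08 * N)
                    g = allele[2 * cand] + allele[2 * cand + 1]
                    if g == 2:
                        break
                    u2 = x - i1
                    if u2 < (acc_het if g == 1 else acc_anc):
                        break
                mother = cand
            else:
                u = np.random.random()
                mother = int(u * N)
            selfed = False
            if sigma > 0.0:
                selfed = np.random.random() < sigma
            if selfed:
                father = mother
            else:
                if sel_on:
                    while True:
                        u = np.random.random()
                        x = u * 67108864.0
                        i1 = int(x)
                        cand = int(i1 * 1.4901161193847656e-08 * N)
                        g = allele[2 * cand] + allele[2 * cand + 1]
                        if g == 2:
                            break
                        u2 = x - i1
                        if u2 < (acc_het if g == 1 else acc_anc):
                            break
                    father = cand
                else:
                    father = int(np.random.random() * N)

            if pool_bits < 2:
                pool = np.random.randint(0, 4611686018427387904)  # 2^62
                pool_bits = 62
            for g in range(2):
                j = 2 * i + g
                q = mother if g == 0 else father
                b = int(pool & 1)
                pool >>= 1
                par[row, j] = q
                a = allele[2 * q + b]
                rec[row, j] = np.uint16(b | (int(a) << 15))
                allele_next[j] = a
                count += a
            pool_bits -= 2

        # held standing phase: condition the derived count back to p0_count
        # by regenerating whole offspring individuals through the true mixed-
        # mating mechanism and accepting regenerations that do not move the
        # count away from the target.  Conditioning at the individual level
        # keeps the genotype composition (selfing homozygosity, heterozygote
        # fraction) that the effective-rate scalings assume; flipping single
        # gametes instead would flood the derived class with heterozygotes.
        if scen == STANDING and not sel_on:
            guard = 0
            while count != p0_count and guard < 500_000:
                guard += 1
                i = np.random.randint(0, N)
                mother = np.random.randint(0, N)
                if sigma > 0.0 and np.random.random() < sigma:
                    father = mother
                else:
                    father = np.random.randint(0, N)
                b0 = 1 if np.random.random() < 0.5 else 0
                b1 = 1 if np.random.random() < 0.5 else 0
                a0 = allele[2 * mother + b0]
                a1 = allele[2 * father + b1]
                old = allele_next[2 * i] + allele_next[2 * i + 1]
                new_count = count + a0 + a1 - old
                if abs(new_count - p0_count) <= abs(count - p0_count):
                    j0 = 2 * i
                    par[row, j0] = mother
                    rec[row, j0] = np.uint16(b0 | (int(a0) << 15))
                    allele_next[j0] = a0
                    par[row, j0 + 1] = father
                    rec[row, j0 + 1] = np.uint16(b1 | (int(a1) << 15))
                    allele_next[j0 + 1] = a1
                    count = new_count
            if count != p0_count:
                return 1, t, onset  # conditioning failed; restart attempt

        # crossovers per interval (independent Bernoulli per gamete)
        for k in range(n_sites):
            m = _bernoulli_indices(two_n, rho[k], scratch)
            bit = np.uint16(1 << (k + 1))
            for idx in range(m):
                rec[row, scratch[idx]] ^= bit

        # recurrent beneficial mutation onto random gametes
        if scen == RECURRENT and mu_b > 0.0:
            m = _bernoulli_indices(two_n, mu_b, scratch)
            for idx in range(m):
                j = scratch[idx]
                if allele_next[j] == 0:
                    allele_next[j] = 1
                    rec[row, j] |= np.uint16(1 << 15)
                    count += 1

        for j in range(two_n):
            allele[j] = allele_next[j]

        if scen == NEUTRAL:
            if t >= fixed_t:
                return OK, t, onset
            continue

        if scen == STANDING and not sel_on:
            continue  # held standing phase cannot lose or fix the allele

        if count == 0:
            if scen == RECURRENT:
                continue  # recurrent mutation will re-introduce the allele
            return 1, t, onset  # lost: restart
        if count == two_n:
            return OK, t, onset


@njit(cache=True)
def _trace_site(par, rec, T, site_mask, samples, n, F, ne2, comb_table,
                derived_count, class_len):
    """Trace one neutral position's sample genealogy back through the window.

    Accumulates expected branch length per derived-count class into
    ``class_len`` (units: generations) and returns (summed pairwise
    coalescence time over all sample pairs with the neutral completion
    included, number of pairs that coalesced on the *derived* background).
    The latter is the event the analytic sweep model prices: a pair counts
    as coalesced only if the merge happens on a haplotype carrying the
    beneficial allele (``derived_root`` marks the founder haplotype that is
    derived at generation zero, or -1 if none).
    """
    # clusters of samples sharing an ancestral haplotype
    cl_pos = np.empty(n, dtype=np.int64)
    cl_mask = np.empty(n, dtype=np.int64)
    cl_birth = np.empty(n, dtype=np.float64)
    for i in range(n):
        cl_pos[i] = samples[i]
        cl_mask[i] = 1 << i
        cl_birth[i] = 0.0
    m = n
    pair_t2 = 0.0
    derived_coal_pairs = 0

    for t in range(T, 0, -1):
        if m == 1:
            break
        row = t - 1
        for c in range(m):
            j = cl_pos[c]
            q = par[row, j]
            strand = _popcount(rec[row, j] & site_mask) & 1
            cl_pos[c] = 2 * q + strand
        tau = float(T - (t - 1))
        # merge clusters that landed on the same ancestral haplotype
        c = 0
        while c < m:
            d = c + 1
            while d < m:
                if cl_pos[d] == cl_pos[c]:
                    sc = _popcount(cl_mask[c])
                    sd = _popcount(cl_mask[d])
                    pair_t2 += sc * sd * tau
                    # derived status of the shared ancestral haplotype
                    if t - 1 >= 1:
                        anc_derived = (rec[t - 2, cl_pos[c]] >> 15) & 1
                    else:
                        anc_derived = 1 if cl_pos[c] < derived_count else 0
                    if anc_derived == 1:
                        derived_coal_pairs += sc * sd
                    if sc < n:
                        class_len[sc - 1] += tau - cl_birth[c]
                    if sd < n:
                        class_len[sd - 1] += tau - cl_birth[d]
                    cl_mask[c] |= cl_mask[d]
                    cl_birth[c] = tau
                    m -= 1
                    cl_pos[d] = cl_pos[m]
                    cl_mask[d] = cl_mask[m]
                    cl_birth[d] = cl_birth[m]
                else:
                    d += 1
            c += 1

    tw = float(T)
    if m > 1:
        # instantaneous IBD merge for root pairs within the same founder
        c = 0
        while c < m:
            d = c + 1
            while d < m:
                if (cl_pos[d] >> 1) == (cl_pos[c] >> 1) and np.random.random() < F:
                    sc = _popcount(cl_mask[c])
                    sd = _popcount(cl_mask[d])
                    pair_t2 += sc * sd * tw
                    if sc < n:
                        class_len[sc - 1] += tw - cl_birth[c]
                    if sd < n:
                        class_len[sd - 1] += tw - cl_birth[d]
                    cl_mask[c] |= cl_mask[d]
                    cl_birth[c] = tw
                    m -= 1
                    cl_pos[d] = cl_pos[m]
                    cl_mask[d] = cl_mask[m]
                    cl_birth[d] = cl_birth[m]
                else:
                    d += 1
            c += 1

    # window branches of the surviving roots end at the window boundary
    sizes = np.empty(m, dtype=np.int64)
    for c in range(m):
        sizes[c] = _popcount(cl_mask[c])
        if sizes[c] < n:
            class_len[sizes[c] - 1] += tw - cl_birth[c]

    if m > 1:
        # neutral-equilibrium completion below the window
        for c in range(m):
            for d in range(c + 1, m):
                pair_t2 += sizes[c] * sizes[d] * (tw + ne2)
        # expected branch lengths: 4Ne/i = 2*ne2/i subtending i of m roots,
        # subset uniform among C(m, i)
        full = (1 << m) - 1
        for sub in range(1, full):
            i = _popcount(sub)
            lsum = 0
            for c in range(m):
                if sub & (1 << c):
                    lsum += sizes[c]
            if lsum <= n - 1:
                class_len[lsum - 1] += 2.0 * ne2 / i / comb_table[m, i]
    return pair_t2, derived_coal_pairs


@njit(cache=True)
def _sample_haplotypes(two_n, n, out):
    """n distinct haplotype indices from range(two_n)."""
    k = 0
    while k < n:
        j = np.random.randint(0, two_n)
        dup = False
        for i in range(k):
            if out[i] == j:
                dup = True
                break
        if not dup:
            out[k] = j
            k += 1


@njit(cache=True)
def run_campaign(seed, n_reps, N, sigma, s, h, scen, p0_count, mu_b, rho,
                 t_cap, restart_cap, fixed_t, n_sample, F, ne2,
                 out_pi, out_esc, out_seg, out_sfs, out_T, out_onset,
                 out_attempts):
    """Simulate ``n_reps`` conditioned replicates and fill the summary arrays.

    out_pi[rep, k]   — expected pi/pi0 at neutral position k given the genealogy
    out_esc[rep, k]  — fraction of sample pairs avoiding derived-background
                       coalescence (the event the analytic ratios model)
    out_seg[rep, k]  — expected segregating sites relative to neutral
    out_sfs[k, l-1]  — summed expected branch length per derived-count class
    out_T, out_onset — window length (generations) and selection-onset time
    out_attempts     — forward attempts consumed (restarts due to loss + 1)

    Returns 0 on success, 2 if the restart cap was exhausted.
    """
    np.random.seed(seed)
    two_n = 2 * N
    n_sites = rho.shape[0]
    n = n_sample
    par = np.empty((t_cap, two_n), dtype=np.uint16)
    rec = np.empty((t_cap, two_n), dtype=np.uint16)
    allele = np.empty(two_n, dtype=np.int8)
    allele_next = np.empty(two_n, dtype=np.int8)
    scratch = np.empty(two_n, dtype=np.int64)
    samples = np.empty(n, dtype=np.int64)
    class_len = np.empty(n - 1, dtype=np.float64)

    comb_table = np.zeros((n + 1, n + 1), dtype=np.float64)
    for mm in range(n + 1):
        comb_table[mm, 0] = 1.0
        for ii in range(1, mm + 1):
            comb_table[mm, ii] = comb_table[mm - 1, ii - 1] + comb_table[mm - 1, ii]

    harm = 0.0
    for l in range(1, n):
        harm += 1.0 / l
    neutral_total_len = 2.0 * ne2 * harm

    npairs = n * (n - 1) / 2.0
    if scen == DE_NOVO:
        derived_count = 1
    elif scen == STANDING:
        derived_count = p0_count
    else:
        derived_count = 0

    for rep in range(n_reps):
        attempts = 0
        while True:
            attempts += 1
            if attempts > restart_cap:
                return RESTARTS_EXHAUSTED
            status, T, onset = _one_attempt(
                par, rec, allele, allele_next, scratch,
                N, sigma, s, h, scen, p0_count, mu_b, rho, t_cap, fixed_t)
            if status == OK:
                break
        out_T[rep] = T
        out_onset[rep] = onset
        out_attempts[rep] = attempts

        _sample_haplotypes(two_n, n, samples)
        for k in range(n_sites):
            site_mask = np.uint16((1 << (k + 2)) - 1)
            for l in range(n - 1):
                class_len[l] = 0.0
            pair_t2, dcoal = _trace_site(par, rec, T, site_mask, samples, n,
                                         F, ne2, comb_table, derived_count,
                                         class_len)
            out_pi[rep, k] = pair_t2 / (npairs * ne2)
            out_esc[rep, k] = 1.0 - dcoal / npairs
            tot = 0.0
            for l in range(n - 1):
                tot += class_len[l]
                out_sfs[k, l] += class_len[l]
            out_seg[rep, k] = tot / neutral_total_len
    return OK


@njit(cache=True)
def trace_site_events(par, rec, T, site_mask, samples, n, F,
                      ev_tau, ev_mask, root_mask, root_pos):
    """Event-level trace of one position (for haplotype export).

    Fills merge events (coalescence time, merged-sample bitmask) and the
    surviving root clusters; returns (n_events, n_roots).  IBD premerges at
    the window boundary are included as events at tau = T.
    """
    cl_pos = np.empty(n, dtype=np.int64)
    cl_mask = np.empty(n, dtype=np.int64)
    for i in range(n):
        cl_pos[i] = samples[i]
        cl_mask[i] = 1 << i
    m = n
    nev = 0
    for t in range(T, 0, -1):
        if m == 1:
            break
        row = t - 1
        for c in range(m):
            j = cl_pos[c]
            q = par[row, j]
            strand = _popcount(rec[row, j] & site_mask) & 1
            cl_pos[c] = 2 * q + strand
        tau = float(T - (t - 1))
        c = 0
        while c < m:
            d = c + 1
            while d < m:
                if cl_pos[d] == cl_pos[c]:
                    cl_mask[c] |= cl_mask[d]
                    ev_tau[nev] = tau
                    ev_mask[nev] = cl_mask[c]
                    nev += 1
                    m -= 1
                    cl_pos[d] = cl_pos[m]
                    cl_mask[d] = cl_mask[m]
                else:
                    d += 1
            c += 1
    tw = float(T)
    if m > 1:
        c = 0
        while c < m:
            d = c + 1
            while d < m:
                if (cl_pos[d] >> 1) == (cl_pos[c] >> 1) and np.random.random() < F:
                    cl_mask[c] |= cl_mask[d]
                    ev_tau[nev] = tw
                    ev_mask[nev] = cl_mask[c]
                    nev += 1
                    m -= 1
                    cl_pos[d] = cl_pos[m]
                    cl_mask[d] = cl_mask[m]
                else:
                    d += 1
            c += 1
    for c in range(m):
        root_mask[c] = cl_mask[c]
        root_pos[c] = cl_pos[c]
    return nev, m


@njit(cache=True)
def run_single(seed, N, sigma, s, h, scen, p0_count, mu_b, rho,
               t_cap, restart_cap, fixed_t, n_sample, F,
               ev_tau, ev_mask, ev_nums, root_mask, root_pos, root_nums,
               sample_out):
    """One conditioned replicate with event-level per-site traces.

    Event arrays are (n_sites, n-1); root arrays (n_sites, n).
    Returns (status, T, onset, attempts).
    """
    np.random.seed(seed)
    two_n = 2 * N
    n_sites = rho.shape[0]
    par = np.empty((t_cap, two_n), dtype=np.uint16)
    rec = np.empty((t_cap, two_n), dtype=np.uint16)
    allele = np.empty(two_n, dtype=np.int8)
    allele_next = np.empty(two_n, dtype=np.int8)
    scratch = np.empty(two_n, dtype=np.int64)

    attempts = 0
    while True:
        attempts += 1
        if attempts > restart_cap:
            return RESTARTS_EXHAUSTED, 0, 0, attempts
        status, T, onset = _one_attempt(
            par, rec, allele, allele_next, scratch,
            N, sigma, s, h, scen, p0_count, mu_b, rho, t_cap, fixed_t)
        if status == OK:
            break

    _sample_haplotypes(two_n, n_sample, sample_out)
    for k in range(n_sites):
        site_mask = np.uint16((1 << (k + 2)) - 1)
        nev, nroot = trace_site_events(par, rec, T, site_mask, sample_out,
                                       n_sample, F,
                                       ev_tau[k], ev_mask[k],
                                       root_mask[k], root_pos[k])
        ev_nums[k] = nev
        root_nums[k] = nroot
    return OK, T, onset, attempts
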