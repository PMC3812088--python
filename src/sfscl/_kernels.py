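"""Numba batch kernels for the structured coalescent.

These kernels simulate genealogies backward in time and accumulate, per
derived-allele frequency class, the total branch length compatible with that
class — without ever materialising a tree. A lineage's frequency class is a
composite index over per-deme descendant counts; because the index is linear
in the descent vector, merging two lineages simply adds their indices.

Waiting times under exponential growth use the exact integrated-hazard
inversion (no Euler stepping). Migration is piecewise-constant between
events; per-deme coalescence and total migration are sampled as competing
risks and re-drawn after every state change (valid by the Markov property).

The pure-Python tree-building simulator in :mod:`sfscl.coalescent` is the
readable reference implementation; the test-suite cross-checks the two.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the simulation core
OK = 0
STUCK = 1  # no coalescence or migration possible and no events left
TIME_CAP = 2

_INF = np.inf


def demography_arrays(d):
    """Flatten a Demography into the array bundle the kernels consume."""
    v = d.num_pops
    nsam = np.asarray(d.sample_sizes, dtype=np.int64)
    sizes = np.asarray(d.sizes, dtype=np.float64)
    growths = np.asarray(d.growth_rates, dtype=np.float64)
    migs = np.stack([np.asarray(m, dtype=np.float64) for m in d.migration_matrices])
    for i in range(migs.shape[0]):
        np.fill_diagonal(migs[i], 0.0)
    rowsum = migs.sum(axis=2)
    ne = len(d.events)
    ev_time = np.empty(ne)
    ev_src = np.empty(ne, dtype=np.int64)
    ev_snk = np.empty(ne, dtype=np.int64)
    ev_prop = np.empty(ne)
    ev_nsize = np.empty(ne)
    ev_ngrow = np.empty(ne)
    ev_mig = np.empty(ne, dtype=np.int64)
    for i, e in enumerate(d.events):
        ev_time[i] = e.time
        ev_src[i] = e.source
        ev_snk[i] = e.sink
        ev_prop[i] = e.proportion
        ev_nsize[i] = np.nan if e.new_size is None else e.new_size
        ev_ngrow[i] = np.nan if e.new_growth is None else e.new_growth
        ev_mig[i] = -1 if e.migration_matrix is None else e.migration_matrix
    dims = nsam + 1
    strides = np.empty(v, dtype=np.int64)
    acc = 1
    for k in range(v - 1, -1, -1):
        strides[k] = acc
        acc *= dims[k]
    nclasses = int(acc)
    return (
        nsam,
        sizes,
        growths,
        migs,
        rowsum,
        ev_time,
        ev_src,
        ev_snk,
        ev_prop,
        ev_nsize,
        ev_ngrow,
        ev_mig,
        strides,
        nclasses,
    )


def pair_strides(d, i: int, j: int):
    """Strides projecting the composite class onto the (i, j) deme pair.

    Demes outside the pair get stride 0, so their descendants do not move the
    class index; the resulting dense array is the exact 2-D marginal spectrum
    (with pair-monomorphic mass landing in the two absorbing corners).
    """
    nsam = np.asarray(d.sample_sizes, dtype=np.int64)
    v = d.num_pops
    strides = np.zeros(v, dtype=np.int64)
    strides[i] = nsam[j] + 1
    strides[j] = 1
    nclasses = int((nsam[i] + 1) * (nsam[j] + 1))
    return strides, nclasses


@njit(cache=True)
def _simulate_one(
    nsam,
    sizes,
    growths,
    migs,
    rowsum,
    ev_time,
    ev_src,
    ev_snk,
    ev_prop,
    ev_nsize,
    ev_ngrow,
    ev_mig,
    strides,
    asc_deme,
    time_cap,
    # scratch buffers
    lin_deme,
    lin_class,
    lin_flag,
    lin_birth,
    size_now,
    growth_now,
    anchor,
    cnt,
    # outputs (accumulated into)
    accum,
    asc_accum,
):
    # A lineage's frequency class is constant between merges, so each branch
    # is accumulated once, at the coalescence that ends it (O(1) per merge).
    v = nsam.shape[0]
    ne = ev_time.shape[0]
    n_act = 0
    for k in range(v):
        cnt[k] = nsam[k]
        size_now[k] = sizes[k]
        growth_now[k] = growths[k]
        anchor[k] = 0.0
        for _ in range(nsam[k]):
            lin_deme[n_act] = k
            lin_class[n_act] = strides[k]
            lin_flag[n_act] = 0
            lin_birth[n_act] = 0.0
            n_act += 1

    if asc_deme >= 0:
        off = 0
        for k in range(asc_deme):
            off += nsam[k]
        na = nsam[asc_deme]
        a = off + int(np.random.random() * na)
        b = off + int(np.random.random() * (na - 1))
        if b >= a:
            b += 1
        lin_flag[a] = 1
        lin_flag[b] = 2

    t = 0.0
    mig_id = 0
    ev_i = 0
    T = 0.0
    Tasc = 0.0

    while n_act > 1:
        t_ev = ev_time[ev_i] if ev_i < ne else _INF

        best_dt = _INF
        best_type = -1
        best_deme = -1
        for k in range(v):
            c = cnt[k]
            if c >= 2:
                g = growth_now[k]
                n_now = size_now[k] * np.exp(-g * (t - anchor[k]))
                rate0 = c * (c - 1) * 0.25 / n_now  # C(c,2)/(2N)
                e = np.random.exponential()
                if g == 0.0:
                    dt = e / rate0
                else:
                    arg = 1.0 + g * e / rate0
                    dt = np.log(arg) / g if arg > 0.0 else _INF
                if dt < best_dt:
                    best_dt = dt
                    best_type = 0
                    best_deme = k
        mtot = 0.0
        for k in range(v):
            mtot += cnt[k] * rowsum[mig_id, k]
        if mtot > 0.0:
            dtm = np.random.exponential() / mtot
            if dtm < best_dt:
                best_dt = dtm
                best_type = 1

        if best_dt == _INF and t_ev == _INF:
            return T, Tasc, STUCK

        if t + best_dt >= t_ev:
            t = t_ev
            for k in range(v):
                size_now[k] = size_now[k] * np.exp(-growth_now[k] * (t - anchor[k]))
                anchor[k] = t
            src = ev_src[ev_i]
            snk = ev_snk[ev_i]
            prop = ev_prop[ev_i]
            if prop > 0.0 and src != snk:
                for i in range(n_act):
                    if lin_deme[i] == src and (
                        prop >= 1.0 or np.random.random() < prop
                    ):
                        lin_deme[i] = snk
                        cnt[src] -= 1
                        cnt[snk] += 1
            if not np.isnan(ev_nsize[ev_i]):
                size_now[snk] = ev_nsize[ev_i]
            if not np.isnan(ev_ngrow[ev_i]):
                growth_now[snk] = ev_ngrow[ev_i]
            if ev_mig[ev_i] >= 0:
                mig_id = ev_mig[ev_i]
            ev_i += 1
            continue

        t += best_dt
        if t > time_cap:
            return T, Tasc, TIME_CAP

        if best_type == 0:
            k = best_deme
            c = cnt[k]
            r = int(np.random.random() * c)
            s = int(np.random.random() * (c - 1))
            if s >= r:
                s += 1
            i1 = -1
            i2 = -1
            seen = 0
            for i in range(n_act):
                if lin_deme[i] == k:
                    if seen == r:
                        i1 = i
                    if seen == s:
                        i2 = i
                    seen += 1
            # close out the two ending branches
            for ii in (i1, i2):
                blen = t - lin_birth[ii]
                accum[lin_class[ii]] += blen
                T += blen
                f = lin_flag[ii]
                if f == 1 or f == 2:
                    asc_accum[lin_class[ii]] += blen
                    Tasc += blen
            lin_class[i1] += lin_class[i2]
            lin_flag[i1] |= lin_flag[i2]
            lin_birth[i1] = t
            lin_deme[i2] = lin_deme[n_act - 1]
            lin_class[i2] = lin_class[n_act - 1]
            lin_flag[i2] = lin_flag[n_act - 1]
            lin_birth[i2] = lin_birth[n_act - 1]
            n_act -= 1
            cnt[k] -= 1
        else:
            u = np.random.random() * mtot
            k = 0
            while k < v - 1:
                w = cnt[k] * rowsum[mig_id, k]
                if u < w:
                    break
                u -= w
                k += 1
            if cnt[k] * rowsum[mig_id, k] <= 0.0:  # float rounding edge
                for kk in range(v):
                    if cnt[kk] * rowsum[mig_id, kk] > 0.0:
                        k = kk
                        break
            idx = int(np.random.random() * cnt[k])
            li = -1
            seen = 0
            for i in range(n_act):
                if lin_deme[i] == k:
                    if seen == idx:
                        li = i
                        break
                    seen += 1
            u2 = np.random.random() * rowsum[mig_id, k]
            j = 0
            while j < v - 1:
                if j != k:
                    if u2 < migs[mig_id, k, j]:
                        break
                    u2 -= migs[mig_id, k, j]
                j += 1
            if j == k:  # numerical edge: redirect to any positive-rate deme
                for jj in range(v):
                    if jj != k and migs[mig_id, k, jj] > 0.0:
                        j = jj
                        break
            lin_deme[li] = j
            cnt[k] -= 1
            cnt[j] += 1

    return T, Tasc, OK


@njit(cache=True)
def expected_sfs_kernel(
    Z,
    seed,
    nsam,
    sizes,
    growths,
    migs,
    rowsum,
    ev_time,
    ev_src,
    ev_snk,
    ev_prop,
    ev_nsize,
    ev_ngrow,
    ev_mig,
    strides,
    nclasses,
    asc_deme,
    time_cap,
):
    """Accumulate per-class branch lengths over Z genealogies.

    Returns (class length sums, ascertained-subtree class length sums,
    per-genealogy total tree lengths, ascertained subtree length sum, status).
    """
    np.random.seed(seed)
    v = nsam.shape[0]
    n = 0
    for k in range(v):
        n += nsam[k]
    lin_deme = np.empty(n, dtype=np.int64)
    lin_class = np.empty(n, dtype=np.int64)
    lin_flag = np.empty(n, dtype=np.uint8)
    lin_birth = np.empty(n)
    size_now = np.empty(v)
    growth_now = np.empty(v)
    anchor = np.empty(v)
    cnt = np.empty(v, dtype=np.int64)
    accum = np.zeros(nclasses)
    asc_accum = np.zeros(nclasses)
    T_arr = np.empty(Z)
    Tasc_sum = 0.0
    for z in range(Z):
        T, Tasc, status = _simulate_one(
            nsam, sizes, growths, migs, rowsum,
            ev_time, ev_src, ev_snk, ev_prop, ev_nsize, ev_ngrow, ev_mig,
            strides, asc_deme, time_cap,
            lin_deme, lin_class, lin_flag, lin_birth, size_now, growth_now, anchor, cnt,
            accum, asc_accum,
        )
        if status != OK:
            return accum, asc_accum, T_arr, Tasc_sum, status
        T_arr[z] = T
        Tasc_sum += Tasc
    return accum, asc_accum, T_arr, Tasc_sum, OK


@njit(cache=True)
def pseudo_data_kernel(
    num_loci,
    mu_locus,
    seed,
    nsam,
    sizes,
    growths,
    migs,
    rowsum,
    ev_time,
    ev_src,
    ev_snk,
    ev_prop,
    ev_nsize,
    ev_ngrow,
    ev_mig,
    strides,
    nclasses,
    asc_deme,
    time_cap,
):
    """Simulate unlinked loci and tabulate mutations into SFS classes.

    Mutation count per locus is Poisson(mu_locus * T); each mutation lands on
    a branch with probability proportional to its length. With ascertainment,
    a mutation is kept only if it falls on the subtree connecting the two
    ascertainment lineages to their MRCA, i.e. only sites heterozygous
    between them are reported (full-tree placement, then filtering).
    """
    np.random.seed(seed)
    v = nsam.shape[0]
    n = 0
    for k in range(v):
        n += nsam[k]
    lin_deme = np.empty(n, dtype=np.int64)
    lin_class = np.empty(n, dtype=np.int64)
    lin_flag = np.empty(n, dtype=np.uint8)
    lin_birth = np.empty(n)
    size_now = np.empty(v)
    growth_now = np.empty(v)
    anchor = np.empty(v)
    cnt = np.empty(v, dtype=np.int64)
    loc_accum = np.zeros(nclasses)
    loc_asc = np.zeros(nclasses)
    counts = np.zeros(nclasses, dtype=np.int64)
    for _ in range(num_loci):
        for c in range(nclasses):
            loc_accum[c] = 0.0
            loc_asc[c] = 0.0
        T, Tasc, status = _simulate_one(
            nsam, sizes, growths, migs, rowsum,
            ev_time, ev_src, ev_snk, ev_prop, ev_nsize, ev_ngrow, ev_mig,
            strides, asc_deme, time_cap,
            lin_deme, lin_class, lin_flag, lin_birth, size_now, growth_now, anchor, cnt,
            loc_accum, loc_asc,
        )
        if status != OK:
            return counts, status
        nmut = np.random.poisson(mu_locus * T)
        for _m in range(nmut):
            if asc_deme >= 0:
                if np.random.random() * T >= Tasc:
                    continue  # mutation invisible to the ascertainment pair
                u = np.random.random() * Tasc
                cum = 0.0
                cls = nclasses - 1
                for c in range(nclasses):
                    cum += loc_asc[c]
                    if u < cum:
                        cls = c
                        break
            else:
                u = np.random.random() * T
                cum = 0.0
                cls = nclasses - 1
                for c in range(nclasses):
                    cum += loc_accum[c]
                    if u < cum:
                        cls = c
                        break
            counts[cls] += 1
    return counts, OK
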