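"""Numba kernels for the two-deme structured coalescent.

Backward-time event grammar is compiled (in :mod:`peripagen.coalescent`) to
piecewise-constant epoch arrays before entering these kernels:

- ``t_bounds``: epoch boundaries, ``t_bounds[0] == 0``, strictly increasing,
  last entry ``np.inf``; epoch ``e`` is active on ``[t_bounds[e], t_bounds[e+1])``.
- ``size0[e]``, ``size1[e]``: diploid effective sizes of demes 0 and 1.
- ``mig01[e]``, ``mig10[e]``: backward per-lineage migration rates
  (0→1 and 1→0 respectively) per generation.
- ``merged[e]``: 1 once the demes have merged (all lineages forced to deme 0,
  migration off).

Within a deme of diploid size ``N`` (and ploidy factor ``pf``), each pair of
lineages coalesces at rate ``1/(4*N*pf) * 2`` per pair per generation, i.e.
``k(k-1)/(4*N*pf)`` overall, so time is measured in generations throughout.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def sim_tree(n1, n2, t_bounds, size0, size1, mig01, mig10, merged, pf, seed):
    """Simulate one genealogy; leaves 0..n1-1 are deme 0, n1..n-1 deme 1.

    Returns (times, parent, node_deme, n_migrations).  Nodes are numbered in
    coalescence order (leaves first); ``parent[root] == -1``.
    """
    np.random.seed(seed)
    n = n1 + n2
    nn = 2 * n - 1
    times = np.zeros(nn)
    parent = np.full(nn, -1, np.int64)
    node_deme = np.zeros(nn, np.int64)
    # active lineages
    node = np.empty(n, np.int64)
    deme = np.empty(n, np.int64)
    for i in range(n):
        node[i] = i
        deme[i] = 0 if i < n1 else 1
        node_deme[i] = deme[i]
    k = n
    t = 0.0
    e = 0
    nxt = n  # next node id
    n_mig = 0
    while k > 1:
        if merged[e] == 1:
            for i in range(k):
                deme[i] = 0
        k0 = 0
        for i in range(k):
            if deme[i] == 0:
                k0 += 1
        k1 = k - k0
        c0 = k0 * (k0 - 1) / (4.0 * size0[e] * pf)
        c1 = k1 * (k1 - 1) / (4.0 * size1[e] * pf)
        g0 = k0 * mig01[e]
        g1 = k1 * mig10[e]
        tot = c0 + c1 + g0 + g1
        if tot <= 0.0:
            t = t_bounds[e + 1]
            e += 1
            continue
        dt = np.random.exponential(1.0 / tot)
        if t + dt >= t_bounds[e + 1]:
            t = t_bounds[e + 1]
            e += 1
            continue
        t += dt
        u = np.random.random() * tot
        if u < c0 + c1:
            d = 0 if u < c0 else 1
            kd = k0 if d == 0 else k1
            # pick an unordered pair within deme d
            r1 = int(np.random.random() * kd)
            r2 = int(np.random.random() * (kd - 1))
            if r2 >= r1:
                r2 += 1
            i1 = -1
            i2 = -1
            c = 0
            for i in range(k):
                if deme[i] == d:
                    if c == r1:
                        i1 = i
                    if c == r2:
                        i2 = i
                    c += 1
            times[nxt] = t
            node_deme[nxt] = d
            parent[node[i1]] = nxt
            parent[node[i2]] = nxt
            node[i1] = nxt
            lo = i2
            node[lo] = node[k - 1]
            deme[lo] = deme[k - 1]
            nxt += 1
            k -= 1
        else:
            d = 0 if u < c0 + c1 + g0 else 1
            kd = k0 if d == 0 else k1
            r = int(np.random.random() * kd)
            c = 0
            for i in range(k):
                if deme[i] == d:
                    if c == r:
                        deme[i] = 1 - d
                        break
                    c += 1
            n_mig += 1
    return times, parent, node_deme, n_mig


@njit(cache=True)
def sim_sfs_branches(n1, n2, t_bounds, size0, size1, mig01, mig10, merged, pf, seed):
    """Accumulate branch lengths by joint descendant counts (i, j).

    Returns matrix B of shape (n1+1, n2+1): total branch length subtending
    exactly i deme-0 leaves and j deme-1 leaves.  E[# segregating sites in
    cell (i,j)] = mu * L * B[i, j] under infinite sites.
    """
    np.random.seed(seed)
    n = n1 + n2
    B = np.zeros((n1 + 1, n2 + 1))
    a = np.empty(n, np.int64)
    b = np.empty(n, np.int64)
    deme = np.empty(n, np.int64)
    for i in range(n):
        a[i] = 1 if i < n1 else 0
        b[i] = 0 if i < n1 else 1
        deme[i] = 0 if i < n1 else 1
    k = n
    t = 0.0
    e = 0
    while k > 1:
        if merged[e] == 1:
            for i in range(k):
                deme[i] = 0
        k0 = 0
        for i in range(k):
            if deme[i] == 0:
                k0 += 1
        k1 = k - k0
        c0 = k0 * (k0 - 1) / (4.0 * size0[e] * pf)
        c1 = k1 * (k1 - 1) / (4.0 * size1[e] * pf)
        g0 = k0 * mig01[e]
        g1 = k1 * mig10[e]
        tot = c0 + c1 + g0 + g1
        if tot <= 0.0:
            t = t_bounds[e + 1]
            e += 1
            continue
        dt = np.random.exponential(1.0 / tot)
        if t + dt >= t_bounds[e + 1]:
            dt = t_bounds[e + 1] - t
            for i in range(k):
                B[a[i], b[i]] += dt
            t = t_bounds[e + 1]
            e += 1
            continue
        for i in range(k):
            B[a[i], b[i]] += dt
        t += dt
        u = np.random.random() * tot
        if u < c0 + c1:
            d = 0 if u < c0 else 1
            kd = k0 if d == 0 else k1
            r1 = int(np.random.random() * kd)
            r2 = int(np.random.random() * (kd - 1))
            if r2 >= r1:
                r2 += 1
            i1 = -1
            i2 = -1
            c = 0
            for i in range(k):
                if deme[i] == d:
                    if c == r1:
                        i1 = i
                    if c == r2:
                        i2 = i
                    c += 1
            a[i1] += a[i2]
            b[i1] += b[i2]
            a[i2] = a[k - 1]
            b[i2] = b[k - 1]
            deme[i2] = deme[k - 1]
            k -= 1
        else:
            d = 0 if u < c0 + c1 + g0 else 1
            kd = k0 if d == 0 else k1
            r = int(np.random.random() * kd)
            c = 0
            for i in range(k):
                if deme[i] == d:
                    if c == r:
                        deme[i] = 1 - d
                        break
                    c += 1
    return B


@njit(cache=True)
def mutate_tree(parent, times, n, rate, seed):
    """Drop infinite-sites mutations at ``rate`` (per generation per branch).

    Returns a boolean (n_sites, n) derived-allele matrix, one row per mutation
    in arbitrary order (positions are assigned by the caller).
    """
    np.random.seed(seed)
    nn = 2 * n - 1
    desc = np.zeros((nn, n), np.bool_)
    for i in range(n):
        desc[i, i] = True
    for v in range(nn - 1):
        p = parent[v]
        for i in range(n):
            if desc[v, i]:
                desc[p, i] = True
    nmut = np.zeros(nn - 1, np.int64)
    total = 0
    for v in range(nn - 1):
        blen = times[parent[v]] - times[v]
        nmut[v] = np.random.poisson(rate * blen)
        total += nmut[v]
    out = np.zeros((total, n), np.bool_)
    s = 0
    for v in range(nn - 1):
        for _ in range(nmut[v]):
            for i in range(n):
                out[s, i] = desc[v, i]
            s += 1
    return out


@njit(cache=True)
def total_branch_length(parent, times):
    tot = 0.0
    for v in range(parent.shape[0]):
        if parent[v] >= 0:
            tot += times[parent[v]] - times[v]
    return tot
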