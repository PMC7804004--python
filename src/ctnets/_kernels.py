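"""Numba kernels for binary-graph metrics.

All functions operate on CSR-style (indptr, indices) adjacency built from a
dense symmetric 0/1 matrix.  They are deliberately allocation-light: the
sparsity sweep evaluates hundreds of thousands of graphs, so each kernel is
O(n + m) to O(n*m) with no Python-level work inside.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "csr_from_dense",
    "component_labels",
    "distance_stats",
    "clustering_mean",
    "local_efficiency_mean",
    "brandes_bc",
    "attack_lcc_sizes",
    "kl_refine",
]


@njit(cache=True)
def csr_from_dense(a):
    n = a.shape[0]
    deg = np.zeros(n, np.int64)
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                deg[i] += 1
    indptr = np.zeros(n + 1, np.int64)
    for i in range(n):
        indptr[i + 1] = indptr[i] + deg[i]
    indices = np.empty(indptr[n], np.int32)
    pos = indptr[:-1].copy()
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                indices[pos[i]] = j
                pos[i] += 1
    return indptr, indices


@njit(cache=True)
def component_labels(indptr, indices, n):
    """Connected-component label per node; labels in discovery order from 0."""
    labels = np.full(n, -1, np.int32)
    queue = np.empty(n, np.int32)
    c = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        labels[s] = c
        qh, qt = 0, 1
        queue[0] = s
        while qh < qt:
            v = queue[qh]
            qh += 1
            for k in range(indptr[v], indptr[v + 1]):
                w = indices[k]
                if labels[w] < 0:
                    labels[w] = c
                    queue[qt] = w
                    qt += 1
        c += 1
    return labels


@njit(cache=True)
def distance_stats(indptr, indices, n, lcc_mask):
    """BFS from every node.

    Returns (sum_dist_lcc, n_ordered_pairs_lcc, sum_inv_dist) where the
    first two restrict to ordered pairs inside the largest component
    (``lcc_mask``) and the inverse-distance sum runs over all ordered
    pairs with 1/inf = 0.
    """
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    sum_d = 0.0
    n_pairs = 0
    sum_inv = 0.0
    for s in range(n):
        for i in range(n):
            dist[i] = -1
        dist[s] = 0
        qh, qt = 0, 1
        queue[0] = s
        while qh < qt:
            v = queue[qh]
            qh += 1
            dv = dist[v]
            for k in range(indptr[v], indptr[v + 1]):
                w = indices[k]
                if dist[w] < 0:
                    dist[w] = dv + 1
                    queue[qt] = w
                    qt += 1
        in_lcc = lcc_mask[s]
        for t in range(n):
            if t == s or dist[t] < 0:
                continue
            d = dist[t]
            sum_inv += 1.0 / d
            if in_lcc and lcc_mask[t]:
                sum_d += d
                n_pairs += 1
    return sum_d, n_pairs, sum_inv


@njit(cache=True)
def clustering_mean(indptr, indices, a, n):
    """Watts-Strogatz clustering: mean over nodes of closed-triple fraction.

    Nodes with degree < 2 contribute 0.
    """
    if n == 0:
        return 0.0
    total = 0.0
    for u in range(n):
        deg = indptr[u + 1] - indptr[u]
        if deg < 2:
            continue
        links = 0
        for p in range(indptr[u], indptr[u + 1]):
            v = indices[p]
            for q in range(p + 1, indptr[u + 1]):
                w = indices[q]
                if a[v, w]:
                    links += 1
        total += 2.0 * links / (deg * (deg - 1))
    return total / n


@njit(cache=True)
def _subgraph_efficiency(members, a):
    """Global efficiency of the subgraph induced by ``members`` (dense lookup)."""
    k = members.shape[0]
    if k < 2:
        return 0.0
    dist = np.empty(k, np.int32)
    queue = np.empty(k, np.int32)
    sum_inv = 0.0
    for s in range(k):
        for i in range(k):
            dist[i] = -1
        dist[s] = 0
        qh, qt = 0, 1
        queue[0] = s
        while qh < qt:
            v = queue[qh]
            qh += 1
            mv = members[v]
            dv = dist[v]
            for w in range(k):
                if dist[w] < 0 and a[mv, members[w]]:
                    dist[w] = dv + 1
                    queue[qt] = w
                    qt += 1
        for t in range(k):
            if t != s and dist[t] > 0:
                sum_inv += 1.0 / dist[t]
    return sum_inv / (k * (k - 1))


@njit(cache=True)
def local_efficiency_mean(indptr, indices, a, n):
    """Mean over nodes of the efficiency of the neighbor-induced subgraph."""
    if n == 0:
        return 0.0
    total = 0.0
    for u in range(n):
        deg = indptr[u + 1] - indptr[u]
        if deg < 2:
            continue
        members = indices[indptr[u]:indptr[u + 1]].astype(np.int32)
        total += _subgraph_efficiency(members, a)
    return total / n


@njit(cache=True)
def brandes_bc(indptr, indices, n):
    """Shortest-path betweenness (Brandes), unordered pairs, endpoints excluded.

    Multiple shortest paths split weight equally.  Works per component on
    disconnected graphs.
    """
    bc = np.zeros(n)
    dist = np.empty(n, np.int32)
    sigma = np.empty(n)
    delta = np.empty(n)
    order = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    for s in range(n):
        for i in range(n):
            dist[i] = -1
            sigma[i] = 0.0
            delta[i] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        qh, qt = 0, 1
        queue[0] = s
        cnt = 0
        while qh < qt:
            v = queue[qh]
            qh += 1
            order[cnt] = v
            cnt += 1
            dv = dist[v]
            sv = sigma[v]
            for k in range(indptr[v], indptr[v + 1]):
                w = indices[k]
                if dist[w] < 0:
                    dist[w] = dv + 1
                    queue[qt] = w
                    qt += 1
                if dist[w] == dv + 1:
                    sigma[w] += sv
        for i in range(cnt - 1, 0, -1):
            w = order[i]
            coef = (1.0 + delta[w]) / sigma[w]
            dw = dist[w]
            for k in range(indptr[w], indptr[w + 1]):
                v = indices[k]
                if dist[v] == dw - 1:
                    delta[v] += sigma[v] * coef
            bc[w] += delta[w]
    return bc / 2.0


@njit(cache=True)
def brandes_with_distances(indptr, indices, n, lcc_mask):
    """Brandes betweenness fused with the all-pairs distance sums.

    One BFS per source serves both the betweenness accumulation and the
    distance statistics of :func:`distance_stats`; returns
    (bc, sum_dist_lcc, n_ordered_pairs_lcc, sum_inv_dist).
    """
    bc = np.zeros(n)
    dist = np.empty(n, np.int32)
    sigma = np.empty(n)
    delta = np.empty(n)
    order = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    sum_d = 0.0
    n_pairs = 0
    sum_inv = 0.0
    for s in range(n):
        for i in range(n):
            dist[i] = -1
            sigma[i] = 0.0
            delta[i] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        qh, qt = 0, 1
        queue[0] = s
        cnt = 0
        while qh < qt:
            v = queue[qh]
            qh += 1
            order[cnt] = v
            cnt += 1
            dv = dist[v]
            sv = sigma[v]
            for k in range(indptr[v], indptr[v + 1]):
                w = indices[k]
                if dist[w] < 0:
                    dist[w] = dv + 1
                    queue[qt] = w
                    qt += 1
                if dist[w] == dv + 1:
                    sigma[w] += sv
        in_lcc = lcc_mask[s]
        for t in range(n):
            if t == s or dist[t] < 0:
                continue
            sum_inv += 1.0 / dist[t]
            if in_lcc and lcc_mask[t]:
                sum_d += dist[t]
                n_pairs += 1
        for i in range(cnt - 1, 0, -1):
            w = order[i]
            coef = (1.0 + delta[w]) / sigma[w]
            dw = dist[w]
            for k in range(indptr[w], indptr[w + 1]):
                v = indices[k]
                if dist[v] == dw - 1:
                    delta[v] += sigma[v] * coef
            bc[w] += delta[w]
    return bc / 2.0, sum_d, n_pairs, sum_inv


@njit(cache=True)
def attack_lcc_sizes(indptr, indices, n, removal_order):
    """Largest-component size after each removal in ``removal_order``.

    Node removal is simulated with an ``active`` mask; each step is a full
    BFS over the surviving subgraph.  Returns an int32 array of length
    ``len(removal_order)``.
    """
    n_steps = removal_order.shape[0]
    active = np.ones(n, np.uint8)
    labels = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    out = np.empty(n_steps, np.int32)
    for step in range(n_steps):
        active[removal_order[step]] = 0
        for i in range(n):
            labels[i] = -1
        best = 0
        for s in range(n):
            if not active[s] or labels[s] >= 0:
                continue
            labels[s] = s
            size = 1
            qh, qt = 0, 1
            queue[0] = s
            while qh < qt:
                v = queue[qh]
                qh += 1
                for k in range(indptr[v], indptr[v + 1]):
                    w = indices[k]
                    if active[w] and labels[w] < 0:
                        labels[w] = s
                        queue[qt] = w
                        qt += 1
                        size += 1
            if size > best:
                best = size
        out[step] = best
    return out


@njit(cache=True)
def leading_eigvec(bg, tol=1e-9, max_iter=150):
    """Leading (most positive) eigenpair of a symmetric matrix.

    Shifted power iteration: the Gershgorin bound makes ``bg + shift*I``
    positive definite with the same leading eigenvector.  Deterministic
    start vector; returns (rayleigh_quotient, vector).  The tolerance is
    deliberately loose: downstream Kernighan-Lin refinement polishes the
    split, so only the eigenvector's sign pattern needs to be roughly
    right.
    """
    k = bg.shape[0]
    shift = 0.0
    for i in range(k):
        row = 0.0
        for j in range(k):
            row += abs(bg[i, j])
        if row > shift:
            shift = row
    v = np.empty(k)
    for i in range(k):
        v[i] = 1.0 + 0.01 * (i % 7)
    v /= np.sqrt(v @ v)
    for _ in range(max_iter):
        w = bg @ v + shift * v
        nrm = np.sqrt(w @ w)
        if nrm == 0.0:
            break
        w /= nrm
        diff = 0.0
        for i in range(k):
            d = w[i] - v[i]
            diff += d * d
        v = w
        if diff < tol:
            break
    lam = v @ (bg @ v)
    return lam, v


@njit(cache=True)
def kl_refine(bg, s, max_passes=10):
    """Kernighan-Lin style refinement of a spectral bisection in place.

    ``bg`` is the (generalized) modularity submatrix and ``s`` the +/-1
    side vector.  Each pass tentatively flips every node once in greedy
    order, keeps the best prefix if it improves s^T B s, and repeats until
    no pass improves.  Deterministic: ties go to the lowest node id.
    Returns the total improvement in s^T B s.
    """
    k = s.shape[0]
    total_gain = 0.0
    bs = bg @ s.astype(np.float64)
    for _ in range(max_passes):
        moved = np.zeros(k, np.uint8)
        flip_seq = np.empty(k, np.int32)
        run = 0.0
        best_run = 0.0
        best_len = 0
        for step in range(k):
            best_i = -1
            best_g = -1e300
            for i in range(k):
                if moved[i]:
                    continue
                g = -4.0 * s[i] * bs[i] + 4.0 * bg[i, i]
                if g > best_g:
                    best_g = g
                    best_i = i
            i = best_i
            moved[i] = 1
            flip_seq[step] = i
            s_i_old = s[i]
            s[i] = -s_i_old
            bs += (-2.0 * s_i_old) * bg[:, i]
            run += best_g
            if run > best_run + 1e-12:
                best_run = run
                best_len = step + 1
        # revert flips beyond the best prefix
        for step in range(k - 1, best_len - 1, -1):
            i = flip_seq[step]
            s_i_old = s[i]
            s[i] = -s_i_old
            bs += (-2.0 * s_i_old) * bg[:, i]
        if best_run <= 1e-12:
            break
        total_gain += best_run
    return total_gain


@njit(cache=True)
def newman_labels(a):
    """Community labels by recursive spectral bisection with KL refinement.

    ``a`` is the dense float64 adjacency.  Implements Newman's modularity
    matrix recursion with an explicit segment stack; a subdivision is kept
    only when it increases Q.  Deterministic.
    """
    n = a.shape[0]
    k = np.zeros(n)
    for i in range(n):
        for j in range(n):
            k[i] += a[i, j]
    m2 = k.sum()
    b = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            b[i, j] = a[i, j] - k[i] * k[j] / m2

    labels = np.zeros(n, np.int32)
    nodes = np.arange(n).astype(np.int64)
    stack_lo = np.empty(2 * n + 2, np.int64)
    stack_hi = np.empty(2 * n + 2, np.int64)
    sp = 0
    stack_lo[sp] = 0
    stack_hi[sp] = n
    sp += 1
    next_label = 1
    while sp > 0:
        sp -= 1
        lo = stack_lo[sp]
        hi = stack_hi[sp]
        sz = hi - lo
        if sz < 2:
            continue
        g = nodes[lo:hi]
        bg = np.empty((sz, sz))
        for ii in range(sz):
            for jj in range(sz):
                bg[ii, jj] = b[g[ii], g[jj]]
        for ii in range(sz):
            row = 0.0
            for jj in range(sz):
                row += bg[ii, jj]
            bg[ii, ii] -= row
        lam, vec = leading_eigvec(bg)
        if lam <= 1e-10:
            continue
        s = np.empty(sz)
        for ii in range(sz):
            s[ii] = 1.0 if vec[ii] >= 0.0 else -1.0
        kl_refine(bg, s)
        dq = s @ (bg @ s)
        if dq <= 1e-10:
            continue
        n_left = 0
        for ii in range(sz):
            if s[ii] > 0:
                n_left += 1
        if n_left == 0 or n_left == sz:
            continue
        # stable partition of the segment: left side first
        buf = np.empty(sz, np.int64)
        p = 0
        for ii in range(sz):
            if s[ii] > 0:
                buf[p] = g[ii]
                p += 1
        for ii in range(sz):
            if s[ii] <= 0:
                buf[p] = g[ii]
                p += 1
        for ii in range(sz):
            nodes[lo + ii] = buf[ii]
        for ii in range(n_left, sz):
            labels[buf[ii]] = next_label
        next_label += 1
        stack_lo[sp] = lo
        stack_hi[sp] = lo + n_left
        sp += 1
        stack_lo[sp] = lo + n_left
        stack_hi[sp] = hi
        sp += 1
    return labels


@njit(cache=True)
def modularity_q_kernel(a, labels):
    """Definitional Newman Q of a labelled partition (dense adjacency)."""
    n = a.shape[0]
    k = np.zeros(n)
    for i in range(n):
        for j in range(n):
            k[i] += a[i, j]
    m2 = k.sum()
    n_c = 0
    for i in range(n):
        if labels[i] + 1 > n_c:
            n_c = labels[i] + 1
    e_c = np.zeros(n_c)
    d_c = np.zeros(n_c)
    for i in range(n):
        d_c[labels[i]] += k[i]
        for j in range(n):
            if a[i, j] and labels[i] == labels[j]:
                e_c[labels[i]] += a[i, j]
    q = 0.0
    for c in range(n_c):
        q += e_c[c] / m2 - (d_c[c] / m2) ** 2
    return q
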