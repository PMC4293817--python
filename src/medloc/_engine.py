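"""Inner loop of the simulated-annealing allocator.

``sa_step`` runs all moves of one temperature step on plain numpy arrays.
It is written as loop code so that the same source runs either as-is
(pure Python, used for tiny instances and validation) or compiled with
numba (used for production-scale runs). Both paths consume the same
pre-drawn uniforms, so their results are bit-identical.
"""

from __future__ import annotations

import numpy as np


def _sa_step_impl(
    times,       # (n, p) travel hours, site x set-member
    tweights,    # (n,) travel weights (demand or 1.0)
    demands,     # (n,) demand loads
    caps,        # (p,) capacities of the set members
    indptr,      # CSR adjacency over sites
    indices,
    gamma,
    lam_cap,
    lam_sp,
    assign,      # (n,) int64, mutated in place
    best_assign,  # (n,) int64, mutated in place
    best,        # best cost so far
    t,           # temperature
    rand,        # (L, 3) uniforms: site pick, neighbor pick, acceptance
):
    n, p = times.shape

    def shortage(load, cap):
        s = (load - cap) / cap
        return s if s > 0.0 else 0.0

    loads = np.zeros(p)
    for i in range(n):
        loads[assign[i]] += demands[i]

    # full cost of the entering state (resynchronizes accumulated deltas)
    travel = 0.0
    for i in range(n):
        travel += tweights[i] * times[i, assign[i]]
    capc = 0.0
    for j in range(p):
        capc += shortage(loads[j], caps[j])
    mono2 = 0
    for i in range(n):
        ai = assign[i]
        for e in range(indptr[i], indptr[i + 1]):
            if assign[indices[e]] == ai:
                mono2 += 1
    cur = travel + lam_cap * capc + lam_sp * (-gamma * mono2)

    n_accept = 0
    elig = np.empty(n, np.int64)
    nb_buf = np.empty(n, np.int64)
    L = rand.shape[0]
    for it in range(L):
        u1 = rand[it, 0]
        u2 = rand[it, 1]
        u3 = rand[it, 2]
        # sites with at least one differently-assigned Voronoi neighbor
        ne = 0
        for i in range(n):
            ai = assign[i]
            for e in range(indptr[i], indptr[i + 1]):
                if assign[indices[e]] != ai:
                    elig[ne] = i
                    ne += 1
                    break
        if ne > 0:
            pick = int(u1 * ne)
            if pick >= ne:
                pick = ne - 1
            i = elig[pick]
            old = assign[i]
            nn = 0
            for e in range(indptr[i], indptr[i + 1]):
                k = indices[e]
                if assign[k] != old:
                    nb_buf[nn] = k
                    nn += 1
            pick = int(u2 * nn)
            if pick >= nn:
                pick = nn - 1
            new = assign[nb_buf[pick]]
        else:
            # uniform assignment everywhere: jump to a random other facility
            if p < 2:
                break
            i = int(u1 * n)
            if i >= n:
                i = n - 1
            old = assign[i]
            idx = int(u2 * (p - 1))
            if idx >= p - 1:
                idx = p - 2
            new = idx if idx < old else idx + 1

        d_travel = tweights[i] * (times[i, new] - times[i, old])
        la = loads[old]
        lb = loads[new]
        di = demands[i]
        d_cap = (
            shortage(lb + di, caps[new])
            - shortage(lb, caps[new])
            + shortage(la - di, caps[old])
            - shortage(la, caps[old])
        )
        cnt_old = 0
        cnt_new = 0
        for e in range(indptr[i], indptr[i + 1]):
            ak = assign[indices[e]]
            if ak == old:
                cnt_old += 1
            elif ak == new:
                cnt_new += 1
        d_spat = -gamma * 2.0 * (cnt_new - cnt_old)
        delta = d_travel + lam_cap * d_cap + lam_sp * d_spat

        if delta <= 0.0 or u3 < np.exp(-delta / t):
            assign[i] = new
            loads[old] = la - di
            loads[new] = lb + di
            cur += delta
            n_accept += 1
            if cur < best:
                best = cur
                for q in range(n):
                    best_assign[q] = assign[q]
    return best, cur, n_accept


sa_step_python = _sa_step_impl

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    sa_step_jit = njit(cache=True)(_sa_step_impl)
except ImportError:  # pragma: no cover
    sa_step_jit = None
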