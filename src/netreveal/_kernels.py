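"""Compiled inner loops of the Monte-Carlo E-step.

Internal layout shared by every kernel:

* nodes are integers ``0 .. n_tot-1``; the first ``n_obs`` are the observed
  residual-graph nodes, the remaining ``T`` are latent slots, slot ``s``
  (the node removed at attack step ``s``) living at index ``n_obs + s``;
* ``C`` is the ``(n_tot, k)`` category-code matrix of the current
  assignment;
* ``Lnk`` is the ``(T, n_tot)`` boolean link matrix of the current
  trajectory: ``Lnk[s, u]`` is the edge between slot ``s`` and ``u``.
  Valid targets of slot ``s`` are the nodes present after its removal:
  observed nodes and slots removed later (``index > s``);
* degrees are replayed with the restoration order ``s = T-1 .. 0`` (slot
  ``T-1`` is restored into the observed graph first).

The attack weight is ``w(d) = d**alpha`` with ``w(0) = 0`` (``w == 1`` for
``alpha == 0``), and a proposed restoration is accepted with probability
``(w(d)/S)**gamma`` where ``S`` sums the weights over the proposed residual
graph — for ``gamma = 1`` this is exactly the attack transition
probability, for ``gamma = 0`` (attack-blind baseline) every attaching
proposal is accepted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "traj_sweep",
    "refine_sweep",
    "swap_sweep",
    "attack_ll_kernel",
    "model_ll_kernel",
    "hist_kernel",
]


@njit(cache=True, inline="always")
def _aw(d, alpha):
    """Attack weight d**alpha; zero-degree nodes are ineligible unless alpha=0."""
    if alpha == 0.0:
        return 1.0
    if d <= 0:
        return 0.0
    return float(d) ** alpha


@njit(cache=True, inline="always")
def _pair_p(P, C, u, v):
    p = 1.0
    for l in range(C.shape[1]):
        p *= P[C[u, l], C[v, l]]
    return p


@njit(cache=True, inline="always")
def _present(u, n_obs, s):
    """Is node u part of the residual graph G_{s+1} (slot s excluded)?"""
    return u < n_obs or (u - n_obs) > s


@njit(cache=True)
def traj_sweep(seed, P, C, deg_obs, Lnk, alpha, gamma, max_attempts, force):
    """Recursive rejection draw of a full restoration path into ``Lnk``.

    For each slot (s = T-1 .. 0) links to all present nodes are proposed
    independently from the model and the proposal is accepted with the
    attack transition probability (raised to gamma).  Zero-degree
    restorations are auto-rejected.  With ``force`` nonzero, a slot whose
    attempt budget runs out commits its best-scoring attempt instead of
    failing (used to initialize the very first sweep).

    Returns -1 on success, or the slot index at which the budget was
    exhausted (``Lnk`` is then left partially filled and must be discarded).
    """
    np.random.seed(seed)
    T = Lnk.shape[0]
    n_tot = Lnk.shape[1]
    n_obs = n_tot - T
    deg = np.zeros(n_tot, np.int64)
    for u in range(n_obs):
        deg[u] = deg_obs[u]
    pv = np.zeros(n_tot)
    prop = np.zeros(n_tot, np.bool_)
    best = np.zeros(n_tot, np.bool_)
    for s in range(T - 1, -1, -1):
        slot = n_obs + s
        for u in range(n_tot):
            Lnk[s, u] = False
            pv[u] = _pair_p(P, C, slot, u) if _present(u, n_obs, s) else 0.0
        accepted = False
        best_score = -1.0
        best_d = 0
        for _ in range(max_attempts):
            d_new = 0
            for u in range(n_tot):
                if pv[u] > 0.0 and np.random.random() < pv[u]:
                    prop[u] = True
                    d_new += 1
                else:
                    prop[u] = False
            if d_new == 0:
                continue
            if gamma == 0.0:
                acc = 1.0
            else:
                wv = _aw(d_new, alpha)
                S = wv
                for u in range(n_tot):
                    if _present(u, n_obs, s):
                        S += _aw(deg[u] + (1 if prop[u] else 0), alpha)
                acc = (wv / S) ** gamma
            if acc >= 1.0 or np.random.random() < acc:
                accepted = True
                for u in range(n_tot):
                    Lnk[s, u] = prop[u]
                    if prop[u]:
                        deg[u] += 1
                deg[slot] = d_new
                break
            if force != 0 and acc > best_score:
                best_score = acc
                best_d = d_new
                for u in range(n_tot):
                    best[u] = prop[u]
        if not accepted:
            if force == 0:
                return s
            if best_score > 0.0:
                for u in range(n_tot):
                    Lnk[s, u] = best[u]
                    if best[u]:
                        deg[u] += 1
                deg[slot] = best_d
            else:
                # every attempt left the slot isolated: attach to the most
                # probable endpoint so the chain can start
                jbest = 0
                pbest = -1.0
                for u in range(n_tot):
                    if pv[u] > pbest:
                        pbest = pv[u]
                        jbest = u
                Lnk[s, jbest] = True
                deg[jbest] += 1
                deg[slot] = 1
    return -1


@njit(cache=True)
def _build_DS(deg_obs, Lnk, alpha, D, Sarr):
    """Per-step degree table and attack-weight sums.

    ``D[s, u]`` is the degree of node u in the residual graph G_s (meaning
    only for nodes present there: observed nodes and slots >= s) and
    ``Sarr[s]`` the attack-weight sum over G_s.
    """
    T = Lnk.shape[0]
    n_tot = Lnk.shape[1]
    n_obs = n_tot - T
    run = np.zeros(n_tot, np.int64)
    for u in range(n_obs):
        run[u] = deg_obs[u]
    for s in range(T - 1, -1, -1):
        slot = n_obs + s
        d_s = 0
        for u in range(n_tot):
            if Lnk[s, u]:
                run[u] += 1
                d_s += 1
        run[slot] += d_s
        total = 0.0
        for u in range(n_tot):
            D[s, u] = run[u]
            if u < n_obs or (u - n_obs) >= s:
                total += _aw(run[u], alpha)
        Sarr[s] = total


@njit(cache=True)
def refine_sweep(seed, P, C, deg_obs, Lnk, alpha, gamma, n_steps, n_redraws, couple):
    """Metropolis chain on each removal event: link-set redraws + rewiring.

    Per event ``k`` (processed from the first-restored slot ``T-1`` down to
    ``0``), ``n_redraws`` independence-MH moves redraw the slot's entire
    link set from the model proposal (each present node linked with its
    pairwise probability), then ``n_steps`` rewiring moves pick an incident
    edge (i, j) of the restored node with probability 1/d(i) and propose a
    new endpoint j' with probability ``p_{i,j'} / sum_y p_{i,y}`` over the
    eligible set (non-neighbors of i plus j, keeping the graph simple;
    forward and reverse eligible sets coincide so their normalizers cancel).

    With ``couple == 0`` the move target is the per-event factor
    ``f(G_k; G_{k+1}) = A_alpha(d_k, G_k)**gamma * prod(link terms)`` and
    the chain leaves it invariant.  With ``couple == 1`` the target is the
    full conditional of event k given the rest of the trajectory, which
    additionally carries ``prod_{k' < k} S_{k'}**-gamma``: the slot and its
    endpoints are present in every earlier residual graph, so changing the
    event also changes the attack normalizers of earlier steps.  Without
    that factor hub restorations escalate beyond what the joint posterior
    supports under strongly degree-targeted attacks.

    Model factors cancel between target and proposal for redraws, so the
    redraw acceptance is a pure ratio of attack terms; zero-degree
    proposals are rejected.  Returns the number of accepted moves.
    """
    np.random.seed(seed)
    T = Lnk.shape[0]
    n_tot = Lnk.shape[1]
    n_obs = n_tot - T
    D = np.zeros((T, n_tot), np.int64)
    Sarr = np.zeros(T)
    prow = np.zeros(n_tot)
    prop = np.zeros(n_tot, np.bool_)
    accepted = 0
    for s in range(T - 1, -1, -1):
        slot = n_obs + s
        _build_DS(deg_obs, Lnk, alpha, D, Sarr)  # fresh tables, no drift
        d_i = 0
        for u in range(n_tot):
            if Lnk[s, u]:
                d_i += 1
        for u in range(n_tot):
            prow[u] = _pair_p(P, C, slot, u) if _present(u, n_obs, s) else 0.0
        kmax = s if couple != 0 else 0  # earlier steps are k' < s
        # ---- link-set redraws (independence MH) ----
        for _ in range(n_redraws):
            d_new = 0
            for u in range(n_tot):
                if prow[u] > 0.0 and np.random.random() < prow[u]:
                    prop[u] = True
                    d_new += 1
                else:
                    prop[u] = False
            if d_new == 0:
                continue
            if gamma == 0.0:
                log_ratio = 0.0
            elif d_i == 0:
                log_ratio = 0.0  # current state outside target support
            else:
                log_ratio = 0.0
                dd = d_new - d_i
                for kp in range(kmax + 1):
                    kk = kp if couple != 0 else s
                    S_new = Sarr[kk]
                    # endpoint toggles
                    for u in range(n_tot):
                        if prop[u] != Lnk[s, u]:
                            delta = 1 if prop[u] else -1
                            S_new += _aw(D[kk, u] + delta, alpha) - _aw(D[kk, u], alpha)
                    # slot-k degree change
                    S_new += _aw(D[kk, slot] + dd, alpha) - _aw(D[kk, slot], alpha)
                    if kk == s:
                        log_ratio += gamma * (
                            np.log(_aw(d_new, alpha) / S_new)
                            - np.log(_aw(d_i, alpha) / Sarr[s])
                        )
                    else:
                        log_ratio += gamma * (np.log(Sarr[kk]) - np.log(S_new))
                    if couple == 0:
                        break
            if log_ratio >= 0.0 or np.log(np.random.random()) < log_ratio:
                dd = d_new - d_i
                for kk in range(s + 1):
                    for u in range(n_tot):
                        if prop[u] != Lnk[s, u]:
                            delta = 1 if prop[u] else -1
                            Sarr[kk] += _aw(D[kk, u] + delta, alpha) - _aw(D[kk, u], alpha)
                            D[kk, u] += delta
                    Sarr[kk] += _aw(D[kk, slot] + dd, alpha) - _aw(D[kk, slot], alpha)
                    D[kk, slot] += dd
                for u in range(n_tot):
                    Lnk[s, u] = prop[u]
                d_i = d_new
                accepted += 1
        if d_i == 0:
            continue
        # ---- rewiring moves ----
        for _ in range(n_steps):
            r = np.random.randint(0, d_i)
            j = -1
            cnt = 0
            for u in range(n_tot):
                if Lnk[s, u]:
                    if cnt == r:
                        j = u
                        break
                    cnt += 1
            total = 0.0
            for u in range(n_tot):
                if prow[u] > 0.0 and (not Lnk[s, u] or u == j):
                    total += prow[u]
            x = np.random.random() * total
            jp = -1
            acc_p = 0.0
            for u in range(n_tot):
                if prow[u] > 0.0 and (not Lnk[s, u] or u == j):
                    acc_p += prow[u]
                    if x < acc_p:
                        jp = u
                        break
            if jp < 0:
                jp = j
            if jp == j:
                continue  # identity move: accepted, state unchanged
            log_ratio = np.log1p(-prow[j]) - np.log1p(-prow[jp])
            ok = True
            if gamma != 0.0:
                for kp in range(kmax + 1):
                    kk = kp if couple != 0 else s
                    S_new = (
                        Sarr[kk]
                        - _aw(D[kk, j], alpha)
                        + _aw(D[kk, j] - 1, alpha)
                        - _aw(D[kk, jp], alpha)
                        + _aw(D[kk, jp] + 1, alpha)
                    )
                    if S_new <= 0.0:
                        ok = False
                        break
                    log_ratio += gamma * (np.log(Sarr[kk]) - np.log(S_new))
                    if couple == 0:
                        break
            if not ok:
                continue
            if log_ratio >= 0.0 or np.log(np.random.random()) < log_ratio:
                for kk in range(s + 1):
                    Sarr[kk] += (
                        _aw(D[kk, j] - 1, alpha)
                        - _aw(D[kk, j], alpha)
                        + _aw(D[kk, jp] + 1, alpha)
                        - _aw(D[kk, jp], alpha)
                    )
                    D[kk, j] -= 1
                    D[kk, jp] += 1
                Lnk[s, j] = False
                Lnk[s, jp] = True
                accepted += 1
    return accepted


@njit(cache=True)
def swap_sweep(seed, P, C, A_full, n_steps):
    """Metropolis swap chain over category assignments.

    Each move swaps the category sequences of two uniformly chosen domain
    elements and accepts with ``min(1, exp(delta))`` where ``delta`` is the
    change of the complete log-likelihood (only the model term depends on
    the assignment; only pairs with differing adjacency contribute).
    Returns the number of accepted swaps.
    """
    np.random.seed(seed)
    n_tot = C.shape[0]
    k = C.shape[1]
    accepted = 0
    for _ in range(n_steps):
        u = np.random.randint(0, n_tot)
        v = np.random.randint(0, n_tot - 1)
        if v >= u:
            v += 1
        same = True
        for l in range(k):
            if C[u, l] != C[v, l]:
                same = False
                break
        if same:
            accepted += 1  # ratio is exactly 1; state unchanged
            continue
        delta = 0.0
        for w in range(n_tot):
            if w == u or w == v:
                continue
            auw = A_full[u, w]
            avw = A_full[v, w]
            if auw == avw:
                continue
            puw = _pair_p(P, C, u, w)
            pvw = _pair_p(P, C, v, w)
            if auw:
                delta += np.log(pvw) - np.log(puw)
                delta += np.log1p(-puw) - np.log1p(-pvw)
            else:
                delta += np.log(puw) - np.log(pvw)
                delta += np.log1p(-pvw) - np.log1p(-puw)
        if delta >= 0.0 or np.log(np.random.random()) < delta:
            for l in range(k):
                tmp = C[u, l]
                C[u, l] = C[v, l]
                C[v, l] = tmp
            accepted += 1
    return accepted


@njit(cache=True)
def attack_ll_kernel(deg_obs, Lnk, alpha):
    """Attack log-likelihood of a trajectory by restoration replay."""
    T = Lnk.shape[0]
    n_tot = Lnk.shape[1]
    n_obs = n_tot - T
    deg = np.zeros(n_tot, np.int64)
    for u in range(n_obs):
        deg[u] = deg_obs[u]
    ll = 0.0
    for s in range(T - 1, -1, -1):
        slot = n_obs + s
        d_new = 0
        for u in range(n_tot):
            if Lnk[s, u]:
                deg[u] += 1
                d_new += 1
        deg[slot] = d_new
        wv = _aw(d_new, alpha)
        if wv <= 0.0:
            return -np.inf
        S = wv
        for u in range(n_tot):
            if _present(u, n_obs, s):
                S += _aw(deg[u], alpha)
        ll += np.log(wv / S)
    return ll


@njit(cache=True)
def model_ll_kernel(P, C, A_obs, Lnk):
    """Bernoulli log-likelihood of the reconstructed original graph."""
    T = Lnk.shape[0]
    n_tot = Lnk.shape[1]
    n_obs = n_tot - T
    ll = 0.0
    for u in range(n_obs):
        for v in range(u + 1, n_obs):
            p = _pair_p(P, C, u, v)
            ll += np.log(p) if A_obs[u, v] else np.log1p(-p)
    for s in range(T):
        slot = n_obs + s
        for u in range(n_tot):
            if _present(u, n_obs, s):
                p = _pair_p(P, C, slot, u)
                ll += np.log(p) if Lnk[s, u] else np.log1p(-p)
    return ll


@njit(cache=True)
def hist_kernel(C, A_full, cls_table, powers, e_hist, ne_hist):
    """Accumulate linked/unlinked pair counts per level-count profile.

    ``cls_table[a, b]`` maps a category pair to its unordered class index and
    ``powers[c] = (k+1)**c`` encodes class counts into a single integer key;
    histograms are accumulated in place (dense, indexed by key).
    """
    n_tot = C.shape[0]
    k = C.shape[1]
    for u in range(n_tot):
        for v in range(u + 1, n_tot):
            key = 0
            for l in range(k):
                key += powers[cls_table[C[u, l], C[v, l]]]
            if A_full[u, v]:
                e_hist[key] += 1.0
            else:
                ne_hist[key] += 1.0
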