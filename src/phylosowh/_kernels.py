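"""Numba-compiled inner loops for the pruning likelihood and branch-length
optimisation, plus the array encodings that feed them.

The kernels evaluate the same partitioned GTR+Γ+I mixture as the NumPy
reference in :mod:`phylosowh.phylomodel` (the test suite asserts agreement)
but without per-node rescaling, which is unnecessary at the tree sizes the
package targets (well under ~100 taxa): if a site likelihood underflows the
kernels return ``-1e300`` and callers treat the proposal as arbitrarily bad.

Branch lengths are optimised by safeguarded Newton steps on each edge using
"above"/"below" partial vectors, refreshed at the start of every sweep; the
best configuration across sweeps is kept, so the returned log-likelihood
never decreases relative to the starting point.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import DataError

MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0
_FAIL = -1e300


# ---------------------------------------------------------------------------
# Encodings

class TreeEncoding:
    """Array form of a tree rooted (for traversal) at an internal node.

    Leaves are numbered by their position in the taxon list; internal nodes
    follow in postorder with the traversal root last.
    """

    __slots__ = ("parents", "porder", "child_ptr", "child_list", "blens",
                 "nodes", "n_leaves")

    def __init__(self, tree, taxon_index: dict[str, int],
                 default_length: float = 0.1):
        L = len(taxon_index)
        post = list(tree.postorder())
        n_internal = sum(1 for n in post if not n.is_leaf)
        M = L + n_internal
        ids: dict[int, int] = {}
        nodes: list = [None] * M
        next_internal = L
        order = []
        leaf_idx = []
        for node in post:
            if node.is_leaf:
                try:
                    i = taxon_index[node.label]
                except KeyError:
                    raise DataError(f"leaf {node.label!r} not in taxon set")
                leaf_idx.append(i)
            else:
                i = next_internal
                next_internal += 1
            ids[id(node)] = i
            nodes[i] = node
            order.append(i)
        if sorted(leaf_idx) != list(range(L)):
            raise DataError("tree leaves do not match the taxon set")
        parents = np.full(M, -1, dtype=np.int64)
        blens = np.zeros(M)
        counts = np.zeros(M + 1, dtype=np.int64)
        for node in post:
            i = ids[id(node)]
            if node.parent is not None:
                parents[i] = ids[id(node.parent)]
                bl = node.length if node.length is not None else default_length
                blens[i] = min(max(bl, MIN_BRANCH), MAX_BRANCH)
        for i in range(M):
            if parents[i] >= 0:
                counts[parents[i] + 1] += 1
        child_ptr = np.cumsum(counts).astype(np.int64)
        child_list = np.empty(M - 1, dtype=np.int64) if M > 1 else np.empty(0, np.int64)
        fill = child_ptr[:-1].copy()
        for i in order:
            p = parents[i]
            if p >= 0:
                child_list[fill[p]] = i
                fill[p] += 1
        self.parents = parents
        self.porder = np.array(order, dtype=np.int64)
        self.child_ptr = child_ptr
        self.child_list = child_list
        self.blens = blens
        self.nodes = nodes
        self.n_leaves = L

    def write_back(self) -> None:
        """Copy optimised branch lengths back onto the tree's nodes."""
        for i, node in enumerate(self.nodes):
            if node is not None and node.parent is not None:
                node.length = float(self.blens[i])


class LikelihoodPack:
    """Model- and data-side arrays consumed by the kernels."""

    __slots__ = ("taxa", "part_off", "leafpart", "wts", "U", "Ui", "lam",
                 "pi", "cat_rates", "cat_w", "pinv", "inv_lik", "_allmatch")

    def __init__(self, patterns, model):
        self.taxa = list(patterns.taxa)
        offs = np.cumsum([0] + [p.n_patterns for p in patterns.parts])
        self.part_off = offs.astype(np.int64)
        masks = np.concatenate([p.masks for p in patterns.parts], axis=1)
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        self.leafpart = ((masks[:, :, None] & bits[None, None, :]) > 0).astype(np.float64)
        # states consistent with every leaf (feeds the invariant class)
        self._allmatch = self.leafpart.all(axis=0)  # (N, 4) bool
        self.wts = np.concatenate([p.weights for p in patterns.parts]).astype(np.float64)
        P = model.n_partitions
        C = model.models[0].n_categories
        self.U = np.empty((P, 4, 4))
        self.Ui = np.empty((P, 4, 4))
        self.lam = np.empty((P, 4))
        self.pi = np.empty((P, 4))
        self.cat_rates = np.empty((P, C))
        self.cat_w = np.empty((P, C))
        self.pinv = np.empty(P)
        self.inv_lik = np.empty(self.part_off[-1])
        self.refresh(model)

    def refresh(self, model) -> None:
        """Rebuild the model-dependent arrays after a parameter change."""
        for q in range(model.n_partitions):
            self.refresh_partition(model, q)

    def refresh_partition(self, model, q: int) -> None:
        sub = model.models[q]
        mult = model.rate_multipliers[q]
        lam, U, Uinv = sub.eigen()
        self.U[q] = U
        self.Ui[q] = Uinv
        self.lam[q] = lam
        self.pi[q] = sub.freqs
        self.cat_rates[q] = sub.category_rates() * mult
        self.cat_w[q] = sub.category_weights()
        self.pinv[q] = sub.p_inv
        s, e = self.part_off[q], self.part_off[q + 1]
        self.inv_lik[s:e] = self._allmatch[s:e] @ sub.freqs


def tree_loglik(enc: TreeEncoding, pack: LikelihoodPack) -> float:
    return _k_loglik(enc.porder, enc.child_ptr, enc.child_list, enc.blens,
                     pack.leafpart, pack.part_off, pack.U, pack.Ui, pack.lam,
                     pack.pi, pack.cat_rates, pack.cat_w, pack.pinv,
                     pack.inv_lik, pack.wts, enc.n_leaves)


def optimize_branches(enc: TreeEncoding, pack: LikelihoodPack,
                      sweeps: int = 4, newton_iters: int = 8,
                      tol: float = 1e-6) -> float:
    """Optimise all branch lengths in place; returns the final lnL."""
    return _k_optimize(enc.porder, enc.child_ptr, enc.child_list, enc.blens,
                       pack.leafpart, pack.part_off, pack.U, pack.Ui, pack.lam,
                       pack.pi, pack.cat_rates, pack.cat_w, pack.pinv,
                       pack.inv_lik, pack.wts, enc.n_leaves,
                       sweeps, newton_iters, tol)


# ---------------------------------------------------------------------------
# Kernels

@njit(cache=False)
def _k_pmat(U, Ui, lam, t, rate, Pm):
    for k in range(4):
        Pm[3, k] = np.exp(lam[k] * t * rate)  # scratch row
    for i in range(4):
        for j in range(4):
            s = 0.0
            for k in range(4):
                s += U[i, k] * Pm[3, k] * Ui[k, j]
            if i < 3:
                Pm[i, j] = s if s > 0.0 else 0.0
            else:
                Pm[i, j] = s
    # fix row 3 (was scratch): recompute cleanly
    e0 = np.exp(lam[0] * t * rate)
    e1 = np.exp(lam[1] * t * rate)
    e2 = np.exp(lam[2] * t * rate)
    e3 = np.exp(lam[3] * t * rate)
    for j in range(4):
        s = U[3, 0] * e0 * Ui[0, j] + U[3, 1] * e1 * Ui[1, j] \
            + U[3, 2] * e2 * Ui[2, j] + U[3, 3] * e3 * Ui[3, j]
        Pm[3, j] = s if s > 0.0 else 0.0


@njit(cache=False)
def _k_fill_F(F, c, q, s, e, porder, child_ptr, child_list, blens, leafpart,
              U, Ui, lam, rate, L):
    M = porder.shape[0]
    Pm = np.empty((4, 4))
    for oi in range(M):
        v = porder[oi]
        if v < L:
            for p in range(s, e):
                for x in range(4):
                    F[c, v, p, x] = leafpart[v, p, x]
            continue
        for p in range(s, e):
            for x in range(4):
                F[c, v, p, x] = 1.0
        for ci in range(child_ptr[v], child_ptr[v + 1]):
            ch = child_list[ci]
            _k_pmat(U[q], Ui[q], lam[q], blens[ch], rate, Pm)
            for p in range(s, e):
                f0 = F[c, ch, p, 0]
                f1 = F[c, ch, p, 1]
                f2 = F[c, ch, p, 2]
                f3 = F[c, ch, p, 3]
                for i in range(4):
                    F[c, v, p, i] *= (Pm[i, 0] * f0 + Pm[i, 1] * f1
                                      + Pm[i, 2] * f2 + Pm[i, 3] * f3)


@njit(cache=False)
def _k_loglik(porder, child_ptr, child_list, blens, leafpart, part_off,
              U, Ui, lam, pi, cat_rates, cat_w, pinv, inv_lik, wts, L):
    M = porder.shape[0]
    P = part_off.shape[0] - 1
    C = cat_rates.shape[1]
    N = leafpart.shape[1]
    root = porder[M - 1]
    F = np.empty((1, M, N, 4))
    total = 0.0
    for q in range(P):
        s, e = part_off[q], part_off[q + 1]
        mix = np.zeros(e - s)
        for c in range(C):
            _k_fill_F(F, 0, q, s, e, porder, child_ptr, child_list, blens,
                      leafpart, U, Ui, lam, cat_rates[q, c], L)
            w = cat_w[q, c]
            for p in range(s, e):
                sl = 0.0
                for x in range(4):
                    sl += pi[q, x] * F[0, root, p, x]
                mix[p - s] += w * sl
        for p in range(s, e):
            lik = mix[p - s] + pinv[q] * inv_lik[p]
            if lik <= 0.0 or not np.isfinite(lik):
                return _FAIL
            total += wts[p] * np.log(lik)
    return total


@njit(cache=False)
def _k_fill_G(F, G, q, s, e, porder, child_ptr, child_list, blens, leafpart,
              U, Ui, lam, pi, cat_rates, L):
    """Above-edge partials: site lik for edge v = sum_i G[v]_i (P(t_v) F[v])_i."""
    M = porder.shape[0]
    C = cat_rates.shape[1]
    root = porder[M - 1]
    Pm = np.empty((4, 4))
    msg = np.empty((3, e - s, 4))  # child messages P(t_ch) @ F[ch]
    H = np.empty((e - s, 4))
    for c in range(C):
        rate = cat_rates[q, c]
        # preorder = reverse postorder: parents before children
        for oi in range(M - 1, -1, -1):
            u = porder[oi]
            if u < L:
                continue
            nch = child_ptr[u + 1] - child_ptr[u]
            # H = partial arriving at u from above (pi at the root)
            if u == root:
                for p in range(e - s):
                    for x in range(4):
                        H[p, x] = pi[q, x]
            else:
                _k_pmat(U[q], Ui[q], lam[q], blens[u], rate, Pm)
                for p in range(s, e):
                    for j in range(4):
                        hv = 0.0
                        for i in range(4):
                            hv += G[c, u, p, i] * Pm[i, j]
                        H[p - s, j] = hv
            # messages from each child
            for ci in range(nch):
                ch = child_list[child_ptr[u] + ci]
                _k_pmat(U[q], Ui[q], lam[q], blens[ch], rate, Pm)
                for p in range(s, e):
                    f0 = F[c, ch, p, 0]
                    f1 = F[c, ch, p, 1]
                    f2 = F[c, ch, p, 2]
                    f3 = F[c, ch, p, 3]
                    for i in range(4):
                        msg[ci, p - s, i] = (Pm[i, 0] * f0 + Pm[i, 1] * f1
                                             + Pm[i, 2] * f2 + Pm[i, 3] * f3)
            # G of each child = H * product of sibling messages
            for ci in range(nch):
                ch = child_list[child_ptr[u] + ci]
                for p in range(s, e):
                    for i in range(4):
                        g = H[p - s, i]
                        for cj in range(nch):
                            if cj != ci:
                                g *= msg[cj, p - s, i]
                        G[c, ch, p, i] = g


@njit(cache=False)
def _k_optimize(porder, child_ptr, child_list, blens, leafpart, part_off,
                U, Ui, lam, pi, cat_rates, cat_w, pinv, inv_lik, wts, L,
                sweeps, newton_iters, tol):
    M = porder.shape[0]
    P = part_off.shape[0] - 1
    C = cat_rates.shape[1]
    N = leafpart.shape[1]
    F = np.empty((C, M, N, 4))
    G = np.empty((C, M, N, 4))
    A = np.empty((C, N, 4))
    B = np.empty((C, N, 4))
    best_blens = blens.copy()
    best_lnl = _k_loglik(porder, child_ptr, child_list, blens, leafpart,
                         part_off, U, Ui, lam, pi, cat_rates, cat_w, pinv,
                         inv_lik, wts, L)
    if best_lnl <= _FAIL:
        return best_lnl
    for sweep in range(sweeps):
        for q in range(P):
            s, e = part_off[q], part_off[q + 1]
            for c in range(C):
                _k_fill_F(F, c, q, s, e, porder, child_ptr, child_list, blens,
                          leafpart, U, Ui, lam, cat_rates[q, c], L)
            _k_fill_G(F, G, q, s, e, porder, child_ptr, child_list, blens,
                      leafpart, U, Ui, lam, pi, cat_rates, L)
        # Newton on every edge against the partials of this sweep
        for oi in range(M - 1):
            v = porder[oi]
            if v == porder[M - 1]:
                continue
            # A = G . U, B = Ui . F  per (category, pattern)
            for q in range(P):
                s, e = part_off[q], part_off[q + 1]
                for c in range(C):
                    for p in range(s, e):
                        for k in range(4):
                            av = 0.0
                            bv = 0.0
                            for i in range(4):
                                av += G[c, v, p, i] * U[q, i, k]
                                bv += Ui[q, k, i] * F[c, v, p, i]
                            A[c, p, k] = av
                            B[c, p, k] = bv
            t = blens[v]
            for it in range(newton_iters):
                d1 = 0.0
                d2 = 0.0
                ok = True
                for q in range(P):
                    s, e = part_off[q], part_off[q + 1]
                    for p in range(s, e):
                        g = pinv[q] * inv_lik[p]
                        g1 = 0.0
                        g2 = 0.0
                        for c in range(C):
                            r = cat_rates[q, c]
                            w = cat_w[q, c]
                            f = 0.0
                            f1 = 0.0
                            f2 = 0.0
                            for k in range(4):
                                lr = lam[q, k] * r
                                ab = A[c, p, k] * B[c, p, k]
                                el = np.exp(lr * t)
                                f += ab * el
                                f1 += ab * el * lr
                                f2 += ab * el * lr * lr
                            g += w * f
                            g1 += w * f1
                            g2 += w * f2
                        if g <= 0.0 or not np.isfinite(g):
                            ok = False
                            break
                        d1 += wts[p] * g1 / g
                        d2 += wts[p] * (g2 * g - g1 * g1) / (g * g)
                    if not ok:
                        break
                if not ok:
                    break
                if d2 < 0.0:
                    step = -d1 / d2
                else:
                    step = 0.5 * t if d1 > 0.0 else -0.5 * t
                nt = t + step
                # damp wild jumps
                if nt > 10.0 * t + 1e-3:
                    nt = 10.0 * t + 1e-3
                if nt < 0.1 * t:
                    nt = 0.1 * t
                if nt < MIN_BRANCH:
                    nt = MIN_BRANCH
                if nt > MAX_BRANCH:
                    nt = MAX_BRANCH
                if abs(nt - t) < 1e-9 * (1.0 + t):
                    t = nt
                    break
                t = nt
            blens[v] = t
        lnl = _k_loglik(porder, child_ptr, child_list, blens, leafpart,
                        part_off, U, Ui, lam, pi, cat_rates, cat_w, pinv,
                        inv_lik, wts, L)
        if lnl > best_lnl:
            improve = lnl - best_lnl
            best_lnl = lnl
            best_blens[:] = blens
            if improve < tol:
                break
        else:
            blens[:] = best_blens
            break
    blens[:] = best_blens
    return best_lnl
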