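"""Maximum-likelihood tree search (exhaustive or NNI hill-climbing, with
optional backbone constraints) and nonparametric bootstrap support.

Topology scoring uses a profile-likelihood scheme: branch lengths are
optimised per candidate topology under the current substitution model; the
model itself is re-fitted on the incumbent best topology between scan rounds
(until the best topology stops changing).  With the exhaustive strategy the
returned tree is the constrained optimum under the final model; equal-lnL
ties (within 1e-9) break to the lexicographically smallest canonical Newick
so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernels as K
from . import phylomodel as pm
from . import treespace as ts
from .errors import UsageError

TIE_TOL = 1e-9


@dataclass
class SearchResult:
    tree: ts.PhyloTree
    model: pm.PartitionedModel
    lnl: float


# ---------------------------------------------------------------------------
# Topology banks (shared across SOWH replicates: encodings are reusable)

@lru_cache(maxsize=8)
def _topology_bank(taxa: tuple[str, ...]):
    """All unrooted binary topologies on ``taxa`` with reusable encodings."""
    tindex = {t: i for i, t in enumerate(taxa)}
    bank = []
    for tree in ts.enumerate_topologies(list(taxa)):
        enc = K.TreeEncoding(tree, tindex)
        bank.append((tree, enc))
    return bank


_constraint_masks: dict[tuple, np.ndarray] = {}


def _constraint_mask(taxa: tuple[str, ...], constraint: ts.PhyloTree | None):
    if constraint is None:
        return None
    key = (taxa, constraint.canonical_newick(),
           tuple(sorted(constraint.leaf_labels())))
    if key not in _constraint_masks:
        bank = _topology_bank(taxa)
        _constraint_masks[key] = np.array(
            [ts.displays(tree, constraint) for tree, _ in bank])
    return _constraint_masks[key]


# ---------------------------------------------------------------------------

def _constrained_start(constraint: ts.PhyloTree, taxa: list[str],
                       rng: np.random.Generator) -> ts.PhyloTree:
    """Random binary starting tree displaying a backbone constraint: resolve
    the constraint's polytomies at random, then stepwise-add missing taxa on
    random edges (neither step can break a displayed split)."""
    tree = constraint.copy()
    # randomly resolve every polytomy into a binary subtree
    for node in list(tree.preorder()):
        limit = 3 if node is tree.root else 2
        while len(node.children) > limit:
            i, j = rng.choice(len(node.children), size=2, replace=False)
            a, b = node.children[int(i)], node.children[int(j)]
            mid = ts.Node(length=0.1)
            node.children = [c for c in node.children if c not in (a, b)]
            node.add(mid)
            mid.add(a)
            mid.add(b)
    if len(tree.root.children) == 2 and not all(c.is_leaf for c in tree.root.children):
        ts._unroot(tree)
    missing = [t for t in taxa if t not in set(tree.leaf_labels())]
    perm = rng.permutation(len(missing)) if missing else []
    for idx in perm:
        edges = ts._edges(tree)
        target = edges[int(rng.integers(len(edges)))]
        ts._insert_leaf_on_edge(tree, target, missing[int(idx)])
    for n in tree.preorder():
        if n.parent is not None and (n.length is None or n.length <= 0):
            n.length = 0.1
    return tree


def search_ml(patterns: pm.SitePatternTable,
              model_init: pm.PartitionedModel | None = None,
              constraint: ts.PhyloTree | None = None,
              strategy: str = "exhaustive", n_starts: int = 5,
              seed: int | None = None, tol: float = 1e-6,
              refit_model: bool = True, branch_sweeps: int = 4,
              model_rounds: int = 2,
              start_tree: ts.PhyloTree | None = None) -> SearchResult:
    """Find the ML tree (optionally among trees displaying ``constraint``)."""
    taxa = tuple(patterns.taxa)
    if len(taxa) < 3:
        raise UsageError("need at least 3 taxa")
    model = (model_init.copy() if model_init is not None
             else pm.PartitionedModel.initial(patterns))
    if constraint is not None:
        if not set(constraint.leaf_labels()) <= set(taxa):
            raise UsageError("constraint taxa not contained in alignment taxa")
    if strategy not in ("exhaustive", "nni"):
        raise UsageError(f"unknown search strategy {strategy!r}")
    if strategy == "exhaustive" and len(taxa) > ts.MAX_EXHAUSTIVE_TAXA:
        raise UsageError("exhaustive search is limited to 9 taxa; use nni")

    pack = K.LikelihoodPack(patterns, model)
    rounds = model_rounds if refit_model else 1
    best_tree = None
    best_lnl = -np.inf
    prev_canonical = None
    for rnd in range(rounds):
        if strategy == "exhaustive":
            best_tree, best_lnl = _scan_exhaustive(taxa, pack, constraint,
                                                   branch_sweeps)
        else:
            best_tree, best_lnl = _scan_nni(taxa, patterns, pack, constraint,
                                            n_starts, seed, tol, branch_sweeps,
                                            start_tree)
        canon = best_tree.canonical_newick()
        if refit_model:
            res = pm.fit(best_tree, patterns, init=model, max_sweeps=4)
            model, best_tree, best_lnl = res.model, res.tree, res.lnl
            pack.refresh(model)
        if canon == prev_canonical:
            break
        prev_canonical = canon
    return SearchResult(tree=best_tree, model=model, lnl=float(best_lnl))


POLISH_SWEEPS = 15
POLISH_TOP = 3


def _polish(tree, blens, taxa, pack):
    """Re-optimise a candidate's branch lengths to tight convergence."""
    tindex = {t: i for i, t in enumerate(taxa)}
    out = tree.copy()
    enc = K.TreeEncoding(out, tindex)
    enc.blens[:] = blens
    lnl = K.optimize_branches(enc, pack, sweeps=POLISH_SWEEPS, tol=1e-10)
    enc.write_back()
    return out, lnl


def _pick_best(candidates):
    """Max-lnL candidate; near-ties (1e-9) break on canonical Newick."""
    best = max(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] > best - TIE_TOL]
    tied.sort(key=lambda c: c[1].canonical_newick())
    return tied[0]


def _scan_exhaustive(taxa, pack, constraint, branch_sweeps):
    bank = _topology_bank(taxa)
    mask = _constraint_mask(taxa, constraint)
    coarse = []
    for i, (tree, enc) in enumerate(bank):
        if mask is not None and not mask[i]:
            continue
        enc.blens[:] = 0.1
        lnl = K.optimize_branches(enc, pack, sweeps=branch_sweeps)
        coarse.append((lnl, tree, enc.blens.copy()))
    if not coarse:
        raise UsageError("no topology displays the constraint")
    coarse.sort(key=lambda c: -c[0])
    polished = [(lnl, t) for _, tree, bl in coarse[:POLISH_TOP]
                for t, lnl in [_polish(tree, bl, taxa, pack)]]
    lnl, tree = _pick_best(polished)
    return tree, lnl


def _scan_nni(taxa, patterns, pack, constraint, n_starts, seed, tol,
              branch_sweeps, start_tree=None):
    rng = np.random.default_rng(seed)
    tindex = {t: i for i, t in enumerate(taxa)}
    best_tree = None
    best_lnl = -np.inf
    for s in range(max(1, n_starts)):
        if s == 0 and start_tree is not None:
            current = start_tree.copy()
        elif constraint is not None:
            current = _constrained_start(constraint, list(taxa), rng)
        else:
            current = ts.random_addition_tree(list(taxa), rng)
        enc = K.TreeEncoding(current, tindex)
        cur_lnl = K.optimize_branches(enc, pack, sweeps=branch_sweeps)
        enc.write_back()
        improved = True
        while improved:
            improved = False
            cand_best = None
            cand_lnl = cur_lnl
            for nb in ts.nni_neighbors(current):
                if constraint is not None and not ts.displays(nb, constraint):
                    continue
                enc_nb = K.TreeEncoding(nb, tindex)
                lnl = K.optimize_branches(enc_nb, pack, sweeps=branch_sweeps)
                if lnl > cand_lnl + tol:
                    enc_nb.write_back()
                    cand_best, cand_lnl = nb, lnl
            if cand_best is not None:
                current, cur_lnl = cand_best, cand_lnl
                improved = True
        blens = K.TreeEncoding(current, tindex).blens
        current, cur_lnl = _polish(current, blens, taxa, pack)
        if (cur_lnl > best_lnl + TIE_TOL
                or (cur_lnl > best_lnl - TIE_TOL and best_tree is not None
                    and current.canonical_newick() < best_tree.canonical_newick())):
            best_tree, best_lnl = current, cur_lnl
    return best_tree, best_lnl


def exhaustive_delta(patterns: pm.SitePatternTable,
                     model: pm.PartitionedModel,
                     constraint: ts.PhyloTree,
                     branch_sweeps: int = 3) -> tuple[SearchResult, SearchResult]:
    """One exhaustive scan scoring every topology once, returning both the
    unconstrained optimum and the optimum among constraint-displaying trees.

    Because both optima come from the same per-topology fits, the likelihood
    difference is exactly non-negative.  The model is held fixed.
    """
    taxa = tuple(patterns.taxa)
    if len(taxa) > ts.MAX_EXHAUSTIVE_TAXA:
        raise UsageError("exhaustive search is limited to 9 taxa")
    pack = K.LikelihoodPack(patterns, model)
    bank = _topology_bank(taxa)
    mask = _constraint_mask(taxa, constraint)
    coarse_u = []
    coarse_c = []
    for i, (tree, enc) in enumerate(bank):
        enc.blens[:] = 0.1
        lnl = K.optimize_branches(enc, pack, sweeps=branch_sweeps)
        coarse_u.append((lnl, tree, enc.blens.copy()))
        if mask[i]:
            coarse_c.append(coarse_u[-1])
    if not coarse_c:
        raise UsageError("no topology displays the constraint")
    coarse_u.sort(key=lambda c: -c[0])
    coarse_c.sort(key=lambda c: -c[0])
    pol_c = [(lnl, t) for _, tree, bl in coarse_c[:POLISH_TOP]
             for t, lnl in [_polish(tree, bl, taxa, pack)]]
    # the unconstrained optimum considers the constrained winners too, so the
    # likelihood difference can never go negative
    pol_u = [(lnl, t) for _, tree, bl in coarse_u[:POLISH_TOP]
             for t, lnl in [_polish(tree, bl, taxa, pack)]] + pol_c
    lnl_c, tree_c = _pick_best(pol_c)
    lnl_u, tree_u = _pick_best(pol_u)
    return (SearchResult(tree=tree_u, model=model, lnl=float(lnl_u)),
            SearchResult(tree=tree_c, model=model, lnl=float(lnl_c)))


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_support(patterns: pm.SitePatternTable,
                      model: pm.PartitionedModel, base_tree: ts.PhyloTree,
                      B: int = 1000, seed: int | None = None,
                      strategy: str = "nni", n_starts: int = 1) -> ts.PhyloTree:
    """Nonparametric bootstrap: resample columns with replacement within each
    partition, re-search every replicate, and map split frequencies (percent
    of ``B``) onto the internal edges of ``base_tree``."""
    if B < 1:
        raise UsageError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=B)
    counts: dict[frozenset, int] = {}
    for b in range(B):
        parts = []
        for part in patterns.parts:
            probs = part.weights / part.weights.sum()
            w = rng.multinomial(part.length, probs)
            nz = w > 0
            parts.append(pm.PatternPartition(part.name,
                                             np.ascontiguousarray(part.masks[:, nz]),
                                             w[nz].astype(np.int64)))
        reps = pm.SitePatternTable(list(patterns.taxa), parts)
        res = search_ml(reps, model, strategy=strategy, n_starts=n_starts,
                        seed=int(rep_seeds[b]), refit_model=False)
        for bp in ts.bipartitions(res.tree):
            counts[bp.key] = counts.get(bp.key, 0) + 1
    out = base_tree.copy()
    below: dict[int, frozenset] = {}
    taxa = frozenset(out.leaf_labels())
    for node in out.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
            continue
        bl = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = bl
        if node.parent is None or len(bl) < 2 or len(taxa - bl) < 2:
            continue
        key = frozenset((bl, taxa - bl))
        node.support = 100.0 * counts.get(key, 0) / B
    return out
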