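"""Shared fixtures and independent oracles.

The brute-force likelihood oracle enumerates all internal-node state
assignments explicitly and builds transition matrices with scipy's generic
matrix exponential, so it shares no code path with the package's pruning
engine (which uses eigendecomposition).
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from phylosowh import phylomodel as pm


@pytest.fixture
def rng():
    return np.random.default_rng(20150513)


def brute_force_loglik(tree, patterns: pm.SitePatternTable,
                       model: pm.PartitionedModel) -> float:
    """Likelihood by explicit summation over internal-node states."""
    total = 0.0
    for part, sub, mult in zip(patterns.parts, model.models,
                               model.rate_multipliers):
        cat_rates = sub.category_rates() * mult
        cat_w = sub.category_weights()
        pi = sub.freqs
        Q = sub.q_matrix()
        internals = [n for n in tree.preorder() if not n.is_leaf]
        leaf_partial = _leaf_vectors(part.masks, patterns.taxa)
        for p in range(part.n_patterns):
            site = 0.0
            for rate, w in zip(cat_rates, cat_w):
                Ps = {id(n): expm(Q * (n.length or 0.0) * rate)
                      for n in tree.preorder() if n.parent is not None}
                cat_lik = 0.0
                for states in itertools.product(range(4), repeat=len(internals)):
                    assign = {id(n): s for n, s in zip(internals, states)}
                    term = pi[assign[id(tree.root)]]
                    for n in tree.preorder():
                        if n.parent is None:
                            continue
                        ps = assign[id(n.parent)]
                        P = Ps[id(n)]
                        if n.is_leaf:
                            term *= float(P[ps] @ leaf_partial[n.label][:, p])
                        else:
                            term *= P[ps, assign[id(n)]]
                    cat_lik += term
                site += w * cat_lik
            if sub.p_inv > 0:
                ok = np.ones(4)
                for leaf in tree.leaves():
                    ok = ok * leaf_partial[leaf.label][:, p]
                site += sub.p_inv * float(ok @ pi)
            total += part.weights[p] * np.log(site)
    return float(total)


def _leaf_vectors(masks: np.ndarray, taxa: list[str]) -> dict[str, np.ndarray]:
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    out = {}
    for i, t in enumerate(taxa):
        out[t] = ((masks[i][None, :] & bits[:, None]) > 0).astype(float)
    return out


def random_gtr(rng: np.random.Generator, n_categories: int = 4,
               p_inv: float = 0.0) -> pm.SubstitutionModel:
    rates = np.exp(rng.normal(0, 0.5, size=6))
    rates /= rates[5]
    freqs = rng.dirichlet(np.full(4, 10.0))
    alpha = float(rng.uniform(0.3, 2.0))
    return pm.SubstitutionModel(rates, freqs, gamma_shape=alpha,
                                n_categories=n_categories, p_inv=p_inv)


def patterns_from_states(taxa: list[str], states: np.ndarray,
                         name: str = "all") -> pm.SitePatternTable:
    """Pattern table from an integer state matrix (no compression)."""
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    masks = bits[states]
    uniq, counts = np.unique(masks, axis=1, return_counts=True)
    part = pm.PatternPartition(name, np.ascontiguousarray(uniq),
                               counts.astype(np.int64))
    return pm.SitePatternTable(list(taxa), [part])
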