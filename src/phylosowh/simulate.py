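"""Sequence simulation along phylogenies and full synthetic-study generation.

``simulate_alignment`` evolves sites edge-by-edge under the same partitioned
GTR+Γ+I mixture the likelihood engine scores: each site is independently
assigned to the invariant class (probability ``p_inv``, rate 0 — the state
drawn at the root is frozen along the whole tree) or to one of ``k`` discrete
gamma categories, and states transition with ``P(t·m·r)`` down every edge.
An optional missing-data footprint masks cells to ``?`` afterwards, which
mimics supermatrices where many isolates lack whole loci.

``synth_study`` builds a complete multilocus study around a known truth:
a Yule-topology tree with one deliberately short "backbone" internal edge,
heterogeneous locus lengths and rates, a long-tailed missing-locus footprint,
and intron-like column blocks whose occupancy is below the curation cutoff
(so the 10 % filter removes exactly those columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import phylomodel as pm
from . import treespace as ts
from .errors import DataError, UsageError
from .seqdata import LocusAlignment, MultiLocusAlignment, Partition, PartitionScheme

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationSpec:
    """Inputs for one alignment simulation."""

    tree: ts.PhyloTree
    model: pm.PartitionedModel
    partition_lengths: list[int]
    partition_names: list[str] | None = None
    taxa: list[str] | None = None  # row order; default sorted leaf labels
    missing_mask: np.ndarray | None = None  # (n_taxa, L) bool; True -> '?'
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.partition_lengths) != self.model.n_partitions:
            raise DataError("partition lengths do not match the model")
        if any(n <= 0 for n in self.partition_lengths):
            raise DataError("partition lengths must be positive")
        if self.taxa is None:
            self.taxa = sorted(self.tree.leaf_labels())
        if set(self.taxa) != set(self.tree.leaf_labels()):
            raise DataError("taxon list does not match the tree's leaves")
        L = sum(self.partition_lengths)
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (len(self.taxa), L):
                raise DataError("missing mask dimensions do not match output")


def simulate_alignment(spec: SimulationSpec,
                       rng: np.random.Generator | None = None) -> MultiLocusAlignment:
    """Simulate a multilocus alignment along ``spec.tree``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    names = spec.partition_names or [f"part{q + 1}" for q in
                                     range(len(spec.partition_lengths))]
    taxa = spec.taxa
    tindex = {t: i for i, t in enumerate(taxa)}
    L = sum(spec.partition_lengths)
    matrix = np.empty((len(taxa), L), dtype="<U1")
    origin_locus = np.empty(L, dtype=object)
    origin_pos = np.empty(L, dtype=np.int64)
    off = 0
    for q, (n, sub, mult) in enumerate(zip(spec.partition_lengths,
                                           spec.model.models,
                                           spec.model.rate_multipliers)):
        states = _simulate_partition(spec.tree, sub, mult, n, rng, tindex)
        matrix[:, off:off + n] = _BASES[states]
        origin_locus[off:off + n] = names[q]
        origin_pos[off:off + n] = np.arange(n)
        off += n
    if spec.missing_mask is not None:
        matrix[spec.missing_mask] = "?"
    return MultiLocusAlignment(list(taxa), matrix, origin_locus, origin_pos)


def _simulate_partition(tree: ts.PhyloTree, sub: pm.SubstitutionModel,
                        mult: float, n_sites: int, rng: np.random.Generator,
                        tindex: dict[str, int]) -> np.ndarray:
    """(n_taxa, n_sites) int states for one partition."""
    k = sub.n_categories
    # site-rate class: 0..k-1 gamma categories, k = invariant
    cls = rng.integers(0, k, size=n_sites)
    if sub.p_inv > 0:
        cls[rng.random(n_sites) < sub.p_inv] = k
    site_rates = np.concatenate([sub.category_rates() * mult, [0.0]])[cls]
    root_states = rng.choice(4, size=n_sites, p=sub.freqs)
    out = np.empty((len(tindex), n_sites), dtype=np.int64)
    state_of = {id(tree.root): root_states}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = state_of[id(node.parent)]
        t = node.length if node.length is not None else 0.0
        child = parent_states.copy()
        for c in range(k):
            sel = np.flatnonzero(cls == c)
            if len(sel) == 0:
                continue
            P = sub.transition_matrix(t, rate=float(site_rates[sel[0]]))
            cum = np.cumsum(P, axis=1)
            cum[:, -1] = 1.0
            u = rng.random(len(sel))
            child[sel] = (u[:, None] > cum[parent_states[sel]]).sum(axis=1)
        # invariant-class sites (cls == k) stay at the parent state
        state_of[id(node)] = child
        if node.is_leaf:
            out[tindex[node.label]] = child
    return out


# ---------------------------------------------------------------------------
# Synthetic studies

@dataclass
class SyntheticStudySpec:
    """Parameters of a generated multilocus study.

    Defaults emulate the shape of an eight-locus fungal supermatrix at desk
    scale: half the loci protein-coding, per-locus lengths and rates
    heterogeneous, a long tail of isolates missing whole loci, and gappy
    intron blocks sitting below the 10 % occupancy cutoff.
    """

    n_taxa: int = 20
    n_loci: int = 8
    locus_length_range: tuple[int, int] = (200, 900)
    coding_fraction: float = 0.5
    missing_fraction: float = 0.25
    n_intron_blocks: int = 3
    intron_block_width: tuple[int, int] = (30, 80)
    intron_present_taxa: int = 1  # occupancy of intron columns (< 10 % of taxa)
    branch_length_mean: float = 0.08
    backbone_length: float = 0.01
    rate_multiplier_sigma: float = 0.5
    gamma_shape_range: tuple[float, float] = (0.3, 1.5)
    p_inv_range: tuple[float, float] = (0.0, 0.3)
    n_categories: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_taxa < 4:
            raise UsageError("need at least 1 locus and 4 taxa")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise UsageError("missing fraction must lie in [0, 1)")
        if self.intron_present_taxa >= self.n_taxa:
            raise UsageError("intron occupancy must be below the taxon count")


def yule_tree(taxa: list[str], rng: np.random.Generator,
              branch_length_mean: float = 0.08,
              backbone_length: float | None = None) -> ts.PhyloTree:
    """Unrooted tree with a Yule (pure-birth) topology; branch lengths are
    redrawn i.i.d. exponential, and optionally the internal edge closest to
    the middle of the taxon set is pinched to ``backbone_length``."""
    n = len(taxa)
    if n < 4:
        raise UsageError("need at least 4 taxa")
    order = rng.permutation(n)
    root = ts.Node()
    for i in order[:3]:
        root.add(ts.Node(label=taxa[i]))
    tree = ts.PhyloTree(root)
    for i in order[3:]:
        # Yule: split a uniformly chosen extant lineage (= pendant edge)
        pendants = [e for e in ts._edges(tree) if e.is_leaf]
        target = pendants[int(rng.integers(len(pendants)))]
        ts._insert_leaf_on_edge(tree, target, taxa[i])
    edges = ts._edges(tree)
    for e in edges:
        e.length = float(rng.exponential(branch_length_mean)) + 1e-4
    if backbone_length is not None:
        internal = [e for e in edges if not e.is_leaf]
        if internal:
            # pinch the most "central" internal edge (most balanced split)
            def balance(e):
                below = sum(1 for x in ts.PhyloTree(e).preorder() if x.is_leaf)
                return abs(2 * below - n)
            target = min(internal, key=balance)
            target.length = backbone_length
    return tree


def synth_study(spec: SyntheticStudySpec):
    """Generate (loci, true_tree, true_model, manifest); deterministic by seed."""
    rng = np.random.default_rng(spec.seed)
    taxa = [f"t{i + 1:03d}" for i in range(spec.n_taxa)]
    tree = yule_tree(taxa, rng, spec.branch_length_mean, spec.backbone_length)

    n_coding = int(round(spec.coding_fraction * spec.n_loci))
    coding_flags = [i >= spec.n_loci - n_coding for i in range(spec.n_loci)]
    lo, hi = spec.locus_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_loci)
    # codon-partitionable loci get a length divisible by 3
    lengths = [int(n - n % 3) if cod else int(n)
               for n, cod in zip(lengths, coding_flags)]

    mults = np.exp(rng.normal(0.0, spec.rate_multiplier_sigma, size=spec.n_loci))
    models = []
    for i in range(spec.n_loci):
        freqs = rng.dirichlet(np.full(4, 8.0))
        base = np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0])
        rates = base * np.exp(rng.normal(0.0, 0.3, size=6))
        rates = rates / rates[5]  # pin GT to 1
        alpha = float(rng.uniform(*spec.gamma_shape_range))
        p_inv = float(rng.uniform(*spec.p_inv_range))
        models.append(pm.SubstitutionModel(rates, freqs, gamma_shape=alpha,
                                           n_categories=spec.n_categories,
                                           p_inv=p_inv))
    model = pm.PartitionedModel(models, mults, np.array(lengths, float))

    # long-tailed missing-locus footprint: per-taxon missing probability drawn
    # from a Beta with mean = missing_fraction (some taxa lose most loci)
    mu = spec.missing_fraction
    if mu > 0:
        a = 0.8
        b = a * (1.0 - mu) / mu
        p_miss = rng.beta(a, b, size=spec.n_taxa)
    else:
        p_miss = np.zeros(spec.n_taxa)
    missing = rng.random((spec.n_taxa, spec.n_loci)) < p_miss[:, None]
    # keep the matrix analyzable: every taxon keeps >= 1 locus, every locus
    # keeps >= 4 taxa
    for i in range(spec.n_taxa):
        if missing[i].all():
            missing[i, int(rng.integers(spec.n_loci))] = False
    for j in range(spec.n_loci):
        present = np.flatnonzero(~missing[:, j])
        if len(present) < 4:
            refill = rng.choice(np.flatnonzero(missing[:, j]),
                                size=4 - len(present), replace=False)
            missing[refill, j] = False

    # intron blocks: (locus, insert position, width); non-coding loci only
    noncoding = [i for i, c in enumerate(coding_flags) if not c] or list(range(spec.n_loci))
    blocks = []
    for _ in range(spec.n_intron_blocks):
        li = int(noncoding[int(rng.integers(len(noncoding)))])
        width = int(rng.integers(spec.intron_block_width[0],
                                 spec.intron_block_width[1] + 1))
        pos = int(rng.integers(0, lengths[li] + 1))
        blocks.append({"locus": li, "pos": pos, "width": width})

    sim_spec = SimulationSpec(tree=tree, model=model,
                              partition_lengths=list(lengths),
                              partition_names=[f"loc{i + 1:02d}" for i in range(spec.n_loci)],
                              taxa=taxa)
    core = simulate_alignment(sim_spec, rng=rng)

    loci = []
    manifest_loci = []
    for i in range(spec.n_loci):
        name = f"loc{i + 1:02d}"
        cols = core.origin_locus == name
        sub = core.matrix[:, cols]
        # drop taxa missing this locus entirely
        keep = ~missing[:, i]
        sub = sub[keep]
        iso = [t for t, k in zip(taxa, keep) if k]
        # insert intron blocks for this locus (descending position so earlier
        # insert positions stay valid)
        my_blocks = sorted((b for b in blocks if b["locus"] == i),
                           key=lambda b: -b["pos"])
        for b in my_blocks:
            col = np.full((len(iso), b["width"]), "?", dtype="<U1")
            present = rng.choice(len(iso), size=min(spec.intron_present_taxa,
                                                    len(iso)), replace=False)
            intron_seq = _BASES[rng.integers(0, 4, size=(len(present), b["width"]))]
            col[present] = intron_seq
            sub = np.concatenate([sub[:, :b["pos"]], col, sub[:, b["pos"]:]], axis=1)
        seqs = {t: "".join(row) for t, row in zip(iso, sub)}
        loci.append(LocusAlignment(name, seqs, coding=coding_flags[i]))
        manifest_loci.append({
            "name": name, "core_length": int(lengths[i]),
            "raw_length": int(sub.shape[1]), "coding": bool(coding_flags[i]),
            "rate_multiplier": float(model.rate_multipliers[i]),
            "model": models[i].to_dict(),
            "missing_taxa": [t for t, m in zip(taxa, missing[:, i]) if m],
            "intron_blocks": [{"pos": b["pos"], "width": b["width"]}
                              for b in sorted(my_blocks, key=lambda b: b["pos"])],
        })
    manifest = {
        "seed": spec.seed,
        "n_taxa": spec.n_taxa,
        "taxa": taxa,
        "true_tree": tree.newick(),
        "intron_columns_total": int(sum(b["width"] for b in blocks)),
        "loci": manifest_loci,
    }
    return loci, tree, model, manifest
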