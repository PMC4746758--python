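"""Partitioned GTR+Γ+I likelihood machinery.

The substitution process is the general time-reversible (GTR) model with
rate matrix :math:`Q_{ij} = r_{ij}\\pi_j` (i ≠ j), normalised so the expected
number of substitutions per unit branch length equals one at the mean site
rate.  Among-site rate heterogeneity uses the discrete-gamma approximation
(``k`` equal-probability categories represented by their category means) plus
an invariant-sites class: a site belongs to the invariant class with
probability ``p_inv`` (rate 0) and otherwise to gamma category ``c`` with
probability ``(1 - p_inv)/k``.  Gamma category rates are divided by
``1 - p_inv`` so the overall mean rate stays one, keeping branch lengths in
expected-substitutions units.

A partitioned model assigns each partition its own substitution model and a
rate multiplier ``m_p`` over a *shared* ("linked") branch-length set; the
length-weighted mean of the multipliers is held at one so branch lengths
remain identifiable.

``log_likelihood`` is a plain NumPy implementation of Felsenstein's pruning
algorithm with per-node rescaling; the numba kernels used by tree search
(:mod:`phylosowh._kernels`) are validated against it in the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .errors import DataError, NumericalError, UsageError

RATE_NAMES = ("AC", "AG", "AT", "CG", "CT", "GT")
P_INV_MAX = 0.99
MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Category rates of the discrete-gamma approximation (category means of
    ``k`` equal-probability classes of Gamma(alpha, 1/alpha)); mean is 1."""
    if alpha <= 0:
        raise UsageError("gamma shape must be positive")
    if k < 1:
        raise UsageError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], edges * alpha, [np.inf]])
    # For X ~ Gamma(alpha, scale=1/alpha): E[X; X <= x] = P(alpha+1, alpha x)
    cum = gammainc(alpha + 1.0, bounds)
    rates = k * np.diff(cum)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """GTR+Γ+I model for one partition."""

    rates: np.ndarray  # exchangeabilities (AC, AG, AT, CG, CT, GT); GT pinned to 1
    freqs: np.ndarray  # stationary base frequencies (A, C, G, T)
    gamma_shape: float = 1.0
    n_categories: int = 4
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise DataError("need 6 positive exchangeabilities")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise DataError("need 4 positive base frequencies")
        if not math.isclose(self.freqs.sum(), 1.0, abs_tol=1e-8):
            raise DataError("base frequencies must sum to 1")
        self.freqs = self.freqs / self.freqs.sum()
        if self.gamma_shape <= 0:
            raise UsageError("gamma shape must be positive")
        if not 0.0 <= self.p_inv <= P_INV_MAX:
            raise UsageError(f"p_inv must lie in [0, {P_INV_MAX}]")
        self._eigen_cache = None

    @classmethod
    def jc(cls, n_categories: int = 1, gamma_shape: float = 1.0,
           p_inv: float = 0.0) -> "SubstitutionModel":
        """Jukes–Cantor specialisation (equal rates, uniform frequencies)."""
        return cls(np.ones(6), np.full(4, 0.25), gamma_shape=gamma_shape,
                   n_categories=n_categories, p_inv=p_inv)

    # -- rate matrix -------------------------------------------------------
    def q_matrix(self) -> np.ndarray:
        """Normalised GTR rate matrix (expected rate 1)."""
        r, pi = self.rates, self.freqs
        q = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for k, (i, j) in enumerate(idx):
            q[i, j] = r[k] * pi[j]
            q[j, i] = r[k] * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(pi, np.diag(q))
        return q / mu

    def eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lam, U, Uinv) with P(t) = U @ diag(exp(lam t)) @ Uinv (all real,
        via the similarity transform that symmetrises the reversible Q)."""
        if self._eigen_cache is None:
            pi = self.freqs
            sq = np.sqrt(pi)
            B = (sq[:, None] * self.q_matrix()) / sq[None, :]
            B = 0.5 * (B + B.T)  # symmetric up to rounding
            lam, V = np.linalg.eigh(B)
            U = V / sq[:, None]
            Uinv = V.T * sq[None, :]
            self._eigen_cache = (lam, U, Uinv)
        return self._eigen_cache

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) at a given site rate; rows sum to 1, detailed balance holds."""
        if t < 0:
            raise UsageError("branch length must be non-negative")
        lam, U, Uinv = self.eigen()
        P = (U * np.exp(lam * t * rate)) @ Uinv
        return np.clip(P, 0.0, None)

    # -- site-rate mixture -------------------------------------------------
    def category_rates(self) -> np.ndarray:
        """Gamma category rates rescaled by 1/(1 - p_inv) (overall mean 1)."""
        base = discrete_gamma_rates(self.gamma_shape, self.n_categories)
        return base / (1.0 - self.p_inv)

    def category_weights(self) -> np.ndarray:
        return np.full(self.n_categories, (1.0 - self.p_inv) / self.n_categories)

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.tolist(),
            "freqs": self.freqs.tolist(),
            "gamma_shape": self.gamma_shape,
            "n_categories": self.n_categories,
            "p_inv": self.p_inv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubstitutionModel":
        return cls(np.array(d["rates"]), np.array(d["freqs"]),
                   gamma_shape=d["gamma_shape"], n_categories=d["n_categories"],
                   p_inv=d["p_inv"])


@dataclass
class PartitionedModel:
    """Per-partition substitution models with linked branch lengths."""

    models: list[SubstitutionModel]
    rate_multipliers: np.ndarray
    partition_lengths: np.ndarray  # weights for the multiplier constraint

    def __post_init__(self) -> None:
        self.rate_multipliers = np.asarray(self.rate_multipliers, dtype=float)
        self.partition_lengths = np.asarray(self.partition_lengths, dtype=float)
        if not (len(self.models) == len(self.rate_multipliers)
                == len(self.partition_lengths)):
            raise DataError("per-partition field lengths disagree")
        if np.any(self.rate_multipliers <= 0):
            raise DataError("rate multipliers must be positive")
        self.normalize_multipliers()

    @property
    def n_partitions(self) -> int:
        return len(self.models)

    def normalize_multipliers(self) -> None:
        """Enforce length-weighted mean multiplier = 1 (identifiability)."""
        w = self.partition_lengths / self.partition_lengths.sum()
        self.rate_multipliers = self.rate_multipliers / np.dot(w, self.rate_multipliers)

    @classmethod
    def single(cls, model: SubstitutionModel, length: int = 1) -> "PartitionedModel":
        return cls([model], np.ones(1), np.array([float(length)]))

    @classmethod
    def initial(cls, patterns: "SitePatternTable", n_categories: int = 4,
                gamma_shape: float = 1.0, p_inv: float = 0.0) -> "PartitionedModel":
        """Starting model: empirical base frequencies, flat exchangeabilities."""
        models = []
        lengths = []
        for part in patterns.parts:
            freqs = part.empirical_freqs()
            models.append(SubstitutionModel(np.ones(6), freqs,
                                            gamma_shape=gamma_shape,
                                            n_categories=n_categories,
                                            p_inv=p_inv))
            lengths.append(part.length)
        return cls(models, np.ones(len(models)), np.array(lengths, float))

    def copy(self) -> "PartitionedModel":
        return PartitionedModel(
            [SubstitutionModel.from_dict(m.to_dict()) for m in self.models],
            self.rate_multipliers.copy(), self.partition_lengths.copy())

    def to_json(self) -> str:
        return json.dumps({
            "models": [m.to_dict() for m in self.models],
            "rate_multipliers": self.rate_multipliers.tolist(),
            "partition_lengths": self.partition_lengths.tolist(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PartitionedModel":
        d = json.loads(text)
        return cls([SubstitutionModel.from_dict(m) for m in d["models"]],
                   np.array(d["rate_multipliers"]),
                   np.array(d["partition_lengths"]))


# ---------------------------------------------------------------------------
# Site patterns

@dataclass
class PatternPartition:
    """Distinct site patterns of one partition, as leaf-state bitmasks."""

    name: str
    masks: np.ndarray  # (n_taxa, n_patterns) uint8; bits A=1 C=2 G=4 T=8
    weights: np.ndarray  # (n_patterns,) positive ints

    @property
    def n_patterns(self) -> int:
        return self.masks.shape[1]

    @property
    def length(self) -> int:
        return int(self.weights.sum())

    def empirical_freqs(self, pseudocount: float = 1.0) -> np.ndarray:
        counts = np.full(4, pseudocount)
        for b in range(4):
            bit = 1 << b
            unambiguous = self.masks == bit
            counts[b] += (unambiguous * self.weights[None, :]).sum()
        return counts / counts.sum()


@dataclass
class SitePatternTable:
    """Pattern-compressed alignment, one block per partition."""

    taxa: list[str]
    parts: list[PatternPartition]

    @property
    def total_length(self) -> int:
        return sum(p.length for p in self.parts)

    @classmethod
    def from_alignment(cls, aln, scheme=None) -> "SitePatternTable":
        """Compress a :class:`~phylosowh.seqdata.MultiLocusAlignment`
        (or anything with ``isolates`` and ``masks()``) into site patterns.
        Without a scheme the whole alignment is one partition."""
        masks = aln.masks()
        taxa = list(aln.isolates)
        parts = []
        if scheme is None:
            groups = [("all", np.arange(masks.shape[1]))]
        else:
            groups = [(p.name, p.indices) for p in scheme]
        for name, idx in groups:
            sub = masks[:, idx]
            uniq, counts = np.unique(sub, axis=1, return_counts=True)
            parts.append(PatternPartition(name, np.ascontiguousarray(uniq),
                                          counts.astype(np.int64)))
        return cls(taxa, parts)


# ---------------------------------------------------------------------------
# Reference pruning likelihood (NumPy, with underflow rescaling)

_SCALE_THRESHOLD = 1e-150


def _leaf_partials(masks: np.ndarray) -> np.ndarray:
    """(n_taxa, n_patterns, 4) partial-likelihood vectors from bitmasks."""
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    return ((masks[:, :, None] & bits[None, None, :]) > 0).astype(float)


def log_likelihood(tree, patterns: SitePatternTable,
                   model: PartitionedModel) -> float:
    """Partitioned GTR+Γ+I log-likelihood of an unrooted tree by pruning.

    Gaps and ambiguity codes enter as partial-likelihood vectors with ones in
    every compatible state.  The per-site likelihood is the
    ``(1-p_inv)/k``-weighted mixture over gamma categories plus ``p_inv``
    times the invariant-class likelihood.
    """
    if len(patterns.parts) != model.n_partitions:
        raise DataError("pattern table and model disagree on partition count")
    taxon_index = {t: i for i, t in enumerate(patterns.taxa)}
    for leaf in tree.leaves():
        if leaf.label not in taxon_index:
            raise DataError(f"tree leaf {leaf.label!r} has no sequence")
    total = 0.0
    for part, sub, mult in zip(patterns.parts, model.models,
                               model.rate_multipliers):
        total += _partition_loglik(tree, part, sub, mult, taxon_index)
    if not np.isfinite(total):
        raise NumericalError("non-finite log-likelihood")
    return float(total)


def _partition_loglik(tree, part: PatternPartition, sub: SubstitutionModel,
                      mult: float, taxon_index: dict[str, int]) -> float:
    leafpart = _leaf_partials(part.masks)
    pi = sub.freqs
    cat_rates = sub.category_rates() * mult
    cat_w = sub.category_weights()
    npat = part.n_patterns
    site_lik = np.zeros(npat)
    log_site = None
    per_cat_logs = []
    for rate, w in zip(cat_rates, cat_w):
        partial, logscale = _prune(tree, leafpart, sub, rate, taxon_index)
        lik = partial @ pi
        with np.errstate(divide="ignore"):
            per_cat_logs.append(np.log(w) + np.log(lik) + logscale)
    stack = np.stack(per_cat_logs)
    if sub.p_inv > 0:
        inv = _invariant_lik(part, pi)
        with np.errstate(divide="ignore"):
            inv_log = np.log(sub.p_inv) + np.log(inv)
        stack = np.vstack([stack, inv_log[None, :]])
    m = stack.max(axis=0)
    log_site = m + np.log(np.exp(stack - m[None, :]).sum(axis=0))
    return float(np.dot(part.weights, log_site))


def _prune(tree, leafpart, sub: SubstitutionModel, rate: float,
           taxon_index: dict[str, int]):
    """Post-order conditional likelihoods at the (traversal) root, with
    per-pattern log rescaling."""
    npat = leafpart.shape[1]
    partial: dict[int, np.ndarray] = {}
    scale: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            partial[id(node)] = leafpart[taxon_index[node.label]]
            scale[id(node)] = np.zeros(npat)
            continue
        acc = np.ones((npat, 4))
        sc = np.zeros(npat)
        for child in node.children:
            P = sub.transition_matrix(child.length or 0.0, rate)
            acc = acc * (partial[id(child)] @ P.T)
            sc = sc + scale[id(child)]
        mx = acc.max(axis=1)
        needs = mx < _SCALE_THRESHOLD
        if needs.any():
            safe = np.where(mx > 0, mx, 1.0)
            acc = np.where(needs[:, None], acc / safe[:, None], acc)
            sc = sc + np.where(needs & (mx > 0), np.log(safe), 0.0)
        partial[id(node)] = acc
        scale[id(node)] = sc
    rid = id(tree.root)
    return partial[rid], scale[rid]


def _invariant_lik(part: PatternPartition, pi: np.ndarray) -> np.ndarray:
    """Likelihood of each pattern under the rate-0 (invariant) class."""
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    ok = (part.masks[:, :, None] & bits[None, None, :]) > 0  # (taxa, pat, 4)
    allmatch = ok.all(axis=0)  # (pat, 4): state consistent with every leaf
    return allmatch @ pi


# ---------------------------------------------------------------------------
# Parameter fitting on a fixed topology

@dataclass
class FitResult:
    tree: object  # PhyloTree with optimised branch lengths
    model: PartitionedModel
    lnl: float
    n_sweeps: int
    converged: bool


def _replace_sub(model: PartitionedModel, q: int, **changes) -> None:
    d = model.models[q].to_dict()
    d.update(changes)
    model.models[q] = SubstitutionModel.from_dict(d)


def fit(tree, patterns: SitePatternTable, init: PartitionedModel | None = None,
        tol: float = 1e-4, max_sweeps: int = 15, branch_sweeps: int = 3,
        optimize_branches: bool = True, optimize_exchangeabilities: bool = True,
        optimize_freqs: bool = True, optimize_alpha: bool = True,
        optimize_pinv: bool = True, optimize_multipliers: bool = True,
        brent_maxiter: int = 20) -> FitResult:
    """Fit model parameters and branch lengths on a fixed topology by cyclic
    coordinate descent (bounded Brent on each scalar, Newton sweeps on branch
    lengths).  lnL is non-decreasing across sweeps; stops when a full sweep
    improves lnL by less than ``tol`` or ``max_sweeps`` is reached.
    """
    from scipy.optimize import minimize_scalar

    from . import _kernels as K

    tree = tree.copy()
    model = init.copy() if init is not None else PartitionedModel.initial(patterns)
    taxon_index = {t: i for i, t in enumerate(patterns.taxa)}
    pack = K.LikelihoodPack(patterns, model)
    enc = K.TreeEncoding(tree, taxon_index)
    lnl = K.tree_loglik(enc, pack)
    if lnl <= -1e299 or not np.isfinite(lnl):
        raise NumericalError("non-finite likelihood at the starting parameters")

    def brent_param(getter, setter, lo, hi, log_space, q, lnl_now, xatol):
        """Optimise one scalar; guaranteed not to decrease lnL."""
        x0 = getter()

        def obj(y):
            setter(math.exp(y) if log_space else y)
            pack.refresh_partition(model, q)
            v = K.tree_loglik(enc, pack)
            return -v

        a, b = (math.log(lo), math.log(hi)) if log_space else (lo, hi)
        res = minimize_scalar(obj, bounds=(a, b), method="bounded",
                              options={"xatol": xatol, "maxiter": brent_maxiter})
        if -res.fun > lnl_now:
            setter(math.exp(res.x) if log_space else res.x)
            pack.refresh_partition(model, q)
            return -res.fun
        setter(x0)
        pack.refresh_partition(model, q)
        return lnl_now

    n_sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        n_sweeps = sweep + 1
        lnl_start = lnl
        if optimize_branches:
            lnl = max(lnl, K.optimize_branches(enc, pack, sweeps=branch_sweeps))
        for q in range(model.n_partitions):
            sub = model.models[q]
            if optimize_exchangeabilities:
                for k in range(5):  # GT stays pinned at 1
                    def get_r(k=k):
                        return model.models[q].rates[k]

                    def set_r(v, k=k):
                        r = model.models[q].rates.copy()
                        r[k] = v
                        _replace_sub(model, q, rates=r.tolist())
                    lnl = brent_param(get_r, set_r, 1e-3, 1e3, True, q, lnl, 2e-2)
            if optimize_freqs:
                for i in range(4):
                    # freeze the reference vector so the coordinate move is
                    # stateless (renormalisation must not compound across
                    # Brent evaluations)
                    base = model.models[q].freqs.copy()

                    def get_f(i=i, base=base):
                        return base[i]

                    def set_f(v, i=i, base=base):
                        f = base.copy()
                        f[i] = v
                        f = f / f.sum()
                        _replace_sub(model, q, freqs=f.tolist())
                    lnl = brent_param(get_f, set_f, 1e-3, 0.97, True, q, lnl, 2e-2)
            if optimize_alpha and sub.n_categories > 1:
                lnl = brent_param(
                    lambda: model.models[q].gamma_shape,
                    lambda v: _replace_sub(model, q, gamma_shape=v),
                    0.02, 100.0, True, q, lnl, 1e-2)
            if optimize_pinv:
                lnl = brent_param(
                    lambda: model.models[q].p_inv,
                    lambda v: _replace_sub(model, q, p_inv=v),
                    0.0, P_INV_MAX, False, q, lnl, 5e-3)
        if optimize_multipliers and model.n_partitions > 1:
            for q in range(model.n_partitions):
                def get_m(q=q):
                    return model.rate_multipliers[q]

                def set_m(v, q=q):
                    model.rate_multipliers[q] = v
                lnl = brent_param(get_m, set_m, 1e-3, 1e3, True, q, lnl, 2e-2)
            # renormalise to weighted mean 1; compensate via branch lengths so
            # the likelihood is exactly unchanged
            w = model.partition_lengths / model.partition_lengths.sum()
            z = float(np.dot(w, model.rate_multipliers))
            model.rate_multipliers /= z
            enc.blens *= z
            np.clip(enc.blens, K.MIN_BRANCH, K.MAX_BRANCH, out=enc.blens)
            pack.refresh(model)
            lnl = K.tree_loglik(enc, pack)
        if lnl - lnl_start < tol:
            converged = True
            break
    enc.write_back()
    return FitResult(tree=tree, model=model, lnl=float(lnl),
                     n_sweeps=n_sweeps, converged=converged)
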