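"""SOWH parametric-bootstrap topology test with sequential stopping.

The Swofford–Olsen–Waddell–Hillis test asks whether the data reject a
topological hypothesis encoded as a backbone constraint.  The test statistic
is ``delta = lnL(unconstrained ML tree) - lnL(best tree displaying the
constraint)``.  Its null distribution is built by parametric bootstrap:
alignments are simulated on the *constrained* ML tree with its own fitted
model parameters (the null hypothesis), and both searches are re-run on each
simulated alignment to give ``delta_r``.

Three p-values are reported side by side:

* ``p_empirical_raw``  = #{delta_r >= delta} / n  (can be exactly 0 or 1);
* ``p_empirical_corrected`` = (#{delta_r >= delta} + 1) / (n + 1) (never 0);
* ``p_parametric_t``   = upper tail of Student-t with n-1 df at
  ``t* = (delta - mean(null)) / (sd(null) * sqrt(1 + 1/n))`` — a smooth
  approximation that cannot reach exactly 0 or 1 and is reported as a
  diagnostic next to the empirical values.

The headline decision (reject iff p < alpha) uses the raw empirical p.
Sequential stopping: once at least ``min_replicates`` null draws exist, a
Wilson score interval for the raw p is computed; sampling halts when the
whole interval falls on one side of alpha, since further replicates are then
unlikely to change the decision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import phylomodel as pm
from . import search as sr
from . import simulate as sim
from . import treespace as ts
from .errors import NumericalError, UsageError
from .seqdata import MultiLocusAlignment, PartitionScheme


#: likelihood differences below the branch-optimiser's convergence scale are
#: indistinguishable from zero; snapping prevents spurious strict orderings
#: between an observed delta of +1e-9 and null deltas of exactly 0
DELTA_EPS = 1e-6


def _snap(delta: float) -> float:
    return 0.0 if abs(delta) < DELTA_EPS else float(delta)


def p_empirical(delta: float, null_deltas) -> tuple[float, float]:
    """Raw and add-one-corrected empirical p-values."""
    null = np.asarray(null_deltas, dtype=float)
    if null.size == 0:
        raise UsageError("empty null distribution")
    count = int((null >= delta).sum())
    return count / null.size, (count + 1) / (null.size + 1)


def p_parametric_t(delta: float, null_deltas) -> float:
    """One-sided t-test of the observed delta against the null sample.

    Uses the prediction-interval form ``sd * sqrt(1 + 1/n)`` (the observed
    delta is a new draw, not the sample mean).  Falls back to the raw
    empirical p with a warning when the null variance is zero.
    """
    null = np.asarray(null_deltas, dtype=float)
    if null.size < 3:
        raise UsageError("need at least 3 null samples for the t approximation")
    sd = null.std(ddof=1)
    if sd == 0.0:
        warnings.warn("null distribution has zero variance; "
                      "returning the empirical p instead")
        return p_empirical(delta, null)[0]
    tstat = (delta - null.mean()) / (sd * np.sqrt(1.0 + 1.0 / null.size))
    return float(stats.t.sf(tstat, df=null.size - 1))


def wilson_interval(successes: int, n: int, confidence: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise UsageError("need at least one trial")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def convergence_check(null_deltas, delta: float, alpha: float = 0.05,
                      confidence: float = 0.95,
                      n_max: int | None = None) -> tuple[bool, float]:
    """Sequential stopping rule: halt when the Wilson interval for the raw
    empirical p lies entirely on one side of alpha.  Returns (stop,
    percent_ratio) where percent_ratio is the fraction of the planned
    ``n_max`` replicates sampled so far (1.0 when n_max is not given)."""
    null = np.asarray(null_deltas, dtype=float)
    if null.size < 10:
        raise UsageError("convergence check needs at least 10 null samples")
    x = int((null >= delta).sum())
    lo, hi = wilson_interval(x, null.size, confidence)
    stop = hi < alpha or lo > alpha
    ratio = null.size / n_max if n_max else 1.0
    return stop, float(ratio)


@dataclass
class SOWHResult:
    """Everything the test computes (the columns of a SOWH results table)."""

    lnl_unconstrained: float
    lnl_constrained: float
    delta: float
    null_deltas: np.ndarray
    p_empirical_raw: float
    p_empirical_corrected: float
    p_parametric_t: float | None
    converged: bool
    percent_ratio: float
    alpha: float
    reject: bool
    seed: int | None
    tree_unconstrained: ts.PhyloTree | None = None
    tree_constrained: ts.PhyloTree | None = None
    replicate_log: list = field(default_factory=list)

    @property
    def n_null(self) -> int:
        return len(self.null_deltas)

    def p_values_disagree(self) -> bool:
        """Flag when the t approximation and the raw empirical p sit on
        opposite sides of alpha."""
        if self.p_parametric_t is None:
            return False
        return ((self.p_empirical_raw < self.alpha)
                != (self.p_parametric_t < self.alpha))

    def to_dict(self) -> dict:
        return {
            "lnl_unconstrained": self.lnl_unconstrained,
            "lnl_constrained": self.lnl_constrained,
            "delta": self.delta,
            "n_null": self.n_null,
            "null_deltas": [float(x) for x in self.null_deltas],
            "p_empirical_raw": self.p_empirical_raw,
            "p_empirical_corrected": self.p_empirical_corrected,
            "p_parametric_t": self.p_parametric_t,
            "converged": self.converged,
            "percent_ratio": self.percent_ratio,
            "alpha": self.alpha,
            "reject": self.reject,
            "p_values_disagree": self.p_values_disagree(),
            "seed": self.seed,
            "tree_unconstrained": (self.tree_unconstrained.newick()
                                   if self.tree_unconstrained else None),
            "tree_constrained": (self.tree_constrained.newick()
                                 if self.tree_constrained else None),
            "replicates": self.replicate_log,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _replicate_mask(aln: MultiLocusAlignment, scheme: PartitionScheme) -> np.ndarray:
    """Observed missing-data footprint reordered to the simulated column
    layout (partition blocks concatenated in scheme order)."""
    pres = aln.presence()
    cols = np.concatenate([p.indices for p in scheme])
    return ~pres[:, cols]


def sowh_test(aln: MultiLocusAlignment, scheme: PartitionScheme,
              constraint: ts.PhyloTree, alpha: float = 0.05,
              n_max: int = 100, strategy: str = "nni",
              seed: int | None = None, stop: bool = True,
              model_init: pm.PartitionedModel | None = None,
              n_categories: int = 4, refit_model: bool = True,
              preserve_missing: bool = True, n_starts: int = 2,
              min_replicates: int = 10,
              keep_replicate_log: bool = False) -> SOWHResult:
    """Run the SOWH test of ``constraint`` against ``aln``.

    Null replicates are simulated on the constrained ML tree with its fitted
    model (H0); by default the observed missing-data footprint is re-imposed
    on every simulated alignment (``preserve_missing``).  The decision rule
    rejects the constraint when the raw empirical p is below ``alpha``.
    """
    if n_max < 10:
        raise UsageError("n_max must be at least 10")
    ss = np.random.SeedSequence(seed)
    search_seeds = ss.spawn(2)
    rep_ss = ss.spawn(n_max)

    patterns = pm.SitePatternTable.from_alignment(aln, scheme)
    if model_init is None:
        model_init = pm.PartitionedModel.initial(patterns,
                                                 n_categories=n_categories)
    # With a fixed model and exhaustive search, one scan gives both optima
    # (and guarantees delta >= 0).
    shared_scan = strategy == "exhaustive" and not refit_model
    if shared_scan:
        res_u, res_c = sr.exhaustive_delta(patterns, model_init, constraint)
    else:
        res_u = sr.search_ml(patterns, model_init, strategy=strategy,
                             n_starts=n_starts,
                             seed=int(search_seeds[0].generate_state(1)[0] % 2**31),
                             refit_model=refit_model)
        res_c = sr.search_ml(patterns, res_u.model, constraint=constraint,
                             strategy=strategy, n_starts=n_starts,
                             seed=int(search_seeds[1].generate_state(1)[0] % 2**31),
                             refit_model=refit_model)
    if not (np.isfinite(res_u.lnl) and np.isfinite(res_c.lnl)):
        raise NumericalError("non-finite fitted likelihoods; aborting SOWH test")
    delta = _snap(res_u.lnl - res_c.lnl)

    part_lengths = [len(p) for p in scheme]
    mask = _replicate_mask(aln, scheme) if preserve_missing else None

    null_deltas: list[float] = []
    rep_log: list = []
    converged = False
    percent_ratio = 1.0
    for r in range(n_max):
        rng = np.random.default_rng(rep_ss[r])
        sim_spec = sim.SimulationSpec(
            tree=res_c.tree, model=res_c.model,
            partition_lengths=part_lengths,
            partition_names=[p.name for p in scheme],
            taxa=list(aln.isolates), missing_mask=mask)
        rep_aln = sim.simulate_alignment(sim_spec, rng=rng)
        rep_scheme = _contiguous_scheme(scheme)
        rep_patterns = pm.SitePatternTable.from_alignment(rep_aln, rep_scheme)
        if shared_scan:
            rep_u, rep_c = sr.exhaustive_delta(rep_patterns, res_c.model,
                                               constraint)
        else:
            s_u = int(rng.integers(2**31))
            s_c = int(rng.integers(2**31))
            # warm starts from the observed best trees cut the climb length;
            # final lnLs are still fully re-optimised per replicate
            rep_u = sr.search_ml(rep_patterns, res_c.model, strategy=strategy,
                                 n_starts=n_starts, seed=s_u,
                                 refit_model=refit_model,
                                 start_tree=res_u.tree)
            rep_c = sr.search_ml(rep_patterns, res_c.model,
                                 constraint=constraint, strategy=strategy,
                                 n_starts=n_starts, seed=s_c,
                                 refit_model=refit_model,
                                 start_tree=res_c.tree)
        d_r = _snap(rep_u.lnl - rep_c.lnl)
        null_deltas.append(d_r)
        if keep_replicate_log:
            rep_log.append({"replicate": r, "delta": d_r,
                            "lnl_unconstrained": rep_u.lnl,
                            "lnl_constrained": rep_c.lnl})
        if stop and len(null_deltas) >= min_replicates:
            halt, percent_ratio = convergence_check(null_deltas, delta,
                                                    alpha=alpha, n_max=n_max)
            if halt:
                converged = True
                break
    else:
        percent_ratio = 1.0
        converged = False

    raw, corrected = p_empirical(delta, null_deltas)
    if len(null_deltas) >= 3 and np.asarray(null_deltas).std(ddof=1) > 0:
        p_t = p_parametric_t(delta, null_deltas)
    else:
        p_t = None
    return SOWHResult(
        lnl_unconstrained=res_u.lnl, lnl_constrained=res_c.lnl, delta=delta,
        null_deltas=np.array(null_deltas),
        p_empirical_raw=raw, p_empirical_corrected=corrected,
        p_parametric_t=p_t, converged=converged, percent_ratio=percent_ratio,
        alpha=alpha, reject=raw < alpha, seed=seed,
        tree_unconstrained=res_u.tree, tree_constrained=res_c.tree,
        replicate_log=rep_log)


def _contiguous_scheme(scheme: PartitionScheme) -> PartitionScheme:
    """Partition scheme for simulated alignments: the same partitions in the
    same order, laid out as contiguous blocks."""
    from .seqdata import Partition
    parts = []
    off = 0
    for p in scheme:
        parts.append(Partition(p.name, np.arange(off, off + len(p)), kind=p.kind))
        off += len(p)
    return PartitionScheme(parts)
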