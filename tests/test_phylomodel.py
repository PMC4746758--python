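"""GTR+Γ+I machinery: gamma discretisation, transition matrices, pruning
likelihood against independent oracles, fitting, serialisation."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

import phylosowh as ps
from phylosowh import _kernels as K
from phylosowh import phylomodel as pm
from phylosowh import simulate as sim
from phylosowh.errors import DataError, UsageError

from conftest import brute_force_loglik, patterns_from_states, random_gtr


class TestDiscreteGamma:
    def test_single_category(self):
        assert ps.discrete_gamma_rates(0.7, 1).tolist() == [1.0]

    def test_large_shape_limit(self):
        rates = ps.discrete_gamma_rates(1e6, 4)
        assert np.all(np.abs(rates - 1) < 1e-2)

    def test_quadrature_oracle(self):
        """Category means match direct numerical integration."""
        alpha, k = 0.5, 4
        rates = ps.discrete_gamma_rates(alpha, k)
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1 / alpha)
        for i in range(k):
            lo, hi = edges[i], min(edges[i + 1], 400.0)
            mean_i, _ = quad(lambda x: x * gamma_dist.pdf(x, alpha, scale=1 / alpha),
                             lo, hi, limit=200)
            assert rates[i] == pytest.approx(k * mean_i, abs=1e-6)

    def test_mean_is_one(self):
        for alpha in (0.1, 0.5, 2.0, 20.0):
            assert ps.discrete_gamma_rates(alpha, 4).mean() == pytest.approx(1.0, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(UsageError):
            ps.discrete_gamma_rates(-1.0, 4)


class TestTransitionMatrix:
    def test_zero_time_identity(self, rng):
        m = random_gtr(rng)
        assert np.allclose(m.transition_matrix(0.0), np.eye(4), atol=1e-12)

    def test_long_time_stationarity(self, rng):
        m = random_gtr(rng)
        P = m.transition_matrix(500.0)
        assert np.allclose(P, np.tile(m.freqs, (4, 1)), atol=1e-10)

    def test_rows_sum_and_detailed_balance(self, rng):
        m = random_gtr(rng)
        P = m.transition_matrix(0.37, rate=1.3)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        flow = m.freqs[:, None] * P
        assert np.allclose(flow, flow.T, atol=1e-12)

    def test_jc_closed_form(self):
        jc = pm.SubstitutionModel.jc()
        t = 0.1
        P = jc.transition_matrix(t)
        same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        expected = np.full((4, 4), diff)
        np.fill_diagonal(expected, same)
        assert np.allclose(P, expected, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(UsageError):
            pm.SubstitutionModel.jc().transition_matrix(-0.1)


class TestLogLikelihood:
    def test_identical_sequences_zero_branch(self):
        L = 40
        states = np.tile(np.arange(4), L // 4)[None, :].repeat(2, axis=0)
        pat = patterns_from_states(["A", "B"], states)
        tree = ps.parse_newick("(A:0.0,B:0.0);")
        model = pm.PartitionedModel.single(pm.SubstitutionModel.jc(), L)
        assert pm.log_likelihood(tree, pat, model) == pytest.approx(
            L * np.log(0.25), abs=1e-10)

    def test_two_taxon_jc_closed_form(self):
        m, k, t = 30, 10, 0.1
        a = np.zeros(m + k, dtype=int)
        b = np.concatenate([np.zeros(m, dtype=int), np.ones(k, dtype=int)])
        pat = patterns_from_states(["A", "B"], np.stack([a, b]))
        tree = ps.parse_newick(f"(A:{t / 2},B:{t / 2});")
        model = pm.PartitionedModel.single(pm.SubstitutionModel.jc(), m + k)
        p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        expected = m * np.log(0.25 * p_same) + k * np.log(0.25 * p_diff)
        assert pm.log_likelihood(tree, pat, model) == pytest.approx(expected, abs=1e-10)

    def test_brute_force_oracle_four_taxa(self, rng):
        """Pruning equals explicit internal-state enumeration (GTR+Γ+I)."""
        tree = ps.parse_newick(
            "((A:0.21,B:0.08):0.12,C:0.33,D:0.05);")
        sub = random_gtr(rng, n_categories=3, p_inv=0.2)
        model = pm.PartitionedModel.single(sub, 20)
        states = rng.integers(0, 4, size=(4, 20))
        pat = patterns_from_states(["A", "B", "C", "D"], states)
        got = pm.log_likelihood(tree, pat, model)
        want = brute_force_loglik(tree, pat, model)
        assert got == pytest.approx(want, abs=1e-8)

    def test_ambiguity_codes_marginalise(self, rng):
        # '?' leaves carry no information: lnL equals the 3-taxon value of
        # dropping... instead check via brute force which marginalises too
        masks = np.array([[1, 15, 3], [2, 4, 15], [8, 8, 8], [15, 1, 2]],
                         dtype=np.uint8)
        part = pm.PatternPartition("all", masks, np.array([5, 2, 1]))
        pat = pm.SitePatternTable(list("ABCD"), [part])
        tree = ps.parse_newick("((A:0.1,B:0.2):0.05,C:0.3,D:0.15);")
        model = pm.PartitionedModel.single(random_gtr(rng, 2, 0.1), 8)
        assert pm.log_likelihood(tree, pat, model) == pytest.approx(
            brute_force_loglik(tree, pat, model), abs=1e-8)

    def test_rerooting_and_leaf_order_invariance(self, rng):
        sub = random_gtr(rng)
        model = pm.PartitionedModel.single(sub, 50)
        states = rng.integers(0, 4, size=(5, 50))
        taxa = list("ABCDE")
        pat = patterns_from_states(taxa, states)
        reps = [
            "(((A:0.1,B:0.2):0.05,C:0.3):0.07,D:0.15,E:0.21);",
            "((A:0.1,B:0.2):0.05,C:0.3,(D:0.15,E:0.21):0.07);",
            "(D:0.15,E:0.21,(C:0.3,(B:0.2,A:0.1):0.05):0.07);",
        ]
        vals = [pm.log_likelihood(ps.parse_newick(n), pat, model) for n in reps]
        # same unrooted tree traversed from three different roots
        assert abs(vals[0] - vals[2]) < 1e-9
        assert abs(vals[0] - vals[1]) < 1e-9

    def test_pattern_compression_exact(self, rng):
        sub = random_gtr(rng, 2)
        states = rng.integers(0, 4, size=(4, 60))
        taxa = list("ABCD")
        compressed = patterns_from_states(taxa, states)
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        uncompressed = pm.SitePatternTable(taxa, [pm.PatternPartition(
            "all", bits[states], np.ones(60, dtype=np.int64))])
        tree = ps.parse_newick("((A:0.1,B:0.2):0.05,C:0.3,D:0.15);")
        ma = pm.PartitionedModel.single(sub, 60)
        assert pm.log_likelihood(tree, compressed, ma) == pytest.approx(
            pm.log_likelihood(tree, uncompressed, ma), abs=1e-9)

    def test_missing_leaf_rejected(self, rng):
        pat = patterns_from_states(["A", "B", "C"], rng.integers(0, 4, (3, 5)))
        tree = ps.parse_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        with pytest.raises(DataError):
            pm.log_likelihood(tree, pat,
                              pm.PartitionedModel.single(pm.SubstitutionModel.jc(), 5))

    def test_kernel_agrees_with_reference(self, rng):
        """Dual-route check: numba kernel vs NumPy reference, partitioned."""
        tree = ps.parse_newick(
            "(((A:0.2,B:0.1):0.3,(C:0.15,D:0.25):0.05):0.1,E:0.3,F:0.12);")
        models = [random_gtr(rng, 4, 0.1), random_gtr(rng, 4, 0.0)]
        model = pm.PartitionedModel(models, np.array([1.4, 0.8]),
                                    np.array([300.0, 200.0]))
        spec = sim.SimulationSpec(tree=tree, model=model,
                                  partition_lengths=[300, 200], seed=5)
        aln = sim.simulate_alignment(spec)
        from phylosowh.seqdata import Partition, PartitionScheme
        scheme = PartitionScheme([Partition("p1", np.arange(300)),
                                  Partition("p2", np.arange(300, 500))])
        pat = pm.SitePatternTable.from_alignment(aln, scheme)
        ref = pm.log_likelihood(tree, pat, model)
        pack = K.LikelihoodPack(pat, model)
        enc = K.TreeEncoding(tree, {t: i for i, t in enumerate(pat.taxa)})
        assert K.tree_loglik(enc, pack) == pytest.approx(ref, abs=1e-7)


class TestFit:
    def test_refit_at_optimum_is_fixed_point(self, rng):
        tree = ps.parse_newick("((A:0.2,B:0.1):0.15,C:0.3,D:0.25);")
        sub = pm.SubstitutionModel.jc(n_categories=1)
        model = pm.PartitionedModel.single(sub, 1000)
        spec = sim.SimulationSpec(tree=tree, model=model,
                                  partition_lengths=[1000], seed=2)
        aln = sim.simulate_alignment(spec)
        pat = pm.SitePatternTable.from_alignment(aln)
        first = pm.fit(tree, pat, model, tol=1e-4,
                       optimize_exchangeabilities=False, optimize_freqs=False,
                       optimize_alpha=False, optimize_pinv=False)
        second = pm.fit(first.tree, pat, model, tol=1e-4,
                        optimize_exchangeabilities=False, optimize_freqs=False,
                        optimize_alpha=False, optimize_pinv=False)
        assert second.lnl - first.lnl < 1e-3
        assert second.lnl >= first.lnl - 1e-9

    def test_fit_never_decreases_loglik(self, rng):
        tree = ps.parse_newick("((A:0.2,B:0.1):0.15,C:0.3,D:0.25);")
        true = pm.PartitionedModel.single(random_gtr(rng, 4, 0.1), 800)
        spec = sim.SimulationSpec(tree=tree, model=true,
                                  partition_lengths=[800], seed=9)
        aln = sim.simulate_alignment(spec)
        pat = pm.SitePatternTable.from_alignment(aln)
        init = pm.PartitionedModel.initial(pat, n_categories=4)
        start = pm.log_likelihood(tree, pat, init)
        res = pm.fit(tree, pat, init, max_sweeps=3)
        assert res.lnl >= start


class TestSerialization:
    def test_json_roundtrip_exact(self, rng):
        model = pm.PartitionedModel([random_gtr(rng, 4, 0.13), random_gtr(rng)],
                                    np.array([1.234567890123, 0.9]),
                                    np.array([123.0, 456.0]))
        back = pm.PartitionedModel.from_json(model.to_json())
        for a, b in zip(model.models, back.models):
            assert a.rates.tolist() == b.rates.tolist()
            assert a.freqs.tolist() == b.freqs.tolist()
            assert a.gamma_shape == b.gamma_shape
            assert a.p_inv == b.p_inv
        assert model.rate_multipliers.tolist() == back.rate_multipliers.tolist()
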