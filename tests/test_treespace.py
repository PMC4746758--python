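"""Tree algebra: Newick round-trips, splits, constraints, enumeration, NNI,
conflict scanning."""

import itertools

import numpy as np
import pytest

import phylosowh as ps
from phylosowh import treespace as ts
from phylosowh.errors import DataError, UsageError


def _split_set(tree):
    """Independent split computation by leaf-set recursion (test-local)."""
    taxa = frozenset(tree.leaf_labels())
    out = set()

    def below(node):
        if node.is_leaf:
            return frozenset([node.label])
        bl = frozenset().union(*(below(c) for c in node.children))
        if node.parent is not None and 2 <= len(bl) <= len(taxa) - 2:
            out.add(frozenset((bl, taxa - bl)))
        return bl

    below(tree.root)
    return out


class TestNewick:
    def test_four_leaf_parse(self):
        t = ps.parse_newick("((A,B),(C,D));")
        assert sorted(t.leaf_labels()) == ["A", "B", "C", "D"]
        bps = ps.bipartitions(t)
        assert len(bps) == 1
        assert bps[0].key == frozenset((frozenset("AB"), frozenset("CD")))

    def test_support_parsing(self):
        t = ps.parse_newick("((A,B)95:0.1,C,D);")
        bp = ps.bipartitions(t)[0]
        assert bp.support == 95
        assert "95" in t.newick()

    def test_parse_errors(self):
        with pytest.raises(DataError):
            ps.parse_newick("((A,B,(C,D));")
        with pytest.raises(DataError):
            ps.parse_newick("((A,B),(A,D));")

    def test_random_roundtrip(self, rng):
        taxa = [f"x{i}" for i in range(20)]
        for _ in range(15):
            t = ts.random_addition_tree(taxa, rng)
            for node in t.preorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.01, 2.0))
                if not node.is_leaf and node.parent is not None:
                    node.support = float(np.round(rng.uniform(0, 100), 1))
            back = ps.parse_newick(t.newick())
            assert _split_set(back) == _split_set(t)
            lens = sorted(n.length for n in t.preorder() if n.parent is not None)
            lens2 = sorted(n.length for n in back.preorder() if n.parent is not None)
            assert np.allclose(lens, lens2, rtol=1e-11)
            sups = sorted(bp.support for bp in ps.bipartitions(t))
            sups2 = sorted(bp.support for bp in ps.bipartitions(back))
            assert sups == sups2

    def test_canonical_newick_is_rooting_invariant(self):
        a = ps.parse_newick("((A,B),(C,D),E);")
        b = ps.parse_newick("((C,D),(A,B),E);")
        c = ps.parse_newick("(((A,B),E),C,D);")
        assert a.canonical_newick() == b.canonical_newick() == c.canonical_newick()


class TestBipartitions:
    def test_caterpillar_six(self):
        t = ps.parse_newick("(A,B,(C,(D,(E,F))));")
        keys = {bp.key for bp in ps.bipartitions(t)}
        taxa = frozenset("ABCDEF")
        expected = {
            frozenset((frozenset("CDEF"), taxa - frozenset("CDEF"))),
            frozenset((frozenset("DEF"), taxa - frozenset("DEF"))),
            frozenset((frozenset("EF"), taxa - frozenset("EF"))),
        }
        assert keys == expected

    def test_restriction(self):
        t = ps.parse_newick("((A,B),(C,(D,E)));")
        bps = ps.bipartitions(t, restrict_to=set("ABCD"))
        keys = {bp.key for bp in bps}
        assert frozenset((frozenset("AB"), frozenset("CD"))) in keys

    def test_fewer_than_four_taxa_empty(self):
        t = ps.parse_newick("((A,B),(C,D),E);")
        assert ps.bipartitions(t, restrict_to=set("ABC")) == []


class TestDisplays:
    def test_star_constraint_always_true(self):
        star = ps.parse_newick("(A,B,C,D,E,F);")
        for t in itertools.islice(ps.enumerate_topologies(list("ABCDEF")), 30):
            assert ps.displays(t, star)

    def test_contradiction(self):
        cons = ps.parse_newick("((A,B),(C,D));")
        t = ps.parse_newick("((A,C),(B,D),E);")
        assert not ps.displays(t, cons)

    def test_exhaustive_six_taxon_oracle(self):
        """displays() agrees with independent split containment on all 105
        topologies for a one-split backbone constraint."""
        taxa = list("ABCDEF")
        cons = ps.monophyly_constraint(["A", "B", "C"], taxa)
        want = frozenset((frozenset("ABC"), frozenset("DEF")))
        n_display = 0
        for t in ps.enumerate_topologies(taxa):
            expected = want in _split_set(t)
            assert ps.displays(t, cons) == expected
            n_display += expected
        # 3 resolutions on each side of the constrained split
        assert n_display == 9

    def test_partial_taxon_constraint(self):
        cons = ps.monophyly_constraint(["A", "B"], ["A", "B", "C", "D"])
        t = ps.parse_newick("(((A,X),B),(C,(D,Y)),Z);")
        assert ps.displays(t, cons)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(4, 3), (6, 105), (7, 945)])
    def test_counts(self, n, count):
        taxa = [f"t{i}" for i in range(n)]
        trees = list(ps.enumerate_topologies(taxa))
        assert len(trees) == count
        # each exactly once
        assert len({t.canonical_newick() for t in trees}) == count

    def test_guard(self):
        with pytest.raises(UsageError):
            next(iter(ps.enumerate_topologies([f"t{i}" for i in range(10)])))


class TestNNI:
    def test_four_taxon_neighbors_are_other_topologies(self):
        taxa = list("ABCD")
        all3 = {t.canonical_newick() for t in ps.enumerate_topologies(taxa)}
        t = ps.parse_newick("((A,B),C,D);")
        nbs = ps.nni_neighbors(t)
        assert len(nbs) == 2
        got = {nb.canonical_newick() for nb in nbs}
        assert got == all3 - {t.canonical_newick()}

    def test_six_taxon_count_distinct(self):
        t = ps.parse_newick("(((A,B),(C,D)),E,F);")
        nbs = ps.nni_neighbors(t)
        assert len(nbs) == 2 * (6 - 3)
        canon = {nb.canonical_newick() for nb in nbs}
        assert len(canon) == 6
        assert t.canonical_newick() not in canon

    def test_symmetry(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        for _ in range(5):
            t = ts.random_addition_tree(taxa, rng)
            for nb in ps.nni_neighbors(t):
                back = {x.canonical_newick() for x in ps.nni_neighbors(nb)}
                assert t.canonical_newick() in back


class TestConflictScan:
    def _with_supports(self, nwk, support):
        t = ps.parse_newick(nwk)
        for n in t.preorder():
            if not n.is_leaf and n.parent is not None:
                n.support = support
        return t

    def test_identical_trees_no_conflict(self):
        a = self._with_supports("((A,B),C,(D,E));", 100)
        b = self._with_supports("((A,B),C,(D,E));", 100)
        assert ps.conflict_scan(a, b) == []

    def test_hand_built_conflict(self):
        a = self._with_supports("((A,B),C,(D,E));", 90)
        b = self._with_supports("((A,C),B,(D,E));", 90)
        pairs = ps.conflict_scan(a, b, cutoff=70)
        assert len(pairs) == 1
        sa, sb = pairs[0]
        assert sa.key == frozenset((frozenset("AB"), frozenset("CDE")))
        assert sb.key == frozenset((frozenset("AC"), frozenset("BDE")))

    def test_below_cutoff_empty(self):
        a = self._with_supports("((A,B),C,(D,E));", 60)
        b = self._with_supports("((A,C),B,(D,E));", 60)
        assert ps.conflict_scan(a, b, cutoff=70) == []

    def test_symmetric(self):
        a = self._with_supports("((A,B),C,(D,E));", 95)
        b = self._with_supports("((A,C),B,(D,E));", 95)
        ab = {(x.key, y.key) for x, y in ps.conflict_scan(a, b)}
        ba = {(y.key, x.key) for x, y in ps.conflict_scan(b, a)}
        assert ab == ba

    def test_few_shared_taxa_warns_empty(self):
        a = self._with_supports("((A,B),C,(D,E));", 95)
        b = self._with_supports("((A,B),X,(Y,Z));", 95)
        with pytest.warns(UserWarning):
            assert ps.conflict_scan(a, b) == []


class TestBootstrapSupport:
    def test_single_replicate_supports_are_zero_or_hundred(self):
        import phylosowh.phylomodel as pm
        import phylosowh.simulate as sim

        tree = ps.parse_newick(
            "((A:0.1,B:0.1):0.25,(C:0.1,D:0.1):0.25,E:0.1);")
        model = pm.PartitionedModel.single(pm.SubstitutionModel.jc(), 300)
        aln = sim.simulate_alignment(sim.SimulationSpec(
            tree=tree, model=model, partition_lengths=[300], seed=14))
        pat = pm.SitePatternTable.from_alignment(aln)
        out = ps.bootstrap_support(pat, model, tree, B=1, seed=2,
                                   strategy="exhaustive")
        sups = [bp.support for bp in ps.bipartitions(out)]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_strong_signal_split_highly_supported(self):
        import phylosowh.phylomodel as pm
        import phylosowh.simulate as sim

        tree = ps.parse_newick(
            "((A:0.1,B:0.1):0.4,(C:0.1,D:0.1):0.4,E:0.1);")
        model = pm.PartitionedModel.single(pm.SubstitutionModel.jc(), 2000)
        aln = sim.simulate_alignment(sim.SimulationSpec(
            tree=tree, model=model, partition_lengths=[2000], seed=15))
        pat = pm.SitePatternTable.from_alignment(aln)
        out = ps.bootstrap_support(pat, model, tree, B=50, seed=3,
                                   strategy="exhaustive")
        focal = frozenset((frozenset("AB"), frozenset("CDE")))
        sup = {bp.key: bp.support for bp in ps.bipartitions(out)}[focal]
        assert sup >= 95.0
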