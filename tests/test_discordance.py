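"""Concordance counts, quartet frequencies, clade arrangements, placements."""
import itertools
import math

import numpy as np
import pytest

from discotree import discordance as dc
from discotree import synthetic_data as syn
from discotree import treeio
from discotree.treeio import read_newick_string


def msc_concordant(T: float) -> float:
    return 1.0 - (2.0 / 3.0) * math.exp(-T)


class TestNodeConcordance:
    def test_identical_gene_trees_fully_concordant(self):
        sp = read_newick_string("(((A,B),C),D);")[0]
        gts = read_newick_string("\n".join("(((A,B),C),D);" for _ in range(20)))
        for r in dc.node_concordance(sp, gts):
            assert r.concordant == 20 and r.conflicting == 0

    def test_50_50_mix_splits_counts(self):
        sp = read_newick_string("(((A,B),C),D);")[0]
        trees = ["(((A,B),C),D);"] * 10 + ["(((A,C),B),D);"] * 10
        gts = read_newick_string("\n".join(trees))
        rec = next(
            r for r in dc.node_concordance(sp, gts) if r.clade == frozenset("AB")
        )
        assert (rec.concordant, rec.conflicting) == (10, 10)

    def test_categories_partition_gene_tree_set(self, triple_trees_t1):
        sp = read_newick_string("((A,B),C);")[0]
        for r in dc.node_concordance(sp, triple_trees_t1):
            assert r.n_trees == len(triple_trees_t1)

    def test_msc_closed_form_concordant_fraction(self, triple_trees_t1):
        """On a T=1 triple, concordance approximates 1 - (2/3)e^-1."""
        sp = read_newick_string("((A,B),C);")[0]
        rec = next(
            r
            for r in dc.node_concordance(sp, triple_trees_t1)
            if r.clade == frozenset("AB")
        )
        n = rec.n_trees
        p = msc_concordant(1.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(rec.concordant / n - p) < 3 * se

    def test_support_collapsing_moves_trees_to_uninformative(self):
        sp = read_newick_string("((A,B),C);")[0]
        gts = read_newick_string("((A,B)50,C);\n((A,B)90,C);")
        rec = dc.node_concordance(sp, gts, support_threshold=70)[0]
        assert (rec.concordant, rec.uninformative) == (1, 1)


class TestQuartetFreqs:
    def test_identical_gene_trees_give_q1_one(self):
        sp = read_newick_string("(((A,B),C),O);")[0]
        gts = read_newick_string("\n".join("(((A,B),C),O);" for _ in range(30)))
        (r,) = dc.quartet_freqs(sp, gts)
        assert (r.q1, r.q2, r.q3) == (1.0, 0.0, 0.0)

    def test_msc_t1_matches_closed_form(self, quartet_trees_t1):
        sp = read_newick_string("(((A,B),C),O);")[0]
        (r,) = dc.quartet_freqs(sp, quartet_trees_t1)
        p = msc_concordant(1.0)
        se = math.sqrt(p * (1 - p) / r.n_resolved)
        assert abs(r.q1 - p) < 3 * se
        assert r.q1 + r.q2 + r.q3 == pytest.approx(1.0)

    def test_star_like_history_gives_equal_thirds(self):
        """T -> 0 means extreme ILS: all three resolutions equally frequent."""
        gts = syn.simulate_gene_trees(
            "(((A:1,B:1):0.001,C:1.001):9,O:10);", n=1000, seed=33
        )
        sp = read_newick_string("(((A,B),C),O);")[0]
        (r,) = dc.quartet_freqs(sp, gts)
        for q in (r.q1, r.q2, r.q3):
            assert abs(q - 1 / 3) < 0.05

    def test_t2_quartet_frequency(self):
        gts = syn.simulate_gene_trees(
            "(((A:1,B:1):2,C:3):7,O:10);", n=3000, seed=34
        )
        sp = read_newick_string("(((A,B),C),O);")[0]
        (r,) = dc.quartet_freqs(sp, gts)
        p = msc_concordant(2.0)
        se = math.sqrt(p * (1 - p) / r.n_resolved)
        assert abs(r.q1 - p) < 3 * se

    def test_exhaustive_sampling_equals_brute_force(self, rng):
        """Frequencies from quartet_freqs match a direct tally over all
        quartets around each branch of an 8-taxon species tree."""
        net = "((((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2):1,(G:1,H:1):3);"
        gts = syn.simulate_gene_trees(net, n=50, seed=35)
        sp = read_newick_string(
            "((((A,B),(C,D)),(E,F)),(G,H));"
        )[0]
        results = dc.quartet_freqs(sp, gts, budget=10**6)
        from discotree.species_inference import quartet_resolution

        gene_clades = []
        for gt in gts:
            clades = []
            dt = gt.dendropy_tree
            for nd in dt.postorder_node_iter():
                if nd.is_leaf():
                    nd._x = frozenset([nd.taxon.label])
                else:
                    nd._x = frozenset().union(*(c._x for c in nd.child_nodes()))
                    clades.append(nd._x)
            gene_clades.append(clades)

        checked = 0
        for r in results:
            groups = _incident_groups(sp, r.clade)
            if groups is None:
                continue
            n1 = n2 = n3 = 0
            for quartet in itertools.product(*[sorted(g) for g in groups]):
                qs = set(quartet)
                ref = min(qs)

                def canon(pair):
                    return pair if ref in pair else frozenset(qs - pair)

                want1 = canon(frozenset(quartet[:2]))
                want2 = canon(frozenset((quartet[0], quartet[2])))
                for clades in gene_clades:
                    res = quartet_resolution(clades, quartet)
                    if res is None:
                        continue
                    if res == want1:
                        n1 += 1
                    elif res == want2:
                        n2 += 1
                    else:
                        n3 += 1
            tot = n1 + n2 + n3
            assert r.q1 == pytest.approx(n1 / tot)
            assert r.q2 + r.q3 == pytest.approx((n2 + n3) / tot)
            checked += 1
        assert checked >= 4


def _incident_groups(sp, clade):
    """The four leaf groups around the branch above `clade` (None if root)."""
    t = sp.dendropy_tree
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd._x = frozenset([nd.taxon.label])
        else:
            nd._x = frozenset().union(*(c._x for c in nd.child_nodes()))
    all_taxa = t.seed_node._x
    for nd in t.preorder_internal_node_iter():
        if nd is t.seed_node or nd._x != clade:
            continue
        kids = nd.child_nodes()
        c1, c2 = set(kids[0]._x), set(kids[1]._x)
        parent = nd.parent_node
        sibling = set().union(
            *(set(k._x) for k in parent.child_nodes() if k is not nd)
        )
        rest = set(all_taxa) - set(nd._x) - sibling
        if not rest:
            sibs = [k for k in parent.child_nodes() if k is not nd]
            if len(sibs) == 1 and not sibs[0].is_leaf():
                sk = sibs[0].child_nodes()
                return [c1, c2, set(sk[0]._x), set().union(*(set(k._x) for k in sk[1:]))]
            return None
        return [c1, c2, sibling, rest]
    return None


class TestCladeTopologyFreqs:
    def test_unanimous_arrangement(self):
        gts = read_newick_string(
            "\n".join("(((a1,a2),(b1,b2)),(c1,c2));" for _ in range(10))
        )
        r = dc.clade_topology_freqs(
            gts, ["a1", "a2"], ["b1", "b2"], ["c1", "c2"], support_threshold=None
        )
        assert r.freq_ab == 1.0 and r.n_voting == 10

    def test_majority_mixture_recovered(self):
        trees = (
            ["(((a1,a2),(b1,b2)),(c1,c2));"] * 60
            + ["(((a1,a2),(c1,c2)),(b1,b2));"] * 25
            + ["(((b1,b2),(c1,c2)),(a1,a2));"] * 15
        )
        gts = read_newick_string("\n".join(trees))
        r = dc.clade_topology_freqs(
            gts, ["a1", "a2"], ["b1", "b2"], ["c1", "c2"], support_threshold=None
        )
        assert r.freq_ab == pytest.approx(0.60, abs=0.04)
        assert r.freq_ac == pytest.approx(0.25, abs=0.04)

    def test_excess_missing_samples_abstain(self):
        # clade A has 10 members but only 7 sampled: 30% missing > 20%
        a = [f"a{i}" for i in range(10)]
        tree = "(((a0,a1,a2,a3,a4,a5,a6),(b1,b2)),(c1,c2));"
        gts = read_newick_string(tree)
        r = dc.clade_topology_freqs(
            gts, a, ["b1", "b2"], ["c1", "c2"],
            support_threshold=None, max_missing=0.20,
        )
        assert r.n_voting == 0 and r.n_abstaining == 1

    def test_non_monophyletic_clade_abstains(self):
        gts = read_newick_string("(((a1,b1),(a2,b2)),(c1,c2));")
        r = dc.clade_topology_freqs(
            gts, ["a1", "a2"], ["b1", "b2"], ["c1", "c2"], support_threshold=None
        )
        assert r.n_voting == 0

    def test_low_support_deciding_node_abstains(self):
        gts = read_newick_string("(((a1,a2)90,(b1,b2)90)40,(c1,c2)90);")
        r = dc.clade_topology_freqs(
            gts, ["a1", "a2"], ["b1", "b2"], ["c1", "c2"], support_threshold=70
        )
        assert r.n_voting == 0

    def test_empty_clade_rejected(self):
        gts = read_newick_string("((a1,b1),c1);")
        with pytest.raises(ValueError):
            dc.clade_topology_freqs(gts, [], ["b1"], ["c1"])


class TestPlacementCodes:
    def _map(self):
        clade = {
            "s1": "c1", "s2": "c1", "s3": "c1",
            "t1": "c2", "t2": "c2", "t3": "c2",
            "zz": "c1",
        }
        return treeio.TaxonMap(
            species={k: k for k in clade}, clade=clade, outgroup=set()
        )

    def test_identical_trees_all_concordant(self):
        a = read_newick_string("(((s1,s2),s3),((t1,t2),t3));")[0]
        codes = dc.placement_codes(a, a.copy(), self._map())
        assert set(codes[s] for s in a.leaf_labels) == {"concordant"}

    def test_cross_clade_move_coded_o(self):
        a = read_newick_string("(((s1,s2),s3),((t1,t2),t3));")[0]
        b = read_newick_string("(((s1,s2),(t3,s3)),(t1,t2));")[0]
        codes = dc.placement_codes(a, b, self._map())
        assert codes["t3"] == "o"

    def test_within_clade_swap_coded_x(self):
        a = read_newick_string("(((s1,s2),s3),((t1,t2),t3));")[0]
        b = read_newick_string("(((s1,s3),s2),((t1,t2),t3));")[0]
        codes = dc.placement_codes(a, b, self._map())
        assert codes["s2"] == "x" and codes["s3"] == "x"
        assert codes["t1"] == "concordant"

    def test_absent_from_both_is_dash_and_one_is_absent_one(self):
        a = read_newick_string("(((s1,s2),s3),((t1,t2),t3));")[0]
        b = read_newick_string("(((s1,s2),s3),(t1,t2));")[0]
        codes = dc.placement_codes(a, b, self._map())
        assert codes["zz"] == "-"
        assert codes["t3"] == "absent-one"


class TestNetDiversification:
    @pytest.mark.parametrize(
        "n,t,expected",
        [
            (19, 4.0, 0.74),
            (1, 3.0, 0.0),
            (int(round(math.e)), 1.0, round(math.log(round(math.e)), 2)),
        ],
    )
    def test_values(self, n, t, expected):
        assert dc.net_diversification(n, t) == expected

    def test_exact_e_gives_one(self):
        # ln(e)/1 = 1.0 using a crown age that cancels the log exactly
        assert dc.net_diversification(20, math.log(20)) == 1.0

    @pytest.mark.parametrize("n,t", [(0, 4), (5, 0), (5, -1)])
    def test_invalid_inputs(self, n, t):
        with pytest.raises(ValueError):
            dc.net_diversification(n, t)
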