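"""Gene-tree and cytonuclear discordance metrics.

Per species-tree node concordance/conflict counts (PhyParts-style), per-branch
quartet frequencies (q1/q2/q3), alternative-topology frequencies for focal
clades, per-sample placement codes between two phylogenies, and the net
diversification rate ln(N)/t.

Under the multispecies coalescent, an internal branch of length T coalescent
units yields a concordant-triple (and quartet) frequency of 1 - (2/3)e^(-T);
equal thirds across the three resolutions therefore indicate extreme ILS.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .species_inference import quartet_resolution
from .treeio import GeneTreeSet, PhyloTree, TaxonMap, collapse_low_support

__all__ = [
    "NodeConcordance",
    "BranchQuartetFreqs",
    "CladeTopologyFreqs",
    "node_concordance",
    "quartet_freqs",
    "clade_topology_freqs",
    "placement_codes",
    "net_diversification",
]


def _rooted_clades(tree: PhyloTree) -> tuple[list[frozenset], frozenset]:
    t = tree.dendropy_tree
    clades = []
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd._ls = frozenset([nd.taxon.label])
        else:
            nd._ls = frozenset().union(*(c._ls for c in nd.child_nodes()))
            if nd is not t.seed_node:
                clades.append(nd._ls)
    return clades, t.seed_node._ls


def _clades_conflict(a: frozenset, b: frozenset) -> bool:
    """Two rooted clades conflict iff they overlap without nesting."""
    inter = a & b
    return bool(inter) and inter != a and inter != b


@dataclass
class NodeConcordance:
    clade: frozenset
    concordant: int
    conflicting: int
    uninformative: int

    @property
    def n_trees(self) -> int:
        return self.concordant + self.conflicting + self.uninformative


def node_concordance(
    species_tree: PhyloTree,
    gene_trees: GeneTreeSet,
    support_threshold: Optional[float] = None,
) -> list[NodeConcordance]:
    """Concordant/conflicting/uninformative gene-tree counts per species-tree
    clade (rooted PhyParts-style semantics).

    Each gene tree is collapsed at the support threshold, restricted to the
    taxa it shares with the species tree, and compared clade-by-clade: a
    species-tree clade (restricted to the shared taxa) is concordant when
    present, conflicting when some gene-tree clade overlaps it without
    nesting, and uninformative otherwise (including when the restriction
    leaves fewer than two members or no outside taxon).
    """
    sp_clades, sp_taxa = _rooted_clades(species_tree)
    results = {c: [0, 0, 0] for c in sp_clades}  # conc, conf, uninf
    for gt in gene_trees:
        t = gt
        if support_threshold is not None:
            t = collapse_low_support(t, support_threshold)
        g_clades, g_taxa = _rooted_clades(t)
        shared = g_taxa & sp_taxa
        for sp_clade in sp_clades:
            r = sp_clade & shared
            if len(r) < 2 or len(shared - r) < 1:
                results[sp_clade][2] += 1
                continue
            g_restricted = {c & shared for c in g_clades}
            g_restricted = {c for c in g_restricted if len(c) >= 2 and c != shared}
            if r in g_restricted:
                results[sp_clade][0] += 1
            elif any(_clades_conflict(r, c) for c in g_restricted):
                results[sp_clade][1] += 1
            else:
                results[sp_clade][2] += 1
    return [
        NodeConcordance(c, *results[c])
        for c in sorted(results, key=lambda s: (len(s), sorted(s)))
    ]


@dataclass
class BranchQuartetFreqs:
    """Relative frequencies of the three resolutions around one branch.

    q1 is the species-tree resolution; q1 + q2 + q3 = 1 over resolved
    sampled quartets.
    """

    clade: frozenset
    q1: float
    q2: float
    q3: float
    n_quartets_sampled: int
    n_resolved: int


def _branch_groups(species_tree: PhyloTree) -> list[tuple[frozenset, list[set]]]:
    """For each internal branch: the four leaf groups incident to it."""
    t = species_tree.dendropy_tree
    _rooted_clades(species_tree)  # sets nd._ls
    all_taxa = t.seed_node._ls
    out = []
    root_children = t.seed_node.child_nodes()
    seen_root_branch = False
    for nd in t.preorder_internal_node_iter():
        if nd is t.seed_node:
            continue
        kids = nd.child_nodes()
        if len(kids) < 2:
            continue
        c1, c2 = set(kids[0]._ls), set().union(*(set(k._ls) for k in kids[1:]))
        parent = nd.parent_node
        sibling = set().union(
            *(set(k._ls) for k in parent.child_nodes() if k is not nd)
        )
        rest = set(all_taxa) - set(nd._ls) - sibling
        if not rest:
            # branch incident to the root: split the sibling side instead
            if seen_root_branch:
                continue
            sib_nodes = [k for k in parent.child_nodes() if k is not nd]
            if len(sib_nodes) == 1 and not sib_nodes[0].is_leaf():
                sk = sib_nodes[0].child_nodes()
                g3 = set(sk[0]._ls)
                g4 = set().union(*(set(k._ls) for k in sk[1:]))
            elif len(sib_nodes) >= 2:
                g3 = set(sib_nodes[0]._ls)
                g4 = set().union(*(set(k._ls) for k in sib_nodes[1:]))
            else:
                continue
            if not g3 or not g4:
                continue
            seen_root_branch = True
            out.append((frozenset(nd._ls), [c1, c2, g3, g4]))
        else:
            out.append((frozenset(nd._ls), [c1, c2, sibling, rest]))
    return out


def quartet_freqs(
    species_tree: PhyloTree,
    gene_trees: GeneTreeSet,
    budget: int = 100,
    seed: int = 0,
) -> list[BranchQuartetFreqs]:
    """Quartet support (q1, q2, q3) for each internal species-tree branch.

    Quartets take one leaf from each of the four clades incident to the
    branch — exhaustively when their number is within ``budget``, otherwise
    a uniform seeded sample — and the three resolutions are tallied across
    all gene trees; q1 is the branch's own (species tree) resolution.
    """
    rng = np.random.default_rng(seed)
    gene_clades = []
    for gt in gene_trees:
        clades, leaves = _rooted_clades(gt)
        gene_clades.append((clades, leaves))
    out = []
    for clade, groups in _branch_groups(species_tree):
        combos = 1
        for g in groups:
            combos *= len(g)
        if combos <= budget:
            quartets = list(itertools.product(*[sorted(g) for g in groups]))
        else:
            quartets = [
                tuple(sorted(g)[rng.integers(len(g))] for g in groups)
                for _ in range(budget)
            ]
        n1 = n2 = n3 = 0
        for a, b, c, d in quartets:
            q = {a, b, c, d}
            ref = min(q)

            def canon(pair):
                return pair if ref in pair else frozenset(q - pair)

            res1 = canon(frozenset((a, b)))
            res2 = canon(frozenset((a, c)))
            for clades, leaves in gene_clades:
                if not {a, b, c, d} <= leaves:
                    continue
                res = quartet_resolution(clades, (a, b, c, d))
                if res is None:
                    continue
                if res == res1:
                    n1 += 1
                elif res == res2:
                    n2 += 1
                else:
                    n3 += 1
        tot = n1 + n2 + n3
        out.append(
            BranchQuartetFreqs(
                clade=clade,
                q1=n1 / tot if tot else float("nan"),
                q2=n2 / tot if tot else float("nan"),
                q3=n3 / tot if tot else float("nan"),
                n_quartets_sampled=len(quartets),
                n_resolved=tot,
            )
        )
    return out


@dataclass
class CladeTopologyFreqs:
    """Frequencies of the three rooted arrangements of (A, B, C) clades."""

    freq_ab: float  # ((A,B),C)
    freq_ac: float
    freq_bc: float
    n_voting: int
    n_abstaining: int


def clade_topology_freqs(
    gene_trees: GeneTreeSet,
    clade_a: Sequence[str],
    clade_b: Sequence[str],
    clade_c: Sequence[str],
    support_threshold: Optional[float] = 70.0,
    max_missing: float = 0.20,
) -> CladeTopologyFreqs:
    """Relative frequency of the three arrangements of three focal clades.

    A gene tree votes iff each clade has at most ``max_missing`` of its
    samples absent, each is monophyletic on the tree pruned to the three
    clades' members, and the deciding node (the mrca of the two grouped
    clades) survives the support threshold. Frequencies are normalized over
    voting trees.
    """
    groups = {"A": set(clade_a), "B": set(clade_b), "C": set(clade_c)}
    for k, g in groups.items():
        if not g:
            raise ValueError(f"clade {k} has no sampled members")
    votes = {"AB": 0, "AC": 0, "BC": 0}
    abstain = 0
    for gt in gene_trees:
        t = gt
        if support_threshold is not None:
            t = collapse_low_support(t, support_threshold)
        leaves = set(t.leaf_labels)
        present = {k: g & leaves for k, g in groups.items()}
        if any(
            (len(g) - len(p)) / len(g) > max_missing or not p
            for (k, g), p in zip(groups.items(), present.values())
        ):
            abstain += 1
            continue
        keep = present["A"] | present["B"] | present["C"]
        sub = t.prune_to(keep)
        dt = sub.dendropy_tree
        clade_sets = []
        support_of = {}
        for nd in dt.postorder_node_iter():
            if nd.is_leaf():
                nd._ls = frozenset([nd.taxon.label])
            else:
                nd._ls = frozenset().union(*(c._ls for c in nd.child_nodes()))
                if nd is not dt.seed_node:
                    clade_sets.append(nd._ls)
                    support_of[nd._ls] = nd.support
        csets = set(clade_sets)

        def is_mono(members: set) -> bool:
            if len(members) == 1:
                return True
            return frozenset(members) in csets

        if not all(is_mono(present[k]) for k in "ABC"):
            abstain += 1
            continue
        vote = None
        for pair, key in ((("A", "B"), "AB"), (("A", "C"), "AC"), (("B", "C"), "BC")):
            union = frozenset(present[pair[0]] | present[pair[1]])
            if union in csets:
                sup = support_of.get(union)
                if (
                    support_threshold is None
                    or sup is None
                    or sup >= support_threshold
                ):
                    vote = key
                break
        if vote is None:
            abstain += 1
        else:
            votes[vote] += 1
    n = sum(votes.values())
    return CladeTopologyFreqs(
        freq_ab=votes["AB"] / n if n else float("nan"),
        freq_ac=votes["AC"] / n if n else float("nan"),
        freq_bc=votes["BC"] / n if n else float("nan"),
        n_voting=n,
        n_abstaining=abstain,
    )


def _sister_set(tree: PhyloTree, sample: str) -> frozenset:
    t = tree.dendropy_tree
    leaf = next(lf for lf in t.leaf_node_iter() if lf.taxon.label == sample)
    parent = leaf.parent_node
    if parent is None:
        return frozenset()
    out = set()
    for k in parent.child_nodes():
        if k is leaf:
            continue
        out.update(lf.taxon.label for lf in k.leaf_iter())
    return frozenset(out)


def placement_codes(
    tree_a: PhyloTree,
    tree_b: PhyloTree,
    taxon_map: TaxonMap,
) -> dict[str, str]:
    """Per-sample placement comparison codes between two rooted trees.

    Codes: "-" sample absent from both trees; "absent-one" present in
    exactly one; "o" attached within different labeled clades; "x" same
    clade but a different sister set (on the shared samples); "concordant"
    otherwise. A sample's attachment clade is the majority clade label of
    its sister group.
    """
    la, lb = set(tree_a.leaf_labels), set(tree_b.leaf_labels)
    shared = la & lb
    sub_a = tree_a.prune_to(shared) if shared != la else tree_a
    sub_b = tree_b.prune_to(shared) if shared != lb else tree_b

    def attach_clade(tree: PhyloTree, s: str) -> Optional[str]:
        sisters = _sister_set(tree, s)
        labels = [taxon_map.clade.get(x) for x in sisters]
        labels = [x for x in labels if x is not None]
        if not labels:
            return None
        counts = {}
        for x in labels:
            counts[x] = counts.get(x, 0) + 1
        top = max(counts.values())
        return min(k for k, v in counts.items() if v == top)

    codes: dict[str, str] = {}
    for s in sorted(set(taxon_map.samples) | la | lb):
        in_a, in_b = s in la, s in lb
        if not in_a and not in_b:
            codes[s] = "-"
            continue
        if in_a != in_b:
            codes[s] = "absent-one"
            continue
        ca = attach_clade(sub_a, s)
        cb = attach_clade(sub_b, s)
        if ca != cb:
            codes[s] = "o"
        elif _sister_set(sub_a, s) != _sister_set(sub_b, s):
            codes[s] = "x"
        else:
            codes[s] = "concordant"
    return codes


def net_diversification(n_species: int, crown_age: float) -> float:
    """Net diversification rate ln(N)/t in species per million years,
    rounded half-up to 2 decimals. ``crown_age`` is in Ma."""
    if n_species < 1 or crown_age <= 0:
        raise ValueError("need n_species >= 1 and crown_age > 0")
    rate = math.log(n_species) / crown_age
    return float(Decimal(repr(rate)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
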