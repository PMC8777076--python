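"""ILS-aware species-tree estimation from gene trees, and distance trees.

Two summary methods stand in for likelihood-based species-tree software:

* a quartet method: the unrooted topology maximizing the summed dominant
  quartet count over gene trees — exhaustive over all (2n-5)!! topologies for
  n <= 8, or via average topological internode distances + neighbor joining
  for larger taxon sets (the NJst/ASTRID family of estimators);
* a distance tree from a concatenated alignment or SNP matrix: missing-aware
  p-distances + neighbor joining.

Both are statistically consistent under the multispecies coalescent.
"""
from __future__ import annotations

import itertools
import warnings
from collections import Counter
from typing import Optional, Sequence, Union

import numpy as np

from .filtering import SnpMatrix
from .treeio import GeneTreeSet, PhyloTree, read_newick_string

__all__ = [
    "quartet_tallies",
    "species_tree_quartet",
    "average_internode_distances",
    "distance_tree",
    "nj_tree",
]


def _clade_leafsets(tree: PhyloTree) -> tuple[list[frozenset], frozenset]:
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


def quartet_resolution(
    clades: Sequence[frozenset], quartet: Sequence[str]
) -> Optional[frozenset]:
    """The pair grouped together for this quartet, or None if unresolved.

    A clade intersecting the quartet in exactly two taxa determines the
    resolution; in a tree all such clades agree. The returned pair is
    canonical: the side containing the quartet's smallest label (xy|zw and
    zw|xy are the same unrooted resolution).
    """
    q = set(quartet)
    ref = min(q)
    for cs in clades:
        inter = cs & q
        if len(inter) == 2:
            return frozenset(inter) if ref in inter else frozenset(q - inter)
    return None


def quartet_tallies(
    gene_trees: GeneTreeSet, taxa: Optional[Sequence[str]] = None
) -> dict[frozenset, Counter]:
    """Counts of the three resolutions per taxon quadruple across gene trees."""
    if taxa is None:
        taxa = sorted(gene_trees.taxon_labels)
    taxa_set = set(taxa)
    tallies: dict[frozenset, Counter] = {
        frozenset(q): Counter() for q in itertools.combinations(sorted(taxa), 4)
    }
    for gt in gene_trees:
        clades, all_leaves = _clade_leafsets(gt)
        present = sorted(all_leaves & taxa_set)
        for q in itertools.combinations(present, 4):
            res = quartet_resolution(clades, q)
            if res is not None:
                tallies[frozenset(q)][res] += 1
    return tallies


def _rooted_topologies(labels: Sequence[str]):
    """All rooted binary topologies on labels, as nested pair tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    for sub in _rooted_topologies(labels[:-1]):
        yield from _insert_leaf(sub, labels[-1])


def _insert_leaf(t, x):
    yield (t, x)
    if isinstance(t, tuple):
        a, b = t
        for a2 in _insert_leaf(a, x):
            yield (a2, b)
        for b2 in _insert_leaf(b, x):
            yield (a, b2)


def _tuple_clades(t, out: list[frozenset]) -> frozenset:
    if not isinstance(t, tuple):
        return frozenset([t])
    a = _tuple_clades(t[0], out)
    b = _tuple_clades(t[1], out)
    s = a | b
    out.append(s)
    return s


def _tuple_to_newick(t) -> str:
    if not isinstance(t, tuple):
        return t
    parts = sorted(_tuple_to_newick(x) for x in t)
    return "(" + ",".join(parts) + ")"


def enumerate_unrooted_topologies(taxa: Sequence[str]):
    """Yield (clade sets, newick) for every unrooted topology on the taxa.

    An unrooted binary tree on n taxa corresponds to a rooted one on n-1
    taxa with the remaining taxon attached at the root, giving (2n-5)!!
    topologies.
    """
    taxa = sorted(taxa)
    first, rest = taxa[0], taxa[1:]
    for t in _rooted_topologies(rest):
        clades: list[frozenset] = []
        _tuple_clades(t, clades)
        newick = "(" + first + "," + _tuple_to_newick(t)[1:-1] + ");"
        yield clades, newick


def species_tree_quartet(
    gene_trees: GeneTreeSet,
    mode: str = "auto",
    taxa: Optional[Sequence[str]] = None,
) -> tuple[PhyloTree, float]:
    """Species tree maximizing the summed dominant-quartet count.

    ``mode``: "exhaustive" (n <= 8; brute force over all unrooted
    topologies), "distance" (average internode distances + NJ), or "auto".
    Taxa present in fewer than two gene trees are excluded with a warning.
    Returns (tree, quartet score); for the distance mode the score is
    computed a posteriori for the NJ topology. Ties are broken toward the
    lexicographically smallest newick.
    """
    if len(gene_trees) < 2:
        raise ValueError("need at least two gene trees")
    counts = Counter()
    for gt in gene_trees:
        counts.update(set(gt.leaf_labels))
    if taxa is None:
        taxa = sorted(l for l in counts if counts[l] >= 2)
    rare = [l for l in counts if counts[l] < 2]
    if rare:
        warnings.warn(f"taxa present in <2 gene trees excluded: {sorted(rare)}")
        taxa = [t for t in taxa if t not in rare]
    if len(taxa) < 4:
        raise ValueError("need at least 4 usable taxa")
    if mode == "auto":
        mode = "exhaustive" if len(taxa) <= 8 else "distance"
    if mode == "exhaustive":
        if len(taxa) > 8:
            raise ValueError("exhaustive mode limited to 8 taxa")
        tallies = quartet_tallies(gene_trees, taxa)
        best = None
        for clades, newick in enumerate_unrooted_topologies(taxa):
            score = 0
            for q, tally in tallies.items():
                res = quartet_resolution(clades, sorted(q))
                if res is not None:
                    score += tally[res]
            key = (-score, newick)
            if best is None or key < best[0]:
                best = (key, newick, score)
        tree = read_newick_string(best[1], rooted=False)[0]
        return tree, float(best[2])
    if mode == "distance":
        dm, names = average_internode_distances(gene_trees, taxa)
        tree = nj_tree(dm, names)
        tallies = quartet_tallies(gene_trees, taxa)
        clades, _ = _clade_leafsets(tree)
        score = 0
        for q, tally in tallies.items():
            res = quartet_resolution(clades, sorted(q))
            if res is not None:
                score += tally[res]
        return tree, float(score)
    raise ValueError(f"unknown mode {mode!r}")


def average_internode_distances(
    gene_trees: GeneTreeSet, taxa: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, list[str]]:
    """Mean topological (edge-count) leaf-pair distances across gene trees.

    Pairs are averaged over the trees containing both taxa; a pair that
    never co-occurs raises an error naming the pair.
    """
    if taxa is None:
        taxa = sorted(gene_trees.taxon_labels)
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for gt in gene_trees:
        t = gt.dendropy_tree
        # depth (edge count from root) of each leaf; pair distance via mrca
        for nd in t.preorder_node_iter():
            nd._depth = 0 if nd.parent_node is None else nd.parent_node._depth + 1
        leaf_info: dict[int, list[tuple[int, int]]] = {}
        for nd in t.postorder_node_iter():
            if nd.is_leaf():
                if nd.taxon.label in idx:
                    nd._leaves = [(idx[nd.taxon.label], nd._depth)]
                else:
                    nd._leaves = []
            else:
                kids = [c._leaves for c in nd.child_nodes()]
                # a bifurcating root is not a node of the unrooted tree
                root_adj = int(
                    nd is t.seed_node and len(nd.child_nodes()) == 2
                )
                for (la, lb) in itertools.combinations(range(len(kids)), 2):
                    for i, di in kids[la]:
                        for j, dj in kids[lb]:
                            d = di + dj - 2 * nd._depth - root_adj
                            total[i, j] += d
                            total[j, i] += d
                            count[i, j] += 1
                            count[j, i] += 1
                nd._leaves = [x for k in kids for x in k]
    missing = np.argwhere((count == 0) & ~np.eye(n, dtype=bool))
    if len(missing):
        i, j = missing[0]
        raise ValueError(
            f"taxa {taxa[i]!r} and {taxa[j]!r} never co-occur in a gene tree"
        )
    with np.errstate(invalid="ignore"):
        avg = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    np.fill_diagonal(avg, 0.0)
    return avg, list(taxa)


def nj_tree(dm: np.ndarray, names: Sequence[str]) -> PhyloTree:
    """Neighbor joining on a distance matrix; negative lengths clamped to 0."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    sk = nj(DistanceMatrix(dm, ids=list(names)))
    for node in sk.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    newick = str(sk).strip()
    return read_newick_string(newick, rooted=False)[0]


def _pdistance_matrix_from_alignment(
    alignment: dict[str, str]
) -> tuple[np.ndarray, list[str]]:
    from .paralog_screen import _MISSING

    names = sorted(alignment)
    arrs = {
        n: np.frombuffer(alignment[n].upper().encode(), dtype="S1") for n in names
    }
    ok = {
        n: ~np.isin(arrs[n], np.array(sorted(_MISSING), dtype="S1")) for n in names
    }
    n = len(names)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = names[i], names[j]
        both = ok[a] & ok[b]
        m = both.sum()
        if m == 0:
            raise ValueError(f"no overlapping sites between {a!r} and {b!r}")
        d = float((arrs[a][both] != arrs[b][both]).mean())
        dm[i, j] = dm[j, i] = d
    return dm, names


def _pdistance_matrix_from_snps(matrix: SnpMatrix) -> tuple[np.ndarray, list[str]]:
    names = list(matrix.samples)
    g = matrix.geno
    n = len(names)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = ~np.isnan(g[i]) & ~np.isnan(g[j])
        m = both.sum()
        if m == 0:
            raise ValueError(
                f"no overlapping sites between {names[i]!r} and {names[j]!r}"
            )
        dm[i, j] = dm[j, i] = float(np.abs(g[i, both] - g[j, both]).mean())
    return dm, names


def distance_tree(data: Union[dict, SnpMatrix]) -> PhyloTree:
    """Neighbor-joining tree from missing-aware p-distances.

    ``data`` is either an aligned sample->sequence mapping or a
    :class:`SnpMatrix` (dosage differences averaged over co-called sites).
    """
    if isinstance(data, SnpMatrix):
        dm, names = _pdistance_matrix_from_snps(data)
    else:
        dm, names = _pdistance_matrix_from_alignment(data)
    if len(names) < 4:
        raise ValueError("need at least 4 samples")
    return nj_tree(dm, names)
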