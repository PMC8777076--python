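"""Tree data model, newick I/O, bipartitions, support collapsing, taxon maps.

Trees are stored as thin wrappers around :class:`dendropy.Tree`. Internal node
support values are kept on a 0-100 (percent) scale: values parsed from newick
are auto-rescaled from the 0-1 scale when every support in a tree is <= 1.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "GeneTreeSet",
    "TaxonMap",
    "Bipartition",
    "read_newick",
    "read_newick_string",
    "write_newick",
    "collapse_low_support",
    "extract_bipartitions",
    "bipartitions_compatible",
    "restrict_bipartition",
    "root_on_outgroup",
]

_SUPPORT_COMMENT = re.compile(r"&?support\s*=\s*([0-9.eE+\-]+)")


class PhyloTree:
    """A rooted or unrooted phylogeny with optional internal-node supports.

    Parameters
    ----------
    tree:
        The underlying dendropy tree. Leaf labels must be unique. Internal
        node ``support`` attributes (floats on a 0-100 scale) are stored on
        ``node.support`` (``None`` when missing).
    rooted:
        Whether the tree should be treated as rooted.
    """

    def __init__(self, tree: dendropy.Tree, rooted: bool = True):
        self._tree = tree
        self.rooted = rooted
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            seen, dup = set(), None
            for lb in labels:
                if lb in seen:
                    dup = lb
                    break
                seen.add(lb)
            raise ValueError(f"duplicate leaf label: {dup!r}")
        for nd in tree.preorder_node_iter():
            if not hasattr(nd, "support"):
                nd.support = None

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def internal_supports(self) -> list[Optional[float]]:
        """Supports of internal non-root nodes, preorder."""
        out = []
        for nd in self._tree.preorder_internal_node_iter():
            if nd is self._tree.seed_node:
                continue
            out.append(nd.support)
        return out

    def copy(self) -> "PhyloTree":
        t2 = self._tree.clone(depth=1)
        for src, dst in zip(
            self._tree.preorder_node_iter(), t2.preorder_node_iter()
        ):
            dst.support = getattr(src, "support", None)
        return PhyloTree(t2, rooted=self.rooted)

    def newick(self, include_supports: bool = True, precision: int = 6) -> str:
        t = self._tree
        for nd in t.preorder_internal_node_iter():
            if include_supports and nd.support is not None:
                nd.label = _fmt_number(nd.support)
            else:
                nd.label = None
        s = t.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=False,
            real_value_format_specifier=f".{precision}f",
        ).strip()
        return s

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Restriction of the tree to a subset of leaves.

        Unifurcations left by the pruning are suppressed (edge lengths
        summed); supports of surviving internal nodes are kept. Built on a
        fresh taxon namespace so the source tree is untouched.
        """
        keep = set(labels)
        ns = dendropy.TaxonNamespace()

        def build(nd):
            if nd.is_leaf():
                if nd.taxon.label not in keep:
                    return None
                new = dendropy.Node()
                new.taxon = ns.require_taxon(label=nd.taxon.label)
                new.edge.length = nd.edge.length
                new.support = None
                return new
            kids = [build(c) for c in nd.child_nodes()]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                k = kids[0]
                if nd.edge.length is not None:
                    k.edge.length = (k.edge.length or 0.0) + nd.edge.length
                return k
            new = dendropy.Node()
            new.support = getattr(nd, "support", None)
            new.edge.length = nd.edge.length
            for k in kids:
                new.add_child(k)
            return new

        root = build(self._tree.seed_node)
        if root is None:
            raise ValueError("pruning retained no leaves")
        t = dendropy.Tree(taxon_namespace=ns)
        t.seed_node = root
        t.is_rooted = self.rooted
        return PhyloTree(t, rooted=self.rooted)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_leaves={self.n_leaves} rooted={self.rooted}>"


class GeneTreeSet:
    """A collection of trees sharing a taxon namespace."""

    def __init__(self, trees: Sequence[PhyloTree]):
        self.trees = list(trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    @property
    def taxon_labels(self) -> set[str]:
        out: set[str] = set()
        for t in self.trees:
            out.update(t.leaf_labels)
        return out


@dataclass
class TaxonMap:
    """sample -> species -> clade assignment plus outgroup flags."""

    species: dict[str, str] = field(default_factory=dict)
    clade: dict[str, str] = field(default_factory=dict)
    outgroup: set[str] = field(default_factory=set)

    @property
    def samples(self) -> list[str]:
        return list(self.species)

    def ingroup_samples(self) -> list[str]:
        return [s for s in self.species if s not in self.outgroup]

    def clade_of(self, sample: str) -> str:
        return self.clade[sample]

    def clades(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, c in self.clade.items():
            out.setdefault(c, []).append(s)
        return out

    @classmethod
    def read_tsv(cls, path) -> "TaxonMap":
        tm = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for col in ("sample", "species", "clade", "is_outgroup"):
                if col not in idx:
                    raise ValueError(f"taxon map missing column {col!r}")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                s = parts[idx["sample"]]
                tm.species[s] = parts[idx["species"]]
                tm.clade[s] = parts[idx["clade"]]
                if parts[idx["is_outgroup"]].strip().lower() in ("1", "true", "yes"):
                    tm.outgroup.add(s)
        return tm

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tspecies\tclade\tis_outgroup\n")
            for s in self.species:
                og = "1" if s in self.outgroup else "0"
                fh.write(f"{s}\t{self.species[s]}\t{self.clade[s]}\t{og}\n")

    def validate_against(self, tree: PhyloTree) -> None:
        missing = [lb for lb in tree.leaf_labels if lb not in self.species]
        if missing:
            raise ValueError(f"tree leaves absent from taxon map: {missing}")


@dataclass(frozen=True)
class Bipartition:
    """A nontrivial split of a taxon set, canonically oriented.

    ``side`` is the half that does *not* contain the reference taxon (the
    lexicographically smallest label in ``taxa``).
    """

    side: frozenset
    taxa: frozenset

    @classmethod
    def from_side(cls, side: Iterable[str], taxa: Iterable[str]) -> "Bipartition":
        taxa = frozenset(taxa)
        side = frozenset(side)
        ref = min(taxa)
        if ref in side:
            side = taxa - side
        return cls(side=side, taxa=taxa)

    @property
    def other_side(self) -> frozenset:
        return self.taxa - self.side


def _fmt_number(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _node_support_from_label_or_comment(nd) -> Optional[float]:
    # internal node label wins over a [&support=x] comment
    if nd.label is not None:
        try:
            return float(nd.label)
        except ValueError:
            pass
    for c in getattr(nd, "comments", []) or []:
        m = _SUPPORT_COMMENT.search(c)
        if m:
            return float(m.group(1))
    return None


def _finalize_supports(dtree: dendropy.Tree) -> None:
    supports = []
    for nd in dtree.preorder_internal_node_iter():
        if nd is dtree.seed_node:
            nd.support = None
            nd.label = None
            continue
        nd.support = _node_support_from_label_or_comment(nd)
        nd.label = None
        if nd.support is not None:
            supports.append(nd.support)
    for lf in dtree.leaf_node_iter():
        lf.support = None
    # 0-1 scale -> percent
    if supports and max(supports) <= 1.0:
        for nd in dtree.preorder_internal_node_iter():
            if nd.support is not None:
                nd.support *= 100.0


def read_newick_string(text: str, rooted: bool = True) -> GeneTreeSet:
    """Parse one or more newick strings into a :class:`GeneTreeSet`."""
    ns = dendropy.TaxonNamespace()
    try:
        tl = dendropy.TreeList.get(
            data=text,
            schema="newick",
            taxon_namespace=ns,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as e:  # dendropy raises several error types
        raise ValueError(f"newick parse error: {e}") from e
    trees = []
    for dt in tl:
        _finalize_supports(dt)
        trees.append(PhyloTree(dt, rooted=rooted))
    if not trees:
        raise ValueError("no trees found in input")
    return GeneTreeSet(trees)


def read_newick(path, rooted: bool = True) -> GeneTreeSet:
    """Read a single- or multi-tree newick file."""
    with open(path) as fh:
        text = fh.read()
    try:
        return read_newick_string(text, rooted=rooted)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_newick(trees: GeneTreeSet | PhyloTree, path, precision: int = 6) -> None:
    if isinstance(trees, PhyloTree):
        trees = GeneTreeSet([trees])
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.newick(precision=precision) + "\n")


def collapse_low_support(
    tree: PhyloTree, threshold: float, collapse_missing: bool = False
) -> PhyloTree:
    """Contract internal edges whose child node support falls below *threshold*.

    Support values are percentages in [0, 100]. Nodes with missing support
    are kept unless ``collapse_missing`` is set (simulated true trees carry
    no supports and must survive untouched).
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0, 100]")
    out = tree.copy()
    t = out.dendropy_tree
    to_collapse = []
    for nd in t.preorder_internal_node_iter():
        if nd is t.seed_node:
            continue
        s = nd.support
        if s is None:
            if collapse_missing:
                to_collapse.append(nd)
        elif s < threshold:
            to_collapse.append(nd)
    for nd in to_collapse:
        nd.edge.collapse()
    return PhyloTree(t, rooted=tree.rooted)


def _clade_sets(tree: PhyloTree) -> list[frozenset]:
    """Leaf-label set under each internal non-root node."""
    t = tree.dendropy_tree
    out = []
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd._leafset = frozenset([nd.taxon.label])
        else:
            s = frozenset().union(*(c._leafset for c in nd.child_nodes()))
            nd._leafset = s
            if nd is not t.seed_node:
                out.append(s)
    return out


def extract_bipartitions(tree: PhyloTree) -> set[Bipartition]:
    """Nontrivial bipartitions, one per internal edge (root edge deduped)."""
    taxa = frozenset(tree.leaf_labels)
    if len(taxa) < 4:
        return set()
    out: set[Bipartition] = set()
    for side in _clade_sets(tree):
        if 2 <= len(side) <= len(taxa) - 2:
            out.add(Bipartition.from_side(side, taxa))
    return out


def bipartitions_compatible(a: Bipartition, b: Bipartition) -> bool:
    """Two splits on the same taxon set are compatible iff one of the four
    pairwise intersections of their sides is empty."""
    if a.taxa != b.taxa:
        raise ValueError("bipartitions are on different taxon sets")
    a1, a2 = a.side, a.other_side
    b1, b2 = b.side, b.other_side
    return (
        not (a1 & b1) or not (a1 & b2) or not (a2 & b1) or not (a2 & b2)
    )


def restrict_bipartition(bp: Bipartition, taxa: Iterable[str]) -> Optional[Bipartition]:
    """Restrict a split to a taxon subset; None when it becomes trivial."""
    taxa = frozenset(taxa) & bp.taxa
    s1 = bp.side & taxa
    s2 = taxa - s1
    if len(s1) < 2 or len(s2) < 2:
        return None
    return Bipartition.from_side(s1, taxa)


def root_on_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root the tree on the given outgroup samples (mrca when several)."""
    og = [lb for lb in outgroup if lb in set(tree.leaf_labels)]
    if not og:
        raise ValueError("no outgroup samples present in tree")
    out = tree.copy()
    t = out.dendropy_tree
    t.is_rooted = True
    if len(og) == 1:
        node = next(
            lf for lf in t.leaf_node_iter() if lf.taxon.label == og[0]
        )
    else:
        node = t.mrca(taxon_labels=og)
        if node is t.seed_node:
            # outgroup spans the root: fall back to the first outgroup leaf
            node = next(
                lf for lf in t.leaf_node_iter() if lf.taxon.label == og[0]
            )
    if node.parent_node is t.seed_node and len(t.seed_node.child_nodes()) == 2:
        # already rooted on the outgroup split
        return PhyloTree(t, rooted=True)
    length = node.edge.length
    t.reroot_at_edge(
        node.edge,
        length1=(length / 2.0 if length is not None else None),
        length2=(length / 2.0 if length is not None else None),
        update_bipartitions=False,
    )
    return PhyloTree(t, rooted=True)
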