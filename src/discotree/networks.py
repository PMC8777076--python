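"""Phylogenetic networks: extended-newick I/O, rooted-triple probabilities
under the multispecies coalescent, pseudo-likelihood scoring of candidate
networks against gene trees, gamma estimation, and AIC model selection.

A :class:`SpeciesNetwork` is a rooted DAG whose branch lengths are in
coalescent units. Reticulation nodes have in-degree 2; the two incoming
edges carry inheritance probabilities gamma and 1-gamma. Only level-1
networks (disjoint reticulation cycles) are intended; the triple-probability
machinery sums over displayed trees, weighting each by the product of the
gamma values of the reticulation edges it retains.

For a rooted 3-taxon species tree whose internal branch has length T
coalescent units, the probability that a gene tree matches the species
topology is 1 - (2/3)e^(-T) and each alternative has probability
(1/3)e^(-T).
"""
from __future__ import annotations

import itertools
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .treeio import GeneTreeSet, collapse_low_support

__all__ = [
    "NetNode",
    "NetEdge",
    "SpeciesNetwork",
    "read_enewick",
    "NetworkModelScore",
    "triple_probs",
    "triple_topology_counts",
    "pseudo_likelihood",
    "fit_gamma",
    "select_model",
]


class NetNode:
    __slots__ = ("name", "parents", "children", "hybrid_tag")

    def __init__(self, name: Optional[str] = None, hybrid_tag: Optional[str] = None):
        self.name = name
        self.hybrid_tag = hybrid_tag
        self.parents: list["NetEdge"] = []
        self.children: list["NetEdge"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_reticulation(self) -> bool:
        return len(self.parents) == 2

    def __repr__(self) -> str:  # pragma: no cover
        return f"<NetNode {self.name or self.hybrid_tag or id(self)}>"


class NetEdge:
    __slots__ = ("parent", "child", "length", "gamma")

    def __init__(self, parent: NetNode, child: NetNode, length=None, gamma=None):
        self.parent = parent
        self.child = child
        self.length = length
        self.gamma = gamma


class SpeciesNetwork:
    """Rooted species tree or level-1 network with coalescent-unit lengths."""

    def __init__(self, root: NetNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        for nd in self.nodes():
            if len(nd.parents) > 2:
                raise ValueError("node with in-degree > 2")
            if nd.is_reticulation:
                gs = [e.gamma for e in nd.parents]
                if any(g is None for g in gs):
                    # default to an even split when unannotated
                    for e in nd.parents:
                        e.gamma = 0.5
                else:
                    tot = sum(gs)
                    if not math.isclose(tot, 1.0, abs_tol=1e-6):
                        raise ValueError(
                            f"reticulation gammas sum to {tot}, expected 1"
                        )
        labels = [nd.name for nd in self.leaves()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in network")

    def nodes(self) -> list[NetNode]:
        seen: list[NetNode] = []
        seen_ids = set()
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if id(nd) in seen_ids:
                continue
            seen_ids.add(id(nd))
            seen.append(nd)
            for e in nd.children:
                stack.append(e.child)
        return seen

    def edges(self) -> list[NetEdge]:
        out, seen = [], set()
        for nd in self.nodes():
            for e in nd.children:
                if id(e) not in seen:
                    seen.add(id(e))
                    out.append(e)
        return out

    def leaves(self) -> list[NetNode]:
        return [nd for nd in self.nodes() if nd.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(nd.name for nd in self.leaves())

    def reticulations(self) -> list[NetNode]:
        return [nd for nd in self.nodes() if nd.is_reticulation]

    @property
    def n_reticulations(self) -> int:
        return len(self.reticulations())

    def gammas(self) -> list[float]:
        """One gamma per reticulation (the first parent edge's value)."""
        return [r.parents[0].gamma for r in self.reticulations()]

    def set_gammas(self, values: Sequence[float]) -> None:
        rets = self.reticulations()
        if len(values) != len(rets):
            raise ValueError("gamma count does not match reticulation count")
        for r, g in zip(rets, values):
            if not 0 <= g <= 1:
                raise ValueError("gamma must be in [0, 1]")
            r.parents[0].gamma = g
            r.parents[1].gamma = 1.0 - g

    def internal_tree_edges(self) -> list[NetEdge]:
        """Internal non-reticulation edges (candidates for length fitting)."""
        return [
            e
            for e in self.edges()
            if not e.child.is_leaf and not e.child.is_reticulation
        ]

    # -- displayed trees ---------------------------------------------------

    def displayed_trees(self) -> list[tuple[float, dict]]:
        """All displayed trees with their gamma weights.

        Each displayed tree is returned as ``(weight, clades)`` where
        ``clades`` maps each retained node id to ``(leafset, depth)`` --
        enough structure for induced-triple calculations. Use
        :func:`_displayed_structures` internally.
        """
        return _displayed_structures(self)

    def node_ages(self) -> dict[int, float]:
        """Age of each node above the leaves (leaves at 0), from lengths."""
        ages: dict[int, float] = {}

        def age(nd: NetNode) -> float:
            if id(nd) in ages:
                return ages[id(nd)]
            if nd.is_leaf:
                a = 0.0
            else:
                a = max(
                    age(e.child) + (e.length if e.length is not None else 0.0)
                    for e in nd.children
                )
            ages[id(nd)] = a
            return a

        age(self.root)
        return ages

    def copy(self) -> "SpeciesNetwork":
        mapping: dict[int, NetNode] = {}

        def clone(nd: NetNode) -> NetNode:
            if id(nd) in mapping:
                return mapping[id(nd)]
            c = NetNode(nd.name, nd.hybrid_tag)
            mapping[id(nd)] = c
            for e in nd.children:
                cc = clone(e.child)
                ne = NetEdge(c, cc, e.length, e.gamma)
                c.children.append(ne)
                cc.parents.append(ne)
            return c

        return SpeciesNetwork(clone(self.root))

    # -- serialization -----------------------------------------------------

    def to_enewick(self) -> str:
        emitted: set[int] = set()
        tags: dict[int, str] = {}
        for i, r in enumerate(self.reticulations(), start=1):
            tags[id(r)] = r.hybrid_tag or f"H{i}"

        def walk(nd: NetNode, edge: Optional[NetEdge]) -> str:
            if nd.is_reticulation:
                tag = tags[id(nd)]
                if id(nd) not in emitted:
                    emitted.add(id(nd))
                    core = subtree(nd) + "#" + tag
                else:
                    core = "#" + tag
                ln = "" if edge.length is None else f"{edge.length:g}"
                if edge.gamma is not None:
                    return f"{core}:{ln}::{edge.gamma:g}"
                return f"{core}:{ln}" if ln else core
            core = subtree(nd)
            if edge is not None and edge.length is not None:
                core += f":{edge.length:g}"
            return core

        def subtree(nd: NetNode) -> str:
            if nd.is_leaf:
                return nd.name
            return "(" + ",".join(walk(e.child, e) for e in nd.children) + ")"

        return subtree(self.root) + ";"


def _displayed_structures(net: SpeciesNetwork):
    """Displayed trees as (gamma weight, {node id: (leafset, age)})."""
    rets = net.reticulations()
    ages = net.node_ages()
    out = []
    for choice in itertools.product([0, 1], repeat=len(rets)):
        weight = 1.0
        removed_edges = set()
        for r, c in zip(rets, choice):
            keep = r.parents[c]
            drop = r.parents[1 - c]
            weight *= keep.gamma if keep.gamma is not None else 0.5
            removed_edges.add(id(drop))
        if weight == 0.0:
            continue
        leafsets: dict[int, frozenset] = {}

        def leafset(nd: NetNode) -> frozenset:
            key = id(nd)
            if key in leafsets:
                return leafsets[key]
            if nd.is_leaf:
                s = frozenset([nd.name])
            else:
                parts = [
                    leafset(e.child)
                    for e in nd.children
                    if id(e) not in removed_edges
                ]
                s = frozenset().union(*parts) if parts else frozenset()
            leafsets[key] = s
            return s

        leafset(net.root)
        clades = {
            id(nd): (leafsets[id(nd)], ages[id(nd)])
            for nd in net.nodes()
            if leafsets.get(id(nd))
        }
        out.append((weight, clades))
    return out


# ---------------------------------------------------------------------------
# extended newick parsing


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;]+")


def read_enewick(text: str) -> SpeciesNetwork:
    """Parse an extended newick string with ``#H`` reticulation labels.

    Branch annotations follow the ``name:length:support:gamma`` convention,
    e.g. ``(A:1,(B:1)#H1:0.5::0.3)`` — the third colon field carries the
    inheritance probability of that reticulation edge. A ``[&gamma=x]``
    comment on the edge is also accepted.
    """
    text = text.strip()
    if text.endswith(";"):
        text = text[:-1]
    hybrids: dict[str, NetNode] = {}
    pos = [0]
    s = text

    def parse_subtree() -> tuple[NetNode, dict]:
        if pos[0] < len(s) and s[pos[0]] == "(":
            pos[0] += 1
            node = NetNode()
            while True:
                child, info = parse_subtree()
                child, edge_attrs = _resolve_hybrid(child, info, hybrids)
                e = NetEdge(node, child, **edge_attrs)
                node.children.append(e)
                child.parents.append(e)
                if pos[0] >= len(s):
                    raise ValueError("unbalanced parentheses in extended newick")
                ch = s[pos[0]]
                if ch == ",":
                    pos[0] += 1
                    continue
                if ch == ")":
                    pos[0] += 1
                    break
                raise ValueError(f"unexpected character {ch!r} at {pos[0]}")
            info = parse_label_and_edge()
            _apply_node_info(node, info)
            return node, info
        info = parse_label_and_edge()
        node = NetNode()
        _apply_node_info(node, info)
        return node, info

    def parse_label_and_edge() -> dict:
        m = re.match(r"[^(),;]*", s[pos[0]:])
        chunk = m.group(0)
        pos[0] += len(chunk)
        info: dict = {"label": None, "hybrid": None, "length": None, "gamma": None}
        if not chunk:
            return info
        gm = re.search(r"\[&?gamma\s*=\s*([0-9.eE+\-]+)\]", chunk)
        if gm:
            info["gamma"] = float(gm.group(1))
            chunk = chunk[: gm.start()] + chunk[gm.end():]
        name_part, _, rest = chunk.partition(":")
        if "#" in name_part:
            pre, _, tag = name_part.partition("#")
            info["label"] = pre or None
            info["hybrid"] = tag
        else:
            info["label"] = name_part or None
        if rest:
            fields = rest.split(":")
            if fields[0]:
                info["length"] = float(fields[0])
            if len(fields) >= 3 and fields[2]:
                info["gamma"] = float(fields[2])
        return info

    def _apply_node_info(node: NetNode, info: dict) -> None:
        if info["label"]:
            node.name = info["label"]
        if info["hybrid"]:
            node.hybrid_tag = info["hybrid"]

    root, _ = parse_subtree()
    if pos[0] != len(s):
        raise ValueError("trailing characters after newick (unbalanced parentheses?)")
    return SpeciesNetwork(root)


def _resolve_hybrid(node: NetNode, info: dict, hybrids: dict) -> tuple[NetNode, dict]:
    edge_attrs = {"length": info["length"], "gamma": info["gamma"]}
    tag = info["hybrid"]
    if tag is None:
        return node, edge_attrs
    if tag in hybrids:
        canonical = hybrids[tag]
        # merge: if this occurrence carries a subtree, graft it
        if node.children:
            if canonical.children:
                raise ValueError(f"hybrid #{tag} has a subtree at two positions")
            canonical.children = node.children
            for e in canonical.children:
                e.parent = canonical
        if node.name and not canonical.name:
            canonical.name = node.name
        return canonical, edge_attrs
    node.hybrid_tag = tag
    hybrids[tag] = node
    return node, edge_attrs


# ---------------------------------------------------------------------------
# rooted-triple probabilities


def _msc_triple_probs_from_clades(clades, triple) -> dict[frozenset, float]:
    """Triple topology probabilities induced by one displayed tree.

    ``clades`` maps node id -> (leafset, age). The pair whose mrca is
    lowest is the concordant pair; T is the age gap between the two mrcas.
    """
    a, b, c = triple

    def mrca_age(subset: frozenset) -> float:
        best = None
        for leafset, age in clades.values():
            if subset <= leafset:
                if best is None or age < best:
                    best = age
        if best is None:
            raise ValueError(f"taxa {set(subset)} not all present in network")
        return best

    age_abc = mrca_age(frozenset((a, b, c)))
    pairs = [frozenset((a, b)), frozenset((a, c)), frozenset((b, c))]
    pair_ages = {p: mrca_age(p) for p in pairs}
    concordant = min(pairs, key=lambda p: (pair_ages[p], sorted(p)))
    t_internal = age_abc - pair_ages[concordant]
    if t_internal < -1e-9:
        raise ValueError("negative internal time in displayed tree")
    p_alt = (1.0 / 3.0) * math.exp(-max(t_internal, 0.0))
    probs = {p: p_alt for p in pairs}
    probs[concordant] = 1.0 - 2.0 * p_alt
    return probs


def triple_probs(
    network: SpeciesNetwork, triple: Sequence[str]
) -> dict[frozenset, float]:
    """Probabilities of the three rooted triple topologies under the MSC.

    Sums over displayed trees: P(topology) = sum_d w_d * P_MSC(topology | d)
    with w_d the product of inheritance probabilities of the reticulation
    edges retained in displayed tree d. Keys are the coalescing pairs
    (``frozenset({x, y})`` means topology ((x,y),z)).

    Raises if any edge on the relevant paths lacks a branch length.
    """
    if len(set(triple)) != 3:
        raise ValueError("triple must contain three distinct taxa")
    for e in network.edges():
        if e.length is None and not e.child.is_leaf:
            raise ValueError("network has missing internal branch lengths")
    probs = _triple_probs_from_structures(
        _displayed_structures(network), sorted(triple)
    )
    if probs is None:
        raise ValueError("no displayed tree contains the requested triple")
    return probs


def _triple_probs_from_structures(structures, triple):
    a, b, c = triple
    total = {frozenset((a, b)): 0.0, frozenset((a, c)): 0.0, frozenset((b, c)): 0.0}
    weight_sum = 0.0
    for weight, clades in structures:
        # a displayed tree may not contain the triple if pruning dropped a leaf
        try:
            probs = _msc_triple_probs_from_clades(clades, (a, b, c))
        except ValueError:
            continue
        for k, v in probs.items():
            total[k] += weight * v
        weight_sum += weight
    if weight_sum <= 0:
        return None
    if abs(weight_sum - 1.0) > 1e-9:
        for k in total:
            total[k] /= weight_sum
    return total


# ---------------------------------------------------------------------------
# pseudo-likelihood over rooted triples


def _resolved_triple(clade_sets: Iterable[frozenset], triple: tuple) -> Optional[frozenset]:
    """The coalescing pair of *triple* in a rooted tree's clade sets, or None."""
    tset = set(triple)
    for cs in clade_sets:
        inter = cs & tset
        if len(inter) == 2:
            return frozenset(inter)
    return None


def triple_topology_counts(
    gene_trees: GeneTreeSet,
    clade_map: Optional[dict[str, str]] = None,
    support_threshold: Optional[float] = None,
) -> dict[frozenset, Counter]:
    """Tally observed rooted-triple topologies across gene trees.

    ``clade_map`` maps sample labels to clade (network leaf) names; each
    clade is represented in each gene tree by its first mapped sample
    present. Returns {triple (frozenset of 3 names): Counter over coalescing
    pairs}; unresolved triples (polytomies after support collapsing) are not
    counted.
    """
    counts: dict[frozenset, Counter] = {}
    for gt in gene_trees:
        t = gt
        if support_threshold is not None:
            t = collapse_low_support(t, support_threshold)
        leaf_labels = t.leaf_labels
        if clade_map is not None:
            rep: dict[str, str] = {}
            for lb in leaf_labels:
                cl = clade_map.get(lb)
                if cl is not None and cl not in rep:
                    rep[cl] = lb
            name_of = {v: k for k, v in rep.items()}
            keep = set(rep.values())
            if len(keep) < 3:
                continue
            t = t.prune_to(keep)
        else:
            name_of = {lb: lb for lb in leaf_labels}
        dt = t.dendropy_tree
        clade_sets = []
        for nd in dt.postorder_node_iter():
            if nd.is_leaf():
                nd._ls = frozenset([name_of[nd.taxon.label]])
            else:
                nd._ls = frozenset().union(*(c._ls for c in nd.child_nodes()))
                if nd is not dt.seed_node:
                    clade_sets.append(nd._ls)
        names = sorted(dt.seed_node._ls)
        for triple in itertools.combinations(names, 3):
            pair = _resolved_triple(clade_sets, triple)
            if pair is None:
                continue
            key = frozenset(triple)
            counts.setdefault(key, Counter())[pair] += 1
    return counts


_LOG_FLOOR = 1e-12


def pseudo_likelihood(
    network: SpeciesNetwork,
    gene_trees: GeneTreeSet | dict,
    clade_map: Optional[dict[str, str]] = None,
    support_threshold: Optional[float] = None,
) -> float:
    """Log pseudo-likelihood of the network given gene-tree rooted triples.

    lnL = sum over taxa triples, sum over gene trees, of
    log P(observed triple topology | network). Triples never resolved in any
    gene tree contribute nothing. ``gene_trees`` may be a pre-computed tally
    from :func:`triple_topology_counts`.
    """
    if isinstance(gene_trees, dict):
        counts = gene_trees
    else:
        counts = triple_topology_counts(
            gene_trees, clade_map=clade_map, support_threshold=support_threshold
        )
    net_taxa = set(network.leaf_labels)
    structures = _displayed_structures(network)
    lnl = 0.0
    for triple, tally in counts.items():
        if not triple <= net_taxa:
            continue
        probs = _triple_probs_from_structures(structures, sorted(triple))
        if probs is None:
            continue
        for pair, n in tally.items():
            lnl += n * math.log(max(probs[pair], _LOG_FLOOR))
    return lnl


# ---------------------------------------------------------------------------
# gamma / branch-length fitting and model selection


def _golden_section(f, lo: float, hi: float, tol: float = 1e-3) -> tuple[float, float]:
    """Maximize a unimodal function on [lo, hi]; returns (x, f(x))."""
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = (a + b) / 2
    return x, f(x)


DEFAULT_LENGTH_GRID = tuple(np.geomspace(0.1, 5.0, 12))


@dataclass
class FitResult:
    gammas: list[float]
    lnl: float
    unidentifiable: bool = False


def fit_gamma(
    network: SpeciesNetwork,
    gene_trees: GeneTreeSet | dict,
    clade_map: Optional[dict[str, str]] = None,
    support_threshold: Optional[float] = None,
    estimate_lengths: bool = False,
    length_grid: Sequence[float] = DEFAULT_LENGTH_GRID,
    tol: float = 1e-3,
    n_sweeps: int = 3,
) -> FitResult:
    """Estimate inheritance probabilities (and optionally internal branch
    lengths) by coordinate-ascent pseudo-likelihood maximization.

    Gammas are optimized by golden-section search on [0, 1]; missing or
    requested internal branch lengths on a log-spaced coalescent-unit grid.
    A flat likelihood surface (range < 1e-6 across the gamma grid) flags the
    gamma estimates as unidentifiable.
    """
    net = network.copy()
    if net.n_reticulations > 3:
        raise ValueError("at most 3 reticulations supported by the fitter")
    if isinstance(gene_trees, dict):
        counts = gene_trees
    else:
        counts = triple_topology_counts(
            gene_trees, clade_map=clade_map, support_threshold=support_threshold
        )

    free_edges = []
    for e in net.internal_tree_edges():
        if e.length is None or estimate_lengths:
            if e.length is None:
                e.length = 1.0
            free_edges.append(e)
    for e in net.edges():
        if e.length is None:
            e.length = 1.0  # pendant / reticulation edges: default

    def lnl_now() -> float:
        return pseudo_likelihood(net, counts)

    rets = net.reticulations()
    flat = False
    for _ in range(max(1, n_sweeps)):
        for e in free_edges:
            best_len, best_val = e.length, None
            for cand in length_grid:
                e.length = float(cand)
                v = lnl_now()
                if best_val is None or v > best_val:
                    best_len, best_val = float(cand), v
            e.length = best_len
        for i, r in enumerate(rets):
            def f(g, _r=r):
                _r.parents[0].gamma = g
                _r.parents[1].gamma = 1.0 - g
                return lnl_now()

            probe = [f(g) for g in (0.0, 0.25, 0.5, 0.75, 1.0)]
            if max(probe) - min(probe) < 1e-6:
                flat = True
            g_hat, _ = _golden_section(f, 0.0, 1.0, tol=tol)
            r.parents[0].gamma = g_hat
            r.parents[1].gamma = 1.0 - g_hat
    return FitResult(gammas=net.gammas(), lnl=lnl_now(), unidentifiable=flat)


@dataclass
class NetworkModelScore:
    network_id: str
    n_reticulations: int
    lnl: float
    k: int
    aic: float
    gammas: list[float] = field(default_factory=list)


def n_base_branches(network: SpeciesNetwork) -> int:
    """Branch count of the base topology (edges of the major displayed tree)."""
    structures = _displayed_structures(network)
    weight, clades = max(structures, key=lambda wc: wc[0])
    # distinct leafsets below the root, after suppressing unifurcations
    all_taxa = frozenset(network.leaf_labels)
    distinct = {ls for ls, _ in clades.values() if ls and ls != all_taxa}
    return len(distinct)


def select_model(
    candidates: Sequence[tuple[str, SpeciesNetwork]] | Sequence[SpeciesNetwork],
    gene_trees: GeneTreeSet | dict,
    clade_map: Optional[dict[str, str]] = None,
    support_threshold: Optional[float] = None,
    n_gene_trees: Optional[int] = None,
    estimate_lengths: bool = False,
) -> list[NetworkModelScore]:
    """Fit each candidate network and rank by AIC (ascending).

    The parameter count is k = (#branches of the base topology) +
    (#reticulations) + (#gene trees); AIC = 2k - 2 lnL. Ties in AIC are
    broken in favor of fewer parameters.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    cands: list[tuple[str, SpeciesNetwork]] = []
    for i, c in enumerate(candidates):
        if isinstance(c, tuple):
            cands.append(c)
        else:
            cands.append((f"net{i}", c))
    if isinstance(gene_trees, dict):
        counts = gene_trees
        if n_gene_trees is None:
            raise ValueError("n_gene_trees required when passing tallies")
        n_trees = n_gene_trees
    else:
        counts = triple_topology_counts(
            gene_trees, clade_map=clade_map, support_threshold=support_threshold
        )
        n_trees = len(gene_trees)
    scores = []
    for name, net in cands:
        fit = fit_gamma(net, counts, estimate_lengths=estimate_lengths)
        r = net.n_reticulations
        k = n_base_branches(net) + r + n_trees
        aic = 2.0 * k - 2.0 * fit.lnl
        scores.append(
            NetworkModelScore(
                network_id=name,
                n_reticulations=r,
                lnl=fit.lnl,
                k=k,
                aic=aic,
                gammas=fit.gammas,
            )
        )
    scores.sort(key=lambda s: (s.aic, s.k))
    return scores


def model_table(scores: Sequence[NetworkModelScore]) -> str:
    """TSV rendering of a model-selection ranking."""
    lines = ["id\tr\tlnL\tk\tAIC\tgammas"]
    for s in scores:
        gam = ",".join(f"{g:.4f}" for g in s.gammas)
        lines.append(
            f"{s.network_id}\t{s.n_reticulations}\t{s.lnl:.4f}\t{s.k}\t{s.aic:.4f}\t{gam}"
        )
    return "\n".join(lines) + "\n"
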