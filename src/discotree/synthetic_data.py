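"""Generators for every input the pipeline consumes.

Gene trees are simulated under the multispecies coalescent (MSC) on a rooted
species tree or level-1 network: within each population (network edge),
lineages coalesce with exponential waiting times at rate k(k-1)/2 per
coalescent unit (time scaled by 2N generations); at a reticulation node each
lineage independently follows a parent edge with probability gamma. SNPs are
dropped on the gene trees under an infinite-sites model (one mutation per
site, placed on a branch with probability proportional to its length), so a
site's derived allele is carried exactly by the leaves the mutated branch
subtends. Sites within a locus share one gene tree, modelling the linkage
that SNP thinning later removes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import dendropy
import numpy as np

from .filtering import SnpMatrix
from .networks import NetNode, SpeciesNetwork, read_enewick
from .treeio import GeneTreeSet, PhyloTree

__all__ = [
    "SimConfig",
    "simulate_gene_trees",
    "simulate_snps",
    "inject_missing",
    "simulate_occupancy",
    "simulate_paralog_divergences",
    "simulate_alignment",
    "simulate_pileup",
]

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic-data generator.

    Branch lengths of ``network`` are in coalescent units; ``mutation_rate``
    is per coalescent-time unit and is used by the Jukes-Cantor alignment
    mode (SNP sites are conditioned on exactly one mutation, so their count
    is set directly by ``n_loci * sites_per_locus``).
    """

    network: Union[str, SpeciesNetwork]
    n_gene_trees: int = 500
    n_loci: int = 100
    sites_per_locus: int = 50
    locus_length_bp: int = 5000
    mutation_rate: float = 0.1
    samples_per_species: Union[int, dict] = 1
    missing_sample_locus_rate: float = 0.0
    missing_site_rate: float = 0.0
    paralog_fraction: float = 0.25
    within_divergence: float = 2.0  # percent
    between_divergence: float = 14.0  # percent
    within_sd: float = 0.5  # percent
    between_sd: float = 2.0  # percent
    seq_length: int = 600
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.network, str):
            self.network = read_enewick(self.network)
        for r in (
            self.missing_sample_locus_rate,
            self.missing_site_rate,
            self.paralog_fraction,
        ):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


class _GNode:
    __slots__ = ("children", "height", "label")

    def __init__(self, children=(), height=0.0, label=None):
        self.children = list(children)
        self.height = height
        self.label = label


def _gnode_to_phylo(root: _GNode, ns: dendropy.TaxonNamespace) -> PhyloTree:
    def conv(g: _GNode) -> dendropy.Node:
        nd = dendropy.Node()
        if not g.children:
            nd.taxon = ns.require_taxon(label=g.label)
        for c in g.children:
            cn = conv(c)
            cn.edge.length = max(g.height - c.height, 0.0)
            nd.add_child(cn)
        return nd

    t = dendropy.Tree(taxon_namespace=ns)
    t.seed_node = conv(root)
    t.is_rooted = True
    return PhyloTree(t, rooted=True)


def _coalesce(
    lineages: list[_GNode], t0: float, t1: float, rng: np.random.Generator
) -> tuple[list[_GNode], float]:
    """Coalesce lineages in (t0, t1]; t1 may be inf. Returns survivors."""
    t = t0
    lin = list(lineages)
    while len(lin) >= 2:
        rate = len(lin) * (len(lin) - 1) / 2.0
        t_next = t + rng.exponential(1.0 / rate)
        if t_next > t1:
            break
        i, j = rng.choice(len(lin), size=2, replace=False)
        a, b = lin[i], lin[j]
        merged = _GNode(children=[a, b], height=t_next)
        lin = [x for k, x in enumerate(lin) if k not in (i, j)]
        lin.append(merged)
        t = t_next
    return lin, t


def _sample_labels(net: SpeciesNetwork, samples_per_species) -> dict[str, list[str]]:
    out = {}
    for leaf in net.leaf_labels:
        if isinstance(samples_per_species, dict):
            k = samples_per_species.get(leaf, 1)
        else:
            k = samples_per_species
        if k == 1:
            out[leaf] = [leaf]
        else:
            out[leaf] = [f"{leaf}_{i + 1}" for i in range(k)]
    return out


def _simulate_one_tree(
    net: SpeciesNetwork,
    ages: dict[int, float],
    order: list[NetNode],
    labels: dict[str, list[str]],
    rng: np.random.Generator,
) -> _GNode:
    pending: dict[int, list[_GNode]] = {}  # edge id -> lineages entering it

    for nd in order:
        t_node = ages[id(nd)]
        if nd.is_leaf:
            survivors = [
                _GNode(height=t_node, label=lb) for lb in labels[nd.name]
            ]
        else:
            survivors = []
            for e in nd.children:
                lin = pending.pop(id(e), [])
                t_child = ages[id(e.child)]
                lin, _ = _coalesce(lin, t_child, t_node, rng)
                survivors.extend(lin)
        if not nd.parents:  # root population
            lin, _ = _coalesce(survivors, t_node, math.inf, rng)
            return lin[0]
        if nd.is_reticulation:
            e0, e1 = nd.parents
            g = e0.gamma if e0.gamma is not None else 0.5
            for x in survivors:
                target = e0 if rng.random() < g else e1
                pending.setdefault(id(target), []).append(x)
        else:
            e = nd.parents[0]
            pending.setdefault(id(e), []).extend(survivors)
    raise RuntimeError("network has no root population")  # pragma: no cover


def _event_order(net: SpeciesNetwork, ages: dict[int, float]) -> list[NetNode]:
    # children strictly before parents; topological depth breaks age ties
    depth: dict[int, int] = {}

    def d(nd: NetNode) -> int:
        if id(nd) in depth:
            return depth[id(nd)]
        v = 0 if nd.is_leaf else 1 + max(d(e.child) for e in nd.children)
        depth[id(nd)] = v
        return v

    d(net.root)
    return sorted(net.nodes(), key=lambda nd: (ages[id(nd)], depth[id(nd)]))


def simulate_gene_trees(
    cfg: Union[SimConfig, SpeciesNetwork, str],
    n: Optional[int] = None,
    seed: Optional[int] = None,
    samples_per_species: Union[int, dict, None] = None,
) -> GeneTreeSet:
    """Simulate rooted gene trees (coalescent-unit branch lengths) under the
    MSC on a species tree or network.

    Accepts a :class:`SimConfig`, or a network (object or extended newick)
    with ``n`` and ``seed`` given explicitly.
    """
    if isinstance(cfg, SimConfig):
        net = cfg.network
        n = n if n is not None else cfg.n_gene_trees
        seed = seed if seed is not None else cfg.seed
        sps = (
            samples_per_species
            if samples_per_species is not None
            else cfg.samples_per_species
        )
    else:
        net = read_enewick(cfg) if isinstance(cfg, str) else cfg
        if n is None or seed is None:
            raise ValueError("n and seed are required without a SimConfig")
        sps = samples_per_species if samples_per_species is not None else 1
    for e in net.edges():
        if e.length is None:
            raise ValueError("network has missing branch lengths")
    rng = np.random.default_rng(seed)
    ages = net.node_ages()
    order = _event_order(net, ages)
    labels = _sample_labels(net, sps)
    ns = dendropy.TaxonNamespace()
    trees = []
    for _ in range(n):
        root = _simulate_one_tree(net, ages, order, labels, rng)
        trees.append(_gnode_to_phylo(root, ns))
    return GeneTreeSet(trees)


# ---------------------------------------------------------------------------
# SNPs


def _tree_branch_clades(tree: PhyloTree) -> tuple[list[frozenset], np.ndarray]:
    """(leafset, length) for every non-root branch of a gene tree."""
    t = tree.dendropy_tree
    clades, lengths = [], []
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd._ls = frozenset([nd.taxon.label])
        else:
            nd._ls = frozenset().union(*(c._ls for c in nd.child_nodes()))
        if nd is not t.seed_node:
            clades.append(nd._ls)
            lengths.append(nd.edge.length or 0.0)
    return clades, np.asarray(lengths, dtype=float)


def simulate_snps(
    gene_trees: GeneTreeSet,
    n_loci: int,
    sites_per_locus: int,
    locus_length_bp: int = 5000,
    seed: int = 0,
    outgroup: Optional[Sequence[str]] = None,
) -> SnpMatrix:
    """Drop one mutation per site on the gene trees (infinite sites).

    Locus i uses gene tree i (cycling); the mutated branch is drawn with
    probability proportional to its length, and the derived allele (dosage 1)
    is carried by the leaves it subtends. The returned matrix is polarized by
    construction (0 = ancestral). When ``outgroup`` is given, sites are
    instead re-polarized by the outgroup-major-allele rule of
    :func:`discotree.filtering.polarize`, which is what a real pipeline sees.
    """
    if n_loci * sites_per_locus == 0:
        import warnings

        warnings.warn("zero sites requested; empty SNP matrix", stacklevel=2)
    rng = np.random.default_rng(seed)
    samples = sorted(gene_trees.taxon_labels)
    sidx = {s: i for i, s in enumerate(samples)}
    cols_locus, cols_pos, cols_geno = [], [], []
    for li in range(n_loci):
        tree = gene_trees[li % len(gene_trees)]
        clades, lengths = _tree_branch_clades(tree)
        probs = lengths / lengths.sum()
        if sites_per_locus > locus_length_bp:
            raise ValueError("sites_per_locus exceeds locus_length_bp")
        positions = np.sort(
            rng.choice(locus_length_bp, size=sites_per_locus, replace=False) + 1
        )
        branch_idx = rng.choice(len(clades), size=sites_per_locus, p=probs)
        present = {lb for lb in tree.leaf_labels}
        for pos, bi in zip(positions, branch_idx):
            derived = clades[bi]
            col = np.zeros(len(samples))
            for s in samples:
                if s not in present:
                    col[sidx[s]] = np.nan
                elif s in derived:
                    col[sidx[s]] = 1.0
            cols_locus.append(f"locus{li:05d}")
            cols_pos.append(int(pos))
            cols_geno.append(col)
    geno = (
        np.array(cols_geno).T if cols_geno else np.zeros((len(samples), 0))
    )
    mat = SnpMatrix(samples, cols_locus, cols_pos, geno, polarized=True)
    if outgroup is not None:
        from .filtering import polarize

        mat.polarized = False
        mat = polarize(mat, outgroup)
    return mat


def inject_missing(
    matrix: SnpMatrix,
    sample_locus_rate: float = 0.0,
    site_rate: float = 0.0,
    seed: int = 0,
) -> SnpMatrix:
    """Structured missingness: per-(sample, locus) dropout, then per-site."""
    for r in (sample_locus_rate, site_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    geno = matrix.geno.copy()
    loci = list(dict.fromkeys(matrix.locus))
    for i in range(matrix.n_samples):
        for loc in loci:
            if rng.random() < sample_locus_rate:
                geno[i, matrix.locus == loc] = np.nan
    if site_rate > 0:
        drop = rng.random(geno.shape) < site_rate
        geno[drop] = np.nan
    return SnpMatrix(
        matrix.samples, matrix.locus, matrix.pos, geno, polarized=matrix.polarized
    )


def simulate_occupancy(
    samples: Sequence[str],
    n_loci: int,
    recovery_rate: Union[float, dict],
    seed: int = 0,
):
    """Bernoulli locus-recovery matrix (fraction recovered is 0 or ~U(0.5,1))."""
    import pandas as pd

    from .filtering import LocusOccupancy

    rng = np.random.default_rng(seed)
    rows = []
    for s in samples:
        r = recovery_rate[s] if isinstance(recovery_rate, dict) else recovery_rate
        recovered = rng.random(n_loci) < r
        frac = np.where(recovered, rng.uniform(0.5, 1.0, n_loci), 0.0)
        rows.append(frac)
    m = pd.DataFrame(
        np.array(rows), index=list(samples), columns=[f"locus{i:04d}" for i in range(n_loci)]
    )
    return LocusOccupancy(matrix=m)


# ---------------------------------------------------------------------------
# paralog divergences


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, to a uniform different base."""
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def _rate_for_pairwise(target: float) -> float:
    """Per-copy substitution rate g so two copies diverge by *target*.

    Pairwise mismatch of two sequences independently mutated at rate g from
    one ancestor is 2g - (4/3)g^2; invert for g.
    """
    target = min(max(target, 0.0), 0.70)
    disc = 4.0 - (16.0 / 3.0) * target
    return (2.0 - math.sqrt(max(disc, 0.0))) / (8.0 / 3.0)


def _class_shift_for_cross(target_cross: float, g: float) -> float:
    """Ancestor-shift rate f so cross-class pairwise divergence hits target.

    With copy rate g on both sides and a class shift f in between,
    D = g + h - (4/3) g h with h = f (1 - (4/3) g) + g; invert for f.
    """
    h = (target_cross - g) / max(1.0 - (4.0 / 3.0) * g, 1e-9)
    f = (h - g) / max(1.0 - (4.0 / 3.0) * g, 1e-9)
    return min(max(f, 0.0), 0.70)


def simulate_paralog_divergences(
    cfg: SimConfig, samples: Optional[Sequence[str]] = None
):
    """Loci with optional duplicated copy classes and a bimodal divergence mix.

    Each locus descends from a random ancestor; duplicated loci carry two
    copy classes whose ancestors differ by (approximately) the configured
    between-class divergence, while copies within a class differ by the
    within-class divergence. Substitution rates are analytically calibrated
    so realized pairwise p-distances match the configured means.

    Returns ``(loci, flags)``: ``loci`` maps locus name to a list of
    ``(sample, copy_label, sequence)``; ``flags`` maps locus name to whether
    it was simulated with a duplication.
    """
    if cfg.paralog_fraction > 0 and cfg.between_divergence <= cfg.within_divergence:
        raise ValueError("between-copy divergence must exceed within-copy")
    rng = cfg.rng()
    if samples is None:
        samples = [f"S{i + 1:02d}" for i in range(8)]
    n_dup = int(round(cfg.n_loci * cfg.paralog_fraction))
    loci: dict[str, list[tuple[str, str, str]]] = {}
    flags: dict[str, bool] = {}
    for li in range(cfg.n_loci):
        name = f"locus{li:04d}"
        duplicated = li < n_dup
        anc = rng.choice(BASES, size=cfg.seq_length)
        w = max(rng.normal(cfg.within_divergence, cfg.within_sd), 0.05) / 100.0
        g = _rate_for_pairwise(w)
        copies = []
        if duplicated:
            d = max(rng.normal(cfg.between_divergence, cfg.between_sd), w * 2) / 100.0
            f = _class_shift_for_cross(d, g)
            anc_b = _mutate(anc, f, rng)
            for s in samples:
                copies.append((s, "A", "".join(_mutate(anc, g, rng))))
                copies.append((s, "B", "".join(_mutate(anc_b, g, rng))))
        else:
            for s in samples:
                copies.append((s, "A", "".join(_mutate(anc, g, rng))))
        loci[name] = copies
        flags[name] = duplicated
    return loci, flags


def simulate_paralog_loci_exact(
    n_loci: int = 100,
    dup_fraction: float = 0.25,
    within_pct: float = 2.0,
    between_pct: float = 14.0,
    seq_length: int = 5000,
    samples: Optional[Sequence[str]] = None,
    seed: int = 0,
):
    """Synthetic loci with *exact* pairwise divergences (deterministic design).

    Substituted sites are laid out in disjoint blocks: a shared class-shift
    block of (between - within)% of sites separates the two copy classes of a
    duplicated locus, and every copy carries a private block of (within/2)%,
    so each within-class pair diverges by exactly ``within_pct`` and each
    cross-class pair by exactly ``between_pct``. Useful where the ortholog
    partition must be unambiguous; :func:`simulate_paralog_divergences` is
    the stochastic counterpart.
    """
    if between_pct <= within_pct:
        raise ValueError("between divergence must exceed within divergence")
    rng = np.random.default_rng(seed)
    if samples is None:
        samples = [f"S{i + 1:02d}" for i in range(8)]
    priv = int(round(within_pct / 200.0 * seq_length))
    shift = int(round((between_pct - within_pct) / 100.0 * seq_length))
    n_copies_max = 2 * len(samples)
    if shift + n_copies_max * priv > seq_length:
        raise ValueError("sequence too short for the requested divergences")
    n_dup = int(round(n_loci * dup_fraction))
    loci: dict[str, list[tuple[str, str, str]]] = {}
    flags: dict[str, bool] = {}

    def flip_block(seq: np.ndarray, start: int, n: int) -> np.ndarray:
        out = seq.copy()
        for i in range(start, start + n):
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[rng.integers(3)]
        return out

    for li in range(n_loci):
        name = f"locus{li:04d}"
        duplicated = li < n_dup
        anc = rng.choice(BASES, size=seq_length)
        copies = []
        cursor = shift  # private blocks start after the shift block
        anc_b = flip_block(anc, 0, shift) if duplicated else None
        for s in samples:
            copies.append((s, "A", "".join(flip_block(anc, cursor, priv))))
            cursor += priv
            if duplicated:
                copies.append((s, "B", "".join(flip_block(anc_b, cursor, priv))))
                cursor += priv
        loci[name] = copies
        flags[name] = duplicated
    return loci, flags


# ---------------------------------------------------------------------------
# alignments and pileups


def simulate_alignment(
    tree: PhyloTree, n_sites: int, mutation_rate: float = 0.1, seed: int = 0
) -> dict[str, str]:
    """Jukes-Cantor sequences on a tree (branch lengths x mutation rate)."""
    rng = np.random.default_rng(seed)
    t = tree.dendropy_tree
    seqs: dict[int, np.ndarray] = {}
    out: dict[str, str] = {}
    for nd in t.preorder_node_iter():
        if nd.parent_node is None:
            seqs[id(nd)] = rng.choice(BASES, size=n_sites)
        else:
            b = (nd.edge.length or 0.0) * mutation_rate
            p_sub = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * b))
            seqs[id(nd)] = _mutate(seqs[id(nd.parent_node)], p_sub, rng)
        if nd.is_leaf():
            out[nd.taxon.label] = "".join(seqs[id(nd)])
    return out


def simulate_pileup(
    sequence: str,
    mean_depth: float = 10.0,
    error_rate: float = 0.01,
    seed: int = 0,
):
    """Per-site A/C/G/T read counts around a known sequence (Poisson depth)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for i, base in enumerate(sequence):
        depth = rng.poisson(mean_depth)
        counts = dict.fromkeys("ACGT", 0)
        for _ in range(depth):
            if base in counts and rng.random() >= error_rate:
                counts[base] += 1
            else:
                counts[rng.choice(BASES)] += 1
        rows.append(
            {"pos": i + 1, "nA": counts["A"], "nC": counts["C"], "nG": counts["G"], "nT": counts["T"]}
        )
    return pd.DataFrame(rows)
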