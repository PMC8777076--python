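"""ABBA-BABA D-statistics, f4-ratio and f-branch introgression screening,
and the iterative pruning loop that removes introgressed samples.

Sites are outgroup-polarized biallelic SNPs; with derived-allele dosages
p1, p2, p3, pO for the four populations of a trio {[(P1,P2)P3]O}, the per-site
pattern weights are ABBA = (1-p1) p2 p3 (1-pO) and BABA = p1 (1-p2) p3 (1-pO).
Under incomplete lineage sorting alone both patterns are equally likely, so
D = (ABBA - BABA) / (ABBA + BABA) is 0 in expectation; an excess of one
pattern indicates gene flow. The f4-ratio estimates the admixture fraction,
and the f-branch statistic arranges f4-ratios onto species-tree branches to
localize donor-recipient pairs.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .filtering import FilterConfig, SnpMatrix
from .treeio import GeneTreeSet, PhyloTree, TaxonMap, root_on_outgroup

__all__ = [
    "TrioDResult",
    "F4Result",
    "FBranchMatrix",
    "PruneLog",
    "count_patterns",
    "d_statistic",
    "all_trio_d",
    "f4_ratio",
    "f_branch",
    "iterative_prune",
]

Taxon = Union[str, Sequence[str]]


def _dosage(matrix: SnpMatrix, taxon: Taxon) -> np.ndarray:
    """Per-site derived-allele dosage of a sample or pooled sample group."""
    names = [taxon] if isinstance(taxon, str) else list(taxon)
    idx = matrix.sample_index(names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(matrix.geno[idx, :], axis=0)


def _pattern_terms(
    matrix: SnpMatrix, trio: Sequence[Taxon], outgroup: Taxon
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site ABBA and BABA weights and the used-site mask."""
    if not matrix.polarized:
        raise ValueError("matrix must be outgroup-polarized")
    p1, p2, p3 = (_dosage(matrix, t) for t in trio)
    po = _dosage(matrix, outgroup)
    used = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(po))
    abba = np.where(used, (1 - p1) * p2 * p3 * (1 - po), 0.0)
    baba = np.where(used, p1 * (1 - p2) * p3 * (1 - po), 0.0)
    return abba, baba, used


def count_patterns(
    matrix: SnpMatrix, trio: Sequence[Taxon], outgroup: Taxon
) -> tuple[float, float, int]:
    """Summed ABBA and BABA pattern weights and the number of sites used.

    Sites with a missing call in any of the four taxa are skipped. Taxa may
    be single samples or sample groups (dosage = derived-allele frequency).
    """
    abba, baba, used = _pattern_terms(matrix, trio, outgroup)
    return float(abba.sum()), float(baba.sum()), int(used.sum())


@dataclass
class TrioDResult:
    trio: tuple
    outgroup: Taxon
    abba: float
    baba: float
    d: Optional[float]
    se: Optional[float]
    z: Optional[float]
    n_sites: int
    undefined: bool = False


def d_statistic(
    matrix: SnpMatrix,
    trio: Sequence[Taxon],
    outgroup: Taxon,
    n_blocks: int = 20,
) -> TrioDResult:
    """D = (ABBA - BABA)/(ABBA + BABA) with a block-jackknife SE and Z score.

    The jackknife deletes each of ``n_blocks`` contiguous blocks of used
    sites in turn. Swapping P1 and P2 negates D exactly. When
    ABBA + BABA = 0 the statistic is flagged undefined.
    """
    abba_t, baba_t, used = _pattern_terms(matrix, trio, outgroup)
    abba, baba = float(abba_t.sum()), float(baba_t.sum())
    n_used = int(used.sum())
    if abba + baba == 0:
        return TrioDResult(
            tuple(trio), outgroup, abba, baba, None, None, None, n_used, True
        )
    d = (abba - baba) / (abba + baba)
    idx = np.nonzero(used)[0]
    blocks = np.array_split(idx, min(n_blocks, max(len(idx), 1)))
    blocks = [b for b in blocks if len(b)]
    d_del = []
    for b in blocks:
        a = abba - abba_t[b].sum()
        bb = baba - baba_t[b].sum()
        if a + bb > 0:
            d_del.append((a - bb) / (a + bb))
    se = z = None
    if len(d_del) >= 2:
        d_del = np.asarray(d_del)
        B = len(d_del)
        se = float(np.sqrt((B - 1) / B * ((d_del - d_del.mean()) ** 2).sum()))
        z = d / se if se > 0 else float("inf") * np.sign(d) if d else 0.0
    return TrioDResult(
        tuple(trio), outgroup, abba, baba, float(d), se, z, n_used, False
    )


def all_trio_d(
    matrix: SnpMatrix,
    samples: Sequence[str],
    outgroup: Taxon,
    n_blocks: int = 20,
) -> pd.DataFrame:
    """D statistics for every trio of *samples* with a fixed outgroup.

    P1/P2 are oriented so that D >= 0 (the usual reporting convention).
    """
    rows = []
    for p1, p2, p3 in itertools.combinations(sorted(samples), 3):
        r = d_statistic(matrix, (p1, p2, p3), outgroup, n_blocks=n_blocks)
        if not r.undefined and r.d is not None and r.d < 0:
            r = d_statistic(matrix, (p2, p1, p3), outgroup, n_blocks=n_blocks)
        rows.append(
            {
                "P1": r.trio[0],
                "P2": r.trio[1],
                "P3": r.trio[2],
                "ABBA": r.abba,
                "BABA": r.baba,
                "D": r.d,
                "SE": r.se,
                "Z": r.z,
                "n_sites": r.n_sites,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class F4Result:
    f: Optional[float]  # clamped to [0, 1]
    raw: Optional[float]
    numerator: float
    denominator: float
    n_sites: int
    undefined: bool = False


def f4_ratio(
    matrix: SnpMatrix,
    p1: Taxon,
    p2: Taxon,
    p3: Taxon,
    outgroup: Taxon,
    p3_den: Optional[Taxon] = None,
) -> F4Result:
    """Admixture-fraction estimate f = num(P1,P2,P3,O) / num(P1,P3',P3,O).

    The numerator sums the per-site ABBA - BABA weight (p2 - p1) p3 (1 - pO);
    the denominator replaces P2 by the donor itself, so f -> 1 when P2's
    derived alleles match P3's. By default P3' = P3; with a single sample
    that inflates the denominator by the donor's own drift (E[p3^2] > shared
    drift), biasing f downward, so when the donor population is sampled more
    than once pass a distinct sample (or subgroup) as ``p3_den``. Reported f
    is clamped to [0, 1]; the raw value is retained. A non-positive
    denominator flags the ratio undefined.
    """
    if not matrix.polarized:
        raise ValueError("matrix must be outgroup-polarized")
    d1, d2, d3 = (_dosage(matrix, t) for t in (p1, p2, p3))
    d3b = d3 if p3_den is None else _dosage(matrix, p3_den)
    do = _dosage(matrix, outgroup)
    used = ~(
        np.isnan(d1) | np.isnan(d2) | np.isnan(d3) | np.isnan(d3b) | np.isnan(do)
    )
    w = (1 - do[used])
    num = float(((d2[used] - d1[used]) * d3[used] * w).sum())
    den = float(((d3b[used] - d1[used]) * d3[used] * w).sum())
    if den <= 0:
        return F4Result(None, None, num, den, int(used.sum()), True)
    raw = num / den
    return F4Result(
        float(min(max(raw, 0.0), 1.0)), float(raw), num, den, int(used.sum()), False
    )


@dataclass
class FBranchMatrix:
    """Branch x candidate-donor matrix of f-branch fractions.

    ``values`` holds the clamped (>= 0) fractions; ``raw`` the unclamped
    medians. Rows are keyed by the branch's descendant-tip set rendered as a
    sorted '+'-joined string; undefined cells (donor nested in the branch,
    or no usable sister) are NaN.
    """

    values: pd.DataFrame
    raw: pd.DataFrame
    branch_tips: dict[str, frozenset] = field(default_factory=dict)

    def max_cell(self) -> tuple[str, str, float]:
        v = self.values.to_numpy(dtype=float)
        if np.all(np.isnan(v)):
            raise ValueError("f-branch matrix has no defined entries")
        i, j = np.unravel_index(np.nanargmax(v), v.shape)
        return (
            str(self.values.index[i]),
            str(self.values.columns[j]),
            float(v[i, j]),
        )


def _branch_list(tree: PhyloTree) -> list[tuple[frozenset, frozenset]]:
    """(descendant tips, sister tips) for every non-root branch."""
    t = tree.dendropy_tree
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            nd._ls = frozenset([nd.taxon.label])
        else:
            nd._ls = frozenset().union(*(c._ls for c in nd.child_nodes()))
    out = []
    for nd in t.preorder_node_iter():
        if nd is t.seed_node:
            continue
        sisters = frozenset().union(
            *(k._ls for k in nd.parent_node.child_nodes() if k is not nd)
        )
        out.append((nd._ls, sisters))
    return out


def f_branch(
    matrix: SnpMatrix,
    species_tree: PhyloTree,
    outgroup: Taxon,
    donors: Optional[Sequence[str]] = None,
) -> FBranchMatrix:
    """The f-branch statistic: excess allele sharing per (branch, donor).

    For branch b with sister tips S(b) and donor C not descended from b,

        fb(b, C) = median over tips a of b of
                   [ min over b' in S(b), b' != C of f4_ratio(b', a, C, O) ],

    with the raw (unclamped) f4 values entering the median and the reported
    value floored at 0. Donors inside b (or equal to a sister when no other
    sister exists) leave the cell undefined.
    """
    tips = set(species_tree.leaf_labels)
    og = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    tips -= og
    missing = tips - set(matrix.samples)
    if missing:
        raise ValueError(f"tree taxa absent from SNP matrix: {sorted(missing)}")
    donors = sorted(tips) if donors is None else sorted(donors)
    work = species_tree.prune_to(tips) if set(species_tree.leaf_labels) != tips else species_tree
    branches = _branch_list(work)
    cache: dict[tuple, Optional[float]] = {}

    def f4raw(b1: str, a: str, c: str) -> Optional[float]:
        key = (b1, a, c)
        if key not in cache:
            r = f4_ratio(matrix, b1, a, c, outgroup)
            cache[key] = None if r.undefined else r.raw
        return cache[key]

    row_keys, rows_raw = [], []
    branch_tips = {}
    for desc, sisters in branches:
        key = "+".join(sorted(desc))
        row_keys.append(key)
        branch_tips[key] = desc
        row = []
        for c in donors:
            if c in desc:
                row.append(np.nan)
                continue
            cands = []
            for a in sorted(desc):
                vals = [
                    v
                    for b1 in sorted(sisters)
                    if b1 != c and (v := f4raw(b1, a, c)) is not None
                ]
                if vals:
                    cands.append(min(vals))
            row.append(float(np.median(cands)) if cands else np.nan)
        rows_raw.append(row)
    raw = pd.DataFrame(rows_raw, index=row_keys, columns=donors, dtype=float)
    values = raw.clip(lower=0.0)
    return FBranchMatrix(values=values, raw=raw, branch_tips=branch_tips)


@dataclass
class PruneIteration:
    iteration: int
    removed: list[tuple[str, float, str]]  # sample, max fb, partner donor
    species_tree_newick: str


@dataclass
class PruneLog:
    iterations: list[PruneIteration] = field(default_factory=list)
    termination: str = ""

    def removed_samples(self) -> list[str]:
        return [s for it in self.iterations for s, _, _ in it.removed]

    def to_tsv(self) -> str:
        lines = ["iteration\tsample\tmax_fbranch\tpartner"]
        for it in self.iterations:
            for s, v, p in it.removed:
                lines.append(f"{it.iteration}\t{s}\t{v:.4f}\t{p}")
        lines.append(f"# termination: {self.termination}")
        return "\n".join(lines) + "\n"


def _estimate_species_tree(
    matrix: SnpMatrix,
    gene_trees: Optional[GeneTreeSet],
    samples: Sequence[str],
    outgroup: Sequence[str],
) -> PhyloTree:
    from .species_inference import distance_tree, species_tree_quartet

    keep = list(samples) + list(outgroup)
    if gene_trees is not None:
        pruned = GeneTreeSet(
            [gt.prune_to(set(keep) & set(gt.leaf_labels)) for gt in gene_trees]
        )
        tree, _ = species_tree_quartet(pruned, mode="distance")
    else:
        tree = distance_tree(matrix.subset_samples(keep))
    return root_on_outgroup(tree, outgroup)


def iterative_prune(
    matrix: SnpMatrix,
    taxon_map: TaxonMap,
    cfg: Optional[FilterConfig] = None,
    gene_trees: Optional[GeneTreeSet] = None,
    max_iterations: int = 20,
) -> tuple[list[str], PruneLog]:
    """Remove introgressed samples until no cross-clade f-branch signal
    exceeds the cutoff.

    Each iteration (re)estimates the species tree on the remaining samples,
    computes the f-branch matrix, and flags every ingroup sample whose
    terminal-branch f-branch value to a donor of a *different* clade exceeds
    ``cfg.fbranch_cutoff`` (default 5%). Flagged samples are removed
    together; the loop stops when nothing is flagged, when fewer than 4
    ingroup samples would remain, or after ``max_iterations``.

    Returns (retained ingroup sample list, prune log).
    """
    cfg = cfg or FilterConfig()
    outgroup = sorted(taxon_map.outgroup & set(matrix.samples))
    if not outgroup:
        raise ValueError("taxon map flags no outgroup sample present in the matrix")
    current = sorted(
        s for s in taxon_map.ingroup_samples() if s in matrix.samples
    )
    log = PruneLog()
    for it in range(1, max_iterations + 1):
        if len(current) < 4:
            log.termination = "fewer than 4 ingroup samples remain"
            break
        tree = _estimate_species_tree(matrix, gene_trees, current, outgroup)
        ingroup_tree = tree.prune_to(current)
        fb = f_branch(matrix.subset_samples(current + outgroup), ingroup_tree, outgroup)
        flagged: list[tuple[str, float, str]] = []
        for s in current:
            if s not in fb.values.index:
                continue
            row = fb.values.loc[s]
            best_val, best_donor = 0.0, None
            for donor, v in row.items():
                if np.isnan(v) or taxon_map.clade.get(donor) == taxon_map.clade.get(s):
                    continue
                if v > best_val:
                    best_val, best_donor = float(v), donor
            if best_donor is not None and best_val > cfg.fbranch_cutoff:
                flagged.append((s, best_val, best_donor))
        log.iterations.append(
            PruneIteration(
                iteration=it,
                removed=flagged,
                species_tree_newick=tree.newick(),
            )
        )
        if not flagged:
            log.termination = "converged: no cross-clade f-branch above cutoff"
            break
        removed = {s for s, _, _ in flagged}
        if len(current) - len(removed) < 4:
            log.termination = "pruning would leave fewer than 4 ingroup samples"
            break
        current = [s for s in current if s not in removed]
    else:
        log.termination = f"max iterations ({max_iterations}) reached"
    return current, log
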