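"""Paralog detection from the distribution of pairwise sequence divergences.

Target-enrichment assemblies can recover multiple copies of a locus. Across
many loci, uncorrected pairwise p-distances between the copies form two
clusters: a low-divergence cluster of allelic variation and a higher one of
paralogy. A two-component Gaussian mixture is fit to the pooled distribution
and the divergence interval mean2 +/- sd2 of the second (higher) component is
taken as the paralogy threshold; copies are then partitioned into ortholog
groups by single-linkage clustering with edges below the interval's lower
bound.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DivergenceProfile",
    "ParalogThreshold",
    "pairwise_divergence",
    "build_divergence_profile",
    "fit_divergence_clusters",
    "partition_copies",
    "screen_loci",
]

_MISSING = set("-?nN")


def pairwise_divergence(seq_a: str, seq_b: str) -> float:
    """Uncorrected p-distance in percent, ignoring gap/N positions.

    Raises on zero comparable sites.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    compared = mismatches = 0
    for x, y in zip(seq_a, seq_b):
        if x in _MISSING or y in _MISSING:
            continue
        compared += 1
        if x.upper() != y.upper():
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable sites between sequences")
    return 100.0 * mismatches / compared


@dataclass
class DivergenceProfile:
    """Pairwise divergences per locus plus the pooled distribution."""

    per_locus: dict[str, list[float]] = field(default_factory=dict)

    @property
    def pooled(self) -> np.ndarray:
        vals = list(itertools.chain.from_iterable(self.per_locus.values()))
        return np.asarray(vals, dtype=float)


def build_divergence_profile(
    loci: dict[str, Sequence[tuple[str, str, str]]]
) -> DivergenceProfile:
    """All pairwise divergences between the copies of each locus.

    ``loci`` maps locus name to (sample, copy_label, sequence) records;
    symmetric pairs are counted once. Pairs with no comparable sites are
    skipped.
    """
    prof = DivergenceProfile()
    for name, copies in loci.items():
        vals = []
        for (_, _, s1), (_, _, s2) in itertools.combinations(copies, 2):
            try:
                vals.append(pairwise_divergence(s1, s2))
            except ValueError:
                continue
        prof.per_locus[name] = vals
    return prof


@dataclass
class ParalogThreshold:
    """The paralogy divergence interval: mean2 +/- sd2 of the upper cluster."""

    mean1: float
    sd1: float
    mean2: float
    sd2: float
    weight1: float
    weight2: float
    unreliable: bool = False

    @property
    def lower(self) -> float:
        return self.mean2 - self.sd2

    @property
    def upper(self) -> float:
        return self.mean2 + self.sd2


def fit_divergence_clusters(
    profile: DivergenceProfile | np.ndarray, seed: int = 0
) -> ParalogThreshold:
    """Two-component 1D Gaussian mixture fit (EM, k-means init, fixed seed).

    Components are ordered by mean; the threshold interval is
    mean2 +/- sd2. A degenerate fit (either component weight < 0.05, or all
    values identical) flags the interval as unreliable.
    """
    from sklearn.mixture import GaussianMixture

    x = profile.pooled if isinstance(profile, DivergenceProfile) else np.asarray(profile, float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError(f"need >= 50 divergence values, got {len(x)}")
    if np.ptp(x) < 1e-12:
        m = float(x[0])
        warnings.warn("degenerate divergence distribution (all values equal)")
        return ParalogThreshold(m, 0.0, m, 0.0, 0.5, 0.5, unreliable=True)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        init_params="kmeans",
        n_init=3,
        random_state=seed,
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    # degenerate when a component vanishes, or when the two components are
    # not separated (Ashman's D < 2 means the mixture is not bimodal)
    ashman_d = abs(m2 - m1) / math.sqrt((s1**2 + s2**2) / 2.0 + 1e-300)
    unreliable = bool(min(w1, w2) < 0.05 or ashman_d < 2.0)
    if unreliable:
        warnings.warn(
            "divergence mixture is effectively unimodal; paralog interval unreliable"
        )
    return ParalogThreshold(
        float(m1), float(s1), float(m2), float(s2), float(w1), float(w2), unreliable
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def partition_copies(
    copies: Sequence[tuple[str, str, str]], threshold: ParalogThreshold
) -> list[dict[str, str]]:
    """Partition one locus's copies into ortholog groups.

    Copies are vertices; edges connect pairs whose divergence is below the
    threshold interval's *lower* bound (divergences inside the interval are
    ambiguous and treated as paralogous). Connected components are the
    ortholog groups; within a group, at most one copy per sample is retained
    (the longest, by non-missing sites). Each group is returned as a
    sample -> sequence alignment.
    """
    n = len(copies)
    if n == 0:
        return []
    uf = _UnionFind(n)
    for i, j in itertools.combinations(range(n), 2):
        try:
            d = pairwise_divergence(copies[i][2], copies[j][2])
        except ValueError:
            continue
        if d < threshold.lower:
            uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    def usable_length(seq: str) -> int:
        return sum(1 for ch in seq if ch not in _MISSING)

    out = []
    for members in groups.values():
        aln: dict[str, str] = {}
        for i in members:
            sample, _, seq = copies[i]
            if sample not in aln or usable_length(seq) > usable_length(aln[sample]):
                aln[sample] = seq
        out.append(aln)
    # deterministic order: by size desc then first sample
    out.sort(key=lambda a: (-len(a), sorted(a)[0]))
    return out


@dataclass
class LocusScreenResult:
    locus: str
    n_copies: int
    n_groups: int
    flagged_paralogous: bool


def screen_loci(
    loci: dict[str, Sequence[tuple[str, str, str]]],
    threshold: ParalogThreshold,
) -> tuple[dict[str, dict[str, str]], list[LocusScreenResult]]:
    """Partition every locus; paralogous loci contribute one alignment per
    ortholog group (named ``locus`` / ``locus__g2`` / ...).

    Returns (alignments, per-locus report).
    """
    alignments: dict[str, dict[str, str]] = {}
    report = []
    for name, copies in loci.items():
        groups = partition_copies(copies, threshold)
        for k, aln in enumerate(groups):
            key = name if k == 0 else f"{name}__g{k + 1}"
            alignments[key] = aln
        report.append(
            LocusScreenResult(
                locus=name,
                n_copies=len(copies),
                n_groups=len(groups),
                flagged_paralogous=len(groups) >= 2,
            )
        )
    return alignments, report


def screen_report_tsv(report: Sequence[LocusScreenResult]) -> str:
    lines = ["locus\tn_copies\tn_groups\tflagged"]
    for r in report:
        lines.append(
            f"{r.locus}\t{r.n_copies}\t{r.n_groups}\t{int(r.flagged_paralogous)}"
        )
    return "\n".join(lines) + "\n"
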