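"""Missing-data filters for samples, sequences, loci and SNPs, plus the
organelle consensus-calling rule and supermatrix concatenation.

The workflow's fixed thresholds live in :class:`FilterConfig`:

* samples are dropped when fewer than 80% of loci were recovered at all;
* within a locus, sequences missing more than 50% of sites are dropped,
  then the locus itself is dropped when fewer than 80% of samples remain;
* SNPs are kept when biallelic, with at most 20% missing calls, and thinned
  to a minimum spacing of 100 bp within each locus;
* consensus bases require read depth >= 2 and a majority fraction >= 0.51,
  otherwise N.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FilterConfig",
    "LocusOccupancy",
    "SnpMatrix",
    "filter_samples",
    "filter_alignment",
    "filter_snps",
    "call_plastome_consensus",
    "read_vcf",
    "write_vcf",
    "polarize",
    "read_fasta",
    "write_fasta",
    "write_supermatrix",
]

MISSING_CHARS = set("-?nN")


@dataclass
class FilterConfig:
    """Every numeric threshold of the filtering stages, with workflow defaults."""

    sample_min_locus_recovery: float = 0.80
    sequence_max_missing: float = 0.50
    locus_min_sample_fraction: float = 0.80
    snp_max_missing: float = 0.20
    snp_thin_bp: int = 100
    fbranch_cutoff: float = 0.05
    support_threshold: float = 70.0
    consensus_min_depth: int = 2
    consensus_majority: float = 0.51

    def __post_init__(self):
        for name in (
            "sample_min_locus_recovery",
            "sequence_max_missing",
            "locus_min_sample_fraction",
            "snp_max_missing",
            "consensus_majority",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.snp_thin_bp < 1:
            raise ValueError("snp_thin_bp must be >= 1")


@dataclass
class LocusOccupancy:
    """Per-sample, per-locus fraction of the locus length recovered."""

    matrix: pd.DataFrame  # samples x loci, values in [0, 1]
    locus_lengths: Optional[dict[str, int]] = None

    def __post_init__(self):
        vals = self.matrix.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("occupancy fractions must be in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def loci(self) -> list[str]:
        return list(self.matrix.columns)


def filter_samples(
    occupancy: LocusOccupancy, cfg: FilterConfig
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples that recovered fewer than the required fraction of loci.

    A locus counts as recovered for a sample when its recovery fraction is
    nonzero. Returns (kept sample list, report of dropped samples with their
    recovered-locus fraction).
    """
    m = occupancy.matrix
    if m.empty:
        raise ValueError("empty occupancy matrix")
    frac = (m.to_numpy(dtype=float) > 0).mean(axis=1)
    kept, dropped = [], []
    for sample, f in zip(m.index, frac):
        if f < cfg.sample_min_locus_recovery:
            dropped.append((sample, float(f)))
        else:
            kept.append(sample)
    report = pd.DataFrame(dropped, columns=["sample", "locus_recovery_fraction"])
    return kept, report


def _missing_fraction(seq: str) -> float:
    if not seq:
        return 1.0
    return sum(1 for ch in seq if ch in MISSING_CHARS) / len(seq)


def filter_alignment(
    alignment: dict[str, str], cfg: FilterConfig, n_total_samples: Optional[int] = None
) -> Optional[dict[str, str]]:
    """Apply the per-locus sequence and occupancy filters, in that order.

    First removes sequences whose missing (gap/N) fraction exceeds
    ``sequence_max_missing``; then drops the locus entirely (returns None)
    when the remaining samples are fewer than ``locus_min_sample_fraction``
    of ``n_total_samples`` (defaults to the alignment's own sample count).
    """
    if not alignment:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    if lengths == {0}:
        raise ValueError("zero-length alignment")
    total = n_total_samples if n_total_samples is not None else len(alignment)
    kept = {
        name: seq
        for name, seq in alignment.items()
        if _missing_fraction(seq) <= cfg.sequence_max_missing
    }
    if len(kept) / total < cfg.locus_min_sample_fraction:
        return None
    return kept


class SnpMatrix:
    """Biallelic sample x site genotype matrix.

    Genotypes are derived-allele dosages in [0, 1] (0 = ancestral when
    polarized, otherwise 0 = reference); missing calls are NaN. Sites carry a
    locus id and a strictly increasing position within the locus.
    """

    def __init__(
        self,
        samples: Sequence[str],
        locus: Sequence[str],
        pos: Sequence[int],
        geno: np.ndarray,
        polarized: bool = False,
    ):
        self.samples = list(samples)
        self.locus = np.asarray(locus, dtype=object)
        self.pos = np.asarray(pos, dtype=int)
        self.geno = np.asarray(geno, dtype=float)
        self.polarized = polarized
        if self.geno.shape != (len(self.samples), len(self.pos)):
            raise ValueError("genotype matrix shape mismatch")
        if len(self.locus) != len(self.pos):
            raise ValueError("locus/pos length mismatch")
        for loc in pd.unique(self.locus):
            p = self.pos[self.locus == loc]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing in locus {loc}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def site_missing_fraction(self) -> np.ndarray:
        return np.isnan(self.geno).mean(axis=0)

    def subset_sites(self, mask: np.ndarray) -> "SnpMatrix":
        return SnpMatrix(
            self.samples,
            self.locus[mask],
            self.pos[mask],
            self.geno[:, mask],
            polarized=self.polarized,
        )

    def subset_samples(self, names: Sequence[str]) -> "SnpMatrix":
        idx = self.sample_index(names)
        return SnpMatrix(
            [self.samples[i] for i in idx],
            self.locus,
            self.pos,
            self.geno[idx, :],
            polarized=self.polarized,
        )


def filter_snps(matrix: SnpMatrix, cfg: FilterConfig) -> SnpMatrix:
    """Missingness filter followed by minimum-distance thinning per locus.

    Sites with missing fraction above ``snp_max_missing`` are removed; then,
    scanning left to right within each locus, a site is kept iff its position
    is at least ``snp_thin_bp`` from the last kept site (so kept sites are
    never closer than the thinning distance).
    """
    keep = matrix.site_missing_fraction() <= cfg.snp_max_missing
    m = matrix.subset_sites(keep)
    thin = np.zeros(m.n_sites, dtype=bool)
    last_kept: dict[str, int] = {}
    for i in range(m.n_sites):
        loc = m.locus[i]
        p = int(m.pos[i])
        prev = last_kept.get(loc)
        if prev is None or p - prev >= cfg.snp_thin_bp:
            thin[i] = True
            last_kept[loc] = p
    out = m.subset_sites(thin)
    if out.n_sites == 0:
        warnings.warn("all SNPs removed by filtering", stacklevel=2)
    return out


def polarize(matrix: SnpMatrix, outgroup: Sequence[str]) -> SnpMatrix:
    """Polarize by the outgroup: the major outgroup allele is ancestral.

    Sites where every outgroup call is missing, or where the outgroup is
    split exactly 50/50, are dropped. Returns a new matrix with dosage 1 =
    derived and ``polarized=True``.
    """
    og = matrix.sample_index(outgroup)
    sub = matrix.geno[og, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_alt = np.nanmean(sub, axis=0)
    keep = ~np.isnan(mean_alt) & (np.abs(mean_alt - 0.5) > 1e-9)
    geno = matrix.geno[:, keep].copy()
    flip = mean_alt[keep] > 0.5
    geno[:, flip] = 1.0 - geno[:, flip]
    return SnpMatrix(
        matrix.samples,
        matrix.locus[keep],
        matrix.pos[keep],
        geno,
        polarized=True,
    )


def call_plastome_consensus(
    pileup: pd.DataFrame, cfg: Optional[FilterConfig] = None
) -> str:
    """Call a consensus sequence from per-site A/C/G/T read counts.

    A site is called N when depth < ``consensus_min_depth`` or when no base
    reaches the ``consensus_majority`` fraction (ties at the threshold are
    called, per the 'minimum threshold' reading).
    """
    cfg = cfg or FilterConfig()
    bases = ["A", "C", "G", "T"]
    cols = [f"n{b}" for b in bases]
    counts = pileup[cols].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative base counts in pileup")
    depth = counts.sum(axis=1)
    out = []
    for row, d in zip(counts, depth):
        if d < cfg.consensus_min_depth:
            out.append("N")
            continue
        i = int(np.argmax(row))
        if row[i] / d >= cfg.consensus_majority:
            out.append(bases[i])
        else:
            out.append("N")
    return "".join(out)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_supermatrix(
    alignments: dict[str, dict[str, str]], fasta_path, partition_path
) -> None:
    """Concatenate loci into a supermatrix with a locus partition file.

    Samples absent from a locus are padded with N. Partition lines follow
    the "DNA, locusName = start-end" convention (1-based, inclusive).
    """
    samples = sorted({s for aln in alignments.values() for s in aln})
    parts, concat = [], {s: [] for s in samples}
    start = 1
    for locus, aln in alignments.items():
        length = len(next(iter(aln.values())))
        for s in samples:
            concat[s].append(aln.get(s, "N" * length))
        parts.append(f"DNA, {locus} = {start}-{start + length - 1}")
        start += length
    write_fasta({s: "".join(chunks) for s, chunks in concat.items()}, fasta_path)
    with open(partition_path, "w") as fh:
        fh.write("\n".join(parts) + "\n")


def read_vcf(path, log: Optional[dict] = None) -> SnpMatrix:
    """Read a minimal VCF into an (unpolarized) SnpMatrix.

    Only the GT field is used; "./." is missing; records that are not
    biallelic SNPs are skipped (count reported via ``log['skipped']``).
    Dosage is the fraction of ALT alleles in the genotype.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    locus, pos, rows = [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        doses = []
        for g in var.genotypes:
            alleles = [a for a in g[:-1] if a >= 0]
            doses.append(np.nan if not alleles else float(np.mean(alleles)))
        locus.append(var.CHROM)
        pos.append(var.POS)
        rows.append(doses)
    if log is not None:
        log["skipped"] = skipped
    geno = (
        np.array(rows, dtype=float).T
        if rows
        else np.zeros((len(samples), 0))
    )
    return SnpMatrix(samples, locus, pos, geno, polarized=False)


def write_vcf(matrix: SnpMatrix, path) -> None:
    """Write the matrix as plain VCF4.2 text (diploid homozygous encoding)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for loc in pd.unique(matrix.locus):
            fh.write(f"##contig=<ID={loc}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in range(matrix.n_sites):
            gts = []
            for i in range(matrix.n_samples):
                g = matrix.geno[i, j]
                if np.isnan(g):
                    gts.append("./.")
                elif g >= 0.75:
                    gts.append("1/1")
                elif g >= 0.25:
                    gts.append("0/1")
                else:
                    gts.append("0/0")
            fh.write(
                f"{matrix.locus[j]}\t{matrix.pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
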