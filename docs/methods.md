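# Methods

`discotree` diagnoses the sources of gene-tree discordance in recent rapid
radiations — incomplete lineage sorting (ILS), hybridization/introgression,
paralogy from genome duplication, and missing-data artifacts — for
target-enrichment (Hyb-Seq) datasets. This note documents the models and
procedures, the generator that the test suite validates them against, the
numerical choices, and the known limits of what the tests demonstrate.

## Models and procedures

### Multispecies coalescent on trees and networks

All coalescent-time quantities are in coalescent units (time / 2N
generations). The central closed form is the rooted-triple distribution: for
a species tree whose internal branch separating the concordant pair has
length `T`, a gene tree shows the concordant triple with probability
`1 − (2/3)·e^(−T)` and each alternative with `(1/3)·e^(−T)`. The same form
drives node-concordance expectations, quartet supports around a branch (with
a distant outgroup), and the network pseudo-likelihood.

Networks are rooted DAGs in which a reticulation node has two parents whose
edges carry inheritance probabilities γ and 1−γ. Triple probabilities on a
network are computed as the γ-weighted mixture over displayed trees:
`P(topology) = Σ_d w_d · P_MSC(topology | displayed tree d)`, where `w_d`
multiplies the γ values of the reticulation edges retained in `d`. This
mixture is exact when at most one lineage of a sampled triple traverses any
given reticulation — which holds for one sample per taxon when the hybrid
taxa subtend the reticulations, the configuration all bundled networks use.
Networks are assumed time-consistent (node ages well defined from branch
lengths); ages are computed as maxima over root-to-leaf paths, so mildly
inconsistent inputs resolve conservatively rather than erroring.

### Pseudo-likelihood, γ estimation, AIC

The network score is a composite likelihood over rooted triples:
`lnL = Σ_triples Σ_gene-trees log P(observed triple | network)`, with
unresolved triples (after support collapsing) skipped. When samples are
mapped to clades, each clade is represented in each gene tree by the first
mapped sample present; with one lineage per clade the triple formula above is
exact. γ values are estimated by coordinate-ascent golden-section search on
[0, 1] (tolerance 1e−3, 3 sweeps); missing internal branch lengths are
profiled on a log-spaced grid of 12 points between 0.1 and 5 coalescent
units. A γ whose likelihood profile is flat to within 1e−6 across
{0, .25, .5, .75, 1} is flagged unidentifiable.

Model selection uses `AIC = 2k − 2·lnL` with
`k = (#branches of the base topology) + (#reticulations) + (#gene trees)`.
The base topology is the major displayed tree (highest-γ parent at every
reticulation), and its branch count is the number of distinct non-root
clades after suppressing unifurcations. The constant `#gene trees` term
cannot change rankings at fixed data; it is retained because the parameter
count is part of the workflow's stated model-selection rule, and it is
reported in the model table so users can verify `k`. Ties in AIC go to the
model with fewer parameters.

### Site-pattern statistics

Sites are outgroup-polarized biallelic SNPs with derived-allele dosages
`p ∈ [0, 1]` per taxon (a taxon may be a pooled sample group). Per site,
`ABBA = (1−p1)·p2·p3·(1−pO)` and `BABA = p1·(1−p2)·p3·(1−pO)`;
`D = (ABBA − BABA)/(ABBA + BABA)` is 0 in expectation under ILS alone.
Standard errors use a delete-one block jackknife over 20 contiguous blocks
of used sites (block count configurable); `Z = D/SE`.

The admixture fraction is the f4-ratio
`f = num(P1, P2, P3, O) / num(P1, P3, P3, O)` with
`num = Σ (p2 − p1)·p3·(1−pO)`. With a single haploid sample as P3 the
denominator includes that sample's own drift (E[p3^2] exceeds the shared
drift) and the ratio is biased downward; when the donor population is
sampled more than once, passing a distinct donor sample for the
denominator's P2 role (the `p3_den` argument) removes the bias, and the
validation fixtures do so. Reported `f` is clamped to [0, 1]; the raw value
is retained.

The f-branch statistic localizes gene flow:
`fb(b, C) = median over descendant tips a of b of
[ min over sister tips b′ of b (b′ ≠ C) of f4-ratio(b′, a, C, O) ]`,
computed from raw (unclamped) f4 values and floored at 0 for reporting.
Cells with the donor nested inside the branch, or with no usable sister, are
undefined. Two caveats are inherent to the statistic and documented here
because the tests exercise them: (i) when a branch's *only* sister is itself
a hybrid, its rows show spurious signal (the hybrid is a contaminated
baseline) — rows for tips whose sister sets contain non-hybrids are
reliable; (ii) within-clade cells are noisy because closely related P1/P3
pairs give small f4 denominators. The pruning rule therefore only acts on
cross-clade donors.

### Iterative introgression pruning

Each iteration estimates a species tree on the remaining samples (quartet
summary over gene trees when available, otherwise an SNP distance tree),
roots it on the outgroup, computes the f-branch matrix, and flags every
ingroup sample whose terminal-branch value toward a donor of a *different*
clade exceeds the 5% cutoff. All flagged samples are removed together; the
loop stops at convergence, after 20 iterations, or when fewer than four
ingroup samples would remain. Removal uses recipient (terminal-branch) rows
only, so donors are not removed along with their hybrids. The min-over-
sisters construction makes cascades possible: a weaker hybrid whose only
sister is a stronger hybrid from the same donor is masked (the f4 baseline
subtracts the shared signal) until the stronger one is removed — the bundled
cascade fixture plants exactly this configuration.

### Species-tree summaries

Two consistent summary estimators stand in for likelihood software. The
quartet method maximizes the summed dominant-quartet count: exhaustive over
all `(2n−5)!!` unrooted topologies for n ≤ 8 (an unrooted n-taxon tree is
enumerated as a rooted (n−1)-taxon tree with the first taxon at the root),
or, for larger sets, average topological internode distances across gene
trees followed by neighbor joining (the NJst/ASTRID family). Internode
distances treat a bifurcating root as suppressed (unrooted path lengths);
pairs are averaged over the gene trees containing both, and a pair that
never co-occurs is an error. Ties in the exhaustive search go to the
lexicographically smallest newick. Distance trees from alignments or SNP
matrices use missing-aware p-distances and neighbor joining with negative
branch lengths clamped to 0.

### Discordance metrics

Node concordance uses rooted clade semantics: each gene tree is collapsed at
the support threshold and restricted to shared taxa; a species-tree clade is
concordant when present, conflicting when some gene-tree clade overlaps it
without nesting, and uninformative otherwise — the three categories
partition the gene-tree set. Per-branch quartet frequencies draw one leaf
from each of the four clades incident to a branch (exhaustive within a
budget, else a seeded uniform sample) and tally the three resolutions over
all gene trees; `q1 ≈ q2 ≈ q3 ≈ 1/3` indicates extreme ILS. Alternative-
topology frequencies for three focal clades require each clade to be
monophyletic on the pruned tree with at most 20% of its samples missing and
the deciding node to survive the 70% support threshold; frequencies are
normalized over voting trees.

Placement codes compare a sample's attachment between two rooted trees on
their shared samples: "−" absent from both, "absent-one" present in exactly
one, "o" attached within a different labeled clade (majority clade label of
the sister group), "x" same clade but a different sister set, concordant
otherwise. "Different position within a clade" is operationalized as
sister-set inequality on the shared-sample restriction; this is the
strictest reading and is the documented convention.

The net diversification rate is `ln(N)/t` (N extant species, t crown age in
Ma), rounded half-up to two decimals.

### Filters

Thresholds and semantics (defaults in `FilterConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `sample_min_locus_recovery` | 0.80 | a sample needs nonzero recovery of ≥80% of loci |
| `sequence_max_missing` | 0.50 | per-locus sequences with >50% gap/N dropped |
| `locus_min_sample_fraction` | 0.80 | locus dropped when <80% of samples remain |
| `snp_max_missing` | 0.20 | sites with >20% missing calls dropped |
| `snp_thin_bp` | 100 | min distance between kept sites within a locus |
| `fbranch_cutoff` | 0.05 | cross-clade f-branch fraction triggering removal |
| `support_threshold` | 70 | percent support below which nodes are collapsed |
| `consensus_min_depth` / `consensus_majority` | 2 / 0.51 | consensus base calling; ties at exactly 0.51 are called (the threshold is a minimum), below it N |

"Recovered locus" means any nonzero recovery fraction, matching per-sample
locus-count reporting. The sequence filter runs before the locus-occupancy
filter (the order changes outcomes and is fixed). Thinning is
minimum-distance (no two kept sites closer than 100 bp), not fixed tiling.
Site missingness is computed over all samples jointly, including the
outgroup (configurable by subsetting first). Polarization takes the major
outgroup allele as ancestral; sites with an exactly split or fully missing
outgroup are dropped.

### Paralog screen

Divergences are uncorrected p-distances in percent, gap/N columns excluded,
pooled across loci (per-locus fitting is possible by passing a subset
profile but pooling is the default). A two-component Gaussian mixture
(EM, k-means initialization, fixed seed, components ordered by mean) gives
the paralogy interval `mean₂ ± sd₂`. The fit is flagged unreliable when a
component weight falls below 0.05 or when Ashman's
`D = |μ₂−μ₁|/√((σ₁²+σ₂²)/2) < 2` (the mixture is not bimodal — e.g., on
data simulated without duplication). Ortholog groups are connected
components of the graph with edges where divergence < the interval's lower
bound: divergences inside the interval are ambiguous and treated as
paralogous, a deliberately conservative linkage. Within a group, one copy
per sample is kept (most non-missing sites).

Single-linkage over the `< lower` relation has a structural consequence
worth knowing: with the threshold only one fitted SD below the second
cluster's mean, roughly the lowest sixth of cross-copy divergences falls
below it, and one such pair merges a locus's two copy classes. On broadly
dispersed divergence distributions some duplicated loci will therefore go
unflagged; that is the price of the conservative interval, not a bug.

## The synthetic-data generator

The generator produces every input the pipeline consumes, under the
assumptions the analysis itself makes:

- **Gene trees** — exponential-waiting-time coalescence at rate k(k−1)/2
  within each network edge (population); at a reticulation each lineage
  independently follows a parent with probability γ; the root population
  coalesces to one lineage. Output trees are rooted with coalescent-unit
  branch lengths. Simultaneous speciation times are processed children-first
  (topological tie-break).
- **SNPs** — infinite sites: each site carries exactly one mutation, placed
  on a branch with probability proportional to its length; the derived
  allele is carried by the subtended leaves, so derived sets are exact
  gene-tree clades (no homoplasy). Sites within a locus share one gene tree,
  modelling the linkage that SNP thinning then removes; positions are
  uniform without replacement within the locus length. Optionally the matrix
  is re-polarized by the outgroup rule rather than by the simulation truth.
- **Missingness** — per-(sample, locus) Bernoulli dropout followed by
  per-site dropout; realized rates converge to the requested ones.
- **Paralog loci** — two modes. The stochastic mode draws per-locus
  within- and between-class divergences from the configured normals and
  analytically inverts the substitution rates (accounting for repeat-hit
  collisions, `2g − (4/3)g²` within and the two-step composition across the
  class shift) so realized p-distances match the configured means. The
  deterministic mode lays substitutions out in disjoint site blocks so every
  pairwise divergence is *exact*; it exists for tests whose expected
  ortholog partition must be unambiguous, and is labelled synthetic in its
  docstring.
- **Alignments / pileups** — Jukes-Cantor sequences on a tree
  (`p_sub = (3/4)(1 − e^(−4b/3))` per branch of length b × mutation rate)
  and Poisson-depth pileups with a uniform error model, for the distance
  tree and consensus-caller tests.

Everything is driven by a single integer seed; outputs are byte-identical
across runs.

**What the generator does not emulate** — and hence what green tests do not
show about real data: intra-locus recombination, substitution-model
misspecification and rate heterogeneity, assembly and alignment error,
sequencing error in SNP calls (pileups aside), demographic change through
time, gene duplication histories more complex than one duplication per
locus, and non-random (phylogenetically structured) missingness. Bootstrap
supports are absent on simulated trees; support-collapsing logic is
exercised with hand-annotated fixtures instead.

## Validation conditions (problem sizes)

The bundled checks run at desk scale, chosen so the whole suite completes in
a few minutes on one core: coalescent closed forms at 10⁴ gene trees;
D-statistic null calibration at 100 replicates × 2 000 linked SNPs;
introgression recovery on 6–13-sample networks with γ = 0.3 and 4 000–12 000
SNPs; network model selection at 20 replicates × 1 000 gene trees on a
5-taxon, 1-reticulation network; paralog screening on 80–150 loci. The
planted-hybrid networks attach donors to *ancestral* branches of foreign
clades — the configuration in which recipient rows light up while donor
(mirror) rows stay near zero; tip-to-tip gene flow additionally marks the
donor, which is biologically indistinguishable from bidirectional exchange
at these statistics' resolution.

## Known limitations

- The exhaustive quartet species tree is capped at 8 taxa ((2n−5)!! growth);
  beyond that the internode-distance estimator is used.
- Pseudo-likelihood over triples cannot discriminate network features that
  only quartets (or full gene-tree distributions) separate, and γ near a
  symmetric reticulation (γ = 0.5 between exchangeable parents) is
  unidentifiable — flagged, not resolved.
- The displayed-tree mixture undercounts coalescent paths when two or more
  sampled lineages traverse one reticulation (multiple samples per hybrid
  species); use one representative per clade, as the scoring functions do.
- f-branch rows whose only sister is another hybrid are unreliable
  (see above); interpretation should lean on rows with clean sisters.
- The iterative pruning acts on point estimates of the f-branch fraction;
  Z-scores are reported for information but do not gate removals.
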