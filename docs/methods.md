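# Methods

## Two-locus segregation model

A nuclear family has *n* children and a designated transmitting parent
with phased haplotypes 1 and 2. For loci A and B separated by genetic
distance *d* (cM), crossovers are assumed to follow a Poisson process on
the genetic scale (no interference), so the Haldane mapping function
r = ½(1 − e^(−2d/100)) gives the per-meiosis probability of an odd number
of crossovers between the loci. A child matches its designated haplotype
at both loci with probability (1 − r)/2 — a fair draw of the transmitted
haplotype at A times the no-recombination probability — and meioses are
independent across children, so the labeled pattern (subset C receives
haplotype 1 at both loci, complement C′ receives haplotype 2) has
probability ((1 − r)/2)^n. The probability depends only on *n*, not on
the bipartition sizes: every child constrains one meiosis.

Design choices:

* The default reports the probability of the **specific labeled**
  configuration; the phase-agnostic probability (×2) is deliberately not
  the default because the observed data identify which haplotype went to
  which child.
* `SegregationConfig` accepts either precomputed cM positions or physical
  loci plus a genetic map; both routes go through the same code path, and
  the locus representative point is the physical midpoint (interval
  lengths here are ≪ 1 cM, so the choice is immaterial at reporting
  precision).
* Reported to four decimals (probability) / two decimals (percent). For
  the reference family (d = 4.5093 cM, n = 4) the closed form gives
  5.2398%, i.e. 5.24% at two decimals; a printed value of 5.25% is
  consistent at ±0.02 percentage points and is presumably carried extra
  precision in the cM inputs or rounding up.
* The Monte-Carlo oracle (`simulate_meioses`) draws the locus-A haplotype
  uniformly and a crossover indicator Bernoulli(r) per child; it is kept
  free of the closed form so the two can check each other.

## Genetic maps

Maps are per-chromosome anchor tables (bp, cumulative cM), strictly
increasing in bp, non-decreasing in cM, ≥ 2 anchors. Interpolation is
linear between anchors; queries outside the anchored range **clamp** to
the terminal anchor with a logged warning — extrapolating a terminal
recombination rate invents genetic distance where the map has no support.
The cM column is cumulative position, not a per-bp rate.

## IBD detection

Input is a stream of biallelic SNVs with per-sample GT/DP/GQ/AD (cyvcf2
does the parsing; multiallelic, non-SNV and FORMAT-incomplete records are
skipped and counted). Site filters are applied **per sample** with strict
inequalities — depth > 14 and genotype quality > 30 for every pedigree
member, Mendelian consistency for every trio (degrading to parent–child
allele sharing when one parent is absent), and heterozygous alt-allele
balance within [0.25, 0.75] (configurable; the balance bound quantifies
"minimal allelic imbalance", for which no published number exists).

For a full-sib pair, a parent's transmission is *resolved* at a site when
that parent is heterozygous and each sibling's allele from that parent is
uniquely determined by the four genotypes. Per-site states:

| evidence                                | state     | definite |
|-----------------------------------------|-----------|----------|
| both parents resolved, both shared       | IBD2      | yes      |
| both resolved, exactly one shared        | IBD1      | yes      |
| both resolved, none shared               | IBD0      | yes      |
| one resolved, shared                     | IBD1      | no       |
| one resolved, not shared                 | ambiguous | no       |
| none resolved                            | dropped   | —        |

The single-evidence IBD1 label is a lower bound ("at least one allele
shared") and is load-bearing: when both parents are heterozygous, the
sibling pair in a truly-IBD1 region necessarily contains a heterozygous
child whose transmission is ambiguous, so truly-IBD1 regions *never*
produce a fully resolved site. Conversely a "one resolved, not shared"
site cannot distinguish IBD0 from IBD1-through-the-other-parent, so it
neither supports nor breaks a segment.

Segments are maximal runs of supporting (IBD1/IBD2) sites, closed by
definite IBD0 evidence, a chromosome change, or a gap > 1 Mb between
supporting sites; runs with < 5 supporting sites are discarded; the
segment label is the majority state among its definite sites (IBD1 when
none). Transitions between IBD1 and IBD2 site labels do **not** close a
run: single-evidence IBD1 labels alternate freely with IBD2 inside a
truly-IBD2 region, and the detection target — intervals where at least
one allele is inherited identically by descent — is exactly the run
logic. Breakpoint resolution is therefore one inter-support-site gap
(empirically ≲ 0.5 Mb on the default simulated grid, always below the
1 Mb segmentation scale).

An optional allele-depth tie-break (off by default) treats two
heterozygous siblings with similar alt-allele fractions (|Δ| ≤ 0.1) at a
fully ambiguous double-heterozygous site as weak sharing evidence. This
is a heuristic: allele-depth ratios cannot identify *which* parental
haplotype was transmitted, only whether the siblings' read support looks
concordant.

Scope: segment detection is defined for full-sib pairs; a parent–child
pair is IBD1 everywhere by construction and is rejected with an
explanatory error. HMM-based callers, population-scale IBD and
statistical phasing are out of scope.

## Frequencies and ACMG combination

Allele frequencies are exact rationals AC/AN (`fractions.Fraction`),
formatted to three significant figures. Tier boundaries are assigned to
the middle tier: AF < 1e−4 very rare, 1e−4 ≤ AF ≤ 1e−3 rare (closed
interval), AF > 1e−3 common — the published interval notation overlaps at
the boundaries, and a deterministic rule is required. The ACMG/AMP
combiner implements the pathogenicity-side combining rules as explicit
count thresholds (PVS/PS/PM/PP by code prefix), written with ≥
comparisons so that adding evidence can never weaken a classification
(verified by property test). Benign-side codes, Bayesian point systems
and founder-effect analysis are out of scope. "VUS with a tendency
toward LP" is not an ACMG class and is reported as plain VUS.

## Network randomization null

The statistic for node *v* is the mean weighted shortest-path distance
from *v* to the seed genes, with edge length 1/weight (stronger
association = shorter; the transform is a single configurable function).
A seed node averages over the *other* seeds. The null preserves the two
marginals named for it — the degree of every node (via double-edge swaps,
target 10× the edge count accepted swaps) and the multiset of edge
weights (permuted over the rewired topology). The empirical p-value is
the plain proportion of simulations with simulated distance ≤ observed
(it can be 0); the (r+1)/(n+1) estimator is available but off by default.
Draws in which a node is disconnected from every seed score +∞ — they
count in the denominator and never undercut a finite observation.
Simulation k derives its RNG stream from `SeedSequence(seed).spawn(k)`,
so results are bit-identical regardless of batch size; the default
schedule is 1000 simulations in batches of 200. Averaging over *seed
genes* (rather than over all nodes) is an interpretation: it is the only
reading under which per-node significance of seed proximity is
meaningful.

## Phenotype statistics

The classifier is a total, deterministic function of the feature flags
(see table in the module docstring). One severe feature with no moderate
abnormality is classed **medium**: the strong class requires two or more
severe features, and a single severe feature is certainly not normal.
Severity is monotone — worsening any feature never moves the class toward
normal (verified by exhaustive enumeration of the feature lattice).
Percentages use half-up rounding to one decimal, matching printed-table
style. Group comparisons use Pearson chi-square without continuity
correction by default (Yates available by flag); an expected cell below 1
annotates a warning but still returns the statistic. Angle comparisons
use tie-corrected Kruskal–Wallis with the chi-square approximation, which
is slightly conservative at n = 20 per group.

The published chi-square of 26.26 for the combined-mutant versus control
comparison is not reconstructible from the printed marginals (the obvious
2×2 table gives ≈ 37.4); the underlying raw table or test variant is not
stated, so this module reports its own statistic and does not target that
number.

## Synthetic data: what it emulates, and what it does not

* **Families** — founder haplotypes i.i.d. Bernoulli at allele frequency
  0.5 (maximally informative markers), meioses with Poisson(L Morgans)
  crossovers placed uniformly on the cM scale — the operational meaning
  of "no interference" — on a default grid of 5000 evenly spaced sites
  over 100 Mbp at 1 cM/Mb. Depth is Poisson (default mean 30, typical of
  the WGS regime the filters were designed for), alt allele depth is
  binomial around the true allele fraction, and GQ is a monotone function
  of depth shrunk by heterozygous imbalance; the `noiseless` preset
  (DP = 60, GQ = 99, exact AD) isolates the detector's logic from the
  noise model. Not emulated: linkage disequilibrium among founders,
  allele-frequency spectra, mapping artifacts, indels — so passing
  recovery tests demonstrate the detector's correctness, not its
  performance on real cohort data.
* **Networks** — Erdős–Rényi background (200 nodes, mean degree 4,
  weights ~U(0.5, 1.5)) with a planted 8-node clique containing both seed
  genes at weights ~U(16, 24): an order of magnitude above background, an
  unambiguous planted functional module. Real functional-association
  networks have heavy-tailed degrees and correlated weights; the planted
  design tests calibration and power of the null machinery, not realism
  of the graph.
* **Phenotypes** — class probabilities default to the integer count
  tables consistent with the published group sizes and percentages
  (e.g. 100/39/13 of n = 152 for the combined-mutant group); feature
  combinations are rejection-sampled until the classifier reproduces the
  drawn class, keeping generator and classifier decoupled.
* **Angles** — Gaussian truncated to (0, 180)°, seven groups of 20. The
  baseline (60° ± 6°) is a typical larval ceratohyal angle scale; single-
  and combined-mutant groups shift by 1–2 SD, the combined-mutant group
  by 2 SD, encoding the qualitative ordering of the published effect.

Every generator is a pure function of (configuration, integer seed).

## Numerical choices

* Haldane inverse uses `log1p` for accuracy near r = 0; the round-trip
  identity holds to 1e−10 over d ∈ [0, 200] cM.
* Empirical p-values are exact fractions of counts; no continuity
  corrections are applied anywhere by default.
* Problem sizes in the test suite (20 family seeds, 5000-site grids,
  200-node networks, 1000-simulation nulls, 100k-meiosis oracle grids)
  were chosen to hold Monte-Carlo error well below the tested tolerances
  while keeping the default test run fast.

## Known limitations

* One nuclear family per pedigree for simulation; deeper pedigrees are
  rejected rather than silently mishandled.
* The IBD caller is a deterministic rule-based detector, not an HMM; its
  breakpoint resolution is bounded by informative-site spacing.
* The ACMG combiner covers pathogenic-side evidence only.
* The network null treats the input network as fixed and error-free;
  uncertainty in network inference is outside the model.
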