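# Methods

`founderscan` reconstructs founder events behind a disease mutation from
phased SNP data: it detects identity-by-descent (IBD) segments, estimates
pairwise degrees of relatedness, clusters carriers sharing a haplotype over
a target locus, extracts each cluster's founder haplotype, and dates the
founder with a gamma model of ancestral haplotype erosion. Because cohorts
of this kind are typically consented patient data that cannot be shared,
the package ships a gene-dropping simulator that reproduces the *structure*
of such a cohort with full ground truth, and every downstream stage is
validated against that truth.

## IBD segment detection

Detection follows the GERMLINE windowed-hashing design. Each chromosome is
cut into consecutive windows of `window_snps` SNPs (default 64); within a
window, haplotypes of distinct samples are bucketed by exact window content
(the byte key doubles as the verification comparison, so output is
collision-free by construction); maximal runs of consecutive matching
windows merge into segments whose endpoints snap to SNP positions; segment
lengths come from linear interpolation of a PLINK-style genetic map, and
segments of at least `min_cm` (default 3 cM) are retained. A per-window
mismatch allowance (`max_mismatch_per_window`, default 0) supports noisy
data: candidate pairs are seeded by at least one exact window and re-scored
by Hamming distance.

Two consequences of windowing matter for interpretation:

* a true shared segment loses up to one window of length at each end
  (mean loss ≈ one window), so reported lengths are slight
  underestimates;
* sharing shorter than `min_cm` plus two windows may be missed entirely.
  The completeness guarantee is therefore stated for identical runs of at
  least `min_cm + 2` windows, with one window of endpoint slack per side.

Mask regions (BED, 0-based half-open) remove or trim segments; trimmed
pieces are re-filtered against `min_cm` so the length contract holds
globally.

## Kinship and degree of relatedness

For each sample pair the IBD1/IBD2 profile is the piecewise count of
distinct shared haplotype pairings along the genome (IBD2 requires two
segments with disjoint haplotype use covering a point). The kinship
coefficient is estimated as

    phi_hat = (0.25 * L_IBD1 + 0.5 * L_IBD2) / L_genome

on the cM scale, and mapped to a degree via d = round(−log2(phi_hat)) − 1
(half-up), realizing phi = 2^(−d−1): d = 1 full siblings, 3 first cousins,
5 second cousins, 7 third cousins. Parent–offspring is recognized first by
IBD1 covering ≥ 95% of the genome with IBD2 ≤ 2% (siblings carry IBD2, PO
essentially none); kinship below 2^(−13) (beyond 11th degree) is classed
unrelated. The cut-points are a declared surrogate for TRIBES' unpublished
internals, evaluated by simulation recovery rather than bit-compatibility.

## Locus networks and founder haplotypes

Samples sharing any IBD segment that overlaps the target locus by ≥ 1 bp
are joined by an edge; samples sharing with no one are omitted. Clusters
are connected components, labelled C1…Ck by decreasing size (ties broken by
smallest sample id) for reproducible reports. Edges between carriers of
different mutations, or carriers lacking their cluster's founder haplotype,
are flagged as discordant — reported, never silently removed (they usually
mark false-positive IBD calls; `drop_flagged` recomputes components
without them as an explicit choice).

Per cluster, the founder haplotype's interval is the intersection of the
member pairs' segments (each pair contributing its longest
locus-overlapping segment, the choice that maximizes core support); the
haplotype itself is the single allele sequence carried by at
least one phased copy of every member across that interval (an autozygous
member that matches on both copies records copy 0 by convention). All
cluster haplotypes are then re-reported over their common interval and the
same SNP set, and SNPs with an identical allele across all founder
haplotypes are pruned: the remainder is exactly what distinguishes founder
events.

## Gamma-method TMRCA

Looking back from each sampled chromosome, recombination erodes the
ancestral haplotype at 1 per Morgan per generation, so each one-sided
length is Exp(g) per Morgan after g generations; a two-sided length (the
mutation interior to the segment) is the sum of two sides. With n
independent lineages (star genealogy) the total length S in Morgans is
Gamma(2n, g), giving the MLE ĝ = 2n/S, a bias-corrected (2n−1)/S variant
behind a flag, and an exact-pivot 95% interval from gamma quantiles —
whose coverage is exact under the model, which the calibration experiment
confirms empirically. Reported generation ranges round the interval bounds
half-up to whole generations; years use a 20-year generation time by
default.

Correlated mode relaxes the star assumption for samples whose lineages
coalesce below the founder (families). Marginal lengths stay Exp(g), so the
point estimate is unchanged, but side lengths of two lineages coalescing t
generations below the present covary by (g−t)/(g²(g+t)) — a closed form
obtained by splitting each side into a private Exp(t) and a shared
Exp(g−t) erosion; the total-length variance is inflated accordingly and
the gamma shape re-matched by moments, widening the interval. With no
coalescence times supplied the mode reduces exactly to the independent
formulas. On Monte-Carlo data with genuinely correlated lineages the
corrected intervals restore ~95% coverage where the independent formula
under-covers (~87% in the bundled test's configuration). Coalescence times
are derived in the pipeline from estimated degrees as t ≈ (d+1)/2.

Dating samples are chosen greedily: one per family (most locus-network
connections, ties by id), then drop samples estimated closer than
`min_degree` (default 6) to any retained sample — approximating lineage
independence.

## The simulator: what it emulates and what it does not

The generator reproduces the study-shaped structure: founder clusters
(each carrier independently g meioses below a founder chromosome,
conditioned on transmitting the mutation — a star genealogy, which makes
one-sided tract lengths exactly Exp(g) and therefore analytically
checkable), relative pairs on minimal connecting pedigrees (full sibs and
descents for odd degrees, an extra descent for even ones; parent–offspring
separately), and unrelated background samples. Recombination is Haldane
(Poisson crossovers, uniform on the cM scale, no interference); meioses
snap crossovers to inter-SNP boundaries. Genotype error is available as
independent allele flips (default 0).

Deliberate non-features, and what that implies: background haplotypes are
drawn site-independently, so there is no background linkage
disequilibrium and essentially no false-positive IBD — passing tests show
the machinery is correct under clean conditions, not that it is robust to
the LD-induced false sharing real panels exhibit (real pipelines handle
that with mask regions, which are supported and tested, but the bundled
masks are synthetic). Star genealogies also mean within-cluster pairs share
*only* the founder tract: genome-wide kinship between cluster members is
far lower than in the real families of the motivating study, where members
are close relatives. Phasing is perfect by construction; phasing error is
out of scope.

Default study conditions (chosen once, a priori): a chr21-like chromosome
of 46.7 Mb / 62 cM; SNP density ~128 per cM so a 64-SNP window spans
~0.5 cM (the window-loss analysis above requires window ≤ ~0.6 cM for 95%
truth coverage; the real study's density, ~1000 SNPs/cM, satisfies this
trivially); five clusters of sizes 22/33/6/3/3 with generational depths
10/8/5/3/4 mirroring the published per-cluster dating ranges; minor allele
frequencies uniform on (0.1, 0.5); mutations planted at fixed hg19-like
positions inside the SOD1 locus (chr21:33,031,935–33,041,243). Genome-wide
degree experiments use 22 chromosomes × 150 cM (≈3300 cM). Experiment
sizes — 20 cluster-recovery replicates, 100 pairs per degree for PO–6th,
1,000 gamma calibration datasets — are the package's chosen problem sizes
for its evaluation suite.

One structural consequence: with a star genealogy the two-sided retained
tract is Gamma(2, g) in Morgans, so a few percent of carriers per cohort
(≈(0.03·g)²/2 each) carry tracts below the 3 cM retention floor and are
necessarily absent from the locus network. Cluster recovery is therefore
judged as a pure bijective correspondence between components and truth
clusters; the networked-carrier fraction (~90–95% at the default depths)
is reported alongside.

## Numerical and degenerate-input choices

* cM interpolation clamps outside the anchored range (no extrapolation);
  anchor positions strictly increase, cM never decreases.
* Degree rounding is half-up; the 2^(−d−0.5) kinship midpoint goes to the
  larger degree number.
* Pair ordering in segments is canonical (lexicographic sample ids), so
  output is invariant to input sample order.
* Empty masks, empty segment lists, and header-only TSVs round-trip
  cleanly; a segment TSV with inconsistent endpoints fails validation on
  read.
* Multiallelic or non-SNP VCF records are skipped with a logged count;
  unphased or missing genotypes are hard errors (the pipeline requires
  complete phased data).
* Autozygous double-matches record haplotype copy 0; extraction with no
  (or more than one) common sequence raises a specific error naming the
  cluster.

## Anchors from the motivating study (not reproducible here)

Several quantities printed by the motivating analysis are properties of
its restricted patient cohort (86 carriers, ~3.5M SNPs) and are **not
reproducible** from synthetic data; they are recorded here only as
descriptive anchors of the analysis shape: 16,414 genome-wide IBD segments
of ≥ 3 cM (1,204 on chromosome 21), IBD sharing over the locus in 954
pairs against 625 expected from pedigrees, unique 350-SNP founder
haplotypes reported over a 481 kb (0.56 cM) common interval, and the three
published TMRCA ranges (3–11, 5–18 and 1–11 generations at a 20-year
generation time). The package's tests validate the same operations on
synthetic cohorts with known truth instead.

## Known limitations

* The locus-network stage treats connected components as clusters; no
  community detection beyond components.
* The correlated-genealogy correction is a moment-matching approximation
  validated by Monte-Carlo, not an exact distributional result.
* Degree estimation above ~7th degree is noise-dominated at realistic
  segment-detection power; estimates are clamped to 1–11 with an
  unrelated class below kinship 2^(−13).
* BCF/indexed access, multiallelic records, genotype likelihoods and
  phasing are out of scope; inputs are phased VCF, PLINK .map, BED masks
  and plain TSVs.
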