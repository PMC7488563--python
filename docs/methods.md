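# Methods

`sweepscan` implements a windowed selection-signature analysis for small
multi-population diploid panels (a few populations of 10–25 animals
each, the typical design of a livestock re-sequencing study), together
with the synthetic-data generator used to validate every stage against
known ground truth.

## Scan statistics

All scans work on biallelic autosomal SNPs with a uniform genetic map
of 1 Mb = 1 cM. Per-site statistics are summarized in non-overlapping
50-kb windows.

**F_ST (cross-population).** The heterozygosity-partition form

    F_ST = ( p̄(1−p̄) − Σ_i c_i p_i(1−p_i) ) / ( p̄(1−p̄) )

with p_i the allele frequency in population i from non-missing calls,
c_i = n_i / Σ_j n_j the relative non-missing chromosome count, and
p̄ = Σ c_i p_i. Concavity of x(1−x) bounds the value in [0, 1]. Sites
monomorphic in the pooled pair are undefined and excluded from window
means. This estimator is *not* the Hudson estimator: its population
expectation under symmetric two-population divergence F is roughly
F/2 / (1 − F/2), so window means are interpreted as relative ranks, not
absolute divergence. The test suite cross-checks the simulator against
a Hudson-style ratio-of-averages estimator, which does recover F.

**CLR (within-population).** A SweepFinder-style composite likelihood
ratio against the genome-wide background site-frequency spectrum (SFS),
built from polarized segregating sites only. At test position x
(50-kb window centres) with sweep intensity α, a site at recombination
distance d Morgans escapes the sweep with probability
p_e = 1 − exp(−α d); its likelihood is
p_e·P_bg(k) + (1−p_e)·P_forced(k), where the forced spectrum puts mass
w on count n−1 and 1−w on count 1, with w the background mean derived
fraction (the hitchhiking haplotype is a random draw from the
population). CLR(x) = 2(max_α ℓ − ℓ_bg), clipped at zero so the
background-only model is always included. Numerical choices: 40
log-spaced α values spanning half-escape footprints of 1 kb–10 Mb;
sites beyond 1 Mb of a test position contribute essentially equally to
both hypotheses and are skipped; p_e is clipped to [1e−12, 1] to guard
sites at zero distance. Under an incomplete sweep (final frequency
0.95) the two-point forced spectrum mismatches counts of n−2, n−3, …,
so CLR can peak one window off-center; the composite score absorbs
this because the haplotype statistics peak on-center.

**EHH / iHS / XP-EHH.** EHH at offset d within a class of n haplotypes
is Σ_h C(c_h,2)/C(n,2) over distinct extended haplotypes spanning the
sites strictly between the focal site and d (EHH(0) ≡ 1; within the
ancestral/derived classes of iHS the focal allele is constant, so this
is the conventional definition). iHH integrates EHH outward by
trapezoids over genetic distance with the selscan v1.2.0a default
behaviour, made explicit and configurable: EHH cutoff 0.05 (trapezoids
only between points at or above the cutoff — the sub-cutoff tail is
excluded), gap penalty 20 kb (a physical gap g > 20 kb scales its
trapezoid by 20 kb/g), gap truncation 200 kb, minor-allele floor 0.05.
A side that reaches the chromosome end before decaying leaves the site
unscored, as selscan does. iHS_raw = ln(iHH_ancestral/iHH_derived),
standardized within 100 equal-width derived-frequency bins; XP-EHH_raw
= ln(iHH_A/iHH_B) over all haplotypes of each population, standardized
genome-wide. Where the ancestral allele is unknown, REF stands in and
the site is flagged. The per-site scans use a numba-compiled
partition-refinement walk; a pure-numpy reference implementation of the
same arithmetic is kept and the tests assert equality to 1e−12.

## DCMS compositing and region calling

Window means (|iHS| and |XP-EHH| are absolute-valued *before*
averaging; CLR is already per window centre) form the statistic
columns: within-run = {CLR, |iHS|} × population, cross-run =
{F_ST, |XP-EHH|} × population pair. Each column's genome-wide
distribution is fitted with a three-parameter skew-normal by maximum
likelihood (method-of-moments start plus a normal start, best
likelihood kept — the likelihood is flat in the shape parameter near
zero and a single start can stall; near symmetry the shape estimate
converges only at rate n^(−1/6) although the fitted distribution itself
converges normally). Upper-tail p-values p = 1 − F(x) are floored at
the smallest positive double. The composite is

    DCMS_i = Σ_s w_s · (−log10 p_{s,i}),   w_s = 1 / Σ_t |r_{s,t}|

with r the Pearson correlation matrix of the −log10 p columns
(diagonal included; Spearman selectable). Windows missing a column use
the available columns with the weight total renormalized. Selection
takes the floor(0.01·n) highest-DCMS windows, ties broken by genomic
order; bookended selected windows merge into sweep regions.

## ROH, F_ROH and hotspots

ROH detection reimplements PLINK v1.90's scanning-window algorithm:
50-SNP windows sliding by one SNP; a window is a hit when it has ≤ 3
heterozygous and ≤ 3 missing calls; a SNP is in homozygous state when
≥ 5% of the complete windows covering it are hits; maximal runs of such
SNPs are kept when spanning ≥ 500 kb and ≥ 50 SNPs. ("Non-overlapping"
window phrasing in descriptions of this analysis is self-contradictory
with PLINK's algorithm; the sliding-window semantics are used because
PLINK is the reference implementation.) PLINK's density and inter-SNP
gap sub-thresholds default to unlimited. F_ROH = S_ROH/L_GEN with
L_GEN defaulting to the 2511.4-Mb cattle autosome length and overridden
by the observed genome span for synthetic data. Per-population F_ROH
comparison uses one-way ANOVA + Tukey HSD (statsmodels) with a
hand-written insert-and-absorb compact letter display. Hotspots are
maximal intervals whose ROH incidence strictly exceeds half the
population's samples, computed by an event sweep over segment
boundaries and verified against a per-basepair counting oracle.

## Population structure

PCA mean-imputes missing calls per site, centers, optionally scales by
sqrt(p(1−p)), drops monomorphic sites and eigendecomposes the sample
covariance. AMOVA partitions pairwise squared Euclidean distances over
raw 0/1/2 genotype vectors (pairwise-complete and rescaled when data
are missing) into among/within components via the standard
distance-based sums of squares, with Φ_ST = σ²_a/(σ²_a+σ²_w);
significance is a label permutation test with the add-one estimator
p = (1 + #{Φ_perm ≥ Φ})/(1 + B), which is never zero. With few samples
per group a random permutation occasionally reproduces the original
partition, so the attainable minimum p is bounded by the partition
multiplicity, not only by B.

## Synthetic data generator

The generator defines the study conditions for every test:

- **Neutral baseline.** Per site, an ancestral allele frequency
  p ~ U(0.05, 0.95); each population draws its frequency from the
  Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F); haplotype alleles are
  sampled independently per site (linkage equilibrium). Defaults:
  2 populations × 24 diploids, 10-Mb chromosomes, one SNP per kb,
  F = 0.05 — sample sizes at the scale of the small multi-breed design
  this package targets, divergence at the low end typical of related
  breeds. About 30% of sites list the derived base as REF so that
  polarization logic is exercised.
- **Sweeps** are phenomenological: the derived allele at the focal SNP
  is lifted to the target frequency (0.95 by default) by recruiting
  random non-carriers, then one carrier haplotype is copied over every
  carrier across a geometric-length interval per side (mean 200 kb),
  mimicking recombination-limited sweep haplotypes. This produces
  exactly the three signal classes the scans respond to — elevated
  differentiation, a high-derived-skewed SFS, and long shared
  haplotypes — without a forward or coalescent simulation, which is
  deliberately not a dependency. Baseline linkage equilibrium means
  background LD is absent; haplotype statistics are exercised solely by
  the injected cores, so passing tests demonstrate detection of
  sweep-like haplotype structure over an LD-free background, not
  performance under realistic background LD.
- **Autozygosity.** Non-overlapping tracts (500 kb + exponential
  remainder, mean 2 Mb) overwrite haplotype 2 with haplotype 1 until
  the per-individual total reaches the target fraction; placement stops
  when the remainder falls below the 500-kb floor, so the constructed
  total is within one floor-length of the target. The floor matches
  the ROH definition's minimum so that every ground-truth tract is in
  principle detectable; recovery studies use a 50-Mb genome so a single
  borderline tract cannot dominate the total.
- **Caller annotations** (FS, rank sums, DP, MQ) are drawn from
  heavy-tailed/normal/overdispersed/mixture distributions purely to
  exercise the quantile hard-filter machinery.

Hard-filter thresholds are recomputed as empirical quantiles of the
data at hand (FS upper 5%; rank sums and DP 2.5% per tail; MQ fixed
floor 30, strict), with realized cut-offs reported so published
cut-offs are recoverable in kind; passing thresholds back freezes them
and makes filtering idempotent. Rank-sum/DP quantiles are computed
after the biallelic/indel filter. The clustered-SNP rule removes every
SNP inside any 20-bp span (positions p..p+19) containing more than 5
SNPs. LD pruning is greedy within 50-SNP windows advancing by 5 SNPs
(the PLINK pairwise-pruning convention), removing the later-positioned
SNP of any pair with genotype r² > 0.1; monomorphic sites count as
r² = 0.

## Problem sizes used by tests and the acceptance script

Sweep power uses 20 replicates of two 10-Mb chromosomes with one
mid-window sweep each (frequency 0.95, 200-kb core, one per
population); power is the fraction of the 40 sweep-containing windows
ranked in the top 1% of the respective DCMS. ROH/F_ROH recovery uses
4 diploids on a 50-Mb genome at target fractions {0.05, 0.10, 0.20}.
Null calibration uses one neutral 10-Mb run (selection fraction and
iHS tail) and 200 shuffled-label AMOVA replicates of 12+12 diploids at
300 kb with 199 permutations. Oracle equivalence covers 50 random ROH
instances up to 2,000 SNPs, 100 random interval sets, and 10⁵ random
frequency/weight draws for the F_ST formula.

## Known limitations

- No background LD in the simulator (above); no demography, mutation
  rate realism, or sequencing error beyond the annotation table.
- The CLR forced spectrum is the two-point projection, not the full
  lineage-sampling model; absolute CLR values are not comparable to
  SweepFinder2 output, only ranks are.
- Skew-normal upper tails underflow for extreme outliers, so −log10 p
  saturates near 308; zero-inflated columns (CLR on short genomes) make
  the skew-normal fit approximate in the extreme tail.
- The ROH detector's length is the SNP-bounded span, so tracts at
  exactly the minimum length can fall just below the floor.
- XP-EHH computes each population's iHH truncation independently
  rather than jointly as selscan does; results agree in rank but not
  byte-for-byte.
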