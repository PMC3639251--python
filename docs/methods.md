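# Methods

`cardiomap` reimplements, against a forward simulator, the genetic-mapping
toolchain used to dissect two heart phenotypes segregating between a
wild-derived, nearly isogenic *Drosophila melanogaster* strain (WE70) and a
laboratory wildtype (*yw*): an elevated arrhythmia index (AI) and a
restrictive-like constriction of the heart tube (reduced systolic diameter,
SD). The package contains four analysis stages — phenotype statistics,
single-feature-polymorphism (SFP) calling, bulked-segregant analysis (BSA)
window scans, and recombinant-inbred-line (RIL) re-sequencing window scans —
plus the simulator that generates every input those stages consume.

## The simulator

**Genome model.** Five chromosome arms (X, 2L, 2R, 3L, 3R) with approximate
*D. melanogaster* euchromatic lengths carry an even marker grid (default
10 kb, ~12,000 markers). Arms are independent linkage units. Alleles are
parental-origin labels (WE70 vs *yw*), which is the resolution every
downstream scan works at.

**Meiosis.** Female meioses draw a Poisson number of crossovers per arm
(mean 1.0 per arm, i.e. a 50 cM arm — close to the observed female map) at
uniform positions, with a fair choice of starting phase. Male meioses never
recombine (male achiasmy, obligatory in *D. melanogaster*): each male gamete
carries one intact parental haplotype per chromosome. Achiasmy halves the
effective map and materially lengthens RIL haplotype blocks; it is not
optional. The X follows standard sex-linked transmission — daughters receive
the father's intact X, sons only a maternal recombinant X. Because the
mapping cross is *yw* males x WE70 females, F1 males carry a full WE70 X,
and F2 females are expected to be 3/4 WE70 on the X — an internal positive
control that both the BSA and RIL scans should (and do) detect.

**Crossing designs.** F2 populations are sib intercrosses of F1s.
RIL lineages start from one F1 pair and proceed by strict full-sib pair
mating; generation 1 is the F2 (heterozygosity 1/2) and heterozygosity then
decays by the classical sib-mating recursion (asymptotic ratio ~0.809 per
generation), reaching >90% homozygosity by generation 12 — ~94-96% in
simulation. An optional per-line survival probability models line loss
during inbreeding (the study founded 200 lines and kept 152); it is off by
default. Whole-chromosome substitution lines are constructed directly
(homozygous WE70 on both arms of chromosome 2 or 3, *yw* elsewhere) rather
than through balancer crosses, which are out of scope.

**Phenotype architectures.** Two genotype->phenotype models:

- *monogenic recessive*: aberrant iff homozygous WE70 at one causal locus;
- *epistatic modules*: aberrant iff **all** loci of at least one module are
  homozygous WE70 (conjunctive within a module, disjunctive between
  modules). The default places one two-locus module on each major autosome
  (one locus per arm), the minimal logic that makes either whole-chromosome
  substitution aberrant while letting a line carrying only part of a module
  complement the other chromosome's substitution line.

Trait means are calibrated to the strains: SD 37 um wildtype vs 20 um
aberrant with 4 um per-fly noise (consistent with the reported group SEMs at
the reported group sizes); AI 0.06 vs 0.28, with larger noise in the
aberrant state and right skew imposed by truncation at zero; DD is SD plus a
positive contraction amplitude (17 +/- 3 um), which makes DD and SD strongly
correlated, as observed. Penetrance defaults to 1 and is a free parameter.
Classification cutoffs (SD < 27 um, the parental midpoint; AI > 0.17) are
configuration values; the study reports no numeric cutoffs.

**Array intensities.** Pooled-DNA hybridization intensity at a probe is the
linear mix of the parental probe means weighted by the pool's WE70 allele
frequency, plus Gaussian array noise — the premise that lets pool allele
frequencies be read back off intensities. Parental arrays are the f=1 and
f=0 cases.

**Pileups.** Low-pass re-sequencing emits Poisson(8) reads per site.
Homozygous sites yield the carried allele, with a 1% per-read chance of
flipping to the other parental allele; heterozygous sites yield each allele
with probability 1/2. By default the genuinely heterozygous sites of the
genome are used. Re-sequenced inbred lines in the study were, however, far
less fixed than 12 generations of sib mating predicts (~1/3 of sites
unfixed per line, attributed to incomplete inbreeding and residual parental
segregation), so the observation model can instead designate a given
fraction of sites as unfixed — site-wise independently by default, or in
contiguous tracts (mean 2 Mb, the ~1/(2g) Morgan scale of residual
identity-by-descent tracts after g=12 generations). The paper-matched
fraction 1/3 is used for the threshold and parameter-recovery experiments;
this choice matters, as discussed below.

## Phenotype statistics

AI is the sample standard deviation of a fly's beat periods divided by its
median period ("index of variance normalized to the median" is ambiguous
between variance and sd; reported AI magnitudes, 0.06-1.22 and
dimensionless, are consistent only with sd/median, so sd it is). It is
scale- and permutation-invariant and requires >= 3 beats. Fractional
shortening is (DD-SD)/DD. Group summaries report n, mean, sd, SEM.
Correlation uses the exact Pearson t test (t = r sqrt(n-2)/sqrt(1-r^2));
regression reports R^2 with its F test (F = t^2 for the same data, asserted
in tests). Between-line variance is the one-way between-group sum of squares
over the total — on simulated panels it converges to
sigma_L^2/(sigma_L^2+sigma_E^2). Extreme-line selection takes the k smallest
and largest line means, ties broken by line id. Two-sided p values
throughout; no multiple-testing correction in this module.

## SFP calling

Raw intensities are floored at 1.0, log2-transformed and quantile-normalized
(mean-of-sorted-columns reference). The per-probe statistic is the SAM
relative difference d_i = (mean_A - mean_B)/(s_i + s0), with s_i the pooled
two-sample standard error and s0 the median of the s_i. The null is the
pooled d over all C(6,3) = 20 balanced label assignments of the 3+3 parental
arrays — including the true labeling, which matches the study's count of 20.
The FDR at a symmetric cut |d| >= delta is the mean permuted exceedance
count divided by the observed count, capped at 1, with no pi0 estimation.
Calling sweeps delta over the observed |d| grid and returns the largest call
set whose smoothed FDR (running minimum over smaller cuts, making the
estimate monotone non-increasing in delta) meets the target; the selected
cut's own raw estimate always meets the target too.

Two estimator properties worth knowing. First, because the 20 assignments
include the true labeling and its mirror, a strongly differentiated probe
contributes 2/20 of itself to the permutation null — the estimate has a
floor of ~0.10 once most true SFPs exceed the cut, which is presumably why a
strong real contrast reports ~11% FDR. Second, at a moderate shift
(4 x array noise, 3v3 arrays) this floor plus the heavy 4-df tails of s_i
make the estimate conservative by roughly a factor of two: the cut that
recovers 90% of true SFPs has realized false-discovery proportion ~0.09 but
estimated ~0.19. Tests therefore check the realized operating characteristic
and estimator conservatism separately from the estimate itself.

## BSA window scan

The pool's WE70 allele frequency at an SFP is
f = (I_pool - I_yw)/(I_WE70 - I_yw), clamped to [0,1]; probes whose parental
log2 contrast is within 0.2 are uninformative and dropped. Profiles are
means over sliding windows of 100 consecutive informative probes (step 1,
never spanning chromosomes; a short chromosome yields one truncated, flagged
window). Both the per-pool departure from the Mendelian 0.5 and the
pool-minus-pool relative frequency are emitted; an intensity-difference mode
exists since the figure axis in the source study is ambiguous between the
two. Significance thresholds are family-wise per genome: pool arrays are
reassigned to pseudo-pools (exhaustively when there are <= 200 assignments,
else sampled), the whole profile recomputed, and the 2.5%/97.5% quantiles of
the permuted genome-wide extrema taken.

## RIL re-sequencing scan

Pileups become genotype calls by site majority (missing on ties or depth
< 2); sites must show both genotypes in >= 3 lines; sites are thinned to one
per 10 kb bin; each site is then oriented to its across-panel major allele
(ties designate WE70). The scan statistic per site is the difference in
major-allele carrier counts between two phenotype groups (six high vs six
low AI, or six wide vs five narrow SD; missing calls count for neither
group), averaged over 100-SNP windows — bounded by +|g1| and -|g2|, with +/-6
the fully penetrant 6v6 extreme.

**Sustained peaks.** Isolated extreme windows are common under drift at this
panel size (single windows reach |5-6| in random 6v6 draws), so both
thresholding and localization use the *span-sustained* statistic: the
highest level maintained by a run of consecutive windows whose genomic span
reaches 10 Mb. The permutation threshold is the 95th percentile, over 1,000
random disjoint 6v6 draws from all lines, of the largest sustained |level|
anywhere in the genome; by construction, ~5% of random draws produce a
callable >= 10 Mb peak at that threshold. Peak calling reports maximal runs
beyond +/- threshold spanning >= 10 Mb. The sustained statistic is computed
exactly with a sparse table of power-of-two sliding minima (vectorized
across permutations), and is verified against a brute-force oracle in tests.

**What the threshold is sensitive to.** With noiseless 12-generation
genotypes the simulated threshold is ~2.9; with the study-matched 1/3
unfixed sites per line it is ~1.0 +/- 0.2 (panel-to-panel). The study's
reported ~1.8 sits between the regimes, consistent with its unspecified
"high confidence" SNP selection having partially depleted unfixed sites.
The package reports the study-matched observation model and documents the
gap rather than interpolating a noise level to match.

**A caveat on major-allele orientation.** At a recessive causal locus the
panel splits into hom-WE70 aberrant lines and non-hom-WE70 others, pinning
the panel allele frequency near 1/2 — exactly where the major-allele
orientation is unstable. Site-to-site flips of "major" self-cancel the
group difference at the causal region and displace the sustained signal to
flanking regions where orientation stabilizes. This is intrinsic to the
proxy (a study that has not sequenced the parents cannot orient by parental
origin) at any panel size. In simulation the parental-origin-oriented
variant (`group_difference_parental`) localizes far better (~80% vs ~30% of
23-line replicates placing the causal locus inside the strongest sustained
peak); the residual failures trace to X-chromosome null peaks, which are
structurally inflated because the cross design fixes X lineages at 3/4 WE70.
Window-level localization at the 23-line scale is therefore unreliable under
realistic observation noise — which mirrors the source study's own inability
to resolve single-gene peaks, and is stated here so that passing tests are
not over-read as evidence the method pinpoints loci on real data.

## What the simulator does and does not emulate

Emulated: the cross structure (including achiasmy and X transmission),
sib-mating fixation dynamics, block-scale linkage, pooled-intensity linear
mixing, Poisson low-pass pileups with error and residual heterozygosity, and
both phenotype architectures with calibrated means and noise. Not emulated:
real probe-level hybridization chemistry (GC effects, cross-hybridization),
segregating variation within the parental stocks, viability selection during
inbreeding, crossover interference and centromere effects, and any video /
image processing (beat-interval series are taken as given). Passing tests
show the pipeline's statistics behave as designed under the stated
stochastic model, not that the biology of a particular array or sequencing
run is captured.

## Numerical and engineering choices

- Every stochastic operation takes an explicit seed or Generator; panels and
  pileup sets derive per-line child seeds deterministically via
  `SeedSequence.spawn`, so runs are reproducible from the manifest alone.
- Intensity floor 1.0 before log2; parental-contrast epsilon 0.2 log2 units;
  genotype-call depth floor 2; window size 100 members, step 1; peak span
  floor 10 Mb; threshold percentile 95; permutation count 1,000 (threshold)
  / 200 (BSA). Grids and sweeps are deterministic; ties in extreme-line
  selection break by line id, ties in orientation designate WE70.
- Degenerate inputs: zero-variance vectors are rejected in correlation
  tests; |r| within 1e-12 of 1 reports t = inf, p = 0; empty SFP call sets
  report an undefined (NaN) FDR rather than 0; chromosomes shorter than one
  window yield a flagged truncated window.
- Problem sizes in tests and the acceptance script (23-line panels, ~12,000
  markers, 9,000 probes, 100-200 replicates) match the study's design scale
  where stated and are otherwise chosen to keep Monte-Carlo error well below
  the asserted tolerances.

## Known limitations

- The group-difference scan inherits the orientation instability described
  above; interpret peak *locations* at arm resolution.
- The FDR estimate is conservative at moderate effect sizes (floor ~0.10
  from the exhaustive permutation set); power statements should use realized
  error on simulated truth, as the tests do.
- Heterozygosity decay on the X is faster than autosomal and panel X allele
  frequencies are asymmetric by design; X-linked thresholds are genuinely
  different from autosomal ones, and the genome-wide family-wise threshold
  is dominated by the X more often than naive intuition suggests.
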