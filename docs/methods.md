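# Methods

## Scope and data model

All statistics operate on a `GenotypeMatrix`: a diploid ALT-dosage matrix
(samples × sites) over biallelic SNPs with per-site chromosome labels and
1-based VCF positions, plus a missing-data sentinel. Phase is discarded on
read: every estimator here (including LD) is dosage-based, which is the
appropriate choice for unphased genotype calls. Multiallelic and non-SNP
VCF records are skipped, not split. Windowing converts internally to
0-based half-open intervals; windows start at 0, advance by the step, and a
trailing region shorter than one window is dropped.

Site filtering keeps a site iff its missing fraction is strictly below the
threshold (default 0.5) and its minor-allele frequency, computed on
non-missing alleles, is strictly above the threshold (default 0.01). Both
inequalities are strict, so boundary sites are removed; the filter report
records counts removed per criterion.

## Diversity

Per site with ALT count *c* out of 2n called alleles, nucleotide diversity
uses the unbiased form π = 2c(2n−c)/(2n(2n−1)). Within a window of L bp and
one population:

- S = sites segregating within that population (≥2 called alleles),
- θ_w = S/(a₁·L) with a₁ = Σ_{i<n} 1/i,
- θ_π = (Σ site π)/L,
- Tajima's D = (Σπ − S/a₁)/√(e₁S + e₂S(S−1)) with the standard 1989
  constants.

n for the constants is the rounded mean called-allele count across the
window's sites — robust to scattered missingness; per-site constants would
be the alternative and give nearly identical values at these missing rates.
Windows with S = 0 report θ = 0 but a null D (the statistic is undefined);
windows with no called sites report all-null. The window denominator is the
full window span in bp by default. Reduced-representation data genotype
only a fraction of each window, so these θ values are calibrated against
the generator's site density rather than against per-bp values from
whole-genome data; a `per_variant` switch divides by the number of
genotyped sites instead. Genome-wide per-population values are unweighted
means over windows (the aggregation is a reporting choice; windowed values
are the primary output).

H_e = mean over dataset-polymorphic sites of 2p(1−p) with p the
population's allele frequency; H_o = mean heterozygote fraction over the
same sites.

## FST

Two estimators, both accumulated as ratio-of-sums (never mean-of-ratios,
which is unstable in sparse windows):

- **Hudson** (Bhatia parameterisation): per site
  N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
  D = p₁(1−p₂) + p₂(1−p₁), FST = ΣN/ΣD, with nᵢ called allele counts.
  Unbiased under the island model, hence the estimator used in all
  analytic recovery checks (on Balding–Nichols pairs with equal F it
  estimates F itself).
- **Weir–Cockerham (1984)**: the two-population variance components a, b, c
  from genotype counts (using observed heterozygosity), FST = Σa/Σ(a+b+c).
  This is the default, matching common practice for published pairwise
  tables; on balanced designs the two estimators agree closely.

Per-window values are reported as computed (small negatives included);
only the rendered tables clip to [−1, 1]. Sites without data in either
population are skipped.

## PCA, p-distance, neighbour joining

PCA mean-imputes missing dosages per site, centres, drops monomorphic
sites, and by default applies Patterson scaling 1/√(2p̂(1−p̂)); scores and
variance fractions come from the SVD of the scaled matrix. `center_only`
reproduces generic PCA.

p-distance between individuals i, j is Σ|gᵢ−gⱼ|/(2m) over the m sites
called in both. NJ is the Saitou–Nei agglomeration with the
Studier–Keppler Q criterion; ties break on the lowest index pair, negative
branch lengths are clamped to zero without redistributing the deficit, and
the result is an unrooted topology rooted at the final three-way join. On
additive inputs the tree reproduces the input path lengths exactly (this is
tested against scikit-bio's independent implementation).

## Directional migration networks

For each ordered pair (a, b), a hypothetical migrant pool takes per-site
frequency (p_a+p_b)/2. Differentiation between the pool and the recipient
b — Nei Gst or Jost's D over the two demes {b, pool}, summed over sites
before ratios; Jost's D carries the two-deme n/(n−1) = 2 factor — is
converted to a raw rate into b: (1−d)/d, or ((1/d)−1)/4 for the Nm
transform. Lower pool-vs-recipient differentiation ⇒ more migration into
the recipient; this orientation follows the published description of the
directional relative-migration method, and because it is the method's
least-documented convention it is called out here deliberately. The full
directed matrix is divided by its maximum (strongest edge ≡ 1), edges under
the filter threshold (default 0.2) are flagged hidden but never deleted,
and a zero-differentiation edge is capped at the largest finite rate before
normalisation. Bootstrap support resamples individuals with replacement
within populations; CIs are percentile 2.5/97.5. The plug-in (uncorrected)
estimators are used; the Nei–Chesser small-sample correction is not
applied. Note the bootstrap distribution of a normalised rate is biased
upward relative to the point estimate (resampling attenuates
differentiation), so the CIs summarise stability, not coverage of the point
value; asymmetry inference uses the CI of the difference m[a→b] − m[b→a],
which is centred.

## LD

r² is the squared Pearson correlation of dosage vectors over samples
called at both sites (the composite measure; no phasing or EM). Decay
curves average r² in half-open distance bins over intra-chromosome pairs
within the maximum distance, with a seeded subsample cap (default 10⁶
pairs). Pairs with an undefined r² (monomorphic site among the shared
samples, <2 shared samples) are excluded from the bins.

## Selection scan

ROD = 1 − θ_π(introduced)/θ_π(source) per window, null when the source
window has zero diversity. Outlier flags take the empirical tails by rank:
the ⌈fraction·n⌉ most extreme non-null values, with boundary ties all
included (conservative toward more candidates). A window is a candidate
when (FST in the top tail OR ROD in the top tail) AND the introduced
population's Tajima's D is in the bottom tail AND negative; the
`require_tajima` flag exposes the OR-only reading. Overlapping and
book-ended candidate windows merge into maximal regions; genes from a GFF3
(1-based inclusive, converted to half-open) overlap a region when the
intervals share ≥1 bp, and a gene counts once globally.

The positive control injects a hard-sweep pattern into a 20 kb block: every
introduced-population genotype becomes homozygous reference except one
singleton heterozygote per site. Diversity collapses (ROD ≈ 0.95) while
every site stays segregating with an all-rare frequency spectrum, so
Tajima's D is strongly negative — the post-sweep signature. A block forced
to exactly zero diversity would instead have S = 0 and an undefined D, and
no window could satisfy the candidate rule; the singleton construction is
the faithful "swept region" compatible with it.

## Synthetic data

`simulate_unlinked` draws, per site: ancestral frequency p₀ ~ U(0.05,
0.95); each native population's frequency from the Balding–Nichols Beta
(p₀(1−F)/F, (1−p₀)(1−F)/F) (F → 0 degenerates to p₀); the introduced
frequency from a binomial founder draw of 2N_f alleles at the source
frequency followed by binomial drift for a few generations at the
established size; genotypes Binomial(2, p) under HWE; i.i.d. missingness.
Defaults mirror the study design being emulated: sample sizes 24/14/18/18,
native F = (0.07, 0.05, 0.10) giving pairwise FST on the 0.04–0.12 scale,
N_f = 10 founders, 2 post-founding generations at size 500, 5% missingness,
5 000 SNPs spaced 200 bp apart on two chromosomes (a reduced-representation
density that fills 10 kb windows with ~50 sites). The founding parameters
are scenario knobs, not estimates — no demographic parameters exist for the
real invasion. Truth records carry every latent frequency so downstream
tests are parameter recovery: e.g. one generation of founding by N_f
diploids multiplies expected heterozygosity by exactly 1 − 1/(2N_f).

What the generator does not emulate: linkage between the unlinked sites
(use the Wright–Fisher flavour), gene flow after founding, selection,
genotyping error beyond missingness, and the site-frequency spectrum of
real RAD data (mid-range ancestral frequencies give few rare variants, so
genome-wide Tajima's D is positive here while the study system's was near
zero or negative). Passing tests therefore demonstrate estimator
correctness and the relative, structural signals — not absolute agreement
with any real dataset's table values.

`simulate_linked` is a forward diploid Wright–Fisher population on a single
chromosome: each offspring haplotype recombines one parent's two haplotypes
with Poisson(rec·L) uniform crossovers, and Poisson(mu·L) mutations per
generation flip the allele at a uniform site (finite sites; a repeat
mutation toggles back, a small downward bias on diversity at high mu).
Defaults N = 100, L = 20 kb, mu = 1.25e-5 (θ = 4Nμ = 0.005 per site), rec =
1e-4, 10N burn-in generations from a monomorphic start (equilibrium
diversity reaches 1 − e^{−5} ≈ 99% of its asymptote), 20 sampled diploids.
These sizes keep a replicate in a few seconds on one core while the
equilibrium checks (mean π within 15% of θ, Tajima's D near 0) remain
sharp.

## Numerical and degenerate-input choices

- Missing genotypes are a sentinel (−1) in an int8 matrix; every estimator
  recomputes called-allele counts rather than imputing (PCA's mean
  imputation is the single, documented exception).
- Quantile flags are rank-based, not interpolation-based, so tie behaviour
  is explicit.
- An empty post-filter matrix is returned with a warning, not an error;
  downstream stages raise individually if they cannot proceed.
- Fixed seeds make both generators, the migration bootstrap, and the LD
  pair subsample bit-reproducible; pipeline reports contain no timestamps,
  so a report directory is byte-identical across runs of the same config.

## Known limitations

- Genome-wide θ and D are means over sliding (hence overlapping,
  autocorrelated) windows; no variance is attached to them.
- The Wright–Fisher simulator is single-population and single-chromosome;
  LD contrasts across populations reuse independent replicates.
- Migration networks give relative, not absolute, rates, and the bootstrap
  bias noted above means their CIs should not be read as coverage
  intervals.
- Gene annotation uses only `gene` features from the GFF3 and intersects
  intervals; no transcript-aware logic.
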