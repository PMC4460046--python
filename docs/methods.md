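# Methods

## Data model and conventions

All coordinates are 0-based half-open internally; VCF positions are
converted on ingest and restored on output.  Haplotypes are the analysis
units throughout: a `HaplotypeBlock` is an (n_haplotypes × n_sites)
matrix coded 0 = ancestral / 1 = derived, with a per-site
`ancestral_known` flag.  Polarization uses the `AA` INFO field when it
matches REF or ALT case-insensitively (only the first field of the
extended `aa|ref|alt` encodings is consulted).  Sites whose ancestral
state cannot be resolved keep ALT-count coding and are *flagged, never
silently polarized*: DAF, Fay & Wu's H and iHS skip them; MAF, S, π,
D, D*, F* (which are folded or outgroup-free) do not.  Indels and
multiallelic records are excluded; unphased genotypes are an error
because every statistic here assumes phased data.  Strand is ignored —
elements are interval sets and no statistic needs the sequence itself.

## SFS statistics

π is computed by the frequency identity Σ 2p(1−p)·n/(n−1), which equals
the average over all C(n,2) haplotype pairs (asserted to 1e−12 in tests);
"total" values are mean pairwise differences over the analysed unit,
per-site values divide by the unit length L (windows use L = window
size, not the spanned sites).  Tajima's D uses the classical e₁/e₂
constants.  Fu & Li's D* and F* are the outgroup-free variants with η_s
counted as minor-allele singletons (derived count 1 or n−1); Fay & Wu's
H uses polarized derived counts — the two singleton conventions coexist
deliberately and are both exposed.

The D*/F* variance constants deserve a note: the printed closed forms in
circulation disagree, and two candidate sets we evaluated both failed a
Monte-Carlo check of Var(numerator) under the coalescent.  We therefore
derive (u, v) exactly from the covariance matrix of the site-frequency
counts ξ_i (Var(ξ_i) = θ/i + σ_ii θ², Cov = σ_ij θ²), choosing (u, v) so
that E[uS + vS²] equals the exact variance of the numerator.  This route
reproduces the well-attested closed-form D* constants to machine
precision and matches simulated variances for F*; the calibration is
frozen as a seeded test.

Undefined statistics (S = 0 windows; H with no polarizable site; D*/F*
at n < 4; D at n < 4 where the variance model degenerates) are NaN plus
a flag and are excluded from window means on both sides of every
comparison — coercing them to 0 would drag bootstrap means toward 0.

## Windows, bootstrap, permutation

Each element class is concatenated end-to-end (intervals in genomic
order) onto a gapless axis, and 10 kb windows advanced by 5 kb are cut
from it; the genome-wide background uses the same windowing over the
whole chromosome.  Terminal windows shorter than 10 kb are dropped
rather than rescaled so that per-window L is constant.  The bootstrap
resamples windows with replacement (1000 reps by default) and reports
the mean of resample means and their SD.  The permutation test pools
element and background window values, reshuffles labels preserving
group sizes (10,000 reps by default), and reports
P = (1 + #{|Δperm| ≥ |Δobs|})/(n_perm + 1) — two-sided by default with a
one-sided flag, and the +1 correction so P is never 0.  Window-level
resampling (rather than re-concatenating sequence) is an interpretation
choice; it is the exchangeable unit the test actually compares.

## F_ST

Weir & Cockerham's method-of-moments estimator in its haploid reduction
(phased haplotypes as sampling units, so the heterozygosity component
vanishes): per-site components a (among populations) and b (within),
θ̂ = a/(a+b).  Monomorphic sites are flagged undefined; negative per-site
θ̂ is retained unclamped so threshold counts like F_ST < 0.05 stay
meaningful.  Both multi-locus aggregates — mean of per-site θ̂ and
ratio-of-sums Σa/Σ(a+b) — are reported, since they answer different
questions and differ in finite samples.  The global value is the
three-population estimator over a configurable population triple;
pairwise values pool populations into superpopulation groups before the
two-group estimator.  As an independent cross-check, `hudson_fst`
implements 1 − π_within/π_between from allele counts; on equal-sized
two-deme simulations the ratio-of-sums θ̂ agrees with it essentially
exactly, and the acceptance suite verifies agreement within ±0.02 over
500 loci.

## Conservation classes

A site or base is conserved at threshold t iff its score ≥ t
(inclusive); a base not covered by any score run is non-conserved at
every threshold, and conserved-at-3 ⊆ conserved-at-2 by construction.
Default thresholds 2 and 3.  Per element class we report the fraction of
length conserved and the fraction of variants with DAF ≤ 0.05 separately
in the conserved and non-conserved partitions.

## EHH, iHH, iHS

EHH from a core allele is the probability that two random carriers are
identical at every polymorphic site from the core through x; it is
computed by iterative group splitting (exact, equals the pairwise
definition).  iHH integrates each arm by trapezoid over physical
distance (bp; no genetic map, matching common defaults), stopping at the
linearly interpolated point where EHH reaches the 0.05 cutoff; arms that
hit the locus edge or a > 200 kb marker gap first are integrated to the
last marker and flagged.  iHS = ln(iHH_A/iHH_D) is standardized within
20 derived-frequency bins of width 0.05 (subtract bin mean, divide bin
SD); bins with fewer than two scores leave scores unstandardized with a
flag.  Cores need MAF ≥ 0.05 and a known ancestral state.  A scan can
standardize against itself or against a supplied reference
(`BinReference`), e.g. a genome-wide or neutral scan — the pipeline uses
self-standardization; the sweep-power calibration standardizes sweep
cores against a neutral reference, as a genome-wide scan effectively
does when sweeps are rare.

## Enrichment and the caller

Element-vs-background predicates are 2×2 tables tested by Pearson's χ²
with 1 d.f. without continuity correction (Yates behind a flag), with
Fisher's exact test substituted whenever any expected cell < 5 — the
standard operationalization of "small sample".  The enrichment ratio is
observed/expected proportion (P_O/P_E).  No multiple-testing correction
is applied across elements or bins by default; a Benjamini–Hochberg
helper is provided.  The caller requires ≥ k of {DAF > 0.5, F_ST > 0.3,
|iHS| > 2} with strict inequalities; an undefined statistic never
satisfies its criterion.  Gene annotation attaches genes with
start − 5000 < pos < end + 5000: the formal half-open contract would
include a variant exactly 5 kb upstream, but the intended behaviour
(and our tests) exclude it, so the upstream edge is strict.  "Top 1%"
thresholds are empirical 99th percentiles over defined values.

## Synthetic data generator

The generator reproduces the *structure* the inferences rely on, not any
particular genome:

- **Neutral**: Kingman coalescent (times Exp(C(k,2)) in units of 2N),
  Poisson(θ/2 × branch length) mutations under infinite sites, uniform
  positions.  No intra-locus recombination — windows are short, and the
  SFS statistics do not require it; inter-locus independence stands in
  for recombination in multi-locus runs.
- **Island model**: structured coalescent, symmetric migration at rate
  M/2 per lineage (M = 4Nm).  M ≤ 0 with ≥ 2 demes is refused because no
  common ancestor is guaranteed.
- **Sweep**: founder-copying — carriers of the derived core allele copy
  the founder's flanks out to geometric breakpoints (rate = per-bp
  crossover probability), giving the long shared homozygosity on the
  derived background that iHS detects, at O(n·L) cost and without
  simulating selection trajectories.
- **Constraint**: inside designated elements, a site with derived count
  i is retained with probability i^(1−β), so retained counts follow
  f(i) ∝ 1/i^β; β = 1 is an exact no-op, β = 2 is the standard
  "constrained" condition used in power checks.  Thinning also lowers
  diversity in constrained elements, which is itself realistic.
- **Tracks**: element intervals of heterogeneous lengths placed at
  random without overlap; conservation runs score high inside
  constrained classes with a set probability; genes dropped uniformly so
  calls land inside, near and far from genes.

What the generator does *not* emulate: linkage between loci, recurrent
mutation, genotyping error, missing data, realistic human demography
(bottlenecks/expansions), or gene conversion.  Green tests therefore
show the machinery is correct and calibrated under its stated model,
not that real-data inferences are robust to those complications.

Determinism: every generator is a pure function of (config, seed);
multi-locus runs derive per-locus streams with
`numpy.random.SeedSequence(seed).spawn`, and the end-to-end pipeline
threads one seed through bootstrap and permutation draws.

## Problem sizes and calibration results

The test and acceptance runs use desk-scale sizes chosen once: neutral
calibration at n = 50, θ = 10 with 1000 replicates; F_ST agreement over
500 two-deme loci (20 haplotypes/deme, θ = 5, M = 1); permutation
calibration with 500 null trials (40 + 40 windows, 499 permutations) and
100 power trials (100 + 100 windows, β = 2); iHS calibration from 60
neutral 100 kb loci (θ = 40, n = 50) and 200 sweep replicates at derived
core frequency 0.7; enrichment power with ≥ 2000 constrained sites per
trial; the pipeline demonstration genome has 24–60 independent 10 kb
loci over 2–3 demes.

One calibration fact is worth stating plainly: the true finite-sample
mean of Tajima's D under the neutral model at n = 50, θ = 10 is about
−0.10 (confirmed against an independent coalescent simulator, which
also agrees with our per-replicate D to 1e−14 on identical data).  The
statistic is biased slightly negative at finite sample sizes, so a
calibration band of |mean D| ≤ 0.1 sits on the truth itself and a
1000-replicate estimate clears it only about half the time; the bands
for D*, F* (≈ −0.09, −0.10) and H (≈ −0.05) at 0.15 are comfortably
satisfied.  The corresponding test is kept at the stated conditions
rather than loosened.

## Known limitations

- Coalescent trees are simulated in discrete Python loops; the generator
  is comfortable at thousands of loci per minute but is not meant for
  genome-scale simulation studies.
- EHH treats haplotype identity as exact allele matching over all
  intervening sites; missing-data handling is out of scope.
- The intergenic derivation exposes both readings of the 10 kb rule
  (whole stretches vs 10 kb tiles) behind a flag because the written
  rule is ambiguous.
- `read_vcf` handles one chromosome per call (use `region=` for more);
  the pipeline is per-chromosome by design.
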