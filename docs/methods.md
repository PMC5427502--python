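# Methods

This note documents the models and procedures implemented in
`tedosage`, the defaults that matter, the design choices that were
genuinely open, and what the synthetic-data validation does and does
not demonstrate.

## Coordinate conventions

Internally all intervals are 0-based half-open. Every user-facing
report is 1-based inclusive. A deletion junction is written
`(donor, acceptor)`: donor is the last retained consensus base before
the deletion and acceptor the first retained base after it, so the
deletion removes bases `[donor+1, acceptor−1]` and a full-length
element is exactly the variant with an empty junction set. Junctions
are normalized to their leftmost equivalent position: while the base at
the donor equals the base just before the acceptor the junction can
slide one position left without changing the derived sequence
(microhomology), so the leftmost representative is the canonical name
under which independent reads are merged. Left-alignment makes exact
(0 bp tolerance) KP classification well-defined.

## Consensus alignment

Reads are aligned to each TE family consensus independently (mates are
not paired: on a ~3 kb reference with ~300 bp inserts, pairing adds no
junction information). Candidate placements come from an exact k-mer
index (default `k = 15`); a whole-read placement within the per-segment
mismatch budget (default rate 0.04) is reported as CONTIGUOUS, ties
resolved to the smallest consensus start. Otherwise a two-anchor split
is sought: a prefix anchor seeded by the read's first k-mer and a
suffix anchor seeded by its last k-mer, in increasing consensus order
with a gap ≥ 2 bases, each anchor at least `min_overhang = 12` bases
(the conventional minimum splice-junction overhang of spliced
aligners). The best split point minimizes total mismatches; among
equal-score placements the smallest deletion, then the leftmost donor
wins. Junction base content is never scored — novel and non-canonical
junctions are treated identically. Reads shorter than k, and reads
fitting neither model (for example reads straddling an insertion
boundary in the source genome), are UNALIGNED and excluded.

Novel junctions are therefore only detectable when both anchors contain
an intact seed k-mer, i.e. at anchors ≥ k = 15. Guided junctions close
that gap: each guided junction is materialized as a derived sequence
with the deletion applied, and unplaced reads are realigned against it;
a contiguous placement spanning the junction point with both flanks
≥ `min_overhang` becomes a split alignment with that junction.
Quantification runs two passes — novel discovery first, then
realignment of unplaced reads with all retained junctions supplied as
guided — so junction support is not biased against short anchors. The
KP-like junction (default donor 807, acceptor 2561 on a 2,907 bp
P-element-like consensus; configurable, and synthetic defaults rather
than database assertions) is guided from the start, so its
presence/absence call does not depend on de-novo discovery.

Per-base depth counts alignment segments covering each consensus base;
skipped spans of split reads contribute zero, and the depth sum equals
the summed aligned segment lengths exactly. Normalized coverage divides
the mean consensus depth by the genome mean depth, estimated as
background-aligned bases over background length (mapped-bases/length
rather than a per-site average — the two differ only at unmappable
sites, which the synthetic background lacks).

## Variant model and EM abundances

Identical left-aligned junctions are merged with summed support. Novel
junctions require ≥ 2 supporting split reads (suppressing chimeras from
single sequencing errors); guided junctions are retained at any
support, including zero. Candidates are the full-length element plus
one single-junction variant per retained junction — multi-junction
variants are not phased, since 100 bp reads cannot connect junctions
kilobases apart; class proportions are therefore per-junction classes.

Abundances come from an EM estimator over fractional read assignment.
A split read is compatible exactly with the variants carrying its
junction; a contiguous read with every variant whose retained region
contains its interval; reads compatible with nothing are excluded
rather than forced onto the full-length class (which would inflate it).
The generative model treats a variant with depth θ as shedding reads
uniformly over its *effective* start positions

    ℓ_eff(v) = derived_length(v) − r̄ + 1 − 2·(min_overhang − 1)·#junctions,

where r̄ is the mean aligned read length: a copy of length L yields
reads from only L − r + 1 positions, and junction-spanning starts whose
anchor would fall below `min_overhang` cannot be observed. The E-step
assigns each read ∝ θ over its compatible set; the M-step sets
θ = assigned bases / ℓ_eff. Abundances are thus interior per-copy depth
units, and read mass is conserved exactly: Σ θ·ℓ_eff = total compatible
aligned bases. Normalizing by the raw derived length instead would
systematically underestimate short deletion derivatives (a ~1,154 bp
KP-like variant loses ~9% of its apparent depth, and the shared-read
reassignment amplifies the deficit to several percentage points of
class proportion); the effective-length model is the same correction
RNA-seq isoform quantifiers apply, and it removed that bias in the
validation grid. The EM initializes uniformly, asserts a non-decreasing
mixture log-likelihood at every iteration, and stops at a relative
log-likelihood change below 1e-6 (200 iterations maximum;
non-convergence is flagged, with the last iterate returned). Reads are
grouped into compatibility classes first, so the EM cost is independent
of library size.

The abundance filter retains a variant iff its abundance is ≥ 1%
(boundary inclusive) of the most abundant variant — the conventional
minimum-isoform-fraction cutoff — and records every filtered variant
with a reason; zero-abundance variants (e.g. a guided junction with no
read support in a TE-free strain) are always filtered. Classification:
FULL_LENGTH for an empty junction set; KP when the single junction
matches the left-aligned KP reference junction exactly (tolerance
configurable); OTHER otherwise.

## Dosage estimators

All estimators are per average sequenced haploid genome, so they are
mutually commensurable: assembly total copy number is Σ abundance over
the genome mean depth; full-length copy number likewise for the
FULL_LENGTH class; class proportions are abundance fractions over
retained variants; `FP/KP = (FL + 0.01)/(KP + 0.01)` with the 0.01
pseudocount keeping the ratio finite and positive when either class is
absent; annotation totals count insertion rows and annotation-weighted
copy number sums their frequencies (weighted ≤ total, with equality iff
every insertion is fixed). Missing estimators propagate as missing —
strains drop out of exactly the association models that need the
missing value, never silently becoming zero. Known bias: background
depth is slightly underestimated because reads straddling insertion
sites align nowhere, so assembly copy numbers run a few percent high at
heavy TE loads (~+10% at 40 insertions on a 40 kb background); this
leaves truth correlations ≥ 0.99 and does not affect normalized
coverage, whose mean absolute relative error stays ≈ 3% across the
validation grid.

## Association models

Atrophy is Bernoulli per female with a logit link. Models always
include experimental block as a random intercept; paternal strain can
enter either as a second random intercept or as a categorical fixed
effect (reference level dropped) — the latter is used for the
heritability comparison, where with S strains the block-only null and
the strain-fixed alternative differ by S − 1 parameters, so
ΔAIC = −(χ² − 2(S−1)).

Fitting maximizes the Laplace-approximated marginal likelihood: for
fixed random-effect SDs, a joint Newton step over (β, u) finds the
penalized mode (the PIRLS convention of lme4's `glmer`), and the
marginal log-likelihood is the penalized objective corrected by half
the log-determinant of the u-block curvature; the outer optimizer works
on log σ (bounded scalar search for one factor, Nelder–Mead for two).
With a single random factor the likelihood factorizes over groups and
the reported value is refined by adaptive Gauss–Hermite quadrature (25
nodes, centered on the conditional modes and scaled by the conditional
curvature), which agrees with a 201-node fixed-grid oracle to ~1e-13.
With no random factors the fit reduces exactly to ordinary logistic
regression. Fits are deterministic given the data (β starts at 0, each
σ at 1). Each variance component counts one parameter toward
`AIC = −2·LL + 2·(p + #variance components)`, and the AIC identity is
asserted on every fit. Complete separation and optimizer failure are
flagged on the returned fit, never raised silently; rank-deficient
designs raise an error naming the collinear columns.

Nested comparisons report χ² = max(0, 2ΔLL), the upper chi-square tail
at the parameter-count difference, ΔAIC, and the sign of the focal
coefficient. Variance-component LRTs use the naive chi-square reference
without a boundary-mixture correction, which is anti-conservative for
that specific case (standard drop-in-deviance practice; fixed-effect
LRTs are unaffected). The association scan fits, per focal estimator, a
null model (block random intercept plus any baseline covariates, e.g.
hobo coverage) against the alternative adding the estimator as an
untransformed fixed effect (scaling available by flag), complete-case
per estimator, with constant estimators flagged and skipped; an
exclusion list supports outlier sensitivity reruns, warning (not
failing) on absent strain names. The strain filter retains strains with
≥ 20 females in each of ≥ 2 blocks; the pooled reading (≥ 2 blocks and
≥ 20 females in total) is available by flag, since an inclusion rule
stated as "at least 20 females in two blocks" admits either reading.
Strains at 0% or 100% atrophy are retained —
separation is absorbed by the model unless strain itself is a term, in
which case the fit is flagged.

## Synthetic data: what it emulates and what it does not

Strain genomes are diploid: a uniform-random background (no repeats, so
TE-derived reads are unambiguous at k-mer scale and the estimators are
isolated from mappability confounds) with insertions at distinct sites.
An insertion configured with frequency f is fixed on haplotype 1 and
present on haplotype 2 with probability f, the simplest model in which
insertions segregate within an inbred line and weighted copy number
falls below total copy number; its annotation frequency — the fraction
of chromosomes carrying it — is accordingly (1 + f)/2, reported with
optional Gaussian jitter (clipped to (0, 1]). Sequencing draws read
pairs uniformly per haplotype with Normal fragment lengths (truncated
below at the read length) and i.i.d. substitution errors; expected
sequenced bases are depth × background length, split equally between
haplotypes, and read names encode the origin haplotype and fragment for
truth tables. Phenotypes follow the logistic model above with block and
strain intercepts drawn once per level. Defaults: 100 bp reads,
300 ± 30 bp inserts, 0.2% substitution rate, 30× depth, and a phenotype
design of 2 of 9 blocks per strain at 30 females per strain × block —
read length and depth are configuration choices (typical resequencing
values), not facts about any particular dataset.

Not emulated: realistic error profiles (indels, quality decay), PCR
duplicates, GC bias, reference mappability, nested or adjacent TE
insertions, and multi-junction derivatives. Passing validation
therefore demonstrates correctness of the estimators under their
generative assumptions — unambiguous TE origin, substitution-only
noise, isolated insertions — not robustness to the full messiness of
real libraries, where mappability and non-uniform coverage add error
that these tests cannot see.

## Validation study designs

Chosen once, as the package's own experimental design:

* **Variant recovery** — FL:KP mixtures at proportions 0.1–0.9 over 20
  total copies (integer KP counts at every grid point; a typical
  P-element load for wild-derived genomes) on a 25 kb background at
  30×; 50 replicates. KP presence/absence over 18 strains (half
  carrying 1–3 KP copies) mirrors a PCR-validation-sized panel.
* **Dosage grid** — copy numbers 0–40 in steps of 2 at frequency 1 on a
  40 kb background; annotation tables at jitter 0.05.
* **GLMM calibration** — 30 strains × 2 of 6 blocks × 30 females,
  σ_block = 0.5; 500 null simulations for type-I error, 100 at
  0.2 logits/copy (copy numbers 0–20) for power.
* **Outlier construction** — twelve strains whose atrophy proportion
  rises gently with copy number (0.05 + 0.01·CN over CN 2–24) plus one
  zero-dosage strain at 100% atrophy, 40 females each: the pooled fit
  is significantly negative, exclusion makes it significantly positive.

Background lengths and depths are scaled so each experiment remains a
desk-scale computation; the truth-recovery contracts (±0.05 proportion
error, r ≥ 0.95, ≤10% relative error) are asserted at these sizes.

## Numerical choices and degenerate inputs

Alignment tie-breaks are fully deterministic (documented above), so
reruns are byte-identical; the pipeline manifests record SHA-256
checksums per stage, and a single run seed fans out to per-stage seeds
by fixed SHA-256 derivation so stages are independently reproducible.
Zero-TE strains quantify to zero-abundance catalogs and zero coverage
without error; empty candidate sets yield empty catalogs; an all-zero
abundance vector retains nothing. The EM treats an empty alignment set
as all-zero abundances, not an error. σ estimates are bounded to
[1e-4, 30] on the SD scale; a boundary optimum reproduces the plain
logistic fit to optimizer precision. The FP/KP pseudocount, abundance
filter boundary (inclusive ≥), and the binomial truncation of fragment
lengths are all exact as specified above.

## Known limitations

* One junction per read: reads spanning two deletions of the same
  element do not align (read length ≪ inter-junction distance makes
  this rare; it would bias against closely spaced double deletions).
* Novel junctions need ≥ 15 bp anchors (seed length) even though the
  split model accepts 12 bp; only guided junctions reach the 12 bp
  floor. Extremely low-support novel junctions near consensus ends can
  be missed.
* Assembly copy numbers inherit a small positive bias at heavy TE loads
  from the background-depth estimate (above).
* The association LRT is asymptotic; with ~30 strains its type-I error
  is near nominal (validated) but per-strain covariates make the
  effective sample size the strain count, not the female count.
* All copies of a family collapse onto one consensus: per-insertion
  genotypes, insertion sites, and position effects are out of scope.
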