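# Methods

This note records the model, its assumptions, the defaults, and the design
choices made where the procedure was genuinely open.

## The weighted genotype distance

Two variant call sets are compared over the union of their called
positions; a position called in neither sample is homozygous reference in
both and excluded, which makes the normalizing constant C_ij
pair-dependent. Treating absent calls as hom-ref is what gives the metric
its false-negative sensitivity: a missed common variant becomes a
disagreement against most of the panel.

Genotypes are unordered allele pairs over {A,C,G,T}; A/G and G/A are the
same genotype. Only diploid SNV genotypes are supported: indels, symbolic
alleles, half-calls and ploidy ≠ 2 are dropped on input (multiallelic SNV
records are resolved through the sample's GT). Records failing FILTER are
excluded by default, mirroring the exclusion of known technical artifacts
from reference call sets; a flag keeps them.

Genotype frequencies come from the reference panel: f(g) = count(g)/n,
with individuals uncalled at a site counted as hom-ref. Unseen genotypes
get f = 1/(n+1), which caps any single weight at n+1; the same floor
applies to hom-ref at sites where every member carries a variant, keeping
all weights finite. At sites the panel does not list, hom-ref has f = 1.

### Exchangeable (leave-pair-out) weighting

When a compared sample is itself a panel member its genotypes are inside
the counts, which systematically lowers the weights of its shared rare
genotypes relative to an external sample's: a doubleton agreement between
two members weighs ~n/2·(1±1/n) while the same configuration involving an
external sample weighs ~n. Since the SDS standardizes an external sample
against member-derived statistics, this asymmetry becomes a bias of order
1/n in IQR units — negligible for panels of ~10³ individuals, visible for
the ~10² panels this package simulates.

The default therefore removes the two compared samples' own copies from
the counts: each sample's frequency is the count among panel individuals
*excluding the pair*, over the unchanged denominator n, floored at
1/(n+1). For two external samples this is exactly the plain rule, and the
plain rule is always available via `leave_one_out=False`. With this
correction, fresh Hardy–Weinberg draws from the panel's frequencies score
SDS 0.0 ± 0.13 against the member-calibrated curve on the default
synthetic panel.

The dissimilarities satisfy symmetry, identity and boundedness exactly;
the triangle inequality is *not* guaranteed with pair-dependent weights
and is checked empirically on synthetic data (violations, when present,
are marginal) — no algorithm in the package relies on it.

## Non-metric MDS

The 2-D embedding minimizes the normalized squared stress
S = Σ(d̂ − ‖φi − φj‖)² / Σ‖φi − φj‖², alternating isotonic regression of
the embedded distances on the input dissimilarity order (Kruskal's primary
tie treatment) with a Guttman majorization step. Initialization is the
deterministic principal-coordinates solution; the seed is used only if it
degenerates. A step that would raise the stress is rejected and iteration
stops, so the stress trace is non-increasing by construction; convergence
is declared when the improvement drops below 1e-6 (max 300 iterations,
both configurable). The square root (Kruskal's stress-1) is reported
alongside the squared form. Embedding a test sample re-runs the
optimization on the augmented matrix; there is no out-of-sample
projection.

## SDS and the reference curve

Reference statistics are the column-wise median and IQR (type-7 quantiles,
diagonal excluded) of the panel's internal distance matrix, averaged over
columns; at least 4 members are required and a zero IQR is an error. The
SDS standardizes the *median* test-to-member distance (the mean is also
reported, but the score is defined on the median, which is robust to a few
aberrant members).

The reference curve simulates, for each error rate p on the grid, panel
members perturbed at rate p and records the SDS median and 5%/95%
quantiles over replicates. Defaults: half-decade grid 1e-6 … 1e-3, 30
replicates per point, binomial-approximation mode. Medians are made
monotone by isotonic regression in grid order before storage (violations
logged); the quantile curves are smoothed the same way and clipped to
bracket the median. Inversion interpolates log10 p piecewise-linearly at
the observed SDS; the 95% curve yields the lower error bound and the 5%
curve the upper. SDS values outside the curve's range are censored at the
grid boundary and always flagged.

The curve is flat below the panel's inter-individual difference density
and rises steeply above it. This phase-transition shape sets a detection
floor: on the default desk-scale panel (1 Mb, ~5,000 sites, n=100) an
error rate of 1e-5 shifts the SDS by ~0.05 while the sampling noise of a
single sample's SDS is ~0.13, so point estimates below ~3e-5 are censored
or highly uncertain there — the uncertainty band still covers the truth.
The floor drops roughly in proportion to target size, which is also why
the estimation band widens monotonically as the target shrinks.

## Error simulation

Explicit injection draws K ~ Binomial(region_size, p) distinct positions
uniformly over the target and applies, with equal probability (mix
configurable), a false positive (spurious het with a random alternate
base), a false negative (existing call deleted), or a genotype swap
(het ↔ hom-alt); inapplicable types fall back to the applicable one, and
the applied tally is recorded. At positions without a known reference
base the simulator draws one at random; since such a call is unseen in the
panel either way, the base identity does not affect the metric.

The approximation route leaves the agreement sum unchanged and adds w·X,
X ~ Binomial(N, p), to the normalizing constant — valid because most
target positions have low variability, so an error is a disagreement at a
constrained site. The per-error weight w defaults to the exact weight of
an unseen genotype against a hom-ref background, 2(n+1)/(n+2) → 2 for
large panels; `per_error_weight=2.0` fixes the large-panel value. The two
routes agree in mean distance within Monte-Carlo error at matched p.
Genotyping accuracy is defined on the target region: 100·(1 − p) percent.

## Synthetic data

The generator emulates what the method assumes about real exome cohorts:
variant sites uniform over the target, ancestral allele frequencies from a
rare-variant-dominated spectrum (density ∝ 1/x on [1/(2n), 0.5];
beta/uniform spectra available), optional population structure via
Balding–Nichols Beta-distributed population frequencies at divergence F,
and Hardy–Weinberg genotypes per individual. Defaults — 100 individuals,
1 Mb region, 5,000 sites — scale a ~28 Mb consensus exome with ~15,000
variants per sample down ~30-fold so the full pipeline runs in seconds.

It deliberately omits linkage disequilibrium/haplotype structure, base-
context effects (GC-biased dropout must be injected explicitly), and any
read-level error model. Passing tests therefore demonstrate correctness of
the *method's* arithmetic and its calibration behaviour under the stated
sampling assumptions, not performance on real exomes with LD and
platform-specific error signatures.

## Auxiliary QC metrics

ti/tv counts distinct non-reference alleles per called site (transitions
A↔G, C↔T); the dbSNP fraction is membership of called sites in a
known-sites list; the het allele-fraction variance uses the AD field and
the n−1 sample variance (unspecified convention; recorded here); flanking
GC excludes the variant base and N bases from the ±100 bp window. The
allele-frequency concordance envelope uses per-site symmetric 2-SD
binomial bounds with the pooled frequency — the qualitative "~95% inside"
behaviour, not a specific ellipse construction. The default dropout filter
flags sites carried by more than half the reference individuals but at
most one test sample (thresholds configurable).

## Interfaces and determinism

Internal coordinates are 1-based (VCF convention); BED input is converted
at the boundary. Panels serialize to a genotype-count TSV (per-individual
VCFs are needed for SDS statistics and clustering); curves serialize to
JSON with full metadata. Every stochastic step takes an explicit seed, and
identical (inputs, seed) reproduce identical outputs, including CLI runs.
Cluster assignment ties break lexicographically on the population label.

## Known limitations

- The detection floor scales with target size (see above); gene panels of
  ≲100 kb give only order-of-magnitude error estimates.
- Reference-panel quality is assumed perfect; systematic panel errors
  shared with the test sample are invisible to the score.
- Unstructured panels are assumed when scoring; a test sample of
  mismatched ancestry inflates the SDS (use cluster assignment first).
- Only SNVs are scored; indel and SV accuracy are out of scope.
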