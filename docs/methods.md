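# Methods

This note describes the models implemented in `accuscan`, the choices made
where the design was open, and what the synthetic fixtures do and do not
emulate.

## Consensus error correction

A circularized cfDNA fragment amplified by rolling-circle amplification
yields a concatemer whose sequenced read pair contains several tandem copies
of the same template. Copies are recovered from the alignments of one read
pair: every mapped (primary or supplementary) record is a candidate copy,
and copies whose reference spans reciprocally overlap by at least 0.9
(configurable) on the same chromosome are grouped as repeats of one
template. The template endpoints are the modal (start, end) of the group,
ties breaking to the smallest span.

At each position in the template span a base call is **repeat confirmed**
when, among copies whose base quality is strictly above Q24, at least two
cover the position and all agree. A confirmed call matching the reference
counts toward molecule depth; a confirmed non-reference call is a
single-molecule variant; anything else (disagreement, insufficient support,
low quality) is discarded as a PCR/sequencing error. Confirmation is
evaluated per position, i.e. a molecule can be confirmed at some positions
and unconfirmed at others. Two independent copy errors only survive when
they hit the same position with the same substituted base, so for per-copy
error rate r and two copies the residual error floor is r²/3 per covered
position; this closed form is verified against simulation in the tests.

Molecules are deduplicated by their fragment endpoints (chrom, start, end).
Duplicates keep the union of confirmed calls; two conflicting confirmed
calls at a position demote it to UNCONFIRMED (conservative: the upstream
evidence is contradictory). Only substitutions are modeled; indels and
structural variants are out of scope, as is strand-aware duplex consensus.

Paired-end caveat: with short templates and paired 150 bp reads, read 1 and
read 2 can each carry the same single copy and be mistaken for two
independent repeats. The default mode counts copies across both mates; a
`strict_single_mate` mode additionally requires at least two copies within
one mate, emulating longer single-end reads.

## Typed background error model

Residual errors after consensus are summarized per collapsed substitution
class, `{C-T, C-G, C-A, A-T, A-G, A-C}`, with purine-reference substitutions
mapped to the reverse complement class. For each class v,

    e_v = variant molecules of class v / molecules interrogated for class v,

where every confirmed molecule at a retained position is interrogated for
the three substitutions its reference base allows. Three filters precede the
ratio: known population variants are removed by exact (chrom, pos, ref, alt)
match (a germline proxy, no allele-frequency threshold); C>T at CpG sites
(either strand) are removed from the C-T class and the overall rate, since
methylcytosine deamination makes them both an error hotspot and a common
polymorphism; and positions carrying two or more variant molecules are
dropped entirely, because such positions are also excluded from the MRD
call and must not inform its null. Positions may be subsampled (seeded)
before estimation to emulate estimating on a random slice of the genome.
Classes with zero observed events report a rate of 0 by default; an
optional floor of 1/(3·denominator) can be enabled, and the MRD likelihood
guards the e_v = 0 case explicitly, so no artificial floor is required.

## MRD likelihood-ratio test

Given a tumor-informed marker set, each marker site of class v contributes
its confirmed molecule depth and variant-molecule count. Marker sites with
two or more variant molecules are excluded (counts and depth) in low-burden
samples: at residual disease levels the expected variant-molecule count per
site is depth·cVAF ≪ 1, so a two-molecule site is far more likely a missed
germline or CHIP variant. The per-site count is modeled as Poisson with
mean depth·cVAF; at 60× the probability of ≥2 molecules is ~1.7×10⁻³ at
cVAF 10⁻³ but essentially 1 for a heterozygous germline site — this P(≥2)
is the discriminator the filters rely on. When more than 10% of covered
markers are multi-molecule (configurable heuristic), the sample is flagged
high-burden and the exclusion is disabled, since in a high-burden sample
multi-molecule sites are genuine signal.

Aggregating sites by class gives counts c_v out of depth d_v with success
probability p_v ≈ VAF + e_v, and log-likelihood (up to a constant)

    l(VAF) = Σ_v [ c_v ln(VAF + e_v) + (d_v − c_v) ln(1 − VAF − e_v) ].

The cVAF estimate maximizes l subject to VAF ≥ 0. The score
Σ (c_v − d_v p_v)/(p_v(1−p_v)) is strictly decreasing on the feasible
interval, so the estimate is its unique root, clipped to 0 when the score
at 0⁺ is non-positive. When all classes share one error rate the problem
collapses to a single binomial with the closed-form root c/d − e; otherwise
a safeguarded bracketing root finder (Brent) is used at relative tolerance
10⁻¹².

The MRD decision tests H0: VAF = 0 with Λ = 2(l(V̂) − l(0)). Because the
null lies on the boundary of the parameter space, Λ is asymptotically the
mixture ½δ₀ + ½χ²₁, so the decision rule CDF_χ²₁(Λ) > 0.98 corresponds to a
mixture p-value below 0.01 and a nominal specificity of 99%. The cutoff is
parameterized as 1 − 2(1 − specificity). Confidence bounds collect the
non-negative VAF values within 3.841 (the χ²₁ 0.95 quantile) of 2·l(V̂):
two-sided around a positive estimate, one-sided upper bound with ci_low = 0
for negative calls. A positive call (Λ above the 0.98 quantile 5.412 >
3.841) always excludes 0 from the interval. Degenerate cases: all-zero
depths raise; e_v = 0 with c_v > 0 makes l(0) = −∞ and the call positive
with a finite positive lower bound.

## Monte-Carlo detection-rate simulator

Each replicate draws, for every marker site, variant molecules as the sum
of two binomials over the site depth — one at the cVAF (signal), one at the
class error rate (background) — truncated at the depth, applies the same
multi-molecule exclusion as the production caller, and runs the LR test.
Detection rate is the positive fraction; specificity is the negative
fraction at cVAF 0.

Sampling is aggregated for speed but remains exact for the fixed-depth law:
the total count for a class is Binomial(n_v·d, p) and molecules are placed
by drawing distinct trial indices, which reproduces independent per-site
binomials (verified against a literal per-site sampler in the tests). The
per-site depth law is not published, so both a fixed law (exactly the
expected depth per site, the default) and a Poisson law are provided; under
the Poisson law the thinning identity Binomial(Poisson(λ), p) = Poisson(λp)
is used, and the depth removed for an excluded multi-molecule site is
approximated by a Poisson draw of the expected depth (the exclusion itself
is a ≲10⁻³ effect at the rates studied). An LOD search scans a log-spaced
cVAF grid from below, relying on detection being monotone in cVAF.

Default problem sizes are 10,000 replicates per grid cell for detection
rates and 5,000 per cell for the null-specificity grid, with seeded
generators throughout; a cell at these sizes runs in seconds.

One calibration observation worth recording: because the count statistic is
integer, the realized null false-positive rate jumps between lattice
points. At 10K markers the exact specificity is 99.1–99.9% at seven of the
eight (depth, error-rate) conditions studied, but at depth 20× with e =
2.8×10⁻⁵ the LR of a 12-count observation (5.49) sits just above the 5.412
threshold, putting the exact specificity at 98.75% — marginally below the
98.8% floor the strictest reading demands. The corresponding assertion is
kept strict and documents this as a property of the stated observation
model rather than adjusting the band.

## Marker selection workflows

**WBC-free filtering.** When white-blood-cell sequencing is unavailable,
tumor variants are filtered against a post-treatment (presumed low-burden)
plasma: any tumor variant seen there with ≥2 unique molecules is removed as
likely germline/CHIP, and CpG C>T variants are removed outright. By the
Poisson argument above this removes ≥99.9% of heterozygous germline sites
at 40–60× while sacrificing ≤5% of true somatic markers at cVAF ≤10⁻³. If
the filter removes >95% of the tumor list the plasma likely carries a high
tumor fraction and a warning is raised — such a sample cannot serve as a
germline proxy.

**Titration SNP selection** applies five criteria in order: heterozygous in
the test donor and absent in the background donor (hom-ref genotype and
zero alt molecules); depth 20–100× at the site in every sample; observed
VAF 0.4–0.6 in the undiluted test sample; not in a repeat region and not a
CpG C>T; and not observed in more than one plasma sample.

**Profile-constrained subsampling** draws exactly n markers whose class
fractions follow a target profile (e.g. a typical colorectal-tumor
substitution profile) using largest-remainder quotas (|n_v − n·f_v| ≤ 1)
and uniform sampling without replacement within class; shortfalls in a
class re-allocate proportionally with a warning. The numeric profile is a
configuration input: fixtures default to a uniform profile, and any
tumor-type-specific profile must be supplied by the user.

**Mismatched-tumor specificity.** For each plasma sample and marker level
n ∈ {2K, 5K, 10K, 20K}, v_i = (60/depth_i)·n variants (nearest integer) are
drawn from a pool of other patients' tumor variants — the depth scaling
holds the expected summed depth constant across plasmas — the MRD test is
run on each of n_reps = 2000 draws, and specificity_i = 1 − FP_i/2000. The
pool must not contain the plasma's own patient's variants; this is checked
when the caller supplies them.

## Synthetic fixtures

The generators emulate the data-generating process end to end: a random
reference with controllable GC (hence CpG density); concatemer read pairs
whose copies carry independent per-copy errors and shared template
variants, with fragment lengths peaked near 170 bp, a configurable
copies-per-molecule distribution, a two-point quality profile (Q20/Q37) to
exercise the strict Q>24 filter, and a configurable duplication rate so
endpoint deduplication is exercised; plasma pileups with binomial molecule
counts at marker, germline and background sites; and multi-patient cohorts
with disjoint variant sets and paired pre/post-treatment plasmas. Reads are
emitted pre-aligned (coordinates known by construction), so no aligner is
needed on the test path. All generators are bit-reproducible given a seed.

What the fixtures do **not** emulate: fragmentomics biology (size-profile
differences between tumor and normal cfDNA), GC and mappability bias,
alignment artifacts near repeats or indels, strand-specific damage, CHIP
mutation spectra, and real trinucleotide-resolution error structure (errors
are typed at the 6-class level only). Tests passing on these fixtures
demonstrate the algorithms' correctness under the stated statistical model,
not performance on real sequencing data; in particular the published error
rates of the assay (10⁻⁴ unfiltered, ~3×10⁻⁵ read-pair corrected, ~4×10⁻⁷
consensus) are properties of real data that desk-scale fixtures only
reproduce qualitatively (orders-of-magnitude suppression from consensus,
with the coincident-error floor).

## Numerical conventions

Coordinates are 0-based half-open internally, 1-based at VCF boundaries.
Quality comparison is strictly greater-than 24. Quota and v_i rounding are
largest-remainder and nearest-integer respectively, for bit-reproducible
marker sets. Root finding uses Brent's method with relative tolerance
10⁻¹² (10⁻¹⁰ for confidence bounds). All randomness flows through
`numpy.random.Generator` objects seeded explicitly; simulation results are
reproducible given (config, seed).
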