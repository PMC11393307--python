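# accuscan

Concatemer-consensus error correction and likelihood-ratio MRD calling for
whole-genome cfDNA sequencing.

Detecting molecular residual disease (MRD) from plasma requires finding
circulating tumor DNA at variant allele fractions (cVAF) of 10⁻⁵ or below —
far beneath the ~10⁻³ substitution error rate of standard short-read WGS.
This package implements the computational side of a whole-genome,
tumor-informed MRD workflow built on rolling-circle-amplification (RCA)
concatemer sequencing, in which each cfDNA fragment is circularized and
read several times within a single read pair so its copies act as internal
replicates for error correction:

- **consensus** — groups the tandem copies of each read pair, repeat-confirms
  base calls (quality > Q24, ≥2 agreeing copies, no disagreement),
  deduplicates molecules by fragment endpoints, and emits a molecule-level
  pileup in which both variant and wild-type calls require confirmation.
- **error_model** — estimates background error rates per collapsed
  substitution class `{C-T, C-G, C-A, A-T, A-G, A-C}` as
  e_v = variant molecules / molecules interrogated, after removing known
  population variants, CpG C>T substitutions, and multi-molecule positions.
- **mrd** — the MRD caller. Markers of class v give binomial counts c_v out
  of depth d_v with p_v ≈ VAF + e_v; the cVAF is the constrained maximizer
  of l(VAF) = Σ_v [c_v ln p_v + (d_v−c_v) ln(1−p_v)], and the call tests the
  boundary null VAF = 0 with Λ = 2(l(V̂) − l(0)), positive when
  CDF_χ²₁(Λ) > 0.98 (mixture p < 0.01, nominal specificity 99%).
  Likelihood-ratio confidence bounds use the χ²₁ 0.95 quantile 3.841.
- **simulate** — Monte-Carlo detection-rate and specificity surfaces over
  error rate × depth × marker count × cVAF, plus an LOD search.
- **markers** — tumor-informed marker handling: WBC-free filtering against a
  post-treatment plasma, titration SNP selection, profile-constrained
  subsampling, and the mismatched-tumor specificity procedure with
  depth-equivalent marker counts v_i = (60/depth_i)·n.
- **fixtures** — synthetic references, concatemer SAM reads with truth
  tables, plasma pileups and multi-patient cohorts, so everything is
  testable without external data.

## Worked example

Simulate the canonical operating point — 10,000 tumor markers tracked at
20× molecule depth with a consensus error rate of 4.2×10⁻⁷ — and call MRD
on one draw at cVAF 2.5×10⁻⁵:

```python
import numpy as np
from accuscan import SimulationConfig, simulate_marker_counts, detection_rate, lr_test

cfg = SimulationConfig(
    n_markers=10_000, expected_depth=20, vaf=2.5e-5,
    error_model=4.2e-7, n_reps=10_000, seed=1,
)

obs = simulate_marker_counts(cfg, np.random.default_rng(1))
res = lr_test(obs, cfg.error_model)
print(res.call, f"cvaf_hat={res.cvaf_hat:.2e}", f"CI=({res.ci_low:.1e},{res.ci_high:.1e})")
print(f"detection rate: {detection_rate(cfg).rate:.3f}")
```

prints

```
POSITIVE cvaf_hat=3.46e-05 CI=(1.5e-05,6.7e-05)
detection rate: 0.965
```

The single draw produced 7 variant molecules over 200,000 interrogated
(hence the estimate 3.5×10⁻⁵ with a likelihood-ratio CI spanning the true
2.5×10⁻⁵), and across 10,000 replicates 96.5% of such samples are called
MRD-positive at 99% nominal specificity.

The same machinery is exposed as a CLI for file-based runs
(`accuscan consensus | error-model | select-markers | call-mrd | simulate |
specificity | fixtures | pipeline`); `accuscan pipeline --out DIR --seed 7`
runs the whole chain on a synthetic fixture.

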