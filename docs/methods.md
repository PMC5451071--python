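# Methods

## The assay and its statistical model

One observation is a culture well: a fixed number N of CD4⁺ T cells from one
donor, irradiated autologous PBMCs as antigen-presenting cells, and either a
test compound or nothing (baseline). Readouts are proliferation cpm
(sextuplicate, day 6 and day 8, N = 1×10⁵) and IL-2 ELISpot spots/well
(triplicate, N = 5×10⁵). Day-6 and day-8 wells are treated as independent
well sets, each with its own day-matched baseline wells.

### Responder classification

For each (donor, compound, readout) the stimulation index is the ratio of
replicate means, SI = mean(treated)/mean(baseline). The ratio-of-means form
(rather than the mean of per-well ratios) is the standard SI convention and
remains well defined when replicate counts differ. Significance is the
classical equal-variance two-tailed unpaired Student t-test (pooled variance,
df = n₁+n₂−2) — Student's, not Welch's, as the classification rule is defined
with the classical test. A readout is positive iff SI > 2 AND p < 0.05, both
strict; a donor responds to a compound iff at least one available readout is
positive (OR). No multiple-testing correction is applied across compounds or
readouts — the rule is a fixed, per-pair decision procedure, and the SI > 2
requirement makes it conservative relative to α alone. Degenerate
conventions: zero pooled variance gives p = 1 for equal means and p = 0
(flagged) otherwise; a non-positive baseline mean is an error unless a floor
(in measurement units) is configured, in which case the result is flagged.

### Limiting-dilution precursor frequency

Rare antigen-specific precursors distribute over wells as Poisson; a well is
negative (no precursor) with probability e^(−fN). Scoring a proliferation
well positive when its cpm strictly exceeds 2× the day-matched baseline mean,
and pooling day-6 and day-8 counts (12 wells under the standard design), the
estimate is

    f̂ = −ln(k / n) / N,   k = negative wells, n = total wells,

the exact MLE of the single-dose binomial likelihood
k·ln(e^(−fN)) + (n−k)·ln(1−e^(−fN)) — verified exhaustively against a
golden-section maximiser for all 1 ≤ k < n ≤ 24 (evaluated in 50-digit
decimal arithmetic, because near the maximum the float64 log-likelihood is
flat over a relative m-window of ~3×10⁻⁸, wider than the 10⁻⁹ agreement
checked). When k = 0 the count is replaced by 0.1, imposing a ceiling of
−ln(0.1/n)/N on the estimate: 40.94 per 10⁶ for 6 wells of 10⁵ cells, 47.87
for 12. The substitution applies only at k = 0; no other continuity
correction is used. k = n gives exactly 0. ELISpot wells are excluded from
frequency estimation: they are bulk-cultured and re-plated, so well-level
limiting-dilution logic does not apply.

Estimator behaviour, demonstrated by the recovery harness in the acceptance
suite (1,000 cohorts × 26 donors × 12 wells, noise-free scoring): at
f = 5×10⁻⁶ per cell the grand mean is within 15% of truth (a small upward
Jensen bias, ~6%); at f = 5×10⁻⁵ nearly every well is positive and estimates
pile up at the 47.87 ceiling — the estimator saturates and cannot report
frequencies above it. Likelihood-ratio confidence intervals
(`frequency_likelihood_ci`) are provided as an optional extra beyond the core
pipeline.

Cohort summaries are the arithmetic mean and SEM (SD/√n, n−1 denominator) of
per-donor frequencies per 10⁶ cells; a single donor reports SEM 0, flagged.
Per-10⁶ values are reported to one decimal in summaries; full precision is
kept internally.

### HLA representativeness

Cohort allele frequencies at a class II locus are chromosome counts over
total chromosomes. A genotype listing a single allele is counted as
homozygous by default (two chromosomes; standard typing-report semantics);
the `single` convention (one chromosome, treating the blank as a typing
failure) is exposed because typing reports do not distinguish the two cases.
Allele frequency — not donor carrier frequency — is the default tabulation.
The comparison against a reference population is a Pearson correlation over
the union of alleles of both tables, absent entries imputed as 0 and the
explicit OTHER remainder bucket excluded; zero variance in either vector
leaves r undefined (flagged) rather than NaN. The bundled reference table is
synthetic — a plausible European-like DRB1 spectrum for tests and examples,
not an estimate of any real population.

## The synthetic cohort generator

The generator exists to give every pipeline stage a ground truth. Per
(donor, compound) it plants a precursor frequency (responders draw uniformly
from a configured range; non-responders default to 0), seeds each well with
a Poisson(f·N) precursor count, and converts counts to signals:

- **Proliferation:** cpm = B + n·S with B ~ lognormal(median 500 cpm,
  geometric SD 1.3) and S ~ lognormal(median `cpm_per_precursor` = 2000 cpm,
  same gsd). The lognormal is the simplest positive, right-skewed model for
  unstimulated ³H-thymidine background; clonal expansion over the 6–8 day
  culture is folded into the per-precursor increment rather than modelled
  dynamically, because the analysis never observes the dynamics.
- **ELISpot:** spots ~ Poisson(background + n·`spots_per_precursor`), with
  background 5 spots/well and one spot per precursor by default (the natural
  single-cell reading of a spot). Co-stimulation and re-stimulation effects
  are absorbed into these signal parameters, not modelled separately.

All parameters are exposed on `SimulationConfig`; output is deterministic
given the seed (byte-identical CSV). Magnitudes are stand-ins with realistic
orders, not estimates of any instrument's behaviour.

### What the generator does and does not emulate

It reproduces the design (replicate structure, cells/well, baseline wells),
the single-hit precursor statistics, and plausible noise shapes. It does not
model plate geometry or edge effects, between-day cpm drift, donor-specific
baselines, HLA-restricted epitope recognition, or pharmacological
interference (e.g. TNF-α blockade suppressing proliferation, a known
confounder for anti-TNF antibodies). Passing recovery tests therefore shows
the analysis is correct under the stated model, not that the assay itself is
unbiased on real donors.

### The calibration preset

`calibration_preset()` defines the reference 26-donor cohort: responder
counts 26 (KLH), 26 (CMV), 1 (infliximab), 5 (rituximab), 2 (adalimumab),
7 (natalizumab), assigned to the first k donor ids per compound so the
planted sets are stable, with a fixed seed (42). Its contract is that the
default classification recovers the planted sets exactly, so its effect
sizes are set with margin on both sides of the decision boundary:

- Responder frequencies: (8×10⁻⁵, 1.2×10⁻⁴) per cell for the four
  antibodies, (4×10⁻⁴, 8×10⁻⁴) for KLH/CMV. At the low end this is ~8
  precursors per proliferation well; the measured per-day miss probability
  of the dual criterion is ≤ 2×10⁻⁴, squared by the day-6/day-8 OR.
- ELISpot background raised to 30 spots/well in the preset (the generic
  default stays 5). At low Poisson backgrounds with n = 3 the dual criterion
  has a ~1% null false-positive rate — about one spurious responder per
  26-donor cohort — which would contaminate exact recovery; at 30 spots/well
  the per-triple rate falls to ~5×10⁻⁶ (family-wise ~4.5×10⁻⁴ over the 89
  non-responder antibody pairs). Both rates were measured by direct
  simulation (4×10⁶ triples).

These planted frequencies are far above real biopharmaceutical precursor
abundances (~0.2–2 per 10⁶); the preset calibrates the pipeline, it does not
simulate realistic effect sizes. `boundary_preset()` places frequencies near
the decision boundary for power studies, and `null_config()` plants no
signal at all for false-positive calibration.

## Numerical and interface choices

- Strict inequalities everywhere a threshold is applied (SI > 2, p < 0.05,
  well value > 2× baseline mean); values exactly at a threshold are negative.
- Baselines are stored as rows with the reserved compound token `BASELINE`
  in a single CSV (columns: donor_id, compound, readout, replicate, value,
  cells_per_well; comma-separated, UTF-8, "." decimal, header required).
- Replicate-count deviations from the 6/6/3 design warn by default and error
  under `--strict`; ELISpot values are stored as reals and validated as
  integers only in strict mode (scanner software sometimes exports averaged
  counts).
- Missing readouts are tolerated: the responder OR runs over whatever
  readouts are present, so partial cohorts can be analysed.
- The mean SI of responders (immunogenicity plot ordinate) averages over
  responders' *positive* readouts by default; `responder_si="all_readouts"`
  exposes the alternative construction.

## Problem sizes

The test suite simulates one 26-donor calibration cohort (shared across
tests), a 120-donor null cohort (2,160 (donor, compound, readout) triples)
for false-positive calibration, and 2×1,000 reduced cohorts for the recovery
harness; the MLE cross-check enumerates all 828 (k, n, N) combinations with
n ≤ 24. These sizes make the full suite run in well under a minute while
keeping Monte-Carlo error far below every asserted tolerance.

## Known limitations

- The 0.1 substitution makes the frequency estimator's ceiling depend on the
  well count; cohort means that mix saturated and unsaturated donors inherit
  that arbitrariness. Estimates at or near −ln(0.1/n)/N mean "at least this
  frequency".
- The t-test operates on 3–6 replicates; its normality assumption is doubtful
  for low ELISpot counts, which is why the dual criterion (not p alone)
  carries the classification and why the null false-positive rate is checked
  empirically rather than assumed to be α.
- Whether a lone listed HLA allele means homozygosity or typing failure is
  unknowable from a typing table; both conventions are implemented and the
  choice is reported with the output.
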