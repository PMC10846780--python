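# Methods

## Model and procedure

`tmbkit` estimates tumor mutation burden from tumor-only whole-exome variant
calls by treating somatic-variant identification as a per-record
classification problem with three independent sources of evidence, applied
after a quality gate:

* **Quality gate (stage 1).** A call is credible if its caller quality is at
  least 10 (Phred-like) and its site depth at least 30×, and it is a coding
  non-synonymous change. Boundaries are inclusive: quality 10 and depth 30
  pass. Synonymous and non-coding calls are excluded from the TMB numerator
  by definition of the statistic.
* **Population evidence (level 1).** A call observed at > 1% allele
  frequency in any annotated population database (global or South Asian) is
  germline polymorphism. The any-database union rule is deliberately the
  more aggressive reading: it removes more germline at negligible cost to
  somatic calls, which essentially never carry a population AF annotation.
  A call with no AF annotation is retained — absence of evidence of
  commonness is not evidence of somatic origin, but the other levels remain
  to catch it.
* **VAF evidence (level 2).** Diploid germline heterozygotes cluster at VAF
  0.5 and homozygotes near 1.0, while somatic VAF scales with tumor purity
  and clonal fraction. Calls with VAF ≤ 0.05 (noise, contamination,
  trace-level artifacts) and calls inside the closed band [0.45, 0.55] are
  removed. Both interval closures are chosen inclusively and symmetrically.
  An optional high-VAF cut (`hom_vaf_cut`, e.g. 0.95) extends the rule to
  germline homozygotes; it ships disabled because high-VAF removal also
  deletes clonal somatic variants in high-purity tumors, and levels 1 and 3
  already remove most homozygous germline sites. The flag exposes the
  stricter policy for users who want it.
* **Baseline evidence (level 3).** Any call whose normalized key occurs in a
  panel of pooled healthy-donor germline calls is removed, regardless of its
  VAF or annotation. This is the only level that catches rare germline
  variants sitting outside the heterozygous band with no database AF.

Levels 1–3 are pure per-record predicates, so their composition is
order-independent (verified by permutation tests); the sequential order is
kept for the audit trace. TMB is the surviving count divided by the capture
size in Mb. SNVs and small indels are counted identically; every variant is
reduced to a parsimony-normalized (chrom, pos, ref, alt) key — shared
suffix trimmed, then shared prefix — so equivalent indel spellings compare
equal across callsets and panels. Full left-alignment through repeat tracts
would need flanking reference sequence, which is not an input; within one
generator/caller ecosystem the parsimonious form is stable.

The matched tumor–normal workflow applies the same stage-1 thresholds to the
tumor and subtracts every variant key present in the matched normal
(unfiltered: presence in constitutional DNA is disqualifying regardless of
the normal call's quality). It serves as the validation oracle: agreement is
summarized by the Pearson correlation between the two workflows' per-sample
TMB estimates, reported as both r and r².

## QC scoring

Four post-alignment metrics with equal weight, each scored 0/1/2 against
two configurable cut-points, cumulative 0–8, categories good (6–8),
intermediate (3–5), poor (0–2), pass at ≥ 3. The shipped cut-points —
coverage ≥ 150× → 2, 100–149 → 1; uniformity ≥ 90% → 2, 80–89.99 → 1;
duplicates ≤ 20% → 2, 20.01–40 → 1; base enrichment ≥ 80% → 2, 60–79.99 → 1
— are conventional exome operating points, not a validated clinical
standard; every band flows through `QCThresholds` so a laboratory
substitutes its own values in the config. Boundary values take the higher
score (a rule had to be fixed; it is stated once and tested exhaustively
over all 81 score combinations). "Uniformity" is treated as an opaque
percentage; no particular depth-fraction definition is assumed.

## Cohort statistics

One percentile definition — linear interpolation between order statistics
(Hyndman–Fan type 7, `numpy.percentile` default) — backs every consumer:
percentile tables, medians, and the bootstrap. The ninth-decile estimate
resamples the cohort at full size with replacement ("phantom cohorts"),
takes the 90th percentile of each of 1,000 iterations, and averages; the
standard deviation across iterations is reported as the Monte-Carlo
uncertainty of a single resampled percentile. Two-cohort comparisons use the
tie-corrected Kruskal–Wallis test per cancer type (two groups, asymptotic
chi-square p), restricted to types with ≥ 30 samples in both cohorts;
p-values are reported raw, flagged unadjusted — with six cancer types the
reader can Bonferroni-correct trivially, and the package does not presume a
family definition.

All randomness descends from one integer seed through `numpy.random.
SeedSequence` with fixed stream tags (pool, per-sample, donors, QC,
bootstrap), so per-sample generation is order-independent and adding an
analysis never perturbs another's stream.

## Synthetic cohort generator

The generator emulates the call-level statistical structure the filters
exploit; parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `true_tmb` | 10 mut/Mb (cohort draw: Uniform(1, 40)) | ground-truth somatic density |
| `target_size_mb` | 30 Mb | exome capture size |
| `purity` | 0.5 (cohort draw: Uniform(0.3, 0.7)) | tumor cell fraction scaling somatic VAF |
| `n_germline_het` / `n_germline_hom` | 3000 / 1500 | coding germline load per sample |
| `frac_common` | 0.7 | share of germline sites with population AF > 1% |
| `het_vaf_sd` | 0.03 | spread of heterozygous VAF around 0.5 |
| `n_noise` | 150 | low-VAF (≤ 0.05) artifact calls, tumor only |
| `depth_mean` | 200× | Poisson mean site depth (floored at 1) |
| `qual_low_frac` | 0.02 | share of records with quality < 10 |
| `recoverable_frac` | 1.0 | share of somatic VAFs nudged outside the removal bands |

Germline sites live in a shared population pool; each patient and each
healthy donor draws from the same pool, which is what makes the
donor-derived baseline panel informative. Heterozygous VAF is
Normal(0.5, sd) clipped to [0, 1] (a standard binomial-sampling
approximation), homozygous VAF Uniform(0.95, 1.0), drawn independently in
tumor and normal. Common-site AFs are log-uniform in (0.01, 0.5], rare-site
AFs log-uniform in (1e-5, 0.01] with a 30% share carrying no annotation —
only the 1% boundary is material to the filter. Somatic VAF is purity ×
Beta(2, 2); with `recoverable_frac = 1` any draw landing in a removal band
is nudged into the nearest recoverable interval, so filter losses are
attributable to quality/depth alone; lowering the knob measures the VAF
filter's intrinsic cost. About 10% of variants are 1–3 bp indels.

What the generator does **not** model: read-level errors, FFPE deamination
signatures, copy-number-driven VAF distortion, subclonal phylogenies,
caller-specific artifacts, or any realistic cancer-type effect on TMB
(labels are assigned round-robin). Passing tests therefore demonstrate that
the filter logic and statistics are correct under the stated model, not
that the thresholds are optimal on real FFPE exomes.

Simulated QC metrics are drawn per requested tier by rejection-sampling a
per-metric score vector in the tier and then a value inside each score band;
the pipeline's simulate command mixes tiers 58.9% good / 20.0% intermediate /
21.1% poor, giving an expected pass rate of ~79%, matching the scale of
attrition a clinical exome cohort shows.

## Problem sizes and numerical choices

The validation experiment uses 20 matched pairs (~5,000 records each) with a
full-coverage baseline panel; parameter-recovery uses 200 tumor-only
samples; bootstrap calibration uses 10,000 Uniform(0, 40) draws, whose 90th
percentile is 36.0 in closed form. These sizes make every experiment exactly
reproducible from one seed on a single CPU in minutes. Degenerate inputs are
hard errors rather than silent defaults: empty score lists for percentiles,
zero-variance coordinates for correlation, empty baseline panels, duplicate
sample ids, out-of-range AFs, and config keys that match nothing.

## Known limitations

* The baseline panel is key-exact; it cannot remove a germline variant the
  donor pool has never seen (in real data: population-private rare
  variants). The generator's shared-pool construction makes panel coverage a
  controllable experiment, not a claim about real panels.
* Tumor-only estimates inherit a small negative bias from the quality gate
  (~`qual_low_frac` of true somatic calls) and the matched workflow a small
  positive bias from low-VAF artifacts it cannot filter; both are visible in
  the simulation and neither affects the workflows' correlation materially.
* No copy-number adjustment of VAF, no MSI, no mutational signatures, no
  clinical TMB-high/low thresholds.
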