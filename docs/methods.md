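# Methods

## Data model

A Ct (threshold cycle) value is the PCR cycle at which a well's fluorescence
crosses the detection threshold. Ct is a log2-scale abundance measure: one
cycle corresponds to a two-fold difference in starting template, and *lower*
Ct means *more* template. Wells that never cross the threshold are "not
detected" and carried as missing values throughout; additionally, Ct values
above a ceiling (default 35 cycles, configurable, disable with `None`) are
treated as not detected at parse time, since late-cycle signal on these
arrays is dominated by primer-dimer and stochastic amplification. The
accepted not-detected markers default to {"Undetermined", "N/A", "NA", ""}
and are configurable, since vendor exports differ.

The standard single plate holds 384 wells: 372 miRNA primer assays, two
replicate wells of the *C. elegans* spike-in cel-miR-39, one well each of the
six endogenous normalizers SNORD61, SNORD68, SNORD72, SNORD95, SNORD96A and
RNU6B, two reverse-transcription control (RTC) wells and two positive PCR
control (PPC) wells. Assay names are matched case-insensitively with
whitespace trimming. Multiple plates measured on the same samples are merged
by row concatenation keyed on (plate id, well position); replicate wells of
the same assay — within or across plates — are combined later, at
normalization, by averaging.

## Sample quality control

Two per-sample checks run in order, both always recorded:

1. **Missingness.** The fraction of not-detected wells must not exceed
   `max_na_fraction` (default 0.10). The denominator counts miRNA wells only
   (configurable): control dropout is diagnosed by the dedicated control
   check and should not be double-counted here.
2. **RT efficiency.** The RTC assay detects an artificial RNA template added
   before reverse transcription; the PPC assay amplifies a pre-dispensed DNA
   template that bypasses RT entirely. Their comparison therefore isolates
   reverse-transcription failure from general PCR inhibition. The statistic
   is mean Ct(RTC) − mean Ct(PPC), and a sample passes iff it is below
   `rt_threshold` (default 5 cycles). Since Ct is log-scale, the difference
   is the dimensionally meaningful comparison; a literal quotient form is
   available via `rt_statistic_form="quotient"` for compatibility with
   vendor wording that speaks of a "ratio". A sample whose RTC or PPC wells
   are all missing fails the check with reason "controls missing" rather
   than raising.

Failing samples are excluded from all downstream stages, each with its
reason in the QC report. The missingness structure across samples is
summarized as exclusive intersection counts of the per-sample missing-miRNA
sets (the data behind an upset plot); the counts sum to the number of miRNAs
missing in at least one sample.

## Normalization

Per sample, the reference Ct is the arithmetic mean of the selected control
assays — arithmetic on the Ct scale being geometric on the linear scale,
the conventional summary for multiple reference genes. Two panels are
offered: endogenous (the six snoRNA/snRNA assays; default) and exogenous
(cel-miR-39, intended for biofluids, where no endogenous RNA is reliable).
Controls missing in a sample are dropped from that sample's mean — control
dropout is common and should not abort a run — and the controls actually
used are recorded per sample; only a sample with *no* usable control is an
error.

Expression is reported as −ΔCt(m, s) = Ct_ref(s) − Ct(m, s), so larger
values mean higher expression and downstream log fold changes have the
conventional sign. Because the same reference is subtracted from every well
of a sample, any global per-sample Ct offset — different input RNA amounts,
RT efficiency, handling — cancels exactly; this is asserted to machine
precision in the tests. The linear companion 2^−ΔCt is emitted alongside.
Differential analysis consumes the −ΔCt (log2) scale, where errors are
approximately additive; the linear scale is for reporting only.

## Differential expression

Per miRNA, a complete-case two-sample fit (a miRNA needs ≥ 2 non-missing
values in each group; others are dropped and listed): β̂ = mean(test) −
mean(reference), pooled variance s² on d = n₁+n₂−2 df, unscaled variance
factor v = 1/n₁ + 1/n₂. No imputation: with 4–12 samples per group any
imputation model would dominate the data.

With few samples the per-miRNA variances are noisy, so they are moderated by
empirical Bayes. Model: s² | σ² ~ σ² χ²_d / d and σ² ~ s₀² d₀ / χ²_{d₀}.
The posterior variance s̃² = (d₀s₀² + d·s²)/(d₀ + d) replaces s², and
t̃ = β̂/√(s̃²v) follows t on d₀ + d df under the null. The hyperparameters
are estimated by moment matching on e = log s² − ψ(d/2) + log(d/2), whose
model mean is log s₀² − ψ(d₀/2) + log(d₀/2) and variance ψ′(d/2) + ψ′(d₀/2):
the excess of var(e) over its expected sampling part determines d₀ through
the inverse trigamma (Newton iteration); no excess dispersion gives d₀ = ∞,
in which case every s̃² = s₀² and t̃ is referred to the normal distribution.
Note the homogeneous case keeps the sampling-bias correction: all s² equal
to c yields s₀² = c·(d/2)/exp(ψ(d/2)) > c, as in the standard estimator.
Rows with exactly zero sample variance carry no log-variance information and
are excluded from hyperparameter estimation (they are still moderated);
d₀ = 0 is accepted downstream as the unmoderated limit, which reproduces the
classic pooled t-test exactly and is used as an oracle in the tests. The
full route (hyperparameters, t̃, p) agrees with the Bioconductor limma
reference implementation to ~1e-15 on a 50×8 fixture; this cross-check runs
as a test via Rscript.

P values are two-sided and Benjamini–Hochberg adjusted (Bonferroni
available); a miRNA is significant iff adjusted p < α (default 0.05).
Significant miRNAs are clustered for the heatmap: rows z-scored (constant
rows map to zero), Euclidean distance, complete linkage, rows and columns
independently; distance and linkage are fixed and documented rather than
configurable, for reproducibility. Fewer than two significant miRNAs skips
the heatmap with a report note, not an error.

## Functional analysis

Target mapping is offline: a TSV of (mirna, gene, source, evidence[, score])
records emulating validated (miRTarBase, TarBase) and predicted
(DIANA-microT, ...) databases. Matching is exact after case-folding — no
-3p/-5p arm expansion, which would silently change results. Genes can be
required to be supported by ≥ `min_sources` distinct databases.

Over-representation uses the hypergeometric upper tail P(X ≥ k) for overlap
k between the n query genes and a set of K genes in a universe of N,
BH-adjusted across all tested sets. The default universe is the union of the
collection's genes, intersected — when a target table is in play — with the
genes reachable through it, so the background matches what the query could
ever contain; an explicit universe overrides. Sets are tested when their
universe-intersected size lies in [2, 2000] (configurable) to avoid
degenerate tests. Sets with zero overlap receive p = 1 and are hidden unless
requested, but still count toward the BH family.

## Synthetic data

The generator emulates the nuisance structure the pipeline must remove, not
real miRNA biology. Per well: Ct = baseline(assay) − planted effect (test
group only) + sample shift + N(0, noise_sd²) noise. Choices and defaults:

- miRNA baselines ~ Uniform(20, 32) cycles — the usable range of these
  arrays; control baselines are fixed (spike-in 18, normalizers ≈ 20,
  RTC 21, PPC 19, so a clean sample's RT statistic is 2 < 5).
- 30 planted effects of ±2 cycles (alternating up/down), 6 samples per group
  labelled normal/tumor, noise SD 0.5 cycles, per-sample global shift
  SD 1 cycle applied to *all* wells including controls — which is what makes
  the shift removable by normalization.
- Dropout uniform over miRNA cells at rate 0.02 by default; an optional
  abundance-biased mode concentrates dropout at high Ct, as in real data.
- RT failures are injected by inflating RTC wells 10 cycles.

Everything derives from one integer seed; same seed, bit-identical output,
and the ground truth (planted signed effects on the −ΔCt scale, shifts, NA
positions, intended QC failures) is recorded alongside. What passing tests
on these plates do **not** show: robustness to assay-specific amplification
efficiencies, melt-curve artefacts, plate-position effects, or non-Gaussian
heavy-tailed noise — none of which the generator models.

## Numerical and design notes

- Inverse trigamma by Newton iteration with asymptotic initialisation;
  converges in < 10 iterations over the relevant range.
- Hypergeometric tails through the survival function of
  `scipy.stats.hypergeom` (log-space internally); verified against exact
  `math.comb` enumeration over the full admissible grid with N ≤ 25.
- BH through `statsmodels` behind a single shared function used by both the
  differential and enrichment stages; verified against the stepwise
  definition.
- Zero posterior variance with zero effect yields p = 1 (no evidence either
  way) rather than NaN.
- Two-group single contrast only; paired designs, covariates and
  robust/trend moderation variants are out of scope.
- The run report echoes all user criteria, lists every excluded sample with
  its rationale, and reports wall-clock time and peak memory; the resource
  numbers are informational and never asserted.

Problem sizes in the test and acceptance runs — single plates of 384 wells,
12 samples, 2000 simulated variances for hyperparameter recovery, oracle
grids with N ≤ 25 and ≤ 8 clustered rows — are the package's chosen
verification scale: large enough to exercise every code path and estimator,
small enough that the full suite runs in seconds.
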