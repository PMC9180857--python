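# Methods

## Study design

All tables are keyed by a full-factorial greenhouse design: 4 contamination
levels (uncontaminated control `C`, bisphenol A `B`, zinc `Zn`, their
combination `B_Zn`) × 2 humic-acid levels (`none`, `H`; doses 0 and 4 g kg⁻¹
dry soil) × 3 cropping levels (`unsown`, sorghum `S`, switchgrass `P`) × 3
replicates = 72 experimental units. `build_design` enumerates it
deterministically; replicate counts and factor levels are configurable.

## Index definitions and conventions

- **Influence factors** are ratios of replicate *means* (ratio of means, not
  mean of ratios), because the defining formula is written on treatment-level
  activities. IF_X contrasts each contaminated level against `C` within the
  same (amendment, crop) stratum; IF_H contrasts `H` against `none` within
  (contamination, crop); IF_P contrasts each sown crop against `unsown`
  within (contamination, amendment). The literal formula divides by the
  control-soil activity only; the within-stratum form is the default because
  the humic-acid and plant coefficients are named as such effects, and a
  `strict_control_reference` mode provides the literal reading.
- **BA21** sums the six enzymes of its printed formula (dehydrogenases,
  catalase, alkaline phosphatase, urease, β-glucosidase, arylsulfatase). Acid
  phosphatase is assayed but absent from the printed sum; `include_pac=True`
  adds it. The default follows the formula as printed and exposes the
  discrepancy rather than resolving it silently.
- **CD** is bounded in [10, 100] by construction; a zero-colony series is an
  error, not 0, because an empty plate carries no kinetic information.
- **EP** uses log base 10 by default so a uniform 10-day emergence scores
  exactly 1; natural log is available (`base=e`), related by
  EP_ln = EP_log10 · ln 10.
- CD/EP are computed per replicate series and then averaged within a
  treatment cell (default); a `pooled` mode sums daily counts across
  replicates first. Whether the original analyses pooled is not decidable
  from the study text; per-replicate is the default because it keeps a
  replicate-level dispersion estimate.
- **Shannon–Wiener** uses natural log (ecology convention), configurable.
  **Simpson** is reported as the Gini–Simpson complement 1 − Σp² so that
  higher = more diverse, consistent with diversity decreasing under
  contamination; Σp² (`dominance`) and 1/Σp² (`inverse`) are available. The
  source study names "Simpson (D)" without printing a formula.
- The **≥1 % filter** retains a taxon if its within-sample proportion at the
  analyzed rank reaches 1 % in *any* sample (inclusive ≥). Group membership
  for the unique/shared partition is presence after this filter, not raw
  presence; `unassigned` bins are excluded from partitioning.
- The **heatmap matrix** maps counts to log₁₀(count), with zero counts going
  to an explicit sentinel (NaN by default) rather than −∞; a log₁₀(count+1)
  floor mode exists.
- Enzyme units are opaque per-variable strings; every index is dimensionless,
  so the unit strings never enter a computation.

## Tukey homogeneous groups

One-way ANOVA gives the within-group mean square MSE on N − k df; each pair
is tested with the Tukey–Kramer statistic
q = |mᵢ − mⱼ| / √(MSE/2 · (1/nᵢ + 1/nⱼ)) against the studentized-range
quantile at (k, N − k). Quantiles come from `scipy.stats.studentized_range`
(numerical accuracy ≈ 1e−6; significance uses one `ppf` evaluation, p-values
are computed lazily because each `sf` evaluation costs ~10 ms). "Homogeneous
groups" are groups of *means*, the standard post-hoc reading. Letters follow
the insert-and-absorb algorithm with groups ordered by descending mean (the
figure convention that 'a' marks the highest mean; ascending is available).
The output is verified against the sharing-iff-non-significant biconditional
before being returned; minimality of the letter count is not guaranteed.
Lettering in the pipeline is joint across all 24 treatment cells per
variable, matching captions that letter "for all xenobiotics" at once.
Zero-variance (noiseless) data has a degenerate MSE; standalone Tukey raises,
and the pipeline's stats stage emits `NA` letters for such variables so that
noiseless validation runs remain executable end-to-end.

PCA z-scores the variables by default (mixed units across enzymes), with a
covariance-only mode; the sign convention makes the largest-magnitude loading
of each component positive.

## Synthetic-data generator

The generator emulates the study's structure, not its numbers (the raw
replicate tables live in an appendix that is not reproduced here):

- **Enzymes and biomass**: value = baseline × θ(variable, cell) ×
  exp(N(0, σ)). Noise is multiplicative lognormal because activities and
  masses are strictly positive and the indices are ratios of means — the
  lognormal mean factor exp(σ²/2) cancels in every IF/TI. θ is built as a
  product of per-factor multipliers, so the noiseless IF recovers each
  multiplier exactly (tested to 1e−12). σ defaults to 0.1 natural-log units
  (≈10 % CV); the study reports no replicate-level variance, so this is a
  free parameter fixed once, at the value used by the parameter-recovery
  validation.
- **Default effect multipliers** encode the study's qualitative findings:
  enzyme θ_X = 0.80 (B), 0.55 (Zn), 0.40 (B_Zn) — combined contamination
  most inhibitory; humic acid 1.15 (urease 1.40, the most stimulated
  enzyme); cropping 1.10/1.20. Biomass θ gives aerial TI of 85/55/40 and
  makes roots slightly less affected than shoots.
- **Colony series**: counts over 10 incubation days are
  multinomial(total, profile) with discretized-Gaussian emergence profiles
  whose peak shifts later and narrows with contamination severity (control
  peaks at day 3, combined contamination at day 6.5), so CD decreases and EP
  responds as in slow-growing stressed communities. Totals default to 200
  cfu per plate (a countable serial-dilution plate). Groups counted on a
  single day in practice (e.g. 4-day Arthrobacter counts) are simply not
  given a series; CD/EP are defined only for the 10-day groups.
- **OTU tables**: one pooled sample per contamination level (four sequencing
  objects), `per_unit=True` for per-pot tables. Expected proportions are the
  base composition times per-level shift multipliers, with each
  treatment-unique genus carrying 5 % expected share in its own level and
  exactly zero elsewhere; sampled compositions are
  Dirichlet(overdispersion × proportions) and counts
  multinomial(50,000 reads). Overdispersion defaults to 500 (mild
  between-sample compositional noise). The unique genera are the ones the
  emulated study names (e.g. *Novosphingobium* for bisphenol A,
  *Lapilicoccus* for Zn, *Serratia* for the combination). No read-level
  artifacts are simulated — no chimeras, misclassification or rarefaction —
  so a green community test establishes the correctness of the analytics on
  well-formed counts, not robustness to sequencing error.
- **Seeding**: one study seed; each table derives a named child stream
  (CRC32-keyed `SeedSequence`), so adding a simulated table never perturbs
  the draws of another, and identical config + seed yields byte-identical
  output bundles.

## Numerical and I/O choices

TSV outputs use 6 significant digits, decimal point, LF endings and `NA` for
missing values, making bundles byte-stable across platforms. OTU tables
round-trip through TSV (lineage columns + sample columns, sample-group header
comment) and a minimal BIOM v1 JSON dialect (dense or sparse, taxonomy in row
metadata). Config files are TOML; unknown keys are rejected. The pipeline
manifest echoes the full configuration and reproduces every output byte.

## Limitations

- The generator's defaults are a plausible stated world, not a calibration to
  the original measurements; numeric agreement with the study's printed IF/TI
  values cannot be checked from the available text, only the formulas and
  their invariants.
- The partition treats group membership as binary presence after the filter;
  proportions just below threshold in a second group can make a genus
  "unique" in a way raw presence would not.
- Tukey assumes homoscedastic groups (single pooled MSE); no Welch-type
  correction is offered.
- SPAD readings are summarized as treatment means only; no chlorophyll model.
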