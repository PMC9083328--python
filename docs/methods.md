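# Methods

This note records the statistical model behind `extractbench`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Data model

A measurement table is samples × metabolites, where a sample is one
replicate of one extraction protocol applied to one *matrix* (organism ×
tissue). Each cell holds a concentration in kit units and one quantitation
status: `below_lod`, `below_loq`, `valid`, or `missing`. Censored cells may
keep the instrument's numeric estimate, as kit software exports do; the
dialect also permits censored cells without a number. Matrices are always
analyzed independently — the pipeline never pools inference across
organisms or tissues.

The portable text dialects (`long_csv`, `wide_tsv`) replace the
color-coded spreadsheet exports of kit software with an explicit status
token per cell. Legacy tokens `< LLOQ` / `> ULOQ` from other kit versions
map to `below_loq` with a warning, since the analysis only distinguishes
the three-tier LOD/LOQ/valid categorization. Concentrations are serialized
as shortest round-trip decimals, so write→read reproduces bit-identical
floats; the normal form orders samples by (organism, tissue, protocol,
replicate) and metabolites by name, making parsing insensitive to row
order.

## Detectability

A metabolite is detectable under a protocol when at least 2 of 3
replicates are above the LOD, where "above LOD" means status `below_loq`
or `valid` (the LOQ lies above the LOD, so a below-LOQ cell is detected
but not reliably quantified) and `missing` counts as no evidence. For
n ≠ 3 replicates the same fraction is kept: at least ⌈2n/3⌉ of n,
configurable. Detectability is monotone in status upgrades by
construction.

## Protocol comparison

For every metabolite detectable under **at least one** protocol of a
matrix, concentrations from **all** protocols enter the comparison —
protocols that failed to recover the metabolite contribute their exported
numbers or imputed floor values and are penalized by the test rather than
dropped.

- **Imputation.** Missing and zero cells are replaced by
  `impute_fraction` (default 0.2) × the metabolite's minimal positive
  value, taken across all samples of the matrix (all protocols and
  replicates; "per metabolite" with no finer grouping). A metabolite with
  no positive value anywhere raises an error instead of being silently
  floored.
- **Transform.** log2, so protocol effects are fold changes in doublings.
- **Inference.** One-way fixed-effects ANOVA with protocol as the factor,
  followed unconditionally by an all-pairs Tukey HSD test (Tukey–Kramer
  standard errors for unequal group sizes). The ANOVA p-value is reported
  but does not gate the post-hoc, because the selection rule below depends
  only on adjusted pairwise p-values.
- **Selection.** Rank protocols by the median of the imputed log2 values;
  the optimal set is the top-median protocol plus every protocol with
  Tukey-adjusted p > α (default 0.05) against it. Exact median ties are
  broken symmetrically: all tied tops anchor the comparison and their
  optimal sets are unioned. A singleton optimal set defines the unique
  best protocol. Mixing a median-based ranking with a mean-based test is
  deliberate — it follows the field's established analysis convention for
  these studies literally.
- **Degenerate groups.** Constant imputation floors can produce groups
  with zero pooled variance. Conventions (always warned): all values
  identical → every p = 1; zero variance with unequal means → ANOVA p = 0
  and pairwise p = 0 for unequal / 1 for equal means.

### Studentized-range evaluation

The Tukey adjusted p-value is the survival function of the studentized
range Q(k, ν) at q = |Δ| / √(s²/2·(1/nᵢ + 1/nⱼ)). The package evaluates
it by tensorized Gauss–Legendre quadrature of the classical double
integral (outer: density of the pooled SD, chi_ν/√ν, integrated between
the 1e-12 chi² quantiles; inner: the normal-maximum integral on |z| ≤ 8.5;
64 × 96 nodes). Agreement with scipy's implementation is ~1e-12 over the
relevant (q, k, ν) range, at microseconds per value in batch — which is
what makes the 10⁵-evaluation null simulations below practical. The test
suite cross-checks it against scipy, against an independent adaptive
quadrature, and against the pooled-t closed form at k = 2 (where
Q = √2·|t|).

## Replicate variability

CV% = 100 × sample SD (n−1 denominator) / mean, computed on **raw**
linear-scale concentrations of detectable (metabolite, protocol) pairs
using only non-missing replicates — no imputation first, since constant
floors would fabricate precision. The MAD is scaled by 1.4826 (normal
consistency; configurable to 1.0). Bands use right-closed intervals on the
unrounded CV: ≤10 excellent, ≤20 good, ≤30 acceptable, >30 not acceptable
— the faithful continuous reading of the conventional "0–10 / 11–20 /
21–30 / >30" integer-display bins, and configurable. Band percentages
divide by a fixed panel denominator (default 630, configurable per
organism) rather than by the protocol's own coverage, so robustness and
coverage are visible in one number; display rounding is half-up to one
decimal.

## Cross-matrix overlap

For one protocol, the detectable sets of k matrices are decomposed into
the 2^k − 1 exclusive membership regions; regions are disjoint, cover the
union, and the all-matrices region is the core. Region keys are sorted
matrix tuples for deterministic output. Beyond k = 6 the full
decomposition is refused (a guardrail — 127+ regions stop being
interpretable) and pairwise intersection counts are emitted instead. A
cross-protocol "detectable anywhere" membership mode is not the default
because overlap figures in these studies are scoped to a single protocol.

## Synthetic generator

The generator emulates the *design* of a kit-based protocol comparison:
630 metabolites in 23 classes (14 small-molecule classes measured by
LC-MS/MS, 107 metabolites; 9 lipid classes by FIA-MS/MS, 523), four
matrices (mouse kidney, mouse liver, zebrafish liver, whole drosophila),
seven extraction protocols, triplicates.

Model: `log2 conc = baseline(metabolite) + effect(protocol, class) +
noise`, with baselines uniform on [−2, 12] log2 kit units (≈0.25–4000,
the realistic span of a broad panel) and noise SD derived from the target
replicate CV by the exact lognormal relation σ_ln = √(ln(1 + cv²)) (then
/ ln 2), so the population CV of the replicates equals the target exactly
rather than only in the small-cv limit. The default target CV of 15%
lands the bulk of simulated CVs in the excellent/good bands with
realistic tails, matching how well-behaved protocols score.

Censoring: each metabolite gets a single constant LOD (instrument
property), placed at the `lod_quantile` (default 0.1) of its analytic
log2 marginal — a normal mixture over groups — so the expected below-LOD
cell fraction equals the configured rate exactly; the LOQ is placed the
same way at `loq_quantile` (default 0.2, counted from zero, i.e.
including the below-LOD tail). Defaults give ≈10% below-LOD, ≈10%
below-LOQ, ≈79% valid and 1% missing cells, a realistic status mix.
Missingness is independent Bernoulli masking (default 0.01).

Reproducibility: one RNG substream per metabolite, seeded by the table
seed plus a stable 64-bit blake2b hash of the metabolite name and consumed
in canonical (sorted) sample order — output is byte-identical across runs
and independent of panel insertion order.

Scenarios (`plant_scenario`) realize the canonical study patterns with
censoring and missingness off: `global_null` (no effects), `one_winner`
and `two_tied_winners` (+4σ planted raises, σ = the within-group log2
SD), and `class_specific_winner` (one class only — e.g. an acidified
acetonitrile protocol winning amino acids).

What the generator does **not** emulate: inter-metabolite correlation,
matrix effects/ion suppression, calibration-curve error structure, or the
real abundance profile of any organism. Passing tests therefore validate
the pipeline's statistical behavior under its stated model, not the
biology of any particular tissue.

## Statistical power of the selection rule, and one known limitation

Monte-Carlo oracles (independent of the package, simple numpy + critical
values) characterize the Tukey-based selection under the study design
(7 protocols, triplicates, α = 0.05):

- **Null false-exclusion rate.** P(optimal set ≠ all protocols) under the
  global null is ≈0.047 — slightly below the nominal 0.05 because only
  pairs against the top-median protocol can exclude, a subset of all
  pairs. The end-to-end pipeline reproduces this within ±0.01.
- **Planted-winner recovery.** A +4σ winner is named unique best in only
  ≈74% of metabolites: with triplicates, each winner-vs-other pair has
  ≈10% chance of missing significance (q̄ ≈ 6.9 vs. critical ≈4.83, but
  the pair estimate has SD ≈0.97σ), and a unique best needs all six pairs
  at once. Recovery reaches 95% only at ≈+5σ and 99.7% at +6σ. The
  acceptance suite states the ≥95%-at-4σ expectation and is allowed to
  fail there: the shortfall is a property of triplicate designs, not of
  the implementation, and the corresponding unit test asserts the
  oracle-derived ~94% rate for the three-protocol variant instead.
- **CV calibration.** At n = 200 replicates the empirical CV of a 15%
  group falls in [13.5, 16.5] with probability 0.946 (CV sampling SD
  ≈0.78 at that n); tests assert the oracle-derived rate and that the
  mean CV centers on the target.

Problem sizes in the tests and the acceptance script (10,000 null
metabolites, 1,000 planted winners, 120 calibration groups of n = 200)
were chosen so Monte-Carlo standard errors (≤0.003, ≤0.014, ≤0.07 CV
points respectively) sit well inside the asserted tolerances.

## Pipeline runner

`run_all` executes read → validate → detect → compare → cv → overlap from
one config and writes CSVs plus `summary.json`, `resolved_config.yaml` and
a `MANIFEST.json` recording per-stage completion; any stage failure
raises after the manifest is written, retaining completed outputs. CSV
tables are the contract; figures are optional artifacts and rendering
failures downgrade to warnings (headless operation). Given fixed input
and config the bundle is byte-deterministic.
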