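# Methods

## The experimental world this package models

A crossed, fixed-effects design: coral species (each classed
*thermosensitive* or *thermotolerant* by whether it survives the highest
temperature) × temperature (an ordered set of levels, default 26/30/32 °C)
× predation (a standardized tissue lesion vs. none), with a fixed number
of fragments per cell and a single end-point assessment after chronic
exposure.  Two kinds of response are measured: a visual condition
category per fragment (normal / pale / bleached / dead) and, for a
subsample of surviving fragments, three protein-normalized biomarkers —
Hsp70 (chaperoning, µg mg⁻¹ protein), total ubiquitin (protein turnover,
µg mg⁻¹), and total antioxidant capacity (TAC, Trolox-equivalent
mM mg⁻¹).  Complete mortality of sensitive species at the top temperature
makes the biomarker design structurally incomplete; every downstream
choice below exists to cope with that.

## Assay quantification

Calibration is ordinary least squares on the standards,
`absorbance = slope·conc + intercept`, with R² reported so poor linearity
is visible; a four-parameter logistic is deliberately not fitted since
the modeled assays are specified by simple calibration lines over stated
ranges (0–2.0 mg ml⁻¹ for Bradford and both ELISAs, 0–0.330 mM for TAC).
Sample duplicates are averaged before inversion.  Two QC flags:
`extrapolated` when the interpolated concentration leaves the standard
range, and `high_cv` when the duplicate coefficient of variation exceeds
a threshold (default 20 %, common plate practice).  No blank subtraction
by default.  Normalization divides by total protein and errors on
non-positive protein rather than guessing.

The plate simulator inverts this model exactly (absorbance from a known
line plus Gaussian read noise), so quantification round-trips the
noise-free simulator for any non-zero slope — a property test, not an
assumption.

## Condition tabulation and aggregation

Percentages are `100·count/N` per (species, temperature, predation)
cell, rounded **half away from zero** to one decimal; empty cells are
absent, never zero-filled.  Group rows (sensitivity classes) are the
**unweighted mean of member-species percentages** rounded to integer
display precision — this convention, not fragment pooling, reproduces
every published grouped cell we bundle for regression testing (e.g.
77.5 → 78.0).  N for a group row is the arithmetically correct summed
fragment count; a printed source that says otherwise is preserved
verbatim in `datasets` and flagged there.

Sensitivity contrasts are two-sided pooled-variance t-tests whose
observation unit is one species × treatment-combination percentage (six
per species) — the unit under which the bundled published statistics
reproduce exactly.  The condition MANOVA takes per-species rows as
multivariate observations with one category dropped (default `bleached`,
the rarest) to break the sum-to-100 degeneracy; with that default it
reproduces the published Wilks F values although no published record of
the exact dependent-variable set exists.

## IBR

Per species, over its surviving conditions:

1. `X` = arithmetic condition mean per biomarker (≥ 2 conditions
   required; all-dead cells are dropped, never imputed).
2. `m`, `s` = mean and **sample** SD (ddof = 1, configurable) of those
   condition means.  Pooling raw replicates instead is available
   (`pooling="replicates"`) since "overall" is ambiguous in the lineage;
   condition-mean pooling is the default because indices are reported
   per species.
3. `Y = (X − m)/s`; `Z = Y` for stimulated (induced) biomarkers, `−Y`
   for inhibited ones.  Default: all three biomarkers stimulated, as all
   are defense responses; override per biomarker.
4. `S = Z + |min Z|`, so `min S = 0` exactly and `ΣY = 0` per biomarker —
   both asserted in tests, not just documented.
5. Scores are placed clockwise on star spokes at `α = 2π/n` and the index
   is the polygon area `Σ ½·Sᵢ·Sᵢ₊₁·sin α` with wrap-around closure
   (`closed=False` drops the closing segment; the summation limits in
   the lineage are ambiguous, closure is the geometric reading).

The segment-area expression printed in parts of the IBR literature
(`Aᵢ = Sᵢ/2·sin β·(Sᵢ cos β + Sᵢ₊₁ sin β)` with
`β = arctan(Sᵢ₊₁ sin α / (Sᵢ − Sᵢ₊₁ cos α))`) is dimensionally
inconsistent as usually typeset and does **not** equal the polygon area
(equilateral unit scores: 1.0245 vs 1.2990).  It is implemented behind
`variant="beta"` for audit only; the default triangle decomposition
equals the shoelace area of the star vertices to 1e-10 over random score
vectors, which the test suite verifies against an independent shoelace
oracle.

Useful identities that follow (and are property-tested): IBR ≥ 0;
IBR(c·S) = c²·IBR(S); cyclic rotations never change the index, and for
n = 3 *any* biomarker permutation is a rotation or reflection, so the
ordering convention (Hsp70, Ub, TAC clockwise) matters only for n > 3.

A biomarker with zero spread across conditions has no standardized
deviation; the default is a loud error naming it, with
`on_degenerate="zero"` available to score a flat response as zero signal.

The IBR ANOVA treats species × condition indices as replicate
observations in a two-factor temperature × predation model with
**Type III** (marginal, sum-to-zero coded) sums of squares — on the
unbalanced 34-cell published set, Type II shifts the predation F from
2.06 to 0.75, so the SS convention is load-bearing and fixed.

## Statistics suite

*Preprocessing.* Shapiro-Wilk on residuals from treatment-cell means and
Levene across cells, per response, at α = 0.05; failure of either gate
applies natural log then autoscaling (mean 0, SD 1).  Non-positive
values under log are an error, not a silent offset.  Every decision is
returned in a report and logged by the pipeline.

*Two-tier split.* The moderate tier keeps all species below the highest
temperature; the severe tier keeps all temperatures for species observed
at every temperature.  Both tiers are complete, making Type III terms
estimable; `factorial_manova` refuses rank-deficient design matrices
outright (the underlying libraries only warn and would return
pseudoinverse artifacts).

*Factorial MANOVA.* Wilks' λ with Rao's F per term under sum-to-zero
coding (marginal tests), univariate Type III ANOVAs per biomarker, and
Tukey–Kramer post-hocs (harmonic-mean cell sizes) for significant
multi-level main effects.  The intercept hypothesis is excluded from the
multivariate test explicitly: on centered responses its SSCP is
numerically zero and crashes the default implementation.

*PCA and clustering.* Correlation-matrix PCA (autoscaled variables);
explained variance sums to 100 % by construction.  Heatmap ordering
autoscales, averages by group, and clusters rows and columns with
Euclidean distance and complete linkage, returning leaf orders and
linkages for external plotting — no figures are rendered.

## Synthetic generator

Conditions are independent multinomial draws per fragment with
probabilities per (sensitivity, temperature, predation) cell; the default
table is read off the published group-level frequencies, with sensitive
species deterministically dead at the top temperature.  Biomarkers are
multiplicative: `baseline × temp × predation × interaction × exp(ε)`,
`ε ~ N(0, σ)` — lognormal noise because concentrations are positive and
right-skewed.  The published record gives qualitative trends only, so
default magnitudes are this package's calibration, chosen once:
temperature multipliers ×1.6–2.8 at 30 °C and ×0.8–3.5 at 32 °C tracing
the reported shape (Hsp70 and TAC peak at 30 °C, ubiquitin keeps rising),
predation ×1.4 on Hsp70, ×1.5 on Ub, ×0.75 on TAC, an interaction
multiplier applied to lesioned fragments above control temperature, and
σ = 0.3 (≈ 30 % CV, typical of ELISA between-fragment variation).  Three
response strategies (inducible / constitutive / biphasic) vary baselines
and multipliers between species.

Sampling honors the incomplete design: all-dead cells yield no biomarker
rows; a surviving cell with fewer fragments than requested replicates is
an error by default, or samples every survivor with
`on_shortfall="all"` (what the emulated experiment did).  A single seed
is split into per-stage substreams (condition / biomarkers / plates) so
stages regenerate independently; identical config and seed give
bit-identical tables.

What a green synthetic test establishes — and what it does not: the
generator reproduces the design geometry, the mortality pattern, the
trend directions and a realistic noise scale, so it validates the
*machinery* (estimability, calibration, power, determinism, geometry).
It does not reproduce the real data's effect magnitudes, between-colony
correlation structure, or condition–biomarker coupling (paleness does
not alter biomarker draws), so numerical agreement with the original
raw-data analyses is out of its reach by construction; those analyses
are supported for user-supplied data instead.

Monte-Carlo calibration, measured once at 1000 null datasets through the
full pipeline (simulate → preprocess → MANOVA): term-wise type-I error
0.061 / 0.051 / 0.061 at α = 0.05 (pooled 0.058 ± 0.004).  Power to
detect the default predation effect on ubiquitin via the moderate-tier
factorial ANOVA is ≈ 100 % at the default design size.

## Numerical conventions and degenerate inputs

- Rounding: half away from zero everywhere percentages are displayed
  (banker's rounding would turn 22.5 into 22).
- Zero pooled variance in a t-test: t = 0, p = 1 for equal means; an
  infinite-statistic result (p = 0) for unequal means.
- All-identical MANOVA/ANOVA inputs short-circuit to λ = 1, F = 0
  rather than raising from a singular decomposition.
- Star geometry requires n ≥ 3 non-negative scores; violations raise.
- Sample SD (ddof = 1) throughout unless stated.

## Known limitations

- No within-experiment time dynamics, tank/position effects, or
  plate-layout artifacts; single end point, as modeled.
- Linear calibration only; configure units if your ELISA standards are
  not literally in mg ml⁻¹.
- The IBR is reported un-normalized (no division by n) and no
  deviation-index ("IBRv2"-style) variant is provided beyond the audit
  flag.
- Tukey post-hocs run per factor, not per interaction cell.
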