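# Methods

## The measurement and its data model

A multiplexed bead-array run reports, for every bead region (analyte) and
every well, the median fluorescence intensity (FI) of the reporter bound
to that bead type. Wells play different roles: titrated **standards** of
known concentration define the dose–response reference; titrated **QC
controls** monitor performance; **unknowns** are study samples;
**background** wells contain buffer only; an optional uncoupled
(**blank**) bead region measures non-specific binding to the beads
themselves. Run workbooks carry one worksheet per bead type, each with
header metadata, a per-well ("raw") and/or per-sample ("summary") data
table, and a footer.

Where a sheet carries both tables, raw rows are authoritative for
computation and summary rows are retained for cross-checking; when only
summary rows exist, analysis proceeds on them and the file's reported %CV
is used (raw replicates are not available to recompute it). Footer
content is captured opaquely and never interpreted. Sample-type codes
follow the B/S/C/X convention (background, standard, QC control, unknown)
with an optional trailing index; positive/negative controls exist in the
data model but no type-code letter is assigned to them here.

## Normalization

The response handed to curve fitting is produced by a fixed pipeline:

1. blank-bead subtraction (optional): per well position, subtract the
   blank-bead sheet's FI in the same well;
2. background subtraction (optional): subtract the arithmetic mean FI of
   the analyte's background wells;
3. conversion (always): `FI' = max(FI, 0) + 1`, absorbing negatives the
   subtractions can introduce and keeping responses ≥ 1;
4. natural-log transform (optional), to damp variance extremes.

Both subtractions are additive per well, so their order is immaterial;
the order above is fixed for reproducibility. Background means are
recomputed from the run's own background wells rather than trusting a
file's "FI − Bkgd" column; a mismatch beyond 1e-6 relative emits a
warning and the recomputed value wins (summary exports can carry stale
columns). The natural log (not log₁₀) is used for fitting; plots may use
log₁₀ axes independently.

## Curve model and fitting

The five-parameter logistic in log dose is

    f(x) = A_min + (A_max − A_min) / (1 + exp(−h (ln x − ln m)))^s

with asymptotes `A_min` (dose → 0, for h > 0) and `A_max`, inflection
dose `m > 0`, slope `h ≠ 0` and asymmetry `s > 0`; `s = 1` is the
symmetric 4pl. Fits minimize the weighted residual sum of squares with
weights `wᵢ = 1 / max(yᵢ, 1)^p` on the observed prepared response
(default exponent `p = 1.8`, configurable per assay design; the floor of
1 guards the division). Weights use observed rather than fitted
responses; iteratively reweighted schemes are out of scope.

Optimization uses Levenberg–Marquardt on an unconstrained
parameterization (`ln m`, `ln s`) with tolerances of 1e-12.
Initialization: asymptotes from the observed response range, `m` at the
dose nearest the half-range crossing, `h = ±1` by the observed monotone
direction, `s = 1`; three seeded, jittered restarts guard against a bad
start, and the best converged start wins. The 5pl start set always
includes the 4pl solution, so the nested-model ordering (5pl weighted
RSS ≤ 4pl weighted RSS) holds by construction of the start set rather
than by luck. A titration left with fewer non-excluded points than free
parameters yields a non-converged fit whose metric cells are empty — the
output row remains.

Per-titration metrics:

- **EC50** — the midpoint dose, where f crosses `(A_min + A_max)/2`:
  `m (2^{1/s} − 1)^{−1/h}`, exactly `m` for `s = 1`. The midpoint-dose
  definition (not the inflection parameter) is used for the 5pl.
- **AUC** — trapezoidal area of (log₁₀ dose, mean response) over the
  observed non-excluded points only, with no extension toward the
  asymptotes. Whether the dose or the dilution axis is "the" AUC axis is
  a genuine design choice; log₁₀ expected concentration is used here and
  fixed in the output contract.
- **HighMFI** — the maximum replicate-group mean on the converted
  (non-log) FI scale, even when fitting used log responses, since the
  quantity is a fluorescence intensity.

Titrated QC controls (and titrated unknowns, when present) are fitted
with the same machinery; interpolation of unknowns always uses the
assigned standard's fit. Interpolation inverts f in closed form,
multiplies by the sample's fold-dilution, and reports responses outside
the open asymptote interval as below/above range — never extrapolated.
The 5pl fit is preferred for interpolation with fallback to the 4pl;
this is configurable.

## Within-run QC

%CV per replicate group (same analyte, sample and dilution) is
`100 · SD / mean` with the sample (n−1) SD — the estimator is a
deliberate choice, as is computing it on the post-subtraction,
pre-conversion FI scale (configurable to raw FI). The automatic flag rule
marks a group when mean FI > 100 **and** %CV > 15 (unknowns) or > 20
(standards and QC controls); comparisons are strict, matching
"greater than", and all three constants are configuration with these
defaults. Positivity calls require both `value ≥ fold_change × baseline`
and `value > threshold`; the fold-change default of 3 is a user
parameter, not an intrinsic constant.

Exclusions (whole analyte or one replicate group) mark rows and are
stored in an append-only JSON sidecar; parsed data is never mutated and
row counts in outputs never change. Excluding a titration point returns
a recompute set of (analyte, titration) pairs whose fits, metrics and
downstream interpolations are refreshed. Because each titration's fit is
seeded from a stable hash of (analysis seed, analyte, titration),
incremental recomputation is exactly equal to a full re-analysis with the
exclusions pre-loaded; the test suite asserts bit-level equality over
random exclusion sequences.

## Cross-run QC

Four metrics per (analyte, titration role) are tracked across runs: 4pl
EC50, 5pl EC50, AUC and HighMFI. A guide set is an explicit, user-chosen
list of baseline runs sharing a lot scope (reagent lot, isotype,
conjugate); membership is never automatic. Its per-metric mean and
sample SD define nested expected ranges at ±1, 2, 3 SD. A non-member
run's metric is flagged when strictly outside ±3 SD — boundary values are
not flagged ("falls outside" the range) — and member runs are never
flagged against their own set. Flags are records: inactivation after
review stores a comment and sets `active=false`, idempotently, without
deletion. Levey-Jennings series order runs by acquisition (ties by run
id) and switch band regimes at lot boundaries. Only the ±3 SD rule is
automated; trend reading is left to the chart. Westgard multi-rule
schemes are out of scope.

## Synthetic data

The generator emulates the study conditions end to end: a 96-well plate
with triplicate wells, a 10-point 3-fold standard series from a top
concentration of 10,000 pg/ml, three antigens with 4pl truth curves
(asymptotes ≈ 50–30,000 FI, inflections 150/400/900 pg/ml, unit slopes),
four unknowns spanning the curve at 1:100 dilution, and buffer-only
background wells (truncated-at-zero normal, mean 25 FI, 10% CV). The
replicate noise model is multiplicative lognormal with unit median and
coefficient of variation `noise_cv` (default 0.05): FI is positive and
its spread grows with signal, which is exactly the heteroscedasticity
the power-law weights address. Workbooks are byte-identical for
identical config and seed (fixed workbook properties and zip
timestamps), and a ground-truth JSON sidecar records true curves, per-
well concentrations, noiseless and realized FI.

What the generator does **not** emulate — plate-position effects, bead-
count failures, doublets, optics drift, cross-reactivity — bounds what
passing tests show: they validate the computational engine against its
own stated model, not robustness to every instrument artifact in real
data.

## Numerical and scale choices

Acceptance-style checks in the test suite run at sizes chosen to probe
the statistics without waste: 100 simulated titrations for EC50 recovery
(median relative error < 5%, unbiasedness within 3 Monte-Carlo SEs,
nesting in 100/100), 10,000 simulated metrics against a 30-run guide set
for the null flag rate (2·Φ(−3) ≈ 0.0027 within 3 Monte-Carlo SDs —
simulated metrics are drawn from the guide set's own fitted mean/SD, the
regime in which the 3-sigma rule has its nominal level), 1,000-point
interpolation round-trips at 1e-9 relative tolerance, and an independent
midpoint-Riemann oracle for the AUC at 1e-9. Degenerate inputs are
defined, not accidental: %CV is absent below two replicates or at zero
mean; EC50 is absent for non-finite closed forms; AUC needs two distinct
doses; guide-set SDs are absent (and flagging disabled) below two
members.

## Known limitations

No limits of detection/quantitation, no mixed-effects or Bayesian curve
models, no drift correction, no plate-layout design, and no parsing of
xPONENT/MILLIPLEX export dialects. The workbook dialect is the one the
generator writes and the parser reads; real-world Bio-Plex exports vary,
and the tolerant column matching (case-insensitive canonical names,
extras preserved) is designed to absorb benign variation, not every
vendor quirk.
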