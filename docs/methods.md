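# Methods

This note documents the models implemented in `herbdiff`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not demonstrate.

## Data model

A **peak table** is one sample's injection: per common peak (integer id
1–18, fixed numbering), a retention time in minutes and a detector area in
arbitrary units (no unit conversion is ever attempted; areas only need to
be consistent within a dataset).  A **calibration series** is a set of
(concentration µg/ml, area) levels for one compound on one instrument.
Compound metadata (formula, nominal Mr, nominal retention time,
calibration line, standard stock concentration) live in a registry keyed
by peak id; the seven calibrated compounds carry the published calibration
lines (e.g. chlorogenic acid: area = 2.564·10⁴·c + 5.208·10³), the three
flavones quantified by extrapolated response factors carry slopes
consistent with those factors, and the four unidentified peaks carry a
generic response of 2.5·10⁴ area/(µg/ml).

The slope of apigenin-7-*O*-6″-malonylglucoside (peak 16) is chained
through the molecular-weight-extrapolation rule from the measured
peak-11/peak-6 slope ratio (2.628·10⁴/1.08), not from an independent
value: the published base response factor (0.76) is not derivable from the
published slopes, and chaining keeps the synthetic world self-consistent —
extrapolated quantification is then exact on noiseless data.

## Fingerprint similarity

Peaks are matched to the 18-slot template when |rt − rt_slot| ≤ 0.1 min
(default tolerance; small against the 65-min gradient and 5σ above the
0.02-min jitter), nearest slot on ties; two distinct peaks claiming one
slot abort with the sample named.  Unmatched slots get area 0.  Similarity
of a sample against the pooled mean chromatogram is the angle cosine by
default (Pearson correlation available), computed on raw areas ("original
data"); relative peak areas — each peak divided by chlorogenic acid
(peak 2), the abundant internal reference of the quantification stage —
are available via `use_rpa`.  Cosine similarity is scale-invariant and
equals 1 for self-comparison; correlation is affine-invariant for
positive slopes.

## OPLS-DA and the marker screen

The class vector is coded CM = 0, CI = 1 and centered; X columns are
autoscaled (mean 0, SD 1 with n−1 denominator; constant columns are
centered, given scale 1 and flagged — the RPA reference column is the
usual case).  The single-y NIPALS orthogonal filter first extracts
`n_ortho` components of X-variation uncorrelated with y (default 1, the
two-class convention), then one predictive component.  R²X and R²Y are
explained-sum-of-squares fractions; Q² comes from stratified 7-fold
cross-validation with seeded fold assignment (folds shrink to the smaller
class count when needed), the only randomness in the fit.

VIP is computed on the predictive component only (marker screening
targets class-predictive variation): with the unit-norm predictive weight
vector w over p variables, VIP_j = √p·|w_j|, so mean(VIP²) = 1
identically.  The univariate screen is the pooled-variance two-sample
Student's t-test (Welch behind a flag); columns degenerate in both groups
get p = 1 (equal means) or 0.  A peak is selected iff VIP > 1.0 **and**
p < 0.05, both strict, without multiplicity correction (the screening
convention); Benjamini–Hochberg is available but off by default.

Note that on either raw areas or RPAs nearly every peak carries *some*
class signal in the default synthetic world — raw areas because the two
classes use different sample masses (0.25 g vs 0.5 g in 25 ml, as in the
preparation protocol), RPAs because the reference peak's content itself
differs by class.  The tests that assert "noise peaks are not selected"
therefore equalize the sample masses so that shared-range peaks are truly
uninformative.

## SSDMC quantification

The response-factor definition and the quantification formula must agree
in orientation; the two printed forms do not.  The implementation adopts

    RRF_x = (1/N) Σ_i (A_si/C_si)/(A_xi/C_xi)      (reference over analyte)
    C_x   = A_x · C_s · RRF_x / A_s

which is the unique pairing under which quantifying synthetic data with
known responses recovers the generating concentrations exactly (verified
to 1e-9 in the tests); the literal typeset alternative is available as
`orientation="as_printed"` for audit.  RRFs average the per-level ratios
over the N = 7 calibration levels; internal references are chlorogenic
acid (caffeoylquinic acids) and luteolin-7-*O*-glucoside (flavone
glycosides).  RRF and RRT are reported to 2 decimals, RSDs to 1 decimal.

Analytes without standards get RRF = (Mr_x/Mr_base)·RRF_base from a
structurally similar base compound with near-identical molar absorptivity
(e.g. 462.3/448.3 × 1.00 = 1.03).  This assumes the chromophore dominates
the molar response so that the mass response scales with Mr — an
approximation, flagged as such.

External-standard quantification (ESM) is ordinary least squares of area
on concentration and C = (A − b)/a, floored at 0 with a warning.  SSDMC
and ESM coincide exactly when calibration intercepts vanish; with the
published nonzero intercepts SSDMC inherits a small concentration-
dependent bias, which is why the exactness properties are stated (and
tested) in the proportional-response world.

### Validation battery

Per calibrated analyte, on synthetic data: linearity r² of a noisy
seven-level series; LOD = 3σ/slope and LOQ = 10σ/slope with σ the SD of
20 blank injections (baseline SD 20 area units by default — chosen to put
LODs far below working concentrations, as in practice); repeatability RSD
over 6 re-injections at 1% area CV; precision RSD over 2 instruments × 3
injections (instrument response factors 1.00/1.01); spike recovery at
75/100/125% of the native amount, 3 replicates per level, with the native
amount taken as the mean of the repeatability determinations (the usual
recovery protocol) and standards injected in triplicate.  Method
comparison pairs the per-analyte mean results of independent SSDMC and
ESM injection series (two-sided paired t) and compares the pooled
relative deviations of the two series (two-sided F).  The battery runs in
the proportional-response model, under which both methods are unbiased
and the comparison behaves as a null: p-values are approximately uniform
across seeds.

## Mass-spectrometric annotation

Monoisotopic masses use full-precision IUPAC atomic masses via pyteomics
(C 12 exactly, H 1.0078250, O 15.9949146, ...).  The default [M-H]⁻
convention subtracts the hydrogen-*atom* mass 1.00783 and neglects the
electron, reproducing conventional 4-decimal table values
(C₁₆H₁₈O₉ → 353.0873); `electron_correct=True` subtracts the proton mass
1.00728 instead (physically exact: 353.0878).  ppm error is
10⁶·(obs − calc)/calc.  Neutral-loss annotation tries every library loss
and every unordered two-loss combination against the precursor−fragment
difference and keeps the smallest residual within 10 ppm (precursor
errors run within ±4 ppm; fragment calibration is looser).  The shipped
library (caffeoyl C₉H₆O₃ 162.0317, glucose residue 162.0528, rhamnose
residue 146.0579, glucuronide residue 176.0321, rutinose residue
308.1107, malonyl 86.0004, CH₃ 15.0235, CO₂ 43.9898) recomputes and
self-checks every mass from its formula at import.

## Logistic discrimination

The published equation is evaluated verbatim: Y = 14.52 − 53.16·C13 +
51.52·C6 − 313.09·C11 − 445.74·C6 + 109.94·C16 + 26.33·C10 with contents
in % w/w.  It contains "C6" twice with different signs; by default the
duplicate keys are summed (peak 6 gets 51.52 − 445.74), and the
alternative reading — the second occurrence meaning peak 15, suggested by
the six-distinct-marker list — is selectable.  Negative Y ⇒ CM; the
boundary Y = 0 goes to CI, since only strictly negative scores meet the
CM criterion.

Our own model is maximum-likelihood logistic regression on the six
distinct quantified markers {6, 10, 11, 13, 15, 16}, with an L2 penalty
of λ = 1e-4 on standardized contents — the synthetic classes are
perfectly separated (three markers are structurally absent in CI), so the
unpenalized MLE diverges.  Coefficients are back-transformed to the raw
content scale; CI is the positive class, so CM scores negative.  Both
held-out (stratified 50/50 split) and resubstitution accuracies are
reported, since it is ambiguous which one a field-validated "100%" refers
to.  Under the default study conditions the held-out accuracy is 100% for
most seeds; occasionally (≈2 seeds in 10) one borderline CM sample lying
at the joint low-content corner of all six markers crosses the fitted
boundary, giving 97.7% — an honest property of a penalized linear
boundary on overlapping continuous markers, not a defect of the
quantification.

## Synthetic generator: what it emulates and what it does not

Emulated: the two-class design (53 CM / 33 CI), per-class marker-content
structure (uniform draws within class ranges; log-uniform optional for
skewed markers), the fixed preparation (0.25 g CM / 0.5 g CI in 25 ml)
linking % w/w contents to solution concentrations, proportional detector
response through each compound's slope, 1% multiplicative area noise,
0.02-min retention jitter, two instruments with a 1% response offset,
seven-level two-fold calibration dilutions, blank-injection baseline
noise, and spike-recovery samples.  Only the class *totals* of the
caffeoylquinic acids and flavone glycosides and the linarin mean are
published; the per-peak splits of those totals are this package's
assumptions (chosen once so the low/high sums reproduce the published
totals and linarin's CI mean is 0.636% at six times its CM mean), as are
all ranges for the non-marker peaks.

Not emulated: continuous chromatogram traces, co-elution, detector
saturation, UV spectra, between-batch drift, or the real samples'
geographic heterogeneity.  Passing tests therefore demonstrate the
*correctness and statistical behaviour of the computations* under the
stated noise model — not that the real herbs are separable with these
exact figures; the published real-sample similarity ranges, OPLS-DA
R²/Q², and LOD/LOQ values depend on the physical samples and are not
reproduction targets.

## Numerical choices and degenerate inputs

Deterministic seeding throughout (numpy `default_rng` with derived
streams; identical config ⇒ bitwise-identical output).  Zero-norm or
constant vectors make cosine/correlation undefined and raise; a zero
reference area blocks RPA and SSDMC; degenerate paired comparisons
(identical vectors) report p = 1 with a zero-variance flag; rank
collapse in the NIPALS loop (n_ortho too large) raises a numerical
error rather than returning noise.  Problem sizes in the test-suite
simulations (86-sample sets, 40-seed recovery sweeps, 1000-variable null
screens) were chosen as the smallest giving stable statistics.

## Known limitations

- RRT is a plain retention-time ratio; it does not model gradient
  nonlinearity between instruments (the published inter-instrument RRT
  pairs are used directly where ruggedness figures are needed).
- The loss library covers the phenolic/glycoside chemistry of these two
  herbs only; adduct chemistry, isotope patterns and positive mode are
  out of scope.
- The discriminant is linear in contents by design; no probability
  calibration or multi-class extension is attempted.
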