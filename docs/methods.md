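# Methods

## Experiment geometry

The analysis targets a plate-based clonogenic assay irradiated through a
12-step range shifter: each column of a 96-well plate receives the
prescription dose scaled by a per-column *dose modulation factor* and a
column-specific dose-averaged LET. The packaged `table1` physics fixture
describes such a jig: factors ≈ 1.000 across columns 3–10 (the SOBP
plateau, LET 2.2267 → 5.6344 keV/μm), a distal high-LET step at column 11
(factor 0.2549, 14.1959 keV/μm), and a column 12 that is effectively
unirradiated (factor 7.94·10⁻⁴). "2 Gy" therefore labels the plateau dose;
delivered dose per column is prescription × factor.

The SOBP window defaults to columns 3–10 inclusive (8 columns). Window
summaries are the arithmetic mean and *sample* standard deviation
(n − 1 denominator) of the per-column values.

## Survival model and fitting

Photon survival follows S(D) = exp(−(αD + βD²)). `fit_lq` minimizes
Σᵢ (S(Dᵢ) − SFᵢ)² over all replicate points individually, on the
untransformed SF scale, with both parameters unconstrained. Rationale for
replicate-level fitting: the reported degrees of freedom of such fits equal
n_points − 2, which is only consistent with fitting individual wells rather
than dose means. Initialization uses α₀ = ΣDᵢyᵢ/ΣDᵢ² with yᵢ = −ln SFᵢ (the
origin-constrained log-linear slope) and β₀ = 0, which is robust for both
downward-curving (α > 0) and shouldered (α < 0, β-dominated) data.
Convergence: Levenberg–Marquardt with ftol = xtol = gtol = 1e-10, at most
600 function evaluations; non-convergence raises rather than returning a
partial fit.

Confidence intervals are asymptotic t-intervals from the analytic Jacobian
at the optimum, cov = (JᵀJ)⁻¹·SS_res/(n−2); R² = 1 − SS_res/SS_tot on the SF
scale; α/β is computed from unrounded parameters. Under the synthetic
binomial-noise conditions below, the joint 95% CI coverage of (α, β)
measures 92/100 (the test asserts ≥ 90).

## Isoeffect dose and the two RBE pathways

For a proton-measured SF, the matched photon dose solves
βD² + αD + ln SF = 0. With β > 0 and SF < 1 the root
(−α + √(α² − 4β ln SF))/(2β) is the unique nonnegative solution (including
for α < 0); β = 0 degrades to the linear model D = −ln SF/α; SF = 1 gives
D = 0 exactly. When SF > 1 the discriminant may be negative or both roots
negative — there is then no photon dose producing that survival, and the
column is flagged `no-real-root`.

RBE = D_iso/D_proton is aggregated two ways and both are always reported,
with the pathway recorded in every output row and in the run manifest:

* **per-column**: invert each window column's SF, average the RBEs
  (mean ± sample SD over columns with a real root);
* **aggregate-SF**: average the window SFs first, invert once.

They coincide only for constant SF (tested); because the LQ inverse is
convex in ln SF they generally differ, and published summaries of this
design have used either — hence both. The default `no_root_policy`
(`exclude`) drops unsolvable columns from the per-column summary and
records their status; `error` aborts instead. A per-column mean computed
after exclusions is conditional on solvability and is not comparable across
cell lines with different exclusion counts — outputs therefore carry the
number excluded.

## Association statistics

LET–RBE association is the Pearson correlation over the window columns
(n = 8), two-tailed p from t = r√(n−2)/√(1−r²) on n − 2 df. Correlations are
only computed from per-column (pathway A) RBEs with ok status; with the
default policy a line/dose whose window contains unsolvable columns gets a
reduced n, reported alongside. No multiple-testing correction is applied.
Surviving-fraction comparisons expose paired, Welch, and pooled two-sample
t-tests; published reports of this assay rarely state the variant, so all
three are available and the variant is recorded in the result.

## Colony counting

Binarization uses Yen's entropic-correlation criterion on the 256-bin
histogram: maximize TC(t) = −ln[(Σ_{i≤t} pᵢ²)(Σ_{i>t} pᵢ²)] +
2 ln[P(t)(1−P(t))], ties broken toward the smallest t; foreground is the
pixel set on the configured polarity side (colonies darker by default).
Components are labeled at 8-connectivity (4 available) and only components
of area ≥ 5 px (strictly "bigger than four pixels") count, one colony each.
Light staining is removed by the threshold itself; there is no second
intensity cutoff, no hole-filling, no watershed — touching colonies merge
into one, a known limitation.

Thresholding is per-well by default (each ROI's own histogram), tolerant of
plate-edge illumination gradients; a whole-plate mode is available. Two
degenerate-well guards exist: a uniform (single-bin) histogram cannot be
thresholded and counts 0 with a warning; and a well whose foreground and
background class means differ by fewer than `min_foreground_contrast` gray
levels (default 20) is treated as colony-free. The second guard addresses a
real failure mode of entropic thresholding measured during development: on
a histogram that is just unimodal background noise, Yen's criterion still
returns a cut and will happily "segment" noise. Stained colonies sit
≥ 100 gray levels from background, so the guard is far from interfering
with real detections; set 0 to disable.

## Synthetic data generator

`simulate_survival_counts` draws each well's colony count from
Binomial(cells_seeded, PE·S(D_c)) with D_c = prescription × factor_c and
α_c = α + (LET slope)·LET_c. Defaults mirror the assay design: 96-well
plates, 100 cells seeded per well, 8 replicate wells per column (one plate
row each; replicate counts beyond 8 spill onto further plates), photon
doses 1–6 Gy, proton prescriptions 2 and 4 Gy. Binomial (not Poisson) noise
is used because the 100-cell seeding is small and bounded. All randomness
derives from one explicit seed through `numpy.random.default_rng`; separate
doses get child streams of the same seed.

`render_plate_image` turns per-well counts into an 8-bit grayscale image:
background 200, colony disks at a stain level drawn per well from
N(65, 5²) (staining varies between wells far more than within), disk radius
uniform in [2.0, 3.0] px, centers rejection-sampled inside the well ROI
with a 4-px rim-to-rim margin (whole-well restart on jams, error when
placement is impossible). The 2.0-px radius floor guarantees a rasterized
area ≥ 12 px at any subpixel center — during development a 1.5-px floor
produced legitimate 4-px disks that the area filter then (correctly)
rejected, a truth-side artifact worth remembering when changing the range.

The default background is noise-free. Under that default the well histogram
is exactly two spikes, Yen's tie-break lands on the colony bin, and
counting recovers ground truth exactly — this is what the round-trip tests
assert (0 mismatches over 9600 wells). With `noise_sd > 0` the generator
adds iid Gaussian pixel noise, and counting is no longer exact: Yen's
criterion places the cut so that a 1–7% slice of the background's lower
tail joins the foreground, producing occasional 5-px speckle clusters
(+1 counts) and, at small inter-colony margins, noise bridges (−1);
measured error rates are ≈0.2–1.2% of wells at sd 1–2. Real plate images
add further effects the generator does not model — uneven illumination,
out-of-focus halos, colony size/shape dispersion, touching colonies — so
exact recovery on synthetic plates validates the bookkeeping (threshold
placement, labeling, area filter), not counting accuracy on real images.

## Numerical conventions and edge cases

* SF values are never clipped at 1; sampling noise routinely produces
  SF > 1 and the RBE stage handles the consequence (no-real-root) instead.
* The control reference for SF normalization is configurable (a designated
  plate column or an unirradiated plate), because which wells serve as
  controls is an experiment-level choice; it must be > 0.
* Isoeffect back-substitution is verified to 1e-9 in tests; the closed form
  is cross-checked against bisection to 1e-6.
* RBE values are carried unrounded; 4-decimal rounding is display-only.
* Window summaries require ≥ 2 columns; Pearson requires n ≥ 3 and nonzero
  variance; all violations raise typed errors rather than returning NaN.

## Problem sizes used in the test suite

Simulation-based tests run at sizes chosen to keep the suite fast while
leaving no statistical ambiguity: 10⁴ replicate wells for law-of-large-
numbers checks (assertions at 3 standard errors), 100 seeded plates for
counting round-trips, 100 seeded fits for CI coverage, 10⁴ null replicates
for p-value calibration (band 0.040–0.060 at the 0.05 level), and 10³
random cases for each oracle-equivalence check.

## Known limitations

* Per-column physics is consumed as given (factor + LET per column); no
  particle transport is modeled.
* The photon LQ fit is unweighted; heteroscedasticity across doses is
  ignored (binomial noise makes low-SF points relatively noisier).
* Entropic thresholding on noisy, low-contrast wells is intrinsically
  fragile (see above); counts from such wells should be treated with care.
* The aggregate-SF pathway has no SD of its own (it is a single inversion);
  comparing its value with a per-column SD mixes estimands.
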