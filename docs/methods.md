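# Methods

## Melting model

Protein denaturation across a temperature gradient is modeled by the
three-parameter sigmoid used throughout chemoproteomic thermal-stability
work:

    f(T) = (1 − plateau) / (1 + exp(b − a/T)) + plateau

- `a` (> 0, °C-scaled): slope numerator; together with `b` it sets the
  transition midpoint and steepness.
- `b` (> 0, dimensionless): offset of the logistic argument.
- `plateau` (∈ [0, 1)): non-denaturable fraction remaining soluble at high
  temperature.

Temperatures are °C, not Kelvin; because the model divides `a` by T the fit
is unit-sensitive, and all defaults assume the 37–67 °C TPP gradient.
The melting temperature is the half-denaturation point,
`Tm = a / (b − ln(0.5/(0.5 − plateau)))`, defined only for `plateau < 0.5`,
and only reported when it falls within 5 °C of the measured gradient
(`[min grid − 5, max grid + 5]`); crossings further out are extrapolation
artifacts and are treated as undefined rather than reported.

Fitting is bounded nonlinear least squares (`scipy.optimize.curve_fit`,
trust-region reflective) from coarse data-driven starts: the plateau is
initialized at the profile minimum, the midpoint at the interpolated
half-crossing, and three values of `b` (10, 6, 16) are tried, keeping the
lowest-RSS converged solution. Solver failure or a variance-free (flat)
profile yields `valid=False` instead of an exception. The per-curve quality
filter (R² ≥ 0.8, plateau < 0.3, Tm defined) follows common TPP practice
and is configurable, since published criteria vary.

Normalization divides each profile by its abundance at the reference
(lowest) temperature; it is idempotent and errors on a missing or
non-positive reference.

## Hypothesis testing

Per protein, the null model pools both conditions and all replicates into
one sigmoid fit (3 parameters); the alternative fits each condition
separately (6 parameters), with replicates pooled as independent
observations within a condition. The F-statistic
`((RSS0 − RSS1)/3) / (RSS1/(n − 6))` is referred to F(3, n−6)
(theoretical degrees of freedom, the default). Proteins whose fits fail are
flagged untestable and excluded before Benjamini–Hochberg adjustment, so
the multiplicity correction runs over the hypotheses actually tested. F is
clamped at 0 when the pooled fit edges out the per-condition fits by solver
tolerance, and a zero alternative RSS reports a p-value floor of 1e-300
with a warning rather than NaN.

With multiplicative (hence heteroscedastic) noise and the plateau bounded
at 0, the theoretical reference distribution has the correct 5% tail in our
simulations but is right-skewed overall: near-boundary plateau estimates
give the alternative model fewer effective parameters than 6. The
`df_method="empirical"` option therefore moment-matches effective degrees
of freedom by maximum-likelihood fitting of scaled chi-square (gamma)
distributions to the across-protein numerator (RSS0 − RSS1) and denominator
(RSS1) samples, the approach established in the NPARC literature, which
restores approximate uniformity of null p-values. The default remains
theoretical; the empirical option is for calibration-sensitive use.

BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
(`fdr_bh`); the test suite cross-checks it against a literal brute-force
step-up implementation. Hit tiers: nominal p < 0.05 (significant), nominal
p < 0.01 (marked, a subset by construction), adjusted p < 0.1 (prime),
the prime tier decided from the adjusted p-value independently of the
nominal ones.

## Synthetic data

The generator emulates TMT-style relative abundances: ten temperatures
evenly spaced over 37–67 °C, two conditions (vehicle/treatment), two
biological replicates, a configurable fraction of true shifters, and
multiplicative Gaussian noise truncated at zero (the data are relative
non-denatured fractions, so the simplest noise model preserving positivity).
Replicates are i.i.d. noise redraws around the same true curve — no
replicate-level biological variance is simulated.

Baseline curves are drawn by sampling `Tm ~ U(46, 62) °C`,
`b ~ U(8, 12)`, `plateau ~ U(0, 0.2)` and deriving `a` from the closed-form
Tm relation. Sampling Tm (rather than `a`) directly guarantees every
baseline melting point lands inside the 45–70 °C span observed for the
human proteome; the induced `a` range is roughly 350–750. A shifter's
treatment curve re-derives `a` so that Tm moves by exactly the injected
ΔTm (drawn N(3, 1) °C by default) while `b` and `plateau` are held fixed,
keeping ground truth exact rather than approximate. Defaults
(`noise_sd = 0.05`, `shift_fraction = 0.1`) are assumptions chosen to give
realistic single-digit-percent quantification noise and a sparse target
set; no published replicate-noise magnitude exists for this design to
calibrate against.

What the generator does **not** emulate: TMT reporter-ion intensities and
their ratio compression, isotopic impurity, peptide-to-protein rollup,
missing channels, or correlated (batch) noise. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to every artifact of real TPP data.

## Compound annotation

Elemental formulas over C, H, N, O, S, P are parsed by an element–count
grammar and summed with standard monoisotopic masses (C 12 exactly,
H 1.00782503, N 14.00307401, O 15.99491462, S 31.97207117, P 30.97376200).
Adducts are [M+H]⁺ in positive mode and [M−H]⁻ in negative mode (proton
mass 1.007276 Da), uniformly — including quaternary alkaloids printed with
neutral-style formulas, for which the uniform treatment still reproduces
the printed m/z within 5 ppm. Two negative-mode glycosides (hastatoside,
atractyloside A) ionize as formate adducts [M+HCOO]⁻, common with a
formic-acid mobile phase; the packaged table marks these rows explicitly
and the calculator supports the adduct. The affinity-capture (binding)
table prints no ionization mode, so the packaged fixture carries a per-row
mode inferred from which adduct matches the printed m/z — an annotation,
not a published value.

The default ppm tolerance is 5 (Orbitrap-typical). All identification
filters use strict inequalities (score > 80, ratio > 20, binding score
> 70), and deduplication/blank-subtraction match names exactly after case
folding and whitespace normalization — no synonym resolution is attempted.

## Evidence integration

Interaction networks are undirected simple graphs over uppercased symbols;
self-loops are dropped and duplicate or reversed edges collapse on load.
Degree ranking breaks ties alphabetically for determinism. The
stable-binding rule flags a docking record when XP GScore < −6 or MM-GBSA
dG Bind < −30 kcal/mol, both strict. No external services (target
prediction, STRING, enrichment) are queried; the package operates only on
user-supplied lists and edge lists.

## Problem sizes and numerical choices

Simulation-based checks in the test suite use 1000 proteins for null
calibration, 120 per shift level for power, 500 for the Tm-distribution and
replicate-reproducibility properties, and 20 × 100 for the
false-discovery-proportion check — sizes at which Monte-Carlo error is
small relative to the asserted margins while the whole suite completes in a
few minutes on one CPU. Parameter-recovery tolerances are 1e-4 relative on
noiseless grids; the closed-form Tm agrees with a bisection root-finder to
1e-6 °C. Exponential arguments in the sigmoid are clipped at ±700 to keep
overflow out of the optimizer's path.

## Known limitations

- The F-test's theoretical degrees of freedom are approximate for bounded,
  nonlinear fits (see above); calibration-critical analyses should use the
  empirical-df option.
- Tm-based ΔTm is computed per replicate and is undefined when either
  condition's curve never crosses 0.5 inside the extrapolation window.
- The compound-name deduplication is only as good as the reported names;
  isomers reported under different names stay distinct.
- Isothermal dose–response designs and spline-based curve comparison are
  out of scope.
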