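# Methods

## Equilibrium model

The package models one rapid-equilibrium-dialysis insert: a red chamber of
volume `redvol` (µL) holding protein at total concentration `t0` (µM) and a
white buffer chamber of volume `whitevol`. A compound added to the red
chamber distributes over three pools — free white (`lwhite`), free red
(`lfred`) and protein-bound (`tl`), all µM — subject to ligand conservation,
protein conservation (`tf + tl = t0`), the 1:1 mass-action law
(`tl·KD = tf·lfred`) and a control-partition factor (`lfred = pc·lwhite`).
`pc` is measured in a protein-free control and corrects for compounds that
equilibrate slowly or partition slightly unevenly; it is a single
multiplicative factor, so strongly non-equilibrating compounds (pc outside
0.90–1.10) are excluded rather than modelled. The model is exact under
ligand depletion: no assumption of protein excess is made.

Assumptions: a single 1:1 binding site (no cooperativity or multi-site
binding), full equilibration within the incubation time, detector response
linear over the calibrated range, and no compound loss beyond what the
mass-balance check flags.

### Forward solve

Eliminating `lwhite`, `tf` via the conservation laws leaves a quadratic in
the complex concentration `tl`:

    pc·redvol·tl² − (pc·(t0·redvol + L) + KD·A)·tl + pc·t0·L = 0

with `L = l0·(redvol + whitevol)` (total ligand, µM·µL) and
`A = whitevol + pc·redvol`. The linear coefficient is strictly negative, so
the physically admissible (smaller) root is computed as `2c/(−b + √(b²−4ac))`,
which is free of subtractive cancellation; admissibility (`0 ≤ tl ≤ t0`,
non-negative concentrations) is what selects the root, not a root index in a
symbolic solver's output order, which is fragile under algebraic
rearrangement. `KD = 0` bypasses the quadratic entirely: binding proceeds to
the stoichiometric limit `tl = min(t0, L/redvol)`. `t0 = 0` gives `tl = 0`.
The solver is verified in the test suite against an independent bisection
root-find of the raw binding law over `tl` (1e-9 relative over 1000 random
configurations spanning two orders of magnitude in every parameter).

### Inverse estimators

Each measured observable determines `(lwhite, tl)` algebraically:

* from `lwhite`: `tl = (L − lwhite·A)/redvol`
* from `lred`:  `lwhite = (L − lred·redvol)/whitevol`, `tl = lred − pc·lwhite`
* from `pt`:    `lwhite = L/(whitevol + pt·redvol)`, `tl = (pt − pc)·lwhite`

and then `KD = pc·lwhite·(t0 − tl)/tl` exactly. These compact substitutions
are algebraically equivalent to the fully expanded closed forms and
round-trip the forward solve to 1e-8 relative in the tests. Domain edges are
surfaced as typed errors: an observable at or beyond its no-binding value
(`pt ≤ pc`; `lwhite` at the protein-free level; `lred` without enrichment)
raises a no-detectable-binding error, and an observable implying `tl ≥ t0`
or negative concentrations raises an infeasible-measurement error.
Estimates above a configurable ceiling (default 500 µM, where precision has
degraded badly) are returned but flagged `above_recommended_range`.

## Uncertainty

Replicates are aggregated as mean and population (divisor-n) standard
deviation — matching the convention of numpy's default `std` — with the
sample (n−1) convention behind a flag. First-order (delta-method) error
propagation uses hand-derived analytic derivatives: all three estimators
share the structure `KD = pc·w·(t0 − tl)/tl` with `w` and `tl` linear or
rational in the observable, so each derivative is a short chain-rule
expression, and `∂tl/∂pc = −w` in every route gives one shared `∂KD/∂pc`
term. Every derivative is cross-checked in the tests against central finite
differences (1e-6 relative) and against a 100,000-draw Monte-Carlo
propagation (within 5% at 1% CV). Uncertainty in `pc` enters only when a
`pc` Measurement is explicitly supplied, in which case its mean also
replaces the configured `pc`.

Confidence intervals use endpoint evaluation: K_D is strictly monotone in
each observable, so evaluating the estimator at `value·(1 ± h)` bounds the
image of the error band exactly. The default half-width `h = 0.025` labels
the interval 2σ, reproducing a ±5% detector error quoted at the 2σ level;
this endpoint convention (rather than a linearised ±5% on K_D) is the one
arithmetic that reproduces all six reference interval endpoints for the
standard system. An endpoint that leaves the estimator's valid domain
raises a partial-interval error naming the failing side.

The sensitivity profile reports `∂KD/∂lred`, `∂KD/∂lwhite` and `∂KD/∂pt`
at the forward-solved observables for a given K_D. For the standard
geometry the red chamber is the least error-sensitive observable at every
K_D, and gradient magnitudes grow roughly 200-fold between K_D = 1 and
500 µM — the quantitative reason the technique is best kept below
~200 µM K_D.

## Calibration and QC

Detector response is fitted by ordinary least squares (`scipy.stats.linregress`)
as `area = k·conc + d`; r² below 0.99 or residuals beyond 3 residual-σ are
flagged (not silently dropped) as linear-range diagnostics — deliberately
conservative defaults, since the protocol itself gives no numeric linearity
criterion. Back-calculation applies the aliquot dilution factor (1 for
HPLC, 20 for LC–MS) and treats areas below the fitted blank as errors
rather than clamping to zero, so detector drift surfaces instead of
vanishing. HPLC curves are in µM, LC–MS curves in nM (the
`concentration_uM` CSV column carries the curve's native unit); the QC
layer converts to µM internally.

QC on the compound-only control: `p_c` is the dilution-corrected red/white
area ratio, paired per device by `sample_id` (pooled mode available — the
protocol does not say which pairing its replicates used); pass band
0.90–1.10. Mass recovery compares `conc_red·redvol + conc_white·whitevol`
(1 µM·µL = 1e-12 mol) with the introduced amount; pass within ±10%. Either
failure sets the exclusion verdict, with reasons listed. With protein
present the red chamber is hard to chromatograph, so `lred` can instead be
derived by difference from the total amount and the measured `lwhite`.

## Experiment planning

`kd_sweep` forward-solves on an inclusive K_D grid (linear by default, the
natural axis for concentration-vs-K_D plots; log optional).
`resolvable_kd_max` formalises the qualitative "usable below ~200 µM"
guidance as a configurable criterion, not a published number: on a 200-point
log grid (default 1–500 µM) it finds the largest K_D whose endpoint interval
on the `lwhite` route satisfies `kd_upper/kd_lower ≤ max_interval_ratio`
(default 2.0). At ±2.5% error in the standard system this lands near
150 µM, consistent with the guidance. K_D values whose endpoints leave the
valid domain count as unresolvable — which makes the resolvable maximum
genuinely non-monotone physics at large half-widths: the low-K_D side hits
the stoichiometric floor while the high side blows up, and nothing may
qualify.

## Synthetic data

The generator emulates the measurement chain, not the chromatography: true
chamber concentrations come from the pc-split (control condition) or the
forward solve at a known K_D (target condition); the detector maps
concentration to peak area through `area = k·conc + d` (defaults
k = 153.2, d = 40.1 area units per µM) with multiplicative log-normal noise
of unit mean and a given CV, since chromatographic peak-area noise scales
with signal. One noise model serves HPLC and LC–MS; the mode changes only
units (µM vs nM) and the 20× dilution. Defaults are the standard HPLC
system (100/300 µL, t0 = 80 µM, l0 = 50 µM, pc = 1) with triplicate
calibration at 10–100 µM (50–1500 nM for LC–MS) and three replicate
devices. Not emulated: retention-time drift, carry-over, co-elution,
detector saturation, heteroscedastic baselines. Passing recovery tests
therefore validate the numerical pipeline end to end, not robustness to
chromatographic artefacts.

The recovery study in the test suite generates 200 independent experiments
at true K_D = 100 µM with 2% detector CV and three replicates, runs the full
pipeline (calibration fit → concentrations → per-device p_c and p_t →
pt-route estimate with propagated error), and checks that the median
estimate is within 10% of truth and the empirical spread within 1.5× the
first-order σ. These sizes keep the whole suite in single-digit seconds
while giving the medians ~1% sampling resolution.

## Numerical choices and limitations

* Units fixed to µM/µL internally; conversions only at I/O boundaries.
* Solver self-consistency tolerance 1e-9 relative, round-trip tolerance
  1e-8: closed forms in double precision are benignly conditioned at
  assay-scale inputs.
* `check_physical` reports invariant residuals at 1e-8 relative (scaled by
  term magnitude, with an absolute floor of 1 for near-zero terms).
* Known limitation: one global `pc` factor cannot represent
  concentration-dependent nonspecific binding; kinetics (time to
  equilibrium) are out of scope — the model assumes equilibrium was
  reached, and the QC band is the only guard.
* The reference simulation values at K_D = 500 µM are reproduced at printed
  rounding except the red-chamber concentration, where the reference's own
  printed white-chamber value forces 27.757 µM by mass conservation rather
  than the printed 27.760; the package reports the conserved value.
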