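# qmdial

Dissociation constants from quantitative equilibrium microdialysis.

Equilibrium dialysis in a rapid-equilibrium-dialysis (RED) insert is one of
the cheapest label-free ways to measure how tightly a small molecule binds a
protein — and to catch compounds whose aggregation or surface binding would
poison downstream assays. The target protein sits in a small "red" chamber
(typically 100 µL) separated from a larger buffer "white" chamber (300 µL)
by a membrane only the small molecule can cross. After equilibration, the
compound concentration in each chamber is read out by RP-HPLC or LC–MS peak
areas; an excess in the protein-containing chamber means binding, and the
size of the excess fixes the dissociation constant K_D.

`qmdial` is the analysis side of that workflow, for assay scientists and
screening groups: an exact 1:1 binding model with ligand depletion and a
control-partition correction, closed-form forward and inverse solutions,
first-order error propagation, calibration-curve and mass-balance QC with
compound-exclusion rules, and simulation tools for planning the experiment.

## The model

At equilibrium the ligand occupies three pools — free in the white chamber
(`lwhite`), free in the red chamber (`lfred`) and protein-bound (`tl`) —
constrained by

```
l0·(whitevol + redvol) = lwhite·whitevol + lred·redvol     (ligand conservation)
lfred = pc·lwhite                                          (control partition)
tl·KD = tf·lfred,   tf + tl = t0                           (1:1 binding law)
lred  = lfred + tl,   pt = lred / lwhite
```

where `l0` is the concentration the ligand would reach in both chambers
without protein, `t0` the total protein concentration in the red chamber,
and `pc` the red/white ratio measured in a protein-free control (1.0 for a
perfectly equilibrating compound; outside 0.90–1.10 the compound is flagged
for exclusion). Eliminating variables leaves a single quadratic in `tl`,
solved with a cancellation-free root formula; solving instead for `KD`
gives three exact estimators driven by whichever quantity was measured:
`lwhite`, `lred`, or the partition ratio `pt`. No excess-protein
approximation is made, so the model remains exact under ligand depletion.
Working units are µM and µL throughout.

## Worked example

A compound measured against its target protein (protein at 80 µM, ligand
equilibrating to 25 µM, standard 100/300 µL chambers) gave a control
partition ratio of 1.02 and a target partition ratio of 1.21:

```
$ qmdial kd --from pt --value 1.21 --l0 25 --t0 80 --pc 1.02
{
  "kd_uM": 405.2456557069635,
  "method": "from_pt",
  "std_error_uM": 0.0,
  "n_replicates": 1,
  "reliability_flag": "ok"
}
```

K_D ≈ 405 µM: a weak but genuine binder. Repeat `--value` for replicate
measurements to get a propagated standard error, and add `--pc-value`
replicates to fold the control-ratio uncertainty in as well.

Planning before the experiment answers "what affinities can this setup
resolve at my measurement error?" — here a ±2.5% (2σ) concentration error
in the standard HPLC system:

```
$ qmdial plan --half-width 0.025
{
  "resolvable": true,
  "kd_max": 147.91973977910888,
  "interval_at_max": [107.56923276055636, 214.69149067438352],
  "relative_half_width": 0.025,
  "max_interval_ratio": 2.0
}
```

The largest K_D whose 2σ interval stays within a two-fold upper/lower ratio
is ≈ 148 µM; beyond that, neighbouring affinities blur together. The other
subcommands are `simulate` (concentration/pt curves over a K_D range), `qc`
(calibration fit, p_c band, mass recovery and the exclusion verdict from
CSV tables) and `synth` (synthetic experiments with known truth). Every
command is a thin wrapper over the library API (`solve_equilibrium`,
`kd_from_pt`/`kd_from_lwhite`/`kd_from_lred`, `kd_interval_endpoints`,
`evaluate_qc`, `kd_sweep`, ...).

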