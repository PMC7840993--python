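# Methods

## The assay and its read-out

A fluorescence thermal-shift (DSF / thermofluor) experiment heats a
protein probe in the presence of a dye that fluoresces on binding
exposed hydrophobic residues.  As the protein unfolds, fluorescence
rises to a maximum and then decays (dye release on aggregation).  The
melting temperature Tm is taken as the maximum of the positive
derivative d(RFU)/dT — the standard instrument read-out — not as the
midpoint of a Boltzmann fit to the raw trace.  A Boltzmann-fit
estimator is deliberately out of scope: on quenched, sloped-baseline
data the derivative peak is the more robust definition, and it is the
definition the assay's published values use.

### Tm estimation

1. Smooth the trace.  Default: Savitzky–Golay, 7-point window, cubic
   polynomial (`SmoothingSpec`).  On the 0.2 °C instrument grid this
   damps shot noise without displacing a 3–6 °C-wide transition peak;
   a moving average and "no smoothing" are available.
2. Differentiate with central differences (one-sided at the ends).
3. Take the derivative maximum inside the search range.  The default
   range excludes two grid points at each boundary and everything above
   a 90 °C quench cutoff, where post-aggregation decay dominates.
4. Refine to sub-grid precision with the parabolic vertex through the
   peak and its two neighbours (clamped to ±half a step; degenerate,
   collinear triples fall back to the grid maximum).

On noiseless two-state curves with flat baselines this recovers the
generating Tm to within one 0.2 °C grid step across 30–70 °C.  The
estimator is exactly invariant to affine rescaling of the fluorescence
(gain and offset).

### Curve QC

Flags, all configurable through `QCThresholds`:

* `high_background` — initial RFU above 0.5 × the curve maximum: the
  dye already binds the native state (disorder-prone construct).
* `low_signal` — dynamic range below `min_dynamic_range` (default
  10 RFU; labs should set this from their instrument's full-signal
  scale, as the detection-limit driver does with 100 RFU).
* `no_transition` — derivative-peak prominence at or below 0.1 × the
  peak height.  This criterion is scale-free: ramps and flat curves
  have a near-constant derivative whose prominence is ~0, while any
  genuine transition stands clear of its surroundings.  (A criterion
  relative to the curve's RFU range was rejected: the derivative peak
  scales as 1/Tm², so a fixed mixed-unit threshold misclassifies
  legitimate high-Tm transitions.)
* `edge_peak` — the maximum sits on a search-range boundary.

Workflows exclude flagged wells with a logged reason rather than
failing the run; every excluded well appears exactly once in the
report.

## Equilibrium binding (ΔTmax, K_D)

ΔTm versus total duplex concentration [D] is fitted with the
ligand-depletion (quadratic) isotherm

    ΔTm([D]) = ((ΔTmax + [D] + K_D) − sqrt((ΔTmax + [D] + K_D)² − 4·ΔTmax·[D])) / 2.

Algebraically the radicand equals ([D] + K_D − ΔTmax)² + 4·K_D·ΔTmax,
so the model is defined for all non-negative inputs, is non-decreasing
in [D], non-increasing in K_D, zero at [D] = 0, and saturates at ΔTmax.

**Unit convention.**  The equation adds a temperature (ΔTmax, °C) to
concentrations, so the fitted K_D depends on the concentration unit.
This package fixes micromolar: with [D] and K_D in µM the published
NF-κB parameters (ΔTmax = 1.678 °C, K_D = 2.228 µM for the p65 probe;
2.462 °C, 0.794 µM for p50) reproduce the observed ~1–1.5 °C and
2–3 °C shifts at 10 µM dsDNA, whereas on a molar scale the same
numbers would predict ~10⁻⁵ °C.  Every result records the unit, and
K_D reports carry the caveat verbatim.

**Site multiplicity.**  `site_multiplicity` rescales [D] for duplexes
with more than one equivalent site (default 1 = duplex concentration).
Note the model family is *not* closed under concentration scaling
(it is degree-1 homogeneous only in (ΔTmax, K_D, D) jointly), so
fitting the same data under a different multiplicity changes both
parameters and leaves residual misfit; only the generating convention
recovers the truth exactly.  Both conventions reproduce the published
shift ranges, so neither is forced.

**Fitting.**  Unweighted least squares (`scipy.optimize.curve_fit`),
both parameters bounded positive; start values ΔTmax = max ΔTm, K_D =
concentration nearest the half-maximal shift.  All-zero series raise a
degenerate-fit error; non-convergence returns a flagged result rather
than raising.  The optimizer is checked against a brute-force 2-D grid
search in the tests.

**Uncertainty.**  Linearized standard errors are unreliable for 7-point
nonlinear fits, so intervals are bootstrapped (seeded, deterministic):

* `bootstrap_ci` (plain titration series): residual resampling with
  residuals rescaled by sqrt(n/(n−p)) (fitted residuals are
  variance-shrunk by the p = 2 parameters) and BCa intervals, with the
  acceleration constant from jackknifing the titration points.  Plain
  percentile intervals measured ~84–88% coverage at nominal 95% in
  simulation; the df-adjusted BCa construction restores ~90%.
* `bootstrap_group_ci` (plate workflows): every ΔTm point on a plate
  shares the same reference-well mean, so replicate noise induces a
  correlated error across the titration that residual resampling
  cannot see (measured ~70% coverage).  Instead, each bootstrap
  replicate draws one reference-mean perturbation plus independent
  per-concentration perturbations from the pooled within-group Tm SD
  around the fitted curve and refits (measured ~93% coverage under the
  study conditions).

## Inhibitor analysis

Two deliberately separate read-outs:

* **Destabilization** — mean Tm(probe + compound) − mean Tm(probe):
  direct binding or covalent modification loosening the fold.
* **Suppression** — 100·(1 − ΔTm(DNA, dose)/ΔTm(DNA, 0)): interference
  with DNA binding.  The DNA shift at each dose is measured against
  probe + inhibitor wells *at the same dose*, so direct destabilization
  does not masquerade as binding inhibition; the reference shift is the
  contemporaneous no-inhibitor ΔTm (plate-to-plate Tm drift cancels).
  Values above 100% are clamped; negative values (enhancement) are
  kept raw.

**IC50.**  Four-parameter logistic on the linear dose axis,
response = bottom + (top − bottom)/(1 + (IC50/dose)^hill), IC50 an
explicit parameter.  For the normalized suppression response both
plateaus are defined by construction (0% at zero dose, 100% at
complete suppression), so the suppression workflow pins them
(`fix_bottom=0, fix_top=100`) and fits (IC50, hill); raw Tm-shift
responses are fitted with all four parameters free.  Under the
benchmark noise conditions (2% response noise, 8 log-spaced doses) the
constrained fit recovers a 16.4 µM truth within 15% in ~100% of seeds,
versus ~76% for the free fit — the anchored estimator is the right one
when the anchors are known.

**Statistics.**  Pooled-variance two-tailed Student t test (Welch
behind a flag), stars at p < 0.05 / 0.01 / 0.001.  Two zero-variance
groups with equal means return t = 0, p = 1 by convention.

## Probe-design screen

Kyte–Doolittle per-residue hydropathy; GRAVY is the window-independent
mean over the full sequence; profiles are unweighted sliding-window
means (default window 9, no edge padding, positions at 1-based window
centers).  `low_hydropathy_segments` reports maximal runs of
consecutive window scores below a threshold (default −1.5, minimum run
10 windows) — candidate disordered regions that would produce high
background in the dye assay.  Trained disorder predictors are not
reimplemented; the screen only flags candidates.

The bundled 551-aa p65/RelA FASTA is a synthetic stand-in reconstructed
offline for the canonical human sequence (its header lists the residue
landmarks verified against the literature); isolated positions may
deviate from the database entry, and its GRAVY evaluates to −0.465.

## The simulator

`SimSpec` draws a two-state van't Hoff melt curve:

    f(T) = 1/(1 + exp(ΔG/(R·T_K))),  ΔG = ΔH_vH·(1 − T_K/Tm_K)
    RFU(T) = [native(T)·(1−f) + (unfolded(T) + amplitude)·f]
             · exp(−quench_rate·max(0, T − quench_onset)) + ε

with temperatures in Kelvin internally (interfaces are °C throughout)
and f(Tm) = 1/2 exactly.  Defaults: 25–95 °C grid at 0.2 °C; Tm
42.5 °C; ΔH_vH 400 kJ/mol (transition ~4 °C wide at half height —
sharper enthalpy narrows the derivative peak); amplitude 800 RFU over
sloped native/unfolded baselines; exponential quench from Tm + 8 °C at
0.02 /°C; Gaussian curve noise 1 RFU (~0.12% of amplitude), which with
the default smoothing reproduces the ~0.1 °C replicate Tm scatter
typical of the assay's reported SD bars.

`PlateSimSpec` assembles whole plates.  Binding-induced shifts are
injected through the same quadratic ligand-depletion model the fitter
uses — the analysis is empirical in ΔTm, so simulator and fitter
sharing the forward model makes round-trip parameter recovery a clean
correctness surface (it does *not* test the isotherm against an
independent thermodynamic linkage model).  Replicate variability is
modelled at the Tm level (`tm_noise_sd`, default 0.1 °C); curves inside
plate simulations are otherwise clean so the two noise sources stay
independently controllable.  Inhibitor plates carry probe-alone,
probe+DNA, probe+inhibitor and probe+DNA+inhibitor wells per dose, with
destabilization from a dose→shift map and suppression from a 4PL
truth.  All randomness flows from one integer seed; per-well streams
derive deterministically from (seed, CRC32(well id)).

**What the simulator does not emulate:** dye-binding kinetics,
unfolding irreversibility, aggregation microphysics, multi-domain or
multi-transition melts, and correlated (drift-like) plate noise.
Passing recovery tests therefore demonstrates the pipeline's
correctness under the stated noise model, not robustness to every
instrument artifact.

## Problem sizes and defaults used in the shipped analyses

The recovery benchmarks use the study design: 7 duplex concentrations
(0.5–10 µM), triplicate wells, 0.1 °C Tm noise, 100 seeds for the
acceptance checks (50 in the optional benchmark driver); bootstrap
n = 1000 by default, 300 inside the seeded benchmark loops, where
percentile ends are already stable.  IC50 benchmarks use 8 log-spaced
doses over 1–100 µM with 2% response noise.

## Known limitations

* K_D from Tm shifts is an *apparent*, unit-convention-dependent
  constant measured at elevated temperature; no extrapolation to a
  reference temperature is attempted.
* The single-site quadratic form is used even where two κB sites exist;
  anti-cooperative multi-site binding is out of scope.
* The 4PL suppression fit assumes complete suppression is attainable;
  partial inhibitors need `fix_top=None`.
* Vendor binary exports are not read; curves travel as the documented
  CSV dialects.
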