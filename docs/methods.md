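# Methods

## Model overview

The package computes virtual fractional flow reserve (vFFR) for a single
coronary lesion with no side branches, under rigid-wall assumptions, from a
two-compartment reduced-order model:

1. **Lesion compartment.** The diseased segment is represented by the odd
   quadratic law `ΔP(Q) = z1·Q + z2·Q·|Q|` (mmHg, ml/s). `z1` aggregates
   distributed viscous (Poiseuille) losses, `z2` convective/expansion losses.
   The coefficients are fitted exactly from two steady (flow, drop)
   evaluations — operationally at 1 and 3 ml/s, a physiological pairing;
   more than two evaluations are handled by least squares on the same
   `[Q, Q²]` design. Negative fitted coefficients (possible only with noisy
   external inputs) clamp to zero with a warning flag. The law is odd in `Q`
   so retrograde instants during systolic myocardial compression dissipate
   with the correct sign.

2. **Microvascular (CMV) compartment.** A lumped afterload: optional series
   characteristic impedance `Zc`, then a compliance `C` referenced to the
   intramyocardial pressure source `Pim(t)`, in parallel with the total
   microvascular resistance `R` draining to venous pressure `Pv`. This is
   the minimal topology consistent with the nine quantities the
   pseudotransient computation depends on (proximal trace, `z1`, `z2`, `R`,
   `C`, and the four `Pim` parameters).

The **pseudotransient** solver advances the scalar compartment state
`Pc` with an explicit scheme (RK4 by default, Heun available): at each
instant the algebraic constraint `Pa(t) − Pc = z1·Q + z2·Q|Q| + Zc·Q` is
solved for `Q` in the cancellation-stable form
`Q = sign(ΔP)·2|ΔP| / (b + sqrt(b² + 4·z2·|ΔP|))`, `b = z1 + Zc`, and the
ODE `dPc/dt = dPim/dt + (Q − (Pc − Pv)/R)/C` is integrated. Cycles repeat
until the cycle-mean distal pressure changes by ≤ 1e-4 mmHg (configurable);
vFFR is the ratio of final-cycle trapezoidal means. Because the capacitor
charge is continuous while `Pim` resets at each cycle start, the reset jump
of `Pim` is applied to `Pc` at cycle boundaries; within a cycle the kinks of
`Pim` use right-hand derivatives.

The **steady** solver collapses the afterload to `R_total` and solves
`Pa − Pv = (z1 + R_total)·Q + z2·Q²` in closed form (same stable root), so
`vFFR = (Pv + R_total·Q)/Pa` is a function of four parameters only.

### Key parameters

| parameter | units | default | notes |
|---|---|---|---|
| `z1`, `z2` | mmHg·s/ml, mmHg·s²/ml² | fitted | from steady pairs at (1, 3) ml/s |
| `R` | mmHg·s/ml | case-specific | hyperemic CMV resistance, ~8–60 by territory |
| `C` | ml/mmHg | 0.002–0.008 | lumped distal compliance |
| `Zc` | mmHg·s/ml | 0 (0.5–2 in cohorts) | series characteristic impedance |
| `Pv` | mmHg | 0 | standard FFR neglects venous pressure |
| `Pim` amplitude | mmHg | 10–30 | effective compressive pressure at the compliant bed |
| `Pim` timing | s | rise 0.08–0.14, plateau 0.10–0.22, decay τ 0.03–0.08 | reset at the aortic upstroke |
| solver `dt` | s | 1e-3 (reference 1e-4) | snapped to an integer divisor of the period |

The compartment time constant `C·R_eff` (~0.01–0.05 s) is far from stiff at
these steps; the accuracy guarantee is the timestep-refinement property
(dt = 1e-3 vs 1e-4 changes vFFR by < 1e-3 across pulsatile cases).

## Waveform models

Aortic pressure is synthesized from four parameters (heart rate, systolic
and diastolic pressure, systolic fraction): a half-sine ejection phase
peaking at `p_sys` inside systole, joined continuously at the dicrotic
junction (0.707 of pulse pressure) to a normalized exponential decay that
reaches exactly `p_dia` at end diastole, making consecutive cycles
bit-identical. This is a stand-in for measured catheter pressure: it covers
the physiological envelope (pressures, rate, pulse shape) but has no
dicrotic notch oscillation, no beat-to-beat variability and no measurement
artifacts.

Intramyocardial pressure is a four-parameter piecewise pulse: linear rise
over `t_gen`, plateau, exponential decay with constant `tau_decay`, reset at
each cycle start. The published description of the generator names exactly
these four quantities (generation, plateau, decay, amplitude) without a
functional form; this form is the package's declared concrete choice. The
amplitude range (10–30 mmHg) is an *effective* lumped value: the compressive
pressure acting at the single compliant node of a one-compartment bed, lower
than peak left-ventricular pressure because the compliance aggregates
sub-epicardial to sub-endocardial layers; it produces the realistic systolic
dip of ~1 ml/s in coronary inflow without unphysiological sustained flow
reversal.

## Vessel surrogate

The paired steady evaluations come from an analytic stenosis model:
`z1* = (8μ/π)·∫ ds/r(s)⁴` (trapezoidal over the sampled profile; blood
viscosity 0.0035 Pa·s) plus a Young–Tsai-type expansion loss
`z2* = (ρ·K_t/2)·(1/A_min − 1/A_prox)²` with `K_t = 1.52` and density
1056 kg/m³. With zero cubic perturbation the surrogate drop is *exactly*
`z1*Q + z2*Q²`, so two-point characterization recovers the analytic
coefficients to rounding — the property the acceptance suite checks. An
optional `ε·Q³` perturbation emulates a solver that deviates from the
quadratic law, making the flow-pair-selection sweep non-degenerate. Note
that with a pure cubic deviation the fit residual at held-out flows is
`ε·Q(Q−Qa)(Q−Qb)`, which favors well-spread interior pairs ((2, 5) type)
over maximal-span ones; the sweep reports the full error table rather than
privileging a particular pair, and the clinical (1, 3) pairing stays within
2× of the widest pair's error at moderate perturbation.

## Tuning

`tune_cmv` minimizes the normalized RMS norm — the RMS of
`(Pd_computed − Pd_measured)/mean(Pd_measured)` over the final cycle — the
same statistic used for goodness-of-fit reporting. The search is
Nelder–Mead within bounds, log-scaled for `R`, `C`, `Zc` and linear for the
`Pim` parameters, seeded multistarts (default 5); a single free parameter
uses bounded scalar minimization. When pulse pressure is near zero the
`Pim` timing parameters are frozen (unidentifiable without pulsatility).
`initial_resistance_estimate` seeds the search by inverting the mean
translesional drop through the lesion law and dividing the mean distal
pressure by that flow, capped when the drop is unidentifiable. Recovery is
intrinsically easier for larger translesional gradients; the tests span
reference FFR ~0.3–0.95.

## Sensitivity analysis

Sobol indices of steady vFFR over uniform ranges of `R_cmv` (5–40),
`z1` (0–5), `z2` (0–2) and mean `Pa` (70–110): Saltelli A/B/AB design,
Saltelli-2010 estimator for main indices, Jansen for totals, percentile
bootstrap CIs, negative estimates reported unclamped as a Monte-Carlo
diagnostic. Sampling uses a seeded scrambled Sobol sequence by default —
bit-reproducible for a fixed seed and accurate to ~1e-3–1e-2 at N = 4096,
where plain pseudo-random sampling still errs by several hundredths; plain
sampling remains available. The default ranges are artifact defaults, not
values inferred from any patient cohort, so the *qualitative* findings are
what the tests pin down: `R_cmv` ranks first and mean proximal pressure has
total effect < 0.05, cross-checked against a 10⁶-evaluation double-loop
Monte-Carlo oracle.

## Synthetic study population

`generate_cohort` samples 73 virtual cases by default (seeded): artery types
with weights 34/21/3/7/8 (LAD/RCA/DX/LCX/LMS) and territory-specific radius
and hyperemic-resistance ranges (small branches higher `R`, left main
lower); 41/73 of cases hyperemic, the rest at rest with resistance scaled by
2.2–3.2; cosine-tapered stenoses with fractional radius reduction
U(0.35, 0.80), calibrated so the reference pressure ratio spans ~0.30–1.0
with ≥ 25 % of cases in the clinically important 0.7–0.9 band (cases below
0.30 — the excluded chronic-total-occlusion regime — are resampled). The
per-case reference FFR is a fine-timestep (dt = 1e-4 s) pseudotransient
solve, playing the role of a fully transient reference computation.
Optional measurement noise is multiplicative Gaussian on the distal trace.

What passing the cohort experiments shows — and does not show: with
case-specific resistance tuned from the case's own distal trace, both
methods agree with the reference to small fractions of a percent and
classify all cases correctly at the 0.80 threshold, and agreement degrades
monotonically as the boundary condition is averaged over groups or the
whole cohort. Because the reference shares the lesion law and afterload
topology with the methods under test, these numbers bound *method* error
(characterization, time integration, mean-value reduction, tuning), not the
model-form error against 3D hemodynamics or real patients.

## Numerical choices and degenerate inputs

* Flow inversion uses the stable quadratic root everywhere (exact in the
  linear limit); `dP = 0` maps to `Q = 0`.
* A lesion with `z1 = z2 = Zc = 0` pins `Pd = Pa`; the solver then returns
  the afterload identity `Q = C·d(Pa − Pim)/dt + (Pa − Pv)/R` instead of
  integrating the degenerate algebraic-differential system.
* `steady_vffr` initializes nothing and cannot fail to converge; the
  pseudotransient solver reports `converged=False` after `max_cycles` rather
  than raising, and raises only on non-finite state.
* `Pc(0)` is the linearized estimate `mean(Pa)·R/(R + z1)`; the convergence
  criterion makes the answer initialization-independent.
* ICC and Sobol variance checks treat variances below a relative 1e-12/1e-20
  floor as degenerate and raise, rather than returning rounding noise.
* Diagnostic "positive" is reference ≤ 0.80 (ties count as significant,
  matching the clinical convention for the ischemic threshold).
* The RMS norm divides by √N after normalizing by the mean (length-invariant
  choice between the "2-norm" and "RMS" readings of the statistic).

## Known limitations

Single lesion, no side-branch flow division; rigid walls, no wave
propagation; the aortic and intramyocardial waveforms are smooth parametric
stand-ins; the vessel surrogate has no inertial/unsteady losses, curvature
or non-Newtonian effects; the cohort's parameter ranges are physiological
choices, not fitted to patient data; and hyperemia-free (non-invasive)
boundary-condition estimation is out of scope — tuning requires a measured
distal trace.
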