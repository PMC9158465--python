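# Methods

## Model structure and assumptions

The model couples a biophysical description of a walled, roughly spherical
cell to a biochemical description of cytosolic calcium handling. Its state
is `[V_os, Ca_cyt, CaMb, CaNb]`: osmotic (water) volume in litres,
cytosolic calcium in nM, Ca²⁺-bound calmodulin in nM, and calmodulin-bound
calcineurin in nM. Canonical units are s, L, MPa, µmol·L⁻¹ for osmolytes
and nM for signaling species; conversions happen only at the parameter
boundary, never inside rate expressions.

Key assumptions:

* **Water, not solutes, changes the volume.** Total volume is
  `V = V_os + V_b` with the solid volume `V_b` constant. The reflection
  coefficient is fixed at σ = 1 (glycerol, the only permeable solute
  considered, reflects almost completely at this temperature).
* **Glycerol is frozen.** Over the ~160-s horizon both intra- and
  extracellular glycerol are held at their initial values, so the
  permeable-solute term contributes no net osmotic pressure. Long-term
  osmoadaptation (glycerol efflux through Fps1) is out of scope.
* **Elastic turgor law with increasing sign.** Turgor is
  `P = ε·ln(V/V₀)` for `V ≥ V₀` and 0 below, with
  `V₀ = V(0)·e^{−P₀/ε}` chosen so that `P(V(0)) = P₀` exactly. Turgor
  *increases* with swelling; this is the sign required for the gating
  mechanism (swelling → higher tension → MS channels open) and is the
  package's deliberate convention.
* **Infinite external reservoir.** The extracellular volume (1000× the
  cell) plays no dynamical role; external osmolarity and calcium follow
  the dilution stimulus only:
  `c(t) = (c⁰ − c⁰/d)·e^{(t_off−t)/t_m} + c⁰/d` after onset.
* **Transport sum, no buffering term.** The calcium balance is a pure sum
  of transporter fluxes; the 3:1 stoichiometric consumption of calcium by
  calmodulin binding is *not* subtracted by default (an optional
  `buffered` flag adds it for exploration). The disabled legacy components
  (`v_IN`, `kI_Cch1`) stay in code behind default-zero parameters so the
  pre-simplification model can be reconstructed.
* **Mass-action feedback.** Calmodulin binds three Ca²⁺ in one cooperative
  mass-action step (`km₋/km₊ = 9000` in the printed nM-based rate forms);
  calcineurin binding/unbinding is bimolecular with `kn₋ = 1000 s⁻¹`,
  which makes bound calcineurin a millisecond-relaxing, quasi-steady
  species — and the stiff direction of the ODE system.

## The resting state is a construction, not an equilibrium

With the default kinetics, calmodulin binding at resting calcium runs at
~5·10⁻⁴ nM/s: its true stationary point (≈2594 nM bound at 215 nM Ca)
would take months to reach and would shut the MS leak entirely. The
package therefore defines rest quasi-statically: bound calmodulin
`CaMb(0)` is a scenario input, bound calcineurin sits at its quasi-steady
value, and resting calcium is the unique zero of the calcium balance at
pre-stimulus turgor (a bracketed Brent solve on [0, Ca_ex(0)]; the balance
is strictly decreasing in Ca).

`CaMb(0)` itself is calibrated per strain so the model baseline matches an
observed value — wild type 215 nM (giving `CaMb(0) ≈ 0.97 nM`), and, as
illustrative defaults where no measured number exists, 215 nM for the
`cch1Δ` and `flc2Δ` strains and 300 nM for `cnb1Δ` (qualitatively elevated
resting calcium). These defaults are config inputs, not claims about
measured baselines. The calibration is monotone (more bound calmodulin →
stronger MS inhibition → lower baseline) and raises a non-identifiability
error when the MS feedback is inert (`k_MS` or `kI_MS` zero); in that case
the self-consistent stationary pair (`stationary_resting_state`) is the
appropriate construction, and it is what the MS-knockout analyses use.

One visible consequence of the quasi-static construction: with no stimulus
the baseline is not perfectly flat. The slow calmodulin creep
(~4.7·10⁻⁴ nM/s), amplified by the large MS inhibition constant
`kI_MS = 26395 nM⁻¹`, drifts the baseline downward by roughly 2% over
160 s. The pre-stimulus window used by `trace_metrics` (mean over
[0, t_off)) is flat to <0.5%.

## Numerical choices

* **Integrator.** LSODA via `scipy.integrate.solve_ivp`; the integration
  is split at `t_off`, where the forcing is continuous but not smooth.
* **Tolerances.** Default rtol 10⁻⁸; absolute tolerances per state
  `(10⁻²² L, 10⁻⁶, 10⁻⁹, 10⁻⁹ nM)`. The volume atol sits far below the
  ~3·10⁻¹⁴ L osmotic volume so the relative tolerance governs that state;
  the bound-calmodulin atol resolves the sub-nanomolar changes that the
  MS feedback amplifies. Tightening everything 10× changes baseline and
  peak by <0.1% (tested).
* **Output grid.** 0.25 s by default (0.1 s in the mixing-time scan, where
  time-to-peak resolution matters).
* **Root-finds.** Brent's method with bracket checks; degenerate inputs
  (all influx parameters zero) short-circuit to 0. Ties in the
  mixing-time argmax break toward the smaller mixing time.
* **Overflow guards.** The Boltzmann gate saturates to 0/1 when its
  argument exceeds ±500; bound fractions are clamped into [0, total] for
  RHS evaluation because stiff solvers probe slightly out-of-bound states.
* **Fitting profile.** The optimizer's inner simulations use rtol 10⁻⁶
  (atol `(10⁻²⁰, 10⁻⁴, 10⁻⁷, 10⁻⁷)`), an accuracy well below measurement
  noise at ~25× the speed.

## Parameter estimation

Global-best PSO with inertia 0.729 and cognitive = social = 1.494
(standard constriction-style values), velocity clamped to half the search
range, absorbing bounds, fully seeded. Parameters whose search range spans
≥3 decades are searched in log₁₀ space. The tying rule mirrors the
physiology: reaction constants are shared across experiments, while
bound-protein initial values (`camb0`) and expression proxies (`v_Pmc1`,
`k_MS`) may vary per experiment. The loss is an equally weighted sum of
squared calcium residuals (optional steady-state penalty). Runs stop at
the iteration cap (default 300), after 50 stagnant iterations, or when the
loss falls below an explicit floor; on noise-free recovery problems a
floor of 10⁻³ nM² (RMS residual 0.0035 nM) ends runs long before the cap.
Freeing `camb0` for an experiment whose `k_MS` is fixed at zero is
rejected as non-identifiable rather than silently fitted.

The package does not attempt to re-derive the published fitted constants —
the underlying experimental traces are not machine-readable — so the
estimation stage is validated by parameter recovery on synthetic data with
known ground truth.

## Synthetic data: what it does and does not emulate

The generator simulates clean trajectories per condition (strain ×
protocol), samples them on a uniform grid (default 1 s over 160 s), and
adds noise `y = clean·(1 + m·ε₁) + a·ε₂` with i.i.d. standard-normal ε,
clamped at zero (defaults: additive sd 10 nM, no multiplicative term).
Per-trace seeds derive deterministically from the master seed, so datasets
regenerate byte-identically and every manifest records the generating
parameters.

It emulates the gross features of reporter-based calcium recordings —
baseline magnitude, transient timing, replicate scatter, strain and
dilution dependence. It does not emulate photon-counting statistics,
calibration nonlinearity of luminescent reporters, cell-to-cell
heterogeneity, or drift in experimental clocks. Passing recovery tests
therefore show that the estimation machinery is correct and well
conditioned under the model's own dynamics, not that the model's fitted
constants are unique against real data.

## Problem sizes used in tests and the acceptance script

The mixing-time scan uses the 1–40 s grid at 1-s steps (40 stiff
integrations, ~1 s total). Recovery benchmarks use a single noise-free
wild-type trace sampled every 2 s with two free parameters (`k_MS`,
`v_Pmc1`), 40 particles, a 300-iteration cap and five swarm seeds; all
five recover both parameters to well under 1%. These sizes are the
package's defaults and are comfortably deterministic across platforms.

## Known limitations

* The printed units of `km₊` (nM⁻⁴·s⁻¹) and `kn₊` (nM⁻²·s⁻¹) are each one
  concentration power away from the termolecular/bimolecular forms of the
  rate laws; the formulas are implemented exactly as stated with
  concentrations in nM, without reinterpretation.
* The quasi-static rest gives a ~2% baseline drift over windows much
  longer than the pre-stimulus period (see above).
* The peak-versus-mixing-time curve is extremely flat near its maximum
  (0.2% over 15–18 s), so the argmax is sensitive at the ±2 s level to
  the resting bound-calmodulin value and solver detail.
* Vacuolar/ER compartment pools, the Yvc1 channel, transcriptional
  (Crz1) feedback and phosphoinositide signaling are intentionally outside
  the model boundary.
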