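# Methods

## Model and assumptions

The cell is one well-mixed compartment in an infinite external medium.
Only the monovalent ions Na⁺, K⁺, Cl⁻ are transported; intracellular
impermeant osmolytes are lumped into a single pool A (mmol) with a fixed
mean valence z, and both A and z are held constant during a run (real
cells can regulate organic osmolytes through signalling; this model
deliberately excludes all signalling so that "physical" responses of the
electrochemical system can be separated from regulatory ones). Divalent
ions, pH/bicarbonate species and membrane capacitance are not modelled:
the membrane is treated as electroneutral and quasi-stationary, with the
potential defined implicitly by the zero-current condition rather than
by charge accumulation.

Five pathways are distinguished by driving force, not molecular
identity: Goldman constant-field channels for each ion; the Na/K pump,
whose Na⁺ efflux is β[Na]ᵢ with fixed stoichiometry γ (default 1.5,
i.e. 3Na:2K); and the electroneutral cotransporters NC (1Na:1Cl), KC
(1K:1Cl) and NKCC (1Na:1K:2Cl), whose fluxes are proportional to the
difference of external and internal concentration products. One rate
coefficient per pathway is deliberate: finer concentration dependences
cannot be constrained by realistic experimental data and would only add
unidentifiable parameters.

Water equilibrates much faster than ions, so V is computed
algebraically from osmotic balance at every instant rather than
integrated; an external medium change therefore produces an
instantaneous volume jump at fixed contents (`apply_medium_jump`).

## Parameters

| symbol | meaning | units | reference-cell default |
|---|---|---|---|
| pna, pk, pcl | channel permeability coefficients | min⁻¹ | fitted (≈0.0017, 0.0115, 0.011 for the full set) |
| beta (β) | pump rate coefficient | min⁻¹ | 0.039 |
| gamma (γ) | pump Na:K stoichiometry | — | 1.5 |
| inc, ikc | NC, KC rate coefficients | ml·µmol⁻¹·min⁻¹ | 7e-5, 8e-5 (full set) |
| inkcc | NKCC rate coefficient | ml³·µmol⁻³·min⁻¹ | 8e-9 (full set) |
| kb | linear pump decay, β(t) = β(1−kb·t) clamped at 0 | min⁻¹ | 0 |
| z, A | impermeant osmolyte valence and amount | —, mmol | −1.75, 1 (normalisation) |

RT/F is fixed at 26.7 mV (37 °C); all potentials and electrochemical
potential differences use this constant, so printed Δμ values are
reproduced exactly rather than to the physical 26.73 mV.

The reference cell (U937-like) rests at [Na]ᵢ 38, [K]ᵢ 147, [Cl]ᵢ 45 mM
with V/A 12.5 ml/mmol in a 310 mOsm RPMI-like medium taken as
Na 140, K 5.8, Cl 116, impermeant non-electrolytes 48.2 mM. The medium
composition is fixed by subtracting 100 mM NaCl from the hypertonic
composition used in the flux-dynamics computations (240/5.8/216/48.2)
and is consistent with the resting Δμ values. Four cotransporter
complements (NC; NC+KC; NC+NKCC; NC+KC+NKCC) balance this same resting
state; their channel permeabilities are re-fitted in closed form at each
complement's resting potential so the rest state is an exact fixed point
(the published 2–3-significant-figure permeabilities are kept as
reference values and agree within 3%).

## Numerics

- **Potential solve.** The zero-current equation (channels plus pump;
  cotransporters carry no charge) is solved for u by Brent's method on
  u ∈ [−10, 5], widened once by ×2 if needed; failure raises an error
  naming the bracket and endpoint values. Inside the integrator a
  secant iteration warm-started from the previous step's u (residual
  tolerance 1e-13, Brent fallback) does the same job cheaply and also
  selects the root nearest the previous step if several existed.
- **Singularity.** u/(1−eᵘ) is evaluated by a 3-term Taylor expansion
  −(1 − u/2 + u²/12) for |u| < 1e-4; the u → 0 channel flux limit is the
  Fick form p([X]ₒ − [X]ᵢ).
- **Integration.** Explicit Euler on the three contents with
  dt = 0.01 min. The system is only mildly stiff at these rate
  coefficients; halving dt changes 240-min endpoints by ~2e-8
  relative, far below the 2% precision of the reproduced states.
  Electroneutrality is conserved to machine-level drift because the
  per-step charge increment is the (≈1e-13) potential-solve residual;
  osmotic balance is exact by construction.
- **Unidirectional split.** For every pathway the influx is the term
  proportional to external concentration(s) and the efflux the internal
  term, so influx ≥ 0 ≥ efflux always and net = influx + efflux.
- **Balance detection.** `find_balanced_state` stops when the largest
  relative content change per minute drops below 1e-8 (checked before
  each step, so a balanced input returns immediately) and otherwise
  flags non-convergence at t_max = 5000 min instead of raising.
- **Permeability fit.** Each steady-state balance is linear in its own
  permeability, giving a closed-form fit; negative solutions are flagged
  infeasible per ion, and a vanishing GHK factor with vanishing residual
  (Cl⁻ at Donnan equilibrium without cotransport) is flagged
  indeterminate rather than silently set.

## Scenario conventions

Hyperosmolar presets add 100 mM NaCl (510 mOsm) or 180 mM sucrose
(490 mOsm) to the normal medium explicitly; the osmolarity ratio kv is
only a derived/reported quantity, except in configs where kv without an
explicit medium is realised as non-electrolyte addition. Parameter
multipliers apply instantaneously at the jump and persist. Scenario
states are reported after a fixed 240-min run (800 min for the slow
pump-β rows) — the incubation time the reference tables and the paired
wet-lab experiments refer to — with an honest convergence flag: most
parameter sets are balanced well within that time, but slowly relaxing
ones (notably the NC-only cell in +NaCl, whose low pCl stretches
equilibration to ~2000 min) are deliberately reported mid-transition,
because that 4-h state is the physiologically observed quantity. The
RVI / weak RVI / AVD labels use thresholds 1.05 / 1.005 / 0.995 on the
ratio of balanced to immediate post-jump volume; the labels are
otherwise qualitative in the source material, and these cutoffs
reproduce every tabulated label.

## What the scenario engine does and does not show

The preset grid emulates computational experiments on a deterministic
model cell: identical resting state, idealised step changes of medium,
parameters constant (or stepped once) in time. Passing tests therefore
demonstrate the internal consistency of the electrochemical system —
e.g. that AVD-like shrinkage in sucrose and RVI-like swelling in NaCl
arise with *no* parameter changes — not that living cells behave
quantitatively this way: real cells add signalling-driven parameter
changes, organic-osmolyte redistribution, and cell-to-cell heterogeneity
(subpopulations in different response stages), none of which are
modelled.

## Known limitations

- Explicit Euler with a fixed step is wasteful for very slow runs; there
  is no adaptive or stiff solver, by design (run lengths are minutes to
  hours and the per-step cost is dominated by the potential solve).
- The potential solve assumes a single physiological root in the
  bracket; pathological parameter sets with multiple roots are handled
  only by the warm-start continuity rule along trajectories.
- A and z cannot change during a run, so phenomena driven by organic
  osmolyte accumulation or release are outside scope.
- The pump model is linear in [Na]ᵢ with no ATP, Km or voltage
  dependence; kb provides only a linear intrinsic decay.
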