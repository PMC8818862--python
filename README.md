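# pumpleak

A pump-leak electrochemical model of monovalent ion and water homeostasis
in animal cells, with a protocol engine for anisosmolar challenges.

Cell volume is not regulated by a dedicated "volume sensor" alone: it is
the equilibrium of a whole electrochemical system in which Na⁺, K⁺ and
Cl⁻ move through channels, the Na/K pump and electroneutral
cation-chloride cotransporters in parallel, while water follows
osmotically. Because every flux depends on the concentrations and the
membrane potential that all the other fluxes shape, the contribution of
any one pathway to responses such as regulatory volume increase (RVI) or
the apoptotic volume decrease (AVD) cannot be measured in isolation — it
has to be computed for the system as a whole. `pumpleak` is a library
and CLI for exactly that computation, aimed at cell physiologists
studying volume regulation, ion homeostasis and the functional
expression of channels and transporters (the built-in reference cell is
a proliferating human lymphoid U937-like cell).

## The model

State variables are the cell's ion contents Na_i, K_i, Cl_i per unit of
intracellular membrane-impermeant osmolyte A (mean valence z). Two
constraints hold at every instant:

- electroneutrality: [Na]ᵢ + [K]ᵢ − [Cl]ᵢ + z·A/V·1000 = 0
- osmotic balance: [Na]ᵢ + [K]ᵢ + [Cl]ᵢ + A/V·1000 = [Na]ₒ + [K]ₒ + [Cl]ₒ + [B]ₒ

so water volume V is slaved to the contents and the membrane potential
U = 26.7·u mV is re-solved from the zero-current condition at each step.
The contents evolve as

    dNaᵢ/dt = V{ p_Na·u([Na]ᵢeᵘ − [Na]ₒ)/g − β[Na]ᵢ + J_NC + J_NKCC }
    dKᵢ/dt  = V{ p_K·u([K]ᵢeᵘ − [K]ₒ)/g + β[Na]ᵢ/γ + J_KC + J_NKCC }
    dClᵢ/dt = V{ p_Cl·u([Cl]ᵢ − [Cl]ₒeᵘ)/g + J_NC + J_KC + 2·J_NKCC }

with g = 1 − eᵘ (Goldman constant-field channel fluxes), pump rate
coefficient β and Na:K stoichiometry γ = 3:2, and cotransport fluxes

    J_NC   = inc  ([Na]ₒ[Cl]ₒ − [Na]ᵢ[Cl]ᵢ)
    J_KC   = ikc  ([K]ₒ[Cl]ₒ − [K]ᵢ[Cl]ᵢ)
    J_NKCC = inkcc([Na]ₒ[K]ₒ[Cl]ₒ² − [Na]ᵢ[K]ᵢ[Cl]ᵢ²)

Each pathway is characterised by a single rate coefficient — a
thermodynamic description that is independent of molecular mechanism.
The library exposes the unidirectional (influx/efflux) decomposition of
every pathway, the electrochemical potential differences
Δμ_X = 26.7·ln([X]ᵢ/[X]ₒ) ± U and the cotransporter driving forces,
closed-form inverse problems (impermeant-osmolyte valence and channel
permeabilities from a resting measurement), and the OSOR diagnostic
(pump-mediated over passive K⁺ influx).

## Worked example

Drop the reference cell into a +180 mM sucrose medium (490 mOsm) with
all membrane parameters unchanged:

```python
from pumpleak import run_scenario

r = run_scenario("sucrose180")
print(f"post-jump V/A:   {r.post_jump_state.v:.2f} ml/mmol")
print(f"balanced V/A:    {r.v_over_a:.2f} ml/mmol  (V/V_initial = {r.v_ratio:.2f})")
print(f"balanced [K]i:   {r.balanced_state.k:5.1f} mM")
print(f"membrane potential: {r.U_hyper:.1f} mV")
print(f"volume response: {r.phenotype}")
```

prints

```
post-jump V/A:   7.91 ml/mmol
balanced V/A:    6.37 ml/mmol  (V/V_initial = 0.81)
balanced [K]i:   261.2 mM
membrane potential: -62.9 mV
volume response: AVD
```

The cell first shrinks osmotically from 12.5 to 7.91 ml water per mmol A,
then — with *no* change in any channel or transporter — keeps shrinking
to 0.81 of the post-jump volume while hyperpolarising from −45 to
−62.9 mV: an AVD-like secondary volume decrease that is a property of
the electrochemical system itself. The same cell in a +100 mM NaCl
medium (`run_scenario("nacl100")`) instead shows a weak RVI, and an
NC-only cell (`run_scenario("nacl100@NC")`) a strong one
(V/V_initial = 1.31). Scenario presets cover inc/ikc/inkcc/pCl/β
multipliers and the HICC (hypertonicity-induced cation channel) case;
`pumpleak scenario all` tabulates the whole grid from the shell, and
`pumpleak simulate`, `fluxes`, `steady-state` and `fit-params` operate
on flat YAML configs using the conventional symbol names (`na0`, `pk`,
`inkcc`, `kv`, ...).

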