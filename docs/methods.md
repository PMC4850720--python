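# Methods

## Network model and assumptions

The model is a lumped stoichiometric description of anaerobic sugar
fermentation in an *E. coli* lineage with ΔldhA ΔfrdAB (no lactate or
succinate — these products are omitted entirely rather than gated),
ΔhycA (formate-hydrogen lyase derepressed) and ΔhyaAB ΔhybBC (no H₂
reuptake; H₂ is terminal). Each glycolytic route is a *pathway mode*: a
fixed per-mol-substrate coefficient vector (pyruvate, NADH, NADPH,
glycolytic CO₂, net ATP) stored as exact rationals. Two closure
identities hold for every mode and are enforced by construction and by
property test:

- carbon: `substrate C = 3·pyr + co2_gly`
- electrons: `substrate γ = 10·pyr + 2·NADH + 2·NADPH`,

where γ is the degree of reduction, 4C + H − 2O.

Mode derivations. Single-pass oxidative PP: 3 G6P → 3 CO₂ + 6 NADPH +
2 F6P + GAP, with F6P continuing down lower glycolysis, giving per glucose
(5/3 pyr, 5/3 NADH, 2 NADPH, 1 CO₂). Cyclic PP: F6P is recycled to G6P,
requiring 3 oxidative turns per net glucose (1 pyr, 1 NADH, 6 NADPH,
3 CO₂) — the data suggest partial cyclic operation in vivo, so both
variants ship; the single-pass mode is the default estimation basis.
ED: G6P → 6PG (1 NADPH) → KDPG → pyr + GAP. Gluconate enters at 6PG,
either through Gnd into the PP scheme (5/3 pyr, 5/3 NADH, 1 NADPH, 1 CO₂)
or through Edd/Eda (2 pyr, 1 NADH). Glycerol → GAP yields an extra NADH
(1 pyr, 2 NADH).

Downstream of pyruvate: PFL (pyr → AcCoA + formate), FHL
(formate → H₂ + CO₂; assumed complete by default since hycA is deleted —
a formate-excretion option relaxes this), AdhE (AcCoA + 2 NAD(P)H →
ethanol), Pta-AckA (AcCoA → acetate, +1 ATP), pyruvate excretion, and two
optional reactions that exist only in ceiling scenarios: a
pyruvate-decarboxylase route (pyr → acetaldehyde + CO₂, then 1 NAD(P)H →
ethanol, the ethanologen configuration) and an NAD(P)H-driven H₂-evolving
reaction (the strict-anaerobe configuration). Every downstream reaction
conserves electrons exactly.

**Pooled redox currency.** NADH and NADPH are summed into one NAD(P)H pool
for all balances, because the cofactor specificity of the dominant ethanol
dehydrogenase under PP-heavy operation cannot be resolved from yield data
(transhydrogenases blur the distinction anyway); the separate tallies are
kept on the mode table for diagnostics.

**ATP.** Net substrate-level ATP is reported (EMP 2, single-pass PP 5/3,
ED 1 per glucose; +1 per acetate) but never constrained: maintenance
demand is unknown and yield data cannot identify it.

## Genotype gating and presets

Strain presets map the lineage's genotypes to admissible reaction sets:
pta-ackA deletion removes the acetate branch, edd-eda deletion removes the
ED-family modes, pfkA deletion does **not** remove EMP (the PfkB isozyme
compensates, as the adapted strains show). Overexpression flags (zwf, gnd)
are informational; they change estimated fluxes, not network structure.

The `strict_anaerobe` ceiling model restricts glycolysis to EMP and adds
the NAD(P)H → H₂ reaction. This is a deliberate modeling choice: the
4 mol/mol H₂ ceiling of clostridial fermentation is an EMP argument, and
admitting cyclic-PP routing alongside unlimited NAD(P)H-driven H₂ would
allow physiologically meaningless optima (up to 8 mol/mol, full oxidation
to CO₂ + acetate).

## Scenarios and LP maxima

`scenario_yields` maps a mode split to products in closed form. Routing
policies: `redox_closed` solves the ethanol/acetate ratio so NAD(P)H
production equals consumption (infeasible — flagged, not raised — when no
solution exists in [0, AcCoA], e.g. without the acetate branch);
`all_ethanol` sends all AcCoA to ethanol and reports the NAD(P)H surplus;
`fixed` audits caller-supplied rates. The co-production ceiling of the
fully PP-diverted strain is the `all_ethanol` scenario of the single-pass
PP mode: 5/3 mol each of H₂ and ethanol with a ⅓ mol surplus. The
unconstrained LP optimum of min(H₂, ethanol) under a closed redox balance
is slightly higher, 12/7 ≈ 1.714 (a mixed EMP/PP split); both numbers are
exposed and labeled because they answer different questions — a stated
scenario versus a network-wide optimum.

`max_yield` solves a small LP over the reaction-level flux space
(mode fluxes, downstream rates, slack, redox surplus) with the substrate,
pyruvate, formate, acetyl-CoA and NAD(P)H balances as equalities and
nonnegativity throughout, using scipy's HiGHS. Optional constraints:
no acetate, H₂ = ethanol, no redox surplus. Argmax ties are broken by
sequentially minimizing each variable in a fixed order (lexicographically
smallest flux vector), so reported optima are deterministic.

## Balance audits

Carbon recovery sums product carbon (+CO₂ per policy, +biomass carbon if
reported) over substrate carbon. CO₂ policies: `strict` (measured CO₂
required), `infer_co2` (CO₂ from carbon closure; recovery is then 1 by
construction and the inferred CO₂ itself is the informative number),
`ignore_co2`. The degree-of-reduction error is (γ_in − γ_out)/γ_in;
biomass electrons count 4.2 per carbon (generic CH₁.₈O₀.₅N₀.₂) when
biomass is reported. Energy recovery covers the fuel products H₂ and
ethanol; both LHV (default — the fuels convention) and HHV are exposed
with pinned constants (LHV, kJ/mol: H₂ 241.8, ethanol 1235, glucose 2539,
glycerol 1479; HHV: 285.8, 1367, 2803, 1655). Gluconate ships without a
combustion enthalpy, so energy recovery on gluconate raises. Published
round-number recoveries (~80 %, ~90 %) fall between our LHV and HHV
figures (86–97 % for the relevant yield vectors); the convention behind
them is unstated, so the package reports both rather than forcing either.
Yeast-extract carbon (≤ 0.16 g carbohydrate per g) is ignored by default;
an additive substrate-carbon correction hook exists.

## Flux-split estimation

Unknowns are the mode fractions on the simplex (Σf + slack = 1, f ≥ 0;
slack absorbs biomass and unmeasured byproducts, keeping the carbon
honest) plus the PFL flux. Two convex least-squares formulations:

- **balance** (default): residuals of the node balances with measured
  products pinned to their reactions — pyruvate
  (Σf·pyr − PFL − y_pyr), acetyl-CoA (PFL − y_EtOH − y_Ace), formate
  (PFL − y_H₂), NAD(P)H (Σf·nad − 2·y_EtOH), and optionally CO₂
  (Σf·co2 + y_H₂ against measured or carbon-closure-inferred CO₂). Makes
  no routing assumption; the default for real yield tables.
- **yield**: fit measured yields to the forward scenario under a routing
  policy. With weights ∝ 1/(CV·y)² (floored at y = 0.1 and normalized)
  this is the Gaussian maximum-likelihood fit for multiplicative noise
  and is markedly more efficient, because the small, precisely measured
  acetate yield then carries its full information weight.

The solver is SLSQP from three deterministic starts (the problem is a
convex QP; no randomness). `grid_oracle` is the brute-force reference —
exhaustive simplex search (step ≤ 0.1, ≤ 3 free dimensions) with the
inner PFL flux solved in closed form per grid point — and agrees with the
QP within twice the grid step on every shipped fixture.
Identifiability is diagnosed from the condition number of the weighted
design restricted to the split directions (inner variables projected
out); `profile_residual` exposes the SSR profile over one fixed mode
fraction for visual confirmation. The CO₂ equation is excluded by default
(`co2_policy="omit"`) because CO₂ yields are rarely printed; inferring
CO₂ from carbon closure attributes biomass carbon to CO₂ and therefore
biases the PP fraction upward — the policy is explicit so the choice is
reproducible. The headline `f_pp` statistic sums the PP-family fractions
(single-pass, cyclic, gluconate–Gnd). Default glucose basis is
{EMP, single-pass PP}; ED is opt-in (its transcription sits near baseline
in the studied lineage).

## Synthetic data

`simulate_yields` computes exact scenario yields and multiplies each
product by an independent Gaussian factor (mean 1, sd = `noise_cv`,
truncated at 0). Defaults are the study conditions: CV 0.10 (replicate
yield SDs below 10 % of the mean) and censored CO₂ (no printed CO₂
yields). Multiplicative Gaussian was chosen over lognormal; at CV ≤ 0.1
the two are indistinguishable. Per-product independence is assumed (no
covariance information exists). What the generator does *not* emulate:
batch effects, time-course dynamics, biomass measurement, correlated
analytical errors — so passing recovery tests demonstrate estimator
correctness under the stated noise model, not robustness to structured
real-world error.

The parameter-recovery experiment uses a true split of f_PP = 0.7,
f_EMP = 0.2, slack = 0.1: the PP fraction matches the strongest measured
estimate, and the 10 % slack matches carbon recoveries "above 90 %"
(biomass is real, and it keeps the truth interior to the simplex as real
data would be). It estimates each simulated sample with the efficient
(yield-space, relative-weight) estimator and reports bias, MAE and the
share of estimates within ±0.1. At CV 0.10 with n = 200 samples this
recovers f_PP with MAE ≈ 0.045 and |bias| ≈ 0.01 in a fraction of a
second.

## Numerical choices

- Mode coefficients are `fractions.Fraction`; closures are exact, float
  comparisons elsewhere use 1e−9 (audits) and 1e−6 (LP round-trip).
- Problem sizes: the grid oracle runs at step 0.01–0.02 on ≤ 3 split
  dimensions; recovery experiments use 200 samples; the LP has ≤ 14
  variables. Everything runs in seconds on one core.
- Degenerate inputs: all-zero yield vectors are rejected in estimation;
  single-mode models return the trivial split with diagnostics;
  inferred CO₂ < 0 raises an inconsistency error; negative fluxes and
  off-simplex fractions raise domain errors.

## Known limitations

- No kinetics, growth coupling, thermodynamic feasibility or
  genome-scale structure; this is yield-space stoichiometry only.
- The absolute in-vivo PP-flux figure depends on CO₂ measurements that
  yield tables usually omit; the package therefore reports the estimate
  under each CO₂ policy instead of asserting one number.
- Confidence statements are limited to residual profiles; no error
  propagation from replicate SDs, no ¹³C-MFA-style resolution of
  parallel routes beyond what product yields identify.
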