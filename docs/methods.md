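# Methods

## Scope

`tbinhale` reimplements, as an auditable open pipeline, the
model-informed chain that turns oral pharmacokinetics of three
anti-tuberculosis drugs — rifampicin (RIF), ethambutol dihydrochloride
(ETH) and moxifloxacin hydrochloride (MOX) — into inhaled lung doses and
fixed-dose-combination molar ratios, together with the aerosol and
dissolution metrics used to characterize candidate dry-powder
formulations. The commercial simulator originally used for this kind of
analysis is replaced by an explicit whole-body PBPK model whose every
assumption is stated below.

## Whole-body PBPK model

**Structure.** Venous and arterial blood pools; the lung in series
receiving the entire cardiac output (CO); 13 perfusion-limited tissues in
parallel (lung, adipose, muscle, liver, spleen, heart, brain, kidney,
skin, reproductive organs, red and yellow marrow, rest-of-body). Each
tissue obeys

    V_i dC_i/dt = Q_i (C_art − C_i·bp/Kp_i)

with plasma-referenced partition coefficients Kp_i and blood-to-plasma
ratio bp; the venous blood leaving tissue i carries `C_i·bp/Kp_i`.
Reported plasma concentration is the venous blood concentration divided
by bp. The model is linear throughout (no saturable binding or
elimination), so doubling the dose doubles every concentration; the test
suite asserts this, along with mass balance at every output time
(within 0.1 % of dose; in practice ~1e-15).

**Absorption.** Oral input passes through a 7-segment
compartmental-absorption-transit chain with total small-intestinal
transit time 3.32 h. A uniform absorption rate constant applies in every
segment, converted from effective permeability via the cylindrical-lumen
relation `ka = 2·P_eff/R` with R = 1.25 cm; drug leaving the last
segment is unabsorbed. Under pure transit competition the absorbed
fraction has the closed form `Fa = 1 − (1 + ka·T/n)^(−n)`, which the
simulation reproduces to 1e-4 relative. No dissolution limitation is
modelled: the permeability values are optimized-model values and the
absorption step is deliberately the simplest structure that uses them.
This is the model's largest structural simplification — a
software-specific absorption model with regional scale factors would
absorb faster for high-permeability compounds (visible as our RIF Cmax
sitting ~15 % below the observed mean, versus the gate's 20 %).

**First pass and elimination.** The absorbed flux enters the liver
inflow, so first-pass loss emerges from the liver model rather than
being imposed. The liver is well-stirred: with hepatic blood clearance
`CL_H = (CL_iv − CL_R)/bp`, the apparent intrinsic clearance
`CL_int = CL_H·Q_H/(Q_H − CL_H)` acts on the liver outflow blood
concentration, where Q_H is the total (arterial + portal) liver flow.
Renal elimination is referenced to the sampled venous plasma with plasma
clearance CL_R. This placement is a deliberate design choice: drawing
renal flux at the arterial side instead makes the venous (sampled) AUC
exceed `F·Dose/CL_iv` by a factor `1 + CL_R/(bp·CO)` — ~9.6 % for ETH,
whose clearance is mostly renal — whereas the venous reference keeps the
clinically defined identities exact for a linear system:
`AUC0-inf = Fa·Fh·Dose/CL_iv` and `AUC_tissue/AUC_plasma = Kp_i` for all
tissues without local input. The liver is the one exception by
construction: the oral first-pass flux raises hepatic exposure, and the
tests hold it to its exact flow balance
`AUC_liv,out = (Q_H·AUC_art + A_absorbed)/(Q_H + CL_int)` (≈1.5–2 %
above the naive Kp prediction for these compounds).

**Kp rescaling.** The per-tissue partition coefficients are inputs, but
their absolute scale is tied to the reported steady-state volume of
distribution by one common factor s solving

    V_plasma + Σ_i s·Kp_i·V_i = Vd_ss·BW.

The factor is recorded on the parameter set (0.911/0.836/0.848 for
RIF/ETH/MOX with the shipped physiology); an s ≤ 0 (Vd_ss below plasma
volume) is a parameter error.

**Numerics.** `scipy.integrate.solve_ivp` with LSODA, rtol 1e-8,
atol 1e-10 µg, output on a 0.05-h grid to 72 h (≈9 terminal half-lives
for the slowest compound). Negative states are clipped only below
1e-15 of dose; anything larger is an error. AUC0-inf always comes from
NCA extrapolation, never from ultra-long integration. Each simulation
runs in ~0.1 s.

## Reference physiology

No physiology table is published alongside the compound parameters, so
the package ships its own versioned reference (73-kg adult male,
`data/reference_human.yaml`): ICRP-style organ volumes, CO 336 L/h,
hematocrit 0.45. Scaling is minimal by design: volumes linear in body
weight, CO ∝ weight^0.75, flows as fixed CO fractions; height and age are
carried but unused beyond subject selection, and all three study
subjects are built male (the underlying simulations used one male
virtual individual per compound).

Three choices matter and are worth stating explicitly:

* **Lung volume.** The lung compartment is parenchyma plus its resident
  capillary blood, 1.17 L at 73 kg (1.37 L for the 85.5-kg subject).
  Perfusion-limited models lump tissue and capillary blood; only the
  central venous/arterial pools are separate. The lung-exposure metric
  multiplies by this volume directly, so it is frozen in a test.
* **Splanchnic routing.** The compound Kp tables carry no gut
  compartment, so the splanchnic bed is routed with the hepatic artery
  directly into the liver inflow: the liver receives 22.5 % of CO
  arterially (hepatic artery proper ~6.5 % plus splanchnic ~16 %) and
  3 % portally via the spleen, giving a physiological total hepatic flow
  of 25.5 % of CO — this is what sets the first-pass extraction.
* **Rest-of-body.** Defined as the soft-tissue remainder excluding bone
  mineral (3.6 L at 73 kg): connective tissue, gastrointestinal walls,
  glands. Because its perfusion would otherwise double-count the
  splanchnic flow already routed to the liver, it keeps only the
  residual 4 % of CO (bone/connective share; skeletal perfusion is
  otherwise carried by the marrow compartments). Its large Kp values
  absorb the Vd_ss remainder after rescaling.

## NCA and the validation gate

Cmax/Tmax from the grid maximum; AUC0-t by linear trapezoid (exact for
piecewise-linear profiles, asserted under grid refinement); terminal
slope by log-linear regression over a fixed window — the last 5 positive
points after Tmax — chosen for determinism over best-fit searches, with
R² reported and a warning below 0.99; `AUC0-inf = AUC0-t +
C(t_last)/λ_z`, flagged as unavailable (never silently equal to AUC0-t)
when fewer than 3 terminal points exist. AUC0-t in report tables uses a
24-h clinical sampling window; the validation gate scores Cmax and
AUC0-inf only, because observed AUC0-t depends on each trial's sampling
horizon. The gate itself: every `%PE = 100·|sim − obs|/obs` ≤ 20 %.
With the shipped parameters the maximum across the six gate metrics is
15.1 % (MOX AUC0-inf).

## Dose translation

Lung exposure is computed exactly as defined for the oral simulations:
`AUC0-inf(lung)·V_lung(mL)/dose(µg)·100`. Its literal units are
hours×100; it is treated as a percentage label and is dose-invariant for
this linear model (asserted). Computed at the trial doses, it gives
1.66 % (RIF), 12.3 % (ETH), 33.6 % (MOX), against published estimates of
1.7/13/32.5. Inhaled dose = oral dose × exposure% / FPF% with FPF fixed
at 40 %; the tenth-of-the-oral-dose literature rule is carried as an
independent column and the two never mix. Molar ratios use the **dosed
salt forms** (RIF free 822.94, ETH·2HCl 277.23, MOX·HCl 437.9 g/mol) —
the only convention that reproduces the published 1:45, 1:23.8 and
1:1.25 simultaneously — while the independent literature tissue-ratio
check (0.38 vs 4 µg per 100 mg dose → MOX/RIF ≈ 21.5) uses free-base
molecular weights, since tissue assays measure the free molecule.
Capsule masses split a fixed fill by mole-ratio × MW weighting and sum
to the fill exactly.

## Formulation analytics

Impactor metrics follow the fast-screening-impactor definitions: emitted
dose = recovered − device; EF = impactor mass (induction port +
preseparator + filter) / recovered; FPM = filter mass; FPF = FPM /
emitted. The preseparator counts toward the impactor mass by default (a
labelled toggle exists because some protocols list it with the device);
nominal-fill denominators are deliberately not used. Content uniformity:
mean within 100 ± 15 % of label and sample-SD RSD < 5 %. PSD summaries
interpolate the cumulative volume curve for x10/x50/x90 (span =
(x90 − x10)/x50) and use geometric-mean bin diameters for the Sauter
mean diameter `SMD = 1/Σ(f_i/d_i)`; laser-diffraction optics are not
reimplemented — binned distributions are the input. The dissolution
correction reconstructs cumulative dissolved drug under
withdraw-and-replace sampling, `A_n = C_n·V + v·Σ_{i<n}C_i`
(V = 55 mL vessel, v = 1 mL aliquot); a declining corrected series warns
rather than fails because in-vessel degradation genuinely produces it.

## Synthetic data

The generators stand in for the clinical profiles and the instruments:

* PK profiles: closed-form one- or two-compartment oral models times
  proportional lognormal noise (default CV 15 %, mean-one multiplier);
  dense noiseless profiles recover AUC to 0.5 %, and at CV 15 % the mean
  NCA AUC over 200 seeded replicates is within 2 % of truth.
* Impactor runs: stage masses constructed by inverting the metric
  formulas so noiseless round trips are exact; additive Gaussian stage
  noise truncated at zero (default SD 1 % of recovered dose) biases the
  recovered metrics by < 0.2 points over 100 seeds.
* Dissolution: exact withdrawal bookkeeping — each aliquot's depletion
  is simulated, so the replacement correction has a machine-precision
  oracle.

Noise magnitudes are free parameters (only means ± SD are published for
the real instruments). What passing these tests shows is that the
*analysis* chain is exact and unbiased on data matching its assumptions;
it does not validate assay-specific error structure, carry-over, or
inter-device variability.

## Known limitations

* Perfusion-limited tissues only; no permeability-limited lung, no
  enterohepatic recirculation, no RIF autoinduction, no nonlinear
  binding. The inhaled route itself (deposition → absorption) is not
  modelled: lung exposure from *oral* dosing is the translation
  currency.
* The absorption chain is deliberately generic; compound-specific gut
  physiology is folded into the optimized permeability values.
* Lung tissue is one well-mixed compartment; regional heterogeneity
  (lesions, cavities) is out of scope.
* The validation gate compares against observed clinical *means*;
  inter-individual variability is not propagated.
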