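# Methods

This note documents the model equations, the parameter choices, the
numerical conventions and the known limitations of `cdpbpk`.

## Model structure and equations

Amounts are in µg, volumes in L (unit tissue density), flows in L/h, time
in hours internally (days in reports).

**Blood and free fraction.** The blood compartment holds amount `A_b` in
volume `V_b`; the total concentration is `C_b = A_b / V_b` and only the
free fraction exchanges or is cleared:

    C_free = (1 − BIND) · C_b

Binding is linear (a constant bound fraction), which is the regime relevant
to all shipped scenarios; saturation of blood binding is not modelled.
The extravascular lipoprotein/lymphatic circulation (ELPLC) is a separate
pool fed by the lymph-routed share of gut absorption and draining to venous
blood at `k_lymph`; it is carried as its own state although anatomically it
is part of the rest of body.

**Permeability-limited tissues** (brain, skin, adipose, liver), each split
into tissue blood (`A_cb`, volume `V_cb`) and tissue matrix (`A_ct`,
`V_ct`):

    dA_cb/dt = Q_c (C_free − C_cb) − PA_c (C_cb − C_ct,free / P_c)
    dA_ct/dt = PA_c (C_cb − C_ct,free / P_c)  [− biliary flux, liver only]

Partition coefficients are expressed against the *free* blood
concentration; measured tissue:whole-blood ratios are therefore
`P_c (1 − BIND)` in the linear regime. The rest of body is flow-limited:
`dA_re/dt = Q_re (C_free − C_re / P_re)`. The lung is lumped with blood
(no inhalation by default).

**Hepatic CDBP binding.** The liver matrix holds free plus saturably bound
CD; given the total concentration `C_tot = A_lt / V_lt`, the free level is
the non-negative root of

    C_tot = C_f + LIBMAXCD1 · C_f / (KD + C_f).

Biliary excretion is driven by the bound pool, reflecting the coupling of
CDBP sequestration to biliary elimination:

    F_bile = CL_bile · LIBMAXCD1 · C_f / (KD + C_f)

so the capacity parameter LIBMAXCD1 is a first-order determinant of chronic
blood levels, and biliary output saturates at high (rat 40 mg/kg) doses.
KD is an effective constant not separately identifiable from the shipped
anchors; its default (5000 µg/L) was chosen so the human model is linear
through the whole environmental concentration range (steady-state doubling
error 0.2% at 0.05→0.10 µg/kg/day) while the rat high-dose kinetics
saturate. LIBMAXCD1 = 45000 µg/L then sets the bound:free ratio ≈ 9 that
produces the liver:fat concentration ratio of 5–10.

**Gut lumen and enterohepatic recirculation.** The lumen has a proximal
(absorbing) segment, a distal (purely excretory) segment and a biliary
metabolite pool. Retention fractions are realized as first-order uptake
rates competing with the transit rate KST, anchored at a frozen reference
transit `kst_ref` (equal to the species default KST):

    k_abs = KA/(1−KA) · kst_ref,      realized absorption  = k_abs/(k_abs + KST)
    k_reab = F_reab/(1−F_reab) · kst_ref, realized reabsorption analogous

At the nominal transit rate the realized fractions equal the stated
parameters exactly; a faster transit reduces net absorption and
recirculation, which is why gut transit is a genuinely sensitive parameter
of chronic blood levels. Oral doses (gavage boluses or continuous dietary
rates) enter the proximal lumen; absorbed flux splits `f_lymph` to lymph
(bypassing first pass) and the rest to the portal vein, i.e. into the
liver tissue-blood pool. The proximal/distal split `f_prox`/`f_dist`
assigns absorbed flux to its entry site: only the proximal site feeds the
lacteal (lymphatic) route. A distally *absorbing* segment was rejected
because it would recapture enteric excretion, which is observed not to be
reabsorbed.

Biliary parent output splits at entry: the realized reabsorbed share
returns to the portal inflow, the remainder transits the distal lumen to
faeces. A fraction KBILE of biliary output leaves as the lumped
CD-OH/CD-O-G metabolite (KBILE = 0 in the rat, which lacks chlordecone
reductase); the metabolite pool is deconjugated/reduced back to CD at
`k_reconv` (competing with transit) and the regenerated CD re-enters the
same reabsorption competition. The human default reconversion efficiency is
0.95 rather than 1: complete reconversion would make the metabolite route
kinetically indistinguishable from the parent route, contradicting both the
observation of faecal CD-OH and the sensitivity of the metabolism fraction;
0.95 also reconciles the two literature estimates of biliary loss (~5% of
biliary parent vs ~10% of total biliary output).

**Other excretion.** Enteric secretion `k_ent · C_free` goes from blood to
the distal lumen (never reabsorbed); urinary clearance is
`k_urine · C_free`. Cumulative administered, absorbed, faecal and urinary
amounts are carried as states, giving an exact ledger:
`administered = in-body + faeces + urine` is enforced at 1e-6 relative on
every output grid (typically ~1e-13).

**Dermal and inhalation routes** exist structurally (deposition into skin
matrix / blood) but are rejected unless explicitly enabled; they are
unvalidated placeholders.

## Parameters

Shipped presets (`rat_default`, `human_default`) are for a 0.25 kg rat and
a 70 kg adult human; physiology uses reference volume and perfusion
fractions with cardiac output and alveolar ventilation scaling as
`15 · BW^0.74` L/h. A polynomial growth model can supply body weight at any
age; the default is the static adult, which every shipped scenario uses.

The defaults that matter most, with their rationale:

| parameter | rat | human | role |
|---|---|---|---|
| BIND | 0.97 | 0.80 | bound fraction in blood; only free CD exchanges |
| KA | 0.90 | 0.90 | net oral absorption at nominal transit (">90%" absorbed) |
| KST (1/h) | 0.3 | 0.3 | lumen transit; competes with every uptake process |
| KBILE | 0 | 0.90 | metabolite share of biliary output |
| F_reab | 0.90 | 0.95 | enterohepatic return of biliary parent |
| f_reconv | 0 | 0.95 | lumen reconversion of metabolite to CD |
| PF (adipose, free basis) | 340 | 33.1 | deep storage; measured fat:blood ≈ PF·(1−BIND) |
| LIBMAXCD1 (µg/L) | 45000 | 45000 | CDBP capacity (bound:free ≈ 9 at low dose) |
| CL_bile (L/h) | 3.47e-4 | 8.18e-3 | biliary clearance of CDBP-bound CD |
| k_ent, k_urine (L/h) | 4.6e-4, 3.0e-5 | 1.64e-2, 5.45e-3 | enteric and urinary clearance of free CD |
| PA_adipose (L/h) | 7.7e-4 | 5.0 | rat fat exchange is slow, producing multiphasic decay |

The rat excretion/permeability constants were fitted (with the package's
own machinery) to three anchors: 60% faecal and 1.5% urinary cumulative
excretion 84 days after a single oral 40 mg/kg bw dose, and a 21-day blood
half-life regressed on days 14–56. The slow adipose exchange makes the rat
decay multiphasic: the 14–56-day window declines with a 21-day half-life
while the deep fat pool retains roughly a third of the dose at day 84 and
releases it over months.

The human preset is the fixed point of `calibrate_human_scale`, which pins
the absolute scale at run time to two anchors: reverse dosimetry of
0.42 µg/L must return 0.007 µg/kg bw/day (within 0.1%), set by scaling the
three irreversible clearances jointly (preserving their shares), and the
terminal blood half-life on days 300–900 after cessation of a 1000-day
exposure must be 131 days (within 2%), set by the adipose partition
coefficient — the dominant volume-of-distribution lever. The two
coordinates are nearly decoupled (partitions do not move steady-state blood
in the linear regime), so the iteration converges in a few rounds and is
idempotent to <0.1%. All other printed dose↔concentration pairs are
out-of-sample: the calibrated model reproduces them within 4%.

## Dosimetry conventions

"Blood concentration" means the total (free + bound) whole-blood
concentration, the quantity biomonitoring studies report; plasma is
identified with whole blood (no haematocrit correction). Steady state is
declared after 1000 days of constant exposure (≈7.6 terminal half-lives); a
non-convergence flag is raised if blood still moves >1% over the last
eighth of the exposure. Dietary exposure is a continuous zero-order input;
discrete daily boluses agree with it at steady state within 2% and are
available behind a flag. Reverse dosimetry first checks linearity (a
doubled probe dose must double the response within 1%) and then inverts by
a monotone fixed-point iteration to a 0.1% residual. Terminal half-lives
come from log-linear regression on fixed windows (human: days 300–900
post-cessation; rat: days 14–56 post-dose); the windows are package
conventions chosen for reproducibility, since multiphasic decay makes "the"
half-life window-dependent.

## Sensitivity screen

Each of the 40 manifest parameters (24 chemical-specific scalars, 16
physiological scalars; the structural anchor `kst_ref` is excluded) is
perturbed ±5% one at a time, and the blood concentration at day 655 of a
chronic 1.0e-3 µg/kg bw/day oral exposure is compared to baseline
(SA% = 100 · ΔC/C). Fraction-valued parameters are clipped to [0, 1] with a
logged warning. With the threshold at 0.2%, the screen flags blood binding
(by far the largest), oral absorption, gut transit, the biliary metabolism
fraction, the CDBP capacity and the adipose partition coefficient — and
also the remaining enterohepatic retention and biliary-magnitude parameters
(F_reab, f_reconv, CL_bile, KD, P_liver, k_ent and the liver/adipose volume
fractions), which is structurally unavoidable: whatever scales the dominant
elimination pathway of a mass-conserving model moves its steady state.

## Likelihood and fitting

Observations follow a proportional-error Gaussian,
`obs ~ N(pred, (σ·pred)²)`, with one relative SD per measurement matrix,
either fixed or profiled analytically as the RMS relative residual.
Below-LOD records contribute the left-censored mass `Φ((LOD − pred)/(σ·pred))`.
Fitting maximizes the summed log-likelihood over log-parameters with
bounded Nelder–Mead; it is deterministic given the start. On seeded
synthetic data (10% noise, the 182-day oral design) the biliary clearance
and adipose partition are recovered within a few percent. The LOD/√2
substitution is reserved for the population-survey workflow, where it is
the field convention; the likelihood itself uses proper censoring.

## Synthetic data

The fixture generators simulate each historical study *design* (sampling
schedule, matrices, dosing) with the shipped parameters and multiplicative
lognormal noise (mean-1, relative SD `sigma_rel`, default 0.15). They
emulate design and noise structure only — no inter-subject variability, no
assay drift, no real-data values — so passing recovery tests demonstrates
the estimation machinery, not agreement with historical measurements. The
population-survey generator draws from a two-piece lognormal whose
quartile-group medians hit (0.04, 0.42, 1.48) µg/L by construction,
censors at the 0.06 µg/L LOD, and reproduces the reference quartile group
sizes (166/337/168 at n = 671).

## Numerics

Stiff integration via `scipy.integrate.solve_ivp` (BDF; rtol 1e-8, atol
1e-9 µg — tight enough that the mass-balance ledger sits near machine
precision, loose enough that BDF's step size does not underflow after
multi-mg boluses; a failed BDF segment is retried with LSODA). Integration
restarts at every dose event and dietary-rate switch. States are clipped to
zero at output (negative excursions are bounded by the tolerances). The
liver free concentration uses the numerically stable root of its quadratic.
Problem sizes throughout (1000–2620-day chronic simulations on 400–600
point grids, 81-run sensitivity screens, ~70-evaluation fits) keep any
single operation at seconds on one CPU.

## Known limitations

- Physiology is frozen during a single simulation: lifetime growth enters
  only through the age-resolved physiology used at run start.
- The metabolite (CD-OH/CD-O-G) is tracked in bile, lumen and faeces but
  has no systemic circulation, consistent with its near-absence in plasma
  and urine.
- The rat terminal (post-day-100) half-life exceeds the literature's
  ~45-day late phase; the shipped rat set prioritizes the three calibration
  anchors above.
- Dermal and inhalation routes are structural placeholders without
  validation data.
- Reverse dosimetry returns point estimates; no uncertainty propagation.
- High-dose blood concentrations in the rat (tens of mg/L immediately
  after 40 mg/kg) are above the historically measured range even though the
  excretion balance and window half-life match; whole-blood binding
  saturation, not modelled, likely matters there.
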