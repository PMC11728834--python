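# Methods

## Model structure

The simulator integrates a whole-body system of amount-balance ODEs for one
virtual individual. Compartments: gut lumen (solid and dissolved pools),
arterial and venous blood, lung (in series, carrying the full cardiac
output), ten perfusion-limited organs (heart, brain, muscle, adipose, skin,
bone, kidney, gut, spleen, rest-of-body), and a two-zone liver.

For a perfusion-limited organ T with regional flow Q_T, volume V_T and
tissue:blood partition Kp_T/B:P,

    dA_T/dt = Q_T (C_art − A_T / (V_T · Kp_T / B:P))

The liver is split into an extracellular zone (30% of liver volume:
vascular plus interstitial, carried at blood concentration) and an
intracellular zone. The extracellular zone receives the hepatic artery, the
gut and spleen effluents (portal vein), and the gut absorption flux — so
all absorbed drug undergoes first pass. Exchange with hepatocytes is
passive:

    uptake = PS · (fu_b · C_ec − C_u,cell),    C_u,cell = A_cell / (V_cell · K_cell)

with K_cell = Kp_liver/fu (the cell-to-unbound-plasma equilibrium implied by
the partitioning model) and PS = P_cell · S_liver · V_liver. Metabolism
removes unbound intracellular drug at the whole-liver intrinsic clearance,
so hepatic elimination is sensitive both to CYP capacity and — when the
liver shrinks in disease — to uptake surface.

Reported concentration is venous plasma: C_blood / B:P, in ng/mL. A running
AUC state is integrated inside the solver so exposure ratios can be checked
at solver precision.

### Absorption

Tablet dissolution follows a Weibull law, F(t) = 1 − exp(−ln2 (t/t50)^β),
implemented as a time-since-dose hazard on the undissolved pool (exactly
first-order for β = 1; for β ≠ 1 the hazard of the most recent dose is
applied to the whole pool, an approximation that only matters for
overlapping tablets). t50 = 120 min. The shape β is not reported for the
product; the packaged value β = 2.0 was chosen once so the predicted
single-dose time-to-peak sits at the reported median (4 h, range 2–8 h) — a
first-order profile (β = 1) leaves a dissolution tail that pushes the
predicted peak just past 8 h. Dissolved concentration is capped at the
aqueous solubility 0.477 µg/mL (a 2 mg dose in ~1 L of luminal fluid sits
near this limit, so the cap shapes the absorption phase without changing
AUC). Absorption flux is P_int · S_gut · C_lumen with P_int = 0.02 cm/min
and S_gut = 2000 cm² effective surface (order of the unfolded
small-intestinal cylinder); there is no luminal loss, so a single dose is
eventually fully absorbed.

### Distribution

Tissue:plasma partition coefficients use the composition-based method for
monoprotic acids and neutrals: extracellular water, ionization-corrected
intracellular water (pH 7.0 cell vs 7.4 plasma), neutral-lipid and
neutral-phospholipid partitioning of the neutral species (P = 10^logP;
adipose uses the vegetable-oil proxy 10^(1.115 logP − 1.35)), and an
albumin-binding term proportional to the tissue:plasma albumin ratio and
the residual plasma binding (1/fu − 1 − plasma-lipid term). Etrasimod is
treated as a monoprotic carboxylic acid (single pKa 4.26, 97.9% bound to
albumin), so the acid/neutral branch applies and AGP is carried in the data
model without affecting binding. An independently coded evaluation of the
same published equations serves as the test oracle (agreement to 6
significant figures).

Tissue compositions, organ volumes and regional flows for the 73 kg / 30 y
reference adult are packaged literature values (ICRP-style reference-man
volumes and flows; partitioning-literature composition tables), versioned
and checksummed. Organ volumes scale linearly with body weight, flows as
weight^0.75.

The blood:plasma ratio is decomposed at the measured hematocrit 0.45 into a
plasma and an erythrocyte term, so hematocrit changes in liver disease
recompose B:P mechanistically.

### Metabolism and interactions

Recombinant-CYP specific intrinsic clearances (µL/min/pmol; CYP2C8 0.01157,
CYP2C9 0.08525, CYP3A4 0.01640, CYP2J2 0.01872, CYP2C19 0.01331) scale to
whole-liver clearance through per-individual whole-liver enzyme amounts and
activity multipliers. The whole-liver amounts are not measurable from the
published inputs; they are calibrated constants (scripts/calibrate.py):
their ratios are fixed exactly by the reported fraction-metabolized vector,
and the overall scale is solved so the simulated healthy 2 mg single-dose
AUC_inf equals the healthy exposure anchor 1750 ng·h/mL (comfortably inside
the standard two-fold acceptance band around the observed 1510 ng·h/mL).
The resulting magnitudes are physiological (whole-liver CYP3A4 ≈ 15 µmol).

Perpetrators act as steady-state multipliers on each enzyme's effective
clearance: competitive inhibition divides by (1 + I_u/Ki) (fluconazole Ki:
CYP3A4 10.7, CYP2C9 19.6, CYP2C19 1.74 µmol/L); induction multiplies by
1 + Emax·C_u/(EC50 + C_u) (rifampicin: CYP3A4 Emax 9, CYP2C8 Emax 3.2, both
EC50 0.34 µmol/L). The default perpetrator exposure is a constant unbound
steady-state concentration — fluconazole 58 µmol/L (≈20 µg/mL total at
400 mg QD, fu 0.89) and rifampicin 1.0 µmol/L (≈5 µg/mL total at 600 mg QD,
fu ≈ 0.17) — documented assumptions reflecting typical steady-state
dosing, since the interaction trials' perpetrator regimens are not part of
the model inputs. A time-profile exposure mode is available. Induction is a
pre-induced steady-state activity multiplier, not an enzyme-turnover model.

### Hepatic impairment

Child–Pugh A/B/C pathophysiology is applied as multiplicative scalers on a
healthy individual: portal-vein flow (gut + spleen), hepatic-artery flow,
renal flow, cardiac index, other-organ flow, albumin, AGP, hematocrit,
functional liver mass (liver volume, hence uptake surface), GFR, and
per-CYP whole-liver activity. Two reading decisions:

- The hematocrit row of the scaler table is an absolute hematocrit
  (0.39/0.37/0.35), converted internally to a fraction of the 0.45
  reference; reading it as a fraction-of-control would imply hematocrits
  below 0.18, which is not physiological.
- The CYP "activity" rows are whole-liver metabolic capacity relative to
  control. Multiplying them additionally by the functional-liver-mass
  scaler would double-count the disease effect and predict several-fold
  exposure increases, far beyond the 13–57% observed clinically; with the
  whole-liver reading the model predicts 10%/37%/54% increases for grades
  A/B/C, consistent with observation. Functional liver mass still reduces
  hepatic uptake PS and distribution volume.

Reduced albumin raises the plasma unbound fraction through a
single-binding-protein model, fu' = 1/(1 + r·(1 − fu)/fu) for albumin ratio
r, and partition coefficients are recomputed with fu'.

Because the cardiac-index scaler and the other-organ-flow scaler are not
mutually consistent (other-organ flow ×2.75 cannot fit inside cardiac
output ×1.36), cardiac output follows the cardiac index and the
"other organs" flow group is renormalized by a common factor so venous
return balances exactly and every flow stays positive. For a low-extraction
drug this hemodynamic detail is nearly invisible in exposure.

## Virtual populations

Populations are drawn around the reference adult with independent
mean-preserving log-normal multipliers per parameter class: CV 0.16 for
organ volumes and flows, CV 0.35 for enzyme amounts (defaults; the
population spread behind published prediction intervals is not reported, so
these are conventional PBPK variability settings). One seeded generator per
population; cardiac output is re-derived from the perturbed flows. The
generator emulates between-subject variability in physiology and enzyme
capacity only — it does not emulate age/sex/ethnicity structure,
within-subject variability, nonadherence, or assay error, so passing
population checks demonstrate internal consistency of the model, not
coverage of real demographic extremes.

The synthetic profile generator (datasets module) produces trial-like noisy
observations: a known truth (closed-form one-compartment curve or a
reference simulation) times independent log-normal deviates with median 1
and CV 10–20%, the standard proportional residual model for digitized PK
data. It exists to validate the NCA/verification tooling by parameter
recovery, not to reproduce any digitized clinical curve.

## Dose selection

For a grade and candidate dose, the healthy population (same seed, hence
the same virtual subjects) is scaled to the grade, given one oral dose, and
summarized by per-individual AUC_inf. The recommended dose minimizes
|candidate mean − healthy 2 mg mean| among candidates whose mean ± SE
interval lies within the healthy population band; ties break toward the
lower dose. The band defaults to healthy mean ± SD: with a mean ± SE band
no reduced dose can ever qualify at n = 100 (the quarter-step candidate
grid forces mean gaps of several percent while SE is ~2% of the mean), so
the SE reading would make the procedure vacuous; mean ± SD expresses
"exposure inside the healthy population's spread" and reproduces the
published recommendation. The candidate grid {2.0, 1.75, 1.5, 1.25, 1.0} mg
walks down from the standard dose in quarter steps. Single-dose AUC_inf is
the exposure metric; under dose-linearity steady-state AUC over a dosing
interval ranks candidates identically.

## Numerics

- Solver: LSODA via scipy, rtol 1e-8, atol 1e-10 mg, integration restarted
  at every dose event; halving tolerances moves AUC_inf far less than 0.5%.
- Mass balance (administered = in-system + eliminated) is reported at every
  output point; the suite enforces |residual| ≤ 1e-6 (typically ~1e-11).
- NCA: linear-up/log-down trapezoid; λz from the best adjusted-R² log-linear
  fit over the last 3–6 points, excluding the peak, requiring a negative
  slope; samples below 1e-6 × Cmax are treated as below quantification.
  When no terminal fit succeeds AUC_inf is withheld explicitly rather than
  guessed.
- Ratio reporting rounds half-away-from-zero to two decimals, matching
  printed PK tables; the average fold error is a geometric mean.
- Packaged data are SHA-256 checksummed; a mismatch fails loading.
- Degenerate inputs (zero dose, zero enzymes, empty populations, saturated
  lumen) are exercised in the test suite; the solubility cap clips the
  dissolution rate smoothly to zero at saturation.

## Problem sizes

Population analyses use 100 virtual subjects (the published population
size); a full dose-selection grid for one grade is 500 individual
simulations and runs in ~12 s on one CPU at default tolerances. Tests use
smaller populations (4–12) where only ordering or determinism is at stake.

## Known limitations

- The liver model lumps vascular and interstitial space; hepatic uptake PS
  is a calibration-scale constant (effective surface 1.35e5 cm²/L liver),
  not a measured sinusoidal area. Predictions several-fold away from the
  calibration anchor inherit this uncertainty.
- Terminal half-life is predicted at ~21 h, at the short end of the
  reported ~30 h mean: composition-based partitioning with the adipose oil
  proxy gives a steady-state volume near 35 L versus ~66 L apparent
  volume reported clinically. Exposure (AUC) anchors are unaffected.
- No transporters, no gut-wall metabolism, no enterohepatic recirculation,
  no metabolite kinetics, no biliary disposition kinetics, no
  time-dependent inhibition or enzyme turnover, no food effect.
- Perpetrator exposure defaults are steady-state constants, not full
  perpetrator PBPK profiles.
- The Child–Pugh scalers describe group averages; the model does not
  capture within-grade heterogeneity of liver disease beyond the sampled
  physiological variability.
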