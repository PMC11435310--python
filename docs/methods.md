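# Methods

## Scope and model structure

`pregpbpk` simulates single oral doses of lamotrigine (LTG) and efavirenz
(EFV) in adult male, adult female and pregnant physiologies, and predicts
their mutual interaction. The whole-body model is perfusion-limited: twelve
tissues (lung, adipose, muscle, liver, kidney, heart, brain, skin, gut,
spleen, reproductive, rest-of-body) plus arterial and venous blood pools,
connected by blood flows with the lung in series carrying the full cardiac
output. Gut and spleen drain through the portal vein into the liver. Amounts
are in µg, volumes in mL, time in h, concentrations in µg/mL.

For tissue *t* with volume *V*, flow *Q* and partition coefficient *Kp*:

    dA_t/dt = Q_t (C_art − C_t · B:P / Kp_t)

Hepatic metabolism acts on the unbound liver water concentration
`Cu = fup·C_liver/Kp_liver` through parallel Michaelis–Menten pathways; at
steady state this reduces exactly to the well-stirred liver model, which the
clearance calibration exploits. Renal clearance acts on the kidney's emergent
plasma concentration and scales with the gestational GFR ratio.

## Absorption

The gastrointestinal tract is a nine-segment compartmental absorption-transit
chain with fasted-state pH, fluid volume, transit time and lumen radius per
segment (bundled defaults; small-intestinal residence 3.22 h). Stomach
transit is exposed as a parameter because gastric emptying dominates the
absorption phase of rapidly permeating drugs; 0.5 h is the default for both
compounds. Dissolution follows the Johnson particle model with the diffusion
layer capped at 30 µm and a fixed mean particle radius (particle shrinkage is
not tracked; both compounds dissolve fast relative to transit, so the
simplification is inconsequential here). Supersaturation precipitates first
order with the compound's precipitation time (900 s). Local solubility is the
Henderson–Hasselbalch value at segment pH capped at the ionization
solubility-factor, overridden by biorelevant FaSSGF (stomach) and FaSSIF
(duodenum/jejunum) measurements by default. Absorption flux is
`Peff · (2V/r) · ASF · C` with the colonic surface factor reduced to 0.2.

Absorbed drug passes one way through a small enterocyte compartment (4% of
gut tissue volume, perfused by 60% of gut blood flow) where gut-wall enzymes
act before the portal vein. This makes gut extraction a genuine first-pass
quantity: an earlier variant that placed gut enzymes in the systemic gut
tissue let recirculating drug dominate the gut-metabolism ledger, which both
deflated FDp artificially and inverted the gestational bioavailability trend
for efavirenz.

Fa is the cumulative absorbed flux over the dose, FDp subtracts first-pass
gut metabolism, and F applies the linear-limit well-stirred hepatic
extraction; the ordering F ≤ FDp ≤ Fa holds by construction and the mass
ledger must close to 1e-6 of the dose on every run.

## Distribution

Tissue-to-plasma partition coefficients use the Rodgers–Rowland method in a
single-equation form: neutral species distribute into tissue water and
lipids (adipose neutral lipid treated as olive oil,
log D_vo = 1.115·logP − 1.35) and bind extracellular proteins via a
tissue-to-plasma albumin ratio; for a strong base (pKa ≥ 7) the cation binds
acidic phospholipids instead, with an association constant back-calculated
once from the measured blood-to-plasma ratio at the reference fraction
unbound. EFV is entered exactly as its source compound table prints it
(base, pKa 10.2) even though it is chemically a weak NH-acid; under the
strong-base equations this yields a physically plausible Vss (~1.6 L/kg raw)
where a neutral treatment of a logP 4.6 compound would not. Rest-of-body
takes the volume-weighted mean Kp of the computed tissues.

## Calibration

Two scalar calibrations, both performed once on the standard 70 kg adult male
and reused unchanged everywhere so that sex and pregnancy effects are purely
physiological:

1. **Kp scale.** A single global factor scales all Kp values so whole-body
   Vss matches the compartmental estimates (LTG 1.13 L/kg → factor 1.17;
   EFV 1.341 L/kg → factor 0.84). The raw, uncalibrated prediction is also
   exposed (`raw_vss_per_kg`) and is what the partitioning check reports.
2. **Clearance.** The reported fm percentages fix the pathway split; the
   non-enzymatic remainder (11.47% for LTG) becomes renal clearance. The
   hepatic share is converted to a total unbound intrinsic clearance by
   inverting the well-stirred model, and enzyme amounts are scaled to meet
   it. For LTG, per-enzyme amounts are first back-solved from the reported
   non-pregnant Clint values (UGT1A4 3.1564 L/h, UGT1A3 0.3411 L/h), so only
   one common factor (1.20) bridges to the in-vivo clearance target of
   2.09 L/h. For EFV no per-enzyme clearances are reported; the calibrated
   total (3.496 L/h plasma) is split by an assumed CYP2B6-dominant fm vector
   (CYP2B6 89.5%, CYP3A4 4%, UGT1A4 2.5%, UGT1A9 4%), which matters only for
   the interaction arithmetic, not the base pharmacokinetics. The gut CYP3A4
   amount is anchored to a first-pass escape fraction Fg = 0.95, consistent
   with the reported bioavailability (~88%) once Fa (~91%) and the hepatic
   escape (~95%) are accounted for.

## Pregnancy

Gestational functions are smooth fraction-of-term forms with term anchors
from the reference literature: +12.5 kg body weight, +48% plasma volume,
−12% hematocrit, +50% GFR, +3.3 L adipose, +5 L utero-placental/conceptus
volume lumped into the reproductive compartment (fetal drug amounts are not
resolved), utero-placental perfusion rising to ~40 L/h, kidney flow
following GFR. Rest-of-body absorbs the residual gain so tissue volumes
always close against body weight; cardiac output is recomputed as the flow
sum, keeping the conservation invariant exact. Plasma protein binding
dilutes with albumin (−22% at term), raising fup as
`fup' = fup/(fup + (1 − fup)·albumin_ratio)`; the shift is on by default and
toggleable. For the UGT pathways of LTG the reported gestational-week Clint
values replace the non-pregnant ones directly (linear interpolation between
tabulated weeks), keeping the adult calibration factor; EFV has no reported
gestational enzyme table, so its pregnancy behaviour is purely
physiological.

## DDI

The static model evaluates the fm-weighted modifier formula at the
perpetrator's average unbound hepatic concentration from its own simulation
(in µM). The dynamic mode couples one way: the perpetrator's unbound liver
concentration trace forces the victim's Km terms (competitive, Ki) and
enzyme-level turnover (Emax/EC50, kdeg = 0.0005/min → ~33 h time constant).
EFV inhibits UGT1A4 (Ki 2 µM) and UGT1A9 (9.4 µM) and induces CYP2B6/CYP3A4,
so LTG's AUC ratio rises (≈1.5 at 200 mg LTG + 400 mg EFV) while its
single-dose Cmax barely moves (ratio ≈1.02) — clearance inhibition cannot
reshape the absorption peak of a long-half-life drug. No interaction
constants exist for LTG as a perpetrator and none are invented, so an
EFV-as-victim run solves an identical system and its ratios are exactly 1;
a null (zero-dose) perpetrator likewise yields ratios of exactly 1.

## PK analysis and synthetic data

NCA uses linear-up/log-down trapezoids; λz comes from the best
adjusted-R² log-linear window of ≥3 post-peak points ending at the last
positive observation, ties resolved toward the longer window, and is flagged
non-identifiable otherwise (AUC0–inf then omitted). CL/F = dose/AUC0–inf.
AFE/AAFE are the log10 fold-error means, standard in PBPK evaluation; the
validation rule is strict: every AUC0–t and Cmax |%PE| < 25.

Compartmental fitting uses analytic/eigendecomposed 1–3-compartment oral
models with seeded multi-start lmfit optimisation. When all observations are
positive the objective is the log-residual sum of squares — the natural
estimator under the multiplicative log-normal error the synthetic generator
produces (its noise is mean-preserving with CV = `noise_cv`); otherwise
1/obs-weighted residuals are used. Model order is selected by AIC.

The synthetic generator emulates sparse digitized literature profiles
(default 13-point schedule over 72 h, CV 10–20% log-normal noise). It does
not emulate assay quantification limits, additive baseline noise,
digitization bias or between-subject variability, so passing recovery tests
demonstrate estimator correctness under the stated error model, not
robustness to every feature of real digitized data.

## Numerical choices

LSODA with rtol 1e-8 / atol 1e-6 µg, dense reporting every 0.05 h, dosing by
state re-initialisation (no events). Dissolution/precipitation switches use
`max(·, 0)` forms, keeping the right-hand side continuous. Problem sizes:
24 h single-dose runs (481 reporting points, ~45 states) take ~0.2 s; the
noisy-replicate fitting study uses 200 profiles at CV 15%.

## Known limitations

- The large sex gap reported for EFV (female exposure far below male) is
  **not** reproduced by reference physiology alone: the smaller
  female body raises concentrations slightly more than the larger adipose
  depot lowers them, so female Cmax comes out marginally above male. The
  gestational trends (falling Cmax, AUC0–24 and F for both drugs) are
  reproduced.
- Observed gestational EFV ratios under LTG co-administration decline
  mildly in the source material; with no LTG perpetrator constants the
  model's EFV ratios are exactly 1.
- Proprietary reference-physiology internals (organ data, gut geometry,
  absorption scale factors) are replaced by published reference values, so
  simulation anchors are compared at ±20%, and Tmax — highly sensitive to
  gut geometry — is systematically later than reported (e.g. 1.55 h vs
  1.12 h for adult LTG).
- CYP2B6 genetic polymorphism, fetal compartment concentrations,
  transporter kinetics, fed-state absorption and controlled-release
  formulations are out of scope.
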