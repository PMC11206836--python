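# Methods

`cbzpbpk` is a whole-body, parent–metabolite physiologically based
pharmacokinetic (PBPK) model of carbamazepine (CBZ) and its active metabolite
carbamazepine-10,11-epoxide (CBZ-E), built to reproduce and interrogate three
linked phenomena: CBZ's dose-dependent (nonlinear) plasma kinetics after oral
dosing, its autoinduction of the CYP enzymes that clear it, and the
drug–drug-interaction (DDI) liability that the same induction creates for
CYP3A4 and CYP2C9 victim drugs.

## Model structure

**Disposition.** Twelve perfusion-limited tissue compartments (lung, adipose,
muscle, liver, kidney, heart, brain, skin, spleen, gut, bone, rest) plus
venous and arterial blood per compound, connected by reference adult-male
blood flows (cardiac output 340 L/h; hepatic blood flow Qh = 90 L/h as the sum
of hepatic arterial, gut and splenic flows). Tissue:plasma partition
coefficients come from the Rodgers–Rowland composition equations for neutral
compounds — CBZ (amide, pKa 10.86) and CBZ-E (pKa 11.03) are treated as fully
un-ionized — with the vegetable-oil surrogate for adipose and a residual
interstitial-protein term scaled by the tissue:plasma albumin ratio. For the
CBZ parameter set this yields a steady-state distribution volume of
~0.8 L/kg, in the physiologic range reported for the drug.

**Hepatic elimination.** Each saturable pathway (CYP2C8/CYP3A4/CYP3A5 →
CBZ-E; CYP2B6/CYP3A4 → OH-CBZ; UGT2B7 → CBZ-glucuronide) uses
Michaelis–Menten kinetics driven by the *unbound liver intracellular*
concentration; remaining metabolism is a linear unbound intrinsic clearance
CL_int,liver,unbound = 3.316 L/h. Per-unit-enzyme Vmax values are scaled to
whole-organ capacities with standard liver abundances (CYP3A4 137, CYP3A5 24,
CYP2C8 24, CYP2B6 17 pmol/mg microsomal protein; 40 mg protein/g liver,
1800 g liver; UGT2B7 on a per-mg-protein basis). These defaults were chosen so
the low-dose pathway split matches the published contribution analysis
(epoxide formation 38.3% vs reported 37.68%; unspecified linear clearance
54.5% vs reported 56%) and give a single-dose plasma clearance of
~1.35–1.40 L/h. CBZ-E is eliminated by a linear hepatic clearance
back-calculated from clinical CL_sys/F = 5.28 L/h via the pre-systemic
availability fixed point (4.86 L/h organ clearance, converted to an unbound
intrinsic clearance by inverting the well-stirred model), plus renal
filtration. Renal filtration for both compounds applies the fixed reported
clearances (0.0084 and 0.14 L/h) to the unbound plasma concentration; at
these magnitudes the unbound-vs-total ambiguity in the source material is
numerically irrelevant.

**Metabolite routing.** Parent metabolic flux whose product is CBZ-E enters
the metabolite's liver compartment directly (hepatic formation) or its
enterocyte pool (gut formation), with a molecular-weight mass correction;
OH-CBZ and CBZ-glucuronide are terminal ledger entries. CBZ-E formed in the
body never re-enters a lumen; gastric degradation of orally dosed CBZ-E is
handled only through the literature dose-correction factor 0.81.

**Oral absorption.** A nine-compartment absorption–transit model (stomach,
duodenum, two jejunal, three ileal segments, caecum, ascending colon) carries
unreleased drug, a polydisperse solid phase, and dissolved drug. Gastric
emptying is first order (t1/2 15 min fasted, 60 min fed); small-intestinal
residence totals 3.3 h split by segment length. Controlled-release and
enteric forms release by their fitted Weibull profiles (release hazard
f'(t)/(1−f(t)), which reproduces the cumulative Weibull exactly); immediate-
release tablets disintegrate instantly into five particle bins spanning the
60 ± 2×20 µm radius distribution with normal-density mass weights; solutions
start dissolved. Dissolution follows the Noyes–Whitney shrinking-sphere law
with diffusion layer h_eff = min(r, 30 µm); bin radii are tracked through a
per-bin reference-mass state so particle number is conserved under transit.
Local solubility interpolates the measured anchors (SGF 0.236, aqueous 0.127,
FaSSIF 0.283, FeSSIF 0.52 mg/mL for CBZ) in bile-salt concentration; the fed
state switches bile salts toward the FeSSIF anchor and slows gastric
emptying. Supersaturated solution relaxes into the smallest particle bin at
50 /h (effectively instant precipitation on transit timescales). Absorption
flux is 2·Peff·ASF/R per segment on the dissolved concentration with no
gastric absorption; enterocyte drug leaves basolaterally with the villous
blood flow and is metabolized by gut CYP3A4 and UGT2B7 (whole-gut CYP3A4
~70 nmol distributed 11/32/28/15/9/5% along the small intestine), driven by
the total enterocyte concentration.

**Enzyme induction.** CYP3A4, CYP3A5, CYP2C8, CYP2B6 and CYP2C9 follow a
turnover equation dE*/dt = kdeg·(1 + Emax·C/(EC50+C) − E*) with the published
Emax/EC50 values (EC50 values are in-vitro total-medium and are used without
binding correction). The driving concentration is unbound liver intracellular
drug for hepatic enzymes and unbound enterocyte drug for gut CYP3A4. kdeg
defaults are 0.0193 /h (t1/2 36 h) in liver and 0.0301 /h (t1/2 23 h) in gut,
literature conventions; the steady-state fold is provably kdeg-independent,
so these set only onset/washout kinetics. UGT2B7 and the linear
CL_int,liver,unbound are not inducible. Turning induction off is implemented
as Emax = 0, so the induction-off and Emax-zero simulations are identical by
construction.

## Absorption-model parameterization

Commercial absorption models do not publish their regional absorption-scale
factors or effective luminal fluid volumes. These constants are therefore
treated as the calibration layer of the absorption model and were fitted once
against published absorption benchmarks for these two compounds — CBZ-E
suspension Fa = 0.9995, CBZ single-dose systemic availability
falling from ≈95% (50 mg) to ≈81% (800 mg), and a sub-percentage-point gap
between cumulative dissolved and absorbed fractions — then frozen in the
versioned physiology file. The calibrated picture is physiologically
conventional: absorption capacity declines distally (ASF 3.2 → 0.4 along the
small intestine, 0.18 in colon), effective small-intestinal dissolution
volume is ~565 mL, and the colon holds almost no free water (3 mL), so solid
drug that escapes the small intestine is essentially unavailable while
already-dissolved drug still absorbs. Under this single configuration the
dose dependence of Dis%, Fa%, FDp% and F% across 50–800 mg is a prediction,
not a fit.

## Evaluation statistics

Non-compartmental analysis uses the linear trapezoid to the last sample, a
log-linear least-squares terminal slope (default: last three points,
configurable), AUC extrapolation by C_last/Ke, and CL/F = dose/AUC_0-inf.
Prediction accuracy uses the absolute average-fold error
AAFE = 10^(mean |log10(pred/obs)|) with the conventional <2 adequacy bound
(absolute values applied; the typeset source formula omits the bars but names
the metric "absolute"), and symmetric 1.25-fold/2-fold flags. Local
sensitivity evaluates AUC_0-inf at nine log-spaced multipliers in [0.8, 1.2]
and reports the log–log regression slope, which consolidates the
per-perturbation definition into one number and equals it in the
small-perturbation limit.

DDI ratios are AUC_last and Cmax of the victim with/without the perpetrator
on a shared grid; acceptance bounds follow the variability-corrected limit
Limit = (1.25 + 2(R−1))/R with R = max(Robs, 1/Robs), giving
lower·upper = Robs² exactly and the (0.8, 1.25) band at Robs = 1. Victim
drugs are generic one-compartment models (optionally Michaelis–Menten for
phenytoin-like kinetics) whose clearance fractions scale with the
perpetrator's enzyme-amount time courses; gut extraction for CYP3A4 victims
scales its intrinsic component with the gut CYP3A4 amount. The shipped victim
parameterizations are literature-style placeholders: the ratio machinery, not
any victim-specific number, is the validated surface.

## Synthetic studies and parameter recovery

Synthetic "observed" studies are model simulations sampled on a clinical
schedule with multiplicative lognormal noise (sigma = sqrt(ln(1+CV²));
default CV 20%, giving an expected AAFE against truth of
10^(sigma·sqrt(2/pi)/ln10) ≈ 1.17) and optional lower-limit-of-quantification
censoring; a fixed seed reproduces a study byte for byte. Recovery refits
named parameters by bounded least squares on log10 concentrations
(seed-controlled multi-start available for Emax-type fits). Identifiability
is probed after the fit: if a ±5% parameter change moves the simulated
profile nowhere by more than 0.01 log10 units (~2.3%, below assay noise), the
parameter is flagged non-identifiable — a single dose, for example, carries
no usable autoinduction signal for Emax. These experiments demonstrate
internal consistency of the pipeline; they cannot validate the model against
real biology, inter-individual variability, or digitization error in
literature profiles, none of which the noise model represents.

## Numerical choices

The coupled system (~120–230 states depending on configuration) integrates
with scipy's BDF using a probed Jacobian sparsity pattern (the right-hand
side is perturbed state-by-state at random positive states; the union pattern
drives grouped finite differences). Default tolerances rtol 1e-7/atol 1e-9
(1e-6/1e-8 for long multiple-dose runs); outputs are resampled to 0.1 h
(0.25–0.5 h for fitting). Dose events restart the integrator; infusions are
piecewise-constant inputs. The per-bin dissolution rate constant is capped at
200 /h — sub-micron particles dissolve effectively instantly, and the cap
removes the 1/r² stiffness as bins empty — and particle radii are floored at
0.01 µm. Mass ledgers close to ~1e-11 relative at these tolerances; the
package asserts 0.1%. Single-dose horizons are 96 h; multiple-dose scans use
30 doses q12h (15 days, >6 induction half-lives, so enzyme pools are at
steady state) with metrics on the terminal dosing interval; recovery
experiments use 20-dose (10-day) iv studies. These problem sizes were chosen
to sit well past the plateau of each quantity while keeping a full run in
minutes.

## Known limitations

* The steady-state clearance contrast under autoinduction (CL fold from 50 to
  800 mg q12h) computes ~1.87 (iv) and ~1.81 (oral) against the published
  1.71/1.64. The published per-enzyme folds are themselves mutually
  inconsistent under any single driving concentration (CYP2C9 parameters
  imply ~1.5-fold where 1.2 is reported, at the same concentration that gives
  the reported 4-fold CYP3A4); this package reports all folds as computed
  (3.65/1.16/1.49 for CYP3A4/3A5/2C9 at 300 mg BID) rather than forcing
  agreement.
* Transporters (P-gp/MRP2), enzyme polymorphisms, CBZ-E's own induction of
  CYP3A, permeability-limited tissues, enterohepatic recirculation, and
  population variability are out of scope; the fitted CYP3A4 Emax may absorb
  the missing CBZ-E induction contribution.
* Paracellular permeability is folded into Peff; meal composition is not
  modeled beyond the fed-state solubility/emptying/Weibull switches.
* Weibull release hazards reference the most recent dose, so overlapping
  controlled-release doses at intervals shorter than the release duration are
  approximated.
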