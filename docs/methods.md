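# Methods

## Scope and data model

The package analyses albumin-inclusive uptake studies in OAT1/3-transduced
proximal tubular cells (ciPTEC-OAT1/3) and extrapolates the results to in
vivo renal clearance. Its inputs are tabular: fraction-unbound replicates
per substrate × albumin condition, uptake time courses (minutes,
pmol/mg lysate protein) per substrate × condition
(control / 1% HSA / 4% HSA / probenecid), transporter abundances, and
physiological constants. The packaged reference tables carry condition
means ± SD; replicate-level raw data were not released, which shapes
several choices below.

Unit conventions: in vitro clearances in μL/min/mg lysate protein, per-cell
clearances in μL/min/10⁶ cells, in vivo clearances in mL/min (L/h only at
the report layer). "x% HSA" is read as x g/dL and converted to μM with a
configurable albumin molar mass, default 66,500 g/mol (1% → 150.4 μM,
4% → 601.5 μM).

## Binding

A single-site model with trace ligand gives the hyperbolic fraction unbound
f_u = K_d/(K_d + [A]). K_d is fitted by nonlinear least squares on log K_d
with multi-start (1, 10, 100, 1000 μM) and relative (1/prediction²)
weighting by default: f_u spans nearly three orders of magnitude across the
panel, and unweighted fits are dominated by the weak binders. Fitting the
two condition means reproduces the tabulated K_d within 3% for all eight
substrates. K_d above 10,000 μM, or all means above 0.95, raises an
"effectively unbound" flag; flagged substrates are excluded from
facilitated-dissociation fits and serve as negative controls. The
protein-free and probenecid conditions are assigned f_u = 1.

## Uptake kinetics

CL_int,u is the OLS slope of intracellular amount vs time divided by the
unbound concentration (μM ≡ pmol/μL). The regression includes an intercept
by default (rapid surface binding produces nonzero intercepts); a
through-origin option exists. r² < 0.8 triggers a linear-phase warning.
Active clearance is total minus the probenecid-condition passive clearance,
subtracted per replicate when counts match, otherwise by the passive mean.
Negative active values are kept and flagged, not clamped; a one-sided
t-test (α = 0.05) on the control-condition active clearance sets a
non-substrate flag. The albumin-effect ratio R is the mean of per-replicate
ratios (the tabulated means are consistent with mean-of-ratios, not
ratio-of-means); an unpaired mode returns the ratio of means with
error-propagated SD.

## Facilitated-dissociation model

Full form: CL(+A) = CL(−A) + V_b,max·[A]/(K_d·(K_d,m+[A])), with the
albumin-free clearance held at its measured value. Reduced form:
R = 1 + EFD·[A]/(K_d·(K_d,m+[A])). B_max and CL_b,int are not separately
identifiable; only their product V_b,max (and, reduced, EFD) is estimated.
Fits are joint across substrates sharing one K_d,m, log-parameterised with
bounds [10⁻³, 10⁶] and eight log-spaced starts; asymptotic SEs come from
the Jacobian via the delta method.

**Residual scale.** The default objective takes residuals on the log scale
(equivalently, multiplicative error with constant CV). This is the
package's own choice where the error model was open: clearances and fold
ratios span two orders of magnitude, replicate SDs in the reference tables
scale roughly with their means, and linear-scale unweighted fits on the
condition means are dominated by the few largest values to the point of
biasing the shared parameters severely. Log-scale fitting of the packaged
means yields EFD = 480 μM and K_d,m = 891 μM (OAT3, reduced), EFD = 584 μM
(OAT1, K_d,m frozen) and K_d,m = 532 μM (OAT3, full) — all within one
standard error of the estimates obtained from the original replicate-level
data. "linear" and "relative" residual options are exposed.

**Sequential strategy.** The substrate-rich OAT3 panel identifies (EFD,
K_d,m) jointly; K_d,m — a property of the cell surface, not the ligand — is
then frozen for the three-substrate OAT1 panel, which otherwise cannot
identify both parameters. A fit with a single substrate and free K_d,m
raises an unidentifiable-model error.

## Empirical regression

OLS of log10 R on log10 f_u,inc per transporter (log10 throughout). RMSE
is reported as the residual standard error √(SSR/(n−2)). The
extra-sum-of-squares F-test compares one pooled line (2 parameters) with
separate lines (4): F = ((SSR_pooled − SSR_sep)/2)/(SSR_sep/(n−4)). On the
condition means (8 + 14 points) the denominator df is 18; the original
replicate-level design (66 points) gives df (2, 62), which the test suite
checks structurally on simulated data together with the null calibration of
p-values. Prospective prediction R = 10^(a + b·log10 f_u) warns below the
fitted f_u range rather than refusing — prospective use below the range is
exactly the intended application, but deserves a flag.

## IVIVE

REF = abundance(cortex)/abundance(cell line); RAF = in vivo probe
clearance / in vitro probe clearance (adefovir for OAT1, oseltamivir
carboxylate for OAT3; the in vivo reference values are consumed as inputs,
back-calculated from clinical data upstream). Scaling chain: μL/min/mg →
μL/min/10⁶ cells via lysate protein content (0.30 / 0.32 mg/10⁶ cells for
the OAT1/OAT3 lines) → × scaler × PTCPGK (99.4 × 10⁶ cells/g, sweepable
60–209) × KW_cortex (169 g) → mL/min, summed over transporters for dual
substrates. Well-stirred kidney model with Q_r = 1008 mL/min and f_u,b;
CL_r = (f_u,p·GFR + CL_sec)·(1 − F_reabs) with GFR = 120 mL/min and
F_reabs = 0 (all panel substrates are net secreted). f_u,b defaults to
f_u,p / (blood-to-plasma ratio), ratio defaulting to 1; for panel substrates
without a reported f_u,p the 4% HSA incubation value stands in (the two
agree within ~1.5-fold here). In RAF mode the probe substrates are excluded
from evaluation since their clinical data define the scaler. Per-transporter
secretion shares are attributed proportionally to scaled intrinsic
clearance.

Accuracy: fold error = predicted/observed; "within k-fold" is the closed
interval [1/k, k]; GMFE = 10^mean|log10 FE| ≥ 1; RMSE on the linear scale
for clearances and log10 scale for regression residuals. Evaluation against
observed clinical renal clearances is gated on a user-supplied reference
table (per-substrate observed CL_r and f_u,b); the packaged data do not
include one, so the gate is exercised in tests with synthetic references.

## Synthetic experiments

The generator forward-simulates the study design from a ground-truth
record: fraction-unbound replicates around the binding model with additive
truncated-Gaussian noise, and uptake time courses whose slopes come from
the facilitated-dissociation forward model at each albumin level, with
multiplicative lognormal noise (amounts are positive; replicate SDs scale
with means). Defaults mirror the study scale: 6–8 substrates with K_d
log-uniform on [1, 130] μM, EFD 513 μM, K_d,m 520 μM, control + 1% + 4%
HSA + probenecid, four time points in 0.5–5 min, triplicates, 15% CV. All
randomness derives from a single recorded seed; identical seed and
configuration give byte-identical output. What the simulations do not
emulate: LC-MS/MS error structure, plate effects, dialysis non-equilibrium,
or saturation kinetics — passing round-trip tests therefore demonstrates
estimator correctness under the stated error model, not robustness to
assay artefacts.

The stochastic recovery study (`fd_recovery_study`, 200 simulated studies
by default) refits the reduced model through the complete processing chain;
at the default design it recovers EFD and K_d,m with ~13–15% median error
and ≥95% empirical coverage of the 95% asymptotic intervals. Problem sizes
throughout the test suite (200-draw recovery studies, 200–500-replicate
null simulations) were chosen as the smallest designs that make the checks
statistically meaningful.

## Known limitations

* Single albumin pool; no other plasma proteins, no CKD-modified albumin.
* No Michaelis–Menten saturation (assays run below K_m) and no intracellular
  binding/metabolism correction.
* B_max and CL_b,int are reported only as their product.
* Abundance SDs are not propagated into REF (point scalers only).
* The condition-mean tables cannot reproduce replicate-level statistics
  exactly (F-statistic, RMSE of the log-log fits); these are validated
  structurally instead.
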