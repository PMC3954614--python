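# Methods

## The model

`chokinet` simulates a CHO (Chinese hamster ovary) cell shake-flask batch
culture with a regulated kinetic-metabolic model: 46 state variables and
35 lumped reactions covering glycolysis, the oxidative pentose phosphate
branch, the TCA cycle, glutaminolysis, grouped amino-acid catabolism,
oxidative phosphorylation with an explicit proton leak, creatine and
adenylate buffering, and lumped biomass and monoclonal-antibody synthesis.

States split into three compartments with fixed units:

* culture: viable cell density Xv (10^6 cells/mL) and antibody titer
  (mg/L);
* extracellular (mM): glucose, lactate, ammonium and the twenty
  proteinogenic amino acids;
* intracellular (nmol per 10^6 cells): glycolytic and TCA intermediates,
  intracellular glutamate, the nucleotide pools ATP/ADP/AMP, NAD(H),
  NADP(H) and phosphocreatine.  Free creatine is not a state; it is
  recovered from a conserved creatine total.

Seven reactions (LDH, GLNS, GLDH, AlaTA, ASTA, CK, AK) are reversible
pairs with separate forward and reverse maximum rates, giving 42 maximum
rates; with 48 affinity constants and 5 regulatory constants the model
has 95 kinetic parameters.  Two further reactions (PGI, MLD) are
reversible with a single maximum rate and an equilibrium-like back term,
which keeps the maximum-rate count at 42.

### Rate laws

Every directional rate is a maximum rate multiplied by dimensionless
hyperbolic factors:

    v = vmax * prod_i c_i/(Km_i + c_i) * r/(K_r + r) * reg terms

with one saturation factor per kinetically limiting substrate and one
nucleotide-ratio driving force r in {ATP/ADP, ADP/ATP, NADH/NAD,
NAD/NADH, NADPH/NADP, NADP/NADPH} where the reaction is redox- or
energy-coupled.  Ratios rather than absolute nucleotide pools drive the
kinetics because the pool sums vary far less than the ratios in batch
culture; this also gives the model its homeostatic character (ATP/ADP is
held near 10 and NADH/NAD near 0.05 by the opposing dependencies of the
producing and consuming reactions).

Bookkeeping of the 48 affinity constants: 45 substrate/product constants
plus the two ratio constants of respiration (on NADH/NAD and ADP/ATP) and
the one of the lumped ATPase (on ATP/ADP), which are the energetically
decisive ones.  The ratio factors of all other reactions use fixed
homeostatic reference ratios (ATP/ADP 10, NADH/NAD 0.05, NADPH/NADP 2) as
structural normalization constants; they are not fitted parameters, so the
kinetic parameter count stays at 95.

Uptake of extracellular nutrients is modelled through the first
intracellular enzyme-catalysed reaction, with the saturation term taken on
the medium concentration — transporter affinities are low relative to
medium levels, so transport is not the controlling step.

### Regulation terms

Five glycolytic regulation factors can be enabled individually or through
the scenarios none / I / I+II / all:

| term | kind | target | effector |
|------|------|--------|----------|
| I | inhibition | hexokinase | G6P (product) |
| II | inhibition | phosphoglucose isomerase | PEP |
| III | inhibition | phosphofructokinase | G6P |
| IV | activation | pyruvate kinase | F6P |
| V | inhibition | lactate dehydrogenase (fwd) | extracellular lactate |

Inhibition multiplies the rate by 1/(1+e/Ki), activation by e/(Ka+e).
The default scenario is I+II: adding term I and then term II each reduces
the simulation error against data generated with both terms active, and
the remaining terms add little, which is why I+II is the working
configuration.  The effector of term V is taken as extracellular lactate
(product inhibition); the choice of effector here is a reconstruction.

Alanine uptake (reverse alanine transaminase) is gated by a smooth
threshold sigmoid on extracellular glutamine, 1/(1+(GLN/theta)^4) with
theta = 0.3 mM: cells only consume alanine once glutamine approaches
depletion.  The Hill exponent 4 makes the gate effectively closed at the
4 mM starting level (<1%) and open (>99%) at depletion.

### Notable lumping choices

* Succinyl-CoA is lumped out: AKGDH carries the alpha-ketoglutarate to
  succinate carbon step (with its NADH), and SCOAS is the substrate-level
  phosphorylation ADP -> ATP, kinetically driven by the succinate pool
  with no net carbon stoichiometry.
* SDH and fumarase are one step (succinate -> malate); its FADH2 is
  folded into the NADH pool.
* Respiration consumes NADH with an ATP yield of 2*(P/O) per NADH
  (default P/O = 1.25, i.e. 2.5 ATP/NADH).  This convention makes the
  oxygen uptake rate qO2 = 0.5*(v_resp + v_leak) and the oxidative term of
  the ATP turnover 2*(P/O)*v_resp simultaneously exact.
* The proton leak is a separate NADH-oxidizing, non-phosphorylating
  reaction; with the default rates it carries ~15% of the oxygen uptake.
* Amino acids are catabolized in three lumped groups entering the TCA
  cycle at pyruvate (Ser via its own reaction, plus Gly/Thr/Cys/Trp and
  Ala via the transaminase pair), glutamate (His/Arg/Pro) and succinate
  (Lys/Ile/Leu/Val/Tyr/Met/Phe); Asn/Asp enter at oxaloacetate through
  ASX and the aspartate transaminase.  Group reactions consume members in
  fixed proportions and are driven by the pooled concentration.
* Biomass synthesis drains G6P, R5P, glutamine, amino acids and ATP in
  fixed stoichiometric amounts per unit growth; its ATP coefficient
  0.00043*3.78 mmol per 10^6 cells is the same constant the
  ATP-partitioning biomarker uses.  Antibody synthesis is tracked on a
  per-residue basis (average residue mass 150 g/mol) and costs 4 ATP per
  unit flux.

### Mass balances

dXv/dt = mu*Xv with mu = v_growth; extracellular species change with
S*v*Xv (converted to mM/h); intracellular pools with S*v (nmol per 10^6
cells per h) minus a growth-dilution term mu*c for carbon intermediates.
Dilution is off for the cofactor pools, and all biosynthetic ATP usage is
written as ATP -> ADP hydrolysis, so the adenylate, NAD(H), NADP(H) and
creatine totals are conserved exactly by the equations (and to integrator
tolerance by the solver) — a standing regression check.

Induction of recombinant expression multiplies the antibody maximum rate
by a clone-specific leaky fraction before the induction event (48 h) and
by 1 after it; integration restarts at the event.  Non-induced cultures
run at the leaky fraction throughout, so induced and control runs of the
same clone differ only through the antibody flux and its drains.

## Numerics

The default integrator is LSODA with rtol 1e-7 / atol 1e-9 (BDF as a
fallback when LSODA gives up on hostile trial parameterizations during
fitting); states are clipped at zero for rate evaluation.  Rate evaluation
is compiled to index arrays — every factor is the hyperbola
num/(K*den+num) on an extended concentration vector — making one
right-hand-side call cheap enough for fitting studies (~10 us).

Pool sizes and affinity constants were chosen jointly so the fastest
local eigenvalues stay below ~1000/h; this keeps the system integrable by
an explicit fixed-step RK4 oracle at dt = 0.001 h, which the test suite
uses as an independent check on the stiff solver (agreement to 1e-4
relative on all states, measured against each state's trajectory scale).

## Calibration

The objective is the weighted sum of squared residuals

    WSSRES = sum_m sum_k (Xsim_mk - Xmea_mk)^2 / var_m

over measured variables m and sampling times k, where Xmea are replicate
means and var_m is the per-variable variance pooled over time from the
replicate flasks (the weight is per variable, not per time point).
Simulated values are interpolated linearly to the observation times.

Screening perturbs parameters one at a time over a grid of relative
deviations and ranks them by the maximum relative change in WSSRES;
parameters below the 15% threshold are frozen at their values.  The
post-fit sensitivity sweep extends the grid to -85%..+300% (intermediate
points {-85,-50,-25,-10,0,+10,+25,+50,+100,+200,+300}% are a package
choice) and normalizes each row to the 0%-change WSSRES, optionally
restricted to a single measured variable; because the objective is
additive over variables, the per-variable maps sum to the global map.

Fitting is bounded nonlinear least squares (scipy trust-region reflective)
on log10-scaled parameters with bounds of two decades either side of the
start — rates are strictly positive and span decades.  During
optimization, finite-difference steps are 1e-2 in log10 (about 2.3% in
the parameter), comfortably above integrator noise; the Jacobian used for
inference is then re-evaluated at the optimum with a 1e-3 step.  The
distinction matters: this homeostatic network responds superlinearly to
percent-scale perturbations of tightly identified rates (the lumped
ATPase above all), so the coarse-step secant overstates the curvature and
would understate those standard errors several-fold.  A trial
parameterization whose simulation diverges returns a large finite penalty
residual so the optimizer backs off.

Confidence intervals follow the asymptotic linearization used by the
classic nonlinear-regression routines: cov = s^2 (J'J)^-1 with the
weighted residual Jacobian J, s^2 the mean squared residual and a
t-quantile; parameter intervals are computed on the log scale and
reported on the linear scale, prediction envelopes by the delta method on
the same Jacobian.  Because s^2 is estimated from the fit, rescaling all
variances by a common factor leaves the intervals unchanged; a
rank-deficient Jacobian yields infinite intervals for the parameters
loading on the null directions, with a warning.  Clone comparisons use a
two-sided Wald z-test on the log-scale estimates, z = (a-b)/sqrt(se_a^2 +
se_b^2); raw p-values are reported without multiplicity correction, and
the default significance level for flagging is alpha = 0.1.

## Synthetic experiments

The generator emulates the comparative shake-flask design: seeding at
0.2e6 cells/mL in medium with 30 mM glucose and 4 mM glutamine, induction
at 48 h, sampling every 24 h for six days, duplicate flasks, and five
cultures (parental; low and high producer, each with and without
induction).  Measured variables are cell density, antibody titer, the
extracellular panel (glucose, lactate, ammonium, glutamate, alanine,
serine, asparagine, aspartate, glutamine), four intracellular pools (G6P,
PEP, pyruvate, succinate), the ATP/ADP and NADH/NAD ratios and qO2.

Noise is multiplicative log-normal, truth*exp(sigma*z) with
sigma = sqrt(ln(1+cv^2)) and a default CV of 5% — unbiased in the log
domain — with duplicate flasks; per-variable variances are then computed
from the replicates exactly as a calibration would.  The generator does
not emulate instrument-specific artifacts (assay drift, saturation,
detection limits, irregular sampling), so passing recovery and coverage
tests shows the estimator is correct under its stated noise model, not
that real assays are this benign.

Clone presets: the low producer raises reverse LDH (x1.8) and the lumped
ATPase (x1.35); the high producer raises reverse LDH (x4), ATPase (x1.5),
forward aspartate transaminase (x1.7) and PDH (x1.75).  The reference
high producer additionally raises pyruvate carboxylase (x2) and forward
GLDH (x1.5) and lowers forward LDH (x0.4) and malic enzyme (x0.6) so the
fixtures show the expected phenotype: the lowest lactate-to-glucose
ratio, the highest pyruvate branch point and net lactate consumption
after glutamine depletion.  The comparison presets restrict overrides to
exactly the attested parameter sets so that power studies can ask for
"exactly these parameters flagged".  Leaky expression fractions are 0.08
(low) and 0.25 (high); the parental line carries no expression cassette
(leak 0).

The comparison study fits each pairwise comparison with the free set
equal to the attested differing set — the sensible post-screening choice,
and the only one under which "exactly the differing parameters flagged at
alpha = 0.1 in >=90% of replicates" is achievable: every additional null
free parameter multiplies the exact-set probability by 0.9.

## Default parameters and their provenance

The published parameter tables for this cell line are not available, so
the shipped defaults are a reconstruction, chosen once so that the
parental reference culture reproduces the canonical batch phenotype:

* maximum cell density ~4.5e6 cells/mL, growth arrest within 12 h of
  glutamine depletion (~92 h);
* glucose never depleted (>5 mM at harvest), lactate produced throughout
  with a lactate-to-glucose ratio near 1;
* alanine and extracellular glutamate produced during growth, alanine
  consumed after glutamine depletion;
* ATP/ADP ~ 10, NADH/NAD 0.03-0.07 and NADPH/NADP ~ 2 during exponential
  growth;
* ~15% of oxygen uptake uncoupled from ATP production (proton leak).

They are order-of-magnitude defaults, not estimates of any published
values, and are labelled as reconstructed in the model document.

## Known limitations

* No cell-death or lysis kinetics: the density plateau comes entirely
  from glutamine-dependent growth kinetics.
* No thermodynamic (Haldane) constraints; reversible pairs are free to
  violate equilibrium ratios.
* Lipid precursors are excluded from the biomass reaction.
* The rate-law algebra (which cofactor ratio drives which reaction, the
  effector of regulation term V, the group stoichiometries of the lumped
  transaminases) is a documented reconstruction; the wiring is stored
  declaratively in the model document so alternatives can be swapped in.
* Fed-batch or perfusion modes, pH/temperature effects and oxygen mass
  transfer are out of scope.
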