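# Methods

`fluxtrace` implements stationary ¹³C metabolic flux analysis (¹³C-MFA)
for compartmentalized mammalian central carbon metabolism, together with
the surrounding measurement models: extracellular rate regression,
natural-isotope-abundance correction of GC–MS fragment MIDs, weighted
least-squares flux estimation with χ² validation and profile-likelihood
confidence intervals, and cofactor/ATP accounting. A synthetic-data
generator reproduces the statistical design of a paired study of parental
HEK293 cells and an isogenic line with diminished fumarate hydratase (FH)
activity, so that every stage of the pipeline can be exercised and
validated offline.

## Network model

A model declares metabolites (compartment, carbon count, rotational
symmetry, balanced flag), reactions with letter atom maps, a lumped
biomass drain and mixing rules. The shipped reference model covers
glycolysis, the oxidative pentose phosphate pathway (lumped transketolase/
transaldolase return), the TCA cycle, anaplerosis (pyruvate carboxylase,
malic enzymes), glutaminolysis, proline synthesis, alanine and serine
exchange, and a citrate→oxaloacetate/acetyl-CoA lipogenic route.
Pyruvate, citrate, oxaloacetate, acetyl-CoA and malate are split between
cytosol and mitochondria. Two mitochondrial pyruvate pools are wired so
that pool 1 feeds pyruvate dehydrogenase and pool 2 feeds anaplerosis and
alanine synthesis, with the carrier flux split between them as free
parameters.

Mixing pools are virtual, non-balanced metabolites that represent what a
whole-cell extract measurement sees: a fitted convex combination of the
compartment pools. They receive label but carry no net flux, so they do
not perturb the flux distribution. The reference model ships mixing pools
for pyruvate ({cytosolic, anaplerotic-mitochondrial}) and malate
({mitochondrial, cytosolic}). Mitochondrial pyruvate pool 1 is fed only by
the carrier, so its MID is structurally identical to cytosolic pyruvate;
including it as a third mixing contributor would add an exactly flat
parameter, which is why the pyruvate pool mixes two contributors. The
citrate fragment sits on the mitochondrial pool for the same reason (the
cytosolic citrate pool is fed only by the transporter and has the same
MID).

Biomass precursor demands are stored per gram dry weight and scaled by a
dry cell weight of 514 pg/cell; the drain flux of each precursor is
μ·coefficient. The shipped coefficients are literature-typical lumped
demands (hexose phosphate, pentose phosphate, 3-phosphoglycerate,
pyruvate, cytosolic acetyl-CoA/oxaloacetate, glutamate, glutamine,
alanine, serine, proline) and are fully overridable in the model file.

Steady state is imposed by construction: the flux space is parameterized
by a particular solution plus a null-space basis of the stoichiometric
matrix over balanced metabolites (with any hard flux constraints appended
as extra rows), and the free coordinates are actual reaction fluxes chosen
by rank-revealing selection so that values are interpretable and
round-trip exactly. Units are nmol/10⁶ cells/h; time is in hours.

## EMU simulation and its oracle

Fragment MIDs are computed by EMU (elementary metabolite unit)
decomposition: starting from the observed fragment backbones, the minimal
set of carbon subsets is traced backwards through the atom maps; EMUs of
equal size satisfy a linear system whose right-hand side convolves smaller
or input EMU MIDs, and the cascade is solved dense-LU layer by layer.
Parallel tracer experiments share one parameter vector and one set of
layer matrices, so both experiments are solved with a single factorization
per layer.

Reversible reactions contribute two opposing direction fluxes, forward =
net⁺ + exchange and backward = net⁻ + exchange; the exchange flux sets the
degree of label back-mixing (the FH reverse flux is the biologically
interesting instance). Rotationally symmetric molecules (fumarate,
succinate) carry equal-weight alternative atom maps — the written map and
its reversal — which yields the positional scrambling that makes, e.g.,
M+3 fumarate informative about the FH reverse reaction. Singular layer
systems (zero-flux dilution traps) raise a named error rather than being
regularized, because they indicate a model pathology the user must see.

Tracer purity is positional and independent: a "99% purity" tracer has
each labelled carbon ¹³C with p = 0.99; unlabelled positions of input
substrates (and unlabelled co-substrates such as CO₂) carry the natural
¹³C fraction 0.0107. The verification oracle enumerates all cumomers of
all balanced metabolites (capped at a total isotopomer state space of
2²⁰), solves the exact linear cascade level by level, and
Möbius-inverts to isotopomer fractions; it shares only the model parsing
with the EMU path and agrees with it to ≤ 10⁻⁸ on all shipped toys and on
the full reference network.

## Natural-abundance correction

The forward model of a derivatized fragment ion is a correction matrix
whose column *j* is the mass-shift distribution of all non-tracer atoms
(formula minus the tracked backbone carbons) shifted by *j*. Raw MIDs
retain 4 masses beyond M+n to capture the Si/S isotope tails of
TBDMS/TMS derivatives. Correction solves the truncated system by
nonnegative least squares and renormalizes, which keeps noisy measured
MIDs on the simplex; matrices with condition number above 10⁸ attach a
warning. The shipped abundance table holds IUPAC standard values and is
overridable; the shipped fragment list is a curated, user-replaceable
stand-in covering the metabolites the study observed (pyruvate, 3PG, PEP,
fumarate, α-KG, malate, proline, glutamate, glutamine, citrate) with
plausible TBDMS-derivative formulas.

## Extracellular rates

With exponential growth (rate μ from a semi-logarithmic count regression)
and first-order degradation (rate k from cell-free series; relevant for
glutamine, k = 0.00345 h⁻¹), the amount of a medium component solves
dA/dt = q X₀ e^(μt) − k A, giving

    A(t) = A₀ e^(−kt) + q X₀ (e^(μt) − e^(−kt)) / (μ + k)

with the limits A₀ + qX₀(e^(μt) − 1)/μ as k → 0 and A₀ + qX₀t as both
rates vanish. The sign convention is secretion q > 0, uptake q < 0;
reports show magnitudes under uptake/secretion headings. (A frequently
reproduced form of this equation with "e^(−kt) + e^(μt)" in the numerator
violates A(0) = A₀ and the k → 0 limit; the ODE-consistent difference form
is implemented.) With μ, X₀ and k known, the model is linear in (A₀, q)
and is solved by least squares; confidence intervals come from a seeded
parametric bootstrap (default 1000 resamples) from the residual variance.
Comparative reports round fluxes to 1 decimal, ratios to 2 decimals and
percent changes to integers (half away from zero), the precision of the
published tables.

## Flux fitting

The estimator minimizes

    RSS(θ) = Σ ((sim_i(θ) − meas_i)/sd_i)²

over all fragment MID masses of both tracer experiments plus soft
extracellular-flux terms. Following the study design, MID SDs are fixed at
0.01; glucose uptake and lactate secretion are soft measurements with 5%
relative SD; the other measured exchange fluxes and the growth rate are
hard constraints. θ comprises the free net fluxes (null-space
coordinates after hard constraints), one exchange flux per reversible
reaction optimized on the bounded transform u = e/(s+e) (scale s = 100),
and one fraction per two-contributor mixing pool. Optimization is
multistart SLSQP (default 20 starts, uniform seeded draws; validation
studies use 2) with linear inequality constraints keeping every reaction
inside its bounds, and a polishing re-run per start. Fits are
deterministic given the seed.

Residuals are evaluated in raw (derivatized-ion) space by default: the
simulated backbone MID is forward-convolved with the correction matrix
and compared to the raw measurement. This choice keeps the error model
exact — correcting measured MIDs by NNLS first would inflate and couple
their errors (covariance σ²(MᵀM)⁻¹) and distort the χ² statistic.
Corrected-space fitting is available through the measurement-set space
tag; correction remains the reporting path.

Degrees of freedom are counted as (fitted MID masses across both tracers
+ soft flux measurements) − (free net fluxes + fitted exchange fluxes +
mixing fractions). Goodness of fit is RSS ≤ χ²₀.₉₅(dof). The 95% CI of a
flux is the profile-likelihood set {v : min RSS with the flux pinned at v
≤ RSS_best + χ²₀.₉₅(1)}, found by an outward grid scan (initial step 5% of
the best value with a configurable minimum absolute step) with bisection
refinement to 0.1%; a direction whose profile never crosses the threshold
before the flux bound is reported as not determined (ND), which is the
expected outcome for structurally weak exchange fluxes. Between
conditions, a flux change is significant exactly when the two 95% CIs are
disjoint; touching (closed) intervals overlap and are not significant, and
an ND bound that blocks the decision marks the comparison indeterminate.

Isotopic stationarity is assessed per fragment by regressing each mass
fraction on quench time and t-testing the slope against zero with
Bonferroni correction across masses.

## Synthetic data

The generator's defaults are the study conditions: growth rates
0.0343/0.0208 h⁻¹ (parental-like / FH-attenuated-like), glutamine
degradation 0.00345 h⁻¹, [1,2-¹³C]glucose at 99% and [U-¹³C]glutamine at
98% purity in parallel experiments, MID noise SD 0.01, 5% relative error
on the soft fluxes, triplicate time courses with 2% CV, quench times
24/29/32 h. Extracellular anchors are the published exchange fluxes
(glucose 578.8/533.5, glutamine 82.7/52.7, lactate 1087.7/1009.8, proline
13.9/1.5 nmol/10⁶ cells/h, …), which also fix the published
lactate/glucose ratios 1.88/1.89; the remaining internal freedom (oxPPP,
pyruvate carboxylase, mitochondrial malic enzyme) is set once to
physiologically plausible values, and the FH-attenuated condition carries
a collapsed FH exchange flux (reverse/forward ratio 0.90 vs 0.17) and
near-zero proline synthesis. Initial amounts emulate a 4 mL dish of
medium with 20 mM glucose and 2 mM glutamine; initial cell numbers
(0.35/0.5 × 10⁶) keep every component positive over the 48 h sampling
window.

Two deliberate statistical choices keep the downstream tests correctly
specified, and differ from what naive generation would do:

- Noisy raw MIDs are **not** renormalized. Renormalizing after adding
  independent Gaussian noise makes the per-fragment errors anticorrelated
  and changes E[RSS] from K to ≈ K − 2 + K·Σx² per fragment, which breaks
  χ² calibration. Slightly negative tail masses are allowed, as
  baseline-subtracted intensities can be; the NNLS correction path clips
  them (with a warning) when correcting for reporting.
- The stated SD of 0.01 applies to the pooled (mean over quench times)
  measurement the fit consumes. Per-quench-time replicates are drawn with
  SD 0.01·√3 so that their mean has SD exactly 0.01; fitting a mean of
  three SD-0.01 replicates against SD 0.01 would deflate RSS threefold.

In the calibration ensemble the hard flux constraints are set at the
generating truth (the "correctly specified" condition); the end-to-end
demonstration instead fixes them at the exometabolomic estimates, as a
real analysis must.

## ATP accounting

Cofactor coefficients per reaction (NADH by compartment, NADPH, FADH₂,
substrate-level ATP, GTP as ATP-equivalent) are shipped as a data file.
ATP production is attributed to glycolysis (net substrate-level
phosphorylation of the glycolytic reactions, ≈ 2 × glucose uptake), the
TCA cycle (succinyl-CoA-synthetase GTP plus oxidative phosphorylation of
TCA-derived mitochondrial NADH at P/O 2.3 and FADH₂ at 1.38 — the default
FADH₂ ratio preserves the conventional 1.5/2.5 efficiency ratio and is
configurable, e.g. to a flat 2.3), and an "other" bucket (non-TCA
mitochondrial NADH, e.g. glutamate dehydrogenase, and net cytosolic NADH
assumed shuttled at no ATP cost). ATP consumed by anaplerosis, citrate
lyase, proline synthesis and the biomass drain forms the consumption row,
so total net ≠ glycolysis + TCA and the discrepancy is auditable. All
rows are linear in the fluxes. Pathway membership sets are configuration,
not code.

## Validation studies and problem sizes

- EMU vs oracle: six toy networks (chain, diamond, cleavage/condensation,
  reversible exchange, symmetric fumarate, TCA loop) plus the full
  reference network, agreement ≤ 10⁻⁸ (observed ≈ 10⁻¹²).
- Natural-abundance round trip: ≤ 10⁻¹⁰ on all shipped fragments
  (observed ≈ 10⁻¹⁶).
- χ² calibration: 100 noisy replicates of the parental condition, 2
  multistarts each; the pass rate at α = 0.05 is expected near 95%
  (mean RSS ≈ dof = 177 with 188 residuals and 11 parameters).
- CI coverage: 10 noisy replicates × 5 audited reactions (glucose uptake,
  lactate secretion, oxPPP, mitochondrial pyruvate import, α-KG
  dehydrogenase), expected ≥ 90% coverage of the generating values. The
  audited set spans the identifiable directions; the pyruvate-cycling
  loop (PC/malic enzymes/MDH/malate transport) is close to flat in the
  likelihood — its members are determined only in combination, their CIs
  are accordingly wide, and noise-free recovery is asserted on an
  absolute (1 nmol/10⁶ cells/h) rather than relative scale.
- Exoflux: noise-free recovery of μ, k and q is exact to optimizer
  precision; bootstrap CI coverage is checked at 200 replicates.

These problem sizes (100/10 replicates, 2 multistarts) are the package's
validation defaults; all studies are seeded and deterministic.

## Known limitations

- The reference network is a curated reconstruction of the described
  scope, not a transcription of any particular supplementary table; the
  same holds for the fragment list and biomass coefficients.
- Stationary MFA only: no isotopically non-stationary fitting, no ²H/¹⁵N
  tracers, unit-mass resolution only.
- The generator emulates measurement noise, not raw chromatograms; peak
  integration, calibration curves and derivatization chemistry are out of
  scope.
- Synthetic MID noise is iid Gaussian, whereas real height-ratio noise is
  heteroscedastic and simplex-constrained; passing calibration here shows
  the estimator and test are self-consistent, not that real data meet the
  0.01-SD assumption.
- Profile CIs assume the χ²(1) threshold calibration of smooth likelihood
  ridges; near bounds (exchange fluxes at zero) intervals are clipped
  rather than corrected.
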