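# Methods

## Model

The model is a linear, six-compartment, constant-coefficient ODE system
for genomic nucleoside pools (mdC, hmdC, fdC, cadC, hmdU, dU), with ten
mass-action fluxes driven by seven enzymes (DNMT1, TET1/2/3, AID, SMUG1,
TDG). Its assumptions, and what they buy:

- **Linear kinetics.** Every flux is (rate coefficient) × (substrate
  level) × (enzyme level); the system is assumed to operate in the linear
  part of any saturating characteristic. No Michaelis–Menten constants
  are needed and the steady state is available in closed form.
- **Transcripts as activity proxies.** Enzyme transcript levels stand in
  for enzyme activities. Affinities (the k's) are shared across cell
  lines; only enzyme levels differ between lines. This is the assumption
  that makes multi-line fitting informative at all.
- **Exogenous dC pool.** The unmodified-dC pool C is a constant (default
  1.0); no dC balance is carried. C can be absorbed into kDNMT1 and
  kAID_C without changing any observable.
- **Lumped repair.** TDG- and SMUG1-initiated base-excision repair are
  single first-order exits (k4·fdC, k5·cadC, kSMUG·hmdU·SMUG1,
  kTDG·U·TDG); downstream BER steps, UNG/MBD4, and deamination of mdC to
  thymine are out of scope.
- **Sign convention for dU.** The dU balance is written
  production-minus-removal (dU/dt = f10 − f9) like every other
  compartment, so dU accumulates under AID action; at steady state
  (f9 = f10) the convention is unobservable.
- **AID affinity.** By default a single kAID multiplies both deamination
  fluxes (f7 on hmdC, f10 on dC). This is deliberate: with separate
  affinities the dU-loop rows constrain only the ratio kAID_C/kTDG, the
  design matrix is structurally rank-deficient (the fitter then warns),
  and NNLS parks both coefficients at zero. `tie_aid=False` exposes the
  split for sensitivity analyses.

The Jacobian is lower-triangular in the state ordering (mdC, hmdC, fdC,
cadC, hmdU, U), so its eigenvalues are its diagonal — the negated total
removal rates. For strictly positive rates all eigenvalues are real and
negative: the steady state is unique, asymptotically stable, and
approached aperiodically. If any removal rate is zero there is no finite
steady state for that species; `steady_state` raises a named error, while
prediction during cross-validation scores the species as 0 and flags the
fold.

## Estimation

Measured levels are treated as steady states, so each cell line
contributes the six balance rows f1=f2, f2=f3+f7, f3=f4+f5, f4=f6, f7=f8,
f9=f10 (the last only when dU is observed), linear in the coefficients.
The stacked system is homogeneous, so a scale must be fixed before
fitting; the convention is kDNMT1 ≡ 1 and C ≡ 1, which turns the
methylation influx C·DNMT1 into a known right-hand side and expresses all
other coefficients in units of that influx. Fitting is plain
`scipy.optimize.nnls` (affinities cannot be negative). Rows and states
are unweighted even though levels span orders of magnitude — a deliberate
fidelity choice with consequences discussed under limitations. Rank
deficiency triggers a `ConditioningWarning` rather than an
error. Residual norms below 1e−12 are reported as zero; cross-validation
indexes below 1e−12 are treated as exact ties so that on noiseless data
the generating structure outranks its supersets via the deterministic
(J_CV, canonical-code) sort.

Structure selection scores each of the 343 candidates by
leave-one-cell-line-out cross-validation. The per-fold design of a
sub-structure is the full-structure design with masked TET columns
removed, so the ranking assembles each fold's design once and
column-selects per structure; a full 343-structure ranking on five cell
lines takes well under a second. The resubstitution (training) MSE of a
fit is also reported but is optimistically biased and never used for
selection. Note that nesting guarantees monotonicity only for the NNLS
residual norm: the steady-state prediction MSE is nonlinear in the
parameters, so a sub-structure can occasionally beat the full structure
on training predictions.

## Synthetic data

The generator produces what the estimator assumes: enzyme profiles drawn
log-uniformly per enzyme within bounds bracketing the published
transcript ranges (e.g. TET3 ~1e−4…3e−2, TET2 ~4e−2…7.5e−1), resampled if
nearly collinear to keep the design identifiable, or optionally the five
packaged reference profiles verbatim; modification levels as exact
closed-form steady states under the ground-truth structure and
parameters; and multiplicative log-normal noise, exp(σZ) with
σ = √ln(1+CV²), which is unbiased in log space and has a factor CV equal
to the configured value (default 0.05). Defaults mirror the study design:
five cell lines, all six states observed.

The preset ground truth uses the best-supported participation pattern
(s1 = {TET1, TET2}, s2 = {TET1, TET3}, s3 = {TET2, TET3}) with
coefficients chosen once so that steady states on reference-like enzyme
levels reproduce the qualitative hierarchy of genomic nucleoside data —
mdC of order 10, hmdC ~100× lower, fdC and cadC ~10× lower again, with
small hmdU and dU. Concretely: k1 = 0.02 for both active TETs; k2 = 5
(TET1) and 50 (TET3); k3 = 10 (TET2) and 100 (TET3) — large TET3
coefficients offset its low transcript levels; k4 = 2, k5 = 5,
kAID = 0.5, kSMUG = 0.05, kTDG = 0.1, all on the kDNMT1 = 1 scale.

What the generator does *not* emulate: assay chemistry and detection
limits, transcript–protein discordance, time-course fluctuation of
expression, correlated measurement error, or oxidative-condition effects
on hmdU. Passing recovery tests therefore demonstrates correctness and
identifiability of the *pipeline under its own assumptions*, not that the
model is an adequate description of any particular cell line.

## Numerical choices

- Integrator: BDF with analytic (constant) Jacobian, rtol 1e−8,
  atol 1e−12; undershoots below 10×atol are clipped to zero.
  Steady-state detection: max |dx/dt| < 1e−10·(1+|x|).
- Long-horizon checks integrate to 40 slowest-timescale units
  (e^−40 ≈ 4e−18, far below the 1e−6 comparison tolerance).
- Stability flags use a relative tolerance of 1e−12 on eigenvalue real
  and imaginary parts.
- Ties in the ranking are broken by the canonical structure code
  (lexicographic ascending per-reaction bitmasks, TET1 = least
  significant bit; the full structure is index 342). Identical indexes do
  occur, so a stable rule is mandatory for reproducibility.
- Floats are serialized with %.17g and parsed with round-trip precision,
  so write→read→write is byte-identical.

## Scope of the simulation studies

The shipped studies are sized for a laptop-class single CPU: 1000 random
parameterisations for the stability sweep, 100 instances for the
closed-form-vs-ODE comparison, 200 tiny systems for the NNLS oracle
check, and 50 replicates for the structure-recovery study (each replicate
a full 343-structure ranking; the whole study runs in seconds).

## Known limitations

- **Weak identifiability of the third oxidation step.** J_CV is
  unweighted while mdC exceeds fdC/cadC by 2–3 orders of magnitude, so
  the index discriminates the mdC→hmdC assignment sharply, the hmdC→fdC
  assignment moderately, and the fdC→cadC assignment barely: structures
  differing only in s3 are near-tied. In the 50-replicate recovery study
  at 5 % noise the generating structure lands in the top 10 of 343 only
  about half the time (median rank 11–15 across seeds), with misses almost always
  within its own near-tied (s1, s2) group. At CV → 0 recovery is exact.
  Users who care about s3 should inspect the whole near-tie group, not
  just the argmin.
- Supersets of the generating structure can reach J_CV = 0 on noiseless
  data (extra coefficients fit to zero); no parsimony penalty is applied,
  only the deterministic code tie-break.
- The reported enzyme levels are transcripts; any systematic
  transcript–activity discordance maps directly into biased affinities.
- A fold whose fitted parameters leave a species without removal is
  scored with that species predicted as 0 and flagged; an alternative
  "disqualify the structure" policy is a documented possibility but not
  the default.
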