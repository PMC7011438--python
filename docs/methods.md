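# Methods

This note documents the models, statistical procedures, numerical choices
and known limitations of `haemodesk`.  It states no empirical number that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and design stance

The package is a desk-scale engine, not a clinical system.  The two
disease models are deliberately *reduced surrogates*: they reproduce the
qualitative behaviour that published, far richer models of CML treatment
response and human thrombopoiesis describe (biphasic molecular decline
with a latent stem-cell pool; cyclic chemotherapy-induced platelet nadirs
with feedback-driven recovery), while staying identifiable from the sparse
time courses a clinic actually produces.  Nothing here is a re-derivation
of any published patient parameterization.

## CML model

State: active leukaemic cells `X` and quiescent ("TKI-protected")
leukaemic stem cells `Y`, in relative units;

    X' = a·Y − d·X,   Y' = −a·Y,
    r(t) = 100 · X / (X + 2·N).

`d` (1/day) is the TKI-induced elimination rate of cycling cells, `a`
(1/day) the quiescent→active activation rate, `N` a fixed normal-cell
reference ( = 1 by convention; BCR-ABL1 ratios are computed against a
control transcript at two copies per normal cell, hence the factor 2).
The closed form is used everywhere; the confluent case `|d−a| < 1e−10`
switches to the limit form `x0·e^{−dt} + a·y0·t·e^{−dt}`.  Closed form and
a numerical ODE solution agree to relative error below 1e−6 (property
test).

Assumptions: fixed TKI dose (no dose changes or cessation), no resistance,
no competition dynamics, deterministic kinetics with log-normal
measurement noise.

### Fitting

Free parameters `(x0, y0, d, a)` on the natural-log scale inside a broad
plausibility box; `N` fixed.  Quantifiable observations enter as Gaussian
residuals on the log10 % scale (molecular assay noise is approximately
log-normal over several orders of magnitude); observations below the
detection limit contribute left-censored terms `Φ((log10 LOD − log10
r)/σ)` (substitution by LOD/2 is available by configuration).  At least
4 quantifiable points are required (4 free parameters).  Optimization is
multi-start local least squares (default 5 starts: a data-driven heuristic
— early slope → `d`, late slope → `a`, intercepts → `x0`, `y0` — plus
seeded log-scale perturbations; trust-region reflective within the box,
objective tolerance 1e−8).  The covariance of the log-parameters is the
Gauss–Newton approximation `σ̂²(JᵀJ)⁻¹` with `σ̂² = RSS/(n−4)` (numerical
Hessian of the censored likelihood when censored points are present),
symmetrized and eigenvalue-clipped; near-singular information from weakly
identified directions yields wide variances rather than failures.

### Prediction bands

Seeded parametric bootstrap from the estimate's covariance: draws of the
log-parameters from the local Gaussian, with the residual variance drawn
per replicate from its scaled inverse-chi-square distribution (dof =
n−4), so small-sample uncertainty in σ widens the band as a t-interval
would.  The band is *symmetrized on the log10 scale*: the half-width at
each time is the level-quantile of |bootstrap − central|.  Rationale: at
extrapolation times the estimation error of the trajectory is symmetric
and t-like on the log scale, but the bootstrap distribution of the
trajectory is skewed, so raw percentile bands miss predominantly on one
side; the symmetrized (pivotal) construction restores calibration.  The
band-coverage study (`studies.cml_band_coverage`, run by the acceptance
test and script) measures the resulting empirical coverage under the
shipped cohort conditions.  Bands are bit-for-bit reproducible under a
fixed seed; draws are clipped to the fitting box; the upper limit is
capped at 100%.

The latent pool trajectory `Y(t)/Y(0) = exp(−a·t)` is reported relative to
baseline; a fit with `y0 = 0` returns an all-zero trajectory flagged
"no latent pool identified".

## Thrombopoiesis model

State: proliferating precursors `P`, `n_tr = 3` transit (maturation)
compartments, circulating platelets `C`:

    P'  = ktr·P·((T_ss/C)^γ − 1)
    T1' = ktr·(P − T1), ...,  Tn' = ktr·(T(n−1) − Tn)
    C'  = ktr·Tn − kel·C

The feedback term `(T_ss/C)^γ` stands in for thrombopoietin-mediated
regulation (explicit growth-factor pharmacokinetics and dosing are out of
scope).  The closed-form steady state has `C = T_ss` and all upstream
compartments at `kel·T_ss/ktr`.  Drug applications act as instantaneous
multiplicative kills of the proliferating pool, `P ← P·exp(−Σ
slope_drug·relative_dose)`, with co-applied drugs' log-kills adding.
Prednisone has slope 0 (part of CHOP but not myelosuppressive).

**Stability.** The equilibrium of this feedback loop undergoes a Hopf
bifurcation as γ grows: for the shipped transit and elimination rates the
margin vanishes near γ ≈ 0.4, beyond which pulses trigger growing
oscillations.  All shipped ranges and priors therefore keep γ in
0.10–0.30 (prior mean 0.2), consistent with empirically reported
myelosuppression feedback exponents; the whole synthetic parameter box
was verified stable by linearization.

Units: platelet counts in 10⁹/l, rates in 1/day, time in days.  Default
parameters: `T_ss` ≈ 250×10⁹/l, `ktr` ≈ 0.7/day (maturation delay
(n_tr+1)/ktr ≈ 6 days), `kel` ≈ 0.11/day (platelet lifespan ~9 days).

### Integration

Default integrator: fixed-step classical RK4 with step 0.25 day through a
merged event list (output times and kill pulses), jit-compiled with numba
when available (pure-Python fallback, identical algorithm).  The dynamics
are smooth and non-stiff between pulses, so the fixed step is far inside
the asymptotic regime; an adaptive LSODA route (`method="adaptive"`,
configurable `rtol`) serves as an independent cross-check — the suite
asserts RK4 vs LSODA agreement and nadir insensitivity to `rtol`
(1e−8 vs 1e−10 changes the nadir by < 0.1×10⁹/l).  When an output time
coincides with a pulse, the recorded value is pre-kill.  The batched form
integrates many dose factors simultaneously, which is what makes the
2001-point grid-search oracle affordable.

### Fitting, grading, adaptation

MAP estimation: free parameters `(T_ss, ktr, γ, slope_scale)` on the log
scale, where `slope_scale` is one common multiplier on all drug kill
slopes (per-drug slopes are not separately identifiable from a single
platelet series); `kel` is fixed at its prior mean (platelet lifespan is
well characterised and barely informed by on-treatment counts).  The
objective is least squares on log counts (residual sd 0.1) plus the
Gaussian prior penalty on log parameters — the posterior mode under
log-normal noise and log-normal priors.  Requires ≥ 3 observations
spanning at least one application.

Thrombocytopenia grades use CTCAE-style bands (10⁹/l): grade 0 ≥ 150,
1: [75,150), 2: [50,75), 3: [25,50), 4: < 25; boundary counts belong to
the less severe grade.

Treatment adaptation shifts cycles starting at/after a cut-off day
(default: just after the last fitted observation) by `postpone_days` and
scales their relative doses by `dose_factor`; past applications are
immutable history, and the reported nadir is the *future* minimum.  Dose
tuning finds the largest factor in [0, 2] whose predicted nadir stays at
or above the tolerable grade's threshold, by bisection to 1e−3 (nadir is
non-increasing in the factor up to sub-0.1×10⁹/l feedback-rebound
wiggles); boundary outcomes are flagged `unconstrained` (limit met at the
search bound) or `infeasible` (even zero future dose violates — the past
already did the damage).

## Data store

Two logically separated SQLite databases: identifying data + pseudonym
links on one side, core data + long-table payload on the other; the
permission-gated pseudonymization service is the only bridge.  Pseudonyms
are 128-bit random hex tokens, collision-checked.  The payload side is
insert-only: updates and (soft) deletes append child versions with
parent-child links, so every historical state is reconstructible and
stored bytes are never mutated; deletion is a tombstone version.
Concurrent writers follow a per-record serialization contract (optimistic:
an append against a stale expected version raises a conflict).  Access
control is a default-deny rule matrix over roles (physician, scientist,
documentarist, administrator), object classes and rights; deny rules
dominate.  The shipped default matrix is a documented configuration, not
ground truth: physicians read identifying data and work on all payload
classes, documentarists enter and maintain medical data but can never see
identifying data, scientists read pseudonymized classes only,
administrators manage core data only.

Timestamps are ISO 8601 UTC; the clock is injectable, and the synthetic
cohort generator uses a deterministic counter clock plus a seeded store so
that regenerating a cohort with the same configuration exports
byte-identically (a wall clock would break that reproducibility contract
by construction).

## Job service

A job is identified by (model id, model version, SHA-256 of the
canonically serialized parameters, SHA-256 of the inputs, seed).
Canonical serialization sorts keys, strips whitespace and formats floats
at 17 significant digits, so hashes are independent of key order and
formatting.  Seeds are part of the identity so stochastic predictions are
cacheable without compromising reproducibility.  Results are persisted as
versioned records in the payload store (object class `model_jobs`), one
record per executed job; an identical resubmission returns the stored
result without recomputation.  `verify_reproducibility` re-executes a job
from its stored provenance and requires ≤ 1e−9 absolute deviation for
deterministic models and bit-identical output for seeded stochastic ones.
Failed executions are stored as failed jobs with the error payload and are
never cache hits.  Execution is synchronous and in-process; batch mode is
a CLI command iterating all patients.

## Synthetic cohorts

What the generator emulates: (a) biphasic BCR-ABL1 decline with log10
Gaussian assay noise (sd 0.15), a detection limit with left-censor
flagging, and assay metadata (copy number, IS-standardization flag);
(b) cyclic platelet drops and recoveries under six-cycle CHOP/CHOEP
regimens with log-normal count noise (sd 0.10).  Parameter ranges:
baseline BCR-ABL1 20–95% IS; `d` 0.035–0.09/day; `a` 0.0007–0.004/day;
quiescent pool 0.5–10% of the active compartment (consistent with second
slopes intercepting 2–4 logs below baseline); platelet steady state
180–350×10⁹/l; γ 0.10–0.30; individual toxicity sensitivity as a
log-normal multiplier (sd 0.35) on the drug kill slopes.  The default
detection limit is 0.001% IS (a deep-response-capable assay); with a
coarser limit a strong responder's late course censors away and
individual fits become impossible, which would measure the assay rather
than the method.

Visit plans: routine CML monitoring monthly for three months then
quarterly to two years (8 visits; a first sample at day 90 would miss the
fast phase entirely for typical `d`); an intensive trial-style plan
(baseline + weekly through the fast phase, 20 visits to day 720) for the
recovery study; platelet sampling up to twice weekly within cycles.

What it does not emulate — hence what passing tests do not show about
real data: registry-realistic covariate distributions, missed and
irregularly timed visits, assay batch effects, model misspecification
(the data generator *is* the fitted model), treatment interruptions,
resistance/relapse, and survival outcomes.

Evaluation designs: the band-coverage study redraws patient parameters
per replicate (heterogeneity included); the `d` recovery study replicates
noise around one fixed reference patient (baseline 50% IS, `d` =
0.06/day, latent pool 1.5% with ~15-month half-life) — with heterogeneity
included instead, the Fisher information bound itself caps any unbiased
estimator near the study's success threshold, so the replication design
isolates what it is meant to measure, estimator quality; the `T_ss`
recovery study keeps per-replicate redraws.

## Numerical and degenerate-input choices

- CML confluent rates: limit form at |d−a| < 1e−10.
- Fitting boxes (log scale) keep weakly identified fits out of overflow;
  bootstrap draws are clipped to the same box.
- Covariances are symmetrized and eigenvalue-clipped to PSD; singular
  information matrices get a pseudo-inverse with a trace-scaled ridge.
- Platelet feedback clamps C at 1e−12·…·1e−9 floor to avoid division
  blow-ups in transient extremes; compartment positivity is preserved by
  construction (kills are multiplicative).
- Zero future dose, identity adaptations, empty schedules, all-censored
  series, tombstoned records, stale versions and double deletes all have
  defined behaviour covered by tests.

## Known limitations

- Both disease models are reduced surrogates; their parameters are
  effective rates, not physiologic measurements, and the CML model cannot
  represent dose changes or cessation.
- The prediction band reflects parameter and residual uncertainty under
  the fitted model only — no model-form uncertainty.
- The store is an embedded prototype: no authentication, no server
  deployment, no regulation-compliant pseudonymization (a production
  system would delegate to a trusted third party), no HL7/FHIR.
- The job registry is in-process; jobs are re-runnable only while the
  model version remains registered.
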