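# haemodesk

Desk-scale, model-based clinical decision support for haematology.

`haemodesk` packages the moving parts of a hospital decision-support
prototype into one installable library: a pseudonymized, insert-only
versioned clinical data store; two individualizable mechanistic disease
models (BCR-ABL1 response of chronic myeloid leukaemia under tyrosine
kinase inhibitor therapy, and chemotherapy-perturbed thrombopoiesis for
aggressive non-Hodgkin lymphoma); a content-hash-cached, fully auditable
simulation-job service; and a seeded synthetic-cohort generator so that
every component is testable end to end without any clinical data.

It is aimed at researchers in systems medicine and medical informatics who
want to prototype, study, or teach the workflow *data capture →
patient-specific model fit → what-if treatment simulation → auditable
decision support* at the desk, with reproducibility guarantees strong
enough that any stored prediction can be re-derived bit for bit.

## The models

**CML under TKI therapy.** The leukaemic burden observable in blood is the
BCR-ABL1 transcript ratio on the international scale (IS).  A reduced
two-compartment activation model reproduces the characteristic biphasic
decline:

```
X'(t) = a·Y(t) − d·X(t)        active (TKI-exposed) leukaemic cells
Y'(t) = −a·Y(t)                quiescent, "TKI-protected" stem cells
r(t)  = 100·X / (X + 2·N)      observed BCR-ABL1 % (N = normal reference)
```

The TKI eliminates cycling cells at rate `d` (fast first slope); the
quiescent pool is recruited at rate `a` (slow second slope) and its
predicted decline `Y(t)/Y(0) = exp(−a·t)` — inaccessible in the clinic —
is exposed as the latent stem-cell trajectory.  Individual parameters
`(x0, y0, d, a)` are fitted by least squares on the log10 % scale, with
below-detection-limit measurements treated as left-censored; prediction
bands come from a seeded parametric bootstrap of the fit's covariance.

**Thrombopoiesis under cytotoxic chemotherapy.** A transit-compartment
model with power-law feedback: a proliferating precursor pool with
production `ktr·P·(T_ss/C)^γ`, three maturation compartments traversed at
rate `ktr`, and circulating platelets `C` cleared at rate `kel`.  Each
drug application multiplies the proliferating pool by
`exp(−slope·relative_dose)` (log-kill).  The shipped regimen library
covers CHOP-14/21 and CHOEP-14/21 (six cycles, four or five drugs).
Individual parameters are estimated by MAP fitting (least squares on log
counts plus a log-normal population prior), and the engine answers the
clinical what-ifs: postpone the next cycle, scale future doses, or solve —
by bisection — for the largest dose factor that keeps predicted
thrombocytopenia at a tolerable grade.

## Worked example

```
$ haemodesk --store demo gen-cohort --seed 3 --n-cml 1 --n-nhl 1
generated 1 CML + 1 NHL patients

$ haemodesk --store demo list --what pseudonyms
42fce8e27f95d7c8ec88eb34f13bc443
bdf0715fa6485e54639ffa61b941c7e0

$ haemodesk --store demo predict --pseudonym 42fce8e27f95d7c8ec88eb34f13bc443
{"job_id": "rec-e8d7f9903be553e0", "disease": "nhl", "cache_hit": false, "nadir_1e9_per_l": 183.8989596769662, "max_grade": 0}

$ haemodesk --store demo predict --pseudonym 42fce8e27f95d7c8ec88eb34f13bc443
{"job_id": "rec-e8d7f9903be553e0", "disease": "nhl", "cache_hit": true, "nadir_1e9_per_l": 183.8989596769662, "max_grade": 0}

$ haemodesk --store demo tune-dose --pseudonym 42fce8e27f95d7c8ec88eb34f13bc443 --grade 2
{"factor": 2.0, "flag": "unconstrained", "nadir_1e9_per_l": 137.55863248251148, "threshold_1e9_per_l": 50.0}

$ haemodesk --store demo predict --pseudonym bdf0715fa6485e54639ffa61b941c7e0
{"job_id": "rec-58403a9e5264798d", "disease": "cml", "cache_hit": false}
```

The first `predict` fits the lymphoma patient's platelet course and
simulates the remaining therapy: the predicted nadir is 184×10⁹/l —
grade 0, no predicted thrombocytopenia.  The second call returns the
stored result from the cache without recomputation (`cache_hit: true`) —
same job id, because a job is identified by model version, parameter
hash, input hash and seed.  `tune-dose` reports that even the maximal
searched dose factor (2.0) keeps this patient's predicted nadir
(137.6×10⁹/l; deeper than at factor 1) above the grade-2 threshold
(50×10⁹/l), so the dose constraint is inactive (`"unconstrained"`).  The
last call fits the CML patient's molecular course and stores the 95%
prediction band job.  `export-plot` writes a JSON
plot bundle (observations, band, therapy bars, grade bands / target
region, latent stem-cell series) validating against the schema shipped in
`src/haemodesk/data/plot_bundle_schema.json`.

Library use mirrors the CLI: `synth.gen_cohort` → `cml.fit_cml` /
`thrombo.fit_thrombo` → `cml.predict_cml` / `thrombo.predict_adapted` /
`thrombo.tune_dose_factor`, with `jobs.JobService` wrapping any model call
in a cached, auditable job.

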