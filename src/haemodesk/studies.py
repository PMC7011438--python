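"""Seeded simulation studies quantifying the system's statistical behaviour.

These studies are the package's own evaluation harness: band coverage and
parameter-recovery rates for the two disease models under the shipped
synthetic-cohort conditions, agreement of the dose-factor bisection with a
dense grid-search oracle, and randomized consistency checks of the
versioned store.  Both the test suite and the results-reproduction script
run them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cml, synth, thrombo
from .errors import ConflictError
from .store import Actor, ClinicalStore, ObservationRecord, counter_clock


# ---------------------------------------------------------------------------
# CML: prediction-band coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageResult:
    n_patients: int
    n_covered: int
    n_failed_fits: int
    level: float
    eval_day: float

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.n_covered / self.n_patients


def cml_band_coverage(
    n_patients: int = 500,
    seed: int = 0,
    level: float = 0.95,
    eval_day: float = 900.0,
    noise_sd: float = 0.15,
    visits=synth.DEFAULT_CML_VISITS,
    lod_pct: float = 0.001,
) -> CoverageResult:
    """Empirical pointwise coverage of the default prediction band.

    Patients are drawn from the shipped parameter ranges, observed at the
    default visit grid with log10 noise, refitted individually, and the
    band at ``eval_day`` is checked against the noise-free true trajectory.
    Failed or non-converged fits count as non-covered (they are part of the
    procedure being evaluated).
    """
    root = np.random.default_rng(seed)
    covered = failed = 0
    for _ in range(n_patients):
        params = synth.draw_cml_params(root)
        course_seed = int(root.integers(2**31))
        obs = synth.gen_cml_course(course_seed, params, visits, noise_sd, lod_pct)
        try:
            fitted = cml.fit_cml(obs, seed=course_seed)
        except Exception:
            failed += 1
            continue
        if not fitted.converged:
            failed += 1
            continue
        band = cml.predict_cml(
            fitted, eval_day, level=level, times=[eval_day], seed=course_seed + 1
        )
        truth = cml.simulate_cml(params, [eval_day])[0]
        if band.lower[0] <= truth <= band.upper[0]:
            covered += 1
    return CoverageResult(
        n_patients=n_patients,
        n_covered=covered,
        n_failed_fits=failed,
        level=level,
        eval_day=eval_day,
    )


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    parameter: str
    n_replicates: int
    n_within: int
    rel_tolerance: float
    rel_errors: list

    @property
    def success_pct(self) -> float:
        return 100.0 * self.n_within / self.n_replicates


#: Reference CML patient for the noise-replication recovery study: a
#: typical optimal responder — baseline burden 50% IS, fast-slope halving
#: time ~11.5 days (d = 0.06/day), quiescent pool 1.5% of the initial
#: burden with ~15-month half-life (a = 0.0015/day).
REFERENCE_CML_PATIENT = cml.CMLParams(
    x0=2.0, y0=0.03, d_tki=0.06, a_act=0.0015, n_ref=1.0
)


def cml_dtki_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    noise_sd: float = 0.15,
    n_obs: int = 20,
    span_days: float = 720.0,
    rel_tolerance: float = 0.10,
    true_params: cml.CMLParams = REFERENCE_CML_PATIENT,
) -> RecoveryResult:
    """Recovery of the TKI elimination rate from noisy courses.

    Noise-replication design: a fixed generating truth (the reference
    patient) observed on the intensive monitoring plan (``n_obs`` visits
    over ``span_days``), with fresh log10 noise per replicate; each
    replicate is refitted and the relative error of the recovered
    elimination rate recorded.  (Cross-patient heterogeneity is exercised
    separately by the band-coverage study, which redraws parameters per
    patient.)
    """
    root = np.random.default_rng(seed)
    visits = np.asarray(synth.INTENSIVE_CML_VISITS, dtype=float)
    assert len(visits) == n_obs and visits[-1] == span_days
    errors = []
    for _ in range(n_replicates):
        course_seed = int(root.integers(2**31))
        obs = synth.gen_cml_course(course_seed, true_params, visits, noise_sd, lod_pct=1e-6)
        try:
            fitted = cml.fit_cml(obs, seed=course_seed)
            errors.append(abs(fitted.params.d_tki - true_params.d_tki) / true_params.d_tki)
        except Exception:
            errors.append(np.inf)
    within = sum(e <= rel_tolerance for e in errors)
    return RecoveryResult("d_tki", n_replicates, within, rel_tolerance, errors)


def thrombo_tss_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    noise_sd: float = 0.10,
    n_obs: int = 12,
    regimen: str = "CHOP-21",
    rel_tolerance: float = 0.15,
) -> RecoveryResult:
    """Recovery of the steady-state platelet count under chemotherapy.

    ``n_obs`` counts per patient (two per cycle: at the cycle start and near
    the expected nadir), log-normal noise, MAP refit against the shipped
    population prior.
    """
    root = np.random.default_rng(seed)
    schedule = thrombo.build_regimen(regimen)
    per_cycle = max(n_obs // len(schedule.cycles), 1)
    offsets = (0.0, 7.0, 4.0, 11.0)[:per_cycle]
    errors = []
    for _ in range(n_replicates):
        params = synth.draw_thrombo_params(root)
        course_seed = int(root.integers(2**31))
        obs, _ = synth.gen_nhl_course(
            course_seed, regimen, params, obs_offsets=offsets, noise_sd=noise_sd
        )
        try:
            fitted = thrombo.fit_thrombo(obs, schedule, seed=course_seed)
            errors.append(abs(fitted.params.t_ss - params.t_ss) / params.t_ss)
        except Exception:
            errors.append(np.inf)
    within = sum(e <= rel_tolerance for e in errors)
    return RecoveryResult("t_ss", n_replicates, within, rel_tolerance, errors)


# ---------------------------------------------------------------------------
# dose-factor tuning vs grid oracle
# ---------------------------------------------------------------------------


@dataclass
class TuningOracleResult:
    n_cases: int
    n_agree: int
    grid_step: float
    max_steps_off: int

    @property
    def agreement_pct(self) -> float:
        return 100.0 * self.n_agree / self.n_cases


def tune_vs_grid_oracle(
    n_cases: int = 100,
    seed: int = 0,
    grid_points: int = 2001,
    f_max: float = 2.0,
    max_steps_off: int = 2,
) -> TuningOracleResult:
    """Bisection dose tuning against a dense grid-search oracle.

    Each case fits a randomized synthetic patient (observations through the
    first three cycles), tunes the dose factor for a random tolerable
    grade, and compares against the largest feasible factor on a uniform
    ``grid_points`` grid over [0, f_max].  Boundary cases (unconstrained /
    infeasible) must agree exactly with the oracle's boundary verdict.
    """
    root = np.random.default_rng(seed)
    grid = np.linspace(0.0, f_max, grid_points)
    step = grid[1] - grid[0]
    agree = 0
    for _ in range(n_cases):
        params = synth.draw_thrombo_params(root)
        regimen = ("CHOP-14", "CHOP-21", "CHOEP-14", "CHOEP-21")[int(root.integers(4))]
        schedule = thrombo.build_regimen(regimen)
        course_seed = int(root.integers(2**31))
        obs, _ = synth.gen_nhl_course(course_seed, regimen, params, noise_sd=0.10)
        obs = [o for o in obs if o.time <= schedule.cycles[2].start_day + 12]
        try:
            fitted = thrombo.fit_thrombo(obs, schedule, seed=course_seed)
        except Exception:
            continue
        grade = int(root.integers(0, 4))
        horizon = schedule.last_application_day() + 60.0
        result = thrombo.tune_dose_factor(
            fitted, schedule, tolerable_grade=grade, horizon_days=horizon, f_max=f_max
        )
        nadirs = thrombo.nadir_for_factors(
            fitted.params, schedule, grid, horizon, from_day=fitted.last_obs_day + 1e-9
        )
        feasible = np.nonzero(nadirs >= result.threshold)[0]
        if len(feasible) == 0:
            oracle_f = 0.0
            ok = result.flag == "infeasible"
        elif feasible[-1] == grid_points - 1:
            oracle_f = f_max
            ok = result.factor == f_max or abs(result.factor - f_max) <= max_steps_off * step
        else:
            oracle_f = grid[feasible[-1]]
            ok = abs(result.factor - oracle_f) <= max_steps_off * step + 1e-12
        agree += bool(ok)
    return TuningOracleResult(
        n_cases=n_cases, n_agree=agree, grid_step=float(step), max_steps_off=max_steps_off
    )


# ---------------------------------------------------------------------------
# store semantics fuzzing
# ---------------------------------------------------------------------------


@dataclass
class StoreFuzzResult:
    n_sequences: int
    n_consistent: int
    n_chain_violations: int

    @property
    def all_consistent(self) -> bool:
        return self.n_consistent == self.n_sequences and self.n_chain_violations == 0


def store_fuzz(n_sequences: int = 1000, seed: int = 0, ops_per_sequence: int = 12) -> StoreFuzzResult:
    """Randomized operation sequences against a brute-force oracle.

    For each sequence: random inserts/updates/deletes on a fresh in-memory
    store, then the current view is compared with a shadow full-scan oracle
    and every chain is checked for gapless parent-child structure.
    """
    root = np.random.default_rng(seed)
    doc = Actor("fuzz-doc", "documentarist")
    phys = Actor("fuzz-phys", "physician")
    consistent = 0
    chain_violations = 0
    for _ in range(n_sequences):
        store = ClinicalStore(seed=int(root.integers(2**31)), clock=counter_clock())
        synth.install_core_data(store)
        shadow: dict = {}
        ids: list = []
        for _ in range(int(root.integers(1, ops_per_sequence + 1))):
            op = ("insert", "update", "delete")[int(root.integers(3))]
            value = float(root.uniform(1, 500))
            if op == "insert" or not ids:
                rec = store.insert_record(doc, _leuko(value))
                ids.append(rec.record_id)
                shadow[rec.record_id] = [("insert", value)]
            else:
                rid = ids[int(root.integers(len(ids)))]
                tombstoned = shadow[rid][-1][0] == "delete"
                try:
                    if op == "update":
                        store.update_record(doc, rid, _leuko(value))
                        shadow[rid].append(("update", value))
                    else:
                        store.delete_record(phys, rid)
                        shadow[rid].append(("delete", None))
                    if tombstoned:
                        chain_violations += 1  # should have conflicted
                except ConflictError:
                    if not tombstoned:
                        chain_violations += 1

        expected = {
            rid: (len(vs), vs[-1][1]) for rid, vs in shadow.items() if vs[-1][0] != "delete"
        }
        got = {
            r.record_id: (r.version_seq, r.payload["value"])
            for r in store.get_current(phys)
        }
        if got == expected:
            consistent += 1
        for rid, vs in shadow.items():
            chain = store.get_history(phys, rid)
            if [c.version_seq for c in chain] != list(range(1, len(vs) + 1)):
                chain_violations += 1
            if chain[0].parent_version is not None or any(
                c.parent_version != c.version_seq - 1 for c in chain[1:]
            ):
                chain_violations += 1
        store.close()
    return StoreFuzzResult(
        n_sequences=n_sequences,
        n_consistent=consistent,
        n_chain_violations=chain_violations,
    )


def _leuko(value: float) -> ObservationRecord:
    return ObservationRecord(
        pseudonym="fuzz-p",
        screening_type="blood_count",
        parameter="leukocyte",
        value=value,
        unit="1e9_per_l",
        sample_time="t",
    )
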