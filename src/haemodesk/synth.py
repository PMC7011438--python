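"""Seeded synthetic-cohort generation.

No clinical data ships with (or is needed by) this package: the generator
produces artificial patient identities, biphasic BCR-ABL1 courses under TKI
therapy, and cyclic platelet courses under CHOP/CHOEP-like chemotherapy,
then pushes everything through the regular store operations so core-data
validation and versioning are exercised on the way in.  A fixed seed fully
determines the generated cohort, including pseudonyms and record ids, so a
regenerated store exports byte-identically.

The generator returns an *answer key* — the hidden true parameters per
patient — which the recovery tests use to check that the fitting routines
find the generating parameters back at realistic noise levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import cml, thrombo
from .errors import ValidationError
from .store import (
    Actor,
    ClinicalStore,
    CoreDataDef,
    ObservationRecord,
    PatientIdentity,
    TherapyEvent,
    counter_clock,
)

# ---------------------------------------------------------------------------
# fake identity vocabulary (no external faker dependency)
# ---------------------------------------------------------------------------

_GIVEN = [
    "Anna", "Ben", "Clara", "David", "Emma", "Felix", "Greta", "Henry",
    "Ida", "Jonas", "Katharina", "Lukas", "Marie", "Niklas", "Olivia",
    "Paul", "Quentin", "Rosa", "Simon", "Theresa", "Uwe", "Viktoria",
    "Wilhelm", "Xenia", "Yannick", "Zoe",
]
_FAMILY = [
    "Ahrens", "Bauer", "Conrad", "Dietrich", "Ebert", "Fischer", "Graf",
    "Hartmann", "Iversen", "Jung", "Keller", "Lang", "Maier", "Neumann",
    "Otte", "Peters", "Quandt", "Richter", "Schmidt", "Thalberg", "Ulrich",
    "Vogel", "Wagner", "Zimmermann",
]


def gen_identity(seed: int, birth_year_range: tuple = (1940, 1995)) -> PatientIdentity:
    """Deterministic plausible fake identity for a seed."""
    rng = np.random.default_rng(seed)
    year = int(rng.integers(birth_year_range[0], birth_year_range[1] + 1))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    return PatientIdentity(
        given_name=_GIVEN[int(rng.integers(len(_GIVEN)))],
        family_name=_FAMILY[int(rng.integers(len(_FAMILY)))],
        birth_date=f"{year:04d}-{month:02d}-{day:02d}",
        sex=["female", "male"][int(rng.integers(2))],
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: CML molecular monitoring: monthly during the steep initial decline, then
#: quarterly out to two years.
DEFAULT_CML_VISITS: tuple = (30.0, 60.0, 90.0, 180.0, 270.0, 360.0, 540.0, 720.0)

#: Intensive (trial-style) molecular sampling plan: baseline at diagnosis,
#: weekly through the fast elimination phase, biweekly through the
#: transition, sparse during the slow phase.  Used by the parameter-recovery
#: study; the baseline sample pins the initial burden and the dense early
#: points identify the fast slope.
INTENSIVE_CML_VISITS: tuple = (
    0.0, 7.0, 14.0, 21.0, 28.0, 35.0, 42.0, 49.0, 56.0, 70.0,
    84.0, 98.0, 112.0, 126.0, 140.0, 240.0, 360.0, 480.0, 600.0, 720.0,
)

#: Platelet sampling offsets within each chemotherapy cycle (days from the
#: cycle start): twice weekly through the nadir and recovery.
DEFAULT_NHL_OFFSETS: tuple = (0.0, 4.0, 7.0, 11.0)

#: Parameter ranges the cohort draws from.  CML: initial burden expressed
#: via the baseline BCR-ABL1 ratio; elimination and activation rates span
#: the clinically observed spread of fast and slow log-decline slopes.
DEFAULT_CML_RANGES: dict = {
    "r0_pct": (20.0, 95.0),  # baseline BCR-ABL1 %, uniform
    "y0_over_x0": (0.005, 0.1),  # quiescent pool relative to active, log-uniform
    "d_tki": (0.035, 0.09),  # 1/day, uniform
    "a_act": (0.0007, 0.004),  # 1/day, log-uniform
}

#: NHL: steady-state count within the normal platelet range, transit and
#: feedback parameters around the population prior, and a log-normal
#: individual toxicity-sensitivity multiplier on the drug kill slopes.
#: The feedback exponent range stays inside the stable region of the
#: linearized feedback loop (instability sets in near 0.4 at these rates).
DEFAULT_NHL_RANGES: dict = {
    "t_ss": (180.0, 350.0),  # 1e9/l, log-uniform
    "ktr": (0.5, 1.0),  # 1/day, log-uniform
    "gamma": (0.10, 0.30),  # log-uniform
    "kel": (0.09, 0.13),  # 1/day, log-uniform
    "slope_scale_sd": 0.35,  # sd of log slope multiplier, centred at 1
}


@dataclass(frozen=True)
class CohortConfig:
    seed: int = 0
    n_cml: int = 5
    n_nhl: int = 5
    cml_noise_sd: float = 0.15  # log10 scale
    nhl_noise_sd: float = 0.10  # natural log scale
    lod_pct: float = 0.001
    cml_visits: tuple = DEFAULT_CML_VISITS
    nhl_offsets: tuple = DEFAULT_NHL_OFFSETS
    cml_ranges: dict = field(default_factory=lambda: dict(DEFAULT_CML_RANGES))
    nhl_ranges: dict = field(default_factory=lambda: dict(DEFAULT_NHL_RANGES))
    regimens: tuple = ("CHOP-14", "CHOP-21", "CHOEP-14", "CHOEP-21")


# ---------------------------------------------------------------------------
# parameter draws
# ---------------------------------------------------------------------------


def draw_cml_params(rng: np.random.Generator, ranges: Optional[dict] = None, n_ref: float = 1.0) -> cml.CMLParams:
    r = {**DEFAULT_CML_RANGES, **(ranges or {})}
    r0 = rng.uniform(*r["r0_pct"])
    x0 = 2.0 * n_ref * r0 / (100.0 - r0)
    ratio = np.exp(rng.uniform(*np.log(r["y0_over_x0"])))
    d = rng.uniform(*r["d_tki"])
    a = np.exp(rng.uniform(*np.log(r["a_act"])))
    return cml.CMLParams(x0=x0, y0=x0 * ratio, d_tki=d, a_act=min(a, 0.9 * d), n_ref=n_ref)


def draw_thrombo_params(rng: np.random.Generator, ranges: Optional[dict] = None) -> thrombo.ThromboParams:
    r = {**DEFAULT_NHL_RANGES, **(ranges or {})}
    scale = float(np.exp(rng.normal(0.0, r["slope_scale_sd"])))
    return thrombo.ThromboParams(
        t_ss=float(np.exp(rng.uniform(*np.log(r["t_ss"])))),
        ktr=float(np.exp(rng.uniform(*np.log(r["ktr"])))),
        gamma=float(np.exp(rng.uniform(*np.log(r["gamma"])))),
        kel=float(np.exp(rng.uniform(*np.log(r["kel"])))),
        drug_slopes={d: s * scale for d, s in thrombo.DEFAULT_DRUG_SLOPES.items()},
    )


# ---------------------------------------------------------------------------
# course generators
# ---------------------------------------------------------------------------


def gen_cml_course(
    seed: int,
    true_params: cml.CMLParams,
    visit_times: Sequence[float] = DEFAULT_CML_VISITS,
    noise_sd: float = 0.15,
    lod_pct: float = 0.001,
) -> list[cml.MolecularObservation]:
    """Noisy molecular course: log10 of the model trajectory plus Gaussian
    noise, left-censored at the detection limit."""
    visit_times = np.asarray(visit_times, dtype=float)
    if np.any(np.diff(visit_times) < 0):
        raise ValidationError("visit times must be non-decreasing")
    rng = np.random.default_rng(seed)
    truth = cml.simulate_cml(true_params, visit_times)
    log_obs = np.log10(truth) + rng.normal(0.0, noise_sd, size=len(visit_times))
    observed = np.minimum(10.0**log_obs, 100.0)
    out = []
    for t, v in zip(visit_times, observed):
        below = bool(v < lod_pct)
        out.append(
            cml.MolecularObservation(
                time=float(t),
                bcr_abl_pct=float(lod_pct if below else v),
                below_lod=below,
                lod_pct=float(lod_pct),
                metadata={
                    "is_standardized": True,
                    "copy_number": int(rng.integers(20000, 80000)),
                },
            )
        )
    return out


def gen_nhl_course(
    seed: int,
    regimen_label: str,
    true_params: thrombo.ThromboParams,
    obs_offsets: Sequence[float] = DEFAULT_NHL_OFFSETS,
    noise_sd: float = 0.10,
    n_cycles: Optional[int] = None,
) -> tuple[list[thrombo.PlateletObservation], thrombo.TherapySchedule]:
    """Noisy platelet course under a library regimen: model trajectory times
    log-normal noise, sampled on the per-cycle offset plan."""
    schedule = thrombo.build_regimen(regimen_label, n_cycles=n_cycles)
    times = np.array(
        sorted(c.start_day + off for c in schedule.cycles for off in obs_offsets)
    )
    rng = np.random.default_rng(seed)
    truth = thrombo.simulate_platelets(true_params, schedule, times)
    counts = truth * np.exp(rng.normal(0.0, noise_sd, size=len(times)))
    obs = [
        thrombo.PlateletObservation(time=float(t), count=float(c))
        for t, c in zip(times, counts)
    ]
    return obs, schedule


# ---------------------------------------------------------------------------
# core data + store population
# ---------------------------------------------------------------------------

CORE_DEFS: list[CoreDataDef] = (
    [
        CoreDataDef("unit", "pct_is", "% (international scale)"),
        CoreDataDef("unit", "1e9_per_l", "10^9/l"),
        CoreDataDef("unit", "mg_per_m2", "mg/m^2"),
        CoreDataDef("unit", "rel_dose", "relative dose (1 = protocol dose)"),
        CoreDataDef("screening_type", "molecular", "molecular diagnostics"),
        CoreDataDef("screening_type", "blood_count", "blood count"),
        CoreDataDef("parameter", "BCR-ABL1", "BCR-ABL1 transcript level", ("pct_is",)),
        CoreDataDef("parameter", "platelets", "platelet count", ("1e9_per_l",)),
        CoreDataDef("parameter", "leukocyte", "leukocyte count", ("1e9_per_l",)),
        CoreDataDef("hospital", "uk-a", "University Hospital A"),
        CoreDataDef("hospital", "uk-b", "University Hospital B"),
    ]
    + [
        CoreDataDef("drug", code, label)
        for code, label in [
            ("imatinib", "imatinib (TKI)"),
            ("nilotinib", "nilotinib (TKI)"),
            ("cyclophosphamide", "cyclophosphamide"),
            ("doxorubicin", "doxorubicin"),
            ("vincristine", "vincristine"),
            ("prednisone", "prednisone"),
            ("etoposide", "etoposide"),
        ]
    ]
)


def install_core_data(store: ClinicalStore, actor: Optional[Actor] = None) -> None:
    """Define the shipped core-data vocabulary (idempotent)."""
    actor = actor or Actor("setup", "administrator")
    have = {(d.kind, d.code) for d in store.list_core()}
    for d in CORE_DEFS:
        if (d.kind, d.code) not in have:
            store.define_core(actor, d)


@dataclass
class CohortAnswerKey:
    """Hidden truth per generated patient."""

    cml: dict  # pseudonym -> {"params": CMLParams, "seed": int}
    nhl: dict  # pseudonym -> {"params": ThromboParams, "regimen": str, "seed": int}


def gen_cohort(config: CohortConfig, store: Optional[ClinicalStore] = None) -> tuple[ClinicalStore, CohortAnswerKey]:
    """Populate a store with a fully synthetic cohort.

    Identities go through ``register_patient``, observations and therapy
    events through ``insert_record``, so the generated data must pass the
    same validation and leaves the same audit chains as manually entered
    data.  With the same config (and a store seeded from it) the exported
    payload is byte-identical across runs.
    """
    if store is None:
        store = ClinicalStore(seed=config.seed, clock=counter_clock())
    registrar = Actor("synth-registrar", "physician")
    documentarist = Actor("synth-documentarist", "documentarist")
    install_core_data(store)

    missing = [
        (d.kind, d.code)
        for d in CORE_DEFS
        if not store.list_core(d.kind) or d.code not in {x.code for x in store.list_core(d.kind)}
    ]
    if missing:
        raise ValidationError(f"core data missing after install: {missing}")

    root = np.random.default_rng(config.seed)
    key = CohortAnswerKey(cml={}, nhl={})

    for i in range(config.n_cml):
        params = draw_cml_params(root, config.cml_ranges)
        course_seed = int(root.integers(2**31))
        pseudonym = store.register_patient(registrar, gen_identity(int(root.integers(2**31))))
        course = gen_cml_course(
            course_seed, params, config.cml_visits, config.cml_noise_sd, config.lod_pct
        )
        for obs in course:
            store.insert_record(
                documentarist,
                ObservationRecord(
                    pseudonym=pseudonym,
                    screening_type="molecular",
                    parameter="BCR-ABL1",
                    value=obs.bcr_abl_pct,
                    unit="pct_is",
                    sample_time=f"day+{obs.time:07.1f}",
                    status="below_lod" if obs.below_lod else "quantified",
                    metadata={**obs.metadata, "lod_pct": obs.lod_pct, "time_days": obs.time},
                ),
            )
        store.insert_record(
            documentarist,
            TherapyEvent(
                pseudonym=pseudonym,
                drug="imatinib",
                dose_value=1.0,
                dose_unit="rel_dose",
                application_time="day+00000.0",
                regimen_label="TKI continuous",
                cycle_index=1,
            ),
        )
        key.cml[pseudonym] = {"params": params, "seed": course_seed}

    for i in range(config.n_nhl):
        params = draw_thrombo_params(root, config.nhl_ranges)
        regimen = config.regimens[int(root.integers(len(config.regimens)))]
        course_seed = int(root.integers(2**31))
        pseudonym = store.register_patient(registrar, gen_identity(int(root.integers(2**31))))
        course, schedule = gen_nhl_course(
            course_seed, regimen, params, config.nhl_offsets, config.nhl_noise_sd
        )
        for obs in course:
            store.insert_record(
                documentarist,
                ObservationRecord(
                    pseudonym=pseudonym,
                    screening_type="blood_count",
                    parameter="platelets",
                    value=obs.count,
                    unit="1e9_per_l",
                    sample_time=f"day+{obs.time:07.1f}",
                    status="quantified",
                    metadata={"time_days": obs.time},
                ),
            )
        for ci, cyc in enumerate(schedule.cycles, start=1):
            for app in cyc.applications:
                store.insert_record(
                    documentarist,
                    TherapyEvent(
                        pseudonym=pseudonym,
                        drug=app.drug,
                        dose_value=app.relative_dose,
                        dose_unit="rel_dose",
                        application_time=f"day+{cyc.start_day + app.day_offset:07.1f}",
                        regimen_label=regimen,
                        cycle_index=ci,
                    ),
                )
        key.nhl[pseudonym] = {"params": params, "regimen": regimen, "seed": course_seed}

    return store, key
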