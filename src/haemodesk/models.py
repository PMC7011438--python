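"""Built-in simulation models wired into the job service.

Each executor is a pure function ``(params, inputs, seed) -> output series``
operating on JSON-able structures only, so that job provenance (parameters,
inputs, seed) fully determines the stored result.

Registered models:

``cml-biphasic:1``
    Deterministic BCR-ABL1 % trajectory of the two-compartment TKI model.
``cml-band:1``
    Individual fit to a molecular time course plus seeded parametric
    bootstrap prediction band and latent stem-cell trajectory (stochastic:
    bit-identical under a fixed seed).
``thrombo-transit:1``
    Deterministic platelet trajectory of the transit-compartment model
    under a therapy schedule.
``thrombo-adapt:1``
    Fit to a platelet course, then prediction under a treatment adaptation
    (postponement / dose factor), with nadir and worst grade.
"""

from __future__ import annotations

import numpy as np

from . import cml, thrombo
from .jobs import JobService, ModelDescriptor, ParamSpec
from .store import Actor


def _exec_cml_simulate(params: dict, inputs: dict, seed: int) -> dict:
    p = cml.CMLParams.from_dict(params["cml_params"])
    times = np.asarray(inputs["times_days"], dtype=float)
    return {
        "times_days": times.tolist(),
        "bcr_abl_pct": cml.simulate_cml(p, times).tolist(),
    }


def _exec_cml_band(params: dict, inputs: dict, seed: int) -> dict:
    obs = [
        cml.MolecularObservation(
            time=float(o["time_days"]),
            bcr_abl_pct=float(o.get("bcr_abl_pct") or 0.5),
            below_lod=bool(o.get("below_lod", False)),
            lod_pct=(float(o["lod_pct"]) if o.get("lod_pct") is not None else None),
        )
        for o in inputs["observations"]
    ]
    fitted = cml.fit_cml(
        obs,
        n_ref=float(params.get("n_ref", 1.0)),
        censoring=params.get("censoring", "likelihood"),
        seed=seed,
    )
    band = cml.predict_cml(
        fitted,
        horizon_days=float(params["horizon_days"]),
        level=float(params.get("level", 0.95)),
        n_boot=int(params.get("n_boot", 1000)),
        seed=seed,
    )
    lsc = cml.predict_lsc(fitted, horizon_days=float(params["horizon_days"]))
    return {"fit": fitted.to_json(), "band": band.to_json(), "lsc": lsc.to_json()}


def _exec_thrombo_simulate(params: dict, inputs: dict, seed: int) -> dict:
    p = thrombo.ThromboParams.from_dict(params["thrombo_params"])
    schedule = thrombo.TherapySchedule.from_json(inputs["schedule"])
    times = np.asarray(inputs["times_days"], dtype=float)
    return {
        "times_days": times.tolist(),
        "platelets_1e9_per_l": thrombo.simulate_platelets(p, schedule, times).tolist(),
    }


def _exec_thrombo_adapt(params: dict, inputs: dict, seed: int) -> dict:
    schedule = thrombo.TherapySchedule.from_json(inputs["schedule"])
    obs = [
        thrombo.PlateletObservation(time=float(o["time_days"]), count=float(o["count"]))
        for o in inputs["observations"]
    ]
    fitted = thrombo.fit_thrombo(obs, schedule, seed=seed)
    adaptation = thrombo.AdaptationQuery(
        postpone_days=int(params.get("postpone_days", 0)),
        dose_factor=float(params.get("dose_factor", 1.0)),
        horizon_days=float(params["horizon_days"]),
        tolerable_grade=int(params.get("tolerable_grade", 3)),
    )
    pred = thrombo.predict_adapted(fitted, schedule, adaptation)
    out = {"fit": fitted.to_json(), "prediction": pred.to_json()}
    if params.get("tune_dose", False):
        tuned = thrombo.tune_dose_factor(
            fitted,
            schedule,
            tolerable_grade=adaptation.tolerable_grade,
            horizon_days=adaptation.horizon_days,
        )
        out["tuned_dose"] = {
            "factor": tuned.factor,
            "flag": tuned.flag,
            "nadir_1e9_per_l": tuned.nadir,
            "threshold_1e9_per_l": tuned.threshold,
        }
    return out


BUILTIN_MODELS = [
    (
        ModelDescriptor(
            model_id="cml-biphasic",
            version="1",
            param_schema=(ParamSpec("cml_params", type="object"),),
            input_schema=("times_days",),
            stochastic=False,
        ),
        _exec_cml_simulate,
    ),
    (
        ModelDescriptor(
            model_id="cml-band",
            version="1",
            param_schema=(
                ParamSpec("horizon_days", minimum=1.0),
                ParamSpec("level", minimum=0.0, maximum=1.0, required=False),
                ParamSpec("n_boot", type="integer", minimum=10, required=False),
                ParamSpec("n_ref", minimum=0.0, required=False),
                ParamSpec("censoring", type="string", required=False),
            ),
            input_schema=("observations",),
            stochastic=True,
        ),
        _exec_cml_band,
    ),
    (
        ModelDescriptor(
            model_id="thrombo-transit",
            version="1",
            param_schema=(ParamSpec("thrombo_params", type="object"),),
            input_schema=("schedule", "times_days"),
            stochastic=False,
        ),
        _exec_thrombo_simulate,
    ),
    (
        ModelDescriptor(
            model_id="thrombo-adapt",
            version="1",
            param_schema=(
                ParamSpec("horizon_days", minimum=1.0),
                ParamSpec("postpone_days", type="integer", minimum=0, required=False),
                ParamSpec("dose_factor", minimum=0.0, required=False),
                ParamSpec("tolerable_grade", type="integer", minimum=0, maximum=4, required=False),
                ParamSpec("tune_dose", type="integer", required=False),
            ),
            input_schema=("schedule", "observations"),
            stochastic=False,
        ),
        _exec_thrombo_adapt,
    ),
]


def register_builtin_models(service: JobService, actor: Actor) -> None:
    """Register the shipped disease models with a job service."""
    for descriptor, executor in BUILTIN_MODELS:
        service.register_model(actor, descriptor, executor)
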