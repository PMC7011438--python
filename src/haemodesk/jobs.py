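"""Model registry and reproducible simulation-job service.

Every simulation request is identified by the registered model id/version,
a content hash of its parameters, a content hash of its input series, and
the random seed.  Before executing, the service looks the identity up in
the payload store; if an identical finished job exists its stored result is
returned without recomputation (a cache hit).  Results are persisted as
versioned records, so the complete provenance — model version, parameters,
inputs, seed, solver settings — stays in the audit chain and any job can be
re-executed and checked bit-for-bit later.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .access import ObjectClass, Right
from .errors import ConflictError, IntegrityError, NotFoundError, ValidationError
from .store import Actor, ClinicalStore, VersionedRecord

# ---------------------------------------------------------------------------
# canonical serialization and hashing
# ---------------------------------------------------------------------------


def _canonical(obj):
    """Normalize to JSON-able structures with fixed float formatting."""
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, bool) or obj is None or isinstance(obj, (int, str)):
        return obj
    if isinstance(obj, float):
        if math.isnan(obj) or math.isinf(obj):
            raise ValidationError("non-finite floats cannot be canonically hashed")
        return float(obj)
    if hasattr(obj, "tolist"):  # numpy scalars/arrays
        return _canonical(obj.tolist())
    raise ValidationError(f"cannot canonically serialize {type(obj).__name__}")


def canonical_json(obj) -> str:
    """Deterministic serialization: sorted keys, no whitespace, floats at 17
    significant digits.  Key order and formatting of the caller's data do
    not affect the output."""
    def fmt(o):
        if isinstance(o, float):
            return float(f"{o:.17g}")
        if isinstance(o, dict):
            return {k: fmt(v) for k, v in o.items()}
        if isinstance(o, list):
            return [fmt(v) for v in o]
        return o

    return json.dumps(fmt(_canonical(obj)), sort_keys=True, separators=(",", ":"))


def content_hash(obj) -> str:
    return hashlib.sha256(canonical_json(obj).encode()).hexdigest()


# ---------------------------------------------------------------------------
# descriptors and jobs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamSpec:
    name: str
    type: str = "number"  # number | integer | string | object
    minimum: Optional[float] = None
    maximum: Optional[float] = None
    required: bool = True


@dataclass(frozen=True)
class ModelDescriptor:
    """A registered, versioned simulation model."""

    model_id: str
    version: str
    param_schema: tuple = ()
    input_schema: tuple = ()  # names of expected input series
    stochastic: bool = False  # seeded stochastic models must reproduce bit-identically

    def __post_init__(self):
        object.__setattr__(self, "param_schema", tuple(self.param_schema))
        object.__setattr__(self, "input_schema", tuple(self.input_schema))

    def validate_params(self, params: dict) -> None:
        known = {p.name for p in self.param_schema}
        for p in self.param_schema:
            if p.required and p.name not in params:
                raise ValidationError(f"missing required parameter {p.name!r}")
        for name, value in params.items():
            if name not in known:
                raise ValidationError(f"unknown parameter {name!r} for {self.model_id}:{self.version}")
            spec = next(p for p in self.param_schema if p.name == name)
            if spec.type == "number" and not isinstance(value, (int, float)):
                raise ValidationError(f"parameter {name!r} must be a number")
            if spec.type == "integer" and not isinstance(value, int):
                raise ValidationError(f"parameter {name!r} must be an integer")
            if spec.type == "string" and not isinstance(value, str):
                raise ValidationError(f"parameter {name!r} must be a string")
            if spec.type == "object" and not isinstance(value, dict):
                raise ValidationError(f"parameter {name!r} must be an object")
            if spec.minimum is not None and isinstance(value, (int, float)) and value < spec.minimum:
                raise ValidationError(f"parameter {name!r} below minimum {spec.minimum}")
            if spec.maximum is not None and isinstance(value, (int, float)) and value > spec.maximum:
                raise ValidationError(f"parameter {name!r} above maximum {spec.maximum}")

    def validate_inputs(self, inputs: dict) -> None:
        for name in self.input_schema:
            if name not in inputs:
                raise ValidationError(f"missing required input series {name!r}")


@dataclass
class ModelJob:
    """Provenance record of one simulation request."""

    job_id: str
    model_id: str
    version: str
    param_hash: str
    input_hash: str
    seed: int
    status: str  # done | failed
    cache_hit: bool
    created_by: str
    created_at: str
    pseudonym: Optional[str] = None
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    result: Optional[dict] = None
    error: Optional[str] = None


Executor = Callable[[dict, dict, int], dict]


class JobService:
    """Synchronous in-process execution with content-hash caching.

    Jobs and their results live in the payload store under the
    ``model_jobs`` object class, one versioned record per job, so the same
    audit-trail guarantees apply to simulations as to medical data.
    """

    def __init__(self, store: ClinicalStore) -> None:
        self.store = store
        self._descriptors: dict[tuple[str, str], ModelDescriptor] = {}
        self._executors: dict[tuple[str, str], Executor] = {}

    # -- registry -----------------------------------------------------------

    def register_model(
        self, actor: Actor, descriptor: ModelDescriptor, executor: Executor
    ) -> ModelDescriptor:
        self.store.policy.require(actor.role, ObjectClass.MODEL_JOBS, Right.CREATE, "register_model")
        key = (descriptor.model_id, descriptor.version)
        if key in self._descriptors:
            raise ConflictError(f"model {key[0]}:{key[1]} already registered")
        self._descriptors[key] = descriptor
        self._executors[key] = executor
        return descriptor

    def descriptor(self, model_id: str, version: str) -> ModelDescriptor:
        try:
            return self._descriptors[(model_id, version)]
        except KeyError:
            raise NotFoundError(f"model {model_id}:{version} is not registered") from None

    # -- submission ---------------------------------------------------------

    def submit_job(
        self,
        actor: Actor,
        model_id: str,
        version: str,
        params: dict,
        inputs: Optional[dict] = None,
        seed: int = 0,
        pseudonym: Optional[str] = None,
    ) -> ModelJob:
        inputs = inputs or {}
        desc = self.descriptor(model_id, version)
        desc.validate_params(params)
        desc.validate_inputs(inputs)
        self.store.policy.require(actor.role, ObjectClass.MODEL_JOBS, Right.CREATE, "submit_job")

        param_hash = content_hash(params)
        input_hash = content_hash(inputs)

        cached = self._find_done(model_id, version, param_hash, input_hash, seed)
        if cached is not None:
            job = self._record_to_job(cached)
            job.cache_hit = True
            return job

        try:
            result = self._executors[(model_id, version)](dict(params), dict(inputs), seed)
            result = json.loads(canonical_json(result))
            status, error = "done", None
        except Exception as exc:  # stored as a failed job, queryable later
            result, status, error = None, "failed", f"{type(exc).__name__}: {exc}"

        payload = {
            "object_class": ObjectClass.MODEL_JOBS.value,
            "type": "model_job",
            "model_id": model_id,
            "model_version": version,
            "param_hash": param_hash,
            "input_hash": input_hash,
            "seed": seed,
            "status": status,
            "pseudonym": pseudonym,
            "params": json.loads(canonical_json(params)),
            "inputs": json.loads(canonical_json(inputs)),
            "result": result,
            "error": error,
            "provenance": {
                "model_id": model_id,
                "model_version": version,
                "seed": seed,
                "stochastic": desc.stochastic,
            },
        }
        rec = self.store.insert_record(actor, payload)
        job = self._record_to_job(rec)
        job.cache_hit = False
        return job

    # -- queries ------------------------------------------------------------

    def _job_records(self) -> list[VersionedRecord]:
        # internal scan; permission enforced by public callers
        recs = self.store.get_current(
            Actor("job-service", "physician"), object_class=ObjectClass.MODEL_JOBS
        )
        return [r for r in recs if r.payload.get("type") == "model_job"]

    def _find_done(self, model_id, version, param_hash, input_hash, seed):
        for rec in self._job_records():
            p = rec.payload
            if (
                p.get("model_id") == model_id
                and p.get("model_version") == version
                and p.get("param_hash") == param_hash
                and p.get("input_hash") == input_hash
                and p.get("seed") == seed
                and p.get("status") == "done"
            ):
                return rec
        return None

    @staticmethod
    def _record_to_job(rec: VersionedRecord) -> ModelJob:
        p = rec.payload
        return ModelJob(
            job_id=rec.record_id,
            model_id=p["model_id"],
            version=p["model_version"],
            param_hash=p["param_hash"],
            input_hash=p["input_hash"],
            seed=p["seed"],
            status=p["status"],
            cache_hit=False,
            created_by=rec.actor,
            created_at=rec.wall_time,
            pseudonym=p.get("pseudonym"),
            params=p.get("params", {}),
            inputs=p.get("inputs", {}),
            result=p.get("result"),
            error=p.get("error"),
        )

    def get_job(self, actor: Actor, job_id: str) -> ModelJob:
        self.store.policy.require(actor.role, ObjectClass.MODEL_JOBS, Right.READ, "get_job")
        chain = self.store.get_history(actor, job_id)
        head = chain[-1]
        if head.payload.get("type") != "model_job":
            raise NotFoundError(f"record {job_id} is not a model job")
        return self._record_to_job(head)

    def list_jobs(self, actor: Actor, pseudonym: Optional[str] = None) -> list[ModelJob]:
        self.store.policy.require(actor.role, ObjectClass.MODEL_JOBS, Right.READ, "list_jobs")
        jobs = [self._record_to_job(r) for r in self._job_records()]
        if pseudonym is not None:
            jobs = [j for j in jobs if j.pseudonym == pseudonym]
        return sorted(jobs, key=lambda j: j.created_at, reverse=True)

    # -- reproducibility ----------------------------------------------------

    def verify_reproducibility(self, job_id: str, atol: float = 1e-9) -> dict:
        """Re-execute a done job from its stored provenance and compare.

        Deterministic models must agree within ``atol`` absolute deviation;
        seeded stochastic models must reproduce bit-identically (their seed
        is part of the job identity).
        """
        actor = Actor("verifier", "physician")
        job = self.get_job(actor, job_id)
        if job.status != "done" or job.result is None:
            raise IntegrityError(f"job {job_id} has no stored result to verify")
        key = (job.model_id, job.version)
        if key not in self._executors:
            raise IntegrityError(f"model {key[0]}:{key[1]} is no longer registered")
        desc = self._descriptors[key]
        fresh = json.loads(canonical_json(self._executors[key](dict(job.params), dict(job.inputs), job.seed)))
        bit_identical = canonical_json(fresh) == canonical_json(job.result)
        max_dev = _max_abs_deviation(fresh, job.result)
        if desc.stochastic:
            passed = bit_identical
        else:
            passed = max_dev is not None and max_dev <= atol
        return {
            "job_id": job_id,
            "model": f"{job.model_id}:{job.version}",
            "stochastic": desc.stochastic,
            "bit_identical": bit_identical,
            "max_abs_deviation": max_dev,
            "tolerance": atol,
            "passed": passed,
        }


def _max_abs_deviation(a, b):
    """Max |a-b| over all aligned numeric leaves; None if structures differ."""
    if isinstance(a, dict) and isinstance(b, dict):
        if set(a) != set(b):
            return None
        devs = [_max_abs_deviation(a[k], b[k]) for k in a]
        return None if any(d is None for d in devs) else max(devs, default=0.0)
    if isinstance(a, list) and isinstance(b, list):
        if len(a) != len(b):
            return None
        devs = [_max_abs_deviation(x, y) for x, y in zip(a, b)]
        return None if any(d is None for d in devs) else max(devs, default=0.0)
    if isinstance(a, (int, float)) and isinstance(b, (int, float)) and not isinstance(a, bool) and not isinstance(b, bool):
        return abs(float(a) - float(b))
    return 0.0 if a == b else None
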