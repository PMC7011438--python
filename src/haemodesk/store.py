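"""Pseudonymized, versioned clinical data store.

Two logically separated embedded SQLite databases back the store: one holds
patient *identifying* data (names, birth dates) plus the pseudonym link
table, the other holds the *payload* — core-data definitions and medical
records in "long table" form, where the kind of datum travels in columns
next to the value so new measurement types need no schema change.

The payload side is *insert-only*: every ``insert``, ``update`` or ``delete``
action appends a new version row carrying parent-child information, so that
any historical state can be reconstructed and no stored byte is ever
mutated.  Deletion is a tombstone child version.

The pseudonymization service (:meth:`ClinicalStore.resolve_pseudonym`) is
the only component that bridges the two databases, and it is permission
gated; no payload query ever returns identity fields.
"""

from __future__ import annotations

import json
import random
import secrets
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Optional, Union

from .access import AccessPolicy, ObjectClass, Right, Role, default_policy
from .errors import AccessError, ConflictError, NotFoundError, ValidationError

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

CORE_KINDS = ("screening_type", "parameter", "unit", "drug", "hospital")


@dataclass(frozen=True)
class Actor:
    """Acting user: an opaque user id plus a role used for access checks."""

    user_id: str
    role: Role

    def __post_init__(self):
        object.__setattr__(self, "role", Role(self.role))


@dataclass(frozen=True)
class PatientIdentity:
    given_name: str
    family_name: str
    birth_date: str  # ISO calendar date
    sex: str
    identity_id: Optional[str] = None


@dataclass(frozen=True)
class CoreDataDef:
    """Master-data definition: a coded object such as a drug, a measurement
    unit, a diagnostic parameter or a screening type."""

    kind: str
    code: str
    label: str = ""
    allowed_units: tuple = ()

    def __post_init__(self):
        if self.kind not in CORE_KINDS:
            raise ValidationError(f"unknown core-data kind: {self.kind!r}")
        if not self.code:
            raise ValidationError("core-data code must be non-empty")
        object.__setattr__(self, "allowed_units", tuple(self.allowed_units))


@dataclass(frozen=True)
class ObservationRecord:
    """One medical datum in long-table form."""

    pseudonym: str
    screening_type: str
    parameter: str
    value: Union[float, str]
    unit: str
    sample_time: str
    status: str = ""
    metadata: dict = field(default_factory=dict)

    object_class = ObjectClass.DIAGNOSTIC_DATA

    @property
    def value_kind(self) -> str:
        return "number" if isinstance(self.value, (int, float)) and not isinstance(self.value, bool) else "text"

    def to_payload(self) -> dict:
        return {
            "type": "observation",
            "pseudonym": self.pseudonym,
            "screening_type": self.screening_type,
            "parameter": self.parameter,
            "value": self.value,
            "value_kind": self.value_kind,
            "unit": self.unit,
            "sample_time": self.sample_time,
            "status": self.status,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_payload(cls, d: dict) -> "ObservationRecord":
        return cls(
            pseudonym=d["pseudonym"],
            screening_type=d["screening_type"],
            parameter=d["parameter"],
            value=d["value"],
            unit=d["unit"],
            sample_time=d["sample_time"],
            status=d.get("status", ""),
            metadata=dict(d.get("metadata", {})),
        )


@dataclass(frozen=True)
class TherapyEvent:
    """One drug application belonging to a treatment regimen."""

    pseudonym: str
    drug: str
    dose_value: float
    dose_unit: str
    application_time: str
    regimen_label: str = ""
    cycle_index: int = 1
    metadata: dict = field(default_factory=dict)

    object_class = ObjectClass.TREATMENT_DATA

    def __post_init__(self):
        if self.cycle_index < 1:
            raise ValidationError("cycle_index must be >= 1")

    def to_payload(self) -> dict:
        return {
            "type": "therapy_event",
            "pseudonym": self.pseudonym,
            "drug": self.drug,
            "dose_value": self.dose_value,
            "dose_unit": self.dose_unit,
            "application_time": self.application_time,
            "regimen_label": self.regimen_label,
            "cycle_index": self.cycle_index,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_payload(cls, d: dict) -> "TherapyEvent":
        return cls(
            pseudonym=d["pseudonym"],
            drug=d["drug"],
            dose_value=d["dose_value"],
            dose_unit=d["dose_unit"],
            application_time=d["application_time"],
            regimen_label=d.get("regimen_label", ""),
            cycle_index=d.get("cycle_index", 1),
            metadata=dict(d.get("metadata", {})),
        )


@dataclass(frozen=True)
class VersionedRecord:
    """Immutable envelope of one payload version in the audit chain."""

    record_id: str
    version_seq: int
    parent_version: Optional[int]
    operation: str  # insert | update | delete
    actor: str
    wall_time: str
    object_class: ObjectClass
    payload: dict

    def payload_obj(self):
        t = self.payload.get("type")
        if t == "observation":
            return ObservationRecord.from_payload(self.payload)
        if t == "therapy_event":
            return TherapyEvent.from_payload(self.payload)
        return dict(self.payload)


Payload = Union[ObservationRecord, TherapyEvent, dict]

# ---------------------------------------------------------------------------
# store
# ---------------------------------------------------------------------------

_IDENTITY_SCHEMA = """
CREATE TABLE IF NOT EXISTS patients (
    identity_id TEXT PRIMARY KEY,
    given_name TEXT NOT NULL,
    family_name TEXT NOT NULL,
    birth_date TEXT NOT NULL,
    sex TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS pseudonym_links (
    identity_id TEXT NOT NULL UNIQUE REFERENCES patients(identity_id),
    pseudonym TEXT NOT NULL UNIQUE
);
"""

_PAYLOAD_SCHEMA = """
CREATE TABLE IF NOT EXISTS core_defs (
    kind TEXT NOT NULL,
    code TEXT NOT NULL,
    label TEXT NOT NULL DEFAULT '',
    allowed_units TEXT NOT NULL DEFAULT '[]',
    PRIMARY KEY (kind, code)
);
CREATE TABLE IF NOT EXISTS records (
    record_id TEXT NOT NULL,
    version_seq INTEGER NOT NULL CHECK (version_seq >= 1),
    parent_version INTEGER,
    operation TEXT NOT NULL CHECK (operation IN ('insert','update','delete')),
    actor TEXT NOT NULL,
    wall_time TEXT NOT NULL,
    object_class TEXT NOT NULL,
    payload TEXT NOT NULL,
    PRIMARY KEY (record_id, version_seq)
);
CREATE INDEX IF NOT EXISTS idx_records_class ON records(object_class);
"""


def _utc_now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="microseconds")


class ClinicalStore:
    """Facade over the identifying and payload databases.

    Parameters
    ----------
    path:
        Directory holding ``identity.db`` and ``payload.db``; ``None`` keeps
        both in memory (useful for tests and ephemeral cohorts).
    policy:
        Access rule matrix; defaults to the shipped role matrix.
    seed:
        Seeds pseudonym and record-id generation.  Without a seed both are
        drawn from the OS entropy pool and differ between runs.
    clock:
        Callable returning the wall-time string stamped on versions.
        Injectable so that regenerated synthetic stores can be byte-stable.
    """

    def __init__(
        self,
        path: Optional[Union[str, Path]] = None,
        policy: Optional[AccessPolicy] = None,
        seed: Optional[int] = None,
        clock: Optional[Callable[[], str]] = None,
    ) -> None:
        self.policy = policy if policy is not None else default_policy()
        self.clock = clock or _utc_now
        self._rng = random.Random(seed) if seed is not None else None
        if path is None:
            self._identity = sqlite3.connect(":memory:")
            self._payload = sqlite3.connect(":memory:")
        else:
            path = Path(path)
            path.mkdir(parents=True, exist_ok=True)
            self._identity = sqlite3.connect(path / "identity.db")
            self._payload = sqlite3.connect(path / "payload.db")
        self._identity.executescript(_IDENTITY_SCHEMA)
        self._payload.executescript(_PAYLOAD_SCHEMA)

    # -- token generation ---------------------------------------------------

    def _token(self, nbits: int = 128) -> str:
        if self._rng is not None:
            return f"{self._rng.getrandbits(nbits):0{nbits // 4}x}"
        return secrets.token_hex(nbits // 8)

    # -- core data ----------------------------------------------------------

    def define_core(self, actor: Actor, definition: CoreDataDef) -> CoreDataDef:
        self.policy.require(actor.role, ObjectClass.CORE_DATA, Right.CREATE, "define_core")
        cur = self._payload.execute(
            "SELECT 1 FROM core_defs WHERE kind=? AND code=?",
            (definition.kind, definition.code),
        )
        if cur.fetchone():
            raise ConflictError(f"core data ({definition.kind}, {definition.code}) already defined")
        if definition.kind == "parameter":
            for u in definition.allowed_units:
                if not self._core_exists("unit", u):
                    raise ValidationError(f"allowed unit {u!r} is not a defined unit")
        self._payload.execute(
            "INSERT INTO core_defs (kind, code, label, allowed_units) VALUES (?,?,?,?)",
            (definition.kind, definition.code, definition.label, json.dumps(list(definition.allowed_units))),
        )
        self._payload.commit()
        return definition

    def _core_exists(self, kind: str, code: str) -> bool:
        cur = self._payload.execute("SELECT 1 FROM core_defs WHERE kind=? AND code=?", (kind, code))
        return cur.fetchone() is not None

    def get_core(self, kind: str, code: str) -> CoreDataDef:
        cur = self._payload.execute(
            "SELECT kind, code, label, allowed_units FROM core_defs WHERE kind=? AND code=?",
            (kind, code),
        )
        row = cur.fetchone()
        if row is None:
            raise NotFoundError(f"core data ({kind}, {code}) not defined")
        return CoreDataDef(kind=row[0], code=row[1], label=row[2], allowed_units=tuple(json.loads(row[3])))

    def list_core(self, kind: Optional[str] = None) -> list[CoreDataDef]:
        q = "SELECT kind, code, label, allowed_units FROM core_defs"
        args: tuple = ()
        if kind is not None:
            q += " WHERE kind=?"
            args = (kind,)
        return [
            CoreDataDef(kind=k, code=c, label=l, allowed_units=tuple(json.loads(u)))
            for k, c, l, u in self._payload.execute(q + " ORDER BY kind, code", args)
        ]

    # -- identities and pseudonyms -----------------------------------------

    def register_patient(self, actor: Actor, identity: PatientIdentity) -> str:
        self.policy.require(actor.role, ObjectClass.IDENTIFYING_DATA, Right.CREATE, "register_patient")
        identity_id = identity.identity_id or f"pid-{self._token(64)}"
        while True:
            pseudonym = self._token(128)
            cur = self._identity.execute(
                "SELECT 1 FROM pseudonym_links WHERE pseudonym=?", (pseudonym,)
            )
            if cur.fetchone() is None:
                break
        try:
            self._identity.execute(
                "INSERT INTO patients (identity_id, given_name, family_name, birth_date, sex) VALUES (?,?,?,?,?)",
                (identity_id, identity.given_name, identity.family_name, identity.birth_date, identity.sex),
            )
        except sqlite3.IntegrityError:
            raise ConflictError(f"identity {identity_id!r} already registered") from None
        self._identity.execute(
            "INSERT INTO pseudonym_links (identity_id, pseudonym) VALUES (?,?)",
            (identity_id, pseudonym),
        )
        self._identity.commit()
        return pseudonym

    def resolve_pseudonym(self, actor: Actor, pseudonym: str) -> PatientIdentity:
        """De-pseudonymization: the single permission-gated bridge between
        the payload and identifying databases."""
        self.policy.require(actor.role, ObjectClass.IDENTIFYING_DATA, Right.READ, "resolve_pseudonym")
        cur = self._identity.execute(
            "SELECT p.identity_id, p.given_name, p.family_name, p.birth_date, p.sex "
            "FROM pseudonym_links l JOIN patients p ON p.identity_id = l.identity_id "
            "WHERE l.pseudonym=?",
            (pseudonym,),
        )
        row = cur.fetchone()
        if row is None:
            raise NotFoundError(f"unknown pseudonym {pseudonym!r}")
        return PatientIdentity(
            identity_id=row[0], given_name=row[1], family_name=row[2], birth_date=row[3], sex=row[4]
        )

    def known_pseudonyms(self) -> list[str]:
        """Distinct pseudonyms appearing in payload records (no identity access)."""
        rows = self._payload.execute(
            "SELECT DISTINCT json_extract(payload, '$.pseudonym') FROM records"
        ).fetchall()
        return sorted(r[0] for r in rows if r[0] is not None)

    # -- payload validation -------------------------------------------------

    def _validate_payload(self, payload: Payload) -> tuple[ObjectClass, dict]:
        if isinstance(payload, ObservationRecord):
            for kind, code in (
                ("screening_type", payload.screening_type),
                ("parameter", payload.parameter),
                ("unit", payload.unit),
            ):
                if not self._core_exists(kind, code):
                    raise ValidationError(f"undefined core {kind} code {code!r}")
            param = self.get_core("parameter", payload.parameter)
            if param.allowed_units and payload.unit not in param.allowed_units:
                raise ValidationError(
                    f"unit {payload.unit!r} not allowed for parameter {payload.parameter!r}"
                )
            return ObjectClass.DIAGNOSTIC_DATA, payload.to_payload()
        if isinstance(payload, TherapyEvent):
            if not self._core_exists("drug", payload.drug):
                raise ValidationError(f"undefined core drug code {payload.drug!r}")
            if not self._core_exists("unit", payload.dose_unit):
                raise ValidationError(f"undefined core unit code {payload.dose_unit!r}")
            return ObjectClass.TREATMENT_DATA, payload.to_payload()
        if isinstance(payload, dict):
            oc = payload.get("object_class", ObjectClass.MODEL_JOBS.value)
            try:
                oc = ObjectClass(oc)
            except ValueError:
                raise ValidationError(f"unknown object class {oc!r}") from None
            body = {k: v for k, v in payload.items() if k != "object_class"}
            return oc, body
        raise ValidationError(f"unsupported payload type {type(payload).__name__}")

    # -- versioned record operations ---------------------------------------

    def _head(self, record_id: str) -> Optional[VersionedRecord]:
        cur = self._payload.execute(
            "SELECT record_id, version_seq, parent_version, operation, actor, wall_time, object_class, payload "
            "FROM records WHERE record_id=? ORDER BY version_seq DESC LIMIT 1",
            (record_id,),
        )
        row = cur.fetchone()
        return self._row_to_record(row) if row else None

    @staticmethod
    def _row_to_record(row) -> VersionedRecord:
        return VersionedRecord(
            record_id=row[0],
            version_seq=row[1],
            parent_version=row[2],
            operation=row[3],
            actor=row[4],
            wall_time=row[5],
            object_class=ObjectClass(row[6]),
            payload=json.loads(row[7]),
        )

    def _append(
        self,
        actor: Actor,
        record_id: str,
        version_seq: int,
        parent_version: Optional[int],
        operation: str,
        object_class: ObjectClass,
        payload: dict,
    ) -> VersionedRecord:
        rec = VersionedRecord(
            record_id=record_id,
            version_seq=version_seq,
            parent_version=parent_version,
            operation=operation,
            actor=actor.user_id,
            wall_time=self.clock(),
            object_class=object_class,
            payload=payload,
        )
        try:
            self._payload.execute(
                "INSERT INTO records (record_id, version_seq, parent_version, operation, actor, wall_time, object_class, payload) "
                "VALUES (?,?,?,?,?,?,?,?)",
                (
                    rec.record_id,
                    rec.version_seq,
                    rec.parent_version,
                    rec.operation,
                    rec.actor,
                    rec.wall_time,
                    rec.object_class.value,
                    json.dumps(rec.payload, sort_keys=True),
                ),
            )
        except sqlite3.IntegrityError:
            # per-record serialization contract: concurrent appenders race on
            # the (record_id, version_seq) primary key; the loser gets a conflict
            raise ConflictError(
                f"version {version_seq} of record {record_id} already exists"
            ) from None
        self._payload.commit()
        return rec

    def insert_record(self, actor: Actor, payload: Payload) -> VersionedRecord:
        object_class, body = self._validate_payload(payload)
        self.policy.require(actor.role, object_class, Right.CREATE, "insert_record")
        record_id = f"rec-{self._token(64)}"
        return self._append(actor, record_id, 1, None, "insert", object_class, body)

    def update_record(
        self,
        actor: Actor,
        record_id: str,
        new_payload: Payload,
        expected_version: Optional[int] = None,
    ) -> VersionedRecord:
        head = self._head(record_id)
        if head is None:
            raise NotFoundError(f"unknown record {record_id!r}")
        if head.operation == "delete":
            raise ConflictError(f"record {record_id} is deleted; cannot update")
        object_class, body = self._validate_payload(new_payload)
        if object_class != head.object_class:
            raise ValidationError("cannot change a record's object class on update")
        self.policy.require(actor.role, object_class, Right.UPDATE, "update_record")
        base = expected_version if expected_version is not None else head.version_seq
        return self._append(actor, record_id, base + 1, base, "update", object_class, body)

    def delete_record(self, actor: Actor, record_id: str) -> VersionedRecord:
        head = self._head(record_id)
        if head is None:
            raise NotFoundError(f"unknown record {record_id!r}")
        if head.operation == "delete":
            raise ConflictError(f"record {record_id} is already deleted")
        self.policy.require(actor.role, head.object_class, Right.DELETE, "delete_record")
        return self._append(
            actor, record_id, head.version_seq + 1, head.version_seq, "delete", head.object_class, {}
        )

    # -- queries ------------------------------------------------------------

    def get_current(
        self,
        actor: Actor,
        object_class: Optional[ObjectClass] = None,
        pseudonym: Optional[str] = None,
        parameter: Optional[str] = None,
        time_range: Optional[tuple] = None,
    ) -> list[VersionedRecord]:
        """Newest non-tombstoned version of each matching record."""
        classes = [ObjectClass(object_class)] if object_class else [
            ObjectClass.DIAGNOSTIC_DATA,
            ObjectClass.TREATMENT_DATA,
            ObjectClass.MODEL_JOBS,
        ]
        for oc in classes:
            self.policy.require(actor.role, oc, Right.READ, "get_current")
        rows = self._payload.execute(
            "SELECT r.record_id, r.version_seq, r.parent_version, r.operation, r.actor, r.wall_time, r.object_class, r.payload "
            "FROM records r JOIN (SELECT record_id, MAX(version_seq) AS v FROM records GROUP BY record_id) h "
            "ON r.record_id = h.record_id AND r.version_seq = h.v "
            "WHERE r.operation != 'delete' ORDER BY r.record_id"
        ).fetchall()
        out = []
        for row in rows:
            rec = self._row_to_record(row)
            if rec.object_class not in classes:
                continue
            if pseudonym is not None and rec.payload.get("pseudonym") != pseudonym:
                continue
            if parameter is not None and rec.payload.get("parameter") != parameter:
                continue
            if time_range is not None:
                t = rec.payload.get("sample_time") or rec.payload.get("application_time")
                if t is None or not (time_range[0] <= t <= time_range[1]):
                    continue
            out.append(rec)
        return out

    def get_history(self, actor: Actor, record_id: str) -> list[VersionedRecord]:
        rows = self._payload.execute(
            "SELECT record_id, version_seq, parent_version, operation, actor, wall_time, object_class, payload "
            "FROM records WHERE record_id=? ORDER BY version_seq",
            (record_id,),
        ).fetchall()
        if not rows:
            raise NotFoundError(f"unknown record {record_id!r}")
        chain = [self._row_to_record(r) for r in rows]
        self.policy.require(actor.role, chain[0].object_class, Right.READ, "get_history")
        return chain

    # -- access check passthrough -------------------------------------------

    def check_access(self, role, object_class, right) -> bool:
        return self.policy.check(role, object_class, right)

    # -- export -------------------------------------------------------------

    def export_payload(self) -> dict:
        """Canonical JSON-able snapshot of the payload database (no identity
        data), suitable for content hashing and byte-stability checks."""
        core = [
            {"kind": d.kind, "code": d.code, "label": d.label, "allowed_units": list(d.allowed_units)}
            for d in self.list_core()
        ]
        records = [
            {
                "record_id": r[0],
                "version_seq": r[1],
                "parent_version": r[2],
                "operation": r[3],
                "actor": r[4],
                "wall_time": r[5],
                "object_class": r[6],
                "payload": json.loads(r[7]),
            }
            for r in self._payload.execute(
                "SELECT record_id, version_seq, parent_version, operation, actor, wall_time, object_class, payload "
                "FROM records ORDER BY record_id, version_seq"
            )
        ]
        return {"core_defs": core, "records": records}

    def close(self) -> None:
        self._identity.close()
        self._payload.close()


def counter_clock(start: int = 0) -> Callable[[], str]:
    """Deterministic clock for reproducible stores: yields strictly
    increasing synthetic timestamps ``T+0``, ``T+1``, ..."""
    state = {"n": start}

    def _tick() -> str:
        n = state["n"]
        state["n"] += 1
        return f"T+{n:08d}"

    return _tick
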