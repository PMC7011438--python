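"""File formats and store <-> model conversions.

CSV layouts
-----------
observations (generic long-table import):
    pseudonym,screening_type,parameter,value,unit,sample_time,metadata_json
molecular course:
    time_days,bcr_abl_pct,below_lod,lod_pct,copy_number,is_standardized
platelet course:
    time_days,platelet_count

Schedules, core data, access rules, fits and prediction bands travel as
JSON mirroring the in-memory dataclasses.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd

from . import cml, thrombo
from .access import AccessPolicy
from .errors import ValidationError
from .store import CoreDataDef, ObservationRecord, TherapyEvent, VersionedRecord

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------


def read_observations_csv(path: PathLike) -> list[ObservationRecord]:
    df = pd.read_csv(path)
    required = {"pseudonym", "screening_type", "parameter", "value", "unit", "sample_time"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"observation CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        meta = {}
        if "metadata_json" in df.columns and isinstance(row.metadata_json, str) and row.metadata_json.strip():
            meta = json.loads(row.metadata_json)
        value = row.value
        try:
            value = float(value)
        except (TypeError, ValueError):
            value = str(value)
        out.append(
            ObservationRecord(
                pseudonym=str(row.pseudonym),
                screening_type=str(row.screening_type),
                parameter=str(row.parameter),
                value=value,
                unit=str(row.unit),
                sample_time=str(row.sample_time),
                metadata=meta,
            )
        )
    return out


def read_molecular_csv(path: PathLike) -> list[cml.MolecularObservation]:
    df = pd.read_csv(path)
    if not {"time_days", "bcr_abl_pct"} <= set(df.columns):
        raise ValidationError("molecular CSV needs columns time_days, bcr_abl_pct")
    out = []
    for row in df.itertuples(index=False):
        below = bool(getattr(row, "below_lod", False))
        lod = getattr(row, "lod_pct", None)
        meta = {}
        if hasattr(row, "copy_number") and pd.notna(row.copy_number):
            meta["copy_number"] = int(row.copy_number)
        if hasattr(row, "is_standardized"):
            meta["is_standardized"] = bool(row.is_standardized)
        out.append(
            cml.MolecularObservation(
                time=float(row.time_days),
                bcr_abl_pct=float(row.bcr_abl_pct),
                below_lod=below,
                lod_pct=float(lod) if lod is not None and pd.notna(lod) else None,
                metadata=meta,
            )
        )
    return out


def read_platelet_csv(path: PathLike) -> list[thrombo.PlateletObservation]:
    df = pd.read_csv(path)
    if not {"time_days", "platelet_count"} <= set(df.columns):
        raise ValidationError("platelet CSV needs columns time_days, platelet_count")
    return [
        thrombo.PlateletObservation(time=float(r.time_days), count=float(r.platelet_count))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# JSON round trips
# ---------------------------------------------------------------------------


def read_schedule_json(path: PathLike) -> thrombo.TherapySchedule:
    with open(path) as fh:
        return thrombo.TherapySchedule.from_json(json.load(fh))


def write_json(path: PathLike, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_core_data_json(path: PathLike) -> list[CoreDataDef]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        CoreDataDef(
            kind=d["kind"],
            code=d["code"],
            label=d.get("label", ""),
            allowed_units=tuple(d.get("allowed_units", ())),
        )
        for d in data
    ]


def write_core_data_json(path: PathLike, defs: list[CoreDataDef]) -> None:
    write_json(
        path,
        [
            {"kind": d.kind, "code": d.code, "label": d.label, "allowed_units": list(d.allowed_units)}
            for d in defs
        ],
    )


def read_access_rules_json(path: PathLike) -> AccessPolicy:
    with open(path) as fh:
        return AccessPolicy.from_json(json.load(fh))


# ---------------------------------------------------------------------------
# store record -> model observation conversion
# ---------------------------------------------------------------------------


def molecular_course_from_records(records: list[VersionedRecord]) -> list[cml.MolecularObservation]:
    """Extract a BCR-ABL1 course from long-table diagnostic records."""
    out = []
    for rec in records:
        p = rec.payload
        if p.get("parameter") != "BCR-ABL1":
            continue
        meta = p.get("metadata", {})
        t = meta.get("time_days")
        if t is None:
            raise ValidationError(f"record {rec.record_id} lacks metadata time_days")
        out.append(
            cml.MolecularObservation(
                time=float(t),
                bcr_abl_pct=float(p["value"]),
                below_lod=p.get("status") == "below_lod",
                lod_pct=meta.get("lod_pct"),
                metadata={k: v for k, v in meta.items() if k not in ("time_days", "lod_pct")},
            )
        )
    return sorted(out, key=lambda o: o.time)


def platelet_course_from_records(records: list[VersionedRecord]) -> list[thrombo.PlateletObservation]:
    out = []
    for rec in records:
        p = rec.payload
        if p.get("parameter") != "platelets":
            continue
        t = p.get("metadata", {}).get("time_days")
        if t is None:
            raise ValidationError(f"record {rec.record_id} lacks metadata time_days")
        out.append(thrombo.PlateletObservation(time=float(t), count=float(p["value"])))
    return sorted(out, key=lambda o: o.time)


def schedule_from_events(records: list[VersionedRecord]) -> thrombo.TherapySchedule:
    """Rebuild a therapy schedule from stored therapy events.

    Events carry absolute application days in metadata-free form
    (``application_time`` of the shape ``day+<number>``); cycles are grouped
    by the stored cycle index.
    """
    events = [r.payload for r in records if r.payload.get("type") == "therapy_event"]
    events = [e for e in events if e.get("drug") in thrombo.DEFAULT_DRUG_SLOPES]
    if not events:
        raise ValidationError("no chemotherapy events found for schedule reconstruction")

    def day_of(e):
        t = e["application_time"]
        if not t.startswith("day+"):
            raise ValidationError(f"unparseable application_time {t!r}")
        return float(t[4:])

    label = events[0].get("regimen_label", "")
    by_cycle: dict = {}
    for e in events:
        by_cycle.setdefault(e.get("cycle_index", 1), []).append(e)
    cycles = []
    for ci in sorted(by_cycle):
        evs = by_cycle[ci]
        start = min(day_of(e) for e in evs)
        apps = tuple(
            thrombo.Application(
                day_offset=day_of(e) - start,
                drug=e["drug"],
                relative_dose=float(e.get("dose_value", 1.0)),
            )
            for e in sorted(evs, key=day_of)
        )
        cycles.append(thrombo.Cycle(start_day=start, applications=apps))
    return thrombo.TherapySchedule(regimen_label=label, cycles=tuple(cycles))
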