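"""Role-based access control.

A small rule matrix relates user roles to permission object classes and
rights.  The policy is *default deny*: a (role, object_class, right) triple
is allowed only if at least one allow rule matches and no deny rule matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .errors import ValidationError


class Role(str, Enum):
    PHYSICIAN = "physician"
    SCIENTIST = "scientist"
    DOCUMENTARIST = "documentarist"
    ADMINISTRATOR = "administrator"


class ObjectClass(str, Enum):
    IDENTIFYING_DATA = "identifying_data"
    CORE_DATA = "core_data"
    DIAGNOSTIC_DATA = "diagnostic_data"
    TREATMENT_DATA = "treatment_data"
    MODEL_JOBS = "model_jobs"


class Right(str, Enum):
    READ = "read"
    UPDATE = "update"
    CREATE = "create"
    DELETE = "delete"


@dataclass(frozen=True)
class AccessRule:
    role: Role
    object_class: ObjectClass
    right: Right
    effect: str = "allow"  # "allow" | "deny"

    def __post_init__(self) -> None:
        if self.effect not in ("allow", "deny"):
            raise ValidationError(f"unknown rule effect: {self.effect!r}")


def _coerce(value, enum_cls, what: str):
    try:
        return enum_cls(value)
    except ValueError:
        raise ValidationError(f"unknown {what}: {value!r}") from None


class AccessPolicy:
    """An ordered collection of access rules with default-deny semantics."""

    def __init__(self, rules: Iterable[AccessRule] = ()) -> None:
        self.rules: list[AccessRule] = list(rules)

    def check(self, role, object_class, right) -> bool:
        """Return True iff the triple is allowed.  Deny rules dominate."""
        role = _coerce(role, Role, "role")
        object_class = _coerce(object_class, ObjectClass, "object class")
        right = _coerce(right, Right, "right")
        matched_allow = False
        for rule in self.rules:
            if (rule.role, rule.object_class, rule.right) == (role, object_class, right):
                if rule.effect == "deny":
                    return False
                matched_allow = True
        return matched_allow

    def require(self, role, object_class, right, context: str = "") -> None:
        from .errors import AccessError

        if not self.check(role, object_class, right):
            suffix = f" ({context})" if context else ""
            raise AccessError(
                f"role {Role(role).value!r} lacks {Right(right).value!r} "
                f"on {ObjectClass(object_class).value!r}{suffix}"
            )

    def to_json(self) -> list[dict]:
        return [
            {
                "role": r.role.value,
                "object_class": r.object_class.value,
                "right": r.right.value,
                "effect": r.effect,
            }
            for r in self.rules
        ]

    @classmethod
    def from_json(cls, data: Iterable[dict]) -> "AccessPolicy":
        return cls(
            AccessRule(
                role=_coerce(d["role"], Role, "role"),
                object_class=_coerce(d["object_class"], ObjectClass, "object class"),
                right=_coerce(d["right"], Right, "right"),
                effect=d.get("effect", "allow"),
            )
            for d in data
        )


def _expand(role, object_classes, rights):
    return [
        AccessRule(role, oc, r)
        for oc in object_classes
        for r in rights
    ]


_MEDICAL = [ObjectClass.DIAGNOSTIC_DATA, ObjectClass.TREATMENT_DATA]
_PSEUDONYMIZED = _MEDICAL + [ObjectClass.MODEL_JOBS, ObjectClass.CORE_DATA]
_ALL = list(ObjectClass)

#: Shipped default matrix.  Physicians read identifying data and work on all
#: payload classes; documentarists enter/maintain medical data but can never
#: see identifying data; scientists get read-only pseudonymized access;
#: administrators manage core data (and the rule set itself, outside this
#: matrix) but see no patient data.
DEFAULT_RULES: list[AccessRule] = (
    _expand(Role.PHYSICIAN, _ALL, [Right.READ])
    + _expand(
        Role.PHYSICIAN,
        [ObjectClass.IDENTIFYING_DATA] + _MEDICAL + [ObjectClass.MODEL_JOBS],
        [Right.CREATE, Right.UPDATE, Right.DELETE],
    )
    + _expand(Role.DOCUMENTARIST, _MEDICAL + [ObjectClass.CORE_DATA], [Right.READ])
    + _expand(Role.DOCUMENTARIST, _MEDICAL, [Right.CREATE, Right.UPDATE])
    + _expand(Role.SCIENTIST, _PSEUDONYMIZED, [Right.READ])
    + _expand(
        Role.ADMINISTRATOR,
        [ObjectClass.CORE_DATA],
        [Right.READ, Right.CREATE, Right.UPDATE, Right.DELETE],
    )
)


def default_policy() -> AccessPolicy:
    return AccessPolicy(DEFAULT_RULES)
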