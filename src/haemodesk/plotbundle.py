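"""Plot-data bundles: structured exports of annotated time courses.

A :class:`PlotBundle` carries everything a front-end needs to render one
patient view — observed points, the model's central prediction with its
pointwise band, therapy application bars, and reference regions (the CML
clinical target range, or the thrombocytopenia grade bands) — on a common
day-based time axis.  The package ships the corresponding JSON schema
(``data/plot_bundle_schema.json``), generated from this model, so external
consumers can validate bundles without importing the package.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .errors import ValidationError


class Series(BaseModel):
    label: str
    times_days: list[float]
    values: list[float]
    unit: str

    @model_validator(mode="after")
    def _lengths(self):
        if len(self.times_days) != len(self.values):
            raise ValueError("series times and values must have equal length")
        return self


class TherapyBar(BaseModel):
    start_day: float
    end_day: float
    drug: str
    dose_label: str = ""

    @model_validator(mode="after")
    def _ordered(self):
        if self.end_day < self.start_day:
            raise ValueError("therapy bar must have end_day >= start_day")
        return self


class ReferenceRegion(BaseModel):
    lo: float
    hi: float
    label: str

    @model_validator(mode="after")
    def _ordered(self):
        if self.hi < self.lo:
            raise ValueError("reference region must have hi >= lo")
        return self


class PlotBundle(BaseModel):
    """Renderable content of one patient view."""

    pseudonym: str
    view: str  # "cml" | "nhl"
    observations: Series
    model_central: Optional[Series] = None
    model_lower: Optional[Series] = None
    model_upper: Optional[Series] = None
    band_level: Optional[float] = Field(default=None, gt=0, lt=1)
    therapy_bars: list[TherapyBar] = Field(default_factory=list)
    reference_regions: list[ReferenceRegion] = Field(default_factory=list)
    latent_series: Optional[Series] = None

    @model_validator(mode="after")
    def _band_ordering(self):
        if self.model_lower is not None and self.model_upper is not None and self.model_central is not None:
            for lo, c, hi in zip(
                self.model_lower.values, self.model_central.values, self.model_upper.values
            ):
                if not (lo <= c + 1e-9 and c <= hi + 1e-9):
                    raise ValueError("band ordering violated: need lower <= central <= upper")
        return self

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "PlotBundle":
        with open(path) as fh:
            try:
                return cls.model_validate_json(fh.read())
            except ValueError as exc:
                raise ValidationError(f"invalid plot bundle: {exc}") from None


def published_schema() -> dict:
    """The JSON schema shipped with the package."""
    with resources.files("haemodesk.data").joinpath("plot_bundle_schema.json").open() as fh:
        return json.load(fh)


def current_schema() -> dict:
    """Schema generated from the live model (must equal the shipped one)."""
    return PlotBundle.model_json_schema()
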