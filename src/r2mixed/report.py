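"""Structured, validated JSON reports for CLI output.

The pydantic models below are the authoritative schema; the JSON Schema
document shipped at ``schemas/r2_report.schema.json`` is generated from
them and published for downstream consumers.
"""

from __future__ import annotations

import json
from importlib import resources

from pydantic import BaseModel, Field


class PartitionReport(BaseModel):
    sigma2_f: float = Field(ge=0)
    sigma2_terms: list[float]
    sigma2_e: float = Field(ge=0)
    sigma2_d: float = Field(ge=0)


class FitReport(BaseModel):
    loglik: float
    method: str
    converged: bool
    boundary: bool = False
    n_groups: int = Field(ge=1)
    iterations: int = Field(ge=0)
    beta: list[float]
    Sigma: list[list[float]]
    sigma2_eps: float = Field(ge=0)


class R2Report(BaseModel):
    """Full variance-partition report written by the ``r2`` command."""

    partition: PartitionReport
    r2_marginal: float = Field(ge=0, le=1)
    r2_conditional: float = Field(ge=0, le=1)
    family_link: str
    fit: FitReport | None = None


def validate_report(payload: dict) -> R2Report:
    """Validate a report dict against the schema; raises on violation."""
    return R2Report.model_validate(payload)


def report_schema() -> dict:
    """The published JSON Schema for :class:`R2Report`."""
    return R2Report.model_json_schema()


def shipped_schema() -> dict:
    """Load the JSON Schema document shipped with the package."""
    text = (
        resources.files("r2mixed") / "schemas" / "r2_report.schema.json"
    ).read_text()
    return json.loads(text)
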