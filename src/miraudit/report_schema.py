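"""Pydantic models backing the JSON audit report and its shipped schema."""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field


class AuditRecord(BaseModel):
    mature_id: str
    max_cpm: float = Field(ge=0)
    argmax_sample: str
    argmax_dataset: str
    bin: str
    not_detected: bool


class AuditReport(BaseModel):
    schema_version: Literal[1]
    manifest: str | None = None
    records: list[AuditRecord]
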