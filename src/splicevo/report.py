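"""Machine-readable run report (pydantic model + published JSON schema)."""

from __future__ import annotations

from pydantic import BaseModel, Field


class StageRecord(BaseModel):
    name: str
    hash: str
    inputs: dict[str, str] = Field(default_factory=dict)
    outputs: dict[str, str] = Field(default_factory=dict)


class SubfamilyCall(BaseModel):
    gene_id: str
    label: str
    score: float


class GroupHistory(BaseModel):
    group: str
    gain_branch: list[str] | None
    loss_branches: list[list[str]]
    cost: int
    fitch_cost: int
    present_leaves: list[str]


class OriginReport(BaseModel):
    verdict: str
    n_groups: int
    linked_pairs: list[list[str]] = Field(default_factory=list)  # [lost, gained, branch-leaves...]
    histories: list[GroupHistory] = Field(default_factory=list)
    ambiguous_groups: list[str] = Field(default_factory=list)


class PerfectRunReport(BaseModel):
    group: str
    start: int
    end: int
    length: int
    n_sequences: int


class HostIntronPercentile(BaseModel):
    gene_id: str
    group: str
    host_intron: int
    intron_length: int
    percentile: float
    top_fraction: float


class ConservationReport(BaseModel):
    perfect_runs: list[PerfectRunReport] = Field(default_factory=list)
    mean_identity_by_group: dict[str, float] = Field(default_factory=dict)
    host_intron_percentiles: list[HostIntronPercentile] = Field(default_factory=list)


class RunReport(BaseModel):
    """Everything one pipeline run produced, with recovery metrics when the
    inputs came from the simulator (metrics are absent otherwise)."""

    seed: int | None = None
    parameters: dict = Field(default_factory=dict)
    stages: list[StageRecord] = Field(default_factory=list)
    n_genes: int = 0
    n_characters: int = 0
    subfamilies: list[SubfamilyCall] = Field(default_factory=list)
    event_counts: dict[str, int] = Field(default_factory=dict)
    nmd_verdict_counts: dict[str, int] = Field(default_factory=dict)
    n_stabilized: int | None = None
    origin: OriginReport | None = None
    conservation: ConservationReport | None = None
    metrics: dict[str, float] | None = None
    files: dict[str, str] = Field(default_factory=dict)

    def to_json(self) -> str:
        import json

        return json.dumps(self.model_dump(), indent=1, sort_keys=True)
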