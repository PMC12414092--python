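"""The screening cascade: ordered filter stages over candidate records.

Each stage is a pure predicate on one field of a :class:`CandidateRecord`
(optionally conditioned on an exact label match).  The cascade reports the
retained count and id set after every stage; because stages are pure
predicates, the final retained set is the intersection of all stage
predicates and is independent of stage order (only intermediate counts
depend on the order).

Default stages follow the published screening narrative: toxicity band
(SVM score > -0.30 and Non-Toxin), amphipathicity, hydrophobicity,
molecular weight (informational by default — the narrative kept every
candidate at that step), and aggregation (Na4vSS >= -57).
"""

from __future__ import annotations

import json
import operator
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd

from .aggregation import NA4VSS_CUTOFF
from .toxicity import NON_TOXIN

__all__ = [
    "CandidateRecord",
    "FilterStage",
    "FunnelReport",
    "StageConfigurationError",
    "default_stages",
    "run_funnel",
    "rank_candidates",
    "records_from_dataframe",
    "records_to_dataframe",
]

_COMPARATORS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
    "==": operator.eq,
}


class StageConfigurationError(ValueError):
    """A stage references a field that is unpopulated or unknown."""


@dataclass
class CandidateRecord:
    """One peptide with its screening descriptors and per-stage provenance."""

    id: str
    sequence: str
    svm_score: float | None = None
    prediction: str | None = None
    hydrophobicity: float | None = None
    amphipathicity: float | None = None
    mol_wt: float | None = None
    net_charge: int | None = None
    na4vss: float | None = None
    sopep_energy: float | None = None
    extras: dict[str, float] = field(default_factory=dict)
    stage_flags: dict[str, bool] = field(default_factory=dict)

    def get(self, name: str) -> Any:
        if hasattr(self, name):
            return getattr(self, name)
        return self.extras.get(name)


@dataclass(frozen=True)
class FilterStage:
    """A pure retain-matching predicate on one record field.

    ``comparator`` is one of ``> >= < <= == in-band``; ``in-band`` retains
    ``threshold < value <= threshold2``.  ``require`` adds exact-match
    side-conditions on other fields (e.g. prediction == Non-Toxin).
    ``informational`` stages report how many records would pass but retain
    everything (used for the molecular-weight step).
    """

    name: str
    field: str
    comparator: str
    threshold: float
    threshold2: float | None = None
    require: tuple[tuple[str, Any], ...] = ()
    informational: bool = False

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS and self.comparator != "in-band":
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.comparator == "in-band" and self.threshold2 is None:
            raise ValueError("in-band comparator needs threshold2")

    def passes(self, record: CandidateRecord) -> bool:
        value = record.get(self.field)
        if value is None:
            raise StageConfigurationError(
                f"stage {self.name!r} requires field {self.field!r}, "
                f"unpopulated on record {record.id!r}"
            )
        for req_field, req_value in self.require:
            actual = record.get(req_field)
            if actual is None:
                raise StageConfigurationError(
                    f"stage {self.name!r} requires field {req_field!r}, "
                    f"unpopulated on record {record.id!r}"
                )
            if actual != req_value:
                return False
        if self.comparator == "in-band":
            return self.threshold < value <= self.threshold2
        return _COMPARATORS[self.comparator](value, self.threshold)


def default_stages(
    tox_lower: float = -0.30,
    amphipathicity_max: float = 0.30,
    hydrophobicity_min: float = -0.20,
    mol_wt_max: float = 900.0,
    mol_wt_informational: bool = True,
    na4vss_cutoff: float = NA4VSS_CUTOFF,
) -> list[FilterStage]:
    """The published cascade with its default thresholds.

    The amphipathicity stage retains values at or below the threshold (all
    surviving candidates in the published table share a low value) and the
    hydrophobicity stage retains values at or above -0.20; both directions of
    these contested thresholds can be obtained by constructing stages
    directly.  The molecular-weight stage is informational by default.
    """
    return [
        FilterStage(
            name="toxicity_band",
            field="svm_score",
            comparator=">",
            threshold=tox_lower,
            require=(("prediction", NON_TOXIN),),
        ),
        FilterStage(
            name="amphipathicity",
            field="amphipathicity",
            comparator="<=",
            threshold=amphipathicity_max,
        ),
        FilterStage(
            name="hydrophobicity",
            field="hydrophobicity",
            comparator=">=",
            threshold=hydrophobicity_min,
        ),
        FilterStage(
            name="molecular_weight",
            field="mol_wt",
            comparator="<=",
            threshold=mol_wt_max,
            informational=mol_wt_informational,
        ),
        FilterStage(
            name="aggregation",
            field="na4vss",
            comparator=">=",
            threshold=na4vss_cutoff,
        ),
    ]


@dataclass
class FunnelReport:
    """Per-stage retained counts and id sets, plus the config snapshot."""

    input_count: int
    stage_names: list[str]
    stage_in: list[int]
    stage_retained: list[int]
    retained_ids: list[list[str]]
    config: list[dict[str, Any]]

    @property
    def final_ids(self) -> list[str]:
        return self.retained_ids[-1] if self.retained_ids else []

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def run_funnel(
    records: list[CandidateRecord], stages: list[FilterStage]
) -> FunnelReport:
    """Apply the stages in order, recording per-stage provenance.

    Every record gains a ``stage_flags[name]`` entry for each stage it
    reached.  Counts are non-increasing; an empty stage list returns the
    input unchanged.
    """
    current = list(records)
    names, n_in, n_ret, id_sets = [], [], [], []
    for stage in stages:
        names.append(stage.name)
        n_in.append(len(current))
        passing = []
        for rec in current:
            ok = stage.passes(rec)
            rec.stage_flags[stage.name] = ok
            if ok:
                passing.append(rec)
        if stage.informational:
            retained = current
        else:
            retained = passing
        n_ret.append(len(retained))
        id_sets.append([r.id for r in retained])
        current = retained
    if not stages:
        names, n_in, n_ret = ["(identity)"], [len(current)], [len(current)]
        id_sets = [[r.id for r in current]]
    return FunnelReport(
        input_count=len(records),
        stage_names=names,
        stage_in=n_in,
        stage_retained=n_ret,
        retained_ids=id_sets,
        config=[asdict(s) for s in stages],
    )


def rank_candidates(
    records: list[CandidateRecord], key: str, direction: str = "asc"
) -> list[CandidateRecord]:
    """Stable sort of records by a field, ties broken by id.

    ``direction="asc"`` puts the most negative value first (the convention
    for energies and docking scores, where lower is better).
    """
    if direction not in ("asc", "desc"):
        raise ValueError("direction must be 'asc' or 'desc'")
    missing = [r.id for r in records if r.get(key) is None]
    if missing:
        raise StageConfigurationError(
            f"ranking key {key!r} unpopulated on records {missing}"
        )
    sign = 1.0 if direction == "asc" else -1.0
    return sorted(records, key=lambda r: (sign * r.get(key), r.id))


_COLUMN_MAP = {
    "id": "id",
    "sequence": "sequence",
    "svm_score": "svm_score",
    "prediction": "prediction",
    "hydrophobicity": "hydrophobicity",
    "amphipathicity": "amphipathicity",
    "mol_wt": "mol_wt",
    "net_charge": "net_charge",
    "na4vss": "na4vss",
    "sopep_energy": "sopep_energy",
}


def records_from_dataframe(df: pd.DataFrame) -> list[CandidateRecord]:
    """Build records from a descriptor table (one row per peptide).

    Recognised columns map onto the record fields; any other numeric column
    lands in ``extras`` (e.g. docking scores used only for ranking).
    """
    records = []
    known = set(_COLUMN_MAP)
    for _, row in df.iterrows():
        kwargs: dict[str, Any] = {}
        extras: dict[str, float] = {}
        for col in df.columns:
            value = row[col]
            if pd.isna(value):
                continue
            if col in known:
                kwargs[_COLUMN_MAP[col]] = value
            else:
                extras[col] = value
        rec = CandidateRecord(
            id=str(kwargs.pop("id")), sequence=str(kwargs.pop("sequence")), **kwargs
        )
        rec.extras = extras
        records.append(rec)
    return records


def records_to_dataframe(records: list[CandidateRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {k: getattr(rec, k) for k in _COLUMN_MAP}
        row.update(rec.extras)
        rows.append(row)
    return pd.DataFrame(rows)
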