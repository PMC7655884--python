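"""Trial-level session data: domain types, CSV/JSON readers and writers.

The IAT task is a seven-block forced-choice categorization procedure.  A
*trial* is one categorization event; its latency runs from target onset to
the correct response (so error trials carry a built-in time penalty).  Two
task versions exist, differing only in which critical phase comes first:
version 1 runs the compatible pairing in blocks 3-4 and the incompatible
pairing in blocks 6-7; version 2 is the reverse.

Trial logs travel as plain CSV (UTF-8, comma, header, decimal point) with
columns ``participant_id, version, block, trial_index, stimulus, latency_ms,
first_correct``.  Task structure travels as JSON; :func:`load_task_spec`
with no argument returns the packaged default task with the 24 English
stimulus words.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Literal, Mapping

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "BlockSpec",
    "Category",
    "TaskSpec",
    "Trial",
    "Session",
    "SessionSet",
    "ValidationReport",
    "TaskSpecError",
    "TrialDataError",
    "load_task_spec",
    "read_trials",
    "write_trials",
    "validate_sessions",
    "TRIAL_COLUMNS",
]

#: Canonical column order for trial-log CSV files.
TRIAL_COLUMNS = [
    "participant_id",
    "version",
    "block",
    "trial_index",
    "stimulus",
    "latency_ms",
    "first_correct",
]

#: Trial counts for blocks B1..B7, identical in both versions.
BLOCK_TRIAL_COUNTS = (24, 24, 24, 48, 48, 24, 48)

CRITICAL_BLOCKS = (3, 4, 6, 7)

Phase = Literal["practice", "critical_compatible", "critical_incompatible"]


class TaskSpecError(ValueError):
    """A task specification violates the seven-block task contract."""


class TrialDataError(ValueError):
    """A trial log row cannot be parsed or violates a trial invariant."""


class BlockSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    block: int
    trials: int
    phase: Phase

    @field_validator("block")
    @classmethod
    def _block_range(cls, v: int) -> int:
        if not 1 <= v <= 7:
            raise ValueError(f"block {v} outside 1-7")
        return v


class Category(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    stimuli: tuple[str, ...]

    @field_validator("stimuli")
    @classmethod
    def _six_distinct(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(v) != 6:
            raise ValueError(f"expected 6 stimuli, got {len(v)}")
        if len(set(v)) != 6:
            raise ValueError("duplicate stimulus within category")
        return v


class TaskSpec(BaseModel):
    """Block structure and stimulus sets of one IAT task.

    Invariants enforced at construction: seven blocks per version with trial
    counts (24, 24, 24, 48, 48, 24, 48) summing to 240; version 1 compatible
    at B3-B4 / incompatible at B6-B7 and version 2 the reverse; four
    categories of exactly six stimuli with no word in two categories.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    categories: Mapping[str, Category]
    response_keys: Mapping[str, str] = {"left": "S", "right": "L"}
    versions: Mapping[int, tuple[BlockSpec, ...]]

    @field_validator("versions", mode="before")
    @classmethod
    def _int_keys(cls, v: Mapping) -> Mapping:
        return {int(k): blocks for k, blocks in v.items()}

    @model_validator(mode="after")
    def _check_structure(self) -> "TaskSpec":
        expected_cats = {"target_a", "target_b", "attribute_good", "attribute_bad"}
        if set(self.categories) != expected_cats:
            missing = expected_cats - set(self.categories)
            raise ValueError(f"missing categories: {sorted(missing)}")
        seen: dict[str, str] = {}
        for key, cat in self.categories.items():
            for word in cat.stimuli:
                if word in seen:
                    raise ValueError(
                        f"stimulus {word!r} appears in both {seen[word]!r} and {key!r}"
                    )
                seen[word] = key
        if set(self.versions) != {1, 2}:
            raise ValueError(f"expected versions 1 and 2, got {sorted(self.versions)}")
        for version, blocks in self.versions.items():
            if len(blocks) != 7:
                raise ValueError(f"version {version}: expected 7 blocks, got {len(blocks)}")
            for i, b in enumerate(blocks, start=1):
                if b.block != i:
                    raise ValueError(f"version {version}: block order broken at position {i}")
                if b.trials != BLOCK_TRIAL_COUNTS[i - 1]:
                    raise ValueError(
                        f"version {version} block {i}: expected "
                        f"{BLOCK_TRIAL_COUNTS[i - 1]} trials, got {b.trials}"
                    )
            first_critical = blocks[2].phase
            expected_first = (
                "critical_compatible" if version == 1 else "critical_incompatible"
            )
            if first_critical != expected_first:
                raise ValueError(
                    f"version {version}: blocks 3-4 must be {expected_first}"
                )
            second = {
                "critical_compatible": "critical_incompatible",
                "critical_incompatible": "critical_compatible",
            }[expected_first]
            for pos, phase in ((3, expected_first), (5, second), (6, second)):
                if blocks[pos].phase != phase:
                    raise ValueError(
                        f"version {version} block {pos + 1}: expected phase {phase}"
                    )
            for pos in (0, 1, 4):
                if blocks[pos].phase != "practice":
                    raise ValueError(
                        f"version {version} block {pos + 1}: expected phase practice"
                    )
        return self

    def trials_per_version(self) -> int:
        return sum(b.trials for b in self.versions[1])

    def block_counts(self, version: int) -> dict[int, int]:
        return {b.block: b.trials for b in self.versions[version]}

    def phase_of(self, version: int, block: int) -> Phase:
        return self.versions[version][block - 1].phase

    def compatible_blocks(self, version: int) -> tuple[int, ...]:
        return tuple(
            b.block for b in self.versions[version] if b.phase == "critical_compatible"
        )

    def all_stimuli(self) -> frozenset[str]:
        return frozenset(w for cat in self.categories.values() for w in cat.stimuli)


@dataclass(frozen=True)
class Trial:
    """One categorization event within a block."""

    block: int
    trial_index: int
    stimulus: str
    latency_ms: float
    first_correct: bool

    def __post_init__(self) -> None:
        if not 1 <= self.block <= 7:
            raise TrialDataError(f"block {self.block} outside 1-7")
        if self.trial_index < 1:
            raise TrialDataError(f"trial_index {self.trial_index} < 1")
        if not self.latency_ms > 0:
            raise TrialDataError(f"latency_ms must be positive, got {self.latency_ms}")


@dataclass
class Session:
    """One participant's run: ordered trials plus the assigned task version."""

    participant_id: str
    version: int
    trials: list[Trial] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.version not in (1, 2):
            raise TrialDataError(f"version must be 1 or 2, got {self.version}")
        index_seen: set[tuple[int, int]] = set()
        for t in self.trials:
            key = (t.block, t.trial_index)
            if key in index_seen:
                raise TrialDataError(
                    f"participant {self.participant_id}: duplicate trial_index "
                    f"{t.trial_index} in block {t.block}"
                )
            index_seen.add(key)

    def block_trials(self, block: int) -> list[Trial]:
        return [t for t in self.trials if t.block == block]

    def block_counts(self) -> dict[int, int]:
        counts = {b: 0 for b in range(1, 8)}
        for t in self.trials:
            counts[t.block] += 1
        return counts


@dataclass
class SessionSet:
    """A cohort of sessions sharing one task specification."""

    task: TaskSpec
    sessions: list[Session] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.participant_id for s in self.sessions]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrialDataError(f"duplicate participant ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def get(self, participant_id: str) -> Session:
        for s in self.sessions:
            if s.participant_id == participant_id:
                return s
        raise KeyError(participant_id)


@dataclass
class ValidationReport:
    """Per-participant structural deviations from the task specification."""

    deviations: dict[str, list[str]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.deviations

    def __str__(self) -> str:
        if self.ok:
            return "all sessions conform to the task specification"
        lines = []
        for pid, msgs in self.deviations.items():
            for m in msgs:
                lines.append(f"{pid}: {m}")
        return "\n".join(lines)


def load_task_spec(source: str | Path | IO[str] | dict | None = None) -> TaskSpec:
    """Load a task specification from JSON; ``None`` loads the packaged default.

    Raises :class:`TaskSpecError` naming the offending field on any
    structural violation (wrong block count, duplicate stimulus, bad phase).
    """
    if source is None:
        text = resources.files("gviat.data").joinpath("default_task.json").read_text("utf-8")
        doc = json.loads(text)
    elif isinstance(source, dict):
        doc = source
    elif isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text("utf-8"))
    else:
        doc = json.load(source)
    try:
        return TaskSpec.model_validate(doc)
    except Exception as exc:  # pydantic ValidationError → domain error
        raise TaskSpecError(str(exc)) from exc


def read_trials(source: str | Path | IO[str], task: TaskSpec) -> SessionSet:
    """Read a trial-log CSV into a :class:`SessionSet`.

    Rows are preserved in file order within each participant.  Missing
    columns, non-numeric latencies and out-of-range blocks raise
    :class:`TrialDataError` naming the column or row.
    """
    df = pd.read_csv(
        source,
        dtype={"participant_id": str, "stimulus": str},
        float_precision="round_trip",
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialDataError(f"missing columns: {missing}")

    for col in ("version", "block", "trial_index", "latency_ms"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((coerced.isna()).idxmax()) + 2  # +1 header, +1 1-based
            raise TrialDataError(f"non-numeric {col} at row {row}")
        df[col] = coerced
    out_of_range = ~df["block"].between(1, 7)
    if out_of_range.any():
        row = int(out_of_range.idxmax()) + 2
        raise TrialDataError(f"block outside 1-7 at row {row}")

    sessions: list[Session] = []
    for pid, grp in df.groupby("participant_id", sort=False):
        versions = grp["version"].unique()
        if len(versions) != 1:
            raise TrialDataError(f"participant {pid}: inconsistent version values")
        trials = [
            Trial(
                block=int(r.block),
                trial_index=int(r.trial_index),
                stimulus=str(r.stimulus),
                latency_ms=float(r.latency_ms),
                first_correct=bool(int(r.first_correct)),
            )
            for r in grp.itertuples()
        ]
        sessions.append(Session(participant_id=str(pid), version=int(versions[0]), trials=trials))
    return SessionSet(task=task, sessions=sessions)


def write_trials(data: SessionSet, sink: str | Path | IO[str]) -> int:
    """Write a :class:`SessionSet` as canonical trial-log CSV; returns rows written.

    Canonical form: columns in :data:`TRIAL_COLUMNS` order, booleans as 0/1,
    UTF-8, comma-delimited, header always present.
    """
    rows = [
        {
            "participant_id": s.participant_id,
            "version": s.version,
            "block": t.block,
            "trial_index": t.trial_index,
            "stimulus": t.stimulus,
            "latency_ms": t.latency_ms,
            "first_correct": int(t.first_correct),
        }
        for s in data.sessions
        for t in s.trials
    ]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.to_csv(sink, index=False)
    return len(df)


def validate_sessions(data: SessionSet) -> ValidationReport:
    """Report structural deviations; empty report iff every session conforms.

    Checks per-block trial counts against the task spec for the session's
    version and flags stimuli not in any category.  Pure: the input is
    unchanged.
    """
    report = ValidationReport()
    known = data.task.all_stimuli()
    for s in data.sessions:
        msgs: list[str] = []
        expected = data.task.block_counts(s.version)
        observed = s.block_counts()
        for block in range(1, 8):
            if observed[block] != expected[block]:
                msgs.append(f"block {block}: {observed[block]}/{expected[block]} trials")
        unknown = sorted({t.stimulus for t in s.trials} - known)
        for word in unknown:
            msgs.append(f"unknown stimulus {word!r}")
        if msgs:
            report.deviations[s.participant_id] = msgs
    return report
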