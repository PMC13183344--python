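"""Typed readers and writers for every on-disk artifact the engine touches.

All downstream modules operate on the validated in-memory objects defined
here: beat-interval streams (:class:`RRSeries`), ecological momentary
assessment entries (:class:`EMAEntry`), the microintervention pool
(:class:`InterventionPool`) and the user-facing decision tree
(:class:`DecisionTree`).  File formats are deliberately plain — CSV for
time series, JSON for structured configuration, JSON-lines for event logs —
so that artifacts are diffable and survive any transport.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "RRSeries",
    "EMAEntry",
    "Microintervention",
    "InterventionPool",
    "TreeNode",
    "DecisionTree",
    "read_rr",
    "write_rr",
    "read_ema",
    "write_ema",
    "read_pool",
    "write_pool",
    "read_tree",
    "write_tree",
    "write_events",
    "read_events",
    "write_trial",
    "read_trial",
    "default_pool",
    "default_tree",
]

EMA_SLOTS = ("morning", "evening", "during_day")
CATEGORIES = ("psychoeducation", "training", "relaxation", "other-CBT")


class ValidationError(ValueError):
    """An in-memory object or parsed file violates a declared invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# RR interval series
# ---------------------------------------------------------------------------


@dataclass
class RRSeries:
    """Timestamped RR intervals (ms) for one participant.

    ``t`` holds beat timestamps in seconds since the epoch (UTC), strictly
    increasing; ``rr`` the beat-to-beat intervals in milliseconds; ``valid``
    marks samples that survived artifact screening.  Gaps (sensor off) are
    implicit: a missing time range simply contains no samples.
    """

    participant_id: str
    t: np.ndarray
    rr: np.ndarray
    valid: np.ndarray

    def __init__(self, participant_id: str, t, rr, valid=None):
        self.participant_id = str(participant_id)
        self.t = np.asarray(t, dtype=float)
        self.rr = np.asarray(rr, dtype=float)
        if valid is None:
            valid = np.ones(self.t.shape, dtype=bool)
        self.valid = np.asarray(valid, dtype=bool)
        self._check()

    def _check(self) -> None:
        if not (self.t.shape == self.rr.shape == self.valid.shape):
            raise ValidationError("t, rr and valid must have equal length")
        if self.t.ndim != 1:
            raise ValidationError("RRSeries arrays must be one-dimensional")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ValidationError("RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.t)

    def with_validity(self, valid: np.ndarray) -> "RRSeries":
        return RRSeries(self.participant_id, self.t, self.rr, valid)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RRSeries)
            and self.participant_id == other.participant_id
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.rr, other.rr)
            and np.array_equal(self.valid, other.valid)
        )


def _parse_timestamp(raw: str) -> float:
    raw = raw.strip()
    try:
        return float(raw)
    except ValueError:
        pass
    ts = pd.Timestamp(raw)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.timestamp()


def read_rr(path, participant_id: str) -> RRSeries:
    """Read an RR CSV (``timestamp,rr_ms``; ISO-8601 or epoch timestamps)."""
    t, rr = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, header required") from None
        cols = [c.strip().lower() for c in header]
        if cols[:2] != ["timestamp", "rr_ms"]:
            raise ParseError(f"{path}: line 1: expected header 'timestamp,rr_ms'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            try:
                ts = _parse_timestamp(row[0])
                iv = float(row[1])
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if iv <= 0:
                raise ValidationError(
                    f"{path}: line {lineno}: nonpositive RR interval {iv}"
                )
            if t and ts <= t[-1]:
                raise ValidationError(
                    f"{path}: line {lineno}: timestamps out of order"
                )
            t.append(ts)
            rr.append(iv)
    return RRSeries(participant_id, np.array(t), np.array(rr))


def write_rr(series: RRSeries, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "rr_ms"])
        for ts, iv in zip(series.t, series.rr):
            w.writerow([repr(float(ts)), repr(float(iv))])


# ---------------------------------------------------------------------------
# EMA entries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EMAEntry:
    """One ecological momentary assessment entry.

    Valence and arousal are 7-point Likert ratings of the current state
    (valence 1 = negative, 7 = positive).  ``event_valence``/``event_arousal``
    rate the most recent stress event and may be absent.  ``chronic_stress``
    is the daily chronic-stress item (1-7) collected in the morning/evening
    slots.
    """

    participant_id: str
    timestamp: float
    slot: str
    valence: int
    arousal: int
    event_valence: Optional[int] = None
    event_arousal: Optional[int] = None
    chronic_stress: Optional[float] = None

    def __post_init__(self):
        if self.slot not in EMA_SLOTS:
            raise ValidationError(f"unknown EMA slot {self.slot!r}")
        for name in ("valence", "arousal", "event_valence", "event_arousal"):
            v = getattr(self, name)
            if v is None:
                continue
            if not (1 <= int(v) <= 7):
                raise ValidationError(f"{name}={v} outside the 1-7 scale")
        if self.chronic_stress is not None and not (1 <= self.chronic_stress <= 7):
            raise ValidationError(
                f"chronic_stress={self.chronic_stress} outside the 1-7 scale"
            )


_EMA_COLUMNS = [
    "participant_id",
    "timestamp",
    "slot",
    "valence",
    "arousal",
    "event_valence",
    "event_arousal",
    "chronic_stress",
]


def read_ema(path) -> list[EMAEntry]:
    """Read an EMA CSV; entries are returned sorted by timestamp.

    Enforces the schedule invariant that the morning and evening slots occur
    at most once per participant-day.
    """
    entries: list[EMAEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(f"{path}: empty file, header required")
        missing = {"participant_id", "timestamp", "slot", "valence", "arousal"} - set(
            reader.fieldnames
        )
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            def _opt_int(key):
                raw = (row.get(key) or "").strip()
                return int(float(raw)) if raw else None

            try:
                entry = EMAEntry(
                    participant_id=row["participant_id"].strip(),
                    timestamp=_parse_timestamp(row["timestamp"]),
                    slot=row["slot"].strip(),
                    valence=int(float(row["valence"])),
                    arousal=int(float(row["arousal"])),
                    event_valence=_opt_int("event_valence"),
                    event_arousal=_opt_int("event_arousal"),
                    chronic_stress=(
                        float(row["chronic_stress"])
                        if (row.get("chronic_stress") or "").strip()
                        else None
                    ),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            entries.append(entry)
    entries.sort(key=lambda e: (e.participant_id, e.timestamp))
    seen: set[tuple[str, int, str]] = set()
    for e in entries:
        if e.slot in ("morning", "evening"):
            day = int(e.timestamp // 86400)
            key = (e.participant_id, day, e.slot)
            if key in seen:
                raise ValidationError(
                    f"duplicate {e.slot} entry for {e.participant_id} on day {day}"
                )
            seen.add(key)
    entries.sort(key=lambda e: e.timestamp)
    return entries


def write_ema(entries: Sequence[EMAEntry], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=_EMA_COLUMNS)
        w.writeheader()
        for e in entries:
            row = dataclasses.asdict(e)
            w.writerow({k: ("" if row[k] is None else row[k]) for k in _EMA_COLUMNS})


# ---------------------------------------------------------------------------
# Intervention pool and decision tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Microintervention:
    id: str
    category: str
    presentation_format: str = "text"
    initial_weight: float = 1.0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.initial_weight < 0:
            raise ValidationError("initial_weight must be nonnegative")


@dataclass
class InterventionPool:
    """The catalogue of short CBT exercises the app can deliver."""

    items: tuple[Microintervention, ...]

    def __init__(self, items: Iterable[Microintervention]):
        self.items = tuple(items)
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValidationError("intervention ids must be unique")
        if self.items and all(it.initial_weight == 0 for it in self.items):
            raise ValidationError("at least one initial weight must be positive")

    def ids(self) -> list[str]:
        return [it.id for it in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, iid: str) -> Microintervention:
        for it in self.items:
            if it.id == iid:
                return it
        raise KeyError(iid)

    def __eq__(self, other) -> bool:
        return isinstance(other, InterventionPool) and self.items == other.items


@dataclass
class TreeNode:
    label: str
    children: list["TreeNode"] = field(default_factory=list)
    leaf_ids: frozenset[str] = frozenset()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class DecisionTree:
    """User-navigable branching structure narrowing the eligible pool.

    Internal nodes carry a choice label; each leaf carries a nonempty set of
    microintervention ids.  Validated against a pool: leaves may only cite
    pool ids and every pool id must be reachable from at least one leaf.
    """

    root: TreeNode

    def leaves(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(node.children)

    def validate_against(self, pool: InterventionPool) -> None:
        pool_ids = set(pool.ids())
        covered: set[str] = set()
        for leaf in self.leaves():
            if not leaf.leaf_ids:
                raise ValidationError(f"leaf {leaf.label!r} carries no ids")
            unknown = leaf.leaf_ids - pool_ids
            if unknown:
                raise ValidationError(
                    f"leaf {leaf.label!r} references unknown ids {sorted(unknown)}"
                )
            covered |= leaf.leaf_ids
        if covered != pool_ids:
            raise ValidationError(
                f"pool ids unreachable from any leaf: {sorted(pool_ids - covered)}"
            )

    def __eq__(self, other) -> bool:
        def as_tuple(n: TreeNode):
            return (n.label, tuple(as_tuple(c) for c in n.children),
                    frozenset(n.leaf_ids))

        return isinstance(other, DecisionTree) and as_tuple(self.root) == as_tuple(
            other.root
        )


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"label": node.label, "interventions": sorted(node.leaf_ids)}
    return {"label": node.label, "children": [_node_to_dict(c) for c in node.children]}


def _node_from_dict(d: dict) -> TreeNode:
    if "children" in d:
        return TreeNode(
            label=d["label"], children=[_node_from_dict(c) for c in d["children"]]
        )
    return TreeNode(label=d["label"], leaf_ids=frozenset(d["interventions"]))


def read_pool(path) -> InterventionPool:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return InterventionPool(
        Microintervention(
            id=it["id"],
            category=it["category"],
            presentation_format=it.get("presentation_format", "text"),
            initial_weight=float(it.get("initial_weight", 1.0)),
        )
        for it in data["items"]
    )


def write_pool(pool: InterventionPool, path) -> None:
    data = {"items": [dataclasses.asdict(it) for it in pool.items]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)


def read_tree(path, pool: Optional[InterventionPool] = None) -> DecisionTree:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    tree = DecisionTree(root=_node_from_dict(data))
    if pool is not None:
        tree.validate_against(pool)
    return tree


def write_tree(tree: DecisionTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_node_to_dict(tree.root), fh, indent=1)


# ---------------------------------------------------------------------------
# Event logs and trial records
# ---------------------------------------------------------------------------


def write_events(events: Sequence, path) -> None:
    """Write stress events as JSON-lines, one event per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict()) + "\n")


def read_events(path) -> list:
    from .trigger_engine import StressEvent

    events = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                events.append(StressEvent.from_dict(json.loads(line)))
    return events


def write_trial(record, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(record.to_dict(), fh)


def read_trial(path):
    from .trial_simulator import TrialRecord

    with open(path, encoding="utf-8") as fh:
        return TrialRecord.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------


def default_pool() -> InterventionPool:
    """The packaged 179-item microintervention pool.

    Content text is synthetic placeholder metadata: ids, a CBT subarea
    category and a presentation format, with uniform initial weights.
    """
    with resources.files("stressjitai.data").joinpath("default_pool.json").open(
        encoding="utf-8"
    ) as fh:
        data = json.load(fh)
    return InterventionPool(
        Microintervention(
            id=it["id"],
            category=it["category"],
            presentation_format=it["presentation_format"],
            initial_weight=float(it["initial_weight"]),
        )
        for it in data["items"]
    )


def default_tree() -> DecisionTree:
    """The packaged default decision tree over the default pool.

    Four branches named after everyday occupational stressor situations;
    each leaf spans all CBT categories so that weighted selection, not the
    branching, carries the personalization.
    """
    with resources.files("stressjitai.data").joinpath("default_tree.json").open(
        encoding="utf-8"
    ) as fh:
        data = json.load(fh)
    return DecisionTree(root=_node_from_dict(data))
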