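"""Personalized stress-event detection from HRV windows and EMA entries.

Physiological triggering uses per-user clamped-quantile thresholds: the
LF/HF trigger level is the 75th percentile of the user's own window history
but never below 1.2, and the RMSSD trigger level is the 25th percentile but
never above 50 ms.  A stress event is annotated when *both* values cross
their thresholds (LF/HF at or above, RMSSD at or below) in two consecutive
5-minute windows.  Subjective triggering is unpersonalized: an EMA entry
with valence <= 3 on the 7-point scale (1 = negative) fires.

With less history than ``min_history`` windows the clamp values themselves
(1.2, 50 ms) act as fixed thresholds, so triggering degrades gracefully for
new users.  After an event a refractory period (default 30 minutes)
suppresses re-annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .hrv_core import HRVWindowFeatures
from .io_formats import EMAEntry

__all__ = [
    "LFHF_FLOOR",
    "RMSSD_CEILING",
    "PersonalThresholds",
    "StressEvent",
    "personal_thresholds",
    "detect_physio_events",
    "detect_subjective_trigger",
    "PhysioTriggerScanner",
]

LFHF_FLOOR = 1.2
RMSSD_CEILING = 50.0
DEFAULT_MIN_HISTORY = 12
DEFAULT_REFRACTORY_S = 1800.0


@dataclass(frozen=True)
class PersonalThresholds:
    """Clamped-quantile trigger thresholds for one user.

    Trigger when LF/HF >= ``theta_lfhf`` and RMSSD <= ``theta_rmssd``.
    """

    theta_lfhf: float
    theta_rmssd: float
    history_n: int
    computed_at: Optional[float] = None

    def __post_init__(self):
        if self.theta_lfhf < LFHF_FLOOR - 1e-12:
            raise ValueError(f"theta_lfhf below the {LFHF_FLOOR} floor")
        if self.theta_rmssd > RMSSD_CEILING + 1e-12:
            raise ValueError(f"theta_rmssd above the {RMSSD_CEILING} ms ceiling")
        if self.history_n < 0:
            raise ValueError("history_n must be nonnegative")


@dataclass(frozen=True)
class StressEvent:
    participant_id: str
    kind: str  # "physiological" | "subjective"
    start: float
    windows: tuple[int, ...] = ()
    ema_index: Optional[int] = None
    theta_lfhf: Optional[float] = None
    theta_rmssd: Optional[float] = None
    valence_cutoff: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("physiological", "subjective"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "physiological" and len(self.windows) < 2:
            raise ValueError("physiological events need >= 2 consecutive windows")

    def to_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "kind": self.kind,
            "start": self.start,
            "windows": list(self.windows),
        }
        for k in ("ema_index", "theta_lfhf", "theta_rmssd", "valence_cutoff"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StressEvent":
        return cls(
            participant_id=d["participant_id"],
            kind=d["kind"],
            start=d["start"],
            windows=tuple(d.get("windows", ())),
            ema_index=d.get("ema_index"),
            theta_lfhf=d.get("theta_lfhf"),
            theta_rmssd=d.get("theta_rmssd"),
            valence_cutoff=d.get("valence_cutoff"),
        )


def _quantile(values: np.ndarray, q: float) -> float:
    # sorted-order statistic with linear interpolation (numpy "linear")
    return float(np.quantile(np.asarray(values, dtype=float), q))


def personal_thresholds(
    history: Sequence[HRVWindowFeatures],
    min_history: int = DEFAULT_MIN_HISTORY,
    computed_at: Optional[float] = None,
) -> PersonalThresholds:
    """Current clamped-quantile thresholds from a user's ok-quality history.

    theta_lfhf = max(Q75 of LF/HF history, 1.2); theta_rmssd = min(Q25 of
    RMSSD history, 50 ms).  With fewer than ``min_history`` usable windows
    the clamp values are returned unchanged.
    """
    lfhf = np.array([w.lf_hf for w in history if w.ok and w.lf_hf is not None])
    rms = np.array([w.rmssd for w in history if w.ok and w.rmssd is not None])
    n = min(len(lfhf), len(rms))
    if n < max(min_history, 1):
        return PersonalThresholds(LFHF_FLOOR, RMSSD_CEILING, n, computed_at)
    return PersonalThresholds(
        theta_lfhf=max(_quantile(lfhf, 0.75), LFHF_FLOOR),
        theta_rmssd=min(_quantile(rms, 0.25), RMSSD_CEILING),
        history_n=n,
        computed_at=computed_at,
    )


def _qualifies(w: HRVWindowFeatures, th: PersonalThresholds) -> bool:
    return (
        w.ok
        and w.lf_hf is not None
        and w.rmssd is not None
        and w.lf_hf >= th.theta_lfhf
        and w.rmssd <= th.theta_rmssd
    )


class PhysioTriggerScanner:
    """Incremental two-consecutive-window trigger with refractory logic.

    Feed windows in time order via :meth:`push`; an event is returned at the
    second of two consecutive qualifying windows.  Two windows are
    consecutive only when their starts differ by exactly ``hop_s`` (a data
    gap breaks the run).  After an event, windows starting within
    ``refractory_s`` of the event start are suppressed and do not seed a
    new run.
    """

    def __init__(
        self,
        participant_id: str,
        hop_s: float = 300.0,
        refractory_s: float = DEFAULT_REFRACTORY_S,
    ):
        self.participant_id = participant_id
        self.hop_s = hop_s
        self.refractory_s = refractory_s
        self._prev: Optional[tuple[int, HRVWindowFeatures]] = None
        self._prev_qualified = False
        self._refractory_until = -np.inf
        self._count = 0

    def push(
        self, w: HRVWindowFeatures, thresholds: PersonalThresholds
    ) -> Optional[StressEvent]:
        idx = self._count
        self._count += 1
        in_refractory = w.window_start < self._refractory_until
        q = _qualifies(w, thresholds) and not in_refractory
        event = None
        if q and self._prev_qualified and self._prev is not None:
            prev_idx, prev_w = self._prev
            if abs(w.window_start - prev_w.window_start - self.hop_s) < 1e-6:
                event = StressEvent(
                    participant_id=self.participant_id,
                    kind="physiological",
                    start=prev_w.window_start,
                    windows=(prev_idx, idx),
                    theta_lfhf=thresholds.theta_lfhf,
                    theta_rmssd=thresholds.theta_rmssd,
                )
                self._refractory_until = event.start + self.refractory_s
                q = False  # the pair is consumed; a fresh run must build up
        self._prev = (idx, w)
        self._prev_qualified = q
        return event


def detect_physio_events(
    features: Sequence[HRVWindowFeatures],
    thresholds_fn: Callable[[int, Sequence[HRVWindowFeatures]], PersonalThresholds],
    participant_id: str = "",
    hop_s: float = 300.0,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> list[StressEvent]:
    """Scan a time-ordered window sequence for physiological stress events.

    ``thresholds_fn(i, features)`` must return the thresholds current at
    window ``i`` (typically recomputed from the history before that
    window); use ``lambda i, f: personal_thresholds(f[:i])`` for the
    expanding-history default.
    """
    scanner = PhysioTriggerScanner(participant_id, hop_s, refractory_s)
    events = []
    for i, w in enumerate(features):
        ev = scanner.push(w, thresholds_fn(i, features))
        if ev is not None:
            events.append(ev)
    return events


def detect_subjective_trigger(entry: EMAEntry, cutoff: int = 3) -> bool:
    """True iff the entry's momentary valence is at or below the cutoff."""
    return entry.valence <= cutoff
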