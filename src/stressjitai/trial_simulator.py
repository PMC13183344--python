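"""End-to-end synthetic two-phase micro-trial of the adaptive stress app.

The simulator generates a cohort of synthetic employees, each with a latent
occupational stress process, and runs the full system — HRV windowing,
personalized triggering, decision-tree delivery, feedback learning — day by
day over two 3-week phases.  In phase 1 every participant runs on the
shared (low-personalization) cohort weight table; at the phase-2 boundary
the cohort is randomized 1:1 into *high* (individual table) and *low*
(shared table) arms.

The physiological generator is built for analytic controllability rather
than cardiovascular realism: RR intervals are a stress-shifted mean plus
two sinusoidal modulations (one inside the LF band, one inside the HF band)
plus Gaussian beat-to-beat jitter.  Under latent stress the HF amplitude
and the jitter shrink while the LF amplitude grows, so RMSSD falls and
LF/HF rises — the exact signature the trigger engine looks for — and the
calm-state amplitudes are solved in closed form so that windowed RMSSD and
LF/HF recover each profile's targets.

Latent stress is a calm/stressed regime process: episode onsets are
Bernoulli per 5-minute step (concentrated in 09:00-17:00 on weekdays),
durations geometric and intensity drawn per episode, which is the standard
two-state Markov regime written as an episode overlay.  Delivered
interventions subtract an exponentially decaying amount from the latent
intensity, scaled by the participant's responsiveness and by whether the
intervention's CBT category matches their latent preference; feedback
ratings are a noisy monotone function of the same match, which is what
makes preference learning recoverable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import evaluation
from .hrv_core import Window, sdrr as _sdrr, rmssd as _rmssd, lf_hf as _lf_hf
from .hrv_core import HRVWindowFeatures
from .io_formats import (
    CATEGORIES,
    DecisionTree,
    EMAEntry,
    InterventionPool,
    Microintervention,
    RRSeries,
    default_pool,
    default_tree,
)
from .intervention_engine import (
    HIGH,
    LOW,
    DEFAULT_LEARNING_RATE,
    DeliveryRecord,
    FeedbackRating,
    WeightTable,
    deliver,
    update_weights,
)
from .trigger_engine import (
    DEFAULT_MIN_HISTORY,
    DEFAULT_REFRACTORY_S,
    PhysioTriggerScanner,
    StressEvent,
    detect_subjective_trigger,
    personal_thresholds,
)

__all__ = [
    "ParticipantProfile",
    "LatentStressState",
    "TrialConfig",
    "ParticipantRecord",
    "TrialRecord",
    "make_cohort",
    "simulate_day",
    "apply_intervention_effect",
    "generate_rating",
    "run_trial",
]

BLOCK_S = 300.0
BLOCKS_PER_DAY = 288
TREE_BRANCHES = ("acute-tension", "rumination", "overload", "interpersonal")
LF_TONE_HZ = 0.10
HF_TONE_HZ = 0.25
LF_BANDWIDTH = 0.15 - 0.04
HF_BANDWIDTH = 0.40 - 0.15


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent ground truth for one synthetic employee."""

    participant_id: str
    baseline_rr_mean: float  # ms
    baseline_rmssd: float  # ms, calm-state windowed RMSSD target
    calm_lfhf: float  # calm-state windowed LF/HF target
    stress_reactivity: float
    preferred_category: str
    stressor_branch: str
    intervention_responsiveness: float
    ema_compliance: float
    sensor_compliance: float

    def __post_init__(self):
        if not (600.0 <= self.baseline_rr_mean <= 1100.0):
            raise ValueError("baseline_rr_mean must lie in [600, 1100] ms")
        for name in ("intervention_responsiveness", "ema_compliance", "sensor_compliance"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.stress_reactivity <= 0:
            raise ValueError("stress_reactivity must be positive")


@dataclass
class LatentStressState:
    """Current latent stress regime carried across simulated days."""

    regime: str = "calm"  # "calm" | "stressed"
    intensity: float = 0.0

    def __post_init__(self):
        if self.regime not in ("calm", "stressed"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")


@dataclass
class TrialConfig:
    """Every tunable of the simulated study, with study-protocol defaults."""

    n_participants: int = 46
    phase_weeks: int = 3
    seed: int = 0
    # EMA schedule
    ema_during_day: int = 3
    # sensor wear
    sensor_hours_per_day: float = 23.0  # continuous wear minus the daily 1-h break
    window_s: float = BLOCK_S
    min_beats: int = 100
    # trigger engine
    min_history: int = DEFAULT_MIN_HISTORY
    refractory_s: float = DEFAULT_REFRACTORY_S
    valence_cutoff: int = 3
    # intervention engine
    learning_rate: float = DEFAULT_LEARNING_RATE
    feedback_probability: float = 0.9
    # latent stress process (per 5-min step)
    p_onset_work: float = 0.012
    p_onset_off: float = 0.002
    p_offset: float = 1.0 / 6.0  # mean episode length 30 min
    intensity_range: tuple[float, float] = (0.8, 1.8)
    work_start_h: float = 9.0
    work_end_h: float = 17.0
    s_max: float = 3.0
    # ground-truth intervention effect model
    effect_size: float = 0.6  # latent-stress drop at delivery for a full match
    effect_window_s: float = 1800.0
    effect_halflife_s: float = 900.0
    partial_match: float = 0.25
    # physiology
    rr_stress_drop: float = 80.0  # ms of mean-RR shortening per unit stress
    stress_mod_gain: float = 0.5  # amplitude scaling rate per unit stress
    # HF tone amplitude as a fraction of the RMSSD target; high tone dominance
    # keeps the per-window LF/HF estimator CV near 10%, so calm windows stay
    # clear of the 1.2 trigger floor
    hf_amp_fraction: float = 0.8
    # bookkeeping
    keep_rr: bool = True

    @property
    def n_weeks(self) -> int:
        return 2 * self.phase_weeks

    @property
    def n_days(self) -> int:
        return 7 * self.n_weeks


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def make_cohort(
    n: int, seed: int | np.random.SeedSequence
) -> list[ParticipantProfile]:
    """Draw ``n`` heterogeneous participant profiles, reproducibly."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 participants")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        profiles.append(
            ParticipantProfile(
                participant_id=f"P{i + 1:03d}",
                baseline_rr_mean=float(np.clip(rng.normal(850, 70), 650, 1050)),
                baseline_rmssd=float(np.clip(rng.normal(22, 5), 10, 40)),
                # calm-state LF/HF sits below the 1.2 trigger floor: the floor
                # is a guard against annotating unstressed users, and stress
                # multiplies the ratio several-fold well past it
                calm_lfhf=float(np.clip(rng.normal(0.88, 0.05), 0.78, 0.98)),
                stress_reactivity=float(np.clip(rng.lognormal(0.0, 0.25), 0.5, 2.0)),
                preferred_category=str(rng.choice(CATEGORIES)),
                stressor_branch=str(rng.choice(TREE_BRANCHES)),
                intervention_responsiveness=float(rng.uniform(0.4, 1.0)),
                ema_compliance=float(rng.uniform(0.85, 1.0)),
                sensor_compliance=float(rng.uniform(0.45, 0.8)),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Physiological generator calibration
# ---------------------------------------------------------------------------


def _calibrate_generator(profile: ParticipantProfile, config: TrialConfig):
    """Solve calm-state tone amplitudes and jitter from the profile targets.

    For a tachogram sampled every tau seconds, a sinusoid of amplitude A at
    frequency f contributes 2*A^2*sin^2(pi*f*tau) to the mean squared
    successive difference and A^2/2 to its band power, while white jitter of
    variance sigma^2 contributes 2*sigma^2 to the former and spreads
    sigma^2 uniformly up to the Nyquist frequency 1/(2*tau).  Fixing the HF
    amplitude as a fraction of the RMSSD target leaves two equations
    (RMSSD, LF/HF) in two unknowns (sigma, LF amplitude).
    """
    R = profile.baseline_rmssd
    r0 = profile.calm_lfhf
    tau = profile.baseline_rr_mean / 1000.0
    f_nyq = 1.0 / (2.0 * tau)
    s_lf = math.sin(math.pi * LF_TONE_HZ * tau)
    s_hf = math.sin(math.pi * HF_TONE_HZ * tau)
    a_hf = config.hf_amp_fraction * R
    num = R**2 * (1.0 - 2.0 * s_hf**2 * config.hf_amp_fraction**2
                  - 2.0 * s_lf**2 * r0 * config.hf_amp_fraction**2)
    den = 2.0 + 4.0 * s_lf**2 * (r0 * HF_BANDWIDTH - LF_BANDWIDTH) / f_nyq
    sigma2 = num / den
    if sigma2 <= 0:
        raise ValueError("infeasible RMSSD / LF-HF target combination")
    a_lf2 = r0 * a_hf**2 + 2.0 * sigma2 * (r0 * HF_BANDWIDTH - LF_BANDWIDTH) / f_nyq
    return math.sqrt(sigma2), a_lf2**0.5, a_hf


def _rr_block(
    profile: ParticipantProfile,
    config: TrialConfig,
    calib: tuple[float, float, float],
    block_start_s: float,
    s_level: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Beat timestamps and RR values (ms) for one 5-minute block."""
    sigma, a_lf, a_hf = calib
    g = 1.0 + config.stress_mod_gain * s_level
    mean_rr = max(profile.baseline_rr_mean - config.rr_stress_drop * s_level, 450.0)
    n_est = int(BLOCK_S * 1000.0 / mean_rr) + 2
    k = np.arange(n_est)
    t_approx = block_start_s + k * mean_rr / 1000.0
    rr = (
        mean_rr
        + (a_lf * g) * np.sin(2 * np.pi * LF_TONE_HZ * t_approx)
        + (a_hf / g) * np.sin(2 * np.pi * HF_TONE_HZ * t_approx + 1.0)
        + (sigma / g) * rng.standard_normal(n_est)
    )
    rr = np.clip(rr, 320.0, 1900.0)
    t = block_start_s + np.cumsum(rr) / 1000.0
    keep = t < block_start_s + BLOCK_S
    return t[keep], rr[keep]


# ---------------------------------------------------------------------------
# Latent stress process
# ---------------------------------------------------------------------------


def _latent_day(
    profile: ParticipantProfile,
    state: LatentStressState,
    day_index: int,
    config: TrialConfig,
    rng: np.random.Generator,
    forced_episodes: Sequence[tuple[int, int, float]] = (),
) -> tuple[np.ndarray, LatentStressState]:
    """Latent stress on the day's 5-minute grid, plus the carried-over state.

    ``forced_episodes`` is a sequence of (start_block, n_blocks, intensity)
    overrides used for controlled experiments.
    """
    weekday = day_index % 7 < 5
    hours = np.arange(BLOCKS_PER_DAY) * BLOCK_S / 3600.0
    p = np.full(BLOCKS_PER_DAY, config.p_onset_off)
    if weekday:
        work = (hours >= config.work_start_h) & (hours < config.work_end_h)
        p[work] = config.p_onset_work
    s = np.zeros(BLOCKS_PER_DAY)
    episodes: list[tuple[int, int, float]] = []
    if state.regime == "stressed":
        dur = int(rng.geometric(config.p_offset))
        episodes.append((0, dur, state.intensity))
    onset = np.flatnonzero(rng.random(BLOCKS_PER_DAY) < p)
    lo, hi = config.intensity_range
    for b in onset:
        if any(b0 <= b < b0 + d for b0, d, _ in episodes):
            continue
        dur = int(rng.geometric(config.p_offset))
        inten = float(
            np.clip(rng.uniform(lo, hi) * profile.stress_reactivity, 0, config.s_max)
        )
        episodes.append((int(b), dur, inten))
    episodes.extend((int(b), int(d), float(i)) for b, d, i in forced_episodes)
    end_state = LatentStressState()
    for b0, d, inten in episodes:
        s[b0 : b0 + d] = np.maximum(s[b0 : b0 + d], inten)
        if b0 + d > BLOCKS_PER_DAY and inten >= end_state.intensity:
            end_state = LatentStressState("stressed", inten)
    return s, end_state


def apply_intervention_effect(
    s_grid: np.ndarray,
    block_idx: int,
    intervention: Microintervention,
    profile: ParticipantProfile,
    config: TrialConfig,
) -> np.ndarray:
    """Subtract the delivered exercise's decaying effect from latent stress.

    The drop at the delivery instant is ``effect_size * responsiveness``
    for a category match (``partial_match`` of that otherwise) and decays
    exponentially with the configured half-life over ``effect_window_s``.
    """
    match = 1.0 if intervention.category == profile.preferred_category else config.partial_match
    amount = config.effect_size * profile.intervention_responsiveness * match
    if amount <= 0:
        return s_grid
    n_blocks = max(int(config.effect_window_s / BLOCK_S), 1)
    idx = np.arange(block_idx, min(block_idx + n_blocks, len(s_grid)))
    dt = (idx - block_idx) * BLOCK_S
    decay = amount * np.power(0.5, dt / config.effect_halflife_s)
    out = s_grid.copy()
    out[idx] = np.maximum(out[idx] - decay, 0.0)
    return out


def generate_rating(
    intervention: Microintervention,
    profile: ParticipantProfile,
    rng: np.random.Generator,
) -> int:
    """Noisy 1-5 feedback rating, higher when the CBT category matches."""
    match = intervention.category == profile.preferred_category
    shift = (1.6 if match else -1.2) * profile.intervention_responsiveness
    raw = 3.0 + shift + rng.normal(0, 0.8)
    return int(np.clip(round(raw), 1, 5))


# ---------------------------------------------------------------------------
# One simulated day (no triggering) — generator surface for direct use
# ---------------------------------------------------------------------------


def _ema_times(config: TrialConfig, rng: np.random.Generator) -> list[tuple[str, float]]:
    """Slot labels and within-day second offsets of the day's EMA prompts."""
    times = [("morning", 7.5 * 3600.0), ("evening", 21.0 * 3600.0)]
    if config.ema_during_day > 0:
        anchors = np.linspace(10.0, 17.5, config.ema_during_day) * 3600.0
        for a in anchors:
            times.append(("during_day", float(a + rng.uniform(-600, 600))))
    return sorted(times, key=lambda x: x[1])


def _ema_entry(
    profile: ParticipantProfile,
    slot: str,
    day_start: float,
    t_off: float,
    s_grid: np.ndarray,
    rng: np.random.Generator,
) -> EMAEntry:
    b = min(int(t_off / BLOCK_S), BLOCKS_PER_DAY - 1)
    s_now = float(s_grid[b])
    valence = int(np.clip(round(5.6 - 1.8 * s_now + rng.normal(0, 0.7)), 1, 7))
    arousal = int(np.clip(round(3.1 + 1.2 * s_now + rng.normal(0, 0.8)), 1, 7))
    ev_val = ev_ar = None
    chronic = None
    if slot == "during_day":
        lookback = s_grid[max(b - 24, 0) : b + 1]
        s_event = float(lookback.max()) if len(lookback) else 0.0
        ev_val = int(np.clip(round(4.4 - 0.8 * s_event + rng.normal(0, 0.6)), 1, 7))
        ev_ar = int(np.clip(round(3.9 + 0.8 * s_event + rng.normal(0, 0.6)), 1, 7))
    else:
        s_day = float(s_grid[: b + 1].mean())
        chronic = float(np.clip(3.0 + 0.6 * s_day + rng.normal(0, 0.5), 1.0, 7.0))
    return EMAEntry(
        participant_id=profile.participant_id,
        timestamp=day_start + t_off,
        slot=slot,
        valence=valence,
        arousal=arousal,
        event_valence=ev_val,
        event_arousal=ev_ar,
        chronic_stress=chronic,
    )


def _wear_blocks(
    config: TrialConfig, rng: np.random.Generator, wearing: bool
) -> np.ndarray:
    """Indices of blocks with the sensor on: the wear window minus a 1-h break."""
    if not wearing or config.sensor_hours_per_day <= 0:
        return np.array([], dtype=int)
    n_wear = min(int(round(config.sensor_hours_per_day * 12)), BLOCKS_PER_DAY)
    start = 0 if n_wear >= BLOCKS_PER_DAY - 12 else int(rng.integers(7 * 12, max(8 * 12, BLOCKS_PER_DAY - n_wear)))
    blocks = np.arange(start, min(start + n_wear + 12, BLOCKS_PER_DAY))
    break_start = int(rng.integers(blocks[0], max(blocks[0] + 1, blocks[-1] - 11)))
    mask = (blocks < break_start) | (blocks >= break_start + 12)
    return blocks[mask][:n_wear]


def simulate_day(
    profile: ParticipantProfile,
    state: LatentStressState,
    day_index: int,
    config: TrialConfig,
    rng: np.random.Generator,
    interventions_today: Sequence[tuple[int, Microintervention]] = (),
    forced_episodes: Sequence[tuple[int, int, float]] = (),
) -> tuple[RRSeries, list[EMAEntry], LatentStressState]:
    """Generate one participant-day: RR stream, EMA entries, next state.

    ``interventions_today`` lists (block_index, intervention) deliveries
    whose ground-truth effect is applied to the latent path.  This is the
    open-loop generator surface; :func:`run_trial` drives the closed loop
    in which deliveries arise from the trigger engine itself.
    """
    day_start = day_index * 86400.0
    s_grid, next_state = _latent_day(
        profile, state, day_index, config, rng, forced_episodes
    )
    for block_idx, intervention in interventions_today:
        s_grid = apply_intervention_effect(
            s_grid, block_idx, intervention, profile, config
        )
    calib = _calibrate_generator(profile, config)
    wearing = rng.random() < profile.sensor_compliance
    blocks = _wear_blocks(config, rng, wearing)
    ts, rrs = [], []
    for b in blocks:
        t, rr = _rr_block(
            profile, config, calib, day_start + b * BLOCK_S, float(s_grid[b]), rng
        )
        ts.append(t)
        rrs.append(rr)
    series = RRSeries(
        profile.participant_id,
        np.concatenate(ts) if ts else np.array([]),
        np.concatenate(rrs) if rrs else np.array([]),
    )
    entries = []
    for slot, t_off in _ema_times(config, rng):
        if rng.random() < profile.ema_compliance:
            entries.append(_ema_entry(profile, slot, day_start, t_off, s_grid, rng))
    return series, entries, next_state


# ---------------------------------------------------------------------------
# Full trial
# ---------------------------------------------------------------------------


@dataclass
class ParticipantRecord:
    profile: ParticipantProfile
    arm: str  # "high" | "low" (phase-2 assignment)
    rr: Optional[RRSeries]
    ema: list[EMAEntry]
    features: list[HRVWindowFeatures]
    events: list[StressEvent]
    deliveries: list[dict]
    ratings: list[FeedbackRating]
    weekly: dict[str, evaluation.WeeklySeries]
    weekly_latent: dict[int, float]


@dataclass
class TrialRecord:
    config: TrialConfig
    participants: list[ParticipantRecord]

    def groups(self) -> dict[str, str]:
        return {p.profile.participant_id: p.arm for p in self.participants}

    def weekly_by_variable(self) -> dict[str, list[evaluation.WeeklySeries]]:
        out: dict[str, list[evaluation.WeeklySeries]] = {}
        for p in self.participants:
            for var, series in p.weekly.items():
                out.setdefault(var, []).append(series)
        return out

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["intensity_range"] = list(self.config.intensity_range)
        return {
            "config": cfg,
            "participants": [
                {
                    "profile": asdict(p.profile),
                    "arm": p.arm,
                    "rr": None
                    if p.rr is None
                    else {"t": p.rr.t.tolist(), "rr": p.rr.rr.tolist(),
                          "valid": p.rr.valid.tolist()},
                    "ema": [asdict(e) for e in p.ema],
                    "features": [asdict(f) for f in p.features],
                    "events": [e.to_dict() for e in p.events],
                    "deliveries": p.deliveries,
                    "ratings": [asdict(r) for r in p.ratings],
                    "weekly": {
                        var: {
                            "values": {str(k): v for k, v in s.values.items()},
                            "missing_fraction": s.missing_fraction,
                        }
                        for var, s in p.weekly.items()
                    },
                    "weekly_latent": {str(k): v for k, v in p.weekly_latent.items()},
                }
                for p in self.participants
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        cfg = dict(d["config"])
        cfg["intensity_range"] = tuple(cfg["intensity_range"])
        config = TrialConfig(**cfg)
        participants = []
        for pd_ in d["participants"]:
            profile = ParticipantProfile(**pd_["profile"])
            rr = None
            if pd_["rr"] is not None:
                rr = RRSeries(
                    profile.participant_id,
                    np.array(pd_["rr"]["t"]),
                    np.array(pd_["rr"]["rr"]),
                    np.array(pd_["rr"]["valid"], dtype=bool),
                )
            participants.append(
                ParticipantRecord(
                    profile=profile,
                    arm=pd_["arm"],
                    rr=rr,
                    ema=[EMAEntry(**e) for e in pd_["ema"]],
                    features=[HRVWindowFeatures(**f) for f in pd_["features"]],
                    events=[StressEvent.from_dict(e) for e in pd_["events"]],
                    deliveries=pd_["deliveries"],
                    ratings=[FeedbackRating(**r) for r in pd_["ratings"]],
                    weekly={
                        var: evaluation.WeeklySeries(
                            participant_id=profile.participant_id,
                            variable=var,
                            values={int(k): v for k, v in s["values"].items()},
                            missing_fraction=s["missing_fraction"],
                        )
                        for var, s in pd_["weekly"].items()
                    },
                    weekly_latent={int(k): v for k, v in pd_["weekly_latent"].items()},
                )
            )
        return cls(config=config, participants=participants)


class _ParticipantSim:
    """Closed-loop state for one participant across the 42 simulated days.

    Each participant owns two independent substreams: ``rng_env`` drives the
    environment (latent stress, beat noise, wear and EMA schedules) and
    ``rng_policy`` drives the app's stochastic choices (weighted selection,
    feedback).  Keeping them separate means two runs that differ only in
    personalization policy see identical stress environments, so policy
    contrasts are not confounded by regenerated episode noise.
    """

    def __init__(self, profile: ParticipantProfile, config: TrialConfig,
                 rng_env: np.random.Generator, rng_policy: np.random.Generator):
        self.profile = profile
        self.config = config
        self.rng_env = rng_env
        self.rng_policy = rng_policy
        self.state = LatentStressState()
        self.calib = _calibrate_generator(profile, config)
        self.scanner = PhysioTriggerScanner(
            profile.participant_id, hop_s=config.window_s,
            refractory_s=config.refractory_s,
        )
        self.history: list[HRVWindowFeatures] = []
        self.features: list[HRVWindowFeatures] = []
        self.events: list[StressEvent] = []
        self.deliveries: list[dict] = []
        self.ratings: list[FeedbackRating] = []
        self.ema: list[EMAEntry] = []
        self.ts: list[np.ndarray] = []
        self.rrs: list[np.ndarray] = []
        self.latent_sum = np.zeros(config.n_weeks)
        self.latent_n = np.zeros(config.n_weeks)
        self.last_delivery_t = -np.inf


def _handle_delivery(
    sim: _ParticipantSim,
    event: StressEvent,
    s_grid: np.ndarray,
    block_idx: int,
    tree: DecisionTree,
    table: WeightTable,
    mode,
    pool: InterventionPool,
    t_now: float,
) -> np.ndarray:
    """Deliver for a detected event, rate it, learn, and apply its effect."""
    cfg = sim.config
    if t_now - sim.last_delivery_t < cfg.refractory_s:
        return s_grid
    sim.last_delivery_t = t_now
    sim.events.append(event)
    rec = deliver(event, tree, table, [sim.profile.stressor_branch], sim.rng_policy)
    intervention = pool[rec.intervention_id]
    sim.deliveries.append(
        {
            "t": t_now,
            "kind": event.kind,
            "intervention_id": rec.intervention_id,
            "category": intervention.category,
            "path": list(rec.path),
            "table_scope": list(table.scope),
        }
    )
    s_grid = apply_intervention_effect(
        s_grid, block_idx, intervention, sim.profile, cfg
    )
    if sim.rng_policy.random() < cfg.feedback_probability:
        rating = FeedbackRating(
            sim.profile.participant_id, rec.intervention_id,
            generate_rating(intervention, sim.profile, sim.rng_policy), t_now,
        )
        sim.ratings.append(rating)
        update_weights(table, rating, mode, cfg.learning_rate)
    return s_grid


def run_trial(
    config: TrialConfig,
    pool: Optional[InterventionPool] = None,
    tree: Optional[DecisionTree] = None,
    arms_override: Optional[Sequence[str]] = None,
) -> TrialRecord:
    """Run the full two-phase study closed loop; reproducible given the seed.

    Phase 1 runs every participant on the shared cohort weight table.  At
    the phase-2 boundary the cohort is randomized 1:1; the *high* arm
    switches to private copies of the cohort table while the *low* arm
    continues on the shared one.
    """
    pool = pool if pool is not None else default_pool()
    tree = tree if tree is not None else default_tree()
    tree.validate_against(pool)
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_arms, ss_parts = root.spawn(3)
    profiles = make_cohort(config.n_participants, ss_cohort)
    part_streams = [s.spawn(2) for s in ss_parts.spawn(len(profiles))]

    if arms_override is not None:
        if len(arms_override) != len(profiles):
            raise ValueError("arms_override must cover every participant")
        arms = list(arms_override)
    else:
        arm_rng = np.random.default_rng(ss_arms)
        order = arm_rng.permutation(len(profiles))
        n_high = len(profiles) // 2
        arms = ["low"] * len(profiles)
        for i in order[:n_high]:
            arms[i] = "high"

    cohort_table = WeightTable.from_pool(pool)
    individual_tables: dict[str, WeightTable] = {}
    sims = [
        _ParticipantSim(
            p, config,
            np.random.default_rng(env_ss), np.random.default_rng(pol_ss),
        )
        for p, (env_ss, pol_ss) in zip(profiles, part_streams)
    ]
    phase2_start_day = 7 * config.phase_weeks

    for day in range(config.n_days):
        week = day // 7
        phase2 = day >= phase2_start_day
        if phase2 and not individual_tables:
            for p, arm in zip(profiles, arms):
                if arm == "high":
                    individual_tables[p.participant_id] = cohort_table.copy_as(
                        ("individual", p.participant_id)
                    )
        for sim, arm in zip(sims, arms):
            pid = sim.profile.participant_id
            if phase2 and arm == "high":
                table, mode = individual_tables[pid], HIGH
            else:
                table, mode = cohort_table, LOW
            day_start = day * 86400.0
            s_grid, sim.state = _latent_day(
                sim.profile, sim.state, day, config, sim.rng_env
            )
            wearing = sim.rng_env.random() < sim.profile.sensor_compliance
            blocks = _wear_blocks(config, sim.rng_env, wearing)
            ema_sched = [
                (slot, off)
                for slot, off in _ema_times(config, sim.rng_env)
                if sim.rng_env.random() < sim.profile.ema_compliance
            ]
            # chronological merge of sensor blocks and EMA prompts
            agenda: list[tuple[float, str, object]] = [
                (b * BLOCK_S + BLOCK_S, "block", int(b)) for b in blocks
            ] + [(off, "ema", slot) for slot, off in ema_sched]
            agenda.sort(key=lambda x: x[0])
            for t_off, kind, payload in agenda:
                if kind == "block":
                    b = payload
                    t, rr = _rr_block(
                        sim.profile, config, sim.calib,
                        day_start + b * BLOCK_S, float(s_grid[b]), sim.rng_env,
                    )
                    sim.ts.append(t)
                    sim.rrs.append(rr)
                    w = Window(
                        start=day_start + b * BLOCK_S,
                        end=day_start + b * BLOCK_S + BLOCK_S,
                        t=t, rr=rr,
                    )
                    if len(rr) < config.min_beats:
                        feat = HRVWindowFeatures(
                            w.start, w.end, len(rr), quality="insufficient_data"
                        )
                    else:
                        lf, hf, ratio = _lf_hf(w)
                        feat = HRVWindowFeatures(
                            w.start, w.end, len(rr),
                            sdrr=_sdrr(w), rmssd=_rmssd(w),
                            lf_power=lf, hf_power=hf, lf_hf=ratio,
                            quality="ok" if ratio is not None else "insufficient_data",
                        )
                    thresholds = personal_thresholds(
                        sim.history, config.min_history, computed_at=w.start
                    )
                    event = sim.scanner.push(feat, thresholds)
                    sim.features.append(feat)
                    if feat.ok:
                        sim.history.append(feat)
                    if event is not None:
                        s_grid = _handle_delivery(
                            sim, event, s_grid, b, tree, table, mode, pool,
                            day_start + t_off,
                        )
                else:
                    entry = _ema_entry(
                        sim.profile, payload, day_start, t_off, s_grid, sim.rng_env
                    )
                    sim.ema.append(entry)
                    if detect_subjective_trigger(entry, config.valence_cutoff):
                        event = StressEvent(
                            participant_id=pid, kind="subjective",
                            start=entry.timestamp, ema_index=len(sim.ema) - 1,
                            valence_cutoff=config.valence_cutoff,
                        )
                        b = min(int(t_off / BLOCK_S), BLOCKS_PER_DAY - 1)
                        s_grid = _handle_delivery(
                            sim, event, s_grid, b, tree, table, mode, pool,
                            entry.timestamp,
                        )
            sim.latent_sum[week] += float(s_grid.sum())
            sim.latent_n[week] += len(s_grid)

    return TrialRecord(
        config=config,
        participants=[
            _finalize_participant(sim, arm, config) for sim, arm in zip(sims, arms)
        ],
    )


_EMA_VARIABLES = {
    "daily_chronic_stress": lambda e: e.chronic_stress,
    "valence_momentary": lambda e: e.valence,
    "arousal_momentary": lambda e: e.arousal,
    "valence_event": lambda e: e.event_valence,
    "arousal_event": lambda e: e.event_arousal,
}
_HRV_VARIABLES = ("sdrr", "rmssd", "lf_hf")


def _finalize_participant(
    sim: _ParticipantSim, arm: str, config: TrialConfig
) -> ParticipantRecord:
    weekly: dict[str, evaluation.WeeklySeries] = {}
    pid = sim.profile.participant_id
    for var, getter in _EMA_VARIABLES.items():
        pairs = [(e.timestamp, getter(e)) for e in sim.ema if getter(e) is not None]
        weekly[var] = evaluation.weekly_aggregate(
            [t for t, _ in pairs], [v for _, v in pairs], 0.0,
            participant_id=pid, variable=var, n_weeks=config.n_weeks,
        )
    ok = [f for f in sim.features if f.ok]
    for var in _HRV_VARIABLES:
        weekly[var] = evaluation.weekly_aggregate(
            [f.window_start for f in ok], [getattr(f, var) for f in ok], 0.0,
            participant_id=pid, variable=var, n_weeks=config.n_weeks,
        )
    rr = None
    if config.keep_rr:
        rr = RRSeries(
            pid,
            np.concatenate(sim.ts) if sim.ts else np.array([]),
            np.concatenate(sim.rrs) if sim.rrs else np.array([]),
        )
    with np.errstate(invalid="ignore"):
        latent = sim.latent_sum / np.maximum(sim.latent_n, 1)
    return ParticipantRecord(
        profile=sim.profile,
        arm=arm,
        rr=rr,
        ema=sim.ema,
        features=sim.features,
        events=sim.events,
        deliveries=sim.deliveries,
        ratings=sim.ratings,
        weekly=weekly,
        weekly_latent={w + 1: float(latent[w]) for w in range(config.n_weeks)},
    )
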