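import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stressjitai import trigger_engine as te
from stressjitai.hrv_core import HRVWindowFeatures
from stressjitai.io_formats import EMAEntry


def feat(i, lfhf, rmssd, start=None, quality="ok", hop=300.0):
    start = i * hop if start is None else start
    if quality != "ok":
        return HRVWindowFeatures(start, start + 300.0, 10, quality=quality)
    return HRVWindowFeatures(
        start, start + 300.0, 350, sdrr=30.0, rmssd=rmssd,
        lf_power=lfhf, hf_power=1.0, lf_hf=lfhf, quality=quality,
    )


def history(lfhf_values, rmssd_values):
    return [
        feat(i, l, r) for i, (l, r) in enumerate(zip(lfhf_values, rmssd_values))
    ]


def brute_quantile(values, q):
    """Sorted-order statistic with linear interpolation, from first principles."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestPersonalThresholds:
    def test_low_lfhf_history_hits_floor(self):
        th = te.personal_thresholds(history([0.8] * 20, [30.0] * 20))
        assert th.theta_lfhf == 1.2

    def test_high_rmssd_history_hits_ceiling(self):
        th = te.personal_thresholds(history([2.0] * 20, [80.0] * 20))
        assert th.theta_rmssd == 50.0

    def test_quantiles_match_brute_force(self):
        lfhf = list(np.arange(1.0, 3.01, 0.1))  # 1.0, 1.1, ..., 3.0
        rms = list(np.linspace(10, 45, len(lfhf)))
        th = te.personal_thresholds(history(lfhf, rms))
        assert th.theta_lfhf == pytest.approx(brute_quantile(lfhf, 0.75))
        assert th.theta_rmssd == pytest.approx(brute_quantile(rms, 0.25))

    def test_empty_history_returns_clamps(self):
        th = te.personal_thresholds([])
        assert (th.theta_lfhf, th.theta_rmssd, th.history_n) == (1.2, 50.0, 0)

    def test_short_history_returns_clamps(self):
        th = te.personal_thresholds(history([3.0] * 5, [15.0] * 5), min_history=12)
        assert (th.theta_lfhf, th.theta_rmssd) == (1.2, 50.0)
        assert th.history_n == 5

    def test_bad_quality_windows_ignored(self):
        h = history([3.0] * 20, [15.0] * 20) + [
            feat(20, 99.0, 1.0, quality="insufficient_data")
        ]
        th = te.personal_thresholds(h)
        assert th.history_n == 20
        assert th.theta_lfhf == pytest.approx(3.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.01, max_value=20.0),
                st.floats(min_value=1.0, max_value=150.0),
            ),
            max_size=60,
        ),
        st.integers(min_value=0, max_value=20),
    )
    def test_clamp_invariants_always_hold(self, pairs, min_history):
        h = history([p[0] for p in pairs], [p[1] for p in pairs])
        th = te.personal_thresholds(h, min_history=min_history)
        assert th.theta_lfhf >= 1.2
        assert th.theta_rmssd <= 50.0
        assert th.history_n >= 0


class TestSubjectiveTrigger:
    @pytest.mark.parametrize("valence,expected", [(3, True), (4, False), (1, True)])
    def test_valence_cutoff(self, valence, expected):
        e = EMAEntry("P1", 0.0, "during_day", valence, 4)
        assert te.detect_subjective_trigger(e) is expected


def fixed_thresholds(lfhf=1.2, rmssd=50.0):
    th = te.PersonalThresholds(lfhf, rmssd, 0)
    return lambda i, f: th


class TestPhysioEvents:
    def test_single_qualifying_window_no_event(self):
        feats = [feat(0, 2.0, 20.0), feat(1, 0.5, 60.0)]
        assert te.detect_physio_events(feats, fixed_thresholds()) == []

    def test_two_consecutive_qualifying_windows_one_event(self):
        feats = [feat(0, 2.0, 20.0), feat(1, 2.0, 20.0)]
        (ev,) = te.detect_physio_events(feats, fixed_thresholds(), "P1")
        assert ev.kind == "physiological"
        assert ev.windows == (0, 1)
        assert ev.start == 0.0

    def test_six_qualifying_windows_one_event_with_refractory(self):
        feats = [feat(i, 2.0, 20.0) for i in range(6)]
        events = te.detect_physio_events(feats, fixed_thresholds(), refractory_s=1800.0)
        assert len(events) == 1

    def test_boundary_values_inclusive(self):
        feats = [feat(0, 1.2, 50.0), feat(1, 1.2, 50.0)]
        assert len(te.detect_physio_events(feats, fixed_thresholds())) == 1

    def test_gap_breaks_consecutiveness(self):
        feats = [feat(0, 2.0, 20.0), feat(1, 2.0, 20.0, start=900.0)]
        assert te.detect_physio_events(feats, fixed_thresholds()) == []

    def test_bad_quality_breaks_run(self):
        feats = [
            feat(0, 2.0, 20.0),
            feat(1, 0.0, 0.0, quality="insufficient_data"),
            feat(2, 2.0, 20.0),
        ]
        assert te.detect_physio_events(feats, fixed_thresholds()) == []

    def test_event_after_refractory_expires(self):
        feats = [feat(i, 2.0, 20.0) for i in range(20)]
        events = te.detect_physio_events(feats, fixed_thresholds(), refractory_s=1800.0)
        # refractory 1800 s from event start: second event builds at window 6
        assert [e.windows for e in events[:2]] == [(0, 1), (6, 7)]

    def test_monotone_in_threshold_strictness(self):
        rng = np.random.default_rng(10)
        feats = [
            feat(i, rng.uniform(0.5, 3.0), rng.uniform(10, 70)) for i in range(200)
        ]
        counts = []
        for lfhf_th in (1.2, 1.6, 2.0, 2.4):
            evs = te.detect_physio_events(
                feats, fixed_thresholds(lfhf=lfhf_th), refractory_s=0.0
            )
            counts.append(len(evs))
        assert counts == sorted(counts, reverse=True)
        counts = []
        for rms_th in (50.0, 40.0, 30.0, 20.0):
            evs = te.detect_physio_events(
                feats, fixed_thresholds(rmssd=rms_th), refractory_s=0.0
            )
            counts.append(len(evs))
        assert counts == sorted(counts, reverse=True)

    def test_matches_naive_reference_scan(self):
        rng = np.random.default_rng(11)
        for trial in range(50):
            n = int(rng.integers(5, 120))
            starts = np.cumsum(rng.choice([300.0, 300.0, 300.0, 600.0], n))
            feats = [
                feat(
                    i,
                    float(rng.uniform(0.5, 3.0)),
                    float(rng.uniform(10, 70)),
                    start=float(starts[i]),
                    quality="ok" if rng.random() > 0.1 else "insufficient_data",
                )
                for i in range(n)
            ]
            refractory = float(rng.choice([0.0, 600.0, 1800.0, 3600.0]))
            th_fn = fixed_thresholds(
                lfhf=float(rng.uniform(1.2, 2.5)), rmssd=float(rng.uniform(20, 50))
            )
            got = te.detect_physio_events(feats, th_fn, refractory_s=refractory)
            expect = naive_scan(feats, th_fn, 300.0, refractory)
            assert [e.windows for e in got] == expect, f"trial {trial}"

    def test_expanding_history_thresholds_adapt(self):
        # personalized thresholds never fire on the calm baseline; the
        # stressed stretch triggers once thresholds are personalized
        calm = [feat(i, 1.0, 35.0) for i in range(24)]
        stressed = [feat(24 + i, 2.5, 18.0) for i in range(48)]
        feats = calm + stressed

        def th_fn(i, f):
            return te.personal_thresholds(f[:i], min_history=12)

        events = te.detect_physio_events(feats, th_fn, refractory_s=1800.0)
        assert len(events) >= 1
        assert all(ev.windows[0] >= 24 for ev in events)


def naive_scan(feats, th_fn, hop, refractory):
    """Independent O(n) reference: explicit rule-by-rule pair scan."""
    out = []
    last_start = -float("inf")
    last_second = -1
    for i in range(1, len(feats)):
        a, b = feats[i - 1], feats[i]
        if abs(b.window_start - a.window_start - hop) > 1e-6:
            continue
        if i - 1 == last_second:
            continue
        tha, thb = th_fn(i - 1, feats), th_fn(i, feats)

        def ok(w, th):
            return (
                w.quality == "ok"
                and w.lf_hf >= th.theta_lfhf
                and w.rmssd <= th.theta_rmssd
            )

        if not (ok(a, tha) and ok(b, thb)):
            continue
        if a.window_start < last_start + refractory:
            continue
        if b.window_start < last_start + refractory:
            continue
        out.append((i - 1, i))
        last_start = a.window_start
        last_second = i
    return out


class TestRegimeSmoke:
    """With thresholds at the clamps, a calm generator regime yields no
    events while a stressed regime yields some."""

    def _simulated_features(self, stressed, seed):
        from stressjitai.trial_simulator import (
            LatentStressState,
            TrialConfig,
            make_cohort,
            simulate_day,
        )
        from stressjitai.hrv_core import compute_features

        cfg = TrialConfig(
            sensor_hours_per_day=4.0, p_onset_work=0.0, p_onset_off=0.0
        )
        profile = make_cohort(2, 5)[0]
        profile = type(profile)(**{**profile.__dict__, "sensor_compliance": 1.0})
        forced = [(0, 288, 1.8)] if stressed else []
        rng = np.random.default_rng(seed)
        rr, _, _ = simulate_day(
            profile, LatentStressState(), 0, cfg, rng, forced_episodes=forced
        )
        return compute_features(rr, policy=None)

    def test_calm_regime_no_events(self):
        feats = self._simulated_features(stressed=False, seed=0)
        events = te.detect_physio_events(feats, fixed_thresholds())
        assert events == []

    def test_stressed_regime_triggers(self):
        feats = self._simulated_features(stressed=True, seed=0)
        events = te.detect_physio_events(feats, fixed_thresholds())
        assert len(events) > 0
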