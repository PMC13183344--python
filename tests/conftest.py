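import numpy as np
import pytest

from stressjitai.hrv_core import Window
from stressjitai.io_formats import (
    DecisionTree,
    InterventionPool,
    Microintervention,
    TreeNode,
)


def make_window(rr_ms, start=0.0):
    """Build a Window whose timestamps are the running sum of its intervals."""
    rr = np.asarray(rr_ms, dtype=float)
    t = start + np.cumsum(rr) / 1000.0
    return Window(start=start, end=float(t[-1]) + 1.0, t=t, rr=rr)


def make_tone_window(freq_hz, amp_ms, mean_rr=800.0, duration_s=300.0, phase=0.0):
    """Tachogram modulated by a single sinusoid, sampled at the beat times."""
    n = int(duration_s * 1000.0 / mean_rr) + 2
    t_approx = np.arange(n) * mean_rr / 1000.0
    rr = mean_rr + amp_ms * np.sin(2 * np.pi * freq_hz * t_approx + phase)
    t = np.cumsum(rr) / 1000.0
    keep = t < duration_s
    return Window(start=0.0, end=duration_s, t=t[keep], rr=rr[keep])


@pytest.fixture
def small_pool():
    return InterventionPool(
        [
            Microintervention("a", "relaxation", "text", 2.0),
            Microintervention("b", "training", "audio", 1.0),
            Microintervention("c", "psychoeducation", "video", 1.0),
        ]
    )


@pytest.fixture
def small_tree(small_pool):
    tree = DecisionTree(
        root=TreeNode(
            label="root",
            children=[
                TreeNode(label="left", leaf_ids=frozenset({"a", "b"})),
                TreeNode(label="right", leaf_ids=frozenset({"c"})),
            ],
        )
    )
    tree.validate_against(small_pool)
    return tree
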