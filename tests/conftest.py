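"""Shared fixtures: simulated VAR paths and small synthetic cohorts."""

import numpy as np
import pytest

from eegretest import make_template, sample_subject_sessions
from eegretest.synth import simulate_var


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def bivariate_var1_data():
    """Long sample path of the reference bivariate VAR(1) with flow 1 -> 2.

    A_1 = [[0.5, 0], [0.4, 0.3]], V = I; channel indices are 0-based, so
    the true flow is channel 0 -> channel 1.
    """
    A = np.array([[[0.5, 0.0], [0.4, 0.3]]])
    data = simulate_var(A, np.eye(2), 50_000, np.random.default_rng(7), burn_in=500)
    return A, data


@pytest.fixture(scope="session")
def small_eeg_recording():
    """A realistic-amplitude 12 s synthetic EEG recording (3 channels)."""
    template = make_template(3, coupling_edges=[(0, 1, 1, 0.3)], band_centers=[10, 20, 6])
    rec, _ = sample_subject_sessions(template, 0.0, 0.0, 6000, seed=11)
    return rec


def brute_force_artifact_mask(data, fs, rules):
    """Literal sliding-window evaluation of the three amplitude rules.

    Kept deliberately naive (explicit loops over every window) so it is
    an independent oracle for the vectorized detector.
    """
    n = data.shape[1]
    mask = np.zeros(n, dtype=bool)

    def ms(sec):
        return int(round(sec * fs))

    for ch in range(data.shape[0]):
        x = data[ch]
        for t in range(1, n):
            if abs(x[t] - x[t - 1]) > rules.max_step:
                mask[max(0, t - ms(rules.step_margin)): t + ms(rules.step_margin) + 1] = True
        w = ms(rules.diff_window)
        for s in range(n - w + 1):
            seg = x[s : s + w]
            if seg.max() - seg.min() > rules.max_diff:
                mask[max(0, s - ms(rules.diff_margin)): s + w + ms(rules.diff_margin)] = True
        w = ms(rules.flat_window)
        for s in range(n - w + 1):
            seg = x[s : s + w]
            if seg.max() - seg.min() < rules.min_diff:
                mask[max(0, s - ms(rules.flat_margin)): s + w + ms(rules.flat_margin)] = True
    return mask
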