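import numpy as np
import pytest

from nnskit.config import ExtractConfig
from nnskit.extract import Burst, CycleEvent
from nnskit.simulate import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def extract_config() -> ExtractConfig:
    return ExtractConfig()


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams()


@pytest.fixture(scope="session")
def small_cohort():
    """Three-subject rendered cohort shared across end-to-end tests."""
    return simulate_cohort(SimParams(n_subjects=3), seed=7)


@pytest.fixture
def worked_trial():
    """The hand-computable trial: bursts [1.0, 1.5, 2.0] and [4.0, 4.4], 3 mbar peaks."""
    times = [1.0, 1.5, 2.0, 4.0, 4.4]
    cycles = [CycleEvent(time=t, amplitude=3.0) for t in times]
    bursts = [
        Burst(cycle_indices=[0, 1, 2], start=1.0, end=2.0),
        Burst(cycle_indices=[3, 4], start=4.0, end=4.4),
    ]
    return cycles, bursts


def brute_force_peaks(x: np.ndarray, fs: float, threshold: float, min_sep: float):
    """Exhaustive local-maxima scan + greedy larger-peak deduplication.

    Independent oracle for detect_cycles: every strict local maximum at or
    above the threshold is a candidate; candidates are visited in
    descending height and any unkept candidate closer than the minimum
    separation to a kept one is dropped.
    """
    cand = [
        i
        for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] >= threshold
    ]
    dist = max(1, round(min_sep * fs))
    kept, removed = [], set()
    for i in sorted(cand, key=lambda i: x[i], reverse=True):
        if i in removed:
            continue
        kept.append(i)
        for j in cand:
            if j != i and j not in removed and abs(j - i) < dist:
                removed.add(j)
    return sorted(kept)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up, written out literally: q_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
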