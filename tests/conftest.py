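import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phasefit import PerformanceSeries, TransferPanel
from phasefit.data import SESSIONS, TASKS


@pytest.fixture
def toy_series() -> PerformanceSeries:
    """5-point series with a visible kink after day 2."""
    return PerformanceSeries(
        "toy", np.arange(1.0, 6.0), np.array([2.1, 3.2, 3.35, 3.4, 3.55])
    )


@pytest.fixture
def noiseless_series() -> PerformanceSeries:
    """22 days from (alpha=3, beta_ts=1, beta_cap=0.05), switch after day 4."""
    t = np.arange(1.0, 23.0)
    y = np.where(t <= 4, (0.05 + 1.0) * t + 3.0, 0.05 * t + 4.0 + 3.0)
    return PerformanceSeries("exact", t, y)


def make_panel(scores: np.ndarray, tasks=TASKS) -> TransferPanel:
    cols = pd.MultiIndex.from_tuples(
        [(t, s) for t in tasks for s in SESSIONS], names=["task", "session"]
    )
    ids = [f"s{i:03d}" for i in range(scores.shape[0])]
    return TransferPanel(pd.DataFrame(scores, index=ids, columns=cols))


@pytest.fixture
def complete_panel() -> TransferPanel:
    rng = np.random.default_rng(17)
    return make_panel(rng.normal(5.0, 1.5, size=(12, 20)))
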