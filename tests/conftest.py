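"""Shared fixtures: simulated session sets and small synthetic cohorts.

Everything is generated programmatically with fixed seeds; session-scoped
fixtures are reused across test modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from probswitch import synth
from probswitch.task import (SESSION_COLUMNS, RFLRAgent, SessionTable,
                             TaskConfig, UniformRandomAgent,
                             WinStayLoseShiftAgent, simulate_cohort)


def make_session(choices, rewards, high_sides=None, mouse_id="m0",
                 session_id="s0", trial_spacing=4.0) -> SessionTable:
    """Build a SessionTable from explicit per-trial choices/rewards.

    Timestamps are regular and valid (CE at k*spacing; CX, SE, FL, SX at
    fixed offsets). high_sides defaults to all 'left'.
    """
    n = len(choices)
    if high_sides is None:
        high_sides = ["left"] * n
    t_ce = np.arange(n) * trial_spacing + 1.5
    df = pd.DataFrame({
        "mouse_id": mouse_id, "session_id": session_id,
        "trial": np.arange(n), "block": 0,
        "high_side": high_sides, "choice": list(choices),
        "rewarded": [bool(r) for r in rewards],
        "t_CE": t_ce, "t_CX": t_ce + 0.3, "t_SE": t_ce + 0.8,
        "t_FL": t_ce + 1.1, "t_SX": t_ce + 2.2,
    }, columns=SESSION_COLUMNS)
    return SessionTable(df, mouse_id, session_id)


@pytest.fixture(scope="session")
def rflr_sessions():
    """12 sessions (6 mice x 2) from an RFLR agent at 90/10."""
    cfg = TaskConfig(p_high=0.9, p_low=0.1, n_trials=400)
    return simulate_cohort(lambda: RFLRAgent(1.0, 2.0, 1.4), cfg, 6, 2,
                           seed=101)


@pytest.fixture(scope="session")
def wsls_sessions():
    cfg = TaskConfig(p_high=0.9, p_low=0.1, n_trials=300)
    return simulate_cohort(WinStayLoseShiftAgent, cfg, 3, 2, seed=55)


@pytest.fixture(scope="session")
def random_sessions():
    cfg = TaskConfig(p_high=0.9, p_low=0.1, n_trials=400)
    return simulate_cohort(UniformRandomAgent, cfg, 3, 2, seed=77)


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort with photometry: 2 mice x 1 session x 150 trials."""
    spec = synth.TruthSpec(task=TaskConfig(n_trials=150))
    return synth.generate_cohort(spec, n_mice=2, sessions_per_mouse=1,
                                 seed=202)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free, drift-free cohort (1 mouse) for round-trip identities."""
    spec = synth.TruthSpec(task=TaskConfig(n_trials=150), ar_sigma=0.0,
                           drift_amplitude=0.0)
    return synth.generate_cohort(spec, n_mice=1, sessions_per_mouse=1,
                                 seed=203, noise=False)
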