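"""Simulate behavioral cohorts at the three reward-probability conditions.

An RFLR agent (alpha=1.0, beta=2.0, tau=1.4) plays the switching task at
90/10, 80/20 and 70/30 per-port reward probabilities; 6 mice x 3 sessions x
500 trials per condition. Writes one sessions CSV per condition under
results/behavior/.
"""

from pathlib import Path

from probswitch.io import write_sessions
from probswitch.task import RFLRAgent, TaskConfig, simulate_cohort

SEED = 20260
OUT = Path(__file__).resolve().parent.parent / "results" / "behavior"
CONDITIONS = {"90_10": (0.9, 0.1), "80_20": (0.8, 0.2), "70_30": (0.7, 0.3)}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (name, (hi, lo)) in enumerate(CONDITIONS.items()):
        cfg = TaskConfig(p_high=hi, p_low=lo, n_trials=500)
        sessions = simulate_cohort(lambda: RFLRAgent(1.0, 2.0, 1.4), cfg,
                                   n_mice=6, sessions_per_mouse=3,
                                   seed=SEED + i)
        path = OUT / f"sessions_{name}.csv"
        write_sessions(sessions, path)
        n = sum(len(s) for s in sessions)
        print(f"{name}: {len(sessions)} sessions, {n} trials -> {path.name}")


if __name__ == "__main__":
    main()
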