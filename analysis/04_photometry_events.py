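"""Synthetic photometry: demodulation and event-aligned fluorescence.

Generates a 3-mouse cohort with known event kernels, demodulates the
167 Hz signal channel and the static 223 Hz control channel, aligns the
z-scored traces to center entry and first lick, and tabulates 500 ms
window means per direction (ipsi/contra) and outcome. The control channel
shows no event-locked modulation. Writes results/photometry/.
"""

from pathlib import Path

import pandas as pd

from probswitch import photometry, synth
from probswitch.task import TaskConfig

OUT = Path(__file__).resolve().parent.parent / "results" / "photometry"
SEED = 20262


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = synth.TruthSpec(task=TaskConfig(n_trials=300))
    cohort = synth.generate_cohort(spec, n_mice=3, sessions_per_mouse=1,
                                   seed=SEED)
    for carrier, tag in ((167.0, "signal"), (223.0, "control")):
        frames = {"CE": [], "FL": []}
        for rec in cohort.recordings:
            sig = photometry.demodulate(rec.raw, carrier)
            for event in frames:
                tensor = photometry.align_events(sig, rec.session, event,
                                                 pre=0.5, post=1.0)
                frames[event].append(photometry.window_mean(tensor))
        for event, fr in frames.items():
            per_trial = pd.concat(fr, ignore_index=True)
            by = ["direction"] if event == "CE" else ["rewarded"]
            g = photometry.group_window_means(per_trial, by)
            g.to_csv(OUT / f"window_means_{event}_{tag}.csv")
            print(f"{tag} channel, {event}-aligned 500 ms window means:")
            print(g.round(3).to_string(), "\n")
    print("Signal channel: ipsi CE rise, contra CE dip; unrewarded > "
          "rewarded at the outcome. Control channel: ~0 everywhere.")


if __name__ == "__main__":
    main()
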