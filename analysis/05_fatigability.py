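#!/usr/bin/env python
"""Diurnal fatigability: afternoon vs evening split-half dose times.

Simulates the strongly diurnal home-program participant taking the 10 °C
dose in 20 afternoon and 20 evening sessions and runs the grouped split-half
comparison.  Expected pattern: first half-dose times near 13.5 min in both
groups; evening second halves ~50% longer than first halves (afternoon
halves statistically indistinguishable); total durations near 27.4 min
(afternoon) and 33.8 min (evening).

Writes results/fatigability.json and results/fatigability_bivariate.png.
"""

import sys
from pathlib import Path

from legwork.config import load_config
from legwork.io import write_dose_events_csv
from legwork.studies import diurnal_study

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int | None = None) -> None:
    cfg = load_config(None)
    seed = seed if seed is not None else cfg.master_seed
    events, report = diurnal_study(
        n_per_group=20, seed=seed, test=cfg["analysis"]["test"]
    )
    OUT.mkdir(exist_ok=True)
    write_dose_events_csv(events, OUT / "diurnal_events.csv")
    (OUT / "fatigability.json").write_text(report.to_json() + "\n")
    print(report.to_text())

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    done = [e for e in events if e.completed]
    hours = [e.start_clock_time.hour + e.start_clock_time.minute / 60 for e in done]
    fig, ax = plt.subplots(figsize=(6.5, 4))
    ax.scatter(hours, [e.t_half for e in done], marker="D", label="time to D/2")
    ax.scatter(hours, [e.t_full for e in done], marker="s", label="time to D")
    ax.axvline(17.0, color="grey", ls=":", lw=1)
    ax.set_xlabel("session start (clock hours)")
    ax.set_ylabel("minutes")
    ax.set_title("half- and full-dose times vs time of day")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "fatigability_bivariate.png", dpi=120)
    print(f"wrote {OUT / 'fatigability.json'} and the bivariate figure")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else None)
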