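#!/usr/bin/env python
"""Classify per-frame attachment status and score transition counts.

Runs the geometric classifier (membrane within 1 µm of the tip surface)
on the demo cohorts, drops censored cells, scores status changes within
codes 1–3, and summarises per group stratified by the state at the first
analysed frame — the study's headline dynamics statistic.
"""

from pathlib import Path

import nichedyn as nd

SEED = 20180
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "attachment"
    out.mkdir(parents=True, exist_ok=True)
    seqs_by_group = {}
    for name, preset in (("control", nd.control_like),
                         ("mutant", nd.mutant_like)):
        scene = nd.generate_scene(preset(n_cells=30, n_frames=98, seed=SEED))
        res = nd.analyze_scene(scene)
        seqs_by_group[name] = res["sequences"]
        res["transitions"].to_csv(out / f"transitions_{name}.csv",
                                  index=False)
        frac = res["attachment_fraction_first_frame"]
        print(f"{name}: {len(res['sequences'])} eligible cells "
              f"({res['n_excluded']} censored), attachment fraction at "
              f"frame 10 = {100 * frac:.0f}%")

    summary = nd.group_transition_summary(seqs_by_group,
                                          initial_state_frame=10)
    summary.to_csv(out / "transition_summary.csv", index=False)
    means = summary[summary.initial_state == "all"].set_index("group")
    fold = means.loc["mutant", "mean_transitions"] / \
        means.loc["control", "mean_transitions"]
    print(summary.to_string(index=False))
    print(f"mutant-like cells switch status {fold:.1f}x more often "
          f"than control-like cells")


if __name__ == "__main__":
    main()
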