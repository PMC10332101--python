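#!/usr/bin/env python
"""Behavior workflow: investigation bouts -> log2 preference -> group test.

Scores the simulated 11-mouse cohort (per-animal log2 IT_A/IT_B) and runs
the two-sided one-sample t-test of the group mean against zero.
"""

import json
from pathlib import Path

import pandas as pd

from vnokit.behavior import group_preference, read_bout_table, score_session

SIM = Path(__file__).resolve().parent.parent / "results" / "sim"
OUT = SIM.parent / "behavior"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sessions = read_bout_table(SIM / "bouts.csv")
    scored = [score_session(s) for s in sessions]
    pd.DataFrame(
        [{"subject_id": s.subject_id, "it_a_s": round(s.it_a, 1),
          "it_b_s": round(s.it_b, 1), "log2_ratio": round(s.score, 3)}
         for s in scored]
    ).to_csv(OUT / "preference_scores.csv", index=False)
    group = group_preference([s.score for s in scored])
    report = {"mean": group.mean, "sem": group.sem, "n": group.n,
              "test": group.test.to_dict()}
    (OUT / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    verdict = "prefers side A" if group.test.significant and group.mean > 0 else \
              "no significant preference"
    print(f"group log2 IT ratio {group.mean:+.2f} +/- {group.sem:.2f} "
          f"(n={group.n}; t={group.test.statistic:.2f}, "
          f"p={group.test.p_value:.3g}): {verdict}")


if __name__ == "__main__":
    main()
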