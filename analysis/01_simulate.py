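#!/usr/bin/env python
"""Generate the synthetic inputs for the downstream analysis steps.

Writes a two-stimulus en face recording site (~2,000 knobs on a 158 x 158
um field at 8.32 knobs/100 um^2, class fractions both 1.6% / A-only 0.5% /
B-only 0.1%), an 11-mouse behavioral cohort planted at a log2 preference
of 0.81, and pS6-style count tables for two genotypes, all under
results/sim/.  The full-size (20,000-knob) run lives in the acceptance
script; this demo site keeps the written table small.
"""

from pathlib import Path

from vnokit.behavior import sessions_to_table
from vnokit.counts import regions_to_table
from vnokit.protocol import two_stimulus_protocol
from vnokit.synth import (
    SynthConfig,
    generate_behavior_cohort,
    generate_count_regions,
    generate_knob_field,
    generate_trace_dataset,
)

SEED = 20_230
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = SynthConfig(seed=SEED, field_area_um=(158.0, 158.0))
    protocol = two_stimulus_protocol()
    field = generate_knob_field(cfg)
    dataset, truth = generate_trace_dataset(field, protocol, cfg)
    dataset.write(OUT / "traces.csv", float_format="%.2f")
    truth.classes.to_csv(OUT / "truth_classes.csv", index=False)
    protocol.save(OUT / "protocol.yaml")
    print(f"imaging site: {len(dataset)} knobs, "
          f"{truth.classes.true_class.ne('none').sum()} planted responders "
          f"-> {OUT / 'traces.csv'}")

    cohort = generate_behavior_cohort(11, planted_mu=0.81, seed=SEED + 1)
    sessions_to_table(cohort).to_csv(OUT / "bouts.csv", index=False)
    print(f"behavior cohort: {len(cohort)} mice -> {OUT / 'bouts.csv'}")

    rows = []
    for geno, p, offset in (("control", 0.0219, 2), ("cko", 0.0098, 3)):
        for subj in range(6):
            regions = generate_count_regions(
                10, p_positive=p, seed=SEED + offset + 10 * subj,
                subject_id=f"{geno}{subj}",
            )
            t = regions_to_table(regions)
            t["genotype"] = geno
            rows.append(t)
    import pandas as pd

    pd.concat(rows).to_csv(OUT / "ps6_counts.csv", index=False)
    print(f"pS6 count tables: 12 subjects -> {OUT / 'ps6_counts.csv'}")


if __name__ == "__main__":
    main()
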