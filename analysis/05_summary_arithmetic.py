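#!/usr/bin/env python
"""Headline summary arithmetic on the published group-level values.

Reproduces the printed density, Venn-share, fold-change and
percent-reduction numbers from their stated inputs, as a check that the
summary operations implement the same conventions (half-away-from-zero
rounding at printed precision, share and fold definitions).
"""

import json
from pathlib import Path

from vnokit.classify import (
    exclusive_share, fold_change, headline, total_response_ratio, venn_shares,
)
from vnokit.counts import percent_reduction
from vnokit.knobs import estimate_total_knobs, pool_group_densities

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    urine = {"A_only": 0.5, "B_only": 0.1, "both": 1.6}
    feces = {"A_only": 0.03, "B_only": 0.6, "both": 0.3}
    rows = {
        "pooled knob density (8.42, 8.21)": pool_group_densities([8.42, 8.21]),
        "total knobs in 40,000 um^2": estimate_total_knobs(40_000, 8.32),
        "total knobs in 13,000 um^2": estimate_total_knobs(13_000, 8.32),
        "urine A-only Venn share %": headline(venn_shares(urine)["A_only"]),
        "urine B-only Venn share %": headline(venn_shares(urine)["B_only"]),
        "LMW A-exclusive fold reduction (0.6 vs 0.018)": headline(
            fold_change(0.6, 0.018)[0]),
        "pS6 reduction % (2.19 -> 0.98)": percent_reduction(2.19, 0.98),
        "FE B-exclusive share %": headline(exclusive_share(feces, "B")),
        "FE total-response fold (B vs A)": headline(total_response_ratio(feces, "B")),
    }
    (OUT / "summary_arithmetic.json").write_text(json.dumps(rows, indent=2) + "\n")
    for k, v in rows.items():
        print(f"{k}: {v:g}")


if __name__ == "__main__":
    main()
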