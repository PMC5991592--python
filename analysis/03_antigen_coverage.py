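#!/usr/bin/env python
"""Which knockout panels service which alloimmunised patients.

Loads the cohort realisation from scratch/data/cohort.tsv, evaluates the
seven-system and five-major-system panels, the marginal gains of adding
Lutheran or Kidd, and the greedy/exhaustive panel-growth path. Writes
coverage.json.
"""

import json
from pathlib import Path

from rbcedit.coverage import (
    ALL_SEVEN,
    BloodGroupSystem as BG,
    Cohort,
    FIVE_MAJOR,
    KnockoutPanel,
    TABLE_ORDER,
    coverage,
    greedy_panel,
    marginal_gain,
    optimal_panel,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    cohort = Cohort.from_tsv(DATA / "cohort.tsv")
    seven = coverage(cohort, KnockoutPanel(ALL_SEVEN), gains=False)
    five = coverage(cohort, KnockoutPanel(FIVE_MAJOR))
    print(
        f"{seven.n_served} of the {len(cohort)} surveyed patients are served by "
        f"the seven-system knockout (the {seven.n_unserved} McLeod patients "
        f"cannot be served by blood-group removal)"
    )
    print(
        f"{five.n_served} of {len(cohort)} are served by the five-major-system "
        f"knockout; adding LUTHERAN gains "
        f"{marginal_gain(cohort, KnockoutPanel(FIVE_MAJOR), BG.LUTHERAN)}, "
        f"adding KIDD gains "
        f"{marginal_gain(cohort, KnockoutPanel(FIVE_MAJOR), BG.KIDD)}"
    )
    path = []
    for k in range(8):
        g = greedy_panel(cohort, k)
        o = optimal_panel(cohort, k)
        path.append(
            {
                "k": k,
                "greedy": sorted(s.value for s in g.systems),
                "greedy_served": coverage(cohort, g, gains=False).n_served,
                "optimal_served": coverage(cohort, o, gains=False).n_served,
            }
        )
    print("greedy panel growth:",
          " -> ".join(f"k={p['k']}:{p['greedy_served']}" for p in path))
    out = {
        "n_patients": len(cohort),
        "seven_system": seven.to_dict(),
        "five_major": five.to_dict(),
        "panel_growth": path,
    }
    (ROOT / "coverage.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
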