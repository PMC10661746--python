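#!/usr/bin/env python
"""Reproduce the interaction tables of the MES isopimpinellin/borneol study.

Runs the summary-mode pipeline over the bundled published estimates and writes
the combination table (experimental vs additive ED50s, Welch t/df/p,
classifications, fraction indices, percent ED50 changes) plus isobologram
coordinates under results/tables/.
"""

import argparse
from pathlib import Path

from isobolo.pipeline import run_study
from isobolo.study_data import load_study_config


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()

    report = run_study(load_study_config(), out_dir=args.out)
    combos = report.combinations

    print(f"wrote {args.out}/combinations.csv ({len(combos)} combinations)\n")
    cols = [
        "combination", "ed50_exp_total", "ed50_add_total", "ed50_add_computed",
        "t", "df", "p", "significance", "classification", "fractions",
        "pct_change_vs_solo",
    ]
    print(combos[cols].to_string(index=False))

    print("\nfindings:")
    for label, n in combos["classification"].value_counts().items():
        print(f"  {n} combinations classified {label}")
    worst = (combos["ed50_add_computed"] - combos["ed50_add_total"]).abs().max()
    print(
        f"  recomputed additive totals agree with the published ones to "
        f"{worst:.3f} mg/kg at worst (the valproate rows carry the source's "
        "rounding residue)"
    )
    print(
        "  known source discrepancy: the CBZ + ISOP (25) varied fraction prints "
        "0.86 in the source but recomputes to 0.89 from its own solo ED50s"
    )


if __name__ == "__main__":
    main()
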