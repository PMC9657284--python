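#!/usr/bin/env python
"""Descriptive stride parameters per breed, gait and condition.

Summarizes the simulated cohorts from 01_simulate_cohorts.py as median and
IQR of stride duration, stance/swing durations, duty factors, dissociations
and suspension — the classic stride-parameter table of an equine gait
study.  Writes results/stride_parameters.csv.
"""

from pathlib import Path

import pandas as pd

from hoofbeat import describe

RESULTS = Path(__file__).resolve().parents[1] / "results"

VARIABLES = [
    "stride_duration_s", "diagonal_dissociation_pct",
    "lateral_dissociation_pct", "suspension_pct",
    "stance_duration_fl_s", "stance_duration_hl_s",
    "swing_duration_fl_s", "swing_duration_hl_s",
    "duty_factor_fl", "duty_factor_hl",
]


def main() -> None:
    table = pd.read_csv(RESULTS / "stride_vars.csv")
    out = describe(table, ["gait", "condition"], VARIABLES)
    out.to_csv(RESULTS / "stride_parameters.csv", index=False,
               float_format="%.9g")
    wide = out.pivot_table(index="variable", columns=["gait", "condition"],
                           values="median")
    pd.set_option("display.width", 200)
    print(wide.round(3))
    print(f"\nwrote {RESULTS / 'stride_parameters.csv'}")


if __name__ == "__main__":
    main()
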