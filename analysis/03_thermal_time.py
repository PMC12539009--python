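#!/usr/bin/env python
"""Cumulative growing degree days for the imaging dates.

Thermal time accumulates from 1 January as the mean of the clamped daily
extremes minus the 4 degC base (upper cap 25 degC); the imaging date itself
is excluded because flights happen in the morning.

Reads:  results/temperatures.csv, results/plot_indices.csv
Writes: results/gdd.csv
"""

from pathlib import Path

import pandas as pd

from staygreen import thermal

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    temps = pd.read_csv(OUT / "temperatures.csv")
    dates = sorted(pd.read_csv(OUT / "plot_indices.csv")["date"].unique())
    table = thermal.gdd_table(temps, dates)
    table.rename_axis("date").reset_index().to_csv(OUT / "gdd.csv", index=False)
    print("cumulative GDD at imaging dates:")
    print(table.round(1).to_string())


if __name__ == "__main__":
    main()
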