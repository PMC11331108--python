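#!/usr/bin/env python
"""Classify survivorship and expansion decay per order.

Runs the full pipeline (filter -> group -> durations/ranges -> exceedance
curves -> trim -> best-transform test) on the synthetic tables written by
01_generate_data.py, at both the genus and species level, and writes:

  results/order_report.tsv — the per-order summary (decay labels per
                             source/level, orders sorted by abundance);
  results/fit_details.tsv  — slope/intercept/R^2 of every candidate
                             transform for every order-level curve.

Expected outcome: the memoryless order classifies LAW on every axis, the
heavy-tailed order classifies Pow, and the present-day table recovers LAW
from censored standing ranges.
"""

from pathlib import Path

import pandas as pd

from rangelaw import occurrences as occ
from rangelaw import pipeline as pl

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    fossil = occ.read_occurrence_table(ROOT / "data" / "fossil_occurrences.tsv",
                                       source_kind="fossil")
    present = occ.read_occurrence_table(ROOT / "data" / "present_day_hexgrid.tsv",
                                        source_kind="present_day")
    config = pl.AnalysisConfig()
    report = pl.run_full_analysis(fossil, present, config)
    report.to_csv(ROOT / "order_report.tsv", sep="\t", index=False)
    print(report.to_string(index=False))

    details = []
    for table in (fossil, present):
        for level in config.levels:
            details.append(pl.order_fit_details(
                pl.analyze_order_table(table, level, config)))
    detail_frame = pd.concat([d for d in details if len(d)], ignore_index=True)
    detail_frame.to_csv(ROOT / "fit_details.tsv", sep="\t", index=False,
                        float_format="%.6f")
    print(f"\nper-transform fit details: {len(detail_frame)} rows "
          f"-> {ROOT / 'fit_details.tsv'}")


if __name__ == "__main__":
    main()
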