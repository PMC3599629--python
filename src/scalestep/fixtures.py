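"""Packaged fixtures: the printed summary tables of the motivating study.

The study's raw 61-patient responses were never deposited; what is available
are the printed marginal frequencies (table 1), Mokken scalabilities
(table 2, including the MADRS variant with item 4 removed, instrument code
``"MADRS-x4"``), graded-response-model item locations (table 3) and relative
item information / discriminations (table 4). These ship as small CSV
resources and are used for fixture-arithmetic checks, never as substitutes
for computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd


@dataclass
class PaperFixtures:
    """Bundle of the printed tables as DataFrames."""

    table1: pd.DataFrame  # marginal category frequencies + missing
    table2: pd.DataFrame  # item/total H, CI bounds, alpha, n_obs (long format)
    table3: pd.DataFrame  # item location, corrected location, SE
    table4: pd.DataFrame  # relative information (display + numeric), discrimination, SE

    def table2_items(self, instrument: str) -> pd.Series:
        """Item scalabilities H_i for one instrument, indexed by item id."""
        df = self.table2[self.table2["instrument"] == instrument]
        summary = {"Total", "CI_low", "CI_high", "alpha", "n_obs"}
        items = df[~df["item"].isin(summary)]
        return items.set_index("item")["H"]

    def table2_summary(self, instrument: str) -> dict[str, float]:
        df = self.table2[self.table2["instrument"] == instrument]
        summary = {"Total", "CI_low", "CI_high", "alpha", "n_obs"}
        rows = df[df["item"].isin(summary)]
        return {k: float(v) for k, v in zip(rows["item"], rows["H"])}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("scalestep") / "fixtures" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_paper_fixtures() -> PaperFixtures:
    """Load the packaged printed tables exactly as published."""
    return PaperFixtures(
        table1=_read("table1.csv"),
        table2=_read("table2.csv"),
        table3=_read("table3.csv"),
        table4=_read("table4.csv"),
    )
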