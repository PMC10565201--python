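"""Cross-country transfer of waterpipe own-price elasticities.

Where no local waterpipe elasticity estimates exist, per-segment estimates
can be inferred from neighbouring countries that have both waterpipe and
cigarette elasticities: for each (country, segment) the waterpipe/cigarette
ratio is formed, ratios are averaged across countries with equal weights,
and the average ratio is applied to the local cigarette elasticity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["ElasticityTable", "transfer"]


@dataclass(frozen=True)
class ElasticityTable:
    """Per (country, segment) waterpipe and cigarette own-price elasticities.

    Backed by a DataFrame with columns ``country, segment, waterpipe,
    cigarette``; every segment must appear in every country and all
    elasticities must be negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"country", "segment", "waterpipe", "cigarette"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"elasticity table missing columns: {sorted(missing)}")
        if self.data.empty:
            raise ValueError("elasticity table must be non-empty")
        bad = self.data[(self.data["waterpipe"] >= 0) | (self.data["cigarette"] >= 0)]
        if not bad.empty:
            rows = bad[["country", "segment"]].to_records(index=False).tolist()
            raise ValueError(f"elasticities must be negative; offending rows: {rows}")
        counts = self.data.groupby("segment")["country"].nunique()
        n_countries = self.data["country"].nunique()
        incomplete = counts[counts < n_countries]
        if not incomplete.empty:
            raise ValueError(
                f"segment(s) missing in some country: {list(incomplete.index)}")

    @classmethod
    def from_csv(cls, path) -> "ElasticityTable":
        """Read a tabular text file with columns country, segment, waterpipe, cigarette."""
        return cls(pd.read_csv(Path(path)))

    @classmethod
    def from_records(cls, records) -> "ElasticityTable":
        return cls(pd.DataFrame.from_records(
            records, columns=["country", "segment", "waterpipe", "cigarette"]))


def transfer(table: ElasticityTable,
             local_cigarette_elasticity: float) -> dict[str, float]:
    """Per-segment waterpipe elasticities transferred to the local market.

    For each segment, the waterpipe/cigarette elasticity ratio is computed
    per country, the ratios are averaged arithmetically with equal country
    weights, and the mean ratio multiplies the local cigarette elasticity.
    The result is negative whenever every ratio is positive.
    """
    if local_cigarette_elasticity >= 0:
        raise ValueError("local cigarette elasticity must be negative")
    df = table.data.copy()
    df["ratio"] = df["waterpipe"] / df["cigarette"]
    mean_ratio = df.groupby("segment", sort=False)["ratio"].mean()
    return {seg: float(r * local_cigarette_elasticity)
            for seg, r in mean_ratio.items()}
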