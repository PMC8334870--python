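"""Impact ranges and rankings from the one-at-a-time sensitivity design.

For each study variable (titer, capital, time, scale, discount) and each
overall recovery yield, the impact is the spread of CoG/g across that
variable's levels with everything else held at base — e.g. for titer, the
CoG/g at the 0.1X multiplier minus the CoG/g at 10X.  Because the yields
live on a discrete grid, overall-yield "bins" are the exact distinct
product values, not histogram intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fixtures import VariationDesign

__all__ = ["ImpactTable", "impact_ranges", "rank_variables"]

_LEVEL_COUNTS = {
    "titer": "multiplier_levels",
    "capital": "multiplier_levels",
    "time": "multiplier_levels",
    "scale": "scale_levels_L",
    "discount": "discount_levels",
}


@dataclass(frozen=True)
class ImpactTable:
    """Per-(variable, overall yield) CoG/g spread, plus a headline ranking.

    ``table`` columns: variable, overall_yield, cog_min, cog_max, range.
    ``ranking`` orders variables by their range at the highest overall
    yield (the all-100% yield vector), descending, ties alphabetical.
    """

    table: pd.DataFrame
    ranking: tuple[str, ...]

    def range_at(self, variable: str, overall_yield: float) -> float:
        sub = self.table[
            (self.table["variable"] == variable)
            & np.isclose(self.table["overall_yield"], overall_yield)
        ]
        if sub.empty:
            raise KeyError(f"no impact row for {variable!r} at yield {overall_yield}")
        return float(sub["range"].iloc[0])


def impact_ranges(
    oat_results: pd.DataFrame, design: VariationDesign | None = None
) -> ImpactTable:
    """Summarise evaluated OAT results into an impact table.

    ``oat_results`` must carry ``variable``, ``overall_yield`` and
    ``cog_per_g`` columns (the output of evaluating
    :func:`~hatea.scenarios.oat_scenarios`).  When a design is given,
    coverage is checked: every (variable, yield) cell must contain one row
    per level of that variable.
    """
    required = {"variable", "overall_yield", "cog_per_g"}
    missing = required - set(oat_results.columns)
    if missing:
        raise ValueError(f"OAT results missing columns {sorted(missing)}")

    # exact distinct products; round away float dust from equal products
    # reached through different factor orderings
    work = oat_results.copy()
    work["overall_yield"] = work["overall_yield"].round(12)

    grouped = (
        work.groupby(["variable", "overall_yield"])["cog_per_g"]
        .agg(cog_min="min", cog_max="max", n="size")
        .reset_index()
    )
    if design is not None:
        for variable, attr in _LEVEL_COUNTS.items():
            expected = len(getattr(design, attr))
            cells = grouped[grouped["variable"] == variable]
            if cells.empty or (cells["n"] < expected).any():
                raise ValueError(
                    f"incomplete OAT coverage for variable {variable!r}"
                )
    grouped["range"] = grouped["cog_max"] - grouped["cog_min"]
    table = grouped.drop(columns="n")

    top_yield = table["overall_yield"].max()
    at_top = table[table["overall_yield"] == top_yield]
    ranking = tuple(
        at_top.sort_values(["range", "variable"], ascending=[False, True])["variable"]
    )
    return ImpactTable(table=table, ranking=ranking)


def rank_variables(table: ImpactTable) -> list[str]:
    """Variables ordered by decreasing impact at the all-100% yield vector."""
    return list(table.ranking)


def plot_impact_ranges(table: ImpactTable, path=None):
    """Tornado-style plot of CoG/g ranges vs overall yield (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for variable, sub in table.table.groupby("variable"):
        sub = sub.sort_values("overall_yield")
        ax.plot(100 * sub["overall_yield"], sub["range"], label=variable)
    ax.set_xlabel("overall recovery yield (%)")
    ax.set_ylabel("CoG/g range, max - min (USD/g)")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
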