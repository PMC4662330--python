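"""Derived comparison statistics: percent reductions, fold differences,
pooled ratios, and the cross-group mean.

These are the headline numbers of a drought x canopy-position analysis:
how much a trait shrank under drought within a canopy position, how many
times larger it is in sun than in shade needles within a treatment, and
pooled versions of both.  All arithmetic is done on unrounded means;
rounding (nearest integer for percentages, one decimal for folds) is a
formatting rule applied only when a report is rendered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import reference_group_means, reference_sapflow_totals

__all__ = [
    "ComparisonStat",
    "percent_reduction",
    "fold_difference",
    "comparison_table",
    "reference_comparisons",
    "sun_shade_gap_shrink",
]

#: Rounding rules applied at formatting time, by comparison kind.
_ROUNDING = {
    "drought_reduction_pct": 0,     # nearest integer percent
    "sun_shade_fold": 1,            # one decimal place
    "pooled_sun_shade_ratio": 1,
    "cross_group_mean": 2,
    "sapflow_reduction_pct": 0,
}


@dataclass(frozen=True)
class ComparisonStat:
    """One derived comparison with its formatting rule."""

    trait: str
    kind: str
    group: str          # e.g. 'sun', 'control', 'all'
    value: float        # unrounded
    rounding: int       # decimal places applied at display time

    @property
    def displayed(self) -> float:
        return round(self.value, self.rounding) if self.rounding else float(round(self.value))


def percent_reduction(control_mean: float, drought_mean: float) -> float:
    """100 * (control - drought) / control; negative means an increase."""
    if not control_mean > 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    return 100.0 * (control_mean - drought_mean) / control_mean


def fold_difference(a: float, b: float) -> float:
    """Ratio a / b (conventionally larger-canopy over smaller)."""
    if not b > 0:
        raise ValueError(f"denominator must be positive, got {b}")
    return a / b


def _cell(means: pd.DataFrame, trait: str, canopy: str, treatment: str) -> float:
    sel = means[
        (means["trait"] == trait)
        & (means["canopy"] == canopy)
        & (means["treatment"] == treatment)
    ]
    if len(sel) != 1:
        raise ValueError(f"expected exactly one mean for {trait}/{canopy}/{treatment}")
    return float(sel["mean"].iloc[0])


def comparison_table(means: pd.DataFrame) -> pd.DataFrame:
    """All derived comparisons from a long group-means table.

    ``means`` needs columns ``trait, canopy, treatment, mean`` (the shape
    produced by the mixed-model stage and by the shipped reference
    fixture).  For every trait: drought reductions within each canopy,
    sun/shade folds within each treatment, the pooled sun/shade ratio
    (mean of treatment cells per canopy), and the cross-group mean.
    """
    stats: list[ComparisonStat] = []
    for trait in means["trait"].unique():
        cells = {
            (c, t): _cell(means, trait, c, t)
            for c in ("sun", "shade") for t in ("control", "drought")
        }
        for canopy in ("sun", "shade"):
            stats.append(ComparisonStat(
                trait, "drought_reduction_pct", canopy,
                percent_reduction(cells[(canopy, "control")], cells[(canopy, "drought")]),
                _ROUNDING["drought_reduction_pct"],
            ))
        for trt in ("control", "drought"):
            stats.append(ComparisonStat(
                trait, "sun_shade_fold", trt,
                fold_difference(cells[("sun", trt)], cells[("shade", trt)]),
                _ROUNDING["sun_shade_fold"],
            ))
        pooled_sun = np.mean([cells[("sun", t)] for t in ("control", "drought")])
        pooled_shade = np.mean([cells[("shade", t)] for t in ("control", "drought")])
        stats.append(ComparisonStat(
            trait, "pooled_sun_shade_ratio", "all",
            fold_difference(pooled_sun, pooled_shade),
            _ROUNDING["pooled_sun_shade_ratio"],
        ))
        stats.append(ComparisonStat(
            trait, "cross_group_mean", "all",
            float(np.mean(list(cells.values()))),
            _ROUNDING["cross_group_mean"],
        ))
    return pd.DataFrame([s.__dict__ | {"displayed": s.displayed} for s in stats])


def sun_shade_gap_shrink(
    means: pd.DataFrame,
    exclude: tuple[str, ...] = ("A_x_pct",),
) -> pd.DataFrame:
    """Exploratory: relative shrink of the sun-shade gap under drought.

    For each trait, gap = sun - shade per treatment; shrink =
    (gap_control - gap_drought) / gap_control.  Averaged over the
    canopy-sensitive traits (the canopy-insensitive xylem proportion is
    excluded).  The aggregation behind the published headline figure is
    unstated, so this summary is exploratory and never an acceptance
    quantity.
    """
    rows = []
    for trait in means["trait"].unique():
        if trait in exclude:
            continue
        gap_c = _cell(means, trait, "sun", "control") - _cell(means, trait, "shade", "control")
        gap_d = _cell(means, trait, "sun", "drought") - _cell(means, trait, "shade", "drought")
        if gap_c <= 0:
            continue
        rows.append({"trait": trait, "gap_control": gap_c, "gap_drought": gap_d,
                     "relative_shrink": (gap_c - gap_d) / gap_c})
    df = pd.DataFrame(rows)
    df.attrs["mean_relative_shrink"] = float(df["relative_shrink"].mean()) if len(df) else np.nan
    return df


def reference_comparisons() -> pd.DataFrame:
    """Derived comparisons computed from the shipped reference group means,
    plus the published sap-flow reduction."""
    table = comparison_table(reference_group_means())
    sap = reference_sapflow_totals().set_index("plot")["accumulated_mm"]
    red = percent_reduction(float(sap["control"]), float(sap["drought"]))
    sap_row = pd.DataFrame([{
        "trait": "sapflow", "kind": "sapflow_reduction_pct", "group": "all",
        "value": red, "rounding": _ROUNDING["sapflow_reduction_pct"],
        "displayed": float(round(red)),
    }])
    return pd.concat([table, sap_row], ignore_index=True)
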