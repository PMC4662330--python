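"""Tabular interfaces: CSV schemas, readers/writers, shipped reference data.

Two measurement tables drive the pipeline:

* tracheid table — one row per tracheid lumen:
  ``treatment, canopy, tree_id, shoot_id, needle_id, tracheid_id,
  d_max_um, d_min_um, a_lum_um2``
* needle table — one row per needle cross-section:
  ``treatment, canopy, tree_id, shoot_id, needle_id, family,
  a_n_mm2, a_v_mm2, a_x_um2, a_p_um2``

The package also ships a read-only fixture with the reference field
study's published group means (2 canopy positions x 2 watering
treatments) so the derived comparison statistics can be reproduced
without any simulation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

TRACHEID_COLUMNS = [
    "treatment", "canopy", "tree_id", "shoot_id", "needle_id",
    "tracheid_id", "d_max_um", "d_min_um", "a_lum_um2",
]

NEEDLE_COLUMNS = [
    "treatment", "canopy", "tree_id", "shoot_id", "needle_id",
    "family", "a_n_mm2", "a_v_mm2", "a_x_um2", "a_p_um2",
]

TREATMENTS = ("control", "drought")
CANOPIES = ("sun", "shade")


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {missing}")
    return df[required]


def read_tracheid_table(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), TRACHEID_COLUMNS, "tracheid table")


def read_needle_table(path: str | Path) -> pd.DataFrame:
    return _check_columns(pd.read_csv(path), NEEDLE_COLUMNS, "needle table")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV deterministically (fixed column order, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def reference_group_means() -> pd.DataFrame:
    """Published group means (with 95% CIs) of the reference study.

    Returns a long table: ``trait, canopy, treatment, mean, ci_lo, ci_hi,
    unit, display_scale``.  Values are in the package's natural units
    (diameters µm, A_n/A_v mm², A_x/A_p/lumen areas µm², k_th in
    kg m s⁻¹ MPa⁻¹, k_s in the reported-scale convention);
    ``display_scale`` recovers the scale the source prints
    (printed value = mean / display_scale).
    """
    with resources.files("needlehydro.data").joinpath(
        "reference_group_means.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def reference_sapflow_totals() -> pd.DataFrame:
    """Published per-plot accumulated sap flow totals (mm) of the study."""
    with resources.files("needlehydro.data").joinpath(
        "reference_sapflow_totals.csv"
    ).open() as fh:
        return pd.read_csv(fh)
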