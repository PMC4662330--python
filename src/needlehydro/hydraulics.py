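"""Tracheid-level hydraulic conductivity and needle-level trait aggregation.

The water-conducting cells of conifer needles (tracheids) have roughly
elliptical lumina.  The theoretical hydraulic conductivity of a single
tracheid follows the Hagen-Poiseuille law for laminar flow, with the
classical ``r^4`` replaced by an effective fourth-power radius for an
elliptical cross-section:

    k_t = (pi * rho / (8 * eta)) * r_lum^4
    r_lum^4 = d_max^3 * d_min^3 / (8 * (d_max^2 + d_min^2))

where ``d_max`` and ``d_min`` are the major and minor lumen diameters,
``rho`` is the density and ``eta`` the dynamic viscosity of water at 20 °C.
Diameters are measured in micrometres and converted to metres before
evaluation, giving ``k_t`` in kg m s⁻¹ MPa⁻¹.

Per needle cross-section, tracheid-level quantities are either averaged
(diameters, lumen area, flatness) or summed (conductivity, lumen area
totals); needle-level areas (whole section, vascular cylinder, xylem,
phloem) are carried through and used for the proportional traits and for
xylem-specific conductivity ``k_s = k_th / A_x``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RHO_WATER_20C",
    "ETA_WATER_20C",
    "PhysicalConstants",
    "TracheidGeometry",
    "NeedleSection",
    "NeedleTraits",
    "orient_tracheid",
    "tracheid_conductivity",
    "needle_traits",
    "compute_traits_table",
    "sections_from_tables",
    "TRAIT_COLUMNS",
    "ID_COLUMNS",
]

#: Density of water at 20 °C, kg m⁻³.
RHO_WATER_20C = 998.205
#: Dynamic viscosity of water at 20 °C, MPa s.
ETA_WATER_20C = 1.002e-9

#: Identifier columns common to the tabular interfaces.
ID_COLUMNS = ["treatment", "canopy", "tree_id", "shoot_id", "needle_id"]

#: Trait columns of the per-needle output table, one per reported trait.
TRAIT_COLUMNS = [
    "A_lum", "A_n", "A_p", "A_p_pct", "A_v", "A_x", "A_x_pct",
    "d_max", "d_min", "F_t", "k_th", "k_s", "k_s_si", "N_lum", "N_t",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants entering the Hagen-Poiseuille law.

    Parameters
    ----------
    rho : float
        Water density, kg m⁻³ (default: 20 °C value).
    eta : float
        Water dynamic viscosity, MPa s (default: 20 °C value).
    """

    rho: float = RHO_WATER_20C
    eta: float = ETA_WATER_20C

    def __post_init__(self) -> None:
        if not (self.rho > 0 and math.isfinite(self.rho)):
            raise ValueError(f"rho must be positive and finite, got {self.rho}")
        if not (self.eta > 0 and math.isfinite(self.eta)):
            raise ValueError(f"eta must be positive and finite, got {self.eta}")

    @property
    def poiseuille_factor(self) -> float:
        """pi * rho / (8 * eta), the prefactor of the conductivity law."""
        return math.pi * self.rho / (8.0 * self.eta)


DEFAULT_CONSTANTS = PhysicalConstants()


def orient_tracheid(d1: float, d2: float) -> tuple[float, float]:
    """Order a diameter pair as (d_max, d_min).

    Idempotent plumbing for callers holding unordered axis measurements.
    """
    d1 = float(d1)
    d2 = float(d2)
    if not (d1 > 0 and d2 > 0 and math.isfinite(d1) and math.isfinite(d2)):
        raise ValueError(f"diameters must be positive and finite, got ({d1}, {d2})")
    return (d1, d2) if d1 >= d2 else (d2, d1)


def tracheid_conductivity(
    d_max_um: float,
    d_min_um: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Theoretical hydraulic conductivity of one elliptical tracheid lumen.

    Parameters
    ----------
    d_max_um, d_min_um : float
        Major and minor lumen diameters in µm; ``d_max_um >= d_min_um > 0``.
        Callers holding unordered pairs must orient them first
        (:func:`orient_tracheid`).
    constants : PhysicalConstants
        Water density/viscosity.

    Returns
    -------
    float
        k_t in kg m s⁻¹ MPa⁻¹.
    """
    d_max_um = float(d_max_um)
    d_min_um = float(d_min_um)
    if not (math.isfinite(d_max_um) and math.isfinite(d_min_um)):
        raise ValueError("diameters must be finite")
    if d_min_um <= 0:
        raise ValueError(f"diameters must be positive, got d_min={d_min_um}")
    if d_max_um < d_min_um:
        raise ValueError(
            f"d_max ({d_max_um}) < d_min ({d_min_um}); orient the pair first"
        )
    dmax = d_max_um * 1e-6
    dmin = d_min_um * 1e-6
    r4 = (dmax**3 * dmin**3) / (8.0 * (dmax**2 + dmin**2))
    return constants.poiseuille_factor * r4


def _conductivity_array(
    d_max_um: np.ndarray,
    d_min_um: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Vectorised k_t for validated arrays of oriented diameters (µm)."""
    dmax = np.asarray(d_max_um, dtype=float) * 1e-6
    dmin = np.asarray(d_min_um, dtype=float) * 1e-6
    r4 = (dmax**3 * dmin**3) / (8.0 * (dmax**2 + dmin**2))
    return constants.poiseuille_factor * r4


@dataclass(frozen=True)
class TracheidGeometry:
    """One measured tracheid lumen: diameters in µm, area in µm²."""

    d_max: float
    d_min: float
    a_lum: float

    def __post_init__(self) -> None:
        if not (self.d_min > 0 and self.d_max >= self.d_min):
            raise ValueError(
                f"require d_max >= d_min > 0, got ({self.d_max}, {self.d_min})"
            )
        if not self.a_lum > 0:
            raise ValueError(f"a_lum must be positive, got {self.a_lum}")

    @property
    def flatness(self) -> float:
        return self.d_max / self.d_min

    @property
    def ellipse_area(self) -> float:
        """Area of the ellipse with these axes (µm²)."""
        return math.pi * self.d_max * self.d_min / 4.0


@dataclass
class NeedleSection:
    """One needle cross-section: design labels, region areas, tracheids.

    Areas follow the measurement convention of the study design:
    ``a_n`` and ``a_v`` in mm², ``a_x`` and ``a_p`` in µm².
    """

    treatment: str
    canopy: str
    tree_id: str
    shoot_id: str
    needle_id: str
    a_n_mm2: float
    a_v_mm2: float
    a_x_um2: float
    a_p_um2: float
    tracheids: Sequence[TracheidGeometry] = field(default_factory=list)
    family: str | None = None

    def validate(self) -> "NeedleSection":
        if len(self.tracheids) < 1:
            raise ValueError("a valid needle has at least one tracheid")
        if not (self.a_x_um2 > 0 and self.a_p_um2 > 0):
            raise ValueError("xylem and phloem areas must be positive")
        a_n_um2 = self.a_n_mm2 * 1e6
        a_v_um2 = self.a_v_mm2 * 1e6
        if not a_v_um2 < a_n_um2:
            raise ValueError("vascular cylinder must be smaller than the needle")
        if self.a_x_um2 + self.a_p_um2 > a_v_um2:
            raise ValueError("xylem + phloem exceed the vascular cylinder")
        total_lum = sum(t.a_lum for t in self.tracheids)
        if total_lum > self.a_x_um2 * (1 + 1e-9):
            raise ValueError("total lumen area exceeds xylem area")
        return self


@dataclass(frozen=True)
class NeedleTraits:
    """The per-needle trait vector (one value per reported trait).

    ``k_s`` is the xylem-specific conductivity in the reported-scale
    convention (``k_th`` divided by A_x *in µm²*); ``k_s_si`` divides by
    A_x in m².  See the methods note for why both are carried.
    """

    a_lum: float      # mean tracheid lumen area, µm²
    a_n: float        # needle cross-section area, mm²
    a_p: float        # phloem area, µm²
    a_p_pct: float    # phloem fraction of needle area, %
    a_v: float        # vascular cylinder area, mm²
    a_x: float        # xylem area, µm²
    a_x_pct: float    # xylem fraction of needle area, %
    d_max: float      # mean maximum lumen diameter, µm
    d_min: float      # mean minimum lumen diameter, µm
    f_t: float        # mean per-tracheid flatness d_max/d_min
    k_th: float       # needle conductivity = sum of k_t, kg m s⁻¹ MPa⁻¹
    k_s: float        # k_th / A_x[µm²] (reported-scale)
    k_s_si: float     # k_th / A_x[m²] (SI)
    n_lum: float      # total lumen area, µm²
    n_t: int          # tracheid count

    def jensen_gap(self, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
        """Diagnostic: k_th - n_t * k_t(d_max_mean, d_min_mean).

        Non-negative for populations whose diameter variation is dominated
        by overall size scaling (k_t scales as size⁴ along rays); the
        elliptical kernel is not jointly convex, so this is a diagnostic,
        not an enforced invariant.
        """
        return self.k_th - self.n_t * tracheid_conductivity(
            self.d_max, self.d_min, constants
        )


def needle_traits(
    section: NeedleSection,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> NeedleTraits:
    """Aggregate one needle section into its trait vector.

    Tracheid-level quantities are averaged (diameters, lumen area,
    flatness as the mean of per-tracheid ratios) or summed (conductivity,
    total lumen area); proportional areas are computed after converting
    the needle area to µm².
    """
    section.validate()
    dmax = np.array([t.d_max for t in section.tracheids])
    dmin = np.array([t.d_min for t in section.tracheids])
    alum = np.array([t.a_lum for t in section.tracheids])
    k_t = _conductivity_array(dmax, dmin, constants)
    k_th = float(k_t.sum())
    a_n_um2 = section.a_n_mm2 * 1e6
    return NeedleTraits(
        a_lum=float(alum.mean()),
        a_n=section.a_n_mm2,
        a_p=section.a_p_um2,
        a_p_pct=100.0 * section.a_p_um2 / a_n_um2,
        a_v=section.a_v_mm2,
        a_x=section.a_x_um2,
        a_x_pct=100.0 * section.a_x_um2 / a_n_um2,
        d_max=float(dmax.mean()),
        d_min=float(dmin.mean()),
        f_t=float((dmax / dmin).mean()),
        k_th=k_th,
        k_s=k_th / section.a_x_um2,
        k_s_si=k_th / (section.a_x_um2 * 1e-12),
        n_lum=float(alum.sum()),
        n_t=len(section.tracheids),
    )


def sections_from_tables(
    tracheids: pd.DataFrame,
    needles: pd.DataFrame,
    rows: Sequence[int] | None = None,
) -> list[NeedleSection]:
    """Materialise :class:`NeedleSection` objects from the two tables.

    ``rows`` selects positional indices of the needle table (default all).
    """
    grouped = tracheids.groupby(ID_COLUMNS, sort=False)
    out = []
    idx = range(len(needles)) if rows is None else rows
    for i in idx:
        row = needles.iloc[i]
        key = tuple(row[c] for c in ID_COLUMNS)
        sub = grouped.get_group(key)
        out.append(NeedleSection(
            treatment=row["treatment"], canopy=row["canopy"], tree_id=row["tree_id"],
            shoot_id=row["shoot_id"], needle_id=row["needle_id"],
            family=row.get("family"),
            a_n_mm2=row["a_n_mm2"], a_v_mm2=row["a_v_mm2"],
            a_x_um2=row["a_x_um2"], a_p_um2=row["a_p_um2"],
            tracheids=[
                TracheidGeometry(r.d_max_um, r.d_min_um, r.a_lum_um2)
                for r in sub.itertuples()
            ],
        ))
    return out


def compute_traits_table(
    tracheids: pd.DataFrame,
    needles: pd.DataFrame,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Vectorised per-needle trait table from the two measurement tables.

    Parameters
    ----------
    tracheids : DataFrame
        Tracheid table with columns ``treatment, canopy, tree_id, shoot_id,
        needle_id, tracheid_id, d_max_um, d_min_um, a_lum_um2``.
    needles : DataFrame
        Needle table with columns ``treatment, canopy, tree_id, shoot_id,
        needle_id, family, a_n_mm2, a_v_mm2, a_x_um2, a_p_um2``.

    Returns
    -------
    DataFrame
        One row per needle: identifier columns, ``family`` (metadata only),
        then :data:`TRAIT_COLUMNS`.
    """
    t = tracheids.copy()
    if (t["d_min_um"] <= 0).any() or not np.isfinite(t[["d_max_um", "d_min_um"]]).all().all():
        raise ValueError("tracheid diameters must be positive and finite")
    if (t["d_max_um"] < t["d_min_um"]).any():
        raise ValueError("tracheid table contains d_max < d_min; orient first")
    if (t["a_lum_um2"] <= 0).any():
        raise ValueError("tracheid lumen areas must be positive")
    t["k_t"] = _conductivity_array(t["d_max_um"].to_numpy(), t["d_min_um"].to_numpy(), constants)
    t["ratio"] = t["d_max_um"] / t["d_min_um"]

    g = t.groupby(ID_COLUMNS, sort=True)
    agg = g.agg(
        A_lum=("a_lum_um2", "mean"),
        d_max=("d_max_um", "mean"),
        d_min=("d_min_um", "mean"),
        F_t=("ratio", "mean"),
        k_th=("k_t", "sum"),
        N_lum=("a_lum_um2", "sum"),
        N_t=("a_lum_um2", "size"),
    ).reset_index()

    need = needles.copy()
    if (need["a_x_um2"] <= 0).any():
        raise ValueError("xylem areas must be positive")
    merged = agg.merge(need, on=ID_COLUMNS, how="inner", validate="one_to_one")
    if len(merged) != len(agg) or len(merged) != len(need):
        raise ValueError(
            "tracheid and needle tables do not describe the same set of needles"
        )
    a_n_um2 = merged["a_n_mm2"] * 1e6
    merged["A_n"] = merged["a_n_mm2"]
    merged["A_v"] = merged["a_v_mm2"]
    merged["A_x"] = merged["a_x_um2"]
    merged["A_p"] = merged["a_p_um2"]
    merged["A_x_pct"] = 100.0 * merged["a_x_um2"] / a_n_um2
    merged["A_p_pct"] = 100.0 * merged["a_p_um2"] / a_n_um2
    merged["k_s"] = merged["k_th"] / merged["a_x_um2"]
    merged["k_s_si"] = merged["k_th"] / (merged["a_x_um2"] * 1e-12)
    cols = ID_COLUMNS + (["family"] if "family" in merged.columns else [])
    return merged[cols + TRAIT_COLUMNS]
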