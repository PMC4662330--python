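"""Hierarchical synthetic dataset generator for the drought x canopy design.

Emulates the reference study's sampling design — 2 watering treatments
(one plot each) x 3 trees per plot x 2 canopy positions x 5 shoots per
tree and position x 7 needles per shoot — with multiplicative lognormal
random effects for trees and for shoots nested in trees, the variance
structure the mixed-model stage assumes.

Per needle, a tracheid count is drawn around the group target; per
tracheid, the minor lumen diameter is lognormal and the major diameter is
minor x an independent flatness draw (1 + gamma excess, so flatness >= 1);
the lumen is a perfect ellipse.  Xylem area is the lumen-area total
divided by a drawn packing fraction, and the remaining section areas
chain from it by the calibration's area ratios with lognormal noise.

Calibration targets are recovered in expectation: the generator computes
the closed-form mean of its own xylem area per group (lognormal second
moments are explicit) and anchors the area chain on it, and anchors the
minor-diameter scale at ``d_max_target / f_t_target`` so that the group
means of d_max and of flatness (a mean of per-tracheid ratios, which for
real anatomies exceeds the ratio of mean diameters) both land on target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CANOPIES, TREATMENTS, NEEDLE_COLUMNS, TRACHEID_COLUMNS, reference_group_means

__all__ = [
    "GroupCalibration",
    "SimulationConfig",
    "CalibrationError",
    "study_calibration",
    "no_drought_calibration",
    "expected_xylem_area",
    "generate_dataset",
]

#: Calibration traits required for every (canopy, treatment) cell.
_TARGET_TRAITS = ("n_t", "d_max", "d_min", "f_t", "a_n_mm2", "a_v_mm2", "a_x_um2", "a_p_um2")


class CalibrationError(ValueError):
    """Raised when a group's targets cannot be realised geometrically."""


@dataclass(frozen=True)
class GroupCalibration:
    """Target group means for one (canopy, treatment) cell.

    Diameters in µm, ``a_n``/``a_v`` in mm², ``a_x``/``a_p`` in µm²;
    ``n_t`` is the mean tracheid count and ``f_t`` the mean per-tracheid
    flatness.
    """

    canopy: str
    treatment: str
    n_t: float
    d_max: float
    d_min: float
    f_t: float
    a_n_mm2: float
    a_v_mm2: float
    a_x_um2: float
    a_p_um2: float

    def __post_init__(self) -> None:
        name = f"{self.canopy}/{self.treatment}"
        for trait in _TARGET_TRAITS:
            v = getattr(self, trait)
            if not (v > 0 and math.isfinite(v)):
                raise CalibrationError(f"group {name}: {trait} must be positive, got {v}")
        if self.d_max < self.d_min:
            raise CalibrationError(f"group {name}: d_max < d_min")
        if self.f_t < 1:
            raise CalibrationError(f"group {name}: flatness target below 1")
        implied_lumen = self.n_t * math.pi / 4.0 * self.d_max * self.d_min
        if implied_lumen > 0.8 * self.a_x_um2:
            raise CalibrationError(
                f"group {name}: implied total lumen area {implied_lumen:.0f} µm² "
                f"is infeasibly close to the xylem target {self.a_x_um2:.0f} µm²"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Design sizes, dispersion parameters and seed for one simulation.

    Random-effect magnitudes are coefficients of variation of
    multiplicative lognormal effects (mean 1); the study reports no
    variance components, so the defaults are modest values typical of
    within-stand anatomical variation.
    """

    trees_per_plot: int = 3
    shoots_per_tree: int = 5
    needles_per_shoot: int = 7
    tree_cv: float = 0.08         # between-tree random effect CV
    shoot_cv: float = 0.05        # shoot-within-tree random effect CV
    diameter_cv: float = 0.25     # tracheid-to-tracheid minor-diameter CV
    count_cv: float = 0.12        # tracheid-count dispersion (CV of the lognormal mean)
    packing_mean: float = 0.35    # lumen area / xylem area
    packing_cv: float = 0.10
    area_cv: float = 0.05         # residual noise on the section-area chain
    flatness_excess_cv: float = 0.5   # CV of the gamma-distributed (flatness - 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trees_per_plot", "shoots_per_tree", "needles_per_shoot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("tree_cv", "shoot_cv", "diameter_cv", "count_cv",
                     "packing_cv", "area_cv", "flatness_excess_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.packing_mean < 1:
            raise ValueError("packing_mean must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


def study_calibration() -> dict[tuple[str, str], GroupCalibration]:
    """The 2x2 calibration preset encoding the study's published group means."""
    ref = reference_group_means().set_index(["trait", "canopy", "treatment"])["mean"]
    out = {}
    for canopy in CANOPIES:
        for trt in TREATMENTS:
            out[(canopy, trt)] = GroupCalibration(
                canopy=canopy,
                treatment=trt,
                n_t=ref[("N_t", canopy, trt)],
                d_max=ref[("d_max", canopy, trt)],
                d_min=ref[("d_min", canopy, trt)],
                f_t=ref[("F_t", canopy, trt)],
                a_n_mm2=ref[("A_n", canopy, trt)],
                a_v_mm2=ref[("A_v", canopy, trt)],
                a_x_um2=ref[("A_x", canopy, trt)],
                a_p_um2=ref[("A_p", canopy, trt)],
            )
    return out


def no_drought_calibration(
    base: Mapping[tuple[str, str], GroupCalibration] | None = None,
) -> dict[tuple[str, str], GroupCalibration]:
    """Null calibration: drought cells copy the control cells per canopy.

    Used to simulate datasets in which the watering treatment has no
    effect at all (type-I error calibration of the drought test).
    """
    base = dict(base) if base is not None else study_calibration()
    out = {}
    for canopy in CANOPIES:
        ctrl = base[(canopy, "control")]
        out[(canopy, "control")] = ctrl
        out[(canopy, "drought")] = replace(ctrl, treatment="drought")
    return out


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal draws parameterised by mean and coefficient of variation."""
    if cv == 0:
        return np.full(size, float(mean))
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _flatness(rng: np.random.Generator, f_t: float, excess_cv: float, size) -> np.ndarray:
    """Flatness draws: 1 + gamma excess with mean f_t - 1, guaranteeing >= 1."""
    mean_excess = f_t - 1.0
    if mean_excess <= 0 or excess_cv == 0:
        return np.full(size, float(f_t))
    shape = 1.0 / (excess_cv * excess_cv)
    scale = mean_excess * excess_cv * excess_cv
    return 1.0 + rng.gamma(shape, scale, size)


def expected_xylem_area(cal: GroupCalibration, config: SimulationConfig) -> float:
    """Closed-form E[a_x] (µm²) of the generator for one group.

    E[a_x] = n_t * (π/4) f_t D² (1+cv_tree²)(1+cv_shoot²)(1+cv_d²)
             * (1+cv_packing²)/packing_mean,  with D = d_max / f_t
    the minor-diameter scale.  Used to anchor the area chain so that the
    group mean of A_n recovers its calibration target.
    """
    d_scale = cal.d_max / cal.f_t
    e_alum = (
        math.pi / 4.0 * cal.f_t * d_scale**2
        * (1 + config.tree_cv**2) * (1 + config.shoot_cv**2) * (1 + config.diameter_cv**2)
    )
    e_inv_packing = (1 + config.packing_cv**2) / config.packing_mean
    return cal.n_t * e_alum * e_inv_packing


def generate_dataset(
    config: SimulationConfig,
    calibration: Mapping[tuple[str, str], GroupCalibration] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one full hierarchical dataset.

    Returns
    -------
    (tracheid_df, needle_df)
        The two standard measurement tables.  Identical ``config``
        (including seed) and calibration give byte-identical CSV output.
    """
    if calibration is None:
        calibration = study_calibration()
    missing = [k for c in CANOPIES for t in TREATMENTS if (k := (c, t)) not in calibration]
    if missing:
        raise CalibrationError(f"incomplete 2x2 calibration, missing cells: {missing}")

    rng = np.random.default_rng(config.seed)
    T, S, N = config.trees_per_plot, config.shoots_per_tree, config.needles_per_shoot
    tracheid_rows: list[pd.DataFrame] = []
    needle_rows: list[pd.DataFrame] = []

    for treatment in TREATMENTS:
        b_tree = _lognormal(rng, 1.0, config.tree_cv, T)
        for canopy in CANOPIES:
            cal = calibration[(canopy, treatment)]
            d_scale = cal.d_max / cal.f_t
            e_ax = expected_xylem_area(cal, config)

            b_shoot = _lognormal(rng, 1.0, config.shoot_cv, (T, S))
            counts = np.maximum(
                1, np.rint(_lognormal(rng, cal.n_t, config.count_cv, (T, S, N))).astype(int)
            )
            n_needles = T * S * N
            flat_counts = counts.reshape(-1)
            total = int(flat_counts.sum())

            needle_of = np.repeat(np.arange(n_needles), flat_counts)
            tree_of_needle = np.repeat(np.arange(T), S * N)
            shoot_of_needle = np.tile(np.repeat(np.arange(S), N), T)

            scale_per_needle = (
                d_scale * b_tree[tree_of_needle] * b_shoot[tree_of_needle, shoot_of_needle]
            )
            d_min = _lognormal(rng, 1.0, config.diameter_cv, total) * scale_per_needle[needle_of]
            f = _flatness(rng, cal.f_t, config.flatness_excess_cv, total)
            d_max = d_min * f
            a_lum = math.pi / 4.0 * d_max * d_min

            n_lum = np.bincount(needle_of, weights=a_lum, minlength=n_needles)
            packing = np.clip(
                _lognormal(rng, config.packing_mean, config.packing_cv, n_needles),
                0.01, 0.95,
            )
            a_x = n_lum / packing

            a_n_target_um2 = cal.a_n_mm2 * 1e6
            a_v_target_um2 = cal.a_v_mm2 * 1e6
            a_n = a_x * (a_n_target_um2 / e_ax) * _lognormal(rng, 1.0, config.area_cv, n_needles)
            a_v = a_n * (a_v_target_um2 / a_n_target_um2) * _lognormal(
                rng, 1.0, config.area_cv, n_needles
            )
            a_p = a_v * (cal.a_p_um2 / a_v_target_um2) * _lognormal(
                rng, 1.0, config.area_cv, n_needles
            )
            # enforce the section hierarchy (adjustments are vanishingly rare
            # under the default dispersions)
            a_p = np.minimum(a_p, np.maximum(a_v - a_x, 0.0) * 0.999)
            bad = a_p <= 0
            if bad.any():
                a_v = np.where(bad, (a_x + cal.a_p_um2) / 0.999, a_v)
                a_p = np.where(bad, float(cal.a_p_um2), a_p)
            a_n = np.maximum(a_n, a_v / 0.99)

            tree_ids = np.array([f"{treatment}_t{i + 1:02d}" for i in range(T)])
            shoot_ids = np.array([f"s{j + 1}" for j in range(S)])
            needle_ids = np.array([f"n{k + 1}" for k in range(N)])
            families = np.array([f"F{i % 3 + 1}" for i in range(T)])

            needle_rows.append(pd.DataFrame({
                "treatment": treatment,
                "canopy": canopy,
                "tree_id": tree_ids[tree_of_needle],
                "shoot_id": shoot_ids[shoot_of_needle],
                "needle_id": np.tile(needle_ids, T * S),
                "family": families[tree_of_needle],
                "a_n_mm2": a_n / 1e6,
                "a_v_mm2": a_v / 1e6,
                "a_x_um2": a_x,
                "a_p_um2": a_p,
            }))
            tracheid_id = np.concatenate([np.arange(1, c + 1) for c in flat_counts])
            tracheid_rows.append(pd.DataFrame({
                "treatment": treatment,
                "canopy": canopy,
                "tree_id": tree_ids[tree_of_needle[needle_of]],
                "shoot_id": shoot_ids[shoot_of_needle[needle_of]],
                "needle_id": np.tile(needle_ids, T * S)[needle_of],
                "tracheid_id": np.char.add("c", tracheid_id.astype(str)),
                "d_max_um": d_max,
                "d_min_um": d_min,
                "a_lum_um2": a_lum,
            }))

    tracheids = pd.concat(tracheid_rows, ignore_index=True)[TRACHEID_COLUMNS]
    needles = pd.concat(needle_rows, ignore_index=True)[NEEDLE_COLUMNS]
    return tracheids, needles
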