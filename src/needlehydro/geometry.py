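"""Geometric surrogate for the microscopy measurement workflow.

Builds an idealised needle cross-section from a :class:`NeedleSection`
(nested ellipses for the needle outline, vascular cylinder, xylem and
phloem, plus non-overlapping elliptical tracheid lumina placed in the
xylem by dart throwing), rasterises it at a chosen resolution with
pixel-center point-in-ellipse membership (no anti-aliasing, so results
are exactly reproducible), and re-measures every area and lumen diameter
from the label mask.

This is a round-trip validation harness for the measurement chain — it
quantifies how much pixel-count measurement distorts the traits — not a
model of real micrographs.  Diameter conventions on the mask: the major
diameter is the maximum pairwise pixel-center distance plus one pixel,
the minor diameter the minimal caliper (rotating projection) width plus
one pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hydraulics import NeedleSection, TracheidGeometry

__all__ = [
    "InfeasibleLayoutError",
    "Ellipse",
    "SectionLayout",
    "MeasuredSection",
    "layout_section",
    "rasterize_and_measure",
]

#: Maximum fraction of the xylem area the lumina may occupy for layout.
MAX_LUMEN_PACKING = 0.6


class InfeasibleLayoutError(RuntimeError):
    """Raised when a section cannot be laid out geometrically."""


@dataclass(frozen=True)
class Ellipse:
    """An ellipse: center (µm), semi-axes (µm), rotation angle (rad)."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def boundary(self, n: int = 24) -> np.ndarray:
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        c, s = math.cos(self.theta), math.sin(self.theta)
        return np.column_stack([self.cx + c * x - s * y, self.cy + s * x + c * y])

    def contains(self, pts: np.ndarray, inflate: float = 1.0) -> np.ndarray:
        pts = np.atleast_2d(pts)
        dx = pts[:, 0] - self.cx
        dy = pts[:, 1] - self.cy
        c, s = math.cos(self.theta), math.sin(self.theta)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / (self.a * inflate)) ** 2 + (v / (self.b * inflate)) ** 2 <= 1.0


def _ellipse_for_area(area: float, aspect: float, cx: float = 0.0, cy: float = 0.0,
                      theta: float = 0.0) -> Ellipse:
    b = math.sqrt(area / (math.pi * aspect))
    return Ellipse(cx, cy, aspect * b, b, theta)


def _inside_with_margin(inner: Ellipse, outer: Ellipse, margin: float = 0.995) -> bool:
    return bool(outer.contains(inner.boundary(48), inflate=margin).all())


def _overlaps(e1: Ellipse, e2: Ellipse, safety: float = 1.02) -> bool:
    """Approximate ellipse-ellipse overlap test.

    Boundary-sampling test with a small safety inflation: conservative
    enough that accepted placements are disjoint in practice while still
    permitting the ~0.35 lumen packing the anatomy requires.
    """
    d = math.hypot(e1.cx - e2.cx, e1.cy - e2.cy)
    if d > (e1.a + e2.a) * safety:
        return False
    if e2.contains(np.array([[e1.cx, e1.cy]]), inflate=safety)[0]:
        return True
    if e1.contains(np.array([[e2.cx, e2.cy]]), inflate=safety)[0]:
        return True
    if e2.contains(e1.boundary(24), inflate=safety).any():
        return True
    if e1.contains(e2.boundary(24), inflate=safety).any():
        return True
    return False


@dataclass
class SectionLayout:
    """Idealised geometric cross-section: nested region ellipses + lumina."""

    section: NeedleSection
    needle: Ellipse
    vascular: Ellipse
    xylem: Ellipse
    phloem: Ellipse
    lumens: list[Ellipse]
    seed: int
    aspect: float

    def region_areas(self) -> dict[str, float]:
        """Analytic region areas (µm²) — exact by construction."""
        return {
            "a_n_um2": self.needle.area,
            "a_v_um2": self.vascular.area,
            "a_x_um2": self.xylem.area,
            "a_p_um2": self.phloem.area,
        }


def layout_section(
    section: NeedleSection,
    seed: int,
    aspect: float = 2.0,
    max_attempts: int = 4000,
) -> SectionLayout:
    """Construct a deterministic idealised layout for one needle section.

    The needle outline and vascular cylinder are concentric ellipses of
    the section's areas (fixed 2:1 aspect, the flattened shape of a
    spruce needle section); xylem and phloem ellipses sit side by side
    inside the vascular cylinder; lumina are placed largest-first by
    rejection sampling (dart throwing) inside the xylem.

    Raises
    ------
    InfeasibleLayoutError
        If the lumina occupy more than 60% of the xylem or placement
        fails after ``max_attempts`` darts for some lumen.
    """
    section.validate()
    total_lum = sum(t.a_lum for t in section.tracheids)
    if total_lum / section.a_x_um2 > MAX_LUMEN_PACKING:
        raise InfeasibleLayoutError(
            f"lumen packing {total_lum / section.a_x_um2:.2f} exceeds the "
            f"feasibility bound {MAX_LUMEN_PACKING}"
        )

    needle = _ellipse_for_area(section.a_n_mm2 * 1e6, aspect)
    vascular = _ellipse_for_area(section.a_v_mm2 * 1e6, aspect)
    gap = 0.02 * vascular.a
    xylem = _ellipse_for_area(section.a_x_um2, aspect)
    phloem = _ellipse_for_area(section.a_p_um2, aspect)
    xylem = Ellipse(-(xylem.a + gap / 2), 0.0, xylem.a, xylem.b)
    phloem = Ellipse(phloem.a + gap / 2, 0.0, phloem.a, phloem.b)
    for inner, outer, what in (
        (vascular, needle, "vascular cylinder in needle"),
        (xylem, vascular, "xylem in vascular cylinder"),
        (phloem, vascular, "phloem in vascular cylinder"),
    ):
        if not _inside_with_margin(inner, outer):
            raise InfeasibleLayoutError(f"cannot nest {what}")

    rng = np.random.default_rng(seed)
    order = sorted(range(len(section.tracheids)),
                   key=lambda i: -section.tracheids[i].a_lum)
    placed: list[Ellipse | None] = [None] * len(section.tracheids)
    for i in order:
        tr = section.tracheids[i]
        # preserve the measured axes; scale to the measured lumen area so the
        # layout's analytic areas reproduce the section exactly
        s = math.sqrt(tr.a_lum / (math.pi * tr.d_max * tr.d_min / 4.0))
        a, b = s * tr.d_max / 2.0, s * tr.d_min / 2.0
        done = False
        for _ in range(max_attempts):
            cx = rng.uniform(xylem.cx - xylem.a, xylem.cx + xylem.a)
            cy = rng.uniform(xylem.cy - xylem.b, xylem.cy + xylem.b)
            theta = rng.uniform(0.0, math.pi)
            cand = Ellipse(cx, cy, a, b, theta)
            if not _inside_with_margin(cand, xylem, margin=0.998):
                continue
            if any(_overlaps(cand, q) for q in placed if q is not None):
                continue
            placed[i] = cand
            done = True
            break
        if not done:
            raise InfeasibleLayoutError(
                f"failed to place lumen {i} (area {tr.a_lum:.1f} µm²) "
                f"after {max_attempts} attempts"
            )
    return SectionLayout(
        section=section, needle=needle, vascular=vascular,
        xylem=xylem, phloem=phloem,
        lumens=[e for e in placed if e is not None],
        seed=seed, aspect=aspect,
    )


@dataclass
class MeasuredSection:
    """Result of re-measuring a rasterised layout."""

    section: NeedleSection           # measured values, same identifiers
    pixels_per_um: float
    lumen_warnings: list[int] = field(default_factory=list)  # lumens < 4 px
    label_image: np.ndarray | None = None


def _mask_ellipse(e: Ellipse, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pixel-center membership mask on the coordinate grid (ys rows, xs cols)."""
    dx = xs[None, :] - e.cx
    dy = ys[:, None] - e.cy
    c, s = math.cos(e.theta), math.sin(e.theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0


def _lumen_diameters(pts: np.ndarray, px: float) -> tuple[float, float]:
    """Major/minor lumen diameters from pixel-center coordinates.

    Major = max pairwise distance + 1 px; minor = minimal rotating-caliper
    projection width + 1 px (both account for the pixel extent).
    """
    if len(pts) == 1:
        return px, px
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    d_major = math.sqrt(float(d2.max())) + px
    angles = np.linspace(0.0, math.pi, 90, endpoint=False)
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = pts @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0) + px
    return d_major, float(widths.min())


def rasterize_and_measure(
    layout: SectionLayout,
    pixels_per_um: float,
    keep_image: bool = False,
) -> MeasuredSection:
    """Rasterise a layout and re-measure all areas and lumen diameters.

    Label classes: 0 background, 1 needle, 2 vascular cylinder, 3 phloem,
    4 xylem, 100+i lumen ``i``.  Measured A_x includes the lumen pixels
    (lumina lie inside the xylem), matching the area convention of the
    measurement workflow.  Lumina covering fewer than 4 pixels are
    flagged in ``lumen_warnings``.
    """
    if not pixels_per_um > 0:
        raise ValueError("resolution must be positive")
    px = 1.0 / pixels_per_um
    pad = 2.0 * px
    x0, x1 = layout.needle.cx - layout.needle.a - pad, layout.needle.cx + layout.needle.a + pad
    y0, y1 = layout.needle.cy - layout.needle.b - pad, layout.needle.cy + layout.needle.b + pad
    nx = int(math.ceil((x1 - x0) / px))
    ny = int(math.ceil((y1 - y0) / px))
    xs = x0 + (np.arange(nx) + 0.5) * px
    ys = y0 + (np.arange(ny) + 0.5) * px

    labels = np.zeros((ny, nx), dtype=np.int32)
    labels[_mask_ellipse(layout.needle, xs, ys)] = 1

    def _window(e: Ellipse) -> tuple[slice, slice, np.ndarray, np.ndarray]:
        r = max(e.a, e.b) + 2 * px
        i0 = max(0, int((e.cy - r - y0) / px))
        i1 = min(ny, int((e.cy + r - y0) / px) + 2)
        j0 = max(0, int((e.cx - r - x0) / px))
        j1 = min(nx, int((e.cx + r - x0) / px) + 2)
        return slice(i0, i1), slice(j0, j1), xs[j0:j1], ys[i0:i1]

    for e, lab in ((layout.vascular, 2), (layout.phloem, 3), (layout.xylem, 4)):
        si, sj, wxs, wys = _window(e)
        labels[si, sj][_mask_ellipse(e, wxs, wys)] = lab

    area = {c: 0 for c in (1, 2, 3, 4)}
    tracheids: list[TracheidGeometry] = []
    warnings_idx: list[int] = []
    for i, e in enumerate(layout.lumens):
        si, sj, wxs, wys = _window(e)
        m = _mask_ellipse(e, wxs, wys)
        win = labels[si, sj]
        win[m] = 100 + i
        npix = int(m.sum())
        if npix < 4:
            warnings_idx.append(i)
        if npix == 0:
            # invisible at this resolution: record as a single-pixel lumen
            tracheids.append(TracheidGeometry(px, px, px * px))
            continue
        ii, jj = np.nonzero(m)
        pts = np.column_stack([wxs[jj], wys[ii]])
        d_major, d_minor = _lumen_diameters(pts, px)
        if d_minor > d_major:
            d_major, d_minor = d_minor, d_major
        tracheids.append(TracheidGeometry(d_major, d_minor, npix * px * px))

    counts = np.bincount(labels.ravel(), minlength=5)
    area[1] = int(counts[1])
    area[2] = int(counts[2])
    area[3] = int(counts[3])
    area[4] = int(counts[4])
    n_lumen_px = int((labels >= 100).sum())
    px2 = px * px
    a_x_um2 = (area[4] + n_lumen_px) * px2
    a_p_um2 = area[3] * px2
    a_v_um2 = (area[2] + area[3] + area[4] + n_lumen_px) * px2
    a_n_um2 = (area[1] + area[2] + area[3] + area[4] + n_lumen_px) * px2

    src = layout.section
    measured = NeedleSection(
        treatment=src.treatment, canopy=src.canopy, tree_id=src.tree_id,
        shoot_id=src.shoot_id, needle_id=src.needle_id, family=src.family,
        a_n_mm2=a_n_um2 / 1e6, a_v_mm2=a_v_um2 / 1e6,
        a_x_um2=a_x_um2, a_p_um2=a_p_um2,
        tracheids=tracheids,
    )
    return MeasuredSection(
        section=measured,
        pixels_per_um=pixels_per_um,
        lumen_warnings=warnings_idx,
        label_image=labels if keep_image else None,
    )
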