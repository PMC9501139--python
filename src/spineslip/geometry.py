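"""Spine geometry extraction from label masks.

A segmented lateral-lumbar mask is reduced to an ordered set of vertebral
quadrilaterals (L1..L5, four corners each) plus the two-point top plate of
the sacrum.  Regions are found as 8-connected components, and corners are
fitted with the extreme-point rule along the two diagonal directions of the
region contour: upper-left minimizes x+y, lower-right maximizes x+y,
upper-right maximizes x-y, lower-left minimizes x-y.

Coordinate convention (used package-wide): 0-based pixel indices, x grows
rightward (columns), y grows downward (rows); "upper" means smaller y.
Points are (x, y) float pairs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

logger = logging.getLogger(__name__)

LEVELS: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5")
JUNCTIONS: tuple[str, ...] = ("L1L2", "L2L3", "L3L4", "L4L5", "L5S1")

#: label values in the two mask dialects
SEVEN_LABEL_VERTEBRAE = (1, 2, 3, 4, 5)
SEVEN_LABEL_SACRUM = 6
THREE_CLASS_VERTEBRA = 1
THREE_CLASS_SACRUM = 2


class EmptyGeometryError(ValueError):
    """Mask contains no usable foreground component."""


class DegenerateRegionError(ValueError):
    """Region is too thin/collinear to carry a quadrilateral."""


@dataclass(frozen=True)
class VertebraQuad:
    """Four corner points of one lumbar vertebra.

    Corners run counterclockwise from the upper-left in anatomical
    convention: p1 upper-left, p2 upper-right, p3 lower-right, p4
    lower-left.
    """

    level: str
    p1: tuple[float, float]
    p2: tuple[float, float]
    p3: tuple[float, float]
    p4: tuple[float, float]

    @property
    def corners(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4], dtype=float)

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.corners.mean(axis=0)
        return (float(c[0]), float(c[1]))

    @property
    def upper_plate(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (self.p1, self.p2)


@dataclass(frozen=True)
class SacrumPlate:
    """Left and right end points of the sacral top plate."""

    p1: tuple[float, float]
    p2: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.p1[0] < self.p2[0]:
            raise ValueError("sacral plate points must be ordered left to right")


@dataclass
class SpineGeometry:
    """Ordered vertebral quadrilaterals plus the sacral top plate.

    ``quads`` maps level name to its quadrilateral; levels that could not
    be recovered from the mask are absent.  ``sacrum`` may be None when no
    sacral region was found.
    """

    quads: dict[str, VertebraQuad] = field(default_factory=dict)
    sacrum: SacrumPlate | None = None

    @property
    def missing_levels(self) -> tuple[str, ...]:
        return tuple(lv for lv in LEVELS if lv not in self.quads)

    def junction_plates(
        self, junction: str
    ) -> tuple[VertebraQuad, tuple[tuple[float, float], tuple[float, float]]] | None:
        """Upper vertebra and lower top plate for a junction, or None if
        either member is missing."""
        if junction not in JUNCTIONS:
            raise ValueError(f"unknown junction {junction!r}")
        idx = JUNCTIONS.index(junction)
        upper = self.quads.get(LEVELS[idx])
        if upper is None:
            return None
        if junction == "L5S1":
            if self.sacrum is None:
                return None
            return upper, (self.sacrum.p1, self.sacrum.p2)
        lower = self.quads.get(LEVELS[idx + 1])
        if lower is None:
            return None
        return upper, lower.upper_plate

    def to_dict(self) -> dict:
        out: dict = {"levels": {}}
        for lv, q in self.quads.items():
            out["levels"][lv] = [list(map(float, p)) for p in (q.p1, q.p2, q.p3, q.p4)]
        out["sacrum"] = (
            None
            if self.sacrum is None
            else [list(map(float, self.sacrum.p1)), list(map(float, self.sacrum.p2))]
        )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SpineGeometry":
        quads = {
            lv: VertebraQuad(lv, *[tuple(p) for p in pts])
            for lv, pts in d.get("levels", {}).items()
        }
        sac = d.get("sacrum")
        sacrum = None if sac is None else SacrumPlate(tuple(sac[0]), tuple(sac[1]))
        return cls(quads=quads, sacrum=sacrum)

    @classmethod
    def from_json(cls, path) -> "SpineGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Component:
    """One 8-connected foreground region of a label mask."""

    label: int
    area: int
    centroid: tuple[float, float]  # (x, y)
    coords: np.ndarray  # (n, 2) array of (row, col)


def infer_dialect(mask: np.ndarray) -> str:
    """Guess the mask dialect: '7label' (1..5 vertebrae, 6 sacrum) or
    '3class' (1 vertebra, 2 sacrum)."""
    labels = np.unique(mask)
    return "7label" if labels.max(initial=0) > 2 else "3class"


def extract_components(
    mask: np.ndarray,
    dialect: str = "auto",
    min_area_frac: float = 0.0005,
) -> list[Component]:
    """8-connected foreground components of a label mask.

    Components smaller than ``min_area_frac`` of the image are treated as
    speckle and discarded.  Raises :class:`EmptyGeometryError` when nothing
    survives.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if dialect == "auto":
        dialect = infer_dialect(mask)
    min_area = max(1, int(round(min_area_frac * mask.size)))
    comps: list[Component] = []
    for value in np.unique(mask):
        if value == 0:
            continue
        lab = measure.label(mask == value, connectivity=2)
        for region in measure.regionprops(lab):
            if region.area < min_area:
                continue
            cy, cx = region.centroid
            comps.append(
                Component(
                    label=int(value),
                    area=int(region.area),
                    centroid=(float(cx), float(cy)),
                    coords=region.coords,
                )
            )
    if not comps:
        raise EmptyGeometryError("no foreground components above the area floor")
    return comps


def fit_quadrilateral(region: Component | np.ndarray) -> np.ndarray:
    """Fit four corners to a region by the diagonal extreme-point rule.

    Returns a (4, 2) array of (x, y) corners ordered p1 upper-left,
    p2 upper-right, p3 lower-right, p4 lower-left.
    """
    coords = region.coords if isinstance(region, Component) else np.asarray(region)
    if len(coords) < 4:
        raise DegenerateRegionError("region has fewer than 4 pixels")
    y = coords[:, 0].astype(float)
    x = coords[:, 1].astype(float)
    ul = np.argmin(x + y)
    lr = np.argmax(x + y)
    ur = np.argmax(x - y)
    ll = np.argmin(x - y)
    pts = np.array(
        [[x[i], y[i]] for i in (ul, ur, lr, ll)], dtype=float
    )
    if len({tuple(p) for p in pts}) < 4:
        raise DegenerateRegionError("extreme points collapse; region too thin")
    # shoelace area of the fitted quad; a sliver means a collinear region
    xs, ys = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(
        np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))
    )
    if area < 0.5:
        raise DegenerateRegionError("fitted corners are collinear")
    return pts


def build_spine_geometry(
    components: Sequence[Component],
    dialect: str = "auto",
    max_regions: int = 6,
) -> SpineGeometry:
    """Assemble SpineGeometry from labeled components.

    Components are ordered by centroid y (top-down).  The sacrum is the
    lowest component of the sacrum class when class identity is available,
    otherwise the lowest component overall; the up-to-five vertebrae above
    it map to L1..L5 top-down.  With fewer regions than expected the
    geometry is returned partial and a warning is issued; downstream
    detectors evaluate only junctions whose both members exist.
    """
    comps = list(components)
    if len(comps) < 2:
        raise EmptyGeometryError("need at least two components for a geometry")
    if dialect == "auto":
        dialect = "7label" if any(c.label > 2 for c in comps) else "3class"
    if len(comps) > max_regions:
        comps = sorted(comps, key=lambda c: c.area, reverse=True)[:max_regions]
        logger.info("kept the %d largest of %d components", max_regions, len(components))
    comps = sorted(comps, key=lambda c: c.centroid[1])

    sacrum_label = SEVEN_LABEL_SACRUM if dialect == "7label" else THREE_CLASS_SACRUM
    sacral = [c for c in comps if c.label == sacrum_label]
    if sacral:
        sacrum_comp = sacral[-1]  # lowest of the sacrum class
        if len(sacral) > 1:
            logger.warning("multiple sacrum-class components; using the lowest")
    else:
        sacrum_comp = comps[-1]  # classes collapsed: lowest region overall
        logger.warning("no sacrum-class component; assuming the lowest region is sacral")
    vertebra_comps = [c for c in comps if c is not sacrum_comp]
    vertebra_comps = [c for c in vertebra_comps if c.centroid[1] < sacrum_comp.centroid[1]]

    geometry = SpineGeometry()
    for level, comp in zip(LEVELS, vertebra_comps[:5]):
        try:
            pts = fit_quadrilateral(comp)
        except DegenerateRegionError:
            warnings.warn(f"degenerate region for {level}; level marked missing")
            continue
        geometry.quads[level] = VertebraQuad(
            level, tuple(pts[0]), tuple(pts[1]), tuple(pts[2]), tuple(pts[3])
        )
    try:
        spts = fit_quadrilateral(sacrum_comp)
        geometry.sacrum = SacrumPlate(tuple(spts[0]), tuple(spts[1]))
    except DegenerateRegionError:
        warnings.warn("degenerate sacral region; plate marked missing")
    if geometry.missing_levels:
        warnings.warn(
            "partial geometry: missing levels " + ", ".join(geometry.missing_levels)
        )
    return geometry


def geometry_from_mask(
    mask: np.ndarray, dialect: str = "auto", min_area_frac: float = 0.0005
) -> SpineGeometry:
    """Convenience: extract_components then build_spine_geometry."""
    return build_spine_geometry(
        extract_components(mask, dialect=dialect, min_area_frac=min_area_frac),
        dialect=dialect,
    )
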