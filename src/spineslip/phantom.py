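"""Synthetic lateral-spine phantoms with exact ground truth.

The generator draws six stacked bone regions — five lumbar vertebral bodies
and a trapezoidal sacrum — as filled quadrilaterals with a brighter
cortical rim on a noisy background, and emits the matching label mask,
analytic corner geometry, and per-junction slip truth.  Realism is not the
goal; geometric fidelity is: every downstream stage (corner fitting, slip
measurement, threshold calibration, segmentation training) can be tested
against truth that is exact by construction.

Slippage is modeled as a purely horizontal translation of the stack above
the chosen junction by ``slip_fraction x plate_width`` pixels, mirroring
the clinical displacement ratio: the slip distance A of the superior
vertebra over its width B gives a P-grade of 100*A/B percent.

Vertebra plates are corner-inclusive: a plate from x0 to x0+w covers w+1
pixel columns, so the fitted plate length equals w exactly and measured
slips agree with the construction whenever slip*width is an integer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import draw

from .geometry import JUNCTIONS, LEVELS, SacrumPlate, SpineGeometry, VertebraQuad

# grayscale rendering levels (8-bit)
_BG_LEVEL = 60.0
_BODY_LEVEL = 160.0
_SACRUM_LEVEL = 140.0
_RIM_LEVEL = 215.0

#: cohort slip ranges: positives are drawn at or above the floor, negatives
#: at or below the ceiling, so a separating detection threshold exists.
POSITIVE_SLIP_FLOOR = 0.15
NEGATIVE_SLIP_CEILING = 0.05

#: P-grade percentage above which a junction's truth label is positive
#: (matches the default clinical threshold K1 = 10).
TRUTH_PGRADE_THRESHOLD = 10.0


class InvalidSpecError(ValueError):
    """Phantom geometry does not fit the requested canvas."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic spine image.

    ``slip_fraction`` is the horizontal displacement of the stack above
    ``slip_junction``, expressed as a fraction of ``plate_width`` (so a
    value of 0.3 constructs a 30% P-grade at that junction).
    """

    image_height: int = 320
    image_width: int = 256
    vertebra_height: int = 36
    plate_width: int = 100
    gap_height: int = 12
    global_tilt: float = 0.0
    slip_junction: str | None = None
    slip_fraction: float = 0.0
    noise_sd: float = 6.0
    seed: int = 0

    #: vertebral bodies per phantom is anatomy, not a parameter
    n_vertebrae: int = field(default=6, init=False)

    @property
    def stack_height(self) -> int:
        # 6 bodies of (vertebra_height+1) rows + 5 inter-body gaps
        return 6 * (self.vertebra_height + 1) + 5 * self.gap_height

    @property
    def top_margin(self) -> int:
        return (self.image_height - self.stack_height) // 2

    @property
    def left_margin(self) -> int:
        return int(round(0.15 * self.image_width))

    def validate(self) -> None:
        if self.vertebra_height < 3 or self.plate_width < 4 or self.gap_height < 1:
            raise InvalidSpecError("vertebra dimensions too small to rasterize")
        if not 0.0 <= self.slip_fraction <= 1.5:
            raise InvalidSpecError("slip_fraction must lie in [0, 1.5]")
        if self.slip_junction is not None and self.slip_junction not in JUNCTIONS:
            raise InvalidSpecError(f"unknown junction {self.slip_junction!r}")
        if self.top_margin < 1:
            raise InvalidSpecError(
                f"stack of {self.stack_height}px does not fit image height "
                f"{self.image_height}"
            )
        slip_px = self.slip_fraction * self.plate_width
        if self.left_margin + self.plate_width + slip_px + 1 > self.image_width:
            raise InvalidSpecError("plate width plus slip displacement exceeds canvas")

    @classmethod
    def small(cls, **overrides) -> "PhantomSpec":
        """A 64x64 preset used for fast segmentation-training experiments."""
        base = dict(
            image_height=64,
            image_width=64,
            vertebra_height=6,
            plate_width=30,
            gap_height=2,
            noise_sd=4.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class PhantomCase:
    """One rendered phantom with its exact ground truth."""

    image: np.ndarray  # uint8 (H, W)
    mask: np.ndarray  # uint8 (H, W), 0=background, 1..5=L1..L5, 6=sacrum
    truth_geometry: SpineGeometry
    truth_labels: dict[str, bool]
    truth_pgrade: dict[str, float]
    spec: PhantomSpec
    case_id: str = "case"

    @property
    def slip_junction(self) -> str | None:
        return self.spec.slip_junction


def _truth_corners(spec: PhantomSpec) -> tuple[list[np.ndarray], np.ndarray]:
    """Analytic corner coordinates (x, y) of the 5 bodies + sacrum quad."""
    x0 = float(spec.left_margin)
    x1 = x0 + spec.plate_width
    vh = spec.vertebra_height
    pitch = vh + 1 + spec.gap_height
    dx = spec.slip_fraction * spec.plate_width
    slip_idx = (
        JUNCTIONS.index(spec.slip_junction) if spec.slip_junction is not None else None
    )

    quads: list[np.ndarray] = []
    for k in range(5):
        y0 = float(spec.top_margin + k * pitch)
        y1 = y0 + vh
        shift = dx if (slip_idx is not None and k <= slip_idx) else 0.0
        quads.append(
            np.array(
                [
                    [x0 + shift, y0],
                    [x1 + shift, y0],
                    [x1 + shift, y1],
                    [x0 + shift, y1],
                ]
            )
        )
    ys = float(spec.top_margin + 5 * pitch)
    # sacrum: full-width top plate narrowing toward the bottom
    inset = 0.22 * spec.plate_width
    sacrum = np.array(
        [
            [x0, ys],
            [x1, ys],
            [x1 - inset, ys + vh],
            [x0 + inset, ys + vh],
        ]
    )
    if spec.global_tilt != 0.0:
        theta = np.deg2rad(spec.global_tilt)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        center = np.array([spec.image_width / 2.0, spec.image_height / 2.0])
        quads = [(q - center) @ rot.T + center for q in quads]
        sacrum = (sacrum - center) @ rot.T + center
    return quads, sacrum


def _rasterize(poly: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Filled-polygon pixels including the (rounded) outline, (rows, cols)."""
    rr, cc = draw.polygon(poly[:, 1], poly[:, 0], shape=shape)
    pr, pc = draw.polygon_perimeter(
        np.round(poly[:, 1]).astype(int),
        np.round(poly[:, 0]).astype(int),
        shape=shape,
        clip=True,
    )
    return np.concatenate([rr, pr]), np.concatenate([cc, pc])


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom; identical spec (including seed) is bit-identical."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    image = np.full((h, w), _BG_LEVEL, dtype=float)
    mask = np.zeros((h, w), dtype=np.uint8)

    quads, sacrum = _truth_corners(spec)
    geometry = SpineGeometry()
    for k, (level, poly) in enumerate(zip(LEVELS, quads)):
        rr, cc = _rasterize(poly, (h, w))
        image[rr, cc] = _BODY_LEVEL
        mask[rr, cc] = k + 1
        pr, pc = draw.polygon_perimeter(
            np.round(poly[:, 1]).astype(int),
            np.round(poly[:, 0]).astype(int),
            shape=(h, w),
            clip=True,
        )
        image[pr, pc] = _RIM_LEVEL
        geometry.quads[level] = VertebraQuad(
            level, tuple(poly[0]), tuple(poly[1]), tuple(poly[2]), tuple(poly[3])
        )
    rr, cc = _rasterize(sacrum, (h, w))
    image[rr, cc] = _SACRUM_LEVEL
    mask[rr, cc] = 6
    pr, pc = draw.polygon_perimeter(
        np.round(sacrum[:, 1]).astype(int),
        np.round(sacrum[:, 0]).astype(int),
        shape=(h, w),
        clip=True,
    )
    image[pr, pc] = _RIM_LEVEL
    geometry.sacrum = SacrumPlate(tuple(sacrum[0]), tuple(sacrum[1]))

    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    truth_pgrade = {j: 0.0 for j in JUNCTIONS}
    if spec.slip_junction is not None:
        truth_pgrade[spec.slip_junction] = 100.0 * spec.slip_fraction
    truth_labels = {j: truth_pgrade[j] > TRUTH_PGRADE_THRESHOLD for j in JUNCTIONS}
    return PhantomCase(
        image=image,
        mask=mask,
        truth_geometry=geometry,
        truth_labels=truth_labels,
        truth_pgrade=truth_pgrade,
        spec=spec,
    )


def generate_flexion_extension_pair(
    spec: PhantomSpec, flexion_slip: float, extension_slip: float
) -> tuple[PhantomCase, PhantomCase]:
    """Paired views sharing anatomy but differing in slip.

    The ground-truth dynamic shift at the slip junction is
    ``|flexion_slip - extension_slip|`` (as a fraction of plate width).
    Requires a ``slip_junction`` on the spec; both slips must fit the
    canvas.
    """
    if spec.slip_junction is None:
        raise InvalidSpecError("flexion/extension pair needs a slip_junction")
    flex = generate_phantom(replace(spec, slip_fraction=flexion_slip))
    ext = generate_phantom(
        replace(spec, slip_fraction=extension_slip, seed=spec.seed + 1)
    )
    flex.case_id, ext.case_id = "flexion", "extension"
    return flex, ext


def generate_cohort(
    n_cases: int,
    positive_rate: float,
    seed: int,
    base_spec: PhantomSpec | None = None,
    positive_floor: float = POSITIVE_SLIP_FLOOR,
    negative_ceiling: float = NEGATIVE_SLIP_CEILING,
    positive_cap: float = 0.5,
) -> list[PhantomCase]:
    """A labeled cohort with randomized slip fractions.

    Positives draw their slip uniformly from [positive_floor, positive_cap]
    at a uniformly chosen junction; negatives draw from
    [0, negative_ceiling] so that a separating threshold exists for
    calibration.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0.0 <= positive_rate <= 1.0:
        raise ValueError("positive_rate must lie in [0, 1]")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for i in range(n_cases):
        positive = rng.random() < positive_rate
        junction = str(rng.choice(JUNCTIONS))
        slip = (
            float(rng.uniform(positive_floor, positive_cap))
            if positive
            else float(rng.uniform(0.0, negative_ceiling))
        )
        spec = replace(
            base,
            slip_junction=junction,
            slip_fraction=slip,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case = generate_phantom(spec)
        case.case_id = f"case{i:04d}"
        cases.append(case)
    return cases


# ---------------------------------------------------------------------------
# disk I/O: 8-bit grayscale PNG image, indexed PNG mask, JSON truth sidecar

_MASK_PALETTE = [
    (0, 0, 0),
    (230, 90, 90),
    (230, 170, 80),
    (170, 220, 90),
    (90, 200, 200),
    (110, 120, 230),
    (200, 110, 210),
]


def save_case(case: PhantomCase, outdir, stem: str | None = None) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or case.case_id
    paths = {
        "image": outdir / f"{stem}.png",
        "mask": outdir / f"{stem}_mask.png",
        "truth": outdir / f"{stem}_truth.json",
    }
    Image.fromarray(case.image, mode="L").save(paths["image"])
    pal_img = Image.fromarray(case.mask, mode="P")
    palette = [v for rgb in _MASK_PALETTE for v in rgb]
    pal_img.putpalette(palette + [0] * (768 - len(palette)))
    pal_img.save(paths["mask"])
    truth = {
        "geometry": case.truth_geometry.to_dict(),
        "labels": case.truth_labels,
        "pgrade": case.truth_pgrade,
        "slip_junction": case.spec.slip_junction,
        "slip_fraction": case.spec.slip_fraction,
        "seed": case.spec.seed,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths


def load_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.uint8)


def write_cohort_manifest(cases: list[PhantomCase], path) -> pd.DataFrame:
    """CSV manifest: one row per case with the per-junction truth labels."""
    rows = []
    for case in cases:
        row = {
            "case_id": case.case_id,
            "view": "lateral",
            "slip_junction": case.spec.slip_junction or "",
            "slip_fraction": case.spec.slip_fraction,
        }
        for j in JUNCTIONS:
            row[f"label_{j}"] = int(case.truth_labels[j])
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
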