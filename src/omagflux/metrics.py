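"""Peripapillary annulus perfusion metrics.

Inside an annulus centered at the optic nerve head (inner diameter 2.5 mm,
outer diameter 3.7 mm — a 0.6-mm-wide ring matching where commercial
devices measure RNFL thickness), two unitless metrics are computed over the
detected RNFL vessel pixels, excluding the large retinal vessels:

* blood flux index — mean flow signal over vessel pixels, normalized to
  [0, 1] by the full dynamic range ``F_max`` of the flow signal;
* vessel area density — fraction of annulus pixels occupied by vessels.

Both are reported globally and for the temporal (315-45 deg), superior
(45-135), nasal (135-225) and inferior (225-315) quadrants, with 0 deg at
the temporal horizontal meridian and angles increasing counterclockwise in
the right-eye layout; left eyes are mirrored first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .enface import EnFaceImage
from .vessels import VesselMask

QUADRANTS = ("temporal", "superior", "nasal", "inferior")


@dataclass
class AnnulusSpec:
    center_px: tuple[float, float]  # (x, y)
    mm_per_pixel: tuple[float, float]  # (x, y)
    inner_diameter_mm: float = 2.5
    outer_diameter_mm: float = 3.7

    def __post_init__(self) -> None:
        if not 0 < self.inner_diameter_mm < self.outer_diameter_mm:
            raise ValueError("require 0 < inner diameter < outer diameter")
        if min(self.mm_per_pixel) <= 0:
            raise ValueError("mm_per_pixel must be positive")


@dataclass
class PerfusionReport:
    blood_flux_index: dict  # global + per-quadrant, values in [0, 1]
    vessel_area_density: dict
    area_annulus_px: dict  # annulus pixel counts (big vessels excluded)
    vessel_px: dict
    excluded_big_vessel_px: int
    empty_regions: list
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.blood_flux_index, self.vessel_area_density):
            for region, v in d.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"metric for {region!r} outside [0, 1]: {v}")
        quad_sum = sum(self.vessel_px[q] for q in QUADRANTS)
        if quad_sum != self.vessel_px["global"]:
            raise ValueError("quadrant vessel pixel counts must sum to the global count")

    def to_dict(self) -> dict:
        return asdict(self)


def make_annulus_mask(
    spec: AnnulusSpec, shape: tuple[int, int], require_inside: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean annulus mask and per-pixel angle map (degrees).

    A pixel belongs to the annulus iff its physical distance from the center
    lies in [inner radius, outer radius].  The angle is 0 at the temporal
    horizontal meridian (negative x from the disc center in the right-eye
    layout, where x increases temporal-to-nasal) and increases
    counterclockwise through superior (90), nasal (180), inferior (270).
    """
    ny, nx = shape
    cx, cy = spec.center_px
    sx, sy = spec.mm_per_pixel
    r_out = spec.outer_diameter_mm / 2.0
    if require_inside:
        if cx * sx < r_out or (nx - 1 - cx) * sx < r_out or cy * sy < r_out or (
            ny - 1 - cy
        ) * sy < r_out:
            raise ValueError(
                "annulus exceeds the image bounds; a montage-scale image is required"
            )
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny))
    dx_mm = (xx - cx) * sx
    dy_mm = (yy - cy) * sy
    r_mm = np.hypot(dx_mm, dy_mm)
    mask = (r_mm >= spec.inner_diameter_mm / 2.0) & (r_mm <= r_out)
    # row index is the inferior->superior axis, so +dy is superior and, with
    # x running temporal->nasal, -dx is temporal (the 0-degree meridian)
    angles = np.degrees(np.arctan2(dy_mm, -dx_mm)) % 360.0
    return mask, angles


def assign_quadrants(angles: np.ndarray) -> np.ndarray:
    """Quadrant label per pixel from the angle map (degrees in [0, 360)).

    temporal [315, 45), superior [45, 135), nasal [135, 225),
    inferior [225, 315) — continuous half-open versions of the instrument's
    integer-degree spans.
    """
    a = np.asarray(angles, dtype=float) % 360.0
    labels = np.empty(a.shape, dtype=object)
    labels[(a >= 315) | (a < 45)] = "temporal"
    labels[(a >= 45) & (a < 135)] = "superior"
    labels[(a >= 135) & (a < 225)] = "nasal"
    labels[(a >= 225) & (a < 315)] = "inferior"
    return labels


def compute_metrics(
    flow_enface: EnFaceImage,
    rnfl_vessels: VesselMask,
    big_vessels: VesselMask,
    annulus: np.ndarray,
    quadrant_labels: np.ndarray,
    f_max: float,
    exclude_big_from_area: bool = True,
) -> PerfusionReport:
    """Blood flux index and vessel area density, global and per quadrant.

    The measured vessel set is ``V = rnfl_vessels & annulus & ~big_vessels``.
    Flux index is the mean of ``flow / f_max`` over V (0 with an empty-region
    flag if V is empty).  Density is ``|V| / Area_Annulus`` where by default
    the annulus area also excludes big-vessel pixels.
    """
    shapes = {
        flow_enface.shape,
        rnfl_vessels.mask.shape,
        big_vessels.mask.shape,
        annulus.shape,
        quadrant_labels.shape,
    }
    if len(shapes) != 1:
        raise ValueError("all images and masks must be co-registered with equal shapes")
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    if flow_enface.laterality != "OD":
        raise ValueError("mirror left eyes to the right-eye layout before quadrant metrics")

    annulus = annulus & flow_enface.valid
    big = big_vessels.mask & annulus
    area_mask = annulus & ~big if exclude_big_from_area else annulus
    v = rnfl_vessels.mask & annulus & ~big

    norm_flow = np.clip(flow_enface.pixels / f_max, 0.0, 1.0)

    flux: dict[str, float] = {}
    density: dict[str, float] = {}
    area_px: dict[str, int] = {}
    vessel_px: dict[str, int] = {}
    empty: list[str] = []

    regions: dict[str, np.ndarray] = {"global": np.ones(annulus.shape, dtype=bool)}
    for q in QUADRANTS:
        regions[q] = quadrant_labels == q

    for name, region in regions.items():
        v_r = v & region
        area_r = int((area_mask & region).sum())
        n_v = int(v_r.sum())
        area_px[name] = area_r
        vessel_px[name] = n_v
        if n_v == 0:
            empty.append(name)
            flux[name] = 0.0
        else:
            flux[name] = float(norm_flow[v_r].mean())
        density[name] = float(n_v / area_r) if area_r > 0 else 0.0

    return PerfusionReport(
        blood_flux_index=flux,
        vessel_area_density=density,
        area_annulus_px=area_px,
        vessel_px=vessel_px,
        excluded_big_vessel_px=int(big.sum()),
        empty_regions=empty,
        params={
            "f_max": f_max,
            "inner_big_vessel_exclusion": True,
            "exclude_big_from_area": exclude_big_from_area,
        },
    )
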