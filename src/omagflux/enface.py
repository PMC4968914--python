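"""En face projections, montage stitching and disc geometry.

The RNFL angiogram is a maximum projection of the (optionally
Gaussian-smoothed) flow volume between the ILM and the posterior RNFL
boundary.  The sub-RPE structural image ``S_RPE(x, y)`` — the mean
structural signal in the 10 axial samples immediately anterior to the RPE —
reveals the shadows of the large retinal vessels and is the input to
big-vessel detection.  A 3x3 grid of tiles with fractional linear overlap is
stitched by linear feathering into the wide-field image on which the
peripapillary annulus is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.measure import label, regionprops

from .flow import FlowVolume
from .layers import LayerBoundaries

RPE_SLAB_SAMPLES = 10


@dataclass
class EnFaceImage:
    """2-D projection image with physical scale and disc geometry.

    ``pixels`` is indexed (y, x) = (B-scan, A-scan).  After orientation
    normalization x increases temporal-to-nasal for a right eye and y
    increases inferior-to-superior; left eyes are mirrored into this layout
    before any quadrant computation.
    """

    pixels: np.ndarray
    mm_per_pixel: tuple[float, float]  # (x, y)
    laterality: str = "OD"
    kind: str = "generic"
    disc_center: tuple[float, float] | None = None  # (x, y) pixels
    disc_margin: np.ndarray | None = None  # (n, 2) polygon, (x, y) pixels
    disc_center_auto: bool = False
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("en face image must be 2-D")
        if min(self.mm_per_pixel) <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.valid is None:
            self.valid = np.ones(self.pixels.shape, dtype=bool)
        if self.disc_center is not None:
            cx, cy = self.disc_center
            ny, nx = self.pixels.shape
            if not (0 <= cx < nx and 0 <= cy < ny):
                raise ValueError("disc center outside the image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def mirrored_to_od(self) -> "EnFaceImage":
        """Flip a left eye horizontally into the right-eye layout."""
        if self.laterality == "OD":
            return self
        nx = self.pixels.shape[1]
        flip = lambda p: (nx - 1 - p[0], p[1])  # noqa: E731
        return replace(
            self,
            pixels=self.pixels[:, ::-1].copy(),
            valid=self.valid[:, ::-1].copy(),
            laterality="OD",
            disc_center=None if self.disc_center is None else flip(self.disc_center),
            disc_margin=None
            if self.disc_margin is None
            else np.column_stack([nx - 1 - self.disc_margin[:, 0], self.disc_margin[:, 1]]),
        )


def _disc_mask_from_margin(shape: tuple[int, int], margin: np.ndarray | None) -> np.ndarray:
    if margin is None:
        return np.zeros(shape, dtype=bool)
    # polygon2mask expects (row, col) = (y, x)
    return polygon2mask(shape, np.column_stack([margin[:, 1], margin[:, 0]]))


def project_rnfl_flow(
    flow: FlowVolume,
    lb: LayerBoundaries,
    gaussian_sigma: float = 1.0,
    axial_sigma: float = 1.0,
    disc_margin: np.ndarray | None = None,
) -> EnFaceImage:
    """Maximum projection of the flow signal within the RNFL slab.

    Per A-scan the output is the maximum of the (Gaussian-smoothed) flow over
    axial samples z with ``ilm <= z <= rnfl_post``.  Pixels inside the disc
    margin are zeroed and marked invalid; so are A-scans with an empty slab.
    """
    if gaussian_sigma < 0 or axial_sigma < 0:
        raise ValueError("smoothing sigma must be >= 0")
    vol = flow.flow
    if gaussian_sigma > 0 or axial_sigma > 0:
        vol = ndimage.gaussian_filter(
            vol, sigma=(gaussian_sigma, gaussian_sigma, axial_sigma), mode="nearest"
        )
    ny, nx, nz = vol.shape
    z = np.arange(nz)[None, None, :]
    band = (z >= lb.ilm[..., None]) & (z <= lb.rnfl_post[..., None])
    pixels = np.where(band, vol, -np.inf).max(axis=-1)
    valid = band.any(axis=-1)
    pixels = np.where(valid, pixels, 0.0)
    disc = _disc_mask_from_margin((ny, nx), disc_margin)
    pixels[disc] = 0.0
    valid &= ~disc
    return EnFaceImage(
        pixels=pixels,
        mm_per_pixel=(flow.dx_mm, flow.dy_mm),
        laterality=flow.laterality,
        kind="flow-RNFL",
        disc_margin=disc_margin,
        valid=valid,
    )


def project_rpe_structure(
    structure: np.ndarray,
    lb: LayerBoundaries,
    mm_per_pixel: tuple[float, float],
    laterality: str = "OD",
    slab_samples: int = RPE_SLAB_SAMPLES,
) -> EnFaceImage:
    """Sub-RPE structural en face: mean signal in the ``slab_samples`` axial
    samples immediately anterior to the RPE boundary.

    A-scans whose RPE sits shallower than the slab are flagged invalid and
    excluded from later thresholding statistics.
    """
    vol = np.asarray(structure, dtype=float)
    ny, nx, nz = vol.shape
    rz = np.rint(lb.rpe).astype(int)
    valid = rz >= slab_samples
    z = np.arange(nz)[None, None, :]
    window = (z >= (rz[..., None] - slab_samples)) & (z < rz[..., None])
    counts = window.sum(axis=-1)
    sums = np.where(window, vol, 0.0).sum(axis=-1)
    pixels = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    pixels = np.where(valid, pixels, 0.0)
    return EnFaceImage(
        pixels=pixels,
        mm_per_pixel=mm_per_pixel,
        laterality=laterality,
        kind="structure-RPE",
        valid=valid,
    )


def stitch_montage(
    tiles: list[list[EnFaceImage]], overlap_fraction: float = 0.10
) -> EnFaceImage:
    """Stitch an n x n grid of equally scaled tiles with linear feathering.

    Adjacent tiles share a strip of ``overlap_fraction`` of the tile width;
    within it the two contributions are blended with complementary linear
    ramps (a partition of unity, so constant tiles stitch losslessly).  With
    3 tiles of width w the stitched physical extent is ``3w - 2*overlap*w``.
    """
    if not 0 <= overlap_fraction < 0.5:
        raise ValueError("overlap_fraction must lie in [0, 0.5)")
    n_rows = len(tiles)
    n_cols = len(tiles[0])
    t0 = tiles[0][0]
    h, w = t0.shape
    for row in tiles:
        for t in row:
            if t.shape != (h, w) or not np.allclose(t.mm_per_pixel, t0.mm_per_pixel):
                raise ValueError("inconsistent tile shapes or scales")
    oy = int(round(overlap_fraction * h))
    ox = int(round(overlap_fraction * w))

    def ramps(n_tiles: int, size: int, o: int) -> list[np.ndarray]:
        out = []
        up = np.arange(1, o + 1) / (o + 1)
        for k in range(n_tiles):
            prof = np.ones(size)
            if k > 0 and o > 0:
                prof[:o] = up
            if k < n_tiles - 1 and o > 0:
                prof[size - o :] = up[::-1]
            out.append(prof)
        return out

    wy = ramps(n_rows, h, oy)
    wx = ramps(n_cols, w, ox)
    ny = n_rows * h - (n_rows - 1) * oy
    nx = n_cols * w - (n_cols - 1) * ox
    acc = np.zeros((ny, nx))
    wacc = np.zeros((ny, nx))
    for r in range(n_rows):
        for c in range(n_cols):
            y0 = r * (h - oy)
            x0 = c * (w - ox)
            wgt = np.outer(wy[r], wx[c])
            acc[y0 : y0 + h, x0 : x0 + w] += wgt * tiles[r][c].pixels
            wacc[y0 : y0 + h, x0 : x0 + w] += wgt
    pixels = acc / np.where(wacc > 0, wacc, 1.0)
    return EnFaceImage(
        pixels=pixels,
        mm_per_pixel=t0.mm_per_pixel,
        laterality=t0.laterality,
        kind=t0.kind,
    )


def montage_extent_mm(
    tile_extent_mm: float, n_tiles: int = 3, overlap_fraction: float = 0.10
) -> float:
    """Physical extent of an n-tile montage with fractional linear overlap."""
    return n_tiles * tile_extent_mm - (n_tiles - 1) * overlap_fraction * tile_extent_mm


def polygon_centroid(polygon: np.ndarray) -> tuple[float, float]:
    """Area centroid of a simple closed polygon (shoelace formula)."""
    p = np.asarray(polygon, dtype=float)
    if not np.allclose(p[0], p[-1]):
        p = np.vstack([p, p[0]])
    x, y = p[:-1, 0], p[:-1, 1]
    xn, yn = p[1:, 0], p[1:, 1]
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if area == 0:
        return float(x.mean()), float(y.mean())
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return float(cx), float(cy)


def locate_disc(
    structure_enface: EnFaceImage,
    margin: np.ndarray | None = None,
    auto_fallback: bool = True,
) -> EnFaceImage:
    """Attach disc geometry to an en face image.

    With a margin polygon (drawn at the end of Bruch's membrane on the
    structural en face) the disc center is its area centroid.  Without one,
    and if ``auto_fallback`` is enabled, the center of the largest connected
    low-intensity region near the image center is used and flagged automatic.
    """
    img = structure_enface
    ny, nx = img.shape
    if margin is not None:
        margin = np.asarray(margin, dtype=float)
        if (
            margin[:, 0].min() < 0
            or margin[:, 0].max() >= nx
            or margin[:, 1].min() < 0
            or margin[:, 1].max() >= ny
        ):
            raise ValueError("disc margin polygon extends outside the image")
        center = polygon_centroid(margin)
        return replace(img, disc_center=center, disc_margin=margin, disc_center_auto=False)
    if not auto_fallback:
        raise ValueError("no disc margin polygon given and automatic fallback disabled")
    vals = img.pixels[img.valid]
    thr = 0.5 * float(np.median(vals))
    low = (img.pixels < thr) & img.valid
    lab = label(low)
    best = None
    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0
    for region in regionprops(lab):
        ry, rx = region.centroid
        # only regions whose centroid lies in the central third of the image
        if abs(ry - cy0) > ny / 6 or abs(rx - cx0) > nx / 6:
            continue
        if best is None or region.area > best.area:
            best = region
    if best is None:
        raise ValueError("no central low-intensity region found for automatic disc location")
    ry, rx = best.centroid
    # approximate margin: circle with the region's equivalent radius
    radius = np.sqrt(best.area / np.pi)
    ang = np.linspace(0, 2 * np.pi, 33)
    poly = np.column_stack([rx + radius * np.cos(ang), ry + radius * np.sin(ang)])
    poly[:, 0] = np.clip(poly[:, 0], 0, nx - 1)
    poly[:, 1] = np.clip(poly[:, 1], 0, ny - 1)
    return replace(
        img, disc_center=(float(rx), float(ry)), disc_margin=poly, disc_center_auto=True
    )
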