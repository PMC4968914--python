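"""Retinal layer segmentation by axial gradient detection.

Three boundaries are extracted from the structural volume: the inner limiting
membrane (ILM, vitreous-to-retina step), the posterior RNFL boundary
(reflectivity drop below the nerve fiber layer) and the RPE (brightest band).
Per A-scan the structural profile is smoothed with a Gaussian and its axial
derivative located; peaks are refined to sub-sample precision by parabolic
interpolation, so a noiseless step whose first tissue sample is ``k`` is
reported at the physical interface position ``k - 0.5``.

The procedure is semiautomatic: sparse manual edit points can be imposed and
interpolated smoothly between (``apply_manual_overrides``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class LayerBoundaries:
    """Per-A-scan axial positions (fractional samples) of ILM, posterior RNFL, RPE."""

    ilm: np.ndarray
    rnfl_post: np.ndarray
    rpe: np.ndarray
    quality: np.ndarray | None = None  # True where the gradient search succeeded
    n_depth: int | None = None

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=float)
        self.rnfl_post = np.asarray(self.rnfl_post, dtype=float)
        self.rpe = np.asarray(self.rpe, dtype=float)
        if not (self.ilm.shape == self.rnfl_post.shape == self.rpe.shape):
            raise ValueError("boundary surfaces must share a shape")
        if self.quality is None:
            self.quality = np.ones(self.ilm.shape, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if np.any(self.ilm > self.rnfl_post) or np.any(self.rnfl_post > self.rpe):
            raise ValueError("boundary ordering violated: require ILM <= posterior RNFL <= RPE")
        if self.n_depth is not None:
            for name, arr in (("ilm", self.ilm), ("rnfl_post", self.rnfl_post), ("rpe", self.rpe)):
                if np.any(arr < -0.5) or np.any(arr >= self.n_depth):
                    raise ValueError(f"boundary {name} outside the axial range")

    def copy(self) -> "LayerBoundaries":
        return LayerBoundaries(
            ilm=self.ilm.copy(),
            rnfl_post=self.rnfl_post.copy(),
            rpe=self.rpe.copy(),
            quality=self.quality.copy(),
            n_depth=self.n_depth,
        )


def _parabolic_refine(profile: np.ndarray, k: int) -> float:
    """Sub-sample peak position by fitting a parabola through k-1, k, k+1."""
    if k <= 0 or k >= profile.size - 1:
        return float(k)
    y0, y1, y2 = profile[k - 1], profile[k], profile[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(k)
    return float(k + 0.5 * (y0 - y2) / denom)


def _parabolic_refine_rows(profiles: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Row-wise parabolic peak refinement; ``profiles`` is (N, nz), ``k`` (N,)."""
    nz = profiles.shape[1]
    kc = np.clip(k, 1, nz - 2)
    rows = np.arange(profiles.shape[0])
    y0 = profiles[rows, kc - 1]
    y1 = profiles[rows, kc]
    y2 = profiles[rows, kc + 1]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom != 0, 0.5 * (y0 - y2) / denom, 0.0)
    out = np.where((k >= 1) & (k <= nz - 2), kc + delta, k.astype(float))
    return out


def segment_layers(
    structure: np.ndarray,
    gradient_sigma: float = 2.0,
    median_size: int = 5,
    min_gradient_frac: float = 0.25,
) -> LayerBoundaries:
    """Locate ILM, posterior RNFL and RPE in a structural volume.

    Parameters
    ----------
    structure
        Log-scaled structural volume, shape ``(n_bscans, n_ascans, n_depth)``,
        vitreous dark / tissue bright.
    gradient_sigma
        Scale (axial samples) of the derivative-of-Gaussian edge operator.
    median_size
        Lateral median-filter window applied to each boundary surface.
    min_gradient_frac
        An A-scan is flagged low-quality when its peak gradient falls below
        this fraction of the volume's median peak gradient; flagged boundaries
        are interpolated from neighbors.
    """
    vol = np.asarray(structure, dtype=float)
    if vol.ndim != 3:
        raise ValueError("structure must be 3-D (bscan, ascan, depth)")
    ny, nx, nz = vol.shape

    smooth = ndimage.gaussian_filter1d(vol, gradient_sigma, axis=-1, mode="nearest")
    grad = ndimage.gaussian_filter1d(vol, gradient_sigma, axis=-1, order=1, mode="nearest")

    g = grad.reshape(-1, nz)
    p = smooth.reshape(-1, nz)
    n = g.shape[0]
    rows = np.arange(n)
    z = np.arange(nz)[None, :]

    g_peak = g.max(axis=1)
    grad_floor = min_gradient_frac * float(np.median(g_peak))
    quality_flat = (g_peak >= grad_floor) & (g_peak > 0)

    # ILM: first strong positive-gradient peak from the vitreous side (the
    # deeper RPE edge can be even stronger, so "first", not "max")
    rising = np.zeros_like(g, dtype=bool)
    rising[:, 1:-1] = (
        (g[:, 1:-1] >= g[:, :-2])
        & (g[:, 1:-1] >= g[:, 2:])
        & (g[:, 1:-1] >= 0.5 * g_peak[:, None])
    )
    has_rising = rising.any(axis=1)
    k_ilm = np.where(has_rising, rising.argmax(axis=1), g.argmax(axis=1))
    z_ilm = _parabolic_refine_rows(g, k_ilm)

    # RPE: deepest strong intensity peak posterior to the ILM (the RPE band
    # outshines inner layers; take the most posterior local maximum within
    # 90% of the peak brightness)
    lo = np.minimum(nz - 1, k_ilm + 2)
    valid = z >= lo[:, None]
    p_masked = np.where(valid, p, -np.inf)
    seg_max = p_masked.max(axis=1)
    strong = valid & (p >= 0.9 * seg_max[:, None])
    local_max = np.zeros_like(p, dtype=bool)
    local_max[:, 1:-1] = (p[:, 1:-1] >= p[:, :-2]) & (p[:, 1:-1] >= p[:, 2:])
    ends = (z == lo[:, None]) | (z == nz - 1)
    candidates = strong & (local_max | ends)
    has_cand = candidates.any(axis=1)
    last_cand = nz - 1 - candidates[:, ::-1].argmax(axis=1)
    k_rpe = np.where(has_cand, last_cand, p_masked.argmax(axis=1))
    z_rpe = _parabolic_refine_rows(p, k_rpe)

    # posterior RNFL: most negative gradient between ILM and RPE
    a = k_ilm + 1
    b = np.maximum(k_ilm + 2, k_rpe - 1)
    in_win = (z >= a[:, None]) & (z < b[:, None])
    g_win = np.where(in_win, g, np.inf)
    k_rnfl = g_win.argmin(axis=1)
    k_rnfl = np.where(in_win[rows, k_rnfl], k_rnfl, a)
    z_rnfl = _parabolic_refine_rows(-g, k_rnfl)

    ilm = z_ilm.reshape(ny, nx)
    rpe = z_rpe.reshape(ny, nx)
    rnfl = np.clip(z_rnfl.reshape(ny, nx), ilm, rpe)
    quality = quality_flat.reshape(ny, nx)

    # fill flagged A-scans from their nearest valid neighbor
    if not quality.all():
        if not quality.any():
            raise ValueError("no A-scan produced a detectable gradient")
        idx = ndimage.distance_transform_edt(~quality, return_distances=False, return_indices=True)
        for surf in (ilm, rnfl, rpe):
            surf[~quality] = surf[idx[0][~quality], idx[1][~quality]]

    if median_size > 1 and min(ny, nx) >= median_size:
        ilm = ndimage.median_filter(ilm, size=median_size, mode="nearest")
        rnfl = ndimage.median_filter(rnfl, size=median_size, mode="nearest")
        rpe = ndimage.median_filter(rpe, size=median_size, mode="nearest")
        rnfl = np.clip(rnfl, ilm, rpe)

    return LayerBoundaries(ilm=ilm, rnfl_post=rnfl, rpe=rpe, quality=quality, n_depth=nz)


def apply_manual_overrides(
    lb: LayerBoundaries,
    edits: list[dict],
    smoothing_mm: float | None = None,
    influence_px: float = 3.0,
) -> LayerBoundaries:
    """Impose sparse manual boundary points with smooth local interpolation.

    Each edit is ``{"surface": "ilm"|"rnfl_post"|"rpe", "y": int, "x": int,
    "z": float}``.  The surface is shifted so it passes exactly through each
    edit point, with the correction decaying as a Gaussian of lateral scale
    ``influence_px`` around it.  Ordering invariants are re-validated; edits
    that violate them are rejected.
    """
    out = lb.copy()
    surfaces = {"ilm": out.ilm, "rnfl_post": out.rnfl_post, "rpe": out.rpe}
    ny, nx = out.ilm.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    for edit in edits:
        name = edit["surface"]
        if name not in surfaces:
            raise ValueError(f"unknown surface {name!r}")
        y, x, z = int(edit["y"]), int(edit["x"]), float(edit["z"])
        if not (0 <= y < ny and 0 <= x < nx):
            raise ValueError(f"edit point ({y}, {x}) outside the en face grid")
        surf = surfaces[name]
        delta = z - surf[y, x]
        d2 = (yy - y) ** 2 + (xx - x) ** 2
        w = np.exp(-d2 / (2 * influence_px**2))
        w[d2 > (3 * influence_px) ** 2] = 0.0  # compact support: edits stay local
        surf += delta * w
        surf[y, x] = z  # exact anchor
    try:
        out.validate()
    except ValueError as exc:
        raise ValueError(f"manual edit rejected: {exc}") from exc
    return out
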