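"""Synthetic multi-repeat complex OCT phantom with known ground truth.

The phantom emulates the acquisition geometry of a 68 kHz spectral-domain
instrument imaging the optic-nerve-head region: per transverse location
R = 4 repeated complex B-scans, a layered retina (vitreous / RNFL / inner
retina / RPE band), an optic disc, large shadow-casting retinal vessels and
an RNFL capillary bed whose inter-repeat complex decorrelation scales with
a per-pixel flux parameter ``phi`` in [0, 1].

Static voxels keep an identical complex value across repeats up to additive
circular-Gaussian speckle noise and a per-B-scan bulk phase.  Flow voxels
are re-drawn each repeat with a phase spread and amplitude jitter
proportional to ``phi``, so the downstream inter-B-scan difference magnitude
grows monotonically with ``phi`` and is exactly zero at ``phi = 0`` in the
noiseless case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .flow import ComplexOCTCube

# reflectivity of each compartment, relative to RNFL tissue; the inner-retina
# and sub-RPE flanks are equal so the bright RPE band is locally symmetric and
# its center can be recovered to machine precision in the noiseless case
AMP_VITREOUS = 0.05
AMP_RNFL = 1.0
AMP_INNER = 0.45
AMP_RPE = 2.0
AMP_SUB_RPE = 0.45
AMP_VESSEL = 1.2
DISC_DIM_FACTOR = 0.35  # structural dimming inside the disc (cup is dark)
RPE_BAND_HALFWIDTH = 2  # samples on each side of the RPE center
CAPILLARY_PHI = 0.9  # default flux parameter on capillary pixels


@dataclass
class BigVessel:
    """A large retinal vessel: en face polyline with physical radius.

    ``shadow_attenuation`` multiplies the structural amplitude of every voxel
    below the vessel (blood absorbs and scatters strongly, casting a shadow
    visible in the sub-RPE structural en face).
    """

    polyline_mm: list[tuple[float, float]]  # (x, y) vertices
    radius_um: float = 40.0
    shadow_attenuation: float = 0.4


@dataclass
class PhantomScene:
    """Full description of one synthetic eye; all downstream truth derives from it."""

    n_bscans: int
    n_ascans: int
    n_depth: int
    lateral_extent_mm: float = 2.4
    axial_extent_mm: float = 2.0
    # layer maps in axial samples, shape (n_bscans, n_ascans); "first sample of
    # the deeper compartment" convention (the physical interface sits 0.5
    # samples anterior)
    ilm: np.ndarray | None = None
    rnfl_post: np.ndarray | None = None
    rpe: np.ndarray | None = None
    disc_center_mm: tuple[float, float] | None = None
    disc_radius_mm: float = 0.0
    big_vessels: list[BigVessel] = field(default_factory=list)
    capillary_mask: np.ndarray | None = None
    flux: np.ndarray | None = None  # per-pixel phi in [0, 1]
    noise_sigma: float = 0.0
    bulk_phases: np.ndarray | None = None  # (R, n_bscans) radians
    n_repeats: int = 4
    aline_rate_hz: float = 68_000.0
    laterality: str = "OD"
    seed: int = 0

    @property
    def dx_mm(self) -> float:
        return self.lateral_extent_mm / self.n_ascans

    @property
    def dy_mm(self) -> float:
        return self.lateral_extent_mm / self.n_bscans

    @property
    def dz_mm(self) -> float:
        return self.axial_extent_mm / self.n_depth

    @property
    def grid2d(self) -> tuple[int, int]:
        return (self.n_bscans, self.n_ascans)

    def __post_init__(self) -> None:
        shape = self.grid2d
        if min(self.n_bscans, self.n_ascans, self.n_depth) < 4:
            raise ValueError(f"invalid grid shape {shape + (self.n_depth,)}: each axis needs >= 4 samples")
        if self.ilm is None:
            self.ilm = np.full(shape, round(0.25 * self.n_depth))
        if self.rnfl_post is None:
            self.rnfl_post = np.full(shape, round(0.45 * self.n_depth))
        if self.rpe is None:
            self.rpe = np.full(shape, round(0.70 * self.n_depth))
        self.ilm = np.broadcast_to(np.asarray(self.ilm, float), shape).copy()
        self.rnfl_post = np.broadcast_to(np.asarray(self.rnfl_post, float), shape).copy()
        self.rpe = np.broadcast_to(np.asarray(self.rpe, float), shape).copy()
        if self.capillary_mask is None:
            self.capillary_mask = np.zeros(shape, dtype=bool)
        self.capillary_mask = np.asarray(self.capillary_mask, dtype=bool)
        if self.flux is None:
            self.flux = np.where(self.capillary_mask, CAPILLARY_PHI, 0.0)
        self.flux = np.asarray(self.flux, dtype=float)
        if self.bulk_phases is None:
            self.bulk_phases = np.zeros((self.n_repeats, self.n_bscans))
        self.bulk_phases = np.asarray(self.bulk_phases, dtype=float)
        self.validate()

    def validate(self) -> None:
        shape = self.grid2d
        if not (np.all(self.ilm < self.rnfl_post) and np.all(self.rnfl_post < self.rpe)):
            raise ValueError("layer monotonicity violated: require ILM < posterior RNFL < RPE at every (x, y)")
        for name, arr in (("ilm", self.ilm), ("rnfl_post", self.rnfl_post), ("rpe", self.rpe)):
            if np.any(arr < 0) or np.any(arr >= self.n_depth):
                raise ValueError(f"layer map {name} leaves the axial range [0, {self.n_depth})")
        if self.capillary_mask.shape != shape or self.flux.shape != shape:
            raise ValueError("capillary mask / flux map must match the en face grid shape")
        if np.any(self.flux < 0) or np.any(self.flux > 1):
            raise ValueError("flux parameter phi must lie in [0, 1]")
        if np.any(self.flux[~self.capillary_mask & ~self._vessel_footprint()] != 0):
            raise ValueError("phi must be 0 outside capillary/vessel pixels")
        if self.bulk_phases.shape != (self.n_repeats, self.n_bscans):
            raise ValueError("bulk_phases must have shape (n_repeats, n_bscans)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def _vessel_footprint(self) -> np.ndarray:
        return rasterize_vessels(self)[0]


@dataclass
class GroundTruth:
    """En face masks, flux map, layer surfaces and disc geometry of a phantom."""

    big_vessel_mask: np.ndarray  # (n_bscans, n_ascans) bool
    capillary_mask: np.ndarray  # (n_bscans, n_ascans) bool
    flux_map: np.ndarray  # per-pixel phi
    ilm: np.ndarray  # interface positions, fractional samples
    rnfl_post: np.ndarray
    rpe: np.ndarray
    disc_center_px: tuple[float, float] | None  # (x, y)
    disc_margin_px: np.ndarray | None  # (n, 2) polygon, (x, y)
    expected_density: dict
    flow_voxel_mask: np.ndarray  # (n_bscans, n_ascans, n_depth) bool

    def __post_init__(self) -> None:
        if self.big_vessel_mask.shape != self.capillary_mask.shape:
            raise ValueError("ground-truth masks must share the en face grid shape")
        for v in self.expected_density.values():
            if not 0 <= v <= 1:
                raise ValueError("expected densities must lie in [0, 1]")


def rasterize_vessels(scene: PhantomScene) -> tuple[np.ndarray, np.ndarray]:
    """En face footprint of the big vessels and per-pixel shadow attenuation."""
    footprint = np.zeros(scene.grid2d, dtype=bool)
    attenuation = np.ones(scene.grid2d)
    for vessel in scene.big_vessels:
        v_mask = np.zeros(scene.grid2d, dtype=bool)
        pts = [
            (int(round(y / scene.dy_mm)), int(round(x / scene.dx_mm)))
            for x, y in vessel.polyline_mm
        ]
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < scene.n_bscans) & (cc >= 0) & (cc < scene.n_ascans)
            v_mask[rr[ok], cc[ok]] = True
        radius_px = vessel.radius_um / 1000.0 / scene.dx_mm
        if radius_px >= 1:
            v_mask = ndimage.binary_dilation(v_mask, structure=disk(int(round(radius_px))))
        footprint |= v_mask
        attenuation = np.where(v_mask, np.minimum(attenuation, vessel.shadow_attenuation), attenuation)
    return footprint, attenuation


def _disc_mask(scene: PhantomScene) -> np.ndarray:
    if scene.disc_center_mm is None or scene.disc_radius_mm <= 0:
        return np.zeros(scene.grid2d, dtype=bool)
    cx, cy = scene.disc_center_mm
    x_mm = (np.arange(scene.n_ascans) + 0.5) * scene.dx_mm
    y_mm = (np.arange(scene.n_bscans) + 0.5) * scene.dy_mm
    xx, yy = np.meshgrid(x_mm, y_mm)
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= scene.disc_radius_mm**2


def _structural_amplitude(scene: PhantomScene) -> np.ndarray:
    """Noise-free reflectivity A(y, x, z) of the layered retina."""
    z = np.arange(scene.n_depth)[None, None, :]
    ilm = scene.ilm[..., None]
    rnfl_post = scene.rnfl_post[..., None]
    rpe = scene.rpe[..., None]
    amp = np.full((scene.n_bscans, scene.n_ascans, scene.n_depth), AMP_VITREOUS)
    amp = np.where((z >= ilm) & (z < rnfl_post), AMP_RNFL, amp)
    amp = np.where((z >= rnfl_post) & (z < rpe - RPE_BAND_HALFWIDTH), AMP_INNER, amp)
    amp = np.where(np.abs(z - rpe) <= RPE_BAND_HALFWIDTH, AMP_RPE, amp)
    amp = np.where(z > rpe + RPE_BAND_HALFWIDTH, AMP_SUB_RPE, amp)
    return amp


def generate_cube(scene: PhantomScene) -> tuple[ComplexOCTCube, GroundTruth]:
    """Render a phantom scene into R repeated complex B-scans plus ground truth."""
    scene.validate()
    rng = np.random.default_rng(scene.seed)
    shape3d = (scene.n_bscans, scene.n_ascans, scene.n_depth)
    z = np.arange(scene.n_depth)[None, None, :]

    amp = _structural_amplitude(scene)
    vessel_mask, shadow = rasterize_vessels(scene)
    disc = _disc_mask(scene)

    # capillaries never inside the disc; vessels dominate where they overlap
    capillary_mask = scene.capillary_mask & ~disc & ~vessel_mask
    flux2d = np.where(capillary_mask, scene.flux, 0.0)
    flux2d = np.where(vessel_mask & ~disc, 1.0, flux2d)

    # big-vessel lumen occupies an axial band in the mid-RNFL
    vz = (scene.ilm + scene.rnfl_post) / 2.0
    vr_px = max(
        (max((v.radius_um for v in scene.big_vessels), default=0.0) / 1000.0) / scene.dz_mm,
        1.0,
    )
    lumen = vessel_mask[..., None] & (np.abs(z - vz[..., None]) <= vr_px)
    # shadow attenuates everything below the vessel lumen
    below = vessel_mask[..., None] & (z > vz[..., None] + vr_px)
    amp = np.where(below, amp * shadow[..., None], amp)
    amp = np.where(lumen, AMP_VESSEL, amp)
    amp = np.where(disc[..., None] & (z >= scene.ilm[..., None]), amp * DISC_DIM_FACTOR, amp)

    # flow voxels: capillaries fill the RNFL band; vessel lumen voxels flow too
    in_rnfl = (z >= scene.ilm[..., None]) & (z < scene.rnfl_post[..., None])
    flow_mask = (capillary_mask[..., None] & in_rnfl) | lumen
    phi = np.where(flow_mask, flux2d[..., None], 0.0)

    static_phase = rng.uniform(-np.pi, np.pi, size=shape3d)
    data = np.empty((scene.n_repeats,) + shape3d, dtype=np.complex64)
    for i in range(scene.n_repeats):
        theta = static_phase.copy()
        a = amp.copy()
        if flow_mask.any():
            n_flow = int(flow_mask.sum())
            # phase spread phi*U(-pi/2, pi/2) keeps |delta theta| <= pi, so the
            # expected difference magnitude is strictly increasing in phi
            theta[flow_mask] += phi[flow_mask] * rng.uniform(-np.pi / 2, np.pi / 2, n_flow)
            a[flow_mask] *= 1.0 + 0.3 * phi[flow_mask] * rng.uniform(-1, 1, n_flow)
        frame = a * np.exp(1j * theta)
        if scene.noise_sigma > 0:
            noise = rng.standard_normal(shape3d) + 1j * rng.standard_normal(shape3d)
            frame = frame + scene.noise_sigma / np.sqrt(2.0) * noise
        frame = frame * np.exp(1j * scene.bulk_phases[i])[:, None, None]
        data[i] = frame.astype(np.complex64)

    cube = ComplexOCTCube(
        data=data,
        dx_mm=scene.dx_mm,
        dy_mm=scene.dy_mm,
        dz_mm=scene.dz_mm,
        aline_rate_hz=scene.aline_rate_hz,
        laterality=scene.laterality,
    )

    disc_center_px = None
    disc_margin_px = None
    if scene.disc_center_mm is not None and scene.disc_radius_mm > 0:
        cx = scene.disc_center_mm[0] / scene.dx_mm - 0.5
        cy = scene.disc_center_mm[1] / scene.dy_mm - 0.5
        disc_center_px = (cx, cy)
        ang = np.linspace(0, 2 * np.pi, 33)
        disc_margin_px = np.column_stack(
            [
                cx + scene.disc_radius_mm / scene.dx_mm * np.cos(ang),
                cy + scene.disc_radius_mm / scene.dy_mm * np.sin(ang),
            ]
        )

    truth = GroundTruth(
        big_vessel_mask=vessel_mask,
        capillary_mask=capillary_mask,
        flux_map=flux2d,
        ilm=scene.ilm - 0.5,
        rnfl_post=scene.rnfl_post - 0.5,
        rpe=scene.rpe.copy(),
        disc_center_px=disc_center_px,
        disc_margin_px=disc_margin_px,
        expected_density={"enface": float(capillary_mask.mean())},
        flow_voxel_mask=flow_mask,
    )
    return cube, truth


# ---------------------------------------------------------------------------
# scene builders
# ---------------------------------------------------------------------------


def _random_curves(
    rng: np.random.Generator,
    shape2d: tuple[int, int],
    target_pixels: int,
    count_mask: np.ndarray | None = None,
    step_sigma: float = 0.25,
    min_len: int = 15,
    max_len: int = 50,
    brush: tuple[tuple[int, int], ...] = ((0, 0), (0, 1)),
) -> np.ndarray:
    """Curvilinear capillary mask from smooth random walks.

    Each walk is painted with ``brush`` (default 2 px wide — a capillary
    broadened by the lateral point spread, as it appears on an en face
    angiogram).  Walks are seeded inside ``count_mask`` (whole grid if None)
    and marked pixel by pixel; generation stops once exactly
    ``target_pixels`` newly marked pixels fall inside ``count_mask``,
    trimming the last walk so the in-region pixel count is hit exactly.
    """
    ny, nx = shape2d
    mask = np.zeros(shape2d, dtype=bool)
    if count_mask is None:
        count_mask = np.ones(shape2d, dtype=bool)
    seeds_y, seeds_x = np.nonzero(count_mask)
    if seeds_y.size == 0 or target_pixels <= 0:
        return mask
    n_in = 0
    guard = 0
    while n_in < target_pixels and guard < 10_000:
        guard += 1
        k = rng.integers(seeds_y.size)
        y, x = float(seeds_y[k]), float(seeds_x[k])
        ang = rng.uniform(0, 2 * np.pi)
        done = False
        for _ in range(int(rng.integers(min_len, max_len))):
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < ny and 0 <= ix < nx):
                break
            for dy, dx in brush:
                jy, jx = iy + dy, ix + dx
                if not (0 <= jy < ny and 0 <= jx < nx) or mask[jy, jx]:
                    continue
                if count_mask[jy, jx]:
                    if n_in >= target_pixels:
                        done = True
                        break
                    n_in += 1
                mask[jy, jx] = True
            if done or n_in >= target_pixels:
                break
            ang += rng.normal(0, step_sigma)
            y += np.sin(ang)
            x += np.cos(ang)
    return mask


def flat_scene(
    shape: tuple[int, int, int] = (64, 64, 128),
    lateral_extent_mm: float = 2.4,
    axial_extent_mm: float = 2.0,
    capillary_density: float = 0.0,
    capillary_phi: float = CAPILLARY_PHI,
    noise_sigma: float = 0.0,
    big_vessel_count: int = 0,
    shadow_attenuation: float = 0.4,
    disc: bool = False,
    bulk_phases: np.ndarray | None = None,
    seed: int = 0,
    n_repeats: int = 4,
) -> PhantomScene:
    """Flat-layered scene; capillaries drawn as random curvilinear walks."""
    n_bscans, n_ascans, n_depth = shape
    rng = np.random.default_rng(seed)
    grid = (n_bscans, n_ascans)
    cap = _random_curves(rng, grid, int(round(capillary_density * n_bscans * n_ascans)))
    vessels = []
    extent = lateral_extent_mm
    for i in range(big_vessel_count):
        x0 = extent * (i + 1) / (big_vessel_count + 1)
        vessels.append(
            BigVessel(
                polyline_mm=[(x0, 0.0), (x0 + 0.1 * extent, extent)],
                radius_um=0.02 * extent * 1000 / 2,  # ~2% of field width
                shadow_attenuation=shadow_attenuation,
            )
        )
    scene = PhantomScene(
        n_bscans=n_bscans,
        n_ascans=n_ascans,
        n_depth=n_depth,
        lateral_extent_mm=lateral_extent_mm,
        axial_extent_mm=axial_extent_mm,
        disc_center_mm=(extent / 2, extent / 2) if disc else None,
        disc_radius_mm=0.16 * extent if disc else 0.0,
        big_vessels=vessels,
        capillary_mask=cap,
        flux=np.where(cap, capillary_phi, 0.0),
        noise_sigma=noise_sigma,
        bulk_phases=bulk_phases,
        seed=seed,
        n_repeats=n_repeats,
    )
    return scene


def annulus_capillary_scene(
    density: float,
    shape: tuple[int, int, int] = (128, 128, 64),
    lateral_extent_mm: float = 4.8,
    inner_diameter_mm: float = 2.5,
    outer_diameter_mm: float = 3.7,
    capillary_phi: float = CAPILLARY_PHI,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> tuple[PhantomScene, np.ndarray]:
    """Scene whose capillary bed covers an exact pixel fraction of the
    peripapillary annulus.

    Returns the scene and the annulus mask used for the count.  The number of
    capillary pixels inside the annulus equals ``round(density * n_annulus)``
    exactly, so perfect-mask vessel-area-density recovery can be asserted to
    machine precision.
    """
    n_bscans, n_ascans, n_depth = shape
    rng = np.random.default_rng(seed)
    dx = lateral_extent_mm / n_ascans
    dy = lateral_extent_mm / n_bscans
    cx = (n_ascans - 1) / 2.0
    cy = (n_bscans - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(n_ascans), np.arange(n_bscans))
    r_mm = np.hypot((xx - cx) * dx, (yy - cy) * dy)
    annulus = (r_mm >= inner_diameter_mm / 2) & (r_mm <= outer_diameter_mm / 2)
    target = int(round(density * annulus.sum()))
    cap = _random_curves(rng, (n_bscans, n_ascans), target, count_mask=annulus)
    # restrict to the annulus so truth masks and annulus metrics agree exactly
    cap &= annulus
    scene = PhantomScene(
        n_bscans=n_bscans,
        n_ascans=n_ascans,
        n_depth=n_depth,
        lateral_extent_mm=lateral_extent_mm,
        disc_center_mm=((cx + 0.5) * dx, (cy + 0.5) * dy),
        disc_radius_mm=0.4,
        capillary_mask=cap,
        flux=np.where(cap, capillary_phi, 0.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return scene, annulus


def generate_cohort(
    n_per_group: int,
    group_flux_multipliers: dict[str, float],
    seed: int,
    shape: tuple[int, int, int] = (32, 32, 48),
    lateral_extent_mm: float = 4.8,
    noise_sigma: float = 0.05,
    capillary_density_range: tuple[float, float] = (0.08, 0.12),
) -> list[tuple[ComplexOCTCube, GroundTruth, str]]:
    """Simulated cohort: per-subject random vessel layouts, group-scaled flux.

    Each subject's capillary ``phi`` is the baseline capillary flux scaled by
    the group multiplier, so the mean true flux of a group with multiplier m
    is m times the normal group's (up to layout sampling error).  Fully
    deterministic given ``seed``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (group statistics undefined otherwise)")
    for g, m in group_flux_multipliers.items():
        if not 0 < m <= 1:
            raise ValueError(f"flux multiplier for group {g!r} must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for group, mult in group_flux_multipliers.items():
        for _ in range(n_per_group):
            subj_seed = int(rng.integers(2**31 - 1))
            subj_rng = np.random.default_rng(subj_seed)
            density = subj_rng.uniform(*capillary_density_range)
            scene = flat_scene(
                shape=shape,
                lateral_extent_mm=lateral_extent_mm,
                capillary_density=density,
                capillary_phi=min(1.0, CAPILLARY_PHI * mult),
                noise_sigma=noise_sigma,
                disc=True,
                bulk_phases=subj_rng.uniform(-0.5, 0.5, (4, shape[0])),
                seed=subj_seed,
            )
            cube, truth = generate_cube(scene)
            out.append((cube, truth, group))
    return out
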