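"""File formats: HDF5 complex cubes, TIFF en face images / masks with JSON
sidecars, YAML scenes.  TIFF has no standard complex dialect, hence HDF5 for
volumes; en face layers are 32-bit float TIFF; masks 8-bit TIFF."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .enface import EnFaceImage
from .flow import ComplexOCTCube, FlowVolume
from .layers import LayerBoundaries
from .phantom import BigVessel, PhantomScene
from .vessels import VesselMask


def save_cube(path: str | Path, cube: ComplexOCTCube) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data.astype(np.complex64))
        f.attrs["meta"] = json.dumps(
            {
                "dx_mm": cube.dx_mm,
                "dy_mm": cube.dy_mm,
                "dz_mm": cube.dz_mm,
                "aline_rate_hz": cube.aline_rate_hz,
                "laterality": cube.laterality,
            }
        )


def load_cube(path: str | Path) -> ComplexOCTCube:
    with h5py.File(path, "r") as f:
        data = f["cube"][()]
        meta = json.loads(f.attrs["meta"])
    return ComplexOCTCube(data=data, **meta)


def save_flow_volume(path: str | Path, vol: FlowVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("flow", data=vol.flow.astype(np.float32))
        f.create_dataset("structure", data=vol.structure.astype(np.float32))
        f.attrs["meta"] = json.dumps(
            {
                "dx_mm": vol.dx_mm,
                "dy_mm": vol.dy_mm,
                "dz_mm": vol.dz_mm,
                "f_max": vol.f_max,
                "laterality": vol.laterality,
            }
        )


def load_flow_volume(path: str | Path) -> FlowVolume:
    with h5py.File(path, "r") as f:
        flow = f["flow"][()]
        structure = f["structure"][()]
        meta = json.loads(f.attrs["meta"])
    return FlowVolume(flow=flow, structure=structure, **meta)


def save_enface(path: str | Path, img: EnFaceImage) -> None:
    """32-bit float TIFF plus a JSON sidecar with scale and disc geometry."""
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    sidecar = {
        "mm_per_pixel": list(img.mm_per_pixel),
        "laterality": img.laterality,
        "kind": img.kind,
        "disc_center": None if img.disc_center is None else list(img.disc_center),
        "disc_margin": None if img.disc_margin is None else np.asarray(img.disc_margin).tolist(),
        "disc_center_auto": img.disc_center_auto,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if not img.valid.all():
        tifffile.imwrite(path.with_name(path.stem + "_valid.tif"), img.valid.astype(np.uint8))


def load_enface(path: str | Path) -> EnFaceImage:
    path = Path(path)
    pixels = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    valid_path = path.with_name(path.stem + "_valid.tif")
    valid = tifffile.imread(valid_path).astype(bool) if valid_path.exists() else None
    return EnFaceImage(
        pixels=pixels,
        mm_per_pixel=tuple(meta["mm_per_pixel"]),
        laterality=meta["laterality"],
        kind=meta["kind"],
        disc_center=None if meta["disc_center"] is None else tuple(meta["disc_center"]),
        disc_margin=None if meta["disc_margin"] is None else np.asarray(meta["disc_margin"]),
        disc_center_auto=meta["disc_center_auto"],
        valid=valid,
    )


def save_mask(path: str | Path, mask: VesselMask) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.mask.astype(np.uint8))
    path.with_suffix(".json").write_text(
        json.dumps({"source": mask.source, "params": mask.params}, indent=1)
    )


def load_mask(path: str | Path) -> VesselMask:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        source, params = meta["source"], meta["params"]
    else:
        # bare mask TIFF (e.g. a phantom ground-truth mask used directly)
        source, params = "rnfl-vessel", {"origin": str(path.name)}
    return VesselMask(
        mask=tifffile.imread(path).astype(bool), source=source, params=params
    )


def save_boundaries(path: str | Path, lb: LayerBoundaries) -> None:
    tifffile.imwrite(
        path,
        np.stack([lb.ilm, lb.rnfl_post, lb.rpe]).astype(np.float32),
        photometric="minisblack",
    )


def load_boundaries(path: str | Path, n_depth: int | None = None) -> LayerBoundaries:
    stack = tifffile.imread(path)
    return LayerBoundaries(ilm=stack[0], rnfl_post=stack[1], rpe=stack[2], n_depth=n_depth)


def save_scene(path: str | Path, scene: PhantomScene) -> None:
    doc = {
        "n_bscans": scene.n_bscans,
        "n_ascans": scene.n_ascans,
        "n_depth": scene.n_depth,
        "lateral_extent_mm": scene.lateral_extent_mm,
        "axial_extent_mm": scene.axial_extent_mm,
        "ilm": scene.ilm.tolist(),
        "rnfl_post": scene.rnfl_post.tolist(),
        "rpe": scene.rpe.tolist(),
        "disc_center_mm": None if scene.disc_center_mm is None else list(scene.disc_center_mm),
        "disc_radius_mm": scene.disc_radius_mm,
        "big_vessels": [
            {
                "polyline_mm": [list(p) for p in v.polyline_mm],
                "radius_um": v.radius_um,
                "shadow_attenuation": v.shadow_attenuation,
            }
            for v in scene.big_vessels
        ],
        "capillary_mask": scene.capillary_mask.astype(int).tolist(),
        "flux": scene.flux.tolist(),
        "noise_sigma": scene.noise_sigma,
        "bulk_phases": scene.bulk_phases.tolist(),
        "n_repeats": scene.n_repeats,
        "aline_rate_hz": scene.aline_rate_hz,
        "laterality": scene.laterality,
        "seed": scene.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc))


def load_scene(path: str | Path) -> PhantomScene:
    doc = yaml.safe_load(Path(path).read_text())
    doc["big_vessels"] = [
        BigVessel(
            polyline_mm=[tuple(p) for p in v["polyline_mm"]],
            radius_um=v["radius_um"],
            shadow_attenuation=v["shadow_attenuation"],
        )
        for v in doc.get("big_vessels", [])
    ]
    for key in ("ilm", "rnfl_post", "rpe", "flux", "bulk_phases"):
        if doc.get(key) is not None:
            doc[key] = np.asarray(doc[key], dtype=float)
    if doc.get("capillary_mask") is not None:
        doc["capillary_mask"] = np.asarray(doc["capillary_mask"], dtype=bool)
    if doc.get("disc_center_mm") is not None:
        doc["disc_center_mm"] = tuple(doc["disc_center_mm"])
    return PhantomScene(**doc)
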