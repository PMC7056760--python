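"""MetaImage (.mhd/.raw) volume and projection IO with JSON sidecars.

Volumes round-trip bit-exactly (grid, spacing, values); every sidecar
carries units, provenance, and the configuration hash so any output can be
regenerated from its sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .geometry import AcquisitionGeometry
from .montecarlo import ProjectionSet
from .physics import EnergyWindow


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(path, array: np.ndarray, spacing_mm, sidecar: dict | None
                 = None) -> None:
    """Write a volume as MetaImage; spacing may be scalar (isotropic)."""
    path = Path(path)
    if np.isscalar(spacing_mm):
        spacing_mm = (spacing_mm,) * array.ndim
    img = sitk.GetImageFromArray(np.ascontiguousarray(array))
    img.SetSpacing(tuple(float(s) for s in reversed(spacing_mm)))
    sitk.WriteImage(img, str(path))
    meta = dict(sidecar or {})
    meta.setdefault("dtype", str(array.dtype))
    meta["shape"] = list(array.shape)
    meta["spacing_mm"] = [float(s) for s in spacing_mm]
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, default=str))


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...], dict]:
    """Read a MetaImage volume: (array, spacing_mm, sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    side = {}
    sp = _sidecar_path(path)
    if sp.exists():
        side = json.loads(sp.read_text())
        if "shape" in side and list(arr.shape) != side["shape"]:
            raise ValueError(
                f"{path}: sidecar shape {side['shape']} does not match "
                f"stored volume {list(arr.shape)}")
    return arr, spacing, side


def write_projections(directory, proj: ProjectionSet,
                      extra_meta: dict | None = None) -> None:
    """One MetaImage stack per window plus an index sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = proj.geom
    index = {
        "windows": [{"label": w.label, "center_kev": w.center,
                     "width_fraction": w.width_fraction}
                    for w in g.windows],
        "stacks": {},
        "geometry": {"n_angles": g.n_angles, "arc_deg": g.arc_deg,
                     "radius_cm": g.radius_cm, "nu": g.nu, "nv": g.nv,
                     "pitch_cm": g.pitch_cm,
                     "time_per_angle_s": g.time_per_angle_s},
        "seed": proj.seed,
        "n_histories": proj.n_histories,
        "poisson": proj.poisson,
        "meta": {**proj.meta, **(extra_meta or {})},
    }
    for lab, arr in proj.counts.items():
        fname = f"proj_{lab}.mhd"
        write_volume(directory / fname, arr, g.pitch_cm * 10.0,
                     {"units": "counts", "window": lab})
        index["stacks"][lab] = fname
    (directory / "projections.json").write_text(
        json.dumps(index, indent=1, default=str))


def read_projections(directory) -> ProjectionSet:
    directory = Path(directory)
    idx_path = directory / "projections.json"
    if not idx_path.exists():
        raise FileNotFoundError(idx_path)
    index = json.loads(idx_path.read_text())
    g = index["geometry"]
    windows = tuple(EnergyWindow(w["label"], w["center_kev"],
                                 w["width_fraction"])
                    for w in index["windows"])
    geom = AcquisitionGeometry(
        n_angles=g["n_angles"], arc_deg=g["arc_deg"],
        radius_cm=g["radius_cm"], nu=g["nu"], nv=g["nv"],
        pitch_cm=g["pitch_cm"], windows=windows,
        time_per_angle_s=g["time_per_angle_s"])
    counts = {}
    for lab, fname in index["stacks"].items():
        fpath = directory / fname
        if not fpath.exists():
            raise FileNotFoundError(f"missing window stack: {fpath}")
        arr, _, _ = read_volume(fpath)
        if arr.shape != (geom.n_angles, geom.nu, geom.nv):
            raise ValueError(f"stack {lab} shape {arr.shape} does not "
                             "match geometry")
        counts[lab] = arr
    return ProjectionSet(counts, geom, seed=index.get("seed"),
                         n_histories=index.get("n_histories", 0),
                         poisson=index.get("poisson", False),
                         meta=index.get("meta", {}))
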