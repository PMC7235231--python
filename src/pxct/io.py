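"""Volume, projection, and spec I/O.

Volumes travel as 32-bit float multi-page TIFF stacks (one page per z slice,
ImageJ-style metadata) with a JSON sidecar carrying the voxel size and
channel, or as NRRD.  Voxel size metadata is mandatory on read: a volume
without a physical scale cannot be quantified, so the absence is an error,
never a silent default.

The NRRD reader/writer handles the raw-encoded little-endian subset of the
format (sufficient for lossless float volumes with spacings).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import phantom as ph
from .physics import BeamGeometry, parse_formula
from .tomo import ProjectionSet
from .volume import Volume3D

__all__ = [
    "write_volume",
    "read_volume",
    "write_nrrd",
    "read_nrrd",
    "write_projections",
    "read_projections",
    "spec_to_yaml",
    "spec_from_yaml",
]


class VolumeIOError(IOError):
    pass


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: Volume3D, path) -> Path:
    """Write a volume; format chosen by extension (.tif/.tiff or .nrrd)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = (
            vol.grid.astype(np.uint8)
            if vol.channel == "label"
            else vol.grid.astype(np.float32)
        )
        tifffile.imwrite(path, data, imagej=True, metadata={"axes": "ZYX"})
        _sidecar(path).write_text(
            json.dumps({"voxel_size_nm": vol.voxel_size_nm, "channel": vol.channel})
        )
        return path
    if path.suffix.lower() == ".nrrd":
        write_nrrd(vol, path)
        return path
    raise VolumeIOError(f"unsupported volume format {path.suffix!r}")


def read_volume(path, channel: str | None = None) -> Volume3D:
    """Read a TIFF-stack or NRRD volume; missing voxel-size metadata is an error."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = tifffile.imread(path)
        side = _sidecar(path)
        if not side.exists():
            raise VolumeIOError(
                f"{path} has no voxel-size metadata (expected sidecar {side.name}); "
                "refusing to guess a physical scale"
            )
        meta = json.loads(side.read_text())
        if "voxel_size_nm" not in meta:
            raise VolumeIOError(f"sidecar {side} lacks 'voxel_size_nm'")
        ch = channel or meta.get("channel", "delta")
        if ch == "label":
            grid = grid.astype(np.uint8)
        return Volume3D(grid=grid, channel=ch, voxel_size_nm=float(meta["voxel_size_nm"]))
    if path.suffix.lower() == ".nrrd":
        return read_nrrd(path, channel=channel)
    raise VolumeIOError(f"unsupported volume format {path.suffix!r}")


_NRRD_DTYPES = {"float": "<f4", "double": "<f8", "uint8": "u1"}
_DTYPE_NRRD = {np.dtype("float32"): "float", np.dtype("float64"): "double", np.dtype("uint8"): "uint8"}


def write_nrrd(vol: Volume3D, path) -> Path:
    path = Path(path)
    data = vol.grid
    if data.dtype not in _DTYPE_NRRD:
        data = data.astype(np.float32)
    s = vol.voxel_size_nm
    header = [
        "NRRD0004",
        "# channel: " + vol.channel,
        f"type: {_DTYPE_NRRD[data.dtype]}",
        "dimension: 3",
        f"sizes: {data.shape[2]} {data.shape[1]} {data.shape[0]}",
        f"spacings: {s!r} {s!r} {s!r}".replace("'", ""),
        "encoding: raw",
        "endian: little",
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        # NRRD fastest axis first: x fastest == C-order (z, y, x) array
        fh.write(np.ascontiguousarray(data.astype(data.dtype.newbyteorder("<"))).tobytes())
    return path


def read_nrrd(path, channel: str | None = None) -> Volume3D:
    path = Path(path)
    fields: dict[str, str] = {}
    comments: list[str] = []
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii").strip()
        if not magic.startswith("NRRD"):
            raise VolumeIOError(f"{path} is not an NRRD file")
        while True:
            line = fh.readline().decode("ascii").rstrip("\n")
            if line == "":
                break
            if line.startswith("#"):
                comments.append(line[1:].strip())
                continue
            key, _, value = line.partition(":")
            fields[key.strip().lower()] = value.strip()
        if fields.get("encoding", "raw") != "raw":
            raise VolumeIOError("only raw-encoded NRRD is supported")
        if fields.get("type") not in _NRRD_DTYPES:
            raise VolumeIOError(f"unsupported NRRD type {fields.get('type')!r}")
        sizes = [int(v) for v in fields["sizes"].split()]
        if len(sizes) != 3:
            raise VolumeIOError("only 3D NRRD volumes are supported")
        if "spacings" not in fields and "space directions" not in fields:
            raise VolumeIOError(f"{path} lacks voxel spacing metadata")
        if "spacings" in fields:
            spac = [float(v) for v in fields["spacings"].split()]
        else:
            rows = fields["space directions"].replace("(", " ").replace(")", " ").replace(",", " ").split()
            vals = [float(v) for v in rows]
            spac = [vals[0], vals[4], vals[8]]
        if not np.allclose(spac, spac[0]):
            raise VolumeIOError("anisotropic voxels are not supported")
        dtype = np.dtype(_NRRD_DTYPES[fields["type"]])
        raw = fh.read(int(np.prod(sizes)) * dtype.itemsize)
        grid = np.frombuffer(raw, dtype=dtype).reshape(sizes[::-1])  # x fastest
    ch = channel
    if ch is None:
        ch = next(
            (c.split(":", 1)[1].strip() for c in comments if c.startswith("channel:")),
            "delta",
        )
    if ch == "label":
        grid = grid.astype(np.uint8)
    else:
        grid = grid.astype(np.float64)
    return Volume3D(grid=grid, channel=ch, voxel_size_nm=spac[0])


def write_projections(p: ProjectionSet, path) -> Path:
    """Projection stack as float TIFF plus a JSON sidecar (angles, pixel size)."""
    path = Path(path)
    tifffile.imwrite(path, p.images.astype(np.float32), imagej=True)
    _sidecar(path).write_text(
        json.dumps(
            {"angles_deg": p.angles_deg.tolist(), "pixel_size_nm": p.pixel_size_nm}
        )
    )
    return path


def read_projections(path) -> ProjectionSet:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise VolumeIOError(f"{path} has no sidecar {side.name} (angles, pixel size)")
    meta = json.loads(side.read_text())
    images = tifffile.imread(path)
    return ProjectionSet(
        angles_deg=np.asarray(meta["angles_deg"], dtype=float),
        images=images.astype(np.float64),
        pixel_size_nm=float(meta["pixel_size_nm"]),
    )


def _material_to_dict(m: ph.Material) -> dict:
    return {
        "name": m.name,
        "density_g_cm3": m.density_g_cm3,
        "formula": "".join(
            f"{el}{n if n > 1 else ''}" for el, n in m.composition.formula.items()
        )
        if m.composition
        else None,
    }


def _material_from_dict(d: dict) -> ph.Material:
    comp = parse_formula(d["formula"]) if d.get("formula") else None
    return ph.Material(d["name"], float(d["density_g_cm3"]), comp)


def spec_to_yaml(spec: ph.PhantomSpec, path=None) -> str:
    """Serialize a PhantomSpec as YAML (inclusions tagged by kind)."""
    incs = []
    for inc in spec.inclusions:
        d = dataclasses.asdict(inc)
        d["kind"] = type(inc).__name__.lower()
        d["material"] = _material_to_dict(inc.material)
        incs.append(d)
    doc = {
        "shape": list(spec.shape),
        "beam": {
            "photon_energy_keV": spec.beam.photon_energy_keV,
            "voxel_size_nm": spec.beam.voxel_size_nm,
        },
        "matrix_material": _material_to_dict(spec.matrix_material),
        "inclusions": incs,
        "psf_fwhm_voxels": spec.psf_fwhm_voxels,
        "noise_sigma_frac": spec.noise_sigma_frac,
        "pillar_radius_voxels": spec.pillar_radius_voxels,
        "seed": spec.seed,
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


_INCLUSION_KINDS = {
    "tube": ph.Tube,
    "octahedron": ph.Octahedron,
    "cube": ph.Cube,
    "sphere": ph.Sphere,
    "ellipsoidvoid": ph.EllipsoidVoid,
}


def spec_from_yaml(source) -> ph.PhantomSpec:
    """Inverse of :func:`spec_to_yaml`; accepts YAML text or a path."""
    text = source
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    doc = yaml.safe_load(text)
    incs = []
    for d in doc.get("inclusions", []):
        d = dict(d)
        kind = d.pop("kind")
        cls = _INCLUSION_KINDS[kind]
        d["material"] = _material_from_dict(d["material"])
        for key in ("center", "axis", "semiaxes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        incs.append(cls(**d))
    return ph.PhantomSpec(
        shape=tuple(doc["shape"]),
        beam=BeamGeometry(**doc["beam"]),
        matrix_material=_material_from_dict(doc["matrix_material"]),
        inclusions=incs,
        psf_fwhm_voxels=float(doc.get("psf_fwhm_voxels", 0.0)),
        noise_sigma_frac=float(doc.get("noise_sigma_frac", 0.0)),
        pillar_radius_voxels=doc.get("pillar_radius_voxels"),
        seed=int(doc.get("seed", 0)),
    )
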