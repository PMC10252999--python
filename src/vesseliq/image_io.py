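"""Image volumes with physical spacing, plus ROI / profile-site configuration I/O.

All geometry in this package is expressed in physical millimetres, never in
pixel indices, so that a single ROI/profile configuration can be applied
unchanged to every reconstruction of a subject regardless of voxel spacing.
The centre of pixel ``(i, j)`` (0-based) sits at physical coordinate
``((i + 0.5) * spacing[0], (j + 0.5) * spacing[1])``.

Supported on-disk formats: NIfTI (``.nii`` / ``.nii.gz``, spacing taken from
the header zooms) and NPY with a JSON sidecar carrying ``spacing_mm`` and
optionally ``origin_mm``, ``kernel_family``, ``sharpness_level``. A volume
without spacing metadata is rejected — spacing is never silently assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml


class MetadataError(ValueError):
    """Required image metadata (e.g. voxel spacing) is missing or invalid."""


class GeometryError(ValueError):
    """An ROI or profile segment does not fit inside the image."""


@dataclass(frozen=True)
class ImageVolume:
    """A 2D or 3D attenuation array (HU) with per-axis physical spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D array, got ndim={data.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != data.ndim:
            raise MetadataError(
                f"spacing has {len(spacing)} entries for a {data.ndim}D array"
            )
        if any(s <= 0 for s in spacing):
            raise MetadataError(f"spacing must be positive, got {spacing}")
        if not np.all(np.isfinite(data)):
            raise ValueError("image data contains non-finite values")
        origin = tuple(float(o) for o in self.origin) or (0.0,) * data.ndim
        if len(origin) != data.ndim:
            raise MetadataError("origin must have one entry per axis")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def extent_mm(self) -> tuple[float, ...]:
        """Physical size of the array along each axis."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def axial_slice(self, index: int | None = None) -> "ImageVolume":
        """Return the 2D analysis plane (slice ``index`` of a 3D volume)."""
        if self.data.ndim == 2:
            return self
        if index is None:
            raise ValueError("a 3D volume needs an explicit slice index")
        return ImageVolume(
            self.data[..., index], self.spacing[:2], self.origin[:2]
        )


@dataclass(frozen=True)
class CircularROI:
    """Circular region of interest in physical mm coordinates."""

    label: str
    center: tuple[float, float]
    radius: float
    slice_index: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if len(self.center) != 2:
            raise ValueError("ROI center must be a 2-vector (mm)")
        if self.radius <= 0:
            raise ValueError(f"ROI radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class ProfileSite:
    """Line-profile site: a segment centred on ``center`` along ``direction``.

    ``direction`` must be a unit 2-vector; the segment spans
    ``center ± half_length * direction`` and is sampled every ``step`` mm.
    """

    label: str
    center: tuple[float, float]
    direction: tuple[float, float]
    half_length: float
    step: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        direction = tuple(float(d) for d in self.direction)
        if len(self.center) != 2 or len(direction) != 2:
            raise ValueError("center and direction must be 2-vectors")
        norm = float(np.hypot(*direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(
                f"direction must have unit norm (got |d| = {norm:.12g})"
            )
        object.__setattr__(self, "direction", direction)
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.half_length < self.step:
            raise ValueError("half_length must be >= step")


# ---------------------------------------------------------------------------
# volume I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(
    volume: ImageVolume, path: str | Path, meta: dict | None = None
) -> Path:
    """Write a volume as NIfTI or NPY + JSON sidecar, chosen by extension.

    ``meta`` (e.g. kernel family/level) is stored in the NPY sidecar; it is
    ignored for NIfTI, whose header carries spacing only.
    """
    path = Path(path)
    name = path.name
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        ndim = volume.data.ndim
        affine = np.eye(4)
        for ax, s in enumerate(volume.spacing):
            affine[ax, ax] = s
            affine[ax, 3] = volume.origin[ax]
        img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), affine)
        img.header.set_zooms(volume.spacing[:ndim])
        nib.save(img, str(path))
        return path
    if name.endswith(".npy"):
        np.save(path, volume.data)
        sidecar = {
            "spacing_mm": list(volume.spacing),
            "origin_mm": list(volume.origin),
        }
        if meta:
            sidecar.update(meta)
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
        return path
    raise ValueError(f"unsupported image format: {name}")


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI or NPY(+sidecar) volume; spacing comes from metadata."""
    path = Path(path)
    name = path.name
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()[: data.ndim]
        if len(zooms) < data.ndim or any(z <= 0 for z in zooms):
            raise MetadataError(f"NIfTI header of {name} lacks valid zooms")
        origin = tuple(float(img.affine[ax, 3]) for ax in range(data.ndim))
        return ImageVolume(data, tuple(float(z) for z in zooms), origin)
    if name.endswith(".npy"):
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise MetadataError(
                f"{name} has no JSON sidecar; voxel spacing is unknown "
                "(spacing is never assumed to be 1 mm)"
            )
        meta = json.loads(sidecar.read_text())
        if "spacing_mm" not in meta:
            raise MetadataError(f"sidecar of {name} lacks 'spacing_mm'")
        data = np.load(path)
        return ImageVolume(
            data,
            tuple(float(s) for s in meta["spacing_mm"]),
            tuple(float(o) for o in meta.get("origin_mm", ())),
        )
    raise ValueError(f"unsupported image format: {name}")


def read_volume_meta(path: str | Path) -> dict:
    """Return the sidecar metadata of an NPY volume ({} for NIfTI)."""
    path = Path(path)
    if path.name.endswith(".npy") and _sidecar_path(path).exists():
        return json.loads(_sidecar_path(path).read_text())
    return {}


# ---------------------------------------------------------------------------
# ROI / profile-site configuration


def read_roi_config(
    path: str | Path,
) -> tuple[list[CircularROI], list[ProfileSite]]:
    """Read a YAML/JSON config with ``rois:`` and ``profile_sites:`` lists.

    Coordinates are physical mm. The same objects are meant to be applied
    unchanged to every reconstruction of a subject.
    """
    path = Path(path)
    text = path.read_text()
    cfg = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    rois = [
        CircularROI(
            label=str(r["label"]),
            center=tuple(r["center"]),
            radius=float(r["radius"]),
            slice_index=r.get("slice_index"),
        )
        for r in cfg.get("rois", [])
    ]
    sites = [
        ProfileSite(
            label=str(s["label"]),
            center=tuple(s["center"]),
            direction=tuple(s["direction"]),
            half_length=float(s["half_length"]),
            step=float(s["step"]),
        )
        for s in cfg.get("profile_sites", [])
    ]
    return rois, sites


def write_roi_config(
    path: str | Path,
    rois: Sequence[CircularROI],
    sites: Sequence[ProfileSite],
) -> Path:
    """Write ROIs and profile sites to a YAML or JSON config file."""
    path = Path(path)
    cfg = {
        "rois": [
            {
                "label": r.label,
                "center": list(r.center),
                "radius": r.radius,
                **({"slice_index": r.slice_index} if r.slice_index is not None else {}),
            }
            for r in rois
        ],
        "profile_sites": [
            {
                "label": s.label,
                "center": list(s.center),
                "direction": list(s.direction),
                "half_length": s.half_length,
                "step": s.step,
            }
            for s in sites
        ],
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=1))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
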