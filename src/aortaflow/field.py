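"""Container for time-resolved three-component velocity data.

A :class:`VelocityField4D` holds the three velocity components (m/s) and the
signal magnitude on a regular grid over the cardiac cycle. Axis order is
(x, y, z, t); world coordinates of voxel centers are
``origin + index * spacing`` in millimetres.

On disk a field is a set of NIfTI volumes (``vx``, ``vy``, ``vz``, ``mag``,
each with cardiac frames on the fourth axis) plus a JSON sidecar carrying
venc, frame duration and voxel spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DataError

__all__ = ["VelocityField4D", "save_field", "load_field"]

_COMPONENT_NAMES = ("vx", "vy", "vz")


@dataclass
class VelocityField4D:
    """Time-resolved velocity field with magnitude.

    Attributes
    ----------
    velocity:
        Array of shape ``(nx, ny, nz, nt, 3)`` in m/s; the last axis holds
        the (x, y, z) components.
    magnitude:
        Array of shape ``(nx, ny, nz, nt)``, arbitrary units.
    spacing:
        Voxel spacing per axis in mm.
    frame_duration:
        Duration of one cardiac frame in ms.
    venc:
        Velocity-encoding limit in m/s; measured velocities outside
        ``(-venc, venc]`` alias (phase-wrap).
    origin:
        World coordinate (mm) of voxel index (0, 0, 0).
    meta:
        Free-form provenance / QC dictionary.
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    spacing: tuple[float, float, float]
    frame_duration: float
    venc: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise DataError(f"velocity must have shape (nx,ny,nz,nt,3), got {self.velocity.shape}")
        if self.magnitude.shape != self.velocity.shape[:4]:
            raise DataError(
                "magnitude shape %s does not match velocity grid %s"
                % (self.magnitude.shape, self.velocity.shape[:4])
            )
        if self.n_frames < 1:
            raise DataError("field needs at least one cardiac frame")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise DataError(f"spacing must be three positive values, got {self.spacing}")
        if self.frame_duration <= 0:
            raise DataError("frame_duration must be positive (ms)")
        if self.venc <= 0:
            raise DataError("venc must be positive (m/s)")
        if not np.all(np.isfinite(self.velocity)):
            raise DataError("velocity contains non-finite values")

    # -- derived quantities -------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[3]

    @property
    def cycle_duration(self) -> float:
        """Cardiac cycle length in ms."""
        return self.n_frames * self.frame_duration

    def speed(self) -> np.ndarray:
        """Per-voxel, per-frame speed |v| in m/s, shape ``(nx, ny, nz, nt)``."""
        return np.linalg.norm(self.velocity, axis=-1)

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (mm) of voxel centers.

        With a boolean ``mask``, returns ``(n_masked, 3)``; otherwise the
        full grid as ``(nx, ny, nz, 3)``.
        """
        idx = np.indices(self.grid_shape, dtype=float)
        coords = np.stack(
            [idx[i] * self.spacing[i] + self.origin[i] for i in range(3)], axis=-1
        )
        if mask is not None:
            return coords[np.asarray(mask, bool)]
        return coords

    def copy_with(self, **kwargs) -> "VelocityField4D":
        """Shallow-copy the field, replacing the given attributes."""
        out = replace(self, **kwargs)
        out.meta = dict(self.meta, **kwargs.get("meta", {}))
        return out


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def save_field(fld: VelocityField4D, out_dir: str | Path) -> Path:
    """Write a field as NIfTI component volumes plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(fld.spacing, fld.origin)
    for c, name in enumerate(_COMPONENT_NAMES):
        nib.save(nib.Nifti1Image(fld.velocity[..., c], aff), out / f"{name}.nii.gz")
    nib.save(nib.Nifti1Image(fld.magnitude, aff), out / "mag.nii.gz")
    sidecar = {
        "venc_m_per_s": fld.venc,
        "frame_duration_ms": fld.frame_duration,
        "spacing_mm": list(fld.spacing),
        "origin_mm": list(fld.origin),
        "n_frames": fld.n_frames,
    }
    (out / "flow.json").write_text(json.dumps(sidecar, indent=2))
    return out


def load_field(in_dir: str | Path) -> VelocityField4D:
    """Load a field written by :func:`save_field`."""
    src = Path(in_dir)
    sidecar_path = src / "flow.json"
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    comps = []
    for name in _COMPONENT_NAMES:
        p = src / f"{name}.nii.gz"
        if not p.exists():
            raise DataError(f"missing velocity component volume {p}")
        comps.append(np.asarray(nib.load(p).dataobj, dtype=float))
    mag = np.asarray(nib.load(src / "mag.nii.gz").dataobj, dtype=float)
    return VelocityField4D(
        velocity=np.stack(comps, axis=-1),
        magnitude=mag,
        spacing=tuple(sidecar["spacing_mm"]),
        frame_duration=float(sidecar["frame_duration_ms"]),
        venc=float(sidecar["venc_m_per_s"]),
        origin=tuple(sidecar.get("origin_mm", (0.0, 0.0, 0.0))),
    )


def save_mask(mask: np.ndarray, spacing, out_path: str | Path, origin=(0.0, 0.0, 0.0)) -> Path:
    """Write a binary mask as a 0/1 NIfTI volume."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing, origin))
    nib.save(img, out_path)
    return out_path


def load_mask(path: str | Path) -> np.ndarray:
    """Load a 0/1 NIfTI mask as a boolean array."""
    return np.asarray(nib.load(path).dataobj) > 0.5
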