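"""Voxel-by-voxel hemodynamic maps and regional summaries.

All maps are computed on the 1 mm isotropic analysis grid:

* **Forward/reverse flow** (FF/RF, mL/cycle): the velocity is projected
  onto the tangent of each voxel's matched centerline plane; positive
  (downstream) and negative (upstream) parts are integrated over the
  cycle through the 1 mm^2 voxel face,
  ``FF = sum_t max(v_par, 0) * A * dt`` (and symmetrically for RF).
* **Stasis** (%): percentage of cardiac frames with speed below the slow
  flow threshold (0.1 m/s).
* **Kinetic energy** (uJ): ``sum_t 1/2 * rho * dV * |v(t)|^2`` with
  rho = 1060 kg/m^3 and dV = 1 mm^3, summed over the cycle.
* **Peak velocity** (m/s): maximum speed over the systolic frames.

Maps carry NaN outside the lumen so projections can distinguish background
from true zeros.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .errors import DataError, ParameterError
from .field import VelocityField4D
from .geometry import AorticGeometryReport, Centerline, RegionLabels, VoxelPlaneAssignment

__all__ = [
    "interpolate_isotropic",
    "forward_reverse_flow",
    "stasis_map",
    "kinetic_energy_map",
    "peak_velocity_map",
    "detect_systole",
    "mean_projection",
    "mip_projection",
    "regional_summary",
    "reynolds_number",
]

log = logging.getLogger(__name__)


def interpolate_isotropic(
    fld: VelocityField4D, mask: np.ndarray, target: float = 1.0, margin: float = 2.0
) -> tuple[VelocityField4D, np.ndarray]:
    """Resample velocities and mask to an isotropic (default 1 mm) grid.

    Velocity components (and magnitude) are interpolated with cubic
    splines; the mask is interpolated linearly and thresholded at 0.5. The
    output grid covers the mask bounding box plus ``margin`` mm, and the
    returned field's ``origin`` keeps world coordinates consistent with
    the input.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise DataError("empty mask")
    spacing = np.asarray(fld.spacing, float)
    bbox = np.argwhere(mask)
    lo_mm = bbox.min(axis=0) * spacing - margin
    hi_mm = bbox.max(axis=0) * spacing + margin
    lo_mm = np.maximum(lo_mm, 0.0)

    axes = [np.arange(lo_mm[i], hi_mm[i] + target / 2, target) for i in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    # index coordinates in the source grid
    idx = np.stack([grid[i] / spacing[i] for i in range(3)])
    flat_idx = idx.reshape(3, -1)
    out_shape = grid[0].shape

    nt = fld.n_frames
    velocity = np.empty(out_shape + (nt, 3))
    magnitude = np.empty(out_shape + (nt,))
    for t in range(nt):
        for c in range(3):
            velocity[..., t, c] = ndimage.map_coordinates(
                fld.velocity[..., t, c], flat_idx, order=3, mode="nearest"
            ).reshape(out_shape)
        magnitude[..., t] = ndimage.map_coordinates(
            fld.magnitude[..., t], flat_idx, order=3, mode="nearest"
        ).reshape(out_shape)

    mask_iso = (
        ndimage.map_coordinates(mask.astype(float), flat_idx, order=1, mode="constant").reshape(
            out_shape
        )
        >= 0.5
    )
    origin = tuple(np.asarray(fld.origin, float) + lo_mm)
    out = fld.copy_with(
        velocity=velocity,
        magnitude=magnitude,
        spacing=(target, target, target),
        origin=origin,
        meta={"resampled_to_mm": target},
    )
    return out, mask_iso


def _check_isotropic(fld: VelocityField4D) -> float:
    sp = fld.spacing
    if not np.allclose(sp, sp[0]):
        raise DataError(f"maps require an isotropic grid, got spacing {sp}")
    return float(sp[0])


def ensure_downstream_orientation(
    fld: VelocityField4D,
    centerline: Centerline,
    assignment: VoxelPlaneAssignment,
) -> tuple[Centerline, VoxelPlaneAssignment, bool]:
    """Orient the centerline along the net flow direction.

    A thinning-based centerline carries no anatomical direction; when the
    inlet position is unknown, the physiologic convention is that the
    cycle-integrated bulk flow runs downstream. If the net tangential flux
    over the lumen is negative the centerline (and the matching
    assignment) are flipped. Returns the possibly-flipped pair and whether
    a flip occurred.
    """
    from .geometry import flip_centerline

    tangents = centerline.tangents[assignment.point_index]
    vox_v = fld.velocity[tuple(assignment.voxel_index.T)]
    net = float(np.einsum("ntc,nc->", vox_v, tangents))
    if net >= 0:
        return centerline, assignment, False
    flipped = flip_centerline(centerline)
    n = len(centerline)
    new_assignment = VoxelPlaneAssignment(
        mask=assignment.mask,
        voxel_index=assignment.voxel_index,
        point_index=(n - 1) - assignment.point_index,
        axial_distance=-assignment.axial_distance,
    )
    log.info("centerline flipped to match the net flow direction")
    return flipped, new_assignment, True


def forward_reverse_flow(
    fld: VelocityField4D,
    assignment: VoxelPlaneAssignment,
    centerline: Centerline,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel forward and reverse flow in mL/cycle.

    The velocity of each lumen voxel is projected on the tangent of its
    matched centerline plane; the downstream (positive) and upstream
    (negative) parts are summed over the cycle through the voxel face
    (1 mm^2 on the isotropic grid). With v in m/s, dt in s and a 1 mm^2
    face, one frame contributes exactly ``v * dt`` millilitres.
    """
    h = _check_isotropic(fld)
    if assignment.mask.shape != fld.grid_shape:
        raise DataError("assignment mask does not match the field grid")
    tangents = centerline.tangents[assignment.point_index]
    if not np.allclose(np.linalg.norm(tangents, axis=1), 1.0, atol=1e-6):
        raise AssertionError("centerline tangents must be unit-norm")

    vox_v = fld.velocity[tuple(assignment.voxel_index.T)]  # (n, nt, 3)
    v_par = np.einsum("ntc,nc->nt", vox_v, tangents)
    dt_s = fld.frame_duration / 1000.0
    face_mm2 = h * h
    # m/s * s * mm^2 = mm^2 * m = 1e-6 m^3 = 1 mL per unit
    ff_vox = np.clip(v_par, 0.0, None).sum(axis=1) * dt_s * face_mm2 / 1.0
    rf_vox = np.clip(-v_par, 0.0, None).sum(axis=1) * dt_s * face_mm2 / 1.0

    ff = np.full(fld.grid_shape, np.nan)
    rf = np.full(fld.grid_shape, np.nan)
    ff[tuple(assignment.voxel_index.T)] = ff_vox
    rf[tuple(assignment.voxel_index.T)] = rf_vox
    return ff, rf


def stasis_map(
    fld: VelocityField4D,
    mask: np.ndarray | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Percent of cardiac frames with speed below the slow-flow threshold."""
    stasis = 100.0 * np.mean(fld.speed() < constants.stasis_threshold, axis=-1)
    if mask is not None:
        stasis = np.where(np.asarray(mask, bool), stasis, np.nan)
    return stasis


def kinetic_energy_map(
    fld: VelocityField4D,
    mask: np.ndarray | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Cycle-summed kinetic energy per voxel in microjoules."""
    speed2 = np.sum(fld.velocity**2, axis=-1)
    ke = 1e6 * np.sum(0.5 * constants.blood_density * constants.voxel_volume * speed2, axis=-1)
    if mask is not None:
        ke = np.where(np.asarray(mask, bool), ke, np.nan)
    return ke


def detect_systole(
    fld: VelocityField4D, mask: np.ndarray, threshold: float = 0.25
) -> np.ndarray:
    """Indices of the contiguous systolic frame window.

    The window contains the frame with maximal spatial-mean speed over the
    lumen and extends in both directions while the spatial-mean speed stays
    at or above ``threshold`` times that maximum.
    """
    if fld.n_frames < 2:
        raise ParameterError("systole detection needs at least 2 frames")
    mask = np.asarray(mask, bool)
    mean_speed = fld.speed()[mask].mean(axis=0)
    peak = int(np.argmax(mean_speed))
    if mean_speed[peak] <= 0:
        warnings.warn("all-zero velocity field: treating every frame as systolic")
        return np.arange(fld.n_frames)
    cut = threshold * mean_speed[peak]
    lo = peak
    while lo > 0 and mean_speed[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < fld.n_frames - 1 and mean_speed[hi + 1] >= cut:
        hi += 1
    return np.arange(lo, hi + 1)


def peak_velocity_map(
    fld: VelocityField4D,
    systole_frames: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Maximum speed over the systolic frames, per voxel (m/s)."""
    systole_frames = np.asarray(systole_frames, int)
    if systole_frames.size == 0:
        raise ParameterError("systole_frames must be a nonempty frame subset")
    pv = fld.speed()[..., systole_frames].max(axis=-1)
    if mask is not None:
        pv = np.where(np.asarray(mask, bool), pv, np.nan)
    return pv


def mean_projection(map_3d: np.ndarray, axis: int | str) -> np.ndarray:
    """Mean-intensity projection over lumen voxels; NaN where no lumen."""
    axis = "xyz".index(axis) if isinstance(axis, str) else axis
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(map_3d, axis=axis)


def mip_projection(map_3d: np.ndarray, axis: int | str) -> np.ndarray:
    """Maximum-intensity projection over lumen voxels; NaN where no lumen."""
    axis = "xyz".index(axis) if isinstance(axis, str) else axis
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmax(map_3d, axis=axis)


def regional_summary(
    maps: dict[str, np.ndarray],
    labels: RegionLabels,
    geometry: AorticGeometryReport | None = None,
) -> pd.DataFrame:
    """Aggregate the voxel maps per region.

    FF, RF, stasis and KE aggregate as the arithmetic voxel mean; peak
    velocity as the regional maximum. Empty regions yield NaN (missing),
    never zero. Returns a tidy frame with one row per region.
    """
    rows = []
    for ri, name in enumerate(labels.names):
        sel = labels.labels == ri
        row: dict[str, float | str] = {"region": name, "n_voxels": int(sel.sum())}
        for pname, m in maps.items():
            if m.shape != labels.labels.shape:
                raise DataError(f"map {pname!r} shape does not match labels")
            vals = m[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                row[pname] = np.nan
            elif pname == "peak_velocity":
                row[pname] = float(vals.max())
            else:
                row[pname] = float(vals.mean())
        if geometry is not None:
            row["diameter"] = geometry.diameters.get(name, np.nan)
            row["indexed_diameter"] = geometry.indexed_diameters.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def reynolds_number(
    peak_map: np.ndarray,
    assignment: VoxelPlaneAssignment,
    diameters_per_station: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Reynolds number at the vena contracta.

    The vena contracta is taken as the centerline station whose
    cross-section contains the global systolic peak-velocity voxel;
    ``Re = rho * v_peak * D / mu`` with the effective diameter D (m) at
    that station.
    """
    vox_pv = peak_map[tuple(assignment.voxel_index.T)]
    if not np.any(np.isfinite(vox_pv)):
        raise DataError("peak-velocity map is empty inside the lumen")
    i_best = int(np.nanargmax(vox_pv))
    v_peak = float(vox_pv[i_best])
    if v_peak == 0.0:
        return 0.0
    station = int(assignment.point_index[i_best])
    d = diameters_per_station[station]
    if not np.isfinite(d):
        valid = np.flatnonzero(np.isfinite(diameters_per_station))
        if valid.size == 0:
            raise DataError("no station has a valid diameter")
        nearest = valid[np.argmin(np.abs(valid - station))]
        warnings.warn(
            f"station {station} has no diameter; using nearest valid station {nearest}"
        )
        d = diameters_per_station[nearest]
    return float(
        constants.blood_density * v_peak * (d * 1e-3) / constants.viscosity
    )
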