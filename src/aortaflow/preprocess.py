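"""Velocity-field preprocessing: noise masking, anti-aliasing, background
phase correction, and the time-averaged PC-MRA.

The PC-MRA combines magnitude weighting with speed so that voxels carrying
flowing blood light up against static tissue; it is computed as the
magnitude-weighted RMS speed over the cycle,

    PCMRA = sqrt( (1/T) * sum_t (M(t) * |v(t)|)^2 ).

Background phase (residual eddy-current) correction fits a first-order
spatial polynomial per velocity component to the temporal-mean velocity of
static tissue and subtracts it everywhere; anti-aliasing unwraps the
velocity-time course of each voxel modulo 2*venc.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .field import VelocityField4D

__all__ = [
    "PCMRAVolume",
    "compute_pcmra",
    "noise_mask",
    "detect_static_tissue",
    "correct_eddy",
    "unwrap_velocity",
    "correct_maxwell",
]

log = logging.getLogger(__name__)


@dataclass
class PCMRAVolume:
    """Time-averaged phase-contrast angiogram (non-negative scalar volume)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if np.any(self.data < 0):
            raise DataError("PC-MRA values must be non-negative")


def compute_pcmra(fld: VelocityField4D) -> PCMRAVolume:
    """Magnitude-weighted RMS-speed angiogram over the cardiac cycle."""
    weighted = fld.magnitude * fld.speed()
    data = np.sqrt(np.mean(weighted**2, axis=-1))
    return PCMRAVolume(data=data, spacing=fld.spacing)


def noise_mask(fld: VelocityField4D, quantile: float = 0.3) -> np.ndarray:
    """Keep-mask excluding voxels whose time-averaged magnitude falls below
    the given quantile of the magnitude distribution.

    Returns a boolean grid; True marks voxels retained for analysis.
    """
    if not 0.0 < quantile < 1.0:
        raise ParameterError("quantile must lie strictly between 0 and 1")
    tmean = fld.magnitude.mean(axis=-1)
    lo, hi = float(tmean.min()), float(tmean.max())
    if hi - lo < 1e-12:
        warnings.warn("constant magnitude image: noise mask keeps every voxel")
        return np.ones(tmean.shape, dtype=bool)
    return tmean >= np.quantile(tmean, quantile)


def detect_static_tissue(fld: VelocityField4D, std_quantile: float = 0.2) -> np.ndarray:
    """Heuristic static-tissue mask for background phase estimation.

    Static voxels show little velocity fluctuation over the cycle but must
    carry real signal, so the mask takes voxels whose temporal speed
    standard deviation is below ``std_quantile`` of its distribution while
    the time-mean magnitude sits above the noise floor (5th percentile).
    """
    speed_std = fld.speed().std(axis=-1)
    tmean_mag = fld.magnitude.mean(axis=-1)
    return (speed_std <= np.quantile(speed_std, std_quantile)) & (
        tmean_mag > np.quantile(tmean_mag, 0.05)
    )


def correct_eddy(
    fld: VelocityField4D, static_mask: np.ndarray | None = None
) -> VelocityField4D:
    """Remove spatially linear background velocity offsets.

    Per component, an offset ``a + b*x + c*y + d*z`` (world mm) is fitted by
    least squares to the temporal-mean velocity over static-tissue voxels
    and subtracted from every frame. With fewer than 10 static voxels the
    correction is skipped with a warning.
    """
    if static_mask is None:
        static_mask = detect_static_tissue(fld)
    static_mask = np.asarray(static_mask, bool)
    if static_mask.shape != fld.grid_shape:
        raise DataError("static mask shape does not match the field grid")
    n_static = int(static_mask.sum())
    if n_static < 10:
        warnings.warn(
            f"only {n_static} static voxels: eddy-current correction skipped"
        )
        return fld.copy_with(meta={"eddy_corrected": False})

    coords = fld.voxel_centers(static_mask)  # (n, 3) mm
    design = np.column_stack([np.ones(len(coords)), coords])
    tmean = fld.velocity.mean(axis=3)  # (nx,ny,nz,3)
    coef, *_ = np.linalg.lstsq(design, tmean[static_mask], rcond=None)  # (4, 3)

    all_coords = fld.voxel_centers()
    all_design = np.concatenate([np.ones(all_coords.shape[:3] + (1,)), all_coords], axis=-1)
    offset = np.einsum("xyzk,kc->xyzc", all_design, coef)
    corrected = fld.velocity - offset[:, :, :, None, :]
    residual = float(np.abs(corrected.mean(axis=3)[static_mask]).mean())
    log.info("eddy correction: %d static voxels, residual %.2e m/s", n_static, residual)
    return fld.copy_with(
        velocity=corrected,
        meta={"eddy_corrected": True, "eddy_residual_m_per_s": residual},
    )


def unwrap_velocity(fld: VelocityField4D) -> VelocityField4D:
    """Temporal phase unwrapping of each voxel's velocity-time course.

    Frame-to-frame jumps larger than venc are treated as wraps and undone
    by adding multiples of 2*venc (period unwrapping along the time axis).
    Velocities up to 3*venc in magnitude are recovered exactly when at most
    one wrap occurs per jump and the first frame is alias-free. Voxels
    whose unwrapped speed exceeds 3*venc are counted in
    ``meta['unwrap_qc_voxels']`` as potentially irresolvable.
    """
    unwrapped = np.unwrap(fld.velocity, axis=3, period=2.0 * fld.venc)
    qc = int(np.any(np.abs(unwrapped) > 3.0 * fld.venc, axis=(3, 4)).sum())
    if qc:
        log.warning("unwrap: %d voxels exceed 3*venc after unwrapping", qc)
    return fld.copy_with(velocity=unwrapped, meta={"unwrap_qc_voxels": qc})


def correct_maxwell(fld: VelocityField4D) -> VelocityField4D:
    """Placeholder for concomitant-gradient (Maxwell term) correction.

    The correction needs the sequence gradient waveforms, which are not
    part of the field representation; the data pass through unchanged and
    the omission is recorded in the provenance metadata.
    """
    log.warning("Maxwell-term correction not applicable: requires sequence gradient data")
    return fld.copy_with(meta={"maxwell_corrected": False})
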