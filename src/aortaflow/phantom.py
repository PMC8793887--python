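"""Ground-truthed synthetic 4D-flow phantoms and synthetic cohort tables.

Two geometries are provided: a straight tube and an aorta-like "candy cane"
(ascending limb, semicircular arch, descending limb). Inside the lumen the
velocity follows a pulsatile Poiseuille (parabolic) profile directed along
the local centerline tangent,

    v(r, t) = 2 * Vbar(t) * (1 - (r/R)^2) * tangent,

where ``Vbar(t)`` is the mean cross-sectional velocity waveform and ``R``
the lumen radius, so the instantaneous volumetric flow rate at every
station is ``Q(t) = Vbar(t) * pi * R^2``. Optional additions: an azimuthal
swirl component (helical flow), Gaussian velocity noise, venc phase
wrapping, and smooth linear background-phase offsets mimicking residual
eddy-current phase errors.

The generator returns exact analytic ground truth (centerline, per-station
flow rate, per-voxel stasis and cycle-summed kinetic energy, lumen mask)
for use as an oracle in tests of the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .constants import DEFAULT_CONSTANTS, REGIONS
from .errors import GeometryError, ParameterError
from .field import VelocityField4D

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "default_waveform",
    "generate",
    "generate_straight_tube",
    "generate_candy_cane",
    "inject_aliasing",
    "inject_eddy_offset",
    "synth_cohort",
    "DEFAULT_COHORT_STATS",
]

#: Fraction of the centerline arc span at which the four region boundaries
#: (LVOT|AAo, AAo|Arch, Arch|PDAo, PDAo|DDAo) sit by default.
DEFAULT_BOUNDARY_FRACTIONS = (0.10, 0.45, 0.60, 0.80)

_FINE_STEP = 0.25  # mm, internal centerline discretisation


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom acquisition.

    Defaults mimic a clinical thoracic-aorta 4D-flow protocol: ~2.4 mm
    acquired voxels (deliberately coarser than the 1 mm analysis grid so
    the isotropic re-interpolation step is exercised), 20 cardiac frames
    over a 1000 ms cycle, venc 1.5 m/s.
    """

    geometry: Literal["straight-tube", "candy-cane"] = "candy-cane"
    radius: float = 10.0  #: lumen radius, mm
    length: float = 120.0  #: straight-tube centerline length, mm
    arch_radius: float = 30.0  #: candy-cane arch radius, mm
    ascending_length: float = 50.0  #: candy-cane ascending limb, mm
    descending_length: float = 60.0  #: candy-cane descending limb, mm
    spacing: tuple[float, float, float] = (2.4, 2.4, 2.4)  #: voxel size, mm
    n_frames: int = 20
    cycle_duration: float = 1000.0  #: ms
    waveform: np.ndarray | None = None  #: mean cross-sectional velocity per frame, m/s (signed)
    peak_mean_velocity: float = 0.5  #: systolic peak of the default waveform, m/s
    retrograde_fraction: float = 0.0  #: fraction of flow reversed, in [0, 1]
    swirl_amplitude: float = 0.0  #: peak azimuthal speed at the wall, m/s
    noise_sigma: float = 0.0  #: Gaussian velocity noise, m/s
    venc: float = 1.5  #: velocity-encoding limit, m/s
    seed: int = 0
    margin: float = 12.0  #: padding between lumen and grid edge, mm

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("lumen radius must be positive")
        if self.n_frames < 2:
            raise ParameterError("need at least 2 cardiac frames")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("grid spacing must be positive")
        if not 0.0 <= self.retrograde_fraction <= 1.0:
            raise ParameterError("retrograde_fraction must lie in [0, 1]")
        if self.venc <= 0:
            raise ParameterError("venc must be positive")
        if self.cycle_duration <= 0:
            raise ParameterError("cycle_duration must be positive")
        if self.geometry == "candy-cane" and self.arch_radius < 2 * self.radius:
            raise GeometryError(
                "arch radius %.1f mm < 2x lumen radius %.1f mm: the arch would "
                "self-intersect" % (self.arch_radius, self.radius)
            )

    @property
    def frame_duration(self) -> float:
        return self.cycle_duration / self.n_frames


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom.

    Stasis and kinetic energy are evaluated on the noiseless velocity field
    at the acquisition grid; the flow rate is the exact cross-sectional
    integral ``Vbar(t) * pi * R^2`` at every centerline station (mL/s).
    """

    centerline_points: np.ndarray  #: (n, 3) mm, ~1 mm arc steps
    centerline_tangents: np.ndarray  #: (n, 3) unit vectors
    arc_length: np.ndarray  #: (n,) cumulative mm
    flow_rate: np.ndarray  #: (n, n_frames) mL/s
    stasis: np.ndarray  #: (nx, ny, nz) percent, NaN outside lumen
    kinetic_energy: np.ndarray  #: (nx, ny, nz) cycle-summed uJ, NaN outside lumen
    mask: np.ndarray  #: (nx, ny, nz) bool lumen mask
    region_boundaries: np.ndarray  #: four arc lengths (mm) splitting the five regions
    peak_speed: float  #: true maximum speed anywhere in the lumen, m/s
    mean_velocity_waveform: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        inside = self.stasis[self.mask]
        if inside.size == 0:
            raise GeometryError("phantom lumen mask is empty")
        assert np.all((inside >= 0) & (inside <= 100))
        assert np.all(self.kinetic_energy[self.mask] >= 0)


def default_waveform(
    n_frames: int,
    peak: float = 0.5,
    systole_fraction: float = 0.35,
    retro_lobe: float = 0.1,
    retro_fraction_of_cycle: float = 0.15,
) -> np.ndarray:
    """Aorta-like mean-velocity waveform sampled at frame centers.

    A half-sine systolic lobe occupies the first ``systole_fraction`` of the
    cycle, followed by a small negative (early-diastolic backflow) lobe of
    relative amplitude ``retro_lobe``, then zero flow for the rest of
    diastole.
    """
    t = (np.arange(n_frames) + 0.5) / n_frames
    w = np.zeros(n_frames)
    sys_mask = t < systole_fraction
    w[sys_mask] = peak * np.sin(np.pi * t[sys_mask] / systole_fraction)
    retro = (t >= systole_fraction) & (t < systole_fraction + retro_fraction_of_cycle)
    w[retro] = -retro_lobe * peak * np.sin(
        np.pi * (t[retro] - systole_fraction) / retro_fraction_of_cycle
    )
    return w


def _effective_waveform(spec: PhantomSpec) -> np.ndarray:
    """Signed mean cross-sectional velocity per frame, m/s.

    The retrograde fraction ``f`` mixes the forward waveform with its
    mirror image: ``(1 - f) * w - f * w = (1 - 2 f) * w``, so ``f = 0``
    leaves the waveform untouched and ``f = 1`` reverses the flow exactly.
    """
    if spec.waveform is not None:
        w = np.asarray(spec.waveform, dtype=float)
        if w.shape != (spec.n_frames,):
            raise ParameterError(
                f"waveform must have one value per frame ({spec.n_frames}), got {w.shape}"
            )
    else:
        w = default_waveform(spec.n_frames, peak=spec.peak_mean_velocity)
    return (1.0 - 2.0 * spec.retrograde_fraction) * w


# ---------------------------------------------------------------------------
# centerline construction


def _straight_centerline(spec: PhantomSpec):
    c = spec.margin + spec.radius
    s = np.arange(0.0, spec.length + _FINE_STEP / 2, _FINE_STEP)
    pts = np.column_stack([np.full_like(s, c), np.full_like(s, c), s + spec.margin])
    tan = np.tile([0.0, 0.0, 1.0], (len(s), 1))
    extent = (2 * c, 2 * c, spec.length + 2 * spec.margin)
    return pts, tan, extent


def _candy_centerline(spec: PhantomSpec):
    """Ascending limb (+z), semicircular arch in the x-z plane, descending limb (-z)."""
    R, L_asc, L_desc = spec.arch_radius, spec.ascending_length, spec.descending_length
    m = spec.margin + spec.radius
    cx = m + R  # arch center x
    cy = m
    z0 = m  # base of ascending limb

    s_asc = np.arange(0.0, L_asc, _FINE_STEP)
    p_asc = np.column_stack([np.full_like(s_asc, m), np.full_like(s_asc, cy), z0 + s_asc])
    t_asc = np.tile([0.0, 0.0, 1.0], (len(s_asc), 1))

    arch_len = np.pi * R
    s_arch = np.arange(0.0, arch_len, _FINE_STEP)
    theta = s_arch / R  # 0 at ascending side, pi at descending side
    p_arch = np.column_stack(
        [cx - R * np.cos(theta), np.full_like(theta, cy), z0 + L_asc + R * np.sin(theta)]
    )
    t_arch = np.column_stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)])

    s_desc = np.arange(0.0, L_desc + _FINE_STEP / 2, _FINE_STEP)
    p_desc = np.column_stack(
        [np.full_like(s_desc, cx + R), np.full_like(s_desc, cy), z0 + L_asc - s_desc]
    )
    t_desc = np.tile([0.0, 0.0, -1.0], (len(s_desc), 1))

    pts = np.vstack([p_asc, p_arch, p_desc])
    tan = np.vstack([t_asc, t_arch, t_desc])
    extent = (2 * m + 2 * R, 2 * m, z0 + L_asc + R + spec.radius + spec.margin)
    return pts, tan, extent


def _resample_polyline(pts: np.ndarray, tan: np.ndarray, step: float = 1.0):
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_new = np.arange(0.0, s[-1] + step / 2, step)
    out_p = np.column_stack([np.interp(s_new, s, pts[:, i]) for i in range(3)])
    out_t = np.column_stack([np.interp(s_new, s, tan[:, i]) for i in range(3)])
    out_t /= np.linalg.norm(out_t, axis=1, keepdims=True)
    return out_p, out_t, s_new


# ---------------------------------------------------------------------------
# field synthesis


def generate(spec: PhantomSpec) -> tuple[VelocityField4D, PhantomTruth]:
    """Generate a phantom according to ``spec.geometry``."""
    if spec.geometry == "straight-tube":
        return generate_straight_tube(spec)
    if spec.geometry == "candy-cane":
        return generate_candy_cane(spec)
    raise ParameterError(f"unknown geometry {spec.geometry!r}")


def generate_straight_tube(spec: PhantomSpec) -> tuple[VelocityField4D, PhantomTruth]:
    """Pulsatile Poiseuille flow in a straight tube along +z."""
    if spec.geometry != "straight-tube":
        raise ParameterError("spec.geometry must be 'straight-tube'")
    pts, tan, extent = _straight_centerline(spec)
    return _generate_from_centerline(spec, pts, tan, extent)


def generate_candy_cane(spec: PhantomSpec) -> tuple[VelocityField4D, PhantomTruth]:
    """Pulsatile Poiseuille flow in an aorta-like candy-cane geometry."""
    if spec.geometry != "candy-cane":
        raise ParameterError("spec.geometry must be 'candy-cane'")
    pts, tan, extent = _candy_centerline(spec)
    return _generate_from_centerline(spec, pts, tan, extent)


def _generate_from_centerline(spec, fine_pts, fine_tan, extent):
    shape = tuple(int(np.ceil(e / sp)) + 1 for e, sp in zip(extent, spec.spacing))
    idx = np.indices(shape, dtype=float)
    coords = np.stack([idx[i] * spec.spacing[i] for i in range(3)], axis=-1)
    flat = coords.reshape(-1, 3)

    tree = cKDTree(fine_pts)
    dist, nearest = tree.query(flat, workers=-1)
    dist = dist.reshape(shape)
    nearest = nearest.reshape(shape)

    mask = dist <= spec.radius
    if not mask.any():
        raise GeometryError("lumen mask empty: grid does not cover the tube")

    vbar = _effective_waveform(spec)  # (nt,)
    nt = spec.n_frames
    profile = np.where(mask, 2.0 * (1.0 - (dist / spec.radius) ** 2), 0.0)
    axial_dir = fine_tan[nearest]  # (nx,ny,nz,3)

    # axial Poiseuille term: profile * vbar(t) * tangent
    velocity = (
        profile[..., None, None] * vbar[None, None, None, :, None] * axial_dir[..., None, :]
    )

    swirl_speed = np.zeros(shape)
    if spec.swirl_amplitude != 0.0:
        radial = flat.reshape(shape + (3,)) - fine_pts[nearest]
        rnorm = np.linalg.norm(radial, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            radial_u = np.where(rnorm[..., None] > 1e-12, radial / rnorm[..., None], 0.0)
        e_phi = np.cross(axial_dir, radial_u)
        envelope = vbar / max(np.max(np.abs(vbar)), 1e-12)  # swirl pulses with the cycle
        swirl_speed = np.where(mask, spec.swirl_amplitude * dist / spec.radius, 0.0)
        velocity += (
            swirl_speed[..., None, None] * envelope[None, None, None, :, None] * e_phi[..., None, :]
        )

    # ground truth from the noiseless field
    axial_speed = np.abs(profile[..., None] * vbar[None, None, None, :])
    if spec.swirl_amplitude != 0.0:
        envelope = vbar / max(np.max(np.abs(vbar)), 1e-12)
        true_speed = np.sqrt(
            axial_speed**2 + (swirl_speed[..., None] * envelope[None, None, None, :]) ** 2
        )
    else:
        true_speed = axial_speed
    thr = DEFAULT_CONSTANTS.stasis_threshold
    stasis = 100.0 * np.mean(true_speed < thr, axis=-1)
    ke = 1e6 * np.sum(
        0.5 * DEFAULT_CONSTANTS.blood_density * DEFAULT_CONSTANTS.voxel_volume * true_speed**2,
        axis=-1,
    )
    stasis = np.where(mask, stasis, np.nan)
    ke = np.where(mask, ke, np.nan)
    peak_speed = float(np.nanmax(np.where(mask[..., None], true_speed, np.nan)))

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        velocity = velocity + rng.normal(0.0, spec.noise_sigma, velocity.shape)

    magnitude = np.where(mask, 1.0, 0.1)[..., None] * np.ones((1, 1, 1, nt))
    if spec.noise_sigma > 0:
        magnitude = np.abs(magnitude + rng.normal(0.0, spec.noise_sigma, magnitude.shape))

    fld = VelocityField4D(
        velocity=velocity,
        magnitude=magnitude,
        spacing=spec.spacing,
        frame_duration=spec.frame_duration,
        venc=spec.venc,
        meta={"phantom_geometry": spec.geometry, "seed": spec.seed},
    )

    cl_pts, cl_tan, cl_s = _resample_polyline(fine_pts, fine_tan, step=1.0)
    area_mm2 = np.pi * spec.radius**2
    q = vbar * area_mm2  # m/s * mm^2 = 1e-6 m^3/s = 1 mL/s per unit
    flow_rate = np.tile(q, (len(cl_s), 1))
    boundaries = cl_s[-1] * np.asarray(DEFAULT_BOUNDARY_FRACTIONS)

    truth = PhantomTruth(
        centerline_points=cl_pts,
        centerline_tangents=cl_tan,
        arc_length=cl_s,
        flow_rate=flow_rate,
        stasis=stasis,
        kinetic_energy=ke,
        mask=mask,
        region_boundaries=boundaries,
        peak_speed=peak_speed,
        mean_velocity_waveform=vbar,
    )
    return fld, truth


# ---------------------------------------------------------------------------
# artifact injection


def inject_aliasing(fld: VelocityField4D) -> VelocityField4D:
    """Phase-wrap velocities to the interval (-venc, venc].

    Applies ``v -> venc - ((venc - v) mod 2 venc)`` per component; values
    already within ``(-venc, venc]`` are unchanged, so the operation is
    idempotent.
    """
    venc = fld.venc
    wrapped = venc - np.mod(venc - fld.velocity, 2.0 * venc)
    return fld.copy_with(velocity=wrapped)


def inject_eddy_offset(fld: VelocityField4D, plane_coefficients: np.ndarray) -> VelocityField4D:
    """Add a time-constant, spatially linear velocity offset per component.

    ``plane_coefficients`` has shape (3, 4): for component ``c`` the offset
    is ``a + b*x + c*y + d*z`` with world coordinates in mm and the
    coefficients in m/s (``a``) and m/s per mm (``b, c, d``). This mimics
    residual background phase from eddy currents.
    """
    coef = np.asarray(plane_coefficients, dtype=float)
    if coef.shape != (3, 4):
        raise ParameterError(f"plane_coefficients must have shape (3, 4), got {coef.shape}")
    if not np.all(np.isfinite(coef)):
        raise ParameterError("plane_coefficients must be finite")
    coords = fld.voxel_centers()  # (nx,ny,nz,3)
    design = np.concatenate([np.ones(coords.shape[:3] + (1,)), coords], axis=-1)
    offset = np.einsum("xyzk,ck->xyzc", design, coef)  # (nx,ny,nz,3)
    return fld.copy_with(velocity=fld.velocity + offset[:, :, :, None, :])


# ---------------------------------------------------------------------------
# synthetic cohort tables

#: Per-group (mean, sd) of each regional hemodynamic parameter used by
#: :func:`synth_cohort` when no explicit statistics are supplied. The values
#: are at the scale reported for BAV patients versus healthy controls in
#: clinical 4D-flow cohorts.
DEFAULT_COHORT_STATS: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "control": {
        ("LVOT", "diameter"): (28, 5), ("AAo", "diameter"): (28, 4),
        ("Arch", "diameter"): (25, 3), ("PDAo", "diameter"): (20, 3),
        ("DDAo", "diameter"): (18, 3),
        ("LVOT", "indexed_diameter"): (15, 2), ("AAo", "indexed_diameter"): (15, 3),
        ("Arch", "indexed_diameter"): (13, 2), ("PDAo", "indexed_diameter"): (11, 2),
        ("DDAo", "indexed_diameter"): (10, 2),
        ("LVOT", "peak_velocity"): (1.3, 0.2), ("AAo", "peak_velocity"): (1.5, 0.3),
        ("Arch", "peak_velocity"): (1.2, 0.2), ("PDAo", "peak_velocity"): (1.2, 0.3),
        ("DDAo", "peak_velocity"): (1.4, 0.4),
        ("LVOT", "ke"): (1.9, 0.5), ("AAo", "ke"): (1.8, 0.6),
        ("Arch", "ke"): (1.5, 0.6), ("PDAo", "ke"): (1.8, 0.7),
        ("DDAo", "ke"): (2.0, 0.9),
        ("LVOT", "ff"): (0.18, 0.04), ("AAo", "ff"): (0.18, 0.04),
        ("Arch", "ff"): (0.17, 0.04), ("PDAo", "ff"): (0.19, 0.05),
        ("DDAo", "ff"): (0.22, 0.07),
        ("LVOT", "rf"): (0.025, 0.01), ("AAo", "rf"): (0.011, 0.001),
        ("Arch", "rf"): (0.010, 0.006), ("PDAo", "rf"): (0.010, 0.01),
        ("DDAo", "rf"): (0.005, 0.004),
        ("LVOT", "stasis"): (33, 9), ("AAo", "stasis"): (50, 10),
        ("Arch", "stasis"): (52, 10), ("PDAo", "stasis"): (53, 10),
        ("DDAo", "stasis"): (43, 13),
    },
    "BAV": {
        ("LVOT", "diameter"): (29, 4), ("AAo", "diameter"): (40, 7),
        ("Arch", "diameter"): (26, 5), ("PDAo", "diameter"): (23, 4),
        ("DDAo", "diameter"): (20, 3),
        ("LVOT", "indexed_diameter"): (14, 2), ("AAo", "indexed_diameter"): (20, 4),
        ("Arch", "indexed_diameter"): (13, 3), ("PDAo", "indexed_diameter"): (11, 2),
        ("DDAo", "indexed_diameter"): (10, 2),
        ("LVOT", "peak_velocity"): (1.9, 1.0), ("AAo", "peak_velocity"): (2.6, 1.2),
        ("Arch", "peak_velocity"): (1.5, 0.8), ("PDAo", "peak_velocity"): (1.3, 0.8),
        ("DDAo", "peak_velocity"): (1.2, 0.5),
        ("LVOT", "ke"): (2.6, 1.8), ("AAo", "ke"): (2.3, 1.2),
        ("Arch", "ke"): (1.7, 1.0), ("PDAo", "ke"): (1.7, 1.1),
        ("DDAo", "ke"): (1.6, 0.9),
        ("LVOT", "ff"): (0.15, 0.06), ("AAo", "ff"): (0.12, 0.03),
        ("Arch", "ff"): (0.14, 0.04), ("PDAo", "ff"): (0.16, 0.05),
        ("DDAo", "ff"): (0.17, 0.05),
        ("LVOT", "rf"): (0.045, 0.05), ("AAo", "rf"): (0.039, 0.02),
        ("Arch", "rf"): (0.029, 0.02), ("PDAo", "rf"): (0.019, 0.02),
        ("DDAo", "rf"): (0.015, 0.025),
        ("LVOT", "stasis"): (22, 12), ("AAo", "stasis"): (23, 11),
        ("Arch", "stasis"): (32, 16), ("PDAo", "stasis"): (35, 18),
        ("DDAo", "stasis"): (38, 17),
    },
}

_POSITIVE_PARAMS = {"ke", "ff", "rf", "peak_velocity", "diameter", "indexed_diameter"}

_DEMOGRAPHICS = {
    # (age_mean, age_sd, bsa_mean, bsa_sd, female_fraction)
    "control": (37, 14, 1.9, 0.3, 8 / 23),
    "BAV": (49, 16, 2.0, 0.3, 21 / 73),
}

_VALVE_TYPES = ("0", "1-RL", "1-RN", "2", "unknown")
_VALVE_PROBS = (19 / 73, 36 / 73, 11 / 73, 4 / 73, 3 / 73)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def synth_cohort(
    n_per_group: dict[str, int] | int,
    group_stats: dict | None = None,
    seed: int = 0,
    surgery_fraction: float = 24 / 73,
):
    """Draw a subject-level cohort table with the requested group separation.

    Parameters
    ----------
    n_per_group:
        Mapping group label -> subject count, or a single count used for
        every group in ``group_stats``.
    group_stats:
        ``{group: {(region, parameter): (mean, sd)}}``; defaults to
        :data:`DEFAULT_COHORT_STATS` (control vs BAV at clinical scale).
    seed:
        Seed for the single random generator used for all draws.

    Strictly positive parameters (KE, FF, RF, peak velocity, diameters) are
    drawn log-normal with moments matched to the requested mean/sd so no
    negative values can occur; stasis is drawn normal and clipped to
    [0, 100].

    Returns a :class:`pandas.DataFrame` with one row per subject and
    columns ``{region}_{parameter}`` plus demographics.
    """
    import pandas as pd

    stats = DEFAULT_COHORT_STATS if group_stats is None else group_stats
    if isinstance(n_per_group, int):
        if n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        n_per_group = {g: n_per_group for g in stats}
    if any(n < 2 for n in n_per_group.values()):
        raise ParameterError("every group needs at least 2 subjects")
    for g, params in stats.items():
        for key, (m, s) in params.items():
            if s < 0:
                raise ParameterError(f"negative sd for {g}/{key}")

    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group, n in n_per_group.items():
        params = stats[group]
        age_m, age_s, bsa_m, bsa_s, female_frac = _DEMOGRAPHICS.get(
            group, (48, 15, 1.95, 0.3, 0.3)
        )
        for _ in range(n):
            row = {
                "subject_id": f"S{sid:04d}",
                "cohort": group,
                "age": float(np.clip(rng.normal(age_m, age_s), 18, None)),
                "sex": "F" if rng.random() < female_frac else "M",
                "bsa": float(np.clip(rng.normal(bsa_m, bsa_s), 1.2, None)),
                "valve_type": (
                    "tricuspid"
                    if group == "control"
                    else str(rng.choice(_VALVE_TYPES, p=_VALVE_PROBS))
                ),
                "surgery": bool(group != "control" and rng.random() < surgery_fraction),
            }
            for (region, param), (m, s) in params.items():
                if param in _POSITIVE_PARAMS and m > 0 and s > 0:
                    mu, sig = _lognormal_params(m, s)
                    val = float(rng.lognormal(mu, sig))
                elif s == 0:
                    val = float(m)
                else:
                    val = float(rng.normal(m, s))
                    if param == "stasis":
                        val = float(np.clip(val, 0.0, 100.0))
                row[f"{region}_{param}"] = val
            rows.append(row)
            sid += 1
    table = pd.DataFrame(rows)
    # dilation class from the maximum ascending-aorta diameter, when present
    if "AAo_diameter" in table.columns:
        from .geometry import classify_dilation

        table["dilation_class"] = table["AAo_diameter"].map(classify_dilation)
    return table
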