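"""Vessel geometry: centerline extraction, nearest-plane voxel matching,
region partitioning, diameters, and body-surface-area indexing.

The centerline is obtained by 3D thinning of the lumen mask, taking the
longest endpoint-to-endpoint geodesic through the skeleton, smoothing it
with a cubic spline, and resampling at 1 mm arc-length steps. Every lumen
voxel is then matched to the centerline point minimizing the Euclidean
distance ("nearest plane"), which defines the local downstream direction
for forward/reverse flow and the voxel's region membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .constants import REGIONS
from .errors import DataError, GeometryError, ParameterError

__all__ = [
    "Centerline",
    "VoxelPlaneAssignment",
    "RegionLabels",
    "AorticGeometryReport",
    "extract_centerline",
    "assign_voxels",
    "split_regions",
    "measure_diameters",
    "station_diameters",
    "bsa",
    "index_diameter",
    "classify_dilation",
]


@dataclass
class Centerline:
    """Ordered centerline with unit tangents and cumulative arc length (mm)."""

    points: np.ndarray  #: (n, 3) world mm
    tangents: np.ndarray  #: (n, 3) unit vectors
    arc_length: np.ndarray  #: (n,) cumulative mm, strictly increasing

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.tangents = np.asarray(self.tangents, float)
        self.arc_length = np.asarray(self.arc_length, float)
        if len(self.points) < 2:
            raise GeometryError("centerline needs at least two points")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise GeometryError("centerline tangents must be unit vectors")
        if np.any(np.diff(self.arc_length) <= 0):
            raise GeometryError("arc length must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def span(self) -> float:
        """Total arc length in mm."""
        return float(self.arc_length[-1] - self.arc_length[0])


@dataclass
class VoxelPlaneAssignment:
    """Nearest-plane match for every lumen voxel."""

    mask: np.ndarray  #: boolean lumen grid
    voxel_index: np.ndarray  #: (n, 3) integer grid indices of masked voxels
    point_index: np.ndarray  #: (n,) matched centerline point per voxel
    axial_distance: np.ndarray  #: (n,) signed distance along the tangent, mm

    def point_index_grid(self) -> np.ndarray:
        """Matched point index as a grid (-1 outside the mask)."""
        grid = np.full(self.mask.shape, -1, dtype=int)
        grid[tuple(self.voxel_index.T)] = self.point_index
        return grid


@dataclass
class RegionLabels:
    """Per-voxel region labels plus the four boundary arc lengths."""

    labels: np.ndarray  #: integer grid, -1 outside mask, else index into REGIONS
    boundaries: np.ndarray  #: four arc lengths (mm), strictly increasing
    names: tuple[str, ...] = REGIONS

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == self.names.index(region)


@dataclass
class AorticGeometryReport:
    """Per-region diameters with body-size indexing and dilation class."""

    diameters: dict[str, float]  #: mm, per region (max over stations)
    indexed_diameters: dict[str, float]  #: mm/m^2
    dilation_class: str
    bsa_m2: float
    diameter_convention: str = "effective (2*sqrt(area/pi))"


# ---------------------------------------------------------------------------
# centerline extraction


def _skeleton_graph(skel: np.ndarray, spacing: np.ndarray) -> nx.Graph:
    coords = np.argwhere(skel)
    index = {tuple(c): i for i, c in enumerate(coords)}
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    offsets = np.array(
        [d for d in np.ndindex(3, 3, 3) if d != (1, 1, 1)]
    ) - 1
    for i, c in enumerate(coords):
        for off in offsets:
            j = index.get(tuple(c + off))
            if j is not None and j > i:
                g.add_edge(i, j, weight=float(np.linalg.norm(off * spacing)))
    return g, coords


def extract_centerline(
    mask: np.ndarray,
    spacing,
    origin=(0.0, 0.0, 0.0),
    step: float = 1.0,
    smoothing: float | None = None,
) -> Centerline:
    """Extract a smooth 1 mm-resampled centerline from a tubular mask.

    Pipeline: 3D thinning -> longest endpoint-to-endpoint geodesic ->
    cubic smoothing spline -> arc-length resampling at ``step`` mm, with
    tangents from central differences on the smoothed curve. The mask must
    be one 26-connected, loop-free component; anything else raises
    :class:`GeometryError` naming the defect.
    """
    mask = np.asarray(mask, bool)
    spacing = np.asarray(spacing, float)
    if not mask.any():
        raise DataError("empty mask")
    n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3)))[1]
    if n_comp != 1:
        raise GeometryError(f"mask has {n_comp} connected components, expected 1")

    skel = skeletonize(mask)
    if skel.sum() < 4:
        raise GeometryError("skeleton too short: mask is not tube-shaped")
    g, coords = _skeleton_graph(skel, spacing)

    # tolerate small thinning artifacts but reject genuine loops
    cycles = nx.cycle_basis(g)
    for cyc in cycles:
        length = sum(
            g[u][v]["weight"]
            for u, v in zip(cyc, cyc[1:] + cyc[:1])
            if g.has_edge(u, v)
        )
        if length > 10.0 * float(spacing.mean()):
            raise GeometryError("mask contains a loop: centerline is ambiguous")
    tree = nx.minimum_spanning_tree(g)

    # longest geodesic via double Dijkstra from any leaf
    leaves = [n for n, d in tree.degree() if d == 1]
    if len(leaves) < 2:
        raise GeometryError("skeleton has no endpoints: mask is not tube-shaped")
    dist = nx.single_source_dijkstra_path_length(tree, leaves[0], weight="weight")
    u = max(dist, key=dist.get)
    dist_u, paths_u = nx.single_source_dijkstra(tree, u, weight="weight")
    v = max(dist_u, key=dist_u.get)
    path = paths_u[v]
    if len(path) < 4:
        raise GeometryError("skeleton path too short for spline fitting")

    pts = coords[path] * spacing + np.asarray(origin, float)

    if smoothing is None:
        # residual budget ~ half a voxel per point
        smoothing = len(pts) * float((0.5 * spacing.mean()) ** 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tck, _ = splprep(pts.T, s=smoothing, k=3)
    u_dense = np.linspace(0.0, 1.0, max(10 * len(pts), 200))
    dense = np.column_stack(splev(u_dense, tck))

    # the thinning skeleton stops short of the tube ends: extend along the
    # end tangents while still inside the mask
    dense = _extend_into_mask(dense, mask, spacing, np.asarray(origin, float))

    points, tangents, s_new = _resample_curve(dense, step)

    # polish: snap each station to the centroid of its normal-plane lumen
    # cross-section, which removes the skeleton's lattice bias
    for _ in range(2):
        points = _snap_to_cross_section_centroids(
            points, tangents, mask, spacing, np.asarray(origin, float)
        )
        points, tangents, s_new = _resample_curve(points, step)
    return Centerline(points=points, tangents=tangents, arc_length=s_new)


def _resample_curve(pts: np.ndarray, step: float):
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    keep = np.concatenate([[True], seg > 1e-9])
    s, pts = s[keep], pts[keep]
    s_new = np.arange(0.0, s[-1] + step / 2, step)
    points = np.column_stack([np.interp(s_new, s, pts[:, i]) for i in range(3)])
    tangents = np.gradient(points, s_new, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return points, tangents, s_new


def _plane_basis(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, t)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(t, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return e1, e2


def _snap_to_cross_section_centroids(
    points, tangents, mask, spacing, origin, plane_radius: float = 25.0, plane_step: float = 0.5
):
    maskf = np.asarray(mask, float)
    r = np.arange(-plane_radius, plane_radius + plane_step / 2, plane_step)
    uu, vv = np.meshgrid(r, r, indexing="ij")
    out = points.copy()
    for i, (p, t) in enumerate(zip(points, tangents)):
        e1, e2 = _plane_basis(t)
        pts = p[None, None, :] + uu[..., None] * e1[None, None, :] + vv[..., None] * e2[None, None, :]
        idx = (pts - origin) / spacing
        inside = (
            ndimage.map_coordinates(
                maskf, idx.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
            ).reshape(uu.shape)
            >= 0.5
        )
        if inside.sum() < 3:
            continue
        du = float(uu[inside].mean())
        dv = float(vv[inside].mean())
        out[i] = p + du * e1 + dv * e2
    return out


def flip_centerline(cl: Centerline) -> Centerline:
    """Reverse the traversal direction of a centerline."""
    arc = cl.arc_length[-1] - cl.arc_length[::-1]
    return Centerline(points=cl.points[::-1].copy(), tangents=-cl.tangents[::-1], arc_length=arc)


def orient_centerline(cl: Centerline, start_near) -> Centerline:
    """Orient a centerline so it starts at the end closest to ``start_near``.

    The downstream direction is anatomical information (the line must run
    LVOT -> DDAo); callers that know the inlet position use this helper,
    others can orient by net flow (see the pipeline).
    """
    start_near = np.asarray(start_near, float)
    d0 = np.linalg.norm(cl.points[0] - start_near)
    d1 = np.linalg.norm(cl.points[-1] - start_near)
    return flip_centerline(cl) if d1 < d0 else cl


def _inside(mask: np.ndarray, spacing: np.ndarray, origin: np.ndarray, p: np.ndarray) -> bool:
    idx = np.rint((p - origin) / spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= mask.shape):
        return False
    return bool(mask[tuple(idx)])


def _extend_into_mask(dense, mask, spacing, origin, max_extend: float = 40.0):
    """Linearly extend both curve ends while the extension stays in the mask.

    The extension stops one step before leaving the lumen; for rounded
    (capped) tube ends it is additionally limited by the shrinking distance
    to the lumen boundary so it does not run into the cap apex.
    """
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    maskf = mask.astype(float)
    step = 0.25 * float(spacing.min())

    def _sample(vol, p):
        idx = (np.asarray(p) - origin) / spacing
        return float(
            ndimage.map_coordinates(vol, idx[:, None], order=1, mode="constant", cval=0.0)[0]
        )

    out = dense
    for end in (0, -1):
        # direction pointing outward at this end
        d = (out[0] - out[1]) if end == 0 else (out[-1] - out[-2])
        d = d / np.linalg.norm(d)
        tail = out[:8] if end == 0 else out[-8:]
        r_here = max(_sample(edt, q) for q in tail)
        # march to the lumen exit (cap apex), then pull back by the local
        # inscribed radius: for a rounded end the apex sits one radius
        # beyond the true centerline endpoint
        t_exit = 0.0
        while t_exit < max_extend and _sample(maskf, out[end] + (t_exit + step) * d) >= 0.5:
            t_exit += step
        # quarter-voxel safety margin: a slight undershoot costs a little
        # arc length, an overshoot bends the end off the true axis
        extend_len = t_exit - r_here - 0.25 * float(spacing.mean())
        n_ext = int(extend_len / step)
        if n_ext >= 1:
            ext_arr = out[end] + np.outer(np.arange(1, n_ext + 1) * step, d)
            out = np.vstack([ext_arr[::-1], out]) if end == 0 else np.vstack([out, ext_arr])
    return out


# ---------------------------------------------------------------------------
# voxel matching and regions


def assign_voxels(
    mask: np.ndarray,
    centerline: Centerline,
    spacing,
    origin=(0.0, 0.0, 0.0),
) -> VoxelPlaneAssignment:
    """Match every masked voxel to its nearest centerline point.

    Nearest is by 3D Euclidean distance between the voxel center and the
    centerline points; ties go to the lower (upstream) index.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise DataError("empty mask")
    spacing = np.asarray(spacing, float)
    vidx = np.argwhere(mask)
    centers = vidx * spacing + np.asarray(origin, float)

    tree = cKDTree(centerline.points)
    k = min(4, len(centerline.points))
    dists, idxs = tree.query(centers, k=k, workers=-1)
    if k == 1:
        dists, idxs = dists[:, None], idxs[:, None]
    # upstream-biased deterministic tie-break among numerically equal distances
    near_tie = dists <= dists[:, :1] + 1e-9
    point_index = np.where(near_tie, idxs, np.iinfo(np.int64).max).min(axis=1)

    delta = centers - centerline.points[point_index]
    axial = np.einsum("ij,ij->i", delta, centerline.tangents[point_index])
    return VoxelPlaneAssignment(
        mask=mask, voxel_index=vidx, point_index=point_index, axial_distance=axial
    )


def split_regions(
    centerline: Centerline,
    assignment: VoxelPlaneAssignment,
    boundaries,
) -> RegionLabels:
    """Partition the lumen into the five regions by arc length.

    ``boundaries`` are the four arc lengths (mm) separating
    LVOT | AAo | Arch | PDAo | DDAo; each voxel inherits the region of its
    matched centerline point.
    """
    boundaries = np.asarray(boundaries, float)
    if boundaries.shape != (4,):
        raise ParameterError("exactly four boundary arc lengths are required")
    if np.any(np.diff(boundaries) <= 0):
        raise ParameterError("boundaries must be strictly increasing")
    lo, hi = centerline.arc_length[0], centerline.arc_length[-1]
    if boundaries[0] <= lo or boundaries[-1] >= hi:
        raise ParameterError(
            f"boundaries {boundaries} outside the centerline arc span ({lo:.1f}, {hi:.1f}) mm"
        )
    point_region = np.searchsorted(boundaries, centerline.arc_length, side="right")
    labels = np.full(assignment.mask.shape, -1, dtype=int)
    labels[tuple(assignment.voxel_index.T)] = point_region[assignment.point_index]
    return RegionLabels(labels=labels, boundaries=boundaries)


def region_boundaries_from_fractions(centerline: Centerline, fractions) -> np.ndarray:
    """Convert span fractions (e.g. 0.10/0.45/0.60/0.80) to arc lengths."""
    fractions = np.asarray(fractions, float)
    return centerline.arc_length[0] + fractions * centerline.span


# ---------------------------------------------------------------------------
# diameters


def station_diameters(
    mask: np.ndarray,
    centerline: Centerline,
    spacing,
    origin=(0.0, 0.0, 0.0),
    max_radius: float = 30.0,
    plane_step: float = 0.5,
) -> np.ndarray:
    """Effective lumen diameter (mm) at every centerline station.

    The lumen cross-section is sampled on the plane normal to the local
    tangent and the effective circular diameter ``2*sqrt(area/pi)`` is
    returned; stations whose plane misses the lumen yield NaN.
    """
    mask = np.asarray(mask, float)
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)

    r = np.arange(-max_radius, max_radius + plane_step / 2, plane_step)
    uu, vv = np.meshgrid(r, r, indexing="ij")
    cell_area = plane_step**2

    diams = np.full(len(centerline), np.nan)
    for i, (p, t) in enumerate(zip(centerline.points, centerline.tangents)):
        # in-plane orthonormal basis
        a = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(a, t)) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(t, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        pts = (
            p[None, None, :]
            + uu[..., None] * e1[None, None, :]
            + vv[..., None] * e2[None, None, :]
        )
        idx = (pts - origin) / spacing
        samples = ndimage.map_coordinates(
            mask, idx.reshape(-1, 3).T, order=1, mode="constant", cval=0.0
        )
        area = float((samples >= 0.5).sum()) * cell_area
        if area > 0:
            diams[i] = 2.0 * np.sqrt(area / np.pi)
    n_empty = int(np.isnan(diams).sum())
    if n_empty:
        warnings.warn(f"{n_empty} centerline stations had empty cross-sections")
    return diams


def measure_diameters(
    mask: np.ndarray,
    centerline: Centerline,
    labels: RegionLabels,
    spacing,
    origin=(0.0, 0.0, 0.0),
    **kwargs,
) -> dict[str, float]:
    """Per-region maximum effective diameter (mm).

    The per-station effective diameters are grouped by the region of each
    centerline station (same arc-length boundaries the voxels use) and the
    regional value is the maximum over that region's stations.
    """
    diams = station_diameters(mask, centerline, spacing, origin=origin, **kwargs)
    point_region = np.searchsorted(labels.boundaries, centerline.arc_length, side="right")
    out: dict[str, float] = {}
    for ri, name in enumerate(labels.names):
        vals = diams[point_region == ri]
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.max()) if vals.size else float("nan")
    return out


# ---------------------------------------------------------------------------
# anthropometrics and dilation


def bsa(height_cm: float, weight_kg: float, formula: str = "mosteller") -> float:
    """Body surface area in m^2 (Mosteller by default, Du Bois optional)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ParameterError("height and weight must be positive")
    if formula == "mosteller":
        return float(np.sqrt(height_cm * weight_kg / 3600.0))
    if formula == "dubois":
        return float(0.007184 * height_cm**0.725 * weight_kg**0.425)
    raise ParameterError(f"unknown BSA formula {formula!r}")


def index_diameter(diameter_mm: float, bsa_m2: float) -> float:
    """BSA-indexed diameter in mm/m^2."""
    if bsa_m2 <= 0:
        raise ParameterError("BSA must be positive")
    return diameter_mm / bsa_m2


def classify_dilation(max_aao_diameter_mm: float) -> str:
    """Dilation severity from the maximum ascending-aorta diameter.

    non-dilated below 35 mm, moderate from 35 to below 45 mm, severe from
    45 mm up (boundary values go to the higher class).
    """
    if max_aao_diameter_mm <= 0:
        raise ParameterError("diameter must be positive")
    if max_aao_diameter_mm < 35.0:
        return "non-dilated"
    if max_aao_diameter_mm < 45.0:
        return "moderate"
    return "severe"


def geometry_report(
    diameters: dict[str, float],
    height_cm: float,
    weight_kg: float,
    formula: str = "mosteller",
) -> AorticGeometryReport:
    """Bundle regional diameters with BSA indexing and the dilation class."""
    b = bsa(height_cm, weight_kg, formula=formula)
    indexed = {k: index_diameter(v, b) for k, v in diameters.items()}
    return AorticGeometryReport(
        diameters=diameters,
        indexed_diameters=indexed,
        dilation_class=classify_dilation(diameters["AAo"]),
        bsa_m2=b,
    )
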