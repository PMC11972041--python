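"""Room-frame geometry of the two-layer mini-tracker and line-line projection.

Coordinate conventions
----------------------
The room frame is right-handed with the isocenter at the origin, the beam
axis along ``+z`` (beam travels toward positive z) and ``+y`` vertically up.
The mini-tracker sits downstream of the isocenter, diagonally above the
phantom: its *focus line* (the line connecting the centers of the two
detection layers) passes through the isocenter at a polar angle of 30 deg to
the beam axis, by default in the y-z plane (azimuth 90 deg).  Both sensor
planes are perpendicular to the focus line.  A small known tilt of the
tracker within its support is modelled as a rotation of the in-plane sensor
basis about the focus line.

All lengths are millimetres, all angles degrees unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "Line3",
    "ApproachResult",
    "TrackerGeometry",
    "SolidAngleEstimate",
    "acceptance_solid_angle",
    "closest_approach",
    "closest_approach_batch",
    "unit_vector",
    "rotate_about_axis",
]

#: Two line directions are treated as parallel when the norm of their cross
#: product falls below this value (double-precision geometry at mm scale).
PARALLEL_TOL = 1e-9

LAYERS = ("front", "back")


def unit_vector(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit Euclidean norm."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero vector has no direction")
    return v / n


def rotate_about_axis(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate vector ``v`` about the unit ``axis`` by ``angle_rad`` (Rodrigues)."""
    axis = unit_vector(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


@dataclass(frozen=True)
class Line3:
    """A straight line in room coordinates: ``origin + t * direction``.

    ``direction`` must be unit-norm within 1e-9; it is normalised on
    construction to guard against drift from upstream arithmetic.
    """

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        direction = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(direction)
        if abs(n - 1.0) > 1e-6:
            if n == 0.0:
                raise ValueError("line direction must be non-zero")
        direction = direction / n
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


@dataclass(frozen=True)
class ApproachResult:
    """Closest approach between two lines.

    ``midpoint`` is the arithmetic mean of the two closest points — the
    reconstructed-vertex definition used throughout the package.  For
    (anti-)parallel lines the closest pair is not unique: ``degenerate`` is
    set, ``distance`` is the perpendicular line separation, and ``midpoint``
    is ``None``.
    """

    point_on_a: np.ndarray
    point_on_b: np.ndarray
    midpoint: np.ndarray | None
    distance: float
    degenerate: bool


def closest_approach(a: Line3, b: Line3) -> ApproachResult:
    """Shortest connection between two lines, with its midpoint.

    Solves the 2x2 normal equations of ``min_{t,s} |a(t) - b(s)|^2``.
    Symmetric under argument swap (identical midpoint and distance).
    """
    da, db = a.direction, b.direction
    w0 = a.origin - b.origin
    cross = np.cross(da, db)
    if np.linalg.norm(cross) < PARALLEL_TOL:
        # parallel: closest pair not unique; report the line separation
        pa = a.origin
        pb = b.origin + np.dot(db, a.origin - b.origin) * db
        dist = float(np.linalg.norm(pa - pb))
        midpoint = pa.copy() if dist == 0.0 else None
        return ApproachResult(pa, pb, midpoint, dist, degenerate=True)
    bb = float(np.dot(da, db))
    d = float(np.dot(da, w0))
    e = float(np.dot(db, w0))
    denom = 1.0 - bb * bb
    t = (bb * e - d) / denom
    s = (e - bb * d) / denom
    pa = a.origin + t * da
    pb = b.origin + s * db
    dist = float(np.linalg.norm(pa - pb))
    return ApproachResult(pa, pb, 0.5 * (pa + pb), dist, degenerate=False)


def closest_approach_batch(
    origins_a: np.ndarray,
    dirs_a: np.ndarray,
    origins_b: np.ndarray,
    dirs_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised closest approach for n line pairs.

    Parameters are (n, 3) arrays; ``dirs_*`` must be unit-norm.  Returns
    ``(midpoints (n, 3), distances (n,), degenerate mask (n,))``; midpoints
    of degenerate pairs are NaN.
    """
    origins_a = np.atleast_2d(origins_a)
    dirs_a = np.atleast_2d(dirs_a)
    origins_b = np.atleast_2d(origins_b)
    dirs_b = np.atleast_2d(dirs_b)
    w0 = origins_a - origins_b
    bb = np.einsum("ij,ij->i", dirs_a, dirs_b)
    d = np.einsum("ij,ij->i", dirs_a, w0)
    e = np.einsum("ij,ij->i", dirs_b, w0)
    cross = np.cross(dirs_a, dirs_b)
    degenerate = np.linalg.norm(cross, axis=1) < PARALLEL_TOL
    denom = 1.0 - bb * bb
    denom_safe = np.where(degenerate, 1.0, denom)
    t = (bb * e - d) / denom_safe
    s = (e - bb * d) / denom_safe
    pa = origins_a + t[:, None] * dirs_a
    pb = origins_b + s[:, None] * dirs_b
    mid = 0.5 * (pa + pb)
    dist = np.linalg.norm(pa - pb, axis=1)
    # report perpendicular separation for parallel pairs
    perp = w0 - e[:, None] * dirs_b
    dist = np.where(degenerate, np.linalg.norm(perp, axis=1), dist)
    mid[degenerate] = np.nan
    return mid, dist, degenerate


@dataclass(frozen=True)
class SolidAngleEstimate:
    omega_sr: float
    std_error_sr: float
    n_hits: int
    n_samples: int


@dataclass(frozen=True)
class TrackerGeometry:
    """Two-layer pixel-telescope geometry and sensor-to-room transforms.

    Defaults describe the mini-tracker used for fragment monitoring: two
    Timepix3 layers of 28 mm x 14 mm active area (55 um pitch, two chips
    sharing one sensor per layer), separated by 20.3 mm along a focus line
    at 30 deg to the beam axis, the front layer 167 mm from the isocenter,
    with a 1.6 deg tilt within its support.
    """

    layer_separation: float = 20.3
    pixel_pitch: float = 0.055
    active_area: tuple[float, float] = (28.0, 14.0)
    pixels_per_layer: tuple[int, int] = (509, 254)  # floor(area / pitch)
    sensor_thickness: float = 0.5
    focus_angle_deg: float = 30.0
    front_layer_distance: float = 167.0
    tilt_deg: float = 1.6
    azimuth_deg: float = 90.0  # focus line in the y-z plane, above the phantom

    @cached_property
    def focus_direction(self) -> np.ndarray:
        """Unit vector from the isocenter toward the tracker."""
        th = np.radians(self.focus_angle_deg)
        az = np.radians(self.azimuth_deg)
        return np.array(
            [np.sin(th) * np.cos(az), np.sin(th) * np.sin(az), np.cos(th)]
        )

    @cached_property
    def _in_plane_basis(self) -> tuple[np.ndarray, np.ndarray]:
        u = self.focus_direction
        zhat = np.array([0.0, 0.0, 1.0])
        e1 = np.cross(u, zhat)
        if np.linalg.norm(e1) < 1e-12:  # focus line along the beam axis
            e1 = np.array([1.0, 0.0, 0.0])
        e1 = unit_vector(e1)
        e2 = np.cross(u, e1)
        tilt = np.radians(self.tilt_deg)
        if tilt != 0.0:
            e1 = rotate_about_axis(e1, u, tilt)
            e2 = rotate_about_axis(e2, u, tilt)
        return e1, e2

    @property
    def basis_columns(self) -> np.ndarray:
        """In-plane unit vector along increasing pixel column (28 mm side)."""
        return self._in_plane_basis[0]

    @property
    def basis_rows(self) -> np.ndarray:
        """In-plane unit vector along increasing pixel row (14 mm side)."""
        return self._in_plane_basis[1]

    def layer_distance(self, layer_id: str) -> float:
        if layer_id == "front":
            return self.front_layer_distance
        if layer_id == "back":
            return self.front_layer_distance + self.layer_separation
        raise ValueError(f"unknown layer_id {layer_id!r}; expected 'front' or 'back'")

    def layer_center(self, layer_id: str) -> np.ndarray:
        """Center of the layer's mid-sensor plane, on the focus line."""
        return self.layer_distance(layer_id) * self.focus_direction

    def sensor_to_room(
        self,
        col,
        row,
        layer_id: str,
        subpixel_offset: tuple[float, float] = (0.0, 0.0),
    ) -> np.ndarray:
        """Map pixel coordinates on a layer to a room-frame point.

        ``col``/``row`` may be fractional (cluster centroids) and may be
        arrays; the result lies on the layer's mid-sensor plane.  Pixel
        (0, 0) is a corner pixel; the point for the fractional center index
        ``((n_cols - 1) / 2, (n_rows - 1) / 2)`` is the layer center.
        """
        col = np.asarray(col, dtype=float) + subpixel_offset[0]
        row = np.asarray(row, dtype=float) + subpixel_offset[1]
        nc, nr = self.pixels_per_layer
        if np.any(col < -0.5) or np.any(col > nc - 0.5) or np.any(row < -0.5) or np.any(row > nr - 0.5):
            raise ValueError("pixel index outside the layer's pixel grid")
        e1, e2 = self._in_plane_basis
        c = self.layer_center(layer_id)
        du = (col - (nc - 1) / 2.0) * self.pixel_pitch
        dv = (row - (nr - 1) / 2.0) * self.pixel_pitch
        return c + np.multiply.outer(du, e1) + np.multiply.outer(dv, e2)

    def room_to_sensor(self, point: np.ndarray, layer_id: str):
        """Inverse of :meth:`sensor_to_room` for in-plane points.

        Returns fractional ``(col, row)``; exact inverse within 1e-9 mm for
        points on the layer plane.
        """
        e1, e2 = self._in_plane_basis
        rel = np.asarray(point, dtype=float) - self.layer_center(layer_id)
        nc, nr = self.pixels_per_layer
        col = rel @ e1 / self.pixel_pitch + (nc - 1) / 2.0
        row = rel @ e2 / self.pixel_pitch + (nr - 1) / 2.0
        return col, row

    def intersect_layer(self, origins: np.ndarray, dirs: np.ndarray, layer_id: str):
        """Forward intersections of rays with a layer plane.

        Returns ``(points (n, 3), hit mask (n,))`` where ``hit`` requires a
        forward intersection inside the active area.
        """
        origins = np.atleast_2d(origins)
        dirs = np.atleast_2d(dirs)
        n = self.focus_direction
        c = self.layer_center(layer_id)
        denom = dirs @ n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ((c - origins) @ n) / denom
        valid = (np.abs(denom) > 1e-12) & (t > 0)
        pts = origins + t[:, None] * dirs
        e1, e2 = self._in_plane_basis
        rel = pts - c
        w, h = self.active_area
        inside = (np.abs(rel @ e1) <= w / 2.0) & (np.abs(rel @ e2) <= h / 2.0)
        return pts, valid & inside

    def layer_corners(self, layer_id: str) -> np.ndarray:
        e1, e2 = self._in_plane_basis
        c = self.layer_center(layer_id)
        w, h = self.active_area
        signs = np.array([(1, 1), (1, -1), (-1, 1), (-1, -1)], dtype=float)
        return c + signs[:, :1] * (w / 2.0) * e1 + signs[:, 1:] * (h / 2.0) * e2


def acceptance_solid_angle(
    geom: TrackerGeometry,
    origin: np.ndarray | None = None,
    n_samples: int = 100_000,
    seed: int | None = None,
    layers: str = "both",
) -> SolidAngleEstimate:
    """Monte Carlo solid angle of directions from ``origin`` hitting the tracker.

    ``layers`` selects which layers a direction must intersect: ``"both"``
    (coincidence acceptance), ``"front"`` or ``"back"``.  Directions are
    sampled uniformly in a spherical cap guaranteed to cover the tracker,
    so the estimate is unbiased with a standard error that shrinks as
    ``1/sqrt(n_samples)``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    wanted = LAYERS if layers == "both" else (layers,)
    for lay in wanted:
        if abs(np.dot(origin - geom.layer_center(lay), geom.focus_direction)) < 1e-9:
            raise ValueError("origin lies on a layer plane; solid angle undefined")

    corners = np.vstack([geom.layer_corners(lay) for lay in wanted])
    dirs_c = corners - origin
    dirs_c /= np.linalg.norm(dirs_c, axis=1, keepdims=True)
    axis = unit_vector(dirs_c.mean(axis=0))
    max_ang = float(np.max(np.arccos(np.clip(dirs_c @ axis, -1.0, 1.0))))
    cap_ang = min(1.2 * max_ang + 1e-3, np.pi)

    rng = np.random.default_rng(seed)
    cos_t = rng.uniform(np.cos(cap_ang), 1.0, size=n_samples)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_samples)
    sin_t = np.sqrt(1.0 - cos_t**2)
    # orthonormal frame around the cap axis
    a1 = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(a1) < 1e-12:
        a1 = np.array([1.0, 0.0, 0.0])
    a1 = unit_vector(a1)
    a2 = np.cross(axis, a1)
    dirs = (
        cos_t[:, None] * axis
        + (sin_t * np.cos(phi))[:, None] * a1
        + (sin_t * np.sin(phi))[:, None] * a2
    )
    origins = np.broadcast_to(origin, dirs.shape)
    hit = np.ones(n_samples, dtype=bool)
    for lay in wanted:
        _, h = geom.intersect_layer(origins, dirs, lay)
        hit &= h
    omega_cap = 2.0 * np.pi * (1.0 - np.cos(cap_ang))
    p = hit.mean()
    omega = omega_cap * p
    se = omega_cap * np.sqrt(max(p * (1.0 - p), 0.0) / n_samples)
    return SolidAngleEstimate(float(omega), float(se), int(hit.sum()), n_samples)
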