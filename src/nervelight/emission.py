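"""Focused-source emission geometry.

Each light source is a lens of a given numerical aperture (NA) aimed at a
focal point inside the nerve.  The lens is represented by the cone of rays
converging on the focal point: the cone's half-angle is ``asin(NA / n_ext)``
and its axis points from the focal point toward the source azimuth on the
cylinder surface.  Intersecting that cone with the cylinder yields the mesh
of surface contact points; every mesh entry carries a unit direction aimed
exactly at the focal point.

NA values at or above the external index cannot be realised in that
surround (``asin`` of >= 1); they are modelled by raising the external
index, i.e. an immersion medium (lens oil) between lens and nerve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .media import NerveModel

__all__ = [
    "LensSpec",
    "EmissionMesh",
    "InvalidLensError",
    "EmissionGeometryError",
    "half_angle",
    "make_emission_mesh",
    "place_sources",
    "lens_for_na",
    "save_mesh_csv",
    "load_mesh_csv",
]

# Largest sin(half-angle) the immersion rule permits; keeps the marginal
# rays of an NA >= n_ext cone off the cylinder end caps at practical
# nerve lengths instead of allowing a degenerate 90-degree cone.
_MAX_SIN_HALF_ANGLE = 0.95


class InvalidLensError(ValueError):
    """NA exceeds what the external medium can support (NA > n_ext)."""


class EmissionGeometryError(ValueError):
    """The emission cone misses the cylinder side wall (end-cap exit)."""


@dataclass(frozen=True)
class LensSpec:
    """A focusing lens characterised by its numerical aperture."""

    numerical_aperture: float

    def __post_init__(self) -> None:
        if not self.numerical_aperture >= 0:
            raise InvalidLensError(
                f"NA must be non-negative, got {self.numerical_aperture}"
            )

    def half_angle(self, external_n: float = 1.0) -> float:
        return half_angle(self, external_n)


def half_angle(lens: LensSpec, external_n: float = 1.0) -> float:
    """Convergence half-angle asin(NA / n_ext) of the lens cone, radians.

    Raises
    ------
    InvalidLensError
        If NA exceeds the external refractive index: no real lens in that
        surround can produce the cone (the classic "NA > 1 in air"
        impossibility).  Model such lenses with an immersion medium by
        raising ``external_n`` (see :func:`lens_for_na`).
    """
    na = lens.numerical_aperture
    if na > external_n:
        raise InvalidLensError(
            f"NA={na} exceeds the external refractive index {external_n}; "
            "an immersion medium (higher external_n) is required"
        )
    return math.asin(na / external_n)


def lens_for_na(na: float, external_n: float = 1.0) -> tuple[LensSpec, float]:
    """Lens and the coupling (immersion) index realising a requested NA.

    When ``na`` approaches or exceeds ``external_n`` the cone half-angle
    degenerates toward 90 degrees; in that regime the coupling index is
    raised to ``na / 0.95`` — an immersion droplet (lens oil) between the
    lens and the nerve — capping the half-angle at asin(0.95) ~ 71.8
    degrees.  The droplet shapes the entry cone only; the rest of the
    nerve surface stays in contact with the original external medium, so
    the total-internal-reflection boundary is unchanged.

    Returns ``(lens, immersion_n)``; pass ``immersion_n`` to
    :func:`make_emission_mesh` / :func:`place_sources`.
    """
    immersion_n = external_n
    if na > _MAX_SIN_HALF_ANGLE * external_n:
        immersion_n = na / _MAX_SIN_HALF_ANGLE
    return LensSpec(na), immersion_n


@dataclass(frozen=True)
class EmissionMesh:
    """Surface contact points and focal-point-aimed directions of one source.

    ``entries`` pairs each surface point (mm) with the unit direction from
    that point toward the focal point.  ``rays_per_point`` is how many
    photon packets are launched per entry during a simulation.
    """

    surface_points: np.ndarray  # (n, 3)
    directions: np.ndarray  # (n, 3), unit norm
    source_azimuth: float
    focal_point: np.ndarray  # (3,)
    rays_per_point: int = 10_000

    def __len__(self) -> int:
        return len(self.surface_points)

    @property
    def entries(self):
        return list(zip(self.surface_points, self.directions))

    def chief_direction(self) -> np.ndarray:
        """Unit direction of the central (chief) ray: azimuth point -> focus."""
        d = self.focal_point - self._azimuth_surface_point()
        return d / np.linalg.norm(d)

    def _azimuth_surface_point(self) -> np.ndarray:
        # radius recovered from any entry; all lie on the side wall
        r = float(np.hypot(*self.surface_points[0, :2]))
        return np.array(
            [
                r * math.cos(self.source_azimuth),
                r * math.sin(self.source_azimuth),
                self.focal_point[2],
            ]
        )

    def validate(self, nerve: NerveModel, lens_half_angle: float) -> None:
        """Assert the mesh invariants; raises AssertionError on violation."""
        r2 = np.sum(self.surface_points[:, :2] ** 2, axis=1)
        assert np.allclose(r2, nerve.radius**2, atol=1e-9)
        norms = np.linalg.norm(self.directions, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)
        aimed = self.focal_point[None, :] - self.surface_points
        aimed /= np.linalg.norm(aimed, axis=1, keepdims=True)
        assert np.allclose(aimed, self.directions, atol=1e-9)
        chief = self.chief_direction()
        cosang = np.clip(self.directions @ chief, -1.0, 1.0)
        assert np.all(np.arccos(cosang) <= lens_half_angle + 1e-9)

    def spot_area(self, nerve: NerveModel) -> float:
        """Approximate illuminated surface area (mm^2) of this source's spot.

        Entry points are unrolled onto the (arc-length, z) plane and the
        area of their convex hull is taken.  Zero for fewer than 3 points.
        """
        if len(self) < 3:
            return 0.0
        from scipy.spatial import ConvexHull, QhullError

        phi = np.arctan2(self.surface_points[:, 1], self.surface_points[:, 0])
        # unwrap about the source azimuth so the spot is contiguous
        dphi = (phi - self.source_azimuth + math.pi) % (2 * math.pi) - math.pi
        pts = np.column_stack([nerve.radius * dphi, self.surface_points[:, 2]])
        try:
            return float(ConvexHull(pts).volume)  # 2-D hull "volume" is area
        except QhullError:
            return 0.0


def _cone_directions(half: float, n_points: int) -> np.ndarray:
    """Symmetric polar grid of unit vectors filling a cone about +z.

    Directions are laid out on concentric rings of the spherical cap
    (polar angles alpha_i, ring populations proportional to sin(alpha_i)).
    Each ring is offset by half its spacing, so no two rings share an
    azimuth exactly (in particular none sits exactly in the meridional
    plane, which would pile every ring's entry point into the same
    axially-projected column), while the set remains exactly mirror
    symmetric about the x-z plane like a real lens spot.
    """
    if n_points <= 1 or half <= 0.0:
        return np.array([[0.0, 0.0, 1.0]])
    n_rings = max(1, round(math.sqrt(n_points)))
    alphas = half * (np.arange(1, n_rings + 1)) / n_rings
    weights = np.sin(alphas)
    remaining = n_points - 1  # one point reserved for the apex direction
    counts = np.maximum(1, np.round(remaining * weights / weights.sum()).astype(int))
    # nudge the outermost ring so the total lands exactly on n_points
    counts[-1] += remaining - counts.sum()
    if counts[-1] < 1:
        counts[-1] = 1
    dirs = [np.array([0.0, 0.0, 1.0])]
    for alpha, m in zip(alphas, counts):
        betas = 2.0 * math.pi * (np.arange(m) + 0.5) / m
        sa, ca = math.sin(alpha), math.cos(alpha)
        ring = np.column_stack([sa * np.cos(betas), sa * np.sin(betas),
                                np.full(m, ca)])
        dirs.append(ring)
    return np.vstack(dirs)


def _cylinder_exit(origin: np.ndarray, direction: np.ndarray,
                   radius: float) -> float:
    """Distance along ``direction`` from an interior point to the side wall."""
    a = direction[0] ** 2 + direction[1] ** 2
    if a < 1e-30:
        return math.inf
    b = origin[0] * direction[0] + origin[1] * direction[1]
    c = origin[0] ** 2 + origin[1] ** 2 - radius**2
    disc = b * b - a * c
    if disc < 0.0:
        return math.inf
    return (-b + math.sqrt(disc)) / a


def make_emission_mesh(
    nerve: NerveModel,
    lens: LensSpec,
    azimuth: float = 0.0,
    focal_point=None,
    target_points: int = 119,
    rays_per_point: int = 10_000,
    immersion_n: float | None = None,
) -> EmissionMesh:
    """Build the surface mesh of one focused source.

    Rays filling the lens cone (apex at ``focal_point``, axis toward the
    surface point at ``azimuth``) are traced outward to the cylinder side
    wall; each intersection becomes a surface entry whose photon direction
    is the unit vector back toward the focal point.

    ``immersion_n`` is the refractive index of the coupling medium that
    sets the cone half-angle ``asin(NA / immersion_n)``; it defaults to
    the nerve's external medium and may be raised locally (an oil droplet
    at the lens) without affecting the boundary elsewhere.

    ``target_points`` controls mesh density; the realised count equals it
    exactly for this construction.  Defaults give ~119 contact points, the
    density used throughout the reference scenarios.
    """
    if target_points < 1:
        raise ValueError("target_points must be >= 1")
    focal = (
        np.array([0.0, 0.0, nerve.length / 2.0])
        if focal_point is None
        else np.asarray(focal_point, dtype=float)
    )
    if not nerve.contains(focal) or np.hypot(focal[0], focal[1]) >= nerve.radius:
        raise ValueError(f"focal point {focal} must lie inside the nerve")
    coupling_n = nerve.external_n if immersion_n is None else immersion_n
    if coupling_n < nerve.external_n:
        raise ValueError("immersion index cannot be below the external medium's")
    half = half_angle(lens, coupling_n)

    axis_target = np.array(
        [
            nerve.radius * math.cos(azimuth),
            nerve.radius * math.sin(azimuth),
            focal[2],
        ]
    )
    axis = axis_target - focal
    axis /= np.linalg.norm(axis)

    local = _cone_directions(half, target_points)
    # rotate +z of the local frame onto the cone axis; keep the local x
    # axis in the plane spanned by the nerve axis and the cone axis so the
    # mirror plane of the ring grid maps onto the meridional plane
    zhat = np.array([0.0, 0.0, 1.0])
    if abs(axis @ zhat) > 0.999999:
        u = np.array([1.0, 0.0, 0.0])
    else:
        u = zhat - (zhat @ axis) * axis
        u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    frame = np.column_stack([u, v, axis])
    world = local @ frame.T

    points = np.empty_like(world)
    for i, d in enumerate(world):
        s = _cylinder_exit(focal, d, nerve.radius)
        if not math.isfinite(s):
            raise EmissionGeometryError(
                "emission cone contains a ray parallel to the nerve axis"
            )
        p = focal + s * d
        if not (0.0 <= p[2] <= nerve.length):
            raise EmissionGeometryError(
                f"emission cone exits through an end cap at z={p[2]:.3f} mm; "
                "increase the nerve length"
            )
        points[i] = p
    dirs = focal[None, :] - points
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return EmissionMesh(
        surface_points=points,
        directions=dirs,
        source_azimuth=azimuth,
        focal_point=focal,
        rays_per_point=rays_per_point,
    )


def place_sources(
    nerve: NerveModel,
    lens: LensSpec,
    k: int,
    focal_point=None,
    target_points: int = 119,
    rays_per_point: int = 10_000,
    immersion_n: float | None = None,
) -> list[EmissionMesh]:
    """``k`` identical sources equally spaced in azimuth starting at 0.

    Meshes of adjacent sources may overlap on the surface for wide cones;
    use :func:`sources_overlap` to detect it.
    """
    if k < 1:
        raise ValueError("source count must be >= 1")
    return [
        make_emission_mesh(
            nerve,
            lens,
            azimuth=2.0 * math.pi * i / k,
            focal_point=focal_point,
            target_points=target_points,
            rays_per_point=rays_per_point,
            immersion_n=immersion_n,
        )
        for i in range(k)
    ]


def sources_overlap(meshes: list[EmissionMesh]) -> bool:
    """True when the azimuthal extents of adjacent source spots overlap."""
    if len(meshes) < 2:
        return False
    spacing = 2.0 * math.pi / len(meshes)
    for mesh in meshes:
        phi = np.arctan2(mesh.surface_points[:, 1], mesh.surface_points[:, 0])
        dphi = (phi - mesh.source_azimuth + math.pi) % (2 * math.pi) - math.pi
        if np.max(np.abs(dphi)) > spacing / 2.0:
            return True
    return False


_CSV_HEADER = "x,y,z,dx,dy,dz,azimuth_id"


def save_mesh_csv(meshes: list[EmissionMesh], path) -> None:
    """Write meshes as CSV with columns x,y,z,dx,dy,dz,azimuth_id."""
    rows = []
    for i, mesh in enumerate(meshes):
        block = np.column_stack(
            [mesh.surface_points, mesh.directions,
             np.full(len(mesh), i, dtype=float)]
        )
        rows.append(block)
    data = np.vstack(rows)
    np.savetxt(path, data, delimiter=",", header=_CSV_HEADER, comments="",
               fmt="%.17g")


def load_mesh_csv(path, focal_point, rays_per_point: int = 10_000
                  ) -> list[EmissionMesh]:
    """Read meshes written by :func:`save_mesh_csv`."""
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    focal = np.asarray(focal_point, dtype=float)
    meshes = []
    for aid in np.unique(data[:, 6]):
        block = data[data[:, 6] == aid]
        pts, dirs = block[:, :3], block[:, 3:6]
        centroid = pts.mean(axis=0)
        azimuth = math.atan2(centroid[1], centroid[0])
        meshes.append(
            EmissionMesh(
                surface_points=pts,
                directions=dirs,
                source_azimuth=azimuth,
                focal_point=focal,
                rays_per_point=rays_per_point,
            )
        )
    return meshes
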