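"""Scanner geometry: arc transducer array, dome, rotating poses, fan illuminator.

Coordinate frame
----------------
The origin sits at the dome's center of curvature.  The z axis is the dome
rotation axis and points away from the dome opening (toward the bottom of the
bowl).  The imaging plane of pose 0 is the x-z plane.  A tomographic pose is a
rigid rotation of the array *and* illuminator about z; the sample stays fixed
in the lab frame.  All lengths are centimeters, all interface angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ArrayGeometry",
    "AcquisitionPlan",
    "IlluminatorGeometry",
    "VoxelGrid",
    "build_array",
    "default_illuminator",
    "rotate_pose",
    "element_angles",
    "solid_angle_weight",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def rotation_about_z(angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about the dome axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class ArrayGeometry:
    """Positions and orientations of the arc transducer elements.

    ``element_positions`` lie on a circle of radius ``arc_radius`` centered at
    the dome center; ``element_normals`` point toward the dome interior.
    ``element_lateral`` is the arc tangent toward increasing element index;
    the elevational direction is ``normal x lateral``.
    """

    n_elements: int
    arc_length: float
    arc_radius: float
    element_positions: np.ndarray  # (n, 3) cm
    element_normals: np.ndarray    # (n, 3) unit
    element_lateral: np.ndarray    # (n, 3) unit
    element_area: float            # cm^2

    @property
    def element_elevational(self) -> np.ndarray:
        return np.cross(self.element_normals, self.element_lateral)

    @property
    def pitch(self) -> float:
        return self.arc_length / (self.n_elements - 1)


@dataclass(frozen=True)
class AcquisitionPlan:
    """Tomographic acquisition parameters (poses, sampling, sound speed)."""

    n_angles: int = 200
    angular_step: float = 1.8       # degrees
    sampling_rate: float = 40e6     # Hz
    n_samples: int = 2080
    sound_speed: float = 1500.0     # m/s

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_samples < 1:
            raise ValueError("n_angles and n_samples must be positive")
        if self.n_angles * self.angular_step > 360.0 + 1e-9:
            raise ValueError("pose angles exceed a full rotation")
        if self.sampling_rate <= 0 or self.sound_speed <= 0:
            raise ValueError("sampling_rate and sound_speed must be positive")

    @property
    def pose_angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.angular_step

    @property
    def sound_speed_cm(self) -> float:
        return self.sound_speed * 100.0

    @property
    def max_range_cm(self) -> float:
        """Farthest element-to-voxel distance the time window can record."""
        return (self.n_samples - 1) * self.sound_speed_cm / self.sampling_rate

    def covers(self, geom: ArrayGeometry, grid: "VoxelGrid") -> bool:
        """Whether the record length reaches every voxel from every element."""
        corners = grid.corners()
        d = np.linalg.norm(
            corners[:, None, :] - geom.element_positions[None, :, :], axis=-1
        )
        return bool(d.max() <= self.max_range_cm)


@dataclass(frozen=True)
class IlluminatorGeometry:
    """Fan-shaped diffuse illuminator rigidly attached to the array.

    The fan originates at a virtual ``source_point`` inside the dome; rays
    diverge by ``wide_divergence`` about ``wide_axis`` (spreading light along
    the 11.5 cm optical window) and by ``narrow_divergence`` about the third
    axis, making a thin light sheet in the imaging plane.  The illuminated
    band B lies on the dome sphere of radius ``dome_radius``.
    """

    source_point: np.ndarray        # (3,) cm
    fan_axis: np.ndarray            # (3,) unit, central ray
    wide_axis: np.ndarray           # (3,) unit, in-plane divergence direction
    wide_divergence: float = 90.0   # degrees, full span
    narrow_divergence: float = 0.24  # degrees, full span
    dome_radius: float = 12.0       # cm
    window_arc_length: float = 11.5  # cm

    @property
    def narrow_axis(self) -> np.ndarray:
        return np.cross(self.fan_axis, self.wide_axis)

    def ray_directions(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Unit ray directions for fan angles (theta wide, phi narrow), radians."""
        theta = np.asarray(theta, float)
        phi = np.asarray(phi, float)
        d = (
            (np.cos(theta) * np.cos(phi))[..., None] * self.fan_axis
            + (np.sin(theta) * np.cos(phi))[..., None] * self.wide_axis
            + np.sin(phi)[..., None] * self.narrow_axis
        )
        return _unit(d)

    def surface_points(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Intersections of fan rays with the dome sphere (the band B)."""
        d = self.ray_directions(theta, phi)
        s = self.source_point
        # |s + t d| = R, take the root in the forward direction
        b = np.sum(d * s, axis=-1)
        c = float(np.dot(s, s)) - self.dome_radius**2
        disc = b * b - c
        if np.any(disc < 0):
            raise ValueError("fan ray misses the dome sphere")
        t = -b + np.sqrt(disc)
        return s + t[..., None] * d


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel grid; ``origin`` is the center of voxel (0,0,0)."""

    origin: tuple[float, float, float]
    spacing: float = 0.05  # cm (0.5 mm)
    shape: tuple[int, int, int] = (64, 64, 64)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(int(s) < 1 for s in self.shape):
            raise ValueError("shape components must be >= 1")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(o[i] + self.spacing * np.arange(self.shape[i]) for i in range(3))

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of voxel center coordinates, C order."""
        ax, ay, az = self.axes()
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def corners(self) -> np.ndarray:
        o = np.asarray(self.origin)
        hi = o + self.spacing * (np.asarray(self.shape) - 1)
        return np.array(
            [[x, y, z] for x in (o[0], hi[0]) for y in (o[1], hi[1]) for z in (o[2], hi[2])]
        )

    def world_to_index(self, point: np.ndarray) -> np.ndarray:
        return (np.asarray(point) - np.asarray(self.origin)) / self.spacing


def build_array(
    n_elements: int = 384,
    arc_length: float = 11.5,
    arc_radius: float = 12.0,
    elevational_aperture: float = 0.5,
    arc_center_polar_deg: float = 45.0,
) -> ArrayGeometry:
    """Construct the arc array in the pose-0 imaging plane (x-z).

    Elements are spaced uniformly along an arc of ``arc_length`` on the circle
    of radius ``arc_radius`` centered at the dome center, symmetric about the
    polar angle ``arc_center_polar_deg`` measured from the +z axis.  The
    element area is pitch x ``elevational_aperture`` (the elevational extent
    of a lensed element is a configurable assumption, not a datasheet value).
    """
    if n_elements < 2:
        raise ValueError("need at least 2 elements")
    if arc_length <= 0 or arc_radius <= 0 or elevational_aperture <= 0:
        raise ValueError("lengths must be positive")
    if arc_length >= 2 * np.pi * arc_radius:
        raise ValueError("arc_length exceeds the full circle")

    span = arc_length / arc_radius  # radians
    center = np.deg2rad(arc_center_polar_deg)
    gamma = center + np.linspace(-span / 2, span / 2, n_elements)
    pos = arc_radius * np.stack(
        [np.sin(gamma), np.zeros_like(gamma), np.cos(gamma)], axis=1
    )
    normals = -pos / arc_radius
    lateral = np.stack([np.cos(gamma), np.zeros_like(gamma), -np.sin(gamma)], axis=1)
    pitch = arc_length / (n_elements - 1)
    return ArrayGeometry(
        n_elements=n_elements,
        arc_length=arc_length,
        arc_radius=arc_radius,
        element_positions=pos,
        element_normals=normals,
        element_lateral=lateral,
        element_area=pitch * elevational_aperture,
    )


def default_illuminator(geom: ArrayGeometry) -> IlluminatorGeometry:
    """Place the fan so its 90-degree wide divergence exactly spans the window.

    The optical window is modeled as an arc congruent to the transducer arc in
    the pose-0 plane.  The virtual fan origin sits on the circle having the
    window chord as diameter (Thales: the chord subtends 90 degrees there),
    on the dome-interior side, with the central ray aimed at the window
    midpoint.  The narrow 0.24-degree divergence is out-of-plane (y).
    """
    span = geom.arc_length / geom.arc_radius
    center = np.arctan2(geom.element_positions[geom.n_elements // 2, 0],
                        geom.element_positions[geom.n_elements // 2, 2])
    g1, g2 = center - span / 2, center + span / 2
    R = geom.arc_radius
    a = R * np.array([np.sin(g1), 0.0, np.cos(g1)])
    b = R * np.array([np.sin(g2), 0.0, np.cos(g2)])
    mid = (a + b) / 2
    mid_hat = mid / np.linalg.norm(mid)
    half_chord = np.linalg.norm(b - a) / 2
    source = mid - half_chord * mid_hat
    wide = _unit(b - a)
    return IlluminatorGeometry(
        source_point=source,
        fan_axis=mid_hat,
        wide_axis=wide,
        dome_radius=R,
        window_arc_length=geom.arc_length,
    )


def rotate_pose(
    geom: ArrayGeometry, illum: IlluminatorGeometry, angle: float
) -> tuple[ArrayGeometry, IlluminatorGeometry]:
    """Rigidly rotate array and illuminator about the dome axis by ``angle`` degrees."""
    Rm = rotation_about_z(angle % 360.0)
    g = replace(
        geom,
        element_positions=geom.element_positions @ Rm.T,
        element_normals=geom.element_normals @ Rm.T,
        element_lateral=geom.element_lateral @ Rm.T,
    )
    il = replace(
        illum,
        source_point=Rm @ illum.source_point,
        fan_axis=Rm @ illum.fan_axis,
        wide_axis=Rm @ illum.wide_axis,
    )
    return g, il


def element_angles(
    element_pos: np.ndarray,
    element_normal: np.ndarray,
    element_lateral: np.ndarray,
    voxel: np.ndarray,
) -> tuple[float, float, float]:
    """Lateral/elevational view angles (degrees) and distance to a voxel.

    theta_L is the angle between the element normal and the voxel direction
    projected onto the lateral (in-plane) axis, theta_E onto the elevational
    (out-of-plane) axis; both via atan2 of the respective direction component
    over the axial component, so on-axis voxels give (0, 0).
    """
    v = np.asarray(voxel, float) - np.asarray(element_pos, float)
    dist = float(np.linalg.norm(v))
    if dist == 0.0:
        raise ZeroDivisionError("voxel coincides with the element position")
    n = np.asarray(element_normal, float)
    lat = np.asarray(element_lateral, float)
    elev = np.cross(n, lat)
    a = float(v @ n)
    b = float(v @ lat)
    c = float(v @ elev)
    theta_l = np.degrees(np.arctan2(b, a))
    theta_e = np.degrees(np.arctan2(c, a))
    return theta_l, theta_e, dist


def solid_angle_weight(
    element_pos: np.ndarray,
    element_normal: np.ndarray,
    element_area: float,
    voxel: np.ndarray,
) -> float:
    """Solid angle (sr) subtended by the element as seen from the voxel.

    dOmega = A cos(Theta) / d^2 with Theta the total inclination between the
    element normal and the voxel direction; back-facing voxels get 0.
    """
    v = np.asarray(voxel, float) - np.asarray(element_pos, float)
    d2 = float(v @ v)
    if d2 == 0.0:
        raise ZeroDivisionError("voxel coincides with the element position")
    cos_t = float(v @ np.asarray(element_normal, float)) / np.sqrt(d2)
    return element_area * max(cos_t, 0.0) / d2
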