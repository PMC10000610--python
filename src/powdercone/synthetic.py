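"""Seeded synthetic cone meshes with controllable lumpiness.

A poured powder heap is close to a right circular cone; surface lumps
show up as radial bulges.  The generator reproduces exactly that
observable: the lateral surface is built on a regular (theta, z) grid
and lumps are added as Gaussian bumps in the radial displacement field

    r(theta, z) = R0 * (1 - z/H) + sum_m a_m
                  * exp(-dtheta_m^2 / (2 sigma_theta_m^2)
                        - (z - z_m)^2 / (2 sigma_z_m^2))

with ``dtheta`` the wrapped angular distance to the bump centre.  Four
roughness grades are provided as presets whose bump count and amplitude
grow with grade and whose bump altitudes are bottom-biased (lumps roll
down the heap), with the angular width tuned so a lump subtends an arc
of roughly ten distance units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_io import TriangleMesh

__all__ = [
    "BumpSpec",
    "SyntheticConeSpec",
    "make_perfect_cone",
    "make_lumpy_cone",
    "make_uniform_density_cone",
    "make_class_sample",
    "sample_class_spec",
    "CLASS_PRESETS",
    "POWDER_TYPES",
]

POWDER_TYPES = ("trim", "whole")

#: nominal lump arc length, distance units
LUMP_ARC_LENGTH = 10.0

#: default heap geometry for graded samples, distance units
DEFAULT_BASE_RADIUS = 50.0
DEFAULT_HEIGHT = 100.0


@dataclass(frozen=True)
class BumpSpec:
    """One Gaussian lump on the cone surface.

    amplitude : peak radial height (distance units), >= 0
    theta_center : angular position (radians)
    z_center : altitude of the bump centre (distance units)
    sigma_theta : angular half-width (radians), > 0
    sigma_z : vertical half-width (distance units), > 0
    """

    amplitude: float
    theta_center: float
    z_center: float
    sigma_theta: float
    sigma_z: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("bump amplitude must be >= 0")
        if self.sigma_theta <= 0 or self.sigma_z <= 0:
            raise ValueError("bump widths must be > 0")


@dataclass(frozen=True)
class SyntheticConeSpec:
    """Parametric description of a lumpy cone mesh."""

    base_radius: float = DEFAULT_BASE_RADIUS
    height: float = DEFAULT_HEIGHT
    n_theta: int = 192
    n_z: int = 96
    bumps: tuple[BumpSpec, ...] = field(default_factory=tuple)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.base_radius <= 0 or self.height <= 0:
            raise ValueError("base_radius and height must be > 0")
        if self.n_theta < 8 or self.n_z < 4:
            raise ValueError("resolution too low: need n_theta >= 8 and n_z >= 4")
        object.__setattr__(self, "bumps", tuple(self.bumps))
        for b in self.bumps:
            if not 0.0 <= b.z_center <= self.height:
                raise ValueError(f"bump z_center {b.z_center} outside [0, {self.height}]")


def displacement_field(
    theta: np.ndarray, z: np.ndarray, bumps: tuple[BumpSpec, ...]
) -> np.ndarray:
    """Sum of Gaussian bump contributions at angles ``theta``, altitudes ``z``."""
    theta = np.asarray(theta, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    out = np.zeros(np.broadcast(theta, z).shape, dtype=np.float64)
    for b in bumps:
        dtheta = np.angle(np.exp(1j * (theta - b.theta_center)))  # wrapped to (-pi, pi]
        out += b.amplitude * np.exp(
            -(dtheta**2) / (2.0 * b.sigma_theta**2)
            - ((z - b.z_center) ** 2) / (2.0 * b.sigma_z**2)
        )
    return out


def _cone_grid(R0, H, n_theta, n_z, bumps):
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    z_levels = H * np.arange(n_z) / n_z
    tt, zz = np.meshgrid(theta, z_levels)  # (n_z, n_theta)
    rr = R0 * (1.0 - zz / H)
    if bumps:
        rr = rr + displacement_field(tt, zz, bumps)
    verts = np.empty((n_z * n_theta + 1, 3))
    verts[:-1, 0] = (rr * np.cos(tt)).ravel()
    verts[:-1, 1] = (rr * np.sin(tt)).ravel()
    verts[:-1, 2] = zz.ravel()
    verts[-1] = (0.0, 0.0, H)  # apex
    faces = []
    for i in range(n_z - 1):
        a = i * n_theta + np.arange(n_theta)
        b = (a + 1) % n_theta + i * n_theta
        c = a + n_theta
        d = b + n_theta
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    top = (n_z - 1) * n_theta + np.arange(n_theta)
    top_next = (n_z - 1) * n_theta + (np.arange(n_theta) + 1) % n_theta
    apex = np.full(n_theta, n_z * n_theta)
    faces.append(np.column_stack([top, top_next, apex]))
    return TriangleMesh(verts, np.concatenate(faces)).validate()


def make_perfect_cone(R0: float, H: float, n_theta: int = 192, n_z: int = 96) -> TriangleMesh:
    """Open lateral surface of an ideal right circular cone.

    Ring ``i`` sits at altitude ``z_i = i*H/n_z`` with every vertex at
    radius ``R0*(1 - z_i/H)`` exactly; a single apex vertex closes the
    top.  Vertex count is ``n_theta*n_z + 1``.
    """
    spec = SyntheticConeSpec(base_radius=R0, height=H, n_theta=n_theta, n_z=n_z)
    return _cone_grid(spec.base_radius, spec.height, spec.n_theta, spec.n_z, ())


def make_lumpy_cone(spec: SyntheticConeSpec) -> TriangleMesh:
    """Cone surface perturbed by the spec's Gaussian bumps.

    With an empty bump list the result is vertex-identical to
    :func:`make_perfect_cone` on the same grid.
    """
    return _cone_grid(spec.base_radius, spec.height, spec.n_theta, spec.n_z, spec.bumps)


# Grade presets: (min bumps, max bumps, min amplitude, max amplitude).
# Bump count and amplitude grow with grade; grade 0 is capped so that even
# two overlapping bumps stay below a 0.15 distance-unit deviation.
CLASS_PRESETS = {
    0: (0, 2, 0.02, 0.06),
    1: (5, 7, 0.4, 0.6),
    2: (10, 14, 0.8, 1.2),
    3: (18, 22, 1.5, 2.1),
}

# Fine-grained surface texture: moisture roughens the whole surface, not
# just where discrete lumps settle, so grades 1-3 carry a population of
# small bumps spread uniformly over altitude.  Values are the nominal
# texture amplitude per grade (distance units); grade 0 has none.
TEXTURE_AMPLITUDE = {0: 0.0, 1: 0.03, 2: 0.06, 3: 0.12}
TEXTURE_COUNT = 40
TEXTURE_ARC_LENGTH = 5.0


def sample_class_spec(
    class_id: int,
    powder_type: str = "trim",
    seed: int = 0,
    *,
    base_radius: float = DEFAULT_BASE_RADIUS,
    height: float = DEFAULT_HEIGHT,
    n_theta: int = 192,
    n_z: int = 96,
) -> SyntheticConeSpec:
    """Draw a reproducible cone spec for one roughness grade.

    Bump altitudes are drawn as ``H * Beta(1, 3)`` fractions, so lumps
    concentrate near the base.  The angular width is set from the
    nominal lump arc length (:data:`LUMP_ARC_LENGTH`) at the bump's own
    altitude, taking the arc subtended by +/- 2 sigma as the lump size.
    The same ``(class_id, powder_type, seed)`` triple always yields the
    same spec.
    """
    if class_id not in CLASS_PRESETS:
        raise ValueError(f"class_id must be one of {sorted(CLASS_PRESETS)}, got {class_id!r}")
    if powder_type not in POWDER_TYPES:
        raise ValueError(f"powder_type must be one of {POWDER_TYPES}, got {powder_type!r}")
    lo, hi, a_lo, a_hi = CLASS_PRESETS[class_id]
    ss = np.random.SeedSequence([int(seed), int(class_id), POWDER_TYPES.index(powder_type)])
    rng = np.random.default_rng(ss)
    n_bumps = int(rng.integers(lo, hi + 1))
    bumps = []
    for _ in range(n_bumps):
        amplitude = float(rng.uniform(a_lo, a_hi))
        theta_c = float(rng.uniform(0.0, 2.0 * np.pi))
        z_c = float(height * rng.beta(1.0, 3.0))
        r_at_z = base_radius * (1.0 - z_c / height)
        # arc length ~ 4 sigma_theta * r(z_c); clip width on thin top rings
        sigma_theta = min(LUMP_ARC_LENGTH / (4.0 * max(r_at_z, 1e-9)), np.pi / 3.0)
        sigma_z = LUMP_ARC_LENGTH / 4.0
        bumps.append(BumpSpec(amplitude, theta_c, z_c, sigma_theta, sigma_z))
    tex_amp = TEXTURE_AMPLITUDE[class_id]
    if tex_amp > 0.0:
        for _ in range(TEXTURE_COUNT):
            amplitude = float(tex_amp * rng.uniform(0.5, 1.5))
            theta_c = float(rng.uniform(0.0, 2.0 * np.pi))
            z_c = float(rng.uniform(0.0, height))
            r_at_z = base_radius * (1.0 - z_c / height)
            sigma_theta = min(TEXTURE_ARC_LENGTH / (4.0 * max(r_at_z, 1e-9)), np.pi / 3.0)
            bumps.append(
                BumpSpec(amplitude, theta_c, z_c, sigma_theta, TEXTURE_ARC_LENGTH / 4.0)
            )
    return SyntheticConeSpec(
        base_radius=base_radius,
        height=height,
        n_theta=n_theta,
        n_z=n_z,
        bumps=tuple(bumps),
        seed=int(seed),
    )


def make_uniform_density_cone(
    R0: float, H: float, edge_length: float, n_z: int = 48
) -> TriangleMesh:
    """Cone surface with roughly uniform triangle size, like a scanned mesh.

    Ring ``i`` at altitude ``i*H/n_z`` carries a vertex count
    proportional to its circumference (at least 8), so contours near the
    base cross more triangles than contours near the apex -- the
    behaviour of real reconstructed meshes, which the regular
    (theta, z) grid of :func:`make_perfect_cone` does not show.
    """
    if R0 <= 0 or H <= 0 or edge_length <= 0:
        raise ValueError("R0, H and edge_length must be > 0")
    if n_z < 4:
        raise ValueError("n_z must be >= 4")
    rings = []  # (vertex start index, angles)
    verts = []
    for i in range(n_z):
        z = H * i / n_z
        r = R0 * (1.0 - z / H)
        n = max(8, int(round(2.0 * np.pi * r / edge_length)))
        angles = 2.0 * np.pi * np.arange(n) / n
        start = len(verts)
        for a in angles:
            verts.append((r * np.cos(a), r * np.sin(a), z))
        rings.append((start, angles))
    apex = len(verts)
    verts.append((0.0, 0.0, H))

    faces = []
    for (sa, aa), (sb, ab) in zip(rings[:-1], rings[1:]):
        na, nb = len(aa), len(ab)
        i = j = 0
        # advance around both rings together, always bridging to the
        # loop whose next vertex comes first in angle
        while i < na or j < nb:
            next_a = aa[(i + 1) % na] + 2.0 * np.pi * ((i + 1) // na)
            next_b = ab[(j + 1) % nb] + 2.0 * np.pi * ((j + 1) // nb)
            if j >= nb or (i < na and next_a <= next_b):
                faces.append((sa + i % na, sa + (i + 1) % na, sb + j % nb))
                i += 1
            else:
                faces.append((sa + i % na, sb + (j + 1) % nb, sb + j % nb))
                j += 1
    s_top, a_top = rings[-1]
    n_top = len(a_top)
    for k in range(n_top):
        faces.append((s_top + k, s_top + (k + 1) % n_top, apex))
    return TriangleMesh(np.array(verts), np.array(faces)).validate()


def make_class_sample(
    class_id: int, powder_type: str = "trim", seed: int = 0, **geometry
) -> TriangleMesh:
    """Generate one graded sample mesh; see :func:`sample_class_spec`."""
    return make_lumpy_cone(sample_class_spec(class_id, powder_type, seed, **geometry))
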