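"""Ray-optics trapping forces on large transparent spheres.

A tightly focused laser beam is discretised into a fan of rays converging on
the focal point.  Each ray that strikes the sphere is refracted and partially
reflected at the surface; the momentum it transfers is obtained from the
classical closed-form result in which the infinite series of internal
reflections is summed analytically (single-interface Fresnel coefficients,
geometric series).  The dimensionless trapping efficiency ``Q`` relates force
to power through

    F = Q * n_m * P / c

with ``n_m`` the immersion-medium index, ``P`` the laser power and ``c`` the
vacuum speed of light.

Sign convention
---------------
Forces are reported as the reaction exerted by the particle *on the beam* —
the quantity a position-sensitive detector in the condenser path measures.
It is equal and opposite to the optical force on the particle, so a trap
placed below the sphere centre on the y axis yields a positive y force.

The model assumes an isotropic sphere; birefringence of real otoliths is
treated empirically downstream (see :mod:`ototrap.forcemap`).  No RNG is used
anywhere in this module: the ray fan is a deterministic stratified grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SPEED_OF_LIGHT = 299_792_458.0  # m/s

#: stratified rays used when the caller does not specify a count
DEFAULT_N_RAYS = 20_000

__all__ = [
    "TrapBeam",
    "SphereParticle",
    "RayBundle",
    "ForceResult",
    "ForceField",
    "InvalidGeometryError",
    "sample_ray_fan",
    "single_ray_momentum_transfer",
    "trap_force",
    "q_profile",
    "force_map",
    "DEFAULT_N_RAYS",
]


class InvalidGeometryError(ValueError):
    """Beam geometry cannot form a focused cone (e.g. NA >= medium index)."""


@dataclass(frozen=True)
class TrapBeam:
    """Laser/objective description.

    Parameters
    ----------
    wavelength_nm:
        Vacuum wavelength. The ray picture is wavelength independent, but the
        value is carried for provenance (1064 nm fibre laser by default).
    power_mw:
        Radiant power at the sample, in milliwatts.
    numerical_aperture:
        ``n sin(theta_max)`` of the objective; sets the cone half-angle.
    medium_index:
        Refractive index of the immersion/sample medium.
    aperture_fill:
        ``"uniform"`` (overfilled objective) or ``"gaussian"``.
    fill_fraction:
        For a gaussian fill, the 1/e^2 beam radius as a fraction of the
        aperture radius. Ignored for uniform fill.
    """

    power_mw: float = 500.0
    wavelength_nm: float = 1064.0
    numerical_aperture: float = 1.0
    medium_index: float = 1.33
    aperture_fill: str = "uniform"
    fill_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.power_mw < 0:
            raise ValueError("power must be >= 0")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be > 0")
        if not 0 < self.numerical_aperture < self.medium_index:
            raise InvalidGeometryError(
                "need 0 < NA < medium index for a focused cone in the medium"
            )
        if self.aperture_fill not in ("uniform", "gaussian"):
            raise ValueError("aperture_fill must be 'uniform' or 'gaussian'")

    @property
    def cone_half_angle_rad(self) -> float:
        """Half-angle of the focused cone in the medium."""
        return float(np.arcsin(self.numerical_aperture / self.medium_index))


@dataclass(frozen=True)
class SphereParticle:
    """Spherical otolith model.

    The force calculation uses the isotropic ``index`` only.  The aragonite
    birefringent triple ``(n_alpha, n_beta, n_gamma)`` is carried for the
    synthetic scan generator, which imprints birefringence empirically as
    angular sectors; the default isotropic index 1.63 is the mean of the
    triple.
    """

    radius_um: float = 27.5
    index: float = 1.63
    birefringent_indices: tuple[float, float, float] | None = (1.53, 1.68, 1.69)
    centre_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be > 0")
        if self.index <= 1:
            raise ValueError("refractive index must exceed 1")
        if self.birefringent_indices is not None and any(
            n <= 1 for n in self.birefringent_indices
        ):
            raise ValueError("birefringent indices must exceed 1")


@dataclass(frozen=True)
class RayBundle:
    """Discretised focused cone: per-ray unit directions and power weights."""

    directions: np.ndarray  # (n, 3), unit norm, propagating toward +z
    weights: np.ndarray  # (n,), >= 0, sum to 1
    polarization: str = "average"  # {"s", "p", "average"}

    def __post_init__(self) -> None:
        d = np.asarray(self.directions, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3 or w.shape != (d.shape[0],):
            raise ValueError("directions must be (n, 3) with matching weights")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be >= 0 and sum to 1")
        if not np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-9):
            raise ValueError("directions must be unit norm")

    def __len__(self) -> int:
        return self.directions.shape[0]


@dataclass(frozen=True)
class ForceResult:
    """Trapping efficiency and force at one trap position.

    ``force_pn = q_vector * medium_index * P / c`` componentwise; the vector
    is the reaction on the beam (see module docstring for the convention).
    """

    q_vector: np.ndarray  # (3,), dimensionless
    force_pn: np.ndarray  # (3,), pN
    trap_position_um: np.ndarray  # (3,), relative to sphere centre


@dataclass(frozen=True)
class ForceField:
    """Q and force sampled on a 2-D grid of trap positions (z = 0 plane)."""

    positions_um: np.ndarray  # (m, 2)
    q: np.ndarray  # (m, 3)
    force_pn: np.ndarray  # (m, 3)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x_um": self.positions_um[:, 0],
                "y_um": self.positions_um[:, 1],
                "Qx": self.q[:, 0],
                "Qy": self.q[:, 1],
                "Fx_pN": self.force_pn[:, 0],
                "Fy_pN": self.force_pn[:, 1],
            }
        )


def sample_ray_fan(
    beam: TrapBeam, n_rays: int, polarization: str = "average"
) -> RayBundle:
    """Deterministic stratified discretisation of the focused cone.

    Rays are placed at cell midpoints of a grid that is uniform in
    ``(sin^2 alpha, phi)`` — uniform in aperture area under the Abbe sine
    condition — so a uniform fill gives equal weights.  The realised ray
    count is ``n_phi * n_alpha <= n_rays`` with ``n_phi`` rays per annulus.
    """
    if n_rays < 8:
        raise ValueError("n_rays must be >= 8")
    theta_max = beam.cone_half_angle_rad
    u_max = float(np.sin(theta_max) ** 2)

    n_u = max(1, int(round(np.sqrt(n_rays / 8.0))))
    n_phi = max(8, n_rays // n_u)
    u = (np.arange(n_u) + 0.5) / n_u * u_max
    phi = (np.arange(n_phi) + 0.5) / n_phi * 2.0 * np.pi

    uu, pp = np.meshgrid(u, phi, indexing="ij")
    uu, pp = uu.ravel(), pp.ravel()
    sin_a = np.sqrt(uu)
    cos_a = np.sqrt(1.0 - uu)
    directions = np.column_stack(
        [sin_a * np.cos(pp), sin_a * np.sin(pp), cos_a]
    )

    if beam.aperture_fill == "uniform":
        weights = np.full(uu.shape, 1.0 / uu.size)
    else:  # gaussian fill: intensity exp(-2 rho^2 / w^2), rho^2 ∝ u
        w2 = (beam.fill_fraction**2) * u_max
        weights = np.exp(-2.0 * uu / w2)
        weights /= weights.sum()

    return RayBundle(directions=directions, weights=weights, polarization=polarization)


def _fresnel_reflectance(
    n1: float, n2: float, cos_i: np.ndarray, polarization: str
) -> tuple[np.ndarray, np.ndarray]:
    """Reflectance R and refraction cosine for incidence cosines ``cos_i``.

    Total internal reflection (possible only for n2 < n1) gives R = 1.
    """
    sin_i = np.sqrt(np.clip(1.0 - cos_i**2, 0.0, 1.0))
    sin_t = n1 / n2 * sin_i
    tir = sin_t > 1.0
    cos_t = np.sqrt(np.clip(1.0 - np.minimum(sin_t, 1.0) ** 2, 0.0, 1.0))

    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    if polarization == "s":
        refl = rs
    elif polarization == "p":
        refl = rp
    else:
        refl = 0.5 * (rs + rp)
    refl = np.where(tir, 1.0, refl)
    return refl, cos_t


def _q_contributions(
    directions: np.ndarray,
    trap_position: np.ndarray,
    radius: float,
    n_particle: float,
    n_medium: float,
    polarization: str,
) -> np.ndarray:
    """Per-ray beam-reaction Q vectors (n, 3); misses contribute zero.

    Each ray is the straight line through the focal point ``trap_position``
    (coordinates relative to the sphere centre).  The momentum transfer is
    the Ashkin closed form: with incidence angle ``theta`` and refraction
    angle ``r``,

        Qs + i*Qg = 1 + R e^{2i theta} - T^2 e^{2i(theta - r)} / (1 + R e^{2i r})

    giving the force on the *sphere* as ``Qs d - Qg a2`` where ``d`` is the
    ray direction and ``a2`` the in-plane unit vector along the transverse
    part of the outward surface normal.  The returned vectors are negated to
    the beam-reaction convention.
    """
    d = directions
    p = np.asarray(trap_position, dtype=float)
    b = d @ p
    disc = b**2 - (p @ p - radius**2)
    hit = disc > 0.0
    if not np.any(hit):
        return np.zeros_like(d)

    dh = d[hit]
    t0 = -b[hit] - np.sqrt(disc[hit])
    x0 = p[None, :] + t0[:, None] * dh
    normal = x0 / radius
    cos_i = np.clip(-np.sum(dh * normal, axis=1), 0.0, 1.0)

    refl, cos_t = _fresnel_reflectance(n_medium, n_particle, cos_i, polarization)
    trans = 1.0 - refl
    theta = np.arccos(cos_i)
    r_ang = np.arccos(cos_t)

    z = (
        1.0
        + refl * np.exp(2j * theta)
        - trans**2 * np.exp(2j * (theta - r_ang)) / (1.0 + refl * np.exp(2j * r_ang))
    )
    qs, qg = z.real, z.imag

    sin_i = np.sqrt(np.clip(1.0 - cos_i**2, 0.0, 1.0))
    a2 = normal + cos_i[:, None] * dh
    with np.errstate(invalid="ignore", divide="ignore"):
        a2 = np.where(sin_i[:, None] > 1e-12, a2 / sin_i[:, None], 0.0)

    on_sphere = qs[:, None] * dh - qg[:, None] * a2
    out = np.zeros_like(d)
    out[hit] = -on_sphere  # reaction on the beam
    return out


def single_ray_momentum_transfer(
    direction: np.ndarray,
    sphere: SphereParticle,
    focus_offset: np.ndarray,
    medium_index: float = 1.33,
    polarization: str = "average",
) -> np.ndarray:
    """Q contribution (beam-reaction convention) of one unit-power ray.

    ``focus_offset`` is the focal point relative to the sphere centre, µm.
    A ray that misses the sphere contributes the zero vector.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return _q_contributions(
        d[None, :],
        np.asarray(focus_offset, dtype=float),
        sphere.radius_um,
        sphere.index,
        medium_index,
        polarization,
    )[0]


def _force_scale_pn(beam: TrapBeam) -> float:
    # n_m * P / c, expressed in piconewtons per unit Q
    return beam.medium_index * beam.power_mw * 1e-3 / SPEED_OF_LIGHT * 1e12


def trap_force(
    beam: TrapBeam,
    sphere: SphereParticle,
    trap_position_um,
    n_rays: int = DEFAULT_N_RAYS,
    rays: RayBundle | None = None,
) -> ForceResult:
    """Total Q and force for a trap focused at ``trap_position_um``.

    Positions are relative to the sphere centre, µm.  ``rays`` may be passed
    to reuse a fan across many positions; otherwise a stratified fan of
    ``n_rays`` is built.  The force is exactly linear in beam power.
    """
    if rays is None:
        rays = sample_ray_fan(beam, n_rays)
    pos = np.asarray(trap_position_um, dtype=float)
    if pos.shape == (2,):
        pos = np.array([pos[0], pos[1], 0.0])
    q_rays = _q_contributions(
        rays.directions,
        pos,
        sphere.radius_um,
        sphere.index,
        beam.medium_index,
        rays.polarization,
    )
    q = rays.weights @ q_rays
    return ForceResult(q_vector=q, force_pn=q * _force_scale_pn(beam), trap_position_um=pos)


def q_profile(
    beam: TrapBeam,
    sphere: SphereParticle,
    axis,
    offsets_um,
    n_rays: int = DEFAULT_N_RAYS,
) -> list[ForceResult]:
    """Q and force along a diameter ``axis`` (unit 2-vector) of the z=0 plane.

    Offsets should stay within ±1.5 sphere radii; a trap below centre on the
    y axis gives a positive y force (beam-reaction convention).
    """
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    rays = sample_ray_fan(beam, n_rays)
    return [
        trap_force(beam, sphere, np.array([ax[0] * s, ax[1] * s, 0.0]), rays=rays)
        for s in np.asarray(offsets_um, dtype=float)
    ]


def force_map(
    beam: TrapBeam,
    sphere: SphereParticle,
    positions_um,
    n_rays: int = DEFAULT_N_RAYS,
) -> ForceField:
    """Q and force at each node of a 2-D grid of trap positions (z = 0).

    ``positions_um`` is an (m, 2) array.  Node values are independent, so any
    sub-grid reproduces the full map at shared nodes exactly.  For an
    isotropic sphere the field is radial.
    """
    pts = np.asarray(positions_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("positions_um must be (m, 2)")
    rays = sample_ray_fan(beam, n_rays)
    q = np.empty((pts.shape[0], 3))
    for i, (x, y) in enumerate(pts):
        q[i] = trap_force(beam, sphere, np.array([x, y, 0.0]), rays=rays).q_vector
    return ForceField(positions_um=pts, q=q, force_pn=q * _force_scale_pn(beam))


def scaled_beam(beam: TrapBeam, power_mw: float) -> TrapBeam:
    """Copy of ``beam`` at a different power."""
    return replace(beam, power_mw=power_mw)
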