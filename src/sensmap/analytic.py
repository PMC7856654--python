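"""Quasi-analytical sphere solutions used as ground truth for FEM validation.

* EEG: truncated Legendre-series potential of a current dipole inside a
  multilayer concentric-sphere conductor with an insulating exterior.  The
  per-degree radial transmission problem is solved with radius-normalized
  basis functions so no term over- or underflows at high harmonic degree.
* MEG: the Sarvas closed form for the total magnetic field of a dipole in a
  spherically symmetric conductor.  Radial dipoles produce exactly zero
  external field; the field does not depend on the conductivity profile.

Inputs are in the package's I/O units (mm, nAm); outputs in uV / fT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre, lpmv

__all__ = [
    "SphereModel",
    "eeg_sphere_potential",
    "eeg_homogeneous_surface_potential",
    "meg_sphere_field",
    "rdm",
    "lnmag",
]

_MU0 = 4e-7 * np.pi  # T m / A


@dataclass
class SphereModel:
    """Concentric-sphere conductor: increasing shell radii (mm), isotropic S/m."""

    radii: np.ndarray          # (L,) outer radius of each shell, increasing, mm
    conductivities: np.ndarray  # (L,) S/m, innermost first
    center: np.ndarray = None  # mm

    def __post_init__(self) -> None:
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        self.conductivities = np.atleast_1d(np.asarray(self.conductivities, dtype=float))
        if self.center is None:
            self.center = np.zeros(3)
        self.center = np.asarray(self.center, dtype=float)
        if len(self.radii) != len(self.conductivities):
            raise ValueError("one conductivity per shell required")
        if np.any(np.diff(self.radii) <= 0) or self.radii[0] <= 0:
            raise ValueError("radii must be positive and strictly increasing")
        if np.any(self.conductivities <= 0):
            raise ValueError("conductivities must be positive")


def _radial_transmission(model: SphereModel, n: int, b_scaled: float) -> float:
    """Surface factor t_n: outer-surface radial solution for a unit source term.

    Source radial dependence is ``b^(n-1) / r^(n+1)`` (scaled units, outer
    radius = 1).  Layer bases are ``(r/r_out)^n`` and ``(r_in/r)^(n+1)``,
    bounded on their layers, which keeps the linear system well-conditioned
    for harmonic degrees in the hundreds.
    """
    x = model.radii / model.radii[-1]   # scaled interface radii, x[-1] == 1
    sig = model.conductivities
    L = len(x)
    src = b_scaled ** (n - 1) if (b_scaled > 0 or n == 1) else 0.0

    if L == 1:
        # single layer: closed-form, sigma u'(1) = 0
        # u = A r^n + src / r^(n+1);  A n - (n+1) src = 0
        a1 = (n + 1) * src / n
        return a1 + src

    m = 2 * L - 1
    A = np.zeros((m, m))
    rhs = np.zeros(m)
    # unknown ordering: [A1, A2, B2, A3, B3, ...]
    col_a = lambda j: 0 if j == 0 else 2 * j - 1
    col_b = lambda j: 2 * j  # j >= 1

    def f_val(j, r):   # (r / x[j])^n
        return (r / x[j]) ** n

    def g_val(j, r):   # (x[j-1] / r)^(n+1)
        return (x[j - 1] / r) ** (n + 1)

    row = 0
    for j in range(L - 1):
        r = x[j]
        # potential continuity at interface j | j+1
        A[row, col_a(j)] += f_val(j, r)
        if j >= 1:
            A[row, col_b(j)] += g_val(j, r)
        A[row, col_a(j + 1)] -= f_val(j + 1, r)
        A[row, col_b(j + 1)] -= g_val(j + 1, r)
        if j == 0:
            rhs[row] = -src / r ** (n + 1)
        row += 1
        # radial current continuity: sigma * u'
        A[row, col_a(j)] += sig[j] * n / r * f_val(j, r)
        if j >= 1:
            A[row, col_b(j)] -= sig[j] * (n + 1) / r * g_val(j, r)
        A[row, col_a(j + 1)] -= sig[j + 1] * n / r * f_val(j + 1, r)
        A[row, col_b(j + 1)] += sig[j + 1] * (n + 1) / r * g_val(j + 1, r)
        if j == 0:
            rhs[row] = sig[0] * (n + 1) * src / r ** (n + 2)
        row += 1
    # outer insulating boundary at r = 1
    A[row, col_a(L - 1)] = n
    A[row, col_b(L - 1)] = -(n + 1) * g_val(L - 1, 1.0)

    sol = np.linalg.solve(A, rhs)
    return sol[col_a(L - 1)] + sol[col_b(L - 1)] * g_val(L - 1, 1.0)


def eeg_sphere_potential(
    model: SphereModel,
    dipole_position,
    dipole_moment,
    electrode_positions,
    n_max: int = 200,
    rtol: float = 1e-8,
    max_eccentricity: float = 0.95,
) -> np.ndarray:
    """Surface potential (uV) of a dipole (position mm, moment nAm vector).

    Electrodes on or outside the outer radius are evaluated at their radial
    projection onto the surface.  The series is truncated adaptively: summation
    stops once a block of 10 further degrees changes no electrode value by more
    than ``rtol`` relative to the running maximum magnitude.
    """
    p0 = np.asarray(dipole_position, dtype=float) - model.center
    m = np.asarray(dipole_moment, dtype=float)  # nAm
    elec = np.atleast_2d(np.asarray(electrode_positions, dtype=float)) - model.center

    R = model.radii[-1]
    b = float(np.linalg.norm(p0))
    if b >= model.radii[0]:
        raise ValueError("dipole must lie strictly inside the innermost shell")
    if b / model.radii[0] > max_eccentricity:
        raise ValueError(
            f"dipole eccentricity {b / model.radii[0]:.3f} exceeds "
            f"{max_eccentricity}; series would converge too slowly"
        )
    er = np.linalg.norm(elec, axis=1)
    if np.any(er < R * (1 - 1e-9)):
        raise ValueError("electrodes must lie on or outside the outer radius")

    # local frame: z along the dipole position, x along the tangential moment
    if b > 1e-12 * R:
        ez = p0 / b
    else:
        b = 0.0
        nm = np.linalg.norm(m)
        ez = m / nm if nm > 0 else np.array([0.0, 0.0, 1.0])
    m_r = float(m @ ez)
    mt_vec = m - m_r * ez
    m_t = float(np.linalg.norm(mt_vec))
    if m_t > 1e-14 * max(np.linalg.norm(m), 1.0):
        ex = mt_vec / m_t
    else:
        m_t = 0.0
        ex = np.array([1.0, 0.0, 0.0])
        if abs(ez[0]) > 0.9:
            ex = np.array([0.0, 1.0, 0.0])
        ex = ex - (ex @ ez) * ez
        ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)

    u = elec / er[:, None]     # radial projection onto the surface
    cos_t = np.clip(u @ ez, -1.0, 1.0)
    az_x, az_y = u @ ex, u @ ey
    az = np.hypot(az_x, az_y)
    cos_p = np.where(az > 1e-15, az_x / np.maximum(az, 1e-300), 1.0)

    b_sc = b / R
    # SI prefactor: moment nAm -> A m (1e-9), radius mm -> m (1e-3), V -> uV (1e6)
    # t_n carries 1/R_m^2 through the scaled radial solution / R_m^2
    R_m = R * 1e-3
    pref = 1e-9 / (4.0 * np.pi * model.conductivities[0] * R_m ** 2) * 1e6

    total = np.zeros(len(elec))
    unchanged = 0
    for n in range(1, n_max + 1):
        t_n = _radial_transmission(model, n, b_sc)
        term = t_n * (
            n * m_r * eval_legendre(n, cos_t)
            - m_t * lpmv(1, n, cos_t) * cos_p
        )
        total += term
        scale = np.max(np.abs(total)) + 1e-300
        if np.max(np.abs(term)) < rtol * scale:
            unchanged += 1
            if unchanged >= 10:
                break
        else:
            unchanged = 0
    return pref * total


def eeg_homogeneous_surface_potential(
    radius: float,
    sigma: float,
    dipole_position,
    dipole_moment,
    electrode_positions,
    n_max: int = 200,
) -> np.ndarray:
    """Independent closed-form series for the homogeneous sphere (uV).

    For a single shell the per-degree surface factor reduces to
    ``(2n+1)/n * b^(n-1) / R^(n+1)`` — coded directly, without the multilayer
    transmission machinery, to serve as an independent oracle for it.
    """
    p0 = np.asarray(dipole_position, dtype=float)
    m = np.asarray(dipole_moment, dtype=float)
    elec = np.atleast_2d(np.asarray(electrode_positions, dtype=float))

    b = float(np.linalg.norm(p0))
    if b > 1e-12 * radius:
        ez = p0 / b
    else:
        b = 0.0
        nm = np.linalg.norm(m)
        ez = m / nm if nm > 0 else np.array([0.0, 0.0, 1.0])
    m_r = float(m @ ez)
    mt_vec = m - m_r * ez
    m_t = float(np.linalg.norm(mt_vec))
    ex = mt_vec / m_t if m_t > 0 else np.array([1.0, 0.0, 0.0])
    if m_t == 0 and abs(ez[0]) > 0.9:
        ex = np.array([0.0, 1.0, 0.0])
    if m_t == 0:
        ex = ex - (ex @ ez) * ez
        ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)

    er = np.linalg.norm(elec, axis=1)
    u = elec / er[:, None]
    cos_t = np.clip(u @ ez, -1.0, 1.0)
    az_x, az_y = u @ ex, u @ ey
    az = np.hypot(az_x, az_y)
    cos_p = np.where(az > 1e-15, az_x / np.maximum(az, 1e-300), 1.0)

    b_sc = b / radius
    R_m = radius * 1e-3
    pref = 1e-9 / (4.0 * np.pi * sigma * R_m ** 2) * 1e6
    total = np.zeros(len(elec))
    for n in range(1, n_max + 1):
        src = b_sc ** (n - 1) if (b_sc > 0 or n == 1) else 0.0
        t_n = (2 * n + 1) / n * src
        total += t_n * (
            n * m_r * eval_legendre(n, cos_t) - m_t * lpmv(1, n, cos_t) * cos_p
        )
        if src < 1e-16 and n > 1:
            break
    return pref * total


def meg_sphere_field(
    center,
    dipole_position,
    dipole_moment,
    point,
) -> np.ndarray:
    """Sarvas closed-form total magnetic field (fT vector) outside a sphere.

    ``dipole_moment`` in nAm; positions in mm.  The result depends only on the
    sphere center, not on radii or conductivities, and vanishes identically
    for radial dipoles.
    """
    c = np.asarray(center, dtype=float)
    r0 = (np.asarray(dipole_position, dtype=float) - c) * 1e-3   # m
    r = (np.asarray(point, dtype=float) - c) * 1e-3              # m
    q = np.asarray(dipole_moment, dtype=float) * 1e-9            # A m

    if np.linalg.norm(r) <= np.linalg.norm(r0):
        raise ValueError("field point must lie strictly outside the dipole radius")
    a_v = r - r0
    a = np.linalg.norm(a_v)
    rn = np.linalg.norm(r)
    if a < 1e-12:
        raise ValueError("field point coincides with the dipole")
    F = a * (rn * a + rn ** 2 - r0 @ r)
    if abs(F) < 1e-12 * (rn ** 2) * max(a, rn):
        raise ValueError("evaluation point on the Sarvas singular line")
    gradF = (a ** 2 / rn + (a_v @ r) / a + 2.0 * a + 2.0 * rn) * r - (
        a + 2.0 * rn + (a_v @ r) / a
    ) * r0
    qxr0 = np.cross(q, r0)
    B = _MU0 / (4.0 * np.pi * F ** 2) * (F * qxr0 - (qxr0 @ r) * gradF)
    return B * 1e15  # T -> fT


def rdm(u, v) -> float:
    """Relative difference measure (topography error) between two vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("RDM undefined for a zero vector")
    return float(np.linalg.norm(u / nu - v / nv))


def lnmag(u, v) -> float:
    """ln of the magnitude ratio ||u|| / ||v||."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("MAG undefined for a zero vector")
    return float(np.log(nu / nv))
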