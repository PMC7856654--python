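"""Triangulated surfaces: synthetic folded cortex and spherical reference shells."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = ["TriSurface", "sphere_surface", "synth_cortex_surface"]


@dataclass
class TriSurface:
    """Closed triangle surface with outward unit vertex normals (mm)."""

    vertices: np.ndarray   # (n, 3) mm
    triangles: np.ndarray  # (m, 3) int
    normals: np.ndarray    # (n, 3) unit, outward

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.normals = np.asarray(self.normals, dtype=float)
        if len(self.normals) != len(self.vertices):
            raise ValueError("one normal per vertex required")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def is_closed_manifold(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    def enclosed_volume(self) -> float:
        return float(self.as_trimesh().volume)


def _vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals, normalized."""
    v = vertices[triangles]
    fn = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])  # 2*area*unit
    normals = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(normals, triangles[:, k], fn)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return normals / norm


def sphere_surface(radius: float, subdivisions: int = 4, center=(0.0, 0.0, 0.0)) -> TriSurface:
    """Icosphere surface of given radius; normals exactly radial."""
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    unit = np.asarray(s.vertices) / np.linalg.norm(s.vertices, axis=1, keepdims=True)
    verts = unit * radius + np.asarray(center, dtype=float)
    return TriSurface(verts, np.asarray(s.faces, dtype=np.int64), unit.copy())


def synth_cortex_surface(
    base_radius: float,
    fold_amplitude: float,
    fold_frequency: int,
    mesh_resolution: int = 4,
    seed: int = 0,
    max_radius: float | None = None,
    sharpness: float = 3.0,
) -> TriSurface:
    """Radially folded sphere emulating a cortical (white-matter) surface.

    The radius field is ``r(u) = base_radius + fold_amplitude * f(u)`` with
    ``f`` a band-limited function in [-1, 1] built from random spherical
    waves of wavenumber ~ ``fold_frequency``, passed through a tanh
    waveshaper (``sharpness``) that flattens crests/troughs and steepens the
    transitions — gyral crowns and sulcal valleys connected by steep walls.
    Folding tilts the surface normals away from the radial direction,
    producing the full range of radial-to-tangential source orientations,
    and spreads vertex radii over ``base_radius ± fold_amplitude`` (a range
    of source depths).

    Parameters
    ----------
    base_radius, fold_amplitude : float
        mm.  ``base_radius + fold_amplitude`` must stay inside the brain
        compartment (checked against ``max_radius`` when given).
    fold_frequency : int
        Approximate angular wavenumber of the folds.
    mesh_resolution : int
        Icosphere subdivision level of the underlying sphere.
    seed : int
        Seeds the random wave directions/phases.
    """
    if fold_amplitude < 0:
        raise ValueError("fold_amplitude must be >= 0")
    if max_radius is not None and base_radius + fold_amplitude >= max_radius:
        raise ValueError("folded surface would escape the brain compartment")

    s = trimesh.creation.icosphere(subdivisions=mesh_resolution, radius=1.0)
    unit = np.asarray(s.vertices) / np.linalg.norm(s.vertices, axis=1, keepdims=True)
    faces = np.asarray(s.faces, dtype=np.int64)

    if fold_amplitude == 0:
        verts = unit * base_radius
        return TriSurface(verts, faces, unit.copy())

    rng = np.random.default_rng(seed)
    n_waves = 24
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    amps = rng.uniform(0.5, 1.0, size=n_waves)
    # random plane waves restricted to the sphere give folds of wavelength
    # ~ 2*pi*base_radius / fold_frequency
    # wavelength ~ 2 * base_radius / fold_frequency along the surface
    f = np.zeros(len(unit))
    for d, p, a in zip(dirs, phases, amps):
        f += a * np.sin(np.pi * fold_frequency * (unit @ d) + p)
    f /= np.max(np.abs(f))
    if sharpness > 0:
        f = np.tanh(sharpness * f) / np.tanh(sharpness)

    verts = unit * (base_radius + fold_amplitude * f)[:, None]
    surf = TriSurface(verts, faces, _vertex_normals(verts, faces))
    if surf.enclosed_volume() <= 0:
        raise ValueError("degenerate folded surface (non-positive volume)")
    return surf
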