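"""Dipole source spaces and their depth/angle covariates.

Cortical dipoles: one per surface vertex of the (synthetic) white-matter
surface, moved to the centroid of the nearest gray-matter element and
oriented along the vertex normal — co-located dipoles with different
orientations are expected and kept.  Subcortical dipoles: Cartesian triplets
(x, y, z orientations) at every node of each region mesh.

Depth is the Euclidean distance to the closest *vertex* of the inner-skull
surface; angle is measured against the outward normal at that vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .meshing import LabeledTetMesh
from .surfaces import TriSurface

__all__ = [
    "DipoleSet",
    "BinnedSummary",
    "cortical_dipoles_from_surface",
    "subcortical_dipoles_from_regions",
    "source_depths",
    "source_angles",
    "bin_values",
]


@dataclass
class DipoleSet:
    """Point dipoles with orientations, grouping and covariates."""

    positions: np.ndarray        # (n, 3) mm
    orientations: np.ndarray     # (n, 3) unit
    group: np.ndarray            # (n,) int; triplets share a group id
    kind: np.ndarray             # (n,) "cortical" | "subcortical"
    region: np.ndarray           # (n,) region name, "" for cortical
    depth: np.ndarray | None = field(default=None)   # mm, once computed
    angle: np.ndarray | None = field(default=None)   # degrees, once computed

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        self.group = np.asarray(self.group)
        self.kind = np.asarray(self.kind)
        self.region = np.asarray(self.region)
        n = len(self.positions)
        if not (len(self.orientations) == len(self.group) == len(self.kind)
                == len(self.region) == n):
            raise ValueError("inconsistent dipole arrays")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("orientations must be unit vectors")

    def __len__(self) -> int:
        return len(self.positions)

    @staticmethod
    def concatenate(sets: list["DipoleSet"]) -> "DipoleSet":
        offs, groups = 0, []
        for s in sets:
            groups.append(s.group + offs)
            offs += s.group.max(initial=-1) + 1
        return DipoleSet(
            np.vstack([s.positions for s in sets]),
            np.vstack([s.orientations for s in sets]),
            np.concatenate(groups),
            np.concatenate([s.kind for s in sets]),
            np.concatenate([s.region for s in sets]),
        )


@dataclass
class BinnedSummary:
    """Equal-width binning with per-bin five-number summaries."""

    edges: np.ndarray            # (n_bins + 1,)
    counts: np.ndarray           # (n_bins,)
    five_number: np.ndarray      # (n_bins, 5): min, Q1, median, Q3, max (NaN if empty)

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def cortical_dipoles_from_surface(
    surface: TriSurface,
    mesh: LabeledTetMesh,
    gray_labels,
) -> DipoleSet:
    """One dipole per surface vertex, at the nearest gray-element centroid.

    ``gray_labels`` may be a single label id or a collection (for the merged
    "brain" compartment of the coarser variants).  Several vertices may map
    to the same centroid; each keeps its own normal orientation.  Dipoles
    sharing a centroid share a group id.
    """
    gray_labels = np.atleast_1d(np.asarray(gray_labels))
    sel = np.isin(mesh.labels, gray_labels)
    if not np.any(sel):
        raise ValueError("mesh has no gray-matter elements")
    centroids = mesh.element_centroids()[sel]
    tree = cKDTree(centroids)
    _, nearest = tree.query(surface.vertices)
    positions = centroids[nearest]
    orientations = surface.normals / np.linalg.norm(
        surface.normals, axis=1, keepdims=True
    )
    # dipoles landing on the same centroid share a location group
    _, group = np.unique(nearest, return_inverse=True)
    n = len(positions)
    return DipoleSet(
        positions, orientations, group,
        np.full(n, "cortical"), np.full(n, "", dtype=object),
    )


def subcortical_dipoles_from_regions(
    regions: list[tuple[str, LabeledTetMesh]],
) -> DipoleSet:
    """Cartesian orientation triplets at every node of each region mesh."""
    pos, ori, grp, reg = [], [], [], []
    g0 = 0
    eye = np.eye(3)
    for name, m in regions:
        nodes = m.nodes
        pos.append(np.repeat(nodes, 3, axis=0))
        ori.append(np.tile(eye, (len(nodes), 1)))
        grp.append(np.repeat(g0 + np.arange(len(nodes)), 3))
        reg.append(np.full(3 * len(nodes), name, dtype=object))
        g0 += len(nodes)
    n = sum(len(p) for p in pos)
    return DipoleSet(
        np.vstack(pos), np.vstack(ori), np.concatenate(grp),
        np.full(n, "subcortical"), np.concatenate(reg),
    )


def source_depths(dipoles: DipoleSet, inner_skull: TriSurface) -> np.ndarray:
    """Distance (mm) to the closest inner-skull *vertex* per dipole."""
    if inner_skull.n_vertices == 0:
        raise ValueError("inner-skull surface is empty")
    tree = cKDTree(inner_skull.vertices)
    d, _ = tree.query(dipoles.positions)
    dipoles.depth = d
    return d


def source_angles(dipoles: DipoleSet, inner_skull: TriSurface) -> np.ndarray:
    """Angle (deg, in [0, 180]) between orientation and the nearest vertex normal."""
    if inner_skull.n_vertices == 0:
        raise ValueError("inner-skull surface is empty")
    nrm = np.linalg.norm(inner_skull.normals, axis=1)
    if np.any(nrm < 1e-12):
        raise ValueError("inner-skull surface has zero-length normals")
    tree = cKDTree(inner_skull.vertices)
    _, idx = tree.query(dipoles.positions)
    n = inner_skull.normals[idx] / nrm[idx, None]
    cosa = np.clip(np.einsum("ij,ij->i", dipoles.orientations, n), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosa))
    dipoles.angle = angles
    return angles


def _five_number(values: np.ndarray) -> np.ndarray:
    # quartiles by linear interpolation of order statistics
    return np.percentile(values, [0, 25, 50, 75, 100], method="linear")


def bin_values(
    values,
    n_bins: int = 5,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, BinnedSummary]:
    """Equal-width binning plus per-bin five-number summaries.

    Bins are right-open except the last, which is closed.  Returns the
    per-value bin assignment (-1 for values outside the range) and the
    summary.  Empty input yields an empty (all-NaN) summary.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = np.asarray(values, dtype=float).ravel()
    if len(values) and not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if value_range is None:
        if len(values) == 0:
            value_range = (0.0, 1.0)
        else:
            value_range = (float(values.min()), float(values.max()))
    lo, hi = map(float, value_range)
    if not hi > lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)

    idx = np.floor((values - lo) / (hi - lo) * n_bins).astype(int)
    idx[values == hi] = n_bins - 1          # last bin closed
    idx[(values < lo) | (values > hi)] = -1

    counts = np.zeros(n_bins, dtype=int)
    five = np.full((n_bins, 5), np.nan)
    for b in range(n_bins):
        vals = values[idx == b]
        counts[b] = len(vals)
        if len(vals):
            five[b] = _five_number(vals)
    return idx, BinnedSummary(edges, counts, five)
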