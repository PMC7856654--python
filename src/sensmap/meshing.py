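"""Tetrahedral volume-conductor meshes.

Layered-sphere head phantoms are built by radially extruding a subdivided
icosahedron: every radial layer shares the same spherical triangulation, so
compartment interfaces fall exactly on node layers and each shell is resolved
by at least one element layer regardless of its thickness.  Prisms between
consecutive layers are split into three tetrahedra with the minimum-vertex
diagonal rule, which guarantees a conforming mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "LabeledTetMesh",
    "build_layered_sphere_mesh",
    "build_ball_mesh",
    "default_label_names",
]

#: compartment name conventions, innermost shell first
default_label_names = {
    1: ["brain"],
    3: ["brain", "skull", "scalp"],
    4: ["brain", "csf", "skull", "scalp"],
    6: [
        "white_matter",
        "gray_matter",
        "csf",
        "skull_spongiosa",
        "skull_compacta",
        "scalp",
    ],
}


@dataclass
class LabeledTetMesh:
    """Tetrahedral mesh with one compartment label per element.

    Coordinates are in mm (the anatomical convention); FEM code converts to SI
    internally.
    """

    nodes: np.ndarray          # (n_nodes, 3) mm
    elements: np.ndarray       # (n_elements, 4) int node indices, positive volume
    labels: np.ndarray         # (n_elements,) int compartment id
    label_names: dict[int, str] = field(default_factory=dict)

    _centroid_tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (n, 4)")
        if len(self.labels) != len(self.elements):
            raise ValueError("one label per element required")
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=0) >= len(self.nodes):
            raise ValueError("element node index out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_vertices(self) -> np.ndarray:
        """(n_elements, 4, 3) vertex coordinates."""
        return self.nodes[self.elements]

    def element_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes (mm^3); positive for valid ordering."""
        v = self.element_vertices()
        a, b, c = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.element_vertices().mean(axis=1)

    def centroid_tree(self) -> cKDTree:
        if self._centroid_tree is None:
            self._centroid_tree = cKDTree(self.element_centroids())
        return self._centroid_tree

    def locate_element(self, point: np.ndarray, k: int = 32) -> int:
        """Element containing ``point`` (mm); ties broken by lowest index.

        Raises ValueError if the point lies outside the mesh.
        """
        point = np.asarray(point, dtype=float)
        n = self.n_elements
        k = min(k, n)
        _, cand = self.centroid_tree().query(point, k=k)
        cand = np.atleast_1d(cand)
        hit = _first_containing(self, np.sort(cand), point)
        if hit >= 0:
            return hit
        # fall back to a full scan before declaring the point outside
        hit = _first_containing(self, np.arange(n), point)
        if hit >= 0:
            return hit
        raise ValueError(f"point {point} lies outside the mesh")

    def barycentric(self, element: int, point: np.ndarray) -> np.ndarray:
        v = self.nodes[self.elements[element]]
        t = np.column_stack([v[1] - v[0], v[2] - v[0], v[3] - v[0]])
        lam = np.linalg.solve(t, np.asarray(point, dtype=float) - v[0])
        return np.concatenate([[1.0 - lam.sum()], lam])

    def boundary_triangles(self) -> np.ndarray:
        """Triangles of the outer boundary (faces shared by a single element)."""
        faces = _element_faces(self.elements)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def boundary_node_indices(self) -> np.ndarray:
        return np.unique(self.boundary_triangles())

    def interface_triangles(self, inner_label: int, outer_label: int) -> np.ndarray:
        """Triangles on the interface between two compartments."""
        faces = _element_faces(self.elements)
        owner = np.repeat(np.arange(self.n_elements), 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort(key.T[::-1])
        key_s, faces_s, owner_s = key[order], faces[order], owner[order]
        same = np.all(key_s[:-1] == key_s[1:], axis=1)
        la, lb = self.labels[owner_s[:-1][same]], self.labels[owner_s[1:][same]]
        sel = ((la == inner_label) & (lb == outer_label)) | (
            (la == outer_label) & (lb == inner_label)
        )
        return faces_s[:-1][same][sel]


def _element_faces(elements: np.ndarray) -> np.ndarray:
    """All 4 faces of every element, outward-oriented for positive tets."""
    e = elements
    return np.concatenate(
        [
            e[:, [1, 2, 3]],
            e[:, [0, 3, 2]],
            e[:, [0, 1, 3]],
            e[:, [0, 2, 1]],
        ],
        axis=0,
    ).reshape(4, -1, 3).transpose(1, 0, 2).reshape(-1, 3)


def _first_containing(mesh: LabeledTetMesh, candidates: np.ndarray, point: np.ndarray,
                      tol: float = 1e-9) -> int:
    for e in candidates:
        lam = mesh.barycentric(int(e), point)
        if np.all(lam >= -tol):
            return int(e)
    return -1


def _fix_orientation(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    v = nodes[elements]
    a, b, c = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c))
    flip = vol < 0
    elements = elements.copy()
    elements[flip] = elements[flip][:, [0, 1, 3, 2]]
    return elements


def _icosphere(subdivisions: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere vertices/faces, optionally rotated by a seeded rotation.

    The random rotation decorrelates mesh symmetry axes from sensor lattices.
    """
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts, faces = np.asarray(s.vertices, dtype=float), np.asarray(s.faces, dtype=np.int64)
    if seed is not None:
        rng = np.random.default_rng(seed)
        q = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(q)
        if np.linalg.det(rot) < 0:
            rot[:, 0] = -rot[:, 0]
        verts = verts @ rot.T
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return verts, faces


def _pick_subdivisions(outer_radius: float, target_edge: float) -> int:
    # base icosahedron edge for unit circumradius is 4/sqrt(10+2*sqrt(5))
    base_edge = 4.0 / np.sqrt(10.0 + 2.0 * np.sqrt(5.0))
    n = int(np.clip(np.round(np.log2(base_edge * outer_radius / target_edge)), 1, 6))
    return n


def _radial_layers(radii: list[float], target_edge: float) -> np.ndarray:
    """Radial node layers: shell interfaces pinned, interiors filled ~uniformly."""
    layers = []
    prev = 0.0
    for r in radii:
        nlay = max(1, int(round((r - prev) / target_edge)))
        layers.extend(prev + (r - prev) * (np.arange(1, nlay + 1) / nlay))
        prev = r
    return np.array(sorted(set(np.round(layers, 9))))


def _split_prisms(bot: np.ndarray, top: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Split prisms between two node layers into 3 tets each.

    ``bot``/``top`` are per-layer node index offsets applied to ``faces``.
    Quad-face diagonals run through the smallest global node index, so shared
    faces of neighbouring prisms agree and the mesh conforms.
    """
    b = bot[faces]           # (F, 3)
    t = top[faces]
    # rotate so b0 is the smallest bottom index
    amin = np.argmin(b, axis=1)
    idx = (amin[:, None] + np.arange(3)[None, :]) % 3
    rows = np.arange(len(b))[:, None]
    b = b[rows, idx]
    t = t[rows, idx]
    caseA = b[:, 1] < b[:, 2]
    tets = np.empty((len(b), 3, 4), dtype=np.int64)
    # diagonals b0-t1, b0-t2 always; third diagonal b1-t2 (A) or b2-t1 (B)
    tets[caseA, 0] = np.column_stack([b[caseA, 0], b[caseA, 1], b[caseA, 2], t[caseA, 2]])
    tets[caseA, 1] = np.column_stack([b[caseA, 0], b[caseA, 1], t[caseA, 2], t[caseA, 1]])
    tets[caseA, 2] = np.column_stack([b[caseA, 0], t[caseA, 1], t[caseA, 2], t[caseA, 0]])
    nB = ~caseA
    tets[nB, 0] = np.column_stack([b[nB, 0], b[nB, 1], b[nB, 2], t[nB, 1]])
    tets[nB, 1] = np.column_stack([b[nB, 0], b[nB, 2], t[nB, 2], t[nB, 1]])
    tets[nB, 2] = np.column_stack([b[nB, 0], t[nB, 2], t[nB, 0], t[nB, 1]])
    return tets.reshape(-1, 4)


def build_layered_sphere_mesh(
    radii,
    target_edge_length: float,
    seed: int = 0,
    label_names: list[str] | None = None,
) -> LabeledTetMesh:
    """Build a labeled tetrahedral mesh of concentric spherical shells.

    Parameters
    ----------
    radii : sequence of float
        Strictly increasing outer radii of the shells, mm.
    target_edge_length : float
        Requested edge length, mm.  Controls both the icosphere subdivision
        and the radial layer spacing; shell interfaces are always pinned.
    seed : int
        Seeds the random rotation applied to the icosphere axes.
    label_names : list of str, optional
        Compartment names innermost-first; defaults by shell count.
    """
    radii = [float(r) for r in radii]
    if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing and positive")
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be positive")
    if target_edge_length >= radii[0]:
        raise ValueError(
            "target_edge_length exceeds the innermost shell radius; "
            "the shell would be unresolved"
        )

    verts, faces = _icosphere(_pick_subdivisions(radii[-1], target_edge_length), seed=seed)
    layer_r = _radial_layers(radii, target_edge_length)
    nv = len(verts)

    nodes = np.vstack([[[0.0, 0.0, 0.0]]] + [verts * r for r in layer_r])
    offsets = [np.full(1, 0)] + [1 + k * nv + np.arange(nv) for k in range(len(layer_r))]

    tets = [np.column_stack([np.zeros(len(faces), dtype=np.int64),
                             offsets[1][faces[:, 0]],
                             offsets[1][faces[:, 1]],
                             offsets[1][faces[:, 2]]])]
    for k in range(len(layer_r) - 1):
        tets.append(_split_prisms(offsets[k + 1], offsets[k + 2], faces))
    elements = _fix_orientation(nodes, np.vstack(tets))

    centroids = nodes[elements].mean(axis=1)
    cr = np.linalg.norm(centroids, axis=1)
    labels = np.searchsorted(np.array(radii[:-1]), cr, side="right")

    if label_names is None:
        label_names = default_label_names.get(
            len(radii), [f"shell_{i}" for i in range(len(radii))]
        )
    if len(label_names) != len(radii):
        raise ValueError("need one label name per shell")
    mesh = LabeledTetMesh(nodes, elements, labels, dict(enumerate(label_names)))
    assert np.all(mesh.element_volumes() > 0)
    return mesh


def build_ball_mesh(
    center,
    radius: float,
    target_edge_length: float,
    seed: int = 0,
    label: int = 0,
    label_name: str = "region",
) -> LabeledTetMesh:
    """Small single-compartment tetrahedral ball (subcortical region stand-in)."""
    mesh = build_layered_sphere_mesh(
        [radius], target_edge_length, seed=seed, label_names=[label_name]
    )
    nodes = mesh.nodes + np.asarray(center, dtype=float)
    return LabeledTetMesh(
        nodes, mesh.elements, np.full(mesh.n_elements, label), {label: label_name}
    )
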