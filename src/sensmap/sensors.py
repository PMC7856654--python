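"""Point EEG electrodes and point MEG coils on/around the scalp."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .meshing import LabeledTetMesh

__all__ = ["SensorSet", "place_sensors", "fibonacci_sphere"]


@dataclass
class SensorSet:
    """Point sensors: electrode positions on the scalp, oriented coils outside it."""

    electrode_positions: np.ndarray   # (N_eeg, 3) mm, on scalp nodes
    electrode_labels: list[str]
    coil_positions: np.ndarray        # (N_meg, 3) mm, outside the scalp
    coil_orientations: np.ndarray     # (N_meg, 3) unit
    coil_labels: list[str]

    @property
    def n_eeg(self) -> int:
        return len(self.electrode_positions)

    @property
    def n_meg(self) -> int:
        return len(self.coil_positions)


def fibonacci_sphere(n: int, radius: float = 1.0, seed: int | None = None) -> np.ndarray:
    """Quasi-uniform points on a sphere (golden-angle spiral), seeded rotation."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    if seed is not None:
        rng = np.random.default_rng(seed)
        rot, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(rot) < 0:
            rot[:, 0] = -rot[:, 0]
        pts = pts @ rot.T
    return pts * radius


def place_sensors(
    mesh: LabeledTetMesh,
    n_electrodes: int = 71,
    n_coils: int = 271,
    coil_offset: float = 20.0,
    seed: int = 0,
) -> SensorSet:
    """Electrodes snapped to scalp mesh nodes, radial coils on an offset sphere.

    Electrode seeds come from a Fibonacci lattice at the scalp radius and are
    snapped to the closest scalp-boundary node (greedy, without reusing a
    node).  Coils sit on a sphere ``coil_offset`` mm outside the scalp with
    radial orientations — point-magnetometer stand-ins for axial gradiometers.
    """
    if n_electrodes <= 0 or n_coils <= 0:
        raise ValueError("sensor counts must be positive")
    if coil_offset <= 0:
        raise ValueError("coil_offset must be positive")

    boundary = mesh.boundary_node_indices()
    if n_electrodes > len(boundary):
        raise ValueError(
            f"{n_electrodes} electrodes requested but only {len(boundary)} scalp nodes"
        )
    scalp_nodes = mesh.nodes[boundary]
    scalp_radius = float(np.mean(np.linalg.norm(scalp_nodes, axis=1)))

    tree = cKDTree(scalp_nodes)
    seeds = fibonacci_sphere(n_electrodes, scalp_radius, seed=seed)
    taken: set[int] = set()
    elec_idx = []
    for p in seeds:
        for _, j in zip(*tree.query(p, k=min(8, len(scalp_nodes)))):
            j = int(j)
            if j not in taken:
                taken.add(j)
                elec_idx.append(j)
                break
        else:
            raise ValueError("could not find a free scalp node for an electrode")
    electrodes = scalp_nodes[elec_idx]

    coils = fibonacci_sphere(n_coils, scalp_radius + coil_offset, seed=seed + 1)
    orient = coils / np.linalg.norm(coils, axis=1, keepdims=True)

    return SensorSet(
        electrode_positions=electrodes,
        electrode_labels=[f"EEG{i + 1:03d}" for i in range(n_electrodes)],
        coil_positions=coils,
        coil_orientations=orient,
        coil_labels=[f"MEG{i + 1:03d}" for i in range(n_coils)],
    )
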