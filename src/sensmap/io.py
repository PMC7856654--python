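"""File I/O for the study's standard formats.

Volume meshes: Gmsh MSH v2.2 ASCII and VTU (XML unstructured grid), element
labels as integer cell data "compartment".  Surfaces: PLY or OFF with vertex
normals.  Scalar surface maps: legacy VTK PolyData ASCII with named
point-data arrays.  Sensors and dipoles: TSV.  Leadfields and baseline
recordings: HDF5.  Configs: YAML with an order-independent content hash.

Readers validate declared counts and reject truncated files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .fem import Leadfield
from .meshing import LabeledTetMesh
from .noise import BaselineRecording
from .sensors import SensorSet
from .sources import DipoleSet
from .surfaces import TriSurface

__all__ = [
    "write_msh", "read_msh", "write_vtu",
    "write_ply", "read_ply", "write_off",
    "write_vtk_polydata", "read_vtk_polydata", "write_surface_map",
    "write_sensors_tsv", "read_sensors_tsv",
    "write_dipoles_tsv", "read_dipoles_tsv",
    "write_leadfield_h5", "read_leadfield_h5",
    "write_baseline_h5", "read_baseline_h5",
    "config_hash", "save_config", "load_config_file",
]


# ---------------------------------------------------------------- volume mesh

def write_msh(mesh: LabeledTetMesh, path) -> None:
    """Gmsh MSH v2.2 ASCII; compartment label as the physical tag."""
    path = Path(path)
    with path.open("w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        if mesh.label_names:
            f.write("$PhysicalNames\n%d\n" % len(mesh.label_names))
            for lid, name in sorted(mesh.label_names.items()):
                f.write(f'3 {lid} "{name}"\n')
            f.write("$EndPhysicalNames\n")
        f.write("$Nodes\n%d\n" % mesh.n_nodes)
        for i, p in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        f.write("$EndNodes\n$Elements\n%d\n" % mesh.n_elements)
        for i, (e, lab) in enumerate(zip(mesh.elements, mesh.labels), start=1):
            f.write(
                f"{i} 4 2 {lab} {lab} {e[0] + 1} {e[1] + 1} {e[2] + 1} {e[3] + 1}\n"
            )
        f.write("$EndElements\n")


def read_msh(path) -> LabeledTetMesh:
    path = Path(path)
    lines = path.read_text().splitlines()
    it = iter(enumerate(lines))
    names: dict[int, str] = {}
    nodes = elements = labels = None
    try:
        for _, line in it:
            if line.strip() == "$PhysicalNames":
                n = int(next(it)[1])
                for _ in range(n):
                    parts = next(it)[1].split(maxsplit=2)
                    names[int(parts[1])] = parts[2].strip('"')
                assert next(it)[1].strip() == "$EndPhysicalNames"
            elif line.strip() == "$Nodes":
                n = int(next(it)[1])
                nodes = np.empty((n, 3))
                for k in range(n):
                    parts = next(it)[1].split()
                    nodes[k] = [float(x) for x in parts[1:4]]
                assert next(it)[1].strip() == "$EndNodes"
            elif line.strip() == "$Elements":
                n = int(next(it)[1])
                elements = np.empty((n, 4), dtype=np.int64)
                labels = np.empty(n, dtype=np.int64)
                for k in range(n):
                    parts = next(it)[1].split()
                    if parts[1] != "4":
                        raise ValueError("only tetrahedral elements supported")
                    ntags = int(parts[2])
                    labels[k] = int(parts[3]) if ntags else 0
                    elements[k] = [int(x) - 1 for x in parts[3 + ntags:7 + ntags]]
                assert next(it)[1].strip() == "$EndElements"
    except (StopIteration, AssertionError, IndexError) as exc:
        raise ValueError(f"truncated or malformed MSH file: {path}") from exc
    if nodes is None or elements is None:
        raise ValueError(f"MSH file missing nodes or elements: {path}")
    return LabeledTetMesh(nodes, elements, labels, names)


def write_vtu(mesh: LabeledTetMesh, path) -> None:
    """VTK XML unstructured grid, ASCII; labels as cell data "compartment"."""
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elements
    pts = " ".join(f"{x:.12g}" for x in mesh.nodes.ravel())
    conn = " ".join(str(i) for i in mesh.elements.ravel())
    offs = " ".join(str(4 * (i + 1)) for i in range(m))
    types = " ".join("10" for _ in range(m))
    labs = " ".join(str(x) for x in mesh.labels)
    path.write_text(f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
  <UnstructuredGrid>
    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">{pts}</DataArray>
      </Points>
      <Cells>
        <DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>
        <DataArray type="UInt8" Name="types" format="ascii">{types}</DataArray>
      </Cells>
      <CellData Scalars="compartment">
        <DataArray type="Int64" Name="compartment" format="ascii">{labs}</DataArray>
      </CellData>
    </Piece>
  </UnstructuredGrid>
</VTKFile>
""")


# ------------------------------------------------------------------- surfaces

def write_ply(surface: TriSurface, path) -> None:
    """ASCII PLY with per-vertex normals."""
    path = Path(path)
    with path.open("w") as f:
        f.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {surface.n_vertices}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property float nx\nproperty float ny\nproperty float nz\n"
            f"element face {len(surface.triangles)}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for v, nrm in zip(surface.vertices, surface.normals):
            f.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {nrm[0]:.9g} {nrm[1]:.9g} {nrm[2]:.9g}\n")
        for t in surface.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_ply(path) -> TriSurface:
    lines = Path(path).read_text().splitlines()
    nv = nf = None
    header_end = 0
    for i, line in enumerate(lines):
        if line.startswith("element vertex"):
            nv = int(line.split()[-1])
        elif line.startswith("element face"):
            nf = int(line.split()[-1])
        elif line.strip() == "end_header":
            header_end = i + 1
            break
    if nv is None or nf is None or len(lines) < header_end + nv + nf:
        raise ValueError(f"truncated or malformed PLY file: {path}")
    data = np.array(
        [[float(x) for x in lines[header_end + k].split()] for k in range(nv)]
    )
    tris = np.array(
        [[int(x) for x in lines[header_end + nv + k].split()[1:4]] for k in range(nf)],
        dtype=np.int64,
    )
    return TriSurface(data[:, :3], tris, data[:, 3:6])


def write_off(surface: TriSurface, path) -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write(f"OFF\n{surface.n_vertices} {len(surface.triangles)} 0\n")
        for v in surface.vertices:
            f.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in surface.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


# ---------------------------------------------------------- scalar surface map

def write_vtk_polydata(surface: TriSurface, scalars: dict[str, np.ndarray], path) -> None:
    """Legacy VTK PolyData ASCII with named per-vertex scalar arrays."""
    path = Path(path)
    for name, arr in scalars.items():
        arr = np.asarray(arr, dtype=float)
        if len(arr) != surface.n_vertices:
            raise ValueError(f"scalar {name!r} length does not match vertex count")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"scalar {name!r} contains non-finite values")
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\nsensmap surface map\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {surface.n_vertices} double\n")
        for v in surface.vertices:
            f.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        m = len(surface.triangles)
        f.write(f"POLYGONS {m} {4 * m}\n")
        for t in surface.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"POINT_DATA {surface.n_vertices}\n")
        for name, arr in scalars.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for x in np.asarray(arr, dtype=float):
                f.write(f"{x:.17g}\n")


def read_vtk_polydata(path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read back points, polygons, and named point-data scalar arrays."""
    lines = Path(path).read_text().splitlines()
    i = 0
    pts = polys = None
    scalars: dict[str, np.ndarray] = {}
    try:
        while i < len(lines):
            tok = lines[i].split()
            if tok and tok[0] == "POINTS":
                n = int(tok[1])
                pts = np.array(
                    [[float(x) for x in lines[i + 1 + k].split()] for k in range(n)]
                )
                i += n + 1
            elif tok and tok[0] == "POLYGONS":
                m = int(tok[1])
                polys = np.array(
                    [[int(x) for x in lines[i + 1 + k].split()[1:4]] for k in range(m)],
                    dtype=np.int64,
                )
                i += m + 1
            elif tok and tok[0] == "SCALARS":
                name = tok[1]
                n = len(pts)
                vals = np.array(
                    [float(lines[i + 2 + k]) for k in range(n)]
                )
                scalars[name] = vals
                i += n + 2
            else:
                i += 1
    except (IndexError, ValueError) as exc:
        raise ValueError(f"truncated or malformed VTK file: {path}") from exc
    if pts is None or polys is None:
        raise ValueError(f"VTK file missing points or polygons: {path}")
    return pts, polys, scalars


def write_surface_map(surface: TriSurface, scalars: dict[str, np.ndarray], path) -> None:
    """Per-vertex scalar map export (differential-SNR maps etc.)."""
    write_vtk_polydata(surface, scalars, path)


# -------------------------------------------------------------------- tables

def write_sensors_tsv(sensors: SensorSet, path) -> None:
    rows = []
    for lab, p in zip(sensors.electrode_labels, sensors.electrode_positions):
        rows.append((lab, *p, np.nan, np.nan, np.nan))
    for lab, p, o in zip(
        sensors.coil_labels, sensors.coil_positions, sensors.coil_orientations
    ):
        rows.append((lab, *p, *o))
    df = pd.DataFrame(rows, columns=["label", "x_mm", "y_mm", "z_mm", "ox", "oy", "oz"])
    df.to_csv(path, sep="\t", index=False)


def read_sensors_tsv(path) -> SensorSet:
    df = pd.read_csv(path, sep="\t")
    need = {"label", "x_mm", "y_mm", "z_mm"}
    if not need <= set(df.columns):
        raise ValueError(f"sensor TSV missing columns {need - set(df.columns)}")
    is_coil = df[["ox", "oy", "oz"]].notna().all(axis=1)
    e, c = df[~is_coil], df[is_coil]
    return SensorSet(
        e[["x_mm", "y_mm", "z_mm"]].to_numpy(float), list(e["label"]),
        c[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        c[["ox", "oy", "oz"]].to_numpy(float), list(c["label"]),
    )


def write_dipoles_tsv(dipoles: DipoleSet, path) -> None:
    df = pd.DataFrame({
        "x_mm": dipoles.positions[:, 0], "y_mm": dipoles.positions[:, 1],
        "z_mm": dipoles.positions[:, 2],
        "ox": dipoles.orientations[:, 0], "oy": dipoles.orientations[:, 1],
        "oz": dipoles.orientations[:, 2],
        "group": dipoles.group, "class": dipoles.kind, "region": dipoles.region,
    })
    df.to_csv(path, sep="\t", index=False)


def read_dipoles_tsv(path) -> DipoleSet:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return DipoleSet(
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        df[["ox", "oy", "oz"]].to_numpy(float),
        df["group"].to_numpy(int),
        df["class"].to_numpy(str),
        df["region"].to_numpy(str),
    )


# --------------------------------------------------------------------- HDF5

def write_leadfield_h5(path, lf_eeg: Leadfield | None, lf_meg: Leadfield | None,
                       attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        if lf_eeg is not None:
            f.create_dataset("eeg", data=lf_eeg.values)  # uV / nAm
        if lf_meg is not None:
            f.create_dataset("meg", data=lf_meg.values)  # fT / nAm
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def read_leadfield_h5(path) -> tuple[Leadfield | None, Leadfield | None, dict]:
    with h5py.File(path, "r") as f:
        lf_eeg = Leadfield(f["eeg"][()], "eeg") if "eeg" in f else None
        lf_meg = Leadfield(f["meg"][()], "meg") if "meg" in f else None
        attrs = dict(f.attrs)
    return lf_eeg, lf_meg, attrs


def write_baseline_h5(path, baseline: BaselineRecording,
                      eeg_variance: float, meg_variance: float) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=baseline.eeg)  # uV
        f.create_dataset("meg", data=baseline.meg)  # fT
        f.attrs["seed"] = -1 if baseline.seed is None else baseline.seed
        f.attrs["eeg_variance"] = eeg_variance
        f.attrs["meg_variance"] = meg_variance
        f.attrs["sfreq"] = baseline.sfreq


def read_baseline_h5(path) -> BaselineRecording:
    with h5py.File(path, "r") as f:
        return BaselineRecording(
            eeg=f["eeg"][()], meg=f["meg"][()],
            sfreq=float(f.attrs.get("sfreq", 1000.0)),
            seed=int(f.attrs.get("seed", -1)),
        )


# -------------------------------------------------------------------- config

def config_hash(config: dict) -> str:
    """Stable content hash: key order independent, 12 hex chars."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def save_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config_file(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data
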