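"""Gmsh MSH ASCII v2.2 subset reader/writer.

Supported blocks: ``$MeshFormat``, ``$PhysicalNames``, ``$Nodes``,
``$Elements`` with element types 2 (triangle) and 4 (tetrahedron).  Physical
tags become compartment names (tets) and patch names (triangles).  Node and
element numbering is 1-based on disk, 0-based in memory; an optional
``unit_scale`` multiplies coordinates on read (files in microns: 1e-6).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .geometry import TetMesh


class UnsupportedMshError(ValueError):
    pass


def _read_blocks(text: str) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                body.append(lines[j].strip())
                j += 1
            if j >= len(lines):
                raise UnsupportedMshError(f"unterminated block ${name}")
            blocks[name] = body
            i = j + 1
        else:
            i += 1
    return blocks


def read_gmsh(path, unit_scale: float = 1.0) -> TetMesh:
    """Read a tetrahedral mesh with physical tags from an MSH v2.2 file."""
    text = Path(path).read_text()
    blocks = _read_blocks(text)
    if "MeshFormat" not in blocks:
        raise UnsupportedMshError("missing $MeshFormat block")
    fmt = blocks["MeshFormat"][0].split()
    version, file_type = fmt[0], int(fmt[1])
    if file_type != 0:
        raise UnsupportedMshError("binary MSH files are not supported")
    if not version.startswith("2.2"):
        raise UnsupportedMshError(
            f"MSH version {version} not supported (ASCII v2.2 required)"
        )

    phys: dict[tuple[int, int], str] = {}
    if "PhysicalNames" in blocks:
        body = blocks["PhysicalNames"]
        n = int(body[0])
        for line in body[1 : 1 + n]:
            dim_s, tag_s, name = line.split(maxsplit=2)
            phys[(int(dim_s), int(tag_s))] = name.strip().strip('"')
    else:
        warnings.warn("MSH file has no $PhysicalNames; mesh will be tagless")

    body = blocks["Nodes"]
    n_nodes = int(body[0])
    node_ids = np.empty(n_nodes, dtype=np.int64)
    coords = np.empty((n_nodes, 3), dtype=np.float64)
    for r, line in enumerate(body[1 : 1 + n_nodes]):
        parts = line.split()
        node_ids[r] = int(parts[0])
        coords[r] = [float(x) for x in parts[1:4]]
    remap = {int(nid): r for r, nid in enumerate(node_ids)}
    coords *= unit_scale

    tets, tet_tag_ids, tris, tri_tag_ids = [], [], [], []
    body = blocks["Elements"]
    n_elem = int(body[0])
    for line in body[1 : 1 + n_elem]:
        parts = [int(x) for x in line.split()]
        etype, ntags = parts[1], parts[2]
        tags = parts[3 : 3 + ntags]
        nodes = [remap[n] for n in parts[3 + ntags :]]
        ptag = tags[0] if tags else -1
        if etype == 2:
            tris.append(nodes)
            tri_tag_ids.append(ptag)
        elif etype == 4:
            tets.append(nodes)
            tet_tag_ids.append(ptag)
        elif etype in (5, 6, 7):  # hexahedron, prism, pyramid
            raise UnsupportedMshError(
                f"non-tetrahedral 3D element type {etype} is not supported"
            )
        # points/lines (15, 1) are silently ignored

    if not tets:
        raise UnsupportedMshError("file contains no tetrahedrons")

    def resolve(dim, raw_ids):
        names, idx = [], []
        lut: dict[int, int] = {}
        for t in raw_ids:
            if t not in lut:
                lut[t] = len(names)
                names.append(phys.get((dim, t), f"tag{t}"))
            idx.append(lut[t])
        return names, np.asarray(idx, dtype=np.int64)

    comp_names, tet_tags = resolve(3, tet_tag_ids)
    patch_names, tri_tags = resolve(2, tri_tag_ids) if tris else ([], np.empty(0, np.int64))
    mesh = TetMesh(
        coords,
        np.asarray(tets, dtype=np.int64),
        tet_tags,
        comp_names,
        np.asarray(tris, dtype=np.int64).reshape(-1, 3),
        tri_tags,
        patch_names,
    )
    mesh.meta["msh_version"] = version
    return mesh


def write_gmsh(mesh: TetMesh, path) -> None:
    """Write a mesh as MSH ASCII v2.2 with physical names."""
    out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    names = []
    for i, n in enumerate(mesh.patch_names):
        names.append(f'2 {i + 1} "{n}"')
    for i, n in enumerate(mesh.comp_names):
        names.append(f'3 {i + 1} "{n}"')
    if names:
        out += ["$PhysicalNames", str(len(names))] + names + ["$EndPhysicalNames"]
    out += ["$Nodes", str(mesh.num_vertices)]
    for i, (x, y, z) in enumerate(mesh.vertices, start=1):
        out.append(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}")
    out.append("$EndNodes")
    out += ["$Elements", str(mesh.num_tris + mesh.num_tets)]
    eid = 1
    for tri, tag in zip(mesh.tris, mesh.tri_tags):
        nodes = " ".join(str(v + 1) for v in tri)
        out.append(f"{eid} 2 2 {tag + 1} {tag + 1} {nodes}")
        eid += 1
    for tet, tag in zip(mesh.tets, mesh.tet_tags):
        nodes = " ".join(str(v + 1) for v in tet)
        out.append(f"{eid} 4 2 {tag + 1} {tag + 1} {nodes}")
        eid += 1
    out.append("$EndElements")
    Path(path).write_text("\n".join(out) + "\n")
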