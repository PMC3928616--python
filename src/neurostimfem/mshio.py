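"""Gmsh MSH ASCII read/write (v2.2 and v4.1) for tagged tetrahedral meshes.

Physical-group names map directly onto :class:`~neurostimfem.mesh.Mesh`
tags: dimension-2 groups become facet tags, dimension-3 groups become
subdomain tags.  Only first-order triangles (type 2) and tetrahedra
(type 4) are supported; point and line elements are skipped; any other
element type raises :class:`UnsupportedElementError`.  Writing with
version "4.1" round-trips coordinates, connectivity and the tag maps
exactly (coordinates are emitted with 17 significant digits).
"""

from __future__ import annotations

import numpy as np

from .mesh import Mesh

__all__ = ["read_mesh", "write_mesh", "MshFormatError", "UnsupportedElementError"]

_TRI, _TET = 2, 4
_SKIP_TYPES = {15: "point", 1: "line"}
_TYPE_NAMES = {3: "quadrangle", 5: "hexahedron", 6: "prism", 7: "pyramid",
               8: "line3", 9: "triangle6", 11: "tetrahedron10"}


class MshFormatError(ValueError):
    pass


class UnsupportedElementError(MshFormatError):
    pass


# ---------------------------------------------------------------------------
# writing

def write_mesh(mesh: Mesh, path, version: str = "4.1") -> None:
    """Write a mesh as Gmsh MSH ASCII (version "2.2" or "4.1")."""
    if version == "2.2":
        _write_v22(mesh, path)
    elif version == "4.1":
        _write_v41(mesh, path)
    else:
        raise MshFormatError(f"unsupported MSH version {version!r}")


def _tag_layout(mesh: Mesh):
    """Stable ordering of physical groups: facet tags then subdomain tags."""
    groups = []  # (dim, phys_id, name, element array)
    pid = 1
    for name in mesh.facet_tags:
        groups.append((2, pid, name, mesh.facet_tags[name]))
        pid += 1
    for name in mesh.subdomain_tags:
        groups.append((3, pid, name, mesh.tets[mesh.subdomain_tags[name]]))
        pid += 1
    tagged = np.zeros(mesh.n_tets, dtype=bool)
    for name in mesh.subdomain_tags:
        tagged[mesh.subdomain_tags[name]] = True
    rest = mesh.tets[~tagged]
    return groups, rest


def _write_v22(mesh: Mesh, path) -> None:
    groups, rest = _tag_layout(mesh)
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        named = [(d, p, n) for d, p, n, _ in groups]
        if named:
            fh.write("$PhysicalNames\n%d\n" % len(named))
            for dim, pid, name in named:
                fh.write('%d %d "%s"\n' % (dim, pid, name))
            fh.write("$EndPhysicalNames\n")
        fh.write("$Nodes\n%d\n" % mesh.n_nodes)
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write("%d %.17g %.17g %.17g\n" % (i, x, y, z))
        fh.write("$EndNodes\n")
        nelem = sum(len(e) for _, _, _, e in groups) + len(rest)
        fh.write("$Elements\n%d\n" % nelem)
        eid = 1
        for dim, pid, _, elems in groups:
            etype = _TRI if dim == 2 else _TET
            for row in elems:
                fh.write("%d %d 2 %d %d %s\n"
                         % (eid, etype, pid, pid, " ".join(str(v + 1) for v in row)))
                eid += 1
        for row in rest:
            fh.write("%d %d 2 0 0 %s\n"
                     % (eid, _TET, " ".join(str(v + 1) for v in row)))
            eid += 1
        fh.write("$EndElements\n")


def _write_v41(mesh: Mesh, path) -> None:
    groups, rest = _tag_layout(mesh)
    surf = [(p, n, e) for d, p, n, e in groups if d == 2]
    vol = [(p, n, e) for d, p, n, e in groups if d == 3]
    if len(rest):
        vol = vol + [(0, None, rest)]
    lo = mesh.nodes.min(axis=0) if mesh.n_nodes else np.zeros(3)
    hi = mesh.nodes.max(axis=0) if mesh.n_nodes else np.zeros(3)
    bb = "%.17g %.17g %.17g %.17g %.17g %.17g" % (*lo, *hi)
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        named = [(d, p, n) for d, p, n, _ in groups]
        if named:
            fh.write("$PhysicalNames\n%d\n" % len(named))
            for dim, pid, name in named:
                fh.write('%d %d "%s"\n' % (dim, pid, name))
            fh.write("$EndPhysicalNames\n")
        fh.write("$Entities\n0 0 %d %d\n" % (len(surf), len(vol)))
        for k, (pid, _, _) in enumerate(surf, start=1):
            fh.write("%d %s %d%s 0\n" % (k, bb, 1 if pid else 0,
                                         (" %d" % pid) if pid else ""))
        for k, (pid, _, _) in enumerate(vol, start=1):
            fh.write("%d %s %d%s 0\n" % (k, bb, 1 if pid else 0,
                                         (" %d" % pid) if pid else ""))
        fh.write("$EndEntities\n")
        fh.write("$Nodes\n1 %d 1 %d\n" % (mesh.n_nodes, mesh.n_nodes))
        fh.write("3 1 0 %d\n" % mesh.n_nodes)
        for i in range(1, mesh.n_nodes + 1):
            fh.write("%d\n" % i)
        for x, y, z in mesh.nodes:
            fh.write("%.17g %.17g %.17g\n" % (x, y, z))
        fh.write("$EndNodes\n")
        nblocks = len(surf) + len(vol)
        nelem = sum(len(e) for _, _, e in surf) + sum(len(e) for _, _, e in vol)
        fh.write("$Elements\n%d %d 1 %d\n" % (nblocks, nelem, nelem))
        eid = 1
        for k, (pid, _, elems) in enumerate(surf, start=1):
            fh.write("2 %d %d %d\n" % (k, _TRI, len(elems)))
            for row in elems:
                fh.write("%d %s\n" % (eid, " ".join(str(v + 1) for v in row)))
                eid += 1
        for k, (pid, _, elems) in enumerate(vol, start=1):
            fh.write("3 %d %d %d\n" % (k, _TET, len(elems)))
            for row in elems:
                fh.write("%d %s\n" % (eid, " ".join(str(v + 1) for v in row)))
                eid += 1
        fh.write("$EndElements\n")


# ---------------------------------------------------------------------------
# reading

def read_mesh(path) -> Mesh:
    """Read a Gmsh MSH ASCII file (v2.2 or v4.1) with physical groups."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                body.append(lines[j])
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1
    if "MeshFormat" not in sections:
        raise MshFormatError("not a Gmsh MSH file (missing $MeshFormat)")
    version = sections["MeshFormat"][0].split()[0]
    if sections["MeshFormat"][0].split()[1] != "0":
        raise MshFormatError("binary MSH files are not supported")

    phys: dict[tuple[int, int], str] = {}
    for line in sections.get("PhysicalNames", [])[1:]:
        parts = line.split(None, 2)
        if len(parts) == 3:
            phys[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')
    if not phys:
        raise MshFormatError(
            "MSH file has no physical groups; expected named groups such as "
            "'electrode_<row>_<col>', 'ground_surface', 'insulating', "
            "'membrane', 'intracellular', 'extracellular'")

    if version.startswith("2"):
        return _read_v22(sections, phys)
    if version.startswith("4"):
        return _read_v41(sections, phys)
    raise MshFormatError(f"unsupported MSH version {version}")


def _finish(nodes, node_ids, tris_by_phys, tets_by_phys):
    nodes = np.asarray(nodes, dtype=float)
    remap = {nid: k for k, nid in enumerate(node_ids)}
    facet_tags, tets, subdomain_tags = {}, [], {}
    for (dim, pid), rows in tris_by_phys.items():
        name = rows["name"] or f"surface_{pid}"
        arr = np.array([[remap[v] for v in r] for r in rows["elems"]], dtype=np.int64)
        facet_tags[name] = arr.reshape(-1, 3)
    for (dim, pid), rows in tets_by_phys.items():
        arr = np.array([[remap[v] for v in r] for r in rows["elems"]], dtype=np.int64)
        start = len(tets)
        tets.extend(arr.reshape(-1, 4))
        if rows["name"] is not None:
            subdomain_tags[rows["name"]] = np.arange(start, len(tets), dtype=np.int64)
    tets = (np.asarray(tets, dtype=np.int64).reshape(-1, 4) if tets
            else np.zeros((0, 4), dtype=np.int64))
    # fix inverted tets (negative volume) by swapping two vertices
    if len(tets):
        from .mesh import tet_volumes
        bad = tet_volumes(nodes, tets) < 0
        tets[bad] = tets[bad][:, [0, 1, 3, 2]]
    return Mesh(nodes=nodes, tets=tets, facet_tags=facet_tags,
                subdomain_tags=subdomain_tags)


def _read_v22(sections, phys) -> Mesh:
    body = sections["Nodes"]
    n = int(body[0])
    node_ids, nodes = [], []
    for line in body[1:1 + n]:
        f = line.split()
        node_ids.append(int(f[0]))
        nodes.append([float(f[1]), float(f[2]), float(f[3])])
    body = sections["Elements"]
    ne = int(body[0])
    tris_by_phys: dict = {}
    tets_by_phys: dict = {}
    for line in body[1:1 + ne]:
        f = [int(x) for x in line.split()]
        etype, ntags = f[1], f[2]
        pid = f[3] if ntags >= 1 else 0
        conn = f[3 + ntags:]
        if etype in _SKIP_TYPES:
            continue
        if etype == _TRI:
            store, dim = tris_by_phys, 2
        elif etype == _TET:
            store, dim = tets_by_phys, 3
        else:
            raise UnsupportedElementError(
                f"unsupported element type {etype} "
                f"({_TYPE_NAMES.get(etype, 'unknown')})")
        name = phys.get((dim, pid)) if pid else None
        entry = store.setdefault((dim, pid), {"name": name, "elems": []})
        entry["elems"].append(conn)
    return _finish(nodes, node_ids, tris_by_phys, tets_by_phys)


def _read_v41(sections, phys) -> Mesh:
    # entity -> physical id map from $Entities
    ent_phys: dict[tuple[int, int], int] = {}
    body = sections.get("Entities")
    if body:
        counts = [int(x) for x in body[0].split()]
        npt, ncrv, nsurf, nvol = counts
        idx = 1
        for _ in range(npt):
            idx += 1
        for _ in range(ncrv):
            idx += 1
        for dim, cnt in ((2, nsurf), (3, nvol)):
            for _ in range(cnt):
                f = body[idx].split()
                tag = int(f[0])
                nphys = int(f[7])
                if nphys > 0:
                    ent_phys[(dim, tag)] = int(f[8])
                idx += 1
    body = sections["Nodes"]
    header = body[0].split()
    nblocks = int(header[0])
    node_ids, nodes = [], []
    idx = 1
    for _ in range(nblocks):
        dim, etag, parametric, nn = (int(x) for x in body[idx].split())
        idx += 1
        ids = [int(body[idx + k].split()[0]) for k in range(nn)]
        idx += nn
        for k in range(nn):
            f = body[idx + k].split()
            nodes.append([float(f[0]), float(f[1]), float(f[2])])
        idx += nn
        node_ids.extend(ids)
    body = sections["Elements"]
    header = body[0].split()
    nblocks = int(header[0])
    tris_by_phys: dict = {}
    tets_by_phys: dict = {}
    idx = 1
    for _ in range(nblocks):
        dim, etag, etype, nn = (int(x) for x in body[idx].split())
        idx += 1
        rows = [[int(x) for x in body[idx + k].split()][1:] for k in range(nn)]
        idx += nn
        if etype in _SKIP_TYPES:
            continue
        if etype == _TRI and dim == 2:
            store = tris_by_phys
        elif etype == _TET and dim == 3:
            store = tets_by_phys
        else:
            raise UnsupportedElementError(
                f"unsupported element type {etype} "
                f"({_TYPE_NAMES.get(etype, 'unknown')})")
        pid = ent_phys.get((dim, etag), 0)
        name = phys.get((dim, pid)) if pid else None
        entry = store.setdefault((dim, pid if pid else -etag), {"name": name,
                                                               "elems": []})
        entry["elems"].extend(rows)
    return _finish(nodes, node_ids, tris_by_phys, tets_by_phys)
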