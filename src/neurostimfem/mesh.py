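"""Tagged tetrahedral meshes: container, topology and quality utilities.

A :class:`Mesh` carries node coordinates in meters, tetrahedra, named facet
tags (boundary or interior interface triangles) and named subdomain tags
(sets of tetrahedra).  Canonical tag names used by the MEA builders:
``electrode_<row>_<col>``, ``ground_surface``, ``insulating``,
``lateral_wall``, ``top``, ``membrane``, ``intracellular``,
``extracellular``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Mesh", "tet_volumes", "triangle_areas", "MeshQuality"]


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra."""
    a, b, c, d = (nodes[tets[:, k]] for k in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def triangle_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a, b, c = (nodes[tris[:, k]] for k in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


@dataclass
class MeshQuality:
    n_nodes: int
    n_tets: int
    min_volume: float
    max_volume: float
    min_dihedral_deg: float
    min_edge: float
    max_edge: float


@dataclass
class Mesh:
    """Unstructured tetrahedral mesh with named facet and subdomain tags."""

    nodes: np.ndarray                                # (N, 3) float, meters
    tets: np.ndarray                                 # (M, 4) int
    facet_tags: dict[str, np.ndarray] = field(default_factory=dict)   # tag -> (K, 3) int
    subdomain_tags: dict[str, np.ndarray] = field(default_factory=dict)  # tag -> tet idx
    recipe: object | None = None                     # generation spec (for refine_near)

    # -- basic topology --------------------------------------------------

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        self.facet_tags = {k: np.asarray(v, dtype=np.int64).reshape(-1, 3)
                           for k, v in self.facet_tags.items()}
        self.subdomain_tags = {k: np.asarray(v, dtype=np.int64).ravel()
                               for k, v in self.subdomain_tags.items()}
        self._face_owner_cache: dict | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    @staticmethod
    def _face_key(tris: np.ndarray) -> np.ndarray:
        return np.sort(np.asarray(tris, dtype=np.int64).reshape(-1, 3), axis=1)

    def _face_owners(self) -> dict[tuple, list[int]]:
        """Map sorted face triple -> list of owning tet indices."""
        if self._face_owner_cache is None:
            faces = {}
            local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
            for ti, tet in enumerate(self.tets):
                for lf in local:
                    key = tuple(sorted(tet[list(lf)]))
                    faces.setdefault(key, []).append(ti)
            self._face_owner_cache = faces
        return self._face_owner_cache

    def boundary_facets(self) -> tuple[np.ndarray, np.ndarray]:
        """All exterior faces and their owning tet: ``(tris (K,3), owner (K,))``."""
        faces = self._face_owners()
        tris, owners = [], []
        for key, tets in faces.items():
            if len(tets) == 1:
                tris.append(key)
                owners.append(tets[0])
        return np.asarray(tris, dtype=np.int64), np.asarray(owners, dtype=np.int64)

    def facet_owners(self, tris: np.ndarray) -> list[list[int]]:
        """Owning tets of each given facet (1 for boundary, 2 for interface)."""
        faces = self._face_owners()
        return [faces.get(tuple(sorted(t)), []) for t in np.asarray(tris).reshape(-1, 3)]

    def outward_normals(self, tris: np.ndarray, owners: np.ndarray) -> np.ndarray:
        """Unit normals of boundary facets pointing out of the owning tet."""
        tris = np.asarray(tris).reshape(-1, 3)
        a, b, c = (self.nodes[tris[:, k]] for k in range(3))
        n = np.cross(b - a, c - a)
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        # opposite vertex of the owner tet
        for i, (tri, ti) in enumerate(zip(tris, owners)):
            opp = [v for v in self.tets[ti] if v not in set(tri)][0]
            if np.dot(n[i], self.nodes[opp] - a[i]) > 0:
                n[i] = -n[i]
        return n

    # -- validation ------------------------------------------------------

    def check(self, volume_eps: float | None = None) -> MeshQuality:
        """Validate invariants; returns a quality report.

        Checks: positive tet volumes (above ``volume_eps``), every tagged
        facet is a face of some tetrahedron, facet tag sets are pairwise
        disjoint.
        """
        vols = self.volumes()
        if np.any(vols < 0):
            raise ValueError(f"{int((vols < 0).sum())} tetrahedra with negative volume")
        edges = self._all_edge_lengths()
        if volume_eps is None:
            volume_eps = 1e-9 * float(np.median(vols))
        if np.any(vols < volume_eps):
            i = int(np.argmin(vols))
            raise ValueError(
                f"tetrahedron {i} has volume {vols[i]:.3g} m^3 below eps "
                f"{volume_eps:.3g} (nodes {self.tets[i].tolist()})")
        faces = self._face_owners()
        seen: dict[tuple, str] = {}
        for tag, tris in self.facet_tags.items():
            for t in tris:
                key = tuple(sorted(t))
                if key not in faces:
                    raise ValueError(f"facet {t.tolist()} of tag '{tag}' is not a "
                                     "face of any tetrahedron")
                if key in seen:
                    raise ValueError(f"facet {t.tolist()} tagged twice: "
                                     f"'{seen[key]}' and '{tag}'")
                seen[key] = tag
        return MeshQuality(n_nodes=self.n_nodes, n_tets=self.n_tets,
                           min_volume=float(vols.min()), max_volume=float(vols.max()),
                           min_dihedral_deg=self.min_dihedral_deg(),
                           min_edge=float(edges.min()), max_edge=float(edges.max()))

    def _all_edge_lengths(self) -> np.ndarray:
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        out = []
        for i, j in pairs:
            out.append(np.linalg.norm(self.nodes[self.tets[:, i]] -
                                      self.nodes[self.tets[:, j]], axis=1))
        return np.concatenate(out)

    def min_dihedral_deg(self) -> float:
        """Minimum dihedral angle over all tetrahedra (degrees)."""
        nds = self.nodes[self.tets]  # (M,4,3)
        local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
        normals = []
        for (a, b, c), opp in zip(local, (3, 2, 1, 0)):
            n = np.cross(nds[:, b] - nds[:, a], nds[:, c] - nds[:, a])
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            sgn = np.sign(np.einsum("ij,ij->i", n, nds[:, opp] - nds[:, a]))
            normals.append(n * sgn[:, None])  # inward normals
        # dihedral angle theta between faces: cos(theta) = -n_i . n_j (inward
        # normals); the minimum angle corresponds to the smallest dot product
        min_dot = 1.0
        for i in range(4):
            for j in range(i + 1, 4):
                c = np.einsum("ij,ij->i", normals[i], normals[j])
                min_dot = min(min_dot, float(c.min()))
        return float(np.degrees(np.arccos(np.clip(-min_dot, -1.0, 1.0))))

    def tagged_untagged_boundary(self) -> np.ndarray:
        """Exterior facets not covered by any facet tag (ideally empty)."""
        tris, _ = self.boundary_facets()
        tagged = set()
        for ts in self.facet_tags.values():
            for t in ts:
                tagged.add(tuple(sorted(t)))
        mask = [tuple(t) not in tagged for t in tris]
        return tris[np.asarray(mask, dtype=bool)]

    def facet_area(self, tag: str) -> float:
        return float(triangle_areas(self.nodes, self.facet_tags[tag]).sum())

    def subdomain_volume(self, tag: str) -> float:
        return float(self.volumes()[self.subdomain_tags[tag]].sum())

    def is_watertight(self, tag: str) -> bool:
        """True if every edge of the tagged facet set bounds exactly 2 triangles."""
        tris = self.facet_tags[tag]
        counts: dict[tuple, int] = {}
        for a, b, c in tris:
            for e in ((a, b), (b, c), (a, c)):
                key = (min(e), max(e))
                counts[key] = counts.get(key, 0) + 1
        return all(v == 2 for v in counts.values())

    def max_edge_of_facets(self, tris: np.ndarray) -> float:
        tris = np.asarray(tris).reshape(-1, 3)
        e = []
        for i, j in ((0, 1), (1, 2), (0, 2)):
            e.append(np.linalg.norm(self.nodes[tris[:, i]] - self.nodes[tris[:, j]],
                                    axis=1))
        return float(np.max(e)) if tris.size else 0.0
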