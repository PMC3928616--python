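"""Geometry construction and tetrahedral meshing of MEA stimulation scenarios.

The multielectrode-array (MEA) chamber is a cylinder whose substrate
(z = 0) carries an 8 x 8-minus-corners grid of 60 planar disk
microelectrodes, optionally surrounded by a conductive ground surface
separated from each electrode by an insulating annular gap.  A neuron
(straight fiber with hemispherical caps — a capsule — optionally with a
spherical soma) can be embedded as an interior membrane interface
separating an intracellular from the extracellular subdomain.

Meshing strategy: the chamber and the half-ball validation domain are
convex, so an unstructured tetrahedral mesh is obtained as the Delaunay
triangulation of a graded point cloud.  Point density follows a sizing
field ``h(x) = min_f (h_f + grade * dist(x, f))`` over a set of
refinement features (stimulation electrode, neuron surface, ...), clipped
to ``h_max``; points are laid out on octree-style lattice levels with
deterministic jitter, plus exact structural points on electrode rims,
circles and the neuron surface.  Tetrahedra are tagged by classifying
centroids with signed distance functions; the membrane interface is the
set of faces shared by an intracellular and an extracellular tetrahedron,
which is watertight by construction.

Polygonal rings inscribed in the fiber cross-section underestimate its
area, which would bias the intracellular axial conductance of the coupled
model; ring radii are therefore dilated so the inscribed polygon area
equals the true circle area (equivalent-area correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield, replace

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .mesh import Mesh, tet_volumes

__all__ = [
    "MEAParams", "NeuronGeometrySpec", "build_mea_chamber",
    "embed_neuron_surface", "refine_near", "box_mesh", "spherical_shell_mesh",
    "half_ball_mesh", "GeometryError",
]

MIN_TARGET_EDGE = 0.5e-6  # refusal limit for refine_near

# electrode rims are inscribed polygons; dilating the rim radius so the
# polygon area equals the disk area removes the systematic area deficit
_ELEC_RIM_N = 12
_ELEC_DIL = math.sqrt(2 * math.pi / (_ELEC_RIM_N *
                                     math.sin(2 * math.pi / _ELEC_RIM_N)))


class GeometryError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# parameter records

@dataclass(frozen=True)
class MEAParams:
    """MEA chamber geometry (meters).

    Defaults reproduce the bundled scenario: 60 electrodes of 10 um
    diameter, 100 um pitch (8 x 8 grid without corners), 10 um annular gap
    to the ground surface.  Chamber radius/height are free parameters of
    the chamber model (the stimulating field 50 um above the array is
    insensitive to doubling them).
    """

    chamber_radius: float = 1.5e-3
    chamber_height: float = 1.0e-3
    electrode_diameter: float = 10e-6
    pitch: float = 100e-6
    ground_gap: float = 10e-6
    ground_surface_enabled: bool = True
    rows: int = 8
    cols: int = 8
    drop_corners: bool = True

    def __post_init__(self):
        if not self.electrode_diameter < self.pitch:
            raise ValueError("electrode_diameter must be < pitch")
        if not self.ground_gap > 0:
            raise ValueError("ground_gap must be > 0")
        span = math.hypot((self.rows - 1) / 2 * self.pitch,
                          (self.cols - 1) / 2 * self.pitch)
        if span + self.pitch > self.chamber_radius:
            raise ValueError("electrode grid does not fit in the chamber")

    def electrode_centers(self) -> list[tuple[str, float, float]]:
        """(tag, cx, cy) for each electrode; 8x8 minus corners -> 60 sites."""
        out = []
        corners = {(0, 0), (0, self.cols - 1), (self.rows - 1, 0),
                   (self.rows - 1, self.cols - 1)}
        for i in range(self.rows):
            for j in range(self.cols):
                if self.drop_corners and (i, j) in corners:
                    continue
                cx = (i - (self.rows - 1) / 2) * self.pitch
                cy = (j - (self.cols - 1) / 2) * self.pitch
                out.append((f"electrode_{i}_{j}", cx, cy))
        return out

    @property
    def central_electrode(self) -> str:
        """Tag of the electrode closest to the chamber axis (ties: lowest tag)."""
        ctr = sorted(self.electrode_centers(),
                     key=lambda t: (round(math.hypot(t[1], t[2]), 12), t[0]))
        return ctr[0][0]

    def electrode_center(self, tag: str) -> tuple[float, float]:
        for t, cx, cy in self.electrode_centers():
            if t == tag:
                return cx, cy
        raise KeyError(tag)


@dataclass(frozen=True)
class NeuronGeometrySpec:
    """A straight fiber (capsule) with an optional spherical soma (meters)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    fiber_diameter: float
    soma_diameter: float | None = None
    soma_center: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not self.fiber_diameter > 0:
            raise ValueError("fiber_diameter must be > 0")
        if self.soma_diameter is not None and \
                not self.soma_diameter > self.fiber_diameter:
            raise ValueError("soma_diameter must exceed fiber_diameter")

    @classmethod
    def fiber_above(cls, center_xy: tuple[float, float], z: float, length: float,
                    diameter: float, axis=(0.0, 1.0, 0.0),
                    soma_diameter: float | None = None) -> "NeuronGeometrySpec":
        """A fiber of given length centered over (cx, cy) at height z."""
        a = np.asarray(axis, dtype=float)
        a /= np.linalg.norm(a)
        c = np.array([center_xy[0], center_xy[1], z])
        return cls(p0=tuple(c - a * length / 2), p1=tuple(c + a * length / 2),
                   fiber_diameter=diameter, soma_diameter=soma_diameter,
                   soma_center=tuple(c) if soma_diameter else None)

    @property
    def fiber_length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))

    @property
    def axis(self) -> np.ndarray:
        d = np.subtract(self.p1, self.p0)
        return d / np.linalg.norm(d)

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance to the neuron surface (< 0 inside)."""
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        a = self.fiber_diameter / 2.0
        d = self.axis
        # capsule of total length fiber_length: segment shortened by the caps
        q0 = np.asarray(self.p0) + a * d
        q1 = np.asarray(self.p1) - a * d
        s = _segment_distance(pts, q0, q1) - a
        if self.soma_diameter is not None:
            c = np.asarray(self.soma_center)
            s = np.minimum(s, np.linalg.norm(pts - c, axis=1) -
                           self.soma_diameter / 2.0)
        return s

    def analytic_volume(self) -> float:
        a = self.fiber_diameter / 2.0
        L = self.fiber_length
        vol = math.pi * a * a * (L - 2 * a) + 4.0 / 3.0 * math.pi * a ** 3
        if self.soma_diameter is not None:
            R = self.soma_diameter / 2.0
            # sphere minus the two spherical caps already inside... the fiber
            # through the sphere adds pi a^2 * (chord) which is already counted;
            # subtract the overlap: cylinder section of length 2*sqrt(R^2-a^2)
            # plus two caps ~ sphere volume - cylinder overlap
            chord = 2.0 * math.sqrt(max(R * R - a * a, 0.0))
            cap_h = R - chord / 2.0
            caps = 2 * math.pi * cap_h ** 2 * (R - cap_h / 3.0)
            vol += 4.0 / 3.0 * math.pi * R ** 3 - math.pi * a * a * chord - caps
        return vol


def _segment_distance(pts: np.ndarray, p0, p1) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    L2 = float(d @ d)
    t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(pts - proj, axis=1)


# ---------------------------------------------------------------------------
# sizing field

@dataclass(frozen=True)
class Feature:
    """A refinement feature: local size h at the feature, growing with distance."""

    kind: str            # point | segment | disk
    data: tuple
    h: float
    grade: float = 0.6

    def dist(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        if self.kind == "point":
            return np.linalg.norm(pts - np.asarray(self.data[0]), axis=1)
        if self.kind == "segment":
            return _segment_distance(pts, self.data[0], self.data[1])
        if self.kind == "disk":
            (cx, cy, cz), r = self.data
            dxy = np.maximum(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r, 0.0)
            return np.hypot(dxy, pts[:, 2] - cz)
        raise ValueError(self.kind)


def _sizing(pts: np.ndarray, features: list[Feature], h_max: float) -> np.ndarray:
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    h = np.full(len(pts), h_max)
    for f in features:
        np.minimum(h, f.h + f.grade * f.dist(pts), out=h)
    return h


def _level_spacings(h_max: float, h_min: float) -> list[float]:
    out = [h_max]
    while out[-1] > 1.4 * h_min:
        out.append(out[-1] / 2.0)
    return out


def _feature_bbox(f: Feature):
    if f.kind == "point":
        p = np.asarray(f.data[0], dtype=float)
        return p.copy(), p.copy()
    if f.kind == "segment":
        p0 = np.asarray(f.data[0], dtype=float)
        p1 = np.asarray(f.data[1], dtype=float)
        return np.minimum(p0, p1), np.maximum(p0, p1)
    if f.kind == "disk":
        (cx, cy, cz), r = f.data
        return (np.array([cx - r, cy - r, cz]), np.array([cx + r, cy + r, cz]))
    raise ValueError(f.kind)


def _int_lattice(boxes, s: float, lo_clip, hi_clip, dims: int) -> np.ndarray:
    """Union of integer lattice cells covering the boxes (globally aligned)."""
    chunks = []
    lo_clip = np.asarray(lo_clip, dtype=float)[:dims]
    hi_clip = np.asarray(hi_clip, dtype=float)[:dims]
    for lo, hi in boxes:
        lo = np.maximum(np.asarray(lo, dtype=float)[:dims], lo_clip)
        hi = np.minimum(np.asarray(hi, dtype=float)[:dims], hi_clip)
        if np.any(hi < lo):
            continue
        axes = [np.arange(math.floor(lo[d] / s), math.floor(hi[d] / s) + 1)
                for d in range(dims)]
        if any(len(a) == 0 for a in axes):
            continue
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        chunks.append(grid.reshape(-1, dims).astype(np.int64))
    if not chunks:
        return np.zeros((0, dims), dtype=np.int64)
    return np.unique(np.vstack(chunks), axis=0)


def _graded_points(features, h_max, h_min, bbox_lo, bbox_hi, inside_fn, rng,
                   jitter=0.25, dims=3, z_plane=0.0) -> np.ndarray:
    """Octree-style graded point cloud following the sizing field.

    Fine lattice levels are only generated within the reach of the features
    that request them, so cost scales with the refined regions, not the
    whole domain.
    """
    levels = _level_spacings(h_max, h_min)
    K = len(levels) - 1
    out = []
    for k, s in enumerate(levels):
        if k == 0:
            boxes = [(np.asarray(bbox_lo, dtype=float),
                      np.asarray(bbox_hi, dtype=float))]
        else:
            boxes = []
            for f in features:
                reach = (2.2 * s - f.h) / max(f.grade, 1e-9)
                if reach <= 0:
                    continue
                lo, hi = _feature_bbox(f)
                boxes.append((lo[:dims] - reach, hi[:dims] + reach))
            if not boxes:
                continue
        ints = _int_lattice(boxes, s, bbox_lo, bbox_hi, dims)
        if not len(ints):
            continue
        cand = (ints + 0.5) * s
        cand = cand + rng.uniform(-jitter * s, jitter * s, size=cand.shape)
        cand3 = cand if dims == 3 else np.column_stack(
            [cand, np.full(len(cand), z_plane)])
        h = _sizing(cand3, features, h_max)
        lev = np.clip(np.floor(np.log2(h_max / np.maximum(h, 1e-30)) + 0.5),
                      0, K).astype(int)
        keep = lev == k
        keep &= inside_fn(cand3, s)
        out.append(cand3[keep])
    return np.vstack(out) if out else np.zeros((0, 3))


def _circle_points(cx, cy, cz, r, spacing, rng, min_n=8, n=None) -> np.ndarray:
    if n is None:
        n = max(min_n, int(math.ceil(2 * math.pi * r / spacing)))
    th = np.arange(n) * 2 * math.pi / n + rng.uniform(0, 2 * math.pi / n)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th),
                            np.full(n, float(cz))])


def _prune_near(points: np.ndarray, structural: np.ndarray,
                radii: np.ndarray, factor: float = 0.55) -> np.ndarray:
    """Drop points closer than factor*radius to any structural point."""
    if not len(points) or not len(structural):
        return points
    tree = cKDTree(structural)
    d, i = tree.query(points, k=1)
    return points[d > factor * radii[i]]


# ---------------------------------------------------------------------------
# recipe and the generic cylinder-chamber generator

@dataclass(frozen=True)
class MeshRecipe:
    """Everything needed to (re)generate an MEA chamber mesh deterministically."""

    mea: MEAParams
    neuron: NeuronGeometrySpec | None = None
    h_stim: float = 4e-6            # target size at the stimulation electrode
    h_electrode: float = 5e-6       # at the other electrodes
    h_neuron: float | None = None   # at the neuron surface (default: diameter)
    h_max: float = 2.0e-4
    grade: float = 0.6
    stim_tag: str | None = None     # default: central electrode
    extra_features: tuple = ()
    enforced: tuple = ()            # ((center, radius, target_edge), ...)
    seed: int = 0
    tag_lateral_wall: bool = True

    def resolved_stim(self) -> str:
        return self.stim_tag or self.mea.central_electrode


def _mea_features(recipe: MeshRecipe) -> list[Feature]:
    mea = recipe.mea
    stim = recipe.resolved_stim()
    r_e = mea.electrode_diameter / 2.0
    feats = []
    for tag, cx, cy in mea.electrode_centers():
        h = recipe.h_stim if tag == stim else recipe.h_electrode
        grade = recipe.grade if tag == stim else 1.5
        feats.append(Feature("disk", ((cx, cy, 0.0), r_e + mea.ground_gap),
                             h=h, grade=grade))
    if recipe.neuron is not None:
        h_n = recipe.h_neuron or recipe.neuron.fiber_diameter
        feats.append(Feature("segment", (recipe.neuron.p0, recipe.neuron.p1),
                             h=h_n, grade=recipe.grade))
        if recipe.neuron.soma_diameter is not None:
            feats.append(Feature("point", (recipe.neuron.soma_center,),
                                 h=h_n * 1.3, grade=recipe.grade))
    feats.extend(recipe.extra_features)
    for center, radius, h in recipe.enforced:
        feats.append(Feature("point", (tuple(center),), h=h, grade=recipe.grade))
    return feats


def _neuron_surface_points(neuron: NeuronGeometrySpec, rng):
    """Structural points on and inside the neuron; returns (surface, interior, radii)."""
    a = neuron.fiber_diameter / 2.0
    d = neuron.axis
    # orthonormal frame
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(d, ref); e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    n_c = 12
    # equivalent-area dilation so the inscribed polygon matches the disk area
    dil = math.sqrt(2 * math.pi / (n_c * math.sin(2 * math.pi / n_c)))
    a_m = a * dil
    ds = max(1.2 * a, 1.0e-6)
    L = neuron.fiber_length
    q0 = np.asarray(neuron.p0) + a * d
    q1 = np.asarray(neuron.p1) - a * d
    Lseg = float(np.linalg.norm(q1 - q0))
    n_st = max(2, int(round(Lseg / ds)) + 1)
    stations = np.linspace(0.0, Lseg, n_st)
    # per-ring deterministic angular offset + small axial jitter breaks the
    # cospherical degeneracies of aligned rings
    surf, inter = [], []
    soma_R = (neuron.soma_diameter / 2.0) if neuron.soma_diameter else None
    soma_c = np.asarray(neuron.soma_center) if soma_R else None
    half_chord = math.sqrt(max(soma_R ** 2 - a ** 2, 0.0)) if soma_R else None
    for i, t in enumerate(stations):
        tj = t + (rng.uniform(-0.15, 0.15) * ds if 0 < i < n_st - 1 else 0.0)
        c = q0 + tj * d
        if soma_R is not None and abs(float((c - soma_c) @ d)) < half_chord:
            continue  # station swallowed by the soma
        th0 = rng.uniform(0, 2 * math.pi)
        th = th0 + np.arange(n_c) * 2 * math.pi / n_c
        ring = c + a_m * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2))
        surf.append(ring)
        inter.append(c[None, :])
    # hemispherical caps
    for center, sign in ((q0, -1.0), (q1, 1.0)):
        for phi in (math.pi / 4,):
            rr = a_m * math.cos(phi)
            zz = a * math.sin(phi)
            th = rng.uniform(0, 2 * math.pi) + np.arange(8) * 2 * math.pi / 8
            ring = (center + sign * zz * d +
                    rr * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2)))
            surf.append(ring)
        surf.append((center + sign * a * d)[None, :])
    if soma_R is not None:
        ds_s = soma_R / 4.0
        n_lat = max(6, int(round(math.pi * soma_R / ds_s)))
        for i in range(1, n_lat):
            phi = i * math.pi / n_lat + rng.uniform(-0.1, 0.1) * math.pi / n_lat
            # polar angle measured from the fiber axis direction
            ring_r = soma_R * math.sin(phi)
            off = soma_R * math.cos(phi)
            if ring_r < 1.4 * a:
                continue  # pole region occupied by the fiber
            th = rng.uniform(0, 2 * math.pi) + \
                np.arange(max(8, int(2 * math.pi * ring_r / ds_s))) * \
                2 * math.pi / max(8, int(2 * math.pi * ring_r / ds_s))
            ring = (soma_c + off * d +
                    ring_r * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2)))
            surf.append(ring)
        # junction circles where the fiber meets the sphere
        for sign in (-1.0, 1.0):
            th = rng.uniform(0, 2 * math.pi) + np.arange(n_c) * 2 * math.pi / n_c
            ring = (soma_c + sign * half_chord * d +
                    a_m * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2)))
            surf.append(ring)
        # soma interior: a small internal lattice plus the center
        inter.append(soma_c[None, :])
        for rr in (soma_R * 0.45, soma_R * 0.75):
            n_i = max(6, int(4 * math.pi * rr * rr / ds_s ** 2 / 4))
            pts = rng.normal(size=(n_i, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            inter.append(soma_c + rr * pts)
    surface = np.vstack(surf)
    interior = np.vstack(inter)
    r_surface = np.full(len(surface), ds)
    return surface, interior, r_surface


def _generate_chamber(recipe: MeshRecipe) -> Mesh:
    mea = recipe.mea
    R, H = mea.chamber_radius, mea.chamber_height
    r_e = mea.electrode_diameter / 2.0
    features = _mea_features(recipe)
    h_min = min(f.h for f in features)
    last_err = None
    for attempt in range(4):
        rng = np.random.default_rng(recipe.seed + 1000 * attempt)
        try:
            return _generate_chamber_once(recipe, features, h_min, rng)
        except GeometryError as err:  # degenerate triangulation: re-jitter
            last_err = err
    raise GeometryError(f"chamber meshing failed after 4 attempts: {last_err}")


def _generate_chamber_once(recipe: MeshRecipe, features, h_min, rng) -> Mesh:
    mea = recipe.mea
    R, H = mea.chamber_radius, mea.chamber_height
    r_e = mea.electrode_diameter / 2.0
    h_max = recipe.h_max

    structural = []
    radii = []

    def add(pts, r_loc):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        structural.append(pts)
        radii.append(np.full(len(pts), float(r_loc)))

    stim = recipe.resolved_stim()
    for tag, cx, cy in mea.electrode_centers():
        h_loc = recipe.h_stim if tag == stim else recipe.h_electrode
        # enforced refinement regions may demand a finer local size
        h_loc = min(h_loc,
                    float(_sizing(np.array([[cx, cy, 0.0]]), features, h_max)[0]))
        add([[cx, cy, 0.0]], h_loc)
        n_rim = max(_ELEC_RIM_N, int(math.ceil(2 * math.pi * r_e / h_loc)))
        dil = math.sqrt(2 * math.pi / (n_rim * math.sin(2 * math.pi / n_rim)))
        add(_circle_points(cx, cy, 0.0, r_e * dil, 0.0, rng, n=n_rim), h_loc)
        if tag == stim and r_e / 2 > h_loc / 2:
            add(_circle_points(cx, cy, 0.0, r_e * dil / 2, h_loc, rng), h_loc)
        add(_circle_points(cx, cy, 0.0, r_e + mea.ground_gap,
                           min(1.5 * h_loc, mea.ground_gap), rng), h_loc)
    # chamber rims and wall
    wall_h = _sizing(np.array([[R, 0.0, 0.0]]), features, h_max)[0]
    add(_circle_points(0, 0, 0.0, R, wall_h, rng), wall_h)
    add(_circle_points(0, 0, H, R, wall_h, rng), wall_h)
    nz = max(2, int(math.ceil(H / wall_h)))
    for k in range(1, nz):
        z = k * H / nz
        add(_circle_points(0, 0, z, R, wall_h, rng), wall_h)

    neuron = recipe.neuron
    sdf = None
    if neuron is not None:
        lo = np.minimum(neuron.p0, neuron.p1)
        hi = np.maximum(neuron.p0, neuron.p1)
        rad = (neuron.soma_diameter or neuron.fiber_diameter) / 2.0
        if min(lo[2], hi[2]) - rad <= 0 or max(lo[2], hi[2]) + rad >= H \
                or math.hypot(max(abs(lo[0]), abs(hi[0])) + rad,
                              max(abs(lo[1]), abs(hi[1])) + rad) >= R:
            raise GeometryError("neuron intersects the chamber boundary or "
                                "touches the substrate")
        surface, interior, r_surf = _neuron_surface_points(neuron, rng)
        structural.append(surface)
        radii.append(r_surf)
        add(interior, float(r_surf[0]))
        sdf = neuron.sdf

    struct_pts = np.vstack(structural)
    struct_r = np.concatenate(radii)

    # substrate (z = 0) graded 2D cloud
    def inside_substrate(p3, s):
        r = np.hypot(p3[:, 0], p3[:, 1])
        ok = r < R - 0.45 * s
        # keep clear of electrode rim circles (they are structural)
        return ok

    sub = _graded_points(features, h_max, h_min, (-R, -R), (R, R),
                         inside_substrate, rng, dims=2, z_plane=0.0)
    # top (z = H) coarse cloud
    top = _graded_points([], h_max, h_max, (-R, -R), (R, R),
                         lambda p3, s: np.hypot(p3[:, 0], p3[:, 1]) < R - 0.45 * s,
                         rng, dims=2, z_plane=H)

    # volume cloud
    def inside_volume(p3, s):
        r = np.hypot(p3[:, 0], p3[:, 1])
        ok = (r < R - 0.45 * s) & (p3[:, 2] > 0.4 * s) & (p3[:, 2] < H - 0.4 * s)
        if sdf is not None:
            ok &= np.abs(sdf(p3)) > 0.6 * np.minimum(
                s, _sizing(p3, features, h_max))
        return ok

    vol = _graded_points(features, h_max, h_min, (-R, -R, 0.0), (R, R, H),
                         inside_volume, rng, dims=3)

    sub = _prune_near(sub, struct_pts, struct_r)
    top = _prune_near(top, struct_pts, struct_r)
    vol = _prune_near(vol, struct_pts, struct_r)
    pts = np.vstack([struct_pts, sub, top, vol])
    mesh = _delaunay_mesh(pts)
    _tag_chamber(mesh, recipe)
    if neuron is not None:
        _tag_neuron(mesh, neuron)
    mesh.recipe = recipe
    return mesh


def _delaunay_mesh(pts: np.ndarray) -> Mesh:
    pts = np.unique(np.round(pts, 12), axis=0)
    tri = Delaunay(pts)
    if len(tri.coplanar):
        raise GeometryError(f"{len(tri.coplanar)} degenerate (cospherical) "
                            "points omitted by the triangulation")
    tets = tri.simplices.astype(np.int64)
    vols = tet_volumes(pts, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    vols = np.abs(vols)
    # drop exact-degenerate slivers only if they are strictly zero volume
    eps = 1e-12 * np.median(vols)
    if np.any(vols <= eps):
        raise GeometryError(f"{int((vols <= eps).sum())} near-zero-volume "
                            "tetrahedra in the triangulation")
    used = np.unique(tets)
    if len(used) != len(pts):
        raise GeometryError("triangulation dropped input points")
    return Mesh(nodes=pts, tets=tets)


def _tag_chamber(mesh: Mesh, recipe: MeshRecipe) -> None:
    mea = recipe.mea
    R, H = mea.chamber_radius, mea.chamber_height
    r_e = mea.electrode_diameter / 2.0
    tris, owners = mesh.boundary_facets()
    cent = mesh.nodes[tris].mean(axis=1)
    ztol = 1e-6 * H
    on_bottom = np.abs(cent[:, 2]) < ztol
    on_top = np.abs(cent[:, 2] - H) < ztol
    centers = mea.electrode_centers()
    ctr_xy = np.array([[cx, cy] for _, cx, cy in centers])
    tree = cKDTree(ctr_xy)
    d_e, i_e = tree.query(cent[:, :2])
    tags: dict[str, list] = {t: [] for t, _, _ in centers}
    tags["insulating"] = []
    if mea.ground_surface_enabled:
        tags["ground_surface"] = []
    if recipe.tag_lateral_wall:
        tags["lateral_wall"] = []
    r_tag = r_e * _ELEC_DIL  # rim dilation used by the generator
    for k in range(len(tris)):
        if on_bottom[k]:
            if d_e[k] <= r_tag * (1 + 1e-9):
                tags[centers[i_e[k]][0]].append(tris[k])
            elif d_e[k] <= (r_e + mea.ground_gap) * (1 + 1e-9):
                tags["insulating"].append(tris[k])
            elif mea.ground_surface_enabled:
                tags["ground_surface"].append(tris[k])
            else:
                tags["insulating"].append(tris[k])
        elif on_top[k]:
            tags["insulating"].append(tris[k])
        else:
            tags["lateral_wall" if recipe.tag_lateral_wall
                 else "insulating"].append(tris[k])
    mesh.facet_tags = {t: np.asarray(v, dtype=np.int64).reshape(-1, 3)
                       for t, v in tags.items() if len(v)}
    missing = [t for t, _, _ in centers if t not in mesh.facet_tags]
    if missing:
        raise GeometryError(f"electrodes with no substrate facets: {missing[:5]}")


def _tag_neuron(mesh: Mesh, neuron: NeuronGeometrySpec) -> None:
    cent = mesh.nodes[mesh.tets].mean(axis=1)
    inside = neuron.sdf(cent) < 0.0
    mesh.subdomain_tags["intracellular"] = np.nonzero(inside)[0]
    mesh.subdomain_tags["extracellular"] = np.nonzero(~inside)[0]
    # interface: faces shared by one intracellular and one extracellular tet
    local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
    faces: dict[tuple, list[bool]] = {}
    for ti, tet in enumerate(mesh.tets):
        flag = bool(inside[ti])
        for lf in local:
            key = tuple(sorted(tet[list(lf)]))
            faces.setdefault(key, []).append(flag)
    mem = [k for k, v in faces.items() if len(v) == 2 and v[0] != v[1]]
    if not mem:
        raise GeometryError("embedded neuron produced no membrane interface")
    mesh.facet_tags["membrane"] = np.asarray(mem, dtype=np.int64)


# ---------------------------------------------------------------------------
# public builders

def build_mea_chamber(params: MEAParams, *, h_stim: float = 4e-6,
                      h_max: float = 2.0e-4, seed: int = 0,
                      stim_tag: str | None = None,
                      extra_features: tuple = ()) -> Mesh:
    """Mesh the MEA chamber: 60 electrode tags + ground surface + insulating.

    The substrate plane carries one facet tag per electrode disk, a
    ``ground_surface`` tag (when enabled) for the substrate outside the
    electrode disks and their annular gaps, and ``insulating`` facets for
    the gaps and the chamber top; the cylindrical wall is tagged
    ``lateral_wall`` (insulating unless a BC is attached, e.g. the distant
    return of a monopolar configuration).
    """
    recipe = MeshRecipe(mea=params, h_stim=h_stim, h_max=h_max, seed=seed,
                        stim_tag=stim_tag, extra_features=tuple(extra_features))
    return _generate_chamber(recipe)


def embed_neuron_surface(mesh_spec: MEAParams, neuron: NeuronGeometrySpec, *,
                         h_stim: float = 4e-6, h_neuron: float | None = None,
                         h_max: float = 2.0e-4, seed: int = 0,
                         stim_tag: str | None = None) -> Mesh:
    """Mesh the chamber with the neuron as an interior membrane interface.

    The returned mesh adds ``intracellular``/``extracellular`` subdomain
    tags and a watertight ``membrane`` facet tag (faces shared by exactly
    one tetrahedron of each side).
    """
    recipe = MeshRecipe(mea=mesh_spec, neuron=neuron, h_stim=h_stim,
                        h_neuron=h_neuron, h_max=h_max, seed=seed,
                        stim_tag=stim_tag)
    return _generate_chamber(recipe)


def refine_near(mesh: Mesh, region, target_edge: float,
                max_rounds: int = 3) -> Mesh:
    """Refine the mesh so elements in ``region`` have edges <= target_edge.

    ``region`` is either a facet tag name or a ``(center, radius)`` sphere.
    The mesh must carry its generation recipe (meshes built by this module
    do); the sizing field is locally overridden and the mesh regenerated,
    iterating until the edge criterion holds in the region.  Asking for a
    target below ``MIN_TARGET_EDGE`` is refused.
    """
    if not target_edge > 0:
        raise ValueError("target_edge must be > 0")
    if target_edge < MIN_TARGET_EDGE:
        raise ValueError(f"target_edge {target_edge:g} m below the configured "
                         f"minimum {MIN_TARGET_EDGE:g} m")
    recipe = mesh.recipe
    if not isinstance(recipe, MeshRecipe):
        raise GeometryError("mesh carries no generation recipe; only meshes "
                            "built by this module can be refined")
    center, radius = _region_sphere(mesh, region)
    if _region_max_edge(mesh, center, radius) <= target_edge:
        return mesh  # already satisfied: no-op
    current = recipe
    out = mesh
    h = target_edge
    for _ in range(max_rounds):
        current = replace(current, enforced=current.enforced +
                          ((tuple(center), radius, 0.8 * h),))
        out = _generate_chamber(current)
        if _region_max_edge(out, center, radius) <= target_edge:
            return out
        h *= 0.6
    return out


def _region_sphere(mesh: Mesh, region):
    if isinstance(region, str):
        tris = mesh.facet_tags[region]
        pts = mesh.nodes[np.unique(tris.ravel())]
        center = pts.mean(axis=0)
        radius = float(np.linalg.norm(pts - center, axis=1).max()) + 1e-9
        return center, radius
    center, radius = region
    return np.asarray(center, dtype=float), float(radius)


def _region_max_edge(mesh: Mesh, center, radius) -> float:
    near = np.linalg.norm(mesh.nodes - center, axis=1) <= radius
    touch = near[mesh.tets].any(axis=1)
    tets = mesh.tets[touch]
    if not len(tets):
        return 0.0
    e = 0.0
    for i, j in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)):
        e = max(e, float(np.linalg.norm(mesh.nodes[tets[:, i]] -
                                        mesh.nodes[tets[:, j]], axis=1).max()))
    return e


# ---------------------------------------------------------------------------
# structured meshes for validation problems

def box_mesh(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int) -> Mesh:
    """Structured box (Kuhn 6-tet-per-cube); faces tagged x0,x1,y0,y1,z0,z1."""
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    corner = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
              (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    kuhn = [(0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
            (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7)]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ids = [nid(i + dx, j + dy, k + dz) for dx, dy, dz in corner]
                for t in kuhn:
                    tets.append([ids[v] for v in t])
    tets = np.asarray(tets, dtype=np.int64)
    vols = tet_volumes(nodes, tets)
    tets[vols < 0] = tets[vols < 0][:, [0, 1, 3, 2]]
    mesh = Mesh(nodes=nodes, tets=tets)
    tris, owners = mesh.boundary_facets()
    cent = nodes[tris].mean(axis=1)
    tol = 1e-9 * max(lx, ly, lz)
    tags = {
        "x0": np.abs(cent[:, 0]) < tol, "x1": np.abs(cent[:, 0] - lx) < tol,
        "y0": np.abs(cent[:, 1]) < tol, "y1": np.abs(cent[:, 1] - ly) < tol,
        "z0": np.abs(cent[:, 2]) < tol, "z1": np.abs(cent[:, 2] - lz) < tol,
    }
    mesh.facet_tags = {t: tris[m] for t, m in tags.items() if m.any()}
    return mesh


def spherical_shell_mesh(r_in: float, r_out: float, subdivisions: int = 2,
                         n_layers: int = 40) -> Mesh:
    """Radially graded shell between two spheres; tags 'inner' and 'outer'.

    Layers are geometric in radius; each icosphere-face prism is split into
    three tetrahedra with index-ordered diagonals, which is conforming
    across neighboring prisms.
    """
    import trimesh
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices)
    faces = np.asarray(ico.faces)
    nv = len(verts)
    radii = np.geomspace(r_in, r_out, n_layers + 1)
    nodes = np.vstack([verts * r for r in radii])
    tets = []
    for layer in range(n_layers):
        lo, hi = layer * nv, (layer + 1) * nv
        for (a, b, c) in faces:
            bot = [lo + a, lo + b, lo + c]
            top = [hi + a, hi + b, hi + c]
            tets.extend(_split_prism(bot, top))
    tets = np.asarray(tets, dtype=np.int64)
    vols = tet_volumes(nodes, tets)
    tets[vols < 0] = tets[vols < 0][:, [0, 1, 3, 2]]
    mesh = Mesh(nodes=nodes, tets=tets)
    inner = faces.copy()
    outer = faces + n_layers * nv
    mesh.facet_tags = {"inner": inner, "outer": outer}
    return mesh


def _split_prism(bot, top):
    """Index-ordered 3-tet split of a prism (conforming across prisms)."""
    # rotate so the smallest vertex (always in the bottom layer here) is first
    imin = int(np.argmin(bot))
    b = bot[imin:] + bot[:imin]
    t = top[imin:] + top[:imin]
    v1, v2, v3 = b
    v4, v5, v6 = t
    if min(v2, v6) < min(v3, v5):
        return [(v1, v2, v3, v6), (v1, v2, v6, v5), (v1, v5, v6, v4)]
    return [(v1, v2, v3, v5), (v1, v5, v3, v6), (v1, v5, v6, v4)]


def box_with_capsule(box: tuple[float, float, float],
                     neuron: NeuronGeometrySpec, *, h_far: float | None = None,
                     seed: int = 0) -> Mesh:
    """A box (origin corner at 0) with an embedded neuron membrane interface.

    Validation fixture: driving opposite box faces with Robin conditions
    produces a nearly uniform exterior field around the capsule.  Faces are
    tagged x0,x1,y0,y1,z0,z1; the neuron adds membrane/intracellular/
    extracellular tags.
    """
    lx, ly, lz = box
    h_far = h_far or min(lx, ly, lz) / 6.0
    rng = np.random.default_rng(seed)
    surface, interior, r_surf = _neuron_surface_points(neuron, rng)
    feats = [Feature("segment", (neuron.p0, neuron.p1),
                     h=neuron.fiber_diameter, grade=0.8)]
    if neuron.soma_diameter is not None:
        feats.append(Feature("point", (neuron.soma_center,),
                             h=neuron.fiber_diameter * 1.3, grade=0.8))
    sdf = neuron.sdf
    lo3, hi3 = np.zeros(3), np.array([lx, ly, lz])

    def inside_vol(p3, s):
        ok = np.all(p3 > 0.4 * s, axis=1) & np.all(p3 < hi3 - 0.4 * s, axis=1)
        ok &= np.abs(sdf(p3)) > 0.6 * np.minimum(s, _sizing(p3, feats, h_far))
        return ok

    vol = _graded_points(feats, h_far, min(f.h for f in feats), lo3, hi3,
                         inside_vol, rng, dims=3)
    face_pts = []
    for axis in range(3):
        for val in (0.0, hi3[axis]):
            others = [d for d in range(3) if d != axis]
            plane = _graded_points(
                feats, h_far, h_far,
                lo3[others], hi3[others],
                lambda p3, s: np.full(len(p3), True), rng, dims=2, z_plane=0.0)
            pts3 = np.zeros((len(plane), 3))
            pts3[:, others[0]] = plane[:, 0]
            pts3[:, others[1]] = plane[:, 1]
            pts3[:, axis] = val
            keep = np.all(pts3[:, others] > 1e-12, axis=1) & \
                np.all(pts3[:, others] < hi3[others] - 1e-12, axis=1)
            face_pts.append(pts3[keep])
    corners = np.array(np.meshgrid([0, lx], [0, ly], [0, lz],
                                   indexing="ij")).reshape(3, -1).T
    # box edges
    edges = []
    for axis in range(3):
        others = [d for d in range(3) if d != axis]
        ticks = np.arange(h_far, hi3[axis] - 0.5 * h_far, h_far)
        for a_val in (0.0, hi3[others[0]]):
            for b_val in (0.0, hi3[others[1]]):
                e = np.zeros((len(ticks), 3))
                e[:, axis] = ticks
                e[:, others[0]] = a_val
                e[:, others[1]] = b_val
                edges.append(e)
    struct = np.vstack([surface, interior, corners] + edges)
    struct_r = np.concatenate([r_surf, np.full(len(interior), float(r_surf[0])),
                               np.full(len(struct) - len(surface) -
                                       len(interior), h_far)])
    pts_extra = _prune_near(np.vstack(face_pts + [vol]), struct, struct_r)
    mesh = _delaunay_mesh(np.vstack([struct, pts_extra]))
    tris, _ = mesh.boundary_facets()
    cent = mesh.nodes[tris].mean(axis=1)
    tol = 1e-9 * max(lx, ly, lz)
    names = {"x0": (0, 0.0), "x1": (0, lx), "y0": (1, 0.0), "y1": (1, ly),
             "z0": (2, 0.0), "z1": (2, lz)}
    tags = {}
    assigned = np.zeros(len(tris), dtype=bool)
    for name, (axis, val) in names.items():
        m = np.abs(cent[:, axis] - val) < tol
        m &= ~assigned
        assigned |= m
        if m.any():
            tags[name] = tris[m]
    mesh.facet_tags = tags
    _tag_neuron(mesh, neuron)
    return mesh


def half_ball_mesh(disk_radius: float, dome_radius: float, *,
                   h_disk: float | None = None, h_max: float | None = None,
                   seed: int = 0) -> Mesh:
    """Half-ball above z = 0 with a centered disk electrode on the plane.

    Facet tags: ``disk`` (r <= disk_radius on the plane), ``plane`` (the
    rest of the substrate plane, insulating) and ``outer`` (the dome).
    Refined toward the disk edge, where the current density of the
    disk-electrode access-resistance problem is singular.
    """
    a, R = disk_radius, dome_radius
    h_disk = h_disk or a / 6.0
    h_max = h_max or R / 6.0
    rng = np.random.default_rng(seed)
    feats = [Feature("disk", ((0.0, 0.0, 0.0), a), h=h_disk, grade=0.5)]
    structural, radii = [], []

    def add(pts, r_loc):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        structural.append(pts)
        radii.append(np.full(len(pts), float(r_loc)))

    add([[0.0, 0.0, 0.0]], h_disk)
    for rr in np.arange(h_disk, a - 0.3 * h_disk, h_disk):
        add(_circle_points(0, 0, 0, rr, h_disk, rng), h_disk)
    add(_circle_points(0, 0, 0, a, h_disk * 0.8, rng), h_disk)
    add(_circle_points(0, 0, 0, R, h_max, rng), h_max)
    # dome structural points
    import trimesh
    ico = trimesh.creation.icosphere(subdivisions=3, radius=R)
    dome = np.asarray(ico.vertices)
    dome = dome[dome[:, 2] > 0.05 * R]
    add(dome, h_max)

    def inside_plane(p3, s):
        r = np.hypot(p3[:, 0], p3[:, 1])
        return r < R - 0.45 * s

    plane = _graded_points(feats, h_max, h_disk, (-R, -R), (R, R),
                           inside_plane, rng, dims=2, z_plane=0.0)

    def inside_vol(p3, s):
        r = np.linalg.norm(p3, axis=1)
        return (r < R - 0.45 * s) & (p3[:, 2] > 0.4 * s)

    vol = _graded_points(feats, h_max, h_disk, (-R, -R, 0.0), (R, R, R),
                         inside_vol, rng, dims=3)
    struct_pts = np.vstack(structural)
    struct_r = np.concatenate(radii)
    plane = _prune_near(plane, struct_pts, struct_r)
    vol = _prune_near(vol, struct_pts, struct_r)
    mesh = _delaunay_mesh(np.vstack([struct_pts, plane, vol]))
    tris, owners = mesh.boundary_facets()
    cent = mesh.nodes[tris].mean(axis=1)
    on_plane = np.abs(cent[:, 2]) < 1e-9 * R
    r2d = np.hypot(cent[:, 0], cent[:, 1])
    tags = {"disk": tris[on_plane & (r2d <= a * (1 + 1e-9))],
            "plane": tris[on_plane & (r2d > a * (1 + 1e-9))],
            "outer": tris[~on_plane]}
    mesh.facet_tags = {t: v for t, v in tags.items() if len(v)}
    return mesh
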