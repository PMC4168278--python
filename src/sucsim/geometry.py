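"""Parametric gyral-slab volume conductor meshes.

The simplified precentral-gyrus model is a rectangular slab with a folded
gray-matter sheet: cerebrospinal fluid (CSF) on top, a gray-matter (GM)
sheet of constant thickness following a smooth cosine-walled gyrus/sulcus
profile extruded along the y axis, and white matter (WM) beneath.
Subdural contacts are disc-shaped Dirichlet patches on the top surface;
the side and bottom surfaces act as the distant return (ground).

Conventions: right-handed coordinates, z up, top surface at ``z = extent_z``,
extrusion along y. All lengths are millimetres. Meshing is a structured
hexahedral grid subdivided into 6 tetrahedra per cell (Kuhn/Freudenthal
triangulation), which is deterministic, conforming, and tessellates the box
exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence

import numpy as np

# Tissue region codes.
CSF, GM, WM = 1, 2, 3
REGION_NAMES = {CSF: "CSF", GM: "GM", WM: "WM"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}


@dataclass(frozen=True)
class SlabSpec:
    """Anatomical and discretization parameters of the extruded slab (mm).

    Defaults approximate typical human precentral-gyrus dimensions and keep
    the mesh at desk scale (~10^6 tetrahedra).
    """

    extent_x: float = 60.0
    extent_y: float = 60.0
    extent_z: float = 40.0
    gyral_width: float = 12.0
    sulcal_width: float = 3.0
    sulcal_depth: float = 15.0
    gm_thickness: float = 2.5
    csf_thickness: float = 2.0
    resolution_h: float = 0.8

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0.0:
                raise ValueError(f"SlabSpec.{name} must be strictly positive")
        if not self.gm_thickness < self.sulcal_depth:
            raise ValueError("gm_thickness must be smaller than sulcal_depth")
        if not self.sulcal_depth + self.csf_thickness < self.extent_z:
            raise ValueError("sulcal_depth + csf_thickness must fit inside extent_z")
        if self.resolution_h > self.gm_thickness:
            raise ValueError(
                "resolution_h exceeds gm_thickness: the gray-matter sheet "
                "would not be resolved by at least one element layer"
            )
        floor = self.extent_z - self.csf_thickness - self.sulcal_depth - self.gm_thickness
        if floor <= 0.0:
            raise ValueError("gyral fold pierces the bottom of the slab")

    @property
    def fold_period(self) -> float:
        return self.gyral_width + self.sulcal_width

    def fold_depth(self, x: np.ndarray) -> np.ndarray:
        """Depth of the pial surface below the CSF/GM interface plane at x.

        Zero on the gyral crown plateau, rising along a half-cosine wall to
        ``sulcal_depth`` at the sulcus centre. A crown is centred at
        ``extent_x / 2``; the profile is periodic with period
        ``gyral_width + sulcal_width``.
        """
        x = np.asarray(x, dtype=float)
        p = self.fold_period
        u = np.abs((x - 0.5 * self.extent_x + 0.5 * p) % p - 0.5 * p)
        s = np.clip(u - 0.5 * self.gyral_width, 0.0, 0.5 * self.sulcal_width)
        return 0.5 * self.sulcal_depth * (1.0 - np.cos(np.pi * s / (0.5 * self.sulcal_width)))

    def pial_height(self, x: np.ndarray) -> np.ndarray:
        """z coordinate of the pial (CSF/GM) surface at x."""
        return self.extent_z - self.csf_thickness - self.fold_depth(x)


@dataclass
class LabeledTetMesh:
    """Tetrahedral mesh with tissue labels and tagged boundary facet sets.

    ``boundary_facets[tag]`` is an (F, 3) array of node triples;
    ``boundary_owners[tag]`` holds the single tetrahedron owning each facet.
    ``grid`` keeps the structured coordinate axes (xs, ys, zs) for meshes
    built from a tensor-product grid (used for interpolation between
    refinement levels); node ordering is then C-order over (ix, iy, iz).
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_labels: np.ndarray
    boundary_facets: Dict[str, np.ndarray]
    boundary_owners: Dict[str, np.ndarray]
    grid: tuple | None = None
    _volumes: np.ndarray | None = field(default=None, repr=False)

    @property
    def num_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def num_tets(self) -> int:
        return self.tets.shape[0]

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes (mm^3); positive for correctly oriented elements."""
        if self._volumes is None:
            p = self.nodes[self.tets]
            e = p[:, 1:] - p[:, :1]
            self._volumes = np.linalg.det(e) / 6.0
        return self._volumes

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def facet_areas(self, tag: str) -> np.ndarray:
        tri = self.nodes[self.boundary_facets[tag]]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def facet_centroids(self, tag: str) -> np.ndarray:
        return self.nodes[self.boundary_facets[tag]].mean(axis=1)


@dataclass
class ElectrodePatch:
    """Disc contact: top-surface facets under the metal plus the node set.

    ``facet_ids`` (facets whose centroids fall inside the disc) define the
    contact area and current-integration surface; ``node_ids`` (top-surface
    nodes inside the disc) define the equipotential Dirichlet set. Using
    the in-disc nodes keeps the effective disc radius centred on the
    nominal one (constraining every vertex of the selected facets would
    bias it outward by O(h)).
    """

    tag: str
    center: np.ndarray
    normal: np.ndarray
    diameter: float
    facet_ids: np.ndarray  # indices into boundary_facets["top"]
    node_ids: np.ndarray | None = None

    def facets(self, mesh: LabeledTetMesh) -> np.ndarray:
        return mesh.boundary_facets["top"][self.facet_ids]

    def nodes(self, mesh: LabeledTetMesh) -> np.ndarray:
        if self.node_ids is not None and self.node_ids.size:
            return self.node_ids
        return np.unique(self.facets(mesh))

    def area(self, mesh: LabeledTetMesh) -> float:
        return float(mesh.facet_areas("top")[self.facet_ids].sum())


@dataclass(frozen=True)
class PaddleLayout:
    """Quincunx 5-contact paddle: four corner contacts around a middle one.

    ``contact_spacing`` is the centre-to-centre distance from the middle
    contact to each corner contact; corners sit on the diagonals of a square
    rotated by ``orientation`` (radians, in the top plane).
    """

    center: tuple = (30.0, 30.0)
    contact_spacing: float = 10.0
    orientation: float = 0.0

    def centers(self) -> np.ndarray:
        cx, cy = self.center
        ang = self.orientation + np.deg2rad([45.0, 135.0, 225.0, 315.0])
        corners = np.stack(
            [cx + self.contact_spacing * np.cos(ang), cy + self.contact_spacing * np.sin(ang)],
            axis=1,
        )
        # Order contacts 1, 2, (middle) 3, 4, 5.
        return np.vstack([corners[:2], [[cx, cy]], corners[2:]])


@dataclass
class ReferenceSet:
    """Grounded boundary: node indices plus the contributing facet tags."""

    tags: tuple
    node_ids: np.ndarray


# ---------------------------------------------------------------------------
# structured box meshing

_STRIDES_PERMS = list(itertools.permutations((0, 1, 2)))


def _perm_sign(p: Sequence[int]) -> int:
    e = np.zeros((3, 3))
    for i, a in enumerate(p):
        e[i, a] = 1.0
    return int(round(np.linalg.det(e)))


def make_box_mesh(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product hexahedral grid split into 6 positively oriented tets
    per cell (Kuhn triangulation, conforming across cells)."""
    xs, ys, zs = (np.asarray(a, dtype=float) for a in (xs, ys, zs))
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    if min(nx, ny, nz) < 1:
        raise ValueError("each axis needs at least 2 grid planes")
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    strides = np.array([(ny + 1) * (nz + 1), nz + 1, 1], dtype=np.int64)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    base = (ii * strides[0] + jj * strides[1] + kk * strides[2]).ravel()

    tet_list = []
    for p in _STRIDES_PERMS:
        o1 = strides[p[0]]
        o2 = o1 + strides[p[1]]
        o3 = o2 + strides[p[2]]
        t = np.stack([base, base + o1, base + o2, base + o3], axis=1)
        if _perm_sign(p) < 0:
            t = t[:, [0, 1, 3, 2]]
        tet_list.append(t)
    # interleave so the 6 tets of a cell are contiguous
    tets = np.stack(tet_list, axis=1).reshape(-1, 4).astype(np.int64)
    return nodes, tets


def _boundary_facets_box(
    nodes: np.ndarray, tets: np.ndarray, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray
) -> tuple[Dict[str, np.ndarray], Dict[str, np.ndarray]]:
    """Extract boundary triangles of the tessellated box, tagged
    top (z = max), bottom (z = min) and side (the four lateral faces)."""
    faces = tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
    owners = np.repeat(np.arange(tets.shape[0], dtype=np.int64), 4)
    fs = np.sort(faces, axis=1)
    key = (fs[:, 0].astype(np.int64) * (1 << 21) + fs[:, 1]) * (1 << 21) + fs[:, 2]
    order = np.argsort(key, kind="stable")
    key_sorted = key[order]
    uniq_start = np.flatnonzero(np.r_[True, key_sorted[1:] != key_sorted[:-1]])
    counts = np.diff(np.r_[uniq_start, key_sorted.size])
    boundary_pos = order[uniq_start[counts == 1]]
    bfaces = fs[boundary_pos]
    bowners = owners[boundary_pos]

    tol = 1e-9 * max(xs[-1] - xs[0], ys[-1] - ys[0], zs[-1] - zs[0])
    fz = nodes[bfaces, 2]
    fx = nodes[bfaces, 0]
    fy = nodes[bfaces, 1]
    on_top = np.all(np.abs(fz - zs[-1]) < tol, axis=1)
    on_bottom = np.all(np.abs(fz - zs[0]) < tol, axis=1)
    on_side = np.all(np.abs(fx - xs[0]) < tol, axis=1)
    on_side |= np.all(np.abs(fx - xs[-1]) < tol, axis=1)
    on_side |= np.all(np.abs(fy - ys[0]) < tol, axis=1)
    on_side |= np.all(np.abs(fy - ys[-1]) < tol, axis=1)

    facets = {"top": bfaces[on_top], "bottom": bfaces[on_bottom], "side": bfaces[on_side]}
    owner = {"top": bowners[on_top], "bottom": bowners[on_bottom], "side": bowners[on_side]}
    n_classified = sum(v.shape[0] for v in facets.values())
    if n_classified != bfaces.shape[0]:
        raise RuntimeError("unclassified boundary facets on a box mesh")
    return facets, owner


def build_box_mesh(
    xs: np.ndarray, ys: np.ndarray, zs: np.ndarray, label: int = WM
) -> LabeledTetMesh:
    """Homogeneous labeled box mesh on a tensor-product grid (benchmarks)."""
    nodes, tets = make_box_mesh(xs, ys, zs)
    labels = np.full(tets.shape[0], label, dtype=np.int8)
    facets, owners = _boundary_facets_box(nodes, tets, xs, ys, zs)
    return LabeledTetMesh(nodes, tets, labels, facets, owners, grid=(xs, ys, zs))


def _segmented_axis(breaks: Sequence[float], h: float, factor: float = 1.0) -> np.ndarray:
    """Grid coordinates hitting every break point exactly, with spacing as
    close to ``h / factor`` as rounding allows within each segment."""
    parts = [np.array([breaks[0]])]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(1, round((b - a) / h * factor))
        parts.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(parts)


def build_slab_mesh(spec: SlabSpec, z_refine: float = 1.0) -> LabeledTetMesh:
    """Build the labeled extruded-slab mesh from anatomical parameters.

    Region labels are assigned from element centroids: CSF above the pial
    surface (including the fluid filling the sulci), a GM sheet of
    ``gm_thickness`` (vertical offset) below it, WM underneath. The z grid
    conforms to the two flat interfaces under the gyral crown (pial surface
    and GM/WM boundary), so the represented geometry does not shift when
    the vertical resolution changes.

    ``z_refine`` multiplies the number of z subdivisions per segment while
    keeping the x-y grid — and hence the top-surface discretization and any
    electrode patches — identical; used for mesh-convergence studies.
    """
    h = spec.resolution_h
    nx = max(1, round(spec.extent_x / h))
    ny = max(1, round(spec.extent_y / h))
    xs = np.linspace(0.0, spec.extent_x, nx + 1)
    ys = np.linspace(0.0, spec.extent_y, ny + 1)
    z_pial = spec.extent_z - spec.csf_thickness
    z_gmwm = z_pial - spec.gm_thickness
    # Grade the vertical grid toward the contact surface: the disc-edge field
    # is singular, so the thin CSF and GM layers carry the steepest gradients.
    zs = np.concatenate(
        [
            _segmented_axis((0.0, z_gmwm), h, z_refine),
            _segmented_axis((z_gmwm, z_pial), h / 2.0, z_refine)[1:],
            _segmented_axis((z_pial, spec.extent_z), h / 4.0, z_refine)[1:],
        ]
    )
    nodes, tets = make_box_mesh(xs, ys, zs)

    c = nodes[tets].mean(axis=1)
    zp = spec.pial_height(c[:, 0])
    labels = np.full(tets.shape[0], WM, dtype=np.int8)
    labels[c[:, 2] > zp] = CSF
    gm_mask = (c[:, 2] <= zp) & (c[:, 2] > zp - spec.gm_thickness)
    labels[gm_mask] = GM
    if not gm_mask.any():
        raise ValueError("mesh resolution too coarse: gray-matter sheet not represented")

    facets, owners = _boundary_facets_box(nodes, tets, xs, ys, zs)
    return LabeledTetMesh(nodes, tets, labels, facets, owners, grid=(xs, ys, zs))


# ---------------------------------------------------------------------------
# electrodes and reference

def _connected(facets: np.ndarray) -> bool:
    """True if the triangle set is edge-connected (union-find over nodes)."""
    if facets.shape[0] <= 1:
        return True
    ids = {n: i for i, n in enumerate(np.unique(facets))}
    parent = list(range(len(ids)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for tri in facets:
        a = find(ids[tri[0]])
        for n in tri[1:]:
            b = find(ids[n])
            parent[b] = a
    roots = {find(i) for i in range(len(ids))}
    return len(roots) == 1


def place_disc_electrode(
    mesh: LabeledTetMesh,
    center: Iterable[float],
    diameter: float = 4.0,
    tag: str = "electrode",
) -> ElectrodePatch:
    """Select the top-surface facets whose centroids fall inside the disc.

    Only the contact (bottom) side of a subdural disc is exposed, so the
    contact is the set of top-boundary facets under the metal.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    center = np.asarray(list(center), dtype=float)
    cent = mesh.facet_centroids("top")
    d2 = (cent[:, 0] - center[0]) ** 2 + (cent[:, 1] - center[1]) ** 2
    ids = np.flatnonzero(d2 <= (0.5 * diameter) ** 2)
    if ids.size == 0:
        raise ValueError(
            f"disc at ({center[0]:.3g}, {center[1]:.3g}) contains no top-surface "
            "facet centroid: check the contact position and mesh resolution"
        )
    facets = mesh.boundary_facets["top"][ids]
    if not _connected(facets):
        raise ValueError("disc electrode patch is not edge-connected")
    ztop = float(mesh.nodes[facets[0, 0], 2])
    c3 = np.array([center[0], center[1], ztop])
    top_nodes = np.unique(mesh.boundary_facets["top"])
    nd2 = (mesh.nodes[top_nodes, 0] - center[0]) ** 2 + (mesh.nodes[top_nodes, 1] - center[1]) ** 2
    node_ids = top_nodes[nd2 <= (0.5 * diameter) ** 2 * (1.0 + 1e-12)]
    return ElectrodePatch(tag, c3, np.array([0.0, 0.0, 1.0]), float(diameter), ids, node_ids)


def place_paddle_array(
    mesh: LabeledTetMesh, layout: PaddleLayout, diameter: float = 4.0
) -> list[ElectrodePatch]:
    """Place the 5-contact paddle; electrode_3 is the middle contact."""
    centers = layout.centers()
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < diameter:
        raise ValueError(
            f"paddle contacts overlap: minimum centre distance {d.min():.3g} mm "
            f"< diameter {diameter:.3g} mm"
        )
    patches = [
        place_disc_electrode(mesh, c, diameter, tag=f"electrode_{i + 1}")
        for i, c in enumerate(centers)
    ]
    seen: set = set()
    for p in patches:
        s = set(p.facet_ids.tolist())
        if seen & s:
            raise ValueError(f"paddle contact {p.tag} overlaps another contact")
        seen |= s
    return patches


def designate_reference(mesh: LabeledTetMesh, tags: Iterable[str] = ("side", "bottom")) -> ReferenceSet:
    """Nodes to be held at 0 V (the distant unipolar return)."""
    tags = tuple(tags)
    if len(tags) == 0:
        raise ValueError("a grounded reference surface is required for a unipolar solve")
    for t in tags:
        if t not in mesh.boundary_facets:
            raise KeyError(f"unknown boundary tag {t!r}; have {sorted(mesh.boundary_facets)}")
    nodes = np.unique(np.concatenate([mesh.boundary_facets[t].ravel() for t in tags]))
    return ReferenceSet(tags, nodes)
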