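"""Triangular finite-element mesh over the tissue domain.

The mesh is a structured right-triangle grid masked to the (rasterized)
domain: grid squares of side ``h`` are split along one diagonal, with ``h``
chosen so the mean edge length equals the requested target (the three edge
populations h, h, h*sqrt(2) average to h(2+sqrt(2))/3).  This is fully
deterministic, tiles the domain to within raster error, and guarantees a
minimum triangle angle of 45 degrees.

Tumor elements are partitioned into spatial regions by k-means on element
centroids; each region carries one proliferation-rate unknown during
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, RegularGridInterpolator
from sklearn.cluster import KMeans

# mean edge of the structured split: (h + h + h*sqrt(2)) / 3
_MEAN_EDGE_FACTOR = (2.0 + np.sqrt(2.0)) / 3.0


@dataclass
class TriMesh:
    """2D mesh of 3-node (P1) triangles in physical mm coordinates."""

    nodes: np.ndarray  # (n_nodes, 2)
    triangles: np.ndarray  # (n_tri, 3), counter-clockwise
    node_in_roi: np.ndarray  # (n_nodes,) bool
    boundary_nodes: np.ndarray  # indices on the domain hull
    _areas: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def areas(self) -> np.ndarray:
        if self._areas is None:
            p = self.nodes[self.triangles]
            self._areas = 0.5 * np.abs(
                (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
            )
        return self._areas

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def edge_lengths(self) -> np.ndarray:
        """Unique edge lengths (each edge counted once)."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e = np.unique(np.sort(e, axis=1), axis=0)
        d = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])


@dataclass
class RegionPartition:
    """Assignment of tumor elements to piecewise-constant parameter regions."""

    element_ids: np.ndarray  # tumor element indices into mesh.triangles
    region_of_element: np.ndarray  # region label per tumor element
    n_regions: int
    region_areas: np.ndarray  # mm^2 per region


def _mask_interpolator(mask: np.ndarray, spacing) -> RegularGridInterpolator:
    sy, sx = spacing[1], spacing[0]
    h, w = mask.shape
    ys = np.arange(h) * sy
    xs = np.arange(w) * sx
    return RegularGridInterpolator(
        (ys, xs), mask.astype(float), bounds_error=False, fill_value=0.0
    )


def build_mesh(
    domain_mask: np.ndarray,
    spacing: tuple[float, float],
    target_edge_mm: float = 1.5,
    roi_mask: np.ndarray | None = None,
) -> TriMesh:
    """Mesh the True region of ``domain_mask`` with ~``target_edge_mm`` triangles.

    Voxel-centered convention: pixel (i, j) sits at physical (x, y) =
    (j*sx, i*sy).  A triangle is kept when its centroid falls inside the
    mask; the largest edge-connected component of kept triangles is returned.
    """
    domain_mask = np.asarray(domain_mask, dtype=bool)
    if not domain_mask.any():
        raise ValueError("domain_mask is empty")
    h = target_edge_mm / _MEAN_EDGE_FACTOR
    mask_area = domain_mask.sum() * spacing[0] * spacing[1]
    if mask_area < 2.0 * h * h:
        raise ValueError(
            "domain too small to mesh at the requested edge length "
            f"({target_edge_mm} mm); refine the mask or reduce the target"
        )
    ii, jj = np.nonzero(domain_mask)
    sy, sx = spacing[1], spacing[0]
    x0, x1 = jj.min() * sx, jj.max() * sx
    y0, y1 = ii.min() * sy, ii.max() * sy
    nx = max(2, int(np.ceil((x1 - x0) / h)) + 1)
    ny = max(2, int(np.ceil((y1 - y0) / h)) + 1)
    # center the grid on the bounding box so symmetric domains mesh
    # symmetrically (the overshoot is split between both sides)
    gx = x0 - ((nx - 1) * h - (x1 - x0)) / 2.0 + np.arange(nx) * h
    gy = y0 - ((ny - 1) * h - (y1 - y0)) / 2.0 + np.arange(ny) * h
    X, Y = np.meshgrid(gx, gy)
    pts = np.column_stack([X.ravel(), Y.ravel()])

    def nid(iy, ix):
        return iy * nx + ix

    tris = []
    for iy in range(ny - 1):
        for ix in range(nx - 1):
            a = nid(iy, ix)
            b = nid(iy, ix + 1)
            c = nid(iy + 1, ix + 1)
            d = nid(iy + 1, ix)
            # alternate the split diagonal checkerboard-wise ("union jack")
            # so the triangulation has no preferred direction
            if (iy + ix) % 2 == 0:
                tris.append([a, b, c])  # CCW in (x, y)
                tris.append([a, c, d])
            else:
                tris.append([a, b, d])
                tris.append([b, c, d])
    tris = np.asarray(tris, dtype=int)

    interp = _mask_interpolator(domain_mask, spacing)
    cent = pts[tris].mean(axis=1)
    inside = interp(cent[:, [1, 0]]) >= 0.5
    tris = tris[inside]
    if tris.shape[0] < 2:
        raise ValueError(
            "domain too small to mesh at the requested edge length "
            f"({target_edge_mm} mm); refine the mask or reduce the target"
        )

    # largest edge-connected component of kept triangles
    tris = _largest_component(tris)

    used = np.unique(tris)
    remap = -np.ones(pts.shape[0], dtype=int)
    remap[used] = np.arange(used.size)
    nodes = pts[used]
    triangles = remap[tris]

    # boundary = nodes of edges used by exactly one triangle
    edges = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    edges_sorted = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges_sorted, axis=0, return_counts=True)
    boundary_nodes = np.unique(uniq[counts == 1])

    if roi_mask is not None:
        roi_interp = _mask_interpolator(np.asarray(roi_mask, dtype=bool), spacing)
        node_in_roi = roi_interp(nodes[:, [1, 0]]) >= 0.5
    else:
        node_in_roi = np.zeros(nodes.shape[0], dtype=bool)

    mesh = TriMesh(
        nodes=nodes,
        triangles=triangles,
        node_in_roi=node_in_roi,
        boundary_nodes=boundary_nodes,
    )
    if np.any(mesh.areas() <= 0):
        raise ValueError("degenerate (zero-area) triangle produced")
    return mesh


def _largest_component(tris: np.ndarray) -> np.ndarray:
    """Keep the largest set of triangles connected through shared edges."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    edges = {}
    for t_idx, tri in enumerate(tris):
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(a, b), max(a, b))
            edges.setdefault(key, []).append(t_idx)
    rows, cols = [], []
    for owners in edges.values():
        if len(owners) == 2:
            rows.append(owners[0])
            cols.append(owners[1])
    n = tris.shape[0]
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp == 1:
        return tris
    sizes = np.bincount(labels)
    return tris[labels == np.argmax(sizes)]


def tumor_elements(mesh: TriMesh, roi_mask: np.ndarray, spacing) -> np.ndarray:
    """Indices of elements whose centroid lies inside the tumor ROI raster."""
    interp = _mask_interpolator(np.asarray(roi_mask, dtype=bool), spacing)
    cent = mesh.centroids()
    return np.nonzero(interp(cent[:, [1, 0]]) >= 0.5)[0]


def partition_regions(
    mesh: TriMesh,
    roi_elements: np.ndarray,
    elements_per_region: int = 5,
    seed: int = 0,
) -> RegionPartition:
    """Cluster tumor-element centroids into regions by k-means.

    ``n_regions = round(|roi_elements| / elements_per_region)`` (at least 1).
    Labels are relabeled in lexicographic order of cluster centers so the
    partition is invariant to k-means' internal label permutation.
    """
    roi_elements = np.asarray(roi_elements, dtype=int)
    if roi_elements.size == 0:
        raise ValueError("roi_elements is empty")
    if elements_per_region < 1:
        raise ValueError("elements_per_region must be >= 1")
    n_regions = max(1, int(round(roi_elements.size / elements_per_region)))
    n_regions = min(n_regions, roi_elements.size)
    cent = mesh.centroids()[roi_elements]
    if n_regions == 1:
        labels = np.zeros(roi_elements.size, dtype=int)
    else:
        km = KMeans(n_clusters=n_regions, n_init=10, random_state=seed)
        raw = km.fit_predict(cent)
        order = np.lexsort((km.cluster_centers_[:, 1], km.cluster_centers_[:, 0]))
        relabel = np.empty(n_regions, dtype=int)
        relabel[order] = np.arange(n_regions)
        labels = relabel[raw]
    areas = mesh.areas()[roi_elements]
    region_areas = np.bincount(labels, weights=areas, minlength=n_regions)
    if np.any(region_areas <= 0):
        raise ValueError("k-means produced an empty region")
    return RegionPartition(
        element_ids=roi_elements,
        region_of_element=labels,
        n_regions=n_regions,
        region_areas=region_areas,
    )


def raster_to_nodal(image: np.ndarray, mesh: TriMesh, spacing) -> np.ndarray:
    """Bilinear sample of a pixel image at the mesh nodes."""
    image = np.asarray(image, dtype=float)
    sy, sx = spacing[1], spacing[0]
    h, w = image.shape
    ys = np.arange(h) * sy
    xs = np.arange(w) * sx
    interp = RegularGridInterpolator((ys, xs), image, bounds_error=True)
    pts = mesh.nodes[:, [1, 0]]
    if (
        pts[:, 0].min() < ys[0] - 1e-9
        or pts[:, 0].max() > ys[-1] + 1e-9
        or pts[:, 1].min() < xs[0] - 1e-9
        or pts[:, 1].max() > xs[-1] + 1e-9
    ):
        raise ValueError("mesh node outside the image frame")
    return interp(np.clip(pts, [ys[0], xs[0]], [ys[-1], xs[-1]]))


def nodal_to_raster(
    field: np.ndarray,
    mesh: TriMesh,
    grid_shape: tuple[int, int],
    spacing,
    fill_value: float = 0.0,
) -> np.ndarray:
    """Barycentric (piecewise-linear) interpolation of a nodal field onto pixels."""
    sy, sx = spacing[1], spacing[0]
    hh, ww = grid_shape
    X, Y = np.meshgrid(np.arange(ww) * sx, np.arange(hh) * sy)
    interp = LinearNDInterpolator(mesh.nodes, np.asarray(field, float), fill_value=fill_value)
    return interp(np.column_stack([X.ravel(), Y.ravel()])).reshape(hh, ww)


def element_field_to_nodal_weights(mesh: TriMesh):
    """Sparse (n_nodes, n_tri) matrix averaging an element field to nodes.

    Node value = area-weighted mean over incident elements.  Used to place
    the piecewise-constant proliferation field on nodes for the reaction
    term; the mapping is linear, so gradients chain through its transpose.
    """
    from scipy.sparse import coo_matrix

    areas = mesh.areas()
    rows = mesh.triangles.ravel()
    cols = np.repeat(np.arange(mesh.n_triangles), 3)
    vals = np.repeat(areas / 3.0, 3)
    W = coo_matrix((vals, (rows, cols)), shape=(mesh.n_nodes, mesh.n_triangles)).tocsr()
    norm = np.asarray(W.sum(axis=1)).ravel()
    norm[norm == 0] = 1.0
    from scipy.sparse import diags

    return diags(1.0 / norm) @ W
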