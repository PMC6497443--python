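"""Occupancy-grid shortest paths inside the walkable nest region.

The walkable region is rasterised on a square grid (default 0.5 mm).  Two
graph metrics are exposed:

* an 8-connected graph with exact step lengths (h, h*sqrt(2)) for wall-aware
  geodesic distances, and
* a 4-connected graph for the rectilinear ("parallel or perpendicular to the
  walls") distance to the entrance.

Because every path between different convex units (chambers/corridors) must
cross the centre line of some opening corridor, cross-unit geodesic queries
are answered exactly on the grid metric by the decomposition

    d(p, q) = min over portal cells c of  d(p, c) + d(c, q)

with full-grid Dijkstra maps precomputed from every portal cell.  Same-unit
queries return the Euclidean distance (units are convex rectangles, so the
straight segment is feasible and optimal).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = ["GridPathEngine"]

_SQRT2 = np.sqrt(2.0)


class GridPathEngine:
    """Wall-aware distance engine for one :class:`~colonystate.geometry.NestGeometry`.

    Parameters
    ----------
    nest : NestGeometry
    resolution : float
        Grid cell size in mm (default 0.5).
    """

    def __init__(self, nest, resolution: float = 0.5):
        self.nest = nest
        self.resolution = float(resolution)
        h = self.resolution
        x0, y0, x1, y1 = nest.bounds
        self._origin = np.array([x0, y0])
        self._ncx = int(np.ceil((x1 - x0) / h - 1e-9))
        self._ncy = int(np.ceil((y1 - y0) / h - 1e-9))
        cx = x0 + (np.arange(self._ncx) + 0.5) * h
        cy = y0 + (np.arange(self._ncy) + 0.5) * h
        xx, yy = np.meshgrid(cx, cy, indexing="ij")
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        mask = nest.unit_of_many(centers) >= 0
        self.mask = mask.reshape(self._ncx, self._ncy)
        self.node_id = np.where(self.mask, np.cumsum(mask).reshape(self.mask.shape) - 1, -1)
        self.n_nodes = int(self.mask.sum())
        self.cell_centers = centers[mask]
        self._graph8 = None
        self._graph4 = None
        self._entrance_map = None
        self._portal_maps = None
        self._portal_nodes = None

    # -- graph construction --------------------------------------------------

    def _build_graph(self, diagonal: bool) -> "coo_matrix":
        h = self.resolution
        ids = self.node_id
        rows, cols, wts = [], [], []
        shifts = [((1, 0), h), ((0, 1), h)]
        if diagonal:
            shifts += [((1, 1), h * _SQRT2), ((1, -1), h * _SQRT2)]
        for (dx, dy), w in shifts:
            a = ids[
                max(0, -dx) : ids.shape[0] - max(0, dx),
                max(0, -dy) : ids.shape[1] - max(0, dy),
            ]
            b = ids[
                max(0, dx) : ids.shape[0] - max(0, -dx),
                max(0, dy) : ids.shape[1] - max(0, -dy),
            ]
            ok = (a >= 0) & (b >= 0)
            rows.append(a[ok])
            cols.append(b[ok])
            wts.append(np.full(ok.sum(), w))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        wts = np.concatenate(wts)
        return coo_matrix((wts, (rows, cols)), shape=(self.n_nodes, self.n_nodes)).tocsr()

    @property
    def graph8(self):
        if self._graph8 is None:
            self._graph8 = self._build_graph(diagonal=True)
        return self._graph8

    @property
    def graph4(self):
        if self._graph4 is None:
            self._graph4 = self._build_graph(diagonal=False)
        return self._graph4

    # -- cell lookup ---------------------------------------------------------

    def cells_of(self, pts: np.ndarray) -> np.ndarray:
        """Node index of the walkable cell containing (or nearest to) each point."""
        pts = np.asarray(pts, dtype=float)
        h = self.resolution
        ix = np.clip(((pts[:, 0] - self._origin[0]) / h).astype(int), 0, self._ncx - 1)
        iy = np.clip(((pts[:, 1] - self._origin[1]) / h).astype(int), 0, self._ncy - 1)
        nodes = self.node_id[ix, iy]
        bad = np.flatnonzero(nodes < 0)
        for k in bad:  # boundary slivers: search outward for nearest walkable cell
            nodes[k] = self._nearest_cell(pts[k], ix[k], iy[k])
        return nodes

    def _nearest_cell(self, p: np.ndarray, ix: int, iy: int) -> int:
        for radius in range(1, max(self._ncx, self._ncy)):
            xs = slice(max(0, ix - radius), min(self._ncx, ix + radius + 1))
            ys = slice(max(0, iy - radius), min(self._ncy, iy + radius + 1))
            sub = self.node_id[xs, ys]
            cand = sub[sub >= 0]
            if cand.size:
                centers = self.cell_centers[cand]
                return int(cand[np.argmin(((centers - p) ** 2).sum(axis=1))])
        raise RuntimeError("no walkable cells in grid")

    # -- entrance (rectilinear) map -------------------------------------------

    @property
    def entrance_map(self) -> np.ndarray:
        """4-connected shortest-path length from every cell to the entrance cell."""
        if self._entrance_map is None:
            src = self.cells_of(np.asarray(self.nest.entrance_point)[None, :])
            self._entrance_map = dijkstra(
                self.graph4, directed=False, indices=src
            )[0]
        return self._entrance_map

    def entrance_distances(self, pts: np.ndarray) -> np.ndarray:
        """Rectilinear wall-aware distance to the entrance for each point.

        Never less than the unconstrained L1 distance to the entrance point.
        """
        pts = np.asarray(pts, dtype=float)
        grid = self.entrance_map[self.cells_of(pts)]
        l1 = np.abs(pts - np.asarray(self.nest.entrance_point)).sum(axis=1)
        return np.maximum(grid, l1)

    # -- portal maps and geodesic distances -----------------------------------

    def _portals(self):
        """Dijkstra maps from the centre-line cells of every opening corridor."""
        if self._portal_maps is None:
            nodes = []
            for rect in self.nest.corridors:
                in_rect = (
                    (self.cell_centers[:, 0] >= rect.x0)
                    & (self.cell_centers[:, 0] <= rect.x1)
                    & (self.cell_centers[:, 1] >= rect.y0)
                    & (self.cell_centers[:, 1] <= rect.y1)
                )
                idx = np.flatnonzero(in_rect)
                if idx.size == 0:
                    raise RuntimeError(
                        "corridor thinner than grid resolution; refine the grid"
                    )
                # keep the column (or row, whichever crosses the gap) closest
                # to the corridor centre: every cross-corridor grid path
                # visits it, so the decomposition over its cells is exact
                axis = 0 if rect.width <= rect.height else 1
                coords = self.cell_centers[idx, axis]
                target = (rect.x0 + rect.x1) / 2 if axis == 0 else (rect.y0 + rect.y1) / 2
                keep = np.abs(coords - target) <= self.resolution / 2 + 1e-9
                nodes.append(idx[keep])
            self._portal_nodes = (
                np.concatenate(nodes) if nodes else np.empty(0, dtype=int)
            )
            if self._portal_nodes.size:
                self._portal_maps = dijkstra(
                    self.graph8, directed=False, indices=self._portal_nodes
                )
            else:
                self._portal_maps = np.empty((0, self.n_nodes))
        return self._portal_maps

    def pair_distances(self, p: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Elementwise wall-aware distance between matching rows of p and q."""
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        up = self.nest.unit_of_many(p)
        uq = self.nest.unit_of_many(q)
        d = np.linalg.norm(p - q, axis=1)
        cross = up != uq
        if np.any(cross):
            maps = self._portals()
            cp = self.cells_of(p[cross])
            cq = self.cells_of(q[cross])
            d[cross] = (maps[:, cp] + maps[:, cq]).min(axis=0)
        return d

    def distance_matrix(self, p: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Full (n, m) wall-aware distance matrix between two point sets."""
        p = np.asarray(p, dtype=float)
        q = np.asarray(q, dtype=float)
        up = self.nest.unit_of_many(p)
        uq = self.nest.unit_of_many(q)
        d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
        cross = up[:, None] != uq[None, :]
        if np.any(cross):
            maps = self._portals()
            cp = self.cells_of(p)
            cq = self.cells_of(q)
            dg = (maps[:, cp][:, :, None] + maps[:, cq][:, None, :]).min(axis=0)
            d[cross] = dg[cross]
        return d
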