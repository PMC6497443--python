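"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised machinery: the occupancy
grid is rasterised with plain Python loops and shortest paths are taken on
the full graph without any portal decomposition, so they exercise a fully
independent code path.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra


class OracleGrid:
    """Loop-built occupancy grid over a nest's walkable rectangles."""

    def __init__(self, nest, h=0.5):
        self.h = h
        rects = nest.units
        x0 = min(r.x0 for r in rects)
        y0 = min(r.y0 for r in rects)
        x1 = max(r.x1 for r in rects)
        y1 = max(r.y1 for r in rects)
        self.origin = (x0, y0)
        nx_ = int(np.ceil((x1 - x0) / h - 1e-9))
        ny_ = int(np.ceil((y1 - y0) / h - 1e-9))
        self.shape = (nx_, ny_)
        self.id = -np.ones((nx_, ny_), dtype=int)
        centers = []
        k = 0
        for i in range(nx_):
            for j in range(ny_):
                cx = x0 + (i + 0.5) * h
                cy = y0 + (j + 0.5) * h
                if any(
                    r.x0 <= cx <= r.x1 and r.y0 <= cy <= r.y1 for r in rects
                ):
                    self.id[i, j] = k
                    centers.append((cx, cy))
                    k += 1
        self.centers = np.array(centers)
        self.n = k

    def graph(self, diagonal: bool):
        h = self.h
        moves = [(1, 0, h), (0, 1, h)]
        if diagonal:
            moves += [(1, 1, h * np.sqrt(2)), (1, -1, h * np.sqrt(2))]
        rows, cols, wts = [], [], []
        nx_, ny_ = self.shape
        for i in range(nx_):
            for j in range(ny_):
                a = self.id[i, j]
                if a < 0:
                    continue
                for dx, dy, w in moves:
                    ii, jj = i + dx, j + dy
                    if 0 <= ii < nx_ and 0 <= jj < ny_ and self.id[ii, jj] >= 0:
                        rows.append(a)
                        cols.append(self.id[ii, jj])
                        wts.append(w)
        return coo_matrix((wts, (rows, cols)), shape=(self.n, self.n)).tocsr()

    def cell(self, p):
        i = min(max(int((p[0] - self.origin[0]) / self.h), 0), self.shape[0] - 1)
        j = min(max(int((p[1] - self.origin[1]) / self.h), 0), self.shape[1] - 1)
        if self.id[i, j] >= 0:
            return self.id[i, j]
        d2 = ((self.centers - np.asarray(p)) ** 2).sum(axis=1)
        return int(np.argmin(d2))


def oracle_geodesic(nest, pairs, h=0.5):
    """Wall-aware distances: Euclid within one convex unit, grid Dijkstra else."""
    grid = OracleGrid(nest, h)
    g = grid.graph(diagonal=True)
    out = np.empty(len(pairs))
    need = []
    for k, (p, q) in enumerate(pairs):
        up, uq = nest.unit_of(p), nest.unit_of(q)
        if up == uq and up >= 0:
            out[k] = float(np.hypot(p[0] - q[0], p[1] - q[1]))
        else:
            need.append(k)
    if need:
        sources = [grid.cell(pairs[k][0]) for k in need]
        dmat = dijkstra(g, directed=False, indices=sources)
        for row, k in enumerate(need):
            out[k] = dmat[row, grid.cell(pairs[k][1])]
    return out


def oracle_rectilinear_entrance(nest, points, h=0.5):
    """4-connected grid BFS distance from each point to the entrance cell."""
    grid = OracleGrid(nest, h)
    g = grid.graph(diagonal=False)
    src = grid.cell(np.asarray(nest.entrance_point))
    dist = dijkstra(g, directed=False, indices=[src])[0]
    return np.array([dist[grid.cell(p)] for p in points])


def set_partitions(items):
    """All set partitions of a sequence (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_best_modularity(graph):
    """Max weighted modularity over every partition of the nodes (n <= 8)."""
    import networkx as nx

    nodes = list(graph.nodes)
    assert len(nodes) <= 8, "exhaustive search only feasible for small graphs"
    best_q, best_part = -np.inf, None
    for part in set_partitions(nodes):
        q = nx.community.modularity(
            graph, [set(p) for p in part], weight="weight"
        )
        if q > best_q:
            best_q, best_part = q, [set(p) for p in part]
    return best_q, best_part


def explicit_edge_jackknife(net, partition):
    """Leave-one-unit-edge-out recomputation of assortativity and its SE."""
    from colonystate.interaction_network import assortativity, build_network
    from colonystate.interaction_network import TrophallaxisEvent

    units = []
    for u, v, w in net.edges(data="weight", default=1):
        units.extend([(u, v)] * int(w))
    r_full = assortativity(net, partition).r
    ss = 0.0
    for k in range(len(units)):
        remaining = units[:k] + units[k + 1 :]
        events = [
            TrophallaxisEvent(u, v, 0, 2) for u, v in remaining
        ]
        g = build_network(events)
        try:
            r_k = assortativity(g, partition).r
        except Exception:
            continue
        ss += (r_k - r_full) ** 2
    return r_full, float(np.sqrt(ss))


def brute_force_ks(a, b):
    """KS statistic by direct CDF evaluation at every sample point."""
    pts = np.concatenate([a, b])
    best = 0.0
    for x in pts:
        fa = np.mean(np.asarray(a) <= x)
        fb = np.mean(np.asarray(b) <= x)
        best = max(best, abs(fa - fb))
    return best
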