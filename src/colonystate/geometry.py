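"""Nest geometry: chambers, openings, wall-aware distances and projection.

The nest is modelled in two dimensions as a union of axis-aligned rectangular
chambers connected by short rectangular opening corridors (default 6 mm wide,
spanning the 2 mm wall gap between adjacent chambers).  All coordinates are in
millimetres in the nest frame: origin at the entrance midpoint, x increasing
into the nest.

Two wall-aware distances are provided:

``geodesic_distance``
    Length of the shortest path between two points that stays inside the
    walkable region.  Within a single convex unit (chamber or corridor) this
    is the Euclidean distance; across units it is computed on an occupancy
    grid (default 0.5 mm, 8-connected moves) by decomposing every path over
    the opening it must cross.

``distance_to_entrance``
    Length of the shortest rectilinear (axis-aligned-segment) path to the
    entrance point, computed on a 4-connected grid.  This mimics an ant
    walking parallel or perpendicular to the nest walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from shapely.geometry import box as _shapely_box
from shapely.ops import unary_union

from .errors import NestConfigError, OutsideRegionError

#: Default chamber footprint (mm) of the wooden nest chamber.
CHAMBER_WIDTH = 65.0
CHAMBER_HEIGHT = 40.0
#: Default width (mm) of the entrance and of inter-chamber openings.
OPENING_WIDTH = 6.0
#: Default wall gap (mm) spanned by an opening corridor.
WALL_GAP = 2.0


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle given by lower-left corner and size (mm)."""

    x0: float
    y0: float
    width: float
    height: float

    @property
    def x1(self) -> float:
        return self.x0 + self.width

    @property
    def y1(self) -> float:
        return self.y0 + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> np.ndarray:
        return np.array([self.x0 + self.width / 2.0, self.y0 + self.height / 2.0])

    def contains(self, p: Sequence[float], tol: float = 0.0) -> bool:
        x, y = float(p[0]), float(p[1])
        return (
            self.x0 - tol <= x <= self.x1 + tol
            and self.y0 - tol <= y <= self.y1 + tol
        )

    def clamp(self, p: Sequence[float]) -> np.ndarray:
        """Nearest point of the (closed) rectangle to ``p``."""
        return np.array(
            [
                min(max(float(p[0]), self.x0), self.x1),
                min(max(float(p[1]), self.y0), self.y1),
            ]
        )

    def overlaps_interior(self, other: "Rect") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


@dataclass(frozen=True)
class Opening:
    """A wall gap connecting two chambers, or the first chamber to outside.

    ``chamber_b`` is an integer chamber index or the string ``"outside"``.
    ``center`` is the midpoint of the opening; ``width`` its clear width (mm).
    """

    chamber_a: int
    chamber_b: int | str
    center: tuple[float, float]
    width: float = OPENING_WIDTH

    @property
    def is_entrance(self) -> bool:
        return self.chamber_b == "outside"


@dataclass
class NestGeometry:
    """Walkable nest region: chambers plus opening corridors.

    Attributes
    ----------
    chambers : list of Rect
        The chamber footprints, indexed from the entrance chamber.
    corridors : list of Rect
        One short corridor rectangle per inter-chamber opening.
    openings : list of Opening
        All openings, including the entrance (``chamber_b == "outside"``).
    entrance_point : ndarray, shape (2,)
        Midpoint of the entrance, on the boundary of the entrance chamber.
    """

    chambers: list[Rect]
    corridors: list[Rect]
    openings: list[Opening]
    entrance_point: np.ndarray
    _engine: object = field(default=None, repr=False, compare=False)
    _polygon: object = field(default=None, repr=False, compare=False)

    @property
    def units(self) -> list[Rect]:
        """All convex walkable units: chambers first, then corridors."""
        return list(self.chambers) + list(self.corridors)

    @property
    def walkable_region(self):
        """Shapely polygon of the walkable region (chambers + corridors)."""
        if self._polygon is None:
            self._polygon = unary_union(
                [_shapely_box(r.x0, r.y0, r.x1, r.y1) for r in self.units]
            )
        return self._polygon

    @property
    def area(self) -> float:
        return float(self.walkable_region.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xs0 = min(r.x0 for r in self.units)
        ys0 = min(r.y0 for r in self.units)
        xs1 = max(r.x1 for r in self.units)
        ys1 = max(r.y1 for r in self.units)
        return xs0, ys0, xs1, ys1

    # -- point classification ------------------------------------------------

    def unit_of(self, p: Sequence[float], tol: float = 1e-9) -> int:
        """Index into ``units`` of the unit containing ``p``; -1 if outside."""
        for i, r in enumerate(self.units):
            if r.contains(p, tol=tol):
                return i
        return -1

    def unit_of_many(self, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Vectorised ``unit_of`` for an (n, 2) array; -1 where outside."""
        pts = np.asarray(pts, dtype=float)
        out = np.full(len(pts), -1, dtype=np.int64)
        for i in reversed(range(len(self.units))):
            r = self.units[i]
            inside = (
                (pts[:, 0] >= r.x0 - tol)
                & (pts[:, 0] <= r.x1 + tol)
                & (pts[:, 1] >= r.y0 - tol)
                & (pts[:, 1] <= r.y1 + tol)
            )
            out[inside] = i
        return out

    def contains(self, p: Sequence[float], tol: float = 1e-9) -> bool:
        return self.unit_of(p, tol=tol) >= 0

    def grid_engine(self, resolution: float = 0.5):
        """Cached wall-aware shortest-path engine (see ``gridpaths``)."""
        from .gridpaths import GridPathEngine

        if self._engine is None or self._engine.resolution != resolution:
            self._engine = GridPathEngine(self, resolution=resolution)
        return self._engine


# ---------------------------------------------------------------------------
# construction


def _corridor_rect(a: Rect, b: Rect, opening: Opening) -> Rect:
    """Corridor rectangle spanning the wall gap between facing walls of a, b."""
    cx, cy = opening.center
    w = opening.width
    if a.x1 <= b.x0 or b.x1 <= a.x0:  # side-by-side, vertical facing walls
        lo, hi = (a, b) if a.x1 <= b.x0 else (b, a)
        gap = hi.x0 - lo.x1
        if gap <= 0:
            raise NestConfigError(
                "chambers touch or overlap; openings need a positive wall gap"
            )
        rect = Rect(lo.x1, cy - w / 2.0, gap, w)
        if rect.y0 < max(lo.y0, hi.y0) - 1e-9 or rect.y1 > min(lo.y1, hi.y1) + 1e-9:
            raise NestConfigError("opening does not lie on the shared wall span")
        return rect
    if a.y1 <= b.y0 or b.y1 <= a.y0:  # stacked, horizontal facing walls
        lo, hi = (a, b) if a.y1 <= b.y0 else (b, a)
        gap = hi.y0 - lo.y1
        if gap <= 0:
            raise NestConfigError(
                "chambers touch or overlap; openings need a positive wall gap"
            )
        rect = Rect(cx - w / 2.0, lo.y1, w, gap)
        if rect.x0 < max(lo.x0, hi.x0) - 1e-9 or rect.x1 > min(lo.x1, hi.x1) + 1e-9:
            raise NestConfigError("opening does not lie on the shared wall span")
        return rect
    raise NestConfigError("chambers joined by an opening must face each other")


def build_nest(config: Mapping) -> NestGeometry:
    """Build a :class:`NestGeometry` from a configuration mapping.

    The mapping has two keys: ``chambers``, a list of ``(x0, y0, width,
    height)`` rectangles in mm, and ``openings``, a list of mappings with keys
    ``a`` (chamber index), ``b`` (chamber index or ``"outside"``), ``center``
    (2-point, mm) and optional ``width`` (mm, default 6).  Exactly the
    openings with ``b == "outside"`` are entrances; the first one defines
    ``entrance_point``.

    Raises
    ------
    NestConfigError
        On overlapping chambers, degenerate openings, openings that do not
        sit on a shared wall, or a disconnected layout.
    """
    chambers = [Rect(*map(float, c)) for c in config["chambers"]]
    if not chambers:
        raise NestConfigError("at least one chamber is required")
    for r in chambers:
        if r.width <= 0 or r.height <= 0:
            raise NestConfigError("chamber dimensions must be positive")
    for i, a in enumerate(chambers):
        for b in chambers[i + 1 :]:
            if a.overlaps_interior(b):
                raise NestConfigError("chambers overlap")

    openings: list[Opening] = []
    for spec in config.get("openings", []):
        op = Opening(
            chamber_a=int(spec["a"]),
            chamber_b=(spec["b"] if spec["b"] == "outside" else int(spec["b"])),
            center=(float(spec["center"][0]), float(spec["center"][1])),
            width=float(spec.get("width", OPENING_WIDTH)),
        )
        if op.width <= 0:
            raise NestConfigError("opening width must be positive")
        if not (0 <= op.chamber_a < len(chambers)):
            raise NestConfigError(f"opening references unknown chamber {op.chamber_a}")
        if not op.is_entrance and not (0 <= op.chamber_b < len(chambers)):
            raise NestConfigError(f"opening references unknown chamber {op.chamber_b}")
        openings.append(op)

    entrances = [op for op in openings if op.is_entrance]
    if not entrances:
        raise NestConfigError("an entrance opening (b: outside) is required")
    ent = entrances[0]
    ent_chamber = chambers[ent.chamber_a]
    ep = np.array(ent.center, dtype=float)
    on_boundary = ent_chamber.contains(ep, tol=1e-6) and (
        np.isclose(ep[0], ent_chamber.x0)
        or np.isclose(ep[0], ent_chamber.x1)
        or np.isclose(ep[1], ent_chamber.y0)
        or np.isclose(ep[1], ent_chamber.y1)
    )
    if not on_boundary:
        raise NestConfigError("entrance center must lie on a chamber wall")

    corridors = []
    adjacency: list[tuple[int, int]] = []
    for op in openings:
        if op.is_entrance:
            continue
        corridors.append(_corridor_rect(chambers[op.chamber_a], chambers[op.chamber_b], op))
        adjacency.append((op.chamber_a, op.chamber_b))

    # connectivity over chambers via openings (union-find)
    parent = list(range(len(chambers)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in adjacency:
        parent[find(a)] = find(b)
    if len({find(i) for i in range(len(chambers))}) > 1:
        raise NestConfigError("nest layout is disconnected")

    return NestGeometry(
        chambers=chambers, corridors=corridors, openings=openings, entrance_point=ep
    )


def load_nest_config(path) -> NestGeometry:
    """Read a YAML nest-config file (see :func:`build_nest`) and build it."""
    with open(path) as fh:
        return build_nest(yaml.safe_load(fh))


def one_chamber_nest(
    width: float = CHAMBER_WIDTH,
    height: float = CHAMBER_HEIGHT,
    entrance_width: float = OPENING_WIDTH,
) -> NestGeometry:
    """Single-chamber (high-density) nest with the entrance at the origin."""
    return build_nest(
        {
            "chambers": [(0.0, -height / 2.0, width, height)],
            "openings": [
                {"a": 0, "b": "outside", "center": (0.0, 0.0), "width": entrance_width}
            ],
        }
    )


def four_chamber_nest(
    width: float = CHAMBER_WIDTH,
    height: float = CHAMBER_HEIGHT,
    opening_width: float = OPENING_WIDTH,
    wall_gap: float = WALL_GAP,
    n_chambers: int = 4,
) -> NestGeometry:
    """Chained multi-chamber (low-density) nest.

    Chambers run in series along +x from the entrance chamber to the queen
    chamber, each pair joined by a centred opening of ``opening_width``
    spanning a ``wall_gap`` wall.
    """
    pitch = width + wall_gap
    chambers = [(i * pitch, -height / 2.0, width, height) for i in range(n_chambers)]
    openings: list[dict] = [
        {"a": 0, "b": "outside", "center": (0.0, 0.0), "width": opening_width}
    ]
    for i in range(n_chambers - 1):
        cx = i * pitch + width + wall_gap / 2.0
        openings.append(
            {"a": i, "b": i + 1, "center": (cx, 0.0), "width": opening_width}
        )
    return build_nest({"chambers": chambers, "openings": openings})


# ---------------------------------------------------------------------------
# affine alignment


@dataclass(frozen=True)
class AffineTransform:
    """Affine map pixel -> mm: ``y = A @ x + b``."""

    matrix: np.ndarray  # (2, 2)
    offset: np.ndarray  # (2,)
    residuals: np.ndarray | None = None  # per-corner residual norms (mm)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix.T + self.offset


def fit_affine(src_corners: np.ndarray, dst_corners: np.ndarray) -> AffineTransform:
    """Least-squares affine map taking pixel corners to nest-frame corners.

    Requires at least three non-collinear correspondences; raises
    ``numpy.linalg.LinAlgError`` when the corners are collinear (rank
    deficient design).
    """
    src = np.asarray(src_corners, dtype=float)
    dst = np.asarray(dst_corners, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    if len(src) < 3:
        raise ValueError("at least 3 correspondences are required")
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise np.linalg.LinAlgError("corner correspondences are collinear")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef[:2].T
    offset = coef[2]
    resid = np.linalg.norm(design @ coef - dst, axis=1)
    return AffineTransform(matrix=matrix, offset=offset, residuals=resid)


# ---------------------------------------------------------------------------
# projection and distances


def project_into_nest(p: Sequence[float], nest: NestGeometry) -> np.ndarray:
    """Nearest point of the walkable region to ``p`` (identity if inside)."""
    p = np.asarray(p, dtype=float)
    if nest.contains(p):
        return p.copy()
    cands = np.array([r.clamp(p) for r in nest.units])
    d2 = ((cands - p) ** 2).sum(axis=1)
    return cands[int(np.argmin(d2))]


def project_into_nest_many(pts: np.ndarray, nest: NestGeometry) -> np.ndarray:
    """Vectorised :func:`project_into_nest` for an (n, 2) array."""
    pts = np.asarray(pts, dtype=float)
    best = None
    best_d2 = None
    for r in nest.units:
        c = np.column_stack(
            [np.clip(pts[:, 0], r.x0, r.x1), np.clip(pts[:, 1], r.y0, r.y1)]
        )
        d2 = ((c - pts) ** 2).sum(axis=1)
        if best is None:
            best, best_d2 = c, d2
        else:
            better = d2 < best_d2
            best[better] = c[better]
            best_d2 = np.minimum(best_d2, d2)
    return best


def geodesic_distance(
    p: Sequence[float], q: Sequence[float], nest: NestGeometry, resolution: float = 0.5
) -> float:
    """Wall-aware shortest-path length between two in-nest points (mm).

    Raises :class:`OutsideRegionError` if either point is outside the
    walkable region; callers should :func:`project_into_nest` first.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not nest.contains(p) or not nest.contains(q):
        raise OutsideRegionError("both points must lie inside the walkable region")
    return float(
        nest.grid_engine(resolution).pair_distances(p[None, :], q[None, :])[0]
    )


def distance_to_entrance(
    p: Sequence[float], nest: NestGeometry, resolution: float = 0.5
) -> float:
    """Shortest rectilinear in-region path length from ``p`` to the entrance."""
    p = np.asarray(p, dtype=float)
    if not nest.contains(p):
        raise OutsideRegionError("point must lie inside the walkable region")
    return float(nest.grid_engine(resolution).entrance_distances(p[None, :])[0])
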