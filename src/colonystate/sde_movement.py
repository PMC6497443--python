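"""Continuous-time correlated random walk with potential and motility surfaces.

Movement is modelled per axis by the velocity SDE

    dv_t = -beta (v_t - mu(x_t)) dt + c(x_t) dW_t

where beta (1/s) sets directional persistence, mu(x) = -c(x) grad P(x) is the
drift down the potential surface P(x), and c(x) is the motility surface
scaling the movement noise.  A second-order discretisation at step h gives a
position model depending on the previous two positions:

    x_t = x_{t-1} (2 - beta h) + x_{t-2} (beta h - 1)
          + beta h^2 mu(x_{t-2}) + N(0, h^3 c^2(x_{t-2}))

Estimation follows a three-step scheme: (1) fit beta and the drift field
(hence P) assuming uniform motility, (2) estimate c(x) from the squared
step-1 residuals, (3) re-fit beta and P weighted by the estimated motility.
Both surfaces use piecewise-constant cells on a grid over the nest with a
squared-second-difference (discrete Laplacian) roughness penalty; the
penalty weight is chosen by generalized cross-validation.  P is identified
up to an additive constant and anchored to mean zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import lsqr

from .errors import FitError
from .geometry import NestGeometry, project_into_nest_many
from .preprocess import AntTrack, stack_positions

__all__ = [
    "SurfaceGrid",
    "VelocityRecords",
    "SDEFit",
    "build_regression",
    "fit_sde",
    "simulate_sde",
    "simulate_positions",
    "regression_loglik",
    "surface_report",
]


class SurfaceGrid:
    """Piecewise-constant 2-D basis on a square grid over the walkable region."""

    def __init__(self, nest: NestGeometry, cell_mm: float = 5.0):
        self.nest = nest
        self.cell_mm = float(cell_mm)
        x0, y0, x1, y1 = nest.bounds
        self._origin = np.array([x0, y0])
        self._ncx = int(np.ceil((x1 - x0) / cell_mm - 1e-9))
        self._ncy = int(np.ceil((y1 - y0) / cell_mm - 1e-9))
        cx = x0 + (np.arange(self._ncx) + 0.5) * cell_mm
        cy = y0 + (np.arange(self._ncy) + 0.5) * cell_mm
        xx, yy = np.meshgrid(cx, cy, indexing="ij")
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        # a cell belongs to the surface if its centre lies in the region or
        # the cell rectangle intersects it (coarse cells straddle walls)
        inside = nest.unit_of_many(centers) >= 0
        if not inside.any():
            raise ValueError("grid too coarse for this nest")
        half = cell_mm / 2.0
        for k in np.flatnonzero(~inside):
            p = centers[k]
            for r in nest.units:
                q = r.clamp(p)
                if abs(q[0] - p[0]) < half and abs(q[1] - p[1]) < half:
                    inside[k] = True
                    break
        self.mask = inside.reshape(self._ncx, self._ncy)
        self.cell_id = np.where(
            self.mask, np.cumsum(inside).reshape(self.mask.shape) - 1, -1
        )
        self.n_cells = int(inside.sum())
        self.centers = centers[inside]

    def cell_of(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        h = self.cell_mm
        ix = np.clip(((pts[:, 0] - self._origin[0]) / h).astype(int), 0, self._ncx - 1)
        iy = np.clip(((pts[:, 1] - self._origin[1]) / h).astype(int), 0, self._ncy - 1)
        cells = self.cell_id[ix, iy]
        for k in np.flatnonzero(cells < 0):
            d2 = ((self.centers - pts[k]) ** 2).sum(axis=1)
            cells[k] = int(np.argmin(d2))
        return cells

    def second_difference(self) -> sparse.csr_matrix:
        """Rows of discrete second differences along x and y (penalty basis)."""
        ids = self.cell_id
        rows = []
        for axis in (0, 1):
            a = np.moveaxis(ids, axis, 0)
            left, mid, right = a[:-2], a[1:-1], a[2:]
            ok = (left >= 0) & (mid >= 0) & (right >= 0)
            li, mi, ri = left[ok], mid[ok], right[ok]
            m = len(li)
            if m == 0:
                continue
            r = np.repeat(np.arange(m), 3)
            c = np.column_stack([li, mi, ri]).ravel()
            v = np.tile([1.0, -2.0, 1.0], m)
            rows.append(sparse.coo_matrix((v, (r, c)), shape=(m, self.n_cells)))
        if not rows:  # tiny grids: fall back to first differences
            return self.first_difference()
        return sparse.vstack(rows).tocsr()

    def first_difference(self) -> sparse.csr_matrix:
        ids = self.cell_id
        rows = []
        for axis in (0, 1):
            a = np.moveaxis(ids, axis, 0)
            lo, hi = a[:-1], a[1:]
            ok = (lo >= 0) & (hi >= 0)
            li, hi_ = lo[ok], hi[ok]
            m = len(li)
            r = np.repeat(np.arange(m), 2)
            c = np.column_stack([li, hi_]).ravel()
            v = np.tile([-1.0, 1.0], m)
            rows.append(sparse.coo_matrix((v, (r, c)), shape=(m, self.n_cells)))
        return sparse.vstack(rows).tocsr()

    def penalty(self) -> sparse.csr_matrix:
        d2 = self.second_difference()
        pen = (d2.T @ d2).tocsr()
        # ridge floor keeps cells outside every second-difference stencil
        # (corridor cells, lone corners) from being unconstrained
        return pen + 1e-8 * sparse.eye(self.n_cells, format="csr")

    def gradient(self, values: np.ndarray) -> np.ndarray:
        """Central-difference gradient of a cell field, (n_cells, 2) in 1/mm units."""
        ids = self.cell_id
        full = np.full(ids.shape, np.nan)
        full[self.mask] = values
        out = np.zeros((self.n_cells, 2))
        h = self.cell_mm
        for axis in (0, 1):
            fwd = np.full(ids.shape, np.nan)
            bwd = np.full(ids.shape, np.nan)
            sl_f = [slice(None)] * 2
            sl_f[axis] = slice(None, -1)
            sl_t = [slice(None)] * 2
            sl_t[axis] = slice(1, None)
            fwd[tuple(sl_f)] = full[tuple(sl_t)]
            bwd[tuple(sl_t)] = full[tuple(sl_f)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                grad = (fwd - bwd) / (2 * h)
                one_sided_f = (fwd - full) / h
                one_sided_b = (full - bwd) / h
            g = np.where(np.isfinite(grad), grad, np.where(
                np.isfinite(one_sided_f), one_sided_f, one_sided_b
            ))
            g = np.where(np.isfinite(g), g, 0.0)
            out[:, axis] = g[self.mask]
        return out

    def integrate_gradient(self, grad: np.ndarray) -> np.ndarray:
        """Least-squares scalar field whose gradient matches ``grad``; mean 0."""
        ids = self.cell_id
        h = self.cell_mm
        rows_r, rows_c, rows_v, rhs = [], [], [], []
        m = 0
        for axis in (0, 1):
            a = np.moveaxis(ids, axis, 0)
            lo, hi = a[:-1], a[1:]
            ok = (lo >= 0) & (hi >= 0)
            li, hi_ = lo[ok], hi[ok]
            g_edge = 0.5 * (grad[li, axis] + grad[hi_, axis])
            k = len(li)
            rows_r.append(np.repeat(np.arange(m, m + k), 2))
            rows_c.append(np.column_stack([li, hi_]).ravel())
            rows_v.append(np.tile([-1.0 / h, 1.0 / h], k))
            rhs.append(g_edge)
            m += k
        A = sparse.coo_matrix(
            (np.concatenate(rows_v), (np.concatenate(rows_r), np.concatenate(rows_c))),
            shape=(m, self.n_cells),
        ).tocsr()
        sol = lsqr(A, np.concatenate(rhs), damp=1e-6)[0]
        return sol - sol.mean()


@dataclass
class VelocityRecords:
    """Second-difference regression records pooled over ants.

    One row per usable (ant, t) with three consecutive in-nest positions:
    ``pos`` is x_{t-2} (surface lookup point), ``vel`` = (x_{t-1}-x_{t-2})/h,
    ``target`` = x_t - 2 x_{t-1} + x_{t-2}, all (m, 2).
    """

    pos: np.ndarray
    vel: np.ndarray
    target: np.ndarray
    h: float = 1.0

    @property
    def n(self) -> int:
        return len(self.pos)


def build_regression(tracks: list[AntTrack], h: float = 1.0) -> VelocityRecords:
    """Assemble the discretised-SDE regression records from tracks.

    Records straddling outside spells are dropped; tracks shorter than three
    seconds contribute nothing (warning).
    """
    pos, vel, tgt = [], [], []
    for tr in tracks:
        if tr.n_seconds < 3:
            warnings.warn(f"ant {tr.ant_id}: track shorter than 3 s, skipped")
            continue
        m = tr.in_nest
        ok = m[:-2] & m[1:-1] & m[2:]
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        x0 = tr.xy[idx]
        x1 = tr.xy[idx + 1]
        x2 = tr.xy[idx + 2]
        pos.append(x0)
        vel.append((x1 - x0) / h)
        tgt.append(x2 - 2 * x1 + x0)
    if not pos:
        raise FitError("no usable 3-second windows in the tracks")
    return VelocityRecords(
        pos=np.concatenate(pos), vel=np.concatenate(vel), target=np.concatenate(tgt), h=h
    )


@dataclass
class SDEFit:
    """Fitted CTCRW with potential and motility surfaces on a grid."""

    beta: float
    potential: np.ndarray  # P(x) per cell, mean 0
    motility: np.ndarray  # c(x) per cell, >= 0
    grid: SurfaceGrid
    h: float
    penalty_drift: float
    penalty_motility: float
    drift_field: np.ndarray = field(repr=False, default=None)  # mu per cell (n, 2)

    def mu_of(self, pts: np.ndarray) -> np.ndarray:
        return self.drift_field[self.grid.cell_of(pts)]

    def c_of(self, pts: np.ndarray) -> np.ndarray:
        return self.motility[self.grid.cell_of(pts)]


def _penalized_drift_fit(
    records: VelocityRecords,
    grid: SurfaceGrid,
    weights: np.ndarray,
    penalty: float | None,
):
    """Solve for (beta, drift field) with a Laplacian-squared penalty.

    Model per axis: target = beta * (-h^2 vel) + d_axis[cell] + noise.
    Returns (beta, d (n_cells, 2), residuals (m, 2), chosen penalty).
    """
    h = records.h
    m = records.n
    cells = grid.cell_of(records.pos)
    nc = grid.n_cells
    # stacked system over both axes; beta shared, drift separate per axis
    reg = -(h**2) * records.vel  # (m, 2)
    w = np.repeat(weights, 2)
    rows = np.arange(2 * m)
    col_beta = np.zeros(2 * m, dtype=int)
    vals_beta = reg.ravel()  # row order: (i, axis)
    cols_d = np.where(
        np.arange(2 * m) % 2 == 0, 1 + cells.repeat(2), 1 + nc + cells.repeat(2)
    )
    X = sparse.coo_matrix(
        (
            np.concatenate([vals_beta, np.ones(2 * m)]),
            (np.concatenate([rows, rows]), np.concatenate([col_beta, cols_d])),
        ),
        shape=(2 * m, 1 + 2 * nc),
    ).tocsr()
    z = records.target.ravel()
    W = sparse.diags(w)
    XtWX = (X.T @ W @ X).toarray()
    XtWz = X.T @ (w * z)
    pen_block = grid.penalty().toarray()
    L = np.zeros_like(XtWX)
    L[1 : 1 + nc, 1 : 1 + nc] = pen_block
    L[1 + nc :, 1 + nc :] = pen_block

    def solve(lam):
        A = XtWX + lam * L
        try:
            theta = np.linalg.solve(A, XtWz)
        except np.linalg.LinAlgError as exc:
            raise FitError(
                "singular penalized system; try a coarser surface grid"
            ) from exc
        return theta, A

    if penalty is None:  # generalized cross-validation over a log-grid
        best = None
        scale = np.trace(XtWX) / max(np.trace(L), 1e-12)
        for lam in scale * np.logspace(-6, 2, 9):
            theta, A = solve(lam)
            resid = z - X @ theta
            rss = float((w * resid**2).sum())
            edf = float(np.trace(np.linalg.solve(A, XtWX)))
            gcv = 2 * m * rss / max(2 * m - edf, 1.0) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam, theta)
        _, lam, theta = best
    else:
        lam = float(penalty)
        theta, _ = solve(lam)
    beta = float(theta[0])
    d = np.column_stack([theta[1 : 1 + nc], theta[1 + nc :]])
    resid = (z - X @ theta).reshape(m, 2)
    return beta, d, resid, lam


def _penalized_cell_mean(
    values: np.ndarray, cells: np.ndarray, grid: SurfaceGrid, penalty: float | None
):
    """Penalized per-cell mean of ``values`` (used for the motility surface)."""
    nc = grid.n_cells
    counts = np.bincount(cells, minlength=nc).astype(float)
    sums = np.bincount(cells, weights=values, minlength=nc)
    NtN = sparse.diags(counts).toarray()
    pen = grid.penalty().toarray()

    def solve(lam):
        return np.linalg.solve(NtN + lam * pen, sums)

    if penalty is None:
        best = None
        scale = counts.sum() / nc
        for lam in scale * np.logspace(-4, 4, 9):
            s = solve(lam)
            rss = float(((values - s[cells]) ** 2).sum())
            edf = float(np.trace(np.linalg.solve(NtN + lam * pen, NtN)))
            n = len(values)
            gcv = n * rss / max(n - edf, 1.0) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam, s)
        _, lam, s = best
    else:
        lam = float(penalty)
        s = solve(lam)
    return s, lam


def fit_sde(
    records: VelocityRecords,
    nest: NestGeometry,
    grid_mm: float = 5.0,
    penalty_drift: float | None = None,
    penalty_motility: float | None = None,
) -> SDEFit:
    """Three-step estimate of beta, P(x) and c(x) from regression records.

    1. beta and the drift field are fitted by penalized least squares
       assuming uniform motility;
    2. c(x) is estimated from the squared step-1 residuals
       (E[resid^2] = h^3 c^2(x));
    3. beta and the drift field are re-fitted weighting by 1 / (h^3 c^2).

    The potential is recovered by least-squares integration of
    grad P = -mu / c and anchored to mean zero.  Penalty weights default to
    generalized cross-validation.
    """
    grid = SurfaceGrid(nest, cell_mm=grid_mm)
    if records.n < 10 * grid.n_cells:
        warnings.warn(
            f"only {records.n} records for {grid.n_cells} basis cells; "
            "surfaces may be under-determined"
        )
    h = records.h
    cells = grid.cell_of(records.pos)
    w0 = np.ones(records.n)
    beta, d, resid, lam_d = _penalized_drift_fit(records, grid, w0, penalty_drift)
    # step 2: motility from residual second moments (both axes pooled)
    sq = 0.5 * (resid**2).sum(axis=1)  # per-record mean over axes
    c2_cells, lam_c = _penalized_cell_mean(sq, cells, grid, penalty_motility)
    c2_cells = np.maximum(c2_cells, 1e-12) / h**3
    c = np.sqrt(c2_cells)
    # step 3: weighted re-fit
    w = 1.0 / np.maximum(h**3 * c2_cells[cells], 1e-10)
    beta, d, resid, lam_d = _penalized_drift_fit(records, grid, w, lam_d)
    if beta <= 0:
        warnings.warn(f"fitted beta = {beta:.3g} is not positive; fit is unstable")
    # mu = d / (beta h^2);  grad P = -mu / c
    denom = beta * h**2 if beta != 0 else np.inf
    mu = d / denom
    grad_p = -mu / np.maximum(c[:, None], 1e-9)
    potential = grid.integrate_gradient(grad_p)
    return SDEFit(
        beta=beta,
        potential=potential,
        motility=c,
        grid=grid,
        h=h,
        penalty_drift=lam_d,
        penalty_motility=lam_c,
        drift_field=mu,
    )


def regression_loglik(records: VelocityRecords, beta: float, mu, c) -> float:
    """Gaussian log-likelihood of the records under (beta, mu(x), c(x)).

    ``mu`` maps (m, 2) positions to (m, 2) drifts, ``c`` maps (m, 2)
    positions to (m,) motilities (callables, or constants broadcast).
    """
    h = records.h
    mu_v = mu(records.pos) if callable(mu) else np.broadcast_to(mu, records.pos.shape)
    c_v = c(records.pos) if callable(c) else np.full(records.n, float(c))
    mean = -beta * h**2 * records.vel + beta * h**2 * mu_v
    var = np.maximum(h**3 * c_v**2, 1e-300)
    resid2 = ((records.target - mean) ** 2).sum(axis=1)
    return float(-0.5 * (2 * np.log(2 * np.pi * var) + resid2 / var).sum())


def simulate_positions(
    nest: NestGeometry,
    n_ants: int,
    duration: int,
    beta: float,
    mu,
    c,
    x0: np.ndarray,
    v0: np.ndarray | None = None,
    h: float = 1.0,
    seed: int | None = 0,
) -> np.ndarray:
    """Forward-simulate the discretised SDE for ``n_ants`` ants.

    ``mu``: callable (n, 2) -> (n, 2) drift, or None for zero drift.
    ``c``: callable (n, 2) -> (n,) motility, or a scalar.
    Every step is projected back into the walkable region.  Returns
    positions of shape (n_ants, duration + 1, 2); bit-reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    x0 = np.broadcast_to(np.asarray(x0, dtype=float), (n_ants, 2)).copy()
    v0 = (
        np.zeros((n_ants, 2))
        if v0 is None
        else np.broadcast_to(np.asarray(v0, dtype=float), (n_ants, 2)).copy()
    )
    n_steps = int(round(duration / h))
    out = np.empty((n_ants, n_steps + 1, 2))
    out[:, 0] = project_into_nest_many(x0, nest)
    prev2 = out[:, 0] - v0 * h  # virtual x_{-1} encoding the initial velocity
    prev1 = out[:, 0]
    for t in range(1, n_steps + 1):
        mu_v = np.zeros((n_ants, 2)) if mu is None else np.asarray(mu(prev2), dtype=float)
        c_v = (
            np.full(n_ants, float(c))
            if np.isscalar(c)
            else np.asarray(c(prev2), dtype=float)
        )
        noise = rng.standard_normal((n_ants, 2)) * (np.sqrt(h**3) * c_v)[:, None]
        x = (
            prev1 * (2 - beta * h)
            + prev2 * (beta * h - 1)
            + beta * h**2 * mu_v
            + noise
        )
        x = project_into_nest_many(x, nest)
        out[:, t] = x
        prev2, prev1 = prev1, x
    return out


def simulate_sde(
    params: SDEFit,
    x0,
    v0,
    duration: int,
    nest: NestGeometry | None = None,
    seed: int | None = 0,
) -> AntTrack:
    """Simulate one track from a fitted model (see :func:`simulate_positions`)."""
    nest = nest if nest is not None else params.grid.nest
    pos = simulate_positions(
        nest,
        1,
        duration,
        params.beta,
        params.mu_of,
        params.c_of,
        np.asarray(x0, dtype=float)[None, :],
        None if v0 is None else np.asarray(v0, dtype=float)[None, :],
        h=params.h,
        seed=seed,
    )[0]
    from .preprocess import IN_NEST

    return AntTrack(
        ant_id="sim", xy=pos, presence=np.full(len(pos), IN_NEST, dtype=np.int8)
    )


def surface_report(fit: SDEFit):
    """Grid tables of the fitted surfaces plus per-chamber mean motility.

    Returns (DataFrame with cell centres, potential and motility; dict of
    chamber index -> mean motility).  Rows cover exactly the grid cells
    intersecting the walkable region.
    """
    import pandas as pd

    df = pd.DataFrame(
        {
            "x_mm": fit.grid.centers[:, 0],
            "y_mm": fit.grid.centers[:, 1],
            "potential": fit.potential,
            "motility": fit.motility,
        }
    )
    nest = fit.grid.nest
    chamber_means: dict[int, float] = {}
    for i, r in enumerate(nest.chambers):
        inside = (
            (fit.grid.centers[:, 0] >= r.x0)
            & (fit.grid.centers[:, 0] <= r.x1)
            & (fit.grid.centers[:, 1] >= r.y0)
            & (fit.grid.centers[:, 1] <= r.y1)
        )
        if inside.any():
            chamber_means[i] = float(fit.motility[inside].mean())
    return df, chamber_means
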