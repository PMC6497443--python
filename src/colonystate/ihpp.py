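"""Pair-based inhomogeneous Poisson process regression of trophallaxis.

Each ant pair's initiation times are an IHPP observed at 1 s resolution.
The rate is zero whenever the pair's wall-aware distance exceeds 20 mm;
on at-risk seconds log lambda_t is linear in colony, treatment and four
annular local-density covariates: the numbers of additional ants (beyond
the focal pair) whose distance from the pair centroid falls in
(0, 5], (5, 10], (10, 15] and (15, 20] mm (n5, n10, n15, n20).  With
lambda_t constant per second the likelihood is
prod_t lambda_t^{y_t} exp(-lambda_t) over at-risk seconds, i.e. Poisson
regression of the initiation indicator with a log link.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError
from .geometry import NestGeometry, project_into_nest_many
from .preprocess import AntTrack, stack_positions

__all__ = [
    "LAGS",
    "AT_RISK_MM",
    "pair_second_table",
    "pair_covariates",
    "IHPPFit",
    "fit_ihpp",
    "rate_effects",
]

LAGS = (5.0, 10.0, 15.0, 20.0)
AT_RISK_MM = 20.0
_CHUNK_PAIRS = 128
_CHUNK_ROWS = 100_000


def _lag_names(lags) -> list[str]:
    return [f"n{int(l)}" for l in lags]


class _DistanceHelper:
    """Vectorised wall-aware distances over an (n_ants, T) position panel."""

    def __init__(self, tracks: list[AntTrack], nest: NestGeometry, euclidean: bool):
        self.xy, self.in_nest = stack_positions(tracks)
        self.n, self.T = self.in_nest.shape
        self.nest = nest
        self.wall_aware = (not euclidean) and len(nest.corridors) > 0
        if self.wall_aware:
            self.engine = nest.grid_engine()
            self.units = np.full((self.n, self.T), -1, dtype=np.int32)
            self.cells = np.zeros((self.n, self.T), dtype=np.int64)
            for i in range(self.n):
                m = self.in_nest[i]
                if m.any():
                    self.units[i, m] = nest.unit_of_many(self.xy[i, m])
                    self.cells[i, m] = self.engine.cells_of(self.xy[i, m])
            self.maps = self.engine._portals()

    def pair_distance(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """(n_pairs, T) distances; inf where either partner is outside."""
        d = np.linalg.norm(self.xy[i] - self.xy[j], axis=-1)
        valid = self.in_nest[i] & self.in_nest[j]
        d[~valid] = np.inf
        if self.wall_aware:
            cross = valid & (self.units[i] != self.units[j]) & (d <= AT_RISK_MM + 1e-9)
            if cross.any():
                ci = self.cells[i][cross]
                cj = self.cells[j][cross]
                d[cross] = (self.maps[:, ci] + self.maps[:, cj]).min(axis=0)
        return d

    def annulus_counts(
        self,
        pair_i: np.ndarray,
        pair_j: np.ndarray,
        times: np.ndarray,
        centroids: np.ndarray,
        lags,
    ) -> np.ndarray:
        """(m, len(lags)) incremental counts of other ants around centroids."""
        lags = np.asarray(lags, dtype=float)
        m = len(times)
        counts = np.zeros((m, len(lags)), dtype=np.int16)
        if self.wall_aware:
            cen_units = self.nest.unit_of_many(centroids)
            cen_cells = self.engine.cells_of(centroids)
        for lo in range(0, m, _CHUNK_ROWS):
            sl = slice(lo, min(lo + _CHUNK_ROWS, m))
            t = times[sl]
            cen = centroids[sl]
            ant_xy = self.xy[:, t, :]  # (n, k, 2)
            d = np.linalg.norm(ant_xy - cen[None, :, :], axis=-1)  # (n, k)
            d[~self.in_nest[:, t]] = np.inf
            k = d.shape[1]
            cols = np.arange(k)
            d[pair_i[sl], cols] = np.inf
            d[pair_j[sl], cols] = np.inf
            if self.wall_aware:
                cross = (self.units[:, t] != cen_units[sl][None, :]) & (
                    d <= lags[-1] + 1e-9
                )
                if cross.any():
                    ca = self.cells[:, t][cross]
                    cc = np.broadcast_to(cen_cells[sl][None, :], cross.shape)[cross]
                    d[cross] = (self.maps[:, ca] + self.maps[:, cc]).min(axis=0)
            prev = np.zeros(k, dtype=np.int64)
            for li, lag in enumerate(lags):
                within = (d <= lag + 1e-9).sum(axis=0)
                counts[sl, li] = (within - prev).astype(np.int16)
                prev = within
        return counts


def _event_lookup(events) -> dict[tuple[str, str], list]:
    table: dict[tuple[str, str], list] = {}
    if events:
        for e in events:
            table.setdefault(e.dyad, []).append(e)
    return table


def pair_second_table(
    tracks: list[AntTrack],
    nest: NestGeometry,
    events=None,
    pairs: list[tuple[int, int]] | None = None,
    lags=LAGS,
    at_risk_mm: float = AT_RISK_MM,
    colony: str = "",
    treatment: str = "",
    euclidean: bool = False,
    censor_ongoing: bool = False,
    censor_busy: bool = False,
    at_risk_only: bool = True,
) -> pd.DataFrame:
    """Pair-second design table for IHPP fitting or simulation.

    One row per (pair, second).  With ``at_risk_only`` (the default) only
    seconds where the pair's wall-aware distance is at most ``at_risk_mm``
    are returned — other seconds have rate zero and contribute nothing to
    the likelihood.  Columns: ``pair_i, pair_j, t, at_risk, n5..n20,
    colony, treatment`` plus ``y`` when ``events`` is given.

    The pair centroid is the midpoint of the two positions, projected into
    the nest if it falls inside a wall.  Annulus counts exclude the focal
    pair and code each additional ant into exactly one distance band.
    A second with an observed initiation is always kept at risk.  With
    ``censor_ongoing`` the seconds during a pair's own ongoing event are
    dropped instead of kept as at-risk zeros; with ``censor_busy`` a pair
    second is dropped whenever either partner is engaged in *any* ongoing
    event (the correct risk set when an ant can share food with only one
    partner at a time), except at observed initiation seconds.
    """
    helper = _DistanceHelper(tracks, nest, euclidean)
    n, T = helper.n, helper.T
    ids = [tr.ant_id for tr in tracks]
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        for i, j in pairs:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"pair ({i}, {j}) not in the roster of {n} tracks")
    ev_table = _event_lookup(events)
    lag_cols = _lag_names(lags)
    busy = None
    if censor_busy and events:
        ant_index = {a: k for k, a in enumerate(ids)}
        busy = np.zeros((n, T), dtype=bool)
        for e in events:
            for a in e.dyad:
                if a in ant_index:
                    busy[ant_index[a], e.start + 1 : e.end + 1] = True

    out = []
    pairs_arr = np.asarray(pairs, dtype=int)
    for lo in range(0, len(pairs_arr), _CHUNK_PAIRS):
        chunk = pairs_arr[lo : lo + _CHUNK_PAIRS]
        pi, pj = chunk[:, 0], chunk[:, 1]
        d = helper.pair_distance(pi, pj)
        at_risk = d <= at_risk_mm + 1e-9

        y = None
        ongoing = None
        if events is not None:
            y = np.zeros_like(at_risk, dtype=np.int8)
            ongoing = np.zeros_like(at_risk, dtype=bool)
            for row, (i, j) in enumerate(chunk):
                for e in ev_table.get(tuple(sorted((ids[i], ids[j]))), []):
                    y[row, e.start] = 1
                    ongoing[row, e.start + 1 : e.end + 1] = True
            at_risk = at_risk | (y == 1)

        keep = at_risk if at_risk_only else (np.isfinite(d) | at_risk)
        if censor_ongoing and ongoing is not None:
            keep = keep & ~ongoing
        if busy is not None:
            keep = keep & (~(busy[pi] | busy[pj]) | (y == 1))
        rows, ts = np.nonzero(keep)
        gi, gj = pi[rows], pj[rows]
        cen = 0.5 * (helper.xy[gi, ts] + helper.xy[gj, ts])
        cen = project_into_nest_many(cen, nest)
        counts = helper.annulus_counts(gi, gj, ts, cen, lags)
        df = pd.DataFrame(
            {
                "pair_i": pd.Categorical([ids[i] for i in gi], categories=ids),
                "pair_j": pd.Categorical([ids[j] for j in gj], categories=ids),
                "t": ts.astype(np.int32),
                "at_risk": at_risk[rows, ts],
            }
        )
        for c, col in enumerate(lag_cols):
            df[col] = counts[:, c]
        if y is not None:
            df["y"] = y[rows, ts]
        out.append(df)
    table = pd.concat(out, ignore_index=True)
    table["colony"] = colony
    table["treatment"] = treatment
    return table


def pair_covariates(
    tracks: list[AntTrack],
    events,
    nest: NestGeometry,
    pair: tuple[int, int],
    lags=LAGS,
    **kwargs,
) -> pd.DataFrame:
    """Per-second records for a single pair (all seconds, with at-risk flag)."""
    return pair_second_table(
        tracks,
        nest,
        events=events,
        pairs=[tuple(pair)],
        lags=lags,
        at_risk_only=False,
        **kwargs,
    )


@dataclass
class IHPPFit:
    """Fitted IHPP regression: coefficient table and log-likelihood."""

    table: pd.DataFrame  # estimate, se, z, p indexed by term
    loglik: float
    lags: tuple
    colonies: list[str]
    dropped_colony_treatment: bool = False
    model: object = field(repr=False, default=None)

    @property
    def fitted_rate_sum(self) -> float:
        return float(self.model.mu.sum())


def _design(records: pd.DataFrame, lags, colony_treatment: bool) -> pd.DataFrame:
    lag_cols = _lag_names(lags)
    colonies = sorted(map(str, records["colony"].unique()))
    treatments = sorted(map(str, records["treatment"].unique()))
    X = pd.DataFrame(index=records.index)
    col = records["colony"].astype(str)
    if len(colonies) > 1:
        for c in colonies:
            X[f"colony[{c}]"] = (col == c).astype(float)
    else:
        X["Intercept"] = 1.0
    if len(treatments) > 1:
        high = "high" if "high" in treatments else treatments[-1]
        X[f"treatment[{high}]"] = (records["treatment"].astype(str) == high).astype(
            float
        )
        if colony_treatment and len(colonies) > 1:
            for c in colonies[1:]:
                X[f"col{c}:treatment[{high}]"] = (
                    X[f"colony[{c}]"] * X[f"treatment[{high}]"]
                )
    for lc in lag_cols:
        X[lc] = records[lc].astype(float)
    if len(colonies) > 1:
        for c in colonies[1:]:
            for lc in lag_cols:
                X[f"col{c}:{lc}"] = X[f"colony[{c}]"] * records[lc].astype(float)
    return X


def fit_ihpp(
    records: pd.DataFrame,
    lags=LAGS,
    drop_ns_colony_treatment: bool = True,
    alpha: float = 0.05,
) -> IHPPFit:
    """Maximise the discretised IHPP likelihood over at-risk pair-seconds.

    ``records`` is the output of :func:`pair_second_table` with a ``y``
    column.  The linear predictor contains per-colony intercepts, a
    treatment effect, the annular counts, and colony x count interactions
    (colony x treatment interactions are fitted first and dropped from the
    report when none is significant, mirroring the convention of reporting
    only significant interaction sets).
    """
    import statsmodels.api as sm
    from scipy import stats as sps

    recs = records[records["at_risk"]] if "at_risk" in records.columns else records
    y = recs["y"].to_numpy()
    if y.sum() == 0:
        raise FitError("no initiations among the at-risk seconds")

    def _fit(with_ct: bool):
        X = _design(recs, lags, colony_treatment=with_ct)
        try:
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200)
        except Exception as exc:  # separation / non-convergence
            raise FitError(f"IHPP fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise FitError("IHPP fit diverged (possible complete separation)")
        return res

    colonies = sorted(map(str, recs["colony"].unique()))
    treatments = sorted(map(str, recs["treatment"].unique()))
    dropped = False
    res = _fit(with_ct=True)
    if drop_ns_colony_treatment and len(colonies) > 1 and len(treatments) > 1:
        ct_terms = [n for n in res.params.index if ":treatment[" in n]
        if ct_terms and all(res.pvalues[t] > alpha for t in ct_terms):
            res = _fit(with_ct=False)
            dropped = True

    z = res.params / res.bse
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "z": z,
            "p": 2 * sps.norm.sf(np.abs(z)),
        }
    )
    return IHPPFit(
        table=table,
        loglik=float(res.llf),
        lags=tuple(lags),
        colonies=colonies,
        dropped_colony_treatment=dropped,
        model=res,
    )


def rate_effects(fit: IHPPFit) -> pd.DataFrame:
    """Percent change in trophallaxis rate per additional ant at each lag.

    For colony c and lag l the effect is
    100 x (exp(coef_l + coef_{c:l}) - 1), with the interaction term zero for
    the reference (first) colony.
    """
    rows = []
    est = fit.table["estimate"]
    for c in fit.colonies or [""]:
        for lc in _lag_names(fit.lags):
            coef = float(est.get(lc, 0.0))
            inter = f"col{c}:{lc}"
            if inter in est.index:
                coef += float(est[inter])
            rows.append(
                {
                    "colony": c,
                    "lag_mm": float(lc[1:]),
                    "coefficient": coef,
                    "percent_change": 100.0 * (np.exp(coef) - 1.0),
                }
            )
    return pd.DataFrame(rows)
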