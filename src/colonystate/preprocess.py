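"""Raw annotation tables -> complete, aligned per-second location tracks.

A recording is 4 h at 1 Hz: integer seconds t = 0 ... 14,400 inclusive, i.e.
14,401 observations per ant.  Ants may be outside the nest (foraging); those
seconds carry no position.  Seconds where an ant was inside but not visible
(e.g. while crossing between chambers) are imputed by linear interpolation
between the flanking observations, with any interpolated point that falls
outside the nest projected back in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError
from .geometry import NestGeometry, project_into_nest_many

#: Default recording duration (s); tracks span t = 0 ... DURATION inclusive.
DURATION = 14_400

# presence codes
IN_NEST = 0
OUTSIDE = 1
IMPUTED = 2
MISSING = 3  # observed-nowhere second, not yet imputed

PRESENCE_LABELS = {IN_NEST: "in_nest", OUTSIDE: "outside", IMPUTED: "imputed"}
PRESENCE_CODES = {v: k for k, v in PRESENCE_LABELS.items()}

#: Nominal video lengths (s) by camera model.
CAMERA_LENGTHS = {"hero3": 1055.0, "hero3_silver": 1564.5}


@dataclass
class AntTrack:
    """Per-second positions of one ant over a recording.

    ``xy`` has shape (T+1, 2) with NaN rows wherever the ant has no position
    (outside the nest, or not yet imputed); ``presence`` holds the per-second
    codes IN_NEST / OUTSIDE / IMPUTED / MISSING.
    """

    ant_id: str
    xy: np.ndarray
    presence: np.ndarray

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.xy.shape != (len(self.presence), 2):
            raise ValueError("xy must be (T+1, 2) matching presence length")

    @property
    def n_seconds(self) -> int:
        return len(self.presence)

    @property
    def in_nest(self) -> np.ndarray:
        """Boolean mask of seconds with a usable in-nest position."""
        return (self.presence == IN_NEST) | (self.presence == IMPUTED)

    @classmethod
    def empty(cls, ant_id: str, duration: int = DURATION) -> "AntTrack":
        n = duration + 1
        return cls(
            ant_id=ant_id,
            xy=np.full((n, 2), np.nan),
            presence=np.full(n, MISSING, dtype=np.int8),
        )


@dataclass(frozen=True)
class RecordingSegment:
    """One video file within a continuous recording.

    The two camera models produce fixed-length videos; the Hero3 silver runs
    half a second long per video, corrected downstream by subtracting one
    second from every second silver video.  ``start_offset`` is the extra
    delay (s) from sequentially switching on cameras, applied when this
    segment starts.
    """

    camera_model: str
    nominal_length: float | None = None
    start_offset: float = 0.0

    @property
    def length(self) -> float:
        if self.nominal_length is not None:
            return float(self.nominal_length)
        try:
            return CAMERA_LENGTHS[self.camera_model]
        except KeyError:
            raise ValueError(f"unknown camera model {self.camera_model!r}") from None


def segment_starts(segments: list[RecordingSegment]) -> np.ndarray:
    """Corrected global start time of each segment.

    Every second video recorded with a Hero3 silver contributes a -1 s clock
    correction (the camera runs 0.5 s long per video); inter-camera start
    offsets are added cumulatively.  Raises :class:`AlignmentError` if the
    corrected segments end up out of order or overlap by more than the 1 s
    correction.
    """
    starts = np.empty(len(segments))
    t = 0.0
    silver_seen = 0
    prev_end = None
    for i, seg in enumerate(segments):
        t += seg.start_offset
        if seg.camera_model == "hero3_silver":
            silver_seen += 1
            if silver_seen % 2 == 0:
                t -= 1.0
        if prev_end is not None and t < prev_end - 1.0 - 1e-9:
            raise AlignmentError(f"segment {i} overlaps the corrected timeline")
        if i > 0 and t < starts[i - 1]:
            raise AlignmentError(f"segment {i} starts before segment {i - 1}")
        starts[i] = t
        prev_end = t + seg.length
        t = prev_end
    return starts


def align_clocks(
    segments: list[RecordingSegment], local_times: list[np.ndarray]
) -> list[np.ndarray]:
    """Map per-segment local times onto the corrected global timeline."""
    if len(local_times) != len(segments):
        raise ValueError("one local-time array per segment is required")
    starts = segment_starts(segments)
    return [np.asarray(lt, dtype=float) + s for lt, s in zip(local_times, starts)]


def interpolate_gaps(track: AntTrack, nest: NestGeometry) -> AntTrack:
    """Impute MISSING seconds by linear interpolation, projecting into the nest.

    Only gaps flanked by in-nest observations are imputed (crossings between
    chambers); outside spells are left untouched.  Gaps at the start or end
    of the recording cannot be interpolated and are trimmed to OUTSIDE with a
    warning.  Complete tracks are returned unchanged (same object).
    """
    if not np.any(track.presence == MISSING):
        return track
    presence = track.presence.copy()
    xy = track.xy.copy()
    obs = presence == IN_NEST
    obs_idx = np.flatnonzero(obs)
    missing_idx = np.flatnonzero(presence == MISSING)

    if obs_idx.size == 0:
        warnings.warn(
            f"ant {track.ant_id}: no in-nest observations; gaps trimmed to outside"
        )
        presence[missing_idx] = OUTSIDE
        return AntTrack(track.ant_id, xy, presence)

    boundary = (missing_idx < obs_idx[0]) | (missing_idx > obs_idx[-1])
    # interior gaps must be flanked by observations on both sides with no
    # outside spell in between: find each missing run's flanks
    interior = missing_idx[~boundary]
    fill = []
    for t in interior:
        left = obs_idx[obs_idx < t]
        right = obs_idx[obs_idx > t]
        lo, hi = left[-1], right[0]
        if np.any(presence[lo:hi] == OUTSIDE):
            continue  # gap abuts a foraging spell: not a tracking gap
        fill.append((t, lo, hi))
    if fill:
        ts, los, his = map(np.asarray, zip(*fill))
        w = (ts - los) / (his - los)
        pts = xy[los] * (1 - w[:, None]) + xy[his] * w[:, None]
        xy[ts] = project_into_nest_many(pts, nest)
        presence[ts] = IMPUTED
    still = presence == MISSING
    if np.any(boundary) or np.any(still[interior] if interior.size else False):
        warnings.warn(
            f"ant {track.ant_id}: {int((presence == MISSING).sum())} unfillable "
            "gap seconds trimmed to outside"
        )
    presence[presence == MISSING] = OUTSIDE
    xy[presence == OUTSIDE] = np.nan
    return AntTrack(track.ant_id, xy, presence)


def preprocess_tracks(
    frame,
    nest: NestGeometry,
    duration: int = DURATION,
    transform=None,
) -> list[AntTrack]:
    """Long observation table -> complete per-second tracks.

    Parameters
    ----------
    frame : DataFrame
        Columns ``ant_id, t_s, x_mm, y_mm, presence`` (presence optional;
        rows with missing coordinates are treated as outside).  With
        ``transform`` given, coordinates are taken as pixels and mapped
        through the affine transform first.
    nest : NestGeometry
    duration : int
        Recording length in seconds; output tracks span t = 0 ... duration.
    transform : AffineTransform, optional
        Camera-to-nest alignment applied before projection.

    Returns
    -------
    list of AntTrack, one per ant, each of length ``duration + 1`` with every
    in-nest/imputed position inside the walkable region.
    """
    tracks = []
    for ant_id, sub in frame.groupby("ant_id", sort=True):
        tr = AntTrack.empty(str(ant_id), duration)
        t = sub["t_s"].to_numpy().astype(int)
        if t.min() < 0 or t.max() > duration:
            raise ValueError(f"ant {ant_id}: observation time outside [0, {duration}]")
        pts = sub[["x_mm", "y_mm"]].to_numpy(dtype=float)
        if transform is not None:
            pts = transform(pts)
        if "presence" in sub.columns:
            outside = sub["presence"].astype(str).to_numpy() == "outside"
        else:
            outside = np.zeros(len(sub), dtype=bool)
        outside |= ~np.isfinite(pts).all(axis=1)
        tr.presence[t[outside]] = OUTSIDE
        inside = ~outside
        tr.xy[t[inside]] = project_into_nest_many(pts[inside], nest)
        tr.presence[t[inside]] = IN_NEST
        tracks.append(interpolate_gaps(tr, nest))
    return tracks


def stack_positions(tracks: list[AntTrack]) -> tuple[np.ndarray, np.ndarray]:
    """Stack tracks into (n_ants, T+1, 2) positions and an in-nest mask."""
    xy = np.stack([tr.xy for tr in tracks])
    in_nest = np.stack([tr.in_nest for tr in tracks])
    return xy, in_nest
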