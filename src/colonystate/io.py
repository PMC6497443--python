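"""Delimited-text readers/writers for track and event tables.

Track tables: columns ``ant_id, t_s, x_mm, y_mm, presence``; event tables:
``ant_i, ant_j, start_s, end_s``.  Files are plain CSV (or any separator
pandas accepts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import PRESENCE_LABELS, AntTrack

TRACK_COLUMNS = ["ant_id", "t_s", "x_mm", "y_mm", "presence"]
EVENT_COLUMNS = ["ant_i", "ant_j", "start_s", "end_s"]


def tracks_to_frame(tracks: list[AntTrack]) -> pd.DataFrame:
    """Long per-second table from a list of tracks."""
    parts = []
    for tr in tracks:
        n = tr.n_seconds
        parts.append(
            pd.DataFrame(
                {
                    "ant_id": tr.ant_id,
                    "t_s": np.arange(n),
                    "x_mm": tr.xy[:, 0],
                    "y_mm": tr.xy[:, 1],
                    "presence": [PRESENCE_LABELS[c] for c in tr.presence],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def read_tracks(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(TRACK_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    return df


def write_tracks(tracks: list[AntTrack], path, sep: str = ",") -> None:
    tracks_to_frame(tracks).to_csv(path, sep=sep, index=False)


def read_events(path, sep: str = ","):
    from .interaction_network import TrophallaxisEvent

    df = pd.read_csv(path, sep=sep)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return [
        TrophallaxisEvent(str(r.ant_i), str(r.ant_j), int(r.start_s), int(r.end_s))
        for r in df.itertuples()
    ]


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.ant_i, e.ant_j, e.start, e.end) for e in events], columns=EVENT_COLUMNS
    )


def write_events(events, path, sep: str = ",") -> None:
    events_to_frame(events).to_csv(path, sep=sep, index=False)
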