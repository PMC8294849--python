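"""Mitochondrial trafficking statistics from particle tracks.

A mitochondrion is scored *mobile* when the path length it covers inside
some contiguous 300-s window exceeds 2 μm; velocities exclude pauses, i.e.
maximal runs of sub-threshold frame steps lasting longer than 10 s, and are
computed as (path length outside pauses) / (time outside pauses).  "Distance
covered" means cumulative path length, not net displacement — organelles
reverse direction, and tracking software reports path statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .errors import InputError, UndefinedResultError

#: defaults from the quantification rules of the source assays
MOBILITY_THRESHOLD_UM = 2.0
MOBILITY_WINDOW_S = 300.0
PAUSE_EXCLUSION_S = 10.0
#: a frame step below this is treated as stationary (localization jitter)
IMMOBILITY_STEP_UM = 0.1

_DT_TOL = 1e-6  # s; allowed non-uniformity of the frame interval


@dataclass
class Track:
    """One tracked mitochondrion: times (s) and xy positions (μm)."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise InputError(f"track {self.track_id}: t/x/y length mismatch")
        if self.t.size < 2:
            raise InputError(f"track {self.track_id}: needs at least 2 points")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise InputError(f"track {self.track_id}: time not strictly increasing")
        if np.ptp(dt) > _DT_TOL:
            raise InputError(f"track {self.track_id}: non-uniform frame interval")

    @property
    def frame_dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n_points(self) -> int:
        return self.t.size


@dataclass
class TrackStats:
    """Per-track summary: path length, pause-excluded velocity, mobility."""

    track_id: str
    path_length: float       # μm
    velocity: float          # μm/s, pause-excluded; NaN when undefined
    is_mobile: bool
    excluded_time: float     # s spent inside pauses > exclusion


def frame_displacements(track: Track) -> np.ndarray:
    """(interval s, step μm) per consecutive frame pair; shape (n-1, 2)."""
    dt = np.diff(track.t)
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    return np.column_stack([dt, steps])


def track_path_length(track: Track) -> float:
    """Cumulative travelled distance (μm) over the whole track."""
    return float(frame_displacements(track)[:, 1].sum())


def windowed_max_path(track: Track, window: float) -> float:
    """Largest path length inside any contiguous window of ``window`` s."""
    disp = frame_displacements(track)
    dt = track.frame_dt
    w = int(round(window / dt))  # number of frame intervals per window
    steps = disp[:, 1]
    if w >= steps.size:
        return float(steps.sum())
    csum = np.concatenate([[0.0], np.cumsum(steps)])
    return float(np.max(csum[w:] - csum[:-w]))


def classify_mobility(
    track: Track,
    threshold: float = MOBILITY_THRESHOLD_UM,
    window: float = MOBILITY_WINDOW_S,
    prorate_short: bool = True,
) -> bool:
    """Mobile iff path length within some ``window``-s stretch exceeds ``threshold`` μm.

    Tracks shorter than the window use a pro-rated threshold
    ``threshold * duration / window`` unless ``prorate_short`` is False, in
    which case a short track is an input error.
    """
    if track.duration < window - _DT_TOL:
        if not prorate_short:
            raise InputError(
                f"track {track.track_id}: duration {track.duration} s < window {window} s"
            )
        threshold = threshold * track.duration / window
    return windowed_max_path(track, window) > threshold


def pause_mask(
    track: Track,
    pause_exclusion: float = PAUSE_EXCLUSION_S,
    immobility_step: float = IMMOBILITY_STEP_UM,
) -> np.ndarray:
    """Boolean per frame interval: True where the interval sits in a pause.

    A pause is a maximal run of consecutive intervals whose step is below
    ``immobility_step`` and whose total duration is strictly greater than
    ``pause_exclusion`` seconds.
    """
    disp = frame_displacements(track)
    still = disp[:, 1] < immobility_step
    mask = np.zeros(still.size, dtype=bool)
    i = 0
    while i < still.size:
        if still[i]:
            j = i
            while j < still.size and still[j]:
                j += 1
            if disp[i:j, 0].sum() > pause_exclusion:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def track_velocity(
    track: Track,
    pause_exclusion: float = PAUSE_EXCLUSION_S,
    immobility_step: float = IMMOBILITY_STEP_UM,
) -> tuple[float, float]:
    """Pause-excluded velocity (μm/s) and the excluded time (s).

    Raises UndefinedResultError when the whole track is one long pause —
    there is no moving time over which a velocity could be defined.
    """
    disp = frame_displacements(track)
    excluded = pause_mask(track, pause_exclusion, immobility_step)
    kept_time = disp[~excluded, 0].sum()
    excluded_time = float(disp[excluded, 0].sum())
    if kept_time <= 0:
        raise UndefinedResultError(
            f"track {track.track_id}: all time excluded as pause; velocity undefined"
        )
    return float(disp[~excluded, 1].sum() / kept_time), excluded_time


def track_stats(track: Track, **params) -> TrackStats:
    """Full per-track summary; velocity is NaN when undefined."""
    try:
        vel, excl = track_velocity(
            track,
            params.get("pause_exclusion", PAUSE_EXCLUSION_S),
            params.get("immobility_step", IMMOBILITY_STEP_UM),
        )
    except UndefinedResultError:
        vel, excl = float("nan"), track.duration
    return TrackStats(
        track_id=track.track_id,
        path_length=track_path_length(track),
        velocity=vel,
        is_mobile=classify_mobility(
            track,
            params.get("threshold", MOBILITY_THRESHOLD_UM),
            params.get("window", MOBILITY_WINDOW_S),
        ),
        excluded_time=excl,
    )


def movie_mobile_fraction(tracks: list[Track], n_total_mito: int, **params) -> float:
    """Percent of all mitochondria in the movie that are mobile.

    ``n_total_mito`` is the denominator (every mitochondrion visible in the
    movie, tracked or not); the tracked set supplies the mobile count.
    """
    if n_total_mito <= 0:
        raise InputError("n_total_mito must be positive")
    n_mobile = sum(classify_mobility(tr, **params) for tr in tracks)
    if n_mobile > n_total_mito:
        raise InputError("more mobile tracks than total mitochondria")
    return 100.0 * n_mobile / n_total_mito


# ---------------------------------------------------------------------------
# CSV interface (track_id, frame, t_s, x_um, y_um)

def read_tracks_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    required = {"track_id", "t_s", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise InputError(f"track CSV must have columns {sorted(required)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_s")
        tracks.append(Track(str(tid), grp["t_s"].values, grp["x_um"].values, grp["y_um"].values))
    return tracks


def write_tracks_csv(path: str | Path, tracks: list[Track]) -> None:
    rows = []
    for tr in tracks:
        for i in range(tr.n_points):
            rows.append((tr.track_id, i, tr.t[i], tr.x[i], tr.y[i]))
    pd.DataFrame(rows, columns=["track_id", "frame", "t_s", "x_um", "y_um"]).to_csv(
        path, index=False
    )


def stats_table(tracks: list[Track], **params) -> pd.DataFrame:
    """Per-track stats as a tidy table (one row per track)."""
    recs = [track_stats(tr, **params) for tr in tracks]
    return pd.DataFrame(
        {
            "track_id": [r.track_id for r in recs],
            "path_length_um": [r.path_length for r in recs],
            "velocity_um_s": [r.velocity for r in recs],
            "is_mobile": [r.is_mobile for r in recs],
            "excluded_time_s": [r.excluded_time for r in recs],
        }
    )
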