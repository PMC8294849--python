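"""Behavioral assay scoring from trajectories and trial logs.

Zone occupancy (elevated plus maze / open field), trajectory kinematics,
the accelerating-rotarod RPM formula, and T-maze spontaneous alternation
with NO-GO exclusion.  Zone membership uses point-in-polygon with the
boundary counted as inside, so frames at arm junctions are never lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .containers import Trajectory
from .errors import InputError, UndefinedResultError


@dataclass
class ZoneMap:
    """Named, non-overlapping polygonal zones of the arena."""

    zones: dict[str, Polygon]

    def __post_init__(self):
        names = list(self.zones)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = self.zones[a].intersection(self.zones[b])
                if inter.area > 1e-9:
                    raise InputError(f"zones {a!r} and {b!r} overlap")

    @classmethod
    def elevated_plus_maze(
        cls, arm_length: float = 30.0, arm_width: float = 5.0, center_size: float = 5.0
    ) -> "ZoneMap":
        """Standard EPM template: four 30×5 cm arms around a 5×5 cm center.

        Closed arms run north–south, open arms east–west; the origin is the
        maze center.  The center square is its own zone.
        """
        h = center_size / 2.0
        w = arm_width / 2.0
        L = arm_length
        closed = Polygon([(-w, h), (w, h), (w, h + L), (-w, h + L)]).union(
            Polygon([(-w, -h), (w, -h), (w, -h - L), (-w, -h - L)])
        )
        open_ = Polygon([(h, -w), (h, w), (h + L, w), (h + L, -w)]).union(
            Polygon([(-h, -w), (-h, w), (-h - L, w), (-h - L, -w)])
        )
        center = Polygon([(-h, -h), (h, -h), (h, h), (-h, h)])
        return cls({"closed": closed, "open": open_, "center": center})

    @classmethod
    def open_field(cls, side: float = 40.0, center_fraction: float = 0.5) -> "ZoneMap":
        """Square open field split into a center zone and periphery."""
        h = side / 2.0
        c = side * center_fraction / 2.0
        center = Polygon([(-c, -c), (c, -c), (c, c), (-c, c)])
        outer = Polygon([(-h, -h), (h, -h), (h, h), (-h, h)])
        periphery = outer.difference(center)
        return cls({"center": center, "periphery": periphery})


def zone_occupancy(traj: Trajectory, zones: ZoneMap) -> dict[str, float]:
    """Percent of frames spent in each zone (boundary counts as inside).

    Occupancies sum to ≤ 100: frames outside every zone are allowed.
    """
    if traj.n_frames == 0:
        raise InputError("trajectory has no frames")
    points = [Point(x, y) for x, y in zip(traj.x, traj.y)]
    out = {}
    for name, poly in zones.zones.items():
        prepared = prep(poly)
        # covers() includes the boundary, unlike contains()
        n = sum(prepared.intersects(p) and poly.covers(p) for p in points)
        out[name] = 100.0 * n / traj.n_frames
    return out


def traj_kinematics(traj: Trajectory) -> tuple[float, float]:
    """(total distance cm, mean velocity cm/s) from calibrated positions."""
    if traj.n_frames < 2:
        raise InputError("need at least two frames")
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y)) * traj.calibration
    dist = float(steps.sum())
    duration = float(traj.t[-1] - traj.t[0])
    return dist, dist / duration


def rotarod_rpm(
    start_speed: float,
    end_speed: float,
    seconds_run: float,
    trial_length: float = 300.0,
) -> float:
    """Rod speed at fall: linear ramp from start to end over the trial.

    RPM = (end − start) / trial_length · seconds_run + start, pinned to the
    start speed at 0 s and the end speed at the full trial length.
    """
    if not 0.0 <= seconds_run <= trial_length:
        raise InputError(
            f"seconds_run {seconds_run} outside [0, {trial_length}]"
        )
    return (end_speed - start_speed) / trial_length * seconds_run + start_speed


NO_GO = "NO-GO"


@dataclass
class AlternationResult:
    percent_alternation: float | None  # None when undefined (< 2 valid choices)
    n_valid: int
    n_nogo: int
    excluded: bool  # animal excluded (> 3 NO-GOs)


def alternation_score(choices: list[str], max_nogo: int = 3) -> AlternationResult:
    """Spontaneous alternation over consecutive valid arm choices.

    NO-GO trials are dropped from the choice sequence; the animal is
    flagged excluded when it logged more than ``max_nogo`` of them.  The
    score is the percentage of consecutive valid-choice pairs that differ.
    """
    n_nogo = sum(1 for c in choices if c == NO_GO)
    valid = [c for c in choices if c != NO_GO]
    excluded = n_nogo > max_nogo
    if len(valid) < 2:
        return AlternationResult(None, len(valid), n_nogo, excluded)
    pairs = list(zip(valid[:-1], valid[1:]))
    pct = 100.0 * sum(a != b for a, b in pairs) / len(pairs)
    return AlternationResult(pct, len(valid), n_nogo, excluded)


# ---------------------------------------------------------------------------
# Trajectory CSV interface (frame, t_s, x, y)

def read_trajectory_csv(path, calibration: float = 1.0) -> Trajectory:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"t_s", "x", "y"}
    if not required.issubset(df.columns):
        raise InputError(f"trajectory CSV must have columns {sorted(required)}")
    return Trajectory(df["t_s"].values, df["x"].values, df["y"].values, calibration)


def write_trajectory_csv(path, traj: Trajectory) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "t_s": traj.t,
            "x": traj.x,
            "y": traj.y,
        }
    ).to_csv(path, index=False)
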