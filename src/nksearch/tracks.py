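"""Cell-migration metrics on timestamped trajectories.

Operates on manually- or software-tracked cell positions in physical units
(seconds, micrometers), as exported from time-lapse imaging, and on the
synthetic tracks from :mod:`nksearch.synth`. The three per-track summary
statistics are

* **velocity** — total path length divided by total duration, reported in
  um/min. The path-length definition (rather than mean frame-to-frame
  speed) is robust to the irregular 16.8–38.2 s frame intervals of the
  source acquisitions; it is this package's choice of formula.
* **persistence** — net displacement between start and end point divided
  by total path length; 1 for a straight path, 0 for a closed loop.
  Undefined for immobile tracks, which must be filtered out first
  (:func:`filter_immobile`).
* **step sizes** — frame-to-frame displacement magnitudes (um).

Encounters with bystander cells are segmented geometrically: an encounter
opens when the cell's distance to a bystander surface first drops below
the approach radius (10 um), and is classified *attracted* if the cell
subsequently touches the bystander before re-exceeding that radius, else
*passing by*. Attracted encounters are split into approach / touch /
leave phases, with all threshold crossings linearly interpolated in time
between frames. Tracks may be 2D or 3D; z is treated symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackMetrics",
    "EncounterEvent",
    "velocity",
    "persistence",
    "step_sizes",
    "track_metrics",
    "filter_immobile",
    "classify_encounters",
    "attracted_fraction",
    "read_tracks_csv",
    "write_tracks_csv",
]

#: approach threshold for encounter classification (um)
APPROACH_RADIUS = 10.0

#: NK-cell radius used for geometric contact (um; cell diameter ~10 um)
KILLER_RADIUS_UM = 5.0

#: immobility filter: net displacement below one cell diameter (um)
IMMOBILE_THRESHOLD_UM = 10.0


@dataclass
class Track:
    """One cell trajectory: times in seconds, positions in micrometers."""

    track_id: str
    t: np.ndarray            # (n,) seconds, strictly increasing
    xy: np.ndarray           # (n, 2) or (n, 3) um
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.ndim != 2 or self.xy.shape[0] != self.t.size:
            raise ValueError("t must be (n,), xy must be (n, dim)")
        if self.xy.shape[1] not in (2, 3):
            raise ValueError("tracks must be 2D or 3D")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite track data")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def dim(self) -> int:
        return int(self.xy.shape[1])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def net_displacement(self) -> float:
        return float(np.linalg.norm(self.xy[-1] - self.xy[0]))

    @property
    def path_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.xy, axis=0), axis=1)))


@dataclass
class TrackMetrics:
    track_id: str
    velocity_um_min: float
    persistence: float
    step_sizes_um: np.ndarray


@dataclass
class EncounterEvent:
    track_id: str
    bystander_id: int
    outcome: str                  # "attracted" | "passing_by"
    approach_s: float
    touch_s: float
    leave_s: float
    t_open_s: float = 0.0         # track time of the approach-radius crossing

    @property
    def total_s(self) -> float:
        return self.approach_s + self.touch_s + self.leave_s


def _require_samples(track: Track, n: int = 2):
    if track.n_samples < n:
        raise ValueError(f"track {track.track_id!r} has fewer than {n} samples")


def velocity(track: Track) -> float:
    """Total path length / total duration, in um/min."""
    _require_samples(track)
    if track.duration <= 0:
        raise ValueError("zero track duration")
    return track.path_length / track.duration * 60.0


def step_sizes(track: Track) -> np.ndarray:
    _require_samples(track)
    return np.linalg.norm(np.diff(track.xy, axis=0), axis=1)


def persistence(track: Track) -> float:
    """Net displacement / path length, in [0, 1].

    Raises for immobile tracks (zero path length); discard those with
    :func:`filter_immobile` before computing statistics.
    """
    _require_samples(track)
    path = track.path_length
    if path <= 0:
        raise ValueError(
            f"track {track.track_id!r} is immobile (zero path length); "
            "persistence is undefined"
        )
    return min(track.net_displacement / path, 1.0)


def track_metrics(track: Track) -> TrackMetrics:
    return TrackMetrics(track.track_id, velocity(track), persistence(track),
                        step_sizes(track))


def filter_immobile(tracks, displacement_threshold: float = IMMOBILE_THRESHOLD_UM):
    """Drop tracks whose net displacement is below the threshold (um).

    Default threshold: one NK-cell diameter. Returns the mobile subset.
    """
    kept = [tr for tr in tracks if tr.net_displacement >= displacement_threshold]
    n_dropped = len(tracks) - len(kept)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "filter_immobile: discarded %d of %d tracks (net displacement < %g um)",
            n_dropped, len(tracks), displacement_threshold,
        )
    return kept


def _interp_crossing(t0, t1, d0, d1, level):
    """Time at which the linear segment d(t) crosses ``level``."""
    if d1 == d0:
        return t1
    return t0 + (level - d0) / (d1 - d0) * (t1 - t0)


def classify_encounters(track: Track, bystanders,
                        approach_radius: float = APPROACH_RADIUS,
                        contact_distance=None,
                        killer_radius: float = KILLER_RADIUS_UM):
    """Segment a track into bystander encounters.

    ``bystanders`` is a sequence of objects with center coordinates and a
    radius: either ``(center, radius)`` tuples or objects with ``x, y, r``
    attributes. Distances are center-of-cell to bystander *surface*; the
    default contact criterion is geometric touch, i.e. center-to-center
    distance <= bystander radius + ``killer_radius`` (``contact_distance``
    overrides the center-to-center threshold).

    An encounter spans one excursion below ``approach_radius``; touch time
    is the span from first to last contact within the excursion, so brief
    contact interruptions count as touching. Excursions still open when the
    track ends are discarded.
    """
    _require_samples(track)
    events = []
    for b_id, b in enumerate(bystanders):
        if hasattr(b, "x"):
            center = np.array([b.x, b.y], dtype=float)
            radius = float(b.r)
        else:
            center = np.asarray(b[0], dtype=float)
            radius = float(b[1])
        if center.size != track.dim:
            raise ValueError(
                f"bystander {b_id} is {center.size}D but track is {track.dim}D"
            )
        c_thresh = (radius + killer_radius if contact_distance is None
                    else float(contact_distance))
        d_surf = np.linalg.norm(track.xy - center, axis=1) - radius
        d_cont = np.linalg.norm(track.xy - center, axis=1) - c_thresh
        events.extend(
            _segment_excursions(track.track_id, b_id, track.t, d_surf, d_cont,
                                approach_radius)
        )
    events.sort(key=lambda e: (e.t_open_s, e.bystander_id))
    return events


def _segment_excursions(track_id, b_id, t, d_surf, d_cont, approach_radius):
    events = []
    n = t.size
    i = 0
    # skip a track that starts already inside the approach zone: the entry
    # crossing is unobserved, so phase durations would be ill-defined
    while i < n and d_surf[i] < approach_radius:
        i += 1
    while i < n:
        # find the down-crossing of the approach radius
        while i < n and d_surf[i] >= approach_radius:
            i += 1
        if i >= n:
            break
        t_open = _interp_crossing(t[i - 1], t[i], d_surf[i - 1], d_surf[i],
                                  approach_radius)
        # scan the excursion
        first_contact = None
        last_contact = None
        j = i
        closed = False
        while j < n:
            if d_cont[j] <= 0.0:
                tc_in = (t[j] if first_contact is not None or d_cont[j - 1] <= 0.0
                         else _interp_crossing(t[j - 1], t[j], d_cont[j - 1],
                                               d_cont[j], 0.0))
                if first_contact is None:
                    first_contact = tc_in
                last_contact = t[j]
            elif last_contact is not None and d_cont[j - 1] <= 0.0:
                # leaving contact: interpolate the up-crossing
                last_contact = _interp_crossing(t[j - 1], t[j], d_cont[j - 1],
                                                d_cont[j], 0.0)
            if d_surf[j] >= approach_radius:
                t_close = _interp_crossing(t[j - 1], t[j], d_surf[j - 1],
                                           d_surf[j], approach_radius)
                closed = True
                break
            j += 1
        if not closed:
            break  # open excursion at track end: discard
        if first_contact is None:
            events.append(EncounterEvent(track_id, b_id, "passing_by",
                                         0.0, 0.0, 0.0, t_open_s=t_open))
        else:
            events.append(
                EncounterEvent(
                    track_id, b_id, "attracted",
                    approach_s=first_contact - t_open,
                    touch_s=last_contact - first_contact,
                    leave_s=t_close - last_contact,
                    t_open_s=t_open,
                )
            )
        i = j
    return events


def attracted_fraction(events, min_encounters: int = 8):
    """Per-track attracted fraction, restricted to tracks with at least
    ``min_encounters`` bystander encounters (the inclusion rule used for
    the experimental analysis). Returns {track_id: fraction}."""
    by_track: dict = {}
    for e in events:
        by_track.setdefault(e.track_id, []).append(e)
    out = {}
    for tid, evs in by_track.items():
        if len(evs) >= min_encounters:
            out[tid] = sum(1 for e in evs if e.outcome == "attracted") / len(evs)
    return out


# =====================================================================
# CSV IO
# =====================================================================

_LONG_COLS = ["track_id", "frame", "t_seconds", "x_um", "y_um"]


def write_tracks_csv(tracks, path) -> None:
    """Long-layout CSV: track_id, frame, t_seconds, x_um, y_um[, z_um]."""
    rows = []
    for tr in tracks:
        for k in range(tr.n_samples):
            row = [tr.track_id, k, tr.t[k], tr.xy[k, 0], tr.xy[k, 1]]
            if tr.dim == 3:
                row.append(tr.xy[k, 2])
            rows.append(row)
    cols = _LONG_COLS + (["z_um"] if tracks and tracks[0].dim == 3 else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False,
                                            float_format="%.17g")


def read_tracks_csv(path, dialect: str = "long"):
    """Read a track table.

    ``dialect='long'``: columns track_id, frame, t_seconds, x_um, y_um[, z_um]
    (one row per track per frame).
    ``dialect='wide'``: a t_seconds column plus x_<id>/y_<id> column pairs
    (one row per frame, one column pair per track; blank cells = absent).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect == "long":
        has_z = "z_um" in df.columns
        tracks = []
        for tid, grp in df.groupby("track_id", sort=True):
            grp = grp.sort_values("frame")
            cols = ["x_um", "y_um"] + (["z_um"] if has_z else [])
            tracks.append(Track(str(tid), grp["t_seconds"].to_numpy(),
                                grp[cols].to_numpy()))
        return tracks
    if dialect == "wide":
        ids = sorted({c[2:] for c in df.columns if c.startswith("x_")})
        tracks = []
        for tid in ids:
            sub = df[["t_seconds", f"x_{tid}", f"y_{tid}"]].dropna()
            tracks.append(Track(str(tid), sub["t_seconds"].to_numpy(),
                                sub[[f"x_{tid}", f"y_{tid}"]].to_numpy()))
        return tracks
    raise ValueError(f"unknown dialect {dialect!r}")


def metrics_table(tracks) -> pd.DataFrame:
    """Per-track metrics as a tidy DataFrame."""
    rows = []
    for tr in tracks:
        m = track_metrics(tr)
        rows.append((m.track_id, m.velocity_um_min, m.persistence,
                     float(np.mean(m.step_sizes_um))))
    return pd.DataFrame(rows, columns=["track_id", "velocity_um_min",
                                       "persistence", "mean_step_um"])
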