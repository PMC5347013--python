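"""Synthetic cell-track generator with known ground truth.

Emits correlated random walks that emulate the acquisition properties of
the source time-lapse data — irregular frame intervals drawn uniformly
from 16.8–38.2 s — while giving independent control of nominal speed and
directional persistence (wrapped-Gaussian turning noise per frame). A
configurable fraction of tracks is immobile (positional jitter only), to
exercise the immobile-cell filter. The generator exists to validate the
metrics code: it makes no claim to reproduce NK-cell biophysics.

An optional local speed-boost zone around placed bystander disks mirrors,
qualitatively, the experimentally observed acceleration near bystanders,
for end-to-end pipeline tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .tracks import EncounterEvent, Track

__all__ = ["TrackGenParams", "generate_tracks", "generate_encounter_fixture"]


@dataclass
class TrackGenParams:
    n_tracks: int = 50
    n_steps: int = 100
    speed_um_min: float = 4.0        # nominal NK speed on coverslips
    turn_sd: float = 0.6             # wrapped-Gaussian turning noise (rad/frame)
    dt_range_s: tuple = (16.8, 38.2)  # frame-interval range of the acquisitions
    jitter_sd_um: float = 0.0        # positional noise SD
    frac_immobile: float = 0.0
    start_box_um: float = 500.0      # tracks start uniformly in this square
    bystanders: list = field(default_factory=list)   # (center, radius) tuples
    boost_factor: float = 1.0        # speed multiplier within boost_radius
    boost_radius_um: float = 0.0     # around each bystander center
    seed: int = 0

    def __post_init__(self):
        if self.speed_um_min < 0:
            raise ValueError("speed must be >= 0")
        if not 0.0 <= self.frac_immobile <= 1.0:
            raise ValueError("frac_immobile must be in [0, 1]")
        lo, hi = self.dt_range_s
        if not (0 < lo <= hi):
            raise ValueError("frame-interval bounds must be positive and ordered")
        if self.turn_sd < 0 or self.jitter_sd_um < 0:
            raise ValueError("noise parameters must be >= 0")

    def with_(self, **kw) -> "TrackGenParams":
        return replace(self, **kw)


def _speed_at(p: TrackGenParams, pos) -> float:
    v = p.speed_um_min / 60.0  # um/s
    if p.boost_factor != 1.0 and p.boost_radius_um > 0.0:
        for center, _radius in p.bystanders:
            c = np.asarray(center, dtype=float)
            if np.linalg.norm(pos - c) < p.boost_radius_um:
                return v * p.boost_factor
    return v


def generate_tracks(params: TrackGenParams, rng=None):
    """Correlated random walks with ground truth attached as metadata.

    Heading is updated each frame by Gaussian turning noise of SD
    ``turn_sd``; step length is speed x frame interval; optional Gaussian
    positional jitter is added on top. Immobile tracks emit jitter-only
    motion. Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lo, hi = params.dt_range_s
    n_immobile = int(round(params.frac_immobile * params.n_tracks))
    tracks = []
    for i in range(params.n_tracks):
        immobile = i < n_immobile
        t = np.empty(params.n_steps + 1)
        xy = np.empty((params.n_steps + 1, 2))
        t[0] = 0.0
        xy[0] = rng.uniform(0.0, params.start_box_um, size=2)
        heading = rng.uniform(0.0, 2.0 * math.pi)
        for k in range(params.n_steps):
            dt = rng.uniform(lo, hi)
            t[k + 1] = t[k] + dt
            if immobile:
                xy[k + 1] = xy[0]
            else:
                heading += rng.normal(0.0, params.turn_sd) if params.turn_sd > 0 else 0.0
                step = _speed_at(params, xy[k]) * dt
                xy[k + 1] = xy[k] + step * np.array(
                    [math.cos(heading), math.sin(heading)]
                )
        if params.jitter_sd_um > 0:
            xy = xy + rng.normal(0.0, params.jitter_sd_um, size=xy.shape)
        tracks.append(
            Track(
                f"synth_{i:04d}", t, xy,
                meta={
                    "immobile": immobile,
                    "speed_um_min": 0.0 if immobile else params.speed_um_min,
                    "turn_sd": params.turn_sd,
                    "jitter_sd_um": params.jitter_sd_um,
                },
            )
        )
    return tracks


def generate_encounter_fixture(bystander_center, bystander_radius,
                               approach_s, touch_s, leave_s,
                               approach_radius: float = 10.0,
                               contact_distance=None,
                               killer_radius: float = 5.0,
                               min_surface_distance: float = 0.5,
                               margin_s: float = 30.0,
                               track_id: str = "scripted"):
    """Scripted radial approach-touch-leave track with its exact expected
    encounter event.

    The cell moves radially toward the bystander, crossing the approach
    radius, reaching contact ``approach_s`` later, staying in contact for
    ``touch_s``, then retreating and re-crossing the approach radius
    ``leave_s`` after contact ends. Knots are placed so that linear
    interpolation between frames reproduces the scripted durations
    exactly. Pass ``touch_s=None`` for a pure passing-by excursion whose
    closest surface distance is ``min_surface_distance``.

    Returns ``(Track, [expected EncounterEvent])``.
    """
    center = np.asarray(bystander_center, dtype=float)
    c_thresh = (bystander_radius + killer_radius if contact_distance is None
                else float(contact_distance))
    contact_surf = c_thresh - bystander_radius  # contact as surface distance
    outside = approach_radius + 5.0

    if touch_s is None:
        # passing-by: dip to min_surface_distance (above contact) and back out
        knots_t = [0.0, margin_s, margin_s + approach_s,
                   margin_s + approach_s + leave_s,
                   margin_s + approach_s + leave_s + margin_s]
        knots_d = [outside, approach_radius, min_surface_distance,
                   approach_radius, outside]
        expected = [EncounterEvent(track_id, 0, "passing_by", 0.0, 0.0, 0.0)] \
            if min_surface_distance < approach_radius else []
    else:
        knots_t = [0.0, margin_s,
                   margin_s + approach_s,
                   margin_s + approach_s + touch_s,
                   margin_s + approach_s + touch_s + leave_s,
                   margin_s + approach_s + touch_s + leave_s + margin_s]
        knots_d = [outside, approach_radius, contact_surf, contact_surf,
                   approach_radius, outside]
        expected = [EncounterEvent(track_id, 0, "attracted",
                                   approach_s, touch_s, leave_s)]

    t = np.array(knots_t)
    d = np.array(knots_d) + bystander_radius  # center distance
    xy = np.column_stack([center[0] + d, np.full(t.size, center[1])])
    return Track(track_id, t, xy), expected
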