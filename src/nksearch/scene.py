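"""Arena geometry for the continuous search model.

The model lives in a square arena of side ``L`` (length unit = one NK-cell
diameter, so all cell-sized disks have radius 0.5 by default) populated with
four species of disks:

* killers   — mobile Brownian searchers (diffusivity ``D``),
* targets   — immobile, removed on contact with a killer,
* obstacles — immobile, purely area-excluding (inactive NK cells),
* bystanders — immobile, area-excluding, and each surrounded by a circular
  acceleration zone of radius ``delta`` inside which killer diffusivity is
  raised from ``D`` to ``D_acc``.

Placement is uniform-at-random rejection sampling: disks must lie fully
inside the arena and may not overlap any previously placed disk.
Acceleration zones are not exclusion areas and may overlap anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml
from numba import njit

__all__ = [
    "Disk",
    "ModelParams",
    "Scene",
    "place_scene",
    "local_diffusion",
    "PlacementError",
]

#: disk kinds in placement order (fixed for reproducibility)
KINDS = ("obstacle", "bystander", "target", "killer")

#: rejection-sampling attempt cap per disk
DEFAULT_MAX_ATTEMPTS = 10_000

#: reject configurations whose total disk area fraction exceeds this
PACKING_LIMIT = 0.5


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a disk (over-dense scene)."""


@dataclass(frozen=True)
class Disk:
    """A disk with center ``(x, y)`` and radius ``r`` in model length units."""

    x: float
    y: float
    r: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("disk center must be finite")
        if not self.r > 0:
            raise ValueError("disk radius must be > 0")

    def distance_to(self, other: "Disk") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass
class ModelParams:
    """All parameters of the continuous model.

    Defaults follow the dimensionless convention: length unit = NK-cell
    diameter (``R = r_k = 0.5``), time unit fixed by ``D = 1``, arena side
    ``L = 50``.
    """

    n_k: int = 1            # killers
    n_t0: int = 1           # initial targets
    n_o: int = 0            # obstacles
    n_b: int = 0            # bystanders
    r_obs: float = 0.5      # obstacle radius
    R: float = 0.5          # target/bystander radius
    r_k: float = 0.5        # killer radius
    D: float = 1.0          # baseline diffusivity
    D_acc: float = 4.0      # diffusivity inside acceleration zones
    delta: float = 3.0      # acceleration-zone radius (> R when n_b > 0)
    L: float = 50.0         # arena side
    t_max: float | None = None   # horizon; default 10 * L^2 / (4 D)
    n_samples: int = 40_000
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("n_k", "n_t0", "n_o", "n_b"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("r_obs", "R", "r_k", "D", "L"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_b > 0:
            if not self.D_acc >= self.D:
                raise ValueError("D_acc must be >= D when bystanders are present")
            if not self.delta > self.R:
                raise ValueError("delta must exceed R when bystanders are present")
        if self.area_fraction() > PACKING_LIMIT:
            raise ValueError(
                f"total disk area fraction {self.area_fraction():.3f} exceeds "
                f"packing limit {PACKING_LIMIT}"
            )

    def area_fraction(self) -> float:
        area = (
            self.n_o * self.r_obs**2
            + (self.n_t0 + self.n_b) * self.R**2
            + self.n_k * self.r_k**2
        ) * math.pi
        return area / self.L**2

    @property
    def horizon(self) -> float:
        """Simulation horizon: ``t_max`` or 10x the single-searcher estimate."""
        if self.t_max is not None:
            return float(self.t_max)
        return 10.0 * self.L**2 / (4.0 * self.D)

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@njit(cache=True)
def _place_kernel(radii, L, max_attempts, seed):  # pragma: no cover - numba
    """Sequential rejection sampling with a uniform cell grid.

    Returns (x, y, ok). Cell size >= 2*r_max so overlap partners always lie
    in the 3x3 cell neighbourhood.
    """
    np.random.seed(seed)
    n = radii.shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    if n == 0:
        return xs, ys, True
    r_max = radii.max()
    cell = max(2.0 * r_max, 1e-9)
    # cap the grid so huge arenas stay cheap; larger cells remain correct
    # (overlap partners are still within the 3x3 neighbourhood)
    ncell = min(max(int(L / cell), 1), 256)
    cell = L / ncell
    cap = 64
    counts = np.zeros((ncell, ncell), np.int64)
    members = np.full((ncell, ncell, cap), -1, np.int64)
    for i in range(n):
        r = radii[i]
        placed = False
        for _ in range(max_attempts):
            x = r + np.random.random() * (L - 2.0 * r)
            y = r + np.random.random() * (L - 2.0 * r)
            cx = min(int(x / cell), ncell - 1)
            cy = min(int(y / cell), ncell - 1)
            ok = True
            for ax in range(max(cx - 1, 0), min(cx + 2, ncell)):
                for ay in range(max(cy - 1, 0), min(cy + 2, ncell)):
                    for k in range(counts[ax, ay]):
                        j = members[ax, ay, k]
                        dx = x - xs[j]
                        dy = y - ys[j]
                        if dx * dx + dy * dy < (r + radii[j]) ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                xs[i] = x
                ys[i] = y
                c = counts[cx, cy]
                if c >= cap:
                    return xs, ys, False
                members[cx, cy, c] = i
                counts[cx, cy] = c + 1
                placed = True
                break
        if not placed:
            return xs, ys, False
    return xs, ys, True


def _as_seed(rng) -> int:
    """Derive a 32-bit seed from an int or numpy Generator."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if not isinstance(rng, np.random.Generator):
        raise TypeError("rng must be an int seed or numpy Generator")
    return int(rng.integers(0, 2**32 - 1))


@dataclass
class Scene:
    """A placed arena: parameters plus the four disk populations."""

    params: ModelParams
    killers: list = field(default_factory=list)
    targets: list = field(default_factory=list)
    obstacles: list = field(default_factory=list)
    bystanders: list = field(default_factory=list)

    def all_disks(self):
        return self.obstacles + self.bystanders + self.targets + self.killers

    def audit_overlaps(self, tol: float = 0.0) -> list:
        """Brute-force O(n^2) pairwise overlap audit.

        Returns the list of offending (i, j) index pairs over ``all_disks()``;
        an empty list certifies the non-overlap invariant.
        """
        disks = self.all_disks()
        bad = []
        for i in range(len(disks)):
            for j in range(i + 1, len(disks)):
                a, b = disks[i], disks[j]
                if a.distance_to(b) - (a.r + b.r) < -tol:
                    bad.append((i, j))
        return bad

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for kind, disks in (
            ("killer", self.killers),
            ("target", self.targets),
            ("obstacle", self.obstacles),
            ("bystander", self.bystanders),
        ):
            for d in disks:
                rows.append((kind, d.x, d.y, d.r))
        return pd.DataFrame(rows, columns=["kind", "x", "y", "radius"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, params: ModelParams) -> "Scene":
        import pandas as pd

        df = pd.read_csv(path, float_precision="round_trip")
        scene = cls(params=params)
        dest = {
            "killer": scene.killers,
            "target": scene.targets,
            "obstacle": scene.obstacles,
            "bystander": scene.bystanders,
        }
        for row in df.itertuples(index=False):
            dest[row.kind].append(Disk(row.x, row.y, row.radius))
        return scene

    # -- convenience array views used by the engines ---------------------
    def _centers(self, disks):
        if not disks:
            return np.empty((0, 2))
        return np.array([[d.x, d.y] for d in disks])


def place_scene(
    params: ModelParams,
    rng,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> Scene:
    """Place all entities uniformly at random without overlap.

    Placement order is obstacles, bystanders, targets, killers; each disk is
    drawn uniformly in the arena interior and rejected if it overlaps any
    previously placed disk. Deterministic given the seed / generator state.

    Raises :class:`PlacementError` if any disk cannot be placed within
    ``max_attempts`` draws (over-dense configuration).
    """
    params.validate()
    radii = np.concatenate(
        [
            np.full(params.n_o, params.r_obs),
            np.full(params.n_b, params.R),
            np.full(params.n_t0, params.R),
            np.full(params.n_k, params.r_k),
        ]
    )
    seed = _as_seed(rng)
    xs, ys, ok = _place_kernel(radii, params.L, max_attempts, seed)
    if not ok:
        raise PlacementError(
            f"could not place all {radii.size} disks within "
            f"{max_attempts} attempts each (area fraction "
            f"{params.area_fraction():.3f}); configuration too dense"
        )
    scene = Scene(params=params)
    i = 0
    for count, r, dest in (
        (params.n_o, params.r_obs, scene.obstacles),
        (params.n_b, params.R, scene.bystanders),
        (params.n_t0, params.R, scene.targets),
        (params.n_k, params.r_k, scene.killers),
    ):
        for _ in range(count):
            dest.append(Disk(xs[i], ys[i], r))
            i += 1
    return scene


def local_diffusion(point, scene: Scene) -> float:
    """Killer diffusivity at ``point``: ``D_acc`` within distance ``delta`` of
    any bystander center, else ``D``. Overlapping zones do not stack."""
    x, y = float(point[0]), float(point[1])
    p = scene.params
    for b in scene.bystanders:
        if (x - b.x) ** 2 + (y - b.y) ** 2 <= p.delta**2:
            return p.D_acc
    return p.D
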