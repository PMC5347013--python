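"""Event-driven Brownian search engine (first-passage kinetic Monte Carlo).

Killers are propagated by exact first-passage jumps: around the current
position we construct a *protective disk* that touches no obstacle, target
or bystander surface, no arena wall, and no acceleration-zone boundary, so
that the diffusivity inside it is a single constant. The first-exit time of
a 2D Brownian particle from the center of a disk of radius ``a`` has the
classical Fourier–Bessel survival function

    S(t) = sum_n [2 / (alpha_n J1(alpha_n))] exp(-alpha_n^2 D t / a^2),

with ``alpha_n`` the zeros of ``J0``; the exit position is uniform on the
circle. We sample the exit time exactly by inverting a pre-tabulated CDF of
the rescaled time ``tau = D t / a^2`` (dense log grid plus the exact
single-exponential tail), which is what makes jumps across empty space
cost O(1) regardless of how empty it is.

Absorbing contact (killer touches target) cannot be reached by shrinking
protective disks alone, so whenever the protective radius would fall below
a small threshold the killer switches to fine-step Brownian dynamics until
it either captures the target, or diffuses clear of all surfaces again.
Captures, reflections and zone crossings are all resolved inside these
bursts; the burst step SD (0.04 length units = 4% of a cell diameter) sets
the only discretisation scale of the scheme.

A plain fixed-timestep Euler–Maruyama integrator (:func:`bd_run`) over the
identical geometry serves as the independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .scene import ModelParams, Scene, place_scene

__all__ = [
    "KillRecord",
    "sample_disk_exit",
    "run_simulation",
    "bd_run",
    "bd_disk_exit",
    "simulate_ensemble",
    "write_records_csv",
    "read_records_csv",
]

# -- propagation constants (model length units; cell diameter = 1) --------
H_FP = 0.08      # min protective radius for a first-passage jump
H_EXIT = 0.2     # burst ends once clear of all surfaces by this margin
SIGMA_BD = 0.04  # per-axis step SD inside a burst
RHO_CAP = 3.0    # protective radius cap (bounds neighbour queries)
RHO_NEAR = 1.0   # first-stage neighbour-query radius (dense-scene fast path)
GATHER = 1.0     # neighbour-gather margin for bursts

_STATUS_MSG = {1: "non-finite killer coordinates", 2: "killer escaped the arena"}


# =====================================================================
# First-passage time table: CDF of tau = D t / a^2 for exit from a disk
# =====================================================================

_FPT_TABLE = None


def _build_fpt_table(n_zeros: int = 2000, n_tau: int = 4096,
                     tau_min: float = 5e-4, tau_max: float = 3.5):
    from scipy.special import j1, jn_zeros

    alphas = jn_zeros(0, n_zeros)
    coef = 2.0 / (alphas * j1(alphas))
    tau = np.geomspace(tau_min, tau_max, n_tau)
    # S(tau) = sum coef_n exp(-alpha_n^2 tau); chunked to bound memory
    S = np.zeros_like(tau)
    for lo in range(0, n_zeros, 256):
        a2 = alphas[lo:lo + 256] ** 2
        S += np.exp(-np.outer(tau, a2)) @ coef[lo:lo + 256]
    F = np.clip(1.0 - S, 0.0, 1.0)
    F = np.maximum.accumulate(F)
    a1sq = alphas[0] ** 2
    s_tail = max(1.0 - F[-1], 1e-300)
    return F, tau, a1sq, s_tail, tau[-1]


def _fpt_table():
    global _FPT_TABLE
    if _FPT_TABLE is None:
        _FPT_TABLE = _build_fpt_table()
    return _FPT_TABLE


@njit(cache=True)
def _invert_tau(u, F, tau, a1sq, s_tail, tau_max):  # pragma: no cover
    """Inverse CDF of the rescaled exit time; exact exponential tail."""
    if u >= F[-1]:
        if u > 1.0 - 1e-16:
            u = 1.0 - 1e-16
        return tau_max + math.log(s_tail / (1.0 - u)) / a1sq
    lo = 0
    hi = F.shape[0] - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if F[mid] < u:
            lo = mid
        else:
            hi = mid
    f0 = F[lo]
    f1 = F[hi]
    if f1 <= f0:
        return tau[lo]
    w = (u - f0) / (f1 - f0)
    return tau[lo] + w * (tau[hi] - tau[lo])


def sample_disk_exit(protective_radius, D_local, rng, size=None):
    """Exact first-passage sample(s) of exit from a disk of the given radius.

    The particle starts at the disk center with diffusivity ``D_local``.
    Returns ``(times, points)`` where ``points`` are exit positions on the
    circle relative to the center (uniform angle). With ``size=None`` both
    are scalars / length-2 arrays.

    The mean exit time is ``protective_radius**2 / (4 * D_local)``.
    """
    if not protective_radius >= 0:
        raise ValueError("protective_radius must be >= 0")
    if not D_local > 0:
        raise ValueError("D_local must be > 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    F, tau, a1sq, s_tail, tau_max = _fpt_table()
    n = 1 if size is None else int(size)
    u = rng.random(n)
    th = np.interp(u, F, tau)
    in_tail = u >= F[-1]
    if in_tail.any():
        ut = np.minimum(u[in_tail], 1.0 - 1e-16)
        th[in_tail] = tau_max + np.log(s_tail / (1.0 - ut)) / a1sq
    times = th * protective_radius**2 / D_local
    ang = rng.random(n) * 2.0 * np.pi
    pts = protective_radius * np.column_stack([np.cos(ang), np.sin(ang)])
    if size is None:
        return float(times[0]), pts[0]
    return times, pts


# =====================================================================
# Kill records
# =====================================================================

@dataclass
class KillRecord:
    """Ordered kill times of one simulation sample.

    ``censored`` flags samples whose half-kill event (the ceil(n_t0/2)-th
    kill) was not reached within ``t_max``.
    """

    sample_id: int
    kill_times: np.ndarray
    n_t0: int
    t_max: float

    def __post_init__(self):
        self.kill_times = np.asarray(self.kill_times, dtype=float)
        if np.any(np.diff(self.kill_times) < 0):
            raise ValueError("kill times must be non-decreasing")
        if self.kill_times.size > self.n_t0:
            raise ValueError("more kills than initial targets")

    @property
    def n_kills(self) -> int:
        return int(self.kill_times.size)

    @property
    def half_index(self) -> int:
        return (self.n_t0 + 1) // 2  # ceil(n_t0 / 2)

    @property
    def half_kill_time(self):
        """Time of the ceil(n_t0/2)-th kill, or None if not reached."""
        if 0 < self.half_index <= self.n_kills:
            return float(self.kill_times[self.half_index - 1])
        return None

    @property
    def censored(self) -> bool:
        return self.half_kill_time is None

    def remaining_at(self, t) -> np.ndarray:
        """N_t(t) evaluated right-continuously on a time grid."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return self.n_t0 - np.searchsorted(self.kill_times, t, side="right")


def write_records_csv(records, path) -> None:
    rows = []
    for rec in records:
        if rec.n_kills == 0:
            rows.append((rec.sample_id, 0, np.nan, rec.censored))
        for k, t in enumerate(rec.kill_times, start=1):
            rows.append((rec.sample_id, k, t, rec.censored))
    df = pd.DataFrame(rows, columns=["sample_id", "kill_index", "kill_time", "censored"])
    df.to_csv(path, index=False, float_format="%.17g")


def read_records_csv(path, n_t0: int, t_max: float):
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    for sid, grp in df.groupby("sample_id", sort=True):
        times = grp["kill_time"].dropna().to_numpy()
        records.append(KillRecord(int(sid), np.sort(times), n_t0, t_max))
    return records


# =====================================================================
# FPKMC kernel
# =====================================================================

@njit(cache=True)
def _grid_min_dist(x, y, sx, sy, sr, ptr, idx, ncell, cs, rq):  # pragma: no cover
    """Min (center distance - radius) over surfaces with centers within rq."""
    dmin = 1e300
    cx0 = int((x - rq) / cs)
    cx1 = int((x + rq) / cs)
    cy0 = int((y - rq) / cs)
    cy1 = int((y + rq) / cs)
    if cx0 < 0:
        cx0 = 0
    if cy0 < 0:
        cy0 = 0
    if cx1 > ncell - 1:
        cx1 = ncell - 1
    if cy1 > ncell - 1:
        cy1 = ncell - 1
    for ax in range(cx0, cx1 + 1):
        for ay in range(cy0, cy1 + 1):
            c = ax * ncell + ay
            for k in range(ptr[c], ptr[c + 1]):
                j = idx[k]
                d = math.hypot(x - sx[j], y - sy[j]) - sr[j]
                if d < dmin:
                    dmin = d
    return dmin


@njit(cache=True)
def _grid_collect(x, y, sx, sy, sr, ptr, idx, ncell, cs, rq,
                  dmax, out):  # pragma: no cover
    """Collect surfaces with (center distance - radius) < dmax into out."""
    n = 0
    cx0 = int((x - rq) / cs)
    cx1 = int((x + rq) / cs)
    cy0 = int((y - rq) / cs)
    cy1 = int((y + rq) / cs)
    if cx0 < 0:
        cx0 = 0
    if cy0 < 0:
        cy0 = 0
    if cx1 > ncell - 1:
        cx1 = ncell - 1
    if cy1 > ncell - 1:
        cy1 = ncell - 1
    for ax in range(cx0, cx1 + 1):
        for ay in range(cy0, cy1 + 1):
            c = ax * ncell + ay
            for k in range(ptr[c], ptr[c + 1]):
                j = idx[k]
                if math.hypot(x - sx[j], y - sy[j]) - sr[j] < dmax:
                    out[n] = j
                    n += 1
    return n


@njit(cache=True)
def _fpkmc_sample(seed, kx0, ky0, sx, sy, sr, ptr, idx, ncell, cs,
                  tx, ty, cap_r, bx, by, delta, D, Dacc, L, rk,
                  t_max, stop_after,
                  F, tau, a1sq, s_tail, tau_max):  # pragma: no cover
    """One FPKMC sample. Returns (kill_times, n_kills, status)."""
    np.random.seed(seed)
    n_k = kx0.shape[0]
    n_t = tx.shape[0]
    n_s = sx.shape[0]
    n_b = bx.shape[0]
    kx = kx0.copy()
    ky = ky0.copy()
    kt = np.zeros(n_k)
    done = np.zeros(n_k, np.uint8)
    alive = np.ones(n_t, np.uint8)
    kill_t = np.empty(n_t)
    n_kills = 0
    nb = np.empty(max(n_s, 1), np.int64)
    tloc = np.empty(max(n_t, 1), np.int64)
    bloc = np.empty(max(n_b, 1), np.int64)
    max_sr = (sr.max() if n_s > 0 else 0.0) + 1e-9
    rq_far = RHO_CAP + max_sr
    rq_near = RHO_NEAR + max_sr
    gather = GATHER
    rq_gather = gather + max_sr
    regather2 = (gather - H_EXIT - 0.2) ** 2
    lo_w = rk
    hi_x = L - rk
    two_pi = 2.0 * math.pi

    # t = 0 capture sweep (killer placed already in contact)
    for i in range(n_k):
        while True:
            jb = -1
            db = 1e300
            for j in range(n_t):
                if alive[j]:
                    d = math.hypot(kx[i] - tx[j], ky[i] - ty[j])
                    if d <= cap_r[j] and d < db:
                        db = d
                        jb = j
            if jb < 0:
                break
            alive[jb] = 0
            kill_t[n_kills] = 0.0
            n_kills += 1
            if n_kills >= stop_after:
                return kill_t[:n_kills], n_kills, 0

    while True:
        # earliest active killer and the runner-up time (causality cap)
        i = -1
        tmin = 1e300
        tsec = 1e300
        for k in range(n_k):
            if done[k] == 0:
                if kt[k] < tmin:
                    tsec = tmin
                    tmin = kt[k]
                    i = k
                elif kt[k] < tsec:
                    tsec = kt[k]
        if i < 0 or tmin >= t_max or n_kills >= stop_after:
            break
        x = kx[i]
        y = ky[i]
        t = tmin
        t_cap = t_max if tsec > t_max else tsec

        if not (math.isfinite(x) and math.isfinite(y)):
            return kill_t[:n_kills], n_kills, 1
        if x < lo_w - 1e-6 or x > hi_x + 1e-6 or y < lo_w - 1e-6 or y > hi_x + 1e-6:
            return kill_t[:n_kills], n_kills, 2

        # distance to nearest constraint of any type (walls, targets,
        # zone boundaries first; surface query staged by range)
        dmin = min(min(x - lo_w, hi_x - x), min(y - lo_w, hi_x - y))
        for j in range(n_t):
            if alive[j]:
                d = math.hypot(x - tx[j], y - ty[j]) - cap_r[j]
                if d < dmin:
                    dmin = d
        # diffusivity is D_acc on the UNION of zones: inside, the domain
        # only needs to fit in one covering zone (max slack); outside, it
        # must not reach the nearest zone
        inside = False
        dz_in = -1e300
        dz_out = 1e300
        for j in range(n_b):
            d = math.hypot(x - bx[j], y - by[j])
            if d < delta:
                inside = True
                if delta - d > dz_in:
                    dz_in = delta - d
            elif d - delta < dz_out:
                dz_out = d - delta
        dz = dz_in if inside else dz_out
        if dz < dmin:
            dmin = dz
        if n_s > 0:
            ds = _grid_min_dist(x, y, sx, sy, sr, ptr, idx, ncell, cs, rq_near)
            if ds >= RHO_NEAR and dmin > RHO_NEAR:
                # nothing within the near range; pay for the full query
                ds = _grid_min_dist(x, y, sx, sy, sr, ptr, idx, ncell, cs,
                                    rq_far)
            if ds < dmin:
                dmin = ds

        if dmin >= H_FP:
            # exact first-passage jump inside the protective disk
            rho = dmin if dmin < RHO_CAP else RHO_CAP
            u = np.random.random()
            th = _invert_tau(u, F, tau, a1sq, s_tail, tau_max)
            Dloc = Dacc if inside else D
            t += rho * rho * th / Dloc
            ang = two_pi * np.random.random()
            x += rho * math.cos(ang)
            y += rho * math.sin(ang)
            if x < lo_w:
                x = lo_w
            elif x > hi_x:
                x = hi_x
            if y < lo_w:
                y = lo_w
            elif y > hi_x:
                y = hi_x
            kx[i] = x
            ky[i] = y
            kt[i] = t
            if t >= t_max:
                done[i] = 1
            continue

        # --- near-surface Brownian burst --------------------------------
        # gather everything reachable within the burst: reflecting surfaces
        # (grid query), live targets, and bystanders whose zone could
        # contain or border the killer while it stays near the anchor
        gx = x
        gy = y
        n_nb = _grid_collect(gx, gy, sx, sy, sr, ptr, idx, ncell, cs,
                             rq_gather, gather, nb)
        n_tl = 0
        for j in range(n_t):
            if alive[j] and math.hypot(gx - tx[j], gy - ty[j]) - cap_r[j] < gather:
                tloc[n_tl] = j
                n_tl += 1
        n_bl = 0
        for j in range(n_b):
            if math.hypot(gx - bx[j], gy - by[j]) < delta + gather:
                bloc[n_bl] = j
                n_bl += 1
        while True:
            # captures (nearest first, then re-evaluate)
            while True:
                jb = -1
                db = 1e300
                for m in range(n_tl):
                    j = tloc[m]
                    if alive[j]:
                        d = math.hypot(x - tx[j], y - ty[j]) - cap_r[j]
                        if d <= 0.0 and d < db:
                            db = d
                            jb = j
                if jb < 0:
                    break
                alive[jb] = 0
                kill_t[n_kills] = t
                n_kills += 1
                if n_kills >= stop_after:
                    return kill_t[:n_kills], n_kills, 0
            # clear of everything? end the burst
            bmin = min(min(x - lo_w, hi_x - x), min(y - lo_w, hi_x - y))
            for m in range(n_nb):
                j = nb[m]
                d = math.hypot(x - sx[j], y - sy[j]) - sr[j]
                if d < bmin:
                    bmin = d
            for m in range(n_tl):
                j = tloc[m]
                if alive[j]:
                    d = math.hypot(x - tx[j], y - ty[j]) - cap_r[j]
                    if d < bmin:
                        bmin = d
            breal = bmin  # nearest reflecting/absorbing surface or wall
            inside = False
            dz_in = -1e300
            dz_out = 1e300
            for m in range(n_bl):
                j = bloc[m]
                d = math.hypot(x - bx[j], y - by[j])
                if d < delta:
                    inside = True
                    if delta - d > dz_in:
                        dz_in = delta - d
                elif d - delta < dz_out:
                    dz_out = d - delta
            dz = dz_in if inside else dz_out
            if dz < bmin:
                bmin = dz
            if bmin >= H_EXIT:
                break
            # one Euler step at the local diffusivity; when only a zone
            # boundary is nearby (no hard surface within 0.3) a coarser
            # step is safe: the boundary neither absorbs nor reflects.
            # The step SD scales with sqrt(D_local/D) exactly as a
            # fixed-dt integrator's would, so accelerated zones do not
            # inflate the step count per unit time.
            Dloc = Dacc if inside else D
            sig = SIGMA_BD if breal < 0.3 else 2.0 * SIGMA_BD
            sig *= math.sqrt(Dloc / D)
            dt = sig * sig / (2.0 * Dloc)
            x += sig * np.random.standard_normal()
            y += sig * np.random.standard_normal()
            t += dt
            # resolve reflections (walls + gathered hard disks)
            for _ in range(4):
                moved = False
                if x < lo_w:
                    x = 2.0 * lo_w - x
                    moved = True
                elif x > hi_x:
                    x = 2.0 * hi_x - x
                    moved = True
                if y < lo_w:
                    y = 2.0 * lo_w - y
                    moved = True
                elif y > hi_x:
                    y = 2.0 * hi_x - y
                    moved = True
                for m in range(n_nb):
                    j = nb[m]
                    dx = x - sx[j]
                    dy = y - sy[j]
                    d = math.hypot(dx, dy)
                    if d < sr[j]:
                        if d < 1e-12:
                            x = sx[j] + sr[j]
                        else:
                            f = (2.0 * sr[j] - d) / d
                            x = sx[j] + dx * f
                            y = sy[j] + dy * f
                        moved = True
                if not moved:
                    break
            # inflated disks may straddle a wall; the mirror pair need not
            # converge there, so end every step strictly inside the walls
            if x < lo_w:
                x = lo_w
            elif x > hi_x:
                x = hi_x
            if y < lo_w:
                y = lo_w
            elif y > hi_x:
                y = hi_x
            if not (math.isfinite(x) and math.isfinite(y)):
                return kill_t[:n_kills], n_kills, 1
            if t >= t_cap:
                # another killer's event is now earlier: pause this burst
                # (checked after the step so every burst entry makes progress)
                break
            if (x - gx) ** 2 + (y - gy) ** 2 > regather2:
                gx = x
                gy = y
                n_nb = _grid_collect(gx, gy, sx, sy, sr, ptr, idx, ncell, cs,
                                     rq_gather, gather, nb)
                n_tl = 0
                for j in range(n_t):
                    if alive[j] and math.hypot(gx - tx[j], gy - ty[j]) - cap_r[j] < gather:
                        tloc[n_tl] = j
                        n_tl += 1
                n_bl = 0
                for j in range(n_b):
                    if math.hypot(gx - bx[j], gy - by[j]) < delta + gather:
                        bloc[n_bl] = j
                        n_bl += 1
        kx[i] = x
        ky[i] = y
        kt[i] = t
        if t >= t_max:
            done[i] = 1
    return kill_t[:n_kills], n_kills, 0


# =====================================================================
# BD oracle kernel (independent of the FPKMC path: no grid, no table)
# =====================================================================

@njit(cache=True)
def _bd_sample(seed, kx0, ky0, sx, sy, sr, tx, ty, cap_r, bx, by,
               delta, D, Dacc, L, rk, dt, t_max, stop_after,
               rec_times):  # pragma: no cover
    """Fixed-step Euler-Maruyama over the full scene.

    Returns (kill_times, n_kills, status, positions) with positions of all
    killers recorded at rec_times (shape (n_rec, n_k, 2)).
    """
    np.random.seed(seed)
    n_k = kx0.shape[0]
    n_t = tx.shape[0]
    n_s = sx.shape[0]
    n_b = bx.shape[0]
    n_rec = rec_times.shape[0]
    kx = kx0.copy()
    ky = ky0.copy()
    alive = np.ones(n_t, np.uint8)
    kill_t = np.empty(max(n_t, 1))
    n_kills = 0
    pos = np.empty((n_rec, n_k, 2))
    lo_w = rk
    hi_x = L - rk
    t = 0.0
    i_rec = 0

    # initial contacts count as immediate kills
    for i in range(n_k):
        while True:
            jb = -1
            db = 1e300
            for j in range(n_t):
                if alive[j]:
                    d = math.hypot(kx[i] - tx[j], ky[i] - ty[j])
                    if d <= cap_r[j] and d < db:
                        db = d
                        jb = j
            if jb < 0:
                break
            alive[jb] = 0
            kill_t[n_kills] = 0.0
            n_kills += 1

    while t < t_max and n_kills < stop_after:
        while i_rec < n_rec and rec_times[i_rec] <= t:
            for i in range(n_k):
                pos[i_rec, i, 0] = kx[i]
                pos[i_rec, i, 1] = ky[i]
            i_rec += 1
        for i in range(n_k):
            x = kx[i]
            y = ky[i]
            Dloc = D
            for j in range(n_b):
                if math.hypot(x - bx[j], y - by[j]) < delta:
                    Dloc = Dacc
                    break
            sig = math.sqrt(2.0 * Dloc * dt)
            x += sig * np.random.standard_normal()
            y += sig * np.random.standard_normal()
            for _ in range(4):
                moved = False
                if x < lo_w:
                    x = 2.0 * lo_w - x
                    moved = True
                elif x > hi_x:
                    x = 2.0 * hi_x - x
                    moved = True
                if y < lo_w:
                    y = 2.0 * lo_w - y
                    moved = True
                elif y > hi_x:
                    y = 2.0 * hi_x - y
                    moved = True
                for j in range(n_s):
                    dx = x - sx[j]
                    dy = y - sy[j]
                    d = math.hypot(dx, dy)
                    if d < sr[j]:
                        if d < 1e-12:
                            x = sx[j] + sr[j]
                        else:
                            f = (2.0 * sr[j] - d) / d
                            x = sx[j] + dx * f
                            y = sy[j] + dy * f
                        moved = True
                if not moved:
                    break
            if x < lo_w:
                x = lo_w
            elif x > hi_x:
                x = hi_x
            if y < lo_w:
                y = lo_w
            elif y > hi_x:
                y = hi_x
            if not (math.isfinite(x) and math.isfinite(y)):
                return kill_t[:n_kills], n_kills, 1, pos[:i_rec]
            kx[i] = x
            ky[i] = y
            # captures
            while True:
                jb = -1
                db = 1e300
                for j in range(n_t):
                    if alive[j]:
                        d = math.hypot(x - tx[j], y - ty[j]) - cap_r[j]
                        if d <= 0.0 and d < db:
                            db = d
                            jb = j
                if jb < 0:
                    break
                alive[jb] = 0
                kill_t[n_kills] = t + dt
                n_kills += 1
                if n_kills >= stop_after:
                    break
            if n_kills >= stop_after:
                break
        t += dt
    while i_rec < n_rec and rec_times[i_rec] <= t + 0.5 * dt:
        for i in range(n_k):
            pos[i_rec, i, 0] = kx[i]
            pos[i_rec, i, 1] = ky[i]
        i_rec += 1
    return kill_t[:n_kills], n_kills, 0, pos[:i_rec]


@njit(cache=True)
def _bd_disk_exit_kernel(seed, n, a, D, dt):  # pragma: no cover
    """BD hitting times of the circle r=a from the center (oracle)."""
    np.random.seed(seed)
    out = np.empty(n)
    sig = math.sqrt(2.0 * D * dt)
    a2 = a * a
    for i in range(n):
        x = 0.0
        y = 0.0
        t = 0.0
        while x * x + y * y < a2:
            x += sig * np.random.standard_normal()
            y += sig * np.random.standard_normal()
            t += dt
        out[i] = t
    return out


def bd_disk_exit(a, D, dt, n, rng):
    """Brute-force BD first-exit times from a disk of radius ``a`` (oracle)."""
    from .scene import _as_seed

    return _bd_disk_exit_kernel(_as_seed(rng), int(n), float(a), float(D), float(dt))


# =====================================================================
# Python wrappers
# =====================================================================

def _scene_arrays(scene: Scene):
    p = scene.params
    refl = scene.obstacles + scene.bystanders
    sx = np.array([d.x for d in refl], dtype=float)
    sy = np.array([d.y for d in refl], dtype=float)
    sr = np.array([d.r + p.r_k for d in refl], dtype=float)  # inflate by r_k
    tx = np.array([d.x for d in scene.targets], dtype=float)
    ty = np.array([d.y for d in scene.targets], dtype=float)
    cap_r = np.array([d.r + p.r_k for d in scene.targets], dtype=float)
    if p.D_acc == p.D:
        # zones with D_acc = D are inert: drop them from the zone lists
        # (the bystander disks above still exclude area)
        bx = np.empty(0)
        by = np.empty(0)
    else:
        bx = np.array([d.x for d in scene.bystanders], dtype=float)
        by = np.array([d.y for d in scene.bystanders], dtype=float)
    kx = np.array([d.x for d in scene.killers], dtype=float)
    ky = np.array([d.y for d in scene.killers], dtype=float)
    return kx, ky, sx, sy, sr, tx, ty, cap_r, bx, by


def _build_grid(sx, sy, L, cell_size=2.0):
    ncell = max(int(L / cell_size), 1)
    cs = L / ncell
    n = sx.size
    if n == 0:
        return np.zeros(ncell * ncell + 1, np.int64), np.empty(0, np.int64), ncell, cs
    cx = np.minimum((sx / cs).astype(np.int64), ncell - 1)
    cy = np.minimum((sy / cs).astype(np.int64), ncell - 1)
    flat = cx * ncell + cy
    order = np.argsort(flat, kind="stable")
    idx = order.astype(np.int64)
    counts = np.bincount(flat, minlength=ncell * ncell)
    ptr = np.zeros(ncell * ncell + 1, np.int64)
    np.cumsum(counts, out=ptr[1:])
    return ptr, idx, ncell, cs


def run_simulation(scene: Scene, rng, t_max=None, stop_after=None,
                   sample_id: int = 0) -> KillRecord:
    """Propagate all killers by FPKMC until ``t_max`` or until ``stop_after``
    targets have been removed (default: all of them).

    Deterministic given the seed; raises RuntimeError on non-finite
    coordinates or arena escape (should not occur for valid scenes).
    """
    from .scene import _as_seed

    p = scene.params
    t_max = p.horizon if t_max is None else float(t_max)
    stop_after = p.n_t0 if stop_after is None else int(stop_after)
    kx, ky, sx, sy, sr, tx, ty, cap_r, bx, by = _scene_arrays(scene)
    ptr, idx, ncell, cs = _build_grid(sx, sy, p.L)
    F, tau, a1sq, s_tail, tau_max = _fpt_table()
    kill_t, n_kills, status = _fpkmc_sample(
        _as_seed(rng), kx, ky, sx, sy, sr, ptr, idx, ncell, cs,
        tx, ty, cap_r, bx, by, p.delta, p.D, p.D_acc, p.L, p.r_k,
        t_max, stop_after, F, tau, a1sq, s_tail, tau_max,
    )
    if status != 0:
        raise RuntimeError(f"FPKMC sample aborted: {_STATUS_MSG[status]}")
    return KillRecord(sample_id, np.sort(kill_t[:n_kills]), p.n_t0, t_max)


def bd_run(scene: Scene, dt, rng, t_max=None, stop_after=None,
           record_times=None, sample_id: int = 0):
    """Fixed-timestep Brownian-dynamics run over the scene (the oracle).

    Step variance is ``2 * D_local * dt`` per axis with ``D_local`` read at
    the step's start position. Refuses ``dt`` so coarse that the RMS step
    exceeds one fifth of the smallest placed entity radius.

    Returns a :class:`KillRecord`, or ``(KillRecord, positions)`` when
    ``record_times`` is given (positions shape ``(n_rec, n_k, 2)``).
    """
    from .scene import _as_seed

    p = scene.params
    if not dt > 0:
        raise ValueError("dt must be > 0")
    radii = [d.r for d in scene.obstacles + scene.bystanders + scene.targets]
    if radii:
        d_max = max(p.D, p.D_acc) if scene.bystanders else p.D
        sig_max = math.sqrt(2.0 * d_max * dt)
        if sig_max > min(radii) / 5.0:
            raise ValueError(
                f"dt={dt} too coarse: RMS step {sig_max:.4f} exceeds "
                f"min radius/5 = {min(radii) / 5.0:.4f}"
            )
    t_max = p.horizon if t_max is None else float(t_max)
    stop_after = p.n_t0 if stop_after is None else int(stop_after)
    if stop_after == 0:
        stop_after = max(p.n_t0, 1)
    kx, ky, sx, sy, sr, tx, ty, cap_r, bx, by = _scene_arrays(scene)
    rec = (np.empty(0) if record_times is None
           else np.asarray(record_times, dtype=float))
    kill_t, n_kills, status, pos = _bd_sample(
        _as_seed(rng), kx, ky, sx, sy, sr, tx, ty, cap_r, bx, by,
        p.delta, p.D, p.D_acc, p.L, p.r_k, float(dt), t_max,
        stop_after if p.n_t0 > 0 else 1, rec,
    )
    if status != 0:
        raise RuntimeError(f"BD sample aborted: {_STATUS_MSG[status]}")
    record = KillRecord(sample_id, np.sort(kill_t[:n_kills]), p.n_t0, t_max)
    if record_times is None:
        return record
    return record, pos


def sample_seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-sample (placement, dynamics) substream seeds from a master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    out = np.empty((n, 2), dtype=np.uint32)
    for i, child in enumerate(ss.spawn(n)):
        out[i] = child.generate_state(2)
    return out


def simulate_ensemble(params: ModelParams, n_samples=None, seed=None,
                      engine: str = "fpkmc", stop_at_half: bool = False,
                      dt=None, t_max=None):
    """Run an ensemble: each sample redraws the random placement and the
    trajectory noise from an independent substream of the master seed.

    ``stop_at_half`` ends each sample at its ceil(n_t0/2)-th kill (enough
    for the per-sample half-time estimator and much cheaper).
    """
    params.validate()
    n_samples = params.n_samples if n_samples is None else int(n_samples)
    seed = params.seed if seed is None else int(seed)
    stop_after = (params.n_t0 + 1) // 2 if stop_at_half else None
    seeds = sample_seeds(seed, n_samples)
    records = []
    for s in range(n_samples):
        scene = place_scene(params, np.random.default_rng(int(seeds[s, 0])))
        dyn_rng = np.random.default_rng(int(seeds[s, 1]))
        if engine == "fpkmc":
            rec = run_simulation(scene, dyn_rng, t_max=t_max,
                                 stop_after=stop_after, sample_id=s)
        elif engine == "bd":
            if dt is None:
                raise ValueError("engine='bd' requires dt")
            rec = bd_run(scene, dt, dyn_rng, t_max=t_max,
                         stop_after=stop_after, sample_id=s)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        records.append(rec)
    return records
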