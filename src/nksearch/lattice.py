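"""Discrete lattice random-walk variants of the search model.

Two continuous-time (Gillespie) models on a W x H square lattice with
4-neighbour hopping at baseline rate ``q`` per allowed direction:

* **Model 1** — bystanders occupy lattice *sites*. A killer whose current
  site has a bystander on any of its 4 neighbouring sites hops with rate
  ``q * multiplier`` in every allowed direction. Bystanders (and targets)
  may optionally move themselves; bystander sites exclude killers when
  ``bystander_exclusion`` is on.
* **Model 2** — bystanders are immobile and sit *between* the lattice
  sites, on plaquette centers. Every edge bordering an occupied plaquette
  is boosted: a killer crossing it hops with rate ``q * multiplier``.

A killer moves onto a target's site to capture it (targets never block);
kill times are in units of ``1/q``. The exact mean hitting time of the
single-killer chain is available from :func:`exact_hitting_time` via a
sparse linear solve over the absorbing Markov chain, and serves as the
oracle for the stochastic runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .fpkmc import KillRecord

__all__ = ["LatticeConfig", "run_lattice", "exact_hitting_time"]


@dataclass
class LatticeConfig:
    width: int = 10
    height: int = 10
    n_killers: int = 1
    n_targets: int = 1
    n_bystanders: int = 0
    q: float = 1.0                 # baseline hop rate per allowed direction
    multiplier: float = 4.0        # bystander acceleration factor (= D_acc/D)
    model: str = "model1"          # "model1" (site bystanders) | "model2" (edges)
    bystander_exclusion: bool = True   # model1: killers cannot enter bystander sites
    bystanders_move: bool = False      # model1 only
    targets_move: bool = False         # model1 only
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.model not in ("model1", "model2"):
            raise ValueError("model must be 'model1' or 'model2'")
        if not self.q > 0:
            raise ValueError("q must be > 0")
        if not self.multiplier >= 1:
            raise ValueError("multiplier must be >= 1")
        for name in ("n_killers", "n_targets", "n_bystanders"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_sites = self.width * self.height
        occupied = self.n_targets + (self.n_bystanders if self.model == "model1" else 0)
        if occupied + min(self.n_killers, 1) > n_sites:
            raise ValueError("more occupied sites than lattice sites")
        if self.model == "model2":
            n_plaq = max(self.width - 1, 0) * max(self.height - 1, 0)
            if self.n_bystanders > n_plaq:
                raise ValueError("more bystanders than plaquettes")

    def with_(self, **kw) -> "LatticeConfig":
        return replace(self, **kw)


_DIRS = ((1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass
class _State:
    cfg: LatticeConfig
    killers: list
    targets: set
    bystanders: set          # sites (model1) or plaquettes (model2)
    boost_edges: set = field(default_factory=set)  # model2: frozenset({a, b})

    @classmethod
    def from_layout(cls, cfg: LatticeConfig, layout: dict,
                    rng: np.random.Generator) -> "_State":
        """Fixed target/bystander sites; killers drawn uniformly over the
        free sites when not given explicitly."""
        targets = {tuple(s) for s in layout["targets"]}
        bystanders = {tuple(s) for s in layout.get("bystanders", ())}
        if "killers" in layout:
            killers = [tuple(s) for s in layout["killers"]]
        else:
            sites = [(x, y) for x in range(cfg.width) for y in range(cfg.height)]
            blocked = bystanders if cfg.model == "model1" else set()
            free = [s for s in sites if s not in targets and s not in blocked]
            kp = rng.choice(len(free), size=cfg.n_killers, replace=False)
            killers = [free[i] for i in kp]
        st = cls(cfg, killers, set(targets), set(bystanders))
        if cfg.model == "model2":
            st._index_boost_edges()
        return st

    def _index_boost_edges(self):
        for (px, py) in self.bystanders:
            self.boost_edges.add(frozenset({(px, py), (px + 1, py)}))
            self.boost_edges.add(frozenset({(px, py + 1), (px + 1, py + 1)}))
            self.boost_edges.add(frozenset({(px, py), (px, py + 1)}))
            self.boost_edges.add(frozenset({(px + 1, py), (px + 1, py + 1)}))

    @classmethod
    def initial(cls, cfg: LatticeConfig, rng: np.random.Generator) -> "_State":
        sites = [(x, y) for x in range(cfg.width) for y in range(cfg.height)]
        if cfg.model == "model1":
            picked = rng.choice(len(sites),
                                size=cfg.n_targets + cfg.n_bystanders,
                                replace=False)
            targets = {sites[i] for i in picked[: cfg.n_targets]}
            bystanders = {sites[i] for i in picked[cfg.n_targets:]}
        else:
            picked = rng.choice(len(sites), size=cfg.n_targets, replace=False)
            targets = {sites[i] for i in picked}
            plaqs = [(x, y) for x in range(cfg.width - 1)
                     for y in range(cfg.height - 1)]
            bp = rng.choice(len(plaqs), size=cfg.n_bystanders, replace=False)
            bystanders = {plaqs[i] for i in bp}
        free = [s for s in sites if s not in targets and s not in bystanders] \
            if cfg.model == "model1" else [s for s in sites if s not in targets]
        if cfg.n_killers > len(free):
            raise ValueError("not enough free sites for killers")
        kp = rng.choice(len(free), size=cfg.n_killers, replace=False)
        killers = [free[i] for i in kp]
        st = cls(cfg, killers, targets, bystanders)
        if cfg.model == "model2":
            for (px, py) in bystanders:
                # the 4 edges bordering plaquette (px, py)
                st.boost_edges.add(frozenset({(px, py), (px + 1, py)}))
                st.boost_edges.add(frozenset({(px, py + 1), (px + 1, py + 1)}))
                st.boost_edges.add(frozenset({(px, py), (px, py + 1)}))
                st.boost_edges.add(frozenset({(px + 1, py), (px + 1, py + 1)}))
        return st

    def in_bounds(self, s) -> bool:
        return 0 <= s[0] < self.cfg.width and 0 <= s[1] < self.cfg.height

    def killer_boost(self, site) -> float:
        """Model 1: multiplier if any 4-neighbour site holds a bystander."""
        for dx, dy in _DIRS:
            if (site[0] + dx, site[1] + dy) in self.bystanders:
                return self.cfg.multiplier
        return 1.0

    def edge_rate(self, a, b) -> float:
        """Model 2: per-edge rate factor."""
        if frozenset({a, b}) in self.boost_edges:
            return self.cfg.multiplier
        return 1.0

    def killer_moves(self, site):
        """(dest, rate) pairs for a killer at ``site``."""
        cfg = self.cfg
        out = []
        base = cfg.q * (self.killer_boost(site) if cfg.model == "model1" else 1.0)
        for dx, dy in _DIRS:
            dest = (site[0] + dx, site[1] + dy)
            if not self.in_bounds(dest):
                continue
            if cfg.model == "model1" and cfg.bystander_exclusion \
                    and dest in self.bystanders:
                continue
            rate = base if cfg.model == "model1" \
                else cfg.q * self.edge_rate(site, dest)
            out.append((dest, rate))
        return out

    def passive_moves(self, site, species: str):
        """Moves of a mobile bystander/target (model 1): rate q to free sites."""
        out = []
        for dx, dy in _DIRS:
            dest = (site[0] + dx, site[1] + dy)
            if not self.in_bounds(dest):
                continue
            if dest in self.bystanders or dest in self.targets:
                continue
            out.append((dest, self.cfg.q))
        return out


def run_lattice(config: LatticeConfig, rng, step_max: int = 10_000_000,
                t_max: float = math.inf, stop_after=None,
                sample_id: int = 0, layout: dict | None = None,
                occupancy=None) -> KillRecord:
    """Gillespie simulation of one lattice sample; returns kill times (1/q units).

    The sample ends when ``stop_after`` targets are caught (default: all),
    or at ``step_max`` events / ``t_max`` time / a fully jammed lattice
    (censored record).

    ``layout`` fixes target/bystander (and optionally killer) sites instead
    of drawing them; ``occupancy`` (a W x H float array) accumulates the
    first killer's dwell time per site for stationarity diagnostics.
    """
    config.validate()
    if config.n_killers < 1 or config.n_targets < 1:
        raise ValueError("need at least one killer and one target")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    st = (_State.from_layout(config, layout, rng) if layout is not None
          else _State.initial(config, rng))
    stop_after = config.n_targets if stop_after is None else int(stop_after)
    kills = []
    t = 0.0
    for _ in range(step_max):
        if len(kills) >= stop_after or t >= t_max:
            break
        movers = []  # (kind, index-or-site, moves)
        total = 0.0
        for i, site in enumerate(st.killers):
            mv = st.killer_moves(site)
            if mv:
                movers.append(("killer", i, mv))
                total += sum(r for _, r in mv)
        if config.model == "model1" and config.bystanders_move:
            for site in list(st.bystanders):
                mv = st.passive_moves(site, "bystander")
                if mv:
                    movers.append(("bystander", site, mv))
                    total += sum(r for _, r in mv)
        if config.model == "model1" and config.targets_move:
            for site in list(st.targets):
                mv = st.passive_moves(site, "target")
                if mv:
                    movers.append(("target", site, mv))
                    total += sum(r for _, r in mv)
        if total <= 0.0:
            break  # jammed: censored
        wait = rng.exponential(1.0 / total)
        if occupancy is not None:
            kx, ky = st.killers[0]
            occupancy[kx, ky] += min(wait, t_max - t)
        t += wait
        if t >= t_max:
            t = t_max
            break
        pick = rng.random() * total
        acc = 0.0
        chosen = None
        for kind, who, mv in movers:
            for dest, rate in mv:
                acc += rate
                if pick < acc:
                    chosen = (kind, who, dest)
                    break
            if chosen:
                break
        kind, who, dest = chosen
        if kind == "killer":
            st.killers[who] = dest
            if dest in st.targets:
                st.targets.discard(dest)
                kills.append(t)
        elif kind == "bystander":
            st.bystanders.discard(who)
            st.bystanders.add(dest)
        else:
            st.targets.discard(who)
            st.targets.add(dest)
    return KillRecord(sample_id, np.array(kills), config.n_targets, t_max)


def lattice_ensemble(config: LatticeConfig, n_samples: int, seed=None,
                     t_max: float = math.inf, stop_at_half: bool = False):
    """Independent lattice samples from per-sample substreams."""
    seed = config.seed if seed is None else int(seed)
    ss = np.random.SeedSequence(seed)
    stop_after = (config.n_targets + 1) // 2 if stop_at_half else None
    return [
        run_lattice(config, np.random.default_rng(child), t_max=t_max,
                    stop_after=stop_after, sample_id=i)
        for i, child in enumerate(ss.spawn(n_samples))
    ]


def exact_hitting_time(config: LatticeConfig, killer_start=None,
                       target_sites=None, bystander_sites=None,
                       max_states: int = 100_000) -> float:
    """Exact expected capture time of a single killer (absorbing-chain solve).

    Builds the generator matrix of the killer's walk with the given (or
    randomly drawn) immobile target/bystander layout, makes target sites
    absorbing, and solves ``-Q m = 1`` over the transient states. Returns
    the expected absorption time from ``killer_start`` (or the mean over a
    uniform start on the transient states if None).
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    config.validate()
    if config.n_killers != 1:
        raise ValueError("exact oracle requires exactly one killer")
    if config.bystanders_move or config.targets_move:
        raise ValueError("exact oracle requires immobile bystanders/targets")
    n_sites = config.width * config.height
    if n_sites > max_states:
        raise ValueError(f"state space {n_sites} exceeds cap {max_states}")

    if target_sites is None or bystander_sites is None:
        rng = np.random.default_rng(config.seed)
        st = _State.initial(config, rng)
        target_sites = sorted(st.targets)
        bystander_sites = sorted(st.bystanders)
        boost_edges = st.boost_edges
    else:
        st = _State(config, [], set(target_sites), set(bystander_sites))
        if config.model == "model2":
            for (px, py) in st.bystanders:
                st.boost_edges.add(frozenset({(px, py), (px + 1, py)}))
                st.boost_edges.add(frozenset({(px, py + 1), (px + 1, py + 1)}))
                st.boost_edges.add(frozenset({(px, py), (px, py + 1)}))
                st.boost_edges.add(frozenset({(px + 1, py), (px + 1, py + 1)}))
        boost_edges = st.boost_edges
    st.targets = set(target_sites)
    st.bystanders = set(bystander_sites)
    st.boost_edges = boost_edges

    sites = [(x, y) for x in range(config.width) for y in range(config.height)]
    blocked = (st.bystanders if config.model == "model1"
               and config.bystander_exclusion else set())
    transient = [s for s in sites if s not in st.targets and s not in blocked]
    index = {s: i for i, s in enumerate(transient)}
    n = len(transient)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for s in transient:
        i = index[s]
        for dest, rate in st.killer_moves(s):
            diag[i] -= rate
            if dest in index:  # else absorbing (target)
                rows.append(i)
                cols.append(index[dest])
                vals.append(rate)
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Q = Q + sp.diags(diag)
    m = spla.spsolve(Q.tocsc(), -np.ones(n))
    if killer_start is not None:
        if killer_start not in index:
            raise ValueError("killer_start is not a transient state")
        return float(m[index[killer_start]])
    return float(np.mean(m))
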