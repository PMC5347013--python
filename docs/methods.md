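# Methods

## The model

`nksearch` simulates natural-killer (NK) cells searching for immobile tumor
targets in a crowded two-dimensional environment, and asks how non-target
*bystander* cells change the search time. The continuous model is a hard-disk
Brownian search: `n_k` killer disks diffuse with diffusivity `D` in an
`L x L` arena containing `n_t0` absorbing target disks (removed on contact),
`n_o` reflecting obstacle disks (inactive NK cells: pure area exclusion),
and `n_b` reflecting bystander disks. Each bystander additionally carries a
circular *acceleration zone* of radius `delta > R` centred on it, inside
which killer diffusivity is raised to `D_acc > D` — a minimal description of
the experimentally observed speed-up of NK cells near bystanders. The
killing-efficiency readout is the half-time `t_1/2`: the average time at
which half the initial targets have been removed.

Units are dimensionless: one NK-cell diameter is the length unit (so
cell-sized disks have radius 0.5) and the time unit is fixed by `D = 1`.
Defaults are `L = 50`, `R = r_k = 0.5`, `D_acc = 4`, `delta = 3`.

Model assumptions, made explicit:

* Killers do not interact with each other (they pass through); crowding is
  modelled only by the explicit obstacle disks. This keeps scaling in `n_k`
  clean and matches the model sketch in which only obstacles exclude area.
* Arena walls are reflecting. Entities are placed without wrap-around, so
  periodic boundaries would be inconsistent with the placement rule; for
  `L = 50` and the densities used here the boundary choice is a small
  perturbation.
* Acceleration is triggered by the killer's *center* entering a zone; zones
  overlap freely and do not stack (the field takes exactly two values,
  `D` and `D_acc`).
* Targets do not move, are removed instantly on first contact, and killers
  continue searching immediately (no handling time, no exhaustion).

## Propagation: first-passage jumps with near-surface bursts

The engine is an event-driven first-passage scheme. Around a killer we
construct a protective disk that touches no obstacle/bystander/target
surface (all inflated by the killer radius, so the killer is treated as a
point), no wall, and no boundary of the *union* of acceleration zones —
hence the diffusivity inside it is one constant. The first-exit time from
the center of a disk of radius `a` has the Fourier–Bessel survival function
over the zeros of J0; we sample it exactly by inverting a pre-tabulated CDF
of the rescaled time `tau = Dt/a^2` (4096-point log grid built from 2000
Bessel zeros, exact single-exponential tail beyond it; the tabulated mean
reproduces the closed form `a^2/(4D)` to 1.4e-6 relative). The exit point
is uniform on the circle. Deep inside overlapping zones only the largest
covering-zone slack constrains the domain, which is what keeps dense
bystander fields affordable.

Absorbing contact can never be reached by shrinking protective domains
alone, so when the protective radius would fall below `h_fp = 0.08` the
killer switches to an Euler–Maruyama *burst* with per-axis step SD
`sigma = 0.04` (scaled by `sqrt(D_local/D)`, exactly as a fixed-dt
integrator's step would scale; doubled when the only nearby feature is a
zone boundary, which neither absorbs nor reflects). Bursts resolve
captures (nearest target first), hard-disk and wall reflections (mirror
rule), and zone crossings (diffusivity read at the step's start), and end
once the killer is clear of everything by `h_exit = 0.2`. The burst step
SD is the only discretisation scale of the scheme; it biases the effective
capture radius by a few per cent of a cell radius, identically across a
parameter sweep, which is why the half-time *trends* are insensitive to it
and why the independent fixed-dt oracle (below) agrees with the engine
within Monte-Carlo error.

With several killers the engine processes the earliest event first; a
burst pauses as soon as its clock passes the next scheduled event of any
other killer, so kills commit in global time order (races for the same
target are resolved correctly up to one burst step).

The independent oracle `bd_run` is a plain fixed-timestep Euler–Maruyama
integrator over the identical geometry — no grids, no exit-time table —
with step variance `2 D_local dt` per axis and the same capture/reflection
rules. It refuses timesteps whose RMS step exceeds one fifth of the
smallest entity radius.

## Ensembles, statistics, censoring

An ensemble redraws the random placement *and* the trajectory noise each
sample from independent substreams of one master seed (`SeedSequence`
spawning), so ensembles are reproducible byte-for-byte and trivially
parallelisable. Two half-time estimators are provided, because "the average
time at which half the targets were found" can be read per-sample or on the
ensemble curve:

* `per_sample` (default): the time of the `ceil(n_t0/2)`-th kill in each
  sample, averaged over samples that reach it. Samples that do not reach it
  within `t_max` are excluded from the mean and reported as censored.
* `curve`: the interpolated time at which the ensemble mean `<N_t(t)>`
  crosses `n_t0/2`, with a bootstrap standard error.

The two agree within Monte-Carlo error on every configuration we run; a
regression test enforces this. The default horizon is
`t_max = 10 L^2 / (4D)`, ten times the single-searcher arena-crossing
estimate; censoring is negligible at the densities studied.

## Lattice variants

Two discrete random-walk models probe whether the continuous conclusion is
an artifact of its geometry. Both are continuous-time (Gillespie) walks on
a W x H square lattice with 4-neighbour hops at baseline rate `q`; a killer
moves *onto* a target site to capture it (targets never block). In
**Model 1** bystanders occupy lattice sites (optionally mobile, optionally
excluding killers from their sites — both exposed as configuration); a
killer with a bystander on any neighbouring site hops at `q x multiplier`
in all allowed directions. In **Model 2** bystanders sit between the sites,
on plaquette centers, and boost the four surrounding edges: crossing a
boosted edge proceeds at `q x multiplier`. The published description does
not fix the functional form of the neighbour-dependent rates, so we
implement this minimal one-multiplier family and default the multiplier to
`D_acc/D = 4` by analogy with the continuous model.

The exact oracle builds the killer's generator matrix with absorbing target
sites and solves `-Q m = 1` (sparse LU) for the expected hitting time from
any start, or the uniform average over transient states — the same
distribution the stochastic runner uses when the start is not fixed.
Because rates enter linearly, multiplying every rate by `m` rescales the
exact hitting time by exactly `1/m`; this identity is tested to machine
precision and anchors the meaning of "rate".

## Track metrics

The migration analyses operate on timestamped positions in physical units
(seconds, micrometers). Velocity is total path length over total duration
(reported in um/min) — a deliberate choice, robust to the irregular
16.8–38.2 s frame intervals of the source acquisitions, since the original
analysis does not state its formula. Persistence is net displacement over
path length; it is undefined for immobile tracks, which are discarded
beforehand by a net-displacement filter whose default threshold is one cell
diameter (10 um) — the original immobility criterion is likewise unstated.
Encounters with bystanders open when the cell's distance to a bystander
surface drops below 10 um and are *attracted* if geometric contact
(center-to-center distance below the radius sum, killer radius defaulting
to 5 um) occurs before the cell re-exceeds 10 um, else *passing by*;
approach/touch/leave phase durations are measured with all threshold
crossings linearly interpolated between frames, which de-biases durations
at coarse frame rates. Tracks may be 3D; all formulas treat z symmetrically.

## Synthetic tracks

The generator emits correlated random walks with independent control of
speed and directional persistence: heading noise is wrapped-Gaussian per
frame (`turn_sd`), step length is speed x frame interval, frame intervals
are drawn uniformly from 16.8–38.2 s to emulate the acquisition cadence,
and a configurable fraction of tracks is immobile. It reproduces the
*sampling* properties of the experimental tables — irregular timing, track
lengths, immobile contaminants — but none of NK biophysics: no
heterogeneity between cells, no speed–turn coupling, no interactions. A
passing metrics test therefore certifies the analysis code, not any
biological claim. Scripted piecewise-linear fixtures place their knots so
that linear interpolation recovers the scripted approach/touch/leave
durations exactly, giving the encounter segmentation a zero-tolerance
oracle.

## Problem sizes and numerical choices

Test and acceptance ensembles are scaled down from the 40,000-sample
production default: monotonicity sweeps use 1,000 samples per point
(standard errors ~0.5 time units, far below the sweep effects of 4–20
units), engine cross-checks 2,000 samples per engine, lattice sweeps
1,500 runs per point, and the acceptance script 300 per point. The BD
oracle uses `dt = 1e-3` in cross-checks (`dt = 0.02` for free diffusion,
where Euler is exact). Degenerate inputs are handled explicitly: contacts
existing at t=0 are immediate kills at t=0, a zero protective radius
yields a zero exit time, jammed lattices terminate as censored records,
and configurations with disk area fraction above 0.5 or stalled rejection
sampling are refused rather than silently mis-placed.

## Known limitations

* The capture bias of the burst/oracle discretisation (~2–4% of a cell
  radius) shifts absolute half-times slightly; trends and cross-engine
  comparisons are unaffected at the ensemble sizes used.
* Only 2D continuous dynamics are implemented; 3D support exists solely in
  the track metrics.
* The lattice rate family is the minimal one-multiplier reading of
  "hopping rates depend on neighbouring cells"; richer dependencies fit
  the exposed configuration surface but are not explored.
* Killer–killer exclusion and periodic boundaries are documented
  alternatives, not options; both were judged second-order at the studied
  densities.
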