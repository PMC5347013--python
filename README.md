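# nksearch

Stochastic models of natural-killer (NK) cell search, built to study a
counter-intuitive effect: non-target *bystander* cells speed up NK killing
rather than getting in the way. Experimentally, NK cells migrate faster and
more persistently near bystanders; `nksearch` implements the corresponding
physical picture — local acceleration of a random search — and the analysis
tools around it:

* **Continuous model** (`nksearch.scene`, `nksearch.fpkmc`): `N_k` killer
  disks diffuse with diffusivity `D` in an `L x L` arena among `N_t(0)`
  absorbing targets, `N_o` reflecting obstacles and `N_b` bystanders, each
  bystander raising killer diffusivity to `D_acc > D` within a zone of
  radius `Δ > R` around it. Propagation is event-driven first-passage
  kinetic Monte Carlo (FPKMC / GFRD-style): exact first-exit-time sampling
  from protective disks, with fine-step Brownian bursts near surfaces. An
  independent fixed-timestep Brownian-dynamics integrator serves as oracle.
* **Lattice models** (`nksearch.lattice`): two discrete Gillespie
  random-walk variants with bystander-dependent hopping rates (bystanders
  on sites, or on plaquettes boosting the surrounding edges), plus an exact
  absorbing-Markov-chain solver for mean hitting times.
* **Ensemble statistics** (`nksearch.stats`): survival curves `<N_t(t)>`
  and the half-time `t_1/2` — the average time at which half the targets
  have been found and removed — via per-sample and curve-crossing
  estimators.
* **Migration metrics** (`nksearch.tracks`): velocity, persistence
  (net displacement / path length), step sizes, immobile-track filtering,
  and attracted / passing-by encounter classification with
  approach–touch–leave phase durations, for experimental or synthetic
  track tables in seconds/μm.
* **Synthetic tracks** (`nksearch.synth`): correlated-random-walk generator
  with known ground truth, emulating irregular 16.8–38.2 s frame intervals.

Model units are dimensionless: length in NK-cell diameters (`R = 0.5`),
time fixed by `D = 1`; defaults `L = 50`, `D_acc = 4`, `Δ = 3`.
See `docs/methods.md` for the numerical scheme and its assumptions.

## Worked example

Half-time of target killing with and without accelerating bystanders, at
20 killers, 20 targets and 200 obstacles:

```python
from nksearch import ModelParams, half_time, simulate_ensemble

params = ModelParams(n_k=20, n_t0=20, n_o=200, D_acc=4.0, delta=3.0)
for n_b in (0, 50):
    records = simulate_ensemble(params.with_(n_b=n_b),
                                n_samples=200, seed=7, stop_at_half=True)
    est = half_time(records)
    print(f"N_b={n_b:3d}: t_1/2 = {est.mean:5.2f} +/- {est.se:.2f} "
          f"({est.n_used} samples, {est.n_censored} censored)")
```

prints

```
N_b=  0: t_1/2 = 28.87 +/- 0.99 (200 samples, 0 censored)
N_b= 50: t_1/2 = 21.90 +/- 0.85 (200 samples, 0 censored)
```

Fifty bystanders cut the mean search half-time by about a quarter even
though they occupy additional area: the local acceleration outweighs the
extra crowding. Sweeping `n_b`, `delta` or `D_acc` (see the `sweep` CLI
subcommand) shows `t_1/2` falling monotonically in all three.

A command-line interface mirrors the library:

```sh
nksearch simulate --config examples/fig_config.yaml --samples 2000 --seed 7
nksearch lattice  --config examples/lattice_sweep.yaml --model 2
nksearch sweep    --config examples/lattice_sweep.yaml
nksearch synth    --n-tracks 100 --speed 4 --out tracks.csv
nksearch analyze-tracks --tracks tracks.csv --out metrics.csv
```

Every run writes a `manifest.json` (config hash, seed, package version)
next to its outputs, and identical config + seed reproduces outputs
byte-for-byte.

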