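"""FPKMC engine behaviour: captures, determinism, physics sanity."""

import numpy as np
import pytest

from nksearch import (
    Disk,
    KillRecord,
    ModelParams,
    Scene,
    bd_run,
    half_time,
    place_scene,
    run_simulation,
    simulate_ensemble,
)


def _two_disk_scene(killer_xy, target_xy, L=10.0, extra=None):
    p = ModelParams(n_k=1, n_t0=1, n_o=len(extra or []), L=L)
    return Scene(
        params=p,
        killers=[Disk(*killer_xy, 0.5)],
        targets=[Disk(*target_xy, 0.5)],
        obstacles=list(extra or []),
    )


class TestCaptures:
    def test_contact_at_t0_is_immediate_kill(self, warm_kernels):
        scene = _two_disk_scene((5.0, 5.0), (5.9, 5.0))
        rec = run_simulation(scene, 1)
        assert rec.n_kills == 1 and rec.kill_times[0] == 0.0
        assert rec.half_kill_time == 0.0 and not rec.censored

    def test_kills_never_exceed_targets_and_are_sorted(self, warm_kernels):
        p = ModelParams(n_k=3, n_t0=6, n_o=10, L=15.0)
        for seed in range(4):
            rec = run_simulation(place_scene(p, seed), seed + 100)
            assert rec.n_kills <= p.n_t0
            assert np.all(np.diff(rec.kill_times) >= 0)

    def test_remaining_plus_kills_conserved(self, warm_kernels):
        p = ModelParams(n_k=3, n_t0=6, n_o=10, L=15.0)
        rec = run_simulation(place_scene(p, 7), 8)
        grid = np.linspace(0, rec.t_max, 50)
        remaining = rec.remaining_at(grid)
        killed = np.array([(rec.kill_times <= t).sum() for t in grid])
        assert np.all(remaining + killed == p.n_t0)


class TestDeterminism:
    def test_same_seed_same_kill_times(self, warm_kernels):
        p = ModelParams(n_k=4, n_t0=4, n_o=30, n_b=6, L=20.0,
                        D_acc=4.0, delta=2.0)
        scene = place_scene(p, 5)
        a = run_simulation(scene, 77)
        b = run_simulation(scene, 77)
        np.testing.assert_array_equal(a.kill_times, b.kill_times)

    def test_ensemble_substreams_reproducible(self, warm_kernels):
        p = ModelParams(n_k=2, n_t0=2, n_o=10, L=15.0)
        r1 = simulate_ensemble(p, n_samples=6, seed=3)
        r2 = simulate_ensemble(p, n_samples=6, seed=3)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.kill_times, b.kill_times)
        r3 = simulate_ensemble(p, n_samples=6, seed=4)
        assert any(a.kill_times.size != b.kill_times.size
                   or not np.array_equal(a.kill_times, b.kill_times)
                   for a, b in zip(r1, r3))


class TestPhysics:
    def test_obstacles_slow_the_killing(self, warm_kernels):
        """More excluded area -> longer mean half-kill time."""
        base = ModelParams(n_k=5, n_t0=5, L=20.0, t_max=2000.0)
        free = half_time(simulate_ensemble(base, n_samples=150, seed=1,
                                           stop_at_half=True))
        crowded = half_time(
            simulate_ensemble(base.with_(n_o=80), n_samples=150, seed=1,
                              stop_at_half=True)
        )
        assert crowded.mean > free.mean

    def test_diffusivity_rescaling_rescales_times_exactly(self, warm_kernels):
        """Multiplying D and D_acc by c divides every kill time by exactly c
        on a shared seed (c = 2 is exact in binary floating point)."""
        p1 = ModelParams(n_k=2, n_t0=3, n_o=20, n_b=4, L=15.0,
                         D=1.0, D_acc=4.0, delta=2.0)
        scene1 = place_scene(p1, 9)
        p2 = p1.with_(D=2.0, D_acc=8.0)
        scene2 = Scene(params=p2, killers=scene1.killers,
                       targets=scene1.targets, obstacles=scene1.obstacles,
                       bystanders=scene1.bystanders)
        a = run_simulation(scene1, 55, t_max=4000.0)
        b = run_simulation(scene2, 55, t_max=2000.0)
        assert a.n_kills == b.n_kills and a.n_kills > 0
        np.testing.assert_array_equal(a.kill_times, 2.0 * b.kill_times)

    def test_fpkmc_agrees_with_bd_oracle_small_instance(self, warm_kernels):
        """Mean first-capture time: event-driven engine vs brute-force
        Euler-Maruyama on the same small random scenes."""
        p = ModelParams(n_k=1, n_t0=1, n_o=5, L=10.0, t_max=2000.0)
        n = 400
        t_fp, t_bd = [], []
        for s in range(n):
            scene = place_scene(p, s)
            t_fp.append(run_simulation(scene, 10_000 + s).kill_times)
            t_bd.append(bd_run(scene, 2e-3, 20_000 + s).kill_times)
        t_fp = np.concatenate(t_fp)
        t_bd = np.concatenate(t_bd)
        assert t_fp.size > 0.9 * n and t_bd.size > 0.9 * n
        se = np.hypot(t_fp.std() / np.sqrt(t_fp.size),
                      t_bd.std() / np.sqrt(t_bd.size))
        assert abs(t_fp.mean() - t_bd.mean()) < 3 * se


class TestBDOracle:
    def test_free_diffusion_law(self, warm_kernels):
        """MSD(t) = 4Dt for unobstructed walkers far from the walls."""
        p = ModelParams(n_k=2025, n_t0=0, L=400.0, D=1.0)
        gx, gy = np.meshgrid(*(np.linspace(155.0, 245.0, 45),) * 2)
        scene = Scene(params=p,
                      killers=[Disk(x, y, 0.5)
                               for x, y in zip(gx.ravel(), gy.ravel())])
        rec_times = np.array([5.0, 10.0, 20.0])
        _, pos = bd_run(scene, 0.02, 3, t_max=20.05, record_times=rec_times)
        start = np.array([[d.x, d.y] for d in scene.killers])
        for k, t in enumerate(rec_times):
            msd = np.mean(np.sum((pos[k] - start) ** 2, axis=1))
            assert 0.95 < msd / (4.0 * t) < 1.05

    def test_frozen_dynamics_at_negligible_diffusivity(self, warm_kernels):
        p = ModelParams(n_k=3, n_t0=2, n_o=5, L=15.0, D=1e-300, D_acc=1e-300)
        scene = place_scene(p, 4)
        rec, pos = bd_run(scene, 0.01, 5, t_max=1.0,
                          record_times=np.array([0.9]))
        start = np.array([[d.x, d.y] for d in scene.killers])
        np.testing.assert_allclose(pos[0], start, atol=1e-140)
        assert rec.n_kills == 0

    def test_crowding_reduces_effective_diffusivity(self, warm_kernels):
        """Ensemble MSD at fixed t decreases as obstacle density rises."""
        msds = []
        for n_o in (0, 72, 144):
            p = ModelParams(n_k=150, n_t0=0, n_o=n_o, L=30.0)
            scene = place_scene(p, 6)
            _, pos = bd_run(scene, 2e-3, 7, t_max=10.01,
                            record_times=np.array([10.0]))
            start = np.array([[d.x, d.y] for d in scene.killers])
            msds.append(float(np.mean(np.sum((pos[0] - start) ** 2, axis=1))))
        assert msds[0] > msds[1] > msds[2]

    def test_too_coarse_dt_refused(self, warm_kernels):
        p = ModelParams(n_k=1, n_t0=1, n_o=3, L=10.0)
        scene = place_scene(p, 1)
        with pytest.raises(ValueError, match="too coarse"):
            bd_run(scene, 0.05, 1)

    def test_obstacle_removal_speeds_capture_on_average(self, warm_kernels):
        """Paired-seed sanity check: the mean capture time without the
        obstacles is no larger than with them."""
        with_obs, without = [], []
        for s in range(60):
            p = ModelParams(n_k=1, n_t0=1, n_o=40, L=12.0, t_max=2000.0)
            scene = place_scene(p, s)
            empty = Scene(params=p.with_(n_o=0), killers=scene.killers,
                          targets=scene.targets)
            a = bd_run(scene, 2e-3, 500 + s)
            b = bd_run(empty, 2e-3, 500 + s)
            if a.n_kills and b.n_kills:
                with_obs.append(a.kill_times[0])
                without.append(b.kill_times[0])
        assert np.mean(without) <= np.mean(with_obs)


class TestKillRecord:
    def test_half_index_uses_ceiling(self):
        rec = KillRecord(0, np.array([1.0, 2.0, 3.0]), n_t0=5, t_max=10.0)
        assert rec.half_index == 3 and rec.half_kill_time == 3.0

    def test_censoring(self):
        rec = KillRecord(0, np.array([1.0]), n_t0=4, t_max=10.0)
        assert rec.censored and rec.half_kill_time is None

    def test_invalid_kill_sequences_rejected(self):
        with pytest.raises(ValueError):
            KillRecord(0, np.array([2.0, 1.0]), n_t0=3, t_max=10.0)
        with pytest.raises(ValueError):
            KillRecord(0, np.array([1.0, 2.0]), n_t0=1, t_max=10.0)
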