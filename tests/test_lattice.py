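"""Lattice random-walk models against the exact Markov-chain oracle."""

import numpy as np
import pytest

from nksearch import LatticeConfig, exact_hitting_time, half_time, run_lattice
from nksearch.lattice import lattice_ensemble


class TestExactOracle:
    def test_single_jump_chain(self):
        """1x2 lattice, killer beside the target: one hop at rate q."""
        for q in (1.0, 2.5):
            cfg = LatticeConfig(width=2, height=1, q=q)
            t = exact_hitting_time(cfg, killer_start=(0, 0),
                                   target_sites=[(1, 0)], bystander_sites=[])
            assert t == pytest.approx(1.0 / q)

    def test_uniform_rate_multiplier_rescales_exactly(self):
        """Scaling every hop rate by m divides the expected time by m."""
        cfg1 = LatticeConfig(width=5, height=5, q=1.0)
        cfg3 = LatticeConfig(width=5, height=5, q=3.0)
        targets = [(4, 4)]
        t1 = exact_hitting_time(cfg1, killer_start=(0, 0),
                                target_sites=targets, bystander_sites=[])
        t3 = exact_hitting_time(cfg3, killer_start=(0, 0),
                                target_sites=targets, bystander_sites=[])
        assert t1 == pytest.approx(3.0 * t3, rel=1e-12)

    def test_model2_fully_boosted_grid_rescales_exactly(self):
        """On a 2x2 grid one plaquette bystander boosts all four edges, so
        the multiplier acts as a uniform rate rescaling."""
        targets = [(1, 1)]
        base = exact_hitting_time(
            LatticeConfig(width=2, height=2, model="model2", multiplier=1.0),
            killer_start=(0, 0), target_sites=targets, bystander_sites=[])
        boosted = exact_hitting_time(
            LatticeConfig(width=2, height=2, model="model2", multiplier=4.0,
                          n_bystanders=1),
            killer_start=(0, 0), target_sites=targets,
            bystander_sites=[(0, 0)])
        assert boosted == pytest.approx(base / 4.0, rel=1e-12)

    def test_state_space_cap(self):
        cfg = LatticeConfig(width=400, height=400)
        with pytest.raises(ValueError, match="state space"):
            exact_hitting_time(cfg, max_states=1000)


class TestStochasticAgainstExact:
    def test_mean_hitting_time_small_grid(self):
        """Gillespie mean capture time vs the linear-solve value (3x3)."""
        cfg = LatticeConfig(width=3, height=3, q=1.0)
        targets = [(2, 2)]
        exact = exact_hitting_time(cfg, target_sites=targets,
                                   bystander_sites=[])
        rng = np.random.default_rng(77)
        times = []
        for _ in range(1500):
            rec = run_lattice(cfg, rng, layout={"targets": targets})
            times.append(rec.kill_times[0])
        times = np.asarray(times)
        se = times.std(ddof=1) / np.sqrt(times.size)
        assert abs(times.mean() - exact) < 3 * se

    def test_accelerated_region_agreement(self):
        """Model 1 with a bystander next to the path: stochastic mean vs
        exact absorbing-chain value."""
        cfg = LatticeConfig(width=4, height=4, q=1.0, multiplier=4.0,
                            n_bystanders=1)
        layout = {"targets": [(3, 3)], "bystanders": [(1, 1)]}
        exact = exact_hitting_time(cfg, target_sites=layout["targets"],
                                   bystander_sites=layout["bystanders"])
        rng = np.random.default_rng(78)
        times = np.array([
            run_lattice(cfg, rng, layout=layout).kill_times[0]
            for _ in range(1500)
        ])
        se = times.std(ddof=1) / np.sqrt(times.size)
        assert abs(times.mean() - exact) < 3 * se


class TestDynamics:
    def test_stationary_occupancy_uniform_without_bystanders(self):
        """With symmetric rates the CTMC dwell-time distribution over a
        finite lattice is uniform (chi-square on long-run occupancy)."""
        cfg = LatticeConfig(width=4, height=4, q=1.0)
        occ = np.zeros((4, 4))
        rng = np.random.default_rng(5)
        run_lattice(cfg, rng, layout={"targets": [(0, 0)], "killers": [(2, 2)]},
                    stop_after=10**9, t_max=20_000.0, occupancy=occ)
        frac = occ.ravel() / occ.sum()
        # uniform target is 1/16 = 0.0625; at this run length the sampling
        # error per site is well under +/-0.015
        assert frac.max() < 0.09 and frac.min() > 0.04

    def test_jammed_lattice_returns_censored_record(self):
        cfg = LatticeConfig(width=3, height=3, n_bystanders=4,
                            bystander_exclusion=True)
        layout = {"targets": [(0, 0)], "killers": [(1, 1)],
                  "bystanders": [(0, 1), (2, 1), (1, 0), (1, 2)]}
        rec = run_lattice(cfg, 1, layout=layout)
        assert rec.n_kills == 0 and rec.censored

    def test_capture_on_entering_target_site(self):
        cfg = LatticeConfig(width=2, height=1)
        rec = run_lattice(cfg, 3, layout={"targets": [(1, 0)],
                                          "killers": [(0, 0)]})
        assert rec.n_kills == 1 and rec.kill_times[0] > 0

    def test_ensemble_determinism(self):
        cfg = LatticeConfig(width=5, height=5, n_targets=3, n_bystanders=2,
                            model="model1")
        a = lattice_ensemble(cfg, 10, seed=9)
        b = lattice_ensemble(cfg, 10, seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.kill_times, rb.kill_times)


class TestBystanderTrend:
    @pytest.mark.parametrize("model", ["model1", "model2"])
    def test_half_time_decreases_with_bystanders(self, model):
        """Scaled-down sweep: more bystanders -> faster target finding."""
        means = []
        for n_b in (0, 8, 20):
            cfg = LatticeConfig(width=10, height=10, n_killers=2, n_targets=6,
                                n_bystanders=n_b, multiplier=4.0, model=model,
                                bystander_exclusion=False)
            recs = lattice_ensemble(cfg, 150, seed=31, stop_at_half=True)
            means.append(half_time(recs).mean)
        assert means[0] > means[2]  # clear ends of the sweep
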