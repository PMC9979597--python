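"""Density, lattice, RDF, bonded-distribution and enthalpy estimators."""

import numpy as np
import pytest

from cogito.chain_mapper import TAGTopology
from cogito.constants import AVOGADRO
from cogito.energy_eval import Configuration
from cogito.traj_analysis import (
    EnergySeries,
    FrameSeries,
    LatticeParams,
    bonded_distributions,
    bootstrap_mean,
    box_from_lattice,
    delta_h_fus,
    delta_h_vap,
    density,
    lattice_params,
    rdf,
    relative_difference,
)


def point_topology(n=1, bead="C3H6"):
    return TAGTopology("GAS", [bead] * n, [0.0] * n, [42.08] * n, [], [])


def gas_config(n, box, seed):
    rng = np.random.default_rng(seed)
    topo = point_topology()
    pos = rng.uniform(0, 1, (n, 3)) * np.asarray(box)
    return Configuration(pos, np.diag(np.asarray(box, float)), topo, n_molecules=n)


class TestDensity:
    def test_closed_form(self, post_topology):
        cfg = Configuration(
            np.zeros((2100, 3)), np.diag([10.0, 10.0, 10.0]), post_topology, 100
        )
        expected = (100 * 861.413 / AVOGADRO) / (1000.0 * 1e-21)
        assert density(cfg) == pytest.approx(expected, rel=1e-12)
        assert density(cfg) == pytest.approx(0.14304, abs=5e-6)

    def test_box_scaling(self, post_lamellar):
        d1 = density(post_lamellar)
        big = Configuration(
            post_lamellar.positions,
            post_lamellar.box * 2,
            post_lamellar.topology,
            post_lamellar.n_molecules,
        )
        assert density(big) == pytest.approx(d1 / 8)

    def test_translation_invariant(self, post_lamellar):
        moved = Configuration(
            post_lamellar.positions + 3.21,
            post_lamellar.box,
            post_lamellar.topology,
            post_lamellar.n_molecules,
        )
        assert density(moved) == density(post_lamellar)

    def test_empty_configuration_raises(self):
        topo = TAGTopology("NONE", [], [], [], [], [])
        cfg = Configuration(np.zeros((0, 3)), np.diag([1.0, 1, 1]), topo, 1)
        with pytest.raises(ValueError, match="empty"):
            density(cfg)


class TestLattice:
    def test_diagonal_box_with_stacking(self):
        cell = lattice_params(np.diag([25.0, 5.0, 40.0]), stacking=(5, 1, 5))
        assert (cell.a, cell.b, cell.c) == (5.0, 5.0, 8.0)
        assert (cell.alpha, cell.beta, cell.gamma) == (90.0, 90.0, 90.0)

    def test_identity_box(self):
        cell = lattice_params(np.eye(3), stacking=(1, 1, 1))
        assert (cell.a, cell.b, cell.c) == (1.0, 1.0, 1.0)

    def test_monoclinic_beta_from_dot_product(self):
        box = np.array([[4.0, 0, 0], [0, 3.0, 0], [-1.0, 0, 5.0]])
        cell = lattice_params(box, stacking=(1, 1, 1))
        expected_beta = np.degrees(np.arccos(-1.0 / np.sqrt(26.0)))
        assert cell.beta == pytest.approx(expected_beta)
        assert cell.alpha == pytest.approx(90.0)

    def test_roundtrip_via_box_construction(self):
        cell = LatticeParams(a=1.9, b=0.8, c=4.5, alpha=90.0, beta=103.7, gamma=90.0)
        back = lattice_params(box_from_lattice(cell, (5, 1, 5)), stacking=(5, 1, 5))
        for attr in ("a", "b", "c", "alpha", "beta", "gamma"):
            assert getattr(back, attr) == pytest.approx(getattr(cell, attr), abs=1e-10)

    def test_angles_stacking_invariant(self):
        cell = LatticeParams(a=1.9, b=0.8, c=4.5, alpha=90.0, beta=103.7, gamma=90.0)
        b1 = lattice_params(box_from_lattice(cell, (5, 1, 5)), stacking=(1, 1, 1))
        assert b1.beta == pytest.approx(103.7, abs=1e-10)

    def test_nonpositive_diagonal_raises(self):
        with pytest.raises(ValueError):
            lattice_params(np.diag([1.0, -1.0, 1.0]))


class TestRdf:
    def test_ideal_gas_plateau(self):
        frames = [gas_config(400, (8.0, 8.0, 8.0), seed=s) for s in range(12)]
        series = FrameSeries(np.arange(12.0), frames)
        idx = np.arange(400)
        r, g = rdf(series, idx, idx, bin_width=0.1, r_max=4.0)
        upper = g[len(g) // 2 :]
        assert np.all(np.abs(upper - 1.0) < 0.05)

    def test_coordination_count(self):
        frames = [gas_config(400, (8.0, 8.0, 8.0), seed=100 + s) for s in range(12)]
        series = FrameSeries(np.arange(12.0), frames)
        idx = np.arange(400)
        r, g = rdf(series, idx, idx, bin_width=0.1, r_max=3.0)
        rho = 399 / 8.0**3  # density of partners around a central bead
        dr = 0.1
        coord = np.sum(g * 4 * np.pi * r**2 * rho * dr)
        expected = 4 / 3 * np.pi * 3.0**3 * rho
        assert coord == pytest.approx(expected, rel=0.02)

    def test_fixed_pair_single_bin(self):
        topo = point_topology()
        pos = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 2.25]])
        cfg = Configuration(pos, np.diag([6.0, 6.0, 6.0]), topo, 2)
        series = FrameSeries([0.0], [cfg])
        r, g = rdf(series, np.array([0]), np.array([1]), bin_width=0.1, r_max=3.0)
        nonzero = np.nonzero(g)[0]
        assert len(nonzero) == 1
        assert r[nonzero[0]] == pytest.approx(1.25)  # d=1.25 lands in bin [1.2, 1.3)

    def test_empty_group_raises(self):
        series = FrameSeries([0.0], [gas_config(10, (6.0, 6.0, 6.0), 0)])
        with pytest.raises(ValueError):
            rdf(series, np.array([], dtype=int), np.arange(10))

    def test_r_max_too_large_raises(self):
        series = FrameSeries([0.0], [gas_config(10, (6.0, 6.0, 6.0), 0)])
        with pytest.raises(ValueError, match="r_max"):
            rdf(series, np.arange(10), np.arange(10), r_max=4.0)


class TestBondedDistributions:
    def test_zero_variance_at_equilibrium(self, post_topology, post_molecule, ff):
        cfg = Configuration(
            post_molecule - post_molecule.min(0) + 2.0,
            np.diag([9.0, 9.0, 9.0]),
            post_topology,
            1,
        )
        series = FrameSeries([0.0, 1.0], [cfg, cfg])
        dist = bonded_distributions(series, post_topology, ("1CH2OCO", "2CHOCO"))
        assert dist.mean == pytest.approx(0.470, abs=1e-9)
        assert dist.std == pytest.approx(0.0, abs=1e-9)

    def test_glycerol_angle_at_equilibrium(self, post_topology, post_molecule):
        cfg = Configuration(
            post_molecule - post_molecule.min(0) + 2.0,
            np.diag([9.0, 9.0, 9.0]),
            post_topology,
            1,
        )
        series = FrameSeries([0.0], [cfg])
        dist = bonded_distributions(
            series, post_topology, ("1CH2OCO", "2CHOCO", "3CH2OCO")
        )
        assert dist.mean == pytest.approx(65.0, abs=1e-6)

    def test_gaussian_perturbed_mean_recovery(self):
        rng = np.random.default_rng(7)
        topo = TAGTopology(
            "PAIR", ["C3H6", "C3H6"], [0.0, 0.0], [42.08, 42.08], [(0, 1)], []
        )
        n_frames, sigma = 200, 0.01
        lengths = 0.4 + rng.normal(0, sigma, n_frames)
        frames = [
            Configuration(
                np.array([[3.0, 3, 3], [3.0 + L, 3, 3]]), np.diag([6.0, 6, 6]), topo, 1
            )
            for L in lengths
        ]
        series = FrameSeries(np.arange(float(n_frames)), frames)
        dist = bonded_distributions(series, topo, ("C3H6", "C3H6"))
        se = sigma / np.sqrt(n_frames)
        assert abs(dist.mean - lengths.mean()) < 1e-12
        assert abs(dist.mean - 0.4) < 3 * se
        assert dist.n_samples == n_frames

    def test_no_matches_raises(self, post_topology, post_molecule):
        cfg = Configuration(
            post_molecule + 2.0, np.diag([9.0, 9.0, 9.0]), post_topology, 1
        )
        series = FrameSeries([0.0], [cfg])
        with pytest.raises(ValueError, match="no instances"):
            bonded_distributions(series, post_topology, ("CHCH", "CHCH"))


class TestBootstrap:
    def test_constant_series(self):
        s = EnergySeries(np.arange(10.0), np.full(10, 5.0))
        mean, (lo, hi) = bootstrap_mean(s, n_boot=200, seed=0)
        assert mean == 5.0
        assert lo == hi == 5.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        s = EnergySeries(np.arange(50.0), rng.normal(size=50))
        assert bootstrap_mean(s, n_boot=500, seed=9) == bootstrap_mean(
            s, n_boot=500, seed=9
        )

    def test_converges_to_sample_mean(self):
        rng = np.random.default_rng(4)
        s = EnergySeries(np.arange(50.0), rng.normal(10.0, 2.0, size=50))
        mean, (lo, hi) = bootstrap_mean(s, n_boot=100_000, seed=1)
        # percentile CI centres on the sample mean as n_boot grows
        assert (lo + hi) / 2 == pytest.approx(s.values.mean(), abs=0.02)

    def test_window_selection(self):
        s = EnergySeries(np.arange(10.0), np.arange(10.0))
        mean, _ = bootstrap_mean(s, window_start=6.0, n_boot=100, seed=0)
        assert mean == pytest.approx(np.mean([6, 7, 8, 9]))

    def test_empty_window_raises(self):
        s = EnergySeries(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            bootstrap_mean(s, window_start=100.0)

    def test_coverage_of_percentile_ci(self):
        """~95% of bootstrap CIs cover the true mean on normal data."""
        mu, sd, n = 3.0, 1.5, 100
        master = np.random.default_rng(2024)
        covered = 0
        reps = 500
        for k in range(reps):
            values = master.normal(mu, sd, n)
            s = EnergySeries(np.arange(float(n)), values)
            _, (lo, hi) = bootstrap_mean(s, n_boot=300, seed=k)
            covered += lo <= mu <= hi
        assert 0.92 <= covered / reps <= 0.98


class TestEnthalpy:
    def test_identical_series_zero(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        a = EnergySeries(np.arange(40.0), v)
        b = EnergySeries(np.arange(40.0), v.copy())
        dh, _ = delta_h_fus(a, b, n_boot=200, seed=0)
        assert dh == 0.0

    def test_constant_offset_recovered(self):
        t = np.arange(40.0)
        rng = np.random.default_rng(1)
        base = rng.normal(size=40)
        melt = EnergySeries(t, base + 50.0)
        crystal = EnergySeries(t, base)
        dh, (lo, hi) = delta_h_fus(melt, crystal, n_boot=500, seed=2)
        assert dh == pytest.approx(50.0)
        assert lo <= 50.0 <= hi

    def test_noisy_offset_within_ci(self):
        rng = np.random.default_rng(5)
        t = np.arange(200.0)
        true_delta = 12.0
        melt = EnergySeries(t, rng.normal(100.0 + true_delta, 3.0, 200))
        crystal = EnergySeries(t, rng.normal(100.0, 3.0, 200))
        dh, (lo, hi) = delta_h_fus(melt, crystal, n_boot=1000, seed=6)
        assert lo <= true_delta <= hi

    def test_delta_h_vap_rt_arithmetic(self):
        assert delta_h_vap(0.0, 0.0, 300.0) == pytest.approx(2.4943, abs=5e-5)
        assert delta_h_vap(10.0, 10.0, 0.0) == 0.0
        assert delta_h_vap(100.0, 0.0, 298.15) == pytest.approx(102.479, abs=5e-4)

    def test_negative_temperature_raises(self):
        with pytest.raises(ValueError):
            delta_h_vap(1.0, 0.0, -10.0)


def test_relative_difference_sign_convention():
    assert relative_difference(1.06, 1.0) == pytest.approx(6.0)
    assert relative_difference(0.94, 1.0) == pytest.approx(-6.0)


def test_frame_series_validation():
    cfgs = [gas_config(5, (6.0, 6, 6), 0), gas_config(5, (6.0, 6, 6), 1)]
    with pytest.raises(ValueError, match="increasing"):
        FrameSeries([1.0, 1.0], cfgs)


def test_energy_series_from_table():
    text = "# comment\n@ legend\n0.0 1.5\n10.0 2.5\n"
    s = EnergySeries.from_table(text)
    assert list(s.times) == [0.0, 10.0]
    assert list(s.values) == [1.5, 2.5]
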