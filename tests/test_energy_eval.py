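"""Energy and force correctness against independent oracles.

The non-bonded sum is checked against a pure-Python double loop with an
explicit image search (written independently of the vectorised
implementation), and analytic forces against central finite differences.
"""

import itertools
import math

import numpy as np
import pytest

from cogito.chain_mapper import TAGTopology
from cogito.energy_eval import (
    Configuration,
    angle_energy,
    bond_energy,
    forces,
    lj_shifted,
    minimize,
    total_energy,
)
from cogito.fixtures import FixtureSpec, build_lamellar, build_melt


def make_config(positions, box, topology, n_molecules=1):
    return Configuration(np.asarray(positions, float), np.diag(box), topology, n_molecules)


def dimer_topology(ff, a="C3H6", b="C3H6"):
    return TAGTopology(
        molecule_name="DIMER",
        bead_types=[a, b],
        charges=[ff.bead(a).charge, ff.bead(b).charge],
        masses=[ff.bead(a).mass, ff.bead(b).mass],
        bonds=[(0, 1)],
        angles=[],
    )


# ---------------------------------------------------------------------------
# closed-form single-term checks


def test_bond_energy_worked_values(ff):
    p = ff.lookup_bond("1CH2OCO", "2CHOCO")
    assert bond_energy(p.r_eq, p) == 0.0
    assert bond_energy(0.480, p) == pytest.approx(0.5 * 4000 * 0.010**2)


def test_bond_energy_zero_force_constant():
    from cogito.ff_model import BondParam

    p = BondParam("A", "B", 0.4, 0.0)
    assert bond_energy(1.7, p) == 0.0


def test_angle_energy_worked_values(ff):
    p = ff.lookup_angle("1CH2OCO", "2CHOCO", "3CH2OCO")
    assert angle_energy(p.theta_eq_rad, p) == pytest.approx(0.0, abs=1e-12)
    expected = 0.5 * 120 * (math.cos(math.pi / 2) - math.cos(math.radians(65))) ** 2
    assert angle_energy(math.pi / 2, p) == pytest.approx(expected)
    assert expected == pytest.approx(10.72, abs=0.01)


def test_angle_energy_cosine_symmetry():
    from cogito.ff_model import AngleParam

    p = AngleParam("A", "B", "C", 90.0, 50.0)
    assert angle_energy(math.radians(180 - 90), p) == pytest.approx(0.0, abs=1e-12)


def test_lj_shifted_zero_at_and_beyond_cutoff():
    assert lj_shifted(1.1, 0.4, 2.0, 1.1) == 0.0
    assert lj_shifted(5.0, 0.4, 2.0, 1.1) == 0.0


def test_lj_shifted_at_sigma_equals_minus_shift():
    sigma, eps, cut = 0.43, 2.5, 1.1
    shift = 4 * eps * ((sigma / cut) ** 12 - (sigma / cut) ** 6)
    assert lj_shifted(sigma, sigma, eps, cut) == pytest.approx(-shift)


# ---------------------------------------------------------------------------
# whole-configuration checks


def test_two_neutral_beads_beyond_cutoff_no_interaction(ff):
    topo = dimer_topology(ff)
    # bonded at r_eq so the bond term vanishes too... place beads far apart
    topo_free = TAGTopology("PAIR", ["C3H6", "C3H6"], [0.0, 0.0], [42.08, 42.08], [], [])
    cfg = make_config([[1, 1, 1], [1, 1, 3.0]], (10, 10, 10), topo_free, 1)
    eb = total_energy(cfg, ff)
    assert eb.total == 0.0


def brute_force_nonbonded(cfg, ff):
    """Independent O(N^2) double loop with explicit 3x3x3 image search."""
    types = cfg.bead_types()
    n_mol = cfg.n_molecules
    nb = cfg.topology.n_beads
    excl = set()
    for m in range(n_mol):
        for i, j in cfg.topology.exclusions:
            excl.add((m * nb + i, m * nb + j))
            excl.add((m * nb + j, m * nb + i))
    box = cfg.box
    shifts = [
        ia * box[0] + ib * box[1] + ic * box[2]
        for ia, ib, ic in itertools.product((-1, 0, 1), repeat=3)
    ]
    e_lj = e_coul = 0.0
    n = len(cfg.positions)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            raw = cfg.positions[j] - cfg.positions[i]
            r = min(np.linalg.norm(raw + s) for s in shifts)
            if r >= ff.cutoff:
                continue
            si, ei = ff.lookup_lj(types[i]).sigma, ff.lookup_lj(types[i]).epsilon
            sj, ej = ff.lookup_lj(types[j]).sigma, ff.lookup_lj(types[j]).epsilon
            s, e = (si + sj) / 2, math.sqrt(ei * ej)
            sr6 = (s / r) ** 6
            sc6 = (s / ff.cutoff) ** 6
            e_lj += 4 * e * (sr6**2 - sr6) - 4 * e * (sc6**2 - sc6)
            qi = ff.bead(types[i]).charge
            qj = ff.bead(types[j]).charge
            e_coul += ff.coulomb_constant * qi * qj / r
    return e_lj, e_coul


def test_nonbonded_matches_brute_force_oracle(post_topology, ff):
    """Vectorised pair sum equals the double-loop oracle to 1e-10 relative."""
    cfg = build_lamellar(FixtureSpec(post_topology, 20, "lamellar", lattice=(5, 1, 4)), ff)
    assert cfg.n_beads == 420
    eb = total_energy(cfg, ff)
    e_lj, e_coul = brute_force_nonbonded(cfg, ff)
    assert eb.lj == pytest.approx(e_lj, rel=1e-10)
    assert eb.coulomb == pytest.approx(e_coul, rel=1e-10)


def test_melt_matches_brute_force_oracle(post_topology, ff):
    cfg = build_melt(
        FixtureSpec(post_topology, 8, "melt", box=(7.0, 7.0, 7.0), seed=3), ff
    )
    eb = total_energy(cfg, ff)
    e_lj, e_coul = brute_force_nonbonded(cfg, ff)
    assert eb.lj == pytest.approx(e_lj, rel=1e-10)
    assert eb.coulomb == pytest.approx(e_coul, rel=1e-10)


def test_periodicity_full_box_translation(post_lamellar, ff):
    e0 = total_energy(post_lamellar, ff).total
    moved = post_lamellar.positions.copy()
    nb = post_lamellar.topology.n_beads
    moved[:nb] += post_lamellar.box[0]  # translate one molecule by a box vector
    cfg2 = Configuration(moved, post_lamellar.box, post_lamellar.topology, 4)
    assert total_energy(cfg2, ff).total == pytest.approx(e0, rel=1e-12)


def test_translational_and_rotational_invariance(post_topology, post_molecule, ff):
    box = (8.0, 8.0, 8.0)
    pos = post_molecule - post_molecule.min(axis=0) + 2.0
    cfg = make_config(pos, box, post_topology)
    e0 = total_energy(cfg, ff).total
    e_shift = total_energy(make_config(pos + [0.37, -1.2, 0.83], box, post_topology), ff).total
    assert e_shift == pytest.approx(e0, rel=1e-12)
    rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)  # 90 deg about z
    e_rot = total_energy(make_config(pos @ rot.T, box, post_topology), ff).total
    assert e_rot == pytest.approx(e0, rel=1e-10)


def test_energy_extensive_two_noninteracting_copies(post_topology, post_molecule, ff):
    pos = post_molecule - post_molecule.min(axis=0) + 2.0
    single = make_config(pos, (8.0, 8.0, 8.0), post_topology)
    e1 = total_energy(single, ff).total
    doubled = np.vstack([pos, pos + [0, 0, 8.0]])
    pair = make_config(doubled, (8.0, 8.0, 16.0), post_topology, n_molecules=2)
    assert total_energy(pair, ff).total == pytest.approx(2 * e1, rel=1e-10)


def test_box_too_small_raises(post_topology, post_molecule, ff):
    with pytest.raises(ValueError, match="box"):
        total_energy(make_config(post_molecule + 5, (2.0, 8.0, 8.0), post_topology), ff)


def test_breakdown_total_is_sum(post_lamellar, ff):
    eb = total_energy(post_lamellar, ff)
    assert eb.total == pytest.approx(eb.bond + eb.angle + eb.lj + eb.coulomb)


# ---------------------------------------------------------------------------
# forces


def fd_forces(cfg, ff, h=1e-6, components=None):
    pos = cfg.positions
    out = {}
    comps = components or [
        (i, d) for i in range(len(pos)) for d in range(3)
    ]
    for i, d in comps:
        acc = 0.0
        for s, sign in ((h, 1.0), (-h, -1.0)):
            p2 = pos.copy()
            p2[i, d] += s
            acc -= sign * total_energy(
                Configuration(p2, cfg.box, cfg.topology, cfg.n_molecules), ff
            ).total
        out[(i, d)] = acc / (2 * h)
    return out


def test_isolated_bead_zero_force(ff):
    topo = TAGTopology("ONE", ["C3H6"], [0.0], [42.08], [], [])
    cfg = make_config([[5.0, 5.0, 5.0]], (10, 10, 10), topo)
    assert np.all(forces(cfg, ff) == 0.0)


def test_stretched_bond_force_magnitude(ff):
    topo = dimer_topology(ff)
    p = ff.lookup_bond("C3H6", "C3H6")
    r = p.r_eq + 0.05
    cfg = make_config([[2, 2, 2], [2 + r, 2, 2]], (10, 10, 10), topo)
    f = forces(cfg, ff)
    # bonded beads are excluded from non-bonded terms: pure harmonic pull
    expected = p.k_b * 0.05
    assert f[0, 0] == pytest.approx(expected, rel=1e-9)
    assert f[1, 0] == pytest.approx(-expected, rel=1e-9)
    assert np.abs(f[:, 1:]).max() == 0.0


def test_forces_match_finite_differences_randomized(post_topology, post_molecule, ff, rng):
    """Analytic gradient vs central differences on perturbed configurations."""
    pos0 = post_molecule - post_molecule.min(axis=0) + 2.0
    for _ in range(5):
        pos = pos0 + rng.normal(0, 0.03, pos0.shape)
        cfg = make_config(pos, (8.0, 8.0, 8.0), post_topology)
        f = forces(cfg, ff)
        scale = max(np.abs(f).max(), 1.0)
        comps = [(int(rng.integers(len(pos))), int(rng.integers(3))) for _ in range(8)]
        fd = fd_forces(cfg, ff, components=comps)
        for (i, d), val in fd.items():
            assert abs(f[i, d] - val) / scale < 1e-4
        assert np.abs(f.sum(axis=0)).max() < 1e-8 * scale


def test_net_force_zero(post_lamellar, ff):
    f = forces(post_lamellar, ff)
    assert np.abs(f.sum(axis=0)).max() < 1e-8


# ---------------------------------------------------------------------------
# minimization


def test_minimize_already_minimal_dimer_unchanged(ff):
    topo = dimer_topology(ff, "C3H6", "C3H7T")
    p = ff.lookup_bond("C3H6", "C3H7T")
    # note: bonded pair is excluded from LJ, so the bond minimum is r_eq
    cfg = make_config([[3, 3, 3], [3 + p.r_eq, 3, 3]], (10, 10, 10), topo)
    out = minimize(cfg, ff, tol=1e-6)
    assert np.allclose(out.positions, cfg.positions)


def test_minimize_recovers_bond_length(ff):
    topo = dimer_topology(ff)
    p = ff.lookup_bond("C3H6", "C3H6")
    cfg = make_config([[3, 3, 3], [3 + p.r_eq + 0.08, 3, 3]], (10, 10, 10), topo)
    out = minimize(cfg, ff, max_steps=5000, tol=1e-6)
    r = np.linalg.norm(out.positions[1] - out.positions[0])
    assert r == pytest.approx(p.r_eq, abs=1e-4)


def test_minimize_lowers_crystal_energy(post_lamellar, ff):
    e0 = total_energy(post_lamellar, ff).total
    out = minimize(post_lamellar, ff, max_steps=50)
    assert total_energy(out, ff).total <= e0
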