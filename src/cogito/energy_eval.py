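"""Potential-energy and force evaluation for periodic CG configurations.

The potential is the sum of harmonic bond terms, GROMOS-96 cosine angle
terms, a Lennard-Jones term with Lorentz-Berthelot mixing and potential
shift at the cut-off, and a plain truncated Coulomb term.  Non-bonded
interactions between first bonded neighbours (within a molecule) are
excluded; second neighbours (angle partners) interact.

The Coulomb term here is truncated at the cut-off rather than treated
with Ewald summation: the evaluator's role is fixture energetics and
consistency testing, charges are small (±0.05 e) and locally neutral, and
production electrostatics are delegated to the MD engine via the emitted
input files.  An optional shift to zero at the cut-off is available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chain_mapper import TAGTopology
from .ff_model import ForceFieldModel

__all__ = [
    "Configuration",
    "EnergyBreakdown",
    "bond_energy",
    "angle_energy",
    "lj_shifted",
    "total_energy",
    "forces",
    "minimize",
    "minimum_image",
]


@dataclass
class Configuration:
    """Bead positions plus a lower-triangular triclinic periodic box.

    The topology describes one molecule; ``n_molecules`` replicas are laid
    out consecutively in ``positions``.
    """

    positions: np.ndarray  # (N, 3), nm
    box: np.ndarray  # (3, 3) lower-triangular, nm (rows are box vectors)
    topology: TAGTopology
    n_molecules: int = 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3, 3):
            raise ValueError("box must be a 3x3 matrix")
        if np.any(np.diag(self.box) <= 0):
            raise ValueError("box diagonal must be positive")
        if not np.allclose(self.box[np.triu_indices(3, 1)], 0.0):
            raise ValueError("box must be lower triangular (GROMACS convention)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        expected = self.n_molecules * self.topology.n_beads
        if len(self.positions) != expected:
            raise ValueError(
                f"expected {expected} beads ({self.n_molecules} molecules x "
                f"{self.topology.n_beads}), got {len(self.positions)}"
            )

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        """Box volume in nm^3 (product of diagonal for a triangular box)."""
        return float(abs(np.linalg.det(self.box)))

    def bead_types(self) -> list[str]:
        return self.topology.bead_types * self.n_molecules

    def replicated_bonds(self) -> np.ndarray:
        return _replicate_tuples(
            self.topology.bonds, self.topology.n_beads, self.n_molecules, width=2
        )

    def replicated_angles(self) -> np.ndarray:
        return _replicate_tuples(
            self.topology.angles, self.topology.n_beads, self.n_molecules, width=3
        )


def _replicate_tuples(tuples, n_beads: int, n_molecules: int, width: int = 2) -> np.ndarray:
    base = np.asarray(tuples, dtype=int)
    if base.size == 0:
        return base.reshape(0, width)
    offsets = np.arange(n_molecules)[:, None, None] * n_beads
    return (base[None, :, :] + offsets).reshape(-1, base.shape[1])


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term potential energy (kJ/mol)."""

    bond: float
    angle: float
    lj: float
    coulomb: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.lj + self.coulomb


def bond_energy(r: float, param) -> float:
    """Harmonic bond energy 1/2 k_b (r - r_eq)^2 at distance r (nm)."""
    return 0.5 * param.k_b * (r - param.r_eq) ** 2


def angle_energy(theta: float, param) -> float:
    """G96 cosine angle energy 1/2 k_theta (cos theta - cos theta_eq)^2.

    ``theta`` in radians.  The cosine form is smooth through 180 degrees,
    which is why near-linear CG chains can be treated without dihedrals.
    """
    return 0.5 * param.k_theta * (np.cos(theta) - param.cos_theta_eq) ** 2


def lj_shifted(r, sigma: float, epsilon: float, cutoff: float):
    """Potential-shifted Lennard-Jones energy, zero at and beyond the cut-off."""
    r = np.asarray(r, dtype=float)
    sr6 = (sigma / r) ** 6
    sc6 = (sigma / cutoff) ** 6
    v = 4.0 * epsilon * (sr6**2 - sr6) - 4.0 * epsilon * (sc6**2 - sc6)
    out = np.where(r < cutoff, v, 0.0)
    return float(out) if out.ndim == 0 else out


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image reduction of displacement vectors for a triclinic box.

    Box rows are the box vectors with the GROMACS lower-triangular
    convention; reduction proceeds c, b, a.  Valid when the interaction
    range is below half the smallest box extent (enforced by callers).
    """
    d = np.array(d, dtype=float, copy=True)
    single = d.ndim == 1
    if single:
        d = d[None, :]
    for k in (2, 1, 0):
        shift = np.round(d[:, k] / box[k, k])
        d -= shift[:, None] * box[k][None, :]
    return d[0] if single else d


def _check_box(config: Configuration, cutoff: float) -> None:
    if min(np.diag(config.box)) <= 2.0 * cutoff:
        raise ValueError(
            "box too small for minimum image: every box extent must exceed "
            f"twice the cut-off ({2 * cutoff:.2f} nm)"
        )


def _pair_tables(config: Configuration, ff: ForceFieldModel):
    """Per-bead sigma, epsilon, charge arrays and the exclusion pair set."""
    types = config.bead_types()
    sigma = np.array([ff.lookup_lj(t).sigma for t in types])
    epsilon = np.array([ff.lookup_lj(t).epsilon for t in types])
    charge = np.array([ff.bead(t).charge for t in types])
    excl = _replicate_tuples(
        config.topology.exclusions, config.topology.n_beads, config.n_molecules
    )
    return sigma, epsilon, charge, excl


def _nonbonded_pairs(config: Configuration, cutoff: float, excl: np.ndarray):
    """Indices i<j within the cut-off (minimum image), exclusions removed.

    Pair search is a vectorised all-pairs distance evaluation with cut-off
    masking, processed in row blocks to bound memory; adequate for the
    fixture-scale systems (thousands of beads) this evaluator targets.
    """
    pos = config.positions
    n = len(pos)
    excl_set = {(min(i, j), max(i, j)) for i, j in map(tuple, excl)}
    out_i, out_j, out_d = [], [], []
    block = 512
    for start in range(0, n, block):
        stop = min(start + block, n)
        d = pos[start:stop, None, :] - pos[None, :, :]
        d = minimum_image(d.reshape(-1, 3), config.box).reshape(stop - start, n, 3)
        dist = np.linalg.norm(d, axis=-1)
        ii, jj = np.nonzero(dist < cutoff)
        ii_global = ii + start
        keep = ii_global < jj
        for a, b in zip(ii_global[keep], jj[keep]):
            if (int(a), int(b)) not in excl_set:
                out_i.append(int(a))
                out_j.append(int(b))
                out_d.append(dist[a - start, b])
    return np.array(out_i, dtype=int), np.array(out_j, dtype=int), np.array(out_d)


def _bonded_geometry(config: Configuration, ff: ForceFieldModel):
    """Bond distances/params and angle cosines/params, minimum-image."""
    pos = config.positions
    types = config.bead_types()
    bonds = config.replicated_bonds()
    rb = minimum_image(pos[bonds[:, 1]] - pos[bonds[:, 0]], config.box)
    r = np.linalg.norm(rb, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("degenerate geometry: bonded beads at zero separation")
    bond_params = [ff.lookup_bond(types[i], types[j]) for i, j in bonds]

    angles = config.replicated_angles()
    u = minimum_image(pos[angles[:, 0]] - pos[angles[:, 1]], config.box)
    v = minimum_image(pos[angles[:, 2]] - pos[angles[:, 1]], config.box)
    angle_params = [ff.lookup_angle(types[i], types[j], types[k]) for i, j, k in angles]
    return bonds, rb, r, bond_params, angles, u, v, angle_params


def total_energy(
    config: Configuration, ff: ForceFieldModel, coulomb_shift: bool = False
) -> EnergyBreakdown:
    """Evaluate the potential on a periodic configuration.

    Bonds and angles are summed over the topology lists with minimum-image
    geometry.  Non-bonded LJ (potential-shifted) and Coulomb (truncated,
    optionally shifted) terms are summed over all pairs within the cut-off
    except first bonded neighbours; intermolecular pairs are never
    excluded.
    """
    _check_box(config, ff.cutoff)
    sigma, epsilon, charge, excl = _pair_tables(config, ff)
    _, _, r, bond_params, _, u, v, angle_params = _bonded_geometry(config, ff)

    e_bond = float(
        sum(0.5 * p.k_b * (ri - p.r_eq) ** 2 for ri, p in zip(r, bond_params))
    )
    if len(u):
        cos_t = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        e_angle = float(
            sum(
                0.5 * p.k_theta * (c - p.cos_theta_eq) ** 2
                for c, p in zip(cos_t, angle_params)
            )
        )
    else:
        e_angle = 0.0

    ii, jj, dist = _nonbonded_pairs(config, ff.cutoff, excl)
    if len(ii):
        s_ij = 0.5 * (sigma[ii] + sigma[jj])
        e_ij = np.sqrt(epsilon[ii] * epsilon[jj])
        sr6 = (s_ij / dist) ** 6
        sc6 = (s_ij / ff.cutoff) ** 6
        e_lj = float(np.sum(4.0 * e_ij * (sr6**2 - sr6) - 4.0 * e_ij * (sc6**2 - sc6)))
        qq = ff.coulomb_constant * charge[ii] * charge[jj]
        e_coul = qq / dist
        if coulomb_shift:
            e_coul = e_coul - qq / ff.cutoff
        e_coul = float(np.sum(e_coul))
    else:
        e_lj = 0.0
        e_coul = 0.0
    return EnergyBreakdown(bond=e_bond, angle=e_angle, lj=e_lj, coulomb=e_coul)


def forces(config: Configuration, ff: ForceFieldModel) -> np.ndarray:
    """Analytic forces F = -grad U, in kJ mol^-1 nm^-1, shape (N, 3)."""
    _check_box(config, ff.cutoff)
    pos = config.positions
    sigma, epsilon, charge, excl = _pair_tables(config, ff)
    bonds, rb, r, bond_params, angles, u, v, angle_params = _bonded_geometry(config, ff)

    f = np.zeros_like(pos)

    # bonds: dU/dr = k (r - r_eq); force on j along +rb, on i along -rb
    k_b = np.array([p.k_b for p in bond_params])
    r_eq = np.array([p.r_eq for p in bond_params])
    if len(bonds):
        coef = (k_b * (r - r_eq) / r)[:, None] * rb  # dU/d(pos_j)
        np.add.at(f, bonds[:, 1], -coef)
        np.add.at(f, bonds[:, 0], coef)

    # angles: U = 1/2 k (cos t - cos t0)^2 with cos t = u.v/(|u||v|)
    if len(angles):
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.einsum("ij,ij->i", u, v) / (nu * nv)
        k_t = np.array([p.k_theta for p in angle_params])
        cos_0 = np.array([p.cos_theta_eq for p in angle_params])
        dU = (k_t * (cos_t - cos_0))[:, None]
        dcos_du = v / (nu * nv)[:, None] - (cos_t / nu**2)[:, None] * u
        dcos_dv = u / (nu * nv)[:, None] - (cos_t / nv**2)[:, None] * v
        fi = -dU * dcos_du
        fk = -dU * dcos_dv
        np.add.at(f, angles[:, 0], fi)
        np.add.at(f, angles[:, 2], fk)
        np.add.at(f, angles[:, 1], -(fi + fk))

    ii, jj, dist = _nonbonded_pairs(config, ff.cutoff, excl)
    if len(ii):
        d = minimum_image(pos[jj] - pos[ii], config.box)
        s_ij = 0.5 * (sigma[ii] + sigma[jj])
        e_ij = np.sqrt(epsilon[ii] * epsilon[jj])
        sr6 = (s_ij / dist) ** 6
        # -dV/dr for LJ (shift does not alter the force) plus truncated Coulomb
        f_scalar = 24.0 * e_ij * (2.0 * sr6**2 - sr6) / dist
        f_scalar = f_scalar + ff.coulomb_constant * charge[ii] * charge[jj] / dist**2
        fv = (f_scalar / dist)[:, None] * d  # force on j
        np.add.at(f, jj, fv)
        np.add.at(f, ii, -fv)
    return f


def minimize(
    config: Configuration,
    ff: ForceFieldModel,
    max_steps: int = 1000,
    tol: float = 10.0,
    step0: float = 0.01,
) -> Configuration:
    """Steepest-descent relaxation with adaptive step size.

    The energy never increases over accepted steps; iteration stops when
    the largest force component falls below ``tol`` (kJ mol^-1 nm^-1) or
    after ``max_steps`` accepted/rejected steps.
    """
    pos = config.positions.copy()
    cfg = replace(config, positions=pos)
    energy = total_energy(cfg, ff).total
    if not np.isfinite(energy):
        raise ValueError("initial configuration has non-finite energy")
    step = step0
    for _ in range(max_steps):
        f = forces(cfg, ff)
        fmax = np.abs(f).max()
        if fmax < tol:
            break
        trial = replace(cfg, positions=cfg.positions + step * f / fmax)
        e_trial = total_energy(trial, ff).total
        if np.isnan(e_trial):
            raise ValueError("minimization diverged: energy is NaN")
        if e_trial < energy:
            cfg, energy = trial, e_trial
            step = min(step * 1.2, 0.05)
        else:
            step *= 0.5
            if step < 1e-8:
                break
    return cfg
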