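"""Synthetic CG configurations: idealized lamellar stacks and random melts.

These generators stand in for diffraction-derived starting structures so
that energy evaluation, file emission and the analysis estimators can be
exercised end to end.  They are idealized — every bond and angle of the
extended molecule sits exactly at its equilibrium value and lamellar
packing is a rectangular lattice of aligned copies — and make no claim
to crystallographic realism (true beta-polymorph cells would require
external XRD coordinates).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .chain_mapper import GLYCEROL_BEADS, TAGTopology
from .energy_eval import Configuration, minimum_image
from .ff_model import ForceFieldModel

__all__ = [
    "FixtureSpec",
    "build_extended_molecule",
    "build_lamellar",
    "build_melt",
]

#: minimum inter-bead separation accepted during random insertion (nm);
#: roughly the smallest LJ sigma in the canonical set.
DEFAULT_CLEARANCE = 0.35

#: default gap between molecule bounding boxes in a lamellar stack (nm);
#: close enough for neighbouring chains to sit in the attractive LJ well.
DEFAULT_SPACING = 0.45


@dataclass
class FixtureSpec:
    """Recipe for a synthetic configuration."""

    topology: TAGTopology
    n_molecules: int = 1
    mode: str = "lamellar"  # or "melt"
    box: tuple[float, float, float] | None = None
    seed: int = 0
    spacing: float = DEFAULT_SPACING
    clearance: float = DEFAULT_CLEARANCE
    lattice: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be at least 1")
        if self.mode not in ("lamellar", "melt"):
            raise ValueError(f"unknown fixture mode {self.mode!r}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _direction_two_constraints(
    u1: np.ndarray, u2: np.ndarray, c1: float, c2: float, sign: float
) -> np.ndarray:
    """Unit vector d with d.u1 = c1 and d.u2 = c2 (cone intersection)."""
    g = float(np.dot(u1, u2))
    det = 1.0 - g * g
    if det < 1e-12:
        raise ValueError("cannot place bead: reference directions are collinear")
    alpha = (c1 - g * c2) / det
    beta = (c2 - g * c1) / det
    rest = 1.0 - (alpha * alpha + beta * beta + 2 * alpha * beta * g)
    if rest < -1e-10:
        raise ValueError("cannot place bead: angle constraints are geometrically infeasible")
    gamma = sign * np.sqrt(max(rest, 0.0))
    return alpha * u1 + beta * u2 + gamma * _unit(np.cross(u1, u2))


def build_extended_molecule(
    topology: TAGTopology, ff: ForceFieldModel
) -> np.ndarray:
    """Coordinates of one molecule with all bonded terms at equilibrium.

    Chains are laid out as planar zig-zags (alternating sides of the chain
    axis at the equilibrium angles); at branch points the new direction is
    solved from the cone intersection of the two already-placed angle
    constraints.  Several discrete plane/side choices are tried and the
    sterically best (largest minimum non-bonded separation) is kept, so
    the construction is deterministic.
    """
    if tuple(topology.bead_types[:3]) != GLYCEROL_BEADS:
        raise ValueError(
            "extended-molecule construction requires a full TAG topology "
            "(three chains on a glycerol-ester backbone)"
        )
    best_pos = None
    best_score = -np.inf
    for choice in itertools.product((1.0, -1.0), repeat=3):
        pos = _build_with_choices(topology, ff, choice)
        d = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(d, axis=-1)
        iu = np.triu_indices(len(pos), 1)
        bonded = set(map(tuple, np.sort(np.asarray(topology.bonds), axis=1)))
        mask = np.array([(i, j) not in bonded for i, j in zip(*iu)])
        score = dist[iu][mask].min()
        if score > best_score:
            best_score, best_pos = score, pos
    assert best_pos is not None
    return best_pos


def _build_with_choices(
    topology: TAGTopology, ff: ForceFieldModel, chain_sides: tuple[float, float, float]
) -> np.ndarray:
    types = topology.bead_types
    neighbours: dict[int, list[int]] = {i: [] for i in range(topology.n_beads)}
    for i, j in topology.bonds:
        neighbours[i].append(j)
        neighbours[j].append(i)

    pos = np.zeros((topology.n_beads, 3))
    placed = {0}
    # glycerol backbone in the xy-plane
    r01 = ff.lookup_bond(types[0], types[1]).r_eq
    pos[1] = [r01, 0.0, 0.0]
    placed.add(1)

    # chain planes: sn-1 and sn-3 zig-zag about z-offset planes, sn-2 uses
    # the out-of-plane branch direction; sides alternate per chain choice.
    chain_of: dict[int, int] = {}
    for c, (sn, idxs) in enumerate(sorted(topology.sn_positions.items())):
        for i in idxs:
            chain_of[i] = c
    zigzag_sign: dict[int, float] = {}

    order = _bfs_order(neighbours, topology.n_beads)
    for k in order:
        if k in placed:
            continue
        js = [j for j in neighbours[k] if j in placed]
        j = js[0]
        placed_nb = [m for m in neighbours[j] if m in placed and m != k]
        rjk = ff.lookup_bond(types[j], types[k]).r_eq
        if not placed_nb:
            d = np.array([1.0, 0.0, 0.0])
        elif len(placed_nb) == 1:
            m = placed_nb[0]
            u = _unit(pos[m] - pos[j])
            theta = ff.lookup_angle(types[m], types[j], types[k]).theta_eq_rad
            chain = chain_of.get(k, chain_of.get(j, 0))
            side = chain_sides[chain] * zigzag_sign.get(j, 1.0)
            zigzag_sign[k] = -zigzag_sign.get(j, 1.0)
            normal = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(normal, u)) > 0.99:
                normal = np.array([0.0, 1.0, 0.0])
            w = _unit(np.cross(normal, u))
            d = np.cos(theta) * u + side * np.sin(theta) * w
        else:
            m1, m2 = placed_nb[:2]
            u1 = _unit(pos[m1] - pos[j])
            u2 = _unit(pos[m2] - pos[j])
            c1 = np.cos(ff.lookup_angle(types[m1], types[j], types[k]).theta_eq_rad)
            c2 = np.cos(ff.lookup_angle(types[m2], types[j], types[k]).theta_eq_rad)
            chain = chain_of.get(k, 1)
            d = _direction_two_constraints(u1, u2, c1, c2, chain_sides[chain])
            zigzag_sign[k] = 1.0
        pos[k] = pos[j] + rjk * _unit(d)
        placed.add(k)
    return pos


def _bfs_order(neighbours: dict[int, list[int]], n: int) -> list[int]:
    order, seen, queue = [], {0}, [0]
    while queue:
        i = queue.pop(0)
        order.append(i)
        for j in sorted(neighbours[i]):
            if j not in seen:
                seen.add(j)
                queue.append(j)
    return order


def _lattice_dims(n: int) -> tuple[int, int, int]:
    """Near-balanced a x b x c factorization with a*b*c >= n."""
    best = None
    for na in range(1, n + 1):
        for nb in range(1, n // na + 2):
            nc = -(-n // (na * nb))
            total = na * nb * nc
            spread = max(na, nb, nc) - min(na, nb, nc)
            key = (total - n, spread, na * nb * nc)
            if best is None or key < best[0]:
                best = (key, (na, nb, nc))
    return best[1]


def build_lamellar(spec: FixtureSpec, ff: ForceFieldModel) -> Configuration:
    """Aligned extended molecules on a rectangular lattice in a periodic box."""
    if spec.mode != "lamellar":
        raise ValueError("spec.mode must be 'lamellar'")
    if spec.spacing < spec.clearance:
        raise ValueError(
            f"lattice spacing {spec.spacing} nm is below the clearance "
            f"{spec.clearance} nm; molecules would overlap — increase spacing"
        )
    mol = build_extended_molecule(spec.topology, ff)
    mol = mol - mol.min(axis=0)
    extent = mol.max(axis=0)
    pitch = extent + spec.spacing
    dims = spec.lattice or _lattice_dims(spec.n_molecules)
    if dims[0] * dims[1] * dims[2] < spec.n_molecules:
        raise ValueError(f"lattice {dims} cannot hold {spec.n_molecules} molecules")
    sites = [
        np.array([ia, ib, ic]) * pitch
        for ia, ib, ic in itertools.product(*(range(d) for d in dims))
    ][: spec.n_molecules]
    positions = np.vstack([mol + s for s in sites])
    box = np.diag(np.asarray(dims) * pitch)
    return Configuration(
        positions=positions,
        box=box,
        topology=spec.topology,
        n_molecules=spec.n_molecules,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_melt(
    spec: FixtureSpec, ff: ForceFieldModel, max_attempts: int = 500
) -> Configuration:
    """Randomly placed and oriented molecules with a hard clearance rule.

    Each molecule is inserted at a uniform random position with a uniform
    random orientation and rejected if any bead comes within ``clearance``
    (minimum image) of an already-placed bead.  Deterministic under the
    spec's seed.
    """
    if spec.mode != "melt":
        raise ValueError("spec.mode must be 'melt'")
    if spec.box is None:
        raise ValueError("melt fixtures require an explicit box")
    box = np.diag(spec.box)
    rng = np.random.default_rng(spec.seed)
    mol = build_extended_molecule(spec.topology, ff)
    mol = mol - mol.mean(axis=0)
    placed: list[np.ndarray] = []
    for m in range(spec.n_molecules):
        for _attempt in range(max_attempts):
            rot = _random_rotation(rng)
            origin = rng.uniform(0, 1, 3) * np.diag(box)
            cand = mol @ rot.T + origin
            if not placed:
                break
            prev = np.vstack(placed)
            d = cand[:, None, :] - prev[None, :, :]
            d = minimum_image(d.reshape(-1, 3), box)
            if np.linalg.norm(d, axis=1).min() >= spec.clearance:
                break
        else:
            raise RuntimeError(
                f"melt insertion failed after {max_attempts} attempts: placed "
                f"{m} of {spec.n_molecules} molecules — enlarge the box or "
                "reduce the clearance"
            )
        placed.append(cand)
    return Configuration(
        positions=np.vstack(placed),
        box=box,
        topology=spec.topology,
        n_molecules=spec.n_molecules,
    )
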