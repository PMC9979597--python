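"""Observable calculations on CG trajectories and energy time series.

Covers the validation observables used for the force field: mass density,
unit-cell lattice parameters recovered from the simulation box, radial
distribution functions between bead groups, pooled bond/angle
distributions for bottom-up fitting, and bootstrap estimators for
enthalpies of fusion and vaporization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chain_mapper import TAGTopology
from .constants import AVOGADRO, GAS_CONSTANT
from .energy_eval import Configuration, minimum_image

__all__ = [
    "FrameSeries",
    "EnergySeries",
    "LatticeParams",
    "BondedDistribution",
    "density",
    "density_series",
    "lattice_params",
    "box_from_lattice",
    "rdf",
    "bonded_distributions",
    "bootstrap_mean",
    "delta_h_fus",
    "delta_h_vap",
    "relative_difference",
]

NM3_TO_CM3 = 1e-21


@dataclass
class FrameSeries:
    """Time-ordered configurations (times in ps, strictly increasing)."""

    times: np.ndarray
    frames: list[Configuration]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        counts = {f.n_beads for f in self.frames}
        if len(counts) > 1:
            raise ValueError("bead count must be constant across frames")

    def last(self, duration_ps: float) -> "FrameSeries":
        """Frames with t >= t_end - duration (inclusive window)."""
        mask = self.times >= self.times[-1] - duration_ps
        return FrameSeries(self.times[mask], [f for f, m in zip(self.frames, mask) if m])


@dataclass
class EnergySeries:
    """Time-stamped scalar samples (enthalpy or total energy, kJ/mol)."""

    times: np.ndarray
    values: np.ndarray
    label: str = "enthalpy"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must be strictly increasing")

    @classmethod
    def from_table(cls, text: str, label: str = "enthalpy") -> "EnergySeries":
        """Read a two-column (time, value) plain-text table; '#'/'@' lines skipped."""
        times, values = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line[0] in "#@;":
                continue
            t, v = line.split()[:2]
            times.append(float(t))
            values.append(float(v))
        return cls(np.array(times), np.array(values), label)

    def window(self, start_ps: float) -> np.ndarray:
        """Values with t >= start_ps (inclusive)."""
        return self.values[self.times >= start_ps]

    def last(self, duration_ps: float) -> np.ndarray:
        return self.values[self.times >= self.times[-1] - duration_ps]


@dataclass(frozen=True)
class LatticeParams:
    """Unit-cell edge lengths (nm) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180) degrees")


def density(config: Configuration, molar_mass: float | None = None) -> float:
    """Mass density in g/cm^3 of a periodic configuration.

    ``molar_mass`` is the total molar mass of the box contents (g/mol);
    by default it is taken from the topology (bead masses x molecule
    count).
    """
    if config.n_beads == 0:
        raise ValueError("cannot compute the density of an empty configuration")
    volume = config.volume
    if volume <= 0:
        raise ValueError("box volume must be positive")
    if molar_mass is None:
        molar_mass = config.topology.molar_mass * config.n_molecules
    return (molar_mass / AVOGADRO) / (volume * NM3_TO_CM3)


def density_series(series: FrameSeries, last_ps: float | None = None) -> float:
    """Mean density over the frames in the trailing time window."""
    sub = series if last_ps is None else series.last(last_ps)
    return float(np.mean([density(f) for f in sub.frames]))


def lattice_params(box: np.ndarray, stacking: tuple[int, int, int] = (5, 1, 5)) -> LatticeParams:
    """Unit-cell parameters from a (stacked) simulation box.

    The box rows are divided by the per-direction stacking counts (the
    crystal is built by replicating the unit cell, by default five times
    along a and c); lengths and the inter-vector angles alpha (b,c), beta
    (a,c) and gamma (a,b) are returned in degrees.
    """
    box = np.asarray(box, dtype=float)
    if np.any(np.diag(box) <= 0):
        raise ValueError("box diagonal must be positive")
    cell = box / np.asarray(stacking, dtype=float)[:, None]
    av, bv, cv = cell
    a, b, c = (np.linalg.norm(v) for v in cell)

    def angle(u, v):
        return math.degrees(math.acos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))

    return LatticeParams(a=a, b=b, c=c, alpha=angle(bv, cv), beta=angle(av, cv), gamma=angle(av, bv))


def box_from_lattice(cell: LatticeParams, stacking: tuple[int, int, int] = (1, 1, 1)) -> np.ndarray:
    """Lower-triangular box matrix realizing the given cell, replicated."""
    al, be, ga = (math.radians(x) for x in (cell.alpha, cell.beta, cell.gamma))
    bx = cell.b * math.cos(ga)
    by = cell.b * math.sin(ga)
    cx = cell.c * math.cos(be)
    cy = cell.c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz = math.sqrt(max(cell.c**2 - cx**2 - cy**2, 0.0))
    box = np.array([[cell.a, 0, 0], [bx, by, 0], [cx, cy, cz]])
    return box * np.asarray(stacking, dtype=float)[:, None]


def rdf(
    series: FrameSeries,
    group_a: np.ndarray,
    group_b: np.ndarray,
    bin_width: float = 0.02,
    r_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) between two bead groups.

    Minimum-image distances, shell-volume and ideal-density normalization,
    averaged over frames.  Self pairs are excluded when the groups
    overlap.  Returns bin centres and g(r).
    """
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("RDF groups must be non-empty")
    half_min_extent = min(np.diag(series.frames[0].box)) / 2.0
    if r_max is None:
        r_max = half_min_extent
    if r_max > half_min_extent + 1e-9:
        raise ValueError(
            f"r_max {r_max} exceeds half the smallest box extent ({half_min_extent:.3f} nm)"
        )
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_overlap = len(np.intersect1d(group_a, group_b))
    n_pairs = len(group_a) * len(group_b) - n_overlap
    if n_pairs <= 0:
        raise ValueError("no distinct pairs between the RDF groups")
    norm = 0.0
    for cfg in series.frames:
        d = cfg.positions[group_a][:, None, :] - cfg.positions[group_b][None, :, :]
        d = minimum_image(d.reshape(-1, 3), cfg.box)
        dist = np.linalg.norm(d, axis=1)
        if n_overlap:
            same = group_a[:, None] == group_b[None, :]
            dist = dist[~same.ravel()]
        hist += np.histogram(dist, bins=edges)[0]
        norm += n_pairs / cfg.volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (shell * norm)
    centres = 0.5 * (edges[1:] + edges[:-1])
    return centres, g


@dataclass
class BondedDistribution:
    """Pooled histogram of a bonded observable with its mean and spread."""

    centres: np.ndarray
    counts: np.ndarray
    mean: float
    std: float
    n_samples: int


def bonded_distributions(
    series: FrameSeries,
    topology: TAGTopology,
    selector: tuple[str, ...],
    bins: int = 100,
) -> BondedDistribution:
    """Pooled distribution of one bond (pair) or angle (triple) type.

    ``selector`` names bead types: two names select all matching bond
    instances (distances in nm), three names select angle instances with
    the middle name as the vertex (angles in degrees).  Samples are pooled
    over every matching instance in every molecule and frame; the mean and
    standard deviation — the two statistics the bottom-up fitting workflow
    matches — are reported alongside the histogram.
    """
    if len(selector) not in (2, 3):
        raise ValueError("selector must name two (bond) or three (angle) bead types")
    types = topology.bead_types
    if len(selector) == 2:
        wanted = tuple(sorted(selector))
        instances = [
            (i, j)
            for i, j in topology.bonds
            if tuple(sorted((types[i], types[j]))) == wanted
        ]
    else:
        lo, hi = sorted((selector[0], selector[2]))
        instances = [
            (i, j, k)
            for i, j, k in topology.angles
            if (types[j] == selector[1] and tuple(sorted((types[i], types[k]))) == (lo, hi))
        ]
    if not instances:
        raise ValueError(f"no instances of {selector} in topology {topology.molecule_name}")

    samples = []
    for cfg in series.frames:
        n = topology.n_beads
        for m in range(cfg.n_molecules):
            off = m * n
            for inst in instances:
                if len(inst) == 2:
                    i, j = inst
                    d = minimum_image(cfg.positions[off + j] - cfg.positions[off + i], cfg.box)
                    samples.append(float(np.linalg.norm(d)))
                else:
                    i, j, k = inst
                    u = minimum_image(cfg.positions[off + i] - cfg.positions[off + j], cfg.box)
                    v = minimum_image(cfg.positions[off + k] - cfg.positions[off + j], cfg.box)
                    cos_t = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                    samples.append(math.degrees(math.acos(np.clip(cos_t, -1, 1))))
    arr = np.asarray(samples)
    counts, edges = np.histogram(arr, bins=bins)
    return BondedDistribution(
        centres=0.5 * (edges[1:] + edges[:-1]),
        counts=counts,
        mean=float(arr.mean()),
        std=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n_samples=len(arr),
    )


def bootstrap_mean(
    series: EnergySeries,
    window_start: float = -np.inf,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap mean and 95% percentile CI of the samples with t >= window_start."""
    values = series.window(window_start)
    if len(values) < 2:
        raise ValueError("bootstrap window must contain at least two samples")
    rng = np.random.default_rng(seed)
    means = rng.choice(values, size=(n_boot, len(values)), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(values.mean()), (float(lo), float(hi))


def delta_h_fus(
    melt: EnergySeries,
    crystal: EnergySeries,
    window_start: float = -np.inf,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Enthalpy of fusion: mean enthalpy of the melt minus the crystal.

    Both series are bootstrap-resampled independently; the CI is the 95%
    percentile interval of the resampled differences.  Repeated runs can
    be aggregated by averaging the returned estimates.
    """
    m = melt.window(window_start)
    c = crystal.window(window_start)
    if len(m) < 2 or len(c) < 2:
        raise ValueError("both series must have at least two samples in the window")
    rng = np.random.default_rng(seed)
    bm = rng.choice(m, size=(n_boot, len(m)), replace=True).mean(axis=1)
    bc = rng.choice(c, size=(n_boot, len(c)), replace=True).mean(axis=1)
    lo, hi = np.percentile(bm - bc, [2.5, 97.5])
    return float(m.mean() - c.mean()), (float(lo), float(hi))


def delta_h_vap(u_gas: float, u_liq: float, temperature: float) -> float:
    """Enthalpy of vaporization: U_gas - U_liq + RT (kJ/mol).

    ``u_gas`` and ``u_liq`` are molar total energies of the gas-phase
    (single molecule, NVT) and liquid (NPT) systems.
    """
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return u_gas - u_liq + GAS_CONSTANT * temperature / 1000.0


def relative_difference(simulated: float, reference: float) -> float:
    """Percent deviation from a reference value: 100 (sim - ref) / ref."""
    return 100.0 * (simulated - reference) / reference
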