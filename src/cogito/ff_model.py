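"""Force-field data model for the COGITO coarse-grained TAG force field.

The model consists of nine bead types (glycerol-ester beads for the three
sn positions, an alkene bead, two- and three-carbon aliphatic beads with
and without an ester-adjacent variant, and a terminal bead), a harmonic
bond table, a GROMOS-96 cosine angle table, and per-bead Lennard-Jones
parameters combined with Lorentz-Berthelot mixing rules.  Non-bonded
interactions between first bonded neighbours are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

from .constants import ATOMIC_WEIGHTS, COULOMB_CONSTANT, DEFAULT_CUTOFF

__all__ = [
    "BeadType",
    "BondParam",
    "AngleParam",
    "LJParam",
    "ForceFieldModel",
    "UnparameterizedInteractionError",
    "bead_mass",
    "canonical_model",
]

#: Accepted spelling variants for bead names.  The sn-2 glycerol-ester bead
#: is written "2CHOCO" in the parameter tables but "CHOCO" in running text.
BEAD_ALIASES: dict[str, str] = {"CHOCO": "2CHOCO"}


class UnparameterizedInteractionError(KeyError):
    """Raised when a bond/angle/LJ lookup has no parameter table entry."""


def _canonical_name(name: str) -> str:
    return BEAD_ALIASES.get(name, name)


def bead_mass(composition: Mapping[str, int]) -> float:
    """Mass (g/mol) of a bead from its atomic composition.

    The sum of standard atomic weights over the composition, rounded to
    three decimals (the precision of the canonical bead-mass table).

    Parameters
    ----------
    composition : mapping of element symbol to non-negative integer count.

    Raises
    ------
    ValueError
        If the composition contains an element without a tabulated weight,
        or a negative/non-integer count.
    """
    total = 0.0
    for element, count in composition.items():
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in bead composition")
        if count != int(count) or count < 0:
            raise ValueError(f"invalid count {count!r} for element {element!r}")
        total += count * ATOMIC_WEIGHTS[element]
    return round(total, 3)


@dataclass(frozen=True)
class BeadType:
    """One CG bead type: name, heavy-atom composition, mass and charge."""

    name: str
    composition: tuple[tuple[str, int], ...] | None
    mass: float
    charge: float

    @classmethod
    def from_composition(
        cls, name: str, composition: Mapping[str, int], charge: float
    ) -> "BeadType":
        return cls(
            name=name,
            composition=tuple(sorted(composition.items())),
            mass=bead_mass(composition),
            charge=charge,
        )

    @property
    def composition_dict(self) -> dict[str, int] | None:
        if self.composition is None:
            return None
        return dict(self.composition)


@dataclass(frozen=True)
class BondParam:
    """Harmonic bond row: V(r) = 1/2 k_b (r - r_eq)^2."""

    bead_i: str
    bead_j: str
    r_eq: float  # nm
    k_b: float  # kJ mol^-1 nm^-2

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.bead_i, self.bead_j)))  # type: ignore[return-value]


@dataclass(frozen=True)
class AngleParam:
    """G96 cosine angle row: V(theta) = 1/2 k_theta (cos theta - cos theta_eq)^2.

    ``bead_j`` is the vertex; lookup is symmetric under swapping the outer
    beads.  ``theta_eq`` is stored in degrees.
    """

    bead_i: str
    bead_j: str
    bead_k: str
    theta_eq: float  # degrees
    k_theta: float  # kJ mol^-1

    def key(self) -> tuple[str, str, str]:
        lo, hi = sorted((self.bead_i, self.bead_k))
        return (lo, self.bead_j, hi)

    @property
    def theta_eq_rad(self) -> float:
        return math.radians(self.theta_eq)

    @property
    def cos_theta_eq(self) -> float:
        return math.cos(self.theta_eq_rad)


@dataclass(frozen=True)
class LJParam:
    """Per-bead Lennard-Jones parameters (sigma in nm, epsilon in kJ/mol)."""

    bead: str
    sigma: float
    epsilon: float


@dataclass
class ForceFieldModel:
    """A complete parameter set: beads, bonds, angles, LJ, and conventions."""

    beads: dict[str, BeadType]
    bonds: dict[tuple[str, str], BondParam]
    angles: dict[tuple[str, str, str], AngleParam]
    lj: dict[str, LJParam]
    cutoff: float = DEFAULT_CUTOFF
    coulomb_constant: float = COULOMB_CONSTANT

    # -- construction -------------------------------------------------

    @classmethod
    def from_tables(
        cls,
        beads: Iterable[BeadType],
        bonds: Iterable[BondParam],
        angles: Iterable[AngleParam],
        lj: Iterable[LJParam],
        cutoff: float = DEFAULT_CUTOFF,
    ) -> "ForceFieldModel":
        return cls(
            beads={b.name: b for b in beads},
            bonds={b.key(): b for b in bonds},
            angles={a.key(): a for a in angles},
            lj={p.bead: p for p in lj},
            cutoff=cutoff,
        )

    def with_lj(self, lj_values: Mapping[str, tuple[float, float]]) -> "ForceFieldModel":
        """Copy of the model with LJ parameters replaced (used by the optimizer)."""
        new_lj = dict(self.lj)
        for name, (sigma, epsilon) in lj_values.items():
            new_lj[_canonical_name(name)] = LJParam(_canonical_name(name), sigma, epsilon)
        return replace(self, lj=new_lj)

    # -- lookups ------------------------------------------------------

    def bead(self, name: str) -> BeadType:
        name = _canonical_name(name)
        try:
            return self.beads[name]
        except KeyError:
            raise UnparameterizedInteractionError(f"unknown bead type {name!r}") from None

    def lookup_bond(self, bead_a: str, bead_b: str) -> BondParam:
        """Bond parameters for the (unordered) bead pair."""
        key = tuple(sorted((_canonical_name(bead_a), _canonical_name(bead_b))))
        try:
            return self.bonds[key]  # type: ignore[index]
        except KeyError:
            raise UnparameterizedInteractionError(
                f"unparameterized interaction: no bond row for {bead_a}-{bead_b}"
            ) from None

    def has_bond(self, bead_a: str, bead_b: str) -> bool:
        key = tuple(sorted((_canonical_name(bead_a), _canonical_name(bead_b))))
        return key in self.bonds

    def lookup_angle(self, bead_a: str, bead_b: str, bead_c: str) -> AngleParam:
        """Angle parameters; ``bead_b`` is the vertex, outer order irrelevant."""
        a, b, c = (_canonical_name(x) for x in (bead_a, bead_b, bead_c))
        lo, hi = sorted((a, c))
        try:
            return self.angles[(lo, b, hi)]
        except KeyError:
            raise UnparameterizedInteractionError(
                f"unparameterized interaction: no angle row for {bead_a}-{bead_b}-{bead_c}"
            ) from None

    def lookup_lj(self, bead: str) -> LJParam:
        name = _canonical_name(bead)
        try:
            return self.lj[name]
        except KeyError:
            raise UnparameterizedInteractionError(
                f"unparameterized interaction: no LJ entry for bead {bead!r}"
            ) from None

    def mix_lj(self, bead_a: str, bead_b: str) -> tuple[float, float]:
        """Lorentz-Berthelot cross parameters (sigma_ab, epsilon_ab).

        sigma by arithmetic mean, epsilon by geometric mean.
        """
        pa, pb = self.lookup_lj(bead_a), self.lookup_lj(bead_b)
        return (pa.sigma + pb.sigma) / 2.0, math.sqrt(pa.epsilon * pb.epsilon)

    # -- validation ----------------------------------------------------

    def validate(self) -> list[str]:
        """Check model invariants; returns a list of human-readable violations.

        The canonical model must produce an empty list: nine bead types,
        one LJ row per bead (18 free scalars), masses consistent with the
        compositions, charges from {-0.05, 0, +0.05}, positive force
        constants, physical equilibrium values, and no bond/angle row that
        names an undefined bead.
        """
        problems: list[str] = []
        if len(self.beads) != 9:
            problems.append(f"expected 9 bead types, found {len(self.beads)}")
        for bead in self.beads.values():
            if bead.composition is not None:
                expected = bead_mass(bead.composition_dict)
                if abs(expected - bead.mass) > 5e-4:
                    problems.append(
                        f"bead {bead.name}: mass {bead.mass} != {expected} from composition"
                    )
            if round(bead.charge, 6) not in (-0.05, 0.0, 0.05):
                problems.append(f"bead {bead.name}: charge {bead.charge} not in {{-0.05,0,0.05}}")
        for key, bond in self.bonds.items():
            for name in key:
                if name not in self.beads:
                    problems.append(f"bond row {key} names undefined bead {name!r}")
            if bond.r_eq <= 0:
                problems.append(f"bond row {key}: r_eq must be positive")
            if bond.k_b <= 0:
                problems.append(f"bond row {key}: k_b must be positive")
        for akey, angle in self.angles.items():
            for name in akey:
                if name not in self.beads:
                    problems.append(f"angle row {akey} names undefined bead {name!r}")
            if not 0 < angle.theta_eq < 180:
                problems.append(f"angle row {akey}: theta_eq must lie in (0, 180)")
            if angle.k_theta <= 0:
                problems.append(f"angle row {akey}: k_theta must be positive")
        if len(self.lj) != len(self.beads):
            problems.append(
                f"expected one LJ entry per bead ({len(self.beads)}), found {len(self.lj)}"
            )
        for name, p in self.lj.items():
            if name not in self.beads:
                problems.append(f"LJ entry names undefined bead {name!r}")
            if p.sigma <= 0 or p.epsilon <= 0:
                problems.append(f"LJ entry {name}: sigma and epsilon must be positive")
        if self.cutoff <= 0:
            problems.append("cutoff must be positive")
        return problems

    @property
    def n_lj_parameters(self) -> int:
        """Number of free LJ scalars (sigma and epsilon per bead)."""
        return 2 * len(self.lj)


# ---------------------------------------------------------------------------
# canonical tables


def _read_table(filename: str) -> list[dict[str, str]]:
    text = resources.files("cogito.data").joinpath(filename).read_text()
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rows.append(dict(zip(header, fields)))
    return rows


def _parse_composition(text: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for part in text.split(","):
        element, count = part.split(":")
        out[element.strip()] = int(count)
    return out


def canonical_model() -> ForceFieldModel:
    """The published COGITO parameter set, loaded from the packaged tables."""
    beads = [
        BeadType.from_composition(
            row["name"], _parse_composition(row["composition"]), float(row["charge"])
        )
        for row in _read_table("beads.tsv")
    ]
    bonds = [
        BondParam(row["bead_i"], row["bead_j"], float(row["r_eq"]), float(row["k_b"]))
        for row in _read_table("bonds.tsv")
    ]
    angles = [
        AngleParam(
            row["bead_i"],
            row["bead_j"],
            row["bead_k"],
            float(row["theta_eq"]),
            float(row["k_theta"]),
        )
        for row in _read_table("angles.tsv")
    ]
    lj = [
        LJParam(row["bead"], float(row["sigma"]), float(row["epsilon"]))
        for row in _read_table("lj.tsv")
    ]
    return ForceFieldModel.from_tables(beads, bonds, angles, lj)
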