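"""Coarse-grained topology construction for arbitrary triacylglycerides.

A TAG is glycerol esterified with three fatty-acid chains at the sn-1,
sn-2 and sn-3 positions.  Each glycerol carbon together with its ester
group (including the chain's carbonyl carbon, C1 in acid numbering) forms
one glycerol-ester bead; the remaining chain carbons are decomposed into
two- and three-carbon beads, with each C=C double bond represented by a
dedicated CHCH bead flanked by C3H6 beads.

The decomposition of a chain is found by exhaustive depth-first search
over bead sequences whose consecutive pairs all have a bond-parameter row,
selecting among complete solutions by (1) fewest two-carbon beads,
(2) C2H4E preferred over C3H6E as the attachment bead, and (3) C2H4 beads
placed nearest the glycerol end.  This rule reproduces the published
arachidic-acid mapping and yields the unique oleic decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ff_model import ForceFieldModel, UnparameterizedInteractionError

__all__ = [
    "FattyAcidSpec",
    "TAGTopology",
    "ChainMappingError",
    "map_chain",
    "build_tag",
    "cog_map",
    "parse_chain_notation",
]

#: carbons absorbed by each chain bead type
BEAD_CARBONS = {"C2H4E": 2, "C2H4": 2, "C3H6E": 3, "C3H6": 3, "C3H7T": 3, "CHCH": 2}
ATTACHMENT_BEADS = ("C2H4E", "C3H6E")
GLYCEROL_BEADS = ("1CH2OCO", "2CHOCO", "3CH2OCO")


class ChainMappingError(ValueError):
    """No legal bead decomposition exists for a fatty-acid chain."""


@dataclass(frozen=True)
class FattyAcidSpec:
    """A fatty-acid chain: carbon count and double-bond list.

    Carbons use acid (delta) numbering with C1 the carbonyl carbon, which
    is absorbed into the glycerol-ester bead.  A double bond at position p
    joins carbons p and p+1; geometry ("cis" or "trans") is recorded as
    metadata only — the parameter tables carry a single CHCH bead.
    """

    n_carbons: int
    double_bonds: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.n_carbons < 7:
            raise ValueError(f"chains shorter than 7 carbons are unsupported (got {self.n_carbons})")
        object.__setattr__(
            self, "double_bonds", tuple(sorted((int(p), g) for p, g in self.double_bonds))
        )
        prev_end = 1  # C1 belongs to the ester bead
        for pos, geometry in self.double_bonds:
            if geometry not in ("cis", "trans"):
                raise ValueError(f"double-bond geometry must be cis or trans, got {geometry!r}")
            if not 2 <= pos <= self.n_carbons - 2:
                raise ValueError(
                    f"double-bond position {pos} outside [2, {self.n_carbons - 2}]"
                )
            if pos - prev_end < 4:
                raise ValueError(
                    f"double bond at {pos} too close to previous feature at carbon {prev_end}:"
                    " each CHCH bead needs a three-carbon flank"
                )
            prev_end = pos + 1
        if self.double_bonds and self.n_carbons - (self.double_bonds[-1][0] + 1) < 3:
            raise ValueError(
                "last double bond too close to the methyl end: CHCH needs a three-carbon flank"
            )

    @property
    def double_bond_positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.double_bonds)

    def __str__(self) -> str:
        if not self.double_bonds:
            return f"{self.n_carbons}:0"
        tags = "".join(f"{'c' if g == 'cis' else 't'}{p}" for p, g in self.double_bonds)
        return f"{self.n_carbons}:{len(self.double_bonds)}{tags}"


def parse_chain_notation(text: str) -> FattyAcidSpec:
    """Parse shorthand like ``"16:0"``, ``"18:1c9"`` or ``"18:2c9c12"``.

    The carbon count and double-bond count are separated by a colon; each
    double bond is given as ``c<pos>`` (cis) or ``t<pos>`` (trans) in acid
    numbering.
    """
    try:
        head, tail = text.strip().split(":")
        n_carbons = int(head)
        import re

        bonds = re.findall(r"([ct])(\d+)", tail)
        n_db = int(re.match(r"(\d+)", tail).group(1))  # type: ignore[union-attr]
    except (ValueError, AttributeError):
        raise ValueError(f"cannot parse chain notation {text!r}") from None
    if len(bonds) != n_db:
        raise ValueError(
            f"chain {text!r}: {n_db} double bonds declared but {len(bonds)} positions given"
        )
    return FattyAcidSpec(
        n_carbons, tuple((int(p), "cis" if c == "c" else "trans") for c, p in bonds)
    )


def map_chain(spec: FattyAcidSpec, ff: ForceFieldModel | None = None) -> list[str]:
    """Decompose a fatty-acid chain into an ordered bead-type list.

    The carbonyl carbon C1 is absorbed into the glycerol-ester bead and is
    not represented in the returned list.  The first bead is an attachment
    bead (C2H4E or C3H6E), the last is the terminal C3H7T, and each CHCH
    bead covers exactly its two double-bond carbons.  Every consecutive
    bead pair is guaranteed to have a bond-parameter row.

    Raises :class:`ChainMappingError` when no decomposition satisfies the
    adjacency table (e.g. a 7-carbon chain, or a double bond whose flanks
    cannot be completed).
    """
    from .ff_model import canonical_model

    if ff is None:
        ff = canonical_model()
    n_chain = spec.n_carbons - 1  # carbons 2..n
    db_starts = set(spec.double_bond_positions)
    db_carbons = set()
    for p in db_starts:
        db_carbons.update((p, p + 1))

    solutions: list[list[str]] = []

    def step(carbon: int, seq: list[str]) -> None:
        # carbon = next unassigned carbon in acid numbering (first is 2)
        remaining = spec.n_carbons - carbon + 1
        if remaining == 0:
            if seq[-1] == "C3H7T":
                solutions.append(list(seq))
            return
        if carbon in db_starts:
            candidates = ["CHCH"]
        elif not seq:
            candidates = list(ATTACHMENT_BEADS)
        else:
            candidates = ["C2H4", "C3H6", "C3H7T"]
        for bead in candidates:
            size = BEAD_CARBONS[bead]
            if size > remaining:
                continue
            covered = range(carbon, carbon + size)
            if bead != "CHCH" and any(c in db_carbons for c in covered):
                continue
            if bead == "C3H7T" and size != remaining:
                continue
            if seq and not ff.has_bond(seq[-1], bead):
                continue
            seq.append(bead)
            step(carbon + size, seq)
            seq.pop()

    step(2, [])
    if not solutions:
        raise ChainMappingError(
            f"no legal bead decomposition for chain {spec}: "
            "no sequence of two-/three-carbon beads satisfies the bond table"
            " (chain too short, or a double bond too close to an end)"
        )

    def preference(seq: list[str]) -> tuple:
        n_two = sum(1 for b in seq if b in ("C2H4E", "C2H4"))
        attach = 0 if seq[0] == "C2H4E" else 1
        c2h4_positions = tuple(i for i, b in enumerate(seq) if b == "C2H4")
        return (n_two, attach, c2h4_positions, tuple(seq))

    assert sum(BEAD_CARBONS[b] for b in min(solutions, key=preference)) == n_chain
    return min(solutions, key=preference)


@dataclass
class TAGTopology:
    """CG topology of one TAG molecule.

    Beads 0..2 are the glycerol-ester backbone (1CH2OCO, 2CHOCO, 3CH2OCO);
    the three chains follow in sn order.  The bond graph is a tree, angles
    are all bonded triples, and non-bonded exclusions are exactly the
    bonded pairs (one-bond exclusion rule).
    """

    molecule_name: str
    bead_types: list[str]
    charges: list[float]
    masses: list[float]
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]]
    sn_positions: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    @property
    def exclusions(self) -> list[tuple[int, int]]:
        """Non-bonded exclusions: first bonded neighbours only."""
        return list(self.bonds)

    @property
    def molar_mass(self) -> float:
        return float(sum(self.masses))

    @property
    def net_charge(self) -> float:
        return float(sum(self.charges))


def _enumerate_angles(n_beads: int, bonds: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    neighbours: list[list[int]] = [[] for _ in range(n_beads)]
    for i, j in bonds:
        neighbours[i].append(j)
        neighbours[j].append(i)
    angles = []
    for j in range(n_beads):
        nb = sorted(neighbours[j])
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    return angles


def build_tag(
    name: str,
    sn1: FattyAcidSpec,
    sn2: FattyAcidSpec,
    sn3: FattyAcidSpec,
    ff: ForceFieldModel,
) -> TAGTopology:
    """Assemble the full CG topology of a TAG from its three chain specs.

    Every bond and angle in the resulting tree is validated against the
    force-field tables; an unsupported adjacency raises
    :class:`~cogito.ff_model.UnparameterizedInteractionError`.
    """
    bead_types = list(GLYCEROL_BEADS)
    bonds: list[tuple[int, int]] = [(0, 1), (1, 2)]
    sn_positions: dict[str, list[int]] = {}
    for sn_index, (sn_name, spec) in enumerate(
        (("sn-1", sn1), ("sn-2", sn2), ("sn-3", sn3))
    ):
        chain = map_chain(spec, ff)
        start = len(bead_types)
        bead_types.extend(chain)
        chain_indices = list(range(start, start + len(chain)))
        sn_positions[sn_name] = chain_indices
        bonds.append((sn_index, start))  # glycerol bead -> attachment bead
        bonds.extend((k, k + 1) for k in chain_indices[:-1])

    angles = _enumerate_angles(len(bead_types), bonds)
    # validate all terms against the force field (raises on absent rows)
    for i, j in bonds:
        ff.lookup_bond(bead_types[i], bead_types[j])
    for i, j, k in angles:
        ff.lookup_angle(bead_types[i], bead_types[j], bead_types[k])

    charges = [ff.bead(t).charge for t in bead_types]
    masses = [ff.bead(t).mass for t in bead_types]
    return TAGTopology(
        molecule_name=name,
        bead_types=bead_types,
        charges=charges,
        masses=masses,
        bonds=bonds,
        angles=angles,
        sn_positions=sn_positions,
    )


def cog_map(atom_positions: np.ndarray, mapping: list[list[int]]) -> np.ndarray:
    """Map atomistic coordinates onto CG beads by centre of geometry.

    Each bead position is the unweighted mean of its atom group's
    coordinates (centre of geometry, not centre of mass).

    Parameters
    ----------
    atom_positions : (n_atoms, 3) array.
    mapping : per-bead lists of atom indices.
    """
    atom_positions = np.asarray(atom_positions, dtype=float)
    if not np.all(np.isfinite(atom_positions)):
        raise ValueError("atom positions must be finite")
    out = np.empty((len(mapping), 3))
    for b, group in enumerate(mapping):
        if len(group) == 0:
            raise ValueError(f"bead {b}: empty atom group in CoG mapping")
        out[b] = atom_positions[np.asarray(group, dtype=int)].mean(axis=0)
    return out
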