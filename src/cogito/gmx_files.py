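"""Readers and writers for the GROMACS text formats the force field touches.

Three dialects are covered:

* ``.gro`` fixed-width coordinate frames (positions on a 3-decimal grid,
  3- or 9-float box line);
* force-field ``.itp`` with ``[defaults]``, ``[atomtypes]``,
  ``[bondtypes]`` and ``[angletypes]`` sections (bond function 1 =
  harmonic, angle function 2 = GROMOS-96 cosine, combination rule 2 =
  Lorentz-Berthelot on sigma/epsilon);
* molecule ``.itp`` (``nrexcl 1`` encodes the one-bond exclusion rule)
  and system ``.top`` files.

Write/read round trips preserve every parameter digit-for-digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain_mapper import TAGTopology, _enumerate_angles
from .ff_model import (
    AngleParam,
    BeadType,
    BondParam,
    ForceFieldModel,
    LJParam,
)

__all__ = [
    "GroFrame",
    "GroParseError",
    "read_gro",
    "write_gro",
    "read_gro_frames",
    "write_ff_itp",
    "read_ff_itp",
    "write_itp",
    "read_itp",
    "write_top",
    "frame_from_configuration",
]


class GroParseError(ValueError):
    """Malformed .gro content; carries the 1-based offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class GroFrame:
    """One .gro coordinate frame."""

    title: str
    residue_numbers: list[int]
    residue_names: list[str]
    atom_names: list[str]
    positions: np.ndarray  # (N, 3) nm
    velocities: np.ndarray | None = None
    box: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    @property
    def n_atoms(self) -> int:
        return len(self.positions)


def read_gro(text: str, start_line: int = 1) -> GroFrame:
    """Parse a single .gro frame from text."""
    lines = text.splitlines()
    frame, consumed = _parse_frame(lines, 0, start_line)
    return frame


def read_gro_frames(text: str) -> list[GroFrame]:
    """Parse a concatenated multi-frame .gro file (trajectory dump)."""
    lines = text.splitlines()
    frames = []
    offset = 0
    while offset < len(lines) and lines[offset].strip() != "":
        frame, consumed = _parse_frame(lines, offset, offset + 1)
        frames.append(frame)
        offset += consumed
    return frames


def _parse_frame(lines: list[str], offset: int, line0: int) -> tuple[GroFrame, int]:
    if offset + 2 > len(lines):
        raise GroParseError("truncated frame: missing title/count lines", line0)
    title = lines[offset]
    try:
        n_atoms = int(lines[offset + 1].strip())
    except ValueError:
        raise GroParseError(
            f"expected atom count, got {lines[offset + 1]!r}", line0 + 1
        ) from None
    if offset + 2 + n_atoms + 1 > len(lines):
        raise GroParseError(
            f"header declares {n_atoms} atoms but the frame is truncated",
            line0 + 1,
        )
    res_nums, res_names, atom_names = [], [], []
    pos = np.empty((n_atoms, 3))
    vel = np.empty((n_atoms, 3))
    has_vel = None
    for k in range(n_atoms):
        line = lines[offset + 2 + k]
        lineno = line0 + 2 + k
        if len(line) < 44:
            raise GroParseError(
                f"atom record too short ({len(line)} chars; need >= 44)", lineno
            )
        try:
            res_nums.append(int(line[0:5]))
            res_names.append(line[5:10].strip())
            atom_names.append(line[10:15].strip())
            pos[k] = [float(line[20 + 8 * d : 28 + 8 * d]) for d in range(3)]
        except ValueError:
            raise GroParseError(f"malformed atom record {line!r}", lineno) from None
        if len(line) >= 68:
            if has_vel is False:
                raise GroParseError("inconsistent velocity columns", lineno)
            has_vel = True
            try:
                vel[k] = [float(line[44 + 8 * d : 52 + 8 * d]) for d in range(3)]
            except ValueError:
                raise GroParseError(f"malformed velocity fields {line!r}", lineno) from None
        else:
            if has_vel is True:
                raise GroParseError("inconsistent velocity columns", lineno)
            has_vel = False
    box_line = lines[offset + 2 + n_atoms]
    box_lineno = line0 + 2 + n_atoms
    try:
        vals = [float(x) for x in box_line.split()]
    except ValueError:
        raise GroParseError(f"malformed box line {box_line!r}", box_lineno) from None
    box = np.zeros((3, 3))
    if len(vals) == 3:
        box[0, 0], box[1, 1], box[2, 2] = vals
    elif len(vals) == 9:
        # v1(x) v2(y) v3(z) v1(y) v1(z) v2(x) v2(z) v3(x) v3(y)
        (box[0, 0], box[1, 1], box[2, 2],
         box[0, 1], box[0, 2], box[1, 0],
         box[1, 2], box[2, 0], box[2, 1]) = vals
    else:
        raise GroParseError(
            f"box line must have 3 or 9 floats, found {len(vals)}", box_lineno
        )
    frame = GroFrame(
        title=title,
        residue_numbers=res_nums,
        residue_names=res_names,
        atom_names=atom_names,
        positions=pos,
        velocities=vel if has_vel else None,
        box=box,
    )
    return frame, 2 + n_atoms + 1


def write_gro(frame: GroFrame) -> str:
    """Serialize a frame in fixed-width .gro format (3-decimal positions)."""
    out = [frame.title, f"{frame.n_atoms:5d}"]
    for k in range(frame.n_atoms):
        rec = (
            f"{frame.residue_numbers[k] % 100000:5d}"
            f"{frame.residue_names[k]:<5.5s}"
            f"{frame.atom_names[k]:>5.5s}"
            f"{(k + 1) % 100000:5d}"
            + "".join(f"{frame.positions[k, d]:8.3f}" for d in range(3))
        )
        if frame.velocities is not None:
            rec += "".join(f"{frame.velocities[k, d]:8.4f}" for d in range(3))
        out.append(rec)
    b = frame.box
    if np.allclose([b[0, 1], b[0, 2], b[1, 0], b[1, 2], b[2, 0], b[2, 1]], 0.0):
        out.append(f"{b[0, 0]:10.5f}{b[1, 1]:10.5f}{b[2, 2]:10.5f}")
    else:
        vals = (b[0, 0], b[1, 1], b[2, 2], b[0, 1], b[0, 2],
                b[1, 0], b[1, 2], b[2, 0], b[2, 1])
        out.append("".join(f"{v:10.5f}" for v in vals))
    return "\n".join(out) + "\n"


def frame_from_configuration(config, title: str = "") -> GroFrame:
    """Build a GroFrame from a Configuration (one residue per molecule)."""
    topo = config.topology
    resname = topo.molecule_name[:5] or "MOL"
    n = topo.n_beads
    res_nums, res_names, atom_names = [], [], []
    for m in range(config.n_molecules):
        res_nums.extend([m + 1] * n)
        res_names.extend([resname] * n)
        atom_names.extend(t[:5] for t in topo.bead_types)
    return GroFrame(
        title=title or f"{topo.molecule_name} x {config.n_molecules}",
        residue_numbers=res_nums,
        residue_names=res_names,
        atom_names=atom_names,
        positions=np.asarray(config.positions, dtype=float),
        box=np.asarray(config.box, dtype=float),
    )


# ---------------------------------------------------------------------------
# topology / parameter files

_FF_HEADER = "; COGITO coarse-grained TAG force field\n"


def _fmt(x: float) -> str:
    """Format a parameter preserving its printed precision (no trailing noise)."""
    return f"{x:.6g}"


def write_ff_itp(ff: ForceFieldModel) -> str:
    """Emit the full parameter set as a GROMACS force-field .itp."""
    lines = [_FF_HEADER]
    lines.append("[ defaults ]")
    lines.append("; nbfunc comb-rule gen-pairs fudgeLJ fudgeQQ")
    lines.append("  1      2         no        1.0     1.0")
    lines.append("")
    lines.append("[ atomtypes ]")
    lines.append("; name  mass      charge   ptype  sigma    epsilon")
    for name in sorted(ff.beads):
        bead = ff.beads[name]
        lj = ff.lookup_lj(name)
        lines.append(
            f"  {name:<8s} {bead.mass:<9.3f} {bead.charge:<8.2f} A "
            f"{_fmt(lj.sigma):>8s} {_fmt(lj.epsilon):>8s}"
        )
    lines.append("")
    lines.append("[ bondtypes ]")
    lines.append("; i        j        funct  r_eq    k_b")
    for key in sorted(ff.bonds):
        b = ff.bonds[key]
        lines.append(
            f"  {b.bead_i:<8s} {b.bead_j:<8s} 1      {b.r_eq:.3f}  {_fmt(b.k_b)}"
        )
    lines.append("")
    lines.append("[ angletypes ]")
    lines.append("; i        j        k        funct  theta_eq  k_theta")
    for key in sorted(ff.angles):
        a = ff.angles[key]
        lines.append(
            f"  {a.bead_i:<8s} {a.bead_j:<8s} {a.bead_k:<8s} 2      "
            f"{_fmt(a.theta_eq):<9s} {_fmt(a.k_theta)}"
        )
    lines.append("")
    return "\n".join(lines)


def _sections(text: str):
    """Split GROMACS topology text into (section, data-line) pairs."""
    current = None
    for raw in text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip().lower()
            continue
        yield current, line


def read_ff_itp(text: str) -> ForceFieldModel:
    """Parse a force-field .itp back into a ForceFieldModel.

    Bead compositions are not part of the file format, so the returned
    bead types carry ``composition=None``; all numeric parameters are
    recovered exactly as printed.
    """
    beads, bonds, angles, lj = [], [], [], []
    for section, line in _sections(text):
        fields = line.split()
        if section == "atomtypes":
            name, mass, charge, _ptype, sigma, epsilon = fields[:6]
            beads.append(BeadType(name, None, float(mass), float(charge)))
            lj.append(LJParam(name, float(sigma), float(epsilon)))
        elif section == "bondtypes":
            i, j, funct, r_eq, k_b = fields[:5]
            if funct != "1":
                raise ValueError(f"unsupported bond function type {funct}")
            bonds.append(BondParam(i, j, float(r_eq), float(k_b)))
        elif section == "angletypes":
            i, j, k, funct, theta, k_theta = fields[:6]
            if funct != "2":
                raise ValueError(f"unsupported angle function type {funct}")
            angles.append(AngleParam(i, j, k, float(theta), float(k_theta)))
    return ForceFieldModel.from_tables(beads, bonds, angles, lj)


def write_itp(topology: TAGTopology, ff: ForceFieldModel) -> str:
    """Emit a molecule .itp with explicit bonded parameters.

    ``nrexcl 1`` encodes the one-bond non-bonded exclusion rule; bonds use
    function type 1 (harmonic) and angles function type 2 (G96 cosine).
    """
    lines = [f"; topology for {topology.molecule_name}", "[ moleculetype ]"]
    lines.append("; name            nrexcl")
    lines.append(f"  {topology.molecule_name:<16s} 1")
    lines.append("")
    lines.append("[ atoms ]")
    lines.append(";  nr  type     resnr residue atom   cgnr  charge  mass")
    resname = topology.molecule_name[:5] or "MOL"
    for i, t in enumerate(topology.bead_types):
        lines.append(
            f"  {i + 1:4d}  {t:<8s} 1     {resname:<7s} {t[:5]:<6s} {i + 1:4d}  "
            f"{topology.charges[i]:<7.2f} {topology.masses[i]:.3f}"
        )
    lines.append("")
    lines.append("[ bonds ]")
    lines.append(";  i    j  funct  r_eq   k_b")
    for i, j in topology.bonds:
        p = ff.lookup_bond(topology.bead_types[i], topology.bead_types[j])
        lines.append(f"  {i + 1:4d} {j + 1:4d} 1      {p.r_eq:.3f}  {_fmt(p.k_b)}")
    lines.append("")
    lines.append("[ angles ]")
    lines.append(";  i    j    k  funct  theta_eq  k_theta")
    for i, j, k in topology.angles:
        p = ff.lookup_angle(
            topology.bead_types[i], topology.bead_types[j], topology.bead_types[k]
        )
        lines.append(
            f"  {i + 1:4d} {j + 1:4d} {k + 1:4d} 2      {_fmt(p.theta_eq):<9s} {_fmt(p.k_theta)}"
        )
    lines.append("")
    return "\n".join(lines)


def read_itp(text: str) -> TAGTopology:
    """Parse a molecule .itp back into a TAGTopology.

    Angles are taken from the file; as a consistency check they must equal
    the exhaustive enumeration of bonded triples from the bond list.
    """
    name = None
    bead_types: list[str] = []
    charges: list[float] = []
    masses: list[float] = []
    bonds: list[tuple[int, int]] = []
    angles: list[tuple[int, int, int]] = []
    for section, line in _sections(text):
        fields = line.split()
        if section == "moleculetype":
            name = fields[0]
            if fields[1] != "1":
                raise ValueError(f"expected nrexcl 1, got {fields[1]}")
        elif section == "atoms":
            bead_types.append(fields[1])
            charges.append(float(fields[6]))
            masses.append(float(fields[7]))
        elif section == "bonds":
            bonds.append((int(fields[0]) - 1, int(fields[1]) - 1))
        elif section == "angles":
            angles.append((int(fields[0]) - 1, int(fields[1]) - 1, int(fields[2]) - 1))
    if name is None:
        raise ValueError("no [ moleculetype ] section found")
    expected = {tuple(sorted((i, k))) + (j,) for i, j, k in _enumerate_angles(len(bead_types), bonds)}
    found = {tuple(sorted((i, k))) + (j,) for i, j, k in angles}
    if expected != found:
        raise ValueError("angle list does not match the bonded triples of the bond graph")
    topo = TAGTopology(
        molecule_name=name,
        bead_types=bead_types,
        charges=charges,
        masses=masses,
        bonds=bonds,
        angles=angles,
    )
    return topo


def write_top(
    molecules: list[tuple[TAGTopology, int]],
    ff: ForceFieldModel,
    system_name: str = "COGITO system",
) -> str:
    """Emit a self-contained system .top (parameters + molecules + counts)."""
    if not molecules:
        raise ValueError("cannot write a topology for an empty system")
    parts = [write_ff_itp(ff)]
    for topo, _count in molecules:
        parts.append(write_itp(topo, ff))
    parts.append("[ system ]")
    parts.append(f"  {system_name}")
    parts.append("")
    parts.append("[ molecules ]")
    parts.append("; name            count")
    for topo, count in molecules:
        parts.append(f"  {topo.molecule_name:<16s} {count}")
    parts.append("")
    return "\n".join(parts)
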