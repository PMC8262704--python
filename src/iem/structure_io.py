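"""PDB structure parsing and the chain/residue/atom object model.

Structures are read with :mod:`gemmi` and flattened into a small, explicit
hierarchy that the rest of the package consumes.  Only the first model of
multi-model (e.g. NMR) files is kept, and alternate locations are resolved
to the highest-occupancy conformer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Literal

import gemmi
import numpy as np

from ._residues import BACKBONE_ATOM_NAMES, STANDARD_AMINO_ACIDS, THREE_TO_ONE
from .errors import EmptyStructureError, InputError, UsageError

Subgroup = Literal["all", "backbone", "sidechain"]
SUBGROUPS = ("all", "backbone", "sidechain")


@dataclass(frozen=True)
class Atom:
    """A single atom: name, element, Cartesian position (Å), mass (Da)."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Å
    mass: float
    serial: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.mass <= 0:
            raise ValueError(f"atom {self.name!r}: mass must be positive")
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass(frozen=True)
class ResidueKey:
    """Identity of a residue: chain, author seq number, insertion code, name."""

    chain_id: str
    seq_number: int
    insertion_code: str
    residue_name: str

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.seq_number}:{self.insertion_code}:{self.residue_name}"


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[Atom]
    is_hetero: bool = False

    @property
    def name(self) -> str:
        return self.key.residue_name

    @property
    def is_standard(self) -> bool:
        return self.key.residue_name in STANDARD_AMINO_ACIDS

    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    chains: list[Chain]
    title: str = ""

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties by first record."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    # preserve file order of the winning records
    seen: set[str] = set()
    out = []
    for atom in res:
        if atom.name in seen:
            continue
        if chosen[atom.name] is atom:
            out.append(atom)
            seen.add(atom.name)
    return out


def parse_pdb(path: str | os.PathLike) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Only model 1 is kept.  Alternate locations resolve to the
    highest-occupancy record (ties: first encountered).  HETATM residues
    are retained and flagged ``is_hetero``; downstream parameter
    assignment will list their atoms as unassigned.

    Raises
    ------
    InputError
        If the file cannot be read.
    EmptyStructureError
        If it contains no ATOM/HETATM coordinate records.
    """
    try:
        st = gemmi.read_structure(os.fspath(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise InputError(f"cannot read PDB file {path!r}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path!r}: no coordinate records")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        chain = Chain(chain_id=gchain.name.strip() or "A")
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            key = ResidueKey(chain.chain_id, gres.seqid.num, icode, gres.name.strip())
            atoms = []
            for ga in _resolve_altlocs(gres):
                elem = ga.element.name if ga.element else ""
                mass = ga.element.weight if ga.element and ga.element.weight > 0 else 1.0
                atoms.append(
                    Atom(
                        name=ga.name.strip(),
                        element=elem,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        mass=mass,
                        serial=ga.serial,
                    )
                )
            if atoms:
                chain.residues.append(
                    Residue(key=key, atoms=atoms, is_hetero=gres.het_flag == "H")
                )
        if chain.residues:
            chains.append(chain)
    if not chains:
        raise EmptyStructureError(f"{path!r}: no coordinate records")
    return Structure(chains=chains, title=st.name or "")


def _format_atom_name(name: str, element: str) -> str:
    """PDB column-13..16 alignment: 1-2 char element right-justified in 13-14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def pdb_string(structure: Structure) -> str:
    """Render a Structure in PDB fixed-column format."""
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title[:70]}")
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            record = "HETATM" if res.is_hetero else "ATOM  "
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.position
                lines.append(
                    f"{record}{serial:>5} {_format_atom_name(atom.name, atom.element)}"
                    f" {res.name:>3} {chain.chain_id[:1]}{res.key.seq_number:>4}"
                    f"{res.key.insertion_code or ' ':1}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2}"
                )
        lines.append(f"TER   {serial + 1:>5}      {chain.residues[-1].name:>3} "
                     f"{chain.chain_id[:1]}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(structure: Structure, path: str | os.PathLike) -> None:
    """Write a Structure back to PDB fixed-column format."""
    with open(path, "w") as fh:
        fh.write(pdb_string(structure))


def extract_chain_sequences(structure: Structure) -> dict[str, str]:
    """One-letter sequence per polypeptide chain, in residue file order.

    Non-standard residues map to ``'X'``.  Chains without a single standard
    amino acid (waters, ligand-only chains) are omitted.
    """
    out: dict[str, str] = {}
    for chain in structure.chains:
        seq = "".join(THREE_TO_ONE.get(r.name, "X") for r in chain.residues)
        if any(r.is_standard for r in chain.residues):
            out[chain.chain_id] = seq
    return out


def select_subgroup(
    structure: Structure, subgroup: Subgroup
) -> dict[ResidueKey, np.ndarray]:
    """Boolean atom mask per residue for ``all``/``backbone``/``sidechain``.

    Backbone covers N, CA, C, O (plus OXT) and the hydrogens bonded to
    them; sidechain is the complement.  The two masks partition ``all``.
    """
    if subgroup not in SUBGROUPS:
        raise UsageError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")
    masks: dict[ResidueKey, np.ndarray] = {}
    for res in structure.residues():
        if subgroup == "all":
            mask = np.ones(len(res.atoms), dtype=bool)
        else:
            bb = np.array([a.name in BACKBONE_ATOM_NAMES for a in res.atoms])
            mask = bb if subgroup == "backbone" else ~bb
        masks[res.key] = mask
    return masks
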