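"""Deterministic toy-input generators.

Every module of the package is testable without downloads: these
generators emit small, well-formed PDB files with matching parameter
tables, and toy alignments with columns of known information content.
Identical (spec, seed) always produces byte-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .conservation import AMINO_ACIDS, Msa
from .errors import UsageError
from .forcefield import (
    AtomParameters,
    ParameterSet,
    builtin_parameter_set,
    parameter_set_to_tsv,
)
from .structure_io import Atom, Chain, Residue, ResidueKey, Structure, pdb_string

STRUCTURE_KINDS = ("two_atom", "two_sphere", "dipeptide", "helix")

#: Generated geometries must keep every interatomic distance above this.
MIN_CLEARANCE = 1.0


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class ToyStructureFixture:
    """A generated structure plus the parameter table that covers it."""

    structure: Structure
    pdb_text: str
    params_text: str
    parameter_set: ParameterSet

    def write(self, directory: str | os.PathLike, stem: str = "fixture") -> tuple[str, str]:
        pdb_path = os.path.join(os.fspath(directory), f"{stem}.pdb")
        tsv_path = os.path.join(os.fspath(directory), f"{stem}_params.tsv")
        with open(pdb_path, "w") as fh:
            fh.write(self.pdb_text)
        with open(tsv_path, "w") as fh:
            fh.write(self.params_text)
        return pdb_path, tsv_path


# Idealized alanine template (local coordinates, Å): standard-length
# bonds, tetrahedral-ish hydrogens, carbonyl O pointing away from the
# next residue's amide.
_ALA_TEMPLATE = [
    ("N", "N", (0.00, 0.00, 0.00)),
    ("H", "H", (-0.50, 0.87, 0.00)),
    ("CA", "C", (1.46, 0.00, 0.00)),
    ("HA", "H", (1.80, -0.51, 0.88)),
    ("CB", "C", (2.00, 1.42, 0.00)),
    ("HB1", "H", (1.66, 1.96, 0.88)),
    ("HB2", "H", (1.66, 1.96, -0.88)),
    ("HB3", "H", (3.09, 1.42, 0.00)),
    ("C", "C", (2.00, -0.72, -1.25)),
    ("O", "O", (1.32, -1.70, -0.97)),
]
#: Rigid-body offset placing residue k+1's amide N ~1.33 Å from residue k's C.
_ALA_STEP = np.array([2.48, -1.25, -2.37])

_ELEMENT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def _check_clearance(structure: Structure) -> None:
    pos = np.array([a.position for a in structure.atoms()])
    # only cross-residue clearance matters for nonbonded sums
    res_idx = np.concatenate(
        [np.full(len(r.atoms), i) for i, r in enumerate(structure.residues())]
    )
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff * diff).sum(-1))
    cross = res_idx[:, None] != res_idx[None, :]
    if cross.any() and d[cross].min() < MIN_CLEARANCE:
        raise AssertionError(
            f"fixture geometry has cross-residue clash: {d[cross].min():.3f} Å"
        )


def _single_atom_pair(
    resnames: tuple[str, str],
    r: float,
    q: tuple[float, float],
    sigma: float,
    epsilon: float,
    gb_rho: float,
    gb_scale: float,
) -> ToyStructureFixture:
    chain = Chain(chain_id="A")
    templates: dict[str, dict[str, AtomParameters]] = {}
    for i, (resname, charge) in enumerate(zip(resnames, q)):
        pos = np.array([i * r, 0.0, 0.0])
        key = ResidueKey("A", i + 1, "", resname)
        chain.residues.append(
            Residue(
                key=key,
                atoms=[Atom(name="Q1", element="C", position=pos,
                            mass=_ELEMENT_MASSES["C"], serial=i + 1)],
                is_hetero=True,
            )
        )
        templates[resname] = {
            "Q1": AtomParameters(charge, sigma, epsilon, gb_rho, gb_scale)
        }
    structure = Structure(chains=[chain], title="toy atom pair")
    ps = ParameterSet(name="toy-pair", residue_templates=templates)
    return ToyStructureFixture(
        structure=structure,
        pdb_text=pdb_string(structure),
        params_text=parameter_set_to_tsv(ps),
        parameter_set=ps,
    )


def _rotation_about_x(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ala_chain(n: int, step: np.ndarray, twist_deg: float = 0.0) -> Structure:
    chain = Chain(chain_id="A")
    serial = 0
    for k in range(n):
        rot = _rotation_about_x(np.deg2rad(twist_deg * k))
        shift = k * step
        atoms = []
        for name, elem, xyz in _ALA_TEMPLATE:
            serial += 1
            atoms.append(
                Atom(
                    name=name,
                    element=elem,
                    position=rot @ np.array(xyz) + shift,
                    mass=_ELEMENT_MASSES[elem],
                    serial=serial,
                )
            )
        chain.residues.append(
            Residue(key=ResidueKey("A", k + 1, "", "ALA"), atoms=atoms)
        )
    return Structure(chains=[chain], title=f"toy poly-ALA n={n}")


def _ala_fixture(n: int, twist_deg: float, step: np.ndarray) -> ToyStructureFixture:
    structure = _ala_chain(n, step, twist_deg)
    _check_clearance(structure)
    builtin = builtin_parameter_set()
    ps = ParameterSet(
        name="toy-ala",
        residue_templates={"ALA": dict(builtin.residue_templates["ALA"])},
    )
    return ToyStructureFixture(
        structure=structure,
        pdb_text=pdb_string(structure),
        params_text=parameter_set_to_tsv(ps),
        parameter_set=ps,
    )


def make_toy_structure(spec: FixtureSpec) -> ToyStructureFixture:
    """Generate a toy structure with a matching parameter table.

    Kinds
    -----
    ``two_atom``
        Two single-atom residues on the x-axis; defaults q = +1 e each,
        r = 3.320636 Å, ε = 0 — the bare-Coulomb worked example.
    ``two_sphere``
        Like ``two_atom`` but neutral with GB radii ρ = 1.5 Å, S = 0.8
        at r = 3.0 Å — the Born-radius fixture.
    ``dipeptide``
        Two all-atom alanine residues joined by a peptide bond.
    ``helix``
        n alanine residues along a twisted axis (default n = 10).
    """
    p = dict(spec.params)
    if spec.kind == "two_atom":
        return _single_atom_pair(
            resnames=("UA1", "UA2"),
            r=p.pop("r", 3.320636),
            q=(p.pop("q1", 1.0), p.pop("q2", 1.0)),
            sigma=p.pop("sigma", 3.4),
            epsilon=p.pop("epsilon", 0.0),
            gb_rho=p.pop("gb_rho", 1.5),
            gb_scale=p.pop("gb_scale", 0.8),
        )
    if spec.kind == "two_sphere":
        return _single_atom_pair(
            resnames=("SP1", "SP2"),
            r=p.pop("r", 3.0),
            q=(p.pop("q1", 0.0), p.pop("q2", 0.0)),
            sigma=p.pop("sigma", 3.4),
            epsilon=p.pop("epsilon", 0.0),
            gb_rho=p.pop("gb_rho", 1.5),
            gb_scale=p.pop("gb_scale", 0.8),
        )
    if spec.kind == "dipeptide":
        return _ala_fixture(2, twist_deg=0.0, step=_ALA_STEP)
    if spec.kind == "helix":
        n = p.pop("n", 10)
        return _ala_fixture(n, twist_deg=p.pop("twist_deg", 100.0),
                            step=np.array(p.pop("step", (3.4, 0.0, 0.0))))
    raise UsageError(f"unknown structure fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# alignments


def make_toy_msa(
    n_rows: int,
    n_cols: int,
    conservation_pattern: dict[int, str] | None = None,
    seed: int = 0,
) -> tuple[Msa, str]:
    """Generate an aligned-FASTA toy MSA with columns of known IC.

    ``conservation_pattern`` maps column index to one of:

    ``conserved``  — the same amino acid in every row (IC = log2 20);
    ``uniform20``  — row i carries amino acid i mod 20 (IC = 0 for
                     20 rows of equal weight);
    ``mixed``      — random draws from the alphabet.

    Unlisted columns are ``mixed``.  Returns the Msa and its FASTA text;
    output is byte-identical for identical arguments.
    """
    if n_rows < 1:
        raise UsageError("n_rows must be >= 1")
    pattern = conservation_pattern or {}
    rng = np.random.default_rng(seed)
    columns: list[list[str]] = []
    for c in range(n_cols):
        kind = pattern.get(c, "mixed")
        if kind == "conserved":
            letter = AMINO_ACIDS[int(rng.integers(20))]
            columns.append([letter] * n_rows)
        elif kind == "uniform20":
            columns.append([AMINO_ACIDS[i % 20] for i in range(n_rows)])
        elif kind == "mixed":
            columns.append(
                [AMINO_ACIDS[int(rng.integers(20))] for _ in range(n_rows)]
            )
        else:
            raise UsageError(f"unknown column pattern {kind!r}")
    rows = ["".join(col[i] for col in columns) for i in range(n_rows)]
    ids = [f"r{i}" for i in range(n_rows)]
    fasta = "".join(f">{i}\n{row}\n" for i, row in zip(ids, rows))
    return Msa(ids=ids, rows=rows), fasta
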