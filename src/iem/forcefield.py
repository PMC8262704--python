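"""Force-field parameter tables and per-atom parameter assignment.

A :class:`ParameterSet` maps residue templates to per-atom charges,
Lennard-Jones parameters and generalized-Born radii/screening factors.
The package ships one minimal, internally consistent illustrative table
covering the 20 standard amino acids; user tables in the same TSV schema
can be loaded for any other force field.

Units package-wide: Å, elementary charges, kcal/mol.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Literal

from ._residues import (
    ATOM_CLASSES,
    CTERM_PATCH,
    NTERM_PATCH,
    STANDARD_AMINO_ACIDS,
    residue_template_rows,
)
from .errors import FormatError
from .structure_io import ResidueKey, Structure

#: Coulomb constant in kcal·Å·mol⁻¹·e⁻².
COULOMB_CONSTANT = 332.0636

#: Dielectric offset subtracted from intrinsic GB radii (Å).
DIELECTRIC_OFFSET = 0.09

TABLE_COLUMNS = ("residue", "atom", "charge", "sigma", "epsilon", "gb_rho", "gb_scale")


@dataclass(frozen=True)
class AtomParameters:
    """Nonbonded parameters of one atom.

    charge in e; lj_sigma in Å; lj_epsilon in kcal/mol; gb_rho the
    intrinsic Born radius in Å; gb_scale the dimensionless HCT
    descreening factor.
    """

    charge: float
    lj_sigma: float
    lj_epsilon: float
    gb_rho: float
    gb_scale: float

    def __post_init__(self) -> None:
        if self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be positive")
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be non-negative")
        if self.gb_rho <= DIELECTRIC_OFFSET:
            raise ValueError("gb_rho must exceed the dielectric offset")
        if not 0 < self.gb_scale <= 1.5:
            raise ValueError("gb_scale must lie in (0, 1.5]")


@dataclass
class ParameterSet:
    name: str
    residue_templates: dict[str, dict[str, AtomParameters]]
    combining_rule: Literal["lorentz_berthelot", "geometric"] = "lorentz_berthelot"

    def template_charge(self, resname: str) -> float:
        return sum(p.charge for p in self.residue_templates[resname].values())


@dataclass
class ParameterizedStructure:
    """A Structure plus the parameters assigned to each of its atoms.

    ``parameters[key][i]`` corresponds to ``atoms[i]`` of residue ``key``;
    entries are None when the lookup failed, and those atoms are listed in
    ``unassigned``.
    """

    structure: Structure
    parameters: dict[ResidueKey, list[AtomParameters | None]]
    unassigned: list[tuple[ResidueKey, str]] = field(default_factory=list)
    #: template atoms (typically hydrogens) absent from the structure;
    #: hydrogens are never added — incomplete residues are refused upstream
    missing_atoms: list[tuple[ResidueKey, str]] = field(default_factory=list)
    parameter_set_name: str = ""


def builtin_parameter_set() -> ParameterSet:
    """The shipped illustrative parameter table (20 standard residues).

    Charges are a simplified, internally consistent scheme (neutral
    residues sum to 0 e, ionizable side chains to their formal charge);
    LJ and GB values are element-class based.  Intended for testing and
    illustration, not production scoring of real proteins.
    """
    templates: dict[str, dict[str, AtomParameters]] = {}
    for resname in sorted(STANDARD_AMINO_ACIDS):
        tmpl: dict[str, AtomParameters] = {}
        for atom, cls, charge in residue_template_rows(resname):
            sigma, eps, rho, scale = ATOM_CLASSES[cls]
            tmpl[atom] = AtomParameters(charge, sigma, eps, rho, scale)
        templates[resname] = tmpl
    return ParameterSet(name="builtin-illustrative", residue_templates=templates)


def _patch_parameters(cls_charge: tuple[str, float]) -> AtomParameters:
    cls, charge = cls_charge
    sigma, eps, rho, scale = ATOM_CLASSES[cls]
    return AtomParameters(charge, sigma, eps, rho, scale)


def parameter_set_to_tsv(ps: ParameterSet) -> str:
    """Serialize a ParameterSet to the documented TSV schema."""
    lines = ["\t".join(TABLE_COLUMNS)]
    for resname in ps.residue_templates:
        for atom, p in ps.residue_templates[resname].items():
            lines.append(
                f"{resname}\t{atom}\t{p.charge:.4f}\t{p.lj_sigma:.4f}"
                f"\t{p.lj_epsilon:.4f}\t{p.gb_rho:.4f}\t{p.gb_scale:.4f}"
            )
    return "\n".join(lines) + "\n"


def load_parameter_set(path: str | os.PathLike, name: str | None = None) -> ParameterSet:
    """Load a parameter table from TSV.

    Schema: header ``residue atom charge sigma epsilon gb_rho gb_scale``
    (tab-separated), one row per template atom, ``#`` comments allowed.

    Raises :class:`FormatError` on malformed lines, missing mandatory
    columns, or duplicate atom rows within one template.
    """
    templates: dict[str, dict[str, AtomParameters]] = {}
    header: list[str] | None = None
    col: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].rstrip("\n").rstrip()
            if not line.strip():
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = set(TABLE_COLUMNS) - set(header)
                if missing:
                    raise FormatError(
                        f"{path}: missing mandatory column(s): {sorted(missing)}"
                    )
                col = {name_: i for i, name_ in enumerate(header)}
                continue
            if len(fields) < len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
            try:
                resname = fields[col["residue"]].strip()
                atom = fields[col["atom"]].strip()
                params = AtomParameters(
                    charge=float(fields[col["charge"]]),
                    lj_sigma=float(fields[col["sigma"]]),
                    lj_epsilon=float(fields[col["epsilon"]]),
                    gb_rho=float(fields[col["gb_rho"]]),
                    gb_scale=float(fields[col["gb_scale"]]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            tmpl = templates.setdefault(resname, {})
            if atom in tmpl:
                raise FormatError(
                    f"{path}:{lineno}: duplicate atom {atom!r} in template {resname!r}"
                )
            tmpl[atom] = params
    if header is None or not templates:
        raise FormatError(f"{path}: no parameter rows found")
    return ParameterSet(name=name or os.path.basename(os.fspath(path)),
                        residue_templates=templates)


def assign_parameters(structure: Structure, ps: ParameterSet) -> ParameterizedStructure:
    """Assign per-atom parameters by (residue_name, atom_name) lookup.

    Terminal-variant atom names (OXT; H1/H2/H3 replacing the amide H) are
    resolved through name-based terminal patches when the residue template
    itself does not carry them.  Atoms with no match are recorded in
    ``unassigned`` — never silently dropped; energy calculations refuse
    structures whose selected atoms are unassigned.
    """
    parameters: dict[ResidueKey, list[AtomParameters | None]] = {}
    unassigned: list[tuple[ResidueKey, str]] = []
    missing: list[tuple[ResidueKey, str]] = []
    for res in structure.residues():
        tmpl = ps.residue_templates.get(res.name)
        atom_names = {a.name for a in res.atoms}
        is_nterm = tmpl is not None and {"H1", "H2", "H3"} & atom_names
        is_cterm = tmpl is not None and "OXT" in atom_names
        if tmpl is not None:
            expected = set(tmpl)
            if is_nterm:
                expected.discard("H")  # replaced by H1/H2/H3
            missing.extend(
                (res.key, name) for name in sorted(expected - atom_names)
            )
        assigned: list[AtomParameters | None] = []
        for atom in res.atoms:
            p: AtomParameters | None = None
            if tmpl is not None:
                if is_nterm and atom.name in NTERM_PATCH:
                    p = _patch_parameters(NTERM_PATCH[atom.name])
                elif is_cterm and atom.name in CTERM_PATCH:
                    p = _patch_parameters(CTERM_PATCH[atom.name])
                else:
                    p = tmpl.get(atom.name)
            if p is None:
                unassigned.append((res.key, atom.name))
            assigned.append(p)
        parameters[res.key] = assigned
    return ParameterizedStructure(
        structure=structure,
        parameters=parameters,
        unassigned=unassigned,
        missing_atoms=missing,
        parameter_set_name=ps.name,
    )


def lj_combine(
    p_i: AtomParameters,
    p_j: AtomParameters,
    rule: Literal["lorentz_berthelot", "geometric"] = "lorentz_berthelot",
) -> tuple[float, float]:
    """Combine two atoms' LJ parameters into (σ_ij, ε_ij).

    Lorentz–Berthelot: arithmetic-mean σ, geometric-mean ε.  The
    all-geometric rule is available per ParameterSet flag.
    """
    eps = math.sqrt(p_i.lj_epsilon * p_j.lj_epsilon)
    if rule == "geometric":
        sigma = math.sqrt(p_i.lj_sigma * p_j.lj_sigma)
    else:
        sigma = 0.5 * (p_i.lj_sigma + p_j.lj_sigma)
    return sigma, eps
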