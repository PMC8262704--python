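"""Pairwise residue interaction energies and the interaction energy matrix.

The interaction energy (IE) of a residue pair is the sum of Lennard-Jones
and electrostatic terms over all cross-residue atom pairs.  Electrostatics
can be evaluated in vacuum (Coulomb's law), with a distance-dependent
dielectric (DDDC, the legacy heuristic ε(r) ∝ r), or with the generalized
Born (GB) continuum model using effective Born radii from the
Onufriev–Bashford–Case model II (OBC-II) built on Hawkins–Cramer–Truhlar
(HCT) pairwise descreening integrals.

GB interaction energies are pairwise separable but *not* pairwise local:
the Born radii entering each pair term depend on the global geometry of
the whole structure, so they are computed once from the full structure
and shared across all pairs.

All energies in kcal/mol, distances in Å, charges in elementary charges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from ._residues import BOND_DIST_FROM_N, BOND_DIST_TO_C
from .errors import DegenerateGeometryError, ParameterizationError, UsageError
from .forcefield import (
    COULOMB_CONSTANT,
    DIELECTRIC_OFFSET,
    ParameterizedStructure,
)
from .structure_io import ResidueKey, select_subgroup

#: Born radii exceeding this cap (Å) indicate over-descreened, malformed
#: geometry; they are clamped with a warning instead of raising.
BORN_RADIUS_CAP = 100.0

#: Standard scaling of 1-4 interactions under the ``ff`` exclusion policy.
ONE_FOUR_COULOMB_SCALE = 1.0 / 1.2
ONE_FOUR_LJ_SCALE = 0.5

ExclusionPolicy = Literal["none", "ff"]


@dataclass(frozen=True)
class SolventModel:
    """Electrostatics model selector.

    kind:
        ``vacuum`` — plain Coulomb in a uniform dielectric ``eps_in``;
        ``dddc`` — distance-dependent dielectric ε(r) = dddc_slope · r;
        ``gb`` — generalized Born with internal/solvent dielectrics.
    """

    kind: Literal["vacuum", "dddc", "gb"]
    eps_in: float = 1.0
    eps_out: float = 78.5
    dddc_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("vacuum", "dddc", "gb"):
            raise UsageError(f"unknown solvent model kind {self.kind!r}")
        if not (self.eps_out >= self.eps_in >= 1.0):
            raise UsageError("require eps_out >= eps_in >= 1")
        if self.dddc_slope <= 0:
            raise UsageError("dddc_slope must be positive")


@dataclass(frozen=True)
class ObcParameters:
    """OBC model II constants: tanh coefficients and dielectric offset (Å)."""

    alpha: float = 1.0
    beta: float = 0.8
    gamma: float = 4.85
    offset: float = DIELECTRIC_OFFSET


@dataclass
class BornRadii:
    """Per-atom effective Born radii over the full structure.

    Arrays follow the structure's atom iteration order; ``index`` maps
    (ResidueKey, atom_name) to positions in the arrays.  Atoms without
    parameters are absent.
    """

    radii: np.ndarray      # Å
    psi: np.ndarray        # dimensionless
    integrals: np.ndarray  # Å⁻¹
    index: dict[tuple[ResidueKey, str], int] = field(default_factory=dict)


@dataclass(frozen=True)
class PairEnergy:
    """Decomposed residue-pair interaction energy (kcal/mol)."""

    electrostatic: float
    lennard_jones: float

    @property
    def total(self) -> float:
        return self.electrostatic + self.lennard_jones


@dataclass
class InteractionEnergyMatrix:
    """Symmetric residue×residue matrix of pairwise IEs, zero diagonal."""

    residue_keys: list[ResidueKey]
    electrostatic: np.ndarray   # (n, n), kcal/mol
    lennard_jones: np.ndarray   # (n, n), kcal/mol
    model: SolventModel
    subgroup: str = "all"

    @property
    def n(self) -> int:
        return len(self.residue_keys)

    @property
    def total(self) -> np.ndarray:
        return self.electrostatic + self.lennard_jones

    def component(self, which: Literal["coulomb", "lj", "total"]) -> np.ndarray:
        if which == "coulomb":
            return self.electrostatic
        if which == "lj":
            return self.lennard_jones
        if which == "total":
            return self.total
        raise UsageError(f"unknown IE component {which!r}")

    def pair(self, a: ResidueKey, b: ResidueKey) -> PairEnergy:
        ia = self.residue_keys.index(a)
        ib = self.residue_keys.index(b)
        return PairEnergy(
            electrostatic=float(self.electrostatic[ia, ib]),
            lennard_jones=float(self.lennard_jones[ia, ib]),
        )


# ---------------------------------------------------------------------------
# scalar pair terms


def lj_pair_energy(sigma_ij: float, epsilon_ij: float, r: float) -> float:
    """12-6 Lennard-Jones energy: 4ε[(σ/r)¹² − (σ/r)⁶]."""
    if r <= 0:
        raise DegenerateGeometryError(f"non-positive interatomic distance r={r}")
    sr6 = (sigma_ij / r) ** 6
    return 4.0 * epsilon_ij * (sr6 * sr6 - sr6)


def electrostatic_pair_energy(
    q_i: float, q_j: float, r: float, model: SolventModel
) -> float:
    """Point-charge electrostatic energy under vacuum or DDDC.

    vacuum: k q_i q_j / (ε_in r); dddc: k q_i q_j / (ε(r) r) with
    ε(r) = dddc_slope · r.  GB pairs must go through
    :func:`gb_pair_energy` (the Born radii are extra state).
    """
    if r <= 0:
        raise DegenerateGeometryError(f"non-positive interatomic distance r={r}")
    if model.kind == "vacuum":
        return COULOMB_CONSTANT * q_i * q_j / (model.eps_in * r)
    if model.kind == "dddc":
        return COULOMB_CONSTANT * q_i * q_j / (model.dddc_slope * r * r)
    raise UsageError("GB electrostatics require gb_pair_energy with Born radii")


def gb_pair_energy(
    q_i: float,
    q_j: float,
    r: float,
    born_r_i: float,
    born_r_j: float,
    model: SolventModel,
) -> float:
    """Generalized-Born screened pair electrostatics.

    E = k q_i q_j/(ε_in r) − k (1/ε_in − 1/ε_out) q_i q_j / f_GB with the
    canonical smoothing function
    f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))).
    Reduces exactly to vacuum Coulomb when ε_out = ε_in.
    """
    if model.kind != "gb":
        raise UsageError("gb_pair_energy requires a model of kind 'gb'")
    if r <= 0:
        raise DegenerateGeometryError(f"non-positive interatomic distance r={r}")
    if born_r_i <= 0 or born_r_j <= 0:
        raise UsageError("Born radii must be positive")
    rr = born_r_i * born_r_j
    f_gb = math.sqrt(r * r + rr * math.exp(-r * r / (4.0 * rr)))
    tau = 1.0 / model.eps_in - 1.0 / model.eps_out
    return COULOMB_CONSTANT * q_i * q_j * (1.0 / (model.eps_in * r) - tau / f_gb)


def hct_descreen_term(
    rho_tilde_i: float, rho_j: float, scale_j: float, r: float
) -> float:
    """HCT pairwise descreening integral (Å⁻¹).

    Analytic value of (1/4π)∫ r'⁻⁴ dV over the sphere of radius
    s_j = S_j ρ_j centred at distance r from atom i, excluding the region
    within ρ̃_i of atom i.  Piecewise: zero when the sphere is engulfed
    by atom i's own sphere; an extra full-shell term when atom i sits
    inside the descreening sphere.
    """
    if rho_tilde_i <= 0 or rho_j <= 0 or scale_j <= 0 or r < 0:
        raise ValueError("hct_descreen_term requires positive radii and r >= 0")
    s = scale_j * rho_j
    if r + s <= rho_tilde_i:
        return 0.0
    if r == 0.0:
        # concentric: full shells from rho_tilde_i out to s
        return 1.0 / rho_tilde_i - 1.0 / s
    upper = r + s
    lower = max(rho_tilde_i, abs(r - s))
    term = 0.5 * (
        1.0 / lower
        - 1.0 / upper
        + (1.0 / (2.0 * r)) * math.log(lower / upper)
        + ((r * r - s * s) / (4.0 * r)) * (1.0 / upper**2 - 1.0 / lower**2)
    )
    if r < s - rho_tilde_i:
        # atom i inside the descreening sphere: inner shells are complete
        term += 1.0 / rho_tilde_i - 1.0 / lower
    return term


# ---------------------------------------------------------------------------
# flattened atom arrays


@dataclass
class _FlatAtoms:
    """Structure flattened to parallel numpy arrays (assigned atoms only)."""

    positions: np.ndarray   # (N, 3)
    charge: np.ndarray
    sigma: np.ndarray
    epsilon: np.ndarray
    rho: np.ndarray
    scale: np.ndarray
    res_index: np.ndarray   # (N,) index into residue_keys
    atom_names: list[str]
    residue_keys: list[ResidueKey]
    in_subgroup: np.ndarray  # (N,) bool


def _flatten(ps: ParameterizedStructure, subgroup: str = "all") -> _FlatAtoms:
    masks = select_subgroup(ps.structure, subgroup)
    pos, q, sig, eps, rho, sc, ridx, names = [], [], [], [], [], [], [], []
    sub = []
    keys: list[ResidueKey] = []
    missing_in_scope: list[str] = []
    for res in ps.structure.residues():
        keys.append(res.key)
        params = ps.parameters[res.key]
        mask = masks[res.key]
        for i, atom in enumerate(res.atoms):
            p = params[i]
            if p is None:
                if mask[i]:
                    missing_in_scope.append(f"{res.key}/{atom.name}")
                continue
            pos.append(atom.position)
            q.append(p.charge)
            sig.append(p.lj_sigma)
            eps.append(p.lj_epsilon)
            rho.append(p.gb_rho)
            sc.append(p.gb_scale)
            ridx.append(len(keys) - 1)
            names.append(atom.name)
            sub.append(bool(mask[i]))
    if missing_in_scope:
        raise ParameterizationError(
            "atoms without parameters in the selected subgroup: "
            + ", ".join(missing_in_scope)
        )
    return _FlatAtoms(
        positions=np.array(pos, dtype=float).reshape(-1, 3),
        charge=np.array(q, dtype=float),
        sigma=np.array(sig, dtype=float),
        epsilon=np.array(eps, dtype=float),
        rho=np.array(rho, dtype=float),
        scale=np.array(sc, dtype=float),
        res_index=np.array(ridx, dtype=int),
        atom_names=names,
        residue_keys=keys,
        in_subgroup=np.array(sub, dtype=bool),
    )


def _distance_matrix(positions: np.ndarray) -> np.ndarray:
    diff = positions[:, None, :] - positions[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


# ---------------------------------------------------------------------------
# Born radii (OBC-II)


def _hct_integrals(flat: _FlatAtoms, obc: ObcParameters) -> np.ndarray:
    """Vectorized Σ_j HCT terms for every atom i (Å⁻¹)."""
    n = len(flat.charge)
    d = _distance_matrix(flat.positions)
    np.fill_diagonal(d, np.inf)
    rt = flat.rho - obc.offset          # ρ̃_i, (N,)
    s = flat.scale * flat.rho           # s_j, (N,)
    rt_i = rt[:, None]
    s_j = s[None, :]
    upper = d + s_j
    lower = np.maximum(rt_i, np.abs(d - s_j))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        term = 0.5 * (
            1.0 / lower
            - 1.0 / upper
            + (1.0 / (2.0 * d)) * np.log(lower / upper)
            + ((d * d - s_j * s_j) / (4.0 * d)) * (1.0 / upper**2 - 1.0 / lower**2)
        )
        inside = d < (s_j - rt_i)
        term = np.where(inside, term + 1.0 / rt_i - 1.0 / lower, term)
    term = np.where(upper <= rt_i, 0.0, term)
    term[~np.isfinite(term)] = 0.0
    np.fill_diagonal(term, 0.0)
    assert term.shape == (n, n)
    return term.sum(axis=1)


def born_radii_obc2(
    ps: ParameterizedStructure, obc: ObcParameters = ObcParameters()
) -> BornRadii:
    """Effective Born radii for every parameterized atom (OBC model II).

    I_i = Σ_{j≠i} HCT(ρ̃_i, ρ_j, S_j, r_ij);  Ψ_i = I_i ρ̃_i;
    R_i⁻¹ = ρ̃_i⁻¹ − ρ_i⁻¹ tanh(α Ψ_i − β Ψ_i² + γ Ψ_i³),
    with ρ̃_i = ρ_i − offset.  Radii are computed from the full structure,
    never per residue pair.  Over-descreened atoms (R_i⁻¹ ≤ 0) are clamped
    to 100 Å with a warning.
    """
    flat = _flatten(ps, "all")
    integrals = _hct_integrals(flat, obc)
    rt = flat.rho - obc.offset
    psi = integrals * rt
    inv_r = 1.0 / rt - (1.0 / flat.rho) * np.tanh(
        obc.alpha * psi - obc.beta * psi**2 + obc.gamma * psi**3
    )
    over = inv_r <= 1.0 / BORN_RADIUS_CAP
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} over-descreened Born radius/radii clamped "
            f"to {BORN_RADIUS_CAP} Å",
            stacklevel=2,
        )
    radii = np.where(over, BORN_RADIUS_CAP, 1.0 / np.where(over, 1.0, inv_r))
    index: dict[tuple[ResidueKey, str], int] = {}
    for i, (ri, name) in enumerate(zip(flat.res_index, flat.atom_names)):
        index[(flat.residue_keys[ri], name)] = i
    return BornRadii(radii=radii, psi=psi, integrals=integrals, index=index)


# ---------------------------------------------------------------------------
# exclusions across the peptide bond


def _adjacent_pairs(ps: ParameterizedStructure) -> list[tuple[ResidueKey, ResidueKey]]:
    """Peptide-bonded (preceding, following) residue pairs."""
    out = []
    for chain in ps.structure.chains:
        for a, b in zip(chain.residues, chain.residues[1:]):
            c_atom = next((at for at in a.atoms if at.name == "C"), None)
            n_atom = next((at for at in b.atoms if at.name == "N"), None)
            if c_atom is None or n_atom is None:
                continue
            if np.linalg.norm(c_atom.position - n_atom.position) < 2.0:
                out.append((a.key, b.key))
    return out


def _bond_separation(name_a: str, name_b: str) -> int | None:
    """Bond count between atom of a preceding residue and the next one."""
    da = BOND_DIST_TO_C.get(name_a)
    db = BOND_DIST_FROM_N.get(name_b)
    if da is None or db is None:
        return None
    return da + 1 + db


def _exclusion_factors(
    flat: _FlatAtoms, ps: ParameterizedStructure
) -> tuple[np.ndarray, np.ndarray]:
    """(coulomb_factor, lj_factor) matrices implementing the ``ff`` policy:

    cross-peptide-bond 1-2 and 1-3 atom pairs removed, 1-4 pairs scaled
    by the standard force-field factors.
    """
    n = len(flat.charge)
    cf = np.ones((n, n))
    lf = np.ones((n, n))
    by_res: dict[ResidueKey, list[int]] = {}
    for i, ri in enumerate(flat.res_index):
        by_res.setdefault(flat.residue_keys[ri], []).append(i)
    for key_a, key_b in _adjacent_pairs(ps):
        for i in by_res.get(key_a, ()):
            for j in by_res.get(key_b, ()):
                sep = _bond_separation(flat.atom_names[i], flat.atom_names[j])
                if sep is None or sep > 3:
                    continue
                if sep <= 2:
                    cf[i, j] = cf[j, i] = 0.0
                    lf[i, j] = lf[j, i] = 0.0
                else:
                    cf[i, j] = cf[j, i] = ONE_FOUR_COULOMB_SCALE
                    lf[i, j] = lf[j, i] = ONE_FOUR_LJ_SCALE
    return cf, lf


# ---------------------------------------------------------------------------
# residue-pair and matrix assembly


def _atom_pair_energies(
    flat: _FlatAtoms,
    model: SolventModel,
    born: BornRadii | None,
    ps: ParameterizedStructure,
    exclusions: ExclusionPolicy,
    cutoff: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(electrostatic, lj) atom-pair energy matrices over subgroup atoms."""
    sel = flat.in_subgroup
    pos = flat.positions[sel]
    q = flat.charge[sel]
    sig = flat.sigma[sel]
    eps = flat.epsilon[sel]
    d = _distance_matrix(pos)
    same_res = flat.res_index[sel][:, None] == flat.res_index[sel][None, :]
    if np.any((d <= 0) & ~same_res & ~np.eye(len(q), dtype=bool)):
        raise DegenerateGeometryError("coincident atoms in different residues")
    np.fill_diagonal(d, np.inf)
    d = np.where(d == 0, np.inf, d)  # intra-residue duplicates never summed

    sig_ij = 0.5 * (sig[:, None] + sig[None, :])
    eps_ij = np.sqrt(eps[:, None] * eps[None, :])
    sr6 = (sig_ij / d) ** 6
    e_lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)

    qq = COULOMB_CONSTANT * q[:, None] * q[None, :]
    if model.kind == "vacuum":
        e_el = qq / (model.eps_in * d)
    elif model.kind == "dddc":
        e_el = qq / (model.dddc_slope * d * d)
    else:
        assert born is not None
        keys = flat.residue_keys
        idx = np.array(
            [
                born.index[(keys[ri], name)]
                for ri, name, s in zip(flat.res_index, flat.atom_names, sel)
                if s
            ]
        )
        radii = born.radii[idx]
        rr = radii[:, None] * radii[None, :]
        with np.errstate(over="ignore"):
            f_gb = np.sqrt(d * d + rr * np.exp(-(d * d) / (4.0 * rr)))
        tau = 1.0 / model.eps_in - 1.0 / model.eps_out
        e_el = qq * (1.0 / (model.eps_in * d) - tau / f_gb)

    if exclusions == "ff":
        cf, lf = _exclusion_factors(flat, ps)
        e_el = e_el * cf[np.ix_(sel, sel)]
        e_lj = e_lj * lf[np.ix_(sel, sel)]
    elif exclusions != "none":
        raise UsageError(f"unknown exclusion policy {exclusions!r}")
    if cutoff is not None:
        beyond = d > cutoff
        e_el = np.where(beyond, 0.0, e_el)
        e_lj = np.where(beyond, 0.0, e_lj)
    return e_el, e_lj


def build_iem(
    ps: ParameterizedStructure,
    model: SolventModel,
    subgroup: str = "all",
    exclusions: ExclusionPolicy = "none",
    cutoff: float | None = None,
    obc: ObcParameters = ObcParameters(),
    born: BornRadii | None = None,
) -> InteractionEnergyMatrix:
    """Assemble the full residue×residue interaction energy matrix.

    For the GB model, Born radii are computed once from the *full*
    structure (all atoms, regardless of subgroup) unless supplied.  The
    matrix is symmetric with a zero diagonal; intra-residue terms and GB
    self-energies are by convention not part of pairwise IEs.
    """
    if model.kind == "gb" and born is None:
        born = born_radii_obc2(ps, obc)
    flat = _flatten(ps, subgroup)
    n = len(flat.residue_keys)
    e_el, e_lj = _atom_pair_energies(flat, model, born, ps, exclusions, cutoff)
    # residue indicator: sum atom-pair energies into residue blocks
    sel_res = flat.res_index[flat.in_subgroup]
    ind = np.zeros((len(sel_res), n))
    ind[np.arange(len(sel_res)), sel_res] = 1.0
    el = ind.T @ e_el @ ind
    lj = ind.T @ e_lj @ ind
    np.fill_diagonal(el, 0.0)
    np.fill_diagonal(lj, 0.0)
    return InteractionEnergyMatrix(
        residue_keys=list(flat.residue_keys),
        electrostatic=el,
        lennard_jones=lj,
        model=model,
        subgroup=subgroup,
    )


def residue_pair_ie(
    ps: ParameterizedStructure,
    a: ResidueKey,
    b: ResidueKey,
    model: SolventModel,
    subgroup: str = "all",
    born: BornRadii | None = None,
    exclusions: ExclusionPolicy = "none",
) -> PairEnergy:
    """Interaction energy of one residue pair (sum over cross atom pairs).

    For the GB model the caller must supply Born radii computed from the
    full structure; they carry the global-geometry dependence.
    """
    if a == b:
        raise UsageError("residue_pair_ie requires two distinct residues")
    if model.kind == "gb" and born is None:
        raise UsageError("GB residue pairs require precomputed Born radii")
    iem = build_iem(ps, model, subgroup=subgroup, exclusions=exclusions, born=born)
    return iem.pair(a, b)


def total_ies(iem: InteractionEnergyMatrix) -> dict[str, np.ndarray]:
    """Per-residue total (net) IEs: row sums of the pair matrix.

    Returns arrays keyed ``total``, ``electrostatic`` and
    ``lennard_jones``, aligned with ``iem.residue_keys``.
    """
    return {
        "total": iem.total.sum(axis=1),
        "electrostatic": iem.electrostatic.sum(axis=1),
        "lennard_jones": iem.lennard_jones.sum(axis=1),
    }
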