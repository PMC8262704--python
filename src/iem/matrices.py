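"""Residue distance matrices, the combined energy/distance view, exports.

Residue–residue distance is measured either as the closest approach of
any cross atom pair or between the centres of mass (COMs) of the selected
atoms.  The combined matrix shows the pairwise IE where residues are
within a distance threshold and the distance elsewhere, hiding the
near-zero energies of well-separated pairs.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .energetics import InteractionEnergyMatrix, total_ies
from .errors import UsageError
from .forcefield import ParameterizedStructure
from .structure_io import Atom, ResidueKey, Structure, select_subgroup

Metric = Literal["closest", "com"]

#: Sentinel for distances undefined under a subgroup (empty selection).
UNDEFINED_DISTANCE = float("nan")

#: Default contact threshold (Å) separating energy- from distance-valued
#: cells in the combined matrix.
DEFAULT_COMBINED_THRESHOLD = 5.0


@dataclass
class DistanceMatrix:
    residue_keys: list[ResidueKey]
    values: np.ndarray  # (n, n), Å; NaN where undefined
    metric: Metric
    subgroup: str = "all"

    @property
    def n(self) -> int:
        return len(self.residue_keys)


@dataclass
class CombinedMatrix:
    """Off-diagonal cells are exactly one of energy- or distance-valued."""

    residue_keys: list[ResidueKey]
    values: np.ndarray     # energy (kcal/mol) where is_energy, else Å
    is_energy: np.ndarray  # (n, n) bool mask
    threshold: float


def residue_distance(
    atoms_a: Iterable[Atom], atoms_b: Iterable[Atom], metric: Metric = "closest"
) -> float:
    """Distance between two residues' atom sets under the chosen metric.

    ``closest``: minimum cross atom-pair Euclidean distance.
    ``com``: distance between mass-weighted centroids.
    Empty selections yield the NaN sentinel.
    """
    if metric not in ("closest", "com"):
        raise UsageError(f"unknown distance metric {metric!r}")
    a = list(atoms_a)
    b = list(atoms_b)
    if not a or not b:
        return UNDEFINED_DISTANCE
    pa = np.array([at.position for at in a])
    pb = np.array([at.position for at in b])
    if metric == "closest":
        diff = pa[:, None, :] - pb[None, :, :]
        return float(np.sqrt((diff * diff).sum(axis=-1)).min())
    ma = np.array([at.mass for at in a])
    mb = np.array([at.mass for at in b])
    com_a = (pa * ma[:, None]).sum(axis=0) / ma.sum()
    com_b = (pb * mb[:, None]).sum(axis=0) / mb.sum()
    return float(np.linalg.norm(com_a - com_b))


def build_distance_matrix(
    ps: ParameterizedStructure | Structure,
    metric: Metric = "closest",
    subgroup: str = "all",
) -> DistanceMatrix:
    """Full symmetric residue distance matrix.

    The subgroup restriction applies to *both* residues' atom sets.
    Residues with an empty selection (e.g. glycine side chain) produce
    NaN rows/columns and a warning.
    """
    structure = ps.structure if isinstance(ps, ParameterizedStructure) else ps
    masks = select_subgroup(structure, subgroup)
    residues = list(structure.residues())
    selections = []
    for res in residues:
        mask = masks[res.key]
        selections.append([a for a, m in zip(res.atoms, mask) if m])
    empty = [res.key for res, sel in zip(residues, selections) if not sel]
    if empty:
        warnings.warn(
            f"{len(empty)} residue(s) have no atoms under subgroup "
            f"{subgroup!r}; their distances are undefined",
            stacklevel=2,
        )
    n = len(residues)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = residue_distance(selections[i], selections[j], metric)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        residue_keys=[r.key for r in residues],
        values=values,
        metric=metric,
        subgroup=subgroup,
    )


def combined_mask(
    iem: InteractionEnergyMatrix,
    dm: DistanceMatrix,
    threshold: float = DEFAULT_COMBINED_THRESHOLD,
) -> CombinedMatrix:
    """Combine an IEM and a distance matrix at a contact threshold.

    Cell (a, b) carries the total pairwise IE when the residues are
    within ``threshold`` Å, and the distance otherwise.  NaN (undefined)
    distances are treated as beyond threshold.
    """
    if iem.residue_keys != dm.residue_keys:
        raise UsageError("IEM and distance matrix describe different residues")
    if iem.subgroup != dm.subgroup:
        raise UsageError(
            f"subgroup mismatch: IEM {iem.subgroup!r} vs distances {dm.subgroup!r}"
        )
    with np.errstate(invalid="ignore"):
        is_energy = dm.values <= threshold
    np.fill_diagonal(is_energy, False)
    values = np.where(is_energy, iem.total, dm.values)
    np.fill_diagonal(values, 0.0)
    return CombinedMatrix(
        residue_keys=list(iem.residue_keys),
        values=values,
        is_energy=is_energy,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# tabular export — 6 significant digits, deterministic


def _fmt(x: float) -> str:
    if np.isnan(x):
        return "nan"
    return format(float(x), ".6g")


def _header(keys: list[ResidueKey]) -> list[str]:
    return [str(k) for k in keys]


def write_matrix_table(
    keys: list[ResidueKey],
    values: np.ndarray,
    path: str | os.PathLike,
    delimiter: str = "\t",
) -> None:
    """Write a residue×residue matrix as TSV/CSV with key headers."""
    head = _header(keys)
    lines = [delimiter.join(["residue"] + head)]
    for name, row in zip(head, values):
        lines.append(delimiter.join([name] + [_fmt(v) for v in row]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_totals_table(
    iem: InteractionEnergyMatrix, path: str | os.PathLike, delimiter: str = "\t"
) -> None:
    """Per-residue total (net) IEs with component decomposition."""
    totals = total_ies(iem)
    lines = [delimiter.join(["residue", "total", "electrostatic", "lennard_jones"])]
    for i, key in enumerate(iem.residue_keys):
        lines.append(
            delimiter.join(
                [
                    str(key),
                    _fmt(totals["total"][i]),
                    _fmt(totals["electrostatic"][i]),
                    _fmt(totals["lennard_jones"][i]),
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_json(
    path: str | os.PathLike,
    iem: InteractionEnergyMatrix | None = None,
    dm: DistanceMatrix | None = None,
    combined: CombinedMatrix | None = None,
) -> None:
    """JSON export carrying matrices, metadata and per-residue totals."""

    def matrix(values: np.ndarray) -> list[list[float | None]]:
        return [
            [None if np.isnan(v) else float(_fmt(v)) for v in row] for row in values
        ]

    doc: dict = {}
    if iem is not None:
        totals = total_ies(iem)
        doc["iem"] = {
            "residues": _header(iem.residue_keys),
            "model": {
                "kind": iem.model.kind,
                "eps_in": iem.model.eps_in,
                "eps_out": iem.model.eps_out,
                "dddc_slope": iem.model.dddc_slope,
            },
            "subgroup": iem.subgroup,
            "coulomb": matrix(iem.electrostatic),
            "lj": matrix(iem.lennard_jones),
            "total": matrix(iem.total),
            "residue_totals": {
                k: [float(_fmt(v)) for v in arr] for k, arr in totals.items()
            },
        }
    if dm is not None:
        doc["distances"] = {
            "residues": _header(dm.residue_keys),
            "metric": dm.metric,
            "subgroup": dm.subgroup,
            "values": matrix(dm.values),
        }
    if combined is not None:
        doc["combined"] = {
            "residues": _header(combined.residue_keys),
            "threshold": combined.threshold,
            "values": matrix(combined.values),
            "is_energy": [[bool(v) for v in row] for row in combined.is_energy],
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
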