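"""Evolutionary conservation: GSC sequence weights and per-column IC.

Sequence redundancy in an MSA is damped with the
Gerstein/Sonnhammer/Chothia (GSC) tree-based weighting scheme: a UPGMA
guide tree is built on fractional-identity distances and each branch
length is shared among the leaves below it in proportion to their
accumulated weights.  The per-column information content (IC) is then

    IC = log2(20) − H,   H = −Σ_a p_a log2 p_a,

with amino-acid frequencies p_a weighted by the GSC weights; gaps and
ambiguous residues are excluded from the counts.  IC ranges from 0 bits
(no conservation) to log2(20) ≈ 4.32 bits (complete conservation).

This mirrors the conservation pipeline of structure-analysis servers
that weight phmmer-derived alignments instead of fitting an explicit
evolutionary model.
"""

from __future__ import annotations

import math
import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from typing import Literal

import numpy as np
from Bio import AlignIO

from .errors import EnvironmentToolError, FormatError, InputError, MappingError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: Characters never counted in column frequencies.
EXCLUDED_SYMBOLS = frozenset("-XBZJUO*")

MAX_IC_BITS = math.log2(20)


@dataclass
class Msa:
    """A multiple sequence alignment: parallel ids and aligned rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("alignment has no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.rows = [r.upper().replace(".", "-") for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.ids.index(row_id)]
        except ValueError:
            raise InputError(f"no row {row_id!r} in alignment") from None


@dataclass
class SequenceWeights:
    """GSC weights per alignment row, rescaled to mean one."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v <= 0):
            raise ValueError("sequence weights must be positive")
        if abs(v.mean() - 1.0) > 1e-9:
            raise ValueError("sequence weights must average to one")
        self.values = v


@dataclass
class ConservationProfile:
    """Per-residue IC (bits) aligned to a chain; NaN where undefined."""

    ic: np.ndarray
    gap_fraction: np.ndarray
    chain_sequence: str


def read_msa(path: str | os.PathLike, format: Literal["fasta", "stockholm"] = "fasta") -> Msa:
    """Read an aligned FASTA or Stockholm file.

    Rows are upper-cased and ``.`` gaps normalized to ``-``; Stockholm
    annotation lines are ignored.  Ragged alignments raise FormatError.
    """
    if format not in ("fasta", "stockholm"):
        raise InputError(f"unknown MSA format {format!r}")
    try:
        records = list(AlignIO.read(os.fspath(path), format))
    except ValueError as exc:
        # Biopython reports both empty files and ragged rows as ValueError
        msg = str(exc)
        if "length" in msg.lower():
            raise FormatError(f"{path}: {msg}") from exc
        raise InputError(f"{path}: {msg}") from exc
    except OSError as exc:
        raise InputError(f"cannot read {path!r}: {exc}") from exc
    if not records:
        raise InputError(f"{path}: empty alignment")
    return Msa(ids=[r.id for r in records], rows=[str(r.seq) for r in records])


# ---------------------------------------------------------------------------
# GSC weighting


def _fractional_identity_distance(a: str, b: str) -> float:
    """1 − identity over columns where neither row is a gap."""
    same = 0
    comparable = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        comparable += 1
        if ca == cb:
            same += 1
    if comparable == 0:
        return 1.0
    return 1.0 - same / comparable


def _upgma(dist: np.ndarray) -> list[tuple[int, int, float]]:
    """Deterministic UPGMA; returns merges (i, j, height), new node ids n….

    Ties are broken by the lowest leaf index contained in each cluster,
    making the guide tree independent of floating-point noise ordering.
    """
    n = dist.shape[0]
    active: dict[int, int] = {i: 1 for i in range(n)}  # node id -> size
    min_leaf = {i: i for i in range(n)}
    d = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), dij in d.items():
            key = (dij, min(min_leaf[i], min_leaf[j]), max(min_leaf[i], min_leaf[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        height = d[(i, j)] / 2.0
        merges.append((i, j, height))
        si, sj = active.pop(i), active.pop(j)
        new_d = {}
        for k in active:
            dik = d.get((min(i, k), max(i, k)))
            djk = d.get((min(j, k), max(j, k)))
            new_d[(k, next_id)] = (si * dik + sj * djk) / (si + sj)
        d = {
            (a, b): v
            for (a, b), v in d.items()
            if a in active and b in active
        }
        for (k, nid), v in new_d.items():
            d[(k, nid)] = v
        active[next_id] = si + sj
        min_leaf[next_id] = min(min_leaf[i], min_leaf[j])
        next_id += 1
    return merges


def gsc_weights(msa: Msa) -> SequenceWeights:
    """Gerstein/Sonnhammer/Chothia tree weights, rescaled to mean one.

    Each branch of the UPGMA guide tree contributes its length to the
    leaves below it, split in proportion to their current accumulated
    weights (evenly while all are still zero).  Identical sequences thus
    share the weight a single copy would have received.
    """
    n = msa.n_rows
    if n == 1:
        return SequenceWeights(values=np.array([1.0]))
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _fractional_identity_distance(
                msa.rows[i], msa.rows[j]
            )
    merges = _upgma(dist)
    heights = {i: 0.0 for i in range(n)}
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    weights = np.zeros(n)
    next_id = n
    for i, j, height in merges:
        for child in (i, j):
            branch = height - heights[child]
            below = leaves[child]
            w = weights[below]
            total = w.sum()
            if total > 0:
                weights[below] += branch * w / total
            else:
                weights[below] += branch / len(below)
        heights[next_id] = height
        leaves[next_id] = leaves.pop(i) + leaves.pop(j)
        next_id += 1
    total = weights.sum()
    if total <= 0:  # all sequences identical: flat weights
        return SequenceWeights(values=np.ones(n))
    return SequenceWeights(values=weights * n / total)


# ---------------------------------------------------------------------------
# information content


def weighted_column_ic(msa: Msa, w: SequenceWeights, column: int) -> float:
    """Weighted information content of one column, in bits.

    Frequencies run over the 20 standard amino acids; gaps and ambiguous
    symbols are excluded and the remaining weight mass renormalized.
    All-gap columns return NaN (undefined).
    """
    if not 0 <= column < msa.n_columns:
        raise IndexError(f"column {column} out of range 0..{msa.n_columns - 1}")
    mass = np.zeros(20)
    for row, ws in zip(msa.rows, w.values):
        c = row[column]
        idx = _AA_INDEX.get(c)
        if idx is not None:
            mass[idx] += ws
    total = mass.sum()
    if total <= 0:
        return float("nan")
    p = mass[mass > 0] / total
    entropy = float(-(p * np.log2(p)).sum())
    return MAX_IC_BITS - entropy


def column_gap_fraction(msa: Msa, w: SequenceWeights, column: int) -> float:
    """Weighted fraction of rows with no counted residue at the column."""
    counted = sum(
        ws for row, ws in zip(msa.rows, w.values) if row[column] in _AA_INDEX
    )
    return 1.0 - counted / w.values.sum()


def profile(msa: Msa, w: SequenceWeights | None = None) -> np.ndarray:
    """IC of every column (bits); NaN for all-gap columns."""
    if w is None:
        w = gsc_weights(msa)
    return np.array([weighted_column_ic(msa, w, c) for c in range(msa.n_columns)])


def map_conservation_to_chain(
    chain_sequence: str,
    msa: Msa,
    query_row: str,
    weights: SequenceWeights | None = None,
) -> ConservationProfile:
    """Project per-column IC onto a structure chain via the query row.

    The k-th non-gap position of the query row maps its column's IC onto
    the k-th chain residue.  ``X`` matches any residue on either side.
    Chain residues beyond the alignment receive NaN.
    """
    row = msa.row(query_row)
    if weights is None:
        weights = gsc_weights(msa)
    columns = [c for c, ch in enumerate(row) if ch != "-"]
    ungapped = row.replace("-", "")
    for k, (qc, cc) in enumerate(zip(ungapped, chain_sequence)):
        if qc != cc and qc != "X" and cc != "X":
            raise MappingError(
                f"query row {query_row!r} does not match the chain sequence: "
                f"first mismatch at position {k} ({qc!r} vs {cc!r})"
            )
    if len(ungapped) > len(chain_sequence):
        raise MappingError(
            f"query row {query_row!r} is longer ({len(ungapped)}) than the "
            f"chain sequence ({len(chain_sequence)})"
        )
    n = len(chain_sequence)
    ic = np.full(n, np.nan)
    gapf = np.full(n, np.nan)
    for k, col in enumerate(columns):
        ic[k] = weighted_column_ic(msa, weights, col)
        gapf[k] = column_gap_fraction(msa, weights, col)
    return ConservationProfile(ic=ic, gap_fraction=gapf, chain_sequence=chain_sequence)


def write_profile_table(
    profile_: ConservationProfile,
    residue_keys,
    path: str | os.PathLike,
) -> None:
    """Per-residue TSV: ``chain resSeq iCode resname IC gap_fraction``."""
    lines = ["chain\tresSeq\tiCode\tresname\tIC\tgap_fraction"]
    for key, ic, gf in zip(residue_keys, profile_.ic, profile_.gap_fraction):
        ic_s = "nan" if math.isnan(ic) else format(ic, ".6g")
        gf_s = "nan" if math.isnan(gf) else format(gf, ".6g")
        lines.append(
            f"{key.chain_id}\t{key.seq_number}\t{key.insertion_code}\t"
            f"{key.residue_name}\t{ic_s}\t{gf_s}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# optional external homology search adapter


def run_homology_search(
    chain_sequence: str,
    database_path: str | os.PathLike,
    query_id: str = "query",
    phmmer_executable: str = "phmmer",
) -> Msa:
    """Build a query-anchored MSA from a phmmer search (optional adapter).

    Runs phmmer with default parameters against a local sequence
    database, keeps the match-state columns of the hit alignment (which
    correspond one-to-one to query positions), and stacks the hits under
    the ungapped query row.  The rest of the package is fully functional
    without this adapter.

    Raises :class:`EnvironmentToolError` when the tool or database is
    unavailable.
    """
    exe = shutil.which(phmmer_executable)
    if exe is None:
        raise EnvironmentToolError(
            f"external search tool {phmmer_executable!r} not found on PATH"
        )
    if not os.path.exists(database_path):
        raise EnvironmentToolError(f"sequence database {database_path!r} not found")
    with tempfile.TemporaryDirectory() as tmp:
        query_path = os.path.join(tmp, "query.fasta")
        hits_path = os.path.join(tmp, "hits.sto")
        with open(query_path, "w") as fh:
            fh.write(f">{query_id}\n{chain_sequence}\n")
        result = subprocess.run(
            [exe, "-A", hits_path, query_path, os.fspath(database_path)],
            capture_output=True,
            text=True,
        )
        if result.returncode != 0:
            raise EnvironmentToolError(
                f"phmmer failed (exit {result.returncode}): {result.stderr.strip()}"
            )
        if not os.path.exists(hits_path) or os.path.getsize(hits_path) == 0:
            return Msa(ids=[query_id], rows=[chain_sequence])
        alignment = AlignIO.read(hits_path, "stockholm")
    rf = alignment.column_annotations.get("reference_annotation")
    if rf is None:
        raise FormatError("phmmer alignment lacks the RF (match-state) annotation")
    match_cols = [i for i, c in enumerate(rf) if c not in ".-~"]
    if len(match_cols) != len(chain_sequence):
        raise FormatError(
            "phmmer match states do not span the query; cannot anchor alignment"
        )
    ids = [query_id]
    rows = [chain_sequence]
    for record in alignment:
        seq = str(record.seq).upper().replace(".", "-")
        rows.append("".join(seq[i] for i in match_cols))
        ids.append(record.id)
    return Msa(ids=ids, rows=rows)
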