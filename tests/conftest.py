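"""Shared fixtures: handwritten PDB snippets and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from iem.fixtures import FixtureSpec, make_toy_structure

# A minimal two-residue PDB written by hand (fixed columns verified).
TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000  -0.720  -1.250  1.00  0.00           C
ATOM      4  O   ALA A   1       1.320  -1.700  -0.970  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000   1.420   0.000  1.00  0.00           C
ATOM      6  N   GLY A   2       2.480  -1.250  -2.370  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.940  -1.250  -2.370  1.00  0.00           C
ATOM      8  C   GLY A   2       4.480  -1.970  -3.620  1.00  0.00           C
ATOM      9  O   GLY A   2       3.800  -2.950  -3.340  1.00  0.00           O
END
"""

# One atom with two alternate locations: A at occupancy 0.60, B at 0.40.
ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.460   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.500   0.100   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.000  -0.720  -1.250  1.00  0.00           C
ATOM      5  O   ALA A   1       1.320  -1.700  -0.970  1.00  0.00           O
END
"""

# Two models; only model 1 (3 atoms) should be retained.
MULTIMODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000  -0.720  -1.250  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.560   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.100  -0.720  -1.250  1.00  0.00           C
ENDMDL
END
"""

# ALA, then the non-standard selenomethionine MSE (HETATM), then GLY;
# plus a water-only chain W.
MIXED_CHAIN_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.460   0.000   0.000  1.00  0.00           C
HETATM    3 SE   MSE A   2       5.000   0.000   0.000  1.00  0.00          SE
ATOM      4  N   GLY A   3       9.000   0.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   3      10.460   0.000   0.000  1.00  0.00           C
HETATM    6  O   HOH W   1      20.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def write_text(tmp_path):
    def _write(name: str, text: str) -> str:
        path = tmp_path / name
        path.write_text(text)
        return str(path)

    return _write


@pytest.fixture
def dipeptide():
    return make_toy_structure(FixtureSpec("dipeptide"))


@pytest.fixture
def helix5():
    return make_toy_structure(FixtureSpec("helix", params={"n": 5}))


def mc_descreen_integral(
    rho_tilde_i: float,
    rho_j: float,
    scale_j: float,
    r: float,
    n_samples: int = 2_000_000,
    seed: int = 1234,
) -> float:
    """Monte-Carlo oracle for the pairwise descreening integral.

    Uniform samples in the descreening sphere of radius s = S_j ρ_j at
    distance r; the estimate of (1/4π)∫ r'⁻⁴ dV excludes the region
    inside ρ̃_i of atom i.  Chunked to bound memory.
    """
    rng = np.random.default_rng(seed)
    s = scale_j * rho_j
    volume = 4.0 / 3.0 * np.pi * s**3
    total = 0.0
    done = 0
    while done < n_samples:
        m = min(500_000, n_samples - done)
        pts = rng.uniform(-s, s, size=(2 * m, 3))
        pts = pts[(pts * pts).sum(axis=1) <= s * s][:m]
        while len(pts) < m:  # top up after rejection
            extra = rng.uniform(-s, s, size=(2 * (m - len(pts)), 3))
            extra = extra[(extra * extra).sum(axis=1) <= s * s]
            pts = np.vstack([pts, extra[: m - len(pts)]])
        pts[:, 0] += r
        d2 = (pts * pts).sum(axis=1)
        keep = d2 >= rho_tilde_i**2
        total += (d2[keep] ** -2).sum()
        done += m
    return float(total / done * volume / (4.0 * np.pi))


def brute_force_pair_components(ps, res_a, res_b, model, born=None):
    """Naive double loop over cross atom pairs: (electrostatic, lj)."""
    from iem import (
        electrostatic_pair_energy,
        gb_pair_energy,
        lj_combine,
        lj_pair_energy,
    )

    el = lj = 0.0
    pa = ps.parameters[res_a.key]
    pb = ps.parameters[res_b.key]
    for i, ai in enumerate(res_a.atoms):
        for j, aj in enumerate(res_b.atoms):
            r = float(np.linalg.norm(ai.position - aj.position))
            sigma, eps = lj_combine(pa[i], pb[j])
            lj += lj_pair_energy(sigma, eps, r)
            if model.kind == "gb":
                r_i = born.radii[born.index[(res_a.key, ai.name)]]
                r_j = born.radii[born.index[(res_b.key, aj.name)]]
                el += gb_pair_energy(pa[i].charge, pb[j].charge, r, r_i, r_j, model)
            else:
                el += electrostatic_pair_energy(pa[i].charge, pb[j].charge, r, model)
    return el, lj
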