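#!/usr/bin/env python
"""Optional integration check on the Antennapedia homeodomain (PDB 1HOM).

Non-gating: requires a locally supplied copy of the 1HOM structure
(protonated, model 1) and a full-coverage parameter table — neither is
bundled and nothing is downloaded.  The qualitative expectation is that
the Phe49–Phe20 hydrophobic-core contact ranks among the most favorable
pairwise interaction energies of Phe49.

Usage:
    python scripts/integration_1hom.py --pdb 1hom.pdb [--params table.tsv]
"""

from __future__ import annotations

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import numpy as np  # noqa: E402

from iem import (  # noqa: E402
    SolventModel,
    assign_parameters,
    build_iem,
    builtin_parameter_set,
    load_parameter_set,
    parse_pdb,
    total_ies,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pdb", required=True, help="local 1HOM PDB file")
    parser.add_argument("--params", default=None,
                        help="parameter table TSV (default: built-in set)")
    parser.add_argument("--top", type=int, default=5)
    args = parser.parse_args()

    structure = parse_pdb(args.pdb)
    params = load_parameter_set(args.params) if args.params else builtin_parameter_set()
    ps = assign_parameters(structure, params)
    if ps.unassigned:
        print(f"warning: {len(ps.unassigned)} unassigned atom(s); "
              "supply a full-coverage table for a faithful check")
    iem = build_iem(ps, SolventModel("gb"), exclusions="ff")

    keys = iem.residue_keys
    totals = total_ies(iem)["total"]
    order = np.argsort(totals)
    print("most favorable total IEs:")
    for i in order[: args.top]:
        print(f"  {keys[i]}  {totals[i]:10.3f} kcal/mol")

    phe49 = next((i for i, k in enumerate(keys)
                  if k.seq_number == 49 and k.residue_name == "PHE"), None)
    phe20 = next((i for i, k in enumerate(keys)
                  if k.seq_number == 20 and k.residue_name == "PHE"), None)
    if phe49 is None or phe20 is None:
        sys.exit("Phe49/Phe20 not found; is this really 1HOM?")
    row = iem.total[phe49].copy()
    row[phe49] = np.inf
    rank = int(np.argsort(row).tolist().index(phe20)) + 1
    print(f"\nPhe49–Phe20 pairwise IE: {iem.total[phe49, phe20]:.3f} kcal/mol "
          f"(rank {rank} of Phe49's partners)")
    ok = rank <= args.top
    print("qualitative check:", "PASS" if ok else "NOT within top ranks")


if __name__ == "__main__":
    main()
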