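#!/usr/bin/env python
"""Rolling conservation profiles of the synthetic core-subunit alignment.

Computes 11-residue rolling identity and homology percentages over all taxa
and within each clade, the way windowed conservation is plotted along RNA
polymerase subunits, and confirms the planted architecture: near-100%
identity in conserved blocks, depressed all-taxa identity in the variable
patches where the PEP-like clade stays internally conserved, and a
clade-specific insertion visible as gaps elsewhere.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pepmap.conservation import clade_profiles, map_columns_to_reference
from pepmap.io import read_alignment

BASE = Path(__file__).resolve().parent.parent / "results"
WINDOW = 11


def main() -> None:
    clade_map = json.loads((BASE / "synthetic" / "clade_map.json").read_text())
    aln = read_alignment(BASE / "synthetic" / "core_alignment.fasta", "fasta",
                         clade_map)
    profiles = clade_profiles(aln, ["pep", "bacteria"], WINDOW)
    ref_map = map_columns_to_reference(aln, aln.taxon_ids[0]).mapping

    frame = {"column": np.arange(1, aln.n_columns + 1)}
    frame["reference_residue"] = [ref_map.get(c, "") for c in frame["column"]]
    for prof in profiles:
        frame[f"identity_{prof.subset_label}"] = prof.rolling_identity.round(3)
        frame[f"homology_{prof.subset_label}"] = prof.rolling_homology.round(3)
    table = pd.DataFrame(frame)
    out = BASE / "conservation_profiles.tsv"
    table.to_csv(out, sep="\t", index=False)

    all_prof, pep_prof, _ = profiles
    variable = slice(65, 96)  # interior of the first planted variable patch
    conserved = slice(5, 56)
    print(f"wrote {out} ({aln.n_columns} columns, window {WINDOW})")
    print(f"conserved block: all-taxa rolling identity "
          f"{all_prof.rolling_identity[conserved].mean():.1f}%")
    print(f"variable patch:  all-taxa {all_prof.rolling_identity[variable].mean():.1f}% "
          f"vs PEP clade {pep_prof.rolling_identity[variable].mean():.1f}%")


if __name__ == "__main__":
    main()
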