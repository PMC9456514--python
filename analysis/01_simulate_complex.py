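#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Emulates the data shapes of the RNA polymerase complex study: a core-subunit
alignment with a variable surface patch and a clade-specific insertion, a
two-shell toy structure with known buried/exposed residues, MS1 intensities
at the canonical 2:1:1:1 core copy numbers, and a crosslink table with the
two planted interaction clusters plus decoys.  Everything downstream
(02-05) reads from results/synthetic/.
"""

import json
from pathlib import Path

from pepmap.io import write_structure_pdb
from pepmap.synthetic import (ComplexSpec, MsaSpec, simulate_crosslinks,
                              simulate_intensities, simulate_msa,
                              simulate_structure, write_crosslink_table)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 2022

MSA_SPEC = MsaSpec(
    clades=(("pep", 8), ("bacteria", 5)),
    length=240,
    variable_patches=((61, 100), (181, 210)),
    clade_insertion=("pep", (121, 160)),
    substitution_rate=0.4,
    seed=SEED,
)

COMPLEX_SPEC = ComplexSpec(
    subunits=(("alpha", 330, 2), ("beta", 1070, 1), ("beta_prime", 680, 1),
              ("beta_double_prime", 1380, 1), ("PAP5", 500, 1),
              ("PAP1", 800, 1), ("PAP2", 900, 1), ("PAP11", 700, 1)),
    noise_sigma=0.3,
    n_replicates=3,
    planted_crosslinks=(
        ("alpha", "PAP5", 160, 370, 12.0),
        ("alpha", "beta", 100, 740, 18.0),
        ("beta", "beta_prime", 60, 490, 22.0),
        ("PAP1", "PAP2", 130, 750, 15.0),
        ("PAP1", "PAP11", 560, 610, 14.0),
    ),
    decoy_links=8,
    seed=SEED,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    aln, msa_truth = simulate_msa(MSA_SPEC)
    with (OUT / "core_alignment.fasta").open("w") as fh:
        for tid, seq in zip(aln.taxon_ids, aln.sequences):
            fh.write(f">{tid}\n{seq}\n")
    (OUT / "clade_map.json").write_text(json.dumps(
        dict(zip(aln.taxon_ids, aln.clade_labels)), indent=2))
    (OUT / "msa_truth.json").write_text(json.dumps(
        {str(k): v for k, v in msa_truth["column_label"].items()}))
    print(f"alignment: {aln.n_taxa} taxa x {aln.n_columns} columns "
          f"(variable {MSA_SPEC.variable_patches}, insertion "
          f"{MSA_SPEC.clade_insertion})")

    model, exposure_truth = simulate_structure(120, "two_shell")
    write_structure_pdb(model, OUT / "two_shell.pdb")
    (OUT / "exposure_truth.json").write_text(json.dumps(
        {str(k): v for k, v in exposure_truth.items()}))
    n_buried = sum(1 for e in exposure_truth.values() if not e)
    print(f"structure: 120 residues ({n_buried} buried by construction)")

    intensities, sequences = simulate_intensities(COMPLEX_SPEC)
    intensities.to_csv(OUT / "intensities.tsv", sep="\t", index=False)
    with (OUT / "sequences.fasta").open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    print(f"intensities: {len(intensities)} rows, "
          f"{COMPLEX_SPEC.n_replicates} replicates, sigma="
          f"{COMPLEX_SPEC.noise_sigma}")

    links, link_truth = simulate_crosslinks(COMPLEX_SPEC)
    write_crosslink_table(links, OUT / "crosslinks.tsv")
    (OUT / "crosslink_truth.json").write_text(json.dumps(link_truth))
    print(f"crosslinks: {len(links)} rows "
          f"({len(COMPLEX_SPEC.planted_crosslinks)} planted in "
          f"{len(link_truth['clusters'])} clusters, "
          f"{COMPLEX_SPEC.decoy_links} decoys)")


if __name__ == "__main__":
    main()
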