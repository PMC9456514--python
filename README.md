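# pepmap

Computational analyses of the **plastid-encoded RNA polymerase (PEP)**
complex — the prokaryotic-type RNA polymerase of chloroplasts whose
catalytic core (α₂ββ′β″, genes *rpoA/rpoB/rpoC1/rpoC2*) assembles with
twelve nuclear-encoded PEP-associated proteins (PAP1–PAP12) plus candidate
subunits (FLN2, pTAC18) into a >900 kDa complex essential for chloroplast
biogenesis.

The package is organised as an analysis project: the library under
`src/pepmap/` implements every computation, the numbered scripts under
`analysis/` drive the study narrative, and everything is testable offline
because a synthetic-data module generates alignments, structures, intensity
tables and crosslink tables with known ground truth.

It is aimed at structural bioinformaticians integrating three evidence
streams about a multi-subunit complex:

1. **Windowed alignment conservation** (`pepmap.conservation`) — per-column
   identity/homology percentages with an 11-residue centred rolling mean,
   over all taxa and clade subsets. Identity at column *c* for subset *S* is
   the modal non-gap residue frequency, `100 · max_a n_a(c) / |S|`; homology
   replaces residues by a six-class physicochemical partition (positive
   KRH, negative DE, polar STNQ, aromatic FWY, aliphatic AVLIMC, special
   GP), so homology ≥ identity columnwise.
2. **Divergence mapped onto structure** (`pepmap.divergence`) — columns
   classified homologous/nonhomologous/gap between two clades, runs of ≥3
   consecutive reference residues with changed functional groups, a
   Shrake–Rupley solvent-accessible surface area (probe 1.4 Å) with relative
   exposure against per-residue maxima (exposed ⇔ rel. SASA ≥ 0.25), and a
   two-sided exact test on the variable/conserved × exposed/buried 2×2
   table.
3. **Crosslinking-MS networks** (`pepmap.xlms`) — DSBU hetero-dipeptide
   tables parsed into records with absolute link positions
   (`abs = from + relative − 1`), filtered (score ≥ 30; link sites in
   {K,S,T,Y} or N-terminal), merged across replicates (union, max score),
   clustered as connected components of the protein graph after restricting
   to complex members, and checked against Cα–Cα distances (compatible ⇔
   ≤ 30 Å).
4. **iBAQ stoichiometry** (`pepmap.ibaq`) — intensity-based absolute
   quantification: summed MS1 intensity divided by the count of fully
   cleaved Trypsin/P peptides of 6–30 residues, normalised per sample,
   summed over replicates, and expressed relative to the α subunit
   (iBAQr). The α:β final-iBAQ ratio estimates core stoichiometry.

A curated subunit registry (`pepmap.registry`) resolves the many aliases in
circulation (PAP5 = pTAC12 = HEMERA, PAP11 = MurE, SaRpoC1 = β′, …) and
keeps paralog ambiguity (PAP6/FLN1 vs FLN2 share peptides) as single group
nodes.

## Worked example

The printed table of the 12 best hetero-dipeptides ships with the package.
Processing it end to end:

```python
from pepmap.registry import load_registry
from pepmap.xlms import (parse_crosslink_table, bundled_table1_path,
                         filter_records, build_graph)

records = parse_crosslink_table(bundled_table1_path())
kept, dropped = filter_records(records, min_score=30.0)
graph = build_graph(kept, load_registry(), restrict_to_members=True)
print(len(records), len(kept), graph.clusters)
```

prints

```
12 12 [['PAP5', 'PAP6/FLN2', 'alpha', 'beta', 'beta_prime'], ['PAP1', 'PAP11', 'PAP2']]
```

— all 12 dipeptides pass the score/site filters, and member-restricted
clustering yields two clusters: PAP5 with the FLN paralog group, α, β′ and
β (the latter joined through two β–β′ dipeptides), and PAP1–PAP2–PAP11.
Non-member copurifiers (ribosomal protein S2, the SPPA protease) attach to
these clusters only when restriction is off. Individual link sites follow
the absolute-position rule, e.g. the α-subunit peptide GYSLKMSNNFEDR
starting at 156 crosslinks through Tyr at relative position 2 → residue
157, and through Lys at relative 5 → residue 160.

The analysis drivers reproduce the full narrative on synthetic data with
known truth:

```bash
python analysis/01_simulate_complex.py     # inputs + ground truth
python analysis/02_conservation_profiles.py
python analysis/03_map_divergence.py
python analysis/04_crosslink_network.py
python analysis/05_ibaq_stoichiometry.py
```

e.g. `05` reports (at the shipped seed):

```
alpha:beta ratio 1.10 (bootstrap 95% CI 0.73-1.72; truth 2.0)
100-seed recovery: median ratio 1.928 (IQR 1.704-2.268)
```

— a single 3-replicate run is noisy under lognormal σ = 0.3 intensity
noise (this seed draws from the low tail), while the estimator's median
over 100 simulations lands within 4% of the true 2:1 α:β copy-number
ratio.

A `pep-map` CLI wraps the same stages
(`conserve | mapdiverge | xlms | ibaq | simulate | run`); see
`pep-map --help`.

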