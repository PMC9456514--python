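# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic benchmarks do and do not establish.

## Conservation statistics

**Identity** at an alignment column, for a taxa subset *S*, is the modal
non-gap residue frequency `100 · max_a n_a / |S|`. This is the statistic a
per-column "percent identity" track needs and matches the shading logic of
BOXSHADE-style alignment displays; it is *not* mean pairwise identity,
which is smoother and lacks a natural per-column mode. Gaps remain in the
denominator and never count as the mode, so a column that is all gaps
scores 0 and a half-gapped column cannot score 100. **Homology** applies
the same statistic after mapping residues to a six-class physicochemical
partition (positive KRH, negative DE, polar STNQ, aromatic FWY, aliphatic
AVLIMC, special GP), making homology ≥ identity a structural invariant.
The partition is a package convention: windowed "homology" tracks in the
literature rarely print their grouping, and this standard partition makes
the statistic operational and testable.

**Rolling profiles** use a centred moving mean, default window 11 residues
(odd enforced). Ends use shrinking windows rather than dropping ⌊w/2⌋
columns per side, so profile length equals alignment length — a requirement
for mapping window values onto structure residues. The shrinking window
biases end values toward their local mean; mean preservation over the whole
profile is exact only for constant input.

## Clade divergence and structure mapping

Columns are compared between two clades by their modal residues: *gap* when
either clade is majority-gap (gaps strictly outnumber residues),
*homologous* when both modal residues share a functional group,
*nonhomologous* otherwise. "Strong functional-group change" is a maximal
run of ≥3 consecutive reference residues whose columns are nonhomologous;
runs are counted in reference-residue coordinates, so columns where the
reference has a gap carry no residue and cannot extend a run. The length-3
threshold separates isolated substitutions from candidate interaction
patches.

**SASA** is a Shrake–Rupley numerical integration: each heavy atom inflated
by the probe radius (default 1.4 Å), sampled with a deterministic
golden-spiral point set (default 960 points/atom), occlusion by
neighbouring inflated spheres found via a k-d tree. Van der Waals radii:
C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20 Å (hydrogens are skipped).
Relative exposure divides residue SASA by a per-residue-type theoretical
maximum (Tien-style table); residues are *exposed* at relative SASA ≥ 0.25,
the common field convention — stated explicitly here because exposure
thresholds are often left implicit. Tests pin the integrator to the
analytic sphere (<2% error at 960 points), to resolution stability
(960 vs 4000 points within 3%), and to an independent implementation
(biotite) on a lattice fixture.

**Surface enrichment** of variable sites uses the 2×2 table
(variable/conserved × exposed/buried) with a two-sided Fisher exact test.
The published observation that variable polymerase-core sites concentrate
at the surface is qualitative; the exact test is this package's way of
making it assertable. A zero row/column margin makes the odds ratio
undefined (flagged, p still reported); a perfectly separated table with
non-zero margins yields an infinite odds ratio, which is reported as such.

## Crosslink processing

Dipeptide rows carry two peptides with 1-based inclusive spans ("From/To")
and link sites as (residue letter, position relative to the peptide).
Absolute positions are `from + relative − 1` throughout. Rows whose span
width disagrees with the peptide length are kept but flagged
(`span_mismatch`): the From coordinate and relative site suffice to place
the link, and such discrepancies in printed tables are typographic more
often than biological. Peptide strings admit the letters B/U/X beyond the
20 amino acids because search engines print modified residues that way
(e.g. carbamidomethyl-Cys as B).

Filtering retains score ≥ 30 (the search engine's minimum reporting
cut-off) and link residues consistent with DSBU chemistry — K, S, T, Y or
the protein N-terminus. Replicate merging is a union keyed by the unordered
(protein, absolute position) pair, keeping the maximum score and all
replicate ids; it is idempotent and commutative.

Graphs are undirected with weighted edges (supporting records, max score).
Ambiguous paralog labels ("PAP6/FLN1; FLN2", "RPS2A; RPS2B") become single
group nodes: shared peptides cannot distinguish paralogs, and duplicating
nodes would fabricate connectivity. Clusters are connected components after
optionally dropping non-member nodes, ordered by size then name. Self-links
are retained as records but cannot join two distinct nodes. The distance
check uses Cα–Cα ≤ 30 Å for DSBU (12.5 Å spacer plus two side chains and
backbone flexibility — the common modelling convention; configurable),
with links to residues absent from the model counted as unmapped, never as
(in)compatible.

## iBAQ and stoichiometry

Digestion follows Trypsin/P: cleavage after every K/R including before
proline. The iBAQ denominator counts *fully cleaved* peptides of 6–30
residues; the "two missed cleavages" setting belongs to the identification
search, not to the theoretical peptide count (both bounds configurable).
Raw iBAQ = summed MS1 intensity / theoretical peptide count. Within each
sample, values are normalised to fractions of the sample total; the final
iBAQ sums these fractions across replicates (a mean-based combiner is
available behind a flag). This makes final iBAQ invariant to per-replicate
global intensity scale, and proteins missing from a replicate contribute 0
there (no imputation). iBAQr divides by the α subunit's final iBAQ, so
iBAQr(α) = 1 identically. Stoichiometry ratios are final-iBAQ quotients
with a percentile bootstrap over replicates; with only 3 replicates the
interval is fragile and a single run can land in the tails (the shipped
demo seed does), which is why the recovery claim rests on the median over
100 simulations.

Shared/razor peptide apportionment is out of scope: the input intensity
table is assumed to carry per-protein razor+specific intensities as the
quantification software exported them.

## Subunit registry

The registry ships as a versioned TSV: 4 core subunits, 12 PAPs, and
candidate members (FLN2, pTAC18), with case-insensitive alias resolution
that also strips species prefixes ("SaRpoA" → α) and collapses synonym
compounds ("PAP5/PTAC12"). The FLN1/FLN2 ambiguity is deliberately *not*
resolved: the printed evidence cannot distinguish the paralogs, so the
registry and graphs carry a shared-peptide group.

## Synthetic data: what it emulates, and what passing tests show

Generators are pure functions of (spec, seed) over `numpy.random.default_rng`.

- **Alignments**: conserved background/blocks identical across taxa;
  variable patches draw a clade-specific consensus then mutate each taxon
  at `substitution_rate` (default 0.5 — high enough that all-taxa and
  within-clade identity separate clearly at the default clade sizes);
  clade insertions are gapped outside their clade. No substitution-matrix
  phylogenetics: columns are independent, so these alignments test the
  statistics, not evolutionary realism.
- **Structures**: ideal α-helix Cα traces (rise 1.5 Å, 100°/residue,
  radius 2.3 Å → consecutive Cα ≈ 3.83 Å), and a "two-shell" fold: a dense
  cubic-lattice ball (1.8 Å spacing) whose surface sits ~3.5 Å beneath a
  sparse spherical shell (~5 Å spacing), the inner/outer split solved at
  build time so both spacings hold at any size. By construction every
  inner residue's relative SASA (~0.02) falls below every outer one's
  (~0.4), straddling the 0.25 threshold — a clean classification target,
  not a protein-like packing.
- **Intensities**: intensity = copy number × theoretical peptide count ×
  lognormal(0, σ) × replicate scale. σ defaults to 0.3, a typical
  label-free MS1 between-replicate error; the replicate scale (lognormal,
  σ=0.5) cancels under per-sample normalisation and exists to prove it.
  Sequences place a Lys at every 10th residue so tryptic peptide counts
  are known exactly.
- **Crosslinks**: planted links join Lys sites of member subunits with
  scores in [40, 150]; decoys attach invented partners with scores uniform
  on [0, 60] so the score filter is exercised on both sides of its cutoff.

Because the generators share none of the analysis code paths (ground truth
is emitted at construction), recovering planted clusters, exposure labels
or copy-number ratios is a genuine round-trip. What passing tests do *not*
show: robustness to homologous mis-assignment, shared-peptide
apportionment, non-multiplicative intensity error, or real crosslink FDR
behaviour — none of which the generators model.

## Problem sizes

Default test and demo sizes are deliberately small: alignments of ≤13 taxa
× ≤400 columns, structures of ≤150 single-Cα residues, 100-seed
stoichiometry sweeps, 960-point SASA spheres. These sizes keep the full
suite in a few seconds while leaving every statistic's sampling error well
inside its assertion band; all are configurable upward.
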