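"""Seeded generators of alignments, structures, intensity tables and
crosslink tables with known ground truth.

These emulate the data shapes of a multi-subunit RNA polymerase study —
alignments with conserved catalytic blocks, clade-specific insertions and
variable surface patches; MS1 intensity tables from known subunit copy
numbers under multiplicative noise; crosslink tables with planted clusters
and decoy partners; toy structures with known buried/exposed residues — so
every analysis stage can be scored against construction-time truth.  All
generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ibaq import DigestConfig, theoretical_peptide_count
from .io import MultipleAlignment, Residue, StructureModel

__all__ = [
    "MsaSpec",
    "ComplexSpec",
    "simulate_msa",
    "simulate_structure",
    "simulate_intensities",
    "simulate_crosslinks",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class MsaSpec:
    """Blueprint of a synthetic alignment.

    Column ranges are 1-based inclusive and must not overlap.  Conserved
    blocks are identical across all taxa; variable patches carry a
    clade-specific consensus mutated per taxon at ``substitution_rate``; the
    clade insertion exists only in its clade and is gapped elsewhere.
    Background columns (in no listed range) are conserved.
    """

    clades: tuple[tuple[str, int], ...]
    length: int
    conserved_blocks: tuple[tuple[int, int], ...] = ()
    variable_patches: tuple[tuple[int, int], ...] = ()
    clade_insertion: tuple[str, tuple[int, int]] | None = None
    substitution_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for _, n in self.clades):
            raise ValueError("every clade needs at least 2 taxa")
        ranges = list(self.conserved_blocks) + list(self.variable_patches)
        if self.clade_insertion is not None:
            label = self.clade_insertion[0]
            if label not in {c for c, _ in self.clades}:
                raise ValueError(f"insertion clade {label!r} not in clades")
            ranges.append(self.clade_insertion[1])
        occupied: set[int] = set()
        for lo, hi in ranges:
            if not 1 <= lo <= hi <= self.length:
                raise ValueError(f"range ({lo}, {hi}) outside 1..{self.length}")
            cols = set(range(lo, hi + 1))
            if cols & occupied:
                raise ValueError("overlapping column ranges")
            occupied |= cols
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")


def simulate_msa(spec: MsaSpec) -> tuple[MultipleAlignment, dict]:
    """Generate an alignment plus ground-truth column labels.

    Returns (alignment, truth) where truth maps 1-based columns to one of
    "conserved" / "variable" / "insertion".
    """
    rng = np.random.default_rng(spec.seed)
    consensus = rng.choice(AMINO_ACIDS, size=spec.length)
    truth = {c: "conserved" for c in range(1, spec.length + 1)}
    variable_cols: set[int] = set()
    for lo, hi in spec.variable_patches:
        for c in range(lo, hi + 1):
            truth[c] = "variable"
            variable_cols.add(c)
    insertion_cols: set[int] = set()
    insertion_clade = None
    if spec.clade_insertion is not None:
        insertion_clade, (lo, hi) = spec.clade_insertion
        for c in range(lo, hi + 1):
            truth[c] = "insertion"
            insertion_cols.add(c)
    # each clade gets its own consensus on variable columns, drawn to differ
    # between clades so clade-internal identity beats all-taxa identity there
    clade_consensus: dict[str, np.ndarray] = {}
    for ci, (label, _) in enumerate(spec.clades):
        cc = consensus.copy()
        for c in variable_cols:
            cc[c - 1] = AMINO_ACIDS[(int(rng.integers(20)) + ci * 7) % 20]
        clade_consensus[label] = cc
    taxon_ids, clade_labels, sequences = [], [], []
    for label, n_taxa in spec.clades:
        for t in range(n_taxa):
            row = clade_consensus[label].copy()
            for c in variable_cols:
                if rng.random() < spec.substitution_rate:
                    row[c - 1] = rng.choice(AMINO_ACIDS)
            for c in insertion_cols:
                if label != insertion_clade:
                    row[c - 1] = "-"
            taxon_ids.append(f"{label}_{t + 1}")
            clade_labels.append(label)
            sequences.append("".join(row))
    aln = MultipleAlignment(taxon_ids, clade_labels, sequences)
    return aln, {"column_label": truth, "consensus": "".join(consensus)}


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def simulate_structure(n_residues: int, fold: str = "helix", chain_id: str = "A",
                       ) -> tuple[StructureModel, dict[int, bool] | None]:
    """Toy Cα-trace structures with known geometry.

    "helix": ideal α-helix trace (rise 1.5 Å, 100° twist, radius 2.3 Å), so
    consecutive Cα–Cα distances are ≈3.8 Å.  "two_shell": an inner cluster
    (ground-truth buried) enclosed by a dense outer shell (ground-truth
    exposed).  Returns (model, exposure truth or None); truth maps residue
    numbers to the exposed flag.
    """
    if fold == "helix":
        if n_residues < 2:
            raise ValueError("helix needs at least 2 residues")
        rise, twist, radius = 1.5, np.deg2rad(100.0), 2.3
        residues = []
        for i in range(n_residues):
            xyz = np.array([radius * np.cos(i * twist),
                            radius * np.sin(i * twist),
                            rise * i])
            residues.append(Residue(chain_id, i + 1, "ALA", {"CA": xyz}))
        return StructureModel(residues), None
    if fold == "two_shell":
        if n_residues < 12:
            raise ValueError("two_shell needs at least 12 residues")
        # inner: a dense cubic-lattice ball (1.8 Å spacing) whose surface sits
        # ~3.5 Å under the shell; outer: a sparse shell (~5 Å spacing) whose
        # atoms keep an open outward hemisphere.  The split between inner and
        # outer counts is solved so both spacings hold at any n, which keeps
        # every inner residue's relative SASA well below every outer one's.
        lattice_spacing, shell_spacing, shell_gap = 1.8, 5.0, 3.5
        m = 8
        g = np.arange(-m, m + 1) * lattice_spacing
        lattice = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        lattice = lattice[np.argsort(np.linalg.norm(lattice, axis=1))]
        best: tuple[float, int, float] | None = None
        for ni in range(1, n_residues - 3):
            ball_r = float(np.linalg.norm(lattice[ni - 1]))
            shell_r = np.sqrt((n_residues - ni) * shell_spacing**2 / (4.0 * np.pi))
            err = abs(shell_r - (ball_r + shell_gap))
            if best is None or err < best[0]:
                best = (err, ni, shell_r)
        _, n_inner, shell_r = best  # type: ignore[misc]
        shell = shell_r * _fibonacci_sphere(n_residues - n_inner)
        residues, truth = [], {}
        for i, pt in enumerate(lattice[:n_inner]):
            residues.append(Residue(chain_id, i + 1, "ALA", {"CA": pt.astype(float)}))
            truth[i + 1] = False
        for j, pt in enumerate(shell):
            num = n_inner + j + 1
            residues.append(Residue(chain_id, num, "ALA", {"CA": pt.copy()}))
            truth[num] = True
        return StructureModel(residues), truth
    raise ValueError(f"unknown fold: {fold!r}")


@dataclass(frozen=True)
class ComplexSpec:
    """Blueprint of a synthetic protein complex for MS emulation.

    ``subunits`` lists (name, sequence length, copy number); sequence
    lengths should be multiples of 10 so tryptic peptide counts are known by
    construction (every 10th residue is a Lys).  ``planted_crosslinks``
    lists (protein 1, protein 2, residue 1, residue 2, true distance Å);
    decoys attach non-member partners with scores spanning the score filter
    cutoff.
    """

    subunits: tuple[tuple[str, int, int], ...]
    noise_sigma: float = 0.3
    n_replicates: int = 3
    planted_crosslinks: tuple[tuple[str, str, int, int, float], ...] = ()
    decoy_links: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(copy < 1 for _, _, copy in self.subunits):
            raise ValueError("copy numbers must be >= 1")
        if any(length < 10 for _, length, _ in self.subunits):
            raise ValueError("subunit lengths must be >= 10")
        if any(d < 0 for *_, d in self.planted_crosslinks):
            raise ValueError("distances must be >= 0")


# 9 non-K/R residues followed by K: a clean tryptic decapeptide unit
_PEPTIDE_UNIT = "ADEFGHILS" + "K"


def synthetic_sequence(length: int) -> str:
    """Sequence of the given length with a K at every 10th position."""
    reps = -(-length // 10)
    return (_PEPTIDE_UNIT * reps)[:length]


def simulate_intensities(spec: ComplexSpec,
                         config: DigestConfig = DigestConfig(),
                         ) -> tuple[pd.DataFrame, dict[str, str]]:
    """MS1 intensity table from known copy numbers under lognormal noise.

    intensity = copy_number x theoretical peptide count x lognormal(0, σ)
    x replicate scale factor; the per-replicate scale cancels under
    per-sample normalisation.
    """
    rng = np.random.default_rng(spec.seed)
    sequences = {name: synthetic_sequence(length) for name, length, _ in spec.subunits}
    rep_scale = np.exp(rng.normal(0.0, 0.5, size=spec.n_replicates))
    rows = []
    for rep in range(spec.n_replicates):
        rep_id = f"rep{rep + 1}"
        for name, _, copy in spec.subunits:
            count = theoretical_peptide_count(sequences[name], config)
            noise = np.exp(rng.normal(0.0, spec.noise_sigma))
            rows.append({
                "protein_id": name,
                "replicate_id": rep_id,
                "intensity": copy * count * noise * rep_scale[rep] * 1e6,
            })
    return pd.DataFrame(rows), sequences


def simulate_crosslinks(spec: ComplexSpec) -> tuple[pd.DataFrame, dict]:
    """Crosslink table in the printed-table dialect, with planted truth.

    Planted links join K sites of member subunits with scores in [40, 150]
    (always above the score cutoff of 30); decoys pair random subunits with
    invented partners at scores uniform on [0, 60], straddling the cutoff.
    Returns (table, truth) with truth holding the planted pairs and the
    expected clusters (connected components of the planted edges).
    """
    rng = np.random.default_rng(spec.seed + 1)
    sequences = {name: synthetic_sequence(length) for name, length, _ in spec.subunits}

    def peptide_at(name: str, residue: int) -> tuple[str, int, int, str]:
        seq = sequences[name]
        if not 1 <= residue <= len(seq):
            raise ValueError(f"residue {residue} outside {name!r}")
        if seq[residue - 1] != "K":
            raise ValueError(f"planted site {name}:{residue} is not a Lys")
        start = max(1, residue - 9)  # tryptic peptide ending at this K
        rel = residue - start + 1
        return seq[start - 1:residue], start, residue, f"K{rel}"

    rows = []
    for p1, p2, r1, r2, _dist in spec.planted_crosslinks:
        pep1, f1, t1, aa1 = peptide_at(p1, r1)
        pep2, f2, t2, aa2 = peptide_at(p2, r2)
        rows.append({
            "Protein 1 Names": p1, "Protein 2 Names": p2,
            "xLinkScore": round(float(rng.uniform(40.0, 150.0)), 2),
            "Peptide 1": f"[{pep1}]", "From": f1, "To": t1, "aa 1": aa1,
            "Peptide 2": f"[{pep2}]", "From_2": f2, "To_2": t2, "aa 2": aa2,
        })
    names = [name for name, _, _ in spec.subunits]
    for d in range(spec.decoy_links):
        partner = names[int(rng.integers(len(names)))]
        seq = sequences[partner]
        k_sites = [i + 1 for i, aa in enumerate(seq) if aa == "K"]
        site = int(rng.choice(k_sites))
        pep, f1, t1, aa1 = peptide_at(partner, site)
        rows.append({
            "Protein 1 Names": partner, "Protein 2 Names": f"DECOY{d + 1}",
            "xLinkScore": round(float(rng.uniform(0.0, 60.0)), 2),
            "Peptide 1": f"[{pep}]", "From": f1, "To": t1, "aa 1": aa1,
            "Peptide 2": "[ADEFGHILSK]", "From_2": 1, "To_2": 10, "aa 2": "K10",
        })
    df = pd.DataFrame(rows, columns=[
        "Protein 1 Names", "Protein 2 Names", "xLinkScore",
        "Peptide 1", "From", "To", "aa 1", "Peptide 2", "From_2", "To_2", "aa 2",
    ]).rename(columns={"From_2": "From", "To_2": "To"})
    # connected components of the planted edges = expected clusters
    adj: dict[str, set[str]] = {}
    for p1, p2, *_ in spec.planted_crosslinks:
        adj.setdefault(p1, set()).add(p2)
        adj.setdefault(p2, set()).add(p1)
    clusters, seen = [], set()
    for node in sorted(adj):
        if node in seen:
            continue
        comp, stack = set(), [node]
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        clusters.append(sorted(comp))
    clusters.sort(key=lambda c: (-len(c), c))
    truth = {"planted": list(spec.planted_crosslinks), "clusters": clusters}
    return df, truth


def write_crosslink_table(df: pd.DataFrame, path) -> None:
    """Write a crosslink table in the tab-delimited printed dialect."""
    df.to_csv(path, sep="\t", index=False)
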