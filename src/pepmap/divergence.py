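"""Functional-group divergence between clades mapped onto structures.

Columns of an alignment are compared between two clades (e.g. the plastid
RNA polymerase clade vs bacterial references): a column is *homologous* when
the modal residues of both clades fall in the same physicochemical group,
*nonhomologous* when they differ, and *gap* when either clade is
majority-gap.  Runs of at least ``min_run`` consecutive nonhomologous
reference residues mark strong functional-group change; mapped onto a
structure, these flag candidate interaction surfaces.  A Shrake–Rupley SASA
classifies residues as exposed or buried so the surface localisation of
variable sites can be tested with an exact 2x2 test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import fisher_exact

from .io import GAP, MultipleAlignment, Residue, StructureModel

__all__ = [
    "FUNCTIONAL_GROUPS",
    "group_of",
    "ColumnClass",
    "classify_columns",
    "StrongChangeRun",
    "find_strong_change_runs",
    "AccessibilityResult",
    "compute_sasa",
    "map_annotations_to_structure",
    "surface_enrichment",
]

# Six-class physicochemical partition of the 20 amino acids.
FUNCTIONAL_GROUPS: dict[str, frozenset[str]] = {
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQ"),
    "aromatic": frozenset("FWY"),
    "aliphatic": frozenset("AVLIMC"),
    "special": frozenset("GP"),
}

_GROUP_OF = {aa: g for g, members in FUNCTIONAL_GROUPS.items() for aa in members}


def group_of(aa: str, table: dict[str, frozenset[str]] = FUNCTIONAL_GROUPS) -> str:
    """Functional group of a residue letter; the gap is its own class."""
    if aa == GAP:
        return "gap"
    if table is FUNCTIONAL_GROUPS:
        try:
            return _GROUP_OF[aa]
        except KeyError:
            raise KeyError(f"unknown residue letter: {aa!r}") from None
    for g, members in table.items():
        if aa in members:
            return g
    raise KeyError(f"unknown residue letter: {aa!r}")


@dataclass
class ColumnClass:
    """Classification of one alignment column between two clades."""

    column: int  # 1-based
    cls: str  # "homologous" | "nonhomologous" | "gap"
    group_a: str | None
    group_b: str | None


def _modal_residue(column: np.ndarray) -> str | None:
    nongap = column[column != GAP]
    if nongap.size == 0:
        return None
    letters, counts = np.unique(nongap, return_counts=True)
    return str(letters[np.argmax(counts)])


def classify_columns(msa: MultipleAlignment, clade_a: list[str], clade_b: list[str],
                     group_table: dict[str, frozenset[str]] = FUNCTIONAL_GROUPS,
                     ) -> list[ColumnClass]:
    """Classify every column as homologous / nonhomologous / gap.

    A clade is majority-gap at a column when gaps outnumber residues; either
    clade majority-gap makes the column class "gap".
    """
    if not clade_a or not clade_b:
        raise ValueError("both clades must be non-empty")
    if set(clade_a) & set(clade_b):
        raise ValueError("clades overlap")
    arr = msa.as_array()
    ia = msa.subset_indices(clade_a)
    ib = msa.subset_indices(clade_b)
    out: list[ColumnClass] = []
    for col in range(msa.n_columns):
        col_a, col_b = arr[ia, col], arr[ib, col]
        gap_a = int((col_a == GAP).sum()) * 2 > len(ia)
        gap_b = int((col_b == GAP).sum()) * 2 > len(ib)
        mod_a, mod_b = _modal_residue(col_a), _modal_residue(col_b)
        if gap_a or gap_b or mod_a is None or mod_b is None:
            out.append(ColumnClass(col + 1, "gap", None, None))
            continue
        ga, gb = group_of(mod_a, group_table), group_of(mod_b, group_table)
        cls = "homologous" if ga == gb else "nonhomologous"
        out.append(ColumnClass(col + 1, cls, ga, gb))
    return out


@dataclass
class StrongChangeRun:
    """Maximal run of consecutive reference residues with changed groups."""

    start_residue: int
    end_residue: int

    @property
    def length(self) -> int:
        return self.end_residue - self.start_residue + 1


def find_strong_change_runs(classes: list[ColumnClass], column_to_reference,
                            min_run: int = 3) -> list[StrongChangeRun]:
    """Runs of >= min_run consecutive reference residues whose columns are
    nonhomologous (modal functional group differs between the clades).

    Runs live in reference numbering: columns unmapped in the reference
    (reference gaps) break runs.
    """
    mapping = column_to_reference.mapping
    flagged = sorted(
        mapping[c.column] for c in classes
        if c.cls == "nonhomologous" and c.column in mapping
    )
    runs: list[StrongChangeRun] = []
    i = 0
    while i < len(flagged):
        j = i
        while j + 1 < len(flagged) and flagged[j + 1] == flagged[j] + 1:
            j += 1
        if j - i + 1 >= min_run:
            runs.append(StrongChangeRun(flagged[i], flagged[j]))
        i = j + 1
    return runs


# Van der Waals radii (Å) by element, and Tien-style theoretical maximum
# SASA (Å²) per residue type for relative exposure.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    # two-letter elements are not expected in protein heavy atoms; the first
    # alphabetic character identifies C/N/O/S/P/H
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


@dataclass
class AccessibilityResult:
    """Per-residue solvent accessibility with an exposed/buried call."""

    absolute: dict[tuple[str, int], float]  # Å²
    relative: dict[tuple[str, int], float]  # fraction of residue-type maximum
    exposed: dict[tuple[str, int], bool]
    probe_radius: float = 1.4
    exposure_threshold: float = 0.25


def compute_sasa(model: StructureModel, probe_radius: float = 1.4,
                 n_points: int = 960,
                 exposure_threshold: float = 0.25) -> AccessibilityResult:
    """Shrake–Rupley numerical SASA per residue.

    Each atom is inflated by the probe radius and sampled with ``n_points``
    quasi-uniform surface points; points inside any neighbouring inflated
    sphere are occluded.  Deterministic for a given ``n_points``.
    """
    atoms: list[tuple[int, np.ndarray, float]] = []  # residue index, centre, radius
    for ri, res in enumerate(model.residues):
        if not res.atoms:
            raise ValueError(f"residue {res.chain_id}/{res.number} has no atoms")
        for name, xyz in res.atoms.items():
            elem = _element_of(name)
            if elem == "H":
                continue
            atoms.append((ri, np.asarray(xyz, float), VDW_RADII[elem] + probe_radius))
    centres = np.array([a[1] for a in atoms])
    radii = np.array([a[2] for a in atoms])
    sphere = _sphere_points(n_points)
    tree = cKDTree(centres)
    max_r = radii.max()
    per_residue: dict[tuple[str, int], float] = {
        (r.chain_id, r.number): 0.0 for r in model.residues
    }
    for i, (ri, centre, radius) in enumerate(atoms):
        pts = centre + radius * sphere
        neighbours = [j for j in tree.query_ball_point(centre, radius + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - centres[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        area = 4.0 * np.pi * radius**2 * accessible.sum() / n_points
        res = model.residues[ri]
        per_residue[(res.chain_id, res.number)] += area
    relative: dict[tuple[str, int], float] = {}
    exposed: dict[tuple[str, int], bool] = {}
    for res in model.residues:
        key = (res.chain_id, res.number)
        max_area = MAX_SASA.get(res.name)
        rel = per_residue[key] / max_area if max_area else float("nan")
        relative[key] = rel
        exposed[key] = bool(rel >= exposure_threshold) if max_area else False
    return AccessibilityResult(per_residue, relative, exposed,
                               probe_radius, exposure_threshold)


def map_annotations_to_structure(annotation: dict[int, dict[str, object]],
                                 model: StructureModel,
                                 chain_id: str) -> int:
    """Attach per-reference-residue attributes to one chain of the model.

    ``annotation`` maps reference residue numbers to attribute dicts (e.g.
    {"divergence_class": ..., "strong_change": ...}).  Returns the number of
    annotated residues absent from the model (tolerated, reported).
    """
    if chain_id not in model.chains:
        raise KeyError(f"chain {chain_id!r} absent from model")
    unmapped = 0
    for resnum, attrs in annotation.items():
        if model.get(chain_id, resnum) is None:
            unmapped += 1
            continue
        model.annotate(chain_id, resnum, **attrs)
    return unmapped


@dataclass
class EnrichmentResult:
    fraction_variable_exposed: float
    fraction_conserved_exposed: float
    odds_ratio: float | None  # None when a contingency margin is zero
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool


def surface_enrichment(model: StructureModel, access: AccessibilityResult,
                       class_attr: str = "divergence_class",
                       variable_classes: tuple[str, ...] = ("nonhomologous",),
                       conserved_classes: tuple[str, ...] = ("homologous",),
                       ) -> EnrichmentResult:
    """Test whether variable residues are enriched at the surface.

    Builds the 2x2 table (variable/conserved x exposed/buried) over residues
    carrying both a divergence class and an accessibility value, and applies
    a two-sided exact test.
    """
    ve = vb = ce = cb = 0
    for key, attrs in model.annotations.items():
        cls = attrs.get(class_attr)
        if key not in access.exposed or cls is None:
            continue
        is_exp = access.exposed[key]
        if cls in variable_classes:
            ve, vb = ve + is_exp, vb + (not is_exp)
        elif cls in conserved_classes:
            ce, cb = ce + is_exp, cb + (not is_exp)
    if ve + vb == 0 or ce + cb == 0:
        raise ValueError("need at least one variable and one conserved residue")
    table = ((ve, vb), (ce, cb))
    degenerate = 0 in (ve + vb, ce + cb, ve + ce, vb + cb)
    odds, p = fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        fraction_variable_exposed=ve / (ve + vb),
        fraction_conserved_exposed=ce / (ce + cb),
        odds_ratio=None if degenerate else float(odds),
        p_value=float(p),
        table=table,
        degenerate=degenerate,
    )
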