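"""Crosslinking-MS dipeptide processing: parsing, filtering, replicate
merging, interaction graphs and Cα–Cα distance compatibility.

A hetero-dipeptide is a pair of crosslinked peptides from two proteins,
identified from one spectrum.  Each row carries the two peptide sequences,
their 1-based inclusive spans in the parent proteins ("From"/"To") and the
crosslinked amino acid with its position relative to the peptide ("K5" =
lysine, 5th residue of the peptide).  The absolute crosslinked position in
the protein is ``from + relative − 1``.  The DSBU crosslinker reacts with
Lys, Ser, Thr, Tyr and protein N-termini, and its spacer geometry bounds
compatible Cα–Cα distances (default 30 Å).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import StructureModel
from .registry import SubunitRegistry

__all__ = [
    "CrosslinkRecord",
    "parse_crosslink_table",
    "bundled_dipeptide_table",
    "absolute_position",
    "filter_records",
    "merge_replicates",
    "InteractionGraph",
    "build_graph",
    "DistanceAssessment",
    "assess_distances",
]

DSBU_SITE_RESIDUES = frozenset("KSTY")
_BRACKETS = str.maketrans("", "", "[](){}")
_SITE_RE = re.compile(r"^([A-Z])(\d+)$")


def absolute_position(from_pos: int, relative_site: int) -> int:
    """Absolute 1-based protein position of a crosslinked residue."""
    if from_pos < 1 or relative_site < 1:
        raise ValueError("positions are 1-based and must be >= 1")
    return from_pos + relative_site - 1


@dataclass
class CrosslinkRecord:
    """One hetero-dipeptide identification."""

    protein_1: str
    protein_2: str
    score: float
    peptide_1: str
    from_1: int
    to_1: int
    site_1: tuple[str, int]  # (residue letter, 1-based position in peptide)
    peptide_2: str
    from_2: int
    to_2: int
    site_2: tuple[str, int]
    replicate_id: str = ""
    flags: list[str] = field(default_factory=list)
    replicate_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("negative crosslink score")
        for side in (1, 2):
            pep = getattr(self, f"peptide_{side}")
            frm, to = getattr(self, f"from_{side}"), getattr(self, f"to_{side}")
            letter, rel = getattr(self, f"site_{side}")
            if frm > to:
                raise ValueError(f"from_{side} > to_{side}")
            if not 1 <= rel <= len(pep):
                raise ValueError(
                    f"site_{side} relative position {rel} outside peptide of "
                    f"length {len(pep)}")
            if to - frm + 1 != len(pep):
                # stored, not silently fixed: the From coordinate and the
                # relative site still define the absolute position
                flag = f"span_mismatch_{side}"
                if flag not in self.flags:
                    self.flags.append(flag)
            if pep[rel - 1] != letter:
                flag = f"site_letter_mismatch_{side}"
                if flag not in self.flags:
                    self.flags.append(flag)
        if self.replicate_id and not self.replicate_ids:
            self.replicate_ids = {self.replicate_id}

    @property
    def absolute_1(self) -> int:
        return absolute_position(self.from_1, self.site_1[1])

    @property
    def absolute_2(self) -> int:
        return absolute_position(self.from_2, self.site_2[1])

    def link_key(self) -> tuple:
        """Unordered identity of the link: (protein, absolute site) pairs."""
        ends = sorted([(self.protein_1, self.absolute_1),
                       (self.protein_2, self.absolute_2)])
        return tuple(ends)


_COLUMN_ALIASES = {
    "protein1names": "protein_1", "protein1": "protein_1", "protein_1": "protein_1",
    "protein2names": "protein_2", "protein2": "protein_2", "protein_2": "protein_2",
    "xlinkscore": "score", "score": "score",
    "peptide1": "peptide_1", "peptide_1": "peptide_1",
    "peptide2": "peptide_2", "peptide_2": "peptide_2",
    "from": "from_1", "from_1": "from_1", "to": "to_1", "to_1": "to_1",
    "from.1": "from_2", "from_2": "from_2", "to.1": "to_2", "to_2": "to_2",
    "aa1": "site_1", "aa_1": "site_1", "site_1": "site_1",
    "aa2": "site_2", "aa_2": "site_2", "site_2": "site_2",
}


def _canonical_header(names: list[str]) -> dict[int, str]:
    """Map column indices to canonical field names, disambiguating the
    duplicated From/To/aa columns of the printed table layout by order."""
    seen: dict[str, int] = {}
    out: dict[int, str] = {}
    for i, raw in enumerate(names):
        key = re.sub(r"\s+", "", raw).lower()
        n = seen.get(key, 0)
        seen[key] = n + 1
        if n == 1 and key in ("from", "to", "aa1", "aa2"):
            key = key + ".1" if key in ("from", "to") else key
        hit = _COLUMN_ALIASES.get(key)
        if hit is not None:
            # second occurrence of from/to belongs to peptide 2
            if n == 1 and hit in ("from_1", "to_1"):
                hit = hit.replace("_1", "_2")
            out[i] = hit
    return out


def _parse_site(text: str) -> tuple[str, int]:
    m = _SITE_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse crosslink site {text!r}")
    return m.group(1), int(m.group(2))


def parse_crosslink_table(path: str | Path, replicate_id: str = "",
                          delimiter: str = "\t") -> list[CrosslinkRecord]:
    """Parse a delimited crosslink dipeptide table.

    Accepts the printed-table dialect (duplicated From/To columns, bracketed
    peptides, "K5"-style site fields) as well as pre-canonicalised headers.
    Peptide strings may contain the MeroX letters B/U/X in addition to the
    20 amino acids.
    """
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for rec in csv.reader(fh, delimiter=delimiter):
            if rec and any(cell.strip() for cell in rec):
                rows.append(rec)
    if not rows:
        warnings.warn(f"empty crosslink table: {path}")
        return []
    header = _canonical_header(rows[0])
    required = {"protein_1", "protein_2", "score", "peptide_1", "from_1", "to_1",
                "site_1", "peptide_2", "from_2", "to_2", "site_2"}
    missing = required - set(header.values())
    if missing:
        raise ValueError(f"crosslink table missing columns: {sorted(missing)}")
    records: list[CrosslinkRecord] = []
    for row in rows[1:]:
        fields = {name: row[i].strip() for i, name in header.items() if i < len(row)}
        try:
            records.append(CrosslinkRecord(
                protein_1=fields["protein_1"],
                protein_2=fields["protein_2"],
                score=float(fields["score"]),
                peptide_1=fields["peptide_1"].translate(_BRACKETS).upper(),
                from_1=int(fields["from_1"]),
                to_1=int(fields["to_1"]),
                site_1=_parse_site(fields["site_1"]),
                peptide_2=fields["peptide_2"].translate(_BRACKETS).upper(),
                from_2=int(fields["from_2"]),
                to_2=int(fields["to_2"]),
                site_2=_parse_site(fields["site_2"]),
                replicate_id=replicate_id,
            ))
        except ValueError as exc:
            raise ValueError(f"bad crosslink row {row!r}: {exc}") from exc
    return records


def bundled_dipeptide_table() -> Path:
    """Path of the bundled 12-row printed dipeptide table."""
    from importlib import resources

    return Path(str(resources.files("pepmap.data").joinpath("printed_dipeptides.tsv")))


def filter_records(records: list[CrosslinkRecord], min_score: float = 30.0,
                   require_site_specificity: bool = True,
                   ) -> tuple[list[CrosslinkRecord], list[tuple[CrosslinkRecord, str]]]:
    """Score and site-specificity filter.

    Keeps records with score >= min_score whose link residues are DSBU
    targets (K/S/T/Y) or protein N-termini (absolute position 1).  Returns
    (kept, dropped-with-reason).
    """
    kept: list[CrosslinkRecord] = []
    dropped: list[tuple[CrosslinkRecord, str]] = []
    for rec in records:
        if rec.score < min_score:
            dropped.append((rec, f"score {rec.score} < {min_score}"))
            continue
        if require_site_specificity:
            bad = [
                f"site_{side} residue {letter!r} not in KSTY and not N-terminal"
                for side, (letter, _) in ((1, rec.site_1), (2, rec.site_2))
                if letter not in DSBU_SITE_RESIDUES
                and getattr(rec, f"absolute_{side}") != 1
            ]
            if bad:
                dropped.append((rec, "; ".join(bad)))
                continue
        kept.append(rec)
    return kept, dropped


def merge_replicates(record_sets: list[list[CrosslinkRecord]]) -> list[CrosslinkRecord]:
    """Union of replicate runs keyed by the unordered link identity.

    Duplicates collapse to one record keeping the maximum score and the
    union of replicate ids.  Idempotent and commutative.
    """
    if not record_sets:
        raise ValueError("need at least one record set")
    merged: dict[tuple, CrosslinkRecord] = {}
    for records in record_sets:
        for rec in records:
            key = rec.link_key()
            prev = merged.get(key)
            if prev is None:
                best = CrosslinkRecord(**{
                    f: getattr(rec, f) for f in (
                        "protein_1", "protein_2", "score", "peptide_1", "from_1",
                        "to_1", "site_1", "peptide_2", "from_2", "to_2", "site_2",
                        "replicate_id")
                })
                best.flags = list(rec.flags)
                best.replicate_ids = set(rec.replicate_ids)
                merged[key] = best
            else:
                prev.score = max(prev.score, rec.score)
                prev.replicate_ids |= rec.replicate_ids
    return sorted(merged.values(), key=lambda r: r.link_key())


@dataclass
class InteractionGraph:
    """Protein interaction graph with registry-aware clusters."""

    graph: nx.Graph
    clusters: list[list[str]]  # connected components, largest first

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, node: str) -> list[str] | None:
        for comp in self.clusters:
            if node in comp:
                return comp
        return None


def build_graph(records: list[CrosslinkRecord], registry: SubunitRegistry,
                restrict_to_members: bool = False) -> InteractionGraph:
    """Build the undirected interaction graph from crosslink records.

    Protein labels are resolved against the registry; ambiguous paralog
    groups become single nodes.  With ``restrict_to_members`` non-member
    nodes (copurifying proteins such as ribosomal subunits or proteases) are
    dropped before clustering.  Self-links are kept in the graph but never
    create edges between distinct nodes.  Clusters are connected components,
    ordered by size then name.
    """
    g = nx.Graph()
    for rec in records:
        n1 = registry.resolve_group(rec.protein_1)
        n2 = registry.resolve_group(rec.protein_2)
        for node in (n1, n2):
            if node.label not in g:
                g.add_node(node.label, is_member=node.is_member,
                           parts=list(node.parts), ambiguous=node.ambiguous)
        if g.has_edge(n1.label, n2.label):
            data = g.edges[n1.label, n2.label]
            data["records"].append(rec)
            data["max_score"] = max(data["max_score"], rec.score)
        else:
            g.add_edge(n1.label, n2.label, records=[rec], max_score=rec.score)
    if restrict_to_members:
        g.remove_nodes_from([n for n, d in g.nodes(data=True) if not d["is_member"]])
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    return InteractionGraph(g, comps)


@dataclass
class DistanceAssessment:
    """Cα–Cα distances of crosslinks against a structural model."""

    distances: list[float | None]  # Å, None = unmapped
    compatible: list[bool | None]
    max_distance: float = 30.0

    @property
    def n_compatible(self) -> int:
        return sum(1 for c in self.compatible if c is True)

    @property
    def n_incompatible(self) -> int:
        return sum(1 for c in self.compatible if c is False)

    @property
    def n_unmapped(self) -> int:
        return sum(1 for c in self.compatible if c is None)


def assess_distances(records: list[CrosslinkRecord], model: StructureModel,
                     chain_map: dict[str, str],
                     max_distance: float = 30.0) -> DistanceAssessment:
    """Measure Cα–Cα distances of crosslinked residue pairs.

    ``chain_map`` sends protein names (as they appear in the records) to
    chain ids; a chain named in the map but absent from the model is an
    error, while proteins absent from the map or residues absent from their
    chain yield unmapped links.
    """
    model_chains = set(model.chains)
    for protein, chain in chain_map.items():
        if chain not in model_chains:
            raise KeyError(f"chain {chain!r} (protein {protein!r}) absent from model")
    distances: list[float | None] = []
    compatible: list[bool | None] = []
    for rec in records:
        cas = []
        for protein, pos in ((rec.protein_1, rec.absolute_1),
                             (rec.protein_2, rec.absolute_2)):
            chain = chain_map.get(protein)
            res = model.get(chain, pos) if chain is not None else None
            cas.append(res.ca if res is not None else None)
        if cas[0] is None or cas[1] is None:
            distances.append(None)
            compatible.append(None)
        else:
            d = float(np.linalg.norm(cas[0] - cas[1]))
            distances.append(d)
            compatible.append(d <= max_distance)
    return DistanceAssessment(distances, compatible, max_distance)
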