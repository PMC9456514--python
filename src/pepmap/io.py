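"""Readers and writers: alignments (FASTA/Clustal), structures (PDB/mmCIF),
per-residue attribute files for molecular viewers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import AlignIO

__all__ = [
    "MultipleAlignment",
    "Residue",
    "StructureModel",
    "read_alignment",
    "read_structure",
    "write_structure_pdb",
    "write_residue_attributes",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


@dataclass
class MultipleAlignment:
    """An aligned set of sequences with taxon ids and clade labels."""

    taxon_ids: list[str]
    clade_labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")
        alphabet = AA20 | {GAP}
        for tid, seq in zip(self.taxon_ids, self.sequences):
            bad = set(seq.upper()) - alphabet
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in sequence of {tid!r}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    def as_array(self) -> np.ndarray:
        """(n_taxa, n_columns) array of single-character strings."""
        return np.array([list(s.upper()) for s in self.sequences], dtype="U1")

    def taxa_in_clade(self, clade: str) -> list[str]:
        return [t for t, c in zip(self.taxon_ids, self.clade_labels) if c == clade]

    def subset_indices(self, taxa: list[str]) -> list[int]:
        index = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"unknown taxa: {missing}")
        return [index[t] for t in taxa]


def read_alignment(path: str | Path, format: str = "fasta",
                   clade_map: dict[str, str] | None = None) -> MultipleAlignment:
    """Read a FASTA or Clustal alignment and attach clade labels.

    Every taxon must appear in *clade_map*; pass None to label all taxa "all".
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        if "same length" in str(exc):
            raise ValueError("ragged alignment: sequences differ in length") from exc
        raise
    taxon_ids = [rec.id for rec in aln]
    if clade_map is None:
        clades = ["all"] * len(taxon_ids)
    else:
        missing = [t for t in taxon_ids if t not in clade_map]
        if missing:
            raise KeyError(f"taxa missing from clade_map: {missing}")
        clades = [clade_map[t] for t in taxon_ids]
    return MultipleAlignment(taxon_ids, clades, [str(rec.seq) for rec in aln])


@dataclass
class Residue:
    chain_id: str
    number: int  # 1-based author numbering
    name: str  # 3-letter code
    atoms: dict[str, np.ndarray]  # atom name -> xyz (Å)

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")


@dataclass
class StructureModel:
    """Chains/residues/atoms plus free-form per-residue annotations."""

    residues: list[Residue]
    annotations: dict[tuple[str, int], dict[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(r.chain_id, r.number) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue number) pairs")
        self._index = {k: r for k, r in zip(keys, self.residues)}

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def get(self, chain_id: str, number: int) -> Residue | None:
        return self._index.get((chain_id, number))

    def annotate(self, chain_id: str, number: int, **attrs: object) -> None:
        if (chain_id, number) not in self._index:
            raise KeyError(f"residue {chain_id}/{number} not in model")
        self.annotations.setdefault((chain_id, number), {}).update(attrs)


def read_structure(path: str | Path, format: str = "pdb",
                   include_het: bool = False) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    Waters and (by default) heteroatoms are excluded: distance checks are
    Cα-based and only need polymer residues.
    """
    path = str(path)
    if format == "pdb":
        st = gemmi.read_pdb(path)
    elif format == "mmcif":
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
    else:
        raise ValueError(f"unsupported structure format: {format!r}")
    st.setup_entities()
    residues: list[Residue] = []
    model = st[0] if len(st) else None
    if model is not None:
        for chain in model:
            for res in chain:
                if res.is_water():
                    continue
                if not include_het and res.het_flag == "H":
                    continue
                atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
                residues.append(Residue(chain.name, res.seqid.num, res.name, atoms))
    if not residues:
        raise ValueError("empty model: no polymer residues found")
    return StructureModel(residues)


def write_structure_pdb(model: StructureModel, path: str | Path,
                        bfactor_attr: str | None = None) -> None:
    """Write the model as PDB; optionally place a numeric annotation in the
    B-factor column (the conventional channel for per-residue colouring)."""
    st = gemmi.Structure()
    st.name = "pepmap"
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in model.residues:
        ch = chains.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = ch
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.number, " ")
        bval = 0.0
        if bfactor_attr is not None:
            val = model.annotations.get((res.chain_id, res.number), {}).get(bfactor_attr)
            if val is not None:
                bval = float(val)  # type: ignore[arg-type]
        for name, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.element = gemmi.Element(name[0])
            atom.occ = 1.0
            atom.b_iso = bval
            gres.add_atom(atom)
        ch.add_residue(gres)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.write_pdb(str(path))


def write_residue_attributes(model: StructureModel, attribute_name: str,
                             path: str | Path) -> None:
    """Write a per-residue attribute as plain text (chain, residue, value).

    Categorical values are encoded as integers, with the code documented in
    the header.  Numeric attributes additionally produce a PDB copy carrying
    the attribute in the B-factor field (``<path>.pdb``).
    """
    rows: list[tuple[str, int, object]] = []
    for (chain, num), attrs in sorted(model.annotations.items()):
        if attribute_name in attrs:
            if model.get(chain, num) is None:
                raise KeyError(f"annotation references missing residue {chain}/{num}")
            rows.append((chain, num, attrs[attribute_name]))
    values = [v for _, _, v in rows]
    numeric = all(isinstance(v, (int, float, np.integer, np.floating)) for v in values)
    encoding: dict[object, int] = {}
    if not numeric:
        for v in values:
            encoding.setdefault(v, len(encoding))
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# attribute: {attribute_name}\n")
        if encoding:
            legend = ", ".join(f"{v}={i}" for v, i in encoding.items())
            fh.write(f"# categorical encoding: {legend}\n")
        fh.write("# chain\tresidue\tvalue\n")
        for chain, num, v in rows:
            out = encoding[v] if encoding else v
            fh.write(f"{chain}\t{num}\t{out}\n")
    if numeric and rows:
        write_structure_pdb(model, path.with_suffix(path.suffix + ".pdb"),
                            bfactor_attr=attribute_name)
    elif not rows:
        warnings.warn(f"no residues annotated with {attribute_name!r}")
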