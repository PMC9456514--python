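"""Per-column and rolling-window conservation statistics over alignments.

Identity at a column is the frequency of the modal non-gap residue among the
chosen taxa; homology replaces the residue with its physicochemical
functional group, so homology can only exceed or equal identity.  Gaps stay
in the denominator and never count as the mode — a column that is all gaps
scores 0.  Rolling profiles are centred moving means with shrinking windows
at the ends, so a profile always has one value per alignment column and can
be mapped onto a reference structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .divergence import FUNCTIONAL_GROUPS, group_of
from .io import GAP, MultipleAlignment

__all__ = [
    "ConservationProfile",
    "ColumnToReferenceMap",
    "column_identity",
    "column_homology",
    "rolling_profile",
    "clade_profiles",
    "map_columns_to_reference",
]


@dataclass
class ConservationProfile:
    """Conservation percentages for one taxa subset along an alignment."""

    subset_label: str
    column_identity: np.ndarray  # per-column, [0, 100]
    column_homology: np.ndarray
    window_size: int
    rolling_identity: np.ndarray
    rolling_homology: np.ndarray

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 1")
        n = len(self.column_identity)
        for arr in (self.column_homology, self.rolling_identity, self.rolling_homology):
            if len(arr) != n:
                raise ValueError("profile arrays must share one length")


@dataclass
class ColumnToReferenceMap:
    """Partial, strictly increasing map alignment column -> reference residue.

    Columns where the reference sequence has a gap are absent.  Both sides
    are 1-based.
    """

    reference_taxon: str
    mapping: dict[int, int]

    def inverse(self) -> dict[int, int]:
        return {v: k for k, v in self.mapping.items()}


def _subset_matrix(msa: MultipleAlignment, subset: list[str]) -> np.ndarray:
    if not subset:
        raise ValueError("empty subset")
    idx = msa.subset_indices(subset)
    return msa.as_array()[idx, :]


def _modal_percentage(column: np.ndarray, mapper=None) -> float:
    """Percentage of the subset carrying the modal non-gap symbol (or group)."""
    symbols = column if mapper is None else np.array([
        sym if sym == GAP else mapper(sym) for sym in column
    ])
    nongap = symbols[symbols != GAP]
    if nongap.size == 0:
        return 0.0
    _, counts = np.unique(nongap, return_counts=True)
    return 100.0 * float(counts.max()) / symbols.size


def column_identity(msa: MultipleAlignment, column: int, subset: list[str]) -> float:
    """Identity percentage at a 1-based column over a taxa subset."""
    if not 1 <= column <= msa.n_columns:
        raise IndexError(f"column {column} out of range 1..{msa.n_columns}")
    mat = _subset_matrix(msa, subset)
    return _modal_percentage(mat[:, column - 1])


def column_homology(msa: MultipleAlignment, column: int, subset: list[str],
                    group_table: dict[str, frozenset[str]] = FUNCTIONAL_GROUPS) -> float:
    """Homology percentage: like identity, on functional groups."""
    if not 1 <= column <= msa.n_columns:
        raise IndexError(f"column {column} out of range 1..{msa.n_columns}")
    mat = _subset_matrix(msa, subset)
    return _modal_percentage(mat[:, column - 1],
                             mapper=lambda aa: group_of(aa, group_table))


def rolling_profile(values: np.ndarray, window_size: int = 11) -> np.ndarray:
    """Centred moving mean with shrinking windows at the ends.

    Output has the same length as the input; the window is truncated rather
    than padded, so end values average over fewer columns.
    """
    values = np.asarray(values, dtype=float)
    if window_size % 2 == 0:
        raise ValueError("window_size must be odd")
    if window_size > len(values):
        raise ValueError("window larger than profile")
    half = window_size // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def _profile_for(msa: MultipleAlignment, label: str, taxa: list[str],
                 window_size: int) -> ConservationProfile:
    ident = np.array([column_identity(msa, c, taxa) for c in range(1, msa.n_columns + 1)])
    homol = np.array([column_homology(msa, c, taxa) for c in range(1, msa.n_columns + 1)])
    return ConservationProfile(
        subset_label=label,
        column_identity=ident,
        column_homology=homol,
        window_size=window_size,
        rolling_identity=rolling_profile(ident, window_size),
        rolling_homology=rolling_profile(homol, window_size),
    )


def clade_profiles(msa: MultipleAlignment, clade_labels: list[str],
                   window_size: int = 11) -> list[ConservationProfile]:
    """One profile for all taxa plus one per requested clade, in that order."""
    profiles = [_profile_for(msa, "all", list(msa.taxon_ids), window_size)]
    for clade in clade_labels:
        taxa = msa.taxa_in_clade(clade)
        if not taxa:
            raise KeyError(f"unknown clade label: {clade!r}")
        if len(taxa) < 2:
            raise ValueError(f"clade {clade!r} has fewer than 2 members")
        profiles.append(_profile_for(msa, clade, taxa, window_size))
    return profiles


def map_columns_to_reference(msa: MultipleAlignment,
                             reference_taxon: str) -> ColumnToReferenceMap:
    """Map alignment columns to 1-based residue numbers of a reference taxon."""
    idx = msa.subset_indices([reference_taxon])[0]
    seq = msa.sequences[idx].upper()
    mapping: dict[int, int] = {}
    residue = 0
    for col, aa in enumerate(seq, start=1):
        if aa != GAP:
            residue += 1
            mapping[col] = residue
    return ColumnToReferenceMap(reference_taxon, mapping)
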