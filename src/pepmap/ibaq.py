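"""iBAQ label-free quantification and stoichiometry estimation.

iBAQ (intensity-based absolute quantification) divides a protein's summed
MS1 peptide intensity by its number of theoretically observable tryptic
peptides, giving a per-copy abundance proxy.  Per sample, iBAQ values are
normalised to the sample total; normalised values are then summed across
replicates into the final iBAQ.  iBAQr expresses final iBAQ relative to the
RNA polymerase α subunit, whose 2:1 ratio over β reflects the α₂ββ′β″ core
stoichiometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DigestConfig",
    "tryptic_digest",
    "theoretical_peptide_count",
    "sequence_coverage",
    "IbaqResult",
    "compute_ibaq",
    "estimate_stoichiometry",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DigestConfig:
    """Trypsin/P digestion parameters.

    Trypsin/P cleaves C-terminal to every K or R, including before proline.
    ``missed_cleavages`` applies to identification-context digests; the iBAQ
    denominator counts fully cleaved peptides within the observable length
    range (default 6–30 residues).
    """

    missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 30

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("invalid observable length range")


def tryptic_digest(sequence: str, missed_cleavages: int = 0,
                   ) -> list[tuple[str, int, int]]:
    """Trypsin/P digest: peptides with 1-based inclusive spans.

    Returns peptides containing 0..missed_cleavages internal cleavage sites,
    ordered by start position then length.
    """
    seq = sequence.upper()
    bad = set(seq) - AA20
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    # cut points after each K/R; cleavage before P is allowed under Trypsin/P
    cuts = [0] + [i + 1 for i, aa in enumerate(seq) if aa in "KR"]
    if not seq:
        return []
    if cuts[-1] != len(seq):
        cuts.append(len(seq))
    peptides: list[tuple[str, int, int]] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(cuts))):
            start, end = cuts[i], cuts[j]
            peptides.append((seq[start:end], start + 1, end))
    peptides.sort(key=lambda p: (p[1], p[2]))
    return peptides


def theoretical_peptide_count(sequence: str, config: DigestConfig = DigestConfig(),
                              ) -> int:
    """Number of fully cleaved tryptic peptides in the observable length range."""
    return sum(
        1 for pep, _, _ in tryptic_digest(sequence, missed_cleavages=0)
        if config.min_length <= len(pep) <= config.max_length
    )


def sequence_coverage(spans: list[tuple[int, int]], protein_length: int) -> float:
    """Percentage of residues covered by the union of 1-based inclusive spans."""
    covered = np.zeros(protein_length, dtype=bool)
    for start, end in spans:
        if start < 1 or end > protein_length or start > end:
            raise ValueError(f"span ({start}, {end}) outside protein of "
                             f"length {protein_length}")
        covered[start - 1:end] = True
    return 100.0 * covered.sum() / protein_length


@dataclass
class IbaqResult:
    """Per-protein iBAQ quantities across replicates."""

    table: pd.DataFrame  # index: protein_id
    replicates: list[str]
    alpha_id: str | None
    excluded: list[str] = field(default_factory=list)  # no observable peptides

    @property
    def final_ibaq(self) -> pd.Series:
        return self.table["final_ibaq"]

    @property
    def ibaqr(self) -> pd.Series:
        return self.table["ibaqr"]


def compute_ibaq(intensities: pd.DataFrame, sequences: dict[str, str],
                 config: DigestConfig = DigestConfig(),
                 alpha_id: str | None = "alpha",
                 combine: str = "sum",
                 peptide_spans: dict[str, list[tuple[int, int]]] | None = None,
                 ) -> IbaqResult:
    """Compute normalised iBAQ, final iBAQ and iBAQr from an intensity table.

    ``intensities`` needs columns (protein_id, replicate_id, intensity).
    Raw iBAQ = intensity / theoretical peptide count; within each replicate
    values are normalised to fractions of the replicate total; the final
    iBAQ combines replicates by sum (default) or mean.  Proteins absent from
    a replicate contribute 0 there; proteins with no observable peptide are
    excluded with a warning.
    """
    required = {"protein_id", "replicate_id", "intensity"}
    if not required <= set(intensities.columns):
        raise ValueError(f"intensity table needs columns {sorted(required)}")
    if (intensities["intensity"] < 0).any():
        raise ValueError("negative intensities")
    if combine not in ("sum", "mean"):
        raise ValueError("combine must be 'sum' or 'mean'")
    counts: dict[str, int] = {}
    excluded: list[str] = []
    for pid in intensities["protein_id"].unique():
        if pid not in sequences:
            raise KeyError(f"no sequence for protein {pid!r}")
        n = theoretical_peptide_count(sequences[pid], config)
        if n == 0:
            excluded.append(pid)
            warnings.warn(f"protein {pid!r} has no observable tryptic peptide; excluded")
        else:
            counts[pid] = n
    data = intensities[intensities["protein_id"].isin(counts)]
    wide = (data.pivot_table(index="protein_id", columns="replicate_id",
                             values="intensity", aggfunc="sum", fill_value=0.0)
            .astype(float))
    replicates = list(wide.columns)
    raw = wide.div(pd.Series(counts).reindex(wide.index), axis=0)
    totals = raw.sum(axis=0)
    if (totals == 0).any():
        warnings.warn("replicate with zero total iBAQ; normalised values set to 0")
    norm = raw.div(totals.replace(0, np.nan), axis=1).fillna(0.0)
    final = norm.sum(axis=1) if combine == "sum" else norm.mean(axis=1)
    table = pd.DataFrame({"theoretical_peptides": pd.Series(counts).reindex(wide.index)})
    for rep in replicates:
        table[f"raw_ibaq_{rep}"] = raw[rep]
        table[f"norm_ibaq_{rep}"] = norm[rep]
    table["final_ibaq"] = final
    if alpha_id is not None and alpha_id in final.index and final[alpha_id] > 0:
        table["ibaqr"] = final / final[alpha_id]
    else:
        if alpha_id is not None:
            warnings.warn(f"reference subunit {alpha_id!r} missing; iBAQr unavailable")
        table["ibaqr"] = np.nan
        alpha_id = None
    if peptide_spans is not None:
        cov = {
            pid: sequence_coverage(peptide_spans.get(pid, []), len(sequences[pid]))
            for pid in table.index
        }
        table["coverage"] = pd.Series(cov)
    table.sort_values("final_ibaq", ascending=False, inplace=True)
    return IbaqResult(table, replicates, alpha_id, excluded)


@dataclass
class StoichiometryEstimate:
    numerator: str
    denominator: str
    ratio: float
    ci_low: float | None
    ci_high: float | None


def estimate_stoichiometry(result: IbaqResult, pairs: list[tuple[str, str]],
                           n_boot: int = 1000, seed: int = 0,
                           ) -> list[StoichiometryEstimate]:
    """Final-iBAQ ratios for subunit pairs, with a bootstrap interval over
    replicates when at least two replicates are present."""
    rng = np.random.default_rng(seed)
    norm_cols = [f"norm_ibaq_{rep}" for rep in result.replicates]
    out: list[StoichiometryEstimate] = []
    for num, den in pairs:
        for pid in (num, den):
            if pid not in result.table.index:
                raise KeyError(f"protein {pid!r} not quantified")
        den_final = result.table.at[den, "final_ibaq"]
        if den_final == 0:
            raise ZeroDivisionError(f"zero final iBAQ for {den!r}")
        ratio = result.table.at[num, "final_ibaq"] / den_final
        ci_low = ci_high = None
        if len(result.replicates) >= 2:
            num_vals = result.table.loc[num, norm_cols].to_numpy(float)
            den_vals = result.table.loc[den, norm_cols].to_numpy(float)
            boots = []
            for _ in range(n_boot):
                pick = rng.integers(0, len(norm_cols), len(norm_cols))
                d = den_vals[pick].sum()
                if d > 0:
                    boots.append(num_vals[pick].sum() / d)
            if boots:
                ci_low, ci_high = np.percentile(boots, [2.5, 97.5]).tolist()
        out.append(StoichiometryEstimate(num, den, float(ratio), ci_low, ci_high))
    return out
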