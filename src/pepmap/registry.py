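"""Curated membership registry of the plastid-encoded RNA polymerase (PEP) complex.

The PEP-A complex comprises the four plastid-encoded core subunits
(α, β, β′, β″, genes rpoA/rpoB/rpoC1/rpoC2) and twelve nuclear-encoded
PEP-associated proteins (PAP1–PAP12), plus candidate additional subunits
detected in purified fractions (FLN2, pTAC18).  Many subunits circulate under
several names (pTAC numbers, functional names such as HEMERA or MurE); the
registry maps every alias back to one canonical member so that downstream
filters (crosslink networks, quantification tables) agree on identities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

__all__ = ["Member", "GroupNode", "SubunitRegistry", "load_registry"]

_WS = re.compile(r"\s+")


def _norm(name: str) -> str:
    """Normalise an alias: strip whitespace, case, and prime variants."""
    s = _WS.sub("", name).lower()
    # unicode primes and apostrophes are interchangeable in subunit names
    return s.replace("′", "'").replace("″", "''")


@dataclass(frozen=True)
class Member:
    """One canonical PEP subunit with its role and known aliases."""

    canonical: str
    role: str  # "core" | "pap" | "candidate"
    aliases: tuple[str, ...] = ()

    @property
    def is_member(self) -> bool:
        return self.role in ("core", "pap", "candidate")


@dataclass(frozen=True)
class GroupNode:
    """A (possibly ambiguous) protein label resolved to a set of identities.

    Shared peptides cannot distinguish close paralogs (e.g. FLN1 vs FLN2, or
    RPS2A vs RPS2B), so an ambiguous label becomes a single node carrying all
    candidate identities rather than several duplicated nodes.
    """

    label: str
    parts: tuple[str, ...]  # canonical names, or raw tokens when unresolvable
    is_member: bool
    ambiguous: bool


class SubunitRegistry:
    """Alias-resolving registry of PEP complex members."""

    def __init__(self, members: list[Member]):
        names = [m.canonical for m in members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate canonical names in registry")
        self.members = list(members)
        self._by_canonical = {m.canonical: m for m in members}
        self._alias_map: dict[str, str] = {}
        for m in members:
            for alias in (m.canonical, *m.aliases):
                key = _norm(alias)
                prev = self._alias_map.get(key)
                if prev is not None and prev != m.canonical:
                    raise ValueError(f"alias {alias!r} maps to both {prev} and {m.canonical}")
                self._alias_map[key] = m.canonical

    def __len__(self) -> int:
        return len(self.members)

    def count(self, role: str) -> int:
        return sum(1 for m in self.members if m.role == role)

    def member(self, canonical: str) -> Member:
        return self._by_canonical[canonical]

    def resolve(self, name: str) -> Member | None:
        """Resolve one alias to its member, or None.

        Handles species prefixes ("SaRpoA") and synonym compounds where every
        part names the same member ("PAP1/pTac3", "PAP5/PTAC12").
        """
        key = _norm(name)
        hit = self._alias_map.get(key)
        if hit is None and key.startswith("sa"):
            hit = self._alias_map.get(key[2:])
        if hit is not None:
            return self._by_canonical[hit]
        if "/" in name:
            parts = {p for p in (self.resolve(tok) for tok in name.split("/")) if p}
            if len(parts) == 1:
                return next(iter(parts))
        return None

    def resolve_group(self, label: str) -> GroupNode:
        """Resolve a protein label, keeping paralog ambiguity as a group.

        Semicolons separate alternative identities that share the observed
        peptide ("PAP6/FLN1; FLN2" → {PAP6, FLN2}); slashes separate synonyms
        of a single identity. Unresolvable tokens are kept verbatim.
        """
        tokens = [t.strip() for t in label.split(";") if t.strip()]
        parts: list[str] = []
        all_member = bool(tokens)
        for tok in tokens:
            m = self.resolve(tok)
            if m is not None:
                if m.canonical not in parts:
                    parts.append(m.canonical)
            else:
                # a compound like "PAP6/FLN1" whose halves are distinct members
                subs = [self.resolve(p) for p in tok.split("/")] if "/" in tok else []
                if subs and all(s is not None for s in subs):
                    for s in subs:
                        if s.canonical not in parts:  # type: ignore[union-attr]
                            parts.append(s.canonical)  # type: ignore[union-attr]
                else:
                    parts.append(tok)
                    all_member = False
        node_label = "/".join(parts)
        return GroupNode(
            label=node_label,
            parts=tuple(parts),
            is_member=all_member,
            ambiguous=len(parts) > 1,
        )


def load_registry() -> SubunitRegistry:
    """Load the bundled PEP subunit registry (4 core + 12 PAP + candidates)."""
    members: list[Member] = []
    text = resources.files("pepmap.data").joinpath("subunits.tsv").read_text("utf-8")
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        canonical, role = fields[0], fields[1]
        aliases = tuple(a for a in fields[2].split(";") if a) if len(fields) > 2 else ()
        members.append(Member(canonical, role, aliases))
    reg = SubunitRegistry(members)
    if reg.count("core") != 4 or reg.count("pap") != 12:
        raise ValueError("registry must contain exactly 4 core subunits and 12 PAPs")
    return reg
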