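"""Canonical amino-acid alphabets, functional groupings and code-entry order.

Everything downstream counts only the 20 canonical residues; ambiguity
letters occurring in transmembrane spans contribute to helix length but
never to per-residue counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Set

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-canonical letters tolerated in sequences (B, Z, J
#: ambiguity codes; U selenocysteine; O pyrrolysine; X unknown).
AMBIGUITY_LETTERS: FrozenSet[str] = frozenset("BJOUXZ")

VALID_SEQUENCE_LETTERS: FrozenSet[str] = frozenset(AMINO_ACIDS) | AMBIGUITY_LETTERS

THREE_LETTER: Mapping[str, str] = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}
ONE_LETTER: Mapping[str, str] = {v: k for k, v in THREE_LETTER.items()}

#: Proposed chronological order of entry of amino acids into the genetic
#: code, used to mask residues that were not yet available when
#: extrapolating ancestral transmembrane compositions.
CODE_ENTRY_ORDER: tuple[str, ...] = (
    "G", "A", "D", "V", "P", "S", "E", "T", "L", "R",
    "N", "I", "Q", "H", "K", "C", "F", "Y", "M", "W",
)


class SchemeError(ValueError):
    """Raised when a grouping scheme references unknown amino acids."""


@dataclass(frozen=True)
class GroupScheme:
    """A named partition (or sub-selection) of the 20 amino acids.

    The default scheme is the five-way functional partition used for
    membrane-protein composition trends: hydrophobic, polar, packing,
    anchoring and charged residues.
    """

    groups: Mapping[str, FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            unknown = set(members) - set(AMINO_ACIDS)
            if unknown:
                raise SchemeError(
                    f"group {name!r} contains unknown amino acids: {sorted(unknown)}"
                )

    @property
    def is_partition(self) -> bool:
        """True when the groups are disjoint and jointly cover all 20 AA."""
        seen: Set[str] = set()
        for members in self.groups.values():
            if seen & set(members):
                return False
            seen |= set(members)
        return seen == set(AMINO_ACIDS)


def default_scheme() -> GroupScheme:
    """Five functional residue classes of transmembrane helices.

    Hydrophobic residues fill the bilayer core; polar residues mediate
    inter-helix hydrogen bonding; small packing residues (Ala/Gly/Pro)
    enable tight helix-helix contacts and kinks; Trp/Tyr/Arg anchor
    helices in the lipid headgroup region; Asp/Glu/Lys are charged.
    """
    return GroupScheme(
        groups={
            "hydrophobic": frozenset("LMIVF"),
            "polar": frozenset("CHNQST"),
            "packing": frozenset("AGP"),
            "anchoring": frozenset("WYR"),
            "charged": frozenset("DEK"),
        }
    )


def group_scheme_from_mapping(mapping: Mapping[str, Set[str]]) -> GroupScheme:
    return GroupScheme(groups={k: frozenset(v) for k, v in mapping.items()})


def as_one_letter(aa: str) -> str:
    """Accept either one- or three-letter codes and return the one-letter code."""
    if len(aa) == 1:
        if aa.upper() not in AMINO_ACIDS:
            raise SchemeError(f"unknown amino acid {aa!r}")
        return aa.upper()
    key = aa.capitalize()
    if key not in ONE_LETTER:
        raise SchemeError(f"unknown amino acid {aa!r}")
    return ONE_LETTER[key]


DEFAULT_GROUP_ORDER: tuple[str, ...] = (
    "hydrophobic", "polar", "packing", "anchoring", "charged",
)
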