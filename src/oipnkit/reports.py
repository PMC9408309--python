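"""Spontaneous adverse-event reports and drug-name normalization.

A spontaneous report (FAERS-style) lists the drugs a patient received, each
with a reporting role, plus the coded reaction preferred terms (PTs).  All
cohorts in this package are anchored on oxaliplatin: every report carries the
anchor drug in some role.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Role",
    "ANCHOR_DRUG",
    "OIPN_TERMS",
    "PPI_CORE",
    "PPI_EXTRA",
    "SpontaneousReport",
    "normalize_drug_name",
    "fold_term",
]

#: Anchor drug present in every cohort report.
ANCHOR_DRUG = "OXALIPLATIN"

#: The three preferred terms defining the peripheral-neuropathy case.
OIPN_TERMS = (
    "Peripheral neuropathy",
    "Peripheral sensory neuropathy",
    "Peripheral sensorimotor neuropathy",
)

#: Proton pump inhibitors analysed individually in the source cohort.
PPI_CORE = ("OMEPRAZOLE", "PANTOPRAZOLE", "RABEPRAZOLE")

#: Additional marketed PPIs included in the default "any PPI" class.
PPI_EXTRA = ("LANSOPRAZOLE", "ESOMEPRAZOLE", "DEXLANSOPRAZOLE")


class Role(str, enum.Enum):
    """Reporting role of a drug on a spontaneous report."""

    SUSPECT = "SUSPECT"
    CONCOMITANT = "CONCOMITANT"


def normalize_drug_name(raw: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Normalize a drug name: trim, collapse whitespace, uppercase, map synonyms.

    ``synonym_map`` (brand -> generic) is applied after normalization; both its
    keys and values are normalized before lookup, and chains are resolved so the
    function is idempotent even for maps like ``{A: B, B: C}``.

    Raises
    ------
    ValueError
        If ``raw`` is empty or blank.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("drug name is empty or blank")
    name = " ".join(str(raw).split()).upper()
    if synonym_map:
        folded = {
            " ".join(str(k).split()).upper(): " ".join(str(v).split()).upper()
            for k, v in synonym_map.items()
        }
        seen = {name}
        while name in folded:
            name = folded[name]
            if name in seen:  # cycle guard
                break
            seen.add(name)
    return name


def fold_term(term: str) -> str:
    """Case-fold and whitespace-trim a reaction preferred term for matching."""
    return " ".join(str(term).split()).casefold()


@dataclass(frozen=True, slots=True)
class SpontaneousReport:
    """One adverse-event case: a set of (drug, role) pairs and a set of PTs."""

    report_id: str
    drugs: frozenset[tuple[str, Role]] = field(default_factory=frozenset)
    reactions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")

    def drug_names(self, roles: Iterable[Role] | None = None) -> frozenset[str]:
        """Names of drugs listed in any of ``roles`` (default: any role)."""
        roleset = frozenset(roles) if roles is not None else frozenset(Role)
        return frozenset(name for name, role in self.drugs if role in roleset)

    def has_drug(self, name: str, roles: Iterable[Role] | None = None) -> bool:
        roleset = frozenset(roles) if roles is not None else frozenset(Role)
        return any((name, role) in self.drugs for role in roleset)
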