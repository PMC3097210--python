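"""Candidate screening by the four GH18 chitinase signature sequences.

Insect chitinases carry four conserved motifs in the catalytic domain. The
most diagnostic, FDGXDLDWEYP, contains the DWEYP consensus whose glutamate
(E) is the catalytic acid; chitinase-like proteins (IDGFs) retain the fold
but carry a substitution at that position, which abrogates activity. A
protein is a candidate family member when it carries at least one of the
four signatures, or a DWEYP-like site with the E replaced.

Pattern language: ``X`` is a wildcard over the 20 standard residues (it
also matches an ``X`` in the sequence); every other pattern position must
match the sequence residue exactly, and a sequence ``X`` never satisfies a
fixed position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import ProteinRecord

__all__ = [
    "SignatureMotif",
    "MotifHit",
    "CandidateCall",
    "SIGNATURE_MOTIFS",
    "PRIMARY_MOTIF_NAME",
    "scan_motifs",
    "classify_candidate",
    "load_motif_file",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_WILDCARD_CLASS = "[" + STANDARD_RESIDUES + "X]"


@dataclass(frozen=True)
class SignatureMotif:
    """A degenerate signature pattern; X positions are wildcards."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = [c for c in self.pattern if c != "X" and c not in STANDARD_RESIDUES]
        if bad:
            raise ValueError(f"motif {self.name}: invalid pattern residues {bad}")

    def regex(self) -> re.Pattern[str]:
        body = "".join(_WILDCARD_CLASS if c == "X" else c for c in self.pattern)
        return re.compile(f"(?=({body}))")

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    position: int  # 1-based start in the protein
    matched_text: str


@dataclass(frozen=True)
class CandidateCall:
    protein_id: str
    is_candidate: bool
    tier: str  # "primary" | "secondary" | "none"
    active_site: str  # "active" | "substituted" | "absent"
    hits: tuple[MotifHit, ...] = ()


PRIMARY_MOTIF_NAME = "FDGXDLDWEYP"

#: The four signature sequences of the insect chitinase catalytic domain.
SIGNATURE_MOTIFS: tuple[SignatureMotif, ...] = (
    SignatureMotif("KXXXXXGGW", "KXXXXXGGW"),
    SignatureMotif("FDGXDLDWEYP", "FDGXDLDWEYP"),
    SignatureMotif("MXYDXXG", "MXYDXXG"),
    SignatureMotif("GXXXWXXDXD", "GXXXWXXDXD"),
)

# DWEYP-like site with the central (catalytic E) position relaxed; used to
# locate substituted, catalytically dead sites.
_RELAXED_SITE = re.compile("(?=(DW([" + STANDARD_RESIDUES + "X])YP))")


def scan_motifs(
    protein: ProteinRecord, motifs: Sequence[SignatureMotif] = SIGNATURE_MOTIFS
) -> list[MotifHit]:
    """All (possibly overlapping) matches of the motifs in the protein,
    sorted by position then motif name."""
    hits: list[MotifHit] = []
    for motif in motifs:
        for m in motif.regex().finditer(protein.sequence):
            hits.append(MotifHit(motif.name, m.start() + 1, m.group(1)))
    hits.sort(key=lambda h: (h.position, h.motif_name))
    return hits


def _active_site_state(sequence: str) -> str:
    """'active' if any DW?YP window has E at the catalytic position,
    'substituted' if such windows exist but none with E, else 'absent'."""
    centers = [m.group(2) for m in _RELAXED_SITE.finditer(sequence)]
    if not centers:
        return "absent"
    return "active" if "E" in centers else "substituted"


def classify_candidate(
    protein: ProteinRecord, motifs: Sequence[SignatureMotif] = SIGNATURE_MOTIFS
) -> CandidateCall:
    """Screen one protein against the signature set.

    Tier "primary" requires the full FDGXDLDWEYP signature (catalytic E in
    place). Proteins matching only the remaining signatures — or only a
    relaxed DW?YP site, as in E-substituted chitinase-like proteins — are
    tier "secondary". Proteins with no signature hit and no DW?YP site are
    not candidates.
    """
    hits = tuple(scan_motifs(protein, motifs))
    active_site = _active_site_state(protein.sequence)
    has_primary = any(h.motif_name == PRIMARY_MOTIF_NAME for h in hits)
    if has_primary:
        tier = "primary"
    elif hits or active_site != "absent":
        tier = "secondary"
    else:
        tier = "none"
    return CandidateCall(
        protein_id=protein.id,
        is_candidate=tier != "none",
        tier=tier,
        active_site=active_site,
        hits=hits,
    )


def load_motif_file(source: Iterable[str]) -> list[SignatureMotif]:
    """Read a plain-text motif file: one ``name<TAB>pattern`` (or just
    ``pattern``) per line; ``#`` comments allowed."""
    motifs = []
    for line in source:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            motifs.append(SignatureMotif(parts[0], parts[0]))
        else:
            motifs.append(SignatureMotif(parts[0], parts[1]))
    return motifs
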