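"""Linear epitope screening of peptide pools.

Peptides are first length-gated per disease: celiac-disease (CD) screening
keeps peptides of >= 9 residues, the minimal length able to occupy the MHC
class II binding groove and stimulate T cells; wheat-allergy (WA) screening
keeps >= 5 residues, the shortest linear epitope in the allergen database.

Intact matching reports every occurrence of a full epitope sequence inside a
peptide.  Partial matching — used to trace proteolytic degradation through
gastroduodenal digestion — reports, for pairs with no intact hit, the longest
contiguous substring shared between peptide and epitope when it reaches a
minimum overlap (default 5 AA).  Matching is case-insensitive and blind to
modifications.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import Disease, EpitopeRecord, IdentifiedPeptide, Stage

__all__ = [
    "LENGTH_GATES",
    "MatchType",
    "EpitopeMatch",
    "length_gate",
    "match_intact",
    "match_partial",
    "hazard_peptides",
    "longest_common_substring",
]

#: Minimal peptide length admitted to screening, per disease.
LENGTH_GATES: dict[Disease, int] = {Disease.CD: 9, Disease.WA: 5}


class MatchType(enum.Enum):
    INTACT = "INTACT"
    PARTIAL = "PARTIAL"


@dataclass(frozen=True)
class EpitopeMatch:
    """An intact or partial hit of one epitope in one peptide."""

    epitope_id: str
    peptide_sequence: str
    sample_id: str
    stage: Stage
    match_type: MatchType
    overlap_length: int
    offset_in_peptide: int  # 0-based start of the shared segment in the peptide
    offset_in_epitope: int = 0  # 0-based start of the shared segment in the epitope


def length_gate(
    peptides: Iterable[IdentifiedPeptide], disease: Disease
) -> list[IdentifiedPeptide]:
    """Retain peptides meeting the disease's minimal screening length."""
    cutoff = LENGTH_GATES[disease]
    return [p for p in peptides if len(p.sequence) >= cutoff]


def match_intact(
    peptides: Iterable[IdentifiedPeptide],
    epitope_table: Sequence[EpitopeRecord],
) -> list[EpitopeMatch]:
    """All full-length occurrences of each epitope within each peptide.

    Every occurrence offset is reported; a peptide equal to the epitope
    counts as containment at offset 0.
    """
    out: list[EpitopeMatch] = []
    for pep in peptides:
        pseq = pep.sequence.upper()
        for epi in epitope_table:
            eseq = epi.sequence.upper()
            start = pseq.find(eseq)
            while start != -1:
                out.append(
                    EpitopeMatch(
                        epitope_id=epi.epitope_id,
                        peptide_sequence=pep.sequence,
                        sample_id=pep.sample_id,
                        stage=pep.stage,
                        match_type=MatchType.INTACT,
                        overlap_length=len(eseq),
                        offset_in_peptide=start,
                        offset_in_epitope=0,
                    )
                )
                start = pseq.find(eseq, start + 1)
    return out


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """Length and offsets of the longest contiguous substring of ``a`` and ``b``.

    Returns ``(length, offset_in_a, offset_in_b)``; ties are broken by the
    smallest offset in ``b``, then the smallest offset in ``a``.  Plain
    dynamic programming — peptides and epitopes are tens of residues, so no
    suffix structures are warranted.
    """
    best_len, best_a, best_b = 0, 0, 0
    la, lb = len(a), len(b)
    # prev[j] = length of common suffix of a[:i] and b[:j]
    prev = [0] * (lb + 1)
    for i in range(1, la + 1):
        curr = [0] * (lb + 1)
        ai = a[i - 1]
        for j in range(1, lb + 1):
            if ai == b[j - 1]:
                curr[j] = prev[j - 1] + 1
                length = curr[j]
                off_a, off_b = i - length, j - length
                if length > best_len or (
                    length == best_len
                    and (off_b, off_a) < (best_b, best_a)
                ):
                    best_len, best_a, best_b = length, off_a, off_b
        prev = curr
    return best_len, best_a, best_b


def match_partial(
    peptides: Iterable[IdentifiedPeptide],
    epitope_table: Sequence[EpitopeRecord],
    min_overlap: int = 5,
) -> list[EpitopeMatch]:
    """Longest shared substrings for pairs lacking an intact match.

    For each (peptide, epitope) pair where the full epitope is absent from
    the peptide, the longest contiguous shared substring is reported as a
    PARTIAL match when its length reaches ``min_overlap``.  Pairs with an
    intact hit are the province of :func:`match_intact` and never appear
    here.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    out: list[EpitopeMatch] = []
    for pep in peptides:
        pseq = pep.sequence.upper()
        for epi in epitope_table:
            eseq = epi.sequence.upper()
            if eseq in pseq:
                continue
            length, off_pep, off_epi = longest_common_substring(pseq, eseq)
            if length >= min_overlap:
                out.append(
                    EpitopeMatch(
                        epitope_id=epi.epitope_id,
                        peptide_sequence=pep.sequence,
                        sample_id=pep.sample_id,
                        stage=pep.stage,
                        match_type=MatchType.PARTIAL,
                        overlap_length=length,
                        offset_in_peptide=off_pep,
                        offset_in_epitope=off_epi,
                    )
                )
    return out


def hazard_peptides(matches: Iterable[EpitopeMatch]) -> set[tuple[str, str]]:
    """Deduplicated ``(sample_id, peptide_sequence)`` pairs with intact hits.

    A peptide containing several epitopes — common in repetitive prolamin
    sequences — counts once.
    """
    return {
        (m.sample_id, m.peptide_sequence)
        for m in matches
        if m.match_type is MatchType.INTACT
    }
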