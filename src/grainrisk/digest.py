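"""In-silico digestion: specific protease cleavage and unspecific enumeration.

Two regimes are modelled.  Specific digestion cuts at a protease's residue
set (chymotrypsin F/L/W/Y; the combined thermolysin+chymotrypsin rule
A/F/I/L/M/V/W/Y) allowing up to a configured number of missed cleavages —
essential for proline/glutamine-rich storage proteins, which are unusually
resistant to proteolysis.  Unspecific enumeration lists every substring in a
length window, emulating how a search engine indexes a gastroduodenal digest
where cleavage is too heterogeneous to model as a single protease.

Coordinates are 1-based and inclusive at both ends.  Cut positions are
expressed as inter-residue offsets: 0 lies before the first residue, ``len``
after the last.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import (
    THERMOLYSIN_CHYMOTRYPSIN,
    CleavageSide,
    DigestParams,
    EnzymeSpec,
    ProteinRecord,
)

__all__ = [
    "PeptideOccurrence",
    "cleavage_sites",
    "digest_specific",
    "digest_dual",
    "enumerate_unspecific",
    "unspecific_count",
    "to_zero_based",
]


@dataclass(frozen=True)
class PeptideOccurrence:
    """A digest product located on its parent protein (1-based, inclusive)."""

    sequence: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates [{self.start}, {self.end}] inconsistent with "
                f"sequence length {len(self.sequence)}"
            )
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)


def to_zero_based(occ: PeptideOccurrence) -> tuple[int, int]:
    """Return half-open 0-based coordinates ``(start, stop)`` for slicing."""
    return occ.start - 1, occ.end


def cleavage_sites(sequence: str, enzyme: EnzymeSpec) -> list[int]:
    """Ordered inter-residue cut offsets for ``enzyme`` on ``sequence``.

    C-terminal enzymes cut after every cleavage residue except the protein's
    final residue; N-terminal enzymes cut before every such residue except
    the first.  A residue named in ``enzyme.blocked_following`` suppresses
    the cut when it immediately follows the site.
    """
    n = len(sequence)
    sites: list[int] = []
    if enzyme.side is CleavageSide.C_TERMINAL:
        for i, res in enumerate(sequence[:-1]):
            if res in enzyme.cleavage_residues:
                if sequence[i + 1] in enzyme.blocked_following:
                    continue
                sites.append(i + 1)
    else:
        for i, res in enumerate(sequence):
            if i == 0:
                continue
            if res in enzyme.cleavage_residues:
                if sequence[i - 1] in enzyme.blocked_following:
                    continue
                sites.append(i)
    return sites


def digest_specific(
    protein: ProteinRecord, enzyme: EnzymeSpec, params: DigestParams = DigestParams()
) -> list[PeptideOccurrence]:
    """All digest peptides of ``protein`` under ``enzyme`` and ``params``.

    Peptides run between two boundaries (cut sites or protein termini) with
    at most ``params.max_missed_cleavages`` skipped internal sites, filtered
    to the configured length window.  Protein termini are boundaries, never
    missed cleavages.  Output is unique by position and sorted by
    ``(start, end)``.
    """
    seq = protein.sequence
    n = len(seq)
    boundaries = [0] + cleavage_sites(seq, enzyme) + [n]
    out: list[PeptideOccurrence] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, len(boundaries)):
            mc = j - i - 1
            if mc > params.max_missed_cleavages:
                break
            length = boundaries[j] - boundaries[i]
            if params.min_len <= length <= params.max_len:
                start = boundaries[i] + 1
                end = boundaries[j]
                out.append(
                    PeptideOccurrence(
                        sequence=seq[boundaries[i] : boundaries[j]],
                        parent_accession=protein.accession,
                        start=start,
                        end=end,
                        missed_cleavages=mc,
                    )
                )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def digest_dual(
    protein: ProteinRecord, params: DigestParams = DigestParams()
) -> list[PeptideOccurrence]:
    """Digest with the combined thermolysin+chymotrypsin specificity."""
    return digest_specific(protein, THERMOLYSIN_CHYMOTRYPSIN, params)


def unspecific_count(n: int, params: DigestParams) -> int:
    """Closed-form number of substrings of an ``n``-mer in the length window."""
    return sum(
        n - length + 1 for length in range(params.min_len, min(params.max_len, n) + 1)
    )


def enumerate_unspecific(
    protein: ProteinRecord, params: DigestParams = DigestParams(max_missed_cleavages=0)
) -> list[PeptideOccurrence]:
    """Every substring of the protein with length in the configured window.

    Emulates unspecific search-space indexing of a gastroduodenal digest;
    missed cleavages are meaningless here and ignored.  A protein shorter
    than ``min_len`` yields an empty list.
    """
    seq = protein.sequence
    n = len(seq)
    out: list[PeptideOccurrence] = []
    for start0 in range(n):
        max_here = min(params.max_len, n - start0)
        for length in range(params.min_len, max_here + 1):
            out.append(
                PeptideOccurrence(
                    sequence=seq[start0 : start0 + length],
                    parent_accession=protein.accession,
                    start=start0 + 1,
                    end=start0 + length,
                    missed_cleavages=0,
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out
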