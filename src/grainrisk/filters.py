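"""Reliability filtering and multiconsensus merging of identification tables.

Search-engine exports are noisy; only peptides backed by enough spectral
evidence are carried into epitope screening.  The default criteria keep a row
when it has at least 3 peptide-spectrum matches, a cross-correlation score of
at least 1, at-least-medium confidence (FDR <= 5% as labelled by the search
engine) and an unambiguous assignment.  Runs of the same sample (e.g. single-
and dual-enzyme digests) are merged into one redundancy-free multiconsensus
list keyed by (sequence, stage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .models import Confidence, DigestLabel, GrainRiskError, IdentifiedPeptide

__all__ = [
    "FilterCriteria",
    "FilterAudit",
    "filter_peptides",
    "merge_multiconsensus",
    "fraction_overlap",
]


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusive thresholds for peptide-level reliability filtering."""

    min_psms: int = 3
    min_score: float = 1.0
    min_confidence: Confidence = Confidence.MEDIUM
    require_unambiguous: bool = True


@dataclass
class FilterAudit:
    """Per-criterion failure tallies for one filtering pass.

    A row failing several criteria increments each corresponding counter, so
    the failure counts need not sum to ``n_removed``.
    """

    n_input: int = 0
    n_retained: int = 0
    failed_psms: int = 0
    failed_score: int = 0
    failed_confidence: int = 0
    failed_ambiguous: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "failed_psms": self.failed_psms,
            "failed_score": self.failed_score,
            "failed_confidence": self.failed_confidence,
            "failed_ambiguous": self.failed_ambiguous,
        }


def filter_peptides(
    rows: Iterable[IdentifiedPeptide], criteria: FilterCriteria = FilterCriteria()
) -> tuple[list[IdentifiedPeptide], FilterAudit]:
    """Apply the reliability criteria; returns (retained rows, audit).

    All thresholds are inclusive; input order is preserved.
    """
    audit = FilterAudit()
    kept: list[IdentifiedPeptide] = []
    for row in rows:
        audit.n_input += 1
        ok = True
        if row.psm_count < criteria.min_psms:
            audit.failed_psms += 1
            ok = False
        if row.score < criteria.min_score:
            audit.failed_score += 1
            ok = False
        if row.confidence < criteria.min_confidence:
            audit.failed_confidence += 1
            ok = False
        if criteria.require_unambiguous and not row.unambiguous:
            audit.failed_ambiguous += 1
            ok = False
        if ok:
            kept.append(row)
            audit.n_retained += 1
    return kept, audit


def merge_multiconsensus(
    runs: Sequence[tuple[DigestLabel, Sequence[IdentifiedPeptide]]],
    strict_modifications: bool = False,
) -> list[IdentifiedPeptide]:
    """Merge per-digest runs of one sample into a redundancy-free list.

    Rows are united by (sequence, stage) — screening is modification-blind,
    so modifications are unioned rather than keyed on, unless
    ``strict_modifications`` adds them to the key.  The merged row carries the
    summed PSM count, the maximum score, the maximum confidence level, the
    union of modifications, and the list of contributing digest labels as
    provenance.  Mixed sample_ids raise an error.
    """
    sample_ids = {row.sample_id for _, rows in runs for row in rows}
    if len(sample_ids) > 1:
        raise GrainRiskError(f"merge across mixed samples: {sorted(sample_ids)}")

    merged: dict[tuple, IdentifiedPeptide] = {}
    order: list[tuple] = []
    for label, rows in runs:
        for row in rows:
            key: tuple = (row.sequence, row.stage)
            if strict_modifications:
                key = key + (row.modifications,)
            if key not in merged:
                merged[key] = IdentifiedPeptide(
                    sequence=row.sequence,
                    sample_id=row.sample_id,
                    stage=row.stage,
                    digest_label=row.digest_label,
                    psm_count=row.psm_count,
                    score=row.score,
                    confidence=row.confidence,
                    unambiguous=row.unambiguous,
                    modifications=row.modifications,
                    provenance=(label,),
                )
                order.append(key)
            else:
                prev = merged[key]
                mods = tuple(dict.fromkeys(prev.modifications + row.modifications))
                prov = prev.provenance
                if label not in prov:
                    prov = prov + (label,)
                merged[key] = IdentifiedPeptide(
                    sequence=prev.sequence,
                    sample_id=prev.sample_id,
                    stage=prev.stage,
                    digest_label=prev.digest_label,
                    psm_count=prev.psm_count + row.psm_count,
                    score=max(prev.score, row.score),
                    confidence=max(prev.confidence, row.confidence),
                    unambiguous=prev.unambiguous or row.unambiguous,
                    modifications=mods,
                    provenance=prov,
                )
    # provenance sorted for run-order invariance of the merged rows
    return [
        replace(
            merged[key],
            provenance=tuple(sorted(merged[key].provenance, key=lambda l: l.value)),
        )
        for key in order
    ]


def fraction_overlap(
    f1: set[str], f2: set[str], f3: set[str]
) -> dict[str, int]:
    """Counts for the 7 Venn regions of the three Osborne-fraction sets.

    Keys: ``F1_only, F2_only, F3_only, F1_F2, F1_F3, F2_F3, F1_F2_F3``;
    the values sum to ``|F1 ∪ F2 ∪ F3|``.
    """
    return {
        "F1_only": len(f1 - f2 - f3),
        "F2_only": len(f2 - f1 - f3),
        "F3_only": len(f3 - f1 - f2),
        "F1_F2": len((f1 & f2) - f3),
        "F1_F3": len((f1 & f3) - f2),
        "F2_F3": len((f2 & f3) - f1),
        "F1_F2_F3": len(f1 & f2 & f3),
    }
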