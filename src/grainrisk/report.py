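"""Summary surfaces: hazard counts, per-class distributions, presence matrices.

Three machine-readable outputs mirror how a comparative risk assessment is
reported: (i) absolute and relative hazard-peptide counts per sample, the
relative value expressed as an integer percentage of the reference sample;
(ii) the distribution of epitope matches across wheat protein classes; and
(iii) a presence/absence matrix of differential epitopes with ``X``/empty
cells, samples as columns and the reference first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .fate import ConservationRow, ConservationStatus
from .models import (
    Disease,
    EpitopeRecord,
    GrainRiskError,
    ProteinClass,
    attribute_protein_class,
)
from .screen import EpitopeMatch

__all__ = [
    "RiskSummary",
    "round_half_away_from_zero",
    "summarize_risk",
    "class_distribution",
    "epitope_class_map",
    "presence_matrix",
]


@dataclass(frozen=True)
class RiskSummary:
    """Per-sample hazard counts with the percentage relative to the reference."""

    sample_id: str
    disease: Disease
    n_screened: int  # peptides surviving the disease length gate
    n_hazard: int  # peptides containing >= 1 intact epitope
    rel_pct: int  # integer percent of the reference hazard count

    def __post_init__(self) -> None:
        if not (0 <= self.n_hazard <= self.n_screened):
            raise ValueError("require 0 <= n_hazard <= n_screened")


def round_half_away_from_zero(x: float) -> int:
    """Round to the nearest integer with halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def summarize_risk(
    hazard_counts: Mapping[str, int],
    screened_counts: Mapping[str, int],
    reference_id: str,
    disease: Disease,
    sample_order: Sequence[str] | None = None,
) -> list[RiskSummary]:
    """Absolute and relative hazard summaries, reference first.

    ``rel_pct`` is ``100 * n_hazard(sample) / n_hazard(reference)`` rounded
    half away from zero; the reference reports 100 by construction.  A zero
    reference hazard count leaves the ratio undefined and raises.
    """
    if reference_id not in hazard_counts:
        raise GrainRiskError(f"reference {reference_id!r} missing from hazard counts")
    ref = hazard_counts[reference_id]
    if ref <= 0:
        raise GrainRiskError("reference hazard count is 0; relative % undefined")
    if sample_order is None:
        sample_order = [reference_id] + [
            s for s in hazard_counts if s != reference_id
        ]
    out = []
    for sample in sample_order:
        n_haz = hazard_counts[sample]
        out.append(
            RiskSummary(
                sample_id=sample,
                disease=disease,
                n_screened=screened_counts[sample],
                n_hazard=n_haz,
                rel_pct=round_half_away_from_zero(100.0 * n_haz / ref),
            )
        )
    return out


def epitope_class_map(
    epitopes: Iterable[EpitopeRecord],
) -> dict[str, ProteinClass]:
    """Protein class per epitope ID from its recorded source-protein label.

    Dual-source labels (e.g. "γ-gliadin or LMW glutenin") resolve to the
    first listed family, which the keyword priority of
    :func:`grainrisk.models.attribute_protein_class` already implements;
    the ambiguity stays visible in the record's label.
    """
    return {
        e.epitope_id: attribute_protein_class(e.source_protein_label)
        for e in epitopes
    }


def class_distribution(
    matches: Iterable[EpitopeMatch],
    class_of_epitope: Mapping[str, ProteinClass] | Callable[[str], ProteinClass],
) -> pd.DataFrame:
    """Counts and percentages of matches per wheat protein class.

    Returns a DataFrame indexed by class name with ``count`` and ``pct``
    columns; percentages sum to 100 up to rounding.  An empty match set
    yields an empty frame (no division by zero).
    """
    lookup = (
        class_of_epitope.__getitem__
        if isinstance(class_of_epitope, Mapping)
        else class_of_epitope
    )
    counts: dict[ProteinClass, int] = {}
    total = 0
    for m in matches:
        cls = lookup(m.epitope_id)
        counts[cls] = counts.get(cls, 0) + 1
        total += 1
    if total == 0:
        return pd.DataFrame(columns=["count", "pct"])
    rows = {
        cls.name: {"count": n, "pct": 100.0 * n / total}
        for cls, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].name))
    }
    return pd.DataFrame.from_dict(rows, orient="index")[["count", "pct"]]


def _id_sort_key(eid: str):
    return (0, int(eid)) if eid.isdigit() else (1, eid)


def presence_matrix(
    rows: Iterable[ConservationRow],
    samples: Sequence[str],
    epitopes: Mapping[str, EpitopeRecord],
) -> pd.DataFrame:
    """Differential-epitope presence table with ``X``/empty cells.

    One row per DIFFERENTIAL epitope among ``rows`` (conserved epitopes are
    excluded — they do not discriminate samples), annotated with sequence,
    restriction/allergen and source label, ordered by (source label, ID).
    Sample columns follow ``samples`` (reference first).
    """
    kept = [r for r in rows if r.status is ConservationStatus.DIFFERENTIAL]
    kept.sort(
        key=lambda r: (
            epitopes[r.epitope_id].source_protein_label,
            _id_sort_key(r.epitope_id),
        )
    )
    data = []
    for r in kept:
        epi = epitopes[r.epitope_id]
        row: dict[str, str] = {
            "epitope_id": r.epitope_id,
            "sequence": epi.sequence,
            "restriction_or_allergen": epi.restriction_or_allergen,
            "source_protein_label": epi.source_protein_label,
        }
        for sample, present in zip(samples, r.presence):
            row[sample] = "X" if present else ""
        data.append(row)
    columns = [
        "epitope_id",
        "sequence",
        "restriction_or_allergen",
        "source_protein_label",
        *samples,
    ]
    return pd.DataFrame(data, columns=columns)
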