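"""Digestion-fate classification and conserved/differential epitope calls.

For each epitope and sample, the Osborne-fraction peptide pool establishes
whether the epitope is expressed at all, and the gastroduodenal (GD) pool
establishes what survived simulated digestion:

* ``NOT_EXPRESSED`` — never found intact in any Osborne fraction;
* ``GD_RESISTANT`` — expressed, and found intact in the GD pool;
* ``PARTIALLY_DEGRADED`` — expressed, only a partial GD match remains;
* ``FULLY_DEGRADED`` — expressed, no trace in the GD pool.

An epitope intact in GD but absent from every fraction is classified
``NOT_EXPRESSED`` and flagged as an audit anomaly (possible under differing
per-route sensitivity) rather than silently promoted.

Across samples, an epitope present (intact in the GD pool by default) in all
samples is CONSERVED; present in some but not all, DIFFERENTIAL.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import EpitopeRecord, GrainRiskError
from .screen import EpitopeMatch, MatchType

__all__ = [
    "Fate",
    "FateStatus",
    "ConservationStatus",
    "ConservationRow",
    "classify_fate",
    "classify_fates",
    "conservation",
    "presence_from_matches",
]


class Fate(enum.Enum):
    NOT_EXPRESSED = "NOT_EXPRESSED"
    GD_RESISTANT = "GD_RESISTANT"
    PARTIALLY_DEGRADED = "PARTIALLY_DEGRADED"
    FULLY_DEGRADED = "FULLY_DEGRADED"


@dataclass(frozen=True)
class FateStatus:
    epitope_id: str
    sample_id: str
    status: Fate
    #: True when a GD match exists for an epitope never seen in the fractions.
    anomaly: bool = False


class ConservationStatus(enum.Enum):
    CONSERVED = "CONSERVED"
    DIFFERENTIAL = "DIFFERENTIAL"


@dataclass(frozen=True)
class ConservationRow:
    epitope_id: str
    presence: tuple[bool, ...]  # ordered as the sample list, reference first
    status: ConservationStatus


def _ids_with_intact(matches: Iterable[EpitopeMatch]) -> set[str]:
    return {m.epitope_id for m in matches if m.match_type is MatchType.INTACT}


def _ids_with_partial(matches: Iterable[EpitopeMatch]) -> set[str]:
    return {m.epitope_id for m in matches if m.match_type is MatchType.PARTIAL}


def classify_fate(
    epitope: EpitopeRecord,
    fraction_matches: Iterable[EpitopeMatch],
    gd_intact: Iterable[EpitopeMatch],
    gd_partial: Iterable[EpitopeMatch],
    sample_id: str,
) -> FateStatus:
    """Fate of one epitope in one sample from pre-computed match sets.

    ``fraction_matches`` are intact matches over the Osborne fractions;
    ``gd_intact``/``gd_partial`` come from intact and partial screening of
    the GD-resistant peptide pool of the same sample.
    """
    eid = epitope.epitope_id
    expressed = eid in _ids_with_intact(fraction_matches)
    in_gd_intact = eid in _ids_with_intact(gd_intact)
    in_gd_partial = eid in _ids_with_partial(gd_partial)
    if not expressed:
        return FateStatus(
            eid, sample_id, Fate.NOT_EXPRESSED, anomaly=in_gd_intact or in_gd_partial
        )
    if in_gd_intact:
        return FateStatus(eid, sample_id, Fate.GD_RESISTANT)
    if in_gd_partial:
        return FateStatus(eid, sample_id, Fate.PARTIALLY_DEGRADED)
    return FateStatus(eid, sample_id, Fate.FULLY_DEGRADED)


def classify_fates(
    epitopes: Sequence[EpitopeRecord],
    fraction_matches: Iterable[EpitopeMatch],
    gd_intact: Iterable[EpitopeMatch],
    gd_partial: Iterable[EpitopeMatch],
    sample_id: str,
) -> list[FateStatus]:
    """Vectorised :func:`classify_fate` over a whole epitope table."""
    expressed = _ids_with_intact(fraction_matches)
    intact_gd = _ids_with_intact(gd_intact)
    partial_gd = _ids_with_partial(gd_partial)
    out: list[FateStatus] = []
    for epi in epitopes:
        eid = epi.epitope_id
        if eid not in expressed:
            out.append(
                FateStatus(
                    eid,
                    sample_id,
                    Fate.NOT_EXPRESSED,
                    anomaly=eid in intact_gd or eid in partial_gd,
                )
            )
        elif eid in intact_gd:
            out.append(FateStatus(eid, sample_id, Fate.GD_RESISTANT))
        elif eid in partial_gd:
            out.append(FateStatus(eid, sample_id, Fate.PARTIALLY_DEGRADED))
        else:
            out.append(FateStatus(eid, sample_id, Fate.FULLY_DEGRADED))
    return out


def presence_from_matches(
    per_sample_matches: Mapping[str, Iterable[EpitopeMatch]],
    samples: Sequence[str],
) -> pd.DataFrame:
    """Boolean presence matrix (epitopes × samples) from intact match sets.

    ``samples`` fixes the column order (reference first); rows cover every
    epitope with at least one intact match anywhere.
    """
    presence: dict[str, set[str]] = {
        s: _ids_with_intact(per_sample_matches.get(s, ())) for s in samples
    }
    all_ids = sorted(set().union(*presence.values()) if presence else set())
    data = {s: [eid in presence[s] for eid in all_ids] for s in samples}
    return pd.DataFrame(data, index=pd.Index(all_ids, name="epitope_id"))


def conservation(presence: pd.DataFrame) -> list[ConservationRow]:
    """Conserved/differential call per epitope from a presence matrix.

    ``presence`` is boolean, indexed by epitope_id with sample columns in
    study order (reference first).  Epitopes absent everywhere are excluded;
    the remainder partition into CONSERVED (all samples) and DIFFERENTIAL.
    """
    if presence.shape[1] < 1:
        raise GrainRiskError("presence matrix needs at least one sample column")
    rows: list[ConservationRow] = []
    for eid, flags in presence.iterrows():
        vec = tuple(bool(v) for v in flags)
        if not any(vec):
            continue
        status = (
            ConservationStatus.CONSERVED
            if all(vec)
            else ConservationStatus.DIFFERENTIAL
        )
        rows.append(ConservationRow(str(eid), vec, status))
    return rows
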