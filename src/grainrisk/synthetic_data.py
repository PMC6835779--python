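"""Synthetic wheat-like proteomes and peptide pools with ground truth.

Real peptide pools from grain peptidomics studies are rarely deposited, so
the pipeline is exercised on generated data that reproduces the structure the
analysis assumes: an Osborne-fractionated proteome (F1 albumin/globulin, F2
gliadin, F3 glutenin, with partial glutenin leakage into F2), storage-protein
sequences biased towards proline/glutamine repeats with known epitopes
implanted verbatim at recorded positions, enzyme-specific fraction digests,
and a gastroduodenal (GD) pool in which each implanted epitope survives
intact with a class-dependent probability or is emitted only as a sub-epitope
fragment.

Every generated dataset carries a ledger of construction-time truths —
per-implant survival, per-epitope expression/GD presence, hazard peptide
sets, fates and conservation calls — computed with plain substring scans so
that end-to-end assertions against the pipeline are exact.  All randomness
flows from a single integer seed; identical seeds give identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digest import digest_dual, digest_specific
from .fate import Fate
from .models import (
    ALBUMIN_GLOBULIN_CLASSES,
    CHYMOTRYPSIN,
    GLIADIN_CLASSES,
    GLUTENIN_CLASSES,
    Confidence,
    DigestLabel,
    DigestParams,
    Disease,
    EpitopeRecord,
    GrainRiskError,
    IdentifiedPeptide,
    ProteinClass,
    ProteinRecord,
    Stage,
    attribute_protein_class,
    load_cd_epitopes,
    load_wa_epitopes,
)
from .screen import LENGTH_GATES

__all__ = [
    "NoiseConfig",
    "SyntheticConfig",
    "Implant",
    "SamplePools",
    "StudyConfig",
    "SampleLedger",
    "StudyLedger",
    "StudyDataset",
    "default_implants",
    "make_proteome",
    "make_fraction_pools",
    "make_study",
    "default_study_config",
]

# Background residue weights for storage proteins: dominated by Q and P with
# moderate hydrophobics, echoing prolamin repeat composition.
STORAGE_BIAS: dict[str, float] = {
    "Q": 0.32,
    "P": 0.20,
    "F": 0.05,
    "L": 0.07,
    "S": 0.06,
    "Y": 0.03,
    "V": 0.05,
    "G": 0.06,
    "I": 0.03,
    "A": 0.04,
    "T": 0.03,
    "H": 0.01,
    "R": 0.02,
    "E": 0.02,
    "N": 0.01,
}

# Albumin/globulin background: closer to uniform usage of common residues.
METABOLIC_BIAS: dict[str, float] = {
    aa: 1.0
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}

_STORAGE_CLASSES = GLIADIN_CLASSES | GLUTENIN_CLASSES

# Free-text descriptions that round-trip through protein-class attribution.
_CLASS_DESCRIPTIONS: dict[ProteinClass, str] = {
    ProteinClass.ALPHA_GLIADIN: "alpha-gliadin (synthetic)",
    ProteinClass.GAMMA_GLIADIN: "gamma-gliadin (synthetic)",
    ProteinClass.OMEGA_GLIADIN: "omega-gliadin (synthetic)",
    ProteinClass.HMW_GS: "HMW glutenin subunit (synthetic)",
    ProteinClass.LMW_GS: "LMW glutenin subunit (synthetic)",
    ProteinClass.ATI: "alpha-amylase inhibitor (synthetic)",
    ProteinClass.NS_LTP: "non-specific lipid transfer protein (synthetic)",
    ProteinClass.PUROTHIONIN: "purothionin (synthetic)",
    ProteinClass.SERPIN: "serpin (synthetic)",
    ProteinClass.GLOBULIN: "globulin (synthetic)",
    ProteinClass.OTHER_METABOLIC: "metabolic enzyme (synthetic)",
    ProteinClass.UNKNOWN: "uncharacterized protein (synthetic)",
}

# Class-dependent probability that an implanted epitope region survives the
# GD digestion intact: lipid-transfer proteins and amylase/trypsin inhibitors
# are protease-resistant; gamma-/omega-gliadins persist largely unchanged;
# alpha-gliadins are more susceptible; glutenin epitopes mostly disappear.
DEFAULT_GD_SURVIVAL: dict[ProteinClass, float] = {
    ProteinClass.ALPHA_GLIADIN: 0.4,
    ProteinClass.GAMMA_GLIADIN: 0.75,
    ProteinClass.OMEGA_GLIADIN: 0.75,
    ProteinClass.HMW_GS: 0.05,
    ProteinClass.LMW_GS: 0.2,
    ProteinClass.ATI: 0.9,
    ProteinClass.NS_LTP: 0.9,
    ProteinClass.PUROTHIONIN: 0.5,
    ProteinClass.SERPIN: 0.3,
    ProteinClass.GLOBULIN: 0.1,
    ProteinClass.OTHER_METABOLIC: 0.1,
    ProteinClass.UNKNOWN: 0.5,
}

DEFAULT_N_PROTEINS: dict[ProteinClass, int] = {
    ProteinClass.ALPHA_GLIADIN: 3,
    ProteinClass.GAMMA_GLIADIN: 3,
    ProteinClass.OMEGA_GLIADIN: 2,
    ProteinClass.HMW_GS: 2,
    ProteinClass.LMW_GS: 3,
    ProteinClass.ATI: 2,
    ProteinClass.NS_LTP: 1,
    ProteinClass.PUROTHIONIN: 1,
    ProteinClass.SERPIN: 1,
    ProteinClass.GLOBULIN: 2,
}


@dataclass(frozen=True)
class NoiseConfig:
    """Decoy and evidence-noise settings; ``decoy_count=0`` switches noise off.

    Genuine rows always receive evidence passing the default reliability
    filters; decoys draw weaker evidence and are screened at generation time
    to contain no fixture epitope.
    """

    decoy_count: int = 0
    decoy_length_range: tuple[int, int] = (9, 25)
    score_mean: float = 3.0
    score_sd: float = 0.5
    decoy_score_mean: float = 0.8
    decoy_score_sd: float = 0.4
    psm_lambda: float = 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Per-sample generator settings; all randomness flows from ``rng_seed``."""

    rng_seed: int = 0
    n_proteins_per_class: Mapping[ProteinClass, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PROTEINS)
    )
    protein_length_range: tuple[int, int] = (250, 400)
    motif_alphabet_bias: Mapping[str, float] = field(
        default_factory=lambda: dict(STORAGE_BIAS)
    )
    #: (epitope_id, target class, copies); ``None`` selects every packaged
    #: epitope once, targeted at its attributed source class.
    implanted_epitopes: tuple[tuple[str, ProteinClass, int], ...] | None = None
    fraction_leakage: float = 0.3
    gd_survival: Mapping[ProteinClass, float] = field(
        default_factory=lambda: dict(DEFAULT_GD_SURVIVAL)
    )
    noise: NoiseConfig = NoiseConfig()
    min_overlap: int = 5
    gd_window_pad: tuple[int, int] = (4, 12)
    #: Emit a sub-epitope fragment for degraded implants (else nothing,
    #: which downstream reads as full degradation).
    degraded_emit_fragments: bool = True

    def __post_init__(self) -> None:
        for cls, p in self.gd_survival.items():
            if not (0.0 <= p <= 1.0):
                raise GrainRiskError(f"gd_survival[{cls}] outside [0, 1]")
        if not (0.0 <= self.fraction_leakage <= 1.0):
            raise GrainRiskError("fraction_leakage outside [0, 1]")


@dataclass(frozen=True)
class Implant:
    """One inserted epitope copy with its recorded genomic position."""

    epitope_id: str
    sequence: str
    accession: str
    protein_class: ProteinClass
    start: int  # 1-based, inclusive
    end: int


def default_implants(
    epitopes: Sequence[EpitopeRecord],
) -> tuple[tuple[str, ProteinClass, int], ...]:
    """One implant per epitope, targeted at its attributed source class.

    Labels the attributor cannot place (e.g. hordein homologues) default to
    omega-gliadin, whose solubility and mobility region they share.
    """
    out = []
    for epi in epitopes:
        cls = attribute_protein_class(epi.source_protein_label)
        if cls is ProteinClass.UNKNOWN:
            cls = ProteinClass.OMEGA_GLIADIN
        out.append((epi.epitope_id, cls, 1))
    return tuple(out)


def _draw_background(rng: np.random.Generator, length: int, bias: Mapping[str, float]) -> str:
    letters = sorted(bias)
    weights = np.array([bias[aa] for aa in letters], dtype=float)
    weights = weights / weights.sum()
    return "".join(rng.choice(letters, size=length, p=weights))


def make_proteome(
    config: SyntheticConfig,
    epitopes: Sequence[EpitopeRecord] | None = None,
) -> tuple[list[ProteinRecord], list[Implant]]:
    """Generate the per-class proteome and its implant registry.

    Storage-class backgrounds are drawn from the P/Q-biased alphabet,
    albumin/globulin backgrounds from a flat alphabet; each configured
    epitope copy is spliced in verbatim at a recorded 1-based position.
    """
    rng = np.random.default_rng(config.rng_seed)
    if epitopes is None:
        epitopes = load_cd_epitopes() + load_wa_epitopes()
    by_id = {e.epitope_id: e for e in epitopes}
    implant_spec = (
        config.implanted_epitopes
        if config.implanted_epitopes is not None
        else default_implants(epitopes)
    )

    lo, hi = config.protein_length_range
    # assign implant copies to (class, protein index) slots
    class_order = sorted(config.n_proteins_per_class, key=lambda c: c.name)
    backgrounds: dict[tuple[ProteinClass, int], str] = {}
    for cls in class_order:
        n = config.n_proteins_per_class[cls]
        bias = (
            config.motif_alphabet_bias if cls in _STORAGE_CLASSES else METABOLIC_BIAS
        )
        for i in range(n):
            backgrounds[(cls, i)] = _draw_background(
                rng, int(rng.integers(lo, hi + 1)), bias
            )

    pending: dict[tuple[ProteinClass, int], list[EpitopeRecord]] = {
        key: [] for key in backgrounds
    }
    for eid, cls, copies in implant_spec:
        if eid not in by_id:
            raise GrainRiskError(f"implant references unknown epitope {eid!r}")
        n = config.n_proteins_per_class.get(cls, 0)
        if n == 0:
            raise GrainRiskError(f"no proteins configured for class {cls.name}")
        epi = by_id[eid]
        for _ in range(copies):
            idx = int(rng.integers(0, n))
            if len(epi.sequence) > len(backgrounds[(cls, idx)]):
                raise GrainRiskError(
                    f"epitope {eid} longer than target protein background"
                )
            pending[(cls, idx)].append(epi)

    proteome: list[ProteinRecord] = []
    registry: list[Implant] = []
    counter = 0
    for cls in class_order:
        for i in range(config.n_proteins_per_class[cls]):
            counter += 1
            accession = f"SYN{counter:04d}"
            background = backgrounds[(cls, i)]
            inserts = pending[(cls, i)]
            positions = sorted(
                int(rng.integers(0, len(background) + 1)) for _ in inserts
            )
            seq_parts: list[str] = []
            cursor = 0
            local: list[tuple[EpitopeRecord, int]] = []
            offset = 0
            for epi, pos in zip(inserts, positions):
                seq_parts.append(background[cursor:pos])
                start0 = pos + offset
                seq_parts.append(epi.sequence)
                local.append((epi, start0))
                offset += len(epi.sequence)
                cursor = pos
            seq_parts.append(background[cursor:])
            sequence = "".join(seq_parts)
            proteome.append(
                ProteinRecord(
                    accession=accession,
                    description=f"{accession} {_CLASS_DESCRIPTIONS[cls]}",
                    sequence=sequence,
                    protein_class=cls,
                )
            )
            for epi, start0 in local:
                registry.append(
                    Implant(
                        epitope_id=epi.epitope_id,
                        sequence=epi.sequence,
                        accession=accession,
                        protein_class=cls,
                        start=start0 + 1,
                        end=start0 + len(epi.sequence),
                    )
                )
    return proteome, registry


@dataclass
class SamplePools:
    """Per-stage identified-peptide tables of one sample, plus GD bookkeeping."""

    sample_id: str
    pools: dict[Stage, list[IdentifiedPeptide]]
    #: survival draw per implant, aligned with the registry
    implant_survived: list[bool]

    def fraction_rows(self) -> list[IdentifiedPeptide]:
        return [
            row
            for stage in (Stage.F1, Stage.F2, Stage.F3)
            for row in self.pools.get(stage, [])
        ]

    def gd_rows(self) -> list[IdentifiedPeptide]:
        return list(self.pools.get(Stage.GD, []))


def _good_evidence(rng, noise: NoiseConfig) -> tuple[int, float]:
    psm = 3 + int(rng.poisson(noise.psm_lambda))
    score = max(1.0, float(rng.normal(noise.score_mean, noise.score_sd)))
    return psm, score


def _contains_any(sequence: str, epitopes: Sequence[EpitopeRecord]) -> bool:
    return any(e.sequence in sequence for e in epitopes)


def _clean_fragment(
    epitope: EpitopeRecord,
    all_epitopes: Sequence[EpitopeRecord],
    min_overlap: int,
) -> str | None:
    """Longest proper sub-epitope fragment containing no fixture epitope.

    Prefers prefixes shortened from the C-terminus, then suffixes; falling
    below ``min_overlap`` gives up (the implant then reads as fully
    degraded).  Nested epitopes in the fixture make the screen necessary:
    a naive prefix can itself be another database epitope.
    """
    seq = epitope.sequence
    for k in range(2, len(seq) - min_overlap + 1):
        for candidate in (seq[:-k], seq[k:]):
            if len(candidate) >= min_overlap and not _contains_any(
                candidate, all_epitopes
            ):
                return candidate
    return None


def make_fraction_pools(
    proteome: Sequence[ProteinRecord],
    registry: Sequence[Implant],
    config: SyntheticConfig,
    sample_id: str,
    epitopes: Sequence[EpitopeRecord] | None = None,
    digest_params: DigestParams = DigestParams(),
) -> SamplePools:
    """Build F1/F2/F3 digest pools and the sampled GD pool for one sample.

    Fractions follow Osborne solubility: F1 holds albumin/globulin classes,
    F2 the gliadins (plus each glutenin protein leaked with probability
    ``fraction_leakage``, as observed for partial glutenin extraction in
    ethanol), F3 the glutenins.  Fraction peptides come from the single- and
    dual-enzyme specific digests.  The GD pool samples, per implant, a
    flanked window containing the intact epitope with probability
    ``gd_survival[class]`` and otherwise (optionally) a clean sub-epitope
    fragment; configured decoys are appended to every pool.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    if epitopes is None:
        epitopes = load_cd_epitopes() + load_wa_epitopes()
    noise = config.noise

    by_class: dict[Stage, list[ProteinRecord]] = {
        Stage.F1: [],
        Stage.F2: [],
        Stage.F3: [],
    }
    for prot in proteome:
        if prot.protein_class in ALBUMIN_GLOBULIN_CLASSES:
            by_class[Stage.F1].append(prot)
        elif prot.protein_class in GLIADIN_CLASSES:
            by_class[Stage.F2].append(prot)
        elif prot.protein_class in GLUTENIN_CLASSES:
            by_class[Stage.F3].append(prot)
        else:
            by_class[Stage.F1].append(prot)
    # partial glutenin extraction already in the ethanolic fraction
    for prot in by_class[Stage.F3]:
        if rng.random() < config.fraction_leakage:
            by_class[Stage.F2].append(prot)

    pools: dict[Stage, list[IdentifiedPeptide]] = {}
    for stage in (Stage.F1, Stage.F2, Stage.F3):
        rows: list[IdentifiedPeptide] = []
        for prot in by_class[stage]:
            for label, occs in (
                (DigestLabel.CHY, digest_specific(prot, CHYMOTRYPSIN, digest_params)),
                (DigestLabel.THE_CHY, digest_dual(prot, digest_params)),
            ):
                seen: set[str] = set()
                for occ in occs:
                    if occ.sequence in seen:
                        continue
                    seen.add(occ.sequence)
                    psm, score = _good_evidence(rng, noise)
                    rows.append(
                        IdentifiedPeptide(
                            sequence=occ.sequence,
                            sample_id=sample_id,
                            stage=stage,
                            digest_label=label,
                            psm_count=psm,
                            score=score,
                            confidence=Confidence.HIGH,
                            unambiguous=True,
                        )
                    )
        pools[stage] = rows

    gd_rows: list[IdentifiedPeptide] = []
    survived: list[bool] = []
    pad_lo, pad_hi = config.gd_window_pad
    for implant in registry:
        lives = bool(rng.random() < config.gd_survival.get(implant.protein_class, 0.0))
        survived.append(lives)
        if lives:
            pad = int(rng.integers(pad_lo, pad_hi + 1))
            left = int(rng.integers(0, pad + 1))
            right = pad - left
            window = (
                _draw_background(rng, left, config.motif_alphabet_bias)
                + implant.sequence
                + _draw_background(rng, right, config.motif_alphabet_bias)
            )
            sequence = window
        else:
            if not config.degraded_emit_fragments:
                continue
            fragment = _clean_fragment(
                next(e for e in epitopes if e.epitope_id == implant.epitope_id),
                epitopes,
                config.min_overlap,
            )
            if fragment is None:
                continue
            sequence = fragment
        psm, score = _good_evidence(rng, noise)
        gd_rows.append(
            IdentifiedPeptide(
                sequence=sequence,
                sample_id=sample_id,
                stage=Stage.GD,
                digest_label=DigestLabel.GD,
                psm_count=psm,
                score=score,
                confidence=Confidence.HIGH,
                unambiguous=True,
            )
        )
    pools[Stage.GD] = gd_rows

    if noise.decoy_count > 0:
        dlo, dhi = noise.decoy_length_range
        for stage in (Stage.F1, Stage.F2, Stage.F3, Stage.GD):
            added = 0
            while added < noise.decoy_count:
                seq = _draw_background(
                    rng, int(rng.integers(dlo, dhi + 1)), config.motif_alphabet_bias
                )
                if _contains_any(seq, epitopes):
                    continue
                psm = 1 + int(rng.poisson(1.0))
                score = max(0.0, float(rng.normal(noise.decoy_score_mean, noise.decoy_score_sd)))
                confidence = Confidence(int(rng.integers(0, 3)))
                pools[stage].append(
                    IdentifiedPeptide(
                        sequence=seq,
                        sample_id=sample_id,
                        stage=stage,
                        digest_label=DigestLabel.GD
                        if stage is Stage.GD
                        else DigestLabel.CHY,
                        psm_count=psm,
                        score=score,
                        confidence=confidence,
                        unambiguous=bool(rng.random() < 0.5),
                    )
                )
                added += 1

    return SamplePools(sample_id=sample_id, pools=pools, implant_survived=survived)


# ---------------------------------------------------------------------------
# Multi-sample studies with a ground-truth ledger
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Ordered sample configs; the first entry is the reference sample."""

    samples: tuple[tuple[str, SyntheticConfig], ...]

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise GrainRiskError("a study needs a reference plus >= 1 genotype")
        ids = [sid for sid, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise GrainRiskError("duplicate sample ids in study config")


@dataclass
class SampleLedger:
    """Construction-time truths for one sample (substring-scan based)."""

    expressed_ids: dict[Disease, set[str]]
    gd_intact_ids: dict[Disease, set[str]]
    gd_partial_ids: dict[Disease, set[str]]
    hazard: dict[Disease, set[tuple[str, str]]]
    screened_counts: dict[Disease, int]
    fates: dict[Disease, dict[str, Fate]]


@dataclass
class StudyLedger:
    samples: list[str]
    per_sample: dict[str, SampleLedger]
    #: disease -> epitope_id -> presence vector over samples (ref first)
    presence: dict[Disease, dict[str, tuple[bool, ...]]]

    def hazard_counts(self, disease: Disease) -> dict[str, int]:
        return {
            sid: len(self.per_sample[sid].hazard[disease]) for sid in self.samples
        }


@dataclass
class StudyDataset:
    config: StudyConfig
    epitopes: dict[Disease, list[EpitopeRecord]]
    proteomes: dict[str, list[ProteinRecord]]
    registries: dict[str, list[Implant]]
    pools: dict[str, SamplePools]
    ledger: StudyLedger

    @property
    def samples(self) -> list[str]:
        return [sid for sid, _ in self.config.samples]

    @property
    def reference_id(self) -> str:
        return self.config.samples[0][0]


def _kmers(sequence: str, k: int) -> list[str]:
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


def _sample_ledger(
    pools: SamplePools,
    epitopes_by_disease: Mapping[Disease, Sequence[EpitopeRecord]],
    min_overlap: int,
) -> SampleLedger:
    """Truths via plain ``in`` scans, independent of the screening module."""
    fraction_seqs = [p.sequence for p in pools.fraction_rows()]
    gd_seqs = [p.sequence for p in pools.gd_rows()]

    expressed: dict[Disease, set[str]] = {}
    gd_intact: dict[Disease, set[str]] = {}
    gd_partial: dict[Disease, set[str]] = {}
    hazard: dict[Disease, set[tuple[str, str]]] = {}
    screened: dict[Disease, int] = {}
    fates: dict[Disease, dict[str, Fate]] = {}

    for disease, table in epitopes_by_disease.items():
        gate = LENGTH_GATES[disease]
        gated_gd = [s for s in gd_seqs if len(s) >= gate]
        screened[disease] = len(gated_gd)
        partial_pool = [s for s in gd_seqs if len(s) >= min_overlap]
        expressed[disease] = {
            e.epitope_id
            for e in table
            if any(e.sequence in s for s in fraction_seqs)
        }
        gd_intact[disease] = {
            e.epitope_id for e in table if any(e.sequence in s for s in gated_gd)
        }
        gd_partial[disease] = set()
        for e in table:
            if e.epitope_id in gd_intact[disease]:
                continue
            kmers = set(_kmers(e.sequence, min_overlap))
            if any(any(k in s for k in kmers) for s in partial_pool):
                gd_partial[disease].add(e.epitope_id)
        hazard[disease] = {
            (pools.sample_id, s)
            for s in gated_gd
            if any(e.sequence in s for e in table)
        }
        fates[disease] = {}
        for e in table:
            eid = e.epitope_id
            if eid not in expressed[disease]:
                fates[disease][eid] = Fate.NOT_EXPRESSED
            elif eid in gd_intact[disease]:
                fates[disease][eid] = Fate.GD_RESISTANT
            elif eid in gd_partial[disease]:
                fates[disease][eid] = Fate.PARTIALLY_DEGRADED
            else:
                fates[disease][eid] = Fate.FULLY_DEGRADED
    return SampleLedger(
        expressed_ids=expressed,
        gd_intact_ids=gd_intact,
        gd_partial_ids=gd_partial,
        hazard=hazard,
        screened_counts=screened,
        fates=fates,
    )


def make_study(
    study: StudyConfig,
    epitopes_cd: Sequence[EpitopeRecord] | None = None,
    epitopes_wa: Sequence[EpitopeRecord] | None = None,
) -> StudyDataset:
    """Generate the full multi-sample dataset plus its ground-truth ledger."""
    cd = list(epitopes_cd) if epitopes_cd is not None else load_cd_epitopes()
    wa = list(epitopes_wa) if epitopes_wa is not None else load_wa_epitopes()
    all_epitopes = cd + wa
    by_disease = {Disease.CD: cd, Disease.WA: wa}

    proteomes: dict[str, list[ProteinRecord]] = {}
    registries: dict[str, list[Implant]] = {}
    pools: dict[str, SamplePools] = {}
    per_sample: dict[str, SampleLedger] = {}
    sample_ids = [sid for sid, _ in study.samples]

    for sid, cfg in study.samples:
        proteome, registry = make_proteome(cfg, all_epitopes)
        sample_pools = make_fraction_pools(
            proteome, registry, cfg, sid, epitopes=all_epitopes
        )
        proteomes[sid] = proteome
        registries[sid] = registry
        pools[sid] = sample_pools
        per_sample[sid] = _sample_ledger(sample_pools, by_disease, cfg.min_overlap)

    presence: dict[Disease, dict[str, tuple[bool, ...]]] = {}
    for disease, table in by_disease.items():
        presence[disease] = {}
        for e in table:
            vec = tuple(
                e.epitope_id in per_sample[sid].gd_intact_ids[disease]
                for sid in sample_ids
            )
            if any(vec):
                presence[disease][e.epitope_id] = vec

    return StudyDataset(
        config=study,
        epitopes=by_disease,
        proteomes=proteomes,
        registries=registries,
        pools=pools,
        ledger=StudyLedger(
            samples=sample_ids, per_sample=per_sample, presence=presence
        ),
    )


def default_study_config(seed: int, n_genotypes: int = 5) -> StudyConfig:
    """A reference-plus-genotypes study emulating a six-sample comparison.

    The reference implants every packaged epitope; each genotype drops a
    deterministic, seed-dependent subset of implants (keep probability 0.7,
    genotype-specific), reproducing the observed pattern of genotypes
    carrying fewer hazard sequences than the commercial reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    epitopes = load_cd_epitopes() + load_wa_epitopes()
    base_implants = default_implants(epitopes)
    samples: list[tuple[str, SyntheticConfig]] = [
        ("REF", SyntheticConfig(rng_seed=seed, implanted_epitopes=base_implants))
    ]
    for g in range(1, n_genotypes + 1):
        keep = tuple(
            spec for spec in base_implants if rng.random() < 0.7
        )
        samples.append(
            (
                str(g),
                SyntheticConfig(rng_seed=seed + g, implanted_epitopes=keep),
            )
        )
    return StudyConfig(samples=tuple(samples))
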