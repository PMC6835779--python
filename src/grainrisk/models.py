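"""Domain types, controlled vocabularies and tabular I/O.

The package models a wheat-grain peptidomics study: proteins extracted as
Osborne fractions (F1 albumin/globulin, F2 gliadin, F3 glutenin) are digested
in silico, identified peptides are filtered for reliability, and the surviving
peptide pools are screened against linear celiac-disease (CD) and wheat-allergy
(WA) epitope tables.  This module holds the shared record types, the
protein-class vocabulary, and readers/writers for every tabular artifact.
"""

from __future__ import annotations

import enum
import re
import unicodedata
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "SEQUENCE_ALPHABET",
    "MODIFICATION_NAMES",
    "ProteinClass",
    "Disease",
    "Stage",
    "DigestLabel",
    "Confidence",
    "CleavageSide",
    "ProteinRecord",
    "EnzymeSpec",
    "DigestParams",
    "IdentifiedPeptide",
    "EpitopeRecord",
    "CHYMOTRYPSIN",
    "THERMOLYSIN_CHYMOTRYPSIN",
    "GrainRiskError",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "attribute_protein_class",
    "read_epitope_table",
    "write_epitope_table",
    "read_peptide_table",
    "write_peptide_table",
    "load_cd_epitopes",
    "load_wa_epitopes",
    "load_epitopes",
    "load_presence_matrix",
    "load_conserved_gd_resistant_ids",
]

#: The 20 proteinogenic residues; ``X`` is additionally accepted in protein
#: sequences as an unknown-residue placeholder.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}

#: Dynamic/static modifications carried by identification tables.
MODIFICATION_NAMES = frozenset(
    {
        "methionine-oxidation",
        "deamidation",
        "pyroglutamate",
        "N-terminal-acetylation",
        "carbamidomethylation",
    }
)


class GrainRiskError(Exception):
    """Base class for package errors."""


class FormatError(GrainRiskError):
    """An input file violates its declared format."""


class ProteinClass(enum.Enum):
    """Wheat protein families reported at parent level.

    Finer subtypes (omega-5 vs omega-1,2 gliadin; x- vs y-type HMW glutenin;
    s/m/i-type LMW glutenin) are collapsed into their parent class, which is
    the resolution at which hazard summaries and per-class distributions are
    reported.
    """

    ALPHA_GLIADIN = "alpha_gliadin"
    GAMMA_GLIADIN = "gamma_gliadin"
    OMEGA_GLIADIN = "omega_gliadin"
    HMW_GS = "hmw_gs"
    LMW_GS = "lmw_gs"
    ATI = "ati"
    NS_LTP = "ns_ltp"
    PUROTHIONIN = "purothionin"
    SERPIN = "serpin"
    GLOBULIN = "globulin"
    OTHER_METABOLIC = "other_metabolic"
    UNKNOWN = "unknown"


#: Classes extracted in the salt-soluble albumin/globulin fraction (F1).
ALBUMIN_GLOBULIN_CLASSES = frozenset(
    {
        ProteinClass.ATI,
        ProteinClass.NS_LTP,
        ProteinClass.PUROTHIONIN,
        ProteinClass.SERPIN,
        ProteinClass.GLOBULIN,
        ProteinClass.OTHER_METABOLIC,
    }
)
#: Alcohol-soluble gliadins (F2).
GLIADIN_CLASSES = frozenset(
    {ProteinClass.ALPHA_GLIADIN, ProteinClass.GAMMA_GLIADIN, ProteinClass.OMEGA_GLIADIN}
)
#: Reduced/denatured-soluble glutenins (F3).
GLUTENIN_CLASSES = frozenset({ProteinClass.HMW_GS, ProteinClass.LMW_GS})


class Disease(enum.Enum):
    CD = "CD"
    WA = "WA"


class Stage(enum.Enum):
    """Origin of a peptide pool: Osborne fraction or gastroduodenal digest."""

    F1 = "F1"
    F2 = "F2"
    F3 = "F3"
    GD = "GD"


class DigestLabel(enum.Enum):
    CHY = "CHY"
    THE_CHY = "THE_CHY"
    GD = "GD"
    NA = "NA"


class Confidence(enum.IntEnum):
    """Search-engine confidence label; ordering supports threshold filters."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


class CleavageSide(enum.Enum):
    C_TERMINAL = "C"
    N_TERMINAL = "N"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a controlled protein-class label."""

    accession: str
    description: str
    sequence: str
    protein_class: ProteinClass = ProteinClass.UNKNOWN

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.accession!r}: invalid residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EnzymeSpec:
    """A protease cleavage rule: residue set plus the cut side.

    ``blocked_following`` optionally names residues that suppress a cut when
    they follow the cleavage site (e.g. the no-cut-before-proline variant of
    chymotrypsin); empty by default.
    """

    name: str
    cleavage_residues: frozenset[str]
    side: CleavageSide = CleavageSide.C_TERMINAL
    blocked_following: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.cleavage_residues:
            raise ValueError("cleavage_residues must be non-empty")
        bad = set(self.cleavage_residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"cleavage residues outside the alphabet: {sorted(bad)!r}")


#: Chymotrypsin: cleaves C-terminal to F/L/W/Y (no proline exception applied).
CHYMOTRYPSIN = EnzymeSpec("CHY", frozenset("FLWY"))
#: Combined thermolysin + chymotrypsin specificity, run as a single rule with
#: the union residue set A/F/I/L/M/V/W/Y on the C-terminal side.
THERMOLYSIN_CHYMOTRYPSIN = EnzymeSpec("THE/CHY", frozenset("AFILMVWY"))


@dataclass(frozen=True)
class DigestParams:
    """Digest bounds: missed cleavages and retained peptide length (AA).

    Defaults mirror a wide search configuration for proteolysis-resistant
    storage proteins: up to 5 missed cleavages, peptides of 4-144 residues.
    Unspecific enumeration ignores missed cleavages (use 0).
    """

    max_missed_cleavages: int = 5
    min_len: int = 4
    max_len: int = 144

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")


UNSPECIFIC_PARAMS = DigestParams(max_missed_cleavages=0, min_len=4, max_len=144)


@dataclass(frozen=True)
class IdentifiedPeptide:
    """One row of a search-engine peptide export with its evidence fields."""

    sequence: str
    sample_id: str
    stage: Stage
    digest_label: DigestLabel = DigestLabel.NA
    psm_count: int = 0
    score: float = 0.0
    confidence: Confidence = Confidence.LOW
    unambiguous: bool = True
    modifications: tuple[tuple[int, str], ...] = ()
    provenance: tuple[DigestLabel, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.psm_count < 0:
            raise ValueError("psm_count must be >= 0")
        if self.score < 0:
            raise ValueError("score must be >= 0")
        for pos, name in self.modifications:
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(
                    f"modification position {pos} outside peptide of "
                    f"length {len(self.sequence)}"
                )
            if name not in MODIFICATION_NAMES:
                raise ValueError(f"unknown modification {name!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EpitopeRecord:
    """A linear CD or WA epitope with its database annotations."""

    epitope_id: str
    disease: Disease
    sequence: str
    restriction_or_allergen: str
    source_protein_label: str
    core_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequence) < 5:
            raise ValueError(
                f"epitope {self.epitope_id!r}: sequence shorter than 5 AA"
            )
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"epitope {self.epitope_id!r}: invalid residue(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Protein-class attribution
# ---------------------------------------------------------------------------

_GREEK = {"α": "alpha", "β": "beta", "γ": "gamma", "ω": "omega"}


def _normalize(text: str) -> str:
    text = unicodedata.normalize("NFKC", text)
    for greek, latin in _GREEK.items():
        text = text.replace(greek, latin)
    return text.lower()


# WHO/IUIS wheat allergen codes, checked before free-text keywords.
_ALLERGEN_CODES: tuple[tuple[str, ProteinClass], ...] = (
    ("tri a 19", ProteinClass.OMEGA_GLIADIN),
    ("tri a 20", ProteinClass.GAMMA_GLIADIN),
    ("tri a 21", ProteinClass.ALPHA_GLIADIN),
    ("tri a 26", ProteinClass.HMW_GS),
    ("tri a 36", ProteinClass.LMW_GS),
    ("tri a 28", ProteinClass.ATI),
    ("tri a 15", ProteinClass.ATI),
    ("tri a 14", ProteinClass.NS_LTP),
    ("tri a 37", ProteinClass.PUROTHIONIN),
)

# Free-text keyword rules, first match wins.  Each entry is a list of regexes
# that must all match the normalized description.
_KEYWORD_RULES: tuple[tuple[tuple[str, ...], ProteinClass], ...] = (
    (("omega", "glia"), ProteinClass.OMEGA_GLIADIN),
    (("alpha", "glia"), ProteinClass.ALPHA_GLIADIN),
    (("gamma", "glia"), ProteinClass.GAMMA_GLIADIN),
    (("hmw",), ProteinClass.HMW_GS),
    (("high molecular weight",), ProteinClass.HMW_GS),
    (("lmw",), ProteinClass.LMW_GS),
    (("low molecular weight",), ProteinClass.LMW_GS),
    (("amylase", "inhibitor"), ProteinClass.ATI),
    (("trypsin", "inhibitor"), ProteinClass.ATI),
    (("lipid transfer",), ProteinClass.NS_LTP),
    (("purothionin",), ProteinClass.PUROTHIONIN),
    (("serpin",), ProteinClass.SERPIN),
    (("globulin",), ProteinClass.GLOBULIN),
    # bare "glutenin" (no HMW/LMW qualifier) → LMW, the most populous family
    (("glutenin",), ProteinClass.LMW_GS),
)


def attribute_protein_class(description: str) -> ProteinClass:
    """Map a free-text protein description to a :class:`ProteinClass`.

    Total and deterministic: allergen codes (``Tri a NN``) take precedence
    over free-text keywords; among keywords the first rule in a fixed
    priority list wins (gliadin subclasses before glutenins before
    albumin/globulin families).  Greek letters are transliterated, matching
    is case-insensitive, and descriptions with no recognized keyword map to
    ``UNKNOWN``.
    """
    text = _normalize(description)
    for code, cls in _ALLERGEN_CODES:
        if code in text:
            return cls
    for needles, cls in _KEYWORD_RULES:
        if all(needle in text for needle in needles):
            return cls
    return ProteinClass.UNKNOWN


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; the protein class is attributed from the
    description line.  A residue outside the alphabet raises
    :class:`FormatError` naming the offending entry; an empty file returns an
    empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        try:
            records.append(
                ProteinRecord(
                    accession=entry.id,
                    description=entry.description,
                    sequence=seq,
                    protein_class=attribute_protein_class(entry.description),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: entry {entry.id!r}: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Epitope tables
# ---------------------------------------------------------------------------

_EPITOPE_COLUMNS = [
    "epitope_id",
    "disease",
    "sequence",
    "restriction_or_allergen",
    "source_protein_label",
    "core_names",
]


def read_epitope_table(path: str | Path) -> list[EpitopeRecord]:
    """Read a delimited epitope table (comma or tab separated).

    Mandated header: ``epitope_id, disease, sequence, restriction_or_allergen,
    source_protein_label, core_names`` (core names semicolon-separated).
    Duplicate IDs and invalid disease codes are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    missing = [c for c in _EPITOPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records: list[EpitopeRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        eid = row["epitope_id"].strip()
        if eid in seen:
            raise FormatError(f"{path}: duplicate epitope_id {eid!r}")
        seen.add(eid)
        try:
            disease = Disease(row["disease"].strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: epitope {eid!r}: invalid disease code {row['disease']!r}"
            ) from exc
        cores = tuple(c for c in row["core_names"].split(";") if c)
        try:
            records.append(
                EpitopeRecord(
                    epitope_id=eid,
                    disease=disease,
                    sequence=row["sequence"].strip().upper(),
                    restriction_or_allergen=row["restriction_or_allergen"].strip(),
                    source_protein_label=row["source_protein_label"].strip(),
                    core_names=cores,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_epitope_table(records: Iterable[EpitopeRecord], path: str | Path) -> None:
    """Write epitopes with the deterministic column order of the reader."""
    rows = [
        {
            "epitope_id": r.epitope_id,
            "disease": r.disease.value,
            "sequence": r.sequence,
            "restriction_or_allergen": r.restriction_or_allergen,
            "source_protein_label": r.source_protein_label,
            "core_names": ";".join(r.core_names),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_EPITOPE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Identified-peptide tables
# ---------------------------------------------------------------------------

_PEPTIDE_COLUMNS = [
    "sequence",
    "sample_id",
    "stage",
    "digest_label",
    "psm_count",
    "score",
    "confidence",
    "unambiguous",
    "modifications",
    "provenance",
]


def _format_mods(mods: tuple[tuple[int, str], ...]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


def _parse_mods(text: str) -> tuple[tuple[int, str], ...]:
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        pos, _, name = item.partition(":")
        out.append((int(pos), name))
    return tuple(out)


def write_peptide_table(rows: Iterable[IdentifiedPeptide], path: str | Path) -> None:
    data = [
        {
            "sequence": p.sequence,
            "sample_id": p.sample_id,
            "stage": p.stage.value,
            "digest_label": p.digest_label.value,
            "psm_count": p.psm_count,
            "score": p.score,
            "confidence": p.confidence.name,
            "unambiguous": p.unambiguous,
            "modifications": _format_mods(p.modifications),
            "provenance": ";".join(lab.value for lab in p.provenance),
        }
        for p in rows
    ]
    pd.DataFrame(data, columns=_PEPTIDE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peptide_table(path: str | Path) -> list[IdentifiedPeptide]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _PEPTIDE_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out: list[IdentifiedPeptide] = []
    for _, row in df.iterrows():
        try:
            out.append(
                IdentifiedPeptide(
                    sequence=row["sequence"].strip().upper(),
                    sample_id=row["sample_id"],
                    stage=Stage(row["stage"]),
                    digest_label=DigestLabel(row["digest_label"] or "NA"),
                    psm_count=int(row["psm_count"] or 0),
                    score=float(row["score"] or 0.0),
                    confidence=Confidence[row["confidence"] or "LOW"],
                    unambiguous=row["unambiguous"].strip().lower()
                    in ("true", "1", "yes"),
                    modifications=_parse_mods(row.get("modifications", "")),
                    provenance=tuple(
                        DigestLabel(v)
                        for v in row.get("provenance", "").split(";")
                        if v
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}: bad row {row['sequence']!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures: differential GD-resistant epitope tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("grainrisk.data").joinpath(name)


def load_cd_epitopes() -> list[EpitopeRecord]:
    """The packaged table of differential GD-resistant CD epitopes (34 rows)."""
    with resources.as_file(_data_path("cd_epitopes.csv")) as p:
        return read_epitope_table(p)


def load_wa_epitopes() -> list[EpitopeRecord]:
    """The packaged table of differential GD-resistant WA epitopes (30 rows)."""
    with resources.as_file(_data_path("wa_epitopes.csv")) as p:
        return read_epitope_table(p)


def load_epitopes(disease: Disease) -> list[EpitopeRecord]:
    return load_cd_epitopes() if disease is Disease.CD else load_wa_epitopes()


def load_presence_matrix(disease: Disease) -> pd.DataFrame:
    """Packaged per-sample presence of each differential epitope.

    Returns a boolean DataFrame indexed by epitope_id with sample columns
    (reference first): True where the epitope was detected intact in that
    sample's gastroduodenal digest.
    """
    name = "cd_presence.tsv" if disease is Disease.CD else "wa_presence.tsv"
    with resources.as_file(_data_path(name)) as p:
        df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    df = df.set_index("epitope_id")
    return df.apply(lambda col: col.str.strip() == "X")


def load_conserved_gd_resistant_ids(disease: Disease) -> list[str]:
    """IDs of GD-resistant epitopes conserved across all study samples.

    These are annotation-only: the source tables list them by database ID
    (and, for CD, partly by 9-AA core name) without printing sequences, so
    they cannot participate in sequence matching.
    """
    name = (
        "cd_conserved_gd_resistant.csv"
        if disease is Disease.CD
        else "wa_conserved_gd_resistant.csv"
    )
    with resources.as_file(_data_path(name)) as p:
        df = pd.read_csv(p, dtype=str).fillna("")
    return [v for v in df["epitope_id"].str.strip() if v]
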