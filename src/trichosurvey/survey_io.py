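"""Data model and file I/O for culture-based soil fungal surveys.

The survey design mirrors large culture-collection studies of *Trichoderma*
in agricultural soils of East China: soil samples are collected across
sampling regions, provinces, climate zones (S = subtropical monsoon,
T = temperate monsoon, B = the boundary belt between them), seasons
(spring/summer/autumn) and crops (rice/wheat/maize/other); total fungal
colonies are counted on selective medium, and isolates of the target genus
are sequenced at the ITS1/ITS2 marker and later collapsed into haplotypes.

No standard file layout exists for such surveys, so this module defines a
plain TSV/CSV schema (documented in the README) together with readers and
writers that validate it strictly at load time: referential integrity
between samples, isolates and sequences is rejected on read, never deferred
to analysis code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("trichosurvey")

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class TrichoSurveyError(Exception):
    """Base class for all package errors."""


class FormatError(TrichoSurveyError):
    """A file does not conform to the expected tabular/FASTA layout."""


class IntegrityError(TrichoSurveyError):
    """Cross-references between records are inconsistent (duplicate ids,
    dangling foreign keys, isolate counts exceeding colony counts)."""


class ValidationError(TrichoSurveyError):
    """A single field value is out of its allowed domain."""


class AlignmentError(TrichoSurveyError):
    """Sequences claimed to be aligned have unequal lengths."""


class DomainError(TrichoSurveyError):
    """An operation was called on an empty or degenerate input."""


class DegenerateInputError(TrichoSurveyError):
    """A matrix input has a zero margin or too little structure to analyse."""


class ConfigError(TrichoSurveyError):
    """A generator or analysis configuration is self-inconsistent."""


# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

CLIMATE_ZONES: tuple[str, ...] = ("S", "T", "B")
SEASONS: tuple[str, ...] = ("spring", "summer", "autumn")
CROPS: tuple[str, ...] = ("rice", "wheat", "maize", "other")

#: IUPAC nucleotide codes accepted in aligned marker sequences.
#: '-' is the alignment gap; everything outside A/C/G/T/- is treated as
#: ambiguous/missing by downstream column selection.
NUCLEOTIDES = frozenset("ACGT")
GAP = "-"
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")
ALLOWED_CHARS = NUCLEOTIDES | IUPAC_AMBIGUITY | {GAP}


class GapPolicy(str, Enum):
    """How alignment columns containing gaps or ambiguity codes are treated
    when deciding whether two sequences are the same haplotype.

    ``EXCLUDE_COLUMNS`` drops every column in which *any* sequence carries a
    gap or an ambiguity code (the conventional treatment of missing sites in
    haplotype callers such as DnaSP); ``LITERAL`` compares all columns,
    treating '-' and ambiguity codes as ordinary characters.
    """

    EXCLUDE_COLUMNS = "exclude_columns"
    LITERAL = "literal"


def _as_gap_policy(value: "GapPolicy | str") -> GapPolicy:
    if isinstance(value, GapPolicy):
        return value
    try:
        return GapPolicy(str(value).replace("-", "_"))
    except ValueError as exc:
        raise ValidationError(f"unknown gap policy: {value!r}") from exc


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SurveySample:
    """One soil sample with its stratum labels and colony count.

    ``total_fungal_colonies`` is the number of fungal colonies of any genus
    counted on the isolation plates for this sample; ``isolate_ids`` lists
    the target-genus isolates recovered from it (possibly empty).
    """

    sample_id: str
    region: str
    province: str
    climate_zone: str
    season: str
    crop: str
    total_fungal_colonies: int
    isolate_ids: list[str] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.climate_zone not in CLIMATE_ZONES:
            raise ValidationError(
                f"sample {self.sample_id!r}: climate_zone {self.climate_zone!r} "
                f"not one of {CLIMATE_ZONES}"
            )
        if self.season not in SEASONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: season {self.season!r} not one of {SEASONS}"
            )
        if self.crop not in CROPS:
            raise ValidationError(
                f"sample {self.sample_id!r}: crop {self.crop!r} not one of {CROPS}"
            )
        self.total_fungal_colonies = int(self.total_fungal_colonies)
        if self.total_fungal_colonies < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative colony count "
                f"{self.total_fungal_colonies}"
            )


@dataclass
class IsolateRecord:
    """One target-genus isolate: its source sample, species call (``None``
    while unidentified), haplotype assignment (``None`` before collapsing)
    and the id of its aligned marker sequence."""

    isolate_id: str
    sample_id: str
    species: str | None
    sequence_id: str
    haplotype_code: str | None = None


@dataclass
class AlignedSequenceSet:
    """Equal-length marker sequences keyed by sequence id.

    Sequences are stored uppercase over the alphabet A/C/G/T, IUPAC
    ambiguity codes, N and '-'.
    """

    entries: dict[str, str]
    alignment_length: int

    @classmethod
    def from_entries(cls, entries: Mapping[str, str]) -> "AlignedSequenceSet":
        normalized: dict[str, str] = {}
        length: int | None = None
        for seq_id, seq in entries.items():
            seq = str(seq).upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"sequence {seq_id!r} has length {len(seq)}, expected {length}"
                )
            for pos, ch in enumerate(seq):
                if ch not in ALLOWED_CHARS:
                    raise ValidationError(
                        f"sequence {seq_id!r}: illegal character {ch!r} at position {pos}"
                    )
            normalized[seq_id] = seq
        if length is None:
            length = 0
        return cls(entries=normalized, alignment_length=length)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __getitem__(self, seq_id: str) -> str:
        return self.entries[seq_id]

    @property
    def ids(self) -> list[str]:
        return list(self.entries)


@dataclass
class SurveyConfig:
    """Analysis-wide knobs: gap policy for haplotype collapsing, logarithm
    base of the Shannon–Wiener index, the dominance threshold of the
    Y > threshold rule, the coding of the correspondence analysis and the
    decimals used when formatting each statistic for display."""

    gap_policy: GapPolicy = GapPolicy.EXCLUDE_COLUMNS
    shannon_log_base: str = "e"  # one of "e", "2", "10"
    dominance_threshold: float = 0.02
    ca_coding: str = "indicator"  # or "burt"
    rounding: dict[str, int] = field(
        default_factory=lambda: {"dominance": 3, "shannon": 2, "rate_percent": 0}
    )

    def __post_init__(self) -> None:
        if self.dominance_threshold <= 0:
            raise ValidationError("dominance_threshold must be > 0")
        if str(self.shannon_log_base) not in {"e", "2", "10"}:
            raise ValidationError(
                f"shannon_log_base must be 'e', '2' or '10', got {self.shannon_log_base!r}"
            )
        if self.ca_coding not in {"indicator", "burt"}:
            raise ValidationError(f"ca_coding must be 'indicator' or 'burt', got {self.ca_coding!r}")


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = (
    "sample_id",
    "region",
    "province",
    "climate_zone",
    "season",
    "crop",
    "total_fungal_colonies",
)

ISOLATE_COLUMNS = ("isolate_id", "sample_id", "species", "sequence_id")


def _separator(path: str | Path, dialect: str | None) -> str:
    """Tab for .tsv, comma for .csv; an explicit ``dialect`` ('tab'/'comma'
    or a literal separator) overrides the extension."""
    if dialect is not None:
        return {"tab": "\t", "comma": ","}.get(dialect, dialect)
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_table(path: str | Path, required: Sequence[str], dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_separator(path, dialect), dtype=str, keep_default_na=False)
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return frame


def read_sample_metadata(path: str | Path, dialect: str | None = None) -> list[SurveySample]:
    """Read the sample-metadata table (one row per soil sample).

    Extra columns beyond the required schema are preserved verbatim in
    ``SurveySample.annotations``. Row order follows the file.
    """
    frame = _read_table(path, SAMPLE_COLUMNS, dialect)
    extra = [c for c in frame.columns if c not in SAMPLE_COLUMNS]
    samples: list[SurveySample] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        record = row._asdict()
        sample_id = record["sample_id"]
        if sample_id in seen:
            raise IntegrityError(f"duplicate sample_id {sample_id!r} in {path}")
        seen.add(sample_id)
        try:
            colonies = int(record["total_fungal_colonies"])
        except ValueError as exc:
            raise ValidationError(
                f"sample {sample_id!r}: total_fungal_colonies "
                f"{record['total_fungal_colonies']!r} is not an integer"
            ) from exc
        samples.append(
            SurveySample(
                sample_id=sample_id,
                region=record["region"],
                province=record["province"],
                climate_zone=record["climate_zone"],
                season=record["season"],
                crop=record["crop"],
                total_fungal_colonies=colonies,
                annotations={k: record[k] for k in extra},
            )
        )
    logger.info("read %d samples from %s", len(samples), path)
    return samples


def write_sample_metadata(samples: Sequence[SurveySample], path: str | Path,
                          dialect: str | None = None) -> None:
    extra = sorted({k for s in samples for k in s.annotations})
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "region": s.region,
            "province": s.province,
            "climate_zone": s.climate_zone,
            "season": s.season,
            "crop": s.crop,
            "total_fungal_colonies": s.total_fungal_colonies,
        }
        row.update({k: s.annotations.get(k, "") for k in extra})
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS) + extra)
    frame.to_csv(path, sep=_separator(path, dialect), index=False)


def read_isolate_table(path: str | Path, dialect: str | None = None) -> list[IsolateRecord]:
    """Read the isolate table. Empty ``species``/``haplotype_code`` cells
    mean "unassigned" and are returned as ``None``."""
    frame = _read_table(path, ISOLATE_COLUMNS, dialect)
    has_hap = "haplotype_code" in frame.columns
    isolates: list[IsolateRecord] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        record = row._asdict()
        isolate_id = record["isolate_id"]
        if isolate_id in seen:
            raise IntegrityError(f"duplicate isolate_id {isolate_id!r} in {path}")
        seen.add(isolate_id)
        isolates.append(
            IsolateRecord(
                isolate_id=isolate_id,
                sample_id=record["sample_id"],
                species=record["species"] or None,
                sequence_id=record["sequence_id"],
                haplotype_code=(record["haplotype_code"] or None) if has_hap else None,
            )
        )
    logger.info("read %d isolates from %s", len(isolates), path)
    return isolates


def write_isolate_table(isolates: Sequence[IsolateRecord], path: str | Path,
                        dialect: str | None = None) -> None:
    frame = pd.DataFrame(
        [
            {
                "isolate_id": i.isolate_id,
                "sample_id": i.sample_id,
                "species": i.species or "",
                "sequence_id": i.sequence_id,
                "haplotype_code": i.haplotype_code or "",
            }
            for i in isolates
        ],
        columns=list(ISOLATE_COLUMNS) + ["haplotype_code"],
    )
    frame.to_csv(path, sep=_separator(path, dialect), index=False)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_aligned_fasta(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned multi-FASTA; ids are the header up to the first
    whitespace; all sequences must have equal length."""
    path = Path(path)
    entries: dict[str, str] = {}
    length: int | None = None
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if record.id in entries:
            raise IntegrityError(f"duplicate sequence id {record.id!r} in {path}")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"{path}: sequence {record.id!r} has length {len(seq)}, "
                f"previous records have length {length}"
            )
        for pos, ch in enumerate(seq):
            if ch not in ALLOWED_CHARS:
                raise ValidationError(
                    f"{path}: sequence {record.id!r} has illegal character "
                    f"{ch!r} at position {pos}"
                )
        entries[record.id] = seq
    logger.info("read %d aligned sequences from %s", len(entries), path)
    return AlignedSequenceSet(entries=entries, alignment_length=length or 0)


def write_aligned_fasta(seqs: AlignedSequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in seqs.entries.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Haplotype table I/O (format owned here; the type lives in haplotype_collapse)
# ---------------------------------------------------------------------------


def write_haplotype_table(table, path: str | Path) -> None:
    """Write a haplotype table as TSV, rows sorted by (species, code).

    The columns-compared list is kept in a leading ``#`` comment so that a
    re-read reconstructs the identical object.
    """
    from .haplotype_collapse import HaplotypeTable  # deferred: avoids cycle

    if not isinstance(table, HaplotypeTable):
        raise TypeError("write_haplotype_table expects a HaplotypeTable")
    rows = sorted(table.rows, key=lambda r: (r.species, r.haplotype_code))
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("# columns_used=" + ";".join(str(c) for c in table.columns_used) + "\n")
        handle.write("haplotype_code\tspecies\tn_isolates\trepresentative_id\tmember_ids\n")
        for row in rows:
            handle.write(
                f"{row.haplotype_code}\t{row.species}\t{row.n_isolates}\t"
                f"{row.representative_id}\t{';'.join(row.member_ids)}\n"
            )
    logger.info("wrote %d haplotypes to %s", len(rows), path)


def read_haplotype_table(path: str | Path):
    from .haplotype_collapse import HaplotypeRow, HaplotypeTable

    path = Path(path)
    columns_used: list[int] = []
    rows: list = []
    with open(path) as handle:
        lines = handle.read().splitlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("# columns_used="):
            spec = line.split("=", 1)[1]
            columns_used = [int(tok) for tok in spec.split(";") if tok != ""]
        elif line.strip():
            body.append(line)
    if not body:
        raise FormatError(f"{path}: empty haplotype table")
    header = body[0].split("\t")
    expected = ["haplotype_code", "species", "n_isolates", "representative_id", "member_ids"]
    if header != expected:
        raise FormatError(f"{path}: expected columns {expected}, found {header}")
    for line in body[1:]:
        code, species, n_str, rep, members = line.split("\t")
        member_ids = [m for m in members.split(";") if m != ""]
        n = int(n_str)
        if n != len(member_ids):
            raise IntegrityError(
                f"{path}: haplotype {code!r} declares {n} isolates but lists "
                f"{len(member_ids)} members"
            )
        rows.append(
            HaplotypeRow(
                haplotype_code=code,
                species=species,
                member_ids=member_ids,
                n_isolates=n,
                representative_id=rep,
            )
        )
    return HaplotypeTable(rows=rows, columns_used=columns_used)


# ---------------------------------------------------------------------------
# Whole-survey loading with referential integrity
# ---------------------------------------------------------------------------


def attach_isolates(samples: Sequence[SurveySample], isolates: Sequence[IsolateRecord]) -> None:
    """Fill each sample's ``isolate_ids`` from the isolate table, rejecting
    dangling sample references and isolate counts above the colony count."""
    by_id = {s.sample_id: s for s in samples}
    if len(by_id) != len(samples):
        raise IntegrityError("duplicate sample ids")
    for s in samples:
        s.isolate_ids = []
    for isolate in isolates:
        sample = by_id.get(isolate.sample_id)
        if sample is None:
            raise IntegrityError(
                f"isolate {isolate.isolate_id!r} references unknown sample "
                f"{isolate.sample_id!r}"
            )
        sample.isolate_ids.append(isolate.isolate_id)
    for s in samples:
        if len(s.isolate_ids) > s.total_fungal_colonies:
            raise IntegrityError(
                f"sample {s.sample_id!r} has {len(s.isolate_ids)} isolates but only "
                f"{s.total_fungal_colonies} total fungal colonies"
            )


def load_survey(
    samples_path: str | Path,
    isolates_path: str | Path,
    fasta_path: str | Path | None = None,
    dialect: str | None = None,
) -> tuple[list[SurveySample], list[IsolateRecord], AlignedSequenceSet | None]:
    """Load and cross-validate a full survey. Every isolate must resolve to
    a sample, and (when a FASTA is given) to an aligned sequence."""
    samples = read_sample_metadata(samples_path, dialect)
    isolates = read_isolate_table(isolates_path, dialect)
    attach_isolates(samples, isolates)
    seqs: AlignedSequenceSet | None = None
    if fasta_path is not None:
        seqs = read_aligned_fasta(fasta_path)
        for isolate in isolates:
            if isolate.sequence_id not in seqs.entries:
                raise IntegrityError(
                    f"isolate {isolate.isolate_id!r} references unknown sequence "
                    f"{isolate.sequence_id!r}"
                )
    return samples, isolates, seqs


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")
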