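"""Collapse aligned ITS marker sequences into haplotypes.

Two isolates share a haplotype when their aligned sequences are identical on
the set of alignment columns selected by the gap policy. Under the default
``exclude_columns`` policy every column containing a gap or an ambiguity
code in *any* sequence is dropped before comparison — the conventional
treatment of gapped/missing sites in haplotype callers — so indel-only
variation never splits a haplotype. The ``literal`` policy compares every
column character-by-character instead.

Collapsing is performed within species groups: haplotype codes are scoped
to a species (e.g. ``harz1``, ``harz2`` for *T. harzianum*), numbered by
order of first appearance in the input, with the first member in input
order acting as the representative strain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .survey_io import (
    AlignedSequenceSet,
    DomainError,
    GapPolicy,
    ValidationError,
    _as_gap_policy,
    NUCLEOTIDES,
)

__all__ = [
    "HaplotypeRow",
    "HaplotypeTable",
    "select_columns",
    "collapse_haplotypes",
    "haplotype_spectrum",
    "species_abbreviations",
]


@dataclass
class HaplotypeRow:
    haplotype_code: str
    species: str
    member_ids: list[str]
    n_isolates: int
    representative_id: str

    def __post_init__(self) -> None:
        if self.n_isolates != len(self.member_ids):
            raise ValidationError(
                f"haplotype {self.haplotype_code!r}: n_isolates={self.n_isolates} "
                f"but {len(self.member_ids)} members listed"
            )
        if self.representative_id not in self.member_ids:
            raise ValidationError(
                f"haplotype {self.haplotype_code!r}: representative "
                f"{self.representative_id!r} is not a member"
            )


@dataclass
class HaplotypeTable:
    """The haplotype inventory of a survey: one row per haplotype, plus the
    alignment columns that were actually compared."""

    rows: list[HaplotypeRow]
    columns_used: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def species_list(self) -> list[str]:
        seen: dict[str, None] = {}
        for row in self.rows:
            seen.setdefault(row.species, None)
        return list(seen)

    def partition(self) -> list[frozenset]:
        """Membership as a partition (set of frozensets of sequence ids)."""
        return [frozenset(row.member_ids) for row in self.rows]

    def species_of_code(self) -> dict[str, str]:
        return {row.haplotype_code: row.species for row in self.rows}

    def counts(self) -> dict[str, int]:
        return {row.haplotype_code: row.n_isolates for row in self.rows}

    def total_isolates(self) -> int:
        return sum(row.n_isolates for row in self.rows)


# ---------------------------------------------------------------------------
# Column selection
# ---------------------------------------------------------------------------


def _char_matrix(seqs: AlignedSequenceSet) -> np.ndarray:
    """Sequences as a (n, L) uint8 matrix of ASCII codes."""
    return np.frombuffer(
        "".join(seqs.entries.values()).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqs.entries), seqs.alignment_length)


_UNAMBIGUOUS_CODES = np.frombuffer("".join(sorted(NUCLEOTIDES)).encode(), dtype=np.uint8)


def select_columns(seqs: AlignedSequenceSet, gap_policy: GapPolicy | str) -> list[int]:
    """Alignment columns to compare under the given gap policy (0-based,
    ascending). ``exclude_columns`` keeps only columns where every sequence
    has an unambiguous base (A/C/G/T); ``literal`` keeps all columns."""
    gap_policy = _as_gap_policy(gap_policy)
    if len(seqs) == 0:
        raise DomainError("cannot select columns of an empty sequence set")
    if gap_policy is GapPolicy.LITERAL:
        return list(range(seqs.alignment_length))
    matrix = _char_matrix(seqs)
    clean = np.isin(matrix, _UNAMBIGUOUS_CODES).all(axis=0)
    return np.flatnonzero(clean).tolist()


# ---------------------------------------------------------------------------
# Species code abbreviations
# ---------------------------------------------------------------------------


def species_abbreviations(species_names: Sequence[str]) -> dict[str, str]:
    """Deterministic short codes per species, from the specific epithet.

    The epithet (last word of the label) is lowercased, stripped of
    non-letters and truncated to four characters; on collision the prefix is
    extended until unique (order of extension follows input order).
    Unassigned species (``None``) map to ``'unid'``.
    """
    out: dict[str, str] = {}
    taken: set[str] = set()
    for name in species_names:
        if name in out:
            continue
        epithet = re.sub(r"[^a-z]", "", (name or "unidentified").split()[-1].lower()) or "sp"
        n = min(4, len(epithet))
        abbrev = epithet[:n]
        while abbrev in taken and n < len(epithet):
            n += 1
            abbrev = epithet[:n]
        if abbrev in taken:  # identical epithets: fall back to numbering
            k = 2
            while f"{abbrev}{k}x" in taken:
                k += 1
            abbrev = f"{abbrev}{k}x"
        taken.add(abbrev)
        out[name] = abbrev
    return out


# ---------------------------------------------------------------------------
# Collapsing
# ---------------------------------------------------------------------------


def collapse_haplotypes(
    seqs: AlignedSequenceSet,
    species_of: Mapping[str, str],
    gap_policy: GapPolicy | str = GapPolicy.EXCLUDE_COLUMNS,
) -> HaplotypeTable:
    """Partition sequences into haplotypes within species groups.

    Parameters
    ----------
    seqs
        The aligned sequences, one per isolate.
    species_of
        Map sequence id -> species label; every id must be present.
    gap_policy
        Column selection rule; see :class:`~trichosurvey.survey_io.GapPolicy`.

    Returns
    -------
    HaplotypeTable
        Rows in order of first appearance (species first seen, then
        haplotype first seen within species); the representative of each
        haplotype is its first member in input order.
    """
    gap_policy = _as_gap_policy(gap_policy)
    if len(seqs) == 0:
        raise DomainError("cannot collapse an empty sequence set")
    missing = [sid for sid in seqs.entries if sid not in species_of]
    if missing:
        raise ValidationError(
            f"{len(missing)} sequence id(s) without a species label, e.g. {missing[0]!r}"
        )
    columns = select_columns(seqs, gap_policy)
    matrix = _char_matrix(seqs)
    projected = matrix[:, columns] if columns else matrix[:, :0]

    ids = list(seqs.entries)
    species_order: dict[str, dict[bytes, list[str]]] = {}
    for i, seq_id in enumerate(ids):
        species = species_of[seq_id]
        groups = species_order.setdefault(species, {})
        groups.setdefault(projected[i].tobytes(), []).append(seq_id)

    abbrevs = species_abbreviations(list(species_order))
    rows: list[HaplotypeRow] = []
    for species, groups in species_order.items():
        for ordinal, members in enumerate(groups.values(), start=1):
            rows.append(
                HaplotypeRow(
                    haplotype_code=f"{abbrevs[species]}{ordinal}",
                    species=species,
                    member_ids=list(members),
                    n_isolates=len(members),
                    representative_id=members[0],
                )
            )
    return HaplotypeTable(rows=rows, columns_used=columns)


def haplotype_spectrum(table: HaplotypeTable, species: str) -> list[tuple[str, int]]:
    """The (haplotype code, isolate count) spectrum of one species, in table
    order; empty if the species is absent."""
    return [
        (row.haplotype_code, row.n_isolates) for row in table.rows if row.species == species
    ]
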