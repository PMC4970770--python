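"""Community statistics for culture-based surveys.

The centrepiece is the dominance index

    Y = (n_i / N) * f_i

where ``n_i`` is the isolate count of taxon *i*, ``N`` the total strain
count at the chosen level, and ``f_i`` the frequency of occurrence — the
proportion of soil samples in which taxon *i* was recovered at least once.
A taxon is called *dominant* when Y exceeds a threshold, strictly
(default 0.02). At genus level N is the total fungal colony count of the
survey; at species or haplotype level N is the genus isolate count, so Y
combines a taxon's share of the community with how widespread it is.

Also here: the Shannon–Wiener index H' = -sum p_i log p_i over haplotype
(or species) counts, isolation and relative rates, and stratified abundance
and relative-frequency tables by province / season / crop / region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .survey_io import (
    DomainError,
    IntegrityError,
    IsolateRecord,
    SurveySample,
    ValidationError,
)

__all__ = [
    "GENUS",
    "DominanceResult",
    "AbundanceTable",
    "frequency_of_occurrence",
    "dominance_index",
    "classify_dominant",
    "shannon_wiener",
    "isolation_rate",
    "relative_rate",
    "build_abundance_table",
    "relative_frequencies",
    "dominance_profile",
    "diversity_profile",
    "format_percent",
    "write_dominance_results",
]

#: Sentinel taxon label for genus-level statistics (any target-genus isolate).
GENUS = "genus"

_LEVELS = ("genus", "species", "haplotype")
_STRATIFIERS = ("province", "season", "crop", "region")


@dataclass
class DominanceResult:
    """Dominance of one taxon within one scope.

    ``Y == (n_i / N) * f_i`` exactly (no display rounding), and
    ``is_dominant == (Y > threshold)`` with a strict inequality.
    """

    taxon: str
    n_i: int
    N: int
    f_i: float
    Y: float
    is_dominant: bool
    level: str = "species"
    scope: str = "survey"


@dataclass
class AbundanceTable:
    """Counts of isolates per stratum (rows) and taxon (columns), plus the
    sample ids backing each stratum."""

    strata: list[str]
    taxa: list[str]
    counts: np.ndarray
    sample_index: dict[str, set[str]]
    stratifier: str = ""
    level: str = "species"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.strata), len(self.taxa)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.strata)} strata x {len(self.taxa)} taxa"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts in abundance table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.strata, columns=self.taxa)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def _taxon_label(isolate: IsolateRecord, level: str) -> str | None:
    if level == "species":
        return isolate.species
    if level == "haplotype":
        return isolate.haplotype_code
    return GENUS


def _isolates_by_sample(isolates: Iterable[IsolateRecord]) -> dict[str, list[IsolateRecord]]:
    index: dict[str, list[IsolateRecord]] = {}
    for isolate in isolates:
        index.setdefault(isolate.sample_id, []).append(isolate)
    return index


def frequency_of_occurrence(
    taxon: str | None,
    samples: Sequence[SurveySample],
    isolates: Sequence[IsolateRecord],
    level: str | None = None,
) -> float:
    """Proportion of samples containing at least one isolate of ``taxon``.

    ``taxon=None`` (or ``level='genus'``) counts any target-genus isolate.
    ``level`` is ``'species'`` (default when a taxon is given) or
    ``'haplotype'``.
    """
    if not samples:
        raise DomainError("frequency_of_occurrence over an empty sample list")
    if level is None:
        level = "genus" if taxon is None or taxon == GENUS else "species"
    if level not in _LEVELS:
        raise ValidationError(f"level must be one of {_LEVELS}, got {level!r}")
    index = _isolates_by_sample(isolates)
    positive = 0
    for sample in samples:
        group = index.get(sample.sample_id, ())
        if level == "genus":
            hit = len(group) > 0
        else:
            hit = any(_taxon_label(i, level) == taxon for i in group)
        positive += hit
    return positive / len(samples)


def dominance_index(n_i: int, N: int, f_i: float) -> float:
    """Y = (n_i / N) * f_i, exact (no rounding)."""
    if N <= 0:
        raise DomainError(f"total strain count N must be positive, got {N}")
    if n_i < 0 or n_i > N:
        raise ValidationError(f"taxon count n_i={n_i} outside [0, N={N}]")
    if not 0.0 <= f_i <= 1.0:
        raise ValidationError(f"frequency of occurrence f_i={f_i} outside [0, 1]")
    return (n_i / N) * f_i


def classify_dominant(Y: float, threshold: float = 0.02) -> bool:
    """Strict rule: dominant iff Y > threshold."""
    if threshold <= 0:
        raise ValidationError(f"dominance threshold must be > 0, got {threshold}")
    return Y > threshold


_LOG_BASE = {"e": None, "2": 2.0, "10": 10.0, 2: 2.0, 10: 10.0}


def shannon_wiener(counts: Sequence[float], log_base: str | int = "e") -> float:
    """Shannon–Wiener index H' = -sum p_i log p_i over nonzero categories.

    ``counts`` are raw counts (normalised internally); zero-count
    categories do not contribute. Natural log by default; base 2 or 10 on
    request.
    """
    if log_base not in _LOG_BASE:
        raise ValidationError(f"log base must be 'e', 2 or 10, got {log_base!r}")
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("counts must be a 1-D vector")
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if arr.sum() <= 0:
        raise DomainError("Shannon–Wiener index of an all-zero count vector")
    base = _LOG_BASE[log_base]
    return float(_scipy_entropy(arr, base=base))


def isolation_rate(samples: Sequence[SurveySample], isolates: Sequence[IsolateRecord]) -> float:
    """Fraction of samples yielding at least one target-genus isolate."""
    return frequency_of_occurrence(None, samples, isolates, level="genus")


def relative_rate(n_isolates: int, n_colonies: int) -> float:
    """Fraction of all fungal colonies that are the target genus."""
    if n_colonies <= 0:
        raise DomainError(f"colony count must be positive, got {n_colonies}")
    if n_isolates < 0 or n_isolates > n_colonies:
        raise ValidationError(
            f"isolate count {n_isolates} outside [0, colonies={n_colonies}]"
        )
    return n_isolates / n_colonies


def format_percent(fraction: float) -> str:
    """Display helper: 0.7557... -> '76%' (integer percent, half-up-free
    round-to-even as printed in survey reports)."""
    return f"{round(fraction * 100):.0f}%"


# ---------------------------------------------------------------------------
# Stratified tables
# ---------------------------------------------------------------------------


def build_abundance_table(
    samples: Sequence[SurveySample],
    isolates: Sequence[IsolateRecord],
    stratifier: str = "province",
    level: str = "species",
) -> AbundanceTable:
    """Isolate counts per stratum and taxon.

    Isolates whose taxon is unassigned at the requested level (no species
    call, or no haplotype code) are excluded from the table; they still
    count toward genus-level totals elsewhere.
    """
    if stratifier not in _STRATIFIERS:
        raise ValidationError(f"stratifier must be one of {_STRATIFIERS}, got {stratifier!r}")
    if level not in ("species", "haplotype"):
        raise ValidationError(f"level must be 'species' or 'haplotype', got {level!r}")
    sample_by_id = {s.sample_id: s for s in samples}
    strata: list[str] = sorted({getattr(s, stratifier) for s in samples})
    sample_index: dict[str, set[str]] = {
        label: {s.sample_id for s in samples if getattr(s, stratifier) == label}
        for label in strata
    }
    taxa = sorted(
        {t for i in isolates if (t := _taxon_label(i, level)) is not None}
    )
    stratum_pos = {label: k for k, label in enumerate(strata)}
    taxon_pos = {label: k for k, label in enumerate(taxa)}
    counts = np.zeros((len(strata), len(taxa)), dtype=int)
    for isolate in isolates:
        sample = sample_by_id.get(isolate.sample_id)
        if sample is None:
            raise IntegrityError(
                f"isolate {isolate.isolate_id!r} references unknown sample "
                f"{isolate.sample_id!r}"
            )
        taxon = _taxon_label(isolate, level)
        if taxon is None:
            continue
        counts[stratum_pos[getattr(sample, stratifier)], taxon_pos[taxon]] += 1
    return AbundanceTable(
        strata=strata,
        taxa=taxa,
        counts=counts,
        sample_index=sample_index,
        stratifier=stratifier,
        level=level,
    )


def relative_frequencies(table: AbundanceTable) -> tuple[pd.DataFrame, list[str]]:
    """Row-normalised frequencies of an abundance table.

    Returns the frequency matrix (strata x taxa) and the list of strata
    whose row sum is zero; those rows are left as NaN and flagged in the
    second return value rather than silently propagated.
    """
    counts = table.counts.astype(float)
    sums = counts.sum(axis=1)
    freqs = np.full_like(counts, np.nan)
    defined = sums > 0
    freqs[defined] = counts[defined] / sums[defined, None]
    undefined = [label for label, ok in zip(table.strata, defined) if not ok]
    return pd.DataFrame(freqs, index=table.strata, columns=table.taxa), undefined


# ---------------------------------------------------------------------------
# Dominance and diversity profiles
# ---------------------------------------------------------------------------

ScopeSpec = "None | tuple[str, str] | Callable[[SurveySample], bool]"


def _apply_scope(samples: Sequence[SurveySample], scope) -> tuple[list[SurveySample], str]:
    if scope is None:
        return list(samples), "survey"
    if callable(scope):
        return [s for s in samples if scope(s)], getattr(scope, "__name__", "custom")
    field_name, value = scope
    if field_name not in _STRATIFIERS + ("climate_zone",):
        raise ValidationError(f"unknown scope field {field_name!r}")
    return [s for s in samples if getattr(s, field_name) == value], f"{field_name}={value}"


def dominance_profile(
    samples: Sequence[SurveySample],
    isolates: Sequence[IsolateRecord],
    level: str = "species",
    scope=None,
    threshold: float = 0.02,
) -> list[DominanceResult]:
    """Dominance results for every taxon present in the scope.

    Scope is the whole survey (``None``), a ``(field, value)`` pair such as
    ``("province", "Zhejiang")``, or a sample predicate. Within the scope,
    species/haplotype level uses N = total genus isolates there; genus
    level uses N = total fungal colonies there. Results are sorted by Y
    descending, ties broken by taxon name.
    """
    scoped, scope_label = _apply_scope(samples, scope)
    if not scoped:
        raise DomainError(f"scope {scope!r} selects no samples")
    if level not in _LEVELS:
        raise ValidationError(f"level must be one of {_LEVELS}, got {level!r}")
    ids = {s.sample_id for s in scoped}
    scoped_isolates = [i for i in isolates if i.sample_id in ids]

    results: list[DominanceResult] = []
    if level == "genus":
        N = sum(s.total_fungal_colonies for s in scoped)
        if N <= 0:
            raise DomainError(f"scope {scope_label}: zero fungal colonies")
        n_i = len(scoped_isolates)
        f_i = isolation_rate(scoped, scoped_isolates)
        Y = dominance_index(n_i, N, f_i)
        results.append(
            DominanceResult(GENUS, n_i, N, f_i, Y, classify_dominant(Y, threshold),
                            level, scope_label)
        )
    else:
        N = len(scoped_isolates)
        taxa = sorted(
            {t for i in scoped_isolates if (t := _taxon_label(i, level)) is not None}
        )
        for taxon in taxa:
            n_i = sum(_taxon_label(i, level) == taxon for i in scoped_isolates)
            f_i = frequency_of_occurrence(taxon, scoped, scoped_isolates, level=level)
            Y = dominance_index(n_i, N, f_i)
            results.append(
                DominanceResult(taxon, n_i, N, f_i, Y,
                                classify_dominant(Y, threshold), level, scope_label)
            )
    results.sort(key=lambda r: (-r.Y, r.taxon))
    return results


def diversity_profile(
    samples: Sequence[SurveySample],
    isolates: Sequence[IsolateRecord],
    level: str = "haplotype",
    by: str | None = None,
    log_base: str | int = "e",
) -> pd.DataFrame:
    """Shannon–Wiener index per stratum (or whole survey when ``by`` is
    None): columns scope, level, H, k (number of observed categories)."""
    rows = []
    if by is None:
        groups: list[tuple[str, list[SurveySample]]] = [("survey", list(samples))]
    else:
        table_strata = sorted({getattr(s, by) for s in samples})
        groups = [
            (f"{by}={label}", [s for s in samples if getattr(s, by) == label])
            for label in table_strata
        ]
    index = _isolates_by_sample(isolates)
    for scope_label, group in groups:
        counts: dict[str, int] = {}
        for sample in group:
            for isolate in index.get(sample.sample_id, ()):
                taxon = _taxon_label(isolate, level)
                if taxon is not None:
                    counts[taxon] = counts.get(taxon, 0) + 1
        if counts:
            h = shannon_wiener(list(counts.values()), log_base)
        else:
            h = math.nan
        rows.append({"scope": scope_label, "level": level, "H": h, "k": len(counts)})
    return pd.DataFrame(rows, columns=["scope", "level", "H", "k"])


def write_dominance_results(results: Sequence[DominanceResult], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "level": r.level,
                "scope": r.scope,
                "n_i": r.n_i,
                "N": r.N,
                "f_i": r.f_i,
                "Y": r.Y,
                "is_dominant": r.is_dominant,
            }
            for r in results
        ]
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
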