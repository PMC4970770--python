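"""Multiple correspondence analysis of sampling regions.

Regions are crossed with categorical descriptors — presence/absence of
selected haplotypes, season, crop — in a 0/1 indicator matrix, and the
chi-square-scaled deviations from row/column independence are decomposed by
SVD. With correspondence matrix P = X / n, row masses r and column masses
c, the standardised residuals are

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2},    S = U Sigma V^T,

principal coordinates F = D_r^{-1/2} U Sigma (rows) and
G = D_c^{-1/2} V Sigma (columns); each axis's inertia is its squared
singular value and the total inertia equals chi^2 / n of the input table.
Centring on r c^T removes the trivial constant dimension up front, so every
reported axis is informative. The biplot reading is the usual one: the
closer two points, the more similar their profiles.

Implemented from scratch on numpy's SVD — the decomposition is the point
of the module, not a wrapped third-party fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survey_io import (
    CROPS,
    DegenerateInputError,
    IsolateRecord,
    SEASONS,
    SurveySample,
    ValidationError,
    write_json,
)

logger = logging.getLogger("trichosurvey")

__all__ = [
    "IndicatorMatrix",
    "CAResult",
    "build_indicator_matrix",
    "correspondence_analysis",
    "distance_to_category",
    "zone_centroids",
    "mca_expected_inertia",
    "write_ca_result",
]


@dataclass
class IndicatorMatrix:
    """A 0/1 coding of rows (regions, or region x season x crop units)
    against category columns. ``variables`` maps each coded variable to its
    category column labels, which is what makes the disjunctive-coding
    invariant and the classical MCA inertia identity checkable."""

    row_labels: list[str]
    column_labels: list[str]
    Z: np.ndarray
    coding: str = "indicator"
    variables: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z)
        if self.Z.shape != (len(self.row_labels), len(self.column_labels)):
            raise ValidationError(
                f"indicator matrix shape {self.Z.shape} does not match labels"
            )
        if not np.isin(self.Z, (0, 1)).all():
            raise ValidationError("indicator matrix cells must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, index=self.row_labels, columns=self.column_labels)

    def to_burt(self) -> pd.DataFrame:
        """The Burt matrix Z^T Z (categories x categories)."""
        burt = self.Z.T @ self.Z
        return pd.DataFrame(burt, index=self.column_labels, columns=self.column_labels)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def is_fully_disjunctive(self) -> bool:
        """True when every variable's category columns sum to 1 in every row."""
        cols = {label: k for k, label in enumerate(self.column_labels)}
        for labels in self.variables.values():
            block = self.Z[:, [cols[c] for c in labels]]
            if not (block.sum(axis=1) == 1).all():
                return False
        return True


@dataclass
class CAResult:
    """Principal coordinates and inertia decomposition of a CA.

    ``singular_values``/``axis_inertia`` cover the full non-trivial
    spectrum (so the inertias sum to ``total_inertia``); coordinates are
    retained for the first ``n_axes`` of them.
    """

    row_labels: list[str]
    col_labels: list[str]
    row_coords: np.ndarray
    col_coords: np.ndarray
    singular_values: np.ndarray
    axis_inertia: np.ndarray
    total_inertia: float
    row_masses: np.ndarray
    col_masses: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.row_coords.shape[1]

    def row_coord(self, label: str) -> np.ndarray:
        try:
            return self.row_coords[self.row_labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown row label {label!r}") from None

    def col_coord(self, label: str) -> np.ndarray:
        try:
            return self.col_coords[self.col_labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown column label {label!r}") from None


# ---------------------------------------------------------------------------
# Indicator coding
# ---------------------------------------------------------------------------

_FACTOR_CATEGORIES = {"season": SEASONS, "crop": CROPS}


def build_indicator_matrix(
    samples: Sequence[SurveySample],
    isolates: Sequence[IsolateRecord],
    haplotypes: Sequence[str],
    factors: Sequence[str] = (),
    row_mode: str = "region",
    haplotype_assignments: Mapping[str, str] | None = None,
) -> IndicatorMatrix:
    """Code regions against haplotype presence (and optional factors).

    Each requested haplotype becomes a two-category variable
    ``<code>:present`` / ``<code>:absent``, coded per row by whether any
    isolate of that haplotype was recovered there.

    ``row_mode='region'`` gives one row per region (rows sorted by label);
    factor categories are then coded by presence in the region's sampling
    records (a region sampled in two seasons carries both season columns).
    ``row_mode='region-season-crop'`` gives one row per observed
    region/season/crop sampling unit, in which case factor variables are
    single-valued and the coding is fully disjunctive.

    ``haplotype_assignments`` (isolate id -> haplotype code) overrides the
    codes stored on the isolate records.
    """
    if row_mode not in ("region", "region-season-crop"):
        raise ValidationError(f"unknown row_mode {row_mode!r}")
    for factor in factors:
        if factor not in _FACTOR_CATEGORIES:
            raise ValidationError(f"unknown factor {factor!r}; expected season/crop")
    hap_of: dict[str, str | None] = {
        i.isolate_id: (haplotype_assignments or {}).get(i.isolate_id, i.haplotype_code)
        for i in isolates
    }
    known = {code for code in hap_of.values() if code is not None}
    unknown = [h for h in haplotypes if h not in known]
    if unknown:
        raise ValidationError(
            f"requested haplotype(s) absent from the survey: {', '.join(unknown)}"
        )

    sample_by_id = {s.sample_id: s for s in samples}

    def row_key(sample: SurveySample) -> str:
        if row_mode == "region":
            return sample.region
        return f"{sample.region}|{sample.season}|{sample.crop}"

    row_labels = sorted({row_key(s) for s in samples})
    row_pos = {label: k for k, label in enumerate(row_labels)}

    # haplotype presence per row
    present = {h: set() for h in haplotypes}
    for isolate in isolates:
        code = hap_of[isolate.isolate_id]
        if code in present:
            sample = sample_by_id.get(isolate.sample_id)
            if sample is None:
                raise ValidationError(
                    f"isolate {isolate.isolate_id!r} references unknown sample "
                    f"{isolate.sample_id!r}"
                )
            present[code].add(row_key(sample))

    column_labels: list[str] = []
    variables: dict[str, list[str]] = {}
    blocks: list[np.ndarray] = []
    n_rows = len(row_labels)

    for hap in haplotypes:
        labels = [f"{hap}:present", f"{hap}:absent"]
        block = np.zeros((n_rows, 2), dtype=int)
        for label in present[hap]:
            block[row_pos[label], 0] = 1
        block[:, 1] = 1 - block[:, 0]
        column_labels += labels
        variables[hap] = labels
        blocks.append(block)

    for factor in factors:
        categories = _FACTOR_CATEGORIES[factor]
        labels = [f"{factor}:{cat}" for cat in categories]
        block = np.zeros((n_rows, len(categories)), dtype=int)
        for sample in samples:
            value = getattr(sample, factor)
            block[row_pos[row_key(sample)], categories.index(value)] = 1
        column_labels += labels
        variables[factor] = labels
        blocks.append(block)

    Z = np.hstack(blocks) if blocks else np.zeros((n_rows, 0), dtype=int)
    # drop all-zero category columns (e.g. a crop never sampled) so CA sees
    # no zero margins; the variable keeps its remaining categories
    keep = Z.sum(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(column_labels, keep) if not k]
        logger.info("dropping empty categories: %s", ", ".join(dropped))
        Z = Z[:, keep]
        column_labels = [c for c, k in zip(column_labels, keep) if k]
        variables = {
            v: [c for c in cats if c in set(column_labels)] for v, cats in variables.items()
        }
    return IndicatorMatrix(
        row_labels=row_labels,
        column_labels=column_labels,
        Z=Z,
        coding="indicator",
        variables=variables,
    )


def mca_expected_inertia(n_categories: int, n_variables: int) -> float:
    """Classical identity for a fully disjunctive indicator matrix with Q
    variables and J categories in total: total inertia = (J - Q) / Q."""
    if n_variables <= 0:
        raise ValidationError("need at least one variable")
    return (n_categories - n_variables) / n_variables


# ---------------------------------------------------------------------------
# The decomposition
# ---------------------------------------------------------------------------

_SV_TOL = 1e-12


def _ca_core(
    X: np.ndarray, row_labels: list[str], col_labels: list[str], n_axes: int
) -> CAResult:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DegenerateInputError("correspondence analysis needs a table of at least 2x2")
    if (X < 0).any():
        raise ValidationError("correspondence analysis input must be non-negative")
    n = X.sum()
    if n <= 0:
        raise DegenerateInputError("correspondence analysis input has zero grand total")
    r = X.sum(axis=1) / n
    c = X.sum(axis=0) / n
    for mass, labels, side in ((r, row_labels, "row"), (c, col_labels, "column")):
        zero = np.flatnonzero(mass == 0)
        if zero.size:
            raise DegenerateInputError(f"zero {side} margin for {labels[zero[0]]!r}")
    P = X / n
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    tol = _SV_TOL * max(1.0, sv[0] if sv.size else 0.0)
    keep = sv > tol
    sv = sv[keep]
    U = U[:, keep]
    Vt = Vt[keep]
    k = min(n_axes, sv.size)

    F = (U[:, :k] * sv[:k]) / np.sqrt(r)[:, None]
    G = (Vt[:k].T * sv[:k]) / np.sqrt(c)[:, None]
    # deterministic sign: largest-magnitude column coordinate positive per axis
    for axis in range(k):
        pivot = np.argmax(np.abs(G[:, axis]))
        if G[pivot, axis] < 0:
            G[:, axis] *= -1
            F[:, axis] *= -1

    return CAResult(
        row_labels=list(row_labels),
        col_labels=list(col_labels),
        row_coords=F,
        col_coords=G,
        singular_values=sv,
        axis_inertia=sv**2,
        total_inertia=float((S**2).sum()),
        row_masses=r,
        col_masses=c,
    )


def correspondence_analysis(
    table: "IndicatorMatrix | pd.DataFrame | np.ndarray",
    n_axes: int = 2,
    coding: str | None = None,
) -> CAResult:
    """Correspondence analysis of a count/indicator table.

    ``table`` may be an :class:`IndicatorMatrix`, a labelled DataFrame or a
    bare array (labels autogenerated). For an indicator matrix,
    ``coding='burt'`` analyses the Burt matrix Z^T Z instead of Z itself
    (rows of the result are then categories, not regions). At most
    ``min(n_axes, rank)`` axes of coordinates are returned; axes are
    ordered by decreasing singular value, and the trivial constant
    dimension is never reported.
    """
    if n_axes < 1:
        raise ValidationError(f"n_axes must be >= 1, got {n_axes}")
    if isinstance(table, IndicatorMatrix):
        if (coding or table.coding) == "burt":
            burt = table.to_burt()
            return _ca_core(
                burt.to_numpy(), list(burt.index), list(burt.columns), n_axes
            )
        return _ca_core(table.Z, table.row_labels, table.column_labels, n_axes)
    if coding == "burt":
        raise ValidationError("burt coding requires an IndicatorMatrix input")
    if isinstance(table, pd.DataFrame):
        return _ca_core(
            table.to_numpy(), [str(i) for i in table.index], [str(c) for c in table.columns],
            n_axes,
        )
    arr = np.asarray(table, dtype=float)
    rows = [f"r{i}" for i in range(arr.shape[0])]
    cols = [f"c{j}" for j in range(arr.shape[1])]
    return _ca_core(arr, rows, cols, n_axes)


# ---------------------------------------------------------------------------
# Reading the map
# ---------------------------------------------------------------------------


def distance_to_category(result: CAResult, row_label: str, col_label: str) -> float:
    """Euclidean distance between a row point and a category point in the
    retained principal-coordinate space."""
    return float(np.linalg.norm(result.row_coord(row_label) - result.col_coord(col_label)))


def zone_centroids(
    result: CAResult, zone_of: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Unweighted mean of member regions' principal coordinates per climate
    zone. Zones without members are omitted (logged)."""
    for label in result.row_labels:
        if label not in zone_of:
            raise ValidationError(f"region {label!r} has no climate zone assigned")
    zones: dict[str, list[np.ndarray]] = {}
    for label, coords in zip(result.row_labels, result.row_coords):
        zones.setdefault(zone_of[label], []).append(coords)
    requested = set(zone_of.values())
    for zone in sorted(requested - set(zones)):
        logger.info("zone %s has no member region in the result; omitted", zone)
    return {zone: np.mean(points, axis=0) for zone, points in sorted(zones.items())}


def write_ca_result(result: CAResult, coords_path, summary_path) -> None:
    """Coordinates as TSV (label, point_type, axis1..axisK) and the inertia
    decomposition as a small JSON summary."""
    axes = [f"axis{k + 1}" for k in range(result.n_axes)]
    rows = []
    for label, coords in zip(result.row_labels, result.row_coords):
        rows.append({"label": label, "point_type": "region",
                     **{a: c for a, c in zip(axes, coords)}})
    for label, coords in zip(result.col_labels, result.col_coords):
        rows.append({"label": label, "point_type": "category",
                     **{a: c for a, c in zip(axes, coords)}})
    frame = pd.DataFrame(rows, columns=["label", "point_type", *axes])
    frame.to_csv(coords_path, sep="\t", index=False, float_format="%.10g")
    write_json(
        {
            "axis_inertia": [float(v) for v in result.axis_inertia],
            "singular_values": [float(v) for v in result.singular_values],
            "total_inertia": result.total_inertia,
            "n_axes": result.n_axes,
        },
        summary_path,
    )
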