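"""Synthetic culture-based survey generator with full ground truth.

The generator emulates the sampling design the analysis modules assume: a
fixed roster of sampling regions (each with a province and climate zone),
samples allocated across region x season strata, a per-sample fungal
colony count (Poisson by default, negative binomial for overdispersion), a
two-stage recovery model for the target genus, and multinomial species and
haplotype composition — optionally province-specific, to plant geographic
gradients. Each haplotype carries one exemplar aligned ITS-like sequence;
every simulated isolate of that haplotype receives an identical copy, so
haplotype collapsing has an exact known answer.

Recovery of the genus is modelled in two stages: a sample harbours the
genus at all with probability ``occupancy_prob``, and each colony in an
occupied sample is the genus with probability ``genus_recovery_prob``
(isolate count ~ Binomial(colonies, p)). One stage alone cannot match the
field reality that the genus is only recovered from about three quarters
of samples while making up only ~3% of colonies; the defaults are
calibrated to reproduce both rates jointly (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .survey_io import (
    CLIMATE_ZONES,
    CROPS,
    ConfigError,
    IsolateRecord,
    SEASONS,
    AlignedSequenceSet,
    SurveySample,
    write_json,
)
from .haplotype_collapse import select_columns
from . import reference

__all__ = [
    "RegionInfo",
    "SequenceModel",
    "GeneratorConfig",
    "GroundTruth",
    "SimulatedSurvey",
    "generate_haplotype_sequences",
    "default_edit_spec",
    "simulate_survey",
    "published_survey_config",
    "write_survey",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class RegionInfo:
    region: str
    province: str
    climate_zone: str

    def __post_init__(self) -> None:
        if self.climate_zone not in CLIMATE_ZONES:
            raise ConfigError(
                f"region {self.region!r}: climate zone {self.climate_zone!r} "
                f"not one of {CLIMATE_ZONES}"
            )


@dataclass
class SequenceModel:
    """How exemplar sequences are built: alignment length, per-haplotype
    edits (position, character; '-' plants a gap) on a random base
    sequence, and the seed of that base sequence. ``edits=None`` means
    "auto-derive a distinct single-substitution edit per haplotype, with a
    shared block of gap columns hitting every third haplotype" (see
    :func:`default_edit_spec`)."""

    alignment_length: int = 600
    edits: dict[str, tuple[tuple[int, str], ...]] | None = None
    seed: int = 20140521  # fixed: sequences are part of the design, not the run
    n_gap_columns: int = 12


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic survey.

    ``species_probs`` is the survey-wide species multinomial;
    ``haplotype_probs`` maps species -> haplotype multinomial. Optional
    ``*_by_province`` overrides plant regional structure (e.g. a
    south-to-north haplotype gradient). ``crop_probs`` allocates crops per
    sample independently of region/season.
    """

    regions: tuple[RegionInfo, ...]
    species_probs: dict[str, float]
    haplotype_probs: dict[str, dict[str, float]]
    seasons: tuple[str, ...] = SEASONS
    crops: tuple[str, ...] = CROPS
    crop_probs: tuple[float, ...] = (312 / 737, 75 / 737, 94 / 737, 256 / 737)
    n_samples: int = reference.TOTAL_SAMPLES
    colony_mean: float = 86.0
    colony_dispersion: float | None = None  # None -> Poisson; else NB size parameter
    occupancy_prob: float = 0.776
    genus_recovery_prob: float = 0.0422
    species_probs_by_province: dict[str, dict[str, float]] | None = None
    haplotype_probs_by_province: dict[str, dict[str, dict[str, float]]] | None = None
    sequence_model: SequenceModel = field(default_factory=SequenceModel)
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not self.regions:
            raise ConfigError("no regions configured")
        if len({r.region for r in self.regions}) != len(self.regions):
            raise ConfigError("duplicate region names")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.colony_mean <= 0:
            raise ConfigError("colony_mean must be positive")
        if self.colony_dispersion is not None and self.colony_dispersion <= 0:
            raise ConfigError("colony_dispersion must be positive")
        for name, p in (("occupancy_prob", self.occupancy_prob),
                        ("genus_recovery_prob", self.genus_recovery_prob)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if len(self.crop_probs) != len(self.crops):
            raise ConfigError("crop_probs length does not match crops")
        self._check_multinomial("crop_probs", dict(zip(self.crops, self.crop_probs)))
        self._check_multinomial("species_probs", self.species_probs)
        for species in self.species_probs:
            if species not in self.haplotype_probs:
                raise ConfigError(f"species {species!r} has no haplotype multinomial")
            self._check_multinomial(
                f"haplotype_probs[{species!r}]", self.haplotype_probs[species]
            )
        for override, per_species in (self.species_probs_by_province or {}).items():
            self._check_multinomial(f"species_probs_by_province[{override!r}]", per_species)
        for province, by_species in (self.haplotype_probs_by_province or {}).items():
            for species, probs in by_species.items():
                self._check_multinomial(
                    f"haplotype_probs_by_province[{province!r}][{species!r}]", probs
                )
        # all haplotype codes, for the sequence model
        self.all_haplotypes()

    @staticmethod
    def _check_multinomial(name: str, probs: Mapping[str, float]) -> None:
        if not probs:
            raise ConfigError(f"{name}: empty probability vector")
        values = np.array(list(probs.values()), dtype=float)
        if (values < 0).any() or (values > 1).any():
            raise ConfigError(f"{name}: probabilities outside [0, 1]")
        if abs(values.sum() - 1.0) > _PROB_TOL:
            raise ConfigError(f"{name}: probabilities sum to {values.sum()!r}, not 1")

    def all_haplotypes(self) -> list[str]:
        codes: dict[str, None] = {}
        sources = [self.haplotype_probs]
        sources += list((self.haplotype_probs_by_province or {}).values())
        for by_species in sources:
            for species, probs in by_species.items():
                for code in probs:
                    codes.setdefault(code, None)
        return list(codes)

    # -- per-province resolution --------------------------------------------

    def species_probs_for(self, province: str) -> dict[str, float]:
        if self.species_probs_by_province and province in self.species_probs_by_province:
            return self.species_probs_by_province[province]
        return self.species_probs

    def haplotype_probs_for(self, province: str, species: str) -> dict[str, float]:
        by_province = self.haplotype_probs_by_province or {}
        if province in by_province and species in by_province[province]:
            return by_province[province][species]
        return self.haplotype_probs[species]


@dataclass
class GroundTruth:
    """Everything the generator knew: per-sample draws, realized counts and
    the generating probabilities echoed back."""

    per_sample: dict[str, list[tuple[str, str]]]  # sample_id -> [(species, haplotype)]
    species_counts: dict[str, int]
    haplotype_counts: dict[str, int]
    species_probs: dict[str, float]
    haplotype_probs: dict[str, dict[str, float]]

    def to_jsonable(self) -> dict:
        return {
            "per_sample": {k: [list(t) for t in v] for k, v in self.per_sample.items()},
            "species_counts": self.species_counts,
            "haplotype_counts": self.haplotype_counts,
            "species_probs": self.species_probs,
            "haplotype_probs": self.haplotype_probs,
        }


@dataclass
class SimulatedSurvey:
    samples: list[SurveySample]
    isolates: list[IsolateRecord]
    sequences: AlignedSequenceSet          # one entry per isolate
    exemplars: AlignedSequenceSet          # one entry per haplotype code
    truth: GroundTruth
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# Exemplar sequences
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _random_base_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def default_edit_spec(
    codes: Sequence[str], length: int = 600, seed: int = 20140521, n_gap_columns: int = 12
) -> dict[str, tuple[tuple[int, str], ...]]:
    """One distinguishing substitution per haplotype at a dedicated
    alignment position, plus a shared block of gap columns planted in every
    third haplotype so the ``exclude_columns`` policy has work to do.

    Draws the base sequence first from ``seed`` so that the substituted
    character is guaranteed to differ from the base — the same stream
    :func:`generate_haplotype_sequences` uses.
    """
    if len(codes) + n_gap_columns > length:
        raise ConfigError(
            f"alignment length {length} too short for {len(codes)} haplotypes "
            f"plus {n_gap_columns} gap columns"
        )
    rng = np.random.default_rng(seed)
    base = _random_base_sequence(length, rng)
    positions = np.sort(rng.choice(length, size=len(codes) + n_gap_columns, replace=False))
    sub_positions = positions[: len(codes)]
    gap_columns = positions[len(codes):]
    edits: dict[str, tuple[tuple[int, str], ...]] = {}
    for k, code in enumerate(codes):
        pos = int(sub_positions[k])
        new_base = _BASES[(_BASES.index(base[pos]) + 1) % 4]
        hap_edits: list[tuple[int, str]] = [(pos, new_base)]
        if k % 3 == 0:
            hap_edits += [(int(g), "-") for g in gap_columns]
        edits[code] = tuple(hap_edits)
    return edits


def generate_haplotype_sequences(
    length: int,
    edits: Mapping[str, Sequence[tuple[int, str]]],
    seed: int = 20140521,
) -> AlignedSequenceSet:
    """Build one exemplar aligned sequence per haplotype.

    A random A/C/G/T base sequence is drawn from ``seed``; each haplotype's
    edits are applied on top. Two haplotypes with identical edit sets, or
    any pair that ends up identical on the columns surviving the
    ``exclude_columns`` policy, are a configuration error: such haplotypes
    could never be told apart by collapsing.
    """
    rng = np.random.default_rng(seed)
    base = _random_base_sequence(length, rng)
    seen: dict[frozenset, str] = {}
    entries: dict[str, str] = {}
    for code, hap_edits in edits.items():
        key = frozenset(hap_edits)
        if key in seen:
            raise ConfigError(
                f"haplotypes {seen[key]!r} and {code!r} share an identical edit set"
            )
        seen[key] = code
        seq = list(base)
        for pos, ch in hap_edits:
            if not 0 <= pos < length:
                raise ConfigError(f"haplotype {code!r}: edit position {pos} out of range")
            ch = ch.upper()
            if ch not in _BASES + "-":
                raise ConfigError(f"haplotype {code!r}: illegal edit character {ch!r}")
            seq[pos] = ch
        entries[code] = "".join(seq)
    exemplars = AlignedSequenceSet.from_entries(entries)
    if len(exemplars) > 1:
        retained = select_columns(exemplars, "exclude_columns")
        projected = {
            code: "".join(seq[c] for c in retained) for code, seq in exemplars.entries.items()
        }
        by_projection: dict[str, str] = {}
        for code, proj in projected.items():
            if proj in by_projection:
                raise ConfigError(
                    f"haplotypes {by_projection[proj]!r} and {code!r} are identical on "
                    "all gap-free columns"
                )
            by_projection[proj] = code
    return exemplars


# ---------------------------------------------------------------------------
# Survey simulation
# ---------------------------------------------------------------------------


def _allocate_samples(config: GeneratorConfig) -> list[tuple[RegionInfo, str]]:
    """Deterministic near-even allocation of n_samples across region x
    season strata (extras go to the earliest strata)."""
    strata = [(region, season) for region in config.regions for season in config.seasons]
    base, extra = divmod(config.n_samples, len(strata))
    out: list[tuple[RegionInfo, str]] = []
    for k, stratum in enumerate(strata):
        out += [stratum] * (base + (1 if k < extra else 0))
    return out


def simulate_survey(config: GeneratorConfig, seed: int | None = None) -> SimulatedSurvey:
    """Draw a full synthetic survey.

    Per sample: colony count from the colony model; the sample harbours
    the genus with ``occupancy_prob``; if so, isolate count ~
    Binomial(colonies, genus_recovery_prob); each isolate's species, then
    haplotype, is drawn from the (possibly province-specific)
    multinomials; each isolate carries a copy of its haplotype's exemplar
    sequence. Identical (config, seed) give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    codes = config.all_haplotypes()
    model = config.sequence_model
    edits = model.edits
    if edits is None:
        edits = default_edit_spec(
            codes, model.alignment_length, model.seed, model.n_gap_columns
        )
    exemplars = generate_haplotype_sequences(model.alignment_length, edits, model.seed)
    missing = [code for code in codes if code not in exemplars.entries]
    if missing:
        raise ConfigError(f"sequence model lacks exemplars for: {', '.join(missing)}")

    allocation = _allocate_samples(config)
    n = len(allocation)
    if config.colony_dispersion is None:
        colonies = rng.poisson(config.colony_mean, size=n)
    else:
        size = config.colony_dispersion
        p = size / (size + config.colony_mean)
        colonies = rng.negative_binomial(size, p, size=n)
    crop_idx = rng.choice(len(config.crops), size=n, p=np.asarray(config.crop_probs))
    occupied = rng.random(n) < config.occupancy_prob
    n_isolates = np.where(
        occupied, rng.binomial(colonies, config.genus_recovery_prob), 0
    )

    samples: list[SurveySample] = []
    isolates: list[IsolateRecord] = []
    sequences: dict[str, str] = {}
    per_sample: dict[str, list[tuple[str, str]]] = {}
    species_counts: dict[str, int] = {}
    haplotype_counts: dict[str, int] = {}

    width = len(str(n))
    for idx, (region, season) in enumerate(allocation):
        sample_id = f"S{idx + 1:0{width}d}"
        crop = config.crops[crop_idx[idx]]
        draws: list[tuple[str, str]] = []
        isolate_ids: list[str] = []
        k = int(n_isolates[idx])
        if k:
            sp_probs = config.species_probs_for(region.province)
            sp_names = list(sp_probs)
            picked = rng.choice(len(sp_names), size=k, p=np.array(list(sp_probs.values())))
            for j, sp_i in enumerate(picked, start=1):
                species = sp_names[int(sp_i)]
                hap_probs = config.haplotype_probs_for(region.province, species)
                hap_names = list(hap_probs)
                hap = hap_names[
                    int(rng.choice(len(hap_names), p=np.array(list(hap_probs.values()))))
                ]
                isolate_id = f"{sample_id}.{j:03d}"
                isolates.append(
                    IsolateRecord(
                        isolate_id=isolate_id,
                        sample_id=sample_id,
                        species=species,
                        sequence_id=isolate_id,
                        haplotype_code=hap,
                    )
                )
                sequences[isolate_id] = exemplars.entries[hap]
                isolate_ids.append(isolate_id)
                draws.append((species, hap))
                species_counts[species] = species_counts.get(species, 0) + 1
                haplotype_counts[hap] = haplotype_counts.get(hap, 0) + 1
        samples.append(
            SurveySample(
                sample_id=sample_id,
                region=region.region,
                province=region.province,
                climate_zone=region.climate_zone,
                season=season,
                crop=crop,
                total_fungal_colonies=max(int(colonies[idx]), k),
                isolate_ids=isolate_ids,
            )
        )
        per_sample[sample_id] = draws

    truth = GroundTruth(
        per_sample=per_sample,
        species_counts=species_counts,
        haplotype_counts=haplotype_counts,
        species_probs=dict(config.species_probs),
        haplotype_probs={sp: dict(p) for sp, p in config.haplotype_probs.items()},
    )
    sequence_set = AlignedSequenceSet(
        entries=sequences, alignment_length=model.alignment_length
    )
    return SimulatedSurvey(
        samples=samples,
        isolates=isolates,
        sequences=sequence_set,
        exemplars=exemplars,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# The survey-shaped default configuration
# ---------------------------------------------------------------------------

#: The 20 sampling regions with province and climate zone (S subtropical
#: monsoon, T temperate monsoon, B boundary belt). Nineteen regions carry
#: the survey's published city names and zone groupings; "Ningbo" is a
#: synthetic twentieth region completing the published count of 20.
SURVEY_REGIONS: tuple[RegionInfo, ...] = (
    RegionInfo("Hangzhou", "Zhejiang", "S"),
    RegionInfo("Quzhou", "Zhejiang", "S"),
    RegionInfo("Taizhou-ZJ", "Zhejiang", "S"),
    RegionInfo("Lishui", "Zhejiang", "S"),
    RegionInfo("Ningbo", "Zhejiang", "S"),
    RegionInfo("Nanjing", "Jiangsu", "S"),
    RegionInfo("Wuxi", "Jiangsu", "S"),
    RegionInfo("Huaian", "Jiangsu", "B"),
    RegionInfo("Xuzhou", "Jiangsu", "B"),
    RegionInfo("Taizhou-JS", "Jiangsu", "B"),
    RegionInfo("Anqing", "Anhui", "S"),
    RegionInfo("Hefei", "Anhui", "S"),
    RegionInfo("Xuancheng", "Anhui", "S"),
    RegionInfo("Bengbu", "Anhui", "B"),
    RegionInfo("Fuyang", "Anhui", "B"),
    RegionInfo("Jinan", "Shandong", "T"),
    RegionInfo("Weifang", "Shandong", "T"),
    RegionInfo("Dezhou", "Shandong", "T"),
    RegionInfo("Linyi", "Shandong", "S"),
    RegionInfo("Jining", "Shandong", "B"),
)


def published_survey_config(n_samples: int = reference.TOTAL_SAMPLES, seed: int = 0) -> GeneratorConfig:
    """A configuration shaped like the published East China survey.

    20 regions in 4 provinces, 3 seasons, rice/wheat/maize/other crops in
    the published sample proportions, 17 species with probabilities
    proportional to the published isolate counts (429, 425, 397, 340, 248,
    ..., 1 of 2075), 48 haplotypes proportioned per species from the
    published inventory, Poisson(86) colonies per sample, and genus
    recovery calibrated so ~76% of samples yield an isolate while ~3.3% of
    colonies are the genus.
    """
    species_counts = reference.reference_species_counts()
    total = sum(species_counts.values())
    species_probs = {sp: count / total for sp, count in species_counts.items()}
    return GeneratorConfig(
        regions=SURVEY_REGIONS,
        species_probs=species_probs,
        haplotype_probs=reference.reference_haplotype_probs(),
        n_samples=n_samples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Writing out
# ---------------------------------------------------------------------------


def write_survey(survey: SimulatedSurvey, outdir) -> dict[str, str]:
    """Write samples.tsv, isolates.tsv, sequences.fasta, exemplars.fasta and
    truth.json into ``outdir``; returns the path map."""
    from pathlib import Path

    from . import survey_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": str(outdir / "samples.tsv"),
        "isolates": str(outdir / "isolates.tsv"),
        "sequences": str(outdir / "sequences.fasta"),
        "exemplars": str(outdir / "exemplars.fasta"),
        "truth": str(outdir / "truth.json"),
    }
    survey_io.write_sample_metadata(survey.samples, paths["samples"])
    survey_io.write_isolate_table(survey.isolates, paths["isolates"])
    survey_io.write_aligned_fasta(survey.sequences, paths["sequences"])
    survey_io.write_aligned_fasta(survey.exemplars, paths["exemplars"])
    write_json(survey.truth.to_jsonable(), paths["truth"])
    return paths
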