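"""Published haplotype inventory of the East China agricultural-soil
*Trichoderma* survey that this package's analysis design follows.

The survey isolated 2078 *Trichoderma* strains from 737 soil samples in 20
regions of four provinces (Anhui, Jiangsu, Shandong, Zhejiang) over three
seasons, and collapsed their ITS1/ITS2 sequences into 48 haplotypes across
17 named species (2075 isolates carry a species name; 3 remained
unidentified). The inventory below transcribes that haplotype table:
haplotype code, species, number of isolated strains, the representative
strain of the culture collection and its GenBank accession (carried as an
opaque string; nothing is fetched).

Two small internal inconsistencies of the published counts are preserved
as printed rather than resolved: *T. capillare* is listed with 1 isolate
here although the prose says 2 (the 2075 column sum is only consistent
with 1), and the *T. harzianum* codes run harz1–harz6, harz8 with no
harz7. See ``docs/methods.md``.
"""

from __future__ import annotations

import io

import pandas as pd

from .haplotype_collapse import HaplotypeRow, HaplotypeTable

__all__ = [
    "reference_inventory",
    "reference_species_counts",
    "reference_haplotype_probs",
    "reference_haplotype_table",
    "GENUS_TOTAL_ISOLATES",
    "SPECIES_TOTAL_ISOLATES",
    "TOTAL_SAMPLES",
    "POSITIVE_SAMPLES",
    "TOTAL_FUNGAL_COLONIES",
]

#: Survey-wide totals as published.
TOTAL_SAMPLES = 737            #: soil samples collected
POSITIVE_SAMPLES = 557         #: samples yielding >= 1 target-genus isolate
GENUS_TOTAL_ISOLATES = 2078    #: Trichoderma isolates (incl. 3 unidentified)
SPECIES_TOTAL_ISOLATES = 2075  #: isolates assigned to one of the 17 species
TOTAL_FUNGAL_COLONIES = 63426  #: all fungal colonies counted

_INVENTORY_TSV = """\
haplotype_code\tspecies\tn_isolates\trepresentative_strain\tgenbank_accession
asper1\tT. asperellum\t237\tCTCCSJ-A-SD31000\tKT314289
asper2\tT. asperellum\t173\tCTCCSJ-A-SC31024\tKT314294
asper3\tT. asperellum\t1\tCTCCSJ-A-SC31096\tKT314300
asper4\tT. asperellum\t1\tCTCCSJ-A-SD31174\tKT314302
asper5\tT. asperellum\t9\tCTCCSJ-A-SC3140\tKT314305
asper6\tT. asperellum\t1\tCTCCSJ-A-GS31670\tKT314308
asper7\tT. asperellum\t1\tCTCCSJ-A-SC3254\tKT314313
asper8\tT. asperellum\t1\tCTCCSJ-A-XM337\tKT314317
asper9\tT. asperellum\t1\tCTCCSJ-A-SD3908\tKT314330
atro\tT. atroviride\t73\tCTCCSJ-A-SC350\tKT314321
brev1\tT. brevicompactum\t67\tCTCCSJ-A-SD31063\tKT314299
brev2\tT. brevicompactum\t3\tCTCCSJ-A-XM3257\tKT314314
brev3\tT. brevicompactum\t2\tCTCCSJ-A-GS3259\tKT314315
brev4\tT. brevicompactum\t1\tCTCCSJ-A-GS3847\tKT314329
erin1\tT. erinaceum\t15\tCTCCSJ-A-SC31615\tKT314307
erin2\tT. erinaceum\t1\tCTCCSJ-A-SC31443\tKT314306
fer\tT. fertile\t26\tCTCCSJ-A-YM3122\tKT314304
ham1\tT. hamatum\t340\tCTCCSJ-A-SD31002\tKT314290
ham2\tT. hamatum\t6\tCTCCSJ-A-SD31012\tKT314293
ham3\tT. hamatum\t44\tCTCCSJ-A-SD31214\tKT314303
ham4\tT. hamatum\t1\tCTCCSJ-A-SD3711\tKT314327
ham5\tT. hamatum\t1\tCTCCSJ-A-QT3177\tKT314309
ham6\tT. hamatum\t1\tCTCCSJ-A-SD3937\tKT314332
ham7\tT. hamatum\t4\tCTCCSJ-A-SD3550\tKT314322
harz1\tT. harzianum\t235\tCTCCSJ-A-SD31009\tKT314292
harz2\tT. harzianum\t66\tCTCCSJ-A-SD31031\tKT314296
harz3\tT. harzianum\t21\tCTCCSJ-A-XM31791\tKU375457
harz4\tT. harzianum\t41\tCTCCSJ-A-MH31042\tKT314298
harz5\tT. harzianum\t26\tCTCCSJ-A-SD3109\tKT314301
harz6\tT. harzianum\t33\tCTCCSJ-A-SD31059\tKU375456
harz8\tT. harzianum\t7\tCTCCSJ-A-SD3775\tKU375462
satur\tT. saturnisporum\t1\tCTCCSJ-A-SD3604\tKT314324
kons1\tT. koningiopsis\t79\tCTCCSJ-A-YC3100\tKT314288
kons2\tT. koningiopsis\t164\tCTCCSJ-A-SD31029\tKT314295
kons3\tT. koningiopsis\t2\tCTCCSJ-A-XM323\tKT314311
kons4\tT. koningiopsis\t2\tCTCCSJ-A-SD3388\tKT314319
kons5\tT. koningiopsis\t1\tCTCCSJ-A-SD3644\tKT314325
longib1\tT. longibrachiatum\t18\tCTCCSJ-A-SC3195\tKT314310
longib2\tT. longibrachiatum\t1\tCTCCSJ-A-SC378\tKT314328
longib3\tT. longibrachiatum\t2\tCTCCSJ-A-YM32425\tKU375460
longib4\tT. longibrachiatum\t1\tCTCCSJ-A-YM32819\tKU375461
obl\tT. oblongisporum\t2\tCTCCSJ-A-GS3677\tKT314326
cfaur\tT. pleuroticola\t16\tCTCCSJ-A-YM3383\tKT314318
poly\tT. polysporum\t2\tCTCCSJ-A-SD3918\tKT314331
capi\tT. capillare\t1\tCTCCSJ-A-SD3940\tKT314333
spir\tT. spirale\t2\tCTCCSJ-A-SC3230\tKT314312
vel\tT. velutinum\t2\tCTCCSJ-A-SD3579\tKT314323
virens\tT. virens\t340\tCTCCSJ-A-SD31006\tKT314291
"""


def reference_inventory() -> pd.DataFrame:
    """The 48-row haplotype inventory as a DataFrame."""
    frame = pd.read_csv(io.StringIO(_INVENTORY_TSV), sep="\t", dtype=str)
    frame["n_isolates"] = frame["n_isolates"].astype(int)
    return frame


def reference_species_counts() -> dict[str, int]:
    """Published isolate count per species (sums to 2075)."""
    frame = reference_inventory()
    grouped = frame.groupby("species", sort=False)["n_isolates"].sum()
    return {species: int(count) for species, count in grouped.items()}


def reference_haplotype_probs() -> dict[str, dict[str, float]]:
    """Per-species haplotype proportions from the published counts."""
    frame = reference_inventory()
    out: dict[str, dict[str, float]] = {}
    for species, sub in frame.groupby("species", sort=False):
        total = sub["n_isolates"].sum()
        out[species] = {
            code: count / total for code, count in zip(sub["haplotype_code"], sub["n_isolates"])
        }
    return out


def reference_haplotype_table() -> HaplotypeTable:
    """The inventory as a :class:`HaplotypeTable`.

    The publication lists only counts and one representative per haplotype,
    not per-isolate membership, so member ids here are synthetic
    placeholders ``<code>.m<k>`` (the representative keeps the published
    strain id) — sufficient for count- and partition-shaped computations.
    """
    rows: list[HaplotypeRow] = []
    for record in reference_inventory().itertuples(index=False):
        members = [record.representative_strain] + [
            f"{record.haplotype_code}.m{k}" for k in range(2, record.n_isolates + 1)
        ]
        rows.append(
            HaplotypeRow(
                haplotype_code=record.haplotype_code,
                species=record.species,
                member_ids=members,
                n_isolates=record.n_isolates,
                representative_id=record.representative_strain,
            )
        )
    return HaplotypeTable(rows=rows, columns_used=[])
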