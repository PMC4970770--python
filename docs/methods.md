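# Methods

## The survey model

The package analyses culture-based surveys in which soil samples are
plated on a selective medium, all fungal colonies are counted, and
colonies of a target genus (*Trichoderma* in the motivating surveys) are
purified and sequenced at the ITS1/ITS2 marker. A survey is three tables:
samples (with stratum labels region / province / climate zone / season /
crop and a total colony count), isolates (sample of origin, species call,
sequence id) and an aligned multi-FASTA. Climate zones are input labels
(S / T / B), not computed from coordinates: the motivating surveys assign
them narratively, so no rule could be implemented. Species identity is
likewise an input — barcode identification services are out of scope.

## Haplotype collapsing

Two sequences are the same haplotype when they agree on every *compared*
column. Which columns are compared is the gap policy:

- `exclude_columns` (default): drop every alignment column in which any
  sequence of the input carries `-`, `N` or an IUPAC ambiguity code. This
  matches the conventional treatment of gapped/missing sites in haplotype
  callers (DnaSP's default behaviour); indel-only or ambiguity-only
  variation never splits a haplotype.
- `literal`: compare all columns, treating `-` and ambiguity codes as
  ordinary characters (a sensitivity check).

The column set is computed once over the whole input (one `columns_used`
list per haplotype table), not per species group. Collapsing is performed
within species: published haplotype codes are species-scoped, and a
cross-species mode would conflate identically-barcoded sister species.
Codes are `<epithet prefix><ordinal>` (e.g. `harz1`), numbered by first
appearance in input order; the representative is the first member.
Identity on fixed columns is an equivalence relation, so the partition is
invariant under input permutation — only codes and representatives depend
on order. Removing columns can only merge classes, hence
`exclude_columns` never yields more haplotypes than `literal`. Both
properties are enforced by randomized tests against a union-find oracle.

## Dominance, rates, diversity

For taxon *i*, the dominance index is Y = (nᵢ/N)·fᵢ, where fᵢ is the
*presence* frequency — the share of samples with ≥1 isolate of the taxon —
not an isolate-count share. (Back-calculation from the published
whole-survey numbers confirms this reading: (2078/63426)·(557/737) = 0.0248
prints as the published 0.025.) The classification rule is strictly
Y > threshold, default 0.02.

Scoping: at genus level N is the total fungal colony count of the scope;
at species/haplotype level N is the scope's genus isolate count. For a
stratified profile (e.g. per province) both N and fᵢ are restricted to the
stratum's samples. The motivating surveys do not state this scoping; it is
this package's reading, chosen because it reproduces the whole-survey
genus value exactly and keeps the per-stratum results self-contained.

Isolation rate = positive samples / all samples; relative rate = genus
isolates / all colonies. Shannon–Wiener H′ = −Σ pᵢ log pᵢ over nonzero
haplotype (or species) counts, natural log by default (the motivating
surveys omit the base; e, 2 and 10 are supported). Unidentified isolates
count toward genus totals but are excluded from species-level tables.

Display conventions, applied only at formatting time (all internal math is
full precision): Y to 3 decimals, H′ to 2, rates as integer percent.
Note that published reports of such surveys are not always internally
consistent at display precision (the motivating study prints one species'
Y as 0.048 in one place and 0.047 in another, lists one species with 1
isolate in its table but 2 in the text, and numbers seven *T. harzianum*
haplotypes 1–6 and 8). The shipped reference inventory transcribes the
table as printed and leaves such discrepancies visible.

## Multiple correspondence analysis

Regions (or region×season×crop sampling units) are coded 0/1 against
categorical variables: each requested haplotype as a present/absent pair,
plus optional season and crop factors. With X the coded table, n its
grand total, P = X/n, row/column masses r, c:

S = D_r^(−1/2) (P − r cᵀ) D_c^(−1/2),  S = U Σ Vᵀ,

row principal coordinates F = D_r^(−1/2) U Σ, column coordinates
G = D_c^(−1/2) V Σ; axis k's inertia is σₖ², Σσ² = total inertia = χ²/n.
Centring on r cᵀ removes the trivial constant dimension before the SVD, so
it is never reported. Singular values below 1e-12·σ₁ are treated as rank
deficiency. Sign convention: each axis is flipped so its
largest-magnitude column coordinate is positive, making outputs
deterministic. Burt-matrix coding (CA of ZᵀZ) is available as an option;
its principal inertias are the squares of the indicator ones (tested).
Zero row/column margins raise a degenerate-input error naming the label;
category columns never observed are dropped before analysis (with a log
line), so the classical MCA identity — total inertia = (J−Q)/Q for Q
variables and J surviving categories — holds and is used as a structural
self-check.

Row-mode choice: with rows = regions (default, matching a
sites-by-descriptors biplot), a region sampled in several seasons carries
several season categories, so factor coding is presence-style rather than
strictly disjunctive; the `region-season-crop` row mode provides fully
disjunctive coding when the identity matters. Climate-zone ellipses of
published biplots are interpretive graphics; only zone centroids
(unweighted means of member regions' coordinates) are computed.

## The synthetic generator

What it emulates: the motivating survey's design — 20 regions in 4
provinces (19 of the region names and their S/T/B groupings are as
published; one region name in the southern province is a synthetic
completion of the published count of 20, and the homonymous city name
appearing in both the S and B groupings is treated as the two distinct
cities), 3 seasons, crops in the published sample proportions
(312 rice / 75 wheat / 94 maize / 256 other of 737), 17 species with
probabilities proportional to the published isolate counts
(429, 425, 397, 340, 248, …, 1 of 2075) and 48 haplotypes proportioned
per species from the published inventory.

Per sample: colonies ~ Poisson(86) (negative binomial optional for
overdispersion; mean 86 makes a 737-sample survey count ≈63,000 colonies,
the published scale; the motivating surveys report only totals, so the
Poisson form is an assumption). Genus recovery is two-stage: the sample
harbours the genus with occupancy probability q, and each colony of an
occupied sample is the genus with probability p (isolates ~
Binomial(colonies, p)). A single-stage binomial cannot reproduce the field
reality jointly — at p = 2078/63426 a Poisson(86) sample is positive with
probability 1−e^(−86p) ≈ 0.94, far above the published 76% — whereas the
two-stage model solves q(1−e^(−86p)) = 557/737 and q·p = 2078/63426,
giving the defaults q = 0.776, p = 0.0422. Species and haplotype draws are
i.i.d. multinomial per isolate, optionally province-specific (used to
plant south–north gradients in tests).

Sequences: each haplotype has one exemplar — a shared random A/C/G/T
backbone plus per-haplotype edits; the default spec gives every haplotype
a unique diagnostic substitution and plants a shared gap-column block in
every third haplotype so the gap policy is exercised. All members of a
haplotype are identical by construction, mirroring the definition of a
haplotype (within-haplotype variation is zero). The generator validates
that distinct haplotypes still differ on gap-free columns, so collapsing
has an exact known answer. Exemplar sequences are seeded independently of
the sampling seed: they are part of the survey design, not of a draw.

What it does **not** emulate: spatial autocorrelation or clustering of
isolates within fields — under i.i.d. multinomial draws species are more
widespread (higher f) and haplotype counts more even (per-province H′
around 2.6 versus the published ~1.3–1.5) than in real, patchy
communities; seasonal abundance dynamics;
within-haplotype sequencing noise; unidentified isolates. Passing
recovery tests therefore demonstrates correctness of the statistics on
i.i.d. stratified multinomial data, not that real communities satisfy
those assumptions.

## Problem sizes and numerical choices

The test suite runs surveys of 240 samples (session fixture, ≈680
isolates) and one 3,550-sample draw (≈10,000 isolates) for the
convergence/recovery checks — within 3 binomial standard errors at fixed
seed; the whole suite completes in a few seconds. Oracle equivalence uses
200 random alignments (≤20×≤60) for collapsing and 100 random ≤10×10
count tables for CA (χ²/n within 1e-8; eigendecomposition within 1e-8).
Probability vectors must sum to 1 within 1e-12; abundance-row frequencies
sum to 1 within 1e-12; zero-count strata are flagged, never NaN-propagated.

## Known limitations

- Per-province dominance and diversity values of the motivating surveys
  are not reproducible (per-sample data undeposited); only their code
  paths are tested, via synthetic ground truth.
- The haplotype-code scheme is deterministic but not identical to
  published code styles (singleton species also get an ordinal, e.g.
  `atro1`; abbreviation is a fixed epithet prefix).
- The generator's colony model ignores sample-to-sample habitat
  covariates; occupancy q is a single global knob (per-stratum overrides
  are possible for species/haplotype composition only).
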