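import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trichosurvey as ts


class TestDominanceIndex:
    def test_survey_wide_genus_dominance(self):
        """The survey's headline arithmetic: 2078 isolates of 63426
        colonies, recovered from 557 of 737 samples."""
        Y = ts.dominance_index(2078, 63426, 557 / 737)
        assert Y == pytest.approx((2078 / 63426) * (557 / 737), abs=0)
        assert round(Y, 3) == 0.025
        assert ts.classify_dominant(Y, 0.02)

    def test_zero_and_maximum_cases(self):
        assert ts.dominance_index(0, 100, 0.5) == 0.0
        assert ts.dominance_index(100, 100, 1.0) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ts.DomainError):
            ts.dominance_index(1, 0, 0.5)
        with pytest.raises(ts.ValidationError):
            ts.dominance_index(5, 4, 0.5)
        with pytest.raises(ts.ValidationError):
            ts.dominance_index(1, 4, 1.5)

    def test_threshold_is_strict(self):
        assert ts.classify_dominant(0.025, 0.02)
        assert not ts.classify_dominant(0.02, 0.02)
        assert not ts.classify_dominant(0.019, 0.02)

    @given(
        n1=st.integers(0, 50), n2=st.integers(0, 50),
        f1=st.floats(0, 1), f2=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=60)
    def test_monotone_in_count_and_frequency(self, n1, n2, f1, f2):
        N = 100
        lo_n, hi_n = sorted((n1, n2))
        lo_f, hi_f = sorted((f1, f2))
        assert ts.dominance_index(lo_n, N, lo_f) <= ts.dominance_index(hi_n, N, lo_f)
        assert ts.dominance_index(lo_n, N, lo_f) <= ts.dominance_index(lo_n, N, hi_f)


class TestRates:
    def test_survey_wide_rates_and_display(self):
        iso = 557 / 737
        rel = ts.relative_rate(2078, 63426)
        assert iso == pytest.approx(0.7558, abs=5e-5)
        assert rel == pytest.approx(0.03276, abs=5e-6)
        assert ts.format_percent(iso) == "76%"
        assert ts.format_percent(rel) == "3%"

    def test_relative_rate_bounds(self):
        assert ts.relative_rate(0, 100) == 0.0
        assert ts.relative_rate(100, 100) == 1.0
        with pytest.raises(ts.DomainError):
            ts.relative_rate(0, 0)

    def test_isolation_rate_on_tiny_survey(self, tiny_survey):
        samples, isolates = tiny_survey
        assert ts.isolation_rate(samples, isolates) == 3 / 4
        assert ts.isolation_rate(samples, []) == 0.0
        with pytest.raises(ts.DomainError):
            ts.isolation_rate([], isolates)


class TestFrequencyOfOccurrence:
    def test_levels_on_tiny_survey(self, tiny_survey):
        samples, isolates = tiny_survey
        assert ts.frequency_of_occurrence(None, samples, isolates) == 3 / 4
        assert ts.frequency_of_occurrence("T. hamatum", samples, isolates) == 2 / 4
        assert ts.frequency_of_occurrence("T. harzianum", samples, isolates) == 2 / 4
        assert ts.frequency_of_occurrence(
            "ham1", samples, isolates, level="haplotype") == 2 / 4
        assert ts.frequency_of_occurrence("T. absent", samples, isolates) == 0.0

    def test_matches_enumeration_on_simulation(self, small_sim):
        samples, isolates = small_sim.samples, small_sim.isolates
        by_sample = {}
        for i in isolates:
            by_sample.setdefault(i.sample_id, set()).add(i.species)
        for species in ("T. harzianum", "T. hamatum", "T. saturnisporum"):
            expected = sum(
                species in by_sample.get(s.sample_id, ()) for s in samples
            ) / len(samples)
            assert ts.frequency_of_occurrence(species, samples, isolates) == expected


class TestShannonWiener:
    def test_uniform_vector_hits_log_k(self):
        assert ts.shannon_wiener([5, 5, 5, 5]) == pytest.approx(math.log(4), abs=1e-12)
        assert ts.shannon_wiener([5, 5, 5, 5], log_base=2) == pytest.approx(2.0, abs=1e-12)

    def test_singleton_is_zero(self):
        assert ts.shannon_wiener([7]) == 0.0

    def test_hand_computed_value(self):
        # p = (1/2, 1/4, 1/4): H = -(.5 ln .5 + .5 ln .25) = 1.0397...
        assert ts.shannon_wiener([2, 1, 1]) == pytest.approx(1.039721, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ts.DomainError):
            ts.shannon_wiener([0, 0, 0])

    @given(st.lists(st.integers(0, 40), min_size=1, max_size=12).filter(lambda c: sum(c) > 0))
    @settings(derandomize=True, max_examples=80)
    def test_invariances_and_bounds(self, counts):
        h = ts.shannon_wiener(counts)
        k = sum(1 for c in counts if c > 0)
        assert 0.0 <= h <= math.log(max(k, 1)) + 1e-12
        assert ts.shannon_wiener(sorted(counts)) == pytest.approx(h, abs=1e-12)
        assert ts.shannon_wiener(counts + [0]) == pytest.approx(h, abs=1e-12)


class TestAbundanceTables:
    def test_single_sample_single_species(self, make_sample):
        samples = [make_sample("A01", colonies=10)]
        isolates = [
            ts.IsolateRecord(f"i{k}", "A01", "T. virens", f"i{k}", None) for k in range(3)
        ]
        table = ts.build_abundance_table(samples, isolates, "province", "species")
        assert table.strata == ["Zhejiang"] and table.taxa == ["T. virens"]
        assert table.counts.tolist() == [[3]]

    def test_counts_match_enumeration_and_marginals(self, small_sim):
        samples, isolates = small_sim.samples, small_sim.isolates
        sample_by_id = {s.sample_id: s for s in samples}
        for stratifier in ("province", "season", "crop"):
            table = ts.build_abundance_table(samples, isolates, stratifier, "species")
            assert int(table.counts.sum()) == len(isolates)
            for s_idx, stratum in enumerate(table.strata):
                expected = sum(
                    getattr(sample_by_id[i.sample_id], stratifier) == stratum
                    for i in isolates
                )
                assert table.counts[s_idx].sum() == expected

    def test_unknown_sample_reference_rejected(self, make_sample):
        samples = [make_sample("A01")]
        isolates = [ts.IsolateRecord("i1", "GHOST", "T. virens", "i1", None)]
        with pytest.raises(ts.IntegrityError, match="GHOST"):
            ts.build_abundance_table(samples, isolates)

    def test_relative_frequencies_rows_sum_to_one(self, small_sim):
        table = ts.build_abundance_table(
            small_sim.samples, small_sim.isolates, "province", "species"
        )
        freqs, undefined = ts.relative_frequencies(table)
        assert undefined == []
        assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-12)
        assert freqs.loc["Zhejiang", "T. harzianum"] == pytest.approx(
            table.to_frame().loc["Zhejiang", "T. harzianum"]
            / table.to_frame().loc["Zhejiang"].sum()
        )

    def test_all_zero_stratum_flagged_not_propagated(self, make_sample):
        samples = [make_sample("A01"), make_sample("B09", province="Anhui")]
        isolates = [ts.IsolateRecord("i1", "A01", "T. virens", "i1", None)]
        table = ts.build_abundance_table(samples, isolates, "province", "species")
        freqs, undefined = ts.relative_frequencies(table)
        assert undefined == ["Anhui"]
        assert freqs.loc["Zhejiang"].sum() == pytest.approx(1.0)


class TestDominanceProfile:
    def test_genus_level_uses_colony_total(self, tiny_survey):
        samples, isolates = tiny_survey
        (result,) = ts.dominance_profile(samples, isolates, level="genus")
        assert result.N == sum(s.total_fungal_colonies for s in samples)
        assert result.n_i == len(isolates)
        assert result.Y == pytest.approx((6 / 180) * (3 / 4))

    def test_species_level_hand_check(self, tiny_survey):
        samples, isolates = tiny_survey
        results = ts.dominance_profile(samples, isolates, level="species")
        by_taxon = {r.taxon: r for r in results}
        ham = by_taxon["T. hamatum"]
        assert (ham.n_i, ham.N, ham.f_i) == (3, 6, 0.5)
        assert ham.Y == pytest.approx(0.25)
        assert [r.Y for r in results] == sorted((r.Y for r in results), reverse=True)

    def test_single_taxon_scope_gives_Y_equal_f(self, make_sample):
        samples = [make_sample("A01"), make_sample("A02")]
        isolates = [ts.IsolateRecord("i1", "A01", "T. virens", "i1", None)]
        (result,) = ts.dominance_profile(samples, isolates, level="species")
        assert result.n_i == result.N == 1
        assert result.Y == pytest.approx(result.f_i) == pytest.approx(0.5)

    def test_scoped_profile_restricts_N_and_f(self, tiny_survey):
        samples, isolates = tiny_survey
        results = ts.dominance_profile(
            samples, isolates, level="species", scope=("province", "Shandong")
        )
        by_taxon = {r.taxon: r for r in results}
        harz = by_taxon["T. harzianum"]
        assert (harz.n_i, harz.N) == (2, 3)   # only Shandong isolates
        assert harz.f_i == 0.5                # 1 of 2 Shandong samples

    def test_empty_scope_rejected(self, tiny_survey):
        samples, isolates = tiny_survey
        with pytest.raises(ts.DomainError):
            ts.dominance_profile(samples, isolates, scope=("province", "Hebei"))

    def test_planted_prevalent_species_dominant_rare_not(self, make_sample):
        samples = [make_sample(f"S{k}") for k in range(10)]
        isolates = []
        for k in range(10):  # common species in every sample
            isolates.append(
                ts.IsolateRecord(f"c{k}", f"S{k}", "T. common", f"c{k}", None)
            )
        isolates.append(ts.IsolateRecord("r0", "S0", "T. rare", "r0", None))
        results = {r.taxon: r for r in ts.dominance_profile(samples, isolates)}
        assert results["T. common"].is_dominant
        assert not results["T. rare"].is_dominant


class TestDiversityProfile:
    def test_whole_survey_haplotype_H(self, small_sim):
        frame = ts.diversity_profile(small_sim.samples, small_sim.isolates,
                                     level="haplotype")
        counts = {}
        for i in small_sim.isolates:
            counts[i.haplotype_code] = counts.get(i.haplotype_code, 0) + 1
        assert frame.loc[0, "H"] == pytest.approx(
            ts.shannon_wiener(list(counts.values()))
        )
        assert frame.loc[0, "k"] == len(counts)

    def test_stratified_scopes_cover_all_provinces(self, small_sim):
        frame = ts.diversity_profile(small_sim.samples, small_sim.isolates,
                                     level="haplotype", by="province")
        assert sorted(frame["scope"]) == [
            "province=Anhui", "province=Jiangsu", "province=Shandong",
            "province=Zhejiang",
        ]
        assert (frame["H"] > 0).all()
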