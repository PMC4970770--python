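import numpy as np
import pytest

import trichosurvey as ts

import oracles


class TestIndicatorMatrix:
    def test_two_regions_one_haplotype_forced_coding(self, make_sample):
        samples = [
            make_sample("A01", region="Hangzhou"),
            make_sample("B01", region="Jinan", province="Shandong", zone="T"),
        ]
        isolates = [ts.IsolateRecord("i1", "A01", "T. hamatum", "i1", "ham1")]
        matrix = ts.build_indicator_matrix(samples, isolates, ["ham1"])
        assert matrix.row_labels == ["Hangzhou", "Jinan"]
        assert matrix.column_labels == ["ham1:present", "ham1:absent"]
        assert matrix.Z.tolist() == [[1, 0], [0, 1]]

    def test_unknown_haplotype_rejected(self, tiny_survey):
        samples, isolates = tiny_survey
        with pytest.raises(ts.ValidationError, match="nope9"):
            ts.build_indicator_matrix(samples, isolates, ["nope9"])

    def test_region_rows_match_survey_design(self, small_sim):
        matrix = ts.build_indicator_matrix(
            small_sim.samples, small_sim.isolates, ["ham1", "harz1"],
            factors=("season", "crop"),
        )
        assert len(matrix.row_labels) == 20  # the 20-region design
        assert matrix.row_labels == sorted(matrix.row_labels)

    def test_cross_rows_are_fully_disjunctive(self, small_sim):
        matrix = ts.build_indicator_matrix(
            small_sim.samples, small_sim.isolates, ["ham1"],
            factors=("season", "crop"), row_mode="region-season-crop",
        )
        assert matrix.is_fully_disjunctive()
        cols = {c: k for k, c in enumerate(matrix.column_labels)}
        season_cols = [cols[c] for c in matrix.variables["season"]]
        assert (matrix.Z[:, season_cols].sum(axis=1) == 1).all()


class TestDecomposition:
    def test_independence_table_has_zero_inertia_and_no_axes(self):
        X = np.outer([10, 20, 30], [1, 2, 3, 4]).astype(float)
        result = ts.correspondence_analysis(X, n_axes=3)
        assert result.total_inertia < 1e-16
        assert result.axis_inertia.size == 0
        assert result.row_coords.shape == (3, 0)

    def test_diagonal_two_by_two_total_inertia_one(self):
        result = ts.correspondence_analysis(np.array([[10, 0], [0, 10]]), n_axes=2)
        assert result.total_inertia == pytest.approx(1.0, abs=1e-12)

    def test_matches_chi_square_and_eigendecomposition_oracles(self):
        rng = np.random.default_rng(77)
        for _ in range(30):
            X = oracles.random_count_table(rng, max_dim=8)
            result = ts.correspondence_analysis(X, n_axes=8)
            assert result.total_inertia == pytest.approx(
                oracles.chi_square_over_n(X), abs=1e-8
            )
            eig = oracles.residual_eigenvalues(X)
            assert np.allclose(
                result.axis_inertia, eig[: result.axis_inertia.size], atol=1e-8
            )

    def test_structural_invariants(self):
        rng = np.random.default_rng(5)
        X = oracles.random_count_table(rng)
        result = ts.correspondence_analysis(X, n_axes=10)
        assert abs(result.axis_inertia.sum() - result.total_inertia) < 1e-10
        assert (np.diff(result.axis_inertia) <= 1e-12).all()
        assert (result.axis_inertia >= 0).all()
        # mass-weighted centroids at the origin
        assert np.abs(result.row_masses @ result.row_coords).max() < 1e-10
        assert np.abs(result.col_masses @ result.col_coords).max() < 1e-10
        # deterministic sign: the largest-|.| column entry per axis is positive
        for axis in range(result.n_axes):
            pivot = np.argmax(np.abs(result.col_coords[:, axis]))
            assert result.col_coords[pivot, axis] > 0

    def test_row_permutation_leaves_coordinates_invariant(self):
        rng = np.random.default_rng(8)
        X = oracles.random_count_table(rng)
        perm = rng.permutation(X.shape[0])
        base = ts.correspondence_analysis(X, n_axes=3)
        shuffled = ts.correspondence_analysis(X[perm], n_axes=3)
        for new_pos, old_pos in enumerate(perm):
            assert np.allclose(
                np.abs(shuffled.row_coords[new_pos]),
                np.abs(base.row_coords[old_pos]),
                atol=1e-10,
            )

    def test_zero_margin_names_offending_label(self):
        import pandas as pd
        X = pd.DataFrame([[1, 0], [2, 0]], index=["r1", "r2"], columns=["good", "dead"])
        with pytest.raises(ts.DegenerateInputError, match="dead"):
            ts.correspondence_analysis(X)

    def test_mca_identity_for_disjunctive_indicator(self, small_sim):
        # pick haplotypes that are present in some regions and absent in
        # others, so every variable keeps both categories
        counts = small_sim.truth.haplotype_counts
        chosen = [c for c, n in sorted(counts.items()) if 3 <= n <= 60][:4]
        assert len(chosen) >= 2
        matrix = ts.build_indicator_matrix(small_sim.samples, small_sim.isolates, chosen)
        assert matrix.is_fully_disjunctive()
        result = ts.correspondence_analysis(matrix, n_axes=2)
        expected = ts.mca_expected_inertia(len(matrix.column_labels), matrix.n_variables)
        assert result.total_inertia == pytest.approx(expected, abs=1e-10)

    def test_burt_coding_squares_the_indicator_inertia_axes(self, small_sim):
        counts = small_sim.truth.haplotype_counts
        chosen = [c for c, n in sorted(counts.items()) if 3 <= n <= 60][:3]
        matrix = ts.build_indicator_matrix(small_sim.samples, small_sim.isolates, chosen)
        ind = ts.correspondence_analysis(matrix, n_axes=5)
        burt = ts.correspondence_analysis(matrix, n_axes=5, coding="burt")
        # Burt-matrix singular values are the squares of the indicator ones
        m = min(ind.singular_values.size, burt.singular_values.size)
        assert np.allclose(
            burt.singular_values[:m], ind.singular_values[:m] ** 2, atol=1e-10
        )
        assert burt.row_labels == matrix.column_labels


class TestBiplotReading:
    def test_distances(self):
        rng = np.random.default_rng(13)
        X = oracles.random_count_table(rng)
        result = ts.correspondence_analysis(X, n_axes=2)
        d = ts.distance_to_category(result, "r0", "c0")
        assert d >= 0
        expected = np.linalg.norm(result.row_coords[0] - result.col_coords[0])
        assert d == pytest.approx(expected, abs=1e-12)
        with pytest.raises(KeyError):
            ts.distance_to_category(result, "r0", "missing")

    def test_distances_on_worked_three_by_three(self):
        X = np.array([[20, 5, 5], [5, 20, 5], [5, 5, 20]], dtype=float)
        result = ts.correspondence_analysis(X, n_axes=2)
        # symmetric table: each row point sits nearest its own column point
        for i in range(3):
            own = ts.distance_to_category(result, f"r{i}", f"c{i}")
            others = [
                ts.distance_to_category(result, f"r{i}", f"c{j}")
                for j in range(3) if j != i
            ]
            assert all(own < other for other in others)

    def test_zone_centroids_simple_cases(self):
        result = ts.correspondence_analysis(
            np.array([[10, 0], [0, 10], [5, 5]]), n_axes=1
        )
        zones = {"r0": "S", "r1": "T", "r2": "B"}
        centroids = ts.zone_centroids(result, zones)
        assert set(centroids) == {"S", "T", "B"}
        assert np.allclose(centroids["S"], result.row_coords[0])
        merged = ts.zone_centroids(result, {"r0": "S", "r1": "S", "r2": "B"})
        assert np.allclose(
            merged["S"], (result.row_coords[0] + result.row_coords[1]) / 2
        )

    def test_missing_zone_assignment_rejected(self):
        result = ts.correspondence_analysis(np.array([[10, 0], [0, 10]]), n_axes=1)
        with pytest.raises(ts.ValidationError, match="r1"):
            ts.zone_centroids(result, {"r0": "S"})

    def test_planted_gradient_separates_zone_centroids(self):
        """Regions sharing a southern-only haplotype split from northern
        regions along axis 1 by more than the within-zone spread."""
        south = [ts.RegionInfo(f"South{k}", "Zhejiang", "S") for k in range(3)]
        north = [ts.RegionInfo(f"North{k}", "Shandong", "T") for k in range(3)]
        config = ts.GeneratorConfig(
            regions=tuple(south + north),
            species_probs={"T. hamatum": 1.0},
            haplotype_probs={"T. hamatum": {"h1": 0.5, "h2": 0.25, "h3": 0.25}},
            haplotype_probs_by_province={
                "Shandong": {"T. hamatum": {"h1": 1.0, "h2": 0.0, "h3": 0.0}}
            },
            n_samples=90,
            colony_mean=30.0,
            occupancy_prob=1.0,
            genus_recovery_prob=0.5,
            sequence_model=ts.SequenceModel(alignment_length=100, n_gap_columns=4),
            seed=21,
        )
        survey = ts.simulate_survey(config)
        matrix = ts.build_indicator_matrix(
            survey.samples, survey.isolates, ["h1", "h2", "h3"]
        )
        result = ts.correspondence_analysis(matrix, n_axes=2)
        zones = {r.region: r.climate_zone for r in config.regions}
        centroids = ts.zone_centroids(result, zones)
        gap = abs(centroids["S"][0] - centroids["T"][0])
        spreads = []
        for label, coords in zip(result.row_labels, result.row_coords):
            spreads.append(abs(coords[0] - centroids[zones[label]][0]))
        assert gap > max(spreads)
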