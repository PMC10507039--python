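import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circkit import specificity as sp

from conftest import make_design


def make_scheme(n_per_class=2):
    design = make_design({ct: n_per_class for ct in sp.FIVE_WAY})
    return sp.CellTypeScheme.from_design(design, "5way", controls_only=False), design


class TestProfiles:
    def test_profile_from_class_means(self):
        scheme, _ = make_scheme(1)
        matrix = pd.DataFrame(
            [[9.0, 0.0, 0.0, 0.0, 0.0]],
            index=["t1"],
            columns=[f"{ct}_0" for ct in sp.FIVE_WAY],
        )
        profiles, _, _, _ = sp.class_mean_profile(matrix, scheme)
        expected = np.array([10, 1, 1, 1, 1]) / 14
        np.testing.assert_allclose(profiles.loc["t1"].to_numpy(), expected)

    def test_all_zero_transcript_is_uniform(self):
        scheme, _ = make_scheme(1)
        matrix = pd.DataFrame(
            [[0.0] * 5], index=["t1"], columns=[f"{ct}_0" for ct in sp.FIVE_WAY]
        )
        profiles, _, _, _ = sp.class_mean_profile(matrix, scheme)
        np.testing.assert_allclose(profiles.loc["t1"].to_numpy(), np.full(5, 0.2))

    def test_sample_permutation_invariance(self):
        scheme, design = make_scheme(3)
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(
            rng.uniform(0, 50, (4, len(design))), columns=design.index,
            index=[f"t{i}" for i in range(4)],
        )
        shuffled = matrix[rng.permutation(matrix.columns)]
        a = sp.class_mean_profile(matrix, scheme)[0]
        b = sp.class_mean_profile(shuffled, scheme)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_profiles_sum_to_one(self):
        scheme, design = make_scheme(2)
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(
            rng.exponential(5, (20, len(design))), columns=design.index,
            index=[f"t{i}" for i in range(20)],
        )
        profiles, _, _, _ = sp.class_mean_profile(matrix, scheme)
        np.testing.assert_allclose(profiles.sum(axis=1), 1.0, atol=1e-12)

    def test_class_without_samples_rejected(self):
        design = make_design({"DA": 2, "TCPY": 2})
        with pytest.raises(ValueError, match="without samples"):
            sp.CellTypeScheme.from_design(design, "5way", controls_only=False)


class TestJSD:
    def test_identity(self):
        assert sp.jsd([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 0.0

    def test_maximal_distance_is_one(self):
        assert sp.jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_vs_unit_five_class(self):
        # H(m) = 1.77095, H(p) = log2 5, H(q) = 0 -> JSD ~ 0.7810
        val = sp.jsd([0.2] * 5, [1, 0, 0, 0, 0])
        assert val == pytest.approx(0.7810, abs=1e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sp.jsd([1.0], [0.5, 0.5])
        with pytest.raises(ValueError):
            sp.jsd([-0.5, 1.5], [0.5, 0.5])
        with pytest.raises(ValueError):
            sp.jsd([0.4, 0.4], [0.5, 0.5])

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(5))
        q = rng.dirichlet(np.ones(5))
        d = sp.jsd(p, q)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(sp.jsd(q, p), abs=1e-12)


class TestScores:
    def test_uniform_profile_score(self):
        profiles = pd.DataFrame([[0.2] * 5], index=["t"], columns=list(sp.FIVE_WAY))
        scores = sp.specificity_scores(profiles)
        np.testing.assert_allclose(scores.loc["t"], 1 - 0.78102, atol=1e-3)

    def test_vectorized_matches_direct_jsd(self):
        rng = np.random.default_rng(3)
        raw = rng.dirichlet(np.ones(5), size=50)
        profiles = pd.DataFrame(raw, columns=list(sp.FIVE_WAY))
        scores = sp.specificity_scores(profiles)
        for i in range(0, 50, 7):
            for ci, cls in enumerate(sp.FIVE_WAY):
                unit = np.zeros(5)
                unit[ci] = 1.0
                assert scores.iloc[i][cls] == pytest.approx(
                    1 - sp.jsd(raw[i], unit), abs=1e-12
                )

    def test_extreme_expression_approaches_one(self):
        scheme, _ = make_scheme(1)
        matrix = pd.DataFrame(
            [[1e9, 0, 0, 0, 0]], index=["t"], columns=[f"{ct}_0" for ct in sp.FIVE_WAY]
        )
        profiles, *_ = sp.class_mean_profile(matrix, scheme)
        scores = sp.specificity_scores(profiles)
        assert scores.loc["t", "DA"] > 0.99

    def test_scale_invariance_of_profile_scores(self):
        base = np.array([11.0, 1.0, 3.0, 1.0, 5.0])
        for scale in (1.0, 7.0, 123.4):
            v = base * scale
            profiles = pd.DataFrame([v / v.sum()], columns=list(sp.FIVE_WAY))
            scores = sp.specificity_scores(profiles)
            ref = sp.specificity_scores(
                pd.DataFrame([base / base.sum()], columns=list(sp.FIVE_WAY))
            )
            np.testing.assert_allclose(scores.to_numpy(), ref.to_numpy(), atol=1e-12)

    def test_best_class_has_largest_profile_entry(self):
        rng = np.random.default_rng(4)
        raw = rng.dirichlet(np.ones(5), size=100)
        profiles = pd.DataFrame(raw, columns=list(sp.FIVE_WAY))
        scores = sp.specificity_scores(profiles)
        best_by_score = scores.to_numpy().argmax(axis=1)
        best_by_profile = raw.argmax(axis=1)
        np.testing.assert_array_equal(best_by_score, best_by_profile)

    def test_monotone_in_target_class_mean(self):
        scheme, _ = make_scheme(1)
        cols = [f"{ct}_0" for ct in sp.FIVE_WAY]
        prev = -1.0
        for da_mean in (1.0, 5.0, 20.0, 100.0, 1000.0):
            matrix = pd.DataFrame([[da_mean, 2, 2, 2, 2]], index=["t"], columns=cols)
            profiles, *_ = sp.class_mean_profile(matrix, scheme)
            s = sp.specificity_scores(profiles).loc["t", "DA"]
            assert s > prev
            prev = s


class TestClassification:
    def _inputs(self, s_value, class_mean, overall_mean, overall_sd):
        scores = pd.DataFrame({"DA": [s_value]}, index=["t"])
        means = pd.DataFrame({"DA": [class_mean]}, index=["t"])
        return scores, means, pd.Series({"t": overall_mean}), pd.Series({"t": overall_sd})

    def test_both_conditions_met(self):
        flags = sp.classify_specific(*self._inputs(0.9, 100.0, 20.0, 30.0))
        assert flags.loc["t", "DA"]

    def test_score_threshold_binds(self):
        flags = sp.classify_specific(*self._inputs(0.49, 1e6, 0.0, 0.0))
        assert not flags.loc["t", "DA"]

    def test_expression_gate_binds(self):
        flags = sp.classify_specific(*self._inputs(0.9, 49.0, 20.0, 30.0))
        assert not flags.loc["t", "DA"]


class TestCircVsLinear:
    def _result(self, matrix, scheme):
        return sp.score_matrix(matrix, scheme)

    def test_identical_matrices_give_p_one(self):
        scheme, design = make_scheme(2)
        rng = np.random.default_rng(5)
        matrix = pd.DataFrame(
            rng.uniform(1, 30, (10, len(design))), columns=design.index,
            index=[f"t{i}" for i in range(10)],
        )
        circ = self._result(matrix, scheme)
        linear = self._result(matrix.rename(index=lambda t: t.replace("t", "L")), scheme)
        locus_map = pd.Series({f"t{i}": f"L{i}" for i in range(10)})
        res = sp.compare_circ_vs_linear(circ, linear, locus_map)
        assert res["p"] == 1.0
        assert res["median_diff"] == 0.0

    def test_planted_specific_circles_beat_flat_linear(self):
        from circkit.quantify import rpm_normalize
        from circkit.simulate import SimulationConfig, simulate_counts, simulate_gene_models

        config = SimulationConfig(
            seed=21, n_genes=220, n_junctions=220, frac_specific=0.2,
            condition_split=0.0, frac_cirna=0.0,
            samples_per_cell_type={ct: 6 for ct in sp.FIVE_WAY},
        )
        models, hosts = simulate_gene_models(config)
        counts, linear, design, truth = simulate_counts(models, config, hosts)
        scheme = sp.CellTypeScheme.from_design(design)
        circ = self._result(rpm_normalize(counts, design), scheme)
        lin = self._result(rpm_normalize(linear, design), scheme)
        locus_map = pd.Series(truth.junction_host)
        res = sp.compare_circ_vs_linear(circ, lin, locus_map)
        assert res["median_diff"] > 0
        assert res["p"] < 0.01

    def test_single_circ_restriction_is_subset(self):
        from circkit.quantify import rpm_normalize
        from circkit.simulate import SimulationConfig, simulate_counts, simulate_gene_models

        config = SimulationConfig(
            seed=33, n_genes=80, n_junctions=40, condition_split=0.0,
            samples_per_cell_type={ct: 3 for ct in sp.FIVE_WAY},
        )
        models, hosts = simulate_gene_models(config)
        counts, linear, design, truth = simulate_counts(models, config, hosts)
        scheme = sp.CellTypeScheme.from_design(design)
        circ = self._result(rpm_normalize(counts, design), scheme)
        lin = self._result(rpm_normalize(linear, design), scheme)
        locus_map = pd.Series(truth.junction_host)
        assert locus_map.value_counts().eq(1).any()  # singleton hosts exist
        full = sp.compare_circ_vs_linear(circ, lin, locus_map)
        single = sp.compare_circ_vs_linear(circ, lin, locus_map, single_circ_only=True)
        assert len(single["table"]) <= len(full["table"])
        assert set(single["table"]["transcript"]) <= set(full["table"]["transcript"])
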