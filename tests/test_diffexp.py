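import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from circkit import diffexp
from circkit.simulate import nb_draw


def make_de_design(n_per_group, seed=0, conditions=("HC", "ILB")):
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        for i in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{cond}_{i}",
                    "cell_type": "DA",
                    "condition": cond,
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "age": float(rng.normal(75, 8)),
                    "PMI": float(rng.uniform(2, 30)),
                    "RIN": float(rng.uniform(6, 9.5)),
                    "library_size": int(rng.integers(1_000_000, 2_000_000)),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_gene_matrix(design, n_genes, base_mean=20.0, alpha=0.1,
                         lfc=None, seed=1):
    """NB counts with an optional planted log2 fold in the ILB samples."""
    rng = np.random.default_rng(seed)
    is_alt = (design["condition"] == "ILB").to_numpy()
    mean = np.full((n_genes, len(design)), base_mean)
    if lfc is not None:
        mean[:, is_alt] *= 2.0 ** np.asarray(lfc)[:, None]
    counts = nb_draw(rng, mean, alpha)
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                        columns=design.index)


class TestAggregation:
    def test_junction_counts_sum_per_gene(self):
        counts = pd.DataFrame({"s1": [5, 7, 2], "s2": [1, 0, 3]},
                              index=["j1", "j2", "j3"])
        hosts = pd.Series({"j1": "G", "j2": "G", "j3": "H"})
        agg = diffexp.aggregate_gene_counts(counts, hosts)
        assert agg.loc["G"].tolist() == [12, 1]
        assert agg.loc["H"].tolist() == [2, 3]

    def test_single_junction_gene_unchanged(self):
        counts = pd.DataFrame({"s1": [4]}, index=["j1"])
        agg = diffexp.aggregate_gene_counts(counts, pd.Series({"j1": "G"}))
        assert agg.loc["G", "s1"] == 4

    def test_orphan_junctions_excluded_and_order_invariant(self):
        counts = pd.DataFrame({"s1": [5, 7, 9]}, index=["j1", "j2", "j3"])
        hosts = pd.Series({"j1": "G", "j2": "G"})
        agg = diffexp.aggregate_gene_counts(counts, hosts)
        assert list(agg.index) == ["G"]
        shuffled = diffexp.aggregate_gene_counts(counts.iloc[[2, 0, 1]], hosts)
        pd.testing.assert_frame_equal(agg, shuffled)


class TestSizeFactors:
    def test_two_sample_doubling(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = diffexp.size_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20], "b": [10, 20], "c": [10, 20]})
        np.testing.assert_allclose(diffexp.size_factors(counts).to_numpy(), 1.0)

    def test_scaling_one_column(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(rng.integers(5, 100, (50, 3)), columns=list("abc"))
        f0 = diffexp.size_factors(base)
        scaled = base.copy()
        scaled["c"] = scaled["c"] * 4
        f1 = diffexp.size_factors(scaled)
        # c's factor grows ~4x relative to the others, up to renormalization
        assert f1["c"] / f0["c"] == pytest.approx(4 ** (2 / 3), rel=1e-6)

    def test_fallback_warns_without_all_positive_row(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.warns(UserWarning, match="total-count"):
            f = diffexp.size_factors(counts)
        np.testing.assert_allclose(f.to_numpy(), 1.0)


class TestDesignMatrix:
    def test_rank_deficiency_names_columns(self):
        design = make_de_design(4)
        design["PMI"] = design["age"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="PMI"):
            diffexp.build_design_matrix(design, ("ILB", "HC"))

    def test_too_few_samples_per_level_rejected(self):
        design = make_de_design(4).iloc[:5]  # 4 HC + 1 ILB
        with pytest.raises(ValueError, match="fewer than 2"):
            diffexp.build_design_matrix(design, ("ILB", "HC"))


class TestNBWald:
    def test_effect_recovery_and_sign(self):
        """A planted 2x fold is recovered as log2FC ~ 1 at large n, and the
        Wald statistic carries the sign of the fold."""
        design = make_de_design(100, seed=3)
        lfc = np.concatenate([np.ones(5), -np.ones(5), np.zeros(5)])
        counts = simulate_gene_matrix(design, 15, base_mean=50.0, alpha=0.05,
                                      lfc=lfc, seed=4)
        factors = pd.Series(1.0, index=design.index)
        res = diffexp.nb_wald(counts, design, factors=factors)
        np.testing.assert_allclose(
            res["log2FoldChange"].to_numpy()[:10], lfc[:10], atol=0.15
        )
        assert (np.sign(res["stat"]) == np.sign(res["log2FoldChange"])).all()

    def test_sample_order_invariance(self):
        design = make_de_design(10, seed=5)
        counts = simulate_gene_matrix(design, 8, seed=6)
        res_a = diffexp.nb_wald(counts, design)
        perm = np.random.default_rng(7).permutation(design.index)
        res_b = diffexp.nb_wald(counts[perm], design.loc[perm])
        pd.testing.assert_frame_equal(res_a, res_b, rtol=1e-6)

    def test_all_zero_genes_skipped(self):
        design = make_de_design(5, seed=8)
        counts = simulate_gene_matrix(design, 3, seed=9)
        counts.iloc[1] = 0
        res = diffexp.nb_wald(counts, design)
        assert "g1" not in res.index and len(res) == 2

    def test_poisson_limit_agreement(self):
        """With Poisson data the NB Wald statistic converges to the Poisson
        GLM Wald statistic (dispersion floored near zero)."""
        design = make_de_design(200, seed=10)
        rng = np.random.default_rng(11)
        y = rng.poisson(40.0, len(design)).astype(float)
        counts = pd.DataFrame([y], index=["g0"], columns=design.index)
        factors = pd.Series(1.0, index=design.index)
        res = diffexp.nb_wald(counts, design, factors=factors)
        X_df, _ = diffexp.build_design_matrix(design, ("ILB", "HC"))
        pois = sm.GLM(y, X_df.to_numpy(), family=sm.families.Poisson()).fit()
        j = list(X_df.columns).index("condition[ILB]")
        pois_stat = pois.params[j] / pois.bse[j]
        assert res.loc["g0", "stat"] == pytest.approx(pois_stat, rel=0.05)


class TestStageAssociation:
    def _stage_counts(self, n_per_stage=15, effect=0.3, seed=12, n_stages=5):
        rng = np.random.default_rng(seed)
        rows = []
        stages = []
        for s in range(n_stages):
            for i in range(n_per_stage):
                rows.append(
                    {
                        "sample_id": f"st{s}_{i}",
                        "cell_type": "DA",
                        "condition": "HC",
                        "sex": "M" if rng.random() < 0.5 else "F",
                        "age": float(rng.normal(75, 8)),
                        "PMI": float(rng.uniform(2, 30)),
                        "RIN": float(rng.uniform(6, 9.5)),
                        "library_size": 1_000_000,
                    }
                )
                stages.append(s)
        design = pd.DataFrame(rows).set_index("sample_id")
        stage = pd.Series(stages, index=design.index, dtype=float)
        mean = 20.0 * np.exp(effect * stage.to_numpy())
        counts = pd.DataFrame(
            nb_draw(rng, np.tile(mean, (5, 1)), 0.1),
            index=[f"g{i}" for i in range(5)], columns=design.index,
        )
        return counts, design, stage

    def test_planted_trend_detected(self):
        counts, design, stage = self._stage_counts(effect=0.3, seed=13)
        # equal library sizes: unit size factors isolate the planted trend
        # (all genes trend together, which normalization would absorb)
        factors = pd.Series(1.0, index=design.index)
        res = diffexp.stage_association(counts, design, stage, factors=factors)
        assert (res["pvalue"] < 0.05).all()
        assert (res["slope"] > 0).all()
        assert res["suggestive"].all()

    def test_constant_stage_rejected(self):
        counts, design, stage = self._stage_counts(seed=14)
        with pytest.raises(ValueError, match="distinct stages"):
            diffexp.stage_association(counts, design, stage * 0.0)

    def test_two_stages_rejected(self):
        counts, design, stage = self._stage_counts(seed=15, n_stages=2)
        with pytest.raises(ValueError, match="distinct stages"):
            diffexp.stage_association(counts, design, stage)
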