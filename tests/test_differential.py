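import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelconcord.differential import (
    candidate_flag,
    differential_expression,
    fisher_exact_2x2,
    fold_change_concordance,
    select_analysis_samples,
    welch_t_test,
)
from panelconcord.exceptions import ConsistencyError, ParameterError
from panelconcord.normalization import log2_floor
from panelconcord.synthetic import PANEL_B, generate_panel_matrix, generate_truth

from conftest import make_matrix
from test_synthetic import noise_free_config


class TestSelectAnalysisSamples:
    def test_primary_only_subject(self, small_metadata):
        chosen = select_analysis_samples(small_metadata)
        assert sorted(chosen) == ["S1.e1m1", "S2.e1m1", "S3.e1m1", "S4.e1m1"]

    def test_first_extract_first_measurement_wins(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["x.e1m1", "x.e1m2", "x.e2m1"],
                "subject_id": ["x"] * 3,
                "her2_ihc": ["3+"] * 3,
                "group": ["HER2+"] * 3,
                "replicate_kind": ["primary", "technical", "extract"],
                "extract": [1, 1, 2],
                "order_index": [1, 2, 3],
            }
        )
        assert select_analysis_samples(meta) == ["x.e1m1"]

    def test_synthetic_metadata_one_per_subject(self, default_panels):
        meta = default_panels["meta"]
        chosen = select_analysis_samples(meta)
        assert len(chosen) == 20
        subj = meta.set_index("sample_id").loc[chosen, "subject_id"]
        assert subj.is_unique


class TestWelchTTest:
    def test_identical_constant_groups(self):
        res = welch_t_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_scipy_oracle(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = welch_t_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert abs(res.t - ref.statistic) < 1e-10
        assert abs(res.p - ref.pvalue) < 1e-10
        assert abs(res.df - ref.df) < 1e-10

    def test_equal_variance_equal_n_df_closed_form(self):
        rng = np.random.default_rng(1)
        shift = rng.normal(size=1)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t_test(a, a + shift)  # identical spread
        assert res.df == pytest.approx(2 * len(a) - 2)

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_df_within_welch_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(size=rng.integers(2, 10))
            res = welch_t_test(a, b)
            assert min(len(a), len(b)) - 1 <= res.df + 1e-9
            assert res.df <= len(a) + len(b) - 2 + 1e-9
            assert 0 < res.p <= 1


class TestCandidacyRules:
    def test_reported_strong_gene_is_candidate(self):
        assert candidate_flag(0.00002, 1.560, "gene")

    def test_reported_weak_gene_is_not(self):
        assert not candidate_flag(0.46187, 0.173, "gene")

    def test_probe_rule_is_stricter(self):
        assert not candidate_flag(0.02, 1.2, "probe")
        assert candidate_flag(0.005, -1.2, "probe")
        assert not candidate_flag(0.005, 1.0, "probe")  # strict inequality


class TestDifferentialExpression:
    def test_noise_free_flagship_exact_and_first(self):
        cfg = noise_free_config(erbb2_fc=1.5)
        truth = generate_truth(cfg)
        mat, _, meta = generate_panel_matrix(truth, cfg, PANEL_B)
        matches = pd.DataFrame(
            {
                "gene_key": truth.gene_ids,
                "panelA_symbol": truth.gene_ids,
                "panelB_symbol": truth.gene_ids,
                "tier": 1,
                "panelA_probe_ids": "",
                "panelB_probe_ids": [
                    ";".join(truth.probes_b.loc[truth.probes_b["gene"] == g, "probe_id"])
                    for g in truth.gene_ids
                ],
            }
        )
        from panelconcord.matching import summarize_gene_level

        gene_mat = summarize_gene_level(log2_floor(mat), matches, "B")
        table = differential_expression(gene_mat, meta, "gene")
        assert table.iloc[0]["unit_id"] == truth.flagship_gene
        assert table.iloc[0]["log2fc"] == pytest.approx(1.5, abs=1e-9)
        assert bool(table.iloc[0]["candidate"])

    def test_too_small_group_rejected(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "subject_id": ["a", "b", "c"],
                "her2_ihc": ["3+", "0", "0"],
                "group": ["HER2+", "HER2-", "HER2-"],
                "replicate_kind": ["primary"] * 3,
                "extract": [1, 1, 1],
                "order_index": [1, 1, 1],
            }
        )
        mat = make_matrix(np.random.default_rng(0).normal(8, 1, (5, 3)))
        mat.values.columns = ["a", "b", "c"]
        with pytest.raises(ParameterError, match="HER2"):
            differential_expression(mat, meta, "gene")


class TestFoldChangeConcordance:
    def de_table(self, fc):
        return pd.DataFrame(
            {"unit_id": [f"g{i}" for i in range(len(fc))], "log2fc": fc}
        )

    def test_perfect_agreement(self):
        fc = np.array([0.5, -1.0, 2.0])
        curve = fold_change_concordance(
            self.de_table(fc), self.de_table(fc), thresholds=[0.0]
        )
        assert curve.iloc[0]["proportion_concordant"] == 1.0

    def test_perfect_disagreement(self):
        fc = np.array([0.5, -1.0, 2.0])
        curve = fold_change_concordance(
            self.de_table(fc), self.de_table(-fc), thresholds=[0.0]
        )
        assert curve.iloc[0]["proportion_concordant"] == 0.0

    def test_partition_identity_and_monotonicity(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 0.6, 300), rng.normal(0, 0.6, 300)
        curve = fold_change_concordance(self.de_table(a), self.de_table(b))
        assert (
            curve["up_up"] + curve["down_down"] + curve["discordant"]
            == curve["n_retained"]
        ).all()
        assert (np.diff(curve["n_retained"]) <= 0).all()

    def test_independent_null_is_half(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=10_000), rng.normal(size=10_000)
        curve = fold_change_concordance(self.de_table(a), self.de_table(b), [0.0])
        assert curve.iloc[0]["proportion_concordant"] == pytest.approx(0.50, abs=0.02)

    def test_disjoint_keys_error(self):
        a = self.de_table(np.ones(3))
        b = self.de_table(np.ones(3))
        b["unit_id"] = ["x1", "x2", "x3"]
        with pytest.raises(ConsistencyError):
            fold_change_concordance(a, b)


class TestFisherExact:
    def test_diagonal_unit_table(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_extreme_table_by_enumeration(self):
        # margins (5,5)/(5,5): enumerate all tables directly
        from math import comb

        total, row1, col1 = 10, 5, 5
        probs = [
            comb(col1, k) * comb(total - col1, row1 - k) / comb(total, row1)
            for k in range(0, 6)
        ]
        p_obs = probs[5]
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(expected, abs=1e-12)

    def test_reported_esr1_her2_table(self):
        assert round(fisher_exact_2x2([[11, 2], [2, 5]]), 3) == 0.022

    def test_margin_and_sign_validation(self):
        with pytest.raises(ParameterError):
            fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ParameterError):
            fisher_exact_2x2([[0, 0], [1, 2]])


def test_permutation_null_type_I_error():
    """Null genes: rejection rate at alpha=0.05 stays near 0.05."""
    rng = np.random.default_rng(42)
    n_genes = 2000
    vals = rng.normal(8.0, 0.5, size=(n_genes, 20))
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(20)],
            "subject_id": [f"s{j}" for j in range(20)],
            "her2_ihc": ["3+"] * 9 + ["0"] * 11,
            "group": ["HER2+"] * 9 + ["HER2-"] * 11,
            "replicate_kind": ["primary"] * 20,
            "extract": [1] * 20,
            "order_index": [1] * 20,
        }
    )
    mat = make_matrix(vals)
    mat.values.columns = meta["sample_id"]
    table = differential_expression(mat, meta, "gene")
    rate = (table["p"] < 0.05).mean()
    assert abs(rate - 0.05) <= 0.02
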