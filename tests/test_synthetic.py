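import numpy as np
import pandas as pd
import pytest

from panelconcord.exceptions import ConfigurationError, ParameterError
from panelconcord.synthetic import (
    PANEL_A,
    PANEL_B,
    SimulationConfig,
    generate_interaction_graph,
    generate_panel_matrix,
    generate_truth,
)


def noise_free_config(**kw):
    base = dict(
        n_genes=20,
        n_pos=4,
        n_neg=4,
        n_tech_rep=2,
        n_extract_rep=2,
        n_overlap_rep=1,
        sigma_tech_a=0.0,
        sigma_tech_b=0.0,
        sigma_extract_a=0.0,
        sigma_extract_b=0.0,
        sigma_probe=0.0,
        sigma_bio=0.0,
        de_fraction=0.0,
        n_seq_matched=3,
        bias_params={"d_max": 0.0, "k": 1.0, "a0": 7.5},
        seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw,msg",
        [
            ({"n_genes": 0}, "n_genes"),
            ({"probes_per_gene_b_dist": {1: 0.5, 2: 0.4}}, "sum to 1"),
            ({"n_overlap_rep": 9}, "n_overlap_rep"),
            ({"n_pos": 1, "n_neg": 2}, "at least 4"),
            ({"sigma_bio": -0.1}, "sigma_bio"),
            ({"fc_range": (-0.5, 1.0)}, "fc_range"),
            ({"sigma_extract_a": 0.1}, "sigma_extract"),
            ({"de_fraction": 1.5}, "de_fraction"),
        ],
    )
    def test_invalid_configs_name_the_field(self, kw, msg):
        with pytest.raises(ConfigurationError, match=msg):
            SimulationConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_genes: 12\nseed: 5\nde_fraction: 0.0\nn_seq_matched: 2\n")
        cfg = SimulationConfig.from_file(path)
        assert cfg.n_genes == 12 and cfg.seed == 5


class TestTruth:
    def test_zero_de_fraction_leaves_only_flagship(self):
        truth = generate_truth(
            SimulationConfig(n_genes=10, de_fraction=0.0, n_seq_matched=2, seed=1)
        )
        nonzero = np.flatnonzero(truth.beta)
        assert list(nonzero) == [truth.gene_ids.index(truth.flagship_gene)]

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=30, seed=9)
        t1, t2 = generate_truth(cfg), generate_truth(cfg)
        np.testing.assert_array_equal(t1.beta, t2.beta)
        np.testing.assert_array_equal(t1.mu, t2.mu)
        pd.testing.assert_frame_equal(t1.probes_b, t2.probes_b)
        assert t1.tier == t2.tier

    def test_de_count_matches_fraction_by_enumeration(self):
        truth = generate_truth(SimulationConfig(n_genes=498, de_fraction=0.1, seed=1))
        flag_idx = truth.gene_ids.index(truth.flagship_gene)
        n_de_others = sum(
            1 for i, b in enumerate(truth.beta) if b != 0 and i != flag_idx
        )
        assert n_de_others == round(0.1 * 498) == 50
        assert truth.beta[flag_idx] == 1.5

    def test_tier_sets_disjoint_and_exhaustive(self, default_truth, default_config):
        tiers = pd.Series(default_truth.tier)
        counts = tiers.value_counts().to_dict()
        assert counts[2] == round(default_config.alias_fractions[0] * 498) == 27
        assert counts[3] == round(default_config.alias_fractions[1] * 498) == 5
        assert counts[1] == 498 - 27 - 5
        assert len(tiers) == 498

    def test_probe_offsets_are_contrasts(self, default_truth):
        for probes in (default_truth.probes_a, default_truth.probes_b):
            per_gene = probes.groupby("gene")["offset"].mean()
            np.testing.assert_allclose(per_gene.to_numpy(), 0.0, atol=1e-12)


class TestPanelMatrix:
    def test_noise_free_flagship_recovery(self):
        cfg = noise_free_config(erbb2_fc=1.5)
        truth = generate_truth(cfg)
        mat, _, meta = generate_panel_matrix(truth, cfg, PANEL_B)
        log2 = np.log2(mat.values)
        flag_probes = truth.probes_b[truth.probes_b["gene"] == truth.flagship_gene][
            "probe_id"
        ]
        pos = meta.loc[meta["group"] == "HER2+", "sample_id"]
        neg = meta.loc[meta["group"] == "HER2-", "sample_id"]
        diff = (
            log2.loc[flag_probes, pos].mean(axis=1)
            - log2.loc[flag_probes, neg].mean(axis=1)
        )
        np.testing.assert_allclose(diff.to_numpy(), 1.5, rtol=1e-12)

    def test_dimension_bookkeeping(self, default_config, default_truth, default_panels):
        mat_a, _ = default_panels["A"]
        c = default_config
        assert mat_a.values.shape[0] == c.n_genes * c.probes_per_gene_a
        assert (
            mat_a.values.shape[1]
            == c.n_pos + c.n_neg + c.n_tech_rep + c.n_extract_rep
        )
        assert (mat_a.values.to_numpy() > 0).all()

    def test_unknown_panel_id_rejected(self, default_config, default_truth):
        with pytest.raises(ParameterError, match="panel"):
            generate_panel_matrix(default_truth, default_config, "96K")

    def test_technical_replicate_sd_converges_to_sqrt2_sigma(self):
        """Monte-Carlo vs the closed form sqrt(2)*sigma over >=20 seeds."""
        sigma = 0.15
        sds = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, sigma_tech_b=sigma, sigma_extract_b=sigma)
            truth = generate_truth(cfg)
            mat, _, meta = generate_panel_matrix(truth, cfg, PANEL_B)
            log2 = np.log2(mat.values)
            tech = meta[meta["replicate_kind"] == "technical"]
            for row in tech.itertuples(index=False):
                primary = f"{row.subject_id}.e1m1"
                d = log2[primary] - log2[row.sample_id]
                sds.append(d.std(ddof=1))
        assert abs(np.mean(sds) - sigma * np.sqrt(2)) / (sigma * np.sqrt(2)) < 0.10

    def test_seq_matched_pairs_are_true_substrings(self, default_truth):
        seqs_a = default_truth.probes_a.set_index("probe_id")["sequence"]
        seqs_b = default_truth.probes_b.set_index("probe_id")["sequence"]
        assert len(default_truth.seq_matched_pairs) == 17
        for row in default_truth.seq_matched_pairs.itertuples(index=False):
            a, b = seqs_a[row.panelA_probe_id], seqs_b[row.panelB_probe_id]
            assert b[row.offset : row.offset + len(a)] == a


class TestInteractionGraph:
    def test_minimal_two_de_one_hub(self):
        cfg = noise_free_config(n_hubs=1, n_distractors=0, de_fraction=0.1, n_genes=11)
        truth = generate_truth(cfg)
        de1, de2 = truth.de_genes[0], truth.de_genes[1]
        g = generate_interaction_graph(truth, cfg)
        hub = truth.hub_genes[0]
        for u, v in [(de1, hub), (hub, de2), (de2, hub), (hub, de1)]:
            assert g.has_edge(u, v)

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=40, de_fraction=0.2, seed=4)
        truth = generate_truth(cfg)
        g1 = generate_interaction_graph(truth, cfg)
        g2 = generate_interaction_graph(truth, cfg)
        assert list(g1.edges(data=True)) == list(g2.edges(data=True))

    def test_all_de_pairs_within_two_steps(self):
        cfg = SimulationConfig(n_genes=100, de_fraction=0.07, seed=7, n_hubs=3)
        truth = generate_truth(cfg)
        g = generate_interaction_graph(truth, cfg)
        # brute-force: direct edge or a shared intermediate
        for u in truth.de_genes:
            for v in truth.de_genes:
                if u == v:
                    continue
                two_step = any(g.has_edge(u, w) and g.has_edge(w, v) for w in g.nodes)
                assert g.has_edge(u, v) or two_step
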