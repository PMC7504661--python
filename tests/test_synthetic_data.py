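import dataclasses
import json

import numpy as np
import pytest
from scipy import stats

from netsig import data_io
from netsig.synthetic_data import (
    SimulationConfig,
    SyntheticTruth,
    simulate_all,
    simulate_drug_screen,
    simulate_expression,
    simulate_pathways,
    simulate_regulatory_network,
    write_dataset,
)
from netsig.upstream_signaling import score_and_prune


class TestConfigValidation:
    @pytest.mark.parametrize(
        "override",
        [
            {"n_genes": 0},
            {"n_tumor": -2},
            {"tf_flip_noise": 1.5},
            {"synergy_fraction": -0.1},
            {"planted_fold": 1.5},
            {"targets_per_tf": (5, 2)},
            {"n_tfs": 2},  # < n_subgroups * active_tfs_per_group
            {"group_proportions": (0.5, 0.5)},
        ],
    )
    def test_invalid_configs_rejected(self, override):
        with pytest.raises(ValueError):
            SimulationConfig(**override)

    def test_infeasible_target_allocation_reported(self):
        with pytest.raises(ValueError, match="infeasible target allocation"):
            simulate_regulatory_network(
                SimulationConfig(n_genes=10, n_tfs=6, targets_per_tf=(5, 5))
            )


class TestDeterminism:
    def test_identical_seed_identical_files(self, small_config, tmp_path):
        d1 = tmp_path / "run1"
        d2 = tmp_path / "run2"
        p1 = write_dataset(simulate_all(small_config), d1)
        p2 = write_dataset(simulate_all(small_config), d2)
        for key in p1:
            f1, f2 = p1[key], p2[key]
            if f1.is_file():
                assert f1.read_bytes() == f2.read_bytes(), key

    def test_different_seed_differs(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a = simulate_all(small_config)
        b = simulate_all(other)
        assert not np.array_equal(a.control.values, b.control.values)

    def test_truth_json_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "truth.json"
        small_dataset.truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        assert back.upregulated == small_dataset.truth.upregulated
        assert back.planted_cascades == small_dataset.truth.planted_cascades
        assert back.synergy_pairs == small_dataset.truth.synergy_pairs


class TestExpression:
    def test_zero_noise_planted_genes_exceed_double(self):
        config = SimulationConfig(
            n_normal=10, n_tumor=12, n_genes=60, n_tfs=6, targets_per_tf=(4, 5),
            noise_sd=0.0, planted_fold=4.0, seed=2,
        )
        control, tumor, truth = simulate_expression(config)
        cmeans = dict(zip(control.genes, control.values.mean(axis=1)))
        tframe = tumor.to_frame()
        for sample, planted in truth.upregulated.items():
            for gene in planted:
                assert tframe.at[gene, sample] > 2 * cmeans[gene]

    def test_planted_mean_near_fold_times_control(self):
        config = SimulationConfig(
            n_normal=88, n_tumor=200, n_genes=40, n_tfs=6, targets_per_tf=(4, 5),
            noise_sd=1.0, planted_fold=4.0, seed=3, active_tfs_per_group=2,
        )
        control, tumor, truth = simulate_expression(config)
        gene = sorted(truth.upregulated[sorted(truth.upregulated)[0]])[0]
        tframe = tumor.to_frame()
        vals = [
            tframe.at[gene, s] for s, planted in truth.upregulated.items() if gene in planted
        ]
        assert len(vals) > 20
        cvals = control.values[control.genes.index(gene)]
        # the control mean is itself an estimate: propagate both standard errors
        se = np.sqrt(np.var(vals, ddof=1) / len(vals) + 16 * np.var(cvals, ddof=1) / len(cvals))
        assert abs(np.mean(vals) - 4 * cvals.mean()) < 3 * se

    def test_every_planted_gene_in_matrix(self, small_dataset):
        genes = set(small_dataset.tumor.genes)
        for planted in small_dataset.truth.upregulated.values():
            assert planted <= genes


class TestRegulatoryNetwork:
    def test_fixed_target_count(self):
        config = SimulationConfig(n_genes=200, n_tfs=8, targets_per_tf=(10, 10))
        net, _ = simulate_regulatory_network(config)
        for tf in net.tfs:
            assert len(net.targets_of(tf)) == 10

    def test_same_seed_identical_edges(self, small_config):
        n1, _ = simulate_regulatory_network(small_config)
        n2, _ = simulate_regulatory_network(small_config)
        assert n1.edges == n2.edges

    def test_shared_core_tfs_active_in_every_group(self):
        config = SimulationConfig(n_genes=250, n_tfs=10, shared_active_tfs=2)
        net, truth = simulate_regulatory_network(config)
        core = set.intersection(*truth.active_tfs.values())
        assert core == {"TF00", "TF01"}
        specific = [truth.active_tfs[g] - core for g in truth.active_tfs]
        assert all(len(s) == 2 for s in specific)
        for a, b in zip(specific, specific[1:]):
            assert not a & b

    def test_planted_tf_enrichment_detectable(self):
        """A planted active TF with all targets up-regulated beats alpha by
        the exact hypergeometric tail sum."""
        from math import comb

        config = SimulationConfig(n_genes=200, n_tfs=8, targets_per_tf=(20, 20))
        net, truth = simulate_regulatory_network(config)
        tf = sorted(truth.active_tfs[0])[0]
        targets = net.targets_of(tf)
        N, K = 200, len(targets)
        m, k = K, K  # the group's up-set contains every target
        tail = sum(comb(K, i) * comb(N - K, m - i) for i in range(k, K + 1)) / comb(N, m)
        assert tail < 0.05


class TestPathways:
    def test_fixed_cascade_length(self):
        config = SimulationConfig(
            n_genes=120, n_tfs=8, targets_per_tf=(6, 8), cascade_length=(3, 3)
        )
        net, truth = simulate_regulatory_network(config)
        _, truth = simulate_pathways(config, net, truth)
        for casc in truth.planted_cascades:
            assert len(casc) == 4  # 3 edges

    def test_sif_roundtrip_isomorphic(self, small_dataset, tmp_path):
        for pw in small_dataset.pathways:
            path = tmp_path / f"{pw.pathway_id}.sif"
            data_io.write_pathway_sif(pw, path)
            back = data_io.read_pathway_sif(path)
            assert back.edges_with_signs() == pw.edges_with_signs()

    def test_planted_path_is_top_ranked_by_exhaustive_scoring(self, small_dataset):
        probs = {g: 1.0 for casc in small_dataset.truth.planted_cascades for g in casc}
        for pw, casc in zip(small_dataset.pathways, small_dataset.truth.planted_cascades):
            tf = casc[-1]
            from netsig.upstream_signaling import enumerate_cascades, start_nodes

            paths = enumerate_cascades(pw, start_nodes(pw), tf)
            retained = score_and_prune([(pw.pathway_id, p) for p in paths], probs, top_k=1)
            assert retained[0].nodes == casc

    def test_terminal_node_is_a_tf(self, small_dataset):
        tfs = {tf for s in small_dataset.truth.active_tfs.values() for tf in s}
        for casc in small_dataset.truth.planted_cascades:
            assert casc[-1] in tfs


class TestDrugScreen:
    def _screen(self, fraction, seed=0, n_drugs=40):
        config = SimulationConfig(
            n_genes=150, n_tfs=8, targets_per_tf=(6, 8), n_drugs=n_drugs,
            synergy_fraction=fraction, seed=seed,
        )
        net, truth = simulate_regulatory_network(config)
        pathways, truth = simulate_pathways(config, net, truth)
        return simulate_drug_screen(config, pathways, truth)

    def test_fraction_zero_no_synergy(self):
        _, records, truth = self._screen(0.0)
        assert all(r.score <= 8 for r in records)
        assert truth.synergy_pairs == set()

    def test_fraction_one_all_synergy(self):
        _, records, truth = self._screen(1.0)
        assert all(r.score > 8 for r in records)
        assert len(truth.synergy_pairs) == len(records)

    def test_observed_fraction_in_binomial_interval(self):
        # ~0.2 of >= 378 pairs synergistic; check the exact binomial 99% band
        catalog, records, truth = self._screen(0.2, seed=7, n_drugs=40)
        n = len(records)
        assert n >= 300
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.2)
        assert lo <= len(truth.synergy_pairs) <= hi

    def test_all_outputs_parse_through_data_io(self, small_dataset, tmp_path):
        import warnings

        paths = write_dataset(small_dataset, tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            data_io.read_expression_matrix(paths["control"])
            data_io.read_expression_matrix(paths["tumor"])
            data_io.read_regulatory_network(paths["network"])
            data_io.read_pathway_dir(paths["pathways_dir"])
            data_io.read_drug_catalog(paths["drugs"])
            data_io.read_synergy_table(paths["synergy"])
            json.loads(paths["truth"].read_text())
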