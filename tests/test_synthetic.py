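"""Synthetic universe: interactome shape, planted module, seeds, fixtures."""

import json

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from pbcnet.enrichment import read_gmt
from pbcnet.errors import ConfigurationError
from pbcnet.interactome import read_edge_list
from pbcnet.synthetic import (
    SyntheticConfig,
    generate_annotation_collection,
    generate_bundle,
    generate_interactome,
    plant_disease_module,
    sample_seeds_and_scores,
    write_fixture_bundle,
)


class TestInteractomeGeneration:
    def test_m1_yields_a_tree(self):
        net = generate_interactome(SyntheticConfig(n_genes=5, attachment_m=1, rng_seed=7,
                                                   module_size=2, n_seeds_early=0,
                                                   n_seeds_late=0, n_seeds_us=0,
                                                   set_size_range=(1, 3)))
        assert net.n_nodes == 5 and net.n_edges == 4
        assert nx.is_tree(net.graph)

    def test_edge_count_closed_form(self):
        # star-initialized preferential attachment has m(n-m) edges
        net = generate_interactome(SyntheticConfig(n_genes=1000, attachment_m=3))
        assert net.n_nodes == 1000
        assert net.n_edges == 3 * (1000 - 3)

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(n_genes=300, rng_seed=13, module_size=20)
        assert generate_interactome(cfg).edges() == generate_interactome(cfg).edges()

    def test_degree_distribution_heavy_tailed(self, default_bundle):
        degrees = [default_bundle.net.degree(s) for s in default_bundle.net.nodes]
        assert max(degrees) > 3 * np.median(degrees)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="attachment_m"):
            SyntheticConfig(attachment_m=0)
        with pytest.raises(ConfigurationError, match="module_size"):
            SyntheticConfig(module_size=0)
        with pytest.raises(ConfigurationError, match="n_planted_sets"):
            SyntheticConfig(n_planted_sets=99, n_annotation_sets=5)


class TestPlantedModule:
    def test_single_gene_module(self):
        cfg = SyntheticConfig(n_genes=50, module_size=1, n_seeds_early=1,
                              n_seeds_late=1, n_seeds_us=1, set_size_range=(2, 10))
        net = generate_interactome(cfg)
        truth = plant_disease_module(net, cfg)
        assert len(truth.module_genes) == 1

    def test_module_is_connected(self, default_bundle):
        sub = default_bundle.net.graph.subgraph(default_bundle.truth.module_genes)
        assert nx.is_connected(sub)

    def test_cohesion_adds_internal_edges(self):
        """Same rng: cohesion=1 strictly densifies the same module vs cohesion=0."""
        def run(cohesion):
            cfg = SyntheticConfig(n_genes=400, module_size=20,
                                  module_cohesion=cohesion, rng_seed=3)
            net = generate_interactome(cfg)
            truth = plant_disease_module(net, cfg)
            sub = net.graph.subgraph(truth.module_genes)
            return set(truth.module_genes), sub.number_of_edges()

        loose_mod, loose_edges = run(0.0)
        tight_mod, tight_edges = run(1.0)
        assert loose_mod == tight_mod  # membership invariant to cohesion
        assert tight_edges > loose_edges
        assert 2 * tight_edges / 20 > 2 * loose_edges / 20  # mean internal degree

    def test_module_is_topologically_local(self, default_bundle):
        """Module genes sit closer to the module root than random genes do."""
        g = default_bundle.net.graph
        module = sorted(default_bundle.truth.module_genes)
        centroid = module[0]
        dist = nx.single_source_shortest_path_length(g, centroid)
        module_mean = np.mean([dist[s] for s in module])
        global_mean = np.mean(list(dist.values()))
        assert module_mean < global_mean

    def test_oversized_module_rejected(self):
        cfg = SyntheticConfig(n_genes=100, module_size=60)
        net = generate_interactome(cfg)
        big = SyntheticConfig(n_genes=2000, module_size=1500)
        from pbcnet.errors import InputError

        with pytest.raises(InputError):
            plant_disease_module(net, big)


class TestSeedSampling:
    def test_zero_count_stage_is_empty(self):
        cfg = SyntheticConfig(n_genes=200, module_size=20, n_seeds_early=0,
                              n_seeds_late=3, n_seeds_us=3, rng_seed=1)
        net = generate_interactome(cfg)
        truth = plant_disease_module(net, cfg)
        df = sample_seeds_and_scores(truth, cfg)
        assert (df["stage"] == "early").sum() == 0

    def test_all_sampled_symbols_in_module(self, default_bundle):
        assert set(default_bundle.seed_rows["symbol"]) <= default_bundle.truth.module_genes

    def test_scores_in_unit_interval(self, default_bundle):
        s = default_bundle.seed_rows["score"]
        assert ((s > 0) & (s <= 1)).all()

    def test_uniform_beta_passes_ks(self):
        """alpha=beta=1 scores are uniform on (0, 1]."""
        cfg = SyntheticConfig(n_genes=1200, module_size=1000, n_seeds_early=1000,
                              n_seeds_late=0, n_seeds_us=0, curated_frac=0.0,
                              score_alpha=1.0, score_beta=1.0, rng_seed=2)
        net = generate_interactome(cfg)
        truth = plant_disease_module(net, cfg)
        df = sample_seeds_and_scores(truth, cfg)
        ks = stats.kstest(df["score"], "uniform").statistic
        assert ks < 0.1

    def test_curated_rows_get_stage_maximum(self, default_bundle):
        df = default_bundle.seed_rows
        for stage, grp in df.groupby("stage"):
            dis = grp.loc[grp["source"] == "disgenet", "score"]
            cur = grp.loc[grp["source"] == "curated", "score"]
            if len(dis) and len(cur):
                assert np.allclose(cur, dis.max())

    def test_components_sum_to_score_for_database_rows(self, default_bundle):
        df = default_bundle.seed_rows
        dis = df[df["source"] == "disgenet"]
        assert np.allclose(dis[["C", "M", "I", "L"]].sum(axis=1), dis["score"], atol=1e-9)


class TestAnnotationCollection:
    def test_full_overlap_planted_set_inside_module(self):
        cfg = SyntheticConfig(n_genes=300, module_size=40, planted_overlap_frac=1.0,
                              set_size_range=(5, 20), rng_seed=4)
        net = generate_interactome(cfg)
        truth = plant_disease_module(net, cfg)
        sets, planted = generate_annotation_collection(net, truth, cfg)
        for s in sets:
            if s.id in planted:
                assert s.members <= truth.module_genes

    def test_exact_planted_count(self):
        cfg = SyntheticConfig(n_genes=300, module_size=30, n_annotation_sets=50,
                              n_planted_sets=5, rng_seed=6)
        net = generate_interactome(cfg)
        truth = plant_disease_module(net, cfg)
        _, planted = generate_annotation_collection(net, truth, cfg)
        assert len(planted) == 5

    def test_both_categories_emitted(self, default_bundle):
        cats = {s.category for s in default_bundle.collection}
        assert cats == {"drug", "pathway"}

    def test_set_sizes_within_configured_range(self, default_bundle):
        lo, hi = default_bundle.config.set_size_range
        assert all(lo <= len(s.members) <= hi for s in default_bundle.collection)


class TestFixtureBundle:
    def test_round_trip_through_pipeline_readers(self, fixture_dir, small_bundle):
        net = read_edge_list(fixture_dir / "edges.tsv")
        assert net.nodes == small_bundle.net.nodes
        assert net.edges() == small_bundle.net.edges()
        sets = read_gmt(fixture_dir / "annotations.gmt")
        assert sets == small_bundle.collection

    def test_gmt_line_field_count(self, tmp_path, small_bundle):
        write_fixture_bundle(tmp_path / "f", small_bundle)
        five = [s for s in small_bundle.collection if len(s.members) == 5]
        lines = (tmp_path / "f" / "annotations.gmt").read_text().splitlines()
        by_id = {ln.split("\t")[0]: ln for ln in lines}
        for s in five:
            assert len(by_id[s.id].split("\t")) == 7

    def test_manifest_row_counts_match_objects(self, fixture_dir, small_bundle):
        manifest = json.loads((fixture_dir / "manifest.json").read_text())
        assert manifest["edges.tsv"]["rows"] == small_bundle.net.n_edges
        assert manifest["seeds.csv"]["rows"] == len(small_bundle.seed_rows)
        assert manifest["annotations.gmt"]["rows"] == len(small_bundle.collection)
        assert manifest["background.txt"]["rows"] == small_bundle.net.n_nodes

    def test_byte_identical_across_equal_configs(self, tmp_path):
        cfg = SyntheticConfig(n_genes=200, module_size=20, rng_seed=8,
                              n_seeds_early=3, n_seeds_late=3, n_seeds_us=5,
                              n_annotation_sets=10, n_planted_sets=2,
                              set_size_range=(5, 15))
        for d in ("a", "b"):
            write_fixture_bundle(tmp_path / d, generate_bundle(cfg))
        for name in ("edges.tsv", "seeds.csv", "annotations.gmt",
                     "background.txt", "ground_truth.json", "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_ground_truth_sidecar_consistent(self, fixture_dir, small_bundle):
        truth = json.loads((fixture_dir / "ground_truth.json").read_text())
        assert set(truth["seed_assignments"]) <= set(truth["module_genes"])
        assert set(truth["planted_set_ids"]) == small_bundle.planted_ids
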