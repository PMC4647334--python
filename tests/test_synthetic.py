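"""Generator contracts: shapes, planted effects, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

import inducemap as im
from inducemap.synthetic import gene_ids, sample_columns


class TestExpression:
    def test_shape_matches_design(self):
        cfg = im.SynthConfig(n_genes=100, seed=0)
        expr, _ = im.generate_expression(cfg)
        assert expr.shape == (100, 33)  # 10 inducers + glucose, 3 replicates
        assert list(expr.index) == gene_ids(100)
        assert list(expr.columns) == sample_columns(cfg)

    def test_no_effects_planted_when_de_fraction_zero(self):
        cfg = im.SynthConfig(n_genes=50, de_fraction_per_inducer=0.0,
                             noise_sd=0.1, seed=1)
        _, truth = im.generate_expression(cfg)
        assert all(not v for v in truth.planted_de.values())

    def test_planted_logfc_recovered_from_emitted_matrix(self):
        cfg = im.SynthConfig(n_genes=200, effect_size_logfc=2.0,
                             noise_sd=0.01, de_fraction_per_inducer=0.1,
                             seed=7)
        expr, truth = im.generate_expression(cfg)
        ref_cols = [c for c in expr.columns if c.startswith(cfg.reference)]
        for inducer, effects in truth.planted_de.items():
            cols = [c for c in expr.columns
                    if c.rsplit("_r", 1)[0] == inducer]
            assert effects
            for gene, lfc in effects.items():
                observed = (expr.loc[gene, cols].mean()
                            - expr.loc[gene, ref_cols].mean())
                assert observed == pytest.approx(lfc, abs=0.1)

    def test_non_planted_genes_have_equal_expected_means(self):
        cfg = im.SynthConfig(n_genes=300, de_fraction_per_inducer=0.0,
                             noise_sd=0.05, seed=3)
        expr, _ = im.generate_expression(cfg)
        ref = expr[[c for c in expr.columns if c.startswith("GLU")]].mean(axis=1)
        che = expr[[c for c in expr.columns
                    if c.rsplit("_r", 1)[0] == "O-CHE"]].mean(axis=1)
        # per-gene difference is pure noise ~ N(0, sd*sqrt(2/3))
        assert abs((che - ref).mean()) < 0.02

    def test_deterministic_under_seed(self, tmp_path):
        cfg = im.SynthConfig(n_genes=60, seed=42)
        a, _ = im.generate_expression(cfg)
        b, _ = im.generate_expression(cfg)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        im.write_expression(a, pa)
        im.write_expression(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            im.SynthConfig(n_genes=0)
        with pytest.raises(ValueError):
            im.SynthConfig(n_replicates=1)
        with pytest.raises(ValueError):
            im.SynthConfig(de_fraction_per_inducer=1.5)
        with pytest.raises(ValueError):
            im.SynthConfig(noise_sd=0.0)

    def test_planted_signs_never_zero(self, study):
        for effects in study.truth.planted_de.values():
            assert all(lfc != 0 for lfc in effects.values())

    def test_ground_truth_json_round_trip(self, study, tmp_path):
        path = tmp_path / "truth.json"
        study.truth.to_json(path)
        back = im.GroundTruth.from_json(path)
        assert back.planted_de == study.truth.planted_de
        assert back.planted_associations == study.truth.planted_associations
        assert back.planted_pathway == study.truth.planted_pathway


class TestAnnotations:
    def test_extracellular_fraction_zero_flags_nobody(self):
        cfg = im.SynthConfig(n_genes=80, extracellular_fraction=0.0, seed=2)
        catalog = im.generate_annotations(cfg, gene_ids(80))
        assert not catalog.extracellular

    def test_pathway_partition_sizes_sum(self):
        cfg = im.SynthConfig(n_genes=200, n_pathways=5, n_pathway_genes=50,
                             seed=4)
        catalog = im.generate_annotations(cfg, gene_ids(200))
        sizes = [len(m) for m in catalog.pathways.values()]
        assert sum(sizes) == 50
        members = [g for m in catalog.pathways.values() for g in m]
        assert len(members) == len(set(members))  # disjoint partition

    def test_ontology_classes_closed_vocabulary(self, study):
        classes = {c for terms in study.catalog.go.values()
                   for _, c in terms}
        assert classes <= {"biological_process", "cellular_component",
                           "molecular_function"}

    def test_duplicate_gene_ids_rejected(self):
        cfg = im.SynthConfig(n_genes=10, seed=0)
        with pytest.raises(ValueError, match="duplicate"):
            im.generate_annotations(cfg, ["a", "a", "b"])


class TestMetabolicNetwork:
    def test_requested_reaction_count(self):
        cfg = im.SynthConfig(n_genes=50, n_reactions=10, n_metabolites=30,
                             seed=5)
        net = im.generate_metabolic_network(cfg, gene_ids(50))
        assert len(net.reactions) == 10

    def test_probe_metabolite_guaranteed_gene_associated_reaction(self, study):
        for probe in study.config.probe_metabolites:
            hits = study.network.reactions_of(probe)
            assert hits and any(r.genes for r in hits)

    def test_unique_reactant_count_equals_set_union_oracle(self, study):
        brute = set()
        for rxn in study.network.reactions:
            brute |= rxn.reactants | rxn.products
        assert study.network.metabolites == brute


class TestDescriptorTable:
    def test_single_cluster_single_label(self):
        cfg = im.SynthConfig(n_descriptor_clusters=1, seed=6)
        _, truth = im.generate_descriptor_table(cfg)
        assert set(truth.planted_clusters.values()) == {0}

    def test_default_dimensions(self):
        desc, _ = im.generate_descriptor_table(im.SynthConfig(seed=0))
        assert desc.shape == (10, 186)

    def test_nearest_center_oracle_recovers_planted_labels(self):
        cfg = im.SynthConfig(center_separation=10.0, seed=8)
        desc, truth = im.generate_descriptor_table(cfg)
        labels = pd.Series(truth.planted_clusters)
        centers = desc.groupby(labels).mean()
        X = desc.to_numpy()
        d = np.linalg.norm(X[:, None, :] - centers.to_numpy()[None], axis=2)
        nearest = centers.index.to_numpy()[d.argmin(axis=1)]
        assert (nearest == labels.loc[desc.index].to_numpy()).all()

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            im.generate_descriptor_table(
                im.SynthConfig(n_descriptor_items=3, n_descriptor_clusters=4))


class TestCoordinatedStudy:
    def test_planted_pathway_genes_all_planted_down(self, study):
        pathway, inducer = study.truth.planted_pathway
        members = study.catalog.pathways[pathway]
        effects = study.truth.planted_de[inducer]
        assert all(g in effects and effects[g] < 0 for g in members)

    def test_association_pairs_share_sign_vector(self, study):
        for c, g in study.truth.planted_associations:
            for inducer in study.config.inducers:
                effects = study.truth.planted_de[inducer]
                assert np.sign(effects[c]) == np.sign(effects[g])

    def test_study_is_deterministic(self, small_config, study):
        again = im.generate_study(small_config)
        pd.testing.assert_frame_equal(again.expression, study.expression)
        assert again.truth.planted_de == study.truth.planted_de
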