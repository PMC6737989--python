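import numpy as np
import pandas as pd
import pytest

from tissueatlas.interactions import find_seed_sites
from tissueatlas.quantify import compute_rpkm
from tissueatlas.simulate import (
    SimulationDesign,
    TruthBundle,
    gene_lengths_from_design,
    nb_counts,
    read_fixture_bundle,
    simulate_atlas,
    write_fixture_bundle,
)


class TestDesignValidation:
    def test_planted_fold_must_exceed_specificity_cutoff(self):
        with pytest.raises(ValueError, match="fold"):
            SimulationDesign(specific_fold_planted=8.0).validate()

    def test_more_planted_features_than_genes_is_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationDesign(n_genes=150).validate()

    def test_more_planted_mirnas_than_mirnas_is_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationDesign(n_mirnas=20).validate()


class TestTruthBundle:
    def test_repressor_and_decoy_sets_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            TruthBundle(
                repressor_pairs={("m", "g", 3, "8mer")},
                decoy_pairs={("m", "g")},
            )

    def test_specific_gene_in_two_tissues_rejected(self):
        with pytest.raises(ValueError, match="two tissues"):
            TruthBundle(specific_ids={"liver": {"g"}, "heart": {"g"}})

    def test_json_round_trip(self, small_atlas):
        truth = small_atlas["truth"]
        back = TruthBundle.from_json(truth.to_json())
        assert back.universal_ids == truth.universal_ids
        assert back.specific_ids == truth.specific_ids
        assert back.repressor_pairs == truth.repressor_pairs
        assert back.host_violations == truth.host_violations


class TestAtlasConstruction:
    def test_same_seed_reproduces_identical_matrices(self, small_design):
        a = simulate_atlas(small_design)
        b = simulate_atlas(small_design)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[3] == b[3]

    def test_low_noise_limit_puts_universal_genes_above_floor_everywhere(self):
        design = SimulationDesign(seed=6, nb_dispersion=1e-6)
        mrna, _, _, _, truth = simulate_atlas(design)
        rpkm = compute_rpkm(mrna, gene_lengths_from_design(design)).values
        planted = rpkm.loc[sorted(truth.universal_ids)]
        assert (planted > 10.0).all().all()

    def test_every_repressor_utr_carries_its_planted_site(self, small_atlas):
        truth, seqs = small_atlas["truth"], small_atlas["sequences"]
        assert len(truth.repressor_pairs) == small_atlas["design"].n_repressor_pairs
        carriers = set()
        for mirna_id, gene_id, pos, site_type in truth.repressor_pairs:
            sites = find_seed_sites(seqs[mirna_id], seqs[gene_id])
            assert any(s.utr_position == pos and s.site_type == site_type for s in sites), (
                f"planted {site_type} at {pos} not rediscovered for {mirna_id}/{gene_id}"
            )
            carriers.add(gene_id)
        assert len(carriers) == small_atlas["design"].n_repressor_pairs

    def test_decoy_utrs_are_site_free_for_their_mirna(self, small_atlas):
        truth, seqs = small_atlas["truth"], small_atlas["sequences"]
        for mirna_id, gene_id in truth.decoy_pairs:
            assert find_seed_sites(seqs[mirna_id], seqs[gene_id]) == []

    def test_intragenic_mirnas_single_copy_same_strand_inside_host(self, small_atlas):
        ann, truth = small_atlas["annotation"], small_atlas["truth"]
        genes = ann.of_type("gene").set_index("name")
        mirs = ann.of_type("miRNA").set_index("name")
        for mirna_id, gene_id in truth.host_pairs:
            m, g = mirs.loc[mirna_id], genes.loc[gene_id]
            assert ann.copy_count(mirna_id) == 1
            assert m.chrom == g.chrom and m.strand == g.strand
            assert g.start <= m.start and m.end <= g.end

    def test_count_mean_converges_to_design_mean(self):
        # NB draws at the design's mean/dispersion: relative error of the
        # empirical mean under 5% at 1,000 replicate draws
        rng = np.random.default_rng(12)
        mean = np.full(1000, 250.0)
        draws = nb_counts(rng, mean, 0.1)
        assert abs(draws.mean() / 250.0 - 1.0) < 0.05

    def test_dispersion_zero_limit_is_poisson(self):
        rng = np.random.default_rng(13)
        draws = nb_counts(rng, np.full(20_000, 100.0), 0.0)
        # Poisson variance equals the mean
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.05)


class TestFixtureBundle:
    def test_write_then_read_reproduces_objects(self, small_atlas, tmp_path):
        paths = write_fixture_bundle(
            small_atlas["mrna"], small_atlas["mirna"], small_atlas["annotation"],
            small_atlas["sequences"], small_atlas["truth"], tmp_path,
            gene_lengths=small_atlas["lengths"],
        )
        mrna, mirna, ann, seqs, truth = read_fixture_bundle(tmp_path)
        pd.testing.assert_frame_equal(mrna, small_atlas["mrna"], check_dtype=False)
        pd.testing.assert_frame_equal(mirna, small_atlas["mirna"], check_dtype=False)
        assert ann == small_atlas["annotation"]
        assert seqs == small_atlas["sequences"]
        assert truth.universal_ids == small_atlas["truth"].universal_ids
        assert truth.repressor_pairs == small_atlas["truth"].repressor_pairs
        assert paths["truth"].exists()

    def test_truth_json_lists_every_requested_category(self, small_atlas, tmp_path):
        import json
        write_fixture_bundle(
            small_atlas["mrna"], small_atlas["mirna"], small_atlas["annotation"],
            small_atlas["sequences"], small_atlas["truth"], tmp_path,
        )
        d = json.loads((tmp_path / "truth.json").read_text())
        assert d["universal_ids"]
        assert all(d["specific_ids"][t] for t in d["specific_ids"])
        assert d["host_pairs"] and d["repressor_pairs"] and d["decoy_pairs"]

    def test_emitted_gtf_contains_mirnas_inside_hosts(self, small_atlas, tmp_path):
        from tissueatlas.io import read_annotation
        write_fixture_bundle(
            small_atlas["mrna"], small_atlas["mirna"], small_atlas["annotation"],
            small_atlas["sequences"], small_atlas["truth"], tmp_path,
        )
        ann = read_annotation(tmp_path / "annotation.gtf")
        genes = ann.of_type("gene").set_index("name")
        mirs = ann.of_type("miRNA")
        truth = small_atlas["truth"]
        hosts = dict((m, g) for m, g in truth.host_pairs)
        for rec in mirs.itertuples(index=False):
            if rec.name in hosts:
                g = genes.loc[hosts[rec.name]]
                assert g.start <= rec.start and rec.end <= g.end
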