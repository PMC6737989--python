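import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import pearson_with_p
from tissueatlas.hostpairs import (
    filter_containment,
    filter_expression_breadth,
    filter_same_strand,
    filter_single_copy,
    find_host_pairs,
    find_intragenic_candidates,
    filter_host_correlation,
)
from tissueatlas.io import FeatureAnnotation

SAMPLES = [f"t{i}" for i in range(11)]


def annotation(rows):
    return FeatureAnnotation(
        pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand", "feature_type"])
    )


@pytest.fixture()
def fixture_bundle():
    """One true intragenic pair plus one violation of each kind.

    mir_ok      - contained, same strand, single copy, broad, correlated
    mir_anti    - contained but antisense
    mir_partial - straddles the gene boundary
    mir_multi   - contained but has a second genomic copy
    mir_narrow  - contained but expressed in only 3 tissues
    """
    from conftest import build_host_fixture

    return build_host_fixture()


class TestCandidateGeneration:
    def test_contained_same_strand_locus_is_candidate(self):
        ann = annotation([
            ("G", "chr1", 100, 5000, "+", "gene"),
            ("m", "chr1", 150, 172, "+", "miRNA"),
        ])
        cands = find_intragenic_candidates(ann, ann)
        assert [(c.mirna_id, c.gene_id) for c in cands] == [("m", "G")]

    def test_partial_overlap_is_not_a_candidate(self):
        ann = annotation([
            ("G", "chr1", 100, 5000, "+", "gene"),
            ("m", "chr1", 90, 112, "+", "miRNA"),
        ])
        assert find_intragenic_candidates(ann, ann) == []

    def test_antisense_candidate_carries_strand_flag(self):
        ann = annotation([
            ("G", "chr1", 100, 5000, "+", "gene"),
            ("m", "chr1", 150, 172, "-", "miRNA"),
        ])
        (cand,) = find_intragenic_candidates(ann, ann)
        assert cand.containment and not cand.same_strand


class TestFilters:
    def test_multi_copy_mirna_removed_everywhere(self):
        ann = annotation([
            ("G1", "chr1", 100, 5000, "+", "gene"),
            ("G2", "chr1", 200, 4000, "+", "gene"),
            ("m", "chr1", 250, 272, "+", "miRNA"),
            ("m", "chr5", 100, 122, "+", "miRNA"),
        ])
        cands = find_intragenic_candidates(ann, ann)
        assert len(cands) == 2  # contained in both overlapping genes
        assert filter_single_copy(cands, ann) == []

    def test_breadth_boundary_is_inclusive(self):
        ann = annotation([
            ("G", "chr1", 100, 5000, "+", "gene"),
            ("m", "chr1", 150, 172, "+", "miRNA"),
        ])
        cands = find_intragenic_candidates(ann, ann)
        tpm = pd.DataFrame([[0.1, 0.1, 0.1, 0.1, 0.1, 0.0, 0, 0, 0, 0, 0]],
                           index=["m"], columns=SAMPLES)
        rpkm = pd.DataFrame([[1.0] * 11], index=["G"], columns=SAMPLES)
        kept = filter_expression_breadth(cands, tpm, rpkm, min_tissues=5, threshold=0.1)
        assert len(kept) == 1 and kept[0].breadth_mirna == 5

    def test_missing_feature_in_matrix_is_hard_error(self):
        ann = annotation([
            ("G", "chr1", 100, 5000, "+", "gene"),
            ("m", "chr1", 150, 172, "+", "miRNA"),
        ])
        cands = find_intragenic_candidates(ann, ann)
        tpm = pd.DataFrame([[1.0] * 11], index=["other"], columns=SAMPLES)
        rpkm = pd.DataFrame([[1.0] * 11], index=["G"], columns=SAMPLES)
        with pytest.raises(KeyError, match="m"):
            filter_expression_breadth(cands, tpm, rpkm, 5, 0.1)

    def test_correlation_matches_textbook_formula(self, rng, fixture_bundle):
        ann, tpm, rpkm = fixture_bundle
        cands = find_intragenic_candidates(ann, ann)
        # randomize profiles so r spans a range, then compare r and p
        tpm_r = pd.DataFrame(rng.lognormal(2, 1, size=tpm.shape),
                             index=tpm.index, columns=tpm.columns)
        out = filter_host_correlation(list(cands), tpm_r, rpkm, r_min=-2, p_max=2)
        assert out  # nothing filtered at vacuous thresholds
        for c in out:
            r_ref, p_ref = pearson_with_p(
                tpm_r.loc[c.mirna_id], rpkm.loc[c.gene_id]
            )
            assert c.r == pytest.approx(r_ref, abs=1e-12)
            assert c.p == pytest.approx(p_ref, abs=1e-12)

    def test_perfect_anticorrelation_fails_sign_rule(self):
        ann = annotation([
            ("G", "chr1", 100, 5000, "+", "gene"),
            ("m", "chr1", 150, 172, "+", "miRNA"),
        ])
        cands = find_intragenic_candidates(ann, ann)
        x = np.arange(1.0, 12.0)
        tpm = pd.DataFrame([x], index=["m"], columns=SAMPLES)
        rpkm = pd.DataFrame([x[::-1]], index=["G"], columns=SAMPLES)
        assert filter_host_correlation(cands, tpm, rpkm) == []
        assert cands[0].r == pytest.approx(-1.0)


class TestFivefilterPipeline:
    def test_exactly_the_true_pair_passes_with_designated_flags(self, fixture_bundle):
        ann, tpm, rpkm = fixture_bundle
        passed, candidates = find_host_pairs(ann, ann, tpm, rpkm)
        assert [(c.mirna_id, c.gene_id) for c in passed] == [("mir_ok", "HOST1")]
        flags = {c.mirna_id: c for c in candidates}
        assert not flags["mir_anti"].same_strand
        assert flags["mir_multi"].copy_count == 2
        assert "mir_partial" not in flags  # rejected at candidate generation
        narrow = [c for c in candidates if c.mirna_id == "mir_narrow"]
        narrow = filter_expression_breadth(narrow, tpm, rpkm, 5, 0.1)
        assert narrow == []

    def test_filters_commute_over_all_orderings(self, fixture_bundle):
        ann, tpm, rpkm = fixture_bundle
        filters = {
            "containment": filter_containment,
            "strand": filter_same_strand,
            "copy": lambda c: filter_single_copy(c, ann),
            "breadth": lambda c: filter_expression_breadth(c, tpm, rpkm, 5, 0.1),
            "correlation": lambda c: filter_host_correlation(c, tpm, rpkm, 0.6, 0.05),
        }
        results = set()
        for order in itertools.permutations(filters):
            cands = find_intragenic_candidates(ann, ann, include_partial=True)
            for name in order:
                cands = filters[name](cands)
            results.add(frozenset((c.mirna_id, c.gene_id) for c in cands))
        assert results == {frozenset({("mir_ok", "HOST1")})}


class TestAtlasRecovery:
    def test_planted_pairs_pass_and_violations_fail_in_low_noise_limit(self):
        from tissueatlas.simulate import SimulationDesign, simulate_atlas, gene_lengths_from_design
        from tissueatlas.quantify import compute_rpkm, compute_tpm_per_million

        design = SimulationDesign(seed=2, nb_dispersion=1e-4)
        mrna, mirna, ann, _, truth = simulate_atlas(design)
        rpkm = compute_rpkm(mrna, gene_lengths_from_design(design)).values
        tpm = compute_tpm_per_million(mirna).values
        passed, _ = find_host_pairs(ann, ann, tpm, rpkm)
        got = {(c.mirna_id, c.gene_id) for c in passed}
        assert truth.host_pairs <= got
        for reason, pairs in truth.host_violations.items():
            assert not (pairs & got), f"{reason} violation passed"

    def test_violations_fail_for_their_planted_reason_at_default_noise(self, default_atlas):
        from tissueatlas.quantify import compute_rpkm, compute_tpm_per_million

        ann, truth = default_atlas["annotation"], default_atlas["truth"]
        rpkm = compute_rpkm(default_atlas["mrna"], default_atlas["lengths"]).values
        tpm = compute_tpm_per_million(default_atlas["mirna"]).values
        passed, candidates = find_host_pairs(ann, ann, tpm, rpkm)
        got = {(c.mirna_id, c.gene_id) for c in passed}
        assert len(got & truth.host_pairs) >= 0.9 * len(truth.host_pairs)
        by_pair = {(c.mirna_id, c.gene_id): c for c in candidates}
        for reason, pairs in truth.host_violations.items():
            for pair in pairs:
                assert pair not in got
                if reason == "partial_overlap":
                    assert pair not in by_pair
                elif reason == "antisense":
                    assert not by_pair[pair].same_strand
                elif reason == "multi_copy":
                    assert by_pair[pair].copy_count > 1
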