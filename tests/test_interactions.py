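import numpy as np
import pandas as pd
import pytest

from _oracles import duplex_mfe_by_enumeration, revcomp, seed_sites_by_scan
from tissueatlas.interactions import (
    SeedSite,
    assemble_interactions,
    duplex_mfe,
    find_seed_sites,
    screen_negative_correlation,
)
from tissueatlas.io import SequenceSet

MIR1 = "UGGAAUGUAAAGAAGUAUGUAU"  # miR-1 mature sequence


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestScreen:
    def test_perfectly_antiordered_profiles_pass(self):
        mi = pd.DataFrame([[3.0, 2.0, 1.0]], index=["m"], columns=list("abc"))
        mr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = screen_negative_correlation(mi, mr, -0.5)
        assert len(out) == 1
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_strictness_at_the_threshold(self):
        mi = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["m"], columns=list("abcd"))
        mr = pd.DataFrame([[4.0, 1.0, 3.0, 2.0]], index=["g"], columns=list("abcd"))
        loose = screen_negative_correlation(mi, mr, -0.1)
        assert len(loose) == 1
        r = float(loose.iloc[0]["r"])
        # re-screen at exactly the computed r: strict < must exclude the pair
        out = screen_negative_correlation(mi, mr, r)
        assert len(out) == 0

    def test_monotone_shrinkage_with_stricter_threshold(self, rng):
        mi = pd.DataFrame(rng.lognormal(0, 1, (20, 6)), index=[f"m{i}" for i in range(20)])
        mr = pd.DataFrame(rng.lognormal(0, 1, (30, 6)), index=[f"g{i}" for i in range(30)])
        loose = screen_negative_correlation(mi, mr, -0.3)
        strict = screen_negative_correlation(mi, mr, -0.7)
        loose_set = set(zip(loose.mirna_id, loose.gene_id))
        strict_set = set(zip(strict.mirna_id, strict.gene_id))
        assert strict_set <= loose_set

    def test_zero_variance_profiles_excluded_not_crashing(self, rng):
        mi = pd.DataFrame([[5.0] * 6, list(rng.lognormal(0, 1, 6))], index=["flat", "m"])
        mr = pd.DataFrame(rng.lognormal(0, 1, (3, 6)), index=["a", "b", "c"])
        out = screen_negative_correlation(mi, mr, -0.2)
        assert "flat" not in set(out.mirna_id)

    def test_too_few_samples_rejected(self):
        mi = pd.DataFrame([[1.0, 2.0]], index=["m"], columns=list("ab"))
        with pytest.raises(ValueError):
            screen_negative_correlation(mi, mi, -0.5)


class TestSeedSites:
    def test_mir1_canonical_site_found_with_oracle_tier(self):
        utr = "GGCGGG" + "ACAUUCCA" + "GGCGG"
        got = find_seed_sites(MIR1, utr)
        ref = seed_sites_by_scan(MIR1, utr)
        assert [(s.utr_position, s.site_type, s.matched_span) for s in got] == ref
        assert len(got) == 1

    def test_seed_built_from_its_own_sequence_matches_nothing(self):
        utr = MIR1[1:8] * 10  # the seed itself, not its complement
        assert find_seed_sites(MIR1, utr) == []

    def test_bare_reverse_complement_of_seed_is_a_7mer_m8(self):
        utr = revcomp(MIR1[1:8])
        (site,) = find_seed_sites(MIR1, utr)
        assert site.site_type == "7mer-m8"
        assert site.matched_span == (0, 7)

    def test_8mer_requires_target_adenine_not_complementarity(self):
        core = revcomp(MIR1[1:8])
        # miR-1 position 1 is U; an A opposite it is a sequence feature
        (site,) = find_seed_sites(MIR1, "CC" + core + "A" + "CC")
        assert site.site_type == "8mer"
        (site2,) = find_seed_sites(MIR1, "CC" + core + "G" + "CC")
        assert site2.site_type == "7mer-m8"

    def test_agrees_with_window_oracle_on_random_draws(self, rng):
        for _ in range(300):
            m = random_rna(rng, 22)
            u = random_rna(rng, 120)
            if rng.random() < 0.4:  # enrich with true sites
                ins = revcomp(m[1:8]) + ("A" if rng.random() < 0.5 else "")
                p = int(rng.integers(0, len(u)))
                u = u[:p] + ins + u[p:]
            got = [(s.utr_position, s.site_type, s.matched_span) for s in find_seed_sites(m, u)]
            assert got == seed_sites_by_scan(m, u)

    def test_non_nucleotide_symbol_rejected_with_position(self):
        with pytest.raises(ValueError, match="position"):
            find_seed_sites(MIR1, "ACGUNACGU")


class TestDuplex:
    def test_matches_exhaustive_enumeration_on_tiny_pairs(self, rng):
        for _ in range(60):
            a = random_rna(rng, int(rng.integers(1, 9)))
            b = random_rna(rng, int(rng.integers(1, 9)))
            assert duplex_mfe(a, b).mfe == pytest.approx(duplex_mfe_by_enumeration(a, b))

    def test_poly_a_strands_have_no_structure(self):
        res = duplex_mfe("AAAA", "AAAA")
        assert res.mfe == 0.0 and res.pairing == []

    def test_perfect_complement_beats_every_single_mutant(self, rng):
        mir = random_rna(rng, 22)
        target = revcomp(mir)
        perfect = duplex_mfe(mir, target).mfe
        for pos in range(22):
            for nt in "ACGU":
                if nt == target[pos]:
                    continue
                mutant = target[:pos] + nt + target[pos + 1 :]
                assert duplex_mfe(mir, mutant).mfe > perfect

    def test_pairing_is_antiparallel_monotone_noncrossing(self, rng):
        for _ in range(30):
            a, b = random_rna(rng, 15), random_rna(rng, 20)
            pairing = duplex_mfe(a, b).pairing
            for (i1, j1), (i2, j2) in zip(pairing, pairing[1:]):
                assert i2 > i1 and j2 < j1

    def test_symmetric_under_reversal_and_swap(self, rng):
        for _ in range(30):
            a, b = random_rna(rng, 12), random_rna(rng, 16)
            assert duplex_mfe(a, b).mfe == pytest.approx(duplex_mfe(b[::-1], a[::-1]).mfe)

    def test_window_guard_rejects_long_targets(self, rng):
        with pytest.raises(ValueError, match="60"):
            duplex_mfe("ACGU", random_rna(rng, 61))

    def test_nonpositive_energy_whenever_pairs_form(self, rng):
        for _ in range(50):
            res = duplex_mfe(random_rna(rng, 10), random_rna(rng, 10))
            if res.pairing:
                assert res.mfe <= 0.0
            else:
                assert res.mfe == 0.0


class TestAssembly:
    def test_screen_sites_and_persistence_flags_are_independent(self):
        # anti-correlated across tissues but flat across stages:
        # in the final set, not the persistent set
        mir = MIR1
        utr = "GG" + revcomp(mir[1:8]) + "A" + "GG"
        mi = pd.DataFrame([[9, 7, 5, 3, 1, 4.0, 4.0, 4.0]], index=["m"],
                          columns=["t1", "t2", "t3", "t4", "t5", "D0", "D30", "D240"])
        mr = pd.DataFrame([[1, 3, 5, 7, 9, 6.0, 6.0, 6.0]], index=["g"],
                          columns=mi.columns)
        screened = screen_negative_correlation(mi, mr, -0.5)
        records = assemble_interactions(
            screened,
            SequenceSet({"m": mir}), SequenceSet({"g": utr}),
            mirna_stage_expr=mi[["D0", "D30", "D240"]],
            mrna_stage_expr=mr[["D0", "D30", "D240"]],
        )
        (rec,) = records
        assert rec.passed_screen and rec.passed_sites
        assert not rec.passed_persistence  # stages are flat

    def test_pairs_without_sequences_are_dropped(self):
        screened = pd.DataFrame({"mirna_id": ["m"], "gene_id": ["g"], "r": [-0.9]})
        records = assemble_interactions(screened, SequenceSet({}), SequenceSet({}))
        assert records == []

    def test_output_sorted_by_r_then_ids(self, rng):
        mirs, utrs = {}, {}
        rows = []
        for k in range(5):
            m = random_rna(rng, 22)
            mirs[f"m{k}"] = m
            utrs[f"g{k}"] = "GG" + revcomp(m[1:8]) + "A"
            rows.append({"mirna_id": f"m{k}", "gene_id": f"g{k}",
                         "r": -0.6 - 0.05 * int(rng.integers(0, 5))})
        screened = pd.DataFrame(rows)
        records = assemble_interactions(screened, SequenceSet(mirs), SequenceSet(utrs))
        keys = [(r.r, r.mirna_id, r.gene_id) for r in records]
        assert keys == sorted(keys)

    def test_enabling_mfe_filter_never_enlarges_final_set(self, rng):
        mirs, utrs, rows = {}, {}, []
        for k in range(8):
            m = random_rna(rng, 22)
            mirs[f"m{k}"] = m
            utrs[f"g{k}"] = random_rna(rng, 30) + revcomp(m[1:8]) + "A" + random_rna(rng, 10)
            rows.append({"mirna_id": f"m{k}", "gene_id": f"g{k}", "r": -0.8})
        screened = pd.DataFrame(rows)
        loose = assemble_interactions(screened, SequenceSet(mirs), SequenceSet(utrs))
        strict = assemble_interactions(screened, SequenceSet(mirs), SequenceSet(utrs),
                                       mfe_filter=True, mfe_max=-15.0)
        loose_final = {(r.mirna_id, r.gene_id) for r in loose if r.passed_sites}
        strict_final = {(r.mirna_id, r.gene_id) for r in strict if r.passed_sites}
        assert strict_final <= loose_final
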