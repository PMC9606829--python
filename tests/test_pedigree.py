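"""Relationship inference, gamete deduction, imputation, null flagging."""

import numpy as np
import pytest

import sploshkit as sk
from sploshkit.pedigree import (DUPLICATE, GAMETE_A, GAMETE_AMBIGUOUS,
                                GAMETE_B, GAMETE_UNKNOWN, GRANDPARENT_LEVEL,
                                PARENT_OFFSPRING, UNRESOLVED, pair_stats)
from sploshkit.simulate import NULL_ALLELE

from conftest import make_panel


@pytest.fixture(scope="module")
def family_panel(default_map):
    """Two species; a trio, a clone pair, and unrelated individuals."""
    model = sk.SpeciesModel(n_species=2, fst=0.3)
    groups = [sk.FounderGroup("domestica", 5, "cultivar"),
              sk.FounderGroup("sieversii", 5, "wild")]
    rng = np.random.default_rng(23)
    panel, truth = sk.simulate_founders(model, groups, default_map, rng)
    spec = sk.PedigreeSpec(
        matings=(sk.Mating("child", "sieversii_000", "sieversii_001"),),
        clones=(sk.Clone("twin", "sieversii_002"),))
    return sk.build_pedigree(spec, panel, truth, rng)


class TestDuplicates:
    def test_clone_pair_grouped_with_perfect_concordance(self, family_panel):
        panel, _ = family_panel
        calls, codes = sk.find_duplicates(panel)
        pairs = {frozenset(c.pair) for c in calls}
        assert frozenset(("twin", "sieversii_002")) in pairs
        assert codes["twin"] == codes["sieversii_002"]
        the = next(c for c in calls
                   if frozenset(c.pair) == frozenset(("twin", "sieversii_002")))
        assert the.concordance == pytest.approx(1.0)

    def test_clone_pair_survives_low_error_rate(self, family_panel):
        panel, truth = family_panel
        noisy = sk.apply_noise(panel, truth, sk.NoiseModel(0.002, 0.0, 0.0),
                               99)
        calls, codes = sk.find_duplicates(noisy)
        assert codes["twin"] == codes["sieversii_002"]

    def test_unrelated_cross_species_pair_not_duplicates(self, family_panel):
        panel, _ = family_panel
        _, codes = sk.find_duplicates(panel)
        assert codes["domestica_000"] != codes["sieversii_003"]


class TestParentOffspring:
    def test_trio_recovered_with_zero_oh(self, family_panel):
        panel, _ = family_panel
        po = sk.find_parent_offspring(panel)
        pairs = {frozenset(c.pair) for c in po}
        assert frozenset(("child", "sieversii_000")) in pairs
        assert frozenset(("child", "sieversii_001")) in pairs
        assert all(c.oh_rate == 0.0 for c in po
                   if "child" in c.pair)

    def test_duplicates_excluded_from_po(self, family_panel):
        panel, _ = family_panel
        dups, _ = sk.find_duplicates(panel)
        po = sk.find_parent_offspring(
            panel, duplicate_pairs={frozenset(c.pair) for c in dups})
        assert frozenset(("twin", "sieversii_002")) not in \
            {frozenset(c.pair) for c in po}

    def test_unrelated_same_species_oh_rate_far_above_threshold(
            self, family_panel):
        panel, _ = family_panel
        _, oh, _ = pair_stats(panel, "sieversii_003", "sieversii_004")
        assert oh > 0.02  # ~ mean of 2 p^2 q^2 over informative SNPs


class TestGrandparentLevel:
    def test_po_pair_excluded_despite_high_splosh(self, family_panel):
        panel, _ = family_panel
        m20 = sk.splosh_matrix(panel, sk.SploshConfig())
        calls, _ = sk.relate(panel, m20)
        by_type = {}
        for c in calls:
            by_type.setdefault(frozenset(c.pair), []).append(c.type)
        # precedence chain total and exclusive: no pair under two types
        assert all(len(v) == 1 for v in by_type.values())
        assert by_type[frozenset(("child", "sieversii_000"))] == \
            [PARENT_OFFSPRING]

    def test_unrelated_cross_species_below_512(self, family_panel):
        panel, _ = family_panel
        m20 = sk.splosh_matrix(panel, sk.SploshConfig())
        assert m20.value("domestica_000", "sieversii_003") < 512


class TestDeduceGamete:
    def test_deduction_table(self, small_map):
        #            off:  AA  AB   AB  AB  BB
        #            par:  BB  AA   BB  AB  --
        panel = make_panel(small_map, [[0, 1, 1, 1, 2], [2, 0, 2, 1, -1]])
        gam = sk.deduce_gamete("ind0", "ind1", panel)
        # SNP0 is an opposing homozygote -> UNKNOWN, counted
        assert list(gam.alleles) == [GAMETE_UNKNOWN, GAMETE_B, GAMETE_A,
                                     GAMETE_AMBIGUOUS, GAMETE_UNKNOWN]
        assert gam.n_conflicts == 1

    def test_homozygous_offspring_determines_allele(self, small_map):
        # non-conflicting parents: offspring HOM_X -> X; a conflicting
        # (opposing-homozygote) SNP is UNKNOWN, not trusted
        panel = make_panel(small_map, [[0, 0, 0, 2, 2], [0, 1, 1, 1, 2]])
        gam = sk.deduce_gamete("ind0", "ind1", panel)
        assert list(gam.alleles) == [GAMETE_A, GAMETE_A, GAMETE_A,
                                     GAMETE_B, GAMETE_B]
        conflict = make_panel(small_map, [[0] * 5, [2, 1, 1, 1, 1]])
        gam2 = sk.deduce_gamete("ind0", "ind1", conflict)
        assert gam2.alleles[0] == GAMETE_UNKNOWN and gam2.n_conflicts == 1

    def test_matches_true_transmitted_haplotype(self, family_panel):
        panel, truth = family_panel
        gam = sk.deduce_gamete("child", "sieversii_000", panel)
        true_gamete = truth.hap_alleles("child", 1)  # from sieversii_001
        det = np.isin(gam.alleles, [GAMETE_A, GAMETE_B])
        assert det.any()
        assert np.array_equal(gam.alleles[det], true_gamete[det])


class TestScanGamete:
    def test_true_second_parent_top_ranked(self, family_panel):
        panel, _ = family_panel
        gam = sk.deduce_gamete("child", "sieversii_000", panel)
        table, uninformative = sk.scan_gamete(gam, panel)
        assert not uninformative
        assert table.iloc[0]["candidate"] == "sieversii_001"
        assert table.iloc[0]["compatible_cM"] > 640

    def test_hidden_parent_rank1_recovery_rate(self, default_map):
        """The true second parent is top-ranked in >=95% of 100 trios."""
        model = sk.SpeciesModel(n_species=1, fst=0.3)
        rng = np.random.default_rng(314)
        panel, truth = sk.simulate_founders(
            model, [sk.FounderGroup("s", 50)], default_map, rng)
        hits = 0
        for rep in range(100):
            f, m = rng.choice(50, size=2, replace=False)
            father, mother = f"s_{f:03d}", f"s_{m:03d}"
            spec = sk.PedigreeSpec(matings=(
                sk.Mating(f"kid{rep}", father, mother),))
            panel2, _ = sk.build_pedigree(spec, panel, truth, rng)
            gam = sk.deduce_gamete(f"kid{rep}", father, panel2)
            table, _ = sk.scan_gamete(gam, panel2, candidates=panel.ids)
            hits += table.iloc[0]["candidate"] == mother
        assert hits >= 95

    def test_fully_opposing_candidate_scores_zero(self, small_map):
        panel = make_panel(small_map, [[0] * 5, [0] * 5, [2] * 5])
        gam = sk.deduce_gamete("ind0", "ind1", panel)
        table, _ = sk.scan_gamete(gam, panel,
                                  sk.SploshConfig(threshold_cM=0.0))
        row = table[table.candidate == "ind2"]
        assert row["compatible_cM"].item() == 0.0

    def test_all_ambiguous_gamete_flagged_uninformative(self, small_map):
        panel = make_panel(small_map, [[1] * 5, [1] * 5, [0] * 5])
        gam = sk.deduce_gamete("ind0", "ind1", panel)
        table, uninformative = sk.scan_gamete(gam, panel)
        assert uninformative
        assert (table["compatible_cM"] == 40.0).all()


class TestUnilateralSharing:
    def test_po_pair_shares_everywhere(self, family_panel):
        panel, _ = family_panel
        assert sk.unilateral_allele_sharing("child", "sieversii_000",
                                            panel) == 1.0

    def test_arithmetic_on_hand_fixture(self):
        gmap = sk.GeneticMap.default(n_chromosomes=2, total_cM=100, n_snps=10)
        panel = make_panel(gmap, [[0] + [1] * 9, [2] + [1] * 9])
        assert sk.unilateral_allele_sharing("ind0", "ind1", panel) == \
            pytest.approx(0.9)

    def test_no_cocalled_snps_is_error(self, small_map):
        panel = make_panel(small_map, [[-1] * 5, [0] * 5])
        with pytest.raises(ValueError, match="co-called"):
            sk.unilateral_allele_sharing("ind0", "ind1", panel)


class TestImputeParent:
    def test_hand_traced_pooling(self, small_map):
        # known parent HOM_A everywhere; offspring {AB, AA, AB} at SNP0
        # deduce alleles {B, A, B} -> HET
        calls = [
            [0, 0, 0, 0, 0],   # known parent
            [1, 1, 0, -1, 1],  # off1
            [0, 1, 0, -1, 1],  # off2
            [1, 1, 1, -1, 1],  # off3
        ]
        panel = make_panel(small_map, calls)
        imp = sk.impute_parent("ghost",
                               [("ind1", "ind0"), ("ind2", "ind0"),
                                ("ind3", "ind0")], panel)
        assert imp.genotypes[0] == sk.HET          # {B, A, B}
        assert imp.genotypes[1] == sk.HOM_B        # {B, B, B}
        assert imp.genotypes[2] == sk.HET          # {A, A, B}
        assert imp.genotypes[3] == UNRESOLVED      # all offspring missing
        assert imp.genotypes[4] == sk.HOM_B

    def test_family_imputation_matches_truth(self, default_map):
        model = sk.SpeciesModel(n_species=1, fst=0.3)
        rng = np.random.default_rng(31)
        panel, truth = sk.simulate_founders(
            model, [sk.FounderGroup("s", 2)], default_map, rng)
        matings = tuple(sk.Mating(f"off{k}", "s_000", "s_001")
                        for k in range(16))
        panel, truth = sk.build_pedigree(sk.PedigreeSpec(matings=matings),
                                         panel, truth, rng)
        fractions = {}
        for size in (2, 4, 8, 16):
            fam = [(f"off{k}", "s_000") for k in range(size)]
            imp = sk.impute_parent("s_001*", fam, panel)
            fractions[size] = imp.imputed_fraction
        # accuracy of resolved calls approaches 100% as the family grows
        truth_calls = panel.genotypes("s_001")
        resolved = imp.genotypes != UNRESOLVED
        acc = (imp.genotypes[resolved] == truth_calls[resolved]).mean()
        assert acc >= 0.99
        assert fractions[16] >= 0.95
        # nested families: resolution only grows with family size
        assert fractions[2] <= fractions[4] <= fractions[8] <= fractions[16]

    def test_failing_offspring_excluded_with_warning(self, family_panel):
        panel, _ = family_panel
        with pytest.warns(UserWarning, match="fails the parent-offspring"):
            imp = sk.impute_parent(
                "ghost", [("child", "sieversii_000"),
                          ("sieversii_003", "sieversii_000"),
                          ("child", "sieversii_001")], panel)
        assert imp.excluded_offspring == ["sieversii_003"]
        assert imp.n_offspring_used == 2

    def test_needs_two_offspring(self, family_panel):
        panel, _ = family_panel
        with pytest.raises(ValueError, match="at least 2"):
            sk.impute_parent("ghost", [("child", "sieversii_000")], panel)


class TestDetectNullSnps:
    def test_inherited_null_flagged_via_offspring(self, default_map):
        model = sk.SpeciesModel(n_species=1, fst=0.3)
        rng = np.random.default_rng(41)
        panel, truth = sk.simulate_founders(
            model, [sk.FounderGroup("s", 6)], default_map, rng)
        # carrier s_000 is A-null at SNP 7; partners are BB there
        snp = 7
        truth.founder_alleles[0, snp] = 0
        truth.founder_alleles[1, snp] = NULL_ALLELE
        for hap in range(2, 12):
            truth.founder_alleles[hap, snp] = 1
        matings = tuple(sk.Mating(f"off{k}", "s_000", f"s_{k + 1:03d}")
                        for k in range(4))
        panel, truth = sk.build_pedigree(sk.PedigreeSpec(matings=matings),
                                         panel, truth, rng)
        calls = np.array([truth.genotypes(i) for i in panel.ids])
        panel = sk.GenotypePanel(panel.gmap, panel.metadata, calls)
        carriers = [f"off{k}" for k in range(4)
                    if panel.genotypes(f"off{k}")[snp] == sk.HOM_B]
        if len(carriers) >= 2:  # null transmitted to >= 2 offspring
            flagged = sk.detect_null_snps("s_000",
                                          [f"off{k}" for k in range(4)], panel)
            assert str(panel.gmap.snp_ids[snp]) in flagged

    def test_zero_noise_no_nulls_empty(self, family_panel):
        panel, _ = family_panel
        assert sk.detect_null_snps("sieversii_000", ["child", "sieversii_001"],
                                   panel) == set()

    def test_single_partner_warns_and_returns_empty(self, family_panel):
        panel, _ = family_panel
        with pytest.warns(UserWarning, match="confirmed partners"):
            out = sk.detect_null_snps("sieversii_000", ["child"], panel)
        assert out == set()
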