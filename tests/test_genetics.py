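"""Mendelian machinery: gametes, crosses, viability rules, classification."""

import itertools

import pytest

from ssims.genetics import (
    Gamete,
    Genotype,
    InvalidGenotypeError,
    all_genotypes,
    classify,
    cross_distribution,
    egi_viable,
    enumerate_gametes,
    fertilize,
    fl_female,
    fl_male,
    ridl_female,
    ridl_male,
    ridl_viable,
    sex_of,
    ssims_female,
    ssims_male,
    wt_female,
    wt_male,
)

STRAIN_FEMALES = [wt_female(), ssims_female(), fl_female(), ridl_female()]
STRAIN_MALES = [wt_male(), ssims_male(), fl_male(), ridl_male()]


class TestGametes:
    def test_distributions_sum_to_one_for_every_genotype(self):
        for g in all_genotypes():
            dist = enumerate_gametes(g)
            assert abs(sum(dist.values()) - 1.0) < 1e-12
            y_mass = sum(p for gam, p in dist.items() if gam.bears_y)
            assert y_mass == pytest.approx(0.5 if not g.is_female else 0.0)

    def test_hemizygous_homozygous_male_emits_two_gametes(self):
        dist = enumerate_gametes(ssims_male())
        assert dist == {
            Gamete("FL", "res", "PTA", "+"): pytest.approx(0.5),
            Gamete(None, "res", "PTA", "+"): pytest.approx(0.5),
        }

    def test_fully_homozygous_female_emits_one_gamete(self):
        dist = enumerate_gametes(wt_female())
        assert dist == {Gamete("+", "wt", "+", "+"): pytest.approx(1.0)}

    def test_triple_heterozygous_female_emits_eight_equiprobable_gametes(self):
        g = Genotype(("+", "FL"), ("res", "wt"), ("PTA", "+"), ("+", "+"))
        dist = enumerate_gametes(g)
        assert len(dist) == 8
        assert all(p == pytest.approx(0.125) for p in dist.values())

    def test_malformed_genotype_rejected(self):
        with pytest.raises(InvalidGenotypeError):
            Genotype(("+",), ("blue", "wt"), ("+", "+"), ("+", "+"))
        with pytest.raises(InvalidGenotypeError):
            Genotype((), ("wt", "wt"), ("+", "+"), ("+", "+"))


class TestFertilize:
    def test_union_of_parental_alleles(self):
        egg = Gamete("+", "wt", "+", "+")
        sperm = Gamete(None, "res", "PTA", "+")
        z = fertilize(egg, sperm)
        assert z.karyotype == "XY"
        assert z.pyr == ("res", "wt")
        assert z.pta == ("+", "PTA")

    def test_ssims_by_ssims_gametes_reconstruct_the_strain(self):
        gam = Gamete("FL", "res", "PTA", "+")
        assert fertilize(gam, gam) == ssims_female()

    def test_y_sperm_gives_male_any_egg(self):
        for mother in STRAIN_FEMALES:
            for egg in enumerate_gametes(mother):
                z = fertilize(egg, Gamete(None, "wt", "+", "+"))
                assert z.karyotype == "XY"

    def test_egg_with_y_rejected(self):
        with pytest.raises(InvalidGenotypeError):
            fertilize(Gamete(None, "wt", "+", "+"), Gamete("+", "wt", "+", "+"))


class TestViability:
    def test_egi_rule_matches_bruteforce_enumeration(self):
        # independent oracle: inviable iff >=1 PTA and >=1 wt promoter
        pairs = lambda a, b: [(a, a), (a, b), (b, b)]  # noqa: E731
        for pta in pairs("PTA", "+"):
            for pyr in pairs("res", "wt"):
                g = Genotype(("+", "+"), pyr, pta, ("+", "+"))
                expected = not ("PTA" in pta and "wt" in pyr)
                assert egi_viable(g) is expected

    def test_hybrid_inviable_truebreeding_viable(self):
        hybrid = Genotype(("+",), ("res", "wt"), ("PTA", "+"), ("+", "+"))
        assert not egi_viable(hybrid)
        assert egi_viable(wt_female())
        assert egi_viable(ssims_male())

    def test_ridl_lethal_off_tet_repressed_on_tet(self):
        het = Genotype(("+",), ("wt", "wt"), ("+", "+"), ("RIDL", "+"))
        assert not ridl_viable(het, 0.0)
        assert ridl_viable(wt_male(), 0.0)
        assert ridl_viable(ridl_male(), 100.0)
        with pytest.raises(InvalidGenotypeError):
            ridl_viable(het, -1.0)

    def test_sex_of(self):
        assert sex_of(wt_female()) == "female"
        assert sex_of(ssims_male()) == "male"


class TestClassify:
    @pytest.mark.parametrize(
        "g, label",
        [
            (wt_female(), "WT"),
            (wt_male(), "WT"),
            (ssims_male(), "SSIMS"),
            (ssims_female(), "SSIMS"),
            (fl_male(), "FL"),
            (ridl_female(), "RIDL"),
            (Genotype(("+",), ("res", "res"), ("PTA", "PTA"), ("+", "+")), "EGI"),
            (Genotype(("+",), ("res", "wt"), ("PTA", "+"), ("+", "+")), "OTHER"),
        ],
    )
    def test_examples(self, g, label):
        assert classify(g) == label

    def test_classification_defined_for_every_genotype(self):
        labels = {"WT", "SSIMS", "EGI", "FL", "RIDL", "OTHER"}
        for g in all_genotypes():
            assert classify(g) in labels


class TestCrossDistribution:
    def test_equals_outer_product_of_gamete_distributions(self):
        # oracle: independently recompute the zygote distribution
        for mother, father in itertools.product(STRAIN_FEMALES, STRAIN_MALES):
            dist = cross_distribution(mother, father)
            assert abs(sum(p for _, p, _ in dist) - 1.0) < 1e-12
            oracle: dict = {}
            for egg, pe in enumerate_gametes(mother).items():
                for sperm, ps in enumerate_gametes(father).items():
                    z = fertilize(egg, sperm)
                    oracle[z] = oracle.get(z, 0.0) + pe * ps
            assert {g: p for g, p, _ in dist} == pytest.approx(oracle)
            for g, _, flag in dist:
                assert flag == egi_viable(g)

    def test_x_linkage_sons_never_daughters_always_carry_fathers_x(self):
        for mother, father in itertools.product(STRAIN_FEMALES, STRAIN_MALES):
            fx = father.x[0]
            for child, p, _ in cross_distribution(mother, father):
                if p == 0:
                    continue
                if child.is_female:
                    assert fx in child.x
                else:
                    assert child.x[0] in mother.x

    def test_ssims_father_wt_mother_every_offspring_inviable(self):
        dist = cross_distribution(wt_female(), ssims_male())
        inviable = sum(p for _, p, v in dist if not v)
        assert inviable == pytest.approx(1.0)
        for child, _, _ in dist:
            assert child.pta == ("+", "PTA")
            assert child.pyr == ("res", "wt")

    def test_wt_cross_and_truebreeding_ssims(self):
        dist = cross_distribution(wt_female(), wt_male())
        assert all(classify(g) == "WT" and v for g, _, v in dist)
        dist = cross_distribution(ssims_female(), ssims_male())
        assert all(classify(g) == "SSIMS" and v for g, _, v in dist)

    def test_same_sex_cross_rejected(self):
        with pytest.raises(InvalidGenotypeError):
            cross_distribution(wt_male(), wt_male())
        with pytest.raises(InvalidGenotypeError):
            cross_distribution(wt_female(), wt_female())


class TestSerialization:
    def test_roundtrip_is_lossless_for_every_genotype(self):
        for g in all_genotypes():
            assert Genotype.from_string(g.to_string()) == g

    def test_known_code(self):
        assert ssims_male().to_string() == "XFL/Y;res,res;PTA,PTA;+,+"
        assert Genotype.from_string("XFL/Y;res,res;PTA,PTA;+,+") == ssims_male()

    @pytest.mark.parametrize(
        "code", ["", "X+/Y;wt,wt;+,+", "Y/Y;wt,wt;+,+;+,+", "X+/Y;wt;+,+;+,+"]
    )
    def test_malformed_codes_rejected(self, code):
        with pytest.raises(InvalidGenotypeError):
            Genotype.from_string(code)
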