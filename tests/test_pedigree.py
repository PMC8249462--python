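import math
from fractions import Fraction

import numpy as np
import pytest

from wolfped import pedigree as pd_
from wolfped.genodata import MicrosatGenotype


def simple_family():
    ped = pd_.Pedigree()
    ped.add_individual("sire", sex="M")
    ped.add_individual("dam", sex="F")
    for kid in ("kid1", "kid2"):
        ped.add_individual(kid, "sire", "dam")
    return ped


def gene_drop_kinship(ped, i, j, n=100_000, seed=0):
    """Independent Monte-Carlo oracle: drop unique founder alleles through
    the pedigree and estimate P(IBD) between random alleles of i and j."""
    rng = np.random.default_rng(seed)
    order = sorted(ped.members, key=ped.depth)
    alleles: dict[str, np.ndarray] = {}
    label = [0]

    def fresh():
        label[0] += 1
        return label[0]

    for ind in order:
        m = ped.members[ind]
        arr = np.empty((n, 2), dtype=np.int64)
        for col, parent in enumerate((m.sire, m.dam)):
            if parent is None:
                # an unknown parent is a unique founder: the transmitted
                # allele can never be IBD with anything else
                arr[:, col] = fresh()
            else:
                p = alleles[parent]
                arr[:, col] = p[np.arange(n), rng.integers(0, 2, n)]
        alleles[ind] = arr
    a, b = alleles[i], alleles[j]
    v = ((a[:, 0] == b[:, 0]).astype(float) + (a[:, 0] == b[:, 1])
         + (a[:, 1] == b[:, 0]) + (a[:, 1] == b[:, 1])) / 4.0
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(n))


class TestKinship:
    def test_full_sibs(self):
        ped = simple_family()
        assert ped.kinship("kid1", "kid2") == pytest.approx(0.25)

    def test_unrelated_founders(self):
        ped = simple_family()
        assert ped.kinship("sire", "dam") == 0.0

    def test_parent_offspring(self):
        ped = simple_family()
        assert ped.kinship("sire", "kid1") == pytest.approx(0.25)

    def test_self_kinship(self):
        ped = simple_family()
        assert ped.kinship("kid1", "kid1") == pytest.approx(0.5)

    def test_symmetry(self, ref_fixture):
        ped = ref_fixture.pedigree
        for a, b in (("GW038m", "GW114f"), ("GW283m", "GW277f")):
            assert ped.kinship(a, b) == ped.kinship(b, a)

    def test_exact_rational(self):
        ped = simple_family()
        assert ped.kinship("kid1", "kid2", exact=True) == Fraction(1, 4)

    def test_reference_value_sp_pair(self, ref_fixture):
        ped = ref_fixture.pedigree
        fp = pd_.round_half_up(float(ped.kinship("GW037m", "GW058f",
                                                 exact=True)), 3)
        assert fp == 0.203

    def test_unknown_parent_contributes_zero(self):
        ped = pd_.Pedigree()
        ped.add_individual("f1")
        ped.add_individual("half1", sire="f1")     # dam unknown
        ped.add_individual("half2", sire="f1")
        assert ped.kinship("half1", "half2") == pytest.approx(0.125)

    def test_adding_unrelated_founder_changes_nothing(self, ref_fixture):
        import copy
        ped = copy.deepcopy(ref_fixture.pedigree)
        before = ped.kinship("GW283m", "GW277f")
        ped.add_individual("NEW001m")
        assert ped.kinship("GW283m", "GW277f") == before
        assert ped.kinship("NEW001m", "GW283m") == 0.0

    def test_cycle_detection(self):
        ped = pd_.Pedigree()
        ped.add_individual("a", sire="b")
        ped.add_individual("b", sire="a")
        with pytest.raises(pd_.PedigreeCycleError):
            ped.kinship("a", "b")

    def test_missing_individual(self):
        ped = simple_family()
        with pytest.raises(ValueError):
            ped.kinship("kid1", "ghost")

    def test_inbreeding_of_founder_offspring_zero(self):
        ped = simple_family()
        assert ped.inbreeding("kid1") == 0.0

    def test_gene_dropping_oracle_reference_pedigree(self, ref_fixture):
        ped = ref_fixture.pedigree
        for a, b, seed in (("GW283m", "GW277f", 1), ("GW038m", "GW114f", 2),
                           ("GW213m", "GW263f", 3)):
            est, se = gene_drop_kinship(ped, a, b, n=100_000, seed=seed)
            assert abs(est - float(ped.kinship(a, b))) < 3 * se

    def test_gene_dropping_oracle_random_pedigree(self):
        rng = np.random.default_rng(17)
        ped = pd_.Pedigree()
        ids = []
        for k in range(30):
            if k < 6:
                ped.add_individual(f"i{k}")
            else:
                sire, dam = rng.choice(ids, 2, replace=False)
                ped.add_individual(f"i{k}", sire=str(sire), dam=str(dam))
            ids.append(f"i{k}")
        for a, b in (("i28", "i29"), ("i20", "i25"), ("i29", "i29")):
            est, se = gene_drop_kinship(ped, a, b, n=100_000,
                                        seed=hash((a, b)) % 2 ** 31)
            assert abs(est - float(ped.kinship(a, b))) < 3 * max(se, 1e-4)


class TestPedigreeStructure:
    def test_validate_parent_sex(self):
        ped = pd_.Pedigree()
        ped.add_individual("a", sex="F")
        ped.add_individual("b", sire="a")      # sire must be male
        with pytest.raises(ValueError):
            ped.validate()

    def test_founder_flag(self):
        ped = simple_family()
        assert set(ped.founders) == {"sire", "dam"}

    def test_roundtrip(self, tmp_path, ref_fixture):
        path = tmp_path / "ped.csv"
        ref_fixture.pedigree.write(path)
        back = pd_.Pedigree.read(path)
        assert set(back.members) == set(ref_fixture.pedigree.members)
        m0 = ref_fixture.pedigree.members["GW283m"]
        m1 = back.members["GW283m"]
        assert (m1.sire, m1.dam, m1.sex) == (m0.sire, m0.dam, m0.sex)
        assert back.kinship("GW283m", "GW277f") == \
            ref_fixture.pedigree.kinship("GW283m", "GW277f")


class TestBreedingPairsAndLitters:
    def test_expand_years(self):
        assert pd_.expand_years(2009, 2015) == tuple(range(2009, 2016))
        assert pd_.expand_years(2012, 2012) == (2012,)
        with pytest.raises(ValueError):
            pd_.expand_years(2015, 2012)

    def test_single_pair_single_year(self):
        ped = simple_family()
        pair = pd_.BreedingPair("T1", "sire", "dam", (2010,))
        summ = pd_.litter_summary([pair], ped)
        assert summ.n_litters == 1
        assert summ.mean_bond_years == 1.0

    def test_inbreeding_coefficient_missing_breeder(self):
        ped = simple_family()
        pair = pd_.BreedingPair("T1", "ghost", "dam", (2010,))
        with pytest.raises(ValueError):
            pd_.inbreeding_coefficient(ped, pair)

    def test_full_sib_pair_fp(self):
        ped = simple_family()
        pair = pd_.BreedingPair("T1", "kid1", "kid2", (2012, 2013))
        assert pd_.inbreeding_coefficient(ped, pair) == pytest.approx(0.25)

    def test_round_half_up(self):
        assert pd_.round_half_up(0.0625, 3) == 0.063
        assert pd_.round_half_up(0.328125, 3) == 0.328
        assert pd_.round_half_up(0.1015625, 3) == 0.102


class TestParentage:
    @staticmethod
    def cand(territory, male_loci, female_loci, years=(2010,)):
        return pd_.CandidatePair(
            pd_.BreedingPair(territory, f"{territory}m", f"{territory}f", years),
            MicrosatGenotype(f"{territory}m", male_loci),
            MicrosatGenotype(f"{territory}f", female_loci))

    def test_forced_transmission_compatible(self):
        off = MicrosatGenotype("o", {f"L{i}": (1, 2) for i in range(8)})
        c = self.cand("A", {f"L{i}": (1, 1) for i in range(8)},
                      {f"L{i}": (2, 2) for i in range(8)})
        res = pd_.assign_parentage(off, [c], max_mendelian_mismatches=0)
        assert res.is_assigned and res.assigned.pair.territory == "A"

    def test_two_exclusions_exceed_tolerance(self):
        loci = {f"L{i}": (1, 1) for i in range(8)}
        off_loci = dict(loci)
        off_loci["L0"] = (3, 3)
        off_loci["L1"] = (3, 3)
        off = MicrosatGenotype("o", off_loci)
        c = self.cand("A", loci, loci)
        res = pd_.assign_parentage(off, [c], max_mendelian_mismatches=1)
        assert not res.is_assigned

    def test_ambiguous_unassigned_with_candidates(self):
        off = MicrosatGenotype("o", {f"L{i}": (1, 2) for i in range(8)})
        loci_m = {f"L{i}": (1, 1) for i in range(8)}
        loci_f = {f"L{i}": (2, 2) for i in range(8)}
        res = pd_.assign_parentage(off, [self.cand("A", loci_m, loci_f),
                                         self.cand("B", loci_m, loci_f)])
        assert not res.is_assigned
        assert set(res.candidates_surviving) == {"A", "B"}

    def test_untestable_below_comparable_threshold(self):
        off = MicrosatGenotype("o", {f"L{i}": (1, 2) for i in range(4)})
        c = self.cand("A", {f"L{i}": (1, 1) for i in range(4)},
                      {f"L{i}": (2, 2) for i in range(4)})
        res = pd_.assign_parentage(off, [c])
        assert not res.is_assigned
        assert res.untestable == ["A"]

    def test_temporal_filter(self):
        off = MicrosatGenotype("o", {f"L{i}": (1, 2) for i in range(8)})
        c = self.cand("A", {f"L{i}": (1, 1) for i in range(8)},
                      {f"L{i}": (2, 2) for i in range(8)}, years=(2014,))
        res = pd_.assign_parentage(off, [c], year=2012)
        assert not res.is_assigned

    def test_mendelian_mismatch_counting(self):
        off = MicrosatGenotype("o", {"L1": (1, 3)})
        sire = MicrosatGenotype("s", {"L1": (1, 2)})
        dam = MicrosatGenotype("d", {"L1": (2, 2)})
        assert pd_.mendelian_mismatches(off, sire, dam) == (1, 1)
        dam2 = MicrosatGenotype("d2", {"L1": (3, 4)})
        assert pd_.mendelian_mismatches(off, sire, dam2) == (1, 0)
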