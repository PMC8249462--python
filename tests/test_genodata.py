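import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wolfped import genodata as gd
from wolfped.simulate import SimConfig, simulate_recolonization, simulate_sampling


def sample_with(calls, sex_flags=None, **kw):
    return gd.SampleRecord("S1", calls=calls,
                           sex_flags=sex_flags or [(True, False)] * 3, **kw)


class TestCallConsensus:
    def test_het_seen_twice_accepted(self):
        s = sample_with({"L1": [(120, 124), (120, 120), (120, 124)]})
        g = gd.call_consensus(s, min_loci=1)
        assert g.loci["L1"] == (120, 124)

    def test_homozygote_needs_three(self):
        s = sample_with({"L1": [(120, 120), (120, 120)]})
        g = gd.call_consensus(s, min_loci=0)
        assert g.loci["L1"] is None

    def test_homozygote_three_accepted(self):
        s = sample_with({"L1": [(120, 120), (120, 120), (120, 120)]})
        g = gd.call_consensus(s, min_loci=1)
        assert g.loci["L1"] == (120, 120)

    def test_het_beats_homozygote(self):
        calls = {"L1": [(120, 124), (120, 124), (120, 120),
                        (120, 120), (120, 120)]}
        g = gd.call_consensus(sample_with(calls), min_loci=1)
        assert g.loci["L1"] == (120, 124)

    def test_nine_loci_rejected(self):
        calls = {f"L{i}": [(100, 102)] * 2 for i in range(9)}
        res = gd.call_consensus(sample_with(calls), min_loci=10)
        assert isinstance(res, gd.ConsensusRejected)
        assert res.n_loci_typed == 9

    def test_conflicting_heterozygotes_flagged_missing(self):
        calls = {"L1": [(120, 124), (120, 124), (120, 128), (120, 128)]}
        g = gd.call_consensus(sample_with(calls), min_loci=0)
        assert g.loci["L1"] is None
        assert any("conflict" in w for w in g.warnings)

    def test_empty_replicates_error(self):
        with pytest.raises(ValueError):
            gd.call_consensus(gd.SampleRecord("S1"))

    def test_precondition_validation(self):
        s = sample_with({"L1": [(1, 2)]})
        with pytest.raises(ValueError):
            gd.call_consensus(s, het_min=0)
        with pytest.raises(ValueError):
            gd.call_consensus(s, het_min=3, hom_min=2)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from([100, 102, 104]),
                              st.sampled_from([100, 102, 104])),
                    min_size=1, max_size=8),
           st.integers(2, 3), st.integers(3, 4))
    def test_support_thresholds_never_violated(self, reps, het_min, hom_min):
        calls = {"L1": [tuple(sorted(p)) for p in reps]}
        g = gd.call_consensus(sample_with(calls), min_loci=0,
                              het_min=het_min, hom_min=hom_min)
        pair = g.loci["L1"]
        if pair is None:
            return
        support = calls["L1"].count(pair)
        assert support >= (het_min if pair[0] != pair[1] else hom_min)


class TestAssignSex:
    def test_male(self):
        s = sample_with({}, sex_flags=[(True, True)] * 3)
        assert gd.assign_sex(s) == gd.MALE

    def test_female(self):
        s = sample_with({}, sex_flags=[(True, False)] * 2)
        assert gd.assign_sex(s) == gd.FEMALE

    def test_single_replicate_unknown(self):
        assert gd.assign_sex(sample_with({}, [(True, True)])) == gd.UNKNOWN
        assert gd.assign_sex(sample_with({}, [(True, False)])) == gd.UNKNOWN

    def test_contradiction_equal_support_unknown(self):
        s = sample_with({}, [(True, True), (True, True),
                             (True, False), (True, False)])
        assert gd.assign_sex(s) == gd.UNKNOWN

    def test_no_amplification_unknown(self):
        assert gd.assign_sex(sample_with({}, [(False, False)] * 4)) == gd.UNKNOWN


class TestHaplotypeAssignment:
    REFS = gd.ReferenceHaplotypeSet({
        "HW01": "ACGT" * 98,               # 392 bp
        "HW02": ("ACGT" * 98)[:250].replace("A", "T", 1),
    })

    def test_exact_identity(self):
        refs = gd.ReferenceHaplotypeSet({"A": "AC" * 125, "B": "GT" * 125})
        assert gd.assign_mtdna_haplotype("AC" * 125, refs) == "A"

    def test_subwindow_containment(self):
        ref = "ACGT" * 98
        refs = gd.ReferenceHaplotypeSet({"HW01": ref})
        assert gd.assign_mtdna_haplotype(ref[50:300], refs) == "HW01"

    def test_one_mismatch_everywhere_no_match(self):
        refs = gd.ReferenceHaplotypeSet({"A": "AC" * 125, "B": "GT" * 125})
        query = "AC" * 124 + "AG"     # ends differ from both refs
        assert gd.assign_mtdna_haplotype(query, refs) == gd.NO_MATCH

    def test_ambiguous_raises(self):
        ref = "ACGT" * 98
        refs = gd.ReferenceHaplotypeSet({"X": ref, "Y": ref[:260]})
        with pytest.raises(gd.AmbiguousHaplotypeError):
            gd.assign_mtdna_haplotype(ref[:250], refs)

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            gd.assign_mtdna_haplotype("ACGT" * 10, self.REFS)


class TestIdentify:
    def two_gts(self, diff_loci, n_loci=13):
        base = {f"L{i}": (100 + 2 * i, 104 + 2 * i) for i in range(n_loci)}
        other = dict(base)
        for i in range(diff_loci):
            a, b = base[f"L{i}"]
            other[f"L{i}"] = (a, a)      # dropout-like difference
        return (gd.MicrosatGenotype("s1", base),
                gd.MicrosatGenotype("s2", other))

    def test_identical_merge(self):
        g1, g2 = self.two_gts(0)
        res = gd.identify_individuals([g1, g2], max_mismatch_loci=1)
        assert len(res.individuals) == 1
        assert res.individuals[0].n_samples == 2

    def test_three_mismatches_split(self):
        g1, g2 = self.two_gts(3)
        res = gd.identify_individuals([g1, g2], max_mismatch_loci=1)
        assert len(res.individuals) == 2

    def test_conflicting_third_allele_refused(self):
        g1, g2 = self.two_gts(0)
        a, b = g2.loci["L0"]
        g2.loci["L0"] = (a, b + 20)      # A/B vs A/C: three alleles
        res = gd.identify_individuals([g1, g2], max_mismatch_loci=1)
        assert len(res.individuals) == 2
        assert res.flagged_pairs

    def test_merged_consensus_prefers_heterozygote(self):
        g1, g2 = self.two_gts(1)
        res = gd.identify_individuals([g1, g2], max_mismatch_loci=1)
        assert res.individuals[0].genotype.loci["L0"] == (100, 104)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        gts = []
        for k in range(12):
            base = {f"L{i}": (100 + 2 * (k % 4), 102 + 2 * (k % 4))
                    for i in range(13)}
            gts.append(gd.MicrosatGenotype(f"s{k}", base))
        ref = gd.identify_individuals(gts, max_mismatch_loci=0)
        for _ in range(3):
            perm = list(rng.permutation(len(gts)))
            res = gd.identify_individuals([gts[i] for i in perm],
                                          max_mismatch_loci=0)
            assert len(res.individuals) == len(ref.individuals)
            ref_parts = {frozenset(i.sample_ids) for i in ref.individuals}
            res_parts = {frozenset(i.sample_ids) for i in res.individuals}
            assert ref_parts == res_parts

    def test_zero_noise_recovers_truth_exactly(self):
        cfg = SimConfig(seed=7, n_years=6, dropout_rate=0.0,
                        false_allele_rate=0.0)
        truth = simulate_recolonization(cfg)
        sset = simulate_sampling(truth)
        gts = []
        for s in sset.samples:
            res = gd.call_consensus(s)
            assert not isinstance(res, gd.ConsensusRejected)
            gts.append(res)
        ident = gd.identify_individuals(gts, max_mismatch_loci=0)
        truth_parts = {}
        for s in sset.samples:
            truth_parts.setdefault(sset.sample_to_individual[s.sample_id],
                                   set()).add(s.sample_id)
        # distinct true individuals may collide only if genotypes coincide
        gt_of = {i.id: tuple(sorted(i.genotype.items()))
                 for i in truth.individuals.values()}
        expected = {}
        for ind, sids in truth_parts.items():
            expected.setdefault(gt_of[ind], set()).update(sids)
        got = {frozenset(i.sample_ids) for i in ident.individuals}
        assert got == {frozenset(v) for v in expected.values()}


class TestIO:
    def test_sample_table_roundtrip(self, tmp_path, small_truth, small_samples):
        from wolfped.simulate import write_sample_csv
        path = tmp_path / "samples.csv"
        write_sample_csv(small_samples, path)
        records = gd.read_sample_table(path)
        assert len(records) == len(small_samples.samples)
        orig = small_samples.samples[0]
        back = next(r for r in records if r.sample_id == orig.sample_id)
        assert back.calls == orig.calls
        assert back.sex_flags == orig.sex_flags

    def test_genepop_roundtrip(self, tmp_path):
        gts = [gd.MicrosatGenotype("a", {"L1": (100, 104), "L2": None}),
               gd.MicrosatGenotype("b", {"L1": (98, 98), "L2": (200, 202)})]
        path = tmp_path / "x.gen"
        gd.to_genepop(gts, path, loci=("L1", "L2"))
        back = gd.read_genepop(path)
        assert [g.loci for g in back] == [g.loci for g in gts]

    def test_individual_table(self, tmp_path):
        gts = [gd.MicrosatGenotype("a", {"L1": (100, 104)})]
        res = gd.identify_individuals(gts, min_comparable_loci=1)
        out = tmp_path / "ind.csv"
        gd.write_individual_table(res, out, loci=("L1",))
        text = out.read_text()
        assert "L1_a" in text and "100" in text

    def test_sex_suffix_advisory(self):
        g = gd.MicrosatGenotype("GW001m", {})
        assert g.sex == gd.MALE
        g2 = gd.MicrosatGenotype("GW002f", {}, sex=gd.MALE)
        assert g2.sex == gd.MALE           # marker call wins
        assert g2.warnings
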