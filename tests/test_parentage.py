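"""Mendelian comparison, inclusion filtering and paternity verdicts."""

import numpy as np
import pytest

from progenyarray import (
    AssignmentConfig,
    AssignmentStatus,
    Generation,
    MultilocusGenotype,
    assign_family,
    assign_paternity,
    compare_to_mother,
    passes_inclusion,
    score_candidate,
    selfing_probability,
    simulate_progeny_arrays,
)
from progenyarray.parentage import ParentageError

from conftest import oracle_assign, random_parentage_instance


def geno(ind_id, calls, gen=Generation.F1, mother=None):
    return MultilocusGenotype(ind_id, gen, mother, calls)


class TestCompareToMother:
    def test_one_non_maternal_allele_is_outcross_consistent(self):
        mom = geno("M", {"L1": (101, 103)})
        juv = geno("J", {"L1": (101, 105)}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, ["L1"])
        assert cmp.outcross_consistent_loci == {"L1"}
        assert cmp.paternal_allele_sets["L1"] == {105}

    def test_both_alleles_maternal_is_ambiguous(self):
        mom = geno("M", {"L1": (101, 103)})
        juv = geno("J", {"L1": (101, 103)}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, ["L1"])
        assert not cmp.outcross_consistent_loci
        assert not cmp.maternal_mismatch_loci
        assert cmp.paternal_allele_sets["L1"] == {101, 103}

    def test_no_shared_allele_is_maternal_mismatch(self):
        mom = geno("M", {"L1": (101, 101)})
        juv = geno("J", {"L1": (103, 105)}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, ["L1"])
        assert cmp.maternal_mismatch_loci == {"L1"}
        assert cmp.paternal_allele_sets["L1"] == {103, 105}

    def test_homozygous_non_maternal_juvenile_is_mismatch_not_outcross(self):
        # juvenile (b,b) with b absent from the mother shares no allele
        # with her, despite having only one distinct non-maternal allele
        mom = geno("M", {"L1": (101, 103)})
        juv = geno("J", {"L1": (105, 105)}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, ["L1"])
        assert cmp.maternal_mismatch_loci == {"L1"}

    def test_missing_loci_do_not_count_as_shared(self):
        loci = [f"L{i}" for i in range(9)]
        mom = geno("M", {l: (1, 2) for l in loci})
        juv_calls = {l: (1, 3) for l in loci[:7]}
        juv = geno("J", juv_calls, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, loci)
        assert cmp.n_shared_loci == 7

    def test_wrong_mother_id_rejected(self):
        juv = geno("J", {}, Generation.F2, "OTHER")
        with pytest.raises(ParentageError):
            compare_to_mother(juv, geno("M", {}), [])


@pytest.mark.parametrize(
    "n_shared, n_mismatch, expect_pass, reason_part",
    [
        (5, 0, False, "criterion-i"),
        (6, 2, False, "criterion-iii"),
        (6, 1, True, None),
        (8, 2, True, None),
        (8, 3, False, "criterion-ii"),
        (10, 0, True, None),
    ],
)
def test_inclusion_criteria(n_shared, n_mismatch, expect_pass, reason_part):
    """At least six shared loci, at most two maternal mismatches, and at
    most one mismatch when exactly six loci are shared."""
    loci = [f"L{i:02d}" for i in range(n_shared)]
    mom = geno("M", {l: (1, 2) for l in loci})
    juv_calls = {}
    for i, l in enumerate(loci):
        juv_calls[l] = (8, 9) if i < n_mismatch else (1, 3)
    juv = geno("J", juv_calls, Generation.F2, "M")
    cmp = compare_to_mother(juv, mom, loci)
    assert cmp.n_shared_loci == n_shared
    assert len(cmp.maternal_mismatch_loci) == n_mismatch
    ok, reason = passes_inclusion(cmp)
    assert ok is expect_pass
    if reason_part:
        assert reason_part in reason


class TestScoreCandidate:
    loci = [f"L{i:02d}" for i in range(9)]

    def make_cmp(self):
        mom = geno("M", {l: (1, 2) for l in self.loci})
        juv = geno("J", {l: (1, 5) for l in self.loci}, Generation.F2, "M")
        return compare_to_mother(juv, mom, self.loci)

    def test_candidate_with_paternal_allele_everywhere_is_perfect(self):
        cmp = self.make_cmp()
        cand = geno("C", {l: (5, 7) for l in self.loci})
        m = score_candidate(cmp, cand)
        assert m.perfect and m.mismatch_count == 0 and m.n_comparable_loci == 9

    def test_one_lacking_locus_means_one_mismatch(self):
        cmp = self.make_cmp()
        calls = {l: (5, 7) for l in self.loci}
        calls["L00"] = (7, 7)
        m = score_candidate(cmp, geno("C", calls))
        assert m.mismatch_count == 1 and not m.perfect

    def test_mother_is_perfect_selfing_match_when_juvenile_all_maternal(self):
        mom = geno("M", {l: (1, 2) for l in self.loci})
        juv = geno("J", {l: (1, 2) for l in self.loci}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, self.loci)
        m = score_candidate(cmp, mom)
        assert m.perfect

    def test_zero_comparable_loci_flagged_unusable(self):
        cmp = self.make_cmp()
        m = score_candidate(cmp, geno("C", {}))
        assert not m.usable and m.n_comparable_loci == 0


class TestAssignPaternity:
    loci = [f"L{i:02d}" for i in range(9)]

    def test_selfed_when_only_selfing_hypothesis_eligible(self):
        mom = geno("M", {l: (1, 2) for l in self.loci})
        juv = geno("J", {l: (1, 2) for l in self.loci}, Generation.F2, "M")
        bad_father = geno("C", {l: (8, 9) for l in self.loci})
        cmp = compare_to_mother(juv, mom, self.loci)
        a = assign_paternity(cmp, [mom, bad_father])
        assert a.status is AssignmentStatus.selfed

    def test_outcrossed_to_unique_perfect_candidate(self):
        mom = geno("M", {l: (1, 2) for l in self.loci})
        juv_calls = {l: (1, 2) for l in self.loci}
        for l in self.loci[:3]:
            juv_calls[l] = (1, 5)  # three outcross-consistent loci
        juv = geno("J", juv_calls, Generation.F2, "M")
        # carries the singleton paternal allele at outcross-consistent
        # loci and a juvenile allele at the ambiguous ones
        father = geno("C", {l: (1, 5) for l in self.loci})
        cmp = compare_to_mother(juv, mom, self.loci)
        a = assign_paternity(cmp, [mom, father])
        assert a.status is AssignmentStatus.outcrossed
        assert a.assigned_father_id == "C"

    def test_tie_without_frequencies_is_ambiguous(self):
        mom = geno("M", {l: (1, 2) for l in self.loci})
        juv = geno("J", {l: (1, 5) for l in self.loci}, Generation.F2, "M")
        c1 = geno("C1", {l: (5, 6) for l in self.loci})
        c2 = geno("C2", {l: (5, 7) for l in self.loci})
        cmp = compare_to_mother(juv, mom, self.loci)
        a = assign_paternity(cmp, [mom, c1, c2], AssignmentConfig(tie_break="none"))
        assert a.status is AssignmentStatus.ambiguous

    def test_likelihood_tie_break_prefers_more_probable_sire(self):
        # both candidates carry the paternal allele 5; C1 is homozygous
        # for it and so transmits it with probability 1 vs 1/2
        mom = geno("M", {l: (1, 2) for l in self.loci})
        juv = geno("J", {l: (1, 5) for l in self.loci}, Generation.F2, "M")
        c1 = geno("C1", {l: (5, 5) for l in self.loci})
        c2 = geno("C2", {l: (5, 7) for l in self.loci})
        cmp = compare_to_mother(juv, mom, self.loci)
        freqs = {l: {1: 0.25, 2: 0.25, 5: 0.25, 7: 0.25} for l in self.loci}
        a = assign_paternity(
            cmp, [mom, c1, c2], AssignmentConfig(allele_freqs=freqs)
        )
        assert a.status is AssignmentStatus.outcrossed
        assert a.assigned_father_id == "C1"

    def test_failed_inclusion_is_excluded(self):
        mom = geno("M", {l: (1, 2) for l in self.loci[:5]})
        juv = geno("J", {l: (1, 2) for l in self.loci[:5]}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, self.loci)
        a = assign_paternity(cmp, [mom])
        assert a.status is AssignmentStatus.excluded
        assert "criterion-i" in a.exclusion_reason

    def test_empty_candidate_list_rejected(self):
        mom = geno("M", {l: (1, 2) for l in self.loci})
        juv = geno("J", {l: (1, 2) for l in self.loci}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, self.loci)
        with pytest.raises(ParentageError):
            assign_paternity(cmp, [])

    def test_selfed_at_zero_tolerance_has_clean_maternal_comparison(self):
        """A max_mismatch=0 selfing verdict implies no outcross-consistent
        and no maternal-mismatch loci."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            juv, mom, cands, loci = random_parentage_instance(rng)
            cmp = compare_to_mother(juv, mom, loci)
            a = assign_paternity(cmp, cands, AssignmentConfig(max_mismatch=0, tie_break="none"))
            if a.status is AssignmentStatus.selfed:
                assert not cmp.outcross_consistent_loci
                assert not cmp.maternal_mismatch_loci

    def test_raising_tolerance_never_unassigns(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            juv, mom, cands, loci = random_parentage_instance(rng)
            cmp = compare_to_mother(juv, mom, loci)
            assigned_low = assign_paternity(
                cmp, cands, AssignmentConfig(max_mismatch=1, tie_break="none")
            ).status in (AssignmentStatus.selfed, AssignmentStatus.outcrossed)
            status_high = assign_paternity(
                cmp, cands, AssignmentConfig(max_mismatch=3, tie_break="none")
            ).status
            if assigned_low:
                assert status_high is not AssignmentStatus.unassigned


def test_assignment_matches_bruteforce_oracle():
    """Verdicts equal exhaustive enumeration over candidate x locus
    tables on random instances (<=10 candidates, <=10 loci)."""
    rng = np.random.default_rng(17)
    for _ in range(300):
        juv, mom, cands, loci = random_parentage_instance(rng)
        cmp = compare_to_mother(juv, mom, loci)
        a = assign_paternity(cmp, cands, AssignmentConfig(tie_break="none"))
        status, father, best = oracle_assign(juv, mom, cands, loci)
        assert a.status.value == status
        assert a.assigned_father_id == father
        assert a.best_mismatches == best


class TestSelfingProbability:
    def test_heterozygous_single_locus_posterior_half(self):
        """Mother (a,b), juvenile (a,b), equifrequent alleles: selfing
        and random-sire likelihoods are both 1/2, prior 1/2 -> 1/2."""
        mom = geno("M", {"L1": (1, 2)})
        juv = geno("J", {"L1": (1, 2)}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, ["L1"])
        p = selfing_probability(cmp, [], {"L1": {1: 0.5, 2: 0.5}})
        assert p == pytest.approx(0.5)

    def test_non_maternal_allele_gives_posterior_zero(self):
        mom = geno("M", {"L1": (1, 2)})
        juv = geno("J", {"L1": (1, 5)}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, ["L1"])
        p = selfing_probability(cmp, [], {"L1": {1: 0.5, 2: 0.3, 5: 0.2}})
        assert p == 0.0

    def test_rare_allele_homozygote_posterior_increases_with_loci(self):
        """Mother and juvenile homozygous for a p=0.01 allele at every
        locus: posterior -> 1 as the locus count grows."""
        freq = {1: 0.01, 2: 0.99}
        posteriors = []
        for n_loci in (1, 3, 6, 9):
            loci = [f"L{i}" for i in range(n_loci)]
            mom = geno("M", {l: (1, 1) for l in loci})
            juv = geno("J", {l: (1, 1) for l in loci}, Generation.F2, "M")
            cmp = compare_to_mother(juv, mom, loci)
            posteriors.append(
                selfing_probability(cmp, [], {l: freq for l in loci})
            )
        assert posteriors == sorted(posteriors)
        assert posteriors[-1] > 0.99
        # hand enumeration for one locus: L_self = 1, L_random = 0.01
        assert posteriors[0] == pytest.approx(1.0 / 1.01)

    def test_invariant_to_allele_relabelling_and_locus_order(self):
        loci = ["L1", "L2", "L3"]
        mom = geno("M", {l: (1, 2) for l in loci})
        juv = geno("J", {l: (1, 1) for l in loci}, Generation.F2, "M")
        freqs = {l: {1: 0.3, 2: 0.7} for l in loci}
        cmp = compare_to_mother(juv, mom, loci)
        base = selfing_probability(cmp, [], freqs)
        # relabel 1 -> 11, 2 -> 22 and reverse locus order
        relab = {1: 11, 2: 22}
        mom2 = geno("M", {l: (11, 22) for l in loci})
        juv2 = geno("J", {l: (11, 11) for l in loci}, Generation.F2, "M")
        freqs2 = {l: {relab[a]: p for a, p in freqs[l].items()} for l in loci}
        cmp2 = compare_to_mother(juv2, mom2, list(reversed(loci)))
        assert selfing_probability(cmp2, [], freqs2) == pytest.approx(base)

    def test_inconsistent_genotypes_raise(self):
        mom = geno("M", {"L1": (1, 2)})
        juv = geno("J", {"L1": (5, 6)}, Generation.F2, "M")
        cmp = compare_to_mother(juv, mom, ["L1"])
        father = geno("C", {"L1": (8, 9)})
        with pytest.raises(ParentageError, match="zero"):
            selfing_probability(cmp, [father], None, include_random_sire=False)


class TestAssignFamily:
    def test_selfed_family_with_unrelated_candidate(self):
        rng = np.random.default_rng(2)
        table, truth, cand_map = simulate_progeny_arrays(
            n_families=1, n_juveniles=3, selfing_rate=1.0, n_candidates=1, seed=21
        )
        mother = table.get("M001")
        juvs = [i for i in table.individuals if i.individual_id.startswith("J")]
        cands = [table.get(c) for c in cand_map["M001"]]
        assignments, summary = assign_family(mother, juvs, cands, table.active_loci)
        assert summary.n_selfed == 3 and summary.n_outcrossed == 0

    def test_counts_always_add_up(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            juv, mom, cands, loci = random_parentage_instance(rng)
            assignments, s = assign_family(mom, [juv], cands, loci)
            assert s.n_genotyped == s.n_excluded + s.n_unassigned + s.n_ambiguous + s.n_assigned
            assert s.n_assigned == s.n_selfed + s.n_outcrossed

    def test_inclusion_failure_reduces_assigned_count(self):
        loci = [f"L{i:02d}" for i in range(9)]
        mom = geno("M", {l: (1, 2) for l in loci})
        good = geno("J1", {l: (1, 2) for l in loci}, Generation.F2, "M")
        bad = geno("J2", {l: (1, 2) for l in loci[:4]}, Generation.F2, "M")
        assignments, s = assign_family(mom, [good, bad], [mom], loci)
        assert s.n_genotyped == 2 and s.n_excluded == 1 and s.n_assigned == 1


def test_true_sire_recovery_on_clean_data():
    """Noise-free data, 9 loci x 10 equifrequent alleles: >= 99% of
    outcrossed juveniles recover their true sire; false selfing calls
    stay below 1%."""
    table, truth, cand_map = simulate_progeny_arrays(
        n_families=40, n_juveniles=12, selfing_rate=0.3, n_candidates=5, seed=77
    )
    truth = truth.set_index("juvenile_id")
    n_assigned = n_correct = n_false_self = 0
    for mother_id, cand_ids in cand_map.items():
        mother = table.get(mother_id)
        juvs = [
            i
            for i in table.individuals
            if i.mother_id == mother_id and i.generation == Generation.F2
        ]
        cands = [table.get(c) for c in cand_ids]
        assignments, _ = assign_family(mother, juvs, cands, table.active_loci)
        for a in assignments:
            t = truth.loc[a.juvenile_id]
            if a.status is AssignmentStatus.selfed:
                n_assigned += 1
                n_correct += bool(t.selfed)
                n_false_self += not t.selfed
            elif a.status is AssignmentStatus.outcrossed:
                n_assigned += 1
                n_correct += a.assigned_father_id == t.sire_id
    assert n_assigned > 400
    assert n_correct / n_assigned >= 0.99
    assert n_false_self / n_assigned <= 0.01
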