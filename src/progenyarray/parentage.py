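"""Exclusion-based paternity assignment for progeny arrays.

The core inference of the package.  Each genotyped juvenile is compared
to its mother locus by locus under Mendelian inheritance; the allele the
mother cannot have contributed constrains the sire.  Every potential
mate of the mother is then scored as a candidate father by counting
loci at which the candidate carries no allele the sire could have
contributed ("mismatches").  Self-fertilization is handled as one more
sire hypothesis — the mother as her own mate — so a single ranking over
all hypotheses yields the verdict: selfed, outcrossed to a named
father, ambiguous (tied hypotheses), or unassigned (no candidate within
the mismatch tolerance).

Locus vocabulary, relative to the mother:

* *outcross-consistent* locus — the juvenile carries exactly one allele
  absent from the mother; that allele must be paternal, so the paternal
  allele set is that singleton.
* *maternal-mismatch* locus — the juvenile shares no allele with the
  mother (genotyping error or a null allele).  A small number of such
  loci is tolerated; for father hypotheses either juvenile allele could
  be paternal there, while the selfing hypothesis necessarily
  mismatches.
* otherwise the locus is uninformative about the sire beyond the
  juvenile's own alleles (either could be paternal).

Juveniles enter the analysis only if they pass three inclusion
criteria: (i) at least six loci called in both juvenile and mother,
(ii) at most two maternal-mismatch loci, and (iii) at most one
maternal-mismatch locus when exactly six loci are shared.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .genotype_io import MultilocusGenotype

#: Default tolerance for father-offspring allelic mismatches, matching
#: the largest mismatch count ever accepted in validated assignments.
DEFAULT_MAX_MISMATCH = 2

#: Frequency floor for alleles unseen in the reference sample, keeping
#: Mendelian likelihoods proper on real data.
FREQ_FLOOR = 1e-3


class ParentageError(ValueError):
    """Inconsistent input to parentage inference."""


class AssignmentStatus(str, enum.Enum):
    excluded = "excluded"        # failed the inclusion criteria
    selfed = "selfed"            # the mother is the unique best sire hypothesis
    outcrossed = "outcrossed"    # a unique candidate father is the best hypothesis
    ambiguous = "ambiguous"      # tied best hypotheses, no tie-break possible
    unassigned = "unassigned"    # no hypothesis within the mismatch tolerance


@dataclass
class MaternalComparison:
    """Per-juvenile Mendelian comparison to the mother.

    ``paternal_allele_sets`` maps each shared locus to the set of
    alleles the sire could have contributed there (a singleton at
    outcross-consistent loci, the juvenile's alleles elsewhere).
    """

    juvenile_id: str
    mother_id: str
    n_shared_loci: int
    maternal_mismatch_loci: frozenset[str]
    outcross_consistent_loci: frozenset[str]
    paternal_allele_sets: dict[str, frozenset[int]]
    juvenile_calls: dict[str, tuple[int, int]] = field(default_factory=dict)
    mother_calls: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class SireMatch:
    """Mismatch score of one sire hypothesis for one juvenile.

    The hypothesis is selfing when ``candidate_id`` equals the mother's
    id.  ``n_comparable_loci`` counts loci called in juvenile, mother
    and candidate; ``usable`` is False when that count is zero.
    """

    candidate_id: str
    n_comparable_loci: int
    mismatch_count: int
    perfect: bool
    usable: bool = True


@dataclass
class PaternityAssignment:
    """The verdict for one juvenile."""

    juvenile_id: str
    mother_id: str
    status: AssignmentStatus
    assigned_father_id: Optional[str] = None
    best_mismatches: Optional[int] = None
    all_matches: list[SireMatch] = field(default_factory=list)
    prob_selfed: Optional[float] = None
    exclusion_reason: Optional[str] = None
    n_shared_loci: Optional[int] = None
    n_outcross_consistent_loci: Optional[int] = None


@dataclass
class AssignmentConfig:
    """Tunable knobs of the assignment rule.

    ``max_mismatch`` — most father-offspring mismatching loci tolerated
    for an eligible hypothesis.  ``tie_break`` — ``"likelihood"`` breaks
    ties among equal-mismatch hypotheses by Mendelian transmission
    likelihood when ``allele_freqs`` is given; ``"none"`` reports ties
    as ambiguous.  Ties are never broken by chance.
    """

    max_mismatch: int = DEFAULT_MAX_MISMATCH
    tie_break: str = "likelihood"
    allele_freqs: Optional[Mapping[str, Mapping[int, float]]] = None
    freq_floor: float = FREQ_FLOOR

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ParentageError("max_mismatch must be >= 0")
        if self.tie_break not in ("likelihood", "none"):
            raise ParentageError(f"unknown tie_break {self.tie_break!r}")


def compare_to_mother(
    juvenile: MultilocusGenotype,
    mother: MultilocusGenotype,
    active_loci: Iterable[str],
) -> MaternalComparison:
    """Classify every locus called in both juvenile and mother.

    Excluded loci must already be absent from *active_loci*.  Loci
    missing in either individual contribute nothing.
    """
    if juvenile.mother_id is not None and juvenile.mother_id != mother.individual_id:
        raise ParentageError(
            f"juvenile {juvenile.individual_id!r} claims mother "
            f"{juvenile.mother_id!r}, not {mother.individual_id!r}"
        )
    mismatch: set[str] = set()
    outcross: set[str] = set()
    paternal: dict[str, frozenset[int]] = {}
    juv_calls: dict[str, tuple[int, int]] = {}
    mom_calls: dict[str, tuple[int, int]] = {}
    n_shared = 0
    for locus in active_loci:
        j = juvenile.call(locus)
        m = mother.call(locus)
        if j is None or m is None:
            continue
        n_shared += 1
        juv_calls[locus] = j
        mom_calls[locus] = m
        j_set, m_set = set(j), set(m)
        non_maternal = j_set - m_set
        if not (j_set & m_set):
            # no juvenile allele occurs in the mother: genotyping error
            # or null allele; either juvenile allele could be paternal
            mismatch.add(locus)
            paternal[locus] = frozenset(j_set)
        elif non_maternal:
            # exactly one non-maternal allele: it must be paternal
            outcross.add(locus)
            paternal[locus] = frozenset(non_maternal)
        else:
            # both juvenile alleles occur in the mother: sire allele ambiguous
            paternal[locus] = frozenset(j_set)
    return MaternalComparison(
        juvenile_id=juvenile.individual_id,
        mother_id=mother.individual_id,
        n_shared_loci=n_shared,
        maternal_mismatch_loci=frozenset(mismatch),
        outcross_consistent_loci=frozenset(outcross),
        paternal_allele_sets=paternal,
        juvenile_calls=juv_calls,
        mother_calls=mom_calls,
    )


def passes_inclusion(cmp: MaternalComparison) -> tuple[bool, Optional[str]]:
    """Apply the three inclusion criteria; returns (ok, failure reason)."""
    n_mm = len(cmp.maternal_mismatch_loci)
    if cmp.n_shared_loci < 6:
        return False, "criterion-i: fewer than six loci called in both juvenile and mother"
    if n_mm > 2:
        return False, "criterion-ii: maternal allele lacking at more than two loci"
    if cmp.n_shared_loci == 6 and n_mm > 1:
        return False, (
            "criterion-iii: exactly six shared loci but maternal allele "
            "lacking at more than one"
        )
    return True, None


def score_candidate(
    cmp: MaternalComparison, candidate: MultilocusGenotype
) -> SireMatch:
    """Count loci at which *candidate* cannot have sired the juvenile.

    A locus is comparable when called in juvenile, mother and candidate;
    it mismatches when the candidate carries no allele of the locus's
    paternal allele set.  The mother herself is a legal candidate (the
    selfing hypothesis): at outcross-consistent and maternal-mismatch
    loci she lacks the required allele by construction, so those loci
    count against selfing without any special-casing.
    """
    n_comparable = 0
    mismatches = 0
    for locus, pat_set in cmp.paternal_allele_sets.items():
        call = candidate.call(locus)
        if call is None:
            continue
        n_comparable += 1
        if not (set(call) & pat_set):
            mismatches += 1
    return SireMatch(
        candidate_id=candidate.individual_id,
        n_comparable_loci=n_comparable,
        mismatch_count=mismatches,
        perfect=(n_comparable > 0 and mismatches == 0),
        usable=n_comparable > 0,
    )


def _mendel_locus_likelihood(
    juvenile: tuple[int, int],
    mother: tuple[int, int],
    sire: Optional[tuple[int, int]],
    freqs: Optional[Mapping[int, float]],
    floor: float,
) -> float:
    """P(juvenile pair | mother x sire) under Mendelian segregation.

    With ``sire=None`` the paternal allele is drawn from *freqs* (a
    random sire from the reference allele pool); alleles absent from
    *freqs* get the floor frequency.
    """
    x, y = juvenile
    prob = 0.0
    for ma in mother:
        # mother transmits ma with probability 1/2; the sire must then
        # supply the complementary juvenile allele
        if ma == x:
            needed = y
        elif ma == y:
            needed = x
        else:
            continue
        if sire is not None:
            p_pat = sum(0.5 for pa in sire if pa == needed)
        else:
            p_pat = (freqs or {}).get(needed, floor)
        prob += 0.5 * p_pat
    return prob


def _hypothesis_likelihood(
    cmp: MaternalComparison,
    candidate: Optional[MultilocusGenotype],
    config: AssignmentConfig,
) -> float:
    """Product Mendelian likelihood of one sire hypothesis (log-safe).

    Loci where the hypothesis has zero transmission probability (the
    mismatch loci already counted) contribute the frequency floor so
    that equal-mismatch hypotheses remain comparable.
    """
    log_l = 0.0
    for locus, juv in cmp.juvenile_calls.items():
        mom = cmp.mother_calls[locus]
        sire_call = candidate.call(locus) if candidate is not None else None
        if candidate is not None and sire_call is None:
            continue  # not comparable for this candidate
        freqs = (config.allele_freqs or {}).get(locus) if config.allele_freqs else None
        p = _mendel_locus_likelihood(juv, mom, sire_call, freqs, config.freq_floor)
        log_l += math.log(max(p, config.freq_floor * 0.25))
    return log_l


def assign_paternity(
    cmp: MaternalComparison,
    candidates: Sequence[MultilocusGenotype],
    config: Optional[AssignmentConfig] = None,
) -> PaternityAssignment:
    """Rank all sire hypotheses for one juvenile and return the verdict.

    *candidates* must contain the mother's own genotype (the selfing
    hypothesis) alongside every potential mate — all of them, whether or
    not copulations were observed.  Hypotheses with a mismatch count at
    most ``config.max_mismatch`` are eligible; a unique minimal-mismatch
    eligible hypothesis wins.  Ties are broken by Mendelian likelihood
    when configured and allele frequencies are available, and otherwise
    reported as ambiguous.
    """
    if config is None:
        config = AssignmentConfig()
    if not candidates:
        raise ParentageError("empty candidate list")
    base = PaternityAssignment(
        juvenile_id=cmp.juvenile_id,
        mother_id=cmp.mother_id,
        status=AssignmentStatus.excluded,
        n_shared_loci=cmp.n_shared_loci,
        n_outcross_consistent_loci=len(cmp.outcross_consistent_loci),
    )
    ok, reason = passes_inclusion(cmp)
    if not ok:
        base.exclusion_reason = reason
        return base

    matches = [score_candidate(cmp, cand) for cand in candidates]
    base.all_matches = matches
    eligible = [
        (m, cand)
        for m, cand in zip(matches, candidates)
        if m.usable and m.mismatch_count <= config.max_mismatch
    ]
    if not eligible:
        base.status = AssignmentStatus.unassigned
        usable = [m.mismatch_count for m in matches if m.usable]
        base.best_mismatches = min(usable) if usable else None
        return base

    best = min(m.mismatch_count for m, _ in eligible)
    winners = [(m, cand) for m, cand in eligible if m.mismatch_count == best]
    base.best_mismatches = best

    if len(winners) > 1 and config.tie_break == "likelihood" and config.allele_freqs:
        scored = [
            (_hypothesis_likelihood(cmp, cand, config), m, cand)
            for m, cand in winners
        ]
        scored.sort(key=lambda t: t[0], reverse=True)
        top = scored[0][0]
        tied = [t for t in scored if math.isclose(t[0], top, rel_tol=1e-9, abs_tol=1e-12)]
        if len(tied) == 1:
            winners = [(scored[0][1], scored[0][2])]

    if len(winners) > 1:
        base.status = AssignmentStatus.ambiguous
        return base

    match, cand = winners[0]
    if cand.individual_id == cmp.mother_id:
        base.status = AssignmentStatus.selfed
    else:
        base.status = AssignmentStatus.outcrossed
        base.assigned_father_id = cand.individual_id
    return base


def selfing_probability(
    cmp: MaternalComparison,
    candidates: Sequence[MultilocusGenotype] = (),
    allele_freqs: Optional[Mapping[str, Mapping[int, float]]] = None,
    prior_self: float = 0.5,
    include_random_sire: bool = True,
    freq_floor: float = FREQ_FLOOR,
) -> float:
    """Posterior probability that the juvenile is selfed.

    The selfing hypothesis (prior ``prior_self``) is weighed against the
    outcross hypotheses — the named candidates (mother excluded) plus,
    optionally, a random sire drawn from ``allele_freqs`` — which share
    the complementary prior equally.  Per-locus likelihoods are exact
    Mendelian transmission probabilities; a juvenile carrying a
    non-maternal allele anywhere has selfing likelihood 0.  Raises when
    every hypothesis has zero likelihood (genotype inconsistency).
    """
    if not 0.0 <= prior_self <= 1.0:
        raise ParentageError("prior_self must be in [0, 1]")
    out_cands = [c for c in candidates if c.individual_id != cmp.mother_id]
    n_out = len(out_cands) + (1 if include_random_sire else 0)
    if n_out == 0:
        raise ParentageError("no outcross hypothesis: supply candidates or allele_freqs")

    def product_likelihood(sire: Optional[MultilocusGenotype], selfing: bool) -> float:
        like = 1.0
        for locus, juv in cmp.juvenile_calls.items():
            mom = cmp.mother_calls[locus]
            freqs = (allele_freqs or {}).get(locus)
            if selfing:
                p = _mendel_locus_likelihood(juv, mom, mom, None, freq_floor)
            elif sire is not None:
                call = sire.call(locus)
                if call is None:
                    p = _mendel_locus_likelihood(juv, mom, None, freqs, freq_floor)
                else:
                    p = _mendel_locus_likelihood(juv, mom, call, None, freq_floor)
            else:
                p = _mendel_locus_likelihood(juv, mom, None, freqs, freq_floor)
            like *= p
            if like == 0.0:
                return 0.0
        return like

    l_self = product_likelihood(None, selfing=True)
    weight_out = (1.0 - prior_self) / n_out
    total_out = sum(weight_out * product_likelihood(c, False) for c in out_cands)
    if include_random_sire:
        total_out += weight_out * product_likelihood(None, False)
    numerator = prior_self * l_self
    denom = numerator + total_out
    if denom == 0.0:
        raise ParentageError(
            f"juvenile {cmp.juvenile_id!r}: all sire hypotheses have zero "
            "likelihood (genotype inconsistency)"
        )
    return numerator / denom


@dataclass
class FamilySummary:
    """Bookkeeping for one progeny array; counts always add up:
    n_genotyped = n_excluded + n_unassigned + n_ambiguous + n_assigned."""

    mother_id: str
    n_genotyped: int
    n_excluded: int
    n_unassigned: int
    n_ambiguous: int
    n_assigned: int
    n_selfed: int
    n_outcrossed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def assign_family(
    mother: MultilocusGenotype,
    juveniles: Sequence[MultilocusGenotype],
    candidates: Sequence[MultilocusGenotype],
    active_loci: Iterable[str],
    config: Optional[AssignmentConfig] = None,
    compute_prob_selfed: bool = False,
) -> tuple[list[PaternityAssignment], FamilySummary]:
    """Assign paternity for every juvenile of one mother.

    The mother is added to the candidate list automatically if absent.
    Deterministic given inputs and configuration.
    """
    if config is None:
        config = AssignmentConfig()
    active = list(active_loci)
    cand_list = list(candidates)
    if all(c.individual_id != mother.individual_id for c in cand_list):
        cand_list = [mother] + cand_list
    assignments = []
    for juv in juveniles:
        cmp = compare_to_mother(juv, mother, active)
        assignment = assign_paternity(cmp, cand_list, config)
        if compute_prob_selfed and assignment.status in (
            AssignmentStatus.selfed,
            AssignmentStatus.outcrossed,
            AssignmentStatus.ambiguous,
        ):
            try:
                assignment.prob_selfed = selfing_probability(
                    cmp,
                    cand_list,
                    allele_freqs=config.allele_freqs,
                    include_random_sire=config.allele_freqs is not None,
                )
            except ParentageError:
                assignment.prob_selfed = None
        assignments.append(assignment)
    counts = {status: 0 for status in AssignmentStatus}
    for a in assignments:
        counts[a.status] += 1
    summary = FamilySummary(
        mother_id=mother.individual_id,
        n_genotyped=len(assignments),
        n_excluded=counts[AssignmentStatus.excluded],
        n_unassigned=counts[AssignmentStatus.unassigned],
        n_ambiguous=counts[AssignmentStatus.ambiguous],
        n_assigned=counts[AssignmentStatus.selfed] + counts[AssignmentStatus.outcrossed],
        n_selfed=counts[AssignmentStatus.selfed],
        n_outcrossed=counts[AssignmentStatus.outcrossed],
    )
    return assignments, summary
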