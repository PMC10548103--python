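"""Selfing-rate estimation, propensity classification and treatment tables.

A family's selfing rate s is the fraction of its assigned offspring
whose sire is the mother herself.  Conventional mating-system bands are
s <= 0.2 (primary outcrossing), 0.2 < s < 0.8 (mixed mating) and
s >= 0.8 (primary selfing); both boundaries are inclusive towards the
outer bands.

An individual's *propensity* for selfing is classified from two
observations: whether it selfed successfully while isolated (developed
embryos before mates were available are necessarily selfed) and its
post-isolation selfing rate once mates were available:

* outcrosser        — never selfed, in isolation or after
* plastic switcher  — selfed in isolation, outcrossed fully thereafter
* plastic mixer     — selfed in isolation, kept a low rate (s <= t_low)
* selfer            — high selfing rate (s >= t_high) throughout

Two extra categories close the logic: ``intermediate_unclassified``
(t_low < s < t_high, a pattern the four-way scheme cannot place) and
``latent_anomaly`` (selfing post-isolation without any selfing in
isolation).  Both are flagged, never silently merged.

For individuals whose offspring were not genotyped, an *apparent*
propensity is read off the timing of reproduction and the occurrence of
female copulations alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .genotype_io import ExperimentRecord, Treatment
from .parentage import AssignmentStatus, PaternityAssignment
from .popstats import ContingencyTable, proportion_ci


class MatingSystemError(ValueError):
    """Inconsistent input to mating-system summarisation."""


class MatingSystemClass(str, enum.Enum):
    primary_outcrossing = "primary_outcrossing"
    mixed_mating = "mixed_mating"
    primary_selfing = "primary_selfing"


class Propensity(str, enum.Enum):
    outcrosser = "outcrosser"
    plastic_switcher = "plastic_switcher"
    plastic_mixer = "plastic_mixer"
    selfer = "selfer"
    intermediate_unclassified = "intermediate_unclassified"
    latent_anomaly = "latent_anomaly"


class ApparentPropensity(str, enum.Enum):
    apparent_outcrosser = "apparent_outcrosser"
    apparent_plastic = "apparent_plastic"
    apparent_selfer = "apparent_selfer"
    female_infertile = "female_infertile"


#: The four primary propensity classes, in the column order used for
#: the 4 x 2 treatment table (high to low selfing propensity).
PRIMARY_PROPENSITY_ORDER = [
    Propensity.selfer,
    Propensity.plastic_mixer,
    Propensity.plastic_switcher,
    Propensity.outcrosser,
]

#: Column order of the 3 x 2 apparent-propensity treatment table.
APPARENT_PROPENSITY_ORDER = [
    ApparentPropensity.apparent_selfer,
    ApparentPropensity.apparent_plastic,
    ApparentPropensity.apparent_outcrosser,
]

#: Fixed row order of all treatment tables.
TREATMENT_ORDER = [Treatment.once_paired, Treatment.repeatedly_paired]


@dataclass(frozen=True)
class MatingSystemThresholds:
    """Band edges for the selfing rate; defaults are the conventional
    20% / 80% cut-offs, both inclusive towards the outer bands."""

    t_low: float = 0.2
    t_high: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.t_low < self.t_high < 1.0):
            raise MatingSystemError("need 0 < t_low < t_high < 1")


@dataclass
class FamilySelfingEstimate:
    """Per progeny-array selfing summary.

    ``s`` is None (undefined, never imputed 0) when no offspring could
    be assigned.  ``n_sires`` counts distinct genetic sires, the mother
    included once if any offspring is selfed; a family with >= 2 sires
    shows multiple paternity (a selfed-plus-outcrossed array counts).
    """

    mother_id: str
    n_assigned: int
    n_selfed: int
    s: Optional[float]
    ci95: Optional[tuple[float, float]]
    n_sires: int
    n_ambiguous: int = 0
    n_unassigned: int = 0
    n_excluded: int = 0

    @property
    def n_outcrossed(self) -> int:
        return self.n_assigned - self.n_selfed

    @property
    def multiple_paternity(self) -> bool:
        return self.n_sires >= 2


def count_sires(assignments: Sequence[PaternityAssignment]) -> tuple[int, bool]:
    """Distinct genetic sires among assigned offspring.

    Fathers are counted by id; the mother counts as one sire when any
    offspring is selfed.  Multiple paternity means >= 2 sires.
    """
    fathers = {
        a.assigned_father_id
        for a in assignments
        if a.status is AssignmentStatus.outcrossed
    }
    any_selfed = any(a.status is AssignmentStatus.selfed for a in assignments)
    n = len(fathers) + (1 if any_selfed else 0)
    if n == 0:
        raise MatingSystemError("no assigned offspring; sire count undefined")
    return n, n >= 2


def estimate_selfing_rate(
    assignments: Sequence[PaternityAssignment],
    ci_method: str = "wilson",
    ci_level: float = 0.95,
) -> FamilySelfingEstimate:
    """Selfing rate of one progeny array.

    Only selfed/outcrossed verdicts enter the denominator; ambiguous,
    unassigned and excluded juveniles are reported but not counted.
    """
    if not assignments:
        raise MatingSystemError("no assignments supplied")
    mothers = {a.mother_id for a in assignments}
    if len(mothers) != 1:
        raise MatingSystemError(f"assignments span several mothers: {sorted(mothers)}")
    n_selfed = sum(a.status is AssignmentStatus.selfed for a in assignments)
    n_out = sum(a.status is AssignmentStatus.outcrossed for a in assignments)
    n_assigned = n_selfed + n_out
    if n_assigned == 0:
        s = ci = None
        n_sires = 0
    else:
        s = n_selfed / n_assigned
        ci = proportion_ci(n_selfed, n_assigned, level=ci_level, method=ci_method)
        n_sires, _ = count_sires(assignments)
    return FamilySelfingEstimate(
        mother_id=mothers.pop(),
        n_assigned=n_assigned,
        n_selfed=n_selfed,
        s=s,
        ci95=ci,
        n_sires=n_sires,
        n_ambiguous=sum(a.status is AssignmentStatus.ambiguous for a in assignments),
        n_unassigned=sum(a.status is AssignmentStatus.unassigned for a in assignments),
        n_excluded=sum(a.status is AssignmentStatus.excluded for a in assignments),
    )


def classify_mating_system(
    s: float, th: MatingSystemThresholds = MatingSystemThresholds()
) -> MatingSystemClass:
    """Band a selfing rate: s <= t_low outcrossing, s >= t_high selfing,
    mixed mating in between (boundaries inclusive outward)."""
    if not 0.0 <= s <= 1.0:
        raise MatingSystemError(f"selfing rate {s} outside [0, 1]")
    if s <= th.t_low:
        return MatingSystemClass.primary_outcrossing
    if s >= th.t_high:
        return MatingSystemClass.primary_selfing
    return MatingSystemClass.mixed_mating


def classify_propensity(
    selfed_in_isolation: bool,
    s_post: Optional[float],
    th: MatingSystemThresholds = MatingSystemThresholds(),
) -> Propensity:
    """Genotype-based propensity class from isolation success and the
    post-isolation selfing rate.

    Raises when ``s_post`` is undefined — such individuals can only be
    classified apparently (see :func:`classify_apparent_propensity`).
    """
    if s_post is None:
        raise MatingSystemError(
            "post-isolation selfing rate undefined; use the apparent classification"
        )
    if not 0.0 <= s_post <= 1.0:
        raise MatingSystemError(f"selfing rate {s_post} outside [0, 1]")
    if not selfed_in_isolation:
        return Propensity.outcrosser if s_post == 0.0 else Propensity.latent_anomaly
    if s_post == 0.0:
        return Propensity.plastic_switcher
    if s_post <= th.t_low:
        return Propensity.plastic_mixer
    if s_post >= th.t_high:
        return Propensity.selfer
    return Propensity.intermediate_unclassified


def classify_apparent_propensity(rec: ExperimentRecord) -> ApparentPropensity:
    """Apparent propensity from reproduction timing and female matings.

    "Reproduced" in a phase means > 0 developed embryos in that phase.
    Individuals that never produced a developed embryo are female
    infertile: their propensity is unknown.
    """
    repro_iso = rec.developed_embryos_isolation > 0
    repro_post = rec.developed_embryos_post > 0
    mated_female = rec.n_female_copulation_partners > 0
    if not repro_iso and not repro_post:
        return ApparentPropensity.female_infertile
    if not mated_female:
        return ApparentPropensity.apparent_selfer
    if repro_iso and repro_post:
        return ApparentPropensity.apparent_plastic
    if repro_post:
        return ApparentPropensity.apparent_outcrosser
    # reproduced only in isolation despite mating as a female: nothing
    # post-isolation can witness outcrossing, so the apparent class is selfer
    return ApparentPropensity.apparent_selfer


@dataclass
class PropensityCall:
    """Propensity verdicts for one individual (either kind may be absent)."""

    individual_id: str
    genotype_based: Optional[Propensity] = None
    apparent: Optional[ApparentPropensity] = None


def _treatment_of(
    individual_id: str, records: Mapping[str, ExperimentRecord]
) -> Treatment:
    try:
        return records[individual_id].treatment
    except KeyError:
        raise MatingSystemError(
            f"individual {individual_id!r} has no treatment metadata"
        ) from None


def build_treatment_tables(
    calls: Sequence[PropensityCall],
    estimates: Sequence[FamilySelfingEstimate],
    records: Mapping[str, ExperimentRecord] | Sequence[ExperimentRecord],
) -> dict[str, ContingencyTable]:
    """The five labelled treatment contingency tables.

    Rows are always (once_paired, repeatedly_paired).  Emitted tables:

    * ``multiple_paternity`` (2x2) — families with >= 2 sires vs one.
    * ``families_with_selfing`` (2x2) — families with any selfed
      offspring vs none.
    * ``selfed_offspring`` (2x2) — assigned offspring, selfed vs
      outcrossed, pooled within treatment.
    * ``apparent_propensity`` (2x3) — female-fertile individuals by
      apparent class (selfer / plastic / outcrosser).
    * ``genotype_propensity`` (2x4) — individuals with genotype-based
      class (selfer / mixer / switcher / outcrosser).
    """
    if not isinstance(records, Mapping):
        records = {r.individual_id: r for r in records}
    defined = [e for e in estimates if e.n_assigned > 0]
    if not defined and not calls:
        raise MatingSystemError("empty input: no estimates and no propensity calls")

    def row_index(ind_id: str) -> int:
        return TREATMENT_ORDER.index(_treatment_of(ind_id, records))

    tables: dict[str, ContingencyTable] = {}
    if defined:
        mp = np.zeros((2, 2), dtype=int)
        fs = np.zeros((2, 2), dtype=int)
        so = np.zeros((2, 2), dtype=int)
        for est in defined:
            r = row_index(est.mother_id)
            mp[r, 0 if est.multiple_paternity else 1] += 1
            fs[r, 0 if est.n_selfed > 0 else 1] += 1
            so[r, 0] += est.n_selfed
            so[r, 1] += est.n_outcrossed
        row_labels = [t.value for t in TREATMENT_ORDER]
        tables["multiple_paternity"] = ContingencyTable(
            mp, row_labels, ["multiple", "single"]
        )
        tables["families_with_selfing"] = ContingencyTable(
            fs, row_labels, ["selfed_offspring_present", "no_selfed_offspring"]
        )
        tables["selfed_offspring"] = ContingencyTable(
            so, row_labels, ["selfed", "outcrossed"]
        )

    apparent_calls = [
        c
        for c in calls
        if c.apparent is not None and c.apparent is not ApparentPropensity.female_infertile
    ]
    if apparent_calls:
        ap = np.zeros((2, 3), dtype=int)
        for call in apparent_calls:
            ap[row_index(call.individual_id), APPARENT_PROPENSITY_ORDER.index(call.apparent)] += 1
        tables["apparent_propensity"] = ContingencyTable(
            ap,
            [t.value for t in TREATMENT_ORDER],
            [p.value for p in APPARENT_PROPENSITY_ORDER],
        )

    genotype_calls = [
        c for c in calls if c.genotype_based in PRIMARY_PROPENSITY_ORDER
    ]
    if genotype_calls:
        gp = np.zeros((2, 4), dtype=int)
        for call in genotype_calls:
            gp[row_index(call.individual_id), PRIMARY_PROPENSITY_ORDER.index(call.genotype_based)] += 1
        tables["genotype_propensity"] = ContingencyTable(
            gp,
            [t.value for t in TREATMENT_ORDER],
            [p.value for p in PRIMARY_PROPENSITY_ORDER],
        )

    if not tables:
        raise MatingSystemError("inputs yielded no tables")
    return tables


def cohort_summary(
    estimates: Sequence[FamilySelfingEstimate],
    calls: Sequence[PropensityCall],
    records: Mapping[str, ExperimentRecord] | Sequence[ExperimentRecord],
) -> dict[str, float]:
    """Headline cohort proportions (fractions in [0, 1]).

    Includes the pooled offspring selfing rate (overall and once-paired),
    the share of families containing selfed offspring (overall and
    once-paired), and the composition of the apparent and genotype-based
    propensity classes.
    """
    if not isinstance(records, Mapping):
        records = {r.individual_id: r for r in records}
    defined = [e for e in estimates if e.n_assigned > 0]
    out: dict[str, float] = {}
    if defined:
        n_assigned = sum(e.n_assigned for e in defined)
        n_selfed = sum(e.n_selfed for e in defined)
        out["pooled_offspring_selfing"] = n_selfed / n_assigned
        once = [
            e for e in defined
            if _treatment_of(e.mother_id, records) is Treatment.once_paired
        ]
        if once:
            out["once_paired_offspring_selfing"] = sum(e.n_selfed for e in once) / sum(
                e.n_assigned for e in once
            )
            out["once_paired_families_with_selfing"] = sum(
                e.n_selfed > 0 for e in once
            ) / len(once)
        out["families_with_selfing"] = sum(e.n_selfed > 0 for e in defined) / len(defined)
    apparent = [
        c.apparent
        for c in calls
        if c.apparent is not None and c.apparent is not ApparentPropensity.female_infertile
    ]
    for cls in APPARENT_PROPENSITY_ORDER:
        if apparent:
            out[f"frac_{cls.value}"] = apparent.count(cls) / len(apparent)
    genotype = [c.genotype_based for c in calls if c.genotype_based in PRIMARY_PROPENSITY_ORDER]
    for cls in PRIMARY_PROPENSITY_ORDER:
        if genotype:
            out[f"frac_{cls.value}"] = genotype.count(cls) / len(genotype)
    return out
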