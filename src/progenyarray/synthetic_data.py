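"""Forward simulator of the hermaphrodite mating-trial experiment.

Generates every input the analysis pipeline consumes — founder
genotypes, outcrossed F1 broods sired from stored allosperm, a
two-treatment mating-trial design (one partner versus six sequential
partners), per-individual selfing propensities, fecundity with
inbreeding depression at two stages (embryo development and juvenile
survival), progeny-array genotypes, and genotyping noise (allelic
dropout plus a null-allele locus) — together with complete truth labels
for parameter-recovery testing.

The generative model, per focal F1 individual:

1. A latent propensity class (outcrosser / plastic switcher / plastic
   mixer / selfer) is drawn once and fixes the true selfing rate in
   each phase: all classes except outcrossers self while isolated;
   post-isolation the class-specific rate applies (0 for outcrossers
   and switchers, a low rate for mixers, a high rate for selfers).
2. Post-isolation eggs are sired by self with that rate, otherwise by a
   partner drawn from the mating-opportunity window open before the
   brood's eggs were laid (all partners for once-paired snails, the
   first 3-5 of six for repeatedly paired ones).
3. Each egg develops into an embryo and each embryo survives to
   genotyping age with selfed-versus-outcrossed probabilities, so
   realized ("secondary") selfing rates among survivors are depressed
   relative to the rates at fertilization — exactly the bias a
   progeny-array study inherits.
4. Progeny arrays of the most productive families are "genotyped";
   dropout and the null-allele locus are then applied.

One global seed expands into named substreams (frequencies, pedigree,
thinning, noise), so identical configurations reproduce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    ExperimentRecord,
    Generation,
    GenotypeTable,
    LocusDef,
    MultilocusGenotype,
    Treatment,
)
from .mating_system import (
    ApparentPropensity,
    FamilySelfingEstimate,
    Propensity,
    PropensityCall,
    classify_apparent_propensity,
    classify_propensity,
)


class SimulationError(ValueError):
    """Inconsistent simulation configuration."""


#: Propensity classes in the order of ``class_probs``.
CLASS_ORDER = [
    Propensity.outcrosser,
    Propensity.plastic_switcher,
    Propensity.plastic_mixer,
    Propensity.selfer,
]


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    Defaults emulate the experiment the package models: ~10 highly
    polymorphic loci with one null-allele locus flagged excluded, 274
    focal F1 snails from 38 field-caught P0 mothers, a 50/50 split
    between once-paired and repeatedly paired (six partners) treatments,
    progeny arrays capped at 22 genotyped juveniles, a bimodal
    distribution of true selfing rates induced by the class mixture
    (roughly 31% outcrossers, 37% mixed maters, 32% selfers), and
    inbreeding depression in embryo development (0.72 vs 0.79) and
    juvenile survival (death 0.695 vs 0.534) for selfed vs outcrossed
    offspring.
    """

    n_loci: int = 9                      # active loci
    n_excluded_loci: int = 1             # null-allele loci, flagged excluded
    alleles_per_locus: int = 10
    freq_concentration: float = 1.0      # Dirichlet concentration per locus
    n_mothers: int = 38
    n_f1: int = 274
    treatment_split: float = 0.5         # fraction once-paired
    n_partners_repeated: int = 6
    genotyped_partner_window: tuple[int, int] = (3, 5)
    # (outcrosser, plastic_switcher, plastic_mixer, selfer)
    class_probs: tuple[float, float, float, float] = (0.31, 0.27, 0.10, 0.32)
    s_mixer: float = 0.1
    s_selfer: float = 0.95
    juveniles_per_family_mean: float = 16.0
    juveniles_per_family_sd: float = 2.0
    juveniles_per_family_floor: int = 3
    juveniles_per_family_cap: int = 22
    n_genotyped_families: int = 56
    p_develop_outcrossed: float = 0.79
    p_develop_selfed: float = 0.72
    p_juv_die_outcrossed: float = 0.534
    p_juv_die_selfed: float = 0.695
    mean_eggs_isolation: float = 130.0
    p_female_mating: float = 0.9         # per-partner female-role copulation
    p_female_mating_selfer: float = 0.5
    dropout_rate: float = 0.05
    null_allele_freq: float = 0.15       # at the excluded locus
    allow_sibling_pairing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or not math.isclose(
            probs.sum(), 1.0, abs_tol=1e-9
        ):
            raise SimulationError("class_probs must be 4 non-negative values summing to 1")
        for name in (
            "treatment_split",
            "s_mixer",
            "s_selfer",
            "p_develop_outcrossed",
            "p_develop_selfed",
            "p_juv_die_outcrossed",
            "p_juv_die_selfed",
            "p_female_mating",
            "p_female_mating_selfer",
            "dropout_rate",
            "null_allele_freq",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.s_mixer > 0.2:
            raise SimulationError("s_mixer must be <= 0.2 (plastic mixers self at a low rate)")
        if self.s_selfer < 0.8:
            raise SimulationError("s_selfer must be >= 0.8 (selfers self at a high rate)")
        if self.alleles_per_locus < 2:
            raise SimulationError("need at least 2 alleles per locus")
        if self.n_loci < 1:
            raise SimulationError("need at least 1 active locus")
        if self.n_mothers < 1 or self.n_f1 < 2:
            raise SimulationError("need >= 1 mother and >= 2 focal individuals")
        lo, hi = self.genotyped_partner_window
        if not 1 <= lo <= hi <= self.n_partners_repeated:
            raise SimulationError("bad genotyped_partner_window")

    def panel(self) -> list[LocusDef]:
        active = [LocusDef(f"L{i + 1:02d}") for i in range(self.n_loci)]
        excluded = [
            LocusDef(
                f"L{self.n_loci + i + 1:02d}",
                excluded=True,
                note="non-negligible null-allele frequency",
            )
            for i in range(self.n_excluded_loci)
        ]
        return active + excluded


@dataclass
class SimulationTruth:
    """Complete generative labels.

    ``individuals`` has one row per focal F1 snail (propensity class,
    true per-phase selfing rates, treatment, partner ids, candidate
    window); ``juveniles`` one row per F2 egg (true sire, selfed flag,
    development/survival outcome, genotyped flag); ``allele_freqs`` the
    true per-locus frequency vectors.
    """

    individuals: pd.DataFrame
    juveniles: pd.DataFrame
    allele_freqs: dict[str, np.ndarray]


@dataclass
class SimulationResult:
    genotypes: GenotypeTable
    records: list[ExperimentRecord]
    truth: SimulationTruth
    config: SimulationConfig


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("freqs", "pedigree", "thinning", "noise")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def draw_allele_frequencies(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, np.ndarray]:
    """One Dirichlet frequency vector per panel locus (excluded ones too)."""
    if rng is None:
        rng = _rng_streams(cfg.seed)["freqs"]
    alpha = np.full(cfg.alleles_per_locus, cfg.freq_concentration)
    return {locus.name: rng.dirichlet(alpha) for locus in cfg.panel()}


def _draw_genotype(
    freqs: dict[str, np.ndarray], rng: np.random.Generator
) -> dict[str, tuple[int, int]]:
    calls = {}
    for locus, p in freqs.items():
        a, b = rng.choice(len(p), size=2, p=p) + 1  # allele codes are 1-based
        calls[locus] = (int(a), int(b))
    return calls


def simulate_founder_genotypes(
    freqs: dict[str, np.ndarray],
    n: int,
    rng: np.random.Generator,
    generation: Generation = Generation.P0,
    id_prefix: str = "P0",
) -> GenotypeTable:
    """Hardy-Weinberg draws: two independent alleles per locus, loci
    independent."""
    loci = list(freqs)
    inds = [
        MultilocusGenotype(f"{id_prefix}_{i + 1:03d}", generation, None, _draw_genotype(freqs, rng))
        for i in range(n)
    ]
    return GenotypeTable([LocusDef(l) for l in loci], inds)


def simulate_offspring_genotype(
    mother: MultilocusGenotype,
    sire: MultilocusGenotype,
    rng: np.random.Generator,
    individual_id: str,
    generation: Generation = Generation.F2,
) -> MultilocusGenotype:
    """Mendelian segregation: one allele uniformly from each parent per
    locus, independent across loci; a locus is called only when both
    parents carry a call.  Selfing is simply ``sire is mother``."""
    calls = {}
    for locus, m_call in mother.calls.items():
        s_call = sire.call(locus)
        if s_call is None:
            continue
        calls[locus] = (
            int(m_call[rng.integers(2)]),
            int(s_call[rng.integers(2)]),
        )
    return MultilocusGenotype(individual_id, generation, mother.individual_id, calls)


def apply_genotyping_noise(
    table: GenotypeTable,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeTable:
    """Allelic dropout plus null-allele masking.

    Every locus call is set missing with ``dropout_rate``.  At loci
    flagged excluded (the designated null-allele loci), each allele copy
    is independently a null with ``null_allele_freq``: a heterozygous
    null carrier appears homozygous for its visible allele (mimicking a
    maternal mismatch downstream), a double null is missing.
    """
    if rng is None:
        rng = _rng_streams(cfg.seed)["noise"]
    null_loci = {l.name for l in table.panel if l.excluded}
    new_inds = []
    for ind in table.individuals:
        calls = {}
        for locus, pair in ind.calls.items():
            a, b = pair
            if locus in null_loci and cfg.null_allele_freq > 0:
                a_null = rng.random() < cfg.null_allele_freq
                b_null = rng.random() < cfg.null_allele_freq
                if a_null and b_null:
                    continue
                if a_null:
                    a = b
                elif b_null:
                    b = a
            if cfg.dropout_rate > 0 and rng.random() < cfg.dropout_rate:
                continue
            calls[locus] = (a, b)
        new_inds.append(
            MultilocusGenotype(ind.individual_id, ind.generation, ind.mother_id, calls)
        )
    return GenotypeTable(list(table.panel), new_inds)


_CLASS_S = {
    Propensity.outcrosser: ("no_self", 0.0),
    Propensity.plastic_switcher: ("self", 0.0),
    Propensity.plastic_mixer: ("self", None),  # s_mixer
    Propensity.selfer: ("self", None),  # s_selfer
}


def expected_selfed_fraction(cfg: SimulationConfig) -> float:
    """Closed-form expectation of the pooled true selfed fraction among
    surviving (genotypable) post-isolation juveniles.

    Each egg is selfed with its class rate s_c and survives to
    genotyping with q_self = p_develop_selfed * (1 - p_juv_die_selfed)
    or the outcrossed analogue; families lay the same expected egg
    number regardless of class, so classes weight by their probability:

        E[selfed | survived] =
            sum_c P(c) s_c q_self / sum_c P(c) (s_c q_self + (1-s_c) q_out)
    """
    q_self = cfg.p_develop_selfed * (1.0 - cfg.p_juv_die_selfed)
    q_out = cfg.p_develop_outcrossed * (1.0 - cfg.p_juv_die_outcrossed)
    s_by_class = {
        Propensity.outcrosser: 0.0,
        Propensity.plastic_switcher: 0.0,
        Propensity.plastic_mixer: cfg.s_mixer,
        Propensity.selfer: cfg.s_selfer,
    }
    num = 0.0
    den = 0.0
    for cls, prob in zip(CLASS_ORDER, cfg.class_probs):
        s = s_by_class[cls]
        num += prob * s * q_self
        den += prob * (s * q_self + (1.0 - s) * q_out)
    return num / den


def simulate_experiment(cfg: SimulationConfig) -> SimulationResult:
    """Run the full generative model and emit genotypes, mating-trial
    metadata and truth labels.

    The emitted genotype table holds P0 mothers, all focal F1 snails and
    the genotyped F2 juveniles of the most productive families, with
    genotyping noise applied.  The allosperm sires of F1 broods come
    from an unobserved founder pool and are absent from the table, so F1
    snails are outcrossed but their fathers unknown — as in the
    experiment emulated.
    """
    rngs = _rng_streams(cfg.seed)
    freqs = draw_allele_frequencies(cfg, rngs["freqs"])
    panel = cfg.panel()
    rng_ped = rngs["pedigree"]
    rng_thin = rngs["thinning"]

    mothers = [
        MultilocusGenotype(f"P0_{i + 1:03d}", Generation.P0, None, _draw_genotype(freqs, rng_ped))
        for i in range(cfg.n_mothers)
    ]
    # unobserved field sires: two per mother, never genotyped
    allosperm = {
        m.individual_id: [
            MultilocusGenotype(f"pool_{m.individual_id}_{k}", Generation.P0, None, _draw_genotype(freqs, rng_ped))
            for k in range(2)
        ]
        for m in mothers
    }

    f1: list[MultilocusGenotype] = []
    f1_mother: dict[str, str] = {}
    for i in range(cfg.n_f1):
        mom = mothers[i % cfg.n_mothers]
        sire = allosperm[mom.individual_id][rng_ped.integers(2)]
        child = simulate_offspring_genotype(
            mom, sire, rng_ped, f"F1_{i + 1:03d}", Generation.F1
        )
        f1.append(child)
        f1_mother[child.individual_id] = mom.individual_id

    classes = rng_ped.choice(4, size=cfg.n_f1, p=np.asarray(cfg.class_probs))
    n_once = int(round(cfg.n_f1 * cfg.treatment_split))
    order = rng_ped.permutation(cfg.n_f1)
    treatment = np.empty(cfg.n_f1, dtype=object)
    treatment[order[:n_once]] = Treatment.once_paired
    treatment[order[n_once:]] = Treatment.repeatedly_paired

    f1_ids = [ind.individual_id for ind in f1]
    s_by_class = {
        Propensity.outcrosser: 0.0,
        Propensity.plastic_switcher: 0.0,
        Propensity.plastic_mixer: cfg.s_mixer,
        Propensity.selfer: cfg.s_selfer,
    }

    def draw_partners(idx: int, k: int) -> list[str]:
        own = f1_ids[idx]
        own_mother = f1_mother[own]
        pool = [
            pid
            for pid in f1_ids
            if pid != own
            and (cfg.allow_sibling_pairing or f1_mother[pid] != own_mother)
        ]
        if not pool:
            raise SimulationError(
                f"no eligible mating partner for {own!r}; enable "
                "allow_sibling_pairing or enlarge the cohort"
            )
        k = min(k, len(pool))  # tiny cohorts get fewer partners
        return list(rng_ped.choice(pool, size=k, replace=False))

    q_out = cfg.p_develop_outcrossed * (1.0 - cfg.p_juv_die_outcrossed)
    records: list[ExperimentRecord] = []
    ind_rows = []
    juv_rows = []
    eggs_by_family: dict[str, list[dict]] = {}

    for idx, ind in enumerate(f1):
        cls = CLASS_ORDER[classes[idx]]
        tr = treatment[idx]
        k = 1 if tr is Treatment.once_paired else cfg.n_partners_repeated
        partners = draw_partners(idx, k)
        selfs_in_isolation = cls is not Propensity.outcrosser
        s_true = s_by_class[cls]

        eggs_iso = int(rng_thin.poisson(cfg.mean_eggs_isolation)) if selfs_in_isolation else 0
        dev_iso = int(rng_thin.binomial(eggs_iso, cfg.p_develop_selfed)) if eggs_iso else 0

        if tr is Treatment.repeatedly_paired:
            lo, hi = cfg.genotyped_partner_window
            window = int(rng_ped.integers(lo, hi + 1))
        else:
            window = 1
        sire_pool = partners[:window]

        target = float(
            np.clip(
                rng_thin.normal(cfg.juveniles_per_family_mean, cfg.juveniles_per_family_sd),
                cfg.juveniles_per_family_floor,
                cfg.juveniles_per_family_cap,
            )
        )
        n_eggs = max(1, int(round(target / q_out)))
        eggs = []
        dev_post = 0
        n_survive = 0
        for e in range(n_eggs):
            selfed = bool(rng_thin.random() < s_true)
            sire_id = (
                ind.individual_id
                if selfed
                else sire_pool[int(rng_thin.integers(len(sire_pool)))]
            )
            p_dev = cfg.p_develop_selfed if selfed else cfg.p_develop_outcrossed
            p_die = cfg.p_juv_die_selfed if selfed else cfg.p_juv_die_outcrossed
            developed = bool(rng_thin.random() < p_dev)
            survived = bool(developed and rng_thin.random() >= p_die)
            dev_post += developed
            n_survive += survived
            eggs.append(
                {
                    "mother_id": ind.individual_id,
                    "sire_id": sire_id,
                    "selfed": selfed,
                    "developed": developed,
                    "survived": survived,
                }
            )
        eggs_by_family[ind.individual_id] = eggs

        p_fem = (
            cfg.p_female_mating_selfer if cls is Propensity.selfer else cfg.p_female_mating
        )
        n_female = int(rng_thin.binomial(len(partners), p_fem))
        n_male = int(rng_thin.binomial(len(partners), 0.8))

        records.append(
            ExperimentRecord(
                individual_id=ind.individual_id,
                treatment=tr,
                partner_ids=partners,
                n_male_copulation_partners=n_male,
                n_female_copulation_partners=n_female,
                eggs_isolation=eggs_iso,
                developed_embryos_isolation=dev_iso,
                eggs_post=n_eggs,
                developed_embryos_post=dev_post,
                n_juveniles_reared=dev_post,
                n_juveniles_dead=dev_post - n_survive,
            )
        )
        ind_rows.append(
            {
                "individual_id": ind.individual_id,
                "mother_id": f1_mother[ind.individual_id],
                "treatment": tr.value,
                "propensity_class": cls.value,
                "selfed_in_isolation": selfs_in_isolation,
                "s_true_post": s_true,
                "partner_ids": ";".join(partners),
                "candidate_window": window,
                "n_survivors": n_survive,
            }
        )

    # genotype the progeny arrays of a random subset of families with
    # enough survivors; sampling is uniform so the class composition of
    # genotyped families tracks the configured class probabilities
    survivors = {
        r["individual_id"]: r["n_survivors"] for r in ind_rows
    }
    eligible = sorted(
        fid
        for fid, n in survivors.items()
        if n >= cfg.juveniles_per_family_floor
    )
    n_pick = min(cfg.n_genotyped_families, len(eligible))
    genotyped_families = set(
        rng_ped.choice(eligible, size=n_pick, replace=False)
    )

    f1_by_id = {ind.individual_id: ind for ind in f1}
    f2: list[MultilocusGenotype] = []
    for fid in sorted(genotyped_families):
        mother = f1_by_id[fid]
        n_done = 0
        for e_idx, egg in enumerate(eggs_by_family[fid]):
            genotyped = bool(
                egg["survived"] and n_done < cfg.juveniles_per_family_cap
            )
            juv_id = f"F2_{fid}_{e_idx + 1:03d}"
            if genotyped:
                n_done += 1
                sire = f1_by_id[egg["sire_id"]]
                f2.append(
                    simulate_offspring_genotype(mother, sire, rng_ped, juv_id)
                )
            juv_rows.append({**egg, "juvenile_id": juv_id, "genotyped": genotyped})
        for r in ind_rows:
            if r["individual_id"] == fid:
                r["n_genotyped"] = n_done
    for fid, eggs in eggs_by_family.items():
        if fid not in genotyped_families:
            for e_idx, egg in enumerate(eggs):
                juv_rows.append(
                    {**egg, "juvenile_id": f"F2_{fid}_{e_idx + 1:03d}", "genotyped": False}
                )

    table = GenotypeTable(panel, mothers + f1 + f2)
    table = apply_genotyping_noise(table, cfg, rngs["noise"])
    truth = SimulationTruth(
        individuals=pd.DataFrame(ind_rows),
        juveniles=pd.DataFrame(juv_rows),
        allele_freqs=freqs,
    )
    return SimulationResult(table, records, truth, cfg)


def simulate_progeny_arrays(
    n_families: int,
    n_juveniles: int,
    selfing_rate: float,
    n_candidates: int,
    n_loci: int = 9,
    alleles_per_locus: int = 10,
    seed: int = 0,
    dirichlet_concentration: Optional[float] = None,
) -> tuple[GenotypeTable, pd.DataFrame, dict[str, list[str]]]:
    """Minimal noise-free progeny-array instance for recovery testing.

    Mothers and candidate fathers are unrelated Hardy-Weinberg draws
    (equifrequent alleles unless a Dirichlet concentration is given);
    each juvenile is selfed with ``selfing_rate``, otherwise sired by a
    uniformly drawn candidate.  Returns the genotype table, a truth
    frame (juvenile_id, mother_id, sire_id, selfed) and the per-mother
    candidate map.
    """
    if not 0.0 <= selfing_rate <= 1.0:
        raise SimulationError("selfing_rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    loci = [f"L{i + 1:02d}" for i in range(n_loci)]
    if dirichlet_concentration is None:
        freqs = {l: np.full(alleles_per_locus, 1.0 / alleles_per_locus) for l in loci}
    else:
        alpha = np.full(alleles_per_locus, dirichlet_concentration)
        freqs = {l: rng.dirichlet(alpha) for l in loci}
    individuals: list[MultilocusGenotype] = []
    truth_rows = []
    candidate_map: dict[str, list[str]] = {}
    for fam in range(n_families):
        mother = MultilocusGenotype(
            f"M{fam + 1:03d}", Generation.F1, None, _draw_genotype(freqs, rng)
        )
        cands = [
            MultilocusGenotype(
                f"C{fam + 1:03d}_{c + 1}", Generation.F1, None, _draw_genotype(freqs, rng)
            )
            for c in range(n_candidates)
        ]
        individuals.append(mother)
        individuals.extend(cands)
        candidate_map[mother.individual_id] = [c.individual_id for c in cands]
        for j in range(n_juveniles):
            selfed = bool(rng.random() < selfing_rate)
            sire = mother if selfed else cands[int(rng.integers(n_candidates))]
            juv = simulate_offspring_genotype(
                mother, sire, rng, f"J{fam + 1:03d}_{j + 1:02d}"
            )
            individuals.append(juv)
            truth_rows.append(
                {
                    "juvenile_id": juv.individual_id,
                    "mother_id": mother.individual_id,
                    "sire_id": sire.individual_id,
                    "selfed": selfed,
                }
            )
    table = GenotypeTable([LocusDef(l) for l in loci], individuals)
    return table, pd.DataFrame(truth_rows), candidate_map


# ---------------------------------------------------------------------------
# deterministic reference cohort
# ---------------------------------------------------------------------------


def study_summary_cohort() -> tuple[
    list[FamilySelfingEstimate],
    list[PropensityCall],
    list[ExperimentRecord],
]:
    """A deterministic cohort matching the published summary margins of
    the mating-trial experiment this package models.

    Families and individuals are constructed so that the treatment
    tables (multiple paternity, families with selfing, selfed offspring,
    apparent and genotype-based propensity compositions) reproduce the
    reported cell counts exactly: 55 genotyped families (31 once-paired,
    24 repeatedly paired) with 717 assigned offspring of which 166 are
    selfed, and 124 female-fertile individuals with apparent classes.
    Used to exercise and validate the contingency-table and summary
    layers without the archived raw data.
    """
    # (treatment, n_selfed, n_outcrossed, n_sires, selfed_in_isolation) per family
    fam_specs: list[tuple[Treatment, int, int, int, bool]] = []
    once = Treatment.once_paired
    rep = Treatment.repeatedly_paired
    # once-paired: 11 fully selfed families (138 selfed offspring in total
    # with the 4 mixed ones), 4 mixed, 15 switched-to-outcrossing, 1 outcrosser
    for size in [12] * 8 + [10] * 3:
        fam_specs.append((once, size, 0, 1, True))
    for _ in range(4):
        fam_specs.append((once, 3, 12, 2, True))
    for size in [14] * 9 + [13] * 6:
        fam_specs.append((once, 0, size, 1, True))
    fam_specs.append((once, 0, 13, 1, False))
    # repeatedly paired: 4 fully selfed, 5 mixed, 11 switchers, 4 outcrossers
    for size in [4, 5, 6, 8]:
        fam_specs.append((rep, size, 0, 1, True))
    for _ in range(5):
        fam_specs.append((rep, 1, 12, 2, True))
    rep_out_sizes = [16] + [15] * 14
    rep_out_sires = [2, 2, 2, 3, 3, 4] + [1] * 9
    rep_out_iso = [True] * 11 + [False] * 4
    for size, sires, iso in zip(rep_out_sizes, rep_out_sires, rep_out_iso):
        fam_specs.append((rep, 0, size, sires, iso))

    estimates: list[FamilySelfingEstimate] = []
    calls: list[PropensityCall] = []
    records: list[ExperimentRecord] = []
    for i, (tr, n_selfed, n_out, n_sires, iso) in enumerate(fam_specs):
        fid = f"G_{tr.value}_{i + 1:02d}"
        n_assigned = n_selfed + n_out
        s = n_selfed / n_assigned
        estimates.append(
            FamilySelfingEstimate(
                mother_id=fid,
                n_assigned=n_assigned,
                n_selfed=n_selfed,
                s=s,
                ci95=None,
                n_sires=n_sires,
            )
        )
        calls.append(
            PropensityCall(fid, genotype_based=classify_propensity(iso, s))
        )
        n_partners = 1 if tr is once else 6
        records.append(
            ExperimentRecord(
                individual_id=fid,
                treatment=tr,
                partner_ids=[f"X{i + 1:02d}_{k}" for k in range(n_partners)],
                n_female_copulation_partners=1,
                eggs_isolation=60 if iso else 0,
                developed_embryos_isolation=40 if iso else 0,
                eggs_post=2 * n_assigned,
                developed_embryos_post=n_assigned,
                n_juveniles_reared=n_assigned,
            )
        )

    # 124 female-fertile individuals with apparent propensity classes
    apparent_specs = [
        (once, ApparentPropensity.apparent_selfer, 29),
        (once, ApparentPropensity.apparent_plastic, 26),
        (once, ApparentPropensity.apparent_outcrosser, 11),
        (rep, ApparentPropensity.apparent_selfer, 11),
        (rep, ApparentPropensity.apparent_plastic, 20),
        (rep, ApparentPropensity.apparent_outcrosser, 27),
    ]
    counter = 0
    for tr, cls, n in apparent_specs:
        for _ in range(n):
            counter += 1
            aid = f"A_{counter:03d}"
            if cls is ApparentPropensity.apparent_selfer:
                iso_dev, post_dev, n_female = 40, 30, 0
            elif cls is ApparentPropensity.apparent_plastic:
                iso_dev, post_dev, n_female = 40, 30, 1
            else:
                iso_dev, post_dev, n_female = 0, 30, 1
            n_partners = 1 if tr is once else 6
            rec = ExperimentRecord(
                individual_id=aid,
                treatment=tr,
                partner_ids=[f"Y{counter:03d}_{k}" for k in range(n_partners)],
                n_female_copulation_partners=n_female,
                eggs_isolation=iso_dev + 10 if iso_dev else 0,
                developed_embryos_isolation=iso_dev,
                eggs_post=post_dev + 10,
                developed_embryos_post=post_dev,
                n_juveniles_reared=post_dev,
            )
            assert classify_apparent_propensity(rec) is cls
            records.append(rec)
            calls.append(PropensityCall(aid, apparent=cls))
    return estimates, calls, records
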