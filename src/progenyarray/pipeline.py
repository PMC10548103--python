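"""End-to-end orchestration: read (or simulate) -> filter -> assign ->
estimate -> classify -> tabulate -> test.

:func:`run_pipeline` drives the whole progeny-array analysis from a
single :class:`RunConfig` and returns a :class:`RunReport` whose every
count can be recomputed from the per-juvenile assignment table it
carries.  Reports are deterministic given the configuration (including
the seed) and are written as JSON plus tabular artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .genotype_io import (
    ExperimentRecord,
    Generation,
    GenotypeTable,
    apply_locus_exclusions,
    read_experiment_records,
    read_genotype_table,
    write_experiment_records,
    write_genotype_table,
)
from .mating_system import (
    FamilySelfingEstimate,
    MatingSystemError,
    MatingSystemThresholds,
    PropensityCall,
    build_treatment_tables,
    classify_propensity,
    classify_apparent_propensity,
    cohort_summary,
    estimate_selfing_rate,
)
from .parentage import AssignmentConfig, assign_family
from .popstats import StatsError, allele_frequencies, fis_weir_cockerham, pearson_chi2
from .synthetic_data import SimulationConfig, simulate_experiment


class PipelineError(ValueError):
    """Invalid run configuration or inconsistent pipeline inputs."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Exactly one input source must be present: file paths (genotypes +
    metadata) or a simulation block.  ``yates_tables`` names the
    treatment tables tested with Yates' continuity correction (by
    default only the 2x2 multiple-paternity table, where the correction
    is conventionally applied at these sample sizes).
    """

    genotypes_path: Optional[str] = None
    metadata_path: Optional[str] = None
    simulate: Optional[SimulationConfig] = None
    locus_exclusions: tuple[str, ...] = ()
    max_mismatch: int = 2
    tie_break: str = "likelihood"
    prior_self: float = 0.5
    t_low: float = 0.2
    t_high: float = 0.8
    yates_tables: tuple[str, ...] = ("multiple_paternity",)
    ci_method: str = "wilson"
    fis_bootstrap: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.genotypes_path is not None and self.metadata_path is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise PipelineError(
                "exactly one input source required: genotypes+metadata paths "
                "or a simulate block"
            )
        if has_files:
            for p in (self.genotypes_path, self.metadata_path):
                if not Path(p).exists():
                    raise PipelineError(f"input file not found: {p}")
        MatingSystemThresholds(self.t_low, self.t_high)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        kwargs = dict(raw)
        if sim is not None:
            kwargs["simulate"] = SimulationConfig(**sim)
        for key in ("locus_exclusions", "yates_tables"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    assignments: pd.DataFrame
    families: pd.DataFrame
    calls: pd.DataFrame
    tables: dict
    chi2: dict
    proportions: dict
    fis: Optional[dict]
    metadata: dict
    estimates: list[FamilySelfingEstimate] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "proportions": self.proportions,
            "tables": self.tables,
            "chi2": self.chi2,
            "fis": self.fis,
            "families": self.families.to_dict(orient="records"),
            "calls": self.calls.to_dict(orient="records"),
            "assignments": self.assignments.to_dict(orient="records"),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        self.assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)
        self.families.to_csv(out / "families.tsv", sep="\t", index=False)
        self.calls.to_csv(out / "propensity_calls.tsv", sep="\t", index=False)


def _load_inputs(cfg: RunConfig):
    if cfg.simulate is not None:
        sim = simulate_experiment(cfg.simulate)
        return sim.genotypes, sim.records, sim.truth
    table = read_genotype_table(cfg.genotypes_path, dialect="tabular")
    records = read_experiment_records(cfg.metadata_path)
    return table, records, None


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run the full analysis chain; deterministic given *cfg*."""
    table, records, truth = _load_inputs(cfg)
    if cfg.locus_exclusions:
        table = apply_locus_exclusions(table, cfg.locus_exclusions)
    if not table.active_loci:
        raise PipelineError("no active loci after exclusions")
    rec_by_id = {r.individual_id: r for r in records}
    th = MatingSystemThresholds(cfg.t_low, cfg.t_high)

    # reference allele frequencies for likelihood tie-breaks, from the
    # parental generation (mothers + candidate fathers)
    freqs = allele_frequencies(table, generation=Generation.F1)
    assign_cfg = AssignmentConfig(
        max_mismatch=cfg.max_mismatch,
        tie_break=cfg.tie_break,
        allele_freqs=freqs if cfg.tie_break == "likelihood" else None,
    )

    juveniles_by_mother: dict[str, list] = {}
    for juv in table.by_generation(Generation.F2):
        if juv.mother_id is None:
            raise PipelineError(f"juvenile {juv.individual_id!r} has no mother id")
        juveniles_by_mother.setdefault(juv.mother_id, []).append(juv)

    assignment_rows = []
    family_rows = []
    call_rows = []
    estimates = []
    calls = []
    for mother_id in sorted(juveniles_by_mother):
        if mother_id not in table:
            raise PipelineError(f"mother {mother_id!r} not genotyped")
        mother = table.get(mother_id)
        rec = rec_by_id.get(mother_id)
        if rec is None:
            raise PipelineError(f"mother {mother_id!r} has no experiment metadata")
        candidates = [mother] + [
            table.get(pid) for pid in rec.partner_ids if pid in table
        ]
        assignments, summary = assign_family(
            mother,
            juveniles_by_mother[mother_id],
            candidates,
            table.active_loci,
            assign_cfg,
            compute_prob_selfed=True,
        )
        est = estimate_selfing_rate(assignments, ci_method=cfg.ci_method)
        estimates.append(est)
        for a in assignments:
            assignment_rows.append(
                {
                    "juvenile_id": a.juvenile_id,
                    "mother_id": a.mother_id,
                    "status": a.status.value,
                    "father_id": a.assigned_father_id or "",
                    "best_mismatches": a.best_mismatches,
                    "n_shared_loci": a.n_shared_loci,
                    "n_outcross_consistent_loci": a.n_outcross_consistent_loci,
                    "prob_selfed": a.prob_selfed,
                    "exclusion_reason": a.exclusion_reason or "",
                }
            )
        family_rows.append(
            {
                **summary.to_dict(),
                "s": est.s,
                "ci95_low": est.ci95[0] if est.ci95 else None,
                "ci95_high": est.ci95[1] if est.ci95 else None,
                "n_sires": est.n_sires,
                "multiple_paternity": est.multiple_paternity,
                "treatment": rec.treatment.value,
            }
        )
        call = PropensityCall(mother_id)
        if est.n_assigned > 0:
            call.genotype_based = classify_propensity(
                rec.developed_embryos_isolation > 0, est.s, th
            )
        calls.append(call)

    # apparent classification for every individual with metadata
    estimated_ids = {c.individual_id for c in calls}
    for rec in records:
        apparent = classify_apparent_propensity(rec)
        existing = next(
            (c for c in calls if c.individual_id == rec.individual_id), None
        )
        if existing is not None:
            existing.apparent = apparent
        else:
            calls.append(PropensityCall(rec.individual_id, apparent=apparent))
    for c in calls:
        call_rows.append(
            {
                "individual_id": c.individual_id,
                "genotype_based": c.genotype_based.value if c.genotype_based else "",
                "apparent": c.apparent.value if c.apparent else "",
            }
        )

    tables_out: dict = {}
    chi2_out: dict = {}
    if estimates or calls:
        try:
            tables = build_treatment_tables(calls, estimates, rec_by_id)
        except MatingSystemError as exc:
            tables = {}
            tables_out["error"] = str(exc)
        for name, tab in tables.items():
            tables_out[name] = tab.to_dict()
            try:
                res = pearson_chi2(tab, yates=name in cfg.yates_tables)
                chi2_out[name] = res.to_dict()
            except StatsError as exc:
                chi2_out[name] = {"error": str(exc)}

    proportions = cohort_summary(estimates, calls, rec_by_id)

    fis_out = None
    f1_inds = table.by_generation(Generation.F1)
    if len(f1_inds) >= 2 and len(table.active_loci) >= 2:
        try:
            fis = fis_weir_cockerham(
                table,
                n_bootstrap=cfg.fis_bootstrap,
                seed=cfg.seed,
                generation=Generation.F1,
            )
            fis_out = {
                "f_is": fis.f_is,
                "ci95": list(fis.ci95) if fis.ci95 else None,
                "h_obs": fis.h_obs,
                "h_exp": fis.h_exp,
            }
        except StatsError:
            fis_out = None

    assignments_df = pd.DataFrame(assignment_rows)
    families_df = pd.DataFrame(family_rows)
    calls_df = pd.DataFrame(call_rows)
    metadata = {
        "package_version": __version__,
        "seed": cfg.seed,
        "n_families": len(family_rows),
        "n_juveniles_genotyped": len(assignment_rows),
        "config": _config_echo(cfg),
    }
    return RunReport(
        assignments=assignments_df,
        families=families_df,
        calls=calls_df,
        tables=tables_out,
        chi2=chi2_out,
        proportions=proportions,
        fis=fis_out,
        metadata=metadata,
        estimates=estimates,
    )


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if d.get("simulate") is not None:
        d["simulate"] = dataclasses.asdict(cfg.simulate)
    for key in ("locus_exclusions", "yates_tables"):
        d[key] = list(d[key])
    if d["simulate"] is not None and "genotyped_partner_window" in d["simulate"]:
        d["simulate"]["genotyped_partner_window"] = list(
            d["simulate"]["genotyped_partner_window"]
        )
        d["simulate"]["class_probs"] = list(d["simulate"]["class_probs"])
    return d


def make_fixture(cfg: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write the standard fixture files.

    Emits the genotype table (with panel sidecar), experiment metadata,
    truth tables, and the configuration used.
    """
    if cfg.simulate is None:
        raise PipelineError("make_fixture requires a simulate block")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_experiment(cfg.simulate)
    paths = {
        "genotypes": out / "genotypes.csv",
        "metadata": out / "metadata.csv",
        "truth_individuals": out / "truth_individuals.csv",
        "truth_juveniles": out / "truth_juveniles.csv",
        "config": out / "config.yaml",
    }
    write_genotype_table(sim.genotypes, paths["genotypes"])
    write_experiment_records(sim.records, paths["metadata"])
    sim.truth.individuals.to_csv(paths["truth_individuals"], index=False)
    sim.truth.juveniles.to_csv(paths["truth_juveniles"], index=False)
    paths["config"].write_text(yaml.safe_dump(_config_echo(cfg), sort_keys=True))
    return paths
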