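"""Data model and file I/O for multilocus microsatellite genotypes.

The package analyses progeny arrays: the genotyped offspring of known
mothers, scored at a panel of codominant microsatellite loci.  An
individual's genotype is an unordered pair of positive integer allele
codes per locus; a locus is either fully called (two alleles) or missing
entirely — half-calls are rejected at read time.  Allele codes are
opaque labels (typically fragment lengths); no size ordering is assumed
anywhere, since parentage inference only ever tests allele identity.

Two on-disk dialects are supported:

* ``tabular`` — a flat delimited file with header
  ``id,generation,mother_id,<locus>_a,<locus>_b,...`` and an optional
  YAML panel sidecar carrying per-locus exclusion flags.  This is the
  package's native, lossless format.
* ``genepop`` — the community-standard exchange format for
  microsatellite data (2- or 3-digit concatenated allele codes,
  ``0``/``000`` meaning missing).  GenePop carries no pedigree or
  generation metadata, so those fields are supplied by the caller on
  read and dropped on write.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml


class GenotypeIOError(ValueError):
    """Malformed genotype/metadata input (message names the offending row/field)."""


class Generation(str, enum.Enum):
    """Experimental generation: founders (P0), focal snails (F1), progeny (F2)."""

    P0 = "P0"
    F1 = "F1"
    F2 = "F2"


class Treatment(str, enum.Enum):
    """Mate-availability treatment of a focal individual."""

    once_paired = "once_paired"
    repeatedly_paired = "repeatedly_paired"


@dataclass(frozen=True)
class LocusDef:
    """One microsatellite locus in the panel.

    ``excluded`` marks loci removed from all analyses (e.g. a locus with
    a non-negligible null-allele frequency); their calls are retained in
    the table but are invisible to downstream counting operations.
    """

    name: str
    excluded: bool = False
    note: str = ""


AllelePair = tuple[int, int]


def _canonical_pair(pair: Sequence[int]) -> AllelePair:
    a, b = int(pair[0]), int(pair[1])
    if a <= 0 or b <= 0:
        raise GenotypeIOError(f"allele codes must be positive, got {pair!r}")
    return (a, b) if a <= b else (b, a)


@dataclass
class MultilocusGenotype:
    """An individual's genotype: an unordered allele pair per called locus.

    ``calls`` maps locus name to a canonically sorted pair of positive
    integers; loci absent from the map are missing.  The pair (a, b) and
    (b, a) denote the same genotype and are stored identically.
    """

    individual_id: str
    generation: Generation
    mother_id: Optional[str] = None
    calls: dict[str, AllelePair] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.generation = Generation(self.generation)
        self.calls = {loc: _canonical_pair(pair) for loc, pair in self.calls.items()}

    def call(self, locus: str) -> Optional[AllelePair]:
        return self.calls.get(locus)

    def has_call(self, locus: str) -> bool:
        return locus in self.calls


@dataclass
class GenotypeTable:
    """A panel of loci plus a set of genotyped individuals.

    Invariants enforced on construction: locus names unique, individual
    ids unique, and every call references a panel locus.
    """

    panel: list[LocusDef]
    individuals: list[MultilocusGenotype]

    def __post_init__(self) -> None:
        names = [l.name for l in self.panel]
        if len(set(names)) != len(names):
            raise GenotypeIOError("duplicate locus names in panel")
        ids = [ind.individual_id for ind in self.individuals]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise GenotypeIOError(f"duplicate individual id(s): {sorted(dupes)}")
        known = set(names)
        for ind in self.individuals:
            unknown = set(ind.calls) - known
            if unknown:
                raise GenotypeIOError(
                    f"individual {ind.individual_id!r} has calls at loci "
                    f"{sorted(unknown)} not in the panel"
                )
        self._index = {ind.individual_id: ind for ind in self.individuals}

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    @property
    def active_loci(self) -> list[str]:
        """Names of loci not flagged excluded (the loci all counting uses)."""
        return [l.name for l in self.panel if not l.excluded]

    def get(self, individual_id: str) -> MultilocusGenotype:
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual id {individual_id!r}") from None

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def __len__(self) -> int:
        return len(self.individuals)

    def by_generation(self, generation: Generation | str) -> list[MultilocusGenotype]:
        gen = Generation(generation)
        return [ind for ind in self.individuals if ind.generation == gen]


@dataclass
class ExperimentRecord:
    """Per-individual mating-trial metadata.

    Covers the pairing design (treatment, ordered partner ids), observed
    copulations in each sexual role, and female reproductive output in
    the isolation and post-isolation phases (eggs laid and eggs
    containing developed embryos), plus juvenile rearing outcomes.
    """

    individual_id: str
    treatment: Treatment
    partner_ids: list[str]
    n_male_copulation_partners: int = 0
    n_female_copulation_partners: int = 0
    eggs_isolation: int = 0
    developed_embryos_isolation: int = 0
    eggs_post: int = 0
    developed_embryos_post: int = 0
    n_juveniles_reared: int = 0
    n_juveniles_dead: int = 0
    body_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.treatment = Treatment(self.treatment)
        for name in (
            "n_male_copulation_partners",
            "n_female_copulation_partners",
            "eggs_isolation",
            "developed_embryos_isolation",
            "eggs_post",
            "developed_embryos_post",
            "n_juveniles_reared",
            "n_juveniles_dead",
        ):
            if getattr(self, name) < 0:
                raise GenotypeIOError(f"{name} < 0 for {self.individual_id!r}")
        if self.developed_embryos_isolation > self.eggs_isolation:
            raise GenotypeIOError(
                f"{self.individual_id!r}: developed embryos exceed eggs (isolation)"
            )
        if self.developed_embryos_post > self.eggs_post:
            raise GenotypeIOError(
                f"{self.individual_id!r}: developed embryos exceed eggs (post-isolation)"
            )
        if self.n_juveniles_dead > self.n_juveniles_reared:
            raise GenotypeIOError(
                f"{self.individual_id!r}: dead juveniles exceed reared juveniles"
            )
        if self.treatment is Treatment.once_paired and len(self.partner_ids) != 1:
            raise GenotypeIOError(
                f"{self.individual_id!r}: once-paired requires exactly 1 partner, "
                f"got {len(self.partner_ids)}"
            )
        if self.body_size is not None and self.body_size <= 0:
            raise GenotypeIOError(f"{self.individual_id!r}: body_size must be positive")


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

_META_COLS = ["id", "generation", "mother_id"]


def _panel_sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".panel.yaml")


def _write_panel_sidecar(panel: Sequence[LocusDef], path: Path) -> None:
    data = [
        {"name": l.name, "excluded": bool(l.excluded), "note": l.note} for l in panel
    ]
    path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_panel_sidecar(path: Path) -> list[LocusDef]:
    data = yaml.safe_load(Path(path).read_text())
    return [
        LocusDef(d["name"], bool(d.get("excluded", False)), d.get("note", ""))
        for d in data
    ]


def _read_tabular(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[:3] != _META_COLS:
        raise GenotypeIOError(
            f"tabular header must start with {','.join(_META_COLS)}, got {cols[:3]}"
        )
    locus_cols = cols[3:]
    loci: list[str] = []
    for i in range(0, len(locus_cols), 2):
        pair_cols = locus_cols[i : i + 2]
        if len(pair_cols) != 2:
            raise GenotypeIOError(f"dangling locus column {pair_cols[0]!r}")
        a_col, b_col = pair_cols
        if not (a_col.endswith("_a") and b_col.endswith("_b")):
            raise GenotypeIOError(
                f"locus columns must come in <locus>_a,<locus>_b pairs; "
                f"got {a_col!r},{b_col!r}"
            )
        if a_col[:-2] != b_col[:-2]:
            raise GenotypeIOError(f"mismatched locus column pair {a_col!r},{b_col!r}")
        loci.append(a_col[:-2])

    sidecar = _panel_sidecar_path(path)
    if sidecar.exists():
        panel = read_panel_sidecar(sidecar)
        if [l.name for l in panel] != loci:
            raise GenotypeIOError(
                f"panel sidecar loci {[l.name for l in panel]} do not match "
                f"table columns {loci}"
            )
    else:
        panel = [LocusDef(name) for name in loci]

    individuals = []
    for row_i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = dict(zip(cols, row))
        ind_id = rec["id"].strip()
        if not ind_id:
            raise GenotypeIOError(f"line {row_i}: empty id")
        try:
            gen = Generation(rec["generation"].strip())
        except ValueError:
            raise GenotypeIOError(
                f"line {row_i}: bad generation {rec['generation']!r}"
            ) from None
        mother = rec["mother_id"].strip() or None
        calls: dict[str, AllelePair] = {}
        for locus in loci:
            a_raw = rec[f"{locus}_a"].strip()
            b_raw = rec[f"{locus}_b"].strip()
            a_missing = a_raw in ("", "0")
            b_missing = b_raw in ("", "0")
            if a_missing and b_missing:
                continue
            if a_missing or b_missing:
                raise GenotypeIOError(
                    f"line {row_i}: half-called locus {locus!r} for {ind_id!r}"
                )
            try:
                calls[locus] = _canonical_pair((int(a_raw), int(b_raw)))
            except (ValueError, GenotypeIOError) as exc:
                raise GenotypeIOError(
                    f"line {row_i}: bad alleles at locus {locus!r} for {ind_id!r}: {exc}"
                ) from None
        individuals.append(MultilocusGenotype(ind_id, gen, mother, calls))
    return GenotypeTable(panel, individuals)


def _write_tabular(table: GenotypeTable, path: Path) -> None:
    loci = table.locus_names
    cols = _META_COLS + [f"{loc}_{ab}" for loc in loci for ab in ("a", "b")]
    rows = []
    for ind in table.individuals:
        row: dict[str, str] = {
            "id": ind.individual_id,
            "generation": ind.generation.value,
            "mother_id": ind.mother_id or "",
        }
        for loc in loci:
            call = ind.call(loc)
            row[f"{loc}_a"] = "" if call is None else str(call[0])
            row[f"{loc}_b"] = "" if call is None else str(call[1])
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    _write_panel_sidecar(table.panel, _panel_sidecar_path(path))


# ---------------------------------------------------------------------------
# genepop dialect
# ---------------------------------------------------------------------------


def _parse_genepop_alleles(token: str, line_no: int, ind_id: str) -> Optional[AllelePair]:
    if len(token) == 4:
        width = 2
    elif len(token) == 6:
        width = 3
    else:
        raise GenotypeIOError(
            f"line {line_no}: genotype token {token!r} for {ind_id!r} must be "
            "4 or 6 digits"
        )
    try:
        a, b = int(token[:width]), int(token[width:])
    except ValueError:
        raise GenotypeIOError(
            f"line {line_no}: non-numeric genotype token {token!r} for {ind_id!r}"
        ) from None
    if a == 0 and b == 0:
        return None
    if a == 0 or b == 0:
        raise GenotypeIOError(
            f"line {line_no}: half-called genotype {token!r} for {ind_id!r}"
        )
    return _canonical_pair((a, b))


def _read_genepop(path: Path, generation: Generation | str = Generation.F1) -> GenotypeTable:
    gen = Generation(generation)
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenotypeIOError("empty GenePop file")
    loci: list[str] = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenotypeIOError("no 'Pop' line in GenePop file")
    individuals = []
    for line_no, line in enumerate(lines[i:], start=i + 1):
        stripped = line.strip()
        if not stripped or stripped.lower() == "pop":
            continue
        if "," not in stripped:
            raise GenotypeIOError(f"line {line_no}: missing ',' separator")
        ind_id, geno_part = stripped.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise GenotypeIOError(
                f"line {line_no}: {ind_id!r} has {len(tokens)} genotype tokens "
                f"for {len(loci)} loci"
            )
        calls = {}
        for locus, token in zip(loci, tokens):
            pair = _parse_genepop_alleles(token, line_no, ind_id)
            if pair is not None:
                calls[locus] = pair
        individuals.append(MultilocusGenotype(ind_id, gen, None, calls))
    panel = [LocusDef(name) for name in loci]
    sidecar = _panel_sidecar_path(path)
    if sidecar.exists():
        panel = read_panel_sidecar(sidecar)
        if [l.name for l in panel] != loci:
            raise GenotypeIOError("panel sidecar loci do not match GenePop loci")
    return GenotypeTable(panel, individuals)


def _write_genepop(table: GenotypeTable, path: Path, title: str = "progenyarray export") -> None:
    loci = table.locus_names
    width = 3
    for ind in table.individuals:
        for pair in ind.calls.values():
            if max(pair) > 999:
                raise GenotypeIOError(
                    f"allele code {max(pair)} too wide for GenePop 3-digit encoding"
                )
    out = [title]
    out.extend(loci)
    out.append("Pop")
    for ind in table.individuals:
        tokens = []
        for loc in loci:
            call = ind.call(loc)
            if call is None:
                tokens.append("0" * (2 * width))
            else:
                tokens.append(f"{call[0]:0{width}d}{call[1]:0{width}d}")
        out.append(f"{ind.individual_id} ,  " + " ".join(tokens))
    Path(path).write_text("\n".join(out) + "\n")
    _write_panel_sidecar(table.panel, _panel_sidecar_path(Path(path)))


# ---------------------------------------------------------------------------
# public I/O surface
# ---------------------------------------------------------------------------


def read_genotype_table(
    path: str | Path,
    dialect: str = "tabular",
    generation: Generation | str = Generation.F1,
) -> GenotypeTable:
    """Read a genotype table.

    Parameters
    ----------
    path:
        Input file. A panel sidecar ``<path>.panel.yaml`` is honoured if
        present (it carries locus exclusion flags).
    dialect:
        ``"tabular"`` or ``"genepop"``.
    generation:
        Generation label applied to all individuals when the dialect
        carries none (GenePop only; ignored for tabular input).
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeIOError(f"no such file: {path}")
    if dialect == "tabular":
        return _read_tabular(path)
    if dialect == "genepop":
        return _read_genepop(path, generation)
    raise GenotypeIOError(f"unknown dialect {dialect!r}")


def write_genotype_table(table: GenotypeTable, path: str | Path, dialect: str = "tabular") -> None:
    """Write a genotype table (plus its panel sidecar) in the given dialect.

    Tabular output round-trips exactly (ids, order, calls, missingness,
    generations, mother links).  GenePop output preserves ids and calls
    only; generation and pedigree metadata are not representable there.
    """
    path = Path(path)
    if dialect == "tabular":
        _write_tabular(table, path)
    elif dialect == "genepop":
        _write_genepop(table, path)
    else:
        raise GenotypeIOError(f"unknown dialect {dialect!r}")


def apply_locus_exclusions(table: GenotypeTable, names: Iterable[str]) -> GenotypeTable:
    """Return a copy of *table* with the named loci flagged excluded.

    Excluded loci stay in the panel (and keep their calls) but disappear
    from ``active_loci`` and hence from all downstream counting.
    Idempotent and order-insensitive; raises if a name is unknown or if
    no active locus would remain.
    """
    names = set(names)
    known = set(table.locus_names)
    unknown = names - known
    if unknown:
        raise GenotypeIOError(f"unknown locus name(s): {sorted(unknown)}")
    panel = [
        dataclasses.replace(l, excluded=l.excluded or l.name in names)
        for l in table.panel
    ]
    if not any(not l.excluded for l in panel):
        raise GenotypeIOError("exclusions would leave no active loci")
    return GenotypeTable(panel, list(table.individuals))


@dataclass
class MissingnessSummary:
    """Missing-call rates: per individual, per locus, and overall."""

    per_individual: "pd.Series"
    per_locus: "pd.Series"
    overall: float


def summarize_missingness(table: GenotypeTable) -> MissingnessSummary:
    """Missing-call rates over the full panel (excluded loci included).

    Per-individual and per-locus rates are fractions of uncalled loci;
    totals are mutually consistent with the grand rate.
    """
    loci = table.locus_names
    if not loci or not table.individuals:
        raise GenotypeIOError("missingness undefined for an empty table")
    miss = pd.DataFrame(
        [[0 if ind.has_call(loc) else 1 for loc in loci] for ind in table.individuals],
        index=[ind.individual_id for ind in table.individuals],
        columns=loci,
    )
    return MissingnessSummary(
        per_individual=miss.mean(axis=1),
        per_locus=miss.mean(axis=0),
        overall=float(miss.values.mean()),
    )


# ---------------------------------------------------------------------------
# experiment metadata I/O
# ---------------------------------------------------------------------------

_REC_INT_COLS = [
    "n_male_copulation_partners",
    "n_female_copulation_partners",
    "eggs_isolation",
    "developed_embryos_isolation",
    "eggs_post",
    "developed_embryos_post",
    "n_juveniles_reared",
    "n_juveniles_dead",
]


def read_experiment_records(path: str | Path) -> list[ExperimentRecord]:
    """Read mating-trial metadata keyed by individual id (CSV).

    ``partner_ids`` is a ``;``-separated ordered list; ``body_size`` may
    be empty.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeIOError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    seen: set[str] = set()
    for row_i, row in enumerate(df.to_dict("records"), start=2):
        ind_id = row["individual_id"].strip()
        if ind_id in seen:
            raise GenotypeIOError(f"line {row_i}: duplicate individual_id {ind_id!r}")
        seen.add(ind_id)
        try:
            kwargs = {c: int(row[c]) for c in _REC_INT_COLS}
        except ValueError as exc:
            raise GenotypeIOError(f"line {row_i}: bad integer field: {exc}") from None
        body = row.get("body_size", "").strip()
        records.append(
            ExperimentRecord(
                individual_id=ind_id,
                treatment=Treatment(row["treatment"].strip()),
                partner_ids=[p for p in row["partner_ids"].split(";") if p],
                body_size=float(body) if body else None,
                **kwargs,
            )
        )
    return records


def write_experiment_records(records: Sequence[ExperimentRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {
            "individual_id": rec.individual_id,
            "treatment": rec.treatment.value,
            "partner_ids": ";".join(rec.partner_ids),
        }
        row.update({c: getattr(rec, c) for c in _REC_INT_COLS})
        row["body_size"] = "" if rec.body_size is None else rec.body_size
        rows.append(row)
    cols = ["individual_id", "treatment", "partner_ids"] + _REC_INT_COLS + ["body_size"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
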