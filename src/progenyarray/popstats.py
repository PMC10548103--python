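"""Contingency-table tests, proportion intervals, allele frequencies and F_IS.

These are the population-genetic and categorical statistics the
progeny-array analysis needs outside of parentage inference proper:
Pearson chi-square tests of treatment effects (optionally with Yates'
continuity correction on 2x2 tables), score/exact confidence intervals
for proportions, per-locus allele frequencies, and the Weir-Cockerham
within-population inbreeding coefficient f (F_IS) with a locus-bootstrap
confidence interval.  Heterozygote deficiency (F_IS > 0) in a progeny
sample is the classic population-level signature of selfing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .genotype_io import Generation, GenotypeTable


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass
class ContingencyTable:
    """An r x c table of non-negative integer counts with axis labels."""

    observed: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=np.int64)
        if self.observed.ndim != 2:
            raise StatsError("observed must be a 2-D matrix")
        r, c = self.observed.shape
        if r < 2 or c < 2:
            raise StatsError(f"need at least a 2x2 table, got {r}x{c}")
        if (self.observed < 0).any():
            raise StatsError("negative cell count")
        if self.observed.sum() == 0:
            raise StatsError("empty table (grand total 0)")
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise StatsError("label lengths do not match table shape")

    def to_dict(self) -> dict:
        return {
            "observed": self.observed.tolist(),
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
        }


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    yates_applied: bool

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "expected": np.round(self.expected, 6).tolist(),
            "yates_applied": self.yates_applied,
        }


def pearson_chi2(table: ContingencyTable, yates: bool = False) -> ChiSquareResult:
    """Two-tailed Pearson chi-square test of independence.

    Expected counts come from the row/column margins; Yates' continuity
    correction is permitted on 2x2 tables only.  A zero margin (which
    would make an expected cell zero) is an error.
    """
    obs = table.observed
    if yates and obs.shape != (2, 2):
        raise StatsError("Yates correction is only defined for 2x2 tables")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise StatsError("zero row/column margin; expected counts undefined")
    statistic, p, df, expected = stats.chi2_contingency(obs, correction=yates)
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        expected=np.asarray(expected, dtype=float),
        yates_applied=bool(yates),
    )


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: str = "wilson"
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion k/n.

    ``wilson`` is the score interval (good coverage at moderate n);
    ``clopper_pearson`` is the exact interval.  The interval always
    contains k/n and lies within [0, 1].
    """
    if n <= 0:
        raise StatsError("n must be positive")
    if not 0 <= k <= n:
        raise StatsError(f"k={k} outside [0, n={n}]")
    methods = {"wilson": "wilson", "clopper_pearson": "beta"}
    if method not in methods:
        raise StatsError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=methods[method])
    return float(lo), float(hi)


def allele_frequencies(
    table: GenotypeTable,
    generation: Optional[Generation | str] = None,
    include_excluded: bool = False,
) -> dict[str, dict[int, float]]:
    """Per-locus allele frequency maps, counting two alleles per called
    individual.

    Missing calls are excluded from the denominators; loci with zero
    calls are omitted with a warning.  By default only active
    (non-excluded) loci are reported.
    """
    inds = table.individuals if generation is None else table.by_generation(generation)
    loci = table.locus_names if include_excluded else table.active_loci
    freqs: dict[str, dict[int, float]] = {}
    for locus in loci:
        counts: Counter[int] = Counter()
        for ind in inds:
            call = ind.call(locus)
            if call is not None:
                counts[call[0]] += 1
                counts[call[1]] += 1
        total = sum(counts.values())
        if total == 0:
            warnings.warn(f"locus {locus!r} has no calls; omitted from frequencies")
            continue
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
    return freqs


@dataclass
class InbreedingSummary:
    """Multi-locus F_IS with per-locus detail.

    ``f_is`` is the Weir-Cockerham within-population f computed as a
    ratio of sums of variance components over loci; ``ci95`` is a
    percentile bootstrap over loci.  ``f_is`` is None when every locus
    is monomorphic (no heterozygosity expected, so f undefined).
    """

    allele_freqs: dict[str, dict[int, float]]
    h_obs: float
    h_exp: float
    f_is: Optional[float]
    ci95: Optional[tuple[float, float]]
    per_locus: pd.DataFrame = field(repr=False, default=None)


def _wc_components(table: GenotypeTable, loci: Sequence[str], inds) -> pd.DataFrame:
    """Per-locus Weir-Cockerham variance components for a single sample.

    For each allele u at a locus with n called individuals, frequency p
    and observed heterozygote share h (individuals carrying u with two
    distinct alleles):

        b_u = n/(n-1) * (p(1-p) - (2n-1)/(4n) * h)
        c_u = h/2

    f = 1 - sum(c) / sum(b + c), summed over alleles and loci.
    """
    rows = []
    for locus in loci:
        calls = [ind.call(locus) for ind in inds]
        calls = [c for c in calls if c is not None]
        n = len(calls)
        if n < 2:
            continue
        p_counts: Counter[int] = Counter()
        het_counts: Counter[int] = Counter()
        n_het = 0
        for a, b in calls:
            p_counts[a] += 1
            p_counts[b] += 1
            if a != b:
                n_het += 1
                het_counts[a] += 1
                het_counts[b] += 1
        sum_b = 0.0
        sum_c = 0.0
        gene_div = 1.0
        for allele, cnt in p_counts.items():
            p = cnt / (2 * n)
            h = het_counts.get(allele, 0) / n
            sum_b += n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            sum_c += h / 2.0
            gene_div -= p * p
        rows.append(
            {
                "locus": locus,
                "n": n,
                "h_obs": n_het / n,
                "h_exp": gene_div,
                "b": sum_b,
                "c": sum_c,
            }
        )
    return pd.DataFrame(rows)


def fis_weir_cockerham(
    table: GenotypeTable,
    n_bootstrap: int = 1000,
    seed: int = 0,
    generation: Optional[Generation | str] = None,
) -> InbreedingSummary:
    """Weir-Cockerham within-population inbreeding coefficient f (F_IS).

    The multi-locus estimate is the ratio-of-sums over loci of the b and
    c variance components; the 95% CI is a percentile bootstrap
    resampling loci (hence it needs >= 2 polymorphic loci).  f = -1 in
    the limit of complete heterozygote excess, ~0 under random mating,
    and -> 1 in a fully inbred (e.g. long-selfed) sample.
    """
    inds = table.individuals if generation is None else table.by_generation(generation)
    if len(inds) < 2:
        raise StatsError("need at least 2 individuals for F_IS")
    comp = _wc_components(table, table.active_loci, inds)
    freqs = allele_frequencies(table, generation=generation)
    if comp.empty:
        raise StatsError("no locus with >= 2 called individuals")
    poly = comp[comp["h_exp"] > 0].reset_index(drop=True)
    if poly.empty:
        return InbreedingSummary(freqs, 0.0, 0.0, None, None, comp)
    denom = (poly["b"] + poly["c"]).sum()
    f_is = float(1.0 - poly["c"].sum() / denom) if denom != 0 else None
    ci: Optional[tuple[float, float]] = None
    if f_is is not None and len(poly) >= 2 and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        b = poly["b"].to_numpy()
        c = poly["c"].to_numpy()
        idx = rng.integers(0, len(poly), size=(n_bootstrap, len(poly)))
        bc = b[idx].sum(axis=1) + c[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boots = 1.0 - c[idx].sum(axis=1) / bc
        boots = boots[np.isfinite(boots)]
        if boots.size:
            ci = (
                float(np.percentile(boots, 2.5)),
                float(np.percentile(boots, 97.5)),
            )
    return InbreedingSummary(
        allele_freqs=freqs,
        h_obs=float(poly["h_obs"].mean()),
        h_exp=float(poly["h_exp"].mean()),
        f_is=f_is,
        ci95=ci,
        per_locus=comp,
    )
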