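"""Shared fixtures and independent oracles.

The oracle functions here re-derive parentage verdicts and chi-square
statistics from first principles, by different routes than the package
(per-allele enumeration instead of set classification; the textbook
closed form instead of scipy).  Tests compare the two.
"""

from __future__ import annotations

import numpy as np
import pytest

from progenyarray import (
    Generation,
    GenotypeTable,
    LocusDef,
    MultilocusGenotype,
)


@pytest.fixture
def small_panel() -> list[LocusDef]:
    return [LocusDef(f"L{i:02d}") for i in range(1, 10)]


def make_genotype(ind_id, calls, generation=Generation.F1, mother=None):
    return MultilocusGenotype(ind_id, generation, mother, calls)


# ---------------------------------------------------------------------------
# brute-force parentage oracle
# ---------------------------------------------------------------------------


def oracle_possible_paternal(juv_pair, mom_pair):
    """Alleles of the juvenile that could be paternal: allele a qualifies
    iff the juvenile's other allele could have come from the mother.
    When no allele qualifies (no juvenile allele is maternal), either
    juvenile allele is treated as possibly paternal (tolerated-error
    convention)."""
    x, y = juv_pair
    options = set()
    if y in mom_pair:
        options.add(x)
    if x in mom_pair:
        options.add(y)
    if not options:
        options = {x, y}
    return options


def oracle_maternal_mismatch(juv_pair, mom_pair):
    return not (set(juv_pair) & set(mom_pair))


def oracle_inclusion(juvenile, mother, loci):
    shared = [
        l for l in loci if l in juvenile.calls and l in mother.calls
    ]
    n_mm = sum(
        oracle_maternal_mismatch(juvenile.calls[l], mother.calls[l]) for l in shared
    )
    if len(shared) < 6:
        return False
    if n_mm > 2:
        return False
    if len(shared) == 6 and n_mm > 1:
        return False
    return True


def oracle_mismatch_count(juvenile, mother, candidate, loci):
    """(n_comparable, n_mismatch) for one candidate, by exhaustive
    per-locus enumeration."""
    n_comp = 0
    n_mis = 0
    for l in loci:
        if l not in juvenile.calls or l not in mother.calls or l not in candidate.calls:
            continue
        n_comp += 1
        options = oracle_possible_paternal(juvenile.calls[l], mother.calls[l])
        if not (set(candidate.calls[l]) & options):
            n_mis += 1
    return n_comp, n_mis


def oracle_assign(juvenile, mother, candidates, loci, max_mismatch=2):
    """Full exclusion-based verdict by enumeration.  Candidates must
    include the mother.  Ties are reported as ambiguous (no likelihood
    tie-break in the oracle)."""
    if not oracle_inclusion(juvenile, mother, loci):
        return ("excluded", None, None)
    scored = []
    for cand in candidates:
        n_comp, n_mis = oracle_mismatch_count(juvenile, mother, cand, loci)
        if n_comp > 0:
            scored.append((n_mis, cand.individual_id))
    eligible = [(m, cid) for m, cid in scored if m <= max_mismatch]
    if not eligible:
        best = min((m for m, _ in scored), default=None)
        return ("unassigned", None, best)
    best = min(m for m, _ in eligible)
    winners = [cid for m, cid in eligible if m == best]
    if len(winners) > 1:
        return ("ambiguous", None, best)
    winner = winners[0]
    if winner == mother.individual_id:
        return ("selfed", None, best)
    return ("outcrossed", winner, best)


def random_parentage_instance(rng, max_candidates=10, max_loci=10):
    """A random family: mother, candidates (mother included), juvenile
    sired either by self, by a candidate, or unrelated, with random
    missingness so all verdict branches are exercised."""
    n_loci = int(rng.integers(6, max_loci + 1))
    n_alleles = int(rng.integers(2, 11))
    n_cands = int(rng.integers(1, max_candidates + 1))
    loci = [f"L{i:02d}" for i in range(n_loci)]

    def draw(ind_id, gen=Generation.F1, mother_id=None, missing_p=0.1):
        calls = {}
        for l in loci:
            if rng.random() < missing_p:
                continue
            calls[l] = (int(rng.integers(1, n_alleles + 1)), int(rng.integers(1, n_alleles + 1)))
        return MultilocusGenotype(ind_id, gen, mother_id, calls)

    mother = draw("MOM", missing_p=0.05)
    cands = [draw(f"C{i}") for i in range(n_cands)]
    mode = rng.integers(3)
    calls = {}
    for l in loci:
        if rng.random() < 0.1:
            continue
        m_call = mother.calls.get(l)
        if mode == 0 and m_call is not None:  # selfed
            calls[l] = (m_call[int(rng.integers(2))], m_call[int(rng.integers(2))])
        elif mode == 1 and m_call is not None and cands[0].calls.get(l):  # outcrossed
            s_call = cands[0].calls[l]
            calls[l] = (m_call[int(rng.integers(2))], s_call[int(rng.integers(2))])
        else:  # unrelated noise
            calls[l] = (int(rng.integers(1, n_alleles + 1)), int(rng.integers(1, n_alleles + 1)))
    juvenile = MultilocusGenotype("JUV", Generation.F2, "MOM", calls)
    return juvenile, mother, [mother] + cands, loci


# ---------------------------------------------------------------------------
# chi-square and Wilson closed-form oracles
# ---------------------------------------------------------------------------


def oracle_chi2(observed, yates=False):
    """Textbook Pearson statistic: sum((|O-E| - 0.5*yates)^2 / E)."""
    from scipy.stats import chi2 as chi2_dist

    obs = np.asarray(observed, dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(chi2_dist.sf(stat, df))


def oracle_wilson(k, n, level=0.95):
    from scipy.stats import norm

    z = norm.ppf(1 - (1 - level) / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half
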