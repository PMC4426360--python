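"""Mendelian-inheritance screening of array markers against F1 cohorts.

The screen asks, for every marker retained by QC, whether offspring genotype
frequencies in single-pair crosses match the Mendelian (Punnett) expectation
given the two parental genotypes.  Only *informative* loci — heterozygous in
exactly one parent, homozygous in the other — carry power under a 1:1
two-class expectation and enter the test.  Per-cohort goodness-of-fit
chi-square p values are combined across cohorts with Fisher's method and the
combined p values are step-down Holm-corrected across loci; loci whose
adjusted p falls at or below alpha are declared deviant and dropped from the
validated marker set.

Offspring genotypes that are impossible under the parental pair (an
observation in an expected-zero category, e.g. a BB offspring from AB x AA)
are flagged ``incompatible`` rather than folded into the statistic: they
signal a parental genotyping error or an off-target assay, not segregation
distortion, and are excluded from the chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AA, AB, BB, NOCALL, CrossCohort, GENOTYPE_STATES

__all__ = [
    "expected_offspring_dist",
    "informative_loci",
    "select_crosses",
    "chi2_gof",
    "fisher_combine",
    "holm_correct",
    "bonferroni_correct",
    "mendel_screen",
    "MendelResult",
    "MendelSummary",
    "CrossCohort",
]

_VALID_PARENT = {AA, AB, BB}

# Per-allele transmission probability of B for each parental genotype under
# fair segregation.
_TRANSMIT_B = {AA: 0.0, AB: 0.5, BB: 1.0}


def expected_offspring_dist(g_mother: int, g_father: int) -> np.ndarray:
    """Punnett expectation over offspring genotypes (AA, AB, BB).

    Parameters are genotype codes (``containers.AA`` etc.).  The result sums
    to 1 and is symmetric in the parents.
    """
    for g in (g_mother, g_father):
        if g not in _VALID_PARENT:
            raise ValueError(f"invalid parental genotype code {g!r}")
    bm = _TRANSMIT_B[g_mother]
    bf = _TRANSMIT_B[g_father]
    p_aa = (1 - bm) * (1 - bf)
    p_bb = bm * bf
    p_ab = 1.0 - p_aa - p_bb
    return np.array([p_aa, p_ab, p_bb])


def informative_loci(maternal: np.ndarray, paternal: np.ndarray) -> np.ndarray:
    """Boolean mask: loci with one heterozygous and one homozygous parent.

    Loci with a missing parental genotype are never informative.
    """
    m = np.asarray(maternal)
    f = np.asarray(paternal)
    het_m = m == AB
    het_f = f == AB
    hom_m = (m == AA) | (m == BB)
    hom_f = (f == AA) | (f == BB)
    return (het_m & hom_f) | (hom_m & het_f)


def select_crosses(
    candidate_crosses: dict[str, set] | dict[str, frozenset],
    k: int,
    exhaustive_limit: int = 15,
) -> list[str]:
    """Choose k crosses maximizing the union of informative loci.

    Greedy maximum-coverage with ties broken by cross id order; for small
    candidate sets (<= ``exhaustive_limit``) an exhaustive search over all
    size-k subsets is used, so the returned set is globally optimal there.
    """
    if not candidate_crosses:
        raise ValueError("no candidate crosses supplied")
    if k < 1 or k > len(candidate_crosses):
        raise ValueError(f"k={k} out of range for {len(candidate_crosses)} candidates")
    ids = sorted(candidate_crosses)
    sets = {cid: frozenset(candidate_crosses[cid]) for cid in ids}

    if len(ids) <= exhaustive_limit:
        from itertools import combinations

        best: tuple[int, tuple[str, ...]] | None = None
        for combo in combinations(ids, k):
            covered = len(frozenset().union(*(sets[c] for c in combo)))
            key = (-covered, combo)
            if best is None or key < best:
                best = key
        assert best is not None
        return list(best[1])

    chosen: list[str] = []
    covered: set = set()
    remaining = list(ids)
    for _ in range(k):
        gains = [(-len(sets[c] - covered), c) for c in remaining]
        gains.sort()
        _, pick = gains[0]
        chosen.append(pick)
        covered |= sets[pick]
        remaining.remove(pick)
    return chosen


def chi2_gof(
    observed: np.ndarray, expected_dist: np.ndarray
) -> tuple[float, int, float] | str:
    """Goodness-of-fit chi-square of offspring counts against an expectation.

    Categories with expected probability zero are excluded; an observation in
    such a category returns the string flag ``"incompatible"`` instead of a
    statistic.  Returns ``(statistic, df, p)`` otherwise.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected_dist, dtype=float)
    n = obs.sum()
    if n < 1:
        raise ValueError("cohort empty after removing no-calls")
    support = exp > 0
    if np.any(obs[~support] > 0):
        return "incompatible"
    obs = obs[support]
    exp_counts = exp[support] * n
    df = int(support.sum()) - 1
    if df == 0:
        return (0.0, 0, 1.0)
    stat = float(((obs - exp_counts) ** 2 / exp_counts).sum())
    p = float(stats.chi2.sf(stat, df))
    return (stat, df, p)


def fisher_combine(p_values) -> float:
    """Fisher's method: X = -2 sum ln p ~ chi-square with 2k df.

    A single p value is returned unchanged; a zero input propagates to a
    combined p of 0 with a warning (log singularity).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one p value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p value combined: result is exactly 0", RuntimeWarning)
        return 0.0
    if p.size == 1:
        return float(p[0])
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))


def holm_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Sequential Bonferroni-Holm step-down adjustment.

    Returns (adjusted p, reject flags); adjusted p values are monotone
    (cumulative max in sorted order), capped at 1, and a hypothesis is
    rejected iff its adjusted p <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


def bonferroni_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Plain Bonferroni adjustment (p * m, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    adjusted = np.minimum(p * p.size, 1.0)
    return adjusted, adjusted <= alpha


@dataclass
class MendelResult:
    """Per-locus outcome of the Mendelian screen."""

    table: pd.DataFrame  # one row per locus


@dataclass
class MendelSummary:
    testable: int
    deviant: int
    incompatible: int
    untestable: int
    retained_loci: list[str]

    def as_dict(self) -> dict:
        return {
            "testable": self.testable,
            "deviant": self.deviant,
            "incompatible": self.incompatible,
            "untestable": self.untestable,
            "retained": len(self.retained_loci),
        }


def _cohort_tests(cohort: CrossCohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-locus chi-square for one cohort.

    Returns (p values with NaN where untested, incompatible mask,
    informative-and-tested mask).  Only informative loci are tested; the
    expectation there is 1:1 over two genotype classes whose identity depends
    on which homozygote the homozygous parent is.
    """
    info = informative_loci(cohort.maternal, cohort.paternal)
    counts = cohort.counts
    n = counts.sum(axis=1)

    p = np.full(len(cohort.locus_ids), np.nan)
    incompatible = np.zeros(len(cohort.locus_ids), dtype=bool)
    tested = np.zeros(len(cohort.locus_ids), dtype=bool)

    hom_parent = np.where(cohort.maternal == AB, cohort.paternal, cohort.maternal)
    # Expected classes: AB x AA -> {AA, AB}; AB x BB -> {AB, BB}.
    zero_col = np.where(hom_parent == AA, BB, AA)

    idx = np.flatnonzero(info & (n >= 1))
    if idx.size == 0:
        return p, incompatible, tested
    zc = zero_col[idx]
    obs_zero = counts[idx, zc]
    bad = obs_zero > 0
    incompatible[idx[bad]] = True

    ok = idx[~bad]
    if ok.size:
        cols = np.array([[0, 1], [1, 2]])  # classes for hom parent AA vs BB
        sel = cols[(hom_parent[ok] == BB).astype(int)]
        obs = np.take_along_axis(counts[ok], sel, axis=1).astype(float)
        n_ok = obs.sum(axis=1)
        exp = n_ok / 2.0
        stat = ((obs - exp[:, None]) ** 2 / exp[:, None]).sum(axis=1)
        p[ok] = stats.chi2.sf(stat, 1)
        tested[ok] = True
    return p, incompatible, tested


def mendel_screen(
    cohorts: list[CrossCohort],
    retained_loci: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[MendelResult, MendelSummary]:
    """Screen loci for Mendelian inheritance across one or more F1 cohorts.

    Each locus is tested in every cohort where it is informative; p values
    from two or more testable cohorts are Fisher-combined, a single testable
    cohort contributes its p directly.  Combined p values are Holm-corrected
    across all testable loci.  Verdicts: ``deviant`` (adjusted p <= alpha),
    ``incompatible`` (an impossible offspring genotype in any cohort),
    ``untestable`` (informative in no cohort, or no called offspring), else
    ``consistent``.  The retained set excludes deviant and incompatible loci.
    """
    if not cohorts:
        raise ValueError("no cohorts supplied")
    locus_ids = cohorts[0].locus_ids
    for c in cohorts[1:]:
        if c.locus_ids != locus_ids:
            raise ValueError("cohorts do not share a locus id set")
    if retained_loci is not None:
        retained_set = set(retained_loci)
        unknown = retained_set - set(locus_ids)
        if unknown:
            raise ValueError(f"retained loci absent from cohorts: {sorted(unknown)[:5]}")
        keep = np.array([lid in retained_set for lid in locus_ids])
    else:
        keep = np.ones(len(locus_ids), dtype=bool)

    n_loci = len(locus_ids)
    per_cohort_p = np.full((len(cohorts), n_loci), np.nan)
    incompat = np.zeros(n_loci, dtype=bool)
    for ci, cohort in enumerate(cohorts):
        p, inc, tested = _cohort_tests(cohort)
        per_cohort_p[ci] = p
        incompat |= inc
    per_cohort_p[:, ~keep] = np.nan
    incompat &= keep

    n_tested = np.sum(~np.isnan(per_cohort_p), axis=0)
    testable = keep & (n_tested > 0) & ~incompat

    combined = np.full(n_loci, np.nan)
    idx = np.flatnonzero(testable)
    if idx.size:
        logs = np.where(np.isnan(per_cohort_p[:, idx]), 0.0, np.log(per_cohort_p[:, idx]))
        k = n_tested[idx]
        x = -2.0 * logs.sum(axis=0)
        combined[idx] = stats.chi2.sf(x, 2 * k)
        single = k == 1
        combined[idx[single]] = np.nanmax(per_cohort_p[:, idx[single]], axis=0)

    adjusted = np.full(n_loci, np.nan)
    if idx.size:
        adj, _ = holm_correct(combined[idx], alpha)
        adjusted[idx] = adj

    verdict = np.full(n_loci, "untestable", dtype=object)
    verdict[incompat] = "incompatible"
    verdict[testable & (adjusted <= alpha)] = "deviant"
    verdict[testable & (adjusted > alpha)] = "consistent"
    verdict[~keep] = "excluded"

    table = pd.DataFrame(
        {
            "locus": locus_ids,
            **{
                f"p_{c.cross_id}": per_cohort_p[ci]
                for ci, c in enumerate(cohorts)
            },
            "n_cohorts_tested": n_tested,
            "combined_p": combined,
            "adjusted_p": adjusted,
            "verdict": verdict,
        }
    ).set_index("locus")

    kept_ids = [
        lid
        for lid, v in zip(locus_ids, verdict)
        if v in ("consistent", "untestable")
    ]
    summary = MendelSummary(
        testable=int(testable.sum()),
        deviant=int(np.sum(verdict == "deviant")),
        incompatible=int(incompat.sum()),
        untestable=int(np.sum(verdict == "untestable")),
        retained_loci=kept_ids,
    )
    return MendelResult(table=table), summary
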