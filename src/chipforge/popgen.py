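"""Population-genetic characterization of validated markers.

Covers the four post-validation analyses of a chip study: pairwise linkage
disequilibrium as genotypic (dosage-correlation) r-squared, exact
Hardy-Weinberg testing with family-wise multiple-test correction,
relatedness via the unadjusted Ajk estimator, and principal-components
analysis of column-standardized dosages with optional balanced subsampling.

LD here is "composite" LD: the squared Pearson correlation between two
markers' B-allele dosage vectors over jointly called samples.  It needs no
phase information and equals the haplotype r-squared whenever phase is
unambiguous.  Note the estimator's small-sample bias: for n unrelated
individuals the expectation of r-squared between truly unlinked markers is
approximately 1/n, not 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from . import mendel
from .containers import DosageMatrix, GenotypeCallMatrix

__all__ = [
    "r2_dosage",
    "ld_scan",
    "LDScanResult",
    "hwe_test",
    "hwe_test_many",
    "HWEResult",
    "hwe_screen",
    "ajk_relatedness",
    "KinshipMatrix",
    "pca_genotypes",
    "PCAResult",
    "multiple_test_correct",
]


def _as_dosage(data) -> DosageMatrix:
    if isinstance(data, GenotypeCallMatrix):
        return data.to_dosage_matrix()
    if isinstance(data, DosageMatrix):
        return data
    raise TypeError("expected a DosageMatrix or GenotypeCallMatrix")


# ---------------------------------------------------------------------------
# linkage disequilibrium


def r2_dosage(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite r²).

    Computed over jointly called samples (dosage >= 0); symmetric and
    invariant to allele relabeling (x -> 2 - x).  Returns NaN when fewer
    than two joint samples remain or either vector is monomorphic among
    them (not computable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (x >= 0) & (y >= 0)
    if mask.sum() < 2:
        return float("nan")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(min(r * r, 1.0))


@dataclass
class LDScanResult:
    """All-pairs LD table plus the summaries a decay figure is built from."""

    pairs: pd.DataFrame  # marker_a, marker_b, same_contig, distance, r2
    mean_r2: float
    same_contig_mean: float
    cross_contig_mean: float
    median_perfect_ld_distance: float  # NaN when no same-contig r2 == 1 pair
    hist2d: pd.DataFrame  # distance-bin x r2-bin pair counts
    lowess_all: np.ndarray  # (points, 2): distance, smoothed r2
    lowess_high: np.ndarray  # same, restricted to r2 >= high_r2_cut
    n_samples: int


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """r² for every marker pair; NaN where not computable."""
    m, n = d.shape
    missing = d < 0
    if not missing.any():
        x = d.astype(float)
        z = x - x.mean(axis=1, keepdims=True)
        denom = np.sqrt((z**2).sum(axis=1))
        poly = denom > 0
        r2 = np.full((m, m), np.nan)
        if poly.sum() >= 2:
            zp = z[poly] / denom[poly][:, None]
            sub = np.minimum((zp @ zp.T) ** 2, 1.0)
            grid = np.ix_(poly, poly)
            r2[grid] = sub
        return r2
    r2 = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(i, m):
            r2[i, j] = r2[j, i] = r2_dosage(d[i], d[j])
    return r2


def ld_scan(
    data,
    distance_bin: int = 200,
    r2_bins: int = 20,
    high_r2_cut: float = 0.2,
    lowess_frac: float = 2.0 / 3.0,
) -> LDScanResult:
    """All-pairs genotypic r² with the standard decay summaries.

    Summaries: global / same-contig / cross-contig mean r²; a 2-D histogram
    of same-contig pairs over half-open physical-distance bins of
    ``distance_bin`` bp crossed with r² bins; LOWESS curves of r² against
    distance for all same-contig pairs and for the subset with
    r² >= ``high_r2_cut``; and the median distance among same-contig pairs
    in perfect LD (r² = 1), NaN when there are none.
    """
    dm = _as_dosage(data)
    if dm.n_markers < 2:
        raise ValueError("need at least two markers")
    r2 = _pairwise_r2(dm.dosages)
    iu, ju = np.triu_indices(dm.n_markers, k=1)
    r2_flat = r2[iu, ju]
    ok = ~np.isnan(r2_flat)
    iu, ju, r2_flat = iu[ok], ju[ok], r2_flat[ok]
    if r2_flat.size == 0:
        raise ValueError("no computable marker pairs (all monomorphic?)")
    same = dm.contigs[iu] == dm.contigs[ju]
    dist = np.where(same, np.abs(dm.positions[iu] - dm.positions[ju]), -1)

    pairs = pd.DataFrame(
        {
            "marker_a": np.asarray(dm.marker_ids, dtype=object)[iu],
            "marker_b": np.asarray(dm.marker_ids, dtype=object)[ju],
            "same_contig": same,
            "distance": dist,
            "r2": r2_flat,
        }
    )

    mean_r2 = float(r2_flat.mean())
    same_mean = float(r2_flat[same].mean()) if same.any() else float("nan")
    cross_mean = float(r2_flat[~same].mean()) if (~same).any() else float("nan")

    perfect = same & (r2_flat >= 1.0 - 1e-9)
    median_perfect = float(np.median(dist[perfect])) if perfect.any() else float("nan")

    if same.any():
        d_same = dist[same]
        r_same = r2_flat[same]
        max_bin = int(d_same.max() // distance_bin) + 1
        d_edges = np.arange(0, (max_bin + 1) * distance_bin, distance_bin)
        r_edges = np.linspace(0, 1, r2_bins + 1)
        h, _, _ = np.histogram2d(d_same, np.clip(r_same, 0, 1 - 1e-12), bins=[d_edges, r_edges])
        hist2d = pd.DataFrame(
            h.astype(int),
            index=pd.Index(d_edges[:-1], name="distance_bin_start"),
            columns=pd.Index(np.round(r_edges[:-1], 3), name="r2_bin_start"),
        )
        lowess_all = _sm_lowess(r_same, d_same, frac=lowess_frac)
        high = r_same >= high_r2_cut
        lowess_high = (
            _sm_lowess(r_same[high], d_same[high], frac=lowess_frac)
            if high.sum() >= 2
            else np.empty((0, 2))
        )
    else:
        hist2d = pd.DataFrame()
        lowess_all = np.empty((0, 2))
        lowess_high = np.empty((0, 2))

    return LDScanResult(
        pairs=pairs,
        mean_r2=mean_r2,
        same_contig_mean=same_mean,
        cross_contig_mean=cross_mean,
        median_perfect_ld_distance=median_perfect,
        hist2d=hist2d,
        lowess_all=np.asarray(lowess_all),
        lowess_high=np.asarray(lowess_high),
        n_samples=dm.n_samples,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg


@lru_cache(maxsize=None)
def _hwe_het_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count given allele counts.

    Conditioning on n diploids carrying n_a copies of allele A (n_b = 2n -
    n_a), the heterozygote count ranges over values with the parity of n_a;
    probabilities follow the standard conditional (Levene) distribution.
    Returns (het_counts, probabilities).
    """
    n_b = 2 * n - n_a
    het_max = min(n_a, n_b)
    hets = np.arange(n_a % 2, het_max + 1, 2)
    n_aa = (n_a - hets) // 2
    n_bb = (n_b - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp)
    p /= p.sum()  # guard against accumulated rounding
    return hets, p


def hwe_test(n_aa: int, n_ab: int, n_bb: int, mode: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p value for one marker's genotype counts.

    ``exact`` (default) is the conditional exact test: the p value sums, over
    heterozygote counts compatible with the observed allele counts, the
    probabilities no larger than that of the observed table.  ``chisq`` is
    the 1-df goodness-of-fit alternative.  Monomorphic markers return 1.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    if mode == "exact":
        hets, probs = _hwe_het_distribution(n, n_a)
        p_obs = probs[np.searchsorted(hets, n_ab)]
        return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
    if mode == "chisq":
        p = n_a / (2.0 * n)
        expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2])
        stat = ((np.array([n_aa, n_ab, n_bb]) - expected) ** 2 / expected).sum()
        return float(stats.chi2.sf(stat, 1))
    raise ValueError(f"unknown HWE mode {mode!r}")


def hwe_test_many(counts: np.ndarray, mode: str = "exact") -> np.ndarray:
    """Vectorized ``hwe_test`` over an (L, 3) genotype-count array."""
    counts = np.asarray(counts, dtype=int)
    return np.array([hwe_test(*row, mode=mode) for row in counts])


@dataclass
class HWEResult:
    table: pd.DataFrame  # marker, n_aa, n_ab, n_bb, p, adjusted_p, deviant
    n_deviant: int


def hwe_screen(
    data,
    alpha: float = 0.05,
    mode: str = "exact",
    method: str = "holm",
) -> HWEResult:
    """Per-marker HWE test with family-wise multiple-test correction."""
    dm = _as_dosage(data)
    d = dm.dosages
    n_aa = (d == 0).sum(axis=1)
    n_ab = (d == 1).sum(axis=1)
    n_bb = (d == 2).sum(axis=1)
    counts = np.stack([n_aa, n_ab, n_bb], axis=1)
    p = hwe_test_many(counts, mode=mode)
    adjusted, reject = multiple_test_correct(p, method=method, alpha=alpha)
    table = pd.DataFrame(
        {
            "marker": dm.marker_ids,
            "n_aa": n_aa,
            "n_ab": n_ab,
            "n_bb": n_bb,
            "p": p,
            "adjusted_p": adjusted,
            "deviant": reject,
        }
    ).set_index("marker")
    return HWEResult(table=table, n_deviant=int(reject.sum()))


# ---------------------------------------------------------------------------
# relatedness


@dataclass
class KinshipMatrix:
    values: np.ndarray  # (S, S) symmetric
    sample_ids: list[str]
    n_markers_used: int
    n_markers_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def ajk_relatedness(data, allele_freqs: np.ndarray | None = None) -> KinshipMatrix:
    """Unadjusted Ajk relatedness from allele-frequency-standardized dosages.

    Off-diagonal:  A_jk = (1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    Diagonal:      A_jj = 1 + (1/N) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2)
                                          / (2 p_i (1 - p_i))

    p_i defaults to the sample B-allele frequency; pass ``allele_freqs`` to
    standardize by external reference frequencies instead.  Note the sample-
    frequency convention centres each marker on the very samples scored, so
    off-diagonals of unrelated pairs average -1/(n-1) rather than 0; with
    true reference frequencies the unrelated expectation is 0.  Markers fixed
    at p in {0, 1} are excluded (their standardization is undefined) and the
    exclusion count is reported.  Missing calls are handled pairwise: each
    pair's sum runs over the markers called in both samples.
    """
    dm = _as_dosage(data)
    x = dm.dosages.astype(float)
    called = x >= 0
    p = dm.allele_freq() if allele_freqs is None else np.asarray(allele_freqs, float)
    if p.shape[0] != dm.n_markers:
        raise ValueError("allele_freqs length does not match marker count")
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    n_excluded = int((~usable).sum())
    if usable.sum() == 0:
        raise ValueError("no polymorphic markers for relatedness")
    x = x[usable]
    called = called[usable]
    p = p[usable][:, None]

    denom = 2.0 * p * (1.0 - p)
    y = np.where(called, (x - 2.0 * p), 0.0) / np.sqrt(denom)
    w = called.astype(float)
    num = y.T @ y
    cnt = w.T @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        a = num / cnt

    diag_term = np.where(called, x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p, 0.0) / denom
    diag_cnt = called.sum(axis=0)
    diag = 1.0 + diag_term.sum(axis=0) / diag_cnt
    np.fill_diagonal(a, diag)
    return KinshipMatrix(
        values=a,
        sample_ids=list(dm.sample_ids),
        n_markers_used=int(usable.sum()),
        n_markers_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    populations: np.ndarray | None
    n_markers_used: int


def pca_genotypes(
    data,
    populations: np.ndarray | None = None,
    subsample_plan: dict[str, int] | None = None,
    seed: int = 0,
    n_components: int = 10,
) -> PCAResult:
    """PCA of column-standardized genotype dosages.

    Markers are centered and scaled to unit variance (zero-variance markers
    dropped); scores come from a singular-value decomposition of the
    standardized samples x markers matrix.  ``subsample_plan`` maps a
    population label to a target sample count and is applied — as a seeded
    uniform draw without replacement — before the decomposition, to keep an
    oversampled population from dominating the axes.  Missing dosages are
    mean-imputed per marker.
    """
    from sklearn.decomposition import PCA

    dm = _as_dosage(data)
    if populations is None and isinstance(data, GenotypeCallMatrix):
        populations = data.populations
    keep = np.arange(dm.n_samples)
    if subsample_plan:
        if populations is None:
            raise ValueError("subsampling requires population labels")
        rng = np.random.default_rng(seed)
        keep_parts = []
        pops = np.asarray(populations, dtype=object)
        for pop in pd.unique(pops):
            idx = np.flatnonzero(pops == pop)
            target = subsample_plan.get(str(pop), idx.size)
            if target > idx.size:
                raise ValueError(
                    f"subsample target {target} exceeds population {pop} size {idx.size}"
                )
            keep_parts.append(np.sort(rng.choice(idx, size=target, replace=False)))
        keep = np.concatenate(keep_parts)
    if keep.size < 2:
        raise ValueError("need at least two samples")

    x = dm.dosages[:, keep].astype(float).T  # samples x markers
    miss = x < 0
    if miss.any():
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, x).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
        x = np.where(miss, col_mean[None, :], x)
    sd = x.std(axis=0)
    poly = sd > 0
    if poly.sum() < 2:
        raise ValueError("need at least two polymorphic markers")
    x = (x[:, poly] - x[:, poly].mean(axis=0)) / sd[poly]

    k = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    sample_ids = [dm.sample_ids[i] for i in keep]
    return PCAResult(
        scores=pd.DataFrame(
            scores, index=sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        populations=None if populations is None else np.asarray(populations, object)[keep],
        n_markers_used=int(poly.sum()),
    )


# ---------------------------------------------------------------------------
# multiple testing


def multiple_test_correct(
    p_values, method: str = "holm", alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Family-wise correction of a p-value family: (adjusted p, reject flags)."""
    if method == "holm":
        return mendel.holm_correct(p_values, alpha)
    if method == "bonferroni":
        return mendel.bonferroni_correct(p_values, alpha)
    raise ValueError(f"unknown correction method {method!r}")
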