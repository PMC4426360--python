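"""Post-genotyping marker quality control.

Each genotyped marker is assigned exactly one QC class, mirroring the ledger
an array-genotyping study reports after calling: markers showing all three
genotype classes, markers lacking the minor-allele homozygote, monomorphic
markers, markers with evidence of a third allele or duplicated locus
(off-target variant), markers below the call-rate threshold, and low-quality
markers.  Only the first two classes — the markers whose biallelic call
model is both working and informative — are retained for the Mendelian
screen.

Class precedence puts data-quality failures before biological classes
(LowQuality, then LowCallRate, then MultiAllele, then Monomorphic /
NoMinorHom / AllGenotypes), so e.g. a low-call-rate monomorphic marker is
accounted as LowCallRate and the classes partition the marker set.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .containers import AA, AB, BB, NOCALL, GenotypeCallMatrix

__all__ = [
    "MarkerClass",
    "QCLedger",
    "call_rate",
    "detect_offtarget",
    "classify_marker",
    "classify_all",
    "build_ledger",
]


class MarkerClass(str, Enum):
    ALL_GENOTYPES = "AllGenotypes"
    NO_MINOR_HOM = "NoMinorHom"
    MONOMORPHIC = "Monomorphic"
    MULTI_ALLELE = "MultiAllele"
    LOW_CALL_RATE = "LowCallRate"
    LOW_QUALITY = "LowQuality"


RETAINED_CLASSES = (MarkerClass.ALL_GENOTYPES, MarkerClass.NO_MINOR_HOM)


def call_rate(calls: np.ndarray) -> float:
    """Fraction of samples with a genotype call at one marker."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("call rate undefined for zero samples")
    return float(np.mean(calls != NOCALL))


def detect_offtarget(
    signal_a: np.ndarray | None,
    signal_b: np.ndarray | None,
    contrast_cutoff: float = 1.0,
    magnitude_ratio: float = 2.0,
    min_cluster: int = 2,
) -> tuple[bool, str]:
    """Heuristic off-target-variant (third allele / duplication) detector.

    Looks at samples in the heterozygote contrast region
    (|log2(signal_A / signal_B)| < ``contrast_cutoff``) and asks whether
    their signal magnitudes split into two groups whose means differ by more
    than ``magnitude_ratio``; a genuine het cluster is a single magnitude
    group, while a third allele or a duplicated locus produces a second,
    displaced cluster.  Markers without intensities are not evaluable and
    return False with a note.
    """
    if signal_a is None or signal_b is None:
        return False, "not evaluable: no intensities"
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("intensities must be non-negative")
    with np.errstate(divide="ignore"):
        contrast = np.log2(np.maximum(a, 1e-12) / np.maximum(b, 1e-12))
    het_region = np.abs(contrast) < contrast_cutoff
    mags = np.sort((a[het_region] + b[het_region]) / 2.0)
    if mags.size < 2 * min_cluster:
        return False, "too few het-region samples"
    # best 1-D two-group split by within-group sum of squares
    best = None
    for cut in range(min_cluster, mags.size - min_cluster + 1):
        lo, hi = mags[:cut], mags[cut:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or ss < best[0]:
            best = (ss, lo.mean(), hi.mean())
    assert best is not None
    _, lo_mean, hi_mean = best
    if lo_mean <= 0:
        return True, "zero-magnitude cluster"
    if hi_mean / lo_mean >= magnitude_ratio:
        return True, f"magnitude split {hi_mean / lo_mean:.2f}x"
    return False, "single magnitude cluster"


def _genotype_class(calls: np.ndarray) -> MarkerClass:
    """Biological class from called genotypes (quality issues handled upstream)."""
    observed = set(np.unique(calls[calls != NOCALL]).tolist())
    if observed == {AA, AB, BB}:
        return MarkerClass.ALL_GENOTYPES
    if observed in ({AA, AB}, {AB, BB}):
        return MarkerClass.NO_MINOR_HOM
    if len(observed) == 1 and AB not in observed:
        return MarkerClass.MONOMORPHIC
    # residual shapes ({AA, BB} with no hets, or hets only) violate the
    # biallelic cluster model without matching a named class; they land in
    # the catch-all low-quality bucket
    return MarkerClass.LOW_QUALITY


def classify_marker(
    calls: np.ndarray,
    signal_a: np.ndarray | None = None,
    signal_b: np.ndarray | None = None,
    quality: float | None = None,
    call_threshold: float = 0.95,
    quality_floor: float | None = None,
    offtarget_flag: bool | None = None,
    **offtarget_kwargs,
) -> MarkerClass:
    """Assign the single QC class of one marker.

    Precedence: LowQuality, LowCallRate, MultiAllele, then the biological
    classes from the observed genotype set.  ``offtarget_flag`` overrides the
    intensity heuristic when a third-allele call is supplied externally (the
    intensity-free mode).  A marker with no calls at all has call rate 0 and
    is LowCallRate.
    """
    calls = np.asarray(calls)
    if quality_floor is not None and quality is not None and quality < quality_floor:
        return MarkerClass.LOW_QUALITY
    if call_rate(calls) < call_threshold:
        return MarkerClass.LOW_CALL_RATE
    if offtarget_flag is None:
        offtarget_flag, _ = detect_offtarget(signal_a, signal_b, **offtarget_kwargs)
    if offtarget_flag:
        return MarkerClass.MULTI_ALLELE
    return _genotype_class(calls)


def classify_all(
    matrix: GenotypeCallMatrix,
    call_threshold: float = 0.95,
    quality_floor: float | None = None,
    offtarget_flags: np.ndarray | None = None,
    **offtarget_kwargs,
) -> pd.Series:
    """QC class per marker of a call matrix (index = marker id)."""
    out = []
    for i in range(matrix.n_markers):
        sa = matrix.intensity_a[i] if matrix.intensity_a is not None else None
        sb = matrix.intensity_b[i] if matrix.intensity_b is not None else None
        q = float(matrix.quality[i]) if matrix.quality is not None else None
        flag = None if offtarget_flags is None else bool(offtarget_flags[i])
        out.append(
            classify_marker(
                matrix.calls[i],
                sa,
                sb,
                quality=q,
                call_threshold=call_threshold,
                quality_floor=quality_floor,
                offtarget_flag=flag,
                **offtarget_kwargs,
            ).value
        )
    return pd.Series(out, index=matrix.marker_ids, name="qc_class")


@dataclass
class QCLedger:
    """Per-class marker counts, percentages, and the retained marker set."""

    counts: dict[str, int]
    retained_ids: list[str]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        t = self.total
        return {k: 100.0 * v / t for k, v in self.counts.items()}

    @property
    def n_retained(self) -> int:
        return sum(self.counts.get(c.value, 0) for c in RETAINED_CLASSES)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": self.counts,
            "percentages": self.percentages,
            "retained": self.n_retained,
        }

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "QCLedger":
        """Ledger arithmetic on externally supplied per-class counts.

        Useful for auditing a published QC table: the retained count is the
        sum of the AllGenotypes and NoMinorHom classes.
        """
        known = {c.value for c in MarkerClass}
        unknown = set(counts) - known
        if unknown:
            raise ValueError(f"unknown marker classes: {sorted(unknown)}")
        return cls(counts=dict(counts), retained_ids=[])


def build_ledger(
    matrix: GenotypeCallMatrix,
    call_threshold: float = 0.95,
    quality_floor: float | None = None,
    offtarget_flags: np.ndarray | None = None,
    **offtarget_kwargs,
) -> tuple[QCLedger, pd.Series]:
    """Classify every marker and assemble the retention ledger.

    Returns the ledger plus the per-marker class series.  The retained set
    is AllGenotypes union NoMinorHom.
    """
    if matrix.n_markers == 0:
        raise ValueError("empty genotype matrix")
    classes = classify_all(
        matrix,
        call_threshold=call_threshold,
        quality_floor=quality_floor,
        offtarget_flags=offtarget_flags,
        **offtarget_kwargs,
    )
    counts = {c.value: int((classes == c.value).sum()) for c in MarkerClass}
    retained = [
        mid
        for mid, cls in classes.items()
        if cls in (MarkerClass.ALL_GENOTYPES.value, MarkerClass.NO_MINOR_HOM.value)
    ]
    return QCLedger(counts=counts, retained_ids=retained), classes
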