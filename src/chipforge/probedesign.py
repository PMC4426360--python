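"""Candidate-probe filtering and marker-spacing statistics.

Variant calls from two discovery tracks feed the chip design: an RNA-seq
track filtered on read depth, minor-allele frequency and the fraction of
reads supporting the two called alleles, and a RAD-seq track filtered on
depth, variant quality and per-sample missingness.  Survivors of either
track must additionally carry 35 bp of invariant flanking sequence on each
side — the hybridization probe is designed over the 71-mer centred on the
SNP, so any second variant inside it would corrupt the assay.  Filtered
candidates from all tracks are pooled (union over site identity, with
cross-track allele conflicts dropped as multiallelic) and ranked by a
pluggable scoring hook standing in for the proprietary array-design scorer.

All thresholds are inclusive at their printed boundary (depth 7 passes a
"minimum 7x" filter, ratio 0.85 passes a "less than 0.85 left out" filter),
and every excluded site records one primary reason — the first failing rule
in the documented order — alongside the full pass/fail vector, so filters
commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NOCALL

__all__ = [
    "VariantSite",
    "CandidateProbe",
    "FilterOutcome",
    "filter_rna_track",
    "filter_rad_track",
    "check_flank_invariance",
    "build_candidate_probes",
    "pool_candidates",
    "PoolResult",
    "rank_candidates",
    "default_gc_hook",
    "spacing_stats",
    "SpacingStats",
    "RNA_RULES",
    "RAD_RULES",
]


@dataclass
class VariantSite:
    """One biallelic candidate site with read support and optional genotypes."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int = 0
    ref_reads: int = 0
    alt_reads: int = 0
    other_reads: int = 0
    qual: float = 0.0
    genotypes: np.ndarray | None = None  # per-sample codes, NOCALL allowed

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.contig}:{self.pos}: ref equals alt")
        if self.ref_reads + self.alt_reads + self.other_reads > self.depth:
            raise ValueError(f"{self.contig}:{self.pos}: allele reads exceed depth")
        if min(self.depth, self.ref_reads, self.alt_reads, self.other_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.qual < 0:
            raise ValueError("variant quality must be non-negative")
        if self.genotypes is not None:
            self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def minor_allele_freq(self) -> float:
        """MAF in [0, 0.5], from called genotypes when available, else reads.

        Genotype-based: alternate-allele dosage over called samples, folded.
        Read-based fallback (pooled-sample discovery data carries no per-
        sample calls): alt reads over ref+alt reads, folded.
        """
        if self.genotypes is not None:
            called = self.genotypes[self.genotypes != NOCALL]
            if called.size:
                freq = called.sum() / (2.0 * called.size)
                return float(min(freq, 1.0 - freq))
        biallelic = self.ref_reads + self.alt_reads
        if biallelic == 0:
            return 0.0
        freq = self.alt_reads / biallelic
        return float(min(freq, 1.0 - freq))

    @property
    def allele_ratio(self) -> float:
        """Fraction of all reads at the site carrying either called allele."""
        if self.depth == 0:
            return 0.0
        return (self.ref_reads + self.alt_reads) / self.depth

    @property
    def missing_fraction(self) -> float:
        if self.genotypes is None or self.genotypes.size == 0:
            return 1.0
        return float(np.mean(self.genotypes == NOCALL))


@dataclass
class FilterOutcome:
    """Per-site filter verdicts: retained sites and labelled exclusions."""

    retained: list[VariantSite]
    excluded: list[tuple[VariantSite, str, dict[str, bool]]]  # site, primary reason, votes

    @property
    def n_in(self) -> int:
        return len(self.retained) + len(self.excluded)

    def exclusion_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason, _ in self.excluded:
            out[reason] = out.get(reason, 0) + 1
        return out


RNA_RULES = ("depth", "maf", "allele_ratio")
RAD_RULES = ("depth", "quality", "missingness")


def _apply_rules(
    sites: Sequence[VariantSite],
    rules: Sequence[tuple[str, Callable[[VariantSite], bool]]],
    special_reason: Callable[[VariantSite, str], str] | None = None,
) -> FilterOutcome:
    retained: list[VariantSite] = []
    excluded: list[tuple[VariantSite, str, dict[str, bool]]] = []
    for site in sites:
        votes = {name: bool(rule(site)) for name, rule in rules}
        if all(votes.values()):
            retained.append(site)
        else:
            primary = next(name for name, ok in votes.items() if not ok)
            if special_reason is not None:
                primary = special_reason(site, primary)
            excluded.append((site, primary, votes))
    return FilterOutcome(retained=retained, excluded=excluded)


def filter_rna_track(
    sites: Sequence[VariantSite],
    min_depth: int = 7,
    min_maf: float = 0.2,
    min_allele_ratio: float = 0.85,
) -> FilterOutcome:
    """RNA-seq discovery filter: depth >= 7, MAF >= 0.2, allele ratio >= 0.85.

    The allele ratio is the fraction of all reads covering the site that
    carry the called reference or alternate allele; a low ratio marks a
    multiallelic or repetitive site.  A zero-depth site is excluded with
    reason ``no_coverage``.
    """
    rules = [
        ("depth", lambda s: s.depth >= min_depth),
        ("maf", lambda s: s.minor_allele_freq >= min_maf),
        ("allele_ratio", lambda s: s.allele_ratio >= min_allele_ratio),
    ]

    def special(site: VariantSite, primary: str) -> str:
        return "no_coverage" if site.depth == 0 else primary

    return _apply_rules(sites, rules, special)


def filter_rad_track(
    sites: Sequence[VariantSite],
    min_depth: int = 7,
    min_qual: float = 25.0,
    max_missing: float = 0.20,
) -> FilterOutcome:
    """RAD-seq discovery filter: depth >= 7, phred quality >= 25, missing <= 20%.

    A site with no genotypes at all counts as fully missing and is excluded
    with reason ``missingness``.
    """
    rules = [
        ("depth", lambda s: s.depth >= min_depth),
        ("quality", lambda s: s.qual >= min_qual),
        ("missingness", lambda s: s.missing_fraction <= max_missing),
    ]
    return _apply_rules(sites, rules)


def check_flank_invariance(
    contig: str,
    pos: int,
    variant_index: Mapping[str, np.ndarray],
    contig_lengths: Mapping[str, int],
    window: int = 35,
) -> bool:
    """True iff ``window`` bp on each side of the site are variant-free and
    lie fully within the contig.

    ``variant_index`` maps contig -> sorted 1-based positions of *all* known
    variants (the site itself must be present, otherwise the index is stale
    and the call is rejected).
    """
    positions = np.asarray(variant_index[contig])
    i = np.searchsorted(positions, pos)
    if i >= positions.size or positions[i] != pos:
        raise ValueError(f"{contig}:{pos} missing from the variant index")
    if pos - window < 1 or pos + window > contig_lengths[contig]:
        return False
    left_ok = i == 0 or positions[i - 1] < pos - window
    right_ok = i == positions.size - 1 or positions[i + 1] > pos + window
    return bool(left_ok and right_ok)


@dataclass
class CandidateProbe:
    """A surviving site plus the probe 71-mer's two invariant flanks."""

    site: VariantSite
    flank_left: str
    flank_right: str
    filters_passed: dict[str, bool] = field(default_factory=dict)
    provenance: set[str] = field(default_factory=set)

    @property
    def seventy_one_mer(self) -> str:
        return self.flank_left + self.site.ref + self.flank_right


def build_candidate_probes(
    sites: Sequence[VariantSite],
    sequences: Mapping[str, str],
    variant_index: Mapping[str, np.ndarray],
    window: int = 35,
    track: str = "unknown",
) -> tuple[list[CandidateProbe], list[VariantSite]]:
    """Attach flanks to sites passing the flank-invariance check.

    Returns (probes, flank-failures).
    """
    lengths = {name: len(seq) for name, seq in sequences.items()}
    probes: list[CandidateProbe] = []
    failed: list[VariantSite] = []
    for site in sites:
        if not check_flank_invariance(site.contig, site.pos, variant_index, lengths, window):
            failed.append(site)
            continue
        seq = sequences[site.contig]
        left = seq[site.pos - 1 - window : site.pos - 1]
        right = seq[site.pos : site.pos + window]
        probes.append(
            CandidateProbe(
                site=site,
                flank_left=left,
                flank_right=right,
                filters_passed={"flank": True},
                provenance={track},
            )
        )
    return probes, failed


@dataclass
class PoolResult:
    candidates: list[CandidateProbe]
    conflicts: list[tuple[str, int]]  # positions excluded for allele conflicts


def pool_candidates(*track_outputs: tuple[str, Sequence[CandidateProbe]]) -> PoolResult:
    """Union candidate probes across tracks, keyed on (contig, pos, ref, alt).

    The same site found by several tracks becomes one candidate carrying all
    provenance tags.  Two tracks calling *different* alleles at one position
    are a multiallelic conflict: every candidate at that position is dropped
    and the position logged.
    """
    by_key: dict[tuple, CandidateProbe] = {}
    keys_by_pos: dict[tuple[str, int], set] = {}
    for track, probes in track_outputs:
        for probe in probes:
            key = probe.site.key
            if key in by_key:
                by_key[key].provenance.add(track)
            else:
                merged = CandidateProbe(
                    site=probe.site,
                    flank_left=probe.flank_left,
                    flank_right=probe.flank_right,
                    filters_passed=dict(probe.filters_passed),
                    provenance=set(probe.provenance) | {track},
                )
                by_key[key] = merged
            keys_by_pos.setdefault((probe.site.contig, probe.site.pos), set()).add(key)
    conflicts = sorted(pos for pos, keys in keys_by_pos.items() if len(keys) > 1)
    conflict_pos = set(conflicts)
    candidates = [
        probe
        for key, probe in sorted(by_key.items(), key=lambda kv: kv[0])
        if (key[0], key[1]) not in conflict_pos
    ]
    return PoolResult(candidates=candidates, conflicts=conflicts)


def default_gc_hook(candidate: CandidateProbe) -> float:
    """Stand-in probe score: GC-content proximity of the 71-mer to 0.5.

    The commercial design pipeline scores probes on hybridization
    thermodynamics, self-hybridization and copy number; none of that is
    reproducible here, so the default hook prefers balanced base composition
    (higher is better, maximum 0 at GC = 0.5).
    """
    mer = candidate.seventy_one_mer.upper()
    if not mer:
        return -0.5
    gc = sum(base in "GC" for base in mer) / len(mer)
    return -abs(gc - 0.5)


def rank_candidates(
    candidates: Sequence[CandidateProbe],
    scoring_hook: Callable[[CandidateProbe], float] | None = None,
    k: int | None = None,
) -> list[CandidateProbe]:
    """Top-k candidates under the scoring hook (stable, deterministic).

    Ties (and a constant hook) preserve input order; ``k`` of None returns
    all, k <= 0 is rejected, k beyond the candidate count returns everything.
    """
    hook = scoring_hook or default_gc_hook
    if k is not None and k <= 0:
        raise ValueError("k must be positive")
    ranked = sorted(candidates, key=lambda c: -hook(c))  # sorted() is stable
    return ranked if k is None else ranked[: min(k, len(ranked))]


@dataclass
class SpacingStats:
    distances: np.ndarray
    contig_lengths_per_distance: np.ndarray
    mean_distance: float  # NaN when no contig holds >= 2 markers
    pearson_r: float | None  # None when not computable
    pearson_p: float | None
    contigs_covered: int
    n_markers: int


def spacing_stats(
    markers: Sequence[tuple[str, int]],
    contig_lengths: Mapping[str, int],
    all_pairs: bool = False,
) -> SpacingStats:
    """Inter-marker distances and the positional-bias correlation.

    Distances are adjacent-pair gaps between consecutive markers within each
    contig (``all_pairs`` switches to every within-contig pair); each
    distance is paired with its contig's length, and the Pearson correlation
    of distance against contig length measures positional bias.  With no
    contig holding two markers the mean is NaN and the correlation is None
    (not computable, distinct from zero).
    """
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    per_contig: dict[str, list[int]] = {}
    for contig, pos in markers:
        per_contig.setdefault(contig, []).append(int(pos))
    dists: list[int] = []
    lens: list[int] = []
    for contig, positions in per_contig.items():
        positions = sorted(positions)
        length = contig_lengths[contig]
        if len(positions) < 2:
            continue
        if all_pairs:
            gaps = [
                positions[j] - positions[i]
                for i in range(len(positions))
                for j in range(i + 1, len(positions))
            ]
        else:
            gaps = list(np.diff(positions))
        dists.extend(int(g) for g in gaps)
        lens.extend([length] * len(gaps))
    d = np.asarray(dists, dtype=float)
    l = np.asarray(lens, dtype=float)
    if d.size == 0:
        mean = float("nan")
        r = p = None
    else:
        mean = float(d.mean())
        if d.size >= 2 and np.ptp(d) > 0 and np.ptp(l) > 0:
            r_val, p_val = stats.pearsonr(d, l)
            r, p = float(r_val), float(p_val)
        elif d.size >= 2 and np.ptp(l) > 0 and np.ptp(d) == 0:
            r = p = None
        else:
            r = p = None
    return SpacingStats(
        distances=d,
        contig_lengths_per_distance=l,
        mean_distance=mean,
        pearson_r=r,
        pearson_p=p,
        contigs_covered=len(per_contig),
        n_markers=len(markers),
    )
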