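"""Seeded generators for every input the validation pipeline consumes.

The generators emulate, with known ground truth, the data a SNP-array design
and validation study produces: a fragmented reference assembly with known
variant positions, structured diploid population samples, biallelic F1 cross
cohorts with controllable segregation distortion and genotyping error,
haplotype pools with distance-dependent linkage, per-site read-count tables
for the probe-filter stage, and genotype matrices with injected marker
defects for classifier benchmarking.

Every generator is deterministic under a fixed seed: all randomness flows
through one ``numpy.random.Generator`` derived from the supplied seed.

Model notes
-----------
* Population differentiation follows the Balding-Nichols construction:
  each population's drifted allele frequency is a Beta(p(1-F)/F, (1-p)(1-F)/F)
  draw around the ancestral frequency p with F = F_ST; F_ST = 0 is the
  no-drift limit (frequencies copied, no division by zero).
* Genotyping error is a symmetric single-step miscall: a homozygote is
  miscalled as the heterozygote; a heterozygote as either homozygote with
  equal probability.
* Linked genotypes come from a copying-with-recombination process over a
  fixed haplotype pool: each gamete is a mosaic of pool haplotypes with
  template switches occurring between adjacent sites with probability
  1 - exp(-rho * d) for inter-site distance d, giving association that
  decays (in expectation) exponentially with distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import mendel
from .containers import (
    AA,
    AB,
    BB,
    NOCALL,
    CrossCohort,
    GenotypeCallMatrix,
    decode_calls,
)

__all__ = [
    "SimulatedReference",
    "PopulationModel",
    "CrossSpec",
    "HaplotypePool",
    "ReadCountTable",
    "simulate_reference",
    "simulate_population",
    "simulate_cross",
    "random_haplotype_pool",
    "simulate_linked_genotypes",
    "simulate_read_counts",
    "inject_marker_defects",
    "DEFECT_CLASSES",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulatedReference:
    """A toy fragmented assembly: supercontig sequences + true variant sites."""

    supercontigs: list[tuple[str, str]]
    true_variant_positions: dict[str, np.ndarray]  # 1-based, sorted, unique

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.supercontigs}

    def all_sites(self) -> list[tuple[str, int]]:
        return [
            (name, int(pos))
            for name, _ in self.supercontigs
            for pos in self.true_variant_positions[name]
        ]


@dataclass
class PopulationModel:
    """Allele-frequency model for one or more drifted populations.

    ``ancestral_freqs`` are per-locus alternate-allele frequencies in (0, 1);
    ``fst`` controls differentiation among populations (Balding-Nichols);
    ``inbreeding`` is the within-population F applied to genotype draws.
    """

    ancestral_freqs: np.ndarray
    fst: float = 0.0
    n_populations: int = 1
    inbreeding: float | Sequence[float] = 0.0

    def __post_init__(self) -> None:
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        if np.any((self.ancestral_freqs <= 0) | (self.ancestral_freqs >= 1)):
            raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
        if not (0 <= self.fst < 1):
            raise ValueError("F_ST must lie in [0, 1)")
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        f = np.broadcast_to(np.asarray(self.inbreeding, float), (self.n_populations,))
        if np.any((f < 0) | (f > 1)):
            raise ValueError("inbreeding F must lie in [0, 1]")
        self._inbreeding = f

    def drifted_freqs(self, rng: np.random.Generator) -> np.ndarray:
        """(n_populations, n_loci) drifted frequencies, clipped away from 0/1."""
        p = self.ancestral_freqs
        if self.fst == 0.0:
            return np.tile(p, (self.n_populations, 1))
        ratio = (1.0 - self.fst) / self.fst
        a = p * ratio
        b = (1.0 - p) * ratio
        draws = rng.beta(a, b, size=(self.n_populations, p.size))
        # keep frequencies polymorphic so downstream statistics stay defined
        return np.clip(draws, 1e-12, 1 - 1e-12)


@dataclass
class CrossSpec:
    """A single-pair mating: parental genotypes and offspring-generation knobs.

    ``distortion`` is the per-locus probability that a heterozygous parent
    transmits the B allele (0.5 = fair segregation); ``error_rate`` and
    ``nocall_rate`` are per-call probabilities of a single-step miscall and
    of a missing call.
    """

    maternal: np.ndarray
    paternal: np.ndarray
    n_offspring: int
    distortion: float | np.ndarray = 0.5
    error_rate: float = 0.0
    nocall_rate: float = 0.0
    locus_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        valid = {AA, AB, BB}
        for name, arr in (("maternal", self.maternal), ("paternal", self.paternal)):
            if not set(np.unique(arr)).issubset(valid):
                raise ValueError(f"{name} genotypes must be AA/AB/BB codes")
        if self.maternal.shape != self.paternal.shape:
            raise ValueError("parental genotype vectors differ in length")
        if self.n_offspring < 1:
            raise ValueError("cohort size must be >= 1")
        d = np.broadcast_to(np.asarray(self.distortion, float), self.maternal.shape)
        if np.any((d < 0) | (d > 1)):
            raise ValueError("distortion must lie in [0, 1]")
        self._distortion = d
        for name, rate in (("error_rate", self.error_rate), ("nocall_rate", self.nocall_rate)):
            if not (0 <= rate <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.locus_ids is None:
            self.locus_ids = [f"L{i:05d}" for i in range(self.maternal.size)]


@dataclass
class HaplotypePool:
    """Per-contig haplotype sets with an effective recombination parameter.

    ``contigs`` maps contig name -> (positions, haplotypes) where positions
    is a sorted 1-based int array of S variant sites and haplotypes is an
    (H, S) binary matrix (H >= 2).  ``rho`` is the per-bp template-switch
    intensity of the copying process.
    """

    contigs: dict[str, tuple[np.ndarray, np.ndarray]]
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("recombination parameter must be >= 0")
        for name, (pos, hap) in self.contigs.items():
            pos = np.asarray(pos, dtype=np.int64)
            hap = np.asarray(hap, dtype=np.int8)
            if hap.ndim != 2 or hap.shape[1] != pos.size:
                raise ValueError(f"contig {name}: haplotype/position shape mismatch")
            if hap.shape[0] < 2:
                raise ValueError(f"contig {name}: pool needs >= 2 haplotypes")
            if not set(np.unique(hap)).issubset({0, 1}):
                raise ValueError(f"contig {name}: haplotype entries must be 0/1")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"contig {name}: positions must be strictly increasing")
            self.contigs[name] = (pos, hap)


@dataclass
class ReadCountTable:
    """Per-site read support and genotype calls for the probe-filter stage."""

    table: pd.DataFrame  # contig, pos, ref, alt, depth, ref_reads, alt_reads,
    # other_reads, qual columns
    genotypes: np.ndarray  # (sites, samples) codes with NOCALL allowed
    sample_ids: list[str]


def simulate_reference(
    n_contigs: int,
    length_distribution,
    variant_density: float,
    seed: int,
    forced_variants: dict[str, Sequence[int]] | None = None,
) -> SimulatedReference:
    """Generate a fragmented reference with known variant positions.

    ``length_distribution`` is either an int (fixed length), a (low, high)
    tuple for uniform integer lengths, or a callable(rng) -> int.  Each base
    carries a variant independently with probability ``variant_density``;
    ``forced_variants`` places variants at exact positions on named contigs
    (in addition to density-driven ones).
    """
    if n_contigs < 1:
        raise ValueError("need at least one contig")
    if not (0 < variant_density < 1) and forced_variants is None:
        raise ValueError("variant density must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    contigs: list[tuple[str, str]] = []
    positions: dict[str, np.ndarray] = {}
    for i in range(n_contigs):
        name = f"ctg{i:04d}"
        if callable(length_distribution):
            length = int(length_distribution(rng))
        elif isinstance(length_distribution, (tuple, list)):
            low, high = length_distribution
            length = int(rng.integers(low, high + 1))
        else:
            length = int(length_distribution)
        if length <= 0:
            raise ValueError(f"contig {name}: non-positive length {length}")
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        if 0 < variant_density < 1:
            mask = rng.random(length) < variant_density
            pos = np.flatnonzero(mask) + 1  # 1-based
        else:
            pos = np.array([], dtype=np.int64)
        if forced_variants and name in forced_variants:
            forced = np.asarray(forced_variants[name], dtype=np.int64)
            if np.any((forced < 1) | (forced > length)):
                raise ValueError(f"forced variant outside contig {name}")
            pos = np.union1d(pos, forced)
        contigs.append((name, seq))
        positions[name] = np.asarray(pos, dtype=np.int64)
    return SimulatedReference(supercontigs=contigs, true_variant_positions=positions)


def _draw_genotypes(
    freqs: np.ndarray, n: int, inbreeding: float, rng: np.random.Generator
) -> np.ndarray:
    """HWE (optionally inbred) genotype draws: (loci, n) codes."""
    q = freqs[:, None]
    f = inbreeding
    p_bb = q * q + f * q * (1 - q)
    p_ab = 2 * q * (1 - q) * (1 - f)
    u = rng.random((freqs.size, n))
    geno = np.full((freqs.size, n), AA, dtype=np.int8)
    geno[u < p_bb + p_ab] = AB
    geno[u < p_bb] = BB
    return geno


def simulate_population(
    model: PopulationModel,
    n_individuals: int | Sequence[int],
    seed: int,
    contig: str = "sim",
    spacing: int = 1000,
) -> GenotypeCallMatrix:
    """Draw diploid genotypes for one or more drifted populations.

    ``n_individuals`` is a per-population count (scalar applies to all).
    With F = 0, genotypes at each locus are HWE draws from the population's
    drifted frequency.  Markers are laid out on one contig at ``spacing`` bp
    so positional code downstream has coordinates to work with.
    """
    rng = np.random.default_rng(seed)
    n_per = np.broadcast_to(np.asarray(n_individuals, int), (model.n_populations,))
    if np.any(n_per < 1):
        raise ValueError("each population needs at least one individual")
    freqs = model.drifted_freqs(rng)
    blocks = []
    labels = []
    sample_ids = []
    for pop in range(model.n_populations):
        g = _draw_genotypes(freqs[pop], int(n_per[pop]), model._inbreeding[pop], rng)
        blocks.append(g)
        labels.extend([f"pop{pop}"] * int(n_per[pop]))
        sample_ids.extend(f"pop{pop}_s{j:04d}" for j in range(int(n_per[pop])))
    calls = np.concatenate(blocks, axis=1)
    n_loci = model.ancestral_freqs.size
    return GenotypeCallMatrix(
        calls=calls,
        marker_ids=[f"M{i:05d}" for i in range(n_loci)],
        sample_ids=sample_ids,
        contigs=np.array([contig] * n_loci, dtype=object),
        positions=np.arange(1, n_loci + 1) * spacing,
        populations=np.array(labels, dtype=object),
    )


def _offspring_probs(gm: int, gf: int, d: float) -> np.ndarray:
    """Offspring genotype distribution under transmission bias d for hets."""
    tb = {AA: 0.0, AB: d, BB: 1.0}
    bm, bf = tb[gm], tb[gf]
    p_aa = (1 - bm) * (1 - bf)
    p_bb = bm * bf
    return np.array([p_aa, 1.0 - p_aa - p_bb, p_bb])


def simulate_cross(spec: CrossSpec, seed: int, cross_id: str = "cross") -> CrossCohort:
    """Generate one F1 cohort's per-locus offspring genotype counts.

    With fair segregation and no error, counts at each locus are a
    multinomial draw from the Punnett expectation
    (``mendel.expected_offspring_dist``).  Miscalls then redistribute counts
    by the single-step error model, and no-calls are removed at
    ``nocall_rate`` per call.
    """
    rng = np.random.default_rng(seed)
    n_loci = spec.maternal.size
    n = spec.n_offspring
    counts = np.zeros((n_loci, 3), dtype=np.int64)

    # group loci by (gm, gf, distortion) so multinomials vectorize
    keys = np.rec.fromarrays(
        [spec.maternal, spec.paternal, spec._distortion], names=["gm", "gf", "d"]
    )
    for k in np.unique(keys):
        idx = np.flatnonzero(keys == k)
        probs = _offspring_probs(int(k.gm), int(k.gf), float(k.d))
        counts[idx] = rng.multinomial(n, probs, size=idx.size)

    if spec.error_rate > 0:
        e = spec.error_rate
        new = np.zeros_like(counts)
        # AA -> AB, BB -> AB; AB -> AA or BB with e/2 each
        for g in (AA, BB):
            flips = rng.binomial(counts[:, g], e)
            new[:, g] += counts[:, g] - flips
            new[:, AB] += flips
        to_hom = rng.binomial(counts[:, AB], e)
        to_aa = rng.binomial(to_hom, 0.5)
        new[:, AB] += counts[:, AB] - to_hom
        new[:, AA] += to_aa
        new[:, BB] += to_hom - to_aa
        counts = new

    nocalls = np.zeros(n_loci, dtype=np.int64)
    if spec.nocall_rate > 0:
        for g in (AA, AB, BB):
            lost = rng.binomial(counts[:, g], spec.nocall_rate)
            counts[:, g] -= lost
            nocalls += lost

    return CrossCohort(
        cross_id=cross_id,
        locus_ids=list(spec.locus_ids),
        maternal=spec.maternal,
        paternal=spec.paternal,
        counts=counts,
        nocalls=nocalls,
        n_offspring=n,
    )


def random_haplotype_pool(
    n_contigs: int,
    sites_per_contig: int,
    contig_length: int,
    n_haplotypes: int,
    rho: float,
    seed: int,
    min_freq: float = 0.2,
) -> HaplotypePool:
    """Build a random haplotype pool with common variants on each contig."""
    if n_haplotypes < 2:
        raise ValueError("pool needs >= 2 haplotypes")
    rng = np.random.default_rng(seed)
    contigs = {}
    for i in range(n_contigs):
        pos = np.sort(
            rng.choice(np.arange(1, contig_length + 1), size=sites_per_contig, replace=False)
        )
        freqs = rng.uniform(min_freq, 1 - min_freq, size=sites_per_contig)
        hap = (rng.random((n_haplotypes, sites_per_contig)) < freqs).astype(np.int8)
        contigs[f"ctg{i:04d}"] = (pos, hap)
    return HaplotypePool(contigs=contigs, rho=rho)


def _mosaic_gametes(
    pos: np.ndarray, hap: np.ndarray, n_gametes: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Copy n_gametes mosaics from the pool: (n_gametes, S) binary."""
    n_hap, s = hap.shape
    templates = np.empty((n_gametes, s), dtype=np.int64)
    templates[:, 0] = rng.integers(0, n_hap, size=n_gametes)
    if s > 1:
        switch_p = 1.0 - np.exp(-rho * np.diff(pos))
        switches = rng.random((n_gametes, s - 1)) < switch_p[None, :]
        new_templates = rng.integers(0, n_hap, size=(n_gametes, s - 1))
        for j in range(1, s):
            templates[:, j] = np.where(
                switches[:, j - 1], new_templates[:, j - 1], templates[:, j - 1]
            )
    return hap[templates, np.arange(s)[None, :]]


def simulate_linked_genotypes(
    pool: HaplotypePool, n_individuals: int, seed: int
) -> GenotypeCallMatrix:
    """Form diplotypes by pairing independent mosaic gametes from the pool.

    Expected pairwise association decays monotonically (in expectation) with
    inter-site distance under the pool's recombination parameter; contigs are
    drawn independently, so cross-contig pairs recombine freely.  A contig
    whose pool is monomorphic at a site yields a monomorphic marker; callers
    can detect those through the allele-frequency view.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    all_calls = []
    marker_ids = []
    contig_col = []
    pos_col = []
    for name in sorted(pool.contigs):
        pos, hap = pool.contigs[name]
        g1 = _mosaic_gametes(pos, hap, n_individuals, pool.rho, rng)
        g2 = _mosaic_gametes(pos, hap, n_individuals, pool.rho, rng)
        dosage = (g1 + g2).astype(np.int8).T  # (S, n)
        all_calls.append(dosage)
        marker_ids.extend(f"{name}_p{p}" for p in pos)
        contig_col.extend([name] * pos.size)
        pos_col.extend(pos.tolist())
    calls = np.concatenate(all_calls, axis=0)
    return GenotypeCallMatrix(
        calls=calls,
        marker_ids=marker_ids,
        sample_ids=[f"s{j:04d}" for j in range(n_individuals)],
        contigs=np.array(contig_col, dtype=object),
        positions=np.array(pos_col, dtype=np.int64),
    )


def simulate_read_counts(
    reference: SimulatedReference,
    n_samples: int,
    seed: int,
    mean_depth: float = 20.0,
    error_other: float = 0.01,
    missing_rate: float = 0.1,
    mean_qual: float = 40.0,
) -> ReadCountTable:
    """Per-site read-count table for the true variants of a reference.

    Depth is Poisson(mean_depth); site allele frequencies are uniform on
    (0.05, 0.5); ref/alt read splits are binomial at the allele frequency
    with a small ``error_other`` fraction of off-allele reads; variant
    quality is exponential around ``mean_qual``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    genos = []
    for contig, pos in [
        (name, p) for name, _ in reference.supercontigs
        for p in reference.true_variant_positions[name]
    ]:
        depth = int(rng.poisson(mean_depth))
        freq = rng.uniform(0.05, 0.5)
        other = int(rng.binomial(depth, error_other))
        alt = int(rng.binomial(depth - other, freq))
        ref = depth - other - alt
        qual = float(rng.exponential(mean_qual))
        ref_base, alt_base = rng.choice(_BASES, size=2, replace=False)
        rows.append(
            dict(
                contig=contig,
                pos=int(pos),
                ref=str(ref_base),
                alt=str(alt_base),
                depth=depth,
                ref_reads=ref,
                alt_reads=alt,
                other_reads=other,
                qual=qual,
            )
        )
        g = _draw_genotypes(np.array([freq]), n_samples, 0.0, rng)[0]
        miss = rng.random(n_samples) < missing_rate
        g[miss] = NOCALL
        genos.append(g)
    table = pd.DataFrame(rows)
    return ReadCountTable(
        table=table,
        genotypes=np.asarray(genos, dtype=np.int8),
        sample_ids=[f"s{j:03d}" for j in range(n_samples)],
    )


DEFECT_CLASSES = (
    "monomorphic",
    "no_minor_hom",
    "low_call_rate",
    "off_target",
    "low_quality",
)

# Intensity generation: a clean biallelic marker puts homozygotes at a high
# signal on one channel and background on the other, heterozygotes near
# equal mid signals.  An off-target (third allele / duplication) marker
# splits its het-contrast cluster into two magnitude groups.
_SIGNAL_HIGH = 2.0
_SIGNAL_LOW = 0.15
_SIGNAL_HET = 1.1
_SIGNAL_SD = 0.08
_OTV_FACTOR = 0.25


def _clean_intensities(
    calls: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    m, s = calls.shape
    a = rng.normal(_SIGNAL_LOW, _SIGNAL_SD / 2, size=(m, s))
    b = rng.normal(_SIGNAL_LOW, _SIGNAL_SD / 2, size=(m, s))
    a[calls == AA] = rng.normal(_SIGNAL_HIGH, _SIGNAL_SD, size=int((calls == AA).sum()))
    b[calls == BB] = rng.normal(_SIGNAL_HIGH, _SIGNAL_SD, size=int((calls == BB).sum()))
    het = calls == AB
    a[het] = rng.normal(_SIGNAL_HET, _SIGNAL_SD, size=int(het.sum()))
    b[het] = rng.normal(_SIGNAL_HET, _SIGNAL_SD, size=int(het.sum()))
    return np.abs(a), np.abs(b)


def inject_marker_defects(
    matrix: GenotypeCallMatrix,
    defect_plan: dict[str, int],
    seed: int,
    low_call_rate: float = 0.80,
    quality_floor: float = 0.5,
) -> tuple[GenotypeCallMatrix, pd.Series]:
    """Overwrite randomly chosen markers with known QC defects.

    ``defect_plan`` maps a defect class (see ``DEFECT_CLASSES``) to a marker
    count; assignments are disjoint (a plan larger than the matrix is
    rejected).  Returns the defected matrix (with synthesized channel
    intensities and per-marker quality scores) and a ground-truth class label
    per marker; markers left untouched are labelled ``all_genotypes`` when
    all three genotype classes are present, otherwise by their natural class.
    """
    unknown = set(defect_plan) - set(DEFECT_CLASSES)
    if unknown:
        raise ValueError(f"unknown defect classes: {sorted(unknown)}")
    total = sum(defect_plan.values())
    if total > matrix.n_markers:
        raise ValueError("defect plan assigns more markers than the matrix holds")
    rng = np.random.default_rng(seed)
    m, s = matrix.calls.shape
    calls = matrix.calls.copy()

    chosen = rng.choice(m, size=total, replace=False)
    labels = np.array(["clean"] * m, dtype=object)
    offset = 0
    assigned: dict[str, np.ndarray] = {}
    for cls in DEFECT_CLASSES:
        k = defect_plan.get(cls, 0)
        idx = chosen[offset : offset + k]
        assigned[cls] = idx
        labels[idx] = cls
        offset += k

    for i in assigned.get("monomorphic", []):
        calls[i, :] = AA
    for i in assigned.get("no_minor_hom", []):
        g = rng.choice([AA, AB], size=s, p=[0.6, 0.4]).astype(np.int8)
        if not np.any(g == AB):
            g[rng.integers(0, s)] = AB
        calls[i, :] = g
    for i in assigned.get("low_call_rate", []):
        n_nocall = s - int(round(low_call_rate * s))
        drop = rng.choice(s, size=n_nocall, replace=False)
        calls[i, drop] = NOCALL

    intensity_a, intensity_b = _clean_intensities(calls, rng)
    for i in assigned.get("off_target", []):
        # force a polymorphic biallelic-looking call set, then split the
        # het-contrast cluster into two magnitude groups
        g = rng.choice([AA, AB, BB], size=s, p=[0.35, 0.45, 0.2]).astype(np.int8)
        calls[i, :] = g
        a, b = _clean_intensities(g[None, :], rng)
        het_idx = np.flatnonzero(g == AB)
        low_group = het_idx[rng.random(het_idx.size) < 0.5]
        if low_group.size == 0 and het_idx.size:
            low_group = het_idx[:1]
        a[0, low_group] *= _OTV_FACTOR
        b[0, low_group] *= _OTV_FACTOR
        intensity_a[i], intensity_b[i] = a[0], b[0]

    quality = rng.uniform(quality_floor + 0.1, 1.0, size=m)
    lq = assigned.get("low_quality", np.array([], dtype=int))
    if lq.size:
        quality[lq] = rng.uniform(0.0, quality_floor * 0.9, size=lq.size)

    # natural labels for untouched markers (matches the QC class semantics)
    for i in np.flatnonzero(labels == "clean"):
        observed = set(calls[i][calls[i] != NOCALL].tolist())
        if observed == {AA, AB, BB}:
            labels[i] = "all_genotypes"
        elif observed in ({AA, AB}, {AB, BB}):
            labels[i] = "no_minor_hom"
        elif len(observed) <= 1 and AB not in observed:
            labels[i] = "monomorphic"
        else:
            labels[i] = "other"

    defected = GenotypeCallMatrix(
        calls=calls,
        marker_ids=list(matrix.marker_ids),
        sample_ids=list(matrix.sample_ids),
        contigs=matrix.contigs.copy(),
        positions=matrix.positions.copy(),
        intensity_a=intensity_a,
        intensity_b=intensity_b,
        quality=quality,
        populations=None if matrix.populations is None else matrix.populations.copy(),
    )
    truth = pd.Series(labels, index=matrix.marker_ids, name="true_class")
    return defected, truth
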