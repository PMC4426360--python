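"""Shared in-memory containers for genotype data.

Genotype calls are held as small integer codes throughout the package and
rendered as two-letter strings (``AA``/``AB``/``BB``/``NN``) only at file
boundaries.  A call is the unordered pair of alleles at a biallelic marker;
the dosage view counts copies of the B (alternate) allele, with ``-1``
marking a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# Integer genotype codes. NOCALL sorts first so that dosage arrays can be
# masked with `>= 0`.
NOCALL: int = -1
AA: int = 0
AB: int = 1
BB: int = 2

CODE_TO_STRING: Mapping[int, str] = {NOCALL: "NN", AA: "AA", AB: "AB", BB: "BB"}
STRING_TO_CODE: Mapping[str, int] = {v: k for k, v in CODE_TO_STRING.items()}

GENOTYPE_STATES: tuple[str, str, str] = ("AA", "AB", "BB")


def encode_calls(strings: np.ndarray | Sequence) -> np.ndarray:
    """Map an array of AA/AB/BB/NN strings to int8 codes."""
    arr = np.asarray(strings, dtype=object)
    out = np.empty(arr.shape, dtype=np.int8)
    flat_in = arr.ravel()
    flat_out = out.ravel()
    for i, value in enumerate(flat_in):
        try:
            flat_out[i] = STRING_TO_CODE[str(value)]
        except KeyError as exc:
            raise ValueError(f"unknown genotype call {value!r}") from exc
    return out


def decode_calls(codes: np.ndarray) -> np.ndarray:
    """Map int8 codes back to AA/AB/BB/NN strings."""
    codes = np.asarray(codes)
    lut = np.array(["NN", "AA", "AB", "BB"], dtype=object)
    return lut[codes + 1]


@dataclass
class GenotypeCallMatrix:
    """Markers x samples genotype calls with optional per-call intensities.

    Parameters
    ----------
    calls
        int8 array of shape (markers, samples) with codes in
        {NOCALL, AA, AB, BB}.
    marker_ids, sample_ids
        Row and column labels.
    contigs, positions
        Physical location of each marker (1-based positions).
    intensity_a, intensity_b
        Optional per-call summarized channel intensities (non-negative);
        either both present for every call or both absent.
    quality
        Optional per-marker quality score (higher is better).
    populations
        Optional per-sample population label.
    """

    calls: np.ndarray
    marker_ids: list[str]
    sample_ids: list[str]
    contigs: np.ndarray
    positions: np.ndarray
    intensity_a: np.ndarray | None = None
    intensity_b: np.ndarray | None = None
    quality: np.ndarray | None = None
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        m, s = self.calls.shape
        if len(self.marker_ids) != m or len(self.sample_ids) != s:
            raise ValueError("marker/sample id lengths do not match call matrix")
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.contigs.shape[0] != m or self.positions.shape[0] != m:
            raise ValueError("contig/position arrays do not match marker count")
        if (self.intensity_a is None) != (self.intensity_b is None):
            raise ValueError("intensity channels must be given together")
        for arr in (self.intensity_a, self.intensity_b):
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.calls.shape:
                    raise ValueError("intensity shape does not match call matrix")
                if np.any(arr < 0):
                    raise ValueError("intensities must be non-negative")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)
            if self.quality.shape[0] != m:
                raise ValueError("quality vector does not match marker count")
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
            if self.populations.shape[0] != s:
                raise ValueError("population labels do not match sample count")

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    @property
    def dosages(self) -> np.ndarray:
        """B-allele dosage view: 0/1/2 with -1 for missing (shares codes)."""
        return self.calls.astype(np.int8)

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of samples with a genotype call."""
        if self.n_samples == 0:
            raise ValueError("call rate undefined for zero samples")
        return (self.calls != NOCALL).mean(axis=1)

    def has_intensities(self) -> bool:
        return self.intensity_a is not None

    def subset_markers(self, index: np.ndarray | Sequence[int]) -> "GenotypeCallMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            calls=self.calls[index],
            marker_ids=[self.marker_ids[i] for i in index],
            contigs=self.contigs[index],
            positions=self.positions[index],
            intensity_a=None if self.intensity_a is None else self.intensity_a[index],
            intensity_b=None if self.intensity_b is None else self.intensity_b[index],
            quality=None if self.quality is None else self.quality[index],
        )

    def subset_samples(self, index: np.ndarray | Sequence[int]) -> "GenotypeCallMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            calls=self.calls[:, index],
            sample_ids=[self.sample_ids[i] for i in index],
            intensity_a=None if self.intensity_a is None else self.intensity_a[:, index],
            intensity_b=None if self.intensity_b is None else self.intensity_b[:, index],
            populations=None if self.populations is None else self.populations[index],
        )

    def select_markers(self, marker_ids: Sequence[str]) -> "GenotypeCallMatrix":
        lookup = {mid: i for i, mid in enumerate(self.marker_ids)}
        try:
            index = [lookup[mid] for mid in marker_ids]
        except KeyError as exc:
            raise KeyError(f"marker {exc.args[0]!r} not in matrix") from exc
        return self.subset_markers(np.asarray(index))

    def to_dosage_matrix(self) -> "DosageMatrix":
        return DosageMatrix(
            dosages=self.dosages.copy(),
            marker_ids=list(self.marker_ids),
            sample_ids=list(self.sample_ids),
            contigs=self.contigs.copy(),
            positions=self.positions.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: marker, contig, pos, then one column per sample."""
        frame = pd.DataFrame(
            decode_calls(self.calls), index=self.marker_ids, columns=self.sample_ids
        )
        frame.insert(0, "pos", self.positions)
        frame.insert(0, "contig", self.contigs)
        frame.index.name = "marker"
        return frame


@dataclass
class DosageMatrix:
    """Markers x samples B-allele dosages in {0, 1, 2}, -1 for missing."""

    dosages: np.ndarray
    marker_ids: list[str]
    sample_ids: list[str]
    contigs: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-marker B-allele frequency over called samples (NaN if none)."""
        d = self.dosages
        called = d >= 0
        n_called = called.sum(axis=1)
        total = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, total / (2.0 * n_called), np.nan)


@dataclass
class CrossCohort:
    """One F1 cohort: two genotyped parents and offspring genotype counts.

    Offspring are stored as per-locus counts over (AA, AB, BB) plus a
    no-call count; counts + no-calls equal the cohort size at every locus.
    """

    cross_id: str
    locus_ids: list[str]
    maternal: np.ndarray  # (L,) genotype codes; NOCALL allowed
    paternal: np.ndarray
    counts: np.ndarray  # (L, 3) offspring counts over AA/AB/BB
    nocalls: np.ndarray  # (L,)
    n_offspring: int

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.nocalls = np.asarray(self.nocalls, dtype=np.int64)
        n_loci = len(self.locus_ids)
        if not (
            self.maternal.shape[0]
            == self.paternal.shape[0]
            == self.counts.shape[0]
            == self.nocalls.shape[0]
            == n_loci
        ):
            raise ValueError("cohort arrays do not share a locus dimension")
        totals = self.counts.sum(axis=1) + self.nocalls
        if np.any(totals != self.n_offspring):
            raise ValueError("offspring counts + no-calls must equal cohort size")
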