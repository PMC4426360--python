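"""File formats: FASTA, VCF v4.2, TSV tables, PLINK PED/MAP export.

The genotype-matrix TSV (row = marker id, contig, 1-based position, then one
AA/AB/BB/NN column per sample) is the internal interchange format — chip
pipelines operate on calls, not reads — with VCF supported at the design
stage and for interoperability.  All user-visible coordinates are 1-based
inclusive (VCF convention).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AA,
    AB,
    BB,
    NOCALL,
    GenotypeCallMatrix,
    decode_calls,
    encode_calls,
)
from .probedesign import VariantSite

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_intensity_tsv",
    "write_intensity_tsv",
    "read_pedigree_tsv",
    "write_pedigree_tsv",
    "write_truth_tsv",
    "write_ped_map",
    "write_json",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Contig name -> sequence (uppercased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str] | Sequence[tuple[str, str]], path, width: int = 70) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, skip_multiallelic: bool = True) -> tuple[list[VariantSite], list[str], int]:
    """Parse a VCF into VariantSite records.

    Returns (sites, sample ids, number of multiallelic records skipped).
    Site-level depth comes from INFO/DP (falling back to summed FORMAT/DP),
    ref/alt read support from summed FORMAT/AD, and per-sample genotypes
    from GT (missing -> no-call).  Multiallelic records are skipped by
    default (with a count) or split is refused — the chip model is biallelic.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    n_multi = 0
    for line_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            if skip_multiallelic:
                n_multi += 1
                continue
            raise ValueError(f"multiallelic or non-SNP record at line {line_no}")
        genotypes = None
        ref_reads = alt_reads = 0
        depth = rec.INFO.get("DP")
        if samples:
            gts = np.array([g[:2] for g in rec.genotypes])
            codes = np.where(
                (gts < 0).any(axis=1), NOCALL, gts.clip(min=0).sum(axis=1)
            ).astype(np.int8)
            genotypes = codes
            try:
                ad = rec.format("AD")
            except Exception:
                ad = None
            if ad is not None:
                ad = np.where(ad < 0, 0, ad)
                ref_reads = int(ad[:, 0].sum())
                alt_reads = int(ad[:, 1].sum()) if ad.shape[1] > 1 else 0
            if depth is None:
                dp = rec.format("DP")
                if dp is not None:
                    depth = int(np.where(dp < 0, 0, dp).sum())
        if depth is None:
            depth = ref_reads + alt_reads
        depth = max(int(depth), ref_reads + alt_reads)
        sites.append(
            VariantSite(
                contig=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                depth=depth,
                ref_reads=ref_reads,
                alt_reads=alt_reads,
                other_reads=max(depth - ref_reads - alt_reads, 0)
                if (ref_reads or alt_reads)
                else 0,
                qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                genotypes=genotypes,
            )
        )
    return sites, samples, n_multi


_GT_STRINGS = {NOCALL: "./.", AA: "0/0", AB: "0/1", BB: "1/1"}


def write_vcf(
    sites: Sequence[VariantSite],
    path,
    sample_ids: Sequence[str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write VariantSites as a minimal VCF v4.2 with GT (and DP/AD info)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chipforge\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AD,Number=R,Type=Integer,Description="Summed allele depths">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        has_genotypes = sample_ids is not None
        if has_genotypes:
            header += ["FORMAT", *sample_ids]
        fh.write("\t".join(header) + "\n")
        for site in sites:
            info = f"DP={site.depth};AD={site.ref_reads},{site.alt_reads}"
            row = [
                site.contig,
                str(site.pos),
                ".",
                site.ref,
                site.alt,
                f"{site.qual:g}",
                "PASS",
                info,
            ]
            if has_genotypes:
                row.append("GT")
                codes = (
                    site.genotypes
                    if site.genotypes is not None
                    else np.full(len(sample_ids), NOCALL, dtype=np.int8)
                )
                row.extend(_GT_STRINGS[int(c)] for c in codes)
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# genotype matrix TSV


def write_genotype_tsv(matrix: GenotypeCallMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_genotype_tsv(path, populations: Mapping[str, str] | None = None) -> GenotypeCallMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={"contig": str})
    sample_cols = [c for c in frame.columns if c not in ("contig", "pos")]
    calls = encode_calls(frame[sample_cols].to_numpy())
    pops = None
    if populations is not None:
        pops = np.array([populations.get(s) for s in sample_cols], dtype=object)
    return GenotypeCallMatrix(
        calls=calls,
        marker_ids=[str(m) for m in frame.index],
        sample_ids=sample_cols,
        contigs=frame["contig"].to_numpy(dtype=object),
        positions=frame["pos"].to_numpy(dtype=np.int64),
        populations=pops,
    )


# ---------------------------------------------------------------------------
# intensity TSV (long format: marker, sample, signal_a, signal_b)


def write_intensity_tsv(matrix: GenotypeCallMatrix, path) -> None:
    if not matrix.has_intensities():
        raise ValueError("matrix carries no intensities")
    rows = []
    for i, mid in enumerate(matrix.marker_ids):
        for j, sid in enumerate(matrix.sample_ids):
            rows.append((mid, sid, matrix.intensity_a[i, j], matrix.intensity_b[i, j]))
    pd.DataFrame(rows, columns=["marker", "sample", "signal_a", "signal_b"]).to_csv(
        path, sep="\t", index=False
    )


def read_intensity_tsv(path, matrix: GenotypeCallMatrix) -> GenotypeCallMatrix:
    """Attach a long-format intensity table to a call matrix (returns a copy)."""
    long = pd.read_csv(path, sep="\t")
    a = long.pivot(index="marker", columns="sample", values="signal_a")
    b = long.pivot(index="marker", columns="sample", values="signal_b")
    a = a.reindex(index=matrix.marker_ids, columns=matrix.sample_ids)
    b = b.reindex(index=matrix.marker_ids, columns=matrix.sample_ids)
    from dataclasses import replace

    return replace(matrix, intensity_a=a.to_numpy(float), intensity_b=b.to_numpy(float))


# ---------------------------------------------------------------------------
# pedigree TSV: cross_id, mother, father, offspring (comma-separated)


def write_pedigree_tsv(crosses: Sequence[tuple[str, str, str, Sequence[str]]], path) -> None:
    rows = [
        {"cross_id": cid, "mother": mo, "father": fa, "offspring": ",".join(off)}
        for cid, mo, fa, off in crosses
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path) -> list[tuple[str, str, str, list[str]]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [
        (row.cross_id, row.mother, row.father, row.offspring.split(","))
        for row in frame.itertuples()
    ]


def write_truth_tsv(truth: pd.Series, path) -> None:
    truth.rename_axis("marker").to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PLINK text export


def write_ped_map(matrix: GenotypeCallMatrix, prefix) -> tuple[Path, Path]:
    """Export calls as PLINK PED/MAP text files (for external cross-checks).

    Alleles are written as A/B letter codes; missing calls as 0 0.  The MAP
    chromosome column carries the contig name and 0 genetic distance.
    """
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for mid, contig, pos in zip(matrix.marker_ids, matrix.contigs, matrix.positions):
            fh.write(f"{contig}\t{mid}\t0\t{pos}\n")
    allele_pairs = {NOCALL: "0 0", AA: "A A", AB: "A B", BB: "B B"}
    with open(ped_path, "w") as fh:
        for j, sid in enumerate(matrix.sample_ids):
            fam = (
                matrix.populations[j]
                if matrix.populations is not None
                else "FAM"
            )
            lead = [str(fam), sid, "0", "0", "0", "-9"]
            geno = [allele_pairs[int(c)] for c in matrix.calls[:, j]]
            fh.write(" ".join(lead + geno) + "\n")
    return ped_path, map_path


def write_json(payload: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
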