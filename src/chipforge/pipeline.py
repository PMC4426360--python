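"""End-to-end pipeline driver: design -> QC -> Mendelian screen -> popgen.

``run_pipeline`` chains the validation stages the way a chip study runs
them: candidate probes are designed from variant calls, genotyped markers
are classified and the retained set (all-genotypes + no-minor-hom classes)
passes to the Mendelian screen, whose survivors form the validated marker
set characterized by LD, HWE, relatedness and PCA.  Every stage writes its
report under the output directory, and a run manifest records the resolved
configuration, seeds and marker counts at every stage boundary so each
number in a report is re-derivable.

With no input paths configured, the driver generates a fully synthetic
study (reference, read counts, population genotypes with injected defects,
and three F1 cross cohorts) from the configured seed — the same ground-truth
generators the test-suite uses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, markerqc, mendel, popgen, probedesign, synthdata
from .containers import AB, NOCALL, CrossCohort, GenotypeCallMatrix, encode_calls

__all__ = ["PipelineConfig", "run_pipeline", "cohorts_from_pedigree"]


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the validation pipeline.

    Defaults are the standard printed values of the design they implement:
    discovery depth 7x, MAF 0.2, allele-ratio 0.85, variant quality 25,
    missingness 20%, 35 bp invariant flanks, 95% call-rate threshold,
    alpha 0.05, and a ~200 cM map for the markers-per-cM quotient.
    """

    # probe design
    min_depth: int = 7
    min_maf: float = 0.2
    min_allele_ratio: float = 0.85
    min_qual: float = 25.0
    max_missing: float = 0.20
    flank: int = 35
    track: str = "rad"
    # QC
    call_threshold: float = 0.95
    quality_floor: float | None = 0.5
    # Mendelian / HWE
    alpha: float = 0.05
    # reporting
    map_length_cm: float = 200.0
    # inputs (None -> synthetic generation)
    vcf: str | None = None
    fasta: str | None = None
    genotypes: str | None = None
    intensities: str | None = None
    pedigree: str | None = None
    # synthetic-study shape
    seed: int = 0
    n_contigs: int = 8
    contig_length: int = 40_000
    variant_density: float = 0.002
    n_discovery_samples: int = 24
    n_population_samples: int = 60
    cohort_sizes: tuple[int, ...] = (32, 31, 32)
    # stage toggles
    run_design: bool = True
    run_qc: bool = True
    run_mendel: bool = True
    run_popgen: bool = True

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def cohorts_from_pedigree(
    matrix: GenotypeCallMatrix,
    crosses: list[tuple[str, str, str, list[str]]],
) -> list[CrossCohort]:
    """Build per-locus offspring count tables from a call matrix + pedigree."""
    col = {sid: j for j, sid in enumerate(matrix.sample_ids)}
    cohorts = []
    for cid, mother, father, offspring in crosses:
        try:
            mo = matrix.calls[:, col[mother]]
            fa = matrix.calls[:, col[father]]
            off = matrix.calls[:, [col[s] for s in offspring]]
        except KeyError as exc:
            raise ValueError(f"pedigree sample {exc.args[0]!r} not in matrix") from exc
        counts = np.stack([(off == g).sum(axis=1) for g in (0, 1, 2)], axis=1)
        nocalls = (off == NOCALL).sum(axis=1)
        cohorts.append(
            CrossCohort(
                cross_id=cid,
                locus_ids=list(matrix.marker_ids),
                maternal=mo,
                paternal=fa,
                counts=counts,
                nocalls=nocalls,
                n_offspring=len(offspring),
            )
        )
    return cohorts


def _synthetic_study(cfg: PipelineConfig):
    """Generate a coherent synthetic study from the configured seed."""
    rng = np.random.default_rng(cfg.seed)
    ref = synthdata.simulate_reference(
        cfg.n_contigs, cfg.contig_length, cfg.variant_density, seed=cfg.seed
    )
    reads = synthdata.simulate_read_counts(
        ref, n_samples=cfg.n_discovery_samples, seed=cfg.seed + 1
    )
    sites = [
        probedesign.VariantSite(
            contig=row.contig,
            pos=row.pos,
            ref=row.ref,
            alt=row.alt,
            depth=row.depth,
            ref_reads=row.ref_reads,
            alt_reads=row.alt_reads,
            other_reads=row.other_reads,
            qual=row.qual,
            genotypes=reads.genotypes[i],
        )
        for i, row in enumerate(reads.table.itertuples())
    ]
    sequences = dict(ref.supercontigs)
    return ref, sites, sequences


def _simulate_genotyping(cfg: PipelineConfig, candidates, seed: int):
    """Population matrix + defect injection for the candidate markers."""
    rng = np.random.default_rng(seed)
    n = len(candidates)
    freqs = rng.uniform(0.1, 0.9, size=n)
    model = synthdata.PopulationModel(ancestral_freqs=freqs)
    matrix = synthdata.simulate_population(model, cfg.n_population_samples, seed=seed)
    matrix = dataclasses.replace(
        matrix,
        marker_ids=[f"{c.site.contig}:{c.site.pos}" for c in candidates],
        contigs=np.array([c.site.contig for c in candidates], dtype=object),
        positions=np.array([c.site.pos for c in candidates], dtype=np.int64),
    )
    n_defect = max(1, n // 10)
    plan = {
        "monomorphic": n_defect,
        "no_minor_hom": n_defect,
        "low_call_rate": n_defect,
        "off_target": n_defect,
        "low_quality": n_defect,
    }
    return synthdata.inject_marker_defects(matrix, plan, seed=seed + 1)


def _simulate_crosses(cfg: PipelineConfig, locus_ids, seed: int) -> list[CrossCohort]:
    rng = np.random.default_rng(seed)
    n_loci = len(locus_ids)
    cohorts = []
    for ci, size in enumerate(cfg.cohort_sizes):
        maternal = rng.choice([0, 1, 2], size=n_loci, p=[0.3, 0.4, 0.3]).astype(np.int8)
        paternal = rng.choice([0, 1, 2], size=n_loci, p=[0.3, 0.4, 0.3]).astype(np.int8)
        spec = synthdata.CrossSpec(
            maternal=maternal,
            paternal=paternal,
            n_offspring=size,
            locus_ids=list(locus_ids),
        )
        cohorts.append(
            synthdata.simulate_cross(spec, seed=seed + 100 + ci, cross_id=f"cross{ci + 1}")
        )
    return cohorts


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the validation pipeline; returns the manifest dictionary."""
    cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.as_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "counts": {},
    }

    # --- design stage -----------------------------------------------------
    if cfg.run_design:
        if cfg.vcf is not None:
            sites, _, n_multi = io.read_vcf(cfg.vcf)
            sequences = io.read_fasta(cfg.fasta) if cfg.fasta else {}
            manifest["counts"]["multiallelic_skipped"] = n_multi
        else:
            _, sites, sequences = _synthetic_study(cfg)
        manifest["counts"]["input_sites"] = len(sites)

        if cfg.track == "rna":
            outcome = probedesign.filter_rna_track(
                sites, cfg.min_depth, cfg.min_maf, cfg.min_allele_ratio
            )
        else:
            outcome = probedesign.filter_rad_track(
                sites, cfg.min_depth, cfg.min_qual, cfg.max_missing
            )
        variant_index = {}
        for s in sites:
            variant_index.setdefault(s.contig, []).append(s.pos)
        variant_index = {k: np.unique(v) for k, v in variant_index.items()}
        probes, flank_failed = probedesign.build_candidate_probes(
            outcome.retained, sequences, variant_index, window=cfg.flank, track=cfg.track
        )
        pool = probedesign.pool_candidates((cfg.track, probes))
        candidates = pool.candidates
        manifest["counts"]["filter_retained"] = len(outcome.retained)
        manifest["counts"]["flank_failed"] = len(flank_failed)
        manifest["counts"]["candidates"] = len(candidates)

        lengths = {name: len(seq) for name, seq in sequences.items()}
        markers = [(c.site.contig, c.site.pos) for c in candidates]
        if len(markers) >= 2:
            spacing = probedesign.spacing_stats(markers, lengths)
            io.write_json(
                {
                    "mean_distance": spacing.mean_distance,
                    "pearson_r": spacing.pearson_r,
                    "pearson_p": spacing.pearson_p,
                    "contigs_covered": spacing.contigs_covered,
                    "n_markers": spacing.n_markers,
                },
                out / "spacing.json",
            )
        pd.DataFrame(
            {
                "contig": [c.site.contig for c in candidates],
                "pos": [c.site.pos for c in candidates],
                "ref": [c.site.ref for c in candidates],
                "alt": [c.site.alt for c in candidates],
                "flank35_left": [c.flank_left for c in candidates],
                "flank35_right": [c.flank_right for c in candidates],
                "provenance": ["|".join(sorted(c.provenance)) for c in candidates],
            }
        ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    else:
        candidates = []

    # --- genotyping + QC stage -------------------------------------------
    if cfg.run_qc:
        if cfg.genotypes is not None:
            matrix = io.read_genotype_tsv(cfg.genotypes)
            if cfg.intensities:
                matrix = io.read_intensity_tsv(cfg.intensities, matrix)
            truth = None
        else:
            if not candidates:
                raise RuntimeError("QC stage requires the design stage or a genotype file")
            matrix, truth = _simulate_genotyping(cfg, candidates, seed=cfg.seed + 10)
            io.write_genotype_tsv(matrix, out / "genotypes.tsv")
            io.write_truth_tsv(truth, out / "truth_classes.tsv")
        ledger, classes = markerqc.build_ledger(
            matrix,
            call_threshold=cfg.call_threshold,
            quality_floor=cfg.quality_floor,
        )
        io.write_json(ledger.as_dict(), out / "qc_ledger.json")
        classes.rename_axis("marker").to_frame().to_csv(out / "qc_classes.tsv", sep="\t")
        retained_ids = ledger.retained_ids
        manifest["counts"]["genotyped"] = matrix.n_markers
        manifest["counts"]["qc_retained"] = len(retained_ids)
    else:
        matrix = None
        retained_ids = []

    # --- Mendelian stage --------------------------------------------------
    if cfg.run_mendel:
        if cfg.pedigree is not None and matrix is not None:
            crosses = io.read_pedigree_tsv(cfg.pedigree)
            cohorts = cohorts_from_pedigree(matrix, crosses)
        else:
            cohorts = _simulate_crosses(cfg, matrix.marker_ids, seed=cfg.seed + 20)
        result, summary = mendel.mendel_screen(cohorts, retained_ids, alpha=cfg.alpha)
        result.table.to_csv(out / "mendel_results.tsv", sep="\t")
        io.write_json(summary.as_dict(), out / "mendel_summary.json")
        final_ids = [mid for mid in retained_ids if mid in set(summary.retained_loci)]
        manifest["counts"]["mendel_testable"] = summary.testable
        manifest["counts"]["mendel_deviant"] = summary.deviant
        manifest["counts"]["mendel_incompatible"] = summary.incompatible
    else:
        final_ids = retained_ids
    manifest["counts"]["final_markers"] = len(final_ids)
    manifest["markers_per_cm"] = len(final_ids) / cfg.map_length_cm

    # --- population characterization -------------------------------------
    if cfg.run_popgen and matrix is not None and len(final_ids) >= 2:
        final = matrix.select_markers(final_ids)
        ld = popgen.ld_scan(final)
        ld.pairs.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
        if not ld.hist2d.empty:
            ld.hist2d.to_csv(out / "ld_hist2d.tsv", sep="\t")
        io.write_json(
            {
                "mean_r2": ld.mean_r2,
                "same_contig_mean": ld.same_contig_mean,
                "cross_contig_mean": ld.cross_contig_mean,
                "median_perfect_ld_distance": ld.median_perfect_ld_distance,
                "n_samples": ld.n_samples,
            },
            out / "ld_summary.json",
        )
        hwe = popgen.hwe_screen(final, alpha=cfg.alpha)
        hwe.table.to_csv(out / "hwe_results.tsv", sep="\t")
        kin = popgen.ajk_relatedness(final)
        kin.to_frame().to_csv(out / "kinship.tsv", sep="\t")
        pca = popgen.pca_genotypes(final)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        manifest["counts"]["hwe_deviant"] = hwe.n_deviant

    io.write_json(manifest, out / "manifest.json")
    return manifest
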