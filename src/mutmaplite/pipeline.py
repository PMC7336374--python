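"""Orchestration: simulate (or ingest) -> index -> windows -> regions ->
candidates -> annotate, with reproducible artifacts.

``run_pipeline`` executes the whole chain from a RunConfig and a seed;
``table1_demo`` replays the packaged worked example's filter cascade
(10 SNPs -> 6 in the 23-27 Mb region -> 2 nonsynonymous -> 1 survivor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .annotate import GeneModel, annotate_table
from .config import RunConfig
from .crosssim import (
    BulkConfig,
    CrossResult,
    EmsVariantSet,
    GenomeSpec,
    simulate_cross,
)
from .fixtures import TABLE1_CHROM, load_table1
from .snpindex import (
    CandidateFilterConfig,
    CandidateRegion,
    WindowSeries,
    candidate_snp_filter,
    compute_index_table,
    detect_candidate_regions,
    filter_sites,
    sliding_window_mean,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
# codon templates guaranteeing a nonsynonymous change when the causal
# substitution sits at the first codon position
_NONSYN_CODON = {("C", "T"): "CTC", ("G", "A"): "GAT"}  # Leu->Phe, Asp->Asn


def build_causal_gene_model(
    variants: EmsVariantSet, genome: GenomeSpec, rng, gene_id: str = "GENE1"
) -> GeneModel:
    """Synthetic single-exon gene model hosting the causal variant.

    The CDS frame is anchored so the causal variant falls on the first
    position of a codon whose ref->alt substitution is nonsynonymous
    (CTC->TTC Leu>Phe for C->T, GAT->AAT Asp>Asn for G->A).  Reference
    bases of any other variants inside the CDS are written into the
    generated sequence so downstream annotation stays consistent.
    """
    chrom, pos = variants.causal
    ref = variants.ref[variants.causal_index]
    alt = variants.alt[variants.causal_index]
    if (ref, alt) not in _NONSYN_CODON:
        raise ValueError("causal variant is not an EMS-type substitution")
    interval = None
    for c, s, e in genome.gene_intervals:
        if c == chrom and s <= pos <= e:
            interval = (s, e)
            break
    if interval is None:
        raise ValueError("causal variant lies outside every CDS interval")
    s, e = interval
    cds_start = s + (pos - s) % 3  # causal at codon position 1
    cds_end = cds_start + 3 * ((e - cds_start + 1) // 3) - 1
    if cds_end < pos + 2:
        raise ValueError("CDS interval too short to host the causal codon")
    length = cds_end - cds_start + 1
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seq = rng.choice(_BASES, size=length)
    off = pos - cds_start
    seq[off : off + 3] = list(_NONSYN_CODON[(ref, alt)])
    # keep other in-CDS variants' reference bases consistent
    on_chrom = variants.chrom == chrom
    inside = on_chrom & (variants.pos >= cds_start) & (variants.pos <= cds_end)
    for i in np.flatnonzero(inside):
        if i == variants.causal_index:
            continue
        seq[variants.pos[i] - cds_start] = variants.ref[i]
    seq[off] = ref  # causal codon wins any overlap
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand="+",
        cds_intervals=((cds_start, cds_end),),
        cds_sequence="".join(seq),
    )


@dataclass
class PipelineResult:
    config: RunConfig
    cross: CrossResult
    gene_model: GeneModel
    index_table: pd.DataFrame
    wp_series: WindowSeries
    mp_series: WindowSeries
    regions: list
    report: pd.DataFrame

    @property
    def candidates(self) -> pd.DataFrame:
        return self.report[self.report["pass_all"]].reset_index(drop=True)

    @property
    def causal_rank(self) -> float:
        """Rank of the true causal SNP among candidates (NaN if filtered out)."""
        t = self.cross.truth
        hit = self.report[
            (self.report["chrom"] == t.causal_chrom)
            & (self.report["pos"] == t.causal_pos)
        ]
        return float(hit["rank"].iloc[0]) if len(hit) else float("nan")


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Execute the full analysis from one seeded configuration."""
    rng = np.random.default_rng(config.seed)
    gene_start = int(
        rng.integers(
            int(0.1 * config.chrom_length),
            int(0.9 * config.chrom_length) - config.gene_length,
        )
    )
    genome = GenomeSpec(
        chromosomes=((config.chrom_name, config.chrom_length),),
        recomb_rate_cm_per_mb=config.recomb_rate_cm_per_mb,
        gene_intervals=(
            (config.chrom_name, gene_start, gene_start + config.gene_length - 1),
        ),
    )
    bulk = BulkConfig(
        n_mp=config.n_mp,
        n_wp=config.n_wp,
        mean_depth=config.mean_depth,
        error_rate=config.error_rate,
        seed=config.seed,
    )
    cross = simulate_cross(
        genome,
        n_variants=config.n_snps,
        spectrum_fraction=config.spectrum_fraction,
        population_size=config.population_size,
        config=bulk,
    )
    gene_model = build_causal_gene_model(
        cross.variants, genome, np.random.default_rng(config.seed + 1)
    )

    index_table = compute_index_table(cross.counts)
    index_table = filter_sites(index_table, min_depth=config.min_depth)

    kwargs = dict(
        window_bp=config.window_bp,
        step_bp=config.step_bp,
        chrom_length=config.chrom_length,
    )
    mp_series = sliding_window_mean(index_table, config.chrom_name, bulk="mp", **kwargs)
    wp_series = sliding_window_mean(index_table, config.chrom_name, bulk="wp", **kwargs)
    regions = detect_candidate_regions(
        mp_series,
        index_threshold=config.region_threshold,
        min_windows=config.min_region_windows,
    )
    region = None
    if regions:
        top = regions[0]
        region = (top.chrom, *mio.to_one_based(top.start, top.end))
    else:
        logger.warning("no candidate region detected; filtering genome-wide")

    annotations = annotate_table(
        index_table,
        [gene_model],
        flank_bp=config.flank_bp,
        chromosomes=genome.chrom_names,
    )
    fconfig = CandidateFilterConfig(
        mp_min_index=config.mp_min_index,
        mp_tolerance=config.mp_tolerance,
        wp_target=config.wp_target,
        wp_band=(config.wp_band_lo, config.wp_band_hi),
        alpha=config.alpha,
        min_depth=config.min_depth,
        require_nonsynonymous=config.require_nonsynonymous,
        region=region,
    )
    report = candidate_snp_filter(index_table, annotations, fconfig)

    result = PipelineResult(
        config=config,
        cross=cross,
        gene_model=gene_model,
        index_table=index_table,
        wp_series=wp_series,
        mp_series=mp_series,
        regions=regions,
        report=report,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    mio.write_counts_tsv(result.cross.counts, out / "counts.tsv")
    mio.write_counts_vcf(result.cross.counts, out / "counts.vcf")
    mio.write_index_tsv(result.index_table, out / "snp_index.tsv")
    mio.write_windows_tsv(result.wp_series, result.mp_series, out / "windows.tsv")
    mio.write_regions_bed(result.regions, out / "regions.bed")
    mio.write_candidates_tsv(result.report, out / "candidates.tsv")
    mio.write_truth_tsv(result.cross.truth, out / "truth.tsv")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("# resolved configuration\n")
        fh.write(result.config.to_text() + "\n")
        fh.write(f"seed = {result.config.seed}\n")
        fh.write(f"n_candidates = {int(result.report['pass_all'].sum())}\n")
        fh.write(f"causal = {result.cross.truth.causal_chrom}:"
                 f"{result.cross.truth.causal_pos}\n")
        fh.write(f"causal_rank = {result.causal_rank}\n")


def table1_demo(config: CandidateFilterConfig | None = None) -> dict:
    """Replay the worked example's 10 -> 6 -> 2 -> 1 filter cascade.

    Returns the counts at each stage plus the surviving record.  The
    region restriction is the published 23-27 Mb span of chromosome 12.
    """
    fixture = load_table1()
    records = fixture.records()
    annotations = fixture.annotations()
    config = config or CandidateFilterConfig(
        region=(TABLE1_CHROM, 23_000_000, 27_000_000)
    )
    report = candidate_snp_filter(records, annotations, config)
    survivors = report[report["pass_all"]]
    return {
        "n_total": len(report),
        "n_mp_index_1": int((report["mp_index"] == 1).sum()),
        "n_in_region": int(report["pass_region"].sum()),
        "n_nonsynonymous": int(report["pass_effect"].sum()),
        "n_candidates": len(survivors),
        "candidate_pos": int(survivors["pos"].iloc[0]) if len(survivors) else None,
        "candidate_wp_index": (
            float(survivors["wp_index"].iloc[0]) if len(survivors) else None
        ),
        "report": report,
    }
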