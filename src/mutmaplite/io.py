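"""Readers/writers for the small set of standard formats the pipeline touches.

Allele-count tables travel either as flat TSV (the eight declared
columns) or as a simplified VCF 4.2 with two samples, WP_BULK and
MP_BULK, whose FORMAT carries AD = ref,alt depths.  VCF/GFF3 positions
are 1-based inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .crosssim import COUNT_COLUMNS, CrossTruth
from .snpindex import CandidateRegion, WindowSeries

VCF_SAMPLES = ("WP_BULK", "MP_BULK")

_VCF_HEADER_TOP = """\
##fileformat=VCFv4.2
##source=mutmaplite
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""
_VCF_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tWP_BULK\tMP_BULK\n"
_VCF_HEADER = _VCF_HEADER_TOP + _VCF_COLUMNS  # header without contig lines


def to_zero_based(start1: int, end1: int) -> tuple:
    """1-based inclusive interval -> 0-based half-open (BED)."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple:
    """0-based half-open (BED) -> 1-based inclusive."""
    return start0 + 1, end0


def _validate_counts(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{origin}: missing columns {missing}")
    df = df[COUNT_COLUMNS].copy()
    count_cols = COUNT_COLUMNS[4:]
    bad = df.index[(df[count_cols] < 0).any(axis=1) | df[count_cols].isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:20])  # +2: header + 1-based
        raise ValueError(f"{origin}: negative or missing counts at line(s) {lines}")
    df["pos"] = df["pos"].astype(np.int64)
    for c in count_cols:
        df[c] = df[c].astype(np.int64)
    order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
    df = df.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return df


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return _validate_counts(df, str(path))


def write_counts_vcf(df: pd.DataFrame, path) -> None:
    """Write the allele-count table as a simplified two-sample VCF."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER_TOP)
        for chrom in pd.unique(df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(_VCF_COLUMNS)
        for r in df.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tAD\t"
                f"{r.wp_ref_reads},{r.wp_alt_reads}\t{r.mp_ref_reads},{r.mp_alt_reads}\n"
            )


def read_counts_vcf(path) -> pd.DataFrame:
    """Read per-bulk AD depths from a VCF with WP_BULK/MP_BULK samples.

    Falls back to positional order (first sample = WP, second = MP) when
    the samples are named differently.  Multi-allelic records or records
    without AD are rejected with their positions listed.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if len(samples) != 2:
        raise ValueError(f"{path}: expected 2 samples, found {len(samples)}")
    wp, mp = (
        VCF_SAMPLES if set(samples) == set(VCF_SAMPLES) else (samples[0], samples[1])
    )
    rows, bad = [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            bad.append(f"{rec.chrom}:{rec.pos} (non-biallelic)")
            continue
        try:
            wp_ad = rec.samples[wp]["AD"]
            mp_ad = rec.samples[mp]["AD"]
        except KeyError:
            bad.append(f"{rec.chrom}:{rec.pos} (missing AD)")
            continue
        if wp_ad is None or mp_ad is None or None in wp_ad or None in mp_ad:
            bad.append(f"{rec.chrom}:{rec.pos} (missing AD)")
            continue
        rows.append(
            (rec.chrom, rec.pos, rec.ref, rec.alts[0],
             wp_ad[0], wp_ad[1], mp_ad[0], mp_ad[1])
        )
    if bad:
        raise ValueError(f"{path}: rejected records: " + "; ".join(bad[:20]))
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return _validate_counts(df, str(path))


def read_counts(path, dialect: str | None = None) -> pd.DataFrame:
    """Dispatch on dialect ('vcf'|'tsv') or on the file extension."""
    if dialect is None:
        dialect = "vcf" if str(path).endswith(".vcf") else "tsv"
    if dialect == "vcf":
        return read_counts_vcf(path)
    if dialect == "tsv":
        return read_counts_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_index_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_windows_tsv(
    wp_series: WindowSeries, mp_series: WindowSeries, path
) -> None:
    """Plot-ready window series: chrom, window midpoint, mean index per bulk."""
    if (wp_series.chrom != mp_series.chrom
            or len(wp_series.frame) != len(mp_series.frame)):
        raise ValueError("window series are not aligned")
    f = wp_series.frame
    out = pd.DataFrame(
        {
            "chrom": wp_series.chrom,
            "midpoint": (f["start"] + f["end"]) // 2,
            "wp_mean_index": f["mean_index"],
            "mp_mean_index": mp_series.frame["mean_index"],
            "wp_n_snps": f["n_snps"],
            "mp_n_snps": mp_series.frame["n_snps"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(regions: Sequence[CandidateRegion], path) -> None:
    """Candidate regions as BED (0-based half-open; score = peak mean x1000)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            score = int(round(1000 * r.peak_mean_index))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion{i}\t{score}\t.\n")


def read_regions_bed(path) -> list[CandidateRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            regions.append(
                CandidateRegion(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    peak_mean_index=float(f[4]) / 1000 if len(f) > 4 else float("nan"),
                    n_windows=0,
                )
            )
    return regions


def write_candidates_tsv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_truth_tsv(truth: CrossTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# causal={truth.causal_chrom}:{truth.causal_pos} seed={truth.seed}\n")
        truth.to_frame().to_csv(fh, sep="\t", index=False)


def write_fasta(sequences: dict, path) -> None:
    """Write {name: sequence} as FASTA (wrapped at 70 columns)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
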