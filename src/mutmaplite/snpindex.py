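"""SNP-index statistics and the dual-bulk causal-SNP filter.

The SNP index of a bulk at a variant site is the fraction of reads
carrying the non-reference (mutant-line) allele.  For a monogenic,
fully penetrant recessive mutation mapped in an F2 between the mutant
and its own parent:

* the mutant-phenotype (MP) bulk is homozygous mutant at the causal
  locus, so its SNP index is 1 there (exactly 1 when sequencing error
  is zero);
* the phenotypically wild-type (WP) bulk is a 1:2 mixture of homozygous
  reference and heterozygous individuals at the causal locus, so its
  expected SNP index is (0*1 + 1*2) / (2*(1+2)) = 1/3;
* unlinked sites have expectation 1/2 in both bulks.

The candidate filter operationalizes the decision rule "MP index = 1
and WP index about 1/3": an MP-index threshold, an optional genomic
region restriction, a WP-index band combined with an exact binomial
consistency test against 1/3, and a coding-effect requirement, ranked
by distance of the WP index from 1/3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

INDEX_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "wp_index", "mp_index", "wp_depth", "mp_depth",
    "wp_alt_reads", "mp_alt_reads",
]


def compute_snp_index(ref_reads: int, alt_reads: int) -> float:
    """alt / (ref + alt); NaN at zero depth; negative counts are an error."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total == 0:
        return float("nan")
    return alt_reads / total


def _check_sorted(chrom: np.ndarray, pos: np.ndarray) -> None:
    # sorted = non-decreasing positions within each contiguous chromosome
    # block, and no chromosome appearing in two separate blocks
    seen = []
    for c in chrom:
        if not seen or seen[-1] != c:
            seen.append(c)
    if len(seen) != len(set(seen)):
        raise ValueError("table not sorted: chromosome appears in separate blocks")
    for c in set(seen):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"table not sorted by position on {c}")


def compute_index_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-variant SNP indices and depths for both bulks.

    Input is an allele-count table (``crosssim.COUNT_COLUMNS``); it must
    be sorted by (chrom, pos).  Indices are NaN exactly where a bulk has
    zero depth.
    """
    chrom = counts["chrom"].to_numpy(dtype=object)
    pos = counts["pos"].to_numpy()
    _check_sorted(chrom, pos)
    for col in ("wp_ref_reads", "wp_alt_reads", "mp_ref_reads", "mp_alt_reads"):
        if (counts[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    out = counts[["chrom", "pos", "ref", "alt"]].copy()
    for prefix in ("wp", "mp"):
        depth = counts[f"{prefix}_ref_reads"] + counts[f"{prefix}_alt_reads"]
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = counts[f"{prefix}_alt_reads"] / depth
        out[f"{prefix}_index"] = idx.where(depth > 0, np.nan)
        out[f"{prefix}_depth"] = depth
        out[f"{prefix}_alt_reads"] = counts[f"{prefix}_alt_reads"]
    return out[INDEX_COLUMNS].reset_index(drop=True)


def filter_sites(records: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Keep records with both bulk depths >= min_depth; order preserved."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    keep = (records["wp_depth"] >= min_depth) & (records["mp_depth"] >= min_depth)
    removed = int((~keep).sum())
    if removed:
        logger.info("depth filter removed %d of %d sites", removed, len(records))
    return records[keep].reset_index(drop=True)


@dataclass
class WindowSeries:
    """Sliding-window mean SNP index along one chromosome."""

    chrom: str
    bulk: str
    window_bp: int
    step_bp: int
    frame: pd.DataFrame  # columns: start, end (half-open, 0-based), mean_index, n_snps


def sliding_window_mean(
    records: pd.DataFrame,
    chrom: str,
    window_bp: int = 1_000_000,
    step_bp: int = 1_000,
    bulk: str = "mp",
    chrom_length: int | None = None,
) -> WindowSeries:
    """Mean SNP index in windows of ``window_bp`` advanced by ``step_bp``.

    Windows are anchored at 0 and half-open: window ``[s, s+W)`` contains
    a variant iff ``s <= pos-1 < s+W`` (positions are 1-based).  The mean
    is the arithmetic mean over contained *defined* indices; ``n_snps``
    counts those, and windows with none carry an undefined (NaN) mean.
    Runs in O(n + windows) but equals the naive per-window recomputation.
    """
    if not (window_bp >= step_bp >= 1):
        raise ValueError("require window_bp >= step_bp >= 1")
    sub = records[records["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    if np.any(np.diff(pos) < 0):
        raise ValueError(f"records not sorted by position on {chrom}")
    vals = sub[f"{bulk}_index"].to_numpy(dtype=float)
    defined = ~np.isnan(vals)
    pos0 = (pos[defined] - 1).astype(np.int64)
    v = vals[defined]

    limit = chrom_length if chrom_length is not None else (int(pos.max()) if len(pos) else window_bp)
    starts = np.arange(0, max(limit, 1), step_bp, dtype=np.int64)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, starts + window_bp, side="left")
    n = hi - lo
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    frame = pd.DataFrame(
        {"start": starts, "end": starts + window_bp, "mean_index": mean, "n_snps": n}
    )
    return WindowSeries(
        chrom=chrom, bulk=bulk, window_bp=window_bp, step_bp=step_bp, frame=frame
    )


@dataclass
class CandidateRegion:
    chrom: str
    start: int  # bp, 0-based half-open
    end: int
    peak_mean_index: float
    n_windows: int


def detect_candidate_regions(
    series: WindowSeries,
    index_threshold: float = 0.9,
    min_windows: int = 1,
) -> list[CandidateRegion]:
    """Maximal runs of consecutive windows with mean >= threshold.

    Runs shorter than ``min_windows`` are discarded; survivors are merged
    into genomic intervals and returned best peak first (ties broken by
    genomic order).
    """
    if not 0 < index_threshold <= 1:
        raise ValueError("index_threshold must be in (0, 1]")
    f = series.frame
    ok = (f["mean_index"] >= index_threshold).to_numpy()
    regions: list[CandidateRegion] = []
    i = 0
    n = len(ok)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1]:
            j += 1
        if j - i + 1 >= min_windows:
            block = f.iloc[i : j + 1]
            regions.append(
                CandidateRegion(
                    chrom=series.chrom,
                    start=int(block["start"].iloc[0]),
                    end=int(block["end"].iloc[-1]),
                    peak_mean_index=float(block["mean_index"].max()),
                    n_windows=j - i + 1,
                )
            )
        i = j + 1
    # window width >> step, so distinct runs can still overlap genomically;
    # merge overlapping intervals into maximal regions
    merged: list[CandidateRegion] = []
    for r in sorted(regions, key=lambda r: r.start):
        if merged and r.start < merged[-1].end:
            last = merged[-1]
            merged[-1] = CandidateRegion(
                chrom=last.chrom,
                start=last.start,
                end=max(last.end, r.end),
                peak_mean_index=max(last.peak_mean_index, r.peak_mean_index),
                n_windows=last.n_windows + r.n_windows,
            )
        else:
            merged.append(r)
    merged.sort(key=lambda r: (-r.peak_mean_index, r.start))
    return merged


def expected_wp_index(genotype_weights: Mapping[int, float] | None = None) -> float:
    """Expected bulk SNP index from a phenotype class's genotype mix.

    The default is the phenotypically wild-type F2 class under a
    monogenic recessive model, AA : Aa = 1 : 2, giving
    (0*1 + 1*2) / (2*(1+2)) = 1/3.  Pass ``{2: 1}`` for the mutant
    class (1.0) or ``{0: 1}`` for a homozygous-reference class (0.0).
    """
    if genotype_weights is None:
        genotype_weights = {0: 1.0, 1: 2.0}
    total = sum(genotype_weights.values())
    if total <= 0:
        raise ValueError("weights must have positive total")
    return sum(g * w for g, w in genotype_weights.items()) / (2.0 * total)


def wp_consistency_pvalue(alt_reads: int, depth: int, p0: float = 1 / 3) -> float:
    """Two-sided exact binomial test of the observed allele fraction vs p0.

    Uses the minimum-likelihood convention: the p-value sums the
    probabilities of all outcomes no more probable than the observed one.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads must be in [0, depth]")
    return stats.binomtest(alt_reads, depth, p0, alternative="two-sided").pvalue


@dataclass
class CandidateFilterConfig:
    """Decision rule for the dual-bulk causal-SNP filter.

    ``wp_band`` is applied as ``lo <= wp_index < hi``; it must contain
    ``wp_target``.  The default band [0.1, 0.6) with ``alpha = 0.01``
    was calibrated by exact computation (`wp_retention_probability`) so
    that a true causal site at the default bulk size and depth is
    retained with probability ~0.98 while sites fixed in both bulks
    (index ~= 1) essentially never pass.  ``mp_tolerance`` absorbs
    sequencing error at the causal site in the MP bulk.
    """

    mp_min_index: float = 1.0
    mp_tolerance: float = 0.1
    wp_target: float = 1 / 3
    wp_band: tuple = (0.1, 0.6)
    alpha: float = 0.01
    min_depth: int = 10
    require_nonsynonymous: bool = True
    region: tuple | None = None  # (chrom, start, end), 1-based inclusive

    def __post_init__(self):
        lo, hi = self.wp_band
        if not (0 <= lo <= self.wp_target < hi <= 1):
            raise ValueError("wp_band must satisfy 0 <= lo <= wp_target < hi <= 1")
        if not 0 <= self.mp_min_index <= 1:
            raise ValueError("mp_min_index must be in [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


#: effect categories accepted when ``require_nonsynonymous`` is set
PROTEIN_CHANGING = ("nonsynonymous", "stop_gain")


def candidate_snp_filter(
    records: pd.DataFrame,
    annotations: pd.DataFrame | None,
    config: CandidateFilterConfig | None = None,
) -> pd.DataFrame:
    """Apply the dual-bulk criterion and rank surviving candidates.

    Returns a report with one row per input record carrying every filter
    verdict (nothing is silently dropped): ``pass_depth``, ``pass_mp``,
    ``pass_region``, ``pass_wp_band``, ``pass_wp_consistency``,
    ``pass_effect``, ``pass_all``, plus ``wp_distance`` and, for records
    passing everything, a 1-based ``rank`` ascending by
    ``|wp_index - wp_target|`` with ties broken by genomic coordinate.

    Verdicts are computed independently, so the composition is
    order-independent by construction.  Depth-based checks (the depth
    filter and the WP consistency test) are treated as non-binding for
    records whose depths are unknown (NaN), e.g. published index tables
    that report indices without read counts.
    """
    config = config or CandidateFilterConfig()
    rep = records.copy().reset_index(drop=True)

    if annotations is not None:
        ann = annotations.drop_duplicates(subset=["chrom", "pos"])
        rep = rep.merge(
            ann[["chrom", "pos", "region_class", "gene_id", "effect"]],
            on=["chrom", "pos"],
            how="left",
        )
    else:
        rep["region_class"] = np.nan
        rep["gene_id"] = np.nan
        rep["effect"] = np.nan

    wp_depth = rep["wp_depth"] if "wp_depth" in rep else pd.Series(np.nan, index=rep.index)
    mp_depth = rep["mp_depth"] if "mp_depth" in rep else pd.Series(np.nan, index=rep.index)
    depth_known = wp_depth.notna() & mp_depth.notna()
    rep["pass_depth"] = ~depth_known | (
        (wp_depth >= config.min_depth) & (mp_depth >= config.min_depth)
    )

    rep["pass_mp"] = rep["mp_index"] >= (config.mp_min_index - config.mp_tolerance)

    if config.region is not None:
        rchrom, rstart, rend = config.region
        rep["pass_region"] = (
            (rep["chrom"] == rchrom) & (rep["pos"] >= rstart) & (rep["pos"] <= rend)
        )
    else:
        rep["pass_region"] = True

    lo, hi = config.wp_band
    rep["pass_wp_band"] = (rep["wp_index"] >= lo) & (rep["wp_index"] < hi)

    pvals = np.ones(len(rep))
    for i in range(len(rep)):
        d = wp_depth.iloc[i]
        if pd.isna(d) or d <= 0:
            continue
        if "wp_alt_reads" in rep and not pd.isna(rep["wp_alt_reads"].iloc[i]):
            alt = int(rep["wp_alt_reads"].iloc[i])
        else:
            alt = int(round(rep["wp_index"].iloc[i] * d))
        pvals[i] = wp_consistency_pvalue(alt, int(d), config.wp_target)
    rep["wp_pvalue"] = pvals
    rep["pass_wp_consistency"] = rep["wp_pvalue"] >= config.alpha

    if config.require_nonsynonymous:
        missing = (
            rep["pass_depth"]
            & rep["pass_mp"]
            & rep["pass_region"]
            & rep["pass_wp_band"]
            & rep["pass_wp_consistency"]
            & rep["region_class"].isna()  # no annotation row joined at all
        )
        if missing.any():
            where = rep.loc[missing, ["chrom", "pos"]].astype(str).agg(":".join, axis=1)
            raise ValueError(
                "annotation missing for surviving record(s): " + ", ".join(where)
            )
        rep["pass_effect"] = rep["effect"].isin(PROTEIN_CHANGING) & (
            rep["region_class"] == "exonic"
        )
    else:
        rep["pass_effect"] = True

    rep["pass_all"] = (
        rep["pass_depth"]
        & rep["pass_mp"]
        & rep["pass_region"]
        & rep["pass_wp_band"]
        & rep["pass_wp_consistency"]
        & rep["pass_effect"]
    )
    rep["wp_distance"] = (rep["wp_index"] - config.wp_target).abs()

    rep["rank"] = np.nan
    chrom_order = {c: i for i, c in enumerate(pd.unique(rep["chrom"]))}
    passing = rep.index[rep["pass_all"]]
    order = sorted(
        passing,
        key=lambda i: (
            rep.at[i, "wp_distance"],
            chrom_order[rep.at[i, "chrom"]],
            rep.at[i, "pos"],
        ),
    )
    for rank, i in enumerate(order, start=1):
        rep.at[i, "rank"] = rank
    return rep.sort_values(
        by=["pass_all", "rank", "chrom", "pos"],
        ascending=[False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)


def wp_retention_probability(
    mean_depth: float = 30.0,
    n_wp: int = 30,
    error_rate: float = 0.005,
    wp_band: tuple = (0.1, 0.6),
    alpha: float = 0.01,
    min_depth: int = 10,
    p_het: float = 2 / 3,
    wp_target: float = 1 / 3,
) -> float:
    """Exact probability that a true causal site passes the WP criterion.

    Marginalizes over the WP-bulk genotype composition (each of the
    ``n_wp`` phenotypically wild-type individuals is heterozygous with
    probability ``p_het``), Poisson total depth, and binomial read
    sampling with the given error rate.  Used to calibrate the default
    ``wp_band``/``alpha`` so the dual-bulk filter has a known miss rate
    at the design depth.
    """
    lo, hi = wp_band
    d_max = int(stats.poisson.ppf(1 - 1e-9, mean_depth)) + 1
    p_depth = stats.poisson.pmf(np.arange(min_depth, d_max + 1), mean_depth)
    p_s = stats.binom.pmf(np.arange(n_wp + 1), n_wp, p_het)
    total = 0.0
    for d, pd_ in zip(range(min_depth, d_max + 1), p_depth):
        ok = [
            x
            for x in range(d + 1)
            if lo <= x / d < hi
            and stats.binomtest(x, d, wp_target).pvalue >= alpha
        ]
        if not ok:
            continue
        ok = np.array(ok)
        for s, ps in zip(range(n_wp + 1), p_s):
            q = s / (2.0 * n_wp)
            p = q * (1 - error_rate) + (1 - q) * error_rate
            total += pd_ * ps * stats.binom.pmf(ok, d, p).sum()
    return float(total)
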