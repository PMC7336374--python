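import numpy as np
import pandas as pd
import pytest

from mutmaplite import EmsVariantSet, GenomeSpec


@pytest.fixture
def genome():
    """30 Mb single-chromosome genome with one 2 kb CDS interval."""
    return GenomeSpec(
        chromosomes=(("chr1", 30_000_000),),
        recomb_rate_cm_per_mb=4.0,
        gene_intervals=(("chr1", 15_000_000, 15_001_999),),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def two_locus_variants(pos1, pos2, chrom1="chr1", chrom2="chr1"):
    """Causal locus + one linked/unlinked marker."""
    order = [chrom1, chrom2]
    if chrom1 == chrom2 and pos2 < pos1:
        raise ValueError("pos2 must follow pos1 on the same chromosome")
    return EmsVariantSet(
        chrom=order,
        pos=[pos1, pos2],
        ref=["C", "C"],
        alt=["T", "T"],
        causal_index=0,
    )


def conditional_allele_freq(r, phenotype):
    """Brute-force enumeration oracle for the bulk allele-frequency laws.

    Enumerates the four ordered gamete types (causal allele, linked
    allele) with probabilities implied by recombination fraction r, pairs
    them into F2 individuals, conditions on phenotype class, and returns
    the expected mutant-allele frequency at the linked locus.
    """
    gametes = [
        (1, 1, (1 - r) / 2),
        (1, 0, r / 2),
        (0, 1, r / 2),
        (0, 0, (1 - r) / 2),
    ]
    num = den = 0.0
    for c1, l1, p1 in gametes:
        for c2, l2, p2 in gametes:
            is_mutant = (c1 + c2) == 2
            if (phenotype == "mutant") != is_mutant:
                continue
            w = p1 * p2
            den += w
            num += w * (l1 + l2) / 2.0
    return num / den


@pytest.fixture
def toy_counts():
    """Three-row allele-count table with hand-computable indices."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1"],
            "pos": [100, 200, 300],
            "ref": ["C", "G", "A"],
            "alt": ["T", "A", "G"],
            "wp_ref_reads": [13, 0, 0],
            "wp_alt_reads": [7, 25, 0],
            "mp_ref_reads": [0, 10, 5],
            "mp_alt_reads": [20, 10, 0],
        }
    )


@pytest.fixture
def toy_cds():
    """60-codon CDS with known landmarks, deterministic content.

    Codon 57 spans CDS positions 169-171 and codon 109 would lie beyond;
    the sequence is long enough for the substitution/indel examples used
    across the annotation tests (CTC at codon 1, CTG at codon 2, TGG at
    codon 3).
    """
    rng = np.random.default_rng(42)
    body = "".join(rng.choice(list("ACGT"), size=180 - 9))
    return "CTC" + "CTG" + "TGG" + body
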