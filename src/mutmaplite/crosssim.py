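"""Forward simulation of a MutMap-style mapping cross.

The model: a fully homozygous EMS mutant line (carrying a set of induced
point mutations, one of which is causal for a fully penetrant recessive
phenotype) is crossed to its non-mutagenized parent.  The F1 is
heterozygous at every induced variant.  F2 individuals are produced by
sampling two independent gametes per individual from a no-interference
(Haldane) crossover process, phenotyped by the recessive rule at the
causal variant, and pooled into two phenotype-selected bulks.  Bulk
sequencing is modelled as Poisson total depth per site with each read
carrying the mutant allele with probability ``q(1-e) + (1-q)e``, where
``q`` is the bulk mutant-allele frequency and ``e`` a per-read miscall
rate.

Haplotypes at marker loci are sampled as a Markov chain along each
chromosome: the phase of the first marker is Bernoulli(1/2) and the
phase switches between adjacent markers at map distance ``d`` Morgans
with probability equal to Haldane's recombination fraction
``r = (1 - exp(-2 d)) / 2``.  Under a Poisson crossover process with no
interference, crossover counts in disjoint intervals are independent
Poisson variables, and the switch indicator between two markers is the
parity of the count in between, i.e. exactly Bernoulli(r), so marker
genotypes are distributionally identical to explicit crossover
simulation while remaining fully vectorizable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MUTANT = "mutant"
WILD_TYPE = "wild_type"

#: EMS predominantly alkylates guanine, producing G:C -> A:T transitions.
EMS_PAIRS = (("G", "A"), ("C", "T"))
_BASES = ("A", "C", "G", "T")
#: Ordered substitution pairs that are *not* the EMS signature.
NON_EMS_PAIRS = tuple(
    (r, a) for r in _BASES for a in _BASES if r != a and (r, a) not in EMS_PAIRS
)

#: Column order of an allele-count table (the pipeline's central input).
COUNT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "wp_ref_reads",
    "wp_alt_reads",
    "mp_ref_reads",
    "mp_alt_reads",
]


def _as_rng(seed) -> np.random.Generator:
    """Accept either a seed or an already-constructed Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome sizes, a uniform genetic map, and optional CDS intervals.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs; order defines sort order.
    recomb_rate_cm_per_mb
        Uniform recombination rate in cM/Mb.  Default 4.0, a rice-like
        order of magnitude (~1500 cM over ~380 Mb).
    gene_intervals
        Optional ``(chrom, start, end)`` 1-based inclusive intervals
        flagged as coding sequence, used to place the causal variant.
    """

    chromosomes: tuple
    recomb_rate_cm_per_mb: float = 4.0
    gene_intervals: tuple = ()

    def __post_init__(self):
        object.__setattr__(
            self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes)
        )
        object.__setattr__(
            self,
            "gene_intervals",
            tuple((str(c), int(s), int(e)) for c, s, e in self.gene_intervals),
        )
        if not self.chromosomes:
            raise ValueError("genome needs at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.recomb_rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")
        lengths = dict(self.chromosomes)
        for chrom, start, end in self.gene_intervals:
            if chrom not in lengths:
                raise ValueError(f"gene interval on unknown chromosome {chrom!r}")
            if not (1 <= start <= end <= lengths[chrom]):
                raise ValueError(
                    f"gene interval {chrom}:{start}-{end} outside chromosome bounds"
                )

    @property
    def chrom_names(self) -> tuple:
        return tuple(name for name, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def morgans_per_bp(self) -> float:
        # cM/Mb -> Morgan/bp: divide by 100 (cM->M) and by 1e6 (Mb->bp)
        return self.recomb_rate_cm_per_mb / 100.0 / 1e6

    def chrom_order(self) -> dict:
        return {name: i for i, name in enumerate(self.chrom_names)}


@dataclass
class EmsVariantSet:
    """Homozygous induced variants private to the mutant line.

    ``causal_index`` points at the single variant whose homozygous
    mutant genotype produces the recessive phenotype.  The alt allele is
    the mutant-line allele at every downstream computation.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    causal_index: int

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n):
            raise ValueError("variant field lengths differ")
        if not 0 <= self.causal_index < n:
            raise ValueError("causal_index out of range")
        if np.any(self.ref == self.alt):
            raise ValueError("ref must differ from alt")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n(self) -> int:
        return len(self.pos)

    @property
    def causal(self) -> tuple:
        i = self.causal_index
        return (self.chrom[i], int(self.pos[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref, "alt": self.alt}
        )
        df["is_causal"] = False
        df.loc[self.causal_index, "is_causal"] = True
        return df


@dataclass
class F2Individual:
    genotype: np.ndarray  # copies of the mutant allele per variant, in {0,1,2}
    phenotype: str


@dataclass
class BulkConfig:
    """Bulk sizes, sequencing depth/error, and the run seed.

    Defaults mirror the mapping design of the study this package
    emulates: two bulks of 30 F2 individuals, ~30x mean depth per bulk.
    """

    n_mp: int = 30
    n_wp: int = 30
    mean_depth: float = 30.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_mp < 1 or self.n_wp < 1:
            raise ValueError("bulk sizes must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class CrossTruth:
    """Simulator ground truth: causal locus, genotypes, bulk membership."""

    causal_chrom: str
    causal_pos: int
    genotypes: np.ndarray  # (n_individuals, n_variants) mutant-allele copies
    phenotypes: np.ndarray
    mp_members: np.ndarray
    wp_members: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Per-individual table: phenotype, bulk membership, genotype string."""
        n = len(self.phenotypes)
        bulk = np.array([""] * n, dtype=object)
        bulk[self.wp_members] = "WP"
        bulk[self.mp_members] = "MP"
        geno = ["".join(str(g) for g in row) for row in self.genotypes]
        return pd.DataFrame(
            {
                "individual": np.arange(n),
                "phenotype": self.phenotypes,
                "bulk": bulk,
                "genotypes": geno,
            }
        )


def simulate_ems_variants(
    genome: GenomeSpec,
    n_variants: int,
    spectrum_fraction: float = 1.0,
    seed=None,
) -> EmsVariantSet:
    """Draw induced point mutations over the genome.

    ``spectrum_fraction`` of the variants carry the EMS signature
    (G->A or C->T); the remainder are drawn uniformly from the other
    ten ordered substitutions.  Exactly one variant is flagged causal
    and placed inside a CDS interval of the genome (its nonsynonymous
    coding context is established by the companion synthetic gene-model
    builder, ``pipeline.build_causal_gene_model``).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not 0.0 <= spectrum_fraction <= 1.0:
        raise ValueError("spectrum_fraction must be in [0, 1]")
    eligible = [iv for iv in genome.gene_intervals if iv[2] - iv[1] + 1 >= 3]
    if not eligible:
        raise ValueError(
            "no CDS interval of >= 3 bp in the genome; cannot place a coding "
            "causal variant (misconfigured genome)"
        )
    rng = _as_rng(seed)

    # causal variant: EMS-type substitution inside a CDS interval
    c_chrom, c_start, c_end = eligible[rng.integers(len(eligible))]
    c_pos = int(rng.integers(c_start, c_end + 1))
    c_ref, c_alt = EMS_PAIRS[rng.integers(len(EMS_PAIRS))]

    # background variants: chromosome chosen proportional to length
    names = list(genome.chrom_names)
    lengths = np.array([genome.length(c) for c in names], dtype=float)
    weights = lengths / lengths.sum()
    taken = {(c_chrom, c_pos)}
    chroms, positions = [], []
    n_bg = n_variants - 1
    while len(positions) < n_bg:
        k = n_bg - len(positions)
        ci = rng.choice(len(names), size=k, p=weights)
        ps = rng.integers(1, lengths[ci].astype(np.int64) + 1)
        for i, p in zip(ci, ps):
            key = (names[i], int(p))
            if key in taken:
                continue
            taken.add(key)
            chroms.append(names[i])
            positions.append(int(p))

    is_ems = rng.random(n_bg) < spectrum_fraction
    pair_idx_ems = rng.integers(len(EMS_PAIRS), size=n_bg)
    pair_idx_other = rng.integers(len(NON_EMS_PAIRS), size=n_bg)
    refs, alts = [], []
    for j in range(n_bg):
        r, a = (
            EMS_PAIRS[pair_idx_ems[j]]
            if is_ems[j]
            else NON_EMS_PAIRS[pair_idx_other[j]]
        )
        refs.append(r)
        alts.append(a)

    chroms.append(c_chrom)
    positions.append(c_pos)
    refs.append(c_ref)
    alts.append(c_alt)

    order = genome.chrom_order()
    idx = sorted(range(n_variants), key=lambda i: (order[chroms[i]], positions[i]))
    causal_index = idx.index(n_variants - 1)
    return EmsVariantSet(
        chrom=np.array([chroms[i] for i in idx], dtype=object),
        pos=np.array([positions[i] for i in idx], dtype=np.int64),
        ref=np.array([refs[i] for i in idx], dtype=object),
        alt=np.array([alts[i] for i in idx], dtype=object),
        causal_index=causal_index,
    )


def haldane_r(d_morgans):
    """Haldane map function: recombination fraction at map distance d."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


def simulate_gametes(
    variants: EmsVariantSet, genome: GenomeSpec, n: int, rng
) -> np.ndarray:
    """Sample ``n`` F1 gametes; returns (n, n_variants) array of 0/1.

    1 encodes the mutant-line allele.  Within each chromosome the
    haplotype phase switches between adjacent variants with Haldane
    probability; chromosomes assort independently.
    """
    rng = _as_rng(rng)
    m = variants.n
    out = np.empty((n, m), dtype=np.int8)
    mpb = genome.morgans_per_bp
    for chrom in genome.chrom_names:
        cols = np.flatnonzero(variants.chrom == chrom)
        if cols.size == 0:
            continue
        d = variants.pos[cols] * mpb
        r = haldane_r(np.diff(d))
        bits = np.empty((n, cols.size), dtype=np.int8)
        bits[:, 0] = rng.integers(0, 2, size=n, dtype=np.int8)
        if cols.size > 1:
            bits[:, 1:] = rng.random((n, cols.size - 1)) < r
        out[:, cols] = np.bitwise_xor.accumulate(bits, axis=1)
    return out


def simulate_f2_population(
    variants: EmsVariantSet, genome: GenomeSpec, n: int, rng
) -> np.ndarray:
    """Genotypes of ``n`` F2 individuals: sum of two independent gametes."""
    rng = _as_rng(rng)
    return simulate_gametes(variants, genome, n, rng) + simulate_gametes(
        variants, genome, n, rng
    )


def assign_phenotype(genotype, causal_index: int) -> str:
    """Fully penetrant recessive rule: mutant iff homozygous at the causal locus."""
    return MUTANT if int(np.asarray(genotype)[causal_index]) == 2 else WILD_TYPE


def assign_phenotypes(genotypes: np.ndarray, causal_index: int) -> np.ndarray:
    return np.where(genotypes[:, causal_index] == 2, MUTANT, WILD_TYPE).astype(object)


def simulate_f2_individual(
    variants: EmsVariantSet, genome: GenomeSpec, rng
) -> F2Individual:
    genotype = simulate_f2_population(variants, genome, 1, rng)[0]
    return F2Individual(
        genotype=genotype, phenotype=assign_phenotype(genotype, variants.causal_index)
    )


def sample_bulks(phenotypes: np.ndarray, config: BulkConfig, rng):
    """Sample bulk members without replacement within each phenotype class."""
    rng = _as_rng(rng)
    members = {}
    for label, size in ((MUTANT, config.n_mp), (WILD_TYPE, config.n_wp)):
        pool = np.flatnonzero(np.asarray(phenotypes, dtype=object) == label)
        if pool.size < size:
            raise ValueError(
                f"cannot fill {label} bulk: need {size} individuals, "
                f"population has {pool.size}"
            )
        members[label] = np.sort(rng.choice(pool, size=size, replace=False))
    return members[MUTANT], members[WILD_TYPE]


def simulate_allele_counts(
    genotypes: np.ndarray,
    mp_members: np.ndarray,
    wp_members: np.ndarray,
    variants: EmsVariantSet,
    config: BulkConfig,
    rng,
) -> pd.DataFrame:
    """Sequencing counts per bulk: Poisson total depth, binomial alt reads.

    Zero-depth sites are emitted with zero counts; the depth filter
    downstream is the single place coverage decisions happen.
    """
    rng = _as_rng(rng)
    m = variants.n
    rows = {"chrom": variants.chrom, "pos": variants.pos,
            "ref": variants.ref, "alt": variants.alt}
    e = config.error_rate
    for prefix, members in (("wp", wp_members), ("mp", mp_members)):
        q = genotypes[members].sum(axis=0) / (2.0 * len(members))
        p = q * (1.0 - e) + (1.0 - q) * e
        depth = rng.poisson(config.mean_depth, size=m)
        alt = rng.binomial(depth, p)
        rows[f"{prefix}_ref_reads"] = depth - alt
        rows[f"{prefix}_alt_reads"] = alt
    df = pd.DataFrame(rows)[COUNT_COLUMNS]
    df["pos"] = df["pos"].astype(np.int64)
    return df


@dataclass
class CrossResult:
    counts: pd.DataFrame
    truth: CrossTruth
    variants: EmsVariantSet


def simulate_cross(
    genome: GenomeSpec,
    n_variants: int = 300,
    spectrum_fraction: float = 1.0,
    population_size: int = 208,
    config: BulkConfig | None = None,
    variants: EmsVariantSet | None = None,
    fixed_class_counts: tuple | None = None,
) -> CrossResult:
    """Run the full forward simulation from one seed.

    The F2 population segregates freely (expected 3 wild-type : 1
    mutant); if a phenotype class is smaller than its bulk, additional
    batches of ``population_size`` individuals are simulated until both
    bulks can be filled.  ``fixed_class_counts=(n_wp, n_mp)`` instead
    accumulates individuals until exactly those class totals are
    reached (e.g. ``(164, 44)`` to match a particular observed cross).
    """
    config = config or BulkConfig()
    rng = np.random.default_rng(config.seed)
    if variants is None:
        variants = simulate_ems_variants(
            genome, n_variants, spectrum_fraction, seed=rng
        )

    genotypes = simulate_f2_population(variants, genome, population_size, rng)
    phenotypes = assign_phenotypes(genotypes, variants.causal_index)

    if fixed_class_counts is not None:
        target_wp, target_mp = fixed_class_counts
        kept_wp = kept_mp = 0
        batches = 0
        # accumulate in simulation order until both class totals reached
        sel = []
        for i, ph in enumerate(phenotypes):
            if ph == WILD_TYPE and kept_wp < target_wp:
                sel.append(i)
                kept_wp += 1
            elif ph == MUTANT and kept_mp < target_mp:
                sel.append(i)
                kept_mp += 1
        while kept_wp < target_wp or kept_mp < target_mp:
            batches += 1
            if batches > 200:
                raise RuntimeError("could not reach requested class counts")
            extra = simulate_f2_population(variants, genome, population_size, rng)
            extra_ph = assign_phenotypes(extra, variants.causal_index)
            base = len(phenotypes)
            genotypes = np.vstack([genotypes, extra])
            phenotypes = np.concatenate([phenotypes, extra_ph])
            for i, ph in enumerate(extra_ph, start=base):
                if ph == WILD_TYPE and kept_wp < target_wp:
                    sel.append(i)
                    kept_wp += 1
                elif ph == MUTANT and kept_mp < target_mp:
                    sel.append(i)
                    kept_mp += 1
        genotypes = genotypes[np.array(sel)]
        phenotypes = phenotypes[np.array(sel)]
    else:
        batches = 0
        while (
            np.count_nonzero(phenotypes == MUTANT) < config.n_mp
            or np.count_nonzero(phenotypes == WILD_TYPE) < config.n_wp
        ):
            batches += 1
            if batches > 200:
                raise RuntimeError("could not fill bulks from the F2 population")
            extra = simulate_f2_population(variants, genome, population_size, rng)
            genotypes = np.vstack([genotypes, extra])
            phenotypes = np.concatenate(
                [phenotypes, assign_phenotypes(extra, variants.causal_index)]
            )

    mp_members, wp_members = sample_bulks(phenotypes, config, rng)
    counts = simulate_allele_counts(
        genotypes, mp_members, wp_members, variants, config, rng
    )
    causal_chrom, causal_pos = variants.causal
    truth = CrossTruth(
        causal_chrom=causal_chrom,
        causal_pos=causal_pos,
        genotypes=genotypes,
        phenotypes=phenotypes,
        mp_members=mp_members,
        wp_members=wp_members,
        seed=config.seed,
    )
    return CrossResult(counts=counts, truth=truth, variants=variants)
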