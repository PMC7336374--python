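"""Variant classification against gene models and coding-effect arithmetic.

Region classes follow the usual annotator vocabulary (exonic, UTR,
intronic, upstream/downstream within a configurable flank, intergenic)
with precedence exonic > UTR > intronic > up/downstream > intergenic.
Coding effects are computed on the spliced, transcript-oriented CDS:
substitutions by codon replacement under the standard genetic code,
indels by rebuilding the mutated CDS and re-translating from codon 1.

Conventions: genomic coordinates are 1-based inclusive (GFF3/VCF);
CDS positions are 1-based offsets into the spliced CDS; the codon index
of CDS position p is floor((p-1)/3) + 1, so e.g. CDS position 745 lies
in codon 249.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

REGION_CLASSES = (
    "exonic", "UTR5", "UTR3", "intronic", "upstream", "downstream", "intergenic",
)
_PRECEDENCE = {
    "exonic": 0, "UTR5": 1, "UTR3": 1, "intronic": 2,
    "upstream": 3, "downstream": 3, "intergenic": 4,
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class GeneModel:
    """Strand-aware spliced CDS with genomic intervals.

    ``cds_intervals`` are genomic, 1-based inclusive, stored in
    ascending genomic order; transcript orientation is derived from
    ``strand``.  ``cds_sequence`` (optional) is the spliced CDS in
    transcript orientation.  ``complete=True`` additionally asserts a
    start codon at the 5' end and a stop codon at the 3' end.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple
    utr5_intervals: tuple = ()
    utr3_intervals: tuple = ()
    cds_sequence: str | None = None
    complete: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        ivs = sorted((int(s), int(e)) for s, e in self.cds_intervals)
        for s, e in ivs:
            if s > e:
                raise ValueError(f"bad CDS interval {s}-{e}")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError("CDS intervals overlap")
        self.cds_intervals = tuple(ivs)
        self.utr5_intervals = tuple(sorted((int(s), int(e)) for s, e in self.utr5_intervals))
        self.utr3_intervals = tuple(sorted((int(s), int(e)) for s, e in self.utr3_intervals))
        if self.cds_sequence is not None:
            self.cds_sequence = self.cds_sequence.upper()
            if len(self.cds_sequence) != self.cds_length:
                raise ValueError("cds_sequence length does not match intervals")
            if len(self.cds_sequence) % 3 != 0:
                raise ValueError("CDS length must be divisible by 3")
            if self.complete:
                if self.cds_sequence[:3] != "ATG":
                    raise ValueError("complete CDS must start with ATG")
                if self.cds_sequence[-3:] not in ("TAA", "TAG", "TGA"):
                    raise ValueError("complete CDS must end with a stop codon")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple:
        ivs = self.cds_intervals + self.utr5_intervals + self.utr3_intervals
        return min(s for s, _ in ivs), max(e for _, e in ivs)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcript 5' end."""
        s, e = self.span
        return s if self.strand == "+" else e

    def transcript_order_cds(self) -> tuple:
        return self.cds_intervals if self.strand == "+" else tuple(reversed(self.cds_intervals))


@dataclass
class RegionClass:
    region: str
    gene_id: str | None = None


@dataclass
class CodingEffect:
    cds_pos: int
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    category: str  # synonymous | nonsynonymous | stop_gain | frameshift
    first_shifted_codon: int | None = None
    premature_stop: int | None = None


def _contains(intervals, pos: int) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def index_gene_models(
    models: Sequence[GeneModel], chromosomes: Iterable[str] = ()
) -> dict:
    """Group models by chromosome; extra chromosome names get empty lists."""
    by_chrom: dict = {c: [] for c in chromosomes}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    return by_chrom


def locate_variant(
    chrom: str,
    pos: int,
    gene_models: Mapping[str, Sequence[GeneModel]] | Sequence[GeneModel],
    flank_bp: int = 1000,
) -> RegionClass:
    """Classify a genomic position against a set of gene models.

    Precedence: exonic > UTR > intronic > upstream/downstream (within
    ``flank_bp`` of the gene span, strand-aware) > intergenic.  Ties
    across genes at equal precedence go to the nearest transcript start,
    then to the lexicographically smallest gene id.
    """
    if isinstance(gene_models, Mapping):
        if chrom not in gene_models:
            raise KeyError(f"unknown chromosome {chrom!r}")
        models = gene_models[chrom]
    else:
        models = [m for m in gene_models if m.chrom == chrom]
        if not models and not any(True for _ in gene_models):
            raise KeyError(f"unknown chromosome {chrom!r}")

    best = None  # (precedence, distance-to-tss, gene_id, region)
    for m in models:
        span_s, span_e = m.span
        if _contains(m.cds_intervals, pos):
            region = "exonic"
        elif _contains(m.utr5_intervals, pos):
            region = "UTR5"
        elif _contains(m.utr3_intervals, pos):
            region = "UTR3"
        elif span_s <= pos <= span_e:
            region = "intronic"
        else:
            if pos < span_s:
                side_up = m.strand == "+"
                dist = span_s - pos
            else:
                side_up = m.strand == "-"
                dist = pos - span_e
            if dist > flank_bp:
                continue
            region = "upstream" if side_up else "downstream"
        key = (_PRECEDENCE[region], abs(pos - m.tss), m.gene_id, region)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is None:
        return RegionClass(region="intergenic", gene_id=None)
    return RegionClass(region=best[3], gene_id=best[2])


def cds_position(pos: int, model: GeneModel) -> int:
    """1-based offset of a genomic position into the spliced CDS.

    Counted from the transcript 5' end; for minus-strand genes callers
    must complement alleles before comparing to the CDS sequence.
    """
    offset = 0
    for s, e in model.transcript_order_cds():
        if s <= pos <= e:
            within = (pos - s + 1) if model.strand == "+" else (e - pos + 1)
            return offset + within
        offset += e - s + 1
    raise ValueError(f"position {pos} not in any CDS interval of {model.gene_id}")


def codon_index(cds_pos: int) -> int:
    if cds_pos < 1:
        raise ValueError("cds_pos must be >= 1")
    return (cds_pos - 1) // 3 + 1


def _translate(cds: str) -> str:
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def classify_substitution(
    cds_sequence: str, cds_pos: int, ref: str, alt: str
) -> CodingEffect:
    """Coding effect of a single-base substitution in transcript coordinates."""
    cds_sequence = cds_sequence.upper()
    ref, alt = ref.upper(), alt.upper()
    if not 1 <= cds_pos <= len(cds_sequence):
        raise ValueError("cds_pos outside CDS")
    if cds_sequence[cds_pos - 1] != ref:
        raise ValueError(
            f"reference mismatch at CDS position {cds_pos}: "
            f"sequence has {cds_sequence[cds_pos - 1]}, variant says {ref} "
            "(coordinate or strand error?)"
        )
    ci = codon_index(cds_pos)
    start = 3 * (ci - 1)
    ref_codon = cds_sequence[start : start + 3]
    within = cds_pos - 1 - start
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    if ref_aa == alt_aa and ref_aa != "*":
        category = "synonymous"
    elif alt_aa == "*" and ref_aa != "*":
        category = "stop_gain"
    else:
        category = "nonsynonymous"
    return CodingEffect(
        cds_pos=cds_pos, codon_index=ci, ref_codon=ref_codon, alt_codon=alt_codon,
        ref_aa=ref_aa, alt_aa=alt_aa, category=category,
    )


def classify_indel(
    cds_sequence: str,
    cds_pos: int,
    insert: str | None = None,
    delete: int | None = None,
) -> CodingEffect:
    """Coding effect of an insertion (after ``cds_pos``) or deletion (at it).

    The mutated CDS is rebuilt and re-translated from codon 1.  For
    frameshifts the effect carries the codon containing the edit point,
    the first codon whose amino acid differs from the reference
    translation, and the codon index of the first stop in the mutated
    frame (None if the shifted frame never hits one).  In-frame indels
    (length divisible by 3) are categorized nonsynonymous: the protein
    changes but the frame is preserved.
    """
    cds_sequence = cds_sequence.upper()
    if (insert is None) == (delete is None):
        raise ValueError("specify exactly one of insert= or delete=")
    if insert is not None:
        if not 0 <= cds_pos <= len(cds_sequence):
            raise ValueError("insertion point outside CDS")
        insert = insert.upper()
        mutated = cds_sequence[:cds_pos] + insert + cds_sequence[cds_pos:]
        delta = len(insert)
    else:
        if delete < 1 or cds_pos < 1 or cds_pos + delete - 1 > len(cds_sequence):
            raise ValueError("deletion outside CDS bounds")
        mutated = cds_sequence[: cds_pos - 1] + cds_sequence[cds_pos - 1 + delete :]
        delta = delete

    edit_pos = max(cds_pos, 1)
    ci = codon_index(edit_pos)
    start = 3 * (ci - 1)
    ref_codon = cds_sequence[start : start + 3]
    alt_codon = mutated[start : start + 3]

    ref_prot = _translate(cds_sequence)
    alt_prot = _translate(mutated)

    first_shift = None
    for i in range(min(len(ref_prot), len(alt_prot))):
        if ref_prot[i] != alt_prot[i]:
            first_shift = i + 1
            break
    if first_shift is None and len(ref_prot) != len(alt_prot):
        first_shift = min(len(ref_prot), len(alt_prot)) + 1

    stop = alt_prot.find("*")
    premature = stop + 1 if stop != -1 else None

    category = "frameshift" if delta % 3 != 0 else "nonsynonymous"
    return CodingEffect(
        cds_pos=edit_pos,
        codon_index=ci,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=_translate(ref_codon) if ref_codon else "",
        alt_aa=_translate(alt_codon) if len(alt_codon) == 3 else "",
        category=category,
        first_shifted_codon=first_shift,
        premature_stop=premature,
    )


def annotate_table(
    records: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    flank_bp: int = 1000,
    chromosomes: Iterable[str] = (),
) -> pd.DataFrame:
    """Region class + coding effect for every (chrom, pos, ref, alt) record.

    Produces a table joinable to the SNP-index table by (chrom, pos):
    columns chrom, pos, region_class, gene_id, effect.  Effects are
    computed only for exonic variants of models that carry a CDS
    sequence; minus-strand alleles are complemented before comparison.
    """
    by_chrom = index_gene_models(gene_models, chromosomes)
    rows = []
    models_by_id = {m.gene_id: m for m in gene_models}
    for rec in records.itertuples(index=False):
        loc = locate_variant(rec.chrom, int(rec.pos), by_chrom, flank_bp=flank_bp)
        effect = None
        if loc.region == "exonic":
            model = models_by_id[loc.gene_id]
            if model.cds_sequence is not None:
                cpos = cds_position(int(rec.pos), model)
                ref, alt = rec.ref, rec.alt
                if model.strand == "-":
                    ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
                effect = classify_substitution(
                    model.cds_sequence, cpos, ref, alt
                ).category
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": int(rec.pos),
                "region_class": loc.region,
                "gene_id": loc.gene_id,
                "effect": effect,
            }
        )
    return pd.DataFrame(rows)


def read_gene_models(gff_path: str, fasta_path: str | None = None) -> list[GeneModel]:
    """Load gene models from GFF3 (one model per mRNA/transcript).

    CDS and UTR children are collected per transcript; when a FASTA is
    given, the spliced CDS sequence is extracted (reverse-complemented
    for minus-strand genes).
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    fasta = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(fasta_path))

    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not cds:
            continue
        utr5 = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype=("five_prime_UTR", "5UTR"))
        ]
        utr3 = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype=("three_prime_UTR", "3UTR"))
        ]
        seq = None
        if fasta is not None:
            pieces = [str(fasta[mrna.seqid][s - 1 : e]) for s, e in sorted(cds)]
            seq = "".join(pieces).upper()
            if mrna.strand == "-":
                seq = revcomp(seq)
        models.append(
            GeneModel(
                gene_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                cds_intervals=tuple(sorted(cds)),
                utr5_intervals=tuple(utr5),
                utr3_intervals=tuple(utr3),
                cds_sequence=seq,
            )
        )
    return models


def write_gene_models_gff3(models: Sequence[GeneModel], path: str) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/CDS/UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            fh.write(
                f"{m.chrom}\tmutmaplite\tgene\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID=gene:{m.gene_id}\n"
            )
            fh.write(
                f"{m.chrom}\tmutmaplite\tmRNA\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent=gene:{m.gene_id}\n"
            )
            phase_pos = 0
            for cs, ce in m.transcript_order_cds():
                phase = (3 - phase_pos % 3) % 3
                fh.write(
                    f"{m.chrom}\tmutmaplite\tCDS\t{cs}\t{ce}\t.\t{m.strand}\t{phase}\t"
                    f"ID=cds:{m.gene_id};Parent={m.gene_id}\n"
                )
                phase_pos += ce - cs + 1
            for kind, ivs in (("five_prime_UTR", m.utr5_intervals),
                              ("three_prime_UTR", m.utr3_intervals)):
                for us, ue in ivs:
                    fh.write(
                        f"{m.chrom}\tmutmaplite\t{kind}\t{us}\t{ue}\t.\t{m.strand}\t.\t"
                        f"Parent={m.gene_id}\n"
                    )
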