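"""Packaged worked example: the ten chromosome-12 SNPs with MP index 1.

The fixture encodes the published candidate table of the rice floral
mutant mapping it reproduces: ten SNPs whose mutant-bulk SNP index is 1,
with their wild-type-bulk indices, region classes, associated ORFs and
synonymous/nonsynonymous calls.  Read depths were not published, so the
records carry indices only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

TABLE1_CHROM = "chr12"

_REGION_MAP = {
    "Exonic": "exonic",
    "Intronic": "intronic",
    "Downstream": "downstream",
    "Upstream": "upstream",
    "Intergenic": "intergenic",
}
_EFFECT_MAP = {"NS": "nonsynonymous", "S": "synonymous"}


@dataclass
class Table1Fixture:
    frame: pd.DataFrame  # pos, ref, alt, wp_index, mp_index, region, orf, mutation_type

    def records(self) -> pd.DataFrame:
        """SNP-index records (depths unknown -> NaN), sorted by position."""
        f = self.frame.sort_values("pos")
        return pd.DataFrame(
            {
                "chrom": TABLE1_CHROM,
                "pos": f["pos"].to_numpy(),
                "ref": f["ref"].to_numpy(),
                "alt": f["alt"].to_numpy(),
                "wp_index": f["wp_index"].to_numpy(dtype=float),
                "mp_index": f["mp_index"].to_numpy(dtype=float),
                "wp_depth": np.nan,
                "mp_depth": np.nan,
                "wp_alt_reads": np.nan,
                "mp_alt_reads": np.nan,
            }
        ).reset_index(drop=True)

    def annotations(self) -> pd.DataFrame:
        """Annotation table joinable to the records by (chrom, pos)."""
        f = self.frame.sort_values("pos")
        return pd.DataFrame(
            {
                "chrom": TABLE1_CHROM,
                "pos": f["pos"].to_numpy(),
                "region_class": f["region"].map(_REGION_MAP).to_numpy(),
                "gene_id": f["orf"].to_numpy(),
                "effect": f["mutation_type"].map(_EFFECT_MAP).to_numpy(),
            }
        ).reset_index(drop=True)


def load_table1() -> Table1Fixture:
    """Load and validate the packaged fixture."""
    with resources.files("mutmaplite.data").joinpath("table1.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype={"orf": "string"})
    frame["orf"] = frame["orf"].where(frame["orf"].notna(), None)
    if len(frame) != 10:
        raise ValueError("fixture must have exactly 10 rows")
    if not (frame["mp_index"] == 1).all():
        raise ValueError("all MP indices must be 1")
    if (frame["mutation_type"] == "NS").sum() != 2:
        raise ValueError("exactly 2 rows must be nonsynonymous")
    in_region = frame["pos"].between(23_000_000, 27_000_000)
    with_orf = frame["orf"].notna()
    if int((in_region & with_orf).sum()) != 5 or int(in_region.sum()) != 6:
        raise ValueError("candidate-region composition does not match the table")
    return Table1Fixture(frame=frame)
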