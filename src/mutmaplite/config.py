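"""Run configuration: every tunable of the pipeline in one flat namespace.

A config can be loaded from a plain-text ``key = value`` file; unknown
keys are rejected.  Precedence is CLI > config file > defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields


@dataclass
class RunConfig:
    # simulator
    chrom_name: str = "chr1"
    chrom_length: int = 30_000_000
    recomb_rate_cm_per_mb: float = 4.0
    gene_length: int = 2_000
    n_snps: int = 300
    spectrum_fraction: float = 1.0
    population_size: int = 208
    n_mp: int = 30
    n_wp: int = 30
    mean_depth: float = 30.0
    error_rate: float = 0.005
    # windows / regions
    window_bp: int = 1_000_000
    step_bp: int = 1_000
    region_threshold: float = 0.9
    min_region_windows: int = 10
    # candidate filter
    min_depth: int = 10
    mp_min_index: float = 1.0
    mp_tolerance: float = 0.1
    wp_target: float = 1 / 3
    wp_band_lo: float = 0.1
    wp_band_hi: float = 0.6
    alpha: float = 0.01
    require_nonsynonymous: bool = True
    # annotation
    flank_bp: int = 1_000
    # reproducibility
    seed: int = 0

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        values = {}
        known = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = _coerce(val, known[key].type)
        values.update(overrides)
        return cls(**values)

    def to_text(self) -> str:
        return "\n".join(
            f"{f.name} = {getattr(self, f.name)}" for f in fields(self)
        )

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def _coerce(val: str, typ) -> object:
    name = typ if isinstance(typ, str) else getattr(typ, "__name__", str(typ))
    if name == "bool":
        if val.lower() in ("true", "1", "yes"):
            return True
        if val.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot parse boolean {val!r}")
    if name == "int":
        return int(val)
    if name == "float":
        return float(val)
    return val
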