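"""Run configuration: every tunable parameter of the pipeline in one place.

The effective configuration is echoed into every output header and into the
log, so each number in a report can be regenerated by calling the
corresponding module operation with the logged parameters.  Serialising a
config and rerunning from the serialised file reproduces the outputs — there
are no hidden defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Union

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # two-pass binding-site scan
    seed_pattern: str = "TCGATAAATT"  # E. coli-type high-affinity site; user-overridable
    max_mismatches: int = 2
    consensus_threshold: float = 0.65
    # GC tiling
    gc_window: int = 1000
    gc_threshold: float = 55.0
    # operons / regulon
    operon_max_gap: int = 100
    upstream: int = 250
    # tetranucleotide binning
    tetra_window: int = 2000
    k: int = 3
    kmeans_max_iter: int = 20
    # genotype comparison
    snp_window: int = 250
    dnds_correction: str = "jukes_cantor"
    # global
    seed: int = 0

    def to_file(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}: {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
                key, _, value = line.partition(":")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
                kwargs[key] = value
        return cls(**{k: _coerce(cls, k, v) for k, v in kwargs.items()})

    def header_lines(self) -> list[str]:
        return [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]


def _coerce(cls: type, key: str, value: str):
    default = getattr(cls(), key)
    if isinstance(default, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(value)
    if isinstance(default, float):
        return float(value)
    return value
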