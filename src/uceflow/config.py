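"""Pipeline configuration.

All thresholds that drive the enrichment workflow live in one frozen-by-default
object.  Numeric defaults are the workflow's published operating point: a
conserved core must exceed 80 bp, cores are buffered to 180 bp for probe
design, 120-bp probes are tiled at 4x density, locus matches must span at
least 120 bp at >= 80% identity, retained loci must sit more than 10 kbp
apart, and species-tree inputs are restricted to loci of at least 50 bp.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class PipelineConfig:
    min_conserved_len: int = 80          # strict greater-than threshold, bp
    buffer_len: int = 180                # bp, probe-design target length
    probe_len: int = 120                 # bp
    tiling_density: int = 4              # probes per locus
    min_match_len: int = 120             # bp, locus-match acceptance
    min_identity: float = 0.80           # fraction, locus-match acceptance
    min_spacing: int = 10_000            # bp, edge-to-edge inter-locus gap
    min_locus_len_genetrees: int = 50    # bp, gene-tree locus floor
    required_taxa: list[str] = field(default_factory=list)
    bootstrap_reps: int = 1000
    collapse_threshold: float = 0.50     # fraction, node-support collapse
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.probe_len > self.buffer_len:
            raise ConfigError(
                f"probe_len ({self.probe_len}) must not exceed "
                f"buffer_len ({self.buffer_len})"
            )
        if self.tiling_density < 1:
            raise ConfigError("tiling_density must be >= 1")
        if not 0.0 < self.min_identity <= 1.0:
            raise ConfigError("min_identity must be in (0, 1]")
        if not 0.0 <= self.collapse_threshold <= 1.0:
            raise ConfigError("collapse_threshold must be in [0, 1]")
        for name in ("min_conserved_len", "buffer_len", "probe_len",
                     "min_match_len", "min_spacing",
                     "min_locus_len_genetrees", "bootstrap_reps"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    # -- flat key=value (de)serialization ------------------------------------

    _LIST_FIELDS = ("required_taxa",)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat ``key = value`` file; unspecified keys keep defaults."""
        overrides: dict[str, object] = {}
        known = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            overrides[key] = cls._parse_value(key, value)
        return cls(**overrides)

    @classmethod
    def _parse_value(cls, key: str, value: str) -> object:
        if key in cls._LIST_FIELDS:
            return [tok for tok in value.replace(",", " ").split() if tok]
        hint = {f.name: f.type for f in dataclasses.fields(cls)}[key]
        if "float" in str(hint):
            return float(value)
        return int(value)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name in self._LIST_FIELDS:
                value = ",".join(value)
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)
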