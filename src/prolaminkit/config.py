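"""Run configuration: every threshold the pipeline applies, in one place.

Defaults are the conventional values for this kind of analysis: an
e-value cutoff of 1e-10 for the homology search, and the three tandem
rules at < 100 kb distance, > 70% coverage, > 70% identity. A YAML file
can override any field; CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .duplication import (TANDEM_MAX_DISTANCE, TANDEM_MIN_COVERAGE,
                          TANDEM_MIN_IDENTITY)
from .errors import InputError, ParameterError
from .homology import ScanParams


@dataclass
class RunConfig:
    # inputs
    genome_fasta: str = ""
    gff3: str = ""
    queries_fasta: str = ""
    counts_tsv: str = ""
    lengths_tsv: str = ""
    samples_tsv: str = ""
    epitope_table: str = ""       # empty -> built-in six-epitope set
    # homology scan
    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    evalue_cutoff: float = 1e-10
    merge_gap: int = 2000
    orf_flank: int = 1000
    # tandem rules
    tandem_max_distance: int = TANDEM_MAX_DISTANCE
    tandem_min_coverage: float = TANDEM_MIN_COVERAGE
    tandem_min_identity: float = TANDEM_MIN_IDENTITY
    # synteny
    anchor_min_identity: float = 50.0
    # expression pattern thresholds
    pattern_drop_frac: float = 0.2
    pattern_flat_ratio: float = 1.5
    # run
    genome_label: str = "E"
    out_dir: str = "prolaminkit_out"
    seed: int = 1

    def __post_init__(self) -> None:
        if not 8 <= self.k <= 16:
            raise ParameterError(f"k={self.k} outside [8, 16]")
        if self.evalue_cutoff <= 0:
            raise ParameterError("evalue_cutoff must be > 0")
        if self.tandem_max_distance <= 0:
            raise ParameterError("tandem_max_distance must be > 0")
        for name in ("tandem_min_coverage", "tandem_min_identity"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ParameterError(f"{name}={v} outside [0, 100]")

    def scan_params(self) -> ScanParams:
        return ScanParams(k=self.k, match=self.match, mismatch=self.mismatch,
                          gap_open=self.gap_open, gap_extend=self.gap_extend,
                          evalue_cutoff=self.evalue_cutoff)

    def thresholds(self) -> dict[str, float]:
        """The values worth logging with every run."""
        return {
            "evalue_cutoff": self.evalue_cutoff,
            "tandem_max_distance_bp": self.tandem_max_distance,
            "tandem_min_coverage_pct": self.tandem_min_coverage,
            "tandem_min_identity_pct": self.tandem_min_identity,
            "anchor_min_identity_pct": self.anchor_min_identity,
            "pattern_drop_frac": self.pattern_drop_frac,
            "pattern_flat_ratio": self.pattern_flat_ratio,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
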