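"""Run configuration: thresholds and input paths.

Every cutoff is configurable but defaults to the published search
protocol; threshold comparisons are exact decimal contracts (boundary
values pass), never epsilon-fuzzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = ["Thresholds", "RunConfig", "ConfigError", "DEFAULT_THRESHOLDS"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class Thresholds:
    """Acceptance filters, decision-tree margins and overlap rules.

    evalue_max        full-sequence E-value ceiling (HMM-based methods)
    zscore_min        profile-profile Z-score floor
    pvalue_max        threading P-value ceiling (with tag CERTAIN)
    coverage_min      query-length coverage floor where a method demands it
    link_zscore_min   Z floor for family-family links feeding indirect mappings
    link_coverage_min coverage floor (both sides) for those links
    evalue_count_margin   hit-count lead required across folds, strict (>)
    zscore_fold_margin    best-Z lead across folds within a class (>=)
    zscore_class_margin   best-Z lead across classes (>=)
    overlap_frac      fraction of either region that must be covered for
                      two domain regions to count as the same region
    ic_min            information-content floor for transferred GO terms
    """

    evalue_max: float = 1e-3
    zscore_min: float = 7.5
    pvalue_max: float = 1e-5
    coverage_min: float = 0.60
    link_zscore_min: float = 9.0
    link_coverage_min: float = 0.80
    evalue_count_margin: int = 10
    zscore_fold_margin: float = 4.0
    zscore_class_margin: float = 6.0
    overlap_frac: float = 0.60
    ic_min: float = 1.5

    def __post_init__(self) -> None:
        for name in ("evalue_max", "zscore_min", "pvalue_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("coverage_min", "link_coverage_min", "overlap_frac"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ConfigError(f"{name} must be in (0, 1], got {value}")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.

    Any method input may be omitted; the pipeline then simply runs on the
    methods that are present.  ``nrichd_domtbl`` is a list because pooled
    hmmsearch/jackhmmer passes arrive as separate tables.
    """

    catalog: Path
    families: Path
    out_dir: Path
    nrichd_domtbl: list[Path] = field(default_factory=list)
    superfamily_domtbl: Optional[Path] = None
    hhsearch_dir: Optional[Path] = None
    supfam_plus_table: Optional[Path] = None
    pdomthreader_table: Optional[Path] = None
    family_links: Optional[Path] = None
    direct_map: Optional[Path] = None
    dcgo_table: Optional[Path] = None
    pdb_ec_table: Optional[Path] = None
    pdb_scop_table: Optional[Path] = None
    tax_nodes: Optional[Path] = None
    tax_names: Optional[Path] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        self.catalog = Path(self.catalog)
        self.families = Path(self.families)
        self.out_dir = Path(self.out_dir)
        self.nrichd_domtbl = [Path(p) for p in self.nrichd_domtbl]
        for name in (
            "superfamily_domtbl",
            "hhsearch_dir",
            "supfam_plus_table",
            "pdomthreader_table",
            "family_links",
            "direct_map",
            "dcgo_table",
            "pdb_ec_table",
            "pdb_scop_table",
            "tax_nodes",
            "tax_names",
        ):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    def validate(self) -> None:
        """Check that every configured input path exists."""
        for name in (
            "catalog",
            "families",
            "superfamily_domtbl",
            "hhsearch_dir",
            "supfam_plus_table",
            "pdomthreader_table",
            "family_links",
            "direct_map",
            "dcgo_table",
            "pdb_ec_table",
            "pdb_scop_table",
            "tax_nodes",
            "tax_names",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"configured input {name} does not exist: {value}")
        for path in self.nrichd_domtbl:
            if not path.exists():
                raise ConfigError(f"configured input nrichd_domtbl does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        missing = {"catalog", "families", "out_dir"} - set(raw)
        if missing:
            raise ConfigError(f"{path}: missing required keys {sorted(missing)}")
        return cls(thresholds=thresholds, **raw)
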