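"""Pipeline configuration.

One config object travels through the whole pipeline; every stage reads
its thresholds from it and every source of randomness is derived from
the single ``seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

IMPUTATION_POLICIES = ("error", "trait_mean")


@dataclass
class PipelineConfig:
    """Thresholds and switches for a screening run.

    Parameters
    ----------
    alpha_screen:
        Significance level for the Pearson correlation screen (default
        0.01, matching the p < 0.01 reporting convention of the assay).
    min_significant_positive:
        A trait is dropped when it has fewer than this many significant
        positive correlations with other traits (default 2).
    eigenvalue_threshold:
        Components with eigenvalue above this are retained (default 1.0,
        the Kaiser rule).
    vigor_day:
        Day of the germination assay on which germination vigor
        (early-germination percentage) is counted (default 5).
    alpha_groups:
        Significance level for Tukey letter displays (default 0.05).
    seed:
        Master seed; all stage-local generators derive from it.
    imputation:
        Missing-cell policy for the tolerance matrix: ``error`` (default)
        or ``trait_mean``.
    bonferroni:
        Apply Bonferroni correction in the correlation screen (off by
        default, matching uncorrected per-pair reporting).
    """

    alpha_screen: float = 0.01
    min_significant_positive: int = 2
    eigenvalue_threshold: float = 1.0
    vigor_day: int = 5
    alpha_groups: float = 0.05
    seed: int = 0
    imputation: str = "error"
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_screen < 1.0:
            raise ValueError("alpha_screen must be in (0, 1)")
        if not 0.0 < self.alpha_groups < 1.0:
            raise ValueError("alpha_groups must be in (0, 1)")
        if self.min_significant_positive < 0:
            raise ValueError("min_significant_positive must be >= 0")
        if not 1 <= int(self.vigor_day) <= 12:
            raise ValueError("vigor_day must be in [1, 12]")
        if self.imputation not in IMPUTATION_POLICIES:
            raise ValueError(f"imputation must be one of {IMPUTATION_POLICIES}")
        self.vigor_day = int(self.vigor_day)
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
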