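"""Run configuration: threshold grids, test levels and estimator choices.

Everything that can change a result lives here and is snapshotted into every
output, so a result file is always traceable to the settings that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .screening import DEFAULT_GRID


@dataclass
class AnalysisConfig:
    """Settings for a full screening + meta-analysis run.

    alpha            significance level of the pooled z-test (per test; no
                     multiplicity correction).
    alpha_het        level of the heterogeneity chi-square test in the
                     fixed/random model decision.
    i2_cut           I^2 percentage above which (together with p_Q < alpha_het)
                     the random-effects model is selected.
    min_k            minimum number of studies for an unflagged pooled result.
    min_studies_per_profile
                     profiles with fewer studies are dropped (1 keeps every
                     non-empty profile; 2 is the minimum for pooling).
    bias_correction  Hedges' small-sample correction J (False -> Cohen's d).
    """

    icrt_grid: tuple[float, ...] = DEFAULT_GRID
    sirt_grid: tuple[float, ...] = DEFAULT_GRID
    alpha: float = 0.05
    alpha_het: float = 0.05
    i2_cut: float = 50.0
    min_k: int = 2
    min_studies_per_profile: int = 1
    bias_correction: bool = True
    tau2_method: str = "DL"
    seed: int | None = None

    def __post_init__(self):
        self.icrt_grid = tuple(float(t) for t in self.icrt_grid)
        self.sirt_grid = tuple(float(t) for t in self.sirt_grid)
        if self.tau2_method != "DL":
            raise ValueError("only the DerSimonian-Laird tau2 estimator is supported")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["icrt_grid"] = list(self.icrt_grid)
        d["sirt_grid"] = list(self.sirt_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
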