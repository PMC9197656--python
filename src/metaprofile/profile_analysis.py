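"""Orchestration: run the meta-analysis over every (profile, indicator) pair.

``run_all`` builds the threshold profiles, then independently pools every
indicator retained in each profile, using only the profile's studies whose
baseline/follow-up pair is complete (studies with missing values are excluded
from each analysis separately). Outputs are deterministic functions of the
dataset and the configuration: a results table, a heatmap matrix in the
"zero when nonsignificant" convention, a per-indicator significance summary,
and per-cell funnel-plot data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .data_model import Dataset, paired_series
from .meta_engine import (
    DegenerateInputError,
    Direction,
    EffectSize,
    MetaResult,
    funnel_points,
    hedges_g,
    select_and_pool,
)
from .screening import Profile, build_profiles, compute_icr

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "profile", "indicator", "k", "model", "pooled_g", "se", "ci_low", "ci_high",
    "z", "p", "Q", "p_Q", "I2", "tau2", "significant", "direction", "flagged",
]


@dataclass
class ResultSet:
    """All pooled results of one run, keyed by (profile name, indicator)."""

    results: dict[tuple[str, str], MetaResult]
    profiles: list[Profile]
    indicator_order: list[str]  # descending ICR, then name
    config: dict
    effects: dict[tuple[str, str], list[EffectSize]] = field(default_factory=dict)

    @property
    def profile_names(self) -> list[str]:
        return [p.name for p in self.profiles]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for prof in self.profiles:
            for ind in self.indicator_order:
                r = self.results.get((prof.name, ind))
                if r is None:
                    continue
                d = r.to_dict()
                d["profile"] = prof.name
                rows.append(d)
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def collect_effects(
    ds: Dataset, profile: Profile, indicator: str, config: AnalysisConfig
) -> list[EffectSize]:
    """Effect sizes from the profile's studies with complete paired data.

    Studies missing any of the six summary numbers, or with a zero pooled SD
    (SMD undefined), are excluded from this one analysis.
    """
    effects = []
    for sid in sorted(profile.studies):
        ps = paired_series(ds, sid, indicator)
        if not ps.complete:
            continue
        b, f = ps.baseline, ps.followup
        try:
            eff = hedges_g(
                (b.mean, b.sd, b.n),
                (f.mean, f.sd, f.n),
                study_id=sid,
                indicator=indicator,
                bias_correction=config.bias_correction,
            )
        except DegenerateInputError:
            logger.debug("excluding degenerate series %s/%s", sid, indicator)
            continue
        effects.append(eff)
    return effects


def analyze_indicator(
    ds: Dataset,
    profile: Profile,
    indicator: str,
    config: AnalysisConfig | None = None,
) -> MetaResult | None:
    """Pool one indicator within one profile; None when no study is usable."""
    config = config or AnalysisConfig()
    if indicator not in profile.indicators:
        raise ValueError(
            f"indicator {indicator!r} is not retained in profile {profile.name}"
        )
    effects = collect_effects(ds, profile, indicator, config)
    if not effects:
        return None
    return select_and_pool(
        effects,
        alpha_het=config.alpha_het,
        i2_cut=config.i2_cut,
        alpha=config.alpha,
        min_k=config.min_k,
    )


def run_all(ds: Dataset, config: AnalysisConfig | None = None) -> ResultSet:
    """Screen, build profiles and pool every (profile, indicator) pair."""
    config = config or AnalysisConfig()
    ct = compute_icr(ds)
    profiles = build_profiles(
        ds, config.icrt_grid, config.sirt_grid,
        min_studies=config.min_studies_per_profile,
    )
    indicator_order = sorted(
        {i for p in profiles for i in p.indicators},
        key=lambda i: (-ct.entries[i], i),
    )
    results: dict[tuple[str, str], MetaResult] = {}
    effects_map: dict[tuple[str, str], list[EffectSize]] = {}
    for prof in profiles:
        k_counts = []
        for ind in sorted(prof.indicators):
            effects = collect_effects(ds, prof, ind, config)
            if not effects:
                continue
            effects_map[(prof.name, ind)] = effects
            results[(prof.name, ind)] = select_and_pool(
                effects,
                alpha_het=config.alpha_het,
                i2_cut=config.i2_cut,
                alpha=config.alpha,
                min_k=config.min_k,
            )
            k_counts.append(len(effects))
        logger.info(
            "profile %s: %d indicators, %d studies, k range %s",
            prof.name, len(prof.indicators), len(prof.studies),
            (min(k_counts), max(k_counts)) if k_counts else "n/a",
        )
    return ResultSet(
        results=results,
        profiles=profiles,
        indicator_order=indicator_order,
        config=config.to_dict(),
        effects=effects_map,
    )


def heatmap_matrix(rs: ResultSet, alpha: float | None = None) -> pd.DataFrame:
    """Indicator x profile grid of pooled SMDs in the zero-if-nonsignificant
    convention.

    Significant cells carry the pooled SMD; tested-but-nonsignificant cells
    carry 0; cells the profile does not contain — or whose k is below the
    configured minimum ("not estimable") — are NaN-masked. Rows are ordered
    by descending coverage, columns by ascending (ICRT, SIRT).
    """
    if alpha is None:
        alpha = rs.config.get("alpha", 0.05)
    mat = pd.DataFrame(np.nan, index=rs.indicator_order, columns=rs.profile_names)
    for (pname, ind), r in rs.results.items():
        if r.flagged:
            continue  # not estimable: masked, not zeroed
        mat.loc[ind, pname] = r.pooled_g if r.p < alpha else 0.0
    return mat


def summarize_significance(rs: ResultSet) -> pd.DataFrame:
    """Per indicator: profiles present in, significant decreases, increases."""
    rows = {}
    for ind in rs.indicator_order:
        rows[ind] = {"n_profiles_present": 0, "n_significant_decrease": 0,
                     "n_significant_increase": 0}
    for (pname, ind), r in rs.results.items():
        row = rows[ind]
        row["n_profiles_present"] += 1
        if r.significant and not r.flagged:
            if r.direction is Direction.DECREASE:
                row["n_significant_decrease"] += 1
            elif r.direction is Direction.INCREASE:
                row["n_significant_increase"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "indicator"
    return df.reset_index()


def _float_fmt(x) -> str:
    return f"{x:.10g}"


def write_outputs(rs: ResultSet, outdir: str | Path) -> None:
    """Serialize a run: profiles.json, results.tsv, heatmap.tsv, summary.tsv,
    funnel/<profile>_<indicator>.tsv and run.log with the config snapshot.

    All writers use fixed orderings and number formatting, so identical runs
    produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "profiles.json", "w") as fh:
        json.dump([p.to_dict() for p in rs.profiles], fh, indent=2, sort_keys=True)
        fh.write("\n")
    rs.to_frame().to_csv(
        outdir / "results.tsv", sep="\t", index=False, float_format="%.10g"
    )
    heatmap_matrix(rs).to_csv(
        outdir / "heatmap.tsv", sep="\t", index_label="indicator",
        float_format="%.10g",
    )
    summarize_significance(rs).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    funnel_dir = outdir / "funnel"
    funnel_dir.mkdir(exist_ok=True)
    safe = str.maketrans({c: "_" for c in " /()%<>"})
    for (pname, ind) in sorted(rs.effects):
        pts = funnel_points(rs.effects[(pname, ind)])
        df = pd.DataFrame(
            [{"study_id": p.study_id, "g": p.g, "se": p.se} for p in pts],
            columns=["study_id", "g", "se"],
        )
        df.to_csv(
            funnel_dir / f"{pname}_{ind.translate(safe)}.tsv",
            sep="\t", index=False, float_format="%.10g",
        )
    with open(outdir / "run.log", "w") as fh:
        fh.write(json.dumps({"config": rs.config}, indent=2, sort_keys=True))
        fh.write("\n")
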