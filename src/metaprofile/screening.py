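"""Indicator/study screening by coverage and integrity ratios.

Two ratios drive the screening:

* **ICR** (indicator coverage ratio) — the fraction of included studies that
  report a given indicator: ``ICR = (number of studies containing the
  indicator) / T_s`` with ``T_s`` the total number of included studies.
* **SIR** (study integrity ratio) — under an ICR threshold (ICRT), the
  fraction of the threshold-retained indicators that a given study reports:
  ``SIR = (retained indicators present in the study) / (total retained
  indicators)``.

Both ratios are cut at threshold grids 0.1, 0.2, ..., 1.0 (ICRT and SIRT).
Each (ICRT, SIRT) combination defines a *profile*, named ``P{10*ICRT}-{10*SIRT}``
(P1-1 means ICRT=0.1, SIRT=0.1). Within one ICRT, a study satisfying several
SIRTs is deduplicated into the highest SIRT it satisfies, so the profiles of
one ICRT partition the studies with SIR above the smallest SIRT. Profiles
with no studies or no indicators are dropped, and profiles whose retained
indicator set *and* study set coincide with another combination's are
deduplicated into the highest (ICRT, SIRT) — repeating an identical analysis
under a different name adds nothing. This is how a 10x10 grid collapses to
the much smaller set of distinct profiles actually analyzed.

Threshold comparisons are closed (``>=``) with an absolute tolerance of 1e-9
to absorb binary-decimal artifacts of the 0.1-step grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, presence_matrix

#: default threshold grid 0.1 ... 1.0
DEFAULT_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))

#: absolute tolerance for threshold comparisons (0.3 != 3*0.1 in floating point)
TOL = 1e-9


class ScreeningError(ValueError):
    pass


class EmptyDatasetError(ScreeningError):
    pass


class EmptyThresholdError(ScreeningError):
    """No indicator reaches the requested ICR threshold."""


class EmptyGridError(ScreeningError):
    pass


def _geq(a: float, b: float) -> bool:
    return a >= b - TOL


@dataclass(frozen=True)
class CoverageTable:
    """ICR per indicator; every value is an integer multiple of 1/T_s."""

    entries: Mapping[str, float]
    T_s: int

    def retained(self, icrt: float) -> frozenset:
        return frozenset(i for i, v in self.entries.items() if _geq(v, icrt))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"indicator": list(self.entries), "icr": list(self.entries.values())}
        ).sort_values(["icr", "indicator"], ascending=[False, True], ignore_index=True)


@dataclass(frozen=True)
class IntegrityTable:
    """SIR per study under one ICR threshold."""

    icrt: float
    retained_indicators: frozenset
    entries: Mapping[str, float]


@dataclass(frozen=True)
class Profile:
    """A named (ICRT, SIRT) combination with its indicator and study sets."""

    name: str
    icrt: float
    sirt: float
    indicators: frozenset
    studies: frozenset

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "icrt": self.icrt,
            "sirt": self.sirt,
            "indicators": sorted(self.indicators),
            "studies": sorted(self.studies),
        }


def profile_name(icrt: float, sirt: float) -> str:
    return f"P{int(round(icrt * 10))}-{int(round(sirt * 10))}"


@dataclass(frozen=True)
class CoverageHistogram:
    """Decile histogram of ICR values: bins [0,0.1), ..., [0.9,1.0]."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    percentages: tuple[float, ...]

    @property
    def total(self) -> int:
        return sum(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
                "percentage": self.percentages,
            }
        )


def compute_icr(ds: Dataset) -> CoverageTable:
    """Coverage ratio of every indicator: presence count / T_s."""
    if ds.T_s < 1 or not ds.measurements:
        raise EmptyDatasetError("cannot compute coverage on an empty dataset")
    pres = presence_matrix(ds)
    counts = pres.sum(axis=0)
    entries = {ind: counts[ind] / ds.T_s for ind in pres.columns}
    return CoverageTable(entries=entries, T_s=ds.T_s)


def compute_sir(
    ds: Dataset, icrt: float, coverage: CoverageTable | None = None
) -> IntegrityTable:
    """Integrity ratio of every study under one ICR threshold.

    The denominator is the total number of indicators retained at the
    threshold; the numerator counts how many of them the study reports.
    """
    ct = coverage if coverage is not None else compute_icr(ds)
    retained = ct.retained(icrt)
    if not retained:
        raise EmptyThresholdError(f"no indicator has ICR >= {icrt}")
    pres = presence_matrix(ds)
    cols = sorted(retained)
    hits = pres[cols].sum(axis=1)
    entries = {sid: hits[sid] / len(retained) for sid in pres.index}
    return IntegrityTable(icrt=icrt, retained_indicators=retained, entries=entries)


def assign_max_sirt(
    it: IntegrityTable, sirt_grid: Sequence[float]
) -> dict[str, float | None]:
    """Map each study to the highest grid threshold its SIR satisfies.

    This is the deduplication rule: a study satisfying several SIRTs counts
    only in the highest one. Studies below the smallest threshold map to None.
    """
    grid = sorted(sirt_grid)
    out: dict[str, float | None] = {}
    for sid, sir in it.entries.items():
        best = None
        for t in grid:
            if _geq(sir, t):
                best = t
        out[sid] = best
    return out


def build_profiles(
    ds: Dataset,
    icrt_grid: Sequence[float] = DEFAULT_GRID,
    sirt_grid: Sequence[float] = DEFAULT_GRID,
    min_studies: int = 1,
    dedupe_identical: bool = True,
) -> list[Profile]:
    """Construct all non-empty deduplicated (ICRT, SIRT) profiles.

    For each ICRT the retained indicator set is fixed; each study is assigned
    to the single profile of its maximal satisfied SIRT. Profiles with no
    studies (or fewer than ``min_studies``) or no indicators are dropped.
    With ``dedupe_identical`` (the default) profiles that retain exactly the
    same indicators and studies as a higher-threshold combination are merged
    into that combination (e.g. a single study reporting a single indicator
    yields only P10-10). Output is ordered by ascending (ICRT, SIRT).
    """
    if not icrt_grid or not sirt_grid:
        raise EmptyGridError("threshold grids must be non-empty")
    ct = compute_icr(ds)
    profiles: list[Profile] = []
    for icrt in sorted(icrt_grid):
        try:
            it = compute_sir(ds, icrt, coverage=ct)
        except EmptyThresholdError:
            continue
        assignment = assign_max_sirt(it, sirt_grid)
        by_sirt: dict[float, set[str]] = {}
        for sid, t in assignment.items():
            if t is not None:
                by_sirt.setdefault(t, set()).add(sid)
        for sirt in sorted(by_sirt):
            studies = by_sirt[sirt]
            if len(studies) < min_studies:
                continue
            profiles.append(
                Profile(
                    name=profile_name(icrt, sirt),
                    icrt=icrt,
                    sirt=sirt,
                    indicators=it.retained_indicators,
                    studies=frozenset(studies),
                )
            )
    if dedupe_identical:
        best: dict[tuple[frozenset, frozenset], Profile] = {}
        for p in profiles:  # ascending (icrt, sirt): later wins
            best[(p.indicators, p.studies)] = p
        keep = {id(p) for p in best.values()}
        profiles = [p for p in profiles if id(p) in keep]
    return profiles


def bin_coverage(
    ct: CoverageTable, n_bins: int = 10
) -> CoverageHistogram:
    """Decile histogram of the coverage distribution.

    Bins are left-closed/right-open with the last bin closed, so a coverage
    of exactly 1.0 lands in [0.9, 1.0]. Percentages are 100*count/total
    rounded to 2 decimals.
    """
    edges = tuple(round(i / n_bins, 10) for i in range(n_bins + 1))
    counts = [0] * n_bins
    for v in ct.entries.values():
        idx = int(np.floor((v + TOL) * n_bins))
        idx = min(idx, n_bins - 1)
        counts[idx] += 1
    total = sum(counts)
    pct = tuple(
        round(100.0 * c / total, 2) if total else 0.0 for c in counts
    )
    return CoverageHistogram(bin_edges=edges, counts=tuple(counts), percentages=pct)
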