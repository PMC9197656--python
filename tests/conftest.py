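"""Shared fixtures: small hand-built datasets and dataset factories."""

from __future__ import annotations

import numpy as np
import pytest

from metaprofile.data_model import (
    Arm,
    Dataset,
    IndicatorMeasurement,
    StudyMeta,
)


def make_measurement(sid, ind, arm, mean=10.0, sd=2.0, n=20):
    return IndicatorMeasurement(sid, ind, arm, mean, sd, n)


def dataset_from_presence(presence: dict[str, set[str]],
                          extra_studies: list[str] | None = None) -> Dataset:
    """Build a dataset whose presence structure is given; arm summaries are
    filled with unremarkable complete values."""
    measurements = []
    for sid, inds in presence.items():
        for ind in sorted(inds):
            measurements.append(make_measurement(sid, ind, Arm.BASELINE))
            measurements.append(make_measurement(sid, ind, Arm.FOLLOWUP, mean=9.0))
    studies = {sid: StudyMeta(sid) for sid in presence}
    for sid in extra_studies or []:
        studies[sid] = StudyMeta(sid)
    return Dataset(measurements, studies)


def random_presence(rng: np.random.Generator, n_studies: int, n_indicators: int,
                    density: float = 0.5) -> dict[str, set[str]]:
    sids = [f"S{i}" for i in range(1, n_studies + 1)]
    inds = [f"I{j}" for j in range(1, n_indicators + 1)]
    out = {sid: set() for sid in sids}
    for sid in sids:
        for ind in inds:
            if rng.random() < density:
                out[sid].add(ind)
    return out


@pytest.fixture
def small_ds() -> Dataset:
    """3 studies, 4 indicators, sparse coverage, all series complete.

    Presence: AHI in all 3 studies; TST in S1, S2; REM in S1; ESS in S2, S3.
    """
    presence = {
        "S1": {"AHI", "TST", "REM"},
        "S2": {"AHI", "TST", "ESS"},
        "S3": {"AHI", "ESS"},
    }
    return dataset_from_presence(presence)
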