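"""Screening: coverage/integrity ratios, threshold profiles, histogram.

The independent oracle works on exact rationals (fractions.Fraction), so the
floating-point tolerance handling of the implementation is checked against
arithmetic that cannot have rounding artifacts.
"""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaprofile.data_model import Dataset
from metaprofile.screening import (
    DEFAULT_GRID,
    CoverageTable,
    EmptyDatasetError,
    EmptyGridError,
    EmptyThresholdError,
    assign_max_sirt,
    bin_coverage,
    build_profiles,
    compute_icr,
    compute_sir,
    profile_name,
)

from conftest import dataset_from_presence, random_presence

GRID_FRACTIONS = [Fraction(i, 10) for i in range(1, 11)]


# ---------------------------------------------------------------------------
# exact-rational oracle

def oracle_profiles(presence: dict[str, set[str]], min_studies: int = 1,
                    dedupe_identical: bool = True):
    """Exhaustive enumeration of all 100 (ICRT, SIRT) combinations on exact
    fractions: max-SIRT study deduplication within each ICRT, then identical
    (indicator set, study set) combinations collapsed into the highest
    (ICRT, SIRT)."""
    studies = sorted(presence)
    T = len(studies)
    indicators = sorted({i for s in presence.values() for i in s})
    icr = {i: Fraction(sum(1 for s in studies if i in presence[s]), T)
           for i in indicators}
    cells = []  # (it, jt, retained, studies), ascending (it, jt)
    for it in GRID_FRACTIONS:
        retained = {i for i in indicators if icr[i] >= it}
        if not retained:
            continue
        by_sirt: dict[Fraction, set[str]] = {}
        for s in studies:
            sir = Fraction(len(retained & presence[s]), len(retained))
            best = None
            for jt in GRID_FRACTIONS:
                if sir >= jt:
                    best = jt
            if best is not None:
                by_sirt.setdefault(best, set()).add(s)
        for jt in sorted(by_sirt):
            if len(by_sirt[jt]) >= min_studies:
                cells.append((it, jt, retained, by_sirt[jt]))
    if dedupe_identical:
        best_cell = {}
        for cell in cells:  # ascending: the last (highest thresholds) wins
            key = (frozenset(cell[2]), frozenset(cell[3]))
            best_cell[key] = cell
        keep = {id(c) for c in best_cell.values()}
        cells = [c for c in cells if id(c) in keep]
    out = {}
    for it, jt, retained, ss in cells:
        name = f"P{it.numerator * 10 // it.denominator}-" \
               f"{jt.numerator * 10 // jt.denominator}"
        out[name] = (retained, ss)
    return out


def profiles_as_dict(profiles):
    return {p.name: (set(p.indicators), set(p.studies)) for p in profiles}


# ---------------------------------------------------------------------------
# ICR

def test_icr_arithmetic(small_ds):
    ct = compute_icr(small_ds)
    assert ct.T_s == 3
    assert ct.entries["AHI"] == pytest.approx(1.0)  # in every study
    assert ct.entries["TST"] == pytest.approx(2 / 3)
    assert ct.entries["REM"] == pytest.approx(1 / 3)


def test_icr_empty_dataset():
    with pytest.raises(EmptyDatasetError):
        compute_icr(Dataset([]))


def test_icr_values_are_multiples_of_one_over_Ts(small_ds):
    ct = compute_icr(small_ds)
    for v in ct.entries.values():
        assert (v * ct.T_s) == pytest.approx(round(v * ct.T_s))


# ---------------------------------------------------------------------------
# SIR

def test_sir_examples():
    presence = {
        "S1": {"A", "B", "C"},          # 3 of the 4 retained
        "S2": {"A", "B", "C", "D"},     # all 4
        "S3": {"A"}, "S4": {"B"}, "S5": {"C"}, "S6": {"D"},
    }
    ds = dataset_from_presence(presence)
    # every indicator appears in >= 2 of 6 studies -> all retained at 0.1
    it = compute_sir(ds, 0.1)
    assert it.retained_indicators == frozenset("ABCD")
    assert it.entries["S1"] == pytest.approx(0.75)
    assert it.entries["S2"] == pytest.approx(1.0)


def test_sir_empty_threshold(small_ds):
    # no indicator can have ICR above 1.0's neighborhood... use tiny dataset
    ds = dataset_from_presence({"S1": {"A"}, "S2": {"B"}, "S3": {"C"}})
    with pytest.raises(EmptyThresholdError):
        compute_sir(ds, 0.9)


def test_sir_matches_bruteforce():
    rng = np.random.default_rng(7)
    presence = random_presence(rng, 6, 8, density=0.45)
    ds = dataset_from_presence(presence)
    for icrt in (0.1, 0.3, 0.5):
        try:
            it = compute_sir(ds, icrt)
        except EmptyThresholdError:
            continue
        T = len(presence)
        icr = {i: Fraction(sum(1 for s in presence.values() if i in s), T)
               for i in {x for s in presence.values() for x in s}}
        retained = {i for i, v in icr.items() if v >= Fraction(round(icrt * 10), 10)}
        assert it.retained_indicators == frozenset(retained)
        for sid, sir in it.entries.items():
            expected = Fraction(len(retained & presence[sid]), len(retained))
            assert sir == pytest.approx(float(expected))


# ---------------------------------------------------------------------------
# deduplication

def test_assign_max_sirt_forced():
    it_stub = type("T", (), {})()
    it_stub.entries = {"S1": 1.0, "S2": 0.55, "S3": 0.09}
    assignment = assign_max_sirt(it_stub, DEFAULT_GRID)
    assert assignment["S1"] == pytest.approx(1.0)
    assert assignment["S2"] == pytest.approx(0.5)
    assert assignment["S3"] is None  # below the smallest threshold


def test_assign_max_sirt_matches_linear_scan():
    rng = np.random.default_rng(3)
    sirs = {f"S{i}": float(rng.integers(0, 11)) / 10 for i in range(30)}
    it_stub = type("T", (), {})()
    it_stub.entries = sirs
    assignment = assign_max_sirt(it_stub, DEFAULT_GRID)
    for sid, sir in sirs.items():
        best = None
        for t in DEFAULT_GRID:
            if Fraction(round(sir * 10), 10) >= Fraction(round(t * 10), 10):
                best = t
        if best is None:
            assert assignment[sid] is None
        else:
            assert assignment[sid] == pytest.approx(best)


def test_threshold_float_artifacts():
    """0.3 is not 3*0.1 in binary; the tolerance must absorb that."""
    it_stub = type("T", (), {})()
    it_stub.entries = {"S1": 0.1 * 3, "S2": 3 / 10}
    assignment = assign_max_sirt(it_stub, [0.1 * 3, 0.4])
    assert assignment["S1"] == assignment["S2"]


# ---------------------------------------------------------------------------
# profiles

def test_single_study_single_indicator_gives_P10_10():
    ds = dataset_from_presence({"S1": {"AHI"}})
    profiles = build_profiles(ds)
    assert len(profiles) == 1
    p = profiles[0]
    assert p.name == "P10-10"
    assert p.indicators == frozenset({"AHI"})
    assert p.studies == frozenset({"S1"})


def test_profile_naming():
    assert profile_name(0.1, 0.1) == "P1-1"
    assert profile_name(0.7, 1.0) == "P7-10"
    assert profile_name(0.1 * 3, 0.6) == "P3-6"


def test_empty_grid_rejected(small_ds):
    with pytest.raises(EmptyGridError):
        build_profiles(small_ds, icrt_grid=[], sirt_grid=DEFAULT_GRID)


def test_profiles_match_oracle_random_fixture():
    rng = np.random.default_rng(11)
    presence = random_presence(rng, 6, 8, density=0.4)
    if not any(presence.values()):
        presence["S1"].add("I1")
    ds = dataset_from_presence(presence)
    got = profiles_as_dict(build_profiles(ds))
    assert got == oracle_profiles(presence)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(1, 8), st.integers(1, 10), st.integers(0, 10_000))
def test_profiles_properties(n_studies, n_indicators, seed):
    """Monotone retained sets; disjoint study sets within one ICRT whose
    union is every study above the smallest SIRT; agreement with the
    exhaustive oracle."""
    rng = np.random.default_rng(seed)
    presence = random_presence(rng, n_studies, n_indicators,
                               density=rng.uniform(0.2, 0.9))
    if not any(presence.values()):
        presence[next(iter(presence))].add("I1")
    ds = dataset_from_presence(presence)
    profiles = build_profiles(ds)
    assert profiles_as_dict(profiles) == oracle_profiles(presence)

    # the partition properties hold on the pre-collapse grid
    full = build_profiles(ds, dedupe_identical=False)
    assert profiles_as_dict(full) == oracle_profiles(
        presence, dedupe_identical=False)

    # retained-set monotonicity in ICRT
    by_icrt = {}
    for p in full:
        by_icrt.setdefault(round(p.icrt, 1), set()).update(p.indicators)
    ts = sorted(by_icrt)
    for lo, hi in zip(ts, ts[1:]):
        assert by_icrt[hi] <= by_icrt[lo]

    # within one ICRT: pairwise disjoint studies, union = {SIR >= min SIRT}
    for icrt in ts:
        group = [p for p in full if round(p.icrt, 1) == icrt]
        seen = set()
        for p in group:
            assert not (seen & p.studies)
            seen |= p.studies
        it = compute_sir(ds, icrt)
        expected = {s for s, v in it.entries.items() if v >= 0.1 - 1e-9}
        assert seen == expected


def test_min_studies_switch():
    ds = dataset_from_presence({"S1": {"A", "B"}, "S2": {"A"}})
    with_singletons = build_profiles(ds, min_studies=1)
    poolable = build_profiles(ds, min_studies=2)
    assert {p.name for p in poolable} <= {p.name for p in with_singletons}
    assert all(len(p.studies) >= 2 for p in poolable)


# ---------------------------------------------------------------------------
# histogram

def test_bin_coverage_all_covered():
    ds = dataset_from_presence({"S1": {"A", "B"}, "S2": {"A", "B"}})
    hist = bin_coverage(compute_icr(ds))
    assert hist.counts[-1] == 2  # ICR = 1.0 lands in the closed last bin
    assert hist.percentages[-1] == pytest.approx(100.0)


def test_bin_coverage_matches_direct_histogram():
    rng = np.random.default_rng(5)
    T = 17
    values = {f"I{i}": int(rng.integers(1, T + 1)) / T for i in range(60)}
    ct = CoverageTable(entries=values, T_s=T)
    hist = bin_coverage(ct)
    direct = [0] * 10
    for v in values.values():
        direct[min(int(Fraction(round(v * T), T) * 10), 9)] += 1
    assert list(hist.counts) == direct
    assert sum(hist.counts) == 60
    assert sum(hist.percentages) == pytest.approx(100.0, abs=0.05)


def test_bin_boundary_left_closed():
    # exact boundary value 0.1 (2 of 20 studies) belongs to [0.1, 0.2)
    ct = CoverageTable(entries={"A": 2 / 20}, T_s=20)
    hist = bin_coverage(ct)
    assert hist.counts[1] == 1 and hist.counts[0] == 0
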