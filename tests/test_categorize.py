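"""Categorization rules, Levenshtein distance and drug matching."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cvhtraj import (CategorizationRules, DrugClassTable, ValidationError,
                     categorize, categorize_cohort, is_treated, levenshtein,
                     match_drug_class)
from cvhtraj.categorize import GLUCOSE_MGDL_BANDS, TREATABLE

from conftest import toy_measurements


# ---------------------------------------------------------------------------
# Levenshtein
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def recursive_distance(a: str, b: str) -> int:
    """Independent exhaustive recursive oracle."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(recursive_distance(a[1:], b) + 1,
               recursive_distance(a, b[1:]) + 1,
               recursive_distance(a[1:], b[1:]) + (a[0] != b[0]))


@pytest.mark.parametrize("a,b,d", [
    ("statin", "statin", 0),
    ("", "abc", 3),
    ("abc", "", 3),
    ("kitten", "sitting", 3),
    ("a", "b", 1),
    ("flaw", "lawn", 2),
])
def test_levenshtein_known_instances(a, b, d):
    assert levenshtein(a, b) == d
    assert levenshtein(b, a) == d


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.text(alphabet="abcdef", max_size=10), st.text(alphabet="abcdef", max_size=10))
def test_levenshtein_matches_recursive_oracle(a, b):
    assert levenshtein(a, b) == recursive_distance(a, b)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.text(alphabet="abcxyz", max_size=12), st.text(alphabet="abcxyz", max_size=12))
def test_levenshtein_metric_properties(a, b):
    d = levenshtein(a, b)
    assert d == levenshtein(b, a)
    assert (d == 0) == (a == b)
    assert d <= max(len(a), len(b))
    assert d >= abs(len(a) - len(b))


def test_levenshtein_agrees_with_edlib(rng):
    edlib = pytest.importorskip("edlib")
    letters = np.array(list("abcdefghijklmnop"))
    for _ in range(300):
        a = "".join(rng.choice(letters, size=rng.integers(0, 15)))
        b = "".join(rng.choice(letters, size=rng.integers(0, 15)))
        assert levenshtein(a, b) == edlib.align(a, b, task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# Drug matching
# ---------------------------------------------------------------------------

def test_exact_name_matches_its_class(drug_table):
    assert match_drug_class("atorvastatin", drug_table) == "hmg-coa reductase inhibitor"
    assert match_drug_class("  Lisinopril ", drug_table) == "ace inhibitor"  # case/space folded


def test_threshold_is_strictly_less_than(drug_table):
    # a name at distance exactly 5 from everything must not match
    assert match_drug_class("qqqqq" + "x" * 40, drug_table) is None
    assert match_drug_class("metformi", drug_table) == "biguanide"  # distance 1


def test_nearest_entry_wins():
    table = DrugClassTable(pd.DataFrame({
        "canonical_name": ["abcdef", "abzzzz"],
        "drug_class": ["near", "far"],
        "treats": [frozenset({"bp"}), frozenset({"ldl"})]}))
    # query at distance 2 from 'abcdef' and 4 from 'abzzzz'
    assert match_drug_class("abcdzz", table) == "near"


def test_equidistant_tie_breaks_by_table_order():
    table = DrugClassTable(pd.DataFrame({
        "canonical_name": ["aaab", "aaac"],
        "drug_class": ["first", "second"],
        "treats": [frozenset({"bp"}), frozenset({"bp"})]}))
    assert match_drug_class("aaad", table) == "first"


def test_empty_table_rejected():
    table = DrugClassTable(pd.DataFrame({
        "canonical_name": ["x"], "drug_class": ["c"], "treats": [frozenset({"bp"})]}))
    table.entries = table.entries.iloc[:0]
    with pytest.raises(ValidationError, match="empty"):
        match_drug_class("anything", table)


def test_is_treated_date_window(drug_table):
    meds = pd.DataFrame({"patient_id": ["p1", "p1"],
                         "date": ["2010-06-01", "2012-01-01"],
                         "raw_name": ["atorvastatin", "metformin"]})
    # statin order counts for ldl on or after its date, never before
    assert is_treated("p1", "ldl", "2010-06-01", meds, drug_table)
    assert is_treated("p1", "ldl", "2011-01-01", meds, drug_table)
    assert not is_treated("p1", "ldl", "2010-05-31", meds, drug_table)
    # class must treat the submetric in question
    assert not is_treated("p1", "bp", "2013-01-01", meds, drug_table)
    assert is_treated("p1", "a1c", "2012-01-01", meds, drug_table)
    assert not is_treated("p2", "ldl", "2013-01-01", meds, drug_table)
    with pytest.raises(ValidationError):
        is_treated("p1", "smk", "2013-01-01", meds, drug_table)


# ---------------------------------------------------------------------------
# Threshold rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("submetric,v1,v2,expected", [
    ("bmi", 31, None, "poor"),
    ("bmi", 24, None, "ideal"),
    ("bmi", 27, None, "intermediate"),
    ("bp", 118, 79, "ideal"),
    ("bp", 118, 92, "poor"),          # diastolic alone can make it poor
    ("bp", 150, 70, "poor"),
    ("bp", 125, 79, "intermediate"),
    ("ldl", 145, None, "intermediate"),
    ("ldl", 170, None, "poor"),
    ("ldl", 99, None, "ideal"),
    ("a1c", 5.0, None, "ideal"),
    ("a1c", 6.0, None, "intermediate"),
    ("a1c", 7.2, None, "poor"),
    ("smk", "current", None, "poor"),
    ("smk", "never", None, "ideal"),
    ("smk", "former", 6, "intermediate"),
    ("smk", "former", 20, "ideal"),
])
def test_category_bands(submetric, v1, v2, expected):
    assert categorize(submetric, v1, v2) == expected


@pytest.mark.parametrize("submetric,v1,v2,expected", [
    ("bmi", 25.0, None, "intermediate"),
    ("bmi", 30.0, None, "poor"),
    ("ldl", 130.0, None, "intermediate"),
    ("ldl", 160.0, None, "poor"),
    ("bp", 120.0, 70.0, "intermediate"),
    ("bp", 140.0, 70.0, "poor"),
    ("bp", 110.0, 80.0, "intermediate"),
    ("bp", 110.0, 90.0, "poor"),
    ("a1c", 6.5, None, "poor"),
    ("a1c", 5.7, None, "intermediate"),
    ("smk", "former", 12.0, "intermediate"),  # quit > 12 months is ideal
])
def test_boundary_values_follow_stated_conventions(submetric, v1, v2, expected):
    assert categorize(submetric, v1, v2) == expected


def test_treated_forces_intermediate_for_any_value():
    for sm, vals in (("ldl", [99, 145, 170]), ("a1c", [5.0, 6.0, 9.0])):
        for v in vals:
            assert categorize(sm, v, treated=True) == "intermediate"
    for sysd in ((110, 70), (130, 85), (180, 100)):
        assert categorize("bp", *sysd, treated=True) == "intermediate"


def test_cap_policy_only_demotes_from_the_extremes():
    rules = CategorizationRules(treated_policy="cap_at_intermediate")
    assert categorize("ldl", 99, treated=True, rules=rules) == "intermediate"
    assert categorize("ldl", 145, treated=True, rules=rules) == "intermediate"


def test_glucose_band_option():
    rules = CategorizationRules(a1c_bands=dict(GLUCOSE_MGDL_BANDS))
    assert categorize("a1c", 95, rules=rules) == "ideal"
    assert categorize("a1c", 110, rules=rules) == "intermediate"
    assert categorize("a1c", 130, rules=rules) == "poor"


def test_monotonic_in_value_for_untreated_numeric_submetrics():
    order = {"poor": 0, "intermediate": 1, "ideal": 2}
    for sm, grid in (("bmi", np.arange(15, 60, 0.1)),
                     ("ldl", np.arange(40, 300, 0.5)),
                     ("a1c", np.arange(4, 14, 0.05))):
        codes = [order[categorize(sm, v)] for v in grid]
        assert all(a >= b for a, b in zip(codes, codes[1:]))
    sys_codes = [order[categorize("bp", v, 70)] for v in np.arange(90, 220, 0.5)]
    assert all(a >= b for a, b in zip(sys_codes, sys_codes[1:]))
    dia_codes = [order[categorize("bp", 110, v)] for v in np.arange(55, 130, 0.5)]
    assert all(a >= b for a, b in zip(dia_codes, dia_codes[1:]))


@pytest.mark.parametrize("args,match", [
    (("bogus", 30, None), "unknown submetric"),
    (("bp", 120, None), "systolic and diastolic"),
    (("bmi", -5, None), "finite and positive"),
    (("smk", "sometimes", None), "smoking status"),
    (("smk", "former", None), "quit_months"),
])
def test_invalid_measurements_rejected(args, match):
    with pytest.raises(ValidationError, match=match):
        categorize(*args)


# ---------------------------------------------------------------------------
# Cohort-level
# ---------------------------------------------------------------------------

def test_empty_input_gives_empty_output(drug_table):
    out = categorize_cohort(toy_measurements([]), None, drug_table)
    assert len(out) == 0
    assert list(out.columns) == ["patient_id", "submetric", "date", "category"]


def test_single_patient_bmi_fixture(drug_table):
    meas = toy_measurements([
        ("p1", "bmi", "2010-01-01", 24, None),
        ("p1", "bmi", "2011-01-01", 27, None),
        ("p1", "bmi", "2012-01-01", 31, None)])
    out = categorize_cohort(meas, None, drug_table)
    assert list(out["category"]) == ["ideal", "intermediate", "poor"]


def test_treatment_applies_from_order_date_onwards(drug_table):
    meas = toy_measurements([
        ("p1", "ldl", "2009-01-01", 170, None),
        ("p1", "ldl", "2011-01-01", 170, None)])
    meds = pd.DataFrame({"patient_id": ["p1"], "date": ["2010-01-01"],
                         "raw_name": ["simvastatin"], "true_class": ["x"]})
    out = categorize_cohort(meas, meds, drug_table)
    assert list(out["category"]) == ["poor", "intermediate"]


def test_generated_categories_recover_hidden_states(small_cohort, drug_table):
    _, (patients, measurements, medications) = small_cohort
    out = categorize_cohort(measurements, medications, drug_table)
    treated_pairs = set()
    for sm in TREATABLE:
        for pid in medications["patient_id"].unique():
            treated_pairs.add((pid, sm))
    joined = out.assign(truth=measurements["true_category"].values)
    untreated = joined[[not ((p, s) in treated_pairs)
                        for p, s in zip(joined["patient_id"], joined["submetric"])]]
    assert len(untreated) > 100
    assert (untreated["category"] == untreated["truth"]).all()
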