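"""Three-level cardiovascular-health categorization of raw measurements.

Each of the five tracked submetrics — smoking status (smk), body mass index
(bmi), blood pressure (bp), hemoglobin A1c (a1c) and LDL cholesterol (ldl) —
is mapped to one of three ordered categories:

    poor (0)  <  intermediate (1)  <  ideal (2)

using the American Heart Association's Life's Simple 7 style threshold bands.
For the three medication-responsive factors (a1c, ldl, bp) a patient on a
qualifying drug is "treated to goal": under the default policy any qualifying
treatment on or before the measurement date forces the intermediate category
regardless of the measured value. Free-text drug names are resolved to drug
classes by minimum Levenshtein distance against a canonical drug-class table,
accepting a match only when the distance is strictly less than a threshold
(default 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBMETRICS = ("smk", "bmi", "bp", "a1c", "ldl")
CATEGORIES = ("poor", "intermediate", "ideal")
#: ordinal encoding: poor=0, intermediate=1, ideal=2
CATEGORY_CODE = {"poor": 0, "intermediate": 1, "ideal": 2}
CODE_CATEGORY = {v: k for k, v in CATEGORY_CODE.items()}
#: submetrics whose category can be overridden by medication
TREATABLE = ("a1c", "ldl", "bp")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# Levenshtein distance and drug-class matching
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions transforming ``a`` into ``b``.

    Iterative two-row dynamic programme; symmetric; 0 iff the strings are
    equal. Empty strings are allowed.
    """
    if a == b:
        return 0
    if len(a) < len(b):  # iterate over the shorter string's columns
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1,            # delete from a
                           cur[j - 1] + 1,         # insert into a
                           prev[j - 1] + (ca != cb)))  # substitute
        prev = cur
    return prev[-1]


@dataclass
class DrugClassTable:
    """Canonical drug names, their drug classes, and the submetrics each
    class treats (subset of a1c / ldl / bp).

    Stands in for a commercial drug-class database such as Multum; entries
    are matched case-folded and whitespace-stripped.
    """

    entries: pd.DataFrame  # columns: canonical_name, drug_class, treats (set)

    def __post_init__(self) -> None:
        required = {"canonical_name", "drug_class", "treats"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValidationError(f"drug table missing columns: {sorted(missing)}")
        names = self.entries["canonical_name"].str.strip().str.casefold()
        if names.duplicated().any():
            dups = names[names.duplicated()].tolist()
            raise ValidationError(f"duplicate canonical names after case-folding: {dups}")
        for i, t in enumerate(self.entries["treats"]):
            t = set(t)
            if not t or not t <= set(TREATABLE):
                raise ValidationError(
                    f"entry {i}: treats must be a non-empty subset of {TREATABLE}, got {t}")

    @classmethod
    def from_csv(cls, path) -> "DrugClassTable":
        df = pd.read_csv(path)
        df["treats"] = [frozenset(t.split(";")) for t in df["treats"]]
        return cls(df)

    @classmethod
    def packaged(cls) -> "DrugClassTable":
        """The drug-class table shipped with the package (~60 entries)."""
        with resources.as_file(
                resources.files("cvhtraj.data") / "drug_classes.csv") as p:
            return cls.from_csv(p)

    def __len__(self) -> int:
        return len(self.entries)


def match_drug_class(raw_name: str, table: DrugClassTable,
                     threshold: int = 5) -> str | None:
    """Resolve a free-text drug name to a drug class.

    Returns the class of the entry minimizing the case-folded Levenshtein
    distance to ``raw_name`` when that minimum is strictly below
    ``threshold``, else ``None``. Equidistant entries are broken by table
    order, deterministically.
    """
    if len(table) == 0:
        raise ValidationError("empty drug-class table")
    if threshold < 1:
        raise ValidationError(f"threshold must be >= 1, got {threshold}")
    query = raw_name.strip().casefold()
    best_d, best_class = None, None
    for name, cls_ in zip(table.entries["canonical_name"],
                          table.entries["drug_class"]):
        d = levenshtein(query, name.strip().casefold())
        if best_d is None or d < best_d:
            best_d, best_class = d, cls_
            if d == 0:
                break
    return best_class if best_d < threshold else None


def is_treated(patient_id: str, submetric: str, as_of_date,
               medications: pd.DataFrame, table: DrugClassTable,
               threshold: int = 5) -> bool:
    """Whether the patient carries a qualifying treatment for ``submetric``
    dated on or before ``as_of_date``.

    ``medications`` is a long-format frame with columns patient_id, date,
    raw_name. Orders dated after the measurement never count.
    """
    if submetric not in TREATABLE:
        raise ValidationError(f"submetric {submetric!r} is not medication-responsive")
    if medications is None or len(medications) == 0:
        return False
    as_of = pd.Timestamp(as_of_date)
    rows = medications[(medications["patient_id"] == patient_id)
                       & (pd.to_datetime(medications["date"]) <= as_of)]
    for raw in rows["raw_name"]:
        cls_ = match_drug_class(raw, table, threshold)
        if cls_ is not None and submetric in _class_treats(table, cls_):
            return True
    return False


def _class_treats(table: DrugClassTable, drug_class: str) -> frozenset:
    sel = table.entries.loc[table.entries["drug_class"] == drug_class, "treats"]
    out: set = set()
    for t in sel:
        out |= set(t)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Threshold rules
# ---------------------------------------------------------------------------

#: hemoglobin A1c bands in percent (clinical prediabetes/diabetes cuts)
A1C_PERCENT_BANDS = {"ideal_below": 5.7, "poor_at_or_above": 6.5}
#: fasting plasma glucose bands in mg/dL, selectable for glucose-valued data
GLUCOSE_MGDL_BANDS = {"ideal_below": 100.0, "poor_at_or_above": 126.0}


@dataclass
class CategorizationRules:
    """Threshold set for the five submetrics plus matching policy knobs.

    ``treated_policy`` controls the "treated to goal" reading:
    ``force_intermediate`` (default) assigns intermediate whenever a
    qualifying treatment exists; ``cap_at_intermediate`` only demotes an
    otherwise-ideal or otherwise-poor value to intermediate.
    """

    bmi_poor: float = 30.0          # kg/m^2, >= is poor
    bmi_ideal: float = 25.0         # < is ideal
    ldl_poor: float = 160.0         # mg/dL
    ldl_ideal: float = 130.0
    sys_poor: float = 140.0         # mmHg
    sys_ideal: float = 120.0
    dia_poor: float = 90.0
    dia_ideal: float = 80.0
    a1c_bands: dict = field(default_factory=lambda: dict(A1C_PERCENT_BANDS))
    smoking_quit_ideal_months: float = 12.0   # quit > 12 months is ideal
    levenshtein_threshold: int = 5            # strictly-less acceptance
    treated_policy: str = "force_intermediate"

    def __post_init__(self) -> None:
        for lo, hi in ((self.bmi_ideal, self.bmi_poor),
                       (self.ldl_ideal, self.ldl_poor),
                       (self.sys_ideal, self.sys_poor),
                       (self.dia_ideal, self.dia_poor),
                       (self.a1c_bands["ideal_below"], self.a1c_bands["poor_at_or_above"])):
            if not lo < hi:
                raise ValidationError(f"ideal bound {lo} must be < poor bound {hi}")
        if self.treated_policy not in ("force_intermediate", "cap_at_intermediate"):
            raise ValidationError(f"unknown treated_policy {self.treated_policy!r}")


def _band(value: float, ideal_below: float, poor_at_or_above: float) -> str:
    if value >= poor_at_or_above:
        return "poor"
    if value < ideal_below:
        return "ideal"
    return "intermediate"


def categorize(submetric: str, value1, value2=None, *, treated: bool = False,
               rules: CategorizationRules | None = None) -> str:
    """Categorize one measurement into poor / intermediate / ideal.

    ``value1``/``value2`` carry the measurement payload: BMI kg/m^2; LDL
    mg/dL; A1c percent; BP systolic+diastolic mmHg; smoking status string
    ("current"/"former"/"never") with months since quitting in ``value2``
    for former smokers. ``treated`` applies only to a1c/ldl/bp.
    """
    rules = rules or CategorizationRules()
    if submetric not in SUBMETRICS:
        raise ValidationError(f"unknown submetric {submetric!r}")

    if submetric == "smk":
        status = str(value1).strip().casefold()
        if status == "current":
            return "poor"
        if status == "never":
            return "ideal"
        if status == "former":
            if value2 is None or (isinstance(value2, float) and np.isnan(value2)):
                raise ValidationError("former smoker requires quit_months")
            return ("intermediate"
                    if float(value2) <= rules.smoking_quit_ideal_months else "ideal")
        raise ValidationError(f"unknown smoking status {value1!r}")

    v = float(value1)
    if not np.isfinite(v) or v <= 0:
        raise ValidationError(f"{submetric} value must be finite and positive, got {value1!r}")

    if submetric == "bmi":
        return _band(v, rules.bmi_ideal, rules.bmi_poor)

    if submetric == "bp":
        if value2 is None or (isinstance(value2, float) and np.isnan(value2)):
            raise ValidationError("blood pressure requires both systolic and diastolic")
        d = float(value2)
        if not np.isfinite(d) or d <= 0:
            raise ValidationError(f"diastolic must be finite and positive, got {value2!r}")
        if treated:
            return _treated_category(
                "poor" if (v >= rules.sys_poor or d >= rules.dia_poor)
                else "ideal" if (v < rules.sys_ideal and d < rules.dia_ideal)
                else "intermediate", rules)
        if v >= rules.sys_poor or d >= rules.dia_poor:
            return "poor"
        if v < rules.sys_ideal and d < rules.dia_ideal:
            return "ideal"
        return "intermediate"

    if submetric == "ldl":
        raw = _band(v, rules.ldl_ideal, rules.ldl_poor)
    else:  # a1c
        raw = _band(v, rules.a1c_bands["ideal_below"], rules.a1c_bands["poor_at_or_above"])
    return _treated_category(raw, rules) if treated else raw


def _treated_category(raw: str, rules: CategorizationRules) -> str:
    if rules.treated_policy == "force_intermediate":
        return "intermediate"
    return "intermediate" if raw != "intermediate" else raw  # cap_at_intermediate


# ---------------------------------------------------------------------------
# Cohort-level categorization
# ---------------------------------------------------------------------------

def categorize_cohort(measurements: pd.DataFrame,
                      medications: pd.DataFrame | None = None,
                      table: DrugClassTable | None = None,
                      rules: CategorizationRules | None = None) -> pd.DataFrame:
    """Categorize every measurement row of a cohort.

    Returns a frame with columns patient_id, submetric, date, category — one
    row per input measurement, a pure function of the inputs. Treatment
    status is assessed per measurement date (orders on or before count).
    """
    rules = rules or CategorizationRules()
    out_cols = ["patient_id", "submetric", "date", "category"]
    if measurements is None or len(measurements) == 0:
        return pd.DataFrame(columns=out_cols)

    if table is None:
        table = DrugClassTable.packaged()

    # Pre-resolve treatment orders once: (patient, submetric) -> sorted dates
    treated_dates: dict[tuple[str, str], np.ndarray] = {}
    if medications is not None and len(medications):
        med = medications.copy()
        med["date"] = pd.to_datetime(med["date"])
        med["_class"] = [match_drug_class(r, table, rules.levenshtein_threshold)
                         for r in med["raw_name"]]
        med = med[med["_class"].notna()]
        med["_treats"] = [_class_treats(table, c) for c in med["_class"]]
        for (pid,), grp in med.groupby(["patient_id"]):
            for sm in TREATABLE:
                dates = grp.loc[[sm in t for t in grp["_treats"]], "date"]
                if len(dates):
                    treated_dates[(pid, sm)] = np.sort(dates.to_numpy())

    rows = []
    for i, row in enumerate(measurements.itertuples(index=False)):
        try:
            date = pd.Timestamp(row.date)
            treated = False
            if row.submetric in TREATABLE:
                key = (row.patient_id, row.submetric)
                if key in treated_dates:
                    treated = bool(treated_dates[key][0] <= np.datetime64(date))
            cat = categorize(row.submetric, row.value1,
                             getattr(row, "value2", None),
                             treated=treated, rules=rules)
        except ValidationError as e:
            raise ValidationError(f"measurement row {i} "
                                  f"(patient {row.patient_id}, {row.submetric}): {e}") from e
        rows.append((row.patient_id, row.submetric, date, cat))

    out = pd.DataFrame(rows, columns=out_cols)
    counts = out.groupby(["submetric", "category"]).size()
    logger.info("categorized %d measurements: %s", len(out), counts.to_dict())
    return out
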