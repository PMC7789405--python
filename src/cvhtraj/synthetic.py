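"""Synthetic longitudinal cohorts with planted, recoverable dynamics.

Real ambulatory quality-registry data of the kind this package targets is
proprietary, so every downstream stage is exercised on cohorts generated
here. The generative model is deliberately simple and fully known:

* per patient and submetric, visit dates follow a homogeneous Poisson
  process over a multi-year observation window (default 13 years);
* the three-level category at successive visits follows a first-order
  Markov chain over (poor, intermediate, ideal) with a configurable
  row-stochastic transition matrix;
* numeric values are drawn uniformly inside the threshold band of the
  planted category (bounded tails for open-ended bands), so categorization
  recovers the hidden state exactly for untreated measurements;
* patients in a non-ideal a1c/ldl/bp state may carry medication orders
  whose free-text names are noisy variants (a fixed number of edit
  operations) of canonical drug names;
* initial states can be coupled across submetrics with a correlation knob;
  dynamics after the initial state are independent across submetrics.

Everything is deterministic under the configured seed; per-patient,
per-submetric random substreams are derived by stable seed-sequence
spawning so that growing the cohort does not reshuffle existing patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .categorize import (CATEGORIES, SUBMETRICS, TREATABLE, CategorizationRules,
                         DrugClassTable, ValidationError, categorize, levenshtein)

#: uniform sampling ranges for each (submetric, category) band; open-ended
#: bands use bounded tails wide enough to bracket plausible clinic data
_VALUE_BANDS = {
    ("bmi", "poor"): (30.0, 60.0),
    ("bmi", "intermediate"): (25.0, 29.9),
    ("bmi", "ideal"): (16.0, 24.9),
    ("ldl", "poor"): (160.0, 300.0),
    ("ldl", "intermediate"): (130.0, 159.0),
    ("ldl", "ideal"): (40.0, 129.0),
    ("a1c", "poor"): (6.5, 14.0),
    ("a1c", "intermediate"): (5.7, 6.4),
    ("a1c", "ideal"): (4.0, 5.6),
    # bp bands are sampled jointly below
    ("sys", "poor"): (140.0, 220.0),
    ("sys", "intermediate"): (120.0, 139.0),
    ("sys", "ideal"): (90.0, 119.0),
    ("dia", "poor"): (90.0, 130.0),
    ("dia", "intermediate"): (80.0, 89.0),
    ("dia", "ideal"): (55.0, 79.0),
}


def _default_transitions() -> dict:
    m = stay_matrix(0.9)
    return {s: m.copy() for s in SUBMETRICS}


def stay_matrix(p: float) -> np.ndarray:
    """Symmetric 3x3 transition matrix with stay-probability ``p`` and the
    remaining mass split evenly between the other two states."""
    off = (1.0 - p) / 2.0
    return np.full((3, 3), off) + np.eye(3) * (p - off)


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_patients: int = 500
    date_window: tuple[str, str] = ("2004-01-01", "2016-12-31")
    #: expected measurements per patient-year, per submetric
    visit_rate: dict = field(default_factory=lambda: {s: 0.5 for s in SUBMETRICS})
    transition_matrix: dict = field(default_factory=_default_transitions)
    initial_distribution: dict = field(
        default_factory=lambda: {s: np.full(3, 1 / 3) for s in SUBMETRICS})
    cross_metric_correlation: float = 0.0
    medication_probability: float = 0.0
    name_noise_edits: int = 2
    #: (female, male, unknown) proportions and age (years) at window start
    sex_proportions: tuple = (0.56, 0.44 - 0.001, 0.001)
    age_mean: float = 45.0
    age_sd: float = 18.0
    #: small probability that a visit duplicates its date with the previous
    #: visit of the same submetric (exercises same-date tie handling)
    same_date_tie_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError(f"n_patients must be >= 1, got {self.n_patients}")
        start, end = (pd.Timestamp(d) for d in self.date_window)
        if not start < end:
            raise ValidationError(f"date_window start {start} must precede end {end}")
        for s in SUBMETRICS:
            if self.visit_rate[s] <= 0:
                raise ValidationError(f"visit_rate[{s}] must be > 0")
            m = np.asarray(self.transition_matrix[s], dtype=float)
            _check_stochastic(m, f"transition_matrix[{s}]")
            init = np.asarray(self.initial_distribution[s], dtype=float)
            if init.shape != (3,) or (init < 0).any() or abs(init.sum() - 1) > 1e-9:
                raise ValidationError(f"initial_distribution[{s}] is not a 3-simplex")
        if not 0 <= self.cross_metric_correlation <= 1:
            raise ValidationError("cross_metric_correlation must be in [0, 1]")
        if not 0 <= self.medication_probability <= 1:
            raise ValidationError("medication_probability must be in [0, 1]")
        if self.name_noise_edits < 0:
            raise ValidationError("name_noise_edits must be >= 0")
        if abs(sum(self.sex_proportions) - 1) > 1e-9:
            raise ValidationError("sex_proportions must sum to 1")

    @property
    def window_years(self) -> float:
        start, end = (pd.Timestamp(d) for d in self.date_window)
        return (end - start).days / 365.25


def _check_stochastic(m: np.ndarray, name: str) -> None:
    if m.shape != (3, 3) or (m < 0).any() or np.abs(m.sum(axis=1) - 1).max() > 1e-9:
        raise ValidationError(f"{name} is not a 3x3 row-stochastic matrix")


# ---------------------------------------------------------------------------
# Primitive samplers
# ---------------------------------------------------------------------------

def sample_trajectory(transition_matrix, initial, n_steps: int,
                      rng: np.random.Generator) -> list[str]:
    """Sample an ``n_steps``-long category sequence from a first-order
    Markov chain over (poor, intermediate, ideal)."""
    m = np.asarray(transition_matrix, dtype=float)
    _check_stochastic(m, "transition_matrix")
    init = np.asarray(initial, dtype=float)
    if init.shape != (3,) or (init < 0).any() or abs(init.sum() - 1) > 1e-9:
        raise ValidationError("initial is not a 3-simplex")
    if n_steps < 1:
        raise ValidationError(f"n_steps must be >= 1, got {n_steps}")
    states = np.empty(n_steps, dtype=np.int64)
    states[0] = rng.choice(3, p=init)
    for t in range(1, n_steps):
        states[t] = rng.choice(3, p=m[states[t - 1]])
    return [CATEGORIES[s] for s in states]


def category_to_value(submetric: str, category: str, rng: np.random.Generator):
    """Draw a measurement value that re-categorizes (untreated) to exactly
    the requested category.

    Returns ``(value1, value2)``: BP gives (systolic, diastolic); smoking
    gives (status, quit_months or None); others give (value, None).
    """
    if submetric not in SUBMETRICS:
        raise ValidationError(f"unknown submetric {submetric!r}")
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")

    if submetric == "smk":
        if category == "poor":
            return "current", None
        if category == "intermediate":
            return "former", float(rng.uniform(0.5, 12.0))
        # ideal: never, or former with a long-enough quit
        if rng.random() < 0.7:
            return "never", None
        return "former", float(rng.uniform(12.5, 36.0))

    if submetric == "bp":
        # joint draw keeping the pair inside the requested category
        sub = ("ideal", "intermediate")
        if category == "poor":  # at least one component in its poor band
            which = int(rng.integers(3))
            s_band = "poor" if which in (0, 2) else sub[rng.integers(2)]
            d_band = "poor" if which in (1, 2) else sub[rng.integers(2)]
        elif category == "ideal":
            s_band = d_band = "ideal"
        else:  # intermediate: neither poor, not both ideal
            opts = (("intermediate", "intermediate"), ("intermediate", "ideal"),
                    ("ideal", "intermediate"))
            s_band, d_band = opts[rng.integers(3)]
        sys_v = float(rng.uniform(*_VALUE_BANDS[("sys", s_band)]))
        dia_v = float(rng.uniform(*_VALUE_BANDS[("dia", d_band)]))
        return round(sys_v, 1), round(dia_v, 1)

    lo, hi = _VALUE_BANDS[(submetric, category)]
    return round(float(rng.uniform(lo, hi)), 2), None


_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def perturb_drug_name(canonical: str, n_edits: int,
                      rng: np.random.Generator, max_tries: int = 200) -> str:
    """Apply exactly ``n_edits`` edit operations so that the result is at
    Levenshtein distance exactly ``n_edits`` from ``canonical``.

    Candidate strings are produced by random insert/delete/substitute
    operations and accepted only when the realized distance matches; edits
    that cancel trigger a retry.
    """
    if not canonical:
        raise ValidationError("canonical name must be non-empty")
    if n_edits < 0:
        raise ValidationError("n_edits must be >= 0")
    if n_edits == 0:
        return canonical
    for _ in range(max_tries):
        s = list(canonical)
        for _ in range(n_edits):
            op = rng.integers(3)
            if op == 0 or not s:  # insert
                pos = int(rng.integers(len(s) + 1))
                s.insert(pos, _ALPHABET[rng.integers(26)])
            elif op == 1:  # delete
                s.pop(int(rng.integers(len(s))))
            else:  # substitute
                pos = int(rng.integers(len(s)))
                s[pos] = _ALPHABET[rng.integers(26)]
        out = "".join(s)
        if levenshtein(out, canonical) == n_edits:
            return out
    raise ValidationError(
        f"could not realize distance {n_edits} from {canonical!r} in {max_tries} tries")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, table: DrugClassTable | None = None):
    """Generate ``(patients, measurements, medications)`` long-format frames.

    ``measurements`` additionally carries a ``true_category`` column — the
    hidden Markov state that produced each value — for testing; it is not
    written by :func:`write_cohort`.
    """
    config.validate()
    if table is None:
        table = DrugClassTable.packaged()
    start = pd.Timestamp(config.date_window[0])
    window_days = int((pd.Timestamp(config.date_window[1]) - start).days)
    years = config.window_years

    # canonical drug names applicable per treatable submetric
    drug_pool = {
        sm: [(n, c) for n, c, t in zip(table.entries["canonical_name"],
                                       table.entries["drug_class"],
                                       table.entries["treats"]) if sm in t]
        for sm in TREATABLE}

    patients, measurements, medications = [], [], []
    for idx in range(config.n_patients):
        pss = np.random.SeedSequence(entropy=config.seed, spawn_key=(1, idx))
        prng = np.random.Generator(np.random.PCG64(pss))
        pid = f"P{idx:06d}"
        sex = ["female", "male", "unknown"][prng.choice(3, p=config.sex_proportions)]
        age0 = float(np.clip(prng.normal(config.age_mean, config.age_sd), 18.0, 95.0))
        birth = start - pd.to_timedelta(int(age0 * 365.25), unit="D")
        patients.append((pid, sex, birth.date().isoformat()))

        # shared latent initial state implements cross-metric coupling
        shared_init = int(prng.choice(3, p=np.full(3, 1 / 3)))

        for sm_i, sm in enumerate(SUBMETRICS):
            sss = np.random.SeedSequence(entropy=config.seed, spawn_key=(2, idx, sm_i))
            rng = np.random.Generator(np.random.PCG64(sss))
            n_visits = rng.poisson(config.visit_rate[sm] * years)
            if n_visits == 0:
                continue
            offsets = np.sort(rng.integers(0, window_days + 1, size=n_visits))
            # occasional duplicated dates exercise downstream tie handling
            for k in range(1, n_visits):
                if rng.random() < config.same_date_tie_rate:
                    offsets[k] = offsets[k - 1]
            offsets = np.sort(offsets)

            init = np.asarray(config.initial_distribution[sm], dtype=float)
            if rng.random() < config.cross_metric_correlation:
                first = shared_init
            else:
                first = int(rng.choice(3, p=init))
            m = np.asarray(config.transition_matrix[sm], dtype=float)
            states = [first]
            for _ in range(1, n_visits):
                states.append(int(rng.choice(3, p=m[states[-1]])))

            for off, st in zip(offsets, states):
                cat = CATEGORIES[st]
                date = (start + pd.Timedelta(days=int(off))).date().isoformat()
                v1, v2 = category_to_value(sm, cat, rng)
                measurements.append((pid, sm, date, v1, v2, cat))
                if (sm in TREATABLE and cat != "ideal"
                        and rng.random() < config.medication_probability):
                    name, _cls = drug_pool[sm][rng.integers(len(drug_pool[sm]))]
                    raw = perturb_drug_name(name, config.name_noise_edits, rng)
                    medications.append((pid, date, raw, _cls))

    patients_df = pd.DataFrame(patients, columns=["patient_id", "sex", "birth_date"])
    meas_df = pd.DataFrame(measurements, columns=[
        "patient_id", "submetric", "date", "value1", "value2", "true_category"])
    med_df = pd.DataFrame(medications, columns=[
        "patient_id", "date", "raw_name", "true_class"])
    return patients_df, meas_df, med_df


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "patients.csv": ["patient_id", "sex", "birth_date"],
    "measurements.csv": ["patient_id", "submetric", "date", "value1", "value2"],
    "medications.csv": ["patient_id", "date", "raw_name", "true_class"],
}
_DATE_COLS = {"patients.csv": ["birth_date"],
              "measurements.csv": ["date"],
              "medications.csv": ["date"]}


def write_cohort(patients: pd.DataFrame, measurements: pd.DataFrame,
                 medications: pd.DataFrame, directory) -> dict[str, Path]:
    """Write the three cohort tables as UTF-8 CSV files with ISO dates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = {"patients.csv": patients,
              "measurements.csv": measurements,
              "medications.csv": medications}
    paths = {}
    for fname, df in frames.items():
        cols = _SCHEMAS[fname]
        out = df.loc[:, cols] if len(df) else pd.DataFrame(columns=cols)
        path = directory / fname
        out.to_csv(path, index=False)
        paths[fname] = path
    return paths


def read_cohort(directory):
    """Load the three cohort tables, validating schema and dates.

    Raises :class:`ValidationError` naming the file, row and column on any
    missing column or unparseable date.
    """
    directory = Path(directory)
    frames = []
    for fname in ("patients.csv", "measurements.csv", "medications.csv"):
        path = directory / fname
        if not path.exists():
            raise ValidationError(f"missing cohort file: {path}")
        df = pd.read_csv(path)
        missing = set(_SCHEMAS[fname]) - set(df.columns)
        if missing:
            raise ValidationError(f"{fname}: missing columns {sorted(missing)}")
        for col in _DATE_COLS[fname]:
            parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
            bad = df.index[parsed.isna() & df[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"{fname}: unparseable date {df.loc[bad[0], col]!r} "
                    f"in row {int(bad[0])}, column {col!r}")
        if fname == "measurements.csv" and len(df):
            # numeric payloads except smoking status strings in value1
            not_smk = df["submetric"] != "smk"
            try:
                df.loc[not_smk, "value1"] = pd.to_numeric(df.loc[not_smk, "value1"])
                df["value2"] = pd.to_numeric(df["value2"], errors="raise")
            except (ValueError, TypeError) as e:
                raise ValidationError(f"{fname}: non-numeric measurement value ({e})") from e
        frames.append(df)
    return tuple(frames)
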