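"""Per-patient feature/label sequences from dated category rows.

For each patient the most recent categorized measurement of a submetric is
the prediction label; every strictly earlier category becomes a feature
token (submetric name + category, e.g. ``"bmipoor"``) carrying a time
offset in days before the patient's latest measurement date. Sequences are
split into train/test at the patient level (80/20 by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .categorize import CATEGORIES, CATEGORY_CODE, SUBMETRICS, ValidationError

logger = logging.getLogger(__name__)

#: fixed submetric order used for multi-output label vectors and the
#: 15-class (submetric x category) flattening
SUBMETRIC_ORDER = ("a1c", "ldl", "bmi", "bp", "smk")
ALL_TOKENS = tuple(f"{s}{c}" for s in SUBMETRIC_ORDER for c in CATEGORIES)


def make_token(submetric: str, category: str) -> str:
    """Concatenate submetric and category into a vocabulary token,
    e.g. ``("bmi", "poor") -> "bmipoor"``."""
    if submetric not in SUBMETRICS or category not in CATEGORIES:
        raise ValidationError(f"invalid (submetric, category): ({submetric}, {category})")
    return f"{submetric}{category}"


def parse_token(token: str) -> tuple[str, str]:
    """Invert :func:`make_token` (category names are suffix-unique)."""
    for c in CATEGORIES:
        if token.endswith(c):
            s = token[: -len(c)]
            if s in SUBMETRICS:
                return s, c
    raise ValidationError(f"unparseable token {token!r}")


@dataclass
class PatientSequence:
    """One patient's ordered token history plus demographics and label(s).

    ``time_offsets`` are days before the patient's latest measurement date,
    oldest first (non-increasing). ``labels`` maps submetric to the ordinal
    code (poor=0, intermediate=1, ideal=2) of its most recent measurement.
    """

    patient_id: str
    tokens: list[str]
    time_offsets: list[int]
    sex: str
    age_years: int
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.time_offsets) or not self.tokens:
            raise ValidationError(
                f"{self.patient_id}: need equal, non-zero token/offset counts")
        offs = self.time_offsets
        if any(offs[i] < offs[i + 1] for i in range(len(offs) - 1)):
            raise ValidationError(f"{self.patient_id}: offsets must be non-increasing")
        for t in self.tokens:
            parse_token(t)


def filter_patients(categories: pd.DataFrame, m: int = 1,
                    target: str = "all") -> list[str]:
    """Patient ids with more than ``m`` distinct measurement dates.

    Single-submetric target: the count applies to that submetric only.
    ``target="all"``: the patient must exceed ``m`` distinct dates in
    every one of the five submetrics.
    """
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    if len(categories) == 0:
        return []
    counts = (categories.groupby(["patient_id", "submetric"])["date"]
              .nunique().unstack(fill_value=0))
    if target == "all":
        need = [s for s in SUBMETRIC_ORDER]
        for s in need:
            if s not in counts.columns:
                return []
        ok = (counts[need] > m).all(axis=1)
    else:
        if target not in SUBMETRICS:
            raise ValidationError(f"unknown target {target!r}")
        if target not in counts.columns:
            return []
        ok = counts[target] > m
    return sorted(counts.index[ok])


def build_sequences(categories: pd.DataFrame, patients: pd.DataFrame,
                    target: str = "all", m: int = 1) -> list[PatientSequence]:
    """Build one :class:`PatientSequence` per eligible patient.

    Rows are sorted by date (same-date ties by input order; the last such
    row wins the label slot, earlier ones stay as features). In
    all-submetric mode each submetric's own latest row is its label and
    offsets are anchored to the patient's global latest measurement date.
    """
    eligible = filter_patients(categories, m=m, target=target)
    if not eligible:
        return []
    cats = categories.copy()
    cats["date"] = pd.to_datetime(cats["date"])
    if target != "all":
        cats = cats[cats["submetric"] == target]
    cats = cats[cats["patient_id"].isin(eligible)]
    # stable sort keeps input order within equal dates
    cats = cats.sort_values("date", kind="stable")

    demo = patients.set_index("patient_id")
    label_metrics = SUBMETRIC_ORDER if target == "all" else (target,)
    out = []
    for pid, grp in cats.groupby("patient_id", sort=True):
        anchor = grp["date"].iloc[-1]  # global latest measurement date
        label_idx: dict[str, int] = {}
        labels: dict[str, int] = {}
        for sm in label_metrics:
            sub = grp[grp["submetric"] == sm]
            label_idx[sm] = sub.index[-1]
            labels[sm] = CATEGORY_CODE[sub["category"].iloc[-1]]
        drop = set(label_idx.values())
        feats = grp.loc[[i not in drop for i in grp.index]]
        if len(feats) == 0:
            logger.warning("patient %s has no feature rows after label removal; dropped", pid)
            continue
        tokens = [make_token(s, c) for s, c in zip(feats["submetric"], feats["category"])]
        offsets = [int(d) for d in (anchor - feats["date"]).dt.days]
        birth = pd.Timestamp(demo.loc[pid, "birth_date"])
        age = int(np.floor((anchor - birth).days / 365.25))
        out.append(PatientSequence(patient_id=pid, tokens=tokens,
                                   time_offsets=offsets, sex=demo.loc[pid, "sex"],
                                   age_years=age, labels=labels))
    return out


def split_patients(sequences: list[PatientSequence], train_fraction: float = 0.8,
                   seed: int = 0):
    """Disjoint, exhaustive patient-level split with
    ``len(train) = round(train_fraction * n)``, deterministic under seed."""
    n = len(sequences)
    if n < 2:
        raise ValidationError(f"need at least 2 sequences to split, got {n}")
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = int(round(train_fraction * n))
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    order = rng.permutation(n)
    train = [sequences[i] for i in sorted(order[:n_train])]
    test = [sequences[i] for i in sorted(order[n_train:])]
    return train, test


# ---------------------------------------------------------------------------
# JSONL round-trip
# ---------------------------------------------------------------------------

def write_sequences(sequences: list[PatientSequence], path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in sequences:
            fh.write(json.dumps(asdict(s)) + "\n")
    return path


def read_sequences(path) -> list[PatientSequence]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                out.append(PatientSequence(**json.loads(line)))
            except (json.JSONDecodeError, TypeError) as e:
                raise ValidationError(f"{path}: bad record on line {i + 1}: {e}") from e
    return out
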