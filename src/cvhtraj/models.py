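"""Training front-end: LSTM classifier and LR / RF baselines.

Three prediction designs are supported, mirroring common practice for
categorical health-trajectory prediction:

* ``single:<submetric>`` — 3-class multiclass prediction of one submetric
  from that submetric's own history;
* ``method2`` — the same 3-class design repeated for each of the five
  submetrics on the common subpopulation;
* ``method1`` — one 15-output multilabel model predicting all five
  submetrics at once (submetric-major class order: a1c, ldl, bmi, bp, smk
  x poor, intermediate, ideal).

The baselines cannot consume variable-length sequences directly, so they
see a fixed-length summary of the same information: bag-of-token counts,
the ordinal code of the last observation per submetric, the gap in days
since the previous measurement, age and a sex one-hot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .categorize import CATEGORIES, ValidationError
from .embedding import SEX_LEVELS, EncodedDataset
from .lstm import LSTMClassifier, LSTMConfig
from .sequences import ALL_TOKENS, SUBMETRIC_ORDER, PatientSequence, parse_token

MULTILABEL_CLASSES = ALL_TOKENS  # 15 = 5 submetrics x 3 categories


@dataclass
class BaselineConfig:
    # logistic regression
    penalty: str = "l2"
    tol: float = 1e-4
    inverse_regularization: float = 1.0
    max_iter: int = 1000
    # random forest
    n_trees: int = 100
    max_features: str = "sqrt"
    min_leaf: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.tol <= 0 or self.inverse_regularization <= 0 or self.n_trees < 1 \
                or self.min_leaf < 1:
            raise ValidationError("baseline hyperparameters must be positive")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it."""

    kind: str                     # lstm | lr | rf
    design: str                   # single:<sm> | method1 | method2:<sm>
    model: object
    config: object
    class_order: tuple
    target: str | None = None     # submetric for 3-class designs
    extra: dict = field(default_factory=dict)

    def predict_proba(self, dataset: EncodedDataset,
                      sequences: list[PatientSequence] | None = None) -> np.ndarray:
        """Probability array; multiclass rows sum to 1, multilabel entries
        lie in [0, 1]. Row order follows the dataset."""
        if self.kind == "lstm":
            return self.model.predict_proba(dataset.features, dataset.mask,
                                            dataset.demographics)
        if sequences is None:
            raise ValidationError("baseline prediction requires the raw sequences")
        X = flatten_features(sequences)
        if self.design == "method1":
            return np.asarray(self.model.predict_proba(X))
        return _reorder_proba(self.model, self.model.predict_proba(X))


def _reorder_proba(clf, proba: np.ndarray) -> np.ndarray:
    """Expand sklearn probabilities to all 3 ordinal classes in order."""
    out = np.zeros((len(proba), 3), dtype=float)
    for j, cls in enumerate(clf.classes_):
        out[:, int(cls)] = proba[:, j]
    return out


# ---------------------------------------------------------------------------
# Baseline feature flattening
# ---------------------------------------------------------------------------

def flatten_features(sequences: list[PatientSequence]) -> np.ndarray:
    """Fixed-length summary features for LR / RF.

    Columns: 15 token counts (submetric-major), last-observed ordinal per
    submetric (-1 when never observed), days since previous measurement,
    age in years, sex one-hot (3).
    """
    n = len(sequences)
    tok_index = {t: i for i, t in enumerate(ALL_TOKENS)}
    X = np.zeros((n, len(ALL_TOKENS) + len(SUBMETRIC_ORDER) + 2 + len(SEX_LEVELS)))
    for i, s in enumerate(sequences):
        for tok in s.tokens:
            X[i, tok_index[tok]] += 1
        last: dict[str, int] = {}
        for tok in s.tokens:  # tokens are oldest-first
            sm, cat = parse_token(tok)
            last[sm] = CATEGORIES.index(cat)
        for j, sm in enumerate(SUBMETRIC_ORDER):
            X[i, 15 + j] = last.get(sm, -1)
        X[i, 20] = min(s.time_offsets)  # gap to the most recent feature
        X[i, 21] = s.age_years
        X[i, 22 + SEX_LEVELS.index(s.sex)] = 1.0
    return X


# ---------------------------------------------------------------------------
# Training entry points
# ---------------------------------------------------------------------------

def train_lstm(dataset: EncodedDataset, target: str | None = None,
               config: LSTMConfig | None = None,
               design: str | None = None) -> TrainedModel:
    """Train the LSTM in either output mode.

    For 3-class designs ``target`` names the submetric whose label is
    predicted; for the 15-output multilabel design pass
    ``config.output_mode = "multilabel15"`` and leave ``target`` unset.
    """
    config = config or LSTMConfig()
    config.validate()
    net = LSTMClassifier(dataset.features.shape[2],
                         dataset.demographics.shape[1], config)
    if config.output_mode == "multiclass3":
        if target is None:
            raise ValidationError("multiclass training requires a target submetric")
        Y = dataset.labels[target]
        class_order = CATEGORIES
        design = design or f"single:{target}"
    else:
        Y = dataset.multilabel_matrix(SUBMETRIC_ORDER)
        class_order = MULTILABEL_CLASSES
        design = design or "method1"
    net.fit(dataset.features, dataset.mask, dataset.demographics, Y)
    return TrainedModel(kind="lstm", design=design, model=net, config=config,
                        class_order=tuple(class_order), target=target)


def train_baseline(sequences: list[PatientSequence], labels, kind: str,
                   config: BaselineConfig | None = None,
                   design: str = "single", target: str | None = None,
                   multilabel: bool = False) -> TrainedModel:
    """Fit a logistic-regression or random-forest baseline.

    ``labels`` is an (n,) ordinal vector for 3-class designs or an
    (n, 15) 0/1 matrix with ``multilabel=True``.
    """
    config = config or BaselineConfig()
    config.validate()
    if kind not in ("lr", "rf"):
        raise ValidationError(f"unknown baseline kind {kind!r}")
    X = flatten_features(sequences)
    Y = np.asarray(labels)

    def make():
        if kind == "lr":
            # L2 penalty (the estimator's default); features standardized so
            # the day-scale gap column does not dominate the solver
            return make_pipeline(
                StandardScaler(),
                LogisticRegression(tol=config.tol,
                                   C=config.inverse_regularization,
                                   max_iter=config.max_iter))
        return RandomForestClassifier(n_estimators=config.n_trees,
                                      max_features=config.max_features,
                                      min_samples_leaf=config.min_leaf,
                                      random_state=config.seed)

    if multilabel:
        clf = OneVsRestClassifier(make())
        if Y.ndim != 2:
            raise ValidationError("multilabel baseline needs an (n, 15) target matrix")
        clf.fit(X, Y)
        return TrainedModel(kind=kind, design="method1", model=clf, config=config,
                            class_order=MULTILABEL_CLASSES)
    if len(np.unique(Y)) < 2:
        raise ValidationError(
            f"training labels contain only class {int(np.unique(Y)[0])}")
    clf = make()
    clf.fit(X, Y)
    return TrainedModel(kind=kind, design=f"{design}:{target}" if target else design,
                        model=clf, config=config, class_order=CATEGORIES,
                        target=target)


def multilabel_to_submetric_proba(proba15: np.ndarray, submetric: str) -> np.ndarray:
    """Slice a 15-output probability matrix down to one submetric's three
    category scores (not renormalized; used for one-vs-rest AUROC)."""
    k = SUBMETRIC_ORDER.index(submetric)
    return proba15[:, 3 * k: 3 * k + 3]
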