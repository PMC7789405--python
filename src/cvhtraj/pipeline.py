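"""End-to-end orchestration: simulate -> categorize -> build -> train ->
evaluate, driven by a single YAML config with one global seed.

Each stage is runnable standalone on the previous stage's files (see the
CLI); ``run_all`` chains them, records per-stage artifact checksums in a
manifest, and derives every stage's seed deterministically from the
global seed so a rerun reproduces the categorical artifacts exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .categorize import CategorizationRules, DrugClassTable, ValidationError, \
    categorize_cohort
from .embedding import EmbeddingConfig, encode, train_embeddings
from .evaluation import evaluate_multiclass, latest_label_correlations
from .lstm import LSTMConfig
from .models import BaselineConfig, train_baseline, train_lstm
from .sequences import SUBMETRIC_ORDER, build_sequences, split_patients, \
    write_sequences
from .synthetic import CohortConfig, generate_cohort, stay_matrix, write_cohort
from .categorize import SUBMETRICS

logger = logging.getLogger(__name__)


def _substream(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (< 2**31)."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def cohort_config_from_dict(d: dict) -> CohortConfig:
    kw = dict(d)
    if "stay_probability" in kw:
        p = kw.pop("stay_probability")
        # an explicit transition_matrix takes precedence over the shorthand
        kw.setdefault("transition_matrix", {s: stay_matrix(p) for s in SUBMETRICS})
    if "visit_rate" in kw and np.isscalar(kw["visit_rate"]):
        kw["visit_rate"] = {s: float(kw["visit_rate"]) for s in SUBMETRICS}
    if "transition_matrix" in kw and not isinstance(kw["transition_matrix"], dict):
        m = np.asarray(kw["transition_matrix"], dtype=float)
        kw["transition_matrix"] = {s: m for s in SUBMETRICS}
    if "date_window" in kw:
        kw["date_window"] = tuple(kw["date_window"])
    return CohortConfig(**kw)


def validate_config(path) -> list[str]:
    """Schema-check a run config; returns a (possibly empty) error list
    without side effects."""
    errors: list[str] = []
    path = Path(path)
    if not path.exists():
        return [f"config file not found: {path}"]
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        return [f"unreadable YAML: {e}"]
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    try:
        cfg = cohort_config_from_dict(raw.get("cohort", {}))
        cfg.validate()
    except (ValidationError, TypeError, KeyError) as e:
        errors.append(f"cohort: {e}")
    tf = raw.get("split", {}).get("train_fraction", 0.8)
    if not 0 < tf < 1:
        errors.append(f"split.train_fraction must be in (0, 1), got {tf}")
    target = raw.get("target", "all")
    if target not in ("all", *SUBMETRICS):
        errors.append(f"target must be one of all/{'/'.join(SUBMETRICS)}, got {target}")
    m = raw.get("m", 1)
    if not (isinstance(m, int) and m >= 1):
        errors.append(f"m must be an integer >= 1, got {m}")
    for key in ("rules_file",):
        if key in raw and not Path(raw[key]).exists():
            errors.append(f"{key}: file not found: {raw[key]}")
    return errors


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config_path, out_dir, seed: int | None = None) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    The run directory holds the cohort CSVs, categories.csv,
    sequences.jsonl, per-model evaluation reports, and manifest.json with
    a checksum for every artifact.
    """
    errors = validate_config(config_path)
    if errors:
        raise ValidationError("invalid config: " + "; ".join(errors))
    raw = yaml.safe_load(Path(config_path).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    global_seed = int(seed if seed is not None else raw.get("seed", 0))

    try:
        # -- simulate -------------------------------------------------------
        cohort_cfg = cohort_config_from_dict(raw.get("cohort", {}))
        cohort_cfg.seed = _substream(global_seed, "simulate")
        patients, measurements, medications = generate_cohort(cohort_cfg)
        write_cohort(patients, measurements, medications, out)
        logger.info("simulated %d patients, %d measurements, %d medication orders",
                    len(patients), len(measurements), len(medications))

        # -- categorize -----------------------------------------------------
        rules = CategorizationRules(**raw.get("rules", {}))
        table = DrugClassTable.packaged()
        categories = categorize_cohort(measurements, medications, table, rules)
        categories_path = out / "categories.csv"
        categories.to_csv(categories_path, index=False)

        # -- build ----------------------------------------------------------
        target = raw.get("target", "all")
        m = int(raw.get("m", 1))
        seqs = build_sequences(categories, patients, target=target, m=m)
        if len(seqs) < 2:
            raise ValidationError(f"only {len(seqs)} eligible patients; need >= 2")
        write_sequences(seqs, out / "sequences.jsonl")
        logger.info("built %d sequences (target=%s, m=%d)", len(seqs), target, m)

        train_seqs, test_seqs = split_patients(
            seqs, raw.get("split", {}).get("train_fraction", 0.8),
            seed=_substream(global_seed, "split"))

        # -- embed + encode -------------------------------------------------
        emb_cfg = EmbeddingConfig(**raw.get("embedding", {}))
        emb_cfg.seed = _substream(global_seed, "embedding")
        vectors = train_embeddings([s.tokens for s in train_seqs], emb_cfg)
        max_len = max(len(s.tokens) for s in seqs)
        enc_train = encode(train_seqs, vectors, emb_cfg, max_len=max_len)
        enc_test = encode(test_seqs, vectors, emb_cfg, max_len=max_len)

        # -- train + evaluate ----------------------------------------------
        model_kinds = raw.get("models", ["lstm", "lr", "rf"])
        eval_target = target if target != "all" else raw.get(
            "eval_submetric", SUBMETRIC_ORDER[0])
        reports = {}
        for kind in model_kinds:
            if kind == "lstm":
                lstm_cfg = LSTMConfig(**raw.get("lstm", {}))
                lstm_cfg.seed = _substream(global_seed, "lstm")
                model = train_lstm(enc_train, target=eval_target, config=lstm_cfg)
                proba = model.predict_proba(enc_test)
            else:
                base_cfg = BaselineConfig(**raw.get("baseline", {}))
                base_cfg.seed = _substream(global_seed, kind)
                model = train_baseline(train_seqs, enc_train.labels[eval_target],
                                       kind, base_cfg, target=eval_target)
                proba = model.predict_proba(enc_test, test_seqs)
            report = evaluate_multiclass(proba, enc_test.labels[eval_target])
            reports[kind] = report
            (out / f"report_{kind}.json").write_text(
                json.dumps(report.to_dict(), indent=2))
            logger.info("%s on %s: micro AUC %.3f, accuracy %.3f", kind,
                        eval_target, report.micro_auc, report.accuracy)

        if target == "all":
            corr = latest_label_correlations(seqs)
            corr.to_csv(out / "label_correlations.csv")

        manifest = {
            "version": __version__,
            "seed": global_seed,
            "config_sha256": _checksum(Path(config_path)),
            "n_patients": len(patients),
            "n_sequences": len(seqs),
            "n_train": len(train_seqs),
            "n_test": len(test_seqs),
            "eval_submetric": eval_target,
            "micro_auc": {k: r.micro_auc for k, r in reports.items()},
            "artifacts": {},
        }
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest["artifacts"][p.name] = _checksum(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception:
        (out / "failed").write_text("run aborted; see logs")
        raise
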