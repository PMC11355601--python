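"""Experiment orchestration: baseline vs DANN vs two-GRL DANN on a
source/target pair, with target-domain evaluation.

Protocol: the target domain is split 50/50 into an *adaptation* half (used
unlabelled during adversarial training) and a *test* half (labels used only
for evaluation), avoiding the optimistic leakage of testing on the very
images the model adapted to.  Training on the full target set is available
via ``holdout=False`` for the alternative protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import MetricsReport, evaluate
from .models import (FeatureExtractorSpec, assemble_baseline, assemble_dann)
from .nn.layers import seed_rng
from .synthetic import SHIFT_PRESETS, ShiftSpec, make_corpus
from .training import (LambdaSchedule, TrainConfig, TrainHistory,
                       train_baseline, train_dann)

__all__ = ["ArmResult", "run_arm", "split_target", "run_shift_benchmark",
           "BENCHMARK_ARMS"]

BENCHMARK_ARMS = ("baseline", "dann", "two_grl_dann")


@dataclass
class ArmResult:
    """Outcome of one training arm on one seed."""

    arm: str
    extractor: str
    seed: int
    report: MetricsReport
    history: TrainHistory
    source_report: MetricsReport | None = None

    @property
    def target_accuracy(self) -> float:
        return self.report.accuracy


def split_target(images, labels, seed: int):
    """Deterministic 50/50 split of the target domain into
    (adapt_images, test_images, test_labels)."""
    n = images.shape[0]
    order = seed_rng(seed, "target-split").permutation(n)
    half = n // 2
    adapt, test = order[:half], order[half:]
    return images[adapt], images[test], labels[test]


def run_arm(arm: str, fe_spec: FeatureExtractorSpec, source_images,
            source_labels, target_adapt, target_test, target_test_labels,
            cfg: TrainConfig) -> ArmResult:
    """Train one arm and evaluate it on the held-out target test set."""
    if arm == "baseline":
        model = assemble_baseline(fe_spec, seed=cfg.seed)
        model, history = train_baseline(model, source_images, source_labels,
                                        cfg)
    elif arm in ("dann", "two_grl_dann"):
        model = assemble_dann(fe_spec, variant=arm, seed=cfg.seed)
        model, history = train_dann(model, source_images, source_labels,
                                    target_adapt, cfg)
    else:
        raise ValueError(f"unknown arm '{arm}'; valid: "
                         f"{', '.join(BENCHMARK_ARMS)}")
    report = evaluate(model, target_test, target_test_labels)
    src_report = evaluate(model, source_images, source_labels)
    return ArmResult(arm=arm, extractor=fe_spec.kind, seed=cfg.seed,
                     report=report, history=history, source_report=src_report)


def run_shift_benchmark(seed: int = 0, n_per_class_per_domain: int = 200,
                        image_size: int = 64, epochs: int = 15,
                        n_seeds: int = 3, extractor: str = "cnn_dropout",
                        shift: ShiftSpec = SHIFT_PRESETS["strong"],
                        arms=BENCHMARK_ARMS,
                        lambda_schedule: LambdaSchedule | None = None):
    """The synthetic strong-shift comparison: each arm trained on the source
    domain, adapted (where applicable) to the unlabelled target half, and
    scored on the held-out target half, over ``n_seeds`` replicate seeds.

    Returns (tidy per-run DataFrame, list of ArmResult).
    """
    if lambda_schedule is None:
        lambda_schedule = LambdaSchedule()
    child_seeds = [int(s) for s in
                   np.random.SeedSequence(seed).generate_state(n_seeds)
                   % (2 ** 31)]
    fe_spec = FeatureExtractorSpec(extractor, image_size)
    rows, results = [], []
    for rep, s in enumerate(child_seeds):
        corpus = make_corpus(n_per_class_per_domain, image_size, shift, seed=s)
        src_i, src_y = corpus.domain(0)
        tgt_i, tgt_y = corpus.domain(1)
        adapt_i, test_i, test_y = split_target(tgt_i, tgt_y, seed=s)
        cfg = TrainConfig(epochs=epochs, batch_size=16,
                          lambda_schedule=lambda_schedule, seed=s)
        for arm in arms:
            res = run_arm(arm, fe_spec, src_i, src_y, adapt_i, test_i, test_y,
                          cfg)
            results.append(res)
            rows.append({
                "arm": arm, "extractor": extractor, "replicate": rep,
                "seed": s,
                "target_accuracy": res.report.accuracy,
                "target_f1": res.report.f1,
                "source_accuracy": res.source_report.accuracy,
                "domain_accuracy_first": (
                    res.history.records[0].domain_accuracy),
                "domain_accuracy_last": (
                    res.history.records[-1].domain_accuracy),
            })
    return pd.DataFrame(rows), results


def history_frame(history: TrainHistory) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in history.records])


# ---------------------------------------------------------------------------
# config-driven experiments
# ---------------------------------------------------------------------------

def _schedule_from(cfg: dict) -> LambdaSchedule:
    return LambdaSchedule(mode=cfg.get("mode", "annealed"),
                          lambda_max=cfg.get("lambda_max", 1.0),
                          gamma=cfg.get("gamma", 10.0))


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    import yaml
    from pathlib import Path
    text = Path(config).read_text()
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise ValueError("experiment config must be a YAML mapping")
    return loaded


def run_experiment(config, out_dir=None):
    """Run the arms a config describes and write report files.

    The config (YAML path or dict) names the data (synthetic preset or
    source/target directories), one or more model variants and extractors,
    and the training hyperparameters.  Writes per-run ``report_*.json`` and
    ``history_*.csv`` plus a combined Table-style ``summary.csv``
    (model x feature extractor x accuracy/F1) under ``out_dir``.

    Returns the summary DataFrame.
    """
    import json
    from pathlib import Path

    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out", "results"))
    out.mkdir(parents=True, exist_ok=True)

    data_cfg = dict(cfg.get("data", {}))
    kind = data_cfg.get("kind", "synthetic")
    image_size = int(data_cfg.get("image_size", 64))
    if kind == "synthetic":
        shift = data_cfg.get("shift", "strong")
        if isinstance(shift, str):
            try:
                shift = SHIFT_PRESETS[shift]
            except KeyError:
                raise ValueError(
                    f"unknown shift preset '{shift}'; valid: "
                    f"{', '.join(SHIFT_PRESETS)}") from None
        else:
            shift = ShiftSpec(**shift)
        corpus = make_corpus(int(data_cfg.get("n_per_class_per_domain", 100)),
                             image_size, shift, seed=seed)
        src_i, src_y = corpus.domain(0)
        tgt_i, tgt_y = corpus.domain(1)
    elif kind == "files":
        from .data import DatasetManifest, load_dataset
        src = load_dataset(DatasetManifest(
            root=data_cfg["source"]["root"],
            labels_csv=data_cfg["source"].get("labels_csv", "labels.csv"),
            image_size=image_size))
        tgt = load_dataset(DatasetManifest(
            root=data_cfg["target"]["root"],
            labels_csv=data_cfg["target"].get("labels_csv", "labels.csv"),
            image_size=image_size))
        src_i, src_y = src.images, src.class_labels
        tgt_i, tgt_y = tgt.images, tgt.class_labels
    else:
        raise ValueError(f"unknown data kind '{kind}'")

    holdout = bool(cfg.get("evaluation", {}).get("holdout", True))
    if holdout:
        adapt_i, test_i, test_y = split_target(tgt_i, tgt_y, seed)
    else:
        adapt_i, test_i, test_y = tgt_i, tgt_i, tgt_y

    train_cfg = dict(cfg.get("train", {}))
    tcfg = TrainConfig(
        epochs=int(train_cfg.get("epochs", 100)),
        batch_size=int(train_cfg.get("batch_size", 16)),
        learning_rate=float(train_cfg.get("learning_rate", 1e-4)),
        lambda_schedule=_schedule_from(train_cfg.get("lambda_schedule", {})),
        seed=seed)

    model_cfg = cfg.get("model", {})
    variants = model_cfg.get("variant", "dann")
    extractors = model_cfg.get("extractor", "cnn_dropout")
    variants = [variants] if isinstance(variants, str) else list(variants)
    extractors = ([extractors] if isinstance(extractors, str)
                  else list(extractors))

    rows = []
    for ex in extractors:
        fe_spec = FeatureExtractorSpec(ex, image_size)
        for arm in variants:
            res = run_arm(arm, fe_spec, src_i, src_y, adapt_i, test_i,
                          test_y, tcfg)
            tag = f"{arm}_{ex}"
            (out / f"report_{tag}.json").write_text(
                json.dumps(res.report.as_dict(), indent=2))
            history_frame(res.history).to_csv(out / f"history_{tag}.csv",
                                              index=False)
            rows.append({"model": arm, "feature_extractor": ex,
                         "accuracy": round(res.report.accuracy, 4),
                         "f1": round(res.report.f1, 2)})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)
    return summary
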