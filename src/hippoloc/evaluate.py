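"""Classification metrics, localization scoring, subject-level folds, the
episode-termination ablation harness, and the end-to-end pipeline.

Metrics follow the standard confusion-matrix definitions with class 1
(disease) as positive; ratios with a zero denominator are reported as
``None`` (absent) rather than 0 so they cannot silently inflate the balanced
accuracy.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, dqn, phantom, preprocess
from .env import EnvConfig, TerminationStrategy, iou

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FoldPlan",
    "confusion_counts",
    "metrics",
    "localization_report",
    "make_fold_plan",
    "run_ablation",
    "run_pipeline",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    n: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def confusion_counts(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    """2x2 tally with 1 as the positive (disease) class."""
    y = np.asarray(true_labels).ravel()
    p = np.asarray(predicted_labels).ravel()
    if y.size == 0 or y.shape != p.shape:
        raise ValueError("labels must be non-empty and of equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall/sensitivity, F1, specificity, balanced accuracy."""
    if counts.total == 0:
        raise ValueError("no samples to evaluate")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    ba = None
    if recall is not None and specificity is not None:
        ba = (recall + specificity) / 2
    return MetricsReport(
        accuracy=(tp + tn) / counts.total,
        precision=precision,
        recall=recall,
        f1=f1,
        sensitivity=recall,
        specificity=specificity,
        balanced_accuracy=ba,
        n=counts.total,
    )


def localization_report(
    episode_results: Sequence[dqn.EpisodeResult],
    success_iou: float = 0.5,
    histogram_bins: int = 10,
) -> dict:
    """Success rate (final IoU >= threshold), mean final IoU and step histogram."""
    if len(episode_results) == 0:
        raise ValueError("no episode results to report")
    ious = np.array([r.final_iou for r in episode_results])
    steps = np.array([r.steps for r in episode_results])
    counts, edges = np.histogram(steps, bins=histogram_bins)
    return {
        "n": len(episode_results),
        "success_rate": float((ious >= success_iou).mean()),
        "mean_final_iou": float(ious.mean()),
        "mean_steps": float(steps.mean()),
        "episode_length_histogram": {
            "counts": counts.tolist(),
            "edges": edges.tolist(),
        },
    }


@dataclass(frozen=True)
class FoldPlan:
    k: int
    folds: dict  # fold index -> tuple of subject_ids
    test_ids: tuple

    def fold_of(self, subject_id: str) -> int | None:
        for i, ids in self.folds.items():
            if subject_id in ids:
                return i
        return None


def make_fold_plan(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified-by-class subject-level folds over the training split.

    The held-out test split never enters any fold.  Deterministic per seed.
    """
    train = manifest[manifest.split == "train"]
    test_ids = tuple(manifest.loc[manifest.split != "train", "subject_id"])
    rng = np.random.default_rng(seed)
    folds: dict[int, list] = {i: [] for i in range(k)}
    for label in sorted(train.label.unique()):
        ids = list(train.loc[train.label == label, "subject_id"])
        if len(ids) < k:
            raise ValueError(
                f"class {label} has {len(ids)} training subjects; need >= {k} for {k} folds"
            )
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            folds[i % k].append(sid)
    return FoldPlan(k=k, folds={i: tuple(v) for i, v in folds.items()}, test_ids=test_ids)


def run_ablation(
    test_slices: Sequence[preprocess.SliceSample],
    env_config: EnvConfig,
    agent: dqn.TrainedAgent | None = None,
    qvalue_fn_factory=None,
    seed: int = 0,
) -> dict:
    """Run localization under both episode-termination strategies.

    Identical pipelines differing only in ``termination_strategy``; the report
    for the IMMEDIATE arm carries the episode-length histogram (under NOOP all
    episodes have the same length by construction).  ``qvalue_fn_factory``
    (sample -> state -> values) may replace the trained agent, e.g. with the
    IoU oracle.
    """
    out = {}
    for strategy in (TerminationStrategy.IMMEDIATE, TerminationStrategy.NOOP):
        cfg = replace(env_config, termination_strategy=strategy)
        rng = np.random.default_rng(seed)
        results = []
        for sample in test_slices:
            qfn = qvalue_fn_factory(sample, cfg) if qvalue_fn_factory is not None else None
            net = agent.target_net if agent is not None else None
            results.append(dqn.localize(net, sample, cfg, rng=rng, qvalue_fn=qfn))
        report = localization_report(results, cfg.success_iou)
        report["strategy"] = strategy.value
        out[strategy.value] = report
    return out


def _extract_crops(slices, boxes, size):
    return np.stack(
        [classify.crop_and_resize(s.image, b, size) for s, b in zip(slices, boxes)]
    )


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Orchestrate generate -> preprocess -> train-dqn -> localize ->
    train-classifier -> evaluate, writing JSON/CSV artifacts to ``out_dir``.

    ``config`` keys (all optional, with fast-profile defaults): ``seed``,
    ``n_per_class``, ``phantom`` / ``env`` / ``dqn`` / ``classifier``
    (dataclass field overrides), ``slice_hw``, ``fusion`` (bool).
    Stages whose artifact file already exists are skipped when
    ``config['resume']`` is true.
    """
    from .env import FAST_ENV_CONFIG

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    resume = bool(config.get("resume", False))

    pcfg = replace(phantom.FAST_PHANTOM_CONFIG, seed=seed, **config.get("phantom", {}))
    dcfg = replace(dqn.FAST_DQN_CONFIG, seed=seed, **config.get("dqn", {}))
    env_over = dict(config.get("env", {}))
    if isinstance(env_over.get("termination_strategy"), str):
        env_over["termination_strategy"] = TerminationStrategy(env_over["termination_strategy"])
    env_cfg = replace(FAST_ENV_CONFIG, **env_over)
    ccfg = replace(classify.FAST_CLASSIFIER_CONFIG, seed=seed, **config.get("classifier", {}))
    slice_hw = tuple(config.get("slice_hw", pcfg.volume_shape[1:]))
    n_per_class = int(config.get("n_per_class", 20))

    def _stage(name: str, fn):
        path = out_dir / f"{name}.json"
        if resume and path.exists():
            return json.loads(path.read_text())
        result = fn()
        path.write_text(json.dumps(result, indent=2))
        return result

    # generate + preprocess (always in-memory; the manifest is the artifact)
    dataset = phantom.generate_dataset(pcfg, n_per_class=n_per_class, seed=seed)
    dataset.manifest.to_csv(out_dir / "manifest.csv", index=False)
    train_vols = dataset.volumes("train")
    test_vols = dataset.volumes("test")
    train_slices = preprocess.make_slice_dataset(train_vols, target_hw=slice_hw)
    # test slices are normalized with training-split statistics
    train_stats = preprocess.NormalizationStats.from_arrays(
        [v.image[preprocess.select_optimal_slice(v.mask)] for v in train_vols]
    )
    test_slices = preprocess.make_slice_dataset(test_vols, target_hw=slice_hw, stats=train_stats)

    agent = dqn.train_dqn(train_slices, env_cfg, dcfg)
    agent.log.to_csv(out_dir / "dqn_training_log.csv", index=False)

    rng = np.random.default_rng(seed)
    loc_results = [dqn.localize(agent.target_net, s, env_cfg, rng=rng) for s in test_slices]
    loc_report = _stage(
        "localization", lambda: localization_report(loc_results, env_cfg.success_iou)
    )

    # classify DQN-extracted crops; failed localizations are retained
    train_loc = [dqn.localize(agent.target_net, s, env_cfg, rng=rng) for s in train_slices]
    size = ccfg.crop_size
    X_train = _extract_crops(train_slices, [r.final_box for r in train_loc], size)
    y_train = [s.label for s in train_slices]
    X_test = _extract_crops(test_slices, [r.final_box for r in loc_results], size)
    y_test = np.array([s.label for s in test_slices])
    clf = classify.train_classifier(X_train, y_train, ccfg)
    _, pred = classify.predict(clf, X_test)
    clf_report = _stage(
        "classification", lambda: metrics(confusion_counts(y_test, pred)).as_dict()
    )
    _write_plots(out_dir, agent.log, loc_results)
    summary = {
        "seed": seed,
        "localization": loc_report,
        "classification": clf_report,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def _write_plots(out_dir: Path, training_log: pd.DataFrame, loc_results) -> None:
    """Episode-length histogram and per-epoch training curve as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist([r.steps for r in loc_results], bins=10, edgecolor="black")
    ax.set_xlabel("steps to final box")
    ax.set_ylabel("count")
    ax.set_title("Episode lengths at test time")
    fig.tight_layout()
    fig.savefig(out_dir / "episode_length_histogram.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    by_epoch = training_log.groupby("epoch").final_iou.mean()
    ax.plot(by_epoch.index, by_epoch.values, marker="o")
    ax.set_xlabel("epoch")
    ax.set_ylabel("mean final IoU (training episodes)")
    ax.set_title("DQN training curve")
    fig.tight_layout()
    fig.savefig(out_dir / "training_curve.png", dpi=120)
    plt.close(fig)
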