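"""Repeated-split benchmark harness for comparing resamplers.

Protocol: per repetition the dataset is partitioned uniformly at random into
``n_groups`` near-equal groups; ``n_test_groups`` of them form the test set
and the rest the training set.  Each (resampler, balance rate, classifier)
cell is evaluated on every repetition and the metric suite is averaged over
repetitions.  A fresh partition is drawn for every repetition.

Two split orders are supported:

* ``resample-then-split`` — the whole dataset is balanced first, then split.
  This mirrors protocols whose reported train/test counts are fractions of
  the already-balanced totals, but it lets synthetic points reach the test
  set.
* ``split-then-resample`` — only the training portion is resampled; the test
  set stays purely original.  This is the leakage-free protocol and the one
  to prefer for real evaluations.

Baseline resamplers beyond classical SMOTE (Borderline-SMOTE1/2, ADASYN) are
optional plug-ins resolved at import time from ``imblearn`` when that
package is installed; their absence shrinks the grid, never fails it.
"""

from __future__ import annotations

import importlib
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .data_model import LabeledDataset, validate_dataset
from .cluster_weighting import as_rng
from .metrics import evaluate, METRIC_NAMES
from .synthesis import classic_smote, oversample

__all__ = [
    "ExperimentConfig", "ExperimentResult", "make_splits", "run_experiment",
    "available_resamplers", "available_classifiers", "load_config",
    "save_config", "plot_metric_panels",
]

RANK_METRICS = ("precision", "recall", "f1", "g_mean", "auc")


@dataclass
class ExperimentConfig:
    """Grid definition for one benchmark run."""

    balance_rates: tuple = (0.6, 0.7, 0.8, 0.9)
    n_repetitions: int = 30
    n_groups: int = 10
    n_test_groups: int = 3
    resamplers: tuple = ("none", "sd-kmsmote", "smote")
    classifiers: tuple = ("decision-tree", "random-forest")
    split_order: str = "resample-then-split"
    seed: int = 0
    resampler_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.n_test_groups < self.n_groups):
            raise ValueError("need 0 < n_test_groups < n_groups")
        for e in self.balance_rates:
            if not (0.0 < e <= 1.0):
                raise ValueError("balance rates must lie in (0, 1]")
        if self.split_order not in ("resample-then-split",
                                    "split-then-resample"):
            raise ValueError(f"unknown split_order {self.split_order!r}")


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("balance_rates", "resamplers", "classifiers"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return ExperimentConfig(**raw)


def save_config(config: ExperimentConfig, path) -> None:
    data = asdict(config)
    for key in ("balance_rates", "resamplers", "classifiers"):
        data[key] = list(data[key])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def make_splits(n_samples, n_groups, n_test_groups, rng, *,
                n_repetitions: int = 1):
    """Random group partitions: a list of (train_idx, test_idx) pairs.

    Samples are shuffled and cut into ``n_groups`` groups whose sizes differ
    by at most one; ``n_test_groups`` randomly chosen groups form the test
    set.  One independent partition per repetition.
    """
    if n_samples < n_groups:
        raise ValueError("too few samples: n_samples < n_groups")
    if not (0 < n_test_groups < n_groups):
        raise ValueError("need 0 < n_test_groups < n_groups")
    rng = as_rng(rng)
    splits = []
    for _ in range(n_repetitions):
        perm = rng.permutation(n_samples)
        groups = np.array_split(perm, n_groups)
        test_ids = rng.choice(n_groups, size=n_test_groups, replace=False)
        test_mask = np.zeros(n_groups, dtype=bool)
        test_mask[test_ids] = True
        test = np.sort(np.concatenate([g for g, t in zip(groups, test_mask) if t]))
        train = np.sort(np.concatenate(
            [g for g, t in zip(groups, test_mask) if not t]))
        splits.append((train, test))
    return splits


# ---------------------------------------------------------------------------
# resampler registry: id -> fn(dataset, target_E, rng, **opts)
#                           -> (LabeledDataset, is_synthetic bool array)

def _resample_none(dataset, target_E, rng, **_):
    return dataset, np.zeros(dataset.n_samples, dtype=bool)


def _resample_sdksmote(dataset, target_E, rng, **opts):
    res = oversample(dataset, target_E, rng=rng, allow_noop=True, **opts)
    return res.balanced_dataset, res.is_synthetic


def _resample_smote(dataset, target_E, rng, **opts):
    res = classic_smote(dataset, target_E, rng=rng, allow_noop=True,
                        k_syn=opts.get("k_syn", 5))
    return res.balanced_dataset, res.is_synthetic


def _imblearn_plugin(maker):
    def fn(dataset, target_E, rng, **_):
        sampler = maker(target_E, int(as_rng(rng).integers(2**31)))
        y = dataset.labels.astype(str)
        try:
            Xr, yr = sampler.fit_resample(dataset.features, y)
        except ValueError:
            return dataset, np.zeros(dataset.n_samples, dtype=bool)
        ds = validate_dataset(Xr, yr.astype(object),
                              str(dataset.minority_label))
        synth = np.zeros(Xr.shape[0], dtype=bool)
        synth[dataset.n_samples:] = True
        return ds, synth
    return fn


def available_resamplers() -> dict:
    """Registry of resampler ids; imblearn-backed entries appear only when
    that optional package is importable."""
    registry = {
        "none": _resample_none,
        "sd-kmsmote": _resample_sdksmote,
        "smote": _resample_smote,
    }
    try:
        over = importlib.import_module("imblearn.over_sampling")
    except ImportError:
        return registry
    registry["borderline-smote1"] = _imblearn_plugin(
        lambda e, s: over.BorderlineSMOTE(sampling_strategy=e, kind="borderline-1",
                                          random_state=s))
    registry["borderline-smote2"] = _imblearn_plugin(
        lambda e, s: over.BorderlineSMOTE(sampling_strategy=e, kind="borderline-2",
                                          random_state=s))
    registry["adasyn"] = _imblearn_plugin(
        lambda e, s: over.ADASYN(sampling_strategy=e, random_state=s))
    return registry


# ---------------------------------------------------------------------------
# classifier adapters: fit on (features, labels); emit hard labels and
# minority scores for new features

class SklearnAdapter:
    """Wraps any sklearn classifier into the harness contract."""

    def __init__(self, estimator, minority_label):
        self.estimator = estimator
        self.minority_label = minority_label

    def fit(self, X, y):
        self.estimator.fit(X, np.asarray(y, dtype=str))
        return self

    def predict(self, X):
        return self.estimator.predict(X).astype(object)

    def minority_scores(self, X):
        if hasattr(self.estimator, "predict_proba"):
            classes = list(self.estimator.classes_)
            col = classes.index(str(self.minority_label))
            return self.estimator.predict_proba(X)[:, col]
        return None


class MajorityVote:
    """Degenerate baseline: always predicts the training majority class."""

    def __init__(self, minority_label=None):
        self.minority_label = minority_label

    def fit(self, X, y):
        y = np.asarray(y, dtype=object)
        vals, counts = np.unique(y.astype(str), return_counts=True)
        self._label = vals[counts.argmax()]
        return self

    def predict(self, X):
        return np.full(len(X), self._label, dtype=object)

    def minority_scores(self, X):
        return None


def available_classifiers() -> dict:
    """Classifier ids -> factory(minority_label, seed)."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.tree import DecisionTreeClassifier
    return {
        "decision-tree": lambda ml, seed: SklearnAdapter(
            DecisionTreeClassifier(random_state=seed), ml),
        "random-forest": lambda ml, seed: SklearnAdapter(
            RandomForestClassifier(random_state=seed), ml),
        "majority-vote": lambda ml, seed: MajorityVote(ml),
    }


@dataclass
class ExperimentResult:
    """Tidy per-repetition metrics plus aggregation helpers."""

    results: pd.DataFrame      # one row per cell per repetition
    config: ExperimentConfig
    n_failures: int = 0

    def aggregate(self) -> pd.DataFrame:
        """Mean metrics over repetitions per (resampler, rate, classifier)."""
        keys = ["resampler", "balance_rate", "classifier"]
        return (self.results.groupby(keys)[list(METRIC_NAMES)]
                .mean().reset_index())

    def rank_tally(self, metrics=RANK_METRICS) -> pd.DataFrame:
        """Count, per resampler, how often it takes each rank.

        One ranking per (balance_rate, classifier, metric) cell; rank 1 is
        the best mean value.  Ties share the better (smaller) rank.
        """
        agg = self.aggregate()
        resamplers = list(self.config.resamplers)
        tally = pd.DataFrame(
            0, index=resamplers,
            columns=[f"rank{r}" for r in range(1, len(resamplers) + 1)],
        )
        for (_, _), cell in agg.groupby(["balance_rate", "classifier"]):
            for metric in metrics:
                ranks = cell.set_index("resampler")[metric].rank(
                    ascending=False, method="min")
                for rs, rk in ranks.items():
                    tally.loc[rs, f"rank{int(rk)}"] += 1
        return tally


def run_experiment(dataset: LabeledDataset, config: ExperimentConfig, *,
                   resamplers=None, classifiers=None,
                   dataset_name: str = "dataset") -> ExperimentResult:
    """Run the full (resampler x balance rate x classifier) grid.

    Classifier failures on individual repetitions are recorded and excluded
    from the means rather than aborting the grid.  The entire run is
    deterministic in ``config.seed``.
    """
    rng = as_rng(config.seed)
    registry = resamplers if resamplers is not None else available_resamplers()
    clf_registry = (classifiers if classifiers is not None
                    else available_classifiers())
    missing = [r for r in config.resamplers if r not in registry]
    if missing:
        warnings.warn(f"resamplers unavailable, skipped: {missing}",
                      stacklevel=2)
    active = [r for r in config.resamplers if r in registry]

    rows = []
    n_failures = 0
    for rep in range(config.n_repetitions):
        # one partition of the *original* data per repetition, shared by the
        # split-then-resample arms so every method sees the same test set
        (orig_train, orig_test), = make_splits(
            dataset.n_samples, config.n_groups, config.n_test_groups, rng)
        for resampler_id in active:
            for rate in config.balance_rates:
                res_rng = np.random.default_rng(rng.integers(2**31))
                opts = config.resampler_options.get(resampler_id, {})
                if config.split_order == "resample-then-split":
                    balanced, _ = registry[resampler_id](
                        dataset, rate, res_rng, **opts)
                    (train, test), = make_splits(
                        balanced.n_samples, config.n_groups,
                        config.n_test_groups,
                        np.random.default_rng(rng.integers(2**31)))
                    train_ds, test_ds = balanced, balanced
                else:
                    sub = validate_dataset(
                        dataset.features[orig_train],
                        dataset.labels[orig_train], dataset.minority_label)
                    balanced, _ = registry[resampler_id](
                        sub, rate, res_rng, **opts)
                    # test indices address the ORIGINAL dataset, so no
                    # synthetic row can ever reach the test set here
                    train = np.arange(balanced.n_samples)
                    test = orig_test
                    train_ds, test_ds = balanced, dataset
                for clf_id in config.classifiers:
                    clf_seed = int(rng.integers(2**31))
                    try:
                        clf = clf_registry[clf_id](dataset.minority_label,
                                                   clf_seed)
                        clf.fit(train_ds.features[train],
                                train_ds.labels[train])
                        y_pred = clf.predict(test_ds.features[test])
                        scores = clf.minority_scores(test_ds.features[test])
                        rep_metrics = evaluate(
                            test_ds.labels[test], y_pred,
                            dataset.minority_label, scores)
                    except Exception as exc:  # recorded, not fatal
                        n_failures += 1
                        warnings.warn(
                            f"classifier {clf_id!r} failed on repetition "
                            f"{rep}: {exc}", stacklevel=2)
                        continue
                    rows.append({
                        "dataset": dataset_name, "repetition": rep,
                        "resampler": resampler_id, "balance_rate": rate,
                        "classifier": clf_id, **rep_metrics.as_dict(),
                    })
    results = pd.DataFrame(rows)
    cfg = ExperimentConfig(**{**asdict(config),
                              "resamplers": tuple(active)})
    return ExperimentResult(results=results, config=cfg,
                            n_failures=n_failures)


def plot_metric_panels(result: ExperimentResult, out_path=None,
                       metrics=RANK_METRICS):
    """Metric-vs-balance-rate panels, one per (metric, classifier)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = result.aggregate()
    classifiers = sorted(agg["classifier"].unique())
    fig, axes = plt.subplots(len(classifiers), len(metrics),
                             figsize=(3 * len(metrics), 2.6 * len(classifiers)),
                             squeeze=False)
    for i, clf in enumerate(classifiers):
        for j, metric in enumerate(metrics):
            ax = axes[i][j]
            for rs, grp in agg[agg["classifier"] == clf].groupby("resampler"):
                grp = grp.sort_values("balance_rate")
                ax.plot(grp["balance_rate"], grp[metric], marker="o", label=rs)
            ax.set_title(f"{metric} / {clf}", fontsize=8)
            ax.set_xlabel("balance rate")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
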