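"""Balanced, repeated, cross-validated SVM evaluation of quality features.

Protocol per repeat: draw a class-balanced subsample (all minority-class
volumes plus an equal-size random draw of the majority class), split it
with stratified k-fold cross-validation, standardize features on each
training fold only, train an SVM, classify the held-out fold, and pool
the fold predictions into accuracy, sensitivity and specificity.  The
repeat loop re-randomizes both the subsample and the fold assignment.

Conventions: sensitivity is the percentage of not-usable volumes
correctly flagged; specificity the percentage of usable volumes
correctly passed; all rates are percentages in [0, 100].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import MriqaError, QualityLabel

__all__ = [
    "FEATURE_GROUPS",
    "ExperimentConfig",
    "EvaluationResult",
    "PermutationResult",
    "DegenerateFoldError",
    "balanced_subsample",
    "kfold_split",
    "build_design_matrix",
    "train_and_evaluate",
    "permutation_null",
    "compare_combinations",
    "severity_contrast",
]

FEATURE_GROUPS = ("VF1", "VF2", "VF3", "ASF1", "ASF2", "ASF3")

_GROUP_COLUMNS = {
    "VF1": [f"vf1_{i:03d}" for i in range(100)],
    "VF2": [f"vf2{c}_{i:03d}" for c in ("gm", "wm", "csf") for i in range(100)],
    "VF3": ["vf3"],
    "ASF1": ["asf1"],
    "ASF2": ["asf2"],
    "ASF3": ["asf3"],
}

_HISTOGRAM_GROUPS = ("VF1", "VF2")

POSITIVE = "not-usable"  # the class sensitivity is defined on
NEGATIVE = "usable"


class DegenerateFoldError(MriqaError):
    """A training fold ended up with a single class too many times."""


@dataclass
class ExperimentConfig:
    """Settings of one evaluation experiment.

    The SVM kernel defaults to radial-basis with C = 1 and the kernel
    width set by the median heuristic on the (standardized) training
    features; all of it is overridable.  ``normalize_histograms`` divides
    VF1/VF2 count blocks by their row totals before use.
    """

    feature_combination: tuple[str, ...] = ("ASF1", "ASF2", "ASF3")
    n_folds: int = 10
    n_repeats: int = 1000
    n_permutations: int = 10000
    seed: int = 0
    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "median"
    normalize_histograms: bool = False

    def __post_init__(self) -> None:
        self.feature_combination = tuple(self.feature_combination)
        if not self.feature_combination:
            raise ValueError("feature combination must be nonempty")
        bad = set(self.feature_combination) - set(FEATURE_GROUPS)
        if bad:
            raise ValueError(f"unknown feature groups {sorted(bad)}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1 or self.n_permutations < 1:
            raise ValueError("n_repeats and n_permutations must be >= 1")


@dataclass
class EvaluationResult:
    """Per-repeat rate distributions from the repeated protocol."""

    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    predictions: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.min() < 0 or arr.max() > 100:
                raise ValueError(f"{name} rates must lie in [0, 100]")
            setattr(self, name, arr)

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity"):
            arr = getattr(self, name)
            sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
            out[name] = {"mean": float(arr.mean()), "sem": sem, "n": int(arr.size)}
        return out


@dataclass
class PermutationResult:
    """Null accuracy distribution under shuffled training labels."""

    accuracies: np.ndarray
    observed_mean: float
    p_value: float


def _final_labels(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        final = lab.final if isinstance(lab, QualityLabel) else str(lab)
        if final not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label {final!r}")
        out.append(final)
    return np.array(out)


def balanced_subsample(labels: Sequence, seed) -> np.ndarray:
    """All minority-class indices plus an equal-size random draw (without
    replacement) of the majority class.  ``seed`` may be an int or a
    ``numpy.random.Generator``."""
    y = _final_labels(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(y == c) for c in (POSITIVE, NEGATIVE)}
    for c, idx in idx_by_class.items():
        if idx.size == 0:
            raise ValueError(f"class {c!r} is empty")
    minority, majority = sorted(idx_by_class.values(), key=lambda a: a.size)
    if minority.size == majority.size:
        return np.sort(np.concatenate([minority, majority]))
    drawn = rng.choice(majority, size=minority.size, replace=False)
    return np.sort(np.concatenate([minority, drawn]))


def kfold_split(
    n: int, k: int = 10, seed: int = 0, labels: Sequence | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint test folds covering [0, n), sizes differing by at most
    one, stratified by class when labels are given."""
    if n < k:
        raise ValueError(f"n={n} must be >= k={k}")
    if labels is None:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros(n))]
    y = _final_labels(labels)
    if len(y) != n:
        raise ValueError("labels length must equal n")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(n), y)]


def build_design_matrix(
    features: pd.DataFrame,
    combination: Sequence[str],
    normalize_histograms: bool = False,
) -> np.ndarray:
    """Column-stack the requested feature groups from a feature table."""
    blocks = []
    for group in combination:
        cols = _GROUP_COLUMNS[group]
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise ValueError(
                f"feature table lacks {len(missing)} columns for group {group}"
            )
        block = features[cols].to_numpy(dtype=np.float64)
        if normalize_histograms and group in _HISTOGRAM_GROUPS:
            totals = block.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            block = block / totals
        blocks.append(block)
    return np.column_stack(blocks)


def _median_gamma(x: np.ndarray) -> float | str:
    sub = x[:150]
    d2 = pdist(sub, "sqeuclidean")
    d2 = d2[d2 > 0]
    if d2.size == 0:
        return "scale"
    return 1.0 / float(np.median(d2))


def _resolve_matrix(features, config: ExperimentConfig) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return build_design_matrix(
            features, config.feature_combination, config.normalize_histograms
        )
    return np.asarray(features, dtype=np.float64)


def _run_cv(
    x: np.ndarray,
    y: np.ndarray,
    config: ExperimentConfig,
    fold_seed: int,
    rng: np.random.Generator,
    shuffle_train: bool = False,
) -> np.ndarray | None:
    """One k-fold pass; returns pooled boolean predictions (positive =
    not-usable) or None if a training fold was single-class."""
    is_pos = y == POSITIVE
    splitter = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=fold_seed
    )
    preds = np.empty(len(y), dtype=bool)
    for tr, te in splitter.split(x, is_pos):
        y_tr = is_pos[tr]
        if shuffle_train:
            y_tr = rng.permutation(y_tr)
        if y_tr.all() or not y_tr.any():
            return None
        scaler = StandardScaler().fit(x[tr])
        x_tr = scaler.transform(x[tr])
        x_te = scaler.transform(x[te])
        gamma = config.gamma
        if gamma == "median":
            gamma = _median_gamma(x_tr)
        clf = SVC(kernel=config.kernel, C=config.C, gamma=gamma)
        clf.fit(x_tr, y_tr)
        preds[te] = clf.predict(x_te)
    return preds


def _rates(preds: np.ndarray, is_pos: np.ndarray) -> tuple[float, float, float]:
    acc = float((preds == is_pos).mean() * 100)
    sens = float(preds[is_pos].mean() * 100)
    spec = float((~preds[~is_pos]).mean() * 100)
    return acc, sens, spec


def train_and_evaluate(
    features, labels: Sequence, config: ExperimentConfig
) -> EvaluationResult:
    """Run the full repeated balanced-subsample CV protocol.

    ``features`` is either a feature table (DataFrame with the extract
    column layout) or a plain (n_subjects, n_features) array.  Degenerate
    repeats (a single-class training fold) are redrawn with a warning.
    """
    x_all = _resolve_matrix(features, config)
    y_all = _final_labels(labels)
    if len(y_all) != len(x_all):
        raise ValueError("features and labels length mismatch")
    ss = np.random.SeedSequence(config.seed)
    accs, sens, specs, all_preds = [], [], [], []
    for child in ss.spawn(config.n_repeats):
        rng = np.random.default_rng(child)
        for attempt in range(20):
            idx = balanced_subsample(y_all, rng)
            fold_seed = int(rng.integers(0, 2**31))
            preds = _run_cv(x_all[idx], y_all[idx], config, fold_seed, rng)
            if preds is not None:
                break
            warnings.warn("single-class training fold; redrawing repeat")
        else:
            raise DegenerateFoldError("could not draw a non-degenerate repeat")
        is_pos = y_all[idx] == POSITIVE
        a, sn, sp = _rates(preds, is_pos)
        accs.append(a)
        sens.append(sn)
        specs.append(sp)
        all_preds.append((idx, preds))
    return EvaluationResult(
        np.array(accs), np.array(sens), np.array(specs), predictions=all_preds
    )


def permutation_null(
    features,
    labels: Sequence,
    config: ExperimentConfig,
    observed_mean: float | None = None,
) -> PermutationResult:
    """Accuracy null distribution with training labels shuffled per fold.

    Test labels stay intact, so each permutation measures how well an
    SVM trained on label-scrambled data classifies real volumes.  The
    p-value for the observed mean accuracy uses the add-one estimator
    (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if observed_mean is None:
        observed_mean = float(
            train_and_evaluate(features, labels, config).accuracy.mean()
        )
    x_all = _resolve_matrix(features, config)
    y_all = _final_labels(labels)
    ss = np.random.SeedSequence(config.seed + 1)
    accs = []
    for child in ss.spawn(config.n_permutations):
        rng = np.random.default_rng(child)
        for attempt in range(20):
            idx = balanced_subsample(y_all, rng)
            fold_seed = int(rng.integers(0, 2**31))
            preds = _run_cv(
                x_all[idx], y_all[idx], config, fold_seed, rng, shuffle_train=True
            )
            if preds is not None:
                break
        else:
            raise DegenerateFoldError("could not draw a non-degenerate permutation")
        accs.append(_rates(preds, y_all[idx] == POSITIVE)[0])
    accs = np.array(accs)
    p = (1 + int((accs >= observed_mean).sum())) / (1 + len(accs))
    return PermutationResult(accs, observed_mean=observed_mean, p_value=p)


def compare_combinations(
    results: Mapping[str, EvaluationResult]
) -> pd.DataFrame:
    """Pairwise two-tailed Student t-tests between accuracy distributions.

    Flags p < 0.05 and p < 1e-3 (the single/double-star convention) and
    adds a Bonferroni-adjusted column.
    """
    names = list(results)
    if len(names) < 2:
        raise ValueError("need at least two combinations to compare")
    sizes = {results[n].accuracy.size for n in names}
    if len(sizes) != 1:
        raise ValueError("all combinations must have equal repeat counts")
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        xa, xb = results[a].accuracy, results[b].accuracy
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            raise ValueError(f"zero-variance distributions for {a} vs {b}")
        t, p = stats.ttest_ind(xa, xb)
        rows.append(
            {
                "combination_a": a,
                "combination_b": b,
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "t": float(t),
                "p": float(p),
                "sig_05": bool(p < 0.05),
                "sig_001": bool(p < 1e-3),
                "p_bonferroni": float(min(p * len(pairs), 1.0)),
            }
        )
    return pd.DataFrame(rows)


SEVERITY_ORDER = ("none", "slight", "moderate", "heavy")


def severity_contrast(
    feature_values: Sequence[float], severities: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group an artifact feature by rated severity and contrast the groups.

    Returns (summary, pairs): per-group n / mean / standard error, and
    all pairwise two-tailed t-tests among groups present in the data
    (absent severities are simply omitted).  Pairs involving a group of
    size one are marked untestable.
    """
    vals = np.asarray(feature_values, dtype=np.float64)
    sevs = np.asarray(severities)
    if vals.shape != sevs.shape:
        raise ValueError("feature_values and severities length mismatch")
    bad = set(sevs) - set(SEVERITY_ORDER)
    if bad:
        raise ValueError(f"unknown severities {sorted(bad)}")
    present = [s for s in SEVERITY_ORDER if (sevs == s).any()]
    if not present:
        raise ValueError("no severity groups present")
    summary_rows = []
    groups = {}
    for s in present:
        g = vals[sevs == s]
        groups[s] = g
        sem = float(g.std(ddof=1) / np.sqrt(g.size)) if g.size > 1 else np.nan
        summary_rows.append(
            {"severity": s, "n": int(g.size), "mean": float(g.mean()), "sem": sem}
        )
    pair_rows = []
    for a, b in itertools.combinations(present, 2):
        ga, gb = groups[a], groups[b]
        testable = ga.size > 1 and gb.size > 1
        if testable:
            t, p = stats.ttest_ind(ga, gb)
            t, p = float(t), float(p)
        else:
            t = p = np.nan
        pair_rows.append(
            {
                "severity_a": a,
                "severity_b": b,
                "t": t,
                "p": p,
                "testable": testable,
                "sig_05": bool(testable and p < 0.05),
                "sig_001": bool(testable and p < 1e-3),
            }
        )
    pair_cols = ["severity_a", "severity_b", "t", "p", "testable", "sig_05", "sig_001"]
    return (
        pd.DataFrame(summary_rows, columns=["severity", "n", "mean", "sem"]),
        pd.DataFrame(pair_rows, columns=pair_cols),
    )
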