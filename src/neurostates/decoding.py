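"""Supervised sanity check: decode tagged behavior from latent factors.

A random-forest classifier (library defaults) predicts the per-bin
behavioral label from the GPFA factors, cross-validated by whole trials
(train on 9/10 of the trials, test on the rest). Performance is compared
against two dummy baselines — "stratified" (random labels drawn from the
training distribution) and "most frequent" — with a one-sided Wilcoxon
signed-rank test across folds; the reported p-value is the larger of the
two, so significance requires beating both baselines.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence

import numpy as np
from scipy.stats import wilcoxon
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier

from .data import ValidationError


def decode_vs_baselines(
    latents: Mapping[int, np.ndarray],
    behavior_labels: Mapping[int, np.ndarray],
    folds: int = 10,
    seed: int = 0,
) -> Dict:
    """Per-fold accuracies of the classifier and both baselines, with p.

    ``latents`` maps trial ids to (T, d) feature matrices and
    ``behavior_labels`` to equally long label vectors. Folds are whole
    trials, never splitting a trial between train and test. Zero
    accuracy differences are dropped by the signed-rank test (standard
    convention); a degenerate test (all differences zero, e.g. a single
    label class) reports p = 1.
    """
    ids = sorted(latents.keys())
    if len(ids) < folds:
        raise ValidationError("need at least as many trials as folds")
    for tid in ids:
        if len(latents[tid]) != len(behavior_labels[tid]):
            raise ValidationError(f"trial {tid}: feature/label lengths differ")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    fold_ids = [
        [ids[j] for j in order[f::folds]] for f in range(folds)
    ]

    def stack(trial_ids):
        X = np.concatenate([np.asarray(latents[t], dtype=float) for t in trial_ids])
        y = np.concatenate([np.asarray(behavior_labels[t]) for t in trial_ids])
        return X, y.astype(str)

    acc_rf, acc_strat, acc_major = [], [], []
    for f in range(folds):
        test = fold_ids[f]
        train = [t for t in ids if t not in test]
        X_tr, y_tr = stack(train)
        X_te, y_te = stack(test)
        rf = RandomForestClassifier(random_state=seed)
        rf.fit(X_tr, y_tr)
        acc_rf.append(float(np.mean(rf.predict(X_te) == y_te)))
        strat = DummyClassifier(strategy="stratified", random_state=seed)
        strat.fit(X_tr, y_tr)
        acc_strat.append(float(np.mean(strat.predict(X_te) == y_te)))
        major = DummyClassifier(strategy="most_frequent")
        major.fit(X_tr, y_tr)
        acc_major.append(float(np.mean(major.predict(X_te) == y_te)))

    p_strat = _one_sided_wilcoxon(acc_rf, acc_strat)
    p_major = _one_sided_wilcoxon(acc_rf, acc_major)
    return {
        "accuracy_classifier": acc_rf,
        "accuracy_stratified": acc_strat,
        "accuracy_most_frequent": acc_major,
        "p_vs_stratified": p_strat,
        "p_vs_most_frequent": p_major,
        "p_value": max(p_strat, p_major),
        "classifier_params": RandomForestClassifier().get_params(),
    }


def _one_sided_wilcoxon(a: Sequence[float], b: Sequence[float]) -> float:
    diffs = np.asarray(a) - np.asarray(b)
    if np.all(diffs == 0):
        return 1.0
    try:
        return float(wilcoxon(diffs, alternative="greater").pvalue)
    except ValueError:
        return 1.0
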