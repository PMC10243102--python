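"""Biomarker-panel performance: cross-validated ROC curves and AUC.

A candidate panel is assessed by repeatedly splitting the two groups into
training and held-out samples, fitting a classifier on the panel columns of
the training set, scoring the held-out samples, and summarising the area
under the ROC curve (AUC). The AUC of a score vector equals the Mann-Whitney
concordance probability: the chance that a random case outscores a random
control (ties counted half).

The default classifier is a random forest; a deterministic centroid-projection
linear score is available as a dependency-free alternative. The 95% confidence
interval is the 2.5/97.5 percentile band of the per-repeat AUCs (an
approximation; with a single repeat it collapses to that repeat's AUC). A
panel is flagged *acceptable* when its AUC exceeds 0.8, the conventional bar
for a useful diagnostic biomarker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .profiles import ProfileMatrix
from .validation import _stratified_train_indices

__all__ = ["RocResult", "roc_curve", "panel_auc", "ACCEPTABLE_AUC"]

#: Conventional threshold above which a biomarker's discrimination is acceptable.
ACCEPTABLE_AUC = 0.8


def roc_curve(scores: Sequence[float], labels, positive_class=None):
    """ROC points and AUC for a continuous score.

    Returns ``(fpr, tpr, thresholds, auc)``. The AUC equals the pairwise
    concordance probability of the scores (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError("ROC requires exactly two classes in the labels")
    if positive_class is None:
        positive_class = classes[1]
    y = (labels == positive_class).astype(int)
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    return fpr, tpr, thr, auc


@dataclass
class RocResult:
    """Cross-validated panel AUC with a percentile confidence interval."""

    auc: float
    ci_lower: float
    ci_upper: float
    n_cv_repeats: int
    per_repeat_aucs: np.ndarray
    panel: tuple[str, ...]
    classifier: str = "random-forest"
    mode: str = "averaged"
    acceptable: bool = False
    pooled_auc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_cv_repeats": self.n_cv_repeats,
            "panel": list(self.panel),
            "classifier": self.classifier,
            "mode": self.mode,
            "acceptable": self.acceptable,
            "pooled_auc": self.pooled_auc,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


class _CentroidScore:
    """Deterministic linear score: projection onto the standardized
    between-class centroid difference."""

    def fit(self, x: np.ndarray, y01: np.ndarray) -> "_CentroidScore":
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd < 1e-12, 1.0, sd)
        xs = (x - mu) / sd
        d = xs[y01 == 1].mean(axis=0) - xs[y01 == 0].mean(axis=0)
        self._mu, self._sd, self._d = mu, sd, d
        return self

    def score(self, x: np.ndarray) -> np.ndarray:
        return ((x - self._mu) / self._sd) @ self._d


def panel_auc(m: "ProfileMatrix | pd.DataFrame", labels, panel: Sequence[str],
              n_repeats: int = 100, seed: "int | None" = None,
              classifier: str = "random-forest", train_fraction: float = 2 / 3,
              positive_class=None, mode: str = "averaged",
              n_estimators: int = 100) -> RocResult:
    """Cross-validated AUC of a metabolite panel.

    Each repeat draws a stratified random training split (default two thirds
    of the samples), fits the classifier on the panel columns only, scores
    the held-out samples, and records the held-out AUC. ``mode='averaged'``
    (default) reports the mean per-repeat AUC; ``mode='pooled'`` reports the
    AUC of all held-out scores pooled across repeats. The CI is the
    2.5/97.5 percentile range of per-repeat AUCs either way.
    """
    if isinstance(m, ProfileMatrix):
        df = m.values
    else:
        df = pd.DataFrame(m)
    panel = [str(p) for p in panel]
    if not panel:
        raise ValueError("panel must be nonempty")
    missing = [p for p in panel if p not in df.columns]
    if missing:
        raise ValueError(f"panel metabolite(s) not in matrix: {missing}")
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or (counts < 5).any():
        raise ValueError("panel AUC requires two classes with >= 5 samples each")
    if positive_class is None:
        positive_class = pd.unique(labels)[1]
    if mode not in ("averaged", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")

    x = df[panel].to_numpy(dtype=float)
    y01 = (labels == positive_class).astype(int)
    rng = np.random.default_rng(np.random.SeedSequence(seed) if seed is not None else None)
    all_idx = np.arange(len(y01))
    aucs = np.empty(n_repeats)
    pooled_scores, pooled_truth = [], []
    for r in range(n_repeats):
        train = _stratified_train_indices(y01, train_fraction, rng)
        test = np.setdiff1d(all_idx, train, assume_unique=True)
        if classifier == "random-forest":
            rf_seed = int(rng.integers(2**31))
            clf = RandomForestClassifier(n_estimators=n_estimators, random_state=rf_seed)
            clf.fit(x[train], y01[train])
            scores = clf.predict_proba(x[test])[:, list(clf.classes_).index(1)]
        elif classifier == "linear":
            scores = _CentroidScore().fit(x[train], y01[train]).score(x[test])
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        aucs[r] = roc_auc_score(y01[test], scores)
        pooled_scores.append(scores)
        pooled_truth.append(y01[test])
    pooled = float(roc_auc_score(np.concatenate(pooled_truth), np.concatenate(pooled_scores)))
    auc = float(np.mean(aucs)) if mode == "averaged" else pooled
    lo, hi = (float(v) for v in np.percentile(aucs, [2.5, 97.5]))
    return RocResult(
        auc=auc, ci_lower=min(lo, auc), ci_upper=max(hi, auc),
        n_cv_repeats=n_repeats, per_repeat_aucs=aucs, panel=tuple(panel),
        classifier=classifier, mode=mode, acceptable=auc > ACCEPTABLE_AUC,
        pooled_auc=pooled,
    )
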