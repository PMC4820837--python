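"""Classifier-based category evidence.

Trains an L2-regularized logistic regression (regularization strength
C = 1) to discriminate face from scene localizer patterns, then scores
each scene-viewing pattern with the logit-transformed face probability.
Every pattern is z-scored across voxels before entering the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.linear_model import LogisticRegression

__all__ = ["FaceEvidence", "face_evidence"]

PROB_CLIP = 1e-6


@dataclass(frozen=True)
class FaceEvidence:
    """Per-scene face-category evidence; evidence 0 iff probability 0.5."""

    table: pd.DataFrame  # columns: scene, predicted, p_face, evidence

    def __post_init__(self) -> None:
        if not np.isfinite(self.table["evidence"]).all():
            raise ValueError("face evidence must be finite")


def _zscore_rows(X: np.ndarray, what: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-variance {what} pattern(s) at rows {bad}; z-scoring undefined")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def face_evidence(
    train_patterns: np.ndarray,
    train_labels,
    scene_patterns: np.ndarray,
    scene_ids=None,
    C: float = 1.0,
) -> FaceEvidence:
    """Train on localizer block patterns (labels 'face' / 'scene') and
    score main-task scene patterns."""
    labels = np.asarray(train_labels)
    classes = set(np.unique(labels))
    if classes != {"face", "scene"}:
        raise ValueError(f"train labels must be 'face'/'scene', got {sorted(classes)}")
    for cls in ("face", "scene"):
        if (labels == cls).sum() < 2:
            raise ValueError(f"need at least 2 training examples of class {cls!r}")

    Xtr = _zscore_rows(train_patterns, "training")
    Xte = _zscore_rows(scene_patterns, "scene")
    clf = LogisticRegression(C=C, solver="liblinear")  # L2 penalty (default)
    clf.fit(Xtr, labels)
    face_col = list(clf.classes_).index("face")
    p_face = np.clip(clf.predict_proba(Xte)[:, face_col], PROB_CLIP, 1 - PROB_CLIP)
    ids = list(scene_ids) if scene_ids is not None else [f"scene{i:02d}" for i in range(len(Xte))]
    table = pd.DataFrame(
        {
            "scene": ids,
            "predicted": clf.predict(Xte),
            "p_face": p_face,
            "evidence": logit(p_face),
        }
    )
    return FaceEvidence(table=table)
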