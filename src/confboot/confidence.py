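"""Confidence models: scoring how likely a candidate pose is correct.

Two implementations share one interface, ``conf.score(x, cplx) -> float``
(higher = more confident; the learned model returns a pre-sigmoid logit):

* :func:`oracle_confidence` / :class:`OracleConfidence` — reads the true pose
  and returns ``tau - ||x - x_star||``; strictly decreasing in the error and
  positive exactly when the pose counts as a success.  The idealized upper
  bound used in ablations.
* :class:`LearnedConfidence` — a logistic-regression success classifier over
  *relative* pocket features computed from the public context only: per
  pocket, its compatibility with the ligand (in the cluster frame), the
  pose-to-center distance, and a hinge at the success threshold.  Checking a
  pose is a local task in these coordinates, which is why the classifier
  generalizes across clusters far better than the generator does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .diffusion import NoiseSchedule, reverse_sample
from .toytask import TAU, ToyComplex

__all__ = [
    "oracle_confidence",
    "OracleConfidence",
    "AntiOracleConfidence",
    "LearnedConfidence",
    "train_confidence",
    "make_confidence_training_set",
    "pose_features",
]


def oracle_confidence(x, cplx: ToyComplex, kappa: float = 1.0) -> float:
    """Ground-truth confidence ``kappa * (tau - ||x - x_star||)``."""
    return float(kappa * (TAU - np.linalg.norm(np.asarray(x, float) - cplx.x_star)))


class OracleConfidence:
    """Oracle confidence as a model object (for ablation runs)."""

    uses_ground_truth = True

    def score(self, x, cplx: ToyComplex) -> float:
        return oracle_confidence(x, cplx)

    def score_batch(self, X, cplx: ToyComplex) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return TAU - np.linalg.norm(X - cplx.x_star, axis=1)


class AntiOracleConfidence(OracleConfidence):
    """Adversarial control: the negated oracle (rewards bad poses)."""

    def score(self, x, cplx: ToyComplex) -> float:
        return -super().score(x, cplx)

    def score_batch(self, X, cplx: ToyComplex) -> np.ndarray:
        return -super().score_batch(X, cplx)


# ---------------------------------------------------------------------------
# learned confidence


def _parse_context(d: np.ndarray, dim: int):
    """Split a context vector into (ligand, centers, pocket features, frame)."""
    d = np.asarray(d, float)
    lig = d[:2]
    per = dim + 2
    body = d[2:-2]
    n_pockets = body.size // per
    centers = np.empty((n_pockets, dim))
    feats = np.empty((n_pockets, 2))
    for j in range(n_pockets):
        blk = body[j * per : (j + 1) * per]
        centers[j] = blk[:dim]
        feats[j] = blk[dim:]
    frame = d[-2:]
    return lig, centers, feats, frame


def pose_features(X, d: np.ndarray, dim: int) -> np.ndarray:
    """Relative check features for poses ``X`` under context ``d``.

    Pockets are ordered by descending ligand compatibility so the feature
    layout is invariant to pocket labelling.  Per pocket: compatibility,
    distance, and ``max(0, tau - distance)``; plus the distance to the most
    compatible pocket and the overall minimum distance.
    """
    X = np.atleast_2d(np.asarray(X, float))
    lig, centers, feats, frame = _parse_context(d, dim)
    c, s = frame
    rot = np.array([[c, -s], [s, c]])
    compat = feats @ (rot @ lig)
    order = np.argsort(-compat)
    dists = np.linalg.norm(X[:, None, :] - centers[None, order, :], axis=2)
    compat_sorted = np.broadcast_to(compat[order], dists.shape)
    hinge = np.maximum(0.0, TAU - dists)
    cols = [compat_sorted, dists, hinge, dists[:, :1], dists.min(axis=1, keepdims=True)]
    return np.concatenate(cols, axis=1)


@dataclass
class LearnedConfidence:
    """Frozen logistic-regression pose checker; ``score`` returns the logit."""

    clf: LogisticRegression
    dim: int
    uses_ground_truth = False

    def score(self, x, cplx: ToyComplex) -> float:
        return float(self.clf.decision_function(pose_features(x, cplx.d, self.dim))[0])

    def score_batch(self, X, cplx: ToyComplex) -> np.ndarray:
        return self.clf.decision_function(pose_features(X, cplx.d, self.dim))

    @property
    def params(self) -> dict:
        return {"conf_coef": self.clf.coef_, "conf_intercept": self.clf.intercept_,
                "conf_dim": np.array([self.dim])}

    @classmethod
    def from_params(cls, coef, intercept, dim: int) -> "LearnedConfidence":
        clf = LogisticRegression()
        clf.coef_ = np.atleast_2d(np.asarray(coef, float))
        clf.intercept_ = np.atleast_1d(np.asarray(intercept, float))
        clf.classes_ = np.array([0, 1])
        return cls(clf, int(dim))


def train_confidence(task, generator_samples, seed: int = 0) -> LearnedConfidence:
    """Fit the success classifier on labelled poses from training clusters.

    ``generator_samples`` is a list of ``(x, d, label)`` with binary labels
    ``1{||x - x_star|| < tau}`` produced by the caller (training clusters
    only — held-out structural data must never enter here).
    """
    clusters, complexes = task
    dim = clusters[0].pocket_layout.shape[1]
    y = np.array([int(lab) for _, _, lab in generator_samples])
    if len(np.unique(y)) < 2:
        raise ValueError("confidence training set contains a single class")
    F = np.vstack([pose_features(x, d, dim) for x, d, _ in generator_samples])
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(F, y)
    return LearnedConfidence(clf, dim)


def make_confidence_training_set(
    train_complexes,
    model,
    schedule: NoiseSchedule,
    n_rollouts: int = 16,
    n_perturbed: int = 8,
    seed: int = 0,
):
    """Build ``(x, d, label)`` samples from training clusters.

    Combines generator rollouts (the deployment distribution of poses) with
    kernel-perturbed true poses at several radii so both classes are always
    populated.  Labels use the training clusters' known poses.
    """
    rng = np.random.default_rng(seed)
    samples = []
    scales = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    for cplx in train_complexes:
        X = reverse_sample(model, cplx.d, schedule, rng=rng, n_samples=n_rollouts)
        for x in X:
            samples.append((x, cplx.d, float(np.linalg.norm(x - cplx.x_star) < TAU)))
        for _ in range(n_perturbed):
            sc = rng.choice(scales)
            x = cplx.x_star + sc * rng.standard_normal(cplx.x_star.shape)
            samples.append((x, cplx.d, float(np.linalg.norm(x - cplx.x_star) < TAU)))
    return samples
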