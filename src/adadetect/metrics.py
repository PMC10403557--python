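"""ROC AUC and its stratified bootstrap confidence interval.

The AUC is the framework's sole readout.  It is computed in the Mann-Whitney
pair formulation: the fraction of (positive, negative) score pairs in which
the positive scores higher, with ties counted 0.5 — identically the
trapezoidal area under the ROC curve.  Confidence intervals use the stratified
percentile bootstrap: positives and negatives are resampled independently with
replacement (preserving ``n_pos`` and ``n_neg``, so no replicate can lose a
class) and the interval is read off the replicate quantiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


def _split_scores(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores and labels differ in length: {scores.size} vs {labels.size}"
        )
    bad = set(np.unique(labels)) - {0, 1}
    if bad:
        raise ValueError(f"labels must be 0 or 1, found {sorted(bad)}")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"AUC undefined: need both classes (n_pos={pos.size}, n_neg={neg.size})"
        )
    return pos, neg


def _auc_from_split(pos: np.ndarray, neg: np.ndarray) -> float:
    # Mann-Whitney via midranks: U = R_pos - n_pos(n_pos+1)/2; AUC = U/(n_pos*n_neg)
    ranks = rankdata(np.concatenate([pos, neg]), method="average")
    n_pos, n_neg = pos.size, neg.size
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve of ``scores`` against binary ``labels``.

    Equals the probability that a random positive outscores a random negative,
    with ties counted half.  Raises if either class is absent.
    """
    pos, neg = _split_scores(np.asarray(scores), np.asarray(labels))
    return _auc_from_split(pos, neg)


@dataclass(frozen=True)
class AUCResult:
    """Point AUC with a stratified-bootstrap percentile confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    replicates: int
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.ci_high <= 1):
            raise ValueError(
                f"invalid CI [{self.ci_low}, {self.ci_high}]"
            )
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")

    @property
    def point_outside_ci(self) -> bool:
        """Flag the pathological case where ties push the point estimate
        outside the percentile interval."""
        return not (self.ci_low <= self.auc <= self.ci_high)

    def format(self) -> str:
        """Two-decimal report style, e.g. ``0.49 [0.48, 0.50]``."""
        return f"{self.auc:.2f} [{self.ci_low:.2f}, {self.ci_high:.2f}]"

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "replicates": self.replicates,
            "level": self.level,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "AUCResult":
        return cls(**{k: d[k] for k in (
            "auc", "ci_low", "ci_high", "n_pos", "n_neg",
            "replicates", "level", "seed",
        )})


def bootstrap_ci(
    scores,
    labels,
    replicates: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> AUCResult:
    """Stratified percentile bootstrap CI for the AUC.

    Positives and negatives are resampled independently with replacement,
    preserving class counts; the interval is the ``(1-level)/2`` and
    ``1-(1-level)/2`` quantiles of the replicate AUCs.  Deterministic given
    ``seed``.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    pos, neg = _split_scores(np.asarray(scores), np.asarray(labels))
    point = _auc_from_split(pos, neg)
    rng = np.random.default_rng(seed)
    boots = np.empty(replicates)
    for b in range(replicates):
        p = pos[rng.integers(0, pos.size, pos.size)]
        n = neg[rng.integers(0, neg.size, neg.size)]
        boots[b] = _auc_from_split(p, n)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return AUCResult(
        auc=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_pos=pos.size,
        n_neg=neg.size,
        replicates=replicates,
        level=level,
        seed=seed,
    )


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points of the empirical ROC curve, for export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(np.asarray(labels), np.asarray(scores))
    return fpr, tpr
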