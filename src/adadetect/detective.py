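"""Ensemble shortcut detectives: training, scoring, serialization.

A detective is an ensemble of binary scorers trained to recognize one
acquisition-dependent attribute perturbation.  Members are trained on
different training-validation partitions of the constructed shortcut
trainset (stratified folds; grouped by patient when patient IDs exist),
each selected at its best validation AUC under early stopping, and combined
by arithmetic mean of member probabilities.

Two feature backends are provided, both feeding a logistic head:

* ``feature_linear`` — global intensity-histogram quantiles plus
  gradient-energy summaries.  The shortcut signal is global by definition, so
  global features suffice; this backend trains in seconds.
* ``conv_features`` — a small convolutional extractor (three 3x3 filter banks
  of widths 8/16/32, ReLU, 2x average pooling, global mean/std pooling) with
  fixed seeded random filters.  It mirrors the receptive-field structure of a
  small convnet while remaining CPU-cheap; additional backends can be
  registered via :data:`BACKENDS`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .ada import ADASpec
from .datasets import LabeledDataset
from .metrics import compute_auc


@dataclass(frozen=True)
class DetectiveConfig:
    """Training configuration for one detective ensemble."""

    backend: str = "feature_linear"
    ensemble_size: int = 5
    validation_fraction: float = 0.2  # used only when ensemble_size == 1
    max_epochs: int = 80
    patience: int = 10
    learning_rate: float = 0.05
    alpha: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError(f"ensemble_size must be >= 1, got {self.ensemble_size}")
        if self.backend not in BACKENDS:
            raise ValueError(
                f"unknown backend {self.backend!r}; registered: {sorted(BACKENDS)}"
            )
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "backend": self.backend,
            "ensemble_size": self.ensemble_size,
            "validation_fraction": self.validation_fraction,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "learning_rate": self.learning_rate,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectiveConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# feature backends


def _linear_features(images: list[np.ndarray]) -> np.ndarray:
    """Global intensity + sharpness summaries, one row per image."""
    qs = [0.01, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 0.99]
    rows = []
    for img in images:
        f = np.asarray(img, dtype=np.float64)
        gy, gx = np.gradient(f)
        gm = np.hypot(gx, gy)
        lap = ndimage.laplace(f, mode="reflect")
        rows.append(np.concatenate([
            np.quantile(f, qs),
            [f.mean(), f.std()],
            [np.log1p(np.mean(gm * gm)), np.log1p(gm.mean())],
            np.log1p(np.quantile(gm, [0.5, 0.9, 0.99])),
            [np.log1p(np.mean(lap * lap))],
        ]))
    return np.asarray(rows)


class _ConvFeatureExtractor:
    """Fixed random 3x3 filter banks + ReLU + 2x average pooling."""

    widths = (8, 16, 32)

    def __init__(self, filter_seed: int):
        self.filter_seed = filter_seed
        rng = np.random.default_rng(filter_seed)
        self.filters = []
        in_c = 1
        for out_c in self.widths:
            w = rng.normal(0.0, np.sqrt(2.0 / (9 * in_c)), size=(out_c, in_c, 3, 3))
            self.filters.append(w)
            in_c = out_c

    def __call__(self, images: list[np.ndarray]) -> np.ndarray:
        rows = []
        for img in images:
            x = np.asarray(img, dtype=np.float64)[:, :, None] / 255.0
            for w in self.filters:
                win = sliding_window_view(x, (3, 3), axis=(0, 1))  # (h,w,c,3,3)
                x = np.einsum("hwcij,ocij->hwo", win, w, optimize=True)
                x = np.maximum(x, 0.0)
                h, wdt = x.shape[0] // 2 * 2, x.shape[1] // 2 * 2
                x = x[:h, :wdt].reshape(h // 2, 2, wdt // 2, 2, -1).mean(axis=(1, 3))
            rows.append(np.concatenate([x.mean(axis=(0, 1)), x.std(axis=(0, 1))]))
        return np.asarray(rows)


#: backend registry; values are ``factory(seed) -> callable(images) -> X``;
#: the extractor is shared by all ensemble members and fixed by the config seed
BACKENDS: dict[str, object] = {
    "feature_linear": lambda seed: _linear_features,
    "conv_features": lambda seed: _ConvFeatureExtractor(seed),
}


def _make_extractor(backend: str, seed: int):
    return BACKENDS[backend](seed)


# ---------------------------------------------------------------------------
# ensemble members


@dataclass
class _Member:
    """One trained logistic scorer over backend features."""

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coef: np.ndarray
    intercept: float
    val_auc: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = (X - self.scaler_mean) / self.scaler_scale
        logits = z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-logits))

    def to_dict(self) -> dict:
        return {
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "val_auc": self.val_auc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Member":
        return cls(
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            coef=np.asarray(d["coef"]),
            intercept=float(d["intercept"]),
            val_auc=float(d["val_auc"]),
        )


def _train_member(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: DetectiveConfig,
    seed: int,
) -> _Member:
    """SGD logistic fit with early stopping on validation AUC."""
    scaler = StandardScaler().fit(X_tr)
    Xs, Xv = scaler.transform(X_tr), scaler.transform(X_val)
    clf = SGDClassifier(
        loss="log_loss",
        alpha=config.alpha,
        learning_rate="constant",
        eta0=config.learning_rate,
        random_state=seed,
    )
    rng = np.random.default_rng(seed)
    best_auc, best_coef, best_icpt = -np.inf, None, None
    stale = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(len(y_tr))
        clf.partial_fit(Xs[order], y_tr[order], classes=np.array([0, 1]))
        val_auc = compute_auc(clf.decision_function(Xv), y_val)
        if val_auc > best_auc:
            best_auc = val_auc
            best_coef = clf.coef_.ravel().copy()
            best_icpt = float(clf.intercept_[0])
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break
    return _Member(
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        coef=best_coef,
        intercept=best_icpt,
        val_auc=float(best_auc),
    )


def _partitions(
    labels: np.ndarray,
    groups: list[str] | None,
    config: DetectiveConfig,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Distinct train/validation index partitions, one per ensemble member."""
    n = len(labels)
    idx = np.arange(n)
    if config.ensemble_size == 1:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(n)
        n_val = max(1, int(round(config.validation_fraction * n)))
        return [(np.sort(perm[n_val:]), np.sort(perm[:n_val]))]
    if groups is not None:
        splitter = StratifiedGroupKFold(
            n_splits=config.ensemble_size, shuffle=True, random_state=config.seed
        )
        return [(tr, va) for tr, va in splitter.split(idx, labels, groups=groups)]
    splitter = StratifiedKFold(
        n_splits=config.ensemble_size, shuffle=True, random_state=config.seed
    )
    return [(tr, va) for tr, va in splitter.split(idx, labels)]


# ---------------------------------------------------------------------------
# the detective


@dataclass
class Detective:
    """Trained ensemble scorer for one acquisition-dependent attribute."""

    members: list[_Member]
    ada: ADASpec | None
    config: DetectiveConfig
    image_shape: tuple[int, int]
    certification: dict | None = None
    provenance_warning: bool = False

    @property
    def is_certified(self) -> bool:
        return bool(self.certification and self.certification.get("passed"))

    def fingerprint(self) -> str:
        """Stable hash over the ADA spec and member weights (integrity check)."""
        payload = json.dumps(
            {
                "ada": self.ada.to_dict() if self.ada else None,
                "members": [m.to_dict() for m in self.members],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


def train_detective(trainset: LabeledDataset, config: DetectiveConfig) -> Detective:
    """Train an ensemble detective on a constructed shortcut trainset.

    Each of ``config.ensemble_size`` members trains on a distinct stratified
    train/validation partition (grouped by patient when patient IDs exist),
    with early stopping and selection at best validation AUC.  Deterministic
    given ``config.seed``.
    """
    trainset.require_both_classes()
    shapes = {img.shape for img in trainset.images}
    if len(shapes) > 1:
        raise ValueError(f"mixed image sizes in trainset: {sorted(shapes)}")
    provenance_warning = trainset.injected_ada is None
    if provenance_warning:
        warnings.warn(
            "trainset carries no injection provenance; training on unknown "
            "data is allowed but the detective is flagged",
            stacklevel=2,
        )
    extractor = _make_extractor(config.backend, config.seed)
    X = extractor(trainset.images)
    y = trainset.labels
    member_seeds = (
        np.random.SeedSequence(config.seed).generate_state(config.ensemble_size)
        % (2**31 - 1)
    )
    members = [
        _train_member(X[tr], y[tr], X[va], y[va], config, int(s))
        for (tr, va), s in zip(
            _partitions(y, trainset.patient_ids, config), member_seeds
        )
    ]
    return Detective(
        members=members,
        ada=trainset.injected_ada[0] if trainset.injected_ada else None,
        config=config,
        image_shape=shapes.pop(),
        provenance_warning=provenance_warning,
    )


def score(detective: Detective, images: list[np.ndarray]) -> np.ndarray:
    """Mean member probability per image, order preserved; pure inference."""
    for img in images:
        if img.shape != detective.image_shape:
            raise ValueError(
                f"image shape {img.shape} does not match training shape "
                f"{detective.image_shape}"
            )
    extractor = _make_extractor(detective.config.backend, detective.config.seed)
    X = extractor(images)
    probs = np.mean([m.predict(X) for m in detective.members], axis=0)
    return np.clip(probs, 0.0, 1.0)


# ---------------------------------------------------------------------------
# serialization


def save_detective(detective: Detective, directory: str | Path) -> Path:
    """Serialize a detective (config + members + provenance) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {
        "format": "adadetect-detective-v1",
        "config": detective.config.to_dict(),
        "ada": detective.ada.to_dict() if detective.ada else None,
        "image_shape": list(detective.image_shape),
        "members": [m.to_dict() for m in detective.members],
        "provenance_warning": detective.provenance_warning,
        "certification": detective.certification,
        "fingerprint": detective.fingerprint(),
    }
    path = directory / "detective.json"
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_detective(directory: str | Path) -> Detective:
    """Load a serialized detective, verifying weight/spec integrity."""
    path = Path(directory) / "detective.json"
    doc = json.loads(path.read_text())
    if doc.get("format") != "adadetect-detective-v1":
        raise ValueError(f"unrecognized detective format in {path}")
    det = Detective(
        members=[_Member.from_dict(m) for m in doc["members"]],
        ada=ADASpec.from_dict(doc["ada"]) if doc["ada"] else None,
        config=DetectiveConfig.from_dict(doc["config"]),
        image_shape=tuple(doc["image_shape"]),
        certification=doc.get("certification"),
        provenance_warning=bool(doc.get("provenance_warning", False)),
    )
    if det.fingerprint() != doc["fingerprint"]:
        raise ValueError(f"detective integrity check failed for {path}")
    cert = det.certification
    if cert and cert.get("detective_fingerprint") not in (None, det.fingerprint()):
        raise ValueError(f"certification block does not match detective in {path}")
    return det
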