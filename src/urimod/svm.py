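"""RBF-kernel SVM engine with class weighting and the 0–9 probability scale.

The classifier is a support vector machine with a radial basis function
kernel. Three parameters matter: ``gamma`` (RBF width), ``cost`` (error
penalty C) and ``pos_weight`` (a multiplier on the positive class's error
penalty, countering the class imbalance between modified and unmodified
uridines). Defaults are gamma=0.05, cost=2, pos_weight=2.

Raw decision scores are signed distances from the separating surface;
larger means more positive-like. For display they are clipped to
[−1.5, 1.5] and mapped affinely to a 0–9 probability score:
``display = 3 · (clip(raw, −1.5, 1.5) + 1.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

MODEL_FORMAT_VERSION = 1

SCORE_CLIP = 1.5  # saturation bound on the raw score
SCORE_SCALE = 3.0  # (clip + 1.5) * 3 spans 0..9


@dataclass(frozen=True)
class SVMParams:
    gamma: float = 0.05
    cost: float = 2.0
    pos_weight: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gamma", "cost", "pos_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ProbabilityScore:
    raw: float
    clipped: float
    display: float  # in [0, 9]


def probability_score(raw: float) -> ProbabilityScore:
    """Clip the raw SVM score to ±1.5 and map it onto the 0–9 scale."""
    clipped = float(np.clip(raw, -SCORE_CLIP, SCORE_CLIP))
    return ProbabilityScore(
        raw=float(raw),
        clipped=clipped,
        display=SCORE_SCALE * (clipped + SCORE_CLIP),
    )


@dataclass
class TrainedModel:
    """A fitted RBF-SVM together with its encoding recipe.

    ``scheme``/``window_len``/``struct_window_len``/``task``/``taxon_scope``
    describe what the feature vectors mean, so prediction can reject
    inputs encoded differently.
    """

    params: SVMParams
    scheme: str
    window_len: int
    task: str
    struct_window_len: int | None = None
    taxon_scope: str = "all"
    svc: SVC | None = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        if self.svc is None:
            raise ValueError("model is not fitted")
        return int(self.svc.n_features_in_)


def train(
    X: np.ndarray,
    y: np.ndarray,
    params: SVMParams = SVMParams(),
    *,
    scheme: str = "bpp",
    window_len: int = 17,
    struct_window_len: int | None = None,
    task: str = "UM",
    taxon_scope: str = "all",
) -> TrainedModel:
    """Fit an RBF-SVM on features *X* and binary labels *y* (1=positive).

    Requires at least one example of each class and a consistent feature
    dimension. The fit is deterministic for identical inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError(f"X must be 2-D, got shape {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"{X.shape[0]} feature vectors but {y.shape[0]} labels"
        )
    classes = set(np.unique(y))
    if classes != {0, 1}:
        raise ValueError(
            f"labels must contain both classes 0 and 1, got {sorted(classes)}"
        )
    # tight tolerance so the decision function is invariant (to ~1e-6)
    # under permutations of the training-set order
    svc = SVC(
        kernel="rbf",
        gamma=params.gamma,
        C=params.cost,
        class_weight={0: 1.0, 1: params.pos_weight},
        tol=1e-7,
    )
    svc.fit(X, y)
    return TrainedModel(
        params=params,
        scheme=scheme,
        window_len=window_len,
        struct_window_len=struct_window_len,
        task=task,
        taxon_scope=taxon_scope,
        svc=svc,
    )


def decision_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Signed decision scores, one per feature vector; may be empty."""
    if model.svc is None:
        raise ValueError("model is not fitted")
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else '?'} does "
            f"not match model scheme {model.scheme!r} "
            f"(expects {model.n_features})"
        )
    return model.svc.decision_function(X)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a fitted model; load_model(save_model(m)) scores identically."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.params,
        "scheme": model.scheme,
        "window_len": model.window_len,
        "struct_window_len": model.struct_window_len,
        "task": model.task,
        "taxon_scope": model.taxon_scope,
        "svc": model.svc,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted / not a joblib archive
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ValueError(f"{path} is not a urimod model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {payload['format_version']} is not "
            f"supported (expected {MODEL_FORMAT_VERSION})"
        )
    return TrainedModel(
        params=payload["params"],
        scheme=payload["scheme"],
        window_len=payload["window_len"],
        struct_window_len=payload["struct_window_len"],
        task=payload["task"],
        taxon_scope=payload["taxon_scope"],
        svc=payload["svc"],
    )
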