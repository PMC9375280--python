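"""Latent-feature classifiers: per-stage PCA or a global autoencoder, IQR
volatility features, and logistic regression.

Both classifiers share the same skeleton.  The 8 modeling channels (METS, HR,
V̇O2, V̇CO2, RER, VE, VTex, VTin) are standardized with statistics pooled over
the *training* breaths only.  A 3-dimensional latent projection is then taken
— per protocol stage for PCA (the channel correlation structure differs at
rest, under load, and in recovery), or by a single global encoder for the
autoencoder — and each patient is summarized by the interquartile range of
each latent component within each stage: 9 volatility features, stage-major.
A logistic regression maps the features to the probability of heart failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPRegressor

from . import io as cio
from .schema import MODEL_CHANNELS, PatientRecord, STAGES, StageAnnotation

__all__ = [
    "standardize_channels",
    "fit_stage_pca",
    "StagePCAModel",
    "AEModel",
    "fit_autoencoder",
    "iqr",
    "extract_features",
    "fit_logistic",
    "PCALogisticClassifier",
    "AutoencoderLogisticClassifier",
    "POSITIVE_CLASS",
]

POSITIVE_CLASS = "heart_failure"


# ---------------------------------------------------------------------------
# standardization

def standardize_channels(records: Sequence[PatientRecord]):
    """Per-channel mean/SD from pooled training breaths + a reusable transform.

    Returns ``(stats, transform)`` where ``stats`` maps channel name to
    (mean, sd) and ``transform(record_or_matrix)`` standardizes with those
    *training* statistics (never the target's own).
    """
    if len(records) == 0:
        raise ValueError("training set is empty")
    pooled = np.vstack([r.series.channel_matrix() for r in records])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [MODEL_CHANNELS[i] for i in dead]
        raise ValueError(f"zero-variance channel(s) in training pool: {names}")
    stats = {c: (float(mean[i]), float(sd[i])) for i, c in enumerate(MODEL_CHANNELS)}

    def transform(x) -> np.ndarray:
        m = x.series.channel_matrix() if isinstance(x, PatientRecord) else np.asarray(x, float)
        return (m - mean) / sd

    return stats, transform


# ---------------------------------------------------------------------------
# PCA path

@dataclass
class StagePCAModel:
    """Top-3 principal axes of one stage's pooled covariance.

    ``components`` rows are the orthonormal axes u1..u3 (non-increasing
    explained variance; sign fixed so each axis' largest-|loading| channel is
    positive).  The sample covariance is retained for audit.
    """

    mean: np.ndarray
    components: np.ndarray            # (k, 8)
    explained_variance_ratio: np.ndarray
    covariance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T


def fit_stage_pca(stage_observations: np.ndarray, n_components: int = 3) -> StagePCAModel:
    """Fit the per-stage PCA on pooled standardized stage observations."""
    X = np.asarray(stage_observations, float)
    if X.ndim != 2 or X.shape[0] < X.shape[1]:
        raise ValueError(
            f"need at least as many pooled observations as channels "
            f"({X.shape[1] if X.ndim == 2 else '?'}), got shape {X.shape}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for row in comps:  # deterministic sign: largest-|loading| positive
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    cov = np.cov(X, rowvar=False, ddof=1)
    return StagePCAModel(
        mean=pca.mean_,
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_,
        covariance=cov,
    )


# ---------------------------------------------------------------------------
# autoencoder path

_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
    "logistic": expit,
}


@dataclass
class AEModel:
    """Encoder/decoder weight stacks plus the MSE training history.

    ``coefs``/``intercepts`` hold four layers (8→h→k→h→8); the first two form
    the encoder f, the last two the decoder g (linear output).
    """

    coefs: list
    intercepts: list
    activation: str = "tanh"
    loss_history: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if len(self.coefs) != 4:
            raise ValueError("an autoencoder bundle has exactly 4 weight layers")

    @property
    def n_components(self) -> int:
        return self.coefs[1].shape[1]

    def encode(self, X: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self.activation]
        h = act(np.asarray(X, float) @ self.coefs[0] + self.intercepts[0])
        return act(h @ self.coefs[1] + self.intercepts[1])

    def decode(self, Z: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self.activation]
        h = act(np.asarray(Z, float) @ self.coefs[2] + self.intercepts[2])
        return h @ self.coefs[3] + self.intercepts[3]

    def reconstruction_mse(self, X: np.ndarray) -> float:
        X = np.asarray(X, float)
        return float(np.mean((X - self.decode(self.encode(X))) ** 2))


def fit_autoencoder(
    X: np.ndarray,
    hidden: int = 6,
    n_components: int = 3,
    activation: str = "tanh",
    batch_size: int = 32,
    max_epochs: int = 500,
    seed: int = 0,
) -> AEModel:
    """Train the 8→hidden→3→hidden→8 autoencoder by minimizing the MSE of
    x vs g(f(x)) on the pooled (standardized) training breaths.

    Mini-batch Adam with an epoch cap and a plateau stop; deterministic given
    ``seed``.  Emits a warning below 100 training rows.
    """
    X = np.asarray(X, float)
    if X.shape[0] < 100:
        warnings.warn(
            f"autoencoder trained on only {X.shape[0]} breaths; latent features "
            "may be unstable", stacklevel=2,
        )
    mlp = MLPRegressor(
        hidden_layer_sizes=(hidden, n_components, hidden),
        activation=activation,
        solver="adam",
        batch_size=min(batch_size, X.shape[0]),
        max_iter=max_epochs,
        tol=1e-7,
        n_iter_no_change=25,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, X)
    if not np.isfinite(mlp.loss_):
        raise RuntimeError(
            f"autoencoder training diverged (loss={mlp.loss_}) after "
            f"{mlp.n_iter_} epochs"
        )
    # sklearn's curve is squared error / 2; report plain MSE
    history = 2.0 * np.asarray(mlp.loss_curve_)
    return AEModel(
        coefs=list(mlp.coefs_),
        intercepts=list(mlp.intercepts_),
        activation=activation,
        loss_history=history,
    )


# ---------------------------------------------------------------------------
# volatility features

def iqr(values) -> float:
    """Interquartile range Q3 − Q1 (linear-interpolation quantiles)."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("IQR needs at least 2 values")
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def extract_features(scores_by_stage: dict) -> np.ndarray:
    """9 IQR features, stage-major (rest c1..c3, test c1..c3, recovery c1..c3)."""
    feats = []
    for stage in STAGES:
        if stage not in scores_by_stage:
            raise ValueError(f"missing scores for stage {stage!r}")
        scores = np.asarray(scores_by_stage[stage], float)
        if scores.ndim != 2 or scores.shape[1] != 3:
            raise ValueError(f"stage {stage!r} must have 3 components, got {scores.shape}")
        feats.extend(iqr(scores[:, j]) for j in range(scores.shape[1]))
    return np.array(feats)


def feature_names(n_components: int = 3) -> list[str]:
    return [f"{s}_c{j + 1}_iqr" for s in STAGES for j in range(n_components)]


# ---------------------------------------------------------------------------
# logistic head

def fit_logistic(features: np.ndarray, labels, seed: int = 0, C: float = 1.0):
    """Maximum-likelihood logistic fit with mild L2 stabilization."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("logistic regression needs both classes in training labels")
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-8,
                             random_state=seed)
    clf.fit(np.asarray(features, float), labels)
    return clf


def predict_heart_failure_probability(clf, features: np.ndarray) -> np.ndarray:
    col = list(clf.classes_).index(POSITIVE_CLASS)
    return clf.predict_proba(np.asarray(features, float))[:, col]


# ---------------------------------------------------------------------------
# estimators

class _LatentLogisticBase(BaseEstimator, ClassifierMixin):
    """Shared skeleton: standardize → latent scores per stage → IQRs → logistic."""

    requires_fit = True

    def _prepare(self, records: Sequence[PatientRecord]):
        out = []
        for rec in records:
            stages = cio.segment_stages(rec.series)
            out.append((rec.series.channel_matrix(), stages))
        return out

    def _fit_latent(self, prepared_std):  # -> None; sets model attributes
        raise NotImplementedError

    def _stage_scores(self, X_std: np.ndarray, stages: StageAnnotation) -> dict:
        raise NotImplementedError

    def _features_of(self, prepared) -> np.ndarray:
        rows = []
        for M, stages in prepared:
            X_std = (M - self._mean_vec_) / self._scale_vec_
            rows.append(extract_features(self._stage_scores(X_std, stages)))
        return np.vstack(rows)

    def _labels(self, X, y):
        if y is None:
            y = [r.label for r in X]
        y = np.asarray(y)
        if any(v is None for v in y):
            raise ValueError("labels required: pass y or label every record")
        return y

    def fit(self, X: Sequence[PatientRecord], y=None):
        y = self._labels(X, y)
        prepared = self._prepare(X)
        self.channel_stats_, _ = standardize_channels(X)
        self._mean_vec_ = np.array([self.channel_stats_[c][0] for c in MODEL_CHANNELS])
        self._scale_vec_ = np.array([self.channel_stats_[c][1] for c in MODEL_CHANNELS])
        prepared_std = [((M - self._mean_vec_) / self._scale_vec_, st) for M, st in prepared]
        self._fit_latent(prepared_std)
        self.features_ = self._features_of(prepared)
        self.feature_names_ = feature_names()
        self.logistic_ = fit_logistic(self.features_, y, seed=self.random_state, C=self.C)
        self.classes_ = self.logistic_.classes_
        return self

    def transform(self, X: Sequence[PatientRecord]) -> np.ndarray:
        """Per-patient 9-dim IQR feature vectors under the fitted models."""
        return self._features_of(self._prepare(X))

    def predict_proba(self, X: Sequence[PatientRecord]) -> np.ndarray:
        return self.logistic_.predict_proba(self.transform(X))

    def predict(self, X: Sequence[PatientRecord]) -> np.ndarray:
        proba = self.predict_proba(X)
        col = list(self.classes_).index(POSITIVE_CLASS)
        other = [c for c in self.classes_ if c != POSITIVE_CLASS][0]
        return np.where(proba[:, col] >= 0.5, POSITIVE_CLASS, other)


class PCALogisticClassifier(_LatentLogisticBase):
    """PCA-regression: per-stage top-3 principal components, IQR features,
    logistic output.  The PCA is refitted per training fold (leakage-safe)."""

    def __init__(self, n_components: int = 3, C: float = 1.0, random_state: int = 0):
        self.n_components = n_components
        self.C = C
        self.random_state = random_state

    def _fit_latent(self, prepared_std) -> None:
        self.stage_pca_ = {}
        for stage in STAGES:
            pooled = np.vstack([X[st.slices()[stage]] for X, st in prepared_std
                                if st.slices()[stage].stop > st.slices()[stage].start])
            self.stage_pca_[stage] = fit_stage_pca(pooled, self.n_components)

    def _stage_scores(self, X_std, stages) -> dict:
        return {s: self.stage_pca_[s].transform(X_std[stages.slices()[s]])
                for s in STAGES}


class AutoencoderLogisticClassifier(_LatentLogisticBase):
    """AE-regression: one global 3-dim-bottleneck autoencoder trained on all
    pooled training breaths, per-stage IQR aggregation of the encoded scores,
    logistic output."""

    def __init__(
        self,
        hidden: int = 6,
        n_components: int = 3,
        activation: str = "tanh",
        batch_size: int = 32,
        max_epochs: int = 500,
        C: float = 1.0,
        random_state: int = 0,
    ):
        self.hidden = hidden
        self.n_components = n_components
        self.activation = activation
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.C = C
        self.random_state = random_state

    def _fit_latent(self, prepared_std) -> None:
        pooled = np.vstack([X for X, _ in prepared_std])
        self.autoencoder_ = fit_autoencoder(
            pooled,
            hidden=self.hidden,
            n_components=self.n_components,
            activation=self.activation,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            seed=self.random_state,
        )

    def _stage_scores(self, X_std, stages) -> dict:
        Z = self.autoencoder_.encode(X_std)
        return {s: Z[stages.slices()[s]] for s in STAGES}
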