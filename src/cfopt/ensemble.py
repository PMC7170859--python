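"""Uncertainty-aware ensemble regressor for yield prediction.

The surrogate is an ensemble of 25 multilayer perceptrons. Each member is
the best of 10 independently initialized fits (selected by training R²),
so an ensemble is 250 network fits. The ensemble's prediction for a
composition is the mean over members; its uncertainty is the member
dispersion, which feeds the upper-confidence-bound acquisition rule.

Members are scikit-learn ``MLPRegressor`` networks with hidden layers
(10, 100, 100, 20), adam, adaptive learning rate and early stopping.
Early stopping is skipped below 50 training rows: a 10 % validation split
of a 20-point training set holds 2 points and stops training on noise, so
small datasets are fitted to convergence instead.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .exceptions import (
    FingerprintMismatchError,
    NotFittedError,
    UnderdeterminedError,
    UnnormalizedInputError,
)

#: below this many rows, early stopping's validation split is too small to
#: be meaningful and is disabled.
MIN_ROWS_FOR_EARLY_STOPPING = 50


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyperparameters of the ensemble.

    Unstated network settings are pinned to one default set (L2 penalty
    ``alpha``, batch size, 10 % early-stopping validation fraction) so
    results reproduce across machines. ``uncertainty`` selects the
    dispersion estimator: ``"std"`` (sample std across members, default)
    or ``"sem"`` (standard error of the member mean). With 25 members the
    SEM is 5x smaller and would nearly silence exploration in the UCB
    rule, hence the std default.
    """

    n_members: int = 25
    restarts_per_member: int = 10
    hidden_layers: tuple[int, ...] = (10, 100, 100, 20)
    max_iterations: int = 20000
    learning_rate: str = "adaptive"
    solver: str = "adam"
    early_stopping: bool = True
    validation_fraction: float = 0.1
    alpha: float = 1e-4
    uncertainty: str = "std"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1 or self.restarts_per_member < 1:
            raise ValueError("n_members and restarts_per_member must be >= 1")
        if self.uncertainty not in ("std", "sem"):
            raise ValueError("uncertainty must be 'std' or 'sem'")
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))

    @classmethod
    def reduced(cls, base_seed: int = 0, **kw) -> "EnsembleConfig":
        """A lighter ensemble for inner loops (subset search, campaign
        benchmarks): fewer members and restarts, capped iterations."""
        kw.setdefault("n_members", 5)
        kw.setdefault("restarts_per_member", 2)
        kw.setdefault("max_iterations", 3000)
        return cls(base_seed=base_seed, **kw)


@dataclass
class PredictionResult:
    mean: np.ndarray
    std: np.ndarray
    member_predictions: np.ndarray  # (n_members, n_points)


@dataclass
class MetricsReport:
    """Observed-vs-predicted statistics.

    ``r2`` is computed over all points; ``q2`` (predictive R², one minus
    prediction-error SS over total SS of the test observations) and the
    linear fit of observed against predicted use the test points only.
    """

    r2: float
    q2: float
    slope: float
    intercept: float


@dataclass
class CVReport:
    scores: list[float]
    mean: float
    std: float


def _validate_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one y per row")
    if len(X) < 2:
        raise UnderdeterminedError("at least 2 training rows required")
    if (X <= 0).any() or (X > 1).any():
        raise UnnormalizedInputError(
            "inputs must be normalized level fractions in (0, 1]; raw "
            "concentrations are rejected — normalization is strongly "
            "encouraged due to scale differences between compounds"
        )
    return X, y


def _member_seeds(base_seed: int, n: int) -> np.ndarray:
    # stable derivation: members differ but the ensemble reproduces
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31 - 1)


def _fit_one(X: np.ndarray, y: np.ndarray, config: EnsembleConfig, seed: int) -> MLPRegressor:
    early = config.early_stopping and len(X) >= MIN_ROWS_FOR_EARLY_STOPPING
    model = MLPRegressor(
        hidden_layer_sizes=config.hidden_layers,
        max_iter=config.max_iterations,
        learning_rate=config.learning_rate,
        solver=config.solver,
        early_stopping=early,
        validation_fraction=config.validation_fraction,
        alpha=config.alpha,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def train_member(
    X: np.ndarray,
    y: np.ndarray,
    restarts: int,
    seed: int,
    config: EnsembleConfig | None = None,
) -> MLPRegressor:
    """Best-of-``restarts`` fit on the full data, selected by training R²."""
    config = config or EnsembleConfig()
    X, y = _validate_inputs(X, y)
    seeds = _member_seeds(seed, restarts)
    best, best_score = None, -np.inf
    for s in seeds:
        model = _fit_one(X, y, config, s)
        score = model.score(X, y)
        if score > best_score:
            best, best_score = model, score
    return best


@dataclass
class Ensemble:
    """A trained ensemble: members plus a fingerprint of what trained them."""

    members: list[MLPRegressor]
    config: EnsembleConfig
    fingerprint: str = ""

    def predict(self, X: np.ndarray) -> PredictionResult:
        """Per-composition mean and dispersion across member predictions.

        Dispersion is the sample std (ddof=1) over the member outputs, or
        the SEM when the config selects it.
        """
        if not self.members:
            raise NotFittedError("ensemble has no trained members")
        X = np.asarray(X, dtype=float)
        preds = np.array([m.predict(X) for m in self.members])
        mean = preds.mean(axis=0)
        if len(self.members) > 1:
            std = preds.std(axis=0, ddof=1)
        else:
            std = np.zeros_like(mean)
        if self.config.uncertainty == "sem":
            std = std / np.sqrt(len(self.members))
        return PredictionResult(mean=mean, std=std, member_predictions=preds)

    # -- persistence ----------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = asdict(self.config)
        meta["fingerprint"] = self.fingerprint
        (d / "config.json").write_text(json.dumps(meta, indent=2))
        for i, m in enumerate(self.members):
            joblib.dump(m, d / f"member_{i:03d}.joblib")

    @classmethod
    def load(cls, directory, expected_fingerprint: str | None = None) -> "Ensemble":
        d = Path(directory)
        meta = json.loads((d / "config.json").read_text())
        fingerprint = meta.pop("fingerprint", "")
        meta["hidden_layers"] = tuple(meta["hidden_layers"])
        config = EnsembleConfig(**meta)
        if expected_fingerprint is not None and fingerprint != expected_fingerprint:
            raise FingerprintMismatchError(
                "model bundle fingerprint does not match the supplied data"
            )
        members = [
            joblib.load(p) for p in sorted(d.glob("member_*.joblib"))
        ]
        return cls(members=members, config=config, fingerprint=fingerprint)


def data_fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.asarray(X, dtype=float)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y, dtype=float)).tobytes())
    return h.hexdigest()


def train_ensemble(X: np.ndarray, y: np.ndarray, config: EnsembleConfig | None = None) -> Ensemble:
    """Train ``n_members`` best-of-restarts members on the whole dataset.

    Member seeds derive deterministically from ``base_seed`` so two runs
    on the same data produce identical ensembles while members still
    differ from each other.
    """
    config = config or EnsembleConfig()
    X, y = _validate_inputs(X, y)
    member_seeds = _member_seeds(config.base_seed, config.n_members)
    members = [
        train_member(X, y, config.restarts_per_member, int(s), config)
        for s in member_seeds
    ]
    return Ensemble(members=members, config=config, fingerprint=data_fingerprint(X, y))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: EnsembleConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """k-fold CV of the full ensemble: train on k-1 folds, score the
    ensemble-mean prediction on the held-out fold (R²)."""
    config = config or EnsembleConfig()
    X, y = _validate_inputs(X, y)
    if len(X) < k:
        raise UnderdeterminedError(f"{len(X)} rows cannot form {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in kf.split(X):
        ens = train_ensemble(X[train_idx], y[train_idx], config)
        pred = ens.predict(X[test_idx])
        scores.append(float(r2_score(y[test_idx], pred.mean)))
    arr = np.asarray(scores)
    return CVReport(scores=scores, mean=float(arr.mean()), std=float(arr.std(ddof=1)))


def regression_metrics(
    predicted: Sequence[float], observed: Sequence[float], train_mask: Sequence[bool]
) -> MetricsReport:
    """R² over all points; Q² and observed-vs-predicted fit over test points."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    mask = np.asarray(train_mask, dtype=bool)
    if p.shape != o.shape or p.shape != mask.shape:
        raise ValueError("predicted, observed and train_mask must align")
    if not (~mask).any():
        raise ValueError("test set is empty")
    if o.std() == 0 or o[~mask].std() == 0:
        raise ValueError("observed values have zero variance; metrics undefined")
    r2 = float(r2_score(o, p))
    ot, pt = o[~mask], p[~mask]
    q2 = float(1.0 - np.sum((ot - pt) ** 2) / np.sum((ot - ot.mean()) ** 2))
    fit = stats.linregress(pt, ot)
    return MetricsReport(r2=r2, q2=q2, slope=float(fit.slope), intercept=float(fit.intercept))
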