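"""Level-0 base predictors and level-1 logistic stacking.

Three base predictors score each (protein, RNA) pair from the
concatenated bi-gram + singular-value feature vector:

* ``RPIseq-RF`` — a random forest on the raw features;
* ``SA-RF``     — a random forest on sparse-stacked-auto-encoder
  codes (unsupervised pre-training only);
* ``SA-FT-RF``  — a random forest on codes from the same auto-encoder
  after supervised fine-tuning.

Their probability outputs s are fused by a level-1 logistic regression
P(y = 1 | s) = sigmoid(wᵀs + c).  The level-1 model is fitted only on
out-of-fold level-0 scores produced by an internal stratified 5-fold
split, so the combiner never sees scores a base model produced on its
own training data.  With equal weights the fused ranking reduces to
average-score voting; with a single non-zero weight it reduces to that
base model alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

from .io_formats import PairTable, ValidationError
from .sae import SaeConfig, SaeModel, fine_tune, sae_encode, sae_train

BASE_MODEL_NAMES = ("RPIseq-RF", "SA-RF", "SA-FT-RF")


def assemble_pair_features(
    pairs: PairTable,
    protein_features: pd.DataFrame,
    rna_features: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-pair protein and RNA feature rows into an
    n x (400 + d) design matrix; unknown ids raise naming the id."""
    for pid in pairs.frame["protein_id"].unique():
        if pid not in protein_features.index:
            raise ValidationError(f"no protein features for id '{pid}'")
    for rid in pairs.frame["rna_id"].unique():
        if rid not in rna_features.index:
            raise ValidationError(f"no RNA features for id '{rid}'")
    Xp = protein_features.loc[pairs.frame["protein_id"]].to_numpy(dtype=np.float64)
    Xr = rna_features.loc[pairs.frame["rna_id"]].to_numpy(dtype=np.float64)
    return np.hstack([Xp, Xr]), pairs.labels.copy()


@dataclass
class BasePredictor:
    """One level-0 predictor: an optional scaler + SAE front end and a
    random forest emitting interaction probabilities."""

    name: str
    rf: RandomForestClassifier
    scaler: MinMaxScaler | None = None
    sae: SaeModel | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            return X
        Xs = np.clip(self.scaler.transform(X), 0.0, 1.0)
        return sae_encode(self.sae, Xs)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        proba = self.rf.predict_proba(self._transform(X))
        pos = list(self.rf.classes_).index(1)
        return proba[:, pos]


def train_base(
    X: np.ndarray,
    y: np.ndarray,
    name: str,
    seed: int = 0,
    sae_config: SaeConfig | None = None,
    n_trees: int = 500,
    pretrained: tuple[MinMaxScaler, SaeModel] | None = None,
) -> BasePredictor:
    """Fit one named base predictor.

    ``pretrained`` lets SA-RF and SA-FT-RF share a single unsupervised
    pre-training run (fine-tuning always works on a copy).
    """
    if name not in BASE_MODEL_NAMES:
        raise ValidationError(f"unknown base model '{name}'")
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValidationError("training labels contain a single class")
    scaler, sae_model = None, None
    X_fit = X
    if name != "RPIseq-RF":
        if sae_config is None:
            sae_config = SaeConfig(seed=seed)
        if pretrained is not None:
            scaler, sae_model = pretrained
        else:
            scaler = MinMaxScaler().fit(X)
            Xs = np.clip(scaler.transform(X), 0.0, 1.0)
            sae_model = sae_train(Xs, sae_config)
        Xs = np.clip(scaler.transform(X), 0.0, 1.0)
        if name == "SA-FT-RF":
            sae_model = fine_tune(sae_model, Xs, y, sae_config)
        X_fit = sae_encode(sae_model, Xs)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed % (2**32),
        n_jobs=1,
    )
    rf.fit(X_fit, y)
    return BasePredictor(name=name, rf=rf, scaler=scaler, sae=sae_model)


@dataclass
class StackedEnsemble:
    """Level-0 base predictors plus the fitted level-1 logistic fusion."""

    bases: list[BasePredictor]
    w: np.ndarray
    intercept: float

    def level0_scores(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([b.predict_proba(X) for b in self.bases])

    def fuse(self, scores: np.ndarray) -> np.ndarray:
        return expit(np.asarray(scores) @ self.w + self.intercept)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.fuse(self.level0_scores(X))

    def predict(self, X: np.ndarray, threshold: float = 0.5):
        """Fused probability and thresholded label (score >= threshold,
        ties inclusive, maps to interacting)."""
        scores = self.predict_proba(X)
        return scores, (scores >= threshold).astype(int)


def train_stack(level0_scores: np.ndarray, labels: np.ndarray):
    """Fit the level-1 logistic combiner on out-of-fold level-0 scores.

    Unregularized by default; falls back to ridge (L2) if the
    unpenalized fit fails to produce finite coefficients (perfectly
    separable score matrices).  Returns ``(w, intercept)``.
    """
    S = np.asarray(level0_scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if S.ndim != 2:
        raise ValidationError("level-0 score matrix must be 2-D")
    if np.unique(y).size < 2:
        raise ValidationError("stacking labels contain a single class")
    if (S < 0).any() or (S > 1).any():
        raise ValidationError("level-0 scores must lie in [0, 1]")
    try:
        lr = LogisticRegression(C=np.inf, max_iter=5000)
        lr.fit(S, y)
        if not np.isfinite(lr.coef_).all() or not np.isfinite(lr.intercept_).all():
            raise ValueError("non-finite coefficients")
    except Exception:
        lr = LogisticRegression(C=1.0, max_iter=5000)
        lr.fit(S, y)
    return lr.coef_.ravel().copy(), float(lr.intercept_[0])


def fit_stacked_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    sae_config: SaeConfig | None = None,
    n_trees: int = 500,
    n_inner_folds: int = 5,
    base_models: tuple[str, ...] | None = None,
) -> tuple[StackedEnsemble, np.ndarray]:
    """Train the full stack on one training set.

    An internal stratified split produces out-of-fold level-0 scores for
    the level-1 fit; the base predictors are then refit on all the data.
    Returns the ensemble and the n x n_bases out-of-fold score matrix.
    """
    names = BASE_MODEL_NAMES if base_models is None else tuple(base_models)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_inner_folds:
        raise ValidationError(
            f"need >= {n_inner_folds} samples per class for the internal "
            f"out-of-fold split; got {counts.tolist()}"
        )
    if sae_config is None:
        sae_config = SaeConfig(seed=seed)
    oof = np.zeros((len(y), len(names)))
    skf = StratifiedKFold(
        n_splits=n_inner_folds, shuffle=True, random_state=seed % (2**32)
    )
    inner_seeds = np.random.SeedSequence(seed).generate_state(n_inner_folds + 1)
    inner_seeds = inner_seeds % (2**31)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        bases = _train_bases(
            X[tr], y[tr], names, int(inner_seeds[fold]), sae_config, n_trees
        )
        for j, base in enumerate(bases):
            oof[te, j] = base.predict_proba(X[te])
    w, intercept = train_stack(oof, y)
    final_bases = _train_bases(
        X, y, names, int(inner_seeds[-1]), sae_config, n_trees
    )
    return StackedEnsemble(bases=final_bases, w=w, intercept=intercept), oof


def _train_bases(X, y, names, seed, sae_config, n_trees) -> list[BasePredictor]:
    """Train the named base predictors, pre-training the SAE only once."""
    pretrained = None
    needs_sae = any(n != "RPIseq-RF" for n in names)
    if needs_sae:
        cfg = SaeConfig(**{**sae_config.__dict__, "seed": seed})
        scaler = MinMaxScaler().fit(X)
        Xs = np.clip(scaler.transform(X), 0.0, 1.0)
        pretrained = (scaler, sae_train(Xs, cfg))
        sae_config = cfg
    return [
        train_base(
            X,
            y,
            name,
            seed=seed + i,
            sae_config=sae_config,
            n_trees=n_trees,
            pretrained=pretrained if name != "RPIseq-RF" else None,
        )
        for i, name in enumerate(names)
    ]
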