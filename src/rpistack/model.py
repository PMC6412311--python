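"""Model/Results surface for the stacked interaction predictor.

`InteractionModel` is built from a pair table plus per-protein and
per-RNA feature frames (or directly from a synthetic dataset / on-disk
files); `fit()` trains the three level-0 random-forest predictors and
the level-1 logistic combiner and returns an `InteractionResults`
carrying the fitted ensemble, its out-of-fold diagnostics and a
`summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import (
    BASE_MODEL_NAMES,
    StackedEnsemble,
    assemble_pair_features,
    fit_stacked_ensemble,
)
from .evaluation import MetricsReport, cross_validate, metrics_from_scores, roc_auc
from .io_formats import (
    PairTable,
    bigram_feature_names,
    read_fasta,
    read_pairs,
    read_pssm,
    sv_feature_names,
)
from .protein_features import bigram_features, normalize_pssm
from .rna_features import rna_feature_matrix
from .sae import SaeConfig
from .synthetic_data import SimDataset


def protein_feature_frame(
    pssms: dict, mode: str = "percentages", length_normalize: bool = False
) -> pd.DataFrame:
    """400-d bi-gram features for a dict of RawPssm, indexed by protein id."""
    ids, rows = [], []
    for pid in sorted(pssms):
        feat = bigram_features(
            normalize_pssm(pssms[pid], mode=mode), length_normalize=length_normalize
        )
        ids.append(pid)
        rows.append(feat.F)
    return pd.DataFrame(
        np.vstack(rows), index=pd.Index(ids, name="id"), columns=bigram_feature_names()
    )


def rna_feature_frame(rnas: list, k: int = 4, d: int = 16) -> pd.DataFrame:
    """Top-d singular-value features for a list of RnaSequence."""
    ids, mat = rna_feature_matrix(rnas, k=k, d=d)
    return pd.DataFrame(mat, index=pd.Index(ids, name="id"), columns=sv_feature_names(d))


class InteractionModel:
    """Stacked sequence-based ncRNA-protein interaction classifier.

    Parameters
    ----------
    pairs : PairTable
        (protein_id, rna_id, label) rows.
    protein_features, rna_features : DataFrame
        Feature frames indexed by id (bi-gram / singular-value columns).
    sae_config : SaeConfig, optional
        Auto-encoder hyper-parameters shared by the SA-RF and SA-FT-RF
        base models.
    n_trees : int
        Trees per random forest.
    base_models : tuple of str, optional
        Subset of ``("RPIseq-RF", "SA-RF", "SA-FT-RF")``.
    """

    def __init__(
        self,
        pairs: PairTable,
        protein_features: pd.DataFrame,
        rna_features: pd.DataFrame,
        sae_config: SaeConfig | None = None,
        n_trees: int = 500,
        base_models: tuple[str, ...] | None = None,
    ):
        self.pairs = pairs
        self.protein_features = protein_features
        self.rna_features = rna_features
        self.sae_config = sae_config
        self.n_trees = n_trees
        self.base_models = BASE_MODEL_NAMES if base_models is None else tuple(base_models)
        self.exog, self.endog = assemble_pair_features(
            pairs, protein_features, rna_features
        )

    # ------------------------------------------------------------------
    @classmethod
    def from_dataset(
        cls,
        dataset: SimDataset,
        k: int = 4,
        d: int = 16,
        mode: str = "percentages",
        **kwargs,
    ) -> "InteractionModel":
        """Build from an in-memory synthetic dataset."""
        return cls(
            dataset.pairs,
            protein_feature_frame(dataset.pssms, mode=mode),
            rna_feature_frame(dataset.rnas, k=k, d=d),
            **kwargs,
        )

    @classmethod
    def from_files(
        cls,
        pairs_path: str | Path,
        pssm_dir: str | Path,
        rna_fasta: str | Path,
        k: int = 4,
        d: int = 16,
        mode: str = "percentages",
        **kwargs,
    ) -> "InteractionModel":
        """Build from a pair TSV, a directory of ``<id>.pssm`` files and
        an RNA FASTA."""
        pairs = read_pairs(pairs_path)
        pssm_dir = Path(pssm_dir)
        pssms = {
            pid: read_pssm(pssm_dir / f"{pid}.pssm", protein_id=pid)
            for pid in sorted(pairs.frame["protein_id"].unique())
        }
        rnas = read_fasta(rna_fasta, moltype="rna")
        return cls(
            pairs,
            protein_feature_frame(pssms, mode=mode),
            rna_feature_frame(rnas, k=k, d=d),
            **kwargs,
        )

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "InteractionResults":
        ensemble, oof = fit_stacked_ensemble(
            self.exog,
            self.endog,
            seed=seed,
            sae_config=self.sae_config,
            n_trees=self.n_trees,
            base_models=self.base_models,
        )
        return InteractionResults(model=self, ensemble=ensemble, oof_scores=oof, seed=seed)

    def cross_validate(self, folds: int = 5, seed: int = 0) -> MetricsReport:
        """Stratified k-fold CV of the whole pipeline (every component
        refitted inside each training fold)."""
        return cross_validate(
            self.pairs,
            self.protein_features,
            self.rna_features,
            sae_config=self.sae_config,
            n_trees=self.n_trees,
            folds=folds,
            seed=seed,
            base_models=self.base_models,
        )


@dataclass
class InteractionResults:
    """Fitted stacked ensemble plus training diagnostics."""

    model: InteractionModel
    ensemble: StackedEnsemble
    oof_scores: np.ndarray = field(repr=False)
    seed: int = 0

    @property
    def params(self) -> pd.Series:
        names = [b.name for b in self.ensemble.bases]
        return pd.Series(
            np.append(self.ensemble.w, self.ensemble.intercept),
            index=names + ["intercept"],
            name="level1_weight",
        )

    def base_oof_auc(self) -> dict[str, float]:
        y = self.model.endog
        return {
            b.name: roc_auc(self.oof_scores[:, j], y)[0]
            for j, b in enumerate(self.ensemble.bases)
        }

    def ensemble_oof_auc(self) -> float:
        """AUC of the level-1 fusion applied to out-of-fold level-0 scores
        (an optimistic-but-honest training diagnostic, not test AUC)."""
        fused = self.ensemble.fuse(self.oof_scores)
        return roc_auc(fused, self.model.endog)[0]

    def predict(
        self, pairs: PairTable | None = None, threshold: float = 0.5
    ) -> pd.DataFrame:
        """Fused probabilities and thresholded labels for a pair table
        (defaults to the training pairs)."""
        if pairs is None:
            pairs = self.model.pairs
        X, _ = assemble_pair_features(
            pairs, self.model.protein_features, self.model.rna_features
        )
        scores, labels = self.ensemble.predict(X, threshold=threshold)
        out = pairs.frame[["protein_id", "rna_id"]].copy()
        out["score"] = scores
        out["predicted_label"] = labels
        return out

    def summary(self) -> str:
        y = self.model.endog
        oof_metrics = metrics_from_scores(self.ensemble.fuse(self.oof_scores), y)
        lines = [
            "Stacked ncRNA-protein interaction model",
            "=" * 55,
            f"pairs: {len(y)}   positives: {int(y.sum())}   "
            f"features: {self.model.exog.shape[1]}",
            f"base models: {', '.join(b.name for b in self.ensemble.bases)}",
            f"seed: {self.seed}",
            "",
            "level-1 logistic weights",
            "-" * 55,
        ]
        for name, value in self.params.items():
            lines.append(f"  {name:<12} {value:>10.4f}")
        lines += ["", "out-of-fold diagnostics (training data)", "-" * 55]
        for name, auc_val in self.base_oof_auc().items():
            lines.append(f"  AUC {name:<12} {auc_val:>8.4f}")
        lines.append(f"  AUC fused        {oof_metrics.auc:>8.4f}")
        lines.append(f"  accuracy fused   {oof_metrics.metrics.accuracy:>8.4f}")
        lines.append(f"  MCC fused        {oof_metrics.metrics.mcc:>8.4f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the fused out-of-fold scores (matplotlib)."""
        import matplotlib.pyplot as plt

        auc_val, fpr, tpr, _ = roc_auc(
            self.ensemble.fuse(self.oof_scores), self.model.endog
        )
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"fused (AUC = {auc_val:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
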