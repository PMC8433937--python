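"""Model-level interface: build once from data, fit, inspect results.

``DTIModel`` bundles the three inputs (interaction graph, fingerprints,
protein features) and the sampling/classifier configuration;
:meth:`DTIModel.fit` returns a :class:`DTIResults` carrying the fitted
ensemble, the cross-validated diagnostics and a printable summary, in
the spirit of the statsmodels model/results split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ProteinFeatures, extract_feature_table, read_feature_table
from .fingerprints import DrugFingerprint, load_fingerprints
from .pssm import load_pssm_dir
from .pipeline import (EvalReport, InteractionSet, LabeledDataset, build_dataset,
                       cross_validate, negative_resample_study)
from .rotation_forest import RoFConfig, RotationForestClassifier

__all__ = ["DTIModel", "DTIResults"]


@dataclass
class DTIModel:
    """Drug-target interaction model over descriptor rows.

    Parameters
    ----------
    interactions : known positive (drug, protein) pairs plus id universes
    fingerprints : drug_id -> 881-bit fingerprint
    features : protein_id -> 256-dim wavelet descriptor
    config : Rotation Forest hyper-parameters (K, L, ...)
    ratio : negatives per positive when sampling (1 -> balanced)
    seed : governs negative sampling and fold assignment
    """

    interactions: InteractionSet
    fingerprints: dict[str, DrugFingerprint]
    features: dict[str, ProteinFeatures]
    config: RoFConfig = field(default_factory=RoFConfig)
    ratio: float = 1.0
    seed: int = 0

    @classmethod
    def from_files(cls, interactions: str | Path, fingerprints: str | Path,
                   features: str | Path | None = None,
                   pssm_dir: str | Path | None = None,
                   config: RoFConfig | None = None, ratio: float = 1.0,
                   seed: int = 0, levels: int = 2,
                   normalize: str = "none") -> "DTIModel":
        """Assemble a model from on-disk tables (and/or a PSSM directory)."""
        inter = InteractionSet.from_table(interactions)
        fps = load_fingerprints(Path(fingerprints))
        if features is not None:
            feats = read_feature_table(features)
        elif pssm_dir is not None:
            feats = extract_feature_table(load_pssm_dir(pssm_dir),
                                          levels=levels, normalize=normalize)
        else:
            raise ValueError("provide either a feature table or a PSSM directory")
        # the interaction table lists only positive pairs; the negative
        # pool spans every drug with a fingerprint x every protein with
        # features, as in the bipartite-complement sampling design
        universe = InteractionSet(
            drugs=sorted(set(inter.drugs) | set(fps)),
            proteins=sorted(set(inter.proteins) | set(feats)),
            positives=inter.positives,
        )
        return cls(universe, fps, feats, config=config or RoFConfig(),
                   ratio=ratio, seed=seed)

    def build(self) -> LabeledDataset:
        return build_dataset(self.interactions, self.fingerprints, self.features,
                             ratio=self.ratio, seed=self.seed)

    def fit(self, cross_validate_folds: int | None = 5) -> "DTIResults":
        """Fit on the full assembled dataset; optionally cross-validate first."""
        dataset = self.build()
        report = None
        if cross_validate_folds:
            report = cross_validate(dataset, self.config,
                                    folds=cross_validate_folds, seed=self.seed)
        classifier = RotationForestClassifier(self.config)
        classifier.fit(dataset.X, dataset.y)
        return DTIResults(model=self, dataset=dataset, classifier=classifier,
                          cv=report)

    def cross_validate(self, folds: int = 5) -> EvalReport:
        return cross_validate(self.build(), self.config, folds=folds, seed=self.seed)

    def negative_resample_study(self, n_resamples: int = 5, folds: int = 5):
        return negative_resample_study(self.interactions, self.fingerprints,
                                       self.features, self.config,
                                       n_resamples=n_resamples, ratio=self.ratio,
                                       folds=folds, seed=self.seed)


@dataclass
class DTIResults:
    """Fitted ensemble plus evaluation diagnostics."""

    model: DTIModel
    dataset: LabeledDataset
    classifier: RotationForestClassifier
    cv: EvalReport | None = None

    def predict_pairs(self, pairs: list[tuple[str, str]]) -> pd.DataFrame:
        """Interaction confidence for arbitrary (drug, protein) pairs."""
        fps = self.model.fingerprints
        feats = self.model.features
        missing = [f"{d}/{p}" for d, p in pairs if d not in fps or p not in feats]
        if missing:
            raise KeyError(f"no fingerprint/features for: {', '.join(missing)}")
        X = np.stack([np.concatenate([fps[d].bits, feats[p].vector])
                      for d, p in pairs])
        conf = self.classifier.decision_scores(X)
        return pd.DataFrame({
            "drug_id": [d for d, _ in pairs],
            "protein_id": [p for _, p in pairs],
            "confidence": conf,
            "predicted": (conf > 0.5).astype(int),
        })

    def summary(self) -> str:
        n_pos = int(self.dataset.y.sum())
        n_neg = int((self.dataset.y == 0).sum())
        lines = [
            "Drug-target interaction model",
            f"  drugs: {len(self.model.interactions.drugs)}   "
            f"proteins: {len(self.model.interactions.proteins)}",
            f"  training rows: {len(self.dataset)} ({n_pos} positive, {n_neg} negative)",
            f"  descriptor: 881 fingerprint bits + 256 wavelet features",
            f"  rotation forest: K={self.model.config.n_subsets} subsets, "
            f"L={self.model.config.n_trees} trees, seed={self.model.seed}",
        ]
        if self.cv is not None:
            lines += ["", self.cv.summary()]
        return "\n".join(lines)
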