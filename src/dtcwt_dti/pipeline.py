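"""Dataset assembly, cross-validated evaluation and the robustness study.

A drug-target interaction problem arrives as a bipartite graph: known
interacting (drug, protein) pairs are the positives, and negatives are
drawn uniformly from the unobserved complement of the drug x protein
grid (a tiny fraction of which may be undiscovered true interactions —
accepted, as the contamination probability is small at gold-standard
sizes).  Every pair becomes a 1137-dimensional descriptor: the 881
fingerprint bits of the drug followed by the 256 wavelet features of the
protein.  Evaluation is stratified k-fold cross-validation reporting
accuracy, precision, sensitivity, Matthews correlation and ROC AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .fingerprints import N_BITS, DrugFingerprint
from .features import N_FEATURES, ProteinFeatures
from .rotation_forest import RoFConfig, RotationForestClassifier

__all__ = [
    "InteractionSet", "LabeledDataset", "Metrics", "FoldResult", "EvalReport",
    "sample_negatives", "build_dataset", "compute_metrics", "roc_auc",
    "cross_validate", "negative_resample_study", "grid_search",
]

DESCRIPTOR_LENGTH = N_BITS + N_FEATURES   # 881 + 256 = 1137


# ---------------------------------------------------------------------------
# interaction graph and dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class InteractionSet:
    """Bipartite interaction graph between drugs and target proteins."""

    drugs: list[str]
    proteins: list[str]
    positives: set[tuple[str, str]]

    def __post_init__(self) -> None:
        drug_set, protein_set = set(self.drugs), set(self.proteins)
        if len(drug_set) != len(self.drugs) or len(protein_set) != len(self.proteins):
            raise ValueError("duplicate drug or protein ids")
        for d, p in self.positives:
            if d not in drug_set or p not in protein_set:
                raise ValueError(f"positive pair ({d}, {p}) references unknown ids")

    @property
    def n_possible_pairs(self) -> int:
        return len(self.drugs) * len(self.proteins)

    @property
    def n_negative_candidates(self) -> int:
        return self.n_possible_pairs - len(self.positives)

    @classmethod
    def from_table(cls, path: str | Path) -> "InteractionSet":
        """Read a drug_id<TAB>protein_id positive-pair list."""
        df = pd.read_csv(path, sep="\t", header=None, names=["drug_id", "protein_id"],
                         dtype=str, comment="#")
        pairs = list(df.itertuples(index=False, name=None))
        drugs = sorted({d for d, _ in pairs})
        proteins = sorted({p for _, p in pairs})
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate interaction pairs in table")
        return cls(drugs=drugs, proteins=proteins, positives=set(pairs))

    def to_table(self, path: str | Path) -> None:
        rows = sorted(self.positives)
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def sample_negatives(s: InteractionSet, ratio: float = 1.0,
                     seed: int = 0) -> set[tuple[str, str]]:
    """Uniform sample (without replacement) of non-interacting pairs.

    Sample size is round(ratio * |positives|); reproducible for a given
    seed.
    """
    n_need = round(ratio * len(s.positives))
    if s.n_negative_candidates < n_need:
        raise ValueError(
            f"cannot draw {n_need} negatives from {s.n_negative_candidates} "
            f"non-interacting pairs"
        )
    n_p = len(s.proteins)
    drug_pos = {d: i for i, d in enumerate(s.drugs)}
    prot_pos = {p: i for i, p in enumerate(s.proteins)}
    pos = np.fromiter((drug_pos[d] * n_p + prot_pos[p] for d, p in s.positives),
                      dtype=np.int64, count=len(s.positives))
    complement = np.setdiff1d(np.arange(s.n_possible_pairs, dtype=np.int64), pos,
                              assume_unique=False)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(complement, size=n_need, replace=False)
    return {(s.drugs[c // n_p], s.proteins[c % n_p]) for c in chosen.tolist()}


@dataclass
class LabeledDataset:
    """Descriptor matrix with labels and full provenance."""

    pairs: list[tuple[str, str]]
    X: np.ndarray
    y: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)


def build_dataset(s: InteractionSet,
                  fingerprints: dict[str, DrugFingerprint],
                  features: dict[str, ProteinFeatures],
                  ratio: float = 1.0, seed: int = 0,
                  negatives: set[tuple[str, str]] | None = None) -> LabeledDataset:
    """Assemble positives plus sampled negatives into descriptor rows.

    Each row is the drug's 881 bits followed by the protein's 256
    features; positives first (sorted), then negatives (sorted), which
    together with the seed makes rebuilding bit-identical.
    """
    if negatives is None:
        negatives = sample_negatives(s, ratio=ratio, seed=seed)
    needed_drugs = {d for d, _ in s.positives} | {d for d, _ in negatives}
    needed_prots = {p for _, p in s.positives} | {p for _, p in negatives}
    missing_fp = sorted(needed_drugs - set(fingerprints))
    missing_ft = sorted(needed_prots - set(features))
    if missing_fp or missing_ft:
        raise KeyError(
            "missing fingerprints for drugs "
            f"{missing_fp} / missing features for proteins {missing_ft}"
        )
    pairs = sorted(s.positives) + sorted(negatives)
    y = np.concatenate([np.ones(len(s.positives), dtype=int),
                        np.zeros(len(negatives), dtype=int)])
    X = np.empty((len(pairs), DESCRIPTOR_LENGTH))
    for i, (d, p) in enumerate(pairs):
        X[i, :N_BITS] = fingerprints[d].bits
        X[i, N_BITS:] = features[p].vector
    return LabeledDataset(pairs=pairs, X=X, y=y,
                          provenance={"seed": seed, "ratio": ratio,
                                      "n_positives": len(s.positives),
                                      "n_negatives": len(negatives)})


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

class Metrics(NamedTuple):
    accuracy: float
    precision: float
    sensitivity: float
    mcc: float
    degenerate: tuple[str, ...] = ()


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    """Accuracy, precision, sensitivity and Matthews correlation.

    ACC = (TP+TN)/(TP+TN+FP+FN);  PR = TP/(TP+FP);  Sen = TP/(FN+TP);
    MCC = (TP*TN - FN*FP) / sqrt((TN+FN)(FN+TP)(TP+FP)(FP+TN)).
    A metric whose denominator is zero is reported as 0 and its name is
    recorded in ``degenerate`` so small-fold reports stay comparable.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion-matrix counts must be non-negative")
    total = tp + fp + tn + fn
    if total < 1:
        raise ValueError("empty confusion matrix")
    degenerate: list[str] = []
    acc = (tp + tn) / total
    pr = sen = mcc = 0.0
    if tp + fp > 0:
        pr = tp / (tp + fp)
    else:
        degenerate.append("precision")
    if fn + tp > 0:
        sen = tp / (fn + tp)
    else:
        degenerate.append("sensitivity")
    denom = (tn + fn) * (fn + tp) * (tp + fp) * (fp + tn)
    if denom > 0:
        mcc = (tp * tn - fn * fp) / np.sqrt(denom)
    else:
        degenerate.append("mcc")
    if degenerate:
        warnings.warn(
            f"zero denominator for {', '.join(degenerate)}; reported as 0",
            RuntimeWarning, stacklevel=2,
        )
    return Metrics(acc, pr, sen, float(mcc), tuple(degenerate))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Threshold-sweep ROC (ties grouped) and trapezoidal AUC.

    Returns (auc, points) with points an (n, 2) array of (FPR, TPR).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes in labels")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return float(np.trapezoid(tpr, fpr)), np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    metrics: Metrics
    auc: float
    roc: np.ndarray
    confusion: tuple[int, int, int, int]     # tp, fp, tn, fn


_METRIC_COLS = ["accuracy", "precision", "sensitivity", "mcc", "auc"]


@dataclass
class EvalReport:
    """Per-fold metrics with the mean +/- sd aggregation row."""

    folds: list[FoldResult]
    seed: int
    config: RoFConfig

    @property
    def per_fold(self) -> pd.DataFrame:
        rows = [
            {"fold": i + 1, "accuracy": f.metrics.accuracy,
             "precision": f.metrics.precision, "sensitivity": f.metrics.sensitivity,
             "mcc": f.metrics.mcc, "auc": f.auc}
            for i, f in enumerate(self.folds)
        ]
        return pd.DataFrame(rows).set_index("fold")

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_fold.std(ddof=1)

    def roc_points(self) -> list[np.ndarray]:
        return [f.roc for f in self.folds]

    def summary(self) -> str:
        df = self.per_fold
        lines = [
            "Cross-validation report "
            f"(K={self.config.n_subsets}, L={self.config.n_trees}, seed={self.seed})",
            "fold    ACC(%)   PR(%)    Sen(%)   MCC(%)   AUC",
        ]
        for fold, row in df.iterrows():
            lines.append(
                f"{fold:>4}    {row.accuracy * 100:6.2f}   {row.precision * 100:6.2f}   "
                f"{row.sensitivity * 100:6.2f}   {row.mcc * 100:6.2f}   {row.auc:.4f}"
            )
        m, s = self.mean, self.sd
        lines.append(
            f"mean    {m.accuracy * 100:6.2f}   {m.precision * 100:6.2f}   "
            f"{m.sensitivity * 100:6.2f}   {m.mcc * 100:6.2f}   {m.auc:.4f}"
        )
        lines.append(
            f"sd      {s.accuracy * 100:6.2f}   {s.precision * 100:6.2f}   "
            f"{s.sensitivity * 100:6.2f}   {s.mcc * 100:6.2f}   {s.auc:.4f}"
        )
        return "\n".join(lines)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


def cross_validate(dataset: LabeledDataset, config: RoFConfig | None = None,
                   folds: int = 5, seed: int = 0) -> EvalReport:
    """Stratified k-fold evaluation of the Rotation Forest pipeline.

    The dataset is split into ``folds`` stratified parts; each part in
    turn is held out while the classifier trains on the rest.  Member
    seeds derive deterministically from ``seed`` and the fold number.
    """
    config = config or RoFConfig()
    y = dataset.y
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"{folds}-fold split impossible: minority class has {counts.min()} rows"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    results: list[FoldResult] = []
    for fold_no, (train_idx, test_idx) in enumerate(splitter.split(dataset.X, y)):
        fold_cfg = RoFConfig(
            n_subsets=config.n_subsets, n_trees=config.n_trees,
            class_subset_prob=config.class_subset_prob,
            bootstrap_frac=config.bootstrap_frac,
            seed=int(np.random.SeedSequence([seed, fold_no]).generate_state(1)[0] % (2 ** 31)),
        )
        model = RotationForestClassifier(fold_cfg)
        model.fit(dataset.X[train_idx], y[train_idx])
        y_pred = model.predict(dataset.X[test_idx])
        scores = model.decision_scores(dataset.X[test_idx])
        tp, fp, tn, fn = _confusion(y[test_idx], y_pred)
        auc, roc = roc_auc(scores, y[test_idx])
        results.append(FoldResult(compute_metrics(tp, fp, tn, fn), auc, roc,
                                  (tp, fp, tn, fn)))
    return EvalReport(folds=results, seed=seed, config=config)


def negative_resample_study(s: InteractionSet,
                            fingerprints: dict[str, DrugFingerprint],
                            features: dict[str, ProteinFeatures],
                            config: RoFConfig | None = None,
                            n_resamples: int = 5, ratio: float = 1.0,
                            folds: int = 5, seed: int = 0
                            ) -> tuple[pd.DataFrame, list[EvalReport]]:
    """Repeat negative sampling + cross-validation to probe robustness.

    Returns a table with one mean +/- sd row per negative draw, and the
    underlying reports.
    """
    rows = []
    reports = []
    for r in range(n_resamples):
        neg_seed = int(np.random.SeedSequence([seed, 7, r]).generate_state(1)[0] % (2 ** 31))
        ds = build_dataset(s, fingerprints, features, ratio=ratio, seed=neg_seed)
        rep = cross_validate(ds, config, folds=folds, seed=seed)
        reports.append(rep)
        row = {"resample": r + 1}
        for c in _METRIC_COLS:
            row[f"{c}_mean"] = rep.mean[c]
            row[f"{c}_sd"] = rep.sd[c]
        rows.append(row)
    return pd.DataFrame(rows).set_index("resample"), reports


def grid_search(dataset: LabeledDataset, k_values, l_values,
                folds: int = 5, seed: int = 0) -> pd.DataFrame:
    """Mean CV accuracy over a (K, L) grid — the tuning surface."""
    records = []
    for k in k_values:
        for l in l_values:
            rep = cross_validate(dataset, RoFConfig(n_subsets=k, n_trees=l),
                                 folds=folds, seed=seed)
            records.append({"K": k, "L": l, "accuracy": rep.mean["accuracy"],
                            "auc": rep.mean["auc"]})
    return pd.DataFrame(records)
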