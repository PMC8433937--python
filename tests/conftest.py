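"""Shared fixtures: the default planted-signal world and its CV reports.

The expensive end-to-end artefacts (feature tables, cross-validation
reports) are session-scoped so the evaluation of the full pipeline runs
once and is inspected by several tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import dtcwt_dti as dd

WORLD_SEED = 0          # SimConfig default
DATASET_SEED = 1        # negative draw + fold assignment


@pytest.fixture(scope="session")
def world():
    cfg = dd.SimConfig()
    interactions, fingerprints, pssms, truth = dd.gen_dti_world(cfg)
    return {"config": cfg, "interactions": interactions,
            "fingerprints": fingerprints, "pssms": pssms, "truth": truth}


@pytest.fixture(scope="session")
def world_features(world):
    return dd.extract_feature_table(world["pssms"])


@pytest.fixture(scope="session")
def planted_dataset(world, world_features):
    return dd.build_dataset(world["interactions"], world["fingerprints"],
                            world_features, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def planted_cv_report(planted_dataset):
    return dd.cross_validate(planted_dataset, dd.RoFConfig(), folds=5,
                             seed=DATASET_SEED)


@pytest.fixture(scope="session")
def null_cv_report():
    cfg = dd.SimConfig(signal_strength=0.0, seed=2)
    interactions, fingerprints, pssms, _ = dd.gen_dti_world(cfg)
    features = dd.extract_feature_table(pssms)
    dataset = dd.build_dataset(interactions, fingerprints, features, seed=3)
    return dd.cross_validate(dataset, dd.RoFConfig(), folds=5, seed=2)


@pytest.fixture(scope="session")
def permuted_cv_report(planted_dataset):
    rng = np.random.default_rng(99)
    shuffled = dd.LabeledDataset(
        pairs=planted_dataset.pairs,
        X=planted_dataset.X,
        y=rng.permutation(planted_dataset.y),
        provenance={"permuted": True},
    )
    return dd.cross_validate(shuffled, dd.RoFConfig(), folds=5, seed=4)


@pytest.fixture(scope="session")
def planted_subset(planted_dataset):
    """Class-mixed random subsets of the planted dataset (rows are stored
    positives-first, so plain slices would be single-class)."""
    def take(n: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(planted_dataset))[:n]
        return planted_dataset.X[idx], planted_dataset.y[idx]
    return take


@pytest.fixture(scope="session")
def small_rof_config():
    """Cheap ensemble for determinism/equality checks."""
    return dd.RoFConfig(n_subsets=5, n_trees=3, seed=11)
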