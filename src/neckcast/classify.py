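"""Random-Forest training and the two validation designs.

Two questions are answered with the same classifier. Leave-one-burst-out
(LOO) on one individual's balanced table shows how separable the behaviors
are when the model has seen the same animal: each of the N rows is
predicted once by a forest trained on the other N-1. Leave-one-individual-
out (cross-individual) validation withholds an entire animal and is the
deployment-relevant test: it exposes attachment/posture differences the
calibration step is meant to absorb.

Forest hyperparameters default to the classic R randomForest settings:
500 trees, sqrt(p) candidate features per split, unlimited depth. Fold i
of LOO is seeded with base_seed + i so the prediction multiset is
reproducible and invariant to row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

FEATURE_META_COLUMNS = ("individual", "burst_id", "label")

#: prediction emitted for test categories absent from training
UNTRAINABLE = "UNTRAINABLE"


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 500
    features_per_split: str | int = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def _split(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    feats = [c for c in table.columns if c not in FEATURE_META_COLUMNS]
    return table[feats], table["label"]


def train_rf(
    features: pd.DataFrame, labels: Sequence[str], config: RFConfig
) -> RandomForestClassifier:
    """Fit the plurality-vote tree ensemble; deterministic under the seed."""
    labels = pd.Series(list(labels))
    if labels.nunique() < 2:
        raise ValueError("training requires at least 2 classes")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.features_per_split,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(np.asarray(features, dtype=float), labels)
    return model


def leave_one_out(table: pd.DataFrame, config: RFConfig) -> pd.DataFrame:
    """N-fold leave-one-burst-out over a feature table.

    Returns a PredictionSet frame (individual, burst_id, true, predicted,
    design) with exactly one row per input row. Fold i trains on every row
    but i with seed ``config.seed + i``; the held-out row's features never
    enter training.
    """
    if len(table) < 2:
        raise ValueError("leave-one-out needs at least 2 bursts")
    X, y = _split(table)
    X = np.asarray(X, dtype=float)
    records = []
    for i in range(len(table)):
        mask = np.ones(len(table), dtype=bool)
        mask[i] = False
        fold_config = RFConfig(
            n_trees=config.n_trees,
            features_per_split=config.features_per_split,
            seed=config.seed + i,
        )
        model = RandomForestClassifier(
            n_estimators=fold_config.n_trees,
            max_features=fold_config.features_per_split,
            random_state=fold_config.seed,
            n_jobs=1,
        )
        model.fit(X[mask], y[mask])
        pred = model.predict(X[~mask])[0]
        records.append(
            {
                "individual": table["individual"].iloc[i],
                "burst_id": table["burst_id"].iloc[i],
                "true": y.iloc[i],
                "predicted": pred,
                "design": "loo",
            }
        )
    return pd.DataFrame(records)


def cross_individual(
    table: pd.DataFrame, test_individual: str, config: RFConfig
) -> pd.DataFrame:
    """Train on all other individuals, predict every test-individual row.

    Test categories unseen in training can never be predicted correctly;
    they are kept in the output (their rows get the model's best guess)
    and reported via the ``untrainable`` attribute on the returned frame.
    """
    test = table[table["individual"] == test_individual]
    train = table[table["individual"] != test_individual]
    if test.empty:
        raise ValueError(f"no rows for test individual {test_individual!r}")
    if train.empty:
        raise ValueError("need at least one training individual")
    train_labels = set(train["label"])
    test_labels = set(test["label"])
    if not (train_labels & test_labels):
        raise ValueError("training and test label sets do not overlap")
    untrainable = sorted(test_labels - train_labels)

    X_train, y_train = _split(train)
    model = train_rf(X_train, y_train, config)
    X_test, y_test = _split(test)
    preds = model.predict(np.asarray(X_test, dtype=float))
    out = pd.DataFrame(
        {
            "individual": test["individual"].to_numpy(),
            "burst_id": test["burst_id"].to_numpy(),
            "true": y_test.to_numpy(),
            "predicted": preds,
            "design": "cross_individual",
        }
    )
    out.attrs["untrainable"] = untrainable
    return out
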