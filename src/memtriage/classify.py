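"""K-nearest-neighbor classification of mutations from triage features.

Features are (rSASA, EC, PD), optionally extended with stability-change
annotations (ddG mean/SD) that external predictors supply; the ddG columns
are carried through but excluded from the default feature set.  Distances
are Euclidean in z-score-standardized feature space (standardization fit
on the training set; can be disabled).  Majority vote with a deterministic
tie break: the single nearest neighbor wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

LABELS = ("pathogenic", "non_pathogenic")
DEFAULT_FEATURES = ("rsasa", "ec", "pd")
ALL_FEATURES = ("rsasa", "ec", "pd", "ddg_mean", "ddg_sd")


@dataclass
class FeatureVector:
    mutation_id: str
    rsasa: float
    ec: float
    pd: float
    label: str = "unknown"
    ddg_mean: Optional[float] = None
    ddg_sd: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("rsasa", "ec", "pd"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} not finite for {self.mutation_id}")
        if self.label not in (*LABELS, "unknown"):
            raise ValueError(f"invalid label {self.label!r} for {self.mutation_id}")


def feature_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mutation_id": v.mutation_id, "rsasa": v.rsasa, "ec": v.ec, "pd": v.pd,
        "ddg_mean": v.ddg_mean, "ddg_sd": v.ddg_sd, "label": v.label,
    } for v in vectors])


def read_feature_table(path) -> List[FeatureVector]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(FeatureVector(
            mutation_id=str(row["mutation_id"]),
            rsasa=float(row["rsasa"]), ec=float(row["ec"]), pd=float(row["pd"]),
            label=str(row["label"]) if "label" in df.columns and not pd.isna(row["label"]) else "unknown",
            ddg_mean=float(row["ddg_mean"]) if "ddg_mean" in df.columns and not pd.isna(row["ddg_mean"]) else None,
            ddg_sd=float(row["ddg_sd"]) if "ddg_sd" in df.columns and not pd.isna(row["ddg_sd"]) else None,
        ))
    return out


def partition(dataset: Sequence[FeatureVector], train_n: int,
              seed: int) -> Tuple[List[FeatureVector], List[FeatureVector]]:
    """Random disjoint/exhaustive train-test split of the labelled rows."""
    labelled = [v for v in dataset if v.label != "unknown"]
    if not 0 < train_n < len(labelled):
        raise ValueError(f"train_n={train_n} invalid for {len(labelled)} labelled rows")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labelled))
    train = [labelled[i] for i in sorted(order[:train_n])]
    test = [labelled[i] for i in sorted(order[train_n:])]
    return train, test


def _matrix(vectors: Sequence[FeatureVector],
            feature_set: Sequence[str]) -> np.ndarray:
    cols = []
    for name in feature_set:
        if name not in ALL_FEATURES:
            raise ValueError(f"unknown feature {name!r}")
        col = [getattr(v, name) for v in vectors]
        if any(c is None for c in col):
            raise ValueError(f"feature {name!r} missing for some rows")
        cols.append(col)
    return np.asarray(cols, dtype=float).T


class KnnModel:
    """Plain KNN with train-set z-scoring and nearest-neighbor tie break."""

    def __init__(self, train: Sequence[FeatureVector], k: int,
                 feature_set: Sequence[str] = DEFAULT_FEATURES,
                 standardize: bool = True):
        if k < 1 or k > len(train):
            raise ValueError(f"k={k} out of range for {len(train)} training points")
        self.train = list(train)
        self.k = k
        self.feature_set = tuple(feature_set)
        self.standardize = standardize
        x = _matrix(self.train, self.feature_set)
        if standardize:
            self.mean_ = x.mean(axis=0)
            sd = x.std(axis=0, ddof=0)
            self.sd_ = np.where(sd > 0, sd, 1.0)  # constant feature -> no-op
        else:
            self.mean_ = np.zeros(x.shape[1])
            self.sd_ = np.ones(x.shape[1])
        self.x_ = (x - self.mean_) / self.sd_
        self.labels_ = [v.label for v in self.train]

    def predict_one(self, query: FeatureVector) -> Tuple[str, Dict[str, int]]:
        q = (_matrix([query], self.feature_set)[0] - self.mean_) / self.sd_
        d = np.sqrt(((self.x_ - q) ** 2).sum(axis=1))
        # stable order so equal distances resolve deterministically
        order = np.argsort(d, kind="stable")[: self.k]
        votes = Counter(self.labels_[i] for i in order)
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            label = self.labels_[order[0]]  # tie -> single nearest neighbor
        else:
            label = top[0][0]
        return label, dict(votes)


def knn_predict(train: Sequence[FeatureVector], query: FeatureVector, k: int,
                feature_set: Sequence[str] = DEFAULT_FEATURES,
                standardize: bool = True) -> Tuple[str, Dict[str, int]]:
    """Predicted label and neighbor vote counts for one query point."""
    return KnnModel(train, k, feature_set, standardize).predict_one(query)


def accuracy(model: KnnModel, test: Sequence[FeatureVector]) -> float:
    hits = sum(model.predict_one(v)[0] == v.label for v in test)
    return hits / len(test)


def k_sweep(train: Sequence[FeatureVector], test: Sequence[FeatureVector],
            k_values: Sequence[int],
            feature_set: Sequence[str] = DEFAULT_FEATURES,
            standardize: bool = True) -> Tuple[pd.DataFrame, int]:
    """Accuracy per k plus the recommended k.

    The recommendation is the median of the set of k values achieving the
    best accuracy (lower-middle element when that set has even size, so the
    recommendation is always an actually-swept value).
    """
    rows = []
    for k in k_values:
        model = KnnModel(train, k, feature_set, standardize)
        rows.append({"k": k, "accuracy": accuracy(model, test)})
    table = pd.DataFrame(rows)
    best = table["accuracy"].max()
    argmax = sorted(table.loc[table["accuracy"] == best, "k"])
    recommended = int(argmax[(len(argmax) - 1) // 2])
    return table, recommended


def classify_unknowns(labelled: Sequence[FeatureVector],
                      unknowns: Sequence[FeatureVector], k: int,
                      feature_set: Sequence[str] = DEFAULT_FEATURES,
                      standardize: bool = True,
                      external: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Predict every unknown-effect mutation; one report row per query.

    ``external`` optionally maps mutation_id to a pass-through annotation
    from an outside predictor, reported alongside for comparison.
    """
    if not unknowns:
        return pd.DataFrame(
            columns=["mutation_id", "predicted", "votes_pathogenic",
                     "votes_non_pathogenic", "vote_margin", "external"])
    model = KnnModel(labelled, k, feature_set, standardize)
    rows = []
    for v in unknowns:
        label, votes = model.predict_one(v)
        vp = votes.get("pathogenic", 0)
        vn = votes.get("non_pathogenic", 0)
        rows.append({
            "mutation_id": v.mutation_id,
            "predicted": label,
            "votes_pathogenic": vp,
            "votes_non_pathogenic": vn,
            "vote_margin": abs(vp - vn),
            "external": (external or {}).get(v.mutation_id, ""),
        })
    return pd.DataFrame(rows)
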