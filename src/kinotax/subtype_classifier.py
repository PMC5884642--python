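"""SVM classification of kinome profiles into breast-cancer subtype groups.

Cell-line profiles restricted to the distinguishing kinase set train a linear
soft-margin SVM; unseen (tumor) profiles are classified into TNBC,
HER2+/Luminal or "other".  Tumor biopsies routinely miss a third to a half of
the feature kinases, so missing features are filled with the training-set
per-feature mean and the prediction records how many were imputed.  A profile
whose best decision value stays below the threshold tau is labelled "other".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .exceptions import ParameterError
from .io_filter import NormalizedMatrix, SampleMeta
from .taxonomy import DistinguishingSet

#: Collapse of expression subtypes onto the two clinically used groups.
BINARY_GROUP_OF = {
    "basal-like": "TNBC",
    "claudin-low": "TNBC",
    "HER2-enriched": "HER2+/Luminal",
    "luminal": "HER2+/Luminal",
}

OTHER_LABEL = "other"
MISSING_WARN_FRAC = 0.60


@dataclass
class ClassifierModel:
    """Linear SVM with per-class weight vectors and an "other" threshold.

    Binary problems store one (weights, bias) pair for the lexicographically
    later class (positive decision value -> that class); multi-class problems
    store one one-vs-rest pair per class.  ``feature_means`` are the training
    per-feature means used for imputation.
    """

    features: list[str]
    classes: list[str]
    weights: np.ndarray  # (n_classes_stored, n_features)
    bias: np.ndarray
    tau: float
    feature_means: pd.Series
    C: float = 1.0

    def decision_values(self, x: np.ndarray) -> dict[str, float]:
        """Per-class decision value for one complete feature vector."""
        raw = self.weights @ x + self.bias
        if len(self.classes) == 2:
            return {self.classes[1]: float(raw[0]), self.classes[0]: float(-raw[0])}
        return {c: float(v) for c, v in zip(self.classes, raw)}

    def to_json(self, path) -> None:
        blob = {
            "features": self.features,
            "classes": self.classes,
            "weights": self.weights.tolist(),
            "bias": self.bias.tolist(),
            "tau": self.tau,
            "feature_means": self.feature_means.tolist(),
            "C": self.C,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            blob = json.load(fh)
        return cls(
            features=blob["features"],
            classes=blob["classes"],
            weights=np.asarray(blob["weights"]),
            bias=np.asarray(blob["bias"]),
            tau=blob["tau"],
            feature_means=pd.Series(blob["feature_means"], index=blob["features"]),
            C=blob["C"],
        )


@dataclass
class Prediction:
    label: str
    decision_values: dict[str, float]
    n_missing_features: int
    high_missing_warning: bool = False


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _training_matrix(
    n: NormalizedMatrix, features: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature-restricted sample matrix with per-feature mean imputation."""
    missing = [f for f in features if f not in n.values.index]
    if missing:
        raise ParameterError(f"features absent from matrix: {missing[:5]}")
    X = n.values.loc[features].T  # samples x features
    means = X.mean(axis=0).fillna(0.0)
    X = X.fillna(means)
    return X, means


def class_labels(meta: SampleMeta, samples: list[str], binary: bool = True) -> pd.Series:
    """Map sample subtypes onto classifier target labels."""
    subtype = meta.loc[samples, "subtype"]
    if not binary:
        return subtype
    unknown = sorted(set(subtype) - set(BINARY_GROUP_OF))
    if unknown:
        raise ParameterError(f"subtypes without a binary group: {unknown}")
    return subtype.map(BINARY_GROUP_OF)


def train_svm(
    n: NormalizedMatrix,
    meta: SampleMeta,
    features: DistinguishingSet | list[str],
    binary: bool = True,
    C: float = 1.0,
    tau: float = 0.0,
) -> ClassifierModel:
    """Train a linear soft-margin SVM on feature-restricted profiles.

    Deterministic given the input order.  ``binary`` collapses subtypes onto
    TNBC vs HER2+/Luminal (the default task); the four-subtype mode trains
    one one-vs-rest machine per class.
    """
    feats = features.kinases if isinstance(features, DistinguishingSet) else list(features)
    if not feats:
        raise ParameterError("empty feature list")
    X, means = _training_matrix(n, feats)
    y = class_labels(meta, list(X.index), binary=binary)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ParameterError("training set has a single class")
    counts = y.value_counts()
    if (counts < 2).any():
        raise ParameterError("every class needs >= 2 training samples")

    if len(classes) == 2:
        svc = SVC(kernel="linear", C=C)
        svc.fit(X.to_numpy(), (y == classes[1]).astype(int).to_numpy())
        W = np.asarray(svc.coef_, dtype=float)
        b = np.asarray(svc.intercept_, dtype=float)
    else:
        rows, biases = [], []
        for c in classes:
            svc = SVC(kernel="linear", C=C)
            svc.fit(X.to_numpy(), (y == c).astype(int).to_numpy())
            rows.append(svc.coef_[0])
            biases.append(svc.intercept_[0])
        W = np.asarray(rows, dtype=float)
        b = np.asarray(biases, dtype=float)
    return ClassifierModel(
        features=feats, classes=classes, weights=W, bias=b, tau=tau,
        feature_means=means, C=C,
    )


# ---------------------------------------------------------------------------
# Imputation + classification
# ---------------------------------------------------------------------------


def impute_missing(
    profile: pd.Series, model: ClassifierModel
) -> tuple[np.ndarray, int, bool]:
    """Complete a query profile over the model's feature list.

    Features absent from the profile (or NaN) are filled with the training
    per-feature mean.  Returns (vector, n_missing, warning flag set when more
    than 60% of the features had to be imputed).
    """
    vec = profile.reindex(model.features)
    missing = vec.isna()
    vec = vec.fillna(model.feature_means)
    n_missing = int(missing.sum())
    warn = n_missing > MISSING_WARN_FRAC * len(model.features)
    return vec.to_numpy(dtype=float), n_missing, warn


def classify(model: ClassifierModel, profile: pd.Series) -> Prediction:
    """Classify one profile; label is "other" when max decision value < tau."""
    x, n_missing, warn = impute_missing(profile, model)
    dv = model.decision_values(x)
    best = max(dv, key=dv.get)
    label = best if dv[best] >= model.tau else OTHER_LABEL
    return Prediction(label, dv, n_missing, warn)


def feature_ablation(
    n: NormalizedMatrix,
    meta: SampleMeta,
    features: DistinguishingSet | list[str],
    queries: pd.DataFrame,
    exclude: set[str],
    binary: bool = True,
    C: float = 1.0,
    tau: float = 0.0,
) -> list[Prediction]:
    """Retrain without ``exclude`` and classify the query profiles.

    ``queries``: kinase-by-query DataFrame of autoscaled profiles.  Used to
    check that no single marker (e.g. ERBB2) carries the classification.
    """
    feats = features.kinases if isinstance(features, DistinguishingSet) else list(features)
    bad = set(exclude) - set(feats)
    if bad:
        raise ParameterError(f"excluded kinases not in feature list: {sorted(bad)[:5]}")
    kept = [f for f in feats if f not in exclude]
    if not kept:
        raise ParameterError("exclusion empties the feature list")
    model = train_svm(n, meta, kept, binary=binary, C=C, tau=tau)
    return [classify(model, queries[q]) for q in queries.columns]


def loo_evaluate(
    n: NormalizedMatrix,
    meta: SampleMeta,
    features: DistinguishingSet | list[str],
    binary: bool = True,
    C: float = 1.0,
) -> pd.DataFrame:
    """Leave-one-out confusion counts per class.

    Returns a confusion DataFrame (true class x predicted label) including an
    "other" column; tau is fixed at -inf here so every held-out sample gets a
    group call and accuracy is read off the diagonal.
    """
    feats = features.kinases if isinstance(features, DistinguishingSet) else list(features)
    samples = n.samples
    y = class_labels(meta, samples, binary=binary)
    classes = sorted(y.unique())
    counts = y.value_counts()
    if (counts < 3).any():
        raise ParameterError("leave-one-out needs >= 3 samples per class")
    conf = pd.DataFrame(0, index=classes, columns=classes + [OTHER_LABEL])
    for s in samples:
        rest = [t for t in samples if t != s]
        sub = NormalizedMatrix(n.values[rest])
        model = train_svm(sub, meta, feats, binary=binary, C=C, tau=-np.inf)
        pred = classify(model, n.values[s])
        conf.loc[y[s], pred.label] += 1
    return conf


def loo_accuracy(conf: pd.DataFrame) -> float:
    """Overall accuracy from a confusion table."""
    correct = sum(conf.loc[c, c] for c in conf.index if c in conf.columns)
    return float(correct / conf.to_numpy().sum())
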