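"""Face-to-DNA classifiers: one two-class classifier per molecular feature.

Continuous DNA-encoded or DNA-inferred aspects are binarized at a
threshold T (age at 30 years, BMI at the training-set median, genomic
background PCs at zero; sex is already two-class with +1 female / -1
male).  Peak-SNP genotypes (additive 0/1/2 with the minor allele counted)
are recoded into two binary variables: a dominant coding (AA=0; Aa,aa=1)
and a recessive coding (AA,Aa=0; aa=1); missing genotypes join the
homozygous-major class.

Each deployed classifier consumes the concatenated PC scores of the facial
segments whose association p-value with the feature passed the selection
threshold, and outputs a calibrated posterior for each class.  Matching a
face against a probe DNA profile then reads off the posterior of the
probe's class per feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.calibration import CalibratedClassifierCV

from facedna._rng import subseed

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularFeature",
    "BinaryFeature",
    "TrainedFaceClassifier",
    "binarize_feature",
    "encode_snp_models",
    "orient_minor_allele",
    "select_segments",
    "train_classifier",
    "match_scores",
]


@dataclass
class MolecularFeature:
    """One DNA-encoded or DNA-inferred aspect of the cohort."""

    name: str
    kind: str  # binary | continuous | genotype
    values: np.ndarray
    provenance: str  # sex | genomic_pc | snp | age | bmi
    threshold: float | None = None
    inheritance_model: str = "none"  # none | dominant | recessive

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.kind not in ("binary", "continuous", "genotype"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "genotype":
            finite = self.values[np.isfinite(self.values)]
            if not np.all(np.isin(finite, [0.0, 1.0, 2.0])):
                raise ValueError("genotype values must be 0/1/2 or missing")


@dataclass
class BinaryFeature:
    """Two-class labels derived from a molecular feature."""

    name: str
    labels: np.ndarray  # {0, 1}
    source: MolecularFeature | None = None
    threshold_used: float | None = None
    inheritance_model: str = "none"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if not np.all(np.isin(self.labels, [0, 1])):
            raise ValueError("labels must be 0/1")

    @property
    def degenerate(self) -> bool:
        return len(np.unique(self.labels)) < 2


def binarize_feature(
    feature: MolecularFeature, threshold: float | None = None
) -> BinaryFeature | None:
    """Binarize a continuous or sex feature at threshold T.

    Sex maps +1 (female) to class 1 and -1 (male) to class 0.  Continuous
    values map to class 1 when strictly greater than T (a value exactly at
    T falls in the lower class).  Default thresholds: 30 years for age, the
    training median for BMI, zero for genomic background PCs.  A degenerate
    (single-class) result is dropped with a warning.
    """
    v = feature.values
    if feature.provenance == "sex":
        labels = (v > 0).astype(int)
        t = 0.0
    else:
        if threshold is None:
            threshold = feature.threshold
        if threshold is None:
            if feature.provenance == "age":
                threshold = 30.0
            elif feature.provenance == "bmi":
                threshold = float(np.median(v))
            elif feature.provenance == "genomic_pc":
                threshold = 0.0
            else:
                raise ValueError(f"no threshold for feature {feature.name!r}")
        t = float(threshold)
        labels = (v > t).astype(int)
    bf = BinaryFeature(
        name=feature.name, labels=labels, source=feature, threshold_used=t
    )
    if bf.degenerate:
        warnings.warn(f"feature {feature.name!r} is single-class after binarization")
        return None
    return bf


def orient_minor_allele(dosages: np.ndarray) -> tuple[np.ndarray, bool]:
    """Flip dosages so they count the cohort's minor allele.

    Returns the (possibly flipped) dosages and whether a flip occurred.
    """
    g = np.asarray(dosages, float)
    af = np.nanmean(g) / 2.0
    if af > 0.5:
        return 2.0 - g, True
    return g, False


def encode_snp_models(
    feature: MolecularFeature, orient: bool = True
) -> tuple[BinaryFeature, BinaryFeature]:
    """Dominant and recessive two-class codings of a SNP genotype.

    Dominant: AA=0, Aa=1, aa=1; recessive: AA=0, Aa=0, aa=1 (A major, a
    minor).  Missing genotypes are assigned to the homozygous-major class
    (label 0 under both codings).
    """
    g = feature.values
    if orient:
        g, flipped = orient_minor_allele(g)
        if flipped:
            logger.info("SNP %s dosages flipped to count the minor allele", feature.name)
    g = np.nan_to_num(g, nan=0.0)
    dom = BinaryFeature(
        name=f"{feature.name}:D", labels=(g >= 1).astype(int), source=feature,
        inheritance_model="dominant",
    )
    rec = BinaryFeature(
        name=f"{feature.name}:R", labels=(g >= 2).astype(int), source=feature,
        inheritance_model="recessive",
    )
    return dom, rec


def select_segments(
    assoc: pd.DataFrame, feature_name: str, p_max: float
) -> list[int]:
    """Facial segments whose association p-value passes ``p <= p_max``.

    ``assoc`` is a long table with columns feature, segment, p.  The
    returned ids follow the hierarchical tree ordering (global segment
    index).  An empty list means the classifier is not deployed.
    """
    rows = assoc[assoc["feature"] == feature_name]
    hits = rows[rows["p"] <= p_max]
    return sorted(int(s) for s in hits["segment"].unique())


# --------------------------------------------------------------------------
# classifier training


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """RBF kernel scale from the median pairwise Euclidean distance."""
    n = len(X)
    if n > 500:
        idx = rng.choice(n, 500, replace=False)
        X = X[idx]
    d = np.sqrt(
        np.maximum(
            np.sum(X**2, 1)[:, None] + np.sum(X**2, 1)[None, :] - 2 * X @ X.T, 0.0
        )
    )
    med = np.median(d[np.triu_indices_from(d, k=1)])
    if not np.isfinite(med) or med <= 0:
        return 1.0
    return 1.0 / (2.0 * med**2)


@dataclass
class TrainedFaceClassifier:
    """A calibrated two-class face classifier for one molecular feature."""

    feature_name: str
    segments: list[int]
    model: object = field(repr=False)
    inheritance_model: str = "none"
    training_balanced_accuracy: float | None = None

    def posterior_class1(self, X: np.ndarray) -> np.ndarray:
        """Calibrated P(class 1 | face); P(class 0) is its complement."""
        proba = self.model.predict_proba(np.asarray(X, float))
        cls = list(self.model.classes_)
        return proba[:, cls.index(1)]


def train_classifier(
    features: np.ndarray,
    labels: BinaryFeature,
    seed: int = 0,
    kind: str = "svm",
    segments: list[int] | None = None,
) -> TrainedFaceClassifier:
    """Train a calibrated two-class classifier on concatenated PC scores.

    The default is a Gaussian-kernel max-margin separator (RBF SVM) with
    class weights inversely proportional to class frequencies and the
    kernel scale set by the median pairwise-distance heuristic; posteriors
    come from a sigmoid (Platt-style) calibration fitted by internal
    5-fold cross-validation.  ``kind`` may also be ``linear`` (logistic
    regression) or ``tree``.
    """
    X = np.asarray(features, float)
    y = labels.labels
    if len(np.unique(y)) < 2:
        raise ValueError("single-class labels")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 5:
        raise ValueError("each class needs at least 5 training instances")
    rng = np.random.default_rng(subseed(seed, f"clf-{labels.name}"))
    rs = subseed(seed, f"clf-state-{labels.name}")
    if kind == "svm":
        gamma = _median_heuristic_gamma(X, rng)
        base = SVC(
            kernel="rbf", gamma=gamma, class_weight="balanced", random_state=rs
        )
        model = CalibratedClassifierCV(base, method="sigmoid", cv=5, ensemble=False)
        model.fit(X, y)
    elif kind == "linear":
        base = LogisticRegression(class_weight="balanced", max_iter=1000)
        model = CalibratedClassifierCV(base, method="sigmoid", cv=5)
        model.fit(X, y)
    elif kind == "tree":
        base = DecisionTreeClassifier(class_weight="balanced", random_state=rs)
        model = CalibratedClassifierCV(base, method="sigmoid", cv=5)
        model.fit(X, y)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    pred = model.predict(X)
    per_class = [np.mean(pred[y == k] == k) for k in (0, 1)]
    return TrainedFaceClassifier(
        feature_name=labels.name,
        segments=list(segments or []),
        model=model,
        inheritance_model=labels.inheritance_model,
        training_balanced_accuracy=float(np.mean(per_class)),
    )


def match_scores(
    posteriors_class1: dict[str, np.ndarray],
    probe_labels: dict[str, int],
    feature_order: list[str],
) -> np.ndarray:
    """Per-face matching-score vectors against one probe DNA profile.

    ``posteriors_class1[f]`` holds P(class 1 | face) for every gallery
    face under feature ``f``'s classifier; the matching score is the
    posterior of the probe's class (its complement for class 0).  A feature
    absent from the probe profile scores an uninformative 0.5.
    """
    n = len(next(iter(posteriors_class1.values())))
    out = np.empty((n, len(feature_order)))
    for j, name in enumerate(feature_order):
        p1 = posteriors_class1[name]
        if name not in probe_labels:
            warnings.warn(f"probe profile missing feature {name!r}; scoring 0.5")
            out[:, j] = 0.5
            continue
        out[:, j] = p1 if int(probe_labels[name]) == 1 else 1.0 - p1
    return out
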