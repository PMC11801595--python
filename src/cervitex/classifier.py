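"""Divergence-weighted naive-Bayes-style classification of texture features.

Training discretizes each of the 40 texture features into R equal-frequency
bins, estimates Laplace-smoothed class-conditional bin distributions, and
scores the class separability of every feature by one of three divergences
between class-conditional distributions:

* ``jsd`` — a per-bin Bernoulli Kullback-Leibler sum
  D(t,u) = sum_k [ P_t log(P_t/P_u) + (1-P_t) log((1-P_t)/(1-P_u)) ],
  symmetrized as (D(t,u)+D(u,t))/2.  ``form='standard'`` gives the textbook
  Jensen-Shannon divergence with mixture m = (t+u)/2 instead.
* ``hd`` — the squared-difference sum sum_k (P_t - P_u)^2
  (``form='standard'`` gives the textbook squared Hellinger
  sum_k (sqrt(P_t) - sqrt(P_u))^2).
* ``td`` — triangular discrimination sum_k (P_t - P_u)^2 / (P_t + P_u).

The per-feature weight is the mean divergence over the three unordered class
pairs, divided by the pooled marginal bin entropy of the feature, and the
weight vector is normalized to unit sum.  Classification is the weighted
naive-Bayes product rule in log domain:

    score(c) = log P(c) + sum_i W(i) log P(bin(a_i) | c),

predicting the arg-max class with ties broken in the fixed label order
normal < benign < malign.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cervitex.image_io import LABELS
from cervitex.texture import FeatureMatrix

logger = logging.getLogger(__name__)

DIVERGENCES = ("jsd", "hd", "td")

_EPS = 1e-12


class DegenerateWeightsError(ValueError):
    """Raised when every feature has zero divergence weight."""


def _check_pair(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError(f"distributions must be 1-D of equal length, "
                         f"got {p.shape} vs {q.shape}")
    return p, q


def _bernoulli_kl_sum(p: np.ndarray, q: np.ndarray) -> float:
    """sum_k p log(p/q) + (1-p) log((1-p)/(1-q)), with 0 log 0 := 0."""
    q = np.clip(q, _EPS, 1 - _EPS)
    pc = np.clip(p, 0.0, 1.0)
    t1 = np.where(pc > 0, pc * np.log(np.maximum(pc, _EPS) / q), 0.0)
    t2 = np.where(pc < 1, (1 - pc) * np.log(np.maximum(1 - pc, _EPS) / (1 - q)), 0.0)
    return float(np.sum(t1 + t2))


def jsd(p: np.ndarray, q: np.ndarray, form: str = "printed") -> float:
    """Jensen-Shannon-style divergence between two binned distributions.

    ``form='printed'`` (default) is the symmetrized per-bin Bernoulli-KL sum;
    ``form='standard'`` the textbook JSD with mixture m = (p+q)/2.  Natural
    logarithm; zero iff the distributions are equal.
    """
    p, q = _check_pair(p, q)
    if form == "printed":
        return 0.5 * (_bernoulli_kl_sum(p, q) + _bernoulli_kl_sum(q, p))
    if form == "standard":
        m = 0.5 * (p + q)
        def kl(a, b):
            mask = a > 0
            return float(np.sum(a[mask] * np.log(a[mask] / np.maximum(b[mask], _EPS))))
        return 0.5 * kl(p, m) + 0.5 * kl(q, m)
    raise ValueError(f"unknown jsd form {form!r}")


def hd(p: np.ndarray, q: np.ndarray, form: str = "printed") -> float:
    """Hellinger-style distance: squared-difference sum by default,
    textbook squared Hellinger with ``form='standard'``."""
    p, q = _check_pair(p, q)
    if form == "printed":
        return float(np.sum((p - q) ** 2))
    if form == "standard":
        return float(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))
    raise ValueError(f"unknown hd form {form!r}")


def td(p: np.ndarray, q: np.ndarray) -> float:
    """Triangular discrimination; bins with p + q = 0 contribute 0."""
    p, q = _check_pair(p, q)
    s = p + q
    d = (p - q) ** 2
    return float(np.sum(np.divide(d, s, out=np.zeros_like(d), where=s > 0)))


_DIV_FUNCS = {"jsd": jsd, "hd": hd, "td": td}


@dataclass
class ClassConditionalModel:
    """Binned class-conditional feature distributions with priors.

    Bin edges are interior equal-frequency cut points from the pooled
    training data (R bins); histograms are Laplace-smoothed with ``alpha``.
    ``pooled`` holds the unsmoothed pooled marginal bin proportions used for
    entropy normalization of the weights.
    """

    classes: tuple[str, ...]
    priors: np.ndarray                      # (n_classes,)
    feature_names: list[str]
    edges: list[np.ndarray]                 # per feature, interior edges
    cond_probs: np.ndarray                  # (n_classes, n_features, R) padded
    pooled: np.ndarray                      # (n_features, R) padded
    n_bins: np.ndarray                      # per-feature actual bin count
    n_train: int
    R: int
    alpha: float

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


@dataclass
class FeatureWeights:
    """Raw and entropy-normalized divergence weights for 40 features."""

    divergence_type: str
    raw: np.ndarray          # W_av(p) >= 0
    normalized: np.ndarray   # W(p) >= 0, sums to 1
    z: float                 # normalization constant


@dataclass
class TrainedClassifier:
    model: ClassConditionalModel
    weights: FeatureWeights
    family: str | None = None
    jsd_form: str = "printed"
    hd_form: str = "printed"


def bin_index(model: ClassConditionalModel, feature: int,
              values: np.ndarray) -> np.ndarray:
    """Bin feature values by the model's edges; out-of-range values clamp."""
    return np.searchsorted(model.edges[feature], values, side="right")


def fit_model(features: pd.DataFrame, feature_columns: list[str] | None = None,
              R: int = 10, alpha: float = 1.0) -> ClassConditionalModel:
    """Estimate the binned class-conditional model from a training table.

    ``features`` must carry a ``label`` column plus numeric feature columns.
    Equal-frequency bin edges come from the pooled (label-blind) training
    values of each feature; a constant feature degenerates to a single bin
    and is flagged (its divergence weight will be zero).
    """
    if "label" not in features.columns:
        raise ValueError("training table must have a 'label' column")
    for label in LABELS:
        if not (features["label"] == label).any():
            raise ValueError(f"class {label!r} missing from training data")
    if feature_columns is None:
        feature_columns = [c for c in features.columns
                           if c not in ("label", "modality", "source_id",
                                        "tile_index", "family", "split", "path")]
    X = features[feature_columns].to_numpy(dtype=np.float64)
    y = features["label"].to_numpy()
    n, n_feat = X.shape

    edges: list[np.ndarray] = []
    n_bins = np.empty(n_feat, dtype=np.int64)
    for j in range(n_feat):
        xj = X[:, j]
        qs = np.quantile(xj, np.linspace(0, 1, R + 1)[1:-1])
        e = np.unique(qs)
        e = e[(e > xj.min()) & (e < xj.max())]  # constant feature -> no edges
        if e.size == 0:
            logger.debug("feature %s is constant: single degenerate bin",
                         feature_columns[j])
        edges.append(e)
        n_bins[j] = e.size + 1

    classes = tuple(LABELS)
    priors = np.array([(y == c).mean() for c in classes])
    Rmax = int(n_bins.max())
    cond = np.zeros((len(classes), n_feat, Rmax))
    pooled = np.zeros((n_feat, Rmax))
    for j in range(n_feat):
        b = np.searchsorted(edges[j], X[:, j], side="right")
        pooled[j, :n_bins[j]] = np.bincount(b, minlength=n_bins[j]) / n
        for ci, c in enumerate(classes):
            cnt = np.bincount(b[y == c], minlength=n_bins[j]).astype(np.float64)
            cnt += alpha
            cond[ci, j, :n_bins[j]] = cnt / cnt.sum()
    return ClassConditionalModel(
        classes=classes, priors=priors, feature_names=list(feature_columns),
        edges=edges, cond_probs=cond, pooled=pooled, n_bins=n_bins,
        n_train=n, R=R, alpha=alpha)


def average_weight(model: ClassConditionalModel, p: int, divergence_type: str,
                   **div_kwargs) -> float:
    """Mean divergence of feature ``p`` over the three unordered class pairs."""
    if divergence_type not in _DIV_FUNCS:
        raise ValueError(f"unknown divergence {divergence_type!r}")
    f = _DIV_FUNCS[divergence_type]
    nb = model.n_bins[p]
    dists = [model.cond_probs[ci, p, :nb] for ci in range(len(model.classes))]
    total = 0.0
    npairs = 0
    for a in range(len(dists)):
        for b in range(a + 1, len(dists)):
            total += f(dists[a], dists[b], **div_kwargs)
            npairs += 1
    return total / npairs


def normalize_weights(raw: np.ndarray, model: ClassConditionalModel,
                      divergence_type: str) -> FeatureWeights:
    """Divide raw weights by pooled marginal bin entropy and normalize to 1.

    H(p) = -sum_r P(a_pr) log P(a_pr) over the pooled (label-blind) bin
    occupancies of feature p; a feature with zero entropy (single bin) gets
    weight 0.  The constant z rescales so the weights sum to one.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if np.any(raw < 0):
        raise ValueError("raw weights must be non-negative")
    H = np.zeros(model.n_features)
    for j in range(model.n_features):
        pj = model.pooled[j, :model.n_bins[j]]
        nz = pj[pj > 0]
        H[j] = -(nz * np.log(nz)).sum()
    w = np.where(H > 0, raw / np.where(H > 0, H, 1.0), 0.0)
    s = w.sum()
    if s <= 0:
        raise DegenerateWeightsError("all divergence weights are zero")
    return FeatureWeights(divergence_type=divergence_type, raw=raw,
                          normalized=w / s, z=float(s))


def train_classifier(features: pd.DataFrame, divergence_type: str,
                     family: str | None = None,
                     feature_columns: list[str] | None = None,
                     R: int = 10, alpha: float = 1.0,
                     jsd_form: str = "printed",
                     hd_form: str = "printed") -> TrainedClassifier:
    """Fit the binned model and divergence weights on a training table.

    If every feature is uninformative (all raw weights zero), falls back to
    uniform weights with a warning rather than failing.
    """
    if family is not None and "family" in features.columns:
        features = features[features["family"] == family]
    model = fit_model(features, feature_columns=feature_columns, R=R, alpha=alpha)
    kwargs = {}
    if divergence_type == "jsd":
        kwargs["form"] = jsd_form
    elif divergence_type == "hd":
        kwargs["form"] = hd_form
    raw = np.array([average_weight(model, p, divergence_type, **kwargs)
                    for p in range(model.n_features)])
    try:
        weights = normalize_weights(raw, model, divergence_type)
    except DegenerateWeightsError:
        logger.warning("degenerate weights: falling back to uniform")
        uni = np.full(model.n_features, 1.0 / model.n_features)
        weights = FeatureWeights(divergence_type=divergence_type, raw=raw,
                                 normalized=uni, z=float("nan"))
    return TrainedClassifier(model=model, weights=weights, family=family,
                             jsd_form=jsd_form, hd_form=hd_form)


def class_scores(clf: TrainedClassifier, values: np.ndarray) -> np.ndarray:
    """Log-domain weighted product scores for one 40-feature vector."""
    model = clf.model
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (model.n_features,):
        raise ValueError(f"expected {model.n_features} features, "
                         f"got shape {values.shape}")
    w = clf.weights.normalized
    scores = np.log(model.priors).copy()
    for j in range(model.n_features):
        b = int(np.searchsorted(model.edges[j], values[j], side="right"))
        scores += w[j] * np.log(model.cond_probs[:, j, b])
    return scores


def classify(clf: TrainedClassifier,
             fm: FeatureMatrix | np.ndarray) -> tuple[str, np.ndarray]:
    """Predict the class of one tile's feature matrix (or 40-vector).

    Returns ``(label, scores)``; ties resolve to the earliest label in the
    fixed order normal < benign < malign.
    """
    values = fm.flatten() if isinstance(fm, FeatureMatrix) else np.asarray(fm)
    scores = class_scores(clf, values)
    return clf.model.classes[int(np.argmax(scores))], scores


def predict_table(clf: TrainedClassifier, features: pd.DataFrame) -> pd.Series:
    """Predict labels for every row of a feature table."""
    cols = clf.model.feature_names
    X = features[cols].to_numpy(dtype=np.float64)
    return pd.Series([classify(clf, x)[0] for x in X], index=features.index,
                     name="prediction")


# ---------------------------------------------------------------------------
# serialization

def save_classifier(clf: TrainedClassifier, path: str | Path) -> None:
    """Serialize a trained classifier to a JSON file."""
    m = clf.model
    doc = {
        "classes": list(m.classes),
        "priors": m.priors.tolist(),
        "feature_names": m.feature_names,
        "edges": [e.tolist() for e in m.edges],
        "cond_probs": m.cond_probs.tolist(),
        "pooled": m.pooled.tolist(),
        "n_bins": m.n_bins.tolist(),
        "n_train": m.n_train,
        "R": m.R,
        "alpha": m.alpha,
        "divergence_type": clf.weights.divergence_type,
        "raw_weights": clf.weights.raw.tolist(),
        "normalized_weights": clf.weights.normalized.tolist(),
        "z": clf.weights.z,
        "family": clf.family,
        "jsd_form": clf.jsd_form,
        "hd_form": clf.hd_form,
    }
    Path(path).write_text(json.dumps(doc))


def load_classifier(path: str | Path) -> TrainedClassifier:
    doc = json.loads(Path(path).read_text())
    model = ClassConditionalModel(
        classes=tuple(doc["classes"]),
        priors=np.array(doc["priors"]),
        feature_names=doc["feature_names"],
        edges=[np.array(e) for e in doc["edges"]],
        cond_probs=np.array(doc["cond_probs"]),
        pooled=np.array(doc["pooled"]),
        n_bins=np.array(doc["n_bins"], dtype=np.int64),
        n_train=doc["n_train"], R=doc["R"], alpha=doc["alpha"])
    weights = FeatureWeights(
        divergence_type=doc["divergence_type"],
        raw=np.array(doc["raw_weights"]),
        normalized=np.array(doc["normalized_weights"]), z=doc["z"])
    return TrainedClassifier(model=model, weights=weights,
                             family=doc["family"], jsd_form=doc["jsd_form"],
                             hd_form=doc["hd_form"])
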