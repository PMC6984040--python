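"""Cross-visit individual identification and GSR-robustness statistics.

A 1-nearest-neighbor classifier with cosine similarity is trained on one
visit's feature vectors and tested on the other visit (both directions).
Identification quality is summarized by the accuracy and by Gorodkin's R_K
coefficient, the multi-class generalization of the Matthews correlation
coefficient. Robustness of a feature kind to global signal regression is
the per-subject cosine distance between with-GSR and without-GSR vectors,
compared across conditions with Kruskal-Wallis and Bonferroni-corrected
Mann-Whitney U tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureExtractor
from .panel import TimeSeriesPanel
from .preprocess import PreprocessConfig, run_pipeline

DIRECTIONS = ("visit1->visit2", "visit2->visit1")


@dataclass
class FingerprintResult:
    """Confusion matrices, accuracies and R_K per identification direction."""

    subjects: list[str]
    confusion: dict[str, np.ndarray]
    accuracy: dict[str, float]
    rk: dict[str, float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.accuracy.values())))

    @property
    def mean_rk(self) -> float:
        return float(np.mean(list(self.rk.values())))


@dataclass
class RobustnessResult:
    """Kruskal-Wallis omnibus plus Bonferroni-adjusted pairwise U tests."""

    groups: dict[str, np.ndarray]
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, u, p, p_adj


def rk_coefficient(confusion: np.ndarray) -> float:
    """Gorodkin's R_K from a square count matrix.

    ``(c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))``
    with ``c`` the trace, ``s`` the total, ``t_k``/``p_k`` the row/column
    sums; a vanishing denominator returns 0 by the usual MCC convention.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(C < 0):
        raise ValueError("confusion counts must be non-negative")
    s = C.sum()
    if s <= 0:
        raise ValueError("confusion matrix total must be positive")
    c = np.trace(C)
    t = C.sum(axis=1)  # true-class counts
    p = C.sum(axis=0)  # predicted-class counts
    denom2 = (s**2 - np.sum(p**2)) * (s**2 - np.sum(t**2))
    if denom2 <= 0:
        return 0.0
    return float((c * s - np.sum(p * t)) / np.sqrt(denom2))


class OneNearestNeighborIdentifier:
    """1-NN with cosine similarity over subject feature vectors.

    sklearn-style: ``fit(X, subject_ids)`` stores the gallery,
    ``predict(X)`` returns the gallery subject with the highest cosine
    similarity for each probe. Ties resolve to the lowest subject id
    (the gallery is sorted at fit time).
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "OneNearestNeighborIdentifier":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    @staticmethod
    def _unit(X: np.ndarray, ids) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        norms = np.linalg.norm(X, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"zero feature vector for subject(s) {[ids[i] for i in bad]}")
        return X / norms[:, None]

    def fit(self, X, subject_ids) -> "OneNearestNeighborIdentifier":
        order = np.argsort(np.asarray(subject_ids, dtype=object))
        self.subject_ids_ = [subject_ids[i] for i in order]
        self.gallery_ = self._unit(np.asarray(X)[order], self.subject_ids_)
        return self

    def predict(self, X) -> list:
        probes = self._unit(X, list(range(len(X))))
        sim = probes @ self.gallery_.T
        return [self.subject_ids_[j] for j in np.argmax(sim, axis=1)]


def _direction(train: dict, test: dict, subjects: list[str]):
    clf = OneNearestNeighborIdentifier().fit(
        [train[s] for s in subjects], list(subjects)
    )
    pred = clf.predict([test[s] for s in subjects])
    index = {s: i for i, s in enumerate(subjects)}
    C = np.zeros((len(subjects), len(subjects)), dtype=int)
    for s, p in zip(subjects, pred):
        C[index[s], index[p]] += 1
    acc = float(np.trace(C) / C.sum())
    return C, acc, rk_coefficient(C)


def one_nn_identify(train_features: dict, test_features: dict) -> FingerprintResult:
    """Identify subjects across visits, in both directions.

    ``train_features``/``test_features`` map subject id to feature vector
    for visit 1 and visit 2 respectively; the reverse direction swaps roles.
    """
    if set(train_features) != set(test_features):
        raise ValueError("train and test must cover the same subjects")
    subjects = sorted(train_features)
    lengths = {len(np.ravel(v)) for v in train_features.values()}
    lengths |= {len(np.ravel(v)) for v in test_features.values()}
    if len(lengths) != 1:
        raise ValueError("all feature vectors must have the same length")
    confusion, accuracy, rk = {}, {}, {}
    for direction, (tr, te) in zip(
        DIRECTIONS, [(train_features, test_features), (test_features, train_features)]
    ):
        C, a, r = _direction(tr, te, subjects)
        confusion[direction] = C
        accuracy[direction] = a
        rk[direction] = r
    return FingerprintResult(subjects, confusion, accuracy, rk)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def gsr_robustness(
    features_with_gsr: dict, features_without_gsr: dict
) -> dict[str, float]:
    """Per-subject cosine distance between with- and without-GSR vectors."""
    if set(features_with_gsr) != set(features_without_gsr):
        raise ValueError("subject sets differ between conditions")
    return {
        s: cosine_distance(
            np.ravel(features_with_gsr[s]), np.ravel(features_without_gsr[s])
        )
        for s in sorted(features_with_gsr)
    }


def compare_robustness(distance_groups: dict[str,  np.ndarray]) -> RobustnessResult:
    """Omnibus Kruskal-Wallis over distance groups plus pairwise U tests.

    Groups of fewer than two observations are excluded with a warning; the
    Bonferroni multiplier is the number of tested pairs.
    """
    groups = {}
    for name, vals in distance_groups.items():
        vals = np.asarray(list(vals.values()) if isinstance(vals, dict) else vals,
                          dtype=float)
        if vals.size < 2:
            warnings.warn(f"group {name!r} has < 2 observations: excluded",
                          stacklevel=2)
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 groups of size >= 2")
    h, p = stats.kruskal(*groups.values())
    pairs = list(itertools.combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        u, pu = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append(
            {"group_a": a, "group_b": b, "u": float(u), "p": float(pu),
             "p_adj": float(min(1.0, pu * len(pairs)))}
        )
    return RobustnessResult(groups, float(h), float(p), pd.DataFrame(rows))


def _visit_vectors(
    panel: TimeSeriesPanel, kind: str, config: PreprocessConfig, visit: int
) -> dict[str, np.ndarray]:
    clean = run_pipeline(panel, config, feature_kind=kind)
    extractor = FeatureExtractor(kind=kind, tr=panel.tr)
    recs = clean.records_for_visit(visit)
    by_subject: dict[str, list[np.ndarray]] = {}
    vectors = extractor.transform([r.matrix for r in recs])
    for rec, vec in zip(recs, vectors):
        by_subject.setdefault(rec.subject_id, []).append(vec)
    # multiple runs per visit average into one vector per subject
    return {s: np.mean(v, axis=0) for s, v in by_subject.items()}


def fingerprint_panel(
    panel: TimeSeriesPanel, kind: str, config: PreprocessConfig | None = None
) -> FingerprintResult:
    """End-to-end: preprocess a two-visit panel, extract one feature kind,
    and run the cross-visit 1-NN identification."""
    config = config or PreprocessConfig()
    visits = panel.visits
    if len(visits) != 2:
        raise ValueError(f"fingerprinting needs exactly 2 visits, found {visits}")
    v1 = _visit_vectors(panel, kind, config, visits[0])
    v2 = _visit_vectors(panel, kind, config, visits[1])
    missing = sorted(set(v1) ^ set(v2))
    if missing:
        raise ValueError(f"subject(s) {missing} missing one of the visits")
    return one_nn_identify(v1, v2)


def stability_sweep(
    panel: TimeSeriesPanel,
    feature_kinds=("lead", "corr", "lagged_corr", "dtw"),
    bands=(None, (0.008, 0.08), (0.008, 0.2)),
    gsr_options=(False, True),
    scaling: str = "quadratic_variation",
) -> pd.DataFrame:
    """The identification grid: feature kind x filter band x GSR.

    Returns a long-format table with one row per condition and direction
    (plus the per-condition mean over directions), mirroring the layout of
    stability tables of identification accuracies.
    """
    rows = []
    for kind in feature_kinds:
        for band in bands:
            for gsr in gsr_options:
                cfg = PreprocessConfig(do_gsr=gsr, filter_band=band, scaling=scaling)
                res = fingerprint_panel(panel, kind, cfg)
                band_name = "none" if band is None else f"{band[0]}-{band[1]}Hz"
                for direction in DIRECTIONS:
                    rows.append(
                        {"feature": kind, "gsr": gsr, "band": band_name,
                         "direction": direction,
                         "accuracy": res.accuracy[direction],
                         "rk": res.rk[direction]}
                    )
                rows.append(
                    {"feature": kind, "gsr": gsr, "band": band_name,
                     "direction": "mean", "accuracy": res.mean_accuracy,
                     "rk": res.mean_rk}
                )
    return pd.DataFrame(rows)
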