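"""Group classification: Monte-Carlo CV, PCA-reduced discriminant analysis,
kernel SVMs, sparse l1-SVM salience selection, and a VAE-augmented CNN.

All learned transforms (standardization, PCA, VAE, network weights) are fit
on training folds only; splits are drawn at the *subject* level so that the
two visits of one subject never straddle the train/test boundary.

The sparse SVM minimizes ``(1/n) sum_i max(0, 1 - t_i (w.x_i + b)) +
lambda * ||w||_1`` -- hinge loss with an l1 penalty -- solved exactly as a
linear program. Its nonzero weights map back to ROI pairs through the
upper-triangle index map, giving a salience graph of the interactions that
drive the separating hyperplane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._nets import VAE, RowColumnCNN
from .features import matricize, vectorize_upper

POSITIVE_CLASS = "patient"

CLASSIFIERS = ("lda", "qda", "svm-linear", "svm-quadratic", "svm-rbf")


@dataclass
class McCvConfig:
    """Monte-Carlo cross-validation: 100 random 70/30 subject splits."""

    n_reps: int = 100
    train_frac: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def mc_splits(
    labels: dict[str, str], config: McCvConfig
) -> list[tuple[list[str], list[str]]]:
    """Subject-level train/test splits, deterministic given the seed.

    The train size is ``floor(train_frac * n_subjects)``; stratification
    allocates per-class counts by largest remainder, keeping the class
    ratio within one subject of the cohort ratio. Degenerate draws (a class
    absent from either side) are redrawn with a warning.
    """
    subjects = sorted(labels)
    classes = sorted(set(labels.values()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to split")
    n_train = int(np.floor(config.train_frac * len(subjects)))
    if not 0 < n_train < len(subjects):
        raise ValueError("train_frac leaves an empty train or test set")
    rng = np.random.default_rng(config.seed)
    splits = []
    for _ in range(config.n_reps):
        for attempt in range(100):
            if config.stratified:
                train: list[str] = []
                quotas = {}
                for cls in classes:
                    members = [s for s in subjects if labels[s] == cls]
                    quotas[cls] = config.train_frac * len(members)
                counts = {c: int(np.floor(q)) for c, q in quotas.items()}
                # largest-remainder top-up to hit n_train exactly
                remainders = sorted(
                    classes, key=lambda c: quotas[c] - counts[c], reverse=True
                )
                i = 0
                while sum(counts.values()) < n_train:
                    counts[remainders[i % len(remainders)]] += 1
                    i += 1
                for cls in classes:
                    members = [s for s in subjects if labels[s] == cls]
                    pick = rng.choice(len(members), size=counts[cls], replace=False)
                    train.extend(members[i] for i in pick)
            else:
                pick = rng.choice(len(subjects), size=n_train, replace=False)
                train = [subjects[i] for i in pick]
            test = [s for s in subjects if s not in set(train)]
            train_classes = {labels[s] for s in train}
            test_classes = {labels[s] for s in test}
            if train_classes == set(classes) and test_classes == set(classes):
                break
            warnings.warn("degenerate split redrawn (class absent)", stacklevel=2)
        splits.append((sorted(train), sorted(test)))
    return splits


def evaluate(preds, truth, positive_class: str = POSITIVE_CLASS) -> dict:
    """Sensitivity, specificity, accuracy and balanced accuracy."""
    preds = np.asarray(preds, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if preds.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    pos = truth == positive_class
    neg = ~pos
    tp = int(np.sum(pos & (preds == truth)))
    tn = int(np.sum(neg & (preds == truth)))
    sens = tp / pos.sum() if pos.any() else np.nan
    spec = tn / neg.sum() if neg.any() else np.nan
    acc = float(np.mean(preds == truth))
    balanced = np.nanmean([sens, spec])
    return {
        "sensitivity": float(sens) if pos.any() else np.nan,
        "specificity": float(spec) if neg.any() else np.nan,
        "accuracy": acc,
        "balanced_accuracy": float(balanced),
    }


@dataclass
class ClassificationReport:
    """Per-repetition rates plus their summary."""

    classifier: str
    condition: str
    rows: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> dict:
        df = self.frame()
        out = {"classifier": self.classifier, "condition": self.condition}
        for col in ("sensitivity", "specificity", "accuracy", "balanced_accuracy"):
            out[f"{col}_mean"] = float(df[col].mean())
            out[f"{col}_sd"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
        return out


def pca_fit_transform(
    train: np.ndarray, test: np.ndarray, n_components: int
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """PCA fit on training vectors only; test projected with train loadings."""
    train = np.asarray(train, dtype=float)
    limit = min(train.shape)
    if n_components > limit:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_train, n_features)={limit}"
        )
    pca = PCA(n_components=n_components, svd_solver="full").fit(train)
    return pca.transform(train), pca.transform(test), pca


def make_classifier(kind: str, seed: int = 0, C: float = 1.0) -> Pipeline:
    """Standardize -> PCA -> classifier, all fit on the training fold.

    Discriminant analyses use a 10-D projection, SVMs a 20-D one (capped at
    fit time by the training-set size). Singular DA covariances are ridge-
    regularized.
    """
    if kind == "lda":
        clf, n_comp = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-4), 10
    elif kind == "qda":
        clf, n_comp = QuadraticDiscriminantAnalysis(reg_param=1e-3), 10
    elif kind == "svm-linear":
        clf, n_comp = SVC(kernel="linear", C=C, random_state=seed), 20
    elif kind == "svm-quadratic":
        clf, n_comp = SVC(kernel="poly", degree=2, C=C, random_state=seed), 20
    elif kind == "svm-rbf":
        clf, n_comp = SVC(kernel="rbf", C=C, random_state=seed), 20
    else:
        raise ValueError(f"unknown classifier {kind!r}; expected {CLASSIFIERS}")
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=n_comp, svd_solver="full")),
            ("clf", clf),
        ]
    )


def _cap_pca(pipe: Pipeline, n_train: int, n_features: int) -> None:
    limit = min(n_train - 1, n_features)
    if pipe.named_steps["pca"].n_components > limit:
        pipe.named_steps["pca"].n_components = limit


def run_mc_cv(
    X: np.ndarray,
    record_subjects: list[str],
    labels: dict[str, str],
    classifier: str,
    config: McCvConfig | None = None,
    condition: str = "",
) -> ClassificationReport:
    """Monte-Carlo CV of one classical classifier on record-level vectors."""
    config = config or McCvConfig()
    X = np.asarray(X, dtype=float)
    record_subjects = list(record_subjects)
    report = ClassificationReport(classifier, condition)
    for rep, (train_subj, test_subj) in enumerate(mc_splits(labels, config)):
        tr = [i for i, s in enumerate(record_subjects) if s in set(train_subj)]
        te = [i for i, s in enumerate(record_subjects) if s in set(test_subj)]
        y_tr = [labels[record_subjects[i]] for i in tr]
        y_te = [labels[record_subjects[i]] for i in te]
        pipe = make_classifier(classifier, seed=config.seed + rep)
        _cap_pca(pipe, len(tr), X.shape[1])
        pipe.fit(X[tr], y_tr)
        preds = pipe.predict(X[te])
        row = evaluate(preds, y_te)
        row["rep"] = rep
        report.rows.append(row)
    return report


# ---------------------------------------------------------------------------
# sparse l1-SVM


def pair_index(n: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle index map (matches vectorize_upper)."""
    iu = np.triu_indices(n, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


@dataclass
class SparseSvmModel:
    """Solution of the l1-regularized hinge-loss linear program."""

    w: np.ndarray
    b: float
    lam: float
    support: np.ndarray  # indices with |w| above threshold
    classes: tuple[str, str]  # (negative, positive)

    def decision_value(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def predict(self, X: np.ndarray):
        d = self.decision_value(X)
        return np.where(d >= 0, self.classes[1], self.classes[0])


@dataclass
class SalienceGraph:
    """ROI-pair edges weighted by |w| of the sparse-SVM solution."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    condition: str = ""

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(condition=self.condition)
        g.add_nodes_from(self.nodes)
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["roi_i", "roi_j", "weight"])


class SparseLinearSVM:
    """sklearn-style estimator for the hinge + l1 linear program.

    Exact solution via ``scipy.optimize.linprog`` (HiGHS): variables are the
    positive/negative parts of ``w``, the intercept parts, and the per-sample
    hinge slacks. Deterministic; ``coef_`` has exact zeros.
    """

    def __init__(self, lam: float = 0.01, support_tol: float = 1e-6):
        self.lam = lam
        self.support_tol = support_tol

    def get_params(self, deep: bool = True) -> dict:
        return {"lam": self.lam, "support_tol": self.support_tol}

    def set_params(self, **params) -> "SparseLinearSVM":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "SparseLinearSVM":
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        classes = sorted(set(y.tolist()))
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {classes}")
        t = np.where(y == classes[1], 1.0, -1.0)
        n, d = X.shape
        # variables: [w+ (d), w- (d), b+, b-, xi (n)]
        c = np.concatenate(
            [np.full(d, self.lam), np.full(d, self.lam), [0.0, 0.0], np.full(n, 1.0 / n)]
        )
        tX = t[:, None] * X
        A_ub = np.hstack(
            [-tX, tX, -t[:, None], t[:, None], -np.eye(n)]
        )
        b_ub = -np.ones(n)
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, method="highs")
        if not res.success:
            raise RuntimeError(f"sparse-SVM LP failed: {res.message}")
        z = res.x
        self.coef_ = z[:d] - z[d : 2 * d]
        self.coef_[np.abs(self.coef_) <= self.support_tol] = 0.0
        self.intercept_ = float(z[2 * d] - z[2 * d + 1])
        self.classes_ = tuple(classes)
        self.support_ = np.flatnonzero(np.abs(self.coef_) > self.support_tol)
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes_[1], self.classes_[0])


def sparse_svm_select(
    vectors: np.ndarray,
    y,
    lam: float,
    roi_names: list[str] | None = None,
    condition: str = "",
    standardize: bool = True,
) -> tuple[SparseSvmModel, SalienceGraph]:
    """Fit the sparse SVM and map its support back to ROI pairs."""
    X = np.asarray(vectors, dtype=float)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    est = SparseLinearSVM(lam=lam).fit(X, y)
    n = int(round((1 + np.sqrt(1 + 8 * X.shape[1])) / 2))
    names = list(roi_names) if roi_names else [f"ROI{i + 1:02d}" for i in range(n)]
    pairs = pair_index(n)
    edges = [
        (names[pairs[i][0]], names[pairs[i][1]], float(abs(est.coef_[i])))
        for i in est.support_
    ]
    model = SparseSvmModel(
        est.coef_, est.intercept_, lam, est.support_, est.classes_
    )
    return model, SalienceGraph(names, edges, condition)


def choose_lambda(
    X: np.ndarray, y, grid=(0.3, 0.1, 0.03, 0.01, 0.003), n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick lambda by k-fold CV accuracy on the training data only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, n_folds)
    best_lam, best_acc = grid[0], -1.0
    for lam in grid:
        accs = []
        for i in range(n_folds):
            te = folds[i]
            tr = np.concatenate([folds[j] for j in range(n_folds) if j != i])
            if len(set(y[tr])) < 2:
                continue
            est = SparseLinearSVM(lam=lam).fit(X[tr], y[tr])
            accs.append(np.mean(est.predict(X[te]) == y[te]))
        acc = float(np.mean(accs)) if accs else 0.0
        if acc > best_acc:
            best_lam, best_acc = lam, acc
    return best_lam


# ---------------------------------------------------------------------------
# VAE augmentation and CNN


class VaeAugmenter:
    """Per-class generative model over vectorized feature matrices.

    Vectors are standardized before training; drawn samples are mean
    adjusted and re-scaled afterwards so their per-dimension moments match
    the training class. ``kind`` controls the symmetry restored when
    samples are matricized.
    """

    def __init__(self, kind: str = "lead", hidden: tuple[int, int] = (256, 64),
                 latent_dim: int = 2, epochs: int = 200, lr: float = 1e-3,
                 seed: int = 0, min_train: int = 20):
        self.kind = kind
        self.hidden = hidden
        self.latent_dim = latent_dim
        self.epochs = epochs
        self.lr = lr
        self.seed = seed
        self.min_train = min_train

    def get_params(self, deep: bool = True) -> dict:
        return {
            "kind": self.kind, "hidden": self.hidden,
            "latent_dim": self.latent_dim, "epochs": self.epochs,
            "lr": self.lr, "seed": self.seed, "min_train": self.min_train,
        }

    def set_params(self, **params) -> "VaeAugmenter":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray) -> "VaeAugmenter":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.min_train:
            raise ValueError(
                f"need >= {self.min_train} training vectors, got {X.shape[0]}"
            )
        self.mu_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        sd_safe = np.where(self.sd_ == 0, 1.0, self.sd_)
        Z = (X - self.mu_) / sd_safe
        self.vae_ = VAE(X.shape[1], hidden=self.hidden,
                        latent_dim=self.latent_dim, lr=self.lr, seed=self.seed)
        self.history_ = self.vae_.fit(Z, epochs=self.epochs)
        return self

    def sample(self, n: int) -> np.ndarray:
        raw = self.vae_.sample(n)
        sd_safe = np.where(self.sd_ == 0, 1.0, self.sd_)
        out = raw * sd_safe + self.mu_
        # moment adjustment: re-center and re-scale the drawn batch
        if n > 1:
            bm, bs = out.mean(axis=0), out.std(axis=0)
            bs_safe = np.where(bs < 1e-12, 1.0, bs)
            out = (out - bm) / bs_safe * self.sd_ + self.mu_
        else:
            out = out - out.mean(axis=0) + self.mu_
        return out

    def sample_matrices(self, n: int) -> np.ndarray:
        return np.stack([matricize(v, self.kind) for v in self.sample(n)])


class ConnectomeCNN:
    """sklearn-style classifier over stacks of square feature matrices."""

    def __init__(self, filters1: int = 16, filters2: int = 32, dense: int = 64,
                 dropout: float = 0.5, epochs: int = 40, lr: float = 1e-3,
                 seed: int = 0):
        self.filters1 = filters1
        self.filters2 = filters2
        self.dense = dense
        self.dropout = dropout
        self.epochs = epochs
        self.lr = lr
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "filters1": self.filters1, "filters2": self.filters2,
            "dense": self.dense, "dropout": self.dropout,
            "epochs": self.epochs, "lr": self.lr, "seed": self.seed,
        }

    def set_params(self, **params) -> "ConnectomeCNN":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y) -> "ConnectomeCNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        self.classes_ = np.array(sorted(set(y.tolist())), dtype=object)
        if len(self.classes_) != 2:
            raise ValueError("ConnectomeCNN is a two-class model")
        codes = np.array([int(v == self.classes_[1]) for v in y])
        self.mu_ = X.mean(axis=0)
        sd = X.std()
        self.sd_ = sd if sd > 0 else 1.0
        Z = (X - self.mu_) / self.sd_
        self.net_ = RowColumnCNN(
            X.shape[1], self.filters1, self.filters2, self.dense,
            self.dropout, self.lr, self.seed,
        )
        self.history_ = self.net_.fit(Z, codes, epochs=self.epochs)
        return self

    def predict(self, X: np.ndarray):
        Z = (np.asarray(X, dtype=float) - self.mu_) / self.sd_
        return self.classes_[self.net_.predict(Z)]


def cnn_fit_eval(
    matrices: np.ndarray,
    record_subjects: list[str],
    labels: dict[str, str],
    kind: str = "lead",
    config: McCvConfig | None = None,
    augmented: bool = False,
    cnn_params: dict | None = None,
    vae_params: dict | None = None,
    condition: str = "",
) -> ClassificationReport:
    """Monte-Carlo CV of the CNN, optionally with per-class VAE augmentation.

    Augmentation draws, per class, as many synthetic matrices as the class
    has real training records (doubling the effective training count). VAEs
    only ever see training-fold records; the test fold is untouched.
    """
    config = config or McCvConfig()
    matrices = np.asarray(matrices, dtype=float)
    record_subjects = list(record_subjects)
    name = "cnn+vae" if augmented else "cnn"
    report = ClassificationReport(name, condition)
    for rep, (train_subj, test_subj) in enumerate(mc_splits(labels, config)):
        train_set, test_set = set(train_subj), set(test_subj)
        if train_set & test_set:
            raise RuntimeError("train/test subject leakage")  # defensive guard
        tr = [i for i, s in enumerate(record_subjects) if s in train_set]
        te = [i for i, s in enumerate(record_subjects) if s in test_set]
        X_tr = matrices[tr]
        y_tr = np.array([labels[record_subjects[i]] for i in tr], dtype=object)
        y_te = [labels[record_subjects[i]] for i in te]
        if augmented:
            extra_X, extra_y = [], []
            for cls in sorted(set(y_tr.tolist())):
                members = X_tr[y_tr == cls]
                vecs = np.stack([vectorize_upper(m) for m in members])
                vp = dict(vae_params or {})
                vp.setdefault("kind", kind)
                vp.setdefault("seed", config.seed + rep)
                vp.setdefault("min_train", min(20, len(vecs)))
                aug = VaeAugmenter(**vp).fit(vecs)
                extra_X.append(aug.sample_matrices(len(members)))
                extra_y.extend([cls] * len(members))
            X_tr = np.concatenate([X_tr] + extra_X)
            y_tr = np.concatenate([y_tr, np.array(extra_y, dtype=object)])
        cp = dict(cnn_params or {})
        cp.setdefault("seed", config.seed + rep)
        clf = ConnectomeCNN(**cp).fit(X_tr, y_tr)
        preds = clf.predict(matrices[te])
        row = evaluate(preds, y_te)
        row["rep"] = rep
        report.rows.append(row)
    return report
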