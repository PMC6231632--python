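"""Repeated nested cross-validation for descriptor benchmarking.

The protocol: stratified outer k-fold (default 10) estimates
generalization; within each outer training split an inner stratified
k-fold (default 5) grid search selects the descriptor threshold T_O and
the classifier hyper-parameters by inner accuracy; the winning
configuration is refit on the whole outer training split and scored on
the held-out fold.  The whole procedure is repeated (default 10 times)
with fresh fold shuffles, and ACC / ROC-AUC statistics are aggregated
over all n_repeats x outer_k fold results.

Because descriptor extraction is unsupervised and per-image, the
feature matrix for every candidate T_O is computed once up front (the
similarity stack is sampled once per image and re-binarized per
threshold); the inner search then only indexes rows, which keeps the
search over T_O cheap and leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .colorspace import md_decompose, to_color_space
from .descriptor import (
    DEFAULT_T_O_GRID,
    _codes_to_index_image,
    similarity_stack,
    texton_histogram,
)
from .estimators import DESCRIPTOR_NAMES
from .exceptions import InvalidInputError
from .fusion import fuse_concat, fuse_joint
from .lbp import lbp_index_image
from .sampling import NeighborhoodSpec, build_rotation_code_table

__all__ = ["EvaluationReport", "nested_cv", "nested_cv_on_features", "roc_auc",
           "feature_bank", "CLASSIFIERS"]

CLASSIFIERS = ("fld", "svm", "knn")

_KNN_K = (1, 3, 5, 7, 9)
_KNN_METRICS = ("euclidean", "manhattan")
_SVM_GAMMA_FACTORS = (0.1, 1.0, 10.0)
_SVM_C = (0.1, 1.0, 10.0, 100.0)


@dataclass
class EvaluationReport:
    """Aggregate nested-CV result for one descriptor/classifier pair."""

    classifier: str
    descriptor: str
    acc_mean: float
    acc_std: float
    auc_mean: float
    auc_std: float
    n_repeats: int
    outer_k: int
    inner_k: int
    fold_acc: list[float] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)
    selected_params: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    The probability that a uniformly random positive sample outscores a
    uniformly random negative one, ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0 or np.unique(labels).size != 2:
        raise InvalidInputError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def feature_bank(
    images,
    descriptor: str = "qdcp-lbp",
    t_o_grid=DEFAULT_T_O_GRID,
    n_samples: int = 8,
    radius: float = 1.0,
    color_space: str = "ycbcr",
    normalize: bool = True,
) -> dict:
    """Feature matrices keyed by T_O (or ``None`` for T_O-free descriptors).

    The expensive per-image work (color conversion, orientation
    sampling, LBP coding) happens once; each T_O entry reuses the
    cached similarity stack.
    """
    if descriptor not in DESCRIPTOR_NAMES:
        raise InvalidInputError(
            f"unknown descriptor {descriptor!r}; expected one of {DESCRIPTOR_NAMES}"
        )
    spec = NeighborhoodSpec(n_samples, radius)
    table = build_rotation_code_table(spec.n_samples)
    uses_t_o = descriptor in ("qdcp", "qdcp-lbp", "qdcp-joint-lbp")
    keys = tuple(float(t) for t in t_o_grid) if uses_t_o else (None,)
    rows: dict = {k: [] for k in keys}
    for img in images:
        ycbcr = to_color_space(img, "ycbcr")
        mag, _ = md_decompose(ycbcr)
        if descriptor == "lbp-luma":
            idx = lbp_index_image(ycbcr.pixels[..., 0], spec, table)
            rows[None].append(texton_histogram(idx, normalize).bins)
            continue
        if descriptor == "lbp-magnitude":
            idx = lbp_index_image(mag.values, spec, table)
            rows[None].append(texton_histogram(idx, normalize).bins)
            continue
        converted = (
            ycbcr if color_space == "ycbcr" else to_color_space(img, color_space)
        )
        _, orient = md_decompose(converted)
        m = similarity_stack(orient, spec)
        if descriptor in ("qdcp-lbp", "qdcp-joint-lbp"):
            l_idx = lbp_index_image(mag.values, spec, table)
        for t_o in keys:
            bits = m < t_o
            q_idx = _codes_to_index_image(bits, orient.shape, spec.border, table)
            if descriptor == "qdcp":
                rows[t_o].append(texton_histogram(q_idx, normalize).bins)
            elif descriptor == "qdcp-lbp":
                rows[t_o].append(
                    fuse_concat(
                        texton_histogram(q_idx, normalize),
                        texton_histogram(l_idx, normalize),
                    ).vector
                )
            else:
                rows[t_o].append(fuse_joint(q_idx, l_idx, normalize).vector)
    return {k: np.vstack(v) for k, v in rows.items()}


def _encode_labels(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise InvalidInputError(f"expected exactly 2 classes, found {classes.size}")
    return (labels == classes[1]).astype(int), classes


def _median_sq_dist(x: np.ndarray, rng: np.random.Generator) -> float:
    n = x.shape[0]
    if n > 200:  # subsample for the heuristic on large sets
        x = x[rng.choice(n, 200, replace=False)]
    sq = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    vals = sq[np.triu_indices_from(sq, k=1)]
    med = float(np.median(vals))
    return med if med > 0 else 1.0


class _MajorityClassifier:
    """Fallback when a candidate feature matrix is degenerate.

    A low threshold can map every image to the same all-agree texton
    histogram; such constant features break discriminant fitting, and
    the honest score for them is majority-class accuracy with
    uninformative (all-equal) decision scores.
    """

    def fit(self, x, y):
        vals, counts = np.unique(y, return_counts=True)
        self.majority_ = vals[np.argmax(counts)]
        return self

    def predict(self, x):
        return np.full(len(x), self.majority_)

    def score(self, x, y):
        return float(np.mean(np.asarray(y) == self.majority_))

    def decision_function(self, x):
        return np.zeros(len(x))

    def predict_proba(self, x):
        return np.full((len(x), 2), 0.5)


def _fit_classifier(name: str, params: dict, x, y):
    clf = _make_classifier(name, params)
    try:
        return clf.fit(x, y)
    except (ValueError, IndexError, np.linalg.LinAlgError):
        return _MajorityClassifier().fit(x, y)


def _make_classifier(name: str, params: dict):
    if name == "fld":
        return LinearDiscriminantAnalysis()
    if name == "svm":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
    if name == "knn":
        return KNeighborsClassifier(
            n_neighbors=params["k"], metric=params["metric"]
        )
    raise InvalidInputError(
        f"unknown classifier {name!r}; expected one of {CLASSIFIERS}"
    )


def _decision_scores(name: str, clf, x: np.ndarray) -> np.ndarray:
    if isinstance(clf, _MajorityClassifier):
        return clf.decision_function(x)
    if name == "knn":
        return clf.predict_proba(x)[:, 1]  # positive-class neighbor fraction
    return clf.decision_function(x)  # signed distance to the boundary


def _candidate_params(name: str, x_train: np.ndarray, n_inner_train: int,
                      rng: np.random.Generator) -> list[dict]:
    if name == "fld":
        return [{}]
    if name == "svm":
        med = _median_sq_dist(x_train, rng)
        return [
            {"gamma": f / med, "C": c}
            for f in _SVM_GAMMA_FACTORS
            for c in _SVM_C
        ]
    ks = [k for k in _KNN_K if k <= n_inner_train]
    return [{"k": k, "metric": m} for k in ks for m in _KNN_METRICS]


def nested_cv_on_features(
    bank: dict,
    labels,
    classifier: str = "svm",
    descriptor: str = "qdcp-lbp",
    outer_k: int = 10,
    inner_k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """Nested CV over precomputed feature matrices keyed by T_O.

    ``bank`` maps each candidate T_O (or ``None``) to an (n_images, d)
    matrix.  The inner loop sees only outer-training rows.
    """
    if classifier not in CLASSIFIERS:
        raise InvalidInputError(
            f"unknown classifier {classifier!r}; expected one of {CLASSIFIERS}"
        )
    y, classes = _encode_labels(labels)
    n = y.size
    for mat in bank.values():
        if mat.shape[0] != n:
            raise InvalidInputError("feature matrix rows must match label count")
    counts = np.bincount(y)
    if counts.min() < outer_k:
        raise InvalidInputError(
            f"each class needs at least outer_k={outer_k} samples, got {counts}"
        )
    t_keys = sorted(bank.keys(), key=lambda k: (k is None, k))
    seeds = np.random.SeedSequence(seed).generate_state(n_repeats)
    fold_acc: list[float] = []
    fold_auc: list[float] = []
    selected: list[dict] = []
    for rep in range(n_repeats):
        rep_seed = int(seeds[rep]) % (2**31)
        rng = np.random.default_rng(rep_seed)
        outer = StratifiedKFold(outer_k, shuffle=True, random_state=rep_seed)
        for fold_i, (tr, te) in enumerate(outer.split(np.zeros(n), y)):
            inner_seed = (rep_seed + 977 * fold_i + 1) % (2**31)
            inner = StratifiedKFold(inner_k, shuffle=True, random_state=inner_seed)
            inner_splits = list(inner.split(np.zeros(tr.size), y[tr]))
            n_inner_train = min(itr.size for itr, _ in inner_splits)
            best = None  # (acc, order, t_o, params)
            order = 0
            for t_o in t_keys:
                x_tr = bank[t_o][tr]
                for params in _candidate_params(
                    classifier, x_tr, n_inner_train, rng
                ):
                    accs = []
                    for itr, ite in inner_splits:
                        clf = _fit_classifier(classifier, params, x_tr[itr], y[tr][itr])
                        accs.append(clf.score(x_tr[ite], y[tr][ite]))
                    mean_acc = float(np.mean(accs))
                    if best is None or mean_acc > best[0]:
                        best = (mean_acc, order, t_o, params)
                    order += 1
            _, _, t_best, p_best = best
            clf = _fit_classifier(classifier, p_best, bank[t_best][tr], y[tr])
            x_te = bank[t_best][te]
            fold_acc.append(float(clf.score(x_te, y[te])))
            fold_auc.append(roc_auc(_decision_scores(classifier, clf, x_te), y[te]))
            selected.append(
                {"repeat": rep, "fold": fold_i, "t_o": t_best, **p_best}
            )
    return EvaluationReport(
        classifier=classifier,
        descriptor=descriptor,
        acc_mean=float(np.mean(fold_acc)),
        acc_std=float(np.std(fold_acc, ddof=1)),
        auc_mean=float(np.mean(fold_auc)),
        auc_std=float(np.std(fold_auc, ddof=1)),
        n_repeats=n_repeats,
        outer_k=outer_k,
        inner_k=inner_k,
        fold_acc=fold_acc,
        fold_auc=fold_auc,
        selected_params=selected,
    )


def nested_cv(
    images,
    labels,
    descriptor: str = "qdcp-lbp",
    classifier: str = "svm",
    t_o_grid=DEFAULT_T_O_GRID,
    outer_k: int = 10,
    inner_k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    n_samples: int = 8,
    radius: float = 1.0,
    color_space: str = "ycbcr",
    normalize: bool = True,
) -> EvaluationReport:
    """Extract features for the T_O grid, then run the nested protocol."""
    bank = feature_bank(
        images,
        descriptor=descriptor,
        t_o_grid=t_o_grid,
        n_samples=n_samples,
        radius=radius,
        color_space=color_space,
        normalize=normalize,
    )
    return nested_cv_on_features(
        bank,
        labels,
        classifier=classifier,
        descriptor=descriptor,
        outer_k=outer_k,
        inner_k=inner_k,
        n_repeats=n_repeats,
        seed=seed,
    )
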