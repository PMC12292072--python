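"""Feature assembly and the RBF-kernel SVM classifier.

A training/prediction row joins three evidence sources for one
(TRIM, target) pair in one cancer: the target's log2 fold change, the
TRIM-target Spearman correlation R, and the docking score (zrank_score),
plus the cancer type.  Rows are admitted only when the target is a DEG,
the correlation is significant, and a docking score exists — the same
filter the curated training set passes through.

Numeric features are z-scored (statistics fit on training data only) and
the cancer type is one-hot encoded; the squared Euclidean distance over
the encoded vector feeds the RBF kernel exp(-gamma ||xi - xj||^2).  The
soft-margin SVM (classes TRUE=1 / FALSE=0) is fit with scikit-learn's
libsvm backend; hyperparameters come from a grid search under stratified
shuffled five-fold cross-validation scored by mean ROC AUC, after which
the final model is refit on the full dataset.  A trained model is
serialised as a portable JSON bundle (support vectors, dual coefficients,
bias, kernel width, standardisation statistics, disease vocabulary).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .family_db import FALSE, TRUE

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
NUMERIC_FEATURES = ("logFC", "R", "zrank_score")

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass
class HyperParams:
    """SVM hyperparameters: soft-margin trade-off C and RBF width gamma."""

    C: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


@dataclass
class FeatureStats:
    """Standardisation statistics and disease vocabulary fit on training data."""

    means: np.ndarray
    scales: np.ndarray
    vocab: list[str]


def build_features(
    de_results: pd.DataFrame,
    correlations: pd.DataFrame,
    docking: pd.DataFrame,
    pairs: pd.DataFrame,
    layer: str,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Inner-join DE, correlation and docking evidence per pair per cancer.

    Parameters
    ----------
    de_results
        Columns gene, cancer, logFC, is_deg (all cancers concatenated).
    correlations
        Columns trim, gene, cancer, rho, significant.
    docking
        Columns trim, target, zrank_score (one row per pair).
    pairs
        Columns trim, target and optionally label.

    Returns
    -------
    (records, losses): the surviving feature rows
    (trim, target, cancer, logFC, R, zrank_score, label) and a count of
    dropped candidates by cause (no_de / not_deg / no_correlation /
    not_significant / no_docking).
    """
    for col in ("gene", "cancer", "logFC", "is_deg"):
        if col not in de_results.columns:
            raise ValueError(f"de_results missing column {col!r}")
    base = pairs[["trim", "target"]].copy()
    base["label"] = pairs["label"] if "label" in pairs else "UNLABELED"
    cancers = sorted(de_results["cancer"].unique())
    cand = base.merge(pd.DataFrame({"cancer": cancers}), how="cross")

    losses = {"no_de": 0, "not_deg": 0, "no_correlation": 0, "not_significant": 0, "no_docking": 0}
    m = cand.merge(
        de_results[["gene", "cancer", "logFC", "is_deg"]],
        left_on=["target", "cancer"],
        right_on=["gene", "cancer"],
        how="left",
    ).drop(columns="gene")
    losses["no_de"] = int(m["is_deg"].isna().sum())
    m = m.dropna(subset=["is_deg"])
    losses["not_deg"] = int((~m["is_deg"].astype(bool)).sum())
    m = m[m["is_deg"].astype(bool)].drop(columns="is_deg")

    m = m.merge(
        correlations[["trim", "gene", "cancer", "rho", "significant"]],
        left_on=["trim", "target", "cancer"],
        right_on=["trim", "gene", "cancer"],
        how="left",
    ).drop(columns="gene")
    losses["no_correlation"] = int(m["significant"].isna().sum())
    m = m.dropna(subset=["significant"])
    losses["not_significant"] = int((~m["significant"].astype(bool)).sum())
    m = m[m["significant"].astype(bool)].drop(columns="significant")
    m = m.rename(columns={"rho": "R"})

    m = m.merge(docking[["trim", "target", "zrank_score"]], on=["trim", "target"], how="left")
    losses["no_docking"] = int(m["zrank_score"].isna().sum())
    m = m.dropna(subset=["zrank_score"])

    logger.info("build_features (%s): %d records kept, losses %s", layer, len(m), losses)
    cols = ["trim", "target", "cancer", "logFC", "R", "zrank_score", "label"]
    return m[cols].reset_index(drop=True), losses


def standardize(
    records: pd.DataFrame, fit_stats: FeatureStats | None = None
) -> tuple[np.ndarray, FeatureStats]:
    """Encode records as a design matrix: z-scored numerics + disease one-hot.

    With ``fit_stats`` absent the statistics are fit on ``records``
    (population sd; a zero-variance feature is an error).  With
    ``fit_stats`` given they are applied verbatim, and an unseen cancer
    code is a vocabulary error — never an all-zero row.
    """
    num = records.loc[:, list(NUMERIC_FEATURES)].to_numpy(dtype=float)
    if not np.isfinite(num).all():
        raise ValueError("numeric features must be finite")
    if fit_stats is None:
        means = num.mean(axis=0)
        scales = num.std(axis=0)
        for name, s in zip(NUMERIC_FEATURES, scales):
            if s == 0:
                raise ValueError(f"zero-variance feature at fit time: {name}")
        vocab = sorted(records["cancer"].unique())
        fit_stats = FeatureStats(means, scales, vocab)
    unseen = set(records["cancer"]) - set(fit_stats.vocab)
    if unseen:
        raise ValueError(f"unseen disease code(s): {sorted(unseen)}")
    z = (num - fit_stats.means) / fit_stats.scales
    onehot = np.zeros((len(records), len(fit_stats.vocab)))
    col = {c: j for j, c in enumerate(fit_stats.vocab)}
    for i, c in enumerate(records["cancer"]):
        onehot[i, col[c]] = 1.0
    return np.hstack([z, onehot]), fit_stats


def rbf_kernel(x, y, gamma: float) -> float:
    """exp(-gamma * ||x - y||^2) over the full encoded feature vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((x - y) ** 2)))


def _labels_to_binary(labels: pd.Series) -> np.ndarray:
    bad = set(labels.unique()) - {TRUE, FALSE}
    if bad:
        raise ValueError(f"records carry non-binary labels: {sorted(bad)}")
    return (labels == TRUE).to_numpy(dtype=int)


@dataclass
class ModelBundle:
    """A trained classifier plus everything needed to reapply it.

    The decision function is f(x) = sum_i coef_i K(sv_i, x) + b with the
    RBF kernel; f(x) > 0 predicts TRUE (the CIV class, mapped to 1).
    """

    layer: str
    hyper: HyperParams
    stats: FeatureStats
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    metadata: dict = field(default_factory=dict)
    schema: int = SCHEMA_VERSION

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + np.sum(self.support_vectors**2, axis=1)[None, :]
        )
        K = np.exp(-self.hyper.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def save(self, path) -> None:
        doc = {
            "schema": self.schema,
            "layer": self.layer,
            "C": self.hyper.C,
            "gamma": self.hyper.gamma,
            "means": self.stats.means.tolist(),
            "scales": self.stats.scales.tolist(),
            "vocab": self.stats.vocab,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path) as fh:
            doc = json.load(fh)
        if doc["schema"] > SCHEMA_VERSION:
            raise ValueError(
                f"model bundle schema {doc['schema']} is newer than supported {SCHEMA_VERSION}"
            )
        return cls(
            layer=doc["layer"],
            hyper=HyperParams(doc["C"], doc["gamma"]),
            stats=FeatureStats(
                np.asarray(doc["means"]), np.asarray(doc["scales"]), list(doc["vocab"])
            ),
            support_vectors=np.asarray(doc["support_vectors"]),
            dual_coef=np.asarray(doc["dual_coef"]),
            intercept=float(doc["intercept"]),
            metadata=doc.get("metadata", {}),
            schema=int(doc["schema"]),
        )


def train(
    records: pd.DataFrame,
    hyper: HyperParams | None = None,
    layer: str = "MS",
    class_weight: str | None = None,
    metadata: dict | None = None,
) -> ModelBundle:
    """Fit the soft-margin RBF SVM on labelled records.

    Standardisation statistics are fit here (training data only) and
    stored in the bundle for prediction time.
    """
    hyper = hyper or HyperParams()
    y = _labels_to_binary(records["label"])
    if len(np.unique(y)) < 2:
        raise ValueError("training needs both TRUE and FALSE records")
    X, stats_ = standardize(records)
    svc = SVC(C=hyper.C, gamma=hyper.gamma, kernel="rbf", class_weight=class_weight)
    svc.fit(X, y)
    return ModelBundle(
        layer=layer,
        hyper=hyper,
        stats=stats_,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        metadata=metadata or {},
    )


def predict(bundle: ModelBundle, records: pd.DataFrame) -> pd.DataFrame:
    """Decision score and TRUE/FALSE call per record.

    Records are standardised with the bundle's stored statistics; an
    unknown cancer code raises rather than silently producing an all-zero
    one-hot row.
    """
    X, _ = standardize(records, fit_stats=bundle.stats)
    f = bundle.decision_function(X)
    out = records[["trim", "target", "cancer"]].copy()
    out["score"] = f
    out["predicted"] = np.where(f > 0, TRUE, FALSE)
    return out


def cross_val_scores(
    records: pd.DataFrame,
    hyper: HyperParams,
    n_folds: int = 5,
    seed: int = 0,
    class_weight: str | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Held-out decision scores under stratified shuffled k-fold CV.

    Standardisation is refit on each training split only — the held-out
    fold never leaks into the feature statistics.  Returns one
    (scores, labels) array pair per fold.
    """
    y = _labels_to_binary(records["label"])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("a CV fold lost one of the classes; reduce n_folds")
        X_tr, st = standardize(records.iloc[tr])
        X_te, _ = standardize(records.iloc[te], fit_stats=st)
        svc = SVC(C=hyper.C, gamma=hyper.gamma, kernel="rbf", class_weight=class_weight)
        svc.fit(X_tr, y[tr])
        folds.append((svc.decision_function(X_te), y[te]))
    return folds


def grid_search_cv(
    records: pd.DataFrame,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    n_folds: int = 5,
    seed: int = 0,
    class_weight: str | None = None,
) -> tuple[HyperParams, pd.DataFrame]:
    """Select (C, gamma) by mean held-out AUC over a stratified shuffled CV.

    Ties break toward the smaller C, then the smaller gamma.  The caller
    retrains on the full dataset with the winning cell (see
    :func:`train`).
    """
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be non-empty")
    y = _labels_to_binary(records["label"])
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError("each class needs at least n_folds members")
    rows = []
    best: tuple[float, HyperParams] | None = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            hp = HyperParams(C, gamma)
            folds = cross_val_scores(records, hp, n_folds, seed, class_weight)
            aucs = [roc_auc_score(yt, sc) for sc, yt in folds]
            mean_auc = float(np.mean(aucs))
            rows.append({"C": C, "gamma": gamma, "mean_auc": mean_auc, "sd_auc": float(np.std(aucs, ddof=1))})
            if best is None or mean_auc > best[0]:
                best = (mean_auc, hp)
    assert best is not None
    logger.info("grid search best: C=%g gamma=%g (AUC %.3f)", best[1].C, best[1].gamma, best[0])
    return best[1], pd.DataFrame(rows)
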