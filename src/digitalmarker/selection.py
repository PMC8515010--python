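"""KNN model selection and evaluation for digital markers.

Given the ranked candidate list from screening, the marker is finalized
by enumerating its size ``m`` (1..30, in rank order) jointly with the
KNN neighbor count ``k`` under stratified 5-fold cross-validation and
keeping the pair with the highest mean CV AUC (ties resolve to the
smaller ``m``, then the smaller ``k``).  Features are log10(1+TPM),
standardized per gene with training statistics; distances are Euclidean;
distance ties break by training-sample index order.

Two evaluation regimes are provided.  The default enumerates on a
ranking computed once from the full dataset, which mirrors common
practice but lets the screen see the evaluation folds; the honest
estimator :func:`nested_cv_auc` re-runs screening *and* the (m, k)
choice inside each outer training set, so its AUC is unbiased and sits
near 0.5 when there is no signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .datamodel import (
    EFFECTIVE,
    INEFFECTIVE,
    CohortPair,
    DrugResponse,
    ExpressionMatrix,
    ValidationError,
    align_expression_response,
)
from . import screening as _screening

DEFAULT_K_GRID = tuple(range(1, 31))
M_MAX = 30

ScreenFn = Callable[[ExpressionMatrix, DrugResponse], Sequence[str]]


# ---------------------------------------------------------------------------
# metrics

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by exact pairwise concordance.

    ``labels`` are truthy for the positive class; higher score = more
    positive.  Computed through the rank-sum identity, which equals
    (concordant + 0.5 * tied pairs) / (n_pos * n_neg) exactly.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels, dtype=bool)
    if scores.shape != pos.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: only one class present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class EvalReport:
    """Confusion-matrix metrics plus AUC/ROC for one evaluation run."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1_weighted: float
    auc: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    roc_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc_points"] = [list(p) for p in self.roc_points]
        return d


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def _roc_points(scores: np.ndarray, pos: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) at every distinct score threshold, ties pooled."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], pos[order]
    n_pos, n_neg = y.sum(), (~y).sum()
    pts = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += int(y[j])
            fp += int(~y[j])
            j += 1
        pts.append((fp / n_neg, tp / n_pos))
        i = j
    return pts


def classification_metrics(pred_labels, true_labels,
                           scores=None) -> EvalReport:
    """Standard confusion-matrix metrics; positive = sensitive/effective.

    ``pred_labels``/``true_labels`` are boolean vectors (True =
    positive).  ``f1_weighted`` is the support-weighted mean of the two
    per-class F1 scores.  When ``scores`` is given (higher = more
    positive) the AUC and ROC points are included.
    """
    pred = np.asarray(pred_labels, dtype=bool)
    true = np.asarray(true_labels, dtype=bool)
    if pred.shape != true.shape:
        raise ValidationError("prediction/truth length mismatch")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    tn = int(np.sum(~pred & ~true))
    fn = int(np.sum(~pred & true))
    total = tp + fp + tn + fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1_pos = _safe_div(2 * precision * recall, precision + recall)
    prec_neg = _safe_div(tn, tn + fn)
    f1_neg = _safe_div(2 * prec_neg * specificity, prec_neg + specificity)
    support_pos, support_neg = tp + fn, tn + fp
    f1_weighted = _safe_div(f1_pos * support_pos + f1_neg * support_neg, total)
    auc = None
    roc = []
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        auc = roc_auc(scores, true)
        roc = _roc_points(scores, true)
    return EvalReport(accuracy=_safe_div(tp + tn, total), precision=precision,
                      recall=recall, specificity=specificity,
                      f1_weighted=f1_weighted, auc=auc,
                      tp=tp, fp=fp, tn=tn, fn=fn, roc_points=roc)


# ---------------------------------------------------------------------------
# the digital marker

@dataclass
class DigitalMarker:
    """A frozen KNN predictor over a short ordered gene list.

    ``train_X`` holds the standardized log10(1+TPM) training matrix
    (samples x genes); ``train_y`` is the training Z-scores (regression)
    or a boolean ineffective indicator (classification).  ``gene_mean``/
    ``gene_sd`` are the per-gene standardization statistics on the
    log10(1+TPM) scale.
    """

    cancer_type: str
    drug: str
    genes: list[str]
    k0: int
    task: str  # "regression" | "classification"
    train_X: np.ndarray
    train_y: np.ndarray
    gene_mean: np.ndarray
    gene_sd: np.ndarray
    train_samples: list[str]
    cv_auc: float | None = None
    z_threshold: float = -1.0

    def __post_init__(self) -> None:
        self.train_X = np.asarray(self.train_X, dtype=float)
        self.gene_mean = np.asarray(self.gene_mean, dtype=float)
        self.gene_sd = np.asarray(self.gene_sd, dtype=float)
        m = len(self.genes)
        if not 1 <= m <= M_MAX:
            raise ValidationError(f"marker size must be in [1, {M_MAX}], got {m}")
        if self.task not in ("regression", "classification"):
            raise ValidationError(f"unknown task {self.task!r}")
        n = self.train_X.shape[0]
        if not 1 <= self.k0 <= n:
            raise ValidationError(f"k0 must be in [1, {n}], got {self.k0}")
        if self.train_X.shape[1] != m:
            raise ValidationError("training matrix width must equal marker size")
        if np.any(self.gene_sd <= 0):
            raise ValidationError("standardization SDs must be positive")
        if self.task == "regression":
            self.train_y = np.asarray(self.train_y, dtype=float)
        else:
            self.train_y = np.asarray(self.train_y, dtype=bool)

    @property
    def m0(self) -> int:
        return len(self.genes)

    def transform(self, query) -> tuple[np.ndarray, list[str]]:
        """Standardize query TPM vectors into marker feature space.

        ``query`` is an :class:`ExpressionMatrix` or a gene-by-sample
        DataFrame of TPM.  Returns (n_query x m0 array, sample ids).
        """
        df = query.values if isinstance(query, ExpressionMatrix) else query
        missing = [g for g in self.genes if g not in df.index]
        if missing:
            raise ValidationError(f"query lacks marker genes: {missing}")
        mat = np.log10(1.0 + df.loc[self.genes].to_numpy(dtype=float).T)
        return (mat - self.gene_mean) / self.gene_sd, list(df.columns)

    def to_json(self, path) -> None:
        obj = {
            "cancer_type": self.cancer_type, "drug": self.drug,
            "genes": self.genes, "k0": int(self.k0), "task": self.task,
            "train_X": self.train_X.tolist(),
            "train_y": np.asarray(self.train_y).tolist(),
            "gene_mean": self.gene_mean.tolist(),
            "gene_sd": self.gene_sd.tolist(),
            "train_samples": self.train_samples,
            "cv_auc": self.cv_auc, "z_threshold": self.z_threshold,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DigitalMarker":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(**obj)


def _stable_neighbor_order(d2: np.ndarray) -> np.ndarray:
    """Row-wise neighbor order by squared distance, ties to lower index."""
    return np.argsort(d2, axis=1, kind="stable")


def _sq_distances(query_X: np.ndarray, train_X: np.ndarray) -> np.ndarray:
    diff = query_X[:, None, :] - train_X[None, :, :]
    return np.einsum("qtm,qtm->qt", diff, diff)


def knn_regress(marker: DigitalMarker, query) -> pd.Series:
    """Predict Z-scores as the unweighted mean of the k0 nearest neighbors."""
    if marker.task != "regression":
        raise ValidationError("marker is not a regression model")
    qx, samples = marker.transform(query)
    order = _stable_neighbor_order(_sq_distances(qx, marker.train_X))
    nn = order[:, : marker.k0]
    preds = marker.train_y[nn].mean(axis=1)
    return pd.Series(preds, index=samples, name="predicted_z")


def knn_classify(marker: DigitalMarker, query) -> pd.DataFrame:
    """Predict the ineffectiveness probability as the neighbor vote fraction.

    ``p_ineffective`` = (# ineffective among k0 nearest)/k0; the label is
    ineffective when p >= 0.5 (ties resolve conservatively to
    ineffective).  A zone column per :func:`~digitalmarker.conversion.zone_of`
    is included.
    """
    if marker.task != "classification":
        raise ValidationError("marker is not a classification model")
    from .conversion import zone_of  # local import to avoid a cycle
    qx, samples = marker.transform(query)
    order = _stable_neighbor_order(_sq_distances(qx, marker.train_X))
    nn = order[:, : marker.k0]
    p = marker.train_y[nn].mean(axis=1)  # train_y: True = ineffective
    labels = np.where(p >= 0.5, INEFFECTIVE, EFFECTIVE)
    zones = [zone_of(pi) for pi in p]
    return pd.DataFrame({"p_ineffective": p, "label": labels, "zone": zones},
                        index=samples)


# ---------------------------------------------------------------------------
# cross-validated (m, k) enumeration

def _prepare(x: ExpressionMatrix, r: DrugResponse, task: str,
             z_threshold: float):
    vals, rr = align_expression_response(x, r)
    logv = np.log10(1.0 + vals.to_numpy(dtype=float).T)  # samples x genes
    gene_pos = {g: i for i, g in enumerate(vals.index)}
    if task == "regression":
        if rr.mode != "continuous":
            raise ValidationError("regression task needs a continuous response")
        y_knn = rr.z.astype(float)
        pos = rr.z <= z_threshold  # positive = sensitive
    elif task == "classification":
        if rr.mode != "binary":
            raise ValidationError("classification task needs a binary response")
        y_knn = (rr.label == INEFFECTIVE).astype(float)
        pos = rr.label == EFFECTIVE
    else:
        raise ValidationError(f"unknown task {task!r}")
    return vals, rr, logv, gene_pos, y_knn, np.asarray(pos, dtype=bool)


def _standardize(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _fold_prefix_predictions(logv, gene_idx, y_knn, train_idx, test_idx,
                             ks: Sequence[int]) -> np.ndarray:
    """KNN predictions for every gene-prefix length and every k.

    Returns an array (M, K, n_test) of mean neighbor responses, where
    prefix m uses the first m genes of ``gene_idx``.  Distances
    accumulate gene by gene so the whole (m, k) grid costs one stable
    sort per prefix.
    """
    sub = logv[:, gene_idx]
    mean, sd = _standardize(sub[train_idx])
    tr = (sub[train_idx] - mean) / sd
    te = (sub[test_idx] - mean) / sd
    y_tr = y_knn[train_idx]
    M = len(gene_idx)
    out = np.empty((M, len(ks), len(test_idx)))
    d2 = np.zeros((len(test_idx), len(train_idx)))
    for mi in range(M):
        d2 += (te[:, mi][:, None] - tr[:, mi][None, :]) ** 2
        order = _stable_neighbor_order(d2)
        cums = np.cumsum(y_tr[order], axis=1)
        for ki, k in enumerate(ks):
            out[mi, ki] = cums[:, k - 1] / k
    return out


def cv_auc_grid(ranked_genes: Sequence[str], x: ExpressionMatrix,
                r: DrugResponse, task: str = "regression",
                z_threshold: float = -1.0,
                k_grid: Sequence[int] = DEFAULT_K_GRID, folds: int = 5,
                seed: int = 0, screen_fn: ScreenFn | None = None,
                m_max: int = M_MAX) -> tuple[np.ndarray, list[int]]:
    """Mean CV AUC for every (m, k) on the enumeration grid.

    Returns (grid, ks) where ``grid[m-1, ki]`` is the mean over folds of
    the test-fold AUC using the top-m genes and ``k = ks[ki]``
    neighbors; ranking score is the negated KNN prediction (-predicted z
    for regression, 1 - p_ineffective up to an order-preserving shift
    for classification).  When ``screen_fn`` is given, the gene ranking
    is recomputed on each training fold (the full-data ``ranked_genes``
    only caps the prefix length).
    """
    vals, rr, logv, gene_pos, y_knn, pos = _prepare(x, r, task, z_threshold)
    n = len(rr.samples)
    if n < 10:
        raise ValidationError(f"need >= 10 samples for CV enumeration, got {n}")
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValidationError("need >= 2 samples per class for stratified CV")
    ranked = [g for g in ranked_genes if g in gene_pos][:m_max]
    if not ranked and screen_fn is None:
        raise ValidationError("no ranked genes present in the expression matrix")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(n), pos))
    min_train = min(len(tr) for tr, _ in splits)
    ks = [k for k in k_grid if 1 <= k <= min_train]
    if not ks:
        raise ValidationError("k grid empty after clipping to fold-train size")
    M = m_max if screen_fn is not None else len(ranked)
    sums = np.zeros((M, len(ks)))
    counts = np.zeros((M, len(ks)))
    for tr_idx, te_idx in splits:
        pos_te = pos[te_idx]
        if pos_te.all() or not pos_te.any():
            continue  # AUC undefined on this fold
        if screen_fn is not None:
            sub_x = ExpressionMatrix(vals.iloc[:, tr_idx],
                                     x.cancer_type, x.dataset_tag)
            sub_r = rr.subset_samples([rr.samples[i] for i in tr_idx])
            fold_ranked = [g for g in screen_fn(sub_x, sub_r)
                           if g in gene_pos][:m_max]
            if not fold_ranked:
                continue
        else:
            fold_ranked = ranked
        gene_idx = [gene_pos[g] for g in fold_ranked]
        preds = _fold_prefix_predictions(logv, gene_idx, y_knn, tr_idx, te_idx, ks)
        for mi in range(preds.shape[0]):
            for ki in range(len(ks)):
                sums[mi, ki] += roc_auc(-preds[mi, ki], pos_te)
                counts[mi, ki] += 1
    if not counts.any():
        raise ValidationError("no CV fold produced a defined AUC")
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return grid, ks


def _best_cell(grid: np.ndarray, ks: Sequence[int]) -> tuple[int, int, float]:
    """Arg-max of the (m, k) grid; ties go to smaller m, then smaller k."""
    best = (-np.inf, 0, 0)
    for mi in range(grid.shape[0]):
        for ki in range(grid.shape[1]):
            v = grid[mi, ki]
            if np.isfinite(v) and v > best[0]:
                best = (v, mi, ki)
    if not np.isfinite(best[0]):
        raise ValidationError("CV grid contains no finite AUC")
    return best[1] + 1, ks[best[2]], best[0]


def select_digital_marker(ranked_genes: Sequence[str], x: ExpressionMatrix,
                          r: DrugResponse, task: str = "regression",
                          z_threshold: float = -1.0,
                          k_grid: Sequence[int] = DEFAULT_K_GRID,
                          folds: int = 5, seed: int = 0,
                          screen_fn: ScreenFn | None = None,
                          m_max: int = M_MAX) -> DigitalMarker:
    """Finalize the digital marker by (m, k) enumeration under 5-fold CV.

    Enumerates m = 1..min(30, candidates) prefixes of ``ranked_genes``
    jointly with every k in ``k_grid`` (clipped to the fold-train size),
    scores each pair by mean test-fold AUC and returns the marker with
    the best score; ties prefer the smaller m, then the smaller k.  The
    returned marker's standardization and training reference data are
    refit on the full cohort.
    """
    grid, ks = cv_auc_grid(ranked_genes, x, r, task, z_threshold, k_grid,
                           folds, seed, screen_fn=screen_fn, m_max=m_max)
    m0, k0, best_auc = _best_cell(grid, ks)
    vals, rr, logv, gene_pos, y_knn, pos = _prepare(x, r, task, z_threshold)
    final_ranked = [g for g in (screen_fn(x, r) if screen_fn is not None
                                else ranked_genes) if g in gene_pos][:m_max]
    genes = final_ranked[:m0]
    gene_idx = [gene_pos[g] for g in genes]
    sub = logv[:, gene_idx]
    mean, sd = _standardize(sub)
    train_y = rr.z if task == "regression" else (rr.label == INEFFECTIVE)
    return DigitalMarker(
        cancer_type=x.cancer_type, drug=r.drug, genes=list(genes), k0=k0,
        task=task, train_X=(sub - mean) / sd, train_y=train_y,
        gene_mean=mean, gene_sd=sd, train_samples=list(rr.samples),
        cv_auc=best_auc, z_threshold=z_threshold,
    )


def cv_evaluate(genes: Sequence[str], k: int, x: ExpressionMatrix,
                r: DrugResponse, task: str = "regression",
                z_threshold: float = -1.0, folds: int = 5,
                seed: int = 0) -> EvalReport:
    """Pooled stratified-CV evaluation of a fixed gene list and k.

    Each fold fits standardization + KNN on its training part and
    predicts its test part; predictions are pooled over folds into one
    confusion matrix and ROC.  Predicted labels: regression calls a
    sample sensitive when the predicted z <= ``z_threshold``;
    classification calls ineffective when the vote fraction >= 0.5.
    """
    vals, rr, logv, gene_pos, y_knn, pos = _prepare(x, r, task, z_threshold)
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        raise ValidationError(f"genes not in expression matrix: {missing}")
    gene_idx = [gene_pos[g] for g in genes]
    n = len(rr.samples)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(n)
    pred_pos = np.empty(n, dtype=bool)
    for tr_idx, te_idx in skf.split(np.zeros(n), pos):
        kf = min(k, len(tr_idx))
        preds = _fold_prefix_predictions(logv, gene_idx, y_knn, tr_idx, te_idx,
                                         [kf])[-1, 0]
        scores[te_idx] = -preds
        if task == "regression":
            pred_pos[te_idx] = preds <= z_threshold
        else:
            pred_pos[te_idx] = preds < 0.5  # positive = effective
    return classification_metrics(pred_pos, pos, scores=scores)


def nested_cv_auc(x: ExpressionMatrix, r: DrugResponse, screen_fn: ScreenFn,
                  task: str = "regression", z_threshold: float = -1.0,
                  k_grid: Sequence[int] = DEFAULT_K_GRID,
                  outer_folds: int = 5, inner_folds: int = 5,
                  seed: int = 0, m_max: int = M_MAX) -> float:
    """Honest generalization AUC with screening and (m, k) choice nested.

    Outer stratified folds are held out for evaluation only; inside each
    outer training set the screen is re-run and (m, k) selected by inner
    CV.  Scores are pooled over the outer test folds into one AUC.
    Under a null cohort (no expression-response association) this
    estimator concentrates near 0.5, unlike enumeration on a full-data
    ranking, which is inflated both by screening leakage and by the
    winner's curse of maximizing over the (m, k) grid.
    """
    vals, rr, logv, gene_pos, y_knn, pos = _prepare(x, r, task, z_threshold)
    n = len(rr.samples)
    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    scores = np.empty(n)
    for fold_i, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(n), pos)):
        sub_x = ExpressionMatrix(vals.iloc[:, tr_idx], x.cancer_type,
                                 x.dataset_tag)
        sub_r = rr.subset_samples([rr.samples[i] for i in tr_idx])
        ranked = [g for g in screen_fn(sub_x, sub_r) if g in gene_pos][:m_max]
        if not ranked:  # nothing screened: uninformative constant score
            scores[te_idx] = 0.0
            continue
        try:
            grid, ks = cv_auc_grid(ranked, sub_x, sub_r, task, z_threshold,
                                   k_grid, inner_folds, seed=seed + fold_i + 1,
                                   m_max=m_max)
            m0, k0, _ = _best_cell(grid, ks)
        except ValidationError:
            m0, k0 = len(ranked), 1
        gene_idx = [gene_pos[g] for g in ranked[:m0]]
        preds = _fold_prefix_predictions(logv, gene_idx, y_knn, tr_idx, te_idx,
                                         [min(k0, len(tr_idx))])[-1, 0]
        scores[te_idx] = -preds
    return roc_auc(scores, pos)


# ---------------------------------------------------------------------------
# cross-prediction harness

def _dataset_ranking(x: ExpressionMatrix, r: DrugResponse,
                     cfg: _screening.FilterConfig) -> list[str]:
    scores, _ = _screening.screen_cell_line_dataset(x, r, cfg)
    return list(_screening.rank_single(scores).index)


def run_cross_prediction(pair: CohortPair, method: int,
                         cfg: _screening.FilterConfig | None = None,
                         task: str = "regression", z_threshold: float = -1.0,
                         k_grid: Sequence[int] = DEFAULT_K_GRID,
                         folds: int = 5, seed: int = 0,
                         m_max: int = M_MAX) -> dict[str, EvalReport]:
    """Evaluate the three screening/prediction regimes on a cohort pair.

    * method 1 — screen both datasets, add the per-gene scores into one
      combined ranking, then select and evaluate by 5-fold CV within
      each dataset separately;
    * method 2 — screen, select and evaluate within the same dataset;
    * method 3 — cross-prediction: the gene ranking *and* the selected
      (m0, k0) come from the other dataset; the evaluation dataset only
      runs fixed 5-fold CV with those choices, so it never informs any
      model decision.

    Returns a dict keyed by ``dataset_tag`` with one report each.
    """
    cfg = cfg or _screening.FilterConfig()
    datasets = {
        pair.expression_a.dataset_tag or "a": (pair.expression_a, pair.response_a),
        pair.expression_b.dataset_tag or "b": (pair.expression_b, pair.response_b),
    }
    tags = list(datasets)
    reports: dict[str, EvalReport] = {}
    if method == 1:
        table = _screening.screen_cell_line_pair(pair, cfg)
        ranking = list(table.index)
        for tag, (x, r) in datasets.items():
            marker = select_digital_marker(ranking, x, r, task, z_threshold,
                                           k_grid, folds, seed, m_max=m_max)
            reports[tag] = cv_evaluate(marker.genes, marker.k0, x, r, task,
                                       z_threshold, folds, seed)
    elif method == 2:
        for tag, (x, r) in datasets.items():
            ranking = _dataset_ranking(x, r, cfg)
            marker = select_digital_marker(ranking, x, r, task, z_threshold,
                                           k_grid, folds, seed, m_max=m_max)
            reports[tag] = cv_evaluate(marker.genes, marker.k0, x, r, task,
                                       z_threshold, folds, seed)
    elif method == 3:
        for tag, other in zip(tags, reversed(tags)):
            x, r = datasets[tag]
            ox, orr = datasets[other]
            ranking = _dataset_ranking(ox, orr, cfg)
            marker = select_digital_marker(ranking, ox, orr, task, z_threshold,
                                           k_grid, folds, seed, m_max=m_max)
            genes = [g for g in marker.genes if g in set(x.genes)]
            if not genes:
                raise ValidationError(
                    "cross-prediction impossible: no marker gene shared"
                )
            reports[tag] = cv_evaluate(genes, marker.k0, x, r, task,
                                       z_threshold, folds, seed)
    else:
        raise ValidationError(f"method must be 1, 2 or 3, got {method}")
    return reports


# ---------------------------------------------------------------------------
# 2D decision map

def project_2d_map(marker: DigitalMarker, extra_points=None,
                   k: int | None = None, grid_size: int = 50,
                   margin: float = 0.5) -> dict:
    """2D PCA coordinates plus a KNN class-probability field.

    The top two principal components of the standardized training matrix
    give the map; extra query points (TPM, gene-by-sample) are projected
    with the same loadings.  The background field is the KNN
    ineffectiveness probability computed *in the 2D space* on a
    grid_size x grid_size lattice with ``k`` neighbors (marker's k0 by
    default).
    """
    if marker.m0 < 2:
        raise ValidationError("2D projection needs a marker with >= 2 genes")
    k = k or marker.k0
    pca = PCA(n_components=2)
    coords = pca.fit_transform(marker.train_X)
    extra_coords = None
    if extra_points is not None:
        qx, _ = marker.transform(extra_points)
        extra_coords = pca.transform(qx)
    if marker.task == "classification":
        ineff = np.asarray(marker.train_y, dtype=bool)
    else:
        ineff = marker.train_y > marker.z_threshold
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(gx, gy)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    order = _stable_neighbor_order(_sq_distances(pts, coords))
    k = min(k, coords.shape[0])
    field = ineff[order[:, :k]].mean(axis=1).reshape(grid_size, grid_size)
    return {"coords": coords, "extra_coords": extra_coords,
            "grid_x": gx, "grid_y": gy, "p_ineffective": field}
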