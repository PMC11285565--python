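"""Connectome-based predictive modeling (CPM).

The procedure, per cross-validation fold:

1. *Edge selection.*  Within the training subjects, relate each edge's weight
   to the behavioral score by partial Pearson correlation controlling for the
   configured covariates (head motion, age and their interaction by default).
   Edges with two-sided ``p < alpha`` (t-transform of the partial correlation,
   ``df = n - 2 - n_covariates``) enter the positive or negative set by the
   sign of the partial correlation.
2. *Summed connectivity.*  Each subject's selected-edge weights are collapsed
   to one scalar: sum over positive edges minus sum over negative edges
   ("combined" mode; positive-only / negative-only modes sum one set).
3. *Linear model.*  Ordinary least squares of score on summed connectivity in
   the training set; the fitted line predicts the held-out fold.

One *iteration* is a fresh random k-fold partition with steps 1-3 per fold,
yielding exactly one out-of-fold prediction per subject.  The ensemble runs
``n_iterations`` such partitions; the iteration with median out-of-fold
Spearman rho represents the model.

Folds in which no edge survives selection (or summed connectivity is
constant) are flagged degenerate and predict the training-mean score, keeping
the ensemble intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .stats import rmse, spearman_rho

COVARIATE_CHOICES = ("ffd", "age", "ffd_x_age")


@dataclass(frozen=True)
class CPMConfig:
    """Configuration of one CPM ensemble."""

    k_folds: int = 5
    n_iterations: int = 1000
    selection_alpha: float = 0.01
    covariates: tuple[str, ...] = COVARIATE_CHOICES
    model_mode: str = "combined"          # combined | positive | negative
    covariates_in_model: bool = False     # add covariates to the fold OLS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.selection_alpha < 1.0):
            raise ValueError("selection_alpha must be in (0, 1)")
        if self.model_mode not in ("combined", "positive", "negative"):
            raise ValueError(f"unknown model_mode {self.model_mode!r}")


@dataclass
class EdgeSelection:
    """Signed edge sets chosen in one training fold."""

    positive: np.ndarray   # edge indices, partial r > 0, p < alpha
    negative: np.ndarray   # edge indices, partial r < 0, p < alpha
    r: np.ndarray | None = None   # per-edge partial correlation (optional)
    p: np.ndarray | None = None   # per-edge two-sided p-value (optional)

    def __post_init__(self) -> None:
        self.positive = np.asarray(self.positive, dtype=np.intp)
        self.negative = np.asarray(self.negative, dtype=np.intp)
        if np.intersect1d(self.positive, self.negative).size:
            raise ValueError("positive and negative edge sets overlap")

    def n_selected(self, mode: str = "combined") -> int:
        if mode == "positive":
            return self.positive.size
        if mode == "negative":
            return self.negative.size
        return self.positive.size + self.negative.size


@dataclass
class FoldModel:
    """Linear map from summed connectivity to score, fit in one fold."""

    slope: float
    intercept: float
    selection: EdgeSelection
    degenerate: bool = False
    fold_id: int = 0


@dataclass
class CPMIterationResult:
    """One k-fold partition's models and out-of-fold predictions."""

    index: int
    fold_assignment: np.ndarray          # length n_subjects, values 0..k-1
    fold_models: list[FoldModel]
    predictions: np.ndarray              # out-of-fold prediction per subject
    rho: float
    rmse: float


def select_edges(X: np.ndarray, y: np.ndarray, covariates: np.ndarray | None,
                 alpha: float = 0.01, keep_stats: bool = False) -> EdgeSelection:
    """Partial-correlation edge screening.

    Both each edge column of ``X`` (subjects x edges) and the score ``y`` are
    residualized on an intercept plus the covariate columns; the Pearson
    correlation of the residuals is the partial correlation, with p-value from
    ``t = r * sqrt(df / (1 - r^2))``, ``df = n - 2 - n_covariates``.  With no
    covariates this reduces to plain Pearson screening.  Constant edges get
    r = 0 and are never selected.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X rows must match y length")
    c = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    if covariates is not None and np.atleast_2d(covariates).shape[0] != n:
        raise ValueError("covariate rows must match y length")
    if n < c + 3:
        raise ValueError(f"need >= {c + 3} subjects for {c} covariates")
    if np.ptp(y) == 0:
        raise ValueError("constant score vector: selection undefined")

    design = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, float)])
    q, _ = np.linalg.qr(design)
    Xr = X - q @ (q.T @ X)
    yr = y - q @ (q.T @ y)
    xn = np.sqrt(np.einsum("ij,ij->j", Xr, Xr))
    yn = float(np.sqrt(yr @ yr))
    # an edge whose residual norm is at rounding scale relative to its raw
    # norm is constant or fully explained by the covariates: r defined as 0
    raw_norm = np.sqrt(np.einsum("ij,ij->j", X, X))
    ok = xn > 1e-8 * np.maximum(raw_norm, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ok, (Xr.T @ yr) / np.where(ok, xn, 1.0) / yn, 0.0)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - c
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    hit = p < alpha
    return EdgeSelection(
        positive=np.flatnonzero(hit & (r > 0)),
        negative=np.flatnonzero(hit & (r < 0)),
        r=r if keep_stats else None,
        p=p if keep_stats else None,
    )


def summed_connectivity(X: np.ndarray, selection: EdgeSelection,
                        mode: str = "combined") -> np.ndarray:
    """Collapse selected-edge weights to a per-subject scalar.

    combined: sum(positive) - sum(negative); positive/negative: one-set sum.
    ``X`` may be a single edge vector or a subjects x edges matrix.
    """
    X2 = np.atleast_2d(np.asarray(X, float))
    pos = X2[:, selection.positive].sum(axis=1)
    neg = X2[:, selection.negative].sum(axis=1)
    if mode == "positive":
        out = pos
    elif mode == "negative":
        out = neg
    elif mode == "combined":
        out = pos - neg
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if np.asarray(X).ndim == 2 else float(out[0])


def fit_fold(X_train: np.ndarray, y_train: np.ndarray, selection: EdgeSelection,
             mode: str = "combined", fold_id: int = 0) -> FoldModel:
    """OLS of score on summed connectivity; degenerate folds fall back to the
    training mean (slope 0)."""
    y_train = np.asarray(y_train, float)
    if y_train.size < 3:
        raise ValueError("need >= 3 training subjects")
    if selection.n_selected(mode) == 0:
        return FoldModel(0.0, float(y_train.mean()), selection, True, fold_id)
    s = summed_connectivity(X_train, selection, mode)
    sc = s - s.mean()
    ss = float(sc @ sc)
    if ss == 0.0:
        return FoldModel(0.0, float(y_train.mean()), selection, True, fold_id)
    slope = float(sc @ (y_train - y_train.mean())) / ss
    intercept = float(y_train.mean() - slope * s.mean())
    return FoldModel(slope, intercept, selection, False, fold_id)


def predict(model: FoldModel, X_test: np.ndarray, mode: str = "combined") -> np.ndarray:
    """Apply a fold model to test-subject edge vectors."""
    if model.degenerate:
        return np.full(np.atleast_2d(X_test).shape[0], model.intercept)
    s = summed_connectivity(X_test, model.selection, mode)
    return model.slope * np.atleast_1d(s) + model.intercept


def make_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Unstratified random partition into k folds with sizes differing by <=1."""
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} subjects")
    assignment = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for f, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = f
    return assignment


def _covariate_matrix(cov_df, names: tuple[str, ...]) -> np.ndarray | None:
    """Assemble the covariate design from a mapping of name -> vector.

    ``ffd_x_age`` is built as the elementwise product of ffd and age.
    """
    if not names:
        return None
    cols = []
    for nm in names:
        if nm == "ffd_x_age":
            cols.append(np.asarray(cov_df["ffd"], float) * np.asarray(cov_df["age"], float))
        else:
            cols.append(np.asarray(cov_df[nm], float))
    return np.column_stack(cols)


def run_cpm(X: np.ndarray, y: np.ndarray, covariates: dict | None,
            config: CPMConfig, keep_stats: bool = False,
            ) -> list[CPMIterationResult]:
    """Run the full CPM ensemble.

    Parameters
    ----------
    X
        Subjects x edges matrix of Fisher-z weights.
    y
        Behavioral score per subject.
    covariates
        Mapping with keys ``ffd`` and ``age`` (vectors per subject), or None.
        The covariates named in ``config.covariates`` are assembled from it.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = y.size
    if n < config.k_folds:
        raise ValueError(f"{n} subjects < {config.k_folds} folds")
    C = _covariate_matrix(covariates, config.covariates) if covariates else None
    rng = np.random.default_rng(config.seed)
    results = []
    for it in range(config.n_iterations):
        results.append(_one_iteration(X, y, C, config, rng, it, keep_stats))
    return results


def _one_iteration(X, y, C, config, rng, index, keep_stats) -> CPMIterationResult:
    n = y.size
    folds = make_folds(n, config.k_folds, rng)
    preds = np.empty(n)
    models: list[FoldModel] = []
    for f in range(config.k_folds):
        test = folds == f
        train = ~test
        sel = select_edges(X[train], y[train],
                           None if C is None else C[train],
                           config.selection_alpha, keep_stats)
        if config.covariates_in_model and C is not None:
            model = _fit_fold_with_covariates(X[train], y[train], C[train], sel,
                                              config.model_mode, f)
            preds[test] = _predict_with_covariates(model, X[test], C[test],
                                                   config.model_mode)
        else:
            model = fit_fold(X[train], y[train], sel, config.model_mode, f)
            preds[test] = predict(model, X[test], config.model_mode)
        models.append(model)
    rho = spearman_rho(preds, y, warn=False)
    return CPMIterationResult(index=index, fold_assignment=folds,
                              fold_models=models, predictions=preds,
                              rho=rho, rmse=rmse(preds, y))


def _fit_fold_with_covariates(X_tr, y_tr, C_tr, sel, mode, fold_id) -> FoldModel:
    """Sensitivity variant: covariates enter the fold-level regression."""
    if sel.n_selected(mode) == 0:
        m = FoldModel(0.0, float(np.mean(y_tr)), sel, True, fold_id)
        m.extra_coef = np.zeros(np.atleast_2d(C_tr).shape[1])  # type: ignore[attr-defined]
        return m
    s = summed_connectivity(X_tr, sel, mode)
    D = np.column_stack([np.ones(len(y_tr)), s, C_tr])
    beta, *_ = np.linalg.lstsq(D, y_tr, rcond=None)
    m = FoldModel(float(beta[1]), float(beta[0]), sel, False, fold_id)
    m.extra_coef = beta[2:]  # type: ignore[attr-defined]
    return m


def _predict_with_covariates(model: FoldModel, X_te, C_te, mode) -> np.ndarray:
    base = predict(model, X_te, mode)
    extra = getattr(model, "extra_coef", None)
    if extra is None or model.degenerate:
        return base
    return base + np.atleast_2d(C_te) @ extra


def median_model(results: list[CPMIterationResult]) -> CPMIterationResult:
    """The iteration with median out-of-fold Spearman rho.

    Iterations are ranked by rho ascending (ties broken by lower iteration
    index); the iteration at rank ceil(m/2) — the lower median for even m —
    is returned.  Iterations with undefined rho (all-degenerate folds) are
    excluded from ranking; if none is defined, the first iteration is
    returned.
    """
    if not results:
        raise ValueError("no iterations")
    valid = [r for r in results if np.isfinite(r.rho)]
    if not valid:
        return results[0]
    order = sorted(valid, key=lambda r: (r.rho, r.index))
    return order[(len(order) + 1) // 2 - 1]


def rho_distribution(results: list[CPMIterationResult]) -> np.ndarray:
    return np.array([r.rho for r in results])


@dataclass
class TransferResult:
    """Cross-group model transfer: per-iteration target-group predictions."""

    predictions: np.ndarray   # n_iterations x n_target
    rho: np.ndarray           # per-iteration Spearman rho on the target group
    rmse: np.ndarray

    @property
    def rho_median(self) -> float:
        vals = self.rho[np.isfinite(self.rho)]
        return float(np.median(vals)) if vals.size else float("nan")


def transfer_model(X_src: np.ndarray, y_src: np.ndarray, cov_src: dict | None,
                   X_tgt: np.ndarray, y_tgt: np.ndarray,
                   config: CPMConfig) -> TransferResult:
    """Train within the source group, predict every target-group subject.

    Each iteration runs the full fold-wise selection + fit inside the source
    group; all k fold models predict the whole target group and their
    predictions are averaged before scoring.  Applying a group's model to
    itself is a valid degenerate case (resubstitution-style evaluation).
    """
    X_tgt = np.asarray(X_tgt, float)
    y_tgt = np.asarray(y_tgt, float)
    if y_tgt.size == 0:
        raise ValueError("empty target group")
    X_src = np.asarray(X_src, float)
    y_src = np.asarray(y_src, float)
    C = _covariate_matrix(cov_src, config.covariates) if cov_src else None
    rng = np.random.default_rng(config.seed)
    n_s = y_src.size
    preds = np.empty((config.n_iterations, y_tgt.size))
    rhos = np.empty(config.n_iterations)
    rmses = np.empty(config.n_iterations)
    for it in range(config.n_iterations):
        folds = make_folds(n_s, config.k_folds, rng)
        acc = np.zeros(y_tgt.size)
        for f in range(config.k_folds):
            train = folds != f
            sel = select_edges(X_src[train], y_src[train],
                               None if C is None else C[train],
                               config.selection_alpha)
            model = fit_fold(X_src[train], y_src[train], sel, config.model_mode, f)
            acc += predict(model, X_tgt, config.model_mode)
        preds[it] = acc / config.k_folds
        rhos[it] = spearman_rho(preds[it], y_tgt, warn=False)
        rmses[it] = rmse(preds[it], y_tgt)
    return TransferResult(predictions=preds, rho=rhos, rmse=rmses)


def config_with_seed(config: CPMConfig, seed: int) -> CPMConfig:
    return replace(config, seed=int(seed))
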