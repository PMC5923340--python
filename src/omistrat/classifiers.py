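"""Classification models on the top-ranked D7/D1 ratio features.

Three model families, all treating the outcome as binary with S = 0 and
NS = 1 on Z-scored features:

* elastic-net logistic regression (L1/L2 mixing weight 0.5) fitted along a
  geometric lambda path, with the shrinkage level chosen by minimal
  cross-validated binomial deviance over 50 repetitions of random fold
  assignments. Two selection strategies are reported: take the coefficient
  vector at the minimal-deviance (repetition, lambda) pair directly
  (strategy A), or take that lambda and refit once on the full training set
  (strategy B);
* linear discriminant analysis (LDA) on the top-10 features, with a small
  ridge shrinkage on the pooled covariance enabled by default because the
  feature count approaches the training-set size;
* PLS-DA with 3 components on the top-10 and top-20 features, class-coded
  +/-1 with weighted centering (each feature centered at the unweighted
  average of the two class means so the majority class does not shift the
  decision boundary), reporting variable-importance-in-projection (VIP)
  scores whose mean square is identically 1.

The elastic-net path solver is written here because model selection needs
the full coefficient path at 100 lambda values inside a 50-repetition
cross-validation loop, which is only tractable with warm starts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CohortMetadata, CohortValidationError

__all__ = [
    "SplitPlan",
    "ElasticNetConfig",
    "ModelResult",
    "make_split",
    "enet_logistic_path",
    "fit_elastic_net",
    "fit_elastic_net_both",
    "fit_lda",
    "fit_plsda",
    "weighted_center",
    "compare_models",
]


# ----------------------------------------------------------------------
# Train/test split
# ----------------------------------------------------------------------

@dataclass
class SplitPlan:
    """A resolved train/test partition of the cohort."""

    train: list[str]
    test: list[str]
    train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    seed: int = 0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_split(
    metadata: CohortMetadata,
    train_fraction: float = 2.0 / 3.0,
    stratified: bool = True,
    seed: int = 0,
) -> SplitPlan:
    """Partition patients into train and test sets (2/3 - 1/3 by default).

    Stratified splits draw round-half-up(train_fraction * class size)
    patients per outcome class, so e.g. 9 S + 8 NS yields a 6 + 5 training
    set and a 3 + 3 test set. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if stratified:
        train: list[str] = []
        test: list[str] = []
        for g in ("S", "NS"):
            ids = metadata.group_samples(g)
            if len(ids) < 2:
                raise CohortValidationError(
                    f"group {g!r} has {len(ids)} member(s); need >= 2 to split"
                )
            n_train = _round_half_up(train_fraction * len(ids))
            n_train = min(max(n_train, 1), len(ids) - 1)
            perm = rng.permutation(ids)
            train += [str(s) for s in perm[:n_train]]
            test += [str(s) for s in perm[n_train:]]
    else:
        ids = metadata.sample_ids
        n_train = _round_half_up(train_fraction * len(ids))
        perm = rng.permutation(ids)
        train = [str(s) for s in perm[:n_train]]
        test = [str(s) for s in perm[n_train:]]
    return SplitPlan(train=train, test=test, train_fraction=train_fraction,
                     stratified=stratified, seed=seed)


# ----------------------------------------------------------------------
# Elastic-net logistic regression
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ElasticNetConfig:
    """Settings of the repeated-CV elastic-net procedure."""

    alpha_mix: float = 0.5
    n_repetitions: int = 50
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    n_cv_folds: int = 5
    strategy: str = "A"  # A: min_deviance_coefficients, B: min_deviance_lambda_refit
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_mix <= 1.0):
            raise ValueError("alpha_mix must be in (0, 1]")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.strategy not in ("A", "B"):
            raise ValueError("strategy must be 'A' or 'B'")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _batch_fista(Xa, y, wmask, nb, lam, alpha, W, L, active,
                 tol=1e-7, max_iter=400):
    """One lambda step of proximal-gradient (FISTA) minimization of
    (1/n) weighted logistic loss + lam*(alpha*||w||_1 + (1-alpha)/2*||w||^2)
    for a batch of subproblems sharing the design matrix ``Xa`` (whose
    column 0 is the unpenalized intercept). ``wmask`` selects each
    subproblem's rows; ``W`` is updated in place from warm starts."""
    Z = W.copy()
    t = np.ones(W.shape[0])
    ridge = lam * (1.0 - alpha)
    thr = lam * alpha / L
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        Za = Z[idx]
        mu = _sigmoid(Za @ Xa.T)
        G = ((mu - y[None, :]) * wmask[idx]) @ Xa / nb[idx, None]
        G[:, 1:] += ridge * Za[:, 1:]
        Wn = Za - G / L[idx, None]
        Wn[:, 1:] = _soft(Wn[:, 1:], thr[idx][:, None])
        tn = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t[idx] ** 2))
        Z[idx] = Wn + ((t[idx] - 1.0) / tn)[:, None] * (Wn - W[idx])
        delta = np.max(np.abs(Wn - W[idx]), axis=1)
        W[idx] = Wn
        t[idx] = tn
        active[idx] = delta >= tol * np.maximum(1.0, np.max(np.abs(Wn), axis=1))
    return W


def _batch_enet_path(Xa, y, wmask, alpha, lambdas, tol=1e-6, max_iter=200,
                     dev_explained_stop=0.99):
    """Elastic-net logistic coefficient paths for a batch of row-weighted
    subproblems over a shared design matrix.

    Returns an array (batch, n_lambda, p + 1). Lambdas are visited in
    descending order with warm starts; once a subproblem explains
    ``dev_explained_stop`` of its null deviance (near-perfect separation,
    where smaller lambdas only inflate coefficients without changing
    fitted classes) its path is frozen and copied forward — the same
    early-stop rule practical lasso-path solvers apply.
    """
    B, n = wmask.shape
    p1 = Xa.shape[1]
    nb = wmask.sum(axis=1)
    ybar = (wmask @ y) / nb
    W = np.zeros((B, p1))
    W[:, 0] = np.log(ybar / (1.0 - ybar))
    L0 = 0.25 * np.linalg.norm(Xa, 2) ** 2 / nb
    dev_null = -2.0 * nb * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    saturated = np.zeros(B, dtype=bool)
    path = np.empty((B, len(lambdas), p1))
    for i, lam in enumerate(lambdas):
        L = L0 + lam * (1.0 - alpha)
        W = _batch_fista(Xa, y, wmask, nb, lam, alpha, W, L,
                         active=~saturated, tol=tol, max_iter=max_iter)
        path[:, i, :] = W
        if not saturated.all():
            mu = np.clip(_sigmoid(W @ Xa.T), 1e-10, 1 - 1e-10)
            dev = -2.0 * np.sum(
                wmask * (y * np.log(mu) + (1 - y) * np.log(1 - mu)), axis=1
            )
            saturated |= dev < (1.0 - dev_explained_stop) * dev_null
    return path


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which every slope coefficient is zero."""
    n = X.shape[0]
    ybar = y.mean()
    return float(np.max(np.abs(X.T @ (y - ybar))) / (n * alpha))


def enet_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> np.ndarray:
    """Coefficient path of elastic-net penalized logistic regression.

    Returns an array of shape (len(lambdas), p + 1); column 0 is the
    intercept. Lambdas are visited in the given (descending) order with
    warm starts.
    """
    n, p = X.shape
    Xa = np.hstack([np.ones((n, 1)), X])
    wmask = np.ones((1, n))
    return _batch_enet_path(Xa, np.asarray(y, float), wmask, alpha,
                            np.asarray(lambdas, float), tol=tol,
                            max_iter=max_iter)[0]


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _stratified_folds(y: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold labels with each class spread evenly across folds."""
    fold = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


@dataclass
class ModelResult:
    """A fitted model with its selection metadata and test performance."""

    family: str
    tier: str
    top_k: int
    features: list[str]
    coefficients: pd.Series | None = None
    intercept: float | None = None
    vip: pd.Series | None = None
    selection: dict = field(default_factory=dict)
    predictions: pd.DataFrame | None = None
    correct: int = 0
    total: int = 0
    scores: pd.DataFrame | None = None

    def selected_features(self, vip_threshold: float = 1.0) -> list[str]:
        """Features the model considers informative: nonzero coefficient
        (elastic net, LDA) or VIP above ``vip_threshold`` (PLS-DA)."""
        if self.vip is not None:
            return list(self.vip.index[self.vip > vip_threshold])
        return list(self.coefficients.index[self.coefficients != 0.0])

    @property
    def all_test_correct(self) -> bool:
        return self.total > 0 and self.correct == self.total

    @property
    def label(self) -> str:
        extra = self.selection.get("strategy")
        tag = f"{self.family}{'-' + extra if extra else ''}"
        return f"{self.tier}/{tag}/top{self.top_k}"


def _predict_result(result: ModelResult, X_test: pd.DataFrame,
                    y_test: np.ndarray, score_fn) -> None:
    score = score_fn(X_test.to_numpy(dtype=float))
    predicted = (score > 0.5).astype(int) if result.family == "elastic_net" \
        else (score > 0.0).astype(int)
    result.predictions = pd.DataFrame(
        {
            "sample_id": list(X_test.index),
            "score": score,
            "predicted": predicted,
            "actual": y_test,
        }
    )
    result.correct = int((predicted == y_test).sum())
    result.total = int(y_test.size)


def fit_elastic_net(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    config: ElasticNetConfig = ElasticNetConfig(),
    tier: str = "",
    top_k: int | None = None,
) -> ModelResult:
    """Repeated-CV elastic-net logistic regression on Z-scored features.

    The lambda grid is 100 geometric values from lambda_max (the smallest
    lambda zeroing all slopes) down by a factor 1e-4. Each of the 50
    repetitions assigns fresh stratified CV folds on the training set and
    accumulates held-out binomial deviance along the path; the (repetition,
    lambda) pair with minimal deviance fixes lambda*. Strategy A reports
    the full-training-path coefficients at lambda*; strategy B refits once
    from scratch on the training set at lambda*. Classes are called at 0.5
    on the logistic output.
    """
    core = _enet_core(X_train, np.asarray(y_train, dtype=float), config)
    return _enet_result(core, config.strategy, X_train, X_test,
                        np.asarray(y_test, dtype=int), config, tier, top_k)


def fit_elastic_net_both(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    config: ElasticNetConfig = ElasticNetConfig(),
    tier: str = "",
    top_k: int | None = None,
) -> dict[str, ModelResult]:
    """Fit once, report both minimal-deviance strategies (they share the
    repeated-CV work, which dominates the cost)."""
    core = _enet_core(X_train, np.asarray(y_train, dtype=float), config)
    y_test = np.asarray(y_test, dtype=int)
    return {
        s: _enet_result(core, s, X_train, X_test, y_test, config, tier, top_k)
        for s in ("A", "B")
    }


def _enet_core(X_train: pd.DataFrame, y_train: np.ndarray,
               config: ElasticNetConfig) -> dict:
    """Shared work of both strategies: the full-training-set path and the
    repeated-CV deviance surface.

    All (repetition, fold) subproblems are solved as one batched path over
    the common design matrix, with per-subproblem row weights; the
    training-set fit rides along as batch element 0.
    """
    if len(np.unique(y_train)) < 2:
        raise CohortValidationError(
            "elastic net: training labels contain a single class"
        )
    X = X_train.to_numpy(dtype=float)
    n, p = X.shape
    lam_max = lambda_max(X, y_train, config.alpha_mix)
    lambdas = np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                           config.n_lambda)
    Xa = np.hstack([np.ones((n, 1)), X])

    rng = np.random.default_rng(config.seed)
    n_folds = int(min(config.n_cv_folds,
                      (y_train == 0).sum(), (y_train == 1).sum()))
    n_folds = max(n_folds, 2)
    folds = np.stack([
        _stratified_folds(y_train.astype(int), n_folds, rng)
        for _ in range(config.n_repetitions)
    ])  # (reps, n)

    masks = [np.ones(n)]  # element 0: the full training fit
    for rep in range(config.n_repetitions):
        for f in range(n_folds):
            masks.append((folds[rep] != f).astype(float))
    wmask = np.stack(masks)

    path = _batch_enet_path(Xa, y_train, wmask, config.alpha_mix, lambdas)

    # held-out binomial deviance, (reps*folds, n_lambda) -> (reps, n_lambda)
    logits = np.einsum("blp,np->bln", path[1:], Xa)
    mu = np.clip(_sigmoid(logits), 1e-10, 1 - 1e-10)
    held = (1.0 - wmask[1:])[:, None, :]
    dev = -2.0 * np.sum(
        held * (y_train * np.log(mu) + (1 - y_train) * np.log(1 - mu)),
        axis=2,
    ).reshape(config.n_repetitions, n_folds, len(lambdas)).sum(axis=1)

    rep_best, i_best = np.unravel_index(np.argmin(dev), dev.shape)
    return {
        "lambdas": lambdas,
        "path": path[0],
        "lam_index": int(i_best),
        "lam_star": float(lambdas[i_best]),
        "repetition": int(rep_best),
        "cv_deviance": float(dev[rep_best, i_best]),
        "Xa": Xa,
        "y": y_train,
    }


def _enet_result(core: dict, strategy: str, X_train: pd.DataFrame,
                 X_test: pd.DataFrame, y_test: np.ndarray,
                 config: ElasticNetConfig, tier: str,
                 top_k: int | None) -> ModelResult:
    n, p1 = core["Xa"].shape
    if strategy == "A":
        w = core["path"][core["lam_index"]]
    else:  # refit once on the full training set at lambda*
        lam = np.array([core["lam_star"]])
        w = _batch_enet_path(core["Xa"], core["y"], np.ones((1, n)),
                             config.alpha_mix, lam, tol=1e-8,
                             max_iter=5000)[0, 0]
    result = ModelResult(
        family="elastic_net",
        tier=tier,
        top_k=top_k if top_k is not None else p1 - 1,
        features=list(X_train.columns),
        coefficients=pd.Series(w[1:], index=X_train.columns),
        intercept=float(w[0]),
        selection={
            "strategy": strategy,
            "lambda": core["lam_star"],
            "cv_deviance": core["cv_deviance"],
            "repetition": core["repetition"],
        },
    )
    _predict_result(
        result, X_test, y_test, lambda M: _sigmoid(w[0] + M @ w[1:])
    )
    return result


# ----------------------------------------------------------------------
# Linear discriminant analysis
# ----------------------------------------------------------------------

def fit_lda(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    shrinkage: float | str | None = "auto",
    priors: str = "equal",
    tier: str = "",
    top_k: int | None = None,
) -> ModelResult:
    """Two-class LDA returning the linear boundary coefficients.

    The pooled within-class covariance is shrunk toward a scaled identity,
    which is essential here because the feature count (10) approaches the
    training-set size (11): ``shrinkage='auto'`` (default) uses the
    Ledoit-Wolf optimal shrinkage intensity, a float adds that fraction of
    the mean diagonal as ridge, and ``None`` uses the raw pooled
    covariance — where a singular matrix raises an error suggesting
    shrinkage. ``priors`` is ``'equal'`` (boundary at the midpoint of the
    class means, the appropriate choice for unbalanced groups) or
    ``'empirical'``.
    """
    y_train = np.asarray(y_train, dtype=int)
    X = X_train.to_numpy(dtype=float)
    n, p = X.shape
    mu0 = X[y_train == 0].mean(axis=0)
    mu1 = X[y_train == 1].mean(axis=0)
    xc = np.vstack([X[y_train == 0] - mu0, X[y_train == 1] - mu1])
    if shrinkage == "auto":
        from sklearn.covariance import ledoit_wolf

        cov, _ = ledoit_wolf(xc, assume_centered=True)
    else:
        cov = xc.T @ xc / max(n - 2, 1)
        if shrinkage:
            cov = cov + shrinkage * float(np.trace(cov)) / p * np.eye(p)
    if np.linalg.cond(cov) > 1e12:
        raise CohortValidationError(
            "singular pooled covariance; enable shrinkage (e.g. 'auto')"
        )
    w = np.linalg.solve(cov, mu1 - mu0)
    b = -float(w @ (mu0 + mu1)) / 2.0
    if priors == "empirical":
        n1 = int((y_train == 1).sum())
        b += math.log(n1 / (n - n1))
    result = ModelResult(
        family="lda",
        tier=tier,
        top_k=top_k if top_k is not None else p,
        features=list(X_train.columns),
        coefficients=pd.Series(w, index=X_train.columns),
        intercept=b,
        selection={"shrinkage": shrinkage, "priors": priors},
    )
    _predict_result(
        result, X_test, np.asarray(y_test, dtype=int), lambda M: M @ w + b
    )
    return result


# ----------------------------------------------------------------------
# PLS-DA with VIP
# ----------------------------------------------------------------------

def weighted_center(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature centering vector: the unweighted mean of the two class
    means, so each class contributes equally to the origin regardless of
    group sizes. Equals the ordinary column mean when classes are balanced.
    """
    y = np.asarray(y)
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    return 0.5 * (mu0 + mu1)


def fit_plsda(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    n_components: int = 3,
    tier: str = "",
    top_k: int | None = None,
) -> ModelResult:
    """PLS-DA with weighted centering and VIP scores.

    The class is coded -1 (S) / +1 (NS). Each feature is centered at the
    unweighted mean of its two class means, so both classes contribute
    equally to the origin and the boundary is not dragged toward the larger
    group (for balanced classes this equals ordinary mean centering).
    Components come from the standard iterative (NIPALS) PLS1 algorithm;
    VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a) with SSY_a the
    response variance explained by component a, so mean(VIP^2) = 1.
    """
    y_train = np.asarray(y_train, dtype=int)
    X = X_train.to_numpy(dtype=float)
    n, p = X.shape
    bound = min(n - 1, p)
    if n_components > bound:
        raise CohortValidationError(
            f"n_components={n_components} exceeds the feasible bound {bound} "
            f"(min(n_train - 1, n_features))"
        )
    center = weighted_center(X, y_train)
    Xc = X - center
    yc = np.where(y_train == 1, 1.0, -1.0)

    Xa, ya = Xc.copy(), yc.copy()
    W, P, Q, T, SSY = [], [], [], [], []
    for _ in range(n_components):
        w = Xa.T @ ya
        nw = float(np.linalg.norm(w))
        if nw < 1e-12:
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p_load = Xa.T @ t / tt
        q = float(ya @ t) / tt
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q * t
        W.append(w)
        P.append(p_load)
        Q.append(q)
        T.append(t)
        SSY.append(q * q * tt)
    A = len(W)
    W_m, P_m = np.column_stack(W), np.column_stack(P)
    q_v, ssy = np.array(Q), np.array(SSY)
    vip = np.sqrt(p * (W_m ** 2 @ ssy) / ssy.sum())
    beta = W_m @ np.linalg.solve(P_m.T @ W_m, q_v)

    result = ModelResult(
        family="plsda",
        tier=tier,
        top_k=top_k if top_k is not None else p,
        features=list(X_train.columns),
        coefficients=pd.Series(beta, index=X_train.columns),
        intercept=0.0,
        vip=pd.Series(vip, index=X_train.columns),
        selection={"n_components": A},
        scores=pd.DataFrame(
            np.column_stack(T), index=X_train.index,
            columns=[f"comp{a + 1}" for a in range(A)],
        ),
    )
    _predict_result(
        result, X_test, np.asarray(y_test, dtype=int),
        lambda M: (M - center) @ beta,
    )
    return result


# ----------------------------------------------------------------------
# Cross-model consensus
# ----------------------------------------------------------------------

def compare_models(
    results: list[ModelResult], vip_threshold: float = 1.0
) -> pd.DataFrame:
    """Consensus table of feature selection across fitted models.

    One row per feature appearing in any model's input; per model, the
    ``selected`` flag (nonzero coefficient, or VIP above the threshold) is
    ``True``/``False`` where the feature entered the model and ``<NA>``
    where it did not. ``selected_by_all`` marks features selected by every
    model they entered (and entering at least two models);
    ``sign_consistent`` marks features whose signed coefficients agree in
    sign across all models providing one.
    """
    if len(results) < 2:
        raise ValueError("compare_models needs >= 2 fitted models")
    all_features: list[str] = []
    for r in results:
        for f in r.features:
            if f not in all_features:
                all_features.append(f)
    out = pd.DataFrame(index=pd.Index(all_features, name="feature"))
    for r in results:
        sel = set(r.selected_features(vip_threshold))
        rank_src = r.vip if r.vip is not None else r.coefficients.abs()
        order = rank_src.sort_values(ascending=False).index
        col_sel = pd.Series(pd.NA, index=out.index, dtype="boolean")
        col_rank = pd.Series(pd.NA, index=out.index, dtype="Int64")
        for pos, f in enumerate(order, start=1):
            col_sel[f] = f in sel
            col_rank[f] = pos
        out[f"selected[{r.label}]"] = col_sel
        out[f"rank[{r.label}]"] = col_rank

    sel_cols = [c for c in out.columns if c.startswith("selected[")]
    n_models = out[sel_cols].notna().sum(axis=1)
    n_selected = (out[sel_cols] == True).sum(axis=1)  # noqa: E712
    out["selected_by_all"] = (n_models >= 2) & (n_selected == n_models)

    signs = []
    for f in out.index:
        s = set()
        for r in results:
            if r.vip is None and f in (r.coefficients.index if
                                       r.coefficients is not None else []):
                c = r.coefficients[f]
                if c != 0:
                    s.add(np.sign(c))
        signs.append(len(s) <= 1)
    out["sign_consistent"] = signs
    return out
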