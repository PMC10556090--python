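"""Nine censoring-aware prognostic models behind one fit/predict contract.

The registry covers the model families commonly benchmarked on
gene-expression survival data: the Cox proportional hazards model and its
L1/L2/elastic-net penalized variants, gradient boosting of the Cox partial
likelihood with componentwise-linear or tree base learners, random survival
forests, a forest whose splits use maximally selected rank statistics, and a
single survival tree.

Orientation contract: ``predict_risk`` always returns scores where **higher
means worse prognosis** — linear models expose the linear predictor, ensemble
and tree models an expected-cumulative-hazard (mortality) score.

Model fitting failures (non-convergence, degenerate inputs) are returned as
flagged :class:`FittedModel` objects carrying a diagnostic rather than raised,
so that large evaluation grids can record them as missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold
from sksurv.ensemble import (
    ComponentwiseGradientBoostingSurvivalAnalysis,
    GradientBoostingSurvivalAnalysis,
    RandomSurvivalForest,
)
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.tree import SurvivalTree
from sksurv.util import Surv

from .concordance import concordance

__all__ = [
    "MODEL_IDS",
    "STUB_MODEL_ID",
    "ModelSpec",
    "FittedModel",
    "ModelContractError",
    "fit",
    "predict_risk",
]

MODEL_IDS = (
    "coxph",
    "lasso",
    "ridge",
    "elastic_net",
    "gb_linear",
    "gb_tree",
    "rsf",
    "rank_rf",
    "stree",
)

#: pseudo-model producing seeded random scores; used for grid dry-runs and
#: null-calibration tests, never part of the nine-model registry.
STUB_MODEL_ID = "stub"


class ModelContractError(ValueError):
    """Violation of the fit/predict contract (unknown model, column mismatch...)."""


@dataclass(frozen=True)
class ModelSpec:
    """A model identifier plus hyperparameter overrides and a seed."""

    model_id: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS and self.model_id != STUB_MODEL_ID:
            raise ModelContractError(
                f"unknown model_id {self.model_id!r}; registry: {MODEL_IDS}"
            )


@dataclass
class FittedModel:
    spec: ModelSpec
    state: object
    train_gene_ids: list
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


# ---------------------------------------------------------------------------
# maximally selected rank statistics forest (no installed library offers one)
# ---------------------------------------------------------------------------


def _logrank_z(left: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (absolute value).

    ``left`` marks group membership.  Hypergeometric variance at each
    distinct event time.
    """
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], left[order]
    n = len(t)
    u = 0.0
    v = 0.0
    i = 0
    at_risk = n
    at_risk_l = int(g.sum())
    while i < n:
        j = i
        d = dl = 0
        while j < n and t[j] == t[i]:
            if e[j]:
                d += 1
                dl += int(g[j])
            j += 1
        if d > 0 and at_risk > 1:
            frac = at_risk_l / at_risk
            u += dl - d * frac
            v += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        # remove everyone with this time from the risk set
        for k in range(i, j):
            at_risk -= 1
            at_risk_l -= int(g[k])
        i = j
    if v <= 0:
        return 0.0
    return abs(u) / np.sqrt(v)


def _leaf_mortality(time, event, grid) -> float:
    """Sum over ``grid`` of the node's Nelson-Aalen cumulative hazard."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    # NA increments at event times
    steps_t, steps_h = [], []
    i = 0
    at_risk = n
    while i < n:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += int(e[j])
            j += 1
        if d:
            steps_t.append(t[i])
            steps_h.append(d / at_risk)
        at_risk -= j - i
        i = j
    if not steps_t:
        return 0.0
    steps_t = np.asarray(steps_t)
    chf = np.cumsum(steps_h)
    idx = np.searchsorted(steps_t, grid, side="right")
    vals = np.concatenate(([0.0], chf))[idx]
    return float(vals.sum())


class _RankTreeNode:
    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self, value=None):
        self.feature = -1
        self.threshold = 0.0
        self.left = None
        self.right = None
        self.value = value


def _build_rank_tree(X, time, event, rng, *, mtry, min_leaf, min_events, grid, depth, max_depth):
    node = _RankTreeNode()
    n = len(time)
    if n < 2 * min_leaf or int(event.sum()) < min_events or depth >= max_depth:
        node.value = _leaf_mortality(time, event, grid)
        return node
    p = X.shape[1]
    candidates = rng.choice(p, size=min(mtry, p), replace=False)
    rng.shuffle(candidates)
    # the split variable is drawn at random among the candidates; the split
    # point maximizes the standardized log-rank statistic over in-node deciles
    for feat in candidates:
        x = X[:, feat]
        cuts = np.unique(np.quantile(x, np.linspace(0.1, 0.9, 9)))
        best_z, best_c = 0.0, None
        for c in cuts:
            left = x <= c
            nl = int(left.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            z = _logrank_z(left, time, event)
            if z > best_z:
                best_z, best_c = z, c
        if best_c is not None and best_z > 0:
            left = x <= best_c
            node.feature = int(feat)
            node.threshold = float(best_c)
            node.left = _build_rank_tree(
                X[left], time[left], event[left], rng,
                mtry=mtry, min_leaf=min_leaf, min_events=min_events,
                grid=grid, depth=depth + 1, max_depth=max_depth,
            )
            node.right = _build_rank_tree(
                X[~left], time[~left], event[~left], rng,
                mtry=mtry, min_leaf=min_leaf, min_events=min_events,
                grid=grid, depth=depth + 1, max_depth=max_depth,
            )
            return node
    node.value = _leaf_mortality(time, event, grid)
    return node


def _rank_tree_predict(node, X) -> np.ndarray:
    out = np.empty(X.shape[0])
    for i, row in enumerate(X):
        cur = node
        while cur.value is None:
            cur = cur.left if row[cur.feature] <= cur.threshold else cur.right
        out[i] = cur.value
    return out


class RankStatForest:
    """Survival forest with maximally-selected-rank-statistic split points.

    Variable choice is decoupled from cutpoint choice: a candidate variable
    is drawn at random among ``mtry`` candidates, then the cutpoint maximizes
    the standardized log-rank statistic over in-node decile cutpoints.  The
    risk score is an ensemble mortality (sum of the leaf Nelson-Aalen
    cumulative hazard over the training event-time grid), higher = worse.
    """

    def __init__(self, n_estimators=100, min_samples_leaf=15, min_events=3,
                 max_depth=20, mtry=None, random_state=0):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.min_events = min_events
        self.max_depth = max_depth
        self.mtry = mtry
        self.random_state = random_state

    def fit(self, X, time, event):
        X = np.asarray(X, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(int)
        n, p = X.shape
        mtry = self.mtry or int(np.ceil(np.sqrt(p)))
        grid = np.unique(time[event == 1])
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        for _ in range(self.n_estimators):
            idx = rng.integers(0, n, size=n)  # bootstrap
            self.trees_.append(
                _build_rank_tree(
                    X[idx], time[idx], event[idx], rng,
                    mtry=mtry, min_leaf=self.min_samples_leaf,
                    min_events=self.min_events, grid=grid,
                    depth=0, max_depth=self.max_depth,
                )
            )
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(X.shape[0])
        for tree in self.trees_:
            out += _rank_tree_predict(tree, X)
        return out / len(self.trees_)


# ---------------------------------------------------------------------------
# stub model (random scores) for grid dry-runs and null calibration
# ---------------------------------------------------------------------------


class _StubModel:
    def __init__(self, seed):
        self.seed = seed

    def fit(self, X, y):
        return self

    def predict(self, X):
        rng = np.random.default_rng(self.seed)
        return rng.standard_normal(X.shape[0])


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def _fit_coxph(hp, X, y, seed):
    alpha = hp.get("alpha", 0.0)
    jitter = hp.get("ridge_jitter", 0.01)
    if X.shape[1] >= X.shape[0]:
        # the unpenalized partial likelihood has no maximizer when p >= n
        alpha = max(alpha, jitter)
    # singular Hessian or diverged Newton: escalate the ridge until finite
    last_exc = None
    for a in (alpha, max(alpha, jitter), 1.0, 100.0):
        try:
            est = CoxPHSurvivalAnalysis(alpha=a, n_iter=hp.get("n_iter", 100))
            est.fit(X, y)
        except (np.linalg.LinAlgError, ValueError, ArithmeticError) as exc:
            last_exc = exc
            continue
        if np.all(np.isfinite(est.coef_)):
            return est
    raise last_exc or np.linalg.LinAlgError("Cox Newton failed at every ridge level")


def _fit_ridge_cv(hp, X, y, seed):
    grid = hp.get("alpha_grid", (0.01, 0.1, 1.0, 10.0, 100.0))
    cv = KFold(n_splits=hp.get("cv_folds", 3), shuffle=True, random_state=seed)
    best_alpha, best_score = grid[0], -np.inf
    for a in grid:
        scores = []
        for tr, te in cv.split(X):
            try:
                est = CoxPHSurvivalAnalysis(alpha=a).fit(X[tr], y[tr])
                scores.append(est.score(X[te], y[te]))
            except (np.linalg.LinAlgError, ValueError, ArithmeticError):
                scores.append(np.nan)
        m = np.nanmean(scores) if not np.all(np.isnan(scores)) else -np.inf
        if m > best_score:
            best_score, best_alpha = m, a
    return CoxPHSurvivalAnalysis(alpha=best_alpha).fit(X, y)


class _CoxnetAtAlpha:
    """Coxnet path model pinned to one CV-selected penalty strength."""

    def __init__(self, est, alpha):
        self.est = est
        self.alpha = alpha

    def predict(self, X):
        return self.est.predict(X, alpha=self.alpha)


def _fit_coxnet_cv(hp, X, y, seed, l1_ratio):
    n_alphas = hp.get("n_alphas", 30)
    path = CoxnetSurvivalAnalysis(
        l1_ratio=l1_ratio, n_alphas=n_alphas,
        alpha_min_ratio=hp.get("alpha_min_ratio", 0.05),
    ).fit(X, y)
    alphas = path.alphas_
    cv = KFold(n_splits=hp.get("cv_folds", 3), shuffle=True, random_state=seed)
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for tr, te in cv.split(X):
        try:
            est = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas).fit(X[tr], y[tr])
        except (ValueError, ArithmeticError):
            continue
        for k, a in enumerate(alphas):
            try:
                pred = est.predict(X[te], alpha=a)
            except ValueError:
                continue
            ev = y[te]["event"]
            tm = y[te]["time"]
            if ev.sum() == 0 or np.ptp(pred) == 0:
                continue
            try:
                scores[k] += concordance(pred, tm, ev.astype(int))
                counts[k] += 1
            except ValueError:
                continue
    with np.errstate(invalid="ignore"):
        mean_scores = np.where(counts > 0, scores / np.maximum(counts, 1), -np.inf)
    best = alphas[int(np.argmax(mean_scores))] if np.isfinite(mean_scores).any() else alphas[-1]
    return _CoxnetAtAlpha(path, float(best))


def fit(spec: ModelSpec, X, time, event, gene_ids=None) -> FittedModel:
    """Fit a registry model to standardized expression ``X`` and outcome.

    Requires at least 20 samples, 2 observed events and a complete matrix.
    Non-convergence is reported as a flagged result (``.error`` set), not an
    exception, so grids can record the cell as missing.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    n, p = X.shape
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{j}" for j in range(p)]
    if len(gene_ids) != p:
        raise ModelContractError("gene_ids length must match number of columns")
    if spec.model_id != STUB_MODEL_ID:
        if n < 20:
            raise ModelContractError(f"need >= 20 samples to fit, got {n}")
        if event.sum() < 2:
            raise ModelContractError("need at least 2 observed events")
    if np.isnan(X).any():
        raise ModelContractError("expression matrix contains missing values")

    hp = dict(spec.hyperparams)
    seed = spec.seed
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    try:
        if spec.model_id == "coxph":
            state = _fit_coxph(hp, X, y, seed)
        elif spec.model_id == "ridge":
            state = _fit_ridge_cv(hp, X, y, seed)
        elif spec.model_id == "lasso":
            state = _fit_coxnet_cv(hp, X, y, seed, l1_ratio=1.0)
        elif spec.model_id == "elastic_net":
            state = _fit_coxnet_cv(hp, X, y, seed, l1_ratio=hp.get("l1_ratio", 0.5))
        elif spec.model_id == "gb_linear":
            state = ComponentwiseGradientBoostingSurvivalAnalysis(
                loss="coxph",
                n_estimators=hp.get("n_estimators", 100),
                learning_rate=hp.get("learning_rate", 0.1),
                random_state=seed,
            ).fit(X, y)
        elif spec.model_id == "gb_tree":
            state = GradientBoostingSurvivalAnalysis(
                loss="coxph",
                n_estimators=hp.get("n_estimators", 100),
                learning_rate=hp.get("learning_rate", 0.1),
                max_depth=hp.get("max_depth", 3),
                random_state=seed,
            ).fit(X, y)
        elif spec.model_id == "rsf":
            state = RandomSurvivalForest(
                n_estimators=hp.get("n_estimators", 500),
                min_samples_leaf=hp.get("min_samples_leaf", 15),
                max_features=hp.get("max_features", "sqrt"),
                random_state=seed,
                n_jobs=1,
            ).fit(X, y)
        elif spec.model_id == "rank_rf":
            state = RankStatForest(
                n_estimators=hp.get("n_estimators", 100),
                min_samples_leaf=hp.get("min_samples_leaf", 15),
                min_events=hp.get("min_events", 3),
                max_depth=hp.get("max_depth", 20),
                mtry=hp.get("mtry"),
                random_state=seed,
            ).fit(X, time, event)
        elif spec.model_id == "stree":
            state = SurvivalTree(
                min_samples_leaf=hp.get("min_samples_leaf", 15),
                max_depth=hp.get("max_depth", None),
                random_state=seed,
            ).fit(X, y)
        elif spec.model_id == STUB_MODEL_ID:
            state = _StubModel(seed)
        else:  # pragma: no cover - guarded by ModelSpec
            raise ModelContractError(spec.model_id)
    except (np.linalg.LinAlgError, ValueError, ArithmeticError) as exc:
        return FittedModel(spec=spec, state=None, train_gene_ids=gene_ids,
                           error=f"{type(exc).__name__}: {exc}")
    return FittedModel(spec=spec, state=state, train_gene_ids=gene_ids)


def predict_risk(m: FittedModel, X, gene_ids=None) -> np.ndarray:
    """Per-sample risk scores (higher = worse prognosis) from a fitted model."""
    if not m.ok:
        raise ModelContractError(f"model {m.spec.model_id!r} failed to fit: {m.error}")
    X = np.asarray(X, dtype=float)
    if gene_ids is not None:
        gene_ids = list(gene_ids)
        if gene_ids != m.train_gene_ids:
            missing = [g for g in m.train_gene_ids if g not in gene_ids]
            raise ModelContractError(
                f"prediction columns must match training genes; missing: {missing}"
            )
    if X.shape[1] != len(m.train_gene_ids):
        raise ModelContractError(
            f"expected {len(m.train_gene_ids)} columns, got {X.shape[1]}"
        )
    scores = np.asarray(m.state.predict(X), dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ModelContractError("model produced non-finite risk scores")
    return scores
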