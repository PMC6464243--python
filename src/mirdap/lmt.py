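"""Two-class Logistic Model Tree: boosted logistic models on tree nodes.

The node models are built with LogitBoost: starting from F(x) = 0
(probability 1/2), each iteration computes working responses
``z_i = (y*_i - p_i) / (p_i (1 - p_i))`` and weights ``w_i = p_i (1 - p_i)``
(weights floored at 1e-10, responses clipped at |z| <= 4 for numerical
stability), fits the single-attribute weighted least-squares regressor
with the smallest weighted squared error, and adds half of it to F. With
linear base learners the accumulated F stays linear, so a node model is
an (intercept, coefficients) pair plus its iteration count, and the
class-1 probability is ``1 / (1 + exp(-2 F(x)))``.

The tree is grown by binary splits maximizing information gain of the
class variable (midpoint thresholds, ties to the lowest attribute
index); each child *warm-starts* from its parent's F and continues
boosting on the child's rows only — the defining trick of the model
family. The number of boosting iterations is chosen once at the root by
internal cross-validation and reused down the tree. The grown tree is
pruned by CART cost-complexity pruning, with the complexity parameter
selected by internal cross-validation.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigurationError, TrainingError

logger = logging.getLogger(__name__)

_W_FLOOR = 1e-10
_Z_MAX = 4.0
_P_CLAMP = 1e-10


@dataclass
class LMTConfig:
    """Hyperparameters of the tree.

    min_instances: fewest rows a node may have and still be split (15 is
        the canonical default for this model family).
    max_boost_iterations: cap on LogitBoost rounds considered at the root.
    cv_folds_for_iterations: folds of the internal CV that picks the
        iteration count (also reused for pruning-strength selection).
    max_depth: hard depth cap on tree growth.
    prune: whether to run cost-complexity pruning.
    """

    min_instances: int = 15
    max_boost_iterations: int = 200
    cv_folds_for_iterations: int = 5
    max_depth: int = 5
    prune: bool = True
    per_node_iterations: bool = True
    lookahead_candidates: int = 8
    lookahead_iterations: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_instances < 2:
            raise ConfigurationError("min_instances must be >= 2")
        for name in ("max_boost_iterations", "cv_folds_for_iterations", "max_depth"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class LogisticModel:
    """Additive logistic model accumulated by LogitBoost (linear overall)."""

    bias: float
    coefs: np.ndarray
    iterations: int
    constant: bool = False  # single-class fallback
    last_update: tuple | None = None  # (attribute, d_bias, d_coef) of last round

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.bias + X @ self.coefs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(y=1 | x) = 1 / (1 + exp(-2 F(x))), clamped to the open interval."""
        return _probs(self.decision(np.asarray(X, dtype=float)))

    def copy(self) -> "LogisticModel":
        return LogisticModel(self.bias, self.coefs.copy(), self.iterations,
                             self.constant)


def _probs(F: np.ndarray) -> np.ndarray:
    # sigma(2F) = (1 + tanh(F)) / 2 -- overflow-free
    p = 0.5 * (1.0 + np.tanh(F))
    return np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)


def _best_wls(X: np.ndarray, z: np.ndarray, w: np.ndarray) -> tuple[int, float, float]:
    """Single-attribute weighted least squares, best attribute by SSE.

    Returns (attribute index, intercept, slope); ties go to the lowest
    attribute index. Attributes with (weighted) zero variance fall back
    to the intercept-only fit.
    """
    sw = w.sum()
    swz = w @ z
    swzz = w @ (z * z)
    swx = w @ X
    swxx = w @ (X * X)
    swxz = (w * z) @ X
    denom = sw * swxx - swx ** 2
    safe = denom > 1e-12 * max(sw, 1.0)
    b = np.where(safe, (sw * swxz - swx * swz) / np.where(safe, denom, 1.0), 0.0)
    a = (swz - b * swx) / sw
    sse = swzz - a * swz - b * swxz
    j = int(np.argmin(sse))  # argmin takes the first (lowest index) on ties
    return j, float(a[j]), float(b[j])


def _constant_model(y: np.ndarray, width: int) -> LogisticModel:
    p = float(np.clip(np.mean(y) if y.size else 0.5, 1e-6, 1.0 - 1e-6))
    bias = 0.5 * np.log(p / (1.0 - p))
    logger.debug("single-class node: constant model at p=%.3g", p)
    return LogisticModel(bias=bias, coefs=np.zeros(width), iterations=0,
                         constant=True)


def logitboost_fit(
    X: np.ndarray,
    y: np.ndarray,
    iterations: int,
    warm: LogisticModel | None = None,
) -> LogisticModel:
    """Run LogitBoost for a fixed number of rounds.

    ``warm`` continues boosting from an existing model's F (the warm-start
    used by child nodes); with both classes absent from y the fit
    degenerates to a flagged constant model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise TrainingError("cannot fit on an empty dataset")
    if len(np.unique(y)) < 2:
        return _constant_model(y, X.shape[1])
    model = warm.copy() if warm is not None else LogisticModel(
        0.0, np.zeros(X.shape[1]), 0)
    F = model.decision(X)
    for _ in range(iterations):
        F = _boost_step(X, y, F, model)
        if model.last_update[1] == 0.0 and model.last_update[2] == 0.0:
            break  # no admissible step remains; later rounds would repeat
    return model


def _nll_of(F: np.ndarray, y: np.ndarray) -> float:
    p = _probs(F)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def _boost_step(X, y, F, model: LogisticModel) -> np.ndarray:
    """One LogitBoost round; mutates model, returns updated F.

    The half-step of the fitted working-response regressor is a damped
    Newton update; because the responses are clipped for stability the
    quadratic model can still overshoot near separation, so the step is
    backtracked (halved) until the training loss does not increase. A
    step that cannot improve at all degenerates to a no-op round.
    """
    p = _probs(F)
    w = np.maximum(p * (1.0 - p), _W_FLOOR)
    z = np.clip((y - p) / w, -_Z_MAX, _Z_MAX)
    j, a, b = _best_wls(X, z, w)
    base = _nll_of(F, y)
    step = 0.5
    direction = a + b * X[:, j]
    for _ in range(8):
        F_try = F + step * direction
        if _nll_of(F_try, y) <= base + 1e-12:
            model.bias += step * a
            model.coefs[j] += step * b
            model.iterations += 1
            model.last_update = (j, step * a, step * b)
            return F_try
        step /= 2.0
    # converged: the same no-op would repeat, callers may stop boosting
    model.iterations += 1
    model.last_update = (j, 0.0, 0.0)
    return F


def negative_log_likelihood(model: LogisticModel, X, y) -> float:
    p = _probs(model.decision(np.asarray(X, dtype=float)))
    y = np.asarray(y, dtype=float)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def choose_iterations(X, y, config: LMTConfig,
                      warm: LogisticModel | None = None,
                      fallback: int | None = None) -> int:
    """Pick the LogitBoost round count by internal stratified CV.

    Each fold is boosted to the cap while the held-out misclassification
    count is tracked per round; the round with the smallest summed error
    (earliest on ties) wins. ``warm`` makes the CV start from an existing
    model, matching the warm-started fit the count will be used for.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = min(config.cv_folds_for_iterations,
                int(np.bincount(y.astype(int), minlength=2).min()))
    if folds < 2:
        return fallback if fallback is not None else max(
            1, config.max_boost_iterations // 10)
    errors = np.zeros(config.max_boost_iterations)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    for train_idx, val_idx in skf.split(X, y):
        ytr = y[train_idx]
        if len(np.unique(ytr)) < 2:
            continue
        Xtr, Xval, yval = X[train_idx], X[val_idx], y[val_idx]
        model = (warm.copy() if warm is not None
                 else LogisticModel(0.0, np.zeros(X.shape[1]), 0))
        F = model.decision(Xtr)
        Fval = model.decision(Xval)
        best_err, best_it = np.inf, 0
        for it in range(config.max_boost_iterations):
            F = _boost_step(Xtr, ytr, F, model)
            j, da, db = model.last_update
            Fval = Fval + da + db * Xval[:, j]
            err = np.sum((Fval >= 0.0) != (yval >= 0.5))
            errors[it] += err
            if err < best_err:
                best_err, best_it = err, it
            stalled = it - best_it >= 25
            converged = da == 0.0 and db == 0.0
            if stalled or converged:
                # held-out error has plateaued (or boosting converged);
                # carry the current error forward for the remaining rounds
                errors[it + 1:] += err
                break
    return int(np.argmin(errors)) + 1


@dataclass
class LMTNode:
    """One node: a logistic model, and for split nodes an axis test."""

    model: LogisticModel
    n_train: int
    depth: int
    split: tuple[int, float] | None = None  # (attribute, threshold); None = leaf
    left: "LMTNode | None" = None   # rows with x[attr] <= threshold
    right: "LMTNode | None" = None
    train_errors: int = 0           # misclassifications of model on own rows

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def leaves(self) -> list["LMTNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["LMTNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()


def _entropy(counts: np.ndarray) -> np.ndarray:
    """Binary entropy from positive counts / totals, elementwise-safe."""
    n = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n
        terms = np.where(counts > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=-1)


def _split_candidates(X: np.ndarray, y: np.ndarray, min_child: int = 2
                      ) -> tuple[list[tuple[float, int, float]],
                                 list[tuple[float, int, float]]]:
    """Per-attribute best (gain, attribute, midpoint threshold) candidates.

    Returns two lists, each sorted by descending gain with ties to the
    lowest attribute index: the unconstrained per-attribute optima, and
    the per-attribute optima among *balanced* cuts (no child below 30%
    of the rows). Thresholds leaving fewer than ``min_child`` rows on a
    side are excluded throughout: with many attributes the extreme-value
    statistics of noise-level gains otherwise favour uninformative
    slivers.
    """
    n, d = X.shape
    pos_total = y.sum()
    parent_h = _entropy(np.array([pos_total, n - pos_total], dtype=float))
    free: list[tuple[float, int, float]] = []
    balanced: list[tuple[float, int, float]] = []
    lo_balanced = max(min_child, int(0.3 * n))
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        cut = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
        cut = cut[(cut + 1 >= min_child) & (n - cut - 1 >= min_child)]
        if cut.size == 0:
            continue
        cum_pos = np.cumsum(ys)
        nl = cut + 1.0
        nr = n - nl
        lp = cum_pos[cut]
        rp = pos_total - lp
        hl = _entropy(np.stack([lp, nl - lp], axis=1))
        hr = _entropy(np.stack([rp, nr - rp], axis=1))
        gain = parent_h - (nl / n) * hl - (nr / n) * hr
        i = int(np.argmax(gain))
        if gain[i] > 1e-12:
            thr = float((xs[cut[i]] + xs[cut[i] + 1]) / 2.0)
            free.append((float(gain[i]), j, thr))
        ok = (nl >= lo_balanced) & (nr >= lo_balanced)
        if ok.any():
            sub = np.flatnonzero(ok)
            i = sub[int(np.argmax(gain[sub]))]
            if gain[i] > 1e-12:
                thr = float((xs[cut[i]] + xs[cut[i] + 1]) / 2.0)
                balanced.append((float(gain[i]), j, thr))
    free.sort(key=lambda c: (-c[0], c[1]))
    balanced.sort(key=lambda c: (-c[0], c[1]))
    return free, balanced


def _choose_split(X: np.ndarray, y: np.ndarray, warm: LogisticModel | None,
                  config: LMTConfig,
                  min_child: int = 2) -> tuple[int, float] | None:
    """Pick the split, re-ranking the top gain candidates by lookahead.

    The class variable can be marginally independent of every single
    attribute even when the node is perfectly separable after one split
    (interaction-only signal), in which case information gain alone is
    pure noise. The top candidates by gain are therefore re-scored by the
    training deviance of briefly boosted child models (one-step
    lookahead), and the candidate whose children explain the labels best
    wins. ``lookahead_candidates <= 1`` recovers the plain argmax-gain
    rule.
    """
    free, balanced = _split_candidates(X, y, min_child=min_child)
    if not free and not balanced:
        return None
    k = max(1, config.lookahead_candidates)
    shortlist = free[:(k + 1) // 2]
    seen = {(j, thr) for _, j, thr in shortlist}
    shortlist += [c for c in balanced[:k] if (c[1], c[2]) not in seen][:k // 2]
    if len(shortlist) == 1 or config.lookahead_candidates <= 1:
        return shortlist[0][1], shortlist[0][2]
    best: tuple[float, int, float] | None = None
    for _gain, j, thr in shortlist:
        mask = X[:, j] <= thr
        nll = 0.0
        for side in (mask, ~mask):
            ys = y[side]
            if len(np.unique(ys)) < 2:
                mdl = _constant_model(ys, X.shape[1])
            else:
                mdl = logitboost_fit(X[side], ys,
                                     config.lookahead_iterations, warm=warm)
            nll += negative_log_likelihood(mdl, X[side], ys)
        if best is None or nll < best[0] - 1e-12:
            best = (nll, j, thr)
    return best[1], best[2]


@dataclass
class LMTModel:
    """Fitted logistic model tree."""

    root: LMTNode
    config: LMTConfig
    n_features: int
    iterations_used: int
    pruning_alpha: float = 0.0
    flags: dict = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability per row, routed to the owning leaf's model."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ConfigurationError(
                f"expected {self.n_features} features, got shape {X.shape}"
            )
        out = np.empty(X.shape[0])
        _route_predict(self.root, X, np.arange(X.shape[0]), out)
        return out

    def to_dict(self) -> dict:
        def node_dict(node: LMTNode) -> dict:
            d = {
                "model": {"bias": node.model.bias,
                          "coefs": node.model.coefs.tolist(),
                          "iterations": node.model.iterations,
                          "constant": node.model.constant},
                "n_train": node.n_train,
                "depth": node.depth,
                "train_errors": node.train_errors,
            }
            if not node.is_leaf:
                d["split"] = list(node.split)
                d["left"] = node_dict(node.left)
                d["right"] = node_dict(node.right)
            return d

        return {
            "config": self.config.__dict__,
            "n_features": self.n_features,
            "iterations_used": self.iterations_used,
            "pruning_alpha": self.pruning_alpha,
            "tree": node_dict(self.root),
        }

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "LMTModel":
        def build(d: dict, depth: int) -> LMTNode:
            m = d["model"]
            node = LMTNode(
                model=LogisticModel(m["bias"], np.array(m["coefs"]),
                                    m["iterations"], m["constant"]),
                n_train=d["n_train"], depth=d["depth"],
                train_errors=d["train_errors"],
            )
            if "split" in d:
                node.split = (int(d["split"][0]), float(d["split"][1]))
                node.left = build(d["left"], depth + 1)
                node.right = build(d["right"], depth + 1)
            return node

        return cls(root=build(payload["tree"], 0),
                   config=LMTConfig(**payload["config"]),
                   n_features=payload["n_features"],
                   iterations_used=payload["iterations_used"],
                   pruning_alpha=payload["pruning_alpha"])

    @classmethod
    def load_json(cls, path) -> "LMTModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _route_predict(node: LMTNode, X, idx, out) -> None:
    if node.is_leaf:
        out[idx] = node.model.predict_proba(X[idx])
        return
    j, thr = node.split
    mask = X[idx, j] <= thr
    _route_predict(node.left, X, idx[mask], out)
    _route_predict(node.right, X, idx[~mask], out)


def _grow(X, y, idx, warm: LogisticModel | None, depth: int,
          iterations: int, config: LMTConfig) -> LMTNode:
    ysub = y[idx]
    Xsub = X[idx]
    pure = len(np.unique(ysub)) < 2
    if pure:
        model = _constant_model(ysub, X.shape[1])
    else:
        n_iter = iterations
        if config.per_node_iterations:
            n_iter = choose_iterations(Xsub, ysub, config, warm=warm,
                                       fallback=iterations)
        model = logitboost_fit(Xsub, ysub, n_iter, warm=warm)
    errors = int(np.sum((model.predict_proba(Xsub) >= 0.5) != (ysub >= 0.5)))
    node = LMTNode(model=model, n_train=len(idx), depth=depth,
                   train_errors=errors)
    if pure or len(idx) < config.min_instances or depth >= config.max_depth:
        return node
    found = _choose_split(Xsub, ysub, model, config,
                          min_child=max(2, config.min_instances // 3))
    if found is None:
        return node
    j, thr = found
    mask = Xsub[:, j] <= thr
    if mask.sum() == 0 or (~mask).sum() == 0:
        return node
    node.split = (j, thr)
    node.left = _grow(X, y, idx[mask], model, depth + 1, iterations, config)
    node.right = _grow(X, y, idx[~mask], model, depth + 1, iterations, config)
    return node


def _subtree_errors(node: LMTNode) -> int:
    return sum(leaf.train_errors for leaf in node.leaves())


def _weakest_link(node: LMTNode, n_total: int) -> tuple[float, LMTNode] | None:
    """Internal node with the smallest cost-complexity g(t), or None."""
    best = None
    for t in node.internal_nodes():
        n_leaves = len(t.leaves())
        g = (t.train_errors - _subtree_errors(t)) / n_total / (n_leaves - 1)
        if best is None or g < best[0] - 1e-15:
            best = (g, t)
    return best


def _collapse(node: LMTNode) -> None:
    node.split = None
    node.left = None
    node.right = None


def _prune_at_alpha(root: LMTNode, alpha: float, n_total: int) -> None:
    """Iteratively collapse weakest links with g(t) <= alpha (in place)."""
    while True:
        wl = _weakest_link(root, n_total)
        if wl is None or wl[0] > alpha + 1e-12:
            return
        _collapse(wl[1])


def _alpha_sequence(root: LMTNode, n_total: int) -> list[float]:
    """Critical alphas of the cost-complexity path (on a working copy)."""
    work = copy.deepcopy(root)
    alphas = []
    while True:
        wl = _weakest_link(work, n_total)
        if wl is None:
            break
        alphas.append(max(wl[0], 0.0))
        _collapse(wl[1])
    return alphas


def _tree_misclass(root: LMTNode, X, y) -> int:
    out = np.empty(X.shape[0])
    _route_predict(root, X, np.arange(X.shape[0]), out)
    return int(np.sum((out >= 0.5) != (y >= 0.5)))


def _select_alpha(X, y, iterations: int, config: LMTConfig,
                  candidates: list[float]) -> float:
    """Pick the pruning strength by internal CV; ties favour larger alpha."""
    y = np.asarray(y, dtype=float)
    folds = min(config.cv_folds_for_iterations, int(np.bincount(y.astype(int)).min()))
    if folds < 2 or not candidates:
        return 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=config.seed + 1)
    errors = np.zeros(len(candidates))
    # fold trees reuse the main tree's iteration count instead of running
    # per-node CV again: the alpha comparison needs comparable structure,
    # not freshly tuned node models
    fold_config = copy.copy(config)
    fold_config.per_node_iterations = False
    for train_idx, val_idx in skf.split(X, y):
        tree = _grow(X[train_idx], y[train_idx], np.arange(len(train_idx)),
                     None, 0, iterations, fold_config)
        n_tr = len(train_idx)
        for a_i, alpha in enumerate(sorted(candidates)):
            _prune_at_alpha(tree, alpha, n_tr)
            errors[a_i] += _tree_misclass(tree, X[val_idx], y[val_idx])
    ordered = sorted(candidates)
    best = min(range(len(ordered)), key=lambda i: (errors[i], -ordered[i]))
    return ordered[best]


def lmt_fit(X, y, config: LMTConfig | None = None) -> LMTModel:
    """Fit a logistic model tree.

    Steps: choose the LogitBoost round count by internal CV at the root;
    grow the tree with warm-started child models; select the
    cost-complexity pruning strength by internal CV and prune.
    """
    config = config or LMTConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ConfigurationError("X must be 2-D with one label per row")
    if X.shape[0] < 2:
        raise TrainingError("need at least 2 rows to fit")
    flags = {}
    if len(np.unique(y)) < 2:
        root = LMTNode(model=_constant_model(y, X.shape[1]),
                       n_train=len(y), depth=0)
        return LMTModel(root=root, config=config, n_features=X.shape[1],
                        iterations_used=0, flags={"single_class": True})
    if config.per_node_iterations:
        # each node runs its own CV; the fallback only covers tiny nodes
        iterations = max(1, config.max_boost_iterations // 10)
    else:
        iterations = choose_iterations(X, y, config)
    root = _grow(X, y, np.arange(len(y)), None, 0, iterations, config)
    if config.per_node_iterations:
        iterations = root.model.iterations
    alpha = 0.0
    if config.prune and not root.is_leaf:
        seq = _alpha_sequence(root, len(y))
        uniq = sorted(set(seq))
        candidates = [0.0]
        for a, b in zip(uniq, uniq[1:]):
            candidates.append(float(np.sqrt(max(a, 1e-12) * max(b, 1e-12))))
        if uniq:
            candidates.extend([uniq[-1], uniq[-1] * 2 + 1e-9])
        alpha = _select_alpha(X, y, iterations, config, sorted(set(candidates)))
        _prune_at_alpha(root, alpha, len(y))
    return LMTModel(root=root, config=config, n_features=X.shape[1],
                    iterations_used=iterations, pruning_alpha=alpha,
                    flags=flags)


class LMTClassifier:
    """scikit-learn-style facade over lmt_fit / predict_proba."""

    def __init__(self, config: LMTConfig | None = None):
        self.config = config or LMTConfig()
        self.model_: LMTModel | None = None

    def fit(self, X, y) -> "LMTClassifier":
        self.model_ = lmt_fit(X, y, self.config)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.model_ is None:
            raise TrainingError("classifier is not fitted")
        p1 = self.model_.predict_proba(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


BASELINE_KINDS = ("svm_rbf", "random_forest")


def fit_baseline(kind: str, X, y, seed: int = 0):
    """Comparison classifiers behind the same probability contract.

    svm_rbf: RBF-kernel support vector machine with C=0.5 and kernel
    width gamma=0.2, Platt-scaled probabilities. random_forest: forest of
    depth-2 trees, other settings default.
    """
    if kind == "svm_rbf":
        clf = SVC(C=0.5, gamma=0.2, kernel="rbf", probability=True,
                  random_state=seed)
    elif kind == "random_forest":
        clf = RandomForestClassifier(max_depth=2, random_state=seed)
    else:
        raise ConfigurationError(
            f"unknown baseline kind {kind!r}; expected one of {BASELINE_KINDS}"
        )
    return clf.fit(X, y)


def make_classifier(kind: str, seed: int = 0, config: LMTConfig | None = None):
    """Unfitted classifier of any supported kind (common fit/predict_proba)."""
    if kind == "lmt":
        cfg = config or LMTConfig(seed=seed)
        return LMTClassifier(cfg)
    if kind == "svm_rbf":
        return SVC(C=0.5, gamma=0.2, kernel="rbf", probability=True,
                   random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(max_depth=2, random_state=seed)
    raise ConfigurationError(f"unknown classifier kind {kind!r}")
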