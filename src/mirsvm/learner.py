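"""Feature selection and the two-stage cost-sensitive RBF-SVM.

mRMR ranks features by mutual information (relevance minus redundancy),
a sequential forward search picks the subset maximising 5-fold
cross-validated F1, and a 2-D grid search tunes (C, gamma) of an RBF
SVM with class weights in the negative:positive cost ratio.  Prediction
chains the site-stage scorer into UTR-level aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import duplexer, features as feat, sitefilter
from .seqdata import MirnaSeq, UtrSeq

logger = logging.getLogger(__name__)

#: decision score assigned to UTRs with no candidate site
FLOOR_SCORE = -1000.0


# ---------------------------------------------------------------------
# F-beta
# ---------------------------------------------------------------------

@dataclass
class FBetaParams:
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def f_beta(p: float, r: float, params: FBetaParams = FBetaParams()) -> float:
    """Weighted harmonic combination of precision and sensitivity.

    Returns 0 when the denominator vanishes (documented convention).
    """
    b2 = params.beta ** 2
    denom = b2 * p + r
    if denom == 0:
        return 0.0
    return (1 + b2) * p * r / denom


# ---------------------------------------------------------------------
# Mutual information & mRMR
# ---------------------------------------------------------------------

def discretize(x: np.ndarray, max_categories: int = 8) -> np.ndarray:
    """3-state discretization at mean +/- 1 std for continuous features;
    features with few distinct values are used as-is."""
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if len(uniq) <= max_categories:
        lookup = {v: i for i, v in enumerate(uniq)}
        return np.array([lookup[v] for v in x], dtype=int)
    mu, sd = x.mean(), x.std()
    out = np.ones(len(x), dtype=int)
    out[x < mu - sd] = 0
    out[x > mu + sd] = 2
    return out


def mutual_information(x: Sequence, y: Sequence,
                       discretized: bool = False) -> float:
    """Plug-in mutual information estimate in bits.

    Continuous inputs are discretized first (3 states at mean +/- std)
    unless ``discretized`` is set.  Constant vectors yield 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if not discretized:
        x = discretize(x)
        y = discretize(y)
    n = len(x)
    mi = 0.0
    xs, ys = np.unique(x), np.unique(y)
    for xv in xs:
        px = np.mean(x == xv)
        for yv in ys:
            pxy = np.mean((x == xv) & (y == yv))
            if pxy > 0:
                py = np.mean(y == yv)
                mi += pxy * np.log2(pxy / (px * py))
    return max(0.0, float(mi))


@dataclass
class MrmrState:
    """Trace of one greedy mRMR run."""

    selected: List[int] = field(default_factory=list)
    relevance: List[float] = field(default_factory=list)   # D after each step
    redundancy: List[float] = field(default_factory=list)  # R after each step
    objective: List[float] = field(default_factory=list)   # Phi = D - R

    @property
    def rank_list(self) -> List[int]:
        return list(self.selected)


def mrmr_rank(X: np.ndarray, labels: Sequence, n_select: Optional[int] = None
              ) -> MrmrState:
    """Greedy mRMR feature ranking.

    Step 1 picks argmax I(x_i; c); each later step adds the feature
    maximising Phi = D - R of the resulting set, where D is the mean
    feature-label MI and R the mean pairwise feature-feature MI over the
    selected set.  Ties break toward the lower feature index.
    """
    X = np.asarray(X, dtype=float)
    n_samples, n_feat = X.shape
    if n_feat < 2:
        raise ValueError("need >= 2 features")
    k = n_feat if n_select is None else min(n_select, n_feat)

    Xd = np.column_stack([discretize(X[:, j]) for j in range(n_feat)])
    yd = discretize(np.asarray(labels))
    rel = np.array([mutual_information(Xd[:, j], yd, discretized=True)
                    for j in range(n_feat)])
    mi_cache: Dict[Tuple[int, int], float] = {}

    def pair_mi(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_cache:
            mi_cache[key] = mutual_information(Xd[:, key[0]], Xd[:, key[1]],
                                               discretized=True)
        return mi_cache[key]

    state = MrmrState()
    remaining = list(range(n_feat))
    red_sum = {j: 0.0 for j in remaining}  # sum of MI with selected set
    off_sum = 0.0  # ordered off-diagonal pair-MI sum within selected set
    rel_sum = 0.0
    while remaining and len(state.selected) < k:
        best_j, best_phi = None, None
        s = len(state.selected) + 1
        for j in remaining:
            D = (rel_sum + rel[j]) / s
            # R over the candidate set S u {j}: double sum of pairwise MI
            # excluding self terms (so that step 1 reduces to argmax
            # relevance), divided by |S u {j}|^2
            pair_sum = off_sum + 2 * red_sum[j]
            phi = D - pair_sum / (s * s)
            if best_phi is None or phi > best_phi + 1e-12:
                best_phi, best_j = phi, j
        state.selected.append(best_j)
        remaining.remove(best_j)
        off_sum += 2 * red_sum[best_j]
        rel_sum += rel[best_j]
        for j in remaining:
            red_sum[j] += pair_mi(j, best_j)
        s = len(state.selected)
        R = off_sum / (s * s)
        state.relevance.append(float(rel_sum / s))
        state.redundancy.append(float(R))
        state.objective.append(float(rel_sum / s - R))
    return state


# ---------------------------------------------------------------------
# Training configuration and stage models
# ---------------------------------------------------------------------

@dataclass
class TrainConfig:
    c_grid: Tuple[float, ...] = tuple(4.0 ** k for k in range(-2, 5))
    gamma_grid: Tuple[float, ...] = tuple(4.0 ** k for k in range(-6, 1))
    cost_ratio: Optional[float] = None  # None -> n_neg / n_pos
    folds: int = 5
    seed: int = 0
    beta: float = 1.0
    max_sfs_features: int = 25
    rank_mode: str = "global"  # or "per_fold"

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if self.cost_ratio is not None and self.cost_ratio <= 0:
            raise ValueError("cost ratio must be > 0")


def _make_svm(C: float, gamma: float, weight: float) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=C, gamma=gamma,
                    class_weight={1: weight})),
    ])


def _cv_f1(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
           weight: float, config: TrainConfig) -> float:
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    scores = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            scores.append(0.0)
            continue
        model = _make_svm(C, gamma, weight)
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        p = (np.sum((pred == 1) & (y[te] == 1)) / np.sum(pred == 1)
             if np.sum(pred == 1) else 0.0)
        r = (np.sum((pred == 1) & (y[te] == 1)) / np.sum(y[te] == 1)
             if np.sum(y[te] == 1) else 0.0)
        scores.append(f_beta(p, r, FBetaParams(config.beta)))
    return float(np.mean(scores))


def rank_features(X: np.ndarray, y: np.ndarray, config: TrainConfig
                  ) -> List[int]:
    """mRMR rank list, either global or per-fold aggregated by mean rank."""
    if config.rank_mode == "global":
        return mrmr_rank(X, y).rank_list
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True,
                          random_state=config.seed)
    n_feat = X.shape[1]
    positions = np.zeros(n_feat)
    for tr, _ in skf.split(X, y):
        order = mrmr_rank(X[tr], y[tr]).rank_list
        for pos, j in enumerate(order):
            positions[j] += pos
    return list(np.argsort(positions, kind="stable"))


def sequential_forward_search(ranked: Sequence[int], X: np.ndarray,
                              y: np.ndarray, config: TrainConfig
                              ) -> Tuple[List[int], float]:
    """Add features in rank order; keep the prefix maximising CV F1.

    Ties go to the smaller subset.  Subset evaluation uses default SVM
    hyperparameters (C=1, gamma=1/n_features after scaling).
    """
    weight = config.cost_ratio or max(
        1.0, float(np.sum(y == 0)) / max(1, np.sum(y == 1)))
    best_k, best_f1 = 1, -1.0
    limit = min(len(ranked), config.max_sfs_features)
    for k in range(1, limit + 1):
        cols = list(ranked[:k])
        f1 = _cv_f1(X[:, cols], y, 1.0, 1.0 / k, weight, config)
        if f1 > best_f1 + 1e-9:
            best_f1, best_k = f1, k
    return list(ranked[:best_k]), best_f1


@dataclass
class StageModel:
    stage: str  # "site" | "utr"
    feature_names: List[str]
    feature_indices: List[int]
    model: Pipeline
    cv_f1: float
    C: float
    gamma: float
    cost_weight: float
    schema: str = ""

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.model.decision_function(np.asarray(X)[:, self.feature_indices])


def grid_search_train(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                      stage: str = "site",
                      feature_names: Optional[Sequence[str]] = None,
                      select: bool = True) -> StageModel:
    """mRMR + SFS feature selection, then 2-D (C, gamma) grid search
    with 5-fold CV F1, refit on all data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]

    if select:
        ranked = rank_features(X, y, config)
        cols, _ = sequential_forward_search(ranked, X, y, config)
    else:
        cols = list(range(X.shape[1]))
    Xs = X[:, cols]

    weight = config.cost_ratio or max(
        1.0, float(np.sum(y == 0)) / max(1, np.sum(y == 1)))
    best = (None, None, -1.0)
    for C in config.c_grid:
        for gamma in config.gamma_grid:
            f1 = _cv_f1(Xs, y, C, gamma, weight, config)
            if f1 > best[2] + 1e-9:
                best = (C, gamma, f1)
    C, gamma, f1 = best
    logger.info("%s-stage grid search: C=%g gamma=%g CV F1=%.3f "
                "(%d features)", stage, C, gamma, f1, len(cols))
    model = _make_svm(C, gamma, weight)
    model.fit(Xs, y)
    return StageModel(stage=stage,
                      feature_names=[feature_names[j] for j in cols],
                      feature_indices=cols, model=model, cv_f1=f1,
                      C=C, gamma=gamma, cost_weight=weight,
                      schema=feat.schema_hash())


# ---------------------------------------------------------------------
# End-to-end prediction
# ---------------------------------------------------------------------

def site_feature_matrix(mirna: MirnaSeq, utr: UtrSeq,
                        sites: Sequence, window_pad: int = 40,
                        params=None) -> np.ndarray:
    params = params or duplexer.DEFAULT_PARAMS
    rows = []
    for site in sites:
        dup = duplexer.fold_duplex(mirna, utr, site, params)
        acc = duplexer.accessibility(utr, site, dup.e_total, window_pad,
                                     params)
        rows.append(feat.extract_site_features(site, utr, dup, acc).values)
    return np.array(rows) if rows else np.empty((0, 113))


def predict_targets(mirna: MirnaSeq, utrs: Sequence[UtrSeq],
                    site_model: StageModel, utr_model: StageModel,
                    window_pad: int = 40,
                    rule5_strict: bool = True) -> List[Tuple[str, float]]:
    """Per-UTR pipeline: scan -> fold -> site features -> site scores ->
    UTR features -> UTR score; ranked descending, ties by utr_id.

    UTRs with no candidate site receive :data:`FLOOR_SCORE` and sort
    last.
    """
    if site_model.schema != utr_model.schema:
        raise ValueError("site and UTR models built on different schemas")
    results = []
    for utr in utrs:
        sites = sitefilter.scan_sites(mirna, utr, rule5_strict)
        if not sites:
            results.append((utr.id, FLOOR_SCORE))
            continue
        Xs = site_feature_matrix(mirna, utr, sites, window_pad)
        site_scores = site_model.decision_scores(Xs)
        uvec = feat.extract_utr_features(utr, sites, site_scores)
        score = float(utr_model.decision_scores(uvec.values[None, :])[0])
        results.append((utr.id, score))
    results.sort(key=lambda t: (-t[1], t[0]))
    return results
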