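"""Cross-validation, ranking metrics and hyperparameter grid search.

The protocol follows standard interaction-prediction practice: known
interactions are split into folds; in each round one fold of positives is
held out (zeroed in the training matrix), the model is trained on the rest,
and the held-out positives are scored against *all* unobserved pairs of the
original matrix as test negatives. Neighbour smoothing is applied per fold
to the training matrix only, so no held-out positive leaks into training.
Vicus matrices depend only on the similarity networks and are shared across
folds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score)

from .coldstart import (build_constraint_graph, known_node_set,
                        project_latent)
from .containers import InteractionMatrix, SimilarityNetwork
from .lmf import LMFLNC
from .vicus import DiffusionConfig, knn_laplacian, vicus_matrix
from .wknnp import wknnp_smooth

__all__ = [
    "CvPlan",
    "MetricReport",
    "PipelineConfig",
    "make_folds",
    "aupr",
    "auc",
    "f1_best",
    "cross_validate",
    "grid_search",
]

logger = logging.getLogger(__name__)


@dataclass
class CvPlan:
    """Fold/repeat layout for cross-validation over known interactions."""

    n_folds: int = 5
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least two folds")
        if self.n_repeats < 1:
            raise ValueError("need at least one repeat")


@dataclass
class MetricReport:
    """Per-(repeat, fold) metrics with aggregate means and deviations."""

    records: pd.DataFrame

    @property
    def means(self) -> pd.Series:
        return self.records[["aupr", "auc", "f1"]].mean()

    @property
    def stds(self) -> pd.Series:
        return self.records[["aupr", "auc", "f1"]].std(ddof=0)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "std": self.stds})


def make_folds(A: InteractionMatrix | np.ndarray, n_folds: int = 5,
               seed: int = 0) -> list[np.ndarray]:
    """Seeded random partition of the positive entries into folds.

    Returns a list of ``(fold_size, 2)`` index arrays (row, column) whose
    union is exactly the set of 1-entries; fold sizes differ by at most one.
    """
    vals = A.values if isinstance(A, InteractionMatrix) else np.asarray(A)
    pos = np.argwhere(vals > 0)
    if len(pos) < n_folds:
        raise ValueError(
            f"only {len(pos)} known interactions for {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pos))
    return [pos[idx] for idx in np.array_split(perm, n_folds)]


def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("metric undefined: labels contain a single class")


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise interpolation)."""
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def auc(scores, labels) -> float:
    """Probability that a positive outranks a negative (ties credit 0.5)."""
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def f1_best(scores, labels, threshold: float | None = None) -> float:
    """Maximum F1 over all score thresholds (or F1 at a fixed threshold)."""
    _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if threshold is not None:
        pred = scores >= threshold
        tp = np.sum(pred & (labels > 0))
        if tp == 0:
            return 0.0
        prec = tp / pred.sum()
        rec = tp / (labels > 0).sum()
        return float(2 * prec * rec / (prec + rec))
    precision, recall, _ = precision_recall_curve(labels, scores)
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.maximum(denom, 1e-300),
                  0.0)
    return float(f1.max())


@dataclass
class PipelineConfig:
    """End-to-end settings for one cross-validated pipeline run."""

    model_params: dict = field(default_factory=dict)
    use_wknnp: bool = True
    wknnp_K: int = 5
    wknnp_eta: float = 0.9
    vicus_K: int = 15
    vicus_alpha: float = 0.9
    regularizer: str = "vicus"        # "vicus" | "laplacian"
    use_projection: bool = True
    proj_K: int = 10
    proj_alpha: float = 0.9


def _build_regularizers(met_sim: SimilarityNetwork,
                        dis_sim: SimilarityNetwork,
                        cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    if cfg.regularizer == "vicus":
        dc_m = DiffusionConfig(K=min(cfg.vicus_K, met_sim.n_nodes - 1),
                               alpha_diff=cfg.vicus_alpha)
        dc_d = DiffusionConfig(K=min(cfg.vicus_K, dis_sim.n_nodes - 1),
                               alpha_diff=cfg.vicus_alpha)
        return (vicus_matrix(met_sim, dc_m).vir,
                vicus_matrix(dis_sim, dc_d).vir)
    if cfg.regularizer == "laplacian":
        return (knn_laplacian(met_sim, cfg.vicus_K).vir,
                knn_laplacian(dis_sim, cfg.vicus_K).vir)
    raise ValueError(f"unknown regularizer {cfg.regularizer!r}")


def _run_fold(A: InteractionMatrix, test_pos: np.ndarray,
              met_sim: SimilarityNetwork, dis_sim: SimilarityNetwork,
              Ru: np.ndarray, Rv: np.ndarray, cfg: PipelineConfig,
              fit_seed: int) -> dict:
    train_vals = A.values.copy()
    train_vals[test_pos[:, 0], test_pos[:, 1]] = 0.0
    # protocol integrity: held-out positives must be absent before smoothing
    assert np.all(train_vals[test_pos[:, 0], test_pos[:, 1]] == 0.0)
    train = InteractionMatrix(list(A.metabolite_ids), list(A.disease_ids),
                              train_vals, binary=A.binary)
    if cfg.use_wknnp:
        smoothed = wknnp_smooth(train, met_sim, dis_sim, K=cfg.wknnp_K,
                                eta=cfg.wknnp_eta)
    else:
        smoothed = train
    params = dict(cfg.model_params)
    params.setdefault("random_state", fit_seed)
    model = LMFLNC(**params).fit(smoothed.values, Ru, Rv)
    U, V = model.U_, model.V_
    if cfg.use_projection:
        gm = build_constraint_graph(met_sim, cfg.proj_K, cfg.proj_alpha)
        gd = build_constraint_graph(dis_sim, cfg.proj_K, cfg.proj_alpha)
        U = project_latent(U, gm, known_node_set(train_vals, "metabolites"))
        V = project_latent(V, gd, known_node_set(train_vals, "diseases"))
    probs = model.predict_proba_matrix(U, V)
    neg = np.argwhere(A.values == 0)
    test_idx = np.vstack([test_pos, neg])
    labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(neg))])
    scores = probs[test_idx[:, 0], test_idx[:, 1]]
    return {"aupr": aupr(scores, labels), "auc": auc(scores, labels),
            "f1": f1_best(scores, labels)}


def cross_validate(A: InteractionMatrix, met_sim: SimilarityNetwork,
                   dis_sim: SimilarityNetwork,
                   plan: CvPlan | None = None,
                   config: PipelineConfig | None = None) -> MetricReport:
    """Repeated k-fold cross-validation of the full pipeline.

    Every source of randomness (fold assignment, model initialization)
    derives from ``plan.seed``, so repeated calls with the same plan
    reproduce the report exactly.
    """
    plan = plan or CvPlan()
    config = config or PipelineConfig()
    A.check_aligned(met_sim, dis_sim)
    Ru, Rv = _build_regularizers(met_sim, dis_sim, config)
    rows = []
    for rep in range(plan.n_repeats):
        rep_seed = (plan.seed * 1_000_003 + rep) % (2 ** 31)
        folds = make_folds(A, plan.n_folds, seed=rep_seed)
        for k, test_pos in enumerate(folds):
            metrics = _run_fold(A, test_pos, met_sim, dis_sim, Ru, Rv,
                                config, fit_seed=(rep_seed + k) % (2 ** 31))
            rows.append({"repeat": rep, "fold": k, **metrics})
            logger.debug("repeat %d fold %d: %s", rep, k, metrics)
    return MetricReport(pd.DataFrame(rows))


def grid_search(A: InteractionMatrix, met_sim: SimilarityNetwork,
                dis_sim: SimilarityNetwork,
                alpha_grid, lambda_grid,
                plan: CvPlan | None = None,
                config: PipelineConfig | None = None,
                ) -> tuple[dict, pd.DataFrame]:
    """AUPR surface over (alpha_reg, lambda_nbr) via cross-validation.

    Returns the best cell (argmax AUPR; ties go to the smaller lambda then
    the smaller alpha) and the full surface as a DataFrame with one row per
    grid cell.
    """
    plan = plan or CvPlan(n_repeats=1)
    config = config or PipelineConfig()
    cells = []
    for a, lam in itertools.product(alpha_grid, lambda_grid):
        cfg = PipelineConfig(**{**config.__dict__,
                                "model_params": {**config.model_params,
                                                 "alpha_reg": float(a),
                                                 "lambda_nbr": float(lam)}})
        report = cross_validate(A, met_sim, dis_sim, plan, cfg)
        cells.append({"alpha_reg": float(a), "lambda_nbr": float(lam),
                      "aupr": report.means["aupr"],
                      "auc": report.means["auc"],
                      "f1": report.means["f1"]})
    surface = pd.DataFrame(cells)
    best_row = surface.sort_values(
        ["aupr", "lambda_nbr", "alpha_reg"],
        ascending=[False, True, True], kind="mergesort").iloc[0]
    best = {"alpha_reg": float(best_row["alpha_reg"]),
            "lambda_nbr": float(best_row["lambda_nbr"]),
            "aupr": float(best_row["aupr"])}
    return best, surface
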