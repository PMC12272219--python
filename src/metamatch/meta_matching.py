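"""Meta-matching: translating a multi-output base model to a new phenotype.

Two variants. *Stacking* ranks the base model's P phenotype outputs by their
coefficient of determination (COD) against the new phenotype on the K shot
participants, keeps the top M = min(K, P) outputs, and trains a kernel ridge
regression with a correlation kernel on those M predictions. *Finetune* keeps
the single best-COD output node's weights as the new head initialization and
finetunes the last two layers, exactly as classical transfer learning does
from a random head.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .baselines import FinetuneConfig, _LastLayersFinetuner, _cv_splits, _safe_cod
from .metrics import cod
from .sfcn import SFCNRegressor
from .tables import NormStats, apply_norm_stats, fit_norm_stats

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "rank_outputs_by_cod",
    "select_top_m",
    "correlation_kernel",
    "correlation_kernel_matrix",
    "MetaMatchingStacking",
    "MetaMatchingFinetune",
    "fit_stacking",
    "predict_stacking",
    "mm_finetune",
]

DEFAULT_LAMBDA_GRID = (0.0, 1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0, 1000.0)


def rank_outputs_by_cod(base_preds: np.ndarray, target: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """COD of each base-model output against the target, plus descending ranking.

    Ties are broken toward the lower output index (stable sort on −COD).
    """
    base_preds = np.atleast_2d(np.asarray(base_preds, dtype=float))
    target = np.asarray(target, dtype=float).ravel()
    if base_preds.shape[0] != target.size:
        raise ValueError("base_preds and target disagree on the number of participants")
    if target.size < 2:
        raise ValueError("need at least 2 participants")
    if np.ptp(target) == 0:
        raise ValueError("COD undefined for a constant target")
    cods = np.array([cod(target, base_preds[:, p]) for p in range(base_preds.shape[1])])
    ranking = np.argsort(-cods, kind="stable")
    return cods, ranking


def select_top_m(ranking: np.ndarray, K: int, P: int) -> np.ndarray:
    """First min(K, P) entries of the ranking (e.g. K=20, P=33 → 20; K=50 → 33)."""
    ranking = np.asarray(ranking)
    m = min(int(K), int(P))
    return ranking[:m]


def correlation_kernel(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two feature vectors of length M ≥ 2."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 2:
        raise ValueError("correlation kernel needs vectors of length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation kernel undefined for constant vectors")
    ac = a - a.mean()
    bc = b - b.mean()
    return float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))


def _row_standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("correlation kernel undefined for a constant feature row")
    return (X - mu) / sd


def correlation_kernel_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise correlation kernel between the rows of A (n×M) and B (k×M)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimension mismatch")
    M = A.shape[1]
    if M < 2:
        raise ValueError("correlation kernel needs M >= 2 features")
    return _row_standardize(A) @ _row_standardize(B).T / M


@dataclass
class StackingModel:
    """Fitted stacking state: which outputs were kept, the K reference rows the
    kernel is evaluated against, the KRR dual coefficients and ridge λ."""

    selected_output_indices: np.ndarray
    reference_preds: np.ndarray  # K × M
    dual_coef: np.ndarray  # K
    ridge_lambda: float
    target_norm: NormStats
    cod_per_output: np.ndarray = field(default=None)  # type: ignore[assignment]


class MetaMatchingStacking(BaseEstimator, RegressorMixin):
    """Meta-matching stacking: correlation-kernel ridge regression on the top-M
    base-model predictions.

    λ is tuned by five-fold CV on the K shots maximizing validation-fold COD;
    the final dual solve α = (G + λI)⁻¹ y uses all K shots. With M = 1 (only
    possible when the base model has a single output) a correlation across a
    length-1 vector is undefined, so the model falls back to plain ridge
    regression on that single prediction.
    """

    def __init__(self, lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
                 cv_folds: int = 5, seed: int = 0, select: bool = True) -> None:
        self.lambda_grid = lambda_grid
        self.cv_folds = cv_folds
        self.seed = seed
        self.select = select

    def fit(self, base_preds: np.ndarray, y: np.ndarray) -> "MetaMatchingStacking":
        preds = np.atleast_2d(np.asarray(base_preds, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        K, P = preds.shape
        if y.size != K:
            raise ValueError("base_preds and y disagree on the number of participants")
        self.target_norm_ = fit_norm_stats(y[:, None], names=["target"])
        yz = apply_norm_stats(y[:, None], self.target_norm_).ravel()
        if self.select:
            cods, ranking = rank_outputs_by_cod(preds, yz)
            selected = select_top_m(ranking, K, P)
        else:
            cods = None
            selected = np.arange(P)
        Xsel = preds[:, selected]
        M = Xsel.shape[1]
        self._single_feature = M == 1
        splits = _cv_splits(K, self.cv_folds, self.seed)

        best = (-np.inf, None)
        self.cv_results_ = []
        for lam in self.lambda_grid:
            scores = []
            for tr, va in splits:
                try:
                    pred_va = self._solve_and_predict(Xsel[tr], yz[tr], Xsel[va], lam)
                except np.linalg.LinAlgError:
                    warnings.warn(f"singular kernel system at lambda={lam}; skipping")
                    scores = [-np.inf]
                    break
                scores.append(_safe_cod(yz[va], pred_va))
            mean_score = float(np.mean(scores))
            self.cv_results_.append({"lambda": lam, "mean_cv_cod": mean_score})
            if mean_score > best[0]:
                best = (mean_score, lam)
        if best[1] is None:
            raise RuntimeError("no feasible lambda in the grid")
        lam = best[1]
        try:
            alpha = self._dual_solve(Xsel, yz, lam)
        except np.linalg.LinAlgError:
            feasible = [d["lambda"] for d in self.cv_results_
                        if np.isfinite(d["mean_cv_cod"]) and d["lambda"] != lam]
            if not feasible:
                raise
            warnings.warn(f"singular final system at lambda={lam}; "
                          f"falling back to lambda={feasible[0]}")
            lam = feasible[0]
            alpha = self._dual_solve(Xsel, yz, lam)
        self.model_ = StackingModel(np.asarray(selected), Xsel.copy(), alpha,
                                    float(lam), self.target_norm_, cods)
        return self

    def _gram(self, A, B):
        if self._single_feature:
            raise RuntimeError("gram matrix not used in single-feature mode")
        return correlation_kernel_matrix(A, B)

    def _dual_solve(self, Xtr, ytr, lam):
        if self._single_feature:
            x = Xtr.ravel()
            # primal ridge on one feature: w = x·y / (x·x + λ)
            return np.array([x @ ytr / (x @ x + lam)]) if (x @ x + lam) != 0 \
                else np.zeros(1)
        G = self._gram(Xtr, Xtr)
        sol = np.linalg.solve(G + lam * np.eye(G.shape[0]), ytr)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError("non-finite dual solution")
        return sol

    def _solve_and_predict(self, Xtr, ytr, Xte, lam):
        alpha = self._dual_solve(Xtr, ytr, lam)
        if self._single_feature:
            return Xte.ravel() * alpha[0]
        return self._gram(Xte, Xtr) @ alpha

    def predict(self, base_preds: np.ndarray) -> np.ndarray:
        """ŷ_i = Σ_j α_j · k(x_i, x_j) over the K reference rows (z-space)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the model first")
        preds = np.atleast_2d(np.asarray(base_preds, dtype=float))
        m = self.model_
        if self.select:
            if preds.shape[1] <= int(np.max(m.selected_output_indices)):
                raise ValueError("base prediction matrix is narrower than the "
                                 "selected output indices")
            X = preds[:, m.selected_output_indices]
        else:
            X = preds
        if X.shape[1] != m.reference_preds.shape[1]:
            raise ValueError(f"expected {m.reference_preds.shape[1]} selected "
                             f"predictions, got {X.shape[1]}")
        if self._single_feature:
            return X.ravel() * m.dual_coef[0]
        return correlation_kernel_matrix(X, m.reference_preds) @ m.dual_coef


class MetaMatchingFinetune(_LastLayersFinetuner):
    """Meta-matching finetune: the head starts from the weights of the base
    output node with the best COD on the K shots (ties → lower index); the
    remaining nodes are removed, then the last two layers are finetuned with
    the same protocol as classical transfer learning.

    ``source_output_`` records which base node seeded the head.
    """

    def _head_init(self, head_rng, feats, icv_z, yz):
        start = self.base.config_.n_blocks - 1
        base_preds = self.base.net_.predict(feats, icv_z, start_block=start)
        _, ranking = rank_outputs_by_cod(base_preds, yz.ravel())
        p_star = int(ranking[0])
        W = self.base.net_.head.params["W"][:, p_star:p_star + 1]
        b = self.base.net_.head.params["b"][p_star:p_star + 1]
        return W.copy(), b.copy(), p_star


def fit_stacking(base_preds_shots: np.ndarray, target: np.ndarray,
                 lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
                 cv_folds: int = 5, seed: int = 0) -> MetaMatchingStacking:
    """KRR stacking on an already-selected K×M prediction matrix."""
    return MetaMatchingStacking(lambda_grid, cv_folds, seed, select=False).fit(
        base_preds_shots, target)


def predict_stacking(model: MetaMatchingStacking, base_preds_test: np.ndarray) -> np.ndarray:
    return model.predict(base_preds_test)


def mm_finetune(base: SFCNRegressor, shot_features: np.ndarray,
                shot_target: np.ndarray, shot_icv: np.ndarray | None = None,
                cfg: FinetuneConfig | None = None) -> MetaMatchingFinetune:
    return MetaMatchingFinetune(base, cfg).fit(shot_features, shot_target, shot_icv)
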