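"""Comparison baselines: elastic net on morphometric features and classical
transfer learning of the pretrained 3D CNN.

Both follow the K-shot protocol: all normalization statistics (features,
targets) are computed from the K shot participants and carried over unchanged
to the held-out test participants, and hyperparameters are chosen by five-fold
cross-validation on the K shots maximizing the coefficient of determination.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import KFold

from .metrics import cod
from .sfcn import SFCNRegressor, TrainConfig, train_network
from .splits import child_seed
from .tables import apply_norm_stats, fit_norm_stats

__all__ = [
    "ElasticNetConfig",
    "FinetuneConfig",
    "MorphometricElasticNet",
    "TransferLearningRegressor",
    "fit_elastic_net",
    "predict_elastic_net",
    "transfer_learn",
]

#: Default λ_total grid (10 log-spaced decades) × L1 mixing ratios; spans the
#: under- to over-regularized regimes at F ≈ 164 features.
DEFAULT_ALPHAS = tuple(np.logspace(-4, 2, 10))
DEFAULT_L1_RATIOS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
DEFAULT_LR_GRID = (1e-2, 1e-3, 1e-4, 1e-5)


@dataclass(frozen=True)
class ElasticNetConfig:
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    l1_ratios: tuple[float, ...] = DEFAULT_L1_RATIOS
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alphas or not self.l1_ratios:
            raise ValueError("hyperparameter grids must be non-empty")
        if min(self.alphas) < 0:
            raise ValueError("regularization strengths must be >= 0")


@dataclass(frozen=True)
class FinetuneConfig:
    lr_grid: tuple[float, ...] = DEFAULT_LR_GRID
    cv_folds: int = 5
    max_epochs: int = 50
    patience: int = 5
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lr_grid:
            raise ValueError("learning-rate grid must be non-empty")


def _cv_splits(n: int, folds: int, seed: int):
    if n < folds:
        raise ValueError(
            f"K={n} participants cannot be split into {folds} CV folds; "
            f"reduce cv_folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _safe_cod(y, yhat) -> float:
    # CV folds of tiny K can have constant targets; score such folds as worthless
    if np.ptp(np.asarray(y, dtype=float)) == 0:
        return -np.inf
    return cod(y, yhat)


class MorphometricElasticNet(BaseEstimator, RegressorMixin):
    """Elastic-net regression on (z-scored) morphometric features.

    λ1/λ2 are parameterized through scikit-learn's (alpha, l1_ratio):
    λ1 = alpha·l1_ratio and λ2 = alpha·(1 − l1_ratio)/2. The grid point with
    the highest mean validation-fold COD is refit on all K shots. Feature and
    target z-scoring statistics are computed from the K shots at fit time and
    reused at predict time; predictions are in target z-space.
    """

    def __init__(self, config: ElasticNetConfig | None = None) -> None:
        self.config = config

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MorphometricElasticNet":
        cfg = self.config if self.config is not None else ElasticNetConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of participants")
        K = X.shape[0]
        splits = _cv_splits(K, cfg.cv_folds, cfg.seed)
        self.feature_norm_ = fit_norm_stats(X)
        self.target_norm_ = fit_norm_stats(y[:, None], names=["target"])
        Xz = apply_norm_stats(X, self.feature_norm_)
        yz = apply_norm_stats(y[:, None], self.target_norm_).ravel()

        best = (-np.inf, None, None)
        cv_results = []
        with warnings.catch_warnings():
            # weakly-penalized grid points routinely stop at max_iter; the CV
            # score already penalizes genuinely unstable fits
            warnings.simplefilter("ignore", ConvergenceWarning)
            for alpha in cfg.alphas:
                for l1_ratio in cfg.l1_ratios:
                    scores = []
                    for tr, va in splits:
                        model = self._make(alpha, l1_ratio, cfg.seed)
                        model.fit(Xz[tr], yz[tr])
                        scores.append(_safe_cod(yz[va], model.predict(Xz[va])))
                    mean_score = float(np.mean(scores))
                    cv_results.append({"alpha": alpha, "l1_ratio": l1_ratio,
                                       "mean_cv_cod": mean_score})
                    if mean_score > best[0]:
                        best = (mean_score, alpha, l1_ratio)
            self.cv_results_ = cv_results
            _, self.alpha_, self.l1_ratio_ = best
            self.lambda1_ = self.alpha_ * self.l1_ratio_
            self.lambda2_ = self.alpha_ * (1 - self.l1_ratio_) / 2
            final = self._make(self.alpha_, self.l1_ratio_, cfg.seed)
            final.fit(Xz, yz)
        self.coef_ = np.asarray(final.coef_, dtype=float).ravel()
        self.intercept_ = float(np.atleast_1d(final.intercept_)[0])
        return self

    @staticmethod
    def _make(alpha: float, l1_ratio: float, seed: int):
        if alpha == 0:
            return LinearRegression()
        return ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000,
                          random_state=seed)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_norm_.names):
            raise ValueError(
                f"feature count {X.shape[1]} does not match the "
                f"{len(self.feature_norm_.names)} features seen at fit time")
        Xz = apply_norm_stats(X, self.feature_norm_)
        return Xz @ self.coef_ + self.intercept_


def fit_elastic_net(features: np.ndarray, target: np.ndarray,
                    cfg: ElasticNetConfig | None = None) -> MorphometricElasticNet:
    return MorphometricElasticNet(config=cfg).fit(features, target)


def predict_elastic_net(model: MorphometricElasticNet, features: np.ndarray) -> np.ndarray:
    return model.predict(features)


# ---------------------------------------------------------------------------
# finetuning machinery shared by classical transfer learning and the
# meta-matching finetune variant (which differ only in head initialization)
# ---------------------------------------------------------------------------


class _LastLayersFinetuner(BaseEstimator, RegressorMixin):
    """Finetunes the last two layers (last conv block + output head) of a
    pretrained base model; all earlier blocks stay frozen.

    ``fit``/``predict`` operate on frozen-trunk feature tensors as produced by
    ``SFCNRegressor.trunk_features`` (computing them once per dataset avoids
    re-running the frozen trunk in every CV fold). The learning rate is chosen
    by five-fold CV on the K shots (each fold trained with early stopping on
    the held-out fold) and the final model is trained on all K with an 80/20
    early-stopping split and at most ``max_epochs`` epochs.
    """

    _head_mode = "random"

    def __init__(self, base: SFCNRegressor, config: FinetuneConfig | None = None) -> None:
        self.base = base
        self.config = config

    # subclass hook: returns (W_column, bias, provenance index or None)
    def _head_init(self, head_rng, feats, icv_z, yz):
        base_head = self.base.net_.head
        n_in = base_head.params["W"].shape[0]
        return head_rng.normal(0.0, 0.01, size=(n_in, 1)), np.zeros(1), None

    def _make_headnet(self, head_W, head_b):
        net = copy.deepcopy(self.base.net_)
        net.n_outputs = 1
        net.head.params["W"] = head_W.copy()
        net.head.params["b"] = head_b.copy()
        for layer in net._layers():
            layer.grads = {}
        return net

    def fit(self, X: np.ndarray, y: np.ndarray,
            icv: np.ndarray | None = None) -> "_LastLayersFinetuner":
        cfg = self.config if self.config is not None else FinetuneConfig()
        feats = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        K = feats.shape[0]
        if y.size != K:
            raise ValueError("X and y disagree on the number of participants")
        splits = _cv_splits(K, cfg.cv_folds, cfg.seed)
        self.target_norm_ = fit_norm_stats(y[:, None], names=["target"])
        yz = apply_norm_stats(y[:, None], self.target_norm_)
        icv_z = self.base._icv_z(icv) if self.base.config_.use_icv else None
        mask = np.ones_like(yz, dtype=bool)
        start = self.base.config_.n_blocks - 1

        head_rng = np.random.default_rng(child_seed(cfg.seed, 0))
        head_W, head_b, self.source_output_ = self._head_init(head_rng, feats, icv_z, yz)

        def _run(train_idx, val_idx, lr, run_seed):
            net = self._make_headnet(head_W, head_b)
            tc = TrainConfig(lr=lr, max_epochs=cfg.max_epochs, patience=cfg.patience,
                             batch_size=cfg.batch_size, seed=run_seed)
            train_network(net, feats, icv_z, yz, mask,
                          np.asarray(train_idx), np.asarray(val_idx), tc,
                          start_block=start)
            return net

        best = (-np.inf, cfg.lr_grid[0])
        self.cv_results_ = []
        for li, lr in enumerate(cfg.lr_grid):
            scores = []
            for fi, (tr, va) in enumerate(splits):
                net = _run(tr, va, lr, child_seed(cfg.seed, 1, li, fi))
                preds = net.predict(feats[va], None if icv_z is None else icv_z[va],
                                    start_block=start)
                scores.append(_safe_cod(yz[va].ravel(), preds.ravel()))
            mean_score = float(np.mean(scores))
            self.cv_results_.append({"lr": lr, "mean_cv_cod": mean_score})
            if mean_score > best[0]:
                best = (mean_score, lr)
        self.lr_ = best[1]

        rng = np.random.default_rng(child_seed(cfg.seed, 2))
        perm = rng.permutation(K)
        n_val = max(int(round(0.2 * K)), 1)
        self.net_ = _run(perm[n_val:], perm[:n_val], self.lr_, child_seed(cfg.seed, 3))
        self._start_block = start
        return self

    def predict(self, X: np.ndarray, icv: np.ndarray | None = None) -> np.ndarray:
        """Predictions (target z-space) from frozen-trunk feature tensors."""
        if not hasattr(self, "net_"):
            raise RuntimeError("fit the model first")
        icv_z = self.base._icv_z(icv) if self.base.config_.use_icv else None
        return self.net_.predict(np.asarray(X, dtype=float), icv_z,
                                 start_block=self._start_block).ravel()

    def trainable_parameter_count(self) -> int:
        return self.net_.parameter_count(from_block=self._start_block)


class TransferLearningRegressor(_LastLayersFinetuner):
    """Classical transfer learning: the output head is re-initialized with
    small random weights before the last two layers are finetuned."""


def transfer_learn(base: SFCNRegressor, shot_features: np.ndarray,
                   shot_target: np.ndarray, shot_icv: np.ndarray | None = None,
                   cfg: FinetuneConfig | None = None) -> TransferLearningRegressor:
    return TransferLearningRegressor(base, cfg).fit(shot_features, shot_target, shot_icv)
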