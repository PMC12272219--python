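"""Haufe-transform feature importance.

For a predictive model, the Haufe transform converts decision weights into an
interpretable activation pattern: the covariance between the model's
prediction and each input feature across participants. A positive value at a
voxel means higher intensity there goes with a higher predicted phenotype.
The same construction applied to the stacking model's inputs yields a
per-base-output (per meta-training phenotype) importance vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HaufeMap", "haufe_voxel", "haufe_average", "haufe_phenotype"]


@dataclass
class HaufeMap:
    """Voxelwise importance grid aligned with the input volume grid."""

    importance: np.ndarray
    n_samples: int
    n_repeats: int = 1

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if self.importance.ndim != 3:
            raise ValueError("importance must be a 3D grid")
        if not np.all(np.isfinite(self.importance)):
            raise ValueError("importance must be finite")


def haufe_voxel(predictions: np.ndarray, volumes: np.ndarray) -> HaufeMap:
    """Per-voxel sample covariance (ddof=1) between prediction and intensity.

    ``predictions`` has length K; ``volumes`` is (K, X, Y, Z).
    """
    predictions = np.asarray(predictions, dtype=float).ravel()
    volumes = np.asarray(volumes, dtype=float)
    K = predictions.size
    if volumes.ndim != 4 or volumes.shape[0] != K:
        raise ValueError("volumes must be (K, X, Y, Z) matching predictions")
    if K < 2:
        raise ValueError("need at least 2 participants")
    if np.ptp(predictions) == 0:
        raise ValueError("Haufe transform undefined for constant predictions")
    pc = predictions - predictions.mean()
    vc = volumes - volumes.mean(axis=0)
    cov = np.tensordot(pc, vc, axes=([0], [0])) / (K - 1)
    return HaufeMap(cov, n_samples=K)


def haufe_average(maps: list[HaufeMap]) -> HaufeMap:
    """Voxelwise mean over repeats (e.g. over repeated K-participant draws)."""
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].importance.shape
    for m in maps[1:]:
        if m.importance.shape != shape:
            raise ValueError("maps have mismatched shapes")
    mean = np.mean([m.importance for m in maps], axis=0)
    return HaufeMap(mean, n_samples=maps[0].n_samples, n_repeats=len(maps))


def haufe_phenotype(stacking_prediction: np.ndarray, base_preds: np.ndarray,
                    use_correlation: bool = False) -> np.ndarray:
    """Importance of each base-model output for the final stacking prediction.

    The covariance (across the K participants) between the stacking model's
    prediction and each of the P inputs to the stacking model — outputs the
    stacking model did not select still get a value. ``use_correlation``
    rescales to Pearson correlations instead.
    """
    pred = np.asarray(stacking_prediction, dtype=float).ravel()
    base_preds = np.atleast_2d(np.asarray(base_preds, dtype=float))
    K = pred.size
    if base_preds.shape[0] != K:
        raise ValueError("base_preds must have one row per participant")
    if K < 2:
        raise ValueError("need at least 2 participants")
    if np.ptp(pred) == 0:
        raise ValueError("Haufe transform undefined for constant predictions")
    pc = pred - pred.mean()
    bc = base_preds - base_preds.mean(axis=0)
    cov = pc @ bc / (K - 1)
    if use_correlation:
        sd = np.sqrt((pc @ pc) / (K - 1)) * bc.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = np.where(sd > 0, cov / sd, 0.0)
    return cov
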