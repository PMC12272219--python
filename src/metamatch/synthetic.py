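"""Synthetic desk-scale datasets with the structure meta-matching exploits.

Participants carry latent factors z ~ N(0, I_L). Volumes are a head-like
template scaled by a per-participant global size factor, plus one additive
Gaussian-blob field per latent factor weighted by that participant's factor
score, plus voxel noise — intensity-coded signal that a covariance-based
interpretation (Haufe transform) can localize. Phenotypes are noisy linear
readouts y = Wz + ε, so any pair of phenotypes sharing loadings is correlated
by an analytically known amount. Morphometric tables are region means/sums of
the same volumes (plus ICV) with added measurement noise, so image-based and
feature-based methods see consistent information. ICV is log-linear in the
global size factor.

``make_meta_benchmark`` builds disjoint meta-training / meta-test participant
and phenotype sets in which each meta-test phenotype has a *specified*
maximum |correlation| with its nearest meta-training phenotype, enabling
sweeps of how translation quality depends on phenotype overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .splits import MetaSplit
from .tables import MorphometricTable, PhenotypeTable

__all__ = ["SyntheticConfig", "SyntheticDataset", "MetaBenchmark",
           "generate", "make_meta_benchmark"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``loadings`` is the P_total × L phenotype loading matrix W; the default
    (None) assigns each phenotype unit-variance loadings on one factor with
    noise variance ``phenotype_noise_var``. ``morph_noise_scale`` is the
    measurement-noise standard deviation of each morphometric readout relative
    to its across-participant signal standard deviation (0 = noiseless
    readouts).
    """

    n: int = 200
    grid_shape: tuple[int, int, int] = (32, 40, 32)
    n_latents: int = 5
    n_blobs_per_latent: int = 3
    blob_radius_range: tuple[float, float] = (4.0, 6.0)
    blob_amplitude: float = 0.15
    template_amplitude: float = 1.0
    size_factor_std: float = 0.05
    voxel_noise_std: float = 0.05
    loadings: np.ndarray | None = None
    phenotype_noise_var: float | np.ndarray = 0.1
    phenotype_names: tuple[str, ...] | None = None
    n_cortical_regions: int = 12
    n_subcortical_regions: int = 8
    morph_noise_scale: float = 1.0
    icv_log_mean: float = 14.2
    icv_size_coupling: float = 3.0
    icv_noise_std: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(v) for v in self.grid_shape))
        object.__setattr__(self, "blob_radius_range",
                           tuple(float(v) for v in self.blob_radius_range))
        if self.phenotype_names is not None:
            object.__setattr__(self, "phenotype_names", tuple(self.phenotype_names))
        if self.n_latents < 1:
            raise ValueError("need at least one latent factor")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        noise = np.atleast_1d(np.asarray(self.phenotype_noise_var, dtype=float))
        if np.any(noise < 0):
            raise ValueError("phenotype noise variances must be >= 0")

    def resolved_loadings(self) -> np.ndarray:
        """W with the default one-factor-per-phenotype pattern when unset."""
        if self.loadings is not None:
            W = np.atleast_2d(np.asarray(self.loadings, dtype=float))
            if W.shape[1] != self.n_latents:
                raise ValueError("loadings must have n_latents columns")
            return W
        P = self.n_latents
        noise = np.broadcast_to(np.atleast_1d(
            np.asarray(self.phenotype_noise_var, dtype=float)), (P,))
        return np.diag(np.sqrt(np.clip(1.0 - noise, 0.0, None)))

    def resolved_noise_var(self, P: int) -> np.ndarray:
        return np.broadcast_to(np.atleast_1d(
            np.asarray(self.phenotype_noise_var, dtype=float)), (P,)).astype(float)


@dataclass
class SyntheticDataset:
    """One generated cohort, bit-reproducible from (config, seed)."""

    config: SyntheticConfig
    participant_ids: list[str]
    volumes: np.ndarray  # (n, X, Y, Z), float32
    icv: np.ndarray  # (n,)
    phenotypes: PhenotypeTable
    morphometrics: MorphometricTable
    latents: np.ndarray  # (n, L)
    loadings: np.ndarray  # (P, L)
    size_factors: np.ndarray  # (n,)
    blob_fields: np.ndarray  # (L, X, Y, Z), float32


def _gaussian_field(grid_shape, center, sigma) -> np.ndarray:
    axes = [np.arange(s, dtype=np.float32) for s in grid_shape]
    d2 = ((axes[0][:, None, None] - center[0]) ** 2
          + (axes[1][None, :, None] - center[1]) ** 2
          + (axes[2][None, None, :] - center[2]) ** 2)
    return np.exp(-d2 / (2.0 * sigma ** 2)).astype(np.float32)


def _head_template(grid_shape) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in grid_shape]
    axes = [np.arange(s, dtype=np.float32) for s in grid_shape]
    r2 = ((axes[0][:, None, None] - center[0]) ** 2 / (0.45 * grid_shape[0]) ** 2
          + (axes[1][None, :, None] - center[1]) ** 2 / (0.45 * grid_shape[1]) ** 2
          + (axes[2][None, None, :] - center[2]) ** 2 / (0.45 * grid_shape[2]) ** 2)
    return np.exp(-r2 * 2.0).astype(np.float32)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a full cohort: volumes + ICV, phenotype and morphometric tables."""
    rng = np.random.default_rng(config.seed)
    gs = config.grid_shape
    r_lo, r_hi = config.blob_radius_range
    if any(2 * r_hi >= s for s in gs):
        raise ValueError(f"blob radius up to {r_hi} does not fit grid {gs}")

    # seeded blob geometry, one field per latent factor
    fields = np.empty((config.n_latents,) + gs, dtype=np.float32)
    masks: list[np.ndarray] = []
    for l in range(config.n_latents):
        f = np.zeros(gs, dtype=np.float32)
        first_mask = None
        for b in range(config.n_blobs_per_latent):
            radius = rng.uniform(r_lo, r_hi)
            center = [rng.uniform(radius, s - 1 - radius) for s in gs]
            g = _gaussian_field(gs, center, radius / 2.0)
            if first_mask is None:
                first_mask = g > 0.5
            f += g
        fields[l] = f
        masks.append(first_mask)

    n = config.n
    z = rng.standard_normal((n, config.n_latents))
    s = 1.0 + config.size_factor_std * rng.standard_normal(n)
    template = _head_template(gs) * config.template_amplitude

    V = int(np.prod(gs))
    vol = (s[:, None].astype(np.float32) * template.reshape(1, V)
           + config.blob_amplitude * (z.astype(np.float32) @ fields.reshape(-1, V))
           + config.voxel_noise_std * rng.standard_normal((n, V), dtype=np.float32))
    volumes = vol.reshape((n,) + gs)

    icv = np.exp(config.icv_log_mean + config.icv_size_coupling * (s - 1.0)
                 + config.icv_noise_std * rng.standard_normal(n))

    W = config.resolved_loadings()
    P = W.shape[0]
    noise_var = config.resolved_noise_var(P)
    y = z @ W.T + rng.standard_normal((n, P)) * np.sqrt(noise_var)
    names = list(config.phenotype_names) if config.phenotype_names is not None \
        else [f"pheno_{j:02d}" for j in range(P)]
    observed = np.ones((n, P), dtype=bool)
    if config.missing_rate > 0:
        observed = rng.random((n, P)) >= config.missing_rate
        for j in range(P):  # keep every phenotype estimable
            if observed[:, j].sum() < 2:
                observed[rng.choice(n, 2, replace=False), j] = True
    ids = [f"sub-{i:04d}" for i in range(n)]
    values = np.where(observed, y, np.nan)
    phenotypes = PhenotypeTable(ids, names, values, observed)

    morphometrics = _morphometrics(config, rng, ids, volumes, masks, icv)

    return SyntheticDataset(config, ids, volumes, icv, phenotypes, morphometrics,
                            z, W, s, fields)


def _morphometrics(config, rng, ids, volumes, blob_masks, icv) -> MorphometricTable:
    """Region readouts: blob-mask regions carry latent signal; extra spherical
    null regions carry only global size. Measurement noise is added relative
    to each readout's across-participant std."""
    gs = config.grid_shape
    n = volumes.shape[0]
    C, S = config.n_cortical_regions, config.n_subcortical_regions
    region_masks: list[np.ndarray] = list(blob_masks)
    while len(region_masks) < C + S:
        radius = rng.uniform(*config.blob_radius_range)
        center = [rng.uniform(radius, s - 1 - radius) for s in gs]
        region_masks.append(_gaussian_field(gs, center, radius / 2.0) > 0.5)
    region_masks = region_masks[:C + S]

    flat = volumes.reshape(n, -1)
    cols = [icv]
    names = ["ICV"]
    means = []
    sums = []
    for mask in region_masks:
        idx = np.flatnonzero(mask.ravel())
        means.append(flat[:, idx].mean(axis=1))
        sums.append(flat[:, idx].sum(axis=1))
    for r in range(C):
        names.append(f"thickness_ctx{r:02d}")
        cols.append(means[r])
    for r in range(C):
        names.append(f"volume_ctx{r:02d}")
        cols.append(sums[r])
    for r in range(S):
        names.append(f"subcortical_volume_s{r:02d}")
        cols.append(sums[C + r])
    X = np.column_stack(cols)
    if config.morph_noise_scale > 0:
        sd = X.std(axis=0, ddof=1)
        X = X + rng.standard_normal(X.shape) * (config.morph_noise_scale * sd)
        X[:, 0] = np.abs(X[:, 0])  # ICV stays positive
    return MorphometricTable(ids, names, X)


@dataclass
class MetaBenchmark:
    """A generated cohort partitioned into disjoint meta-training and meta-test
    participant/phenotype sets with controlled phenotype overlap."""

    dataset: SyntheticDataset
    split: MetaSplit
    max_corr_targets: np.ndarray
    nearest_train_phenotype: list[str]

    def _indices(self, ids: Sequence[str]) -> np.ndarray:
        pos = {p: i for i, p in enumerate(self.dataset.participant_ids)}
        return np.array([pos[i] for i in ids])

    @property
    def train_indices(self) -> np.ndarray:
        return self._indices(self.split.meta_train_ids)

    @property
    def test_indices(self) -> np.ndarray:
        return self._indices(self.split.meta_test_ids)

    def phenotype_table(self, which: str) -> PhenotypeTable:
        if which == "meta_train":
            return self.dataset.phenotypes.subset(self.split.meta_train_ids,
                                                  self.split.meta_train_phenotypes)
        if which == "meta_test":
            return self.dataset.phenotypes.subset(self.split.meta_test_ids,
                                                  self.split.meta_test_phenotypes)
        raise ValueError(f"unknown set {which!r}")


def make_meta_benchmark(config: SyntheticConfig, n_train_phenos: int,
                        n_test_phenos: int,
                        max_corr_targets: float | Sequence[float],
                        n_meta_test: int | None = None,
                        train_noise_var: float = 0.1,
                        test_noise_floor: float = 0.0,
                        seed: int | None = None) -> MetaBenchmark:
    """Cohort with analytic control of meta-test↔meta-training phenotype overlap.

    Meta-training phenotype q loads a·z_q with a = √(1 − train_noise_var) on
    its own latent factor, so distinct meta-training phenotypes are mutually
    uncorrelated. Meta-test phenotype t is assigned a nearest meta-training
    phenotype q_t (cyclically) and loads c·z_{q_t} with c = ρ_t/a, giving
    corr(y_t, y_{q_t}) = ρ_t exactly and zero correlation with all other
    meta-training phenotypes; its noise variance is 1 − c². A ρ_t requiring
    c² > 1 − test_noise_floor is unreachable and raises.
    """
    rho = np.broadcast_to(np.atleast_1d(np.asarray(max_corr_targets, dtype=float)),
                          (n_test_phenos,)).astype(float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("correlation targets must be in [0, 1]")
    a = float(np.sqrt(1.0 - train_noise_var))
    if a == 0:
        raise ValueError("train_noise_var = 1 leaves no signal")
    c = rho / a
    if np.any(c ** 2 > 1.0 - test_noise_floor + 1e-12):
        bad = rho[c ** 2 > 1.0 - test_noise_floor + 1e-12]
        raise ValueError(
            f"correlation targets {bad} unreachable: they require shared-signal "
            f"variance above the noise floor {test_noise_floor}")

    L = n_train_phenos
    W = np.zeros((n_train_phenos + n_test_phenos, L))
    noise_var = np.empty(n_train_phenos + n_test_phenos)
    W[:n_train_phenos] = a * np.eye(n_train_phenos, L)
    noise_var[:n_train_phenos] = train_noise_var
    nearest = []
    train_names = [f"src_{q:02d}" for q in range(n_train_phenos)]
    test_names = [f"tgt_{t:02d}" for t in range(n_test_phenos)]
    for t in range(n_test_phenos):
        q = t % n_train_phenos
        W[n_train_phenos + t, q] = c[t]
        noise_var[n_train_phenos + t] = 1.0 - c[t] ** 2
        nearest.append(train_names[q])

    cfg = replace(config,
                  n_latents=L,
                  loadings=W,
                  phenotype_noise_var=noise_var,
                  phenotype_names=tuple(train_names + test_names),
                  seed=config.seed if seed is None else seed)
    dataset = generate(cfg)

    n_meta_test = n_meta_test if n_meta_test is not None else cfg.n // 3
    if not 0 < n_meta_test < cfg.n:
        raise ValueError(f"n_meta_test={n_meta_test} infeasible for n={cfg.n}")
    rng = np.random.default_rng(cfg.seed + 1)
    perm = rng.permutation(cfg.n)
    test_ids = sorted(dataset.participant_ids[i] for i in perm[:n_meta_test])
    train_ids = sorted(dataset.participant_ids[i] for i in perm[n_meta_test:])
    split = MetaSplit(train_ids, test_ids, train_names, test_names)
    return MetaBenchmark(dataset, split, rho.copy(), nearest)
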