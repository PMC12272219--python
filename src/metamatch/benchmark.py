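"""End-to-end K-shot benchmark driver.

For every (method, K, repeat, phenotype) cell: adapt on the K shot
participants, evaluate on the remaining meta-test participants, and record
Pearson's r, COD and MAE. All methods share identical shot/test splits per
(K, repeat) cell, normalization statistics are computed from the K shots and
carried over to the test participants, and every stochastic step is seeded
from the experiment plan's master seed, so a rerun reproduces the records
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import (ElasticNetConfig, FinetuneConfig, MorphometricElasticNet,
                        TransferLearningRegressor)
from .meta_matching import MetaMatchingFinetune, MetaMatchingStacking
from .metrics import EvalRecord, aggregate, cod, mae, pearson, records_to_frame
from .sfcn import SFCNRegressor
from .splits import ExperimentPlan, child_seed, make_kshot_splits
from .synthetic import MetaBenchmark
from .tables import apply_norm_stats
from .volumes import mean_normalize

__all__ = ["METHODS", "run_benchmark", "report", "pretrain_base_model"]

METHODS = ("elasticnet", "transfer", "mm-finetune", "mm-stack")


def pretrain_base_model(bench: MetaBenchmark, config=None, train_config=None) -> SFCNRegressor:
    """Pretrain the multi-output base model on the meta-training participants
    and phenotypes of a benchmark (volumes mean-normalized per image)."""
    from .sfcn import SFCNConfig

    ds = bench.dataset
    idx = bench.train_indices
    vols = _normalized_volumes(ds.volumes[idx])
    table = bench.phenotype_table("meta_train")
    if config is None:
        config = SFCNConfig(input_shape=ds.config.grid_shape)
    model = SFCNRegressor(config=config, train_config=train_config)
    model.fit(vols, table.values, icv=ds.icv[idx], observed=table.observed)
    return model


def _normalized_volumes(vols: np.ndarray) -> np.ndarray:
    out = np.empty_like(vols, dtype=np.float32)
    for i in range(vols.shape[0]):
        out[i] = mean_normalize(vols[i])
    return out


@dataclass
class _TestPool:
    """Per-benchmark caches shared by all cells: normalized volumes, trunk
    features and base-model predictions for the meta-test participants."""

    ids: list[str]
    morph: np.ndarray
    icv: np.ndarray
    table: object
    trunk: np.ndarray | None
    base_preds: np.ndarray | None

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        pos = {p: i for i, p in enumerate(self.ids)}
        return np.array([pos[i] for i in ids])


def _build_pool(bench: MetaBenchmark, base: SFCNRegressor | None,
                methods: Sequence[str]) -> _TestPool:
    ds = bench.dataset
    idx = bench.test_indices
    ids = list(bench.split.meta_test_ids)
    morph = ds.morphometrics.subset(ids).values
    table = bench.phenotype_table("meta_test")
    trunk = base_preds = None
    if any(m in methods for m in ("transfer", "mm-finetune", "mm-stack")):
        vols = _normalized_volumes(ds.volumes[idx])
        trunk = base.trunk_features(vols)
        icv_z = base._icv_z(ds.icv[idx]) if base.config_.use_icv else None
        base_preds = base.net_.predict(trunk, icv_z,
                                       start_block=base.config_.n_blocks - 1)
    return _TestPool(ids, morph, ds.icv[idx], table, trunk, base_preds)


def run_benchmark(bench: MetaBenchmark, base: SFCNRegressor | None,
                  plan: ExperimentPlan, methods: Sequence[str] = METHODS,
                  elastic_cfg: ElasticNetConfig | None = None,
                  finetune_cfg: FinetuneConfig | None = None,
                  stacking_lambda_grid: tuple[float, ...] | None = None,
                  phenotypes: Sequence[str] | None = None,
                  out_dir: str | Path | None = None,
                  resume: bool = False) -> list[EvalRecord]:
    """All (method, K, repeat, phenotype) cells → EvalRecords.

    ``phenotypes`` restricts evaluation to a subset of the meta-test
    phenotypes (default: all). With ``out_dir`` set, finished cells are
    checkpointed to ``cells.jsonl``
    (finetune-style cells dominate the cost); a partial prior run requires
    ``resume=True`` to continue, and the completed records are read back
    instead of recomputed.
    """
    methods = list(methods)
    unknown = [m for m in methods if m not in METHODS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}; choose from {METHODS}")
    needs_base = [m for m in methods if m != "elasticnet"]
    if needs_base and base is None:
        raise ValueError(f"methods {needs_base} require a pretrained base model")

    ckpt = None
    done: dict[tuple, dict] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt = out_dir / "cells.jsonl"
        if ckpt.exists():
            if not resume:
                raise RuntimeError(
                    f"{ckpt} holds a partial prior run; pass resume=True to continue")
            for line in ckpt.read_text().splitlines():
                d = json.loads(line)
                done[(d["method"], d["K"], d["repeat_index"], d["phenotype"])] = d

    pool = _build_pool(bench, base, methods)
    if phenotypes is None:
        phenotypes = list(pool.table.phenotype_names)
    else:
        unknown = [p for p in phenotypes if p not in pool.table.phenotype_names]
        if unknown:
            raise ValueError(f"not meta-test phenotypes: {unknown}")
    splits = make_kshot_splits(pool.ids, plan)
    records: list[EvalRecord] = []
    for split in splits:
        shot_rows = pool.rows(split.shot_ids)
        test_rows = pool.rows(split.test_ids)
        cell_seed = child_seed(plan.master_seed, split.K, split.repeat_index)
        for phenotype in phenotypes:
            j = pool.table.phenotype_names.index(phenotype)
            obs = pool.table.observed[:, j]
            y = pool.table.values[:, j]
            sh = shot_rows[obs[shot_rows]]
            te = test_rows[obs[test_rows]]
            for method in methods:
                key = (method, split.K, split.repeat_index, phenotype)
                if key in done:
                    d = done[key]
                    records.append(EvalRecord(**{k: d[k] for k in (
                        "method", "K", "repeat_index", "phenotype", "pearson_r",
                        "cod", "mae", "n_test")}))
                    continue
                rec = _run_cell(method, pool, sh, te, y, split.K,
                                split.repeat_index, phenotype, cell_seed,
                                elastic_cfg, finetune_cfg, stacking_lambda_grid,
                                base)
                records.append(rec)
                if ckpt is not None:
                    with ckpt.open("a") as fh:
                        fh.write(json.dumps(vars(rec)) + "\n")
    if out_dir is not None:
        records_to_frame(records).to_csv(Path(out_dir) / "records.csv", index=False)
        from . import __version__

        (Path(out_dir) / "provenance.json").write_text(json.dumps({
            "package_version": __version__,
            "master_seed": plan.master_seed,
            "K_values": list(plan.K_values),
            "repeats": plan.repeats,
            "methods": methods,
            "phenotypes": list(phenotypes),
        }, indent=2))
    return records


def _run_cell(method, pool, sh, te, y, K, repeat, phenotype, seed,
              elastic_cfg, finetune_cfg, stacking_lambda_grid, base) -> EvalRecord:
    if method == "elasticnet":
        cfg = elastic_cfg if elastic_cfg is not None else ElasticNetConfig()
        cfg = ElasticNetConfig(cfg.alphas, cfg.l1_ratios, cfg.cv_folds, seed)
        model = MorphometricElasticNet(cfg).fit(pool.morph[sh], y[sh])
        preds = model.predict(pool.morph[te])
        tn = model.target_norm_
    elif method == "mm-stack":
        grid = stacking_lambda_grid
        model = MetaMatchingStacking(seed=seed) if grid is None else \
            MetaMatchingStacking(lambda_grid=grid, seed=seed)
        model.fit(pool.base_preds[sh], y[sh])
        preds = model.predict(pool.base_preds[te])
        tn = model.target_norm_
    else:
        cfg = finetune_cfg if finetune_cfg is not None else FinetuneConfig()
        cfg = FinetuneConfig(cfg.lr_grid, cfg.cv_folds, cfg.max_epochs,
                             cfg.patience, cfg.batch_size, seed)
        cls = TransferLearningRegressor if method == "transfer" else MetaMatchingFinetune
        model = cls(base, cfg).fit(pool.trunk[sh], y[sh], pool.icv[sh])
        preds = model.predict(pool.trunk[te], pool.icv[te])
        tn = model.target_norm_
    # evaluate in the z-space defined by the K-shot stats (carry-over protocol)
    yz_test = apply_norm_stats(y[te][:, None], tn).ravel()
    # a fully-shrunk model can emit constant predictions; score r as 0 then
    r = 0.0 if np.ptp(preds) == 0 else pearson(yz_test, preds)
    return EvalRecord(method, K, repeat, phenotype,
                      r, cod(yz_test, preds),
                      mae(yz_test, preds), n_test=len(te))


def report(records: Sequence[EvalRecord], out_dir: str | Path | None = None
           ) -> pd.DataFrame:
    """Summary over repeats (mean, std, quartiles of the phenotype-averaged
    metric) per method/K/metric; optional CSV + unstyled boxplot export."""
    if not records:
        raise ValueError("no records to report")
    rows = []
    for metric in ("pearson_r", "cod", "mae"):
        agg = aggregate(records, metric)
        for (method, K), grp in agg.groupby(["method", "K"]):
            v = grp["value"].to_numpy()
            rows.append({"method": method, "K": K, "metric": metric,
                         "mean": v.mean(), "std": v.std(ddof=1) if v.size > 1 else 0.0,
                         "q25": np.percentile(v, 25), "median": np.median(v),
                         "q75": np.percentile(v, 75), "n_repeats": v.size})
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.6f")
        _boxplot(records, out_dir / "summary_boxplot.png")
    return summary


def _boxplot(records, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = aggregate(records, "pearson_r")
    fig, ax = plt.subplots(figsize=(7, 4))
    labels, data = [], []
    for (method, K), grp in agg.groupby(["method", "K"]):
        labels.append(f"{method}\nK={K}")
        data.append(grp["value"].to_numpy())
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("Pearson r (mean over phenotypes)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
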