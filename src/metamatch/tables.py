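"""Tabular data containers: phenotype and morphometric tables, z-normalization stats.

Phenotype tables are participants × phenotypes with an explicit observed mask
(real behavioural batteries are incomplete); morphometric tables are fully
observed feature matrices of region-wise thickness/volume measures plus
intracranial volume (ICV).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "MorphometricTable",
    "NormStats",
    "read_table",
    "write_table",
    "fit_norm_stats",
    "apply_norm_stats",
    "assemble_morphometric_features",
]


def _check_unique(names: Sequence[str], what: str) -> list[str]:
    names = [str(n) for n in names]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate {what}: {dupes}")
    return names


@dataclass
class PhenotypeTable:
    """Participants × phenotypes matrix with a boolean observed mask.

    Unobserved cells hold NaN in ``values`` and False in ``observed``. Every
    phenotype column must retain at least 2 observed entries so that
    normalization stats stay defined.
    """

    participant_ids: list[str]
    phenotype_names: list[str]
    values: np.ndarray
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.participant_ids = _check_unique(self.participant_ids, "participant ids")
        self.phenotype_names = _check_unique(self.phenotype_names, "phenotype names")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participant_ids), len(self.phenotype_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.participant_ids)} participants × {len(self.phenotype_names)} phenotypes"
            )
        if self.observed is None:
            self.observed = np.isfinite(self.values)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != self.values.shape:
            raise ValueError("observed mask shape mismatch")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise ValueError("observed entries must be finite")
        counts = self.observed.sum(axis=0)
        if len(self.participant_ids) and np.any(counts < 2):
            bad = [n for n, c in zip(self.phenotype_names, counts) if c < 2]
            raise ValueError(f"phenotypes with fewer than 2 observed values: {bad}")

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_names)

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.copy()
        vals[~self.observed] = np.nan
        return pd.DataFrame(vals, index=self.participant_ids, columns=self.phenotype_names)

    def subset(self, participant_ids: Sequence[str] | None = None,
               phenotype_names: Sequence[str] | None = None) -> "PhenotypeTable":
        """Row/column subset preserving order of the requested ids/names."""
        pid = list(participant_ids) if participant_ids is not None else self.participant_ids
        phe = list(phenotype_names) if phenotype_names is not None else self.phenotype_names
        row_index = {p: i for i, p in enumerate(self.participant_ids)}
        col_index = {p: i for i, p in enumerate(self.phenotype_names)}
        try:
            rows = [row_index[p] for p in pid]
        except KeyError as e:
            raise KeyError(f"unknown participant id {e.args[0]!r}") from None
        try:
            cols = [col_index[p] for p in phe]
        except KeyError as e:
            raise KeyError(f"unknown phenotype {e.args[0]!r}") from None
        return PhenotypeTable(pid, phe, self.values[np.ix_(rows, cols)],
                              self.observed[np.ix_(rows, cols)])


@dataclass
class MorphometricTable:
    """Participants × morphometric features, fully observed.

    Canonical feature order is [ICV, cortical thickness (region order),
    cortical volume (region order), subcortical volume (region order)], so the
    feature count is 1 + 2·C + S for C cortical and S subcortical regions.
    """

    participant_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.participant_ids = _check_unique(self.participant_ids, "participant ids")
        self.feature_names = _check_unique(self.feature_names, "feature names")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participant_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids × features")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("morphometric tables must be fully observed and finite")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.participant_ids, columns=self.feature_names)

    def subset(self, participant_ids: Sequence[str]) -> "MorphometricTable":
        row_index = {p: i for i, p in enumerate(self.participant_ids)}
        rows = [row_index[p] for p in participant_ids]
        return MorphometricTable(list(participant_ids), self.feature_names, self.values[rows])


def read_table(path: str | Path, kind: str) -> PhenotypeTable | MorphometricTable:
    """Read a CSV/TSV table (header row, first column = participant id).

    ``kind`` is ``"phenotype"`` (empty/NA cells become mask=False) or
    ``"morphometric"`` (missing cells are an error). The delimiter is inferred
    from the suffix: ``.tsv`` → tab, otherwise comma.
    """
    path = Path(path)
    if kind not in ("phenotype", "morphometric"):
        raise ValueError(f"unknown table kind {kind!r}")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate participant ids in {path}: {dupes}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                raise ValueError(
                    f"non-numeric cell in column {col!r} of {path} "
                    f"(first at participant {df.index[bad.argmax()]!r})"
                )
            df[col] = coerced
    values = df.to_numpy(dtype=float)
    ids = list(df.index)
    names = list(df.columns)
    if kind == "phenotype":
        return PhenotypeTable(ids, names, values, np.isfinite(values))
    if not np.all(np.isfinite(values)):
        raise ValueError(f"missing cells in morphometric table {path}")
    return MorphometricTable(ids, names, values)


def write_table(table: PhenotypeTable | MorphometricTable, path: str | Path) -> None:
    """Write a table as CSV/TSV (suffix-selected); unobserved cells are empty."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.to_frame().to_csv(path, sep=sep, index_label="participant_id")


@dataclass
class NormStats:
    """Per-variable mean/std computed on a reference sample, for carry-over z-scoring.

    In the K-shot protocol the stats come from the K shot participants and are
    then applied unchanged to the held-out test participants. Degenerate
    variables (std == 0 on the reference sample) z-score to 0.
    """

    names: list[str]
    mean: np.ndarray
    std: np.ndarray
    n_source: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if not (len(self.names) == self.mean.size == self.std.size):
            raise ValueError("names/mean/std lengths differ")
        if np.any(self.std < 0):
            raise ValueError("std must be nonnegative")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "names": self.names,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "n_source": self.n_source,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormStats":
        d = json.loads(Path(path).read_text())
        return cls(d["names"], np.array(d["mean"]), np.array(d["std"]), d["n_source"])


def fit_norm_stats(values: np.ndarray, names: Sequence[str] | None = None,
                   observed: np.ndarray | None = None) -> NormStats:
    """Per-variable mean and sample std (ddof=1) over observed entries.

    Raises if any variable has fewer than 2 observed values, naming it.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    if names is None:
        names = [f"var{j}" for j in range(p)]
    names = list(names)
    if observed is None:
        observed = np.isfinite(values)
    observed = np.asarray(observed, dtype=bool)
    counts = observed.sum(axis=0)
    if np.any(counts < 2):
        bad = [names[j] for j in np.nonzero(counts < 2)[0]]
        raise ValueError(f"cannot compute normalization stats with <2 observed values: {bad}")
    mean = np.empty(p)
    std = np.empty(p)
    for j in range(p):
        col = values[observed[:, j], j]
        mean[j] = col.mean()
        std[j] = col.std(ddof=1)
    return NormStats(names, mean, std, n_source=int(n))


def apply_norm_stats(values: np.ndarray, stats: NormStats,
                     names: Sequence[str] | None = None) -> np.ndarray:
    """(x − mean)/std per variable; variables with std 0 map to 0 everywhere."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != len(stats.names):
        raise ValueError(
            f"value matrix has {values.shape[1]} variables, stats have {len(stats.names)}")
    if names is not None and list(names) != list(stats.names):
        raise ValueError("variable names do not match normalization stats")
    out = values - stats.mean
    safe = np.where(stats.std > 0, stats.std, 1.0)
    out = out / safe
    out[:, stats.std == 0] = 0.0
    return out


def assemble_morphometric_features(
    participant_id: str,
    icv: float,
    cortical_thickness: dict[str, float],
    cortical_volume: dict[str, float],
    subcortical_volume: dict[str, float],
    cortical_regions: Sequence[str] | None = None,
    subcortical_regions: Sequence[str] | None = None,
) -> MorphometricTable:
    """Assemble one participant's feature row in canonical order.

    The order is [ICV, thickness per cortical region, volume per cortical
    region, volume per subcortical region], giving F = 1 + 2·C + S features
    (e.g. C=62, S=39 → 164; C=62, S=41 → 166). Every cortical region must
    supply both a thickness and a volume.
    """
    cortical_regions = list(cortical_regions) if cortical_regions is not None \
        else sorted(set(cortical_thickness) | set(cortical_volume))
    subcortical_regions = list(subcortical_regions) if subcortical_regions is not None \
        else sorted(subcortical_volume)
    for r in cortical_regions:
        if r not in cortical_thickness:
            raise ValueError(f"missing thickness for cortical region {r!r}")
        if r not in cortical_volume:
            raise ValueError(f"missing volume for cortical region {r!r}")
    for r in subcortical_regions:
        if r not in subcortical_volume:
            raise ValueError(f"missing volume for subcortical region {r!r}")
    names = (["ICV"]
             + [f"thickness_{r}" for r in cortical_regions]
             + [f"volume_{r}" for r in cortical_regions]
             + [f"subcortical_volume_{r}" for r in subcortical_regions])
    row = np.array([icv]
                   + [cortical_thickness[r] for r in cortical_regions]
                   + [cortical_volume[r] for r in cortical_regions]
                   + [subcortical_volume[r] for r in subcortical_regions], dtype=float)
    return MorphometricTable([participant_id], names, row[None, :])
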