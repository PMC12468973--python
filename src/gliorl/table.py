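"""Sample tables: the universal currency of the pipeline.

A :class:`SampleTable` holds one row per sample (an original patient scan or
an augmented copy of one) with a shared ordered feature namespace, plus the
reserved metadata columns ``sample_id``, ``group_id`` (origin patient, shared
by augmented copies — the unit of leakage control), ``modality``, ``label``,
``survival_days`` and ``age``.  Everything downstream — feature selection,
the reinforcement-learning environment, evaluation — consumes these tables.

This module also owns the sample-level plumbing: delimited-text IO,
survival-day binning into short/medium/long classes, group-atomic stratified
splitting, z-score normalization and multi-modality feature fusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold

__all__ = [
    "RESERVED_COLUMNS",
    "SampleTable",
    "SurvivalClassSpec",
    "bin_survival_days",
    "read_feature_table",
    "write_feature_table",
    "grouped_stratified_split",
    "kfold_splits",
    "zscore_normalize",
    "fuse_modalities",
    "SchemaError",
    "ParseError",
]

#: Columns that are metadata, never features.
RESERVED_COLUMNS = ("sample_id", "group_id", "modality", "label", "survival_days", "age")

MODALITIES = ("FLAIR", "T1", "T2", "T1CE")


class SchemaError(ValueError):
    """Mandatory column missing, duplicated, or otherwise malformed."""


class ParseError(ValueError):
    """A feature cell could not be parsed as a number."""


@dataclass(frozen=True)
class SurvivalClassSpec:
    """Day boundaries of the short/medium/long overall-survival classes.

    ``edges = (a, b, c)`` defines class 0 as days in [0, a], class 1 as
    (a, b] and class 2 as (b, c]; upper bounds are inclusive.  The default
    (250, 500, 1800) matches the conventional short (0–250 d), medium
    (251–500 d) and long (501–1800 d) post-imaging survival bins.
    """

    edges: tuple[int, int, int] = (250, 500, 1800)

    def __post_init__(self) -> None:
        a, b, c = self.edges
        if not (0 < a < b < c):
            raise ValueError(f"edges must be strictly increasing and positive: {self.edges}")


def bin_survival_days(days: int, spec: SurvivalClassSpec | None = None) -> int:
    """Map a survival duration in days to its class index (0/1/2).

    Upper bounds are inclusive: with default edges, 250 -> 0, 251 -> 1,
    500 -> 1, 501 -> 2, 1800 -> 2.  Days above the last edge are a range
    error; negative days are invalid.
    """
    spec = spec or SurvivalClassSpec()
    if days < 0:
        raise ValueError(f"survival days must be nonnegative, got {days}")
    for idx, edge in enumerate(spec.edges):
        if days <= edge:
            return idx
    raise ValueError(f"survival days {days} above last class edge {spec.edges[-1]}")


class SampleTable:
    """Samples × named features with patient/group ids, modality and labels.

    Thin wrapper over a :class:`pandas.DataFrame` whose columns are the
    reserved metadata columns followed by the feature namespace, in order.
    """

    def __init__(self, df: pd.DataFrame):
        self._validate(df)
        self._df = df.reset_index(drop=True)

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        for col in ("sample_id", "group_id", "modality"):
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        if df.columns.duplicated().any():
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise SchemaError(f"duplicated column names: {dupes}")
        feats = [c for c in df.columns if c not in RESERVED_COLUMNS]
        for col in feats:
            if not np.issubdtype(df[col].dtype, np.number):
                # locate the first offending cell for a precise error
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                row = int(bad.idxmax()) if bad.any() else 0
                raise ParseError(
                    f"non-numeric feature value in column {col!r}, row {row}: "
                    f"{df[col].iloc[row]!r}"
                )
        if "label" in df.columns and df["label"].notna().any():
            labels = df["label"].dropna().unique()
            if not set(int(v) for v in labels) <= {0, 1, 2}:
                raise SchemaError(f"labels must be in {{0,1,2}}, got {sorted(labels)}")

    # -- accessors ---------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def n_samples(self) -> int:
        return len(self._df)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self._df.columns if c not in RESERVED_COLUMNS]

    @property
    def features(self) -> np.ndarray:
        """(n_samples, n_features) float matrix in namespace order."""
        return self._df[self.feature_names].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        if "label" not in self._df.columns or self._df["label"].isna().all():
            raise ValueError("table has no labels")
        return self._df["label"].to_numpy(dtype=int)

    @property
    def has_labels(self) -> bool:
        return "label" in self._df.columns and self._df["label"].notna().all()

    @property
    def group_ids(self) -> np.ndarray:
        return self._df["group_id"].to_numpy(dtype=str)

    @property
    def sample_ids(self) -> np.ndarray:
        return self._df["sample_id"].to_numpy(dtype=str)

    @property
    def modality(self) -> str:
        mods = self._df["modality"].unique()
        return mods[0] if len(mods) == 1 else "+".join(sorted(mods))

    def subset_rows(self, index: Sequence[int] | np.ndarray) -> "SampleTable":
        return SampleTable(self._df.iloc[list(index)].reset_index(drop=True))

    def with_features(self, matrix: np.ndarray, names: list[str] | None = None) -> "SampleTable":
        """Return a copy with the feature block replaced (metadata kept)."""
        names = names if names is not None else self.feature_names
        meta = self._df[[c for c in RESERVED_COLUMNS if c in self._df.columns]]
        block = pd.DataFrame(np.asarray(matrix, dtype=float), columns=names)
        return SampleTable(pd.concat([meta.reset_index(drop=True), block], axis=1))

    def select_features(self, names: Sequence[str]) -> "SampleTable":
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise KeyError(f"features not in namespace: {missing}")
        meta = self._df[[c for c in RESERVED_COLUMNS if c in self._df.columns]]
        return SampleTable(pd.concat([meta, self._df[list(names)]], axis=1))

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        return (
            f"SampleTable(n={len(self)}, features={len(self.feature_names)}, "
            f"modality={self.modality!r})"
        )

    @classmethod
    def from_arrays(
        cls,
        features: np.ndarray,
        feature_names: Sequence[str],
        *,
        labels: Sequence[int] | None = None,
        sample_ids: Sequence[str] | None = None,
        group_ids: Sequence[str] | None = None,
        modality: str = "FLAIR",
        survival_days: Sequence[int] | None = None,
        age: Sequence[float] | None = None,
    ) -> "SampleTable":
        features = np.asarray(features, dtype=float)
        n = features.shape[0]
        sample_ids = list(sample_ids) if sample_ids is not None else [f"s{i:04d}" for i in range(n)]
        group_ids = list(group_ids) if group_ids is not None else list(sample_ids)
        data: dict = {
            "sample_id": sample_ids,
            "group_id": group_ids,
            "modality": [modality] * n,
        }
        if labels is not None:
            data["label"] = np.asarray(labels, dtype=int)
        if survival_days is not None:
            data["survival_days"] = np.asarray(survival_days, dtype=int)
        if age is not None:
            data["age"] = np.asarray(age, dtype=float)
        df = pd.DataFrame(data)
        block = pd.DataFrame(features, columns=list(feature_names))
        return cls(pd.concat([df, block], axis=1))


# -- IO --------------------------------------------------------------------


def read_feature_table(path: str | Path, schema: dict[str, str] | None = None) -> SampleTable:
    """Read a delimited feature table (CSV, or TSV by ``.tsv`` suffix).

    ``schema`` optionally maps file column names onto the reserved names,
    e.g. ``{"patient": "group_id"}``.  All non-reserved columns are features
    and must be numeric.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if schema:
        df = df.rename(columns=schema)
    return SampleTable(df)


def write_feature_table(table: SampleTable, path: str | Path) -> None:
    """Write a table as delimited text; round-trips losslessly via repr."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # 17 significant digits round-trip any float64 exactly
    table.df.to_csv(path, sep=sep, index=False, float_format=lambda v: format(v, ".17g"))


# -- splitting -------------------------------------------------------------


def _per_class_train_targets(counts: dict[int, int], fraction: float) -> dict[int, int]:
    """Largest-remainder apportionment of round(fraction*n) across classes."""
    n = sum(counts.values())
    total_train = int(np.floor(fraction * n + 0.5))
    raw = {c: fraction * k for c, k in counts.items()}
    base = {c: int(np.floor(v)) for c, v in raw.items()}
    short = total_train - sum(base.values())
    # distribute the remainder to the largest fractional parts (ties: class order)
    order = sorted(counts, key=lambda c: (-(raw[c] - base[c]), c))
    for c in order[:short]:
        base[c] += 1
    return base


def grouped_stratified_split(
    table: SampleTable, train_fraction: float, seed: int
) -> tuple[SampleTable, SampleTable]:
    """Split into train/test with no group on both sides, stratified by label.

    Train size is ``round(fraction * n)`` apportioned per class by largest
    remainder, subject to group atomicity (a patient's augmented copies all
    land on one side).  Deterministic under ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train fraction must be in (0, 1)")
    labels = table.labels
    groups = table.group_ids
    rng = np.random.default_rng(seed)

    counts = {int(c): int(k) for c, k in zip(*np.unique(labels, return_counts=True))}
    targets = _per_class_train_targets(counts, train_fraction)

    # group -> (majority label, row indices); groups are label-homogeneous in
    # practice (augmented copies keep their origin's label)
    group_rows: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        group_rows.setdefault(g, []).append(i)
    for g, rows in group_rows.items():
        if len(rows) > train_fraction * len(table):
            warnings.warn(
                f"group {g!r} alone exceeds the train fraction; stratification degraded",
                stacklevel=2,
            )

    group_names = sorted(group_rows)
    rng.shuffle(group_names)
    need = dict(targets)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for g in group_names:
        rows = group_rows[g]
        lab = int(np.bincount(labels[rows]).argmax())
        if need.get(lab, 0) >= len(rows):
            train_idx.extend(rows)
            need[lab] -= len(rows)
        else:
            test_idx.extend(rows)
    train_idx.sort()
    test_idx.sort()
    return table.subset_rows(train_idx), table.subset_rows(test_idx)


def kfold_splits(
    table: SampleTable, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group-atomic stratified k-fold split of row indices.

    Every sample appears in exactly one validation fold and no group id is
    split across the train/validation sides of any fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    groups = table.group_ids
    if k > len(set(groups)):
        raise ValueError(f"k={k} exceeds the number of groups ({len(set(groups))})")
    cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (np.asarray(tr), np.asarray(va))
        for tr, va in cv.split(table.features, table.labels, groups)
    ]


# -- normalization & fusion ------------------------------------------------


def zscore_normalize(
    table: SampleTable, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[SampleTable, tuple[np.ndarray, np.ndarray]]:
    """Per-feature standardization; fit on the table or apply given stats.

    In fit mode (``stats is None``) means and population standard deviations
    are computed from the table; zero-variance features map to all zeros.
    In transform mode the supplied ``(mean, sd)`` are applied unchanged —
    the mode used for held-out data with training-set statistics.
    """
    x = table.features
    if stats is None:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
    else:
        mean, sd = stats
        if mean.shape[0] != x.shape[1] or sd.shape[0] != x.shape[1]:
            raise ValueError(
                f"stats dimension {mean.shape[0]} does not match namespace {x.shape[1]}"
            )
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[:, sd == 0] = 0.0
    return table.with_features(z), (mean, sd)


def fuse_modalities(tables: Sequence[SampleTable], masks: Sequence) -> SampleTable:
    """Concatenate per-modality selected features into one fused table.

    Tables must be aligned on ``sample_id``.  Each selected feature is
    prefixed ``<modality>.<feature>`` so provenance survives fusion.  Labels
    and other metadata are taken from the first table.
    """
    if len(tables) != len(masks):
        raise ValueError("one mask per table required")
    if not tables:
        raise ValueError("no tables to fuse")
    base_ids = list(tables[0].sample_ids)
    blocks = []
    names: list[str] = []
    for t, m in zip(tables, masks):
        if list(t.sample_ids) != base_ids:
            raise ValueError("sample-id mismatch between modality tables")
        selected = m.selected_names() if hasattr(m, "selected_names") else list(m)
        sub = t.df[selected].to_numpy(dtype=float) if selected else np.empty((len(t), 0))
        blocks.append(sub)
        names.extend(f"{t.modality}.{f}" for f in selected)
    fused = np.hstack(blocks) if blocks else np.empty((len(tables[0]), 0))
    meta = tables[0].df[[c for c in RESERVED_COLUMNS if c in tables[0].df.columns]].copy()
    meta["modality"] = "+".join(t.modality for t in tables)
    block = pd.DataFrame(fused, columns=names)
    return SampleTable(pd.concat([meta.reset_index(drop=True), block], axis=1))
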