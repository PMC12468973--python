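"""Radiomics-like synthetic feature tables with planted class signal.

The generator emulates the *structure* of a multimodal glioma radiomics
study — per-modality feature tables, a minority class inflated by
label-preserving augmentation, and survival-day labels falling into
short/medium/long bands — without attempting to match the marginal
distributions of real texture features.  Informative features receive a
class-dependent standardized mean shift (the effect size); the rest are
pure noise.  Every table is deterministic under its seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import SampleTable, SurvivalClassSpec, bin_survival_days

__all__ = ["SynthSpec", "generate_classification_table", "generate_survival_table", "augment_table"]

#: Survival-day bands of the default short/medium/long classes.
DEFAULT_DAY_RANGES = ((0, 250), (251, 500), (501, 1800))


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic feature table.

    class_counts
        Samples per class before augmentation.  Defaults emulate a glioma
        grading cohort of 76 low-grade vs 293 high-grade cases.
    n_features
        Total features per modality (default 105, the size of a standard
        whole-tumour radiomics extraction).
    n_informative
        Number of features carrying class signal.
    effect_size
        Standardized mean separation of informative features between
        adjacent classes (Cohen's d per step).
    noise_sd
        Standard deviation of the feature noise.
    day_ranges
        Per-class survival-day bands for survival tables.
    """

    class_counts: tuple[int, ...] = (76, 293)
    n_features: int = 105
    n_informative: int = 10
    effect_size: float = 1.5
    noise_sd: float = 1.0
    day_ranges: tuple[tuple[int, int], ...] = DEFAULT_DAY_RANGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("informative feature count exceeds total features")
        if any(c <= 0 for c in self.class_counts):
            raise ValueError("class counts must be positive")
        for lo, hi in self.day_ranges:
            if not (0 <= lo <= hi <= 1800):
                raise ValueError(f"day range ({lo}, {hi}) outside (0, 1800]")


def _feature_names(n: int) -> list[str]:
    return [f"f{j:03d}" for j in range(n)]


def generate_classification_table(
    spec: SynthSpec, modality: str = "FLAIR"
) -> tuple[SampleTable, np.ndarray]:
    """Binary (or multiclass) table with planted informative features.

    Informative feature j of a class-c sample is drawn
    N(c * effect_size * noise_sd, noise_sd²); the remaining features are
    N(0, noise_sd²) regardless of class.  Returns the table and the sorted
    index set of the informative features (the recovery ground truth).

    Each modality gets an independent stream derived from (seed, modality)
    so multi-modality studies share labels but not noise.
    """
    rng = np.random.default_rng([spec.seed, zlib.crc32(modality.encode()) % 2**31])
    n = sum(spec.class_counts)
    labels = np.repeat(np.arange(len(spec.class_counts)), spec.class_counts)
    informative = rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    informative = np.sort(informative)
    x = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    # class-ordered mean shift so 3-class survival signal is monotone
    shift = labels[:, None] * spec.effect_size * spec.noise_sd
    x[:, informative] += shift
    table = SampleTable.from_arrays(
        x,
        _feature_names(spec.n_features),
        labels=labels,
        sample_ids=[f"s{i:04d}" for i in range(n)],  # patient-keyed: aligned across modalities
        group_ids=[f"p{i:04d}" for i in range(n)],
        modality=modality,
    )
    return table, informative


def generate_survival_table(spec: SynthSpec, modality: str = "FLAIR") -> SampleTable:
    """Three-class survival table with uniform days inside each class band.

    Labels are assigned by binning the drawn day values, so they match
    :func:`bin_survival_days` by construction.  An age column is drawn from
    Normal(60, 12) years truncated to [18, 90], a realistic glioma cohort
    profile.
    """
    if len(spec.class_counts) != len(spec.day_ranges):
        raise ValueError("one day range per class required")
    base, informative = generate_classification_table(spec, modality)
    rng = np.random.default_rng([spec.seed + 1, zlib.crc32(modality.encode()) % 2**31])
    days = np.concatenate(
        [
            rng.integers(lo, hi + 1, size=c)
            for (lo, hi), c in zip(spec.day_ranges, spec.class_counts)
        ]
    )
    bin_spec = SurvivalClassSpec(tuple(hi for _, hi in spec.day_ranges))
    labels = np.array([bin_survival_days(int(d), bin_spec) for d in days])
    age = np.clip(rng.normal(60.0, 12.0, size=len(days)), 18.0, 90.0)
    df = base.df.copy()
    df["label"] = labels
    df["survival_days"] = days.astype(int)
    df["age"] = age
    return SampleTable(df)


def augment_table(
    table: SampleTable, copies_per_sample: int, jitter_sd: float | None = None, seed: int = 0
) -> SampleTable:
    """Label-preserving feature-space augmentation.

    Appends ``copies_per_sample`` jittered copies of every row; copies keep
    their origin's group id and label so that grouped splitting keeps a
    patient's augmented versions on one side.  Gaussian feature jitter
    (default sd = 0.1 × per-feature sd) stands in for the image-space
    flips/rotations/noise of a real augmentation pipeline — downstream only
    the row counts and the leakage structure matter.
    """
    if copies_per_sample < 0:
        raise ValueError("copies per sample must be >= 0")
    if copies_per_sample == 0:
        return table
    rng = np.random.default_rng(seed)
    x = table.features
    sd = x.std(axis=0)
    jitter = jitter_sd if jitter_sd is not None else 0.1 * sd
    frames = [table.df]
    for k in range(copies_per_sample):
        df = table.df.copy()
        df["sample_id"] = [f"{s}-aug{k + 1}" for s in table.sample_ids]
        noisy = x + rng.normal(0.0, 1.0, size=x.shape) * jitter
        df[table.feature_names] = noisy
        frames.append(df)
    return SampleTable(pd.concat(frames, ignore_index=True))
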