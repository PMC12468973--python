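"""Radiomics feature manifest: named feature categories and the flat namespace.

A manifest declares which radiomics features a table is expected to carry,
grouped into the standard extraction categories (shape, first-order
statistics, and the texture-matrix families GLCM/GLDM/GLRLM/GLSZM/NGTDM).
The packaged default describes a 105-feature extraction typical of a
whole-tumour 3D radiomics pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["FeatureManifest", "default_manifest", "load_manifest"]


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered feature categories with a globally unique feature namespace."""

    categories: tuple[tuple[str, tuple[str, ...]], ...]
    version: str = "1.0"

    def __post_init__(self) -> None:
        names = self.feature_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names across categories: {dupes}")

    def feature_names(self) -> list[str]:
        """Flat feature namespace, category order then declared order."""
        return [name for _, names in self.categories for name in names]

    def category_counts(self) -> dict[str, int]:
        return {cat: len(names) for cat, names in self.categories}

    @property
    def n_features(self) -> int:
        return sum(len(names) for _, names in self.categories)

    def category_of(self, feature: str) -> str:
        for cat, names in self.categories:
            if feature in names:
                return cat
        raise KeyError(feature)


def load_manifest(path: str | Path) -> FeatureManifest:
    """Load a manifest from a YAML file mapping category -> feature names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cats = tuple(
        (str(cat), tuple(str(n) for n in names))
        for cat, names in raw["categories"].items()
    )
    return FeatureManifest(categories=cats, version=str(raw.get("version", "1.0")))


def default_manifest() -> FeatureManifest:
    """The packaged 105-feature default manifest."""
    ref = resources.files("gliorl").joinpath("data/manifest.yaml")
    with resources.as_file(ref) as path:
        return load_manifest(path)
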