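"""Versioned manifest of the 53-feature acoustic set.

The feature composition is data, not code: the packaged JSON manifest fixes
the names, categories and column order used by the extractor, the cohort
generator, the classifier and every exported table. Swapping the manifest
changes the feature set without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

__all__ = ["FeatureManifest", "load_manifest", "METADATA_COLUMNS"]

#: metadata columns preceding the feature block in every cohort table
METADATA_COLUMNS = ("subject_id", "group", "frs_bulb", "sex")


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered feature registry: names, categories, interaction subsets."""

    version: str
    names: tuple[str, ...]
    categories: Mapping[str, str]          # feature name -> category
    units: Mapping[str, str]
    interaction_subsets: Mapping[str, tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.names)

    def names_in_category(self, category: str) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.categories[n] == category)

    @property
    def category_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for n in self.names:
            seen.setdefault(self.categories[n], None)
        return tuple(seen)

    def interaction_features(self) -> tuple[str, ...]:
        """Features receiving sex-interaction terms (F0 + designated HNR)."""
        out: list[str] = []
        for subset in self.interaction_subsets.values():
            out.extend(subset)
        return tuple(out)

    def validate_names(self, names: Sequence[str]) -> None:
        unknown = sorted(set(names) - set(self.names))
        if unknown:
            raise ValueError(
                f"unknown feature name(s) {unknown}; valid names are {list(self.names)}"
            )


def load_manifest(path: str | None = None) -> FeatureManifest:
    """Load the packaged manifest, or an alternative manifest from ``path``."""
    if path is None:
        ref = resources.files("bulbarvoice").joinpath("data/feature_manifest.json")
        raw = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    feats = raw["features"]
    names = tuple(f["name"] for f in feats)
    if len(set(names)) != len(names):
        raise ValueError("manifest contains duplicate feature names")
    return FeatureManifest(
        version=raw["version"],
        names=names,
        categories={f["name"]: f["category"] for f in feats},
        units={f["name"]: f.get("unit", "") for f in feats},
        interaction_subsets={
            k: tuple(v) for k, v in raw.get("interaction_subsets", {}).items()
        },
    )
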