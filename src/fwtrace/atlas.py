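"""White-matter tract registry and synthetic atlas masks.

The registry enumerates 48 white-matter tracts grouped into 7 tract types:
limbic, association and projection pathways plus transcallosal (TC)
projections of prefrontal, motor, parietal and occipital cortex.  Together
with the 5 microstructural metrics (FW, FAt, MDt, AxDt, RDt) this yields
240 tract-specific features per imaging session.

Masks are optional: in tabular mode a tract is just a column-name key; for
the volumetric extraction path :func:`synthetic_atlas` partitions a grid
into per-tract binary masks so the whole map->feature path can be exercised
without any template download.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "METRICS",
    "TRACT_TYPES",
    "Tract",
    "TractAtlas",
    "atlas_registry",
    "synthetic_atlas",
    "feature_name",
    "feature_names",
]

METRICS = ("FW", "FAt", "MDt", "AxDt", "RDt")

TRACT_TYPES = (
    "limbic",
    "association",
    "projection",
    "prefrontal TC",
    "motor TC",
    "parietal TC",
    "occipital TC",
)

# 48 tracts, each in exactly one of the 7 type groups.
_REGISTRY: tuple[tuple[str, str], ...] = (
    # limbic (5)
    ("cingulum", "limbic"),
    ("fornix", "limbic"),
    ("uncinate fasciculus", "limbic"),
    ("parahippocampal cingulum", "limbic"),
    ("posterior cingulum", "limbic"),
    # association (7)
    ("SLF", "association"),
    ("SLF-TP", "association"),
    ("ILF", "association"),
    ("IFOF", "association"),
    ("arcuate fasciculus", "association"),
    ("middle longitudinal fasciculus", "association"),
    ("frontal aslant tract", "association"),
    # projection (7)
    ("corticospinal tract", "projection"),
    ("anterior thalamic radiation", "projection"),
    ("superior thalamic radiation", "projection"),
    ("posterior thalamic radiation", "projection"),
    ("corticostriatal tract", "projection"),
    ("frontopontine tract", "projection"),
    ("optic radiation", "projection"),
    # prefrontal TC (8)
    ("TC superior frontal gyrus", "prefrontal TC"),
    ("TC middle frontal gyrus", "prefrontal TC"),
    ("TC IFG", "prefrontal TC"),
    ("TC medial frontal gyrus", "prefrontal TC"),
    ("TC orbitofrontal cortex", "prefrontal TC"),
    ("TC frontal pole", "prefrontal TC"),
    ("TC anterior cingulate", "prefrontal TC"),
    ("TC dorsolateral prefrontal", "prefrontal TC"),
    # motor TC (7)
    ("TC precentral gyrus", "motor TC"),
    ("TC SMA", "motor TC"),
    ("TC preSMA", "motor TC"),
    ("TC PMd", "motor TC"),
    ("TC PMv", "motor TC"),
    ("TC paracentral lobule", "motor TC"),
    ("TC supplementary eye field", "motor TC"),
    # parietal TC (7)
    ("TC angular gyrus", "parietal TC"),
    ("TC supramarginal gyrus", "parietal TC"),
    ("TC SPL", "parietal TC"),
    ("TC IPL", "parietal TC"),
    ("TC precuneus", "parietal TC"),
    ("TC postcentral gyrus", "parietal TC"),
    ("TC posterior cingulate", "parietal TC"),
    # occipital TC (7)
    ("TC occipital pole", "occipital TC"),
    ("TC lingual gyrus", "occipital TC"),
    ("TC cuneus", "occipital TC"),
    ("TC lateral occipital", "occipital TC"),
    ("TC fusiform gyrus", "occipital TC"),
    ("TC calcarine", "occipital TC"),
    ("TC inferior temporal gyrus", "occipital TC"),
)


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


@dataclass
class Tract:
    """One named tract: display name, type group, slug key and optional mask.

    ``mask`` may be a binary or probabilistic 3-D weight array (volumetric
    mode) or ``None`` (tabular mode, where ``slug`` keys feature columns).
    """

    name: str
    tract_type: str
    slug: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.slug:
            self.slug = _slug(self.name)
        if self.tract_type not in TRACT_TYPES:
            raise ValueError(f"unknown tract type: {self.tract_type!r}")


@dataclass
class TractAtlas:
    tracts: list[Tract] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.tracts]
        if len(set(names)) != len(names):
            raise ValueError("tract names must be unique")

    def __len__(self) -> int:
        return len(self.tracts)

    def __iter__(self):
        return iter(self.tracts)

    def by_type(self, tract_type: str) -> list[Tract]:
        return [t for t in self.tracts if t.tract_type == tract_type]

    @property
    def types(self) -> list[str]:
        seen: list[str] = []
        for t in self.tracts:
            if t.tract_type not in seen:
                seen.append(t.tract_type)
        return seen

    def tract_type_of(self, slug: str) -> str:
        for t in self.tracts:
            if t.slug == slug:
                return t.tract_type
        raise KeyError(slug)


def atlas_registry() -> TractAtlas:
    """The packaged 48-tract registry (7 type groups), tabular mode."""
    return TractAtlas([Tract(name, ttype) for name, ttype in _REGISTRY])


def feature_name(tract: Tract | str, metric: str) -> str:
    slug = tract.slug if isinstance(tract, Tract) else _slug(tract)
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    return f"{slug}_{metric}"


def feature_names(atlas: TractAtlas | None = None,
                  metrics: tuple[str, ...] = METRICS) -> list[str]:
    """All tract x metric feature column names (240 for the full registry)."""
    if atlas is None:
        atlas = atlas_registry()
    return [feature_name(t, m) for t in atlas for m in metrics]


def synthetic_atlas(shape: tuple[int, int, int] = (8, 8, 6),
                    seed: int = 0) -> TractAtlas:
    """Partition a voxel grid into 48 disjoint binary masks, one per tract.

    Stands in for the study's tractography templates so the volumetric
    extraction path is testable; the masks carry no anatomical meaning.
    """
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(shape))
    if n_vox < len(_REGISTRY):
        raise ValueError("grid too small for 48 non-empty masks")
    assignment = np.repeat(np.arange(len(_REGISTRY)),
                           int(np.ceil(n_vox / len(_REGISTRY))))[:n_vox]
    rng.shuffle(assignment)
    assignment = assignment.reshape(shape)
    tracts = []
    for i, (name, ttype) in enumerate(_REGISTRY):
        tracts.append(Tract(name, ttype, mask=(assignment == i).astype(float)))
    return TractAtlas(tracts)
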