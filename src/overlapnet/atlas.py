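"""Social brain atlas: region table loading, validation, and cluster bookkeeping.

The default fixture ships 36 regions in four functional clusters
(visual-sensory, limbic, intermediate, higher-associative). Region order is
fixed alphabetically within cluster and defines the column order of every
volume matrix downstream. Coordinates in the default fixture are literature
approximations; supply your own atlas CSV/JSON to override.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateRegionError, MissingFileError, SchemaError

CLUSTERS = ("visual_sensory", "limbic", "intermediate", "higher_associative")
HEMISPHERES = ("left", "right", "midline")

_COLUMNS = ["name", "hemisphere", "x", "y", "z", "cluster"]


@dataclass(frozen=True)
class AtlasRegion:
    """One named location with a stereotaxic mm coordinate and cluster label."""

    name: str
    hemisphere: str
    mni_xyz: tuple[float, float, float]
    cluster: str

    def __post_init__(self):
        if self.hemisphere not in HEMISPHERES:
            raise SchemaError(f"unknown hemisphere {self.hemisphere!r} for region {self.name!r}")
        if self.cluster not in CLUSTERS:
            raise SchemaError(f"unknown cluster {self.cluster!r} for region {self.name!r}")
        if not np.all(np.isfinite(self.mni_xyz)):
            raise SchemaError(f"non-finite coordinate for region {self.name!r}")


@dataclass(frozen=True)
class SocialBrainAtlas:
    """Ordered collection of atlas regions; order defines matrix columns."""

    regions: tuple[AtlasRegion, ...]
    source: str = "unknown"

    def __post_init__(self):
        names = [r.name for r in self.regions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DuplicateRegionError(f"duplicate region names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def coordinates(self) -> np.ndarray:
        """(R, 3) array of mm coordinates in atlas order."""
        return np.array([r.mni_xyz for r in self.regions], dtype=float)

    @property
    def clusters(self) -> list[str]:
        return [r.cluster for r in self.regions]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": r.name,
                "hemisphere": r.hemisphere,
                "x": r.mni_xyz[0],
                "y": r.mni_xyz[1],
                "z": r.mni_xyz[2],
                "cluster": r.cluster,
            }
            for r in self.regions
        ]
        return pd.DataFrame(rows, columns=_COLUMNS)


def _atlas_from_frame(df: pd.DataFrame, source: str) -> SocialBrainAtlas:
    if list(df.columns) != _COLUMNS:
        raise SchemaError(
            f"expected columns {_COLUMNS}, got {list(df.columns)}",
        )
    bad = df[~df["cluster"].isin(CLUSTERS)]
    if len(bad):
        raise SchemaError(
            f"unknown cluster labels: {sorted(bad['cluster'].unique())}",
            rows=bad.index.tolist(),
        )
    bad = df[~df["hemisphere"].isin(HEMISPHERES)]
    if len(bad):
        raise SchemaError(
            f"unknown hemisphere labels: {sorted(bad['hemisphere'].unique())}",
            rows=bad.index.tolist(),
        )
    try:
        xyz = df[["x", "y", "z"]].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric coordinates: {exc}") from exc
    regions = tuple(
        AtlasRegion(
            name=str(row["name"]),
            hemisphere=str(row["hemisphere"]),
            mni_xyz=tuple(xyz[i]),
            cluster=str(row["cluster"]),
        )
        for i, (_, row) in enumerate(df.iterrows())
    )
    return SocialBrainAtlas(regions=regions, source=source)


def load_atlas(path: str | Path = "default") -> SocialBrainAtlas:
    """Load and validate an atlas from CSV/JSON, or the shipped default.

    CSV schema: header ``name,hemisphere,x,y,z,cluster``; coordinates in mm.
    JSON: a list of objects with the same fields.
    """
    if path == "default":
        ref = resources.files("overlapnet.data") / "social_brain_atlas_default.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
        return _atlas_from_frame(df, source="default")
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"atlas file not found: {path}")
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        df = pd.DataFrame(records, columns=_COLUMNS)
    else:
        df = pd.read_csv(path)
    return _atlas_from_frame(df, source=str(path))


def save_atlas(atlas: SocialBrainAtlas, path: str | Path) -> None:
    """Write the atlas as CSV (or JSON if the path ends in .json)."""
    path = Path(path)
    df = atlas.to_frame()
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        df.to_csv(path, index=False)


def cluster_membership_matrix(atlas: SocialBrainAtlas) -> pd.DataFrame:
    """Binary (4 clusters x R regions) membership matrix; columns sum to 1."""
    mat = np.zeros((len(CLUSTERS), len(atlas)), dtype=int)
    for j, region in enumerate(atlas.regions):
        mat[CLUSTERS.index(region.cluster), j] = 1
    return pd.DataFrame(mat, index=list(CLUSTERS), columns=atlas.region_names)
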