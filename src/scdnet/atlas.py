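"""Cortical ROI atlas used to spatially embed source-space networks.

The default atlas covers 29 Brodmann areas available bilaterally in
standard low-resolution electromagnetic tomography source space, giving
58 regions of interest.  Coordinates are approximate MNI centroids of each
area taken from common literature values: they are a documented
reconstruction (the precise centroid set of any given source-localization
package is not redistributed here) and can be replaced by loading a custom
CSV with the same columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ROIAtlas", "load_default_atlas", "load_atlas"]

_REQUIRED_COLUMNS = ["id", "ba", "label", "hemisphere", "lobe", "x", "y", "z"]


@dataclass(frozen=True)
class ROIAtlas:
    """Table of ROIs: id, Brodmann area, hemisphere, lobe and MNI coordinates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        ids = self.table["id"]
        if ids.duplicated().any():
            raise ValueError("atlas ROI ids must be unique")
        coords = self.table[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("atlas coordinates must be finite")

    @property
    def roi_ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def n_rois(self) -> int:
        return len(self.table)

    def coordinates(self) -> np.ndarray:
        """ROI coordinates in atlas order, shape (n_rois, 3), mm."""
        return self.table[["x", "y", "z"]].to_numpy(float)

    def coordinate_map(self) -> dict[str, np.ndarray]:
        coords = self.coordinates()
        return {rid: coords[i] for i, rid in enumerate(self.roi_ids)}

    def lobe_of(self, roi_id: str) -> str:
        row = self.table.loc[self.table["id"] == roi_id]
        if row.empty:
            raise KeyError(f"unknown ROI id {roi_id!r}")
        return str(row["lobe"].iloc[0])

    def diameter(self) -> float:
        """Largest pairwise Euclidean distance between ROI centroids (mm)."""
        coords = self.coordinates()
        diffs = coords[:, None, :] - coords[None, :, :]
        return float(np.sqrt((diffs**2).sum(-1)).max())


def load_atlas(path: str | Path) -> ROIAtlas:
    """Load an ROI atlas from a CSV with the standard columns."""
    return ROIAtlas(pd.read_csv(path))


def load_default_atlas() -> ROIAtlas:
    """The shipped 58-ROI bilateral Brodmann atlas."""
    ref = resources.files("scdnet.data").joinpath("atlas_58_brodmann.csv")
    with resources.as_file(ref) as path:
        atlas = load_atlas(path)
    if atlas.n_rois != 58:
        raise RuntimeError("shipped atlas is expected to contain 58 ROIs")
    return atlas
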