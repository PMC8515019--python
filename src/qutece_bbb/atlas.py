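"""Label-atlas container and NIfTI round trip.

The atlas maps every brain voxel to exactly one bilateral region label
(0 = background) and additionally carries three reference masks that the
phantom generator lays down alongside the brain: a pure-blood pool, a
pure-tissue reference, and a uniform calibration tube used for z-axis
coil-sensitivity estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["AtlasLabels", "load_atlas", "save_atlas"]

_MASK_CODES = {"blood": 1, "tissue": 2, "tube": 3}


@dataclass
class AtlasLabels:
    """Integer label volume plus region table and reference masks.

    ``table`` has columns ``id``, ``name``, ``hemisphere`` with one row
    per nonzero label; left/right partners share a name stem.
    """

    labels: np.ndarray
    table: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    blood_mask: np.ndarray | None = None
    tissue_mask: np.ndarray | None = None
    tube_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        missing = set(np.unique(self.labels)) - {0} - set(self.table["id"])
        if missing:
            raise ValueError(f"labels {sorted(missing)} absent from region table")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def region_ids(self) -> np.ndarray:
        return np.asarray(sorted(self.table["id"]))

    def region_voxels(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def hemisphere_of(self, region_id: int) -> str:
        row = self.table.loc[self.table["id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return str(row["hemisphere"].iloc[0])


def save_atlas(atlas: AtlasLabels, out_dir: str | Path) -> Path:
    """Write labels + masks as NIfTI and the region table as TSV/JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine),
        out_dir / "atlas_labels.nii.gz",
    )
    masks = np.zeros(atlas.labels.shape, dtype=np.int16)
    for name, code in _MASK_CODES.items():
        mask = getattr(atlas, f"{name}_mask")
        if mask is not None:
            masks[mask] = code
    nib.save(nib.Nifti1Image(masks, atlas.affine), out_dir / "atlas_masks.nii.gz")
    atlas.table.to_csv(out_dir / "atlas_regions.tsv", sep="\t", index=False)
    meta = {"mask_codes": _MASK_CODES}
    (out_dir / "atlas_meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def load_atlas(in_dir: str | Path) -> AtlasLabels:
    in_dir = Path(in_dir)
    img = nib.load(in_dir / "atlas_labels.nii.gz")
    labels = np.asarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(in_dir / "atlas_regions.tsv", sep="\t")
    masks_img = nib.load(in_dir / "atlas_masks.nii.gz")
    masks = np.asarray(masks_img.dataobj).astype(np.int16)
    kwargs = {
        f"{name}_mask": masks == code for name, code in _MASK_CODES.items()
    }
    return AtlasLabels(labels=labels, table=table, affine=img.affine, **kwargs)
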