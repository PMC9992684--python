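"""Region map construction: atlas parcellation and voxel-wise average FC.

Parcellation slices a 3-D volume into per-region voxel vectors using a
label atlas; the FC builder turns a voxel x time BOLD array into each
voxel's mean Fisher-z connectivity to the other voxels. Voxel order is
always the sorted linear (row-major) index order of the label volume, and
indices are 0-based; NIfTI affines are ignored beyond shape checks.

Upstream preprocessing (registration, nuisance regression, bandpass
filtering, tensor fitting) is out of scope: inputs are assumed already
normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import Atlas, Region

__all__ = [
    "RegionMap", "parcellate_volume", "fisher_z", "build_fc_map",
    "load_volume", "load_label_atlas", "write_region_maps", "read_region_maps",
    "R_CLAMP",
]

logger = logging.getLogger(__name__)

# Correlations are clamped to +/-(1 - R_CLAMP) before arctanh so degenerate
# perfect correlations stay finite.
R_CLAMP = 1e-7


@dataclass
class RegionMap:
    """Voxel values of one subject x atlas region x modality.

    ``voxel_order`` holds the linear indices (into the source volume) of the
    values, in sorted order, so maps from different subjects align.
    """

    subject_id: str
    modality: str
    region_id: int
    values: np.ndarray
    voxel_order: np.ndarray


def parcellate_volume(volume: np.ndarray, atlas: Atlas, subject_id: str = "") -> list[RegionMap]:
    """Slice a 3-D volume into one RegionMap per atlas region.

    Voxels outside every region are ignored. Raises on shape mismatch or if
    the atlas has no regions.
    """
    volume = np.asarray(volume)
    if volume.shape != tuple(atlas.shape):
        raise ValueError(
            f"volume shape {volume.shape} does not match atlas shape {tuple(atlas.shape)}")
    if not atlas.regions:
        raise ValueError("atlas defines no regions")
    flat = volume.reshape(-1)
    out = []
    for reg in atlas.regions:
        idx = np.sort(np.asarray(reg.voxel_indices))
        vals = flat[idx]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"region {reg.region_id}: non-finite voxel values")
        out.append(RegionMap(subject_id=subject_id, modality=atlas.modality,
                             region_id=reg.region_id, values=vals, voxel_order=idx))
    return out


def fisher_z(r):
    """Fisher z transformation, arctanh(r), with correlations clamped to
    +/-(1 - 1e-7) first. Odd and strictly increasing on (-1, 1)."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("fisher_z requires finite correlations")
    z = np.arctanh(np.clip(r, -(1.0 - R_CLAMP), 1.0 - R_CLAMP))
    return float(z) if z.ndim == 0 else z


def build_fc_map(timeseries: np.ndarray) -> np.ndarray:
    """Average voxel-wise functional connectivity.

    For each voxel v the output is the mean over all other voxels u of
    fisher_z(pearson(v, u)); self-pairs are excluded. A constant-in-time
    voxel is assigned zero correlation with everything (logged). The caller
    chooses the averaging scope by choosing which voxels are in the array
    (whole analyzed volume or a single region).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("timeseries must be (n_voxels >= 2, n_timepoints)")
    v, t = ts.shape
    if t < 3:
        raise ValueError("need at least 3 time points for correlation")
    centered = ts - ts.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    const = norms == 0
    if const.any():
        logger.warning("build_fc_map: %d constant voxel(s); their correlations set to 0",
                       int(const.sum()))
        norms = np.where(const, 1.0, norms)
    z_rows = centered / norms[:, None]
    # chunk the Gram matrix so whole-volume averaging stays in bounded memory
    chunk = max(1, int(2e7) // max(v, 1))
    out = np.empty(v)
    for start in range(0, v, chunk):
        stop = min(v, start + chunk)
        corr = z_rows[start:stop] @ z_rows.T
        if const.any():
            corr[:, const] = 0.0
            corr[const[start:stop], :] = 0.0
        np.clip(corr, -(1.0 - R_CLAMP), 1.0 - R_CLAMP, out=corr)
        z = np.arctanh(corr)
        idx = np.arange(start, stop)
        z[idx - start, idx] = 0.0  # exclude self-pairs
        out[start:stop] = z.sum(axis=1) / (v - 1)
    return out


# ---------------------------------------------------------------------------
# NIfTI and tabular I/O
# ---------------------------------------------------------------------------

def load_volume(path) -> np.ndarray:
    """Read a NIfTI volume as a float array (3-D map or 4-D time series)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64)


def load_label_atlas(path, modality: str) -> Atlas:
    """Build an Atlas from a NIfTI integer label volume.

    Every distinct positive label becomes a region; voxel order is sorted
    linear index. Raises if no positive labels are present.
    """
    vol = np.asarray(nib.load(str(path)).dataobj)
    labels = np.unique(vol)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError(f"{path}: label volume contains no positive labels")
    flat = vol.reshape(-1)
    regions = [
        Region(region_id=int(lab), name=f"{modality}_{int(lab):03d}",
               voxel_indices=np.flatnonzero(flat == lab))
        for lab in labels
    ]
    return Atlas(modality=modality, regions=regions, shape=tuple(vol.shape))


def write_region_maps(maps: list[RegionMap], path) -> Path:
    """Write region maps as one compressed long-format table
    (subject_id, region_id, voxel_index, value)."""
    path = Path(path)
    frames = [
        pd.DataFrame({
            "subject_id": m.subject_id,
            "region_id": m.region_id,
            "voxel_index": m.voxel_order,
            "value": m.values,
        })
        for m in maps
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    return path


def read_region_maps(path, modality: str) -> list[RegionMap]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sid, rid), grp in df.groupby(["subject_id", "region_id"], sort=True):
        grp = grp.sort_values("voxel_index")
        out.append(RegionMap(subject_id=str(sid), modality=modality, region_id=int(rid),
                             values=grp["value"].to_numpy(),
                             voxel_order=grp["voxel_index"].to_numpy()))
    return out
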