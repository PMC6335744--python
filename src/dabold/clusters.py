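"""Cluster extraction from thresholded bootstrap-ratio maps.

Voxels with |BSR| at or above a Z-like threshold (default 3.29, two-tailed
p = 0.001) are grouped into contiguous clusters (26-neighbor connectivity by
default; positive and negative saliences clustered separately). Clusters
smaller than a minimum extent are dropped. Within a cluster, the global
maximum is the peak; additional local maxima at least ``min_sep_mm`` from
every stronger reported maximum appear as subcluster rows. Clusters from
separate connected components whose peaks fall closer than ``min_sep_mm``
are merged, the weaker peak demoted to a subcluster. Peak coordinates are
reported in mm through the volume affine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import InvalidSpecError

__all__ = ["ClusterTable", "threshold_and_cluster", "bsr_threshold_p"]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterTable:
    """Peak table mirroring the conventional neuroimaging cluster report."""

    table: pd.DataFrame   # columns: cluster_id, x, y, z, bsr, k, subcluster, sign
    threshold: float
    min_size: int
    min_sep_mm: float

    def __len__(self) -> int:
        return len(self.table)

    def to_markdown(self) -> str:
        cols = ["x", "y", "z", "bsr", "k", "subcluster"]
        return self.table[cols].to_markdown(index=False)


def bsr_threshold_p(threshold: float = 3.29) -> float:
    """Two-tailed standard-normal tail probability of a |Z| threshold."""
    from scipy import stats

    return float(2.0 * stats.norm.sf(threshold))


def _local_maxima(vals: np.ndarray, mask: np.ndarray, struct: np.ndarray) -> np.ndarray:
    """Boolean map of voxels that are >= all masked neighbors (strict on ties
    resolved by coordinate order later)."""
    filled = np.where(mask, vals, -np.inf)
    dilated = ndimage.maximum_filter(filled, footprint=struct, mode="constant", cval=-np.inf)
    return mask & (filled >= dilated)


def _extract_sign(
    signed: np.ndarray,
    affine: np.ndarray,
    threshold: float,
    min_size: int,
    min_sep_mm: float,
    struct: np.ndarray,
    sign: int,
) -> list[dict]:
    mag = signed * sign
    mask = mag >= threshold
    labels, n_comp = ndimage.label(mask, structure=struct)
    rows: list[dict] = []
    comps = []
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        size = int(comp_mask.sum())
        if size < min_size:
            continue
        maxima = _local_maxima(mag, comp_mask, struct)
        coords = np.argwhere(maxima)
        strengths = mag[tuple(coords.T)]
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -strengths))
        coords, strengths = coords[order], strengths[order]
        comps.append({"size": size, "coords": coords, "strengths": strengths})

    # merge components whose primary peaks are closer than min_sep_mm
    def mm(ijk):
        return (affine @ np.append(ijk, 1.0))[:3]

    comps.sort(key=lambda c: -c["strengths"][0])
    merged: list[dict] = []
    for c in comps:
        peak_mm = mm(c["coords"][0])
        host = None
        for m in merged:
            if np.linalg.norm(peak_mm - mm(m["coords"][0])) < min_sep_mm:
                host = m
                break
        if host is None:
            merged.append(c)
        else:
            host["size"] += c["size"]
            host["coords"] = np.vstack([host["coords"], c["coords"]])
            host["strengths"] = np.concatenate([host["strengths"], c["strengths"]])

    for cid, c in enumerate(merged):
        order = np.argsort(-c["strengths"])
        coords, strengths = c["coords"][order], c["strengths"][order]
        reported_mm: list[np.ndarray] = []
        for ijk, val in zip(coords, strengths):
            pos = mm(ijk)
            if reported_mm and min(np.linalg.norm(pos - q) for q in reported_mm) < min_sep_mm:
                continue
            rows.append({
                "x": float(pos[0]), "y": float(pos[1]), "z": float(pos[2]),
                "bsr": float(val * sign), "k": c["size"],
                "subcluster": bool(reported_mm), "sign": sign,
                "_peak_mag": float(strengths[0]),
            })
            reported_mm.append(pos)
    return rows


def threshold_and_cluster(
    bsr_map: np.ndarray,
    affine: Optional[np.ndarray] = None,
    threshold: float = 3.29,
    min_size: int = 50,
    min_sep_mm: float = 10.0,
    connectivity: int = 26,
) -> ClusterTable:
    """Extract a peak/cluster table from a 3-D BSR map.

    Positive and negative maps are clustered separately; rows are sorted by
    peak |BSR| with each cluster's subcluster rows following its peak.
    """
    bsr_map = np.asarray(bsr_map, dtype=float)
    if bsr_map.ndim != 3:
        raise InvalidSpecError("bsr_map must be 3-D")
    if not np.isfinite(bsr_map).all():
        raise InvalidSpecError("bsr_map must be finite (mask or clamp infinities first)")
    if connectivity not in _STRUCTS:
        raise InvalidSpecError("connectivity must be one of 6, 18, 26")
    if affine is None:
        affine = np.eye(4)
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise InvalidSpecError("affine must be an invertible 4x4 matrix")
    struct = _STRUCTS[connectivity]

    rows: list[dict] = []
    for sign in (+1, -1):
        rows.extend(_extract_sign(bsr_map, affine, threshold, min_size,
                                  min_sep_mm, struct, sign))

    if rows:
        df = pd.DataFrame(rows)
        df = df.sort_values(["_peak_mag", "subcluster", "bsr"],
                            ascending=[False, True, False], kind="stable")
        df["cluster_id"] = (~df["subcluster"]).cumsum() - 1
        df = df.drop(columns="_peak_mag").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=["x", "y", "z", "bsr", "k", "subcluster", "sign",
                                   "cluster_id"])
    return ClusterTable(table=df, threshold=threshold, min_size=min_size,
                        min_sep_mm=min_sep_mm)
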