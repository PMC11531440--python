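"""Ordered vs unordered network regions.

Cortical bone shows regions where canaliculi run radially aligned in a dense
comb-like arrangement ("ordered") next to bands of sparser, isotropic
whirl-like network left over from woven bone ("unordered").  The separation
itself is a judgment call made on a z-projection of the skeletonized stack;
this module projects the skeleton, ingests 2D region masks, and computes
area fractions and per-region parameter distributions.  Masks are 2D and
extruded along z for subvolume assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import Skeleton
from .metrics import SubvolumeMap

__all__ = [
    "REGION_OUTSIDE",
    "REGION_ORDERED",
    "REGION_UNORDERED",
    "RegionMask2D",
    "project_skeleton_z",
    "region_statistics",
    "orientation_coherence",
    "RegionStatistics",
]

REGION_OUTSIDE = 0
REGION_ORDERED = 1
REGION_UNORDERED = 2

_REGION_NAMES = {REGION_ORDERED: "ordered", REGION_UNORDERED: "unordered"}


@dataclass
class RegionMask2D:
    """2D label image in the stack's xy frame.

    Labels: 0 outside the ROI, 1 ordered, 2 unordered.  ``provenance``
    records whether the mask was drawn manually or taken from phantom truth.
    """

    labels: np.ndarray  # (nx, ny) integer
    pixel_spacing_um: tuple[float, float]
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("region mask must be 2D")
        bad = set(np.unique(self.labels)) - {
            REGION_OUTSIDE,
            REGION_ORDERED,
            REGION_UNORDERED,
        }
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}")


def project_skeleton_z(skel: Skeleton, mode: str = "count") -> np.ndarray:
    """Intensity projection of the skeleton along z onto the xy plane.

    ``count`` sums skeleton voxels per xy column; ``max`` gives a binary
    projection.
    """
    if mode == "count":
        return skel.mask.sum(axis=2).astype(np.int32)
    if mode == "max":
        return skel.mask.max(axis=2).astype(np.int32)
    raise ValueError(f"unknown projection mode {mode!r}")


@dataclass
class RegionStatistics:
    """Per-region subvolume-parameter distributions and area fractions."""

    area_fraction_pct: dict  # region name -> % of in-ROI pixels
    values: dict  # region name -> {parameter -> 1D array}
    n_cells: dict = field(default_factory=dict)  # region name -> cell count


def region_statistics(
    submap: SubvolumeMap, mask: RegionMask2D
) -> RegionStatistics:
    """Assign subvolume cells to regions and summarize per region.

    Each valid cell takes the majority region label of its xy footprint in
    the mask (outside pixels excluded; ties resolved toward "unordered",
    conservative for the sparser class).  Area fractions are shares of
    in-ROI pixels and sum to 100%.
    """
    labels = mask.labels
    px, py = mask.pixel_spacing_um
    h = submap.cell_edge_um
    ncx, ncy, _ = submap.can_dn.shape
    # xy extent of the subvolume grid must fit within the mask frame
    need_x = int(np.ceil(ncx * h / px))
    need_y = int(np.ceil(ncy * h / py))
    if labels.shape[0] * px + px < (ncx - 1) * h or labels.shape[1] * py + py < (ncy - 1) * h:
        raise ValueError(
            f"region mask ({labels.shape}) does not cover the subvolume grid "
            f"({need_x} x {need_y} pixels needed)"
        )

    in_roi = labels != REGION_OUTSIDE
    n_in = int(in_roi.sum())
    area_fraction = {}
    for code, name in _REGION_NAMES.items():
        area_fraction[name] = (
            100.0 * float((labels == code).sum()) / n_in if n_in else 0.0
        )

    # per-cell majority label over the xy footprint
    xs = (np.arange(labels.shape[0]) + 0.5) * px
    ys = (np.arange(labels.shape[1]) + 0.5) * py
    cell_x = np.floor(xs / h).astype(int)
    cell_y = np.floor(ys / h).astype(int)
    okx = cell_x < ncx
    oky = cell_y < ncy
    sub_labels = labels[np.ix_(okx, oky)]
    cx = np.broadcast_to(cell_x[okx][:, None], sub_labels.shape)
    cy = np.broadcast_to(cell_y[oky][None, :], sub_labels.shape)
    flat = (cx * ncy + cy) * 3 + sub_labels
    counts = np.bincount(flat.ravel(), minlength=ncx * ncy * 3).reshape(
        ncx, ncy, 3
    )
    ordered_ct = counts[:, :, REGION_ORDERED]
    unordered_ct = counts[:, :, REGION_UNORDERED]
    cell_region = np.where(
        (ordered_ct + unordered_ct) == 0,
        REGION_OUTSIDE,
        np.where(ordered_ct > unordered_ct, REGION_ORDERED, REGION_UNORDERED),
    )

    values: dict[str, dict[str, np.ndarray]] = {}
    n_cells: dict[str, int] = {}
    for code, name in _REGION_NAMES.items():
        sel2d = cell_region == code
        sel = sel2d[:, :, None] & submap.valid
        n_cells[name] = int(sel.sum())
        vals = {}
        for param in ("can_dn", "nd_nr", "nd_dg"):
            arr = getattr(submap, param)[sel]
            vals[param] = arr[np.isfinite(arr)]
        values[name] = vals
    return RegionStatistics(
        area_fraction_pct=area_fraction, values=values, n_cells=n_cells
    )


def orientation_coherence(
    projection: np.ndarray, sigma_px: float = 4.0
) -> np.ndarray:
    """Structure-tensor anisotropy of a skeleton z-projection, in [0, 1].

    High coherence marks locally parallel (comb-like) texture, low coherence
    isotropic (whirl-like) texture.  Offered as a drafting aid for region
    masks; it is not a replacement for manual segmentation.
    """
    from scipy import ndimage

    img = np.asarray(projection, float)
    gx, gy = np.gradient(img)
    jxx = ndimage.gaussian_filter(gx * gx, sigma_px)
    jxy = ndimage.gaussian_filter(gx * gy, sigma_px)
    jyy = ndimage.gaussian_filter(gy * gy, sigma_px)
    tr = jxx + jyy
    det_term = np.sqrt(np.maximum((jxx - jyy) ** 2 + 4 * jxy**2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(tr > 1e-12, det_term / tr, 0.0)
    return coh
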