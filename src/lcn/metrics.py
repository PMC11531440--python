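"""Quantitative LCN descriptors: subvolume maps, lacunar morphometry,
degree distributions, regressions, smoothed histograms and group statistics.

Conventions
-----------
* Can.Dn [µm/µm³]: total canalicular length per unit volume, evaluated by
  clipping edge paths exactly to cubic subvolume cells (half-open intervals
  per axis), so that summed cell lengths conserve the total length.
* Nd.Nr [µm⁻³]: branching points per unit volume.  Counts junction and
  lacuna nodes; free endpoint terminals are not branching points.
* Nd.Dg [-]: mean degree of "genuine" nodes (degree >= 3, excluding
  lacunae) in a cell; undefined (NaN) where a cell holds none.
* All standard deviations use the n-1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import LacunaShape, LCNGraph, SegmentedMask

__all__ = [
    "SubvolumeMap",
    "DegreeDistribution",
    "RegressionResult",
    "SmoothedHistogram",
    "VariabilitySummary",
    "TTestResult",
    "compute_subvolume_maps",
    "lacuna_morphometry",
    "cumulative_degree_fit",
    "linear_regression",
    "power_law_fit",
    "smoothed_histogram",
    "variability_summary",
    "group_comparison",
]

DEFAULT_SUBVOLUME_UM3 = 400.0


@dataclass
class SubvolumeMap:
    """Per-cell network parameters on a grid of cubic subvolumes."""

    can_dn: np.ndarray  # (ncx, ncy, ncz) µm/µm³
    nd_nr: np.ndarray  # µm^-3
    nd_dg: np.ndarray  # NaN where no genuine node in cell
    valid: np.ndarray  # bool
    cell_edge_um: float
    v_sub_um3: float
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    warnings: list = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def values(self, parameter: str, drop_nan: bool = True) -> np.ndarray:
        """Flattened per-cell values of one parameter over valid cells."""
        arr = getattr(self, parameter)[self.valid]
        if drop_nan:
            arr = arr[np.isfinite(arr)]
        return arr

    def to_dataframe(self) -> pd.DataFrame:
        ix, iy, iz = np.indices(self.can_dn.shape)
        return pd.DataFrame(
            {
                "ix": ix.ravel(),
                "iy": iy.ravel(),
                "iz": iz.ravel(),
                "can_dn": self.can_dn.ravel(),
                "nd_nr": self.nd_nr.ravel(),
                "nd_dg": self.nd_dg.ravel(),
                "valid": self.valid.ravel(),
            }
        )


def _clip_segment_lengths(
    p: np.ndarray, q: np.ndarray, h: float, shape: tuple[int, int, int], out: np.ndarray
) -> None:
    """Distribute the length of segment p->q exactly over the cells it crosses."""
    d = q - p
    seg_len = float(np.linalg.norm(d))
    if seg_len == 0.0:
        return
    t = 0.0
    while t < 1.0 - 1e-12:
        point = p + t * d
        cell = np.floor(point / h).astype(int)
        np.clip(cell, 0, np.asarray(shape) - 1, out=cell)
        # parametric distance to the next cell boundary along each axis
        t_next = 1.0
        for ax in range(3):
            if d[ax] > 1e-15:
                bound = (cell[ax] + 1) * h
                t_hit = (bound - p[ax]) / d[ax]
            elif d[ax] < -1e-15:
                bound = cell[ax] * h
                t_hit = (bound - p[ax]) / d[ax]
            else:
                continue
            if t + 1e-12 < t_hit < t_next:
                t_next = t_hit
        out[tuple(cell)] += (t_next - t) * seg_len
        if t_next <= t:  # numerical guard
            t_next = t + 1e-9
        t = t_next


def compute_subvolume_maps(
    graph: LCNGraph,
    domain_size_um: Sequence[float],
    v_sub_um3: float = DEFAULT_SUBVOLUME_UM3,
    roi_mask: np.ndarray | None = None,
    roi_spacing_um: Sequence[float] | None = None,
) -> SubvolumeMap:
    """Evaluate Can.Dn, Nd.Nr and Nd.Dg within cubic subvolumes.

    Cells are cubes of volume ``v_sub_um3`` (edge ``v_sub**(1/3)``) with
    half-open extents ``[i*h, (i+1)*h)``.  A cell is valid only if it lies
    entirely inside the domain and, when ``roi_mask`` is given, entirely
    inside the mask — partial boundary cells would otherwise bias densities
    downward.
    """
    h = float(v_sub_um3) ** (1.0 / 3.0)
    size = np.asarray(domain_size_um, float)
    shape = tuple(int(math.ceil(s / h)) for s in size)
    can_len = np.zeros(shape)
    nd_count = np.zeros(shape, dtype=int)
    genuine_deg_sum = np.zeros(shape)
    genuine_count = np.zeros(shape, dtype=int)

    for path in graph.edge_paths():
        pts = np.asarray(path, float)
        cells = np.floor(pts / h).astype(int)
        same = np.all(cells[1:] == cells[:-1], axis=1)
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        # fast path: whole segment inside one cell
        idx = cells[:-1][same]
        np.clip(idx, 0, np.asarray(shape) - 1, out=idx)
        if len(idx):
            np.add.at(
                can_len.ravel(),
                np.ravel_multi_index(tuple(idx.T), shape),
                seg_len[same],
            )
        for k in np.nonzero(~same)[0]:
            _clip_segment_lengths(pts[k], pts[k + 1], h, shape, can_len)

    for n, d in graph.g.nodes(data=True):
        if d["kind"] == "endpoint":
            continue
        cell = np.floor(d["pos"] / h).astype(int)
        cell = np.clip(cell, 0, np.asarray(shape) - 1)
        nd_count[tuple(cell)] += 1
        deg = graph.g.degree(n)
        if d["kind"] == "junction" and deg >= 3:
            genuine_deg_sum[tuple(cell)] += deg
            genuine_count[tuple(cell)] += 1

    # validity: cell entirely inside domain (and ROI mask if given)
    valid = np.ones(shape, dtype=bool)
    for ax in range(3):
        n_full = int(math.floor(size[ax] / h + 1e-9))
        sl = [slice(None)] * 3
        sl[ax] = slice(n_full, None)
        valid[tuple(sl)] = False
    if roi_mask is not None:
        if roi_spacing_um is None:
            raise ValueError("roi_spacing_um required with roi_mask")
        sp = np.asarray(roi_spacing_um, float)
        vox_idx = np.argwhere(~np.asarray(roi_mask, bool))
        if len(vox_idx):
            centers = (vox_idx + 0.5) * sp
            cells = np.floor(centers / h).astype(int)
            inside = np.all((cells >= 0) & (cells < np.asarray(shape)), axis=1)
            for cell in cells[inside]:
                valid[tuple(cell)] = False

    warnings: list[str] = []
    if not valid.any():
        warnings.append("no valid subvolume cells inside the ROI")

    with np.errstate(invalid="ignore"):
        nd_dg = np.where(
            genuine_count > 0, genuine_deg_sum / np.maximum(genuine_count, 1), np.nan
        )
    return SubvolumeMap(
        can_dn=can_len / v_sub_um3,
        nd_nr=nd_count / v_sub_um3,
        nd_dg=nd_dg,
        valid=valid,
        cell_edge_um=h,
        v_sub_um3=float(v_sub_um3),
        warnings=warnings,
    )


MIN_LACUNA_VOXELS = 10


def lacuna_morphometry(
    seg: SegmentedMask, graph: LCNGraph | None = None
) -> list[LacunaShape]:
    """Ellipsoid morphometry of every labelled lacuna.

    Semi-axes come from the second central moments of the voxel cloud: for a
    solid ellipsoid the eigenvalues of the covariance satisfy λ = axis²/5,
    so semi-axis = sqrt(5 λ).  Lacunae smaller than 10 voxels are flagged
    invalid and carry no shape.
    """
    lc_dg = graph.lacuna_degrees() if graph is not None else {}
    spacing = seg.voxel_spacing_um
    vox_vol = seg.voxel_volume_um3
    out: list[LacunaShape] = []
    for lac_id in seg.lacuna_ids:
        idx = np.argwhere(seg.lacuna_mask(int(lac_id)))
        n = len(idx)
        volume = n * vox_vol
        centroid = (idx.mean(axis=0) + 0.5) * spacing + seg.origin_um
        if n < MIN_LACUNA_VOXELS:
            out.append(
                LacunaShape(
                    lacuna_id=int(lac_id),
                    volume_um3=volume,
                    semi_axes_um=(math.nan, math.nan, math.nan),
                    stretch=math.nan,
                    oblateness=math.nan,
                    degree=lc_dg.get(int(lac_id)),
                    centroid_um=centroid,
                    valid=False,
                )
            )
            continue
        pts = (idx + 0.5) * spacing
        cov = np.cov(pts.T, ddof=0)
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
        lam = np.maximum(lam, 0.0)
        a, b, c = np.sqrt(5.0 * lam)
        st, ob = LacunaShape.shape_descriptors(a, b, c)
        out.append(
            LacunaShape(
                lacuna_id=int(lac_id),
                volume_um3=volume,
                semi_axes_um=(float(a), float(b), float(c)),
                stretch=float(st),
                oblateness=float(ob),
                degree=lc_dg.get(int(lac_id)),
                centroid_um=centroid,
                valid=True,
            )
        )
    return out


@dataclass
class DegreeDistribution:
    """Cumulative degree distribution of genuine nodes, C(x) = P(K >= x)."""

    x: np.ndarray  # integer degrees from 3 upward
    cumulative: np.ndarray  # C(x), C(3) = 1
    beta: float  # exponent of exp(-beta (x - 3)); NaN if undefined
    n_nodes: int
    note: str = ""


def cumulative_degree_fit(graph_or_degrees) -> DegreeDistribution:
    """Cumulative node-degree distribution and its exponential-tail exponent.

    C(x) is the fraction of genuine nodes (degree >= 3, lacunae excluded)
    with degree >= x.  The tail exponent β of ``exp(-β (x - 3))`` is fitted
    by least squares of ``-ln C(x)`` against ``x - 3`` through the origin,
    over the observed degrees with C(x) > 0.
    """
    if isinstance(graph_or_degrees, LCNGraph):
        degrees = graph_or_degrees.genuine_degrees()
    else:
        degrees = np.asarray(graph_or_degrees, dtype=int)
    degrees = degrees[degrees >= 3]
    if degrees.size == 0:
        raise ValueError("no genuine nodes (degree >= 3)")
    xs = np.arange(3, degrees.max() + 1)
    cum = np.array([(degrees >= x).mean() for x in xs])
    pos = cum > 0
    xr = (xs[pos] - 3).astype(float)
    neg_log = -np.log(cum[pos])
    denom = float((xr**2).sum())
    if denom == 0.0:
        return DegreeDistribution(
            x=xs,
            cumulative=cum,
            beta=math.nan,
            n_nodes=int(degrees.size),
            note="all nodes have degree 3; tail exponent undefined",
        )
    beta = float((xr * neg_log).sum() / denom)
    return DegreeDistribution(
        x=xs, cumulative=cum, beta=beta, n_nodes=int(degrees.size)
    )


@dataclass
class RegressionResult:
    """Least-squares fit: linear (slope/intercept) or power-law mode.

    In power-law mode ``y = prefactor * x**exponent`` is fitted by ordinary
    least squares on log-log axes; ``r`` is the Pearson correlation on the
    fitted axes.
    """

    mode: str  # "linear" | "power"
    r: float
    slope: float | None = None
    intercept: float | None = None
    exponent: float | None = None
    prefactor: float | None = None


def _finite_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def linear_regression(x, y) -> RegressionResult:
    """Least-squares straight-line fit with Pearson R."""
    x, y = _finite_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0.0:
        raise ValueError("x has zero variance; fit undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        mode="linear",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
    )


def power_law_fit(x, y) -> RegressionResult:
    """Fit y = prefactor * x**exponent by least squares on log-log axes."""
    x, y = _finite_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0.0:
        raise ValueError("x has zero variance; fit undefined")
    res = stats.linregress(lx, ly)
    return RegressionResult(
        mode="power",
        exponent=float(res.slope),
        prefactor=float(math.exp(res.intercept)),
        r=float(res.rvalue),
    )


@dataclass
class SmoothedHistogram:
    bin_centers: np.ndarray
    frequencies: np.ndarray  # sum to 1
    sigma_bins: float


def smoothed_histogram(
    values, bin_edges, sigma_bins: float = 1.0
) -> SmoothedHistogram:
    """Normalized frequency histogram smoothed with a discrete Gaussian kernel.

    ``sigma_bins`` is the kernel width in units of bins (σ = 1 by default);
    σ -> 0 returns the raw normalized histogram.  Frequencies are
    renormalized to sum to 1 after smoothing.
    """
    values = np.asarray(values, float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to histogram")
    counts, edges = np.histogram(values, bins=bin_edges)
    freq = counts.astype(float)
    total = freq.sum()
    if total == 0:
        raise ValueError("all values fall outside the bin range")
    freq /= total
    if sigma_bins > 0:
        radius = max(1, int(math.ceil(4.0 * sigma_bins)))
        k = np.arange(-radius, radius + 1, dtype=float)
        kernel = np.exp(-0.5 * (k / sigma_bins) ** 2)
        kernel /= kernel.sum()
        freq = np.convolve(freq, kernel, mode="same")
        freq /= freq.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return SmoothedHistogram(
        bin_centers=centers, frequencies=freq, sigma_bins=float(sigma_bins)
    )


@dataclass
class VariabilitySummary:
    """Inter- vs intra-individual variability decomposition.

    ``inter`` is the SD of the per-sample means; ``intra`` is the mean of the
    per-sample SDs.
    """

    sample_means: np.ndarray
    sample_sds: np.ndarray
    inter: float
    intra: float


def variability_summary(per_sample_values: Sequence[Sequence[float]]) -> VariabilitySummary:
    if len(per_sample_values) < 2:
        raise ValueError("need at least 2 samples")
    means, sds = [], []
    for vals in per_sample_values:
        arr = np.asarray(vals, float).ravel()
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            raise ValueError("each sample needs at least 2 values")
        means.append(arr.mean())
        sds.append(arr.std(ddof=1))
    means = np.asarray(means)
    sds = np.asarray(sds)
    return VariabilitySummary(
        sample_means=means,
        sample_sds=sds,
        inter=float(means.std(ddof=1)),
        intra=float(sds.mean()),
    )


@dataclass
class TTestResult:
    t: float
    p: float
    df: float
    paired: bool


def group_comparison(a, b, paired: bool = False) -> TTestResult:
    """Two-sided Student's t-test between two groups of values.

    Paired mode requires equal lengths.  Degenerate zero-variance inputs
    with equal means report t = 0, p = 1.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        res = stats.ttest_rel(a, b)
        df = a.size - 1
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    t, p = float(res.statistic), float(res.pvalue)
    if not math.isfinite(t) and math.isclose(a.mean(), b.mean()):
        t, p = 0.0, 1.0
    return TTestResult(t=t, p=p, df=float(df), paired=paired)
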