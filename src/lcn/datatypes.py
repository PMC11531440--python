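"""Core in-memory containers for lacunocanalicular network (LCN) analysis.

Axis convention
---------------
All 3D arrays are indexed ``[ix, iy, iz]`` and carry a voxel spacing vector
``(sx, sy, sz)`` in micrometres.  The physical position of the centre of voxel
``(i, j, k)`` is ``origin + ((i, j, k) + 0.5) * spacing``.  2D images derived
from stacks (z-projections, region masks, qBEI maps) are indexed ``[ix, iy]``.
On disk, multi-page TIFF stacks store pages along z (axis order ``z, y, x``);
the I/O layer transposes on read/write so in-memory order is always
``x, y, z``.  All graph geometry is expressed in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np

__all__ = [
    "ImageStack",
    "BinaryMask",
    "SegmentedMask",
    "Skeleton",
    "BranchPath",
    "LCNGraph",
    "LacunaShape",
    "LABEL_BACKGROUND",
    "LABEL_CANALICULUS",
    "LACUNA_LABEL_OFFSET",
]

#: segmentation label codes: 0 background, 1 canaliculus, lacuna i -> i + 1
LABEL_BACKGROUND = 0
LABEL_CANALICULUS = 1
LACUNA_LABEL_OFFSET = 1


@dataclass
class ImageStack:
    """A 3D intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities.  Any real dtype.
    voxel_spacing_um : array-like of 3 floats
        Physical voxel edge lengths (sx, sy, sz) in µm; strictly positive.
    origin_um : array-like of 3 floats
        Physical coordinate of the corner of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_spacing_um: np.ndarray
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.voxel_spacing_um = np.asarray(self.voxel_spacing_um, dtype=float)
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        if self.voxel_spacing_um.shape != (3,) or np.any(self.voxel_spacing_um <= 0):
            raise ValueError("voxel_spacing_um must be 3 positive floats")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def domain_size_um(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_spacing_um

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_spacing_um))


@dataclass
class BinaryMask:
    """Boolean foreground mask on the same grid as its source stack."""

    mask: np.ndarray
    voxel_spacing_um: np.ndarray
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_spacing_um = np.asarray(self.voxel_spacing_um, dtype=float)
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass
class SegmentedMask:
    """Per-voxel labels separating background, canaliculi and lacunae.

    ``labels == 0`` is background, ``labels == 1`` canaliculus, and lacuna
    ``i`` (``i >= 1``) occupies ``labels == i + 1``.
    """

    labels: np.ndarray
    voxel_spacing_um: np.ndarray
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.voxel_spacing_um = np.asarray(self.voxel_spacing_um, dtype=float)
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_spacing_um))

    @property
    def lacuna_ids(self) -> np.ndarray:
        """Sorted ids of lacunae present in the mask."""
        labs = np.unique(self.labels)
        labs = labs[labs > LABEL_CANALICULUS]
        return labs - LACUNA_LABEL_OFFSET

    def lacuna_mask(self, lacuna_id: int) -> np.ndarray:
        return self.labels == lacuna_id + LACUNA_LABEL_OFFSET

    @property
    def canaliculus_mask(self) -> np.ndarray:
        return self.labels == LABEL_CANALICULUS

    @property
    def any_lacuna_mask(self) -> np.ndarray:
        return self.labels > LABEL_CANALICULUS


@dataclass
class Skeleton:
    """Voxel-wide centerlines of the canalicular mask (26-connectivity).

    ``lacuna_labels`` keeps the segmentation's label grid so that branch
    tracing can record on which lacuna a skeleton branch terminates.
    """

    mask: np.ndarray
    voxel_spacing_um: np.ndarray
    origin_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    lacuna_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_spacing_um = np.asarray(self.voxel_spacing_um, dtype=float)
        self.origin_um = np.asarray(self.origin_um, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_positions_um(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return self.origin_um + (idx + 0.5) * self.voxel_spacing_um


@dataclass
class BranchPath:
    """One simple skeleton path between two terminals, in µm coordinates.

    ``end_a`` / ``end_b`` describe the terminal a path attaches to:
    ``("junction", cluster_id)``, ``("endpoint", None)`` or
    ``("lacuna", lacuna_id)``.
    """

    points_um: np.ndarray  # (m, 3)
    end_a: tuple[str, int | None]
    end_b: tuple[str, int | None]

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1).sum())

    @property
    def chord_um(self) -> float:
        return float(np.linalg.norm(self.points_um[-1] - self.points_um[0]))


NODE_KINDS = ("lacuna", "junction", "endpoint")


class LCNGraph:
    """Spatial network of lacunae, junctions and endpoints.

    Thin wrapper around a :class:`networkx.MultiGraph`.  Node attributes:
    ``pos`` (3-vector, µm), ``kind`` (one of ``lacuna``, ``junction``,
    ``endpoint``) and, for lacuna nodes, ``lacuna_id``.  Edge attributes:
    ``path`` (``(m, 3)`` float array, µm, ordered from source to target) and
    ``length_um`` (arc length of the path).
    """

    def __init__(self, graph: nx.MultiGraph | None = None):
        self.g: nx.MultiGraph = graph if graph is not None else nx.MultiGraph()

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: int, pos, kind: str, **attrs) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        self.g.add_node(node_id, pos=np.asarray(pos, dtype=float), kind=kind, **attrs)

    def add_edge(self, u: int, v: int, path: np.ndarray) -> None:
        path = np.asarray(path, dtype=float)
        if path.ndim != 2 or path.shape[1] != 3 or path.shape[0] < 2:
            raise ValueError("edge path must be an (m>=2, 3) array")
        length = float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())
        self.g.add_edge(u, v, path=path, length_um=length)

    # -- queries ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes_of_kind(self, kind: str) -> list[int]:
        return [n for n, d in self.g.nodes(data=True) if d["kind"] == kind]

    def degree(self, node_id: int) -> int:
        return int(self.g.degree(node_id))

    def positions(self, nodes: Iterator[int] | None = None) -> np.ndarray:
        nodes = list(self.g.nodes) if nodes is None else list(nodes)
        if not nodes:
            return np.empty((0, 3))
        return np.array([self.g.nodes[n]["pos"] for n in nodes])

    def genuine_nodes(self) -> list[int]:
        """Non-lacuna nodes of degree >= 3 ('genuine' network nodes)."""
        return [
            n
            for n, d in self.g.nodes(data=True)
            if d["kind"] == "junction" and self.g.degree(n) >= 3
        ]

    def genuine_degrees(self) -> np.ndarray:
        return np.array([self.g.degree(n) for n in self.genuine_nodes()], dtype=int)

    def lacuna_degrees(self) -> dict[int, int]:
        """Lc.Dg: number of canaliculi incident to each lacuna node, keyed by lacuna_id."""
        return {
            d["lacuna_id"]: int(self.g.degree(n))
            for n, d in self.g.nodes(data=True)
            if d["kind"] == "lacuna"
        }

    def total_length_um(self) -> float:
        return float(sum(d["length_um"] for _, _, d in self.g.edges(data=True)))

    def edge_paths(self) -> Iterator[np.ndarray]:
        for _, _, d in self.g.edges(data=True):
            yield d["path"]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kinds = {k: len(self.nodes_of_kind(k)) for k in NODE_KINDS}
        return (
            f"LCNGraph({kinds['lacuna']} lacunae, {kinds['junction']} junctions, "
            f"{kinds['endpoint']} endpoints, {self.n_edges} edges, "
            f"{self.total_length_um():.1f} um total length)"
        )


@dataclass
class LacunaShape:
    """Ellipsoid-based morphometry of a single osteocyte lacuna.

    ``stretch`` (Lc.St) is ``1 - c/a`` for semi-axes ``a >= b >= c``: 0 for a
    sphere, approaching 1 for a needle.  ``oblateness`` (Lc.Ob) is
    ``2*(b - c)/(a - c) - 1``: -1 for a rod (prolate), +1 for a plate
    (oblate), defined as 0 when ``a - c`` vanishes.
    """

    lacuna_id: int
    volume_um3: float
    semi_axes_um: tuple[float, float, float]  # a >= b >= c
    stretch: float
    oblateness: float
    degree: int | None = None
    centroid_um: np.ndarray | None = None
    valid: bool = True

    @staticmethod
    def shape_descriptors(a: float, b: float, c: float) -> tuple[float, float]:
        """Stretch and oblateness from ordered semi-axes a >= b >= c."""
        stretch = 1.0 - c / a
        oblateness = 0.0 if (a - c) < 1e-6 else 2.0 * (b - c) / (a - c) - 1.0
        return stretch, oblateness
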