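"""Ground-truthed synthetic lacunocanalicular network (LCN) phantoms.

The generator draws a spatial network with the statistical structure that the
downstream analysis assumes: ellipsoidal lacunae placed by a hard-core point
process, junctions whose degree distribution has survival function
``P(K >= k) = exp(-beta * (k - 3))`` for ``k >= 3``, edges with controlled
tortuosity whose total length realises a target canalicular density
(Can.Dn, µm/µm³), an ordered region with aligned canaliculi next to a sparser
isotropic "unordered" region, an optional mineral interface plane that no
edge crosses, and confocal-like degradation (anisotropic blur, background
gradient, noise).  Everything is reproducible from a single seed.

Randomness is drawn from named substreams spawned from the master seed in a
fixed documented order (``lacunae``, ``junctions``, ``degrees``, ``matching``,
``geometry``, ``noise``), so adding draws to one stage never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .datatypes import ImageStack, LacunaShape, LCNGraph

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "StrainPreset",
    "CohortSample",
    "QBEIPhantom",
    "ParameterizationError",
    "STRAIN_PRESETS",
    "generate_ground_truth",
    "rasterize",
    "degrade",
    "generate_cohort",
    "generate_qbei_phantom",
    "ellipsoid_surface_area",
    "ellipsoid_volume",
    "sample_lacuna_population",
    "implied_mean_edge_length",
]

REGION_ORDERED = 1
REGION_UNORDERED = 2

_SUBSTREAMS = ("lacunae", "junctions", "degrees", "matching", "geometry", "noise")


class ParameterizationError(ValueError):
    """Raised when generator targets are mutually infeasible."""


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    return 4.0 / 3.0 * math.pi * a * b * c


def ellipsoid_surface_area(a: float, b: float, c: float, p: float = 1.6075) -> float:
    """Thomsen's approximation to the surface area of an ellipsoid.

    Accurate to ~1% for all aspect ratios; exact closed forms need elliptic
    integrals, which is unwarranted for a generator target.
    """
    ap, bp, cp = a**p, b**p, c**p
    return 4.0 * math.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)


def implied_mean_edge_length(
    can_density: float, node_density: float, mean_degree: float
) -> float:
    """Mean edge length L implied by Can.Dn = Nd.Nr * Nd.Dg / 2 * L."""
    return can_density / (node_density * mean_degree / 2.0)


def _mean_degree(beta: float) -> float:
    """Mean of the discrete law P(K >= k) = exp(-beta (k - 3)), k >= 3."""
    return 3.0 + 1.0 / math.expm1(beta)


@dataclass
class GeneratorParams:
    """Targets and imaging conditions for one synthetic LCN stack.

    Densities mirror measured murine cortical bone: canalicular density
    ~0.21 µm/µm³, node density ~0.05 µm⁻³, lacunar volume ~350 µm³ with
    rod-like axis ratios, canaliculus radius 150 nm.
    """

    domain_size_um: tuple[float, float, float] = (50.0, 50.0, 50.0)
    voxel_spacing_um: tuple[float, float, float] = (0.379, 0.379, 0.340)
    lacuna_number_density: float = 3.0e-5  # µm^-3
    lacuna_mean_volume_um3: float = 350.0
    lacuna_axis_ratios: tuple[float, float, float] = (1.0, 0.54, 0.34)
    target_node_density: float = 0.05  # µm^-3
    target_can_density: float = 0.21  # µm/µm^3
    degree_tail_beta: float = 2.0
    canaliculus_radius_um: float = 0.15
    unordered_fraction: float = 0.28
    ordered_alignment_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    tortuosity_factor: float = 1.03
    psf_sigma_um: tuple[float, float, float] = (0.12, 0.12, 0.35)
    noise_sd: float = 0.01
    background_gradient: float = 0.0005  # intensity per µm along x
    seed: int = 0
    # secondary knobs
    area_per_canaliculus_um2: float = 5.0
    unordered_density_factor: float = 0.7
    alignment_half_angle_deg: float = 20.0
    interface_plane_x_um: float | None = None
    lacuna_scale_spread: float = 0.2  # uniform linear-size factor 1 +/- spread
    junction_min_separation_um: float = 1.8  # hard-core spacing of junctions

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        spacing = np.asarray(self.voxel_spacing_um, float)
        if np.any(spacing <= 0):
            raise ParameterizationError("voxel spacing must be positive")
        for name in (
            "lacuna_number_density",
            "target_node_density",
            "target_can_density",
        ):
            if getattr(self, name) < 0:
                raise ParameterizationError(f"{name} must be >= 0")
        if self.degree_tail_beta <= 0:
            raise ParameterizationError("degree_tail_beta must be > 0")
        if not 0.0 <= self.unordered_fraction <= 1.0:
            raise ParameterizationError("unordered_fraction must be in [0, 1]")
        if self.tortuosity_factor < 1.0:
            raise ParameterizationError("tortuosity_factor must be >= 1")
        if np.linalg.norm(self.ordered_alignment_axis) == 0:
            raise ParameterizationError("ordered_alignment_axis must be nonzero")
        if self.target_node_density > 0:
            if self.target_can_density <= 0:
                raise ParameterizationError(
                    "target_can_density must be > 0 when junctions are requested"
                )
            ell = implied_mean_edge_length(
                self.target_can_density,
                self.target_node_density,
                _mean_degree(self.degree_tail_beta),
            )
            if ell < 2.0 * float(spacing.min()):
                raise ParameterizationError(
                    f"implied mean edge length {ell:.3f} µm is shorter than two "
                    f"voxels ({2 * spacing.min():.3f} µm); targets are infeasible"
                )

    @property
    def mean_degree(self) -> float:
        return _mean_degree(self.degree_tail_beta)

    @property
    def implied_edge_length_um(self) -> float:
        if self.target_node_density <= 0:
            return float("nan")
        return implied_mean_edge_length(
            self.target_can_density, self.target_node_density, self.mean_degree
        )

    def base_semi_axes(self) -> tuple[float, float, float]:
        """Semi-axes of the mean-volume lacuna at the configured ratios."""
        r = np.asarray(self.lacuna_axis_ratios, float)
        s = (self.lacuna_mean_volume_um3 / (4.0 / 3.0 * math.pi * np.prod(r))) ** (
            1.0 / 3.0
        )
        a, b, c = sorted(s * r, reverse=True)
        return float(a), float(b), float(c)


@dataclass
class StrainPreset:
    """Generator targets emulating one mouse strain's network statistics."""

    name: str
    target_can_density: float
    target_node_density: float
    degree_tail_beta: float
    lacuna_mean_volume_um3: float
    unordered_fraction: float

    def apply(self, params: GeneratorParams) -> GeneratorParams:
        return replace(
            params,
            target_can_density=self.target_can_density,
            target_node_density=self.target_node_density,
            degree_tail_beta=self.degree_tail_beta,
            lacuna_mean_volume_um3=self.lacuna_mean_volume_um3,
            unordered_fraction=self.unordered_fraction,
        )


#: BALB/c-like vs C57BL/6J-like density targets (C57-like strictly denser).
STRAIN_PRESETS: dict[str, StrainPreset] = {
    "balbc_like": StrainPreset("balbc_like", 0.21, 0.050, 2.0, 350.0, 0.28),
    "c57_like": StrainPreset("c57_like", 0.23, 0.059, 1.8, 380.0, 0.30),
}


@dataclass
class TrueLacuna:
    """Generator-side lacuna: shape plus pose."""

    shape: LacunaShape
    centroid_um: np.ndarray
    rotation: np.ndarray  # columns = principal axes (a, b, c directions)


@dataclass
class GroundTruth:
    graph: LCNGraph
    lacunae: list[TrueLacuna]
    region_label_field: np.ndarray  # uint8 grid, 1 ordered / 2 unordered
    interface_plane_x_um: float | None
    per_region_targets: dict[str, dict[str, float]]
    realized: dict[str, float]
    params: GeneratorParams
    seed: int
    metadata: dict = field(default_factory=dict)

    def region_of_points(self, points: np.ndarray) -> np.ndarray:
        """Region label (1 ordered / 2 unordered) of physical points."""
        return _region_of_x(
            np.atleast_2d(points)[:, 0],
            self.params.unordered_fraction,
            self.params.domain_size_um[0],
        )

    def region_mask_2d(self) -> np.ndarray:
        """xy-plane region label image on the voxel grid (1/2)."""
        return self.region_label_field[:, :, 0].copy()


def _region_of_x(x: np.ndarray, unordered_fraction: float, lx: float) -> np.ndarray:
    """Unordered region = central slab of width f*Lx along x."""
    lo = (0.5 - unordered_fraction / 2.0) * lx
    hi = (0.5 + unordered_fraction / 2.0) * lx
    out = np.full(np.shape(x), REGION_ORDERED, dtype=np.uint8)
    out[(np.asarray(x) >= lo) & (np.asarray(x) < hi)] = REGION_UNORDERED
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _cone_direction(
    rng: np.random.Generator, axis: np.ndarray, half_angle_deg: float
) -> np.ndarray:
    """Uniform direction within a double cone of given half angle about axis."""
    axis = _unit(axis)
    cos_max = math.cos(math.radians(half_angle_deg))
    cosang = rng.uniform(cos_max, 1.0)
    sinang = math.sqrt(max(0.0, 1.0 - cosang**2))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    # orthonormal frame about axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(axis, helper))
    e2 = np.cross(axis, e1)
    d = cosang * axis + sinang * (math.cos(phi) * e1 + math.sin(phi) * e2)
    return d if rng.random() < 0.5 else -d


def _rotation_with_long_axis(rng: np.random.Generator, v: np.ndarray) -> np.ndarray:
    """Rotation matrix whose first column is v (unit), random roll."""
    v = _unit(v)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(v @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(v, helper))
    e2 = np.cross(v, e1)
    roll = rng.uniform(0.0, 2.0 * math.pi)
    b = math.cos(roll) * e1 + math.sin(roll) * e2
    c = np.cross(v, b)
    return np.column_stack([v, b, c])


def _sample_degrees(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Draw junction degrees with survival P(K >= k) = exp(-beta (k - 3))."""
    u = rng.random(n)
    return 3 + np.floor(-np.log(u) / beta).astype(int)


def sample_lacuna_population(
    n: int,
    rng: np.random.Generator,
    base_semi_axes: tuple[float, float, float] = (7.7, 4.15, 2.62),
    scale_range: tuple[float, float] = (0.7, 1.3),
    area_per_canaliculus_um2: float = 5.0,
) -> list[LacunaShape]:
    """Ellipsoidal lacunae with fixed axis ratios and random linear size.

    Each lacuna's degree (number of primary canaliculi) is set to
    ``round(surface_area / area_per_canaliculus)`` — the constant
    area-per-canaliculus hypothesis, under which lacunar volume scales as
    degree^(3/2).
    """
    a0, b0, c0 = base_semi_axes
    scales = rng.uniform(*scale_range, size=n)
    out = []
    for i, s in enumerate(scales):
        a, b, c = a0 * s, b0 * s, c0 * s
        area = ellipsoid_surface_area(a, b, c)
        st, ob = LacunaShape.shape_descriptors(a, b, c)
        out.append(
            LacunaShape(
                lacuna_id=i + 1,
                volume_um3=ellipsoid_volume(a, b, c),
                semi_axes_um=(a, b, c),
                stretch=st,
                oblateness=ob,
                degree=int(round(area / area_per_canaliculus_um2)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# ground-truth graph generation
# ---------------------------------------------------------------------------


def _place_lacunae(
    params: GeneratorParams, rng: np.random.Generator
) -> list[TrueLacuna]:
    size = np.asarray(params.domain_size_um, float)
    volume = float(np.prod(size))
    n_target = int(rng.poisson(params.lacuna_number_density * volume))
    if n_target == 0:
        return []
    a0, b0, c0 = params.base_semi_axes()
    min_sep = 2.0 * a0  # hard-core: twice the mean long semi-axis
    centers: list[np.ndarray] = []
    max_tries = 200 * n_target
    tries = 0
    while len(centers) < n_target and tries < max_tries:
        tries += 1
        p = rng.uniform(0.0, 1.0, size=3) * size
        # keep the body inside the domain
        if np.any(p < a0) or np.any(p > size - a0):
            continue
        if centers and np.min(np.linalg.norm(np.array(centers) - p, axis=1)) < min_sep:
            continue
        centers.append(p)
    lacunae = []
    spread = params.lacuna_scale_spread
    axis = np.asarray(params.ordered_alignment_axis, float)
    for i, ctr in enumerate(centers):
        s = rng.uniform(1.0 - spread, 1.0 + spread)
        a, b, c = a0 * s, b0 * s, c0 * s
        region = _region_of_x(
            np.array([ctr[0]]), params.unordered_fraction, size[0]
        )[0]
        if region == REGION_ORDERED:
            v = _cone_direction(rng, axis, params.alignment_half_angle_deg)
        else:
            v = _random_unit(rng)[0]
        rot = _rotation_with_long_axis(rng, v)
        st, ob = LacunaShape.shape_descriptors(a, b, c)
        shape = LacunaShape(
            lacuna_id=i + 1,
            volume_um3=ellipsoid_volume(a, b, c),
            semi_axes_um=(a, b, c),
            stretch=st,
            oblateness=ob,
            degree=0,
            centroid_um=ctr,
        )
        lacunae.append(TrueLacuna(shape=shape, centroid_um=ctr, rotation=rot))
    return lacunae


def _inside_any_lacuna(
    points: np.ndarray, lacunae: list[TrueLacuna], margin_um: float = 0.5
) -> np.ndarray:
    inside = np.zeros(len(points), dtype=bool)
    for lac in lacunae:
        a, b, c = lac.shape.semi_axes_um
        local = (points - lac.centroid_um) @ lac.rotation
        q = (
            (local[:, 0] / (a + margin_um)) ** 2
            + (local[:, 1] / (b + margin_um)) ** 2
            + (local[:, 2] / (c + margin_um)) ** 2
        )
        inside |= q <= 1.0
    return inside


class _HardcoreGrid:
    """Grid hash for incremental minimum-separation checks."""

    def __init__(self, min_sep: float):
        self.min_sep = min_sep
        self.cell = max(min_sep, 1e-6)
        self.table: dict[tuple[int, int, int], list[np.ndarray]] = {}

    def ok(self, p: np.ndarray) -> bool:
        c = tuple((p // self.cell).astype(int))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in self.table.get((c[0] + dx, c[1] + dy, c[2] + dz), ()):
                        if np.sum((p - q) ** 2) < self.min_sep**2:
                            return False
        return True

    def add(self, p: np.ndarray) -> None:
        c = tuple((p // self.cell).astype(int))
        self.table.setdefault(c, []).append(p)


def _place_junctions(
    params: GeneratorParams,
    lacunae: list[TrueLacuna],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and region labels of junction nodes.

    Counts are Poisson per region; positions are placed by dart throwing
    with a hard-core minimum separation (branch points closer than the
    resolvable branch-segment scale do not occur) and are re-drawn when
    they fall inside a lacuna, so the realized count is not biased.
    """
    size = np.asarray(params.domain_size_um, float)
    f = params.unordered_fraction
    gamma = params.unordered_density_factor
    denom = (1.0 - f) + f * gamma
    rho_ord = params.target_node_density / denom
    rho_un = gamma * rho_ord
    slabs = [
        (REGION_ORDERED, rho_ord, 1.0 - f),
        (REGION_UNORDERED, rho_un, f),
    ]
    lo_un = (0.5 - f / 2.0) * size[0]
    hi_un = (0.5 + f / 2.0) * size[0]
    grid = _HardcoreGrid(params.junction_min_separation_um)
    all_pos, all_reg = [], []
    for label, rho, vol_frac in slabs:
        v_region = vol_frac * float(np.prod(size))
        n = int(rng.poisson(rho * v_region)) if rho > 0 and v_region > 0 else 0
        if n == 0:
            continue
        placed: list[np.ndarray] = []
        batch = max(256, n)
        tries = 0
        while len(placed) < n and tries < 80:
            tries += 1
            cand = rng.uniform(0.0, 1.0, size=(batch, 3)) * size
            if label == REGION_UNORDERED:
                cand[:, 0] = lo_un + rng.uniform(0.0, 1.0, batch) * (hi_un - lo_un)
            else:
                width = size[0] - (hi_un - lo_un)
                u = rng.uniform(0.0, 1.0, batch) * width
                cand[:, 0] = np.where(u < lo_un, u, u + (hi_un - lo_un))
            cand = cand[~_inside_any_lacuna(cand, lacunae)]
            for p in cand:
                if len(placed) >= n:
                    break
                if grid.ok(p):
                    grid.add(p)
                    placed.append(p)
        if placed:
            all_pos.append(np.array(placed))
            all_reg.append(np.full(len(placed), label, dtype=np.uint8))
    if not all_pos:
        return np.empty((0, 3)), np.empty(0, dtype=np.uint8)
    return np.concatenate(all_pos), np.concatenate(all_reg)


def _tortuous_path(
    p: np.ndarray,
    q: np.ndarray,
    tortuosity: float,
    rng: np.random.Generator,
    step_um: float = 1.0,
) -> np.ndarray:
    """Polyline from p to q with arc/chord ratio ~ tortuosity.

    A single random perpendicular half-sine bump, amplitude solved by
    bisection on the discrete arc length.
    """
    chord = float(np.linalg.norm(q - p))
    if chord == 0.0:
        return np.vstack([p, q])
    n_seg = max(2, int(round(chord / step_um)) + 1)
    t = np.linspace(0.0, 1.0, n_seg + 1)
    base = p[None, :] + t[:, None] * (q - p)[None, :]
    if tortuosity <= 1.0 + 1e-9:
        return base
    u = _random_unit(rng)[0]
    d = (q - p) / chord
    u = u - (u @ d) * d
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        u = _unit(np.cross(d, [1.0, 0.3, 0.2]))
    else:
        u = u / nu
    bump = np.sin(math.pi * t)[:, None] * u[None, :]

    def arc(h: float) -> float:
        pts = base + h * bump
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    target = tortuosity * chord
    lo, hi = 0.0, chord
    while arc(hi) < target and hi < 10 * chord:
        hi *= 2.0
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if arc(mid) < target:
            lo = mid
        else:
            hi = mid
    return base + 0.5 * (lo + hi) * bump


def _clamp_to_side(
    path: np.ndarray, plane_x: float | None, eps: float = 0.05
) -> np.ndarray:
    """Force a path to stay on the side of the interface plane it starts on."""
    if plane_x is None:
        return path
    if path[0, 0] < plane_x:
        path[:, 0] = np.minimum(path[:, 0], plane_x - eps)
    else:
        path[:, 0] = np.maximum(path[:, 0], plane_x + eps)
    return path


def _crosses_plane(p: np.ndarray, q: np.ndarray, plane_x: float | None) -> bool:
    if plane_x is None:
        return False
    return (p[0] - plane_x) * (q[0] - plane_x) <= 0.0


def _surface_point_and_normal(
    lac: TrueLacuna, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    axes = np.asarray(lac.shape.semi_axes_um)
    s = _random_unit(rng)[0]
    local_pt = axes * s
    local_n = _unit(s / axes)
    pt = lac.centroid_um + lac.rotation @ local_pt
    normal = _unit(lac.rotation @ local_n)
    return pt, normal


def generate_ground_truth(params: GeneratorParams) -> GroundTruth:
    """Draw a ground-truth LCN graph realizing the configured targets.

    See the module docstring for the construction.  Junction degrees are
    exact by construction: every drawn stub becomes either an edge to a
    partner junction or an edge to a terminal endpoint node.
    """
    params.validate()
    size = np.asarray(params.domain_size_um, float)
    volume = float(np.prod(size))
    master = np.random.default_rng(params.seed)
    streams = dict(zip(_SUBSTREAMS, master.spawn(len(_SUBSTREAMS))))
    plane_x = params.interface_plane_x_um

    lacunae = _place_lacunae(params, streams["lacunae"])
    jpos, jreg = _place_junctions(params, lacunae, streams["junctions"])
    n_j = len(jpos)
    degrees = _sample_degrees(streams["degrees"], n_j, params.degree_tail_beta)
    if n_j > 1:
        # assign the drawn degrees by local crowding: junctions with more
        # close neighbors take the higher degrees.  This keeps the marginal
        # degree law exact while letting every extra branch find a nearby
        # partner, and reproduces the positive spatial correlation between
        # node density and node degree seen in measured networks.
        crowd_tree = cKDTree(jpos)
        crowd = np.array(
            [len(v) for v in crowd_tree.query_ball_point(jpos, 3.0)]
        )
        rank = np.argsort(-crowd, kind="stable")
        degrees_sorted = np.sort(degrees)[::-1]
        assigned = np.empty_like(degrees)
        assigned[rank] = degrees_sorted
        degrees = assigned

    graph = LCNGraph()
    next_id = 0
    lac_node: dict[int, int] = {}
    for lac in lacunae:
        graph.add_node(
            next_id, lac.centroid_um, "lacuna", lacuna_id=lac.shape.lacuna_id
        )
        lac_node[lac.shape.lacuna_id] = next_id
        next_id += 1
    j_node = np.arange(next_id, next_id + n_j)
    for i in range(n_j):
        graph.add_node(int(j_node[i]), jpos[i], "junction")
    next_id += n_j

    # --- per-region length budgets -------------------------------------
    f = params.unordered_fraction
    gamma = params.unordered_density_factor
    denom = (1.0 - f) + f * gamma
    rho_can_ord = params.target_can_density / denom
    budgets = {
        REGION_ORDERED: rho_can_ord * (1.0 - f) * volume,
        REGION_UNORDERED: gamma * rho_can_ord * f * volume,
    }
    tortuosity = params.tortuosity_factor
    ell_bar = params.implied_edge_length_um
    axis = _unit(np.asarray(params.ordered_alignment_axis, float))
    cos_tol = math.cos(math.radians(params.alignment_half_angle_deg))
    geom_rng = streams["geometry"]
    match_rng = streams["matching"]

    # --- edge ends --------------------------------------------------------
    # Every drawn junction degree contributes that many "ends"; every lacuna
    # contributes one end per primary canaliculus (count = surface area /
    # area-per-canaliculus), anchored at a random surface point.  Ends are
    # paired into junction-junction / lacuna-junction edges by a
    # budget-aware greedy matching; leftover ends become endpoint-terminated
    # terminal branches.
    end_pos: list[np.ndarray] = []
    end_owner: list[int] = []  # graph node id
    end_is_lacuna: list[bool] = []
    end_normal: list[np.ndarray | None] = []
    for i in range(n_j):
        for _ in range(int(degrees[i])):
            end_pos.append(jpos[i])
            end_owner.append(int(j_node[i]))
            end_is_lacuna.append(False)
            end_normal.append(None)
    for lac in lacunae:
        area = ellipsoid_surface_area(*lac.shape.semi_axes_um)
        n_can = int(round(area / params.area_per_canaliculus_um2))
        lac.shape.degree = n_can
        for _ in range(n_can):
            pt, normal = _surface_point_and_normal(lac, geom_rng)
            end_pos.append(pt)
            end_owner.append(lac_node[lac.shape.lacuna_id])
            end_is_lacuna.append(True)
            end_normal.append(normal)
    n_ends = len(end_pos)
    end_pos_arr = np.asarray(end_pos).reshape(n_ends, 3) if n_ends else np.empty((0, 3))
    end_region = (
        _region_of_x(end_pos_arr[:, 0], f, size[0])
        if n_ends
        else np.empty(0, dtype=np.uint8)
    )

    # --- budget-aware greedy matching of ends -----------------------------
    # Candidate pairs within 2 L̄ are processed in order of an alignment-
    # penalized chord length (ordered-region chords off the alignment axis
    # are deprioritized).  A pair is accepted while the projected total —
    # matched arcs plus a minimum-length terminal branch for every still-
    # free end — stays within the region's length budget; short pairs are
    # always accepted because pairing two ends is cheaper than giving each
    # its own terminal branch.
    stub_min = max(2.0 * float(np.min(params.voxel_spacing_um)), 1.4)
    stub_max = 4.0 * ell_bar if np.isfinite(ell_bar) else 10.0
    pair_min = max(1.2, 0.95 * params.junction_min_separation_um)
    align_penalty = 1.5
    free = np.ones(n_ends, dtype=bool)
    arcs = {REGION_ORDERED: 0.0, REGION_UNORDERED: 0.0}
    n_free_region = {
        REGION_ORDERED: int(np.sum(end_region == REGION_ORDERED)),
        REGION_UNORDERED: int(np.sum(end_region == REGION_UNORDERED)),
    }
    matched: list[tuple[int, int]] = []  # end indices
    # budget-consistent target chord, assuming ~85% of ends pair and the
    # rest become minimum-length terminal branches
    total_budget = budgets[REGION_ORDERED] + budgets[REGION_UNORDERED]
    if n_ends:
        ell_target = (total_budget / tortuosity - 0.15 * n_ends * stub_min) / (
            0.85 * n_ends / 2.0
        )
        ell_target = max(ell_target, pair_min / 0.95)
    else:
        ell_target = ell_bar
    if n_ends > 1 and np.isfinite(ell_bar):
        r_max = 2.0 * ell_bar
        tree = cKDTree(end_pos_arr)
        cand = np.array(sorted(tree.query_pairs(r_max)))
        if len(cand):
            pvec = end_pos_arr[cand[:, 1]] - end_pos_arr[cand[:, 0]]
            chords = np.linalg.norm(pvec, axis=1)
            ok = chords >= pair_min
            owners = np.array(end_owner)
            ok &= owners[cand[:, 0]] != owners[cand[:, 1]]
            lac_flags = np.array(end_is_lacuna)
            ok &= ~(lac_flags[cand[:, 0]] & lac_flags[cand[:, 1]])
            cand, pvec, chords = cand[ok], pvec[ok], chords[ok]
            with np.errstate(invalid="ignore"):
                sin2 = 1.0 - (pvec @ axis) ** 2 / np.maximum(chords, 1e-12) ** 2
            both_ordered = (end_region[cand[:, 0]] == REGION_ORDERED) & (
                end_region[cand[:, 1]] == REGION_ORDERED
            )
            # shortest-first keeps total length near the budget; off-axis
            # ordered-region chords are deprioritized; lacuna links are
            # prioritized so primary canaliculi join the network rather
            # than dead-ending at the lacuna surface
            lac_pair = lac_flags[cand[:, 0]] | lac_flags[cand[:, 1]]
            key = chords * (
                1.0
                + np.where(
                    both_ordered, align_penalty * np.maximum(sin2, 0.0), 0.0
                )
            )
            key = np.where(lac_pair, 0.5 * key, key)
            order = np.argsort(key, kind="stable")
            connected_pairs: set[tuple[int, int]] = set()
            mid_region = _region_of_x(
                0.5 * (end_pos_arr[cand[:, 0], 0] + end_pos_arr[cand[:, 1], 0]),
                f,
                size[0],
            )
            for idx in order:
                a, b = int(cand[idx, 0]), int(cand[idx, 1])
                if not (free[a] and free[b]):
                    continue
                okey = (min(end_owner[a], end_owner[b]), max(end_owner[a], end_owner[b]))
                if okey in connected_pairs:
                    continue
                if _crosses_plane(end_pos_arr[a], end_pos_arr[b], plane_x):
                    continue
                region = int(mid_region[idx])
                chord = float(chords[idx])
                if chord > 2.0 * ell_target:
                    continue
                free[a] = free[b] = False
                n_free_region[int(end_region[a])] -= 1
                n_free_region[int(end_region[b])] -= 1
                arcs[region] += chord * tortuosity
                connected_pairs.add(okey)
                matched.append((a, b, region, chord, bool(lac_pair[idx])))

    # --- enforce the length budget by releasing the longest links ---------
    # Un-matching a junction-junction pair longer than two minimum terminal
    # branches lowers the projected total; release longest-first until each
    # region's projection fits its budget.  Lacuna links are kept.
    lacuna_stub_len = 3.0  # µm; primary canaliculi reach past the lacuna halo
    lac_flags_arr = np.array(end_is_lacuna) if n_ends else np.empty(0, bool)

    def _projected(region: int) -> float:
        n_lac_free = int(np.sum(free & (end_region == region) & lac_flags_arr))
        n_j_free = n_free_region[region] - n_lac_free
        return arcs[region] + tortuosity * (
            n_j_free * stub_min + n_lac_free * lacuna_stub_len
        )

    droppable = sorted(
        (m for m in matched if not m[4] and m[3] > 4.0 * stub_min),
        key=lambda m: -m[3],
    )
    dropped: set[tuple[int, int]] = set()
    for a, b, region, chord, _ in droppable:
        if _projected(region) <= budgets[region]:
            continue
        dropped.add((a, b))
        free[a] = free[b] = True
        n_free_region[int(end_region[a])] += 1
        n_free_region[int(end_region[b])] += 1
        arcs[region] -= chord * tortuosity
    matched = [m for m in matched if (m[0], m[1]) not in dropped]

    # --- terminal branch lengths from the remaining budget ----------------
    stub_len = {}
    for region in (REGION_ORDERED, REGION_UNORDERED):
        n_lac_free = int(np.sum(free & (end_region == region) & lac_flags_arr))
        n_j_stub = n_free_region[region] - n_lac_free
        remaining = max(
            0.0,
            budgets[region]
            - arcs[region]
            - n_lac_free * lacuna_stub_len * tortuosity,
        )
        stub_len[region] = (
            float(np.clip(remaining / (n_j_stub * tortuosity), stub_min, stub_max))
            if n_j_stub
            else 0.0
        )

    # --- build edge geometry --------------------------------------------
    margin = float(np.min(params.voxel_spacing_um))

    def clip_domain(path: np.ndarray) -> np.ndarray:
        return np.clip(path, margin, size - margin)

    for a, b, _, _, _ in matched:
        path = _tortuous_path(end_pos_arr[a], end_pos_arr[b], tortuosity, geom_rng)
        path = clip_domain(_clamp_to_side(path, plane_x))
        graph.add_edge(end_owner[a], end_owner[b], path)

    for a in np.nonzero(free)[0]:
        region = int(end_region[a])
        length = lacuna_stub_len if end_is_lacuna[a] else stub_len[region]
        if length <= 0:
            continue
        start = end_pos_arr[a]
        if end_is_lacuna[a]:
            d = _unit(end_normal[a] + 0.3 * _random_unit(geom_rng)[0])
        elif region == REGION_ORDERED:
            d = _cone_direction(geom_rng, axis, params.alignment_half_angle_deg)
        else:
            d = _random_unit(geom_rng)[0]
        end = start + d * length
        if plane_x is not None and _crosses_plane(start, end, plane_x):
            # truncate before the interface
            t_hit = (plane_x - start[0]) / (end[0] - start[0])
            end = start + d * max(0.3 * length, (t_hit * length) - 0.3)
        end = np.clip(end, margin, size - margin)
        path = _tortuous_path(start, end, tortuosity, geom_rng)
        path = clip_domain(_clamp_to_side(path, plane_x))
        graph.add_node(next_id, path[-1], "endpoint")
        graph.add_edge(end_owner[a], next_id, path)
        next_id += 1

    # --- region label field & bookkeeping --------------------------------
    spacing = np.asarray(params.voxel_spacing_um, float)
    shape = tuple(int(math.ceil(s / sp)) for s, sp in zip(size, spacing))
    x_centers = (np.arange(shape[0]) + 0.5) * spacing[0]
    col = _region_of_x(x_centers, f, size[0])
    region_field = np.broadcast_to(
        col[:, None, None], shape
    ).astype(np.uint8).copy()

    per_region: dict[str, dict[str, float]] = {}
    region_names = {REGION_ORDERED: "ordered", REGION_UNORDERED: "unordered"}
    edge_mid_region = {}
    for u, v, key, d in graph.g.edges(keys=True, data=True):
        mid = d["path"][len(d["path"]) // 2]
        edge_mid_region[(u, v, key)] = int(_region_of_x(np.array([mid[0]]), f, size[0])[0])
    for region, name in region_names.items():
        v_region = volume * ((1.0 - f) if region == REGION_ORDERED else f)
        if v_region <= 0:
            continue
        length = sum(
            d["length_um"]
            for (u, v, k), r in edge_mid_region.items()
            if r == region
            for d in [graph.g.edges[u, v, k]]
        )
        jn = int(np.sum(jreg == region))
        lacs = sum(
            1
            for lac in lacunae
            if _region_of_x(np.array([lac.centroid_um[0]]), f, size[0])[0] == region
        )
        degs = degrees[jreg == region]
        per_region[name] = {
            "can_dn": length / v_region,
            "nd_nr": (jn + lacs) / v_region,
            "nd_dg": float(np.mean(degs)) if len(degs) else float("nan"),
            "volume_um3": v_region,
        }

    realized = {
        "can_dn": graph.total_length_um() / volume,
        "nd_nr": (n_j + len(lacunae)) / volume,
        "nd_dg": float(np.mean(degrees)) if n_j else float("nan"),
        "n_junctions": float(n_j),
        "n_lacunae": float(len(lacunae)),
    }
    metadata = {
        "implied_mean_edge_length_um": params.implied_edge_length_um,
        "mean_degree_target": params.mean_degree,
        "stub_length_um": stub_len,
        "matched_pairs": len(matched),
    }
    return GroundTruth(
        graph=graph,
        lacunae=lacunae,
        region_label_field=region_field,
        interface_plane_x_um=plane_x,
        per_region_targets=per_region,
        realized=realized,
        params=params,
        seed=params.seed,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

MAX_VOXELS_DEFAULT = 256**3


def rasterize(
    truth: GroundTruth,
    params: GeneratorParams | None = None,
    max_voxels: int = MAX_VOXELS_DEFAULT,
) -> ImageStack:
    """Voxelize a ground truth into an intensity stack.

    Lacunae are filled by 3x-per-axis supersampled ellipsoid membership.
    Canaliculi (radius well below a voxel) deposit their line integral:
    a voxel crossed by length ``dL`` of tube receives intensity
    ``dL * pi r^2 / voxel_volume`` — the exact partial-volume fraction of a
    thin tube.  Voxel value is the maximum over structures, capped at 1.
    """
    params = params or truth.params
    spacing = np.asarray(params.voxel_spacing_um, float)
    size = np.asarray(params.domain_size_um, float)
    shape = tuple(int(math.ceil(s / sp)) for s, sp in zip(size, spacing))
    if int(np.prod(shape)) > max_voxels:
        raise MemoryError(
            f"rasterization grid {shape} exceeds the {max_voxels} voxel contract"
        )
    img = np.zeros(shape, dtype=np.float32)
    vox_vol = float(np.prod(spacing))

    # --- canaliculi ------------------------------------------------------
    r = params.canaliculus_radius_um
    tube_area = math.pi * r * r
    step = float(spacing.min()) / 4.0
    flat = img.ravel()
    for path in truth.graph.edge_paths():
        seglen = np.linalg.norm(np.diff(path, axis=0), axis=1)
        total = seglen.sum()
        if total <= 0:
            continue
        n = max(2, int(math.ceil(total / step)) + 1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        s = np.linspace(0.0, total, n)
        pts = np.column_stack(
            [np.interp(s, cum, path[:, k]) for k in range(3)]
        )
        mids = 0.5 * (pts[1:] + pts[:-1])
        dl = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        idx = np.floor(mids / spacing).astype(int)
        np.clip(idx, 0, np.asarray(shape) - 1, out=idx)
        lin = np.ravel_multi_index(tuple(idx.T), shape)
        np.add.at(flat, lin, (dl * tube_area / vox_vol).astype(np.float32))
    np.minimum(img, 1.0, out=img)

    # --- lacunae (3x supersampling) --------------------------------------
    sub = 3
    offs = (np.arange(sub) + 0.5) / sub  # sub-voxel fractions
    oi, oj, ok = np.meshgrid(offs, offs, offs, indexing="ij")
    sub_off = np.column_stack([oi.ravel(), oj.ravel(), ok.ravel()])  # (27, 3)
    for lac in truth.lacunae:
        a, b, c = lac.shape.semi_axes_um
        half = np.array([a, a, a])  # conservative bbox: rotated ellipsoid fits
        lo = np.maximum(np.floor((lac.centroid_um - half) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((lac.centroid_um + half) / spacing).astype(int),
            np.asarray(shape),
        )
        if np.any(lo >= hi):
            continue
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        corners = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        frac = np.zeros(len(corners), dtype=np.float32)
        inv_axes = 1.0 / np.array([a, b, c])
        for off in sub_off:
            pts = (corners + off) * spacing
            local = (pts - lac.centroid_um) @ lac.rotation
            frac += (np.sum((local * inv_axes) ** 2, axis=1) <= 1.0).astype(
                np.float32
            )
        frac /= len(sub_off)
        block = img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(block, frac.reshape(block.shape), out=block)

    return ImageStack(img, spacing)


def degrade(
    image: ImageStack, params: GeneratorParams, seed: int | None = None
) -> ImageStack:
    """Confocal-like degradation: anisotropic PSF blur, background, noise.

    The noise stream is derived from ``params.seed`` (or an explicit seed),
    so the same parameters give bit-identical output.
    """
    psf = np.asarray(params.psf_sigma_um, float)
    if np.any(psf < 0) or params.noise_sd < 0:
        raise ValueError("psf_sigma_um and noise_sd must be >= 0")
    out = image.values.astype(np.float32, copy=True)
    if np.any(psf > 0):
        sigma_vox = psf / image.voxel_spacing_um
        out = ndimage.gaussian_filter(out, sigma=sigma_vox).astype(np.float32)
    if params.background_gradient != 0.0:
        x = (np.arange(image.shape[0]) + 0.5) * image.voxel_spacing_um[0]
        out = out + (params.background_gradient * x)[:, None, None].astype(
            np.float32
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(
            [params.seed if seed is None else seed, 0xD5]
        )
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape).astype(
            np.float32
        )
    return ImageStack(out, image.voxel_spacing_um, image.origin_um)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSample:
    stack: ImageStack | None
    truth: GroundTruth
    labels: dict


def generate_cohort(
    presets: Sequence[StrainPreset],
    n_per_group: int,
    seed: int = 0,
    base_params: GeneratorParams | None = None,
    between_animal_cv: float = 0.03,
    render: bool = False,
) -> list[CohortSample]:
    """Paired-limb cohorts for each strain preset.

    Each synthetic animal draws one multiplicative jitter (CV
    ``between_animal_cv``) applied to its density targets; both limbs share
    those animal-level targets but use different realization seeds, so the
    between-animal spread of means is small compared to the within-stack
    spread — the variability structure seen in paired-limb mouse studies.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    base = base_params or GeneratorParams()
    master = np.random.default_rng(seed)
    samples: list[CohortSample] = []
    for preset in presets:
        for animal in range(n_per_group):
            jitter = float(
                np.clip(1.0 + between_animal_cv * master.normal(), 0.5, 1.5)
            )
            animal_params = preset.apply(base)
            animal_params = replace(
                animal_params,
                target_can_density=preset.target_can_density * jitter,
                target_node_density=preset.target_node_density * jitter,
                lacuna_mean_volume_um3=preset.lacuna_mean_volume_um3 * jitter,
            )
            for limb in ("right", "left"):
                limb_seed = int(master.integers(0, 2**31 - 1))
                p = replace(animal_params, seed=limb_seed)
                truth = generate_ground_truth(p)
                stack = None
                if render:
                    stack = degrade(rasterize(truth, p), p)
                samples.append(
                    CohortSample(
                        stack=stack,
                        truth=truth,
                        labels={
                            "strain": preset.name,
                            "animal": f"{preset.name}_{animal:02d}",
                            "limb": limb,
                            "loaded": limb == "left",
                            "seed": limb_seed,
                        },
                    )
                )
    return samples


# ---------------------------------------------------------------------------
# qBEI phantom
# ---------------------------------------------------------------------------


@dataclass
class QBEIPhantom:
    gray: np.ndarray  # uint8 (nx, ny)
    true_ca_wt: np.ndarray  # float (nx, ny)
    pixel_spacing_um: tuple[float, float]


def generate_qbei_phantom(
    truth: GroundTruth,
    low_ca: float,
    high_ca: float,
    curve=None,
    noise_gl_sd: float = 0.0,
    seed: int | None = None,
) -> QBEIPhantom:
    """Co-registered calcium-content map with a sharp interface.

    The Ca step is located at the truth's interface plane (where, by
    construction, the network is disrupted): ``x < plane`` maps to ``low_ca``
    and ``x >= plane`` to ``high_ca``, emulating later-deposited, higher
    mineralized bone.  Gray levels are the inverse of the qBEI calibration
    ``curve`` (default two-reference curve), so calibrating the phantom
    recovers the wt% Ca levels to within one gray-level quantum.
    """
    if not 0.0 <= low_ca < high_ca:
        raise ValueError("need 0 <= low_ca < high_ca")
    from .qbei import default_calibration

    curve = curve or default_calibration()
    params = truth.params
    spacing = np.asarray(params.voxel_spacing_um, float)
    size = np.asarray(params.domain_size_um, float)
    nx = int(math.ceil(size[0] / spacing[0]))
    ny = int(math.ceil(size[1] / spacing[1]))
    x = (np.arange(nx) + 0.5) * spacing[0]
    ca = np.full((nx, ny), low_ca, dtype=float)
    if truth.interface_plane_x_um is not None:
        ca[x >= truth.interface_plane_x_um, :] = high_ca
    gl = curve.gray_from_ca(ca)
    if noise_gl_sd > 0:
        rng = np.random.default_rng([truth.seed if seed is None else seed, 0xBE])
        gl = gl + rng.normal(0.0, noise_gl_sd, size=gl.shape)
    gray = np.clip(np.rint(gl), 0, 255).astype(np.uint8)
    return QBEIPhantom(
        gray=gray,
        true_ca_wt=ca,
        pixel_spacing_um=(float(spacing[0]), float(spacing[1])),
    )
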