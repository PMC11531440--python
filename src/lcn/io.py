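"""File formats: TIFF stacks with spacing sidecars, GraphML/CSV graphs,
region masks, YAML pipeline configuration and JSON run manifests.

Stacks are multi-page TIFFs with pages along z; in memory the axis order is
(x, y, z) (see :mod:`lcn.datatypes`).  Voxel spacing travels in a JSON
sidecar named ``<stack>.json`` next to the TIFF; a missing sidecar falls
back to ImageJ-style TIFF metadata and otherwise raises an error that names
the convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import ImageStack, LCNGraph
from .extract import ExtractionConfig
from .regions import RegionMask2D
from .synth import GeneratorParams

__all__ = [
    "read_stack",
    "write_stack",
    "read_graph",
    "write_graph",
    "read_region_mask",
    "write_region_mask",
    "PipelineConfig",
    "write_manifest",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, stack: ImageStack) -> Path:
    """Write a stack as multi-page TIFF (pages along z) plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.transpose(stack.values, (2, 1, 0)), photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "voxel_spacing_um": list(map(float, stack.voxel_spacing_um)),
                "origin_um": list(map(float, stack.origin_um)),
                "axes_in_memory": "xyz",
                "tiff_page_axis": "z",
            },
            indent=2,
        )
    )
    return path


def read_stack(path) -> ImageStack:
    """Read a multi-page TIFF stack and its spacing sidecar."""
    path = Path(path)
    values = tifffile.imread(path)
    if values.ndim == 2:
        raise ValueError(
            f"{path} is a single 2D image; a 3D multi-page TIFF stack is required"
        )
    if values.ndim != 3:
        raise ValueError(f"{path}: expected 3 dimensions, got {values.ndim}")
    sidecar = _sidecar_path(path)
    origin = np.zeros(3)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = np.asarray(meta["voxel_spacing_um"], float)
        origin = np.asarray(meta.get("origin_um", [0, 0, 0]), float)
    else:
        spacing = _spacing_from_tiff_tags(path)
        if spacing is None:
            raise ValueError(
                f"no voxel spacing for {path}: provide a JSON sidecar "
                f"'{sidecar.name}' with key 'voxel_spacing_um' ([sx, sy, sz] in µm)"
            )
    return ImageStack(np.transpose(values, (2, 1, 0)), spacing, origin)


def _spacing_from_tiff_tags(path: Path) -> np.ndarray | None:
    """Best-effort spacing from ImageJ metadata / resolution tags (µm)."""
    try:
        with tifffile.TiffFile(path) as tf:
            ij = tf.imagej_metadata or {}
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if xres and yres and "spacing" in ij:
                sx = xres.value[1] / xres.value[0]
                sy = yres.value[1] / yres.value[0]
                return np.array([sx, sy, float(ij["spacing"])])
    except Exception:
        return None
    return None


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

_PATH_FMT = "%.7f"


def _path_to_wkt(path: np.ndarray) -> str:
    pts = ", ".join(
        " ".join(_PATH_FMT % c for c in p) for p in np.asarray(path, float)
    )
    return f"LINESTRING Z ({pts})"


def _path_from_wkt(s: str) -> np.ndarray:
    inner = s[s.index("(") + 1 : s.rindex(")")]
    return np.array(
        [[float(c) for c in p.split()] for p in inner.split(",")], dtype=float
    )


def write_graph(path, graph: LCNGraph, csv: bool = True) -> Path:
    """Write a graph as GraphML; optionally paired nodes.csv/edges.csv."""
    path = Path(path)
    g = nx.MultiGraph()
    for n, d in graph.g.nodes(data=True):
        attrs = {
            "x_um": float(d["pos"][0]),
            "y_um": float(d["pos"][1]),
            "z_um": float(d["pos"][2]),
            "kind": d["kind"],
        }
        if "lacuna_id" in d:
            attrs["lacuna_id"] = int(d["lacuna_id"])
        g.add_node(n, **attrs)
    for u, v, k, d in graph.g.edges(keys=True, data=True):
        g.add_edge(
            u,
            v,
            key=k,
            length_um=float(d["length_um"]),
            path_wkt=_path_to_wkt(d["path"]),
        )
    nx.write_graphml(g, path)
    if csv:
        nodes = pd.DataFrame(
            [
                {
                    "id": n,
                    "x_um": d["x_um"],
                    "y_um": d["y_um"],
                    "z_um": d["z_um"],
                    "kind": d["kind"],
                    "degree": g.degree(n),
                    "lacuna_id": d.get("lacuna_id", ""),
                }
                for n, d in g.nodes(data=True)
            ]
        )
        edges = pd.DataFrame(
            [
                {
                    "source": u,
                    "target": v,
                    "key": k,
                    "length_um": d["length_um"],
                    "path": d["path_wkt"],
                }
                for u, v, k, d in g.edges(keys=True, data=True)
            ]
        )
        nodes.to_csv(path.with_suffix(".nodes.csv"), index=False)
        edges.to_csv(path.with_suffix(".edges.csv"), index=False)
    return path


def read_graph(path) -> LCNGraph:
    """Read a graph written by :func:`write_graph` (GraphML)."""
    path = Path(path)
    g = nx.read_graphml(path, node_type=int, force_multigraph=True)
    out = LCNGraph()
    for n, d in g.nodes(data=True):
        extra = {}
        if "lacuna_id" in d and d["lacuna_id"] != "":
            extra["lacuna_id"] = int(d["lacuna_id"])
        out.add_node(
            int(n), [d["x_um"], d["y_um"], d["z_um"]], d["kind"], **extra
        )
    for u, v, k, d in g.edges(keys=True, data=True):
        if int(u) not in out.g.nodes or int(v) not in out.g.nodes:
            raise ValueError(f"edge ({u}, {v}) references a missing node")
        out.add_edge(int(u), int(v), _path_from_wkt(d["path_wkt"]))
    return out


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------


def write_region_mask(path, mask: RegionMask2D) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.transpose(mask.labels.astype(np.uint8)), photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "legend": {"0": "outside", "1": "ordered", "2": "unordered"},
                "pixel_spacing_um": list(map(float, mask.pixel_spacing_um)),
                "provenance": mask.provenance,
                "axes_in_memory": "xy",
            },
            indent=2,
        )
    )
    return path


def read_region_mask(path) -> RegionMask2D:
    path = Path(path)
    labels = np.transpose(np.asarray(tifffile.imread(path)))
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"region mask {path} needs a sidecar '{sidecar.name}' with "
            "'pixel_spacing_um'"
        )
    meta = json.loads(sidecar.read_text())
    return RegionMask2D(
        labels=labels.astype(np.int64),
        pixel_spacing_um=tuple(meta["pixel_spacing_um"]),
        provenance=meta.get("provenance", "file"),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All stage parameters plus the global seed, YAML round-trippable."""

    generator: GeneratorParams = field(default_factory=GeneratorParams)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    subvolume_um3: float = 400.0
    qbei_gl_carbon: float = 25.0
    qbei_gl_aluminum: float = 225.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # plain types only

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, sub_cls in (("generator", GeneratorParams), ("extraction", ExtractionConfig)):
            if name in data and isinstance(data[name], dict):
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(data[name]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown {name} config keys: {sorted(sub_unknown)}"
                    )
                kwargs = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in data[name].items()
                }
                data[name] = sub_cls(**kwargs)
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, params: dict, outputs: list) -> Path:
    """Machine-readable record of one CLI run: command, params, checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "params": params,
        "outputs": [
            {"path": str(Path(p).name), "sha256": _sha256(Path(p))}
            for p in outputs
            if Path(p).exists()
        ],
    }
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
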