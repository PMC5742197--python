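"""Synthetic whole-brain vascular phantoms with full ground truth.

The phantom emulates the statistical structure of modified-Nissl MOST stacks:
stained tissue is mid-gray, unstained vessel lumina and the resin outside the
brain are bright, pial vessels run on the brain surface and carve concave
dents into the contour, penetrating trees dive inward from pial attachment
points with tapering radii, and a capillary mesh of short tubes links tree
terminals.  Everything the pipeline later estimates — brain mask, vessel
mask, per-vessel labels, region labels, and the centerline ground-truth
graph — is returned exactly.

Geometry is procedural: a superellipsoid brain, random surface-following pial
paths, recursive binary branching for penetrating trees, and straight
terminal-to-terminal capillaries.  The same parameters (including the seed)
always produce a bit-identical scene.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import graph as vgraph
from .stack import BinaryVolume, ImageStack, LabelVolume, read_volume, write_volume
from .graph import TYPE_ARTERY, TYPE_CAPILLARY, TYPE_VEIN, VesselGraph


class PhantomError(ValueError):
    """Invalid phantom parameters (e.g. volume too small for any vessel)."""


@dataclass
class PhantomParams:
    """Generation parameters.

    Intensities follow the observed contrast: tissue mean 117 gray levels,
    lumina (and background resin, both unstained) offset +40 by default, an
    optional darker 1-voxel wall shell, Gaussian noise clipped to [0, 255] and
    quantized to 8 bits.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_um: tuple[float, float, float] = (5.0, 5.0, 5.0)
    tissue_mean: float = 117.0
    tissue_sd: float = 8.0
    lumen_offset: float = 40.0
    wall_offset: float | None = None
    n_pial_vessels: int = 2
    n_penetrating_trees: int = 3
    branching_depth: int = 3
    radius_range_um: tuple[float, float] = (3.0, 25.0)
    capillary_density_target: float = 500.0  # capillary centerline mm per mm^3 tissue
    n_regions: int = 5
    brain_geometry: str = "superellipsoid"  # or "full": a tissue cube with no surface
    seed: int = 0

    def __post_init__(self) -> None:
        if self.brain_geometry not in ("superellipsoid", "full"):
            raise PhantomError("brain_geometry must be 'superellipsoid' or 'full'")
        if self.brain_geometry == "full" and self.n_pial_vessels > 0:
            raise PhantomError("a full-tissue cube has no surface for pial vessels")
        self.shape = tuple(int(s) for s in self.shape)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if any(s < 1 for s in self.shape):
            raise PhantomError("shape dims must be >= 1")
        if any(v <= 0 for v in self.voxel_size_um):
            raise PhantomError("voxel sizes must be > 0")
        for name in ("n_pial_vessels", "n_penetrating_trees", "branching_depth", "n_regions"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be >= 0")
        if self.capillary_density_target < 0:
            raise PhantomError("capillary_density_target must be >= 0")
        if self.radius_range_um[0] <= 0 or self.radius_range_um[1] < self.radius_range_um[0]:
            raise PhantomError("radius_range_um must satisfy 0 < min <= max")


@dataclass
class PhantomScene:
    intensity: ImageStack
    brain_mask: BinaryVolume
    vessel_mask: BinaryVolume
    vessel_labels: LabelVolume
    region_labels: LabelVolume
    truth_graph: VesselGraph
    params: PhantomParams
    pial_mask: BinaryVolume | None = None


# ---------------------------------------------------------------------------
# Superellipsoid brain
# ---------------------------------------------------------------------------

_SE_EXP = 2.5


def _brain_field(shape, voxel_size_um):
    """Superellipsoid implicit field F(p) (inside where F <= 1), plus center/axes (um)."""
    vs = np.asarray(voxel_size_um, dtype=float)
    extent = (np.asarray(shape) - 1) * vs
    center = extent / 2.0
    axes = 0.42 * np.maximum(extent, 1e-6)
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * vs[0],
        np.arange(shape[1]) * vs[1],
        np.arange(shape[2]) * vs[2],
        indexing="ij",
    )
    f = (
        (np.abs(zz - center[0]) / axes[0]) ** _SE_EXP
        + (np.abs(yy - center[1]) / axes[1]) ** _SE_EXP
        + (np.abs(xx - center[2]) / axes[2]) ** _SE_EXP
    )
    return f, center, axes


def _surface_project(p, center, axes):
    d = p - center
    val = float(np.sum((np.abs(d) / axes) ** _SE_EXP))
    if val <= 0:
        return center + axes * np.array([1.0, 0.0, 0.0])
    return center + d * val ** (-1.0 / _SE_EXP)


def _inside(p, center, axes):
    return float(np.sum((np.abs(p - center) / axes) ** _SE_EXP)) <= 1.0


# ---------------------------------------------------------------------------
# Graph assembly helpers (builds node arrays component by component)
# ---------------------------------------------------------------------------


class _GraphBuilder:
    def __init__(self):
        self.rows = []  # (id, type, x, y, z, radius, parent)
        self.labels = []  # per-node vessel label
        self.next_id = 1

    def add_node(self, p_zyx_um, radius_um, type_code, label, parent_id=-1):
        nid = self.next_id
        self.next_id += 1
        z, y, x = (float(v) for v in p_zyx_um)
        self.rows.append((nid, type_code, x, y, z, float(radius_um), parent_id))
        self.labels.append(label)
        return nid

    def build(self) -> tuple[VesselGraph, np.ndarray]:
        if not self.rows:
            return VesselGraph.empty(), np.zeros(0, dtype=np.int64)
        arr = np.asarray(self.rows, dtype=float)
        g = VesselGraph(
            ids=arr[:, 0].astype(np.int64),
            type_code=arr[:, 1].astype(np.int64),
            x=arr[:, 2],
            y=arr[:, 3],
            z=arr[:, 4],
            radius=arr[:, 5],
            parent=arr[:, 6].astype(np.int64),
        )
        return g, np.asarray(self.labels, dtype=np.int64)


def _unit(v, rng):
    n = np.linalg.norm(v)
    if n < 1e-9:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def make_phantom(params: PhantomParams) -> PhantomScene:
    """Generate a complete seeded phantom scene (deterministic per params)."""
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(params.voxel_size_um, dtype=float)
    shape = params.shape
    field_, center, axes = _brain_field(shape, params.voxel_size_um)
    if params.brain_geometry == "full":
        # a microvessel-style cube sampled from inside a brain region:
        # all tissue, no surface
        brain0 = np.ones(shape, dtype=bool)
        axes = 0.49 * (np.asarray(shape) - 1) * vs
    else:
        brain0 = field_ <= 1.0

    r_min, r_max = params.radius_range_um
    any_vessels = (
        params.n_pial_vessels > 0
        or params.n_penetrating_trees > 0
        or params.capillary_density_target > 0
    )
    if any_vessels and float(axes.min()) <= r_min:
        raise PhantomError(
            f"volume too small: min brain semi-axis {axes.min():.1f} um cannot contain "
            f"a vessel of minimum radius {r_min:.1f} um"
        )

    gb = _GraphBuilder()
    label_names: dict[int, str] = {}
    next_label = 1
    step_len = 2.0 * float(vs.max())
    # Interior vessels stay clear of the pial dent zone (pial tubes are bright
    # like the outside background, so a penetrating lumen touching one would
    # merge with the background under a global threshold).
    margin_um = 2.0 * r_max + 2.0 * float(vs.max())
    axes_inner = np.maximum(axes - margin_um, 0.25 * axes)

    # --- pial surface vessels (alternating artery/vein), radius near r_max ---
    pial_node_count_before = 0
    for i in range(params.n_pial_vessels):
        label = next_label
        next_label += 1
        kind = TYPE_ARTERY if i % 2 == 0 else TYPE_VEIN
        label_names[label] = f"pial_{'artery' if kind == TYPE_ARTERY else 'vein'}_{i + 1}"
        r = float(rng.uniform(0.7, 1.0) * r_max)
        p = _surface_project(center + _unit(rng.normal(size=3), rng) * axes, center, axes)
        direction = _unit(rng.normal(size=3), rng)
        n_steps = max(3, int(0.9 * float(axes.min()) / step_len))
        parent = gb.add_node(p, r, kind, label)
        for _ in range(n_steps):
            direction = _unit(direction + 0.3 * rng.normal(size=3), rng)
            q = _surface_project(p + direction * step_len, center, axes)
            direction = _unit(q - p, rng)
            p = q
            parent = gb.add_node(p, r, kind, label, parent)

    # --- penetrating trees ---
    terminals: list[np.ndarray] = []
    for i in range(params.n_penetrating_trees):
        label = next_label
        next_label += 1
        kind = TYPE_ARTERY if i % 2 == 0 else TYPE_VEIN
        label_names[label] = f"tree_{'artery' if kind == TYPE_ARTERY else 'vein'}_{i + 1}"
        p = _surface_project(center + _unit(rng.normal(size=3), rng) * axes, center, axes)
        r0 = float(rng.uniform(0.5, 0.8) * r_max)
        seg_len = 0.45 * float(axes_inner.min())
        # attach below the pial zone so the trunk lumen never touches the
        # bright outside-brain background or a pial lumen
        p = _surface_project(p, center, axes_inner)
        root = gb.add_node(p, r0, kind, label)

        stack = [(p, _unit(center - p, rng), r0, seg_len, root, 0)]
        while stack:
            p0, d0, r, L, parent, depth = stack.pop()
            n_sub = max(2, int(L / step_len))
            cur = p0
            cur_parent = parent
            for s in range(1, n_sub + 1):
                d0 = _unit(d0 + 0.15 * rng.normal(size=3), rng)
                q = cur + d0 * (L / n_sub)
                # confine so the tube surface stays clear of the pial zone
                if not _inside(q, center, 0.95 * axes_inner):
                    q = center + (q - center) * 0.85
                    d0 = _unit(q - cur, rng)
                rr = r * (1.0 - 0.3 * s / n_sub)
                cur_parent = gb.add_node(q, rr, kind, label, cur_parent)
                cur = q
            if depth + 1 < params.branching_depth:
                for _ in range(2):
                    child_dir = _unit(d0 + 0.8 * rng.normal(size=3), rng)
                    stack.append(
                        (cur, child_dir, 0.7 * rr, 0.7 * L, cur_parent, depth + 1)
                    )
            else:
                terminals.append(cur)

    # --- capillary mesh: short tubes between / near tree terminals ---
    cap_label = 0
    if params.capillary_density_target > 0:
        cap_label = next_label
        next_label += 1
        label_names[cap_label] = "capillaries"
        brain_vol_mm3 = float(brain0.sum()) * float(np.prod(vs)) * 1e-9
        target_len_um = params.capillary_density_target * brain_vol_mm3 * 1e3  # mm -> um
        total = 0.0
        attempts = 0
        max_attempts = 100000
        while total < target_len_um and attempts < max_attempts:
            attempts += 1
            if terminals and rng.random() < 0.5:
                a = terminals[int(rng.integers(len(terminals)))]
            else:
                a = center + rng.uniform(-0.7, 0.7, size=3) * axes
            b = a + _unit(rng.normal(size=3), rng) * rng.uniform(20.0, 80.0)
            if not (_inside(a, center, axes_inner) and _inside(b, center, axes_inner)):
                continue
            rc = float(rng.uniform(max(1.0, 0.5 * r_min), min(4.0, max(r_min, 2.0))))
            n0 = gb.add_node(a, rc, TYPE_CAPILLARY, cap_label)
            gb.add_node(b, rc, TYPE_CAPILLARY, cap_label, n0)
            total += float(np.linalg.norm(b - a))

    truth_graph, node_labels = gb.build()

    # --- rasterize per label -------------------------------------------------
    vessel_labels = np.zeros(shape, dtype=np.uint16)
    pial_mask = np.zeros(shape, dtype=bool)
    vessel_mask = np.zeros(shape, dtype=bool)
    for label in sorted(label_names):
        sel = node_labels == label
        if not sel.any():
            continue
        sub = _subgraph_by_nodes(truth_graph, sel)
        m = vgraph.render_tubes(sub, shape, params.voxel_size_um)
        is_pial = label_names[label].startswith("pial")
        if is_pial:
            pial_mask |= m
        else:
            m &= brain0 | pial_mask  # penetrating vessels live inside the brain
        vessel_labels[m & (vessel_labels == 0)] = label
        vessel_mask |= m

    brain_mask = brain0 & ~pial_mask  # pial tubes carve exact surface dents

    # --- region labels: Voronoi cells of random interior seeds ---------------
    region_labels = np.zeros(shape, dtype=np.uint16)
    if params.n_regions > 0 and brain_mask.any():
        seeds = []
        while len(seeds) < params.n_regions:
            cand = center + rng.uniform(-0.8, 0.8, size=3) * axes
            if _inside(cand, center, axes):
                seeds.append(cand)
        seeds = np.asarray(seeds)
        zz, yy, xx = np.meshgrid(
            np.arange(shape[0]) * vs[0],
            np.arange(shape[1]) * vs[1],
            np.arange(shape[2]) * vs[2],
            indexing="ij",
        )
        best_d = np.full(shape, np.inf)
        best_i = np.zeros(shape, dtype=np.uint16)
        for i, s in enumerate(seeds, start=1):
            d2 = (zz - s[0]) ** 2 + (yy - s[1]) ** 2 + (xx - s[2]) ** 2
            better = d2 < best_d
            best_d[better] = d2[better]
            best_i[better] = i
        region_labels = np.where(brain_mask & ~vessel_mask, best_i, 0).astype(np.uint16)

    # --- intensities ----------------------------------------------------------
    tissue = brain_mask & ~vessel_mask
    base = np.where(tissue, params.tissue_mean, params.tissue_mean + params.lumen_offset)
    if params.wall_offset is not None:
        from . import _morph

        shell = _morph.dilate(vessel_mask, 1.0) & tissue
        base = np.where(shell, params.tissue_mean + params.wall_offset, base)
    noise = rng.normal(0.0, params.tissue_sd, size=shape) if params.tissue_sd > 0 else 0.0
    intensity = np.clip(np.rint(base + noise), 0, 255).astype(np.uint8)

    vs_t = params.voxel_size_um
    return PhantomScene(
        intensity=ImageStack(intensity, vs_t),
        brain_mask=BinaryVolume(brain_mask, vs_t, "brain_mask"),
        vessel_mask=BinaryVolume(vessel_mask, vs_t, "vessel_mask"),
        vessel_labels=LabelVolume(vessel_labels, vs_t, names=label_names),
        region_labels=LabelVolume(region_labels, vs_t),
        truth_graph=truth_graph,
        params=params,
        pial_mask=BinaryVolume(pial_mask, vs_t, "vessel_mask"),
    )


def _subgraph_by_nodes(g: VesselGraph, sel: np.ndarray) -> VesselGraph:
    """Node-subset subgraph keeping original ids (parents outside become -1)."""
    keep_ids = set(int(i) for i in g.ids[sel])
    parent = np.where(
        np.isin(g.parent, list(keep_ids)), g.parent, -1
    )
    return VesselGraph(
        g.ids[sel],
        g.type_code[sel],
        g.x[sel],
        g.y[sel],
        g.z[sel],
        g.radius[sel],
        parent[sel],
        [e for e in g.loop_edges if e[0] in keep_ids and e[1] in keep_ids],
    )


# ---------------------------------------------------------------------------
# Disk round trip
# ---------------------------------------------------------------------------

_FILES = {
    "intensity": "intensity.tif",
    "brain_mask": "brain_mask.tif",
    "vessel_mask": "vessel_mask.tif",
    "pial_mask": "pial_mask.tif",
    "vessel_labels": "vessel_labels.tif",
    "region_labels": "region_labels.tif",
    "truth_swc": "truth.swc",
    "manifest": "manifest.json",
}


def scene_to_disk(scene: PhantomScene, directory) -> dict:
    """Write TIFF stacks, the ground-truth SWC, and a JSON manifest.

    Reading the directory back reproduces every array bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(scene.intensity.voxels, directory / _FILES["intensity"])
    write_volume(scene.brain_mask.voxels, directory / _FILES["brain_mask"])
    write_volume(scene.vessel_mask.voxels, directory / _FILES["vessel_mask"])
    if scene.pial_mask is not None:
        write_volume(scene.pial_mask.voxels, directory / _FILES["pial_mask"])
    write_volume(scene.vessel_labels.voxels.astype(np.uint16), directory / _FILES["vessel_labels"])
    write_volume(scene.region_labels.voxels.astype(np.uint16), directory / _FILES["region_labels"])
    vgraph.write_swc(scene.truth_graph, directory / _FILES["truth_swc"])
    p = asdict(scene.params)
    p["wall_offset"] = scene.params.wall_offset
    manifest = {
        "params": p,
        "seed": scene.params.seed,
        "shape": list(scene.params.shape),
        "voxel_size_um": list(scene.params.voxel_size_um),
        "label_names": {str(k): v for k, v in scene.vessel_labels.names.items()},
        "files": dict(_FILES),
    }
    with open(directory / _FILES["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def scene_from_disk(directory) -> PhantomScene:
    directory = Path(directory)
    with open(directory / _FILES["manifest"]) as fh:
        manifest = json.load(fh)
    pdict = manifest["params"]
    pdict["shape"] = tuple(pdict["shape"])
    pdict["voxel_size_um"] = tuple(pdict["voxel_size_um"])
    pdict["radius_range_um"] = tuple(pdict["radius_range_um"])
    params = PhantomParams(**pdict)
    vs = params.voxel_size_um
    names = {int(k): v for k, v in manifest["label_names"].items()}
    pial_path = directory / _FILES["pial_mask"]
    return PhantomScene(
        intensity=ImageStack(read_volume(directory / _FILES["intensity"]), vs),
        brain_mask=BinaryVolume(read_volume(directory / _FILES["brain_mask"]) > 0, vs, "brain_mask"),
        vessel_mask=BinaryVolume(read_volume(directory / _FILES["vessel_mask"]) > 0, vs, "vessel_mask"),
        vessel_labels=LabelVolume(
            read_volume(directory / _FILES["vessel_labels"]).astype(np.uint16), vs, names=names
        ),
        region_labels=LabelVolume(
            read_volume(directory / _FILES["region_labels"]).astype(np.uint16), vs
        ),
        truth_graph=vgraph.read_swc(directory / _FILES["truth_swc"]),
        params=params,
        pial_mask=BinaryVolume(read_volume(pial_path) > 0, vs, "vessel_mask")
        if pial_path.exists()
        else None,
    )
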