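"""Vascular statistics: tracing validation, density, distribution, branch levels.

Quantities produced here:

* **R/P/D validation** — traced centerlines are rendered back to the raster
  grid and compared to a ground-truth mask on slices sampled every 70 um:
  R = B/B1 (recall over ground-truth regions), P = B/B2 (precision over traced
  regions), D = A1/A2 (traced over true cross-sectional area).
* **Fv** — fractional vascular volume: vessel voxels / region voxels, per
  diameter bin (D <= 8, 8 < D <= 20, D > 20 um).
* **Nl** — normalized vascular length in mm of centerline per mm^3 of tissue,
  per diameter bin; loop-closing edges are counted exactly once.
* **Shrinkage correction** — resin embedding shrinks the specimen linearly by
  s = 25.9 +/- 1.6 %; corrected lengths scale by 1/(1-s), volumes by 1/(1-s)^3,
  hence Nl_corr = Nl_raw (1-s)^2 while Fv is shrinkage-invariant.
* **Distribution matrices** — per-vessel volume proportions across labeled
  brain regions (rows sum to 1 including an "unassigned" column); pial
  branches without segmented lumina are rasterized at the literature radii
  (artery 150 um, vein 250 um).
* **Branch levels** — branch counts at three diameter levels
  (D > 90, 40 < D <= 90, D <= 40 um), split by hemisphere.
* **Region comparison** — one-way ANOVA across regions, computed from
  between/within mean squares, with a pairwise p-value grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .graph import TYPE_ARTERY, TYPE_VEIN, VesselGraph, render_tubes
from .stack import BinaryVolume, LabelVolume


# ---------------------------------------------------------------------------
# Bins and cutoffs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiameterBins:
    """Diameter groups: small D <= 8 um (capillaries), medium 8-20, large > 20."""

    small_max_um: float = 8.0
    medium_max_um: float = 20.0

    BIN_NAMES = ("small", "medium", "large")

    def assign(self, diameter_um) -> np.ndarray:
        d = np.asarray(diameter_um, dtype=float)
        out = np.where(d <= self.small_max_um, 0, np.where(d <= self.medium_max_um, 1, 2))
        return out

    def name(self, idx: int) -> str:
        return self.BIN_NAMES[idx]


@dataclass(frozen=True)
class LevelCutoffs:
    """Branch levels: 1st D > 90 um, 2nd 40 < D <= 90 um, 3rd D <= 40 um."""

    level1_min_um: float = 90.0
    level2_min_um: float = 40.0

    def __post_init__(self) -> None:
        if not self.level1_min_um > self.level2_min_um > 0:
            raise ValueError("cutoffs must be decreasing and positive")

    def assign(self, diameter_um: float) -> int:
        if diameter_um > self.level1_min_um:
            return 1
        if diameter_um > self.level2_min_um:
            return 2
        return 3


DEFAULT_PIAL_RADII_UM = {"artery": 150.0, "vein": 250.0}


# ---------------------------------------------------------------------------
# R / P / D validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    per_slice: pd.DataFrame  # z, B, B1, B2, A1, A2, R, P, D
    pooled_recall: float
    pooled_precision: float
    pooled_diameter_ratio: float
    mean_diameter_ratio: float
    sampling_interval_um: float
    mode: str


def validate_tracing(
    traced,
    truth: BinaryVolume,
    interval_um: float = 70.0,
    mode: str = "region",
) -> ValidationReport:
    """Compare a tracing (graph or mask) against a ground-truth mask.

    ``traced`` may be a :class:`VesselGraph` (rendered back to the truth grid
    as tapered tubes) or a mask on the same grid.  On every sampled slice,
    B1/B2 are the ground-truth/traced totals, B the overlapped count, and
    A1/A2 the traced/true areas.  In ``region`` mode (default) counting is
    over connected 2D regions — B for recall is the number of truth regions
    the tracing touches, and for precision the number of traced regions that
    touch the truth; in ``voxel`` mode counts are voxel-wise.
    """
    if mode not in ("region", "voxel"):
        raise ValueError("mode must be 'region' or 'voxel'")
    if isinstance(traced, VesselGraph):
        traced_mask = render_tubes(traced, truth.shape, truth.voxel_size_um)
    elif isinstance(traced, BinaryVolume):
        traced_mask = traced.voxels
    else:
        traced_mask = np.asarray(traced, dtype=bool)
    t_mask = truth.voxels
    if traced_mask.shape != t_mask.shape:
        raise ValueError("traced and truth grids differ")
    dz = truth.voxel_size_um[0]
    step = max(1, int(round(interval_um / dz)))
    zs = list(range(0, t_mask.shape[0], step))
    if not any(t_mask[z].any() for z in zs):
        raise ValueError("ground truth empty on every sampled slice")

    rows = []
    sB = sB1 = sB2 = sBp = 0
    sA1 = sA2 = 0
    s8 = ndimage.generate_binary_structure(2, 2)
    for z in zs:
        tr, gt = traced_mask[z], t_mask[z]
        A1, A2 = int(tr.sum()), int(gt.sum())
        if mode == "voxel":
            B = int(np.count_nonzero(tr & gt))
            B1, B2, Bp = A2, A1, B
        else:
            lab_t, n_t = ndimage.label(gt, structure=s8)
            lab_p, n_p = ndimage.label(tr, structure=s8)
            hit_t = np.unique(lab_t[tr & gt])
            hit_p = np.unique(lab_p[tr & gt])
            B = int(np.count_nonzero(hit_t))
            Bp = int(np.count_nonzero(hit_p))
            B1, B2 = n_t, n_p
        R = B / B1 if B1 else np.nan
        P = Bp / B2 if B2 else np.nan
        D = A1 / A2 if A2 else np.nan
        rows.append((z, B, B1, B2, A1, A2, R, P, D))
        sB += B
        sBp += Bp
        sB1 += B1
        sB2 += B2
        sA1 += A1
        sA2 += A2
    df = pd.DataFrame(rows, columns=["z", "B", "B1", "B2", "A1", "A2", "R", "P", "D"])
    return ValidationReport(
        per_slice=df,
        pooled_recall=sB / sB1 if sB1 else np.nan,
        pooled_precision=sBp / sB2 if sB2 else np.nan,
        pooled_diameter_ratio=sA1 / sA2 if sA2 else np.nan,
        mean_diameter_ratio=float(df["D"].dropna().mean()) if df["D"].notna().any() else np.nan,
        sampling_interval_um=interval_um,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Fv / Nl
# ---------------------------------------------------------------------------


def _bin_masks(graph: VesselGraph, shape, voxel_size_um, bins: DiameterBins):
    """Rasterize a graph per diameter bin (segment bin = mean endpoint diameter)."""
    masks = []
    for b in range(3):
        m = render_tubes(
            graph,
            shape,
            voxel_size_um,
            segment_filter=lambda i, j, L, d, b=b: bins.assign(d) == b,
        )
        masks.append(m)
    return masks


def fractional_volume(
    vessels,
    bins: DiameterBins | None = None,
    roi=None,
    shape=None,
    voxel_size_um=None,
) -> dict[str, float]:
    """Fractional vascular volume Fv per diameter bin (plus ``total``).

    ``vessels`` is a :class:`VesselGraph` (rasterized as tapered tubes, one
    raster per bin) or a :class:`BinaryVolume` (no diameters: all volume is
    reported under ``total`` only).  ``roi`` is a mask restricting the tissue
    volume; by default the whole grid counts as tissue.
    """
    bins = bins or DiameterBins()
    if isinstance(vessels, VesselGraph):
        if shape is None or voxel_size_um is None:
            raise ValueError("graph input needs shape and voxel_size_um")
        bin_masks = _bin_masks(vessels, shape, voxel_size_um, bins)
        total_mask = np.zeros(shape, dtype=bool)
        for m in bin_masks:
            total_mask |= m
    else:
        vol = vessels.voxels if isinstance(vessels, BinaryVolume) else np.asarray(vessels, bool)
        bin_masks = None
        total_mask = vol
        shape = vol.shape
    if roi is None:
        roi_mask = np.ones(shape, dtype=bool)
    elif isinstance(roi, (BinaryVolume, LabelVolume)):
        roi_mask = roi.voxels.astype(bool)
    else:
        roi_mask = np.asarray(roi).astype(bool)
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    out = {"total": float(np.count_nonzero(total_mask & roi_mask)) / n_roi}
    if bin_masks is not None:
        # partition: a voxel belongs to the largest-diameter bin that claims it
        claimed = np.zeros(shape, dtype=bool)
        for b in (2, 1, 0):
            m = bin_masks[b] & ~claimed
            out[bins.name(b)] = float(np.count_nonzero(m & roi_mask)) / n_roi
            claimed |= bin_masks[b]
        out["total"] = float(np.count_nonzero(claimed & roi_mask)) / n_roi
    return out


def normalized_length(
    graph: VesselGraph, bins: DiameterBins | None = None, roi_volume_mm3: float = 1.0
) -> dict[str, float]:
    """Normalized vascular length Nl (mm of centerline per mm^3), per bin.

    Segment bin = mean of its endpoint diameters; loop-closing edges are
    counted exactly once (they appear once in the segment table).
    """
    bins = bins or DiameterBins()
    if roi_volume_mm3 <= 0:
        raise ValueError("roi_volume_mm3 must be > 0")
    out = {name: 0.0 for name in bins.BIN_NAMES}
    seg = graph.segment_table()
    if seg.size:
        b = bins.assign(seg[:, 3])
        for k, name in enumerate(bins.BIN_NAMES):
            out[name] = float(seg[b == k, 2].sum()) / 1000.0 / roi_volume_mm3
    out["total"] = sum(out[name] for name in bins.BIN_NAMES)
    return out


# ---------------------------------------------------------------------------
# Density report and shrinkage correction
# ---------------------------------------------------------------------------

DEFAULT_SHRINKAGE = 0.259  # linear shrinkage fraction (SD 0.016)


@dataclass
class DensityReport:
    """Fv and Nl per region x diameter bin; raw or shrinkage-corrected."""

    fv: pd.DataFrame  # index = region, columns = small/medium/large/total
    nl: pd.DataFrame
    shrinkage: float = 0.0
    corrected: bool = False


def corrected_diameter(diameter_um, s: float = DEFAULT_SHRINKAGE):
    """In-vivo diameter from a measured one: d / (1 - s)."""
    if not 0 <= s < 1:
        raise ValueError("shrinkage fraction must satisfy 0 <= s < 1")
    return np.asarray(diameter_um, dtype=float) / (1.0 - s)


def shrinkage_correct(report: DensityReport, s: float = DEFAULT_SHRINKAGE) -> DensityReport:
    """Apply linear-shrinkage closed forms to a binned report.

    Lengths scale by 1/(1-s) and tissue volumes by 1/(1-s)^3, so
    Nl_corr = Nl_raw (1-s)^2; Fv is a volume fraction and is invariant under
    isotropic scaling.  s = 0 returns the report unchanged.  (Re-binning on
    corrected diameters is done where the graph is still available; see
    :func:`density_report`.)
    """
    if not 0 <= s < 1:
        raise ValueError("shrinkage fraction must satisfy 0 <= s < 1")
    return DensityReport(
        fv=report.fv.copy(),
        nl=report.nl * (1.0 - s) ** 2,
        shrinkage=s,
        corrected=True,
    )


def shrinkage_invert(report: DensityReport) -> DensityReport:
    """Undo a correction: applying s then s' = -s/(1-s) restores raw values."""
    s = report.shrinkage
    return DensityReport(
        fv=report.fv.copy(), nl=report.nl / (1.0 - s) ** 2, shrinkage=0.0, corrected=False
    )


def fill_region_labels(
    region_labels: LabelVolume, domain: np.ndarray | None = None
) -> np.ndarray:
    """Propagate each region label into unlabeled voxels by nearest region.

    Region label volumes leave vessel lumina unlabeled (label 0); statistics
    that must attribute vessel voxels to the surrounding region use this
    nearest-region assignment.  ``domain`` restricts which zero voxels are
    filled (e.g. the brain plus vessel masks); outside it labels stay 0.
    """
    lab = region_labels.voxels
    if not (lab > 0).any():
        return lab.copy()
    _, (iz, iy, ix) = ndimage.distance_transform_edt(
        lab == 0, sampling=region_labels.voxel_size_um, return_indices=True
    )
    filled = lab[iz, iy, ix]
    if domain is not None:
        filled = np.where((lab > 0) | domain, filled, 0)
    return filled


def density_report(
    graph: VesselGraph,
    region_labels: LabelVolume,
    bins: DiameterBins | None = None,
    shrinkage: float | None = None,
) -> DensityReport:
    """Per-region Fv and Nl by diameter bin from a radius-annotated graph.

    Vessel voxels themselves carry no region label, so each rendered vessel
    voxel (and each centerline segment) is attributed to its nearest region;
    the region volume in the denominators likewise includes the vessel voxels
    assigned to it.  With ``shrinkage`` set, diameters are corrected to their
    in-vivo values *before* binning and the Nl closed form is applied; Fv
    stays a fraction of the (equally shrunken) tissue volume.
    """
    bins = bins or DiameterBins()
    vs = region_labels.voxel_size_um
    shape = region_labels.shape
    voxel_mm3 = float(np.prod(vs)) * 1e-9
    s = shrinkage or 0.0
    scale = 1.0 / (1.0 - s)

    bin_masks = _bin_masks_scaled(graph, shape, vs, bins, diameter_scale=scale)
    vessel_any = np.zeros(shape, dtype=bool)
    for m in bin_masks:
        vessel_any |= m
    filled = fill_region_labels(region_labels, domain=vessel_any)
    seg = graph.segment_table()
    regions = [int(r) for r in region_labels.labels()]
    fv_rows, nl_rows = [], []
    pos = graph.positions_um()
    for r in regions:
        roi = filled == r  # region tissue plus its vessel voxels
        n_roi = int(roi.sum())
        roi_mm3 = n_roi * voxel_mm3
        claimed = np.zeros(shape, dtype=bool)
        fv_row = {}
        for b in (2, 1, 0):
            m = bin_masks[b] & ~claimed
            fv_row[bins.name(b)] = np.count_nonzero(m & roi) / n_roi if n_roi else 0.0
            claimed |= bin_masks[b]
        fv_row["total"] = np.count_nonzero(claimed & roi) / n_roi if n_roi else 0.0
        nl_row = {name: 0.0 for name in bins.BIN_NAMES}
        if seg.size and roi_mm3 > 0:
            mid = (pos[seg[:, 0].astype(int)] + pos[seg[:, 1].astype(int)]) / 2.0
            idx = np.rint(mid / np.asarray(vs)).astype(np.int64)
            ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
            in_roi = np.zeros(len(seg), dtype=bool)
            in_roi[ok] = roi[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
            b_assign = bins.assign(seg[:, 3] * scale)
            for k, name in enumerate(bins.BIN_NAMES):
                L_mm = seg[in_roi & (b_assign == k), 2].sum() / 1000.0
                nl_row[name] = float(L_mm) * (1.0 - s) ** 2 / roi_mm3
        nl_row["total"] = sum(nl_row[name] for name in bins.BIN_NAMES)
        fv_rows.append(fv_row)
        nl_rows.append(nl_row)
    cols = list(bins.BIN_NAMES) + ["total"]
    return DensityReport(
        fv=pd.DataFrame(fv_rows, index=regions)[cols],
        nl=pd.DataFrame(nl_rows, index=regions)[cols],
        shrinkage=s,
        corrected=s > 0,
    )


def _bin_masks_scaled(graph, shape, voxel_size_um, bins, diameter_scale=1.0):
    return [
        render_tubes(
            graph,
            shape,
            voxel_size_um,
            segment_filter=lambda i, j, L, d, b=b: bins.assign(d * diameter_scale) == b,
        )
        for b in range(3)
    ]


# ---------------------------------------------------------------------------
# Distribution matrices
# ---------------------------------------------------------------------------


@dataclass
class DistributionMatrix:
    """Rows = vessels, columns = region labels + 'unassigned'; rows sum to 1."""

    frame: pd.DataFrame
    voxel_counts: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        sums = self.frame.sum(axis=1)
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("distribution rows must sum to 1 (+-1e-9)")


def distribution_proportions(
    vessel_labels: LabelVolume,
    region_labels: LabelVolume,
    pial_graph: VesselGraph | None = None,
    default_pial_radius_um: dict[str, float] | None = None,
    pial_classes: dict[int, str] | None = None,
) -> DistributionMatrix:
    """Per-vessel volume proportions across brain regions.

    Vessel volume is the voxel count of each vessel label.  Pial-surface
    branches whose lumina were never segmented are rasterized from
    ``pial_graph`` with a uniform radius per class (artery 150 um, vein
    250 um) and added under labels taken from the graph nodes' type codes
    (``pial_classes`` maps pial vessel label -> 'artery'/'vein' when the graph
    itself is unlabeled).  Voxels outside every region fall in 'unassigned'.
    """
    if vessel_labels.shape != region_labels.shape:
        raise ValueError("vessel and region grids differ")
    radii = dict(DEFAULT_PIAL_RADII_UM)
    if default_pial_radius_um:
        radii.update(default_pial_radius_um)
    vlab = vessel_labels.voxels.copy()
    if pial_graph is not None and pial_graph.n_nodes:
        next_label = int(vlab.max()) + 1
        for comp in pial_graph.components():
            tc = int(np.bincount(pial_graph.type_code[comp]).argmax())
            cls = "vein" if tc == TYPE_VEIN else "artery"
            sub = _component_subgraph(pial_graph, comp)
            m = render_tubes(
                sub,
                vessel_labels.shape,
                vessel_labels.voxel_size_um,
                radius_override=radii[cls],
            )
            vlab = np.where((vlab == 0) & m, next_label, vlab)
            next_label += 1

    regions = [int(r) for r in np.unique(region_labels.voxels) if r != 0]
    vessels = [int(v) for v in np.unique(vlab) if v != 0]
    cols = regions + ["unassigned"]
    rows = {}
    counts = {}
    for v in vessels:
        sel = vlab == v
        total = int(sel.sum())
        counts[v] = total
        reg = region_labels.voxels[sel]
        bc = np.bincount(reg, minlength=(max(regions) + 1 if regions else 1))
        row = {r: bc[r] / total for r in regions}
        row["unassigned"] = (total - sum(bc[r] for r in regions)) / total
        rows[v] = row
    name_map = vessel_labels.names or {}
    frame = pd.DataFrame.from_dict(rows, orient="index")[cols] if rows else pd.DataFrame(columns=cols)
    frame.index = [name_map.get(v, v) for v in frame.index]
    return DistributionMatrix(frame=frame, voxel_counts=pd.Series(counts))


def _component_subgraph(g: VesselGraph, comp: np.ndarray) -> VesselGraph:
    sel = np.zeros(g.n_nodes, dtype=bool)
    sel[comp] = True
    keep = set(int(i) for i in g.ids[sel])
    parent = np.where(np.isin(g.parent, list(keep)), g.parent, -1)
    return VesselGraph(
        g.ids[sel], g.type_code[sel], g.x[sel], g.y[sel], g.z[sel], g.radius[sel],
        parent[sel], [e for e in g.loop_edges if e[0] in keep and e[1] in keep],
    )


def mean_distribution(matrices: list[DistributionMatrix]) -> DistributionMatrix:
    """Element-wise mean across subjects (a convex combination stays row-stochastic)."""
    if not matrices:
        raise ValueError("no matrices")
    ref = matrices[0].frame
    for m in matrices[1:]:
        if not (m.frame.index.equals(ref.index) and m.frame.columns.equals(ref.columns)):
            raise ValueError("matrices have mismatched vessel/region labels")
    mean = sum(m.frame for m in matrices) / len(matrices)
    return DistributionMatrix(frame=mean)


# ---------------------------------------------------------------------------
# Branch levels
# ---------------------------------------------------------------------------


def count_branch_levels(
    graph: VesselGraph,
    cutoffs: LevelCutoffs | None = None,
    side_plane_x_um: float | None = None,
) -> pd.DataFrame:
    """Branch counts per diameter level, split left/right of a sagittal plane.

    A branch is a maximal parent-chain between branch points (root,
    bifurcations, leaves); its level comes from its mean diameter.  The side
    plane defaults to the mid-x of the graph's extent.
    """
    cutoffs = cutoffs or LevelCutoffs()
    if graph.n_nodes == 0:
        raise ValueError("graph has no nodes (no root)")
    if side_plane_x_um is None:
        side_plane_x_um = float((graph.x.min() + graph.x.max()) / 2.0)
    idx = graph._index()
    children: dict[int, list[int]] = {int(i): [] for i in graph.ids}
    for k, p in enumerate(graph.parent):
        if int(p) != -1:
            children[int(p)].append(int(graph.ids[k]))
    roots = [int(graph.ids[k]) for k in graph.roots()]

    counts = {(lvl, side): 0 for lvl in (1, 2, 3) for side in ("left", "right")}
    for root in roots:
        # branch start nodes: root, and every child of a bifurcation
        stack = [(root, None)]
        while stack:
            start, parent_of_start = stack.pop()
            chain = [start] if parent_of_start is None else [parent_of_start, start]
            cur = start
            while len(children[cur]) == 1:
                cur = children[cur][0]
                chain.append(cur)
            ks = [idx[c] for c in chain]
            mean_d = float(np.mean(2.0 * graph.radius[ks]))
            mean_x = float(np.mean(graph.x[ks]))
            lvl = cutoffs.assign(mean_d)
            side = "left" if mean_x < side_plane_x_um else "right"
            counts[(lvl, side)] += 1
            for ch in children[cur]:
                stack.append((ch, cur))
    df = pd.DataFrame(
        {
            "left": [counts[(1, "left")], counts[(2, "left")], counts[(3, "left")]],
            "right": [counts[(1, "right")], counts[(2, "right")], counts[(3, "right")]],
        },
        index=[1, 2, 3],
    )
    df["total"] = df["left"] + df["right"]
    df.index.name = "level"
    return df


# ---------------------------------------------------------------------------
# Annotation and region comparison
# ---------------------------------------------------------------------------


def annotate_vessel(
    orientations,
    region: str | None = None,
    kind: str | None = None,
    connected_vessel: str | None = None,
) -> str:
    """Vessel name from the naming rules.

    ``orientation-brain region-artery/vein`` for 1-3 orientations, or
    ``orientation-branch of-<connected vessel>`` when the branch is only
    distinguishable by its parent vessel.
    """
    orientations = list(orientations)
    if not 1 <= len(orientations) <= 3:
        raise ValueError("need 1 to 3 orientations")
    if connected_vessel is not None:
        return "-".join(orientations + ["branch of", connected_vessel])
    if region is None or kind is None:
        raise ValueError("need region and kind (or a connected vessel)")
    if kind not in ("artery", "vein"):
        raise ValueError("kind must be 'artery' or 'vein'")
    return "-".join(orientations + [region, kind])


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise_p: pd.DataFrame


def compare_regions(values: dict[str, list]) -> AnovaResult:
    """One-way ANOVA across regions, from between/within mean squares.

    ``values`` maps region name -> replicate measurements (e.g. Fv per
    sample).  The pairwise grid holds the two-group ANOVA p-value (identical
    to a two-sided two-sample equal-variance t-test, F = t^2) for every pair.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")

    def _anova(gs: list[np.ndarray]) -> tuple[float, float, int, int]:
        all_v = np.concatenate(gs)
        grand = all_v.mean()
        ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
        dfb = len(gs) - 1
        dfw = all_v.size - len(gs)
        if ssw == 0:
            raise ValueError("zero within-group variance in every group")
        f = (ssb / dfb) / (ssw / dfw)
        return f, float(stats.f.sf(f, dfb, dfw)), dfb, dfw

    f, p, dfb, dfw = _anova(list(groups.values()))
    names = list(groups)
    grid = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            _, pp, _, _ = _anova([groups[a], groups[b]])
            grid.loc[a, b] = grid.loc[b, a] = pp
    return AnovaResult(f, p, dfb, dfw, grid)
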