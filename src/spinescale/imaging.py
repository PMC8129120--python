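"""ROI-based two-channel spine quantification and turnover classification.

Each spine is quantified from four regions of interest: a spineROI around
the head (excluding voxels inside the dendritic backbone tube), a shaftROI
covering the backbone tube within +-2 um arclength of the spine's backbone
foot, and congruent background translates of both.  All ROIs span the best
imaging plane +-1 in z.  After background subtraction, spine SEP, spine
dsRed2 and shaft SEP sums are normalized to the mean per-voxel
background-subtracted shaft dsRed2 signal, which cancels session-wide gain.

Conventions: arrays are indexed (z, y, x); physical coordinates are (x, y, z)
in micrometres with the origin at the centre of voxel (0, 0, 0); sub-voxel
ROI membership is decided by voxel-centre inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

PERSISTENT = "persistent"
FORMED = "formed"
ELIMINATED = "eliminated"
ABSENT = "none"


@dataclass
class ImageStack:
    green: np.ndarray  # SEP-GluA1, shape (nz, ny, nx)
    red: np.ndarray  # dsRed2, same shape
    voxel_xy: float  # um
    voxel_z: float  # um

    def __post_init__(self):
        if self.green.shape != self.red.shape:
            raise ValueError("green and red channels must share a shape")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")


@dataclass
class DendriteTrace:
    backbone: np.ndarray  # (n, 3) points (x, y, z) in um
    radius: float  # um

    def __post_init__(self):
        self.backbone = np.asarray(self.backbone, dtype=float)
        if self.backbone.ndim != 2 or self.backbone.shape[0] < 2:
            raise ValueError("backbone needs at least 2 points")
        if self.radius <= 0:
            raise ValueError("backbone radius must be positive")

    def densified(self, step: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Points sampled every ``step`` um along the polyline, with their
        arclengths."""
        pts = [self.backbone[0]]
        arcs = [0.0]
        total = 0.0
        for a, b in zip(self.backbone[:-1], self.backbone[1:]):
            seg = b - a
            length = float(np.linalg.norm(seg))
            if length == 0:
                continue
            n = max(int(np.ceil(length / step)), 1)
            for i in range(1, n + 1):
                t = i / n
                pts.append(a + t * seg)
                arcs.append(total + t * length)
            total += length
        return np.asarray(pts), np.asarray(arcs)


@dataclass
class SpineMark:
    centroid: tuple[float, float, float]  # (x, y, z) um
    best_z: int  # plane index
    width: float  # head width, um
    protrusion: float  # distance from backbone, um

    def __post_init__(self):
        if self.width < 0 or self.protrusion < 0:
            raise ValueError("width and protrusion must be >= 0")


@dataclass
class ROISet:
    spine: np.ndarray  # (n, 3) voxel indices (z, y, x)
    shaft: np.ndarray
    background_spine: np.ndarray
    background_shaft: np.ndarray


def apply_inclusion_filters(marks: list[SpineMark], voxel_xy: float) -> list[SpineMark]:
    """Retain marks with head width > 3 pixels and protrusion > 6 pixels
    (pixel = x/y voxel size); both inequalities strict, order preserved."""
    if voxel_xy <= 0:
        raise ValueError("voxel size must be positive")
    return [
        m
        for m in marks
        if m.width > 3 * voxel_xy and m.protrusion > 6 * voxel_xy
    ]


def backbone_foot(trace: DendriteTrace, point) -> tuple[np.ndarray, float]:
    """Nearest densified backbone point to ``point`` (Euclidean distance,
    ties broken by lower arclength) and its arclength."""
    pts, arcs = trace.densified()
    d = np.linalg.norm(pts - np.asarray(point, dtype=float), axis=1)
    # argmin returns the first (lowest-arclength) minimiser
    i = int(np.argmin(d))
    return pts[i], float(arcs[i])


def _z_planes(best_z: int, nz: int) -> np.ndarray:
    planes = np.array([best_z - 1, best_z, best_z + 1])
    if planes.min() < 0 or planes.max() >= nz:
        raise ValueError("ROI z-extent (best plane +-1) leaves the stack")
    return planes


def build_rois(
    trace: DendriteTrace,
    mark: SpineMark,
    stack_shape: tuple[int, int, int],
    voxel_xy: float,
    voxel_z: float,
    roi_width: float = 0.7,
    background_offset: tuple[float, float, float] = (0.0, 3.0, 0.0),
) -> ROISet:
    """Construct the four ROIs for one spine.

    spineROI: voxels whose centres lie within ``roi_width/2`` of the head
    centroid in x/y, minus voxels inside the backbone tube.  shaftROI:
    backbone-tube voxels within +-2 um arclength of the spine's backbone
    foot.  Background ROIs are the same voxel sets translated by
    ``background_offset`` (um, (x, y, z)).  Every ROI spans the best plane
    +-1 in z.  Raises if any ROI leaves the stack or the spineROI is empty
    after backbone exclusion.
    """
    if not 0.5 <= roi_width <= 1.0:
        raise ValueError("roi_width must lie in [0.5, 1.0] um")
    nz, ny, nx = stack_shape
    planes = _z_planes(mark.best_z, nz)
    cx, cy, _ = mark.centroid

    pts, arcs = trace.densified()
    # the backbone tube footprint and exclusion zone are defined in the
    # imaging plane (x/y) and replicated across the best +-1 planes
    tree = cKDTree(pts[:, :2])

    # candidate voxels: bounding box around the centroid
    half = roi_width / 2.0
    j_lo = int(np.floor((cy - half) / voxel_xy))
    j_hi = int(np.ceil((cy + half) / voxel_xy))
    k_lo = int(np.floor((cx - half) / voxel_xy))
    k_hi = int(np.ceil((cx + half) / voxel_xy))
    jj, kk = np.meshgrid(
        np.arange(j_lo, j_hi + 1), np.arange(k_lo, k_hi + 1), indexing="ij"
    )
    jj, kk = jj.ravel(), kk.ravel()
    keep = (kk * voxel_xy - cx) ** 2 + (jj * voxel_xy - cy) ** 2 <= half**2
    jj, kk = jj[keep], kk[keep]
    coords = np.column_stack([kk * voxel_xy, jj * voxel_xy])
    d, _ = tree.query(coords)
    outside = d > trace.radius
    spine_vox = [
        (z, j, k) for z in planes for j, k in zip(jj[outside], kk[outside])
    ]
    if not spine_vox:
        raise ValueError("spineROI is empty after backbone exclusion")
    spine_vox = np.asarray(spine_vox, dtype=int)

    # shaftROI: tube voxels near the foot
    _, foot_arc = backbone_foot(trace, mark.centroid)
    margin = 2.0 + trace.radius + voxel_xy
    sel = np.abs(arcs - foot_arc) <= margin
    box_lo = pts[sel].min(axis=0) - trace.radius - voxel_xy
    box_hi = pts[sel].max(axis=0) + trace.radius + voxel_xy
    j_rng = np.arange(
        int(np.floor(box_lo[1] / voxel_xy)), int(np.ceil(box_hi[1] / voxel_xy)) + 1
    )
    k_rng = np.arange(
        int(np.floor(box_lo[0] / voxel_xy)), int(np.ceil(box_hi[0] / voxel_xy)) + 1
    )
    jj2, kk2 = np.meshgrid(j_rng, k_rng, indexing="ij")
    jj2, kk2 = jj2.ravel(), kk2.ravel()
    coords2 = np.column_stack([kk2 * voxel_xy, jj2 * voxel_xy])
    d2, idx2 = tree.query(coords2)
    ok = (d2 <= trace.radius) & (np.abs(arcs[idx2] - foot_arc) <= 2.0)
    shaft_vox = [
        (z, j, k) for z in planes for j, k in zip(jj2[ok], kk2[ok])
    ]
    if not shaft_vox:
        raise ValueError("shaftROI is empty")
    shaft_vox = np.asarray(shaft_vox, dtype=int)

    off = np.array(
        [
            int(round(background_offset[2] / voxel_z)),
            int(round(background_offset[1] / voxel_xy)),
            int(round(background_offset[0] / voxel_xy)),
        ]
    )
    bg_spine = spine_vox + off
    bg_shaft = shaft_vox + off

    for name, vox in [
        ("spineROI", spine_vox),
        ("shaftROI", shaft_vox),
        ("background spineROI", bg_spine),
        ("background shaftROI", bg_shaft),
    ]:
        if vox[:, 0].min() < 0 or vox[:, 0].max() >= nz:
            raise ValueError(f"{name} leaves the stack in z")
        if vox[:, 1].min() < 0 or vox[:, 1].max() >= ny:
            raise ValueError(f"{name} leaves the stack in y")
        if vox[:, 2].min() < 0 or vox[:, 2].max() >= nx:
            raise ValueError(f"{name} leaves the stack in x")
    return ROISet(
        spine=spine_vox,
        shaft=shaft_vox,
        background_spine=bg_spine,
        background_shaft=bg_shaft,
    )


def choose_background_offset(
    stack: ImageStack,
    trace: DendriteTrace,
    mark: SpineMark,
    candidates=((0.0, 3.0, 0.0), (0.0, -3.0, 0.0), (3.0, 0.0, 0.0), (-3.0, 0.0, 0.0)),
    roi_width: float = 0.7,
):
    """Pick the candidate background translation minimising the mean voxel
    intensity (summed over both channels) of the background ROIs; ties go to
    the first listed candidate."""
    best = None
    best_val = np.inf
    for cand in candidates:
        try:
            rois = build_rois(
                trace,
                mark,
                stack.green.shape,
                stack.voxel_xy,
                stack.voxel_z,
                roi_width=roi_width,
                background_offset=cand,
            )
        except ValueError:
            continue
        vox = np.vstack([rois.background_spine, rois.background_shaft])
        val = float(
            stack.green[vox[:, 0], vox[:, 1], vox[:, 2]].mean()
            + stack.red[vox[:, 0], vox[:, 1], vox[:, 2]].mean()
        )
        if val < best_val - 1e-12:
            best_val = val
            best = cand
    if best is None:
        raise ValueError("no feasible background offset among candidates")
    return best


def _roi_sum(channel: np.ndarray, vox: np.ndarray) -> float:
    return float(channel[vox[:, 0], vox[:, 1], vox[:, 2]].sum())


@dataclass
class QuantRecord:
    spine_sep: float
    spine_dsred: float
    shaft_sep: float
    shaft_dsred: float
    norm_spine_sep: float
    norm_spine_dsred: float
    norm_shaft_sep: float


def quantify(stack: ImageStack, rois: ROISet) -> QuantRecord:
    """Background-subtracted summed intensities and their normalization to
    the mean per-voxel background-subtracted shaft dsRed2 signal.

    Raises if that normalizer is <= 0 (quantification undefined).
    """
    spine_sep = _roi_sum(stack.green, rois.spine) - _roi_sum(
        stack.green, rois.background_spine
    )
    spine_dsred = _roi_sum(stack.red, rois.spine) - _roi_sum(
        stack.red, rois.background_spine
    )
    shaft_sep = _roi_sum(stack.green, rois.shaft) - _roi_sum(
        stack.green, rois.background_shaft
    )
    shaft_dsred = _roi_sum(stack.red, rois.shaft) - _roi_sum(
        stack.red, rois.background_shaft
    )
    denom = shaft_dsred / len(rois.shaft)
    if denom <= 0:
        raise ValueError(
            "mean background-subtracted shaft dsRed2 <= 0: normalization undefined"
        )
    return QuantRecord(
        spine_sep=spine_sep,
        spine_dsred=spine_dsred,
        shaft_sep=shaft_sep,
        shaft_dsred=shaft_dsred,
        norm_spine_sep=spine_sep / denom,
        norm_spine_dsred=spine_dsred / denom,
        norm_shaft_sep=shaft_sep / denom,
    )


def classify_turnover(presence: np.ndarray) -> np.ndarray:
    """Per-spine per-interval turnover labels from a (spines x timepoints)
    boolean presence matrix.

    Interval k (between timepoints k and k+1) is labelled ``persistent`` if
    the spine is present at both, ``formed`` if absent then present,
    ``eliminated`` if present then absent, and ``none`` if absent at both.
    Requires at least 2 timepoints.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.ndim != 2 or presence.shape[1] < 2:
        raise ValueError("presence matrix must be (n_spines, >=2 timepoints)")
    prev = presence[:, :-1]
    nxt = presence[:, 1:]
    labels = np.full(prev.shape, ABSENT, dtype=object)
    labels[prev & nxt] = PERSISTENT
    labels[~prev & nxt] = FORMED
    labels[prev & ~nxt] = ELIMINATED
    return labels
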