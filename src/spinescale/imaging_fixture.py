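"""Rendered two-channel image fixtures with per-spine ground truth.

The fixture draws a straight dendrite tube plus Gaussian spine-head blobs
into a small 3-D stack at realistic two-photon sampling (0.12 um x/y voxels,
1 um z-step), with a uniform background offset and optional Poisson shot
noise.  Blob kernels are normalised so the rendered integrated intensity of
each spine equals its stored ground truth exactly; the stored normalized
ground truth is the blob's integrated intensity divided by the per-voxel
shaft dsRed2 density, i.e. the value an ideal ROI quantifier recovers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cohort import lognormal_params, log_correlation
from .config import SynthConfig
from .imaging import DendriteTrace, ImageStack, SpineMark


@dataclass
class FixtureConfig:
    """Geometry and photometry of the rendered fixture."""

    shape: tuple[int, int, int] = (9, 72, 104)  # (nz, ny, nx)
    voxel_xy: float = 0.12  # um
    voxel_z: float = 1.0  # um
    dendrite_radius: float = 0.30  # um
    n_spines: int = 4
    spine_spacing: float = 2.2  # um along the dendrite
    min_separation: float = 1.5  # um; closer placements are rejected
    protrusion: float = 1.0  # um from the backbone
    head_width: float = 0.5  # um
    blob_sigma_xy: float = 0.10  # um
    blob_sigma_z: float = 0.35  # um
    shaft_green_density: float = 0.25  # per-voxel shaft SEP
    shaft_red_density: float = 1.0  # per-voxel shaft dsRed2 (normalizer)
    background: float = 0.002  # uniform offset per voxel
    photon_scale: float = 20000.0  # photons per intensity unit for shot noise
    noise: bool = True
    spine_positions: list | None = None  # optional explicit (x, side) pairs
    green_intensities: list | None = None  # optional explicit integrated G_i
    red_intensities: list | None = None


@dataclass
class ImageFixture:
    stack: ImageStack
    trace: DendriteTrace
    marks: list[SpineMark]
    truth: pd.DataFrame
    config: FixtureConfig = field(repr=False)


def _render_blob(img, center, sigma_xy, sigma_z, voxel_xy, voxel_z, total):
    """Add a Gaussian blob whose voxel sum equals ``total`` exactly."""
    cx, cy, cz = center
    nz, ny, nx = img.shape
    rx = int(np.ceil(4 * sigma_xy / voxel_xy))
    rz = int(np.ceil(4 * sigma_z / voxel_z))
    k0 = int(round(cx / voxel_xy))
    j0 = int(round(cy / voxel_xy))
    i0 = int(round(cz / voxel_z))
    ks = np.arange(max(k0 - rx, 0), min(k0 + rx, nx - 1) + 1)
    js = np.arange(max(j0 - rx, 0), min(j0 + rx, ny - 1) + 1)
    is_ = np.arange(max(i0 - rz, 0), min(i0 + rz, nz - 1) + 1)
    zz, yy, xx = np.meshgrid(
        is_ * voxel_z, js * voxel_xy, ks * voxel_xy, indexing="ij"
    )
    kernel = np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_xy**2)
        - (zz - cz) ** 2 / (2 * sigma_z**2)
    )
    kernel *= total / kernel.sum()
    img[np.ix_(is_, js, ks)] += kernel


def generate_image_fixture(
    config: SynthConfig | None = None,
    seed: int = 0,
    fixture: FixtureConfig | None = None,
) -> ImageFixture:
    """Render a fixture stack with known per-spine normalized intensities.

    Per-spine normalized SEP intensities are drawn from the cohort's
    baseline log-normal; dsRed2 intensities are drawn with the configured
    spine SEP <-> dsRed2 coupling.  Raises if any two spines are placed
    closer than ``min_separation`` (contamination of neighbouring spineROIs).
    """
    cfg = config or SynthConfig()
    fx = fixture or FixtureConfig()
    rng = np.random.default_rng(seed)
    nz, ny, nx = fx.shape
    z_mid = (nz // 2) * fx.voxel_z
    y_mid = 2.0  # um: dendrite axis offset from the stack edge
    # margin so every shaftROI (+-2 um along x) stays inside the stack
    x_lo, x_hi = 2.5, (nx - 1) * fx.voxel_xy - 2.5

    if fx.spine_positions is not None:
        positions = list(fx.spine_positions)
    else:
        positions = [
            (x_lo + i * fx.spine_spacing, 1 if i % 2 == 0 else -1)
            for i in range(fx.n_spines)
        ]
        if positions and positions[-1][0] > x_hi:
            raise ValueError("stack too small for the requested spine count")
    xs = sorted(p[0] for p in positions)
    for a, b in zip(xs[:-1], xs[1:]):
        if b - a < fx.min_separation:
            raise ValueError(
                f"spine placements {a:.2f} and {b:.2f} um violate the "
                f"minimum separation of {fx.min_separation} um"
            )

    n = len(positions)
    if fx.green_intensities is not None:
        g_norm = np.asarray(fx.green_intensities, dtype=float)
        r_norm = np.asarray(
            fx.red_intensities
            if fx.red_intensities is not None
            else fx.green_intensities,
            dtype=float,
        )
    else:
        mu_g, sg_g = lognormal_params(*cfg.baseline_lognormal)
        mu_r, sg_r = lognormal_params(*cfg.dsred_lognormal)
        rho = log_correlation(cfg.dsred_coupling, sg_g, sg_r)
        zg = rng.standard_normal(n)
        zr = rho * zg + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        g_norm = np.exp(mu_g + sg_g * zg)
        r_norm = np.exp(mu_r + sg_r * zr)
    g_total = g_norm * fx.shaft_red_density
    r_total = r_norm * fx.shaft_red_density

    green = np.full(fx.shape, fx.background, dtype=float)
    red = np.full(fx.shape, fx.background, dtype=float)

    # dendrite along x at (y_mid, z_mid): in-plane footprint of the stated
    # radius, smeared axially over one z-step up and down (the axial PSF at
    # 1 um z-steps spreads a thin dendrite across adjacent planes)
    zc = np.arange(nz)[:, None, None] * fx.voxel_z
    yc = np.arange(ny)[None, :, None] * fx.voxel_xy
    tube = (np.abs(yc - y_mid) <= fx.dendrite_radius) & (
        np.abs(zc - z_mid) <= fx.voxel_z
    )
    tube = np.broadcast_to(tube, fx.shape)
    green[tube] += fx.shaft_green_density
    red[tube] += fx.shaft_red_density

    marks = []
    truth_rows = []
    for i, (x, side) in enumerate(positions):
        cy = y_mid + side * fx.protrusion
        center = (x, cy, z_mid)
        _render_blob(
            green, center, fx.blob_sigma_xy, fx.blob_sigma_z,
            fx.voxel_xy, fx.voxel_z, g_total[i],
        )
        _render_blob(
            red, center, fx.blob_sigma_xy, fx.blob_sigma_z,
            fx.voxel_xy, fx.voxel_z, r_total[i],
        )
        marks.append(
            SpineMark(
                centroid=center,
                best_z=int(round(z_mid / fx.voxel_z)),
                width=fx.head_width,
                protrusion=fx.protrusion,
            )
        )
        truth_rows.append(
            {
                "spine": i,
                "x_um": x,
                "y_um": cy,
                "z_um": z_mid,
                "green_integrated": g_total[i],
                "red_integrated": r_total[i],
                "norm_spine_sep": g_norm[i],
                "norm_spine_dsred": r_norm[i],
                "shaft_green_density": fx.shaft_green_density,
                "shaft_red_density": fx.shaft_red_density,
            }
        )

    if fx.noise:
        green = rng.poisson(green * fx.photon_scale) / fx.photon_scale
        red = rng.poisson(red * fx.photon_scale) / fx.photon_scale

    stack = ImageStack(
        green=green.astype(float),
        red=red.astype(float),
        voxel_xy=fx.voxel_xy,
        voxel_z=fx.voxel_z,
    )
    trace = DendriteTrace(
        backbone=np.array(
            [[0.0, y_mid, z_mid], [(nx - 1) * fx.voxel_xy, y_mid, z_mid]]
        ),
        radius=fx.dendrite_radius,
    )
    return ImageFixture(
        stack=stack, trace=trace, marks=marks, truth=pd.DataFrame(truth_rows),
        config=fx,
    )


def save_fixture(fixture: ImageFixture, out_dir: str | Path) -> None:
    """Write the stack as a channel-major multi-page TIFF plus JSON
    trace/marks (0-based pixel coordinates, voxel size in um in metadata)
    and the ground-truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = fixture.stack
    pages = np.concatenate([stack.green, stack.red], axis=0).astype(np.float32)
    tifffile.imwrite(out / "stack.tif", pages, metadata={
        "axes": "QYX",
        "channels": ["SEP-GluA1", "dsRed2"],
        "voxel_xy_um": stack.voxel_xy,
        "voxel_z_um": stack.voxel_z,
    })
    vx, vz = stack.voxel_xy, stack.voxel_z
    meta = {
        "voxel_xy_um": vx,
        "voxel_z_um": vz,
        "trace": {
            "backbone_px": [
                [p[0] / vx, p[1] / vx, p[2] / vz] for p in fixture.trace.backbone
            ],
            "radius_um": fixture.trace.radius,
        },
        "marks": [
            {
                "centroid_px": [
                    m.centroid[0] / vx,
                    m.centroid[1] / vx,
                    m.centroid[2] / vz,
                ],
                "best_z": m.best_z,
                "width_um": m.width,
                "protrusion_um": m.protrusion,
            }
            for m in fixture.marks
        ],
    }
    with open(out / "trace_marks.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    fixture.truth.to_csv(out / "ground_truth.csv", index=False)
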