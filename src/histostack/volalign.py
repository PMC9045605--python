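"""3D alignment of an MRI volume to blockface space.

A single low-regularization deformable registration between MRI and
blockface contrasts is unreliable (artifact regions and variably-filled
ventricles derail the similarity metric), so the alignment is staged: an
affine initialization followed by three deformable passes with strictly
decreasing field regularization, each seeded by the previous result.
Ventricle-scale interior holes of the blockface mask can be excluded from
the metric support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import TissueMask, Volume3D, mask_background
from .register2d import (
    RegistrationParams,
    Transform2D,
    WeightedTarget,
    apply_transform,
    register_pair,
)

log = logging.getLogger("histostack")

# A 3D transform shares the affine+field representation of the 2D one
# (3x4 affine, (3, nz, ny, nx) field, pull-back convention).
Transform3D = Transform2D


@dataclass
class RegularizationSchedule:
    """Three deformable stages with strictly decreasing field smoothing.

    ``stages`` is an ordered list of ``(field_smoothing_sigma, iterations)``;
    sigmas are in voxels of the blockface grid.
    """

    stages: tuple = ((4.0, 25), (2.0, 25), (1.0, 25))

    def __post_init__(self) -> None:
        self.stages = tuple((float(s), int(n)) for s, n in self.stages)
        if len(self.stages) != 3:
            raise ValueError("the schedule has exactly three stages")
        sigmas = [s for s, _ in self.stages]
        if not all(a > b for a, b in zip(sigmas, sigmas[1:])):
            raise ValueError("stage sigmas must be strictly decreasing")


def resample_to_grid(volume: Volume3D, reference: Volume3D) -> Volume3D:
    """Linear resampling of ``volume`` onto the reference voxel grid."""
    if volume.shape == reference.shape and volume.voxel_size == reference.voxel_size:
        return volume
    # physical axis order of voxel_size is (dx, dy, dz); arrays are (z, y, x)
    scale = [
        reference.voxel_size[2 - i] / volume.voxel_size[2 - i] for i in range(3)
    ]
    coords = np.indices(reference.shape, dtype=np.float64)
    coords = [c * s for c, s in zip(coords, scale)]
    data = ndi.map_coordinates(np.asarray(volume.voxels, dtype=np.float64), coords, order=1, mode="nearest")
    return Volume3D(data, voxel_size=reference.voxel_size)


def skull_strip(mri: Volume3D, blockface_mask: TissueMask | np.ndarray, t: Transform3D) -> Volume3D:
    """Resample the MRI into blockface space and zero it outside the mask."""
    m = blockface_mask.mask if isinstance(blockface_mask, TissueMask) else np.asarray(blockface_mask, bool)
    if not m.any():
        raise ValueError("blockface mask is empty; cannot skull-strip")
    resampled = apply_transform(np.asarray(mri.voxels, dtype=np.float64), t, cval=0.0)
    out = np.where(m, resampled, 0.0)
    return Volume3D(out, voxel_size=(200.0, 200.0, 200.0) if m.ndim == 3 else mri.voxel_size)


def register_volume(
    mri: Volume3D,
    blockface: Volume3D,
    schedule: RegularizationSchedule | None = None,
    exclusion_mask: np.ndarray | None = None,
    mi_bins: int = 32,
) -> Transform3D:
    """Staged MRI -> blockface deformable registration.

    The MRI is first resampled to the blockface grid, affinely initialized,
    then refined by three demons stages with decreasing regularization; the
    metric support excludes ``exclusion_mask`` (ventricle-like artifact
    regions).  The returned transform is defined on the blockface grid and
    carries per-stage metadata; applying it to the (resampled) MRI yields a
    blockface-grid volume.
    """
    schedule = schedule or RegularizationSchedule()
    moving = resample_to_grid(mri, blockface)
    # metric support: dilated blockface tissue (the background tells the
    # metric nothing about the warp and only dilutes it) minus excluded
    # artifact regions
    try:
        support = ndi.binary_dilation(mask_background(blockface).mask, iterations=5)
    except ValueError:
        support = np.ones(blockface.shape, dtype=bool)
    if exclusion_mask is not None:
        support &= ~np.asarray(exclusion_mask, dtype=bool)
    target = WeightedTarget(np.asarray(blockface.voxels, dtype=np.float64), weight=1.0, support_mask=support)
    init: Transform3D | None = None
    stage_meta = []
    stage_fields: list = []
    best_metric = -np.inf
    for si, (sigma, iters) in enumerate(schedule.stages):
        params = RegistrationParams(
            n_scales=3,
            coarsest_downsampling=4,
            mi_bins=mi_bins,
            smoothing_sigma_field=sigma,
            smoothing_sigma_fluid=4.0,
            iterations_per_scale=iters,
            do_affine=(si == 0),
            min_level_extent=8,
            # warm stages rerun the full pyramid: smooth residual error is
            # only correctable at coarse scale
            warm_scales=3,
            warm_iterations=iters,
        )
        t = register_pair(np.asarray(moving.voxels, dtype=np.float64), [target], params, init=init)
        metric = t.meta["trace"][-1]
        if metric < best_metric and init is not None:
            # a lower-regularization stage that degrades the metric is
            # rejected: keep the previous stage's result
            log.warning("stage %d degraded the metric (%.4f < %.4f); keeping previous", si, metric, best_metric)
            t = init
            metric = best_metric
        best_metric = max(best_metric, metric)
        stage_meta.append({"sigma": sigma, "metric": float(metric)})
        stage_fields.append(t.displacement())
        init = t
    assert init is not None
    init.meta["stages"] = stage_meta
    init.meta["stage_fields"] = stage_fields
    return init


def blockface_exclusion_mask(blockface: Volume3D, min_hole_radius: float = 5.0) -> np.ndarray:
    """Large interior holes of the blockface mask (ventricle-scale artifacts)."""
    tm = mask_background(blockface)
    lab, n = ndi.label(tm.holes)
    out = np.zeros(tm.holes.shape, dtype=bool)
    min_vox = (4.0 / 3.0) * np.pi * min_hole_radius**3
    for i in range(1, n + 1):
        sel = lab == i
        if sel.sum() >= min_vox:
            out |= sel
    return out
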