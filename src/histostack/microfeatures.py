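"""Microstructure maps: structure-tensor directionality and vessel density.

The structure (shape) tensor is the Gaussian-windowed outer product of
Gaussian-derivative image gradients; its dominant eigenvector angle (modulo
180 deg) and the anisotropy ``1 - lambda2/lambda1`` summarize local texture
orientation, a proxy for fiber architecture at the section scale.  Maps
computed on individual sections are recombined into the common 3D space by
warping the tensor components through each section's transform, reorienting
them with the local Jacobian, and averaging tensors (never angles, which
wrap at 0/180 deg) per output voxel.  Vessel density accumulates the
detected vessel masks of all stains per voxel and smooths with a normalized
Gaussian, preserving total vessel mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import SectionImage, Volume3D
from .register2d import Transform2D, apply_transform
from .stackalign import AlignmentState

log = logging.getLogger("histostack")


@dataclass
class OrientationMap:
    """Per-pixel texture orientation (degrees in [0, 180)) and anisotropy."""

    orientation: np.ndarray  # degrees, NaN where undefined
    anisotropy: np.ndarray  # in [0, 1]
    valid: np.ndarray  # where gradient energy exceeded the threshold
    tensor: np.ndarray  # (3, ny, nx): (Jxx, Jxy, Jyy) in (x, y) axes


def structure_tensor(
    section: SectionImage | np.ndarray,
    sigma_grad: float = 1.0,
    sigma_window: float = 8.0,
    energy_rel_threshold: float = 1e-4,
) -> OrientationMap:
    """Structure-tensor orientation and anisotropy of one section.

    Gradients are Gaussian derivatives at ``sigma_grad``; the outer product
    is windowed at ``sigma_window``.  Orientation is the angle of the
    dominant eigenvector w.r.t. the +x axis, modulo 180 degrees; pixels with
    tensor energy below ``energy_rel_threshold`` times the image maximum are
    flagged undefined (NaN orientation).  Invariant to affine intensity
    rescaling by construction of the normalization.
    """
    img = section.pixels if isinstance(section, SectionImage) else np.asarray(section, dtype=np.float64)
    gy = ndi.gaussian_filter(img, sigma_grad, order=(1, 0))
    gx = ndi.gaussian_filter(img, sigma_grad, order=(0, 1))
    jxx = ndi.gaussian_filter(gx * gx, sigma_window)
    jxy = ndi.gaussian_filter(gx * gy, sigma_window)
    jyy = ndi.gaussian_filter(gy * gy, sigma_window)
    tr = jxx + jyy
    det_term = np.sqrt(np.maximum(((jxx - jyy) / 2) ** 2 + jxy**2, 0.0))
    lam1 = tr / 2 + det_term
    lam2 = tr / 2 - det_term
    valid = lam1 > energy_rel_threshold * max(float(lam1.max()), 1e-300)
    anis = np.zeros_like(lam1)
    anis[valid] = 1.0 - np.clip(lam2[valid] / lam1[valid], 0.0, 1.0)
    theta = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
    theta = np.mod(theta, 180.0)
    orientation = np.where(valid, theta, np.nan)
    return OrientationMap(orientation, anis, valid, np.stack([jxx, jxy, jyy]))


def _tensor_from_map(omap: OrientationMap) -> np.ndarray:
    """Unit-trace, anisotropy-weighted tensor (Jxx, Jxy, Jyy) per pixel."""
    th = np.deg2rad(np.nan_to_num(omap.orientation))
    vx, vy = np.cos(th), np.sin(th)
    a = np.where(omap.valid, omap.anisotropy, 0.0)
    return np.stack([a * vx * vx, a * vx * vy, a * vy * vy])


def _local_jacobian(t: Transform2D) -> np.ndarray:
    """Per-pixel 2x2 Jacobian d(map)/d(out) in (y, x) axis order."""
    m = t.map_coordinates_grid()
    j00, j01 = np.gradient(m[0])  # d(map_y)/dy, d(map_y)/dx
    j10, j11 = np.gradient(m[1])
    return np.stack([j00, j01, j10, j11]).reshape(2, 2, *t.shape)


def aggregate_to_blockface(
    per_section: dict,
    state: AlignmentState,
    aggregation_factor: int = 1,
) -> tuple[Volume3D, Volume3D]:
    """Recombine per-section orientation maps into the blockface volume.

    ``per_section`` maps ``(slice_index, stain)`` to an
    :class:`OrientationMap` on that section's native grid.  Tensors are
    warped into blockface space with the section's transform, reoriented by
    the inverse local Jacobian (a direction ``v`` on the output grid
    corresponds to ``J v`` in the section), averaged per voxel across stains,
    optionally block-averaged by ``aggregation_factor`` (e.g., a fine-scale
    to 200-um reduction), and eigendecomposed into orientation/anisotropy
    volumes (NaN orientation where undefined).
    """
    bf = state.blockface
    nz = bf.n_slices
    shape = bf.voxels.shape[1:]
    acc = np.zeros((3, nz, *shape))
    cnt = np.zeros((nz, *shape))
    for key, omap in per_section.items():
        z, stain = key
        st = state.sections.get(key)
        t = (
            Transform2D.identity(shape)
            if st is None
            else (st.best_transform if st.best_transform is not None else st.transform)
        )
        tens = _tensor_from_map(omap)
        warped = np.stack([apply_transform(c, t, cval=0.0) for c in tens])
        support = apply_transform(omap.valid.astype(np.float64), t, cval=0.0) > 0.5
        jac = _local_jacobian(t)
        # reorient: T_out = J^-1 T_in J^-T per pixel (directions pull back via J)
        a, b_, c_, d = jac[0, 0], jac[0, 1], jac[1, 0], jac[1, 1]
        det = a * d - b_ * c_
        det = np.where(np.abs(det) < 1e-6, 1e-6, det)
        # J^-1 in (y, x) = [[d, -b], [-c, a]] / det ; tensors are in (x, y) axes
        # convert: x-axis is array axis 1, y-axis is array axis 0
        ixx = d / det  # d(out_x)/d(in_x) block of J^-1 expressed for (x, y)
        ixy = -c_ / det
        iyx = -b_ / det
        iyy = a / det
        txx, txy, tyy = warped
        rxx = ixx * (ixx * txx + ixy * txy) + ixy * (ixx * txy + ixy * tyy)
        rxy = iyx * (ixx * txx + ixy * txy) + iyy * (ixx * txy + ixy * tyy)
        ryy = iyx * (iyx * txx + iyy * txy) + iyy * (iyx * txy + iyy * tyy)
        out_t = np.stack([rxx, rxy, ryy])
        acc[:, z] += np.where(support, out_t, 0.0)
        cnt[z] += support
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_t = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    if aggregation_factor > 1:
        f = aggregation_factor
        ny, nx = shape
        mean_t = mean_t[:, :, : ny - ny % f, : nx - nx % f]
        mean_t = mean_t.reshape(3, nz, ny // f, f, nx // f, f).mean(axis=(3, 5))
        cnt = cnt[:, : ny - ny % f, : nx - nx % f].reshape(nz, ny // f, f, nx // f, f).mean(axis=(2, 4))
    jxx, jxy, jyy = mean_t
    theta = np.mod(0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy)), 180.0)
    tr = jxx + jyy
    det_term = np.sqrt(np.maximum(((jxx - jyy) / 2) ** 2 + jxy**2, 0.0))
    lam1 = tr / 2 + det_term
    lam2 = tr / 2 - det_term
    defined = (lam1 > 1e-12) & (cnt > 0)
    anis = np.where(defined, 1.0 - np.clip(np.where(defined, lam2, 0) / np.where(defined, lam1, 1), 0, 1), 0.0)
    orientation = np.where(defined, theta, np.nan)
    vs = bf.voxel_size if aggregation_factor == 1 else tuple(
        v * (aggregation_factor if i < 2 else 1) for i, v in enumerate(bf.voxel_size)
    )
    return Volume3D(orientation, voxel_size=vs), Volume3D(anis, voxel_size=vs)


def vessel_density(
    state: AlignmentState,
    smoothing_sigma_um: float = 400.0,
    vessel_masks: dict | None = None,
) -> Volume3D:
    """3D vessel volume-fraction map on the blockface grid.

    Detected vessel masks of every stain are warped into blockface space
    (nearest-neighbor), accumulated per voxel, divided by the number of
    contributing sections at that slice, and smoothed with a normalized
    Gaussian (integral-preserving).  Values lie in [0, 1].
    """
    bf = state.blockface
    nz = bf.n_slices
    shape = bf.voxels.shape[1:]
    acc = np.zeros((nz, *shape))
    count = np.zeros(nz)
    for key, st in sorted(state.sections.items()):
        z, stain = key
        if vessel_masks is not None:
            vm = vessel_masks.get(key)
            if vm is None:
                continue
            t = st.best_transform if st.best_transform is not None else st.transform
            warped = apply_transform(np.asarray(vm, dtype=np.float64), t, order=0, cval=0.0)
        else:
            if st.features is None:
                continue
            warped = st.features.vessel_mask.astype(np.float64)  # already on blockface grid
        acc[z] += warped
        count[z] += 1
    if acc.sum() == 0:
        log.warning("vessel_density: no vessels detected anywhere; returning zero map")
    nzslices = count > 0
    acc[nzslices] /= count[nzslices, None, None]
    if smoothing_sigma_um > 0:
        sig = [smoothing_sigma_um / v for v in (bf.voxel_size[2], bf.voxel_size[1], bf.voxel_size[0])]
        acc = ndi.gaussian_filter(acc, sig)
    return Volume3D(np.clip(acc, 0.0, 1.0), voxel_size=bf.voxel_size)


def density_ridge(density: Volume3D) -> dict:
    """Per-slice intensity-weighted ridge position of a density map.

    Returns ``z -> (y, x)`` of the centroid of the top-decile density; used
    to compare a reconstructed tube against its true centerline.
    """
    out = {}
    for z in range(density.n_slices):
        plane = density.voxels[z]
        if plane.max() <= 0:
            continue
        thr = np.quantile(plane[plane > 0], 0.9)
        sel = plane >= thr
        ys, xs = np.nonzero(sel)
        w = plane[sel]
        out[z] = (float(np.average(ys, weights=w)), float(np.average(xs, weights=w)))
    return out
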