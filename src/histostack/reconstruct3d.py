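"""Assembly of registered sections into multi-contrast 3D volumes.

Two post-registration steps happen here: (1) linear interslice intensity
matching, which removes slow staining-session drift with a per-slice gain
and offset chained along z (a deliberately restrained model that preserves
each stain's dynamic range), and (2) guided nonlocal-means interpolation of
the slices a stain did not sample, where each missing pixel is a weighted
average of the same channel's measured slices nearby and the weights come
from patch similarity in a fully-sampled guide volume (the blockface by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .io import Volume3D, mask_background
from .register2d import apply_transform
from .stackalign import AlignmentState

log = logging.getLogger("histostack")

MEASURED, INTERPOLATED, MISSING = "measured", "interpolated", "missing"


@dataclass
class MultiContrastVolume:
    """Co-registered per-stain volumes on the common blockface grid."""

    channels: dict = field(default_factory=dict)  # stain -> Volume3D
    provenance: dict = field(default_factory=dict)  # stain -> list of flags per z
    intensity_params: dict = field(default_factory=dict)  # stain -> list of (gain, offset)


# ---------------------------------------------------------------------------
# intensity harmonization
# ---------------------------------------------------------------------------


def linear_intensity_match(
    channel: Volume3D | np.ndarray,
    measured_flags: list[bool] | np.ndarray,
    tissue_masks: np.ndarray | None = None,
    min_tissue_pixels: int = 100,
) -> tuple[Volume3D, list]:
    """Chain per-slice linear gain/offset corrections along z.

    Each measured slice is least-squares matched to its already-matched
    predecessor over their joint tissue support; the first measured slice is
    the untouched reference, so the chain preserves the channel's original
    dynamic range.  Returns the matched volume and per-slice ``(gain,
    offset)`` of the *forward drift model* ``I_z ~ gain * M_prev + offset``
    (identity ``(1, 0)`` for reference/unmatched slices).
    """
    vox = channel.voxels if isinstance(channel, Volume3D) else np.asarray(channel, dtype=float)
    vsize = channel.voxel_size if isinstance(channel, Volume3D) else (1.0, 1.0, 1.0)
    flags = np.asarray(measured_flags, dtype=bool)
    measured = np.flatnonzero(flags)
    if len(measured) < 2:
        raise ValueError("need at least two measured slices to match intensities")
    out = np.array(vox, dtype=np.float64, copy=True)
    params: list[tuple[float, float]] = [(1.0, 0.0)] * vox.shape[0]
    prev = None
    for z in measured:
        if prev is None:
            prev = z
            continue
        if tissue_masks is not None:
            sel = np.asarray(tissue_masks[z], dtype=bool) & np.asarray(tissue_masks[prev], dtype=bool)
        else:
            sel = _auto_tissue(out[z]) & _auto_tissue(out[prev])
        if sel.sum() < min_tissue_pixels:
            log.warning("slice %d: only %d joint tissue pixels, passed through unmatched", z, int(sel.sum()))
            prev = z
            continue
        x = out[z][sel]
        y = out[prev][sel]  # predecessor is already matched
        # symmetric (reduced major axis) fit: both slices are noisy, and an
        # ordinary regression would attenuate the gain toward zero
        sx, sy = x.std(), y.std()
        if sx < 1e-12:
            log.warning("slice %d: constant tissue intensities, passed through", z)
            prev = z
            continue
        sign = 1.0 if np.corrcoef(x, y)[0, 1] >= 0 else -1.0
        a = sign * sy / sx
        b = y.mean() - a * x.mean()
        out[z] = a * out[z] + b
        # forward drift model: I_z = gain * M_prev + offset
        params[z] = (1.0 / a, -b / a)
        prev = z
    return Volume3D(out, voxel_size=vsize), params


def _auto_tissue(plane: np.ndarray) -> np.ndarray:
    try:
        return mask_background(plane).mask
    except ValueError:
        return np.zeros(plane.shape, dtype=bool)


def interslice_jump(channel: Volume3D | np.ndarray, measured_flags, tissue_masks=None) -> float:
    """Mean |mean pixel-wise intensity step| between consecutive measured slices.

    The statistic is the absolute mean of the pixel-wise difference over the
    joint tissue support — the component a per-slice gain/offset can remove;
    anatomy-driven pixel differences average out.
    """
    vox = channel.voxels if isinstance(channel, Volume3D) else np.asarray(channel, dtype=float)
    measured = np.flatnonzero(np.asarray(measured_flags, dtype=bool))
    jumps = []
    for z0, z1 in zip(measured[:-1], measured[1:]):
        if tissue_masks is not None:
            m0, m1 = np.asarray(tissue_masks[z0], bool), np.asarray(tissue_masks[z1], bool)
        else:
            m0, m1 = _auto_tissue(vox[z0]), _auto_tissue(vox[z1])
        joint = m0 & m1
        if joint.any():
            jumps.append(abs((vox[z1][joint] - vox[z0][joint]).mean()))
    return float(np.mean(jumps)) if jumps else float("nan")


# ---------------------------------------------------------------------------
# nonlocal-means interpolation
# ---------------------------------------------------------------------------


def nlm_slice_weights(
    guide: np.ndarray,
    z: int,
    candidates: list[int],
    patch_radius: int = 2,
    h: float | None = None,
) -> np.ndarray:
    """Per-pixel normalized weights of each candidate slice for slice ``z``.

    Weight of candidate ``z'`` at pixel ``p`` is
    ``exp(-||G(z, patch around p) - G(z', patch around p)||^2 / h^2)``,
    normalized to sum 1 over candidates.  ``h`` defaults to the square root
    of the median patch distance (an adaptive, deterministic bandwidth).
    """
    size = 2 * patch_radius + 1
    d2 = np.stack(
        [
            ndi.uniform_filter((guide[z] - guide[zc]) ** 2, size=size, mode="nearest")
            for zc in candidates
        ]
    )
    # shift by the per-pixel best distance: numerically stable (softmax
    # style) and makes the weighting relative, not absolute
    d2 = d2 - d2.min(axis=0)
    if h is None:
        pos = d2[d2 > 0]
        h2 = max(float(np.median(pos)) if pos.size else 1.0, 1e-12)
    else:
        h2 = max(float(h) ** 2, 1e-12)
    w = np.exp(-d2 / h2)
    return w / w.sum(axis=0)


def nlm_interpolate(
    channel: Volume3D | np.ndarray,
    guide: Volume3D | np.ndarray,
    measured_flags,
    patch_radius: int = 2,
    search_depth: int = 3,
    h: float | None = None,
) -> tuple[Volume3D, list]:
    """Fill unmeasured slices by guided nonlocal-means along z.

    Each missing-slice pixel is the weight-normalized average of the same
    pixel in measured slices within ``search_depth``, weighted by patch
    similarity of the guide volume.  Gaps wider than the search depth on
    both sides fall back to the nearest measured slice and are flagged
    ``missing``.
    """
    vox = channel.voxels if isinstance(channel, Volume3D) else np.asarray(channel, dtype=float)
    vsize = channel.voxel_size if isinstance(channel, Volume3D) else (1.0, 1.0, 1.0)
    gvox = guide.voxels if isinstance(guide, Volume3D) else np.asarray(guide, dtype=float)
    if gvox.shape != vox.shape:
        raise ValueError("guide and channel must share the grid")
    flags = np.asarray(measured_flags, dtype=bool)
    measured = np.flatnonzero(flags)
    if len(measured) == 0:
        raise ValueError("channel has no measured slices")
    out = np.array(vox, dtype=np.float64, copy=True)
    provenance = [MEASURED if flags[z] else INTERPOLATED for z in range(vox.shape[0])]
    for z in range(vox.shape[0]):
        if flags[z]:
            continue
        cands = [int(zc) for zc in measured if abs(int(zc) - z) <= search_depth]
        if not cands:
            nearest = int(measured[np.argmin(np.abs(measured - z))])
            out[z] = vox[nearest]
            provenance[z] = MISSING
            log.warning("slice %d: gap exceeds search depth, copied nearest measured slice %d", z, nearest)
            continue
        w = nlm_slice_weights(gvox, z, cands, patch_radius=patch_radius, h=h)
        out[z] = (w * np.stack([vox[zc] for zc in cands])).sum(axis=0)
    return Volume3D(out, voxel_size=vsize), provenance


def linear_z_interpolate(channel: np.ndarray, measured_flags) -> np.ndarray:
    """Plain linear interpolation along z between measured slices (baseline)."""
    vox = np.asarray(channel, dtype=np.float64)
    flags = np.asarray(measured_flags, dtype=bool)
    measured = np.flatnonzero(flags)
    out = np.array(vox, copy=True)
    for z in range(vox.shape[0]):
        if flags[z]:
            continue
        lo = measured[measured < z]
        hi = measured[measured > z]
        if len(lo) == 0:
            out[z] = vox[hi[0]]
        elif len(hi) == 0:
            out[z] = vox[lo[-1]]
        else:
            z0, z1 = int(lo[-1]), int(hi[0])
            a = (z - z0) / (z1 - z0)
            out[z] = (1 - a) * vox[z0] + a * vox[z1]
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble(
    state: AlignmentState,
    patch_radius: int = 2,
    search_depth: int = 3,
    h: float | None = None,
    intensity_match: bool = True,
    background: float | None = None,
) -> MultiContrastVolume:
    """Build per-stain volumes on the blockface grid from a completed alignment.

    Each measured section is resampled exactly once through its final (best)
    transform; channels are then intensity-matched and their sampling gaps
    NLM-interpolated with the blockface as guide.  Voxels outside the
    blockface tissue mask are set to the channel background.
    """
    bf = state.blockface
    nz = bf.n_slices
    stains = sorted({k[1] for k in state.sections})
    out = MultiContrastVolume()
    bf_masks = np.stack([_auto_tissue(bf.voxels[z]) for z in range(nz)])
    for stain in stains:
        vol = np.zeros(bf.voxels.shape, dtype=np.float64)
        flags = np.zeros(nz, dtype=bool)
        bgs = []
        for (z, s), st in sorted(state.sections.items()):
            if s != stain or st.failed:
                continue
            t = st.best_transform if st.best_transform is not None else st.transform
            vol[z] = apply_transform(st.section.pixels, t, cval=background)
            flags[z] = True
            border = np.ones(st.section.pixels.shape, bool)
            border[1:-1, 1:-1] = False
            bgs.append(float(np.median(st.section.pixels[border])))
        bg = background if background is not None else (float(np.median(bgs)) if bgs else 0.0)
        vol[~flags] = bg
        params: list = [(1.0, 0.0)] * nz
        channel = Volume3D(vol, voxel_size=bf.voxel_size)
        if intensity_match and flags.sum() >= 2:
            channel, params = linear_intensity_match(channel, flags, tissue_masks=bf_masks)
        channel, provenance = nlm_interpolate(
            channel, bf, flags, patch_radius=patch_radius, search_depth=search_depth, h=h
        )
        vox = channel.voxels
        vox[~bf_masks] = bg
        out.channels[stain] = Volume3D(vox, voxel_size=bf.voxel_size)
        out.provenance[stain] = provenance
        out.intensity_params[stain] = params
    return out
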