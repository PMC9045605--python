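"""Boundary and vessel feature maps.

Both maps are derived from the background/foreground separation of a
section: the boundary map is a Gaussian of the distance to the tissue
contour (giving the registration metric a smooth capture range around the
brain border), and vessel candidates are small round interior holes —
background-intensity components enclosed by tissue.  Ventricle-scale holes
are rejected by the radius filter, tears by the solidity filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label, regionprops

from .io import SectionImage, TissueMask

log = logging.getLogger("histostack")


@dataclass
class FeatureMaps:
    """Registration/QC features of one section."""

    boundary_map: np.ndarray
    vessel_mask: np.ndarray
    vessel_centroids: list = field(default_factory=list)  # (y, x) pixel coords


def boundary_map(mask: TissueMask | np.ndarray, decay_sigma: float = 5.0) -> np.ndarray:
    """``exp(-d^2 / 2 sigma^2)`` of the unsigned distance to the mask contour.

    ``decay_sigma`` is in pixels (default 5, about one blockface millimeter).
    The map is exactly 1 on contour pixels and decays monotonically away
    from the contour on both sides.
    """
    m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot compute a boundary map of an empty mask")
    contour = m & ~ndi.binary_erosion(m, border_value=0)
    if not contour.any():  # mask fills the whole raster
        raise ValueError("mask has no contour inside the raster")
    d = ndi.distance_transform_edt(~contour)
    return np.exp(-(d**2) / (2.0 * decay_sigma**2))


def contour_pixels(mask: TissueMask | np.ndarray) -> np.ndarray:
    """Boolean raster of the one-pixel-wide tissue contour."""
    m = mask.mask if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    return m & ~ndi.binary_erosion(m, border_value=0)


def detect_vessels(
    section: SectionImage | np.ndarray,
    mask: TissueMask,
    radius_range: tuple[float, float] = (1.5, 5.0),
    min_solidity: float = 0.8,
) -> tuple[np.ndarray, list]:
    """Detect vessel cross-sections among the interior holes of a mask.

    A hole qualifies as a vessel when its equivalent radius lies in
    ``radius_range`` and its solidity is at least ``min_solidity``;
    centroids are intensity-weighted (darker-than-surround holes weigh by
    background proximity) and returned as ``(y, x)`` pixel coordinates.
    """
    pixels = section.pixels if isinstance(section, SectionImage) else np.asarray(section, dtype=np.float64)
    holes = mask.holes
    vessel_mask = np.zeros_like(holes)
    centroids: list[tuple[float, float]] = []
    if not holes.any():
        return vessel_mask, centroids
    r_lo, r_hi = radius_range
    lab = cc_label(holes, connectivity=2)
    # weight pixels by how background-like they are: vessels render at
    # background intensity, so invert the deviation from the hole minimum
    for prop in regionprops(lab):
        r_eq = np.sqrt(prop.area / np.pi)
        if not (r_lo <= r_eq <= r_hi):
            continue
        if prop.solidity < min_solidity:
            continue
        sel = lab == prop.label
        vessel_mask |= sel
        vals = pixels[sel]
        w = 1.0 / (1.0 + np.abs(vals - np.median(vals)))
        ys, xs = np.nonzero(sel)
        cy = float(np.average(ys, weights=w))
        cx = float(np.average(xs, weights=w))
        centroids.append((cy, cx))
    return vessel_mask, centroids


def extract_features(
    section: SectionImage | np.ndarray,
    mask: TissueMask,
    decay_sigma: float = 5.0,
    radius_range: tuple[float, float] = (1.5, 5.0),
) -> FeatureMaps:
    """Boundary map plus vessel detection for one section."""
    bmap = boundary_map(mask, decay_sigma=decay_sigma)
    vmask, cents = detect_vessels(section, mask, radius_range=radius_range)
    return FeatureMaps(bmap, vmask, cents)


def match_f1(detected: list, truth: list, tol: float = 2.0) -> float:
    """F1 score of detected centroids against ground-truth centroids.

    Greedy one-to-one matching within ``tol`` pixels.
    """
    if not detected and not truth:
        return 1.0
    if not detected or not truth:
        return 0.0
    det = np.asarray(detected, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    d = np.sqrt(((det[:, None, :] - tru[None, :, :]) ** 2).sum(-1))
    pairs = []
    used_d: set[int] = set()
    used_t: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if d[i, j] > tol:
            break
        if i in used_d or j in used_t:
            continue
        pairs.append((i, j))
        used_d.add(i)
        used_t.add(j)
    tp = len(pairs)
    prec = tp / len(detected)
    rec = tp / len(truth)
    return 0.0 if tp == 0 else 2 * prec * rec / (prec + rec)
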