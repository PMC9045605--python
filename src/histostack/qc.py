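"""Quantitative QC of the reconstruction: interslice feature distances.

After alignment, the tissue boundary and the vessel cross-sections of
consecutive sections should nearly coincide: the residual distances, within
and across stains, measure registration quality directly on the microscopy
features.  The boundary statistic is the symmetric mean contour distance
(Hausdorff reported as a secondary column); vessel agreement is the mean
distance of mutually-nearest matched centroids.  Blockface features are
excluded from QC since the blockface background separation is unreliable
for fine detail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .features import contour_pixels
from .io import mask_background
from .stackalign import AlignmentState

log = logging.getLogger("histostack")


@dataclass
class QCSummary:
    records: pd.DataFrame
    per_marker_mean_um: dict
    across_marker_mean_um: float
    flagged: list  # (slice_index, stain_pair) with boundary distance > threshold


def boundary_distance(contour_a: np.ndarray, contour_b: np.ndarray, pixel_size: float = 1.0) -> float:
    """Symmetric mean contour distance in micrometers.

    For each contour pixel the distance to the nearest pixel of the other
    contour is taken; the two directed means are averaged.
    """
    a = np.asarray(contour_a, dtype=bool)
    b = np.asarray(contour_b, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("both contours must be non-empty")
    d_to_b = ndi.distance_transform_edt(~b)
    d_to_a = ndi.distance_transform_edt(~a)
    ab = d_to_b[a].mean()
    ba = d_to_a[b].mean()
    return float(0.5 * (ab + ba) * pixel_size)


def hausdorff_distance(contour_a: np.ndarray, contour_b: np.ndarray, pixel_size: float = 1.0) -> float:
    """Symmetric Hausdorff distance between two contours, micrometers."""
    a = np.asarray(contour_a, dtype=bool)
    b = np.asarray(contour_b, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("both contours must be non-empty")
    d_to_b = ndi.distance_transform_edt(~b)
    d_to_a = ndi.distance_transform_edt(~a)
    return float(max(d_to_b[a].max(), d_to_a[b].max()) * pixel_size)


def vessel_distance(
    centroids_a: list,
    centroids_b: list,
    max_match: float = np.inf,
    pixel_size: float = 1.0,
) -> tuple[float, int]:
    """Mean distance of mutually-nearest matched centroids (um), plus count.

    Matching is greedy on mutual nearest neighbors under ``max_match``
    (given in micrometers); with no matches the distance is NaN.
    """
    if not centroids_a or not centroids_b:
        return float("nan"), 0
    a = np.asarray(centroids_a, dtype=np.float64)
    b = np.asarray(centroids_b, dtype=np.float64)
    ta, tb = cKDTree(a), cKDTree(b)
    d_ab, j_ab = tb.query(a)  # nearest b for each a
    d_ba, j_ba = ta.query(b)
    dists = []
    for i in range(len(a)):
        j = j_ab[i]
        if j_ba[j] == i and d_ab[i] * pixel_size <= max_match:
            dists.append(d_ab[i] * pixel_size)
    if not dists:
        return float("nan"), 0
    return float(np.mean(dists)), len(dists)


def qc_profile(
    state: AlignmentState,
    threshold_um: float = 2000.0,
    vessel_max_match_um: float = 2000.0,
) -> QCSummary:
    """Interslice distance profile of a completed reconstruction.

    For each pair of consecutive measured sections (nearest neighbors within
    a marker, and nearest any-marker neighbors across markers) the symmetric
    mean boundary distance and the matched vessel-centroid distance are
    recorded; slices whose boundary distance exceeds ``threshold_um``
    (default 2 mm, the scale of genuinely missing structure) are flagged.
    """
    px = state.blockface.voxel_size[0]
    by_key = {}
    for key, st in sorted(state.sections.items()):
        if st.failed:
            continue
        try:
            m = mask_background(st.resampled)
        except ValueError:
            log.info("qc: slice %s has no separable tissue, skipped", key)
            continue
        cont = contour_pixels(m)
        cents = st.features.vessel_centroids if st.features is not None else []
        by_key[key] = (cont, cents)

    rows = []

    def record(key_a, key_b, kind):
        ca, va = by_key[key_a]
        cb, vb = by_key[key_b]
        if not ca.any() or not cb.any():
            return
        bd = boundary_distance(ca, cb, px)
        hd = hausdorff_distance(ca, cb, px)
        vd, nm = vessel_distance(va, vb, max_match=vessel_max_match_um, pixel_size=px)
        rows.append(
            {
                "slice_index": key_a[0],
                "stain_a": key_a[1],
                "stain_b": key_b[1],
                "slice_b": key_b[0],
                "pair_kind": kind,
                "boundary_distance_um": bd,
                "hausdorff_um": hd,
                "vessel_distance_um": vd,
                "n_vessel_matches": nm,
            }
        )

    keys = sorted(by_key)
    # within marker: consecutive measured slices of the same stain
    stains = sorted({k[1] for k in keys})
    for stain in stains:
        zs = [k[0] for k in keys if k[1] == stain]
        for z0, z1 in zip(zs[:-1], zs[1:]):
            record((z0, stain), (z1, stain), "within")
    # across markers: each section vs the nearest later section of a different stain
    for key in keys:
        z, stain = key
        later = [k for k in keys if k[0] > z and k[1] != stain]
        if later:
            nxt = min(later, key=lambda k: (k[0], k[1]))
            record(key, nxt, "across")

    df = pd.DataFrame(rows)
    if df.empty:
        return QCSummary(df, {}, float("nan"), [])
    within = df[df.pair_kind == "within"]
    per_marker = {s: float(g.boundary_distance_um.mean()) for s, g in within.groupby("stain_a")}
    across = df[df.pair_kind == "across"]
    across_mean = float(across.boundary_distance_um.mean()) if len(across) else float("nan")
    flagged = [
        (int(r.slice_index), (r.stain_a, r.stain_b))
        for r in df.itertuples()
        if r.boundary_distance_um > threshold_um
    ]
    return QCSummary(df, per_marker, across_mean, flagged)


def plot_profile(summary: QCSummary, out_path=None):
    """Distance-vs-slice plot per marker with mean lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    df = summary.records
    within = df[df.pair_kind == "within"]
    for stain, g in within.groupby("stain_a"):
        g = g.sort_values("slice_index")
        ax.plot(g.slice_index, g.boundary_distance_um, marker=".", label=stain)
        ax.axhline(summary.per_marker_mean_um[stain], ls="--", lw=0.8, alpha=0.6)
    ax.set_xlabel("slice index")
    ax.set_ylabel("interslice boundary distance (μm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
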