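"""Pairwise deformable registration driven by mutual information.

The engine aligns a moving raster to one or more weighted fixed targets by
maximizing the weighted sum of mutual-information (MI) terms.  Optimization
is coarse-to-fine over a geometric scale pyramid; at the coarsest retained
level a global affine (translation + rotation) is estimated first, after
which a dense displacement field is refined by Gaussian-regularized
demons-style ascent.

Cross-contrast forces are obtained by remapping the warped moving image
through the conditional mean of the target intensity given the moving
intensity (a correlation-ratio-style transfer function, re-estimated every
iteration).  This makes the force term invariant to arbitrary intensity
lookups between the images, which is the property MI provides for the
metric itself; MI proper is used to score iterates and select the best one.

All transforms use the pull-back convention: ``map(x)`` gives, for each
output-grid coordinate ``x``, the coordinate in the input raster to sample.
The total map is ``affine o (identity + field)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize
from skimage.measure import block_reduce
from skimage.registration import phase_cross_correlation

log = logging.getLogger("histostack")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def _identity_affine(ndim: int) -> np.ndarray:
    return np.hstack([np.eye(ndim), np.zeros((ndim, 1))])


@dataclass
class Transform2D:
    """Affine + dense displacement field on the fixed (output) grid.

    ``affine`` is 2x3 acting on homogeneous ``(y, x, 1)`` index coordinates;
    ``field`` has shape ``(2, ny, nx)`` with components along the array axes,
    in pixels.  Total map: ``x -> affine @ (x + field(x), 1)``.
    """

    affine: np.ndarray = None  # type: ignore[assignment]
    field: np.ndarray = None  # type: ignore[assignment]
    shape: tuple = None  # type: ignore[assignment]
    meta: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.field is not None:
            self.field = np.asarray(self.field, dtype=np.float64)
            if self.shape is None:
                self.shape = self.field.shape[1:]
        if self.shape is None:
            raise ValueError("shape required when no field is given")
        self.shape = tuple(int(n) for n in self.shape)
        ndim = len(self.shape)
        if self.affine is None:
            self.affine = _identity_affine(ndim)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.field is None:
            self.field = np.zeros((ndim, *self.shape))
        if self.field.shape != (ndim, *self.shape):
            raise ValueError("field shape must be (ndim, *grid)")

    @classmethod
    def identity(cls, shape) -> "Transform2D":
        return cls(shape=tuple(shape))

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def map_coordinates_grid(self) -> np.ndarray:
        """Mapped input coordinates for every output-grid point, ``(ndim, *grid)``."""
        grid = np.indices(self.shape, dtype=np.float64)
        p = grid + self.field
        lin = self.affine[:, :-1]
        off = self.affine[:, -1]
        out = np.tensordot(lin, p, axes=(1, 0))
        return out + off.reshape((-1,) + (1,) * len(self.shape))

    def displacement(self) -> np.ndarray:
        """Total displacement (mapped minus identity) per output-grid point."""
        return self.map_coordinates_grid() - np.indices(self.shape, dtype=np.float64)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            np.allclose(self.affine, _identity_affine(self.ndim), atol=tol)
            and float(np.abs(self.field).max(initial=0.0)) <= tol
        )


# 3D shares the representation; volalign re-exports this alias.
Transform3D = Transform2D


def apply_transform(image: np.ndarray, t: Transform2D, order: int = 1, cval: float | None = None) -> np.ndarray:
    """Resample ``image`` through ``t`` (pull-back, linear by default).

    ``order=0`` gives the nearest-neighbor variant for masks and labels.
    Out-of-domain pixels are filled with ``cval`` (default: the image's
    border median, a robust background estimate).
    """
    image = np.asarray(image, dtype=np.float64)
    if cval is None:
        cval = border_value(image)
    coords = t.map_coordinates_grid()
    return ndi.map_coordinates(image, coords, order=order, mode="constant", cval=cval)


def border_value(image: np.ndarray) -> float:
    """Median intensity of the raster border, used as background fill."""
    border = np.ones(image.shape, dtype=bool)
    border[tuple(slice(1, -1) for _ in range(image.ndim))] = False
    return float(np.median(image[border]))


def compose(t1: Transform2D, t2: Transform2D) -> Transform2D:
    """Transform equivalent to applying ``t1`` to an image, then ``t2``.

    In pull-back terms the composed map is ``m1 o m2`` evaluated on ``t2``'s
    grid: ``apply(compose(t1, t2), im) == apply(t2, apply(t1, im))`` up to
    interpolation.  Grids must match in dimensionality.
    """
    if t1.ndim != t2.ndim:
        raise ValueError("cannot compose transforms of different dimensionality")
    q = t2.map_coordinates_grid()  # (ndim, *grid2) points in t1's output grid
    # evaluate t1's map at the (generally non-integer) points q
    u1_at_q = np.stack(
        [ndi.map_coordinates(t1.field[d], q, order=1, mode="nearest") for d in range(t1.ndim)]
    )
    p = q + u1_at_q
    lin = t1.affine[:, :-1]
    off = t1.affine[:, -1]
    mapped = np.tensordot(lin, p, axes=(1, 0)) + off.reshape((-1,) + (1,) * t2.ndim)
    grid = np.indices(t2.shape, dtype=np.float64)
    return Transform2D(field=mapped - grid, shape=t2.shape)


def invert(t: Transform2D, n_iter: int = 30, tol: float = 1e-3) -> Transform2D:
    """Numeric fixed-point inverse of a smooth transform.

    Iterates ``v <- -d(x + v)`` where ``d`` is the total displacement of
    ``t``; converges for fields with positive Jacobian.
    """
    d = t.displacement()
    ndim = t.ndim
    grid = np.indices(t.shape, dtype=np.float64)
    v = np.zeros_like(d)
    for _ in range(n_iter):
        coords = grid + v
        d_at = np.stack(
            [ndi.map_coordinates(d[k], coords, order=1, mode="nearest") for k in range(ndim)]
        )
        v_new = -d_at
        delta = float(np.abs(v_new - v).max())
        v = v_new
        if delta < tol:
            break
    return Transform2D(field=v, shape=t.shape)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32, support_mask: np.ndarray | None = None) -> float:
    """Histogram mutual information in bits.

    Equal-width bins over each image's observed range within the support.
    A constant image carries zero entropy, hence MI 0 (logged).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if support_mask is not None:
        sel = np.asarray(support_mask, dtype=bool)
        a, b = a[sel], b[sel]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size == 0 or np.ptp(a) == 0 or np.ptp(b) == 0:
        log.debug("mutual_information: constant image within support, MI = 0")
        return 0.0
    h, _, _ = np.histogram2d(a, b, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    h_joint = -np.sum(p[nz] * np.log2(p[nz]))
    h_x = -np.sum(px[px > 0] * np.log2(px[px > 0]))
    h_y = -np.sum(py[py > 0] * np.log2(py[py > 0]))
    return float(h_x + h_y - h_joint)


@dataclass
class WeightedTarget:
    """One fixed target for multi-target registration.

    ``moving`` optionally names the channel of the moving section that this
    target should be compared against (e.g., a boundary map is paired with
    the moving section's own boundary map); when ``None`` the main moving
    raster is used.  ``support_mask`` zeroes per-pixel metric and force
    contributions over unreliable regions.

    ``metric`` selects the similarity for this target: ``"mi"`` (mutual
    information, for cross-contrast intensity images) or ``"ncc"`` (Pearson
    correlation, for same-modality feature channels such as boundary maps,
    where a histogram metric on a mostly-flat raster is ill-behaved).
    """

    image: np.ndarray
    weight: float = 1.0
    support_mask: np.ndarray | None = None
    moving: np.ndarray | None = None
    metric: str = "mi"
    #: multiplier on this target's contribution to the ascent forces (its
    #: metric weight is unaffected); lets sharp feature channels steer the
    #: iterate selection without injecting ill-conditioned ridge forces
    force_scale: float = 1.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.weight < 0:
            raise ValueError("target weight must be nonnegative")
        if self.metric not in ("mi", "ncc"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class RegistrationParams:
    """Tunables of the pairwise engine (pixel units at each pyramid level)."""

    n_scales: int = 6
    coarsest_downsampling: int = 64
    mi_bins: int = 32
    smoothing_sigma_field: float = 3.0
    smoothing_sigma_fluid: float = 4.0
    iterations_per_scale: int = 60
    convergence_tol: float = 1e-4
    step_size: float = 2.0
    do_affine: bool = True
    min_level_extent: int = 16
    # warm starts (non-identity init) skip the coarse levels already solved
    warm_scales: int = 2
    warm_iterations: int = 25

    def scale_factors(self, shape) -> list[int]:
        """Geometric pyramid ``coarsest, coarsest/2, ..., 2, 1`` truncated so
        that every level keeps at least ``min_level_extent`` pixels per axis
        and at most ``n_scales`` levels remain (coarsest dropped first)."""
        factors = []
        f = self.coarsest_downsampling
        while f > 1:
            factors.append(f)
            f //= 2
        factors.append(1)
        keep = [f for f in factors if min(shape) // f >= self.min_level_extent]
        if not keep:
            keep = [1]
        keep = keep[-self.n_scales:]
        if len(keep) < len(factors):
            log.debug(
                "scale schedule truncated from %s to %s for shape %s", factors, keep, tuple(shape)
            )
        return keep

    def bins_for(self, n_pixels: int) -> int:
        """Histogram bins shrink on small grids to keep counts meaningful."""
        return int(min(self.mi_bins, max(8, np.sqrt(n_pixels) / 4)))


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------


def conditional_mean_remap(moving: np.ndarray, target: np.ndarray, bins: int = 32, support: np.ndarray | None = None) -> np.ndarray:
    """Remap ``moving`` intensities to the conditional mean of ``target``.

    Estimates E[target | moving] on equal-width bins of the moving range and
    applies the resulting lookup; empty bins are filled by linear
    interpolation between populated neighbors.
    """
    m = moving.ravel()
    t = target.ravel()
    if support is not None:
        s = support.ravel() > 0
    else:
        s = np.ones(m.shape, dtype=bool)
    lo, hi = float(m[s].min(initial=0.0)), float(m[s].max(initial=1.0))
    if hi <= lo:
        return np.full_like(moving, float(t[s].mean()) if s.any() else 0.0)
    idx = np.clip(((m - lo) / (hi - lo) * bins).astype(np.intp), 0, bins - 1)
    counts = np.bincount(idx[s], minlength=bins).astype(np.float64)
    sums = np.bincount(idx[s], weights=t[s], minlength=bins)
    populated = counts > 0
    means = np.zeros(bins)
    means[populated] = sums[populated] / counts[populated]
    if not populated.all():
        xs = np.flatnonzero(populated)
        means = np.interp(np.arange(bins), xs, means[xs])
    return means[idx].reshape(moving.shape)


def normalized_correlation(a: np.ndarray, b: np.ndarray, support_mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two rasters over the support, in [-1, 1]."""
    if support_mask is not None:
        sel = np.asarray(support_mask, dtype=bool)
        a, b = a[sel], b[sel]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom <= 0:
        return 0.0
    return float((a * b).sum() / denom)


def _target_similarity(warped: np.ndarray, tgt: WeightedTarget, bins: int) -> float:
    if tgt.metric == "ncc":
        return normalized_correlation(tgt.image, warped, support_mask=tgt.support_mask)
    return mutual_information(tgt.image, warped, bins=bins, support_mask=tgt.support_mask)


def _weighted_metric(warped_channels, targets, bins) -> float:
    num = 0.0
    den = 0.0
    for w, tgt in zip(warped_channels, targets):
        if tgt.weight == 0:
            continue
        num += tgt.weight * _target_similarity(w, tgt, bins)
        den += tgt.weight
    return num / den if den > 0 else 0.0


def _normalize(img: np.ndarray) -> tuple[np.ndarray, float]:
    lo, hi = np.percentile(img, [1, 99])
    rng = max(hi - lo, 1e-9)
    return (img - lo) / rng, rng


def _demons_level(
    moving_channels: list[np.ndarray],
    targets: list[WeightedTarget],
    channel_of_target: list[int],
    field: np.ndarray,
    params: RegistrationParams,
    cvals: list[float],
) -> tuple[np.ndarray, list[float]]:
    """Demons refinement of ``field`` at a single pyramid level.

    Returns the best field found (by weighted MI) and the metric trace.
    """
    ndim = field.shape[0]
    grid = np.indices(field.shape[1:], dtype=np.float64)
    trace: list[float] = []
    best_field = field.copy()
    best_metric = -np.inf
    wsum = sum(t.weight * t.force_scale for t in targets)
    if wsum <= 0:
        wsum = 1.0
    bins = params.bins_for(field[0].size)
    target_norms = [_normalize(t.image)[0] for t in targets]
    target_grads = [np.gradient(tn) for tn in target_norms]
    gain = 1.0  # trust-region style step gain, shrinks when the metric drops
    for it in range(params.iterations_per_scale):
        coords = grid + field
        warped = [
            ndi.map_coordinates(ch, coords, order=1, mode="constant", cval=cv)
            for ch, cv in zip(moving_channels, cvals)
        ]
        metric = _weighted_metric([warped[c] for c in channel_of_target], targets, bins)
        trace.append(metric)
        if metric > best_metric:
            best_metric = metric
            best_field = field.copy()
        if it > 2 and all(x < best_metric - 1e-3 for x in trace[-3:]):
            # three consecutive iterates below the best: shrink the step
            gain = max(gain * 0.7, 0.05)
        # early stop once the metric plateaus
        if it >= 3 and abs(trace[-1] - trace[-4]) < params.convergence_tol * max(abs(trace[-4]), 1e-9):
            break
        force = np.zeros_like(field)
        for ti, (tgt, ci) in enumerate(zip(targets, channel_of_target)):
            if tgt.weight * tgt.force_scale == 0:
                continue
            w = warped[ci]
            if tgt.metric == "ncc":
                # same-modality channel: direct residual forces
                rn, _ = _normalize(w)
            else:
                remap = conditional_mean_remap(w, tgt.image, bins=bins, support=tgt.support_mask)
                rn, _ = _normalize(remap)
            tn = target_norms[ti]
            diff = tn - rn
            if tgt.support_mask is not None:
                diff = diff * (np.asarray(tgt.support_mask) > 0)
            # symmetric (ESM-style) forces: average moving and fixed gradients
            grads = [0.5 * (gm + gf) for gm, gf in zip(np.gradient(rn), target_grads[ti])]
            gsq = sum(g * g for g in grads)
            denom = gsq + diff * diff + 1e-12
            step = np.stack([diff * g / denom for g in grads])
            # equal-contribution weighting: normalize each source's force
            # scale before mixing so no single channel dominates by raw
            # gradient magnitude
            # equal-contribution weighting: normalize each source's force
            # scale before mixing so no single channel dominates by raw
            # gradient magnitude
            mag = np.sqrt((step**2).sum(axis=0))
            scale = float(np.percentile(mag, 95))
            if scale > 1e-9:
                step = step / scale
            force += (tgt.weight * tgt.force_scale / wsum) * step
        for d in range(ndim):
            force[d] = ndi.gaussian_filter(force[d], params.smoothing_sigma_fluid)
        norm = np.sqrt((force**2).sum(axis=0))
        peak = float(norm.max())
        if peak > 1e-9:
            # normalize the peak step to step_size: demons-normalized forces
            # are bounded by construction, so amplification (not only
            # capping) is needed for brisk convergence; the gain backs the
            # step off when the metric stops improving
            force *= gain * params.step_size / peak
        # compositive update: u'(x) = delta(x) + u(x + delta(x))
        coords_d = grid + force
        field = force + np.stack(
            [ndi.map_coordinates(field[d], coords_d, order=1, mode="nearest") for d in range(ndim)]
        )
        for d in range(ndim):
            field[d] = ndi.gaussian_filter(field[d], params.smoothing_sigma_field)
    return best_field, trace


def _downsample(img: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return np.asarray(img, dtype=np.float64)
    pad = [(0, (-s) % f) for s in img.shape]
    arr = np.pad(img, pad, mode="edge") if any(p[1] for p in pad) else img
    return block_reduce(np.asarray(arr, dtype=np.float64), (f,) * img.ndim, np.mean)


def _upsample_field(field: np.ndarray, factor: float, shape) -> np.ndarray:
    out = np.stack(
        [
            ndi.zoom(field[d], [s / c for s, c in zip(shape, field.shape[1:])], order=1, mode="nearest", grid_mode=True)
            for d in range(field.shape[0])
        ]
    )
    return out * factor


def _affine_stage(moving: np.ndarray, target: WeightedTarget, bins: int, max_rotation: float = 15.0) -> np.ndarray:
    """Global affine maximizing MI at one level.

    2D: translation + in-plane rotation; 3D: translation + Euler rotations
    + isotropic scale.  Initialized by phase correlation on the
    contrast-remapped moving image; refined with Powell.  Returns a dense
    displacement field equivalent on the level grid.
    """
    ndim = moving.ndim
    remap = conditional_mean_remap(moving, target.image, bins=bins)
    try:
        shift, _, _ = phase_cross_correlation(
            target.image, remap, upsample_factor=10, normalization=None
        )
    except Exception:  # degenerate inputs
        shift = np.zeros(ndim)
    center = (np.asarray(moving.shape, dtype=np.float64) - 1) / 2

    def make_map(par):
        if ndim == 2:
            th = np.deg2rad(par[0])
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            t = np.asarray(par[1:])
        else:
            # translation + Euler rotations + isotropic log-scale
            t = np.asarray(par[:3])
            az, ay, ax_ = np.deg2rad(par[3:6])
            ca, sa = np.cos(az), np.sin(az)
            cb, sb = np.cos(ay), np.sin(ay)
            cc, sc = np.cos(ax_), np.sin(ax_)
            rz = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            rx = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
            rot = np.exp(par[6]) * (rz @ ry @ rx)
        grid = np.indices(moving.shape, dtype=np.float64)
        rel = grid - center.reshape((-1,) + (1,) * ndim)
        p = np.tensordot(rot, rel, axes=(1, 0)) + center.reshape((-1,) + (1,) * ndim)
        return p + t.reshape((-1,) + (1,) * ndim)

    def neg_mi(par):
        coords = make_map(par)
        w = ndi.map_coordinates(moving, coords, order=1, mode="nearest")
        return -mutual_information(target.image, w, bins=bins, support_mask=target.support_mask)

    # pull-back: to shift the moving image by +s we sample at x - s
    if ndim == 2:
        x0 = np.concatenate([[0.0], -shift])
    else:
        x0 = np.concatenate([-np.asarray(shift, dtype=np.float64), [0.0, 0.0, 0.0, 0.0]])
    try:
        res = minimize(neg_mi, x0, method="Powell", options={"xtol": 0.05, "ftol": 1e-4, "maxiter": 200})
        par = res.x if res.fun <= neg_mi(x0) else x0
    except Exception:
        par = x0
    if ndim == 2 and abs(par[0]) > max_rotation:
        par = x0
    elif ndim == 3 and (np.abs(par[3:6]).max() > max_rotation or abs(par[6]) > 0.2):
        par = x0
    grid = np.indices(moving.shape, dtype=np.float64)
    if ndim == 3:
        # full 12-parameter refinement: a smooth bulk warp has substantial
        # shear/anisotropic-scale content that the similarity stage misses
        t = np.asarray(par[:3])
        az, ay, ax_ = np.deg2rad(par[3:6])
        ca, sa = np.cos(az), np.sin(az)
        cb, sb = np.cos(ay), np.sin(ay)
        cc, sc = np.cos(ax_), np.sin(ax_)
        rz = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rx = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        m0 = np.exp(par[6]) * (rz @ ry @ rx)

        def full_map(q):
            m = m0 + q[:9].reshape(3, 3)
            tt = t + q[9:]
            rel = grid - center.reshape((-1, 1, 1, 1))
            p = np.tensordot(m, rel, axes=(1, 0)) + center.reshape((-1, 1, 1, 1))
            return p + tt.reshape((-1, 1, 1, 1))

        def neg_mi_full(q):
            coords = full_map(q)
            w = ndi.map_coordinates(moving, coords, order=1, mode="nearest")
            return -_target_similarity(w, target, bins)

        q0 = np.zeros(12)
        try:
            res = minimize(
                neg_mi_full, q0, method="Powell",
                options={"xtol": 0.01, "ftol": 1e-5, "maxiter": 600},
            )
            q = res.x if res.fun <= neg_mi_full(q0) else q0
            if np.abs(q[:9]).max() > 0.3:  # implausible deformation: reject
                q = q0
        except Exception:
            q = q0
        return full_map(q) - grid
    return make_map(par) - grid


# ---------------------------------------------------------------------------
# public registration entry point
# ---------------------------------------------------------------------------


def register_pair(
    moving: np.ndarray,
    targets: list[WeightedTarget],
    params: RegistrationParams | None = None,
    init: Transform2D | None = None,
) -> Transform2D:
    """Deformable registration of ``moving`` onto weighted fixed ``targets``.

    Maximizes the weighted sum of per-target MI terms, coarse-to-fine; the
    returned transform carries a ``meta`` dict with the scale schedule and
    the full-resolution metric trace at each level's best iterate (a
    non-decreasing sequence, since the best transform is carried across
    levels).
    """
    params = params or RegistrationParams()
    moving = np.asarray(moving, dtype=np.float64)
    targets = [t for t in targets]
    if not any(t.weight > 0 for t in targets):
        raise ValueError("at least one target must have positive weight")
    shape = targets[0].image.shape
    for t in targets:
        if t.image.shape != shape:
            raise ValueError("all targets must share the fixed grid")
        if t.moving is not None and np.asarray(t.moving).shape != moving.shape:
            raise ValueError("paired moving channels must match the moving grid")

    # moving channels: channel 0 is the main raster; extra paired channels follow
    channels: list[np.ndarray] = [moving]
    channel_of_target: list[int] = []
    for t in targets:
        if t.moving is None:
            channel_of_target.append(0)
        else:
            channels.append(np.asarray(t.moving, dtype=np.float64))
            channel_of_target.append(len(channels) - 1)
    cvals = [border_value(ch) for ch in channels]

    factors = params.scale_factors(shape)
    warm = init is not None and not init.is_identity()
    if warm:
        factors = factors[-params.warm_scales:]
        params = replace(params, iterations_per_scale=params.warm_iterations, do_affine=False)
    meta: dict = {"scale_factors": factors, "trace": [], "level_traces": [], "warm_start": warm}

    field_prev: np.ndarray | None = None
    prev_factor: int | None = None
    best_full: tuple[float, np.ndarray] | None = None
    if warm:
        # the supplied initialization competes with every level's result, so
        # a warm restart can never end worse than it began (by the metric)
        init_field = init.displacement()
        warped_init = [
            apply_transform(ch, Transform2D(field=init_field, shape=shape), cval=cv)
            for ch, cv in zip(channels, cvals)
        ]
        metric_init = _weighted_metric([warped_init[c] for c in channel_of_target], targets, params.mi_bins)
        best_full = (metric_init, init_field)
    for li, f in enumerate(factors):
        lvl_shape = tuple(-(-s // f) for s in shape)
        lvl_channels = [_downsample(ch, f) for ch in channels]
        lvl_targets = []
        for t in targets:
            lvl_targets.append(
                WeightedTarget(
                    image=_downsample(t.image, f),
                    weight=t.weight,
                    support_mask=None
                    if t.support_mask is None
                    else _downsample(np.asarray(t.support_mask, dtype=np.float64), f) > 0.5,
                    metric=t.metric,
                    force_scale=t.force_scale,
                )
            )
        if field_prev is None:
            if warm:
                field = np.stack([_downsample(c, f) for c in init.displacement()]) / f
            else:
                field = np.zeros((len(shape), *lvl_shape))
            if params.do_affine and not warm:
                # run the affine search at a resolution where the histogram
                # metric is well conditioned (>= 24 px per axis), then
                # rescale the (linear) displacement onto this level's grid
                f_aff = f
                while f_aff > 1 and min(shape) // f_aff < 24:
                    f_aff //= 2
                if f_aff == f:
                    primary = max(lvl_targets, key=lambda t: t.weight)
                    field = field + _affine_stage(lvl_channels[0], primary, params.mi_bins)
                else:
                    pi = int(np.argmax([t.weight for t in targets]))
                    aff_target = WeightedTarget(
                        image=_downsample(targets[pi].image, f_aff),
                        support_mask=None
                        if targets[pi].support_mask is None
                        else _downsample(np.asarray(targets[pi].support_mask, dtype=np.float64), f_aff) > 0.5,
                        metric=targets[pi].metric,
                    )
                    aff_field = _affine_stage(_downsample(channels[0], f_aff), aff_target, params.mi_bins)
                    field = field + _upsample_field(aff_field, f_aff / f, lvl_shape)
        else:
            field = _upsample_field(field_prev, prev_factor / f, lvl_shape)
        field, trace = _demons_level(lvl_channels, lvl_targets, channel_of_target, field, params, cvals)
        meta["level_traces"].append(trace)
        # score this level's best at full resolution for a comparable trace
        full_field = _upsample_field(field, f, shape) if f != 1 else field
        t_full = Transform2D(field=full_field, shape=shape)
        warped_full = [apply_transform(ch, t_full, cval=cv) for ch, cv in zip(channels, cvals)]
        metric_full = _weighted_metric([warped_full[c] for c in channel_of_target], targets, params.mi_bins)
        if best_full is None or metric_full >= best_full[0]:
            best_full = (metric_full, full_field)
        meta["trace"].append(best_full[0])
        field_prev, prev_factor = field, f
    assert best_full is not None
    out = Transform2D(field=best_full[1], shape=shape)
    out.meta = meta
    if not np.all(np.isfinite(out.field)):
        raise FloatingPointError("registration produced a non-finite displacement field")
    return out


def endpoint_error(recovered: Transform2D, true: Transform2D, mask: np.ndarray | None = None) -> float:
    """Mean residual |true(recovered(x)) - x| in pixels over ``mask``.

    Zero when the recovered transform is the exact inverse of the true
    distortion (the composition is then the identity map).
    """
    comp = compose(true, recovered)
    disp = comp.displacement()
    mag = np.sqrt((disp**2).sum(axis=0))
    if mask is not None:
        mag = mag[np.asarray(mask, dtype=bool)]
    return float(mag.mean())
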