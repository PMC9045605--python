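"""Forward-backward, blockface-anchored alignment of a multi-stain stack.

Each stained section is registered not only to its own blockface photograph
(the geometric anchor, weight 1) but also to the nearest previously
coregistered section of the same stain plus its boundary map (weight 1/2
each) and the two nearest previously coregistered sections of any stain
plus their boundary maps (weight 1/4 each), all restricted to a sliding
window of three slices on the already-visited side of the sweep.  Because
each registration depends only on upstream results, the stack forms a
Markov-chain-like dependency that is solved by sweeping rostral->caudal and
back, several times; after every sweep each section reverts to its archived
best transform as scored by mutual information against the blockface, so
the archive is monotone and the anchor prevents the cumulative bending
("banana effect") of purely neighbor-driven schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMaps, boundary_map, detect_vessels
from .io import SectionImage, TissueMask, Volume3D, mask_background
from .register2d import (
    RegistrationParams,
    Transform2D,
    WeightedTarget,
    apply_transform,
    mutual_information,
    register_pair,
)

log = logging.getLogger("histostack")

#: paper-equal-contribution weights for the multi-target scheme
WEIGHT_BLOCKFACE = 1.0
WEIGHT_SAME_STAIN = 0.5
WEIGHT_ANY_STAIN = 0.25
#: sliding window (slices) for neighbor targets
NEIGHBOR_WINDOW = 3


@dataclass
class SectionState:
    """Mutable per-(slice, stain) registration state."""

    section: SectionImage  # original (distorted) raster on the blockface grid
    transform: Transform2D
    resampled: np.ndarray
    features: FeatureMaps | None = None
    mask: TissueMask | None = None
    moving_boundary: np.ndarray | None = None  # boundary map of the *moving* raster
    score: float = -np.inf  # MI vs blockface of the current resampling
    best_transform: Transform2D | None = None
    best_score: float = -np.inf
    failed: bool = False


@dataclass
class AlignmentState:
    """Whole-stack state: sections keyed by (slice_index, stain)."""

    blockface: Volume3D
    sections: dict = field(default_factory=dict)
    blockface_boundaries: dict = field(default_factory=dict)  # z -> boundary map
    iteration: int = 0
    sweep_log: list = field(default_factory=list)
    trace: list = field(default_factory=list)  # (iteration, direction, key, score)
    failures: list = field(default_factory=list)

    def keys_at(self, z: int) -> list:
        return [k for k in self.sections if k[0] == z]

    @property
    def mean_score(self) -> float:
        scores = [s.best_score for s in self.sections.values() if np.isfinite(s.best_score)]
        return float(np.mean(scores)) if scores else float("nan")


def initialize_state(
    blockface: Volume3D,
    sections: list[SectionImage],
    decay_sigma: float = 2.0,
    mi_bins: int = 32,
    initial_transforms: dict | None = None,
) -> AlignmentState:
    """Set up identity (or supplied) transforms and per-section features."""
    state = AlignmentState(blockface=blockface)
    for z in range(blockface.n_slices):
        try:
            bmask = mask_background(blockface.voxels[z])
            state.blockface_boundaries[z] = boundary_map(bmask, decay_sigma)
        except ValueError:
            state.blockface_boundaries[z] = None
    shape = blockface.voxels.shape[1:]
    for sec in sections:
        z = sec.slice_index
        if z >= blockface.n_slices:
            raise ValueError(f"section {z} has no blockface anchor (stack has {blockface.n_slices})")
        key = (z, sec.stain)
        t = (initial_transforms or {}).get(key) or Transform2D.identity(shape)
        st = SectionState(section=sec, transform=t, resampled=apply_transform(sec.pixels, t))
        try:
            st.mask = mask_background(sec.pixels)
            st.moving_boundary = boundary_map(st.mask, decay_sigma)
        except ValueError:
            st.mask = None
            st.moving_boundary = None
        _refresh(state, st, key, mi_bins, decay_sigma)
        st.best_transform = t
        st.best_score = st.score
        state.sections[key] = st
    return state


def _refresh(state: AlignmentState, st: SectionState, key, mi_bins: int, decay_sigma: float) -> None:
    """Recompute resampled raster, features and blockface MI for a section."""
    z, _ = key
    st.resampled = apply_transform(st.section.pixels, st.transform)
    st.score = mutual_information(state.blockface.voxels[z], st.resampled, bins=mi_bins)
    try:
        rmask = mask_background(st.resampled)
        bmap = boundary_map(rmask, decay_sigma)
        vmask, cents = detect_vessels(st.resampled, rmask)
        st.features = FeatureMaps(bmap, vmask, cents)
    except ValueError:
        st.features = None


def build_target_set(
    state: AlignmentState,
    slice_index: int,
    stain: str,
    direction: str,
    registered: set | None = None,
    blockface_weight: float = WEIGHT_BLOCKFACE,
) -> list[WeightedTarget]:
    """Weighted targets for registering one section during a sweep.

    ``registered`` holds the (slice, stain) keys already visited in the
    current sweep; only those count as "previously coregistered", and only
    within :data:`NEIGHBOR_WINDOW` slices on the sweep's upstream side.
    """
    z = slice_index
    if z >= state.blockface.n_slices:
        raise ValueError(f"no blockface image for slice {z}: the anchor is mandatory")
    registered = registered if registered is not None else set(state.sections)
    step = 1 if direction == "forward" else -1
    me = state.sections.get((z, stain))
    moving_bnd = me.moving_boundary if me is not None else None

    targets: list[WeightedTarget] = []
    if blockface_weight > 0:
        targets.append(WeightedTarget(state.blockface.voxels[z], weight=blockface_weight))

    def upstream(key) -> int | None:
        dz = (z - key[0]) * step  # positive if key is on the visited side
        if 0 < dz <= NEIGHBOR_WINDOW and key in registered and key != (z, stain):
            return dz
        return None

    candidates = [(upstream(k), k) for k in state.sections]
    candidates = sorted((d, k) for d, k in candidates if d is not None)

    def add_neighbor(key, weight):
        st = state.sections[key]
        targets.append(WeightedTarget(st.resampled, weight=weight))
        if st.features is not None and moving_bnd is not None:
            # boundary maps are same-modality features: correlation metric.
            # They steer the best-iterate selection only (force_scale 0):
            # thin-ridge forces from chained neighbors destabilize the
            # sweep, while intensity forces already carry the contour.
            targets.append(
                WeightedTarget(
                    st.features.boundary_map, weight=weight, moving=moving_bnd,
                    metric="ncc", force_scale=0.0,
                )
            )

    same = [(d, k) for d, k in candidates if k[1] == stain]
    chosen_same = same[0][1] if same else None
    if chosen_same is not None:
        add_neighbor(chosen_same, WEIGHT_SAME_STAIN)
    others = [(d, k) for d, k in candidates if k != chosen_same]
    for _, k in others[:2]:
        add_neighbor(k, WEIGHT_ANY_STAIN)
    return targets


def sweep(
    state: AlignmentState,
    direction: str,
    params: RegistrationParams | None = None,
    decay_sigma: float = 2.0,
    blockface_weight: float = WEIGHT_BLOCKFACE,
) -> AlignmentState:
    """One directional pass over the stack, registering every section in place.

    Later slices see the refreshed results of earlier ones (the Markov-chain
    dependency); registration failures are recorded and the sweep continues.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    params = params or RegistrationParams()
    zs = range(state.blockface.n_slices)
    if direction == "backward":
        zs = reversed(zs)
    registered: set = set()
    for z in zs:
        for key in sorted(state.keys_at(z), key=lambda k: k[1]):
            st = state.sections[key]
            try:
                targets = build_target_set(
                    state, z, key[1], direction, registered, blockface_weight=blockface_weight
                )
                if not any(t.weight > 0 for t in targets):
                    registered.add(key)
                    continue
                t_new = register_pair(st.section.pixels, targets, params, init=st.transform)
                st.transform = t_new
                _refresh(state, st, key, params.mi_bins, decay_sigma)
                state.trace.append((state.iteration, direction, key, st.score))
                if st.score >= st.best_score:
                    st.best_score = st.score
                    st.best_transform = t_new
                elif st.best_transform is not None:
                    # keep only MI-improving results: the archived best (by
                    # blockface MI) is what downstream slices see, so a
                    # degraded registration never propagates along the chain
                    st.transform = st.best_transform
                    _refresh(state, st, key, params.mi_bins, decay_sigma)
            except (ValueError, FloatingPointError) as exc:
                st.failed = True
                state.failures.append((key, str(exc)))
                log.warning("registration failed for %s: %s", key, exc)
            registered.add(key)
    state.sweep_log.append(direction)
    return state


def revert_to_best(state: AlignmentState, mi_bins: int = 32, decay_sigma: float = 2.0) -> None:
    """Reset every section to its archived best-MI transform."""
    for key, st in state.sections.items():
        if st.best_transform is not None and st.best_transform is not st.transform:
            st.transform = st.best_transform
            _refresh(state, st, key, mi_bins, decay_sigma)


def run_reconstruction(
    blockface: Volume3D,
    sections: list[SectionImage],
    params: RegistrationParams | None = None,
    n_iterations: int = 3,
    decay_sigma: float = 2.0,
    initial_transforms: dict | None = None,
    blockface_weight: float = WEIGHT_BLOCKFACE,
    low_score_percentile: float = 5.0,
    iteration_callback=None,
) -> AlignmentState:
    """Full reconstruction: ``n_iterations`` forward-backward cycles.

    After each sweep, sections revert to their archived best-MI transforms
    before seeding the next sweep, so successive iterations restart from
    the best state found so far.  The returned state carries the best
    transforms, the full metric trace and a summary of low-scoring slices.
    """
    params = params or RegistrationParams()
    state = initialize_state(
        blockface, sections, decay_sigma=decay_sigma, mi_bins=params.mi_bins,
        initial_transforms=initial_transforms,
    )
    for it in range(n_iterations):
        state.iteration = it
        for direction in ("forward", "backward"):
            sweep(state, direction, params, decay_sigma, blockface_weight=blockface_weight)
            revert_to_best(state, params.mi_bins, decay_sigma)
        if iteration_callback is not None:
            iteration_callback(it, state)
    scores = {k: s.best_score for k, s in state.sections.items() if np.isfinite(s.best_score)}
    if scores:
        cutoff = np.percentile(list(scores.values()), low_score_percentile)
        flagged = sorted(k for k, v in scores.items() if v <= cutoff)
        log.info("slices below the %g%% MI percentile (inspect): %s", low_score_percentile, flagged)
        state.low_score_sections = flagged  # type: ignore[attr-defined]
    return state


def centroid_curve(state: AlignmentState) -> dict:
    """Per-slice tissue centroid (y, x) of the resampled stained sections.

    Averaged over stains present at each slice; used for bending diagnostics
    against the blockface centroid curve.
    """
    out: dict[int, np.ndarray] = {}
    for z in range(state.blockface.n_slices):
        pts = []
        for key in state.keys_at(z):
            st = state.sections[key]
            try:
                m = mask_background(st.resampled).mask
            except ValueError:
                continue
            ys, xs = np.nonzero(m)
            if len(ys):
                pts.append((ys.mean(), xs.mean()))
        if pts:
            out[z] = np.mean(np.asarray(pts), axis=0)
    return out


def blockface_centroid_curve(blockface: Volume3D) -> dict:
    out: dict[int, np.ndarray] = {}
    for z in range(blockface.n_slices):
        try:
            m = mask_background(blockface.voxels[z]).mask
        except ValueError:
            continue
        ys, xs = np.nonzero(m)
        if len(ys):
            out[z] = np.array([ys.mean(), xs.mean()])
    return out


def centroid_rms_deviation(state: AlignmentState) -> float:
    """RMS deviation (px) between stained and blockface centroid curves."""
    bf = blockface_centroid_curve(state.blockface)
    st = centroid_curve(state)
    common = sorted(set(bf) & set(st))
    if not common:
        return float("nan")
    d = np.asarray([st[z] - bf[z] for z in common])
    return float(np.sqrt((d**2).sum(axis=1).mean()))
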