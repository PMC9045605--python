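"""Synthetic serially-sectioned specimens with known ground truth.

The phantom emulates the data situation of a blockface-referenced serial
sectioning study: a smooth multi-class "brain" volume with embedded tubular
vessels is rendered once per contrast (five stains plus a sixth blockface
contrast), each stained section receives a smooth nonlinear in-plane
distortion plus a small affine jitter, intensities drift slowly along the
rostro-caudal axis, stains are sampled on interleaved slice intervals with
gaps, and individual sections may be marked damaged (omitted from staining
but present in the blockface).  Every corruption is returned alongside its
exact ground truth so that registration, interpolation, vessel detection
and QC can be validated by recovery.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi

from .io import SectionImage, Volume3D, write_section, write_volume, write_displacement_field
from .register2d import Transform2D, apply_transform

log = logging.getLogger("histostack")


# Default per-stain renderings: tissue class -> (mean intensity, noise SD).
# Class 0 is background.  Intensities on an 8-bit-like scale; the blockface
# contrast is deliberately unrelated to every stain so that any registration
# against it must be cross-contrast.
DEFAULT_STAIN_PROFILES: dict[str, dict[int, tuple[float, float]]] = {
    "blockface": {0: (20.0, 0.0), 1: (120.0, 0.0), 2: (170.0, 0.0), 3: (210.0, 0.0)},
    "nissl": {0: (235.0, 3.0), 1: (90.0, 5.0), 2: (150.0, 5.0), 3: (60.0, 5.0)},
    "bielschowsky": {0: (230.0, 3.0), 1: (170.0, 5.0), 2: (70.0, 5.0), 3: (120.0, 5.0)},
    "parvalbumin": {0: (240.0, 3.0), 1: (130.0, 5.0), 2: (170.0, 5.0), 3: (90.0, 5.0)},
    "calretinin": {0: (238.0, 3.0), 1: (175.0, 5.0), 2: (110.0, 5.0), 3: (155.0, 5.0)},
    "calbindin": {0: (242.0, 3.0), 1: (110.0, 5.0), 2: (60.0, 5.0), 3: (180.0, 5.0)},
}

# Interleaved sampling intervals "1:n" with per-stain phase offsets chosen so
# the union of the three dense stains covers every slice.
DEFAULT_SAMPLING_PLAN: dict[str, str] = {
    "nissl": "1:3",
    "bielschowsky": "1:3",
    "parvalbumin": "1:3",
    "calretinin": "1:6",
    "calbindin": "1:6",
}
DEFAULT_PLAN_OFFSETS: dict[str, int] = {
    "nissl": 0,
    "bielschowsky": 1,
    "parvalbumin": 2,
    "calretinin": 1,
    "calbindin": 4,
}


def parse_interval(pattern: str) -> int:
    """Parse a sampling pattern like ``"1:3"`` into the slice interval 3."""
    parts = pattern.split(":")
    if len(parts) != 2 or parts[0] != "1":
        raise ValueError(f"sampling pattern must look like '1:n', got {pattern!r}")
    n = int(parts[1])
    if n < 1:
        raise ValueError("sampling interval must be >= 1")
    return n


@dataclass
class PhantomSpec:
    """Study conditions of a synthetic specimen.

    Distances are in pixels of the in-plane grid unless noted; ``voxel_size``
    is micrometers (200 isotropic by default, the blockface working scale).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 60)  # (nx, ny, nz)
    voxel_size: float = 200.0
    n_tissue_classes: int = 3
    vessel_count: int = 8
    vessel_radius_range: tuple[float, float] = (2.0, 4.0)
    stain_profiles: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STAIN_PROFILES.items()})
    sampling_plan: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLING_PLAN))
    plan_offsets: dict = field(default_factory=lambda: dict(DEFAULT_PLAN_OFFSETS))
    distortion_amplitude: float = 10.0
    affine_jitter: tuple[float, float] = (2.0, 3.0)  # (max rotation deg, max translation px)
    drift_rate: float = 0.5
    damaged_slices: list = field(default_factory=list)
    seed: int = 0

    def stain_slices(self, stain: str) -> list[int]:
        """Slice indices sampled for ``stain`` (before damage removal)."""
        nz = self.grid_shape[2]
        interval = parse_interval(self.sampling_plan[stain])
        offset = self.plan_offsets.get(stain, 0) % interval
        return list(range(offset, nz, interval))


@dataclass
class GroundTruth:
    """Exact generative state of a phantom."""

    label_volume: Volume3D
    vessel_volume: Volume3D
    true_fields: dict  # (slice_index, stain) -> Transform2D
    true_affines: dict  # (slice_index, stain) -> 2x3 ndarray


@dataclass
class PhantomDataset:
    """Blockface stack, distorted stained sections and their ground truth."""

    spec: PhantomSpec
    blockface: Volume3D
    sections: list  # distorted SectionImage, stains only
    clean_sections: dict  # (slice_index, stain) -> SectionImage before distortion
    truth: GroundTruth

    def section(self, slice_index: int, stain: str) -> SectionImage:
        for s in self.sections:
            if s.slice_index == slice_index and s.stain == stain:
                return s
        raise KeyError((slice_index, stain))


# ---------------------------------------------------------------------------
# geometry generation
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    return f / max(f.std(), 1e-12)


def generate_label_volume(spec: PhantomSpec) -> tuple[Volume3D, Volume3D]:
    """Generate the tissue-class volume and the vessel tube volume.

    Tissue geometry comes from thresholded band-limited noise inside an
    approximately convex brain region (a noise-perturbed ellipsoid); vessels
    are smooth, mostly rostro-caudal tubes with radii in
    ``vessel_radius_range``, placed without mutual intersection.
    """
    nx, ny, nz = spec.grid_shape
    if nx < 32 or ny < 32 or nz < 8:
        raise ValueError(f"grid_shape {spec.grid_shape} too small; need at least (32, 32, 8)")
    if spec.n_tissue_classes < 2:
        raise ValueError("need at least 2 tissue classes")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    zz, yy, xx = np.indices((nz, ny, nx), dtype=np.float64)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    # brain support: perturbed ellipsoid, background class 0 outside
    # the z semi-axis exceeds the stack: the sampled sections cover the
    # central portion of a longer specimen, so the tissue outline changes
    # slowly from slice to slice, as 200-um serial sections of a real brain do
    r2 = ((xx - cx) / (0.38 * nx)) ** 2 + ((yy - cy) / (0.38 * ny)) ** 2 + ((zz - cz) / (1.5 * nz)) ** 2
    # physically isotropic feature scales (voxels are isotropic), so that
    # anatomy varies as slowly across slices as it does in plane — the
    # interslice continuity that serial sectioning of real tissue exhibits
    s_shape = min(nx, ny) / 6
    bump = _smooth_noise(rng, (nz, ny, nx), sigma=s_shape)
    brain = (r2 + 0.08 * bump) < 1.0
    # tissue classes: quantiles of an independent band-limited field
    s_tex = min(nx, ny) / 8
    texture = _smooth_noise(rng, (nz, ny, nx), sigma=s_tex)
    labels = np.zeros((nz, ny, nx), dtype=np.int16)
    vals = texture[brain]
    qs = np.quantile(vals, np.linspace(0, 1, spec.n_tissue_classes + 1)[1:-1])
    labels[brain] = 1 + np.searchsorted(qs, vals)
    vessels = _generate_vessels(spec, brain, rng)
    vs = (spec.voxel_size,) * 3
    return Volume3D(labels, voxel_size=vs), Volume3D(vessels, voxel_size=vs)


def _generate_vessels(spec: PhantomSpec, brain: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = brain.shape
    vessels = np.zeros(brain.shape, dtype=bool)
    if spec.vessel_count == 0:
        return vessels
    r_lo, r_hi = spec.vessel_radius_range
    # vessels are in-plane disks: erode in-plane only, not along z
    flat = np.zeros((1, 3, 3), dtype=bool)
    flat[0] = True
    core = ndi.binary_erosion(brain, structure=flat, iterations=int(np.ceil(r_hi)) + 2)
    if not core.any():
        raise ValueError(
            f"grid {spec.grid_shape} too small to contain vessels of radius up to {r_hi}"
        )
    yy, xx = np.indices((ny, nx), dtype=np.float64)
    placed = 0
    for _ in range(50 * spec.vessel_count):
        if placed == spec.vessel_count:
            break
        radius = float(rng.uniform(r_lo, r_hi))
        # smooth centerline running the full z extent with lateral wiggle
        zs = np.arange(nz)
        ok_xy = np.argwhere(core[nz // 2])
        if len(ok_xy) == 0:
            break
        y0, x0 = ok_xy[rng.integers(len(ok_xy))]
        wig_y = ndi.gaussian_filter1d(rng.standard_normal(nz), nz / 6) * 6.0
        wig_x = ndi.gaussian_filter1d(rng.standard_normal(nz), nz / 6) * 6.0
        cy = y0 + wig_y - wig_y[nz // 2]
        cx = x0 + wig_x - wig_x[nz // 2]
        # keep only z-runs where the full disk lies inside the tissue, so
        # every cross-section is a complete, detectable circle (tubes end
        # cleanly instead of leaving clipped slivers at the brain border)
        ok = np.zeros(nz, dtype=bool)
        disks = []
        for z in zs:
            disk = ((yy - cy[z]) ** 2 + (xx - cx[z]) ** 2) <= radius**2
            disks.append(disk)
            if disk.any() and brain[z].any():
                eroded = ndi.binary_erosion(brain[z], iterations=1)
                ok[z] = bool((disk <= eroded).all())
        run = _longest_run(ok)
        tube = np.zeros(brain.shape, dtype=bool)
        for z in range(*run):
            tube[z] = disks[z]
        inside = (run[1] - run[0]) >= max(nz // 4, 3)
        # reject tubes touching already-placed vessels (keeps components countable)
        grown = ndi.binary_dilation(tube, iterations=2)
        if inside and not (grown & vessels).any():
            vessels |= tube
            placed += 1
    if placed < spec.vessel_count:
        raise ValueError(
            f"could not place {spec.vessel_count} non-intersecting vessels of radius "
            f"{spec.vessel_radius_range} in grid {spec.grid_shape}"
        )
    return vessels


# ---------------------------------------------------------------------------
# rendering and distortion
# ---------------------------------------------------------------------------


def render_volume(
    labels: Volume3D,
    vessels: Volume3D,
    profile: dict,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Volume3D:
    """Render a full 3D volume from the label geometry with one contrast.

    Used for the synthetic quantitative-MRI volume: same anatomy as the
    blockface, independent intensity lookup, optional Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels.voxels)
    out = np.zeros(lab.shape, dtype=np.float64)
    for cls in np.unique(lab):
        if int(cls) not in profile:
            raise KeyError(f"profile lacks intensity for class {int(cls)}")
        out[lab == cls] = profile[int(cls)][0]
    out[np.asarray(vessels.voxels, dtype=bool)] = profile[0][0]
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, out.shape)
    return Volume3D(out, voxel_size=labels.voxel_size)


def distort_volume(
    volume: Volume3D,
    amplitude: float,
    seed: int = 0,
    field_sigma: float | None = None,
    mask: np.ndarray | None = None,
) -> tuple[Volume3D, Transform2D]:
    """Smooth random 3D warp with known ground truth.

    The displacement field is band-limited noise scaled so the mean
    magnitude over ``mask`` (or the whole grid) equals ``amplitude`` voxels;
    emulates the smooth bulk deformation between MRI and blockface space.
    """
    rng = np.random.default_rng(seed)
    shape = volume.shape
    sigma = field_sigma if field_sigma is not None else min(shape) / 3.0
    raw = np.stack([ndi.gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)])
    mag = np.sqrt((raw**2).sum(axis=0))
    sel = np.asarray(mask, dtype=bool) if mask is not None else np.ones(shape, dtype=bool)
    raw *= amplitude / max(float(mag[sel].mean()), 1e-12)
    t = Transform2D(field=raw)
    warped = apply_transform(np.asarray(volume.voxels, dtype=np.float64), t)
    return Volume3D(warped, voxel_size=volume.voxel_size), t


def _longest_run(ok: np.ndarray) -> tuple[int, int]:
    """Longest contiguous True run as a half-open (start, stop) range."""
    best = (0, 0)
    start = None
    for i, v in enumerate(list(ok) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return best


def render_section(
    labels_slice: np.ndarray,
    vessels_slice: np.ndarray,
    stain_profile: dict,
    slice_index: int,
    drift_rate: float = 0.0,
    noise_seed: int = 0,
    pixel_size: float = 200.0,
    stain: str = "other",
) -> SectionImage:
    """Render one section: class lookup + drift + noise, vessels as background.

    Tissue pixels get ``profile[class][0] + drift_rate * slice_index`` plus
    zero-mean Gaussian noise of the class SD; vessel lumina and background
    are rendered at the background intensity (class 0), which stays constant
    along z (no drift).
    """
    labels_slice = np.asarray(labels_slice)
    vessels_slice = np.asarray(vessels_slice, dtype=bool)
    present = np.unique(labels_slice)
    missing = [int(c) for c in present if int(c) not in stain_profile]
    if missing:
        raise KeyError(f"stain profile lacks intensities for tissue classes {missing}")
    rng = np.random.default_rng(noise_seed)
    out = np.zeros(labels_slice.shape, dtype=np.float64)
    noise_sd = np.zeros(labels_slice.shape, dtype=np.float64)
    for cls in present:
        mean, sd = stain_profile[int(cls)]
        sel = labels_slice == cls
        out[sel] = mean + (drift_rate * slice_index if cls != 0 else 0.0)
        noise_sd[sel] = sd
    bg_mean, bg_sd = stain_profile[0]
    out[vessels_slice] = bg_mean
    noise_sd[vessels_slice] = bg_sd
    if np.any(noise_sd > 0):
        out = out + rng.standard_normal(out.shape) * noise_sd
    return SectionImage(out, pixel_size=pixel_size, stain=stain, slice_index=slice_index)


def distort_section(
    section: SectionImage,
    distortion_amplitude: float,
    affine_jitter: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    field_sigma: float | None = None,
) -> tuple[SectionImage, Transform2D]:
    """Apply a smooth random warp + affine jitter; return image and transform.

    The displacement field is Gaussian-smoothed white noise scaled to the
    requested mean magnitude; if the scaling would fold the warp (Jacobian
    <= 0 anywhere) it is automatically reduced with a logged warning.  The
    returned transform reproduces the warped image exactly via
    ``apply_transform(section.pixels, t)``.
    """
    if distortion_amplitude < 0:
        raise ValueError("distortion amplitude must be >= 0")
    ny, nx = section.shape
    rng = np.random.default_rng(seed)
    sigma = field_sigma if field_sigma is not None else max(min(ny, nx) / 5.0, 4.0)
    if distortion_amplitude > 0:
        raw = np.stack([ndi.gaussian_filter(rng.standard_normal((ny, nx)), sigma) for _ in range(2)])
        mag = np.sqrt((raw**2).sum(axis=0))
        raw *= distortion_amplitude / max(mag.mean(), 1e-12)
        raw = _ensure_invertible(raw)
    else:
        raw = np.zeros((2, ny, nx))
    max_deg, max_t = affine_jitter
    theta = np.deg2rad(rng.uniform(-max_deg, max_deg)) if max_deg > 0 else 0.0
    trans = rng.uniform(-max_t, max_t, size=2) if max_t > 0 else np.zeros(2)
    c = np.array([(ny - 1) / 2, (nx - 1) / 2])
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    offset = c - rot @ c + trans
    affine = np.hstack([rot, offset[:, None]])
    t = Transform2D(affine=affine, field=raw, shape=(ny, nx))
    warped = apply_transform(section.pixels, t)
    out = SectionImage(warped, pixel_size=section.pixel_size, stain=section.stain, slice_index=section.slice_index)
    return out, t


def _ensure_invertible(field_arr: np.ndarray, min_jac: float = 0.1) -> np.ndarray:
    """Rescale a displacement field until its Jacobian stays positive."""
    for _ in range(20):
        gyy, gyx = np.gradient(field_arr[0])
        gxy, gxx = np.gradient(field_arr[1])
        jac = (1 + gyy) * (1 + gxx) - gyx * gxy
        if jac.min() > min_jac:
            return field_arr
        warnings.warn("distortion amplitude rescaled to keep the warp invertible", stacklevel=2)
        log.warning("distortion field rescaled by 0.8 to keep Jacobian positive")
        field_arr = field_arr * 0.8
    return field_arr


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def build_phantom_dataset(spec: PhantomSpec) -> PhantomDataset:
    """Generate the complete phantom: blockface stack, stained sections, truth.

    The blockface covers every slice, rendered with its own contrast and no
    distortion (it is the geometric anchor).  Each stained section is
    rendered from the same slice geometry, then distorted; damaged slices
    are omitted from all stains but kept in the blockface.
    """
    labels, vessels = generate_label_volume(spec)
    nz = spec.grid_shape[2]
    damaged = set(spec.damaged_slices)
    stain_names = list(spec.sampling_plan)
    bf_profile = spec.stain_profiles["blockface"]
    bf_sections = [
        render_section(
            labels.voxels[z], vessels.voxels[z], bf_profile, z,
            drift_rate=0.0,
            noise_seed=_derived_seed(spec.seed, z, "blockface"),
            pixel_size=spec.voxel_size, stain="blockface",
        )
        for z in range(nz)
    ]
    blockface = Volume3D(
        np.stack([s.pixels for s in bf_sections]),
        voxel_size=(spec.voxel_size, spec.voxel_size, spec.voxel_size),
    )
    sections: list[SectionImage] = []
    clean: dict = {}
    true_fields: dict = {}
    true_affines: dict = {}
    for stain in stain_names:
        profile = spec.stain_profiles[stain]
        for z in spec.stain_slices(stain):
            if z in damaged:
                continue
            sec = render_section(
                labels.voxels[z], vessels.voxels[z], profile, z,
                drift_rate=spec.drift_rate,
                noise_seed=_derived_seed(spec.seed, z, stain),
                pixel_size=spec.voxel_size, stain=stain,
            )
            warped, t = distort_section(
                sec, spec.distortion_amplitude, spec.affine_jitter,
                seed=_derived_seed(spec.seed, z, stain + ":warp"),
            )
            sections.append(warped)
            clean[(z, stain)] = sec
            true_fields[(z, stain)] = t
            true_affines[(z, stain)] = t.affine
    _check_coverage(spec, sections)
    truth = GroundTruth(labels, vessels, true_fields, true_affines)
    return PhantomDataset(spec, blockface, sections, clean, truth)


def _derived_seed(seed: int, z: int, tag: str) -> int:
    # crc32 keeps the per-section seed stable across processes
    ss = np.random.SeedSequence([seed, z, zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _check_coverage(spec: PhantomSpec, sections: list[SectionImage]) -> None:
    covered = {s.slice_index for s in sections}
    damaged = set(spec.damaged_slices)
    uncovered = [z for z in range(spec.grid_shape[2]) if z not in covered and z not in damaged]
    if uncovered:
        log.warning("sampling plan leaves slices %s with no stain", uncovered)


def evaluate_recovery(dataset: PhantomDataset, recovered: dict) -> dict:
    """Mean endpoint error (px) of recovered transforms against truth.

    ``recovered`` maps ``(slice_index, stain)`` to a Transform2D that was
    estimated to undo the section's true distortion.  Errors are measured
    over the true (undistorted) tissue support of each slice.
    """
    from .register2d import endpoint_error

    per_section = {}
    labels = dataset.truth.label_volume.voxels
    for key, t_rec in recovered.items():
        z, _ = key
        if key not in dataset.truth.true_fields:
            continue
        mask = labels[z] > 0
        if not mask.any():
            continue
        per_section[key] = endpoint_error(t_rec, dataset.truth.true_fields[key], mask=mask)
    mean = float(np.mean(list(per_section.values()))) if per_section else float("nan")
    return {"per_section": per_section, "mean": mean}


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------


def write_phantom(dataset: PhantomDataset, out_dir) -> None:
    """Write the dataset: TIFF sections, NIfTI truth, YAML manifest."""
    out = Path(out_dir)
    (out / "blockface").mkdir(parents=True, exist_ok=True)
    (out / "sections").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for z in range(dataset.blockface.n_slices):
        sec = SectionImage(
            dataset.blockface.voxels[z], pixel_size=dataset.spec.voxel_size,
            stain="blockface", slice_index=z,
        )
        write_section(out / "blockface" / f"blockface_{z:04d}.tif", sec)
    for s in dataset.sections:
        write_section(out / "sections" / f"{s.stain}_{s.slice_index:04d}.tif", s)
    write_volume(out / "truth" / "labels.nii.gz", dataset.truth.label_volume)
    write_volume(out / "truth" / "vessels.nii.gz", Volume3D(
        dataset.truth.vessel_volume.voxels.astype(np.uint8),
        voxel_size=dataset.truth.vessel_volume.voxel_size,
    ))
    for (z, stain), t in dataset.truth.true_fields.items():
        write_displacement_field(
            out / "truth" / f"field_{stain}_{z:04d}.nii.gz", t.displacement(),
            pixel_size=dataset.spec.voxel_size,
        )
    manifest = {
        "grid_shape": list(dataset.spec.grid_shape),
        "voxel_size_um": dataset.spec.voxel_size,
        "sampling_plan": dict(dataset.spec.sampling_plan),
        "plan_offsets": dict(dataset.spec.plan_offsets),
        "damaged_slices": list(dataset.spec.damaged_slices),
        "distortion_amplitude_px": dataset.spec.distortion_amplitude,
        "drift_rate": dataset.spec.drift_rate,
        "seed": dataset.spec.seed,
        "n_sections": len(dataset.sections),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
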