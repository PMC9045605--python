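"""Core containers and file I/O for sections, volumes and masks.

Conventions
-----------
* Rasters are indexed ``(row, col)`` = ``(y, x)``; volumes are indexed
  ``(z, y, x)`` with ``z`` the slice index increasing rostral -> caudal.
* Indices are 0-based and voxel-centered.
* ``Volume3D.voxel_size`` is ``(dx, dy, dz)`` in micrometers, following the
  physical-axis order even though arrays are stored ``(z, y, x)``.
* All spatial transforms elsewhere in the package use the pull-back
  convention: they map output-grid coordinates into the input raster.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import nibabel as nib
from scipy import ndimage as ndi


log = logging.getLogger("histostack")

#: recognized stain / contrast labels
STAINS = (
    "blockface",
    "nissl",
    "bielschowsky",
    "parvalbumin",
    "calretinin",
    "calbindin",
    "other",
)

#: section thickness of the cutting plan, micrometers
SECTION_THICKNESS_UM = 200.0


@dataclass
class SectionImage:
    """One digitized 2D section.

    Parameters
    ----------
    pixels : ndarray
        Single-channel floating raster, indexed ``(y, x)``.
    pixel_size : float
        In-plane pixel size in micrometers (> 0).
    stain : str
        One of :data:`STAINS`.
    slice_index : int
        Position in the rostral->caudal cutting order (>= 0).
    """

    pixels: np.ndarray
    pixel_size: float
    stain: str = "other"
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D raster")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.stain not in STAINS:
            raise ValueError(f"unknown stain {self.stain!r}; expected one of {STAINS}")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Volume3D:
    """A 3D raster on a regular grid, stored ``(z, y, x)``."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (200.0, 200.0, 200.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D raster")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice(self, z: int) -> np.ndarray:
        return self.voxels[z]


@dataclass
class TissueMask:
    """Binary tissue support plus its interior holes.

    ``mask`` is the hole-filled dominant foreground component; ``holes`` are
    the interior background components (candidate vessels / ventricles),
    reported separately so downstream feature extraction can use them.
    """

    mask: np.ndarray
    holes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.holes is None:
            self.holes = np.zeros_like(self.mask)
        self.holes = np.asarray(self.holes, dtype=bool)
        if self.holes.shape != self.mask.shape:
            raise ValueError("holes raster must match mask shape")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def to_grayscale(
    rgb_raster: np.ndarray,
    pixel_size: float = 1.0,
    stain: str = "other",
    slice_index: int = 0,
) -> SectionImage:
    """Convert an RGB raster to grayscale with exactly equal channel weights.

    The output intensity is ``(R + G + B) / 3`` per pixel.
    """
    arr = np.asarray(rgb_raster, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected an (ny, nx, 3) raster, got shape {arr.shape}")
    gray = arr.sum(axis=-1) / 3.0
    return SectionImage(gray, pixel_size=pixel_size, stain=stain, slice_index=slice_index)


def restack_blockface(
    sections: list[SectionImage],
    slice_thickness: float = SECTION_THICKNESS_UM,
) -> Volume3D:
    """Stack blockface sections into a volume without any registration.

    Slices are keyed by ``slice_index`` (input order is irrelevant); indices
    must form a complete run with no duplicates.  Blockface photographs are
    geometrically consistent by acquisition, so slice ``z`` of the output is
    section ``z`` verbatim.
    """
    if not sections:
        raise ValueError("no sections to stack")
    idx = [s.slice_index for s in sections]
    counts = np.bincount(np.asarray(idx) - min(idx))
    dup = [i + min(idx) for i, c in enumerate(counts) if c > 1]
    missing = [i + min(idx) for i, c in enumerate(counts) if c == 0]
    if dup or missing:
        raise ValueError(
            f"blockface stack incomplete: duplicated indices {dup}, missing indices {missing}"
        )
    order = sorted(sections, key=lambda s: s.slice_index)
    px = order[0].pixel_size
    shape = order[0].shape
    planes = []
    for s in order:
        if s.shape != shape or s.pixel_size != px:
            plane = _resample_plane(s, px, shape)
            log.info("restack: resampled slice %d to common grid", s.slice_index)
        else:
            plane = s.pixels
        planes.append(plane)
    return Volume3D(np.stack(planes, axis=0), voxel_size=(px, px, slice_thickness))


def _resample_plane(s: SectionImage, pixel_size: float, shape: tuple[int, int]) -> np.ndarray:
    """Linear resampling of one section onto the common blockface grid."""
    scale = s.pixel_size / pixel_size
    yy, xx = np.indices(shape, dtype=np.float64)
    return ndi.map_coordinates(
        s.pixels, [yy / scale, xx / scale], order=1, mode="nearest"
    )


def mask_background(image, closing_radius: int = 1, k_sigma: float = 6.0) -> TissueMask:
    """Separate tissue from background by automatic thresholding.

    The background intensity is estimated robustly from the raster border
    (median and MAD); foreground is everything deviating from it by more
    than ``k_sigma`` noise SDs (at least 5% of the dynamic range).  Unlike a
    bimodal split this handles multi-modal stain histograms where some
    tissue class sits on the background's side of an Otsu threshold.  The
    foreground is cleaned by light morphological closing, reduced to its
    largest connected component and hole-filled; interior holes are
    returned separately as vessel/ventricle candidates.

    Accepts a :class:`SectionImage`, :class:`Volume3D` or bare ndarray.
    """
    if isinstance(image, SectionImage):
        arr = image.pixels
    elif isinstance(image, Volume3D):
        arr = np.asarray(image.voxels, dtype=np.float64)
    else:
        arr = np.asarray(image, dtype=np.float64)
    if np.ptp(arr) == 0:
        raise ValueError("cannot mask a constant image: no background/foreground separation")
    border = np.ones(arr.shape, dtype=bool)
    border[tuple(slice(1, -1) for _ in range(arr.ndim))] = False
    bg = float(np.median(arr[border]))
    noise = 1.4826 * float(np.median(np.abs(arr[border] - bg)))
    thr = max(k_sigma * noise, 0.05 * float(np.ptp(arr)))
    fg = np.abs(arr - bg) > thr
    if not fg.any():
        raise ValueError("no foreground found above automatic threshold")
    if closing_radius > 0:
        struct = _ball(arr.ndim, closing_radius)
        fg = ndi.binary_closing(fg, structure=struct)
    labels, n = ndi.label(fg)
    if n == 0:
        raise ValueError("no foreground component found")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    main = labels == (1 + int(np.argmax(sizes)))
    filled = ndi.binary_fill_holes(main)
    holes = filled & ~main
    return TissueMask(filled, holes)


def _ball(ndim: int, radius: int) -> np.ndarray:
    grids = np.indices((2 * radius + 1,) * ndim) - radius
    return (grids**2).sum(axis=0) <= radius**2


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def write_section(path, section: SectionImage) -> None:
    """Write a section as baseline TIFF with metadata in the description tag."""
    meta = {
        "pixel_size_um": section.pixel_size,
        "stain": section.stain,
        "slice_index": section.slice_index,
    }
    tifffile.imwrite(str(path), section.pixels, description=json.dumps(meta))


def read_section(path) -> SectionImage:
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    return SectionImage(
        arr,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        stain=str(meta.get("stain", "other")),
        slice_index=int(meta.get("slice_index", 0)),
    )


def write_volume(path, volume: Volume3D) -> None:
    """Write a volume as NIfTI-1 (array reordered to the x, y, z axes)."""
    dx, dy, dz = volume.voxel_size
    affine = np.diag([dx / 1000.0, dy / 1000.0, dz / 1000.0, 1.0])
    img = nib.Nifti1Image(np.transpose(volume.voxels, (2, 1, 0)), affine)
    img.header.set_zooms((dx / 1000.0, dy / 1000.0, dz / 1000.0))
    nib.save(img, str(path))


def read_volume(path) -> Volume3D:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    return Volume3D(data, voxel_size=tuple(1000.0 * z for z in zooms))


def write_displacement_field(path, field_arr: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write a displacement field as multi-channel NIfTI plus a JSON sidecar.

    ``field_arr`` has shape ``(ndim, *grid)`` with components ordered along
    the array axes (``(dy, dx)`` in 2D); values are in pixels on the output
    grid, pull-back convention.
    """
    path = Path(path)
    ndim = field_arr.shape[0]
    grid = field_arr.shape[1:]
    flat = np.moveaxis(field_arr, 0, -1)  # (*grid, ndim)
    if ndim == 2:
        data = np.transpose(flat, (1, 0, 2))[:, :, None, :]
    else:
        data = np.transpose(flat, (2, 1, 0, 3))
    img = nib.Nifti1Image(data.astype(np.float64), np.eye(4))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    meta = {
        "convention": "pull-back: field maps output-grid index coordinates into the input raster",
        "component_order": "array axes (z,)y,x",
        "units": "pixels",
        "pixel_size_um": pixel_size,
        "grid_shape_zyx": list(grid),
    }
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2))


def read_displacement_field(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[2] == 1 and data.shape[3] == 2:
        flat = np.transpose(data[:, :, 0, :], (1, 0, 2))
    elif data.ndim == 4:
        flat = np.transpose(data, (2, 1, 0, 3))
    else:
        raise ValueError(f"unrecognized displacement field layout {data.shape}")
    return np.moveaxis(flat, -1, 0)
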