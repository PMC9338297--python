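"""I/O and preprocessing for micro-CT volumes and vessel-class label volumes.

Volumes are 3D scalar grids with an isotropic voxel size in micrometres.
Label volumes carry a fixed five-class code table distinguishing the
uteroplacental vessel compartments (spiral arteries, radial arteries,
maternal canals, uterine arteries) from background.

Supported on-disk formats: multipage TIFF, NIfTI-1, and raw binary with a
JSON header.  TIFF and raw files carry their voxel size in a JSON sidecar
(``<file>.json`` next to the data file); NIfTI carries it in its affine
zooms.  Round trips are bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.measure import block_reduce
from skimage.morphology import ball

#: vessel-class code table shared by every label volume
CLASS_TABLE = {0: "background", 1: "spiral", 2: "radial", 3: "canal", 4: "uterine"}
BACKGROUND, SPIRAL, RADIAL, CANAL, UTERINE = 0, 1, 2, 3, 4
VESSEL_CLASSES = (SPIRAL, RADIAL, CANAL, UTERINE)


@dataclass
class Volume:
    """A 3D intensity grid with isotropic voxel size in μm."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if not np.isfinite(self.voxel_size_um) or self.voxel_size_um <= 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Per-voxel vessel-class codes (see :data:`CLASS_TABLE`)."""

    labels: np.ndarray
    voxel_size_um: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got ndim={self.labels.ndim}")
        if not np.isfinite(self.voxel_size_um) or self.voxel_size_um <= 0:
            raise ValueError(f"voxel_size_um must be positive, got {self.voxel_size_um}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        bad = set(np.unique(self.labels)) - set(CLASS_TABLE)
        if bad:
            raise ValueError(f"unknown vessel-class codes: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def class_mask(self, classes) -> np.ndarray:
        """Binary union mask of the requested vessel classes."""
        return np.isin(self.labels, np.asarray(list(classes)))


@dataclass
class PreClassVolume:
    """Coarse background / transitional / vessel pre-classification."""

    labels: np.ndarray
    thresholds: list = field(default_factory=list)

    def __post_init__(self):
        t = list(self.thresholds)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly ascending")
        self.thresholds = t


# ---------------------------------------------------------------------------
# file I/O


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _infer_format(path: Path) -> str:
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        return "tiff-stack"
    if suffixes.endswith((".nii", ".nii.gz")):
        return "nifti"
    if suffixes.endswith(".raw"):
        return "raw+json"
    raise ValueError(f"cannot infer volume format from {path.name!r}")


def load_volume(path, format: str | None = None, voxel_size_um: float | None = None) -> Volume:
    """Load a 3D volume.

    Parameters
    ----------
    path : str or Path
        Data file.  TIFF and raw volumes look for a ``<file>.json`` sidecar
        carrying ``voxel_size_um``; NIfTI uses its header zooms.
    format : {"tiff-stack", "nifti", "raw+json"}, optional
        Inferred from the suffix when omitted.
    voxel_size_um : float, optional
        Overrides (or supplies, when missing) the stored voxel size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = format or _infer_format(path)

    meta_size = None
    if fmt == "tiff-stack":
        data = tifffile.imread(path)
        if _sidecar(path).exists():
            meta_size = json.loads(_sidecar(path).read_text()).get("voxel_size_um")
    elif fmt == "nifti":
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        if len(set(np.round(zooms, 9))) == 1 and zooms[0] > 0:
            meta_size = float(zooms[0])
    elif fmt == "raw+json":
        sc = _sidecar(path)
        if not sc.exists():
            raise ValueError(f"raw volume {path} is missing its JSON header {sc.name}")
        hdr = json.loads(sc.read_text())
        data = np.fromfile(path, dtype=np.dtype(hdr["dtype"])).reshape(hdr["shape"])
        meta_size = hdr.get("voxel_size_um")
    else:
        raise ValueError(f"unknown volume format {fmt!r}")

    size = voxel_size_um if voxel_size_um is not None else meta_size
    if size is None:
        raise ValueError(
            f"{path} carries no voxel-size metadata; pass voxel_size_um explicitly"
        )
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D volume (ndim={data.ndim})")
    return Volume(data, float(size))


def save_volume(vol: Volume, path, format: str | None = None) -> Path:
    """Write a volume; the inverse of :func:`load_volume` (bit-exact)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff-stack":
        tifffile.imwrite(path, vol.data)
        _sidecar(path).write_text(json.dumps({"voxel_size_um": vol.voxel_size_um}))
    elif fmt == "nifti":
        affine = np.diag([vol.voxel_size_um] * 3 + [1.0])
        nib.save(nib.Nifti1Image(vol.data, affine), path)
    elif fmt == "raw+json":
        vol.data.tofile(path)
        _sidecar(path).write_text(
            json.dumps(
                {
                    "shape": list(vol.data.shape),
                    "dtype": vol.data.dtype.str,
                    "voxel_size_um": vol.voxel_size_um,
                }
            )
        )
    else:
        raise ValueError(f"unknown volume format {fmt!r}")
    return path


def load_labels(path, format: str | None = None, voxel_size_um: float | None = None) -> LabelVolume:
    """Load a vessel-class label volume (same formats as :func:`load_volume`)."""
    vol = load_volume(path, format=format, voxel_size_um=voxel_size_um)
    return LabelVolume(np.asarray(vol.data).astype(np.uint8), vol.voxel_size_um)


def save_labels(labels: LabelVolume, path, format: str | None = None) -> Path:
    p = save_volume(Volume(labels.labels.astype(np.uint8), labels.voxel_size_um), path, format)
    sc = _sidecar(Path(path))
    if sc.exists():
        meta = json.loads(sc.read_text())
        meta["class_table"] = {str(k): v for k, v in CLASS_TABLE.items()}
        sc.write_text(json.dumps(meta))
    return p


# ---------------------------------------------------------------------------
# preprocessing


def downscale_and_denoise(vol: Volume, factor: float = 0.5, median_radius_voxels: int = 2) -> Volume:
    """Downscale a volume then apply an isotropic 3D median filter.

    The default parameters halve each axis (block-mean over 2x2x2 cells) and
    median-filter with a spherical neighborhood of radius 2 voxels.  The
    output voxel size is ``voxel_size_um / factor``; the output shape is
    ``floor(shape * factor)`` per axis.
    """
    if not 0 < factor <= 1:
        raise ValueError(f"downscale factor must be in (0, 1], got {factor}")
    if median_radius_voxels < 0:
        raise ValueError("median_radius_voxels must be non-negative")

    data = np.asarray(vol.data, dtype=np.float64)
    if factor == 1.0:
        out = data.copy()
    else:
        inv = 1.0 / factor
        target = tuple(int(np.floor(s * factor)) for s in vol.shape)
        if abs(inv - round(inv)) < 1e-12:
            n = int(round(inv))
            trimmed = data[tuple(slice(0, t * n) for t in target)]
            out = block_reduce(trimmed, (n, n, n), np.mean)
        else:
            zoom = [t / s for t, s in zip(target, vol.shape)]
            out = ndimage.zoom(data, zoom, order=1, grid_mode=True, mode="nearest")
            out = out[tuple(slice(0, t) for t in target)]

    if median_radius_voxels > 0:
        out = ndimage.median_filter(out, footprint=ball(median_radius_voxels), mode="nearest")
    return Volume(out, vol.voxel_size_um / factor)


def multi_otsu_preclass(vol: Volume, n_classes: int = 3) -> PreClassVolume:
    """Pre-classify voxels as background / transitional / vessel.

    Thresholds maximize the between-class variance of the intensity
    histogram (256 uniform bins over the observed range); voxels are mapped
    to ascending classes.  Raises on volumes with fewer distinct intensity
    values than classes.
    """
    data = np.asarray(vol.data)
    n_distinct = len(np.unique(data))
    if n_distinct < n_classes:
        raise ValueError(
            f"multi-Otsu needs >= {n_classes} distinct intensity values, found {n_distinct}"
        )
    thresholds = threshold_multiotsu(data, classes=n_classes, nbins=256)
    labels = np.digitize(data, thresholds).astype(np.uint8)
    return PreClassVolume(labels, [float(t) for t in thresholds])
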