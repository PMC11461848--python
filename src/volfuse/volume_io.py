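"""Volume input/output and the simplified preprocessing contract.

Volumes are read from NIfTI-1 files or DICOM slice-series directories into
``VolumeSample`` objects (``(depth, height, width)`` voxel arrays, 0-based
indices) and preprocessed by trilinear resampling to the model input size
(56x56x56 by default) followed by volume-wide z-scoring. Skull stripping
and bias-field correction are intentionally out of scope: real MRI should
be cleaned upstream with the standard external tools before entering this
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from . import _dicom

__all__ = ["VolumeSample", "read_volume", "write_nifti", "preprocess_volume",
           "DEFAULT_TARGET_SHAPE"]

DEFAULT_TARGET_SHAPE = (56, 56, 56)


@dataclass
class VolumeSample:
    """A labeled 3D intensity volume with voxel spacing in millimetres."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    label: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.label is not None and self.label not in (0, 1, 2):
            raise ValueError(f"label must be in {{0,1,2}}, got {self.label}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def read_volume(path: str | Path, format: str | None = None,
                label: int | None = None) -> VolumeSample:
    """Read a NIfTI file or a DICOM slice-series directory.

    ``format`` is ``"nifti"`` or ``"dicom_series"``; when omitted it is
    inferred (directory -> DICOM series, file -> NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path, label)
    if format == "dicom_series":
        return _read_dicom_series(path, label)
    raise ValueError(f"unsupported format {format!r}")


def _read_nifti(path: Path, label) -> VolumeSample:
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj, dtype=np.float64)
    if voxels.ndim == 4 and voxels.shape[3] == 1:
        voxels = voxels[..., 0]
    zooms = img.header.get_zooms()[:3]
    return VolumeSample(
        voxels=voxels, spacing=tuple(float(z) for z in zooms),
        subject_id=path.stem.replace(".nii", ""), label=label,
        provenance={"source": str(path), "format": "nifti"})


def _read_dicom_series(path: Path, label) -> VolumeSample:
    files = sorted(p for p in path.iterdir()
                   if p.is_file() and not p.name.startswith("."))
    if not files:
        raise FileNotFoundError(f"no DICOM slices found under {path}")
    slices = []
    for f in files:
        el = _dicom.read_elements(f)
        rows = _dicom.get_us(el, _dicom.TAG_ROWS)
        cols = _dicom.get_us(el, _dicom.TAG_COLUMNS)
        bits = _dicom.get_us(el, _dicom.TAG_BITS_ALLOCATED)
        if bits != 16:
            raise ValueError(f"{f}: only 16-bit pixel data is supported")
        signed = _dicom.get_us(el, _dicom.TAG_PIXEL_REPRESENTATION) == 1
        _, raw = el[_dicom.TAG_PIXEL_DATA]
        px = np.frombuffer(raw[: rows * cols * 2],
                           dtype="<i2" if signed else "<u2").reshape(rows, cols)
        orient = tuple(_dicom.get_ds(el, _dicom.TAG_IMAGE_ORIENTATION))
        pos = np.array(_dicom.get_ds(el, _dicom.TAG_IMAGE_POSITION))
        inst = _dicom.get_is(el, _dicom.TAG_INSTANCE_NUMBER)
        pxspacing = _dicom.get_ds(el, _dicom.TAG_PIXEL_SPACING)
        thickness = _dicom.get_ds(el, _dicom.TAG_SLICE_THICKNESS)[0]
        slices.append({"px": px, "orient": orient, "pos": pos, "inst": inst,
                       "spacing": pxspacing, "thickness": thickness,
                       "shape": (rows, cols)})
    ref = slices[0]
    for s in slices[1:]:
        if s["shape"] != ref["shape"] or not np.allclose(s["orient"], ref["orient"]):
            raise ValueError(
                f"{path}: inconsistent slice geometry across the series")
    r = np.array(ref["orient"][:3])
    c = np.array(ref["orient"][3:])
    normal = np.cross(r, c)
    # order by position along the slice normal; ties by instance number
    slices.sort(key=lambda s: (float(np.dot(s["pos"], normal)), s["inst"]))
    voxels = np.stack([s["px"].astype(np.float64) for s in slices])
    if len(slices) > 1:
        gaps = np.diff([float(np.dot(s["pos"], normal)) for s in slices])
        dz = float(np.mean(gaps)) if np.all(gaps > 0) else ref["thickness"]
    else:
        dz = ref["thickness"]
    spacing = (abs(dz), float(ref["spacing"][0]), float(ref["spacing"][1]))
    return VolumeSample(voxels=voxels, spacing=spacing, subject_id=path.name,
                        label=label,
                        provenance={"source": str(path), "format": "dicom_series",
                                    "n_slices": len(slices)})


def write_nifti(sample: VolumeSample, path: str | Path) -> Path:
    """Write as NIfTI-1 with an identity affine scaled by voxel spacing."""
    path = Path(path)
    affine = np.diag(list(sample.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(sample.voxels, dtype=np.float32), affine)
    img.header.set_zooms(sample.spacing)
    nib.save(img, str(path))
    return path


def preprocess_volume(v: VolumeSample,
                      target_shape: tuple[int, int, int] = DEFAULT_TARGET_SHAPE
                      ) -> VolumeSample:
    """Resample (trilinear) to ``target_shape`` and z-score the intensities.

    A constant-intensity volume maps to all zeros instead of dividing by a
    zero standard deviation.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or any(s <= 0 for s in target_shape):
        raise ValueError(f"target shape must be a positive triple, got {target_shape}")
    voxels = np.asarray(v.voxels, dtype=np.float64)
    if voxels.shape != target_shape:
        zoom = [t / s for t, s in zip(target_shape, voxels.shape)]
        voxels = ndimage.zoom(voxels, zoom, order=1, mode="nearest",
                              grid_mode=True)
        # grid_mode zoom can be off by one voxel for awkward ratios; assert
        assert voxels.shape == target_shape, voxels.shape
    sd = voxels.std()
    if sd < 1e-12:
        voxels = np.zeros(target_shape)
    else:
        voxels = (voxels - voxels.mean()) / sd
    new_spacing = tuple(sp * s / t for sp, s, t
                        in zip(v.spacing, v.shape, target_shape))
    return VolumeSample(voxels=voxels, spacing=new_spacing,
                        subject_id=v.subject_id, label=v.label,
                        provenance={**v.provenance, "preprocessed": True,
                                    "target_shape": list(target_shape)})
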