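"""DICOM / NIfTI / MetaImage input and output.

Readers cover the radiotherapy export triplet — a CT image series,
an RT-DOSE grid, and an RT-STRUCT structure set — via pydicom, plus the
research formats NIfTI-1 (nibabel) and MetaImage (SimpleITK) for both
scalar volumes and displacement fields.  Matching writers produce
synthetic DICOM fixtures so every reader can be exercised round-trip
without patient data; they are not a clinical export path.

Geometry notes: DICOM stores in-plane positions as (x, y) and slice
positions as z in the patient (LPS) system, while this package orders
axes (z, y, x); the converters below do the bookkeeping.  NIfTI affines
are written with LPS world coordinates (the ITK convention) so that
round-trips through this module are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import FormatError, LookupError_
from .grid import BinaryMask, DisplacementField, VolumeImage

__all__ = [
    "StructureSet",
    "read_ct_series",
    "write_ct_series",
    "read_rtdose",
    "write_rtdose",
    "read_rtstruct",
    "write_rtstruct",
    "rasterize_structure",
    "write_volume",
    "read_volume",
]

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_DOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_STRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"


@dataclass
class StructureSet:
    """Named structures, each a list of closed planar contours.

    Every contour is an (N, 3) array of world points (x, y, z in mm,
    DICOM patient system), N ≥ 3, all points on one axial plane.
    """

    structures: dict[str, list[np.ndarray]]

    def names(self) -> list[str]:
        return list(self.structures)

    def __getitem__(self, name: str) -> list[np.ndarray]:
        try:
            return self.structures[name]
        except KeyError:
            raise LookupError_(f"no structure named {name!r}") from None


# ---------------------------------------------------------------------------
# CT series


def _file_meta(sop_class: str, sop_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_ct_series(image: VolumeImage, directory) -> list[Path]:
    """Write one CT file per slice (int16 with slope 1 / intercept −1024)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    intercept = -1024.0
    stored = np.round(image.values - intercept).astype(np.int16)
    paths = []
    for k in range(image.shape[0]):
        sop_uid = generate_uid()
        ds = Dataset()
        ds.file_meta = _file_meta(_CT_SOP, sop_uid)
        ds.SOPClassUID = _CT_SOP
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            float(image.origin[2]),
            float(image.origin[1]),
            float(image.origin[0] + k * image.spacing[0]),
        ]
        ds.PixelSpacing = [float(image.spacing[1]), float(image.spacing[2])]
        ds.SliceThickness = float(image.spacing[0])
        ds.Rows, ds.Columns = image.shape[1], image.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = stored[k].tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_ct_series(source) -> VolumeImage:
    """Read a CT series from a directory or an explicit list of files.

    Slices are sorted by their position along the slice axis; the rescale
    slope/intercept is applied so values are HU.  Mixed series UIDs or a
    non-uniform slice gap (0.01 mm tolerance) raise a format error.
    """
    if isinstance(source, (str, Path)):
        files = sorted(Path(source).glob("*.dcm"))
    else:
        files = [Path(f) for f in source]
    if not files:
        raise FormatError("no DICOM files found")
    slices = [pydicom.dcmread(f) for f in files]
    uids = {s.SeriesInstanceUID for s in slices}
    if len(uids) != 1:
        raise FormatError(f"mixed series UIDs: {sorted(uids)}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if np.any(gaps <= 0) or np.ptp(gaps) > 0.01:
            raise FormatError(f"non-uniform slice positions: gaps {gaps}")
        dz = float(gaps[0])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    values = np.stack(
        [
            s.pixel_array.astype(float) * float(s.RescaleSlope) + float(s.RescaleIntercept)
            for s in slices
        ]
    )
    spacing = (dz, float(first.PixelSpacing[0]), float(first.PixelSpacing[1]))
    origin = (
        float(first.ImagePositionPatient[2]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[0]),
    )
    return VolumeImage(values, spacing, origin)


# ---------------------------------------------------------------------------
# RT-DOSE


def write_rtdose(dose: VolumeImage, path, scaling: float = 1e-4) -> Path:
    """Write a multi-frame RT-DOSE object (uint32 scaled by ``scaling`` Gy)."""
    path = Path(path)
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(_DOSE_SOP, sop_uid)
    ds.SOPClassUID = _DOSE_SOP
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = float(scaling)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [
        float(dose.origin[2]),
        float(dose.origin[1]),
        float(dose.origin[0]),
    ]
    ds.PixelSpacing = [float(dose.spacing[1]), float(dose.spacing[2])]
    ds.GridFrameOffsetVector = [float(k * dose.spacing[0]) for k in range(dose.shape[0])]
    ds.NumberOfFrames = dose.shape[0]
    ds.Rows, ds.Columns = dose.shape[1], dose.shape[2]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.round(dose.values / scaling).astype(np.uint32).tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtdose(path) -> VolumeImage:
    """Read an RT-DOSE grid; values = stored × DoseGridScaling, in Gy."""
    ds = pydicom.dcmread(path)
    if "DoseGridScaling" not in ds:
        raise FormatError("RT-DOSE file has no DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    values = ds.pixel_array.astype(float) * scaling
    if values.ndim == 2:
        values = values[None]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1:
        gaps = np.diff(offsets)
        if np.ptp(gaps) > 0.01:
            raise FormatError("non-uniform dose frame offsets")
        dz = float(gaps[0])
    else:
        dz = 1.0
    origin = (
        float(ds.ImagePositionPatient[2]) + offsets[0],
        float(ds.ImagePositionPatient[1]),
        float(ds.ImagePositionPatient[0]),
    )
    spacing = (dz, float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return VolumeImage(values, spacing, origin)


# ---------------------------------------------------------------------------
# RT-STRUCT


def write_rtstruct(structset: StructureSet, path) -> Path:
    """Write the structure set as an RT-STRUCT object."""
    path = Path(path)
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(_STRUCT_SOP, sop_uid)
    ds.SOPClassUID = _STRUCT_SOP
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "synthetic"
    roi_seq, contour_seq = [], []
    for number, (name, contours) in enumerate(structset.structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        roi_seq.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        seq = []
        for poly in contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            pts = np.asarray(poly, float).reshape(-1, 3)
            c.NumberOfContourPoints = len(pts)
            c.ContourData = [float(v) for v in pts.ravel()]
            seq.append(c)
        rc.ContourSequence = seq
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(path, enforce_file_format=True)
    return path


def read_rtstruct(path) -> StructureSet:
    """Read ROI names and closed planar contours from an RT-STRUCT file."""
    ds = pydicom.dcmread(path)
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    structures: dict[str, list[np.ndarray]] = {name: [] for name in names.values()}
    for rc in getattr(ds, "ROIContourSequence", []):
        name = names[int(rc.ReferencedROINumber)]
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            if len(pts) < 3:
                raise FormatError(f"contour of {name!r} has fewer than 3 vertices")
            structures[name].append(pts)
    return StructureSet(structures)


def rasterize_structure(structset: StructureSet, name: str, ref: VolumeImage) -> BinaryMask:
    """Rasterize a named structure onto the grid of ``ref``.

    A voxel is inside iff its center lies inside the contour polygon of
    its slice under the even-odd rule; overlapping contours on one slice
    toggle (XOR), so holes and islands are honoured.  Slices without
    contours are empty.  Vertex order (CW vs CCW) is irrelevant.
    """
    from matplotlib.path import Path as MplPath

    contours = structset[name]
    mask = np.zeros(ref.shape, dtype=bool)
    ys = ref.origin[1] + ref.spacing[1] * np.arange(ref.shape[1])
    xs = ref.origin[2] + ref.spacing[2] * np.arange(ref.shape[2])
    XX, YY = np.meshgrid(xs, ys)  # (ny, nx)
    centers = np.column_stack([XX.ravel(), YY.ravel()])
    for poly in contours:
        pts = np.asarray(poly, float).reshape(-1, 3)
        z = float(np.mean(pts[:, 2]))
        k = int(round((z - ref.origin[0]) / ref.spacing[0]))
        if not (0 <= k < ref.shape[0]):
            continue
        inside = MplPath(pts[:, :2]).contains_points(centers).reshape(ref.shape[1:])
        mask[k] ^= inside
    return BinaryMask.from_image(ref, mask)


# ---------------------------------------------------------------------------
# Research formats (NIfTI-1, MetaImage)


def _is_field(obj) -> bool:
    return isinstance(obj, DisplacementField)


def write_volume(obj, path, format: str | None = None) -> Path:
    """Write a :class:`VolumeImage` or :class:`DisplacementField` losslessly.

    ``format`` is ``"nifti"`` or ``"metaimage"``; inferred from the
    extension (.nii/.nii.gz vs .mha/.mhd) when omitted.
    """
    path = Path(path)
    if format is None:
        format = "metaimage" if path.suffix.lower() in (".mha", ".mhd") else "nifti"
    if format == "nifti":
        return _write_nifti(obj, path)
    if format == "metaimage":
        return _write_metaimage(obj, path)
    raise FormatError(f"unknown format {format!r}")


def read_volume(path, field: bool = False):
    """Read a volume (or displacement field with ``field=True``) written by
    :func:`write_volume`."""
    path = Path(path)
    if path.suffix.lower() in (".mha", ".mhd"):
        return _read_metaimage(path, field)
    return _read_nifti(path, field)


def _nifti_affine(spacing, origin) -> np.ndarray:
    # data is stored (x, y, z); world kept in LPS
    aff = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    aff[:3, 3] = [origin[2], origin[1], origin[0]]
    return aff


def _write_nifti(obj, path) -> Path:
    import nibabel as nib

    if _is_field(obj):
        data = np.transpose(obj.vectors, (3, 2, 1, 0))[..., ::-1]  # (x,y,z,3) comps x,y,z
    else:
        data = np.transpose(obj.values, (2, 1, 0))
    img = nib.Nifti1Image(np.asarray(data, np.float64), _nifti_affine(obj.spacing, obj.origin))
    nib.save(img, str(path))
    return path


def _read_nifti(path, field: bool):
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    spacing = (abs(aff[2, 2]), abs(aff[1, 1]), abs(aff[0, 0]))
    origin = (aff[2, 3], aff[1, 3], aff[0, 3])
    if field:
        if data.ndim != 4 or data.shape[-1] != 3:
            raise FormatError("expected a 4-D (x,y,z,3) displacement field")
        vec = np.transpose(data[..., ::-1], (3, 2, 1, 0))
        return DisplacementField(vec, spacing, origin)
    if data.ndim != 3:
        raise FormatError("expected a 3-D scalar volume")
    return VolumeImage(np.transpose(data, (2, 1, 0)), spacing, origin)


def _write_metaimage(obj, path) -> Path:
    import SimpleITK as sitk

    if _is_field(obj):
        arr = np.transpose(obj.vectors, (1, 2, 3, 0))[..., ::-1]  # (z,y,x,3) comps x,y,z
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=True)
    else:
        img = sitk.GetImageFromArray(obj.values)
    img.SetSpacing((float(obj.spacing[2]), float(obj.spacing[1]), float(obj.spacing[0])))
    img.SetOrigin((float(obj.origin[2]), float(obj.origin[1]), float(obj.origin[0])))
    sitk.WriteImage(img, str(path))
    return path


def _read_metaimage(path, field: bool):
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    sp = img.GetSpacing()
    og = img.GetOrigin()
    spacing = (sp[2], sp[1], sp[0])
    origin = (og[2], og[1], og[0])
    if field:
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise FormatError("expected a vector MetaImage with 3 components")
        vec = np.transpose(arr[..., ::-1], (3, 0, 1, 2))
        return DisplacementField(vec, spacing, origin)
    return VolumeImage(arr.astype(float), spacing, origin)
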