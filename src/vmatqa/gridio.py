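"""File formats: plain-text dose grids, CSV sample maps, DICOM RT Dose.

The native grid format is a small self-describing text file:

    # vmatqa dose grid v1
    nx 4
    ny 3
    origin_mm -5.0 -5.0
    spacing_mm 1.0 1.0
    <ny rows of nx values, row-major, y increasing down the file>

Values are written with 17 significant digits so that a write -> read
round trip is bit-exact for float64.  Measured/coalesced maps travel as
CSV (x_mm, y_mm, dose).  A minimal DICOM RT Dose import/export maps the
2D grid, spacing, origin and DoseGridScaling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import GroundTruthDose, VoxelPhantom
from .detector import MeasuredMap
from .reconstruction import ReconstructedDose

__all__ = [
    "write_dose_grid",
    "read_dose_grid",
    "write_measured_map",
    "read_measured_map",
    "write_volume",
    "read_rtdose",
    "write_rtdose",
    "GridFormatError",
]

_MAGIC = "# vmatqa dose grid v1"


class GridFormatError(ValueError):
    """Malformed dose-grid file."""


def write_dose_grid(grid: GroundTruthDose, path) -> None:
    path = Path(path)
    ny, nx = grid.values.shape
    with path.open("w") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(f"nx {nx}\n")
        fh.write(f"ny {ny}\n")
        fh.write(f"origin_mm {grid.origin[0]!r} {grid.origin[1]!r}\n")
        fh.write(f"spacing_mm {grid.spacing[0]!r} {grid.spacing[1]!r}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_dose_grid(path) -> GroundTruthDose:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if header != _MAGIC:
            raise GridFormatError(f"not a dose-grid file: {path}")
        meta = {}
        for _ in range(4):
            line = fh.readline().split()
            if not line:
                raise GridFormatError("truncated header")
            meta[line[0]] = line[1:]
        try:
            nx = int(meta["nx"][0])
            ny = int(meta["ny"][0])
            origin = (float(meta["origin_mm"][0]), float(meta["origin_mm"][1]))
            spacing = (float(meta["spacing_mm"][0]), float(meta["spacing_mm"][1]))
        except (KeyError, IndexError, ValueError) as exc:
            raise GridFormatError(f"malformed header: {exc}") from exc
        if nx <= 0 or ny <= 0:
            raise GridFormatError("grid dimensions must be positive")
        if min(spacing) <= 0:
            raise GridFormatError("grid spacing must be positive")
        try:
            values = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise GridFormatError(f"non-numeric payload: {exc}") from exc
    if values.shape != (ny, nx):
        raise GridFormatError(
            f"payload shape {values.shape} does not match header ({ny}, {nx})"
        )
    return GroundTruthDose(values=values, origin=origin, spacing=spacing)


def write_measured_map(mm: MeasuredMap, path) -> None:
    pd.DataFrame(
        {"x_mm": mm.positions[:, 0], "y_mm": mm.positions[:, 1], "dose": mm.values}
    ).to_csv(path, index=False, float_format="%.17g")


def read_measured_map(path, array_model: str = "") -> MeasuredMap:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x_mm", "y_mm", "dose"):
        if col not in df.columns:
            raise GridFormatError(f"measured-map CSV lacks column {col!r}")
    return MeasuredMap(
        positions=df[["x_mm", "y_mm"]].to_numpy(dtype=float),
        values=df["dose"].to_numpy(dtype=float),
        shift_mm=(0.0, 0.0),
        array_model=array_model,
        source=str(path),
    )


def write_volume(recon: ReconstructedDose, path) -> None:
    """Stacked plain-text z-slices of a reconstructed volume, plus metadata."""
    path = Path(path)
    ph: VoxelPhantom = recon.phantom
    nz, ny, nx = recon.values.shape
    with path.open("w") as fh:
        fh.write("# vmatqa dose volume v1\n")
        fh.write(f"nx {nx}\nny {ny}\nnz {nz}\n")
        fh.write(f"origin_mm {ph.origin[0]!r} {ph.origin[1]!r} {ph.origin[2]!r}\n")
        fh.write(f"spacing_mm {ph.spacing[0]!r} {ph.spacing[1]!r} {ph.spacing[2]!r}\n")
        for iz in range(nz):
            fh.write(f"# slice {iz}\n")
            for row in recon.values[iz]:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# DICOM RT Dose (optional interchange)
# ---------------------------------------------------------------------------

def read_rtdose(path) -> GroundTruthDose:
    """Import a single-frame DICOM RT Dose plane as a planar dose grid."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float) * float(getattr(ds, "DoseGridScaling", 1.0))
    if arr.ndim == 3:
        if arr.shape[0] != 1:
            raise GridFormatError("multi-frame RT Dose: planar import expects one frame")
        arr = arr[0]
    spacing = tuple(float(v) for v in ds.PixelSpacing)  # (row, col) mm
    ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    return GroundTruthDose(
        values=arr,
        origin=(float(ipp[0]), float(ipp[1])),
        spacing=(spacing[1], spacing[0]),
    )


def write_rtdose(grid: GroundTruthDose, path) -> None:
    """Export a planar dose grid as a minimal DICOM RT Dose object."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    scaling = float(grid.values.max()) / (2**31 - 1) if grid.values.max() > 0 else 1.0
    pixels = np.round(grid.values / scaling).astype(np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = pydicom.uid.RTDoseStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.Rows, ds.Columns = grid.values.shape
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
    ds.ImagePositionPatient = [grid.origin[0], grid.origin[1], 0.0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.DoseGridScaling = scaling
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)
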