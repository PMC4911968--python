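"""Volume and report I/O.

NIfTI is handled by nibabel.  A minimal uncompressed MetaImage (.mha)
reader/writer is provided for interoperability with ITK-based tools; it
covers only single-file, non-compressed scalar volumes.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import PlanarImage, VoxelGrid

_MHA_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}


class UnsupportedFormatError(ValueError):
    pass


def _format_of(path: os.PathLike) -> str:
    name = str(path)
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".mha"):
        return "mha"
    raise UnsupportedFormatError(f"unsupported volume format: {name!r}")


def read_volume(path: os.PathLike) -> VoxelGrid:
    """Read a 3D volume (.nii/.nii.gz/.mha) into a :class:`VoxelGrid`."""
    fmt = _format_of(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return VoxelGrid(data, spacing)
    return _read_mha(path)


def write_volume(grid: VoxelGrid, path: os.PathLike) -> None:
    """Write a :class:`VoxelGrid` as NIfTI or uncompressed MetaImage."""
    fmt = _format_of(path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        affine = np.diag([*grid.spacing, 1.0])
        nib.save(nib.Nifti1Image(grid.data, affine), str(path))
        return
    _write_mha(grid, path)


def read_paired_volumes(activity_path, hu_path) -> tuple[VoxelGrid, VoxelGrid]:
    """Read co-registered activity and HU volumes, rejecting mismatches."""
    activity = read_volume(activity_path)
    hu = read_volume(hu_path)
    activity.require_same_grid(hu)
    return activity, hu


def _read_mha(path) -> VoxelGrid:
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise UnsupportedFormatError(f"{path}: truncated MetaImage header")
            key, _, value = line.decode("ascii").partition("=")
            header[key.strip()] = value.strip()
            if key.strip() == "ElementDataFile":
                break
        if header.get("ElementDataFile") != "LOCAL":
            raise UnsupportedFormatError("only single-file (LOCAL) .mha supported")
        if header.get("CompressedData", "False").lower() == "true":
            raise UnsupportedFormatError("compressed .mha not supported")
        etype = header.get("ElementType", "")
        if etype not in _MHA_TYPES:
            raise UnsupportedFormatError(f"unsupported ElementType {etype!r}")
        shape = tuple(int(v) for v in header["DimSize"].split())
        spacing = tuple(float(v) for v in header["ElementSpacing"].split())
        raw = fh.read()
    data = np.frombuffer(raw, dtype=_MHA_TYPES[etype])
    if data.size != int(np.prod(shape)):
        raise UnsupportedFormatError(f"{path}: data size does not match DimSize")
    # MetaImage stores fastest-varying axis first
    data = data.reshape(shape[::-1]).transpose().astype(np.float64)
    return VoxelGrid(data, spacing)


def _write_mha(grid: VoxelGrid, path) -> None:
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n"
        f"ElementSpacing = {grid.spacing[0]} {grid.spacing[1]} {grid.spacing[2]}\n"
        "ElementType = MET_DOUBLE\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(grid.data.transpose()).tobytes())


def write_planar_csv(img: PlanarImage, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, img.counts, delimiter=",")


def read_planar_csv(path, pixel_spacing, view) -> PlanarImage:
    counts = np.loadtxt(path, delimiter=",")
    return PlanarImage(counts=counts, pixel_spacing=pixel_spacing, view=view)
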