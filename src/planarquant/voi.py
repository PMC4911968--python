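"""Automatic VOI/ROI construction and kidney geometry measurement.

Builds the kidney VOI, body mask, projection column VOI, true-background
VOI (column minus kidney), ten 36-degree sector background ROIs at a fixed
distance around the kidney silhouette, and the surrounding ROI B11; and
measures the thicknesses/depth/volume needed by the planar quantification
formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import AXIS_AP, Mask3D, ROI2D, VoxelGrid

_CONN6 = ndimage.generate_binary_structure(3, 1)


class EmptyMaskError(ValueError):
    """An operation produced or received an empty mask/ROI."""


class DegenerateGeometryError(ValueError):
    """The geometric configuration does not admit the requested measure."""


@dataclass(frozen=True)
class KidneyGeometry:
    """Per-kidney geometry for the planar quantification formulas.

    Attributes
    ----------
    t_k : float
        Kidney thickness in the anterior-posterior direction (cm).
    t_p : float
        Patient (body) AP thickness at the kidney midsection (cm).
    d_k : float
        Distance from the posterior body surface to the posterior kidney
        surface (cm).
    v_k : float
        Kidney volume (ml).
    """

    t_k: float
    t_p: float
    d_k: float
    v_k: float

    def __post_init__(self) -> None:
        if not (0 < self.t_k < self.t_p):
            raise DegenerateGeometryError(
                f"need 0 < t_k < t_p, got t_k={self.t_k}, t_p={self.t_p}"
            )
        if not (-1e-9 <= self.d_k <= self.t_p - self.t_k + 1e-9):
            raise DegenerateGeometryError(
                f"need 0 <= d_k <= t_p - t_k, got d_k={self.d_k}"
            )
        if self.v_k <= 0:
            raise DegenerateGeometryError("v_k must be > 0")


def _fill_ap_columns(mask: np.ndarray) -> np.ndarray:
    """Fill every anterior-posterior column between its first and last voxel."""
    ny = mask.shape[AXIS_AP]
    any_col = mask.any(axis=AXIS_AP)
    first = np.argmax(mask, axis=AXIS_AP)
    last = ny - 1 - np.argmax(mask[:, ::-1, :], axis=AXIS_AP)
    j = np.arange(ny)[None, :, None]
    filled = (j >= first[:, None, :]) & (j <= last[:, None, :])
    filled &= any_col[:, None, :]
    return filled


def body_mask(counts: VoxelGrid, threshold: float = 5.0) -> Mask3D:
    """Separate the patient body from surrounding air by count thresholding.

    Voxels with ``counts >= threshold`` are kept; the largest 6-connected
    component is selected and holes are filled along AP columns.
    """
    if (counts.data < 0).any():
        raise ValueError("count volume must be non-negative")
    raw = counts.data >= threshold
    if not raw.any():
        raise EmptyMaskError(f"no voxel reaches the body threshold {threshold}")
    labels, n = ndimage.label(raw, structure=_CONN6)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    largest = labels == sizes.argmax()
    return Mask3D(_fill_ap_columns(largest), counts.spacing, "body")


def segment_kidney(
    counts: VoxelGrid,
    seed_point: tuple[int, int, int],
    frac: float = 0.5,
    probe_radius_mm: float = 50.0,
    min_volume_ml: float = 20.0,
    label: str = "kidney",
) -> Mask3D:
    """Fraction-of-maximum region growing from a seed voxel.

    The threshold is ``frac`` times the maximum count inside a
    seed-centred probe sphere; the mask is the 6-connected component of
    supra-threshold voxels containing the seed.  Segments smaller than
    ``min_volume_ml`` are rejected as degenerate seeds.
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    seed = tuple(int(i) for i in seed_point)
    if any(i < 0 or i >= n for i, n in zip(seed, counts.shape)):
        raise ValueError(f"seed point {seed} outside the grid")

    coords = [
        (np.arange(n, dtype=np.float64) - s) * sp
        for n, s, sp in zip(counts.shape, seed, counts.spacing)
    ]
    xs, ys, zs = np.meshgrid(*coords, indexing="ij", sparse=True)
    probe = xs**2 + ys**2 + zs**2 <= probe_radius_mm**2
    peak = counts.data[probe].max()
    if peak <= 0:
        raise EmptyMaskError("no counts inside the probe sphere")

    supra = counts.data >= frac * peak
    if not supra[seed]:
        raise EmptyMaskError("seed voxel is below the segmentation threshold")
    labels, _ = ndimage.label(supra, structure=_CONN6)
    segment = labels == labels[seed]
    volume = segment.sum() * counts.voxel_volume_ml
    if volume < min_volume_ml:
        raise EmptyMaskError(
            f"segment volume {volume:.1f} ml below minimum {min_volume_ml} ml"
        )
    return Mask3D(segment, counts.spacing, label)


def project_mask_to_roi(m: Mask3D) -> ROI2D:
    """Silhouette of a mask on the (x, z) plane: pixel on iff any voxel in
    its AP column is on."""
    if m.voxel_count == 0:
        raise EmptyMaskError("cannot project an empty mask")
    sx, _, sz = m.spacing
    return ROI2D(m.voxels.any(axis=AXIS_AP), (sx, sz), m.label)


def backproject_roi_to_column(roi: ROI2D, body: Mask3D) -> Mask3D:
    """Sweep an ROI back along the AP axis, clipped to the body mask.

    Column length per pixel therefore equals the local anterior-to-posterior
    body extent (the patient thickness).
    """
    if roi.pixel_count == 0:
        raise EmptyMaskError("cannot backproject an empty ROI")
    voxels = roi.pixels[:, None, :] & body.voxels
    if not voxels.any():
        raise EmptyMaskError(f"ROI {roi.label!r} lies entirely outside the body")
    return Mask3D(voxels, body.spacing, roi.label or "column")


def true_background_voi(column: Mask3D, kidney: Mask3D) -> Mask3D:
    """Over- and underlying tissue VOI: the column minus the kidney."""
    if not kidney.is_subset_of(column):
        raise ValueError("kidney VOI must be a subset of its column VOI")
    tb = column.voxels & ~kidney.voxels
    if not tb.any():
        raise DegenerateGeometryError("true background VOI is empty")
    return Mask3D(tb, column.spacing, "TB")


def roi_centroid(roi: ROI2D) -> tuple[float, float]:
    """Unweighted mean of the on-pixel coordinates (no rounding)."""
    ix, iz = np.nonzero(roi.pixels)
    if ix.size == 0:
        raise EmptyMaskError("centroid of an empty ROI")
    return float(ix.mean()), float(iz.mean())


def sector_angles_deg(roi: ROI2D, center: tuple[float, float]) -> np.ndarray:
    """Angle of each on-pixel about ``center``, in [0, 360).

    0 deg points cranial (+z); angles grow toward the patient's left (+x).
    """
    ix, iz = np.nonzero(roi.pixels)
    dx = ix - center[0]
    dz = iz - center[1]
    return np.degrees(np.arctan2(dx, dz)) % 360.0


def build_background_rois(
    kidney_roi: ROI2D,
    gap: int = 2,
    width: int = 4,
    n_sectors: int = 10,
) -> dict[str, ROI2D]:
    """Build the sector background ROIs B1..Bn and the surrounding ROI.

    A band at Euclidean pixel distance in (gap, gap + width] from the
    kidney silhouette forms the surrounding ROI ("B11" for the default 10
    sectors).  Each band pixel is assigned to sector k when its angle about
    the kidney-ROI centroid falls in [(k-1)*360/n, k*360/n); the sectors
    partition the band exactly.
    """
    if kidney_roi.pixel_count == 0:
        raise EmptyMaskError("kidney ROI is empty")
    if gap < 0 or width <= 0 or n_sectors < 1:
        raise ValueError("need gap >= 0, width > 0, n_sectors >= 1")

    dist = ndimage.distance_transform_edt(~kidney_roi.pixels)
    band = (dist > gap) & (dist <= gap + width)
    if not band.any():
        raise EmptyMaskError("background band is empty")
    outer = dist <= gap + width
    edge = np.zeros_like(outer)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    if (outer & edge).any():
        raise DegenerateGeometryError(
            "background band is clipped by the image border"
        )

    center = roi_centroid(kidney_roi)
    ix, iz = np.nonzero(band)
    theta = np.degrees(np.arctan2(ix - center[0], iz - center[1])) % 360.0
    sector = np.floor(theta / (360.0 / n_sectors)).astype(int)
    sector = np.clip(sector, 0, n_sectors - 1)  # theta == 360 folds to last

    spacing = kidney_roi.pixel_spacing
    rois: dict[str, ROI2D] = {}
    for k in range(n_sectors):
        pix = np.zeros_like(band)
        pix[ix[sector == k], iz[sector == k]] = True
        rois[f"B{k + 1}"] = ROI2D(pix, spacing, f"B{k + 1}")
    rois[f"B{n_sectors + 1}"] = ROI2D(band, spacing, f"B{n_sectors + 1}")
    return rois


def measure_geometry(
    kidney: Mask3D, body: Mask3D, spacing_mm: tuple[float, float, float]
) -> KidneyGeometry:
    """Measure t_k, t_p, d_k (cm) and v_k (ml) from kidney and body masks.

    Measurements are taken in the transverse slice at the kidney centroid,
    along the AP line through the kidney's in-slice centroid.  d_k runs from
    the posterior body surface to the posterior kidney surface.
    """
    if kidney.voxel_count == 0 or body.voxel_count == 0:
        raise EmptyMaskError("kidney and body masks must be non-empty")
    kx, ky, kz = np.nonzero(kidney.voxels)
    z_mid = int(round(kz.mean()))
    in_slice = kidney.voxels[:, :, z_mid]
    if not in_slice.any():
        raise DegenerateGeometryError("kidney absent from its centroid slice")
    sx_idx = int(round(np.nonzero(in_slice)[0].mean()))
    k_line = kidney.voxels[sx_idx, :, z_mid]
    b_line = body.voxels[sx_idx, :, z_mid]
    if not k_line.any() or not b_line.any():
        raise DegenerateGeometryError("no kidney/body voxels on the AP centroid line")

    dy_cm = spacing_mm[AXIS_AP] / 10.0
    kj = np.nonzero(k_line)[0]
    bj = np.nonzero(b_line)[0]
    t_k = (kj[-1] - kj[0] + 1) * dy_cm
    t_p = (bj[-1] - bj[0] + 1) * dy_cm
    d_k = (bj[-1] - kj[-1]) * dy_cm
    voxel_volume_ml = spacing_mm[0] * spacing_mm[1] * spacing_mm[2] / 1000.0
    v_k = kidney.voxel_count * voxel_volume_ml
    return KidneyGeometry(t_k=t_k, t_p=t_p, d_k=max(d_k, 0.0), v_k=v_k)
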