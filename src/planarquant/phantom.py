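"""Synthetic SPECT/CT torso phantoms with known ground-truth activity.

A phantom is a labelled pair of co-registered volumes: an activity volume
(expected counts per voxel) and an HU volume, together with per-organ masks
and a truth table of activity concentrations.  Geometry is rasterised by
voxel-centre inclusion, so a fixed spec yields a bit-identical phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import Mask3D, VoxelGrid

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

AIR_HU = -1000.0


class PhantomSpecError(ValueError):
    """The phantom specification violates an invariant."""


@dataclass(frozen=True)
class Organ:
    """One geometric primitive of the phantom.

    ``size_mm`` is interpreted per shape: semi-axes for ``ellipsoid``,
    full edge lengths for ``box``.
    """

    name: str
    shape: str  # "ellipsoid" | "box"
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    activity_conc: float  # counts/ml
    hu: float

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "box"):
            raise PhantomSpecError(f"unknown organ shape {self.shape!r}")
        if self.activity_conc < 0:
            raise PhantomSpecError(
                f"organ {self.name!r}: activity concentration must be >= 0"
            )
        if any(s <= 0 for s in self.size_mm):
            raise PhantomSpecError(f"organ {self.name!r}: size must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom.

    Organs are painted in the order body, kidneys, extra organs; a
    later-listed organ overwrites earlier ones where they overlap.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 64)
    voxel_spacing: tuple[float, float, float] = (2.21, 2.21, 4.42)
    body: Organ | None = None
    kidneys: tuple[Organ, ...] = ()
    extra_organs: tuple[Organ, ...] = ()
    psf_fwhm_mm: float = 0.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body is None:
            raise PhantomSpecError("a body organ is required")
        if any(n < 8 for n in self.grid_shape):
            raise PhantomSpecError("grid_shape must be >= 8 voxels per axis")
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomSpecError("voxel_spacing must be positive")
        if self.psf_fwhm_mm < 0:
            raise PhantomSpecError("psf_fwhm_mm must be >= 0")
        object.__setattr__(self, "kidneys", tuple(self.kidneys))
        object.__setattr__(self, "extra_organs", tuple(self.extra_organs))


@dataclass(frozen=True)
class LabeledPhantom:
    """Phantom volumes plus per-organ masks and the ground-truth table.

    ``truth`` has columns ``organ``, ``concentration`` (counts/ml) and
    ``volume_ml``; it reflects the ideal pre-noise, pre-blur volume.
    """

    activity: VoxelGrid
    hu: VoxelGrid
    organ_masks: dict[str, Mask3D]
    truth: pd.DataFrame
    spec: PhantomSpec | None = None


def _voxel_centers(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    """Open coordinate grids of voxel-centre positions in mm."""
    axes = [
        (np.arange(n, dtype=np.float64) + 0.5) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _rasterise(organ: Organ, coords) -> np.ndarray:
    cx, cy, cz = organ.center_mm
    xs, ys, zs = coords
    if organ.shape == "ellipsoid":
        ax, ay, az = organ.size_mm
        r2 = (
            ((xs - cx) / ax) ** 2
            + ((ys - cy) / ay) ** 2
            + ((zs - cz) / az) ** 2
        )
        return r2 <= 1.0
    # box: size_mm are full extents, voxel-centre inclusion with closed bounds
    ex, ey, ez = organ.size_mm
    return (
        (np.abs(xs - cx) <= ex / 2)
        & (np.abs(ys - cy) <= ey / 2)
        & (np.abs(zs - cz) <= ez / 2)
    )


def build_phantom(spec: PhantomSpec) -> LabeledPhantom:
    """Rasterise a :class:`PhantomSpec` into a :class:`LabeledPhantom`.

    Deterministic given the spec: membership is decided by voxel-centre
    inclusion and organs are painted in listed order (later wins).

    Raises
    ------
    PhantomSpecError
        If a kidney is not strictly inside the body or the spec is
        otherwise invalid.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = tuple(float(s) for s in spec.voxel_spacing)
    coords = _voxel_centers(shape, spacing)

    body_mask = _rasterise(spec.body, coords)
    if not body_mask.any():
        raise PhantomSpecError("body does not cover any voxel")

    conc = np.zeros(shape, dtype=np.float64)
    hu = np.full(shape, AIR_HU, dtype=np.float64)
    conc[body_mask] = spec.body.activity_conc
    hu[body_mask] = spec.body.hu

    organs = list(spec.kidneys) + list(spec.extra_organs)
    names = [o.name for o in organs]
    if len(set(names)) != len(names):
        raise PhantomSpecError("organ names must be unique")
    if "body" in names or "background" in names:
        raise PhantomSpecError("'body' and 'background' are reserved organ names")

    raw_masks: dict[str, np.ndarray] = {}
    for organ in organs:
        m = _rasterise(organ, coords)
        if not m.any():
            raise PhantomSpecError(f"organ {organ.name!r} covers no voxel")
        raw_masks[organ.name] = m
    for kidney in spec.kidneys:
        m = raw_masks[kidney.name]
        if (m & ~body_mask).any():
            raise PhantomSpecError(
                f"kidney {kidney.name!r} is not strictly inside the body"
            )

    # later-listed organs overwrite earlier ones
    final_masks: dict[str, np.ndarray] = {}
    for i, organ in enumerate(organs):
        m = raw_masks[organ.name].copy()
        for later in organs[i + 1 :]:
            m &= ~raw_masks[later.name]
        final_masks[organ.name] = m
        conc[m] = organ.activity_conc
        hu[m] = organ.hu

    any_organ = np.zeros(shape, dtype=bool)
    for m in final_masks.values():
        any_organ |= m
    background = body_mask & ~any_organ

    voxel_volume_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    activity = conc * voxel_volume_ml  # expected counts per voxel

    masks = {"body": Mask3D(body_mask, spacing, "body")}
    masks["background"] = Mask3D(background, spacing, "background")
    for name, m in final_masks.items():
        masks[name] = Mask3D(m, spacing, name)

    rows = [
        {
            "organ": "background",
            "concentration": spec.body.activity_conc,
            "volume_ml": background.sum() * voxel_volume_ml,
        }
    ]
    for organ in organs:
        m = final_masks[organ.name]
        rows.append(
            {
                "organ": organ.name,
                "concentration": organ.activity_conc,
                "volume_ml": m.sum() * voxel_volume_ml,
            }
        )
    truth = pd.DataFrame(rows, columns=["organ", "concentration", "volume_ml"])

    return LabeledPhantom(
        activity=VoxelGrid(activity, spacing),
        hu=VoxelGrid(hu, spacing),
        organ_masks=masks,
        truth=truth,
        spec=spec,
    )


def apply_psf_blur(vol: VoxelGrid, fwhm_mm: float) -> VoxelGrid:
    """Gaussian blur with the given FWHM (mm), identical per axis.

    Emulates reconstruction resolution.  Uses zero padding at the grid
    boundary, so total counts are conserved only while the blurred support
    stays inside the grid; callers must keep activity away from the edges.
    ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / s for s in vol.spacing]
    blurred = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="constant")
    return vol.with_data(blurred)


def add_poisson_noise(vol: VoxelGrid, seed: int) -> VoxelGrid:
    """Replace each voxel by a Poisson draw with that voxel as expectation."""
    if (vol.data < 0).any():
        raise ValueError("activity volume must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(vol.data).astype(np.float64)
    return vol.with_data(noisy)


def ground_truth_ac(ph: LabeledPhantom, organ: str) -> float:
    """True activity concentration (counts/ml) of an organ, by construction."""
    hit = ph.truth.loc[ph.truth["organ"] == organ]
    if hit.empty:
        raise KeyError(f"unknown organ {organ!r}")
    return float(hit["concentration"].iloc[0])
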