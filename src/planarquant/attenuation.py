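"""HU-to-attenuation conversion and attenuated planar forward projection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import ANTERIOR, AXIS_AP, POSTERIOR, PlanarImage, VoxelGrid

#: Default effective linear attenuation coefficient of water at 208 keV
#: (narrow-beam, cm^-1).  A parameter of the method, overridable in config.
DEFAULT_MU_WATER = 0.136


@dataclass(frozen=True)
class AttenuationMap:
    """Voxelwise linear attenuation coefficients (cm^-1) plus the water value."""

    mu: VoxelGrid
    mu_w: float


def hu_to_mu(hu: VoxelGrid, mu_w: float = DEFAULT_MU_WATER) -> AttenuationMap:
    """Convert a Hounsfield volume to linear attenuation coefficients.

    mu = mu_w + HU * mu_w / 1000, clamped below at zero (air voxels can
    dip negative through rounding).  HU = 0 maps exactly to ``mu_w``.
    """
    if mu_w <= 0:
        raise ValueError("mu_w must be > 0")
    if not np.isfinite(hu.data).all():
        raise ValueError("HU volume contains non-finite values")
    mu = mu_w + hu.data * (mu_w / 1000.0)
    np.clip(mu, 0.0, None, out=mu)
    return AttenuationMap(mu=hu.with_data(mu), mu_w=float(mu_w))


def attenuated_project(
    activity: VoxelGrid, att: AttenuationMap | None, view: str
) -> PlanarImage:
    """Form an attenuated planar image along the anterior-posterior axis.

    For each (x, z) column the pixel value is

        sum_i a_i * exp(-(sum_{j nearer detector} mu_j + mu_i / 2) * dy)

    with ``dy`` the AP voxel size in cm; the emitting voxel contributes half
    its own attenuation so that the discrete sum converges to the continuous
    slab integral.  "Nearer the detector" means smaller y index for the
    anterior view and larger y index for the posterior view.  ``att=None``
    (or an all-zero map) reduces to a plain ray sum.
    """
    if view not in (ANTERIOR, POSTERIOR):
        raise ValueError(f"view must be '{ANTERIOR}' or '{POSTERIOR}'")
    a = activity.data
    if att is None:
        mu = np.zeros_like(a)
    else:
        activity.require_same_grid(att.mu)
        mu = att.mu.data
    dy_cm = activity.spacing[AXIS_AP] / 10.0

    if view == POSTERIOR:
        a = a[:, ::-1, :]
        mu = mu[:, ::-1, :]
    # path to voxel i: all voxels before it along the ray plus half of itself
    cum = np.cumsum(mu, axis=AXIS_AP)
    path = (cum - 0.5 * mu) * dy_cm
    counts = np.sum(a * np.exp(-path), axis=AXIS_AP)

    sx, _, sz = activity.spacing
    return PlanarImage(counts=counts, pixel_spacing=(sx, sz), view=view)
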