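"""ROI counting, scaled-background net counts, and the conjugate-view /
posterior-view activity-concentration estimators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Mask3D, PlanarImage, ROI2D, VoxelGrid
from .voi import KidneyGeometry

#: Below this value of mu * t_k the closed-form zero-attenuation limits are
#: used instead of the full expressions.
SMALL_MU_TK = 1e-8


class NegativeNetCountsError(ValueError):
    """Net counts are non-positive; the estimator refuses rather than
    returning a non-physical concentration."""


@dataclass(frozen=True)
class NetCountResult:
    """Background-subtracted kidney counts for one background ROI."""

    a_net: float
    p_net: float
    bg_label: str

    @property
    def conjv_negative(self) -> bool:
        return self.a_net <= 0 or self.p_net <= 0

    @property
    def postv_negative(self) -> bool:
        return self.p_net <= 0


@dataclass(frozen=True)
class ACEstimate:
    """An activity-concentration estimate (counts/ml) with its provenance."""

    value: float
    method: str  # "ConjV" | "PostV" | "SPECT"
    bg_label: str | None = None


def roi_counts(img: PlanarImage, roi: ROI2D) -> float:
    """Total counts inside a planar ROI."""
    if img.shape != roi.pixels.shape:
        raise ValueError(
            f"image shape {img.shape} does not match ROI shape {roi.pixels.shape}"
        )
    return float(img.counts[roi.pixels].sum())


def voi_mean_concentration(
    vol: VoxelGrid, m: Mask3D, voxel_volume_ml: float | None = None
) -> float:
    """Mean concentration (counts/ml) inside a VOI.

    This is the volumetric reference quantification the planar estimates
    are compared against.
    """
    if m.voxel_count == 0:
        raise ValueError("empty mask")
    if voxel_volume_ml is None:
        voxel_volume_ml = vol.voxel_volume_ml
    mean_counts = float(vol.data[m.voxels].mean())
    return mean_counts / voxel_volume_ml


def background_scale_factor(
    kidney_column: Mask3D, kidney: Mask3D, bg_column: Mask3D
) -> float:
    """Scale that makes background-ROI counts comparable to the over- and
    underlying tissue volume: (column - kidney) voxels / background voxels."""
    if not kidney.is_subset_of(kidney_column):
        raise ValueError("kidney VOI must be a subset of its column VOI")
    if bg_column.voxel_count == 0:
        raise ValueError("background column VOI is empty")
    return (kidney_column.voxel_count - kidney.voxel_count) / bg_column.voxel_count


def net_counts(
    kidney_counts_a: float,
    kidney_counts_p: float,
    bg_counts_a: float,
    bg_counts_p: float,
    scale: float,
    bg_label: str = "",
) -> NetCountResult:
    """Subtract scaled background counts from kidney counts in both views.

    Negative results are data, not errors: they are recorded through the
    negativity flags and tallied at report level.
    """
    for name, v in (
        ("kidney_counts_a", kidney_counts_a),
        ("kidney_counts_p", kidney_counts_p),
        ("bg_counts_a", bg_counts_a),
        ("bg_counts_p", bg_counts_p),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    return NetCountResult(
        a_net=kidney_counts_a - scale * bg_counts_a,
        p_net=kidney_counts_p - scale * bg_counts_p,
        bg_label=bg_label,
    )


def ac_conjv(nc: NetCountResult, g: KidneyGeometry, mu: float) -> ACEstimate:
    """Conjugate-view activity concentration estimate.

    AC = mu * t_k * sqrt(A_net * P_net)
         / (exp(-mu * t_p / 2) * (exp(mu * t_k / 2) - exp(-mu * t_k / 2)) * v_k)

    with the exact limit sqrt(A_net * P_net) * exp(mu * t_p / 2) / v_k as
    mu * t_k -> 0.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if nc.conjv_negative:
        raise NegativeNetCountsError(
            f"non-positive net counts for background {nc.bg_label!r} "
            f"(a_net={nc.a_net:.1f}, p_net={nc.p_net:.1f})"
        )
    gm = np.sqrt(nc.a_net * nc.p_net)
    if mu * g.t_k < SMALL_MU_TK:
        value = gm * np.exp(mu * g.t_p / 2.0) / g.v_k
    else:
        numer = mu * g.t_k * gm
        denom = (
            np.exp(-mu * g.t_p / 2.0)
            * (np.exp(mu * g.t_k / 2.0) - np.exp(-mu * g.t_k / 2.0))
            * g.v_k
        )
        value = numer / denom
    return ACEstimate(value=float(value), method="ConjV", bg_label=nc.bg_label)


def ac_postv(nc: NetCountResult, g: KidneyGeometry, mu: float) -> ACEstimate:
    """Posterior-view activity concentration estimate.

    AC = (P_net / v_k) * exp(mu * d_k) * t_k * mu / (1 - exp(-mu * t_k))

    with the exact limit P_net * exp(mu * d_k) / v_k as mu * t_k -> 0.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if nc.postv_negative:
        raise NegativeNetCountsError(
            f"non-positive posterior net counts for background {nc.bg_label!r} "
            f"(p_net={nc.p_net:.1f})"
        )
    if mu * g.t_k < SMALL_MU_TK:
        value = nc.p_net * np.exp(mu * g.d_k) / g.v_k
    else:
        value = (
            (nc.p_net / g.v_k)
            * np.exp(mu * g.d_k)
            * g.t_k
            * mu
            / (1.0 - np.exp(-mu * g.t_k))
        )
    return ACEstimate(value=float(value), method="PostV", bg_label=nc.bg_label)
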