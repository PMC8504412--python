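"""Phase-contrast angiography: CD angiogram, vessel enhancement, binarization.

A cardiac-gated phase-contrast acquisition yields, per time frame, a
magnitude image ``m`` and three velocity components (cm/s). Temporal means
of these fields are combined into a complex-difference (CD) angiogram

    CD = m̄ · sin(θ),   θ = π · ‖v̄‖ / venc   clipped to [0, π/2],

which is bright wherever flow is present. The CD volume is then enhanced
with a multiscale Hessian-eigenvalue vesselness filter (the τ-parameterized
response of Jerman-style enhancement) and binarized at a fraction of the
global maximum of the filtered response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class EmptyMaskError(ValueError):
    """Raised when binarization cannot produce any vessel voxels."""


@dataclass
class FlowVolume4D:
    """Cardiac-gated 4D flow reconstruction.

    Parameters
    ----------
    magnitude : ndarray, shape (X, Y, Z, M)
        Signal magnitude per frame, arbitrary units, >= 0.
    vel_x, vel_y, vel_z : ndarray, shape (X, Y, Z, M)
        Velocity components in cm/s.
    venc : float
        Velocity-encoding limit in cm/s; velocities beyond it would alias.
    voxel_size : ndarray, shape (3,)
        Voxel spacing in mm.
    frame_times : ndarray, shape (M,)
        Time of each cardiac frame in seconds, strictly increasing.
    """

    magnitude: np.ndarray
    vel_x: np.ndarray
    vel_y: np.ndarray
    vel_z: np.ndarray
    venc: float
    voxel_size: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.vel_x = np.asarray(self.vel_x, dtype=float)
        self.vel_y = np.asarray(self.vel_y, dtype=float)
        self.vel_z = np.asarray(self.vel_z, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.frame_times = np.asarray(self.frame_times, dtype=float).ravel()
        shape = self.magnitude.shape
        for name in ("vel_x", "vel_y", "vel_z"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != magnitude shape {shape}")
        if self.magnitude.ndim != 4:
            raise ValueError("expected 4D arrays (x, y, z, frame)")
        if self.magnitude.shape[-1] != self.frame_times.size:
            raise ValueError("frame_times length does not match the frame axis")
        if self.frame_times.size < 2:
            raise ValueError("need at least two cardiac frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if not self.venc > 0:
            raise ValueError("venc must be positive")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    @property
    def period(self) -> float:
        """Cardiac period in seconds, assuming frames cover one full cycle."""
        m = self.n_frames
        return float((self.frame_times[-1] - self.frame_times[0]) * m / (m - 1))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape[:3]


@dataclass
class AngiogramVolume:
    """Complex-difference angiogram with the parameters that produced it."""

    cd: np.ndarray
    voxel_size: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class VesselMask:
    """Binary vessel lumen mask from thresholding the filtered angiogram."""

    mask: np.ndarray
    voxel_size: np.ndarray
    threshold_fraction: float
    filter_params: dict = field(default_factory=dict)


def compute_cd(flow: FlowVolume4D) -> AngiogramVolume:
    """Compute the complex-difference angiogram from temporal-mean fields.

    Each velocity component is averaged over frames first and the speed is
    taken from the component-wise means (preserving flow directionality);
    θ = π‖v̄‖/venc is clipped to [0, π/2] before CD = m̄·sin(θ).

    NaN voxels propagate to the output with a warning.
    """
    m_bar = flow.magnitude.mean(axis=-1)
    vx = flow.vel_x.mean(axis=-1)
    vy = flow.vel_y.mean(axis=-1)
    vz = flow.vel_z.mean(axis=-1)
    speed = np.sqrt(vx * vx + vy * vy + vz * vz)
    theta = np.clip(np.pi * speed / flow.venc, 0.0, np.pi / 2.0)
    cd = m_bar * np.sin(theta)
    n_nan = int(np.isnan(cd).sum())
    if n_nan:
        warnings.warn(f"CD angiogram contains {n_nan} NaN voxels", stacklevel=2)
    return AngiogramVolume(
        cd=cd,
        voxel_size=flow.voxel_size,
        provenance={"venc": flow.venc, "theta_truncated": True},
    )


def _hessian_physical(volume: np.ndarray, scale_mm: float, voxel_size: np.ndarray) -> np.ndarray:
    """Scale-normalized Hessian (mm^-2 units times scale^2) at one scale.

    Gaussian derivatives with per-axis sigma = scale/voxel_size (so the
    aperture is isotropic in physical space), converted to physical second
    derivatives and multiplied by scale^2 for cross-scale comparability.
    Boundaries are handled by reflection.
    """
    sigma_vox = scale_mm / voxel_size
    h = np.empty(volume.shape + (3, 3))
    for a in range(3):
        for b in range(a, 3):
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            d = ndimage.gaussian_filter(volume, sigma_vox, order=order, mode="reflect")
            d /= voxel_size[a] * voxel_size[b]
            h[..., a, b] = d
            h[..., b, a] = d
    h *= scale_mm**2
    return h


def _tau_vesselness_single_scale(h: np.ndarray, tau: float, noise_floor: float = 0.0) -> np.ndarray:
    """τ-regularized bright-tube vesselness from a Hessian field.

    Eigenvalues are ordered by magnitude; for a bright tube on a dark
    background the two largest-magnitude eigenvalues are negative. Working
    with their negations l2 <= l3 (positive inside bright tubes), the
    response is

        v = l2² (lρ − l2) (3 / (l2 + lρ))³,

    with v = 1 where l2 >= lρ/2 > 0 and v = 0 where l2 <= 0 or lρ <= 0,
    where lρ is l3 regularized from below at τ·max(l3) over the volume.
    The response lies in [0, 1].
    """
    eig = np.linalg.eigvalsh(h)  # ascending by value
    order = np.argsort(np.abs(eig), axis=-1)
    eig_mag = np.take_along_axis(eig, order, axis=-1)
    l2 = -eig_mag[..., 1]
    l3 = -eig_mag[..., 2]

    # eigenvalues that are pure round-off relative to the image intensity
    # scale (flat input) must not fire the "uniform plateau" branch below
    l3_pos = l3[l3 > noise_floor]
    if l3_pos.size == 0:
        return np.zeros(h.shape[:-2])
    cutoff = tau * float(np.nanmax(l3_pos))
    l_rho = np.where(l3 > cutoff, l3, cutoff)
    l_rho = np.where(l3 <= noise_floor, 0.0, l_rho)

    with np.errstate(divide="ignore", invalid="ignore"):
        resp = l2 * l2 * (l_rho - l2) * (3.0 / (l2 + l_rho)) ** 3
    resp = np.where((l2 >= l_rho / 2.0) & (l_rho > 0), 1.0, resp)
    resp = np.where((l2 <= 0) | (l_rho <= 0), 0.0, resp)
    return np.clip(np.nan_to_num(resp, nan=0.0), 0.0, 1.0)


def vesselness_filter(
    cd: AngiogramVolume | np.ndarray,
    scales_mm: list[float] | tuple[float, ...] = (0.5, 1.0, 1.5, 2.0),
    tau: float = 1.0,
    voxel_size: np.ndarray | None = None,
) -> np.ndarray:
    """Multiscale Hessian vessel-enhancement of the CD angiogram.

    Parameters
    ----------
    cd : AngiogramVolume or ndarray
        The angiogram. If an ndarray is given, ``voxel_size`` is required.
    scales_mm : sequence of float
        Gaussian scales in mm; the response is the voxelwise maximum over
        scales. Defaults span the radii of intracranial arteries.
    tau : float
        Regularization of the largest eigenvalue: lower values boost the
        response uniformity inside large vessels.

    Returns
    -------
    ndarray in [0, 1], same shape as the input volume.
    """
    if isinstance(cd, AngiogramVolume):
        volume = cd.cd
        voxel_size = cd.voxel_size
    else:
        volume = np.asarray(cd, dtype=float)
        if voxel_size is None:
            raise ValueError("voxel_size required when passing a bare array")
    voxel_size = np.asarray(voxel_size, dtype=float).reshape(3)
    scales = [float(s) for s in scales_mm]
    if not scales:
        raise ValueError("scales_mm must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("all scales must be positive")
    if not tau > 0:
        raise ValueError("tau must be positive")

    response = np.zeros(volume.shape)
    # the Hessian is invariant to constant offsets; removing the mean makes
    # that exact numerically (kernel-truncation residues scale with offset)
    finite = volume[np.isfinite(volume)]
    centered = volume - (float(finite.mean()) if finite.size else 0.0)
    noise_floor = 1e-9 * (float(np.abs(centered[np.isfinite(centered)]).max()) if finite.size else 0.0)
    for s in scales:
        h = _hessian_physical(centered, s, voxel_size)
        np.maximum(response, _tau_vesselness_single_scale(h, tau, noise_floor), out=response)
    return response


def binarize_global(
    filtered: np.ndarray,
    fraction: float = 0.025,
    voxel_size: np.ndarray | None = None,
    filter_params: dict | None = None,
) -> VesselMask:
    """Threshold the filtered volume at ``fraction`` of its global maximum.

    NaNs are excluded from the global-maximum computation and never enter
    the mask. An all-zero (or all-NaN) input raises :class:`EmptyMaskError`.
    """
    filtered = np.asarray(filtered, dtype=float)
    finite = filtered[np.isfinite(filtered)]
    if finite.size == 0 or float(finite.max()) <= 0:
        raise EmptyMaskError("filtered volume has no positive values; no vessels detectable")
    peak = float(finite.max())
    with np.errstate(invalid="ignore"):
        mask = filtered >= fraction * peak
    mask &= np.isfinite(filtered)
    if fraction == 0:
        with np.errstate(invalid="ignore"):
            mask = np.isfinite(filtered) & (filtered > 0)
    if voxel_size is None:
        voxel_size = np.ones(3)
    return VesselMask(
        mask=mask,
        voxel_size=np.asarray(voxel_size, dtype=float).reshape(3),
        threshold_fraction=float(fraction),
        filter_params=dict(filter_params or {}),
    )
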