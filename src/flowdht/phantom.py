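"""Seeded 3D numerical cell phantoms.

A phantom emulates the refractive-index (RI) tomogram of a suspended cell as
it would appear at the end of a tomographic pipeline: a compact cell body in
a watery medium (n0 = 1.334) whose interior carries a smooth Gaussian random
RI texture rescaled into a physiological range ([1.334, 1.410] by default),
deliberately without recognizable organelle structure.  The construction is
a pure function of its spec, so the same spec and seed always reproduce the
same volume voxel for voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomSpec", "Tomogram", "generate_phantom", "isolevel_thresholds"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a numerical cell phantom.

    Parameters
    ----------
    grid_size : int
        Voxels per axis of the cubic grid.
    voxel_size : float
        Isotropic voxel pitch in micrometres.
    medium_ri : float
        Refractive index of the surrounding medium (background voxels).
    ri_range : (float, float)
        Closed interval into which the intracellular RI values are rescaled.
    cell_radius : float
        Radius of the (default spherical) cell support, micrometres.
    correlation_length : float
        1/e half-width of the Gaussian smoothing kernel applied to the white
        noise field, micrometres; sets the texture scale of the interior.
    edge_voxels : float
        Width of the linear blend at the support edge, voxels (1 by default,
        against aliasing in projections; 0 gives a hard edge).
    seed : int
        RNG seed; identical spec (including seed) gives bit-identical output.
    axis_ratios : (float, float, float)
        Relative semi-axes (z, y, x) for an ellipsoidal support; (1, 1, 1)
        is a sphere.
    """

    grid_size: int = 128
    voxel_size: float = 0.1
    medium_ri: float = 1.334
    ri_range: tuple[float, float] = (1.334, 1.410)
    cell_radius: float = 4.0
    correlation_length: float = 0.8
    seed: int = 0
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    edge_voxels: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be at least 2")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        lo, hi = self.ri_range
        if lo > hi:
            raise ValueError("ri_range must be ordered [min, max]")
        if lo < self.medium_ri:
            raise ValueError(
                "invariant violated: ri_range[0] >= medium_ri "
                f"({lo} < {self.medium_ri})"
            )
        half_extent = self.grid_size * self.voxel_size / 2.0
        if self.cell_radius * max(self.axis_ratios) >= half_extent:
            raise ValueError(
                "invariant violated: cell_radius < grid_size*voxel_size/2 "
                f"(radius {self.cell_radius} um vs half-extent {half_extent} um)"
            )
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be non-negative")


@dataclass
class Tomogram:
    """A 3D refractive-index volume.

    ``values`` holds absolute RI on a (z, y, x) grid with isotropic voxels of
    ``voxel_size`` micrometres; ``medium_ri`` is the background index n0.
    The RI contrast Delta-n = n - n0 is the quantity the tomographic solvers
    actually reconstruct.
    """

    values: np.ndarray
    voxel_size: float
    medium_ri: float = 1.334

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Tomogram.values must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Tomogram.values must be finite everywhere")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def contrast(self) -> np.ndarray:
        """RI contrast Delta-n = n - n0."""
        return self.values - self.medium_ri

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def _support_weight(spec: PhantomSpec) -> np.ndarray:
    """Soft-edged cell support: 1 inside, 0 outside, one voxel of linear blend."""
    n = spec.grid_size
    c = (n - 1) / 2.0
    ax = (np.arange(n) - c) * spec.voxel_size
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    az, ay, axr = spec.axis_ratios
    r_eff = np.sqrt((z / az) ** 2 + (y / ay) ** 2 + (x / axr) ** 2)
    if spec.edge_voxels == 0:
        return (r_eff <= spec.cell_radius).astype(float)
    return np.clip(
        (spec.cell_radius - r_eff) / (spec.edge_voxels * spec.voxel_size),
        0.0, 1.0,
    )


def generate_phantom(spec: PhantomSpec) -> Tomogram:
    """Generate a seeded random-texture cell phantom.

    White Gaussian noise on the grid is low-pass filtered with a Gaussian
    kernel of width ``correlation_length``, then affinely rescaled inside the
    cell support into ``ri_range``; a one-voxel linear blend softens the
    support edge against aliasing in projections.  Background voxels equal
    ``medium_ri`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.grid_size,) * 3)
    sigma_vox = spec.correlation_length / spec.voxel_size
    texture = gaussian_filter(noise, sigma_vox) if sigma_vox > 0 else noise

    w = _support_weight(spec)
    inside = w > 0
    lo, hi = spec.ri_range
    values = np.full((spec.grid_size,) * 3, spec.medium_ri, dtype=float)
    if inside.any():
        tmin = texture[inside].min()
        tmax = texture[inside].max()
        span = tmax - tmin
        if span == 0 or hi == lo:
            unit = np.zeros_like(texture)
        else:
            unit = (texture - tmin) / span
        dn = (lo - spec.medium_ri) + unit * (hi - lo)
        values = spec.medium_ri + w * dn
    np.clip(values, spec.medium_ri, hi if hi > spec.medium_ri else spec.medium_ri,
            out=values)
    return Tomogram(values=values, voxel_size=spec.voxel_size,
                    medium_ri=spec.medium_ri)


def isolevel_thresholds(
    tomogram: Tomogram,
    fractions: list[float] | tuple[float, ...],
    scale: str = "contrast",
) -> list[float]:
    """Isosurface thresholds at given fractions of the maximum RI.

    With ``scale="contrast"`` (default) each fraction f maps to
    f * max(Delta-n), i.e. a threshold on the RI-contrast scale used for
    isolevel rendering and segmentation.  ``scale="absolute"`` gives the
    literal reading f * max(n).
    """
    if tomogram.values.size == 0:
        raise ValueError("empty tomogram")
    fractions = list(fractions)
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"fractions must lie in (0, 1]; got {f}")
    if scale == "contrast":
        peak = float(tomogram.contrast.max())
    elif scale == "absolute":
        peak = float(tomogram.values.max())
    else:
        raise ValueError(f"unknown scale {scale!r}; use 'contrast' or 'absolute'")
    return [f * peak for f in fractions]
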