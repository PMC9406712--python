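"""Optical forward simulation: phase projections and synthetic off-axis holograms.

This module closes the loop for testing without instrument data: it projects
a rotating refractive-index phantom into quantitative phase maps (straight-ray
model), synthesizes off-axis interference records with a tilted plane-wave
reference, and assembles whole rolling sequences of a cell translating and
rotating along a 45-degree-tilted microfluidic channel, returning the
ground-truth projection angles alongside the frames.

Geometry conventions: volumes are (z, y, x) with the optical axis along z;
the cell rolls about the x axis, so in the un-tilted frame its projections
vary along y (the flow direction) and a rotation by ``angle`` degrees is a
rotation in the (z, y) plane.  In the camera frame the whole scene is rotated
by ``tilt_angle`` so the flow runs diagonally, as in the tilted-channel
cytometer layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .holo import ComplexField, Hologram, QPM, object_bandwidth
from .phantom import PhantomSpec, Tomogram, generate_phantom

__all__ = [
    "OpticalConfig",
    "FlowSpec",
    "RollingSimulation",
    "project_phase",
    "synthesize_hologram",
    "simulate_rolling_sequence",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging-system parameters of the holographic cytometer."""

    wavelength: float = 0.488          # um
    magnification: float = 55.0
    camera_pitch: float = 5.5          # um at the sensor
    numerical_aperture: float = 0.5
    frame_rate: float = 30.0           # frames/s

    @property
    def object_pixel(self) -> float:
        """Object-space pixel, camera_pitch / magnification (um)."""
        return self.camera_pitch / self.magnification

    @property
    def lateral_resolution(self) -> float:
        """Theoretical lateral resolution estimate 0.82 lambda / NA (um)."""
        return 0.82 * self.wavelength / self.numerical_aperture


@dataclass(frozen=True)
class FlowSpec:
    """Kinematics of a cell rolling along the tilted channel.

    The rotation-to-translation ratio is constant across frames, which is the
    proportionality assumption underlying displacement-based angle recovery.
    """

    tilt_angle: float = 45.0           # degrees between flow and sensor y axis
    translation_per_frame: float = 0.8  # um
    rotation_per_frame: float = 10.0    # degrees
    n_frames: int = 40
    noise_sigma: float = 0.08           # rad, additive phase noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt_angle <= 90.0):
            raise ValueError("tilt_angle must lie in [0, 90] degrees")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class RollingSimulation:
    """Output bundle of a simulated rolling-cell acquisition."""

    holograms: list[Hologram]
    truth_angles: np.ndarray           # degrees per frame
    truth_phases: list[QPM]            # noise-free object phase per frame
    reference_hologram: Hologram       # cell-free frame, identically synthesized
    carrier: tuple[float, float]       # cycles/pixel (fy, fx)
    flow: FlowSpec
    optics: OpticalConfig


def project_phase(
    tomogram: Tomogram,
    angle: float,
    rotation_axis: str = "x",
    config: OpticalConfig | None = None,
    interpolation_order: int = 1,
) -> QPM:
    """Straight-ray phase projection of the volume rotated by ``angle`` degrees.

    phase(y, x) = (2 pi / lambda) * sum_ray Delta-n * voxel_size, computed by
    rotating the RI-contrast volume about the given in-plane axis (trilinear
    interpolation by default) and summing along the optical axis z.
    """
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    config = config or OpticalConfig()
    axes = {"x": (0, 1), "y": (0, 2)}.get(rotation_axis)
    if axes is None:
        raise ValueError("rotation_axis must be 'x' or 'y' (in the image plane)")
    contrast = tomogram.contrast
    ang = angle % 360.0
    if ang != 0.0:
        contrast = ndimage.rotate(
            contrast, ang, axes=axes, reshape=False,
            order=interpolation_order, mode="constant", cval=0.0,
        )
    opd = contrast.sum(axis=0) * tomogram.voxel_size
    phase = 2.0 * np.pi / config.wavelength * opd
    return QPM(phase, pixel_pitch=tomogram.voxel_size)


def synthesize_hologram(
    field: ComplexField,
    carrier: tuple[float, float] = (0.25 / np.sqrt(2), 0.25 / np.sqrt(2)),
    reference_amplitude: float = 1.0,
    frame_index: int = 0,
) -> Hologram:
    """Off-axis interference of the object field with a tilted plane wave.

    H = |U + R|^2 with R = a exp(-2 pi i (fy y + fx x)); ``carrier`` is
    (fy, fx) in cycles/pixel.  The sign convention places the U R-bar
    cross term (the +1 order, carrying the object phase with its proper
    sign) at +(fy, fx) in the spectrum, where ``demodulate`` extracts it.
    The carrier magnitude must exceed twice the estimated object bandwidth
    so the +1 order separates from the autocorrelation term.
    """
    fy, fx = carrier
    mag = float(np.hypot(fy, fx))
    bw = object_bandwidth(field.data)
    if mag <= 2.0 * bw:
        raise ValueError(
            f"carrier magnitude {mag:.4f} cycles/px below separation bound; "
            f"need > {2.0 * bw:.4f} (twice the object bandwidth estimate)"
        )
    ny, nx = field.data.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    ref = reference_amplitude * np.exp(-2j * np.pi * (fy * yy + fx * xx))
    intensity = np.abs(field.data + ref) ** 2
    return Hologram(intensity, field.pixel_pitch, frame_index)


def _embed(patch: np.ndarray, fov: int) -> np.ndarray:
    """Place a square patch at the centre of a fov x fov canvas."""
    canvas = np.zeros((fov, fov))
    n = patch.shape[0]
    o = (fov - n) // 2
    canvas[o:o + n, o:o + patch.shape[1]] = patch
    return canvas


def simulate_rolling_sequence(
    spec: PhantomSpec,
    flow: FlowSpec | None = None,
    config: OpticalConfig | None = None,
    fov_pixels: int = 256,
    carrier: tuple[float, float] = (0.25 / np.sqrt(2), 0.25 / np.sqrt(2)),
) -> RollingSimulation:
    """Simulate a cell rolling through the tilted channel, frame by frame.

    Frame k (k = 0, 1, ...) shows the phantom rotated by k * rotation_per_frame
    about the rolling axis and translated by k * translation_per_frame along
    the tilt direction; Gaussian phase noise of ``noise_sigma`` rad is added
    before interference.  Ground-truth angles (and noise-free phase maps) are
    returned for validation.  The trajectory must stay inside the field of
    view; the first offending frame index is reported otherwise.
    """
    flow = flow or FlowSpec()
    config = config or OpticalConfig()
    phantom = generate_phantom(spec)
    rng = np.random.default_rng(flow.seed)
    pitch = spec.voxel_size

    tilt = np.deg2rad(flow.tilt_angle)
    # displacement per frame in object-space um: at 45 deg to the y axis
    step_um = flow.translation_per_frame
    dxy = (step_um * np.cos(tilt), step_um * np.sin(tilt))  # (dy, dx)

    half_patch = spec.grid_size / np.sqrt(2.0) / 2.0 + 2  # rotated patch half-size, px
    centre = (fov_pixels - 1) / 2.0
    holograms: list[Hologram] = []
    truth_phases: list[QPM] = []
    angles = np.arange(flow.n_frames) * flow.rotation_per_frame

    # centre the whole trajectory in the field of view
    k0 = (flow.n_frames - 1) / 2.0
    for k in range(flow.n_frames):
        shift_px = ((k - k0) * dxy[0] / pitch, (k - k0) * dxy[1] / pitch)
        for s in shift_px:
            if centre + abs(s) + half_patch > fov_pixels - 1:
                raise ValueError(
                    f"trajectory exits field of view at frame {k}; "
                    "enlarge fov_pixels or shorten the sequence"
                )
        qpm = project_phase(phantom, angles[k], "x", config)
        patch = qpm.phase
        if flow.tilt_angle != 0.0:
            patch = ndimage.rotate(
                patch, -flow.tilt_angle, reshape=True, order=3,
                mode="constant", cval=0.0, prefilter=True,
            )
        canvas = _embed(patch, fov_pixels)
        if shift_px != (0.0, 0.0):
            canvas = ndimage.shift(canvas, shift_px, order=3,
                                   mode="constant", cval=0.0)
        truth_phases.append(QPM(canvas, pitch, frame_index=k))
        noisy = canvas
        if flow.noise_sigma > 0:
            noisy = canvas + rng.normal(0.0, flow.noise_sigma, canvas.shape)
        u = ComplexField(np.exp(1j * noisy), pitch)
        holograms.append(
            synthesize_hologram(u, carrier=carrier, frame_index=k)
        )

    ref_field = ComplexField(np.ones((fov_pixels, fov_pixels), dtype=complex), pitch)
    reference = synthesize_hologram(ref_field, carrier=carrier, frame_index=-1)

    return RollingSimulation(
        holograms=holograms,
        truth_angles=angles,
        truth_phases=truth_phases,
        reference_hologram=reference,
        carrier=carrier,
        flow=flow,
        optics=config,
    )
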