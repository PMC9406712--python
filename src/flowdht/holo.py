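"""Off-axis hologram processing: from interference records to quantitative phase maps.

The processing chain follows standard off-axis digital holographic microscopy
practice: the recorded intensity frame is apodized with a tapered-cosine
window, the +1 diffraction order is isolated in the Fourier spectrum and
re-centred (demodulation), the complex field is refocused by angular-spectrum
propagation to the plane minimizing the Tamura coefficient of its amplitude,
optical aberrations are removed by dividing by an identically processed
cell-free reference field, the phase is unwrapped, and correlated speckle
noise is attenuated by windowed-Fourier filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, ifft2, fftshift, ifftshift, fftfreq
from scipy.signal.windows import tukey, hann
from skimage.restoration import unwrap_phase as _skimage_unwrap

__all__ = [
    "Hologram",
    "ComplexField",
    "QPM",
    "apodize",
    "demodulate",
    "propagate_angular_spectrum",
    "tamura_coefficient",
    "autofocus",
    "compensate_reference",
    "unwrap_phase",
    "wft_denoise",
    "process_sequence",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class Hologram:
    """One recorded or simulated off-axis intensity frame.

    ``pixel_pitch`` is the object-space sampling in micrometres (camera pitch
    divided by magnification).
    """

    intensity: np.ndarray
    pixel_pitch: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("Hologram.intensity must be 2D")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("Hologram.intensity must be finite")
        if self.intensity.min() < 0:
            raise ValueError("Hologram.intensity must be non-negative")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


@dataclass
class ComplexField:
    """Demodulated complex amplitude U(x, y; z).

    ``depth_z`` records the cumulative propagation offset from the recording
    plane, micrometres.
    """

    data: np.ndarray
    pixel_pitch: float
    depth_z: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("ComplexField.data must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ComplexField.data must be finite")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)


@dataclass
class QPM:
    """Unwrapped quantitative phase map, radians."""

    phase: np.ndarray
    pixel_pitch: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("QPM.phase must be 2D")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("QPM.phase must be finite")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def apodize(h: Hologram, taper_fraction: float = 0.2) -> Hologram:
    """Apply a separable 2D tapered-cosine (Tukey) window to reduce border effects.

    ``taper_fraction`` is the Tukey shape parameter: 0 leaves the frame
    untouched (rectangular window), 1 gives a full Hann taper.  The interior
    plateau is unchanged.
    """
    if not (0.0 <= taper_fraction <= 1.0):
        raise ValueError("taper_fraction must lie in [0, 1]")
    if taper_fraction == 0.0:
        return Hologram(h.intensity.copy(), h.pixel_pitch, h.frame_index)
    ny, nx = h.intensity.shape
    wy = tukey(ny, taper_fraction)
    wx = tukey(nx, taper_fraction)
    return Hologram(h.intensity * np.outer(wy, wx), h.pixel_pitch, h.frame_index)


def _spectral_radius(spectrum_power: np.ndarray, energy_fraction: float = 0.99) -> float:
    """Radius (cycles/pixel) of the centred disc enclosing the given energy fraction."""
    ny, nx = spectrum_power.shape
    fy = fftshift(fftfreq(ny))
    fx = fftshift(fftfreq(nx))
    rr = np.hypot(*np.meshgrid(fy, fx, indexing="ij"))
    order = np.argsort(rr, axis=None)
    cum = np.cumsum(spectrum_power.ravel()[order])
    total = cum[-1]
    if total <= 0:
        return 0.0
    idx = np.searchsorted(cum, energy_fraction * total)
    idx = min(idx, len(order) - 1)
    return float(rr.ravel()[order][idx])


def object_bandwidth(u: np.ndarray, energy_fraction: float = 0.8) -> float:
    """Estimate the object's spectral half-bandwidth in cycles/pixel.

    The mean (DC) is removed first so a flat field reports zero bandwidth.
    The default energy fraction is deliberately moderate so a white-noise
    floor (spread evenly over the spectrum) does not masquerade as object
    bandwidth; the estimate feeds the carrier-separation guard, which is
    meant to catch clear violations rather than to be a sharp bound.
    """
    u = np.asarray(u, dtype=complex)
    centred = u - u.mean()
    power = np.abs(fftshift(fft2(centred))) ** 2
    return _spectral_radius(power, energy_fraction)


def demodulate(
    h: Hologram,
    order_center="auto",
    crop_radius: float | None = None,
    min_carrier: float = 0.03,
) -> ComplexField:
    """Extract the +1 diffraction order from an off-axis hologram.

    The spectrum is computed, the order located (``order_center="auto"``
    searches for the strongest peak in the upper half-plane, excluding a disc
    of radius ``min_carrier`` cycles/pixel around DC; a (fy, fx) tuple in
    cycles/pixel overrides the search), cropped to a disc of ``crop_radius``
    (default: half the carrier magnitude), re-centred, and inverse
    transformed.  Sub-bin carrier components are removed by a spatial ramp so
    a pure carrier demodulates to a constant phase.
    """
    ny, nx = h.intensity.shape
    spectrum = fftshift(fft2(h.intensity))
    fy = fftshift(fftfreq(ny))
    fx = fftshift(fftfreq(nx))
    FY, FX = np.meshgrid(fy, fx, indexing="ij")

    if isinstance(order_center, str) and order_center == "auto":
        power = np.abs(spectrum) ** 2
        mask = (FY > 0) & (np.hypot(FY, FX) > min_carrier)
        if not mask.any():
            raise ValueError("no carrier detected: search region empty")
        masked = np.where(mask, power, 0.0)
        peak = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[peak] <= 0 or masked[peak] < 50.0 * np.median(power[mask]):
            raise ValueError("no carrier detected: no off-centre peak above noise floor")
        # parabolic sub-bin refinement on log-power along each axis
        ci, cj = peak
        f0 = [fy[ci], fx[cj]]
        for axis, (c, freqs, n) in enumerate([(ci, fy, ny), (cj, fx, nx)]):
            if 0 < c < n - 1:
                if axis == 0:
                    triplet = power[c - 1:c + 2, cj]
                else:
                    triplet = power[ci, c - 1:c + 2]
                lm, l0, lp = np.log(np.maximum(triplet, 1e-300))
                denom = lm - 2 * l0 + lp
                delta = 0.5 * (lm - lp) / denom if denom != 0 else 0.0
                delta = float(np.clip(delta, -0.5, 0.5))
                f0[axis] = freqs[c] + delta * (freqs[1] - freqs[0])
        f0y, f0x = f0
    else:
        f0y, f0x = float(order_center[0]), float(order_center[1])

    carrier_mag = float(np.hypot(f0y, f0x))
    if crop_radius is None:
        crop_radius = carrier_mag / 2.0
    if carrier_mag <= crop_radius:
        raise ValueError(
            "carrier not separable from DC: |carrier| "
            f"{carrier_mag:.4f} cycles/px must exceed crop_radius {crop_radius:.4f}"
        )

    # shift the order to the nearest-bin centre, crop, inverse transform
    ci = int(np.argmin(np.abs(fy - f0y)))
    cj = int(np.argmin(np.abs(fx - f0x)))
    rolled = np.roll(np.roll(spectrum, ny // 2 - ci, axis=0), nx // 2 - cj, axis=1)
    disc = np.hypot(FY, FX) <= crop_radius
    field = ifft2(ifftshift(rolled * disc))

    # remove the residual sub-bin carrier with an explicit spatial ramp
    dy = f0y - fy[ci]
    dx = f0x - fx[cj]
    if dy != 0.0 or dx != 0.0:
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        field = field * np.exp(-2j * np.pi * (dy * yy + dx * xx))

    return ComplexField(field, h.pixel_pitch, depth_z=0.0)


def propagate_angular_spectrum(
    u: ComplexField, dz: float, wavelength: float
) -> ComplexField:
    """Angular-spectrum propagation of the field by ``dz`` micrometres.

    The spectrum is multiplied by exp(i 2 pi dz sqrt(1/lambda^2 - fx^2 - fy^2));
    evanescent components (negative radicand) are zeroed.  dz = 0 is the
    identity.
    """
    if not np.isfinite(dz):
        raise ValueError("dz must be finite")
    if dz == 0.0:
        return ComplexField(u.data.copy(), u.pixel_pitch, u.depth_z)
    ny, nx = u.data.shape
    fy = fftfreq(ny, d=u.pixel_pitch)
    fx = fftfreq(nx, d=u.pixel_pitch)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    radicand = 1.0 / wavelength**2 - FY**2 - FX**2
    propagating = radicand > 0
    kernel = np.zeros((ny, nx), dtype=complex)
    kernel[propagating] = np.exp(2j * np.pi * dz * np.sqrt(radicand[propagating]))
    out = ifft2(fft2(u.data) * kernel)
    return ComplexField(out, u.pixel_pitch, u.depth_z + dz)


def tamura_coefficient(u: ComplexField | np.ndarray, sqrt_variant: bool = False) -> float:
    """Tamura coefficient TC = sigma(|U|) / mu(|U|) of the field amplitude.

    A contrast-type sharpness metric, minimized at focus for phase objects.
    ``sqrt_variant`` returns sqrt(sigma/mu), a monotone transform with the
    same argmin.
    """
    amp = np.abs(u.data) if isinstance(u, ComplexField) else np.abs(np.asarray(u))
    mean = amp.mean()
    if mean == 0:
        raise ValueError("Tamura coefficient undefined for zero-mean amplitude")
    tc = amp.std() / mean
    return float(np.sqrt(tc)) if sqrt_variant else float(tc)


def autofocus(
    u: ComplexField,
    z_candidates,
    wavelength: float,
    sqrt_variant: bool = False,
) -> float:
    """In-focus depth: argmin over candidates of the Tamura coefficient.

    Ties (within 1e-12 of the minimum) are broken by the smallest |z|.
    """
    z_candidates = list(z_candidates)
    if not z_candidates:
        raise ValueError("z_candidates must be non-empty")
    if not np.all(np.isfinite(z_candidates)):
        raise ValueError("z_candidates must be finite")
    scores = [
        tamura_coefficient(propagate_angular_spectrum(u, z, wavelength), sqrt_variant)
        for z in z_candidates
    ]
    best = min(scores)
    tied = [z for z, s in zip(z_candidates, scores) if s <= best + 1e-12]
    return float(min(tied, key=abs))


def compensate_reference(
    u: ComplexField, u_ref: ComplexField, eps: float = 1e-3
) -> ComplexField:
    """Divide by an identically processed cell-free reference field.

    Aberration phase (and amplitude shading) common to both fields cancels in
    the complex ratio.  ``eps`` guards the division: reference amplitudes
    below eps times the reference median amplitude raise an error.
    """
    if u.data.shape != u_ref.data.shape:
        raise ValueError("field and reference shapes differ")
    if u.pixel_pitch != u_ref.pixel_pitch:
        raise ValueError("field and reference pixel pitch differ")
    amp = np.abs(u_ref.data)
    guard = eps * np.median(amp)
    bad = int(np.count_nonzero(amp <= guard))
    if bad:
        raise ValueError(
            f"reference amplitude below guard at {bad} pixel(s); cannot divide"
        )
    return ComplexField(u.data / u_ref.data, u.pixel_pitch, u.depth_z)


def unwrap_phase(
    wrapped: np.ndarray, pixel_pitch: float = 1.0, frame_index: int = 0
) -> QPM:
    """2D phase unwrapping with the congruence guarantee.

    Uses a quality-guided unwrapper; the output equals the input modulo 2 pi
    pixelwise, and for wrapped versions of a smooth surface whose gradient
    stays below pi per pixel it recovers that surface up to one global 2 pi k
    offset.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    out = np.asarray(_skimage_unwrap(wrapped), dtype=float)
    return QPM(out, pixel_pitch, frame_index)


def wft_denoise(
    q: QPM,
    window_size: int = 32,
    threshold: float = 2.0,
    step: int | None = None,
) -> QPM:
    """Windowed-Fourier hard-threshold filtering of a phase map.

    Overlapping Hann-windowed patches are Fourier transformed; coefficients
    with magnitude below ``threshold`` times the patch's RMS coefficient
    magnitude are zeroed; patches are inverse transformed and overlap-added
    with exact window normalization, so threshold = 0 is the identity.
    Attenuates correlated speckle noise while preserving the smooth phase.
    """
    if window_size < 4:
        raise ValueError("window_size must be >= 4")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ny, nx = q.phase.shape
    if window_size > min(ny, nx):
        raise ValueError("window larger than image")
    if step is None:
        step = max(1, window_size // 4)

    pad = window_size
    # odd reflection continues smooth surfaces (ramps) linearly across the
    # border, avoiding the kink a plain reflection would filter against
    padded = np.pad(q.phase, pad, mode="reflect", reflect_type="odd")
    py, px = padded.shape
    w1 = hann(window_size, sym=False)
    w2 = np.outer(w1, w1)

    acc = np.zeros((py, px))
    norm = np.zeros((py, px))
    for i0 in range(0, py - window_size + 1, step):
        for j0 in range(0, px - window_size + 1, step):
            patch = padded[i0:i0 + window_size, j0:j0 + window_size] * w2
            if threshold > 0:
                coeffs = fft2(patch)
                scale = np.sqrt(np.mean(np.abs(coeffs) ** 2))
                coeffs[np.abs(coeffs) < threshold * scale] = 0.0
                patch = ifft2(coeffs).real
            acc[i0:i0 + window_size, j0:j0 + window_size] += patch * w2
            norm[i0:i0 + window_size, j0:j0 + window_size] += w2**2
    out = acc[pad:pad + ny, pad:pad + nx] / norm[pad:pad + ny, pad:pad + nx]
    return QPM(out, q.pixel_pitch, q.frame_index)


# --------------------------------------------------------------------------
# End-to-end sequence processing
# --------------------------------------------------------------------------

def process_sequence(
    holograms: list[Hologram],
    reference_hologram: Hologram,
    wavelength: float,
    carrier="auto",
    taper_fraction: float = 0.2,
    z_candidates=None,
    denoise: bool = True,
    window_size: int = 32,
    threshold: float = 2.0,
    remove_offset: bool = True,
    border_crop: int | None = None,
) -> list[QPM]:
    """Run the full hologram-to-QPM chain over a frame sequence.

    The in-focus depth z-bar is estimated on the first frame by Tamura
    autofocus and frozen for all subsequent holograms; the cell-free
    reference is processed identically and divided out to cancel aberrations
    (and any common demodulation residue); phases are unwrapped and, by
    default, windowed-Fourier denoised.  ``remove_offset`` subtracts each
    frame's median phase so the empty background sits at zero.

    The apodization taper drives the border amplitude towards zero, so a
    border margin (the taper width plus the demodulation smear, by default)
    is cropped from every frame before the reference division.
    """
    if z_candidates is None:
        z_candidates = [0.0]
    ny, nx = holograms[0].intensity.shape
    if border_crop is None:
        border_crop = int(np.ceil(min(ny, nx) * taper_fraction / 2)) + 8

    def crop(u: ComplexField) -> ComplexField:
        c = border_crop
        if c == 0:
            return u
        return ComplexField(u.data[c:-c, c:-c], u.pixel_pitch, u.depth_z)

    def demod(h: Hologram) -> ComplexField:
        return demodulate(apodize(h, taper_fraction), carrier)

    u_ref = demod(reference_hologram)
    first = demod(holograms[0])
    z_bar = autofocus(first, z_candidates, wavelength)
    if z_bar != 0.0:
        u_ref = propagate_angular_spectrum(u_ref, z_bar, wavelength)
    u_ref = crop(u_ref)

    qpms = []
    for h in holograms:
        u = demod(h)
        if z_bar != 0.0:
            u = propagate_angular_spectrum(u, z_bar, wavelength)
        u = compensate_reference(crop(u), u_ref)
        q = unwrap_phase(u.phase, h.pixel_pitch, h.frame_index)
        if denoise:
            q = wft_denoise(q, window_size=window_size, threshold=threshold)
        if remove_offset:
            q = QPM(q.phase - np.median(q.phase), q.pixel_pitch, q.frame_index)
        qpms.append(q)
    return qpms
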