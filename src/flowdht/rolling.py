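"""Rolling-angle recovery for cells in the 45-degree-tilted channel.

A cell rolling along the channel wall rotates in proportion to how far it has
translated.  The projection angle of frame k is therefore assigned from the
centroid displacement l_k relative to the first frame:

    theta_k = 0            for k = 1 (first frame, by convention)
    theta_k = 360 l_k / L360   for k > 1

where L360 is the displacement at the frame completing a full turn.  That
frame is identified as the one minimizing the Tamura Similarity Index (TSI)
against the first frame: when the cell returns to its initial orientation the
two phase maps coincide and their difference map loses structured contrast.
Because l_k is a Euclidean distance, the assignment is independent of the
channel tilt.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .holo import QPM

__all__ = [
    "RollingTrack",
    "AngularSequence",
    "track_centroids",
    "tamura_similarity_index",
    "find_full_rotation",
    "assign_angles",
]


@dataclass
class RollingTrack:
    """Per-frame centroid track of a rolling cell.

    ``centroids`` are (x_k, y_k) in object-space micrometres relative to the
    frame-1 centroid; ``displacements`` are l_k = sqrt(x_k^2 + y_k^2).
    ``frame_of_360``/``L360`` are filled once the full-rotation frame is known.
    """

    centroids: np.ndarray              # (n, 2) as (x, y), um, relative to frame 1
    displacements: np.ndarray          # (n,) um
    pixel_pitch: float
    frame_of_360: int | None = None
    L360: float | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 2:
            raise ValueError("centroids must be (n, 2)")
        if len(self.displacements) != len(self.centroids):
            raise ValueError("displacements and centroids length mismatch")

    def with_full_rotation(self, frame: int) -> "RollingTrack":
        """Return a copy with the full-rotation frame and L360 recorded."""
        if not (0 < frame < len(self.displacements)):
            raise ValueError("frame_of_360 must index a frame after the first")
        return replace(self, frame_of_360=frame,
                       L360=float(self.displacements[frame]))


@dataclass
class AngularSequence:
    """Projection angles theta_k (degrees) for the retained frames."""

    angles: np.ndarray
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.frames = np.asarray(self.frames, dtype=int)
        if self.angles.shape != self.frames.shape:
            raise ValueError("angles and frames must align")


def _segment_single_cell(
    phase: np.ndarray, threshold_method: str, min_area: int, frame: int
):
    """Binary mask of the single above-threshold component; errors otherwise."""
    if threshold_method == "otsu":
        if np.ptp(phase) == 0:
            raise ValueError(f"frame {frame}: empty frame, no cell to track")
        thr = threshold_otsu(phase)
    else:
        thr = float(threshold_method)
    mask = phase > thr
    labels, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(phase), labels, range(1, n + 1))
    big = [i + 1 for i, s in enumerate(sizes) if s >= min_area]
    if len(big) == 0:
        raise ValueError(f"frame {frame}: no component above minimum area")
    if len(big) > 1:
        raise ValueError(
            f"frame {frame}: {len(big)} qualifying components, expected one"
        )
    return labels == big[0]


def track_centroids(
    qpms: list[QPM],
    threshold_method: str = "otsu",
    min_area: int = 20,
) -> RollingTrack:
    """Track the cell centroid across a sequence of phase maps.

    Each frame is thresholded (Otsu by default; a numeric string gives a
    fixed threshold), the single qualifying connected component is kept, and
    the phase-weighted (sub-pixel) centroid computed.  Coordinates are
    re-expressed in micrometres relative to the first frame.
    """
    if not qpms:
        raise ValueError("empty sequence")
    pitch = qpms[0].pixel_pitch
    cents = []
    for k, q in enumerate(qpms):
        mask = _segment_single_cell(q.phase, threshold_method, min_area, k)
        weights = np.where(mask, np.clip(q.phase, 0.0, None), 0.0)
        cy, cx = ndimage.center_of_mass(weights)
        cents.append((cx * pitch, cy * pitch))
    cents = np.asarray(cents)
    rel = cents - cents[0]
    disp = np.hypot(rel[:, 0], rel[:, 1])
    return RollingTrack(centroids=rel, displacements=disp, pixel_pitch=pitch)


def tamura_similarity_index(q1: QPM, qk: QPM) -> float:
    """Tamura Similarity Index between two phase maps.

    TSI is the Tamura coefficient (sigma/mu) of the absolute difference map
    after mean-offset removal: identical maps (or maps differing by a
    constant) give 0; structured disagreement gives larger values.
    """
    if q1.phase.shape != qk.phase.shape:
        raise ValueError("phase map shapes differ")
    d = q1.phase - qk.phase
    d = d - d.mean()
    a = np.abs(d)
    mu = a.mean()
    if mu < 1e-12 * max(1.0, float(np.abs(q1.phase).max())):
        return 0.0
    return float(a.std() / mu)


def _centered_crop(q: QPM, size: int) -> QPM:
    """Crop ``size`` pixels about the segmented cell's weighted centroid.

    The centroid is computed on the thresholded phase (as in tracking) so
    background noise does not bias the crop towards the frame centre.
    """
    try:
        mask = _segment_single_cell(q.phase, "otsu", 20, q.frame_index)
        w = np.where(mask, np.clip(q.phase, 0.0, None), 0.0)
    except ValueError:
        w = np.clip(q.phase, 0.0, None)
    if w.sum() == 0:
        cy, cx = (np.array(q.phase.shape) - 1) / 2.0
    else:
        cy, cx = ndimage.center_of_mass(w)
    ny, nx = q.phase.shape
    half = size / 2.0
    shift = ((ny - 1) / 2.0 - cy, (nx - 1) / 2.0 - cx)
    centred = ndimage.shift(q.phase, shift, order=1, mode="constant", cval=0.0)
    o_y = (ny - size) // 2
    o_x = (nx - size) // 2
    return QPM(centred[o_y:o_y + size, o_x:o_x + size], q.pixel_pitch,
               q.frame_index)


def find_full_rotation(
    qpms: list[QPM],
    search_window: tuple[int, int] | None = None,
    min_lag: int = 10,
    crop_size: int | None = None,
    tie_tolerance: float = 0.04,
) -> int:
    """Index of the frame completing a full 360-degree rotation.

    Minimizes TSI(q1, qk) over ``search_window`` (default: [min_lag, n)),
    comparing cell-centred crops so translation along the channel does not
    enter.  The minimum-lag guard avoids the trivial minimum at the first
    frames.

    Because the per-frame TSI fluctuates with noise, the raw curve is
    smoothed with a three-frame moving average before locating dips; a
    sequence spanning several full turns dips at every completed turn, and
    the earliest (smoothed) local minimum within ``tie_tolerance`` of the
    global minimum is returned, so repeated turns resolve to the first one.
    """
    n = len(qpms)
    if search_window is None:
        search_window = (min_lag, n)
    lo, hi = search_window
    lo = max(lo, 1)
    hi = min(hi, n)
    if hi <= lo:
        raise ValueError("empty search window")
    if crop_size is None:
        crop_size = min(qpms[0].phase.shape) // 2
    ref = _centered_crop(qpms[0], crop_size)
    tsis = np.array([
        tamura_similarity_index(ref, _centered_crop(qpms[k], crop_size))
        for k in range(lo, hi)
    ])
    if len(tsis) == 1:
        return lo
    smooth = tsis.copy()
    smooth[1:-1] = (tsis[:-2] + tsis[1:-1] + tsis[2:]) / 3.0
    best = smooth.min()
    minima = [i for i in range(1, len(smooth) - 1)
              if smooth[i] <= smooth[i - 1] and smooth[i] <= smooth[i + 1]]
    for i in minima:
        if smooth[i] <= best * (1.0 + tie_tolerance):
            return lo + i
    return lo + int(np.argmin(smooth))


def assign_angles(track: RollingTrack) -> AngularSequence:
    """Assign projection angles theta_k = 360 l_k / L360 to the retained frames.

    The first frame is theta = 0 by convention; frames beyond the
    full-rotation frame are discarded from the tomographic set.
    """
    if track.frame_of_360 is None or track.L360 is None:
        raise ValueError("track has no full-rotation frame; "
                         "call with_full_rotation first")
    if track.L360 <= 0:
        raise ValueError("L360 must be positive")
    k360 = track.frame_of_360
    frames = np.arange(k360 + 1)
    angles = 360.0 * track.displacements[: k360 + 1] / track.L360
    angles[0] = 0.0
    return AngularSequence(angles=angles, frames=frames)
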