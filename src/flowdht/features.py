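"""Single-cell morphometrics and tomogram similarity metrics.

From a reconstructed refractive-index tomogram the module derives the
label-free features most used in cell phenotyping — average RI, biovolume,
equivalent diameter and dry mass — plus the similarity measures used to
score reconstructions (3D SSIM against ground truth) and to quantify
measurement repeatability (pairwise Pearson correlation between repeated
tomograms of the same cell).

Dry mass follows the standard refraction-increment relation
m = (1/alpha) * integral of Delta-n dV with alpha the specific refraction
increment (0.2 mL/g by convention for cellular dry matter); with volumes in
um^3 and alpha in mL/g the integral converts to picograms directly
(1 um^3 * g/cm^3 = 1 pg).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .phantom import Tomogram

__all__ = [
    "FeatureRecord",
    "segment_cell",
    "compute_features",
    "ssim_3d",
    "correlation_matrix",
    "align_tomograms",
]

#: conventional specific refraction increment, mL/g
DEFAULT_ALPHA = 0.2

#: default segmentation threshold as a fraction of the maximum RI contrast
DEFAULT_THRESHOLD_FRACTION = 0.33


@dataclass
class FeatureRecord:
    """Morphometric features of one segmented cell."""

    average_ri: float
    biovolume: float            # um^3
    equivalent_diameter: float  # um
    dry_mass: float             # pg
    segmentation_threshold: float  # Delta-n
    alpha: float                # mL/g

    def __post_init__(self) -> None:
        if self.biovolume < 0 or self.dry_mass < 0:
            raise ValueError("biovolume and dry_mass must be non-negative")


def segment_cell(t: Tomogram, threshold: float) -> np.ndarray:
    """Binary cell mask: largest connected component above a contrast threshold.

    Voxels with Delta-n > threshold are labelled; the largest connected
    component is kept and its holes filled.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    above = t.contrast > threshold
    if not above.any():
        raise ValueError(f"no cell at threshold {threshold}")
    labels, n = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones(t.shape), labels, range(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


def compute_features(
    t: Tomogram,
    mask: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    segmentation_threshold: float = float("nan"),
) -> FeatureRecord:
    """Morphometric features over a binary mask.

    average RI = mean n over the mask; biovolume V = voxel count times
    voxel^3; equivalent diameter = (6 V / pi)^(1/3); dry mass =
    (1/alpha) * sum of Delta-n * voxel^3, reported in picograms.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t.shape:
        raise ValueError("mask shape does not match tomogram")
    if not mask.any():
        raise ValueError("mask is empty")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    voxel_volume = t.voxel_size**3
    biovolume = float(mask.sum()) * voxel_volume
    average_ri = float(t.values[mask].mean())
    dry_mass = float(t.contrast[mask].sum()) * voxel_volume / alpha
    eq_diameter = (6.0 * biovolume / np.pi) ** (1.0 / 3.0)
    return FeatureRecord(
        average_ri=average_ri,
        biovolume=biovolume,
        equivalent_diameter=eq_diameter,
        dry_mass=dry_mass,
        segmentation_threshold=segmentation_threshold,
        alpha=alpha,
    )


def ssim_3d(t: Tomogram, truth: Tomogram, data_range: float | None = None) -> float:
    """3D structural similarity index against a reference volume.

    Standard Gaussian-window SSIM (sigma = 1.5, the usual constants) averaged
    over the entire volume; the dynamic range defaults to the reference's
    max - min.
    """
    if t.shape != truth.shape:
        raise ValueError("tomogram shapes differ")
    if data_range is None:
        data_range = float(truth.values.max() - truth.values.min())
        if data_range == 0:
            raise ValueError("reference volume is constant; pass data_range")
    return float(
        structural_similarity(
            truth.values,
            t.values,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def align_tomograms(tomograms: list[Tomogram]) -> list[Tomogram]:
    """Rigidly align repeated tomograms of one cell by contrast centroid.

    Each volume is shifted (spline interpolation) so the centre of mass of
    its RI contrast sits at the grid centre.  Sufficient for repeated
    observations acquired with a common starting orientation; principal-axes
    re-orientation is deliberately not applied by default because its sign
    ambiguities can worsen well-aligned inputs.
    """
    out = []
    for t in tomograms:
        c = np.clip(t.contrast, 0.0, None)
        if c.sum() == 0:
            out.append(t)
            continue
        com = ndimage.center_of_mass(c)
        target = (np.asarray(t.shape) - 1) / 2.0
        shifted = ndimage.shift(t.contrast, target - np.asarray(com),
                                order=1, mode="constant", cval=0.0)
        out.append(Tomogram(values=t.medium_ri + shifted,
                            voxel_size=t.voxel_size, medium_ri=t.medium_ri))
    return out


def correlation_matrix(tomograms: list[Tomogram], align: bool = True) -> np.ndarray:
    """Pairwise Pearson correlation between tomograms (voxelwise).

    Returns a symmetric matrix with unit diagonal.  Constant volumes make
    the correlation undefined and raise an error.  With ``align`` the volumes
    are first centred on their contrast centroid.
    """
    if len(tomograms) < 2:
        raise ValueError("need at least two tomograms")
    shapes = {t.shape for t in tomograms}
    if len(shapes) != 1:
        raise ValueError("tomograms must share one shape (pre-aligned crops)")
    if align:
        tomograms = align_tomograms(tomograms)
    flat = [t.values.ravel() for t in tomograms]
    for i, v in enumerate(flat):
        if np.ptp(v) == 0:
            raise ValueError(f"tomogram {i} is constant; correlation undefined")
    m = len(flat)
    out = np.eye(m)
    for i, j in combinations(range(m), 2):
        r = float(np.corrcoef(flat[i], flat[j])[0, 1])
        out[i, j] = out[j, i] = r
    return out
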