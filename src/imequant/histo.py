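"""Concentric-ring quantification of marker intensity and neuron density.

Pixels are binned by Euclidean distance from the outer edge of the implant
hole into 50 um annuli out to 650 um.  Mean marker intensity (or neuron
density, counts per mm^2) is summarised per annulus, with artifact-masked
pixels excluded from both the numerator and the area, and normalized to the
650-um-most annulus (600-650 um), which is treated as healthy background
tissue.  Markers absent from healthy parenchyma (CD68, IgG) use a
normalization factor of 0 so background maps to 0; constitutive markers
(GFAP, NeuN) use factor 1 so background maps to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, measure, morphology

__all__ = [
    "ImplantImage",
    "RingProfile",
    "DensityProfile",
    "MARKER_FACTORS",
    "ring_labels",
    "bin_intensity",
    "normalize_profile",
    "detect_centroids",
    "density_profile",
    "detect_hole",
]

RING_WIDTH_UM = 50.0
MAX_DIST_UM = 650.0
N_BINS = int(MAX_DIST_UM / RING_WIDTH_UM)  # 13 half-open bins [0,50) .. [600,650)
BACKGROUND_BIN = N_BINS - 1

#: Normalization factor per marker: 1 for markers present in healthy tissue,
#: 0 for markers absent from it.
MARKER_FACTORS = {"NeuN": 1, "GFAP": 1, "CD68": 0, "IgG": 0}


@dataclass
class ImplantImage:
    """A fluorescence image of an implant site plus its masks."""

    intensity: np.ndarray
    hole_mask: np.ndarray
    microns_per_pixel: float
    marker: str
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        self.hole_mask = np.asarray(self.hole_mask, dtype=bool)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros_like(self.hole_mask)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.hole_mask.shape != self.intensity.shape:
            raise ValueError("hole mask shape differs from image shape")
        if self.artifact_mask.shape != self.intensity.shape:
            raise ValueError("artifact mask shape differs from image shape")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.marker not in MARKER_FACTORS:
            raise ValueError(f"unknown marker {self.marker!r}; expected {sorted(MARKER_FACTORS)}")
        n_comp = measure.label(self.hole_mask).max()
        if n_comp != 1:
            raise ValueError(f"hole mask must be one connected component, found {n_comp}")


@dataclass
class RingProfile:
    marker: str
    bin_edges: np.ndarray  # um, length 14 (0, 50, ..., 650)
    mean_raw: np.ndarray  # per bin; NaN where no usable pixel
    n_pixels: np.ndarray
    normalized: np.ndarray | None = None
    marker_factor: int | None = None


@dataclass
class DensityProfile:
    bin_edges: np.ndarray
    counts: np.ndarray
    area_mm2: np.ndarray
    density: np.ndarray  # counts / mm^2
    normalized: np.ndarray


def _bin_edges() -> np.ndarray:
    return np.arange(N_BINS + 1, dtype=float) * RING_WIDTH_UM


def ring_labels(
    hole_mask: np.ndarray,
    microns_per_pixel: float,
    width_um: float = RING_WIDTH_UM,
    max_dist_um: float = MAX_DIST_UM,
) -> np.ndarray:
    """Per-pixel annulus index from distance to the hole edge.

    Returns an int image: bin b for pixels whose Euclidean distance to the
    nearest hole pixel falls in [b*width, (b+1)*width), and -1 for pixels
    inside the hole or at/beyond ``max_dist_um`` (half-open outer boundary).
    Raises if the rings would be truncated by the image border.
    """
    hole = np.asarray(hole_mask, dtype=bool)
    if not hole.any():
        raise ValueError("hole mask is empty")
    margin_px = max_dist_um / microns_per_pixel
    rows = np.any(hole, axis=1).nonzero()[0]
    cols = np.any(hole, axis=0).nonzero()[0]
    if (rows[0] < margin_px or cols[0] < margin_px
            or hole.shape[0] - 1 - rows[-1] < margin_px
            or hole.shape[1] - 1 - cols[-1] < margin_px):
        raise ValueError(
            f"hole is within {max_dist_um} um of the image border; rings would be truncated"
        )
    # Distance from each outside pixel to the nearest hole pixel = EDT of ~hole.
    dist_um = ndimage.distance_transform_edt(~hole, sampling=microns_per_pixel)
    labels = np.floor(dist_um / width_um).astype(int)
    labels[hole] = -1
    labels[dist_um >= max_dist_um] = -1
    return labels


def bin_intensity(image: ImplantImage, labels: np.ndarray) -> RingProfile:
    """Mean raw intensity per annulus over non-artifact pixels."""
    usable = (labels >= 0) & ~image.artifact_mask
    vals = image.intensity.astype(float)
    mean_raw = np.full(N_BINS, np.nan)
    n_pixels = np.zeros(N_BINS, dtype=int)
    flat_labels = labels[usable]
    flat_vals = vals[usable]
    counts = np.bincount(flat_labels, minlength=N_BINS)[:N_BINS]
    sums = np.bincount(flat_labels, weights=flat_vals, minlength=N_BINS)[:N_BINS]
    nonzero = counts > 0
    mean_raw[nonzero] = sums[nonzero] / counts[nonzero]
    n_pixels[:] = counts
    return RingProfile(marker=image.marker, bin_edges=_bin_edges(),
                       mean_raw=mean_raw, n_pixels=n_pixels)


def normalize_profile(profile: RingProfile, marker_factor: int | None = None) -> RingProfile:
    """Normalize ring means to the 600-650 um background bin.

    normalized_b = mean_b / mean_background - (1 - f), so the background bin
    maps exactly to the marker factor f: ratio scale for constitutive
    markers (f = 1), background-subtracted ratio scale for markers absent
    from healthy tissue (f = 0).
    """
    f = MARKER_FACTORS[profile.marker] if marker_factor is None else marker_factor
    bg = profile.mean_raw[BACKGROUND_BIN]
    if not np.isfinite(bg) or bg <= 0:
        raise ValueError("background-bin mean must be positive for normalization")
    profile.normalized = profile.mean_raw / bg - (1 - f)
    profile.marker_factor = f
    return profile


def detect_centroids(
    image: ImplantImage,
    soma_diameter_um: float = 12.0,
    threshold_rel: float = 0.25,
) -> np.ndarray:
    """Neuron centroids (row, col in px) by Laplacian-of-Gaussian blob detection.

    A single-scale LoG filter matched to the configured soma diameter;
    centroids are the local response minima (bright blobs drive the LoG
    strongly negative) below ``threshold_rel`` of the strongest blob
    response, estimated robustly from the high tail.  A deterministic
    stand-in for learned segmentation; centroid lists from external
    segmentation tools can be fed to :func:`density_profile` directly
    instead.  Blobs inside the hole or artifact masks are discarded.
    """
    if image.marker != "NeuN":
        raise ValueError("centroid detection applies to NeuN (neuron) images")
    img = image.intensity.astype(float)
    if img.max() == img.min():
        return np.empty((0, 2))
    sigma = soma_diameter_um / 4.0 / image.microns_per_pixel
    response = -ndimage.gaussian_laplace(img, sigma=sigma)  # positive at blobs
    # Strongest blob sets the response scale; a rare k-fold soma overlap can
    # at most k-fold it, so a fixed fraction still clears isolated somata.
    scale = response.max()
    if scale <= 0:
        return np.empty((0, 2))
    coords = feature.peak_local_max(
        response,
        min_distance=max(int(round(sigma)), 1),
        threshold_abs=threshold_rel * scale,
        exclude_border=False,
    )
    if coords.size == 0:
        return np.empty((0, 2))
    keep = ~image.hole_mask[coords[:, 0], coords[:, 1]] & ~image.artifact_mask[
        coords[:, 0], coords[:, 1]
    ]
    return coords[keep].astype(float)


def density_profile(
    centroids: np.ndarray,
    labels: np.ndarray,
    microns_per_pixel: float,
    artifact_mask: np.ndarray | None = None,
) -> DensityProfile:
    """Neuron density per annulus, normalized to the background annulus.

    Counts centroids per ring and divides by the usable ring area in mm^2
    (artifact pixels excluded from the area, mirroring their exclusion from
    the counts).  Requires at least one centroid in the background bin.
    """
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    usable = labels >= 0
    if artifact_mask is not None:
        usable &= ~np.asarray(artifact_mask, dtype=bool)
    px_area_mm2 = (microns_per_pixel / 1000.0) ** 2
    area = np.bincount(labels[usable], minlength=N_BINS)[:N_BINS] * px_area_mm2

    counts = np.zeros(N_BINS, dtype=int)
    if len(centroids):
        rc = np.clip(np.round(centroids).astype(int), 0, np.array(labels.shape) - 1)
        ok = usable[rc[:, 0], rc[:, 1]]
        binned = labels[rc[ok, 0], rc[ok, 1]]
        counts = np.bincount(binned, minlength=N_BINS)[:N_BINS]

    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(area > 0, counts / area, np.nan)
    if counts[BACKGROUND_BIN] < 1:
        raise ValueError("background bin (600-650 um) contains no centroids; cannot normalize")
    normalized = density / density[BACKGROUND_BIN]
    return DensityProfile(bin_edges=_bin_edges(), counts=counts, area_mm2=area,
                          density=density, normalized=normalized)


def detect_hole(
    intensity: np.ndarray,
    quantile: float = 0.02,
    min_area_px: int = 50,
    closing_radius_px: int = 3,
    hole_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Segment the (dark) implant hole; a user-supplied mask always wins.

    Thresholds at a low intensity quantile, closes small gaps, and keeps the
    largest connected component.
    """
    if hole_mask is not None:
        return np.asarray(hole_mask, dtype=bool)
    img = np.asarray(intensity, dtype=float)
    thr = np.quantile(img, quantile)
    cand = img <= thr
    if cand.all() or not cand.any():
        raise ValueError("no contrast between hole and tissue; supply a manual hole mask")
    # opening kills isolated dark noise pixels; closing then heals the hole rim
    cand = ndimage.binary_opening(cand, structure=np.ones((3, 3)))
    cand = ndimage.binary_closing(cand, structure=morphology.disk(closing_radius_px))
    cand = ndimage.binary_fill_holes(cand)
    lab = measure.label(cand)
    if lab.max() == 0:
        raise ValueError("no hole candidate found; supply a manual hole mask")
    sizes = np.bincount(lab.ravel())[1:]
    if sizes.max() < min_area_px:
        raise ValueError(
            f"largest dark component ({sizes.max()} px) is below {min_area_px} px; "
            "supply a manual hole mask"
        )
    return lab == (int(np.argmax(sizes)) + 1)
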