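"""Synthetic implant-site fluorescence images with known radial truths.

Images emulate 16-bit slide-scanner captures of tissue around a circular
implant hole.  For intensity markers (GFAP, CD68, IgG) every pixel's
expected value is a function of its distance to the hole edge; for NeuN the
image is rendered from an inhomogeneous Poisson point process of soma-sized
blobs whose density follows the configured radial profile.  Radial truths
are step functions over the 13 half-open 50 um bins, so bin-level truths
are exact by construction.  Artifact patches (simulating tissue folds or
staining debris) are placed and recorded in the artifact mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from imequant.histo import MAX_DIST_UM, N_BINS, RING_WIDTH_UM, ImplantImage

__all__ = ["IhcImageConfig", "gen_ihc_image", "default_ihc_config", "DEFAULT_BIN0_RETENTION"]

#: Fraction of background neuron density retained in the 0-50 um bin for the
#: two arms whose histology the pipeline is calibrated against.
DEFAULT_BIN0_RETENTION = {"DEXSPPIN": 0.59, "DILUENT": 0.21}

HOLE_INTENSITY = 80.0  # dark hole interior, well below tissue background
TISSUE_BASELINE = 2000.0  # 16-bit background-tissue intensity scale


def ramp_profile(v0: float, v_bg: float = 1.0) -> np.ndarray:
    """Per-bin truth ramping linearly in bin index from v0 to v_bg."""
    return v0 + (v_bg - v0) * np.arange(N_BINS) / (N_BINS - 1)


@dataclass
class IhcImageConfig:
    marker: str = "NeuN"
    image_size: int = 2480  # px, square
    microns_per_pixel: float = 0.65
    hole_radius_um: float = 150.0
    #: per-bin truth over the 13 bins: relative intensity, or relative neuron
    #: density, each bin's value relative to the background bin
    profile: np.ndarray = field(default_factory=lambda: ramp_profile(0.59))
    background_density_mm2: float = 1500.0  # NeuN only: absolute density in the last bin
    soma_diameter_um: float = 8.0
    artifact_patches: int = 0
    noise_sigma: float = 40.0  # additive Gaussian, 16-bit intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (N_BINS,):
            raise ValueError(
                f"profile must give one value per {RING_WIDTH_UM} um bin on "
                f"[0, {MAX_DIST_UM}] um ({N_BINS} values), got shape {self.profile.shape}"
            )
        if np.any(self.profile < 0):
            raise ValueError("profile values must be non-negative")
        margin_um = (self.image_size / 2.0) * self.microns_per_pixel - self.hole_radius_um
        if margin_um < MAX_DIST_UM:
            raise ValueError(
                f"hole must fit with >= {MAX_DIST_UM} um margin; have {margin_um:.0f} um"
            )


@dataclass
class IhcGroundTruth:
    profile: np.ndarray  # the per-bin truth
    centroids: np.ndarray | None  # (n, 2) row/col px, NeuN only
    artifact_boxes: list[tuple[int, int, int, int]]


def _distance_bins(config: IhcImageConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = config.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r_um = np.hypot(yy - c, xx - c) * config.microns_per_pixel
    hole = r_um <= config.hole_radius_um
    dist_um = ndimage.distance_transform_edt(~hole, sampling=config.microns_per_pixel)
    return hole, dist_um, r_um


def gen_ihc_image(config: IhcImageConfig) -> tuple[ImplantImage, IhcGroundTruth]:
    """Render one synthetic implant-site image plus masks and ground truth."""
    rng = np.random.default_rng(config.seed)
    hole, dist_um, _ = _distance_bins(config)
    bins = np.clip((dist_um / RING_WIDTH_UM).astype(int), 0, N_BINS - 1)
    outside = ~hole

    img = np.full(hole.shape, HOLE_INTENSITY, dtype=float)
    centroids: np.ndarray | None = None

    if config.marker == "NeuN":
        img[outside] = TISSUE_BASELINE * 0.15  # dim neuropil between somata
        centroids = _render_somata(config, rng, img, hole, dist_um, bins)
    else:
        rel = np.where(outside, config.profile[bins], 0.0)
        # Beyond the last bin the tissue continues at background level.
        rel[outside & (dist_um >= MAX_DIST_UM)] = config.profile[-1]
        img[outside] = TISSUE_BASELINE * rel[outside]

    artifact_mask = np.zeros(hole.shape, dtype=bool)
    boxes = []
    for _ in range(config.artifact_patches):
        h = int(rng.integers(30, 120))
        w = int(rng.integers(30, 120))
        r0 = int(rng.integers(0, hole.shape[0] - h))
        c0 = int(rng.integers(0, hole.shape[1] - w))
        artifact_mask[r0:r0 + h, c0:c0 + w] = True
        img[r0:r0 + h, c0:c0 + w] = rng.uniform(0, 65535)
        boxes.append((r0, c0, h, w))

    if config.noise_sigma > 0:
        img += rng.normal(0, config.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)

    image = ImplantImage(
        intensity=img,
        hole_mask=hole,
        artifact_mask=artifact_mask,
        microns_per_pixel=config.microns_per_pixel,
        marker=config.marker,
    )
    truth = IhcGroundTruth(profile=config.profile.copy(), centroids=centroids,
                           artifact_boxes=boxes)
    return image, truth


def _render_somata(
    config: IhcImageConfig,
    rng: np.random.Generator,
    img: np.ndarray,
    hole: np.ndarray,
    dist_um: np.ndarray,
    bins: np.ndarray,
) -> np.ndarray:
    """Poisson point process of Gaussian somata following the density profile.

    Thinning of a homogeneous process at the profile's maximum density keeps
    the per-bin expected density exactly profile * background density.
    """
    mpp = config.microns_per_pixel
    px_area_mm2 = (mpp / 1000.0) ** 2
    usable = ~hole & (dist_um < MAX_DIST_UM)
    rel = config.profile[bins]
    lam_max = config.background_density_mm2 * config.profile.max()
    n_cand = rng.poisson(lam_max * img.size * px_area_mm2)
    rows = rng.uniform(0, img.shape[0], size=n_cand)
    cols = rng.uniform(0, img.shape[1], size=n_cand)
    ri, ci = rows.astype(int), cols.astype(int)
    accept = usable[ri, ci] & (
        rng.random(n_cand) < rel[ri, ci] * config.background_density_mm2 / lam_max
    )
    pts = np.column_stack([rows[accept], cols[accept]])

    # Stamp each soma as a bright Gaussian blob.
    sigma_px = config.soma_diameter_um / 4.0 / mpp
    half = int(np.ceil(3 * sigma_px))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    stamp = np.exp(-(yy**2 + xx**2) / (2 * sigma_px**2))
    amp = TISSUE_BASELINE * 4.0
    h, w = img.shape
    for r, c in pts:
        r0, c0 = int(round(r)) - half, int(round(c)) - half
        r1, c1 = r0 + stamp.shape[0], c0 + stamp.shape[1]
        sr0, sc0 = max(0, -r0), max(0, -c0)
        sr1 = stamp.shape[0] - max(0, r1 - h)
        sc1 = stamp.shape[1] - max(0, c1 - w)
        img[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)] += (
            amp * stamp[sr0:sr1, sc0:sc1]
        )
    return pts


def default_ihc_config(arm: str = "DEXSPPIN", seed: int = 0, **overrides) -> IhcImageConfig:
    """Default NeuN image configuration for a study arm's histology."""
    v0 = DEFAULT_BIN0_RETENTION[arm]
    return IhcImageConfig(marker="NeuN", profile=ramp_profile(v0), seed=seed, **overrides)
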