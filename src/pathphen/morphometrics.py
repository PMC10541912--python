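"""Spheroid radial morphometrics.

Quantifies equatorial cross-sections of 3-D mammospheres from two-channel
immunofluorescence images: a nuclear stain (lumen clearing) and a basement
membrane marker such as laminin (apico-basal polarity), with a cell-wide
marker channel (e.g. beta-catenin) used as the segmentation mask.

The central statistic is a 20-bin concentric radial intensity profile:
every mask pixel is assigned to one of 20 equal-radius rings around the
mask centroid, the mean intensity per ring is computed, and each ring mean
is divided by the total mask pixel count so that profiles from spheroids of
different sizes are comparable.  From the nuclear profile an inner/outer
intensity ratio scores hollowness (hollow lumen -> ratio near 0); from the
membrane-marker profile the peripheral share of signal scores polarity
(basally polarized -> share near 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

N_BINS_DEFAULT = 20


@dataclass
class SpheroidImage:
    """Two-channel spheroid image plus a segmentation-marker channel.

    All channels share a shape; intensities are nonnegative.  ``truth``
    carries ground-truth labels for synthetic images (``hollow``,
    ``peripheral_laminin``) and is ``None`` for real data.
    """

    nuclear: np.ndarray
    laminin: np.ndarray
    mask_marker: np.ndarray
    pixel_size: float = 1.0
    truth: dict | None = None

    def __post_init__(self):
        shapes = {self.nuclear.shape, self.laminin.shape, self.mask_marker.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name in ("nuclear", "laminin", "mask_marker"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"negative intensities in {name} channel")


@dataclass
class RadialProfile:
    """Per-ring mean intensities of one channel over the spheroid mask.

    ``bin_means`` are area-normalized (divided by total mask pixel count);
    ``raw_means`` are the plain per-ring mean intensities.  Rings that
    contain no pixel are reported as 0 and flagged in ``empty_bins``.
    """

    bin_means: np.ndarray
    raw_means: np.ndarray
    bin_pixel_counts: np.ndarray
    n_bins: int = N_BINS_DEFAULT
    empty_bins: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS_DEFAULT, bool))

    @property
    def mask_area_px(self) -> int:
        return int(self.bin_pixel_counts.sum())


def segment_spheroid(image: SpheroidImage) -> tuple[np.ndarray, tuple[float, float]]:
    """Global-threshold segmentation of the spheroid from the marker channel.

    Otsu threshold, hole filling, then the largest connected component
    (ties broken by first-found label).  Returns the binary mask and the
    mask center of mass (row, col).
    """
    chan = image.mask_marker
    if not np.any(chan > 0):
        raise ValueError("empty mask-marker channel: nothing to segment")
    if np.ptp(chan) == 0:
        binary = chan > 0
    else:
        binary = chan > threshold_otsu(chan)
    binary = ndimage.binary_fill_holes(binary)
    labels = sk_label(binary)
    if labels.max() == 0:
        raise ValueError("segmentation produced an empty mask")
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1  # argmax -> first-found on ties
    mask = labels == largest
    centroid = ndimage.center_of_mass(mask)
    return mask, centroid


def cross_section_area(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Equatorial cross-section area in square micrometres."""
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty mask")
    return n * pixel_size ** 2


def radial_bin_profile(mask: np.ndarray, channel: np.ndarray,
                       n_bins: int = N_BINS_DEFAULT,
                       centroid: tuple[float, float] | None = None) -> RadialProfile:
    """Concentric equal-radius ring profile of ``channel`` over ``mask``.

    A pixel at distance r from the centroid lands in bin ceil(n_bins * r /
    r_max) (the centre pixel, r = 0, lands in bin 1), where r_max is the
    largest distance over mask pixels.  Ring means are additionally divided
    by the total mask pixel count (``bin_means``); ``raw_means`` keeps the
    unnormalized version.
    """
    if mask.shape != channel.shape:
        raise ValueError("mask and channel shapes differ")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    if centroid is None:
        centroid = ndimage.center_of_mass(mask)
    r = np.hypot(rows - centroid[0], cols - centroid[1])
    r_max = r.max()
    if r_max == 0:
        bins = np.ones(r.size, dtype=int)
    else:
        bins = np.ceil(n_bins * r / r_max).astype(int)
        bins[bins < 1] = 1
        bins[bins > n_bins] = n_bins
    vals = channel[rows, cols].astype(float)
    counts = np.bincount(bins, minlength=n_bins + 1)[1:]
    sums = np.bincount(bins, weights=vals, minlength=n_bins + 1)[1:]
    empty = counts == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} of {n_bins} radial bins are empty")
    raw = np.divide(sums, counts, out=np.zeros(n_bins), where=~empty)
    total_px = rows.size
    return RadialProfile(bin_means=raw / total_px, raw_means=raw,
                         bin_pixel_counts=counts, n_bins=n_bins,
                         empty_bins=empty)


def hollowness_score(nuclear_profile: RadialProfile) -> float:
    """Inner/outer nuclear-intensity ratio; lower means a clearer lumen.

    mean(bins 1..n/2) / mean(bins n/2+1..n).  A fully cleared lumen gives 0;
    a uniformly filled spheroid gives about 1.  Zero outer signal returns
    +inf with a warning.
    """
    half = nuclear_profile.n_bins // 2
    inner = nuclear_profile.bin_means[:half].mean()
    outer = nuclear_profile.bin_means[half:].mean()
    if outer == 0:
        warnings.warn("zero outer nuclear signal; hollowness undefined (+inf)")
        return np.inf
    return float(inner / outer)


def polarity_score(laminin_profile: RadialProfile, peripheral_bins: int = 5) -> float:
    """Peripheral share of the membrane-marker profile, in [0, 1].

    sum of the outermost ``peripheral_bins`` ring means over the sum of all
    ring means.  1 means fully basally polarized; a uniform marker gives
    roughly ``peripheral_bins / n_bins``.  All-zero profile returns NaN
    with a warning.
    """
    total = laminin_profile.bin_means.sum()
    if total == 0:
        warnings.warn("all-zero laminin profile; polarity undefined (NaN)")
        return float("nan")
    outer = laminin_profile.bin_means[-peripheral_bins:].sum()
    return float(outer / total)


def polarity_phenotype(polarity: float, reference_polarity: float) -> float:
    """Scalar polarity-disruption phenotype: -log2(polarity / reference).

    Defined so that loss of basal polarity (smaller peripheral share than
    the reference line) is positive, i.e. aggressive-positive, matching the
    orientation of the other phenotype scores.
    """
    if polarity <= 0 or reference_polarity <= 0:
        raise ValueError("polarity scores must be positive for the log ratio")
    return float(-np.log2(polarity / reference_polarity))


def quantify_spheroid(image: SpheroidImage, n_bins: int = N_BINS_DEFAULT) -> dict:
    """End-to-end morphometrics for one image.

    Segments the spheroid and returns area (um^2), the nuclear and
    membrane-marker radial profiles, and the hollowness and polarity
    scores.
    """
    mask, centroid = segment_spheroid(image)
    nuc = radial_bin_profile(mask, image.nuclear, n_bins, centroid)
    lam = radial_bin_profile(mask, image.laminin, n_bins, centroid)
    return {
        "area_um2": cross_section_area(mask, image.pixel_size),
        "mask_area_px": int(np.count_nonzero(mask)),
        "centroid": centroid,
        "nuclear_profile": nuc,
        "laminin_profile": lam,
        "hollowness": hollowness_score(nuc),
        "polarity": polarity_score(lam),
    }
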