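"""Nuclear-density quantification from two-channel confocal-like images.

The segmentation chain mirrors the study's automated procedure: histogram
thresholding of the nucleus (DAPI) channel at mode + 2 SD, Gaussian blurring
and one erosion/dilation pass to remove small segments, watershed separation
of touching nuclei on the negated distance transform, and division of the
nucleus count by the tissue area taken from the matrix (WGA) channel.

Measured densities map onto the three classes used as classifier labels:
low [0, 2000), medium [2000, 3800), high [3800, inf) nuclei/mm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, erosion
from skimage.segmentation import watershed


@dataclass(frozen=True)
class SegmentationParams:
    histogram_bins: int = 256
    blur_sigma_px: float = 2.0
    morph_radius_px: int = 2
    watershed_min_seed_distance_px: int = 10
    seed_smooth_sigma_px: float = 2.0  # EDT smoothing before peak detection

    def __post_init__(self) -> None:
        if min(self.histogram_bins, self.blur_sigma_px, self.morph_radius_px,
               self.watershed_min_seed_distance_px) <= 0:
            raise ValueError("segmentation parameters must be positive")


@dataclass(frozen=True)
class NDMeasurement:
    nucleus_count: int
    tissue_area_mm2: float
    nd: float

    def __post_init__(self) -> None:
        if self.tissue_area_mm2 <= 0:
            raise ValueError("tissue area must be positive")


@dataclass(frozen=True)
class NDClassScheme:
    """Half-open ND class bins: low [0, b0), medium [b0, b1), high [b1, inf)."""

    boundaries: tuple[float, float] = (2000.0, 3800.0)
    labels: tuple[str, str, str] = ("low", "medium", "high")

    def __post_init__(self) -> None:
        if not self.boundaries[0] < self.boundaries[1]:
            raise ValueError("class boundaries must be strictly increasing")


DEFAULT_SCHEME = NDClassScheme()


def threshold_nuclei(nucleus_image: np.ndarray,
                     params: SegmentationParams = SegmentationParams()
                     ) -> np.ndarray:
    """Binary nucleus mask: pixels strictly above histogram mode + 2 SD.

    The mode is the argmax bin center of a ``histogram_bins``-bin intensity
    histogram over the image's full dynamic range; the SD is computed over all
    pixels.  A constant image yields an empty mask with a warning.
    """
    img = np.asarray(nucleus_image, dtype=float)
    if img.size == 0 or img.ndim != 2:
        raise ValueError("expected a non-empty single-channel image")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("constant image: empty nucleus mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    counts, edges = np.histogram(img, bins=params.histogram_bins,
                                 range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = centers[int(np.argmax(counts))]
    thr = mode + 2.0 * img.std()
    return img > thr


def clean_mask(mask: np.ndarray,
               params: SegmentationParams = SegmentationParams()
               ) -> np.ndarray:
    """Remove small segments: blur + re-threshold, then erosion and dilation.

    The mask is Gaussian-blurred (sigma ``blur_sigma_px``) and re-thresholded
    at 0.5, then eroded and dilated once with a disk of ``morph_radius_px``.
    Objects smaller than the structuring element vanish.
    """
    m = np.asarray(mask, dtype=bool)
    blurred = ndi.gaussian_filter(m.astype(float), params.blur_sigma_px)
    m = blurred > 0.5
    selem = disk(params.morph_radius_px)
    return dilation(erosion(m, selem), selem).astype(bool)


def split_touching_nuclei(mask: np.ndarray,
                          params: SegmentationParams = SegmentationParams()
                          ) -> np.ndarray:
    """Label image separating touching nuclei by seeded watershed.

    Seeds are local maxima of the (lightly smoothed) Euclidean distance
    transform, at least ``watershed_min_seed_distance_px`` apart; the
    watershed runs on the negated distance transform within the mask.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros(m.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(m)
    smooth = ndi.gaussian_filter(dist, params.seed_smooth_sigma_px) \
        if params.seed_smooth_sigma_px > 0 else dist
    coords = peak_local_max(smooth,
                            min_distance=params.watershed_min_seed_distance_px,
                            labels=m, exclude_border=False)
    markers = np.zeros(m.shape, dtype=np.int32)
    if coords.size == 0:
        # degenerate: fall back to connected components
        markers, _ = ndi.label(m)
        return markers
    markers[tuple(coords.T)] = np.arange(1, coords.shape[0] + 1)
    return watershed(-dist, markers, mask=m).astype(np.int32)


def compute_nd(label_image: np.ndarray, matrix_image: np.ndarray,
               pixel_size_um: float) -> NDMeasurement:
    """ND = number of distinct nuclei / tissue area from the matrix channel.

    Tissue is the Otsu-thresholded matrix (WGA) channel with holes filled;
    area converts through the squared pixel size.
    """
    labels = np.asarray(label_image)
    mat = np.asarray(matrix_image, dtype=float)
    if labels.shape != mat.shape:
        raise ValueError("label image and matrix channel differ in shape")
    count = int(np.count_nonzero(np.unique(labels)))
    tissue = ndi.binary_fill_holes(mat > threshold_otsu(mat))
    area_mm2 = float(tissue.sum()) * (pixel_size_um / 1000.0) ** 2
    if area_mm2 <= 0:
        raise ValueError("zero tissue area")
    return NDMeasurement(count, area_mm2, count / area_mm2)


def measure_nd(nucleus_image: np.ndarray, matrix_image: np.ndarray,
               pixel_size_um: float,
               params: SegmentationParams = SegmentationParams()
               ) -> NDMeasurement:
    """Full chain: threshold -> clean -> watershed split -> density."""
    mask = clean_mask(threshold_nuclei(nucleus_image, params), params)
    labels = split_touching_nuclei(mask, params)
    return compute_nd(labels, matrix_image, pixel_size_um)


def assign_nd_class(nd: float, scheme: NDClassScheme = DEFAULT_SCHEME) -> str:
    """Class label for a density value (half-open bins)."""
    if nd < 0:
        raise ValueError("nd must be non-negative")
    b0, b1 = scheme.boundaries
    if nd < b0:
        return scheme.labels[0]
    if nd < b1:
        return scheme.labels[1]
    return scheme.labels[2]


class FitConvergenceError(RuntimeError):
    def __init__(self, message: str, p0, maxfev: int):
        super().__init__(f"{message} (initial values {p0}, maxfev {maxfev})")
        self.p0 = p0
        self.maxfev = maxfev


def fit_nd_age_decay(measurements: list[tuple[float, float]]):
    """Least-squares fit of nd_floor + nd_amplitude*exp(-age/tau).

    ``measurements`` is a list of (age_months, nd) points; at least 4 points
    over at least 3 distinct ages are required.  Returns an
    :class:`~lssnd.synthetic.NDAgeModel` and a residual summary dict.
    """
    from .synthetic import NDAgeModel  # local import avoids a cycle

    pts = np.asarray(measurements, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (age, nd) measurements")
    ages, nds = pts[:, 0], pts[:, 1]
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages")

    def model(a, floor, amp, tau):
        return floor + amp * np.exp(-a / tau)

    span = ages.max() - ages.min()
    p0 = (max(nds.min(), 1e-6),
          max(nds.max() - nds.min(), 1e-6),
          max(span / 3.0, 1e-3))
    maxfev = 20000
    try:
        popt, _ = curve_fit(model, ages, nds, p0=p0,
                            bounds=([1e-9, 1e-9, 1e-9],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=maxfev)
    except RuntimeError as err:
        raise FitConvergenceError(str(err), p0, maxfev) from err
    resid = nds - model(ages, *popt)
    summary = {"rss": float(np.sum(resid ** 2)),
               "rmse": float(np.sqrt(np.mean(resid ** 2))),
               "n": int(len(nds))}
    return NDAgeModel(nd_floor=float(popt[0]), nd_amplitude=float(popt[1]),
                      tau=float(popt[2])), summary
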