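"""Reading, validation, and preprocessing of light-scattering spectra.

A spectrometer acquisition is a trace of backscattered intensity on a
wavelength grid.  Each probe placement yields one trace per collection-fiber
set (R1, near ring; R2, far ring).  The preprocessing chain applied before any
machine-learning step is fixed:

    normalize (to mean intensity) -> Gaussian filter -> [wavelength window]
    -> concatenate fiber pair -> [downsample by factor K]

Each :class:`SpectrumRecord` tracks which stages have been applied and the
operations refuse out-of-order application.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

FIBERS = ("R1", "R2")
CONCATENATED_FIBER = "R1+R2"

#: native acquisition grid: evenly spaced points over the instrument's
#: 500--1100 nm range.  3648 is a standard CCD line length and matches the
#: ~0.165 nm spacing implied by "a standard deviation of 20 measures (~3.3 nm)".
#: Downstream code is length-agnostic; this is only a default.
NATIVE_N_POINTS = 3648
NATIVE_RANGE_NM = (500.0, 1100.0)


class SpectrumFormatError(ValueError):
    """Raised for malformed spectra files or records."""


class PipelineOrderError(RuntimeError):
    """Raised when a preprocessing step is applied out of order."""


def native_grid(n_points: int = NATIVE_N_POINTS,
                lo_nm: float = NATIVE_RANGE_NM[0],
                hi_nm: float = NATIVE_RANGE_NM[1]) -> np.ndarray:
    """Evenly spaced wavelength grid over the closed interval [lo, hi]."""
    return np.linspace(lo_nm, hi_nm, n_points)


@dataclass(frozen=True)
class FilterSpec:
    """1D Gaussian filter: SD and kernel width, both in grid samples."""

    sd_measures: float = 20.0
    kernel_measures: int = 80

    def __post_init__(self) -> None:
        if self.sd_measures <= 0:
            raise ValueError("sd_measures must be positive")
        if self.kernel_measures < 1:
            raise ValueError("kernel_measures must be >= 1")


@dataclass(frozen=True)
class DownsampleSpec:
    """Resolution-reduction factor K (may be non-integer, K >= 1)."""

    K: float

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("downsampling factor K must be >= 1")


@dataclass
class SpectrumRecord:
    """One acquisition's intensity trace plus its provenance metadata.

    ``wavelength_nm`` is ``None`` once fibers have been concatenated or the
    trace downsampled, at which point the axis is a plain sample index.
    """

    wavelength_nm: np.ndarray | None
    intensity: np.ndarray
    sample_id: str
    fiber: str
    acquisition_index: int
    stages: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm is not None:
            self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
            if self.wavelength_nm.shape != self.intensity.shape:
                raise SpectrumFormatError(
                    f"{self.sample_id}/{self.fiber}/{self.acquisition_index}: "
                    "wavelength and intensity lengths differ")
            if np.any(np.diff(self.wavelength_nm) <= 0):
                raise SpectrumFormatError(
                    f"{self.sample_id}/{self.fiber}/{self.acquisition_index}: "
                    "wavelengths must be strictly increasing")
        if self.fiber not in FIBERS + (CONCATENATED_FIBER,):
            raise SpectrumFormatError(f"unknown fiber label {self.fiber!r}")

    @property
    def n_points(self) -> int:
        return self.intensity.size

    def has(self, stage: str) -> bool:
        return stage in self.stages

    def _with(self, intensity: np.ndarray, *, stage: str | None = None,
              **kw) -> "SpectrumRecord":
        stages = self.stages if stage is None or stage in self.stages \
            else self.stages + (stage,)
        return replace(self, intensity=intensity, stages=stages, **kw)


def normalize_to_mean(record: SpectrumRecord) -> SpectrumRecord:
    """Divide the trace by its mean intensity (output mean exactly 1).

    Removes the acquisition-to-acquisition gain variability caused by fiber
    bending and coupling losses.  Idempotent.
    """
    for late in ("filtered", "concatenated", "downsampled"):
        if record.has(late):
            raise PipelineOrderError(f"cannot normalize after '{late}'")
    m = float(np.mean(record.intensity))
    if m <= 0:
        raise ValueError("cannot normalize a spectrum with non-positive mean")
    return record._with(record.intensity / m, stage="normalized")


def gaussian_kernel(sd: float, width: int) -> np.ndarray:
    """Symmetric Gaussian kernel truncated at +/- width//2 samples, sum 1."""
    radius = width // 2
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def gaussian_smooth(record: SpectrumRecord,
                    spec: FilterSpec = FilterSpec()) -> SpectrumRecord:
    """Smooth the trace with a truncated, renormalized Gaussian kernel.

    Boundary handling is reflect padding; the DC gain of the kernel is exactly
    1, so a constant trace is unchanged and the trace mean is preserved on
    interior points.
    """
    if not record.has("normalized"):
        raise PipelineOrderError("filter requires a normalized spectrum")
    for late in ("concatenated", "downsampled"):
        if record.has(late):
            raise PipelineOrderError(f"cannot filter after '{late}'")
    if record.n_points < spec.kernel_measures:
        raise ValueError(
            f"trace length {record.n_points} shorter than kernel "
            f"({spec.kernel_measures} measures)")
    radius = spec.kernel_measures // 2
    smoothed = gaussian_filter1d(record.intensity, sigma=spec.sd_measures,
                                 mode="reflect",
                                 truncate=radius / spec.sd_measures)
    return record._with(smoothed, stage="filtered")


def window_wavelengths(record: SpectrumRecord, lo_nm: float,
                       hi_nm: float) -> SpectrumRecord:
    """Restrict a per-fiber trace to wavelengths in the half-open [lo, hi).

    One exception to the half-open rule: when ``hi_nm`` reaches the last grid
    wavelength, that final point is retained.  Under this convention the three
    study windows (500-700, 700-900, 900-1100 nm) partition the native grid
    with no overlap and no gap, and windowing with the full range is the
    identity.
    """
    if record.has("concatenated") or record.has("downsampled"):
        raise PipelineOrderError("windowing applies per fiber, before "
                                 "concatenation and downsampling")
    if record.wavelength_nm is None:
        raise PipelineOrderError("record has no wavelength axis")
    if lo_nm >= hi_nm:
        raise ValueError("window requires lo < hi")
    wl = record.wavelength_nm
    if hi_nm >= wl[-1]:
        keep = wl >= lo_nm
    else:
        keep = (wl >= lo_nm) & (wl < hi_nm)
    if not np.any(keep):
        raise ValueError(f"window [{lo_nm}, {hi_nm}) contains no grid points")
    return record._with(record.intensity[keep],
                        wavelength_nm=record.wavelength_nm[keep])


def concatenate_fibers(r1: SpectrumRecord,
                       r2: SpectrumRecord) -> SpectrumRecord:
    """Join the R1 and R2 traces of one acquisition into a single vector.

    Both inputs must be normalized and filtered; the output axis is a sample
    index (R1 first, then R2).
    """
    if (r1.sample_id, r1.acquisition_index) != (r2.sample_id,
                                                r2.acquisition_index):
        raise ValueError(
            f"fiber pairing mismatch: {r1.sample_id}/{r1.acquisition_index} "
            f"vs {r2.sample_id}/{r2.acquisition_index}")
    for r in (r1, r2):
        if not (r.has("normalized") and r.has("filtered")):
            raise PipelineOrderError(
                "concatenation requires normalized, filtered traces")
        if r.has("concatenated"):
            raise PipelineOrderError("record already concatenated")
    return SpectrumRecord(
        wavelength_nm=None,
        intensity=np.concatenate([r1.intensity, r2.intensity]),
        sample_id=r1.sample_id,
        fiber=CONCATENATED_FIBER,
        acquisition_index=r1.acquisition_index,
        stages=tuple(dict.fromkeys(r1.stages + r2.stages)) + ("concatenated",),
    )


def _resample_positions(n: int, K: float) -> np.ndarray:
    """Fractional query positions for factor-K reduction of an n-point trace.

    M = max(2, round(n / K)) evenly spaced positions over [0, n - 1]; K = 1
    reproduces the integer grid exactly.
    """
    m = max(2, int(np.floor(n / K + 0.5)))
    return np.linspace(0.0, n - 1.0, m)


def downsample_array(values: np.ndarray, K: float) -> np.ndarray:
    """Linear-interpolation downsampling of the last axis by factor K."""
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples to downsample")
    if K < 1:
        raise ValueError("downsampling factor K must be >= 1")
    pos = _resample_positions(n, K)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    frac = pos - i0
    return values[..., i0] * (1.0 - frac) + values[..., i1] * frac


def downsample_by_factor(record: SpectrumRecord,
                         spec: DownsampleSpec) -> SpectrumRecord:
    """Reduce trace resolution by the (possibly non-integer) factor K."""
    out = downsample_array(record.intensity, spec.K)
    wl = None
    if record.wavelength_nm is not None:
        wl = downsample_array(record.wavelength_nm, spec.K)
    return record._with(out, wavelength_nm=wl, stage="downsampled")


# ---------------------------------------------------------------------------
# file I/O: long-format delimited text
# ---------------------------------------------------------------------------

_COLUMNS = ["wavelength_nm", "intensity", "sample_id", "fiber",
            "acquisition_index"]


def write_spectra(records: list[SpectrumRecord], path) -> None:
    """Write per-fiber records to a delimited text table (CSV).

    Columns: wavelength_nm, intensity, sample_id, fiber, acquisition_index.
    Values are written with enough digits for a lossless round trip.
    """
    frames = []
    for r in records:
        if r.wavelength_nm is None:
            raise ValueError("only per-fiber records with a wavelength axis "
                             "can be written to the delimited format")
        frames.append(pd.DataFrame({
            "wavelength_nm": r.wavelength_nm,
            "intensity": r.intensity,
            "sample_id": r.sample_id,
            "fiber": r.fiber,
            "acquisition_index": r.acquisition_index,
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra(path) -> list[SpectrumRecord]:
    """Read records written by :func:`write_spectra`.

    Returns one record per (sample_id, fiber, acquisition_index) group, in
    file order.  Malformed rows raise :class:`SpectrumFormatError` naming the
    offending group; an empty file returns an empty list with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        warnings.warn(f"spectra file {path} is empty", stacklevel=2)
        logger.warning("spectra file %s is empty", path)
        return []
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise SpectrumFormatError(f"missing columns: {sorted(missing)}")
    bad = ~df["fiber"].isin(FIBERS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SpectrumFormatError(
            f"unknown fiber label {df['fiber'].iloc[row]!r} at row {row}")
    records = []
    for (sid, fiber, acq), g in df.groupby(
            ["sample_id", "fiber", "acquisition_index"], sort=False):
        wl = g["wavelength_nm"].to_numpy(float)
        if np.any(np.diff(wl) <= 0):
            raise SpectrumFormatError(
                f"non-monotone wavelengths in {sid}/{fiber}/{acq} "
                f"(first file row {g.index[0]})")
        records.append(SpectrumRecord(wl, g["intensity"].to_numpy(float),
                                      str(sid), str(fiber), int(acq)))
    return records


# ---------------------------------------------------------------------------
# whole-dataset convenience
# ---------------------------------------------------------------------------

def preprocess_dataset(records: list[SpectrumRecord],
                       filter_spec: FilterSpec = FilterSpec(),
                       window: tuple[float, float] | None = None,
                       downsample_K: float | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Run the full chain on raw per-fiber records and stack the result.

    Returns ``(X, sample_ids)`` where row i of X is the concatenated
    (optionally windowed, optionally downsampled) R1+R2 trace of acquisition i
    and ``sample_ids[i]`` its source sample.
    """
    by_key: dict[tuple[str, int], dict[str, SpectrumRecord]] = {}
    for r in records:
        by_key.setdefault((r.sample_id, r.acquisition_index), {})[r.fiber] = r
    rows, sids = [], []
    for (sid, acq), pair in by_key.items():
        if set(pair) != set(FIBERS):
            raise ValueError(f"acquisition {sid}/{acq} lacks a fiber pair")
        processed = {}
        for fiber in FIBERS:
            rec = gaussian_smooth(normalize_to_mean(pair[fiber]), filter_spec)
            if window is not None:
                rec = window_wavelengths(rec, *window)
            processed[fiber] = rec
        cat = concatenate_fibers(processed["R1"], processed["R2"])
        if downsample_K is not None:
            cat = downsample_by_factor(cat, DownsampleSpec(downsample_K))
        rows.append(cat.intensity)
        sids.append(sid)
    return np.vstack(rows), np.asarray(sids)
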