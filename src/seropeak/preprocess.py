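"""Raw-spectrum preprocessing: segment normalization, valley-to-valley
centroiding, unit-m/z binning, and triplicate averaging.

The pipeline turns profile traces (m/z, intensity pairs) into the
samples x bins peak-area matrix consumed by the LOOCV/PCV classifier.
Every sample is processed through the identical sequence:

    normalize_segments -> centroid_valley_to_valley -> bin_peaks
    -> average_triplicates
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawSpectrum",
    "CentroidPeak",
    "PeakMatrix",
    "SpectrumFormatError",
    "normalize_segments",
    "centroid_valley_to_valley",
    "bin_peaks",
    "average_triplicates",
    "build_peak_matrix",
]


class SpectrumFormatError(ValueError):
    """Raised for malformed spectral input (unsorted m/z, negative intensity)."""


@dataclass
class RawSpectrum:
    """One replicate's profile trace for one serum sample.

    Parameters
    ----------
    sample_id : str
        Sample identifier shared by the (usually three) replicates.
    replicate_index : int
        1-based replicate number.
    mz : ndarray
        Strictly increasing m/z grid.
    intensity : ndarray
        Non-negative intensities, same length as ``mz``.
    """

    sample_id: str
    replicate_index: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise SpectrumFormatError("mz and intensity must be 1-D and equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise SpectrumFormatError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise SpectrumFormatError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class CentroidPeak:
    """A centroided peak: intensity-weighted position, trapezoidal area and
    the valley bounds that delimit it."""

    centroid_mz: float
    area: float
    bounds: tuple[float, float]


@dataclass
class PeakMatrix:
    """Samples x unit-m/z bins matrix of triplicate-averaged peak areas.

    ``areas`` is indexed by sample_id with one column per bin (bin label =
    left edge of the unit-m/z bin); ``meta`` is indexed by sample_id with
    columns ``group``, ``sex``, ``age``.
    """

    areas: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.areas.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.areas.index]
        if (self.areas.values < 0).any():
            raise ValueError("peak areas must be non-negative")

    @property
    def bins(self) -> np.ndarray:
        return self.areas.columns.to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def groups(self) -> list:
        """The distinct group labels, in order of first appearance."""
        return list(pd.unique(self.meta["group"]))

    def relabeled(self, assignment: pd.Series) -> "PeakMatrix":
        """Return a copy with ``group`` replaced by ``assignment`` (sample_id -> label)."""
        meta = self.meta.copy()
        meta["group"] = assignment.reindex(meta.index)
        return PeakMatrix(self.areas.copy(), meta)


def normalize_segments(
    spectrum: RawSpectrum, segment_width: float = 10.0, anchor: float = 400.0
) -> RawSpectrum:
    """Rescale intensities so every non-overlapping ``segment_width`` m/z
    window sums to 100 intensity units.

    Segments are half-open ``[a, a + segment_width)`` anchored at ``anchor``
    (400, 410, ... by default). Windows whose raw sum is zero are left
    all-zero rather than divided by zero. The operation is idempotent.
    """
    if len(spectrum) == 0:
        return spectrum
    seg = np.floor((spectrum.mz - anchor) / segment_width).astype(np.int64)
    seg -= seg.min()
    sums = np.bincount(seg, weights=spectrum.intensity)
    scale = np.where(sums > 0, 100.0 / np.where(sums > 0, sums, 1.0), 0.0)
    out = spectrum.intensity * scale[seg]
    return RawSpectrum(spectrum.sample_id, spectrum.replicate_index, spectrum.mz, out)


def _local_minima(y: np.ndarray, lo: int, hi: int) -> list[int]:
    """Indices of interior local minima in y[lo:hi+1] (plateau-safe single cut)."""
    cuts = []
    for i in range(lo + 1, hi):
        if y[i] <= y[i - 1] and y[i] < y[i + 1]:
            cuts.append(i)
    return cuts


def centroid_valley_to_valley(
    spectrum: RawSpectrum, min_area: float = 0.0
) -> list[CentroidPeak]:
    """Convert a profile trace into centroided peaks delimited valley to valley.

    Valleys are interior local intensity minima; runs of zero intensity and
    the trace endpoints also delimit peaks. Each peak's area is the
    trapezoidal integral of the trace between its valleys and its centroid
    is the intensity-weighted mean m/z. Peaks with area <= ``min_area`` are
    dropped.
    """
    mz, y = spectrum.mz, spectrum.intensity
    n = mz.size
    if n == 0:
        return []
    peaks: list[CentroidPeak] = []
    nonzero = y > 0
    if not nonzero.any():
        return []
    # maximal runs of nonzero intensity
    idx = np.flatnonzero(nonzero)
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[run_breaks + 1]))
    ends = np.concatenate((idx[run_breaks], [idx[-1]]))
    for s, e in zip(starts, ends):
        # extend one sample into the flanking zeros so the ramp is integrated
        lo = max(s - 1, 0)
        hi = min(e + 1, n - 1)
        bounds = [lo] + _local_minima(y, lo, hi) + [hi]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b <= a:
                continue
            area = float(np.trapezoid(y[a : b + 1], mz[a : b + 1]))
            w = y[a : b + 1]
            if area <= min_area or w.sum() <= 0:
                continue
            centroid = float(np.dot(w, mz[a : b + 1]) / w.sum())
            peaks.append(CentroidPeak(centroid, area, (float(mz[a]), float(mz[b]))))
    return peaks


def bin_peaks(peaks: list[CentroidPeak], bin_width: float = 1.0) -> dict[float, float]:
    """Assign centroids to ``floor(centroid / bin_width) * bin_width`` bins,
    summing the areas of co-binned peaks.

    A small epsilon guards against a centroid sitting a rounding error below
    a bin edge.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    out: dict[float, float] = {}
    for p in peaks:
        b = float(np.floor(p.centroid_mz / bin_width + 1e-6) * bin_width)
        out[b] = out.get(b, 0.0) + p.area
    return out


def average_triplicates(replicate_maps: list[dict[float, float]]) -> dict[float, float]:
    """Per-bin arithmetic mean over the three replicate bin->area maps.

    A bin absent from a replicate contributes area 0 for that replicate; the
    union of bins is retained. Fewer or more than 3 maps triggers a warning
    and the mean is taken over however many were supplied.
    """
    n = len(replicate_maps)
    if n == 0:
        raise ValueError("no replicate maps supplied")
    if n != 3:
        warnings.warn(
            f"expected 3 replicates, got {n}; averaging over {n}", stacklevel=2
        )
    out: dict[float, float] = {}
    for m in replicate_maps:
        for b, a in m.items():
            out[b] = out.get(b, 0.0) + a
    return {b: a / n for b, a in sorted(out.items())}


def build_peak_matrix(
    samples: dict[str, list[RawSpectrum]],
    meta: pd.DataFrame,
    segment_width: float = 10.0,
    bin_width: float = 1.0,
    anchor: float = 400.0,
    min_area: float = 0.0,
) -> PeakMatrix:
    """Run the full normalize -> centroid -> bin -> average pipeline on every
    sample and assemble the peak matrix over the union of bins.

    ``samples`` maps sample_id to its replicate spectra; ``meta`` is indexed
    by sample_id (or carries a ``sample_id`` column) with ``group``, ``sex``,
    ``age``. Bins absent from a sample are filled with 0.
    """
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    missing = [sid for sid in meta.index if sid not in samples]
    if missing:
        raise ValueError(f"no spectra supplied for samples: {missing}")
    rows: dict[str, dict[float, float]] = {}
    for sid in meta.index:
        maps = [
            bin_peaks(
                centroid_valley_to_valley(
                    normalize_segments(sp, segment_width, anchor), min_area
                ),
                bin_width,
            )
            for sp in samples[sid]
        ]
        rows[sid] = average_triplicates(maps)
    areas = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    areas = areas.reindex(sorted(areas.columns), axis=1)
    areas.index.name = "sample_id"
    return PeakMatrix(areas, meta.copy())
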