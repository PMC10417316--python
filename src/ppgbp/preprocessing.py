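"""PPG/ABP preprocessing chain.

The chain turns a raw paired record into fixed-length training segments:

1. quality control — reject records containing flatlines or flat peaks;
2. 8-level discrete wavelet decomposition (Daubechies db4) and denoising by
   zeroing the baseline band (A8, below ~0.244 Hz at 125 Hz) and the two
   highest-frequency detail bands (D1-D2, above ~15.6 Hz);
3. systolic-peak detection on the denoised PPG;
4. two-cycle peak-to-peak segmentation with one-cycle overlap;
5. cubic-spline resampling of every excerpt to 200 samples;
6. reference SBP/DBP extraction from the synchronized ABP excerpt;
7. removal of abnormal pressures (SBP >= 200, DBP >= 120, SBP <= 80, DBP <= 40);
8. per-segment z-score standardization (population SD).

All sample coordinates are 0-based with half-open spans [start, stop).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .errors import (
    InvalidArgumentError,
    LabelExtractionError,
    StandardizationError,
)
from .synthetic import SignalRecord

__all__ = [
    "SubbandSet",
    "Segment",
    "QCReport",
    "flat_region_qc",
    "subband_frequency_ranges",
    "dwt_decompose",
    "dwt_reconstruct",
    "dwt_denoise",
    "detect_systolic_peaks",
    "segment_two_cycle",
    "spline_resample",
    "extract_bp_labels",
    "bp_range_filter",
    "zscore_standardize",
    "record_to_segments",
    "segments_to_arrays",
    "write_segments_text",
    "read_segments_text",
    "write_segments_npz",
    "read_segments_npz",
]

TARGET_LENGTH = 200
DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 8
#: detail bands zeroed during denoising (highest frequencies)
DENOISE_DROP_DETAILS = (1, 2)


@dataclass
class QCReport:
    flatline_spans: list[tuple[int, int]] = field(default_factory=list)
    flatpeak_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flatline_spans and not self.flatpeak_spans


@dataclass
class SubbandSet:
    """Coefficients of a dyadic wavelet decomposition.

    ``approximation`` is the deepest low-pass band (A_levels); ``details[k]``
    holds D_{k+1}, i.e. details are ordered from the highest-frequency band
    D1 down to D_levels.
    """

    approximation: np.ndarray
    details: list[np.ndarray]
    wavelet_name: str
    levels: int
    sampling_rate: float
    signal_length: int

    def band_count(self) -> int:
        return 1 + len(self.details)


@dataclass
class Segment:
    """One standardized 200-sample PPG excerpt with its pressure labels."""

    values: np.ndarray
    sbp: float
    dbp: float
    subject_id: str
    span: tuple[int, int]
    peak_indices: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != TARGET_LENGTH:
            raise InvalidArgumentError(f"segment must have {TARGET_LENGTH} samples")
        if not self.dbp < self.sbp:
            raise InvalidArgumentError("segment needs dbp < sbp")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray):
    """Yield (start, stop) of maximal True runs in a boolean array."""
    if mask.size == 0:
        return
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        yield int(start), int(stop)


def flat_region_qc(
    signal,
    sampling_rate: float,
    min_flat_duration: float = 1.0,
    slope_tolerance: float = 0.0,
) -> QCReport:
    """Locate flatlines and flat peaks caused by acquisition dropouts/clipping.

    A *flatline* is a maximal run where successive differences stay within
    ``slope_tolerance`` for at least ``min_flat_duration`` seconds.  A *flat
    peak* is a plateau of >= 3 identical samples that forms a local maximum
    (the signature of amplitude clipping).  The record passes QC iff neither
    is found.
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise InvalidArgumentError("empty signal")
    min_samples = int(np.ceil(min_flat_duration * sampling_rate))
    if x.size < min_samples:
        raise InvalidArgumentError("signal shorter than min_flat_duration")

    diff = np.diff(x)
    report = QCReport()
    for start, stop in _runs(np.abs(diff) <= slope_tolerance):
        # a run of `m` flat differences covers m + 1 samples
        if stop - start + 1 >= min_samples:
            report.flatline_spans.append((start, stop + 1))

    for start, stop in _runs(diff == 0):
        n_samples = stop - start + 1
        if n_samples < 3:
            continue
        level = x[start]
        left_drop = start == 0 or x[start - 1] < level
        right_drop = stop + 1 >= x.size or x[stop + 1] < level
        if left_drop and right_drop:
            report.flatpeak_spans.append((start, stop + 1))
    return report


# ---------------------------------------------------------------------------
# wavelet decomposition and denoising
# ---------------------------------------------------------------------------

def subband_frequency_ranges(sampling_rate: float, levels: int = DEFAULT_LEVELS):
    """Nominal frequency span of each band of a ``levels``-deep decomposition.

    Detail band D_k spans (fs/2^(k+1), fs/2^k]; the final approximation
    A_levels spans [0, fs/2^(levels+1)].  Together the levels+1 bands
    partition [0, Nyquist].
    """
    if levels < 1 or sampling_rate <= 0:
        raise InvalidArgumentError("need levels >= 1 and positive sampling_rate")
    bands = []
    for k in range(1, levels + 1):
        bands.append((f"D{k}", sampling_rate / 2 ** (k + 1), sampling_rate / 2**k))
    bands.append((f"A{levels}", 0.0, sampling_rate / 2 ** (levels + 1)))
    return bands


def dwt_decompose(
    signal,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    sampling_rate: float = 125.0,
) -> SubbandSet:
    """Multilevel DWT returning one approximation and ``levels`` detail bands."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("signal must be one-dimensional")
    if x.size < 2**levels:
        raise InvalidArgumentError(
            f"signal of length {x.size} too short for a {levels}-level decomposition"
        )
    coeffs = pywt.wavedec(x, wavelet, level=levels)
    approximation = coeffs[0]
    details = list(coeffs[1:][::-1])  # reorder to D1 (finest) .. D_levels
    return SubbandSet(
        approximation=approximation,
        details=details,
        wavelet_name=wavelet,
        levels=levels,
        sampling_rate=sampling_rate,
        signal_length=x.size,
    )


def dwt_reconstruct(bands: SubbandSet) -> np.ndarray:
    """Inverse transform of a (possibly modified) sub-band set."""
    coeffs = [bands.approximation] + bands.details[::-1]
    out = pywt.waverec(coeffs, bands.wavelet_name)
    return out[: bands.signal_length]


def dwt_denoise(
    signal,
    sampling_rate: float = 125.0,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    drop_details: tuple[int, ...] = DENOISE_DROP_DETAILS,
) -> np.ndarray:
    """Remove baseline drift and high-frequency artifacts from a PPG trace.

    Zeroes the deepest approximation band (A8: < fs/512, ~0.244 Hz at 125 Hz)
    and the detail bands in ``drop_details`` (defaults D1-D2: > fs/8,
    ~15.6 Hz), retaining the band that carries the PPG fundamental and its
    harmonics.
    """
    x = np.asarray(signal, dtype=float)
    # odd-reflect padding (continuous value and slope) keeps the filter-bank
    # boundary transient out of the returned samples
    pad = min(x.size - 1, 4 * 2**levels)
    padded = np.pad(x, pad, mode="reflect", reflect_type="odd") if pad > 0 else x
    bands = dwt_decompose(padded, wavelet, levels, sampling_rate)
    bands.approximation = np.zeros_like(bands.approximation)
    for k in drop_details:
        bands.details[k - 1] = np.zeros_like(bands.details[k - 1])
    return dwt_reconstruct(bands)[pad : pad + x.size]


# ---------------------------------------------------------------------------
# beats and segments
# ---------------------------------------------------------------------------

def detect_systolic_peaks(
    signal,
    sampling_rate: float,
    hr_bounds: tuple[float, float] = (40.0, 180.0),
) -> np.ndarray:
    """Systolic-peak indices on a denoised PPG trace.

    Local maxima separated by at least one minimal cardiac period
    (fs * 60 / hr_max samples) with prominence at least 0.3 times the
    signal's interquartile range.
    """
    lo, hi = hr_bounds
    if not (20 < lo < hi < 220):
        raise InvalidArgumentError("hr_bounds must satisfy 20 < lo < hi < 220 bpm")
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        return np.array([], dtype=int)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    distance = max(1, int(sampling_rate * 60.0 / hi))
    if iqr == 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(x, distance=distance, prominence=0.3 * iqr)
    return peaks.astype(int)


def segment_two_cycle(signal, peaks) -> list[tuple[int, int]]:
    """Two-cycle peak-to-peak spans with one-cycle overlap.

    Span i runs from peaks[i] to peaks[i+2]; with n peaks this yields n - 2
    spans, consecutive spans sharing exactly one cardiac cycle.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 3:
        return []
    return [(int(peaks[i]), int(peaks[i + 2])) for i in range(peaks.size - 2)]


def spline_resample(excerpt, target_length: int = TARGET_LENGTH) -> np.ndarray:
    """Resample an excerpt to ``target_length`` samples with a cubic spline.

    Query points are uniform over the excerpt's index range, endpoints
    included, so the first and last values are preserved.  Both stretching
    (short excerpts) and compressing (long excerpts) use the same spline.
    """
    y = np.asarray(excerpt, dtype=float)
    if y.size < 4:
        raise InvalidArgumentError("cubic spline needs at least 4 points")
    if target_length < 2:
        raise InvalidArgumentError("target_length must be >= 2")
    spline = CubicSpline(np.arange(y.size), y)
    query = np.linspace(0.0, y.size - 1.0, target_length)
    return spline(query)


def extract_bp_labels(
    abp,
    span: tuple[int, int],
    sampling_rate: float,
    hr_bounds: tuple[float, float] = (40.0, 180.0),
) -> tuple[float, float]:
    """Reference (SBP, DBP) for a span: means of per-beat ABP extrema.

    ABP systolic peaks inside the span are located by a distance rule derived
    from ``hr_bounds`` with prominence at least half the window's
    peak-to-peak range (stricter than the PPG rule, so the dicrotic bump on
    the pressure downstroke is never mistaken for a beat); DBP is the mean of
    the minima of the inter-peak troughs, including the partial cycles at the
    span edges.
    """
    x = np.asarray(abp, dtype=float)
    start, stop = int(span[0]), int(span[1])
    if not 0 <= start < stop <= x.size:
        raise InvalidArgumentError("span outside the ABP trace")
    window = x[start:stop]
    if np.ptp(window) == 0:
        raise LabelExtractionError("constant ABP excerpt")
    distance = max(1, int(sampling_rate * 60.0 / hr_bounds[1]))
    peaks, _ = find_peaks(window, distance=distance, prominence=0.5 * np.ptp(window))
    if peaks.size == 0:
        # a two-cycle span may start/end exactly at systolic peaks; fall back
        # to the window extremes if no interior peak is prominent enough
        raise LabelExtractionError("no ABP beat found in span")
    sbp = float(np.mean(window[peaks]))
    bounds = [0, *peaks.tolist(), window.size]
    minima = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= 2:
            minima.append(window[a:b].min())
    dbp = float(np.mean(minima))
    if not dbp < sbp:
        raise LabelExtractionError("degenerate labels (dbp >= sbp)")
    return sbp, dbp


def bp_range_filter(labels: tuple[float, float]) -> bool:
    """True (keep) unless SBP >= 200, DBP >= 120, SBP <= 80, or DBP <= 40."""
    sbp, dbp = labels
    if not (np.isfinite(sbp) and np.isfinite(dbp)):
        raise InvalidArgumentError("labels must be finite")
    return not (sbp >= 200 or dbp >= 120 or sbp <= 80 or dbp <= 40)


def zscore_standardize(values) -> np.ndarray:
    """Z-score a segment using the population standard deviation (divide by N)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise StandardizationError("zero-variance segment")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# record -> segments
# ---------------------------------------------------------------------------

def record_to_segments(
    record: SignalRecord,
    hr_bounds: tuple[float, float] = (40.0, 180.0),
    target_length: int = TARGET_LENGTH,
    qc: bool = True,
    min_flat_duration: float = 1.0,
    slope_tolerance: float = 0.0,
) -> list[Segment]:
    """Run the full preprocessing chain on one record.

    Returns the standardized segments that survive QC, label extraction, and
    the abnormal-pressure filter.  A record failing QC yields no segments
    (whole-record rejection).
    """
    if qc and not flat_region_qc(
        record.ppg, record.sampling_rate, min_flat_duration, slope_tolerance
    ).passed:
        return []
    denoised = dwt_denoise(record.ppg, record.sampling_rate)
    peaks = detect_systolic_peaks(denoised, record.sampling_rate, hr_bounds)
    segments: list[Segment] = []
    for i, (start, stop) in enumerate(segment_two_cycle(denoised, peaks)):
        try:
            sbp, dbp = extract_bp_labels(
                record.abp, (start, stop), record.sampling_rate, hr_bounds
            )
        except LabelExtractionError:
            continue
        if not bp_range_filter((sbp, dbp)):
            continue
        try:
            values = zscore_standardize(
                spline_resample(denoised[start:stop], target_length)
            )
        except StandardizationError:
            continue
        segments.append(
            Segment(
                values=values,
                sbp=sbp,
                dbp=dbp,
                subject_id=record.subject_id,
                span=(start, stop),
                peak_indices=(int(peaks[i]), int(peaks[i + 1]), int(peaks[i + 2])),
            )
        )
    return segments


def segments_to_arrays(segments, target: str = "sbp"):
    """Stack segments into (X, y) arrays for model training."""
    if target not in ("sbp", "dbp"):
        raise InvalidArgumentError("target must be 'sbp' or 'dbp'")
    X = np.stack([s.values for s in segments])
    y = np.array([getattr(s, target) for s in segments], dtype=float)
    return X, y


# ---------------------------------------------------------------------------
# segment container I/O
# ---------------------------------------------------------------------------

def write_segments_text(segments, path) -> None:
    """Tab-delimited container: 200 value columns + sbp + dbp + subject + span + peaks."""
    with open(str(path), "w") as fh:
        header = [f"v{i}" for i in range(TARGET_LENGTH)]
        header += ["sbp", "dbp", "subject_id", "span_start", "span_stop", "p0", "p1", "p2"]
        fh.write("\t".join(header) + "\n")
        for s in segments:
            row = [f"{v:.17g}" for v in s.values]
            row += [f"{s.sbp:.17g}", f"{s.dbp:.17g}", s.subject_id]
            row += [str(s.span[0]), str(s.span[1])]
            row += [str(p) for p in s.peak_indices]
            fh.write("\t".join(row) + "\n")


def read_segments_text(path) -> list[Segment]:
    segments = []
    with open(str(path)) as fh:
        next(fh)  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            values = np.array([float(v) for v in parts[:TARGET_LENGTH]])
            sbp, dbp = float(parts[TARGET_LENGTH]), float(parts[TARGET_LENGTH + 1])
            subject = parts[TARGET_LENGTH + 2]
            span = (int(parts[TARGET_LENGTH + 3]), int(parts[TARGET_LENGTH + 4]))
            peaks = tuple(int(p) for p in parts[TARGET_LENGTH + 5 : TARGET_LENGTH + 8])
            segments.append(Segment(values, sbp, dbp, subject, span, peaks))
    return segments


def write_segments_npz(segments, path) -> None:
    """Binary container equivalent to the text format."""
    np.savez_compressed(
        str(path),
        values=np.stack([s.values for s in segments]),
        sbp=np.array([s.sbp for s in segments]),
        dbp=np.array([s.dbp for s in segments]),
        subject_id=np.array([s.subject_id for s in segments]),
        span=np.array([s.span for s in segments], dtype=int),
        peaks=np.array([s.peak_indices for s in segments], dtype=int),
    )


def read_segments_npz(path) -> list[Segment]:
    data = np.load(str(path), allow_pickle=False)
    return [
        Segment(
            values=data["values"][i],
            sbp=float(data["sbp"][i]),
            dbp=float(data["dbp"][i]),
            subject_id=str(data["subject_id"][i]),
            span=tuple(int(v) for v in data["span"][i]),
            peak_indices=tuple(int(v) for v in data["peaks"][i]),
        )
        for i in range(len(data["sbp"]))
    ]
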