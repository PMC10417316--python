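"""Synthetic paired PPG/ABP records with known per-beat blood pressure.

Real cuffless-BP studies train on intensive-care waveform databases in which
a photoplethysmogram (PPG) and an invasive arterial-blood-pressure (ABP) line
are recorded simultaneously at 125 Hz.  This module generates stand-in records
with the same geometry so the full pipeline — quality control, denoising,
beat segmentation, label extraction, model training — runs and can be tested
without any external database.

Each heartbeat is a two-Gaussian pulse (systolic peak plus dicrotic wave).
The ABP beat is the pulse affinely scaled so its maximum is exactly that
beat's systolic pressure (SBP) and its minimum the diastolic pressure (DBP).
The PPG beat encodes the same pressures in its *morphology*: the systolic
peak width (as a fraction of the cardiac cycle) is a linear function of SBP
and the dicrotic-wave amplitude a linear function of DBP.  The coupling is
deliberately linear and invertible (constants below) so parameter-recovery
tests have a closed-form target, while remaining a plausible caricature of
the physiological association between pulse shape and pressure.

Baseline drift, additive noise, and optional flatline / flat-peak corruption
are applied only *after* the per-beat ground truth is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptySpanError, InvalidArgumentError

__all__ = [
    "SyntheticConfig",
    "SignalRecord",
    "synth_pulse",
    "synth_record",
    "ground_truth_for_span",
    "measure_beat_morphology",
    "morphology_to_bp",
    "write_record",
    "read_record",
]

# Linear BP -> morphology coupling.  Widths are fractions of one cardiac
# cycle; amplitudes are relative to a unit systolic peak.
WIDTH_AT_REF_SBP = 0.095
WIDTH_PER_MMHG = 0.0005
REF_SBP = 135.0
DICROTIC_AT_REF_DBP = 0.30
DICROTIC_PER_MMHG = 0.006
REF_DBP = 65.0
DICROTIC_DELAY = 0.60       # fraction of the cycle after beat onset
DICROTIC_WIDTH = 0.10
SYSTOLIC_CENTER = 0.32


def _width_for_sbp(sbp: float) -> float:
    return WIDTH_AT_REF_SBP + WIDTH_PER_MMHG * (sbp - REF_SBP)


def _dicrotic_for_dbp(dbp: float) -> float:
    return DICROTIC_AT_REF_DBP + DICROTIC_PER_MMHG * (dbp - REF_DBP)


def morphology_to_bp(width_fraction, dicrotic_amplitude):
    """Invert the generator's linear morphology coupling.

    Returns the (sbp, dbp) pair that produces a beat with the given systolic
    width fraction and relative dicrotic amplitude.  Used as the closed-form
    target in recovery tests.
    """
    sbp = REF_SBP + (np.asarray(width_fraction) - WIDTH_AT_REF_SBP) / WIDTH_PER_MMHG
    dbp = REF_DBP + (np.asarray(dicrotic_amplitude) - DICROTIC_AT_REF_DBP) / DICROTIC_PER_MMHG
    return sbp, dbp


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic subject record.

    Defaults emulate the acquisition conditions of ICU waveform data used in
    cuffless-BP work: 300 s of paired signal at 125 Hz, heart rate and
    pressures drifting slowly from beat to beat inside physiologically
    plausible ranges.
    """

    sampling_rate: float = 125.0          # Hz
    duration: float = 300.0               # seconds
    heart_rate_range: tuple[float, float] = (55.0, 95.0)   # bpm
    sbp_range: tuple[float, float] = (90.0, 180.0)         # mmHg
    dbp_range: tuple[float, float] = (45.0, 80.0)          # mmHg
    hr_variability: float = 0.02          # fractional per-beat HR jitter
    bp_walk_step: float = 2.0             # mmHg max per-beat walk step
    noise_sd: float = 0.02                # PPG additive noise (signal units)
    abp_noise_sd: float = 0.3             # ABP additive noise (mmHg)
    drift_amplitude: float = 0.3          # PPG baseline drift (signal units)
    drift_frequency: float = 0.1          # Hz, must sit in the A8 band
    flatline_prob: float = 0.0            # per-record corruption probability
    flatpeak_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise InvalidArgumentError("sampling_rate and duration must be positive")
        for name in ("heart_rate_range", "sbp_range", "dbp_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidArgumentError(f"{name} must be a nonempty (low, high) pair")
        if not self.sbp_range[0] > self.dbp_range[1]:
            raise InvalidArgumentError("sbp_range lower bound must exceed dbp_range upper bound")
        # The level-8 approximation band of an 8-level dyadic decomposition
        # ends at fs / 2^9; drift must live inside it so denoising removes it.
        if not 0 < self.drift_frequency < self.sampling_rate / 2**9:
            raise InvalidArgumentError(
                f"drift_frequency must lie in (0, {self.sampling_rate / 2**9:g}) Hz"
            )
        for name in ("flatline_prob", "flatpeak_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise InvalidArgumentError(f"{name} must be a probability")


@dataclass
class SignalRecord:
    """One subject's synchronized PPG and ABP traces.

    ``beats`` holds (systolic_peak_index, sbp, dbp) triples when ground truth
    is known (synthetic records); loaded real records leave it empty.
    """

    subject_id: str
    sampling_rate: float
    ppg: np.ndarray
    abp: np.ndarray
    beats: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.ppg.shape != self.abp.shape:
            raise InvalidArgumentError("ppg and abp must have equal length")
        last = -1
        for idx, sbp, dbp in self.beats:
            if not 0 <= idx < len(self.ppg):
                raise InvalidArgumentError("beat index out of range")
            if idx <= last:
                raise InvalidArgumentError("beat indices must be strictly increasing")
            if not dbp < sbp:
                raise InvalidArgumentError("each beat needs dbp < sbp")
            last = idx

    def __len__(self) -> int:
        return len(self.ppg)


def synth_pulse(
    length: int,
    systolic_amplitude: float,
    dicrotic_amplitude: float,
    dicrotic_delay: float,
    systolic_width: float = WIDTH_AT_REF_SBP,
    dicrotic_width: float = DICROTIC_WIDTH,
) -> np.ndarray:
    """One pulse waveform: systolic Gaussian plus delayed dicrotic Gaussian.

    ``dicrotic_delay`` and the widths are fractions of the pulse length.  The
    waveform is endpoint-detrended (starts and ends exactly at zero) and
    rescaled so its global maximum equals ``systolic_amplitude``.
    """
    if not isinstance(length, (int, np.integer)) or length < 20:
        raise InvalidArgumentError("length must be an integer >= 20")
    if not systolic_amplitude > 0:
        raise InvalidArgumentError("systolic_amplitude must be positive")
    if not 0 < dicrotic_amplitude < systolic_amplitude:
        raise InvalidArgumentError("need 0 < dicrotic_amplitude < systolic_amplitude")
    if not 0.3 < dicrotic_delay < 0.9:
        raise InvalidArgumentError("dicrotic_delay must lie in (0.3, 0.9)")
    if not 0 < systolic_width < 0.25:
        raise InvalidArgumentError("systolic_width must lie in (0, 0.25)")

    t = np.arange(length) / length
    wave = systolic_amplitude * np.exp(-0.5 * ((t - SYSTOLIC_CENTER) / systolic_width) ** 2)
    wave += dicrotic_amplitude * np.exp(-0.5 * ((t - dicrotic_delay) / dicrotic_width) ** 2)
    # Remove the (tiny) endpoint pedestal so consecutive beats join smoothly.
    wave -= wave[0] + (wave[-1] - wave[0]) * t / t[-1]
    wave *= systolic_amplitude / wave.max()
    return wave


def _bounded_walk(rng: np.random.Generator, n: int, lo: float, hi: float, step: float) -> np.ndarray:
    """Random walk of length n reflected into [lo, hi]."""
    out = np.empty(n)
    x = rng.uniform(lo, hi)
    for i in range(n):
        out[i] = x
        x += rng.uniform(-step, step)
        if x < lo:
            x = lo + (lo - x)
        if x > hi:
            x = hi - (x - hi)
        x = min(max(x, lo), hi)
    return out


def synth_record(config: SyntheticConfig) -> SignalRecord:
    """Generate one paired PPG/ABP record under ``config``.

    Beat-level heart rate follows a multiplicative jitter walk; SBP and DBP
    follow independent bounded random walks.  Ground-truth beats are recorded
    before drift, noise, or corruption are applied.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))

    hr_lo, hr_hi = config.heart_rate_range
    ppg = np.zeros(n)
    abp = np.zeros(n)
    beats: list[tuple[int, float, float]] = []

    # Upper bound on beat count, walks generated lazily beat by beat.
    hr = rng.uniform(hr_lo, hr_hi)
    sbp = rng.uniform(*config.sbp_range)
    dbp = rng.uniform(*config.dbp_range)
    start = 0
    while start < n:
        period = int(round(fs * 60.0 / hr))
        width = _width_for_sbp(sbp)
        dic = _dicrotic_for_dbp(dbp)
        pulse = synth_pulse(period, 1.0, dic, DICROTIC_DELAY, systolic_width=width)
        shape = pulse / pulse.max()                       # in [0, 1], max exactly 1
        abp_beat = dbp + (sbp - dbp) * shape
        peak = start + int(np.argmax(pulse))

        stop = min(start + period, n)
        ppg[start:stop] = pulse[: stop - start]
        abp[start:stop] = abp_beat[: stop - start]
        if stop - start == period and peak < n:
            beats.append((peak, float(sbp), float(dbp)))
            # advance the walks only for complete beats
            hr = float(np.clip(hr * (1 + rng.uniform(-1, 1) * config.hr_variability), hr_lo, hr_hi))
            sbp = _reflect(sbp + rng.uniform(-1, 1) * config.bp_walk_step, *config.sbp_range)
            dbp = _reflect(dbp + rng.uniform(-1, 1) * config.bp_walk_step, *config.dbp_range)
        start += period

    # Ground truth is frozen; now contaminate.
    t = np.arange(n) / fs
    if config.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        ppg = ppg + config.drift_amplitude * np.sin(2 * np.pi * config.drift_frequency * t + phase)
    if config.noise_sd > 0:
        ppg = ppg + rng.normal(0, config.noise_sd, n)
    if config.abp_noise_sd > 0:
        abp = abp + rng.normal(0, config.abp_noise_sd, n)

    if config.flatline_prob > 0 and rng.random() < config.flatline_prob:
        dur = int(rng.uniform(1.0, 3.0) * fs)
        i0 = rng.integers(0, max(1, n - dur))
        ppg[i0 : i0 + dur] = ppg[i0]
    if config.flatpeak_prob > 0 and rng.random() < config.flatpeak_prob:
        dur = int(rng.uniform(1.0, 3.0) * fs)
        i0 = rng.integers(0, max(1, n - dur))
        window = ppg[i0 : i0 + dur]
        clip = np.quantile(window, 0.9)
        ppg[i0 : i0 + dur] = np.minimum(window, clip)

    return SignalRecord(
        subject_id=f"synthetic-{config.seed:06d}",
        sampling_rate=fs,
        ppg=ppg,
        abp=abp,
        beats=beats,
    )


def _reflect(x: float, lo: float, hi: float) -> float:
    if x < lo:
        x = lo + (lo - x)
    if x > hi:
        x = hi - (x - hi)
    return float(min(max(x, lo), hi))


def ground_truth_for_span(record: SignalRecord, start: int, stop: int) -> tuple[float, float]:
    """Mean per-beat (SBP, DBP) over beats whose systolic peak lies in [start, stop)."""
    if not record.beats:
        raise EmptySpanError("record carries no ground-truth beats")
    sel = [(s, d) for idx, s, d in record.beats if start <= idx < stop]
    if not sel:
        raise EmptySpanError(f"no beats with peak index in [{start}, {stop})")
    sbps, dbps = zip(*sel)
    return float(np.mean(sbps)), float(np.mean(dbps))


def measure_beat_morphology(record: SignalRecord) -> np.ndarray:
    """Estimate (width_fraction, dicrotic_amplitude) per beat from the waveform.

    Intended for clean (noise- and drift-free) records: the systolic Gaussian
    width is recovered by a log-parabola fit around the peak and the dicrotic
    amplitude read at its known phase.  Returns an array of shape (n_beats, 2).
    Beats whose neighbourhood leaves the record are skipped.
    """
    out = []
    peaks = [idx for idx, _, _ in record.beats]
    for k, peak in enumerate(peaks):
        nxt = peaks[k + 1] if k + 1 < len(peaks) else None
        if nxt is None:
            break
        period = nxt - peak
        beat_start = peak - int(round(SYSTOLIC_CENTER * period))
        if beat_start < 0 or beat_start + period > len(record):
            continue
        # log-parabola through the 3 samples at the systolic peak gives the
        # Gaussian sigma in samples: log y = c - (t-mu)^2 / (2 sigma^2)
        y = record.ppg[peak - 1 : peak + 2]
        if np.any(y <= 0):
            continue
        ly = np.log(y)
        curv = ly[0] - 2 * ly[1] + ly[2]
        if curv >= 0:
            continue
        sigma = np.sqrt(-1.0 / curv)
        dic_idx = beat_start + int(round(DICROTIC_DELAY * period))
        dic = record.ppg[dic_idx] / record.ppg[peak]
        out.append((sigma / period, dic))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# plain-text record I/O
# ---------------------------------------------------------------------------

def write_record(record: SignalRecord, data_path, meta_path=None) -> None:
    """Write a record as two-column text (ppg, abp) plus a key-value sidecar.

    The sidecar stores the sampling rate, subject id, and one ``beat:`` line
    per ground-truth beat.  Floats are written with 17 significant digits so
    the round trip is exact.
    """
    data_path = str(data_path)
    meta_path = str(meta_path) if meta_path is not None else data_path + ".meta"
    cols = np.column_stack([record.ppg, record.abp])
    np.savetxt(data_path, cols, fmt="%.17g", delimiter="\t", header="ppg\tabp")
    with open(meta_path, "w") as fh:
        fh.write(f"subject_id: {record.subject_id}\n")
        fh.write(f"sampling_rate: {record.sampling_rate:.17g}\n")
        for idx, sbp, dbp in record.beats:
            fh.write(f"beat: {idx} {sbp:.17g} {dbp:.17g}\n")


def read_record(data_path, meta_path=None) -> SignalRecord:
    """Read a record written by :func:`write_record`."""
    data_path = str(data_path)
    meta_path = str(meta_path) if meta_path is not None else data_path + ".meta"
    cols = np.loadtxt(data_path, delimiter="\t")
    subject_id = "unknown"
    sampling_rate = None
    beats: list[tuple[int, float, float]] = []
    with open(meta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, value = line.partition(":")
            key, value = key.strip(), value.strip()
            if key == "subject_id":
                subject_id = value
            elif key == "sampling_rate":
                sampling_rate = float(value)
            elif key == "beat":
                idx, sbp, dbp = value.split()
                beats.append((int(idx), float(sbp), float(dbp)))
    if sampling_rate is None:
        raise InvalidArgumentError(f"{meta_path} lacks a sampling_rate entry")
    return SignalRecord(
        subject_id=subject_id,
        sampling_rate=sampling_rate,
        ppg=cols[:, 0],
        abp=cols[:, 1],
        beats=beats,
    )
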