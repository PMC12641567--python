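"""Per-ion frequency, charge and mass recovery from trap traces.

The trace is cut into rectangular (unapodized) STFT segments (25 ms windows,
5 ms hop by default).  In each segment the fundamental oscillation peak is
located in the discrete spectrum, corroborated by energy at its 2nd-4th
harmonics (the classic guard against picking a harmonic as the fundamental),
and refined off-grid: for a rectangular window the complex-bin interpolator

    delta = -Re[(X[k+1] - X[k-1]) / (2 X[k] - X[k+1] - X[k-1])]

recovers the fractional bin offset of a sinusoid exactly in the noiseless
limit, and the harmonic amplitudes follow from the peak bins after dividing
out the Dirichlet-kernel attenuation.  The per-segment fundamental is the
weighted least-squares combination of the interpolated harmonic frequencies
f_n ~ n*f0 (weights (n*A_n)^2, the inverse frequency variances), which is
the frequency-domain equivalent of least-squares fitting the harmonic model
against the segment with a grid-free f0.

Per-ion values are robust (median) centers over converged segments; charge
comes from weighted least squares of the harmonic amplitudes against the
rectangular-waveform pattern z * gain * 2|sin(n pi d)|/(n pi); mass is
(C/f0^2) * z.  In-trap mass change is detected from the slope of f0 versus
time; because overlapping windows correlate the segment noise, the
significance test runs on a segment-stride-decimated subset of the fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .instrument import AcquisitionConfig, TimeTrace, TrapCalibration, harmonic_gains

__all__ = [
    "SegmentFit",
    "IonMeasurement",
    "stft_segments",
    "fit_segment",
    "track_ion",
    "analyze_trace",
    "analyze_traces",
    "mz_from_frequency",
    "charge_from_amplitudes",
]

logger = logging.getLogger(__name__)

#: peak must exceed this multiple of the median spectral amplitude
DETECT_SNR = 5.0
#: harmonic corroboration threshold, same units
HARMONIC_SNR = 2.5
#: harmonics must exceed this to contribute to the frequency combination
FREQ_USE_SNR = 5.0


@dataclass
class SegmentFit:
    """Harmonic fit of one STFT segment."""

    t_center_ms: float
    f0_hz: float
    harmonic_amplitudes: np.ndarray
    residual_rms: float
    converged: bool


@dataclass(frozen=True)
class IonMeasurement:
    """Recovered per-ion quantities.  mass_da = mz_th * charge_e."""

    ion_id: int
    f0_hz: float
    amplitude: float
    mz_th: float
    charge_e: float
    mass_da: float
    n_segments_used: int
    drift_hz_per_s: float
    flags: frozenset = frozenset()
    extra: dict = field(default_factory=dict, compare=False)

    @property
    def flags_str(self) -> str:
        return "|".join(sorted(self.flags))


def stft_segments(trace: TimeTrace, acq: AcquisitionConfig):
    """Rectangular STFT segmentation: left-aligned windows of segment_ms at
    hop step_ms; the final partial window is discarded.

    Returns (segments, t_centers_ms); a trace shorter than one segment gives
    a (0, segment_samples) array (the SHORT_TRAP condition).
    """
    x = np.asarray(trace.samples, dtype=float)
    seg = acq.segment_samples
    step = acq.step_samples
    if len(x) < seg:
        return np.empty((0, seg)), np.empty(0)
    n_seg = (len(x) - seg) // step + 1
    segments = np.lib.stride_tricks.sliding_window_view(x, seg)[:: step][:n_seg]
    starts = np.arange(n_seg) * step
    t_centers_ms = (starts + seg / 2.0) / acq.sample_rate_hz * 1000.0
    return segments, t_centers_ms


def _interp_bin(X: np.ndarray, k: np.ndarray):
    """Fractional bin offset and corrected amplitude at peak bins ``k``.

    ``X`` is the (n_seg, n_bins) complex spectrum; returns (delta, amp) with
    amp already corrected for the Dirichlet-kernel attenuation (amplitude of
    the time-domain cosine, window length inferred from the spectrum).
    """
    n_seg = X.shape[0]
    n = 2 * (X.shape[1] - 1)
    rows = np.arange(n_seg)
    kc = np.clip(k, 1, X.shape[1] - 2)
    xm, x0, xp = X[rows, kc - 1], X[rows, kc], X[rows, kc + 1]
    den = 2.0 * x0 - xm - xp
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = -np.real((xp - xm) / den)
    delta = np.where(np.isfinite(delta), np.clip(delta, -0.6, 0.6), 0.0)
    small = np.abs(delta) < 1e-12
    ratio = np.empty_like(delta)
    ratio[small] = 1.0
    ds = delta[~small]
    ratio[~small] = np.sin(np.pi * ds) / (n * np.sin(np.pi * ds / n))
    attenuation = np.abs(ratio)
    amp = 2.0 * np.abs(x0) / n / attenuation
    return delta, amp, attenuation


def _fit_segments_batch(segments: np.ndarray, acq: AcquisitionConfig):
    """Vectorized harmonic fit of all segments of one trace.

    Returns (f0, amps, resid_rms, converged) arrays; f0 is NaN where a
    segment did not converge.
    """
    n_seg, n = segments.shape
    fs = acq.sample_rate_hz
    binw = fs / n
    nh = acq.max_harmonic
    x = segments - segments.mean(axis=1, keepdims=True)
    X = np.fft.rfft(x, axis=1)
    absX = np.abs(X)
    n_bins = X.shape[1]

    f0 = np.full(n_seg, np.nan)
    amps = np.zeros((n_seg, nh))
    resid = np.zeros(n_seg)
    converged = np.zeros(n_seg, dtype=bool)

    # global candidate from the mean spectrum, searched below the harmonic
    # aliasing limit and away from DC
    mean_spec = absX.mean(axis=0)
    k_max = int(min(n_bins - 2, (fs / (2.0 * nh)) / binw))
    k_min = 3
    if k_max <= k_min:
        return f0, amps, resid, converged
    noise = np.median(mean_spec)
    row_noise_all = np.median(absX, axis=1)
    band = mean_spec[k_min:k_max]
    order = np.argsort(band)[::-1]
    cand_bin = -1
    for idx in order[:8]:
        k = k_min + int(idx)
        if mean_spec[k] < DETECT_SNR * noise:
            break
        # corroborate in the single strongest segment: in-trap frequency
        # drift smears harmonics across bins of the trace-averaged spectrum
        # but leaves them sharp within one segment
        row = int(np.argmax(absX[:, k]))
        spec_row = absX[row]
        thr_row = HARMONIC_SNR * row_noise_all[row]
        support = 0
        for h in range(2, nh + 1):
            kk = h * k
            if kk + 2 >= n_bins:
                continue
            if spec_row[kk - 2 : kk + 3].max() > thr_row:
                support += 1
        if support >= 1:
            # octave guard: prefer a corroborated sub-harmonic of comparable
            # strength (tie-break toward the lower frequency)
            for div in (2, 3):
                ks = int(round(k / div))
                if ks >= k_min and mean_spec[ks - 1 : ks + 2].max() > 0.5 * mean_spec[k]:
                    k = ks - 1 + int(np.argmax(mean_spec[ks - 1 : ks + 2]))
            cand_bin = k
            break
    if cand_bin < 0:
        return f0, amps, resid, converged

    # per-segment fundamental peak near the global candidate (tracks drift)
    lo = max(k_min, cand_bin - 5)
    hi = min(k_max, cand_bin + 6)
    k1 = lo + np.argmax(absX[:, lo:hi], axis=1)
    row_noise = row_noise_all
    converged = absX[np.arange(n_seg), k1] > 0.8 * DETECT_SNR * row_noise

    delta1, a1, att1 = _interp_bin(X, k1)
    f1 = (k1 + delta1) * binw

    # Rician debiasing: |X| of a weak harmonic in noise overestimates its
    # amplitude; subtract the first-order noise contribution using the
    # per-row noise level (Rayleigh median of the noise bins).
    noise_s = row_noise / 1.1774  # per-component complex-noise SD

    def _debias(a, att):
        sigma_a = 2.0 * noise_s / (n * np.maximum(att, 1e-12))
        return np.sqrt(np.maximum(a**2 - 2.0 * sigma_a**2, 0.0))

    # harmonic frequencies and amplitudes
    f_n = np.zeros((n_seg, nh))
    snr_n = np.zeros((n_seg, nh))
    f_n[:, 0] = f1
    amps[:, 0] = _debias(a1, att1)
    snr_n[:, 0] = absX[np.arange(n_seg), k1] / np.maximum(row_noise, 1e-300)
    for h in range(2, nh + 1):
        kh = np.rint(h * f1 / binw).astype(int)
        valid = (kh >= 1) & (kh < n_bins - 1)
        kh_c = np.where(valid, kh, 1)
        dh, ah, atth = _interp_bin(X, kh_c)
        f_n[:, h - 1] = np.where(valid, (kh_c + dh) * binw, np.nan)
        amps[:, h - 1] = np.where(valid, _debias(ah, atth), 0.0)
        snr_n[:, h - 1] = np.where(
            valid, np.abs(X[np.arange(n_seg), kh_c]) / np.maximum(row_noise, 1e-300), 0.0
        )

    # weighted LS of f_n ~ n*f0 over usable harmonics
    orders = np.arange(1, nh + 1)[None, :]
    usable = (snr_n > FREQ_USE_SNR) & np.isfinite(f_n)
    usable[:, 0] = True
    w = np.where(usable, (orders * amps) ** 2, 0.0)
    f0 = np.where(
        converged,
        np.sum(w * orders * np.where(usable, f_n, 0.0), axis=1) / np.sum(w * orders**2, axis=1),
        np.nan,
    )

    power = 0.5 * np.sum(amps**2, axis=1)
    resid = np.sqrt(np.maximum(x.var(axis=1) - power, 0.0))
    amps[~converged] = 0.0
    return f0, amps, resid, converged


def fit_segment(segment, acq: AcquisitionConfig, cal: TrapCalibration | None = None) -> SegmentFit:
    """Fit one STFT segment; ``converged=False`` with zero amplitudes when no
    peak rises above the noise floor."""
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    f0, amps, resid, conv = _fit_segments_batch(seg, acq)
    return SegmentFit(
        t_center_ms=float(acq.segment_ms / 2.0),
        f0_hz=float(f0[0]) if conv[0] else 0.0,
        harmonic_amplitudes=amps[0],
        residual_rms=float(resid[0]),
        converged=bool(conv[0]),
    )


def mz_from_frequency(f0_hz: float, cal: TrapCalibration) -> float:
    """m/z in Th from the oscillation frequency: C / f^2."""
    if f0_hz <= 0:
        raise ValueError("f0 must be strictly positive")
    return cal.mass_cal_c / f0_hz**2


def charge_from_amplitudes(harmonic_amplitudes, cal: TrapCalibration, weights=None) -> float:
    """Charge (real-valued, elementary units) from harmonic amplitudes.

    Weighted least squares of observed A_n against the rectangular-waveform
    pattern z * gain * 2|sin(n pi d)|/(n pi), n = 1..len(A).  With only the
    fundamental supplied this reduces to A1 * pi / (2 gain sin(pi d)).
    All-zero amplitudes give 0.
    """
    a = np.asarray(harmonic_amplitudes, dtype=float)
    if a.size == 0:
        raise ValueError("need at least the fundamental amplitude")
    g = harmonic_gains(cal, a.size)
    w = np.ones_like(g) if weights is None else np.asarray(weights, dtype=float)
    denom = np.sum(w * g * g)
    if denom == 0 or np.all(a == 0):
        return 0.0
    return float(np.sum(w * g * a) / denom)


def _drift_significant(t_s: np.ndarray, f0: np.ndarray, stride: int) -> bool:
    """Slope significance on a decimated, effectively independent subset."""
    td, fd = t_s[::stride], f0[::stride]
    if td.size < 4:
        return False
    A = np.vstack([td - td.mean(), np.ones_like(td)]).T
    coef, res, *_ = np.linalg.lstsq(A, fd, rcond=None)
    dof = td.size - 2
    if dof <= 0 or res.size == 0:
        return False
    se = float(np.sqrt(res[0] / dof / np.sum((td - td.mean()) ** 2)))
    # absolute floor guards against numerically-zero residuals on noiseless
    # traces (0.1 Hz/s is far below the frequency jitter at any real noise)
    return abs(float(coef[0])) > 3.0 * se + 0.1


def track_ion(
    fits: list[SegmentFit],
    acq: AcquisitionConfig,
    cal: TrapCalibration,
    ion_id: int = 0,
    n_total_segments: int | None = None,
) -> IonMeasurement:
    """Combine segment fits into one ion measurement.

    Medians of f0 and the harmonic amplitudes over converged segments; the
    drift is the OLS slope of f0 versus time over all converged segments,
    flagged MASS_CHANGE when significant on the decimated subset; UNSTABLE
    when fewer than 80% of segments converged.  Raises if no segment
    converged (callers drop the ion with a log record).
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged segment fits; ion dropped")
    n_total = n_total_segments if n_total_segments is not None else len(fits)
    t_s = np.array([f.t_center_ms for f in good]) / 1000.0
    f0s = np.array([f.f0_hz for f in good])
    amp_mat = np.vstack([f.harmonic_amplitudes for f in good])

    f0 = float(np.median(f0s))
    amps = np.median(amp_mat, axis=0)
    z = charge_from_amplitudes(amps, cal)
    mz = mz_from_frequency(f0, cal)

    flags = set()
    drift = 0.0
    if len(good) >= 2 and np.ptp(t_s) > 0:
        drift = float(np.polyfit(t_s, f0s, 1)[0])
        stride = max(1, int(round(acq.segment_ms / acq.step_ms)))
        if _drift_significant(t_s, f0s, stride):
            flags.add("MASS_CHANGE")
    if len(good) < 0.8 * n_total:
        flags.add("UNSTABLE")
    if len(good) == 1:
        flags.add("UNSTABLE")

    return IonMeasurement(
        ion_id=ion_id,
        f0_hz=f0,
        amplitude=float(amps[0]),
        mz_th=mz,
        charge_e=z,
        mass_da=mz * z,
        n_segments_used=len(good),
        drift_hz_per_s=drift,
        flags=frozenset(flags),
    )


def analyze_trace(
    trace: TimeTrace,
    cal: TrapCalibration,
    acq: AcquisitionConfig,
    return_fits: bool = False,
):
    """Full per-trace analysis: segment, fit, track.

    Returns an :class:`IonMeasurement` (with SHORT_TRAP flagged and NaN
    estimates if the trace is shorter than one segment), or None when no
    segment converged; optionally also the list of segment fits.
    """
    segments, t_centers = stft_segments(trace, acq)
    if segments.shape[0] == 0:
        logger.warning("ion %d: trace shorter than one segment (SHORT_TRAP)", trace.ion_id)
        meas = IonMeasurement(
            ion_id=trace.ion_id,
            f0_hz=float("nan"),
            amplitude=float("nan"),
            mz_th=float("nan"),
            charge_e=float("nan"),
            mass_da=float("nan"),
            n_segments_used=0,
            drift_hz_per_s=0.0,
            flags=frozenset({"SHORT_TRAP"}),
        )
        return (meas, []) if return_fits else meas
    f0, amps, resid, conv = _fit_segments_batch(segments, acq)
    fits = [
        SegmentFit(
            t_center_ms=float(t_centers[i]),
            f0_hz=float(f0[i]) if conv[i] else 0.0,
            harmonic_amplitudes=amps[i],
            residual_rms=float(resid[i]),
            converged=bool(conv[i]),
        )
        for i in range(segments.shape[0])
    ]
    try:
        meas = track_ion(fits, acq, cal, ion_id=trace.ion_id, n_total_segments=len(fits))
    except ValueError:
        logger.warning("ion %d: no converged segments; dropped", trace.ion_id)
        return (None, fits) if return_fits else None
    return (meas, fits) if return_fits else meas


def analyze_traces(traces, cal: TrapCalibration, acq: AcquisitionConfig) -> list[IonMeasurement]:
    """Analyze an iterable of traces, dropping (and logging) failed ions."""
    out = []
    n_in = 0
    for trace in traces:
        n_in += 1
        meas = analyze_trace(trace, cal, acq)
        if meas is not None and "SHORT_TRAP" not in meas.flags:
            out.append(meas)
    logger.info("analyzed %d traces -> %d measurements", n_in, len(out))
    return out
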