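"""Trap calibration, acquisition settings, and core record types.

In an electrostatic linear ion trap (ELIT) a trapped ion oscillates through a
cylindrical detector tube; its oscillation frequency encodes m/z through the
calibration law

    m/z [Th] = C / f^2

and the induced-charge amplitude encodes z through the detector gain and the
duty cycle (the fraction of each oscillation period the ion spends inside the
tube, which fixes the harmonic content of the rectangular induced waveform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrapCalibration",
    "AcquisitionConfig",
    "IonGroundTruth",
    "TimeTrace",
    "harmonic_gains",
]


@dataclass(frozen=True)
class TrapCalibration:
    """Instrument calibration for the simulated ELIT.

    Parameters
    ----------
    mass_cal_c : float
        Calibration constant C in Th*Hz^2 (m/z = C/f^2).  The default places
        a 4.93 MDa, 165 e ion at 10.000 kHz, so every species of interest
        oscillates in a 5-25 kHz band under 1 MHz sampling.
    gain : float
        Detected amplitude units per elementary charge.
    duty_cycle : float
        Fraction of the period spent inside the detector tube.  0.45 (not
        0.5) so that harmonics 2-4 are non-zero and can be fitted.
    noise_rms : float
        Additive white-noise RMS in amplitude units.  The default 300 gives a
        single 25 ms segment charge SD of ~4 e and a full 500 ms trap per-ion
        charge SD of ~1 e, typical CDMS precision.
    """

    mass_cal_c: float = 2.9879e12
    gain: float = 1.0
    duty_cycle: float = 0.45
    noise_rms: float = 300.0

    def __post_init__(self) -> None:
        if self.mass_cal_c <= 0 or self.gain <= 0:
            raise ValueError("mass_cal_c and gain must be strictly positive")
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValueError("duty_cycle must be in (0, 1)")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")

    def frequency_for(self, mass_da: float, charge_e: float) -> float:
        """Oscillation frequency (Hz) of an ion from m/z = C/f^2."""
        if mass_da <= 0 or charge_e <= 0:
            raise ValueError("mass and charge must be positive")
        return float(np.sqrt(self.mass_cal_c * charge_e / mass_da))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Digitizer and STFT settings.

    Defaults: 1 MHz sampling, 500 ms trap events, 25 ms rectangular STFT
    segments stepped by 5 ms, harmonics fitted up to the fourth.
    """

    sample_rate_hz: float = 1e6
    trap_ms: float = 500.0
    segment_ms: float = 25.0
    step_ms: float = 5.0
    max_harmonic: int = 4

    def __post_init__(self) -> None:
        if self.segment_ms > self.trap_ms:
            raise ValueError("segment_ms must not exceed trap_ms")
        if self.step_ms > self.segment_ms:
            raise ValueError("step_ms must not exceed segment_ms")
        if self.max_harmonic < 1:
            raise ValueError("max_harmonic must be >= 1")
        n = self.sample_rate_hz * self.segment_ms / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_rate_hz * segment_ms must give an integer sample count")

    @property
    def segment_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.segment_ms / 1000.0))

    @property
    def step_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.step_ms / 1000.0))

    @property
    def trap_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.trap_ms / 1000.0))


@dataclass(frozen=True)
class IonGroundTruth:
    """True parameters of one simulated ion.

    ``f0_hz`` must satisfy m/z = C/f^2 for the calibration used to build the
    ensemble.  ``mass_loss_rate_da_per_s`` > 0 makes the oscillation
    frequency drift upward during the trap event as the ion loses mass.
    """

    mass_da: float
    charge_e: float
    f0_hz: float
    population_label: str = ""
    mass_loss_rate_da_per_s: float = 0.0
    ion_id: int = 0

    def __post_init__(self) -> None:
        # charge 0 is admitted as the degenerate "no signal" limit
        if self.mass_da <= 0 or self.charge_e < 0 or self.f0_hz <= 0:
            raise ValueError("mass and frequency must be positive, charge non-negative")


@dataclass
class TimeTrace:
    """Sampled induced-charge signal for one trap event."""

    samples: np.ndarray
    sample_rate_hz: float
    ion_id: int = 0
    ground_truth: IonGroundTruth | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate_hz


def harmonic_gains(cal: TrapCalibration, n_harmonics: int) -> np.ndarray:
    """Amplitude per elementary charge at harmonics 1..n.

    A rectangular induced-charge waveform of duty cycle d and plateau
    gain*z has harmonic amplitudes z * gain * 2|sin(n*pi*d)|/(n*pi).
    """
    n = np.arange(1, n_harmonics + 1)
    return cal.gain * 2.0 * np.abs(np.sin(n * np.pi * cal.duty_cycle)) / (n * np.pi)
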