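"""Acoustic-emission feedback pressure controller.

Implements the sonication scheme used for microbubble-mediated BBB opening:
10 ms bursts at f0 = 1.68 MHz, 1 Hz pulse repetition frequency for 120 s.
The applied pressure ramps up from 0.2 MPa in 0.02 MPa steps (one step per
burst) until a harmonic emission -- by default the 1.5*f0 ultra-harmonic --
is detected in the burst's received spectrum, at which point the pressure is
dropped to 25% of the peak for the remainder of the sonication. Source
pressures are derated to in-situ values by the skull insertion loss and
exponential tissue attenuation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import EmissionModel, EmissionSpectrum, make_emission_spectrum

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SonicationConfig:
    """All ultrasound and controller constants.

    Attributes
    ----------
    f0
        Transducer center frequency, MHz.
    burst_length
        Burst duration, seconds.
    prf
        Pulse repetition frequency, Hz (one burst, and one potential
        pressure step, per 1/prf seconds).
    duration
        Total sonication time, seconds; ``duration * prf`` bursts.
    start_pressure, step
        Ramp origin and per-burst increment, MPa.
    drop_fraction
        Post-detection plateau as a fraction of the peak pressure.
    insertion_loss
        Fractional pressure loss through the skull bone.
    tissue_attenuation
        Brain tissue attenuation coefficient, Np/m/MHz.
    tissue_depth
        Tissue path to the focus, meters.
    detect_band_halfwidth
        Half-width of the detection band around each harmonic, Hz.
    detect_threshold_db
        Band power must exceed the noise floor by this many dB to count
        as a detection.
    trigger_mode
        ``"ultra_only"`` (default) drops the pressure on ultra-harmonic
        detection only; ``"sub_or_ultra"`` drops on either tone.
    """

    f0: float = 1.68  # MHz
    burst_length: float = 0.010  # s
    prf: float = 1.0  # Hz
    duration: float = 120.0  # s
    start_pressure: float = 0.2  # MPa
    step: float = 0.02  # MPa
    drop_fraction: float = 0.25
    insertion_loss: float = 0.18
    tissue_attenuation: float = 5.0  # Np/m/MHz
    tissue_depth: float = 2.5e-3  # m
    detect_band_halfwidth: float = 50e3  # Hz
    detect_threshold_db: float = 6.0
    trigger_mode: str = "ultra_only"

    def __post_init__(self) -> None:
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")
        if not 0 <= self.insertion_loss < 1:
            raise ValueError("insertion_loss must be in [0, 1)")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        n_bursts = self.duration * self.prf
        if abs(n_bursts - round(n_bursts)) > 1e-9:
            raise ValueError("duration * prf must be an integer number of bursts")
        if self.trigger_mode not in ("ultra_only", "sub_or_ultra"):
            raise ValueError(f"unknown trigger_mode {self.trigger_mode!r}")

    @property
    def n_bursts(self) -> int:
        return round(self.duration * self.prf)

    @property
    def f0_hz(self) -> float:
        return self.f0 * 1e6


@dataclass
class HarmonicDetection:
    """Detection state of one burst's spectrum."""

    sub_detected: bool
    ultra_detected: bool
    sub_band_power: float
    ultra_band_power: float
    noise_floor: float


@dataclass
class PressureTrace:
    """Per-burst applied (source) pressure for one focal spot."""

    pressures: np.ndarray  # MPa, length = duration * prf
    peak_pressure: float | None
    detection_burst: int | None
    plateau_pressure: float | None
    focus_id: str = "focus-0"

    @property
    def no_detection(self) -> bool:
        return self.detection_burst is None

    def to_frame(self, prf: float = 1.0) -> pd.DataFrame:
        """Trace as a tidy table (burst_index, time_s, pressure_mpa, phase)."""
        n = len(self.pressures)
        phase = np.full(n, "ramp", dtype=object)
        if self.detection_burst is not None:
            phase[self.detection_burst + 1 :] = "plateau"
        return pd.DataFrame(
            {
                "burst_index": np.arange(n),
                "time_s": np.arange(n) / prf,
                "pressure_mpa": self.pressures,
                "phase": phase,
            }
        )


def derate_pressure(source_pressure: float, config: SonicationConfig) -> float:
    """Convert source (free-field) pressure to estimated in-situ pressure.

    Applies the skull insertion loss and exponential tissue attenuation
    ``exp(-alpha * f0 * depth)`` with alpha in Np/m/MHz, f0 in MHz and depth
    in meters. With the default constants (18% loss, 5 Np/m/MHz, 1.68 MHz,
    2.5 mm) the derating factor is ~0.803.
    """
    if source_pressure < 0:
        raise ValueError("pressure must be >= 0")
    attenuation = math.exp(-config.tissue_attenuation * config.f0 * config.tissue_depth)
    return source_pressure * (1.0 - config.insertion_loss) * attenuation


def detect_harmonics(
    spectrum: EmissionSpectrum, config: SonicationConfig
) -> HarmonicDetection:
    """Scan one burst's spectrum for sub- and ultra-harmonic tones.

    Band power is the maximum magnitude within ``detect_band_halfwidth`` of
    0.5*f0 (sub) and 1.5*f0 (ultra). The noise floor is the median magnitude
    outside all harmonic bands (the 0.5/1/1.5/2 * f0 bands are excluded so
    injected tones and harmonics cannot inflate it). A tone is detected when
    its band power is at least ``detect_threshold_db`` above the floor.
    """
    freqs = np.asarray(spectrum.frequencies, dtype=float)
    mags = np.asarray(spectrum.magnitudes, dtype=float)
    f0 = config.f0_hz
    hw = config.detect_band_halfwidth

    def band_mask(center: float) -> np.ndarray:
        m = np.abs(freqs - center) <= hw
        if not m.any():
            raise ValueError(
                f"detection band at {center:g} Hz lies outside the spectrum "
                f"[{freqs[0]:g}, {freqs[-1]:g}] Hz"
            )
        return m

    if freqs[0] > 0.25 * f0 or freqs[-1] < 2.0 * f0:
        raise ValueError("spectrum must cover [0.25*f0, 2*f0]")

    sub_mask = band_mask(0.5 * f0)
    ultra_mask = band_mask(1.5 * f0)
    exclude = sub_mask | ultra_mask | band_mask(1.0 * f0) | band_mask(2.0 * f0)
    noise_floor = float(np.median(mags[~exclude]))

    threshold = noise_floor * 10.0 ** (config.detect_threshold_db / 20.0)
    sub_power = float(mags[sub_mask].max())
    ultra_power = float(mags[ultra_mask].max())
    return HarmonicDetection(
        sub_detected=sub_power >= threshold,
        ultra_detected=ultra_power >= threshold,
        sub_band_power=sub_power,
        ultra_band_power=ultra_power,
        noise_floor=noise_floor,
    )


def run_controller(
    emission_model: EmissionModel,
    config: SonicationConfig | None = None,
    focus_id: str = "focus-0",
    n_bins: int = 2048,
) -> PressureTrace:
    """Run the feedback controller against an emission model.

    One burst fires every 1/prf seconds. Before detection, burst k is driven
    at ``start_pressure + k * step``. The first burst whose spectrum triggers
    the detector (per ``trigger_mode``) defines the peak pressure; every
    subsequent burst runs at ``drop_fraction * peak``. If no burst triggers,
    the full monotone ramp is returned with ``no_detection`` set.
    """
    if config is None:
        config = SonicationConfig()
    n = config.n_bursts
    pressures = np.empty(n)
    peak: float | None = None
    detection_burst: int | None = None
    plateau: float | None = None

    for k in range(n):
        if detection_burst is None:
            p = config.start_pressure + k * config.step
            pressures[k] = p
            spectrum = make_emission_spectrum(
                p, emission_model, f0=config.f0_hz, n_bins=n_bins, burst_index=k
            )
            det = detect_harmonics(spectrum, config)
            triggered = (
                det.ultra_detected
                if config.trigger_mode == "ultra_only"
                else det.ultra_detected or det.sub_detected
            )
            if triggered:
                detection_burst = k
                peak = p
                plateau = config.drop_fraction * peak
        else:
            pressures[k] = plateau

    return PressureTrace(
        pressures=pressures,
        peak_pressure=peak,
        detection_burst=detection_burst,
        plateau_pressure=plateau,
        focus_id=focus_id,
    )


def summarize_peaks(
    traces: list[PressureTrace],
    design: pd.DataFrame,
    derated: bool = False,
    config: SonicationConfig | None = None,
) -> pd.DataFrame:
    """Tabulate peak pressures per focal spot against the group design.

    ``design`` must carry one row per trace, in order, with columns
    ``mouse, focus, genotype, treatment``. Traces that never detected are
    excluded with a logged warning. With ``derated=True`` the peaks are
    converted to in-situ pressures via :func:`derate_pressure`.
    """
    if len(traces) == 0:
        raise ValueError("no traces provided")
    if len(design) != len(traces):
        raise ValueError("design must have one row per trace")
    if config is None:
        config = SonicationConfig()

    rows = []
    for trace, (_, drow) in zip(traces, design.iterrows()):
        if trace.no_detection:
            logger.warning(
                "trace %s never detected harmonics; excluded from peak summary",
                trace.focus_id,
            )
            continue
        peak = trace.peak_pressure
        if derated:
            peak = derate_pressure(peak, config)
        rows.append(
            {
                "mouse": drow["mouse"],
                "focus": drow["focus"],
                "genotype": drow["genotype"],
                "treatment": drow["treatment"],
                "peak_mpa": peak,
            }
        )
    if not rows:
        raise ValueError("all traces were no_detection; nothing to summarize")
    return pd.DataFrame(rows)
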