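"""Synthetic inputs for the FUS-BBB analysis chain.

Everything the downstream stages consume can be generated here: acoustic
emission spectra as a function of applied pressure, multi-timepoint
contrast-enhancement image series with programmed closure times, Evans-blue
calibration standards, and the four-group (genotype x treatment) closure
fixtures whose percent-permeable curves match the study's printed values.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

GROUP_LABELS = ("nonTg-PBS", "nonTg-VT", "TgCRND8-PBS", "TgCRND8-VT")

#: Assessment schedule (hours post-sonication) for contrast MRI.
TIMEPOINTS_H = (0.0, 6.0, 12.0, 20.0)


class EmissionSpectrum(NamedTuple):
    """Single-burst magnitude spectrum of microbubble acoustic emissions."""

    frequencies: np.ndarray  # Hz
    magnitudes: np.ndarray  # linear magnitude, same length


@dataclass(frozen=True)
class EmissionModel:
    """Phenomenological microbubble emission model.

    Nonlinear bubble oscillation produces tones at 0.5*f0 (sub-harmonic) and
    1.5*f0 (ultra-harmonic) once the applied rarefactional pressure crosses a
    per-focus onset threshold. The model places a flat noise floor with small
    dB jitter and injects each tone, ``tone_level_db`` above the floor, when
    its onset pressure is reached.

    Parameters
    ----------
    onset_pressure_uh
        Pressure (MPa) at/above which the 1.5*f0 ultra-harmonic appears.
    onset_pressure_sh
        Pressure (MPa) at/above which the 0.5*f0 sub-harmonic appears.
    tone_level_db
        Tone height above the noise floor, dB (20*log10 convention).
    noise_floor
        Baseline spectral magnitude (linear units).
    noise_jitter_db
        Standard deviation of the per-bin dB jitter around the floor.
    seed
        Base seed; combined with the burst index so every burst has its own
        reproducible noise realization.
    """

    onset_pressure_uh: float = 0.36
    onset_pressure_sh: float = 0.36
    tone_level_db: float = 10.0
    noise_floor: float = 1.0
    noise_jitter_db: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.onset_pressure_uh <= 0 or self.onset_pressure_sh <= 0:
            raise ValueError("onset pressures must be > 0")
        if self.tone_level_db <= 0:
            raise ValueError("tone_level_db must be > 0")
        if self.noise_floor <= 0:
            raise ValueError("noise_floor must be > 0")


def make_emission_spectrum(
    pressure: float,
    model: EmissionModel,
    f0: float = 1.68e6,
    n_bins: int = 2048,
    burst_index: int = 0,
    f_max: float | None = None,
) -> EmissionSpectrum:
    """Simulate one burst's received emission spectrum at a given pressure.

    Parameters
    ----------
    pressure
        Applied peak-negative pressure, MPa. Must be >= 0.
    model
        Emission model carrying onsets, tone level and noise floor.
    f0
        Transducer center frequency, Hz.
    n_bins
        Number of spectral bins from 0 to ``f_max``.
    burst_index
        Index of the burst within the sonication; decorrelates noise across
        bursts while staying deterministic for a fixed model seed.
    f_max
        Upper edge of the spectrum, Hz (default ``2.5 * f0``).

    Returns
    -------
    EmissionSpectrum
        Frequencies (Hz) and linear magnitudes. The tone bin nearest
        0.5*f0 / 1.5*f0 is set to ``noise_floor * 10**(tone_level_db/20)``
        whenever the corresponding onset pressure is reached.
    """
    if pressure < 0:
        raise ValueError(f"pressure must be >= 0, got {pressure}")
    if f_max is None:
        f_max = 2.5 * f0
    if not (0 < 2.0 * f0 <= f_max):
        raise ValueError(f"f0={f0} Hz outside spectral range [0, {f_max}] Hz")
    freqs = np.linspace(0.0, f_max, n_bins)
    bin_width = f_max / (n_bins - 1)
    if bin_width > 0.05 * f0:
        raise ValueError("n_bins too small to resolve 0.5*f0 and 1.5*f0 bins")

    rng = np.random.default_rng(np.random.SeedSequence([model.seed, burst_index]))
    jitter_db = rng.normal(0.0, model.noise_jitter_db, n_bins)
    mags = model.noise_floor * 10.0 ** (jitter_db / 20.0)

    tone = model.noise_floor * 10.0 ** (model.tone_level_db / 20.0)
    if pressure >= model.onset_pressure_sh:
        mags[int(np.argmin(np.abs(freqs - 0.5 * f0)))] = tone
    if pressure >= model.onset_pressure_uh:
        mags[int(np.argmin(np.abs(freqs - 1.5 * f0)))] = tone
    return EmissionSpectrum(freqs, mags)


# ---------------------------------------------------------------------------
# Group closure fixtures (Fig-6-style four-group design)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupClosureFixture:
    """Per-group focal-spot closure counts over the 20 h observation window."""

    group_label: str
    n_foci: int
    closed_by_6h: int
    closed_6_to_12h: int
    closed_12_to_20h: int
    permeable_at_20h: int

    def __post_init__(self) -> None:
        counts = (
            self.closed_by_6h,
            self.closed_6_to_12h,
            self.closed_12_to_20h,
            self.permeable_at_20h,
        )
        if any(c < 0 for c in counts):
            raise ValueError("closure counts must be >= 0")
        if sum(counts) != self.n_foci:
            raise ValueError("closure counts must sum to n_foci")
        if not 21 <= self.n_foci <= 24:
            raise ValueError("n_foci must be within 21-24 foci per group")

    def closure_times(self) -> list[float]:
        """Programmed closure time per focus; inf = still permeable at 20 h."""
        return (
            [6.0] * self.closed_by_6h
            + [12.0] * self.closed_6_to_12h
            + [20.0] * self.closed_12_to_20h
            + [math.inf] * self.permeable_at_20h
        )

    def to_closure_table(self) -> pd.DataFrame:
        """Programmed event table (mouse, focus, group, event_time_h, event).

        The idealized table the imaging chain should recover: closure scored
        at the first assessment time at/after the programmed closure, foci
        still permeable at 20 h censored there.
        """
        rows = []
        for i, t in enumerate(self.closure_times()):
            rows.append(
                {
                    "mouse": f"{self.group_label}-m{i // 4}",
                    "focus": i % 4,
                    "group": self.group_label,
                    "event_time_h": 20.0 if math.isinf(t) else t,
                    "event": "censored" if math.isinf(t) else "closed",
                }
            )
        return pd.DataFrame(rows)

    def percent_permeable(self) -> dict[float, float]:
        open_counts = {
            0.0: self.n_foci,
            6.0: self.n_foci - self.closed_by_6h,
            12.0: self.n_foci - self.closed_by_6h - self.closed_6_to_12h,
            20.0: self.permeable_at_20h,
        }
        return {t: 100.0 * c / self.n_foci for t, c in open_counts.items()}


# Canonical reconstruction of the four study groups: counts chosen so that
# count/n, rounded to integer percent, reproduces the printed permeability
# percentages at 6/12/20 h, with n inside the legend's 21-24 range.
_CANONICAL_FIXTURES = {
    "TgCRND8-VT": (23, 17, 2, 1, 3),
    "TgCRND8-PBS": (21, 4, 2, 5, 10),
    "nonTg-PBS": (24, 4, 7, 3, 10),
    "nonTg-VT": (23, 9, 8, 0, 6),
}


def generate_group_fixture(group_label: str) -> GroupClosureFixture:
    """Return the canonical closure fixture for one of the four groups."""
    try:
        n, c6, c12, c20, perm = _CANONICAL_FIXTURES[group_label]
    except KeyError:
        raise ValueError(
            f"unknown group label {group_label!r}; expected one of {GROUP_LABELS}"
        ) from None
    return GroupClosureFixture(group_label, n, c6, c12, c20, perm)


def fixtures_table() -> pd.DataFrame:
    """All four canonical fixtures as a tidy table."""
    rows = []
    for label in GROUP_LABELS:
        f = generate_group_fixture(label)
        rows.append(
            {
                "group": f.group_label,
                "n_foci": f.n_foci,
                "closed_by_6h": f.closed_by_6h,
                "closed_6_12h": f.closed_6_to_12h,
                "closed_12_20h": f.closed_12_to_20h,
                "permeable_20h": f.permeable_at_20h,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contrast-enhancement image series
# ---------------------------------------------------------------------------

#: Default in-plane focus centers (row, col), all in the left hemisphere of a
#: 96x96 slice split at column 48. Spacing >> ROI and exclusion radius.
DEFAULT_FOCUS_CENTERS = ((24, 16), (24, 32), (72, 16), (72, 32))


@dataclass(frozen=True)
class ImageGenSpec:
    """Parameters for one mouse's synthetic T1w enhancement series.

    A sonicated focus renders as a Gaussian intensity bump on a noisy
    background; once its programmed closure time has passed, the focus
    renders as background only (step closure at the first assessment time
    at/after the closure time -- the schedule observes only at 6/12/20 h).
    """

    shape: tuple[int, int] = (96, 96)
    hemisphere_boundary_col: int = 48
    focus_centers: tuple[tuple[int, int], ...] = DEFAULT_FOCUS_CENTERS
    closure_times_h: tuple[float, ...] = (math.inf,) * 4
    amplitude: float = 100.0
    sigma: float = 2.5
    background: float = 100.0
    noise_sd: float = 10.0
    timepoints_h: tuple[float, ...] = TIMEPOINTS_H

    def __post_init__(self) -> None:
        if len(self.closure_times_h) != len(self.focus_centers):
            raise ValueError("need one closure time per focus")
        for r, c in self.focus_centers:
            if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
                raise ValueError(f"focus center ({r}, {c}) outside grid {self.shape}")
            if c >= self.hemisphere_boundary_col:
                raise ValueError(
                    f"focus center ({r}, {c}) outside the sonicated hemisphere"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude != 0 and self.noise_sd > 0:
            if self.amplitude <= 2.0 * self.noise_sd:
                raise ValueError("amplitude must exceed 2 x noise sd for detectability")


@dataclass
class ImageSeries:
    """One mouse's grayscale enhancement images at 0/6/12/20 h."""

    images: dict[float, np.ndarray]
    hemisphere_mask: np.ndarray  # True where sonicated
    focus_coords: list[tuple[int, int]]  # recorded at t=0
    mouse_id: str = "m0"
    group: str = ""

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.images)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.images.values())).shape


def _gaussian_bump(shape, center, amplitude, sigma):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return amplitude * np.exp(-d2 / (2.0 * sigma**2))


def generate_image_series(spec: ImageGenSpec, seed: int = 0) -> ImageSeries:
    """Render a mouse's multi-timepoint enhancement series.

    At t=0 every focus carries its full Gaussian bump; at a later assessment
    time a focus whose closure time has been reached renders as background
    plus noise only, while an open focus retains its full amplitude. The
    contralateral hemisphere is never enhanced.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros(spec.shape, dtype=bool)
    mask[:, : spec.hemisphere_boundary_col] = True

    images: dict[float, np.ndarray] = {}
    for t in spec.timepoints_h:
        img = spec.background + rng.normal(0.0, spec.noise_sd, spec.shape)
        for center, closure in zip(spec.focus_centers, spec.closure_times_h):
            open_now = t == 0.0 or t < closure
            if open_now:
                img += _gaussian_bump(spec.shape, center, spec.amplitude, spec.sigma)
        images[t] = img
    return ImageSeries(
        images=images,
        hemisphere_mask=mask,
        focus_coords=[tuple(c) for c in spec.focus_centers],
    )


def generate_group_image_series(
    fixture: GroupClosureFixture,
    seed: int = 0,
    base_spec: ImageGenSpec | None = None,
    foci_per_mouse: int = 4,
) -> list[ImageSeries]:
    """Render image series for every mouse in a group fixture.

    Closure times from the fixture are shuffled and dealt out four foci per
    mouse (the sonication grid), the final mouse taking the remainder.
    """
    if base_spec is None:
        base_spec = ImageGenSpec()
    label_key = zlib.crc32(fixture.group_label.encode()) % 2**31
    rng = np.random.default_rng(np.random.SeedSequence([seed, label_key]))
    times = np.array(fixture.closure_times())
    rng.shuffle(times)

    series: list[ImageSeries] = []
    n_mice = math.ceil(fixture.n_foci / foci_per_mouse)
    for m in range(n_mice):
        chunk = times[m * foci_per_mouse : (m + 1) * foci_per_mouse]
        spec = replace(
            base_spec,
            focus_centers=base_spec.focus_centers[: len(chunk)],
            closure_times_h=tuple(chunk),
        )
        s = generate_image_series(spec, seed=int(rng.integers(2**31)))
        s.mouse_id = f"{fixture.group_label}-m{m}"
        s.group = fixture.group_label
        series.append(s)
    return series


# ---------------------------------------------------------------------------
# Evans-blue calibration standards
# ---------------------------------------------------------------------------


def generate_eb_standards(
    slope: float = 100.0,
    intercept: float = 5.0,
    ng_levels: Sequence[float] = (1, 2.5, 5, 10, 25, 50, 100, 250),
    noise_sd: float = 0.0,
    saturation_ng: float = math.inf,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic semi-log Evans-blue standard curve with optional saturation.

    Radiance follows ``slope * log10(ng) + intercept`` plus Gaussian noise for
    quantities below ``saturation_ng``; above saturation the radiance is
    flattened at the saturation level, creating the non-linear portion that
    the calibration fit must exclude.
    """
    ng = np.asarray(ng_levels, dtype=float)
    if np.any(ng <= 0):
        raise ValueError("ng levels must be positive")
    if np.any(np.diff(ng) <= 0):
        raise ValueError("ng levels must be strictly ascending")
    rng = np.random.default_rng(seed)
    effective_ng = np.minimum(ng, saturation_ng)
    radiance = slope * np.log10(effective_ng) + intercept
    radiance = radiance + rng.normal(0.0, noise_sd, ng.size)
    return pd.DataFrame({"ng": ng, "radiance": radiance})


# ---------------------------------------------------------------------------
# Peak-pressure (harmonic-onset threshold) samples
# ---------------------------------------------------------------------------

#: Default group mean onset thresholds (MPa): the treated transgenic group
#: sits 25% below the other three, inside the reported 21-29% reduction.
DEFAULT_THRESHOLD_MEANS = {
    "nonTg-PBS": 0.44,
    "nonTg-VT": 0.44,
    "TgCRND8-PBS": 0.44,
    "TgCRND8-VT": 0.33,
}


def generate_threshold_samples(
    group_means: dict[str, float] | None = None,
    sd: float = 0.05,
    n_per_group: int = 24,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-focus peak-pressure samples for the 2x2 group design.

    Returns a long-format table (value, genotype, treatment, mouse, focus)
    ready for the two-way ANOVA / Tukey stage.
    """
    if group_means is None:
        group_means = DEFAULT_THRESHOLD_MEANS
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for label in GROUP_LABELS:
        if label not in group_means:
            raise ValueError(f"missing mean for group {label!r}")
        genotype, treatment = label.split("-")
        values = rng.normal(group_means[label], sd, n_per_group)
        for i, v in enumerate(values):
            rows.append(
                {
                    "value": float(v),
                    "genotype": genotype,
                    "treatment": treatment,
                    "mouse": f"{label}-m{i // 4}",
                    "focus": i % 4,
                }
            )
    return pd.DataFrame(rows)
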