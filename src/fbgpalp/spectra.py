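"""Reflection-spectrum model for a four-FBG palpation probe.

A fiber Bragg grating (FBG) reflects a narrow band around its Bragg
wavelength; the interrogator samples the combined reflection of all four
gratings on a uniform wavelength grid (2 pm hardware step).  This module
holds the in-memory spectrum model, a forward synthesizer (sum of Gaussian
peaks scaled by grating reflectivity and the interrogator's source-power
envelope, plus additive white noise), and columnar text I/O.

Units: wavelengths in nm, grid steps and Bragg shifts in pm, intensity in
arbitrary (unitless) interrogator counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "PM_PER_NM",
    "DEFAULT_FWHM_PM",
    "DEFAULT_SIGMA_REL",
    "WavelengthGrid",
    "BraggChannel",
    "Spectrum",
    "NoiseModel",
    "SpectrumParseError",
    "ChannelConfigError",
    "default_channels",
    "default_grid",
    "identity_envelope",
    "linear_ramp_envelope",
    "synth_spectrum",
    "read_spectrum",
    "write_spectrum",
]

PM_PER_NM = 1000.0

#: Default full width at half maximum of a synthesized Bragg peak, pm.
DEFAULT_FWHM_PM = 60.0

#: Default additive-noise standard deviation, as a fraction of the tallest
#: peak amplitude.
DEFAULT_SIGMA_REL = 0.01

#: Default constant spectral floor, as a fraction of unit amplitude.  The
#: interrogator's raw output shows a non-zero baseline under the peaks.
DEFAULT_BASELINE = 0.05


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its standard deviation."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class SpectrumParseError(ValueError):
    """Raised when a columnar spectrum file cannot be parsed."""


class ChannelConfigError(ValueError):
    """Raised when a Bragg-channel configuration violates its invariants."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling grid of one interrogation frame.

    Parameters
    ----------
    start_nm : first sample wavelength, nm.
    step_pm : grid spacing, pm (2 pm for the hardware described here).
    n_points : number of samples; at least 16.
    """

    start_nm: float
    step_pm: float = 2.0
    n_points: int = 40001

    def __post_init__(self) -> None:
        if not self.step_pm > 0:
            raise ValueError(f"grid step must be positive, got {self.step_pm} pm")
        if self.n_points < 16:
            raise ValueError(f"grid needs >= 16 points, got {self.n_points}")

    @property
    def step_nm(self) -> float:
        return self.step_pm / PM_PER_NM

    @property
    def stop_nm(self) -> float:
        return self.start_nm + (self.n_points - 1) * self.step_nm

    @property
    def span_nm(self) -> tuple[float, float]:
        return (self.start_nm, self.stop_nm)

    def wavelengths_nm(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def contains(self, wavelength_nm: float) -> bool:
        lo, hi = self.span_nm
        return lo <= wavelength_nm <= hi


@dataclass(frozen=True)
class BraggChannel:
    """One FBG sensing channel on the hemispherical dome.

    ``azimuth_deg`` is the angular position of the grating around the dome
    (the four gratings sit 90 degrees apart); ``fiber_position_mm`` is the
    inscription position along the fiber (two pairs, 15 mm within a pair,
    100 mm between pairs).
    """

    channel_id: int
    nominal_center_nm: float
    azimuth_deg: float
    reflectivity: float = 0.30
    fiber_position_mm: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.reflectivity <= 1.0:
            raise ChannelConfigError(
                f"channel {self.channel_id}: reflectivity must be in (0, 1], "
                f"got {self.reflectivity}"
            )


def validate_channels(channels: Sequence[BraggChannel]) -> None:
    """Check the cross-channel invariants of a probe configuration."""
    if len(channels) == 0:
        raise ChannelConfigError("no channels configured")
    ids = [c.channel_id for c in channels]
    if len(set(ids)) != len(ids):
        raise ChannelConfigError(f"duplicate channel ids: {ids}")
    ordered = sorted(channels, key=lambda c: c.channel_id)
    centers = [c.nominal_center_nm for c in ordered]
    if any(b <= a for a, b in zip(centers, centers[1:])):
        raise ChannelConfigError(
            f"nominal centers must strictly increase with channel id, got {centers}"
        )
    azimuths = [c.azimuth_deg % 360.0 for c in channels]
    if len(set(azimuths)) != len(azimuths):
        raise ChannelConfigError(f"azimuths must be distinct, got {azimuths}")
    for c in channels:
        if c.azimuth_deg % 90.0 != 0.0:
            raise ChannelConfigError(
                f"channel {c.channel_id}: azimuth must be a multiple of 90 deg, "
                f"got {c.azimuth_deg}"
            )


def default_channels() -> list[BraggChannel]:
    """The four-channel probe layout used throughout.

    Nominal Bragg wavelengths 1520/1540/1560/1580 nm (C-band stand-ins; the
    device's true wavelengths are only shown graphically), azimuths at
    0/90/180/270 degrees, ~30% reflectivity, fiber positions in two pairs.
    """
    centers = (1520.0, 1540.0, 1560.0, 1580.0)
    azimuths = (0.0, 90.0, 180.0, 270.0)
    positions = (0.0, 15.0, 115.0, 130.0)
    return [
        BraggChannel(
            channel_id=i + 1,
            nominal_center_nm=centers[i],
            azimuth_deg=azimuths[i],
            fiber_position_mm=positions[i],
        )
        for i in range(4)
    ]


def default_grid() -> WavelengthGrid:
    """1510-1590 nm at the 2 pm hardware step (40001 samples)."""
    return WavelengthGrid(start_nm=1510.0, step_pm=2.0, n_points=40001)


@dataclass
class NoiseModel:
    """Additive white Gaussian intensity noise.

    ``sigma_rel`` scales the noise standard deviation as a fraction of the
    tallest synthesized peak amplitude; negative intensities produced by the
    noise are clipped at zero (the interrogator reports counts >= 0).
    """

    sigma_rel: float = DEFAULT_SIGMA_REL
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError(f"sigma_rel must be >= 0, got {self.sigma_rel}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Spectrum:
    """One interrogation frame: intensity sampled on a wavelength grid."""

    grid: WavelengthGrid
    intensity: np.ndarray
    timestamp: Optional[str] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensity length {self.intensity.shape} does not match grid "
                f"n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("intensity contains negative values")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.grid.wavelengths_nm()


def identity_envelope(wavelength_nm: np.ndarray | float) -> np.ndarray | float:
    """Flat source-power envelope (unit gain everywhere)."""
    return np.ones_like(np.asarray(wavelength_nm, dtype=float))


def linear_ramp_envelope(
    grid: WavelengthGrid, gain_lo: float = 0.6, gain_hi: float = 1.4
) -> Callable[[np.ndarray | float], np.ndarray]:
    """Linear gain ramp across the grid span.

    The interrogator's non-linear optical power output makes equal-reflectivity
    gratings show unequal peak amplitudes, favouring the red side of the
    spectrum; a linear ramp reproduces that qualitatively.
    """
    lo, hi = grid.span_nm

    def envelope(wavelength_nm: np.ndarray | float) -> np.ndarray:
        w = np.asarray(wavelength_nm, dtype=float)
        return gain_lo + (gain_hi - gain_lo) * (w - lo) / (hi - lo)

    return envelope


def synth_spectrum(
    channels: Sequence[BraggChannel],
    centers_nm: Sequence[float],
    grid: WavelengthGrid,
    source_envelope: Optional[Callable[[np.ndarray | float], np.ndarray]] = None,
    noise: Optional[NoiseModel] = None,
    fwhm_pm: float | Sequence[float] = DEFAULT_FWHM_PM,
    baseline: float = DEFAULT_BASELINE,
    rng: Optional[np.random.Generator] = None,
) -> Spectrum:
    """Synthesize one interrogation frame.

    The intensity is a constant floor plus one Gaussian peak per channel,
    each with amplitude ``reflectivity * envelope(center)``, plus additive
    white noise (clipped at zero).  ``centers_nm`` gives the instantaneous
    Bragg wavelength of each channel (in channel order); under strain these
    move away from the nominal centers.

    Parameters
    ----------
    fwhm_pm : peak full width at half maximum, pm; scalar or per channel.
    rng : optional generator overriding ``noise.seed`` (used by the session
        simulator to derive reproducible per-press streams).
    """
    centers = np.asarray(centers_nm, dtype=float)
    if centers.shape != (len(channels),):
        raise ValueError(
            f"need one center per channel, got {centers.shape[0]} centers "
            f"for {len(channels)} channels"
        )
    for ch, c in zip(channels, centers):
        if not grid.contains(c):
            raise ValueError(
                f"channel {ch.channel_id}: center {c} nm outside grid span "
                f"{grid.span_nm}"
            )
    fwhms = np.broadcast_to(np.asarray(fwhm_pm, dtype=float), (len(channels),))
    if source_envelope is None:
        source_envelope = identity_envelope

    w = grid.wavelengths_nm()
    intensity = np.full(w.shape, float(baseline))
    amplitudes = []
    for ch, c, fw in zip(channels, centers, fwhms):
        sigma_nm = fwhm_to_sigma(fw) / PM_PER_NM
        amp = ch.reflectivity * float(np.asarray(source_envelope(c)))
        amplitudes.append(amp)
        intensity += amp * np.exp(-0.5 * ((w - c) / sigma_nm) ** 2)

    if noise is not None and noise.sigma_rel > 0:
        gen = rng if rng is not None else noise.rng()
        sigma = noise.sigma_rel * max(amplitudes)
        intensity = intensity + gen.normal(0.0, sigma, w.shape)
        np.clip(intensity, 0.0, None, out=intensity)

    return Spectrum(grid=grid, intensity=intensity)


# ---------------------------------------------------------------------------
# Columnar text I/O
# ---------------------------------------------------------------------------

_GRID_RTOL = 1e-6  # relative tolerance for the uniform-step check on read


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text (``wavelength_nm,intensity``)."""
    w = spectrum.wavelengths_nm
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("wavelength_nm,intensity\n")
        buf = io.StringIO()
        np.savetxt(buf, np.column_stack([w, spectrum.intensity]),
                   fmt="%.10e", delimiter=",")
        fh.write(buf.getvalue())


def read_spectrum(path) -> Spectrum:
    """Read a two-column text spectrum (comma, tab or whitespace separated).

    One header line is permitted.  Raises :class:`SpectrumParseError`, naming
    the offending line, on missing columns, non-monotone or non-uniform
    wavelengths, or negative intensity.
    """
    wavelengths: list[float] = []
    intensities: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").replace("\t", " ").split() if p]
            try:
                values = [float(p) for p in parts]
            except ValueError:
                if lineno == 1 and not wavelengths:
                    continue  # header line
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric data {line!r}"
                ) from None
            if len(values) < 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected two columns "
                    f"(wavelength_nm, intensity), got {len(values)}"
                )
            if values[1] < 0:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: negative intensity {values[1]}"
                )
            wavelengths.append(values[0])
            intensities.append(values[1])

    if len(wavelengths) < 16:
        raise SpectrumParseError(
            f"{path}: too few samples ({len(wavelengths)}) for a spectrum"
        )
    w = np.asarray(wavelengths)
    steps = np.diff(w)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0))
        raise SpectrumParseError(
            f"{path}: wavelengths not strictly increasing near line {bad + 2}"
        )
    step = (w[-1] - w[0]) / (len(w) - 1)
    if np.max(np.abs(steps - step)) > _GRID_RTOL * step:
        raise SpectrumParseError(f"{path}: wavelength grid is not uniform")
    grid = WavelengthGrid(start_nm=float(w[0]), step_pm=step * PM_PER_NM,
                          n_points=len(w))
    return Spectrum(grid=grid, intensity=np.asarray(intensities))
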