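"""Sub-resolution Bragg-peak localization and shift tracking.

The interrogator samples at a 2 pm hardware step; fitting a Gaussian (plus
constant baseline) to each channel's spectral window localizes the Bragg
wavelength well below that step.  The spectrum is partitioned into one
window per channel (boundaries at the midpoints between adjacent nominal
Bragg wavelengths), a Gaussian is fitted in each window, and per-channel
shifts are the differences of fitted centers between a pressed and a
reference (light-contact) frame, reported in pm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .spectra import (
    DEFAULT_FWHM_PM,
    PM_PER_NM,
    BraggChannel,
    ChannelConfigError,
    Spectrum,
    fwhm_to_sigma,
    validate_channels,
)

__all__ = [
    "ChannelWindow",
    "PeakFit",
    "ShiftVector",
    "ShiftError",
    "partition_windows",
    "fit_gaussian_peak",
    "extract_peaks",
    "compute_shifts",
    "localization_error_study",
]

# Fit bounds on the Gaussian width, as multiples of the default width.
_SIGMA_LO_FACTOR = 0.2
_SIGMA_HI_FACTOR = 5.0
# Relative parameter tolerance and iteration budget of the least-squares fit.
_FIT_XTOL = 1e-10
_FIT_MAX_ITER = 200


class ShiftError(ValueError):
    """Raised when Bragg shifts cannot be computed for a palpation point."""


@dataclass(frozen=True)
class ChannelWindow:
    """Wavelength window in which one channel's Bragg peak is expected to move."""

    channel_id: int
    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError(
                f"channel {self.channel_id}: window bounds must satisfy "
                f"lo < hi, got [{self.lo_nm}, {self.hi_nm}]"
            )


@dataclass
class PeakFit:
    """Fitted Gaussian-plus-baseline parameters for one channel window.

    ``center_nm`` is the Bragg wavelength estimate; ``converged`` is False
    when the fit failed or the center estimate is pinned at a window bound,
    in which case ``message`` carries the diagnostic.
    """

    channel_id: int
    center_nm: float
    sigma_nm: float
    amplitude: float
    baseline: float
    converged: bool
    rss: float
    message: str = ""


@dataclass(frozen=True)
class ShiftVector:
    """Per-channel signed Bragg shifts, pressed minus reference, in pm."""

    channel_ids: tuple[int, ...]
    shifts_pm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.channel_ids) != len(self.shifts_pm):
            raise ValueError("channel_ids and shifts_pm length mismatch")
        if not all(np.isfinite(self.shifts_pm)):
            raise ValueError(f"non-finite shift in {self.shifts_pm}")

    def __len__(self) -> int:
        return len(self.shifts_pm)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.shifts_pm, dtype=float)

    def __neg__(self) -> "ShiftVector":
        return ShiftVector(self.channel_ids, tuple(-s for s in self.shifts_pm))


def partition_windows(
    spectrum: Spectrum,
    channels: Sequence[BraggChannel],
    n_channels: int = 4,
) -> list[ChannelWindow]:
    """Divide the grid into per-channel windows at nominal-center midpoints.

    Interior boundaries sit midway between adjacent nominal Bragg
    wavelengths; the outer boundaries are the grid ends.  The probe is
    four-channel by construction (``n_channels=4``); pass a different count
    to generalize.
    """
    if len(channels) != n_channels:
        raise ChannelConfigError(
            f"expected {n_channels} channels, got {len(channels)}"
        )
    validate_channels(channels)
    ordered = sorted(channels, key=lambda c: c.nominal_center_nm)
    lo, hi = spectrum.grid.span_nm
    for ch in ordered:
        if not spectrum.grid.contains(ch.nominal_center_nm):
            raise ChannelConfigError(
                f"channel {ch.channel_id}: nominal center "
                f"{ch.nominal_center_nm} nm outside grid span ({lo}, {hi})"
            )
    centers = [c.nominal_center_nm for c in ordered]
    mids = [(a + b) / 2.0 for a, b in zip(centers, centers[1:])]
    bounds = [lo] + mids + [hi]
    return [
        ChannelWindow(channel_id=ch.channel_id, lo_nm=bounds[i], hi_nm=bounds[i + 1])
        for i, ch in enumerate(ordered)
    ]


def _gaussian_baseline(x: np.ndarray, center: float, sigma: float,
                       amplitude: float, baseline: float) -> np.ndarray:
    return baseline + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fit_gaussian_peak(
    spectrum: Spectrum,
    window: ChannelWindow,
    fwhm_pm: float = DEFAULT_FWHM_PM,
) -> PeakFit:
    """Fit a Gaussian plus constant baseline inside one channel window.

    Initialization: center at the window argmax (smallest-wavelength maximum
    on ties), amplitude = max - min, baseline = min, width from the default
    FWHM.  The center is bounded to the window and the width to
    [0.2x, 5x] the default.  Failures (flat window, no convergence, center
    pinned at a bound) are reported with ``converged=False`` and a
    diagnostic message instead of silently returning garbage.
    """
    w = spectrum.wavelengths_nm
    mask = (w >= window.lo_nm) & (w <= window.hi_nm)
    x = w[mask]
    y = spectrum.intensity[mask]
    if x.size < 8:
        return PeakFit(window.channel_id, np.nan, np.nan, np.nan, np.nan,
                       False, np.nan, message="window contains < 8 samples")
    span = float(y.max() - y.min())
    if span <= 0:
        return PeakFit(window.channel_id, np.nan, np.nan, np.nan, np.nan,
                       False, float(np.sum((y - y.mean()) ** 2)),
                       message="flat window: no peak to fit")

    sigma0 = fwhm_to_sigma(fwhm_pm) / PM_PER_NM
    # np.argmax returns the first (smallest-wavelength) maximum on ties.
    p0 = [float(x[np.argmax(y)]), sigma0, span, float(y.min())]
    lo = [window.lo_nm, _SIGMA_LO_FACTOR * sigma0, 0.0, -np.inf]
    hi = [window.hi_nm, _SIGMA_HI_FACTOR * sigma0, np.inf, np.inf]
    p0[0] = min(max(p0[0], lo[0]), hi[0])
    try:
        popt, _ = curve_fit(
            _gaussian_baseline, x, y, p0=p0, bounds=(lo, hi), method="trf",
            xtol=_FIT_XTOL, ftol=_FIT_XTOL, gtol=_FIT_XTOL,
            max_nfev=_FIT_MAX_ITER * (len(p0) + 1),
        )
    except RuntimeError as exc:
        return PeakFit(window.channel_id, np.nan, np.nan, np.nan, np.nan,
                       False, np.nan, message=f"fit did not converge: {exc}")
    center, sigma, amplitude, baseline = (float(v) for v in popt)
    rss = float(np.sum((y - _gaussian_baseline(x, *popt)) ** 2))
    step_nm = spectrum.grid.step_nm
    if center - window.lo_nm < step_nm or window.hi_nm - center < step_nm:
        return PeakFit(window.channel_id, center, sigma, amplitude, baseline,
                       False, rss,
                       message="center estimate pinned at a window bound")
    if amplitude <= 0:
        return PeakFit(window.channel_id, center, sigma, amplitude, baseline,
                       False, rss, message="non-positive fitted amplitude")
    return PeakFit(window.channel_id, center, sigma, amplitude, baseline,
                   True, rss)


def extract_peaks(
    spectrum: Spectrum,
    channels: Sequence[BraggChannel],
    fwhm_pm: float = DEFAULT_FWHM_PM,
    windows: Optional[Sequence[ChannelWindow]] = None,
) -> list[PeakFit]:
    """Partition the spectrum and fit every channel, in channel order.

    Per-channel failures are reported in the returned :class:`PeakFit`
    objects without aborting the remaining channels.
    """
    if windows is None:
        windows = partition_windows(spectrum, channels, n_channels=len(channels))
    by_id = {win.channel_id: win for win in windows}
    fits = [
        fit_gaussian_peak(spectrum, by_id[ch.channel_id], fwhm_pm=fwhm_pm)
        for ch in sorted(channels, key=lambda c: c.channel_id)
    ]
    return fits


def compute_shifts(
    reference: Sequence[PeakFit], pressed: Sequence[PeakFit]
) -> ShiftVector:
    """Bragg shifts (pressed minus reference fitted centers) in pm.

    The summed-shift statistic needs all channels, so a single unconverged
    fit on either side refuses the whole point.  Negative values are
    blue-shifts (compressive strain), positive are red-shifts (tensile).
    """
    ref_ids = tuple(f.channel_id for f in reference)
    prs_ids = tuple(f.channel_id for f in pressed)
    if ref_ids != prs_ids:
        raise ShiftError(
            f"channel ids do not match: reference {ref_ids} vs pressed {prs_ids}"
        )
    bad = [f.channel_id for f in (*reference, *pressed) if not f.converged]
    if bad:
        raise ShiftError(
            "cannot compute shifts: unconverged fit on channel(s) "
            f"{sorted(set(bad))}"
        )
    shifts = tuple(
        (p.center_nm - r.center_nm) * PM_PER_NM
        for r, p in zip(reference, pressed)
    )
    return ShiftVector(channel_ids=ref_ids, shifts_pm=shifts)


def localization_error_study(
    n_trials: int = 1000,
    sigma_rel: float = 0.01,
    seed: int = 0,
    fwhm_pm: float = DEFAULT_FWHM_PM,
    step_pm: float = 2.0,
    amplitude: float = 1.0,
    baseline: float = 0.05,
    window_halfwidth_nm: float = 1.0,
) -> np.ndarray:
    """Monte-Carlo study of the Bragg-center estimator at the hardware grid.

    Each trial synthesizes a single Gaussian peak (height ``amplitude`` on a
    constant ``baseline``) whose true center is drawn uniformly off-grid
    (within one grid cell of the window center), samples it at ``step_pm``,
    adds white noise with standard deviation ``sigma_rel * amplitude``, fits
    the Gaussian-plus-baseline model, and records |fitted - true| in pm.

    Returns the array of absolute center errors; its 95th percentile is the
    sub-resolution localization figure of merit.  Note the information-
    theoretic floor: at these defaults the Cramér-Rao bound for the center
    is ~0.076 pm, so the 95th-percentile error cannot fall below ~0.15 pm
    for any unbiased estimator — quieter spectra or narrower peaks are
    needed to push it further down.
    """
    from .spectra import BraggChannel, NoiseModel, WavelengthGrid, synth_spectrum

    rng = np.random.default_rng(seed)
    center0 = 1540.0
    n_points = int(round(2 * window_halfwidth_nm / (step_pm / PM_PER_NM))) + 1
    grid = WavelengthGrid(start_nm=center0 - window_halfwidth_nm,
                          step_pm=step_pm, n_points=n_points)
    channel = BraggChannel(channel_id=1, nominal_center_nm=center0,
                           azimuth_deg=0.0, reflectivity=min(amplitude, 1.0))
    window = ChannelWindow(1, grid.span_nm[0], grid.span_nm[1])
    noise = NoiseModel(sigma_rel=sigma_rel)

    errors = np.empty(n_trials)
    for i in range(n_trials):
        true = center0 + rng.uniform(-1.0, 1.0) * step_pm / PM_PER_NM
        spec = synth_spectrum([channel], [true], grid, noise=noise,
                              fwhm_pm=fwhm_pm, baseline=baseline, rng=rng)
        fit = fit_gaussian_peak(spec, window, fwhm_pm=fwhm_pm)
        if not fit.converged:
            errors[i] = np.inf  # count failures against the estimator
        else:
            errors[i] = abs(fit.center_nm - true) * PM_PER_NM
    return errors
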