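"""Forward simulator of palpation sessions over a tissue phantom.

The phantom is a rectangular patch of soft tissue (default 40 mm x 40 mm,
mirroring the marked liver area of the blade-under-parenchyma experiment)
with an optional rigid line-segment inclusion — a scalpel blade or stitching
needle slid underneath the surface.  A press at (x, y) produces a pair of
interrogation frames: a light-contact spectrum with every channel at its
nominal Bragg wavelength, and a pressed spectrum whose per-channel shifts
follow the probe's linear response,

    shift_pm(ch) = response_slope * press_depth * stimulus(x, y) * w_ch,

where ``stimulus`` is the local relative stiffness felt by the probe tip and
``w_ch`` is a signed direction weight: a centered press compresses all four
gratings equally (common blue-shift), while a press laterally offset from a
stiff inclusion splits the grating pair aligned with the offset into a
tensile (red-shifted) side facing the inclusion and compressive sides
elsewhere.  Side contact also attenuates the inclusion's contribution by
roughly an order of magnitude relative to pressing directly on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .mapping import PalpationPoint, PalpationSession, write_manifest
from .spectra import (
    DEFAULT_FWHM_PM,
    PM_PER_NM,
    BraggChannel,
    NoiseModel,
    Spectrum,
    WavelengthGrid,
    synth_spectrum,
    write_spectrum,
)

__all__ = [
    "Inclusion",
    "PhantomField",
    "PalpationProtocol",
    "local_stiffness",
    "simulate_press",
    "simulate_session",
    "lattice_points",
]


@dataclass(frozen=True)
class Inclusion:
    """Rigid line-segment inclusion under the phantom surface.

    ``half_width_mm`` is half the lateral footprint of the blade;
    ``stiffness_multiplier`` scales the background stiffness directly above
    it; ``depth_attenuation`` in (0, 1] discounts the contrast for deeper
    insertion; ``taper_mm`` is the width of the continuous linear taper from
    elevated to background stiffness at the footprint edge.
    """

    x0: float
    y0: float
    x1: float
    y1: float
    half_width_mm: float = 1.5
    stiffness_multiplier: float = 30.0
    depth_attenuation: float = 1.0
    taper_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.half_width_mm <= 0:
            raise ValueError("half_width_mm must be positive")
        if self.stiffness_multiplier <= 0:
            raise ValueError("stiffness_multiplier must be positive")
        if not 0 < self.depth_attenuation <= 1:
            raise ValueError("depth_attenuation must be in (0, 1]")
        if self.taper_mm < 0:
            raise ValueError("taper_mm must be >= 0")

    def distance_mm(self, x: float, y: float) -> float:
        """Distance from (x, y) to the inclusion axis segment."""
        p = np.array([x, y], dtype=float)
        a = np.array([self.x0, self.y0], dtype=float)
        b = np.array([self.x1, self.y1], dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        return float(np.linalg.norm(p - (a + t * ab)))

    def nearest_point(self, x: float, y: float) -> tuple[float, float]:
        p = np.array([x, y], dtype=float)
        a = np.array([self.x0, self.y0], dtype=float)
        b = np.array([self.x1, self.y1], dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        q = a + t * ab
        return float(q[0]), float(q[1])

    def centroid(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)


@dataclass(frozen=True)
class PhantomField:
    """2D relative-stiffness field of the tissue phantom."""

    roi: tuple[float, float] = (40.0, 40.0)
    background_stiffness: float = 1.0
    inclusion: Optional[Inclusion] = None

    def __post_init__(self) -> None:
        if self.background_stiffness <= 0:
            raise ValueError("background_stiffness must be positive")
        if self.inclusion is not None:
            w, h = self.roi
            for (x, y) in [(self.inclusion.x0, self.inclusion.y0),
                           (self.inclusion.x1, self.inclusion.y1)]:
                if not (0 <= x <= w and 0 <= y <= h):
                    raise ValueError(
                        f"inclusion endpoint ({x}, {y}) outside ROI {w} x {h} mm"
                    )

    def contains(self, x: float, y: float) -> bool:
        w, h = self.roi
        return 0 <= x <= w and 0 <= y <= h


def local_stiffness(field: PhantomField, x: float, y: float) -> float:
    """Relative stiffness of the phantom surface at (x, y).

    Background value away from the inclusion; directly over the inclusion
    footprint the value is ``background * multiplier * depth_attenuation``,
    with a continuous linear taper back to background over ``taper_mm`` at
    the footprint edge.
    """
    if not field.contains(x, y):
        raise ValueError(f"point ({x}, {y}) outside ROI {field.roi} mm")
    bg = field.background_stiffness
    inc = field.inclusion
    if inc is None:
        return bg
    d = inc.distance_mm(x, y)
    elevated = bg * inc.stiffness_multiplier * inc.depth_attenuation
    if d <= inc.half_width_mm:
        return elevated
    if inc.taper_mm > 0 and d < inc.half_width_mm + inc.taper_mm:
        frac = (d - inc.half_width_mm) / inc.taper_mm
        return float(elevated + (bg - elevated) * frac)
    return bg


@dataclass
class PalpationProtocol:
    """How the probe is pressed over the phantom.

    ``press_depth_mm`` — indentation between the contact and pressed frames
    (the device limits it mechanically to 2 mm).  ``response_slope`` — pm of
    per-channel Bragg shift per mm of indentation per unit relative
    stiffness; the default 5 pm/mm puts a 2 mm press on background tissue at
    10 pm per channel, far above the localization floor and far below the
    large-deformation (nm-scale) regime.  ``side_contact_attenuation`` — the
    fraction of the inclusion's elevated response that is felt when pressing
    beside it rather than on it (default 0.1: direct contact is an order of
    magnitude stronger).  ``influence_radius_mm`` bounds how far that side
    influence reaches.
    """

    points: list[tuple[float, float]] = field(default_factory=list)
    press_depth_mm: float = 2.0
    response_slope: float = 5.0
    side_contact_attenuation: float = 0.1
    influence_radius_mm: float = 6.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.press_depth_mm < 0:
            raise ValueError("press_depth_mm must be >= 0")
        if self.response_slope <= 0:
            raise ValueError("response_slope must be positive")
        if not 0 < self.side_contact_attenuation <= 1:
            raise ValueError("side_contact_attenuation must be in (0, 1]")


def lattice_points(
    roi: tuple[float, float], nx: int, ny: int, margin_mm: float = 4.0
) -> list[tuple[float, float]]:
    """Regular nx x ny press lattice inside the ROI, row-major order."""
    xs = np.linspace(margin_mm, roi[0] - margin_mm, nx)
    ys = np.linspace(margin_mm, roi[1] - margin_mm, ny)
    return [(float(x), float(y)) for y in ys for x in xs]


def _direction_weights(
    field: PhantomField,
    protocol: PalpationProtocol,
    channels: Sequence[BraggChannel],
    x: float,
    y: float,
) -> tuple[float, np.ndarray]:
    """Stimulus magnitude and per-channel signed weights for one press.

    Returns ``(stimulus, weights)`` with ``weights`` in channel order,
    -1 = compression (blue-shift), +1 = tension (red-shift).
    """
    bg = field.background_stiffness
    inc = field.inclusion
    n = len(channels)
    compressive = -np.ones(n)

    if inc is None:
        return local_stiffness(field, x, y), compressive

    d = inc.distance_mm(x, y)
    direct_limit = inc.half_width_mm + inc.taper_mm
    if d <= direct_limit:
        # pressing (at least partly) on the inclusion: uniform compression
        return local_stiffness(field, x, y), compressive
    if d <= protocol.influence_radius_mm:
        # side contact: the inclusion is felt laterally, strongly attenuated;
        # the stimulus is whichever dominates — the tissue under the tip or
        # the attenuated inclusion response.
        elevated = bg * inc.stiffness_multiplier * inc.depth_attenuation
        stimulus = max(bg, elevated * protocol.side_contact_attenuation)
        qx, qy = inc.nearest_point(x, y)
        u = np.array([qx - x, qy - y], dtype=float)
        norm = np.linalg.norm(u)
        weights = compressive.copy()
        if norm > 0:
            u /= norm
            for i, ch in enumerate(channels):
                az = np.deg2rad(ch.azimuth_deg)
                a = np.array([np.cos(az), np.sin(az)])
                if float(a @ u) >= 0.5:
                    weights[i] = 1.0  # grating facing the inclusion: tensile
        return stimulus, weights
    return local_stiffness(field, x, y), compressive


def simulate_press(
    field: PhantomField,
    protocol: PalpationProtocol,
    channels: Sequence[BraggChannel],
    grid: WavelengthGrid,
    noise: Optional[NoiseModel],
    x: float,
    y: float,
    fwhm_pm: float = DEFAULT_FWHM_PM,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Spectrum, Spectrum]:
    """Simulate one palpation point: (contact, pressed) spectrum pair.

    The contact frame has every channel at its nominal Bragg wavelength
    (light contact, no strain); the pressed frame applies the linear shift
    model.  Independent noise realizations are drawn for the two frames.
    """
    if not field.contains(x, y):
        raise ValueError(f"press point ({x}, {y}) outside ROI {field.roi} mm")
    if protocol.press_depth_mm < 0:
        raise ValueError("press_depth_mm must be >= 0")
    ordered = sorted(channels, key=lambda c: c.channel_id)
    nominal = [ch.nominal_center_nm for ch in ordered]

    stimulus, weights = _direction_weights(field, protocol, ordered, x, y)
    shift_pm = protocol.response_slope * protocol.press_depth_mm * stimulus * weights
    pressed_centers = [c + s / PM_PER_NM for c, s in zip(nominal, shift_pm)]

    if rng is None and noise is not None:
        rng = noise.rng()
    contact = synth_spectrum(ordered, nominal, grid, noise=noise,
                             fwhm_pm=fwhm_pm, rng=rng)
    pressed = synth_spectrum(ordered, pressed_centers, grid, noise=noise,
                             fwhm_pm=fwhm_pm, rng=rng)
    return contact, pressed


def simulate_session(
    field: PhantomField,
    protocol: PalpationProtocol,
    channels: Sequence[BraggChannel],
    grid: WavelengthGrid,
    noise: Optional[NoiseModel] = None,
    out_dir=None,
    session_id: str = "sim",
    fwhm_pm: float = DEFAULT_FWHM_PM,
) -> tuple[PalpationSession, dict[str, tuple[Spectrum, Spectrum]]]:
    """Simulate a full palpation session over the phantom.

    One contact/pressed spectrum pair is produced per protocol point, fully
    reproducible from ``protocol.seed`` (per-point noise streams are spawned
    from one seed sequence, so the session is deterministic regardless of
    chunking).  When ``out_dir`` is given, spectra are written as columnar
    text files and a JSON manifest ties them together; the returned dict
    maps point ids to the in-memory pairs either way.
    """
    if len(protocol.points) < 1:
        raise ValueError("protocol has no press points")
    seq = np.random.SeedSequence(protocol.seed)
    streams = [np.random.default_rng(s) for s in seq.spawn(len(protocol.points))]

    out = None if out_dir is None else Path(out_dir)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    points: list[PalpationPoint] = []
    spectra: dict[str, tuple[Spectrum, Spectrum]] = {}
    for i, ((x, y), rng) in enumerate(zip(protocol.points, streams)):
        pid = f"p{i + 1:03d}"
        contact, pressed = simulate_press(
            field, protocol, channels, grid, noise, x, y,
            fwhm_pm=fwhm_pm, rng=rng,
        )
        contact_name = f"{pid}_contact.csv"
        pressed_name = f"{pid}_pressed.csv"
        if out is not None:
            write_spectrum(contact, out / contact_name)
            write_spectrum(pressed, out / pressed_name)
        spectra[pid] = (contact, pressed)
        points.append(PalpationPoint(
            point_id=pid, x_rel=x, y_rel=y,
            contact_spectrum=contact_name, pressed_spectrum=pressed_name,
            order=i,
        ))

    session = PalpationSession(session_id=session_id, roi=field.roi, points=points)
    if out is not None:
        write_manifest(session, out / "manifest.json")
        meta = {"seed": protocol.seed, "press_depth_mm": protocol.press_depth_mm,
                "response_slope": protocol.response_slope}
        with open(out / "session_meta.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)
    return session, spectra
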