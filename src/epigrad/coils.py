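"""Gradient-coil and EPI-protocol data types, presets and trapezoid algebra.

A gradient coil is characterised here by the limits that matter for pulse
sequence timing: the absolute amplitude ceiling ``g_abs_max`` (reachable for
short, low-duty-cycle pulses such as diffusion lobes), the duty-cycle-limited
nominal amplitude ``g_nom_max`` that can be sustained through an EPI readout
train, the slew-rate limit ``sr_max``, and the echo-spacing intervals that
are excluded to avoid mechanical resonances of the coil former.

Three presets ship with the package:

========  =========  =========  ========  =====================
name      g_abs_max  g_nom_max  sr_max    forbidden ES bands
========  =========  =========  ========  =====================
impulse   200        85         900       0.82-0.92, 0.46-0.48,
                                          0.35-0.36, 0.26 ms
ac84      80         50         333       none
xr_body   80         40         200       none
========  =========  =========  ========  =====================

Units: amplitudes in mT/m, slew in T/m/s (numerically equal to mT/m per ms),
times in ms, gradient areas in (mT/m)*ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "GAMMA_HZ_PER_T",
    "GradientCoilSpec",
    "EPIProtocol",
    "TrapezoidPulse",
    "load_coil_preset",
    "trapezoid_for_area",
]

#: Proton gyromagnetic ratio, gamma-bar, in Hz/T.
GAMMA_HZ_PER_T = 42.576e6

#: Allowed partial-Fourier fractions.
_PF_ALLOWED = (1.0, 7 / 8, 6 / 8, 5 / 8)


@dataclass(frozen=True)
class GradientCoilSpec:
    """Timing-relevant limits of one gradient coil.

    Parameters
    ----------
    name : str
        Identifier (preset name or user label).
    g_abs_max : float
        Absolute amplitude limit in mT/m; governs short low-duty-cycle
        pulses (diffusion encoding lobes).
    g_nom_max : float
        Duty-cycle-limited nominal amplitude in mT/m usable in sustained
        EPI readouts.
    sr_max : float
        Slew-rate limit in T/m/s.
    forbidden_es_bands : tuple of (float, float)
        Closed echo-spacing intervals in ms that the scanner excludes to
        avoid mechanical resonances.  A degenerate band (lo == hi) marks a
        single excluded echo spacing.
    sensitivity : float, optional
        Gradient field per unit current, mT/m/A (metadata only).
    linearity_pct : tuple of float, optional
        Per-axis deviation from linearity on a 20 cm sphere, in percent
        (metadata only).
    """

    name: str
    g_abs_max: float
    g_nom_max: float
    sr_max: float
    forbidden_es_bands: tuple = ()
    sensitivity: float | None = None
    linearity_pct: tuple | None = None

    def __post_init__(self):
        if not (0 < self.g_nom_max <= self.g_abs_max):
            raise ValueError(
                f"require 0 < g_nom_max <= g_abs_max, got "
                f"g_nom_max={self.g_nom_max}, g_abs_max={self.g_abs_max}"
            )
        if self.sr_max <= 0:
            raise ValueError(f"sr_max must be positive, got {self.sr_max}")
        bands = tuple(tuple(float(x) for x in b) for b in self.forbidden_es_bands)
        for lo, hi in bands:
            if lo > hi:
                raise ValueError(f"forbidden band has lower bound > upper: ({lo}, {hi})")
        for (lo1, hi1), (lo2, hi2) in zip(sorted(bands), sorted(bands)[1:]):
            if hi1 >= lo2 and not (hi1 == lo2 == hi2):
                raise ValueError("forbidden bands must be disjoint")
        object.__setattr__(self, "forbidden_es_bands", bands)

    @property
    def slew_mT_per_m_per_ms(self) -> float:
        """Slew limit in mT/m per ms (numerically equal to T/m/s)."""
        return self.sr_max


@dataclass(frozen=True)
class EPIProtocol:
    """Requested EPI acquisition geometry.

    ``matrix_n`` is the phase/read matrix size; ``grappa_r`` the in-plane
    parallel-imaging acceleration; ``segments`` the number of in-plane
    shots; ``sms_factor`` the simultaneous-multislice factor (carried for
    bookkeeping, it does not change in-plane timing).
    """

    resolution: float  # mm in-plane
    fov: float  # mm
    matrix_n: int
    grappa_r: int = 1
    partial_fourier: float = 1.0
    sms_factor: int = 1
    segments: int = 1
    pe_axis: str = "AP"

    def __post_init__(self):
        if self.resolution <= 0 or self.fov <= 0 or self.matrix_n <= 0:
            raise ValueError("resolution, fov and matrix_n must be positive")
        if abs(self.matrix_n * self.resolution - self.fov) > self.resolution:
            raise ValueError(
                f"matrix_n*resolution = {self.matrix_n * self.resolution:.2f} mm "
                f"disagrees with fov = {self.fov} mm by more than one voxel"
            )
        if not 0.5 < self.partial_fourier <= 1.0:
            raise ValueError(f"partial_fourier must lie in (0.5, 1], got {self.partial_fourier}")
        if self.grappa_r < 1 or self.segments < 1 or self.sms_factor < 1:
            raise ValueError("grappa_r, segments and sms_factor must be >= 1")

    @classmethod
    def from_resolution(cls, resolution, fov, **kw) -> "EPIProtocol":
        """Build a protocol with matrix_n = round(fov / resolution)."""
        n = int(round(fov / resolution))
        return cls(resolution=fov / n, fov=fov, matrix_n=n, **kw)

    @property
    def in_plane_acceleration(self) -> int:
        return self.grappa_r * self.segments

    def readout_kspace_area(self) -> float:
        """Gradient area of one readout line in (mT/m)*ms.

        The k-space width to traverse per line is matrix_n / FOV (cycles/m);
        dividing by gamma-bar gives the gradient-time integral.
        """
        fov_m = self.fov * 1e-3
        area_T_s_per_m = self.matrix_n / (fov_m * GAMMA_HZ_PER_T)
        return area_T_s_per_m * 1e6  # T*s/m -> (mT/m)*ms


@dataclass(frozen=True)
class TrapezoidPulse:
    """Symmetric trapezoidal (or triangular) gradient lobe.

    ``area`` is the exact time integral amplitude * (flat + ramp) in
    (mT/m)*ms; for a triangle flat == 0.
    """

    amplitude: float  # mT/m
    ramp_ms: float
    flat_ms: float

    def __post_init__(self):
        if self.amplitude < 0 or self.ramp_ms < 0 or self.flat_ms < 0:
            raise ValueError("trapezoid parameters must be non-negative")

    @property
    def area(self) -> float:
        return self.amplitude * (self.flat_ms + self.ramp_ms)

    @property
    def duration_ms(self) -> float:
        return self.flat_ms + 2.0 * self.ramp_ms

    @property
    def slew(self) -> float:
        """Ramp slew rate in T/m/s (= mT/m/ms)."""
        if self.ramp_ms == 0:
            return 0.0
        return self.amplitude / self.ramp_ms

    def samples(self, raster_us: float = 1.0):
        """Amplitude samples on a uniform raster (for numeric checks)."""
        import numpy as np

        dt = raster_us * 1e-3
        t = np.arange(0.0, self.duration_ms + dt, dt)
        up = np.clip(t / max(self.ramp_ms, dt * 1e-6), 0, 1)
        down = np.clip((self.duration_ms - t) / max(self.ramp_ms, dt * 1e-6), 0, 1)
        return t, self.amplitude * np.minimum(up, down)


def trapezoid_for_area(
    target_area: float,
    coil: GradientCoilSpec,
    use_abs_limit: bool = False,
) -> TrapezoidPulse:
    """Shortest symmetric trapezoid achieving a gradient area under coil limits.

    The amplitude ceiling is ``g_nom_max`` (sustained EPI readout) unless
    ``use_abs_limit`` is set, in which case the short-pulse absolute limit
    ``g_abs_max`` applies (diffusion lobes).  When the required area is below
    the capacity of the slew-limited triangle the result is a triangle with
    peak sqrt(area * slew); timing is continuous (no raster rounding).

    Parameters
    ----------
    target_area : float
        Required area in (mT/m)*ms, > 0.
    """
    if target_area <= 0:
        raise ValueError(f"target_area must be positive, got {target_area}")
    gmax = coil.g_abs_max if use_abs_limit else coil.g_nom_max
    slew = coil.slew_mT_per_m_per_ms
    triangle_capacity = gmax * gmax / slew  # area when ramps just meet gmax
    if target_area >= triangle_capacity:
        ramp = gmax / slew
        flat = target_area / gmax - ramp
        return TrapezoidPulse(amplitude=gmax, ramp_ms=ramp, flat_ms=flat)
    peak = math.sqrt(target_area * slew)
    return TrapezoidPulse(amplitude=peak, ramp_ms=peak / slew, flat_ms=0.0)


# ---------------------------------------------------------------------------
# preset loading / coil spec files

_PRESET_FILES = {"impulse": "impulse.cfg", "ac84": "ac84.cfg", "xr_body": "xr_body.cfg"}

_REQUIRED_KEYS = (
    "name",
    "g_abs_max_mT_per_m",
    "g_nom_max_mT_per_m",
    "sr_max_T_per_m_per_s",
)


def _parse_bands(text: str):
    bands = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            lo, hi = chunk.split("-")
        else:
            lo = hi = chunk
        bands.append((float(lo), float(hi)))
    return tuple(bands)


def _spec_from_text(text: str, source: str) -> GradientCoilSpec:
    kv = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed line in coil spec {source!r}: {line!r}")
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()
    for key in _REQUIRED_KEYS:
        if key not in kv:
            raise ValueError(f"coil spec {source!r} is missing required field {key!r}")
    lin = kv.get("linearity_pct")
    return GradientCoilSpec(
        name=kv["name"],
        g_abs_max=float(kv["g_abs_max_mT_per_m"]),
        g_nom_max=float(kv["g_nom_max_mT_per_m"]),
        sr_max=float(kv["sr_max_T_per_m_per_s"]),
        forbidden_es_bands=_parse_bands(kv.get("forbidden_es_bands_ms", "")),
        sensitivity=float(kv["sensitivity_mT_per_m_per_A"]) if "sensitivity_mT_per_m_per_A" in kv else None,
        linearity_pct=tuple(float(x) for x in lin.split(",")) if lin else None,
    )


def load_coil_preset(name: str) -> GradientCoilSpec:
    """Load a bundled coil preset or a user key/value spec file.

    ``name`` is one of ``impulse``, ``ac84``, ``xr_body``, or a path to a
    flat key/value file (see the bundled ``presets/*.cfg`` for the format).
    """
    if name in _PRESET_FILES:
        text = (resources.files("epigrad") / "presets" / _PRESET_FILES[name]).read_text()
        return _spec_from_text(text, name)
    path = Path(name)
    if path.is_file():
        return _spec_from_text(path.read_text(), str(path))
    raise KeyError(
        f"unknown coil preset {name!r}; expected one of {sorted(_PRESET_FILES)} "
        "or a path to a coil spec file"
    )
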