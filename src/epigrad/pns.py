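"""SAFE-style peripheral nerve stimulation (PNS) supervision of gradient
waveforms.

The supervision model filters the gradient slew rate of each axis through a
weighted chain of first-order low-pass stages, rectifies, combines the axes
by root sum of squares and compares the time-maximum to a rheobase-like
scale.  The result is expressed as a fraction of the first-level ceiling
Stimlim; the normal operating mode is capped at 0.8 x Stimlim (IEC
60601-2-33 wording).

The filter constants and rheobase that parameterise a real scanner derive
from volunteer stimulation studies and are not public.  The defaults here
are a documented placeholder calibration with the right qualitative
geometry: long-rise (slow) ramps are limited by amplitude, short-rise ramps
by the filtered slew; the 98 mT/m / 213 T/m/s / 0.92 ms bipolar readout
train evaluates as allowed while a 200 mT/m train at 900 T/m/s does not.
All parameters are user-replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "SAFEParams",
    "GradientWaveform",
    "safe_response",
    "operating_curve",
    "bipolar_readout_train",
    "trapezoid_waveform",
]


@dataclass(frozen=True)
class SAFEParams:
    """Filter chain and scaling of the PNS supervision model.

    ``filters`` is a tuple of (time constant in ms, weight) pairs applied
    to each axis' slew rate; ``rheobase`` (T/m/s) converts the filtered
    slew into units of Stimlim; ``stim_limit`` is the first-level ceiling
    (dimensionless, 1.0 by convention) and ``normal_mode_fraction`` the
    normal-mode cap, fixed at 0.8.
    """

    filters: tuple = ((1.0, 1.0),)
    rheobase: float = 120.0
    stim_limit: float = 1.0
    normal_mode_fraction: float = 0.8

    def __post_init__(self):
        if self.normal_mode_fraction != 0.8:
            raise ValueError("normal_mode_fraction is fixed at 0.8 by the IEC normal mode")
        for tau, w in self.filters:
            if tau <= 0 or w <= 0:
                raise ValueError("filter time constants and weights must be positive")
        if self.rheobase <= 0 or self.stim_limit <= 0:
            raise ValueError("rheobase and stim_limit must be positive")


@dataclass(frozen=True)
class GradientWaveform:
    """Per-axis gradient amplitude samples (mT/m) on a uniform us raster."""

    samples: np.ndarray  # shape (n, n_axes)
    raster_us: float = 10.0

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if s.shape[0] == 1 and s.shape[1] > 3:
            s = s.T
        if not np.all(np.isfinite(s)):
            raise ValueError("waveform samples must be finite")
        if self.raster_us <= 0:
            raise ValueError("raster_us must be positive")
        object.__setattr__(self, "samples", s)

    def slew(self) -> np.ndarray:
        """Per-sample slew rate in T/m/s (= mT/m per ms)."""
        return np.diff(self.samples, axis=0) / (self.raster_us * 1e-3)

    def check_coil(self, coil) -> None:
        peak = np.abs(self.slew()).max() if self.samples.shape[0] > 1 else 0.0
        if peak > coil.slew_mT_per_m_per_ms * (1 + 1e-9):
            raise ValueError(
                f"waveform slew {peak:.1f} T/m/s exceeds coil limit {coil.sr_max}"
            )


def safe_response(w: GradientWaveform, p: SAFEParams | None = None) -> float:
    """Peak stimulation of a waveform as a fraction of Stimlim.

    Per axis the slew rate is passed through the weighted first-order
    low-pass chain (zero initial state) and rectified; axes combine by
    root sum of squares and the time-maximum, scaled by the rheobase,
    is returned in units of Stimlim.  The pipeline is positively
    homogeneous and invariant to time shifts.
    """
    p = p or SAFEParams()
    if w.samples.shape[0] < 2:
        return 0.0
    dt = w.raster_us * 1e-3  # ms
    slew = w.slew()  # (n-1, axes)
    filtered = np.zeros_like(slew)
    for tau, weight in p.filters:
        a = np.exp(-dt / tau)
        filtered += weight * lfilter([1.0 - a], [1.0, -a], slew, axis=0)
    stim = np.sqrt((np.abs(filtered) ** 2).sum(axis=1))
    return float(stim.max() / (p.rheobase * p.stim_limit))


def operating_curve(
    p: SAFEParams,
    rise_times_ms,
    coil=None,
    raster_us: float = 2.0,
    tol: float = 1e-3,
):
    """Maximum normal-mode trapezoid amplitude versus rise time.

    For each rise time, bisects the amplitude of a single trapezoidal pulse
    (equal rise and fall, short flat top) until its response reaches the
    normal-mode cap 0.8 x Stimlim.  If a coil is given the amplitude is
    additionally capped by its absolute limit and the rise time must be
    slew-feasible.  Returns a list of (rise_time_ms, amplitude_mT_per_m);
    the curve is non-decreasing in rise time.
    """
    out = []
    target = p.normal_mode_fraction * p.stim_limit
    for tr in rise_times_ms:
        if tr <= 0:
            raise ValueError("rise times must be positive")
        amp_cap = np.inf
        if coil is not None:
            amp_cap = min(coil.g_abs_max, coil.slew_mT_per_m_per_ms * tr)

        def resp(amp: float) -> float:
            return safe_response(trapezoid_waveform(amp, tr, flat_ms=0.2,
                                                    raster_us=raster_us), p)

        # response is linear in amplitude (positive homogeneity), so one
        # evaluation fixes the scale; bisection kept for model generality
        lo, hi = 0.0, 1.0
        while resp(hi) < target and hi < 1e7:
            lo, hi = hi, hi * 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if resp(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo <= tol * max(hi, 1.0):
                break
        out.append((float(tr), float(min(0.5 * (lo + hi), amp_cap))))
    return out


# ---------------------------------------------------------------------------
# waveform builders


def trapezoid_waveform(
    amplitude: float, ramp_ms: float, flat_ms: float = 0.0,
    raster_us: float = 2.0, axis: int = 0, n_axes: int = 3,
    pad_ms: float = 2.0,
) -> GradientWaveform:
    """Single trapezoidal pulse on one axis, zero-padded at both ends."""
    dt = raster_us * 1e-3
    t = np.arange(0.0, 2 * ramp_ms + flat_ms + dt / 2, dt)
    up = np.clip(t / ramp_ms, 0, 1)
    down = np.clip((t[-1] - t) / ramp_ms, 0, 1)
    g = amplitude * np.minimum(up, down)
    npad = int(round(pad_ms / dt))
    g = np.concatenate([np.zeros(npad), g, np.zeros(npad)])
    out = np.zeros((g.size, n_axes))
    out[:, axis] = g
    return GradientWaveform(out, raster_us=raster_us)


def bipolar_readout_train(
    amplitude: float, slew: float, es_ms: float, n_lobes: int = 32,
    raster_us: float = 2.0, axis: int = 0, n_axes: int = 3,
) -> GradientWaveform:
    """Alternating-polarity EPI readout train.

    Each lobe lasts one echo spacing: ramp at ``slew`` (T/m/s) to
    +/-``amplitude`` (mT/m), hold, ramp to the opposite polarity.  Raises
    if the requested amplitude cannot be reached within one echo spacing.
    """
    ramp = amplitude / slew  # ms, 0 -> amp
    if 2 * ramp > es_ms * 1.01:  # 1% slack for rounded print-precision inputs
        raise ValueError("amplitude unreachable within one echo spacing at this slew")
    dt = raster_us * 1e-3
    n_per = int(round(es_ms / dt))
    g_prev = 0.0
    sign = 1.0
    parts = [np.zeros(int(round(1.0 / dt)))]
    for _ in range(n_lobes):
        target = sign * amplitude
        t = (np.arange(n_per) + 1) * dt
        ramp_dur = abs(target - g_prev) / slew
        lobe = np.where(
            t < ramp_dur,
            g_prev + np.sign(target - g_prev) * slew * t,
            target,
        )
        parts.append(lobe)
        g_prev = float(lobe[-1])
        sign = -sign
    # ramp back to zero
    t = (np.arange(int(np.ceil(abs(g_prev) / slew / dt)) + 1) + 1) * dt
    parts.append(np.clip(np.abs(g_prev) - slew * t, 0, None) * np.sign(g_prev))
    g = np.concatenate(parts)
    out = np.zeros((g.size, n_axes))
    out[:, axis] = g
    return GradientWaveform(out, raster_us=raster_us)
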