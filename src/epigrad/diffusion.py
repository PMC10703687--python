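"""Stejskal-Tanner diffusion-encoding timing for monopolar trapezoidal
pulsed-gradient spin echo (PGSE).

For a pair of trapezoidal lobes of amplitude G, flat-top-plus-one-ramp
duration delta, ramp time eps and leading-edge separation Delta, the
b-value is

    b = gamma^2 G^2 [ delta^2 (Delta - delta/3) + eps^3/30 - delta eps^2/6 ]

(s/mm^2 with G in T/m, times in s), reducing to the rectangular
gamma^2 G^2 delta^2 (Delta - delta/3) as eps -> 0.  At constant b the
b = G^2 t^3 scaling means the encoding time shrinks by g_ratio^(-2/3) when
the amplitude grows by g_ratio.

``min_te_pgse`` packs the two lobes symmetrically against the refocusing
pulse (diffusion lobes run at the coil's absolute amplitude limit: encoding
is low duty cycle) and solves for the smallest delta reaching a target b by
bisection; TE = refocus + 2 * (lobe duration + readout-to-centre time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .coils import GradientCoilSpec

__all__ = ["PGSEParams", "b_value", "encoding_time_factor", "min_te_pgse",
           "GAMMA_RAD_PER_S_PER_T"]

GAMMA_RAD_PER_S_PER_T = 2.6752218744e8


@dataclass(frozen=True)
class PGSEParams:
    """Monopolar PGSE lobe geometry.

    delta_ms is the Stejskal-Tanner lobe duration (flat top + one ramp);
    Delta_ms the separation of the two lobes' leading edges; the physical
    duration of one lobe is delta + ramp.
    """

    g_amp: float  # mT/m
    delta_ms: float
    Delta_ms: float
    ramp_ms: float = 0.0
    b: float | None = None  # s/mm^2, filled in by b_value / min_te_pgse
    gamma: float = GAMMA_RAD_PER_S_PER_T

    def __post_init__(self):
        if self.Delta_ms < self.delta_ms:
            raise ValueError(
                f"Delta ({self.Delta_ms} ms) must be >= delta ({self.delta_ms} ms)"
            )
        if self.delta_ms <= 0 or self.ramp_ms < 0 or self.g_amp < 0:
            raise ValueError("delta must be > 0; ramp and amplitude >= 0")
        if self.b is not None:
            stated = self.b
            computed = b_value(replace(self, b=None))
            if stated < 0 or (computed > 0 and abs(stated - computed) > 1e-3 * computed):
                raise ValueError(
                    f"stated b = {stated} disagrees with computed {computed:.4f} s/mm^2"
                )

    @property
    def lobe_duration_ms(self) -> float:
        return self.delta_ms + self.ramp_ms


def b_value(params: PGSEParams) -> float:
    """Diffusion weighting b in s/mm^2 for trapezoidal monopolar PGSE."""
    G = params.g_amp * 1e-3  # T/m
    d = params.delta_ms * 1e-3
    D = params.Delta_ms * 1e-3
    e = params.ramp_ms * 1e-3
    b_s_per_m2 = (params.gamma ** 2) * (G ** 2) * (
        d * d * (D - d / 3.0) + e ** 3 / 30.0 - d * e * e / 6.0
    )
    return b_s_per_m2 * 1e-6  # s/m^2 -> s/mm^2


def encoding_time_factor(g_ratio: float) -> float:
    """Encoding-time shrink factor at constant b: g_ratio^(-2/3)."""
    if g_ratio <= 0:
        raise ValueError("g_ratio must be positive")
    return g_ratio ** (-2.0 / 3.0)


def min_te_pgse(
    b_target: float,
    coil: GradientCoilSpec,
    readout_to_center_ms: float = 8.0,
    refocus_ms: float = 7.0,
    tol: float = 1e-6,
) -> tuple[PGSEParams, float]:
    """Smallest TE whose packed symmetric lobes reach a target b-value.

    Lobes run at ``coil.g_abs_max`` with the steepest ramps the coil
    allows, sit immediately before and after the refocusing pulse
    (Delta = delta + ramp + refocus), and the echo centre follows the
    second lobe by ``readout_to_center_ms``.  Spin-echo symmetry then gives

        TE = refocus + 2 * (delta + ramp + readout_to_center).

    Returns the lobe parameters (with b filled in) and TE in ms.  The
    printed TE should be read as a model quantity: overheads such as fat
    saturation are not included, so cross-coil TE ratios are diluted
    relative to the asymptotic g_ratio^(-2/3) law by the fixed overheads.
    """
    if b_target <= 0:
        raise ValueError("b_target must be positive")
    if readout_to_center_ms < 0 or refocus_ms < 0:
        raise ValueError("overhead times must be >= 0")
    G = coil.g_abs_max
    slew = coil.slew_mT_per_m_per_ms

    def lobe(duration_ms: float) -> PGSEParams:
        # trapezoid at the absolute amplitude limit once the duration
        # allows it, slew-limited triangle below
        if duration_ms >= 2.0 * G / slew:
            amp, ramp = G, G / slew
        else:
            ramp = duration_ms / 2.0
            amp = slew * ramp
        delta = duration_ms - ramp
        return PGSEParams(g_amp=amp, delta_ms=delta,
                          Delta_ms=delta + ramp + refocus_ms, ramp_ms=ramp)

    def b_of(duration_ms: float) -> float:
        return b_value(lobe(duration_ms))

    lo, hi = 1e-9, 1.0
    while b_of(hi) < b_target:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("infeasible geometry: b_target unreachable")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if b_of(mid) < b_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    params = lobe(hi)
    params = replace(params, b=b_value(params))
    te = refocus_ms + 2.0 * (params.lobe_duration_ms + readout_to_center_ms)
    return params, te
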