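"""EPI readout timing: echo spacing, echo train, minimum TE, and the
inverse problem of the finest resolution reachable at a target TE.

Model
-----
The readout is ramp-sampled: the ADC is active over the ramps, so one echo
spacing is the full duration of the minimal readout trapezoid (at the
duty-cycle nominal amplitude) plus a fixed per-echo dead time (default
30 us) covering phase-encode blips and ADC gaps.  Echo spacings that fall
inside a coil's forbidden mechanical-resonance band are bumped to the upper
band edge, mirroring scanner practice, and flagged.

The echo train covers matrix_n * partial_fourier k-space lines in steps of
grappa_r * segments lines per echo (ceil at every division).  The k-space
centre is reached after ceil(matrix_n * (partial_fourier - 1/2) /
(grappa_r * segments)) echoes, so

    TE_min = pre_readout + echoes_before_center * ES,

with a fixed pre-readout time (default 1.3 ms: excitation half-duration
plus phase pre-winders).  Timing is continuous; an optional raster mode
rounds the echo spacing up to a gradient raster for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .coils import EPIProtocol, GradientCoilSpec, trapezoid_for_area

__all__ = ["EPITiming", "min_echo_spacing", "min_te", "achievable_resolution"]

DEFAULT_OVERHEAD_US = 30.0
DEFAULT_PRE_TIME_MS = 1.3


@dataclass(frozen=True)
class EPITiming:
    """Derived timing of an EPI readout train.

    ``es_eff_ms`` is the effective phase-encode dwell es / (grappa_r *
    segments) that governs distortion; ``bw_per_pixel_hz`` the read-axis
    bandwidth per pixel, approximately 1/es.
    """

    es_ms: float
    es_eff_ms: float
    bw_per_pixel_hz: float
    n_echoes: int
    echoes_before_center: int
    train_ms: float
    te_min_ms: float
    es_bumped: bool = False  # echo spacing was raised out of a forbidden band

    def __post_init__(self):
        if self.te_min_ms + 1e-9 < self.echoes_before_center * self.es_ms:
            raise ValueError("te_min_ms implies negative pre-readout time")
        if abs(self.train_ms - self.n_echoes * self.es_ms) > 1e-9 * max(1.0, self.train_ms):
            raise ValueError("train_ms must equal n_echoes * es_ms")


def min_echo_spacing(
    protocol: EPIProtocol,
    coil: GradientCoilSpec,
    overhead_us: float = DEFAULT_OVERHEAD_US,
    raster_us: float | None = None,
    return_flag: bool = False,
):
    """Minimum echo spacing in ms for a protocol under a coil's limits.

    The readout trapezoid must traverse matrix_n / (FOV * gamma-bar) of
    gradient area at the nominal (duty-cycle) amplitude; its duration plus
    the per-echo dead time is the echo spacing.  If the result falls inside
    a forbidden echo-spacing band it is bumped to the band's upper edge.

    With ``return_flag=True`` returns ``(es_ms, bumped)``.
    """
    if overhead_us < 0:
        raise ValueError("overhead_us must be >= 0")
    pulse = trapezoid_for_area(protocol.readout_kspace_area(), coil)
    es = pulse.duration_ms + overhead_us * 1e-3
    if raster_us:
        es = math.ceil(es / (raster_us * 1e-3) - 1e-12) * raster_us * 1e-3
    bumped = False
    for lo, hi in coil.forbidden_es_bands:
        if lo <= es <= hi:
            es = hi
            bumped = True
            break
    return (es, bumped) if return_flag else es


def min_te(
    protocol: EPIProtocol,
    coil: GradientCoilSpec,
    pre_time_ms: float = DEFAULT_PRE_TIME_MS,
    overhead_us: float = DEFAULT_OVERHEAD_US,
    raster_us: float | None = None,
) -> EPITiming:
    """Minimum TE and full echo-train structure for a protocol."""
    if protocol.partial_fourier <= 0.5:
        raise ValueError("partial_fourier must exceed 1/2")
    es, bumped = min_echo_spacing(
        protocol, coil, overhead_us=overhead_us, raster_us=raster_us, return_flag=True
    )
    acc = protocol.in_plane_acceleration
    n = protocol.matrix_n
    # 1e-9 guard so float representation of exact fractions does not bump
    # the ceil to the next echo
    echoes_before_center = math.ceil(n * (protocol.partial_fourier - 0.5) / acc - 1e-9)
    n_echoes = math.ceil(n * protocol.partial_fourier / acc - 1e-9)
    te = pre_time_ms + echoes_before_center * es
    return EPITiming(
        es_ms=es,
        es_eff_ms=es / acc,
        bw_per_pixel_hz=1e3 / es,
        n_echoes=n_echoes,
        echoes_before_center=echoes_before_center,
        train_ms=n_echoes * es,
        te_min_ms=te,
        es_bumped=bumped,
    )


def achievable_resolution(
    coil: GradientCoilSpec,
    te_target_ms: float,
    fov_mm: float,
    grappa_r: int = 1,
    partial_fourier: float = 1.0,
    segments: int = 1,
    pre_time_ms: float = DEFAULT_PRE_TIME_MS,
    overhead_us: float = DEFAULT_OVERHEAD_US,
    min_matrix: int = 16,
    max_matrix: int = 2048,
) -> float:
    """Finest in-plane resolution (mm) whose minimum TE fits a target TE.

    Scans matrix sizes upward and returns fov / N for the largest feasible
    N.  Because TE(N) is monotone apart from ceil steps and forbidden-band
    bumps, the scan is exhaustive rather than bisected.
    """
    if te_target_ms <= pre_time_ms:
        raise ValueError("te_target_ms must exceed the pre-readout time")

    def te_of(n: int) -> float:
        prot = EPIProtocol(
            resolution=fov_mm / n,
            fov=fov_mm,
            matrix_n=n,
            grappa_r=grappa_r,
            partial_fourier=partial_fourier,
            segments=segments,
        )
        return min_te(prot, coil, pre_time_ms=pre_time_ms, overhead_us=overhead_us).te_min_ms

    best = None
    for n in range(min_matrix, max_matrix + 1):
        if te_of(n) <= te_target_ms:
            best = n
    if best is None:
        raise ValueError(
            f"no matrix in [{min_matrix}, {max_matrix}] reaches TE <= {te_target_ms} ms"
        )
    return fov_mm / best
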