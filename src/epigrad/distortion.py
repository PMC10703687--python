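"""EPI susceptibility distortion: forward model from a field map and
symmetric warp estimation from opposed phase-encode pairs.

Off-resonance Delta-f (Hz) accrues phase across the phase-encode (PE)
samples of an EPI train, displacing each voxel along PE by

    d = Delta-f * es_eff * N_pe   [pixels],

where es_eff = ES / (grappa_r * segments) is the effective PE dwell and
N_pe the reconstructed matrix size (partial Fourier does not change the
dwell).  Reversing the PE direction flips the sign.  The forward model is
purely 1D along PE, with mass-preserving linear splatting so intensity is
modulated by the transform Jacobian.

``estimate_warp`` inverts the model without knowing the field map: given
the same object acquired with opposite PE polarities (displacements +u and
-u), it finds the displacement field minimising

    || ap(y + u(y)) - pa(y - u(y)) ||^2  +  lambda ||D2 u||^2

by Gauss-Newton on a coarse-to-fine pyramid, per PE column with a
second-difference smoothness penalty (a compact reimplementation of the
reversed-gradient principle used by standard correction tools).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .epi import EPITiming

__all__ = ["epi_distort", "estimate_warp", "WarpResult", "displacement_map"]


def displacement_map(
    fmap_hz: np.ndarray,
    timing: EPITiming,
    n_pe: int,
    pe_direction: int = +1,
) -> np.ndarray:
    """Voxel displacement along PE in pixels for a field map and timing."""
    if pe_direction not in (+1, -1):
        raise ValueError("pe_direction must be +1 or -1")
    return pe_direction * fmap_hz * (timing.es_eff_ms * 1e-3) * n_pe


def epi_distort(
    image: np.ndarray,
    fmap_hz: np.ndarray,
    timing: EPITiming,
    pe_direction: int = +1,
    pe_axis: int = -1,
) -> np.ndarray:
    """Forward-distort an image along the phase-encode axis.

    Each voxel's intensity is moved by its displacement and deposited with
    linear splatting, which conserves total signal and therefore applies
    the Jacobian intensity modulation (pile-up and stretching) implicitly.
    A zero field map returns the image unchanged; displacements are linear
    in the effective echo spacing.
    """
    image = np.asarray(image, dtype=float)
    fmap_hz = np.asarray(fmap_hz, dtype=float)
    if image.shape != fmap_hz.shape:
        raise ValueError("image and field map shapes must agree")
    pe_axis = pe_axis % image.ndim
    n_pe = image.shape[pe_axis]
    disp = displacement_map(fmap_hz, timing, n_pe, pe_direction)
    if np.abs(disp).max() >= n_pe:
        raise ValueError("displacement exceeds the phase-encode FOV")
    img = np.moveaxis(image, pe_axis, -1)
    d = np.moveaxis(disp, pe_axis, -1)
    lines = img.reshape(-1, n_pe)
    dl = d.reshape(-1, n_pe)
    y = np.arange(n_pe)[None, :] + dl
    lo = np.floor(y).astype(int)
    frac = y - lo
    out = np.zeros_like(lines)
    rows = np.repeat(np.arange(lines.shape[0]), n_pe).reshape(lines.shape)
    for idx, wgt in ((lo, 1.0 - frac), (lo + 1, frac)):
        inside = (idx >= 0) & (idx < n_pe)
        np.add.at(out, (rows[inside], idx[inside]), (lines * wgt)[inside])
    out = out.reshape(img.shape)
    return np.moveaxis(out, -1, pe_axis)


@dataclass(frozen=True)
class WarpResult:
    """Estimated PE displacement field and per-column convergence flags."""

    warp_mm: np.ndarray  # displacement of the AP-polarity image, in mm
    warp_pix: np.ndarray
    converged: np.ndarray  # bool, per PE column

    @property
    def all_converged(self) -> bool:
        return bool(np.all(self.converged))


def _interp_lines(lines: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of each row of ``lines`` at positions ``pos``."""
    n = lines.shape[1]
    p = np.clip(pos, 0, n - 1)
    lo = np.floor(p).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    frac = p - lo
    r = np.arange(lines.shape[0])[:, None]
    return lines[r, lo] * (1 - frac) + lines[r, hi] * frac


def _grad_lines(lines: np.ndarray) -> np.ndarray:
    return np.gradient(lines, axis=1)


def _cumulative_mass_init(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Initial displacement per PE line from equal-cumulative-mass matching.

    The 1D distortion conserves the line integral of intensity, so points
    of equal cumulative mass in the two opposed acquisitions are images of
    the same source point displaced by +d and -d; half their separation is
    the displacement.  Robust for arbitrarily large smooth displacements.
    """
    ncols, n = A.shape
    u = np.zeros_like(A)
    y = np.arange(n, dtype=float)
    edges = np.arange(n + 1, dtype=float)
    for i in range(ncols):
        ca = np.concatenate([[0.0], np.cumsum(A[i])])
        cb = np.concatenate([[0.0], np.cumsum(B[i])])
        tot = min(ca[-1], cb[-1])
        if tot <= 0:
            continue
        levels = np.linspace(0.0, tot, 2 * n)
        ya = np.interp(levels, ca, edges)
        yb = np.interp(levels, cb, edges)
        mid = 0.5 * (ya + yb)
        disp = 0.5 * (ya - yb)
        u[i] = np.interp(y, mid, disp)
    return u


def estimate_warp(
    img_ap: np.ndarray,
    img_pa: np.ndarray,
    voxel_mm: float = 1.0,
    pe_axis: int = -1,
    lam: float = 0.1,
    smooth_levels: tuple = (2.0, 1.0, 0.0),
    n_iter: int = 20,
    tol: float = 1e-3,
    cross_smooth_sigma: float = 1.0,
) -> WarpResult:
    """Symmetric 1D displacement field from an opposed-PE image pair.

    Returns u such that img_ap resampled at y + u and img_pa at y - u
    agree: u is the displacement experienced by the AP-polarity
    acquisition, in mm (sign along the PE axis).  Swapping the inputs
    negates u exactly.

    The solver initialises each PE line by equal-cumulative-mass matching
    (the distortion conserves line integrals) and refines by per-column
    damped Gauss-Newton with a second-difference smoothness penalty
    ``lam``, matching the images at decreasing smoothing widths.  Columns
    whose final update exceeds 10x ``tol`` pixels are flagged as
    unconverged.
    """
    a = np.asarray(img_ap, dtype=float)
    b = np.asarray(img_pa, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a grid")
    pe_axis = pe_axis % a.ndim
    a = np.moveaxis(a, pe_axis, -1)
    b = np.moveaxis(b, pe_axis, -1)
    lead_shape = a.shape[:-1]
    n = a.shape[-1]
    scale = max(a.std(), b.std(), 1e-12)
    A = (a / scale).reshape(-1, n)
    B = (b / scale).reshape(-1, n)
    ncols = A.shape[0]

    # second-difference smoothness operator (free boundaries)
    D2 = (np.diag(np.full(n, -2.0)) + np.diag(np.ones(n - 1), 1)
          + np.diag(np.ones(n - 1), -1))
    D2[0], D2[-1] = 0, 0
    R = lam * (D2.T @ D2) + 1e-6 * np.eye(n)

    u = _cumulative_mass_init(A, B)
    y = np.arange(n)[None, :]
    step = np.zeros(ncols)
    for sigma in smooth_levels:
        if sigma > 0:
            As = ndimage.gaussian_filter1d(A, sigma=sigma, axis=1)
            Bs = ndimage.gaussian_filter1d(B, sigma=sigma, axis=1)
        else:
            As, Bs = A, B
        gA = _grad_lines(As)
        gB = _grad_lines(Bs)

        def residual(uu):
            # mass conservation: orig = ap(y+u)(1+u') = pa(y-u)(1-u'),
            # so both warps carry their Jacobian intensity correction
            up = np.gradient(uu, axis=1)
            return (_interp_lines(As, y + uu) * (1.0 + up)
                    - _interp_lines(Bs, y - uu) * (1.0 - up))

        mu = 1e-2 * max(float((gA ** 2 + gB ** 2).mean()), 1e-12)
        for _ in range(n_iter):
            r = residual(u)
            J = _interp_lines(gA, y + u) + _interp_lines(gB, y - u)
            # per-column Levenberg-damped Gauss-Newton:
            # (diag(J)^2 + mu I + R) du = -J r
            du = np.empty_like(u)
            for col in range(ncols):
                H = np.diag(J[col] ** 2 + mu) + R
                du[col] = np.linalg.solve(H, -(J[col] * r[col]))
            du = np.clip(du, -0.5, 0.5)
            # accept the step only for columns whose data misfit improves
            r_new = residual(u + du)
            better = (r_new ** 2).sum(axis=1) <= (r ** 2).sum(axis=1)
            du = np.where(better[:, None], du, 0.0)
            u = u + du
            if cross_smooth_sigma and len(lead_shape) and ncols > 1:
                u2 = u.reshape(*lead_shape, n)
                for ax in range(len(lead_shape)):
                    u2 = ndimage.gaussian_filter1d(u2, cross_smooth_sigma, axis=ax)
                u = u2.reshape(ncols, n)
            step = np.abs(du).max(axis=1)
            if step.max() < tol:
                break
    converged = step < 10 * tol
    u_full = u.reshape(*lead_shape, n)
    warp_pix = np.moveaxis(u_full, -1, pe_axis)
    return WarpResult(
        warp_mm=warp_pix * voxel_mm,
        warp_pix=warp_pix,
        converged=converged.reshape(lead_shape) if lead_shape else converged,
    )
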