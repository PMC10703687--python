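"""Synthetic multi-channel receive arrays: helmet geometries, loop-field
sensitivities, channel noise covariance, optimal-combination SNR maps and
SENSE g-factor (retained SNR) maps.

Receive sensitivities are modelled quasi-statically as the field of a
circular current loop (reciprocity), evaluated with the standard elliptic
integral expressions; the complex receive phase follows from the
transverse field components with B0 along the lab z axis.  The optimal
(noise-covariance-weighted) coil combination gives voxelwise

    SNR  proportional to  sqrt( S^H Psi^-1 S ),

and the SENSE noise amplification of an aliasing set A (in-plane folding
combined with SMS/CAIPI slice shifts) is

    g_j = sqrt( [(S_A^H Psi^-1 S_A)^-1]_jj  [S_A^H Psi^-1 S_A]_jj ) >= 1,

reported as retained SNR 1/g in (0, 1].  Sensitivities are known exactly
here, which makes the SENSE algebra the natural noise-propagation model
for simulated data (a deliberate substitution for autocalibrated
reconstructions used on scanners, whose g-factors it approximates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ellipe, ellipk

__all__ = [
    "CoilArrayGeometry",
    "SensitivitySet",
    "NoiseCovariance",
    "SamplingPattern",
    "build_helmet_array",
    "sensitivities",
    "noise_cov",
    "snr_map",
    "retained_snr_map",
]

# row layouts per supported channel count, vertex row first; the 96-channel
# helmet keeps 12/18/24 in the top three rows with 42 below
_ROW_LAYOUTS = {
    8: (3, 5),
    32: (6, 10, 16),
    64: (10, 14, 18, 22),
    96: (12, 18, 24, 42),
    128: (14, 22, 28, 64),
}


@dataclass(frozen=True)
class CoilArrayGeometry:
    """Loop centres (mm), radii (mm) and unit normals on a helmet surface."""

    centers: np.ndarray  # (n, 3)
    radii: np.ndarray  # (n,)
    normals: np.ndarray  # (n, 3), unit
    helmet_semiaxes: tuple = (87.5, 107.5, 100.0)
    row_counts: tuple = ()

    @property
    def n_channels(self) -> int:
        return self.centers.shape[0]


@dataclass(frozen=True)
class SensitivitySet:
    """Complex per-channel sensitivity on a 3D grid (arbitrary units)."""

    values: np.ndarray  # (n_channels, nx, ny, nz) complex
    grid_spacing_mm: float = 1.0

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class NoiseCovariance:
    """Hermitian positive-definite channel noise covariance Psi."""

    psi: np.ndarray

    def __post_init__(self):
        psi = np.asarray(self.psi)
        if psi.ndim != 2 or psi.shape[0] != psi.shape[1]:
            raise ValueError("psi must be square")
        if not np.allclose(psi, psi.conj().T, atol=1e-10 * max(1.0, np.abs(psi).max())):
            raise ValueError("psi must be Hermitian")
        if np.linalg.eigvalsh(psi).min() <= 0:
            raise ValueError("psi must be positive-definite")
        object.__setattr__(self, "psi", psi)


@dataclass(frozen=True)
class SamplingPattern:
    """In-plane acceleration, SMS factor, and CAIPI inter-slice shift.

    ``caipi_shift`` is an integer: simultaneously excited slice m is
    shifted along phase encode by m * caipi_shift / sms of the FOV.
    """

    r_pe: int = 1
    sms: int = 1
    caipi_shift: int = 0

    def __post_init__(self):
        if self.r_pe < 1 or self.sms < 1:
            raise ValueError("accelerations must be integers >= 1")
        if not 0 <= self.caipi_shift < max(self.sms, 1):
            raise ValueError("caipi_shift must satisfy 0 <= shift < sms")


def build_helmet_array(
    n_channels: int,
    helmet_semiaxes: tuple = (87.5, 107.5, 100.0),
    seed: int = 0,
    polar_min_deg: float = 18.0,
    polar_max_deg: float = 105.0,
    overlap: float = 0.8,
) -> CoilArrayGeometry:
    """Deterministic rows of overlapped loops tiling an ellipsoidal helmet.

    Rows of loops are placed at evenly spaced polar angles between
    ``polar_min_deg`` (near the vertex) and ``polar_max_deg`` (below the
    ears); each row's loops are spread uniformly in azimuth with a small
    seeded azimuthal stagger between rows.  Loop radius is ``overlap``
    times the in-row centre spacing, so it shrinks as the channel count
    grows (about 2 cm radius at 96 channels).
    """
    if n_channels not in _ROW_LAYOUTS:
        raise ValueError(
            f"unsupported channel count {n_channels}; supported: {sorted(_ROW_LAYOUTS)}"
        )
    rows = _ROW_LAYOUTS[n_channels]
    a, b, c = helmet_semiaxes
    rng = np.random.default_rng(seed)
    thetas = np.deg2rad(np.linspace(polar_min_deg, polar_max_deg, len(rows)))
    centers, radii, normals = [], [], []
    for theta, m in zip(thetas, rows):
        phi0 = rng.uniform(0, 2 * np.pi / m)
        phis = phi0 + 2 * np.pi * np.arange(m) / m
        x = a * np.sin(theta) * np.cos(phis)
        y = b * np.sin(theta) * np.sin(phis)
        z = c * np.cos(theta) * np.ones_like(phis)
        pts = np.stack([x, y, z], axis=1)
        # outward surface normal of the ellipsoid at each point
        nrm = pts / np.array([a * a, b * b, c * c])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        # in-row spacing from the mean row circumference; radius capped so
        # sparse bottom rows do not grow unphysically large loops
        rho = np.sin(theta) * 0.5 * (a + b)
        spacing = 2 * np.pi * rho / m
        centers.append(pts)
        radii.append(np.full(m, min(overlap * spacing, 27.0)))
        normals.append(nrm)
    return CoilArrayGeometry(
        centers=np.concatenate(centers),
        radii=np.concatenate(radii),
        normals=np.concatenate(normals),
        helmet_semiaxes=tuple(helmet_semiaxes),
        row_counts=tuple(rows),
    )


def _loop_field(center, normal, radius, points, wire_radius_mm=0.5, strict=False):
    """Quasi-static field of a unit-current circular loop at given points.

    Returns the lab-frame B vector (arbitrary units) using the elliptic
    integral solution in the loop frame (axis along ``normal``).  Points
    closer to the conductor ring than the wire radius are projected onto
    the wire surface so the field stays finite; with ``strict`` such
    points raise instead (use for voxels that must not intersect a loop).
    """
    rel = points - center
    nhat = normal / np.linalg.norm(normal)
    z = rel @ nhat
    rho_vec = rel - np.outer(z, nhat)
    rho = np.linalg.norm(rho_vec, axis=1)
    a = radius
    # distance to the conductor ring itself
    ring_dist = np.sqrt(z * z + (rho - a) ** 2)
    close = ring_dist < wire_radius_mm
    if np.any(close):
        if strict:
            raise ValueError(
                f"grid point within {wire_radius_mm} mm of a loop conductor"
            )
        scale = wire_radius_mm / np.maximum(ring_dist, 1e-9)
        z = np.where(close, z * scale, z)
        rho = np.where(close, a + (rho - a) * scale, rho)
    q = (a + rho) ** 2 + z * z
    m = 4 * a * rho / q  # elliptic parameter
    K = ellipk(m)
    E = ellipe(m)
    denom = (a - rho) ** 2 + z * z
    pref = 1.0 / np.sqrt(q)
    bz = pref * (K + E * (a * a - rho * rho - z * z) / denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        brho = pref * (z / rho) * (E * (a * a + rho * rho + z * z) / denom - K)
    on_axis = rho < 1e-9
    brho = np.where(on_axis, 0.0, brho)
    rho_hat = np.where(on_axis[:, None], 0.0,
                       rho_vec / np.where(on_axis, 1.0, rho)[:, None])
    return bz[:, None] * nhat + brho[:, None] * rho_hat


def sensitivities(
    geom: CoilArrayGeometry,
    grid_shape: tuple,
    grid_spacing_mm: float,
    center_mm=(0.0, 0.0, 0.0),
    mask: np.ndarray | None = None,
) -> SensitivitySet:
    """Complex receive sensitivity of every loop on a regular 3D grid.

    The grid is centred on ``center_mm``; receive sensitivity is the
    rotating-frame combination Bx - i By of the loop field (B0 along z).
    With a boolean ``mask`` only masked voxels are evaluated (others are
    zero) and a masked voxel intersecting a loop conductor raises; without
    a mask near-conductor voxels (background, outside any object of
    interest) get the finite wire-surface field instead.
    """
    nx, ny, nz = grid_shape
    ax = [(np.arange(n) - (n - 1) / 2.0) * grid_spacing_mm + c
          for n, c in zip(grid_shape, center_mm)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    strict = mask is not None
    if mask is not None:
        if mask.shape != tuple(grid_shape):
            raise ValueError("mask shape must match grid_shape")
        sel = mask.ravel()
        pts = pts[sel]
    vals = np.zeros((geom.n_channels, nx * ny * nz), dtype=complex)
    for ch in range(geom.n_channels):
        B = _loop_field(geom.centers[ch], geom.normals[ch], geom.radii[ch],
                        pts, strict=strict)
        if mask is not None:
            vals[ch, sel] = B[:, 0] - 1j * B[:, 1]
        else:
            vals[ch] = B[:, 0] - 1j * B[:, 1]
    return SensitivitySet(
        values=vals.reshape(geom.n_channels, nx, ny, nz),
        grid_spacing_mm=grid_spacing_mm,
    )


def noise_cov(
    geom: CoilArrayGeometry,
    coupling_scale: float = 0.2,
    sigma: float = 1.0,
    reference_radius_mm: float | None = None,
    floor: float = 1e-6,
) -> NoiseCovariance:
    """Channel noise covariance sigma^2 (I + coupling * overlap kernel).

    The overlap kernel decays as a Gaussian of the centre-to-centre
    distance with length scale the sum of the two loop radii; the matrix
    is symmetrised and its eigenvalues floored to stay positive-definite.
    With ``reference_radius_mm`` set, each channel's noise amplitude is
    scaled by loop_radius / reference (body-noise dominance: a larger loop
    sees more tissue noise), the regime in which shrinking the loops pays
    off at the periphery.
    """
    d = np.linalg.norm(geom.centers[:, None, :] - geom.centers[None, :, :], axis=2)
    ell = geom.radii[:, None] + geom.radii[None, :]
    kernel = np.exp(-(d / ell) ** 2)
    np.fill_diagonal(kernel, 0.0)
    base = np.eye(geom.n_channels) + coupling_scale * kernel
    if reference_radius_mm is not None:
        sig = sigma * geom.radii / reference_radius_mm
        psi = np.outer(sig, sig) * base
    else:
        psi = sigma ** 2 * base
    psi = 0.5 * (psi + psi.T)
    w, v = np.linalg.eigh(psi)
    w = np.clip(w, floor * sigma ** 2, None)
    return NoiseCovariance((v * w) @ v.T)


def snr_map(s: SensitivitySet, psi: NoiseCovariance) -> np.ndarray:
    """Relative SNR of the noise-covariance-weighted optimal combination.

    Voxelwise sqrt(S^H Psi^-1 S), in arbitrary units (no absolute
    calibration: synthetic excitation is uniform).
    """
    nch = s.n_channels
    if psi.psi.shape[0] != nch:
        raise ValueError("channel count mismatch between sensitivities and psi")
    flat = s.values.reshape(nch, -1)
    sol = np.linalg.solve(psi.psi.astype(complex), flat)
    val = np.real(np.einsum("cv,cv->v", flat.conj(), sol))
    return np.sqrt(np.clip(val, 0, None)).reshape(s.values.shape[1:])


def retained_snr_map(
    s: SensitivitySet,
    psi: NoiseCovariance,
    pat: SamplingPattern,
    pe_axis: int = 1,
    slice_axis: int = 2,
) -> np.ndarray:
    """Retained SNR 1/g of SENSE unfolding for an acceleration pattern.

    The aliasing set of a voxel combines its r_pe in-plane replicas along
    ``pe_axis`` with the sms simultaneously excited slices along
    ``slice_axis``, each slice CAIPI-shifted along phase encode.  A
    rank-deficient aliasing system yields 1/g = 0 for its voxels.
    """
    vol = s.values
    nch = s.n_channels
    shape = vol.shape[1:]
    ny, nz = shape[pe_axis], shape[slice_axis]
    if ny % pat.r_pe or nz % pat.sms:
        raise ValueError("grid must divide evenly by the accelerations")
    if pat.r_pe == 1 and pat.sms == 1:
        return np.ones(shape)
    # gather the aliasing sets: iterate over replica offsets, rolling the
    # sensitivity volume so every voxel's aliases line up with it
    offsets = []
    for mslice in range(pat.sms):
        dz = mslice * (nz // pat.sms)
        dy_caipi = (mslice * pat.caipi_shift * ny) // pat.sms
        for p in range(pat.r_pe):
            offsets.append(((p * ny) // pat.r_pe + dy_caipi, dz))
    na = len(offsets)
    nv = int(np.prod(shape))
    SA = np.empty((nv, nch, na), dtype=complex)
    for k, (dy, dz) in enumerate(offsets):
        rolled = np.roll(np.roll(vol, -dy, axis=1 + pe_axis), -dz, axis=1 + slice_axis)
        SA[:, :, k] = rolled.reshape(nch, nv).T
    psi_inv = np.linalg.inv(psi.psi.astype(complex))
    M = np.matmul(SA.conj().transpose(0, 2, 1), np.matmul(psi_inv, SA))
    diagM = np.real(np.einsum("vaa->va", M))
    out = np.zeros((nv,))
    # entry 0 of each aliasing set is the voxel itself (offset 0)
    with np.errstate(invalid="ignore"):
        try:
            Minv = np.linalg.inv(M)
            diagMinv = np.real(np.einsum("vaa->va", Minv))
            g2 = diagMinv[:, 0] * diagM[:, 0]
            good = np.isfinite(g2) & (g2 > 0)
            out[good] = 1.0 / np.sqrt(g2[good])
        except np.linalg.LinAlgError:
            # fall back voxelwise when some systems are singular
            for v in range(nv):
                try:
                    mi = np.linalg.inv(M[v])
                    g2 = np.real(mi[0, 0]) * diagM[v, 0]
                    out[v] = 1.0 / np.sqrt(g2) if g2 > 0 else 0.0
                except np.linalg.LinAlgError:
                    out[v] = 0.0
    return np.clip(out, 0.0, 1.0).reshape(shape)
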