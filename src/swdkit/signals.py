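"""Derived signals: kernel-method LFP and the gamma HRF basis.

The local field potential proxy follows the kernel method: each
population rate is convolved with a unit-area Gaussian kernel, scaled
and delayed, and the two contributions are summed (the inhibitory
amplitude is negative and larger in magnitude, giving the LFP its
characteristic polarity).  The hemodynamic machinery builds the
third-order gamma basis used to model fMRI responses and reassembles
region-level HRFs from fitted beta weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "LFPKernelParams",
    "HRFBasis",
    "compute_lfp",
    "gamma_basis",
    "hrf_from_betas",
    "extreme_beta",
]


@dataclass(frozen=True)
class LFPKernelParams:
    """Gaussian kernel amplitudes (a.u.), widths and delays (ms)."""

    A_e: float = 1.0
    A_i: float = -1.6
    sigma_e: float = 2.1
    sigma_i: float = 2.1
    d_e: float = 1.5
    d_i: float = 0.5

    def __post_init__(self):
        if self.sigma_e <= 0 or self.sigma_i <= 0:
            raise ValueError("kernel widths must be > 0")
        if self.d_e < 0 or self.d_i < 0:
            raise ValueError("kernel delays must be >= 0")


def _gaussian_kernel(sigma_ms: float, fs: float) -> np.ndarray:
    """Unit-area Gaussian sampled at fs (Hz), truncated at 5 sigma."""
    sigma_samp = sigma_ms * 1e-3 * fs
    half = max(int(np.ceil(5 * sigma_samp)), 1)
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma_samp) ** 2)
    return k / k.sum()


def compute_lfp(nu_e, nu_i, fs: float, params: LFPKernelParams | None = None) -> np.ndarray:
    """Kernel-method LFP from excitatory/inhibitory population rates.

    LFP(t) = A_e (G_sigma_e * nu_e)(t - d_e) + A_i (G_sigma_i * nu_i)(t - d_i)
    with unit-area Gaussian kernels; linear in each input and zero-phase
    apart from the stated delays (delays are rounded to whole samples).
    """
    params = params or LFPKernelParams()
    nu_e = np.asarray(nu_e, dtype=float)
    nu_i = np.asarray(nu_i, dtype=float)
    if nu_e.shape != nu_i.shape:
        raise ValueError("rate series must have equal length")
    if min(params.sigma_e, params.sigma_i) * 1e-3 < 2.0 / fs:
        raise ValueError("sampling rate too low to resolve the LFP kernels")
    out = np.zeros_like(nu_e)
    for A, sigma, d, x in ((params.A_e, params.sigma_e, params.d_e, nu_e),
                           (params.A_i, params.sigma_i, params.d_i, nu_i)):
        y = np.convolve(x, _gaussian_kernel(sigma, fs), mode="same")
        shift = int(round(d * 1e-3 * fs))
        if shift:
            y = np.concatenate([np.full(shift, y[0]), y[:-shift]])
        out += A * y
    return out


@dataclass
class HRFBasis:
    """Third-order gamma basis for HRF modelling.

    ``matrix`` holds one unit-peak basis function per column, sampled at
    the repetition time ``TR`` over ``duration`` seconds; column k peaks
    at (shape_k - 1) * scale_k seconds.
    """

    TR: float
    duration: float
    shapes: tuple              # ((shape, scale), ...) gamma pairs
    matrix: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)

    @property
    def n_basis(self) -> int:
        return self.matrix.shape[1]


DEFAULT_SHAPES = ((3.0, 1.0), (5.0, 1.0), (7.0, 1.0))


def gamma_basis(TR: float, duration: float = 20.0,
                shapes=DEFAULT_SHAPES, t_grid=None) -> HRFBasis:
    """Build the gamma basis (unit peak height per column).

    Each (shape k, scale theta) pair yields t^(k-1) exp(-t/theta)
    normalized by its value at the mode (k-1)*theta, so sampling any
    time grid evaluates the same analytic curve.  Defaults peak at
    2/4/6 s, matching the early rodent hemodynamic response.
    """
    shapes = tuple(tuple(map(float, s)) for s in shapes)
    for k, theta in shapes:
        if k <= 1:
            raise ValueError("gamma shape must exceed 1 (no interior peak)")
        if duration < (k - 1) * theta + 3 * theta:
            raise ValueError("duration too short for the slowest basis function")
    t = np.arange(0.0, duration + 1e-9, TR) if t_grid is None else np.asarray(t_grid, float)
    cols = []
    for k, theta in shapes:
        mode = (k - 1) * theta
        peak = sstats.gamma.pdf(mode, a=k, scale=theta)
        cols.append(sstats.gamma.pdf(t, a=k, scale=theta) / peak)
    return HRFBasis(TR=TR, duration=duration, shapes=shapes,
                    matrix=np.column_stack(cols), times=t)


def hrf_from_betas(betas, basis: HRFBasis) -> np.ndarray:
    """HRF curve = sum_k beta_k * basis_k, sampled like the basis."""
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (basis.n_basis,):
        raise ValueError(
            f"expected {basis.n_basis} betas, got {betas.shape}"
        )
    return basis.matrix @ betas


def extreme_beta(values) -> float:
    """Signed value of largest magnitude; ties resolve to the positive one."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("extreme_beta needs a non-empty input")
    vmax, vmin = values.max(), values.min()
    return float(vmax if abs(vmax) >= abs(vmin) else vmin)
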