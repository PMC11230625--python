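"""AdEx mean-field model of one brain region.

A region is a pair of coupled populations — excitatory regular-spiking
cells with spike-frequency adaptation and inhibitory fast-spiking cells —
described by their mean firing rates (nu_e, nu_i), the mean adaptation
current W, and the derived membrane-potential statistics.  The
population transfer function is semi-analytic: Gaussian membrane
statistics are computed from shot-noise theory of the conductance input,
and the output rate follows an error-function escape rate across a
phenomenological effective threshold whose polynomial coefficients are
fitted once against a Monte-Carlo AdEx single-neuron simulation.

Low adaptation strength ``b`` yields an asynchronous-irregular (AI)
regime; high ``b`` yields slow synchronous oscillations whose rate/LFP
signature matches spike-and-wave discharges (SWD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.special import erfc, erfcinv

from .params import NodeParams, NodeState, Population, TransferCoefficients, N_COEFFS

__all__ = [
    "conductance_stats",
    "transfer_rate",
    "effective_threshold",
    "fit_transfer_coefficients",
    "step_node",
    "simulate_node",
    "classify_regime",
    "scan_adaptation",
    "RegimeMetrics",
]

_SIGMA_EPS = 1e-6  # mV; below this the transfer degenerates to a hard threshold


def _check_finite(name, value):
    if not np.all(np.isfinite(value)):
        raise ValueError(f"non-finite value in input '{name}'")


def conductance_stats(nu_e_in, nu_i_in, W, params: NodeParams, population: Population = "e"):
    """Membrane-potential statistics under Poissonian conductance bombardment.

    Parameters
    ----------
    nu_e_in, nu_i_in : float or ndarray
        Presynaptic excitatory / inhibitory rates (Hz) seen by one neuron
        of the requested population.
    W : float or ndarray
        Adaptation current (pA), subtracted from the input current.
    population : {"e", "i"}
        Selects the leak reversal of the receiving population.

    Returns
    -------
    mu_V, sigma_V, tau_V, tau_m_eff : ndarray or float
        Mean (mV), standard deviation (mV), autocorrelation time (ms) of
        the membrane potential and the effective membrane time constant
        (ms).  In the zero-input limit ``tau_V`` equals ``tau_m_eff``.
    """
    for name, v in (("nu_e_in", nu_e_in), ("nu_i_in", nu_i_in), ("W", W)):
        _check_finite(name, v)
    return _stats_core(nu_e_in, nu_i_in, W, params, population)


def _stats_core(nu_e_in, nu_i_in, W, params: NodeParams, population: Population):
    """conductance_stats without input validation (hot path)."""
    nu_e = np.maximum(np.asarray(nu_e_in, dtype=float), 0.0) * 1e-3  # kHz
    nu_i = np.maximum(np.asarray(nu_i_in, dtype=float), 0.0) * 1e-3
    W = np.asarray(W, dtype=float)

    E_L = params.E_L(population)
    mu_Ge = params.K_e * nu_e * params.tau_e * params.Q_e
    mu_Gi = params.K_i * nu_i * params.tau_i * params.Q_i
    mu_G = params.g_L + mu_Ge + mu_Gi
    tau_m_eff = params.C_m / mu_G
    mu_V = (mu_Ge * params.E_e + mu_Gi * params.E_i + params.g_L * E_L - W) / mu_G

    U_e = (params.Q_e / mu_G) * (params.E_e - mu_V)
    U_i = (params.Q_i / mu_G) * (params.E_i - mu_V)
    s_e = params.K_e * nu_e * (U_e * params.tau_e) ** 2
    s_i = params.K_i * nu_i * (U_i * params.tau_i) ** 2
    var_V = s_e / (2 * (tau_m_eff + params.tau_e)) + s_i / (2 * (tau_m_eff + params.tau_i))
    sigma_V = np.sqrt(np.maximum(var_V, 0.0))

    num = s_e + s_i
    den = s_e / (tau_m_eff + params.tau_e) + s_i / (tau_m_eff + params.tau_i)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_V = np.where(den > 0, num / np.where(den > 0, den, 1.0), tau_m_eff)
    return mu_V, sigma_V, tau_V, tau_m_eff


def _poly_basis(x, y, z):
    """11-term second-order basis (with triple cross term) in (x, y, z)."""
    one = np.ones_like(x)
    return np.stack(
        [one, x, y, z, x * x, y * y, z * z, x * y, x * z, y * z, x * y * z],
        axis=-1,
    )


def effective_threshold(mu_V, sigma_V, tau_V, mu_G_over_Cm, coeffs: TransferCoefficients,
                        population: Population):
    """Phenomenological firing threshold V_thr_eff (mV)."""
    x = (np.asarray(mu_V) - coeffs.mu_V0) / coeffs.d_mu_V0
    y = (np.asarray(sigma_V) - coeffs.sigma_V0) / coeffs.d_sigma_V0
    z = (np.asarray(tau_V) * mu_G_over_Cm - coeffs.tau_VN0) / coeffs.d_tau_VN0
    basis = _poly_basis(x, y, z)
    return basis @ coeffs.P(population)


def transfer_rate(nu_e_in, nu_i_in, W, params: NodeParams,
                  coeffs: TransferCoefficients, population: Population = "e",
                  sigma_eps: float = _SIGMA_EPS):
    """Stationary output rate (Hz) of a population given its inputs.

    rate = Erfc((V_thr_eff - mu_V) / (sqrt(2) sigma_V)) / (2 tau_V),
    saturating at 1/tau_V.  For vanishing sigma_V the Erfc collapses to a
    hard threshold (0 below V_thr_eff, 1/tau_V above).
    """
    if len(coeffs.P(population)) != N_COEFFS:  # pragma: no cover - guarded upstream
        raise ValueError("missing transfer coefficients for population " + population)
    stats = conductance_stats(nu_e_in, nu_i_in, W, params, population)
    rate = _rate_from_stats(stats, coeffs, population, sigma_eps)
    return rate if rate.ndim else float(rate)


def _rate_from_stats(stats, coeffs: TransferCoefficients, population: Population,
                     sigma_eps: float = _SIGMA_EPS):
    """Erfc escape rate from precomputed membrane statistics (hot path)."""
    mu_V, sigma_V, tau_V, tau_m = stats
    v_thr = effective_threshold(mu_V, sigma_V, tau_V, 1.0 / tau_m, coeffs, population)
    sat = 1e3 / (2.0 * tau_V)  # Hz; half the saturation rate times 2
    arg = (v_thr - mu_V) / (np.sqrt(2.0) * np.where(sigma_V > sigma_eps, sigma_V, 1.0))
    smooth = sat * erfc(arg)
    hard = np.where(mu_V < v_thr, 0.0, 2.0 * sat)
    return np.where(sigma_V > sigma_eps, smooth, hard)


def fit_transfer_coefficients(
    grid: "np.ndarray",
    rates: "np.ndarray",
    params: NodeParams,
    population: Population,
    base: TransferCoefficients | None = None,
    min_points: int = 30,
    max_rms_hz: float = 5.0,
    rate_range=(0.05, 100.0),
    refine: bool = True,
):
    """Fit the 11 threshold-polynomial coefficients to an oracle rate grid.

    Parameters
    ----------
    grid : (n, 3) array
        Columns (nu_e_in Hz, nu_i_in Hz, W pA) of the sampled inputs.
    rates : (n,) array
        Oracle output rates (Hz), e.g. from the Monte-Carlo AdEx neuron.
    population : {"e", "i"}
        Which coefficient vector to fit.
    base : TransferCoefficients, optional
        Supplies normalization constants and the other population's
        coefficients; defaults to zeros for the untouched population.

    Returns
    -------
    (TransferCoefficients, rms_hz)

    Notes
    -----
    Each grid point with an oracle rate inside ``rate_range`` (Hz) is
    inverted through the Erfc relation to an empirical effective
    threshold and the polynomial is obtained by linear least squares;
    with ``refine`` the coefficients are then polished by nonlinear least
    squares directly on the rate residuals.  Points outside
    ``rate_range`` carry little threshold information (zero rates none
    at all) and are excluded from both fit and RMS; fewer than
    ``min_points`` informative points, or a collinear basis, raise
    ``ValueError``.
    """
    grid = np.asarray(grid, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if base is None:
        base = TransferCoefficients(P_e=(0.0,) * N_COEFFS, P_i=(0.0,) * N_COEFFS)
    mu_V, sigma_V, tau_V, tau_m = conductance_stats(
        grid[:, 0], grid[:, 1], grid[:, 2], params, population
    )
    rate_ms = rates * 1e-3  # kHz
    # invert rate = erfc(u)/(2 tau_V):  u = erfcinv(2 rate tau_V)
    q = 2.0 * rate_ms * tau_V
    keep = (rates >= rate_range[0]) & (rates <= rate_range[1]) & (q < 2.0) & (sigma_V > _SIGMA_EPS)
    if keep.sum() < min_points:
        raise ValueError(
            f"transfer fit needs >= {min_points} informative grid points, got {int(keep.sum())}"
        )
    v_thr_emp = mu_V[keep] + np.sqrt(2.0) * sigma_V[keep] * erfcinv(q[keep])
    x = (mu_V[keep] - base.mu_V0) / base.d_mu_V0
    y = (sigma_V[keep] - base.sigma_V0) / base.d_sigma_V0
    z = (tau_V[keep] / tau_m[keep] - base.tau_VN0) / base.d_tau_VN0
    A = _poly_basis(x, y, z)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("degenerate (collinear) oracle grid; widen the sampling")
    P, *_ = np.linalg.lstsq(A, v_thr_emp, rcond=None)

    key = "P_e" if population == "e" else "P_i"

    def with_P(P_vec):
        kw = base.to_dict()
        kw[key] = np.asarray(P_vec).tolist()
        return TransferCoefficients.from_dict(kw)

    if refine:
        from scipy.optimize import least_squares

        sub = grid[keep]
        target = rates[keep]

        def resid(P_vec):
            pred = transfer_rate(sub[:, 0], sub[:, 1], sub[:, 2], params,
                                 with_P(P_vec), population)
            return np.asarray(pred) - target

        P = least_squares(resid, P, method="lm", max_nfev=2000).x
    fitted = with_P(P)
    pred = transfer_rate(grid[keep, 0], grid[keep, 1], grid[keep, 2], params,
                         fitted, population)
    rms = float(np.sqrt(np.mean((np.asarray(pred) - rates[keep]) ** 2)))
    if rms > max_rms_hz:
        raise ValueError(f"transfer fit RMS error {rms:.2f} Hz exceeds {max_rms_hz} Hz")
    return fitted, rms


def _drift(nu_e, nu_i, W, aff_e, aff_i, params: NodeParams, coeffs: TransferCoefficients,
           aff_e_for_i=None):
    """Time derivatives of (nu_e, nu_i, W); rates Hz, W pA, time ms.

    ``aff_e`` is the external excitatory afferent to the excitatory
    population; ``aff_e_for_i`` the one seen by the inhibitory
    population (``None`` means both see ``aff_e``).  ``aff_i`` is an
    additional inhibitory input rate to both populations.
    """
    tot_e = nu_e + aff_e + params.nu_ext
    tot_i = nu_i + aff_i
    stats_e = _stats_core(tot_e, tot_i, W, params, "e")
    F_e = _rate_from_stats(stats_e, coeffs, "e")
    if aff_e_for_i is None:
        tot_e_i = tot_e
    else:
        tot_e_i = nu_e + aff_e_for_i + params.nu_ext
    stats_i = _stats_core(tot_e_i, tot_i, 0.0, params, "i")
    F_i = _rate_from_stats(stats_i, coeffs, "i")
    mu_V = stats_e[0]
    d_nu_e = (F_e - nu_e) / params.T
    d_nu_i = (F_i - nu_i) / params.T
    d_W = (-W + params.a * (mu_V - params.E_L_e)) / params.tau_w + params.b * nu_e * 1e-3
    return d_nu_e, d_nu_i, d_W, mu_V


def step_node(state: NodeState, afferent, dt, noise_draw, params: NodeParams,
              coeffs: TransferCoefficients, step_index: int = 0,
              exc_to_inhibitory=None) -> NodeState:
    """Advance one node by ``dt`` ms with a stochastic Heun step.

    ``afferent`` is the (excitatory Hz, inhibitory Hz) external input to
    the excitatory population; ``exc_to_inhibitory`` optionally routes a
    different excitatory afferent to the inhibitory population (``None``
    means both populations receive ``afferent[0]``).  ``noise_draw`` is
    an already-sampled rate perturbation (Hz) entering the excitatory
    rate equation alongside the transfer function.  The step is
    deterministic given its arguments.
    """
    if dt > 0.5:
        raise ValueError("dt must be <= 0.5 ms for stability")
    aff_e, aff_i = afferent
    d1 = _drift(state.nu_e, state.nu_i, state.W, aff_e, aff_i, params, coeffs,
                exc_to_inhibitory)
    ne_p = state.nu_e + dt * (d1[0] + noise_draw / params.T)
    ni_p = state.nu_i + dt * d1[1]
    W_p = state.W + dt * d1[2]
    ne_p = min(max(ne_p, 0.0), params.rate_cap)
    ni_p = min(max(ni_p, 0.0), params.rate_cap)
    d2 = _drift(ne_p, ni_p, W_p, aff_e, aff_i, params, coeffs, exc_to_inhibitory)
    nu_e = state.nu_e + 0.5 * dt * (d1[0] + d2[0]) + dt * noise_draw / params.T
    nu_i = state.nu_i + 0.5 * dt * (d1[1] + d2[1])
    W = state.W + 0.5 * dt * (d1[2] + d2[2])
    nu_e = min(max(nu_e, 0.0), params.rate_cap)
    nu_i = min(max(nu_i, 0.0), params.rate_cap)
    mu_V = d2[3]
    out = NodeState(nu_e=nu_e, nu_i=nu_i, W=W, mu_V=float(mu_V))
    for name in ("nu_e", "nu_i", "W", "mu_V"):
        if not np.isfinite(getattr(out, name)):
            raise FloatingPointError(
                f"non-finite {name} after integration step {step_index}"
            )
    return out


def simulate_node(params: NodeParams, coeffs: TransferCoefficients, duration: float,
                  dt: float = 0.1, noise_std: float = 0.5, seed: int = 0,
                  init: NodeState | None = None, stimulus=None,
                  stim_to_inhibitory: bool = False):
    """Simulate a single isolated node.

    Parameters
    ----------
    duration : s
    dt : ms
    noise_std : Hz
        Base amplitude of the Gaussian drive noise; the per-step draw is
        scaled by sqrt(T/dt) so the integrated rate diffusion is
        dt-independent.
    stimulus : callable or None
        Optional ``stimulus(t_seconds) -> Hz`` added to the excitatory
        afferent of the excitatory population (and of the inhibitory
        population too when ``stim_to_inhibitory``).

    Returns
    -------
    dict with keys t (s), nu_e, nu_i (Hz), W (pA), mu_V (mV).
    """
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration * 1e3 / dt))
    state = init or NodeState(nu_e=2.0, nu_i=10.0, W=0.0)
    scale = noise_std * np.sqrt(params.T / dt)
    out = {k: np.empty(n_steps) for k in ("nu_e", "nu_i", "W", "mu_V")}
    t = np.arange(n_steps) * dt * 1e-3
    for k in range(n_steps):
        aff_e = stimulus(t[k]) if stimulus is not None else 0.0
        noise = rng.normal(0.0, scale)
        state = step_node(state, (aff_e, 0.0), dt, noise, params, coeffs, step_index=k,
                          exc_to_inhibitory=aff_e if stim_to_inhibitory else 0.0)
        out["nu_e"][k] = state.nu_e
        out["nu_i"][k] = state.nu_i
        out["W"][k] = state.W
        out["mu_V"][k] = state.mu_V
    out["t"] = t
    return out


@dataclass
class RegimeMetrics:
    label: str                # "AI" or "SWD"
    peak_hz: float            # dominant spectral peak in 1-20 Hz
    oscillation_index: float  # power fraction in peak +/- 1.5 Hz
    amplitude_hz: float       # peak-to-trough rate excursion


def classify_regime(trace, fs, transient_s: float = 1.0,
                    osc_threshold: float = 0.4, amp_floor_hz: float = 10.0,
                    band=(1.0, 20.0)) -> RegimeMetrics:
    """Label a rate trace as asynchronous-irregular (AI) or SWD-like.

    The trace (Hz, sampled at ``fs`` Hz) is labeled SWD when the spectral
    power fraction within +/-1.5 Hz of the in-band peak, relative to the
    total power inside ``band``, exceeds ``osc_threshold`` and the
    peak-to-trough excursion exceeds ``amp_floor_hz``; otherwise AI.
    The fraction is taken within the 1-20 Hz classification band on
    purpose: a spike-and-wave cycle is strongly non-sinusoidal and
    carries much of its power in harmonics above 20 Hz, which should not
    count against its rhythmicity.  The first ``transient_s`` seconds
    are discarded.
    """
    trace = np.asarray(trace, dtype=float)
    start = int(round(transient_s * fs))
    kept = trace[start:]
    if kept.size < 5 * fs:
        raise ValueError("need >= 5 s of trace after the discarded transient")
    nper = int(min(kept.size, 4 * fs))
    freqs, pxx = sps.welch(kept - kept.mean(), fs=fs, nperseg=nper)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    peak_hz = float(freqs[in_band][np.argmax(pxx[in_band])])
    around = (freqs >= peak_hz - 1.5) & (freqs <= peak_hz + 1.5)
    total = float(np.trapezoid(pxx[in_band], freqs[in_band]))
    osc = float(np.trapezoid(pxx[around & in_band], freqs[around & in_band]) / total) if total > 0 else 0.0
    amplitude = float(kept.max() - kept.min())
    label = "SWD" if (osc > osc_threshold and amplitude > amp_floor_hz) else "AI"
    return RegimeMetrics(label=label, peak_hz=peak_hz,
                         oscillation_index=osc, amplitude_hz=amplitude)


def scan_adaptation(b_grid, params: NodeParams, coeffs: TransferCoefficients,
                    duration: float = 11.0, dt: float = 0.1, noise_std: float = 0.5,
                    seed: int = 0, transient_s: float = 1.0):
    """Simulate the node across an adaptation-strength grid.

    Returns a list of dicts (b_pA, regime, peak_hz, amplitude_hz),
    one per grid value, all sharing the same seed policy.  Used once to
    calibrate the shipped interictal/ictal ``b`` defaults.
    """
    b_grid = list(b_grid)
    if len(b_grid) < 3 and len(b_grid) != 1:
        raise ValueError("b_grid needs >= 3 points (or exactly 1)")
    if any(b2 <= b1 for b1, b2 in zip(b_grid, b_grid[1:])):
        raise ValueError("b_grid must be sorted ascending")
    rows = []
    fs = 1e3 / dt
    for b in b_grid:
        try:
            sim = simulate_node(params.replace(b=b), coeffs, duration, dt=dt,
                                noise_std=noise_std, seed=seed)
            metrics = classify_regime(sim["nu_e"], fs, transient_s=transient_s)
        except (FloatingPointError, ValueError) as exc:
            raise RuntimeError(f"simulation failed at b={b}: {exc}") from exc
        rows.append({
            "b_pA": float(b),
            "regime": metrics.label,
            "peak_hz": metrics.peak_hz,
            "amplitude_hz": metrics.amplitude_hz,
            "oscillation_index": metrics.oscillation_index,
        })
    return rows
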