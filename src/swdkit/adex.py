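"""Monte-Carlo single-neuron AdEx oracle.

A direct Euler simulation of one adaptive-exponential integrate-and-fire
neuron receiving Poissonian conductance bombardment.  It is deliberately
independent of the mean-field equations: it is used to validate the
semi-analytic membrane statistics and to generate the rate grids from
which the transfer-function coefficients are fitted.  Simulations are
vectorized across input-grid points and seeds (one virtual neuron per
column), which keeps the brute-force oracle desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import NodeParams, Population

__all__ = ["SpikeParams", "membrane_stats_mc", "firing_rate_mc", "oracle_grid"]


@dataclass(frozen=True)
class SpikeParams:
    """AdEx spiking mechanism parameters (not part of the mean-field state)."""

    V_T: float = -50.0      # threshold of the exponential term, mV
    Delta_T: float = 2.0    # spike sharpness, mV (use ~0.5 for fast-spiking)
    V_reset: float = -65.0  # post-spike reset, mV
    t_ref: float = 5.0      # absolute refractory period, ms

    @classmethod
    def for_population(cls, population: Population) -> "SpikeParams":
        if population == "i":
            return cls(Delta_T=0.5, V_T=-50.0, V_reset=-65.0, t_ref=5.0)
        return cls()


def _run(params: NodeParams, population: Population, nu_e, nu_i, W, duration_s,
         dt, seed, spiking: bool, spike: SpikeParams | None):
    """Shared integration loop; returns (V samples, spike counts)."""
    nu_e = np.atleast_1d(np.asarray(nu_e, dtype=float))
    nu_i = np.atleast_1d(np.asarray(nu_i, dtype=float))
    W = np.broadcast_to(np.asarray(W, dtype=float), nu_e.shape).astype(float)
    n = nu_e.size
    rng = np.random.default_rng(seed)
    E_L = params.E_L(population)
    spike = spike or SpikeParams.for_population(population)

    lam_e = params.K_e * nu_e * 1e-3 * dt  # expected presynaptic events per step
    lam_i = params.K_i * nu_i * 1e-3 * dt
    dec_e = np.exp(-dt / params.tau_e)
    dec_i = np.exp(-dt / params.tau_i)
    n_steps = int(round(duration_s * 1e3 / dt))
    warmup = int(round(0.5e3 / dt))  # discard 500 ms

    V = np.full(n, E_L)
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    ref = np.zeros(n)  # remaining refractory time, ms
    counts = np.zeros(n)
    sum_V = np.zeros(n)
    sum_V2 = np.zeros(n)
    n_kept = 0
    v_cut = spike.V_T + 5.0 * spike.Delta_T

    for k in range(n_steps):
        g_e = g_e * dec_e + params.Q_e * rng.poisson(lam_e)
        g_i = g_i * dec_i + params.Q_i * rng.poisson(lam_i)
        I_exp = (
            params.g_L * spike.Delta_T * np.exp(np.minimum((V - spike.V_T) / spike.Delta_T, 20.0))
            if spiking else 0.0
        )
        dV = (
            -params.g_L * (V - E_L) + I_exp
            - g_e * (V - params.E_e) - g_i * (V - params.E_i) - W
        ) / params.C_m
        active = ref <= 0
        V = np.where(active, V + dt * dV, V)
        ref = np.maximum(ref - dt, 0.0)
        if spiking:
            fired = V >= v_cut
            counts += fired & (k >= warmup)
            V = np.where(fired, spike.V_reset, V)
            ref = np.where(fired, spike.t_ref, ref)
        if k >= warmup:
            sum_V += V
            sum_V2 += V * V
            n_kept += 1

    mean_V = sum_V / n_kept
    std_V = np.sqrt(np.maximum(sum_V2 / n_kept - mean_V**2, 0.0))
    rate = counts / (duration_s - 0.5)
    return mean_V, std_V, rate


def membrane_stats_mc(params: NodeParams, nu_e, nu_i, W=0.0, population: Population = "e",
                      duration_s: float = 5.0, dt: float = 0.05, seed: int = 0):
    """Empirical (mean, std) of the free membrane potential (mV).

    Integrates the passive membrane (no spike mechanism) under Poisson
    conductance input; the oracle counterpart of
    :func:`swdkit.meanfield.conductance_stats`.
    """
    mean_V, std_V, _ = _run(params, population, nu_e, nu_i, W, duration_s, dt,
                            seed, spiking=False, spike=None)
    return mean_V, std_V


def firing_rate_mc(params: NodeParams, nu_e, nu_i, W=0.0, population: Population = "e",
                   duration_s: float = 10.0, dt: float = 0.05, seeds=(0, 1, 2, 3, 4),
                   spike: SpikeParams | None = None):
    """Monte-Carlo firing rate (Hz) of the AdEx neuron, averaged over seeds."""
    rates = []
    for s in seeds:
        *_, rate = _run(params, population, nu_e, nu_i, W, duration_s, dt, s,
                        spiking=True, spike=spike)
        rates.append(rate)
    return np.mean(rates, axis=0)


def oracle_grid(params: NodeParams, population: Population = "e",
                nu_e_values=(0.5, 1, 2, 3, 5, 8, 12, 16, 20),
                nu_i_values=(1, 3, 6, 10, 16, 24),
                W_values=(0.0, 30.0, 60.0), duration_s: float = 10.0, dt: float = 0.05,
                seeds=(0, 1, 2)):
    """Sample the single-neuron rate surface on an input grid.

    Returns ``(grid, rates)`` with grid columns (nu_e Hz, nu_i Hz, W pA),
    directly consumable by
    :func:`swdkit.meanfield.fit_transfer_coefficients`.
    """
    pts = np.array([(e, i, w) for w in W_values for e in nu_e_values for i in nu_i_values])
    rates = firing_rate_mc(params, pts[:, 0], pts[:, 1], pts[:, 2], population,
                           duration_s=duration_s, dt=dt, seeds=seeds)
    return pts, rates
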