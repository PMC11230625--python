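"""Whole-brain network simulation of coupled mean-field regions.

Regions (one AdEx mean-field node each) are coupled through a directed
weighted connectome; long-range connections are excitatory and feed the
excitatory input of both target populations (switchable).  Sensory
stimulation is a periodic square pulse train added to the excitatory
input of the target regions, and responsiveness is quantified per region
by a paired block-vs-baseline statistic over repeated stimulation
trials, corrected for multiple comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import meanfield
from .params import NodeParams, TransferCoefficients, ictal_params, interictal_params

__all__ = [
    "Connectome",
    "StimulusProtocol",
    "SimulationConfig",
    "SimulationResult",
    "RegionStats",
    "build_stimulus",
    "simulate_network",
    "responsiveness_map",
    "count_significant",
    "grid_layout",
]


@dataclass
class Connectome:
    """Directed weighted region-to-region coupling (row = target)."""

    weights: np.ndarray
    labels: list
    delays: np.ndarray | None = None  # ms

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if self.weights.shape[0] < 2:
            raise ValueError("connectome needs >= 2 regions")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")
        self.labels = list(self.labels)
        if len(self.labels) != self.weights.shape[0]:
            raise ValueError("label count must match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.delays is not None:
            self.delays = np.asarray(self.delays, dtype=float)
            if self.delays.shape != self.weights.shape or np.any(self.delays < 0):
                raise ValueError("delays must match weights shape and be >= 0")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def row_normalized(self) -> np.ndarray:
        """Incoming weights scaled to unit row sum (zero rows stay zero)."""
        sums = self.weights.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, self.weights / np.where(sums > 0, sums, 1.0), 0.0)


@dataclass
class StimulusProtocol:
    """Square-pulse stimulation of target regions.

    Defaults mirror the visual protocol: 3 Hz pulse trains of 166 ms
    pulses in 6 s blocks.
    """

    target_regions: list = field(default_factory=lambda: ["V1"])
    amplitude: float = 20.0       # Hz of added excitatory drive
    pulse_freq: float = 3.0       # Hz
    pulse_width: float = 166.0    # ms
    block_duration: float = 6.0   # s
    onsets: list = field(default_factory=list)  # s

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.pulse_width >= 1e3 / self.pulse_freq:
            raise ValueError("pulse_width must be shorter than the pulse period")
        self.onsets = sorted(float(t) for t in self.onsets)
        for t0, t1 in zip(self.onsets, self.onsets[1:]):
            if t1 < t0 + self.block_duration:
                raise ValueError("stimulation blocks must not overlap")


@dataclass
class SimulationConfig:
    dt: float = 0.1                 # ms
    duration: float = 10.0          # s
    transient_discard: float = 1.0  # s
    coupling_scale: float = 0.05    # S, dimensionless
    noise_std: float = 0.5          # Hz
    seed: int = 0
    state: str = "interictal"       # selects the adaptation-strength default
    couple_to_inhibitory: bool = False
    record_stride: int = 1          # keep every k-th sample

    def __post_init__(self):
        if self.dt <= 0 or self.dt > 0.5:
            raise ValueError("dt must lie in (0, 0.5] ms")
        if self.duration <= self.transient_discard:
            raise ValueError("duration must exceed transient_discard")
        if self.coupling_scale < 0:
            raise ValueError("coupling_scale must be >= 0")

    def node_params(self, **overrides) -> NodeParams:
        if self.state == "ictal":
            return ictal_params(**overrides)
        if self.state == "interictal":
            return interictal_params(**overrides)
        raise ValueError(f"unknown state '{self.state}'")


@dataclass
class SimulationResult:
    """Per-region time series (transient already discarded)."""

    time: np.ndarray      # s
    nu_e: np.ndarray      # (n_regions, n_samples) Hz
    nu_i: np.ndarray
    W: np.ndarray
    mu_V: np.ndarray
    labels: list
    config: SimulationConfig
    seed_children: list   # per-region entropy used for the noise streams


def build_stimulus(protocol: StimulusProtocol, time_grid, labels) -> np.ndarray:
    """Per-region stimulus series (Hz) on a uniform time grid (s).

    Values are exactly 0 or ``amplitude``: within each block, pulses of
    ``pulse_width`` ms recur at ``pulse_freq`` Hz; regions outside
    ``target_regions`` receive zero.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size > 1:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
    series = np.zeros(t.size)
    period = 1.0 / protocol.pulse_freq
    width_s = protocol.pulse_width * 1e-3
    t_end = t[-1] if t.size else 0.0
    for onset in protocol.onsets:
        if onset + protocol.block_duration > t_end + 1e-9:
            raise ValueError(f"stimulation block at {onset} s extends past the grid end")
        rel = t - onset
        in_block = (rel >= 0) & (rel < protocol.block_duration)
        in_pulse = np.mod(rel, period) < width_s
        series[in_block & in_pulse] = protocol.amplitude
    out = np.zeros((len(labels), t.size))
    for name in protocol.target_regions:
        if name not in labels:
            raise ValueError(f"protocol target '{name}' not in connectome labels")
        out[list(labels).index(name)] = series
    return out


def _spawn_streams(seed, n):
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children], children


def _integrate(weights_norm, params, coeffs, stim, config: SimulationConfig,
               labels, couple: bool, delays_ms=None):
    """Vectorized stochastic-Heun loop over all regions.

    Mirrors :func:`swdkit.meanfield.step_node` arithmetic exactly (same
    drift function, clipping and noise placement), so a decoupled run
    reproduces the single-node integrator bit-for-bit given the same
    per-region noise stream.  With ``delays_ms`` the coupling reads each
    source's excitatory rate from a ring buffer of its past.
    """
    n = len(labels)
    dt = config.dt
    n_steps = int(round(config.duration * 1e3 / dt))
    rngs, children = _spawn_streams(config.seed, n)
    scale = config.noise_std * np.sqrt(params.T / dt)

    nu_e = np.full(n, 2.0)
    nu_i = np.full(n, 10.0)
    W = np.zeros(n)
    stride = config.record_stride
    n_rec = n_steps // stride
    rec = {k: np.empty((n, n_rec)) for k in ("nu_e", "nu_i", "W", "mu_V")}

    d_steps = None
    if delays_ms is not None and np.any(delays_ms > 0):
        d_steps = np.round(np.asarray(delays_ms) / dt).astype(int)
        ring_len = int(d_steps.max()) + 1
        ring = np.tile(nu_e, (ring_len, 1))  # (L, n) past excitatory rates
        head = 0

    chunk = 4096
    noise_buf = np.empty((n, chunk))
    buf_pos = chunk
    S = config.coupling_scale
    cap = params.rate_cap
    for k in range(n_steps):
        if buf_pos == chunk:
            for j, rng in enumerate(rngs):
                noise_buf[j] = rng.normal(0.0, scale, chunk)
            buf_pos = 0
        noise = noise_buf[:, buf_pos]
        buf_pos += 1

        if weights_norm is not None and S > 0:
            if d_steps is None:
                aff = S * (weights_norm @ nu_e)
            else:
                past = ring[(head - d_steps) % ring_len, np.arange(n)[None, :]]
                aff = S * (weights_norm * past).sum(axis=1)
        else:
            aff = 0.0
        stim_k = stim[:, k] if stim is not None else 0.0
        aff_e = aff + stim_k
        # long-range coupling and stimulation are excitatory; by default
        # they target only the excitatory population (couple=True routes
        # them to the inhibitory population as well)
        aff_e_i = None if couple else 0.0
        d1 = meanfield._drift(nu_e, nu_i, W, aff_e, 0.0, params, coeffs, aff_e_i)
        ne_p = np.clip(nu_e + dt * (d1[0] + noise / params.T), 0.0, cap)
        ni_p = np.clip(nu_i + dt * d1[1], 0.0, cap)
        W_p = W + dt * d1[2]
        d2 = meanfield._drift(ne_p, ni_p, W_p, aff_e, 0.0, params, coeffs, aff_e_i)
        nu_e = np.clip(nu_e + 0.5 * dt * (d1[0] + d2[0]) + dt * noise / params.T, 0.0, cap)
        nu_i = np.clip(nu_i + 0.5 * dt * (d1[1] + d2[1]), 0.0, cap)
        W = W + 0.5 * dt * (d1[2] + d2[2])
        if not np.all(np.isfinite(nu_e)) or not np.all(np.isfinite(W)):
            bad = int(np.argmax(~np.isfinite(nu_e + W)))
            raise FloatingPointError(
                f"numerical blow-up in region '{labels[bad]}' at t={k * dt * 1e-3:.3f} s"
            )
        if d_steps is not None:
            head = (head + 1) % ring_len
            ring[head] = nu_e
        if (k + 1) % stride == 0:
            j = k // stride
            rec["nu_e"][:, j] = nu_e
            rec["nu_i"][:, j] = nu_i
            rec["W"][:, j] = W
            rec["mu_V"][:, j] = d2[3]
    t = (np.arange(n_rec) + 1) * stride * dt * 1e-3
    return rec, t, children


def simulate_network(connectome: Connectome, params: NodeParams,
                     protocol: StimulusProtocol | None,
                     config: SimulationConfig,
                     coeffs: TransferCoefficients,
                     discard_transient: bool = True) -> SimulationResult:
    """Simulate the coupled network; bit-reproducible given the seed.

    The excitatory afferent of region k is
    ``S * sum_j w_norm[k, j] * nu_e_j + stimulus_k(t)`` on top of the
    node's own recurrent input and ambient drive.  With
    ``discard_transient`` the leading ``config.transient_discard``
    seconds are dropped from the returned series.
    """
    n_steps = int(round(config.duration * 1e3 / config.dt))
    if protocol is not None and protocol.onsets:
        t_grid = np.arange(n_steps) * config.dt * 1e-3
        stim = build_stimulus(protocol, t_grid, connectome.labels)
    else:
        stim = None
    rec, t, children = _integrate(connectome.row_normalized(), params, coeffs, stim,
                                  config, connectome.labels, config.couple_to_inhibitory,
                                  delays_ms=connectome.delays)
    if discard_transient:
        keep = t >= config.transient_discard
        rec = {k: v[:, keep] for k, v in rec.items()}
        t = t[keep]
    return SimulationResult(time=t, nu_e=rec["nu_e"], nu_i=rec["nu_i"], W=rec["W"],
                            mu_V=rec["mu_V"], labels=list(connectome.labels),
                            config=config, seed_children=[c.entropy for c in children])


@dataclass
class RegionStats:
    """Per-region stimulus responsiveness statistics."""

    table: pd.DataFrame   # columns: region, effect_hz, t, z, p, p_corrected, significant, flat
    alpha: float
    n_trials: int
    method: str = "ttest"

    def __iter__(self):  # convenience for tests
        return iter(self.table.itertuples())


def _bh_correct(p):
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def responsiveness_map(connectome: Connectome, params: NodeParams,
                       protocol: StimulusProtocol, config: SimulationConfig,
                       coeffs: TransferCoefficients, n_trials: int = 10,
                       alpha: float = 0.05, method: str = "ttest",
                       n_permutations: int = 999) -> RegionStats:
    """Paired block-vs-baseline responsiveness statistic per region.

    ``n_trials`` stimulation blocks are placed in one continuous
    simulation, each preceded by an equal-length baseline window.  Per
    region, the trial-wise differences (block-mean minus baseline-mean
    of nu_e) enter a paired t-test (or sign-flip permutation test) and
    p-values are Benjamini-Hochberg corrected at ``alpha``.
    """
    if n_trials < 10:
        raise ValueError("n_trials must be >= 10")
    bd = protocol.block_duration
    gap = 2.0 * bd + 1.0  # baseline + block + 1 s settling between trials
    t0 = config.transient_discard + bd + 0.5
    onsets = [t0 + i * gap for i in range(n_trials)]
    duration = onsets[-1] + bd + 1.0
    protocol = replace(protocol, onsets=onsets)
    config = replace(config, duration=duration)
    sim = simulate_network(connectome, params, protocol, config, coeffs)

    diffs = np.empty((connectome.n, n_trials))
    for i, onset in enumerate(onsets):
        in_block = (sim.time >= onset) & (sim.time < onset + bd)
        in_base = (sim.time >= onset - bd) & (sim.time < onset)
        diffs[:, i] = sim.nu_e[:, in_block].mean(axis=1) - sim.nu_e[:, in_base].mean(axis=1)

    effect = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    flat = sd < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = np.where(flat, 0.0, effect / np.where(flat, 1.0, sd / np.sqrt(n_trials)))
    if method == "ttest":
        p = 2.0 * sstats.t.sf(np.abs(tstat), df=n_trials - 1)
    elif method == "permutation":
        rng = np.random.default_rng(config.seed + 1)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_trials))
        null = np.abs(signs @ diffs.T / n_trials)  # (n_perm, n_regions)
        p = (1.0 + np.sum(null >= np.abs(effect)[None, :], axis=0)) / (n_permutations + 1.0)
    else:
        raise ValueError(f"unknown method '{method}'")
    p = np.where(flat, 1.0, p)
    p_corr = _bh_correct(p)
    significant = (p_corr < alpha) & ~flat
    z = sstats.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0) * np.sign(effect)
    table = pd.DataFrame({
        "region": connectome.labels,
        "effect_hz": effect,
        "t": tstat,
        "z": z,
        "p": p,
        "p_corrected": p_corr,
        "significant": significant,
        "flat": flat,
    })
    return RegionStats(table=table, alpha=alpha, n_trials=n_trials, method=method)


def count_significant(stats: RegionStats) -> int:
    """Number of regions flagged significant."""
    return int(stats.table["significant"].sum())


def grid_layout(labels) -> dict:
    """Deterministic row-major placement of regions on a near-square grid."""
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    ncols = math.ceil(math.sqrt(len(labels)))
    return {name: divmod(i, ncols) for i, name in enumerate(labels)}
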