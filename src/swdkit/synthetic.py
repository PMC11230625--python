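"""Synthetic-data generators with exact ground truth.

Every generator is a pure function of (parameters, seed) and returns a
SyntheticTruth record sufficient to score any downstream analysis stage:
modular log-normal connectomes, 1/f EEG with embedded spike-and-wave
epochs, stimulation schedules targeting ictal/interictal periods, and
4D fMRI volumes with known region-wise beta maps, gamma HRFs, AR(1)
noise and motion spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .eeg import EEGTrace, SeizureInterval, StimulationBlock
from .network import Connectome
from .signals import HRFBasis, gamma_basis

__all__ = [
    "SyntheticTruth",
    "make_connectome",
    "make_eeg",
    "make_stim_schedule",
    "make_fmri",
]


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic fixture."""

    seed: int
    params: dict = field(default_factory=dict)
    seizure_intervals: list = field(default_factory=list)   # SeizureInterval
    blocks: list = field(default_factory=list)              # StimulationBlock
    intended_states: list = field(default_factory=list)     # per block
    beta_maps: dict = field(default_factory=dict)           # cond -> (mask, betas)
    motion_spike_frames: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "params": self.params,
            "seizure_intervals": [[iv.start, iv.end] for iv in self.seizure_intervals],
            "blocks": [[b.onset, b.duration, b.label] for b in self.blocks],
            "intended_states": list(self.intended_states),
            "motion_spike_frames": list(map(int, self.motion_spike_frames)),
        }
        d["beta_maps"] = {
            cond: {"voxels": np.argwhere(mask).tolist(), "betas": list(map(float, betas))}
            for cond, (mask, betas) in self.beta_maps.items()
        }
        return d


def make_connectome(n_regions: int = 496, n_modules: int = 8,
                    weight_lognorm_params=(0.0, 1.0), density: float = 0.1,
                    seed: int = 0) -> Connectome:
    """Modular directed connectome with log-normal weights.

    Connections are denser within modules (4x the between-module
    probability, capped at 1) while matching the requested overall
    ``density`` in expectation.  Labels are atlas-like; a primary visual
    ("V1") and barrel-field ("S1BF") region are always present so
    stimulation protocols can target them by name.
    """
    if n_regions < 2:
        raise ValueError("need >= 2 regions")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    modules = np.arange(n_regions) % n_modules
    same = modules[:, None] == modules[None, :]
    f_within = same.mean()
    # p_within = min(4 p_between, 1); solve for overall expected density
    p_between = density / (4 * f_within + (1 - f_within))
    p_within = 4 * p_between
    if p_within > 1.0:
        p_within = 1.0
        p_between = (density - f_within) / (1 - f_within) if f_within < 1 else 1.0
        if p_between < 0:
            raise ValueError(
                "density incompatible with module structure: within-module "
                "pairs alone exceed the requested density"
            )
    p = np.where(same, p_within, p_between)
    np.fill_diagonal(p, 0.0)
    mu, sigma = weight_lognorm_params
    weights = (rng.random((n_regions, n_regions)) < p) * rng.lognormal(
        mu, sigma, (n_regions, n_regions)
    )
    labels = ["V1", "S1BF"] + [f"R{i:03d}" for i in range(2, n_regions)]
    return Connectome(weights=weights, labels=labels[:n_regions])


def _one_over_f(n: int, fs: float, exponent: float, rng) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / np.sqrt(np.mean(x**2))


def _spike_wave(t: np.ndarray, freq: float) -> np.ndarray:
    """Periodic sharp-spike/slow-wave waveform (fundamental + 2 harmonics).

    Cosine harmonics with aligned phase add constructively once per
    cycle, producing the spike; the remainder of the cycle is the wave.
    """
    w = (np.cos(2 * np.pi * freq * t)
         + 0.6 * np.cos(2 * np.pi * 2 * freq * t)
         + 0.35 * np.cos(2 * np.pi * 3 * freq * t))
    return w / np.sqrt(np.mean(w**2))


def make_eeg(duration: float, fs: float = 1024.0, seizure_schedule=(),
             swd_freq: float = 8.0, amp_ratio: float = 3.0,
             noise_exponent: float = 1.0, rms_uV: float = 20.0,
             seed: int = 0):
    """EEG trace: 1/f background with embedded spike-and-wave epochs.

    Each scheduled (start, end) epoch receives an additive spike-wave
    waveform at ``swd_freq`` scaled to ``amp_ratio`` times the
    background RMS.  Returns ``(EEGTrace, SyntheticTruth)``; the truth
    lists the exact epoch boundaries.
    """
    if not 1.0 < swd_freq < fs / 4:
        raise ValueError("swd_freq must lie in (1, fs/4)")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    x = _one_over_f(n, fs, noise_exponent, rng)
    t = np.arange(n) / fs
    intervals = []
    for start, end in seizure_schedule:
        if end > duration or start < 0:
            raise ValueError(f"scheduled epoch ({start}, {end}) outside the trace")
        sel = (t >= start) & (t < end)
        x[sel] += amp_ratio * _spike_wave(t[sel] - start, swd_freq)
        intervals.append(SeizureInterval(float(start), float(end)))
    trace = EEGTrace(samples=x * rms_uV, fs=fs)
    truth = SyntheticTruth(
        seed=seed,
        params={"duration": duration, "fs": fs, "swd_freq": swd_freq,
                "amp_ratio": amp_ratio, "noise_exponent": noise_exponent},
        seizure_intervals=intervals,
    )
    return trace, truth


def make_stim_schedule(duration: float, seizure_intervals,
                       block_duration: float = 6.0, min_gap: float = 20.0,
                       policy: str = "alternate", clearance: float = 5.0,
                       seed: int = 0):
    """Stimulation blocks targeting ictal and interictal periods.

    The default policy alternates between onsets placed inside scheduled
    seizures (ictal) and onsets at least ``clearance`` s away from any
    seizure (interictal), with >= ``min_gap`` s between consecutive
    blocks, emulating manual stimulation aiming for equal sampling of
    both states.  Returns ``(blocks, truth)`` where the truth records
    each block's intended state.
    """
    if policy not in ("alternate", "interictal_only", "ictal_only"):
        raise ValueError(f"unknown targeting policy '{policy}'")
    seizures = sorted(seizure_intervals)
    rng = np.random.default_rng(seed)

    def is_ictal_onset(t):
        return any(s.start <= t and t < s.end for s in seizures)

    def is_clear(t):
        a, b = t - clearance, t + block_duration + clearance
        return all(s.end <= a or s.start >= b for s in seizures)

    blocks, states = [], []
    want_ictal = policy in ("alternate", "ictal_only") and bool(seizures)
    t = clearance
    step = 0.25
    while t + block_duration <= duration:
        target = "ictal" if want_ictal else "interictal"
        ok = is_ictal_onset(t) if target == "ictal" else is_clear(t)
        if ok:
            blocks.append(StimulationBlock(onset=round(t, 3), duration=block_duration))
            states.append(target)
            if policy == "alternate" and seizures:
                want_ictal = not want_ictal
            t += block_duration + min_gap + step * rng.integers(0, 8)
        else:
            t += step
    if len(blocks) < 2:
        raise ValueError(
            "infeasible schedule: fewer than 2 blocks fit; binding constraint is "
            + ("seizure availability for ictal targeting" if want_ictal
               else f"duration vs block+min_gap ({block_duration}+{min_gap} s)")
        )
    truth = SyntheticTruth(
        seed=seed,
        params={"duration": duration, "block_duration": block_duration,
                "min_gap": min_gap, "policy": policy, "clearance": clearance},
        seizure_intervals=list(seizures),
        blocks=blocks,
        intended_states=states,
    )
    return blocks, truth


def default_roi_mask(dims, corner, size) -> np.ndarray:
    mask = np.zeros(dims, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    mask[sl] = True
    return mask


def make_fmri(dims=(20, 20, 12), TR: float = 2.0, n_volumes: int = 150,
              design_events=None, roi_beta_maps=None,
              basis: HRFBasis | None = None, noise_sigma: float = 0.5,
              ar1: float = 0.3, motion_spikes=(), motion_spike_mm: float = 0.5,
              baseline: float = 100.0, seed: int = 0):
    """Synthetic 4D fMRI with known effects.

    Parameters
    ----------
    design_events : dict condition -> list of (onset_s, duration_s)
    roi_beta_maps : dict condition -> (bool mask of ``dims``, 3 betas)
        Per-condition region and basis-function weights; the injected
        voxel signal is sum_k beta_k * (boxcar * basis_k)(t).
    motion_spikes : frame indices receiving a simultaneous jump in the
        motion parameters and an intensity artifact.

    Returns
    -------
    (img, motion, truth) : nibabel Nifti1Image (float32), pandas
    DataFrame with columns trans_x/y/z_mm and rot_x/y/z_deg, and the
    serialized SyntheticTruth.

    Notes
    -----
    Defaults are desk-scale; a full 45 min acquisition at the 2 s
    volume time corresponds to ``n_volumes=1350``.
    """
    import nibabel as nib

    design_events = design_events or {}
    roi_beta_maps = roi_beta_maps or {}
    basis = basis or gamma_basis(TR=TR)
    rng = np.random.default_rng(seed)
    dims = tuple(dims)
    n_vox = int(np.prod(dims))
    frame_times = np.arange(n_volumes) * TR

    # dense-grid convolution of condition boxcars with each basis column
    from .glm import condition_regressors

    signal = np.zeros((n_volumes, n_vox))
    truth_maps = {}
    for cond, (mask, betas) in roi_beta_maps.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dims:
            raise ValueError(f"ROI mask for '{cond}' does not match volume dims")
        if not mask.any():
            raise ValueError(f"ROI mask for '{cond}' is empty")
        events = design_events.get(cond, [])
        for onset, dur in events:
            if onset + dur > n_volumes * TR:
                raise ValueError(f"event ({onset}, {dur}) of '{cond}' outside the run")
        reg = condition_regressors(events, basis, frame_times)  # (T, 3)
        betas = np.asarray(betas, dtype=float)
        signal[:, mask.ravel()] += (reg @ betas)[:, None]
        truth_maps[cond] = (mask, betas)

    noise = np.zeros((n_volumes, n_vox))
    eps = rng.standard_normal((n_volumes, n_vox)) * noise_sigma
    if noise_sigma > 0:
        noise[0] = eps[0] / np.sqrt(max(1 - ar1**2, 1e-12))
        for k in range(1, n_volumes):
            noise[k] = ar1 * noise[k - 1] + eps[k]

    data = baseline + signal + noise

    # motion: slow sub-micrometre random walk (matching well-habituated
    # awake-rat recordings) plus spikes (parameter jump + artifact)
    motion = np.cumsum(rng.standard_normal((n_volumes, 6)) * 1e-4, axis=0)
    motion_spikes = sorted(int(f) for f in motion_spikes)
    for f in motion_spikes:
        if not 0 <= f < n_volumes:
            raise ValueError(f"motion spike frame {f} outside the run")
        motion[f:, :3] += motion_spike_mm
        motion[f:, 3:] += motion_spike_mm * 2.0
        data[f] += rng.standard_normal(n_vox) * 5.0 * max(noise_sigma, 0.1)

    vol = data.T.reshape(dims + (n_volumes,)).astype(np.float32)
    img = nib.Nifti1Image(vol, affine=np.diag([0.5, 0.5, 1.0, 1.0]))
    img.header.set_zooms((0.5, 0.5, 1.0, TR))
    motion_df = pd.DataFrame(
        motion,
        columns=["trans_x_mm", "trans_y_mm", "trans_z_mm",
                 "rot_x_deg", "rot_y_deg", "rot_z_deg"],
    )
    truth = SyntheticTruth(
        seed=seed,
        params={"dims": list(dims), "TR": TR, "n_volumes": n_volumes,
                "noise_sigma": noise_sigma, "ar1": ar1,
                "basis_shapes": [list(s) for s in basis.shapes]},
        beta_maps=truth_maps,
        motion_spike_frames=motion_spikes,
    )
    return img, motion_df, truth
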