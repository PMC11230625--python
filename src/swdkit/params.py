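"""Parameter containers for the AdEx mean-field model.

Unit conventions throughout the package: membrane potentials in mV,
conductances in nS, capacitance in pF, currents in pA, time constants in
ms, population rates in Hz at every public interface (converted to kHz
internally where a rate multiplies a time constant in ms).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import yaml

Population = Literal["e", "i"]


@dataclass(frozen=True)
class NodeParams:
    """Biophysical parameters of one mean-field node (two populations).

    The node lumps an excitatory (regular-spiking, adapting) and an
    inhibitory (fast-spiking) population coupled by conductance-based
    synapses; ``b`` sets the spike-triggered adaptation strength that
    switches the node between asynchronous-irregular and spike-and-wave
    regimes.
    """

    g_L: float = 10.0          # leak conductance, nS
    E_L_e: float = -64.0       # excitatory leak reversal, mV
    E_L_i: float = -65.0       # inhibitory leak reversal, mV
    C_m: float = 200.0         # membrane capacitance, pF
    E_e: float = 0.0           # excitatory synaptic reversal, mV
    E_i: float = -80.0         # inhibitory synaptic reversal, mV
    Q_e: float = 1.5           # excitatory quantal conductance, nS
    Q_i: float = 3.0           # inhibitory quantal conductance, nS
    tau_e: float = 5.0         # excitatory synaptic time constant, ms
    tau_i: float = 5.0         # inhibitory synaptic time constant, ms
    N_tot: int = 10_000        # neurons per node
    p_conn: float = 0.05       # connection probability
    frac_exc: float = 0.8      # excitatory fraction
    T: float = 5.0             # population rate time constant, ms
    tau_w: float = 40.0        # adaptation time constant, ms
    b: float = 10.0            # spike-triggered adaptation increment, pA (per spike)
    a: float = 0.0             # subthreshold adaptation conductance, nS
    nu_ext: float = 1.0        # ambient external excitatory drive, Hz
    rate_cap: float = 200.0    # numerical guard on population rates, Hz

    def __post_init__(self) -> None:
        positive = ("g_L", "C_m", "Q_e", "Q_i", "tau_e", "tau_i", "T", "tau_w")
        for name in positive:
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"NodeParams.{name} must be finite and > 0")
        if not 0 < self.frac_exc < 1:
            raise ValueError("frac_exc must lie strictly between 0 and 1")
        if not 0 <= self.p_conn <= 1:
            raise ValueError("p_conn must lie in [0, 1]")
        if not self.E_i < self.E_L_e < self.E_e:
            raise ValueError("reversals must satisfy E_i < E_L_e < E_e")

    @property
    def K_e(self) -> float:
        """Number of excitatory synapses per neuron."""
        return self.p_conn * self.frac_exc * self.N_tot

    @property
    def K_i(self) -> float:
        """Number of inhibitory synapses per neuron."""
        return self.p_conn * (1.0 - self.frac_exc) * self.N_tot

    def E_L(self, population: Population) -> float:
        return self.E_L_e if population == "e" else self.E_L_i

    def replace(self, **changes) -> "NodeParams":
        return dataclasses.replace(self, **changes)


# Basis of the effective-threshold polynomial: a full second-order
# polynomial in the three normalized membrane statistics plus the triple
# cross term, 11 coefficients in total.
N_COEFFS = 11


@dataclass(frozen=True)
class TransferCoefficients:
    """Fitted effective-threshold polynomial for one population pair.

    ``P_e``/``P_i`` hold the 11 polynomial coefficients (mV) of the
    phenomenological firing threshold for the excitatory and inhibitory
    populations.  The normalization constants recentre the membrane
    statistics (mu_V, sigma_V, tau_V * mu_G / C_m) before the polynomial
    is evaluated.
    """

    P_e: tuple = ()
    P_i: tuple = ()
    mu_V0: float = -60.0     # mV
    d_mu_V0: float = 10.0    # mV
    sigma_V0: float = 4.0    # mV
    d_sigma_V0: float = 6.0  # mV
    tau_VN0: float = 0.5     # dimensionless (tau_V / tau_m_eff scale)
    d_tau_VN0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("P_e", "P_i"):
            P = getattr(self, name)
            if len(P) != N_COEFFS:
                raise ValueError(
                    f"{name} must hold exactly {N_COEFFS} coefficients, got {len(P)}"
                )
        for name in ("d_mu_V0", "d_sigma_V0", "d_tau_VN0"):
            if getattr(self, name) == 0:
                raise ValueError(f"normalization constant {name} must be nonzero")

    def P(self, population: Population) -> np.ndarray:
        return np.asarray(self.P_e if population == "e" else self.P_i, dtype=float)

    def to_dict(self) -> dict:
        return {
            "P_e": list(self.P_e),
            "P_i": list(self.P_i),
            "mu_V0": self.mu_V0,
            "d_mu_V0": self.d_mu_V0,
            "sigma_V0": self.sigma_V0,
            "d_sigma_V0": self.d_sigma_V0,
            "tau_VN0": self.tau_VN0,
            "d_tau_VN0": self.d_tau_VN0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferCoefficients":
        d = dict(d)
        d["P_e"] = tuple(d["P_e"])
        d["P_i"] = tuple(d["P_i"])
        return cls(**d)


@dataclass
class NodeState:
    """Instantaneous state of one node: rates, adaptation, mean potential."""

    nu_e: float = 2.0   # Hz
    nu_i: float = 10.0  # Hz
    W: float = 0.0      # pA
    mu_V: float = -64.0  # mV


def load_transfer_coefficients(path=None) -> TransferCoefficients:
    """Load transfer-function coefficients from YAML.

    Without ``path`` the coefficient set shipped with the package is used;
    it was produced by :func:`swdkit.meanfield.fit_transfer_coefficients`
    against the in-repo Monte-Carlo AdEx single-neuron oracle.
    """
    if path is None:
        text = (
            resources.files("swdkit.data")
            .joinpath("transfer_coefficients.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return TransferCoefficients.from_dict(yaml.safe_load(text))


def save_transfer_coefficients(coeffs: TransferCoefficients, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(coeffs.to_dict(), fh, sort_keys=False)


# Regime defaults.  The adaptation strengths were fixed once by running
# swdkit.meanfield.scan_adaptation over a b-grid with the parameters above:
# b_interictal sits comfortably inside the asynchronous-irregular plateau;
# b_ictal is the grid value whose spectral peak lies near the centre of the
# 7-12 Hz spike-and-wave band across seeds (see docs/methods.md).
B_INTERICTAL = 10.0
B_ICTAL = 700.0


def interictal_params(**overrides) -> NodeParams:
    """Shipped interictal (asynchronous-irregular) parameter set."""
    kw = {"b": B_INTERICTAL}
    kw.update(overrides)
    return NodeParams(**kw)


def ictal_params(**overrides) -> NodeParams:
    """Shipped ictal (spike-and-wave) parameter set."""
    kw = {"b": B_ICTAL}
    kw.update(overrides)
    return NodeParams(**kw)
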