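"""Model constants and mean-field construction.

All printed model parameters live here: adaptive exponential
integrate-and-fire (AdEx) neuron constants, exponential synapse kinetics,
population sizes, and the microscopic coupling table (connection
probabilities ``p_ab`` and strengths ``J_ab``).  From those this module
builds the macroscopic quantities of balanced-network theory: the balance
parameter ``epsilon = 1/(K_EX * J_EX)``, the normalized recurrent and
feedforward connectivity matrices ``W`` and ``W_X``, and the rescaled
external drive ``X``.

Conventions
-----------
* All currents are expressed per membrane capacitance, in mV/ms, so the
  capacitance never appears explicitly.
* ``epsilon`` is stored as a pure number; since ``K*J`` carries mV, its
  reciprocal carries 1/mV.
* Rates are in Hz, times in ms, potentials in mV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .exceptions import ParameterError

__all__ = [
    "NeuronParams",
    "SynapseKinetics",
    "PopulationSizes",
    "CouplingTable",
    "MeanFieldMatrices",
    "compute_epsilon",
    "build_meanfield",
    "scale_network",
    "psp_peak",
    "external_drive",
    "rescale_stimulus",
    "MV_MS_TO_MV_S",
    "default_config",
    "load_config",
    "RHEOBASE_DISPLAY",
    "REFERENCE_N",
]

#: Display divisor used to express synaptic currents in "rheobase units"
#: (rheobase per capacitance, mV/ms).  Presentation-only; affects no
#: computation.
RHEOBASE_DISPLAY = 10.5

#: Network size at which the printed coupling table applies unchanged.
REFERENCE_N = 5000

#: Rates are in Hz (1/s) while synaptic currents are quoted in mV/ms, so the
#: mean-field combination K*J*r carries mV/s; this factor converts a current
#: from mV/ms into those mean-field units (and back).
MV_MS_TO_MV_S = 1000.0

_POPS_POST = ("E", "I")
_POPS_PRE = ("E", "I", "X")


@dataclass(frozen=True)
class NeuronParams:
    """AdEx neuron constants.  Potentials in mV, times in ms.

    ``B`` is the adaptation increment per capacitance (mV/ms).
    """

    tau_m: float = 15.0
    E_L: float = -72.0
    V_T: float = -60.0
    V_th: float = -15.0
    Delta_T: float = 1.5
    V_re: float = -72.0
    V_lb: float = -100.0
    tau_ref: float = 1.0
    tau_w: float = 150.0
    B: float = 0.267

    def __post_init__(self) -> None:
        if not (self.V_lb < self.V_re <= self.E_L < self.V_T < self.V_th):
            raise ParameterError(
                "potentials must satisfy V_lb < V_re <= E_L < V_T < V_th"
            )
        for name in ("tau_m", "tau_ref", "tau_w"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.Delta_T <= 0:
            raise ParameterError("Delta_T must be positive")


@dataclass(frozen=True)
class SynapseKinetics:
    """Exponential synaptic kernel time constants, ms.

    Each kernel ``eta_b(t) = exp(-t/tau_b)/tau_b`` integrates to one, so the
    time constant does not affect time-averaged currents.
    """

    tau_E: float = 8.0
    tau_I: float = 4.0
    tau_X: float = 10.0

    def __post_init__(self) -> None:
        for name in ("tau_E", "tau_I", "tau_X"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    def tau(self, pop: str) -> float:
        return {"E": self.tau_E, "I": self.tau_I, "X": self.tau_X}[pop]


@dataclass(frozen=True)
class PopulationSizes:
    """Population counts and the stimulated fraction ``q``.

    The recurrent network holds ``N`` neurons, 80% excitatory; ``N_X``
    external neurons drive it.  ``q`` is the fraction of excitatory neurons
    targeted by partial stimulation.
    """

    N: int = 5000
    N_X: int = 4000
    q: float = 0.2

    def __post_init__(self) -> None:
        if self.N <= 0 or self.N_X <= 0:
            raise ParameterError("population counts must be positive")
        if not 0.0 <= self.q <= 1.0:
            raise ParameterError("q must lie in [0, 1]")

    @property
    def N_E(self) -> int:
        return int(round(0.8 * self.N))

    @property
    def N_I(self) -> int:
        return self.N - self.N_E

    def count(self, pop: str) -> int:
        return {"E": self.N_E, "I": self.N_I, "X": self.N_X}[pop]


def _default_p() -> dict:
    return {
        ("E", "E"): 0.1, ("E", "I"): 0.2, ("E", "X"): 0.2,
        ("I", "E"): 0.1, ("I", "I"): 0.2, ("I", "X"): 0.1,
    }


def _default_J() -> dict:
    return {
        ("E", "E"): 0.4, ("E", "I"): -1.67, ("E", "X"): 0.47,
        ("I", "E"): 0.83, ("I", "I"): -1.67, ("I", "X"): 0.47,
    }


@dataclass(frozen=True)
class CouplingTable:
    """Microscopic connectivity: ``p_ab`` (probability) and ``J_ab`` (mV).

    Keys are ordered pairs ``(post, pre)`` with post in {E, I} and pre in
    {E, I, X}.  Inhibitory strengths (pre = I) must be non-positive and all
    others non-negative.
    """

    p: Mapping = field(default_factory=_default_p)
    J: Mapping = field(default_factory=_default_J)

    def __post_init__(self) -> None:
        for a in _POPS_POST:
            for b in _POPS_PRE:
                if (a, b) not in self.p or (a, b) not in self.J:
                    raise ParameterError(f"coupling table missing pair ({a},{b})")
                pab = self.p[(a, b)]
                if not 0.0 <= pab <= 1.0:
                    raise ParameterError(f"p_{a}{b}={pab} outside [0, 1]")
                Jab = self.J[(a, b)]
                if b == "I" and Jab > 0:
                    raise ParameterError("inhibitory strengths must be <= 0")
                if b != "I" and Jab < 0:
                    raise ParameterError("excitatory strengths must be >= 0")

    def K(self, a: str, b: str, sizes: PopulationSizes) -> float:
        """Mean in-degree ``K_ab = p_ab * N_b``."""
        return self.p[(a, b)] * sizes.count(b)


@dataclass(frozen=True)
class MeanFieldMatrices:
    """Macroscopic connectivity for a population partition.

    ``W[i, j] = K_ij * J_ij / (K_EX * J_EX)`` and ``W_X`` is the feedforward
    column; by construction the excitatory external weight is one.  ``D`` is
    the diagonal inverse-gain matrix used by the linear rate correction.
    """

    epsilon: float
    W: np.ndarray
    W_X: np.ndarray
    partition: tuple

    def D(self, g) -> np.ndarray:
        """Inverse-gain matrix diag(1/g) in mean-field units.

        ``g`` is the rectified-linear gain in Hz per (mV/ms), scalar or
        per-population; since the mean-field drive W r + X carries mV/s, the
        diagonal is ``MV_MS_TO_MV_S / g``.
        """
        g_arr = np.broadcast_to(np.asarray(g, dtype=float), (len(self.partition),))
        if np.any(g_arr <= 0):
            raise ParameterError("gains must be positive")
        return np.diag(MV_MS_TO_MV_S / g_arr)


def compute_epsilon(coupling: CouplingTable, sizes: PopulationSizes) -> float:
    """Balance parameter ``epsilon = 1/(K_EX * J_EX)``.

    1/epsilon is the mean current a neuron in E would receive if every
    external neuron spiked once simultaneously; small epsilon means strong
    feedforward coupling.
    """
    KJ = coupling.K("E", "X", sizes) * coupling.J[("E", "X")]
    if KJ <= 0:
        raise ParameterError("K_EX * J_EX must be positive")
    return 1.0 / KJ


def build_meanfield(
    coupling: CouplingTable,
    sizes: PopulationSizes,
    partition: str = "EI",
) -> MeanFieldMatrices:
    """Construct (epsilon, W, W_X) for a population partition.

    Partitions
    ----------
    ``"EI"``
        The two-population matrix of the excitatory/inhibitory network.
    ``"exp-nexp-I"``
        Excitatory neurons split into a stimulated (expressing) fraction
        ``q`` and the remainder.  Local connectivity is independent of
        expression, so the expressing and non-expressing rows are identical
        while the columns carry factors ``q`` and ``1-q``; the resulting W is
        singular with a one-dimensional nullspace for q in (0, 1).
    """
    eps = compute_epsilon(coupling, sizes)
    KJ = 1.0 / eps

    def w(a: str, b: str) -> float:
        return coupling.K(a, b, sizes) * coupling.J[(a, b)] / KJ

    if partition == "EI":
        W = np.array([[w("E", "E"), w("E", "I")],
                      [w("I", "E"), w("I", "I")]])
        W_X = np.array([w("E", "X"), w("I", "X")])
        labels = ("E", "I")
    elif partition == "exp-nexp-I":
        q = sizes.q
        wEE, wEI = w("E", "E"), w("E", "I")
        wIE, wII = w("I", "E"), w("I", "I")
        W = np.array([
            [q * wEE, (1 - q) * wEE, wEI],
            [q * wEE, (1 - q) * wEE, wEI],
            [q * wIE, (1 - q) * wIE, wII],
        ])
        W_X = np.array([w("E", "X"), w("E", "X"), w("I", "X")])
        labels = ("exp", "nexp", "I")
    else:
        raise ParameterError(f"unknown partition {partition!r}")
    return MeanFieldMatrices(epsilon=eps, W=W, W_X=W_X, partition=labels)


def scale_network(
    coupling: CouplingTable, sizes: PopulationSizes, N_new: int
) -> tuple[CouplingTable, PopulationSizes]:
    """Rescale the network to ``N_new`` recurrent neurons.

    Population counts scale proportionally (preserving the 4:1 E:I ratio)
    and every ``J_ab`` and ``p_ab`` is multiplied by ``(5000/N_new)**(1/4)``,
    so the coupling table is unchanged at the reference size N = 5000 and
    epsilon scales like ``N**(-1/2)``.
    """
    if N_new <= 0:
        raise ParameterError("N_new must be positive")
    m = (REFERENCE_N / N_new) ** 0.25
    new_p = {k: v * m for k, v in coupling.p.items()}
    for k, v in new_p.items():
        if v > 1.0:
            raise ParameterError(
                f"scaled connection probability p_{k[0]}{k[1]}={v:.3f} exceeds 1"
            )
    new_J = {k: v * m for k, v in coupling.J.items()}
    factor = N_new / sizes.N
    new_sizes = replace(sizes, N=N_new, N_X=int(round(sizes.N_X * factor)))
    return CouplingTable(p=new_p, J=new_J), new_sizes


def psp_peak(J: float, tau_s: float, tau_m: float) -> float:
    """Peak deflection (mV) of a passive membrane to one synaptic event.

    Integrating ``dV/dt = -V/tau_m + J*eta(t)`` with the unit-integral
    exponential kernel gives a double exponential whose extremum lies at
    ``t* = tau_m*tau_s/(tau_m - tau_s) * ln(tau_m/tau_s)``.  The returned
    value is signed by J; the degenerate case ``tau_s == tau_m`` uses the
    alpha-function limit for continuity.
    """
    if tau_s <= 0 or tau_m <= 0:
        raise ParameterError("time constants must be positive")
    if J == 0:
        return 0.0
    if math.isclose(tau_s, tau_m, rel_tol=1e-12):
        # alpha-function limit: V(t) = J * (t/tau) * exp(-t/tau), peak at t=tau
        return J * math.exp(-1.0)
    t_star = tau_m * tau_s / (tau_m - tau_s) * math.log(tau_m / tau_s)
    amp = tau_m / (tau_m - tau_s) * (
        math.exp(-t_star / tau_m) - math.exp(-t_star / tau_s)
    )
    return J * amp


def rescale_stimulus(S: float, epsilon: float) -> float:
    """Rescaled stimulus ``s`` for a raw injected current S in mV/ms.

    The external drive X is measured in the same mV/s units as K*J*r, so
    ``s = epsilon * S * MV_MS_TO_MV_S``; the amplified rate response
    ``g*s/epsilon`` then reduces to the physical ``g * S``.
    """
    return epsilon * S * MV_MS_TO_MV_S


def external_drive(
    mf: MeanFieldMatrices,
    r_X: float,
    stim: Sequence[float] | None = None,
) -> np.ndarray:
    """Rescaled external input ``X = W_X * r_X + stim``.

    ``stim`` entries are the rescaled stimulus ``s`` from
    :func:`rescale_stimulus`.  For the two-population view of partial
    stimulation, pass ``s*q`` in the excitatory entry.
    """
    if r_X < 0:
        raise ParameterError("external rate must be non-negative")
    X = mf.W_X * float(r_X)
    if stim is not None:
        stim = np.asarray(stim, dtype=float)
        if stim.shape != X.shape:
            raise ParameterError("stimulus vector length must match partition")
        X = X + stim
    return X


# ---------------------------------------------------------------------------
# Config plumbing


def default_config() -> dict:
    """Config dict reproducing the printed parameter values."""
    return {
        "neuron": {
            "tau_m": 15.0, "E_L": -72.0, "V_T": -60.0, "V_th": -15.0,
            "Delta_T": 1.5, "V_re": -72.0, "V_lb": -100.0,
            "tau_ref": 1.0, "tau_w": 150.0, "B": 0.267,
        },
        "synapse": {"tau_E": 8.0, "tau_I": 4.0, "tau_X": 10.0},
        "sizes": {"N": 5000, "N_X": 4000, "q": 0.2},
        "coupling": {
            "p": {"EE": 0.1, "EI": 0.2, "EX": 0.2,
                  "IE": 0.1, "II": 0.2, "IX": 0.1},
            "J": {"EE": 0.4, "EI": -1.67, "EX": 0.47,
                  "IE": 0.83, "II": -1.67, "IX": 0.47},
        },
        "stimulus": {"S": 2.0, "r_X": 5.0, "onset_fraction": 0.5},
    }


def _parse_config(raw: dict) -> dict:
    cfg = default_config()
    for section in cfg:
        if section in raw:
            if section == "coupling":
                for tab in ("p", "J"):
                    cfg["coupling"][tab].update(raw["coupling"].get(tab, {}))
            else:
                cfg[section].update(raw[section])
    neuron = NeuronParams(**cfg["neuron"])
    kinetics = SynapseKinetics(**cfg["synapse"])
    sizes = PopulationSizes(**cfg["sizes"])
    coupling = CouplingTable(
        p={(k[0], k[1]): v for k, v in cfg["coupling"]["p"].items()},
        J={(k[0], k[1]): v for k, v in cfg["coupling"]["J"].items()},
    )
    return {
        "neuron": neuron,
        "kinetics": kinetics,
        "sizes": sizes,
        "coupling": coupling,
        "stimulus": cfg["stimulus"],
    }


def load_config(path: str) -> dict:
    """Read a YAML or JSON config; missing entries fall back to defaults.

    Returns a dict with keys neuron, kinetics, sizes, coupling (constructed
    dataclasses) and stimulus (plain dict with S, r_X, onset_fraction).
    """
    with open(path) as fh:
        text = fh.read()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    return _parse_config(raw)
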