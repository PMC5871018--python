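"""Forward-Euler integration of AdEx networks with exponential synapses.

The membrane potential of each recurrent neuron follows

    dV/dt = [-(V - E_L) + Delta_T * exp((V - V_T)/Delta_T)] / tau_m
            + X(t) + R(t) - w,          tau_w dw/dt = -w,

with all currents per capacitance (mV/ms).  On crossing V_th a spike is
recorded, V is held for the refractory period and reset to V_re, and the
adaptation variable w is incremented by B.  V is clamped below at V_lb.
Synaptic input is the sum of exponentially filtered presynaptic spike
trains, one filter state per kinetics class (E, I, X); filters decay by the
exact factor exp(-dt/tau) between events and jump by weight/tau on each
spike arrival.  Spikes are delivered with a one-step delay so the Euler
update is independent of neuron ordering.

Optogenetic-style stimulation adds a constant S (mV/ms) to the external
current of a targeted subset of excitatory neurons from an onset time
onward.  Multi-layer chaining reuses the excitatory spikes of one simulated
network as the external population of the next.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .connectivity_sampler import SynapticGraph, _sample_block
from .exceptions import ParameterError
from .model_parameters import NeuronParams, SynapseKinetics

__all__ = [
    "SimConfig",
    "SpikeRaster",
    "CurrentTraces",
    "StimulusProtocol",
    "SimResult",
    "poisson_drive",
    "apply_stimulation",
    "simulate",
    "chain_layers",
]


@dataclass(frozen=True)
class SimConfig:
    """Integration settings.  Times in ms."""

    duration: float
    dt: float = 0.1
    seed: int = 0
    burn_in: float = 500.0
    record_idx: np.ndarray | None = None  # neurons with full current traces
    trace_stride: int = 10  # record traces every this many steps

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < self.dt:
            raise ParameterError("need dt > 0 and duration >= dt")


@dataclass(frozen=True)
class SpikeRaster:
    """Time-sorted spike times (ms) and neuron indices."""

    times: np.ndarray
    ids: np.ndarray
    n_neurons: int
    duration: float

    def counts(self, ids_subset=None, t0: float = 0.0, t1=None) -> np.ndarray:
        """Per-neuron spike counts in [t0, t1)."""
        t1 = self.duration if t1 is None else t1
        in_win = (self.times >= t0) & (self.times < t1)
        counts = np.bincount(self.ids[in_win], minlength=self.n_neurons)
        if ids_subset is not None:
            counts = counts[ids_subset]
        return counts

    def restrict(self, max_id: int) -> "SpikeRaster":
        """Keep spikes of neurons with index < max_id."""
        keep = self.ids < max_id
        return SpikeRaster(self.times[keep], self.ids[keep], max_id, self.duration)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "neuron": self.ids})


@dataclass
class CurrentTraces:
    """Decomposed synaptic currents (mV/ms) for a recorded neuron subset."""

    idx: np.ndarray
    times: np.ndarray
    X: np.ndarray  # (n_rec, n_t) external incl. stimulation
    R: np.ndarray  # (n_rec, n_t) recurrent

    @property
    def I(self) -> np.ndarray:
        return self.X + self.R


@dataclass(frozen=True)
class StimulusProtocol:
    """Constant extra inward current S (mV/ms) to targeted excitatory neurons."""

    S: float
    onset: float
    targets: np.ndarray

    @classmethod
    def from_fraction(
        cls, q: float, N_E: int, S: float, onset: float, seed: int
    ) -> "StimulusProtocol":
        """Target a seeded random fraction q of the excitatory population."""
        if not 0.0 <= q <= 1.0:
            raise ParameterError("q must lie in [0, 1]")
        rng = np.random.default_rng(seed)
        n = int(round(q * N_E))
        targets = np.sort(rng.choice(N_E, size=n, replace=False))
        return cls(S=S, onset=onset, targets=targets)


@dataclass
class SimResult:
    raster: SpikeRaster
    traces: CurrentTraces | None
    epochs: dict  # name -> (t0, t1)
    #: per-epoch, per-neuron statistics: spike counts, mean X and mean R
    counts: dict = field(default_factory=dict)
    mean_X: dict = field(default_factory=dict)
    mean_R: dict = field(default_factory=dict)

    def rate(self, name: str, ids=None) -> np.ndarray:
        t0, t1 = self.epochs[name]
        c = self.counts[name] if ids is None else self.counts[name][ids]
        return c / (t1 - t0) * 1000.0  # Hz


def poisson_drive(
    count: int, rate, duration: float, seed: int
) -> SpikeRaster:
    """Independent Poisson spike trains; rate scalar or per-neuron (Hz)."""
    rate = np.broadcast_to(np.asarray(rate, dtype=float), (count,))
    if np.any(rate < 0):
        raise ParameterError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    n_spikes = rng.poisson(rate * duration / 1000.0)
    ids = np.repeat(np.arange(count), n_spikes)
    times = rng.random(ids.size) * duration
    order = np.argsort(times, kind="stable")
    return SpikeRaster(times[order], ids[order], count, duration)


def apply_stimulation(protocol: StimulusProtocol, traces: CurrentTraces) -> CurrentTraces:
    """Add the protocol's current to the external traces of targeted neurons."""
    X = traces.X.copy()
    targeted = np.isin(traces.idx, protocol.targets)
    X[np.ix_(targeted, traces.times >= protocol.onset)] += protocol.S
    return CurrentTraces(idx=traces.idx, times=traces.times, X=X, R=traces.R)


def _stack_kinetics(graph: SynapticGraph, N_E: int, N_I: int) -> dict:
    """One CSC delivery matrix per presynaptic kinetics class, rows = E then I."""
    mats = {}
    for pre in ("E", "I", "X"):
        rows = []
        for post, n_post in (("E", N_E), ("I", N_I)):
            blk = graph.blocks.get((post, pre))
            if blk is None:
                n_pre = next(
                    (g.shape[1] for (a, b), g in graph.blocks.items() if b == pre), 0
                )
                blk = sp.csr_matrix((n_post, n_pre))
            rows.append(blk)
        if rows[0].shape[1] == 0:
            mats[pre] = None
        else:
            mats[pre] = sp.vstack(rows).tocsc()
    return mats


def simulate(
    graph: SynapticGraph,
    neuron: NeuronParams,
    kinetics: SynapseKinetics,
    external: SpikeRaster,
    protocol: StimulusProtocol | None,
    config: SimConfig,
) -> SimResult:
    """Integrate the recurrent network driven by an external spike raster.

    Initial membrane potentials are drawn uniformly in [V_re, V_T] from the
    config seed; adaptation and synaptic filter states start at zero.  The
    burn-in window is excluded from all epoch statistics.  Returns the spike
    raster, current traces for ``config.record_idx`` (subsampled by
    ``trace_stride``), and per-epoch per-neuron spike counts and mean
    external/recurrent currents, with epochs "pre" (burn-in to stimulus
    onset) and, when stimulated, "during" (onset to end).
    """
    NE_graph = graph.blocks[("E", "E")].shape[0] if ("E", "E") in graph.blocks else 0
    NI_graph = graph.blocks[("I", "I")].shape[0] if ("I", "I") in graph.blocks else 0
    N = NE_graph + NI_graph
    if N == 0:
        raise ParameterError("graph has no recurrent neurons")
    mats = _stack_kinetics(graph, NE_graph, NI_graph)
    if mats["X"] is not None and external.n_neurons != mats["X"].shape[1]:
        raise ParameterError("external raster size does not match X-block width")

    dt = config.dt
    n_steps = int(round(config.duration / dt))
    rng = np.random.default_rng(config.seed)

    V = rng.uniform(neuron.V_re, neuron.V_T, size=N)
    w = np.zeros(N)
    sE = np.zeros(N)
    sI = np.zeros(N)
    sX = np.zeros(N)
    refr = np.zeros(N, dtype=np.int64)
    ref_steps = max(1, int(round(neuron.tau_ref / dt)))

    decay = {p: math.exp(-dt / kinetics.tau(p)) for p in ("E", "I", "X")}
    inv_tau = {p: 1.0 / kinetics.tau(p) for p in ("E", "I", "X")}
    exp_cap = (neuron.V_th - neuron.V_T) / neuron.Delta_T

    # stimulation; the protocol onset also splits the epoch bookkeeping even
    # when S = 0 (e.g. downstream layers follow the upstream onset)
    stim_vec = None
    onset_step = n_steps  # epoch split
    stim_start = n_steps
    if protocol is not None:
        if 0 < protocol.onset < config.duration:
            onset_step = int(round(protocol.onset / dt))
        if protocol.S != 0 and protocol.targets.size:
            stim_vec = np.zeros(N)
            stim_vec[protocol.targets] = protocol.S
            stim_start = max(int(round(protocol.onset / dt)), 0)

    # external spikes binned to steps, delivered with one-step delay
    ext_steps = np.minimum((external.times / dt).astype(np.int64), n_steps - 1) + 1
    order = np.argsort(ext_steps, kind="stable")
    ext_steps = ext_steps[order]
    ext_ids = external.ids[order]
    ext_ptr = 0

    # epochs
    burn_step = int(round(config.burn_in / dt))
    epochs = {}
    if onset_step < n_steps:
        epochs["pre"] = (burn_step, onset_step)
        epochs["during"] = (onset_step, n_steps)
    else:
        epochs["pre"] = (burn_step, n_steps)

    sums_X = {k: np.zeros(N) for k in epochs}
    sums_R = {k: np.zeros(N) for k in epochs}
    counts = {k: np.zeros(N, dtype=np.int64) for k in epochs}

    rec_idx = config.record_idx
    if rec_idx is not None:
        rec_idx = np.asarray(rec_idx, dtype=np.int64)
        n_rec_t = len(range(0, n_steps, config.trace_stride))
        tr_X = np.zeros((rec_idx.size, n_rec_t), dtype=np.float32)
        tr_R = np.zeros((rec_idx.size, n_rec_t), dtype=np.float32)
        tr_times = np.zeros(n_rec_t)
        rec_col = 0

    spike_times: list = []
    spike_ids: list = []

    mE, mI, mX = mats["E"], mats["I"], mats["X"]
    pend_E = np.empty(0, dtype=np.int64)
    pend_I = np.empty(0, dtype=np.int64)

    for step in range(n_steps):
        # deliver last step's recurrent spikes (one-step delay)
        if pend_E.size and mE is not None:
            for c in pend_E:
                sl = slice(mE.indptr[c], mE.indptr[c + 1])
                sE[mE.indices[sl]] += mE.data[sl] * inv_tau["E"]
        if pend_I.size and mI is not None:
            for c in pend_I:
                sl = slice(mI.indptr[c], mI.indptr[c + 1])
                sI[mI.indices[sl]] += mI.data[sl] * inv_tau["I"]
        # deliver external spikes binned to this step
        if mX is not None:
            p0 = ext_ptr
            while ext_ptr < ext_steps.size and ext_steps[ext_ptr] == step:
                ext_ptr += 1
            for c in ext_ids[p0:ext_ptr]:
                sl = slice(mX.indptr[c], mX.indptr[c + 1])
                sX[mX.indices[sl]] += mX.data[sl] * inv_tau["X"]
        else:
            while ext_ptr < ext_steps.size and ext_steps[ext_ptr] == step:
                ext_ptr += 1

        if stim_vec is not None and step >= stim_start:
            X_cur = sX + stim_vec
        else:
            X_cur = sX
        R_cur = sE + sI

        # bookkeeping before the voltage update
        for name, (a, b) in epochs.items():
            if a <= step < b:
                sums_X[name] += X_cur
                sums_R[name] += R_cur
        if rec_idx is not None and step % config.trace_stride == 0:
            tr_X[:, rec_col] = X_cur[rec_idx]
            tr_R[:, rec_col] = R_cur[rec_idx]
            tr_times[rec_col] = step * dt
            rec_col += 1

        active = refr == 0
        arg = np.minimum((V - neuron.V_T) / neuron.Delta_T, exp_cap)
        dV = dt * (
            (-(V - neuron.E_L) + neuron.Delta_T * np.exp(arg)) / neuron.tau_m
            + X_cur + R_cur - w
        )
        V = np.where(active, V + dV, V)
        np.maximum(V, neuron.V_lb, out=V)
        w = w - dt * w / neuron.tau_w

        spiking = active & (V > neuron.V_th)
        idx = np.flatnonzero(spiking)
        if idx.size:
            spike_times.append(np.full(idx.size, (step + 1) * dt))
            spike_ids.append(idx.copy())
            V[idx] = neuron.V_re
            w[idx] += neuron.B
            refr[idx] = ref_steps
            for name, (a, b) in epochs.items():
                if a <= step < b:
                    np.add.at(counts[name], idx, 1)
            pend_E = idx[idx < NE_graph]
            pend_I = idx[idx >= NE_graph] - NE_graph
        else:
            pend_E = pend_I = np.empty(0, dtype=np.int64)
        refr[refr > 0] -= 1

        sE *= decay["E"]
        sI *= decay["I"]
        sX *= decay["X"]

    if spike_times:
        times = np.concatenate(spike_times)
        ids = np.concatenate(spike_ids).astype(np.int64)
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    order = np.argsort(times, kind="stable")
    raster = SpikeRaster(times[order], ids[order], N, config.duration)

    traces = None
    if rec_idx is not None:
        traces = CurrentTraces(idx=rec_idx, times=tr_times, X=tr_X, R=tr_R)

    res = SimResult(
        raster=raster,
        traces=traces,
        epochs={k: (a * dt, b * dt) for k, (a, b) in epochs.items()},
    )
    for name, (a, b) in epochs.items():
        n_in = b - a
        res.counts[name] = counts[name]
        res.mean_X[name] = sums_X[name] / max(n_in, 1)
        res.mean_R[name] = sums_R[name] / max(n_in, 1)
    return res


def chain_layers(
    upstream_raster: SpikeRaster,
    upstream_N_E: int,
    coupling,
    sizes,
    seed: int,
) -> tuple[SpikeRaster, dict]:
    """Turn upstream excitatory spikes into downstream external drive.

    The excitatory neurons of the upstream layer become the external
    population of the downstream layer, so the downstream network must have
    ``N_X`` equal to the upstream excitatory count.  The downstream X-blocks
    are sampled with the feedforward probabilities and strengths
    (p_EX, p_IX, J_EX, J_IX).  Returns the restricted raster and the two
    sampled X-blocks keyed by postsynaptic population.
    """
    if sizes.N_X != upstream_N_E:
        raise ParameterError(
            f"downstream N_X={sizes.N_X} must equal upstream N_E={upstream_N_E}"
        )
    raster = upstream_raster.restrict(upstream_N_E)
    rng = np.random.default_rng(seed)
    blocks = {}
    for post in ("E", "I"):
        mat, _ = _sample_block(
            sizes.count(post), upstream_N_E,
            coupling.p[(post, "X")], coupling.J[(post, "X")], rng,
        )
        blocks[(post, "X")] = mat
    return raster, blocks
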