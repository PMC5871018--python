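"""AdEx network integration: oracle agreement, invariants, drive plumbing."""

import numpy as np
import pytest

from imbalnet.connectivity_sampler import sample_graph
from imbalnet.exceptions import ParameterError
from imbalnet.model_parameters import (
    CouplingTable,
    NeuronParams,
    PopulationSizes,
    SynapseKinetics,
)
from imbalnet.spiking_simulator import (
    SimConfig,
    SpikeRaster,
    StimulusProtocol,
    apply_stimulation,
    chain_layers,
    poisson_drive,
    simulate,
)


def _empty_coupling():
    return CouplingTable(
        p={k: 0.0 for k in CouplingTable().p},
        J={k: 0.0 for k in CouplingTable().J},
    )


def _tiny_net(seed=0, N=50, N_X=20):
    sizes = PopulationSizes(N=N, N_X=N_X)
    graph = sample_graph(CouplingTable(), sizes, seed)
    return sizes, graph


class TestPoissonDrive:
    def test_zero_rate_is_silent(self):
        raster = poisson_drive(100, 0.0, 1000.0, seed=0)
        assert raster.times.size == 0

    def test_total_count_matches_poisson_statistics(self):
        raster = poisson_drive(4000, 5.0, 10_000.0, seed=1)
        expected = 4000 * 5.0 * 10.0
        assert abs(raster.times.size - expected) < 5 * np.sqrt(expected)

    def test_count_variance_to_mean_near_one(self):
        raster = poisson_drive(4000, 5.0, 10_000.0, seed=2)
        counts = raster.counts()
        fano = counts.var() / counts.mean()
        assert abs(fano - 1.0) < 5 * np.sqrt(2 / (counts.size - 1))

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            poisson_drive(10, -1.0, 100.0, seed=0)

    def test_times_sorted_within_duration(self):
        raster = poisson_drive(50, 20.0, 500.0, seed=3)
        assert np.all(np.diff(raster.times) >= 0)
        assert raster.times.min() >= 0 and raster.times.max() <= 500.0


class TestSimulateCore:
    def test_no_drive_no_spikes(self):
        sizes = PopulationSizes(N=50, N_X=20)
        graph = sample_graph(_empty_coupling(), sizes, 0)
        ext = poisson_drive(sizes.N_X, 0.0, 500.0, seed=0)
        res = simulate(
            graph, NeuronParams(), SynapseKinetics(), ext, None,
            SimConfig(duration=500.0, seed=1, burn_in=0.0),
        )
        assert res.raster.times.size == 0

    def test_suprathreshold_rate_matches_fine_step_oracle(self):
        # constant drive at 1.5x the EIF rheobase, adaptation disabled
        neuron = NeuronParams(B=0.0)
        I0 = 1.5 * (neuron.V_T - neuron.E_L - neuron.Delta_T) / neuron.tau_m
        sizes = PopulationSizes(N=2, N_X=1)
        graph = sample_graph(_empty_coupling(), sizes, 0)
        ext = poisson_drive(1, 0.0, 2000.0, seed=0)
        prot = StimulusProtocol(S=I0, onset=0.0, targets=np.array([0]))
        res = simulate(
            graph, neuron, SynapseKinetics(), ext, prot,
            SimConfig(duration=2000.0, dt=0.1, seed=1),
        )
        t = res.raster.times[res.raster.ids == 0]
        rate_sim = np.count_nonzero(t >= 500) / 1.5

        dt = 0.001
        V, ref, spikes = neuron.E_L, 0, []
        cap = (neuron.V_th - neuron.V_T) / neuron.Delta_T
        for i in range(int(2000 / dt)):
            if ref > 0:
                ref -= 1
                continue
            V += dt * (
                (-(V - neuron.E_L)
                 + neuron.Delta_T * np.exp(min((V - neuron.V_T) / neuron.Delta_T, cap)))
                / neuron.tau_m + I0
            )
            if V > neuron.V_th:
                spikes.append(i * dt)
                V, ref = neuron.V_re, int(neuron.tau_ref / dt)
        rate_ref = np.count_nonzero(np.array(spikes) >= 500) / 1.5
        assert rate_sim == pytest.approx(rate_ref, rel=0.02)

    def test_bit_identical_rasters_for_identical_seeds(self):
        sizes, graph = _tiny_net()
        ext = poisson_drive(sizes.N_X, 10.0, 500.0, seed=4)
        cfg = SimConfig(duration=500.0, seed=5, burn_in=0.0)
        kin = SynapseKinetics()
        r1 = simulate(graph, NeuronParams(), kin, ext, None, cfg).raster
        r2 = simulate(graph, NeuronParams(), kin, ext, None, cfg).raster
        np.testing.assert_array_equal(r1.times, r2.times)
        np.testing.assert_array_equal(r1.ids, r2.ids)

    def test_refractory_period_respected(self):
        sizes, graph = _tiny_net()
        ext = poisson_drive(sizes.N_X, 50.0, 1000.0, seed=6)
        prot = StimulusProtocol(
            S=2.0, onset=0.0, targets=np.arange(sizes.N_E)
        )
        res = simulate(
            graph, NeuronParams(), SynapseKinetics(), ext, prot,
            SimConfig(duration=1000.0, seed=7, burn_in=0.0),
        )
        raster = res.raster
        assert raster.times.size > 0
        for nid in np.unique(raster.ids):
            isis = np.diff(raster.times[raster.ids == nid])
            if isis.size:
                assert isis.min() >= NeuronParams().tau_ref - 1e-9

    def test_mismatched_external_size_rejected(self):
        sizes, graph = _tiny_net()
        ext = poisson_drive(sizes.N_X + 5, 5.0, 100.0, seed=0)
        with pytest.raises(ParameterError):
            simulate(graph, NeuronParams(), SynapseKinetics(), ext, None,
                     SimConfig(duration=100.0, seed=0, burn_in=0.0))


class TestStimulation:
    def test_targeted_neurons_see_exactly_S_in_external_trace(self):
        # zero external spiking isolates the injected current in X
        sizes, _ = _tiny_net()
        graph = sample_graph(CouplingTable(), PopulationSizes(N=50, N_X=20), 0)
        ext = poisson_drive(20, 0.0, 400.0, seed=0)
        prot = StimulusProtocol(S=1.3, onset=200.0, targets=np.array([0, 1, 2]))
        res = simulate(
            graph, NeuronParams(), SynapseKinetics(), ext, prot,
            SimConfig(duration=400.0, seed=1, burn_in=0.0,
                      record_idx=np.array([0, 10]), trace_stride=1),
        )
        tr = res.traces
        on = tr.times >= 200.0
        np.testing.assert_allclose(tr.X[0, on], 1.3)
        np.testing.assert_allclose(tr.X[0, ~on], 0.0)
        np.testing.assert_allclose(tr.X[1, :], 0.0)

    def test_zero_amplitude_is_identity(self):
        sizes, graph = _tiny_net()
        ext = poisson_drive(sizes.N_X, 10.0, 400.0, seed=2)
        cfg = SimConfig(duration=400.0, seed=3, burn_in=0.0)
        kin = SynapseKinetics()
        base = simulate(graph, NeuronParams(), kin, ext, None, cfg).raster
        prot = StimulusProtocol(S=0.0, onset=200.0, targets=np.arange(10))
        stim = simulate(graph, NeuronParams(), kin, ext, prot, cfg).raster
        np.testing.assert_array_equal(base.times, stim.times)
        np.testing.assert_array_equal(base.ids, stim.ids)

    def test_seeded_fraction_selects_q_share_of_excitatory(self):
        prot = StimulusProtocol.from_fraction(0.2, 4000, S=2.0, onset=0.0, seed=0)
        assert prot.targets.size == 800
        assert prot.targets.max() < 4000
        prot2 = StimulusProtocol.from_fraction(0.2, 4000, S=2.0, onset=0.0, seed=0)
        np.testing.assert_array_equal(prot.targets, prot2.targets)

    def test_apply_stimulation_offsets_targeted_traces(self):
        from imbalnet.spiking_simulator import CurrentTraces

        tr = CurrentTraces(
            idx=np.array([0, 1]), times=np.array([0.0, 100.0, 200.0]),
            X=np.zeros((2, 3)), R=np.zeros((2, 3)),
        )
        prot = StimulusProtocol(S=2.0, onset=100.0, targets=np.array([1]))
        out = apply_stimulation(prot, tr)
        np.testing.assert_allclose(out.X[1], [0.0, 2.0, 2.0])
        np.testing.assert_allclose(out.X[0], 0.0)
        np.testing.assert_allclose(out.I, out.X + out.R)


class TestChaining:
    def test_silent_upstream_gives_silent_drive(self, coupling):
        sizes = PopulationSizes(N=50, N_X=40)
        upstream = SpikeRaster(np.empty(0), np.empty(0, dtype=int), 50, 500.0)
        raster, blocks = chain_layers(upstream, 40, coupling, sizes, seed=0)
        assert raster.times.size == 0
        assert blocks[("E", "X")].shape == (sizes.N_E, 40)

    def test_population_count_mismatch_rejected(self, coupling):
        sizes = PopulationSizes(N=50, N_X=33)
        upstream = SpikeRaster(np.empty(0), np.empty(0, dtype=int), 50, 500.0)
        with pytest.raises(ParameterError):
            chain_layers(upstream, 40, coupling, sizes, seed=0)

    def test_doubled_upstream_rate_doubles_downstream_drive(self, coupling):
        # synaptic filtering is linear in presynaptic rate
        sizes = PopulationSizes(N=100, N_X=80)
        kin = SynapseKinetics()
        graph = sample_graph(coupling, sizes, 0)
        means = []
        for rate in (10.0, 20.0):
            up = poisson_drive(80, rate, 2000.0, seed=5)
            raster, blocks = chain_layers(up, 80, coupling, sizes, seed=6)
            graph.blocks.update(blocks)
            res = simulate(
                graph, NeuronParams(), kin, raster, None,
                SimConfig(duration=2000.0, seed=7, burn_in=200.0),
            )
            means.append(res.mean_X["pre"].mean())
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.1)
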