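"""Turn simulation output into measured quantities, and drive experiments.

Estimators: population firing rates (epoch means and sliding-window time
courses), epoch-averaged synaptic current decompositions in rheobase
display units, the rectified-linear gain fit r = g [I - I0]_+ that supplies
the gain used by the corrected mean-field theory, and wrapped-Gaussian
profile-width fits for spatial rate fields.

Experiment runners reproduce the study protocols end to end at a chosen
scale: full and partial optogenetic-style stimulation, two-layer chaining,
the scaled weak-stimulus network, the spatial network, size-tuning scans
and the deconvolution demo.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize

from . import meanfield_discrete as mfd
from . import meanfield_spatial as mfs
from .connectivity_sampler import sample_graph, wrapped_gaussian
from .exceptions import FitError, ParameterError
from .model_parameters import (
    RHEOBASE_DISPLAY,
    CouplingTable,
    NeuronParams,
    PopulationSizes,
    SynapseKinetics,
    build_meanfield,
    compute_epsilon,
    external_drive,
    rescale_stimulus,
    scale_network,
)
from .spiking_simulator import (
    SimConfig,
    SpikeRaster,
    StimulusProtocol,
    chain_layers,
    poisson_drive,
    simulate,
)

__all__ = [
    "estimate_rates",
    "mean_currents",
    "fit_gain",
    "fit_profile_width",
    "run_experiment",
    "EXPERIMENTS",
]


def estimate_rates(
    raster: SpikeRaster,
    masks: dict,
    epochs: dict,
    window: float = 100.0,
    timeseries: bool = False,
) -> dict:
    """Population firing rates from a spike raster.

    ``masks`` maps labels to neuron-index arrays; ``epochs`` maps epoch
    names to (t0, t1) windows in ms.  Epoch means are total spike count /
    (neuron count * epoch length).  With ``timeseries`` a centered
    sliding-window rate curve (default 100 ms window) is returned per label.
    """
    out = {"mean": {}, "timeseries": {}}
    for label, ids in masks.items():
        ids = np.asarray(ids)
        if ids.size == 0:
            raise ParameterError(f"empty mask {label!r}")
        sel = np.isin(raster.ids, ids)
        t = raster.times[sel]
        for name, (t0, t1) in epochs.items():
            n = np.count_nonzero((t >= t0) & (t < t1))
            out["mean"][(label, name)] = n / ids.size / (t1 - t0) * 1000.0
        if timeseries:
            step = window / 5.0
            centers = np.arange(window / 2, raster.duration - window / 2 + step, step)
            t_sorted = np.sort(t)
            lo = np.searchsorted(t_sorted, centers - window / 2)
            hi = np.searchsorted(t_sorted, centers + window / 2)
            out["timeseries"][label] = (centers, (hi - lo) / ids.size / window * 1000.0)
    return out


def mean_currents(result, masks: dict, rheobase: float = RHEOBASE_DISPLAY) -> dict:
    """Epoch-averaged external/recurrent/total currents per population.

    Values are population means of the per-neuron epoch-mean currents,
    divided by the rheobase display constant (so 1.0 means one rheobase of
    net drive).  ``result`` is a :class:`SimResult`.
    """
    out = {}
    for label, ids in masks.items():
        ids = np.asarray(ids)
        for name in result.epochs:
            X = result.mean_X[name][ids].mean() / rheobase
            R = result.mean_R[name][ids].mean() / rheobase
            out[(label, name)] = {"X": X, "R": R, "I": X + R}
    return out


def fit_gain(currents, rates) -> dict:
    """Rectified-linear fit ``rate = g * [I - I0]_+`` by least squares.

    The threshold I0 is found by scanning candidate values (midpoints of the
    sorted currents); for each candidate the slope has a closed-form
    least-squares solution and points below threshold contribute their full
    squared rate.  Returns g (Hz per mV/ms), I0 and the residual sum of
    squares.
    """
    I = np.asarray(currents, dtype=float).ravel()
    r = np.asarray(rates, dtype=float).ravel()
    if I.size != r.size or I.size < 2:
        raise FitError("need at least two (current, rate) points")
    if np.all(r == 0):
        raise FitError("all rates are zero: gain unidentifiable")
    if np.ptp(I) < 1e-14:
        raise FitError("currents are a single cluster: threshold unidentifiable")
    order = np.argsort(I, kind="stable")
    Is, rs = I[order], r[order]
    n = Is.size
    # candidate active sets: the m points of largest current, for each m
    sizes_m = np.arange(2, n + 1)
    if n > 1024:  # coarsen for very large point clouds
        sizes_m = np.unique(np.linspace(2, n, 1024).astype(int))
    best = None
    for m in sizes_m:
        x, y = Is[n - m:], rs[n - m:]
        if np.ptp(x) < 1e-14:
            continue
        a, b = np.polyfit(x, y, 1)  # joint (slope, intercept) on the active set
        if a <= 0:
            continue
        pred = np.clip(a * Is + b, 0.0, None)
        sse = float(np.sum((rs - pred) ** 2))
        if best is None or sse < best[2]:
            best = (float(a), float(-b / a), sse)
    if best is None:
        raise FitError("no rectified-linear fit with positive gain exists")
    g, I0, sse = best
    return {"g": g, "I0": I0, "residual": sse}


def fit_profile_width(field_vals: np.ndarray, axis: int = 0) -> dict:
    """Fit baseline + amplitude * wrapped-Gaussian to an axis marginal.

    The field is averaged over the other axes, then
    ``b + A * g(x - x0; sigma)`` is fit by nonlinear least squares.  Returns
    sigma together with the other fitted parameters.  Raises when the
    marginal has no dominant peak or the fit fails to converge.
    """
    f = np.asarray(field_vals, dtype=float)
    other = tuple(i for i in range(f.ndim) if i != axis)
    prof = f.mean(axis=other) if other else f
    n = prof.size
    x = np.arange(n) / n
    span = float(prof.max() - prof.min())
    if span < 1e-10 * max(abs(prof).max(), 1.0) or span == 0.0:
        raise FitError("profile is flat: no peak to fit")
    x0_init = x[int(np.argmax(prof))]
    # crude width from the half-maximum crossing
    above = prof - prof.min() > span / 2
    sigma_init = max(above.sum() / n / 2.355, 1.5 / n)

    def model(xv, base, amp, x0, sigma):
        return base + amp * wrapped_gaussian(xv - x0, abs(sigma) + 1e-12)

    p0 = [float(prof.min()), span * np.sqrt(2 * np.pi) * sigma_init,
          float(x0_init), float(sigma_init)]
    try:
        popt, _ = scipy.optimize.curve_fit(model, x, prof, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise FitError(f"width fit did not converge: {exc}") from exc
    base, amp, x0, sigma = popt
    return {"sigma": float(abs(sigma)), "center": float(x0 % 1.0),
            "baseline": float(base), "amplitude": float(amp)}


# ---------------------------------------------------------------------------
# Experiment runners


def _population_masks(sizes: PopulationSizes, targets=None) -> dict:
    masks = {
        "E": np.arange(sizes.N_E),
        "I": np.arange(sizes.N_E, sizes.N),
    }
    if targets is not None and 0 < targets.size < sizes.N_E:
        masks["exp"] = targets
        masks["nexp"] = np.setdiff1d(np.arange(sizes.N_E), targets)
    return masks


def _run_stimulated(
    coupling: CouplingTable,
    sizes: PopulationSizes,
    q: float,
    S: float,
    duration: float,
    seed: int,
    r_X: float = 5.0,
    dt: float = 0.1,
    burn_in: float = 500.0,
) -> dict:
    """Common machinery of the stimulation protocols: sample, drive, run."""
    neuron = NeuronParams()
    kinetics = SynapseKinetics()
    graph = sample_graph(coupling, sizes, seed)
    external = poisson_drive(sizes.N_X, r_X, duration, seed + 1)
    protocol = StimulusProtocol.from_fraction(
        q, sizes.N_E, S=S, onset=duration / 2, seed=seed + 2
    )
    config = SimConfig(duration=duration, dt=dt, seed=seed + 3, burn_in=burn_in)
    result = simulate(graph, neuron, kinetics, external, protocol, config)
    masks = _population_masks(sizes, protocol.targets)
    rates = estimate_rates(result.raster, masks, result.epochs)
    currents = mean_currents(result, masks)
    # gain from the pre-stimulus epoch, pooled over E and I neurons
    I_pre = result.mean_X["pre"] + result.mean_R["pre"]
    r_pre = result.rate("pre")
    gain = fit_gain(I_pre, r_pre)
    return {
        "result": result,
        "protocol": protocol,
        "masks": masks,
        "rates": rates["mean"],
        "currents": currents,
        "gain": gain,
        "sizes": sizes,
        "coupling": coupling,
        "r_X": r_X,
        "S": S,
        "seed": seed,
        "duration": duration,
    }


def _theory_block(bundle: dict, g: float | None = None) -> dict:
    """Mean-field predictions matching a stimulated-run bundle."""
    coupling, sizes = bundle["coupling"], bundle["sizes"]
    r_X, S = bundle["r_X"], bundle["S"]
    q = bundle["protocol"].targets.size / sizes.N_E
    g = bundle["gain"]["g"] if g is None else g
    eps = compute_epsilon(coupling, sizes)
    s = rescale_stimulus(S, eps)
    mf2 = build_meanfield(coupling, sizes, "EI")
    theory = {"epsilon": eps, "g": g}
    X_pre = external_drive(mf2, r_X)
    X_on = external_drive(mf2, r_X, stim=[s * q, 0.0])
    theory["corrected2_pre"] = mfd.corrected_rates(mf2.W, X_pre, eps, g).r
    theory["corrected2_on"] = mfd.corrected_rates(mf2.W, X_on, eps, g).r
    try:
        theory["balanced2_pre"] = mfd.balanced_rates(mf2.W, X_pre).r
        theory["balanced2_on"] = mfd.balanced_rates(mf2.W, X_on).r
    except mfd.BalanceInfeasibleError:  # pragma: no cover - generic W invertible
        pass
    if 0 < q < 1:
        sizes_q = PopulationSizes(N=sizes.N, N_X=sizes.N_X, q=q)
        mf3 = build_meanfield(coupling, sizes_q, "exp-nexp-I")
        X3_pre = external_drive(mf3, r_X)
        X3_on = external_drive(mf3, r_X, stim=[s, 0.0, 0.0])
        theory["corrected3_pre"] = mfd.corrected_rates(mf3.W, X3_pre, eps, g).r
        theory["corrected3_on"] = mfd.corrected_rates(mf3.W, X3_on, eps, g).r
    return theory


def run_full_stimulation(
    seed: int = 0, duration: float = 10_000.0, N: int = 5000, S: float = 2.0,
) -> dict:
    """Stimulate every excitatory neuron (q = 1)."""
    coupling, sizes = CouplingTable(), PopulationSizes()
    if N != sizes.N:
        coupling, sizes = scale_network(coupling, sizes, N)
    bundle = _run_stimulated(coupling, sizes, q=1.0, S=S, duration=duration, seed=seed)
    bundle["theory"] = _theory_block(bundle)
    return bundle


def run_partial_stimulation(
    seed: int = 0, duration: float = 10_000.0, N: int = 5000, S: float = 2.0,
    q: float = 0.2, g: float | None = None,
) -> dict:
    """Stimulate a random fraction q of excitatory neurons."""
    coupling, sizes = CouplingTable(), PopulationSizes(q=q)
    if N != sizes.N:
        coupling, sizes = scale_network(coupling, sizes, N)
    bundle = _run_stimulated(coupling, sizes, q=q, S=S, duration=duration, seed=seed)
    bundle["theory"] = _theory_block(bundle, g=g)
    rates = bundle["rates"]
    bundle["sign_pattern"] = (
        np.sign(rates[("exp", "during")] - rates[("exp", "pre")]),
        np.sign(rates[("nexp", "during")] - rates[("nexp", "pre")]),
        np.sign(rates[("I", "during")] - rates[("I", "pre")]),
    )
    return bundle


def run_two_layer(
    seed: int = 0, duration: float = 10_000.0, N: int = 5000, S: float = 2.0,
    q: float = 0.2, upstream: dict | None = None,
) -> dict:
    """Chain the partially stimulated network into a downstream layer."""
    if upstream is None:
        upstream = run_partial_stimulation(seed=seed, duration=duration, N=N, S=S, q=q)
    coupling, sizes = upstream["coupling"], upstream["sizes"]
    ext_raster, xblocks = chain_layers(
        upstream["result"].raster, sizes.N_E, coupling, sizes, seed + 10
    )
    graph = sample_graph(coupling, sizes, seed + 11)
    graph.blocks.update(xblocks)
    onset = upstream["protocol"].onset
    config = SimConfig(duration=duration, dt=0.1, seed=seed + 12)
    # no direct stimulation downstream; epochs follow the upstream onset
    protocol = StimulusProtocol(S=0.0, onset=onset, targets=np.empty(0, dtype=int))
    result = simulate(
        graph, NeuronParams(), SynapseKinetics(), ext_raster, protocol, config
    )
    masks = _population_masks(sizes)
    rates = estimate_rates(result.raster, masks, result.epochs)
    return {
        "upstream": upstream,
        "result": result,
        "rates": rates["mean"],
        "currents": mean_currents(result, masks),
        "masks": masks,
    }


def run_weak_stimulus(
    S: float, seed: int = 0, duration: float = 10_000.0, N: int = 20_000,
) -> dict:
    """Scaled-up network (eps halved at N = 2e4) with a weak stimulus.

    The stimulus amplitude has no canonical value and must be supplied.
    """
    coupling, sizes = scale_network(CouplingTable(), PopulationSizes(), N)
    bundle = _run_stimulated(
        coupling, sizes, q=sizes.q, S=S, duration=duration, seed=seed
    )
    bundle["theory"] = _theory_block(bundle)
    return bundle


def run_spatial(
    seed: int = 0,
    shape: tuple = (64, 64, 16),
    g: float = 12.0,
    epsilon: float | None = None,
    sigma_X_broad: float = 0.2,
    sigma_X_narrow: float = 0.06,
) -> dict:
    """Mean-field solution of the spatial network for two stimulus sizes."""
    kernels = mfs.default_spatial_kernels()
    out = {"kernels": kernels, "shape": shape}
    for tag, sx in (("broad", sigma_X_broad), ("narrow", sigma_X_narrow)):
        spec = mfs.StimulusSpec(sigma_X=sx)
        r_X = mfs.build_stimulus(spec, shape)
        r, I = mfs.spatial_corrected_rates(
            kernels, r_X, epsilon=epsilon, g=g, return_input=True
        )
        entry = {"r_X": r_X, "corrected": r, "mean_input": I,
                 "widths": mfs.gaussian_widths(
                     sx, kernels.alpha["X"], kernels.alpha["E"], kernels.alpha["I"]
                 )}
        try:
            entry["balanced"] = mfs.spatial_balanced_rates(kernels, r_X)
            entry["sigma_E_fit"] = fit_profile_width(entry["balanced"][0], axis=0)["sigma"]
        except mfs.BalanceInfeasibleError as exc:
            entry["balanced_error"] = str(exc)
        out[tag] = entry
    return out


def run_size_tuning(
    seed: int = 0,
    sigma_X_values=None,
    g: float = 12.0,
    epsilon: float | None = None,
    variant: str = "gaussian",
    alpha_E: float = 0.15,
    shape: tuple = (64, 64, 1),
) -> dict:
    """Center-rate size-tuning curves (mean-field only)."""
    kernels = mfs.default_spatial_kernels(alpha_E=alpha_E)
    if sigma_X_values is None:
        sigma_X_values = np.linspace(0.02, 0.35, 23)
    stim = mfs.StimulusSpec(variant=variant)
    scan = mfs.size_tuning_scan(
        kernels, sigma_X_values, epsilon=epsilon, g=g, stimulus=stim, shape=shape
    )
    scan["kernels"] = kernels
    return scan


def run_deconvolution(
    seed: int = 0,
    alpha_ratio: float = 1.0,
    contrast_map: np.ndarray | None = None,
    g: float = 12.0,
    epsilon: float | None = None,
    shape: tuple = (64, 64, 1),
    radius: float = 0.2,
) -> dict:
    """Edge-sharpness recovery by the recurrent high-pass filter.

    Lateral excitatory width is ``alpha_ratio`` times the feedforward width;
    at ratio 1 the recurrent filter cancels the feedforward blur.  Reports
    the sharpness (max center-line slope) of the external input field and of
    the excitatory rate field.
    """
    base = mfs.default_spatial_kernels()
    alpha_X = base.alpha["X"]
    kernels = mfs.default_spatial_kernels(alpha_E=alpha_ratio * alpha_X)
    if contrast_map is not None:
        spec = mfs.StimulusSpec(variant="contrast_map", contrast_map=contrast_map)
    else:
        spec = mfs.StimulusSpec(variant="disc", sigma_X=radius)
    r_X = mfs.build_stimulus(spec, shape)
    Wt, WtX = mfs.kernel_fourier(kernels, shape)
    XE = mfs._inverse(WtX[0] * mfs._forward(r_X))  # input to E after divergence
    r = mfs.spatial_corrected_rates(kernels, r_X, epsilon=epsilon, g=g)
    return {
        "r_X": r_X,
        "X_E": XE,
        "r_E": r[0],
        "sharpness_input": mfs.sharpness_index(XE),
        "sharpness_output": mfs.sharpness_index(r[0]),
        "kernels": kernels,
    }


EXPERIMENTS = {
    "1": run_full_stimulation,
    "2": run_partial_stimulation,
    "3": run_two_layer,
    "4": run_weak_stimulus,
    "5": run_spatial,
    "6": run_size_tuning,
    "7": run_deconvolution,
    "full-stim": run_full_stimulation,
    "partial-stim": run_partial_stimulation,
    "two-layer": run_two_layer,
    "weak-stim": run_weak_stimulus,
    "spatial": run_spatial,
    "size-tuning": run_size_tuning,
    "deconvolve": run_deconvolution,
}


def run_experiment(name, seed: int = 0, **overrides) -> dict:
    """Dispatch an experiment protocol by id (1-7) or by name."""
    key = str(name)
    if key not in EXPERIMENTS:
        raise ParameterError(f"unknown experiment {name!r}")
    return EXPERIMENTS[key](seed=seed, **overrides)
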