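"""Mean-field theory of continuously indexed balanced networks.

Neurons are indexed by position on the periodic unit square and preferred
orientation on [0, 1) (fractions of 180 degrees).  Recurrent and feedforward
connectivity act as circular-convolution operators with wrapped-Gaussian
kernels, so in the Fourier domain each mode (n, k) decouples into an
ordinary 2x2 problem with

    w~_ab(n, k) = wbar_ab * exp[-2 pi^2 (|n|^2 alpha_b^2 + k^2 alpha_{b,theta}^2)]

where alpha_b is the projection width of presynaptic population b.  The
balanced solution r~ = -W~^{-1} X~ exists mode-wise but its Fourier series
diverges when external input is sharper than recurrent connectivity; the
linear correction r~ = (eps D - W~)^{-1} X~ is always summable and exhibits
the high-pass amplification responsible for surround suppression, size
tuning and edge sharpening.

The transform convention is the forward integral
``u~(n,k) = int u(x,theta) exp(-2 pi i (x.n + k theta)) dx dtheta``,
realized by an FFT with 1/M normalization on the forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .connectivity_sampler import wrapped_gaussian
from .exceptions import BalanceInfeasibleError, ParameterError
from .model_parameters import MV_MS_TO_MV_S

__all__ = [
    "SpatialKernelSet",
    "StimulusSpec",
    "WidthModel",
    "default_spatial_kernels",
    "kernel_fourier",
    "build_stimulus",
    "spatial_corrected_rates",
    "spatial_balanced_rates",
    "gaussian_widths",
    "size_tuning_scan",
    "sharpness_index",
    "field_to_csv",
    "field_from_csv",
]

_PRE = ("E", "I", "X")


@dataclass(frozen=True)
class SpatialKernelSet:
    """Normalized kernel weights and projection widths.

    ``wbar[(a, b)] = J_ab pbar_ab N_b / (J_EX pbar_EX N_X)`` is the total
    kernel weight (its zero-mode Fourier coefficient); ``alpha[b]`` and
    ``alpha_theta[b]`` are the spatial and orientation projection widths of
    presynaptic population b.  ``epsilon`` is the balance parameter of the
    underlying network.
    """

    wbar: dict
    alpha: dict
    alpha_theta: dict
    epsilon: float

    def __post_init__(self) -> None:
        for b in _PRE:
            if self.alpha[b] <= 0 or self.alpha_theta[b] <= 0:
                raise ParameterError("projection widths must be positive")
        if abs(self.wbar[("E", "X")] - 1.0) > 1e-12:
            raise ParameterError("wbar_EX must equal 1 (normalization)")

    @property
    def W0(self) -> np.ndarray:
        """Zero-mode recurrent matrix (equals the discrete two-population W)."""
        return np.array([
            [self.wbar[("E", "E")], self.wbar[("E", "I")]],
            [self.wbar[("I", "E")], self.wbar[("I", "I")]],
        ])

    @property
    def W0_X(self) -> np.ndarray:
        return np.array([self.wbar[("E", "X")], self.wbar[("I", "X")]])


def default_spatial_kernels(
    alpha_E: float = 0.15,
    alpha_I: float = 0.04,
    alpha_X: float = 0.04,
    alpha_E_theta: float = 0.1,
    alpha_I_theta: float = 0.1,
    alpha_X_theta: float = 0.125,
) -> SpatialKernelSet:
    """Kernel set for the visual-cortex (L4 -> L2/3) example.

    Weights derive from the printed coupling table with strengths scaled by
    1.2 and populations N_E = 1.6e5, N_I = 4e4, N_X = 1.6e5; broad lateral
    excitation (alpha_E) and narrow feedforward/inhibitory projections.
    """
    from .model_parameters import CouplingTable, PopulationSizes, compute_epsilon

    coupling = CouplingTable()
    coupling = CouplingTable(
        p=coupling.p, J={k: 1.2 * v for k, v in coupling.J.items()}
    )
    sizes = PopulationSizes(N=200_000, N_X=160_000)
    KJ = coupling.K("E", "X", sizes) * coupling.J[("E", "X")]
    wbar = {
        (a, b): coupling.K(a, b, sizes) * coupling.J[(a, b)] / KJ
        for a in ("E", "I") for b in _PRE
    }
    return SpatialKernelSet(
        wbar=wbar,
        alpha={"E": alpha_E, "I": alpha_I, "X": alpha_X},
        alpha_theta={"E": alpha_E_theta, "I": alpha_I_theta, "X": alpha_X_theta},
        epsilon=compute_epsilon(coupling, sizes),
    )


@dataclass(frozen=True)
class StimulusSpec:
    """External (L4) firing-rate profile specification.

    variant "gaussian": ``r_X(x,theta) = F(x) * [c_theta + (1-c_theta)
    g(theta-theta0; sigma_X_theta)]`` where the spatial factor F is a wrapped
    Gaussian bump of width sigma_X on a baseline; when ``calibrate`` is set,
    the amplitude and baseline of F are rescaled so its minimum and maximum
    over the grid equal ``r_min`` and ``r_max`` (Hz).  variant "disc": F is
    the indicator of a disc of radius sigma_X with Gaussian edge blur.
    variant "contrast_map": F is a user 2-D matrix of non-negative contrasts
    (blurred, then scaled to [r_min, r_max]); orientation factor uniform.
    """

    variant: str = "gaussian"
    rbar_X: float = 10.0
    c: float = 0.2
    c_theta: float = 0.75
    sigma_X: float = 0.2
    sigma_X_theta: float = 0.1
    x0: tuple = (0.5, 0.5)
    theta0: float = 0.5
    edge_blur: float = 0.01
    contrast_map: np.ndarray | None = None
    calibrate: bool = True
    r_min: float = 10.0
    r_max: float = 20.0


@dataclass(frozen=True)
class WidthModel:
    """Gaussian width calculus of the balanced state.

    Synaptic divergence broadens rate profiles into input profiles,
    ``beta_a^2 = sigma_a^2 + alpha_a^2``; balance forces all input widths to
    match beta_X, giving ``sigma_E^2 = beta_X^2 - alpha_E^2`` and likewise
    for I.  Infeasible (no balanced solution) when either lateral projection
    is broader than the feedforward input profile.
    """

    sigma_X: float
    beta_X: float
    feasible: bool
    sigma_E: float | None = None
    sigma_I: float | None = None


def gaussian_widths(
    sigma_X: float, alpha_X: float, alpha_E: float, alpha_I: float
) -> WidthModel:
    """Predict balanced rate-profile widths from stimulus and kernel widths."""
    if min(sigma_X, alpha_X, alpha_E, alpha_I) < 0:
        raise ParameterError("widths must be non-negative")
    beta_X = float(np.hypot(sigma_X, alpha_X))
    feasible = alpha_E < beta_X and alpha_I < beta_X
    if not feasible:
        return WidthModel(sigma_X=sigma_X, beta_X=beta_X, feasible=False)
    return WidthModel(
        sigma_X=sigma_X,
        beta_X=beta_X,
        feasible=True,
        sigma_E=float(np.sqrt(beta_X**2 - alpha_E**2)),
        sigma_I=float(np.sqrt(beta_X**2 - alpha_I**2)),
    )


def _mode_numbers(shape: tuple) -> tuple:
    """Integer Fourier mode grids (n1, n2, k) for an (nx, ny, ntheta) grid."""
    nx, ny, nt = shape
    n1 = np.fft.fftfreq(nx, d=1.0 / nx)
    n2 = np.fft.fftfreq(ny, d=1.0 / ny)
    k = np.fft.fftfreq(nt, d=1.0 / nt)
    return np.meshgrid(n1, n2, k, indexing="ij")


def kernel_fourier(kernels: SpatialKernelSet, shape: tuple) -> tuple:
    """Per-mode connectivity matrices W~(n, k) and W~_X(n, k).

    Returns ``Wt`` of shape (2, 2) + grid shape and ``WtX`` of shape
    (2,) + grid shape, real-valued (Gaussian kernels are even).
    """
    n1, n2, k = _mode_numbers(shape)
    nsq = n1**2 + n2**2
    decay = {
        b: np.exp(
            -2 * np.pi**2 * (
                nsq * kernels.alpha[b] ** 2
                + k**2 * kernels.alpha_theta[b] ** 2
            )
        )
        for b in _PRE
    }
    Wt = np.empty((2, 2) + shape)
    for i, a in enumerate(("E", "I")):
        for j, b in enumerate(("E", "I")):
            Wt[i, j] = kernels.wbar[(a, b)] * decay[b]
    WtX = np.empty((2,) + shape)
    for i, a in enumerate(("E", "I")):
        WtX[i] = kernels.wbar[(a, "X")] * decay["X"]
    return Wt, WtX


def _grid_coords(n: int) -> np.ndarray:
    return np.arange(n) / n


def _periodic_delta(u: np.ndarray) -> np.ndarray:
    return u - np.round(u)


def _spatial_factor(spec: StimulusSpec, shape: tuple) -> np.ndarray:
    nx, ny = shape[:2]
    xs = _grid_coords(nx)[:, None]
    ys = _grid_coords(ny)[None, :]
    if spec.variant == "gaussian":
        G = (
            wrapped_gaussian(xs - spec.x0[0], spec.sigma_X)
            * wrapped_gaussian(ys - spec.x0[1], spec.sigma_X)
        )
        F = spec.rbar_X * (spec.c + (1 - spec.c) * G)
    elif spec.variant == "disc":
        dx = _periodic_delta(xs - spec.x0[0])
        dy = _periodic_delta(ys - spec.x0[1])
        F = (np.hypot(dx, dy) <= spec.sigma_X).astype(float)
        if spec.edge_blur > 0:
            F = _gaussian_blur2d(F, spec.edge_blur)
        F = spec.rbar_X * (spec.c + (1 - spec.c) * F)
    elif spec.variant == "contrast_map":
        M = np.asarray(spec.contrast_map, dtype=float)
        if M.shape != (nx, ny):
            raise ParameterError("contrast map shape must match the grid")
        if np.any(M < 0):
            raise ParameterError("contrasts must be non-negative")
        if spec.edge_blur > 0:
            M = _gaussian_blur2d(M, spec.edge_blur)
        F = M
    else:
        raise ParameterError(f"unknown stimulus variant {spec.variant!r}")
    if spec.calibrate:
        lo, hi = float(F.min()), float(F.max())
        if hi - lo < 1e-12:
            F = np.full_like(F, spec.r_max)
        else:
            F = spec.r_min + (spec.r_max - spec.r_min) * (F - lo) / (hi - lo)
    return F


def _gaussian_blur2d(F: np.ndarray, width: float) -> np.ndarray:
    nx, ny = F.shape
    n1 = np.fft.fftfreq(nx, 1.0 / nx)[:, None]
    n2 = np.fft.fftfreq(ny, 1.0 / ny)[None, :]
    filt = np.exp(-2 * np.pi**2 * (n1**2 + n2**2) * width**2)
    return np.real(np.fft.ifftn(np.fft.fftn(F) * filt))


def build_stimulus(spec: StimulusSpec, shape: tuple) -> np.ndarray:
    """Evaluate the external rate field r_X(x, theta) on the grid (Hz)."""
    if min(shape) < 1 or any(s < 4 for s in shape[:2]):
        raise ParameterError("grid must have at least 4 points per spatial axis")
    F = _spatial_factor(spec, shape)
    nt = shape[2]
    if spec.variant == "contrast_map" or nt == 1:
        theta_factor = np.ones(nt)
    else:
        thetas = _grid_coords(nt)
        theta_factor = spec.c_theta + (1 - spec.c_theta) * wrapped_gaussian(
            thetas - spec.theta0, spec.sigma_X_theta
        )
    field_vals = F[:, :, None] * theta_factor[None, None, :]
    if np.any(field_vals < 0):
        raise ParameterError("stimulus produced negative rates")
    return field_vals


def _forward(u: np.ndarray) -> np.ndarray:
    return np.fft.fftn(u) / u.size


def _inverse(ut: np.ndarray) -> np.ndarray:
    out = np.fft.ifftn(ut * ut.size)
    resid = np.linalg.norm(out.imag) / max(np.linalg.norm(out.real), 1e-300)
    if resid > 1e-8:
        raise ParameterError(f"inverse transform not real (residue {resid:.2e})")
    return out.real


def _solve_modes(A: np.ndarray, Xt: np.ndarray) -> np.ndarray:
    """Solve the per-mode 2x2 systems A r = X by the closed-form inverse."""
    a, b = A[0, 0], A[0, 1]
    c, d = A[1, 0], A[1, 1]
    det = a * d - b * c
    if np.any(np.abs(det) < 1e-300):
        raise ParameterError("singular per-mode matrix")
    r0 = (d * Xt[0] - b * Xt[1]) / det
    r1 = (a * Xt[1] - c * Xt[0]) / det
    return np.stack([r0, r1])


def spatial_corrected_rates(
    kernels: SpatialKernelSet,
    r_X: np.ndarray,
    epsilon: float | None = None,
    g: float = 12.0,
    return_input: bool = False,
):
    """Linearly corrected rate fields r_E, r_I on the grid (Hz).

    Per mode, solves ``(eps D - W~) r~ = X~`` with ``X~ = W~_X r~_X``; ``g``
    is the rectified-linear gain in Hz per (mV/ms) and D carries the
    mV/ms -> mV/s conversion, as in the discrete solver.  With
    ``return_input`` also returns the mean-input field I = (W r + X)/eps in
    mV/ms.
    """
    eps = kernels.epsilon if epsilon is None else epsilon
    if eps <= 0 or g <= 0:
        raise ParameterError("epsilon and g must be positive")
    shape = r_X.shape
    Wt, WtX = kernel_fourier(kernels, shape)
    rXt = _forward(r_X)
    Xt = WtX * rXt
    A = eps * MV_MS_TO_MV_S / g * np.eye(2)[(...,) + (None,) * 3] - Wt
    rt = _solve_modes(A, Xt)
    r = np.stack([_inverse(rt[0]), _inverse(rt[1])])
    if not return_input:
        return r
    It = (np.einsum("ij...,j...->i...", Wt, rt) + Xt) / eps / MV_MS_TO_MV_S
    I = np.stack([_inverse(It[0]), _inverse(It[1])])
    return r, I


def spatial_balanced_rates(
    kernels: SpatialKernelSet, r_X: np.ndarray, check_feasible: bool = True
) -> np.ndarray:
    """Balanced-limit rate fields ``r~ = -W~^{-1} X~`` (Hz).

    Refuses to run when the reconstructed Fourier series does not decay:
    if the summed mode power over the top octave of retained frequencies is
    not smaller than over the previous octave, the input is sharper than the
    recurrent kernels and balance cannot be realized.
    """
    shape = r_X.shape
    rXt = _forward(r_X)
    # drop stimulus modes at the double-precision noise floor so they are not
    # spuriously amplified by the analytic growth factors below
    floor = 1e-13 * np.abs(rXt).max()
    rXt = np.where(np.abs(rXt) >= floor, rXt, 0.0)
    # W~ factors as W0 * diag(decay_E, decay_I) per mode (column scaling by
    # the presynaptic kernel), so -W~^{-1} X~ = -diag(1/decay) W0^{-1} W0X
    # decay_X r~X.  Solving with the constant W0 and applying the exponent
    # *differences* analytically avoids spurious underflow at high modes.
    W0inv = np.linalg.inv(kernels.W0)
    y = -np.einsum("ij,j...->i...", W0inv, kernels.W0_X[:, None, None, None] * rXt)
    n1, n2, k = _mode_numbers(shape)
    nsq = n1**2 + n2**2
    rt = np.empty_like(y)
    with np.errstate(over="ignore"):
        for i, a in enumerate(("E", "I")):
            log_ratio = -2 * np.pi**2 * (
                nsq * (kernels.alpha["X"] ** 2 - kernels.alpha[a] ** 2)
                + k**2 * (kernels.alpha_theta["X"] ** 2 - kernels.alpha_theta[a] ** 2)
            )
            rt[i] = y[i] * np.exp(np.minimum(log_ratio, 700.0))
    if check_feasible:
        power = np.abs(rt[0]) ** 2 + np.abs(rt[1]) ** 2
        nyq = [max(s // 2, 1) for s in shape]
        frac = np.maximum.reduce([
            np.abs(n1) / nyq[0], np.abs(n2) / nyq[1],
            np.abs(k) / nyq[2] if shape[2] > 1 else np.zeros_like(k),
        ])
        top = power[(frac > 0.5) & (frac <= 1.0)].sum()
        prev = power[(frac > 0.25) & (frac <= 0.5)].sum()
        if (not np.isfinite(top)) or (top > 0 and top >= prev):
            raise BalanceInfeasibleError(
                "balance cannot be realized: external input is narrower than "
                "recurrent connectivity (non-decaying Fourier tail)"
            )
    return np.stack([_inverse(rt[0]), _inverse(rt[1])])


def size_tuning_scan(
    kernels: SpatialKernelSet,
    sigma_X_values,
    epsilon: float | None = None,
    g: float = 12.0,
    stimulus: StimulusSpec | None = None,
    shape: tuple = (64, 64, 1),
) -> dict:
    """Center-neuron rate versus stimulus size.

    For each stimulus width sigma_X the (orientation-averaged by default,
    ntheta = 1) corrected solution is evaluated at the stimulus center.
    Returns the E and I curves and their local-extrema counts (peaks found
    with a small prominence floor to ignore numerical ripple).
    """
    base = stimulus if stimulus is not None else StimulusSpec()
    sigma_X_values = np.asarray(list(sigma_X_values), dtype=float)
    rE, rI = [], []
    ci = (int(base.x0[0] * shape[0]), int(base.x0[1] * shape[1]))
    for sx in sigma_X_values:
        spec = replace(base, sigma_X=float(sx))
        r_X = build_stimulus(spec, shape)
        r = spatial_corrected_rates(kernels, r_X, epsilon=epsilon, g=g)
        rE.append(r[0][ci[0], ci[1], :].mean())
        rI.append(r[1][ci[0], ci[1], :].mean())
    rE = np.array(rE)
    rI = np.array(rI)

    def n_maxima(y: np.ndarray) -> int:
        span = float(y.max() - y.min())
        if span <= 0:
            return 0
        peaks, _ = find_peaks(y, prominence=1e-3 * span)
        return int(peaks.size)

    return {
        "sigma_X": sigma_X_values,
        "rate_E": rE,
        "rate_I": rI,
        "n_maxima_E": n_maxima(rE),
        "n_maxima_I": n_maxima(rI),
        "monotone_I": bool(np.all(np.diff(rI) >= -1e-9 * max(rI.max(), 1.0))),
    }


def sharpness_index(field2d: np.ndarray, axis: int = 0, line: int | None = None):
    """Maximum finite-difference slope magnitude along a center line.

    For a field on an n-point periodic axis the slope is the wrapped
    difference times n (per unit length); a step of height h on an n-point
    grid scores h*n.  Used to compare edge sharpness of input and output
    profiles.
    """
    f = np.asarray(field2d, dtype=float)
    if f.ndim == 3:
        f = f.mean(axis=2)
    if line is None:
        line = f.shape[1 - axis] // 2
    profile = f[:, line] if axis == 0 else f[line, :]
    n = profile.size
    slopes = (np.roll(profile, -1) - profile) * n
    return float(np.max(np.abs(slopes)))


def field_to_csv(field_vals: np.ndarray, path: str) -> None:
    """Flattened CSV with a header line recording the grid shape."""
    shape = field_vals.shape
    with open(path, "w") as fh:
        fh.write("# shape=" + "x".join(str(s) for s in shape) + "\n")
        np.savetxt(fh, field_vals.reshape(-1, 1), delimiter=",")


def field_from_csv(path: str) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# shape="):
            raise ParameterError("missing shape header")
        shape = tuple(int(s) for s in header.split("=")[1].split("x"))
        data = np.loadtxt(fh, delimiter=",")
    return data.reshape(shape)
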