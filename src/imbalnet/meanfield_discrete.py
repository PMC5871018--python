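"""Mean-field rate solutions and the nullspace analysis of amplification.

The balanced limit gives firing rates ``r = -W^{-1} X``; when W is singular
no such solution exists and the mean input cannot stay finite as the
coupling strengthens.  A linear rectified f-I approximation with gain g
yields the finite-size correction ``r = (eps*D - W)^{-1} X`` with
``D = diag(1/g)``, which stays finite even for singular W.  External input
components in the nullspace of ``W^T`` cannot be canceled by recurrent
feedback and are amplified by a factor 1/eps -- or 1/delta with
``delta = |lambda| + eps`` when W is only nearly singular.  This module
computes those solutions and the decomposition that quantifies the
amplified component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import BalanceInfeasibleError, DegenerateGeometryError, ParameterError
from .model_parameters import (
    MV_MS_TO_MV_S,
    CouplingTable,
    PopulationSizes,
    build_meanfield,
    external_drive,
    rescale_stimulus,
)

__all__ = [
    "RateSolution",
    "NullspaceDecomposition",
    "balanced_rates",
    "corrected_rates",
    "nullspace_decompose",
    "amplified_component",
    "partial_stim_expansion",
    "near_singular_scale",
    "SINGULARITY_RTOL",
]

#: W is treated as singular when its smallest singular value is below this
#: fraction of the largest.
SINGULARITY_RTOL = 1e-8


@dataclass(frozen=True)
class RateSolution:
    """Per-population rates (Hz) with bookkeeping.

    ``mean_input`` is ``(W r + X)/eps`` in mV/ms (infinite in the balanced
    limit, reported as None there); ``residual`` is ``||W r + X||``.
    Negative entries are reported, not clipped: the linear model is only
    valid when all rates are strictly positive.
    """

    r: np.ndarray
    residual: float
    method: str
    mean_input: np.ndarray | None = None

    @property
    def any_negative(self) -> bool:
        return bool(np.any(self.r < 0))


@dataclass(frozen=True)
class NullspaceDecomposition:
    """Nullspace geometry of a (near-)singular W under drive X.

    v0 spans null(W), v2 spans null(W^T); X0 is the component of X along v2
    (uncancelable by recurrence) and X1 = X - X0 lies in the column space.
    For multi-dimensional nullspaces v0/v2 are orthonormal bases (columns)
    and the scalar expansion is disabled.
    """

    v0: np.ndarray
    v2: np.ndarray
    lam: complex
    epsilon: float | None
    X0: np.ndarray
    X1: np.ndarray
    nullity: int

    @property
    def delta(self) -> float | None:
        if self.epsilon is None:
            return None
        return abs(self.lam) + self.epsilon


def _sign_fix(v: np.ndarray) -> np.ndarray:
    """Sign convention: first nonzero entry positive, for reproducible output."""
    idx = np.flatnonzero(np.abs(v) > 1e-14)
    if idx.size and v[idx[0]] < 0:
        return -v
    return v


def balanced_rates(W: np.ndarray, X: np.ndarray) -> RateSolution:
    """Balanced-limit rates ``r = -W^{-1} X``.

    Raises
    ------
    BalanceInfeasibleError
        If W is singular (smallest singular value below ``SINGULARITY_RTOL``
        of the largest): no rate vector can cancel X, so the mean input
        cannot remain finite in the strong-coupling limit.
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    sv = np.linalg.svd(W, compute_uv=False)
    if sv[-1] < SINGULARITY_RTOL * sv[0]:
        raise BalanceInfeasibleError(
            "W is singular: it is impossible for the mean input to remain "
            "finite; external drive has a component in null(W^T) that "
            "recurrent feedback cannot cancel"
        )
    r = np.linalg.solve(W, -X)
    residual = float(np.linalg.norm(W @ r + X))
    return RateSolution(r=r, residual=residual, method="balanced")


def corrected_rates(
    W: np.ndarray, X: np.ndarray, epsilon: float, g
) -> RateSolution:
    """Linear finite-size correction ``r = (eps*D - W)^{-1} X``.

    ``g`` is the rectified-linear gain in Hz per (mV/ms), scalar or
    per-population; D carries the mV/ms -> mV/s conversion (see
    :meth:`MeanFieldMatrices.D`).  Finite even when W is singular.  The
    reported ``mean_input`` is in mV/ms.
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    g_arr = np.broadcast_to(np.asarray(g, dtype=float), X.shape)
    if np.any(g_arr <= 0):
        raise ParameterError("gains must be positive")
    A = epsilon * np.diag(MV_MS_TO_MV_S / g_arr) - W
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < SINGULARITY_RTOL * sv[0]:
        raise ParameterError("eps*D - W is numerically singular")
    r = np.linalg.solve(A, X)
    residual = float(np.linalg.norm(W @ r + X))
    return RateSolution(
        r=r,
        residual=residual,
        method="corrected",
        mean_input=(W @ r + X) / epsilon / MV_MS_TO_MV_S,
    )


def nullspace_decompose(
    W: np.ndarray, X: np.ndarray, epsilon: float | None = None
) -> NullspaceDecomposition:
    """Split the drive X into its uncancelable and cancelable parts.

    v0 and v2 come from the singular vectors of the smallest singular
    value(s); lambda is the eigenvalue of W of smallest magnitude.  Both
    vectors use the sign convention that their first nonzero entry is
    positive.
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    U, sv, Vt = np.linalg.svd(W)
    small = sv < SINGULARITY_RTOL * sv[0]
    nullity = int(np.sum(small))
    eig = np.linalg.eigvals(W)
    lam = eig[np.argmin(np.abs(eig))]
    if nullity == 0:
        # empty nullspace: keep the least-significant singular directions for
        # reference but X0 = 0
        v0 = _sign_fix(Vt[-1])
        v2 = _sign_fix(U[:, -1])
        X0 = np.zeros_like(X)
    elif nullity == 1:
        v0 = _sign_fix(Vt[-1])
        v2 = _sign_fix(U[:, -1])
        X0 = (v2 @ X) * v2
    else:
        v0 = Vt[-nullity:].T  # orthonormal columns spanning null(W)
        v2 = U[:, -nullity:]
        X0 = v2 @ (v2.T @ X)
    return NullspaceDecomposition(
        v0=v0, v2=v2, lam=lam, epsilon=epsilon, X0=X0, X1=X - X0,
        nullity=nullity,
    )


def amplified_component(W: np.ndarray, X: np.ndarray, g) -> np.ndarray:
    """The O(1/eps) rate component ``r0 = (v2.X / v2.D.v0) v0``.

    ``g`` in Hz per (mV/ms), as elsewhere.  Requires a one-dimensional
    nullspace; r0 lies in null(W) and equals the limit of
    ``eps * corrected_rates`` as eps -> 0.  For a rescaled stimulus
    ``s = eps * S * MV_MS_TO_MV_S`` in the drive, the amplified rate r0/eps
    works out to the physical ``g * S`` response.  Returns the zero vector
    when W is invertible (no amplification).
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    dec = nullspace_decompose(W, X)
    if dec.nullity == 0:
        return np.zeros_like(X)
    if dec.nullity > 1:
        raise DegenerateGeometryError(
            "scalar amplified component requires a one-dimensional nullspace"
        )
    g_arr = np.broadcast_to(np.asarray(g, dtype=float), X.shape)
    denom = dec.v2 @ (dec.v0 * MV_MS_TO_MV_S / g_arr)
    if abs(denom) < 1e-14:
        raise DegenerateGeometryError("v2 . D v0 = 0: amplified component undefined")
    return (dec.v2 @ X) / denom * dec.v0


def partial_stim_expansion(
    coupling: CouplingTable,
    sizes: PopulationSizes,
    g: float,
    S: float,
    r_X: float = 5.0,
    epsilon: float | None = None,
) -> dict:
    """Leading-order rates under partial stimulation of a fraction q.

    Stimulating only a fraction q of the excitatory population makes the
    three-population (expressing / non-expressing / inhibitory) W singular,
    so the off-stimulus rates r_off are obtained from the two-population
    balanced solution replicated across the excitatory split, and the
    on-stimulus rates acquire an amplified component::

        r_on = r_off + (g*s/eps) * [1-q, -q, 0] + O(s) + O(eps)

    with the rescaled stimulus ``s`` of :func:`rescale_stimulus`, so the
    leading stimulus response is ``g*S*[1-q,-q,0]`` independent of eps.  Returns the expansion pieces together with the exact
    corrected solutions for comparison, and ``c = |w_IE / w_II|``, the
    relative inhibitory gain appearing in the O(s) term.
    """
    mf2 = build_meanfield(coupling, sizes, "EI")
    mf3 = build_meanfield(coupling, sizes, "exp-nexp-I")
    eps = mf3.epsilon if epsilon is None else epsilon
    q = sizes.q
    if not 0.0 < q < 1.0:
        raise ParameterError("partial stimulation requires q in (0, 1)")
    s = rescale_stimulus(S, eps)

    r2 = balanced_rates(mf2.W, external_drive(mf2, r_X)).r
    r_off = np.array([r2[0], r2[0], r2[1]])

    amp = g * S * np.array([1.0 - q, -q, 0.0])
    r_on_leading = r_off + amp

    X3_off = external_drive(mf3, r_X)
    X3_on = external_drive(mf3, r_X, stim=[s, 0.0, 0.0])
    exact_off = corrected_rates(mf3.W, X3_off, eps, g)
    exact_on = corrected_rates(mf3.W, X3_on, eps, g)

    c = abs(mf3.W[2, 0] / q / mf3.W[2, 2])
    return {
        "r_off": r_off,
        "r_on_leading": r_on_leading,
        "amplified": amp,
        "exact_off": exact_off,
        "exact_on": exact_on,
        "c": c,
        "s": s,
        "epsilon": eps,
        "negative_rates": bool(np.any(r_on_leading < 0)),
    }


def near_singular_scale(W: np.ndarray, epsilon: float) -> dict:
    """Amplification scale for nearly singular W.

    Returns the smallest-magnitude eigenvalue lambda of W, its unit left
    eigenvector v (of W^T), and ``delta = |lambda| + eps``; input components
    along v are amplified by 1/delta.
    """
    W = np.asarray(W, dtype=float)
    eigvals, eigvecs = np.linalg.eig(W.T)
    i = int(np.argmin(np.abs(eigvals)))
    lam = eigvals[i]
    v = eigvecs[:, i]
    if np.max(np.abs(v.imag)) < 1e-12:
        v = _sign_fix(np.real(v))
    v = v / np.linalg.norm(v)
    delta = float(abs(lam) + epsilon)
    return {
        "lam": lam if abs(lam.imag) > 1e-12 else float(lam.real),
        "delta": delta,
        "v": v,
        "amplification": 1.0 / delta,
    }
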