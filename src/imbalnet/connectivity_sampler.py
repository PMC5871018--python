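"""Realize explicit synaptic graphs from the coupling table.

Two sampling schemes are implemented, both with fixed out-degree and
sampling with replacement so that repeated draws accumulate synaptic
multiplicity:

* uniform random sampling -- every presynaptic neuron in population b picks
  exactly ``round(p_ab * N_a)`` postsynaptic targets uniformly from
  population a;
* distance- and tuning-dependent sampling -- targets are drawn with
  probability proportional to a wrapped-Gaussian kernel of the periodic
  displacement in physical space (unit square) and orientation space
  (unit circle), with the same fixed out-degree so the mean connection
  probability equals ``p_ab`` by construction.

Synaptic weights are (number of contacts) * J_ab.  Self-connections are
permitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import ParameterError

__all__ = [
    "SpatialLayout",
    "SynapticGraph",
    "grid_layout",
    "wrapped_gaussian",
    "sample_graph",
    "sample_spatial_block",
    "sample_spatial_graph",
]

_BLOCK_ORDER = [("E", "E"), ("E", "I"), ("E", "X"),
                ("I", "E"), ("I", "I"), ("I", "X")]


@dataclass(frozen=True)
class SpatialLayout:
    """Neuron positions on the unit square and preferred orientations.

    Positions form a regular grid (cell centers, so periodic distances are
    symmetric); orientations are uniform on [0, 1), i.e. fractions of 180
    degrees.
    """

    positions: np.ndarray  # (n, 2)
    orientations: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ParameterError("positions must be (n, 2)")
        if np.any((self.orientations < 0) | (self.orientations >= 1)):
            raise ParameterError("orientations must lie in [0, 1)")

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass
class SynapticGraph:
    """Sparse weighted connections per ordered (post, pre) population pair.

    ``blocks[(a, b)]`` is an ``N_a x N_b`` CSR matrix whose entries are
    integer multiples of ``J[(a, b)]``; ``out_degree[(a, b)]`` is the exact
    number of draws each presynaptic neuron made into population a.
    """

    blocks: dict
    out_degree: dict
    J: dict
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def block(self, post: str, pre: str) -> sp.csr_matrix:
        return self.blocks[(post, pre)]

    def to_edge_list(self, post: str, pre: str) -> pd.DataFrame:
        coo = self.blocks[(post, pre)].tocoo()
        return pd.DataFrame(
            {"pre": coo.col, "post": coo.row, "weight": coo.data}
        ).sort_values(["pre", "post"], ignore_index=True)

    def export_csv(self, prefix: str) -> None:
        """Write one edge-list CSV per block plus a JSON metadata sidecar."""
        for (a, b) in self.blocks:
            self.to_edge_list(a, b).to_csv(f"{prefix}_{a}{b}.csv", index=False)
        sidecar = {
            "seed": self.seed,
            "out_degree": {f"{a}{b}": v for (a, b), v in self.out_degree.items()},
            "J": {f"{a}{b}": v for (a, b), v in self.J.items()},
            **self.meta,
        }
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def grid_layout(count: int, rng: np.random.Generator) -> SpatialLayout:
    """Arrange ``count`` neurons on a uniform grid covering the unit square.

    Non-square counts use the most-square factorization; positions are cell
    centers, row-major.  Orientations are drawn uniformly from [0, 1).
    """
    if count <= 0:
        raise ParameterError("count must be positive")
    nx = int(np.sqrt(count))
    while count % nx:
        nx -= 1
    ny = count // nx
    xs = (np.arange(nx) + 0.5) / nx
    ys = (np.arange(ny) + 0.5) / ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    positions = np.column_stack([gx.ravel(), gy.ravel()])
    orientations = rng.random(count)
    return SpatialLayout(positions=positions, orientations=orientations)


def wrapped_gaussian(u, alpha: float):
    """Wrapped Gaussian density on the unit circle.

    ``g(u; alpha) = sum_j exp(-(u+j)^2/(2 alpha^2)) / sqrt(2 pi alpha^2)``,
    truncated when additional terms fall below 1e-12 of the running sum.
    Symmetric, periodic with period 1, and integrates to one.
    """
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    u = np.asarray(u, dtype=float)
    # wrap into [-0.5, 0.5) so few terms are needed
    u = u - np.round(u)
    norm = 1.0 / np.sqrt(2.0 * np.pi) / alpha
    total = norm * np.exp(-u**2 / (2 * alpha**2))
    j = 1
    while True:
        term = norm * (
            np.exp(-((u + j) ** 2) / (2 * alpha**2))
            + np.exp(-((u - j) ** 2) / (2 * alpha**2))
        )
        total = total + term
        if np.max(term) < 1e-12 * np.max(total):
            break
        j += 1
    return total


def _sample_block(
    n_post: int, n_pre: int, p: float, J: float, rng: np.random.Generator
) -> tuple[sp.csr_matrix, int]:
    n_out = int(round(p * n_post))
    if n_out < 0:
        raise ParameterError("p * N must be non-negative")
    if n_out == 0 or n_pre == 0:
        return sp.csr_matrix((n_post, n_pre)), n_out
    targets = rng.integers(0, n_post, size=(n_pre, n_out))
    rows = targets.ravel()
    cols = np.repeat(np.arange(n_pre), n_out)
    mat = sp.coo_matrix(
        (np.full(rows.size, float(J)), (rows, cols)), shape=(n_post, n_pre)
    ).tocsr()
    mat.sum_duplicates()
    return mat, n_out


def sample_graph(coupling, sizes, seed: int) -> SynapticGraph:
    """Uniform random graph with exact out-degrees (spatially unstructured).

    For every presynaptic neuron in population b the sampler draws exactly
    ``round(p_ab * N_a)`` postsynaptic targets in population a, uniformly
    with replacement.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    blocks, degrees, J = {}, {}, {}
    for (a, b) in _BLOCK_ORDER:
        mat, n_out = _sample_block(
            sizes.count(a), sizes.count(b), coupling.p[(a, b)],
            coupling.J[(a, b)], rng,
        )
        blocks[(a, b)] = mat
        degrees[(a, b)] = n_out
        J[(a, b)] = coupling.J[(a, b)]
    return SynapticGraph(blocks=blocks, out_degree=degrees, J=J, seed=seed)


def sample_spatial_block(
    post_layout: SpatialLayout,
    pre_layout: SpatialLayout,
    p_bar: float,
    J: float,
    alpha: float,
    alpha_theta: float,
    rng: np.random.Generator,
) -> tuple[sp.csr_matrix, int]:
    """Distance/tuning-dependent block with fixed out-degree.

    Each presynaptic neuron draws ``round(p_bar * N_post)`` targets with
    replacement, choosing each target with probability proportional to
    ``G(dx; alpha) * g(dtheta; alpha_theta)`` evaluated over all candidates
    with periodic distances.  The exact categorical draw (rather than
    rejection) keeps the realized mean connection probability at ``p_bar``.
    """
    if alpha <= 0 or alpha_theta <= 0:
        raise ParameterError("kernel widths must be positive")
    n_post, n_pre = len(post_layout), len(pre_layout)
    n_out = int(round(p_bar * n_post))
    if n_out == 0:
        return sp.csr_matrix((n_post, n_pre)), 0
    rows_all = np.empty(n_pre * n_out, dtype=np.int64)
    for j in range(n_pre):
        dx = post_layout.positions - pre_layout.positions[j]
        dth = post_layout.orientations - pre_layout.orientations[j]
        kern = (
            wrapped_gaussian(dx[:, 0], alpha)
            * wrapped_gaussian(dx[:, 1], alpha)
            * wrapped_gaussian(dth, alpha_theta)
        )
        probs = kern / kern.sum()
        rows_all[j * n_out:(j + 1) * n_out] = rng.choice(
            n_post, size=n_out, replace=True, p=probs
        )
    cols = np.repeat(np.arange(n_pre), n_out)
    mat = sp.coo_matrix(
        (np.full(rows_all.size, float(J)), (rows_all, cols)),
        shape=(n_post, n_pre),
    ).tocsr()
    mat.sum_duplicates()
    return mat, n_out


def sample_spatial_graph(
    layouts: dict,
    p_bar: dict,
    J: dict,
    alpha: dict,
    alpha_theta: dict,
    seed: int,
    pairs=None,
) -> SynapticGraph:
    """Full distance/tuning-dependent graph over population pairs.

    ``layouts`` maps population labels to :class:`SpatialLayout`; ``alpha``
    and ``alpha_theta`` are keyed by the presynaptic population (projection
    widths travel with the sender).
    """
    rng = np.random.default_rng(seed)
    if pairs is None:
        pairs = [pr for pr in _BLOCK_ORDER if pr[0] in layouts and pr[1] in layouts]
    blocks, degrees, Jout = {}, {}, {}
    for (a, b) in pairs:
        mat, n_out = sample_spatial_block(
            layouts[a], layouts[b], p_bar[(a, b)], J[(a, b)],
            alpha[b], alpha_theta[b], rng,
        )
        blocks[(a, b)] = mat
        degrees[(a, b)] = n_out
        Jout[(a, b)] = J[(a, b)]
    return SynapticGraph(blocks=blocks, out_degree=degrees, J=Jout, seed=seed)
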