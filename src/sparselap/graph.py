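"""Individual-by-individual weight graph and normalized Laplacian spectrum.

Individuals are vertices; edges connect genetically *close* pairs only. The
distance is a monotone transform of the between-individual Pearson
correlation of normalized genotypes, edges get a Gaussian (heat-kernel)
weight w_ij = exp(-d_ij^2 / t) when d_ij <= epsilon and 0 otherwise, and the
embedding coordinates (LAP1, LAP2, ...) are the eigenfunctions of the
normalized graph Laplacian attached to its smallest nontrivial eigenvalues.
Because only near neighbors carry edges, the embedding preserves local
structure and is far less sensitive to outlying individuals than PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree

from .errors import DisconnectedGraphError, InputError
from .genotypes import NormalizedMatrix


@dataclass
class WeightGraph:
    """Symmetric nonnegative adjacency with zero diagonal.

    ``degrees[i]`` is the weighted degree (row sum); ``epsilon`` is the
    resolved neighborhood radius actually used.
    """

    W: np.ndarray
    degrees: np.ndarray
    t: float
    epsilon: float
    n_edges: int

    @property
    def n_vertices(self) -> int:
        return self.W.shape[0]


@dataclass
class LaplacianSpectrum:
    """K+1 smallest eigenpairs of the normalized graph Laplacian.

    Eigenvalues ascend from 0; index 0 is the trivial pair (eigenvalue 0,
    eigenfunction proportional to D^{1/2} 1 under the symmetric
    normalization, constant under the random-walk one).
    """

    eigenvalues: np.ndarray
    eigenfunctions: np.ndarray
    normalization: str
    trivial_index: int = 0

    @property
    def n_nontrivial(self) -> int:
        return self.eigenvalues.size - 1


@dataclass
class Embedding:
    """Low-dimensional coordinates LAP1..LAPK (nontrivial eigenfunctions)."""

    coords: np.ndarray
    sample_ids: list[str]
    source: str  # "full" or "sparse"
    params: dict

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def to_frame(self):
        import pandas as pd

        prefix = "SLAP" if self.source == "sparse" else "LAP"
        cols = [f"{prefix}{k + 1}" for k in range(self.n_components)]
        df = pd.DataFrame(self.coords, index=self.sample_ids, columns=cols)
        df.index.name = "sample_id"
        return df


def sample_correlation(X, sample_ids=None) -> np.ndarray:
    """Pearson correlation between individuals (rows of the normalized matrix).

    Raises on zero-variance rows, naming the offending sample.
    """
    if isinstance(X, NormalizedMatrix):
        sample_ids = sample_ids or X.sample_ids
        X = X.X
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        i = int(np.argmin(sd))
        name = sample_ids[i] if sample_ids else str(i)
        raise InputError(f"sample {name!r} has zero variance across markers")
    R = np.corrcoef(X)
    R = np.clip(R, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def genetic_distance(R: np.ndarray, formula: str = "sqrt") -> np.ndarray:
    """Distance from correlation: sqrt(1 - r) (default) or 1 - r.

    Both map r = 1 (identical individuals) to 0 and decrease monotonically
    in r; sqrt(1 - r) is the metric form (it embeds isometrically for PSD
    correlation matrices).
    """
    R = np.asarray(R, dtype=float)
    if np.nanmax(np.abs(R)) > 1.0 + 1e-10:
        raise InputError("correlation entries must lie in [-1, 1]")
    R = np.clip(R, -1.0, 1.0)
    if formula == "sqrt":
        D = np.sqrt(np.maximum(1.0 - R, 0.0))
    elif formula == "linear":
        D = 1.0 - R
    else:
        raise InputError(f"unknown distance formula {formula!r}")
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def resolve_epsilon(D: np.ndarray, epsilon) -> float:
    """Turn an epsilon spec into a radius.

    Accepts a positive float (absolute radius), ``("quantile", q)`` — the
    q-th quantile of off-diagonal distances — or ``"connect"``, the largest
    minimum-spanning-tree edge (the smallest radius keeping the graph
    connected), padded by 1e-9 relative.
    """
    n = D.shape[0]
    off = D[np.triu_indices(n, 1)]
    if isinstance(epsilon, str):
        if epsilon != "connect":
            raise InputError(f"unknown epsilon spec {epsilon!r}")
        mst = minimum_spanning_tree(scipy.sparse.csr_matrix(D + 1e-300))
        return float(mst.data.max()) * (1.0 + 1e-9)
    if isinstance(epsilon, (tuple, list)):
        kind, q = epsilon
        if kind != "quantile" or not (0 < q <= 1):
            raise InputError(f"bad epsilon spec {epsilon!r}")
        return float(np.quantile(off, q))
    eps = float(epsilon)
    if eps <= 0:
        raise InputError(f"epsilon must be positive, got {eps}")
    return eps


def build_weight_graph(D: np.ndarray, t: float = 1.0,
                       epsilon=("quantile", 0.05)) -> WeightGraph:
    """Gaussian weights on the epsilon-neighborhood graph.

    w_ij = exp(-d_ij^2 / t) if d_ij <= epsilon and i != j, else 0. ``t`` is
    the global diffusion scale; ``epsilon`` sets each subject's neighborhood
    size (see `resolve_epsilon`). Any vertex left with no neighbor is an
    error — raise epsilon.
    """
    if t <= 0:
        raise InputError(f"diffusion scale t must be positive, got {t}")
    D = np.asarray(D, dtype=float)
    eps = resolve_epsilon(D, epsilon)
    W = np.where(D <= eps, np.exp(-(D ** 2) / t), 0.0)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    degrees = W.sum(axis=1)
    if np.any(degrees == 0):
        k = int(np.argmin(degrees))
        raise DisconnectedGraphError(
            n_components=int(np.sum(degrees == 0)) + 1,
            message=f"vertex {k} has no neighbors within epsilon={eps:.4g}; "
            "increase epsilon",
        )
    n_edges = int(np.count_nonzero(np.triu(W, 1)))
    return WeightGraph(W=W, degrees=degrees, t=t, epsilon=eps, n_edges=n_edges)


def _check_connected(W: np.ndarray) -> None:
    ncomp, _ = connected_components(scipy.sparse.csr_matrix(W), directed=False)
    if ncomp > 1:
        raise DisconnectedGraphError(ncomp)


def laplacian_spectrum(Wg: WeightGraph, K: int = 2,
                       normalization: str = "symmetric") -> LaplacianSpectrum:
    """K+1 smallest eigenpairs of the normalized Laplacian.

    The symmetric normalization is L_sym = I - D^{-1/2} W D^{-1/2}
    (symmetric PSD, spectrum in [0, 2]); the random-walk normalization
    D^{-1} L shares the same eigenvalues, with eigenfunctions
    psi = D^{-1/2} phi. A disconnected graph is an error reporting the
    component count (the multiplicity of eigenvalue 0).

    Sign convention: in every eigenfunction the entry of largest magnitude
    is made positive, so results are deterministic.
    """
    if K < 1:
        raise InputError(f"K must be >= 1, got {K}")
    n = Wg.n_vertices
    if K + 1 > n:
        raise InputError(f"K+1={K + 1} eigenpairs requested but only {n} vertices")
    if normalization not in ("symmetric", "random_walk"):
        raise InputError(f"unknown normalization {normalization!r}")
    _check_connected(Wg.W)
    dinv_sqrt = 1.0 / np.sqrt(Wg.degrees)
    Lsym = -(dinv_sqrt[:, None] * Wg.W * dinv_sqrt[None, :])
    np.fill_diagonal(Lsym, 1.0)
    Lsym = (Lsym + Lsym.T) / 2.0
    if n < 2000:
        vals, vecs = scipy.linalg.eigh(Lsym, subset_by_index=[0, K])
    else:
        # shift-invert converges fast for the smallest eigenvalues
        vals, vecs = scipy.sparse.linalg.eigsh(
            scipy.sparse.csr_matrix(Lsym), k=K + 1, sigma=-1e-6, which="LM"
        )
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    vals = np.maximum(vals, 0.0)
    vals[0] = 0.0
    if normalization == "random_walk":
        vecs = dinv_sqrt[:, None] * vecs
        vecs /= np.linalg.norm(vecs, axis=0, keepdims=True)
    vecs = _fix_signs(vecs)
    return LaplacianSpectrum(
        eigenvalues=vals, eigenfunctions=vecs, normalization=normalization
    )


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    vecs = vecs.copy()
    for k in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[i, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return vecs


def embed(spectrum: LaplacianSpectrum, K: int, sample_ids=None,
          source: str = "full", params: dict | None = None) -> Embedding:
    """Drop the trivial eigenfunction and return LAP1..LAPK coordinates."""
    if K > spectrum.n_nontrivial:
        raise InputError(
            f"K={K} requested but spectrum holds {spectrum.n_nontrivial} "
            "nontrivial eigenpairs"
        )
    coords = spectrum.eigenfunctions[:, 1:K + 1].copy()
    n = coords.shape[0]
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    return Embedding(coords=coords, sample_ids=ids, source=source,
                     params=dict(params or {}))


def embed_normalized(
    X: NormalizedMatrix,
    K: int = 2,
    t: float = 1.0,
    epsilon=("quantile", 0.05),
    distance: str = "sqrt",
    normalization: str = "symmetric",
    source: str = "full",
) -> tuple[Embedding, LaplacianSpectrum]:
    """Full pipeline: correlation -> distance -> weight graph -> spectrum -> embedding."""
    R = sample_correlation(X)
    D = genetic_distance(R, formula=distance)
    Wg = build_weight_graph(D, t=t, epsilon=epsilon)
    spec = laplacian_spectrum(Wg, K=K, normalization=normalization)
    params = {
        "K": K, "t": t, "epsilon": epsilon, "epsilon_resolved": Wg.epsilon,
        "distance": distance, "normalization": normalization,
    }
    return embed(spec, K, sample_ids=X.sample_ids, source=source, params=params), spec
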