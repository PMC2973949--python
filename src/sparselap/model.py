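"""Model/Results interface tying the pipeline together.

`SparseLaplacianEigenmap` is constructed from genotype data and pipeline
parameters; `fit` runs QC -> imputation -> normalization -> weight graph ->
Laplacian spectrum -> elastic-net loadings -> marker ranking and returns a
`SparseLaplacianResults` carrying the embedding, the sparse loadings, the
marker scores and a `summary()` table, with `sparse_embedding` /
`select_top` / plotting hanging off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate, genotypes as gio, graph, selection
from .errors import InputError
from .genotypes import GenotypeMatrix, NormalizedMatrix
from .graph import Embedding, LaplacianSpectrum
from .selection import MarkerRanking, ScanConfig, SparseLoadings


class SparseLaplacianEigenmap:
    """Sparse Laplacian eigenfunction model of population structure.

    Parameters
    ----------
    genotypes
        A `GenotypeMatrix` (see `from_dataframe` / `from_file` for other
        entry points).
    n_components
        Number of nontrivial Laplacian eigenfunctions K to retain
        (LAP1..LAPK).
    t
        Global diffusion scale of the Gaussian edge weight exp(-d^2/t).
    epsilon
        Neighborhood radius: absolute float, ``("quantile", q)`` of the
        off-diagonal distances, or ``"connect"`` (smallest connecting
        radius). Larger values emphasize global patterns, smaller values
        local ones.
    distance
        ``"sqrt"`` for d = sqrt(1 - r), ``"linear"`` for d = 1 - r.
    normalization
        ``"symmetric"`` or ``"random_walk"`` Laplacian normalization (same
        spectrum).
    qc, maf_min, miss_max
        Whether/how to QC-filter markers before the analysis.

    Examples
    --------
    >>> model = SparseLaplacianEigenmap(G, n_components=2)
    >>> res = model.fit(lambda1="auto", target_nonzero=0.03)
    >>> panel = res.select_top(300)
    >>> slap = res.sparse_embedding(panel)
    """

    def __init__(self, genotypes: GenotypeMatrix, *, n_components: int = 2,
                 t: float = 1.0, epsilon=("quantile", 0.05),
                 distance: str = "sqrt", normalization: str = "symmetric",
                 qc: bool = True, maf_min: float = 0.01, miss_max: float = 0.10):
        self.raw = genotypes
        self.n_components = int(n_components)
        self.t = float(t)
        self.epsilon = epsilon
        self.distance = distance
        self.normalization = normalization
        self.qc = qc
        self.maf_min = maf_min
        self.miss_max = miss_max
        self._prepared: tuple[GenotypeMatrix, NormalizedMatrix] | None = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, markers: pd.DataFrame | None = None,
                       **kwargs) -> "SparseLaplacianEigenmap":
        """Build from a samples x markers DataFrame ({0, 0.5, 1, NaN})."""
        if markers is None:
            markers = gio.default_marker_table(df.columns)
        G = GenotypeMatrix(df.to_numpy(dtype=float),
                           list(df.index.astype(str)), markers)
        return cls(G, **kwargs)

    @classmethod
    def from_file(cls, path, format: str | None = None, **kwargs):
        return cls(gio.load_genotypes(path, format=format), **kwargs)

    # -- pipeline ---------------------------------------------------------
    def _prepare(self) -> tuple[GenotypeMatrix, NormalizedMatrix]:
        if self._prepared is None:
            Gi, X = gio.prepare(self.raw, qc=self.qc, maf_min=self.maf_min,
                                miss_max=self.miss_max)
            # restrict the genotype matrix to the markers that survived
            # normalization so genotype and X columns correspond 1:1
            if X.kept_marker_indices.size != Gi.n_markers:
                Gi = Gi.subset_markers(X.kept_marker_indices)
            self._prepared = (Gi, X)
        return self._prepared

    @property
    def exog_names(self) -> list[str]:
        return list(self._prepare()[1].marker_ids)

    def embed(self) -> tuple[Embedding, LaplacianSpectrum]:
        """Full-data Laplacian embedding (no marker selection)."""
        _, X = self._prepare()
        return graph.embed_normalized(
            X, K=self.n_components, t=self.t, epsilon=self.epsilon,
            distance=self.distance, normalization=self.normalization,
        )

    def fit(self, lambda1="auto", lambda2: float | None = None,
            weights="uniform", target_nonzero: float = 0.01,
            scan: ScanConfig | None = None) -> "SparseLaplacianResults":
        """Fit the sparse loadings and rank all markers.

        Parameters
        ----------
        lambda1
            L1 penalty; ``"auto"`` picks the largest value on a geometric
            grid at which, on average, ``target_nonzero`` of the loadings
            per eigenfunction are nonzero.
        lambda2
            L2 penalty; defaults to lambda1 (one effective tuning knob).
        weights
            Eigenfunction weights of the rank statistic: ``"uniform"``,
            ``"eigen_variance"`` or an explicit vector.
        scan
            Optional `ScanConfig`; when given and the marker count exceeds
            ``scan.group_size``, the stepwise whole-genome scan is used.
        """
        Gq, X = self._prepare()
        embedding, spectrum = self.embed()
        Phi = embedding.coords
        eigvals = spectrum.eigenvalues[1:self.n_components + 1]
        if lambda1 == "auto":
            ratio = 1.0 if lambda2 is None else None
            if ratio is None:
                raise InputError("with lambda1='auto', leave lambda2 unset")
            lam1, loadings = selection.tune_lambda1(
                X, Phi, target_nonzero=target_nonzero, lambda2_ratio=ratio)
            lam2 = lam1
            if scan is not None and X.n_markers > scan.group_size:
                loadings = None  # re-fit through the scan below
        else:
            lam1 = float(lambda1)
            lam2 = lam1 if lambda2 is None else float(lambda2)
            loadings = None
        if scan is not None and X.n_markers > scan.group_size:
            ranking = selection.genome_scan(
                X, Phi, scan, Gq.markers, lam1, lam2,
                weights=weights, eigenvalues=eigvals)
            loadings = None
        else:
            if loadings is None:
                loadings = selection.fit_sparse_loadings(X, Phi, lam1, lam2)
            ranking = selection.rank_markers(loadings, weights, eigvals)
        return SparseLaplacianResults(
            model=self, genotypes=Gq, normalized=X, embedding=embedding,
            spectrum=spectrum, loadings=loadings, ranking=ranking,
            lambda1=lam1, lambda2=lam2,
        )


@dataclass
class SparseLaplacianResults:
    """Fitted sparse Laplacian eigenmap: embedding, loadings, marker ranks."""

    model: SparseLaplacianEigenmap
    genotypes: GenotypeMatrix          # post-QC, imputed, non-constant markers
    normalized: NormalizedMatrix
    embedding: Embedding
    spectrum: LaplacianSpectrum
    loadings: SparseLoadings | None
    ranking: MarkerRanking
    lambda1: float
    lambda2: float
    _cache: dict = field(default_factory=dict, repr=False)

    # -- accessors --------------------------------------------------------
    @property
    def eigenvalues(self) -> np.ndarray:
        """Nontrivial Laplacian eigenvalues backing LAP1..LAPK."""
        return self.spectrum.eigenvalues[1:self.model.n_components + 1]

    @property
    def scores(self) -> np.ndarray:
        return self.ranking.scores

    def scores_frame(self, n_top: int | None = None,
                     labels=None) -> pd.DataFrame:
        """Ranked marker table (rank, id, chrom, pos, score), optionally with
        the informativeness-for-assignment column computed from ``labels``."""
        order = self.ranking.order
        if n_top is not None:
            order = order[:n_top]
        mk = self.genotypes.markers.iloc[order]
        df = pd.DataFrame({
            "rank": np.arange(1, order.size + 1),
            "marker": mk["id"].to_numpy(),
            "chrom": mk["chrom"].to_numpy(),
            "pos": mk["pos"].to_numpy(),
            "score": self.ranking.scores[order],
        })
        if labels is not None:
            In = evaluate.informativeness_for_assignment(self.genotypes, labels)
            df["In"] = In[order]
        return df

    # -- selection / re-embedding ----------------------------------------
    def select_top(self, n_top: int) -> np.ndarray:
        """Indices (into this results' marker axis) of the top panel."""
        return selection.select_top(self.ranking, n_top)

    def panel_ids(self, n_top: int) -> list[str]:
        idx = self.select_top(n_top)
        return [self.genotypes.marker_ids[i] for i in idx]

    def sparse_embedding(self, panel) -> Embedding:
        """Recompute the embedding from a marker panel only (SLAP).

        ``panel`` is an integer, meaning the top-``panel`` markers of the
        ranking, or an explicit index array.
        """
        idx = self.select_top(panel) if np.isscalar(panel) else np.asarray(panel, int)
        return selection.sparse_eigenfunctions(
            self.genotypes, idx, K=self.model.n_components, t=self.model.t,
            epsilon=self.model.epsilon, distance=self.model.distance,
            normalization=self.model.normalization,
        )

    # -- reporting --------------------------------------------------------
    def summary(self, n_top: int = 10) -> str:
        """Human-readable fit summary in the spirit of statsmodels."""
        m = self.model
        lines = [
            "Sparse Laplacian Eigenmap Results",
            "=" * 45,
            f"samples:               {self.genotypes.n_samples}",
            f"markers (post-QC):     {self.genotypes.n_markers}",
            f"components K:          {m.n_components}",
            f"diffusion scale t:     {m.t}",
            f"epsilon:               {self.embedding.params.get('epsilon_resolved', m.epsilon):.6g}",
            f"distance:              {m.distance}",
            f"normalization:         {m.normalization}",
            f"lambda1 / lambda2:     {self.lambda1:.6g} / {self.lambda2:.6g}",
            f"eigenvalues:           "
            + ", ".join(f"{v:.4g}" for v in self.eigenvalues),
            f"zero-score fraction:   {self.ranking.zero_fraction:.4f}",
        ]
        if self.loadings is not None:
            lines.append(
                "loading sparsity:      "
                + ", ".join(f"{s:.4f}" for s in self.loadings.sparsity)
            )
        lines.append("")
        lines.append(f"Top {n_top} markers by rank statistic S_j:")
        lines.append(self.scores_frame(n_top=n_top).to_string(index=False))
        return "\n".join(lines)

    def plot_embedding(self, labels=None, dims=(1, 2), sparse_panel=None,
                       ax=None):
        """Biplot of two embedding dimensions, optionally colored by labels.

        With ``sparse_panel`` given, plots the panel's SLAP coordinates
        instead of the full-data LAP coordinates.
        """
        import matplotlib.pyplot as plt

        emb = (self.sparse_embedding(sparse_panel) if sparse_panel is not None
               else self.embedding)
        i, j = dims[0] - 1, dims[1] - 1
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        prefix = "SLAP" if emb.source == "sparse" else "LAP"
        if labels is None:
            ax.scatter(emb.coords[:, i], emb.coords[:, j], s=12, alpha=0.7)
        else:
            labels = np.asarray(labels)
            for lab in np.unique(labels):
                sel = labels == lab
                ax.scatter(emb.coords[sel, i], emb.coords[sel, j], s=12,
                           alpha=0.7, label=str(lab))
            if np.unique(labels).size <= 12:
                ax.legend(fontsize=7)
        ax.set_xlabel(f"{prefix}{dims[0]}")
        ax.set_ylabel(f"{prefix}{dims[1]}")
        return ax
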