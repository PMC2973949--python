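"""Panel-quality metrics: Mantel test, embedding correlation, LD redundancy,
membership prediction, informativeness for assignment.

These quantify how faithfully a small selected marker panel reproduces the
population structure seen with all markers, and how redundant (in LD terms)
or ancestry-informative the panel is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .errors import InputError
from .genotypes import GenotypeMatrix
from .graph import Embedding


@dataclass
class MantelResult:
    """Cross-product Mantel statistic and its permutation null.

    ``z_raw`` is the sum over unordered pairs of products of corresponding
    distances; ``z_score`` standardizes it against the permutation
    distribution; the one-sided p-value has floor 1/(n_perm + 1).
    """

    z_raw: float
    z_score: float
    p_value: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "z_raw": self.z_raw, "z_score": self.z_score,
            "p_value": self.p_value, "n_perm": self.n_perm, "seed": self.seed,
        }


@dataclass
class PredictionReport:
    """Cross-validated membership-prediction accuracy for a marker panel."""

    overall_accuracy: float
    per_class_error: dict
    accuracies: list = field(default_factory=list)
    classifier_config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "per_class_error": self.per_class_error,
            "accuracies": list(self.accuracies),
            "classifier_config": self.classifier_config,
        }


def _check_distance_matrix(D, name):
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InputError(f"{name} must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise InputError(f"{name} must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-10:
        raise InputError(f"{name} must have zero diagonal")
    return D


def mantel_z(D1, D2, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Mantel congruence test between two distance matrices.

    The statistic is z = sum_{i<j} D1_ij * D2_ij; the null is generated by
    jointly permuting rows and columns of D2. One-sided p-value
    (1 + #{perm >= observed}) / (n_perm + 1).
    """
    D1 = _check_distance_matrix(D1, "D1")
    D2 = _check_distance_matrix(D2, "D2")
    n = D1.shape[0]
    if D2.shape[0] != n:
        raise InputError("distance matrices must have the same size")
    z_raw = float((D1 * D2).sum() / 2.0)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for b in range(n_perm):
        p = rng.permutation(n)
        perm_stats[b] = (D1 * D2[np.ix_(p, p)]).sum() / 2.0
    sd = perm_stats.std()
    if sd == 0:
        raise InputError("permutation distribution is degenerate (constant matrix)")
    z_score = (z_raw - perm_stats.mean()) / sd
    p_value = (1.0 + np.sum(perm_stats >= z_raw)) / (n_perm + 1.0)
    return MantelResult(z_raw=z_raw, z_score=float(z_score),
                        p_value=float(p_value), n_perm=n_perm, seed=seed)


def embedding_distances(E) -> np.ndarray:
    """Euclidean distance matrix between embedded individuals."""
    coords = E.coords if isinstance(E, Embedding) else np.asarray(E, float)
    return squareform(pdist(coords))


def eigenmap_correlation(E1, E2) -> np.ndarray:
    """Per-dimension Pearson correlation between two embeddings after sign
    alignment (eigenfunctions are defined up to sign). Values in [0, 1]."""
    A = E1.coords if isinstance(E1, Embedding) else np.asarray(E1, float)
    B = E2.coords if isinstance(E2, Embedding) else np.asarray(E2, float)
    A, B = np.atleast_2d(A.T).T, np.atleast_2d(B.T).T
    if A.shape != B.shape:
        raise InputError(f"embedding shapes differ: {A.shape} vs {B.shape}")
    out = np.empty(A.shape[1])
    for k in range(A.shape[1]):
        a, b = A[:, k], B[:, k]
        if a.std() == 0 or b.std() == 0:
            raise InputError(f"embedding dimension {k + 1} has zero variance")
        out[k] = abs(np.corrcoef(a, b)[0, 1])
    return out


def _pairwise_r2(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared pairwise-complete Pearson correlation between genotype
    columns; second return flags pairs with undefined r^2."""
    mask = ~np.isnan(g)
    gz = np.where(mask, g, 0.0)
    m = mask.astype(float)
    n_ab = m.T @ m
    s_a = gz.T @ m
    s_b = m.T @ gz
    s_ab = gz.T @ gz
    s_aa = (gz ** 2).T @ m
    s_bb = m.T @ (gz ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s_ab - s_a * s_b / n_ab
        var_a = s_aa - s_a ** 2 / n_ab
        var_b = s_bb - s_b ** 2 / n_ab
        r2 = cov ** 2 / (var_a * var_b)
    undefined = (var_a <= 0) | (var_b <= 0) | (n_ab < 2) | ~np.isfinite(r2)
    return np.where(undefined, np.nan, r2), undefined


def ld_r2_summary(G: GenotypeMatrix, panel,
                  bin_edges=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
                  ) -> pd.DataFrame:
    """Distribution of pairwise genotype r^2 within a marker panel.

    r^2 is the squared Pearson correlation of genotype columns with
    pairwise deletion of missing calls (composite LD — no phase needed).
    Bins follow the conventional layout r^2 < e_1, (e_1, e_2], ...,
    r^2 > e_last; pairs with undefined r^2 (a monomorphic marker) are
    counted separately. Counts sum to C(|panel|, 2).
    """
    panel = np.asarray(panel, dtype=int)
    if panel.size < 2:
        raise InputError("panel must contain at least 2 markers")
    r2, undef = _pairwise_r2(G.genotypes[:, panel])
    iu = np.triu_indices(panel.size, 1)
    vals, undef_pairs = r2[iu], undef[iu]
    defined = vals[~undef_pairs]
    edges = np.concatenate([[-np.inf], np.asarray(bin_edges, float), [np.inf]])
    counts, _ = np.histogram(defined, bins=edges)
    labels = [f"r2 <= {bin_edges[0]}"]
    labels += [
        f"{bin_edges[i]} < r2 <= {bin_edges[i + 1]}"
        for i in range(len(bin_edges) - 1)
    ]
    labels += [f"r2 > {bin_edges[-1]}"]
    df = pd.DataFrame({"bin": labels, "n_pairs": counts})
    df.attrs["n_undefined"] = int(undef_pairs.sum())
    df.attrs["n_total_pairs"] = int(vals.size)
    return df


def _median_heuristic_gamma(F: np.ndarray, rng) -> float:
    sub = F if F.shape[0] <= 500 else F[rng.choice(F.shape[0], 500, replace=False)]
    d2 = pdist(sub, metric="sqeuclidean")
    med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
    return 1.0 / med


def membership_prediction(G: GenotypeMatrix, panel, labels, split_seed: int = 0,
                          n_repeats: int = 10, C: float = 1.0,
                          normalized: bool = False) -> PredictionReport:
    """RBF-kernel SVM prediction of population membership from a panel.

    Per repeat: a stratified equal split into training and testing halves,
    an RBF support-vector classifier (C = 1, kernel width from the median
    heuristic on the training half) fit on the panel's genotype columns,
    accuracy measured on the held-out half. Reports the mean overall
    accuracy and per-class error across repeats.
    """
    from sklearn.model_selection import StratifiedShuffleSplit
    from sklearn.svm import SVC

    panel = np.asarray(panel, dtype=int)
    if panel.size == 0:
        raise InputError("panel is empty")
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise InputError("need at least 2 classes")
    if counts.min() < 2:
        raise InputError("every class needs at least 2 samples for a split")
    F = G.genotypes[:, panel].astype(float)
    if np.isnan(F).any():
        col_means = np.nanmean(F, axis=0)
        rr, cc = np.nonzero(np.isnan(F))
        F[rr, cc] = col_means[cc]
    if normalized:
        F = (F - F.mean(axis=0)) / np.where(F.std(axis=0) == 0, 1, F.std(axis=0))
    rng = np.random.default_rng(split_seed)
    splitter = StratifiedShuffleSplit(n_splits=n_repeats, test_size=0.5,
                                      random_state=split_seed % (2**31))
    accs = []
    err_sum = {c: 0.0 for c in classes}
    for train, test in splitter.split(F, labels):
        gamma = _median_heuristic_gamma(F[train], rng)
        clf = SVC(C=C, kernel="rbf", gamma=gamma)
        clf.fit(F[train], labels[train])
        pred = clf.predict(F[test])
        accs.append(float(np.mean(pred == labels[test])))
        for c in classes:
            in_c = labels[test] == c
            err_sum[c] += float(np.mean(pred[in_c] != c)) if in_c.any() else 0.0
    per_class_error = {str(c): err_sum[c] / n_repeats for c in classes}
    return PredictionReport(
        overall_accuracy=float(np.mean(accs)),
        per_class_error=per_class_error,
        accuracies=accs,
        classifier_config={"kernel": "rbf", "C": C, "gamma": "median-heuristic",
                           "n_repeats": n_repeats, "split_seed": split_seed,
                           "normalized": normalized},
    )


def informativeness_for_assignment(G: GenotypeMatrix, labels) -> np.ndarray:
    """Rosenberg-style informativeness for assignment, In, per marker.

    In = -sum_a pbar_a ln pbar_a + (1/P) sum_pops sum_a p_pop,a ln p_pop,a
    with natural logs, allele frequencies from non-missing calls, the
    population average unweighted, and 0 ln 0 = 0. In >= 0, equal to 0 when
    every population shares the same frequencies, and ln 2 when two
    populations are fixed for opposite alleles.
    """
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if pops.size < 2:
        raise InputError("need at least 2 populations")
    g = G.genotypes
    P = pops.size
    freqs = np.empty((P, G.n_markers))
    for i, p in enumerate(pops):
        sub = g[labels == p]
        if sub.shape[0] == 0:
            raise InputError(f"population {p!r} has no samples")
        with np.errstate(invalid="ignore"):
            freqs[i] = np.nanmean(sub, axis=0)
    freqs = np.nan_to_num(freqs, nan=0.0)

    def plogp(x):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(x > 0, x * np.log(x), 0.0)

    pbar = freqs.mean(axis=0)
    In = np.zeros(G.n_markers)
    for q, qbar in ((freqs, pbar), (1.0 - freqs, 1.0 - pbar)):
        In += -plogp(qbar) + plogp(q).mean(axis=0)
    return np.maximum(In, 0.0)


def circular_correlation(a, b, ranked: bool = True) -> float:
    """Circular-circular correlation (Fisher-Lee) between two angle vectors.

    With ``ranked=True`` the angles are first replaced by their circular
    ranks 2*pi*rank/n, giving a rank statistic invariant to monotone
    deformation along each circle. The value lies in [-1, 1]; its sign flips
    under reflection of either circle, so comparisons against a threshold
    should use the absolute value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("angle vectors must be 1-D and equally long")
    if ranked:
        n = a.size
        a = 2.0 * np.pi * rankdata(a) / n
        b = 2.0 * np.pi * rankdata(b) / n
    da = a[:, None] - a[None, :]
    db = b[:, None] - b[None, :]
    num = np.sum(np.sin(da) * np.sin(db))
    den = np.sqrt(np.sum(np.sin(da) ** 2) * np.sum(np.sin(db) ** 2))
    if den == 0:
        raise InputError("degenerate (constant) angles")
    return float(num / den)


def hudson_fst(G: GenotypeMatrix, labels, pop_a, pop_b) -> float:
    """Hudson's FST estimator between two populations (ratio of averages
    across loci)."""
    labels = np.asarray(labels)
    out = []
    for p in (pop_a, pop_b):
        sub = G.genotypes[labels == p]
        if sub.shape[0] < 2:
            raise InputError(f"population {p!r} needs >= 2 samples")
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(sub, axis=0)
        n_allele = 2 * (~np.isnan(sub)).sum(axis=0)
        out.append((freq, n_allele))
    (p1, n1), (p2, n2) = out
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
    return float(num[ok].sum() / den[ok].sum())
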