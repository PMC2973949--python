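"""Seeded coalescent and Balding-Nichols genotype simulators.

`simulate_ring` builds the validation scenario for outlier-robust structure
methods: a ring species of equally spaced demes exchanging migrants only
with their two ring neighbors, plus fully isolated outlier demes that split
from the common ancestral population long ago. Each locus is an independent
structured-coalescent genealogy (simulated with msprime) carrying exactly
one segregating site, so loci are unlinked and biallelic by construction.

`simulate_discrete_pops` draws island-model genotypes from the
Balding-Nichols model with a tunable FST — the standard quick fixture for
discrete population structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .genotypes import GenotypeMatrix, default_marker_table

_MAX_SPLIT_CHUNK = 50  # msprime caps populations per split event at 100


@dataclass
class SimulatedSample:
    """Genotypes plus the truth used to generate them."""

    genotypes: GenotypeMatrix
    deme_labels: np.ndarray       # deme index per sample
    deme_angles: np.ndarray       # ring position in radians; NaN for outliers
    is_outlier: np.ndarray        # bool per sample
    params: dict

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.genotypes.sample_ids,
                "deme": self.deme_labels,
                "is_outlier": self.is_outlier.astype(int),
                "angle": self.deme_angles,
            }
        )


def _ring_demography(n_demes, n_outlier_demes, deme_size, migration_frac,
                     split_time_factor):
    import msprime

    dem = msprime.Demography()
    total = n_demes + n_outlier_demes
    for i in range(total):
        dem.add_population(name=f"deme{i}", initial_size=deme_size)
    dem.add_population(name="anc", initial_size=deme_size * total)
    for i in range(n_demes):
        j = (i + 1) % n_demes
        if i == j:
            continue
        # backward-time migrant fraction = forward migrant fraction at equilibrium
        dem.set_migration_rate(f"deme{i}", f"deme{j}", migration_frac)
        dem.set_migration_rate(f"deme{j}", f"deme{i}", migration_frac)
    T = split_time_factor * deme_size
    names = [f"deme{i}" for i in range(total)]
    for c in range(0, total, _MAX_SPLIT_CHUNK):
        dem.add_population_split(time=T, derived=names[c:c + _MAX_SPLIT_CHUNK],
                                 ancestral="anc")
    dem.sort_events()
    return dem


def _single_site_genotypes(ts, rng, n_retry=20) -> np.ndarray | None:
    """Place one mutation uniformly on the genealogy (branch chosen with
    probability proportional to its length) and return haplotype 0/1 calls.
    Returns None if no segregating placement exists (never for a binary
    coalescent tree with >= 2 leaves)."""
    tree = ts.first()
    time = ts.tables.nodes.time
    parent = tree.parent_array
    nodes = np.flatnonzero(parent[: ts.num_nodes] >= 0)
    lens = time[parent[nodes]] - time[nodes]
    total = lens.sum()
    if total <= 0:
        return None
    n_samples = ts.num_samples
    for _ in range(n_retry):
        u = int(nodes[rng.choice(nodes.size, p=lens / total)])
        carriers = np.fromiter(tree.samples(u), dtype=np.int64)
        if 0 < carriers.size < n_samples:
            hap = np.zeros(n_samples, dtype=np.int8)
            hap[carriers] = 1
            return hap
    return None


def simulate_ring(
    n_demes: int = 100,
    samples_per_deme: int = 10,
    n_loci: int = 10_000,
    migration_frac: float = 0.1,
    n_outlier_demes: int = 2,
    seed: int = 1,
    deme_size: int = 10,
    split_time_factor: float = 10.0,
) -> SimulatedSample:
    """Circular stepping-stone ring plus isolated outlier demes.

    Parameters
    ----------
    n_demes, samples_per_deme, n_loci
        Ring deme count, diploids sampled per deme (ring and outlier demes
        alike), and number of independent biallelic loci.
    migration_frac
        Fraction of each ring deme made up of migrants from *each* adjacent
        deme per generation; non-adjacent demes exchange no gametes and the
        outlier demes neither send nor receive migrants.
    n_outlier_demes
        Demes that split from the ancestral population at
        ``split_time_factor * deme_size`` generations and evolve in
        isolation; all demes merge into the ancestral population at that
        same time, which bounds the depth of the structured phase.
    deme_size
        Diploid size of every deme (the per-deme drift scale).

    Each locus is an independent single-tree coalescent under this
    demography with exactly one segregating site, placed uniformly at random
    on the genealogy. Diploids pair the two msprime-sampled haplotypes of
    each simulated individual.
    """
    import msprime

    if not (0 < migration_frac <= 0.5):
        raise InputError(f"migration_frac must be in (0, 0.5], got {migration_frac}")
    if n_outlier_demes < 0 or n_demes < 3:
        raise InputError("need n_demes >= 3 and n_outlier_demes >= 0")
    total = n_demes + n_outlier_demes
    n = total * samples_per_deme
    dem = _ring_demography(n_demes, n_outlier_demes, deme_size, migration_frac,
                           split_time_factor)
    samples = {f"deme{i}": samples_per_deme for i in range(total)}
    rng = np.random.default_rng(seed)
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, num_replicates=n_loci,
        random_seed=int(seed) % (2**31 - 2) + 1, ploidy=2,
    )
    haps = np.empty((n_loci, 2 * n), dtype=np.int8)
    k = 0
    for ts in reps:
        hap = _single_site_genotypes(ts, rng)
        if hap is None:
            continue
        haps[k] = hap
        k += 1
    if k < n_loci:
        raise InputError(
            f"only {k}/{n_loci} loci produced a segregating site"
        )
    geno = (haps[:, 0::2] + haps[:, 1::2]).T / 2.0  # (n, m) in {0,.5,1}
    sample_ids = [
        f"d{d:03d}_i{i:02d}" for d in range(total) for i in range(samples_per_deme)
    ]
    markers = default_marker_table([f"L{j:05d}" for j in range(n_loci)])
    deme_labels = np.repeat(np.arange(total), samples_per_deme)
    angles = np.where(
        deme_labels < n_demes,
        2.0 * np.pi * deme_labels / n_demes,
        np.nan,
    )
    params = {
        "n_demes": n_demes, "samples_per_deme": samples_per_deme,
        "n_loci": n_loci, "migration_frac": migration_frac,
        "n_outlier_demes": n_outlier_demes, "seed": int(seed),
        "deme_size": deme_size, "split_time_factor": split_time_factor,
    }
    return SimulatedSample(
        genotypes=GenotypeMatrix(geno, sample_ids, markers),
        deme_labels=deme_labels,
        deme_angles=angles,
        is_outlier=deme_labels >= n_demes,
        params=params,
    )


def ring_migration_matrix(n_demes: int, migration_frac: float,
                          n_outlier_demes: int = 0) -> np.ndarray:
    """Explicit deme-by-deme migration-rate matrix of the ring topology
    (audit helper: row sums over ring demes equal 2 * migration_frac)."""
    total = n_demes + n_outlier_demes
    M = np.zeros((total, total))
    for i in range(n_demes):
        j = (i + 1) % n_demes
        if i != j:
            M[i, j] = M[j, i] = migration_frac
    return M


def simulate_discrete_pops(
    n_pops: int,
    fst: float,
    samples_per_pop: int,
    n_loci: int,
    seed: int = 1,
    p_ancestral_range: tuple[float, float] = (0.1, 0.9),
) -> SimulatedSample:
    """Balding-Nichols island-model genotypes with target FST.

    Per locus the ancestral frequency p is Uniform(0.1, 0.9); each
    population draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), whose
    mean is p and variance F p (1-p); genotypes are Binomial(2, p_pop)/2.
    Loci monomorphic in the pooled sample are re-drawn so every locus
    segregates.
    """
    if not (0 < fst < 0.5):
        raise InputError(f"fst must be in (0, 0.5), got {fst}")
    if min(n_pops, samples_per_pop, n_loci) < 1:
        raise InputError("all counts must be positive")
    rng = np.random.default_rng(seed)
    n = n_pops * samples_per_pop
    geno = np.empty((n, n_loci))
    a_scale = (1.0 - fst) / fst
    lo, hi = p_ancestral_range
    filled = 0
    for _ in range(200):  # batches of redraws until every locus segregates
        todo = n_loci - filled
        if todo == 0:
            break
        p = rng.uniform(lo, hi, size=todo)
        p_pop = rng.beta(p * a_scale, (1.0 - p) * a_scale, size=(n_pops, todo))
        g = rng.binomial(2, np.repeat(p_pop, samples_per_pop, axis=0)) / 2.0
        seg = np.ptp(g, axis=0) > 0
        k = int(seg.sum())
        geno[:, filled:filled + k] = g[:, seg]
        filled += k
    if filled < n_loci:
        raise InputError("could not produce enough segregating loci")
    sample_ids = [
        f"p{p}_i{i:03d}" for p in range(n_pops) for i in range(samples_per_pop)
    ]
    markers = default_marker_table([f"L{j:05d}" for j in range(n_loci)])
    labels = np.repeat(np.arange(n_pops), samples_per_pop)
    params = {
        "n_pops": n_pops, "fst": fst, "samples_per_pop": samples_per_pop,
        "n_loci": n_loci, "seed": int(seed),
    }
    return SimulatedSample(
        genotypes=GenotypeMatrix(geno, sample_ids, markers),
        deme_labels=labels,
        deme_angles=np.full(n, np.nan),
        is_outlier=np.zeros(n, dtype=bool),
        params=params,
    )
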