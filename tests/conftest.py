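import numpy as np
import pytest

from sparselap import GenotypeMatrix, simulate_discrete_pops, simulate_ring
from sparselap.genotypes import default_marker_table


def make_genotypes(array, sample_ids=None, chrom="1") -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw array with synthetic metadata."""
    g = np.asarray(array, dtype=float)
    n, m = g.shape
    ids = sample_ids or [f"s{i}" for i in range(n)]
    return GenotypeMatrix(g, ids, default_marker_table(
        [f"m{j}" for j in range(m)], chrom=chrom))


@pytest.fixture(scope="session")
def two_pop_sim():
    """Two Balding-Nichols populations, FST 0.2 (clear but realistic split)."""
    return simulate_discrete_pops(n_pops=2, fst=0.2, samples_per_pop=50,
                                  n_loci=400, seed=11)


@pytest.fixture(scope="session")
def small_ring():
    """Scaled-down ring species: 20 ring demes + 2 outliers, 5 diploids each,
    1,200 independent loci."""
    return simulate_ring(n_demes=20, samples_per_deme=5, n_loci=1200,
                         migration_frac=0.1, n_outlier_demes=2, seed=7)


@pytest.fixture(scope="session")
def ld_block_sim():
    """Two-population genotypes with blocks of near-duplicated markers.

    60 LD blocks of 8 markers each (block members are copies of a base
    marker with 2% of calls flipped) plus 1,520 independent markers, so LD
    structure is known by construction.
    """
    rng = np.random.default_rng(42)
    base = simulate_discrete_pops(n_pops=2, fst=0.25, samples_per_pop=100,
                                  n_loci=2000, seed=42)
    g = base.genotypes.genotypes.copy()
    n = g.shape[0]
    block_size, n_blocks = 8, 60
    block_of = np.full(g.shape[1], -1)
    j = 0
    for b in range(n_blocks):
        src = g[:, j].copy()
        for k in range(block_size):
            col = src.copy()
            flip = rng.random(n) < 0.02
            col[flip] = rng.choice([0.0, 0.5, 1.0], size=flip.sum())
            g[:, j + k] = col
            block_of[j + k] = b
        j += block_size
    G = GenotypeMatrix(g, base.genotypes.sample_ids,
                       base.genotypes.markers.copy())
    return G, base.deme_labels, block_of


@pytest.fixture()
def tiny_vcf(tmp_path):
    """3 biallelic SNPs + 1 multiallelic site, 2 samples, one missing call."""
    text = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB
1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t1/1
1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t./.
1\t300\trs3\tG\tA\t.\t.\t.\tGT\t1/1\t0/0
1\t400\trs4\tG\tA,C\t.\t.\t.\tGT\t1/2\t0/0
"""
    path = tmp_path / "tiny.vcf"
    path.write_text(text)
    return path
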