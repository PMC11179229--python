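import numpy as np
import pandas as pd
import pytest

from mtgwas.genotypes import GenotypeMatrix
from mtgwas.simulate import SimConfig, simulate_genotypes


def make_genotypes(calls, chrom=None, pos=None, line_ids=None) -> GenotypeMatrix:
    """Tiny GenotypeMatrix builder for hand-constructed examples."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    if chrom is None:
        chrom = ["1"] * m
    if pos is None:
        pos = list(range(1, m + 1))
    if line_ids is None:
        line_ids = [f"L{i}" for i in range(n)]
    smap = pd.DataFrame(
        {"snp": [f"S{c}_{p}" for c, p in zip(chrom, pos)], "chrom": chrom, "pos": pos}
    )
    return GenotypeMatrix(calls, line_ids, smap)


@pytest.fixture(scope="session")
def small_panel() -> GenotypeMatrix:
    """120 inbred lines, 3 chromosomes, realistic LD; no missing calls."""
    cfg = SimConfig(
        n_lines=120, n_chrom=3, snps_per_chrom=150, chrom_length_bp=20_000_000,
        ld_segment_bp=150_000, seed=11,
    )
    return simulate_genotypes(cfg)
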