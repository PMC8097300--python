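import numpy as np
import pytest

from tpbwt import HaplotypeAlignment


def make_alignment(
    alleles: np.ndarray,
    length_cm: float | None = None,
    bp_step: int = 1000,
    chromosome: str = "1",
) -> HaplotypeAlignment:
    """Wrap an allele matrix with a uniform map (default 0.02 cM per site)."""
    alleles = np.asarray(alleles, dtype=np.int8)
    m, n = alleles.shape
    bp = np.arange(1, n + 1, dtype=np.int64) * bp_step
    if length_cm is None:
        length_cm = 0.02 * (n - 1)
    cm = np.linspace(0.0, length_cm, n)
    ids = [f"s{i}" for i in range(m // 2)]
    return HaplotypeAlignment(alleles, bp, cm, ids, chromosome)


def random_alignment(
    rng: np.random.Generator,
    n_haplotypes: int,
    n_sites: int,
    length_cm: float | None = None,
    missing_rate: float = 0.0,
) -> HaplotypeAlignment:
    alleles = rng.integers(0, 2, size=(n_haplotypes, n_sites)).astype(np.int8)
    if missing_rate > 0:
        alleles[rng.random(alleles.shape) < missing_rate] = -1
    return make_alignment(alleles, length_cm=length_cm)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
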