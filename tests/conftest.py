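import numpy as np
import pytest


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trio():
    """An 80-kb trio with SNVs and indels, shared across read-only tests."""
    from dipeval import synthio

    cfg = synthio.TrioConfig(
        seed=7, chrom_lengths=(80_000,), snv_rate=1e-3, indel_rate=2e-4
    )
    return synthio.gen_trio(cfg)


@pytest.fixture(scope="session")
def trio_hapmers(small_trio):
    """Hapmers of the small trio from error-free parental/child genome k-mers."""
    from dipeval import kmerset

    t = small_trio
    mk = kmerset.count_kmers(
        list(t.mother_hap1.values()) + list(t.mother_hap2.values()), 21
    )
    pk = kmerset.count_kmers(
        list(t.father_hap1.values()) + list(t.father_hap2.values()), 21
    )
    ck = kmerset.count_kmers(
        list(t.child_mat.values()) + list(t.child_pat.values()), 21
    )
    return kmerset.hapmer_sets(mk, pk, ck, reliable_min=1)
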