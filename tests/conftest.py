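import numpy as np
import pytest

from mdmcensus import build_index, generate_catalog, generate_community
from mdmcensus.catalog import ReferenceIndex, reverse_complement


@pytest.fixture(scope="session")
def small_catalog():
    return generate_catalog(30, seed=7)


@pytest.fixture(scope="session")
def small_index(small_catalog):
    return build_index(small_catalog.records, small_catalog.ssu)


@pytest.fixture(scope="session")
def small_world(small_catalog):
    """50 samples, moderate community, all planted tags exact matches."""
    return generate_community(
        small_catalog, n_samples=50, n_taxa=200,
        f_sequenced_abundance=0.5, seed=11,
    )


@pytest.fixture
def planted_index():
    """Tiny hand-checkable index with known categories."""
    from mdmcensus.catalog import Category

    rng = np.random.default_rng(123)
    bases = np.array(list("ACGT"))
    seqs = {f"G{i}": ["".join(rng.choice(bases, size=300))] for i in range(5)}
    cats = {
        "G0": Category.ISOLATION,
        "G1": Category.COMPLETE,
        "G2": Category.HQ,
        "G3": Category.MQ,
        "G4": Category.LQ,
    }
    return ReferenceIndex(seqs, cats)


def naive_hamming_scan(query: str, index: ReferenceIndex) -> dict[str, int]:
    """Independent O(n * L * m) both-strand sliding-window oracle.

    Compares every full-length window of every reference against the query
    (and its reverse complement) position by position; N on either side is a
    mismatch. No seeding/filtering — deliberately brute force.
    """
    n_code = ord("N")
    best: dict[str, int] = {}
    for q in (query.upper(), reverse_complement(query.upper())):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for acc, seqs in index.entries.items():
            for ref in seqs:
                if len(ref) < len(q):
                    continue
                ra = np.frombuffer(ref.encode(), dtype=np.uint8)
                windows = np.lib.stride_tricks.sliding_window_view(ra, len(q))
                mism = (windows != qa) | (windows == n_code) | (qa == n_code)
                d = int(mism.sum(axis=1).min())
                if d < best.get(acc, 1 << 30):
                    best[acc] = d
    return best
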