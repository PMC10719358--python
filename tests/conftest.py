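import numpy as np
import pytest

from svpopscan import Cohort, GenotypeMatrix, SVRecord, SVType


def make_sv(
    id="sv1",
    chrom="chr1",
    start=1000,
    end=2000,
    svtype=SVType.DEL,
    length=None,
    **kwargs,
):
    if svtype is SVType.INS:
        end = start
        length = length or 300
    else:
        length = end - start
    return SVRecord(id=id, chrom=chrom, start=start, end=end, svtype=svtype, length=length, **kwargs)


@pytest.fixture
def two_pop_cohort():
    items = [(f"A{i}", "POP_A") for i in range(10)] + [(f"B{i}", "POP_B") for i in range(10)]
    return Cohort.from_items(items)


@pytest.fixture
def two_block_matrix(two_pop_cohort):
    """Two sample blocks with disjoint SV sets."""
    rng = np.random.default_rng(0)
    n, m = 20, 40
    d = np.zeros((n, m), dtype=np.int8)
    d[:10, :20] = rng.integers(1, 3, size=(10, 20))
    d[10:, 20:] = rng.integers(1, 3, size=(10, 20))
    ids = [f"v{j}" for j in range(m)]
    return GenotypeMatrix(d, list(two_pop_cohort.samples), ids)


def random_sv_set(rng, n, chrom_size=10_000_000, chroms=("chr1", "chr2"), jitter_from=None):
    """Random SVs; with jitter_from, noisy copies of an existing list."""
    out = []
    if jitter_from is not None:
        for i, base in enumerate(jitter_from):
            ds = int(rng.integers(-50, 51))
            start = max(0, base.start + ds)
            if base.svtype is SVType.INS:
                out.append(base.with_(id=f"j{i}", start=start, end=start))
            else:
                out.append(
                    base.with_(id=f"j{i}", start=start, end=start + base.length)
                )
        return out
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        svtype = [SVType.DEL, SVType.INS, SVType.DUP, SVType.INV][int(rng.integers(4))]
        length = int(rng.integers(50, 5000))
        start = int(rng.integers(0, chrom_size - length))
        end = start if svtype is SVType.INS else start + length
        out.append(
            SVRecord(
                id=f"r{i}", chrom=chrom, start=start, end=end, svtype=svtype, length=length
            )
        )
    return out
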