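import numpy as np
import pytest

import uvspectra as uv


@pytest.fixture(scope="session")
def toy_genome():
    """A 10 kb random single-chromosome genome."""
    rng = np.random.default_rng(1234)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
    return uv.make_genome({"chrA": seq})


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic reference plus a merged record list."""
    cfg = uv.SyntheticConfig(
        seed=101, n_chroms=2, chrom_length=50_000, n_genes=20, gene_length=1200,
        n_origins=5, n_isolates=4, mutations_per_isolate=200,
    )
    reference, table = uv.simulate_dataset(cfg)
    records = frame_to_records(table)
    return cfg, reference, uv.merge_tandems(records)


def frame_to_records(table):
    return [
        uv.MutationRecord(r.chrom, int(r.pos), r.ref, r.alt, r.isolate)
        for r in table.itertuples()
    ]
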