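import numpy as np
import pytest

from recfine.io_formats import VariantRecord, VariantTable
from recfine.synthetic_data import (
    SimulationParams,
    make_gene_fixture,
    make_rflp_fixture,
    make_table1_fixture,
    simulate_cohort,
)

BASES = "ACGT"


@pytest.fixture(scope="session")
def table1():
    return make_table1_fixture()


@pytest.fixture(scope="session")
def gene_fixture():
    return make_gene_fixture()


@pytest.fixture(scope="session")
def rflp_fixture():
    return make_rflp_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort: 1.5 Mb segment, 12 controls, 500 kb planted tract."""
    params = SimulationParams(
        segment_length=1_500_000,
        n_controls=12,
        roh_interval=(500_000, 1_000_000),
        seed=42,
    )
    return params, simulate_cohort(params)


def random_variant_table(rng: np.random.Generator, n_records=50, n_samples=2,
                         chroms=("1", "2")) -> VariantTable:
    """A random multi-sample table with some multi-allelic sites and missing
    genotypes, for round-trip tests."""
    records = []
    used = set()
    while len(records) < n_records:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, 100_000))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = BASES[int(rng.integers(4))]
        n_alts = 1 + int(rng.random() < 0.2)
        alts = tuple(rng.permutation([b for b in BASES if b != ref])[:n_alts])
        gts = []
        for _ in range(n_samples):
            if rng.random() < 0.1:
                gts.append((None, None))
            else:
                gts.append(
                    (int(rng.integers(n_alts + 1)), int(rng.integers(n_alts + 1)))
                )
        called = sum(1 for g in gts if g[0] is not None)
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alts=alts, genotypes=tuple(gts),
                mean_depth=round(float(rng.uniform(1, 40)), 2),
                call_rate=called / n_samples,
                id=f"var{len(records)}" if rng.random() < 0.5 else None,
            )
        )
    return VariantTable([f"s{i}" for i in range(n_samples)], records)
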