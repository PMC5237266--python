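import numpy as np
import pytest

import trekkit as tk


@pytest.fixture(scope="session")
def small_reference() -> tk.ReferenceSeq:
    return tk.make_reference(400, 0.42, seed=101)


@pytest.fixture(scope="session")
def truth7() -> tk.TruthModel:
    """Heptamer-context truth with rates in the 0.2-4 byr^-1 band."""
    return tk.TruthModel.random(102, n_per_age=800, full_length_fraction=1.0)


@pytest.fixture(scope="session")
def truth3_db() -> tk.TrekDatabase:
    """Complete 3-mer-context fixture database for the evolver."""
    return tk.TruthModel.random(103, k=3).to_database()


@pytest.fixture(scope="session")
def small_pools(small_reference, truth7):
    pools, logs = tk.evolve_remnant_pool(small_reference, truth7, seed=104)
    return pools, logs


@pytest.fixture(scope="session")
def small_db(small_reference, small_pools) -> tk.TrekDatabase:
    pools, _ = small_pools
    prs = tk.infer_rates(pools, small_reference, trusted_offsets=True)
    return tk.build_database(prs, small_reference)


def random_rate_db(rng: np.random.Generator, n: int = 100) -> tk.TrekDatabase:
    """A random valid database (used by round-trip tests)."""
    db = tk.TrekDatabase()
    bases = "ACGT"
    while len(db) < n:
        level = int(rng.choice([1, 3, 5, 7]))
        kmer = "".join(rng.choice(list(bases), size=level))
        central = kmer[level // 2]
        target = rng.choice([b for b in bases if b != central])
        db.add(tk.RateConstant(
            kmer=kmer, target_base=str(target), rate=float(rng.uniform(0, 5)),
            context_level=level,
            t_value=None if rng.random() < 0.3 else float(rng.normal(6, 2)),
            n_occurrences=int(rng.integers(1, 40)),
        ))
    return db
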