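import numpy as np
import pytest

from mbgp.simdata import GenotypeMatrix


def make_genotypes(n_a, n_b, m, seed=0, labels=("A", "B")):
    """Unstructured random genotype fixture (uniform codes, two breeds)."""
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, size=(n_a + n_b, m)).astype(np.int8)
    # keep every marker polymorphic within each breed: a heterozygote in the
    # first row of a breed guarantees a frequency strictly inside (0, 1)
    for rows in (slice(0, n_a), slice(n_a, n_a + n_b)):
        block = codes[rows]
        total = block.sum(axis=0)
        mono = (total == 0) | (total == 2 * block.shape[0])
        codes[rows.start if rows.start else 0, mono] = 1
    la, lb = labels
    ids = [f"{la}{i}" for i in range(n_a)] + [f"{lb}{i}" for i in range(n_b)]
    breed_of = {i: la for i in ids[:n_a]} | {i: lb for i in ids[n_a:]}
    markers = [f"m{j}" for j in range(m)]
    return GenotypeMatrix(codes, ids, breed_of, markers)


@pytest.fixture
def toy_geno():
    return make_genotypes(4, 2, 20, seed=11)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated replicate shared by prediction-level tests."""
    from mbgp import simdata

    g = simdata.simulate_two_breed_genotypes(300, 150, 900, fst=0.1, seed=42)
    kept = simdata.qc_min_minor_copies(g, 5)
    g = g.subset_markers(kept[:800])
    rng = np.random.default_rng(43)
    causal = np.sort(rng.choice(g.n_markers, 100, replace=False))
    top = np.sort(rng.choice(causal, 50, replace=False))
    effects = simdata.sample_causal_effects(100, 1.0, seed=44)
    tbv = simdata.true_breeding_values(g, causal, effects)
    y, s2a = simdata.simulate_phenotypes(g, tbv, 0.8, seed=45)
    truth = simdata.SimulationTruth(
        causal_indices=causal, top_indices=top, effects=effects,
        tbv=tbv, h2=0.8, rg_sim=1.0, sigma2_a=s2a)
    pheno = simdata.write_phenotypes(None, g, y, tbv=tbv)
    return g, truth, pheno
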