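import numpy as np
import pytest

from ploidyscope.model import FormRates, caterpillar_topology
from ploidyscope.simulate import SimulationDesign, run_design
from ploidyscope.smudge import find_one_away_pairs, select_genomic


@pytest.fixture(scope="session")
def triploid_sim():
    """Triploid dataset at the smudge study conditions: 1 Mbp monoploid,
    25x per homolog, 1% error, 10% repetitiveness, 2% divergence."""
    top = caterpillar_topology(3)
    rates = FormRates.for_topology(top, [0.02, 0.0])
    design = SimulationDesign(
        progenitor_size=1_000_000, p=3, topology=top, form_rates=rates,
        d=0.10, coverage_per_homolog=25.0, seed=7,
    )
    return run_design(design)


@pytest.fixture(scope="session")
def triploid_pairs(triploid_sim):
    return find_one_away_pairs(select_genomic(triploid_sim.counts))


@pytest.fixture(scope="session")
def triploid_kmer_lambda(triploid_sim):
    """Realized monoploid k-mer coverage: genomic k-mer mass per homolog base."""
    genomic = select_genomic(triploid_sim.counts)
    mass = float(genomic.counts.sum())
    return mass / (3 * triploid_sim.truth.monoploid_length)


def synthetic_pairs(structures, lam, rng):
    """Synthetic pair cloud drawn at given (a, b, count) smudge centers with
    Poisson coverage noise; a stand-in for pair sets whose genome-level
    generation is outside the simulator's model (e.g. repeat-borne AABB)."""
    from ploidyscope.smudge import PairSet

    cov_a, cov_b = [], []
    for a, b, count in structures:
        cov_a.append(rng.poisson(a * lam, count))
        cov_b.append(rng.poisson(b * lam, count))
    cov_a = np.concatenate(cov_a)
    cov_b = np.concatenate(cov_b)
    swap = cov_b > cov_a
    major = np.where(swap, cov_b, cov_a).astype(np.int64)
    minor = np.where(swap, cov_a, cov_b).astype(np.int64)
    keep = minor >= 1
    n = int(keep.sum())
    return PairSet(
        k=21,
        code_a=np.zeros(n, dtype=np.uint64),
        code_b=np.zeros(n, dtype=np.uint64),
        cov_a=major[keep],
        cov_b=minor[keep],
    )
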