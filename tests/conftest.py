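import numpy as np
import pytest

from cobashare.io_formats import ProfileHMMHit, SampleMetadata, TaxonAssignment
from cobashare.synthetic_data import make_community, simulate_hit_table


def random_hits(rng, n_reads, genes, hmm_lengths, multi_prob=0.5):
    """Random hit lists where some reads align to several HMMs."""
    hits = []
    for r in range(n_reads):
        n = 1 + int(rng.random() < multi_prob) + int(rng.random() < 0.2)
        chosen = rng.choice(genes, size=min(n, len(genes)), replace=False)
        for g in chosen:
            L = hmm_lengths[g]
            a = int(rng.integers(1, L))
            b = int(rng.integers(a, L + 1))
            hits.append(ProfileHMMHit(
                read_id=f"r{r:05d}",
                frame=int(rng.choice([1, 2, 3, -1, -2, -3])),
                hmm_name=str(g),
                hmm_accession="ACC",
                evalue=float(10.0 ** -rng.uniform(2, 20)),
                bitscore=float(rng.uniform(10, 300)),
                hmm_from=a,
                hmm_to=b,
                hmm_length=L,
            ))
    return hits


@pytest.fixture(scope="session")
def small_truth():
    return make_community(n_species=12, n_producers=3, n_salvagers=3,
                          frac_dependent=0.5, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    """A compact 2-study, 8-sample simulated dataset with no noise."""
    return simulate_hit_table(
        small_truth, n_samples=8, n_studies=2, reads_per_sample=800,
        fp_rate=0.0, seed=12, n_trace_genes=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
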