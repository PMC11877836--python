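import numpy as np
import pandas as pd
import pytest

from slmkit import io, simulate


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale study: one 150-kb chromosome, planted loci of all classes."""
    return simulate.SimConfig(seed=11, n_chrom=1, chrom_length=150_000,
                              n_genes=12, n_tes=20,
                              n_planted_slm=6, n_planted_slh=3, n_planted_dmr=12)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate.simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_methylomes(small_cfg, small_sim):
    genome, features, truth = small_sim
    return simulate.simulate_methylome(genome, features, truth, small_cfg)


@pytest.fixture(scope="session")
def small_groups(small_methylomes):
    return {ct: io.coverage_filter(io.merge_replicates(reps))
            for ct, reps in small_methylomes.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_methylome(records):
    """Build a canonical methylome table from (chrom,pos,strand,context,meth,total)."""
    return pd.DataFrame(records, columns=io.METHYLOME_COLUMNS)


@pytest.fixture(scope="session")
def random_methylome():
    """A dense random methylome on one 10-kb chromosome (for oracle checks)."""
    gen = np.random.default_rng(123)
    n = 3000
    pos = np.sort(gen.choice(np.arange(1, 10_001), size=n, replace=False))
    total = gen.poisson(12, size=n)
    meth = gen.binomial(total, 0.3)
    return pd.DataFrame({
        "chrom": "chr1",
        "pos": pos,
        "strand": gen.choice(["+", "-"], size=n),
        "context": gen.choice(["CG", "CHG", "CHH"], size=n),
        "meth": meth,
        "total": total,
    })
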