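import numpy as np
import pytest
from hypothesis import settings

from magcatkit import synthdata

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from magcatkit.quality import GenomeBin


@pytest.fixture(scope="session")
def ancestors_50k():
    return synthdata.generate_ancestors(2, 50_000, seed=101)


@pytest.fixture(scope="session")
def conspecific_pair_200k():
    """A 200-kb ancestor and a descendant at planted substitution rate 0.03."""
    anc = synthdata.generate_ancestors(1, 200_000, seed=5)[0]
    evolved, positions = synthdata.evolve_genome(anc, 0.03, seed=6)
    return anc, evolved, positions


@pytest.fixture
def simple_bin():
    rng = np.random.default_rng(0)
    contigs = ["".join(rng.choice(list("ACGT"), size=n)) for n in (30_000, 20_000, 10_000)]
    return GenomeBin(
        bin_id="b0",
        contigs=contigs,
        completeness=95.0,
        contamination=1.0,
        has_5S=True,
        has_16S=True,
        has_23S=True,
        trna_count=20,
    )
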