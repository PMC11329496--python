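import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from deamap.simulate import SimConfig, generate_reference

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """A small but fully featured universe shared by unit tests."""
    return SimConfig(seed=7, n_genes=12, exons_per_gene=(2, 3),
                     exon_len=(150, 250), intron_len=(500, 1200),
                     utr_len=(80, 150), n_bound_motifs=4, n_snps=8,
                     alt_isoform_fraction=0.3, lr_violation_fraction=0.02,
                     n_replicates=2)


@pytest.fixture(scope="session")
def tiny_reference(tiny_config):
    return generate_reference(tiny_config)


def brute_force_overlap(query: pd.Series, subjects: pd.DataFrame) -> bool:
    """Reference implementation of >=1 nt same-strand interval overlap."""
    for s in subjects.itertuples():
        if (s.chrom == query["chrom"] and s.strand == query["strand"]
                and s.start0 < query["end0"] and query["start0"] < s.end0):
            return True
    return False


def intervals(rows) -> pd.DataFrame:
    """Build an interval frame from (chrom, start, end, strand) tuples."""
    return pd.DataFrame(
        [dict(chrom=c, start0=s, end0=e, strand=st,
              name=f"iv{i}", score=0.0)
         for i, (c, s, e, st) in enumerate(rows)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
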