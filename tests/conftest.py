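import numpy as np
import pytest

from dnmseek.pipeline import load_reference_dnm_table, reference_table_to_calls
from dnmseek.variant_io import GenotypeObservation, TrioSite, VariantRecord


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_dnm_table()


@pytest.fixture(scope="session")
def reference_calls():
    return reference_table_to_calls()


def make_obs(gt=(0, 1), depth=40, alt=20, gq=99.0, strand=None):
    return GenotypeObservation(genotype=gt, depth=depth, alt_depth=alt,
                               gq=gq, strand_counts=strand)


def make_site(proband=None, father=None, mother=None, trio_id="T1",
              pos=1000, **variant_kwargs):
    variant = VariantRecord(chrom=variant_kwargs.pop("chrom", "1"), pos=pos,
                            ref=variant_kwargs.pop("ref", "A"),
                            alt=variant_kwargs.pop("alt", "G"),
                            **variant_kwargs)
    return TrioSite(
        variant=variant,
        proband=proband or make_obs(),
        father=father or make_obs(gt=(0, 0), alt=0),
        mother=mother or make_obs(gt=(0, 0), alt=0),
        trio_id=trio_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
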