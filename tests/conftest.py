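import numpy as np
import pytest

from mirnovo import synthetic_data as sd


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A compact end-to-end synthetic study shared by slower tests."""
    outdir = tmp_path_factory.mktemp("dataset")
    return sd.generate_dataset(
        str(outdir), rng_seed=1234, n_known=6, n_novel=6, n_trna=2,
        n_rrna=2, n_random=2, n_chrom=2, chrom_len=12_000, n_utrs=6)


@pytest.fixture(scope="session")
def strong_hairpin():
    """An unambiguous perfect-stem precursor (22 bp stem, 8 nt loop)."""
    hp = sd.make_hairpin_locus("AGAGGCUGUCCGAGUGCUGAU", loop_len=8,
                               wobble_rate=0.0, rng_seed=7)
    return hp
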