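import numpy as np
import pandas as pd
import pytest

from emqtlkit.core_io import CpGManifest, GenomicInterval, TFBSCollection
from emqtlkit.synthetic import small_config, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One reduced-scale simulated study shared by read-only tests."""
    return simulate_study(small_config(seed=11))


@pytest.fixture()
def toy_manifest():
    df = pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr1", "chr2"], "pos": [900, 899, 1105, 500]},
        index=pd.Index(["cgA", "cgB", "cgC", "cgD"], name="probe_id"),
    )
    return CpGManifest(df)


@pytest.fixture()
def toy_tfbs():
    return TFBSCollection(
        {
            "FOXA1": [GenomicInterval("chr1", 1100, 1110)],
            "GATA3": [GenomicInterval("chr2", 480, 490)],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
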