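import numpy as np
import pandas as pd
import pytest

from ovokit.synthetic import ScenarioConfig, simulate_scenario


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One default-condition synthetic bundle shared across the suite."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_scenario(ScenarioConfig(seed=11), out_dir=out)


@pytest.fixture(scope="session")
def bundle_dir(bundle):
    return bundle.out_dir


@pytest.fixture()
def tiny_fasta(tmp_path):
    """A two-contig toy genome on disk."""
    path = tmp_path / "tiny.fa"
    path.write_text(">chrX\nAACGTACGTTGCA\n>chrY\nGGGGCCCCAAAA\n")
    return path


def ctss_frame(rows):
    """rows of (chrom, pos, strand, count) -> DataFrame."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
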