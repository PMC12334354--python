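from pathlib import Path

import pytest

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def query_corpus():
    lines = (DATA_DIR / "query_corpus.txt").read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


@pytest.fixture(scope="session")
def small_fixture_dataset(tmp_path_factory):
    """A small generated dataset shared across read-oriented tests."""
    from massql.synthetic import generate_dataset

    outdir = tmp_path_factory.mktemp("fixture_small")
    files, manifest = generate_dataset(
        outdir, n_files=2, k_iron=4, k_phosphate=3, n_decoy_ms1=40,
        n_decoy_ms2=24, seed=11,
    )
    return files, manifest
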