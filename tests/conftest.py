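import pytest
from hypothesis import settings

from xmapqc.bioplex_io import parse_workbook
from xmapqc.synthetic import default_config, generate_run_workbook

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("synth")


@pytest.fixture(scope="session")
def default_run(synth_dir):
    """One standard synthetic run: (config, workbook path, truth, parsed)."""
    cfg = default_config(seed=11)
    path, truth = generate_run_workbook(cfg, synth_dir / "run11.xlsx")
    run = parse_workbook(path)
    return cfg, path, truth, run
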