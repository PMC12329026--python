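import hashlib
from pathlib import Path

import pytest

from iclipsites.pipeline import RunConfig, run_on_fixture
from iclipsites.simulate import end_to_end_fixture, small_config

SEED = 11


@pytest.fixture(scope="session")
def sim_fixture(tmp_path_factory):
    """The default small synthetic experiment (shared across the suite)."""
    outdir = tmp_path_factory.mktemp("fixture")
    return end_to_end_fixture(small_config(SEED), outdir)


@pytest.fixture(scope="session")
def pipeline_result(sim_fixture, tmp_path_factory):
    """Full pipeline run on the shared fixture."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    fixture_dir = sim_fixture.paths["genome"].parent
    return run_on_fixture(fixture_dir, outdir, RunConfig(seed=SEED))


def tree_digest(directory) -> str:
    """Order-stable digest of every file under a directory."""
    h = hashlib.sha256()
    for p in sorted(Path(directory).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def near(planted, found, tol: int = 4) -> bool:
    """Same chrom+strand and peak within ``tol`` nt."""
    return (
        planted[0] == found[0]
        and planted[1] == found[1]
        and abs(planted[2] - found[2]) <= tol
    )
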