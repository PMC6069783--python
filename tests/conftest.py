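import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from smallrna import fixtures, pipeline
from smallrna.aligner import PlacementPolicy
from smallrna.cascade import PipelineParams


@pytest.fixture(scope="session")
def small_fixture():
    """Mixed-composition synthetic library with exact ground truth."""
    return fixtures.simulate(fixtures.FixtureParams(seed=3, n_reads=400))


@pytest.fixture(scope="session")
def fixture_paths(small_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return fixtures.write_fixture(small_fixture, outdir)


def make_config(paths, outdir, *, render=False, seed=7, structural=True, **kw):
    return pipeline.RunConfig(
        fastq=[paths["reads"]],
        genome=paths["genome"],
        te=paths["TE"],
        transcripts=paths["transcript"],
        mirna=paths["miRNA"],
        rrna=paths["rRNA"] if structural else None,
        trna=paths["tRNA"] if structural else None,
        snrna=paths["snRNA"] if structural else None,
        params=PipelineParams(),
        policy=PlacementPolicy("random_one", seed),
        outdir=outdir,
        chrom_bin=500,
        render=render,
        **kw,
    )


@pytest.fixture(scope="session")
def pipeline_run(fixture_paths, tmp_path_factory):
    """Full pipeline run (with figures) on the mixed fixture."""
    outdir = tmp_path_factory.mktemp("run")
    config = make_config(fixture_paths, outdir, render=True)
    bundle = pipeline.run_pipeline(config)
    return bundle
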